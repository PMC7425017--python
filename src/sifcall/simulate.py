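"""Synthetic fragment maps and Hi-C contact libraries with ground truth.

The generator emulates the statistical structure the caller assumes:

* a single synthetic chromosome tiled by restriction fragments with
  geometric-like lengths (a 6-cutter averages ~4 kb, a 4-cutter ~256 bp);
* planted true loops whose USF counts are Poisson(lambda_2);
* background fragment pairs whose anchor separation follows a power law
  p(d) ∝ d^alpha and whose counts are Poisson(lambda_1) per touched pair;
* a configurable fraction of self-/re-ligation artifacts.

Read positions are placed uniformly within their fragments and the output
pair stream is shuffled.  Every quantity needed to score a caller —
the planted loop list, the rates, the seed — is retained in
:class:`SimTruth`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .contacts import PAIR_COLUMNS, normalize_pairs
from .fragments import FragmentMap

__all__ = ["SimTruth", "simulate_fragment_map", "simulate_contacts",
           "default_scenario", "DEFAULT_SCENARIO"]

# The stated default world: one chromosome of 1000 ~4 kb fragments, 50
# planted loops at fragment offset >= 50 (well off the diagonal), random
# component mean 1 vs proximate mean 8, power-law decay exponent -1,
# digestion efficiency 0.7, 10% self- and 5% re-ligation artifacts, and
# 4000 read pairs so that random-ligation records dominate (~97%) the USF
# table as they do in real libraries.
DEFAULT_SCENARIO = dict(
    n_fragments=1000,
    mean_length=4000,
    n_loops=50,
    min_loop_offset=50,
    lambda_random=1.0,
    lambda_proximate=8.0,
    alpha=-1.0,
    efficiency=0.7,
    self_rate=0.10,
    re_rate=0.05,
    n_pairs=4000,
)


@dataclass
class SimTruth:
    """Ground truth of a simulated contact library."""

    loops: list[tuple[int, int]]
    lambda_random: float
    lambda_proximate: float
    alpha: float
    efficiency: float
    self_rate: float
    re_rate: float
    seed: int
    n_pairs_generated: int = 0
    chrom: str = "chrSim"

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["loops"] = [list(t) for t in self.loops]
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        d["loops"] = [tuple(t) for t in d["loops"]]
        return cls(**d)


def simulate_fragment_map(n_fragments: int, mean_length: float = 4000,
                          seed: int = 0, chrom: str = "chrSim",
                          lengths=None) -> FragmentMap:
    """One synthetic chromosome tiled by ``n_fragments`` fragments.

    Lengths are geometric with the given mean (minimum 50 bp so fragments
    stay mappable); pass ``lengths`` explicitly to reproduce a fixed layout
    such as the eight-fragment worked example.
    """
    if n_fragments < 2:
        raise ValueError("need at least 2 fragments")
    if lengths is None:
        rng = np.random.default_rng(seed)
        min_len = 50
        p = 1.0 / max(mean_length - min_len, 1.0)
        lengths = min_len + rng.geometric(p, size=n_fragments) - 1
    lengths = np.asarray(lengths, dtype=np.int64)
    if len(lengths) != n_fragments or np.any(lengths <= 0):
        raise ValueError("lengths must be positive and match n_fragments")
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    return FragmentMap({chrom: bounds}, enzyme="simulated")


def _sample_power_law_distance(rng: np.random.Generator, n: int, alpha: float,
                               d_min: float, d_max: float) -> np.ndarray:
    """Inverse-CDF samples from p(d) ∝ d^alpha on [d_min, d_max]."""
    u = rng.random(n)
    if abs(alpha + 1.0) < 1e-12:  # log-uniform special case
        return d_min * (d_max / d_min) ** u
    a1 = alpha + 1.0
    return (u * (d_max ** a1 - d_min ** a1) + d_min ** a1) ** (1.0 / a1)


def simulate_contacts(fmap: FragmentMap, truth: SimTruth, n_pairs: int,
                      seed: int | None = None) -> tuple[pd.DataFrame, SimTruth]:
    """Generate a shuffled read-pair stream realizing ``truth``.

    Budgeting: ``n_pairs`` total reads are split into self-ligation and
    re-ligation artifacts at the configured rates; each planted loop draws
    a Poisson(lambda_proximate) count; the remaining budget is spread over
    background pairs, each drawn by sampling an anchor fragment uniformly
    and a partner at a power-law distance, with a Poisson(lambda_random)
    count per touched pair.  The realized total is close to, not exactly,
    ``n_pairs``.
    """
    if n_pairs < len(truth.loops):
        raise ValueError("n_pairs must be at least the number of planted loops")
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    chrom = truth.chrom
    nfrag = fmap.n_fragments(chrom)
    bounds = fmap._boundaries(chrom)
    chrom_len = int(bounds[-1])

    for i, j in truth.loops:
        if not (0 <= i < nfrag and 0 <= j < nfrag):
            raise ValueError(f"planted loop ({i}, {j}) outside the fragment map")

    records: list[tuple[int, int]] = []  # (frag_i, frag_j) per read

    # planted loops
    loop_counts = rng.poisson(truth.lambda_proximate, size=len(truth.loops))
    loop_counts = np.maximum(loop_counts, 1)  # a planted loop exists
    for (i, j), c in zip(truth.loops, loop_counts):
        records.extend([(i, j)] * int(c))

    # artifact budget
    n_self = rng.binomial(n_pairs, truth.self_rate)
    n_re = rng.binomial(n_pairs, truth.re_rate)
    for _ in range(n_self):
        i = int(rng.integers(0, nfrag))
        records.append((i, i))
    for _ in range(n_re):
        i = int(rng.integers(0, nfrag - 1))
        records.append((i, i + 1))

    # background: spread the remaining read budget over power-law pairs
    n_background_reads = max(n_pairs - n_self - n_re - int(loop_counts.sum()), 0)
    n_bg_pairs = int(round(n_background_reads / max(truth.lambda_random, 1e-9)))
    loop_set = set(truth.loops)
    d_min = max(float(np.median(np.diff(bounds))), 1.0)
    attempts = 0
    emitted = 0
    while emitted < n_background_reads and attempts < 50 * max(n_bg_pairs, 1):
        attempts += 1
        # sample the separation first, then place it uniformly within the
        # chromosome, so the realized distance marginal is exactly d^alpha
        d = float(_sample_power_law_distance(rng, 1, truth.alpha, d_min,
                                             chrom_len - 1)[0])
        x = rng.uniform(0.0, chrom_len - d)
        i = fmap.locate(chrom, int(x))
        j = fmap.locate(chrom, int(x + d))
        a, b = min(i, j), max(i, j)
        # offset <= 1 would masquerade as self-/re-ligation artifacts
        if b - a <= 1 or (a, b) in loop_set:
            continue
        c = int(rng.poisson(truth.lambda_random))
        if c == 0:
            continue
        c = min(c, n_background_reads - emitted)
        records.extend([(a, b)] * c)
        emitted += c

    # realize read positions uniformly within fragments
    rec = np.asarray(records, dtype=np.int64)
    order = rng.permutation(len(rec))
    rec = rec[order]
    p1 = bounds[rec[:, 0]] + rng.integers(
        0, np.maximum(bounds[rec[:, 0] + 1] - bounds[rec[:, 0]], 1))
    p2 = bounds[rec[:, 1]] + rng.integers(
        0, np.maximum(bounds[rec[:, 1] + 1] - bounds[rec[:, 1]], 1))
    strands = np.array(["+", "-"])
    pairs = pd.DataFrame({
        "read_id": [f"sim_{k}" for k in range(len(rec))],
        "chrom1": chrom, "pos1": p1,
        "chrom2": chrom, "pos2": p2,
        "strand1": strands[rng.integers(0, 2, len(rec))],
        "strand2": strands[rng.integers(0, 2, len(rec))],
    })
    truth_out = SimTruth(**{**asdict(truth), "seed": seed,
                            "n_pairs_generated": len(pairs)})
    truth_out.loops = list(truth.loops)
    return normalize_pairs(pairs), truth_out


def default_scenario(seed: int = 0, **overrides) -> tuple[FragmentMap, pd.DataFrame, SimTruth]:
    """Generate the default synthetic world; see :data:`DEFAULT_SCENARIO`.

    Returns ``(fragment_map, pairs, truth)``.  Planted loop anchors are
    uniform over fragment pairs at offset >= ``min_loop_offset`` so true
    loops are clearly off-diagonal.
    """
    cfg = {**DEFAULT_SCENARIO, **overrides}
    rng = np.random.default_rng(seed)
    fmap = simulate_fragment_map(cfg["n_fragments"], cfg["mean_length"],
                                 seed=int(rng.integers(2**31)))
    nfrag = cfg["n_fragments"]
    loops: set[tuple[int, int]] = set()
    while len(loops) < cfg["n_loops"]:
        i = int(rng.integers(0, nfrag - cfg["min_loop_offset"]))
        j = int(rng.integers(i + cfg["min_loop_offset"], nfrag))
        loops.add((i, j))
    truth = SimTruth(
        loops=sorted(loops),
        lambda_random=cfg["lambda_random"],
        lambda_proximate=cfg["lambda_proximate"],
        alpha=cfg["alpha"],
        efficiency=cfg["efficiency"],
        self_rate=cfg["self_rate"],
        re_rate=cfg["re_rate"],
        seed=int(rng.integers(2**31)),
    )
    pairs, truth = simulate_contacts(fmap, truth, cfg["n_pairs"])
    return fmap, pairs, truth
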