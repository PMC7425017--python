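"""Paired-end contact parsing, ligation QC, USF score table, distance profile.

A contact library is held as a pandas DataFrame of read pairs with columns
``read_id, chrom1, pos1, strand1, chrom2, pos2, strand2``; pairs are
normalized so that (chrom1, pos1) <= (chrom2, pos2) in genome order.

Ligation classes follow the quality-control step of fragment-level Hi-C
processing: a pair whose two ends fall in the same restriction fragment is a
self-ligation (un-cut or re-circularized fragment), ends in immediately
adjacent fragments are a re-ligation (the two halves of an original cut
re-joined), everything else is a valid ligation.  Inter-chromosomal pairs are
always valid.  The score of a fragment pair — its USF count — is the number
of deduplicated valid pairs whose ends map to that (unordered) fragment pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fragments import FragmentMap

PAIR_COLUMNS = ["read_id", "chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2"]

SELF_LIGATION = "self_ligation"
RE_LIGATION = "re_ligation"
VALID = "valid"


# ---------------------------------------------------------------------------
# pairs I/O

def read_pairs(path: str | Path) -> pd.DataFrame:
    """Read a 7-column tab-delimited pairs file; '#' comment lines ignored."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=PAIR_COLUMNS,
        dtype={"read_id": str, "chrom1": str, "chrom2": str,
               "pos1": np.int64, "pos2": np.int64,
               "strand1": str, "strand2": str},
    )
    return normalize_pairs(df)


def write_pairs(pairs: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        pairs[PAIR_COLUMNS].to_csv(fh, sep="\t", header=False, index=False)


def normalize_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Order each pair so (chrom1, pos1) <= (chrom2, pos2) genome-wise."""
    pairs = pairs.reset_index(drop=True)
    swap = (pairs["chrom1"] > pairs["chrom2"]) | (
        (pairs["chrom1"] == pairs["chrom2"]) & (pairs["pos1"] > pairs["pos2"])
    )
    if swap.any():
        pairs = pairs.copy()
        for a, b in (("chrom1", "chrom2"), ("pos1", "pos2"), ("strand1", "strand2")):
            pairs.loc[swap, [a, b]] = pairs.loc[swap, [b, a]].to_numpy()
    return pairs


def deduplicate_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Collapse PCR duplicates: identical (chrom,pos,strand) on both ends."""
    key = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]
    return pairs.drop_duplicates(subset=key, keep="first").reset_index(drop=True)


# ---------------------------------------------------------------------------
# ligation classification

def classify_pairs(pairs: pd.DataFrame, fmap: FragmentMap) -> pd.Series:
    """Vectorized ligation class per pair."""
    labels = np.full(len(pairs), VALID, dtype=object)
    intra = (pairs["chrom1"] == pairs["chrom2"]).to_numpy()
    for chrom in pairs.loc[intra, "chrom1"].unique():
        sel = intra & (pairs["chrom1"] == chrom).to_numpy()
        i = fmap.locate_many(chrom, pairs.loc[sel, "pos1"].to_numpy())
        j = fmap.locate_many(chrom, pairs.loc[sel, "pos2"].to_numpy())
        off = np.abs(i - j)
        lab = np.where(off == 0, SELF_LIGATION, np.where(off == 1, RE_LIGATION, VALID))
        labels[sel] = lab
    # inter-chromosomal ends still must be mappable
    for chrom, pos_col in (("chrom1", "pos1"), ("chrom2", "pos2")):
        inter = ~intra
        for c in pairs.loc[inter, chrom].unique():
            sel = inter & (pairs[chrom] == c).to_numpy()
            fmap.locate_many(c, pairs.loc[sel, pos_col].to_numpy())
    return pd.Series(labels, index=pairs.index, name="ligation_class")


def classify_pair(read_pair, fmap: FragmentMap) -> str:
    """Ligation class of a single pair (mapping or namedtuple-like)."""
    p = read_pair if isinstance(read_pair, dict) else read_pair._asdict()
    if p["chrom1"] != p["chrom2"]:
        fmap.locate(p["chrom1"], p["pos1"])
        fmap.locate(p["chrom2"], p["pos2"])
        return VALID
    i = fmap.locate(p["chrom1"], p["pos1"])
    j = fmap.locate(p["chrom2"], p["pos2"])
    if i == j:
        return SELF_LIGATION
    if abs(i - j) == 1:
        return RE_LIGATION
    return VALID


def qc_report(pairs: pd.DataFrame, fmap: FragmentMap) -> dict:
    """Counts of self-/re-/valid-ligation events after deduplication."""
    dedup = deduplicate_pairs(pairs)
    classes = classify_pairs(dedup, fmap)
    counts = classes.value_counts().to_dict()
    return {
        "total": len(pairs),
        "deduplicated": len(dedup),
        SELF_LIGATION: int(counts.get(SELF_LIGATION, 0)),
        RE_LIGATION: int(counts.get(RE_LIGATION, 0)),
        VALID: int(counts.get(VALID, 0)),
    }


# ---------------------------------------------------------------------------
# USF score table

USF_COLUMNS = ["chrom1", "idx1", "chrom2", "idx2", "score"]


def build_usf_table(
    pairs: pd.DataFrame,
    fmap: FragmentMap,
    intra_only: bool = True,
    deduplicate: bool = True,
) -> pd.DataFrame:
    """Tally valid pairs into one record per unordered fragment pair.

    Returns a DataFrame with columns ``chrom1, idx1, chrom2, idx2, score``
    where (idx1, idx2) are fragment indices with idx1 <= idx2 for
    intra-chromosomal records.
    """
    if deduplicate:
        pairs = deduplicate_pairs(pairs)
    if len(pairs) == 0:
        return pd.DataFrame(columns=USF_COLUMNS).astype(
            {"idx1": np.int64, "idx2": np.int64, "score": np.int64})
    pairs = normalize_pairs(pairs)
    if intra_only:
        pairs = pairs[pairs["chrom1"] == pairs["chrom2"]]
    idx1 = np.empty(len(pairs), dtype=np.int64)
    idx2 = np.empty(len(pairs), dtype=np.int64)
    for chrom in pd.unique(pd.concat([pairs["chrom1"], pairs["chrom2"]])):
        sel1 = (pairs["chrom1"] == chrom).to_numpy()
        sel2 = (pairs["chrom2"] == chrom).to_numpy()
        idx1[sel1] = fmap.locate_many(chrom, pairs.loc[sel1, "pos1"].to_numpy())
        idx2[sel2] = fmap.locate_many(chrom, pairs.loc[sel2, "pos2"].to_numpy())
    rec = pd.DataFrame({
        "chrom1": pairs["chrom1"].to_numpy(),
        "idx1": idx1,
        "chrom2": pairs["chrom2"].to_numpy(),
        "idx2": idx2,
    })
    intra = rec["chrom1"] == rec["chrom2"]
    flip = intra & (rec["idx1"] > rec["idx2"])
    rec.loc[flip, ["idx1", "idx2"]] = rec.loc[flip, ["idx2", "idx1"]].to_numpy()
    out = (
        rec.groupby(["chrom1", "idx1", "chrom2", "idx2"], sort=True)
        .size()
        .reset_index(name="score")
    )
    return out


def usf_to_bedpe(records: pd.DataFrame, fmap: FragmentMap, path: str | Path) -> None:
    """Write USF records as BEDPE (fragment intervals, name, score)."""
    with open(path, "w") as fh:
        for n, row in enumerate(records.itertuples(index=False)):
            f1 = fmap.fragment(row.chrom1, int(row.idx1))
            f2 = fmap.fragment(row.chrom2, int(row.idx2))
            fh.write(
                f"{f1.chrom}\t{f1.start}\t{f1.end}\t{f2.chrom}\t{f2.start}\t{f2.end}"
                f"\tusf_{n}\t{int(row.score)}\n"
            )


def usf_from_bedpe(path: str | Path, fmap: FragmentMap) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            c1, s1, _e1, c2, s2, _e2, _name, score = line.rstrip("\n").split("\t")[:8]
            rows.append((c1, fmap.locate(c1, int(s1)), c2, fmap.locate(c2, int(s2)),
                         int(score)))
    return pd.DataFrame(rows, columns=USF_COLUMNS)


# ---------------------------------------------------------------------------
# distance profile

@dataclass
class DistanceProfile:
    """Ligation probability versus genomic distance.

    ``edges`` are bin edges (length m+1, strictly increasing, bp);
    ``probability`` is the fraction of intra-chromosomal pairs per bin
    (sums to 1 over non-empty support).
    """

    edges: np.ndarray
    probability: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.probability = np.asarray(self.probability, dtype=float)
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if abs(self.probability.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    @property
    def centers(self) -> np.ndarray:
        # geometric centers suit the log-spaced default binning
        return np.sqrt(self.edges[:-1] * self.edges[1:])


def log_bins(d_min: float, d_max: float, bins_per_decade: int = 50) -> np.ndarray:
    """Logarithmic bin edges, default 50 per decade."""
    n = max(2, int(np.ceil(np.log10(d_max / d_min) * bins_per_decade)) + 1)
    return np.logspace(np.log10(d_min), np.log10(d_max), n)


def distance_profile(
    pairs: pd.DataFrame,
    edges: np.ndarray | None = None,
    d_min: float = 1e3,
    bins_per_decade: int = 50,
) -> DistanceProfile:
    """Empirical ligation probability per genomic-distance bin.

    Distances are |pos2 − pos1| of intra-chromosomal pairs; counts are
    normalized to probabilities.  Default binning is logarithmic from
    ``d_min`` (1 kb) to the largest observed distance.
    """
    intra = pairs[pairs["chrom1"] == pairs["chrom2"]]
    if len(intra) == 0:
        raise ValueError("no intra-chromosomal pairs")
    d = np.abs(intra["pos2"].to_numpy() - intra["pos1"].to_numpy()).astype(float)
    if edges is None:
        edges = log_bins(d_min, max(float(d.max()), d_min * 10), bins_per_decade)
    counts, _ = np.histogram(d, bins=edges)
    total = counts.sum()
    if total == 0:
        raise ValueError("no pairs fall inside the bin range")
    return DistanceProfile(edges=np.asarray(edges, float), probability=counts / total)


# ---------------------------------------------------------------------------
# reservoir subsampling

def subsample_pairs(pairs: pd.DataFrame, n: int, seed: int) -> pd.DataFrame:
    """Uniform subsample of ``n`` pairs by reservoir sampling (Algorithm R).

    Single streaming pass with an explicitly seeded 64-bit PRNG; every pair
    has inclusion probability ``min(n, M)/M``.  Returns rows in order of
    first appearance in the reservoir, reproducibly for a given seed.
    """
    if n < 0:
        raise ValueError("target count must be non-negative")
    rng = np.random.default_rng(seed)
    reservoir: list[int] = []
    for t, row_index in enumerate(pairs.index):
        if t < n:
            reservoir.append(row_index)
        else:
            j = int(rng.integers(0, t + 1))
            if j < n:
                reservoir[j] = row_index
    return pairs.loc[reservoir].reset_index(drop=True)
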