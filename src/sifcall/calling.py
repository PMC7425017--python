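"""Significant-interaction calling: empirical null, local FDR, FTR, merging.

For a fragment-pair score d the local false discovery rate is

    FDR_d = FP_d / (FP_d + TP_d),

where TP_d is the Poisson density of the proximate mixture component
(mean lambda_2) and FP_d is an empirical null density built by resampling
scores uniformly at random from the observed score multiset a large number
of times (Np).  With no biological replication no p-value can be computed,
which is why the local-FDR route is used rather than a global
Benjamini-Hochberg procedure.

Candidates must additionally exceed the fragment threshold rate (FTR), an
integer count floor: a record is retained when ``score > FTR`` and
``FDR_score < fdr_threshold``.  Retained single-fragment calls whose anchors
are adjacent on both sides and share the same score are merged (like ChIP-seq
peak summits) into one interaction; the merged anchor interval's length is
the call's per-side resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .fragments import FragmentMap
from .mixture import PoissonMixture

__all__ = [
    "FdrTable", "SIF", "empirical_null", "tp_density", "local_fdr",
    "build_fdr_table", "call_sifs", "merge_equal_score",
    "write_sif_bedpe", "read_sif_bedpe",
]


# ---------------------------------------------------------------------------
# densities and FDR


def empirical_null(scores, n_resample: int = 100_000, seed: int = 0) -> pd.Series:
    """Empirical false-positive density by score resampling.

    Draws ``n_resample`` (Np) scores uniformly with replacement from the
    observed score multiset and returns the normalized histogram indexed by
    integer score.
    """
    d = np.asarray(scores, dtype=np.int64)
    if d.size == 0:
        raise ValueError("cannot build a null from an empty record set")
    if n_resample < 1:
        raise ValueError("Np must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.choice(d, size=n_resample, replace=True)
    counts = np.bincount(draws)
    dens = counts / n_resample
    support = np.nonzero(dens)[0]
    return pd.Series(dens[support], index=support, name="fp")


def tp_density(model: PoissonMixture, max_score: int | None = None) -> pd.Series:
    """True-positive density: Poisson pmf of the proximate component.

    The proximate component is the larger mean lambda_2; raises if the two
    fitted means are indistinct.
    """
    lam1, lam2 = float(model.lambdas_[0]), float(model.lambdas_[-1])
    if lam2 <= lam1 + 1e-9:
        raise ValueError("mixture components indistinct (lambda_2 <= lambda_1)")
    if max_score is None:
        max_score = int(stats.poisson.ppf(1 - 1e-12, lam2)) + 1
    support = np.arange(max_score + 1)
    return pd.Series(stats.poisson.pmf(support, lam2), index=support, name="tp")


def local_fdr(score: int, fp: pd.Series, tp: pd.Series) -> float:
    """FDR_d = FP_d / (FP_d + TP_d) for one integer score."""
    fp_d = float(fp.get(score, 0.0))
    tp_d = float(tp.get(score, 0.0))
    if fp_d + tp_d <= 0.0:
        raise ValueError(f"FDR undefined at score {score}: FP + TP = 0")
    return fp_d / (fp_d + tp_d)


@dataclass
class FdrTable:
    """Per-score TP/FP densities and local FDR values.

    ``table`` is indexed by integer score with columns fp, tp, fdr.  Scores
    above the top of the support inherit the last defined FDR (conservative
    tail handling); FDR is applied as a step function over integer scores.
    """

    table: pd.DataFrame
    n_resample: int

    def fdr(self, score: int) -> float:
        idx = self.table.index
        if score in idx:
            return float(self.table.loc[score, "fdr"])
        if score > idx.max():
            return float(self.table["fdr"].iloc[-1])
        lower = idx[idx < score]
        if len(lower) == 0:
            return 1.0  # below the observed support: no evidence of signal
        return float(self.table.loc[lower.max(), "fdr"])

    def fdr_many(self, scores) -> np.ndarray:
        return np.array([self.fdr(int(s)) for s in np.asarray(scores)])


def build_fdr_table(scores, model: PoissonMixture, n_resample: int = 100_000,
                    seed: int = 0) -> FdrTable:
    """Assemble the FDR table from the empirical null and the TP density."""
    fp = empirical_null(scores, n_resample=n_resample, seed=seed)
    max_score = int(max(fp.index.max(), np.asarray(scores).max()))
    tp = tp_density(model, max_score=max_score)
    support = np.arange(max_score + 1)
    fp_full = fp.reindex(support, fill_value=0.0)
    tp_full = tp.reindex(support, fill_value=0.0)
    denom = fp_full + tp_full
    fdr = np.where(denom > 0, fp_full / denom.replace(0, np.nan), np.nan)
    tab = pd.DataFrame({"fp": fp_full, "tp": tp_full, "fdr": fdr}, index=support)
    tab = tab[denom > 0]
    return FdrTable(table=tab, n_resample=n_resample)


# ---------------------------------------------------------------------------
# calling and merging


@dataclass
class SIF:
    """A called significant interaction with merged anchors.

    Anchors are half-open genomic intervals spanning the member restriction
    fragments; ``resolution1``/``resolution2`` are the anchor lengths in bp.
    """

    chrom1: str
    start1: int
    end1: int
    chrom2: str
    start2: int
    end2: int
    score: int
    fdr: float
    fragments1: list[int] = field(default_factory=list)
    fragments2: list[int] = field(default_factory=list)

    @property
    def resolution1(self) -> int:
        return self.end1 - self.start1

    @property
    def resolution2(self) -> int:
        return self.end2 - self.start2


def call_sifs(records: pd.DataFrame, ftr: int, fdr_threshold: float,
              fdr_table: FdrTable) -> pd.DataFrame:
    """Double filter: retain records with score > FTR and FDR_score < cutoff.

    Returns the retained records with an ``fdr`` column appended; each row is
    a single-fragment-anchor candidate call.
    """
    if len(records) == 0:
        return records.assign(fdr=np.array([], dtype=float))
    scores = records["score"].to_numpy()
    fdr = fdr_table.fdr_many(scores)
    keep = (scores > ftr) & (fdr < fdr_threshold)
    return records.assign(fdr=fdr)[keep].reset_index(drop=True)


def merge_equal_score(calls: pd.DataFrame, fmap: FragmentMap) -> list[SIF]:
    """Merge equal-score calls adjacent on both anchors into single SIFs.

    Two calls merge when their anchor-1 fragments are adjacent (index offset
    exactly 1), their anchor-2 fragments are adjacent, and their scores are
    equal; merging is transitive (union-find over the merge graph).  The
    merged anchor interval spans the member fragments on each side and its
    length is the per-side resolution.
    """
    n = len(calls)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    rows = calls.reset_index(drop=True)
    # group by (chrom pair, score); only same-score same-chromosome calls can merge
    by_key: dict[tuple, list[int]] = {}
    for r, row in enumerate(rows.itertuples(index=False)):
        by_key.setdefault((row.chrom1, row.chrom2, row.score), []).append(r)
    for members in by_key.values():
        for a_pos, a in enumerate(members):
            ra = rows.iloc[a]
            for b in members[a_pos + 1:]:
                rb = rows.iloc[b]
                if (abs(int(ra["idx1"]) - int(rb["idx1"])) == 1
                        and abs(int(ra["idx2"]) - int(rb["idx2"])) == 1):
                    union(a, b)

    groups: dict[int, list[int]] = {}
    for r in range(n):
        groups.setdefault(find(r), []).append(r)

    sifs = []
    for members in groups.values():
        sub = rows.iloc[members]
        chrom1 = sub["chrom1"].iloc[0]
        chrom2 = sub["chrom2"].iloc[0]
        frags1 = sorted(int(i) for i in sub["idx1"].unique())
        frags2 = sorted(int(j) for j in sub["idx2"].unique())
        f1 = [fmap.fragment(chrom1, i) for i in frags1]
        f2 = [fmap.fragment(chrom2, j) for j in frags2]
        sifs.append(SIF(
            chrom1=chrom1, start1=f1[0].start, end1=f1[-1].end,
            chrom2=chrom2, start2=f2[0].start, end2=f2[-1].end,
            score=int(sub["score"].iloc[0]),
            fdr=float(sub["fdr"].min()) if "fdr" in sub else float("nan"),
            fragments1=frags1, fragments2=frags2,
        ))
    sifs.sort(key=lambda s: (s.chrom1, s.start1, s.chrom2, s.start2))
    return sifs


# ---------------------------------------------------------------------------
# BEDPE I/O


def write_sif_bedpe(sifs: list[SIF], path: str | Path, header: str | None = None) -> None:
    """BEDPE with name, score, fdr and per-side resolution columns."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for n, s in enumerate(sifs):
            fh.write(
                f"{s.chrom1}\t{s.start1}\t{s.end1}\t{s.chrom2}\t{s.start2}\t{s.end2}"
                f"\tsif_{n}\t{s.score}\t{s.fdr:.6g}\t{s.resolution1}\t{s.resolution2}\n"
            )


def read_sif_bedpe(path: str | Path) -> list[SIF]:
    sifs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            sifs.append(SIF(
                chrom1=f[0], start1=int(f[1]), end1=int(f[2]),
                chrom2=f[3], start2=int(f[4]), end2=int(f[5]),
                score=int(f[7]) if len(f) > 7 else 0,
                fdr=float(f[8]) if len(f) > 8 else float("nan"),
            ))
    return sifs
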