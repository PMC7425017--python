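"""Loop-set evaluation: aggregate peak analysis and ROC/AUC.

APA sums fixed-size contact-matrix submatrices centered on each loop call;
a real loop set shows a focal enrichment of the central pixel over the
corner background.  The APA value is the ratio of the central pixel to the
mean of the lower-left corner block (the corner farthest from the diagonal
for an upper-triangular intra-chromosomal matrix), with the other three
corner ratios reported as diagnostics.

ROC evaluation takes a fixed universe of putative loops, labels each
positive when it overlaps a reference loop set (e.g. ChIA-PET), predicts
each from overlap with the called set at a sweeping score/FDR threshold,
and accumulates TP/FP/TN/FN per threshold: TPR = TP/(TP+FN),
FPR = FP/(FP+TN); AUC by the trapezoid rule with (0,0) and (1,1) endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation import _match_flags
from .calling import SIF

__all__ = ["ContactMatrix", "ROCResult", "apa", "roc_curve"]


class ContactMatrix:
    """Sparse upper-triangular binned contact counts for one chromosome."""

    def __init__(self, chrom: str, bin_size: int,
                 counts: dict[tuple[int, int], float] | None = None):
        self.chrom = chrom
        self.bin_size = int(bin_size)
        self._counts: dict[tuple[int, int], float] = {}
        for (i, j), v in (counts or {}).items():
            self.set(i, j, v)

    def set(self, i: int, j: int, value: float) -> None:
        if value < 0:
            raise ValueError("counts must be non-negative")
        if i > j:
            i, j = j, i
        self._counts[(i, j)] = float(value)

    def get(self, i: int, j: int) -> float:
        if i > j:
            i, j = j, i
        return self._counts.get((i, j), 0.0)

    def submatrix(self, center_i: int, center_j: int, window: int) -> np.ndarray:
        """(2w+1)×(2w+1) dense block centered on (center_i, center_j)."""
        w = window
        out = np.zeros((2 * w + 1, 2 * w + 1))
        for a in range(-w, w + 1):
            for b in range(-w, w + 1):
                out[a + w, b + w] = self.get(center_i + a, center_j + b)
        return out

    @classmethod
    def from_text(cls, path: str | Path) -> "ContactMatrix":
        """Read 4-column triples (chrom, bin_i, bin_j, count).

        The header line ``# chrom=<name> bin_size=<bp>`` declares metadata.
        """
        chrom, bin_size = None, None
        counts: dict[tuple[int, int], float] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    meta = dict(kv.split("=", 1)
                                for kv in line.lstrip("# ").split() if "=" in kv)
                    chrom = meta.get("chrom", chrom)
                    bin_size = int(meta.get("bin_size", bin_size or 0)) or bin_size
                    continue
                if not line.strip():
                    continue
                c, i, j, v = line.split()
                chrom = chrom or c
                counts[(int(i), int(j))] = float(v)
        if chrom is None or not bin_size:
            raise ValueError("matrix file must declare chrom and bin_size in a header")
        return cls(chrom, bin_size, counts)

    def to_text(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# chrom={self.chrom} bin_size={self.bin_size}\n")
            for (i, j), v in sorted(self._counts.items()):
                fh.write(f"{self.chrom}\t{i}\t{j}\t{v:g}\n")


def apa(loops: list[SIF], matrix: ContactMatrix, window: int = 5,
        ) -> tuple[np.ndarray, float, dict]:
    """Aggregate peak analysis of a loop set on a binned contact matrix.

    Loops closer than ``2*window`` bins to the diagonal are excluded to
    avoid diagonal contamination.  Returns the summed (2w+1)×(2w+1)
    submatrix, the APA value (central pixel over the mean of the w×w
    lower-left corner block), and the four corner ratios as diagnostics.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    w = window
    agg = np.zeros((2 * w + 1, 2 * w + 1))
    used = 0
    for loop in loops:
        if loop.chrom1 != matrix.chrom or loop.chrom2 != matrix.chrom:
            continue
        bi = int((0.5 * (loop.start1 + loop.end1)) // matrix.bin_size)
        bj = int((0.5 * (loop.start2 + loop.end2)) // matrix.bin_size)
        if bi > bj:
            bi, bj = bj, bi
        if bj - bi <= 2 * w:
            continue  # too close to the diagonal
        agg += matrix.submatrix(bi, bj, w)
        used += 1
    if used == 0:
        raise ValueError("no eligible loops for APA")
    center = agg[w, w]
    corners = {
        # array row 0 = lowest bin_i; "lower left" = largest i, smallest j
        "lower_left": agg[w + 1:, :w],
        "upper_left": agg[:w, :w],
        "upper_right": agg[:w, w + 1:],
        "lower_right": agg[w + 1:, w + 1:],
    }
    ratios = {name: float(center / block.mean()) if block.mean() > 0 else float("inf")
              for name, block in corners.items()}
    return agg, ratios["lower_left"], {"n_loops": used, "corner_ratios": ratios}


@dataclass
class ROCResult:
    """ROC points ordered from strict to permissive thresholds."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    counts: list[dict] = field(default_factory=list)


def roc_curve(universe: list[SIF], called: list[SIF], reference: list[SIF],
              slack: int = 5000, score_attr: str = "score") -> ROCResult:
    """ROC of a called loop set against a reference, over a putative universe.

    Each putative loop is positive iff it overlaps the reference set
    (reciprocal anchor overlap with ``slack`` bp).  At each threshold t over
    the called loops' ``score_attr``, a putative loop is predicted positive
    iff it overlaps a called loop with score >= t.  For ``score_attr="fdr"``
    pass negated FDRs upstream or use scores; sweeping uses >= on the
    attribute value.
    """
    if not universe:
        raise ValueError("empty putative-loop universe")
    labels = _match_flags(universe, reference, slack)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("universe must contain both positive and negative loops")

    # best (max) called score overlapping each universe loop; -inf if none
    from .annotation import _anchors_match
    by_chrom: dict[tuple[str, str], list[SIF]] = {}
    for c in called:
        by_chrom.setdefault((c.chrom1, c.chrom2), []).append(c)
    best = np.full(len(universe), -np.inf)
    for idx, u in enumerate(universe):
        for c in by_chrom.get((u.chrom1, u.chrom2), ()):
            s = getattr(c, score_attr)
            if s > best[idx] and _anchors_match(u, c, slack):
                best[idx] = s

    thresholds = np.unique(best[np.isfinite(best)])[::-1]
    tpr_list, fpr_list, counts = [0.0], [0.0], []
    for t in thresholds:
        pred = best >= t
        tp = int((pred & labels).sum())
        fp = int((pred & ~labels).sum())
        fn = n_pos - tp
        tn = n_neg - fp
        tpr_list.append(tp / (tp + fn))
        fpr_list.append(fp / (fp + tn))
        counts.append({"threshold": float(t), "TP": tp, "FP": fp, "TN": tn, "FN": fn})
    tpr_list.append(1.0)
    fpr_list.append(1.0)
    fpr_arr = np.asarray(fpr_list)
    tpr_arr = np.asarray(tpr_list)
    auc = float(np.trapezoid(tpr_arr, fpr_arr))
    return ROCResult(thresholds=thresholds, tpr=tpr_arr, fpr=fpr_arr,
                     auc=auc, counts=counts)
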