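"""Promoter-distal loop classification and loop-set comparison.

A called interaction is a promoter-distal loop (PDL) when one anchor lies in
a promoter window around a TSS (upstream 5 kb / downstream 1 kb, mirrored
for minus-strand genes) and the other anchor lies within +/-100 kb of some
TSS outside any promoter window.  If the distal anchor's closest gene is the
same gene whose promoter holds the other anchor the loop is P1D1; if it is a
different gene, P1D2.  Anchor membership is tested by anchor midpoint, which
keeps each anchor in at most one promoter window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calling import SIF

__all__ = [
    "GeneAnnotation", "PDLCall", "read_genes_gtf", "read_genes_bed",
    "classify_pdl", "classify_pdls", "compare_conditions", "replicate_overlap",
]

P1D1 = "P1D1"
P1D2 = "P1D2"
NOT_PDL = "not_PDL"

PROMOTER_UPSTREAM = 5_000
PROMOTER_DOWNSTREAM = 1_000
DISTAL_HALF_WIDTH = 100_000


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene: id, chromosome, TSS (0-based bp) and strand."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def promoter_window(self, upstream: int = PROMOTER_UPSTREAM,
                        downstream: int = PROMOTER_DOWNSTREAM) -> tuple[int, int]:
        """Strand-aware half-open promoter interval around the TSS."""
        if self.strand == "+":
            return (self.tss - upstream, self.tss + downstream)
        return (self.tss - downstream, self.tss + upstream)

    def distal_window(self, half_width: int = DISTAL_HALF_WIDTH) -> tuple[int, int]:
        return (self.tss - half_width, self.tss + half_width)


@dataclass
class PDLCall:
    sif: SIF
    category: str
    promoter_gene: str | None = None
    distal_gene: str | None = None


# ---------------------------------------------------------------------------
# annotation input


def read_genes_gtf(path: str | Path) -> list[GeneAnnotation]:
    """Genes from GTF ``gene`` feature lines; TSS = start for +, end−1 for −.

    GTF is 1-based inclusive; positions are converted to 0-based.
    """
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            chrom, start, end, strand, attrs = f[0], int(f[3]), int(f[4]), f[6], f[8]
            gene_id = None
            for kv in attrs.split(";"):
                kv = kv.strip()
                if kv.startswith("gene_id"):
                    gene_id = kv.split(None, 1)[1].strip().strip('"')
                    break
            if gene_id is None:
                continue
            tss = start - 1 if strand == "+" else end - 1
            genes.append(GeneAnnotation(gene_id, chrom, tss, strand))
    return genes


def read_genes_bed(path: str | Path) -> list[GeneAnnotation]:
    """Genes from 6-column BED (chrom start end name score strand)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            tss = int(start) if strand == "+" else int(end) - 1
            genes.append(GeneAnnotation(name, chrom, tss, strand))
    return genes


# ---------------------------------------------------------------------------
# PDL classification


def _promoter_gene(mid: float, genes: list[GeneAnnotation]) -> GeneAnnotation | None:
    """Gene whose promoter window contains the midpoint; nearest-TSS ties."""
    hits = [g for g in genes
            if g.promoter_window()[0] <= mid < g.promoter_window()[1]]
    if not hits:
        return None
    return min(hits, key=lambda g: (abs(mid - g.tss), g.gene_id))


def _closest_gene(mid: float, genes: list[GeneAnnotation]) -> GeneAnnotation:
    return min(genes, key=lambda g: (abs(mid - g.tss), g.gene_id))


def classify_pdl(sif: SIF, genes: list[GeneAnnotation]) -> PDLCall:
    """Classify one interaction as P1D1, P1D2 or not a PDL.

    One anchor must sit in a promoter window and the other in a distal
    window (+/-100 kb of some TSS, outside every promoter window); the
    distal anchor's closest gene (minimal |midpoint − TSS| over all genes)
    decides P1D1 (same gene) vs P1D2 (different gene).
    """
    if sif.chrom1 != sif.chrom2:
        return PDLCall(sif, NOT_PDL)
    chrom_genes = [g for g in genes if g.chrom == sif.chrom1]
    if not chrom_genes:
        return PDLCall(sif, NOT_PDL)
    mids = (0.5 * (sif.start1 + sif.end1), 0.5 * (sif.start2 + sif.end2))
    for prom_end, distal_end in ((0, 1), (1, 0)):
        prom_gene = _promoter_gene(mids[prom_end], chrom_genes)
        if prom_gene is None:
            continue
        dm = mids[distal_end]
        if _promoter_gene(dm, chrom_genes) is not None:
            continue  # both ends promoter-bound: not promoter-distal
        in_distal = any(g.distal_window()[0] <= dm < g.distal_window()[1]
                        for g in chrom_genes)
        if not in_distal:
            continue
        closest = _closest_gene(dm, chrom_genes)
        category = P1D1 if closest.gene_id == prom_gene.gene_id else P1D2
        return PDLCall(sif, category, prom_gene.gene_id, closest.gene_id)
    return PDLCall(sif, NOT_PDL)


def classify_pdls(sifs: list[SIF], genes: list[GeneAnnotation]) -> list[PDLCall]:
    return [classify_pdl(s, genes) for s in sifs]


# ---------------------------------------------------------------------------
# loop-set comparison


def _anchors_match(a: SIF, b: SIF, slack: int) -> bool:
    """Reciprocal anchor overlap after extending each anchor by slack bp."""
    def ov(c1, s1, e1, c2, s2, e2):
        return c1 == c2 and s1 - slack < e2 + slack and s2 - slack < e1 + slack
    return (ov(a.chrom1, a.start1, a.end1, b.chrom1, b.start1, b.end1)
            and ov(a.chrom2, a.start2, a.end2, b.chrom2, b.start2, b.end2))


def _match_flags(sifs_a: list[SIF], sifs_b: list[SIF], slack: int) -> np.ndarray:
    """For each SIF in a, whether it matches >= 1 SIF in b (sweep by chrom)."""
    flags = np.zeros(len(sifs_a), dtype=bool)
    by_chrom: dict[tuple[str, str], list[SIF]] = {}
    for b in sifs_b:
        by_chrom.setdefault((b.chrom1, b.chrom2), []).append(b)
    for i, a in enumerate(sifs_a):
        for b in by_chrom.get((a.chrom1, a.chrom2), ()):
            if _anchors_match(a, b, slack):
                flags[i] = True
                break
    return flags


def compare_conditions(sifs_a: list[SIF], sifs_b: list[SIF], slack: int = 5000) -> dict:
    """Partition two loop sets into common / lost (unique to a) / gained.

    Matching is one-to-many-aware: a loop is "common" when it matches at
    least one loop in the other set, so the two common counts can differ.
    """
    in_b = _match_flags(sifs_a, sifs_b, slack)
    in_a = _match_flags(sifs_b, sifs_a, slack)
    return {
        "common_a": [s for s, f in zip(sifs_a, in_b) if f],
        "common_b": [s for s, f in zip(sifs_b, in_a) if f],
        "unique_a": [s for s, f in zip(sifs_a, in_b) if not f],
        "unique_b": [s for s, f in zip(sifs_b, in_a) if not f],
        "counts": {
            "a": len(sifs_a), "b": len(sifs_b),
            "common_a": int(in_b.sum()), "common_b": int(in_a.sum()),
            "unique_a": int((~in_b).sum()), "unique_b": int((~in_a).sum()),
        },
    }


def _extend_to_size(s: SIF, size: int) -> SIF:
    """Pad both anchors symmetrically out to at least ``size`` bp."""
    def pad(start, end):
        grow = max(0, size - (end - start))
        lo = grow // 2
        return start - lo, end + (grow - lo)
    s1, e1 = pad(s.start1, s.end1)
    s2, e2 = pad(s.start2, s.end2)
    return SIF(s.chrom1, s1, e1, s.chrom2, s2, e2, s.score, s.fdr)


def replicate_overlap(sifs_a: list[SIF], sifs_b: list[SIF],
                      extensions: list[int], fdr_cutoffs: list[float]) -> pd.DataFrame:
    """Fraction of set-a loops matched in set-b per (extension, FDR cutoff).

    Both sets are restricted to FDR < cutoff and anchors padded to the
    stated fragment size before matching; an empty restricted set-a gives
    NaN, not 0.
    """
    rows = []
    for cutoff in fdr_cutoffs:
        a_cut = [s for s in sifs_a if s.fdr < cutoff]
        b_cut = [s for s in sifs_b if s.fdr < cutoff]
        for ext in extensions:
            a_ext = [_extend_to_size(s, ext) for s in a_cut]
            b_ext = [_extend_to_size(s, ext) for s in b_cut]
            if not a_ext:
                frac = float("nan")
            else:
                frac = float(_match_flags(a_ext, b_ext, slack=0).mean())
            rows.append({"extension": ext, "fdr_cutoff": cutoff, "overlap": frac})
    return pd.DataFrame(rows)
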