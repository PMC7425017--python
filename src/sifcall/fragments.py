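"""Restriction-fragment coordinate system.

In-silico digestion of genome sequences into restriction fragments, position
-> fragment lookup, and BED serialization.  All coordinates are 0-based
half-open (BED convention).  Fragments on one chromosome are non-overlapping,
sorted, and tile the sequence with no gaps, so a fragment is fully determined
by the ordered cut positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
from Bio import SeqIO

# Built-in enzyme presets: recognition site and cut offset within the site.
# HindIII cuts A^AGCTT, MboI/DpnII cut ^GATC.
ENZYMES: dict[str, tuple[str, int]] = {
    "HindIII": ("AAGCTT", 1),
    "MboI": ("GATC", 0),
    "DpnII": ("GATC", 0),
}

_PALINDROME = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class RestrictionFragment:
    """A single restriction fragment: half-open interval plus its ordinal."""

    chrom: str
    start: int
    end: int
    index: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"degenerate fragment [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


class FragmentMap:
    """Ordered restriction fragments per chromosome.

    Internally each chromosome is an array of boundary positions
    ``[0, c1, ..., cm, L]``; fragment *i* spans ``[bounds[i], bounds[i+1])``.
    Lookup by position is ``searchsorted`` on the boundaries, total over
    ``[0, L)``.
    """

    def __init__(
        self,
        boundaries: Mapping[str, np.ndarray],
        enzyme: str = "custom",
        site: str = "",
        cut_offset: int = 0,
    ) -> None:
        self._bounds: dict[str, np.ndarray] = {}
        for chrom, b in boundaries.items():
            arr = np.asarray(b, dtype=np.int64)
            if arr.size < 2 or arr[0] != 0:
                raise ValueError(f"{chrom}: boundaries must start at 0 and define >=1 fragment")
            if np.any(np.diff(arr) <= 0):
                raise ValueError(f"{chrom}: boundaries must be strictly increasing")
            self._bounds[chrom] = arr
        self.enzyme = enzyme
        self.site = site
        self.cut_offset = cut_offset

    # -- basic queries ---------------------------------------------------

    @property
    def chromosomes(self) -> list[str]:
        return list(self._bounds)

    def chrom_length(self, chrom: str) -> int:
        return int(self._boundaries(chrom)[-1])

    def n_fragments(self, chrom: str) -> int:
        return len(self._boundaries(chrom)) - 1

    def _boundaries(self, chrom: str) -> np.ndarray:
        try:
            return self._bounds[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def fragment(self, chrom: str, index: int) -> RestrictionFragment:
        b = self._boundaries(chrom)
        if not 0 <= index < len(b) - 1:
            raise IndexError(f"fragment index {index} out of range for {chrom}")
        return RestrictionFragment(chrom, int(b[index]), int(b[index + 1]), index)

    def fragments(self, chrom: str) -> Iterator[RestrictionFragment]:
        b = self._boundaries(chrom)
        for i in range(len(b) - 1):
            yield RestrictionFragment(chrom, int(b[i]), int(b[i + 1]), i)

    def lengths(self, chrom: str) -> np.ndarray:
        return np.diff(self._boundaries(chrom))

    def midpoints(self, chrom: str) -> np.ndarray:
        b = self._boundaries(chrom)
        return 0.5 * (b[:-1] + b[1:])

    # -- position -> fragment --------------------------------------------

    def locate(self, chrom: str, pos: int) -> int:
        """Index of the fragment with ``start <= pos < end``."""
        b = self._boundaries(chrom)
        if not 0 <= pos < b[-1]:
            raise ValueError(f"position {pos} outside [0, {b[-1]}) on {chrom}")
        return int(np.searchsorted(b, pos, side="right") - 1)

    def locate_many(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        b = self._boundaries(chrom)
        positions = np.asarray(positions)
        if positions.size and (positions.min() < 0 or positions.max() >= b[-1]):
            raise ValueError(f"positions outside [0, {b[-1]}) on {chrom}")
        return np.searchsorted(b, positions, side="right") - 1

    def assign(self, chrom: str, pos: int) -> RestrictionFragment:
        return self.fragment(chrom, self.locate(chrom, pos))

    # -- I/O ---------------------------------------------------------------

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# enzyme={self.enzyme} site={self.site} cut_offset={self.cut_offset}\n")
            for chrom in self.chromosomes:
                for frag in self.fragments(chrom):
                    fh.write(f"{chrom}\t{frag.start}\t{frag.end}\tfrag_{chrom}_{frag.index}\n")

    @classmethod
    def from_bed(cls, path: str | Path) -> "FragmentMap":
        enzyme, site, cut_offset = "custom", "", 0
        bounds: dict[str, list[int]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    meta = dict(
                        kv.split("=", 1) for kv in line.lstrip("# ").split() if "=" in kv
                    )
                    enzyme = meta.get("enzyme", enzyme)
                    site = meta.get("site", site)
                    cut_offset = int(meta.get("cut_offset", cut_offset))
                    continue
                chrom, start, end = line.split("\t")[:3]
                bounds.setdefault(chrom, [0])
                if int(start) != bounds[chrom][-1]:
                    raise ValueError(f"fragments on {chrom} do not tile: gap before {start}")
                bounds[chrom].append(int(end))
        return cls({c: np.array(b) for c, b in bounds.items()}, enzyme, site, cut_offset)

    @classmethod
    def from_boundaries(cls, boundaries: Mapping[str, np.ndarray], **kw) -> "FragmentMap":
        return cls(boundaries, **kw)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FragmentMap):
            return NotImplemented
        return self._bounds.keys() == other._bounds.keys() and all(
            np.array_equal(self._bounds[c], other._bounds[c]) for c in self._bounds
        )


def digest_genome(
    sequences: Mapping[str, str],
    site: str | None = None,
    cut_offset: int | None = None,
    enzyme: str | None = None,
) -> FragmentMap:
    """Digest genome sequences in silico into a :class:`FragmentMap`.

    The forward strand is scanned for literal occurrences of ``site``
    (overlapping occurrences allowed); a cut is placed at
    ``occurrence_start + cut_offset``.  Only palindromic, non-degenerate
    sites are accepted, which makes a reverse-strand scan redundant.
    Zero-length fragments from cuts at sequence ends are dropped.

    Parameters
    ----------
    sequences
        Mapping of chromosome name to uppercase ACGTN sequence.
    site, cut_offset
        Recognition motif and cut position within it; alternatively pass a
        preset ``enzyme`` name ("HindIII", "MboI", "DpnII").
    """
    if enzyme is not None:
        if enzyme not in ENZYMES:
            raise ValueError(f"unknown enzyme {enzyme!r}; presets: {sorted(ENZYMES)}")
        site, cut_offset = ENZYMES[enzyme]
    else:
        enzyme = "custom"
    if not site:
        raise ValueError("recognition site must be non-empty")
    if cut_offset is None or not 0 <= cut_offset <= len(site):
        raise ValueError(f"cut_offset must lie within [0, {len(site)}]")
    if set(site) - set("ACGT"):
        raise ValueError("degenerate (IUPAC) recognition sites are not supported")
    if site != site.translate(_PALINDROME)[::-1]:
        raise ValueError("non-palindromic recognition sites are not supported")
    if not sequences:
        raise ValueError("empty sequence set")

    bounds: dict[str, np.ndarray] = {}
    for chrom, seq in sequences.items():
        length = len(seq)
        if length == 0:
            raise ValueError(f"{chrom}: empty sequence")
        cuts = [0]
        start = seq.find(site)
        while start != -1:
            cut = start + cut_offset
            if 0 < cut < length and cut != cuts[-1]:
                cuts.append(cut)
            start = seq.find(site, start + 1)  # overlapping occurrences allowed
        cuts.append(length)
        bounds[chrom] = np.array(sorted(set(cuts)), dtype=np.int64)
    return FragmentMap(bounds, enzyme=enzyme, site=site, cut_offset=cut_offset)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load genome sequences as uppercase strings keyed by record id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
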