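"""In-silico double digestion honouring CpG methylation sensitivity.

A genome is cleaved by one or more anchor enzymes (NsiI/PstI) plus one of
the isoschizomers MspI/HpaII.  Every anchor site always cuts; a cutter site
is skipped when the cutter is methylation-sensitive and the site's CCGG
start position is recorded as methylated.  Fragments are the intervals
between consecutive top-strand cut coordinates; library chemistry keeps
only fragments with exactly one anchor-derived end and one cutter-derived
end (one barcode adapter ligates to the anchor overhang, one common adapter
to the CCGG overhang).

Coordinates are 0-based half-open; a cut is the single coordinate
``motif_start + cut_offset``.  Sticky-end overhangs are ignored for length
bookkeeping (a <= 4 bp simplification).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet, Iterable, Mapping, Sequence

from .enzymes import RestrictionEnzyme, find_sites

__all__ = ["Fragment", "Methylome", "digest_library", "size_select", "chrom_cut_map"]

#: Per-chromosome set of methylated CCGG motif start positions (0-based).
Methylome = Mapping[str, AbstractSet[int]]


@dataclass(frozen=True)
class Fragment:
    """A digested fragment between two top-strand cut coordinates."""

    chrom: str
    start: int
    end: int
    left_enzyme: str
    right_enzyme: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"fragment must have start < end: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start


def chrom_cut_map(
    sequence: str,
    anchors: Sequence[RestrictionEnzyme],
    cutter: RestrictionEnzyme,
    methylated: AbstractSet[int] = frozenset(),
) -> list[tuple[int, str, str]]:
    """All cut coordinates on one chromosome as ``(pos, kind, enzyme_name)``.

    ``kind`` is ``"anchor"`` or ``"cutter"``.  Sensitive cutters skip sites
    whose motif start is in ``methylated``.  Sorted by position; if several
    enzymes cut at the same coordinate (impossible for the built-in catalog)
    each cut is listed.
    """
    cuts: list[tuple[int, str, str]] = []
    for enzyme in anchors:
        for pos in find_sites(sequence, enzyme.motif):
            cuts.append((pos + enzyme.cut_offset, "anchor", enzyme.name))
    for pos in find_sites(sequence, cutter.motif):
        if cutter.methylation_sensitive and pos in methylated:
            continue
        cuts.append((pos + cutter.cut_offset, "cutter", cutter.name))
    cuts.sort()
    return cuts


def digest_library(
    genome: Mapping[str, str],
    methylome: Methylome,
    anchors: Sequence[RestrictionEnzyme],
    cutter: RestrictionEnzyme,
) -> list[Fragment]:
    """Digest ``genome`` and return the anchor/cutter library fragments.

    Fragments flanked by two anchors or two cutter sites, and the terminal
    pieces before the first / after the last cut, are excluded: they carry
    the wrong adapter combination and never enter the sequencing library.

    Fragments are returned in (chromosome, coordinate) order, chromosomes
    in the genome's own iteration order.
    """
    fragments: list[Fragment] = []
    for chrom, sequence in genome.items():
        meth = methylome.get(chrom, frozenset())
        cuts = chrom_cut_map(sequence, anchors, cutter, meth)
        for (lpos, lkind, lname), (rpos, rkind, rname) in zip(cuts, cuts[1:]):
            if lpos == rpos:
                continue
            if {lkind, rkind} == {"anchor", "cutter"}:
                fragments.append(Fragment(chrom, lpos, rpos, lname, rname))
    return fragments


def size_select(
    fragments: Iterable[Fragment], min_len: int, max_len: int
) -> list[Fragment]:
    """Keep fragments with ``min_len <= length <= max_len`` (inclusive bounds).

    Mirrors the 200-400 bp capture window of the library preparation.
    Order is preserved.
    """
    if min_len < 0 or max_len < 0:
        raise ValueError("size-selection bounds must be nonnegative")
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    return [f for f in fragments if min_len <= f.length <= max_len]
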