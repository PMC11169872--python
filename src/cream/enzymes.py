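"""Restriction enzymes and closed-form digestion theory.

The CREAM design rests on four enzymes: two six-base "anchor" cutters
(NsiI ``ATGCA/T`` and PstI ``CTGCA/G``) that fix one end of every library
fragment at a reproducible genomic coordinate, and the isoschizomer pair
MspI/HpaII that both recognise ``C/CGG`` but differ in sensitivity to full
methylation of the internal CpG: MspI cuts regardless, HpaII is blocked.

On an i.i.d. sequence model a k-base motif occurs once every
``1 / prod_i p(motif_i)`` bases; for uniform base composition a six-cutter
therefore cuts every 4**6 = 4096 bp, and the two anchors combined every
2048 bp.  These expectations are exposed here as closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "RestrictionEnzyme",
    "NSI_I",
    "PST_I",
    "MSP_I",
    "HPA_II",
    "ENZYMES",
    "UNIFORM_BASE_PROBS",
    "find_sites",
    "gc_content",
    "expected_cut_spacing",
    "combined_anchor_spacing",
]

_BASES = frozenset("ACGT")

#: Uniform base composition (the textbook i.i.d. model).
UNIFORM_BASE_PROBS: Mapping[str, float] = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A type-II restriction enzyme as used by the digestion model.

    Parameters
    ----------
    name : str
        Catalog name, e.g. ``"MspI"``.
    motif : str
        Recognition motif on the top strand, over ``{A, C, G, T}``.
    cut_offset : int
        Bases from the motif start to the top-strand cut coordinate.
    methylation_sensitive : bool
        True if the enzyme is blocked when the CpG inside its motif is
        fully methylated (HpaII); False if it cuts regardless (MspI).
    """

    name: str
    motif: str
    cut_offset: int
    methylation_sensitive: bool = False

    def __post_init__(self) -> None:
        if len(self.motif) < 4:
            raise ValueError(f"motif must be >= 4 bases, got {self.motif!r}")
        if not set(self.motif) <= _BASES:
            raise ValueError(f"motif must be over A/C/G/T, got {self.motif!r}")
        if not 0 <= self.cut_offset <= len(self.motif):
            raise ValueError(
                f"cut_offset must lie within the motif: {self.cut_offset} "
                f"for motif of length {len(self.motif)}"
            )


NSI_I = RestrictionEnzyme("NsiI", "ATGCAT", 5, methylation_sensitive=False)
PST_I = RestrictionEnzyme("PstI", "CTGCAG", 5, methylation_sensitive=False)
MSP_I = RestrictionEnzyme("MspI", "CCGG", 1, methylation_sensitive=False)
HPA_II = RestrictionEnzyme("HpaII", "CCGG", 1, methylation_sensitive=True)

#: Built-in enzyme catalog, keyed by name.
ENZYMES: Mapping[str, RestrictionEnzyme] = {
    e.name: e for e in (NSI_I, PST_I, MSP_I, HPA_II)
}


def find_sites(sequence: str, motif: str) -> list[int]:
    """Return ascending 0-based start positions of every ``motif`` occurrence.

    Occurrences may overlap.  ``N`` (or any non-ACGT character) in the
    sequence never matches.
    """
    if not motif:
        raise ValueError("motif must be nonempty")
    positions: list[int] = []
    start = sequence.find(motif)
    while start != -1:
        positions.append(start)
        start = sequence.find(motif, start + 1)
    return positions


def gc_content(motif: str) -> float:
    """Fraction of G/C bases in ``motif`` (in [0, 1])."""
    if not motif:
        raise ValueError("motif must be nonempty")
    if not set(motif) <= _BASES:
        raise ValueError(f"motif must be over A/C/G/T, got {motif!r}")
    return (motif.count("G") + motif.count("C")) / len(motif)


def _site_probability(motif: str, base_probs: Mapping[str, float]) -> float:
    p = 1.0
    for base in motif:
        p *= base_probs[base]
    return p


def _check_base_probs(base_probs: Mapping[str, float]) -> None:
    if any(p < 0 for p in base_probs.values()):
        raise ValueError("base probabilities must be nonnegative")
    if not math.isclose(sum(base_probs.values()), 1.0, abs_tol=1e-9):
        raise ValueError("base probabilities must sum to 1")


def expected_cut_spacing(
    motif: str, base_probs: Mapping[str, float] = UNIFORM_BASE_PROBS
) -> float:
    """Expected distance in bp between motif occurrences on i.i.d. sequence.

    Returns ``1 / prod_i p(motif_i)``; ``math.inf`` if any motif base has
    probability zero (the motif then never occurs).

    Examples
    --------
    >>> expected_cut_spacing("ATGCAT")
    4096.0
    """
    if not motif:
        raise ValueError("motif must be nonempty")
    _check_base_probs(base_probs)
    p = _site_probability(motif, base_probs)
    if p == 0.0:
        return math.inf
    return 1.0 / p


def combined_anchor_spacing(
    motifs: Sequence[str] | Iterable[str],
    base_probs: Mapping[str, float] = UNIFORM_BASE_PROBS,
) -> float:
    """Expected distance between cuts when several anchor motifs act together.

    Cut rates add (motifs are assumed not to occur inside one another), so
    the combined spacing is the harmonic combination
    ``1 / sum_m 1 / expected_cut_spacing(m)``.  For a single motif this
    reduces to :func:`expected_cut_spacing`.

    Examples
    --------
    >>> combined_anchor_spacing(["ATGCAT", "CTGCAG"])
    2048.0
    """
    motifs = list(motifs)
    if not motifs:
        raise ValueError("at least one motif required")
    rate = 0.0
    for motif in motifs:
        spacing = expected_cut_spacing(motif, base_probs)
        if math.isfinite(spacing):
            rate += 1.0 / spacing
    if rate == 0.0:
        return math.inf
    return 1.0 / rate
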