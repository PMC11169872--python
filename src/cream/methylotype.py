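"""The CREAM methylotyping pipeline.

Takes coordinate-sorted MspI- and HpaII-library alignments per sample,
filters read pairs, reconstructs the sequenced insert fragments from mate
coordinates, sweeps all inserts into population loci, applies the
population coverage filter, and classifies every (locus, sample) cell into
one of the comparative possibilities:

A  identical inserts in both libraries        -> unmethylated
B  insert only in the MspI library            -> methylated
C  shared anchor end, different CCGG end      -> methylated (length shift)
D  insert only in the HpaII library           -> methylated

plus ``ambiguous`` (conflicting evidence) and ``missing`` (no evidence).
The binary view treats B/C/D as methylated and A as unmethylated.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .digest import chrom_cut_map
from .enzymes import HPA_II, MSP_I, NSI_I, PST_I, RestrictionEnzyme

__all__ = [
    "PipelineConfig",
    "Insert",
    "Locus",
    "MethylotypeMatrix",
    "PipelineResult",
    "STATUSES",
    "filter_alignments",
    "exclude_low_yield_samples",
    "reconstruct_inserts",
    "call_loci",
    "coverage_filter",
    "classify_locus_sample",
    "build_matrix",
    "coverage_stats",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

#: All possible per-(locus, sample) calls.
STATUSES = ("A", "B", "C", "D", "AMB", "NA")
METHYLATED_STATUSES = frozenset({"B", "C", "D"})


@dataclass
class PipelineConfig:
    """Thresholds of the calling pipeline.

    ``mapq_min`` (20) and the 20X ``cov_min`` / half-of-samples locus
    filter follow the published pipeline; ``min_reads_per_library``
    (100,000 mean reads over the two libraries) is the sample-exclusion
    rule.  ``presence_min`` (inserts needed to count a library as present
    in a sample) and ``end_slop`` (bp tolerance when comparing insert
    boundaries) are exposed knobs; slop 0 suits exact simulated
    alignments, 2-3 bp is sensible for real aligner output.
    """

    mapq_min: int = 20
    nm_max: int = 5
    min_reads_per_library: float = 100_000
    cov_min: int = 20
    min_sample_fraction: float = 0.5
    presence_min: int = 5
    end_slop: int = 0
    check_boundary_motifs: bool = True

    def __post_init__(self) -> None:
        for name in ("mapq_min", "nm_max", "cov_min", "presence_min", "end_slop"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.min_reads_per_library < 0:
            raise ValueError("min_reads_per_library must be >= 0")
        if not 0.0 < self.min_sample_fraction <= 1.0:
            raise ValueError("min_sample_fraction must be in (0, 1]")


@dataclass(frozen=True)
class Insert:
    """A reconstructed sequenced fragment (leftmost read start to rightmost
    read end, 0-based half-open), with the number of supporting read pairs."""

    chrom: str
    start: int
    end: int
    library: str
    sample: str
    support: int = 1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"insert must have start < end: {self}")
        if self.support < 1:
            raise ValueError("support must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Locus:
    """A population locus: leftmost-to-rightmost span of a transitive group
    of overlapping inserts, any sample, any library."""

    chrom: str
    start: int
    end: int
    type: str  # "overlapping" | "msp_only" | "hpa_only"
    # evidence[sample][library] -> list of (start, end, support)
    evidence: dict[str, dict[str, list[tuple[int, int, int]]]] = field(
        default_factory=dict
    )

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def sample_support(self, sample: str) -> int:
        """Total insert support for ``sample`` over both libraries."""
        ev = self.evidence.get(sample, {})
        return sum(sup for lib in ev.values() for _, _, sup in lib)


def filter_alignments(
    records: Iterable[pysam.AlignedSegment], config: PipelineConfig
) -> tuple[list[pysam.AlignedSegment], Counter]:
    """Keep primary, properly paired records with MAPQ >= ``mapq_min``,
    NM <= ``nm_max`` and the mate on the same chromosome.

    Returns the retained records and a counter of drop reasons (plus the
    ``input``/``retained`` totals).
    """
    kept: list[pysam.AlignedSegment] = []
    counts: Counter = Counter()
    for rec in records:
        counts["input"] += 1
        try:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                counts["not_primary_mapped"] += 1
                continue
            if not rec.is_paired or not rec.is_proper_pair:
                counts["not_proper_pair"] += 1
                continue
            if rec.mapping_quality < config.mapq_min:
                counts["low_mapq"] += 1
                continue
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            if nm > config.nm_max:
                counts["high_nm"] += 1
                continue
            if rec.next_reference_id != rec.reference_id:
                counts["mate_other_chrom"] += 1
                continue
        except (ValueError, KeyError) as exc:  # unparseable record
            counts["unparseable"] += 1
            logger.warning("skipping unparseable record %s: %s", rec.query_name, exc)
            continue
        counts["retained"] += 1
        kept.append(rec)
    return kept, counts


def exclude_low_yield_samples(
    read_counts: Mapping[str, Mapping[str, int]], config: PipelineConfig
) -> list[str]:
    """Samples whose mean read count over the two libraries meets
    ``min_reads_per_library`` (boundary inclusive).

    ``read_counts[sample][library]`` are raw per-library read counts; a
    missing library counts as 0 with a warning.
    """
    retained = []
    for sample in sorted(read_counts):
        counts = read_counts[sample]
        per_lib = []
        for library in ("MspI", "HpaII"):
            if library not in counts:
                logger.warning(
                    "sample %s missing %s library; counting 0 reads", sample, library
                )
            per_lib.append(counts.get(library, 0))
        if sum(per_lib) / 2.0 >= config.min_reads_per_library:
            retained.append(sample)
        else:
            logger.info(
                "excluding sample %s: mean %.0f reads/library below %.0f",
                sample,
                sum(per_lib) / 2.0,
                config.min_reads_per_library,
            )
    return retained


def _boundary_cut_sets(
    genome: Mapping[str, str],
    anchors: Sequence[RestrictionEnzyme],
    cutter: RestrictionEnzyme,
) -> dict[str, tuple[set[int], set[int]]]:
    """Per chromosome: (anchor cut coordinates, cutter cut coordinates),
    methylation ignored (an insert boundary must abut *some* cut)."""
    out = {}
    for chrom, seq in genome.items():
        cuts = chrom_cut_map(seq, anchors, cutter)
        anchor_cuts = {pos for pos, kind, _ in cuts if kind == "anchor"}
        cutter_cuts = {pos for pos, kind, _ in cuts if kind == "cutter"}
        out[chrom] = (anchor_cuts, cutter_cuts)
    return out


def _near(pos: int, cuts: set[int], slop: int) -> bool:
    return any(pos + d in cuts for d in range(-slop, slop + 1))


def reconstruct_inserts(
    records: Iterable[pysam.AlignedSegment],
    sample: str,
    library: str,
    config: PipelineConfig,
    genome: Mapping[str, str] | None = None,
    anchors: Sequence[RestrictionEnzyme] = (NSI_I, PST_I),
    cutter: RestrictionEnzyme | None = None,
) -> tuple[list[Insert], Counter]:
    """Rebuild inserts from filtered, paired records.

    The insert spans ``[min(read starts), max(read ends))``; identical
    intervals are collapsed with their support summed.  When
    ``config.check_boundary_motifs`` and a genome are given, an insert is
    kept only if one boundary abuts an anchor cut and the other a CCGG cut
    (within ``end_slop``) — the guarantee that both restriction sites were
    present in the sequenced fragment.
    """
    counts: Counter = Counter()
    pending: dict[str, tuple[str, int, int]] = {}
    intervals: Counter = Counter()
    for rec in records:
        key = rec.query_name
        start, end = rec.reference_start, rec.reference_end
        if end is None:
            counts["no_alignment_end"] += 1
            continue
        if key not in pending:
            pending[key] = (rec.reference_name, start, end)
            continue
        chrom, s0, e0 = pending.pop(key)
        if chrom != rec.reference_name:
            counts["mate_other_chrom"] += 1
            continue
        lo, hi = min(s0, start), max(e0, end)
        if lo >= hi:
            counts["negative_length"] += 1
            continue
        counts["pairs"] += 1
        intervals[(chrom, lo, hi)] += 1
    counts["unpaired"] += len(pending)

    cut_sets = None
    if config.check_boundary_motifs and genome is not None:
        if cutter is None:
            cutter = MSP_I if library == "MspI" else HPA_II
        cut_sets = _boundary_cut_sets(genome, anchors, cutter)

    inserts: list[Insert] = []
    for (chrom, lo, hi), support in sorted(intervals.items()):
        if cut_sets is not None:
            anchor_cuts, cutter_cuts = cut_sets.get(chrom, (set(), set()))
            slop = config.end_slop
            ok = (
                _near(lo, anchor_cuts, slop) and _near(hi, cutter_cuts, slop)
            ) or (_near(lo, cutter_cuts, slop) and _near(hi, anchor_cuts, slop))
            if not ok:
                counts["boundary_motif_fail"] += 1
                continue
        inserts.append(Insert(chrom, lo, hi, library, sample, support))
    counts["inserts"] = len(inserts)
    return inserts, counts


def call_loci(inserts: Iterable[Insert]) -> list[Locus]:
    """Merge all inserts (any sample, any library) sharing >= 1 bp overlap
    into loci by a single left-to-right sweep per chromosome.

    A locus spans the leftmost to the rightmost member coordinate and is
    typed ``overlapping`` when both libraries contribute, else
    ``msp_only`` / ``hpa_only``.
    """
    by_chrom: dict[str, list[Insert]] = defaultdict(list)
    for ins in inserts:
        by_chrom[ins.chrom].append(ins)
    loci: list[Locus] = []
    for chrom in sorted(by_chrom):
        chrom_inserts = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        group: list[Insert] = []
        group_end = -1
        for ins in chrom_inserts:
            if group and ins.start >= group_end:
                loci.append(_make_locus(chrom, group))
                group = []
            group.append(ins)
            group_end = max(group_end, ins.end)
        if group:
            loci.append(_make_locus(chrom, group))
    return loci


def _make_locus(chrom: str, group: list[Insert]) -> Locus:
    start = min(i.start for i in group)
    end = max(i.end for i in group)
    libraries = {i.library for i in group}
    if libraries == {"MspI", "HpaII"}:
        ltype = "overlapping"
    elif libraries == {"MspI"}:
        ltype = "msp_only"
    else:
        ltype = "hpa_only"
    evidence: dict[str, dict[str, list[tuple[int, int, int]]]] = {}
    for ins in group:
        evidence.setdefault(ins.sample, {}).setdefault(ins.library, []).append(
            (ins.start, ins.end, ins.support)
        )
    return Locus(chrom, start, end, ltype, evidence)


def coverage_filter(
    loci: Iterable[Locus], samples: Sequence[str], config: PipelineConfig
) -> list[Locus]:
    """Keep a locus iff at least ``ceil(min_sample_fraction * n_samples)``
    samples have total insert support >= ``cov_min`` at that locus."""
    samples = list(samples)
    if not samples:
        raise ValueError("coverage_filter requires >= 1 sample")
    needed = math.ceil(config.min_sample_fraction * len(samples))
    kept = []
    for locus in loci:
        n_ok = sum(
            1 for s in samples if locus.sample_support(s) >= config.cov_min
        )
        if n_ok >= needed:
            kept.append(locus)
    return kept


def _present_intervals(
    intervals: list[tuple[int, int, int]], config: PipelineConfig
) -> list[tuple[int, int]]:
    """Distinct intervals after end_slop merging, kept when their summed
    support reaches ``presence_min``."""
    if not intervals:
        return []
    merged: list[list[int]] = []  # [start, end, support]
    for s, e, sup in sorted(intervals):
        for m in merged:
            if abs(m[0] - s) <= config.end_slop and abs(m[1] - e) <= config.end_slop:
                m[2] += sup
                break
        else:
            merged.append([s, e, sup])
    return [(s, e) for s, e, sup in merged if sup >= config.presence_min]


def classify_locus_sample(
    locus: Locus, sample: str, config: PipelineConfig
) -> str:
    """Classify one sample at one locus into A/B/C/D/AMB/NA.

    A library is "present" when it shows a distinct insert interval with
    support >= ``presence_min``.  NA: neither present.  B/D: one library
    only.  With both present and a single interval each: A when both ends
    agree (within ``end_slop``), C when exactly one end agrees (the shared
    end is the restriction-anchored one, the CCGG end shifted), AMB when
    both ends differ.  More than one distinct interval in a library is AMB.
    """
    ev = locus.evidence.get(sample, {})
    msp = _present_intervals(ev.get("MspI", []), config)
    hpa = _present_intervals(ev.get("HpaII", []), config)
    if not msp and not hpa:
        return "NA"
    if len(msp) > 1 or len(hpa) > 1:
        return "AMB"
    if msp and not hpa:
        return "B"
    if hpa and not msp:
        return "D"
    (ms, me), (hs, he) = msp[0], hpa[0]
    start_eq = abs(ms - hs) <= config.end_slop
    end_eq = abs(me - he) <= config.end_slop
    if start_eq and end_eq:
        return "A"
    if start_eq or end_eq:
        return "C"
    return "AMB"


@dataclass
class MethylotypeMatrix:
    """Samples x loci status table with a binary methylated view."""

    statuses: pd.DataFrame  # samples x locus_id, values in STATUSES
    loci: list[Locus]

    @property
    def binary(self) -> pd.DataFrame:
        """1 = methylated (B/C/D), 0 = unmethylated (A), NaN = AMB/NA."""
        mapping = {"A": 0.0, "B": 1.0, "C": 1.0, "D": 1.0}
        return self.statuses.apply(lambda col: col.map(mapping))

    def locus_summary(self) -> pd.DataFrame:
        """Per-locus status counts and the majority-based population set."""
        rows = []
        for locus in self.loci:
            col = self.statuses[locus.locus_id]
            counts = col.value_counts()
            meth = int(sum(counts.get(s, 0) for s in METHYLATED_STATUSES))
            unmeth = int(counts.get("A", 0))
            amb = int(counts.get("AMB", 0))
            if meth > max(unmeth, amb):
                population_set = "methylated"
            elif unmeth > max(meth, amb):
                population_set = "unmethylated"
            else:
                population_set = "ambiguous"
            rows.append(
                {
                    "locus": locus.locus_id,
                    "chrom": locus.chrom,
                    "start": locus.start,
                    "end": locus.end,
                    "type": locus.type,
                    **{f"n_{s}": int(counts.get(s, 0)) for s in STATUSES},
                    "n_methylated": meth,
                    "set": population_set,
                }
            )
        return pd.DataFrame(rows)


def build_matrix(
    loci: Sequence[Locus], samples: Sequence[str], config: PipelineConfig
) -> MethylotypeMatrix:
    """Classify every (locus, sample) cell and assemble the matrix."""
    if not samples:
        raise ValueError("build_matrix requires >= 1 sample")
    ids = [locus.locus_id for locus in loci]
    if len(set(ids)) != len(ids):
        raise ValueError("locus ids are not unique")
    data = {
        locus.locus_id: [
            classify_locus_sample(locus, sample, config) for sample in samples
        ]
        for locus in loci
    }
    statuses = pd.DataFrame(data, index=list(samples), columns=ids, dtype=object)
    return MethylotypeMatrix(statuses=statuses, loci=list(loci))


def coverage_stats(
    inserts: Iterable[Insert], genome_lengths: Mapping[str, int]
) -> dict[str, dict[str, float]]:
    """Per library: percent of the genome covered by the insert union and
    mean depth over covered positions (0 with ``empty=True`` if no inserts)."""
    genome_size = sum(genome_lengths.values())
    if genome_size <= 0:
        raise ValueError("empty genome")
    by_lib: dict[str, list[Insert]] = defaultdict(list)
    for ins in inserts:
        by_lib[ins.library].append(ins)
    stats: dict[str, dict[str, float]] = {}
    for library, lib_inserts in by_lib.items():
        intervals = sorted({(i.chrom, i.start, i.end) for i in lib_inserts})
        covered = 0
        cur = None
        for chrom, s, e in intervals:
            if cur is None or chrom != cur[0] or s > cur[2]:
                if cur is not None:
                    covered += cur[2] - cur[1]
                cur = [chrom, s, e]
            else:
                cur[2] = max(cur[2], e)
        if cur is not None:
            covered += cur[2] - cur[1]
        insert_bases = sum(i.length * i.support for i in lib_inserts)
        stats[library] = {
            "pct_covered": 100.0 * covered / genome_size,
            "mean_depth": (insert_bases / covered) if covered else 0.0,
            "empty": not lib_inserts,
        }
    return stats


@dataclass
class PipelineResult:
    """Everything the calling pipeline produced, plus stage accounting."""

    matrix: MethylotypeMatrix
    loci: list[Locus]
    all_loci: list[Locus]  # before the coverage filter
    samples: list[str]
    excluded_samples: list[str]
    stage_counts: dict[str, Counter]
    coverage: dict[str, dict[str, float]]


def run_pipeline(
    manifest: pd.DataFrame,
    genome: Mapping[str, str],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run filter -> inserts -> loci -> coverage filter -> classify -> matrix.

    ``manifest`` needs columns sample / library / path (SAM or BAM).
    Samples lacking one of the two libraries, or below the read-yield
    threshold, are excluded with a warning.
    """
    if config is None:
        config = PipelineConfig()
    required = {"sample", "library", "path"}
    if not required <= set(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")

    read_counts: dict[str, dict[str, int]] = defaultdict(dict)
    inserts_by_sample: dict[str, list[Insert]] = defaultdict(list)
    stage_counts: dict[str, Counter] = {}
    for row in manifest.itertuples(index=False):
        with pysam.AlignmentFile(str(row.path), require_index=False) as af:
            records = list(af)
        kept, fcounts = filter_alignments(records, config)
        inserts, icounts = reconstruct_inserts(
            kept, row.sample, row.library, config, genome=genome
        )
        read_counts[row.sample][row.library] = fcounts["input"]
        inserts_by_sample[row.sample].extend(inserts)
        stage_counts[f"{row.sample}/{row.library}"] = fcounts + icounts

    complete = [
        s for s in read_counts if {"MspI", "HpaII"} <= set(read_counts[s])
    ]
    for s in sorted(set(read_counts) - set(complete)):
        logger.warning("sample %s lacks one library; excluded", s)
    samples = [
        s
        for s in exclude_low_yield_samples(
            {s: read_counts[s] for s in complete}, config
        )
    ]
    excluded = sorted(set(read_counts) - set(samples))

    all_inserts = [i for s in samples for i in inserts_by_sample[s]]
    all_loci = call_loci(all_inserts)
    if samples:
        loci = coverage_filter(all_loci, samples, config)
        matrix = build_matrix(loci, samples, config)
    else:
        loci = []
        matrix = MethylotypeMatrix(
            statuses=pd.DataFrame(index=[], columns=[], dtype=object), loci=[]
        )
    coverage = coverage_stats(all_inserts, {c: len(s) for c, s in genome.items()})
    logger.info(
        "pipeline: %d samples retained (%d excluded), %d loci called, %d after "
        "coverage filter",
        len(samples),
        len(excluded),
        len(all_loci),
        len(loci),
    )
    return PipelineResult(
        matrix=matrix,
        loci=loci,
        all_loci=all_loci,
        samples=samples,
        excluded_samples=excluded,
        stage_counts=stage_counts,
        coverage=coverage,
    )
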