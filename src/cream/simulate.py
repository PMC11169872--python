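"""Seeded generator of synthetic CREAM experiments.

Builds, from a single integer seed: a multi-chromosome genome with GC-rich
"genic" blocks, per-sample CpG methylomes layered as shared base
methylation + clonal-line epimutations + per-sample singleton epimutations,
the MspI and HpaII library fragments of every sample, perfectly aligned
paired-end reads (SAM, optionally FASTQ), and a ground-truth table of the
per-region methylation possibility (A/B/C/D) each sample should yield.

Because the simulator writes correct alignments directly, recovery tests
never need an external aligner; the emitted FASTQ lets users run one anyway.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .digest import Fragment, Methylome, digest_library, size_select
from .enzymes import HPA_II, MSP_I, NSI_I, PST_I, find_sites

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_genome",
    "simulate_methylomes",
    "simulate_reads",
    "ground_truth",
    "simulate_experiment",
]

ANCHORS = (NSI_I, PST_I)
_BASE_ARRAY = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class SimConfig:
    """Study-design parameters of a synthetic CREAM experiment.

    Defaults mirror the published design at desk scale: two sister clonal
    lines, 150 bp paired-end reads, 200-400 bp size selection, a genome
    GC fraction of 0.33 with GC-richer genic blocks, and ~30 insert copies
    sequenced per captured fragment.
    """

    seed: int
    n_chrom: int = 2
    chrom_length: int = 1_000_000
    background_gc: float = 0.33
    genic_block_fraction: float = 0.30
    genic_gc: float = 0.60
    genic_block_size: int = 50_000
    n_lines: int = 2
    n_samples_per_line: int = 10
    base_methylation_prob: float = 0.30
    line_epimutation_rate: float = 0.05
    sample_epimutation_rate: float = 0.01
    depth: float = 30.0
    read_length: int = 150
    substitution_error_rate: float = 0.0
    size_min: int = 200
    size_max: int = 400

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        fractions = {
            "background_gc": self.background_gc,
            "genic_block_fraction": self.genic_block_fraction,
            "genic_gc": self.genic_gc,
            "base_methylation_prob": self.base_methylation_prob,
            "line_epimutation_rate": self.line_epimutation_rate,
            "sample_epimutation_rate": self.sample_epimutation_rate,
            "substitution_error_rate": self.substitution_error_rate,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_chrom < 1 or self.chrom_length < 1:
            raise ValueError("genome dimensions must be positive")
        if self.n_lines < 1 or self.n_samples_per_line < 1:
            raise ValueError("need >= 1 line and >= 1 sample per line")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.read_length < 1:
            raise ValueError("read_length must be positive")
        if not 0 <= self.size_min <= self.size_max:
            raise ValueError("need 0 <= size_min <= size_max")

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{line}S{i + 1:02d}"
            for line in self.line_ids
            for i in range(self.n_samples_per_line)
        ]

    @property
    def line_ids(self) -> list[str]:
        return [f"L{j + 1}" for j in range(self.n_lines)]

    @property
    def line_of_sample(self) -> dict[str, str]:
        return {s: s.split("S")[0] for s in self.sample_ids}


def _random_segment(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    codes = rng.choice(4, size=length, p=[at, gc / 2.0, gc / 2.0, at])
    return codes


def simulate_genome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], pd.DataFrame]:
    """Simulate the genome and its genic-block annotation.

    Bases are i.i.d. at ``background_gc`` outside genic blocks and
    ``genic_gc`` inside; blocks (one per equal-width window, randomly
    offset) cover ``genic_block_fraction`` of each chromosome and are
    returned as a gene table with columns chrom/start/end/gene_id.
    """
    if config.chrom_length < 1000:
        raise ValueError("chrom_length must be >= 1 kb")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genome: dict[str, str] = {}
    gene_rows: list[dict] = []
    block = min(config.genic_block_size, config.chrom_length)
    for c in range(config.n_chrom):
        chrom = f"chr{c + 1}"
        length = config.chrom_length
        n_blocks = int(round(config.genic_block_fraction * length / block))
        n_blocks = min(n_blocks, length // block)
        # blocks occupy randomly chosen block-sized slots: gene density then
        # varies between regions (binomial per bin), as in real genomes
        starts: list[int] = []
        if n_blocks > 0:
            slots = length // block
            chosen = rng.choice(slots, size=n_blocks, replace=False)
            starts = sorted(int(s) * block for s in chosen)
        segments: list[np.ndarray] = []
        cursor = 0
        for i, s in enumerate(starts):
            if s > cursor:
                segments.append(_random_segment(rng, s - cursor, config.background_gc))
            segments.append(_random_segment(rng, block, config.genic_gc))
            gene_rows.append(
                {"chrom": chrom, "start": s, "end": s + block,
                 "gene_id": f"gene_{chrom}_{i + 1:04d}"}
            )
            cursor = s + block
        if cursor < length:
            segments.append(_random_segment(rng, length - cursor, config.background_gc))
        codes = np.concatenate(segments) if segments else np.empty(0, dtype=int)
        genome[chrom] = _BASE_ARRAY[codes].tobytes().decode("ascii")
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "gene_id"])
    return genome, genes


def simulate_methylomes(
    genome: Mapping[str, str],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, Methylome], dict[str, str]]:
    """Per-sample methylomes with shared, line and singleton layers.

    Each CCGG site gets a population base state (methylated with
    ``base_methylation_prob``); each clonal line toggles the site with
    ``line_epimutation_rate`` (one draw per line, shared by all its
    samples); each sample then toggles independently with
    ``sample_epimutation_rate``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    samples = config.sample_ids
    line_index = {line: j for j, line in enumerate(config.line_ids)}
    methylomes: dict[str, dict[str, frozenset[int]]] = {s: {} for s in samples}
    for chrom, seq in genome.items():
        sites = np.asarray(find_sites(seq, "CCGG"), dtype=np.int64)
        n = sites.size
        base = rng.random(n) < config.base_methylation_prob
        line_flip = rng.random((config.n_lines, n)) < config.line_epimutation_rate
        for sample in samples:
            j = line_index[config.line_of_sample[sample]]
            sample_flip = rng.random(n) < config.sample_epimutation_rate
            state = base ^ line_flip[j] ^ sample_flip
            methylomes[sample][chrom] = frozenset(int(p) for p in sites[state])
    return methylomes, dict(config.line_of_sample)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _inject_errors(
    seq: str, rate: float, rng: np.random.Generator
) -> tuple[str, int]:
    if rate <= 0.0:
        return seq, 0
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        current = arr[i]
        choices = [b for b in (b"A", b"C", b"G", b"T") if b != current]
        arr[i] = choices[int(rng.integers(0, 3))]
    return arr.tobytes().decode("ascii"), int(hits.size)


def sam_header(genome: Mapping[str, str]) -> str:
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for chrom, seq in genome.items():
        lines.append(f"@SQ\tSN:{chrom}\tLN:{len(seq)}")
    return "\n".join(lines) + "\n"


def simulate_reads(
    genome: Mapping[str, str],
    fragments: list[Fragment],
    sample_id: str,
    library: str,
    config: SimConfig,
    rng: np.random.Generator,
    sam_path: Path,
    fastq_paths: tuple[Path, Path] | None = None,
) -> int:
    """Sequence ``fragments`` into a coordinate-sorted SAM file.

    Each fragment is sampled ``Poisson(depth)`` times; every copy yields a
    proper read pair (read 1 forward from the fragment start, read 2
    reverse from the fragment end, length ``min(read_length, fragment
    length)``) written with exact coordinates, proper-pair flags, MAPQ 60
    and an NM tag counting injected substitution errors.  Returns the
    number of read pairs written.
    """
    fragments = sorted(fragments, key=lambda f: (f.chrom, f.start, f.end))
    n_pairs = 0
    fq1 = fq2 = None
    sam = open(sam_path, "w")
    try:
        sam.write(sam_header(genome))
        if fastq_paths is not None:
            fq1 = gzip.open(fastq_paths[0], "wt")
            fq2 = gzip.open(fastq_paths[1], "wt")
        for frag in fragments:
            copies = int(rng.poisson(config.depth))
            if copies == 0:
                continue
            rl = min(config.read_length, frag.length)
            seq = genome[frag.chrom]
            fwd_template = seq[frag.start : frag.start + rl]
            # read 2 comes off the reverse strand; SAM stores it in
            # forward-reference orientation, FASTQ as actually sequenced
            rev_template = seq[frag.end - rl : frag.end]
            qual = "I" * rl
            pos1 = frag.start + 1
            pos2 = frag.end - rl + 1
            tlen = frag.length
            records1, records2, fqr1, fqr2 = [], [], [], []
            for copy in range(copies):
                qname = (
                    f"{sample_id}:{library}:{frag.chrom}:{frag.start}:"
                    f"{frag.end}:{copy}"
                )
                read1, nm1 = _inject_errors(
                    fwd_template, config.substitution_error_rate, rng
                )
                read2, nm2 = _inject_errors(
                    rev_template, config.substitution_error_rate, rng
                )
                records1.append(
                    f"{qname}\t99\t{frag.chrom}\t{pos1}\t60\t{rl}M\t=\t{pos2}\t"
                    f"{tlen}\t{read1}\t{qual}\tNM:i:{nm1}\n"
                )
                records2.append(
                    f"{qname}\t147\t{frag.chrom}\t{pos2}\t60\t{rl}M\t=\t{pos1}\t"
                    f"{-tlen}\t{read2}\t{qual}\tNM:i:{nm2}\n"
                )
                if fq1 is not None:
                    fqr1.append(f"@{qname}/1\n{read1}\n+\n{qual}\n")
                    fqr2.append(f"@{qname}/2\n{_revcomp(read2)}\n+\n{qual}\n")
            # read-1 records precede read-2 records: keeps the file
            # coordinate-sorted because pos1 <= pos2 < next fragment start
            sam.writelines(records1)
            sam.writelines(records2)
            if fq1 is not None:
                fq1.writelines(fqr1)
                fq2.writelines(fqr2)
            n_pairs += copies
    finally:
        sam.close()
        if fq1 is not None:
            fq1.close()
        if fq2 is not None:
            fq2.close()
    return n_pairs


def _region_key(frag: Fragment) -> tuple[str, int, str]:
    """Anchored-region key: (chrom, anchor cut coordinate, side).

    Side "L" means the anchor is the left end of the fragment (region
    extends rightward to the CCGG cut), "R" the mirror case.
    """
    if frag.left_enzyme in ("NsiI", "PstI"):
        return (frag.chrom, frag.start, "L")
    return (frag.chrom, frag.end, "R")


@dataclass
class GroundTruth:
    """True per-region, per-sample methylation possibility.

    ``table`` has one row per capturable (region, sample) cell with columns
    chrom / start / end (union extent over samples and libraries) /
    anchor_pos / side / sample / status (A, B, C or D).
    """

    table: pd.DataFrame
    methylomes: dict[str, Methylome] = field(repr=False)
    lines: dict[str, str] = field(default_factory=dict)

    def status_matrix(self) -> pd.DataFrame:
        """Samples x regions matrix of statuses (NaN where not capturable)."""
        df = self.table.copy()
        df["locus"] = (
            df["chrom"]
            + ":"
            + df["anchor_pos"].astype(str)
            + df["side"]
        )
        return df.pivot(index="sample", columns="locus", values="status")


def ground_truth(
    genome: Mapping[str, str],
    methylomes: dict[str, Methylome],
    lines: dict[str, str],
    config: SimConfig,
) -> GroundTruth:
    """Derive the expected A/B/C/D status of every capturable region.

    For each anchored region (anchor cut + side) and sample: A when the
    MspI and the sample's HpaII fragment are identical and size-selected;
    B when only the MspI fragment survives selection; D when only the
    HpaII fragment does; C when both survive with different lengths.  A
    (region, sample) cell with neither fragment selected is omitted.
    """
    msp_selected: dict[tuple, Fragment] = {}
    msp_frags = size_select(
        digest_library(genome, {}, ANCHORS, MSP_I), config.size_min, config.size_max
    )
    for frag in msp_frags:
        msp_selected[_region_key(frag)] = frag

    rows: list[dict] = []
    extent: dict[tuple, list[int]] = {}

    def note_extent(key: tuple, frag: Fragment) -> None:
        if key not in extent:
            extent[key] = [frag.start, frag.end]
        else:
            extent[key][0] = min(extent[key][0], frag.start)
            extent[key][1] = max(extent[key][1], frag.end)

    for key, frag in msp_selected.items():
        note_extent(key, frag)

    for sample in config.sample_ids:
        hpa_frags = size_select(
            digest_library(genome, methylomes[sample], ANCHORS, HPA_II),
            config.size_min,
            config.size_max,
        )
        hpa_selected = {_region_key(f): f for f in hpa_frags}
        for key in set(msp_selected) | set(hpa_selected):
            msp = msp_selected.get(key)
            hpa = hpa_selected.get(key)
            if msp is None and hpa is None:
                continue
            if msp is not None and hpa is not None:
                status = "A" if (msp.start, msp.end) == (hpa.start, hpa.end) else "C"
            elif msp is not None:
                status = "B"
            else:
                status = "D"
            if hpa is not None:
                note_extent(key, hpa)
            chrom, anchor_pos, side = key
            rows.append(
                {"chrom": chrom, "anchor_pos": anchor_pos, "side": side,
                 "sample": sample, "status": status}
            )

    table = pd.DataFrame(
        rows, columns=["chrom", "anchor_pos", "side", "sample", "status"]
    )
    if len(table):
        table["start"] = [
            extent[(c, a, s)][0]
            for c, a, s in zip(table["chrom"], table["anchor_pos"], table["side"])
        ]
        table["end"] = [
            extent[(c, a, s)][1]
            for c, a, s in zip(table["chrom"], table["anchor_pos"], table["side"])
        ]
    else:
        table["start"] = []
        table["end"] = []
    table = table[["chrom", "start", "end", "anchor_pos", "side", "sample", "status"]]
    table = table.sort_values(["chrom", "anchor_pos", "side", "sample"]).reset_index(
        drop=True
    )
    return GroundTruth(table=table, methylomes=methylomes, lines=dict(lines))


def simulate_experiment(
    config: SimConfig,
    outdir: str | Path,
    force: bool = False,
    emit_fastq: bool = True,
) -> dict[str, Path]:
    """Run the full simulator and write an experiment directory.

    Writes genome FASTA, genic-block GFF3, per-sample methylome BED,
    per-sample-per-library coordinate-sorted SAM (and optionally gzipped
    FASTQ), ground-truth TSV, sample metadata TSV and an alignment
    manifest TSV.  Deterministic for a given config (seed included).
    """
    from . import io as cio  # local import: io pulls in Bio / yaml

    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"output directory {outdir} is not empty (use force)")
    (outdir / "alignments").mkdir(parents=True, exist_ok=True)
    (outdir / "methylomes").mkdir(exist_ok=True)
    if emit_fastq:
        (outdir / "reads").mkdir(exist_ok=True)

    ss = np.random.SeedSequence(config.seed)
    genome_ss, meth_ss, reads_ss = ss.spawn(3)
    genome, genes = simulate_genome(config, np.random.default_rng(genome_ss))
    methylomes, lines = simulate_methylomes(
        genome, config, np.random.default_rng(meth_ss)
    )
    truth = ground_truth(genome, methylomes, lines, config)

    paths: dict[str, Path] = {}
    paths["genome"] = outdir / "genome.fasta"
    cio.write_fasta(genome, paths["genome"])
    paths["genes"] = outdir / "genes.gff3"
    cio.write_gff3_genes(genes, paths["genes"])
    paths["truth"] = outdir / "truth.tsv"
    truth.table.to_csv(paths["truth"], sep="\t", index=False)

    for sample in config.sample_ids:
        cio.write_methylome_bed(
            methylomes[sample], outdir / "methylomes" / f"{sample}.bed"
        )

    samples = config.sample_ids
    metadata = pd.DataFrame(
        {
            "sample": samples,
            "line": [lines[s] for s in samples],
            # subculture counts cycle over the 6-11 range of the study design
            "subculture": [6 + i % 6 for i in range(len(samples))],
        }
    )
    paths["metadata"] = outdir / "metadata.tsv"
    metadata.to_csv(paths["metadata"], sep="\t", index=False)

    msp_frags = size_select(
        digest_library(genome, {}, ANCHORS, MSP_I), config.size_min, config.size_max
    )
    manifest_rows = []
    child_seeds = reads_ss.spawn(len(samples) * 2)
    k = 0
    for sample in samples:
        for library in ("MspI", "HpaII"):
            if library == "MspI":
                frags = msp_frags
            else:
                frags = size_select(
                    digest_library(genome, methylomes[sample], ANCHORS, HPA_II),
                    config.size_min,
                    config.size_max,
                )
            sam_path = outdir / "alignments" / f"{sample}_{library}.sam"
            fastq_paths = None
            if emit_fastq:
                fastq_paths = (
                    outdir / "reads" / f"{sample}_{library}_R1.fastq.gz",
                    outdir / "reads" / f"{sample}_{library}_R2.fastq.gz",
                )
            simulate_reads(
                genome,
                frags,
                sample,
                library,
                config,
                np.random.default_rng(child_seeds[k]),
                sam_path,
                fastq_paths,
            )
            k += 1
            # manifest paths relative to the experiment directory: the tree
            # stays byte-identical wherever it is written
            manifest_rows.append(
                {"sample": sample, "library": library,
                 "path": str(sam_path.relative_to(outdir))}
            )
    manifest = pd.DataFrame(manifest_rows)
    paths["manifest"] = outdir / "manifest.tsv"
    manifest.to_csv(paths["manifest"], sep="\t", index=False)
    paths["config"] = outdir / "config.yaml"
    cio.write_yaml(asdict(config), paths["config"])
    return paths
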