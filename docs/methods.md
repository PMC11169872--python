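# Methods

## Digestion model

A genome is a mapping chromosome → uppercase A/C/G/T/N string. All
coordinates are 0-based half-open. A restriction cut is a single top-strand
coordinate, `motif start + cut_offset`; sticky-end overhangs are ignored in
length bookkeeping, a ≤ 4 bp simplification that affects no comparison the
pipeline makes (both libraries share it). Motif scanning is exhaustive and
allows overlaps; `N` never matches.

Built-in catalog: NsiI (`ATGCAT`, cut at +5), PstI (`CTGCAG`, +5), MspI
(`CCGG`, +1, methylation-insensitive), HpaII (`CCGG`, +1, blocked by full
methylation of the internal CpG). Methylation is modelled only at the CpG
of CCGG, as fully methylated or not; CHG/CHH contexts, hemimethylation and
MspI's outer-cytosine sensitivity are out of scope. A methylome is the set
of methylated CCGG start positions per chromosome.

`digest_library` cuts at every anchor site plus every cutter site not
blocked by methylation, forms fragments between consecutive cuts and keeps
only fragments with one anchor end and one cutter end. This mirrors the
library chemistry: the barcode adapter ligates to the anchor overhang and
the common adapter to the CCGG overhang, so anchor–anchor and
cutter–cutter fragments never amplify. Terminal chromosome pieces are
likewise excluded. Size selection keeps lengths in the inclusive window
[200, 400] bp by default (a plain reading of the 200–400 bp capture).

Closed forms on the i.i.d. sequence model: a motif occurs every
`1 / Π p(base)` bp (4096 bp for a six-cutter at uniform composition); cut
rates of distinct anchors add, giving `1 / Σ rate` (2048 bp for NsiI +
PstI). A zero-probability base yields an explicit infinite spacing.

## Simulator

`SimConfig` holds the study design; the seed is mandatory and drives every
stage through spawned NumPy `SeedSequence` children, so a config is
bit-reproducible (SAM, FASTQ, truth tables identical across runs).

Defaults and rationale:

- `n_lines=2`, `n_samples_per_line=10` — two sister clonal lines at desk
  scale.
- `background_gc=0.33` — the overall GC fraction of the cannabis genome;
  `genic_gc=0.60`, `genic_block_fraction=0.30`, `genic_block_size=50 kb` —
  genic regions in plants are GC-richer than intergenic space, which is
  what concentrates 100%-GC CCGG sites (and anchor sites) in gene-dense
  regions. Blocks occupy randomly chosen non-overlapping block-sized
  slots, so gene density per 500-kb bin is binomial rather than constant —
  without that variation the density correlation would be undefined.
- methylome layers: each CCGG site is methylated in the whole population
  with `base_methylation_prob=0.30`; each line then toggles it with
  `line_epimutation_rate=0.05` (one draw shared by the line's samples);
  each sample toggles independently with `sample_epimutation_rate=0.01`.
  The three layers produce the observed spectrum structure — a monomorphic
  peak at k = n, line peaks at the line sizes, and singletons at k = 1.
  The real line/singleton rates are not known quantitatively; these values
  are fixed as plausible magnitudes and exposed as free parameters.
- `depth=30` mean insert copies, Poisson per fragment — Poisson models
  amplification variance simply; `read_length=150` paired-end;
  `substitution_error_rate=0` by default (errors, when enabled, are
  i.i.d. substitutions counted in the NM tag).

Reads are emitted as coordinate-sorted SAM with exact coordinates, proper
pair flags, MAPQ 60 and NM tags; read 2 is stored in forward-reference
orientation as SAM requires, while FASTQ carries the as-sequenced reverse
complement. Reads shorter than the fragment leave an unsequenced middle
gap; insert reconstruction uses mate coordinates, so the gap is harmless.
PCR duplicates, adapter read-through, barcode demultiplexing, real error
profiles and within-sample cell heterogeneity are not modelled.

Ground truth: for each anchored region (anchor cut + side) and sample, the
status is a pure function of the digestion model — A if the MspI fragment
and the sample's HpaII fragment are identical and size-selected, B if only
MspI survives selection, D if only HpaII does, C if both survive at
different lengths; a cell with neither fragment is not capturable.

## Calling pipeline

Per library and sample, alignments are kept when primary, properly paired,
MAPQ ≥ 20 (`mapq_min`), edit distance ≤ 5 (`nm_max`) and the mate maps to
the same chromosome. Samples are excluded when their mean read count over
the two libraries falls below `min_reads_per_library` (default 100,000,
the full-scale exclusion rule; desk-scale runs pass a proportionally
smaller threshold). Inserts span leftmost read start to rightmost read
end; identical intervals collapse with support summed. An optional
boundary check (`check_boundary_motifs`, on by default) keeps only inserts
with one end abutting an anchor cut and the other a CCGG cut in the
reference — the guarantee that both restriction sites were present in the
fragment.

Loci are the transitive closure of ≥ 1 bp insert overlap, pooled over
samples and libraries, computed by a left-to-right sweep; a locus spans
the leftmost-to-rightmost member coordinates and is typed by the
contributing libraries. The coverage filter keeps a locus iff at least
`ceil(min_sample_fraction × n_samples)` samples (default: half) have total
insert support ≥ `cov_min` (default 20). The source description of this
filter is self-contradictory; keeping loci that at least half the samples
cover at ≥ 20X is the only reading that filters low-coverage loci, and
both knobs are configurable.

Classification per (locus, sample): a library is present when it shows a
distinct insert interval with support ≥ `presence_min` (default 5, chosen
to suppress stray mismapped pairs at ~30X; not part of the original
description). Interval ends are compared within `end_slop` bp (default 0,
appropriate for exact simulated alignments; 2–3 bp is recommended for real
aligner output). Both absent → missing; one present → B or D; both present
with equal ends → A; exactly one equal end → C (the shared end is the
restriction-anchored one by the library geometry); both ends different,
or > 1 distinct interval within a library → ambiguous. Ambiguous cells are
reported, never dropped. The binary view maps B/C/D → methylated and A →
unmethylated, masking ambiguous/missing; the per-locus population summary
assigns each locus to the methylated/unmethylated/ambiguous output set by
majority over non-missing cells (ties → ambiguous).

## Population statistics

- Frequency spectrum: loci counted by the number of samples methylated;
  monomorphic = methylated in all samples, singletons = exactly one; a
  line-exclusive locus is methylated in every sample of one line and none
  of the others.
- Kruskal–Wallis on per-sample methylated-locus counts grouped by
  subculture number (midrank tie correction, χ² p-value; all-tied input
  returns H = 0, p = 1 rather than dividing by zero).
- PCA: binary matrix, masked cells imputed by the locus mean, all-masked
  loci dropped, columns centered, no scaling, SVD. Variance fractions sum
  to one; a zero-variance matrix returns a flagged degenerate result.
- Densities: features binned by start coordinate into 500-kb bins (final
  partial bin kept); Spearman's ρ between gene and methylated-locus counts
  per bin, undefined (NaN, warned) for constant vectors.
- Proximity: a locus is assigned to every transcript whose interval
  expanded by ±1 kb overlaps it by ≥ 1 bp.
- Enrichment: one-sided hypergeometric over-representation per term on
  unique transcript ids (targets = methylated loci near transcripts,
  background = all captured loci near transcripts), Benjamini–Hochberg
  adjusted, significant below FDR 0.10. Flat term map only; no ontology
  propagation.

## Verification scale and what it shows

The end-to-end recovery suite simulates 2 lines × 10 samples on a 6-Mb
genome (3 × 2 Mb chromosomes) at depth 30, error-free — sizes chosen so
the whole suite runs in well under a minute per simulation while leaving
thousands of (locus, sample) cells. Pipeline calls match ground truth for
≥ 99% of cells at regions that at least half the samples capture, with
zero unmethylated calls where truth is methylated. Regions captured by
fewer than half the samples — HpaII-only loci methylated in a minority,
where unmethylated samples yield no fragment at any depth — can never pass
the half-of-samples coverage rule; their exclusion is method design, not
recovery error, and they are excluded from the concordance denominator
(stochastic coverage-filter losses still count against the pipeline).

The spectrum check restricts to loci backed by the MspI library, whose
capture is independent of methylation state and therefore an unbiased
sample of CCGG sites; expected per-k counts come from an exact
enumeration/convolution over the configured layer rates. Digestion is
checked against a naive enumerate-all-cuts oracle on 1,000 random 50-kb
genomes with random methylomes; the locus sweep against a brute-force
transitive-closure oracle; the rank statistics and enrichment against
hand-rank and exhaustive-combinatorial oracles.

Passing these tests shows the pipeline inverts the simulator's generative
model at realistic depth. It does not show robustness to the things the
simulator omits: mismapping and multi-mapping reads, indels, partial
digestion, chimeric fragments, PCR duplicates, or cell-mixture
heterogeneity. For real aligner output, enable the boundary-motif check
and a 2–3 bp `end_slop`, and expect an ambiguous fraction rather than the
near-zero one seen on simulated data.

## Known limitations

Binary per-locus methylation status only (no quantitative methylation
level); CpG-of-CCGG context only; one methylome per sample (bulk
homogeneity); no partial digestion or star activity; alignment itself is
out of scope — the pipeline consumes coordinate-sorted SAM/BAM produced
elsewhere (or by the simulator).
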