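"""Population-level analyses of a methylotype matrix.

Frequency spectrum of methylated loci, the subculture (clonal-age)
Kruskal-Wallis test, PCA of the binary methylotypes, 500-kb gene /
methylation density binning with Spearman correlation, transcript
proximity annotation, and flat-term over-representation testing with
Benjamini-Hochberg control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FrequencySpectrum",
    "PCAResult",
    "frequency_spectrum",
    "kruskal_wallis",
    "pca_methylotypes",
    "bin_densities",
    "spearman_rho",
    "proximity_annotation",
    "term_enrichment",
    "plot_spectrum",
    "plot_pca",
]


@dataclass
class FrequencySpectrum:
    """Counts of methylated loci by the number of samples carrying them."""

    counts: dict[int, int]  # k -> number of loci methylated in exactly k samples
    n_samples: int
    line_exclusive: dict[str, int]

    @property
    def monomorphic(self) -> int:
        return self.counts.get(self.n_samples, 0)

    @property
    def singletons(self) -> int:
        return self.counts.get(1, 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        ks = sorted(self.counts)
        return pd.DataFrame({"k": ks, "n_loci": [self.counts[k] for k in ks]})


def frequency_spectrum(
    binary: pd.DataFrame, metadata: pd.DataFrame
) -> FrequencySpectrum:
    """Spectrum of the binary methylotype matrix (samples x loci).

    A locus counts at k when exactly k samples are methylated (masked
    cells are not methylated evidence).  A locus is exclusive to a clonal
    line when every sample of that line is methylated and no sample of
    any other line is.
    """
    if set(binary.index) != set(metadata["sample"]):
        raise ValueError("metadata samples do not match matrix samples")
    meth = binary == 1.0
    k_per_locus = meth.sum(axis=0).astype(int)
    counts: dict[int, int] = {}
    for k in k_per_locus:
        if k > 0:
            counts[k] = counts.get(k, 0) + 1
    line_of = dict(zip(metadata["sample"], metadata["line"]))
    lines = sorted(set(line_of.values()))
    line_exclusive: dict[str, int] = {}
    for line in lines:
        members = [s for s in binary.index if line_of[s] == line]
        others = [s for s in binary.index if line_of[s] != line]
        exclusive = meth.loc[members].all(axis=0) & ~meth.loc[others].any(axis=0)
        line_exclusive[line] = int(exclusive.sum())
    return FrequencySpectrum(
        counts=counts, n_samples=len(binary.index), line_exclusive=line_exclusive
    )


def kruskal_wallis(
    values: Sequence[float], groups: Sequence
) -> tuple[float, float]:
    """Kruskal-Wallis H (midrank tie correction) and chi-square p-value.

    ``groups`` assigns each value to a group (e.g. the subculture count);
    requires >= 2 groups.  Degenerate all-tied data yields H = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    levels = np.unique(groups)
    if levels.size < 2:
        raise ValueError("kruskal_wallis requires >= 2 groups")
    arrays = [values[groups == g] for g in levels]
    if np.all(values == values[0]):
        # all values tied: zero rank variance, tie correction degenerates
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        result = sps.kruskal(*arrays)
    return float(result.statistic), float(result.pvalue)


@dataclass
class PCAResult:
    """Sample coordinates and the variance fraction of each component."""

    coordinates: pd.DataFrame  # samples x PC1..PCk
    explained_variance_ratio: np.ndarray
    degenerate: bool = False


def pca_methylotypes(binary: pd.DataFrame) -> PCAResult:
    """Column-centered SVD of the binary methylotype matrix.

    Masked cells (NaN) are imputed with the locus mean; loci masked in
    every sample are dropped.  Variance fractions are nonnegative and sum
    to 1 unless the matrix has zero variance (then flagged degenerate).
    """
    if binary.shape[0] < 2 or binary.shape[1] < 2:
        raise ValueError("pca_methylotypes requires >= 2 samples and >= 2 loci")
    X = binary.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(X, axis=0, keepdims=True)
    all_nan = np.isnan(col_mean[0])
    X = X[:, ~all_nan]
    col_mean = col_mean[:, ~all_nan]
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean[0], inds[1])
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    total = float((S**2).sum())
    if total == 0.0:
        k = S.size
        return PCAResult(
            coordinates=pd.DataFrame(
                np.zeros((binary.shape[0], k)),
                index=binary.index,
                columns=[f"PC{i + 1}" for i in range(k)],
            ),
            explained_variance_ratio=np.zeros(k),
            degenerate=True,
        )
    coords = U * S
    ratio = S**2 / total
    return PCAResult(
        coordinates=pd.DataFrame(
            coords,
            index=binary.index,
            columns=[f"PC{i + 1}" for i in range(S.size)],
        ),
        explained_variance_ratio=ratio,
        degenerate=False,
    )


def bin_densities(
    loci: pd.DataFrame,
    genes: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    bin_size: int = 500_000,
) -> pd.DataFrame:
    """Per-bin gene and methylated-locus counts.

    Bins of ``bin_size`` tile each chromosome (final partial bin
    included); a feature is counted in the bin containing its start.
    Columns: chrom, bin_start, gene_count, locus_count.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be positive")
    rows = []
    index: dict[tuple[str, int], int] = {}
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        n_bins = max(1, -(-length // bin_size))
        for b in range(n_bins):
            index[(chrom, b)] = len(rows)
            rows.append(
                {"chrom": chrom, "bin_start": b * bin_size, "gene_count": 0,
                 "locus_count": 0}
            )
    for name, df, col in (("gene", genes, "gene_count"), ("locus", loci, "locus_count")):
        if df is None or not len(df):
            continue
        for chrom, start in zip(df["chrom"], df["start"]):
            if chrom not in chrom_lengths:
                raise ValueError(f"{name} on unknown chromosome {chrom}")
            if start >= chrom_lengths[chrom] or start < 0:
                raise ValueError(
                    f"{name} start {start} beyond chromosome {chrom} end"
                )
            rows[index[(chrom, start // bin_size)]][col] += 1
    return pd.DataFrame(rows)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson on midranks, tie-aware).

    Returns NaN for a constant vector (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("spearman_rho requires equal-length vectors of size >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("spearman_rho undefined for a constant vector", RuntimeWarning)
        return float("nan")
    return float(sps.spearmanr(x, y).statistic)


def proximity_annotation(
    loci: pd.DataFrame, transcripts: pd.DataFrame, window: int = 1_000
) -> pd.DataFrame:
    """Assign each locus to every transcript within ``window`` bp.

    A locus is assigned when the transcript interval expanded by
    ``window`` on both sides shares >= 1 bp with the locus.  Returns rows
    (locus, transcript) using the ``locus``/``gene_id`` id columns.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    trees: dict[str, IntervalTree] = {}
    for row in transcripts.itertuples(index=False):
        start = max(0, row.start - window)
        trees.setdefault(row.chrom, IntervalTree()).addi(
            start, row.end + window, row.gene_id
        )
    rows = []
    locus_ids = (
        loci["locus"]
        if "locus" in loci.columns
        else loci["chrom"] + ":" + loci["start"].astype(str) + "-" + loci["end"].astype(str)
    )
    for locus_id, chrom, start, end in zip(
        locus_ids, loci["chrom"], loci["start"], loci["end"]
    ):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(start, end)):
            rows.append({"locus": locus_id, "transcript": hit.data})
    return pd.DataFrame(rows, columns=["locus", "transcript"])


def term_enrichment(
    target: set[str],
    background: set[str],
    gene_terms: pd.DataFrame,
    alpha: float = 0.10,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per term with BH-FDR.

    ``gene_terms`` is a two-column (gene, term) map; terms are tested
    flat, no ontology propagation.  ``target`` must be a subset of
    ``background``.  Returns per-term hits, sizes, raw and adjusted p, and
    the significance flag at ``alpha``.
    """
    if not target <= background:
        raise ValueError("target gene set must be a subset of the background")
    gene_terms = gene_terms.drop_duplicates()
    by_term: dict[str, set[str]] = {
        term: set(sub["gene"]) for term, sub in gene_terms.groupby("term")
    }
    M = len(background)
    n = len(target)
    rows = []
    for term in sorted(by_term):
        members = by_term[term] & background
        K = len(members)
        if K == 0:
            continue
        k = len(members & target)
        p = float(sps.hypergeom.sf(k - 1, M, K, n))
        rows.append(
            {"term": term, "target_hits": k, "background_hits": K,
             "target_size": n, "background_size": M, "p_value": min(p, 1.0)}
        )
    result = pd.DataFrame(
        rows,
        columns=["term", "target_hits", "background_hits", "target_size",
                 "background_size", "p_value"],
    )
    if len(result):
        _, adj, _, _ = multipletests(result["p_value"], method="fdr_bh")
        result["p_adjusted"] = np.maximum(adj, result["p_value"])
        result["significant"] = result["p_adjusted"] < alpha
    else:
        result["p_adjusted"] = []
        result["significant"] = []
    return result


def plot_spectrum(spectrum: FrequencySpectrum, path) -> None:
    """Bar plot of the methylated-locus frequency spectrum."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = spectrum.to_frame()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(frame["k"], frame["n_loci"], color="#2a7e43")
    ax.set_xlabel("samples methylated (k)")
    ax.set_ylabel("methylated loci")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_pca(pca: PCAResult, metadata: pd.DataFrame, path) -> None:
    """PC1/PC2 scatter coloured by clonal line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    line_of = dict(zip(metadata["sample"], metadata["line"]))
    fig, ax = plt.subplots(figsize=(5, 5))
    for line in sorted(set(line_of.values())):
        members = [s for s in pca.coordinates.index if line_of.get(s) == line]
        sub = pca.coordinates.loc[members]
        ax.scatter(sub["PC1"], sub["PC2"], label=line, s=25)
    pct = pca.explained_variance_ratio * 100
    ax.set_xlabel(f"PC1 ({pct[0]:.1f}%)")
    if len(pct) > 1:
        ax.set_ylabel(f"PC2 ({pct[1]:.1f}%)")
    ax.legend(title="line")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
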