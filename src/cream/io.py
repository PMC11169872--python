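"""Format readers/writers and manifest handling.

Conventions: BED output is 0-based half-open, GFF3 is 1-based inclusive;
the conversions live only here.  SAM is accepted everywhere BAM is.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .digest import Fragment, Methylome

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_fragments_bed",
    "write_gff3_genes",
    "read_gff3_genes",
    "read_gene_table",
    "write_methylome_bed",
    "read_methylome_bed",
    "read_manifest",
    "read_metadata",
    "read_matrix",
    "write_matrix",
    "read_term_map",
    "read_yaml",
    "write_yaml",
    "write_loci_bed",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Genome FASTA into an ordered chrom -> uppercase sequence mapping."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_fragments_bed(fragments: list[Fragment], path: str | Path) -> None:
    """Fragments as BED6: name = left/right enzyme pair, score = length."""
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t{f.left_enzyme}/{f.right_enzyme}"
                f"\t{f.length}\t+\n"
            )


def write_gff3_genes(genes: pd.DataFrame, path: str | Path) -> None:
    """Gene table (chrom/start/end/gene_id, 0-based half-open) to GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\tcream\tgene\t{row.start + 1}\t{row.end}\t.\t+\t.\t"
                f"ID={row.gene_id}\n"
            )


def read_gff3_genes(path: str | Path, feature: str = "gene") -> pd.DataFrame:
    """GFF3 ``feature`` rows back to a 0-based half-open gene table."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != feature:
                continue
            attrs = dict(
                item.split("=", 1) for item in fields[8].split(";") if "=" in item
            )
            rows.append(
                {
                    "chrom": fields[0],
                    "start": int(fields[3]) - 1,
                    "end": int(fields[4]),
                    "gene_id": attrs.get("ID", f"{fields[0]}:{fields[3]}"),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Gene annotation as GFF3 or TSV with chrom/start/end/gene_id columns."""
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        return read_gff3_genes(path)
    df = pd.read_csv(path, sep="\t")
    missing = {"chrom", "start", "end", "gene_id"} - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return df


def write_methylome_bed(methylome: Methylome, path: str | Path) -> None:
    """Methylated CCGG start positions as 4-bp BED intervals."""
    with open(path, "w") as fh:
        for chrom in sorted(methylome):
            for pos in sorted(methylome[chrom]):
                fh.write(f"{chrom}\t{pos}\t{pos + 4}\tCCGG\n")


def read_methylome_bed(path: str | Path) -> dict[str, frozenset[int]]:
    meth: dict[str, set[int]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, *_ = line.split("\t")
            meth.setdefault(chrom, set()).add(int(start))
    return {c: frozenset(p) for c, p in meth.items()}


def write_loci_bed(summary: pd.DataFrame, path: str | Path) -> None:
    """Locus summary to BED6 (+ type column): score = methylated samples."""
    with open(path, "w") as fh:
        for row in summary.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.locus}\t"
                f"{row.n_methylated}\t+\t{row.type}\n"
            )


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Alignment manifest TSV: sample, library (MspI|HpaII), path.

    Relative alignment paths are resolved against the manifest's own
    directory.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"sample", "library", "path"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    base = Path(path).parent
    df["path"] = [
        str(p) if Path(p).is_absolute() else str(base / p) for p in df["path"]
    ]
    bad = set(df["library"]) - {"MspI", "HpaII"}
    if bad:
        raise ValueError(f"manifest library labels must be MspI/HpaII, got {bad}")
    dup = df.duplicated(subset=["sample", "library"])
    if dup.any():
        raise ValueError("manifest has duplicate (sample, library) rows")
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV: sample, line, subculture."""
    df = pd.read_csv(path, sep="\t")
    missing = {"sample", "line", "subculture"} - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if df["sample"].duplicated().any():
        raise ValueError("metadata sample ids must be unique")
    if (df["subculture"] < 0).any():
        raise ValueError("subculture counts must be >= 0")
    return df


def write_matrix(statuses: pd.DataFrame, path: str | Path) -> None:
    """Methylotype matrix TSV (rows = samples, columns = loci)."""
    statuses.to_csv(path, sep="\t", index_label="sample")


def read_matrix(path: str | Path) -> pd.DataFrame:
    # keep_default_na=False: the NA status is a literal token, not NaN
    return pd.read_csv(
        path, sep="\t", index_col="sample", dtype=object, keep_default_na=False
    )


def read_term_map(path: str | Path) -> pd.DataFrame:
    """Two-column gene -> term TSV (headerless or headered)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("term map must have two columns (gene, term)")
    if list(df.iloc[0]) == ["gene", "term"]:
        df = df.iloc[1:]
    df = df.iloc[:, :2]
    df.columns = ["gene", "term"]
    return df.reset_index(drop=True)


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def write_yaml(data: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(data), fh, sort_keys=False)
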