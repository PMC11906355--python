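"""Readers and writers for the on-disk artifacts of the pipeline.

All tabular artifacts are plain TSV with a header row.  Sample-by-feature
matrices carry sample identifiers in a first ``sample_id`` column; missing
cells are written as empty fields (never 0).  Genomic coordinates are 1-based
internally (the VCF convention); BED input is converted on read.  Protein
amino-acid coordinates are 1-based inclusive.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortBundle",
    "FormatError",
    "SchemaError",
    "SUMMARY_STATS_COLUMNS",
    "read_vcf",
    "write_vcf",
    "read_matrix",
    "write_matrix",
    "read_summary_stats",
    "write_summary_stats",
    "read_gene_bed",
    "read_table",
    "write_table",
]

#: fixed column order of the GWAS summary-statistics exchange format
SUMMARY_STATS_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "consequence", "gene_id", "aa_pos"]

COVARIATE_COLUMNS = ["age", "sex", "bmi_sds", "obesity", "puberty", "storage", "pc1"]


class FormatError(ValueError):
    """A file violates its format contract (malformed record, bad GT, ...)."""


class SchemaError(ValueError):
    """A table is missing required columns or carries inconsistent keys."""


@dataclasses.dataclass
class CohortBundle:
    """All measured quantities for one cohort, sample-aligned.

    Attributes
    ----------
    genotypes : DataFrame, samples x variants
        Alternate-allele dosages in {0, 1, 2}; NaN for missing calls.
    variants : DataFrame indexed by variant id
        Columns ``chrom, pos, ref, alt, consequence, gene_id, aa_pos``.
    proteins : DataFrame, samples x proteins
        log2 intensities, NaN missing.
    protein_genes : DataFrame indexed by protein id
        Columns ``gene_id, chrom, tss, strand`` mapping each protein to the
        transcription start site of its coding gene.
    peptides : DataFrame, samples x peptides
        log2 intensities, NaN missing.
    peptide_map : DataFrame indexed by peptide id
        Columns ``protein_id, aa_start, aa_end`` (1-based inclusive).
    covariates : DataFrame, samples x covariates
        Columns ``age, sex, bmi_sds, obesity, puberty, storage, pc1``.
    """

    genotypes: pd.DataFrame
    variants: pd.DataFrame
    proteins: pd.DataFrame
    protein_genes: pd.DataFrame
    peptides: pd.DataFrame
    peptide_map: pd.DataFrame
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        sample_ref = list(self.proteins.index)
        for name in ("genotypes", "peptides", "covariates"):
            idx = list(getattr(self, name).index)
            if idx != sample_ref:
                raise SchemaError(
                    f"sample identifiers of '{name}' do not match the protein "
                    "matrix (identical order required; use CohortBundle.aligned)"
                )
        missing_v = set(self.genotypes.columns) - set(self.variants.index)
        if missing_v:
            raise SchemaError(f"variants absent from variant table: {sorted(missing_v)[:5]}")
        unknown = set(self.peptide_map["protein_id"]) - set(self.proteins.columns)
        if unknown:
            raise SchemaError(
                f"peptide map references proteins absent from the protein matrix: "
                f"{sorted(unknown)[:5]}"
            )
        orphan = set(self.peptides.columns) - set(self.peptide_map.index)
        if orphan:
            raise SchemaError(f"peptides without a map entry: {sorted(orphan)[:5]}")
        if (self.variants["pos"] <= 0).any():
            raise SchemaError("genomic positions must be positive (1-based)")
        same = self.variants["ref"] == self.variants["alt"]
        if same.any():
            raise SchemaError(
                f"ref == alt for variants {list(self.variants.index[same])[:5]}"
            )

    @classmethod
    def aligned(cls, genotypes, variants, proteins, protein_genes,
                peptides, peptide_map, covariates) -> "CohortBundle":
        """Build a bundle, intersecting and reordering samples across matrices."""
        common = proteins.index
        for m in (genotypes, peptides, covariates):
            common = common.intersection(m.index)
        if len(common) == 0:
            raise SchemaError("no samples shared across matrices")
        order = [s for s in proteins.index if s in set(common)]
        return cls(
            genotypes=genotypes.loc[order],
            variants=variants,
            proteins=proteins.loc[order],
            protein_genes=protein_genes,
            peptides=peptides.loc[order],
            peptide_map=peptide_map,
            covariates=covariates.loc[order],
        )

    @property
    def n_samples(self) -> int:
        return self.proteins.shape[0]

    def subset_samples(self, samples) -> "CohortBundle":
        return CohortBundle(
            genotypes=self.genotypes.loc[samples],
            variants=self.variants,
            proteins=self.proteins.loc[samples],
            protein_genes=self.protein_genes,
            peptides=self.peptides.loc[samples],
            peptide_map=self.peptide_map,
            covariates=self.covariates.loc[samples],
        )

    def write(self, outdir: str | Path) -> None:
        """Write every component to ``outdir`` in the formats of this module."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_vcf(outdir / "genotypes.vcf", self.genotypes, self.variants)
        write_table(outdir / "variants.tsv", self.variants, index_label="variant_id")
        write_matrix(outdir / "proteins.tsv", self.proteins)
        write_table(outdir / "protein_genes.tsv", self.protein_genes,
                    index_label="protein_id")
        write_matrix(outdir / "peptides.tsv", self.peptides)
        write_table(outdir / "peptide_map.tsv", self.peptide_map,
                    index_label="peptide_id")
        write_matrix(outdir / "covariates.tsv", self.covariates)

    @classmethod
    def read(cls, indir: str | Path) -> "CohortBundle":
        indir = Path(indir)
        genotypes, _ = read_vcf(indir / "genotypes.vcf")
        variants = read_table(indir / "variants.tsv", index_col="variant_id",
                              required=VARIANT_COLUMNS)
        return cls.aligned(
            genotypes=genotypes,
            variants=variants,
            proteins=read_matrix(indir / "proteins.tsv"),
            protein_genes=read_table(indir / "protein_genes.tsv",
                                     index_col="protein_id",
                                     required=["gene_id", "chrom", "tss", "strand"]),
            peptides=read_matrix(indir / "peptides.tsv"),
            peptide_map=read_table(indir / "peptide_map.tsv", index_col="peptide_id",
                                   required=["protein_id", "aa_start", "aa_end"]),
            covariates=read_matrix(indir / "covariates.tsv"),
        )


# ---------------------------------------------------------------------------
# VCF

_GT_DOSAGE = {
    "0/0": 0.0, "0|0": 0.0,
    "0/1": 1.0, "1/0": 1.0, "0|1": 1.0, "1|0": 1.0,
    "1/1": 2.0, "1|1": 2.0,
    "./.": np.nan, ".|.": np.nan, ".": np.nan,
}


def read_vcf(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a biallelic-SNP VCF with GT into (dosage matrix, variant table).

    GT "0/0"/"0/1"/"1/1" map to dosages 0/1/2 (phased separators accepted);
    "./." maps to missing.  Multi-allelic records and unrecognized GT strings
    raise :class:`FormatError` naming the offending line.
    """
    path = Path(path)
    samples: list[str] = []
    ids, rows, vrows = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if len(fields) < 10:
                    raise FormatError(f"{path}:{lineno}: VCF has no sample columns")
                samples = fields[9:]
                continue
            if not samples:
                raise FormatError(f"{path}:{lineno}: data line before #CHROM header")
            fields = line.split("\t")
            if len(fields) != 9 + len(samples):
                raise FormatError(
                    f"{path}:{lineno}: expected {9 + len(samples)} columns, "
                    f"got {len(fields)}"
                )
            chrom, pos, vid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if "," in alt:
                raise FormatError(
                    f"{path}:{lineno}: multi-allelic record {chrom}:{pos} "
                    f"(ALT={alt}) is not supported"
                )
            fmt = fields[8].split(":")
            try:
                gt_idx = fmt.index("GT")
            except ValueError:
                raise FormatError(f"{path}:{lineno}: FORMAT lacks GT") from None
            dosages = []
            for s, cell in zip(samples, fields[9:]):
                gt = cell.split(":")[gt_idx]
                if gt not in _GT_DOSAGE:
                    raise FormatError(
                        f"{path}:{lineno}: malformed GT {gt!r} for sample {s}"
                    )
                dosages.append(_GT_DOSAGE[gt])
            ids.append(vid if vid != "." else f"{chrom}:{pos}:{ref}:{alt}")
            rows.append(dosages)
            vrows.append((chrom, int(pos), ref, alt))
    if not ids:
        raise FormatError(f"{path}: no variant records")
    geno = pd.DataFrame(np.array(rows, dtype=float).T, index=samples, columns=ids)
    geno.index.name = "sample_id"
    var = pd.DataFrame(vrows, index=pd.Index(ids, name="variant_id"),
                       columns=["chrom", "pos", "ref", "alt"])
    var["chrom"] = var["chrom"].astype(str)
    return geno, var


def write_vcf(path: str | Path, genotypes: pd.DataFrame,
              variants: pd.DataFrame) -> None:
    """Write a minimal VCF v4.2 (GT only) from a dosage matrix."""
    inv = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, genotypes.index)) + "\n")
        order = variants.loc[genotypes.columns]
        for vid, row in order.iterrows():
            cells = [
                inv.get(d, "./.") if np.isfinite(d) else "./."
                for d in genotypes[vid].to_numpy(dtype=float)
            ]
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{vid}\t{row['ref']}\t"
                     f"{row['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# TSV matrices and tables

def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a samples-x-features TSV matrix (first column ``sample_id``)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "sample_id":
        raise SchemaError(f"{path}: first column must be 'sample_id', "
                          f"found {df.columns[0]!r}")
    df = df.set_index("sample_id")
    return df.apply(pd.to_numeric, errors="coerce") if df.shape[1] else df


def write_matrix(path: str | Path, matrix: pd.DataFrame) -> None:
    out = matrix.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.15g", na_rep="")


def read_table(path: str | Path, index_col: str,
               required: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = [index_col] + (required or [])
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return df.set_index(index_col)


def write_table(path: str | Path, table: pd.DataFrame, index_label: str) -> None:
    table.to_csv(path, sep="\t", index_label=index_label,
                 float_format="%.15g", na_rep="")


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SUMMARY_STATS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: summary-stats file missing columns {missing}")
    df["chrom"] = df["chrom"].astype(str)
    return df[SUMMARY_STATS_COLUMNS]


def write_summary_stats(path: str | Path, stats: pd.DataFrame) -> None:
    missing = [c for c in SUMMARY_STATS_COLUMNS if c not in stats.columns]
    if missing:
        raise SchemaError(f"summary-stats table missing columns {missing}")
    stats[SUMMARY_STATS_COLUMNS].to_csv(path, sep="\t", index=False,
                                        float_format="%.15g", na_rep="")


def read_gene_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED-like gene table into a 1-based TSS table.

    Accepts ``chrom start end name [score] strand`` (whitespace separated,
    0-based half-open).  The TSS is ``start + 1`` on the + strand and ``end``
    on the − strand, both 1-based.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise FormatError(f"{path}:{lineno}: need at least 5 BED columns")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5] if len(parts) >= 6 else parts[4]
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            tss = start + 1 if strand == "+" else end
            rows.append((name, chrom, tss, strand))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])
    return df.set_index("gene_id")
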