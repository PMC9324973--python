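"""Readers and writers for the pipeline's plain-text interchange formats.

Formats:

* genotype dosages — VCF with a ``DS`` FORMAT field (read via cyvcf2,
  written as uncompressed VCF 4.2 text) or a variant-per-row TSV matrix;
* SNP weights — TSV: variant_id, effect_allele, other_allele, weight
  (compatible with a three-column scoring-file layout plus the other allele);
* metabolite abundances — CSV, samples x metabolites, empty cell = missing;
* metabolite annotation — CSV: metabolite_id, superpathway, subpathway,
  xenobiotic;
* phenotypes — CSV, one row per sample.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix, PhenotypeTable


# -- genotypes ---------------------------------------------------------------

def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Variant-per-row dosage matrix: variant_id, effect_allele, other_allele,
    then one column per sample (dosage of the effect allele)."""
    df = genotypes.variants.copy()
    dos = pd.DataFrame(genotypes.dosages.T, columns=genotypes.samples)
    pd.concat([df.reset_index(drop=True), dos], axis=1).to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path: str | os.PathLike) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["variant_id", "effect_allele", "other_allele"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: dosage TSV lacks columns {missing}")
    samples = [c for c in df.columns if c not in meta_cols]
    return GenotypeMatrix(
        samples=samples,
        variants=df[meta_cols].copy(),
        dosages=df[samples].to_numpy(dtype=float).T,
    )


def write_vcf(genotypes: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Uncompressed VCF 4.2 with the effect allele as ALT and per-sample
    dosage in the DS FORMAT field (GT emitted as ./. placeholders)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of ALT allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(genotypes.samples) + "\n")
        for j, row in enumerate(genotypes.variants.itertuples(index=False)):
            ds = genotypes.dosages[:, j]
            cells = "\t".join(f"./.:{d:.3f}" for d in ds)
            fh.write(f"1\t{j + 1}\t{row.variant_id}\t{row.other_allele}\t{row.effect_allele}\t.\tPASS\t.\tGT:DS\t{cells}\n")


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read dosages from the DS FORMAT field; ALT is the counted allele."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, effect, other, rows = [], [], [], []
    for var in vcf:
        ds = var.format("DS")
        if ds is None:
            raise ValueError(f"{path}: variant {var.ID} has no DS field")
        ids.append(var.ID)
        other.append(var.REF)
        effect.append(var.ALT[0])
        rows.append(np.asarray(ds, dtype=float).reshape(-1))
    return GenotypeMatrix(
        samples=samples,
        variants=pd.DataFrame({"variant_id": ids, "effect_allele": effect, "other_allele": other}),
        dosages=np.asarray(rows).T if rows else np.empty((len(samples), 0)),
    )


def read_genotypes(path: str | os.PathLike) -> GenotypeMatrix:
    """Dispatch on extension: .vcf -> VCF, otherwise dosage TSV."""
    if str(path).endswith((".vcf", ".vcf.gz")):
        return read_vcf(path)
    return read_dosage_tsv(path)


# -- weights -----------------------------------------------------------------

def write_weights_tsv(weights: pd.DataFrame, path: str | os.PathLike) -> None:
    weights[["variant_id", "effect_allele", "other_allele", "weight"]].to_csv(path, sep="\t", index=False)


def read_weights_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"variant_id", "effect_allele", "weight"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: weights TSV needs columns {sorted(required)}")
    if "other_allele" not in df.columns:
        df["other_allele"] = ""
    if df["variant_id"].duplicated().any():
        dups = df.loc[df["variant_id"].duplicated(), "variant_id"].tolist()
        raise ValueError(f"{path}: duplicated variant ids {dups[:5]}")
    if not np.isfinite(df["weight"].to_numpy(dtype=float)).all():
        raise ValueError(f"{path}: non-finite weights")
    return df


# -- metabolites -------------------------------------------------------------

def write_abundance_csv(abundance: pd.DataFrame, path: str | os.PathLike) -> None:
    """Samples x metabolites; NaN written as empty cells."""
    abundance.to_csv(path, index=True, index_label="sample_id", na_rep="")


def read_abundance_csv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="sample_id")
    return df.astype(float)


def write_annotation_csv(annotation: pd.DataFrame, path: str | os.PathLike) -> None:
    annotation.to_csv(path, index=False)


def read_annotation_csv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "xenobiotic" in df.columns:
        df["xenobiotic"] = df["xenobiotic"].astype(bool)
    return df


# -- phenotypes --------------------------------------------------------------

def write_phenotypes_csv(phenotypes: PhenotypeTable, path: str | os.PathLike, series_path: str | os.PathLike | None = None) -> None:
    phenotypes.data.to_csv(path, index=False)
    if series_path is not None and phenotypes.bmi_series is not None:
        phenotypes.bmi_series.to_csv(series_path, index=False)


def read_phenotypes_csv(path: str | os.PathLike, series_path: str | os.PathLike | None = None) -> PhenotypeTable:
    data = pd.read_csv(path)
    series = None
    if series_path is not None and Path(series_path).exists():
        series = pd.read_csv(series_path)
    return PhenotypeTable(data=data, bmi_series=series)
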