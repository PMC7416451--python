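"""Readers and writers for cohort artifacts.

Plain-text formats only: subjects/covariates and metabolite matrices as
TSV (censored cells written as "NA"), genotypes as a dosage TSV and as
a minimal VCF v4.2 (GT from dosage rounding, DS carrying the dosage),
and the simulation ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .qc import MetaboliteMatrix
from .simulate import SyntheticCohort

__all__ = [
    "write_cohort",
    "write_metabolites",
    "read_metabolites",
    "read_subjects",
    "write_vcf",
    "read_vcf_dosages",
]


def write_metabolites(m: MetaboliteMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", na_rep="NA")


def read_metabolites(path, meta: pd.DataFrame, timepoint: str, transform: str = "raw",
                     batch: pd.Series | None = None) -> MetaboliteMatrix:
    vals = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
    vals.columns.name = "metabolite"
    return MetaboliteMatrix(values=vals, meta=meta.loc[vals.columns], timepoint=timepoint,
                            transform=transform, batch=batch)


def read_subjects(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_vcf(dosages: pd.DataFrame, snp_meta: pd.DataFrame, path) -> None:
    """Minimal VCF v4.2: GT by rounding dosage, DS with the dosage itself."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of the ALT allele">\n')
        samples = "\t".join(dosages.index)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for snp in dosages.columns:
            row = snp_meta.loc[snp]
            dos = dosages[snp].to_numpy(dtype=float)
            cells = "\t".join(
                f"{gt_map[int(round(min(max(d, 0), 2)))]}:{d:g}" for d in dos
            )
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{snp}\t{row['other_allele']}\t"
                f"{row['effect_allele']}\t.\tPASS\t.\tGT:DS\t{cells}\n"
            )


def read_vcf_dosages(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read dosages (DS preferred, else GT allele counts) and SNP metadata."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, meta_rows, ids = [], [], []
    for variant in vcf:
        snp_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
        ds = variant.format("DS")
        if ds is not None:
            dos = np.asarray(ds, dtype=float).ravel()
        else:
            gts = variant.genotypes  # [allele0, allele1, phased]
            dos = np.array([g[0] + g[1] for g in gts], dtype=float)
        cols.append(dos)
        ids.append(snp_id)
        meta_rows.append(
            {
                "chrom": variant.CHROM,
                "pos": variant.POS,
                "effect_allele": variant.ALT[0] if variant.ALT else ".",
                "other_allele": variant.REF,
            }
        )
    dosages = pd.DataFrame(np.column_stack(cols), index=samples, columns=ids)
    snp_meta = pd.DataFrame(meta_rows, index=pd.Index(ids, name="snp"))
    return dosages, snp_meta


def write_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Write all cohort artifacts; returns {name: path}."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _save(name, fn):
        p = out / name
        fn(p)
        paths[name] = str(p)

    _save("subjects.tsv", lambda p: cohort.subjects.to_csv(p, sep="\t", na_rep="NA"))
    _save("metabolites_fasting.tsv", lambda p: write_metabolites(cohort.fasting, p))
    _save("metabolites_1h.tsv", lambda p: write_metabolites(cohort.one_hour, p))
    _save("metabolite_meta.tsv", lambda p: cohort.fasting.meta.to_csv(p, sep="\t"))
    _save("dosages.tsv", lambda p: cohort.dosages.to_csv(p, sep="\t"))
    _save("snp_meta.tsv", lambda p: cohort.snp_meta.to_csv(p, sep="\t"))
    _save("genotypes.vcf", lambda p: write_vcf(cohort.dosages, cohort.snp_meta, p))
    _save(
        "truth.json",
        lambda p: p.write_text(json.dumps(cohort.truth.scalars(), indent=2, sort_keys=True)),
    )
    return paths
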