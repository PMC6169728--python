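"""File I/O for summary statistics and genotype panels.

Text formats only: a documented tab-separated summary-statistics layout,
PLINK-style ``.traw`` transposed dosage text, and plain (uncompressed) VCF.
The effect allele is the COUNTED allele in ``.traw`` and the ALT allele in
VCF output.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd

from .prs import GenotypePanel, SummaryStatRecord

__all__ = [
    "SUMSTATS_COLUMNS",
    "write_sumstats",
    "read_sumstats",
    "write_traw",
    "read_traw",
    "write_vcf",
    "read_vcf",
]

#: Column order of the summary-statistics TSV (schema v1).
SUMSTATS_COLUMNS = (
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "z",
    "p_value",
    "allele_freq",
    "n_eff",
    "info",
    "is_multiallelic",
)


def write_sumstats(records: Sequence[SummaryStatRecord], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [
            {c: getattr(r, c) for c in SUMSTATS_COLUMNS}
            for r in records
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_sumstats(path: str | os.PathLike) -> list[SummaryStatRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = set(SUMSTATS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"summary statistics file missing columns: {sorted(missing)}")
    return [
        SummaryStatRecord(
            variant_id=str(row.variant_id),
            chromosome=str(row.chromosome),
            position=int(row.position),
            effect_allele=str(row.effect_allele),
            other_allele=str(row.other_allele),
            z=float(row.z),
            p_value=float(row.p_value),
            allele_freq=float(row.allele_freq),
            n_eff=float(row.n_eff),
            info=float(row.info),
            is_multiallelic=bool(row.is_multiallelic),
        )
        for row in df.itertuples(index=False)
    ]


def write_traw(panel: GenotypePanel, path: str | os.PathLike) -> None:
    """PLINK-style transposed dosage text: one row per variant."""
    v = panel.variants
    head = pd.DataFrame(
        {
            "CHR": v["chromosome"].astype(str),
            "SNP": v["variant_id"],
            "(C)M": 0,
            "POS": v["position"],
            "COUNTED": v["effect_allele"],
            "ALT": v["other_allele"],
        }
    )
    dose = pd.DataFrame(panel.dosages.T, columns=panel.sample_ids)
    pd.concat([head.reset_index(drop=True), dose], axis=1).to_csv(
        path, sep="\t", index=False, na_rep="NA"
    )


def read_traw(path: str | os.PathLike) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    meta_cols = ["CHR", "SNP", "(C)M", "POS", "COUNTED", "ALT"]
    missing = set(meta_cols) - set(df.columns)
    if missing:
        raise ValueError(f".traw file missing columns: {sorted(missing)}")
    sample_ids = [c for c in df.columns if c not in meta_cols]
    variants = pd.DataFrame(
        {
            "variant_id": df["SNP"].astype(str),
            "chromosome": df["CHR"].astype(str),
            "position": df["POS"].astype(int),
            "effect_allele": df["COUNTED"].astype(str),
            "other_allele": df["ALT"].astype(str),
        }
    )
    dosages = df[sample_ids].to_numpy(dtype=float).T
    return GenotypePanel(sample_ids=list(sample_ids), variants=variants, dosages=dosages)


_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(panel: GenotypePanel, path: str | os.PathLike) -> None:
    """Plain-text VCF with hard-call genotypes; ALT is the effect allele."""
    v = panel.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(v["chromosome"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        order = np.lexsort((v["position"].to_numpy(), v["chromosome"].astype(str).to_numpy()))
        for j in order:
            row = v.iloc[j]
            calls = []
            for d in panel.dosages[:, j]:
                if np.isnan(d):
                    calls.append("./.")
                else:
                    calls.append(_GT_CODE[round(float(d))])
            fh.write(
                f"{row.chromosome}\t{row.position}\t{row.variant_id}\t"
                f"{row.other_allele}\t{row.effect_allele}\t.\t.\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def read_vcf(path: str | os.PathLike) -> GenotypePanel:
    """Read a VCF into a dosage panel (effect allele = ALT allele count)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    meta = []
    rows = []
    for rec in vcf:
        alt = rec.ALT[0] if rec.ALT else "."
        meta.append(
            {
                "variant_id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "chromosome": str(rec.CHROM),
                "position": int(rec.POS),
                "effect_allele": alt,
                "other_allele": rec.REF,
            }
        )
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types.astype(float)
        dose = np.where(gt == 3, 2.0, gt)
        dose[gt == 2] = np.nan
        rows.append(dose)
    vcf.close()
    variants = pd.DataFrame(meta)
    dosages = np.array(rows, dtype=float).T if rows else np.empty((len(sample_ids), 0))
    return GenotypePanel(sample_ids=sample_ids, variants=variants, dosages=dosages)
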