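"""Reading and writing the package's on-disk formats.

Genotypes travel as VCF v4.2 (homozygous GT for inbred panels, unphased GT
for hybrids; genetic-map position carried in the INFO ``CM`` field),
phenotypes and pedigrees as plain CSV, and population designs as JSON.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypeMatrix

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CM,Number=1,Type=Float,Description="Genetic map position (cM)">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = pd.unique(g.loci["chrom"])
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.ids)
            + "\n"
        )
        dosage = g.dosage
        for j, rec in enumerate(g.loci.itertuples(index=False)):
            info = f"CM={rec.cm:.4f}" if np.isfinite(rec.cm) else "."
            gts = "\t".join(_GT[int(d)] for d in dosage[:, j])
            fh.write(
                f"{rec.chrom}\t{int(rec.pos)}\t{rec.id}\t{rec.ref}\t{rec.alt}"
                f"\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    loci_rows = []
    dosage_cols = []
    for var in vcf:
        cm = var.INFO.get("CM")
        loci_rows.append(
            (
                var.ID or f"{var.CHROM}_{var.POS}",
                var.CHROM,
                var.POS,
                float(cm) if cm is not None else np.nan,
                var.REF,
                var.ALT[0] if var.ALT else "N",
            )
        )
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types
        col = np.full(len(ids), MISSING, dtype=np.int8)
        col[gt == 0] = 0
        col[gt == 1] = 1
        col[gt == 3] = 2
        dosage_cols.append(col)
    vcf.close()
    loci = pd.DataFrame(
        loci_rows, columns=["id", "chrom", "pos", "cm", "ref", "alt"]
    )
    dosage = (
        np.column_stack(dosage_cols)
        if dosage_cols
        else np.zeros((len(ids), 0), dtype=np.int8)
    )
    return GenotypeMatrix(ids, loci, dosage)


def write_phenotypes(records: pd.DataFrame, path) -> None:
    cols = ["genotype_id", "env", "block", "trait", "value"]
    records[cols].to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"genotype_id": str, "env": str, "block": str})
    required = {"genotype_id", "env", "block", "trait", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    return df


def write_pedigree(lines: pd.DataFrame, path) -> None:
    lines.to_csv(path, index=False)


def read_pedigree(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str)
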