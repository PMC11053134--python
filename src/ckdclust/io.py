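"""Readers and writers for the pipeline's plain-text formats.

Conventions: TSV with header for variant/proxy/association tables
(1-based positions), dosage matrices as TSV with individuals in rows, a
minimal VCF (GT only) for genotype interchange, CSV for phenotypes and
cohort tables, GMT for gene sets.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .assoc import ProxyLink, TraitAssociation, VariantRecord

__all__ = [
    "read_variants", "write_variants",
    "read_proxies", "write_proxies",
    "read_associations", "write_associations",
    "read_dosages", "write_dosages",
    "read_vcf", "write_vcf",
    "read_gmt", "write_gmt",
]


def write_variants(path, variants: list[VariantRecord]) -> None:
    pd.DataFrame(
        [
            {
                "rsid": v.rsid, "chrom": v.chrom, "pos": v.pos,
                "effect_allele": v.effect_allele, "other_allele": v.other_allele,
                "kidney_decreasing_allele": v.kidney_decreasing_allele,
            }
            for v in variants
        ]
    ).to_csv(path, sep="\t", index=False)


def read_variants(path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        VariantRecord(
            rsid=r.rsid, chrom=str(r.chrom), pos=int(r.pos),
            effect_allele=r.effect_allele, other_allele=r.other_allele,
            kidney_decreasing_allele=r.kidney_decreasing_allele,
        )
        for r in df.itertuples()
    ]


def write_proxies(path, proxies: list[ProxyLink]) -> None:
    pd.DataFrame(
        [{"lead_rsid": p.lead_rsid, "proxy_rsid": p.proxy_rsid, "r2": p.r2} for p in proxies]
    ).to_csv(path, sep="\t", index=False)


def read_proxies(path) -> list[ProxyLink]:
    df = pd.read_csv(path, sep="\t")
    return [ProxyLink(r.lead_rsid, r.proxy_rsid, float(r.r2)) for r in df.itertuples()]


def write_associations(path, records: list[TraitAssociation]) -> None:
    pd.DataFrame(
        [
            {
                "proxy_rsid": r.proxy_rsid, "trait": r.trait, "B": r.B, "SE": r.SE,
                "p": r.p, "n": r.n, "gender_specific": r.gender_specific,
                "study_id": r.study_id, "effect_allele": r.effect_allele or "",
                "decoy_rule": r.decoy_rule or "",
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def read_associations(path) -> list[TraitAssociation]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    out = []
    for r in df.itertuples():
        out.append(
            TraitAssociation(
                proxy_rsid=r.proxy_rsid, trait=r.trait, B=float(r.B), SE=float(r.SE),
                p=float(r.p), n=int(r.n),
                gender_specific=str(r.gender_specific).lower() in ("true", "1"),
                study_id=str(r.study_id),
                effect_allele=str(r.effect_allele) or None,
                decoy_rule=str(r.decoy_rule) or None,
            )
        )
    return out


def write_dosages(path, dosages: pd.DataFrame) -> None:
    dosages.to_csv(path, sep="\t", index_label="individual_id")


def read_dosages(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="individual_id")


def write_vcf(path, dosages: pd.DataFrame, chrom: str = "1") -> None:
    """Write hard-call dosages as a minimal GT-only VCF (REF=G, ALT=A).

    The ALT allele is the counted allele, so dosage == ALT allele count.
    Missing dosages become './.'.
    """
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(dosages.index)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j, rsid in enumerate(dosages.columns):
            calls = [
                gt_of.get(int(d), "./.") if not np.isnan(d) else "./."
                for d in dosages[rsid].to_numpy(dtype=float)
            ]
            fh.write(
                f"{chrom}\t{10_000 + 100 * j}\t{rsid}\tG\tA\t.\tPASS\t.\tGT\t"
                + "\t".join(calls) + "\n"
            )


def read_vcf(path) -> pd.DataFrame:
    """Read GT calls from a VCF into a dosage matrix (ALT allele count)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    ids, rows = [], []
    for var in vcf:
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        # gt_types: 0=hom ref, 1=het, 2=hom alt (gts012), 3=unknown
        dos = np.array(var.gt_types, dtype=float)
        dos[dos == 3] = np.nan
        rows.append(dos)
    vcf.close()
    return pd.DataFrame(np.array(rows).T, index=samples, columns=ids)


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file into {set name: [genes]}."""
    from gseapy.parser import read_gmt as _read_gmt

    return _read_gmt(str(path))


def write_gmt(path, gene_sets: dict[str, list[str]], description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")
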