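"""Genotype tables: per-individual effect-allele counts plus HLA genotype.

The in-memory representation is a pandas DataFrame indexed by individual id
with an ``hla_genotype`` column and one column per rsid holding effect-allele
counts in {0, 1, 2} (NaN = missing).
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .weights import HLA_CLASSES, SchemaError, WeightTable

logger = logging.getLogger(__name__)

HLA_COL = "hla_genotype"

AMBIGUOUS_PAIRS = frozenset({frozenset("AT"), frozenset("CG")})
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def validate_genotypes(genotypes: pd.DataFrame) -> pd.DataFrame:
    if HLA_COL not in genotypes.columns:
        raise SchemaError(f"genotype table lacks an {HLA_COL!r} column")
    bad_hla = ~genotypes[HLA_COL].isin(HLA_CLASSES)
    if bad_hla.any():
        raise SchemaError(
            f"unknown HLA genotype class for individuals "
            f"{list(genotypes.index[bad_hla][:5])}"
        )
    counts = genotypes.drop(columns=[HLA_COL])
    vals = counts.to_numpy(dtype=float)
    ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
    if not ok.all():
        r, c = np.argwhere(~ok)[0]
        raise SchemaError(
            f"allele count outside {{0,1,2,NA}} at individual "
            f"{genotypes.index[r]!r}, SNP {counts.columns[c]!r}"
        )
    return genotypes


def read_genotype_tsv(path) -> pd.DataFrame:
    """Read a genotype TSV: individual_id, hla_genotype, one column per rsid."""
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    if df.columns[0] != "individual_id":
        raise SchemaError(f"{path}: first column must be individual_id")
    df = df.set_index("individual_id")
    return validate_genotypes(df)


def write_genotype_tsv(genotypes: pd.DataFrame, path) -> None:
    genotypes.to_csv(path, sep="\t", index_label="individual_id", na_rep="NA")


def read_vcf_dosages(path, hla_genotypes: pd.Series) -> pd.DataFrame:
    """Extract diploid effect-allele counts from a VCF's GT fields.

    The ALT allele is taken as the counted allele (harmonize downstream with
    :func:`harmonize_effect_alleles`).  Half-calls and missing genotypes are
    treated as missing.  ``hla_genotypes`` supplies the HLA class per sample,
    since HLA DR-DQ genotypes are not encoded in the SNP VCF.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    data: dict[str, np.ndarray] = {}
    for var in vcf:
        if var.ID is None or len(var.ALT) != 1:
            continue
        gts = var.genotype.array()[:, :2]
        counts = (gts > 0).sum(axis=1).astype(float)
        counts[(gts < 0).any(axis=1)] = np.nan
        data[var.ID] = counts
    df = pd.DataFrame(data, index=pd.Index(samples, name="individual_id"))
    df.insert(0, HLA_COL, hla_genotypes.reindex(samples))
    return validate_genotypes(df)


def harmonize_effect_alleles(
    table: WeightTable,
    genotypes: pd.DataFrame,
    counted_alleles: dict[str, str],
    other_alleles: dict[str, str] | None = None,
    drop_ambiguous: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Flip counts where the genotype file counted the non-effect allele.

    ``counted_alleles`` maps rsid -> the allele whose copies the genotype
    column counts.  Where that allele differs from the weight table's effect
    allele, counts c become 2 - c.  Strand-ambiguous SNPs (A/T or C/G) whose
    counted allele mismatches are unresolvable without frequency information
    and are excluded by default (counts set to missing).

    Returns the harmonized table and the list of flagged ambiguous rsids.
    """
    out = genotypes.copy()
    flagged: list[str] = []
    for rsid, sw in table.snp_weights.items():
        if rsid not in out.columns or rsid not in counted_alleles:
            continue
        counted = counted_alleles[rsid]
        if counted == sw.effect_allele:
            continue
        other = (other_alleles or {}).get(rsid)
        if other is not None and counted != other:
            raise ValueError(
                f"{rsid}: counted allele {counted!r} matches neither score allele "
                f"({sw.effect_allele}/{other})"
            )
        pair = frozenset({sw.effect_allele, counted})
        if pair in AMBIGUOUS_PAIRS:
            flagged.append(rsid)
            if drop_ambiguous:
                out[rsid] = np.nan
                logger.warning("%s: strand-ambiguous allele mismatch; excluded", rsid)
                continue
        out[rsid] = 2.0 - out[rsid]
    return out, flagged
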