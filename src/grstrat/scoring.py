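"""Per-individual genetic score computation.

score = HLA genotype weight + Σ_snp weight × effect-allele count, summed over
the SNPs that are non-missing for the individual.  Missing SNPs contribute
zero (no renormalisation), matching how the published scores were computed on
incomplete typing panels.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import HLA_COL, validate_genotypes
from .weights import WeightTable


def compute_scores(table: WeightTable, genotypes: pd.DataFrame) -> pd.DataFrame:
    """Compute one score per individual.

    Parameters
    ----------
    table
        Weight table (already proxy-resolved against the typing panel).
    genotypes
        DataFrame indexed by individual id with ``hla_genotype`` and per-rsid
        count columns; NaN counts are missing.

    Returns
    -------
    DataFrame indexed by individual id with columns ``score``,
    ``n_snps_used`` and ``n_snps_missing`` (used + missing = table.n_snps).
    """
    validate_genotypes(genotypes)
    hla = genotypes[HLA_COL].map(table.hla_weights)
    if hla.isna().any():
        bad = genotypes.index[hla.isna()][:5]
        raise ValueError(f"no HLA weight for genotype of individuals {list(bad)}")

    rsids = table.rsids
    weights = np.array([table.snp_weights[r].weight for r in rsids])
    counts = genotypes.reindex(columns=rsids).to_numpy(dtype=float)

    missing = np.isnan(counts)
    contrib = np.where(missing, 0.0, counts) @ weights
    return pd.DataFrame(
        {
            "score": hla.to_numpy(dtype=float) + contrib,
            "n_snps_used": (~missing).sum(axis=1),
            "n_snps_missing": missing.sum(axis=1),
        },
        index=genotypes.index,
    )


def write_scores_tsv(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index_label="individual_id")


def read_scores_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"individual_id": str}).set_index(
        "individual_id"
    )
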