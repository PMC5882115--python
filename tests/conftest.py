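import numpy as np
import pandas as pd
import pytest

from grstrat import (
    CohortConfig,
    WeightTable,
    SnpWeight,
    load_demo_maf,
    load_demo_tables,
    merge_weight_tables,
    apply_proxy_map,
)
from grstrat.genotypes import HLA_COL


def make_table(specs, hla=None, name="test", proxy_map=None):
    """specs: iterable of (rsid, effect_allele, weight)."""
    weights = {
        rsid: SnpWeight(rsid=rsid, locus=f"LOC_{rsid}", effect_allele=ea,
                        weight=w, source=name)
        for rsid, ea, w in specs
    }
    return WeightTable(
        name=name,
        snp_weights=weights,
        hla_weights=hla or {"DR3/DR4-DQ8": 3.0, "DR4-DQ8/DR4-DQ8": 2.5},
        proxy_map=proxy_map or {},
    )


def make_genotypes(counts, hla="DR3/DR4-DQ8"):
    """counts: dict rsid -> list of per-individual counts (NaN = missing)."""
    n = len(next(iter(counts.values())))
    df = pd.DataFrame(counts, index=pd.Index([f"i{k}" for k in range(n)],
                                             name="individual_id"))
    df.insert(0, HLA_COL, hla if isinstance(hla, str) else list(hla))
    return df


@pytest.fixture(scope="session")
def demo_tables():
    return load_demo_tables()


@pytest.fixture(scope="session")
def demo_maf():
    return load_demo_maf()


@pytest.fixture(scope="session")
def merged_demo(demo_tables, demo_maf):
    winkler, oram = demo_tables
    panel = set(demo_maf)
    return merge_weight_tables(
        apply_proxy_map(winkler, panel), apply_proxy_map(oram, panel)
    )


@pytest.fixture(scope="session")
def demo_config(demo_maf):
    return CohortConfig(n_individuals=4000, maf=demo_maf, seed=20180403)


@pytest.fixture(scope="session")
def demo_cohort(demo_config, merged_demo):
    from grstrat import simulate_cohort

    return simulate_cohort(demo_config, merged_demo)


@pytest.fixture
def rng():
    return np.random.default_rng(97)
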