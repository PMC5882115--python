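"""Weight tables for additive type 1 diabetes genetic risk scores.

A genetic score is the HLA DR-DQ genotype weight plus, for each non-HLA SNP,
a per-allele weight multiplied by the individual's effect-allele count
(0, 1 or 2).  Two published scores (here called *winkler* and *oram*) share a
subset of loci; a *merged* score averages the weights of shared SNPs and
keeps the original weight of score-unique SNPs, except for SNPs whose weight
sign disagrees between the two sources, where the oram weight is kept.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
HLA_CLASSES = ("DR3/DR4-DQ8", "DR4-DQ8/DR4-DQ8")

#: SNPs with a negative weight in the winkler score but a positive weight in
#: the oram score; the merged score keeps the oram weight for these.
SIGN_CONFLICT_RSIDS = frozenset({"rs2069763", "rs3825932"})


class SchemaError(ValueError):
    """A weight/genotype file violates its documented schema."""


@dataclass(frozen=True)
class SnpWeight:
    """Additive per-effect-allele weight (log-odds scale) for one SNP."""

    rsid: str
    locus: str
    effect_allele: str
    weight: float
    source: str = "unknown"

    def __post_init__(self):
        if not self.rsid:
            raise SchemaError("empty rsid")
        if self.effect_allele not in VALID_ALLELES:
            raise SchemaError(
                f"{self.rsid}: effect allele {self.effect_allele!r} not one of A/C/G/T"
            )
        if not pd.notna(self.weight) or abs(self.weight) == float("inf"):
            raise SchemaError(f"{self.rsid}: non-finite weight")


@dataclass(frozen=True)
class HlaWeight:
    genotype_class: str
    weight: float

    def __post_init__(self):
        if self.genotype_class not in HLA_CLASSES:
            raise SchemaError(f"unknown HLA genotype class {self.genotype_class!r}")
        if not pd.notna(self.weight) or abs(self.weight) == float("inf"):
            raise SchemaError(f"{self.genotype_class}: non-finite weight")


@dataclass
class WeightTable:
    """One genetic score: SNP weights keyed by rsid plus HLA genotype weights."""

    name: str
    snp_weights: dict[str, SnpWeight] = field(default_factory=dict)
    hla_weights: dict[str, float] = field(default_factory=dict)
    proxy_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        # proxy_map keys are rsids that may appear in snp_weights (they are
        # what gets renamed); a proxy *target* colliding with an existing
        # weight entry would silently overwrite a weight, so it is rejected.
        for missing, proxy in self.proxy_map.items():
            if proxy in self.snp_weights:
                raise SchemaError(
                    f"proxy target {proxy} for {missing} collides with an existing weight entry"
                )

    @property
    def rsids(self) -> list[str]:
        return list(self.snp_weights)

    @property
    def n_snps(self) -> int:
        return len(self.snp_weights)

    def hla_weight(self, genotype_class: str) -> float:
        if genotype_class not in self.hla_weights:
            raise ValueError(
                f"{self.name}: no HLA weight for genotype class {genotype_class!r}"
            )
        return self.hla_weights[genotype_class]


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def load_weight_table(
    snp_path,
    hla_path=None,
    proxy_path=None,
    source: str = "unknown",
) -> WeightTable:
    """Load a weight table from TSV files.

    ``snp_path`` columns: rsid, locus, effect_allele, weight.
    ``hla_path`` columns: genotype_class, weight.
    ``proxy_path`` columns: missing_rsid, proxy_rsid.
    """
    df = _read_tsv(snp_path)
    required = ["rsid", "locus", "effect_allele", "weight"]
    if list(df.columns[: len(required)]) != required:
        raise SchemaError(
            f"{snp_path}: expected columns {required}, got {list(df.columns)}"
        )
    snp_weights: dict[str, SnpWeight] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            weight = float(row.weight)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{snp_path} line {i}: bad weight {row.weight!r}") from exc
        if row.rsid in snp_weights:
            raise SchemaError(f"{snp_path} line {i}: duplicate rsid {row.rsid}")
        snp_weights[row.rsid] = SnpWeight(
            rsid=row.rsid,
            locus=row.locus,
            effect_allele=row.effect_allele,
            weight=weight,
            source=source,
        )

    hla_weights: dict[str, float] = {}
    if hla_path is not None:
        hdf = _read_tsv(hla_path)
        if list(hdf.columns[:2]) != ["genotype_class", "weight"]:
            raise SchemaError(f"{hla_path}: expected columns genotype_class, weight")
        for i, row in enumerate(hdf.itertuples(index=False), start=2):
            hw = HlaWeight(row.genotype_class, float(row.weight))
            if hw.genotype_class in hla_weights:
                raise SchemaError(f"{hla_path} line {i}: duplicate genotype class")
            hla_weights[hw.genotype_class] = hw.weight

    proxy_map: dict[str, str] = {}
    if proxy_path is not None:
        pdf = _read_tsv(proxy_path)
        if list(pdf.columns[:2]) != ["missing_rsid", "proxy_rsid"]:
            raise SchemaError(f"{proxy_path}: expected columns missing_rsid, proxy_rsid")
        proxy_map = dict(zip(pdf["missing_rsid"], pdf["proxy_rsid"]))

    return WeightTable(
        name=source, snp_weights=snp_weights, hla_weights=hla_weights, proxy_map=proxy_map
    )


def apply_proxy_map(table: WeightTable, available_rsids: set[str]) -> WeightTable:
    """Rename unavailable rsids to their typed proxies; drop those without one.

    An unavailable SNP with an available proxy keeps its weight under the
    proxy's rsid.  An unavailable SNP with no usable proxy is removed from the
    table (and logged); the score is then computed over fewer SNPs with no
    renormalisation.
    """
    available = set(available_rsids)
    new_weights: dict[str, SnpWeight] = {}
    for rsid, sw in table.snp_weights.items():
        if rsid in available:
            new_weights[rsid] = sw
            continue
        proxy = table.proxy_map.get(rsid)
        if proxy is not None and proxy in available:
            new_weights[proxy] = replace(sw, rsid=proxy)
        else:
            logger.warning(
                "%s: %s (%s) not typed and no proxy available; dropped from score",
                table.name, rsid, sw.locus,
            )
    return WeightTable(
        name=table.name,
        snp_weights=new_weights,
        hla_weights=dict(table.hla_weights),
        proxy_map={},
    )


def merge_weight_tables(
    winkler: WeightTable,
    oram: WeightTable,
    sign_conflict_rsids: frozenset[str] | set[str] = SIGN_CONFLICT_RSIDS,
    name: str = "merged",
) -> WeightTable:
    """Merge two scores: mean weight for shared SNPs, pass-through for unique
    SNPs, and the oram weight for the declared sign-conflict SNPs.

    HLA genotype weights are merged by the same mean rule.
    """
    merged: dict[str, SnpWeight] = {}
    for rsid in list(winkler.snp_weights) + [
        r for r in oram.snp_weights if r not in winkler.snp_weights
    ]:
        in_w = rsid in winkler.snp_weights
        in_o = rsid in oram.snp_weights
        if in_w and in_o:
            sw, so = winkler.snp_weights[rsid], oram.snp_weights[rsid]
            if sw.effect_allele != so.effect_allele:
                raise ValueError(
                    f"{rsid}: effect-allele disagreement between scores "
                    f"({sw.effect_allele} vs {so.effect_allele}); harmonize upstream"
                )
            weight = so.weight if rsid in sign_conflict_rsids else (sw.weight + so.weight) / 2.0
            merged[rsid] = replace(sw, weight=weight, source=name)
        else:
            src = winkler.snp_weights[rsid] if in_w else oram.snp_weights[rsid]
            merged[rsid] = replace(src, source=name)

    hla: dict[str, float] = {}
    for gc in set(winkler.hla_weights) | set(oram.hla_weights):
        vals = [t.hla_weights[gc] for t in (winkler, oram) if gc in t.hla_weights]
        hla[gc] = sum(vals) / len(vals)

    return WeightTable(name=name, snp_weights=merged, hla_weights=hla, proxy_map={})


def _data_path(fname: str) -> Path:
    return Path(resources.files("grstrat.data") / fname)


def load_demo_tables() -> tuple[WeightTable, WeightTable]:
    """Load the bundled synthetic demonstration winkler and oram tables.

    The tables reproduce the documented *structure* of the published scores
    (SNP counts, proxies, sign conflicts, score scale) with synthetic weights.
    """
    winkler = load_weight_table(
        _data_path("winkler_snps.tsv"),
        _data_path("winkler_hla.tsv"),
        _data_path("proxy_map.tsv"),
        source="winkler",
    )
    oram = load_weight_table(
        _data_path("oram_snps.tsv"),
        _data_path("oram_hla.tsv"),
        _data_path("proxy_map.tsv"),
        source="oram",
    )
    return winkler, oram


def load_demo_maf() -> dict[str, float]:
    """Allele frequencies for the demonstration typing panel (43 SNPs)."""
    df = pd.read_csv(_data_path("demo_maf.tsv"), sep="\t")
    return dict(zip(df["rsid"], df["maf"].astype(float)))
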