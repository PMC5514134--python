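"""Module-level annotation statistics: hypergeometric ORA, binding fold change,
and per-module summaries of per-gene genomic values (expression, H3K4me3,
methylation, ...)."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .modules import ModulePartition

logger = logging.getLogger("motifnet")


class EnrichmentError(ValueError):
    pass


@dataclass
class EnrichmentResult:
    """Two-sided hypergeometric evidence for one gene set against a population.

    fold = (k/m) / (Kpop/Npop): the module's annotated proportion relative
    to the population's.  p_enrich is the upper tail P(X >= k), p_deplete
    the lower tail P(X <= k); both include the observed count, so they sum
    to at least 1.
    """

    set_id: str
    module_size: int
    population_size: int
    annotated_in_population: int
    annotated_in_module: int
    fold: float
    p_enrich: float
    p_deplete: float


def hypergeom_ora(
    module: Iterable[str],
    annotated: Iterable[str],
    population: Iterable[str],
    set_id: str = "",
) -> EnrichmentResult:
    """Exact hypergeometric over/under-representation of an annotation in a module."""
    population = set(population)
    module = set(module)
    if not population:
        raise EnrichmentError("empty population")
    if not module <= population:
        raise EnrichmentError("module must be a subset of the population")
    annotated = set(annotated) & population
    m, npop, kpop = len(module), len(population), len(annotated)
    k = len(module & annotated)
    if m == 0:
        raise EnrichmentError("empty module")
    fold = 0.0 if kpop == 0 else (k / m) / (kpop / npop)
    p_enrich = float(stats.hypergeom.sf(k - 1, npop, kpop, m))
    p_deplete = float(stats.hypergeom.cdf(k, npop, kpop, m))
    return EnrichmentResult(set_id, m, npop, kpop, k, fold, p_enrich, p_deplete)


def binding_fold_enrichment(
    module: Iterable[str],
    bound: Iterable[str],
    population: Iterable[str],
    set_id: str = "binding",
) -> EnrichmentResult:
    """Fold change and tails of TF binding within a module vs the genome-wide level.

    Identical machinery to :func:`hypergeom_ora` with annotated = bound
    genes; the fold is the module's bound fraction over the population's.
    """
    return hypergeom_ora(module, bound, population, set_id=set_id)


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file (term, description, genes...) into term -> gene set."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                continue
            terms[f[0]] = set(g for g in f[2:] if g)
    if not terms:
        raise EnrichmentError(f"no terms parsed from {path}")
    return terms


def enrich_modules(
    partition: ModulePartition,
    term_sets: Mapping[str, Iterable[str]],
    population: Iterable[str],
    bh_column: bool = False,
) -> pd.DataFrame:
    """ORA of every module against every term set; one row per module x term.

    Raw p-values are reported (fixed thresholds are the intended use); a
    Benjamini-Hochberg column over p_enrich can be added optionally.
    """
    population = set(population)
    rows = []
    for mid, genes in partition.modules.items():
        mod = set(genes) & population
        if not mod:
            continue
        for term, members in term_sets.items():
            r = hypergeom_ora(mod, set(members), population, set_id=term)
            rows.append(
                {
                    "module": mid, "term": term, "module_size": r.module_size,
                    "annotated_in_module": r.annotated_in_module,
                    "annotated_in_population": r.annotated_in_population,
                    "fold": round(r.fold, 2),
                    "p_enrich": r.p_enrich, "p_deplete": r.p_deplete,
                }
            )
    df = pd.DataFrame(rows)
    if bh_column and not df.empty:
        df["p_enrich_bh"] = stats.false_discovery_control(df["p_enrich"], method="bh")
    return df


def module_value_summary(
    partition: ModulePartition,
    per_gene_values: Mapping[str, float],
    statistic: str = "median",
) -> dict[int, float]:
    """Per-module median (or mean) of per-gene genomic values.

    Genes without a value are ignored; a module with no valued genes maps
    to NaN (flagged missing).
    """
    if statistic not in ("median", "mean"):
        raise EnrichmentError("statistic must be 'median' or 'mean'")
    fn = np.median if statistic == "median" else np.mean
    out: dict[int, float] = {}
    for mid, genes in partition.modules.items():
        vals = [per_gene_values[g] for g in genes if g in per_gene_values]
        if not vals:
            logger.warning("module %d has no values for the %s summary", mid, statistic)
            out[mid] = float("nan")
        else:
            out[mid] = float(fn(vals))
    return out
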