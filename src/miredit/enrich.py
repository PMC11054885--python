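"""Hypergeometric over-representation analysis of target gene sets.

For a query of n genes from a universe of N, a pathway with K members
and overlap k is scored with the one-sided hypergeometric tail
P(X >= k); Benjamini-Hochberg q-values are computed over all pathways
and a pathway is enriched at q < alpha. The universe defaults to the
genes whose UTRs were actually scanned, since targets can only be
drawn from those.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class PathwayCollection:
    pathways: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("empty gene universe")
        # clip pathways to the universe so K counts testable genes only
        self.pathways = {
            name: set(genes) & self.universe for name, genes in self.pathways.items()
        }


def hypergeom_enrich(
    query: set[str],
    collection: PathwayCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One row per pathway: overlap, hypergeometric p, BH q, enriched flag."""
    dropped = query - collection.universe
    if dropped:
        logger.warning("%d query genes outside the universe dropped", len(dropped))
    query = query & collection.universe
    N = len(collection.universe)
    n = len(query)
    rows = []
    for name, genes in sorted(collection.pathways.items()):
        K = len(genes)
        k = len(query & genes)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append({"pathway": name, "k": k, "K": K, "n": n, "N": N, "pvalue": min(p, 1.0)})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["qvalue"] = multipletests(df["pvalue"], method="fdr_bh")[1]
    df["enriched"] = df["qvalue"] < alpha
    return df


def compare_wt_et_pathways(wt_rows: pd.DataFrame, et_rows: pd.DataFrame) -> dict:
    """Pathway-level gain/loss between the WT and ET enrichment results."""
    if set(wt_rows["pathway"]) != set(et_rows["pathway"]):
        raise ValueError("WT and ET enrichments computed on different pathway collections")
    wt_hit = set(wt_rows.loc[wt_rows["enriched"], "pathway"])
    et_hit = set(et_rows.loc[et_rows["enriched"], "pathway"])
    return {
        "lost": wt_hit - et_hit,
        "gained": et_hit - wt_hit,
        "shared": wt_hit & et_hit,
    }
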