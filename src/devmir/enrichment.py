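"""Hypergeometric overrepresentation testing of gene sets against flat
category maps, with Benjamini-Hochberg correction."""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

from .de import adjust_bh

logger = logging.getLogger(__name__)


def hypergeom_pvalue(k: int, big_n: int, big_k: int, n: int) -> float:
    """Upper-tail P[X >= k] for drawing n from a universe of big_n with
    big_k annotated."""
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, big_n, big_k, n))


def hypergeom_enrichment(
    query: Iterable[str],
    categories: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Test each category for overrepresentation in the query set.

    Query genes outside the universe are dropped with a warning; category
    sets are intersected with the universe.  Returns a frame sorted by FDR
    with columns category, k, K, n, N, p_raw, fdr.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    outside = query - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query genes outside the universe were dropped", stacklevel=2
        )
        query &= universe
    big_n, n = len(universe), len(query)
    rows = []
    for category, genes in categories.items():
        annotated = set(genes) & universe
        big_k = len(annotated)
        k = len(annotated & query)
        rows.append(
            {
                "category": category,
                "k": k,
                "K": big_k,
                "n": n,
                "N": big_n,
                "p_raw": hypergeom_pvalue(k, big_n, big_k, n),
            }
        )
    table = pd.DataFrame(rows, columns=["category", "k", "K", "n", "N", "p_raw"])
    if not table.empty:
        table["fdr"] = adjust_bh(table["p_raw"])
        table = table.sort_values(["fdr", "p_raw", "category"], kind="stable").reset_index(drop=True)
    else:
        table["fdr"] = []
    return table
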