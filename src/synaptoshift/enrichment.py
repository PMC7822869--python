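"""Right-tailed Fisher-exact gene-set enrichment with a -log10(p) score.

For a query of n genes drawn from a universe of N, and a gene set with K
members inside the universe, the overlap k is scored with the right tail
of the hypergeometric distribution, P(X >= k) — equivalently a one-sided
Fisher's exact test on the 2x2 membership table. Scores are the negative
decimal exponent of the p-value, -log10(p), the convention used to size
nodes in pathway/network plots. The background universe should be the
detected genes of the relevant fraction, not the genome, so that the
enrichment background matches the detection filter.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .detection import bh_adjust
from .io import GeneSetCollection

log = logging.getLogger(__name__)


def network_score(p_value: float) -> float:
    """-log10 of an enrichment p-value (p must lie in (0, 1])."""
    if not 0 < p_value <= 1:
        raise ValueError(f"p-value must lie in (0, 1], got {p_value}")
    return float(-np.log10(p_value))


def fisher_enrichment(
    query,
    sets: GeneSetCollection,
    universe,
    alpha: float = 0.05,
    fdr_max: float = 0.05,
    min_set_size: int = 2,
) -> pd.DataFrame:
    """Score every gene set for overlap with a query, BH-corrected.

    ``query`` must be a subset of ``universe``; set members are
    intersected with the universe and sets smaller than ``min_set_size``
    after intersection are skipped. Results are sorted by p ascending
    (ties by set name) and flagged ``significant`` when p < alpha and
    q < fdr_max.
    """
    universe = frozenset(universe)
    query = frozenset(query)
    if not universe:
        raise ValueError("universe must be non-empty")
    if not query:
        raise ValueError("query must be non-empty")
    outside = query - universe
    if outside:
        raise ValueError(
            f"{len(outside)} query genes outside the universe (e.g. {sorted(outside)[:3]})"
        )
    N, n = len(universe), len(query)
    rows = []
    for name, members in sets.items():
        inside = members & universe
        if len(inside) < min_set_size:
            log.info("set %r skipped: %d members in universe", name, len(inside))
            continue
        K = len(inside)
        k = len(inside & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(p, 1.0)
        rows.append(
            dict(
                set_name=name,
                k_overlap=k,
                n_query=n,
                K_set=K,
                N_universe=N,
                p_value=p,
                score=network_score(p),
                fold_enrichment=(k / n) / (K / N),
            )
        )
    result = pd.DataFrame(rows)
    if result.empty:
        return result
    result["q_value"] = bh_adjust(result["p_value"].to_numpy())
    result["significant"] = (result["p_value"] < alpha) & (result["q_value"] < fdr_max)
    result = result.sort_values(["p_value", "set_name"]).reset_index(drop=True)
    return result[
        [
            "set_name",
            "k_overlap",
            "n_query",
            "K_set",
            "N_universe",
            "p_value",
            "q_value",
            "score",
            "fold_enrichment",
            "significant",
        ]
    ]
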