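"""Gene-set overrepresentation with exact hypergeometric tails and BH-FDR.

A local replacement for web-service overrepresentation analysis: given a hit
list (e.g. the 200 most convergent genes), a background universe (the genes
that passed the CPM filter in the relevant comparison — not the genome), and
a GMT collection, each set is tested one-sided for enrichment with the
hypergeometric upper tail, and p-values are Benjamini–Hochberg adjusted
across the sets tested for that one hit list. Fold enrichment is
(k/n)/(K/N), the ratio of observed to expected hit rate.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneSetCollection, ValidationError

log = logging.getLogger("conflux")

__all__ = ["overrepresentation_test", "bh_fdr", "select_significant"]


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def overrepresentation_test(
    hits: Sequence[str],
    universe: Sequence[str],
    sets: GeneSetCollection,
) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation of each gene set.

    With N = |universe|, K = |set ∩ universe|, n = |hits| and k the overlap,
    ``p = P(X >= k)`` for X ~ Hypergeometric(N, K, n). Hits outside the
    universe are dropped with a logged count; sets empty after intersection
    with the universe are skipped. Rows are sorted by p-value ascending and
    carry BH-adjusted q-values.
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("universe must be non-empty")
    hit_set = set(hits)
    outside = hit_set - uni
    if outside:
        log.warning("overrepresentation_test: %d hit(s) outside universe dropped",
                    len(outside))
        hit_set &= uni
    N, n = len(uni), len(hit_set)
    rows = []
    for name, members in sets.sets.items():
        in_uni = members & uni
        K = len(in_uni)
        if K == 0:
            continue
        k = len(in_uni & hit_set)
        expected = K / N * n
        fold = (k / expected) if expected > 0 else 0.0
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "set_name": name,
                "universe_size": N,
                "set_in_universe": K,
                "hits": n,
                "overlap": k,
                "fold_enrichment": fold,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["set_name", "universe_size", "set_in_universe", "hits",
                 "overlap", "fold_enrichment", "p_value"],
    )
    if len(out):
        out["q_value"] = bh_fdr(out["p_value"].to_numpy())
        out = out.sort_values(
            ["p_value", "set_name"], kind="mergesort", ignore_index=True
        )
    else:
        out["q_value"] = pd.Series(dtype=float)
    return out


def select_significant(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Rows with q < alpha, sorted by fold enrichment descending.

    An empty result is a valid outcome (some hit lists enrich no pathway at
    all) and is returned as an empty frame, not an error. ``alpha >= 1``
    disables the filter (q-values are capped at exactly 1, which a strict
    inequality would otherwise drop).
    """
    if "q_value" not in records.columns:
        raise ValidationError("records lack q_value; run overrepresentation_test first")
    out = records if alpha >= 1 else records[records["q_value"] < alpha]
    return out.sort_values(
        ["fold_enrichment", "set_name"], ascending=[False, True],
        kind="mergesort", ignore_index=True,
    )
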