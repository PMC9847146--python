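"""Convergence/divergence scoring against a reference condition.

A gene's convergence score compares how far its expression sits from primary
tissue in standard culture versus in postconfluent culture:

    score(g) = DEI(standard vs primary)(g) - DEI(postconfluent vs primary)(g)

A positive score means the gene's postconfluent expression moved *toward*
the primary-tissue level (convergent); negative means it moved away
(divergent). The statistic is antisymmetric under exchanging the two DEI
tables. Ranked lists take the top n by |score| within a direction, with a
deterministic lexicographic tie-break on the gene symbol.
"""

from __future__ import annotations

import logging
from typing import Literal

import pandas as pd

from .datatypes import ValidationError

log = logging.getLogger("conflux")

__all__ = ["convergence_scores", "top_n_selection", "dei_ranking"]

Direction = Literal["convergent", "divergent", "largest_dei"]


def convergence_scores(dei_std: pd.DataFrame, dei_post: pd.DataFrame) -> pd.DataFrame:
    """Score genes for convergence toward primary tissue.

    Both inputs are DEI tables versus the same primary reference (as built
    by :func:`conflux.expression.compute_dei`) over the same gene universe;
    genes blocked by the CPM filter in either comparison are excluded from
    the output.

    Returns a frame indexed by gene with columns ``dei_std_vs_primary``,
    ``dei_post_vs_primary``, ``score`` and ``label`` in
    {convergent, divergent, neutral}.
    """
    sym_diff = dei_std.index.symmetric_difference(dei_post.index)
    if len(sym_diff):
        raise ValidationError(
            f"DEI tables cover different gene universes ({len(sym_diff)} gene(s) differ)"
        )
    blocked = pd.Series(False, index=dei_std.index)
    for tbl in (dei_std, dei_post):
        if "blocked" in tbl.columns:
            blocked |= tbl["blocked"].reindex(dei_std.index).fillna(False).astype(bool)
    keep = dei_std.index[~blocked]
    if blocked.any():
        log.info("convergence_scores: %d gene(s) blocked in at least one comparison",
                 int(blocked.sum()))
    score = dei_std.loc[keep, "dei"] - dei_post.loc[keep, "dei"]
    label = pd.Series("neutral", index=keep, dtype=object)
    label[score > 0] = "convergent"
    label[score < 0] = "divergent"
    out = pd.DataFrame(
        {
            "dei_std_vs_primary": dei_std.loc[keep, "dei"],
            "dei_post_vs_primary": dei_post.loc[keep, "dei"],
            "score": score,
            "label": label,
        }
    )
    out.index.name = "gene"
    return out


def top_n_selection(
    records: pd.DataFrame, n: int = 200, direction: Direction = "convergent"
) -> pd.DataFrame:
    """Top-n genes in the requested direction, ordered by effect magnitude.

    ``convergent``/``divergent`` rank by |score| descending within genes of
    that label; ``largest_dei`` ranks by the ``dei`` column. Ties break
    lexicographically on gene symbol so repeated runs agree. Asking for more
    genes than exist returns them all with a warning.
    """
    if n <= 0:
        raise ValidationError("n must be a positive integer")
    if direction in ("convergent", "divergent"):
        sub = records[records["label"] == direction]
        key = sub["score"].abs()
    elif direction == "largest_dei":
        if "dei" not in records.columns:
            raise ValidationError("largest_dei ranking needs a 'dei' column")
        sub = records
        key = sub["dei"]
    else:
        raise ValidationError(f"invalid direction {direction!r}")
    order = (
        pd.DataFrame({"key": key.to_numpy(), "gene": sub.index.to_numpy()})
        .sort_values(["key", "gene"], ascending=[False, True], kind="mergesort")["gene"]
        .to_numpy()
    )
    if n > len(sub):
        log.warning("top_n_selection: requested %d of %d scored gene(s); returning all",
                    n, len(sub))
    out = sub.loc[order].head(n).copy()
    out["rank"] = range(1, len(out) + 1)
    return out


def dei_ranking(dei_table: pd.DataFrame, n: int = 200) -> pd.DataFrame:
    """Genes ranked by DEI descending between two conditions, sign retained.

    Blocked genes (if a ``blocked`` column is present) are excluded first;
    an all-zero table falls back to lexicographic order with a warning.
    """
    tbl = dei_table
    if "blocked" in tbl.columns:
        tbl = tbl[~tbl["blocked"].astype(bool)]
    if not len(tbl):
        raise ValidationError("DEI table is empty after filtering")
    if (tbl["dei"] == 0).all():
        log.warning("dei_ranking: all DEI values are zero; order is lexicographic")
    order = (
        pd.DataFrame({"key": tbl["dei"].to_numpy(), "gene": tbl.index.to_numpy()})
        .sort_values(["key", "gene"], ascending=[False, True], kind="mergesort")["gene"]
        .to_numpy()
    )
    out = tbl.loc[order].head(n).copy()
    out["rank"] = range(1, len(out) + 1)
    return out
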