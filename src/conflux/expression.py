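"""Normalization, filtering, lineage pooling and the differential expression index.

The differential expression index (DEI) of a gene between two groups is the
geometric mean of a ratio-based component — the pseudocounted absolute log2
fold change of group-mean expression — and a difference-based component, the
absolute difference of group-mean CPM:

    r = |log2((mean_A + c) / (mean_B + c))|,   d = |mean_A - mean_B|,
    DEI = sqrt(r * d)

Group means are arithmetic means of per-sample CPM so both components share
the same group summary; the direction of change is carried as a separate
sign, since a geometric mean of signed quantities is undefined. The ratio
component can optionally be computed on median-of-ratios-normalized counts
(the DESeq2 normalization scheme) instead of plain CPM.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import AnalysisConfig, CountMatrix, SampleMeta, ValidationError

log = logging.getLogger("conflux")

__all__ = [
    "cpm_normalize",
    "size_factor_normalize",
    "median_of_ratios_size_factors",
    "filter_min_cpm",
    "pool_lineage_counts",
    "group_mean",
    "ratio_de",
    "difference_de",
    "dei_combine",
    "compute_dei",
    "relative_expression",
]


def cpm_normalize(
    cm: CountMatrix, size_factors: Optional[pd.Series] = None
) -> pd.DataFrame:
    """Counts-per-million normalization.

    ``value(g, s) = (count(g,s)/f_s) / sum_g'(count(g',s)/f_s) * 1e6``; each
    column sums to 1e6. Note that a per-sample factor ``f_s`` cancels in the
    ratio, so the result is invariant to size factors — they are accepted
    for interface symmetry with :func:`size_factor_normalize`, which is the
    normalization that actually depends on them.

    Raises
    ------
    ValidationError
        If any sample has zero total count (named in the message).
    """
    counts = cm.counts.astype(float)
    if size_factors is not None:
        sf = pd.Series(size_factors).reindex(counts.columns)
        if sf.isna().any() or (sf <= 0).any():
            raise ValidationError("size factors must be positive and cover every sample")
        counts = counts / sf
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValidationError(f"sample(s) with zero total count: {zero}")
    return counts.div(totals, axis=1) * 1e6


def size_factor_normalize(cm: CountMatrix, size_factors: pd.Series) -> pd.DataFrame:
    """Counts divided by per-sample size factors (DESeq2-style normalized counts)."""
    sf = pd.Series(size_factors).reindex(cm.counts.columns)
    if sf.isna().any() or (sf <= 0).any():
        raise ValidationError("size factors must be positive and cover every sample")
    return cm.counts.astype(float).div(sf, axis=1)


def median_of_ratios_size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors (the DESeq2 normalization scheme).

    For each sample, the factor is the median over reference-eligible genes
    (positive counts in every sample) of count(g, s) / geometric-mean_g.
    """
    counts = cm.counts.astype(float)
    eligible = (counts > 0).all(axis=1)
    if not eligible.any():
        raise ValidationError(
            "no gene has positive counts in every sample; cannot compute size factors"
        )
    sub = counts.loc[eligible]
    log_geomean = np.log(sub).mean(axis=1)
    ratios = np.exp(np.log(sub).sub(log_geomean, axis=0))
    factors = ratios.median(axis=0)
    factors.name = "size_factor"
    return factors


def filter_min_cpm(nm: pd.DataFrame, min_cpm: float = 2.0) -> pd.Series:
    """Boolean mask of genes kept by the low-expression filter.

    A gene is *blocked* (mask False) when its CPM is below ``min_cpm`` in
    every sample of ``nm`` — mirroring "fewer than 2 CPM across all
    specimens"; a single sample at or above the threshold keeps the gene.
    """
    if min_cpm < 0:
        raise ValidationError("min_cpm threshold must be non-negative")
    kept = (nm >= min_cpm).any(axis=1)
    log.info(
        "filter_min_cpm: %d/%d gene(s) blocked at < %g CPM in all %d sample(s)",
        int((~kept).sum()), len(kept), min_cpm, nm.shape[1],
    )
    kept.name = "kept"
    return kept


def pool_lineage_counts(
    cm: CountMatrix, meta: SampleMeta
) -> tuple[CountMatrix, SampleMeta]:
    """Sum specimen-matched LEp and MEp counts into one pooled sample each.

    Used for genes expressed across the epithelial bilayer (e.g. basement
    membrane components). A (specimen, culture) pair lacking an LEp or an
    MEp sample is skipped with a warning naming it.
    """
    sub = meta.table.loc[meta.table.index.intersection(cm.counts.columns)]
    pooled_cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for (specimen, culture), grp in sub.groupby(["specimen", "culture"], sort=True):
        leps = grp.index[grp["lineage"] == "LEp"].tolist()
        meps = grp.index[grp["lineage"] == "MEp"].tolist()
        if not leps or not meps:
            log.warning(
                "pool_lineage_counts: specimen '%s' culture '%s' lacks %s sample(s); skipped",
                specimen, culture, "LEp" if not leps else "MEp",
            )
            continue
        name = f"{specimen}_{culture}_pooled"
        pooled_cols[name] = cm.counts[leps + meps].sum(axis=1).to_numpy()
        meta_rows.append(
            {"sample_id": name, "specimen": specimen, "lineage": "bulk", "culture": culture}
        )
    if not pooled_cols:
        raise ValidationError("no (specimen, culture) pair has both LEp and MEp samples")
    pooled = pd.DataFrame(pooled_cols, index=cm.counts.index)
    return CountMatrix(pooled), SampleMeta(pd.DataFrame(meta_rows).set_index("sample_id"))


def _check_groups(nm: pd.DataFrame, group_a: Sequence[str], group_b: Sequence[str]) -> None:
    if not len(group_a) or not len(group_b):
        raise ValidationError("both groups must be non-empty")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValidationError(f"groups overlap in sample(s): {sorted(overlap)}")
    missing = [s for s in [*group_a, *group_b] if s not in nm.columns]
    if missing:
        raise ValidationError(f"unknown sample(s): {missing}")


def group_mean(nm: pd.DataFrame, samples: Sequence[str]) -> pd.Series:
    """Arithmetic mean expression per gene over the given samples."""
    return nm[list(samples)].mean(axis=1)


def ratio_de(
    nm: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Signed log2 fold change of pseudocounted group means (A over B)."""
    _check_groups(nm, group_a, group_b)
    if pseudocount < 0:
        raise ValidationError("pseudocount must be non-negative")
    lfc = np.log2(group_mean(nm, group_a) + pseudocount) - np.log2(
        group_mean(nm, group_b) + pseudocount
    )
    lfc.name = "lfc"
    return lfc


def difference_de(
    nm: pd.DataFrame, group_a: Sequence[str], group_b: Sequence[str]
) -> pd.Series:
    """Absolute difference of group-mean expression, |mean_A - mean_B|."""
    _check_groups(nm, group_a, group_b)
    d = (group_mean(nm, group_a) - group_mean(nm, group_b)).abs()
    d.name = "d"
    return d


def dei_combine(r: pd.Series, d: pd.Series) -> pd.DataFrame:
    """Combine the signed ratio and absolute difference components.

    Returns a frame indexed by gene with columns ``r`` (|lfc|), ``d``,
    ``dei`` = sqrt(r*d) and ``sign`` (direction of the ratio component).
    """
    r = pd.Series(r).astype(float)
    d = pd.Series(d).astype(float)
    if (d < 0).any():
        raise ValidationError("difference component must be non-negative")
    if not r.index.equals(d.index):
        raise ValidationError("ratio and difference components index different genes")
    abs_r = r.abs()
    return pd.DataFrame(
        {
            "r": abs_r,
            "d": d,
            "dei": np.sqrt(abs_r * d),
            "sign": np.sign(r).astype(int),
        },
        index=r.index,
    )


def compute_dei(
    nm: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    config: Optional[AnalysisConfig] = None,
    ratio_values: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-gene DEI table between two sample groups.

    Columns: gene (index), r, d, dei, sign, blocked. ``blocked`` marks genes
    below the CPM floor in every sample of A∪B; blocked genes keep their
    values but are excluded from downstream ranking. ``ratio_values`` may
    supply an alternative normalized matrix (e.g. median-of-ratios) for the
    ratio component only; the difference component always uses CPM.
    """
    config = config or AnalysisConfig()
    r = ratio_de(
        ratio_values if ratio_values is not None else nm,
        group_a, group_b, config.pseudocount,
    )
    d = difference_de(nm, group_a, group_b)
    out = dei_combine(r, d)
    kept = filter_min_cpm(nm[list(group_a) + list(group_b)], config.min_cpm)
    out["blocked"] = ~kept
    return out


def relative_expression(
    nm: pd.DataFrame,
    genes: Sequence[str],
    meta: SampleMeta,
    group_key: str = "culture",
) -> pd.DataFrame:
    """Group-mean log2(CPM+1), min–max rescaled to [0, 1] per gene.

    The heat-map summary used for marker panels: rows are the requested
    genes, columns the levels of ``group_key`` present in the metadata.
    Genes absent from the matrix are reported via warning, never silently
    dropped; a gene constant across groups maps to all-zero.
    """
    present = [g for g in genes if g in nm.index]
    absent = [g for g in genes if g not in nm.index]
    if absent:
        log.warning("relative_expression: gene(s) absent from matrix: %s", absent)
    sub = meta.table.loc[meta.table.index.intersection(nm.columns)]
    if group_key not in sub.columns:
        raise ValidationError(f"unknown metadata column '{group_key}'")
    logcpm = np.log2(nm.loc[present, sub.index] + 1.0)
    means = logcpm.T.groupby(sub[group_key], observed=True).mean().T
    lo = means.min(axis=1)
    span = means.max(axis=1) - lo
    scaled = means.sub(lo, axis=0).div(span.replace(0.0, np.inf), axis=0)
    scaled.index.name = "gene"
    return scaled
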