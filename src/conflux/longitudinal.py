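"""Longitudinal viability/senescence models and ANOVA effect sizes.

Two model surfaces:

* :class:`BlockedTimepointModel` — the repeated-measures analysis of bounded
  fractions (viability, SAβG+ area): measurements are logit-transformed and
  regressed on a categorical timepoint with a per-specimen block. For the
  balanced few-specimen designs this targets, the fixed specimen block gives
  timepoint contrasts and tests identical to a random-intercept (REML) fit;
  that equivalence breaks for unbalanced data, which is documented rather
  than patched with REML machinery.
* :func:`two_way_anova` — ordinary two-way ANOVA (sequential/type-I sums of
  squares, as appropriate for the balanced designs here) with classical
  eta-squared, Cohen's f, and Tukey HSD pairwise contrasts computed from the
  fitted model's residual mean square and degrees of freedom via the
  studentized-range distribution.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import studentized_range

from .datatypes import ValidationError

log = logging.getLogger("conflux")

__all__ = [
    "logit_transform",
    "inverse_logit",
    "BlockedTimepointModel",
    "BlockedTimepointResults",
    "two_way_anova",
    "AnovaResult",
    "eta_squared_to_cohens_f",
    "fold_change",
]

ArrayLike = Union[float, Sequence[float], np.ndarray, pd.Series]


def logit_transform(p: ArrayLike, epsilon: float = 1e-3) -> Union[float, np.ndarray]:
    """Clamped log-odds, ``ln(p/(1-p))`` with p first clamped to [eps, 1-eps].

    The clamp keeps boundary observations (viability of exactly 100% is
    common) finite. Values outside [0, 1] are a hard error.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise ValidationError("fractions must lie in [0, 1]")
    if not 0 < epsilon < 0.5:
        raise ValidationError("epsilon must lie in (0, 0.5)")
    clamped = np.clip(arr, epsilon, 1.0 - epsilon)
    out = np.log(clamped / (1.0 - clamped))
    return float(out) if np.isscalar(p) or np.ndim(p) == 0 else out


def inverse_logit(x: ArrayLike) -> Union[float, np.ndarray]:
    arr = np.asarray(x, dtype=float)
    out = 1.0 / (1.0 + np.exp(-arr))
    return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out


@dataclass
class BlockedTimepointResults:
    """Results of a :class:`BlockedTimepointModel` fit.

    ``contrasts`` holds one row per timepoint level: the estimated marginal
    contrast versus the baseline level on the logit scale, its standard
    error, t statistic and p-value on the residual degrees of freedom. The
    baseline row is exactly zero by construction.
    """

    baseline: str
    timepoints: list[str]
    contrasts: pd.DataFrame
    marginal_means: pd.Series
    residual_sd: float
    df_resid: float
    model: object = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            "Blocked timepoint model (logit scale)",
            f"  baseline level: {self.baseline}",
            f"  residual SD {self.residual_sd:.4f} on {self.df_resid:.0f} df",
            "",
            self.contrasts.to_string(float_format=lambda v: f"{v: .4f}"),
        ]
        return "\n".join(lines)

    def marginal_mean_fractions(self) -> pd.Series:
        """Back-transformed per-timepoint marginal means, as fractions."""
        return pd.Series(
            inverse_logit(self.marginal_means.to_numpy()),
            index=self.marginal_means.index,
            name="fraction",
        )


class BlockedTimepointModel:
    """Repeated-measures model ``logit(fraction) ~ timepoint + specimen block``.

    Parameters
    ----------
    data
        Long-format table with columns ``specimen``, ``timepoint`` and
        ``fraction`` (values in [0, 1]).
    baseline
        Timepoint level contrasts are taken against; defaults to the first
        level in order of appearance.
    epsilon
        Clamp for the logit transform.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        baseline: Optional[str] = None,
        epsilon: float = 1e-3,
    ) -> None:
        for col in ("specimen", "timepoint", "fraction"):
            if col not in data.columns:
                raise ValidationError(f"longitudinal table missing column '{col}'")
        df = data.copy()
        dup = df.duplicated(["specimen", "timepoint"])
        if dup.any():
            raise ValidationError(
                "duplicate (specimen, timepoint) row(s): "
                f"{df.loc[dup, ['specimen', 'timepoint']].to_records(index=False)[:5]}"
            )
        counts = df.groupby("specimen")["timepoint"].nunique()
        lonely = counts.index[counts < 2].tolist()
        if lonely:
            log.warning(
                "BlockedTimepointModel: specimen(s) observed at a single timepoint "
                "dropped: %s", lonely
            )
            df = df[~df["specimen"].isin(lonely)]
        if df["timepoint"].nunique() < 2:
            raise ValidationError("need at least 2 timepoint levels")
        if df["specimen"].nunique() < 2:
            raise ValidationError("need at least 2 specimens")
        self.data = df.reset_index(drop=True)
        self.timepoints = list(dict.fromkeys(self.data["timepoint"]))
        self.baseline = baseline if baseline is not None else self.timepoints[0]
        if self.baseline not in self.timepoints:
            raise ValidationError(f"baseline level {self.baseline!r} not in data")
        self.epsilon = epsilon

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "BlockedTimepointModel":
        return cls(data, **kwargs)

    def fit(self) -> BlockedTimepointResults:
        df = self.data.assign(
            y=logit_transform(self.data["fraction"].to_numpy(), self.epsilon)
        )
        formula = (
            f"y ~ C(timepoint, Treatment(reference={self.baseline!r})) + C(specimen)"
        )
        ols = smf.ols(formula, data=df).fit()
        if ols.df_resid <= 0 or np.linalg.matrix_rank(ols.model.exog) < ols.model.exog.shape[1]:
            raise ValidationError("singular design: model is not estimable")

        prefix = f"C(timepoint, Treatment(reference={self.baseline!r}))[T."
        rows = [{
            "timepoint": self.baseline, "estimate": 0.0, "se": 0.0,
            "t": np.nan, "p_value": np.nan,
        }]
        for tp in self.timepoints:
            if tp == self.baseline:
                continue
            name = f"{prefix}{tp}]"
            rows.append({
                "timepoint": tp,
                "estimate": float(ols.params[name]),
                "se": float(ols.bse[name]),
                "t": float(ols.tvalues[name]),
                "p_value": float(ols.pvalues[name]),
            })
        contrasts = pd.DataFrame(rows).set_index("timepoint")

        # marginal means: baseline fit + contrast, averaged over specimen blocks
        spec_terms = [n for n in ols.params.index if n.startswith("C(specimen)")]
        spec_mean = float(np.mean([0.0] + [ols.params[n] for n in spec_terms]))
        intercept = float(ols.params["Intercept"])
        mm = pd.Series(
            {tp: intercept + spec_mean + contrasts.loc[tp, "estimate"]
             for tp in self.timepoints},
            name="marginal_mean",
        )
        return BlockedTimepointResults(
            baseline=self.baseline,
            timepoints=self.timepoints,
            contrasts=contrasts,
            marginal_means=mm,
            residual_sd=float(np.sqrt(ols.mse_resid)),
            df_resid=float(ols.df_resid),
            model=ols,
        )


# ---------------------------------------------------------------------------
# two-way ANOVA with effect sizes and Tukey HSD


def eta_squared_to_cohens_f(eta_squared: float) -> float:
    """Cohen's f from classical eta-squared: ``f = sqrt(eta2 / (1 - eta2))``."""
    if not 0 <= eta_squared < 1:
        raise ValidationError("eta_squared must lie in [0, 1)")
    return float(np.sqrt(eta_squared / (1.0 - eta_squared)))


@dataclass
class AnovaResult:
    """Two-way ANOVA table with effect sizes and Tukey HSD contrasts.

    ``table`` has one row per effect (plus Residual) with sum_sq, df, F,
    p_value, eta_sq (SS_effect / SS_total) and cohens_f. ``tukey`` maps each
    factor name to a frame of all pairwise level contrasts (estimate,
    q statistic, adjusted p from the studentized-range distribution on the
    model's residual df).
    """

    table: pd.DataFrame
    tukey: dict[str, pd.DataFrame]
    residual_df: float
    residual_ms: float
    model: object = field(repr=False, default=None)

    def summary(self) -> str:
        parts = ["Two-way ANOVA", self.table.to_string(float_format=lambda v: f"{v: .4g}")]
        for factor, tbl in self.tukey.items():
            parts += ["", f"Tukey HSD — {factor}",
                      tbl.to_string(float_format=lambda v: f"{v: .4g}")]
        return "\n".join(parts)


def _tukey_hsd(
    data: pd.DataFrame, value: str, factor: str, ms_resid: float, df_resid: float
) -> pd.DataFrame:
    """Tukey–Kramer pairwise contrasts using the model residual mean square."""
    groups = data.groupby(factor)[value]
    means, sizes = groups.mean(), groups.size()
    levels = sorted(means.index)
    k = len(levels)
    rows = []
    for a, b in itertools.combinations(levels, 2):
        diff = means[a] - means[b]
        se = np.sqrt(ms_resid / 2.0 * (1.0 / sizes[a] + 1.0 / sizes[b]))
        if se == 0:
            q, p = np.inf if diff != 0 else 0.0, 0.0 if diff != 0 else 1.0
        else:
            q = abs(diff) / se
            p = float(studentized_range.sf(q, k, df_resid))
        rows.append({"level_a": a, "level_b": b, "estimate": float(diff),
                     "q": float(q), "p_adj": min(p, 1.0)})
    return pd.DataFrame(rows)


def two_way_anova(
    data: pd.DataFrame,
    value: str,
    factor_a: str,
    factor_b: str,
    include_interaction: bool = False,
) -> AnovaResult:
    """Two-way ANOVA ``value ~ factor_a + factor_b [+ factor_a:factor_b]``.

    Sequential (type-I) sums of squares in formula order — on the balanced
    designs this analysis targets they coincide with every other type.
    Classical eta-squared per effect, its Cohen's f, and Tukey HSD contrasts
    per factor from the fitted model's residual mean square.
    """
    for col in (value, factor_a, factor_b):
        if col not in data.columns:
            raise ValidationError(f"missing column '{col}'")
    for f in (factor_a, factor_b):
        if data[f].nunique() < 2:
            raise ValidationError(f"factor '{f}' needs at least 2 levels")
    if include_interaction:
        cells = data.groupby([factor_a, factor_b]).size()
        full = data[factor_a].nunique() * data[factor_b].nunique()
        if len(cells) < full:
            raise ValidationError("interaction requested but some factor cells are empty")

    y = data[value].to_numpy(dtype=float)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    terms = [f"C(Q('{factor_a}'))", f"C(Q('{factor_b}'))"]
    if include_interaction:
        terms.append(f"C(Q('{factor_a}')):C(Q('{factor_b}'))")
    formula = f"Q('{value}') ~ " + " + ".join(terms)
    ols = smf.ols(formula, data=data).fit()

    if ss_total == 0:
        log.warning("two_way_anova: response is constant; all effects reported as 0")
        rows = [{"effect": n, "sum_sq": 0.0, "df": np.nan, "F": np.nan,
                 "p_value": np.nan, "eta_sq": 0.0, "cohens_f": 0.0}
                for n in [factor_a, factor_b] + ([f"{factor_a}:{factor_b}"] if include_interaction else [])]
        table = pd.DataFrame(rows).set_index("effect")
        return AnovaResult(table=table, tukey={}, residual_df=float(ols.df_resid),
                           residual_ms=0.0, model=ols)

    aov = sm.stats.anova_lm(ols, typ=1)
    rename = {terms[0]: factor_a, terms[1]: factor_b}
    if include_interaction:
        rename[terms[2]] = f"{factor_a}:{factor_b}"
    aov = aov.rename(index=rename)
    aov["eta_sq"] = aov["sum_sq"] / ss_total
    aov["cohens_f"] = [
        eta_squared_to_cohens_f(e) if np.isfinite(e) and name != "Residual" else np.nan
        for name, e in aov["eta_sq"].items()
    ]
    aov = aov.rename(columns={"PR(>F)": "p_value"})

    ms_resid = float(ols.mse_resid)
    df_resid = float(ols.df_resid)
    tukey = {
        factor_a: _tukey_hsd(data, value, factor_a, ms_resid, df_resid),
        factor_b: _tukey_hsd(data, value, factor_b, ms_resid, df_resid),
    }
    return AnovaResult(table=aov, tukey=tukey, residual_df=df_resid,
                       residual_ms=ms_resid, model=ols)


def fold_change(
    nm: pd.DataFrame,
    gene: str,
    group_a: Sequence[str],
    group_b: Sequence[str],
    pseudocount: float = 0.0,
) -> float:
    """Ratio of pseudocounted group-mean expression for one gene (A over B)."""
    if gene not in nm.index:
        raise ValidationError(f"gene '{gene}' not in matrix")
    if not len(group_a) or not len(group_b):
        raise ValidationError("both groups must be non-empty")
    mean_a = float(nm.loc[gene, list(group_a)].mean()) + pseudocount
    mean_b = float(nm.loc[gene, list(group_b)].mean()) + pseudocount
    if mean_b <= 0 or mean_a <= 0:
        raise ValidationError("group means must be positive after pseudocount")
    return mean_a / mean_b
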