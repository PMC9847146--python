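"""Synthetic data generators mirroring the statistical structure of the study.

Three generators cover the three data modalities the pipeline consumes:

* :func:`simulate_counts` — negative-binomial RNA-seq counts for sorted
  luminal (LEp) and myoepithelial (MEp) samples across primary tissue,
  standard subconfluent culture and postconfluent culture, with planted
  "convergent" and "divergent" genes whose expression in postconfluent
  culture moves toward, or away from, the primary-tissue level.
* :func:`simulate_flow_events` — log-normal fluorescence mixtures for the
  CD133/CD271/CD117/DAPI panel, with an optional additive autofluorescence
  shift (postconfluent cells are markedly autofluorescent).
* :func:`simulate_longitudinal` — bounded viability/senescence fractions
  generated on the logistic scale with specimen random intercepts, matching
  the repeated-measures model used downstream.

All generators are pure functions of (configuration, seed): a fixed seed
reproduces the output byte for byte. Sub-streams are derived from the one
seed with ``numpy.random.SeedSequence.spawn`` so the generators stay
reproducible independently of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, SampleMeta, ValidationError

__all__ = [
    "SimConfig",
    "simulate_counts",
    "simulate_flow_events",
    "simulate_longitudinal",
    "default_flow_populations",
    "DEFAULT_VIABILITY_MEANS",
    "DEFAULT_SABG_MEANS",
]


@dataclass
class SimConfig:
    """Configuration for :func:`simulate_counts`.

    Defaults describe a specimen-matched design of transcriptome scale
    (2000 genes stands in for ~20k at 1:10), with 10% of genes planted
    convergent and 10% divergent at a 2 log2-unit condition effect that
    postconfluent culture shrinks by a factor ``shrink`` for convergent
    genes. Baseline log2 means are normal(5, 2) truncated below at 0 so the
    2-CPM filter boundary is populated; library sizes vary log-normally
    (SD 0.2 on the natural-log scale).
    """

    n_genes: int = 2000
    specimens: Sequence[str] = ("S1", "S2", "S3", "S4", "S5")
    lineages: Sequence[str] = ("LEp", "MEp")
    cultures: Sequence[str] = ("primary", "standard", "postconfluent")
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    dispersion: float = 0.1
    specimen_sd: float = 0.3
    fraction_convergent: float = 0.1
    fraction_divergent: float = 0.1
    effect_size: float = 2.0
    effect_direction: int = 1
    shrink: float = 0.25
    library_size_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.specimens:
            raise ValidationError("specimen list must be non-empty")
        if self.n_genes <= 0:
            raise ValidationError("n_genes must be positive")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0 (0 = Poisson limit)")
        if self.fraction_convergent < 0 or self.fraction_divergent < 0:
            raise ValidationError("planted fractions must be non-negative")
        if self.fraction_convergent + self.fraction_divergent > 1:
            raise ValidationError("fraction_convergent + fraction_divergent must be <= 1")
        if not 0 <= self.shrink <= 1:
            raise ValidationError("shrink must lie in [0, 1]")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be non-negative")
        if self.effect_direction not in (-1, 1):
            raise ValidationError("effect_direction must be +1 or -1")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + mu^2 * dispersion; Poisson at dispersion 0."""
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(
    cfg: SimConfig,
) -> tuple[CountMatrix, SampleMeta, pd.DataFrame]:
    """Simulate a count matrix with planted convergent/divergent genes.

    Counts for gene g in sample s are negative binomial with mean
    ``2**(b_g + effect(class_g, culture_s) + u_{g,spec(s)}) * L_s`` where
    ``b_g`` is the baseline log2 mean, ``u`` the specimen effect (shared by
    all of a specimen's samples, emulating the specimen-matched design) and
    ``L_s`` a log-normal library-size factor. Condition effects relative to
    primary tissue, in log2 units with delta = effect_direction *
    effect_size (up-regulation by default; set effect_direction=-1 to plant
    losses of expression instead):

    =============  ========  ==============
    gene class     standard  postconfluent
    =============  ========  ==============
    convergent     delta     shrink * delta
    divergent      0         delta
    neutral        0         0
    =============  ========  ==============

    Returns the count matrix, its sample metadata and a truth table with
    columns ``gene``, ``gene_class`` and ``direction`` (sign of delta for
    planted genes, 0 for neutral ones).
    """
    ss = np.random.SeedSequence(cfg.seed)
    s_base, s_class, s_spec, s_lib, s_counts = ss.spawn(5)
    rng_base = np.random.default_rng(s_base)
    rng_class = np.random.default_rng(s_class)
    rng_spec = np.random.default_rng(s_spec)
    rng_lib = np.random.default_rng(s_lib)
    rng_counts = np.random.default_rng(s_counts)

    genes = [f"G{i:05d}" for i in range(1, cfg.n_genes + 1)]
    base_log2 = np.maximum(
        rng_base.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_genes), 0.0
    )

    n_conv = int(round(cfg.fraction_convergent * cfg.n_genes))
    n_div = int(round(cfg.fraction_divergent * cfg.n_genes))
    classes = np.array(["neutral"] * cfg.n_genes, dtype=object)
    planted = rng_class.choice(cfg.n_genes, size=n_conv + n_div, replace=False)
    classes[planted[:n_conv]] = "convergent"
    classes[planted[n_conv:]] = "divergent"
    direction = np.zeros(cfg.n_genes, dtype=int)
    direction[planted] = cfg.effect_direction

    # per-(gene, specimen) effects shared across cultures and lineages
    spec_eff = {
        spec: rng_spec.normal(0.0, cfg.specimen_sd, cfg.n_genes)
        for spec in cfg.specimens
    }

    # log2 offsets per culture implied by each gene's class
    delta = cfg.effect_size * direction

    def culture_offset(culture: str) -> np.ndarray:
        off = np.zeros(cfg.n_genes)
        conv = classes == "convergent"
        div = classes == "divergent"
        if culture == "standard":
            off[conv] = delta[conv]
        elif culture == "postconfluent":
            off[conv] = cfg.shrink * delta[conv]
            off[div] = delta[div]
        return off

    offsets = {c: culture_offset(c) for c in cfg.cultures}

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for spec in cfg.specimens:
        for culture in cfg.cultures:
            for lineage in cfg.lineages:
                sample = f"{spec}_{culture}_{lineage}"
                lib = float(np.exp(rng_lib.normal(0.0, cfg.library_size_sd)))
                mean = np.exp2(base_log2 + offsets[culture] + spec_eff[spec]) * lib
                columns[sample] = _nb_draw(rng_counts, mean, cfg.dispersion)
                meta_rows.append(
                    {"sample_id": sample, "specimen": spec, "lineage": lineage,
                     "culture": culture}
                )

    counts = pd.DataFrame(columns, index=pd.Index(genes, name="gene"), dtype=np.int64)
    meta = SampleMeta(pd.DataFrame(meta_rows).set_index("sample_id"))
    truth = pd.DataFrame({"gene": genes, "gene_class": classes, "direction": direction})
    return CountMatrix(counts), meta, truth


# ---------------------------------------------------------------------------
# flow cytometry

#: Marker intensity medians (location) and log-scale SDs per population.
#: Locations are in arbitrary fluorescence units; a gate threshold of 100
#: cleanly separates the high (1000) and low (10) modes at the default scale.
def default_flow_populations() -> dict[str, dict[str, tuple[float, float]]]:
    hi, lo, sc = 1000.0, 10.0, 0.5
    return {
        "LEp":    {"CD133": (hi, sc), "CD271": (lo, sc), "CD117": (lo, sc), "DAPI": (lo, sc)},
        "MEp":    {"CD133": (lo, sc), "CD271": (hi, sc), "CD117": (lo, sc), "DAPI": (lo, sc)},
        "cKit":   {"CD133": (hi, sc), "CD271": (lo, sc), "CD117": (hi, sc), "DAPI": (lo, sc)},
        "dneg":   {"CD133": (lo, sc), "CD271": (lo, sc), "CD117": (lo, sc), "DAPI": (lo, sc)},
        "dead":   {"CD133": (lo, sc), "CD271": (lo, sc), "CD117": (lo, sc), "DAPI": (hi, sc)},
    }


def simulate_flow_events(
    n_events: int,
    weights: Mapping[str, float],
    populations: Optional[Mapping[str, Mapping[str, tuple[float, float]]]] = None,
    autofluorescence: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a flow event table as a mixture of labelled populations.

    Each event is drawn from one population with the given weights (must sum
    to 1); marker intensity is log-normal with the population's median
    ``loc`` and log-scale ``scale`` (``scale`` 0 gives exactly ``loc``), plus
    an additive ``autofluorescence`` baseline applied to every marker —
    emulating the upward intensity shift of postconfluent cells. The truth
    label is retained per event in the ``truth`` column.
    """
    if n_events <= 0:
        raise ValidationError("n_events must be positive")
    pops = dict(populations) if populations is not None else default_flow_populations()
    unknown = set(weights) - set(pops)
    if unknown:
        raise ValidationError(f"weights given for unknown population(s): {sorted(unknown)}")
    total = float(sum(weights.values()))
    if abs(total - 1.0) > 1e-8:
        raise ValidationError(f"population weights must sum to 1 (got {total})")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    names = sorted(weights)
    probs = np.array([weights[n] for n in names], dtype=float)
    assignment = rng.choice(len(names), size=n_events, p=probs)

    markers = ("CD133", "CD271", "CD117", "DAPI")
    out = {m: np.empty(n_events) for m in markers}
    for idx, name in enumerate(names):
        mask = assignment == idx
        k = int(mask.sum())
        if k == 0:
            continue
        for m in markers:
            loc, scale = pops[name][m]
            vals = loc * np.exp(rng.normal(0.0, 1.0, k) * scale) if scale > 0 else np.full(k, loc)
            out[m][mask] = vals + autofluorescence
    events = pd.DataFrame(out)
    events.insert(0, "event_id", [f"E{i:06d}" for i in range(n_events)])
    events["truth"] = [names[i] for i in assignment]
    return events


# ---------------------------------------------------------------------------
# longitudinal viability / senescence

def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


#: Study-condition defaults on the logit scale: viability holds near 99%
#: through four weeks of postconfluent culture and then begins to decline;
#: the senescence-associated beta-galactosidase positive area fraction rises
#: from ~5% at confluence to ~18/30/35% after 1/2/3 weeks.
DEFAULT_VIABILITY_MEANS: dict[str, float] = {
    "confluent": _logit(0.99),
    "1wk": _logit(0.99),
    "2wk": _logit(0.99),
    "3wk": _logit(0.99),
    "4wk": _logit(0.99),
    "5wk": _logit(0.92),
}

DEFAULT_SABG_MEANS: dict[str, float] = {
    "confluent": _logit(0.05),
    "1wk": _logit(0.18),
    "2wk": _logit(0.30),
    "3wk": _logit(0.35),
}


def simulate_longitudinal(
    specimens: Sequence[str],
    timepoints: Sequence[str],
    logit_means: Mapping[str, float],
    specimen_sd: float = 0.3,
    residual_sd: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate bounded per-specimen trajectories on the logistic scale.

    ``fraction = expit(mu_t + b_specimen + eps)`` with
    ``b_specimen ~ N(0, specimen_sd)`` and ``eps ~ N(0, residual_sd)``;
    all values lie strictly inside (0, 1). Columns: specimen, timepoint,
    fraction.
    """
    if not timepoints:
        raise ValidationError("timepoints must be non-empty")
    mus = np.array([logit_means[t] for t in timepoints], dtype=float)
    if not np.all(np.isfinite(mus)):
        raise ValidationError("logit-scale means must be finite")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    b = rng.normal(0.0, specimen_sd, len(specimens)) if specimen_sd > 0 else np.zeros(len(specimens))
    rows = []
    for i, spec in enumerate(specimens):
        eps = rng.normal(0.0, residual_sd, len(timepoints)) if residual_sd > 0 else np.zeros(len(timepoints))
        eta = mus + b[i] + eps
        frac = 1.0 / (1.0 + np.exp(-eta))
        for t, f in zip(timepoints, frac):
            rows.append({"specimen": spec, "timepoint": t, "fraction": float(f)})
    return pd.DataFrame(rows)
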