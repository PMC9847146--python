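"""Core domain types shared by every pipeline stage.

The working containers are thin wrappers around pandas objects with the
validation the pipeline relies on: a gene-by-sample integer count matrix
(:class:`CountMatrix`), per-sample annotations (:class:`SampleMeta`), a named
collection of gene sets (:class:`GeneSetCollection`), and the analysis
configuration (:class:`AnalysisConfig`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

LINEAGES = ("LEp", "MEp", "cKit", "bulk")
CULTURES = ("primary", "confluent", "standard", "postconfluent")

#: Columns a flow event table must carry (see :mod:`conflux.cytometry`).
FLOW_MARKERS = ("CD133", "CD271", "CD117", "DAPI")


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


def _check_unique(values: pd.Index, kind: str) -> None:
    if values.has_duplicates:
        dups = values[values.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {kind} identifier(s): {dups[:10]}")


@dataclass
class CountMatrix:
    """Integer gene-by-sample count matrix.

    Parameters
    ----------
    counts
        DataFrame indexed by gene symbol (rows) with sample identifiers as
        columns. All entries must be non-negative integers; gene and sample
        identifiers must be unique. HGNC symbols are case-significant and are
        matched case-sensitively throughout.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "gene")
        _check_unique(self.counts.columns, "sample")
        values = self.counts.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.integer):
                # accept float input that is exactly integral
                if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                    bad = self._first_bad(lambda v: (not np.isfinite(v)) or v != np.floor(v))
                    raise ValidationError(f"non-integer count at {bad}")
                self.counts = self.counts.astype(np.int64)
                values = self.counts.to_numpy()
            if np.any(values < 0):
                bad = self._first_bad(lambda v: v < 0)
                raise ValidationError(f"negative count at {bad}")

    def _first_bad(self, pred) -> str:
        arr = self.counts.to_numpy()
        for i in range(arr.shape[0]):
            for j in range(arr.shape[1]):
                if pred(arr[i, j]):
                    return (
                        f"gene '{self.counts.index[i]}', sample "
                        f"'{self.counts.columns[j]}' (value {arr[i, j]!r})"
                    )
        return "<unknown>"

    @property
    def gene_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_samples(self, samples: Sequence[str]) -> "CountMatrix":
        missing = [s for s in samples if s not in self.counts.columns]
        if missing:
            raise ValidationError(f"unknown sample(s): {missing}")
        return CountMatrix(self.counts.loc[:, list(samples)])


@dataclass
class SampleMeta:
    """Per-sample annotations keyed by sample identifier.

    ``table`` is indexed by sample_id with columns ``specimen``, ``lineage``,
    ``culture`` and (optionally) ``timepoint_weeks``. A missing timepoint is
    NA, never 0 — RNA-seq samples have no timepoint.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample")
        for col in ("specimen", "lineage", "culture"):
            if col not in self.table.columns:
                raise ValidationError(f"metadata missing required column '{col}'")
        bad_lineage = set(self.table["lineage"]) - set(LINEAGES)
        if bad_lineage:
            raise ValidationError(
                f"unknown lineage value(s) {sorted(bad_lineage)}; allowed: {LINEAGES}"
            )
        bad_culture = set(self.table["culture"]) - set(CULTURES)
        if bad_culture:
            raise ValidationError(
                f"unknown culture value(s) {sorted(bad_culture)}; allowed: {CULTURES}"
            )
        if "timepoint_weeks" not in self.table.columns:
            self.table = self.table.assign(timepoint_weeks=pd.Series(dtype="Float64"))
        else:
            tw = pd.to_numeric(self.table["timepoint_weeks"], errors="coerce")
            if ((tw < 0) & tw.notna()).any():
                raise ValidationError("timepoint_weeks must be non-negative")
            self.table = self.table.assign(timepoint_weeks=tw.astype("Float64"))

    @property
    def sample_ids(self) -> list[str]:
        return self.table.index.tolist()

    def samples_where(self, **criteria: str) -> list[str]:
        """Sample ids matching all ``column=value`` criteria (e.g. culture="standard")."""
        mask = pd.Series(True, index=self.table.index)
        for col, value in criteria.items():
            if col not in self.table.columns:
                raise ValidationError(f"unknown metadata column '{col}'")
            mask &= self.table[col] == value
        return self.table.index[mask].tolist()


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional explicit background universe."""

    sets: dict[str, frozenset[str]]
    universe: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(members) for name, members in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def restricted_to(self, universe: Sequence[str]) -> "GeneSetCollection":
        uni = frozenset(universe)
        return GeneSetCollection(
            {name: members & uni for name, members in self.sets.items()},
            universe=list(universe),
        )


@dataclass
class GateConfig:
    """Threshold gates for the four-marker flow panel.

    Intensity equal to a threshold counts as positive (>=). ``per_culture``
    optionally overrides thresholds for named culture types, e.g. to raise
    every gate for postconfluent samples whose autofluorescence shifts the
    whole intensity distribution upward.
    """

    cd133: float = 100.0
    cd271: float = 100.0
    cd117: float = 100.0
    dapi: float = 100.0
    per_culture: dict[str, "GateConfig"] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("cd133", "cd271", "cd117", "dapi"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"gate threshold {name} must be > 0")

    def for_culture(self, culture: Optional[str]) -> "GateConfig":
        if culture is not None and culture in self.per_culture:
            return self.per_culture[culture]
        return self


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters with the pipeline's defaults.

    pseudocount
        CPM added to both group means before the log-ratio (default 1).
    min_cpm
        A gene is blocked when its CPM falls below this in *every* sample of
        the relevant group (default 2).
    top_n
        Size of the convergent/divergent gene lists (default 200, roughly 1%
        of a transcriptome-scale feature set).
    fdr_alpha
        Benjamini–Hochberg significance cut-off for gene-set tests.
    """

    pseudocount: float = 1.0
    min_cpm: float = 2.0
    top_n: int = 200
    fdr_alpha: float = 0.05
    gates: GateConfig = field(default_factory=GateConfig)
    logit_epsilon: float = 1e-3
    float_precision: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")
        if self.min_cpm < 0:
            raise ValidationError("min_cpm must be non-negative")
        if self.top_n <= 0:
            raise ValidationError("top_n must be a positive integer")
        if not 0 < self.fdr_alpha < 1:
            raise ValidationError("fdr_alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        gates_raw = raw.pop("gates", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if gates_raw is not None:
            per_culture = {
                cult: GateConfig(**sub)
                for cult, sub in (gates_raw.pop("per_culture", {}) or {}).items()
            }
            cfg.gates = GateConfig(per_culture=per_culture, **gates_raw)
        return cfg

    def snapshot(self) -> Mapping[str, object]:
        d = dataclasses.asdict(self)
        return d
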