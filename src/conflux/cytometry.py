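"""Flow-cytometry gate classification and lineage composition tables.

Events are classified with one-dimensional threshold gates on the
CD133/CD271/CD117/DAPI panel:

* DAPI >= threshold — dead/permeable, discarded;
* CD133+ / CD271-  — luminal epithelial (LEp);
* CD133- / CD271+  — myoepithelial (MEp);
* double-positive or double-negative — other;
* CD117 >= threshold — c-Kit+ progenitor flag, evaluated on the
  non-discarded events *orthogonally* to the LEp/MEp partition.

"Positive" means intensity >= threshold (boundary counts as positive).
Composition tables report percentages of DAPI-negative events, with the
c-Kit+ fraction computed independently of the lineage partition.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import FLOW_MARKERS, GateConfig, ValidationError

log = logging.getLogger("conflux")

__all__ = ["classify_events", "composition_table", "GateConfig"]


def classify_events(events: pd.DataFrame, gates: GateConfig) -> pd.DataFrame:
    """Classify each event as LEp / MEp / other / discarded, plus a c-Kit flag.

    Returns a copy of ``events`` with added columns ``label`` and ``ckit``
    (nullable boolean; NA for discarded events). If the table has a
    ``culture`` column and ``gates.per_culture`` names that culture, the
    per-culture thresholds are applied to those events.
    """
    missing = [m for m in FLOW_MARKERS if m not in events.columns]
    if missing:
        raise ValidationError(f"event table missing marker column(s): {missing}")
    vals = events[list(FLOW_MARKERS)].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)) or np.any(vals < 0):
        raise ValidationError("marker intensities must be finite and non-negative")

    out = events.copy()
    label = np.empty(len(events), dtype=object)
    ckit = np.full(len(events), pd.NA, dtype=object)

    if "culture" in events.columns and gates.per_culture:
        groups = list(events.groupby("culture", sort=False).groups.items())
    else:
        groups = [(None, events.index)]

    for culture, idx in groups:
        g = gates.for_culture(culture)
        pos = events.loc[idx]
        dead = pos["DAPI"].to_numpy(float) >= g.dapi
        cd133 = pos["CD133"].to_numpy(float) >= g.cd133
        cd271 = pos["CD271"].to_numpy(float) >= g.cd271
        cd117 = pos["CD117"].to_numpy(float) >= g.cd117
        lab = np.where(
            dead, "discarded",
            np.where(cd133 & ~cd271, "LEp", np.where(~cd133 & cd271, "MEp", "other")),
        )
        loc = out.index.get_indexer(idx)
        label[loc] = lab
        ckit[loc] = np.where(dead, pd.NA, cd117)

    out["label"] = label
    out["ckit"] = pd.array(ckit, dtype="boolean")
    n_disc = int((out["label"] == "discarded").sum())
    log.info("classify_events: %d event(s), %d discarded (DAPI+)", len(out), n_disc)
    return out


def composition_table(
    labeled: pd.DataFrame,
    group_cols: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Lineage composition as percent of DAPI-negative events.

    ``labeled`` is the output of :func:`classify_events`, optionally carrying
    ``specimen``/``culture`` columns to group by (``group_cols`` defaults to
    whichever of those are present; with neither, one overall row is
    produced). Columns ``pct_LEp + pct_MEp + pct_other`` sum to 100 within
    rounding; ``pct_cKit`` is the independent c-Kit+ fraction of the same
    denominator. Groups whose events were all discarded are omitted with a
    warning.
    """
    if "label" not in labeled.columns:
        raise ValidationError("events are not classified; run classify_events first")
    if group_cols is None:
        group_cols = [c for c in ("specimen", "culture") if c in labeled.columns]

    def one_row(sub: pd.DataFrame) -> Optional[dict]:
        live = sub[sub["label"] != "discarded"]
        if not len(live):
            return None
        n = len(live)
        return {
            "n_events": n,
            "pct_LEp": 100.0 * (live["label"] == "LEp").sum() / n,
            "pct_MEp": 100.0 * (live["label"] == "MEp").sum() / n,
            "pct_other": 100.0 * (live["label"] == "other").sum() / n,
            "pct_cKit": 100.0 * live["ckit"].fillna(False).astype(bool).sum() / n,
        }

    rows = []
    if group_cols:
        for key, sub in labeled.groupby(group_cols, sort=True):
            row = one_row(sub)
            if row is None:
                log.warning("composition_table: all events discarded for group %r; omitted", key)
                continue
            key = key if isinstance(key, tuple) else (key,)
            rows.append({**dict(zip(group_cols, key)), **row})
    else:
        row = one_row(labeled)
        if row is None:
            log.warning("composition_table: all events discarded; empty table")
        else:
            rows.append(row)
    cols = group_cols + ["n_events", "pct_LEp", "pct_MEp", "pct_other", "pct_cKit"]
    return pd.DataFrame(rows, columns=cols)
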