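"""Readers and writers for the pipeline's text formats.

Everything is plain text: TSV count matrices (gene symbols in the first
column, sample ids in the header), TSV sample metadata keyed by sample_id,
GMT gene-set files, and CSV flow event tables. Files are UTF-8 with '.' as
the decimal separator; gene symbols are matched case-sensitively.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .datatypes import (
    FLOW_MARKERS,
    CountMatrix,
    GeneSetCollection,
    SampleMeta,
    ValidationError,
)

log = logging.getLogger("conflux")

PathLike = Union[str, Path]


def read_counts(path: PathLike) -> CountMatrix:
    """Read a TSV count matrix, validating integer non-negative counts.

    Raises
    ------
    ValidationError
        On duplicate gene symbols, or any non-integer or negative count; the
        message names the offending gene/sample cell.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate gene symbol(s): {dups[:10]}")
    parsed = pd.DataFrame(index=df.index, columns=df.columns, dtype=np.int64)
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (numeric != np.floor(numeric.fillna(0))) | (numeric < 0)
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValidationError(
                f"{path}: invalid count at gene '{gene}', sample '{col}' "
                f"(value {df.loc[gene, col]!r}): counts must be non-negative integers"
            )
        parsed[col] = numeric.astype(np.int64)
    cm = CountMatrix(parsed)
    log.info("read_counts: %d genes x %d samples from %s", *cm.shape, path)
    return cm


def read_sample_meta(path: PathLike) -> SampleMeta:
    """Read TSV sample metadata keyed by a ``sample_id`` column (or first column)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    key = "sample_id" if "sample_id" in df.columns else df.columns[0]
    df = df.set_index(key)
    df.index = df.index.astype(str)
    return SampleMeta(df)


def read_counts_with_metadata(
    counts_path: PathLike, meta_path: PathLike
) -> tuple[CountMatrix, SampleMeta]:
    """Read and cross-validate a count matrix with its sample metadata.

    Every sample in the matrix must have exactly one metadata row (hard
    error naming the orphan otherwise); metadata rows without a matching
    sample are reported as a warning and retained.
    """
    cm = read_counts(counts_path)
    meta = read_sample_meta(meta_path)
    missing = [s for s in cm.sample_ids if s not in meta.table.index]
    if missing:
        raise ValidationError(
            f"sample(s) in {counts_path} without metadata in {meta_path}: {missing}"
        )
    extra = [s for s in meta.table.index if s not in cm.counts.columns]
    if extra:
        log.warning("metadata rows without matching samples: %s", extra)
    return cm, meta


def write_counts(cm: CountMatrix, path: PathLike) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene")


def read_gmt(path: PathLike) -> GeneSetCollection:
    """Read a GMT gene-set file (set name, description, tab-separated members).

    Duplicate members within one line are deduplicated with a warning; a
    duplicate set name or a line with fewer than three fields is a hard
    error naming the line.
    """
    sets: dict[str, frozenset[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s); "
                    "expected set name, description and at least one member"
                )
            name = fields[0]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate gene-set name '{name}'")
            members = [m for m in fields[2:] if m]
            unique = frozenset(members)
            if len(unique) < len(members):
                log.warning(
                    "%s:%d: set '%s' has duplicate members; deduplicated %d -> %d",
                    path, lineno, name, len(members), len(unique),
                )
            sets[name] = unique
    log.info("read_gmt: %d set(s) from %s", len(sets), path)
    return GeneSetCollection(sets)


def write_gmt(gsc: GeneSetCollection, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in gsc.sets.items():
            fh.write("\t".join([name, "."] + sorted(members)) + "\n")


def read_flow_events(path: PathLike) -> pd.DataFrame:
    """Read a CSV flow event table with CD133/CD271/CD117/DAPI columns."""
    df = pd.read_csv(path)
    missing = [m for m in FLOW_MARKERS if m not in df.columns]
    if missing:
        raise ValidationError(f"{path}: flow event table missing marker column(s) {missing}")
    for m in FLOW_MARKERS:
        vals = df[m].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValidationError(f"{path}: marker {m} has non-finite or negative intensities")
    return df


def write_results(table: pd.DataFrame, path: PathLike, float_precision: int = 6) -> None:
    """Write a result table as UTF-8 TSV with a header row.

    Column order is preserved as given (deterministic); floats are rendered
    with ``float_precision`` significant digits.
    """
    table.to_csv(
        path,
        sep="\t",
        index=False,
        float_format=f"%.{float_precision}g",
        encoding="utf-8",
    )
    log.info("write_results: %d row(s) x %d column(s) -> %s", len(table), table.shape[1], path)


def read_results(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_longitudinal(path: PathLike) -> pd.DataFrame:
    """Read a TSV longitudinal table (specimen, timepoint, fraction).

    Accepts either a ``fraction`` column in [0,1] or a ``percent`` column in
    [0,100] (divided by 100 on read) — published viability/senescence tables
    come in both layouts.
    """
    df = pd.read_csv(path, sep="\t", dtype={"specimen": str, "timepoint": str})
    if "fraction" not in df.columns:
        if "percent" in df.columns:
            df = df.assign(fraction=pd.to_numeric(df["percent"]) / 100.0)
        else:
            raise ValidationError(f"{path}: expected a 'fraction' or 'percent' column")
    frac = pd.to_numeric(df["fraction"])
    if ((frac < 0) | (frac > 1)).any():
        bad = df.loc[(frac < 0) | (frac > 1)].index[0]
        raise ValidationError(f"{path}: fraction outside [0,1] at row {bad + 2}")
    df["fraction"] = frac
    return df
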