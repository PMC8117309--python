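"""Columnar text I/O for survey records, census weights and estimates.

Survey CSV: columns age_group, sex, education, urbanicity, region,
occupation, waist_cm; an empty string marks a missing value.
Weights CSV: the six factor columns plus ``weight``, one row per cell.
Estimates CSV: grouping columns plus median, lower95, upper95, direct,
n, y.  All round-trip stable through :func:`write_survey` /
:func:`read_survey` and :func:`write_estimates`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .classification import (
    FACTOR_COLUMNS,
    CellClassification,
    validate_records,
)
from .poststrat import PostStratTable

__all__ = [
    "read_survey",
    "write_survey",
    "read_weights",
    "write_weights",
    "write_estimates",
    "read_estimates",
    "load_config",
]


class IOFormatError(ValueError):
    pass


def read_survey(
    path, classification: CellClassification | None = None
) -> pd.DataFrame:
    """Read respondent records; empty fields become NaN (missing).

    If a classification is given, level labels and waist plausibility
    are validated; a malformed row raises an error naming its line
    number (1-based, counting the header as line 1).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in (*FACTOR_COLUMNS, "waist_cm") if c not in df.columns]
    if missing_cols:
        raise IOFormatError(f"survey file lacks columns {missing_cols}")
    df = df.replace("", np.nan)
    waist = pd.to_numeric(df["waist_cm"], errors="coerce")
    bad = df["waist_cm"].notna() & waist.isna()
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise IOFormatError(f"line {line}: waist_cm={df['waist_cm'][line - 2]!r} is not numeric")
    df["waist_cm"] = waist
    if classification is not None:
        try:
            validate_records(df, classification, allow_missing=True)
        except ValueError as e:
            raise IOFormatError(str(e)) from e
    return df


def write_survey(path, records: pd.DataFrame) -> None:
    """Write respondent records; missing values become empty fields."""
    cols = [*FACTOR_COLUMNS, "waist_cm"]
    records[cols].to_csv(path, index=False, na_rep="")


def read_weights(
    path, classification: CellClassification, fill_missing: bool = False
) -> PostStratTable:
    """Read a census weight table keyed by level labels.

    Every classification cell must appear exactly once; absent cells
    raise an error listing them unless ``fill_missing=True``, in which
    case they are zero-filled.  Unknown level labels raise an error
    naming the label and factor.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in classification.factor_names if c not in df.columns]
    if missing_cols:
        raise IOFormatError(f"weights file lacks columns {missing_cols}")
    if "weight" not in df.columns:
        raise IOFormatError("weights file lacks column 'weight'")

    multi = []
    for name in classification.factor_names:
        levels = list(classification.levels(name))
        codes = pd.Categorical(df[name], categories=levels).codes
        if (codes < 0).any():
            row = int(np.argmax(codes < 0))
            raise IOFormatError(
                f"line {row + 2}: {df[name].iloc[row]!r} is not a level of factor {name!r}"
            )
        multi.append(codes.astype(np.int64))
    idx = np.ravel_multi_index(multi, classification.shape)
    if len(np.unique(idx)) != len(idx):
        dup = int(pd.Series(idx).duplicated().idxmax())
        raise IOFormatError(f"line {dup + 2}: duplicate cell")

    w = np.full(classification.n_cells, np.nan)
    w[idx] = pd.to_numeric(df["weight"], errors="raise").to_numpy(float)
    absent = np.flatnonzero(np.isnan(w))
    if len(absent):
        if not fill_missing:
            shown = [classification.levels_of(int(i)) for i in absent[:5]]
            raise IOFormatError(
                f"weight table missing {len(absent)} cells, e.g. {shown}; "
                "pass fill_missing=True to zero-fill"
            )
        w[absent] = 0.0
    return PostStratTable(classification, w)


def write_weights(path, table: PostStratTable) -> None:
    table.to_frame().to_csv(path, index=False)


def write_estimates(path, estimates: pd.DataFrame) -> None:
    """Write an estimate table (any grouping) as CSV; NaN -> empty field."""
    estimates.to_csv(path, index=False, na_rep="")


def read_estimates(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path) -> dict:
    """Load a YAML run configuration (factor levels, priors, MCMC, seeds)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise IOFormatError("config must be a YAML mapping")
    return cfg
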