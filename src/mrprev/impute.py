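"""k-nearest-neighbour imputation of missing survey fields.

Distances between respondent records use the Gower dissimilarity:
0/1 mismatch for categorical variables, range-scaled absolute
difference for numeric ones, averaged over the variables observed in
both records.  Each missing categorical value is replaced by the mode
among the k nearest donors that have the variable observed (median for
numeric values).  Ties in distance are broken by record order after a
seeded shuffle, so the result is deterministic under a seed without
depending on the incidental ordering of the input file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ImputationConfig", "gower_distance", "knn_impute"]


class ImputationError(ValueError):
    pass


@dataclass
class ImputationConfig:
    """k (default 5, the common kNN-imputation default), the variables
    entering the distance (default: all others), and the aggregation
    rule (mode for categorical, median for numeric)."""

    k: int = 5
    distance_variables: tuple[str, ...] | None = None  # None -> all other variables
    numeric_variables: tuple[str, ...] = ("waist_cm",)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ImputationError("k must be >= 1")
        if self.distance_variables is not None and len(self.distance_variables) == 0:
            raise ImputationError("distance variable set must be non-empty")


def gower_distance(
    a: pd.Series | dict,
    b: pd.Series | dict,
    variables: tuple[str, ...] | list[str],
    numeric: tuple[str, ...] = ("waist_cm",),
    ranges: dict[str, float] | None = None,
) -> float:
    """Gower dissimilarity between two records over the given variables.

    Variables missing in either record do not contribute; if no
    variable is observed in both, the records are maximally distant
    (distance 1).  Numeric differences are scaled by the variable's
    observed range (``ranges``; a zero or absent range contributes 0
    for equal values, 1 otherwise).
    """
    if len(variables) == 0:
        raise ImputationError("empty variable list")
    a = dict(a) if not isinstance(a, dict) else a
    b = dict(b) if not isinstance(b, dict) else b
    total, used = 0.0, 0
    for v in variables:
        x, z = a.get(v), b.get(v)
        if _is_missing(x) or _is_missing(z):
            continue
        used += 1
        if v in numeric:
            rng = (ranges or {}).get(v, 0.0)
            if rng > 0:
                total += min(abs(float(x) - float(z)) / rng, 1.0)
            else:
                total += 0.0 if float(x) == float(z) else 1.0
        else:
            total += 0.0 if x == z else 1.0
    if used == 0:
        return 1.0
    return total / used


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v))


def _distance_matrix_to(
    records: pd.DataFrame,
    target_idx: int,
    variables: list[str],
    numeric: tuple[str, ...],
    ranges: dict[str, float],
) -> np.ndarray:
    """Gower distance from one record to all records, vectorised."""
    n = len(records)
    total = np.zeros(n)
    used = np.zeros(n)
    for v in variables:
        col = records[v]
        x = col.iloc[target_idx]
        if _is_missing(x):
            continue
        observed = col.notna().to_numpy()
        if v in numeric:
            vals = pd.to_numeric(col, errors="coerce").to_numpy(float)
            rng = ranges.get(v, 0.0)
            if rng > 0:
                d = np.minimum(np.abs(vals - float(x)) / rng, 1.0)
            else:
                d = (vals != float(x)).astype(float)
        else:
            d = (col.to_numpy(object) != x).astype(float)
        total[observed] += d[observed]
        used[observed] += 1.0
    out = np.ones(n)
    np.divide(total, used, out=out, where=used > 0)
    return out


def knn_impute(
    records: pd.DataFrame,
    config: ImputationConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[dict]]:
    """Complete all missing fields by kNN over Gower distances.

    Donors are drawn from the original (pre-imputation) records, so the
    result does not depend on the order in which missing fields are
    visited.  Observed values are never altered.

    Returns the completed table and a log: one entry per imputed field
    with the record index, variable, donor indices, distances and the
    imputed value.

    Raises
    ------
    ImputationError
        If a record is entirely missing, or a variable has fewer than k
        records with the value observed.
    """
    config = config or ImputationConfig()
    out = records.copy()
    cols = list(records.columns)
    numeric = tuple(v for v in config.numeric_variables if v in cols)

    obs_mask = records.notna()
    if (~obs_mask).all(axis=1).any():
        row = int((~obs_mask).all(axis=1).idxmax())
        raise ImputationError(f"record {row} has no observed values")

    ranges: dict[str, float] = {}
    for v in numeric:
        vals = pd.to_numeric(records[v], errors="coerce")
        if vals.notna().any():
            ranges[v] = float(vals.max() - vals.min())

    # positional index after a seeded shuffle: the tie-breaking order
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(len(records))
    tie_rank = np.empty(len(records), dtype=int)
    tie_rank[shuffled] = np.arange(len(records))

    log: list[dict] = []
    rows_missing = np.flatnonzero((~obs_mask).any(axis=1).to_numpy())
    for r in rows_missing:
        for v in cols:
            if obs_mask.iloc[r][v]:
                continue
            if config.distance_variables is not None:
                dist_vars = [u for u in config.distance_variables if u != v]
            else:
                dist_vars = [u for u in cols if u != v]
            if not dist_vars:
                raise ImputationError("distance variable set must be non-empty")
            d = _distance_matrix_to(records, r, dist_vars, numeric, ranges)
            eligible = obs_mask[v].to_numpy().copy()
            eligible[r] = False
            cand = np.flatnonzero(eligible)
            if len(cand) < config.k:
                raise ImputationError(
                    f"variable {v!r}: only {len(cand)} eligible donors, need k={config.k}"
                )
            order = cand[np.lexsort((tie_rank[cand], d[cand]))]
            donors = order[: config.k]
            donor_vals = records[v].iloc[donors]
            if v in numeric:
                value = float(pd.to_numeric(donor_vals).median())
            else:
                counts = donor_vals.value_counts()
                top = counts[counts == counts.max()].index
                if len(top) == 1:
                    value = top[0]
                else:
                    # mode tie: take the nearest donor holding a tied value
                    value = next(
                        records[v].iloc[i] for i in donors if records[v].iloc[i] in set(top)
                    )
            out.iloc[r, out.columns.get_loc(v)] = value
            log.append(
                {
                    "record": int(r),
                    "variable": v,
                    "donors": [int(i) for i in donors],
                    "distances": [float(d[i]) for i in donors],
                    "value": value,
                }
            )
    return out, log
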