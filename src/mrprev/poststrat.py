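"""Post-stratification: from posterior draws to weighted prevalence estimates.

The model produces draws of the 1760 cell prevalences pi_i.  For a
reporting group g (any combination of factor levels), the population
prevalence in each draw s is the census-weighted average

    pibar_g^(s) = sum_{i in g} w_i pi_i^(s) / sum_{i in g} w_i,

and the point estimate / 95% credible interval are the median and the
2.5 / 97.5% quantiles of pibar_g over draws (linear interpolation
between order statistics).  Direct estimates pool counts first
(y/n over the group's cells), matching survey tabulation practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classification import CellClassification, CellCounts, SEDENTARY_GROUP

__all__ = [
    "PostStratTable",
    "direct_estimates",
    "poststratify",
    "summarize_run",
    "shrinkage_report",
]


class PostStratError(ValueError):
    pass


@dataclass
class PostStratTable:
    """Census population weight per classification cell (counts or shares)."""

    classification: CellClassification
    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        k = self.classification.n_cells
        if self.w.shape != (k,):
            raise PostStratError(f"weights must have length {k}, got {self.w.shape}")
        if (self.w < 0).any():
            raise PostStratError("weights must be non-negative")
        if not (self.w > 0).any():
            raise PostStratError("at least one weight must be positive")

    def normalized(self) -> "PostStratTable":
        return PostStratTable(self.classification, self.w / self.w.sum())

    def to_frame(self) -> pd.DataFrame:
        out = self.classification.cells()
        out["weight"] = self.w
        return out


def _group_codes(
    classification: CellClassification, grouping: tuple[str, ...]
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Map each cell to its group; return (cell labels, group id per cell, group key table)."""
    for f in grouping:
        if f not in classification.factor_names:
            raise PostStratError(f"unknown grouping factor {f!r}")
    cells = classification.cells()
    if not grouping:
        gid = np.zeros(classification.n_cells, dtype=int)
        keys = pd.DataFrame(index=[0])
        return cells, gid, keys
    codes = classification.level_codes()
    shape = [len(classification.levels(f)) for f in grouping]
    gid = np.ravel_multi_index([codes[f].to_numpy() for f in grouping], shape)
    n_groups = int(np.prod(shape))
    grids = np.meshgrid(*[np.arange(k) for k in shape], indexing="ij")
    keys = pd.DataFrame(
        {
            f: np.asarray(classification.levels(f), dtype=object)[g.ravel()]
            for f, g in zip(grouping, grids)
        }
    )
    assert len(keys) == n_groups
    return cells, gid, keys


def direct_estimates(
    counts: CellCounts, grouping: tuple[str, ...] | list[str]
) -> pd.DataFrame:
    """Observed proportions y/n pooled within each group.

    Returns one row per group with columns ``n``, ``y`` and ``direct``
    (NaN where the pooled n is zero, i.e. the direct estimate is
    undefined).
    """
    grouping = tuple(grouping)
    _, gid, keys = _group_codes(counts.classification, grouping)
    n_groups = len(keys)
    n = np.bincount(gid, weights=counts.n, minlength=n_groups)
    y = np.bincount(gid, weights=counts.y, minlength=n_groups)
    out = keys.copy()
    out["n"] = n.astype(int)
    out["y"] = y.astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["direct"] = np.where(n > 0, y / np.where(n > 0, n, 1), np.nan)
    return out


def poststratify(
    pi_draws: np.ndarray,
    weights: PostStratTable,
    grouping: tuple[str, ...] | list[str],
) -> pd.DataFrame:
    """Census-weighted prevalence estimates with 95% credible intervals.

    Parameters
    ----------
    pi_draws : ndarray, shape (S, n_cells)
        Posterior draws of all cell prevalences (chains already pooled).
    weights : PostStratTable
        Population weight per cell, aligned to the same classification.
    grouping : tuple of factor names
        The reporting classification; () gives a single overall row.

    Returns
    -------
    DataFrame
        One row per group: grouping levels, ``median``, ``lower95``,
        ``upper95``.

    Raises
    ------
    PostStratError
        If any requested group has zero total weight.
    """
    grouping = tuple(grouping)
    classification = weights.classification
    pi_draws = np.asarray(pi_draws, dtype=float)
    if pi_draws.ndim != 2 or pi_draws.shape[1] != classification.n_cells:
        raise PostStratError(
            f"pi_draws must be (S, {classification.n_cells}); got {pi_draws.shape}"
        )
    _, gid, keys = _group_codes(classification, grouping)
    n_groups = len(keys)
    wtot = np.bincount(gid, weights=weights.w, minlength=n_groups)
    if (wtot <= 0).any():
        bad = keys.iloc[int(np.argmax(wtot <= 0))].to_dict()
        raise PostStratError(f"group {bad} has zero total weight")

    # per-draw weighted averages: (S, n_groups)
    ind = np.zeros((classification.n_cells, n_groups))
    ind[np.arange(classification.n_cells), gid] = weights.w
    ind /= wtot[None, :]
    pibar = pi_draws @ ind

    q = np.quantile(pibar, [0.025, 0.5, 0.975], axis=0, method="linear")
    out = keys.copy()
    out["median"] = q[1]
    out["lower95"] = q[0]
    out["upper95"] = q[2]
    return out


def _attach_sedentary(table: pd.DataFrame) -> pd.DataFrame:
    if "occupation" in table.columns:
        table = table.copy()
        table["activity_group"] = table["occupation"].map(
            lambda o: SEDENTARY_GROUP.get(o, "unknown")
        )
    return table


def summarize_run(
    pi_draws: np.ndarray,
    weights: PostStratTable,
    counts: CellCounts,
    groupings: list[tuple[str, ...]],
    diagnostics_table: pd.DataFrame | None = None,
    allow_flagged: bool = False,
) -> dict[tuple[str, ...], pd.DataFrame]:
    """Estimate tables for several reporting groupings at once.

    Each table carries the model median and interval, the pooled direct
    estimate with its counts, and (when occupation is a grouping
    factor) the sedentary / non-sedentary tag.  If a diagnostics table
    with unresolved convergence flags is supplied, the run is refused
    unless ``allow_flagged=True``.
    """
    if diagnostics_table is not None and not allow_flagged:
        flagged = diagnostics_table[
            diagnostics_table.get("flagged", pd.Series(dtype=bool)).astype(bool)
        ]
        if len(flagged):
            names = ", ".join(flagged["parameter"].head(5))
            raise PostStratError(
                f"{len(flagged)} parameters failed convergence checks ({names}...); "
                "pass allow_flagged=True to override"
            )
    out: dict[tuple[str, ...], pd.DataFrame] = {}
    for grouping in groupings:
        grouping = tuple(grouping)
        model = poststratify(pi_draws, weights, grouping)
        direct = direct_estimates(counts, grouping)
        merged = model.merge(direct, on=list(grouping), how="left") if grouping else (
            model.assign(**direct[["n", "y", "direct"]].iloc[0].to_dict())
        )
        out[grouping] = _attach_sedentary(merged)
    return out


def shrinkage_report(
    pi_draws: np.ndarray,
    counts: CellCounts,
    group_factors: tuple[str, ...] = ("age_group", "sex", "education"),
    max_n: int = 3,
) -> pd.DataFrame:
    """Quantify shrinkage of model estimates towards group-level means.

    For cells with 1 <= n_i <= ``max_n`` (where direct estimates exist
    but are noisy), compares the absolute deviation of the model's
    per-cell posterior median and of the direct estimate y_i/n_i from
    the pooled direct estimate of the cell's group (default: its
    age x sex x education margin).  Hierarchical pooling should pull
    model estimates towards these central values, so the model column's
    mean should not exceed the direct column's.
    """
    classification = counts.classification
    _, gid, _ = _group_codes(classification, tuple(group_factors))
    n_groups = gid.max() + 1
    gn = np.bincount(gid, weights=counts.n, minlength=n_groups)
    gy = np.bincount(gid, weights=counts.y, minlength=n_groups)
    with np.errstate(invalid="ignore", divide="ignore"):
        gmean = np.where(gn > 0, gy / np.where(gn > 0, gn, 1), np.nan)

    med = np.quantile(np.asarray(pi_draws, float), 0.5, axis=0)
    mask = (counts.n >= 1) & (counts.n <= max_n) & ~np.isnan(gmean[gid])
    direct = counts.y[mask] / counts.n[mask]
    center = gmean[gid][mask]
    return pd.DataFrame(
        {
            "n_cells": [int(mask.sum())],
            "mad_model": [float(np.mean(np.abs(med[mask] - center)))],
            "mad_direct": [float(np.mean(np.abs(direct - center)))],
        }
    )
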