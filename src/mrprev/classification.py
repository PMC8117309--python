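"""Cross-classification of post-stratification cells and outcome coding.

The estimation target is obesity prevalence within every cell of a
six-way cross-classification (age x sex x education x urban-rural
residence x region x occupation).  This module defines the cell index,
the waist-circumference obesity cutoffs, and the tabulation of
respondent records into per-cell binomial counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CellClassification",
    "CellCounts",
    "CUTOFFS_CM",
    "SEDENTARY_GROUP",
    "FACTOR_COLUMNS",
    "apply_cutoff",
    "build_classification",
    "default_classification",
    "tabulate",
    "validate_records",
]


class ClassificationError(ValueError):
    """Raised when records or configuration violate the classification."""


#: Sex- and population-standard-specific waist circumference thresholds
#: (cm).  A respondent is coded obese iff waist >= threshold (the
#: non-strict convention; the cutoff value itself counts as obese).
CUTOFFS_CM: dict[tuple[str, str], float] = {
    ("asian", "male"): 90.0,
    ("asian", "female"): 80.0,
    ("european", "male"): 102.0,
    ("european", "female"): 88.0,
}

#: Plausibility range for measured waist circumference, in cm.
WAIST_RANGE_CM: tuple[float, float] = (30.0, 250.0)

DEFAULT_AGE_LEVELS = ("20-29", "30-39", "40-49", "50-59")
DEFAULT_SEX_LEVELS = ("female", "male")
DEFAULT_EDUCATION_LEVELS = ("primary or lower", "secondary or higher")
DEFAULT_URBANICITY_LEVELS = ("urban", "rural")
DEFAULT_REGION_LEVELS = ("Bangkok", "Central", "North", "Northeast", "South")
DEFAULT_OCCUPATION_LEVELS = (
    "Legislators, senior officials, and managers",
    "Professionals",
    "Technicians and associate professionals",
    "Clerical support workers",
    "Service workers and shop and market sale workers",
    "Elementary occupations",
    "Skilled agricultural and fishery workers",
    "Armed forces",
    "Plant and machine operators and assemblers",
    "No occupation",
    "Other",
)

#: Occupation groups classified by predominant activity at work.  Used
#: only for reporting (marking panels), never inside the model itself.
SEDENTARY_GROUP: dict[str, str] = {
    "Legislators, senior officials, and managers": "sedentary",
    "Professionals": "sedentary",
    "Technicians and associate professionals": "sedentary",
    "Clerical support workers": "sedentary",
    "Service workers and shop and market sale workers": "non-sedentary",
    "Elementary occupations": "non-sedentary",
    "Skilled agricultural and fishery workers": "non-sedentary",
    "Armed forces": "non-sedentary",
    "Plant and machine operators and assemblers": "non-sedentary",
    "No occupation": "unknown",
    "Other": "unknown",
}

#: Canonical column order for survey tables.
FACTOR_COLUMNS = ("age_group", "sex", "education", "urbanicity", "region", "occupation")


def apply_cutoff(waist_cm: float, sex: str, standard: str = "asian") -> bool:
    """Classify a waist measurement as obese under a population standard.

    Parameters
    ----------
    waist_cm : float
        Waist circumference in centimetres.
    sex : str
        ``"female"`` or ``"male"``.
    standard : str
        ``"asian"`` (90 cm men / 80 cm women) or ``"european"``
        (102 cm men / 88 cm women).

    Returns
    -------
    bool
        True iff ``waist_cm`` is at or above the threshold (>=).

    Raises
    ------
    ValueError
        If waist or sex is missing, or waist lies outside the
        plausibility range.
    """
    if sex is None or (isinstance(sex, float) and np.isnan(sex)):
        raise ValueError("cannot classify: sex is missing")
    if waist_cm is None or np.isnan(waist_cm):
        raise ValueError("cannot classify: waist_cm is missing")
    key = (str(standard).lower(), str(sex).lower())
    if key not in CUTOFFS_CM:
        raise ValueError(f"unknown standard/sex combination {key!r}")
    lo, hi = WAIST_RANGE_CM
    if not lo <= waist_cm <= hi:
        raise ValueError(f"waist_cm={waist_cm} outside plausibility range [{lo}, {hi}]")
    return bool(waist_cm >= CUTOFFS_CM[key])


@dataclass(frozen=True)
class CellClassification:
    """Ordered cross-classification; maps cell index <-> level tuple.

    Cells are ordered row-major in the declared factor order: the last
    factor varies fastest.
    """

    factors: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        if not self.factors:
            raise ClassificationError("at least one factor is required")
        for name, levels in self.factors:
            if len(levels) == 0:
                raise ClassificationError(f"factor {name!r} has no levels")
            if len(set(levels)) != len(levels):
                raise ClassificationError(f"factor {name!r} has duplicate level labels")
        names = [name for name, _ in self.factors]
        if len(set(names)) != len(names):
            raise ClassificationError("duplicate factor names")

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.factors)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(levels) for _, levels in self.factors)

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    def levels(self, factor: str) -> tuple[str, ...]:
        for name, levels in self.factors:
            if name == factor:
                return levels
        raise KeyError(f"unknown factor {factor!r}")

    def index_of(self, level_tuple: tuple[str, ...]) -> int:
        """Cell index of a tuple of level labels (in factor order)."""
        if len(level_tuple) != len(self.factors):
            raise ClassificationError(
                f"expected {len(self.factors)} levels, got {len(level_tuple)}"
            )
        multi = []
        for (name, levels), value in zip(self.factors, level_tuple):
            try:
                multi.append(levels.index(value))
            except ValueError:
                raise ClassificationError(
                    f"{value!r} is not a level of factor {name!r}"
                ) from None
        return int(np.ravel_multi_index(multi, self.shape))

    def levels_of(self, index: int) -> tuple[str, ...]:
        """Level-label tuple of a cell index."""
        if not 0 <= index < self.n_cells:
            raise IndexError(f"cell index {index} out of range [0, {self.n_cells})")
        multi = np.unravel_index(index, self.shape)
        return tuple(levels[j] for (_, levels), j in zip(self.factors, multi))

    def level_codes(self) -> pd.DataFrame:
        """Integer level code per factor for every cell (n_cells rows)."""
        grids = np.meshgrid(*[np.arange(k) for k in self.shape], indexing="ij")
        return pd.DataFrame(
            {name: g.ravel() for (name, _), g in zip(self.factors, grids)}
        )

    def cells(self) -> pd.DataFrame:
        """Level labels per factor for every cell, in cell order."""
        codes = self.level_codes()
        out = {}
        for name, levels in self.factors:
            out[name] = np.asarray(levels, dtype=object)[codes[name].to_numpy()]
        return pd.DataFrame(out)


def build_classification(
    factor_spec: list[tuple[str, list[str]]] | dict[str, list[str]],
) -> CellClassification:
    """Build a :class:`CellClassification` from ordered factor levels."""
    if isinstance(factor_spec, dict):
        items = list(factor_spec.items())
    else:
        items = list(factor_spec)
    return CellClassification(
        factors=tuple((name, tuple(levels)) for name, levels in items)
    )


def default_classification() -> CellClassification:
    """The default six-factor classification: 4*2*2*2*5*11 = 1760 cells."""
    return build_classification(
        [
            ("age_group", list(DEFAULT_AGE_LEVELS)),
            ("sex", list(DEFAULT_SEX_LEVELS)),
            ("education", list(DEFAULT_EDUCATION_LEVELS)),
            ("urbanicity", list(DEFAULT_URBANICITY_LEVELS)),
            ("region", list(DEFAULT_REGION_LEVELS)),
            ("occupation", list(DEFAULT_OCCUPATION_LEVELS)),
        ]
    )


@dataclass
class CellCounts:
    """Per-cell respondent count n and obese count y.

    ``true_pi`` carries the generating prevalence when the counts are
    synthetic; it is None for real data.
    """

    classification: CellClassification
    n: np.ndarray
    y: np.ndarray
    true_pi: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.int64)
        k = self.classification.n_cells
        if self.n.shape != (k,) or self.y.shape != (k,):
            raise ClassificationError(
                f"counts must have length {k}; got n {self.n.shape}, y {self.y.shape}"
            )
        if (self.n < 0).any() or (self.y < 0).any():
            raise ClassificationError("counts must be non-negative")
        if (self.y > self.n).any():
            bad = int(np.argmax(self.y > self.n))
            raise ClassificationError(f"y > n at cell {bad}")
        if self.true_pi is not None:
            self.true_pi = np.asarray(self.true_pi, dtype=float)
            if self.true_pi.shape != (k,):
                raise ClassificationError(f"true_pi must have length {k}")
            if ((self.true_pi < 0) | (self.true_pi > 1)).any():
                raise ClassificationError("true_pi must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        out = self.classification.cells()
        out["n"] = self.n
        out["y"] = self.y
        if self.true_pi is not None:
            out["true_pi"] = self.true_pi
        return out


def validate_records(
    records: pd.DataFrame,
    classification: CellClassification,
    allow_missing: bool = True,
) -> None:
    """Check level labels and waist plausibility; raise on violations.

    Missing entries (NaN / empty) are permitted unless
    ``allow_missing=False``.
    """
    for name in classification.factor_names:
        if name not in records.columns:
            raise ClassificationError(f"records lack required column {name!r}")
        col = records[name]
        missing = col.isna()
        if not allow_missing and missing.any():
            row = int(missing.idxmax())
            raise ClassificationError(f"record {row}: missing value for factor {name!r}")
        levels = set(classification.levels(name))
        bad = ~missing & ~col.isin(levels)
        if bad.any():
            row = int(bad.idxmax())
            raise ClassificationError(
                f"record {row}: {col[row]!r} is not a level of factor {name!r}"
            )
    if "waist_cm" in records.columns:
        w = pd.to_numeric(records["waist_cm"], errors="coerce")
        missing = w.isna()
        if not allow_missing and missing.any():
            row = int(missing.idxmax())
            raise ClassificationError(f"record {row}: missing waist_cm")
        lo, hi = WAIST_RANGE_CM
        bad = ~missing & ((w < lo) | (w > hi))
        if bad.any():
            row = int(bad.idxmax())
            raise ClassificationError(
                f"record {row}: waist_cm={w[row]} outside plausibility range"
            )


def tabulate(
    records: pd.DataFrame,
    classification: CellClassification,
    standard: str = "asian",
) -> CellCounts:
    """Tabulate completed respondent records into per-cell (n, y) counts.

    Records must be fully imputed (no missing factor levels or waist
    measurements).  Obesity is coded by :func:`apply_cutoff` under the
    given standard.  Cells with no respondents get n = y = 0, so the
    totals are conserved: sum(n) equals the number of records and
    sum(y) the number of obese records.
    """
    validate_records(records, classification, allow_missing=False)
    k = classification.n_cells
    if len(records) == 0:
        return CellCounts(classification, np.zeros(k, int), np.zeros(k, int))

    multi = []
    for name in classification.factor_names:
        levels = list(classification.levels(name))
        codes = pd.Categorical(records[name], categories=levels).codes
        multi.append(codes.astype(np.int64))
    idx = np.ravel_multi_index(multi, classification.shape)

    waist = pd.to_numeric(records["waist_cm"], errors="raise").to_numpy(float)
    std = str(standard).lower()
    thresholds = np.array(
        [CUTOFFS_CM[(std, str(s).lower())] for s in records["sex"]], dtype=float
    )
    obese = (waist >= thresholds).astype(np.int64)

    n = np.bincount(idx, minlength=k)
    y = np.bincount(idx, weights=obese, minlength=k).astype(np.int64)
    return CellCounts(classification, n, y)
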