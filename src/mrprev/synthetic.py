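"""Synthetic survey and census data with known ground truth.

The real health-examination microdata and census one-percent sample
are access-restricted, so every downstream stage is exercised on
generated data that emulates their structure: a sparse six-way
cross-classification (most cells empty, median respondent count per
cell of 1 at the default size of 10,127 respondents over 1760 cells),
binomial outcomes driven by logit-scale main effects and second-order
interactions, and a fraction of a percent of missing values per
variable.

Ground truth is always explicit, so recovery and coverage tests have
an unambiguous target: :func:`default_scenario` emulates the study
(intercept at the survey's pooled prevalence, study-like effect
spreads), while :func:`calibration_scenario` draws parameters from the
model's own prior, the regime in which credible intervals are exactly
calibrated on average.  All randomness flows from one root seed with
named substreams per operation.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .classification import (
    CUTOFFS_CM,
    WAIST_RANGE_CM,
    CellClassification,
    CellCounts,
)
from .design import ModelSpec
from .model import HyperParameters
from .poststrat import PostStratTable

__all__ = [
    "TrueParams",
    "calibration_scenario",
    "SparsityProfile",
    "DEFAULT_INTERCEPT",
    "draw_true_parameters",
    "default_scenario",
    "simulate_cell_counts",
    "simulate_respondents",
    "simulate_census_weights",
]

logger = logging.getLogger(__name__)

#: Default per-variable missingness rates (share of respondents),
#: matching the magnitudes seen in national health-examination data
#: (a few per thousand, completely at random).
DEFAULT_MISSINGNESS = {
    "education": 0.0022,
    "urbanicity": 0.0007,
    "occupation": 0.0034,
    "waist_cm": 0.0013,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream: one root seed, one independent stream per operation."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stream.encode())])
    )


@dataclass
class TrueParams:
    """Ground-truth parameters and the cell prevalences they imply."""

    spec: ModelSpec
    beta: np.ndarray
    tau: dict[str, float]
    sigma: float
    eta: np.ndarray  # true logit(pi) per cell

    @property
    def pi(self) -> np.ndarray:
        return special.expit(self.eta)


@dataclass
class SparsityProfile:
    """How unevenly respondents spread over cells, and missingness.

    ``concentration`` is the symmetric Dirichlet parameter for the
    cell-allocation probabilities: smaller values give a more uneven,
    sparser spread; None gives exactly equal probabilities.  The
    default 0.3 reproduces the survey's sparsity at the default total
    (median respondent count over all cells of 1, and roughly 55-60%
    of cells with zero obese respondents at typical prevalences).
    """

    total_respondents: int = 10127
    concentration: float | None = 0.3
    missingness: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS)
    )

    def __post_init__(self) -> None:
        if self.total_respondents < 0:
            raise ValueError("total_respondents must be >= 0")
        if self.concentration is not None and self.concentration <= 0:
            raise ValueError("concentration must be positive (or None for uniform)")
        for v, r in self.missingness.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"missingness rate for {v!r} must be in [0, 1]")


def draw_true_parameters(
    spec: ModelSpec,
    seed: int = 0,
    hyper: HyperParameters | None = None,
    effects: dict[str, np.ndarray | float] | None = None,
    sigma: float | None = None,
    spreads: dict[str, float] | None = None,
    center_effects: bool = False,
) -> TrueParams:
    """Draw ground-truth parameters from the model's own prior.

    ``effects`` fixes named terms' coefficient blocks instead of
    drawing them (a scalar is broadcast over the block); ``spreads``
    fixes named terms' effect standard deviations (instead of the
    prior-drawn tau or the fixed prior scale); ``sigma`` fixes the
    cell-level residual scale (0 is allowed, giving eta = x'beta
    exactly); ``center_effects`` recentres every drawn block to sum to
    zero, so the intercept alone sets the population-level prevalence.
    Everything else is drawn from the prior: tau ~
    HalfNormal(A) for hierarchical terms, beta ~ N(0, tau^2) within
    each term, eta ~ N(x'beta, sigma^2).
    """
    hyper = hyper or HyperParameters(sigma_scale=spec.sigma_scale)
    effects = effects or {}
    spreads = spreads or {}
    rng = _rng(seed, "true-params")

    tau: dict[str, float] = {}
    beta = np.zeros(spec.n_cols)
    for t in spec.terms:
        if t.name in spreads:
            scale = float(spreads[t.name])
            if scale < 0:
                raise ValueError(f"spread for term {t.name!r} must be >= 0")
            if t.is_hierarchical:
                tau[t.name] = scale
        elif t.is_hierarchical:
            if t.name in hyper.tau_fixed:
                tau[t.name] = hyper.tau_fixed[t.name]
            else:
                tau[t.name] = float(np.abs(rng.normal(0.0, t.scale)))
            scale = tau[t.name]
        else:
            scale = t.scale
        if t.name in effects:
            beta[t.cols] = np.broadcast_to(
                np.asarray(effects[t.name], float), (t.n_levels,)
            )
        else:
            draw = rng.normal(0.0, scale, size=t.n_levels)
            if center_effects and t.n_levels > 1:
                draw -= draw.mean()
            beta[t.cols] = draw

    if sigma is None:
        if hyper.sigma_fixed is not None:
            sigma = hyper.sigma_fixed
        else:
            sigma = float(np.abs(rng.normal(0.0, hyper.sigma_scale)))
    if sigma < 0:
        raise ValueError("sigma must be non-negative")

    K = spec.classification.n_cells
    m = spec.X @ beta if spec.n_cols else np.zeros(K)
    eta = m + sigma * rng.standard_normal(K) if sigma > 0 else m
    return TrueParams(spec=spec, beta=beta, tau=tau, sigma=float(sigma), eta=eta)


#: Default generator intercept: the logit of the pooled observed
#: obesity prevalence in the survey being emulated (3570 obese of
#: 10127 respondents under the Asian cutoffs, ~35%).  Drawing the
#: intercept from its wide N(0, 10^2) reporting prior would instead
#: produce populations with prevalences arbitrarily close to 0 or 1,
#: which no health survey resembles.
DEFAULT_INTERCEPT = float(special.logit(3570 / 10127))


#: Study-like effect spreads for the default scenario, on the logit
#: scale: age/education gradients of a few tenths, small interactions,
#: moderate residual cell-level heterogeneity.  These sit well inside
#: the model's prior but avoid the extreme populations (prevalence
#: ~0 or ~1 everywhere) that unconstrained prior draws can produce.
DEFAULT_SCENARIO_SPREADS = {"main": 0.4, "interaction": 0.15, "sigma": 0.3}


def calibration_scenario(spec: ModelSpec, seed: int = 0) -> TrueParams:
    """Ground truth for calibration (interval-coverage) studies.

    Every effect, tau and sigma is drawn from the model's own prior —
    the condition under which posterior credible intervals are exactly
    calibrated on average — except the intercept, which is pinned at
    the study-level prevalence so the simulated survey is informative
    rather than a population with prevalence indistinguishable from 0
    or 1.
    """
    return draw_true_parameters(
        spec, seed=seed, effects={"intercept": DEFAULT_INTERCEPT}
    )


def default_scenario(spec: ModelSpec, seed: int = 0) -> TrueParams:
    """Ground truth for the default study-scale scenario.

    The intercept is pinned at the emulated survey's pooled prevalence
    (:data:`DEFAULT_INTERCEPT`); effects are drawn independently with
    study-like spreads (:data:`DEFAULT_SCENARIO_SPREADS`): 0.4 on the
    logit scale for main effects, 0.15 for interactions, residual
    sigma 0.3.
    """
    spreads = {
        t.name: (
            DEFAULT_SCENARIO_SPREADS["interaction"]
            if len(t.factors) == 2
            else DEFAULT_SCENARIO_SPREADS["main"]
        )
        for t in spec.terms
        if t.factors
    }
    return draw_true_parameters(
        spec,
        seed=seed,
        effects={"intercept": DEFAULT_INTERCEPT},
        spreads=spreads,
        sigma=DEFAULT_SCENARIO_SPREADS["sigma"],
        center_effects=True,
    )


def _allocate_cells(
    n_cells: int, profile: SparsityProfile, rng: np.random.Generator
) -> np.ndarray:
    if profile.total_respondents == 0:
        return np.zeros(n_cells, dtype=np.int64)
    if profile.concentration is None:
        p = np.full(n_cells, 1.0 / n_cells)
    else:
        p = rng.dirichlet(np.full(n_cells, profile.concentration))
    return rng.multinomial(profile.total_respondents, p)


def sparsity_statistics(counts: CellCounts) -> dict[str, float]:
    """Empirical sparsity summary of a count table."""
    y, n = counts.y, counts.n
    nz = y[y > 0]
    return {
        "share_zero_y": float(np.mean(y == 0)),
        "median_nonzero_y": float(np.median(nz)) if len(nz) else float("nan"),
        "mean_nonzero_y": float(np.mean(nz)) if len(nz) else float("nan"),
        "median_n": float(np.median(n)),
        "mean_n": float(np.mean(n)),
    }


def simulate_cell_counts(
    true_params: TrueParams, profile: SparsityProfile | None = None, seed: int = 0
) -> CellCounts:
    """Allocate respondents over cells and draw binomial obese counts.

    n_i comes from a seeded multinomial with Dirichlet-distributed cell
    probabilities (concentration from the profile); y_i ~ Binomial(n_i,
    pi_i) at the true prevalences.  Empirical sparsity statistics are
    logged at INFO level.
    """
    profile = profile or SparsityProfile()
    classification = true_params.spec.classification
    rng = _rng(seed, "cell-counts")
    n = _allocate_cells(classification.n_cells, profile, rng)
    y = rng.binomial(n, true_params.pi)
    counts = CellCounts(classification, n, y, true_pi=true_params.pi)
    logger.info("synthetic cell counts: %s", sparsity_statistics(counts))
    return counts


# ---------------------------------------------------------------------------
# respondent-level simulation
# ---------------------------------------------------------------------------

#: Sex-specific baseline waist distributions (two-component normal
#: mixture, cm): a lean and a heavier component, giving realistic
#: right skew.  Per cell the whole mixture is location-shifted so that
#: P(waist >= threshold) equals the cell's true prevalence.
BASELINE_WAIST = {
    "female": {"w": 0.65, "m1": 74.0, "s1": 8.0, "m2": 88.0, "s2": 11.0},
    "male": {"w": 0.65, "m1": 80.0, "s1": 8.5, "m2": 95.0, "s2": 12.0},
}


def _mixture_ppf(q: float, par: dict) -> float:
    def cdf(x: float) -> float:
        return par["w"] * stats.norm.cdf(x, par["m1"], par["s1"]) + (
            1 - par["w"]
        ) * stats.norm.cdf(x, par["m2"], par["s2"])

    return optimize.brentq(lambda x: cdf(x) - q, -2000.0, 2000.0)


def _mixture_draw(rng: np.random.Generator, par: dict, size: int) -> np.ndarray:
    comp = rng.uniform(size=size) < par["w"]
    x = np.where(
        comp,
        rng.normal(par["m1"], par["s1"], size=size),
        rng.normal(par["m2"], par["s2"], size=size),
    )
    return x


def simulate_respondents(
    true_params: TrueParams,
    profile: SparsityProfile | None = None,
    standard: str = "asian",
    seed: int = 0,
) -> pd.DataFrame:
    """Generate respondent records whose tabulation matches the model.

    Waist circumference is drawn from a sex-specific two-component
    mixture, location-shifted per cell so that the exceedance
    probability over the sex's cutoff equals the cell's true
    prevalence pi_i; hence ``tabulate(records)`` is distributed as
    ``simulate_cell_counts`` output.  For the degenerate prevalences 0
    and 1 the draw is forced to the correct side of the cutoff.
    Missingness is injected completely at random at the profile's
    per-variable rates.
    """
    profile = profile or SparsityProfile()
    classification = true_params.spec.classification
    std = str(standard).lower()
    if not all(sex in BASELINE_WAIST for sex in classification.levels("sex")):
        raise ValueError("sex levels must be 'female'/'male' for waist simulation")

    rng_alloc = _rng(seed, "respondent-alloc")
    rng_waist = _rng(seed, "respondent-waist")
    rng_miss = _rng(seed, "respondent-missing")
    n = _allocate_cells(classification.n_cells, profile, rng_alloc)

    cells = classification.cells()
    pi = true_params.pi
    lo, hi = WAIST_RANGE_CM
    eps = 1e-12

    frames = []
    for i in np.flatnonzero(n):
        row = cells.iloc[i]
        sex = row["sex"]
        par = BASELINE_WAIST[sex]
        t = CUTOFFS_CM[(std, sex)]
        k = int(n[i])
        base = _mixture_draw(rng_waist, par, k)
        if pi[i] <= 0.0:
            med = _mixture_ppf(0.5, par)
            waist = t - 0.5 - np.abs(base - med)
            waist = np.clip(waist, lo, t - 0.01)
        elif pi[i] >= 1.0:
            med = _mixture_ppf(0.5, par)
            waist = t + np.abs(base - med)
            waist = np.clip(waist, t, hi)
        else:
            q = float(np.clip(1.0 - pi[i], eps, 1.0 - eps))
            shift = t - _mixture_ppf(q, par)
            waist = base + shift
            # clipping to the plausibility range never flips obesity status
            waist = np.clip(waist, lo, hi)
        rec = pd.DataFrame({c: [row[c]] * k for c in classification.factor_names})
        rec["waist_cm"] = np.round(waist, 1)
        frames.append(rec)

    if not frames:
        out = pd.DataFrame(columns=[*classification.factor_names, "waist_cm"])
        return out
    out = pd.concat(frames, ignore_index=True)
    # shuffle rows so the file looks like survey order, deterministically
    perm = _rng(seed, "respondent-order").permutation(len(out))
    out = out.iloc[perm].reset_index(drop=True)

    for v, rate in profile.missingness.items():
        if v not in out.columns or rate <= 0:
            continue
        mask = rng_miss.uniform(size=len(out)) < rate
        out.loc[mask, v] = np.nan
    return out


def simulate_census_weights(
    classification: CellClassification,
    seed: int = 0,
    dispersion: float = 0.5,
    proportions: bool = False,
    total: float = 100_000.0,
) -> PostStratTable:
    """Census-like population weights per cell.

    ``dispersion`` controls the coefficient of variation of weights
    across cells (0 gives exactly equal weights); ``proportions=True``
    normalises the weights to sum to 1, otherwise they sum to
    ``total`` person counts.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    K = classification.n_cells
    if dispersion == 0:
        w = np.full(K, 1.0 / K)
    else:
        rng = _rng(seed, "census-weights")
        shape = 1.0 / dispersion**2
        w = rng.gamma(shape, 1.0 / shape, size=K)
        w = w / w.sum()
    if not proportions:
        w = w * total
    return PostStratTable(classification, w)
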