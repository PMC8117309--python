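"""Design matrix and prior configuration for the hierarchical model.

Every term (intercept, main effect, pairwise interaction) contributes
one indicator column per level; no reference level is dropped.
Identifiability comes from the shrinkage priors, which pull each
effect block towards zero, so the model is a hierarchical ANOVA-style
decomposition rather than a classical full-rank regression.

Prior assignment follows the few-levels rule: a term with three or
fewer levels gets a fixed effect standard deviation (tau = 1, no
pooling of scale), while a term with four or more levels gets a
half-normal hyperprior on tau — scale A = 1 for main effects and
A = 0.5 for interactions, encoding the assumption that interactions
tend to be smaller than main effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classification import CellClassification

__all__ = ["Term", "ModelConfig", "ModelSpec", "build_design_matrix", "default_model_spec"]


class ModelConfigError(ValueError):
    """Raised for inconsistent model configuration."""


@dataclass(frozen=True)
class Term:
    """One block of coefficients: intercept, main effect, or interaction."""

    name: str
    factors: tuple[str, ...]  # empty for the intercept
    n_levels: int
    start: int  # first column of this term's block
    prior: str  # "fixed_normal" (tau fixed) or "halfnormal" (tau ~ N+(0, A^2))
    scale: float  # tau itself if fixed, the half-normal scale A otherwise

    @property
    def cols(self) -> slice:
        return slice(self.start, self.start + self.n_levels)

    @property
    def is_hierarchical(self) -> bool:
        return self.prior == "halfnormal"


@dataclass
class ModelConfig:
    """Which terms enter the linear predictor and how they are priced.

    Defaults reproduce the standard specification: main effects for all
    six classifying factors plus all pairwise interactions among age,
    sex, education and occupation.
    """

    main_effects: tuple[str, ...] | None = None  # None -> all factors
    interactions: tuple[tuple[str, str], ...] | None = None  # None -> default set
    intercept: bool = True
    intercept_scale: float = 10.0
    fixed_tau: float = 1.0
    fixed_tau_max_levels: int = 3
    scale_main: float = 1.0
    scale_interaction: float = 0.5
    sigma_scale: float = 1.0

    DEFAULT_INTERACTION_FACTORS = ("age_group", "sex", "education", "occupation")

    def resolve(self, classification: CellClassification) -> "ModelConfig":
        mains = self.main_effects
        if mains is None:
            mains = classification.factor_names
        inters = self.interactions
        if inters is None:
            facs = [f for f in self.DEFAULT_INTERACTION_FACTORS if f in mains]
            inters = tuple(
                (facs[i], facs[j]) for i in range(len(facs)) for j in range(i + 1, len(facs))
            )
        return ModelConfig(
            main_effects=tuple(mains),
            interactions=tuple(tuple(p) for p in inters),
            intercept=self.intercept,
            intercept_scale=self.intercept_scale,
            fixed_tau=self.fixed_tau,
            fixed_tau_max_levels=self.fixed_tau_max_levels,
            scale_main=self.scale_main,
            scale_interaction=self.scale_interaction,
            sigma_scale=self.sigma_scale,
        )


@dataclass
class ModelSpec:
    """Resolved model: term list, 0/1 design matrix, prior configuration.

    ``X`` has one row per cell of the classification.  Every row has
    exactly one 1 in each term's column block (13 ones per row under
    the default specification: intercept + 6 mains + 6 interactions).
    """

    classification: CellClassification
    terms: tuple[Term, ...]
    X: np.ndarray
    sigma_scale: float = 1.0

    @property
    def n_cols(self) -> int:
        return self.X.shape[1]

    @property
    def hierarchical_terms(self) -> tuple[Term, ...]:
        return tuple(t for t in self.terms if t.is_hierarchical)

    def term(self, name: str) -> Term:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(f"unknown term {name!r}")

    def column_labels(self) -> list[str]:
        labels: list[str] = []
        for t in self.terms:
            if not t.factors:
                labels.append("intercept")
                continue
            level_lists = [self.classification.levels(f) for f in t.factors]
            grids = np.meshgrid(*[np.arange(len(ls)) for ls in level_lists], indexing="ij")
            combos = np.stack([g.ravel() for g in grids], axis=1)
            for combo in combos:
                parts = [level_lists[j][c] for j, c in enumerate(combo)]
                labels.append(f"{t.name}[{':'.join(parts)}]")
        return labels


def build_design_matrix(
    classification: CellClassification, config: ModelConfig | None = None
) -> ModelSpec:
    """Construct the indicator design matrix and per-term priors.

    Raises
    ------
    ModelConfigError
        If a main effect or interaction references an absent factor.
    """
    config = (config or ModelConfig()).resolve(classification)
    names = classification.factor_names
    for f in config.main_effects:
        if f not in names:
            raise ModelConfigError(f"main effect references absent factor {f!r}")
    for pair in config.interactions:
        for f in pair:
            if f not in names:
                raise ModelConfigError(f"interaction references absent factor {f!r}")

    codes = classification.level_codes()
    n_cells = classification.n_cells
    terms: list[Term] = []
    blocks: list[np.ndarray] = []
    start = 0

    def add_term(name: str, factors: tuple[str, ...], cell_level: np.ndarray, k: int,
                 prior: str, scale: float) -> None:
        nonlocal start
        block = np.zeros((n_cells, k))
        block[np.arange(n_cells), cell_level] = 1.0
        terms.append(Term(name, factors, k, start, prior, scale))
        blocks.append(block)
        start += k

    def assign_prior(k: int, is_interaction: bool) -> tuple[str, float]:
        if k <= config.fixed_tau_max_levels:
            return "fixed_normal", config.fixed_tau
        return "halfnormal", (config.scale_interaction if is_interaction else config.scale_main)

    if config.intercept:
        add_term("intercept", (), np.zeros(n_cells, dtype=int), 1,
                 "fixed_normal", config.intercept_scale)
    for f in config.main_effects:
        k = len(classification.levels(f))
        prior, scale = assign_prior(k, is_interaction=False)
        add_term(f, (f,), codes[f].to_numpy(), k, prior, scale)
    for fa, fb in config.interactions:
        ka = len(classification.levels(fa))
        kb = len(classification.levels(fb))
        k = ka * kb
        level = codes[fa].to_numpy() * kb + codes[fb].to_numpy()
        prior, scale = assign_prior(k, is_interaction=True)
        add_term(f"{fa}:{fb}", (fa, fb), level, k, prior, scale)

    X = np.concatenate(blocks, axis=1) if blocks else np.zeros((n_cells, 0))
    return ModelSpec(classification, tuple(terms), X, sigma_scale=config.sigma_scale)


def default_model_spec(classification: CellClassification | None = None) -> ModelSpec:
    """Default specification on the default classification (135 columns)."""
    from .classification import default_classification

    if classification is None:
        classification = default_classification()
    return build_design_matrix(classification, ModelConfig())
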