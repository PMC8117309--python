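"""Three-layer Bayesian hierarchical binomial-logit model and its sampler.

Model
-----
Layer 1 (data):        y_i ~ Binomial(n_i, pi_i)
Layer 2 (cells):       logit(pi_i) = eta_i ~ Normal(x_i' beta, sigma^2)
Layer 3 (effects):     beta_l ~ Normal(0, tau_term^2) within each term
Hyperpriors:           tau_term ~ HalfNormal(A_term) for terms with >= 4
                       levels (A = 1 for main effects, 0.5 for
                       interactions); tau fixed at 1 for smaller terms;
                       sigma ~ HalfNormal(1); intercept ~ Normal(0, 10^2).

Cells with n_i = 0 stay in the state: their eta_i is drawn from the
prior layer given (beta, sigma), which is exactly what lets the
post-stratification step cover the full census classification.

Sampling
--------
A blocked Gibbs scheme:

* ``eta`` for observed cells — per-cell adaptive random-walk
  Metropolis (vectorised over cells; step sizes adapted only during
  burn-in so the retained chain is a valid Markov chain); empty cells
  are exact Gaussian conditional draws.
* ``beta`` — exact multivariate-normal conditional (the latent layer
  is linear-Gaussian given eta), via a Cholesky solve.
* ``tau`` per hierarchical term and ``sigma`` — univariate slice
  sampling on the log scale.

A dense-grid numerical-integration oracle (:func:`grid_posterior_oracle`)
provides ground truth for toy models with at most three free
parameters, and :func:`diagnostics` computes split R-hat / ESS through
arviz.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import linalg, special, stats

from .classification import CellClassification, CellCounts
from .design import ModelSpec, Term

__all__ = [
    "HyperParameters",
    "ParameterState",
    "McmcConfig",
    "PosteriorDraws",
    "GridConfig",
    "log_posterior",
    "fit",
    "grid_posterior_oracle",
    "diagnostics",
]

_LOG_HALFNORMAL_CONST = 0.5 * np.log(2.0 / np.pi)


class SamplingError(RuntimeError):
    pass


@dataclass
class HyperParameters:
    """Scales of the variance priors; term-level tau handling lives on the
    ModelSpec terms and can be overridden here.

    ``sigma_fixed`` pins the cell-level residual standard deviation at a
    known value (used in toy models and oracle comparisons);
    ``tau_fixed`` pins individual terms' tau by name.
    """

    sigma_scale: float = 1.0
    sigma_fixed: float | None = None
    tau_fixed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sigma_scale <= 0:
            raise ValueError("sigma_scale must be strictly positive")
        if self.sigma_fixed is not None and self.sigma_fixed <= 0:
            raise ValueError("sigma_fixed must be strictly positive")
        for name, v in self.tau_fixed.items():
            if v <= 0:
                raise ValueError(f"fixed tau for term {name!r} must be positive")

    def sampled_terms(self, spec: ModelSpec) -> tuple[Term, ...]:
        return tuple(
            t for t in spec.hierarchical_terms if t.name not in self.tau_fixed
        )


@dataclass
class ParameterState:
    """One point in parameter space: coefficients, scales, cell logits."""

    beta: np.ndarray  # (p,)
    tau: dict[str, float]  # per hierarchical term (sampled or fixed override)
    sigma: float
    eta: np.ndarray  # (n_cells,)


@dataclass
class McmcConfig:
    chains: int = 4
    iterations: int = 2000
    burn_in: int = 1000
    thinning: int = 1
    seed: int = 0
    target_accept: float = 0.44
    adapt_interval: int = 50
    rhat_threshold: float = 1.1
    ess_threshold: float = 100.0

    def __post_init__(self) -> None:
        if not self.iterations > self.burn_in >= 0:
            raise ValueError("need iterations > burn_in >= 0")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.chains < 1:
            raise ValueError("need at least one chain")


def _effective_tau(term: Term, state: ParameterState, hyper: HyperParameters) -> float:
    if term.name in hyper.tau_fixed:
        return hyper.tau_fixed[term.name]
    if term.is_hierarchical:
        return state.tau[term.name]
    return term.scale  # fixed_normal: scale IS tau


def log_posterior(
    state: ParameterState,
    counts: CellCounts,
    spec: ModelSpec,
    hyper: HyperParameters | None = None,
) -> float:
    """Unnormalised log posterior density of a full parameter state.

    Sums the binomial layer (empty cells contribute zero), the Gaussian
    latent layer, the per-term effect priors, and the half-normal
    hyperpriors on the sampled tau's and on sigma.  Returns -inf when
    any tau or sigma is negative.
    """
    hyper = hyper or HyperParameters(sigma_scale=spec.sigma_scale)
    if state.sigma < 0 or any(v < 0 for v in state.tau.values()):
        return -np.inf

    eta = np.asarray(state.eta, float)
    pi = special.expit(eta)
    lp = float(stats.binom.logpmf(counts.y, counts.n, pi).sum())

    m = spec.X @ state.beta if spec.n_cols else np.zeros_like(eta)
    sigma = hyper.sigma_fixed if hyper.sigma_fixed is not None else state.sigma
    lp += float(stats.norm.logpdf(eta, m, sigma).sum())

    for t in spec.terms:
        tau = _effective_tau(t, state, hyper)
        lp += float(stats.norm.logpdf(state.beta[t.cols], 0.0, tau).sum())
    for t in hyper.sampled_terms(spec):
        tau = state.tau[t.name]
        lp += _LOG_HALFNORMAL_CONST - np.log(t.scale) - tau**2 / (2 * t.scale**2)
    if hyper.sigma_fixed is None:
        lp += (
            _LOG_HALFNORMAL_CONST
            - np.log(hyper.sigma_scale)
            - state.sigma**2 / (2 * hyper.sigma_scale**2)
        )
    return lp


def _slice_sample(x0: float, logf, rng: np.random.Generator, w: float = 1.0,
                  max_steps: int = 50) -> float:
    """Univariate slice sampler with stepping-out (Neal 2003)."""
    logy = logf(x0) + np.log(rng.uniform())
    u = rng.uniform()
    lo, hi = x0 - w * u, x0 + w * (1 - u)
    for _ in range(max_steps):
        if logf(lo) < logy:
            break
        lo -= w
    for _ in range(max_steps):
        if logf(hi) < logy:
            break
        hi += w
    for _ in range(200):
        x1 = rng.uniform(lo, hi)
        if logf(x1) >= logy:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0  # pathological shrinkage; keep current point


def _scale_log_density(n_terms: int, ssq: float, scale: float):
    """Log density of u = log(s) where s has 'variance-like' conditional
    propto s^-n_terms * exp(-ssq / (2 s^2)) * exp(-s^2 / (2 scale^2))."""

    def logf(u: float) -> float:
        s2 = np.exp(2 * u)
        return -(n_terms - 1) * u - 0.5 * ssq / s2 - 0.5 * s2 / scale**2

    return logf


@dataclass
class PosteriorDraws:
    """Retained MCMC draws of all model quantities, per chain.

    Arrays are indexed (chain, draw, ...).  ``pi()`` returns the
    chain-pooled draws of all cell prevalences, which is what the
    post-stratification step consumes.
    """

    spec: ModelSpec
    beta: np.ndarray  # (C, S, p)
    tau: np.ndarray  # (C, S, T) for sampled hierarchical terms
    sigma: np.ndarray  # (C, S)
    eta: np.ndarray  # (C, S, n_cells)
    tau_terms: tuple[str, ...]
    config: McmcConfig

    @property
    def n_chains(self) -> int:
        return self.eta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.eta.shape[1]

    def pi(self) -> np.ndarray:
        """Pooled prevalence draws, shape (chains * draws, n_cells)."""
        c, s, k = self.eta.shape
        return special.expit(self.eta.reshape(c * s, k))

    def to_arviz(self):
        import arviz as az

        data = {
            "sigma": self.sigma,
            "eta": self.eta,
        }
        if self.beta.shape[2]:
            data["beta"] = self.beta
        if self.tau.shape[2]:
            data["tau"] = self.tau
        coords = {
            "cell": np.arange(self.eta.shape[2]),
            "coef": np.arange(self.beta.shape[2]),
            "tau_term": list(self.tau_terms),
        }
        dims = {"eta": ["cell"], "beta": ["coef"], "tau": ["tau_term"]}
        return az.from_dict(posterior=data, coords=coords, dims=dims)

    def save(self, path) -> None:
        """Persist draws as an .npz archive with a JSON metadata header."""
        meta = {
            "factors": [[n, list(ls)] for n, ls in self.spec.classification.factors],
            "tau_terms": list(self.tau_terms),
            "config": asdict(self.config),
        }
        np.savez_compressed(
            path,
            beta=self.beta,
            tau=self.tau,
            sigma=self.sigma,
            eta=self.eta,
            meta=np.array(json.dumps(meta)),
        )

    @classmethod
    def load(cls, path, spec: ModelSpec) -> "PosteriorDraws":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            return cls(
                spec=spec,
                beta=z["beta"],
                tau=z["tau"],
                sigma=z["sigma"],
                eta=z["eta"],
                tau_terms=tuple(meta["tau_terms"]),
                config=McmcConfig(**meta["config"]),
            )


def _init_eta(counts: CellCounts) -> np.ndarray:
    eta = np.zeros(counts.classification.n_cells)
    obs = counts.n > 0
    p0 = (counts.y[obs] + 0.5) / (counts.n[obs] + 1.0)
    eta[obs] = special.logit(p0)
    return eta


def _run_chain(
    counts: CellCounts,
    spec: ModelSpec,
    hyper: HyperParameters,
    config: McmcConfig,
    rng: np.random.Generator,
    chain_id: int,
):
    K = counts.classification.n_cells
    X = spec.X
    p = spec.n_cols
    XtX = X.T @ X if p else None
    y = counts.y.astype(float)
    n = counts.n.astype(float)
    obs = counts.n > 0
    n_obs = int(obs.sum())

    sampled = hyper.sampled_terms(spec)
    state = ParameterState(
        beta=np.zeros(p),
        tau={t.name: t.scale for t in spec.hierarchical_terms},
        sigma=hyper.sigma_fixed if hyper.sigma_fixed is not None else hyper.sigma_scale,
        eta=_init_eta(counts),
    )
    for name, v in hyper.tau_fixed.items():
        state.tau[name] = v

    step = np.full(n_obs, 2.4)  # RW-MH scale for observed-cell logits
    acc = np.zeros(n_obs)
    # proposal scales for the joint rescaling (interweaving) moves
    iw_step_sigma = 0.5
    iw_acc_sigma = 0.0
    iw_step_tau = {t.name: 0.5 for t in sampled}
    iw_acc_tau = {t.name: 0.0 for t in sampled}
    # per-term translation moves (beta level and its cells' logits move
    # together); columns within a term partition the cells
    term_cell_col = {
        t.name: np.argmax(X[:, t.cols], axis=1) for t in spec.terms
    } if p else {}
    tr_step = {t.name: 1.0 for t in spec.terms}
    tr_acc = {t.name: 0.0 for t in spec.terms}
    y_obs, n_obs_arr = y[obs], n[obs]

    n_keep = (config.iterations - config.burn_in + config.thinning - 1) // config.thinning
    out_beta = np.empty((n_keep, p))
    out_tau = np.empty((n_keep, len(sampled)))
    out_sigma = np.empty(n_keep)
    out_eta = np.empty((n_keep, K))
    kept = 0

    # per-term prior precision vector over columns (fixed parts constant)
    prior_prec = np.empty(p)
    for t in spec.terms:
        if not t.is_hierarchical:
            prior_prec[t.cols] = 1.0 / t.scale**2

    def binom_loglik(e: np.ndarray) -> np.ndarray:
        return y[obs] * e - n[obs] * np.logaddexp(0.0, e)

    for it in range(config.iterations):
        sigma = state.sigma
        m = X @ state.beta if p else np.zeros(K)

        # --- eta | rest ---
        e0 = state.eta[obs]
        prop = e0 + step * rng.standard_normal(n_obs)
        logr = (
            binom_loglik(prop)
            - binom_loglik(e0)
            - ((prop - m[obs]) ** 2 - (e0 - m[obs]) ** 2) / (2 * sigma**2)
        )
        accept = np.log(rng.uniform(size=n_obs)) < logr
        e0[accept] = prop[accept]
        state.eta[obs] = e0
        ne = (~obs).sum()
        if ne:
            state.eta[~obs] = m[~obs] + sigma * rng.standard_normal(ne)
        acc += accept

        if it < config.burn_in and (it + 1) % config.adapt_interval == 0:
            rate = acc / config.adapt_interval
            step *= np.exp(np.clip(rate - config.target_accept, -0.5, 0.5))
            np.clip(step, 1e-3, 25.0, out=step)
            acc[:] = 0.0

        # --- beta | eta, tau, sigma (exact Gaussian conditional) ---
        if p:
            for t in spec.hierarchical_terms:
                prior_prec[t.cols] = 1.0 / state.tau[t.name] ** 2
            A = XtX / sigma**2 + np.diag(prior_prec)
            b = X.T @ state.eta / sigma**2
            cho = linalg.cho_factor(A, lower=True)
            mean = linalg.cho_solve(cho, b)
            z = rng.standard_normal(p)
            state.beta = mean + linalg.solve_triangular(cho[0], z, lower=True, trans="T")
            m = X @ state.beta

            # --- translation (ASIS) sweep: move each effect level and
            # the logits of its cells together.  The Gaussian layer is
            # invariant (eta - m unchanged), so acceptance depends on
            # the binomial likelihood and the effect prior; this breaks
            # the stiff beta <-> eta coupling when sigma is small.
            for t in spec.terms:
                col_of = term_cell_col[t.name]
                tau_t = _effective_tau(t, state, hyper)
                delta = tr_step[t.name] * rng.standard_normal(t.n_levels)
                shift = delta[col_of]
                e_obs = state.eta[obs]
                shift_obs = shift[obs]
                dll = (
                    y_obs * shift_obs
                    - n_obs_arr * (np.logaddexp(0.0, e_obs + shift_obs) - np.logaddexp(0.0, e_obs))
                )
                dll_col = np.bincount(col_of[obs], weights=dll, minlength=t.n_levels)
                bt = state.beta[t.cols]
                dprior = ((bt**2) - (bt + delta) ** 2) / (2 * tau_t**2)
                acc_col = np.log(rng.uniform(size=t.n_levels)) < dll_col + dprior
                if acc_col.any():
                    applied = np.where(acc_col, delta, 0.0)
                    state.beta[t.cols] = bt + applied
                    state.eta += applied[col_of]
                    m += applied[col_of]
                tr_acc[t.name] += float(acc_col.mean())

        # --- tau per sampled hierarchical term (slice on log tau) ---
        for t in sampled:
            ssq = float(np.sum(state.beta[t.cols] ** 2))
            logf = _scale_log_density(t.n_levels, ssq, t.scale)
            u = _slice_sample(np.log(state.tau[t.name]), logf, rng)
            state.tau[t.name] = float(np.exp(u))

        # --- interweaved rescaling of (tau, beta-block) per term ---
        # Proposes tau' = c tau, beta' = c beta jointly; the prior-layer
        # "funnel" terms cancel analytically, so acceptance depends only
        # on how strongly eta constrains the block.  This breaks the
        # slow tau <-> beta random walk that plain Gibbs suffers from
        # when cells are sparse.
        for t in sampled:
            c = float(np.exp(iw_step_tau[t.name] * rng.standard_normal()))
            tau_old = state.tau[t.name]
            block = state.beta[t.cols]
            delta_m = (c - 1.0) * (X[:, t.cols] @ block)
            m_new = m + delta_m
            logr = (
                -0.5 * float(np.sum((state.eta - m_new) ** 2 - (state.eta - m) ** 2))
                / sigma**2
                + np.log(c)
                - (c**2 - 1.0) * tau_old**2 / (2 * t.scale**2)
            )
            if np.log(rng.uniform()) < logr:
                state.tau[t.name] = c * tau_old
                state.beta[t.cols] = c * block
                m = m_new
                iw_acc_tau[t.name] += 1.0

        # --- sigma (slice on log sigma) ---
        if hyper.sigma_fixed is None:
            ssr = float(np.sum((state.eta - m) ** 2))
            logf = _scale_log_density(K, ssr, hyper.sigma_scale)
            u = _slice_sample(np.log(state.sigma), logf, rng)
            state.sigma = float(np.exp(u))

            # interweaved rescaling of (sigma, eta residuals): eta' =
            # m + c (eta - m), sigma' = c sigma.  The Gaussian layer and
            # Jacobian cancel except for a single log c, so acceptance
            # is driven by the binomial likelihood of the observed cells.
            c = float(np.exp(iw_step_sigma * rng.standard_normal()))
            eta_new = m + c * (state.eta - m)
            logr = (
                float(np.sum(binom_loglik(eta_new[obs]) - binom_loglik(state.eta[obs])))
                + np.log(c)
                - (c**2 - 1.0) * state.sigma**2 / (2 * hyper.sigma_scale**2)
            )
            if np.log(rng.uniform()) < logr:
                state.eta = eta_new
                state.sigma = c * state.sigma
                iw_acc_sigma += 1.0

        if it < config.burn_in and (it + 1) % config.adapt_interval == 0:
            r = iw_acc_sigma / config.adapt_interval
            iw_step_sigma = float(
                np.clip(iw_step_sigma * np.exp(r - config.target_accept), 1e-2, 3.0)
            )
            iw_acc_sigma = 0.0
            for name in iw_step_tau:
                r = iw_acc_tau[name] / config.adapt_interval
                iw_step_tau[name] = float(
                    np.clip(iw_step_tau[name] * np.exp(r - config.target_accept), 1e-2, 3.0)
                )
                iw_acc_tau[name] = 0.0
            for name in tr_step:
                r = tr_acc[name] / config.adapt_interval
                tr_step[name] = float(
                    np.clip(tr_step[name] * np.exp(r - config.target_accept), 1e-2, 10.0)
                )
                tr_acc[name] = 0.0

        if not (np.isfinite(state.eta).all() and np.isfinite(state.beta).all()
                and np.isfinite(state.sigma)):
            raise SamplingError(f"non-finite state in chain {chain_id} at iteration {it}")

        if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0:
            out_beta[kept] = state.beta
            out_tau[kept] = [state.tau[t.name] for t in sampled]
            out_sigma[kept] = state.sigma
            out_eta[kept] = state.eta
            kept += 1

    return out_beta[:kept], out_tau[:kept], out_sigma[:kept], out_eta[:kept]


def fit(
    counts: CellCounts,
    spec: ModelSpec,
    hyper: HyperParameters | None = None,
    config: McmcConfig | None = None,
) -> PosteriorDraws:
    """Sample the posterior by blocked Gibbs / Metropolis-within-Gibbs.

    Identical ``(seed, config)`` produce identical draws.  Every cell's
    prevalence is represented in every draw, including empty cells.
    """
    hyper = hyper or HyperParameters(sigma_scale=spec.sigma_scale)
    config = config or McmcConfig()
    if spec.classification.n_cells != counts.classification.n_cells:
        raise ValueError("counts and spec use different classifications")

    sampled = hyper.sampled_terms(spec)
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.chains)
    chains = [
        _run_chain(counts, spec, hyper, config, np.random.default_rng(ss), c)
        for c, ss in enumerate(children)
    ]
    return PosteriorDraws(
        spec=spec,
        beta=np.stack([c[0] for c in chains]),
        tau=np.stack([c[1] for c in chains]),
        sigma=np.stack([c[2] for c in chains]),
        eta=np.stack([c[3] for c in chains]),
        tau_terms=tuple(t.name for t in sampled),
        config=config,
    )


# ---------------------------------------------------------------------------
# dense-grid oracle for toy models
# ---------------------------------------------------------------------------


@dataclass
class GridConfig:
    """Grid for the numerical-integration oracle (toy models only)."""

    n_points: int | None = None  # default: 4001 / 801 / 121 for 1 / 2 / 3 dims
    eta_lo: float = -14.0
    eta_hi: float = 14.0
    sigma_lo: float = 1e-3
    sigma_hi: float = 8.0
    free_sigma: bool = False
    beta_fixed: np.ndarray | None = None  # fixed coefficient vector (default 0)


def grid_posterior_oracle(
    counts: CellCounts,
    spec: ModelSpec,
    hyper: HyperParameters,
    grid: GridConfig | None = None,
) -> pd.DataFrame:
    """Posterior marginal quantiles by dense-grid numerical integration.

    Free parameters are the cell logits eta_1..eta_K (beta held fixed)
    plus, optionally, sigma.  Refuses models with more than three free
    parameters — the oracle exists to provide independent ground truth
    for toy models, not to replace the sampler.

    Returns a table with rows ``eta[i]``, ``pi[i]`` and optionally
    ``sigma``, each with columns mean, q2.5, q50, q97.5.
    """
    grid = grid or GridConfig()
    K = counts.classification.n_cells
    dims = K + (1 if grid.free_sigma else 0)
    if dims > 3:
        raise ValueError(f"oracle supports at most 3 free parameters, got {dims}")
    if not grid.free_sigma and hyper.sigma_fixed is None:
        raise ValueError("sigma must be fixed (hyper.sigma_fixed) or free on the grid")

    npts = grid.n_points or {1: 4001, 2: 801, 3: 121}[dims]
    beta = grid.beta_fixed
    if beta is None:
        beta = np.zeros(spec.n_cols)
    m = spec.X @ beta if spec.n_cols else np.zeros(K)

    axes = [np.linspace(grid.eta_lo, grid.eta_hi, npts) for _ in range(K)]
    names = [f"eta[{i}]" for i in range(K)]
    if grid.free_sigma:
        axes.append(np.linspace(grid.sigma_lo, grid.sigma_hi, npts))
        names.append("sigma")

    # Accumulate the log *mass* per grid cell by broadcasting.  The
    # Gaussian latent layer is integrated exactly over each eta cell
    # (CDF differences) rather than point-evaluated: the posterior has
    # an integrable ridge at sigma -> 0 that point evaluation on a
    # fixed grid cannot resolve.
    shape = [npts] * dims
    logp = np.zeros(shape)
    sigma_ax = axes[-1] if grid.free_sigma else None
    for i in range(K):
        e = axes[i]
        half = 0.5 * (e[1] - e[0])
        bshape = [1] * dims
        bshape[i] = npts
        ll = counts.y[i] * e - counts.n[i] * np.logaddexp(0.0, e)
        logp += ll.reshape(bshape)
        if grid.free_sigma:
            s = sigma_ax  # (npts,)
            z_hi = (e[:, None] + half - m[i]) / s[None, :]
            z_lo = (e[:, None] - half - m[i]) / s[None, :]
            mass = special.ndtr(z_hi) - special.ndtr(z_lo)
            with np.errstate(divide="ignore"):
                lm = np.log(mass)
            new_shape = [1] * dims
            new_shape[i] = npts
            new_shape[-1] = npts
            logp += lm.reshape(new_shape)
        else:
            s = hyper.sigma_fixed
            mass = special.ndtr((e + half - m[i]) / s) - special.ndtr((e - half - m[i]) / s)
            with np.errstate(divide="ignore"):
                logp += np.log(mass).reshape(bshape)
    if grid.free_sigma:
        s = sigma_ax.reshape([1] * (dims - 1) + [npts])
        logp += -0.5 * (s / hyper.sigma_scale) ** 2

    w = np.exp(logp - logp.max())

    rows = []
    for d, (name, ax) in enumerate(zip(names, axes)):
        marg = w.sum(axis=tuple(j for j in range(dims) if j != d))
        marg = marg / marg.sum()
        cdf = np.cumsum(marg) - 0.5 * marg
        q = np.interp([0.025, 0.5, 0.975], cdf, ax)
        mean = float(np.sum(marg * ax))
        rows.append({"parameter": name, "mean": mean,
                     "q2.5": q[0], "q50": q[1], "q97.5": q[2]})
        if name.startswith("eta"):
            i = int(name[4:-1])
            pi_ax = special.expit(ax)
            rows.append({
                "parameter": f"pi[{i}]",
                "mean": float(np.sum(marg * pi_ax)),
                "q2.5": special.expit(q[0]),
                "q50": special.expit(q[1]),
                "q97.5": special.expit(q[2]),
            })
    return pd.DataFrame(rows)


def diagnostics(
    draws: PosteriorDraws,
    rhat_threshold: float | None = None,
    ess_threshold: float | None = None,
) -> pd.DataFrame:
    """Split R-hat and effective sample size for every stored quantity.

    Parameters failing either threshold are flagged; constant
    (degenerate) chains are reported with R-hat 1 and flagged as
    degenerate rather than left undefined.  Requires at least two
    chains.
    """
    import warnings

    import arviz as az

    if draws.n_chains < 2:
        raise ValueError("diagnostics require at least 2 chains")
    rhat_threshold = rhat_threshold or draws.config.rhat_threshold
    ess_threshold = ess_threshold or draws.config.ess_threshold

    idata = draws.to_arviz()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)

    rows = []
    post = idata.posterior
    for var in post.data_vars:
        r = np.atleast_1d(np.asarray(rhat[var]))
        e = np.atleast_1d(np.asarray(ess[var]))
        vals = np.asarray(post[var])  # (C, S, ...)
        flat = vals.reshape(vals.shape[0] * vals.shape[1], -1)
        const = np.ptp(flat, axis=0) == 0.0
        labels = (
            [var] if r.size == 1 else [f"{var}[{i}]" for i in range(r.size)]
        )
        for j, label in enumerate(labels):
            rj, ej = float(r.ravel()[j]), float(e.ravel()[j])
            degen = bool(const.ravel()[j])
            if degen or not np.isfinite(rj):
                rj = 1.0
            rows.append(
                {
                    "parameter": label,
                    "rhat": rj,
                    "ess": ej,
                    "degenerate": degen,
                    "flagged": degen or rj > rhat_threshold or ej < ess_threshold,
                }
            )
    return pd.DataFrame(rows)
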