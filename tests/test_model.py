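import numpy as np
import pytest
from scipy import special, stats

import mrprev as m


@pytest.fixture(scope="module")
def toy_two_cell():
    c = m.build_classification([("cell", ["a", "b"])])
    spec = m.build_design_matrix(
        c, m.ModelConfig(main_effects=(), interactions=(), intercept=False)
    )
    counts = m.CellCounts(c, n=[5, 8], y=[2, 3])
    return spec, counts


def make_state(spec, eta, beta=None, tau=None, sigma=1.0):
    beta = np.zeros(spec.n_cols) if beta is None else np.asarray(beta, float)
    tau = tau or {t.name: t.scale for t in spec.hierarchical_terms}
    return m.ParameterState(beta=beta, tau=tau, sigma=sigma, eta=np.asarray(eta, float))


class TestLogPosterior:
    def test_single_cell_binomial_term(self):
        # n=2, y=1, eta=0: binomial pmf = C(2,1)/4 = 1/2
        c = m.build_classification([("cell", ["a"])])
        spec = m.build_design_matrix(
            c, m.ModelConfig(main_effects=(), interactions=(), intercept=False)
        )
        counts = m.CellCounts(c, n=[2], y=[1])
        hyper = m.HyperParameters(sigma_fixed=1.0)
        state = make_state(spec, [0.0], sigma=1.0)
        lp = m.log_posterior(state, counts, spec, hyper)
        # subtract the (known) latent-layer normal term to isolate the
        # binomial contribution
        latent = stats.norm.logpdf(0.0, 0.0, 1.0)
        assert lp - latent == pytest.approx(-np.log(2))

    def test_empty_cell_contributes_only_latent_layer(self):
        c = m.build_classification([("cell", ["a", "b"])])
        spec = m.build_design_matrix(
            c, m.ModelConfig(main_effects=(), interactions=(), intercept=False)
        )
        hyper = m.HyperParameters(sigma_fixed=1.0)
        counts = m.CellCounts(c, n=[2, 0], y=[1, 0])
        # moving the empty cell's eta changes only the latent normal
        # term: its binomial contribution is identically zero
        lp1 = m.log_posterior(make_state(spec, [0.3, -0.2]), counts, spec, hyper)
        lp2 = m.log_posterior(make_state(spec, [0.3, 0.9]), counts, spec, hyper)
        expected = stats.norm.logpdf(0.9, 0, 1) - stats.norm.logpdf(-0.2, 0, 1)
        assert lp2 - lp1 == pytest.approx(expected)

    def test_three_cell_independent_summation(self, small_spec):
        # independent term-by-term oracle with scipy building blocks
        c = m.build_classification([("g", ["a", "b", "c"])])
        spec = m.build_design_matrix(
            c, m.ModelConfig(main_effects=("g",), interactions=())
        )
        counts = m.CellCounts(c, n=[4, 0, 9], y=[1, 0, 5])
        rng = np.random.default_rng(8)
        beta = rng.normal(size=spec.n_cols)
        eta = rng.normal(size=3)
        state = make_state(spec, eta, beta=beta, sigma=0.7)
        hyper = m.HyperParameters(sigma_scale=1.0)

        expected = 0.0
        pi = special.expit(eta)
        for i in range(3):
            expected += stats.binom.logpmf(counts.y[i], counts.n[i], pi[i])
        mean = spec.X @ beta
        expected += stats.norm.logpdf(eta, mean, 0.7).sum()
        # effect priors: intercept N(0,10); g is a 3-level main effect
        # -> fixed tau 1
        expected += stats.norm.logpdf(beta[0], 0, 10.0)
        expected += stats.norm.logpdf(beta[1:], 0, 1.0).sum()
        # sigma ~ half-normal(1)
        expected += stats.halfnorm.logpdf(0.7, scale=1.0)
        assert m.log_posterior(state, counts, spec, hyper) == pytest.approx(expected)

    def test_negative_scales_give_minus_inf(self, toy_two_cell):
        spec, counts = toy_two_cell
        state = make_state(spec, [0.0, 0.0], sigma=-0.1)
        assert m.log_posterior(state, counts, spec) == -np.inf

    def test_invariant_under_cell_relabelling(self):
        rng = np.random.default_rng(1)
        c = m.build_classification([("g", ["a", "b", "c", "d"])])
        spec = m.build_design_matrix(
            c, m.ModelConfig(main_effects=("g",), interactions=(), intercept=False)
        )
        counts = m.CellCounts(c, n=[3, 1, 0, 6], y=[1, 0, 0, 2])
        beta = rng.normal(size=4)
        eta = rng.normal(size=4)
        tau = {"g": 0.8}
        hyper = m.HyperParameters()
        lp = m.log_posterior(
            m.ParameterState(beta, dict(tau), 0.5, eta), counts, spec, hyper
        )
        perm = np.array([2, 0, 3, 1])
        c2 = m.build_classification([("g", [c.levels("g")[i] for i in perm])])
        spec2 = m.build_design_matrix(
            c2, m.ModelConfig(main_effects=("g",), interactions=(), intercept=False)
        )
        counts2 = m.CellCounts(c2, n=counts.n[perm], y=counts.y[perm])
        lp2 = m.log_posterior(
            m.ParameterState(beta[perm], dict(tau), 0.5, eta[perm]),
            counts2,
            spec2,
            hyper,
        )
        assert lp2 == pytest.approx(lp)


class TestGridOracle:
    def test_flat_latent_limit_matches_conjugate_beta(self):
        # with a very diffuse latent prior, the posterior of pi for a
        # single cell approaches Beta(y, n-y) (the flat-on-logit limit)
        c = m.build_classification([("cell", ["a"])])
        spec = m.build_design_matrix(
            c, m.ModelConfig(main_effects=(), interactions=(), intercept=False)
        )
        counts = m.CellCounts(c, n=[20], y=[7])
        hyper = m.HyperParameters(sigma_fixed=50.0)
        table = m.grid_posterior_oracle(
            counts, spec, hyper, m.GridConfig(eta_lo=-30, eta_hi=30, n_points=8001)
        )
        row = table[table.parameter == "pi[0]"].iloc[0]
        ref = stats.beta(7, 13)
        assert row["q2.5"] == pytest.approx(ref.ppf(0.025), abs=2e-3)
        assert row["q50"] == pytest.approx(ref.ppf(0.5), abs=2e-3)
        assert row["q97.5"] == pytest.approx(ref.ppf(0.975), abs=2e-3)

    def test_symmetry_under_outcome_swap(self, toy_two_cell):
        spec, _ = toy_two_cell
        c = spec.classification
        hyper = m.HyperParameters(sigma_fixed=1.0)
        a = m.grid_posterior_oracle(
            m.CellCounts(c, n=[5, 8], y=[2, 3]), spec, hyper
        )
        b = m.grid_posterior_oracle(
            m.CellCounts(c, n=[5, 8], y=[3, 5]), spec, hyper
        )
        for i in range(2):
            ra = a[a.parameter == f"pi[{i}]"].iloc[0]
            rb = b[b.parameter == f"pi[{i}]"].iloc[0]
            assert ra["q50"] == pytest.approx(1 - rb["q50"], abs=1e-6)
            assert ra["q2.5"] == pytest.approx(1 - rb["q97.5"], abs=1e-6)

    def test_grid_refinement_stable(self, toy_two_cell):
        spec, counts = toy_two_cell
        hyper = m.HyperParameters(sigma_fixed=1.0)
        coarse = m.grid_posterior_oracle(counts, spec, hyper, m.GridConfig(n_points=401))
        fine = m.grid_posterior_oracle(counts, spec, hyper, m.GridConfig(n_points=801))
        for i in range(2):
            for q in ("q2.5", "q50", "q97.5"):
                ca = coarse[coarse.parameter == f"pi[{i}]"].iloc[0][q]
                fa = fine[fine.parameter == f"pi[{i}]"].iloc[0][q]
                assert abs(ca - fa) < 2e-3

    def test_refuses_more_than_three_dims(self):
        c = m.build_classification([("cell", ["a", "b", "c", "d"])])
        spec = m.build_design_matrix(
            c, m.ModelConfig(main_effects=(), interactions=(), intercept=False)
        )
        counts = m.CellCounts(c, n=[1] * 4, y=[0] * 4)
        with pytest.raises(ValueError, match="at most 3"):
            m.grid_posterior_oracle(counts, spec, m.HyperParameters(sigma_fixed=1.0))


class TestFit:
    def test_same_seed_bit_identical(self, toy_two_cell, tmp_path):
        spec, counts = toy_two_cell
        cfg = m.McmcConfig(chains=2, iterations=300, burn_in=100, seed=11)
        hyper = m.HyperParameters(sigma_fixed=1.0)
        a = m.fit(counts, spec, hyper, cfg)
        b = m.fit(counts, spec, hyper, cfg)
        np.testing.assert_array_equal(a.eta, b.eta)
        np.testing.assert_array_equal(a.sigma, b.sigma)
        pa, pb = tmp_path / "a.npz", tmp_path / "b.npz"
        a.save(pa)
        b.save(pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_draws_round_trip(self, toy_two_cell, tmp_path):
        spec, counts = toy_two_cell
        draws = m.fit(counts, spec, m.HyperParameters(sigma_fixed=1.0),
                      m.McmcConfig(chains=2, iterations=200, burn_in=100, seed=1))
        path = tmp_path / "draws.npz"
        draws.save(path)
        back = m.PosteriorDraws.load(path, spec)
        np.testing.assert_array_equal(back.eta, draws.eta)
        assert back.config == draws.config

    def test_half_data_concentrates_at_half(self):
        c = m.build_classification([("cell", ["a", "b"])])
        spec = m.build_design_matrix(
            c, m.ModelConfig(main_effects=(), interactions=(), intercept=False)
        )
        counts = m.CellCounts(c, n=[4000, 4000], y=[2000, 2000])
        draws = m.fit(counts, spec, m.HyperParameters(sigma_fixed=1.0),
                      m.McmcConfig(chains=2, iterations=2000, burn_in=500, seed=2))
        med = np.median(draws.pi(), axis=0)
        np.testing.assert_allclose(med, 0.5, atol=0.03)

    def test_every_cell_has_draws_including_empty(self, small_spec):
        tp = m.default_scenario(small_spec, seed=1)
        counts = m.simulate_cell_counts(
            tp, m.SparsityProfile(total_respondents=60, missingness={}), seed=1
        )
        assert (counts.n == 0).any()
        draws = m.fit(counts, small_spec,
                      config=m.McmcConfig(chains=2, iterations=400, burn_in=200, seed=3))
        assert draws.eta.shape[2] == small_spec.classification.n_cells
        assert np.isfinite(draws.pi()).all()

    def test_shrinkage_increases_as_hyper_scale_shrinks(self, small_classification):
        # posterior effect magnitudes of a hierarchical term shrink
        # monotonically (up to MC noise) as its half-normal scale A -> 0
        spec0 = m.build_design_matrix(
            small_classification, m.ModelConfig(interactions=())
        )
        tp = m.default_scenario(spec0, seed=9)
        counts = m.simulate_cell_counts(
            tp, m.SparsityProfile(total_respondents=400, missingness={}), seed=9
        )
        mags = []
        for a_scale in (1.0, 0.3, 0.05):
            spec = m.build_design_matrix(
                small_classification,
                m.ModelConfig(interactions=(), scale_main=a_scale),
            )
            draws = m.fit(
                counts, spec,
                config=m.McmcConfig(chains=2, iterations=1200, burn_in=400, seed=4),
            )
            t = spec.term("age_group")
            mags.append(float(np.mean(np.abs(draws.beta[:, :, t.cols]))))
        assert mags[2] < mags[1] < mags[0] * 1.05
        assert mags[2] < 0.5 * mags[0]


class TestDiagnostics:
    def _draws_from_eta(self, eta, spec):
        c, s, k = eta.shape
        return m.PosteriorDraws(
            spec=spec,
            beta=np.zeros((c, s, 0)),
            tau=np.zeros((c, s, 0)),
            sigma=np.ones((c, s)),
            eta=eta,
            tau_terms=(),
            config=m.McmcConfig(chains=c, iterations=s + 1, burn_in=0, seed=0),
        )

    def test_iid_chains_rhat_near_one(self, toy_two_cell):
        spec, _ = toy_two_cell
        rng = np.random.default_rng(0)
        eta = rng.normal(size=(2, 4000, 2))
        table = m.diagnostics(self._draws_from_eta(eta, spec))
        eta_rows = table[table.parameter.str.startswith("eta")]
        assert ((eta_rows.rhat > 0.99) & (eta_rows.rhat < 1.02)).all()
        assert not eta_rows.flagged.any()

    def test_shifted_chain_flagged(self, toy_two_cell):
        spec, _ = toy_two_cell
        rng = np.random.default_rng(0)
        eta = rng.normal(size=(2, 1000, 2))
        eta[1] += 10.0
        table = m.diagnostics(self._draws_from_eta(eta, spec))
        eta_rows = table[table.parameter.str.startswith("eta")]
        assert (eta_rows.rhat > 1.1).all()
        assert eta_rows.flagged.all()

    def test_constant_chain_degenerate_convention(self, toy_two_cell):
        spec, _ = toy_two_cell
        eta = np.zeros((2, 500, 2))
        table = m.diagnostics(self._draws_from_eta(eta, spec))
        eta_rows = table[table.parameter.str.startswith("eta")]
        assert (eta_rows.rhat == 1.0).all()
        assert eta_rows.degenerate.all()
        assert eta_rows.flagged.all()

    def test_single_chain_rejected(self, toy_two_cell):
        spec, counts = toy_two_cell
        draws = m.fit(counts, spec, m.HyperParameters(sigma_fixed=1.0),
                      m.McmcConfig(chains=1, iterations=200, burn_in=100, seed=0))
        with pytest.raises(ValueError, match="2 chains"):
            m.diagnostics(draws)
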