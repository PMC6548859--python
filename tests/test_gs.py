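"""Gibbs sampler: closed-form oracles, limits, invariances, prediction."""

import numpy as np
import pytest

from spudsel import gs, simulate

from .conftest import make_loci


def _toy_problem(n=20, m=10, seed=3):
    rng = np.random.default_rng(seed)
    Z = rng.choice([0, 0.25, 0.5, 0.75, 1.0], size=(n, m))
    y = Z @ rng.normal(0, 0.5, m) + rng.normal(0, 1, n)
    return Z, y


def test_pinned_variances_reproduce_ridge_solution():
    """With common fixed marker/residual variances the posterior mean of the
    effects is the ridge estimator (Zc'Zc + (s2e/s2v) I)^-1 Zc'(y - ybar)."""
    Z, y = _toy_problem()
    s2v, s2e = 0.05, 0.5
    cfg = gs.GSConfig(
        model="BayesA", n_iter=20_000, burn_in=2_000, h2_prior=0.5, seed=2,
        fix_marker_variance=s2v, fix_residual_variance=s2e,
    )
    fit = gs.fit(Z, y, cfg, keep_trace=False)
    Zc = Z - Z.mean(axis=0)
    ridge = np.linalg.solve(
        Zc.T @ Zc + (s2e / s2v) * np.eye(Z.shape[1]), Zc.T @ (y - y.mean())
    )
    assert (np.abs(fit.effects - ridge) <= 3 * fit.effect_sd).all()


def test_all_zero_markers_give_zero_effects_and_mean_intercept():
    Z = np.zeros((15, 4))
    rng = np.random.default_rng(0)
    y = rng.normal(10, 1, 15)
    cfg = gs.GSConfig(n_iter=2_000, burn_in=500, seed=1)
    with pytest.warns(UserWarning, match="zero-variance"):
        fit = gs.fit(Z, y, cfg, keep_trace=False)
    assert np.array_equal(fit.effects, np.zeros(4))
    assert fit.mu == pytest.approx(y.mean(), abs=3 * np.std(y) / np.sqrt(15))


def test_chain_is_seed_deterministic():
    Z, y = _toy_problem()
    cfg = gs.GSConfig(model="BayesB", prob_in=0.1, n_iter=800, burn_in=100, seed=9)
    a = gs.fit(Z, y, cfg, keep_trace=False)
    b = gs.fit(Z, y, cfg, keep_trace=False)
    assert np.array_equal(a.effects, b.effects)
    assert a.mu == b.mu and a.var_e == b.var_e


def test_scale_equivariance_in_y():
    Z, y = _toy_problem()
    cfg = gs.GSConfig(n_iter=1_500, burn_in=300, seed=4)
    base = gs.fit(Z, y, cfg, keep_trace=False)
    scaled = gs.fit(Z, 10.0 * y, cfg, keep_trace=False)
    assert scaled.mu == pytest.approx(10.0 * base.mu, rel=1e-9)
    np.testing.assert_allclose(scaled.effects, 10.0 * base.effects, rtol=1e-9)


def test_variance_trace_stays_positive():
    Z, y = _toy_problem()
    cfg = gs.GSConfig(n_iter=1_000, burn_in=100, seed=5)
    fit = gs.fit(Z, y, cfg)
    assert (fit.trace["var_e"] > 0).all()


def test_bayesb_at_prob_in_one_matches_bayesa():
    rng = np.random.default_rng(7)
    Z = rng.choice([0, 0.25, 0.5, 0.75, 1.0], size=(30, 20))
    y = Z @ rng.normal(0, 0.5, 20) + rng.normal(0, 1, 30)
    common = dict(n_iter=12_000, burn_in=2_000, h2_prior=0.5)
    fa = gs.fit(Z, y, gs.GSConfig(model="BayesA", seed=1, **common), keep_trace=False)
    fb = gs.fit(
        Z, y, gs.GSConfig(model="BayesB", prob_in=1.0, seed=2, **common),
        keep_trace=False,
    )
    mc = 3 * np.sqrt(fa.effect_sd**2 + fb.effect_sd**2) / np.sqrt(500)  # ~ESS
    assert (np.abs(fa.effects - fb.effects) <= np.maximum(mc, 0.02)).all()
    assert (fb.inclusion_prob == 1.0).all()


def test_bayesb_concentrates_on_true_qtl():
    hits = 0
    for seed in range(10):
        truth = simulate.simulate_cohort(300, 200, seed=seed, h2_target=0.75)
        ph = simulate.simulate_phenotypes(
            truth, architecture="sparse", n_qtl=2, seed=seed + 100, h2=0.75
        )
        qtl = np.flatnonzero(ph.trait_effects["trait"] != 0)
        y = ph.values_for("trait", truth.true_dosage.samples)
        cfg = gs.GSConfig(
            model="BayesB", prob_in=0.01, n_iter=4_000, burn_in=1_000,
            h2_prior=0.75, seed=seed,
        )
        fit = gs.fit(truth.true_dosage.codes, y, cfg, keep_trace=False)
        top = np.argsort(fit.effects_sq)[::-1][:10]  # top 5% of 200
        Z = truth.true_dosage.codes
        found_all = True
        for q in qtl:
            r2 = max(np.corrcoef(Z[:, q], Z[:, c])[0, 1] ** 2 for c in top)
            found_all &= (q in top) or r2 > 0.8
        hits += found_all
    assert hits >= 8


class TestPredict:
    def test_noiseless_trait_recovered_on_training_data(self):
        truth = simulate.simulate_cohort(400, 100, seed=2)
        ph = simulate.simulate_phenotypes(truth, seed=3, h2=1.0)
        y = ph.values_for("trait", truth.true_dosage.samples)
        cfg = gs.GSConfig(n_iter=3_000, burn_in=500, h2_prior=0.9, seed=1)
        fit = gs.fit(truth.true_dosage.codes, y, cfg, keep_trace=False)
        gebv = gs.predict(fit, truth.true_dosage.codes)
        assert np.corrcoef(gebv, y)[0, 1] > 0.99

    def test_zero_effects_predict_constant_mu(self):
        Z, y = _toy_problem()
        cfg = gs.GSConfig(n_iter=500, burn_in=100, seed=0)
        fit = gs.fit(Z, y, cfg, keep_trace=False)
        fit.effects[:] = 0.0
        assert np.allclose(gs.predict(fit, Z), fit.mu)

    def test_duplicated_sample_row_duplicates_gebv(self):
        Z, y = _toy_problem()
        cfg = gs.GSConfig(n_iter=500, burn_in=100, seed=0)
        fit = gs.fit(Z, y, cfg, keep_trace=False)
        doubled = np.vstack([Z, Z[:1]])
        gebv = gs.predict(fit, doubled)
        assert gebv[-1] == gebv[0]

    def test_marker_mismatch_listed(self):
        Z, y = _toy_problem(m=4)
        loci = make_loci(4)
        cfg = gs.GSConfig(n_iter=300, burn_in=50, seed=0)
        fit = gs.fit(Z, y, cfg, loci=loci, keep_trace=False)
        with pytest.raises(ValueError, match="absent"):
            gs.predict(fit, Z[:, :3], loci=loci.iloc[:3])


def test_manhattan_table_squares_and_sorts():
    Z, y = _toy_problem(m=6)
    loci = make_loci(6)
    loci["pos"] = [600, 100, 500, 200, 400, 300]  # scrambled coordinates
    cfg = gs.GSConfig(n_iter=500, burn_in=100, seed=0)
    fit = gs.fit(Z, y, cfg, loci=loci, keep_trace=False)
    fit.effects[:] = [-0.3, 0.1, 0.2, 0.0, -0.1, 0.05]
    table = gs.manhattan_table(fit)
    assert len(table) == 6
    assert table["pos"].is_monotonic_increasing
    row = table.loc[table["pos"] == 600].iloc[0]
    assert row["effect_sq"] == pytest.approx(0.09)


def test_config_validation():
    with pytest.raises(ValueError):
        gs.GSConfig(model="BayesC")
    with pytest.raises(ValueError):
        gs.GSConfig(burn_in=100, n_iter=100)
    with pytest.raises(ValueError):
        gs.GSConfig(prob_in=0.0, model="BayesB")
    with pytest.raises(ValueError):
        gs.GSConfig(h2_prior=0.0)
    Z, y = _toy_problem()
    with pytest.raises(ValueError, match="constant"):
        gs.fit(Z, np.ones(len(y)), gs.GSConfig(n_iter=10, burn_in=1))
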