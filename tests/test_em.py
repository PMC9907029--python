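"""Constrained EM: initialization, convergence, recovery, GMM oracle."""

import dataclasses

import numpy as np
import pytest

from centimix import (
    FitConfig,
    GeneratorPreset,
    MixtureParams,
    dpms_preset,
    fit_em,
    generate_cohort,
    pnhs_preset,
    random_init,
)
from conftest import resized


def test_random_init_is_deterministic(dpms_cohort):
    a = random_init(dpms_cohort, 13)
    b = random_init(dpms_cohort, 13)
    assert a == b
    assert a != random_init(dpms_cohort, 14)


def test_random_init_satisfies_invariants_over_many_draws(dpms_cohort):
    cfg = FitConfig()
    x = dpms_cohort["centiloid"].to_numpy()
    med = float(np.median(x))
    for seed in range(1000):
        p = random_init(dpms_cohort, seed, cfg)
        assert p.mu_neg < p.mu_pos
        assert p.sigma_neg >= cfg.sigma_floor and p.sigma_pos >= cfg.sigma_floor
        assert p.pi_neg + p.pi_int + p.pi_pos == pytest.approx(1.0)
        assert x.min() <= p.mu_neg <= med
        assert med <= p.mu_pos <= x.max()


def test_random_init_respects_sample_range():
    rng = np.random.default_rng(0)
    x = np.concatenate([[-10.0, 120.0], rng.uniform(-10, 120, 98)])
    med = float(np.median(x))
    for seed in range(300):
        p = random_init(x, seed)
        assert -10.0 <= p.mu_neg <= med
        assert med <= p.mu_pos <= 120.0


def test_random_init_rejects_degenerate_data():
    with pytest.raises(ValueError, match="identical"):
        random_init(np.full(50, 7.0), 0)
    with pytest.raises(ValueError, match=">= 10"):
        random_init(np.arange(5.0), 0)


def test_absent_intermediate_component_shrinks():
    # data from two well-separated pure Gaussians: fitted pi_int ~ 0
    params = MixtureParams(0.5, 0.0, 0.5, mu_neg=0.0, mu_pos=100.0,
                           sigma_neg=5.0, sigma_pos=5.0)
    cohort = generate_cohort(GeneratorPreset("pure", params, n=2000), seed=21)
    fit = fit_em(cohort, FitConfig(seed=21))
    assert fit.converged
    assert fit.params.pi_int <= 0.02


@pytest.mark.parametrize("seed", [3, 17])
def test_loglik_trace_non_decreasing_within_slack(seed):
    # the tied M-step is not textbook EM, so ascent is monitored rather
    # than taken on faith; violations beyond 1e-8 relative slack are
    # counted by the fitter itself
    cohort = generate_cohort(dpms_preset(), seed=seed)
    fit = fit_em(cohort, FitConfig(seed=seed))
    assert fit.monotone_violations == 0
    diffs = np.diff(fit.loglik_trace)
    assert np.all(diffs >= -1e-8 * np.maximum(1.0, np.abs(fit.loglik_trace[:-1])))


def test_responsibilities_sum_to_one(dpms_fit):
    sums = dpms_fit.responsibilities.sum(axis=1)
    np.testing.assert_allclose(sums, 1.0, atol=1e-9)
    pis = (dpms_fit.params.pi_neg, dpms_fit.params.pi_int, dpms_fit.params.pi_pos)
    assert sum(pis) == pytest.approx(1.0, abs=1e-9)


def test_canonical_ordering_always_holds():
    for seed in range(5):
        cohort = generate_cohort(resized(pnhs_preset(), 400), seed=seed)
        fit = fit_em(cohort, FitConfig(seed=seed, n_starts=2))
        assert fit.params.mu_neg < fit.params.mu_pos


def test_two_component_mode_matches_sklearn_gmm(dpms_cohort):
    from sklearn.mixture import GaussianMixture

    x = dpms_cohort["centiloid"].to_numpy()
    cfg = FitConfig(include_intermediate=False, seed=5, n_starts=8, rel_tol=1e-9)
    fit = fit_em(x, cfg)
    gm = GaussianMixture(n_components=2, n_init=10, tol=1e-7, random_state=5,
                         max_iter=1000).fit(x[:, None])
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    weights = gm.weights_[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    assert fit.params.mu_neg == pytest.approx(means[0], abs=0.5)
    assert fit.params.mu_pos == pytest.approx(means[1], abs=0.5)
    assert fit.params.pi_pos == pytest.approx(weights[1], abs=0.02)
    assert fit.params.sigma_neg == pytest.approx(sds[0], abs=0.5)
    assert fit.params.pi_int == 0.0


def test_two_component_loglik_equals_plain_gmm_loglik(dpms_cohort):
    # with pi_int = 0 the three-part density IS the two-component GMM
    from scipy.stats import norm

    from centimix import log_likelihood

    params = MixtureParams(0.6, 0.0, 0.4, mu_neg=1.0, mu_pos=90.0,
                           sigma_neg=8.0, sigma_pos=25.0)
    x = dpms_cohort["centiloid"].to_numpy()
    direct = np.sum(np.log(0.6 * norm.pdf(x, 1.0, 8.0) + 0.4 * norm.pdf(x, 90.0, 25.0)))
    assert log_likelihood(x, params) == pytest.approx(direct, abs=1e-8)
    assert log_likelihood(x, params, FitConfig(include_intermediate=False)) == pytest.approx(direct, abs=1e-8)


@pytest.mark.parametrize("preset_fn", [dpms_preset, pnhs_preset])
def test_parameter_recovery_at_large_n(preset_fn):
    """Fitted parameters approach the generating values at n=10,000.

    Tolerances reflect what the tied model can identify: the mixel
    density at mixing fractions near 0/1 mimics the pure Gaussians, so
    the intermediate proportion and the positive mean sit on a flat
    likelihood ridge and recover more loosely than the well-identified
    negative component.
    """
    preset = resized(preset_fn(), 10000)
    truth = preset.params
    cohort = generate_cohort(preset, seed=2)
    fit = fit_em(cohort, FitConfig(seed=2))
    assert fit.converged
    assert fit.params.mu_neg == pytest.approx(truth.mu_neg, abs=1.0)
    assert fit.params.mu_pos == pytest.approx(truth.mu_pos, abs=3.0)
    for name in ("pi_neg", "pi_int", "pi_pos"):
        assert getattr(fit.params, name) == pytest.approx(getattr(truth, name), abs=0.04)
    for name in ("sigma_neg", "sigma_pos"):
        assert getattr(fit.params, name) == pytest.approx(getattr(truth, name), rel=0.15)


def test_sigma_floor_clamp_is_reported_not_fatal():
    # a tight cluster plus outliers provokes collapse onto the cluster
    rng = np.random.default_rng(0)
    x = np.concatenate([np.full(200, 0.0) + rng.normal(0, 1e-4, 200),
                        rng.normal(90, 20, 50)])
    fit = fit_em(x, FitConfig(seed=0, n_starts=3))
    assert fit.params.sigma_neg >= 0.5
    assert fit.n_sigma_clamps > 0
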