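"""Bootstrap inference: percentile intervals, reproducibility, overlap."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from centimix import (
    FitConfig,
    PARAM_NAMES,
    bootstrap_fit,
    compare_strata,
    dpms_preset,
    generate_cohort,
    percentile_ci,
    pnhs_preset,
)
from conftest import resized


def test_percentile_ci_linear_interpolation_oracle():
    # 1..100 at level 0.95: positions 2.475 and 97.525 on the sorted scale
    lo, hi = percentile_ci(np.arange(1.0, 101.0), 0.95)
    assert lo == pytest.approx(3.475)
    assert hi == pytest.approx(97.525)


def test_percentile_ci_single_sample():
    assert percentile_ci([7.0]) == (7.0, 7.0)


def test_percentile_ci_rejects_empty_and_bad_level():
    with pytest.raises(ValueError):
        percentile_ci([])
    with pytest.raises(ValueError):
        percentile_ci([1.0], level=1.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    samples=st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=60),
    seed=st.integers(0, 2**16),
)
def test_percentile_ci_permutation_invariant_and_ordered(samples, seed):
    arr = np.array(samples)
    lo, hi = percentile_ci(arr)
    assert lo <= hi
    shuffled = np.random.default_rng(seed).permutation(arr)
    assert percentile_ci(shuffled) == (lo, hi)
    assert arr.min() <= lo and hi <= arr.max()


@pytest.fixture(scope="module")
def small_cohort():
    return generate_cohort(resized(dpms_preset(), 300), seed=31)


def test_small_b_percentiles_match_hand_sorted_oracle(small_cohort):
    cfg = FitConfig(seed=31, n_starts=1)
    summary = bootstrap_fit(small_cohort, B=3, config=cfg, seed=31)
    assert summary.B_succeeded == 3
    for j, name in enumerate(PARAM_NAMES):
        v = np.sort(summary.replicates[:, j])
        # linear interpolation at rank positions 0.025*(B-1), 0.975*(B-1)
        def q(p):
            pos = p * (len(v) - 1)
            i = int(np.floor(pos))
            frac = pos - i
            return v[i] + frac * (v[min(i + 1, len(v) - 1)] - v[i])
        assert summary.ci[name][0] == pytest.approx(q(0.025), abs=1e-12)
        assert summary.ci[name][1] == pytest.approx(q(0.975), abs=1e-12)


def test_disabled_resampling_collapses_intervals(small_cohort):
    # test hook: no resampling and no re-initialization -> every replicate
    # repeats the point fit, so lower = upper = point for all parameters
    cfg = FitConfig(seed=31, n_starts=2)
    summary = bootstrap_fit(small_cohort, B=5, config=cfg, seed=31,
                            resample=False, reinit=False)
    point = summary.point.as_dict()
    for name in PARAM_NAMES:
        lo, hi = summary.ci[name]
        assert lo == pytest.approx(point[name], abs=1e-12)
        assert hi == pytest.approx(point[name], abs=1e-12)


def test_bootstrap_is_deterministic(small_cohort):
    cfg = FitConfig(seed=5, n_starts=2)
    a = bootstrap_fit(small_cohort, B=20, config=cfg, seed=5)
    b = bootstrap_fit(small_cohort, B=20, config=cfg, seed=5)
    assert a.as_dict() == b.as_dict()
    np.testing.assert_array_equal(a.replicates, b.replicates)


def test_replicates_always_canonically_ordered(small_cohort):
    summary = bootstrap_fit(small_cohort, B=30, config=FitConfig(seed=8), seed=8)
    mu_neg = summary.replicates[:, PARAM_NAMES.index("mu_neg")]
    mu_pos = summary.replicates[:, PARAM_NAMES.index("mu_pos")]
    assert np.all(mu_neg < mu_pos)
    for name in PARAM_NAMES:
        lo, hi = summary.ci[name]
        assert lo <= hi
    assert summary.B_succeeded <= summary.B_requested


def test_ci_width_shrinks_with_sample_size():
    cfg = FitConfig(seed=2)
    widths = {}
    for n in (300, 3000):
        cohort = generate_cohort(resized(dpms_preset(), n), seed=2)
        s = bootstrap_fit(cohort, B=60, config=cfg, seed=2)
        lo, hi = s.ci["mu_neg"]
        widths[n] = hi - lo
    assert widths[3000] < widths[300]


def test_bootstrap_rejects_invalid_b(small_cohort):
    with pytest.raises(ValueError):
        bootstrap_fit(small_cohort, B=0, config=FitConfig(), seed=1)


def test_compare_strata_identical_summaries_overlap(small_cohort):
    s = bootstrap_fit(small_cohort, B=10, config=FitConfig(seed=3), seed=3)
    verdict = compare_strata(s, s)
    assert verdict["overall"] is True
    assert all(verdict[name] for name in PARAM_NAMES)


def test_compare_strata_disjoint_interval_fails_overall(small_cohort):
    s = bootstrap_fit(small_cohort, B=10, config=FitConfig(seed=3), seed=3)
    other = dataclasses.replace(s)
    other.ci = dict(s.ci)
    other.ci["mu_neg"] = (s.ci["mu_neg"][1] + 10.0, s.ci["mu_neg"][1] + 20.0)
    verdict = compare_strata(s, other)
    assert verdict["mu_neg"] is False
    assert verdict["overall"] is False
    # symmetry in the arguments
    assert compare_strata(other, s) == verdict


def test_compare_strata_rejects_mismatched_model_configs(small_cohort):
    a = bootstrap_fit(small_cohort, B=5, config=FitConfig(seed=3), seed=3)
    b = bootstrap_fit(small_cohort, B=5,
                      config=FitConfig(seed=3, include_intermediate=False), seed=3)
    with pytest.raises(ValueError, match="different model configs"):
        compare_strata(a, b)
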