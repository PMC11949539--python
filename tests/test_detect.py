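"""Windowed stability detector vs an independent brute-force window scan."""

import math

import numpy as np
import pytest

from prevstab import PrevalenceCurve, StabilityParams, detect_stability

from conftest import noisy_curve


def curve_of(means, group="g", species="s"):
    means = np.asarray(means, dtype=float)
    return PrevalenceCurve(
        group=group, species=species, k_max=means.size, means=means,
        observed_prevalence=float(means[-1]), n_replicates=1,
    )


def oracle_scan(means, x, y, z, sqrt_index="later", window="means", report_point="window_end"):
    """Independently written exhaustive window scan (pure python)."""
    wlen = x if window == "means" else x + 1
    K = len(means)
    for s in range(1, K - wlen + 2):  # 1-based window start
        w = [means[i - 1] for i in range(s, s + wlen)]
        ok = True
        for i in range(1, wlen):
            k_later = s + i
            k_corr = k_later if sqrt_index == "later" else k_later - 1
            if not abs(w[i] - w[i - 1]) < y / math.sqrt(k_corr):
                ok = False
                break
        if ok and (max(w) - min(w)) < z:
            return s + wlen - 1 if report_point == "window_end" else s
    return None


def test_constant_curve_stabilises_at_first_window(default_params):
    res = detect_stability(curve_of(np.full(30, 50.0)), default_params)
    assert res.stability_point == 10  # first window spans k = 1..10
    assert res.estimated_prevalence == 50.0
    assert res.window_delta == 0.0
    assert res.tail_prevalence == 50.0


def test_short_curve_yields_na(default_params):
    res = detect_stability(curve_of([50, 50, 51, 50, 50]), default_params)
    assert res.is_na
    assert math.isnan(res.estimated_prevalence)
    assert "window" in res.note


def test_deterministic_hyperbolic_curve_matches_oracle(default_params):
    m = 50 + 10 / np.arange(1, 31)
    res = detect_stability(curve_of(m), default_params)
    expected = oracle_scan(m, 10, 2.0, 1.0)
    assert res.stability_point == expected == 16
    assert res.estimated_prevalence == m[15]


@pytest.mark.parametrize("seed", range(12))
@pytest.mark.parametrize(
    "options",
    [
        {},
        {"sqrt_index": "earlier"},
        {"window": "differences"},
        {"report_point": "window_start"},
    ],
    ids=["default", "earlier-index", "diff-window", "start-report"],
)
def test_detector_equals_brute_force_on_noisy_curves(seed, options):
    m = noisy_curve(seed, k_max=20 + 5 * seed, scale=2.0 + seed % 3)
    params = StabilityParams(successive_points=5 + seed % 6, seed=None)
    res = detect_stability(curve_of(m), params, **options)
    expected = oracle_scan(
        m, params.successive_points, params.mean_diff_threshold,
        params.delta_threshold, **options,
    )
    assert res.stability_point == expected


def test_threshold_comparisons_are_strict():
    # at k = 4 the correction sqrt(k) = 2 is exact, so y = 1.0 puts the
    # threshold exactly at the difference 0.5: ties must fail
    m = curve_of([0.0, 100.0, 50.0, 50.5])
    tie = StabilityParams(successive_points=2, mean_diff_threshold=1.0, delta_threshold=2.0)
    above = StabilityParams(successive_points=2, mean_diff_threshold=1.02, delta_threshold=2.0)
    assert detect_stability(m, tie).is_na
    assert detect_stability(m, above).stability_point == 4
    # window range exactly at z must fail too
    pz = StabilityParams(successive_points=2, mean_diff_threshold=100.0, delta_threshold=0.5)
    assert detect_stability(curve_of([50.0, 50.5]), pz).is_na
    assert detect_stability(curve_of([50.0, 50.4]), pz).stability_point == 2


def _point_or_inf(res):
    return math.inf if res.stability_point is None else res.stability_point


@pytest.mark.parametrize("seed", range(8))
def test_stability_point_monotone_in_window_length(seed):
    """Longer windows can only delay stability: a qualifying long window
    implies its leading sub-window qualifies."""
    m = curve_of(noisy_curve(seed, k_max=60, scale=4.0))
    points = [
        _point_or_inf(detect_stability(m, StabilityParams(successive_points=x)))
        for x in (2, 5, 10, 20)
    ]
    assert points == sorted(points)


@pytest.mark.parametrize("seed", range(8))
def test_stability_point_monotone_in_thresholds(seed):
    """Decreasing y or z (stricter flatness) never decreases the stability point."""
    m = curve_of(noisy_curve(seed, k_max=60, scale=4.0))
    for ys, zs in [((4.0, 2.0, 1.0, 0.5), (1.0,)), ((2.0,), (2.0, 1.0, 0.5, 0.25))]:
        pts = [
            _point_or_inf(
                detect_stability(
                    m, StabilityParams(mean_diff_threshold=y, delta_threshold=z)
                )
            )
            for y in ys
            for z in zs
        ]
        assert pts == sorted(pts)


def test_accepted_window_delta_is_below_threshold(default_params):
    for seed in range(6):
        res = detect_stability(curve_of(noisy_curve(seed, k_max=80, scale=2.0)), default_params)
        if res.stability_point is not None:
            assert res.window_delta < default_params.delta_threshold
            assert 1 <= res.stability_point <= 80


def test_params_validation():
    with pytest.raises(ValueError):
        StabilityParams(n_replicates=0)
    with pytest.raises(ValueError):
        StabilityParams(successive_points=1)
    with pytest.raises(ValueError):
        StabilityParams(mean_diff_threshold=0.0)
    with pytest.raises(ValueError):
        StabilityParams(delta_threshold=-1.0)
    assert StabilityParams() == StabilityParams(50, 10, 2.0, 1.0, None)
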