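"""Take-off Cq calling and the three efficiency estimators."""

import numpy as np
import pytest

from splicequant.cq import (
    ExponentialWindowError,
    NoExponentialPhaseError,
    StandardCurvePoint,
    cq_slope_efficiency,
    fit_baseline,
    fit_standard_curve,
    linreg_efficiency,
    mean_efficiency,
    takeoff_cq,
    EfficiencyEstimate,
    EfficiencyMethod,
)
from splicequant.io import FluorescenceCurve
from splicequant.simulate import AmpSimConfig, simulate_amplification


def brute_force_takeoff(curve, fraction=0.2):
    """Independent oracle: raw second-difference scan, no smoothing."""
    f = curve.fluorescence
    d2 = f[2:] - 2 * f[1:-1] + f[:-2]
    cc = curve.cycles[1:-1]
    i = int(np.argmax(d2))
    thr = fraction * d2[i]
    for k in range(i, -1, -1):
        if d2[k] < thr:
            lo, hi = d2[k], d2[k + 1]
            t = (np.log(thr) - np.log(lo)) / (np.log(hi) - np.log(lo))
            return cc[k] + t
    return cc[0]


@pytest.mark.parametrize("efficiency", [1.7, 1.8, 1.9, 2.0])
def test_takeoff_matches_brute_force_scan(efficiency):
    curve = simulate_amplification(AmpSimConfig(efficiency_true=efficiency))
    est = takeoff_cq(curve)
    assert abs(est.cq - brute_force_takeoff(curve)) <= 0.1
    assert curve.cycles[0] <= est.cq <= curve.cycles[-1]


def test_flat_curve_has_no_exponential_phase():
    curve = FluorescenceCurve("flat", np.arange(1, 41), np.ones(40))
    with pytest.raises(NoExponentialPhaseError):
        takeoff_cq(curve)


def test_takeoff_shift_equivariance():
    """5 extra pre-takeoff cycles (template / E^5) shift the call by 5.0."""
    base = takeoff_cq(simulate_amplification(AmpSimConfig())).cq
    shifted = takeoff_cq(
        simulate_amplification(AmpSimConfig(n0=1e4 * 1.9**-5))
    ).cq
    assert shifted - base == pytest.approx(5.0, abs=0.1)


def test_takeoff_monotone_in_template():
    cqs = [
        takeoff_cq(simulate_amplification(AmpSimConfig(n0=n0))).cq
        for n0 in (1e3, 1e4, 1e5, 1e6)
    ]
    assert all(a > b for a, b in zip(cqs, cqs[1:]))


@pytest.mark.parametrize("efficiency", [1.7, 1.8, 1.9, 2.0])
def test_efficiency_recovery_noiseless(efficiency):
    """All curve-based estimators recover the true E within 0.02."""
    curve = simulate_amplification(AmpSimConfig(efficiency_true=efficiency))
    cq = takeoff_cq(curve)
    e_slope = cq_slope_efficiency(curve, cq)
    e_linreg = linreg_efficiency(curve)
    assert e_slope.efficiency == pytest.approx(efficiency, abs=0.02)
    assert e_linreg.efficiency == pytest.approx(efficiency, abs=0.02)
    assert abs(e_slope.efficiency - e_linreg.efficiency) <= 0.05
    assert not e_slope.flag_out_of_range


def test_perfect_doubling_curve():
    curve = simulate_amplification(AmpSimConfig(efficiency_true=2.0))
    e = cq_slope_efficiency(curve, takeoff_cq(curve))
    assert e.efficiency == pytest.approx(2.0, abs=0.01)
    lr = linreg_efficiency(curve)
    assert lr.efficiency == pytest.approx(2.0, abs=0.01)
    assert round(lr.fit_r2, 3) == 1.0


def test_super_doubling_artifact_is_flagged():
    """A dye-distorted curve rising faster than doubling flags E > 2."""
    cycles = np.arange(1, 41, dtype=float)
    n = 1e3 * 2.25**cycles
    flu = 2.0 + 1e-10 * np.minimum(n, 1e12)
    curve = FluorescenceCurve("hot", cycles, flu)
    e = cq_slope_efficiency(curve, takeoff_cq(curve))
    assert e.efficiency > 2.0
    assert e.flag_out_of_range


def test_exponential_window_too_short():
    cycles = np.arange(1, 21, dtype=float)
    flu = np.ones(20)
    flu[-3:] = [5.0, 50.0, 500.0]  # rise with almost no usable window
    curve = FluorescenceCurve("late", cycles, flu)
    with pytest.raises((ExponentialWindowError, NoExponentialPhaseError)):
        cq_slope_efficiency(curve, takeoff_cq(curve))


def test_baseline_recovers_true_offset():
    curve = simulate_amplification(AmpSimConfig(baseline_offset=3.7))
    fit = fit_baseline(curve)
    assert fit.offset == pytest.approx(3.7, abs=0.01)


def test_linreg_noisy_replicates_recover_truth():
    """Replicate mean E on mildly noisy curves (0.5 % of plateau)."""
    estimates = [
        linreg_efficiency(
            simulate_amplification(
                AmpSimConfig(efficiency_true=1.85, noise_sd=0.005, seed=300 + s)
            )
        ).efficiency
        for s in range(9)
    ]
    assert np.mean(estimates) == pytest.approx(1.85, abs=0.05)


def test_linreg_requires_log_linear_phase():
    rng = np.random.default_rng(1)
    cycles = np.arange(1, 41, dtype=float)
    flu = 10.0 + cycles * 0.8 + rng.normal(0, 0.3, 40)  # linear, not exponential
    curve = FluorescenceCurve("lin", cycles, flu)
    with pytest.raises(NoExponentialPhaseError):
        linreg_efficiency(curve)


def test_standard_curve_perfect_doubling_dilutions():
    points = [
        StandardCurvePoint(lg, cq)
        for lg, cq in [
            (8, 10.0),
            (7, 13.3219),
            (6, 16.6439),
            (5, 19.9658),
            (4, 23.2877),
            (3, 26.6096),
        ]
    ]
    fit = fit_standard_curve(points)
    assert fit.slope_m == pytest.approx(-3.3219, abs=0.0005)
    assert fit.efficiency == pytest.approx(2.000, abs=0.001)
    assert round(fit.r2, 4) == 1.0
    assert not fit.inverted_slope


def test_standard_curve_slope_to_efficiency():
    # E = 10^(1/3.6) for a -3.6 slope
    points = [StandardCurvePoint(lg, 40 - 3.6 * lg) for lg in (3, 4, 5, 6)]
    fit = fit_standard_curve(points)
    assert fit.efficiency == pytest.approx(1.895, abs=0.001)


def test_standard_curve_needs_three_levels():
    points = [StandardCurvePoint(3, 26.0), StandardCurvePoint(4, 23.0)]
    with pytest.raises(ValueError):
        fit_standard_curve(points)


def test_standard_curve_inverted_labels_flagged():
    points = [StandardCurvePoint(lg, 10 + 3.3 * lg) for lg in (3, 4, 5)]
    assert fit_standard_curve(points).inverted_slope


def test_mean_efficiency_average_identity_and_mixing():
    ests = [
        EfficiencyEstimate(f"w{i}", e, EfficiencyMethod.CQ_SLOPE)
        for i, e in enumerate([1.88, 1.90, 1.92])
    ]
    assert mean_efficiency(ests).efficiency == pytest.approx(1.90)
    assert mean_efficiency(ests[:1]) is ests[0]
    mixed = ests[:1] + [EfficiencyEstimate("x", 1.9, EfficiencyMethod.LINREG)]
    with pytest.raises(ValueError, match="mixed"):
        mean_efficiency(mixed)


def test_mean_efficiency_from_noisy_triplicates():
    rng = np.random.default_rng(7)
    ests = [
        EfficiencyEstimate(
            f"w{i}", 1.9 + rng.normal(0, 0.02), EfficiencyMethod.CQ_SLOPE
        )
        for i in range(3)
    ]
    assert mean_efficiency(ests).efficiency == pytest.approx(1.9, abs=0.03)
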