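"""Efficiency-corrected Cq, relative incidences, copies and the t test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicequant.io import Target
from splicequant.quantify import (
    CorrectedCq,
    analyze_experiment,
    copies,
    corrected_cq,
    riv,
    riv_for_sample,
    ttest_vs_reference,
)
from splicequant.simulate import MixtureScenario, simulate_mixture_experiment


class TestCorrectedCq:
    @pytest.mark.parametrize(
        "cq, e, expected",
        [(20.0, 2.0, 20.0), (20.0, 1.9, 18.52), (25.0, 1.8, 21.20)],
    )
    def test_values(self, cq, e, expected):
        assert corrected_cq(cq, e) == pytest.approx(expected, abs=0.01)

    def test_cqe_never_exceeds_cq_for_e_below_2(self):
        assert corrected_cq(30.0, 1.5) < 30.0

    def test_no_amplification_rejected(self):
        with pytest.raises(ValueError):
            corrected_cq(20.0, 1.0)
        with pytest.raises(ValueError):
            corrected_cq(-1.0, 1.9)


class TestRiv:
    def test_one_extra_cycle_halves(self):
        assert riv(21.0, 2.0, 20.0, 2.0) == pytest.approx(50.0)

    def test_identity(self):
        assert riv(20.0, 1.9, 20.0, 1.9) == pytest.approx(100.0)

    def test_direct_evaluation(self):
        # 2^(18.520 - 20.372) * 100
        assert riv(22.0, 1.9, 20.0, 1.9) == pytest.approx(27.7, abs=0.1)

    @given(
        cq_var=st.floats(10.0, 35.0),
        cq_con=st.floats(10.0, 35.0),
        e=st.floats(1.5, 2.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotonicity(self, cq_var, cq_con, e):
        base = riv(cq_var, e, cq_con, e)
        assert riv(cq_var + 0.5, e, cq_con, e) < base
        assert riv(cq_var, e, cq_con + 0.5, e) > base


class TestCopies:
    def test_tenfold(self):
        # 3.3219 cycles at perfect doubling = one decade
        assert copies(13.3219, 2.0, 10.0, 2.0, 1e8) == pytest.approx(1e7, rel=1e-3)

    def test_reference_identity(self):
        assert copies(17.0, 1.9, 17.0, 1.9, 5e7) == pytest.approx(5e7)


def _exact_cq(n0, efficiency, n_cq=1e10):
    """Cycle count at which a perfectly exponential reaction reaches n_cq."""
    return math.log(n_cq / n0) / math.log(efficiency)


def test_sum_identity_is_exact_for_exact_inputs():
    """With exact Cq and E the two RIVs close to 100 % for any ratio."""
    e = 1.87
    for frac in (0.01, 0.1, 0.5, 0.77, 0.99):
        total = 3e4
        cq1 = _exact_cq(frac * total, e)
        cq2 = _exact_cq((1 - frac) * total, e)
        cqc = _exact_cq(total, e)
        total_riv = riv(cq1, e, cqc, e) + riv(cq2, e, cqc, e)
        assert total_riv == pytest.approx(100.0, abs=1e-9)


def test_scale_invariance_of_rivs():
    """Multiplying every template by a constant leaves all RIVs unchanged."""
    base = simulate_mixture_experiment(
        MixtureScenario(ratios=((3.0, 1.0),), total_copies=2e4)
    )
    scaled = simulate_mixture_experiment(
        MixtureScenario(ratios=((3.0, 1.0),), total_copies=8e4)
    )
    _, res_base = analyze_experiment(base.curves, base.design)
    _, res_scaled = analyze_experiment(scaled.curves, scaled.design)
    r1, r2 = res_base["M1"], res_scaled["M1"]
    assert r1.riv_variant1 == pytest.approx(r2.riv_variant1, abs=0.3)
    assert r1.riv_variant2 == pytest.approx(r2.riv_variant2, abs=0.3)


def _cqe_replicates(sample, mapping):
    reps = []
    for target, cqe_values in mapping.items():
        for i, cqe in enumerate(cqe_values):
            reps.append(
                CorrectedCq(
                    well_id=f"{sample}_{target.value}_{i}",
                    target=target,
                    cq=cqe,
                    efficiency=2.0,
                    cqe=cqe,
                )
            )
    return reps


class TestRivForSample:
    def test_even_mixture(self):
        reps = _cqe_replicates(
            "S",
            {
                Target.VARIANT1: [21.0, 21.0],
                Target.VARIANT2: [21.0, 21.0],
                Target.CONTROL1: [20.0],
                Target.CONTROL2: [20.0, 20.0],
            },
        )
        res = riv_for_sample("S", reps)
        assert res.riv_variant1 == pytest.approx(50.0)
        assert res.riv_variant2 == pytest.approx(50.0)
        assert res.riv_control_check == pytest.approx(100.0)
        assert res.deviation_d == pytest.approx(0.0)
        assert res.qc_pass

    def test_missing_control2_refused(self):
        reps = _cqe_replicates("S", {Target.VARIANT1: [21.0]})
        with pytest.raises(ValueError, match="control2"):
            riv_for_sample("S", reps)

    def test_missing_variant_gives_partial_result(self):
        reps = _cqe_replicates(
            "S", {Target.VARIANT1: [21.0], Target.CONTROL2: [20.0]}
        )
        res = riv_for_sample("S", reps)
        assert res.riv_variant1 is not None
        assert res.riv_variant2 is None
        assert res.sum_percent is None and res.qc_pass is None

    def test_qc_fails_outside_tolerance(self):
        reps = _cqe_replicates(
            "S",
            {
                Target.VARIANT1: [21.0],
                Target.VARIANT2: [22.5],
                Target.CONTROL2: [20.0],
            },
        )
        res = riv_for_sample("S", reps, qc_tolerance_percent=10.0)
        assert res.sum_percent < 90.0
        assert not res.qc_pass


def test_pipeline_recovers_even_mixture(mixture_dataset):
    _, results = analyze_experiment(mixture_dataset.curves, mixture_dataset.design)
    res = results["M3"]  # the 1:1 mixture
    assert res.riv_variant1 == pytest.approx(50.0, abs=0.5)
    assert res.riv_variant2 == pytest.approx(50.0, abs=0.5)
    assert res.deviation_d <= 0.5
    assert res.riv_control_check == pytest.approx(100.0, abs=0.5)


def test_riv_linearity_across_mixtures(mixture_dataset):
    """Recovered RIVs are linear in the true mixture fraction and the two
    variants' slopes have matching magnitude (within 5 %)."""
    _, results = analyze_experiment(mixture_dataset.curves, mixture_dataset.design)
    truth = mixture_dataset.truth.set_index("sample")
    frac = truth["true_riv_v1"] / 100.0
    v1 = np.array([results[s].riv_variant1 for s in truth.index])
    v2 = np.array([results[s].riv_variant2 for s in truth.index])
    s1 = np.polyfit(frac, v1, 1)[0]
    s2 = np.polyfit(frac, v2, 1)[0]
    assert s1 > 0 > s2
    assert abs(abs(s1) - abs(s2)) / abs(s1) <= 0.05
    for y, slope in ((v1, s1), (v2, s2)):
        r = np.corrcoef(frac, y)[0, 1] ** 2
        assert r >= 0.98


def test_standard_curve_method_end_to_end():
    """Standards-flagged wells drive per-target efficiencies for unknowns."""
    from splicequant.io import DesignRow, DesignSheet
    from splicequant.simulate import simulate_dilution_series

    mixture = simulate_mixture_experiment(
        MixtureScenario(ratios=((3.0, 1.0),), seed=8)
    )
    curves = list(mixture.curves)
    rows = list(mixture.design.rows)
    for target in (Target.VARIANT1, Target.VARIANT2, Target.CONTROL1, Target.CONTROL2):
        std = simulate_dilution_series([4, 5, 6], replicates=1, target=target, seed=8)
        for curve, row in zip(std.curves, std.design.rows):
            well = f"{target.value}_{row.well_id}"
            curves.append(
                type(curve)(
                    well_id=well,
                    cycles=curve.cycles,
                    fluorescence=curve.fluorescence,
                    target=target,
                )
            )
            rows.append(
                DesignRow(
                    well_id=well,
                    sample_id=f"{target.value}_{row.sample_id}",
                    target=target,
                    role="standard",
                    log10_copies=row.log10_copies,
                )
            )
    design = DesignSheet(rows=rows)
    _, results = analyze_experiment(curves, design, method="standard_curve")
    res = results["M1"]
    assert res.riv_variant1 == pytest.approx(75.0, abs=2.0)
    assert res.riv_variant2 == pytest.approx(25.0, abs=2.0)
    assert res.sum_percent == pytest.approx(100.0, abs=2.0)


def test_method_concordance_on_noiseless_data(mixture_dataset):
    """cq_slope- and linreg-based RIVs agree within 2 % without noise."""
    _, by_slope = analyze_experiment(
        mixture_dataset.curves, mixture_dataset.design, method="cq_slope"
    )
    _, by_linreg = analyze_experiment(
        mixture_dataset.curves, mixture_dataset.design, method="linreg"
    )
    for sample in by_slope:
        assert by_slope[sample].riv_variant1 == pytest.approx(
            by_linreg[sample].riv_variant1, abs=2.0
        )
        assert by_slope[sample].riv_variant2 == pytest.approx(
            by_linreg[sample].riv_variant2, abs=2.0
        )


class TestTTest:
    def test_degenerate_equal_values(self):
        res = ttest_vs_reference([100.0, 100.0, 100.0], 100.0)
        assert res.p == 1.0 and res.degenerate

    def test_degenerate_offset_values(self):
        res = ttest_vs_reference([90.0, 90.0], 100.0)
        assert res.p < 1e-300 and res.degenerate

    def test_textbook_example(self):
        res = ttest_vs_reference([90.0, 92.0, 88.0], 100.0)
        # t = (90 - 100) / (2 / sqrt(3)) = -8.66
        assert res.t == pytest.approx(-8.6603, abs=1e-3)
        assert res.p < 0.05

    def test_two_sample_variant(self):
        res = ttest_vs_reference([90.0, 92.0, 88.0], [100.0, 101.0, 99.0])
        assert res.p < 0.01

    def test_type_i_error_calibration(self):
        """Null rejection rate stays near the nominal level."""
        rng = np.random.default_rng(123)
        alpha = 0.05
        hits = sum(
            ttest_vs_reference(rng.normal(100.0, 3.0, size=5), 100.0).p < alpha
            for _ in range(1000)
        )
        assert hits / 1000 == pytest.approx(alpha, abs=0.02)
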