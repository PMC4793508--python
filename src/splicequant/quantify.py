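"""Efficiency-corrected relative quantification of two splice variants.

The amplicon count after ``Cq`` cycles is ``N_Cq = N0 * E^Cq``.  Replacing the
cycle count by its perfect-doubling equivalent ``CqE = Cq * log(E) / log(2)``
lets reactions with different efficiencies be compared on one scale:
``N_Cq = N0 * 2^CqE``.  Two reactions run in parallel on the same instrument
reach the same amplicon count at their take-off points, so the starting
amounts compare as::

    RIV = N0(var) / N0(con) * 100 %  =  2^(CqE_con - CqE_var) * 100 %

Because the two splice variants are mutually exclusive transcripts of one
gene, their relative incidences against a common control amplicon must add up
to 100 %; the deviation ``D = |RIV1 + RIV2 - 100|`` is the method's built-in
error monitor, and the control-1-versus-control-2 incidence (which must also
be 100 %) monitors uniform reverse transcription.

Normalization target is the control-2 amplicon; control 1 is reported as the
concordance check.  RIVs are deliberately never renormalized to force a 100 %
sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cq import (
    CqEstimate,
    EfficiencyEstimate,
    EfficiencyMethod,
    StandardCurvePoint,
    cq_slope_efficiency,
    fit_standard_curve,
    linreg_efficiency,
    mean_efficiency,
    takeoff_cq,
)
from .io import DesignSheet, FluorescenceCurve, Target

__all__ = [
    "CorrectedCq",
    "RIVResult",
    "CopyEstimate",
    "TTestResult",
    "corrected_cq",
    "riv",
    "copies",
    "riv_for_sample",
    "ttest_vs_reference",
    "analyze_experiment",
]

LOG2 = math.log(2.0)


def corrected_cq(cq: float, efficiency: float) -> float:
    """Efficiency-corrected quantification cycle CqE = Cq * log(E)/log(2).

    ``E`` must exceed 1 (an efficiency of 1 means no amplification at all, so
    no finite cycle count is equivalent).  Values of ``E`` above 2 are
    computed here and flagged upstream.
    """
    if cq <= 0:
        raise ValueError(f"Cq must be positive, got {cq}")
    if efficiency <= 1.0:
        raise ValueError(
            f"efficiency must exceed 1 (no amplification), got {efficiency}"
        )
    return cq * math.log(efficiency) / LOG2


def riv(cq_var: float, e_var: float, cq_con: float, e_con: float) -> float:
    """Relative incidence of a variant versus a control amplicon, in percent.

    ``2^(CqE_con - CqE_var) * 100``.  Both reactions must come from the same
    run (the identical amplicon count at take-off is the cancellation that
    makes the formula valid); enforcing that is the caller's contract.
    """
    return 100.0 * 2.0 ** (corrected_cq(cq_con, e_con) - corrected_cq(cq_var, e_var))


def copies(
    cq_x: float,
    e_x: float,
    cq_ref: float,
    e_ref: float,
    reference_copies: float = 1e8,
) -> float:
    """Absolute copy estimate against a reference reaction of known input.

    ``2^(CqE_ref - CqE_x) * reference_copies``.
    """
    if reference_copies <= 0:
        raise ValueError("reference_copies must be positive")
    return reference_copies * 2.0 ** (
        corrected_cq(cq_ref, e_ref) - corrected_cq(cq_x, e_x)
    )


@dataclass(frozen=True)
class CorrectedCq:
    """One well's efficiency-corrected quantification cycle."""

    well_id: str
    target: Target
    cq: float
    efficiency: float
    cqe: float

    @classmethod
    def from_estimates(
        cls, cq: CqEstimate, efficiency: EfficiencyEstimate, target: Target
    ) -> "CorrectedCq":
        return cls(
            well_id=cq.well_id,
            target=target,
            cq=cq.cq,
            efficiency=efficiency.efficiency,
            cqe=corrected_cq(cq.cq, efficiency.efficiency),
        )


@dataclass(frozen=True)
class CopyEstimate:
    sample_id: str
    target: Target
    copies: float
    reference_copies: float


@dataclass(frozen=True)
class RIVResult:
    """Per-sample relative incidences and the sum-to-100 quality control."""

    sample_id: str
    riv_variant1: float | None
    riv_variant2: float | None
    riv_control_check: float | None
    sum_percent: float | None
    deviation_d: float | None
    se_variant1: float | None
    se_variant2: float | None
    qc_pass: bool | None
    qc_tolerance_percent: float = 10.0


def _se(values: Sequence[float]) -> float | None:
    if len(values) < 2:
        return None
    return float(np.std(values, ddof=1) / math.sqrt(len(values)))


def riv_for_sample(
    sample_id: str,
    replicates: Sequence[CorrectedCq],
    qc_tolerance_percent: float = 10.0,
) -> RIVResult:
    """Compute both variants' relative incidences for one sample.

    The control-2 CqE values of the sample are averaged first; each variant
    replicate's RIV is computed against that mean and the replicate RIVs are
    then averaged (mean +/- SE).  When control-1 wells are present their
    incidence against control 2 is computed identically and serves as the
    reverse-transcription concordance check.

    QC passes when the sum of the two variant RIVs deviates from 100 % by at
    most ``qc_tolerance_percent`` and, if the control check is available, the
    check also lies within the tolerance of 100 %.
    """
    groups: dict[Target, list[CorrectedCq]] = {}
    for rep in replicates:
        groups.setdefault(rep.target, []).append(rep)
    if Target.CONTROL2 not in groups:
        raise ValueError(
            f"sample {sample_id}: no control2 wells; the control-2 amplicon "
            f"is the normalization target and is required"
        )
    con2_cqe = float(np.mean([r.cqe for r in groups[Target.CONTROL2]]))

    def mean_riv(target: Target) -> tuple[float | None, float | None]:
        if target not in groups:
            return None, None
        vals = [100.0 * 2.0 ** (con2_cqe - r.cqe) for r in groups[target]]
        return float(np.mean(vals)), _se(vals)

    riv1, se1 = mean_riv(Target.VARIANT1)
    riv2, se2 = mean_riv(Target.VARIANT2)
    check, _ = mean_riv(Target.CONTROL1)
    if riv1 is not None and riv2 is not None:
        total = riv1 + riv2
        dev = abs(total - 100.0)
        ok = dev <= qc_tolerance_percent
        if check is not None:
            ok = ok and abs(check - 100.0) <= qc_tolerance_percent
    else:
        total = dev = ok = None
    return RIVResult(
        sample_id=sample_id,
        riv_variant1=riv1,
        riv_variant2=riv2,
        riv_control_check=check,
        sum_percent=total,
        deviation_d=dev,
        se_variant1=se1,
        se_variant2=se2,
        qc_pass=ok,
        qc_tolerance_percent=qc_tolerance_percent,
    )


class TTestResult(NamedTuple):
    t: float
    p: float
    degenerate: bool = False


def ttest_vs_reference(
    rivs: Sequence[float],
    reference: float | Sequence[float] = 100.0,
    equal_var: bool = True,
) -> TTestResult:
    """Two-tailed Student's t test of RIV readings against the reference.

    With a scalar ``reference`` (the control amplicon defined as 100 %) this
    is the one-sample test; with a sequence it is the unpaired two-sample
    test (``equal_var=False`` selects Welch's variant).  A zero-variance
    sample is degenerate: p is 1.0 if the mean equals the reference and
    reported as below machine resolution otherwise, with the flag set.
    """
    rivs = np.asarray(rivs, dtype=float)
    if len(rivs) < 2:
        raise ValueError("at least two values are required")
    if np.isscalar(reference) or isinstance(reference, (int, float)):
        ref = float(reference)
        if np.allclose(np.std(rivs), 0.0):
            if np.isclose(float(np.mean(rivs)), ref):
                return TTestResult(t=0.0, p=1.0, degenerate=True)
            sign = math.copysign(1.0, float(np.mean(rivs)) - ref)
            return TTestResult(t=sign * math.inf, p=5e-324, degenerate=True)
        res = stats.ttest_1samp(rivs, popmean=ref)
        return TTestResult(t=float(res.statistic), p=float(res.pvalue))
    other = np.asarray(reference, dtype=float)
    res = stats.ttest_ind(rivs, other, equal_var=equal_var)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue))


def _well_efficiencies(
    curves: dict[str, FluorescenceCurve],
    cqs: dict[str, CqEstimate],
    design: DesignSheet,
    method: EfficiencyMethod,
) -> dict[str, EfficiencyEstimate]:
    """Per-amplicon mean efficiencies, mapped back onto each well."""
    out: dict[str, EfficiencyEstimate] = {}
    if method is EfficiencyMethod.STANDARD_CURVE:
        targets = {row.target for row in design.rows if row.role == "unknown"}
        for target in targets:
            standards = design.standards(target)
            if len({s.log10_copies for s in standards}) < 3:
                raise ValueError(
                    f"standard-curve efficiency for target {target.value!r} "
                    f"needs standards at >= 3 dilution levels"
                )
            points = [
                StandardCurvePoint(log10_copies=s.log10_copies, cq=cqs[s.well_id].cq)
                for s in standards
                if s.well_id in cqs
            ]
            fit = fit_standard_curve(points)
            est = EfficiencyEstimate(
                well_id=f"std:{target.value}",
                efficiency=fit.efficiency,
                method=EfficiencyMethod.STANDARD_CURVE,
                fit_r2=fit.r2,
            )
            for row in design.rows:
                if row.target is target and row.role == "unknown":
                    out[row.well_id] = est
        return out
    per_group: dict[tuple[str, Target], list[EfficiencyEstimate]] = {}
    for row in design.rows:
        if row.role != "unknown" or row.well_id not in curves:
            continue
        curve = curves[row.well_id]
        if method is EfficiencyMethod.CQ_SLOPE:
            est = cq_slope_efficiency(curve, cqs[row.well_id])
        elif method is EfficiencyMethod.LINREG:
            est = linreg_efficiency(curve)
        else:  # pragma: no cover - exhaustive enum
            raise ValueError(f"unknown method {method}")
        per_group.setdefault((row.sample_id, row.target), []).append(est)
    means = {key: mean_efficiency(ests) for key, ests in per_group.items()}
    for row in design.rows:
        key = (row.sample_id, row.target)
        if key in means:
            out[row.well_id] = means[key]
    return out


def analyze_experiment(
    curves: Sequence[FluorescenceCurve],
    design: DesignSheet,
    method: EfficiencyMethod | str = EfficiencyMethod.CQ_SLOPE,
    qc_tolerance_percent: float = 10.0,
    takeoff_fraction: float = 0.2,
    smooth_window: int = 5,
    true_efficiencies: dict[Target, float] | None = None,
) -> tuple[pd.DataFrame, dict[str, RIVResult]]:
    """Run the full pipeline: Cq calling, efficiency estimation, RIVs.

    Returns the long result table (one row per sample x target) and the
    per-sample :class:`RIVResult` objects.  ``true_efficiencies`` bypasses
    estimation with externally known per-target values (used for simulation
    studies where ground truth is available).
    """
    method = EfficiencyMethod(method)
    curve_map = {c.well_id: c for c in curves}
    missing = [r.well_id for r in design.rows if r.well_id not in curve_map]
    if missing:
        raise ValueError(f"design wells without curves: {missing[:5]}")
    cqs = {
        well: takeoff_cq(
            curve, smooth_window=smooth_window, takeoff_fraction=takeoff_fraction
        )
        for well, curve in curve_map.items()
        if well in {r.well_id for r in design.rows}
    }
    if true_efficiencies is not None:
        effs = {
            row.well_id: EfficiencyEstimate(
                well_id=row.well_id,
                efficiency=true_efficiencies[row.target],
                method=method,
            )
            for row in design.rows
            if row.role == "unknown"
        }
    else:
        effs = _well_efficiencies(curve_map, cqs, design, method)

    results: dict[str, RIVResult] = {}
    records = []
    for sample in design.samples:
        reps = []
        for row in design.rows:
            if row.sample_id != sample or row.role != "unknown":
                continue
            if row.target is Target.OTHER or row.well_id not in effs:
                continue
            reps.append(
                CorrectedCq.from_estimates(
                    cqs[row.well_id], effs[row.well_id], row.target
                )
            )
        res = riv_for_sample(sample, reps, qc_tolerance_percent=qc_tolerance_percent)
        results[sample] = res
        by_target: dict[Target, list[CorrectedCq]] = {}
        for rep in reps:
            by_target.setdefault(rep.target, []).append(rep)
        riv_cols = {
            Target.VARIANT1: (res.riv_variant1, res.se_variant1),
            Target.VARIANT2: (res.riv_variant2, res.se_variant2),
            Target.CONTROL1: (res.riv_control_check, None),
        }
        for target, group in sorted(by_target.items(), key=lambda kv: kv[0].value):
            riv_val, riv_se = riv_cols.get(target, (None, None))
            records.append(
                {
                    "sample": sample,
                    "target": target.value,
                    "method": method.value,
                    "Cq": float(np.mean([g.cq for g in group])),
                    "E": float(np.mean([g.efficiency for g in group])),
                    "CqE": float(np.mean([g.cqe for g in group])),
                    "RIV_percent": float("nan") if riv_val is None else riv_val,
                    "RIV_SE": float("nan") if riv_se is None else riv_se,
                    "sum_percent": (
                        float("nan") if res.sum_percent is None else res.sum_percent
                    ),
                    "deviation_D": (
                        float("nan") if res.deviation_d is None else res.deviation_d
                    ),
                    "qc_pass": "" if res.qc_pass is None else bool(res.qc_pass),
                }
            )
    return pd.DataFrame.from_records(records), results
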