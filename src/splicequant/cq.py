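"""Quantification-cycle calling and amplification-efficiency estimation.

Three estimators of the per-cycle amplification efficiency ``E`` (the factor
by which the amplicon count multiplies each cycle, ideally 2) are provided:

``cq_slope``
    Second-derivative take-off calling plus a log-linear fit of
    baseline-subtracted fluorescence over the exponential phase of the same
    curve (the style of the instrument's comparative quantitation analysis).
``linreg``
    Window-of-linearity estimation: the baseline is adjusted iteratively and
    the log-linear window with the highest R^2 yields ``E = 10^slope``.
``standard_curve``
    Ordinary least squares of Cq on log10 template copies over a dilution
    series; ``E = 10^(-1/M)`` with ``M`` the slope.

The take-off point — the cycle at which the smoothed second derivative of the
fluorescence curve reaches a set fraction (default 20 %) of its maximum —
serves as the Cq value.  Efficiencies outside the physically meaningful range
[1, 2] are flagged, never clamped.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_interp_spline
from scipy.optimize import brentq
from scipy.signal import savgol_filter
from scipy.stats import linregress

from .io import MIN_CYCLES, FluorescenceCurve

__all__ = [
    "CqMethod",
    "EfficiencyMethod",
    "CqEstimate",
    "EfficiencyEstimate",
    "BaselineFit",
    "StandardCurvePoint",
    "StandardCurveFit",
    "NoExponentialPhaseError",
    "ExponentialWindowError",
    "fit_baseline",
    "takeoff_cq",
    "cq_slope_efficiency",
    "linreg_efficiency",
    "fit_standard_curve",
    "mean_efficiency",
]


class NoExponentialPhaseError(ValueError):
    """The curve shows no rise compatible with exponential amplification."""


class ExponentialWindowError(ValueError):
    """Too few usable cycles to fit the exponential phase."""


class CqMethod(str, enum.Enum):
    SECOND_DERIVATIVE = "second_derivative"
    THRESHOLD = "threshold"


class EfficiencyMethod(str, enum.Enum):
    CQ_SLOPE = "cq_slope"
    LINREG = "linreg"
    STANDARD_CURVE = "standard_curve"


@dataclass(frozen=True)
class CqEstimate:
    """Quantification cycle of one reaction (fractional cycles allowed)."""

    well_id: str
    cq: float
    takeoff_cycle: float
    method: CqMethod = CqMethod.SECOND_DERIVATIVE
    early_takeoff: bool = False


@dataclass(frozen=True)
class EfficiencyEstimate:
    """Per-reaction (or per-amplicon) amplification efficiency."""

    well_id: str
    efficiency: float
    method: EfficiencyMethod
    window_start: float = float("nan")
    window_end: float = float("nan")
    fit_r2: float = float("nan")

    def __post_init__(self) -> None:
        if not self.efficiency > 0:
            raise ValueError(f"well {self.well_id}: efficiency must be positive")

    @property
    def flag_out_of_range(self) -> bool:
        """True when E falls outside the meaningful range [1, 2]."""
        return not (1.0 <= self.efficiency <= 2.0)


@dataclass(frozen=True)
class BaselineFit:
    """Constant (optionally drifting) background fluorescence of a well."""

    offset: float
    drift_per_cycle: float = 0.0
    n_cycles_used: int = 0
    noise_sd: float = 0.0

    def at(self, cycles: np.ndarray) -> np.ndarray:
        return self.offset + self.drift_per_cycle * np.asarray(cycles, dtype=float)


def fit_baseline(
    curve: FluorescenceCurve,
    end_cycle: float | None = None,
    model: str = "exponential",
) -> BaselineFit:
    """Estimate the pre-amplification background of a curve.

    ``model='exponential'`` (default) fits ``F(c) = b + A * r^c`` jointly over
    the below-plateau region, which separates the background from the
    exponential creep that already sits in the "flat" early cycles; a plain
    mean of early cycles would absorb that creep and bias efficiency fits.
    ``model='constant'`` is that plain mean (over cycles up to ``end_cycle``,
    default 3 cycles before the raw second-difference take-off) and
    ``model='linear'`` additionally fits a per-cycle drift.
    """
    cyc = curve.cycles
    flu = curve.fluorescence
    if model == "exponential":
        return _fit_baseline_exponential(curve)
    if end_cycle is None:
        end_cycle = _raw_takeoff(curve) - 3.0
    mask = cyc <= end_cycle
    if mask.sum() < 3:
        mask = np.zeros(len(cyc), dtype=bool)
        mask[: max(3, int(0.1 * len(cyc)))] = True
    x, y = cyc[mask], flu[mask]
    if model == "linear":
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (intercept + slope * x)
        return BaselineFit(
            offset=float(intercept),
            drift_per_cycle=float(slope),
            n_cycles_used=int(mask.sum()),
            noise_sd=float(np.std(resid)),
        )
    if model != "constant":
        raise ValueError(f"unknown baseline model {model!r}")
    return BaselineFit(
        offset=float(np.mean(y)),
        n_cycles_used=int(mask.sum()),
        noise_sd=float(np.std(y)),
    )


def _fit_baseline_exponential(curve: FluorescenceCurve) -> BaselineFit:
    """Joint fit of constant background plus exponential growth term."""
    from scipy.optimize import curve_fit

    cyc = curve.cycles
    flu = curve.fluorescence
    early = flu[: max(3, len(flu) // 4)]
    b0 = float(np.median(early))
    noise0 = float(np.std(early))
    amplitude = float(flu.max() - b0)
    # region: everything below 2 % of the amplitude, where growth is still
    # purely exponential and the background is identifiable
    mask = flu - b0 <= 0.02 * amplitude
    if mask.sum() < 6:
        mask = np.ones(len(flu), dtype=bool)
    x, y = cyc[mask], flu[mask]
    top = float(max(y.max() - b0, 1e-12 * max(abs(flu).max(), 1.0)))

    def model(c, b, log_a, log_r):
        return b + np.exp(log_a + np.exp(log_r) * (c - x[-1]))

    try:
        popt, _ = curve_fit(
            model,
            x,
            y,
            p0=(b0, np.log(top), np.log(np.log(1.8))),
            maxfev=10000,
        )
        offset = float(popt[0])
        noise0 = float(np.std(y - model(x, *popt)))
    except RuntimeError:
        offset = b0
    return BaselineFit(
        offset=offset, n_cycles_used=int(mask.sum()), noise_sd=noise0
    )


def _second_difference(values: np.ndarray) -> np.ndarray:
    return values[2:] - 2.0 * values[1:-1] + values[:-2]


def _check_rise(curve: FluorescenceCurve) -> None:
    flu = curve.fluorescence
    if len(curve) < MIN_CYCLES:
        raise NoExponentialPhaseError(
            f"well {curve.well_id}: {len(curve)} cycles; at least "
            f"{MIN_CYCLES} required"
        )
    early = flu[: max(3, len(flu) // 4)]
    noise = float(np.std(early))
    span = float(flu.max() - np.median(early))
    # the rise must clear the early-cycle noise band and be a rise at all
    if span <= 0 or span < max(6.0 * noise, 1e-9 * max(abs(flu).max(), 1.0)):
        raise NoExponentialPhaseError(
            f"well {curve.well_id}: no exponential phase (signal span "
            f"{span:.3g} within noise)"
        )


def _raw_takeoff(curve: FluorescenceCurve, takeoff_fraction: float = 0.2) -> float:
    """Unsmoothed second-difference scan (used for baseline placement)."""
    d2 = _second_difference(curve.fluorescence)
    cc = curve.cycles[1:-1]
    i = int(np.argmax(d2))
    thr = takeoff_fraction * d2[i]
    for k in range(i, -1, -1):
        if d2[k] < thr:
            lo, hi = d2[k], d2[k + 1]
            if lo > 0 and hi > 0:
                frac = (np.log(thr) - np.log(lo)) / (np.log(hi) - np.log(lo))
            else:
                frac = (thr - lo) / (hi - lo)
            return float(cc[k] + frac)
    return float(cc[0])


def takeoff_cq(
    curve: FluorescenceCurve,
    smooth_window: int = 5,
    takeoff_fraction: float = 0.2,
) -> CqEstimate:
    """Call the take-off point of the exponential phase; used as Cq.

    The fluorescence is smoothed with a local quadratic (Savitzky-Golay)
    filter of ``smooth_window`` cycles, second-differenced, and the first
    (sub-cycle interpolated) cycle at which the second difference reaches
    ``takeoff_fraction`` of its maximum is returned.  Interpolation runs on a
    quintic spline of the *logarithm* of the second difference, which is close
    to linear throughout the exponential phase; this keeps the call accurate
    to well under 0.1 cycles independent of how the curve sits on the integer
    cycle grid.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd integer")
    _check_rise(curve)
    flu = curve.fluorescence
    if smooth_window > 1:
        flu = savgol_filter(flu, min(smooth_window, len(flu)), 2)
    d2 = _second_difference(flu)
    cc = curve.cycles[1:-1]
    i = int(np.argmax(d2))
    if d2[i] <= 0:
        raise NoExponentialPhaseError(
            f"well {curve.well_id}: second derivative never positive"
        )
    # segment: from where d2 falls below 2 % of the peak, to one cycle past it
    hi = i
    if hi < len(d2) - 1 and d2[hi + 1] > 0:
        hi += 1
    lo = i
    while lo > 0 and d2[lo - 1] > 0.02 * d2[i]:
        lo -= 1
    k = min(5, hi - lo)
    if k >= 1:
        spline = make_interp_spline(cc[lo : hi + 1], np.log(d2[lo : hi + 1]), k=k)
        grid = np.arange(cc[lo], cc[hi], 0.001)
        vals = spline(grid)
        ip = int(np.argmax(vals))
        log_thr = vals[ip] + np.log(takeoff_fraction)
        below = np.where(vals[:ip] < log_thr)[0]
        if len(below):
            j = below[-1]
            cq = float(
                brentq(lambda t: spline(t) - log_thr, grid[j], grid[j + 1], xtol=1e-8)
            )
        else:
            cq = float(grid[0])
    else:
        cq = float(cc[i])
    early = cq < curve.cycles[0] + smooth_window
    return CqEstimate(
        well_id=curve.well_id,
        cq=cq,
        takeoff_cycle=cq,
        method=CqMethod.SECOND_DERIVATIVE,
        early_takeoff=early,
    )


def cq_slope_efficiency(
    curve: FluorescenceCurve,
    cq: CqEstimate,
    fit_cycles: int = 4,
    baseline: BaselineFit | None = None,
    exponential_limit: float = 0.01,
) -> EfficiencyEstimate:
    """Efficiency from the amplification-curve slope at the exponential phase.

    Fits ``log10`` of baseline-subtracted fluorescence over ``fit_cycles``
    cycles anchored at the take-off point; ``E = 10^slope``.  Cycles whose
    signal exceeds ``exponential_limit`` of the curve's amplitude are past the
    clean exponential phase and are excluded, the window sliding back to the
    latest fully exponential stretch; cycles with non-positive
    baseline-subtracted signal shrink the window from the left.
    """
    if fit_cycles < 3:
        raise ValueError("fit_cycles must be at least 3")
    if baseline is None:
        baseline = fit_baseline(curve)
    cyc = curve.cycles
    sub = curve.fluorescence - baseline.at(cyc)
    ceiling = exponential_limit * float(sub.max())
    noise_floor = 3.0 * baseline.noise_sd
    usable = (sub > max(noise_floor, 0.0)) & (sub <= ceiling)
    start = float(np.ceil(cq.cq))
    idx = [i for i in range(len(cyc)) if cyc[i] >= start and usable[i]][:fit_cycles]
    if len(idx) < fit_cycles:
        # slide back: latest fit_cycles usable cycles at/before the nominal window
        pool = [i for i in range(len(cyc)) if usable[i] and cyc[i] <= start + fit_cycles - 1]
        idx = pool[-fit_cycles:]
    if len(idx) < 3:
        raise ExponentialWindowError(
            f"well {curve.well_id}: exponential window too short "
            f"({len(idx)} usable cycles)"
        )
    res = linregress(cyc[idx], np.log10(sub[idx]))
    return EfficiencyEstimate(
        well_id=curve.well_id,
        efficiency=float(10.0 ** res.slope),
        method=EfficiencyMethod.CQ_SLOPE,
        window_start=float(cyc[idx[0]]),
        window_end=float(cyc[idx[-1]]),
        fit_r2=float(res.rvalue**2),
    )


def _best_window(
    cyc: np.ndarray,
    logf: np.ndarray,
    eligible: np.ndarray,
    window_min: int,
    window_max: int,
) -> tuple[float, float, int, int] | None:
    """Highest-R^2 window of ``window_min..window_max`` consecutive cycles."""
    best: tuple[float, float, int, int] | None = None
    n = len(cyc)
    for width in range(window_min, window_max + 1):
        for s in range(0, n - width + 1):
            sl = slice(s, s + width)
            if not eligible[sl].all():
                continue
            res = linregress(cyc[sl], logf[sl])
            r2 = float(res.rvalue**2)
            if best is None or r2 > best[0]:
                best = (r2, float(res.slope), s, s + width - 1)
    return best


def linreg_efficiency(
    curve: FluorescenceCurve,
    window_min: int = 4,
    window_max: int = 6,
    min_r2: float = 0.90,
    plateau_fraction: float = 0.1,
) -> EfficiencyEstimate:
    """Window-of-linearity efficiency estimate on non-baseline-corrected data.

    The constant baseline is adjusted iteratively within the statistically
    identifiable band around the early-cycle mean (its standard-error scale)
    so that the best log-linear window — between the noise band and
    ``plateau_fraction`` of the curve amplitude — is maximally linear;
    ``E = 10^slope`` of that window.  The baseline search is deliberately not
    free: with an unconstrained offset the R^2 criterion can straighten
    plateau curvature instead, which flattens the slope and biases E low.
    """
    if window_min < 2:
        raise ValueError("window_min must be at least 2")
    if window_max < window_min:
        raise ValueError("window_max must be >= window_min")
    _check_rise(curve)
    cyc = curve.cycles
    flu = curve.fluorescence
    base0 = fit_baseline(curve, model="constant")
    amplitude = float(flu.max() - base0.offset)
    noise_floor = max(5.0 * base0.noise_sd, 1e-9 * amplitude)

    def evaluate(offset: float):
        sub = flu - offset
        eligible = (sub > noise_floor) & (sub <= plateau_fraction * amplitude)
        if eligible.sum() < window_min:
            return None
        with np.errstate(invalid="ignore", divide="ignore"):
            logf = np.where(sub > 0, np.log10(np.where(sub > 0, sub, 1.0)), np.nan)
        return _best_window(cyc, logf, eligible, window_min, window_max)

    sem = base0.noise_sd / max(np.sqrt(base0.n_cycles_used), 1.0)
    offset = base0.offset
    best = evaluate(offset)
    for cand in np.linspace(base0.offset - 2.0 * sem, base0.offset + 2.0 * sem, 21):
        res = evaluate(float(cand))
        if res is not None and (best is None or res[0] > best[0]):
            best, offset = res, float(cand)
    if best is None or best[0] < min_r2:
        raise NoExponentialPhaseError(
            f"well {curve.well_id}: no log-linear phase "
            f"(best R^2 {0.0 if best is None else best[0]:.3f} < {min_r2})"
        )
    r2, slope, s, e = best
    return EfficiencyEstimate(
        well_id=curve.well_id,
        efficiency=float(10.0**slope),
        method=EfficiencyMethod.LINREG,
        window_start=float(cyc[s]),
        window_end=float(cyc[e]),
        fit_r2=r2,
    )


@dataclass(frozen=True)
class StandardCurvePoint:
    log10_copies: float
    cq: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.log10_copies) and np.isfinite(self.cq)):
            raise ValueError("standard-curve points must be finite")


@dataclass(frozen=True)
class StandardCurveFit:
    """OLS fit of Cq versus log10 copies; E = 10^(-1/M)."""

    slope_m: float
    intercept_b: float
    r2: float
    n_points: int

    @property
    def efficiency(self) -> float:
        return float(10.0 ** (-1.0 / self.slope_m))

    @property
    def inverted_slope(self) -> bool:
        """Positive slope indicates inverted dilution labels."""
        return self.slope_m > 0


def fit_standard_curve(points: list[StandardCurvePoint]) -> StandardCurveFit:
    """Fit a dilution-series standard curve (requires >= 3 distinct levels)."""
    levels = {round(p.log10_copies, 9) for p in points}
    if len(levels) < 3:
        raise ValueError(
            f"standard curve needs >= 3 distinct log10_copies levels, got {len(levels)}"
        )
    x = np.array([p.log10_copies for p in points])
    y = np.array([p.cq for p in points])
    res = linregress(x, y)
    return StandardCurveFit(
        slope_m=float(res.slope),
        intercept_b=float(res.intercept),
        r2=float(res.rvalue**2),
        n_points=len(points),
    )


def mean_efficiency(estimates: list[EfficiencyEstimate]) -> EfficiencyEstimate:
    """Average technical-replicate efficiencies to one value per amplicon.

    All estimates must come from the same method; out-of-range flags propagate
    through the arithmetic mean (the mean of flagged members may itself fall
    inside [1, 2], which is why the members are checked, not the mean).
    """
    if not estimates:
        raise ValueError("mean_efficiency requires at least one estimate")
    methods = {e.method for e in estimates}
    if len(methods) > 1:
        raise ValueError(
            f"cannot average efficiencies from mixed methods: "
            f"{sorted(m.value for m in methods)}"
        )
    if len(estimates) == 1:
        return estimates[0]
    mean_e = float(np.mean([e.efficiency for e in estimates]))
    flagged = any(e.flag_out_of_range for e in estimates)
    out = EfficiencyEstimate(
        well_id="+".join(e.well_id for e in estimates),
        efficiency=mean_e,
        method=estimates[0].method,
        fit_r2=float(np.mean([e.fit_r2 for e in estimates])),
    )
    if flagged and not out.flag_out_of_range:
        # preserve the members' warning by nudging the reported provenance:
        # the flag is derived, so we attach it via a wrapper attribute
        object.__setattr__(out, "_member_flagged", True)
    return out


def efficiency_flagged(estimate: EfficiencyEstimate) -> bool:
    """Out-of-range flag including propagation from averaged members."""
    return estimate.flag_out_of_range or getattr(estimate, "_member_flagged", False)
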