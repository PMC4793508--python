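"""Melt-curve analysis: derivative curves, peak detection, amplicon calls.

A dissociation (melt) curve records SYBR-stained fluorescence while the
products are heated; each double-stranded amplicon releases its dye over a
narrow temperature range around its melting temperature Tm.  The negative
derivative -dF/dT therefore shows one positive peak per amplicon, which is
how the control-2 primer pair's two size-distinguishable products appear as
two discriminable peaks in one reaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks
from scipy.signal import peak_widths, savgol_filter

from .io import MeltRamp

__all__ = [
    "MeltPeak",
    "AmpliconCall",
    "derivative_curve",
    "find_peaks",
    "classify_amplicons",
]


@dataclass(frozen=True)
class MeltPeak:
    """One detected melting transition."""

    tm: float
    height: float
    prominence: float
    width_half_height: float

    def __post_init__(self) -> None:
        if not self.prominence > 0:
            raise ValueError("peak prominence must be positive")


@dataclass(frozen=True)
class AmpliconCall:
    """Assignment of a melt peak to an expected amplicon (or a reject label)."""

    label: str
    tm_observed: float
    tm_expected: float | None
    delta: float | None


def derivative_curve(
    ramp: MeltRamp, smooth_window: int = 9
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed negative derivative -dF/dT of a melt ramp.

    Local-quadratic (Savitzky-Golay) smoothing over ``smooth_window`` points,
    then central differences; half a smoothing window is trimmed from each
    end, where the filter pads.
    """
    if smooth_window < 3 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be an odd integer >= 3")
    if len(ramp) < smooth_window:
        raise ValueError(
            f"well {ramp.well_id}: {len(ramp)} points is fewer than the "
            f"smoothing window ({smooth_window})"
        )
    temp = ramp.temperatures
    flu = savgol_filter(ramp.fluorescence, smooth_window, 2)
    deriv = -np.gradient(flu, temp)
    half = smooth_window // 2
    sl = slice(half, len(temp) - half)
    return temp[sl], deriv[sl]


def find_peaks(
    temperatures: np.ndarray,
    minus_df_dt: np.ndarray,
    min_prominence_fraction: float = 0.05,
) -> list[MeltPeak]:
    """Detect melting peaks in a derivative curve.

    Keeps peaks whose prominence reaches ``min_prominence_fraction`` of the
    global derivative maximum (default 5 %, low enough to keep the minor
    product of a 1:9 template mixture), refines each Tm by quadratic
    interpolation around the maximum, and returns peaks sorted by descending
    height.  An empty list is a valid result.
    """
    temperatures = np.asarray(temperatures, dtype=float)
    v = np.asarray(minus_df_dt, dtype=float)
    if len(v) < 3:
        return []
    vmax = float(v.max())
    if vmax <= 0:
        return []
    idx, props = _scipy_find_peaks(v, prominence=min_prominence_fraction * vmax)
    if len(idx) == 0:
        return []
    widths = peak_widths(v, idx, rel_height=0.5)[0]
    step = float(np.mean(np.diff(temperatures)))
    peaks = []
    for k, i in enumerate(idx):
        tm = float(temperatures[i])
        height = float(v[i])
        if 0 < i < len(v) - 1:
            y0, y1, y2 = v[i - 1], v[i], v[i + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                delta = 0.5 * (y0 - y2) / denom
                tm = float(np.interp(i + delta, np.arange(len(v)), temperatures))
                height = float(y1 - 0.25 * (y0 - y2) * delta)
        peaks.append(
            MeltPeak(
                tm=tm,
                height=height,
                prominence=float(props["prominences"][k]),
                width_half_height=float(widths[k] * step),
            )
        )
    return sorted(peaks, key=lambda p: p.height, reverse=True)


def classify_amplicons(
    peaks: list[MeltPeak],
    expected: dict[str, float],
    tolerance: float = 1.0,
) -> list[AmpliconCall]:
    """Assign detected peaks to expected amplicons by melting temperature.

    Greedy nearest-match within ``tolerance`` (each expected label used at
    most once); unmatched peaks more than 3 degC below the lowest expected Tm
    are called ``primer_dimer``, anything else unmatched is ``unassigned``.
    Expected amplicons with no matching peak are reported as absent (observed
    Tm NaN).
    """
    if not expected:
        raise ValueError("expected Tm map must not be empty")
    pairs = []
    for pi, peak in enumerate(peaks):
        for label, tm_exp in expected.items():
            delta = peak.tm - tm_exp
            if abs(delta) <= tolerance:
                pairs.append((abs(delta), pi, label))
    pairs.sort()
    assigned_peaks: set[int] = set()
    assigned_labels: set[str] = set()
    calls: dict[int, AmpliconCall] = {}
    for _, pi, label in pairs:
        if pi in assigned_peaks or label in assigned_labels:
            continue
        assigned_peaks.add(pi)
        assigned_labels.add(label)
        calls[pi] = AmpliconCall(
            label=label,
            tm_observed=peaks[pi].tm,
            tm_expected=expected[label],
            delta=peaks[pi].tm - expected[label],
        )
    lowest_expected = min(expected.values())
    out = []
    for pi, peak in enumerate(peaks):
        if pi in calls:
            out.append(calls[pi])
        elif peak.tm < lowest_expected - 3.0:
            out.append(
                AmpliconCall(
                    label="primer_dimer",
                    tm_observed=peak.tm,
                    tm_expected=None,
                    delta=None,
                )
            )
        else:
            out.append(
                AmpliconCall(
                    label="unassigned",
                    tm_observed=peak.tm,
                    tm_expected=None,
                    delta=None,
                )
            )
    for label, tm_exp in expected.items():
        if label not in assigned_labels:
            out.append(
                AmpliconCall(
                    label=f"{label} (absent)",
                    tm_observed=float("nan"),
                    tm_expected=tm_exp,
                    delta=None,
                )
            )
    return out
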