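"""Seeded simulator of amplification and melt data with known ground truth.

The amplification model follows the exponential growth law
``N(c+1) = N(c) * E_eff`` with a per-cycle efficiency that declines smoothly
as the reaction approaches its plateau::

    E_eff(N) = 1 + (E - 1) / (1 + (N / plateau)^h)

With the default Hill exponent ``h = 2`` the curve is exponential at the true
efficiency ``E`` until roughly 1-2 % of the plateau and then bends into a
realistic sigmoid.  Fluorescence is proportional to amplicon copies plus a
constant offset, optional linear drift and optional Gaussian noise.

Cq noise is injected as a lognormal perturbation of the starting template
(``N0 -> N0 * E^-eps`` with ``eps ~ Normal(0, cq_noise_sd)``), so a noise SD
expressed in cycles translates exactly into take-off jitter while the curve
shape stays self-consistent.

Every generator takes an explicit seed; identical configuration and seed give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    DesignRow,
    DesignSheet,
    FluorescenceCurve,
    MeltRamp,
    Target,
    write_amplification_table,
    write_design,
)

__all__ = [
    "AmpSimConfig",
    "MeltSimConfig",
    "MixtureScenario",
    "SimulatedDataset",
    "simulate_amplification",
    "simulate_melt",
    "simulate_mixture_experiment",
    "simulate_dilution_series",
]


@dataclass(frozen=True)
class AmpSimConfig:
    """Configuration of one simulated amplification reaction.

    Defaults give a 40-cycle reaction starting from 10^4 template copies with
    efficiency 1.9 (the value the reference dilution-series experiments
    recover), a 10^12-copy plateau and a noiseless, drift-free background.
    """

    n0: float = 1e4
    efficiency_true: float = 1.9
    plateau_copies: float = 1e12
    hill_exponent: float = 2.0
    fluorescence_per_copy: float = 1e-10
    baseline_offset: float = 2.0
    baseline_drift_per_cycle: float = 0.0
    noise_sd: float = 0.0  # fraction of plateau fluorescence
    cycles: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1.0 < self.efficiency_true <= 2.0):
            raise ValueError("efficiency_true must lie in (1, 2]")
        if not self.n0 > 0:
            raise ValueError("n0 must be positive")
        if not self.n0 < self.plateau_copies:
            raise ValueError("n0 must be below plateau_copies")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.cycles < 1:
            raise ValueError("cycles must be positive")


def simulate_amplification(
    config: AmpSimConfig, well_id: str = "A1", target: Target = Target.OTHER
) -> FluorescenceCurve:
    """Generate one amplification curve from the saturating growth model."""
    rng = np.random.default_rng(config.seed)
    n = np.empty(config.cycles + 1)
    n[0] = config.n0
    e1 = config.efficiency_true - 1.0
    for c in range(config.cycles):
        x = n[c] / config.plateau_copies
        n[c + 1] = n[c] * (1.0 + e1 / (1.0 + x**config.hill_exponent))
    cycles = np.arange(1, config.cycles + 1, dtype=float)
    flu = (
        config.fluorescence_per_copy * n[1:]
        + config.baseline_offset
        + config.baseline_drift_per_cycle * cycles
    )
    if config.noise_sd > 0:
        plateau_flu = config.fluorescence_per_copy * config.plateau_copies
        flu = flu + rng.normal(0.0, config.noise_sd * plateau_flu, config.cycles)
    return FluorescenceCurve(
        well_id=well_id, cycles=cycles, fluorescence=flu, target=target
    )


@dataclass(frozen=True)
class MeltSimConfig:
    """Configuration of a simulated melt ramp.

    Each transition ``(tm, width, amplitude)`` contributes a logistic
    dissociation step.  ``width`` is the full width at half maximum of the
    resulting -dF/dT peak (the scale a melt trace is read at), so transitions
    separated by at least twice their width appear as distinct peaks.
    """

    transitions: tuple[tuple[float, float, float], ...] = ((85.0, 1.5, 10.0),)
    temp_start: float = 60.0
    temp_end: float = 95.0
    temp_step: float = 0.3
    baseline: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.transitions:
            raise ValueError("at least one melt transition required")
        for tm, width, amp in self.transitions:
            if width <= 0:
                raise ValueError("transition widths must be positive")
            if amp <= 0:
                raise ValueError("transition amplitudes must be positive")
        if self.temp_step <= 0:
            raise ValueError("temp_step must be positive")
        if self.temp_end - self.temp_start < 10.0:
            raise ValueError("melt ramp must span at least 10 degC")


def simulate_melt(config: MeltSimConfig, well_id: str = "A1") -> MeltRamp:
    """Generate one melt ramp as a sum of logistic dissociation steps."""
    rng = np.random.default_rng(config.seed)
    temps = np.arange(
        config.temp_start, config.temp_end + 0.5 * config.temp_step, config.temp_step
    )
    flu = np.full(len(temps), config.baseline)
    # logistic scale such that the derivative peak's FWHM equals `width`
    fwhm_factor = 2.0 * np.log(3.0 + 2.0 * np.sqrt(2.0))
    for tm, width, amp in config.transitions:
        scale = width / fwhm_factor
        flu = flu + amp / (1.0 + np.exp((temps - tm) / scale))
    if config.noise_sd > 0:
        flu = flu + rng.normal(0.0, config.noise_sd, len(temps))
    return MeltRamp(well_id=well_id, temperatures=temps, fluorescence=flu)


@dataclass(frozen=True)
class MixtureScenario:
    """A two-template mixture experiment in the style of a plasmid titration.

    ``ratios`` lists (variant1 : variant2) molar ratios, one sample each; the
    default five span 1:9 to 9:1.  Four primer-pair targets are simulated per
    sample: each variant-specific target amplifies its variant's copies, both
    control targets amplify the sum.
    """

    ratios: tuple[tuple[float, float], ...] = (
        (1.0, 9.0),
        (1.0, 3.0),
        (1.0, 1.0),
        (3.0, 1.0),
        (9.0, 1.0),
    )
    total_copies: float = 2e4
    replicates: int = 3
    efficiencies: dict[Target, float] = field(
        default_factory=lambda: {
            Target.VARIANT1: 1.9,
            Target.VARIANT2: 1.9,
            Target.CONTROL1: 1.9,
            Target.CONTROL2: 1.9,
        }
    )
    cq_noise_sd: float = 0.0  # cycles
    rt_yield: dict[Target, float] = field(default_factory=dict)
    amp: AmpSimConfig = AmpSimConfig()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for v1, v2 in self.ratios:
            if v1 <= 0 or v2 <= 0:
                raise ValueError("ratio components must be positive")
        if self.cq_noise_sd < 0:
            raise ValueError("cq_noise_sd must be non-negative")


@dataclass
class SimulatedDataset:
    """Curves plus design sheet plus the generating ground truth."""

    curves: list[FluorescenceCurve]
    design: DesignSheet
    truth: pd.DataFrame

    def write(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "amplification": write_amplification_table(
                self.curves, directory / "amplification.csv"
            ),
            "design": write_design(self.design, directory / "design.csv"),
        }
        truth_path = directory / "truth.csv"
        self.truth.to_csv(truth_path, index=False)
        paths["truth"] = truth_path
        return paths


_TARGET_ORDER = (Target.VARIANT1, Target.VARIANT2, Target.CONTROL1, Target.CONTROL2)


def _jittered_n0(n0: float, efficiency: float, cq_sd: float, rng) -> float:
    if cq_sd <= 0:
        return n0
    eps = rng.normal(0.0, cq_sd)
    return n0 * efficiency**-eps


def simulate_mixture_experiment(scenario: MixtureScenario) -> SimulatedDataset:
    """Simulate the full mixture titration with attached ground truth.

    Ground truth carries the true relative incidences (which always close to
    100 %) and the per-target true efficiencies.
    """
    rng = np.random.default_rng(scenario.seed)
    curves: list[FluorescenceCurve] = []
    rows: list[DesignRow] = []
    truth_records = []
    for m, (v1, v2) in enumerate(scenario.ratios, start=1):
        sample = f"M{m}"
        frac1 = v1 / (v1 + v2)
        copies = {
            Target.VARIANT1: scenario.total_copies * frac1,
            Target.VARIANT2: scenario.total_copies * (1.0 - frac1),
            Target.CONTROL1: scenario.total_copies,
            Target.CONTROL2: scenario.total_copies,
        }
        for target in _TARGET_ORDER:
            eff = scenario.efficiencies.get(target, 1.9)
            yield_factor = scenario.rt_yield.get(target, 1.0)
            for rep in range(1, scenario.replicates + 1):
                well = f"{sample}_{target.value}_r{rep}"
                n0 = _jittered_n0(
                    copies[target] * yield_factor, eff, scenario.cq_noise_sd, rng
                )
                cfg = replace(
                    scenario.amp,
                    n0=n0,
                    efficiency_true=eff,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                curves.append(simulate_amplification(cfg, well_id=well, target=target))
                rows.append(
                    DesignRow(
                        well_id=well,
                        sample_id=sample,
                        target=target,
                        replicate_index=rep,
                    )
                )
        truth_records.append(
            {
                "sample": sample,
                "true_riv_v1": 100.0 * frac1,
                "true_riv_v2": 100.0 * (1.0 - frac1),
                "true_copies_v1": copies[Target.VARIANT1],
                "true_copies_v2": copies[Target.VARIANT2],
                "true_E_variant1": scenario.efficiencies.get(Target.VARIANT1, 1.9),
                "true_E_variant2": scenario.efficiencies.get(Target.VARIANT2, 1.9),
                "true_E_control1": scenario.efficiencies.get(Target.CONTROL1, 1.9),
                "true_E_control2": scenario.efficiencies.get(Target.CONTROL2, 1.9),
            }
        )
    return SimulatedDataset(
        curves=curves,
        design=DesignSheet(rows=rows),
        truth=pd.DataFrame.from_records(truth_records),
    )


def simulate_dilution_series(
    levels: list[float],
    efficiency_true: float = 1.9,
    replicates: int = 3,
    cq_noise_sd: float = 0.0,
    target: Target = Target.CONTROL2,
    amp: AmpSimConfig = AmpSimConfig(),
    seed: int = 0,
) -> SimulatedDataset:
    """Simulate a standard-curve dilution series.

    ``levels`` are log10 template copies (>= 3 levels required); all wells are
    flagged ``role='standard'`` in the design sheet and share one true
    efficiency.
    """
    if len(levels) < 3:
        raise ValueError("a dilution series needs at least 3 levels")
    rng = np.random.default_rng(seed)
    curves: list[FluorescenceCurve] = []
    rows: list[DesignRow] = []
    truth_records = []
    for level in levels:
        copies = 10.0**level
        for rep in range(1, replicates + 1):
            well = f"S{level:g}_r{rep}"
            n0 = _jittered_n0(copies, efficiency_true, cq_noise_sd, rng)
            cfg = replace(
                amp,
                n0=n0,
                efficiency_true=efficiency_true,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            curves.append(simulate_amplification(cfg, well_id=well, target=target))
            rows.append(
                DesignRow(
                    well_id=well,
                    sample_id=f"std_{level:g}",
                    target=target,
                    replicate_index=rep,
                    role="standard",
                    log10_copies=float(level),
                )
            )
        truth_records.append(
            {
                "sample": f"std_{level:g}",
                "log10_copies": float(level),
                "true_copies": copies,
                "true_E": efficiency_true,
            }
        )
    return SimulatedDataset(
        curves=curves,
        design=DesignSheet(rows=rows),
        truth=pd.DataFrame.from_records(truth_records),
    )
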