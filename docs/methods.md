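# Methods

## Model

A PCR reaction that starts from `N0` target molecules and amplifies with
per-cycle efficiency `E` holds `N(c) = N0 · E^c` molecules after `c` cycles,
as long as reagents are not limiting. The quantification cycle `Cq` is the
take-off point — the cycle at which the exponential phase becomes visible in
the fluorescence signal — so `N_Cq = N0 · E^Cq`. The efficiency-corrected
cycle count `CqE = Cq · log E / log 2` is the number of perfect doublings
equivalent to the observed amplification; two reactions run in parallel
reach (to good approximation) the same `N_Cq`, so their starting amounts
compare as `N0(a)/N0(b) = 2^(CqE_b − CqE_a)`.

For a single splice site the two isoforms are mutually exclusive, and a
control amplicon common to both transcripts measures their sum. The relative
incidence of each variant, `RIV = 2^(CqE_con − CqE_var) · 100 %`, therefore
obeys `RIV1 + RIV2 = 100 %` exactly when Cq and E are exact. The package
never renormalizes to force this: the deviation `D` of the observed sum from
100 % is the assay's error signal, and the incidence of one control pair
against the other (also ideally 100 %) checks that reverse transcription
treated both transcripts alike. Cross-sample comparison and multi-site
isoform deconvolution are out of scope by design.

## Take-off (Cq) calling

`takeoff_cq` smooths the raw fluorescence with a Savitzky–Golay filter
(degree 2, default 5-cycle window), forms discrete second differences, and
returns the first sub-cycle position at which they reach a set fraction
(default 20 %) of their maximum. Two numerical choices matter:

- **Log-domain interpolation.** In the exponential phase the second
  difference itself grows geometrically, so its logarithm is nearly linear
  in cycle number. The crossing is solved on a quintic spline of
  `log(d²F)` over the segment from 2 % of the peak to one cycle past it.
  This makes the call equivariant to sub-cycle shifts of the curve to
  ≲ 0.01 cycles — a property the sum-to-100 identity inherits directly,
  since an incidence error of 1 % corresponds to only ~0.014 cycles.
- **Peak bracketing.** Restricting the spline segment on the right (one
  cycle past the peak) avoids ringing from the steep post-peak fall-off of
  the second difference.

Curves with fewer than 15 cycles, without a rise clearing the early-cycle
noise band, or with a non-positive second derivative raise a
"no exponential phase" error; take-offs landing inside the first smoothing
window are flagged as early.

## Efficiency estimators

**Curve slope (`cq_slope`).** `E = 10^slope` of an ordinary least-squares
fit of `log10` baseline-subtracted fluorescence over (default) four cycles
anchored at the take-off. Cycles whose signal exceeds an exponential-phase
ceiling (default 1 % of the curve amplitude) are already bending toward the
plateau and are excluded, the window sliding back to the latest fully
exponential stretch; cycles below three times the baseline noise shrink it
from the left. Fewer than three usable cycles is an error. Estimates outside
[1, 2] are flagged, never clamped — super-doubling values are a recognized
dye-artifact signature and must stay visible.

**Baseline.** The background is estimated by jointly fitting
`F(c) = b + A·r^c` over the region below 2 % of the curve amplitude
(`fit_baseline(model="exponential")`). A plain mean of early cycles absorbs
the exponential creep already present in the "flat" region and biases the
slope fit upward by several hundredths in E; the joint fit recovers the
offset to ~10⁻⁵ of the amplitude on clean curves.

**Window of linearity (`linreg`).** Works on non-baseline-corrected data: a
constant offset is adjusted iteratively and the 4–6-cycle window with the
highest R² between the noise band (5 × baseline noise) and 10 % of the
amplitude gives `E = 10^slope`. The offset search is bounded to ±2 standard
errors of the early-cycle mean: with a fully free offset the R² criterion
can straighten plateau curvature instead of the exponential phase, which
flattens the slope and biases E low by ~0.2 (measured on simulated curves).
No window reaching R² ≥ 0.90 is an error.

**Standard curve.** OLS of Cq on log10 copies over a dilution series
(≥ 3 distinct levels); `E = 10^(−1/M)` from the slope `M`, with the
intercept, R² and an inverted-slope flag reported.

Technical-replicate efficiencies are averaged per amplicon (arithmetic mean)
before Cq correction; mixed-method averaging is rejected and out-of-range
flags propagate.

## RIV aggregation

Within a sample the control-2 CqE values are averaged first; each variant
replicate's RIV is computed against that mean, and the replicate RIVs are
then averaged (mean ± SE). The aggregation order is a documented choice —
averaging before or after the exponent differs at second order in the
replicate scatter. Control 1, when present, is processed identically and
reported as the concordance check. QC passes when `D` and the control check
deviation both lie within the tolerance (default 10 %, configurable); the
default reflects the deviation range curve-derived efficiencies typically
produce at realistic replicate noise. The t test against the reference
(control 2 defined as 100 %) is the two-tailed one-sample Student test; an
unpaired two-sample form (optionally Welch) is available when a second
group of readings is supplied.

## Melt analysis

The negative derivative −dF/dT is computed by central differences after
Savitzky–Golay smoothing (default 9 points at 0.2–0.3 °C/step ramps), with
half a window trimmed at each end. Peaks are detected by prominence
(default 5 % of the global maximum — low enough to keep the minor product of
a 1:9 mixture) and Tm is refined by quadratic interpolation around the
maximum, since the ramp step is coarser than the desired Tm resolution.
Assignment to expected amplicons is greedy nearest-match within a tolerance
(default ±1.0 °C); unmatched peaks more than 3 °C below the lowest expected
Tm are labelled primer dimers, and expected amplicons with no matching peak
are reported absent — which is also how an unresolved (merged) pair of
products surfaces. Expected Tm values are user-supplied; predicting absolute
amplicon Tm from sequence is out of scope.

## Primer checks

GC content, GC clamp (G/C count in the 3′-terminal five bases — the common
tool convention; the threshold is configurable because definitions vary),
nearest-neighbor Tm via Biopython (SantaLucia unified parameters, 50 mM
Na⁺, 300 nM primer by default; the parameter set is always reported with the
value, since absolute Tm depends on it), self-complementarity as the longest
contiguous complementary stretch over all ungapped self-alignments (the stem
a self-dimer or hairpin could form), and 3′-end complementarity as the
longest run anchored at either primer's 3′ terminus against the partner.
Amplicon length on a supplied template is counted inclusively from the 5′
end of the forward footprint to the 5′ end of the reverse footprint.
Constraint failures are report entries, never errors. Genome-wide
specificity screening is not implemented.

## Simulator

Amplicon copies follow `N(c+1) = N(c) · E_eff(N)` with
`E_eff = 1 + (E−1)/(1 + (N/P)^h)`: efficiency `E` declines smoothly to 1 as
copies approach the plateau capacity `P`. The Hill exponent (default
`h = 2`) keeps growth purely exponential below ~1–2 % of the plateau and
then bends the curve into a realistic sigmoid; a first-order (logistic-type)
decline would leak saturation into the visible exponential phase and make
even noiseless curves violate the method's own exactness properties.
Fluorescence is proportional to copies (default 10⁻¹⁰ per copy against a
10¹²-copy plateau, i.e. plateau signal 100 over a baseline offset of 2) plus
optional linear drift and Gaussian noise expressed as a fraction of the
plateau signal. Defaults are 40 cycles, 10⁴ starting copies and efficiency
1.9 — the efficiency the reference dilution-series experiments recover.

Cq noise is injected as a lognormal template perturbation
(`N0 → N0 · E^−ε`, `ε ~ N(0, sd)`), so a noise SD stated in cycles produces
exactly that take-off jitter while the curve shape stays self-consistent.
Melt ramps are sums of logistic dissociation steps whose `width` parameter
is the FWHM of the resulting derivative peak. The mixture generator emulates
a two-plasmid titration: five ratios 1:9…1:1…9:1 by default, both variants'
copies summed for each control target, ground-truth incidences (which close
to 100 % exactly) attached, and an optional per-target yield factor to
emulate reverse-transcription bias that the control concordance check should
catch. One seeded generator per dataset; identical configuration and seed
give bit-identical output.

What the simulator does *not* emulate: amplicon-specific dye binding,
inter-well optical crosstalk, pipetting-correlated replicate structure,
probe chemistries, and reverse-transcription kinetics beyond the constant
yield factor. Passing tests therefore demonstrate the correctness of the
calculation scheme and its estimators under the stated noise model, not the
wet-lab performance of any particular assay.

## Problem sizes and tolerances

The shipped analyses use the scales a single plate run would produce: five
mixtures × four targets × triplicates (60 wells) for titration studies, six
tenfold dilution levels in triplicate (18 wells) for standard curves, and
1000 replicate draws for the t-test calibration. The acceptance script
(`scripts/acceptance.py`) regenerates all of these from a single seed.
Numerical tolerances in the tests reflect the estimators' measured
noiseless accuracy (take-off within 0.1 cycles of a brute-force scan,
efficiencies within 0.02 of truth, sum-to-100 within 0.5 %) rather than
machine precision, since sub-cycle interpolation and finite fit windows set
the floor.

## Known limitations

- The take-off caller assumes curves that plateau within the run; reactions
  still rising at the final cycle anchor the second-derivative maximum at
  the run's edge and lose shift equivariance.
- `cq_slope` needs a clean exponential stretch of ≥ 3 cycles above the
  baseline noise; at high fluorescence noise its window sits close to the
  noise band and the estimate degrades faster than `linreg`'s.
- The Eq.-level identity `RIV1 + RIV2 = 100 %` holds for a single splice
  site only; transcripts differing at several regions violate the
  mutual-exclusivity premise.
- Melt peak assignment relies on user-supplied expected Tm values from a
  reference run; it cannot discover unknown products beyond flagging them
  unassigned or as primer dimers.
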