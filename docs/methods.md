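# Methods

## Response model and fitting

Each analyte × acquisition-mode dilution series is modeled as
`y(x) = b + C(1 − exp(−x/R))`: linear with slope `C/R` for `x ≪ R`,
asymptotically flat at `b + C` for `x ≫ R`. The same functional form is
both the fitted calibration model and the simulator's detector transfer
function, which is deliberate: a linear true response `a·x` pushed
through the transfer `I_obs = Imax(1 − exp(−I_true/Imax))` lands exactly
on the model with `C = Imax`, `R = Imax/a`, so every figure of merit has
a closed form against which the pipeline can be validated.

Least squares is performed on `log10(y + b̂)` (b̂ = background estimate,
or `1e−9·max(y)` when none is available) so that levels spanning several
orders of magnitude carry comparable weight; unweighted linear-space
residuals would be dominated entirely by the top level. `C` and `R` are
optimized in log space with box constraint `b ≥ 0`. Initialization is
deterministic — `C₀ = max(y)`, `R₀ = geometric mean(x)`, `b₀ = min(y)` —
so repeated fits are bit-reproducible. Optimizer tolerances are set to
1e−15 (scipy `least_squares`, trust-region reflective), which recovers
noiseless parameters to better than 1e−9 relative.

**Linear fallback.** When the fitted curvature over the measured range is
negligible (`max(x)/R < 0.05`) or a straight line fits no worse, the
series carries no saturation information: the fit is replaced by the
`R → ∞` limit, only the slope `C/R` is reported, and the ULOQ is censored
at the top measured concentration. A converged fit whose
`u*(δ)·R` exceeds the measured range is likewise censored rather than
extrapolated — the package never claims a quantifiable range it has not
observed. This cap is a package design choice: an uncensored
extrapolated ULOQ would inflate LDR exactly for the series least
affected by saturation.

## Noise and LLOQ

Background level `b` and noise SD `s` (unbiased, n−1) are estimated from
the replicate responses at the lowest concentration level when no blank
injections are present — the lowest level of a well-designed dilution
series sits at or below the quantification limit, making it a serviceable
blank proxy. The LLOQ solves `C(1 − exp(−x/R)) = s` by Brent's method to
1e−12 relative (≈ `R·s/C` when `s ≪ C`). Degenerate inputs: `s = 0`
yields LLOQ 0 flagged "undefined by noise"; `s ≥ C` yields no LLOQ.

## ULOQ and LDR

The model has no interior inflection in the second-derivative sense, so
the upper limit is defined operationally as the departure-from-linearity
point: the relative shortfall from the low-concentration tangent,
`f(u) = 1 − (1 − e^(−u))/u` with `u = x/R`, is strictly increasing, and
`ULOQ = u*(δ)·R` with `f(u*) = δ`. The default δ = 0.2 (20 % shortfall,
`u* ≈ 0.4642`) is a configuration knob, and every report records the δ
used. LDR = log10(ULOQ/LLOQ) in orders of magnitude.

## Saturation detection

**Isotope test (MS1).** For isotope channels k and k+1 with theoretical
abundance ratio `t = a[k+1]/a[k]`, a level flags channel k as saturated
when the replicate-mean observed ratio exceeds `t(1 + tol)`. The highest
channel has no heavier neighbor and is assumed unsaturated; per-level
`k*` is the lowest unflagged channel.

**MS2 test.** The reference ratio k̂ = median of MS1/ΣMS2 over the lowest
half of usable levels (minimum 2), re-derived once after a first-pass
screen so an already-saturated level cannot contaminate it; a level is
flagged when its ratio drops below `(1 − tol)·k̂`.

Both detectors apply two stabilizers:

- **Noise guard.** Levels whose channel intensities fall below
  `(2/tol)·b + 3s` are exempt from testing. An additive background of
  mean b biases an intensity ratio by up to ≈ `b/I`, so requiring
  `I > (2/tol)·b` bounds the floor-induced bias below half the detection
  tolerance. Without the guard, floor-dominated ratios at the bottom of
  the series trigger spurious flags which monotone closure would then
  propagate everywhere.
- **Monotone closure.** A flag at one level implies flags at all higher
  levels: physical saturation cannot recede as more analyte is loaded.

The default `tol = 0.2` comfortably exceeds duplicate-injection noise
(median abundance errors of a few percent) while catching the > 20 %
distortions that matter. Note an interaction worth knowing: at a given
degree of compression the isotope-ratio deviation is roughly *half* the
response shortfall, so with `tol = δ = 0.2` detection engages slightly
*above* the ULOQ. When the goal is to correct the whole nonlinear
region — e.g. to measure the dynamic-range gain of a correction — run
detection at `tol ≈ δ/2`.

## Corrections

Flagged levels only are altered; unflagged levels pass through
unchanged (identity is exact, not approximate). The isotope correction
rescales the lowest unsaturated isotope peak by its theoretical ratio to
the monoisotopic peak; the MS2 correction rescales the summed fragment
intensities by k̂. A flagged level with no usable donor channel is
marked *uncorrectable* and its monoisotopic record is dropped — no value
is invented. When both corrections are applicable the pipeline computes
and reports both; the better method is analyte-specific and no automatic
winner is chosen.

On a series where only the monoisotopic channel is driven into
saturation and `I0th/I1th = 2`, the corrected curve follows the first
isotope's transfer curve scaled by 2 — asymptote 2C, onset 2R — so the
refit ULOQ grows by a factor approaching 2 and LDR by ≈ 0.30 orders.
This closed-form consequence is used as an end-to-end check.

## Panel summaries

Per mode and correction variant, analytes with failed fits or undefined
metrics are excluded, then Iglewicz–Hoaglin modified z-scores
(`M = 0.6745(x − med)/MAD`, mean-absolute-deviation fallback scaled by
1.253314 when MAD = 0) are computed independently on LLOQ and LDR;
analytes exceeding the threshold (default 3.5, the standard
recommendation) on either metric are excluded (union). Reported spread
is the SD across retained analytes, labeled as such.

## Synthetic data generator

The generator emulates the structure of a serial-dilution study: 5–7
(default 7) fold-stepped levels (default 10×, starting at 1 unit),
duplicate injections, per-channel true intensities
`slope · x · abundance` for MS1 isotopologues and `slope · x · yield`
for CID fragments, each passed through the bounded transfer function
with its channel-class ceiling. Noise has three seeded components:
mean-one lognormal replicate noise (default CV 5 %, matching the few-
percent duplicate-injection errors typical of standards in matrix),
an additive lognormal background floor (positive, heavy-tailed — the
character of chemical noise), and Gaussian m/z jitter (default 4 ppm,
mid-range for a well-calibrated ToF). An optional ceiling multiplier
< 1 emulates the earlier saturation onset of ion-mobility-gated
acquisition. The ground-truth sidecar records true intensities and the
analytic LLOQ/ULOQ/LDR implied by the configuration.

What the generator does **not** emulate: chromatographic peak shape and
integration error, matrix interference and co-elution, ionization
suppression, inter-day drift, or detector dead-time physics beyond the
smooth bounded transfer. Passing tests therefore demonstrate that the
estimators and corrections are mathematically correct and robust to the
modeled noise — not that any particular instrument follows the transfer
function exactly.

The bundled example panel (`example_metabolite_panel`) fixes eight
small-molecule analytes (caffeine-like formulas, slopes spread over one
order of magnitude, two fragments each, shared 2e5 ceiling) with the
panel composition frozen and only the noise realization moved by the
seed.

## Problem sizes and defaults

Simulation-backed tests use single-analyte series of 13 half-decade
levels in duplicate (saturation onset well resolved) or the 8-analyte ×
5-level panel; Monte-Carlo checks use 200 replicates at 5 % noise. The
isotope engine ships a fixed plain-text elemental isotope table (IUPAC
2013 representative compositions) covering C, H, N, O, S, P and common
hetero-elements; distributions are unit-mass binned (fine structure is
out of scope) and truncated at a trailing abundance fraction of 1e−9
before renormalization. The averagine route rounds non-hydrogen counts
to the nearest integer and adjusts hydrogens to bring the monoisotopic
mass within half a hydrogen of target. For elements whose most abundant
isotope is not the lightest (e.g. Fe), offsets are indexed from the
lightest isotope; biomolecular formulas are unaffected.

## Known limitations

- The isotope detector cannot test the highest isotope channel (no
  heavier neighbor); at extreme loads where every channel saturates,
  corrected values become underestimates unless the level is caught by
  the donor-missing path.
- The MS2 reference k̂ assumes at least two levels that are both above
  the noise floor and below saturation onset; very narrow clean windows
  bias k̂ toward the uncorrected side.
- LLOQ may fall below the lowest measured level when the floor is small
  relative to the response slope; unlike the ULOQ it is not censored,
  since the noise floor — not the design range — is its physical basis.
- Concentration units are opaque labels; mixed-unit panels are the
  caller's responsibility.
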