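# Methods

This note documents the models, numerical choices, and limitations behind
`spheromech`, in the order the pipeline runs.

## OCE forward model and inversion

**Forward model (`synth.make_oce_phase_map`).** A single mechanical pulse
travels axially at speed `c` through a homogeneous medium. The displacement
at depth `z` is a Gaussian in time,

    u(z, t) = A · exp(−(t − t₀ − z/c)² / 2w²),

optionally attenuated exponentially with depth. Displacement maps to
optical phase as `Δφ = 4π n u / λ₀`; additive Gaussian phase noise is
applied and the result wrapped to (−π, π]. This is deliberately not an
elastodynamic simulation: no speckle, no guided-wave dispersion from the
spheroid boundary, no multiple wavefronts from simultaneous nanodroplet
activations. Passing the recovery suites therefore demonstrates the
*inversion* is correct under the stated wave model, not that the model
captures everything a real spheroid does.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| depth extent / samples | 400 μm / 64 | spheroid diameter scale; ~6 μm axial pitch |
| frame interval / frames | 10 μs / 256 | 2.56 ms window covers arrivals for c ∈ [0.25, 10] m/s |
| pulse width | 50 μs | transient comparable to reported wavefronts |
| displacement amplitude | 50 nm | peak phase 0.66 rad, safely inside the wrap bound |
| refractive index n | 1.38 | soft-tissue convention; free parameter (unmeasured here) |
| center wavelength λ₀ | 1310 nm | swept-source system wavelength |
| phase noise std | 4π·n·2.6/λ₀ ≈ 0.034 rad | equivalent to the system's 2.6 nm displacement stability |

The config validates that the pulse (±3σ) fits inside the time window at
the deepest sample, and refuses amplitudes whose clean phase would exceed a
wrap-safety bound (default π) unless wrapping is explicitly allowed.

**Inversion (`oce`).** Phase is unwrapped per depth along time
(`numpy.unwrap`) and converted back to nm. Arrival delay per depth is
estimated by normalized cross-correlation against a reference depth's
waveform with parabolic interpolation of the correlation peak, giving
sub-frame precision; the peak correlation value doubles as a quality score
(default threshold 0.5; flat waveforms flagged invalid rather than raised).
Peak-arrival-time tracking would be the simpler alternative; correlation was
chosen because it uses the whole waveform and degrades gracefully with
noise. Delay vs depth is fit by OLS by default (Theil–Sen available for
outlier-heavy profiles, stderr from its 95% CI half-width); speed is the
inverse slope with a delta-method stderr (`se_c = se_b/b²`). A non-positive
slope is rejected as "no propagating wave". The shallowest 10% of depths is
excluded from the fit by default (surface artifacts); depths here are
optical-path-corrected physical depths, and the generator uses the identical
convention so round trips are exact. Replicates aggregate as mean ± SD
(SD across replicates when ≥2, otherwise the fit stderr), and the modulus
comes from the mean speed via `E = 2ρ(1+ν)c²` (ρ = 1000 kg/m³, ν = 0.49).

Measured behavior (recomputed by `scripts/acceptance.py` and the test
suite): noiseless recovery error < 0.05% across 0.5–4 m/s; at the 2.6 nm
noise level the median |error| over 400 seeded runs is ≈ 0.3%.

## Brillouin forward model, calibration, and decoding

**Forward model (`synth.make_brillouin_spectrum`).** Exactly two spectral
orders, each an anti-Stokes/Stokes pair of Lorentzians of FWHM
`linewidth/dispersion` pixels, placed symmetrically about order centers one
FSR apart, with intra-order separation `(FSR − 2Ω)/dispersion` pixels —
the same convention the decoder inverts, by construction. Noise is optional
Gaussian or Poisson (shot-noise regime); peaks falling off the pixel axis
raise an error naming the offending order. Instrument broadening is not
modeled: the physical Brillouin lineshape is Lorentzian, and a
VIPA-broadened Voigt profile is out of scope.

**Peak fitting.** A running-median baseline (51 px) is subtracted (making
seeding invariant to constant offsets), local maxima above 5% relative
prominence seed per-peak Lorentzian-plus-offset least squares
(`scipy.optimize.curve_fit`) in a ±3·FWHM window. Seeds closer than 10 px
are merged: shot noise can split one line top into neighboring local
maxima, and two lines within a linewidth are unresolvable regardless.

**Calibration.** With references of known shift Ωᵢ, the measured
separations obey `d_px = FSR/dispersion − (2/dispersion)·Ωᵢ` — linear in
the unknowns, so a polyfit gives `dispersion = −2/slope` and
`FSR = intercept·dispersion` in closed form (exact for two materials;
least-squares with per-material residuals for more). Reference shifts are
user inputs; the tabulated defaults use `Ω = 2nv/λ` at 660 nm with
(n, v) = water (1.330, 1482 m/s), acetone (1.359, 1174), methanol
(1.328, 1103), giving 5.97 / 4.83 / 4.44 GHz. A residual RMS above
0.05 GHz sets a warning flag on the calibration object.

**Decoding.** `Ω = (FSR − dispersion·d̄_px)/2` from the mean of the two
intra-order separations; stderr propagates the fitted center covariances.
Decoded shifts outside (0, FSR/2) raise an order-ambiguity error. The
chain stops at GHz — converting shift to a longitudinal modulus would
require refractive-index and density maps this study does not use.

Measured behavior: noiseless round-trip error ~1e-6 GHz; over 200
Poisson-noise spectra (peak SNR ≈ 19) the mean bias is below two standard
errors of the mean (~1e-4 GHz).

## Imaging

Repeat averaging is a pixelwise mean; the per-frame noise std is estimated
from residuals about the mean (unbiased in the frame count), and the SNR
gain is √N under the independence assumption — identical frames are flagged
degenerate instead of reporting an infinite-looking estimate as real.

Segmentation uses Otsu's between-class-variance threshold (appropriate
because spheroid-on-background images are bimodal; debris-heavy fields
would need local methods and are a documented limitation). The *smaller*
class is taken as foreground, holes filled, largest 8-connected component
kept. Contrast is judged by inter-class mean separation in pooled
within-class std units (default floor 4σ) — affine-invariant, so `a·I + b`
(a > 0) cannot change the result; zero within-class spread with distinct
classes counts as perfect contrast. Equivalent diameter is defined from
mask area (`2√(area/π)`), so the diameter–area identity is exact by
construction; circularity uses the Crofton perimeter estimate and is
clipped at 1 (discretization can push the raw ratio slightly above it).

## Study statistics

The design is 3 groups × 2 conditions × days {0, 4, 7}, with 9 replicates
per cell in the analysis drivers (three independent experiments in
triplicate).

**Mann–Whitney U** reports `U = min(U₁, U₂)` with the two-sided exact
p-value defined as `2·min(P(U₁≤u), P(U₁≥u))`, capped at 1 (the doubling
convention; the underlying study reports raw p-values without stating one).
The tie-free exact null distribution comes from the rank-count recurrence
`N(u; n, m) = N(u−m; n−1, m) + N(u; n, m−1)`, cheap at any sample size.
With ties, `auto` mode falls back to the tie-corrected normal approximation
with continuity correction, while `exact` mode enumerates all C(n+m, n)
labelings on mid-ranks (limited to n+m ≤ 14). Note the classic identity
KW(2 groups) = z² holds for the normal approximation *without* continuity
correction; the `continuity` flag exposes that.

**Kruskal–Wallis** uses the rank formula with tie correction and a
chi-square (k−1 df) tail; an exact permutation option enumerates all group
assignments for total n ≤ 10. An all-identical sample is defined as
H = 0, p = 1.

**Normalization** is the ratio of treated to control *cell means* per
(group, day) (ratio-of-means rather than mean-of-ratios — the replicates
are not paired across conditions, so per-replicate ratios are not defined),
with first-order error propagation
`sd = ratio·√((sd_t/m_t)² + (sd_c/m_c)²)`. Day-0 ratios are reported as
computed, not rebased to 1. Cells with a missing condition or non-positive
control mean are flagged invalid, never silently dropped.

**Report.** Per (group, condition) KW across days, per (group, day) U test
of control vs treated, plus the normalized summary — one reading of
"comparisons between experimental groups and longitudinal samples"; the
pooled-across-conditions alternative is not implemented. No
multiple-testing correction is applied by default, matching the raw
p-value reporting convention of this kind of study. Cell values are
sorted before aggregation so the report is bit-identical under row
permutations of the input table.

## Synthetic study effects

The generator's effect structure is a synthetic stand-in chosen once to
mimic the qualitative biology — treated LN229 declines most, HA stays
nearly flat, co-culture is intermediate — not measured values. Wave-speed
baselines are 2.0 / 1.5 / 1.8 m/s (LN229 / HA / CO) with day-7 treated
factors 0.50 / 0.93 / 0.75 against controls near 0.90–0.95, giving day-7
treated/control ratios ≈ 0.56 < 0.83 < 0.98. Brillouin baselines are
5.20 / 5.05 / 5.12 GHz with percent-level declines. Replicate noise is
lognormal, parameterized to unit mean so cell means are exact in
expectation; the default CV is 10% for wave speed and 1% for Brillouin
shift (shift effects are only a few percent, so percent-level scatter is
the realistic regime for a spectrometer resolving ~10 MHz). At CV = 10%
and 9 replicates, the day-7 ordering of normalized ratios is recovered in
≈ 99% of seeded runs.

## Problem sizes and determinism

The verification suites use 64×256 maps, 700-pixel spectra, 100 seeds per
speed (4 speeds), 200 Poisson spectra, 500 enumeration cases, 2000 null
simulations, and 200 study runs — sizes at which every Monte-Carlo margin
above is stable to well under its tolerance. All generators take explicit
integer seeds and are bit-reproducible; `scripts/acceptance.py` derives
every stream from its single `--seed` via `numpy.random.SeedSequence`.

## Known limitations

* The OCE forward model is kinematic (a moving Gaussian pulse), not
  elastodynamic; viscoelastic dispersion, guided waves in a bounded
  spheroid, and speckle decorrelation are not represented.
* Brillouin spectra are ideal two-order Lorentzian combs; VIPA instrument
  broadening, order-overlap crosstalk, and EMCCD gain noise are not.
* Otsu segmentation assumes a bimodal intensity histogram; fields with
  debris comparable to the spheroid would defeat the largest-component
  rule.
* The exact-with-ties U test enumerates labelings and is limited to
  n + m ≤ 14.
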