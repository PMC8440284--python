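# Methods

This note documents the models, estimators and numerical choices in
`petblock`, the conditions its synthetic-data generator emulates, and the
limits of what its validation shows about real data.

## Compartment models

The standard two-tissue compartment model (2TCM) describes tracer exchange
between metabolite-corrected arterial plasma C_p and two tissue pools, free
plus non-specific (C1) and specifically bound (C2):

    dC1/dt = K1 C_p − (k2 + k3) C1 + k4 C2
    dC2/dt = k3 C1 − k4 C2
    C_model = (1 − V_B)(C1 + C2) + V_B C_b

with K1 in mL·cm⁻³·min⁻¹, k2..k4 in min⁻¹, fractional blood volume
V_B ∈ [0, 0.2], and whole-blood activity C_b. Macro-parameters:
V_T = (K1/k2)(1 + k3/k4), V_ND = K1/k2, V_S = V_T − V_ND.

The 2TCM1K variant adds an irreversible vascular (endothelial) trap fed
from whole blood, dC_vasc/dt = K_b C_b, whose content is added to the
measured signal unscaled; K_b never enters V_T. With K_b = 0 the two
models are numerically identical (same code path), which the tests assert
bitwise.

**Evaluation.** The tissue response is the convolution of a bi-exponential
impulse response (rates θ₁,₂ = [(k2+k3+k4) ± √((k2+k3+k4)² − 4k2k4)]/2)
with C_p. On a uniform fine grid (default dt = 0.005 min) with C_p treated
as piecewise linear, each exponential convolution has an exact one-pole
recursion evaluated by `scipy.signal.lfilter`; against an adaptive ODE
integration the frame-averaged curves agree to ~1e−8 relative. Model
values are averaged over each frame interval (exact trapezoid on the fine
grid), not sampled at midpoints — the 15-s early frames make midpoint
evaluation biased. Coincident impulse-response roots are separated by a
1e−12 nudge; θ = 0 (irreversible limits) uses the series form of the
recursion coefficients.

**Weighted NLLS.** Fits minimise Σ wᵢ (TACᵢ − modelᵢ)², with
wᵢ ∝ durationᵢ / max(TACᵢ, ε), ε = 10⁻³·max(TAC), normalised to sum to 1 —
the inverse of the count-statistics frame variance assumed by the noise
model below, so weighting and generation are self-consistent. The
optimiser is bounded trust-region least squares with three multi-starts
(the default initialisation K1=0.1, k2=0.1, k3=0.05, k4=0.05, V_B=0.05,
K_b=0.01, and ×0.5 / ×2 rescalings); the lowest-WRSS solution wins.
Parameter CVs come from the Jacobian-based asymptotic covariance
σ̂²(JᵀWJ)⁻¹ with σ̂² = WRSS/(n−p), propagated to V_T by the delta method;
a singular covariance yields infinite CVs rather than an error, which
forces exclusion. Fits with V_T > 10 mL/cm³ or CV(V_T) > 50% are flagged
non-physiological and excluded from downstream plots.

**SUV.** SUV(t) = activity / (injected dose / body weight) with dose in
kBq and weight in g. The scan-level summary is the frame-duration-weighted
mean over 0–90 min; the final-frame value is available as an option. The
mean was chosen because a single late frame is the noisiest part of the
curve; both conventions are defensible readings of "computed 90 min after
injection".

## Blood processing

The input function is composed as
C_p(t) = C_b(t−Δ)·POB(t−Δ)·PPf(t−Δ), zero before the delay Δ.

* **Parent fraction**: PPf(t) = 1 − a·tᵇ/(tᵇ+c), a ∈ [0,1], b, c > 0 — an
  "extended Hill" family anchored at PPf(0) = 1 and monotone declining.
  The exact parameterisation in the source literature is not printed
  anywhere we could verify, so this form is stated as the package's
  definition and used consistently by generator and fitter.
* **POB ratio**: the same family plus a free offset,
  POB(t) = r₀ + a·tᵇ/(tᵇ+c), with r₀ initialised at the earliest measured
  ratio. The offset must be free (not clamped to the first sample) for the
  family to be self-inverting on noiseless data.
* **Whole blood**: zero before onset t_on, linear rise to the measured
  peak, then a sum of 2 or 3 decaying exponentials constrained to be
  continuous at the peak (amplitudes parameterised by stick-breaking
  fractions of the peak value). The exponential order is chosen by AIC;
  the model extrapolates beyond the last sample with no clamp.
* **Calibration**: the continuous sampling line (first 15 min, 1 Hz) is
  scaled onto the discrete samples by a least-squares-through-origin
  factor over the shared 5/10/15-min samples.
* **Delay**: Δ is grid-searched over ±1 min in 0.01-min steps, each
  candidate scored by the WNLLS residual of a one-tissue-compartment fit
  (K1, k2, V_B) to the whole-brain TAC restricted to the first 5 min;
  boundary solutions are flagged. The search bounds cover typical
  radial-artery delays.

All curves are assumed decay-corrected on input; no decay constant is
applied anywhere. Dispersion correction of the continuous line is out of
scope.

## Occupancy (Lassen) plot

Under blocking with unchanged V_ND and one occupancy across regions,
ΔV_T = Occ·(V_T,base − V_ND). Individual fits use plain OLS of ΔV_T on
baseline V_T — noise on the abscissa is deliberately ignored to match
standard practice in occupancy studies; total-least-squares (orthogonal)
regression is available behind a flag but is not the default. Occupancy
and V_ND outside their physical ranges are reported as computed and
flagged, never clipped. Individual 95% CIs are nonparametric bootstrap
percentiles over regions (2000 resamples, seeded).

The population-constrained fit solves the joint nonlinear least-squares
problem ΔV_T,ij = Occ_i·(V_T,base,ij − V_ND) with one shared V_ND: for
fixed V_ND every Occ_i is closed-form, so the fit reduces to a 1-D profile
minimisation. The 95% CI for V_ND is the profile-likelihood interval
RSS(V_ND) ≤ RSS_min·(1 + F₀.₉₅(1, N−p)/(N−p)), p = n_subjects + 1; the
summary occupancy is the mean ± SD of the Occ_i. Constraining can only
increase the pooled SSE relative to the sum of individual fits, which is
property-tested.

**Known bias.** Because ΔV_T shares the baseline measurement error with
the regressor, the OLS slope is biased upward and the x-intercept (V_ND)
with it — an intrinsic limitation of the occupancy plot under noisy V_T,
of order (1−Occ)·σ²_e/σ²_x leveraged by the extrapolation distance. Under
the generator's calibrated V_T noise (below) this bias is about +0.03
mL/cm³ and the nominal-95% profile CI covers the generating V_ND in
roughly 87% of replicate cohorts rather than 95%. Consumers of individual
V_ND values should prefer the population-constrained estimate, as the
original occupancy-study literature does.

## SIME

For each candidate V_ND on a grid (default 0.01 to 5 mL/cm³, step 0.01),
the 2TCM is refitted to every regional baseline TAC with k2 eliminated via
k2 = K1/V_ND (free: K1, k3, k4, V_B), using the same per-region
duration/TAC weights normalised within region; the pooled weighted RSS
over regions and frames is minimised over the grid. Ties resolve to the
smaller V_ND. Whether the pooled objective should use raw or weighted
residuals is not decidable from the method's public descriptions; weighted
is used for consistency with the kinetic modelling and stated here as an
assumption. Each grid point is warm-started from its neighbour's solution,
which makes the 500-point sweep desk-scale (tens of seconds per subject).
Only baseline scans may enter: TACs labelled as blocking scans are
rejected, and this contract is tested. A flat RSS profile (e.g. zero
signal) is flagged degenerate rather than returning an arbitrary grid
point silently.

## Synthetic-data generator

The generator reproduces the study conditions the analysis assumes, and
its defaults are fixed at the scale of the modelled blocking study:

* 26-frame, 90-min schedule (8×15 s, 3×1, 5×2, 5×5, 5×10 min);
* 12 regions with baseline V_T means from the published 2TCM baseline
  column (4.30–6.67 mL/cm³), log-normal between-subject scatter (σ = 0.25
  on V_S) plus a small per-region jitter (σ = 0.05);
* shared true V_ND = 1.99 mL/cm³ enforced as K1/k2 in every region, so the
  occupancy-plot truth and the SIME truth coincide by construction;
* one occupancy per subject drawn uniformly from 0.66–0.77 (the blocking
  dose's target range); blocking scans share K1, k2, k4, V_B with baseline
  while k3 is scaled by (1 − occupancy);
* an optional outlier subject whose baseline V_T is inflated by 38%
  multiplicatively (the high-uptake subject reported by the study);
* micro-parameter scales K1 ≈ 0.15 mL·cm⁻³·min⁻¹, k4 ≈ 0.05 min⁻¹,
  V_B ∈ [0.03, 0.07] — plausible TSPO-tracer values; the study publishes
  only V_T, so these set scale, not targets;
* injected doses ~N(321, 32) MBq baseline / N(302, 75) MBq blocking;
  weights ~N(92, 12) kg (the reported 90 mg ≈ 0.98 mg/kg dosing);
* frame noise: zero-mean Gaussian, SD = noise_scale·√(TAC/duration),
  default noise_scale = 0.1 (≈2% on late 10-min frames, ≈15% on 15-s
  frames) — a count-statistics proxy; the study gives no noise model;
* blood: linear rise to a peak before 2 min then tri-exponential decay,
  Hill-shaped PPf decline and POB rise, discrete samples at the manual
  times (5–90 min), HPLC parent fractions on the 7-sample subset,
  continuous line at 1 Hz for 15 min with a hidden ±5% calibration factor.
  Blood sample noise scales with noise_scale (5% CV continuous, 2.5% CV
  discrete whole blood, ±0.02 additive on POB/PPf at the default).

`simulate_vt_pairs` is a fast path that skips TAC synthesis and fitting:
it samples "measured" regional V_T pairs by applying multiplicative
log-normal noise to the true values. Its CV default (0.022) is calibrated
once to the measured propagation of the default TAC noise through
unconstrained 2TCM fits (relative V_T error SD 2.1–2.2%, negligible bias,
in both conditions), so occupancy-stage statistics computed on sampled
pairs match the full path while running in milliseconds per cohort.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: partial-volume and motion effects, dispersion of
the continuous sampling line, violations of the shared-V_ND assumption
across regions (real K1/k2 varies regionally — the very reason SIME and
blocking estimates disagree in practice), within-scan correlated V_T
errors from a mis-measured input function (present only in the full
refit path, not the pair sampler), TSPO genotype mixtures, and any
pathology-driven change in V_ND itself.

## Problem sizes and determinism

Everything is deterministic given the configuration seed
(`numpy.random.SeedSequence` spawning per subject). The test suite and the
acceptance script size their simulations for a single core: kinetic
recovery properties use ~100 regional fits; SIME exactness uses a
noiseless 4-region subject on the full default grid; the coverage study
uses 100 replicate 7-subject cohorts through the pair sampler; the
end-to-end pipeline demonstrations use 2–5 subjects and 3–6 regions with
SIME restricted to a subset of subjects.

## Known limitations

* CVs are asymptotic (Jacobian-based); no bootstrap at the TAC level.
* The whole-blood peak is taken from the measured maximum sample, so the
  rise is only as sharp as the sampling grid.
* The occupancy-plot OLS bias described above; orthogonal regression is
  offered but not default, and likelihood-based Lassen variants are out of
  scope.
* 2TCM1K's vascular term follows the irreversible-trap reading stated
  above; other parameterisations exist in the literature.
* Voxel-level synthesis, parametric mapping, image registration and
  genotype analyses are out of scope.
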