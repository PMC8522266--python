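# Methods

This note documents the models implemented in `hemoptics`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that affect results.

## Photon-diffusion forward models

Both optical modalities are modeled in the semi-infinite homogeneous
diffusion regime with an extrapolated boundary.

* **Geometry.** Source and detector sit on the surface at separation ρ
  (default 25 mm, a typical adult transcranial separation). The isotropic
  source depth is z₀ = 1/μ_s′ and the extrapolated-boundary distance
  z_b = 2AD with A = (1+R_eff)/(1−R_eff); R_eff(n) uses the standard
  polynomial approximation in the refractive index (n = 1.4 by default).
  The diffusion coefficient is absorption-free, D = 1/(3μ_s′) — the
  dominant convention in the TR-NIRS/DCS literature; with that choice the
  effective attenuation is μ_eff = √(3μ_aμ_s′).
* **Time-domain reflectance** is the image-source pair evaluated as the
  normal photon flux across the boundary. Two exact identities are used as
  tests: increasing μ_a by Δ multiplies R(ρ,t) by exp(−Δ·v·t) point-wise
  (Beer–Lambert factorization), and the time integral equals the
  independently coded steady-state closed form (the acceptance check,
  agreement ≲10⁻⁵ %).
* **Correlation diffusion.** Scatterer dynamics follow the diffusive-flow
  model, ⟨Δr²(τ)⟩ = 6·BFi·τ, giving
  K(τ)² = 3μ_s′μ_a + 6μ_s′²k₀²·BFi·τ and
  g₁(τ) ∝ e^{−K r₁}/r₁ − e^{−K r₂}/r₂, normalized at τ→0. The Siegert
  relation g₂ = 1 + βg₁² maps to the measured intensity autocorrelation.
* **Units.** mm and 1/mm for lengths and optical coefficients, ps for DTOF
  times, s for correlation lags, mm²/s for BFi. The speed of light in
  tissue is c/n in mm/ps.

The boundary-condition variant (extrapolated boundary, flux reflectance,
absorption-free D) is a documented choice among the standard family; the
package does not claim any specific instrument's convention, and all
inverse problems use the same forward model, so internal consistency is
exact by construction.

## Inverse problems

* **DTOF fit.** Free parameters (μ_a, μ_s′, t_shift); the amplitude enters
  linearly and is profiled out analytically each iteration (weighted
  projection), which halves the nonlinear dimension and removes a scaling
  degeneracy. Weights are Poisson, 1/√max(counts,1). Fit window: 50% of
  peak on the rising edge to 1% of peak on the tail — early bins carry
  model error (diffusion fails at short path lengths), far-tail bins carry
  mostly noise. The IRF–data shift is bounded at ±200 ps to absorb trigger
  offsets. Initialization is deterministic (μ_a = 0.01/mm, μ_s′ = 1.0/mm,
  shift 0); a trust-region reflective least-squares solver with bounds
  ([10⁻⁴, 0.5] for μ_a, [0.05, 10] for μ_s′) does the rest. Windows with
  fewer than 1000 counts are rejected rather than fitted.
* **g₂ fit.** (BFi, β) fitted jointly (β from early lags alone is
  supported implicitly by the joint fit's initialization from the first
  three lags); fit range runs to the lag where g₂−1 drops below 0.05β, so
  the fully decayed tail does not dilute the residual. BFi is bounded at
  zero; a curve with no measurable decay is reported `converged=False`
  with BFi pinned at the bound (flow is unidentifiable there, not zero
  with confidence). Noiseless round trips recover all parameters to ≪1%;
  a dense 2-D grid search is used as a brute-force oracle in the tests.

## From optics to physiology

* **Chromophores.** μ_a(λ) − water term = ln10·[ε_HbO·HbO + ε_HbR·HbR],
  solved exactly at 2 wavelengths and by least squares at ≥3. The
  compiled-in table (690/785/830 nm) is rounded from S. Prahl's hemoglobin
  tabulation with Hale & Querry water absorption; a 75% water volume
  fraction is subtracted before the solve. Since the generator and the
  inverse share the table, its absolute accuracy affects no test — with
  real instruments the table should be overridden (TSV hook provided).
* **OEF.** StO₂ is treated as a γ-weighted venous/arterial mixture with
  venous fraction γ = 0.75 (conventional compartment assumption,
  configurable). OEF values are clipped to [0,1] with a warning. Because
  OEF is reported as a change from baseline, γ mainly scales the
  amplitude, not the sign, of reported effects. This formulation is a
  reconstruction of the usual compartment model, documented here rather
  than asserted to match any particular instrument pipeline.
* **rCMRO₂** follows the Fick principle on relative quantities,
  rCMRO₂ = rCBF·(OEF_t/OEF₀)·(SaO₂_t/SaO₂₀), with SaO₂ taken from the
  pulse-oximetry channel (nearest sample in time). The log of the product
  decomposes additively to machine precision — a tested invariant.
* **Reporting modes.** Ratio to baseline for CBF and CMRO₂; difference
  from baseline for StO₂, tHb, OEF (percentage points), MAP, HR, RR,
  SpO₂, TcCO₂, EtCO₂. Ratio results are printed as percent change.

## The study pipeline

Epoch design (seconds, 0 = mask placement): baseline [−300, 0), placement
exclusion [0, 30) (synthetic default; per-subject annotations can replace
it), analysis [180, 600] — the 3-min stabilization mark to the end of the
10-min mask epoch. Processing order per subject/mask: artifact flagging →
placement exclusion → 30-s smoothing → hemisphere merge → normalization
and epoch means. Smoothing and merging are both linear, so their order is
immaterial on artifact-free data (tested to machine precision).

* **Artifacts** are flagged by a robust z-score against a rolling median
  with rolling-MAD scale (window 15 s, threshold 5); flagged samples are
  excluded from every downstream mean. The study this emulates removed
  artifacts manually; an automated robust rule replaces that step so runs
  are reproducible.
* **Smoothing** is a centered moving average over valid samples within
  ±15 s; samples with no valid neighbour become NaN rather than invented.
* **Hemisphere merging** averages left and right sample-wise after a
  paired Wilcoxon signed-rank test on per-subject epoch-mean changes per
  cerebral channel. A significant side difference raises a warning but
  does not block merging (the analysis is defined on the merged series;
  the warning tells the analyst the premise failed). All-zero differences
  give P = 1 by convention. Under the no-lateralization generator the
  side test is a true null, so ~5% of channel × mask checks will warn —
  expected behavior, not a defect.
* **Statistics.** Per-subject changes are analysis-window means of the
  normalized series; the population estimate is the mean with a two-sided
  t-based 95% CI (the simplest estimator consistent with mean-and-CI
  reporting), significance = CI excludes the null (0 for differences, 1
  for ratios). A Hodges–Lehmann/signed-rank alternative sits behind
  `method="wilcoxon"`. Between-mask contrasts are paired per-subject
  differences (FFP2 − surgical) with the same interval. No
  multiple-testing correction is applied by default, matching
  per-parameter CI reporting; zero-variance degenerate inputs yield
  zero-width intervals flagged non-significant. EtCO₂ never enters the
  results table unless explicitly enabled.

## Synthetic-data generator

The generator defines the study conditions every statistical claim is
tested under: 13 subjects, two 10-min epochs per mask, two mask types,
bilateral recording at 1 Hz.

* **Baselines** per subject: CBF 50 ± 10 a.u. (analyzed as a ratio, so
  units are immaterial), StO₂ 65 ± 3%, tHb 55 ± 6 µM, MAP 85 ± 8 mmHg,
  HR 70 ± 8 bpm, RR 14 ± 2 breaths/min, SpO₂ 98 ± 0.8% (capped at 100),
  TcCO₂ 40 ± 3 mmHg, BFi 1.2×10⁻⁶ ± 2×10⁻⁷ mm²/s — typical resting
  young-adult values.
* **Effects.** The `paper-effects` preset injects the reported population
  changes (rCBF 1.065/1.062, ΔStO₂ +0.9%, ΔtHb +0.9 µM FFP2, ΔMAP
  +4.1 mmHg and ΔHR +2.0 bpm surgical, ΔRR −3.2 breaths/min FFP2, EtCO₂
  +6 mmHg as a deliberate probe artifact). Arms reported as
  non-significant get smaller magnitudes consistent with that finding
  (FFP2 HR +0.8 bpm, making the between-mask HR difference 1.2 bpm in
  magnitude; FFP2 MAP +1.5 mmHg; surgical tHb +0.5 µM; surgical RR
  −1.5 breaths/min). Between-subject effect SDs are set so 13-subject CI
  widths resemble the reported intervals (e.g. rCBF SD 0.065) — an
  emulation-tuning choice, documented as such, not ground truth. OEF and
  CMRO₂ are *derived*, not injected, so the generated data are internally
  consistent with the Fick arithmetic.
* **Onset.** Effects ramp in as a logistic sigmoid rescaled to start
  exactly at t = 0 (midpoint 60 s, time constant 20 s): zero effect leaks
  into the baseline, and the plateau is reached well before the 3-min
  analysis mark.
* **Noise** is stationary Gaussian AR(1) per channel (lag-1 coefficient
  0.9, marginal SDs of a few percent of baseline), independent per
  hemisphere for cerebral channels and shared for systemic ones. Real
  monitors have richer spectra (cardiac and respiratory pulsatility,
  slow drifts, probe-motion transients); AR(1) is an explicit stand-in,
  so passing tests demonstrate correct pipeline arithmetic and calibrated
  statistics under well-behaved noise, not robustness to every real-world
  artifact class.
* **Raw optics.** On request the generator emits, per acquisition, DTOFs
  (forward reflectance ⊛ Gaussian IRF, Poisson-sampled at 10⁶ total
  counts) and g₂ curves (Siegert, with a lag-dependent Gaussian noise SD
  parameterized by count rate and averaging time — a simplified
  correlation-noise model with the right qualitative structure: variance
  ∝ 1/averaging, shot term ∝ 1/count rate). Fitting these streams closes
  the loop back to the injected trajectories (<1% noiseless, tested).
* **Determinism.** Everything derives from one `numpy` Generator seeded by
  the caller; the same seed reproduces the study bit-for-bit.

## Problem sizes and runtime choices

The replicate studies used for calibration (CI coverage and null
false-positive rate) run 500 replicates of the full 13-subject pipeline at
1 Hz in the test suite and 200 in the acceptance script; population-mean
time courses are skipped inside replicate loops. These sizes give binomial
Monte-Carlo error well inside the ±2.5-percentage-point acceptance bands
while keeping a full run in minutes on one core. The raw-optics round
trips are exercised at sparse cadence (one acquisition per tens of
seconds) because each acquisition involves three DTOF fits and a g₂ fit;
the physics does not change with cadence.

## Known limitations

* Homogeneous semi-infinite medium only: no layered/heterogeneous models,
  no Monte-Carlo transport, no short-separation scalp regression, so
  extracerebral contamination is not modeled or corrected.
* OEF/CMRO₂ depend on the compartment assumption (γ) and on SpO₂ as the
  arterial saturation surrogate; absolute CMRO₂ is out of scope.
* The artifact detector is a generic robust rule, not a reconstruction of
  any manual cleaning; heavily contaminated channels fail loudly rather
  than silently.
* The generator's effect-onset shape, noise model and between-subject SDs
  are emulation choices; conclusions about real recordings require the
  real deposit, which the reader/`analyze` path ingests via the
  column-mapping configuration.
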