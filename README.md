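# hemoptics

Forward and inverse models for hybrid transcranial diffuse optics —
time-resolved near-infrared spectroscopy (TR-NIRS) and diffuse correlation
spectroscopy (DCS) — together with the full analysis pipeline of a paired
within-subject face-mask physiology study: from raw photon-level
observables to cerebral hemodynamic parameters and population change
estimates with confidence intervals.

It is aimed at researchers in biomedical optics and cerebral hemodynamics
who want a tested, reproducible implementation of the standard semi-infinite
diffusion models, the corresponding nonlinear inverse problems, and a
two-condition (no-mask / mask) study pipeline that can be exercised
end-to-end on synthetic data with known ground truth.

## The models

**TR-NIRS.** Photon transport is modeled by the time-domain diffusion
Green's function for a semi-infinite homogeneous medium with an
extrapolated boundary (image-source formulation):

```
R(ρ,t) = (4πDv)^{-3/2} t^{-5/2} / 2 · exp(−μ_a v t − ρ²/(4Dvt))
         · [ z₀ e^{−z₀²/(4Dvt)} + (z₀+2z_b) e^{−(z₀+2z_b)²/(4Dvt)} ]
```

with D = 1/(3μ_s′), z₀ = 1/μ_s′, z_b = 2AD, v = c/n. A measured photon
distribution of times of flight (DTOF) is this reflectance convolved with
the instrument response function (IRF); the inverse problem recovers
(μ_a, μ_s′) by Poisson-weighted nonlinear least squares with the overall
amplitude solved analytically and a bounded trigger-offset shift.

**DCS.** The correlation diffusion equation with diffusive scatterer motion
⟨Δr²(τ)⟩ = 6·BFi·τ gives the field autocorrelation g₁(τ) through the decaying
attenuation K(τ)² = 3μ_s′μ_a + 6μ_s′²k₀²·BFi·τ; the measured intensity
autocorrelation follows from the Siegert relation g₂ = 1 + β·g₁². The fit
recovers the blood flow index BFi and coherence factor β jointly.

**Hemodynamics.** Multi-wavelength μ_a (default 690/785/830 nm) is
decomposed into HbO/HbR after subtracting a 75% water fraction, giving
StO₂ = HbO/(HbO+HbR) and tHb. Oxygen extraction and metabolism use a
venous-compartment reconstruction (venous fraction γ = 0.75) and the Fick
principle on relative quantities:

```
SvO₂ = (StO₂ − (1−γ)·SaO₂)/γ,   OEF = (SaO₂ − SvO₂)/SaO₂
rCMRO₂ = rCBF · (OEF_t/OEF₀) · (SaO₂_t/SaO₂₀)
```

**The pipeline.** Per subject and mask condition: robust-z artifact
flagging, exclusion of the mask-placement interval, 30-s moving-average
smoothing, hemisphere averaging (after a paired Wilcoxon check that left
and right do not differ), baseline normalization to the 300 s before
mask-on (ratio for CBF and CMRO₂, difference otherwise), analysis-window
means from the 3-min mark to the end of the mask epoch, and paired t-based
95% confidence intervals per mask and between masks. EtCO₂ is ingested but
excluded by default (an in-mask probe reads trapped air).

## Worked example

```
$ hemoptics simulate --preset paper-effects --n-subjects 13 --seed 0 --out study/
wrote 52 series to study
$ hemoptics analyze --data study/ --config study/study.yaml --out study/out
wrote 30 result rows to study/out/results.tsv
```

`results.tsv` contains one row per parameter × mask plus between-mask rows,
for example (seed 0):

```
parameter  mask_type  mode   estimate  ci_low    ci_high  ci_level  n_subjects  significant
CBF        FFP2       r      5.41593   1.03569   9.79617  0.95      13          True
StO2       FFP2       delta  1.08769   0.173087  2.0023   0.95      13          True
tHb        FFP2       delta  0.30411   -0.250794 0.859014 0.95      13          False
...
```

Read: with this synthetic cohort the FFP2 epoch raised cerebral blood flow
by 5.4% (95% CI 1.0–9.8%) relative to the pre-mask baseline — the
generator injected a +6.5% population effect with 6.5% between-subject SD,
so a single 13-subject realization scatters around the truth exactly as a
real cohort would. `hemoptics report` renders the per-parameter change
chart and population time courses; `hemoptics simulate --raw` +
`hemoptics fit-raw` exercise the photon-level round trip (g₂/DTOF streams
fitted back to BFi, StO₂, tHb).

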