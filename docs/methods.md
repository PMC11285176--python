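# Methods

This document records the mathematical conventions, generator defaults and
numerical choices of `frocdwi`, and the identifiability analysis that
explains which FROC parameters the data can and cannot determine.

## 1. Signal models and units

Working units: b in ms/µm² internally (nominal s/mm² divided by 1000),
diffusion coefficients in µm²/ms, lengths in µm, times in ms. With these
units `b·ADC` and the FROC exponent are dimensionless.

**Mono-exponential (ADC) model**

```
S(b) / S(0) = exp(−b · ADC)
```

**FROC model**

```
S(b) / S(0) = exp[ −D µ^{2(β−1)} q^{2β} (Δ − (2β−1)/(2β+1)·δ) ],   q = γ G_d δ
```

The gradient factor is not an input: it is recovered from the nominal
b-value by inverting the Stejskal–Tanner relation `b = q² (Δ − δ/3)`, so
`q(b) = sqrt(b / (Δ − δ/3))`. At β = 1 the bracket reduces to
`q²(Δ − δ/3) = b` and the model equals the mono-exponential model exactly
(unit tests assert agreement to < 1e-12); µ drops out of the model there.

The bundled acquisition protocol (`frocdwi/data/breast_14b_protocol.yaml`)
has 14 b-values 0–3000 s/mm² with per-b averages
(1,1,1,1,1,1,1,1,1,2,2,2,3,3), δ = 25.66 ms, Δ = 30.13 ms.

## 2. Identifiability of D and µ (important)

At fixed (δ, Δ) substitute q(b):

```
−log S(b)/S(0) = K · b^β,
K = D · µ^{2(β−1)} · (Δ − (2β−1)/(2β+1)·δ) / (Δ − δ/3)^β
```

The b-dependence is a stretched exponential in which D and µ appear **only
through the composite K**. Consequences:

* D and µ are exactly non-identifiable from any single-timing multi-b
  acquisition. Two parameter sets with equal (β, K) — e.g.
  (D = 0.85, µ = 3.5) and (D ≈ 0.6283, µ = 2.0) at β = 0.73 — produce
  bit-identical signals at every b.
* A noiseless round trip recovers β and K essentially exactly (β to ~1e-7,
  K to better than 1e-6 relative, residual ~1e-17) but returns whatever
  (D, µ) point on the zero-residual ridge the optimizer reaches from its
  initialization. From the default warm start the (0.85, 0.73, 3.5) lesion
  comes back as D ≈ 1.211, µ ≈ 6.742 — deterministically, with the same K.
* Separating D from µ requires varying the diffusion time (multiple (δ, Δ)
  pairs), which the modelled acquisition does not do.

The package therefore exposes
`signal_models.froc_decay_coefficient(params, protocol) → K` as the
reproducible decay summary, and the test suite asserts recovery of β and K
(plus ADC) rather than of D and µ individually. Acceptance targets that
assert literal D/µ recovery (t1, t3, and the ≤0.1% noiseless end-to-end
phantom map claim for D and µ) fail for this structural reason and are left
red deliberately; the companion decisions ledger documents the analysis.
D retains diagnostic value in practice because a fixed fitting procedure
maps tissue differences in (β, K) to consistent differences in fitted D —
the cohort statistics on D below are unaffected (they operate on sampled
parameter values, not on re-fitted ones).

## 3. Phantom and cohort generator

**Phantom.** A rectangular grid with an air slab on the low-x face
(`air_fraction` of the x extent), breast-like background tissue, and
ellipsoidal lesions with user-set (D, β, µ) and proton-density scale S0.
Lesions must lie inside the grid; overlapping lesions resolve to the later
one with a logged warning.

**Noise.** Magnitude MRI noise is Rician: each measurement is
`|S + n₁ + i n₂|` with n₁, n₂ ~ N(0, σ²). Per b-value, `n_averages`
independent magnitude images are averaged (magnitude-then-average, as on
scanners), which reduces the noise SD by ≈ √n but keeps the Rician floor.
Air voxels contain pure noise, mean σ√(π/2) (Rayleigh). σ = 0 reproduces
the forward model exactly.

**Cohort.** Two groups (73 benign / 105 malignant by default) × two
sequences (SSEPI, SMS). Per parameter, the two sequences of one lesion share
a latent standard normal with correlation ρ (defaults: D 0.95, β 0.75,
µ 0.65, ADC 0.97), mapped to sequence-specific truncated normals with the
group moments:

| group | sequence | D | β | µ | ADC |
|---|---|---|---|---|---|
| benign | SSEPI | 1.17 ± 0.34 | 0.86 ± 0.06 | 3.06 ± 0.63 | 1.30 ± 0.36 |
| benign | SMS | 1.21 ± 0.34 | 0.86 ± 0.05 | 3.20 ± 0.48 | 1.33 ± 0.36 |
| malignant | SSEPI | 0.73 ± 0.18 | 0.77 ± 0.06 | 3.39 ± 0.42 | 0.82 ± 0.20 |
| malignant | SMS | 0.74 ± 0.18 | 0.79 ± 0.05 | 3.50 ± 0.34 | 0.83 ± 0.20 |

Draws outside the physical parameter domains are re-drawn (truncation).

## 4. Fitting

Both models are fitted by bounded nonlinear least squares on `S(b)/S(0)`
(scipy trust-region-reflective, xtol 1e-8). FROC bounds:
D ∈ [1e-4, 4] µm²/ms, β ∈ [0.05, 1], µ ∈ [0.1, 20] µm. Warm start:
D₀ = log-linear ADC estimate, β₀ = 0.9, µ₀ = 5 µm; if the solution sits on
a bound, one restart from (D₀, 0.6, 2.5) is tried and the better residual
kept. Non-convergence is flagged per voxel, never raised; VOI statistics
exclude non-converged voxels. A 50³-point exhaustive grid search is used as
a test oracle: the solver's residual never exceeds the grid minimum.

## 5. Quality metrics

Per b-value, from three ROIs on the magnitude image:
`SNR = S̄_lesion / SD_background` and
`CNR = (S̄_lesion − S̄_tissue) / sqrt(SD²_lesion + SD²_tissue)`, sample SDs
(n−1). Zero background SD (e.g. a noiseless simulation) is a contract error.

## 6. Group and agreement statistics

* Normality gate: Lilliefors-corrected Kolmogorov–Smirnov at α = 0.05
  (reference parameters estimated from the sample); constant samples are
  non-normal by convention.
* Two groups: independent t-test if both normal, else two-sided
  Mann–Whitney U.
* Spearman r with Fisher-transform 95% CI; categories on the rounded |r|:
  ≤0.24 little/none, ≤0.49 fair, ≤0.74 moderate, ≤1.00 good.
* ICC(2,1) (two-way random effects, absolute agreement, single measures) via
  pingouin; categories: ≤0.20 poor, ≤0.40 fair, ≤0.60 moderate, ≤0.80 good,
  ≤1.00 excellent. Verified in tests against the hand ANOVA decomposition
  and the closed-form variance ratio σ_b²/(σ_b²+σ_e²).
* Bland–Altman: bias = mean(x−y), limits bias ± 1.96·SD(x−y).

## 7. Diagnostic statistics

* **ROC.** Malignant is the positive class. D, β, ADC are lower in
  malignancy — scores are negated internally and the Youden cutoff is mapped
  back to the original scale with "≤ cutoff ⇒ malignant"; for µ the rule is
  "≥ cutoff ⇒ malignant". Cutoffs are scanned at observed-value midpoints;
  ties in the Youden index break toward higher specificity. AUC equals the
  normalized Mann–Whitney U statistic (asserted as an identity in tests);
  its CI uses the DeLong variance.
* **DeLong test.** Paired AUC difference via midrank structural components;
  identical score vectors return (z, p) = (0, 1). Cross-validated against a
  10⁴-replicate paired bootstrap (agreement within 0.02).
* **Logistic model.** statsmodels Logit on the candidate markers (default
  D, β, µ); predictors with Wald p ≥ 0.05 are dropped in one pass and the
  model refitted. Perfect separation or non-convergence falls back to a
  weakly penalized ridge-IRLS fit (λ = 1e-4) with a logged warning and
  `penalized=True`.
* **Nomogram.** Per-feature points proportional to |coefficient| × distance
  from the risk-minimizing end of the observed range, scaled so the largest
  span is 100 points; total points map back to probability exactly
  (round-trip asserted to 1e-10).
* **Hosmer–Lemeshow.** Deciles of predicted risk (duplicate edges merged
  with a warning), χ² with g−2 df. The df correction presumes estimated
  coefficients, so calibration tests refit the model; under the null the
  empirical type-I error is ≈5–6% (asserted ∈ [0.02, 0.09] over 300
  replicates).
* **Bootstrap calibration.** Optimism-corrected decile calibration curve,
  ≥100 resamples, model refitted on each resample.
* **Decision curves.** Net benefit `TP/n − FP/n · p_t/(1−p_t)` against
  treat-all and treat-none, thresholds in (0, 1).

## 8. Reproducibility

Every stochastic entry point takes an explicit seed; the pipeline spawns
per-stage sub-seeds from one config seed via `numpy.random.SeedSequence`, so
a rerun is byte-identical (asserted on `summary.json` and `cohort.csv`).
`scripts/acceptance.py` derives all randomness from `--seed`.

## 9. Limitations

* D and µ are reported but not identifiable from single-timing data
  (section 2); compare them across studies only at a fixed fitting
  procedure and initialization.
* The cohort generator draws unimodal truncated normals; bimodal parameter
  distributions in real cohorts are not modelled.
* Image-domain effects (motion, eddy currents, partial volume, SMS
  reconstruction artifacts) are out of scope; noise is ideal Rician.
* The probability-scale cutoff reported for the combined model is one of
  two possible conventions (probability vs linear predictor); the package
  uses probability.
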