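# Methods

## OJIP transient analysis

A fast transient is a two-column record of time (10 µs–1 s, log-spaced,
≥ 20 samples spanning ≥ 4 decades) and fluorescence (instrument units,
positive). All marker reading and curve resampling is **linear in signal
versus log10(time)**: fast-fluorimeter grids are log-spaced, and linear
interpolation in log-time preserves the curve shape equally well across
five decades, which interpolation in linear time does not.

Fiducial values are read at fixed times — Fo at 20 µs (the first reliable
sample of most fast fluorimeters), F300 at 300 µs, F_J at exactly 2 ms,
F_I at 30 ms — all configurable via `MarkerConfig`. The J and I steps are
read at their conventional times rather than detected as inflections;
inflection detection is out of scope. Fm is the global maximum of the
record (ties broken by earliest time), not the value at 1 s, because a
transient that peaks before the end of the record should not have its
peak underestimated by the P-phase decline.

Derived parameters follow the JIP-test conventions listed in the README.
Two choices deserve comment:

- **M0.** The initial slope dV/dt0 is the 0.25 ms chord,
  4·(F300 − Fo)/Fv per ms. A least-squares slope of V against time over
  50–300 µs (`fitted_initial_slope`) is provided as an alternative for
  records whose earliest samples are noisy; the chord is the default
  because it is the standard printed definition and is exactly
  reproducible from the markers alone.
- **Area.** "Area over the OJIP curve" is integrated trapezoidally over
  *linear* time from the Fo marker time to t_Fm, of (Fm − F_t) clipped at
  zero. Both the raw area (fluorescence·s) and the Fv-normalized variant
  (the Sm convention, seconds) are reported, since the raw value scales
  with instrument gain while Sm is scale-free.

Degenerate transients (Fm ≤ Fo) raise in single-curve analysis and are
reported as flagged rows — excluded from group statistics with a logged
count — in `jip_summary`. A non-monotone O–J rise (Fo ≤ F300 ≤ F_J
violated) flags the curve but does not fail it. No smoothing is applied
by default; `smooth_median3` offers a 3-point moving median for noisy
records.

Group summaries use mean and SE = sd/√n; percent change against a named
reference group reuses the phenomics `percent_change`.

## 820 nm transmittance

Curves are divided by their first sample (normalization is idempotent and
scale-invariant); analysis then reduces each curve to the oxidation
amplitude 1 − min(I/I0), the time of the minimum, and the final recovery
level — the minimal statistics supporting amplitude and ordering claims.
The minimum is located on the sampled grid after a centered 3-point
moving average: transmittance valleys are broad, so dozens of samples lie
within noise of the true minimum and the raw pointwise minimum is biased
low by noise selection (at 0.2% multiplicative noise the raw estimator
misses a 0.005 absolute error budget in roughly one run in ten, while the
3-point average meets it with noise-free bias < 1e-4). `smooth=1`
restores the raw-grid behaviour. Group ranking sorts ascending mean
minimum (lowest transmittance = strongest P700 oxidation), breaking exact
ties lexicographically and flagging them. Normalization is on by default;
the CLI exposes `--raw`. No deconvolution of P700⁺/plastocyanin
contributions and no rate fitting is attempted.

## Trait statistics

Trait tables are long-format (genotype, treatment, replicate, trait,
value) with unique replicate keys. Summaries report mean and SE = sd/√n
(n = 1 groups flagged, SE set to 0 by convention). Percent reduction is
100·(1 − value/reference); display rounding to whole percent happens only
at the report layer.

Electrolyte leakage is 100·EC_initial/EC_total — initial conductivity of
the bathing solution over conductivity after complete lysis — the
convention of the standard membrane-injury protocol this assay cites.

The t-test is classical pooled-variance Student (Welch behind a flag),
delegated to scipy. One-way ANOVA is implemented as the explicit
between/within sums-of-squares decomposition because the protected LSD
needs the error mean square and its degrees of freedom, which
`scipy.stats.f_oneway` does not expose; scipy serves as the independent
oracle in the tests. F is defined as 0 (p = 1) when both sums of squares
vanish. Fisher's protected LSD applies the pairwise criterion
|m_i − m_j| > t(1 − α/2, df_W)·√(MSE·(1/n_i + 1/n_j)) only when the
omnibus p < α, so by construction it never declares a pair significant
under a non-significant ANOVA; the family-wise null rejection rate is
held near α (measured ≤ 0.06 at α = 0.05).

A transcribed yield-trait reference table (three genotypes × three
treatments × six traits, mean ± SE, n = 9) ships as package data. The
knock-down line's salinity-stress reproductive traits are recorded as 0:
those plants did not reach the reproductive phase under salt, and the
zeros are the operational yield of that group.

## qPCR (ddCt)

Replicate Cts are averaged per (sample, gene role) before differencing —
no pairing structure is assumed between target and reference wells.
dCt = mean Ct_target − mean Ct_reference; ddCt subtracts the calibrator
sample's dCt, so the calibrator's RQ is exactly 1 under any row ordering;
RQ = 2^−ddCt assumes doubling efficiency (efficiency correction is out of
scope). The display transform is log10(RQ) by default, with base 2 behind
a flag. RQ is invariant to any constant shift applied to all Ct values,
since it cancels in the double difference.

## Metabolomics

Internal-standard normalization divides each sample's intensities by its
ribitol intensity (errors name the offending sample); it commutes with
sample subsetting. Metabolites absent (zero) in more than 50% of samples
are dropped; remaining zeros are flagged-missing, never imputed.

Fold changes are per-genotype, per-time-point
log2(mean stress / mean control) on normalized data, using group means —
the aggregation the ratio convention implies. Entries with a missing
condition or a nonpositive group mean are NaN and listed in the result's
`attrs["flagged"]`, never silently zeroed. Venn classification calls a
metabolite "up"/"down" when its entry exceeds ±threshold (default 0, the
sign rule; the demo pipeline and recovery checks use 0.5 to separate
programmed effects from noise) and reports exclusive and shared sets per
time point and direction.

PCA mean-centers columns and by default scales them to unit variance
(common metabolomics practice; zero-variance columns are dropped first),
then decomposes by SVD. Explained-variance fractions sum to 1 over all
components and scores have diagonal sample covariance;
`sklearn.decomposition.PCA` is the cross-check oracle in the tests, not
the implementation. Box–whisker summaries report mean and 1.96·sd whisker
half-widths — an approximate 95% interval for individual observations
under normality, not quartiles. Supervised PLS-DA is out of scope.

## Synthetic data

Generators are pure functions of (config, seed); identical inputs give
bitwise-identical outputs, and every dataset ships with a JSON-serializable
truth record sufficient to score recovery.

- **OJIP**: F(t) = Fo + (Fm − Fo)·Σ_k w_k/(1 + (τ_k/t)^{h_k}), a weighted
  sum of Hill sigmoids, one per O–J, J–I and I–P phase. This is geometry,
  not mechanism: it reproduces the phase structure while making V(t)
  available in closed form at any time, so marker extraction has exact
  oracles. Defaults: Fo = 500, Fm = 2500 (Fv/Fm = 0.8, the healthy-leaf
  value), weights 0.5/0.25/0.25, half-times 0.4 ms/10 ms/100 ms,
  steepness 2, 118 log-spaced points over 10 µs–1 s, 1% multiplicative
  Gaussian noise (gain/shot-like; additive noise is out of scope). The
  closed form gives V(2 ms) = 0.4905.
- **820 nm**: I(t)/I0 = 1 − A·(1 − e^{−t/τ_ox})·e^{−t/τ_red}. Defaults
  τ_ox = 5 ms, τ_red = 2 s separate oxidation from re-reduction enough
  that the realized minimum depth is within 2% of the nominal amplitude
  A; with strongly overlapping kinetics (e.g. τ_ox = 20 ms, τ_red =
  0.5 s) the realized depth is only ~0.84·A, and recovery must then be
  scored against the dense-grid minimum of the closed form
  (`p700_true_minimum`), as the tests do for that pair.
- **Traits**: replicate value = mean + N(0, (SE·√n)²), defaults
  transcribed from the packaged reference table with n = 9.
- **Ct**: reference Cts are N(ct_ref_mean, sd²); target Cts add the
  calibrator dCt minus log2 of the programmed RQ, so ddCt analysis
  recovers RQ in expectation.
- **Metabolites**: intensity = 2^(baseline + effect·1[stress]) × sample
  loading × (1 + N(0, cv²)); the internal-standard column equals the
  loading alone, so normalization must remove the loading exactly. One
  signed effect per metabolite per time point keeps programmed up/down
  sets disjoint by construction.

What the generators do **not** emulate: real transients' instrument
response and detector saturation, thermal-phase heterogeneity between
leaves, batch effects and drift in GC-MS runs, missing-not-at-random
metabolite dropout, and biological covariance between traits. Passing
recovery tests therefore demonstrates the estimators' correctness and
noise behaviour under the stated noise model, not field performance on
real leaves.

## Problem sizes and tolerances

Recovery checks use 50–100 seeded replicates per claim, null-calibration
checks 2 000 (protected LSD) and 10 000 (t-test) replicates, and oracle
equivalence 200 random designs — sizes at which the binomial error of
every asserted rate is well inside its margin while the whole suite runs
in seconds. Numerical tolerances: worked formula examples at 1e-12;
oracle equivalence at 1e-10 (ANOVA) and 1e-8 (PCA); marker interpolation
on the default 118-point grid is accurate to ~5e-4 relative (the F300
marker, on the steepest part of the rise, is worst). Stochastic bounds —
V_J within 0.03 and Fv/Fm within 0.01 in ≥ 95/100 noisy transients,
amplitude within 0.005 in ≥ 95/100 curves, Venn sensitivity ≥ 90% —
were chosen from the noise models' analytic error budgets.

## Known limitations

- F_J is read at exactly 2 ms; transients whose J step drifts from 2 ms
  (strong heat stress, K-band phenomena) will mis-read V_J.
- The fold-change pipeline assumes a shared metabolite panel across
  genotypes; panels must be harmonized upstream.
- The protected LSD controls the family-wise rate only weakly for many
  groups (an inherent property of the procedure, kept for fidelity to
  the field's convention).
- No energy-flux JIP parameters beyond those listed, no quenching
  analysis, no kinetic model fitting, and no chromatogram-level GC-MS
  processing.
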