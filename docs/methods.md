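# Methods notes

## Scope and data model

The package analyses 19-channel 10–20 resting-state EEG (the 21-channel
Electro-cap montage with the earlobe references A1/A2 dropped) sampled
at 500 samples/s, and per-subject reaction-time samples from a
processing-speed task. The in-memory containers are deliberately thin:
`EEGRecording` (channels × samples, rate, labels), `EpochSet`
(epochs × channels × samples), `ConnectivityMatrix` (symmetric, zero
diagonal, values in [0, 1]), `SpanningTree` (label edge list; validated
N − 1 edges, connected, hence acyclic) and plain dataclasses for metric
records and fitted parameters. Cohort-level results live in pandas
DataFrames.

## Preprocessing

- **Common average reference.** The reference is the per-sample mean of
  all channels except Fp1/Fp2 and A1/A2 (EMG-prone sites); it is
  subtracted from every retained channel and A1/A2 are dropped. CAR is
  a linear re-mix of channels: for synthetic recordings whose phase-lag
  structure is planted directly in sensor space it would distort the
  planted geometry, so the pipeline exposes `car=False` and the
  planted-recovery experiments use it. Real referenced recordings
  should keep the default.
- **Band-pass filtering.** Zero-phase FIR: a Hamming-window band-pass
  designed per band (delta 0.5–4, theta 4–8, lower alpha 8–10, upper
  alpha 10–12, beta 13–30, low gamma 30–48 Hz), applied by FFT
  convolution with exact group-delay compensation (odd symmetric taps).
  The transition width is min(low edge, half bandwidth, 2 Hz); with the
  Hamming stopband (> 50 dB) this comfortably exceeds the 20 dB
  attenuation requirement one transition-width beyond the band edges.
  A separate 50 Hz notch is unnecessary because every analysis band
  lies below 48 Hz.
- **Epoching.** Consecutive non-overlapping epochs of 4096 samples
  (~8 s); the trailing remainder is discarded. No overlap is used.
- **Epoch selection.** 30 epochs per subject are retained, chosen by an
  automated artifact score: the robust z-score (median/MAD across
  epochs, scale floored at 5% of the median level so homogeneous epoch
  sets are never flagged) of each epoch's peak amplitude and
  log-variance, maximised over channels. Epochs scoring above 10, or
  hitting an optional absolute-amplitude rail, are inadmissible; if
  fewer than k remain the stage fails loudly rather than padding. This
  screen is an automated stand-in for expert visual artifact rejection
  and cannot reproduce expert judgement; its thresholds are documented,
  not clinically validated.

## Phase lag index

PLI(x, y) = |mean_t sign(Δφ(t))| with Δφ the phase difference of the
Hilbert analytic signals wrapped to (−π, π]. Conventions: sign(0)
contributes 0, so identical signals score exactly 0 (zero-lag coupling
is discounted by design); no edge trimming is applied after the Hilbert
transform by default because epochs (4096 samples) are long relative to
edge effects (a `trim` parameter exists). PLI is computed per epoch and
averaged across the 30 epochs, not on concatenated data. The per-band
scalar "global PLI" is the grand mean over all 171 electrode pairs.

## Spanning tree and metrics

The tree of strongest connections is built by Kruskal's algorithm on
descending weight with union–find; equal weights are ordered by the
lexicographic (label, label) pair, making trees reproducible across
runs and platforms. Maximising total PLI weight is equivalent to the
minimum spanning tree under w → 1 − w (verified as a test invariant).
A matrix whose nonzero entries leave the graph disconnected is
rejected.

Metrics per tree: maximal degree; leaf number L and leaf fraction
L_f = L/m, m = N − 1; diameter in raw hops (a normalized d/m variant is
emitted alongside for cross-study comparison); betweenness centrality
normalized by (N−1)(N−2)/2 node pairs — forced by the convention that
a star hub scores exactly 1 — with BC_max and the mean over all N nodes
(leaves included) as the global value; Newman edge-endpoint
assortativity for the degree correlation R (undefined, reported as NaN,
when endpoint degrees have zero variance, e.g. the 2-node tree);
regional BC as the arithmetic mean over the anterior and posterior
electrode sets, with the central strip C3/C4/Cz excluded from both.
Betweenness, diameter and connectivity checks delegate to networkx;
Kruskal's construction is this package's own, cross-checked in tests
against exhaustive enumeration (all 125 labelled 5-node trees via
Prüfer sequences) and networkx's maximum spanning tree.

Per subject and band, metrics are computed per epoch (one PLI matrix →
one tree → one metric record) and averaged arithmetically across
epochs.

## Ex-Gaussian model

RT = Normal(μ, σ) + Exp(τ), density the Normal⊛Exponential convolution
evaluated through scipy's exponentially-modified normal (K = τ/σ),
which is stable in log space for τ ≪ σ and τ ≫ σ. Fitting maximises
the log-likelihood with L-BFGS-B under box constraints
σ, τ ≥ 10⁻³ ms, from a moment-based start (skewness inversion for τ)
plus two jittered restarts — skewed small samples can have multimodal
likelihoods, and the best converged run wins. Non-convergence is
reported, never silent; a parameter sitting at its bound (e.g. τ for a
symmetric sample) is flagged `at_bound` since it is then unidentified
rather than estimated. Near the τ → 0 boundary the likelihood is flat
in τ, so on symmetric data the optimiser may stop a few ms above the
bound; the fit is then numerically indistinguishable from the direct
Gaussian MLE (asserted in tests). No outlier trimming is applied by
default — the long tail is the object of interest — but a symmetric
percentile trim (≤ 5%) is available. Conventional summaries (mean RT,
iSD with n − 1 denominator) are computed alongside.

## Group statistics

- ANCOVA is realised as OLS of the outcome on a two-level group
  indicator plus covariates (age, education, premorbid IQ by default).
  The group F is the residual-sum-of-squares increase when the
  indicator is dropped, on (1, n − p − 1) df; with a single two-level
  factor and covariates always retained, Type I/II/III sums of squares
  coincide for the group term. Partial eta squared is
  SS_group/(SS_group + SS_error). Rows with missing values are dropped
  listwise per model, and df always reflect the n actually used.
- Network metrics are log-transformed, ln(x + 10⁻²⁴), before modelling
  (the offset only guards exact zeros, e.g. a leaf fraction of a pure
  path's complement); the degree correlation can be negative and is
  modelled untransformed. Raw values are preserved in the cohort table.
- Bonferroni correction is applied across the full per-band metric
  family actually tested; the family size equals the number of rows in
  the network report and is visible there. Correlation tests use the
  fixed p < 0.01 rule.
- The multivariate regression z-scores outcome and regressors, so
  coefficients are standardized betas; duration of illness, duration of
  untreated psychosis and risperidone equivalent enter as controlled
  predictors, and the overall F counts all k regressors, df
  (k, n − k − 1). Rank deficiency fails loudly naming the collinear
  columns.
- The normality screen is a one-sample KS test against a normal with
  the sample's own mean and SD; because the reference is fitted from
  the same data the p-value is anti-conservative (the Lilliefors
  caveat) — it is used only as a screen, never as a confirmatory test.

## Synthetic data: what it emulates and what it does not

- **Coupled signals.** Band-limited Gaussian noise propagates along the
  planted tree from the lowest-index node: each child is its parent
  phase-shifted by a constant lag (default π/4) scaled by the edge
  strength w ∈ (0, 1], plus √(1 − w²) independent innovation; sensor
  noise is added per channel. The lag direction alternates with tree
  depth, so two-hop shared components cancel to zero lag — which PLI
  discounts — while every edge carries a constant nonzero lag. This
  makes tree edges the strongest PLI pairs and the planted topology
  recoverable by the spanning-tree stage (the star hub is recovered as
  the BC_max node in ≥ 95% of seeds at low noise; asserted). Lags that
  are multiples of π are rejected as unidentifiable for PLI. The
  generator is a verification instrument, not biophysics: no 1/f
  background, no volume conduction, no nonstationarity.
- **Reaction times.** Direct Normal + Exponential draws; session sizes
  default to the 55–75 stimulus range typical of digit-symbol tasks.
- **Cohorts.** Correlated columns (network metrics, μ, τ) are drawn
  through a Gaussian copula — multivariate standard normal with the
  target correlation matrix (PSD required; a singular target is handled
  by eigendecomposition), mapped to per-group Normal marginals — giving
  exact control of the target cross-correlations in expectation.
  Clinical covariates (duration of illness ~ N(12.31, 5.65) months,
  untreated-psychosis duration ~ N(4.85, 4.79) months, risperidone
  equivalent ~ N(4.37, 1.48) mg, clipped at 0) attach to the patient
  group only and are structurally missing for controls. The cohort
  generator draws metric values directly; it does not pass through the
  signal pipeline.

Default study conditions mirrored by the generators: 30 retained epochs
of 4096 samples at 500 samples/s per subject, 35 subjects per group,
and the published group-level ex-Gaussian triples
(patients μ = 990.44, σ = 78.31, τ = 673.93 ms; controls μ = 765.19,
σ = 90.81, τ = 455.23 ms).

Passing tests on these data show that the pipeline's algebra and
recovery behaviour are correct under the planted generative model; they
do not certify performance on real EEG, where artifact structure,
volume conduction and nonstationarity are the dominant difficulties.

## Problem sizes used in the shipped checks

The planted-effect end-to-end check runs 8 + 8 subjects with 12 epochs
each in the gamma band — the planted star-vs-balanced contrast is
extreme (leaf fraction 1.0 vs ≈ 0.55), so this size already yields
decisive Bonferroni-corrected effects. Null calibration uses 600
replicate null cohorts of n = 70; correlation power uses 40 replicates
at the study's n = 35 with generative r = 0.72. The acceptance script
fits 100,000 reaction times per group triple.

## Known limitations

- The automated epoch screen is not expert artifact rejection.
- CAR and planted sensor-space coupling are mutually exclusive by
  construction; analyses of real recordings should re-reference, and
  synthetic verification should not.
- The KS normality p-values are anti-conservative (see above).
- EDF support targets the plain 16-bit EDF profile (1-second records);
  EDF+ annotations are ignored on read and not written.
- Group-level clinical findings from any particular study are not
  reproducible here without that study's recordings; the statistics
  layer reproduces the *machinery*, verified on synthetic cohorts.
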