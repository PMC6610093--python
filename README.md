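# eegmst

Resting-state EEG functional-connectivity networks analysed as spanning
trees, together with ex-Gaussian decomposition of reaction times and the
group-statistics layer that links the two.

## The problem

In network studies of psychiatric populations, comparing functional
connectivity graphs across subjects is confounded by the arbitrary
threshold used to binarise connection strengths. The spanning tree of
strongest connections removes that arbitrariness: every subject's
network is reduced to the same backbone of N nodes and N − 1 edges, and
tree-topology metrics (leaf fraction, diameter, betweenness centrality,
degree assortativity) become directly comparable. This package
implements that analysis chain for 19-channel 10–20 scalp EEG, plus the
behavioural side — modelling a subject's reaction-time distribution as
an ex-Gaussian to separate typical speed from attentional lapses — and
the covariate-adjusted statistics connecting the two.

Because clinical recordings of this kind are rarely shared, the package
ships a first-class synthetic-data module: multichannel signals whose
phase-lag coupling follows a *planted* tree topology, reaction-time
samples with known (μ, σ, τ), and whole cohorts with imposed
metric–behaviour correlations. Every stage of the pipeline is verified
against this known ground truth.

## Methods in brief

- **Phase lag index (PLI).** For two signals with instantaneous phases
  φ_x, φ_y from the Hilbert analytic signal,
  `PLI = |⟨sign(Δφ)⟩|` with Δφ wrapped to (−π, π]. PLI ∈ [0, 1];
  consistent zero-lag coupling (volume conduction) scores 0.
- **Maximum spanning tree.** Kruskal's algorithm on descending PLI
  weight (equivalently the minimum spanning tree of 1 − PLI); ties are
  broken lexicographically so trees are bit-reproducible. On N = 19
  electrodes the tree always has 18 edges.
- **Tree metrics.** Leaf number L and leaf fraction L_f = L/m
  (m = N − 1), diameter d in hops (d ≤ m − L + 2), betweenness
  centrality normalized by (N−1)(N−2)/2 pairs so a star hub scores
  exactly 1 and leaves 0, BC_max, mean BC, Newman degree correlation R,
  and mean BC over anterior {Fp1, Fp2, F7, F8, F3, F4, Fz} and
  posterior {T5, T6, P3, P4, Pz, O1, O2} electrode sets.
- **Ex-Gaussian reaction times.** RT ~ Normal(μ, σ) + Exp(τ), fitted by
  maximum likelihood (moment-based start, multi-start L-BFGS-B);
  mean = μ + τ, variance = σ² + τ².
- **Group statistics.** ANCOVA (OLS with a group indicator and
  age/education/premorbid-IQ covariates) with partial eta squared,
  Bonferroni control across the per-band metric family, Pearson/Spearman
  correlations at a fixed p < 0.01 rule, and standardized multivariate
  regression with clinical control predictors. Network metrics are
  log-transformed, ln(x + 1e−24), before modelling.

## Worked example

Plant a 19-channel star-topology recording, recover its network, and
fit an ex-Gaussian to simulated reaction times:

```python
import eegmst as em

star = em.make_reference_tree("star", 19, strength=0.9)
cfg = em.CouplingConfig(band=(8.0, 12.0), noise_sd=0.2, seed=0)
rec = em.simulate_coupled_eeg(star, cfg)

mat = em.pli_matrix(rec.samples, rec.labels)
tree = em.max_spanning_tree(mat)
m = em.tree_metrics(tree)
print(f"leaf fraction {m.leaf_fraction:.3f}  diameter {m.diameter:.0f}  "
      f"BC_max {m.bc_max:.3f}  R {m.degree_correlation:.3f}")

rts = em.sample_exgaussian_rts(
    em.ExGaussianParams(990.44, 78.31, 673.93), 5000, seed=1)
print(em.ExGaussianModel(rts).fit().summary())
```

prints

```
leaf fraction 1.000  diameter 2  BC_max 1.000  R -1.000

Ex-Gaussian maximum-likelihood fit
n_obs = 5000, converged = True
  mu (normal mean, ms)                    983.804
  sigma (normal SD, ms)                    77.588
  tau (exponential mean, ms)              684.856
  implied mean RT (mu + tau)             1668.660
  implied SD (sqrt(sigma^2+tau^2))        689.237
  log-likelihood                       -38144.454
```

The recovered tree is exactly the planted star: every non-hub node is a
leaf (leaf fraction 1), any two leaves are two hops apart (diameter 2),
the hub carries every shortest path (BC_max 1) and hubs attach only to
degree-1 nodes (R = −1). The ex-Gaussian fit recovers the generating
parameters to within sampling error at n = 5000.

The cohort-level entry point is `run_group_pipeline`, which takes a
list of `SubjectData` (recording + reaction times + covariates) and
returns tidy per-subject, group-comparison and brain–behaviour
correlation tables. A thin CLI wraps the same functions:
`eegmst simulate | pli | mst | exgauss | groupstats`.

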