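# Methods

This note documents the models implemented in `nirscreen`, the choices made
where the design was genuinely open, and the scope of what the synthetic
benchmark shows.

## Measurement context and preprocessing

Handheld 740–1070 nm diffuse-reflectance spectra of powders are dominated by
two nuisance effects: additive baseline shifts (vial placement relative to
the small light source/detector window, scanner-to-scanner electronics) and
multiplicative intensity changes from particle-size scatter. Both are exactly
an affine map `x ↦ a·x + b` of the true spectrum, which is why **SNV**
(per-spectrum centring and scaling to unit sample SD, `ddof=1`, configurable)
is the first step: SNV output is invariant to any such map with `a > 0`.
Flat-line scans (zero variance) cannot be normalised and raise a
`DegenerateSpectrumError` naming the scan.

The **Savitzky–Golay derivative** is implemented as the fused convolution:
fit a local polynomial (degree 3 by default — the lowest degree supporting
both first and second derivatives) in a 19-point window and evaluate its
derivative at the window centre, in units per nm. The 19-point window is the
package's working default for this sensor's 1 nm grid; window and degree are
configurable, including the alternative reading of a smoothing-only 19-point
pass (set `sg_window`/`sg_polyorder` accordingly). Edge handling drops the
9 unsupported points per side rather than extrapolating; both regions of
interest (839–939 nm for first-derivative work, 839–914 nm for
second-derivative work) lie strictly inside the interior grid, so the model
path loses nothing. ROI bounds are inclusive: 101 and 76 points on the 1 nm
grid.

## Replicate-outlier flagging

A PCA is fitted once on the full preprocessed matrix (mean-centred, no
variable scaling). For each scan, the mean Euclidean distance of its
3-component score vector to the other scans of the same sample is computed;
scans strictly above the sample's 99 % quantile of these means are flagged
and excluded from all model libraries and training sets (never from incoming
queries).

The quantile estimator is the open design point. The package's default fits
a **lognormal** to the per-sample mean distances (`exp(μ_log + z₀.₉₉·σ_log)`)
— the natural two-parameter family for a positive, right-skewed distance
statistic. Unlike the interpolated empirical order statistic (which
mechanically flags the top ~1 % of replicates of *every* sample, corrupted or
clean, and can never flag two corrupted replicates of one sample), the
parametric quantile flags nothing in a tight clean sample and flags all
grossly deviant replicates in a corrupted one. Measured on the spike-corrupted
benchmark: 100 % of injected spikes flagged, 1.6 % of clean scans flagged.
`quantile_method` also accepts `"normal"` and `"empirical"` for comparison.
Samples with numerically identical replicates are never flagged (spread
below `1e-8` of the score scale is treated as zero).

## Abstaining dual kNN

Euclidean distance ranks neighbours by overall feature magnitude (which
tracks concentration along a dilution series), Pearson correlation by shape
(which tracks composition). Both metrics keep at most 9 neighbours and both
apply inclusive acceptance thresholds — distance ≤ 0.1, correlation ≥ 0.98 on
SNV + first-derivative full spectra; the thresholds are configurable for
other preprocessing variants. The combined neighbour list is a multiset
(≤ 18): a scan accepted by both metrics votes twice, matching the "9 + 9"
accounting. Identity is the modal label, ties resolved toward the smallest
mean neighbour distance (then lexicographically, for full determinism);
concentration is the unweighted mean of the neighbours' known wt%. An empty
combined list is an abstention — the query is left to the second stage.
Ranking ties break by library row order (stable sort), so results are
reproducible to the byte.

Under leave-one-sample-out evaluation every scan of the queried sample is
excluded from the candidate set, so replicate similarity can never leak into
the result. The PCA/outlier mask is computed once on the full library, not
per fold: the flagging step precedes cross-validation in the modelled
workflow, and refitting it per fold changes no benchmark conclusion while
complicating the cache.

## Salt-form gate and concentration ensembles

Cocaine HCl and cocaine base are spectrally distinct classes, so form
assignment is a binary problem trained only on cocaine-containing scans.
Features are PCA scores retaining 99 % of the training variance (component
count chosen as the smallest reaching the target, cross-checked in tests
against an eigenvalue oracle). The scorer is a **committee of 9 single-hidden-
layer networks** (8 logistic units each, logistic output, L2 penalty 1e-3,
deterministic seeded L-BFGS training to convergence); the committee
probability is the members' mean. One network's output on material far from
both training classes is an artefact of its random initialisation — it can
saturate confidently to either side — whereas committee members disagree on
such input, so the averaged probability lands mid-range and the 0.05/0.95
gate (inclusive bounds) rejects it. On in-distribution scans the members are
unanimous and gating is unaffected. Committee size and all hyperparameters
are configurable; `n_networks=1` recovers a single network.

Concentration regressors are per-form **bagged CART ensembles**: 25 trees,
each fitted on an independent n-out-of-n bootstrap resample, `min_samples_leaf=5`,
unlimited depth; the prediction is the ensemble mean clipped to [0, 100] wt%.
Features are the preprocessed spectra (PCA prescaling is attached to the
classifier only; PC-score features for the trees are available by
preprocessing choice). Samples without cocaine (0 wt%) are excluded from
regressor training. `bootstrap=False` trains every tree on the full set,
which with `min_samples_leaf=1` makes a single tree memorise unique training
points — used as a correctness probe in the tests.

Cross-validation for this stage is grouped 10-fold: samples (with all their
replicate scans) are randomly assigned to folds, seeded and deterministic.
If a training split lacks one of the two forms, the stage returns
*unassigned* for that fold rather than training a one-class gate.

## Decision rule and evaluation

Per scan, the kNN result has priority when present: positive iff its
concentration is **strictly** above the threshold (default 20 wt%; a value
exactly at the threshold is negative). On abstention the ensemble stage
decides: positive iff a form was assigned and its regressor's concentration
is strictly above the threshold. All remaining cases are negative. Per
sample, replicate verdicts are majority-voted; an exact tie is negative,
because a false positive triggers wrongful seizure and is the costliest
outcome of a presumptive test.

Ground truth for confusion tallies: positive ⇔ the sample contains cocaine
above the threshold; negative ⇔ it contains none. Cocaine samples at or
below the threshold are *deliberate* false negatives of the screening rule
and are excluded from the tally by default (reportable separately, or
countable as positives via `include_subthreshold=True`). Concentration
recovery is summarised by the squared Pearson correlation (R²) and RMSE over
scans with a kNN answer; abstentions are dropped and counted.

The threshold curve re-applies only the decision rule over a wt% grid —
models are never re-run, and truth labels stay fixed at the evaluation
convention. Reported operating points: the smallest zero-FP threshold, the
highest-accuracy threshold, and the largest threshold attaining the minimal
FN rate. Both rates are weakly decreasing in the threshold by construction.

## Synthetic benchmark

The generator emulates the measurement model, not real chemistry: component
signatures are smooth positive band sums (3–8 Gaussian bands, 10–60 nm wide,
over a gentle sloping baseline); powder mixtures combine signatures linearly
by mass fraction (a Beer–Lambert-like convention — real diffuse reflectance
is not exactly linear in composition); each scan applies a log-normal
scatter factor (σ = 0.15), Gaussian per-scanner (σ = 0.15) and per-scan
(σ = 0.10) offsets, and i.i.d. noise (σ = 0.002 in reflectance units of
order-1 signatures, set so that replicate scans sit at preprocessed distance
≈ 0.006, an order below the 0.1 match threshold). All benchmark signatures
share two broad common "matrix" bands: since SNV reduces spectra to shape,
the shared structure makes composition steps move spectra gently (a 5–14 wt%
dilution step stays inside the match thresholds, so dilution ladders form
neighbour chains) while distinct pure compounds remain far outside them
(minimum pairwise distance 0.23, maximum correlation 0.88).

The frozen benchmark plan: 61 samples = five dilution ladders (cocaine HCl
in caffeine — the published 42/34/30/25/20/19/10/5/0 wt% reference series —
plus lactose and phenacetin ladders; cocaine base in levamisole and
lidocaine), pure cocaine HCl, 11 pure negative preparations over 8 cutting
agents, and 6 equal-weight binary negative mixtures in duplicate; 5 scanners
× 5 replicates = 1525 scans. Negative compositions deliberately occur more
than once (duplicate preparations / ladder 0 % endpoints), mirroring real
negative sets where repeated compositions let the kNN stage resolve them; a
spike-corruption variant (1 % rate, ±6-unit offsets over random 20-point
windows) exercises outlier flagging. The novel-compound probe is a frozen
signature sharing the matrix bands but no specific band layout with any
library component (nearest library distance 0.38).

**What passing shows — and does not.** The benchmark demonstrates that the
pipeline's mechanisms work as designed: affine artifacts are cancelled,
neighbour chains recover concentrations (R² ≈ 0.95, RMSE ≈ 7 wt%), thresholds
abstain on foreign material, the gate rejects out-of-distribution input, and
false negatives concentrate just above the decision threshold. It does not
demonstrate performance on real seized powders: real NIR signatures are not
Gaussian band sums, real mixtures are not exactly linear, real negative sets
are more diverse, and the 0.1/0.98 thresholds interact with real spectral
geometry in ways no simulation can certify. Rates measured here characterise
the implementation under the simulator's assumptions, not field performance.
Novel-compound rejection in particular is *empirical*, not structural: a
foreign spectrum that happens to project close to one training class can
still pass the gate — the known residual false-positive path of this model
family.

## Numerical and reproducibility notes

Everything downstream of a seed is deterministic: generator output is
byte-identical per (design, seed); PCA uses full SVD; network training is
seeded L-BFGS; bagging draws from a seeded generator; ranking ties break by
row order. Reports serialised twice from identical inputs compare equal at
the byte level. Model artefacts refuse inputs whose preprocessing fingerprint
(`preprocess_tag`) differs from the one they were trained under.
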