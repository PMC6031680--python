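# Methods

This package re-implements, as a tested pipeline over synthetic data, a
source-level weighted functional-network analysis of Go/NoGo EEG: phase
locking between cortical nodes per frequency band, weighted graph indices
at the global and nodal level, and covariate-adjusted comparisons across
three childhood-trauma groups. This note documents the models, the
parameter choices, and what the synthetic experiments do and do not show.

## Signal model of the synthetic cohort

On trial *k*, node *i* carries a band-limited oscillation

    x_ik(t) = A cos(2 pi f t + theta_k + eps_ik) + n_ik(t),

with a common trial phase `theta_k ~ Uniform(-pi, pi]`, wrapped-normal
per-node phase jitter `eps_ik ~ WN(0, sigma_i^2)` independent over nodes
and trials, and white amplitude noise `n`. Because the common phase
cancels in every pairwise difference, the across-trials phase-locking
value has the closed form

    PLV_ij = E|exp(i(eps_i - eps_j))| = exp(-(sigma_i^2 + sigma_j^2)/2).

Wrapped-normal jitter (rather than von Mises) was chosen precisely for
this closed form: `sigma` is an analytic dial for coupling, and every
downstream stage can be checked against `expected_plv`. Jitter is
per-node; an optional correlated-jitter mode (a node-by-node correlation
matrix for `eps`) provides per-edge structure via a Gaussian copula, with
expected PLV `exp(-(s_i^2 + s_j^2 - 2 r_ij s_i s_j)/2)`.

### Study conditions (generator defaults)

| parameter | default | rationale |
|---|---|---|
| trials | 300, 80% Go / 20% NoGo | the emulated task design |
| epoch window | -100..900 ms, half-open | stimulus-locked ERP convention |
| sample rate | 1000 Hz (`SimConfig`); 250 Hz in the replicate experiments | desk-scale economy; all bands sit far below either Nyquist rate |
| carrier | 15 Hz | centre of the low beta band (12-18 Hz), the band with the strongest published group effect |
| amplitude / noise | 10 uV / 1 uV | tens-of-microvolt cortical signals; high SNR so phase jitter, not additive noise, controls coupling |
| group jitter sigma | 0.90 / 0.915 / 0.938 rad | plants an expected low-vs-high PLV gap of 0.03, the upper edge of the 0.02-0.03 calibration band implied by the published group means |
| between-subject sigma SD | 0.025 rad | maps to a between-subject PLV SD of ~0.02, matching the magnitude of the published between-subject SDs (0.02-0.06) |
| accuracies | Go 0.94, NoGo 0.88 | published hit/false-alarm rates; leaves ~48 usable correct NoGo epochs of 60 |

Trauma-questionnaire totals are drawn per group from truncated normals
with the published group means/SDs (low 31.4 +/- 2.1, middle 40.4 +/- 3.6,
high 60.2 +/- 10.0) on disjoint ranges, so the 25%/75% quartile split
re-derives the generative groups up to boundary subjects. Subscale scores
split the total minus the 5-point floors by a Dirichlet draw weighted
toward emotional neglect, capped at 25 each. Psychological covariates
(SAI, TAI, BDI, BIS, CAARS, BIS/BAS) are Gaussian around group-graded
means taken from the published descriptives — their *direction*
(anxiety/depression/ADHD scores increase with trauma load) is the modeled
property; the absolute levels are illustrative.

What the generator does **not** emulate: ERP morphology (no N2/P3 peaks),
volume-conduction leakage patterns, ocular or movement artifacts,
non-stationary coupling within the epoch. Passing tests therefore show
that the pipeline recovers phase-coupling structure it is pointed at, not
that it would be robust to those real-data complications.

## Preprocessing

Zero-phase (forward-backward) 4th-order Butterworth filtering — causal
filtering would shift phases inside the analysis window. Epochs use the
half-open convention `[tmin, tmax)`, so a -100..900 ms epoch at 1000 Hz
has exactly 1000 samples. The +/- 75 uV rejection rule is read strictly
(a sample exactly at the threshold survives); the boundary behaviour is a
convention, not a derivable fact, and is documented as such. A simple
EOG-regression helper exists for real recordings; no ICA, re-referencing,
or channel interpolation.

## Source estimation

The minimum-norm inverse `W = G^T (G G^T + lambda^2 I)^-1` with a
synthetic lead field: dipoles with seeded random fixed orientations on a
unit sphere, sensors on an outer shell, inverse-square kernel,
unit-normalized columns. An anatomically meaningful head model cannot be
rebuilt without its template assets, and nothing downstream depends on
anatomy — the inverse is exercised through round-trip tests (row-space
sources recovered with correlation > 0.9, single active sources localized
by the power argmax). Default regularization
`lambda^2 = tr(GG^T)/(n_sensors SNR^2)` with SNR 3; no depth weighting or
noise-covariance whitening. Node reduction uses deterministic
farthest-point sampling: the source nearest the centroid seeds the
distance field, each pick maximizes the minimum distance to the chosen
set, ties break to the lowest index. Node series are vertex picks, not
patch averages.

## Connectivity

PLV in the across-trials convention: resultant over trials at each
sample of the 200-700 ms post-stimulus window, then averaged over window
samples. This is the standard form for event-locked data, but since the
averaging order is a convention, a within-trial-over-time mode is
available behind a flag. Band filtering runs over the whole epoch before
cropping, keeping filter/Hilbert edge transients outside the window.
Bands: alpha 8-12, low beta 12-18, high beta 18-30, gamma 30-55 Hz; delta
and theta are excluded because the 500 ms window holds only one or two of
their cycles, which biases phase-locking estimates. A single trial under
the across-trials convention gives PLV = 1 identically and is rejected
with guidance. No leakage-corrected variants (imaginary coherence, PLI,
wPLI) — parity with the emulated analysis.

## Graph indices

Weights are used directly (no thresholding). Strength is reported
globally as the **mean** nodal strength: on a complete n-node PLV graph
this is (n-1) times the mean weight, the only reading consistent with the
published magnitudes (~179 on 314 nodes alongside a clustering of ~0.57).
Clustering is the Onnela geometric-mean-of-triangles form without
max-weight renormalization (renormalizing would force C = 1 on every
uniform graph). Path length and efficiency use edge lengths `1/w`
(`-log w` available) with Floyd-Warshall all-pairs distances — chosen
over Dijkstra so results are bit-identical to an enumeration oracle with
the same update order. Uniform complete graphs pin the contract:
`(S, C, L, E) = ((n-1)w, w, 1/w, w)`. A disconnected graph raises for L
(PLV graphs are complete in practice) and contributes zero inverse
distance to E.

## Statistics

Groups: low `<= Q1`, high `>= Q3`, quartiles by inclusive linear
interpolation; boundary ties go to the outer groups. The published
multivariate ANOVA with covariates is implemented as per-index ANCOVA
(GLM with the group factor plus SAI/TAI/BDI/CAARS), since the published
results are reported per index; a Wilks-lambda multivariate test is
available. Effect size is partial eta squared
`SS_group / (SS_group + SS_error)`. Bonferroni families: 16 global tests
(4 indices x 4 bands, threshold 0.003125), one test per node at the nodal
level (0.05/314 = 0.000159 at full scale), 60 correlation tests
(0.000833); the family sizes are configurable because the full-scale
enumeration is a study-design fact, not a derivable one. Post-hoc
pairwise contrasts multiply p by 3 and cap at 1. Partial correlations
residualize both variables on the covariates (always including an
intercept) and use t on `n - k - 2` degrees of freedom. ANOVA power comes
from the noncentral F with `lambda = f^2 n`; the published power figure
does not state its effect-size metric, so power is provided as a tool,
not asserted as a reproduction.

## Replicate experiments and problem sizes

The validation experiments (`plvnet.experiments`) run at desk scale:
15/25/15 subjects, 20 nodes, 48 NoGo trials, 250 Hz, chosen so a
100-replicate experiment costs minutes on one CPU while preserving every
qualitative property of the full-scale design. Two operating
characteristics are measured: (i) family-wise type-I error of the whole
chain on null cohorts (no jitter difference), which must stay at the
nominal 5% of the 0.003125-per-test family; (ii) recovery of the planted
trauma effect — all four global indices in the published direction and
the low-vs-high contrast significant at 0.05 — in at least 80% of
replicates.

The recovery contrast is **unadjusted**: the synthetic covariates are
group-correlated confounder proxies with no direct influence on the
network metrics, so partialling them out of a group contrast only
inflates its variance; the experiment asks whether the planted
physiological effect is detected. The pipeline's statistics stage, by
contrast, always adjusts — and at this desk scale (14 vs 14 after the
quartile split) the adjusted omnibus tests do *not* clear the 0.003125
threshold, as the worked example's report shows honestly. The full-scale
published contrast has three times the subjects and 314 nodes of
averaging; detecting the same gap there is a strictly easier problem.

The planted-partial-correlation check builds covariates, a trauma-score
analog loading on them, and a clustering analog loading on both the
covariates and the trauma score's covariate-orthogonal component with
partial correlation -0.285 (the published effect magnitude). The
construction orthonormalizes in sample, so the planted value is the
realized sample value and the check isolates estimator correctness: at
n = 150 the sampling SD of a partial r near -0.3 is ~0.075, and a purely
stochastic plant would fail a +/-0.1 band one run in five by chance
alone. The naive Pearson correlation on the same data is confounded away
from the planted value, which the check also asserts.

## Numerical conventions

* PLV matrices are symmetrized, clipped to [0, 1], zero diagonal; they
  round-trip through delimited text bit-exactly (`%.17g`).
* All randomness flows from one root seed through fixed spawn keys;
  fixed-seed pipeline runs are byte-for-byte reproducible, and stage
  re-runs from persisted intermediates reproduce downstream artifacts
  exactly.
* Floyd-Warshall distances make L and E bit-reproducible against the
  enumeration oracle; Dijkstra agreement is asserted to 1e-12 instead.
* The noncentral F is undefined at zero noncentrality; power falls back
  to the central F there (giving exactly alpha).

## Known limitations

* The synthetic lead field is geometrically plausible but anatomically
  meaningless; nodal findings have no region labels.
* Single-carrier signals mean only one band carries coupling structure;
  the other bands sit at the finite-trial PLV noise floor (~0.13 at 48
  trials), which is itself a useful null but not a multi-band coupling
  model.
* PLV leakage through the inverse (spurious zero-lag locking between
  reconstructed nodes) is present, as it is in any minimum-norm
  pipeline without leakage correction; the generator's ground truth
  makes it visible but the pipeline does not correct it.
* Between-subject heterogeneity enters only through sigma; real cohorts
  vary in amplitude, SNR, and usable trial counts too (trial counts do
  vary here via the accuracy model).
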