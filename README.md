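# plvnet

Source-level phase-locking network analysis of Go/NoGo EEG, built around a
synthetic phase-coupled cohort generator.

## The problem

Individuals with a history of childhood trauma show altered cortical
functional networks during response inhibition. The analysis this package
implements quantifies that claim with EEG: during the NoGo-P3 window
(200–700 ms after a withheld response), node-level cortical time series
are band-limited, their pairwise **phase-locking values**

  PLV_ij = mean over window samples t of | (1/N) Σ_k exp(i(φ_i,k(t) − φ_j,k(t))) |

form a weighted adjacency per subject and frequency band (alpha 8–12,
low beta 12–18, high beta 18–30, gamma 30–55 Hz), and four weighted graph
indices summarize each network:

* **strength** — mean over nodes of s_i = Σ_j w_ij,
* **clustering** — mean Onnela coefficient
  C_i = Σ_{j≠h} (w_ij w_ih w_jh)^{1/3} / (k_i(k_i−1)),
* **characteristic path length** — mean shortest-path distance with edge
  lengths 1/w,
* **global efficiency** — mean inverse shortest-path distance.

Subjects are split into low/middle/high trauma groups at the 25%/75%
quantiles of their Childhood Trauma Questionnaire total, and the indices
are compared by ANCOVA with anxiety, depression and ADHD scores as
covariates, under Bonferroni control (0.05/16 = 0.003125 globally,
0.05/314 per node, 0.05/60 for partial correlations of nodal clustering
with trauma measures).

Raw study EEG of this kind is not publicly deposited, so the package is
exercised end to end on a **synthetic cohort**: node signals
cos(2πft + θ_k + ε_ik) with a shared trial phase and wrapped-normal
per-node jitter ε of group-dependent scale σ, for which the expected PLV
has the closed form exp(−(σ_i² + σ_j²)/2). The high-trauma analog gets
larger jitter, hence weaker coupling — the published effect direction —
and every stage can be validated against the analytic law. See
`docs/methods.md` for the full model and parameter rationale.

## Worked example

The numbered drivers under `analysis/` run the study on the default
synthetic cohort (55 subjects, 20 nodes, 300-trial sessions, 32 synthetic
sensors) and write their tables under `results/pipeline/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_preprocess.py
...
python analysis/07_report.py
```

Stage 04 prints the group-resolved coupling (the 15 Hz carrier sits in
low beta; the remaining bands show the 48-trial PLV noise floor):

```
mean PLV by band and group:
group_label    low  middle   high
band
alpha        0.168   0.168  0.165
gamma        0.135   0.138  0.135
high_beta    0.134   0.137  0.134
low_beta     0.470   0.462  0.449
```

and stage 05 the low beta indices, which move exactly as the trauma
gradient plants them — strength, clustering and efficiency decrease, path
length increases:

```
group_label    low  middle   high
index
clustering   0.466   0.457  0.444
efficiency   0.471   0.462  0.449
path_length  2.203   2.254  2.324
strength     8.939   8.776  8.523
```

Stage 06 reports the covariate-adjusted omnibus tests (low beta
F ≈ 1.9–2.0, partial η² ≈ 0.076 at this desk scale — consistent effect
sizes that do not clear the 0.003125 threshold with 14 subjects per outer
group; the replicate experiments below quantify detection properly), and
stage 07 renders `report.md` with the mean ± SD tables per band and
index.

The same pipeline is scriptable (`plvnet run-all --seed 1 --outdir run/`)
and usable as a library: `SimConfig`/`generate_cohort`, `band_plv`,
`global_metrics`, `ancova_group_test`, `partial_correlation`, …

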