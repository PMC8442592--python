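# lscpm — connectome-based prediction of life satisfaction

`lscpm` is a tested, reusable implementation of the connectome-based
predictive modeling (CPM) protocol for a continuous psychological trait —
here life satisfaction (LS), a core facet of subjective well-being — from
resting-state functional connectivity. It is written for neuroimaging
researchers who want the full protocol as an importable, seeded, unit-tested
library rather than a one-off analysis script: every stage from raw ROI time
series to network-level enrichment is a plain Python function with explicit
contracts, and a synthetic cohort generator with planted, known signal makes
the whole pipeline testable without access to any restricted dataset.

## The method

**Connectome construction.** Each subject's ROI time series (R regions,
e.g. the 427-ROI atlas: 400 cortical parcels + 17 subcortical + 10
cerebellar) is post-processed by dropping the first 10 s, regressing out
20 nuisance signals (intercept, linear trend, 6 rigid-body motion
parameters, mean white-matter/ventricle/gray-matter signals, and the
temporal derivatives of the 9 signal regressors), band-pass filtering at
0.008–0.1 Hz (zero-phase 4th-order Butterworth), and censoring frames with
framewise displacement FD > 0.5 mm, where

FD_t = Σ|Δd_t| + 50 mm · Σ|Δθ_t|

over the three translations d and three rotations θ. Pearson correlations
between all ROI pairs are Fisher-transformed, z = atanh(r), and the strict
lower triangle is vectorized into E = R(R−1)/2 edges (90,951 for R = 427),
giving an n × E feature matrix.

**Prediction.** PCA reduces the discovery feature matrix to K = n−1
components (99 for n = 100). Ridge regression on the PC scores,

min_β Σᵢ (yᵢ − b − βᵀsᵢ)² + λ‖β‖²,

is fit with 10-fold cross-validation; λ is chosen per outer fold by an inner
5-fold CV that never touches the outer test fold. Discovery performance is
the Pearson r between out-of-fold predictions and actual scores; external
validation projects a held-out cohort through the *discovery* PCA and
averages the 10 fold models' predictions. Significance comes from a
permutation test (default 5000 iterations) that shuffles y and refits the
entire CV pipeline, with p = (1 + #{r_null ≥ r_obs}) / (1 + n_perm).

**Interpretation.** Since PCA and ridge are both linear, each fold model is
exactly equivalent to edge-space weights w_f = T β_f (T the E × K PCA
transformation matrix), giving 10 weights per edge. One-sample t-tests
across folds with Bonferroni correction over E edges flag consistently
contributing edges, split by sign; an upper-tail hypergeometric test over
the 45 network pairs (9 within + 36 between, for nine resting-state
networks: Vis, Somat, DAN, VAN, Limb, FP, DMN, BG, CER) locates where each
sign's edges concentrate, Bonferroni-corrected at α = 0.025/45 per sign.

## Worked example

`examples/03_fit_and_validate.py` generates a 160-subject synthetic cohort
with 30 planted trait-coupled edges among 780 (R = 40), fits on the first
100 subjects and validates on the remaining 60:

```
PCA: 99 components from 100 subjects x 780 edges
discovery out-of-fold r = 0.798 (n=100)
validation r = 0.880 (n=60)
```

The out-of-fold r says the 10-fold CV models predict unseen discovery
subjects' trait scores; the validation r says the averaged fold models
transfer to a cohort that contributed nothing to the fit — the
generalization claim at the heart of the protocol. With the planted effect
set to zero both correlations collapse to chance, and the permutation test
(`examples/04_permutation_test.py`) does not reject:

```
planted signal  observed r = +0.790, null mean = -0.085, p = 0.010
no signal       observed r = +0.118, null mean = -0.091, p = 0.070
```

The other examples cover cohort simulation with motion spikes
(`01_simulate_cohort.py`), the preprocessing chain step by step
(`02_preprocess_connectome.py`), edge contributions and network enrichment
(`05_edge_contributions.py`), and the end-to-end driver with its provenance
manifest (`06_run_all.py`). A thin CLI mirrors the stages:

```bash
lscpm run-all --smoke            # tiny end-to-end run
lscpm simulate --config my.yaml  # or stage by stage
lscpm preprocess ... ; lscpm fit ... ; lscpm permute --stage discovery ...
```

### File formats

Per-subject inputs are TSV: time series (header of ROI names, T × R),
motion (units comment line, 6 named columns, translations in mm and
rotations in radians), tissue signals (3 named columns), plus a cohort
`subjects.tsv` (`subject_id`, `ls`), an atlas table
(`roi_index` 1-based, `roi_name`, `network` — exactly the nine network
labels), and a `truth.json` with the planted edge indices for synthetic
cohorts. All outputs (feature matrix, predictions, null distributions,
edge and enrichment tables) are TSV/JSON with fixed float formatting, so
equal configs and seeds reproduce every file byte for byte.

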