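# Methods

This note documents the models, conventions and numerical choices behind
`metabopipe`, the parameters that matter, what the synthetic-data generator
does and does not emulate, and the known limitations.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model

A `MetaboDataset` holds a features × samples intensity matrix, per-sample
metadata (`class` ∈ {Subject, QC, Blank}, `group`, `batch`,
`injection_order`), per-feature metadata (m/z in Da, RT in seconds,
polarity), attached MS2 spectra, and an append-only operation log.  Two
conventions are load-bearing:

* **Missing is a marker, never zero.**  A zero peak area means "not
  detected"; by default zeros in input tables are converted to the missing
  marker (NaN).  All missing-rate rules downstream depend on the
  distinction between absence and low signal, so imputation and
  normalization are forbidden from conflating them: imputation never
  alters observed entries, normalization preserves the missingness
  pattern.
* **RT is stored in seconds.**  Readers auto-detect minute-scale columns
  (maximum ≤ 120 is read as minutes, since >2 h gradients in minutes are
  unheard of) and log the decision; an explicit override flag exists.

Checkpoints are versioned JSON containers (`metabopipe-checkpoint/1`).
Floats are serialized as C99 hex strings so the matrix round-trips
bitwise; a truncated file or an unknown schema id raises a typed error
rather than being guessed at.  Each pipeline stage appends exactly one log
entry (stage, parameters, before/after counts), which is what makes the
`run --resume-from` contract auditable.

## Cleaning

Stage order in the default pipeline: noise filter → outlier triage →
KNN imputation → SVR drift correction → batch integration.  Rates are
always computed on the un-imputed matrix.

**Noise filter.**  A feature is removed iff its missing rate among QC
samples exceeds `qc_thresh` (default 0.2) OR its missing rate exceeds
`group_thresh` (default 0.2) in *every* study group.  The every-group
reading is deliberate: in heterogeneous designs (tissues, time points,
mutant panels) a metabolite cleanly detected in one group is biology, not
noise.  Thresholds are strict inequalities — a rate of exactly 0.20 is
kept.  The filter is monotone: raising either threshold never removes
more features.

**Outlier triage.**  Subject samples are partitioned by missing rate:
keep (< 0.5), review (0.5–0.8, closed interval), remove (> 0.8).  Removal
is a separate explicit call (`drop_samples`) because the review band is a
judgement call the analyst must make; the triage itself never mutates the
dataset.

**KNN imputation.**  For a missing entry (feature f, sample s) the
imputed value is the mean of the observed values in sample s of the k
(default 10) features nearest to f.  Nearness is the mean squared
difference between log2(x+1) profiles over the samples where both
features are observed — the per-sample scaling makes short overlaps
comparable to long ones when the missingness pattern is uneven; with a
complete matrix it ranks identically to plain Euclidean distance.
Neighbours missing in the target sample are skipped in favour of the next
nearest; a feature with no usable neighbour falls back to its own mean.
Features that are 100% missing must be filtered first (error otherwise).

**SVR drift correction.**  Per feature and per batch, a radial-kernel
support-vector regression (C = 1, ε = 0.1, γ = sklearn's `scale`
heuristic — fixed and logged for determinism) of log2 QC intensity on
injection order models the drift curve; every sample in the batch is
corrected by `raw × median(QC raw) / predicted(order)`.  Predictions
below `1e-6 × median` fall back to the median, guarding against wild
extrapolation at the batch edges.  A per-feature guard keeps the raw
values whenever the correction would *raise* that feature's QC RSD within
the batch, so the median QC RSD cannot increase.  The covariate is
injection order alone; correlated-feature ensembles (as in some QC-based
normalizers) are a possible extension but need more QC injections than
small batches provide.  At least 5 QC samples per batch are required; with
fewer, the error message points at `normalize_median_fold`, a QC-free
median fold-change fallback.

**Batch integration.**  Per feature, each batch is rescaled so its QC
median equals the global QC median; single-batch input is a logged no-op.
On a drifted multi-batch fixture the combination of SVR + integration
drives the batch silhouette of the QC samples below 0.1 (they stop being
separable by batch in PCA space), which the acceptance script measures.

## Annotation

Candidate generation is MS1: for each feature, every library record is
tried under the supported adducts ([M+H]+, [M+Na]+, [M+NH4]+, [M−H2O+H]+,
[M−H]−, [M+HCOO]−; charge sign must match the feature's polarity) and a
hit requires |ppm error| ≤ `ppm_tol` (default 25 ppm — configurable, and
worth tightening on well-calibrated instruments).

MS2 similarity is the cosine of square-root-intensity vectors with greedy
one-to-one fragment pairing within `frag_tol_da` (default 0.02 Da):
candidate pairs are sorted by |Δm/z| and consumed nearest-first, each
fragment used once; unpaired fragments contribute zero to the other side.
The score is symmetric, lies in [0, 1], and is invariant to uniform
intensity scaling.  Square-root weighting is the standard compromise that
keeps base peaks from dominating while still weighting by abundance.

MSI levels: level 1 = m/z + RT + MS2 evidence, level 2 = m/z + MS2,
level 3 = m/z only.  RT evidence requires the library record to carry an
RT and |ΔRT| ≤ `rt_tol_s` (default 30 s); MS2 evidence requires a score ≥
`ms2_score_min` (default 0.5).  m/z + RT without MS2 stays level 3:
retention time alone is too weak to lift a bare mass match.  Evidence can
only upgrade a record, never downgrade it.

`total_score` is the weighted mean of the evidences present (m/z 0.25,
RT 0.25, MS2 0.5, renormalized over what is available; each evidence is
scored 1 − |error|/tolerance, MS2 by its cosine).  Deduplication keeps,
per feature, the record with the highest total score; ties break by more
confident MSI level first (level 1 beats level 2 beats level 3), then
smaller |ppm|, then compound id — deterministic under input reordering.
Distinct features sharing one annotation are all preserved by default
(isomers and in-source artefacts are indistinguishable at this stage); a
`best_feature` strategy exists for strict one-compound-one-feature
exports.

## Differential statistics and enrichment

Tests run per feature on log2(x+1) intensities: Welch's unequal-variance
t-test (chosen over Student's t — metabolite variances are rarely equal
across genotypes) or the Wilcoxon rank-sum alternative, with
Benjamini–Hochberg FDR across the feature family (Bonferroni and BY
available).  Fold change is reported on the raw scale,
log2(mean_a/mean_b), matching how peak-area changes are communicated.
Zero-variance features get p = 1 and a flag.  The null calibration of the
Welch path (fraction of p < 0.05 on same-distribution groups ≈ 5%) is
checked by the acceptance script on 40,000 simulated features.

VIP comes from a PLS-DA fit (NIPALS, 2 components, y = group indicator)
on unit-variance-scaled log2 data restricted to the two compared groups —
using only those samples keeps the projection aligned with the contrast
being tested.  VIP_j = sqrt(p · Σ_a SSY_a w²_ja / Σ_a SSY_a) with
normalized weight vectors, so the mean squared VIP equals 1 by
construction (asserted to 1e-8 in tests).  OPLS-DA is deliberately out of
scope: for a two-group DAM criterion PLS-DA VIP plays the identical role
and is simpler and deterministic.

DAM selection returns per-criterion membership (|FC|, FDR, VIP) plus all
intersections, ready for UpSet-style reporting.  Enrichment is the
upper-tail hypergeometric test P(X ≥ k) with population N = |universe|,
term size n, selection size m, overlap k, BH across terms, and the
reported ratio k/n.  The default universe is the annotated metabolites of
the dataset, not the whole library — enrichment against compounds that
could never have been selected inflates significance.

## Iterative WGCNA

Round structure: (1) soft threshold β chosen once in round 1 as the
smallest power whose signed scale-free fit R² ≥ 0.8 (log10 frequency vs
log10 binned connectivity, 10 bins; argmax if none qualifies) and then
held fixed so later rounds stay comparable; (2) unsigned adjacency
|cor|^β (a signed option exists); (3) TOM; (4) average-linkage clustering
of 1 − TOM with a static cut at 0.995 × the dendrogram height, clusters
below `min_module_size` (default 10) going grey; (5) eigenmetabolite per
module = first left singular vector of the z-scored module submatrix,
sign-flipped so its mean correlation with members is positive; modules
whose eigenmetabolites correlate above 1 − `merge_cut` (default 0.75) are
merged and recomputed; (6) kME = cor(feature, eigenmetabolite); features
that are grey or whose own-module kME < `kme_cutoff` (default 0.5) are
dropped and the loop repeats, terminating when nothing is dropped (the
feature set strictly decreases, so termination is guaranteed) or at
`max_rounds` (then flagged unconverged).

The static cut was chosen over dynamic-hybrid tree cutting: it is
deterministic, two lines of code, and recovers planted partitions in
tests because the iteration itself supplies the robustness that dynamic
cutting provides in a single-shot analysis — features a static cut
mis-handles are dropped by the kME rule and the remainder re-clustered.
Dynamic-hybrid remains a sensible future extension.  Pearson correlation
is used throughout; biweight midcorrelation is out of scope.

Hub metabolites are members with kME strictly above `hub_kme`
(default 0.8; a kME of exactly 0.8 is excluded).  The kME cutoff for
dropping (0.5) is deliberately distinct from the hub threshold: the first
is an iteration control, the second a reporting definition.  Module
labels follow the conventional color sequence ordered by module size;
`export_network` emits per-module edge lists (weight = TOM) and node
tables (kME, hub flag) in deterministic order for Cytoscape/Gephi.

On the planted-partition benchmark (5 modules × 40 features, within-module
correlation 0.9, 100 noise features, 100 samples) the loop recovers the
planted labels with adjusted Rand index ≥ 0.9 and drops ≥ 90% of the
noise, across seeds; the acceptance script recomputes this.  On a noisier
cohort-scale fixture (12 modules × 30 at correlation 0.85 with MNAR
dropout, 206 samples) the members the kME rule discards go grey rather
than astray: assignment quality among kept features stays at ARI ≈ 1
while overall recall drops with the noise level — the expected trade-off
of the drop-and-recluster design.

## Pseudotargeted matching

MRM selection takes, per feature with MS2, precursor = feature m/z and
product = the most intense fragment below precursor − 3 Da (the margin
excludes the unfragmented precursor; ties go to the larger m/z, which is
usually the more specific fragment).  Features without a qualifying
fragment are reported, not dropped.

Cross-run classification uses the windows: precise = precursor < 100 ppm,
product < 20 ppm, ΔRT < 30 s; rough = precursor 100–1,000 ppm with the
same product/RT gates.  An A-feature counts as matched if one or more B
partners qualify; both the per-A summary and the full pair list are
emitted.  ppm denominators use the reference (A) m/z — the convention is
stated in output headers because at 1,000 ppm the choice is no longer
negligible.  Cross-platform consensus (30 ppm / 30 s gates) uses greedy
nearest-first 1:1 pairing under the combined normalized distance
(mean of ppm/30 and ΔRT/30); greedy rather than optimal bipartite
matching because it is deterministic, O(n log n), and the gates are tight
enough that the two rarely differ.

## Synthetic data generator

`simulate_dataset` emulates the statistical structure each stage assumes:
log-normal baselines (log2 means uniform in [12, 20], residual σ = 0.5);
planted modules driven by shared latent factors with loading
σ·sqrt(w/(1−w)) so the expected within-module correlation is w; pooled-QC
samples injected every `qc_every` runs as the mean profile + technical
noise (σ = 0.1 in log2); per-batch multiplicative drift
1 + slope × injection order; missingness as MCAR plus MNAR with dropout
probability logistic in −log2 intensity centred on the 10th intensity
percentile — the low-abundance dropout that dominates real LC–MS
missingness and that the QC-rate filters presuppose.  One seed governs
everything through deterministically spawned substreams.

`simulate_library` plants MSI evidence tiers: level 1 records share mass,
RT and an MS2 spectrum with their feature; level 2 share mass and MS2 but
no RT; level 3 mass only; decoys sit ≥ 50 ppm from every feature under
every supported adduct.  The annotate→recover closed loop is exact by
construction and is what the acceptance script measures.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: chromatographic peak shapes and co-elution,
in-source fragmentation (a known annotation confound), correlated
missingness between isotopologues/adducts of one compound, heavy-tailed
intensity noise, RT drift (only intensity drift is modelled), and real
spectral similarity structure (library spectra are random fragment sets,
so the MS2 score threshold is exercised only at its extremes).

## Problem sizes

Defaults were sized so the whole suite and the acceptance script each run
in well under a minute of CPU on one core: planted-partition benchmarks at
300–460 features and 100–206 samples, the null calibration at 40,000
features, match oracles at 500 features.  These sizes give the stochastic
checks comfortable margins (binomial SE of the type-I rate at n = 40,000
is ≈ 0.1 percentage points) without needing cohort-scale matrices.

## Known limitations

* No raw-signal (mzML/mzXML) peak picking; the pipeline starts at the
  peak table.
* No in-source-fragment detection or removal; redundant annotations from
  fragments survive deduplication if they score well.
* No LOESS/quantile normalization alternatives; SVR and median-fold only.
* Level-3 annotation by mass alone is intrinsically error-prone; the
  default 25 ppm tolerance is configurable and should be tightened when
  instrument calibration allows.
* The static tree cut can split large diffuse modules more readily than
  dynamic-hybrid cutting; the iteration compensates but module counts on
  borderline data are parameter-contingent (β, cut height, kME cutoff).
* Module–trait correlation against external phenotypes is out of scope;
  the eigenmetabolite matrix is exported so it can be done downstream.
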