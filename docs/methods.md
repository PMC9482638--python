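# Methods

This note documents the models, estimators and numerical choices behind
each module, what the synthetic-data generators do and do not emulate,
and the design decisions taken where the procedure was genuinely open.

## CRISPR screen scoring (`mmras.crispr`)

**Normalization and LFC.** Sample depths are equalized with
median-of-ratios size factors: for guides with nonzero counts in every
sample, factor_j = median_i(count_ij / geometric-mean_i). The guide-level
log2 fold change is log2((m̄_num + c)/(m̄_den + c)), where m̄ is the mean
normalized count across replicates within a group and c is a pseudocount
(default 0.5, configurable). Averaging replicates on the normalized-count
scale before the ratio — rather than averaging per-replicate LFCs — keeps
guides with a zero in one replicate well-behaved. This is a deliberately
simple LFC estimator; no shrinkage or dispersion modeling is applied,
because the downstream mode/RMSD normalization dominates the behavior of
the final score.

**Blocklisting.** The blocklist is applied to the count table before size
factors are estimated, so removed guides influence nothing downstream
(verified by a byte-identity test against pre-filtered input). Genes that
lose all guides are dropped, not imputed.

**Mode/RMSD normalization (CSS).** Gene-level LFCs are centered on the
argmax of a Gaussian KDE (Silverman bandwidth; 2,048-point grid spanning
the data range ± 3 bandwidths; argmax ties break toward the grid point
nearest the median) and divided by the root-mean-square deviation from
that mode with a 1/n denominator. Because the bandwidth and grid are both
equivariant under positive affine maps of the data, CSS is exactly
invariant to translation and positive rescaling of the input (tested to
1e−7 absolute). A minimum of 50 genes is required; mode estimation on
fewer points is unstable. Note that the argmax of a KDE on n = 20,000
standard-normal draws has sampling sd ≈ 0.075 — far larger than the grid
spacing — so "mode ≈ 0" holds only to that statistical, not numerical,
precision.

**Screen flavors.** FACS-sort screens score low vs high populations with
the same pipeline (positive CSS = enriched in the low sort); modifier
screens difference two CSS tables over their shared gene universe.

## Outlier detection (`mmras.outliers`)

The single-outlier extra sum-of-squares construction: reduced model = one
OLS line through all n points; full model = line + indicator for the
focal point, equivalent to fitting the focal point exactly and refitting
the line on the remaining n − 1 points. F = (SSE_red − SSE_full)/(SSE_full
/(n − 3)), p upper-tail F(1, n−3), one test per gene with no multiplicity
correction (each gene is screened at the nominal level; a
Benjamini–Hochberg flag is trivial to add downstream since p-values are
returned). `call_outliers` computes all leave-one-out SSEs at once by
exact rank-one downdates of the regression sufficient statistics; a test
verifies equality with an explicit two-model least-squares refit to
1e−10 relative. Direction: a gene above the fitted line (positive
vertical residual — anomalously negative x for its y) is called
A-selective, below the line B-selective. If the remaining points are
exactly collinear, F is reported as +inf for any off-line focal point and
0 for an on-line one.

## Interactome (`mmras.interactome`)

SILAC rows need ≥ 2 ratio counts (and no contaminant/decoy flag) to be
retained. Combination across baits/cell lines is an unweighted mean over
observed values with `n_observed` recorded — proteins detected in a
subset of experiments are kept rather than requiring full coverage.
Essential-interactome thresholds (CSS ≤ −1.0, log2fc ≥ +1.0) are
inclusive. Protein↔gene matching is by exact symbol. The differential
interactome reports a protein when |Δlog2fc| ≥ 0.5 in ≥ 2 cell lines with
no opposite-direction change of that size anywhere — a strict
sign-consistency reading; a mixed 2-up/2-down protein is not reported.

## Synergy and DTSEA (`mmras.synergy`)

Effects are E = 1 − V so positive excess means synergy. The per-matrix
aggregate is the **sum** of per-well excess over combination wells on the
×100 percent-effect scale (the matrix-screening convention; `agg="mean"`
is available). Viability is not clipped before scoring — values above 1
appear as negative effect. Single-agent margins (dose 0 row/column) are
required.

Pre-ranked enrichment is the classic weighted KS running sum: drugs
sorted by score descending (ties broken by name for determinism), hits
increment by |score|^w normalized to sum 1 over set members (w = 1
default), misses decrement by 1/(N − N_hit); ES is the extremum of the
running sum, so ES ∈ [−1, 1] by construction. The null permutes set
membership labels (random same-size subsets of the ranked universe),
n_perm = 1,000 by default with an explicit seed. NES divides ES by the
mean |null ES| of the same sign; nominal p is the same-sign tail
fraction; FDR q is the standard same-sign tail ratio of pooled null NES
vs observed NES, capped at 1. Sets whose overlap with the universe falls
below the minimum (3) are skipped.

## Signature and survival (`mmras.signature`)

Signature membership requires the timepoint-averaged log2fc to clear the
cutoff in **every** cell line; the boundary is inclusive (≤ −0.5), with a
`strict` flag for the strict reading. Sample scores are unweighted means
of member-gene log-scale expression, with ≥ 50% gene coverage required
and no within-gene standardization (none is part of the procedure being
implemented; scores enter the Cox model raw). Tertiles cut at the 1/3 and
2/3 empirical quantiles (linear interpolation) with ties assigned to the
lower group.

The Cox model uses the Breslow partial likelihood for the single
continuous covariate, maximized by Newton–Raphson to gradient < 1e−8
(steps clipped at ±5 per iteration; |β| > 50 flags monotone likelihood /
separation). The likelihood-ratio statistic 2(ℓ(β̂) − ℓ(0)) is referred
to χ²(1). Breslow ties were chosen over Efron for oracle simplicity; on
tie-free data the two coincide and the fit is cross-checked against an
independent survival library in the tests. The Kaplan–Meier estimator is
the plain product limit.

## PLA statistics (`mmras.pla`)

Nucleus-area filtering removes cells strictly below 750 px (the boundary
cell is retained). Scores normalize each cell's spot count to the control
mean within its experiment before pooling — the only reading that makes
pooling across imaging sessions unit-free; a global-normalization flag
exists. Dunnett's post test uses the exact equicorrelated multivariate-t
representation of the max-|t| null (correlation √(λ_i λ_j), λ_i =
n_i/(n_i + n_0), shared χ² scale) sampled by seeded Monte Carlo, 100,000
draws by default (MC SE < 0.0016 on a p-value near 0.1, < 0.0005 near
0.025); with a single comparison it converges to the unadjusted
two-sided t, and it is cross-checked against an independent
implementation in the tests. The xenograft utility computes volume =
length × width²/2.

## Synthetic-data generators (`mmras.simulate`)

All generators are pure functions of their config (seed included); truth
labels are always returned alongside the data.

- **Screens**: Day 0 counts are negative binomial (mean 500 reads/guide —
  deep-coverage screening practice; dispersion 0.05), Day 21 counts are
  Poisson thinnings of each replicate's own Day 0 counts scaled by
  2^(gene effect + per-guide N(0, 0.3) jitter), so guide-level timepoint
  correlation matches real screens. Essential genes default to a −2 log2
  dropout over the screen; non-essential genes have effect exactly 0 (the
  efficacy jitter applies only where there is an effect to jitter).
- **SILAC**: true interactors N(3.0, 0.5) log2fc, background N(0, 0.5),
  categorical ratio counts ≥ 1.
- **Dose matrices**: Hill single agents (default EC50 16, slope 1, max
  effect 0.6 on the 0–256 grid of a 5-dose 1:4 dilution series plus the
  zero dose); combination wells sit at the HSA expectation minus the
  planted per-well excess, plus Gaussian plate noise, clipped to
  [0, 1.2] to mimic above-control plate noise without unbounded values.
- **PLA**: negative binomial spot counts (dispersion 0.3) and truncated
  normal nucleus areas (mean 1,500 px, sd 400 — a realistic imaging
  spread that leaves a small tail below the 750 px filter).
- **Expression/survival**: a latent standard-normal per-sample score;
  signature genes express score + N(0, 0.5), other genes pure noise;
  exponential event times with hazard h0·exp(β·score) (h0 = 1/365 per
  day) and independent exponential censoring whose rate is chosen so the
  null censoring fraction equals `censor_rate`.

What the generators do **not** emulate: guide-specific cutting biases and
copy-number effects in screens; peptide-level missingness structure and
contaminants in MS; plate-position artifacts and dose-response curve
misspecification in matrices; batch effects and non-proportional hazards
in the survival cohort. Passing recovery tests therefore demonstrates the
estimators are correct under their stated models, not that real-data
nuisances are handled.

## Problem sizes

The test suite and acceptance script run screens of 1,000 genes × 4
guides × 2 replicates, 10,000-gene outlier nulls, 100 seeded 6×6
matrices, enrichment over ~30–60 sets at 250–1,000 permutations, Cox
cohorts of 120–600 samples, and PLA tables of ~100 cells/condition —
sizes at which every stochastic check has comfortable power while the
full suite completes in well under a minute of compute.
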