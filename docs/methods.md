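# Methods

This note documents the statistical models, the synthetic-data design and
the numerical choices behind `gcresponse`.

## Differential expression

Samples are paired aliquots of the same culture treated with
dexamethasone or vehicle, so the response is modelled per individual as
the log2 fold change `lfc = y_treat − y_ctrl` (both inputs already log2
scale) and tested with a **paired one-sample moderated t-test** rather
than a two-sample contrast. The empirical-Bayes variance prior (d₀, s₀²)
is estimated by moment matching on z_g = log s²_g: with
e_g = z_g − ψ(d/2) + log(d/2), the hierarchical model implies
Var(e) = ψ′(d/2) + ψ′(d₀/2) and E(e) = log s₀² − ψ(d₀/2) + log(d₀/2);
ψ′ is inverted by bracketed root finding. When the observed variances are
under-dispersed relative to pure sampling noise (Var(e) ≤ ψ′(d/2)) the
solver has no root and d₀ = ∞ is used — every posterior variance then
equals s₀² and the test statistic is normal. Genes with zero variance and
no moderation (forced d₀ = 0) are flagged with undefined p.

q-values use the single-λ Storey estimator π̂₀ = #{p > 0.5}/(m/2),
clipped to (0, 1], with the step-up transform
q_(i) = min_{j≥i} π̂₀ m p_(j)/j. The spline-smoothed π₀(λ) variant was
considered and left out: at the cohort sizes this package targets the
fixed-λ estimator is more stable. A gene is called responsive if
q ≤ FDR (default 0.05) at **one or more** timepoints.

## Time-course summarisation and clustering

Log2 fold change accumulates over the time course (transcript made early
is still present later), so clustering on the raw profiles groups genes
by intensity rather than dynamics. The package therefore clusters the
per-interval change df: df₁ = f(t₁) − 0 and df_j = f(t_j) − f(t_{j−1}),
where f is the per-timepoint **median** across samples (robust to a
single outlying cell line). Cumulative summation inverts the transform
exactly, which is asserted to 1e-12.

k-means uses Lloyd's algorithm with k-means++ seeding, the best of
`n_init = 10` restarts, Euclidean distance on raw df (no scaling), and a
fixed random seed; it is delegated to scikit-learn's `KMeans`, with a
brute-force exhaustive-assignment oracle pinning global optimality on
small instances. The default k = 8 is the study design; no automatic
elbow rule is imposed — the CLI reports inertia over a user-given k grid
instead. Cluster centers are summarised by cumulating back to f*, taking
the timepoint of max |f*| (ties broken toward the **earlier** timepoint,
for reproducible summaries) and the sign of f* there; an all-zero center
is reported as `flat`.

## Binding-region features and the direction model

Distances are anchored on the **peak midpoint** (symmetric, matches
summit-centric practice) and the gene's TSS; coordinates are 0-based
half-open throughout, converted at the I/O boundary (VCF POS is 1-based).
Windows are boundary-inclusive: a midpoint exactly 100,000 bp from the
TSS is inside the 100 kb window. The nearest peak is chosen by absolute
midpoint distance with ties broken toward the smaller start coordinate.
Direction d is strand-aware (on minus-strand genes larger coordinates are
upstream); D enters the regression unsigned with d as a separate
covariate. C is true when the nearest peak's midpoint is strictly closer
to some other gene's TSS; c when any CTCF interval midpoint lies strictly
between TSS and peak midpoint; Dh when the peak interval shares at least
one base with a DNase interval.

The motif flag M comes from a log-odds PWM scan: every window on both
strands is scored, and significance is an empirical upper-tail p against
the score distribution over all windows of a user-supplied background
sequence (add-one corrected), with hits at p < 0.01. This replaces
randomization-based motif callers with an equivalent, testable primitive;
the default matrix encodes the canonical receptor palindrome
AGAACAnnnTGTTCT (consensus base probability 0.85, uninformative 3-bp
spacer). The per-peak flag Šidák-corrects the best window's p for the
number of windows scanned, so peak width does not inflate the false-flag
rate (at a window-level 0.01 threshold a motif-free 157 bp peak would
otherwise be flagged ~75% of the time).

The logistic fit is plain maximum likelihood by IRLS (tolerance 1e-8 on
the coefficient step, ≤ 100 iterations), with Wald two-sided p-values
from the observed information. Quasi-complete separation (|η| > 30 or a
perfect fit) is flagged with a warning while still reporting
coefficients; a rank-deficient design raises an error naming the
collinear columns. An independent Newton solver and statsmodels pin the
estimates to 1e-6 in the tests.

## Interaction-eQTL Bayes factors

For n individuals with paired expression (y_t, y_c) and genotype dosage
g, the 2n observations are stacked with condition-specific intercepts
(flat priors), a shared residual variance σ² with Jeffreys prior 1/σ²,
and genotype-effect columns per model: one shared column (no-interaction),
treatment-rows-only (GC-only), control-rows-only (control-only), or both
condition-specific columns (general). Effects carry a
Normal(0, σ_a²σ²) prior. With P projecting out the intercepts
(block centering), A = ZᵀPZ and b = ZᵀPy:

    BF(σ_a) = |I + σ_a²A|^{−1/2} · (RSS₁/RSS₀)^{−(2n−2)/2},
    RSS₁ = RSS₀ − bᵀ(A + I/σ_a²)^{−1} b,  RSS₀ = yᵀPy,

averaged with equal weights over the scale grid
σ_a ∈ {0.1, 0.2, 0.4, 0.8, 1.6}. Scaling the effect prior by σ² makes
the BF exactly invariant under affine transforms of the expression
values, and the symmetric design guarantees that swapping the two
condition labels exactly exchanges the GC-only and control-only BFs —
both properties are asserted in the tests, and the closed form is pinned
to 3 significant figures against an independent quadrature oracle that
integrates the effects numerically. Genotypes are centered and missing
dosages mean-imputed per SNP (keeps the closed form; standard eQTL
practice). A monomorphic SNP carries no information and returns BF = 1
for every model, flagged. The residual variance is shared across
conditions; a per-condition-variance variant was considered and not made
the default, since the shared-variance construction preserves the exact
swap symmetry and the conjugate closed form.

Posteriors use the conservative prior 0.999 on the null and 0.001/4 on
each alternative. The calling rule — argmax over the four alternatives
if that posterior exceeds 0.5, otherwise null — is this package's
documented choice; with the 0.999 prior an alternative needs a BF near
2,000 to be called, which is what keeps the false non-null rate on
truly-null genes below 5% in the recovery tests.

## Enrichment and overlap statistics

Cluster enrichment is the one-tailed hypergeometric upper tail
P(X ≥ k | N, K, n), computed in log space (scipy). The global
"randomly distributed across clusters?" question uses a Monte-Carlo
multinomial goodness-of-fit: the statistic is the multinomial
log-likelihood of the observed per-cluster successes under
size-proportional expectation, with p = (1 + #{sim ≤ obs})/(1 + n_sim)
over 10⁴ draws by default — an exact-enumeration oracle validates it on
small instances. The Mann–Whitney U test uses exact enumeration when
n·m ≤ 400 and the pooled sample is tie-free, otherwise the normal
approximation with tie and continuity corrections.

eQTL-class overlap uses boundary-inclusive distance to the nearest peak
interval (0 inside), with 100 bp windows for GR and 1 kb for NF-κB. The
resampling p-value permutes the class labels across the pooled SNPs of
the two compared classes, holding class sizes fixed — the two classes are
assumed exchangeable in ascertainment (allele frequency, local LD), which
is the rationale for comparing them in the first place. The statistic is
the difference in overlap counts and the p-value is add-one corrected,
so p ∈ (0, 1] and the floor at 1000 resamples is 1/1001.

## Synthetic cohort design

Defaults encode the study conditions: 57 individuals (the eQTL cohort),
8 time-course samples at 2, 4, 8, 12, 16, 24 h, mean binding-region
width 157 bp (rounded Gamma, shape 8), negative-binomial tag counts
(mean 50, dispersion 5 — overdispersion typical of ChIP-seq), and a
+16% NF-κB tag gain under treatment at sites colocalized with receptor
regions. Genes sit on a 150 kb TSS grid with alternating strands; each
gene owns one causal SNP within ±50 kb of its TSS (one causal SNP per
gene matches the cis design and keeps truth unambiguous), with
Hardy–Weinberg genotypes at a MAF uniform in [0.05, 0.5]. Planted eQTL
classes default to 50% null, 20% no-interaction, 10% each GC-only,
control-only and general; the general class uses β′ = −β/2 so it is
distinguishable from both single-condition classes. Effect size 1.0 and
noise 0.2 (log2 units) set the per-allele signal-to-noise ratio to 5 —
real effect and noise magnitudes are not identifiable from the source
material, so these are free parameters chosen once at a level where the
classifier should succeed, and the recovery tests quantify that it does.
A configurable fraction (default 0.6) of GC-only causal SNPs is planted
inside receptor binding regions, and of control-only SNPs inside NF-κB
regions — the mechanism the overlap analysis exists to detect. DNase
sites partially colocalize with peaks, as open chromatin does with TF
occupancy.

What the generator does **not** emulate: linkage disequilibrium and
population structure (each SNP is independent), probe-level microarray
noise, read-level ChIP-seq artefacts, and any dependence between the
time-course shapes and the eQTL classes. Passing recovery tests
therefore demonstrate correctness of the statistical machinery under the
assumed model, not robustness to LD-confounded or batch-affected real
data.

## Problem sizes and determinism

The default cohort (120 genes/SNPs, 57 individuals, 240 receptor peaks)
was chosen so a full pipeline run completes in about a second while every
stage still has enough rows for stable estimates; the recovery analyses
in the tests use 200 genes at n = 50. All randomness flows from a single
seed through per-generator `numpy` substreams, so reruns under a fixed
configuration are byte-identical; every output table is stamped with a
hash of the configuration that produced it.

## Known limitations

* The peak-relocation step that plants causal SNPs inside binding
  regions assumes relocation targets are farther apart than peak widths
  (true on the gene grid); pathological inputs could leave two relocated
  peaks overlapping.
* The moderated-t prior estimation excludes zero-variance genes; with
  fewer than two positive variances it refuses to fit.
* `read_genotypes` handles the GT-only VCF subset (multi-allelic records
  skipped with a warning); INFO fields are ignored.
* The direction-model feature extraction is quadratic in track sizes —
  appropriate at desk scale, not for genome-wide tracks.
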