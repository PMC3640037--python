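# gcresponse

Glucocorticoids (GCs) mediate the stress response and are front-line
anti-inflammatory drugs. They act through the glucocorticoid receptor
(GR), a ligand-activated transcription factor that, upon hormone binding,
occupies DNA and cross-talks with inflammatory factors such as NF-κB.
`gcresponse` implements the computational chain used to dissect this
response in lymphoblastoid cell lines, for regulatory-genomics analysts
who want each statistical step reusable and testable:

* **Differential expression** from paired treatment/control samples: the
  per-individual log2 fold change is tested with a paired one-sample
  *moderated t-test* — per-gene variances s²_g (d = n−1 df) are shrunk
  toward an empirical-Bayes prior (d₀, s₀²) estimated by moment matching
  on log s²_g, giving s̃²_g = (d₀s₀² + d s²_g)/(d₀+d) and
  t = m_g/(s̃_g/√n) on d₀+d df — with Storey–Tibshirani q-values
  (π̂₀ at λ = 0.5) controlling the FDR.
* **Time-course clustering**: per gene the median log2 fold change across
  samples at each timepoint (f_g2 … f_g24 over 2–24 h) is reduced to the
  per-interval change df_g (anchored at 0 at time 0), and genes are
  clustered with k-means (default k = 8) on df_g; each cluster is
  summarized by direction (Up/Down) and peak time.
* **Binding-region annotation and the direction model**: peaks are
  assigned to genes by midpoint-to-TSS distance; seven covariates —
  distance D, upstream flag d, closer-to-another-gene flag C, tag count
  T, intervening-CTCF flag c, DNase overlap Dh, canonical motif M (PWM
  scan with empirical p < 0.01 against a background sequence) — enter a
  logistic regression of P(lfc > 0).
* **Interaction eQTLs**: for each cis SNP–gene pair (|SNP − TSS| ≤ 100 kb)
  Bayes factors compare four models of genotype effect — no-interaction,
  GC-only, control-only, general — against a no-effect null, using a
  conjugate Bayesian regression on the stacked paired observations
  (condition intercepts flat, effect prior N(0, σ_a²σ²) averaged over
  σ_a ∈ {0.1, 0.2, 0.4, 0.8, 1.6}, Jeffreys 1/σ²). Posteriors combine
  the BFs with a conservative prior (0.999 null, 0.001/4 per
  alternative): P(m) = π_m·BF_m / Σ π_m′·BF_m′.
* **Enrichment**: one-tailed hypergeometric tests per cluster, a
  Monte-Carlo multinomial goodness-of-fit test, Mann–Whitney U tag
  comparisons, and label-permutation resampling p-values for the overlap
  of eQTL classes with binding regions (100 bp windows for GR, 1 kb for
  NF-κB).

Every stage runs end-to-end on synthetic data with planted truth
(`gcresponse.simulate`): Hardy–Weinberg genotypes, paired expression with
planted eQTL classes, planted time-course shapes, non-overlapping peaks
with 157 bp mean width and negative-binomial tags, and annotation tracks
with planted motifs — so the whole pipeline is verifiable without any
external download.

## Worked example

The numbered drivers under `analysis/` run the full chain on the default
synthetic cohort (57 individuals, 120 genes/SNPs, seed 0) and write their
tables under `results/`:

```sh
cd analysis
python 01_simulate_cohort.py
python 06_interaction_eqtl.py
python 07_eqtl_binding_overlap.py
```

prints (abridged):

```
planted eQTL classes: {'null': 75, 'no_interaction': 21, 'gc_only': 11,
                       'control_only': 7, 'general': 6}
...
tested 120 gene-SNP pairs within 100 kb
causal-pair agreement with planted truth: 100.0%
...
GR: 6 GC-only vs 0 control-only within 100 bp (fold undefined, p = 0.030)
NFKB: 3 GC-only vs 6 control-only within 1000 bp (0.5-fold, p = 1.000)
```

Every planted interaction class is recovered by the Bayes-factor
classifier at the default signal-to-noise ratio, and the planted
mechanism — GC-only causal variants sitting inside GR binding regions,
control-only variants inside NF-κB regions — is detected by the overlap
analysis: GC-only eQTLs are significantly enriched within 100 bp of GR
peaks (label-permutation p = 0.03), while control-only eQTLs dominate
near NF-κB sites. The other drivers report the cross-condition peak
overlap, the per-timepoint DE calls, the k = 8 cluster table
(direction, peak time, size, primary-target percentage, hypergeometric
p) and the seven-covariate logistic fit.

The same stages are exposed as a CLI (`gcresponse run --seed 0 --out out/`
for the full pipeline, or `simulate`, `de`, `cluster`, `features`,
`enrich`, `eqtl`, `overlap`, `peaks` individually on TSV/BED/VCF inputs).

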