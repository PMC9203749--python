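# Methods

## Statistical model

### Summary-statistic methylation imputation

The discovery statistic treats methylation at a CpG as a linear genetic
score $M = \sum_l w_l g_l + e$ over its cis SNPs (within 1 Mb). Given
marginal GWAS effects $\beta_l$ (standard error $se_l$) and an LD
reference panel, the association of genetically predicted methylation
with the trait is

$$Z \;=\; \sum_l w_l \frac{\sigma_l}{\sigma_g} \frac{\beta_l}{se_l},
\qquad \sigma_g^2 = w^\top \Sigma w ,$$

with $\Sigma$ the empirical dosage covariance (denominator $n-1$) and
$\sigma_l$ its diagonal square roots, both taken from the panel rather
than from GWAS allele frequencies. For a single SNP the weight cancels
and $Z$ reduces to sign$(w)\,\beta/se$; generally $Z$ is invariant to
rescaling the weight vector up to sign. When the panel *is* the cohort,
$Z$ equals the individual-level regression z of $Gw$ on the phenotype
up to $O(\beta^2)$ terms in the per-SNP residual variances; the test
suite verifies correlation > 0.99 and $|\Delta Z| < 0.2$ over 50
models at $n = 2000$. Model SNPs absent from the GWAS are dropped
(partial-model imputation, coverage reported); a model is skipped when
no SNP remains or $\sigma_g \le 10^{-8}$. P values are two-sided
normal; FDR is Benjamini–Hochberg across tested units.

$\Sigma$ is used unregularised. With the small cis models generated
here it is always well conditioned; a PSD floor would only matter for
much larger models.

### Tissue differential methylation

Per CpG an OLS fit of the beta value on sample type, age, age$^2$ and
the top $K$ principal components of the post-QC matrix. QC removes
CpGs missing in more than 10% of the samples of *any* sample group
(tumour / NAT / healthy evaluated separately), imputes remaining gaps
with the CpG median, then removes samples whose PC1 score falls outside
$[Q_1 - 1.5\,\mathrm{IQR},\, Q_3 + 1.5\,\mathrm{IQR}]$ within their own
group, once, skipping groups of fewer than four samples. PCs are then
recomputed on the combined case+control matrix of the specific
contrast. The sample-type coefficient is tested with a two-sided t
test (exact small-sample reference distribution) and converted to a
signed z so that $p = 2\Phi(-|z|)$ holds exactly in the shared
association-table format; $z < 0$ is hypomethylation in cases.

At the desk scale used here (40 CpGs) the pipeline default is $K = 2$
components: the generator plants a single technical batch axis, and
with so few features additional components begin to align with the
biological contrast itself and absorb it. With array-scale data
(hundreds of thousands of CpGs) larger $K$ — ten or five components
are typical choices — does not have this degeneracy; `--pcs` exposes
the choice.

### Overlap cascade

All association tables are intersected to a shared CpG universe. With
current set size $n$, overlap $k$ with the next DM set, and null
proportion $p_0$ = (that analysis's DM count)/(universe size), each
iteration is a one-sided (greater) exact binomial test; the cascade
proceeds only while $p < 0.05$ (strict) and otherwise returns the empty
set. The iteration trace records $k, n, p_0, p$ in order; permuting
the cascade order can change the outcome, which is why the trace keeps
it. Directional variants first restrict every analysis to nominally
significant CpGs (uncorrected $p < 0.05$) of one methylation direction.
Annotation-category tests use the **two-sided**
point-probability-summation binomial convention (sum of $P(X=j)$ over
all $j$ with $P(X=j) \le (1+10^{-7})P(X=k)$) so that depletion is
detectable; enrichment vs depletion is read from the sign of $k/n-p_0$.

### Expression linkage

* **Interval annotation** with precedence splicing (within 2 bp of an
  internal exon boundary) > exonic > UTRs > intronic > upstream /
  downstream (1 kb beyond the transcript, strand-aware) > intergenic;
  non-coding genes yield ncRNA_exonic / ncRNA_intronic. All
  overlapping genes are reported.
* **Differential expression** is a transparent stand-in for a full
  negative-binomial Wald pipeline: median-of-ratios size factors,
  removal of genes with total count < 10, per-gene OLS t test on
  $\log_2(\text{normalized}+0.5)$, fold change = ratio of normalized
  group means, BH FDR. Fold changes are invariant to library
  rescaling; per-gene p values will differ from a shrinkage-based NB
  fit, but downstream logic consumes only DEG flags and fold changes.
* **Distance windows**: for each window $w$ in
  {1k, 5k, 10k, 25k, 50k, 100k, 500k, 1M, 5M, 10M} bp, genes
  overlapping (even partially) $\pm w$ of any CpG are collected, the
  DEG proportion computed and tested one-sided against the genome-wide
  DE rate; the selected window is the one *before* the maximum drop in
  proportion, ties toward the smaller window. DEG sets are monotone in
  $w$ by construction.
* **eQTL overlap**: per gene, $k$ = eQTL SNPs shared with the CpG
  set's meQTL union out of $n$ eQTL SNPs; the null is the median
  $k/n$ over genes with $k \ge 1$; one-sided binomial, BH FDR. Genes
  passing FDR < 0.05 are candidates for imputed differential
  expression via the same Z statistic with expression weights.
* **Mediation**: per CpG–gene pair on matched samples,
  $\log_2(\text{norm}+1) \sim \text{type} + M + \text{type} \times M$;
  the interaction coefficient carries the conditional association.
  Collinear designs (e.g. constant methylation) give NA rows excluded
  from the FDR denominator. The p value is invariant to affine
  rescaling of the methylation covariate.
* **Concordance**: negative coupling = (hypo, up) or (hyper, down).

### Genetics

* **FRR**: $\sum_i p_i(1-p_i)(\beta_i^2-\tau_i^2)/\ln\lambda$ with
  $p_i = \min(\text{eaf}, 1-\text{eaf})$, implemented exactly in this
  form; negative per-SNP terms are retained. The conventional
  $2p(1-p)$ variance form is available behind a `factor2` flag because
  the printed form omits the factor 2.
* **Region classes** from the minimum GWAS p within $\pm 1$ Mb:
  genome-wide significant ($p \le 5\times10^{-8}$), suggestive
  ($5\times10^{-8} < p \le 10^{-5}$), else novel.
* **Conditional scan**: joint normal equations reconstructed as
  $X^\top X \approx n\,\mathrm{diag}(\sqrt d) R\,\mathrm{diag}(\sqrt d)$
  with $d_j = 2p_j(1-p_j)$ from GWAS frequencies, $R$ the panel
  correlation, and $X^\top y_j = n d_j \beta_j$; $n$ is the median GWAS
  sample size (per-SNP n refinement, as the original conditional-
  analysis software performs, is out of scope and is the main source
  of divergence from it). The phenotypic variance is inferred from the
  marginal summaries as the median of $d(n\,se^2 + \beta^2)$; the
  residual variance is re-estimated after each selection and floored
  at 10% of the phenotypic variance. Selection starts at the smallest
  marginal $p < 0.05$, then repeatedly adds the candidate with the
  smallest conditional p below 0.05, never choosing candidates with
  $r^2 > 0.9$ to the selected set; singular systems skip the candidate
  with a collinearity flag rather than ridging. CpGs within 1 Mb are
  pooled into one region before scanning. With an empty selected set
  the first conditional p equals the marginal p exactly.
* **Meta-analysis**: inverse-variance fixed effect
  ($\bar\beta = \sum w_i\beta_i/\sum w_i$, $w_i = se_i^{-2}$,
  $se = (\sum w_i)^{-1/2}$), Cochran's
  $Q = \sum w_i(\beta_i-\bar\beta)^2 \sim \chi^2_{k-1}$, heterogeneity
  flagged at $p_{het} < 0.05$, NA for single-study SNPs. Allele frames
  are rotated onto the first study.
* **Pleiotropy**: two CpGs are linked when they share a meQTL SNP or
  any cross pair of their meQTL SNPs has $r^2 > 0.4$.

## Harmonization and formats

Internal coordinates are 1-based inclusive; BED block files are
converted at the boundary. The reference panel counts the alt allele;
GWAS and weight frames are rotated onto it (swapped alleles flip the
sign of $\beta$ or $w$ and map eaf to 1-eaf), strand-ambiguous A/T and
C/G SNPs are dropped by default (a flag keeps them), and SNPs absent
from any one source or with irreconcilable allele pairs are dropped
with counts reported. Harmonization is idempotent. Every loader
accounts rows as kept + dropped, and result tables round-trip through
TSV at full float precision.

## Synthetic-data generator

The generator emulates the structures the analysis assumes, not any
particular cohort:

* **Genotypes**: copy-chain haplotypes — allele $l{+}1$ copies allele
  $l$ with probability `ld_decay`, else is a fresh Bernoulli draw —
  giving first-order LD with adjacent-dosage correlation ≈ `ld_decay`;
  MAFs uniform on `maf_range`. The GWAS cohort shares the panel's
  frequency and LD process.
* **Weight models**: the `snps_per_cpg` SNPs nearest each CpG, Gaussian
  weights rescaled so the genetic score explains `h2_meth` of the
  unit-variance latent methylation.
* **Phenotype**: $y = \sum_{c\,\text{causal}} \gamma s_c M_c +
  \varepsilon$ with random signs $s_c$; marginal per-SNP OLS summaries
  are computed on the cohort. Individual-level cohort data are kept on
  the truth set so oracle tests can re-fit them.
* **Tissue methylation**: latent Gaussian = baseline + age slope +
  batch offset + tumour shift (`dm_effect`·$s_c$ at causal CpGs),
  logistic-squashed into [0,1]. Causal CpGs sit at intermediate
  baseline (beta ≈ 0.5), where array variability is maximal. Batches
  alternate across samples — orthogonal to sample type — so principal
  components have technical structure to remove without absorbing the
  contrast. ~2% of entries go missing; `n_outliers` samples receive a
  uniform latent shift of 2.0 and are recorded for the PC1-removal
  check.
* **Expression**: negative-binomial counts (dispersion
  `nb_dispersion`), library sizes ×[0.5, 2]. Genes linked to causal
  CpGs are split: most receive a pure tumour shift of `de_log2fc` with
  sign opposite to the CpG's methylation direction; the genes linked
  to the last `n_mediation_genes` causal CpGs instead receive a
  tumour-specific log2-expression slope on the observed CpG beta
  (centred so group means are untouched), giving the interaction
  regression a pure planted signal.

All randomness flows from `SimulationConfig.seed` through NumPy's
PCG64 generator with fixed per-stage child seeds, so identical configs
reproduce bit-identically across platforms and stages remain
reproducible when called in isolation.

### Default conditions

| parameter | default | meaning |
|---|---|---|
| `n_panel` | 500 | LD reference individuals |
| `n_cohort` | 2000 | GWAS cohort size |
| `m_snps`, `n_cpgs`, `n_causal` | 300, 40, 8 | features on a 3 Mb chromosome |
| `ld_decay` | 0.3 | adjacent-SNP copy probability |
| `maf_range` | (0.05, 0.5) | minor-allele frequencies |
| `snps_per_cpg`, `h2_meth` | 3, 0.3 | cis architecture; blood cis-heritability of methylation is typically 0.2–0.4 |
| `gamma` | 0.3 | per-causal-CpG phenotype effect (liability sd units) |
| `dm_effect` | 0.15 | latent tumour−control shift |
| `meth_noise_sd` | 0.15 | within-group latent noise; ≈0.04 beta-scale replicate sd at mid-methylation, typical of array data |
| `age_effect` | 0.01/yr | latent methylation drift with age |
| `batch_sd` | 0.15 | per-batch per-CpG technical offsets |
| `n_tumour`/`n_nat`/`n_healthy` | 60/60/60 | tissue samples |
| `de_log2fc` | 1.0 | injected expression shift (2-fold) |
| `mediation_effect` | 8.0 | log2-expression per beta-unit slope difference; ≈1.6 log2 units across the observed beta spread, a strongly methylation-regulated gene |
| `nb_dispersion` | 0.1 | count overdispersion |

What passing tests show — and do not. The generator produces
first-order LD, a single technical batch axis, balanced age, and
independent noise; real data have long-range LD, cell-type
composition effects, probe artefacts and unbalanced confounding.
Recovery results here validate the statistical machinery and its
calibration, not performance on any real cohort. Imputation false
positives from LD with causal CpGs are faithfully present (enriched
sets include occasional neighbours of causal CpGs).

## Numerical choices

* Exact binomial tails throughout; the two-sided convention is
  point-probability summation with a $1+10^{-7}$ tolerance factor.
* BH FDR via the standard step-up with enforced monotonicity; NA rows
  (constant CpGs, collinear mediation designs) are excluded from the
  denominator.
* t-distribution p values wherever an OLS coefficient is tested;
  conversion to signed z preserves the two-sided p exactly.
* Ties in the window-selection rule break toward the smaller window;
  ties at the cascade threshold require strict $p < \alpha$.
* Degenerate inputs: empty CpG universe, zero testable models, all-QC
  removal, $\lambda \le 1$, invalid null proportions and sub-50
  cohorts are fatal; monomorphic panel SNPs, multi-allelic VCF records
  and beyond-cis weight entries are dropped with warnings.

## Problem sizes in the test suite

Acceptance checks run at the default conditions: 50 weight models at
$n = 2000$ for the oracle-equivalence check; ten AR(0.6) regions of
2 causal + 18 null SNPs for the conditional-scan oracle; ten all-null
and ten default-effect end-to-end runs; 500 null units for type-I
calibration; 200 resampled set pairs for cascade calibration. The full
suite completes in well under a minute of CPU on a laptop-class core.

## Known limitations

* The conditional scan uses a shared median sample size and a floored
  residual-variance update; with heterogeneous per-SNP n its p values
  will diverge from tools that model per-SNP n.
* The DE stand-in has no dispersion shrinkage; at small n its p values
  are conservative relative to NB-based tools.
* The eQTL-based imputed-DE route reuses the imputation Z with
  expression weights; tissue-specific weight sets are the caller's
  responsibility.
* No genome-build liftover, genotype imputation, raw-array (IDAT)
  handling or cell-type deconvolution.
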