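# Methods

## Model

Per sample *i* and probe *j*, the generator and the analysis share one view
of a beta value:

    beta_ij = Σ_k w_ik m_jk + δ_j (age_i − a₀) + ε_ij,   truncated to [0, 1]

where `w_i` is the sample's cell-type composition (6 blood cell types),
`m_jk` the mean methylation of probe *j* in purified cell type *k*, `δ_j` a
per-year drift coefficient that is non-zero only at planted clusters and
blocks, `a₀` the youngest cohort age (the drift anchor), and `ε` Gaussian
noise on the beta scale. The analysis estimates the age term per probe
*cluster* by OLS of the cluster-mean beta on age plus covariates;
composition enters either as a confounder (unadjusted analysis) or as
estimated covariates (adjusted analysis).

Anchoring drift at the youngest age rather than the mean age keeps planted
trajectories inside [0, 1] (a low-baseline island can only gain, a
high-baseline open-sea probe can only lose); OLS slopes are invariant to the
anchor, so the estimand is unchanged.

## Regional clustering

Probes are classed by distance to the nearest CpG island: 0 → island,
≤ 2 kb → shore, ≤ 4 kb → shelf (shores and shelves merged into one
`shore_shelf` class), else open sea. Within a (chromosome, class) track,
clustering is greedy left-to-right: a probe joins the current cluster iff
its gap to the previous probe is ≤ 500 bp **and** its distance to the
cluster's first probe is ≤ 1500 bp. Greedy splitting is deterministic; width
is measured on 1 bp CpG coordinates. Cluster means are arithmetic averages.

## Age-DMR regression

One OLS per cluster, `mean beta ~ intercept + age + covariates`, with
categorical covariates dummy-encoded (first level dropped). The design is
checked for rank: covariate columns that are perfectly collinear with
already-included columns are dropped with a logged notice (the typical case
is a plate factor that fully encodes ethnicity or processing site), while
collinearity involving age itself is an error. p-values are two-sided on the
age t-statistic; an exact fit (zero residual) reports t = ±inf (p = 0), or
t = 0, p = 1 when the coefficient is also zero. BH adjustment uses the
standard step-up with monotonicity. Top-fraction selection takes the
⌈f·N⌉ smallest p-values, breaking ties by larger |t| then cluster id.
"Non-age-associated" clusters (for the expression classes) are those with
nominal p > 0.8.

## Cell-type deconvolution

The reference-based estimator solves, per sample,

    w* = argmin ‖y − M w‖²  subject to  w ≥ 0, Σw ≤ 1

over the panel CpGs. Because the problem is a 6-variable convex QP, it is
solved *exactly* by enumerating active sets: for each support subset and each
state of the sum constraint, the equality-constrained least-squares solution
is computed; the best feasible candidate is the global optimum. This keeps
the estimator deterministic with no iterative-solver tolerance. `1 − Σw` is
reported as "unexplained". In the adjusted regression the granulocyte column
is dropped (reference level) so the near-simplex fractions do not make the
design singular; fractions are used raw, not renormalised to sum to one,
since the constrained estimates are the direct analogue of the published
procedure and renormalisation would distort samples with a large unexplained
component.

## Block detection

Open-sea clusters are grouped along chromosomes with a 250 kb gap rule
(start-to-end gap; a gap of exactly 250 kb still merges). Within each group,
per-cluster age coefficients (per 10 years) are smoothed with a
tricube-weighted running mean whose window spans 250 kb (half-width 125 kb);
groups of fewer than 7 clusters pass through unsmoothed. A tricube running
mean rather than a loess fit keeps the stage linear in the coefficients —
the smoothing operator is a fixed row-stochastic matrix per group — which
both makes it deterministic and lets the bootstrap reuse the precomputed
operator. Candidate blocks are maximal same-sign runs with
|smoothed coef| > cutoff (default 0.005 per 10 years, exposed as a
parameter), scored by area = Σ|smoothed coef|.

FWER uses a residual bootstrap under the no-age null: the null model
(intercept + covariates, no age) is fitted per cluster, bootstrap data are
null fitted values plus residual *vectors* resampled across samples with
replacement (preserving cross-cluster correlation), age coefficients are
refit by the precomputed linear contrast, smoothed, and scanned; the
genome-wide maximum candidate area is recorded per iteration. A block's FWER
is the fraction of bootstrap maxima reaching its area; zero counts are
reported as the bound `< 1/n_boot`. 500 iterations is the default
(resolution 0.002). The null-model (rather than full-model) residual
bootstrap is the standard choice for strong FWER control of bump statistics.

CGI enrichment inside a block uses the binomial tail
P(Bin(n_cgi, p_genome) ≥ obs), where n_cgi counts island clusters whose
midpoint lies inside the block span and p_genome is the genome-wide
proportion of age-hypermethylated (FDR < 0.001) island clusters. Blocks with
fewer than 5 CGIs are flagged rather than suppressed. Length-matched random
blocks are sampled without replacement from windows over non-significant
open-sea runs, stratified by the deciles of the observed length
distribution, borrowing from the nearest stratum when one is short. The
cross-cohort comparison computes, per block, each sample's mean beta over
the open-sea probes in the span, then a two-sample t (second cohort minus
first) and a two-sided Wilcoxon rank-sum; the distribution of observed-block
t statistics is compared to the random blocks' by a one-sided KS test
(observed CDF above ⇒ shifted negative).

## TFBS enrichment

narrowPeak coordinates stay 0-based half-open; a probe at 1-based position p
overlaps a peak [s, e) iff s < p ≤ e. A cluster carries a factor's flag iff
any member probe overlaps any peak of that factor; the per-factor fraction of
probe CpGs inside peaks is reported alongside. Fisher tests are one-tailed
("greater") on the 2×2 table of selection × flag over the tested-cluster
background (the background is a parameter; all tested clusters is the
default), run separately for hyper- and hypo-methylated DMR sets, with BH
across factors within a direction. Redundant profiles are removed when
pairwise Jaccard overlap exceeds 0.7 (the smaller profile is dropped;
identical duplicates always collapse). The multivariate stage regresses the
per-cluster age t-statistic on the retained binary profiles plus an
intercept; clusters with non-finite t (exact fits) are excluded from this
regression. Same-factor profiles from different labs keep a lab suffix and
are treated as distinct.

## Promoter methylation and expression

Island clusters link to a gene when a member probe lies within 200 bp
upstream-through-TSS on the gene's strand or inside the first exon. A gene
with several linked clusters is classed by the most TSS-proximal one
(exposed as a parameter): AgeHyperM/AgeHypoM if that cluster is in the DMR
selection, NonAgeDMR if its nominal p > 0.8, otherwise unclassed. Expression
is summarised as the per-gene mean over samples before class comparison;
neighbouring classes are compared by Wilcoxon rank-sum and the overall trend
by OLS on the ordinal class code (AgeHypoM = 0, NonAgeDMR = 1,
AgeHyperM = 2). The methylation-vs-expression association uses Spearman rank
correlation over linked genes.

## Synthetic cohort

The generator emulates a large whole-blood aging cohort:

- **Geography.** Each chromosome alternates island clumps (4–10 probes,
  60–160 bp apart) with one shore and one shelf probe downstream, and
  open-sea runs of 6–12 probes spaced 0.5–50 kb. This yields island clusters
  of realistic width, shore/shelf clusters, and mostly-singleton open-sea
  clusters whose 250 kb grouping is exercised.
- **Ages** uniform on 19–101 years; sex and a 3-level plate factor are
  drawn independently, with small Gaussian plate offsets (sd 0.003) added to
  all probes so covariate adjustment is exercised.
- **Composition.** Per sample, fractions are Dirichlet (concentration 200)
  around a base composition (Gran 0.60, CD4T 0.15, CD8T 0.08, B 0.07,
  NK 0.05, Mono 0.05) whose granulocyte+monocyte share increases linearly
  with age (default 0.001/year, 90% to granulocytes) at the expense of the
  lymphoid types. 20% of eligible non-island probes get a myeloid-vs-lymphoid
  baseline contrast of ±0.1–0.3, which is what makes composition a real
  confounder. The deconvolution panel is 120 open-sea probes (20 per cell
  type) given one-vs-rest reference profiles (0.85 vs 0.15).
- **Drift.** 20% of island clusters are planted (85% hyper on low-baseline
  islands, 15% hypo on high-baseline ones) and 5% of open-sea clusters
  outside blocks are planted hypo, all at ±0.05 per 10 years. Blocks are
  1–3 Mb intervals containing ≥ 8 open-sea clusters, effect −0.05 per
  10 years, placed ≥ 500 kb apart — two planted blocks closer than the
  smoothing span would in truth be a single contiguous hypomethylated
  region, so separation keeps the ground truth well defined; scattered
  open-sea drift likewise stays 500 kb clear of blocks.
- **Noise** is truncated Gaussian on the beta scale (sd 0.02): simpler than
  a Beta model and adequate for the rank/regression statistics downstream.
- **Peaks.** Enriched factors cover 30% of planted hyper island clusters
  plus 3% background; null factors cover 3% everywhere. Peaks are ~100 bp
  intervals centred on a member probe.
- **Expression** baselines are Normal per gene class — hyper-target (4, 1),
  neutral (7, 2), hypo-target (9, 1) on a log2-like scale — with no age
  dependence, so methylation drift is decoupled from expression change by
  construction.
- **Second cohort.** The normal/"cancer" comparison cohort uses idealized
  age matching: every sample sits at the cohort mid-age, so within-group
  variance is noise and mixture variation rather than age drift, and the
  only systematic normal-vs-cancer difference is the planted extra
  hypomethylation inside block intervals. (With ages spanning the full
  range, drift variance would dominate the block-level statistics and the
  observed-vs-random comparison would mix a scale difference into the
  location shift of interest.)

The **global-null configuration** (`simulate.null_config`) turns off drift,
blocks, the composition-age trend, *and* cell-specific probes. The last is
deliberate: shared mixture noise is correlated across clusters, and although
each cluster's p-value remains marginally uniform, the dependence breaks the
independence assumed by a genome-wide KS uniformity check.

What the generator does **not** emulate: type I/II probe chemistry, batch
effects needing BMIQ/ISVA-style correction, SNP/cross-reactive probes,
regional sample-to-sample biological covariance beyond the cell mixture, or
any coupling between drift and expression change. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
model, not robustness to those real-data artifacts.

## Numerical choices and degenerate inputs

- Exact-fit regressions report t = ±inf (p = 0), or t = 0, p = 1 for a
  constant response; the tolerance is scaled to the response magnitude.
- The deconvolution QP tolerates −1e−10 constraint violations before
  clipping at 0; ties between active sets resolve to the first-found
  minimum, which is unique for full-rank panels.
- Blocks with no CGIs get an undefined enrichment (flagged, not dropped);
  n_cgi < 5 is flagged "few CGIs".
- Zero-flag TF profiles are dropped before Jaccard filtering (undefined J).
- Wilcoxon tests use the exact null for small samples, normal approximation
  otherwise (ties force the approximation).
- All randomness flows from explicit seeds; pipeline reports embed the
  configuration hash and seed and are byte-identical across reruns.

## Default problem sizes

The default pipeline scale is 150 samples over 4 chromosomes × 1200 probes
(~3100 clusters, 6 planted blocks, 8 TF peak sets, ~350 genes) with 500
bootstrap iterations; the test suite uses 60–200 samples and 1–4
chromosomes per property. These sizes were chosen so each statistical check
is well-powered at desk scale while the full suite runs in minutes; all of
them are configuration parameters, not constants.

## Known limitations

- The bounded-clustering rule is greedy; a width-optimal split could differ
  at cluster boundaries (the published function's exact split is unstated).
- The FWER bootstrap assumes exchangeable residual vectors across samples;
  heteroscedastic age-dependent noise would call for a wild bootstrap.
- Fisher enrichment treats clusters as exchangeable units regardless of
  probe count; larger clusters are more likely to carry a peak flag, which
  the per-factor overlap fraction makes visible but the test does not model.
- The expression stage compares gene-level means; sample-level mixed models
  are out of scope.
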