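# Methods

## Count model

Gene-level counts are modelled per gene as negative binomial,
`K_gj ~ NB(mu_gj, alpha_g)` with variance `mu + alpha mu^2`, log link
and size-factor offsets:

    log mu_gj = log s_j + x_j' beta_g

Size factors `s_j` use the median-of-ratios estimator: genes containing
any zero are excluded from the per-gene geometric-mean reference, and
each sample's factor is the median of count/reference ratios. Factors
are not rescaled to geometric mean 1 by default (a flag enables it);
between-sample ratios are invariant either way. If no gene is nonzero
in every sample the estimator refuses and points at the total-count
fallback.

The design matrix is intercept + main effects: treatment coding against
a declared reference level per categorical variable, continuous
covariates passed through unchanged. The SEP covariate (a fluorescence
marker median per sample) is min–max scaled to [0, 1] before entering
the model, so its coefficient reads as the log2 expression change from
a fully pre-SEP to a fully post-SEP sample. Rank-deficient designs are
rejected with the confounded columns named; in the default synthetic
cohort TRP1 is constant within genotype and is therefore not part of
the default model.

**Fitting.** Coefficients are estimated by Fisher-scoring IRLS, batched
across genes in numpy (the score with respect to the linear predictor
is `(y - mu)/(1 + alpha mu)` and the expected information weight
`mu/(1 + alpha mu)`), with step halving on likelihood decrease, an
eta clip at +/-30 and a 1e-10 ridge for numerical safety. Standard
errors come from the observed information at the converged fit,
`w_obs = mu (1 + alpha y)/(1 + alpha mu)^2`. Internally the fit is on
the natural-log scale; coefficients and SEs are divided by ln 2 at the
reporting boundary so everything user-facing is log2. Non-converged
genes keep their last iterate and are flagged. A test certifies the
IRLS solution against an independent derivative-free maximisation of
the identical likelihood (agreement within 1e-4 log2 units).

**Dispersion.** Per-gene alpha is estimated by profile likelihood: a
Poisson-limit fit provides means for a method-of-moments start, then
two rounds of 1-D maximisation of the Cox–Reid adjusted likelihood
(`loglik - 0.5 log det X'WX`) given fitted means, each followed by a
coefficient refit. The Cox–Reid term compensates for the mean
parameters being estimated from the same data; without it alpha is
biased low at 18 samples with 6 design columns and Wald intervals
undercover. Alphas are floored at 1e-8 and capped at 10; all-zero genes
are excluded and flagged; genes where the MLE and moments estimates
disagree more than 10-fold are flagged. No empirical-Bayes shrinkage of
dispersions or coefficients is applied: coefficients are reported raw
so they stay interpretable as log2 abundance changes, and correctness
is certified against the likelihood oracle instead of a reference
implementation.

**Testing.** Two-sided Wald z = beta/SE, Benjamini–Hochberg adjustment
over exactly the genes with a defined p-value, and significance calls
requiring adjusted p below the FDR (default 0.05) *and* |log2FC| above
the threshold (default 0.5) — the threshold is a post-hoc filter on the
point estimate, not a composite-null test; the choice is exposed via
the `lfc_threshold` argument.

## Attribution

The contribution of factor f between two condition profiles is
`sum_c beta_c (x_c(test) - x_c(ref))` over f's design columns; the
residual is defined as observed change minus all contributions, so the
decomposition is exact by construction. Observed change is computed
from condition-mean normalised counts on the log2(x+1) scale — not from
model-fitted means — because the reconstruction panels compare against
the observed aged profile. Percentages (contribution/observed x 100)
are deliberately unclipped: values outside 0–100% mean the model
predicts the wrong direction or too large a magnitude and are part of
the signal. Genes with normalised log-phase counts below 4 are excluded
from summaries, as are genes with exactly zero observed change (counted
separately). Two aggregate statistics are printed because per-gene
percentages are heavy-tailed: the median of per-gene percentages
(headline) and the L1-weighted aggregate
`sum|contribution| / sum|observed| x 100`.

## Chromosome-arm statistics

ChrXIIr is defined as chromosome XII genes with start strictly beyond a
boundary defaulting to the right edge of the rDNA exclusion zone
(XII:450000–491000 in the real genome); XII genes left of the boundary
belong to neither comparison group. DE-gene enrichment per chromosome
is observed/(total_DE x n_chrom/n_genome), with XII always split at the
rDNA into "XII-left" and "XIIr" rows (whole-XII rows behind a flag).
The ERC proxy is the log2 change of the reverse-strand IGS2 probe
(IGS2-1AS by default; configurable, because probe S/AS labels versus
the quantified strand convention of reverse-stranded libraries leave
room for inversion). Per-sample ChrXIIr amplification is the median
(mean available) log2 change of ChrXIIr genes against a reference
condition mean — under uniform dosage this estimates log2 of the
copy-number ratio. Marker regressions are ordinary least squares with
R² and a pointwise t-based 95% confidence band for the mean response
(prediction intervals are out of scope).

## Copy-number windows

Sliding windows (genome: 25 kb every 5 kb; rDNA: 1 kb every 200 bp)
start at position 1 and must fit inside the chromosome. A read is
assigned to every window containing its start position — simple and
deterministic, and ratio statistics at these window sizes are
insensitive to the assignment rule. Windows overlapping any mask
interval by at least 1 bp are dropped from every downstream statistic.
Size factors are median-of-ratios over unmasked windows excluding those
overlapping the rDNA zone; ChrXIIr windows are *not* excluded, so the
copy-neutral majority anchors the factors and genuine amplifications
survive normalisation. Ratios with a zero reference count are NaN and
flagged. Coordinates are 1-based inclusive internally; BED conversion
happens only at I/O.

## Synthetic data generator

The generator emulates the study design at desk scale with full ground
truth. Defaults (all overridable on `SimConfig`):

- **Genome**: 16 chromosomes at ~1/10 S. cerevisiae lengths
  (~1.2 Mb total). Chromosome XII is 150 kb with an rDNA zone at
  45–65 kb and ChrXIIr beyond 65 kb (~68 genes). The zone is larger
  than linear scaling would give: physically the rDNA tract is
  megabase-scale tandem repeats collapsed onto a short reference
  region, so real libraries are read-rich over the zone; a linearly
  scaled 4 kb zone would make rDNA ratio estimates Poisson-noise-bound
  at desk-scale library sizes while 20 kb (~1.6% of the genome) keeps
  depth realistic without perturbing size factors.
- **Cohort**: 3 genotypes (wild type plus two mutants patterned on
  ERC-deficient strains) x 3 ages (log, 24 h, 48 h) x 2 replicates =
  18 RNA samples. Latent SEP per condition rises with age in wild type
  and the recombination-deficient mutant but stays low in the other
  (senescence and ERC load dissociate across cohorts); replicate SEP
  jitter SD 0.08. ERC load is ~exponential in age for wild type
  (1, 20, 100 arbitrary units) and near-flat in the mutants; magnitudes
  are free parameters of the generator, not claims about real cells.
- **Expression**: per-gene baseline log2 mean ~ N(7, 2) clipped to
  [2, 14]; a 150-gene SEP signature with |log2 effect| uniform in
  [0.75, 2.5] and balanced signs (so the count composition stays
  stable, as in a real stress-response signature with induced and
  repressed branches); age and genotype effects N(0, 0.15) and
  N(0, 0.10) per gene and level; ChrXIIr genes gain
  0.585 log2 x SEP (1.5x at full SEP — one extra copy in a diploid);
  IGS probes scale linearly with ERC load. Counts are NB with
  dispersion alpha = 0.02 (typical for isogenic replicate cultures),
  drawn as a gamma-Poisson mixture; library factors are log-normal
  (SD 0.15).
- **SEP marker**: affine transform of latent SEP (500 + 4500x) plus
  Gaussian noise (SD 50), standing in for an imaging marker median in
  arbitrary fluorescence units.
- **DNA**: 1e5 uniform read starts per library, weighted by regional
  copy number (baseline diploid; configurable ChrXIIr copies and
  per-cell rDNA fold).

What the generator does **not** model: batch effects, GC/length bias,
outlier samples, single-cell structure, or read sequences. Passing
tests therefore demonstrate correctness of the estimators and pipeline
plumbing under the declared noise model, not robustness to artefacts of
real libraries.

## Validation design choices

- Estimator-recovery experiments (fixed SEP effect of 1.0 across 200
  genes) use a SEP pattern deliberately decoupled from genotype and age
  and known (unit) size factors: when half the transcriptome carries a
  designed effect, count composition contaminates size-factor
  estimation, and the recovery test is meant to isolate the GLM
  estimator. In the default cohort — where the signature is a small
  minority — estimated factors are used throughout.
- Sensitivity and observed FDR of end-to-end signature recovery are
  binomial draws per simulated cohort; the corresponding test averages
  them over three replicate simulations rather than asserting on a
  single draw.
- The per-sample SEP covariate in the default pipeline is the min–max
  scaled noisy marker, mirroring how a real analysis would enter
  fluorescence medians.

## Known limitations

- Wald tests with 2-per-group designs are anticonservative (as for any
  NB GLM without moderation); the null-calibration test uses 6 + 6.
- No interaction terms, LRT, independent filtering, or coefficient
  shrinkage; single NB family only.
- The IGS probe coordinate duplication between sense and antisense
  records is reproduced as printed in the source annotation and not
  resolved; records are distinguished by strand.
- Real-data headline quantities (e.g. attribution percentages of a
  specific wild-type ageing comparison) depend on the deposited
  datasets and are not asserted by this package; the pipeline reports
  both aggregation conventions instead.
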