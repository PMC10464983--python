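# repliage

Analysis toolkit for dissecting gene expression change in replicatively
ageing budding yeast. Ageing yeast mother cells accumulate
extrachromosomal rDNA circles (ERCs), pass an abrupt senescence entry
point (SEP, scored by a Tom70-GFP focus marker), and amplify ChrXIIr — a
noncentromeric fragment of chromosome XII spanning part of the rDNA
array and the ~0.6 Mb gene-bearing right arm. `repliage` implements the
statistical machinery needed to ask which of these processes actually
drives the ageing transcriptome:

- **Multi-factor negative-binomial GLM** for gene-level counts,
  `K_gj ~ NB(mu_gj, alpha_g)` with `Var = mu + alpha mu^2` and
  `log mu_gj = log s_j + x_j' beta_g`, where `s_j` are median-of-ratios
  size factors, `x_j` mixes treatment-coded categorical covariates
  (genotype, age, TRP1, carbon source, ERC class) with a continuous SEP
  covariate min–max scaled to [0, 1]. Coefficients are reported in log2
  units; per-gene dispersions come from a Cox–Reid adjusted profile
  likelihood; testing is two-sided Wald with Benjamini–Hochberg FDR
  (defaults FDR < 0.05, |log2FC| > 0.5).
- **Attribution**: the observed log2 change between two conditions is
  decomposed as `observed = sum_f beta_f * Delta x_f + residual`, with
  percent attribution `contribution / observed x 100` (out-of-range
  values retained; genes under 4 normalised log-phase counts excluded).
- **Chromosome-arm signal**: ChrXIIr vs other-chromosome change
  distributions, per-chromosome DE enrichment `obs / (total_DE x
  n_chrom / n_genome)` with chromosome XII split at the rDNA, a
  per-sample ChrXIIr amplification estimate, an ERC proxy from the
  reverse-strand IGS2 ncRNA probe, and OLS marker regressions with R²
  and t-based 95% confidence bands.
- **Copy number from resequencing**: reads counted in 25 kb windows
  spaced 5 kb (1 kb / 200 bp across the rDNA), exclusion masks, size
  factors from unmasked non-rDNA windows, aged/reference ratio tracks.
- **Synthetic data generator** emulating the full study design with
  ground truth: NB counts under genotype/age/SEP effects, SEP-coupled
  ChrXIIr gene dosage, ERC-driven IGS induction, noisy SEP marker
  values, and diploid read-depth profiles with rDNA/ChrXIIr gains.

See `docs/methods.md` for the model, generator and numerical details.

## Worked example

Run the end-to-end synthetic demonstration (simulate → normalise → fit →
test → attribute → arm statistics → copy number):

```sh
repliage run-all --seed 1 --out demo/
```

The report (`demo/report.json`) from this command contains, among other
entries:

```json
"de":  {"sep": {"up": 91, "down": 82}},
"arm_change": {"ChrXIIr": {"median": 0.4287, "n": 68},
               "other":   {"median": -0.0549, "n": 879}},
"regressions": {
  "chrxiir_amplification_vs_marker": {"r_squared": 0.9518},
  "erc_proxy_vs_marker":             {"r_squared": 0.1825}},
"cnv": {"chrxiir_median_ratio": 1.5051, "rdna_median_ratio": 14.2423}
```

Reading these numbers: 173 genes are called significantly associated
with the continuous SEP covariate (the generator planted a 150-gene
signature plus SEP-coupled dosage on 68 ChrXIIr genes); ChrXIIr genes
rise by a median 0.43 log2 units from log phase to 48 h while other
chromosomes stay flat; the per-sample ChrXIIr amplification estimate
tracks the SEP marker tightly (R² = 0.95) whereas the IGS2-based ERC
proxy — decoupled from the SEP in the generator's design — correlates
weakly (R² = 0.18); and the DNA window pipeline recovers the simulated
one-extra-copy ChrXIIr gain (ratio 1.5 in a diploid) and the 14-fold
rDNA amplification.

Individual stages are exposed as `repliage simulate | normalize | fit |
test | attribute | arm | enrich | erc-proxy | cnv`, and everything is
importable from Python (`import repliage`).

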