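"""End-to-end orchestration on synthetic data.

Runs the full analysis in method order — simulate, normalise, fit the
multi-factor NB GLM with a continuous SEP covariate, test, attribute
expression change to model factors, chromosome-arm statistics, ERC proxy
and marker regressions, and the DNA copy-number window pipeline — and
writes a JSON report of headline statistics.  Deterministic under a
fixed seed.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import attribution as attr
from . import chrom_signal as sig
from . import cnv
from . import nbglm
from . import normalization as norm
from . import simulate as sim

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds default to the study's stated values."""
    seed: int = 1
    outdir: str | None = None
    fdr: float = 0.05
    lfc_threshold: float = 0.5
    min_ref: float = 2.0       # MA-plot reference filter (linear scale)
    min_count: float = 4.0     # attribution log-phase inclusion filter
    sim: sim.SimConfig = field(default_factory=sim.SimConfig)

    def __post_init__(self):
        if min(self.fdr, self.lfc_threshold, self.min_ref, self.min_count) <= 0:
            raise ValueError("thresholds must be positive")
        if self.sim.seed != self.seed:
            self.sim = self.sim.with_(seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        sim_cfg = sim.SimConfig(**data.pop("sim", {}))
        return cls(sim=sim_cfg, **data)


def chrxiir_dosage_benchmark(seed: int = 1, n_reads: int = 100_000) -> float:
    """Median ChrXIIr window ratio for an aged diploid carrying one extra
    ChrXIIr copy (copies 3 vs 2); expectation 1.5.

    Runs the full copy-number pipeline: 25 kb / 5 kb windows, mask step,
    read counting, size factors from unmasked non-rDNA windows, ratios.
    """
    cfg = sim.SimConfig(seed=seed, n_dna_reads=n_reads)
    profiles = {"log": sim.CopyProfile(),
                "aged": sim.CopyProfile(chrxiir_copies=3.0)}
    reads = sim.simulate_dna_reads(cfg, profiles)
    windows = cnv.make_windows(cfg.chrom_sizes)
    windows = cnv.apply_masks(windows, pd.DataFrame(columns=["chrom", "start", "end"]))
    track = cnv.WindowTrack.from_reads(windows, reads)
    track = cnv.normalize_and_ratio(track, "log", rdna_region=cfg.rdna_region)
    region = ("XII", cfg.chrxiir_boundary + 1, cfg.chrom_sizes["XII"])
    return cnv.region_median_ratio(track, "aged", region)


def rdna_fold_benchmark(seed: int = 1, n_reads: int = 100_000,
                        fold: float = 14.0) -> float:
    """Median rDNA window ratio for an aged library with *fold*-amplified
    per-cell rDNA (1 kb / 200 bp windows, size factors from non-rDNA
    genome windows); expectation *fold*."""
    cfg = sim.SimConfig(seed=seed, n_dna_reads=n_reads)
    profiles = {"log": sim.CopyProfile(),
                "aged": sim.CopyProfile(rdna_fold=fold)}
    reads = sim.simulate_dna_reads(cfg, profiles)
    windows = cnv.make_windows(cfg.chrom_sizes)
    track = cnv.WindowTrack.from_reads(windows, reads)
    track = cnv.normalize_and_ratio(track, "log", rdna_region=cfg.rdna_region)
    rdna = cnv.rdna_track(reads, cfg.rdna_region, genome_track=track)
    return float(rdna.ratios["aged"].median())


def default_model_spec(config: sim.SimConfig) -> nbglm.ModelSpec:
    """Genotype + Age + SEP main-effects model for the default cohort.

    TRP1 is constant within genotype in the default design (hence
    confounded) and is therefore not a default model variable.
    """
    return nbglm.ModelSpec([
        nbglm.Variable("Genotype", "categorical", list(config.genotypes),
                       config.genotypes[0]),
        nbglm.Variable("Age", "categorical", list(config.ages), config.ages[0]),
        nbglm.Variable("SEP", "continuous"),
    ])


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage on synthetic data; return the report dict."""
    report: dict = {"seed": config.seed,
                    "thresholds": {"fdr": config.fdr,
                                   "lfc": config.lfc_threshold,
                                   "min_ref": config.min_ref,
                                   "min_count": config.min_count}}
    scfg = config.sim

    logger.info("stage simulate: seed=%d", config.seed)
    genes = sim.simulate_annotation(scfg)
    samples = sim.simulate_phenotypes(scfg)
    counts, truth = sim.simulate_counts(scfg, genes, samples)

    logger.info("stage annotation: %d genes", len(genes))
    genes = ann.filter_genes(genes)
    genes = ann.flag_chrxiir(genes, boundary=scfg.chrxiir_boundary)
    counts = counts.loc[counts.index.intersection(genes["gene_id"])]

    logger.info("stage normalize")
    factors = norm.size_factors(counts)
    normalized = norm.normalize(counts, factors)

    logger.info("stage fit: NB GLM with SEP covariate")
    samples = samples.copy()
    samples["SEP"] = nbglm.scale_minmax(samples["sep_marker"].values)
    spec = default_model_spec(scfg)
    design = nbglm.build_design(samples, spec)
    disp = nbglm.estimate_dispersion(counts, design, factors)
    fit = nbglm.fit_nbglm(counts, design, factors, disp["alpha"])

    logger.info("stage test")
    de_sep = nbglm.wald_test(fit, "SEP", config.fdr, config.lfc_threshold)
    de_age = nbglm.wald_test(fit, f"Age[{scfg.ages[-1]}]",
                             config.fdr, config.lfc_threshold)
    report["de"] = {
        "sep": {"up": int((de_sep["call"] == "up").sum()),
                "down": int((de_sep["call"] == "down").sum())},
        "age_final": {"up": int((de_age["call"] == "up").sum()),
                      "down": int((de_age["call"] == "down").sum())},
        "n_genes_tested": int(de_sep["pvalue"].notna().sum()),
    }

    geno0, age0, age_last = scfg.genotypes[0], scfg.ages[0], scfg.ages[-1]
    ref_ids = [s for s, r in samples.iterrows()
               if r["Genotype"] == geno0 and r["Age"] == age0]
    test_ids = [s for s, r in samples.iterrows()
                if r["Genotype"] == geno0 and r["Age"] == age_last]

    logger.info("stage attribute: %s %s -> %s", geno0, age0, age_last)
    ref_mean = norm.condition_mean(normalized, ref_ids)
    test_mean = norm.condition_mean(normalized, test_ids)
    observed = np.log2(test_mean + 1) - np.log2(ref_mean + 1)
    prof_ref = {"Genotype": geno0, "Age": age0,
                "SEP": float(samples.loc[ref_ids, "SEP"].mean())}
    prof_test = {"Genotype": geno0, "Age": age_last,
                 "SEP": float(samples.loc[test_ids, "SEP"].mean())}
    contrib = attr.factor_contribution(fit, spec, prof_ref, prof_test)
    table = attr.attribution_table(observed, contrib)
    _, summary = attr.percent_attribution(table, ref_mean, config.min_count)
    report["attribution"] = summary

    logger.info("stage chrom-signal")
    arm_table, arm_summary = sig.arm_change(normalized, genes, ref_ids, test_ids)
    report["arm_change"] = {
        grp: {"median": float(row["median"]), "n": int(row["n"])}
        for grp, row in arm_summary.iterrows()}
    enrich = sig.chromosome_enrichment(de_sep, genes)
    report["enrichment_xiir_ratio"] = (
        float(enrich.loc["XIIr", "ratio"]) if "XIIr" in enrich.index else None)

    amp, proxy, marker = [], [], []
    for sid, sample in samples.iterrows():
        geno_ref = [s for s, r in samples.iterrows()
                    if r["Genotype"] == sample["Genotype"] and r["Age"] == age0]
        amp.append(sig.chrxiir_amplification(normalized, genes, geno_ref, sid))
        proxy.append(sig.erc_proxy(normalized, genes, geno_ref, [sid]))
        marker.append(sample["sep_marker"])
    reg_amp = sig.marker_regression(marker, amp)
    reg_erc = sig.marker_regression(marker, proxy)
    report["regressions"] = {
        "chrxiir_amplification_vs_marker": reg_amp.to_dict(),
        "erc_proxy_vs_marker": reg_erc.to_dict(),
    }

    logger.info("stage cnv: %d reads/library", scfg.n_dna_reads)
    reads = sim.simulate_dna_reads(scfg)
    windows = cnv.make_windows(scfg.chrom_sizes)
    track = cnv.WindowTrack.from_reads(windows, reads)
    track = cnv.normalize_and_ratio(track, "log", rdna_region=scfg.rdna_region)
    chrxiir_region = ("XII", scfg.chrxiir_boundary + 1,
                      scfg.chrom_sizes["XII"])
    rdna = cnv.rdna_track(reads, scfg.rdna_region, genome_track=track)
    report["cnv"] = {
        "chrxiir_median_ratio": cnv.region_median_ratio(track, "aged",
                                                        chrxiir_region),
        "rdna_median_ratio": float(rdna.ratios["aged"].median()),
    }

    if config.outdir:
        os.makedirs(config.outdir, exist_ok=True)
        counts.rename_axis("gene_id").to_csv(
            os.path.join(config.outdir, "counts.tsv"), sep="\t")
        samples.to_csv(os.path.join(config.outdir, "samples.tsv"), sep="\t")
        ann.write_gene_table(genes, os.path.join(config.outdir, "annotation.tsv"))
        fit.coef.rename_axis("gene_id").to_csv(
            os.path.join(config.outdir, "coefficients.tsv"), sep="\t")
        de_sep.rename_axis("gene_id").to_csv(
            os.path.join(config.outdir, "de_sep.tsv"), sep="\t")
        table.rename_axis("gene_id").to_csv(
            os.path.join(config.outdir, "attribution.tsv"), sep="\t")
        enrich.to_csv(os.path.join(config.outdir, "enrichment.tsv"), sep="\t")
        cnv.write_ratio_tsv(track, os.path.join(config.outdir, "cnv_ratios.tsv"))
        with open(os.path.join(config.outdir, "report.json"), "w") as handle:
            json.dump(report, handle, indent=2, sort_keys=True)
    return report
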