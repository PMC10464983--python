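"""Synthetic data generator with full ground truth.

Emulates the statistical structure of a replicative-ageing study in
budding yeast at desk scale: a ~1.2 Mb sixteen-chromosome genome
(~1/10 of S. cerevisiae), chromosome XII carrying an rDNA zone and a
gene-bearing right arm (ChrXIIr), and three cohorts (wild type plus two
mutants differing in ERC accumulation and senescence kinetics) sampled at
log phase, 24 h and 48 h of ageing in duplicate.

Per-gene log2 expected expression is additive in genotype, age, a latent
senescence (SEP) value multiplied by a designed signature, and — for
ChrXIIr genes — a gene-dosage term coupled linearly to the latent SEP
(default 0.585 log2 per unit SEP, i.e. 1.5x at full SEP, one extra copy
in a diploid).  The four rDNA intergenic-spacer probes scale with a
per-sample ERC load, which follows a roughly exponential age trajectory
in the wild type but stays low in the mutants, decoupling ERC load from
the SEP across cohorts.  Counts are negative-binomial around
library-scaled means.  DNA libraries are uniform read starts weighted by
regional copy number (baseline diploid, optional extra ChrXIIr copies
and rDNA fold change).

One simulated feature of real data deliberately absent: batch effects,
GC/length bias and outlier samples are not modelled; the noise model is
NB only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import RDNA_REGION  # noqa: F401  (real-genome default, for reference)

__all__ = [
    "SimConfig", "SimTruth", "CopyProfile",
    "simulate_annotation", "simulate_counts", "simulate_phenotypes",
    "simulate_dna_reads", "default_dna_profiles",
]

# S. cerevisiae R64 chromosome lengths scaled to ~1/10.  XII is enlarged
# and given a 20 kb rDNA zone: the physical rDNA tract is megabase-scale
# repeats collapsed onto a short reference zone, so read depth over the
# zone is high in real libraries; a linearly scaled zone would be
# unrealistically read-poor at desk-scale library sizes.
DEFAULT_CHROM_SIZES = {
    "I": 23_000, "II": 81_300, "III": 31_700, "IV": 153_200, "V": 57_700,
    "VI": 27_000, "VII": 109_100, "VIII": 56_300, "IX": 44_000, "X": 74_600,
    "XI": 66_700, "XII": 150_000, "XIII": 92_400, "XIV": 78_400,
    "XV": 109_100, "XVI": 94_800,
}
DEFAULT_RDNA_REGION = ("XII", 45_001, 65_000)
DEFAULT_CHRXIIR_BOUNDARY = 65_000

# Latent SEP value by (genotype, age): wild type and rad52 senesce
# strongly with age while spt3 stays largely pre-SEP; ERC load rises
# steeply with age in wild type only (arbitrary units, log phase = 1).
DEFAULT_LATENT_SEP = {
    ("wt", "log"): 0.05, ("wt", "24h"): 0.55, ("wt", "48h"): 0.95,
    ("spt3", "log"): 0.05, ("spt3", "24h"): 0.10, ("spt3", "48h"): 0.20,
    ("rad52", "log"): 0.05, ("rad52", "24h"): 0.75, ("rad52", "48h"): 1.00,
}
DEFAULT_ERC_LOAD = {
    ("wt", "log"): 1.0, ("wt", "24h"): 20.0, ("wt", "48h"): 100.0,
    ("spt3", "log"): 1.0, ("spt3", "24h"): 3.0, ("spt3", "48h"): 8.0,
    ("rad52", "log"): 1.0, ("rad52", "24h"): 1.5, ("rad52", "48h"): 2.5,
}


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Generator configuration; defaults define the study conditions."""
    seed: int = 1
    chrom_sizes: dict = field(default_factory=lambda: dict(DEFAULT_CHROM_SIZES))
    rdna_region: tuple = DEFAULT_RDNA_REGION
    chrxiir_boundary: int = DEFAULT_CHRXIIR_BOUNDARY
    n_genes: int = 1000
    te_every: int = 50                  # every k-th gene is a transposable element
    genotypes: tuple = ("wt", "spt3", "rad52")
    ages: tuple = ("log", "24h", "48h")
    n_reps: int = 2
    carbon: str = "glucose"
    latent_sep: dict = field(default_factory=lambda: dict(DEFAULT_LATENT_SEP))
    sep_jitter_sd: float = 0.08         # replicate-to-replicate SEP spread
    erc_load: dict = field(default_factory=lambda: dict(DEFAULT_ERC_LOAD))
    n_sep_signature: int = 150
    sep_effect_range: tuple = (0.75, 2.5)   # |log2 effect| of signature genes
    sep_effect_fixed: float | None = None   # overrides the range when set
    age_effect_sd: float = 0.15         # per gene, per aged level (log2)
    genotype_effect_sd: float = 0.10    # per gene, per non-wt genotype (log2)
    chrxiir_dosage_per_sep: float = 0.585   # log2 per unit SEP (1.5x at SEP=1)
    igs_baseline_log2: float = 5.0
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 2.0
    dispersion: float = 0.02            # NB alpha, Var = mu + alpha mu^2
    libsize_sd: float = 0.15            # log-normal spread of library factors
    sep_marker_intercept: float = 500.0  # arbitrary fluorescence units
    sep_marker_slope: float = 4500.0
    sep_marker_noise_sd: float = 50.0
    n_dna_reads: int = 100_000
    min_chrxiir_genes: int = 30

    def __post_init__(self):
        if self.seed is None:
            raise SimulationError("seed is mandatory")
        if self.chrxiir_dosage_per_sep < 0:
            raise SimulationError("dosage coupling must be >= 0")
        if any(v <= 0 for v in self.erc_load.values()):
            raise SimulationError("ERC loads must be > 0")
        if not all(0.0 <= v <= 1.0 for v in self.latent_sep.values()):
            raise SimulationError("latent SEP values must lie in [0, 1]")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class SimTruth:
    """Ground truth recorded by the count generator."""
    log2_mean: pd.DataFrame            # genes x samples, pre-noise (normalised scale)
    sep_beta: pd.Series                # designed signature effect per gene
    sep_beta_total: pd.Series          # signature + ChrXIIr dosage coupling
    signature_genes: list
    age_effects: pd.DataFrame          # genes x aged levels
    genotype_effects: pd.DataFrame     # genes x non-reference genotypes
    latent_sep: pd.Series              # per sample
    erc_load: pd.Series                # per sample
    lib_factors: pd.Series             # per sample
    dispersion: float

    def true_sep_de(self, lfc_threshold: float = 0.5) -> pd.Series:
        """Genes whose total SEP-coupled effect exceeds the threshold."""
        return self.sep_beta_total.abs() > lfc_threshold


IGS_PROBE_PLAN = (
    # (gene_id, offset_start, offset_end, strand) within the rDNA zone
    ("IGS2-1S", 500, 1400, "-"),
    ("IGS2-1AS", 500, 1400, "+"),
    ("IGS1-2S", 2000, 2900, "-"),
    ("IGS1-2AS", 2000, 2900, "+"),
)


def simulate_annotation(config: SimConfig) -> pd.DataFrame:
    """Tile non-overlapping genes over the synthetic genome.

    Chromosome XII carries the rDNA zone (gene-free apart from the four
    injected IGS probes) and a ChrXIIr right arm that must receive at
    least 30 genes.  The result satisfies the gene-table invariants of
    :mod:`repliage.annotation`.
    """
    total = sum(config.chrom_sizes.values())
    records = []
    gene_counter = 0
    for chrom, length in config.chrom_sizes.items():
        n_c = max(1, round(config.n_genes * length / total))
        spacing = length // n_c
        if spacing < 300:
            raise SimulationError(
                f"too many genes for chromosome {chrom} (spacing {spacing} bp)")
        gene_len = max(200, int(spacing * 0.6))
        for i in range(n_c):
            start = i * spacing + 101
            end = start + gene_len - 1
            if end > length:
                continue
            if chrom == config.rdna_region[0]:
                lo, hi = config.rdna_region[1], config.rdna_region[2]
                if lo <= start <= hi or lo <= end <= hi:
                    continue
            gene_counter += 1
            biotype = ("transposable_element"
                       if gene_counter % config.te_every == 0
                       else "protein_coding")
            records.append({
                "gene_id": f"g{chrom}-{i:04d}", "chrom": chrom,
                "start": start, "end": end,
                "strand": "+" if i % 2 == 0 else "-",
                "biotype": biotype, "is_chrxiir": False, "printed_coords": "",
            })
    zone_chrom, zone_lo, _zone_hi = config.rdna_region
    for gene_id, off_lo, off_hi, strand in IGS_PROBE_PLAN:
        records.append({
            "gene_id": gene_id, "chrom": zone_chrom,
            "start": zone_lo + off_lo, "end": zone_lo + off_hi,
            "strand": strand, "biotype": "rDNA_intergenic",
            "is_chrxiir": False, "printed_coords": "",
        })
    genes = pd.DataFrame(records)
    genes["is_chrxiir"] = ((genes["chrom"] == "XII")
                           & (genes["start"] > config.chrxiir_boundary))
    n_arm = int(genes["is_chrxiir"].sum())
    if n_arm < config.min_chrxiir_genes:
        raise SimulationError(
            f"only {n_arm} ChrXIIr genes generated; need >= "
            f"{config.min_chrxiir_genes} — enlarge chromosome XII or the "
            "gene budget")
    genes.attrs["rdna_region"] = tuple(config.rdna_region)
    return genes


def simulate_phenotypes(config: SimConfig) -> pd.DataFrame:
    """Sample table with latent SEP, ERC load and a noisy SEP marker.

    The marker stands in for a fluorescence median (arbitrary units): an
    affine transform of the latent SEP plus Gaussian noise.  Min-max
    scaling of the marker recovers the latent ordering when noise is 0.
    """
    rng = np.random.default_rng([config.seed, 11])
    rows = []
    for genotype in config.genotypes:
        for age in config.ages:
            for rep in range(1, config.n_reps + 1):
                base_sep = config.latent_sep[(genotype, age)]
                sep = float(np.clip(base_sep + rng.normal(0, config.sep_jitter_sd),
                                    0.0, 1.0))
                marker = (config.sep_marker_intercept
                          + config.sep_marker_slope * sep
                          + rng.normal(0, config.sep_marker_noise_sd))
                rows.append({
                    "sample_id": f"{genotype}_{age}_{rep}",
                    "Genotype": genotype, "Age": age,
                    "TRP1": "absent" if genotype == "wt" else "present",
                    "Carbon": config.carbon, "replicate": rep,
                    "sep_latent": sep,
                    "erc_load": config.erc_load[(genotype, age)],
                    "sep_marker": float(marker),
                })
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_counts(
    config: SimConfig,
    genes: pd.DataFrame,
    samples: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """NB count matrix plus ground truth for the given annotation.

    Per-gene log2 mean = baseline + genotype offset + age offset +
    latent_SEP x signature effect + ChrXIIr dosage x latent_SEP; IGS
    probes additionally add log2(ERC load).  Counts are
    NB(mean x library factor, alpha).
    """
    if samples is None:
        samples = simulate_phenotypes(config)
    rng = np.random.default_rng([config.seed, 23])
    gene_ids = genes["gene_id"].tolist()
    G, S = len(gene_ids), len(samples)
    is_igs = (genes["biotype"] == "rDNA_intergenic").values
    is_arm = genes["is_chrxiir"].astype(bool).values

    baseline = np.clip(
        rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, G),
        2.0, 14.0)
    baseline[is_igs] = config.igs_baseline_log2

    candidates = np.flatnonzero(~is_igs & ~is_arm)
    if config.n_sep_signature > len(candidates):
        raise SimulationError("signature larger than the eligible gene pool")
    sig_idx = rng.choice(candidates, size=config.n_sep_signature, replace=False)
    sep_beta = np.zeros(G)
    if config.sep_effect_fixed is not None:
        magnitudes = np.full(config.n_sep_signature, config.sep_effect_fixed)
    else:
        magnitudes = rng.uniform(*config.sep_effect_range, config.n_sep_signature)
    # balanced signs keep the count composition stable, as in a real
    # stress-response signature with induced and repressed branches
    signs = rng.choice([-1.0, 1.0], config.n_sep_signature)
    sep_beta[sig_idx] = signs * magnitudes

    aged_levels = [a for a in config.ages[1:]]
    age_eff = {a: rng.normal(0, config.age_effect_sd, G) for a in aged_levels}
    geno_levels = [g for g in config.genotypes[1:]]
    geno_eff = {g: rng.normal(0, config.genotype_effect_sd, G) for g in geno_levels}

    lib = np.exp(rng.normal(0, config.libsize_sd, S))

    log2_mean = np.tile(baseline[:, None], (1, S))
    for j, (sid, sample) in enumerate(samples.iterrows()):
        sep = sample["sep_latent"]
        if sample["Age"] in age_eff:
            log2_mean[:, j] += age_eff[sample["Age"]]
        if sample["Genotype"] in geno_eff:
            log2_mean[:, j] += geno_eff[sample["Genotype"]]
        log2_mean[:, j] += sep_beta * sep
        log2_mean[:, j] += is_arm * config.chrxiir_dosage_per_sep * sep
        log2_mean[is_igs, j] += np.log2(sample["erc_load"])

    mu = (2.0 ** log2_mean) * lib[None, :]
    alpha = config.dispersion
    if alpha < 1e-7:
        counts = rng.poisson(mu)
    else:
        # NB via gamma-Poisson mixture
        shape = 1.0 / alpha
        lam = rng.gamma(shape, mu * alpha)
        counts = rng.poisson(lam)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples.index)
    truth = SimTruth(
        log2_mean=pd.DataFrame(log2_mean, index=gene_ids, columns=samples.index),
        sep_beta=pd.Series(sep_beta, index=gene_ids),
        sep_beta_total=pd.Series(
            sep_beta + is_arm * config.chrxiir_dosage_per_sep, index=gene_ids),
        signature_genes=[gene_ids[i] for i in sig_idx],
        age_effects=pd.DataFrame({a: age_eff[a] for a in aged_levels},
                                 index=gene_ids),
        genotype_effects=pd.DataFrame({g: geno_eff[g] for g in geno_levels},
                                      index=gene_ids),
        latent_sep=samples["sep_latent"].copy(),
        erc_load=samples["erc_load"].copy(),
        lib_factors=pd.Series(lib, index=samples.index),
        dispersion=alpha,
    )
    return counts_df, truth


@dataclass
class CopyProfile:
    """Per-sample copy-number profile for DNA read simulation."""
    ploidy: float = 2.0
    chrxiir_copies: float = 2.0   # absolute copies of the ChrXIIr region
    rdna_fold: float = 1.0        # per-cell rDNA content relative to reference


def default_dna_profiles() -> dict[str, CopyProfile]:
    """Log-phase copy-neutral diploid vs an aged sample with one extra
    ChrXIIr copy and strong rDNA amplification."""
    return {
        "log": CopyProfile(),
        "aged": CopyProfile(chrxiir_copies=3.0, rdna_fold=14.0),
    }


def simulate_dna_reads(
    config: SimConfig,
    profiles: dict[str, CopyProfile] | None = None,
    n_reads: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Uniform read-start libraries weighted by regional copy number.

    Each chromosome contributes reads proportional to ploidy x length;
    on XII the rDNA zone is weighted by ``rdna_fold`` and the ChrXIIr
    region by its absolute copy number.  Returns per-sample DataFrames
    with columns ``chrom`` and ``pos`` (1-based).
    """
    if profiles is None:
        profiles = default_dna_profiles()
    n_reads = n_reads or config.n_dna_reads
    zone_chrom, zone_lo, zone_hi = config.rdna_region
    boundary = config.chrxiir_boundary
    out = {}
    for k, (name, prof) in enumerate(profiles.items()):
        rng = np.random.default_rng([config.seed, 37, k])
        segments = []  # (chrom, lo, hi, weight)
        for chrom, length in config.chrom_sizes.items():
            if chrom == zone_chrom:
                segments.append((chrom, 1, zone_lo - 1, prof.ploidy))
                segments.append((chrom, zone_lo, zone_hi,
                                 prof.ploidy * prof.rdna_fold))
                if boundary > zone_hi:
                    segments.append((chrom, zone_hi + 1, boundary, prof.ploidy))
                segments.append((chrom, boundary + 1, length, prof.chrxiir_copies))
            else:
                segments.append((chrom, 1, length, prof.ploidy))
        weights = np.array([(hi - lo + 1) * w for _, lo, hi, w in segments], float)
        probs = weights / weights.sum()
        alloc = rng.multinomial(n_reads, probs)
        chroms, positions = [], []
        for (chrom, lo, hi, _w), n_seg in zip(segments, alloc):
            if n_seg == 0:
                continue
            chroms.append(np.full(n_seg, chrom, dtype=object))
            positions.append(rng.integers(lo, hi + 1, size=n_seg))
        out[name] = pd.DataFrame({
            "chrom": np.concatenate(chroms),
            "pos": np.concatenate(positions).astype(int),
        })
    return out
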