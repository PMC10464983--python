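"""Shared fixtures: the default synthetic cohort and its fitted model.

Session-scoped so the expensive pieces (dispersion estimation, GLM fit)
run once for the whole suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pytest

import repliage as r
from repliage.pipeline import default_model_spec


@dataclass
class Dataset:
    cfg: r.SimConfig
    genes: pd.DataFrame
    samples: pd.DataFrame
    counts: pd.DataFrame
    truth: r.SimTruth


@dataclass
class FittedModel:
    dataset: Dataset
    spec: r.ModelSpec
    design: pd.DataFrame
    factors: pd.Series
    normalized: pd.DataFrame
    dispersion: pd.DataFrame
    fit: r.GLMFit
    de_sep: pd.DataFrame


def simulate_dataset(cfg: r.SimConfig) -> Dataset:
    genes = r.simulate_annotation(cfg)
    samples = r.simulate_phenotypes(cfg)
    counts, truth = r.simulate_counts(cfg, genes, samples)
    return Dataset(cfg, genes, samples, counts, truth)


def fit_sep_model(data: Dataset, sep_covariate: str = "sep_marker",
                  factors: pd.Series | None = None) -> FittedModel:
    """Fit the genotype + age + SEP model on a simulated cohort."""
    samples = data.samples.copy()
    if sep_covariate == "sep_latent":
        samples["SEP"] = samples["sep_latent"]
    else:
        samples["SEP"] = r.scale_minmax(samples["sep_marker"].values)
    spec = default_model_spec(data.cfg)
    design = r.build_design(samples, spec)
    if factors is None:
        factors = r.size_factors(data.counts)
    normalized = r.normalize(data.counts, factors)
    disp = r.estimate_dispersion(data.counts, design, factors)
    fit = r.fit_nbglm(data.counts, design, factors, disp["alpha"])
    de_sep = r.wald_test(fit, "SEP")
    model = FittedModel(data, spec, design, factors, normalized, disp, fit, de_sep)
    model.dataset.samples = samples
    return model


@pytest.fixture(scope="session")
def default_dataset() -> Dataset:
    return simulate_dataset(r.SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_model(default_dataset) -> FittedModel:
    return fit_sep_model(default_dataset)
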