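"""Chromosome-arm signal statistics.

Expression-based readouts of chromosome-scale events in ageing yeast:
per-gene log2 change grouped into ChrXIIr versus other chromosomes,
per-chromosome enrichment of differentially expressed genes (chromosome
XII split at the rDNA), an ERC proxy from the reverse-strand IGS2 ncRNA
signal, a per-sample ChrXIIr amplification estimate, and simple OLS
marker regressions with R^2 and t-based 95% confidence bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import t as _tdist


class SignalError(ValueError):
    pass


#: Default probe reporting ERC load: the IGS2 probe antisense to the
#: Pol I-transcribed 35S unit ("reverse strand" IGS2 ncRNA signal).
#: Configurable because S/AS probe labels versus the quantified strand
#: convention of reverse-stranded libraries leave room for inversion.
DEFAULT_ERC_PROBE = "IGS2-1AS"


def _condition_change(
    norm: pd.DataFrame, ref_samples, test_samples,
) -> pd.Series:
    """Per-gene log2 change of condition means, pseudocount 1."""
    ref = norm[list(ref_samples)].mean(axis=1)
    test = norm[list(test_samples)].mean(axis=1)
    return np.log2(test + 1.0) - np.log2(ref + 1.0)


def arm_change(
    norm: pd.DataFrame,
    genes: pd.DataFrame,
    ref_samples,
    test_samples,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene log2 change grouped as ChrXIIr vs other chromosomes.

    Genes on XII that are not on ChrXIIr belong to neither group and are
    excluded.  Returns the per-gene table (``change``, ``group``) and a
    per-group summary (median, quartiles, n).
    """
    genes = genes.set_index("gene_id") if "gene_id" in genes.columns else genes
    shared = norm.index.intersection(genes.index)
    change = _condition_change(norm.loc[shared], ref_samples, test_samples)
    sub = genes.loc[shared]
    group = pd.Series(pd.NA, index=shared, dtype=object)
    group[sub["is_chrxiir"].astype(bool)] = "ChrXIIr"
    group[sub["chrom"] != "XII"] = "other"
    table = pd.DataFrame({"change": change, "group": group}).dropna(subset=["group"])
    if not (table["group"] == "ChrXIIr").any():
        raise SignalError("no ChrXIIr genes in the analysed set")
    if not (table["group"] == "other").any():
        raise SignalError("no non-XII comparator genes in the analysed set")
    summary = table.groupby("group")["change"].agg(
        median="median",
        q25=lambda v: v.quantile(0.25),
        q75=lambda v: v.quantile(0.75),
        n="size",
    )
    return table, summary


def chromosome_enrichment(
    de: pd.DataFrame,
    genes: pd.DataFrame,
    split_xii: bool = True,
    calls: tuple = ("up", "down"),
) -> pd.DataFrame:
    """Observed/expected differentially expressed genes per chromosome.

    ``expected = total_DE x genes_on_chromosome / genes_in_genome`` and
    ``ratio = observed / expected``.  Chromosome XII is reported as two
    rows, left of the rDNA ("XII-left") and ChrXIIr, unless
    ``split_xii=False``.  With zero DE genes all ratios are reported as 0
    and flagged.
    """
    genes = genes.set_index("gene_id") if "gene_id" in genes.columns else genes
    shared = de.index.intersection(genes.index)
    if len(shared) < len(de):
        raise SignalError("DE genes missing from the gene table: "
                          f"{sorted(de.index.difference(genes.index))[:5]}")
    sub = genes.loc[shared]
    if split_xii:
        labels = sub["chrom"].where(sub["chrom"] != "XII",
                                    np.where(sub["is_chrxiir"], "XIIr", "XII-left"))
    else:
        labels = sub["chrom"]
    labels = pd.Series(labels, index=shared, name="chromosome")
    is_de = de.loc[shared, "call"].isin(calls)
    total_de = int(is_de.sum())
    total_genes = len(shared)
    rows = []
    for chrom, members in labels.groupby(labels):
        n_c = len(members)
        observed = int(is_de[members.index].sum())
        expected = total_de * n_c / total_genes
        ratio = observed / expected if expected > 0 else 0.0
        rows.append({"chromosome": chrom, "n_genes": n_c,
                     "observed": observed, "expected": expected,
                     "ratio": ratio, "undefined": expected == 0})
    return pd.DataFrame(rows).set_index("chromosome")


def erc_proxy(
    norm: pd.DataFrame,
    genes: pd.DataFrame,
    ref_samples,
    test_samples,
    probe_id: str = DEFAULT_ERC_PROBE,
) -> float:
    """ERC accumulation proxy: log2 change of the reverse-strand IGS2 signal.

    The change in normalised signal of the designated rDNA-intergenic
    probe between conditions reports ERC load, since the IGS ncRNAs are
    massively induced on ERCs.
    """
    genes = genes.set_index("gene_id") if "gene_id" in genes.columns else genes
    if probe_id not in norm.index or probe_id not in genes.index:
        raise SignalError(f"required ERC probe {probe_id!r} absent from data")
    ref = float(norm.loc[probe_id, list(ref_samples)].mean())
    test = float(norm.loc[probe_id, list(test_samples)].mean())
    return float(np.log2(test + 1.0) - np.log2(ref + 1.0))


def chrxiir_amplification(
    norm: pd.DataFrame,
    genes: pd.DataFrame,
    ref_samples,
    test_sample: str,
    stat: str = "median",
) -> float:
    """Per-sample ChrXIIr amplification estimated from expression.

    The median (or mean) log2 change of ChrXIIr genes in one aged sample
    relative to the reference-condition mean; under uniform dosage this
    approximates log2 of the copy-number ratio.
    """
    genes = genes.set_index("gene_id") if "gene_id" in genes.columns else genes
    shared = norm.index.intersection(genes.index)
    mask = genes.loc[shared, "is_chrxiir"].astype(bool)
    ids = shared[mask]
    if len(ids) == 0:
        raise SignalError("no ChrXIIr genes in the analysed set")
    change = _condition_change(norm.loc[ids], list(ref_samples), [test_sample])
    if stat == "median":
        return float(change.median())
    if stat == "mean":
        return float(change.mean())
    raise SignalError(f"unknown statistic {stat!r}")


@dataclass
class RegressionSummary:
    """OLS fit summary with a pointwise t-based 95% CI for the mean response."""
    slope: float
    intercept: float
    r_squared: float
    n: int
    slope_se: float
    intercept_se: float
    resid_sd: float
    x_mean: float
    sxx: float
    conf_level: float = 0.95

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, float)

    def confidence_band(self, x) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise CI for the mean response at the given x values."""
        x = np.asarray(x, float)
        tcrit = _tdist.ppf(0.5 + self.conf_level / 2, self.n - 2)
        half = tcrit * self.resid_sd * np.sqrt(
            1.0 / self.n + (x - self.x_mean) ** 2 / self.sxx)
        yhat = self.predict(x)
        return yhat - half, yhat + half

    def to_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept,
                "r_squared": self.r_squared, "n": self.n,
                "slope_se": self.slope_se, "intercept_se": self.intercept_se}


def marker_regression(x, y) -> RegressionSummary:
    """OLS regression of y on x with R^2 and a 95% mean-response CI band."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise SignalError("x and y lengths differ")
    if len(x) < 3:
        raise SignalError("need at least 3 points")
    if np.ptp(x) == 0:
        raise SignalError("x is constant; regression undefined")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    resid_sd = float(np.sqrt(res.ssr / res.df_resid)) if res.df_resid > 0 else 0.0
    return RegressionSummary(
        slope=float(res.params[1]), intercept=float(res.params[0]),
        r_squared=float(res.rsquared), n=len(x),
        slope_se=float(res.bse[1]), intercept_se=float(res.bse[0]),
        resid_sd=resid_sd, x_mean=float(x.mean()),
        sxx=float(((x - x.mean()) ** 2).sum()),
    )


def correlate_signature(
    coefs: pd.Series,
    external_change: pd.Series,
    gene_subset=None,
) -> RegressionSummary:
    """Regress an external per-gene change vector on model coefficients.

    Gene identifiers are intersected (optionally restricted to
    *gene_subset*, e.g. an ESR gene list); at least 3 shared genes are
    required.
    """
    coefs, external_change = coefs.align(external_change, join="inner")
    if gene_subset is not None:
        keep = coefs.index.intersection(pd.Index(gene_subset))
        coefs, external_change = coefs.loc[keep], external_change.loc[keep]
    mask = coefs.notna() & external_change.notna()
    coefs, external_change = coefs[mask], external_change[mask]
    if len(coefs) < 3:
        raise SignalError(
            f"only {len(coefs)} shared genes; need at least 3")
    return marker_regression(coefs.values, external_change.values)
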