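"""Decomposition of observed expression change into model-factor contributions.

Given a fitted NB GLM, the contribution of a factor to the change between
two conditions is beta_f * (x_f(test) - x_f(ref)) summed over that
factor's design columns — linear bookkeeping on fitted coefficients, no
causal claim.  The residual is defined as the remainder, so observed
change always equals the sum of contributions plus the residual exactly.
Percent attribution divides a factor's contribution by the observed
change; values outside 0-100% are retained, since they are meaningful
(the model predicting change in the wrong direction or of too great a
magnitude).  Genes with a normalised read count below 4 at the reference
(log-phase) condition are excluded from summaries.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .nbglm import GLMFit, ModelSpec, encode_profile

logger = logging.getLogger(__name__)


class AttributionError(ValueError):
    pass


def factor_contribution(
    fit: GLMFit,
    spec: ModelSpec,
    cond_ref: dict,
    cond_test: dict,
    factors: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene, per-factor log2 contributions between two condition profiles.

    *cond_ref* / *cond_test* map every model variable to a level (for
    categorical variables) or numeric value (continuous).  A factor whose
    covariates are identical in both profiles contributes exactly 0; a
    warning is logged when a requested factor has zero covariate
    difference (e.g. TRP1 when comparing the same strain at two ages).
    """
    x_ref = encode_profile(spec, cond_ref)
    x_test = encode_profile(spec, cond_test)
    dx = x_test - x_ref
    names = factors if factors is not None else [v.name for v in spec.variables]
    out = {}
    for name in names:
        cols = spec.columns_for(name)
        delta = dx[cols]
        if (delta == 0).all():
            logger.warning("factor %r has zero covariate difference between "
                           "the compared profiles; contribution is 0", name)
        out[name] = fit.coef[cols].values @ delta.values
    return pd.DataFrame(out, index=fit.coef.index)


def attribution_table(
    observed_change: pd.Series,
    contributions: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble observed change, contributions and the residual remainder.

    ``observed = sum(contributions) + residual`` holds exactly by
    construction for every gene.
    """
    observed, contributions = observed_change.align(
        contributions, join="inner", axis=0)
    table = contributions.copy()
    table.insert(0, "observed_change", observed)
    table["residual"] = observed - contributions.sum(axis=1)
    return table


def percent_attribution(
    attr: pd.DataFrame,
    log_phase_norm: pd.Series,
    min_count: float = 4.0,
) -> tuple[pd.DataFrame, dict]:
    """Per-gene percent attribution and per-factor summaries.

    *attr* is the output of :func:`attribution_table`;
    *log_phase_norm* gives each gene's normalised count (linear scale) at
    the reference condition; genes below *min_count* (default 4) are
    excluded.  Percentages are contribution / observed change x 100 and
    are deliberately not clipped to 0-100.  Genes with exactly zero
    observed change have undefined percentages and are excluded from
    summaries (their number is reported).

    Returns the per-gene percentage table (with an ``included`` flag) and
    a summary dict: per-factor median and quartiles of included per-gene
    percentages, plus an L1-weighted aggregate
    ``sum|contribution| / sum|observed| x 100``.
    """
    factor_cols = [c for c in attr.columns if c != "observed_change"]
    log_phase_norm = log_phase_norm.reindex(attr.index)
    included = log_phase_norm >= min_count
    observed = attr["observed_change"]
    defined = observed != 0
    pct = attr[factor_cols].div(observed, axis=0) * 100.0
    pct[~defined] = np.nan
    pct["included"] = included

    use = included & defined
    summary: dict = {
        "n_genes": int(len(attr)),
        "n_included": int(included.sum()),
        "n_zero_observed": int((included & ~defined).sum()),
        "factors": {},
    }
    for col in factor_cols:
        vals = pct.loc[use, col]
        summary["factors"][col] = {
            "median_percent": float(vals.median()) if len(vals) else float("nan"),
            "q25": float(vals.quantile(0.25)) if len(vals) else float("nan"),
            "q75": float(vals.quantile(0.75)) if len(vals) else float("nan"),
            "aggregate_percent": float(
                attr.loc[use, col].abs().sum()
                / max(observed[use].abs().sum(), 1e-300) * 100.0),
        }
    return pct, summary


def reconstruct_profile(
    log_phase_log2: pd.Series,
    contribution: pd.Series,
) -> pd.Series:
    """Log-phase expression with a component's contribution added (log2).

    Suitable as the test condition of an MA comparison against log phase:
    passing the full observed change reproduces the aged profile exactly;
    passing observed minus the SEP and Age contributions gives the
    residual panel.
    """
    log_phase_log2, contribution = log_phase_log2.align(contribution, join="inner")
    return log_phase_log2 + contribution
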