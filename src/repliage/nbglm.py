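"""Multi-factor negative-binomial GLM for count matrices.

The engine behind the pipeline's linear models: per-gene negative-binomial
regression (variance mu + alpha*mu^2) with a log link, size factors as
offsets, treatment-coded categorical covariates and continuous covariates
(e.g. a min-max-scaled senescence marker).  Fitting is batched
Fisher-scoring IRLS across genes; coefficients are reported in log2 units
(natural-log estimates divided by ln 2) so that a coefficient reads as the
log2 normalised mRNA abundance change caused by that factor.  Standard
errors come from the observed information at the converged fit.  Testing
is a two-sided Wald test with Benjamini-Hochberg FDR adjustment; genes are
called up/down when adjusted p < fdr and |log2FC| exceeds the fold-change
threshold (defaults 0.05 and 0.5).

Dispersion is estimated per gene by profile likelihood: method-of-moments
initialisation from a Poisson fit, then alternating 1-D maximum-likelihood
updates of alpha given fitted means and coefficient refits.  No
empirical-Bayes shrinkage of dispersions or coefficients is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import norm as _normal
from statsmodels.stats.multitest import multipletests

LN2 = float(np.log(2.0))
MIN_ALPHA = 1e-8
MAX_ALPHA = 10.0
_ETA_CLIP = 30.0


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Model specification and design matrices
# ---------------------------------------------------------------------------

@dataclass
class Variable:
    name: str
    kind: str  # "categorical" | "continuous"
    levels: list[str] | None = None
    reference: str | None = None

    def __post_init__(self):
        if self.kind not in ("categorical", "continuous"):
            raise ModelError(f"unknown variable kind: {self.kind!r}")
        if self.kind == "categorical":
            if not self.levels:
                raise ModelError(f"categorical variable {self.name!r} needs levels")
            if self.reference is None:
                self.reference = self.levels[0]
            if self.reference not in self.levels:
                raise ModelError(
                    f"reference {self.reference!r} not among levels of {self.name!r}")


@dataclass
class ModelSpec:
    """Intercept + main effects model over the listed variables."""
    variables: list[Variable] = field(default_factory=list)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelSpec":
        return cls([Variable(**v) for v in data["variables"]])

    @classmethod
    def from_yaml(cls, path: str) -> "ModelSpec":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle))

    def design_columns(self) -> list[str]:
        cols = ["Intercept"]
        for var in self.variables:
            if var.kind == "categorical":
                cols += [f"{var.name}[{lv}]" for lv in var.levels if lv != var.reference]
            else:
                cols.append(var.name)
        return cols

    def columns_for(self, name: str) -> list[str]:
        for var in self.variables:
            if var.name == name:
                if var.kind == "categorical":
                    return [f"{name}[{lv}]" for lv in var.levels if lv != var.reference]
                return [name]
        raise ModelError(f"unknown model variable: {name!r}")


def scale_minmax(values) -> np.ndarray:
    """Min-max scale to [0, 1].  Errors on a constant vector."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise ModelError("constant covariate: min-max scaling undefined "
                         "(covariate uninformative)")
    return (values - lo) / (hi - lo)


def encode_profile(spec: ModelSpec, profile: dict) -> pd.Series:
    """Design-row encoding of a single condition profile (dict of
    variable name -> level or numeric value)."""
    row = {"Intercept": 1.0}
    for var in spec.variables:
        if var.name not in profile:
            raise ModelError(f"profile missing value for variable {var.name!r}")
        value = profile[var.name]
        if var.kind == "categorical":
            if value not in var.levels:
                raise ModelError(
                    f"value {value!r} not a level of {var.name!r} {var.levels}")
            for lv in var.levels:
                if lv != var.reference:
                    row[f"{var.name}[{lv}]"] = 1.0 if value == lv else 0.0
        else:
            row[var.name] = float(value)
    return pd.Series(row).reindex(spec.design_columns())


def build_design(samples: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Treatment-coded design matrix (samples x columns) from a sample table.

    One column per non-reference level per categorical variable, one per
    continuous variable, plus an all-ones intercept.  Raises on rank
    deficiency, listing the confounded columns.
    """
    rows = []
    for _, sample in samples.iterrows():
        rows.append(encode_profile(spec, sample.to_dict()))
    design = pd.DataFrame(rows, index=samples.index)
    X = design.values.astype(float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [design.columns[i] for i in range(len(diag))
               if diag[i] < 1e-8 * max(diag.max(), 1.0)]
        raise ModelError(
            f"design matrix is rank deficient; confounded columns: {bad}")
    return design


# ---------------------------------------------------------------------------
# Likelihood and batched IRLS
# ---------------------------------------------------------------------------

def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha) -> np.ndarray:
    """Negative-binomial log-likelihood summed over samples, per gene.

    Parameterisation: Var = mu + alpha * mu^2 (r = 1/alpha).  Shapes:
    y, mu (G, N); alpha scalar or (G,).  Returns (G,).
    """
    y = np.asarray(y, float)
    mu = np.maximum(np.asarray(mu, float), 1e-300)
    alpha = np.broadcast_to(np.asarray(alpha, float), (y.shape[0],))
    r = 1.0 / np.maximum(alpha, MIN_ALPHA)
    rr = r[:, None]
    ll = (gammaln(y + rr) - gammaln(rr) - gammaln(y + 1.0)
          + y * np.log(mu / (mu + rr)) + rr * np.log(rr / (rr + mu)))
    return ll.sum(axis=1)


def _irls(Y, X, offset, alpha, max_iter=100, tol=1e-10, ridge=1e-10):
    """Batched Fisher-scoring IRLS for NB regression with log link.

    Y (G, N) counts; X (N, P) design; offset (N,) natural-log offsets;
    alpha (G,) dispersions.  Returns natural-log coefficients (G, P),
    converged flags, iteration counts and fitted means (G, N).
    """
    Y = np.asarray(Y, float)
    G, N = Y.shape
    P = X.shape[1]
    alpha = np.broadcast_to(np.asarray(alpha, float), (G,)).copy()
    a = alpha[:, None]

    z0 = np.log(np.maximum(Y, 0.5)) - offset[None, :]
    beta, *_ = np.linalg.lstsq(X, z0.T, rcond=None)
    beta = beta.T  # (G, P)

    def loglik(b):
        eta = np.clip(b @ X.T + offset[None, :], -_ETA_CLIP, _ETA_CLIP)
        return nb_loglik(Y, np.exp(eta), alpha)

    ll = loglik(beta)
    converged = np.zeros(G, bool)
    iterations = np.zeros(G, int)
    eye = ridge * np.eye(P)
    for it in range(1, max_iter + 1):
        eta = np.clip(beta @ X.T + offset[None, :], -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        denom = 1.0 + a * mu
        W = mu / denom
        score = (Y - mu) / denom
        XtWX = np.einsum("gn,np,nq->gpq", W, X, X) + eye
        rhs = score @ X  # (G, P)
        try:
            delta = np.linalg.solve(XtWX, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            delta = np.einsum("gpq,gq->gp", np.linalg.pinv(XtWX), rhs)
        step = np.ones(G)
        beta_new, ll_new = beta, ll
        for _half in range(8):
            beta_new = beta + step[:, None] * delta
            ll_new = loglik(beta_new)
            worse = ll_new < ll - 1e-9
            if not worse.any():
                break
            step[worse] *= 0.5
        moved = np.max(np.abs(step[:, None] * delta), axis=1)
        newly_done = (moved < tol) & ~converged
        iterations[~converged] = it
        converged |= newly_done
        beta, ll = beta_new, ll_new
        if converged.all():
            break
    eta = np.clip(beta @ X.T + offset[None, :], -_ETA_CLIP, _ETA_CLIP)
    return beta, converged, iterations, np.exp(eta)


# ---------------------------------------------------------------------------
# Dispersion estimation
# ---------------------------------------------------------------------------

def estimate_dispersion(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    factors: pd.Series,
    n_rounds: int = 2,
) -> pd.DataFrame:
    """Per-gene dispersion alpha (variance mu + alpha mu^2) by profile MLE.

    A Poisson fit provides initial means for a method-of-moments estimate;
    then *n_rounds* of (1-D likelihood maximisation of alpha given fitted
    means, coefficient refit at the new alpha).  The 1-D objective is the
    Cox-Reid adjusted profile likelihood (a -0.5 log det X'WX penalty),
    which removes the downward bias incurred by estimating the mean
    parameters from the same data.  Alphas are floored at 1e-8 and capped
    at 10.  All-zero genes get alpha NaN and are flagged; genes where the
    MLE and moments estimates disagree by >10x are flagged for inspection
    but keep the MLE.

    Returns a DataFrame indexed by gene with columns ``alpha``,
    ``alpha_mom``, ``flagged``, ``note``.
    """
    X = design.values.astype(float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ModelError("design matrix is rank deficient")
    if counts.shape[1] <= X.shape[1]:
        raise ModelError("need more samples than design columns")
    offset = np.log(factors.reindex(counts.columns).values.astype(float))
    Y_all = counts.values.astype(float)
    nonzero = Y_all.sum(axis=1) > 0
    Y = Y_all[nonzero]
    G = Y.shape[0]
    resid_df = Y.shape[1] - X.shape[1]

    # Poisson-limit fit for initial means
    beta, _, _, mu = _irls(Y, X, offset, np.full(G, MIN_ALPHA))
    num = ((Y - mu) ** 2 - mu).sum(axis=1)
    alpha_mom = np.clip(num / np.maximum((mu ** 2).sum(axis=1), 1e-300),
                        MIN_ALPHA, MAX_ALPHA)

    alpha = alpha_mom.copy()
    log_lo, log_hi = np.log(MIN_ALPHA), np.log(MAX_ALPHA)
    for _ in range(n_rounds):
        _, _, _, mu = _irls(Y, X, offset, alpha)
        for g in range(G):
            yg, mug = Y[g:g + 1], mu[g:g + 1]

            def nll(log_a):
                a = np.exp(log_a)
                w = mug[0] / (1.0 + a * mug[0])
                _, logdet = np.linalg.slogdet((X * w[:, None]).T @ X)
                return -float(nb_loglik(yg, mug, a)[0]) + 0.5 * logdet

            res = minimize_scalar(nll, bounds=(log_lo, log_hi),
                                  method="bounded",
                                  options={"xatol": 1e-4})
            alpha[g] = np.exp(res.x)
    alpha = np.clip(alpha, MIN_ALPHA, MAX_ALPHA)

    disagree = (alpha / alpha_mom > 10) | (alpha_mom / alpha > 10)
    # at the Poisson boundary both estimators pile on the floor; not a conflict
    disagree &= ~((alpha <= 10 * MIN_ALPHA) | (alpha_mom <= 10 * MIN_ALPHA))

    out = pd.DataFrame(index=counts.index, columns=["alpha", "alpha_mom"],
                       dtype=float)
    out.loc[counts.index[nonzero], "alpha"] = alpha
    out.loc[counts.index[nonzero], "alpha_mom"] = alpha_mom
    out["flagged"] = False
    out.loc[counts.index[nonzero], "flagged"] = disagree
    out.loc[counts.index[~nonzero], "flagged"] = True
    out["note"] = ""
    out.loc[counts.index[~nonzero], "note"] = "all_zero"
    out.loc[counts.index[nonzero][disagree], "note"] = "mle_mom_disagree"
    _ = resid_df
    return out


# ---------------------------------------------------------------------------
# Fitting and testing
# ---------------------------------------------------------------------------

@dataclass
class GLMFit:
    """Per-gene NB GLM fits: coefficients and SEs in log2 units."""
    coef: pd.DataFrame          # genes x design columns (log2)
    se: pd.DataFrame            # genes x design columns (log2)
    mu: pd.DataFrame            # fitted means, genes x samples (count scale)
    alpha: pd.Series            # per-gene dispersion used
    converged: pd.Series
    iterations: pd.Series
    design: pd.DataFrame
    size_factors: pd.Series


def fit_nbglm(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    factors: pd.Series,
    alpha: pd.Series | float,
    max_iter: int = 100,
) -> GLMFit:
    """Fit the NB GLM gene by gene (batched IRLS).

    *alpha* is a per-gene Series (NaN entries are excluded and flagged)
    or a scalar.  Size factors enter as natural-log offsets, so
    coefficients describe normalised abundance.  Genes with all-zero
    counts are excluded.
    """
    X = design.values.astype(float)
    offset = np.log(factors.reindex(counts.columns).values.astype(float))
    if np.isscalar(alpha):
        alpha = pd.Series(float(alpha), index=counts.index)
    else:
        alpha = alpha.reindex(counts.index)
    usable = (counts.sum(axis=1) > 0) & alpha.notna()
    Y = counts.values[usable.values].astype(float)
    a = np.maximum(alpha.values[usable.values].astype(float), MIN_ALPHA)

    beta, conv, iters, mu = _irls(Y, X, offset, a, max_iter=max_iter)

    # observed-information standard errors
    aa = a[:, None]
    w_obs = mu * (1.0 + aa * Y) / (1.0 + aa * mu) ** 2
    info = np.einsum("gn,np,nq->gpq", w_obs, X, X)
    info += 1e-12 * np.eye(X.shape[1])
    cov = np.linalg.inv(info)
    se = np.sqrt(np.maximum(np.einsum("gpp->gp", cov), 0.0))

    idx = counts.index[usable.values]
    cols = list(design.columns)
    nan_frame = pd.DataFrame(np.nan, index=counts.index, columns=cols)
    coef_df = nan_frame.copy()
    coef_df.loc[idx] = beta / LN2
    se_df = nan_frame.copy()
    se_df.loc[idx] = se / LN2
    mu_df = pd.DataFrame(np.nan, index=counts.index, columns=counts.columns)
    mu_df.loc[idx] = mu
    conv_s = pd.Series(False, index=counts.index)
    conv_s.loc[idx] = conv
    iter_s = pd.Series(0, index=counts.index)
    iter_s.loc[idx] = iters
    return GLMFit(coef=coef_df, se=se_df, mu=mu_df,
                  alpha=alpha, converged=conv_s, iterations=iter_s,
                  design=design.copy(), size_factors=factors.copy())


def wald_test(
    fit: GLMFit,
    coefficient: str,
    fdr: float = 0.05,
    lfc_threshold: float = 0.5,
) -> pd.DataFrame:
    """Two-sided Wald test of one coefficient with BH-FDR adjustment.

    Calls ``up`` when adjusted p < *fdr* and log2FC > *lfc_threshold*,
    ``down`` for log2FC < -*lfc_threshold*, else ``ns``.  Genes with an
    undefined statistic (zero or missing SE) are excluded from the BH
    family and marked ``undefined``.
    """
    if coefficient not in fit.coef.columns:
        raise ModelError(f"coefficient {coefficient!r} not in fit "
                         f"(have {list(fit.coef.columns)})")
    lfc = fit.coef[coefficient]
    se = fit.se[coefficient]
    ok = lfc.notna() & se.notna() & (se > 0)
    stat = pd.Series(np.nan, index=lfc.index)
    stat[ok] = lfc[ok] / se[ok]
    pval = pd.Series(np.nan, index=lfc.index)
    pval[ok] = 2.0 * _normal.sf(np.abs(stat[ok]))
    padj = pd.Series(np.nan, index=lfc.index)
    if ok.any():
        padj[ok] = multipletests(pval[ok], method="fdr_bh")[1]
    call = pd.Series("ns", index=lfc.index)
    call[~ok] = "undefined"
    call[ok & (padj < fdr) & (lfc > lfc_threshold)] = "up"
    call[ok & (padj < fdr) & (lfc < -lfc_threshold)] = "down"
    return pd.DataFrame({
        "log2FC": lfc, "SE": se, "stat": stat,
        "pvalue": pval, "padj": padj, "call": call,
    })


def pairwise_de(
    counts: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fdr: float = 0.05,
    lfc_threshold: float = 0.5,
    alpha: pd.Series | float | None = None,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Two-group differential expression (B vs A) via the NB GLM.

    Convenience wrapper: single two-level factor with A as reference, so
    positive log2FC means higher in *group_b*.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ModelError("both groups must be non-empty")
    sub = counts[group_a + group_b]
    samples = pd.DataFrame({
        "group": ["A"] * len(group_a) + ["B"] * len(group_b),
    }, index=sub.columns)
    spec = ModelSpec([Variable("group", "categorical", ["A", "B"], "A")])
    design = build_design(samples, spec)
    if factors is None:
        from .normalization import size_factors as _sf
        factors = _sf(sub)
    if alpha is None:
        alpha = estimate_dispersion(sub, design, factors)["alpha"]
    fit = fit_nbglm(sub, design, factors, alpha)
    return wald_test(fit, "group[B]", fdr=fdr, lfc_threshold=lfc_threshold)
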