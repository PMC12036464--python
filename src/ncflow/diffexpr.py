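"""Differential-expression engines and multiple-testing correction.

Two engines are provided:

* a moderated linear model on log2 expression: per-gene ordinary least
  squares followed by empirical-Bayes variance moderation, with the prior
  degrees of freedom and prior variance estimated by moment matching on
  the log residual variances (digamma/trigamma inversion);
* a joint negative-binomial GLM on raw counts: per-gene NB regression with
  a per-sample additive background offset and multiplicative size-factor
  offsets, profile-likelihood dispersion estimation with empirical-Bayes
  shrinkage toward the across-gene mean, and likelihood-ratio tests of the
  group coefficients.

Both feed a uniform results table with Benjamini-Hochberg q-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

from .errors import ConfigurationError, ValidationError
from .experiment import Experiment, ProbeClass, TESTED_CLASSES
from .normalize import NBSizeFactors

_LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Samples x p design with named columns and group metadata."""

    matrix: pd.DataFrame
    referent: str
    group_columns: list[str]
    covariate_columns: list[str] = field(default_factory=list)
    w_columns: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]


def _encode_covariate(values: pd.Series, name: str) -> pd.Series:
    if pd.api.types.is_numeric_dtype(values):
        return values.astype(float)
    levels = sorted(values.dropna().unique())
    if len(levels) == 2:
        return values.map({levels[0]: 0.0, levels[1]: 1.0}).astype(float)
    raise ValidationError(
        f"covariate {name!r} is non-numeric with {len(levels)} levels; "
        "only numeric or binary covariates are supported"
    )


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    full_rank = np.linalg.matrix_rank(X)
    culprits = []
    for j, name in enumerate(names):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full_rank:
            culprits.append(name)
    return culprits


def build_design(
    meta: pd.DataFrame,
    referent: str,
    covariates=None,
    W: pd.DataFrame | None = None,
) -> DesignMatrix:
    """Intercept + group indicators vs a referent + covariates + W columns.

    Raises a rank-deficiency error naming the collinear columns.
    """
    groups = meta["group"].astype(str)
    levels = sorted(groups.unique())
    if referent not in levels:
        raise ValidationError(f"referent group {referent!r} not present")
    if len(levels) < 2:
        raise ValidationError("need at least two groups for a design")

    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(meta))}
    group_cols = []
    for level in levels:
        if level == referent:
            continue
        name = f"group_{level}"
        cols[name] = (groups == level).to_numpy(float)
        group_cols.append(name)

    cov_cols = []
    for cov in covariates or []:
        if cov not in meta.columns:
            raise ValidationError(f"covariate {cov!r} not in metadata")
        cols[cov] = _encode_covariate(meta[cov], cov).to_numpy()
        cov_cols.append(cov)

    w_cols = []
    if W is not None and W.shape[1] > 0:
        W = W.loc[meta.index]
        for j, name in enumerate(W.columns):
            cols[str(name)] = W.iloc[:, j].to_numpy(float)
            w_cols.append(str(name))

    matrix = pd.DataFrame(cols, index=meta.index)
    X = matrix.to_numpy(float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        culprits = _collinear_columns(X, list(matrix.columns))
        raise ValidationError(
            f"design matrix is rank deficient; collinear columns: {culprits}"
        )
    return DesignMatrix(
        matrix=matrix,
        referent=referent,
        group_columns=group_cols,
        covariate_columns=cov_cols,
        w_columns=w_cols,
    )


# ---------------------------------------------------------------------------
# Moderated linear model
# ---------------------------------------------------------------------------

@dataclass
class LinearFit:
    """Per-gene OLS fit shared by the empirical-Bayes moderation step."""

    coef: pd.DataFrame  # genes x p, log2 scale
    s2: pd.Series  # residual variance per gene
    df_residual: int
    design: DesignMatrix
    unscaled_var: pd.Series  # diag((X'X)^-1) per column


def fit_linear(log2_expr: pd.DataFrame, design: DesignMatrix) -> LinearFit:
    """Ordinary least squares per gene.

    Parameters
    ----------
    log2_expr
        probes x samples matrix on the log2 scale.
    design
        Samples x p design; rows must match the expression columns.
    """
    X = design.matrix.to_numpy(float)
    if list(design.matrix.index) != list(log2_expr.columns):
        raise ValidationError("design rows do not match expression columns")
    n, p = X.shape
    if n <= p:
        raise ValidationError(f"need n > p, got n={n}, p={p}")

    Y = log2_expr.to_numpy(float).T  # n x genes
    Q, R = np.linalg.qr(X)
    coef = np.linalg.solve(R, Q.T @ Y)  # p x genes
    resid = Y - X @ coef
    rss = np.einsum("ij,ij->j", resid, resid)
    s2 = rss / (n - p)
    Rinv = np.linalg.solve(R, np.eye(p))
    xtx_inv_diag = np.einsum("ij,ij->i", Rinv, Rinv)
    return LinearFit(
        coef=pd.DataFrame(coef.T, index=log2_expr.index, columns=design.matrix.columns),
        s2=pd.Series(s2, index=log2_expr.index, name="s2"),
        df_residual=n - p,
        design=design,
        unscaled_var=pd.Series(xtx_inv_diag, index=design.matrix.columns),
    )


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma_inverse needs x > 0")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching fit of the scaled-F hierarchy on log variances.

    Models s2_g ~ s0^2 * chi^2_df / df with sigma^2_g ~ scaled-inv-chi^2(d0,
    s0^2); returns (d0, s0^2), with d0 = +inf when the observed spread of
    log s2 does not exceed the chi^2 sampling spread.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValidationError("need at least 2 genes with positive variance")
    e = np.log(s2[ok]) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - special.polygamma(1, df / 2.0)
    if excess > 0:
        d0 = 2.0 * trigamma_inverse(excess)
        s02 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(e_mean))
    return d0, s02


@dataclass
class ModeratedStats:
    """Empirical-Bayes moderated t statistics per gene and contrast."""

    coef: pd.DataFrame  # genes x contrasts (log2 fold change)
    t: pd.DataFrame
    p: pd.DataFrame
    s2_post: pd.Series
    d0: float
    s02: float
    df_total: float
    design: DesignMatrix
    method: str = "moderated"

    @property
    def contrasts(self) -> list[str]:
        return list(self.coef.columns)

    def log2fc(self, contrast: str) -> pd.Series:
        return self.coef[contrast]


def ebayes(
    fit: LinearFit,
    contrasts=None,
    prior_df: float | None = None,
) -> ModeratedStats:
    """Empirical-Bayes variance moderation and moderated t statistics.

    The prior (d0, s0^2) is estimated by moment matching on log s2 unless
    ``prior_df`` overrides d0 (0 reproduces the ordinary t; +inf the
    normal-theory limit with all variances shrunk to s0^2).
    """
    s2 = fit.s2.to_numpy(float)
    df = float(fit.df_residual)
    if prior_df is None:
        d0, s02 = _fit_f_dist(s2, df)
    else:
        d0 = float(prior_df)
        _, s02 = _fit_f_dist(s2, df) if d0 > 0 else (None, float(np.mean(s2)))

    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
    df_total = d0 + df

    contrasts = list(contrasts) if contrasts is not None else fit.design.group_columns
    t_cols, p_cols, c_cols = {}, {}, {}
    for name in contrasts:
        if name not in fit.coef.columns:
            raise ValidationError(f"unknown contrast column {name!r}")
        v = float(fit.unscaled_var[name])
        beta = fit.coef[name].to_numpy(float)
        se = np.sqrt(s2_post * v)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.inf))
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(tstat))
        else:
            p = 2.0 * stats.t.sf(np.abs(tstat), df_total)
        t_cols[name], p_cols[name], c_cols[name] = tstat, p, beta
    genes = fit.coef.index
    return ModeratedStats(
        coef=pd.DataFrame(c_cols, index=genes),
        t=pd.DataFrame(t_cols, index=genes),
        p=pd.DataFrame(p_cols, index=genes),
        s2_post=pd.Series(s2_post, index=genes, name="s2_post"),
        d0=d0,
        s02=s02,
        df_total=df_total,
        design=fit.design,
    )


# ---------------------------------------------------------------------------
# Joint negative-binomial GLM
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    mu = np.maximum(mu, 1e-10)
    if phi < 1e-8:
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1.0)))
    r = 1.0 / phi
    return float(
        np.sum(
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1.0)
            + y * np.log(phi * mu / (1.0 + phi * mu))
            - r * np.log1p(phi * mu)
        )
    )


def _nb_irls(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi: float,
    beta0: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, bool]:
    """Fisher scoring for an NB GLM with log link and offset."""
    n, p = X.shape
    if beta0 is None:
        beta = np.zeros(p)
        beta[0] = np.log(max(np.mean(y / np.exp(offset)), 1e-4))
    else:
        beta = beta0.copy()
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = np.clip(X @ beta + offset, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + phi * mu)
        z = (eta - offset) + (y - mu) / mu
        XtW = X.T * w
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            return beta, False
        ll = _nb_loglik(y, np.exp(np.clip(X @ beta_new + offset, -30, 30)), phi)
        step = 1.0
        while ll < ll_old - 1e-8 and step > 1e-4:  # damped step on divergence
            step /= 2.0
            beta_try = beta + step * (beta_new - beta)
            ll = _nb_loglik(y, np.exp(np.clip(X @ beta_try + offset, -30, 30)), phi)
            beta_new = beta_try
        converged = abs(ll - ll_old) < tol * (abs(ll_old) + 1.0)
        beta, ll_old = beta_new, ll
        if converged:
            return beta, True
    return beta, False


def _profile_dispersion(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    beta0: np.ndarray,
    bounds: tuple[float, float] = (1e-6, 10.0),
) -> float:
    """Profile-ML dispersion: maximize the NB likelihood over log phi."""
    state = {"beta": beta0}

    def neg_ll(log_phi: float) -> float:
        phi = float(np.exp(log_phi))
        beta, _ = _nb_irls(y, X, offset, phi, beta0=state["beta"])
        state["beta"] = beta
        mu = np.exp(np.clip(X @ beta + offset, -30, 30))
        return -_nb_loglik(y, mu, phi)

    res = optimize.minimize_scalar(
        neg_ll,
        bounds=(np.log(bounds[0]), np.log(bounds[1])),
        method="bounded",
        options={"xatol": 1e-3},
    )
    return float(np.exp(res.x))


@dataclass
class NBFit:
    """Joint NB GLM fit: coefficients, dispersions, LRT statistics."""

    coef: pd.DataFrame  # genes x p, natural-log scale
    log2fc_table: pd.DataFrame  # genes x contrasts, log2 scale
    dispersion_raw: pd.Series
    dispersion: pd.Series  # shrunk
    lrt: pd.DataFrame  # genes x contrasts
    p: pd.DataFrame
    converged: pd.Series
    size_factors: NBSizeFactors
    design: DesignMatrix
    method: str = "nbglm"

    @property
    def coef_log2(self) -> pd.DataFrame:
        return self.coef / _LN2

    @property
    def contrasts(self) -> list[str]:
        return list(self.lrt.columns)

    def log2fc(self, contrast: str) -> pd.Series:
        return self.log2fc_table[contrast]


def nb_glm_de(
    exp: Experiment,
    design: DesignMatrix,
    sf: NBSizeFactors,
    prior_weight: float = 10.0,
    genes=None,
) -> NBFit:
    """Negative-binomial GLM differential expression with EB shrinkage.

    Models ``E[Y_ig] = lambda_i + c_i d_i mu_ig`` with ``log mu = x' beta``:
    the per-sample background is subtracted from the counts (floored at 0)
    and ``log(c_i d_i)`` enters as an offset.  Per-gene dispersions are
    estimated by profile likelihood, shrunk on the log scale toward their
    across-gene mean with weight ``prior_weight / (prior_weight + n)``, and
    each group coefficient is tested by a 1-df likelihood-ratio test at the
    shrunk dispersion.

    Genes whose fit fails to converge are reported with NA statistics and
    excluded from the BH denominator downstream.
    """
    X = design.matrix.to_numpy(float)
    if list(design.matrix.index) != list(exp.samples.index):
        raise ValidationError("design rows do not match experiment samples")
    if genes is None:
        genes = list(exp.names_of(*TESTED_CLASSES))
    genes = list(genes)

    lam = sf.lam.to_numpy(float)
    offset = np.log(sf.c.to_numpy(float) * sf.d.to_numpy(float))
    counts = exp.counts.loc[genes].to_numpy(float)
    Yadj = np.maximum(counts - lam[None, :], 0.0)

    contrasts = design.group_columns
    col_idx = {c: design.matrix.columns.get_loc(c) for c in contrasts}

    betas = np.full((len(genes), X.shape[1]), np.nan)
    phi_raw = np.full(len(genes), np.nan)
    converged = np.zeros(len(genes), dtype=bool)

    for g in range(len(genes)):
        y = Yadj[g]
        if np.all(y < 1e-12):
            continue
        beta, ok = _nb_irls(y, X, offset, phi=0.1)
        if not ok:
            beta, ok = _nb_irls(y, X, offset, phi=0.1, max_iter=500)
        if not ok:
            continue
        phi_raw[g] = _profile_dispersion(y, X, offset, beta)
        beta, ok = _nb_irls(y, X, offset, phi_raw[g], beta0=beta)
        betas[g] = beta
        converged[g] = ok

    # empirical-Bayes shrinkage of log dispersions toward the global mean
    ok_mask = converged & np.isfinite(phi_raw)
    if ok_mask.sum() == 0:
        raise ValidationError("no gene converged in the NB fit")
    log_phi_bar = float(np.mean(np.log(phi_raw[ok_mask])))
    w = prior_weight / (prior_weight + float(exp.n_samples))
    phi_shrunk = np.where(
        ok_mask, np.exp(w * log_phi_bar + (1 - w) * np.log(phi_raw)), np.nan
    )

    lrt = np.full((len(genes), len(contrasts)), np.nan)
    pvals = np.full_like(lrt, np.nan)
    for g in range(len(genes)):
        if not ok_mask[g]:
            continue
        y = Yadj[g]
        phi = float(phi_shrunk[g])
        beta_full, ok = _nb_irls(y, X, offset, phi, beta0=betas[g])
        if not ok:
            converged[g] = False
            continue
        betas[g] = beta_full
        mu_full = np.exp(np.clip(X @ beta_full + offset, -30, 30))
        ll_full = _nb_loglik(y, mu_full, phi)
        for j, cname in enumerate(contrasts):
            keep = [k for k in range(X.shape[1]) if k != col_idx[cname]]
            Xr = X[:, keep]
            beta_r, ok_r = _nb_irls(y, Xr, offset, phi, beta0=beta_full[keep])
            if not ok_r:
                continue
            mu_r = np.exp(np.clip(Xr @ beta_r + offset, -30, 30))
            stat = max(2.0 * (ll_full - _nb_loglik(y, mu_r, phi)), 0.0)
            lrt[g, j] = stat
            pvals[g, j] = stats.chi2.sf(stat, df=1)

    gene_index = pd.Index(genes, name="gene")
    coef = pd.DataFrame(betas, index=gene_index, columns=design.matrix.columns)
    log2fc = pd.DataFrame(
        {c: betas[:, col_idx[c]] / _LN2 for c in contrasts}, index=gene_index
    )
    return NBFit(
        coef=coef,
        log2fc_table=log2fc,
        dispersion_raw=pd.Series(phi_raw, index=gene_index, name="phi_raw"),
        dispersion=pd.Series(phi_shrunk, index=gene_index, name="phi"),
        lrt=pd.DataFrame(lrt, index=gene_index, columns=contrasts),
        p=pd.DataFrame(pvals, index=gene_index, columns=contrasts),
        converged=pd.Series(converged, index=gene_index, name="converged"),
        size_factors=sf,
        design=design,
    )


# ---------------------------------------------------------------------------
# Multiple testing and result tables
# ---------------------------------------------------------------------------

def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class DEResult:
    """Uniform differential-expression results table for one contrast."""

    table: pd.DataFrame  # gene-indexed: log2fc, stat, p, q, significant, direction
    method: str
    contrast: str
    referent: str
    threshold: float
    n_failed: int = 0

    @property
    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def de_table(stats_obj, contrast: str, threshold: float = 0.05) -> DEResult:
    """Assemble the per-gene results table for one contrast.

    Works for both engines; genes with failed fits (NA p) are excluded from
    the BH denominator and reported via ``n_failed``.  Rows sort by q then
    by |log2FC| descending; ``direction`` is over/under relative to the
    referent group.
    """
    if contrast not in stats_obj.contrasts:
        raise ValidationError(
            f"unknown contrast {contrast!r}; available: {stats_obj.contrasts}"
        )
    lfc = stats_obj.log2fc(contrast)
    pvals = stats_obj.p[contrast]
    stat = (
        stats_obj.t[contrast] if hasattr(stats_obj, "t") else stats_obj.lrt[contrast]
    )
    valid = pvals.notna()
    n_failed = int((~valid).sum())

    table = pd.DataFrame(
        {"log2fc": lfc[valid], "stat": stat[valid], "p": pvals[valid]}
    )
    table["q"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["q"] < threshold
    table["direction"] = np.where(table["log2fc"] >= 0, "over", "under")
    table = table.sort_values(
        ["q", "log2fc"], key=lambda s: s.abs() if s.name == "log2fc" else s,
        ascending=[True, False],
    )
    return DEResult(
        table=table,
        method=getattr(stats_obj, "method", "unknown"),
        contrast=contrast,
        referent=stats_obj.design.referent,
        threshold=threshold,
        n_failed=n_failed,
    )


# ---------------------------------------------------------------------------
# Estimator facades
# ---------------------------------------------------------------------------

class ModeratedLinearDE(BaseEstimator):
    """Moderated linear-model differential expression as an estimator.

    Parameters
    ----------
    referent : str
        Referent group level for the contrasts.
    covariates : sequence of str, optional
        Metadata columns to adjust for (numeric or binary).
    threshold : float
        BH q-value significance threshold.

    After :meth:`fit`: ``stats_`` (the :class:`ModeratedStats`),
    ``results_`` (contrast -> :class:`DEResult`), ``design_``.
    """

    def __init__(self, referent: str = "TA", covariates=None, threshold: float = 0.05):
        self.referent = referent
        self.covariates = covariates
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y, W: pd.DataFrame | None = None):
        """Fit on a samples x genes log2 matrix and group labels ``y``."""
        X = pd.DataFrame(X)
        meta = pd.DataFrame({"group": np.asarray(y, dtype=object)}, index=X.index)
        if self.covariates:
            raise ConfigurationError(
                "pass covariates through fit_meta() when labels come as a vector"
            )
        self.design_ = build_design(meta, self.referent, W=W)
        fit = fit_linear(X.T, self.design_)
        self.stats_ = ebayes(fit)
        self.results_ = {
            c: de_table(self.stats_, c, self.threshold)
            for c in self.stats_.contrasts
        }
        return self

    def fit_meta(self, X: pd.DataFrame, meta: pd.DataFrame, W=None):
        """Fit with a full metadata table (enables covariate adjustment)."""
        X = pd.DataFrame(X)
        self.design_ = build_design(
            meta.loc[X.index], self.referent, covariates=self.covariates, W=W
        )
        fit = fit_linear(X.T, self.design_)
        self.stats_ = ebayes(fit)
        self.results_ = {
            c: de_table(self.stats_, c, self.threshold)
            for c in self.stats_.contrasts
        }
        return self


class NegativeBinomialDE(BaseEstimator):
    """Joint negative-binomial differential expression as an estimator.

    Normalization (size factors from the spike-in and housekeeping
    controls) and DE are performed together on the raw counts of an
    :class:`Experiment`.
    """

    def __init__(
        self,
        referent: str = "TA",
        covariates=None,
        prior_weight: float = 10.0,
        threshold: float = 0.05,
    ):
        self.referent = referent
        self.covariates = covariates
        self.prior_weight = prior_weight
        self.threshold = threshold

    def fit(self, exp: Experiment, y=None):
        from .normalize import nb_size_factors

        self.size_factors_ = nb_size_factors(exp)
        self.design_ = build_design(
            exp.samples, self.referent, covariates=self.covariates
        )
        self.stats_ = nb_glm_de(
            exp, self.design_, self.size_factors_, prior_weight=self.prior_weight
        )
        self.results_ = {
            c: de_table(self.stats_, c, self.threshold)
            for c in self.stats_.contrasts
        }
        return self
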