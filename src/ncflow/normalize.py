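"""The three normalization strategies for nCounter count data.

* nSolver-style scaling: positive-spike geometric-mean factors, negative
  control background subtraction, housekeeping geometric-mean factors.
* RUVg-style control-gene factor analysis: latent unwanted-variation
  factors W estimated by SVD of the centered housekeeping block of the
  log2 counts; W can either be subtracted from the matrix or carried as
  design covariates into differential expression (the mode used by the
  DE path).
* Negative-binomial size factors (positive factor, background mean,
  housekeeping factor) feeding the joint NB differential-expression model.

All three are deterministic; there is no RNG anywhere in this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigurationError, NormalizationError, ValidationError
from .experiment import BIOLOGICAL_CLASSES, Experiment, ProbeClass

#: floor applied to counts before any geometric mean or log (prevents -inf)
ZERO_FLOOR = 0.5


def geometric_mean(values) -> float:
    """exp(mean(log(values))) for strictly positive values."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of an empty collection")
    if np.any(arr <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(arr))))


def _floored(values: np.ndarray, floor: float = ZERO_FLOOR) -> np.ndarray:
    return np.maximum(np.asarray(values, dtype=float), floor)


@dataclass
class NormalizedExpression:
    """Log2-scale normalized expression plus method-specific artifacts."""

    log2_expr: pd.DataFrame  # probes x samples
    method: str
    scaling: pd.DataFrame | None = None  # per-sample factors
    W: pd.DataFrame | None = None  # samples x k unwanted-variation factors
    alpha: pd.DataFrame | None = None  # k x probes loadings


@dataclass
class NBSizeFactors:
    """Per-sample factors of the joint negative-binomial model.

    ``c`` (positive-spike size factor) and ``d`` (housekeeping size factor)
    are rescaled to geometric mean 1 across samples; ``lam`` is the
    per-sample background mean from the negative controls and coincides
    with the QC background threshold.
    """

    c: pd.Series
    d: pd.Series
    lam: pd.Series

    def __post_init__(self) -> None:
        if np.any(self.c <= 0) or np.any(self.d <= 0) or np.any(self.lam < 0):
            raise ValidationError("size factors must be positive, background >= 0")


# ---------------------------------------------------------------------------
# nSolver-style scaling
# ---------------------------------------------------------------------------

class NSolverNormalizer(BaseEstimator, TransformerMixin):
    """Positive-control / background / housekeeping scaling normalization.

    Per sample i: the positive factor ``f_i = mean_j(p_j) / p_i`` (p the
    geometric mean of the positive spikes) rescales all counts; the scaled
    negative-control mean is subtracted as background (floored at 0.5);
    the housekeeping factor ``g_i = mean_j(h_j) / h_i`` (h the geometric
    mean of the background-subtracted housekeeping counts) rescales again.
    The output is ``log2(x + pseudocount)`` over the biological probes.

    Attributes (after :meth:`fit`)
    ------------------------------
    scaling_ : pd.DataFrame
        Per-sample ``pos_factor``, ``background`` and ``hk_factor``.
    """

    def __init__(self, zero_floor: float = ZERO_FLOOR, pseudocount: float = 1.0):
        self.zero_floor = zero_floor
        self.pseudocount = pseudocount

    def fit(self, exp: Experiment, y=None):
        for cls in (
            ProbeClass.POSITIVE_SPIKE,
            ProbeClass.NEGATIVE_SPIKE,
            ProbeClass.HOUSEKEEPING,
        ):
            if len(exp.names_of(cls)) == 0:
                raise ConfigurationError(
                    f"nSolver normalization needs {cls.name} probes"
                )
        pos = exp.counts_of(ProbeClass.POSITIVE_SPIKE).to_numpy(float)
        p = np.exp(np.mean(np.log(_floored(pos, self.zero_floor)), axis=0))
        all_floored_pos = np.all(pos <= 0, axis=0)
        pos_factor = p.mean() / p

        neg_scaled = (
            exp.counts_of(ProbeClass.NEGATIVE_SPIKE).to_numpy(float) * pos_factor
        )
        background = neg_scaled.mean(axis=0)

        hk_scaled = (
            exp.counts_of(ProbeClass.HOUSEKEEPING).to_numpy(float) * pos_factor
        )
        hk_sub = hk_scaled - background
        all_floored_hk = np.all(hk_sub <= self.zero_floor, axis=0)
        h = np.exp(np.mean(np.log(_floored(hk_sub, self.zero_floor)), axis=0))
        hk_factor = h.mean() / h

        bad = all_floored_pos | all_floored_hk
        if np.any(bad):
            names = list(exp.samples.index[bad])
            raise NormalizationError(
                f"samples not normalizable (all control probes at the zero "
                f"floor): {names}"
            )
        self.scaling_ = pd.DataFrame(
            {
                "pos_factor": pos_factor,
                "background": background,
                "hk_factor": hk_factor,
            },
            index=exp.samples.index,
        )
        return self

    def transform(self, exp: Experiment) -> pd.DataFrame:
        """Normalized log2 expression, samples x biological probes."""
        scal = self.scaling_
        bio = exp.biological_counts
        scaled = bio.to_numpy(float) * scal["pos_factor"].to_numpy()
        sub = _floored(
            scaled - scal["background"].to_numpy(), self.zero_floor
        )
        final = sub * scal["hk_factor"].to_numpy()
        log2 = np.log2(final + self.pseudocount)
        return pd.DataFrame(log2.T, index=exp.samples.index, columns=bio.index)


def nsolver_normalize(exp: Experiment) -> NormalizedExpression:
    """nSolver-style scaling normalization of an experiment."""
    est = NSolverNormalizer().fit(exp)
    expr = est.transform(exp)
    return NormalizedExpression(
        log2_expr=expr.T, method="NSOLVER", scaling=est.scaling_
    )


# ---------------------------------------------------------------------------
# RUVg-style control-gene factor analysis
# ---------------------------------------------------------------------------

def _log_matrix(data, pseudocount: float) -> pd.DataFrame:
    """samples x probes log2 matrix from an Experiment or a ready matrix."""
    if isinstance(data, Experiment):
        bio = data.biological_counts
        return pd.DataFrame(
            np.log2(bio.to_numpy(float).T + pseudocount),
            index=data.samples.index,
            columns=bio.index,
        )
    return pd.DataFrame(data)


class RUVgNormalizer(BaseEstimator, TransformerMixin):
    """Removal of unwanted variation estimated from control genes.

    On the samples x probes log2 matrix Y, the control-gene columns are
    centered across samples and decomposed by SVD; ``W_`` holds the first
    ``k`` left-singular columns scaled by their singular values, and
    ``alpha_`` the least-squares loadings of all probes on W.  Each W
    column's entry of largest magnitude is made positive so the
    decomposition is deterministic.

    Parameters
    ----------
    k : int
        Number of unwanted-variation factors (default 1; ``k=0`` is the
        identity transform).
    control_genes : sequence of str, optional
        Control probe names; defaults to the housekeeping probes when
        fitting an :class:`Experiment`.
    """

    def __init__(self, k: int = 1, control_genes=None, pseudocount: float = 1.0):
        self.k = k
        self.control_genes = control_genes
        self.pseudocount = pseudocount

    def fit(self, data, y=None):
        if self.k < 0:
            raise ConfigurationError("k must be >= 0")
        Y = _log_matrix(data, self.pseudocount)
        controls = self.control_genes
        if controls is None:
            if not isinstance(data, Experiment):
                raise ConfigurationError(
                    "control_genes is required when fitting a plain matrix"
                )
            controls = list(data.names_of(ProbeClass.HOUSEKEEPING))
        controls = list(controls)
        missing = [c for c in controls if c not in Y.columns]
        if missing:
            raise ValidationError(f"control probes not in data: {missing}")
        if self.k > 0:
            if len(controls) < self.k:
                raise ConfigurationError(
                    f"need at least k={self.k} control probes, got {len(controls)}"
                )
            if Y.shape[0] < self.k + 1:
                raise ConfigurationError(
                    f"need at least k+1={self.k + 1} samples, got {Y.shape[0]}"
                )

        self.control_names_ = controls
        self.feature_names_ = list(Y.columns)
        if self.k == 0:
            self.W_ = pd.DataFrame(index=Y.index)
            self.alpha_ = pd.DataFrame(columns=Y.columns)
            return self

        Yc = Y[controls].to_numpy(float)
        Yc = Yc - Yc.mean(axis=0)
        U, s, _ = np.linalg.svd(Yc, full_matrices=False)
        tol = max(Yc.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
        rank = int(np.sum(s > tol))
        if rank < self.k:
            raise ValidationError(
                f"control block has rank {rank}, cannot extract k={self.k} factors"
            )
        W = U[:, : self.k] * s[: self.k]
        # deterministic sign: dominant entry of each column positive
        for j in range(W.shape[1]):
            idx = np.argmax(np.abs(W[:, j]))
            if W[idx, j] < 0:
                W[:, j] = -W[:, j]
        alpha, *_ = np.linalg.lstsq(W, Y.to_numpy(float), rcond=None)
        self.W_ = pd.DataFrame(
            W, index=Y.index, columns=[f"W{j + 1}" for j in range(self.k)]
        )
        self.alpha_ = pd.DataFrame(
            alpha, index=self.W_.columns, columns=Y.columns
        )
        return self

    def transform(self, data) -> pd.DataFrame:
        """Y - W alpha, samples x probes (identity when ``k=0``)."""
        Y = _log_matrix(data, self.pseudocount)
        if self.k == 0:
            return Y
        return Y - self.W_.to_numpy() @ self.alpha_.to_numpy()


def ruvg_fit(data, control_probes=None, k: int = 1):
    """Estimate unwanted-variation factors W and loadings alpha.

    ``data`` may be an :class:`Experiment` (log2(count+1) is formed over the
    biological probes) or a samples x probes log-scale matrix.
    """
    est = RUVgNormalizer(k=k, control_genes=control_probes).fit(data)
    return est.W_, est.alpha_


def ruvg_normalize(exp, control_probes=None, k: int = 1) -> NormalizedExpression:
    """RUVg normalization: the factor-subtracted log2 matrix plus W.

    W is retained in the result so differential expression can include it
    as design covariates instead of using the subtracted matrix.
    """
    est = RUVgNormalizer(k=k, control_genes=control_probes).fit(exp)
    adjusted = est.transform(exp)
    return NormalizedExpression(
        log2_expr=adjusted.T,
        method="RUVG",
        W=est.W_.copy(),
        alpha=est.alpha_.copy(),
    )


# ---------------------------------------------------------------------------
# Negative-binomial size factors
# ---------------------------------------------------------------------------

def nb_size_factors(exp: Experiment, zero_floor: float = ZERO_FLOOR) -> NBSizeFactors:
    """Positive, background and housekeeping factors of the joint NB model.

    ``c`` is the geometric mean of the positive spikes, ``lam`` the mean of
    the negative controls, and ``d`` the geometric mean of the
    background-subtracted housekeeping counts (floored at 0.5); ``c`` and
    ``d`` are rescaled to geometric mean 1 across samples.
    """
    for cls in (
        ProbeClass.POSITIVE_SPIKE,
        ProbeClass.NEGATIVE_SPIKE,
        ProbeClass.HOUSEKEEPING,
    ):
        if len(exp.names_of(cls)) == 0:
            raise ConfigurationError(f"NB size factors need {cls.name} probes")

    pos = exp.counts_of(ProbeClass.POSITIVE_SPIKE).to_numpy(float)
    if np.any(np.all(pos <= 0, axis=0)):
        bad = list(exp.samples.index[np.all(pos <= 0, axis=0)])
        raise NormalizationError(f"samples with all-zero positive spikes: {bad}")
    c = np.exp(np.mean(np.log(_floored(pos, zero_floor)), axis=0))
    c = c / np.exp(np.mean(np.log(c)))

    lam = exp.counts_of(ProbeClass.NEGATIVE_SPIKE).to_numpy(float).mean(axis=0)

    hk = exp.counts_of(ProbeClass.HOUSEKEEPING).to_numpy(float)
    hk_sub = _floored(hk - lam, zero_floor)
    if np.any(np.all(hk - lam <= zero_floor, axis=0)):
        bad = list(exp.samples.index[np.all(hk - lam <= zero_floor, axis=0)])
        raise NormalizationError(
            f"samples with all housekeeping probes at the background floor: {bad}"
        )
    d = np.exp(np.mean(np.log(hk_sub), axis=0))
    d = d / np.exp(np.mean(np.log(d)))

    index = exp.samples.index
    return NBSizeFactors(
        c=pd.Series(c, index=index, name="c"),
        d=pd.Series(d, index=index, name="d"),
        lam=pd.Series(lam, index=index, name="lambda"),
    )
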