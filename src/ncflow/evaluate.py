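"""Cross-method comparison and permutation-based Type I error estimation.

The Type I simulation permutes the lesion-group labels, re-runs the
requested normalization + differential-expression pipeline from scratch on
the permuted labels, and records the fraction of endogenous genes with
unadjusted p < alpha; the mean of those fractions over replicates is the
empirical Type I error of the pipeline.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import (
    DEResult,
    build_design,
    de_table,
    ebayes,
    fit_linear,
    nb_glm_de,
)
from .errors import ConfigurationError, ValidationError
from .experiment import Experiment, ProbeClass, TESTED_CLASSES
from .normalize import RUVgNormalizer, nb_size_factors, nsolver_normalize

PIPELINES = ("ruvg+moderated", "nsolver+moderated", "nbjoint")


# ---------------------------------------------------------------------------
# Pipelines (normalization + DE) used by comparison and simulation
# ---------------------------------------------------------------------------

def run_de_pipeline(
    exp: Experiment,
    method: str,
    referent: str = "TA",
    k: int = 1,
    covariates=None,
    threshold: float = 0.05,
):
    """Run one normalization + DE pipeline end to end.

    Returns ``(stats, results)`` where ``stats`` is the engine's statistics
    object and ``results`` maps each contrast to a :class:`DEResult` over
    the endogenous + biological-positive genes.
    """
    if method not in PIPELINES:
        raise ConfigurationError(f"unknown pipeline {method!r}; use one of {PIPELINES}")
    tested = list(exp.names_of(*TESTED_CLASSES))

    if method == "ruvg+moderated":
        from .normalize import _log_matrix

        ruv = RUVgNormalizer(k=k).fit(exp)
        Y = _log_matrix(exp, ruv.pseudocount)
        design = build_design(
            exp.samples, referent, covariates=covariates, W=ruv.W_
        )
        fit = fit_linear(Y.T.loc[tested], design)
        stats = ebayes(fit)
    elif method == "nsolver+moderated":
        norm = nsolver_normalize(exp)
        design = build_design(exp.samples, referent, covariates=covariates)
        fit = fit_linear(norm.log2_expr.loc[tested], design)
        stats = ebayes(fit)
    else:  # nbjoint
        sf = nb_size_factors(exp)
        design = build_design(exp.samples, referent, covariates=covariates)
        stats = nb_glm_de(exp, design, sf, genes=tested)

    results = {c: de_table(stats, c, threshold) for c in stats.contrasts}
    return stats, results


# ---------------------------------------------------------------------------
# Fold-change correlation and DEG overlap
# ---------------------------------------------------------------------------

def logfc_correlation(a: DEResult, b: DEResult) -> float:
    """Pearson correlation of log2 fold changes over the shared genes."""
    shared = a.table.index.intersection(b.table.index)
    x = a.table.loc[shared, "log2fc"]
    y = b.table.loc[shared, "log2fc"]
    ok = x.notna() & y.notna()
    if ok.sum() < 3:
        raise ValidationError("need at least 3 shared genes for a correlation")
    return float(np.corrcoef(x[ok], y[ok])[0, 1])


@dataclass
class ComparisonResult:
    """Pairwise fold-change correlations and DEG overlap counts."""

    methods: list[str]
    correlations: pd.DataFrame  # methods x methods Pearson r
    overlap: dict[frozenset, int]  # exclusive region counts per subset
    deg_counts: dict[str, int]
    threshold: float

    def to_dict(self) -> dict:
        return {
            "methods": self.methods,
            "correlations": self.correlations.to_dict(),
            "overlap": {
                "+".join(sorted(key)): value for key, value in self.overlap.items()
            },
            "deg_counts": self.deg_counts,
            "threshold": self.threshold,
        }


def deg_overlap(
    results: list[DEResult], threshold: float = 0.05, labels=None
) -> ComparisonResult:
    """Exclusive membership counts for every non-empty subset of methods.

    Counts are Venn-region counts on the common gene universe: a gene is
    tallied for the subset of methods (and only those) that call it
    significant at ``q < threshold``.
    """
    labels = list(labels) if labels is not None else [r.method for r in results]
    if len(set(labels)) != len(labels):
        labels = [f"{lab}_{i}" for i, lab in enumerate(labels)]
    universe = results[0].table.index
    for r in results[1:]:
        universe = universe.intersection(r.table.index)

    sig = {
        lab: set(r.table.index[(r.table["q"] < threshold)]) & set(universe)
        for lab, r in zip(labels, results)
    }
    overlap: dict[frozenset, int] = {}
    for r in range(1, len(labels) + 1):
        for subset in itertools.combinations(labels, r):
            inside = set(universe)
            for lab in subset:
                inside &= sig[lab]
            for lab in set(labels) - set(subset):
                inside -= sig[lab]
            overlap[frozenset(subset)] = len(inside)

    corr = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for (i, a), (j, b) in itertools.combinations(enumerate(results), 2):
        r_val = logfc_correlation(a, b)
        corr.iloc[i, j] = corr.iloc[j, i] = r_val
    return ComparisonResult(
        methods=labels,
        correlations=corr,
        overlap=overlap,
        deg_counts={lab: len(sig[lab]) for lab in labels},
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Permutation Type I error
# ---------------------------------------------------------------------------

@dataclass
class TypeIResult:
    """Empirical Type I error of one pipeline under label permutation."""

    method: str
    B: int
    alpha: float
    fractions: np.ndarray  # per-replicate fraction of genes with p < alpha
    seed: int
    child_seeds: np.ndarray
    n_failed: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.fractions))

    @property
    def mc_se(self) -> float:
        if len(self.fractions) < 2:
            return float("nan")
        return float(np.std(self.fractions, ddof=1) / np.sqrt(len(self.fractions)))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "B": self.B,
            "alpha": self.alpha,
            "mean": self.mean,
            "mc_se": self.mc_se,
            "fractions": [float(f) for f in self.fractions],
            "seed": self.seed,
            "n_failed": self.n_failed,
        }


def _permuted_experiment(
    exp: Experiment, rng: np.random.Generator, stratify: str | None
) -> Experiment:
    groups = exp.samples["group"].to_numpy().copy()
    if stratify is None:
        perm = rng.permutation(len(groups))
        groups = groups[perm]
    else:
        strata = exp.samples[stratify].to_numpy()
        for level in pd.unique(strata):
            idx = np.flatnonzero(strata == level)
            groups[idx] = groups[idx[rng.permutation(len(idx))]]
    permuted = Experiment(
        counts=exp.counts.copy(),
        probes=exp.probes.copy(),
        samples=exp.samples.copy(),
    )
    permuted.samples["group"] = groups
    return permuted


def type_i_simulation(
    exp: Experiment,
    method: str,
    B: int,
    alpha: float = 0.05,
    seed: int = 0,
    referent: str = "TA",
    k: int = 1,
    stratify: str | None = None,
) -> TypeIResult:
    """Estimate the empirical Type I error of a pipeline by permutation.

    For each of ``B`` replicates the group labels are permuted uniformly at
    random (optionally within a stratification column such as the
    cartridge), the full normalization + DE pipeline is re-run from
    scratch, and the fraction of endogenous genes with unadjusted p <
    ``alpha`` (pooled over the group contrasts) is recorded.  A master seed
    spawns one child seed per replicate so the run is reproducible
    end to end.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=B)
    endog = exp.names_of(ProbeClass.ENDOGENOUS)

    fractions = []
    n_failed = 0
    for b in range(B):
        rng = np.random.default_rng(int(child_seeds[b]))
        permuted = _permuted_experiment(exp, rng, stratify)
        try:
            stats, _ = run_de_pipeline(permuted, method, referent=referent, k=k)
        except Exception:
            n_failed += 1
            continue
        p = stats.p.loc[stats.p.index.intersection(endog)].to_numpy(float)
        p = p[np.isfinite(p)]
        fractions.append(float(np.mean(p < alpha)) if alpha > 0 else 0.0)
    return TypeIResult(
        method=method,
        B=B,
        alpha=alpha,
        fractions=np.asarray(fractions),
        seed=seed,
        child_seeds=child_seeds,
        n_failed=n_failed,
    )


# ---------------------------------------------------------------------------
# Volcano export
# ---------------------------------------------------------------------------

def volcano_table(res: DEResult) -> pd.DataFrame:
    """Plotting-ready volcano table: gene, log2FC, -log10 q, significance."""
    q = np.maximum(res.table["q"].to_numpy(float), np.finfo(float).tiny)
    return pd.DataFrame(
        {
            "gene": res.table.index,
            "log2fc": res.table["log2fc"].to_numpy(),
            "neg_log10_q": -np.log10(q),
            "significant": res.table["significant"].to_numpy(),
        }
    ).set_index("gene")
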