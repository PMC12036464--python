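"""Synthetic nCounter experiment generator.

Emulates the statistical structure the pipeline assumes: a codeset of 277
endogenous immune genes, 15 housekeeping genes, 11 tissue-specific
biological positive controls, 6 positive spikes at a known titration and 8
negative probes; 12-lane cartridges with bounded lane-efficiency and
cartridge batch effects; three lesion groups (SSL / TV / TA); planted
differential expression; FFPE-style degradation that attenuates biological
probes but leaves the synthetic spikes untouched; and global-shift outlier
lanes.

Counts are drawn as negative-binomial signal plus additive Poisson
background on every probe.  Negative probes carry probe-specific
background affinities with right-skewed (lognormal) spread, so the
negative-control mean — the background threshold — sits above the typical
nonspecific level of a biological probe, as it does on the real platform.
All randomness flows from one seeded generator; the emitted ``SimTruth``
records every latent quantity for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .codeset_io import BIO_POSITIVE_GENES, HOUSEKEEPING_GENES
from .errors import ConfigurationError, ValidationError
from .experiment import Experiment, ProbeClass


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic experiment.

    The defaults reproduce the panel and cohort this workflow was designed
    around: 277 endogenous genes, 15 housekeeping, 11 biological positive
    controls, spikes at 128..0.125 fM, 25 SSL / 27 TV / 48 TA samples laid
    out 10 study lanes per 12-lane cartridge.  Technical variation is
    bounded (uniform on the log2 scale): lane size factors within
    ``size_factor_log2_width`` and cartridge batch effects within
    ``batch_log2_width``, the latter acting through gene-specific loadings
    (``batch_gene_sd``) as reagent-lot effects do.
    """

    n_endogenous: int = 277
    n_housekeeping: int = 15
    n_bio_positive: int = 11
    pos_concentrations: tuple[float, ...] = (128.0, 32.0, 8.0, 2.0, 0.5, 0.125)
    n_neg_spike: int = 8
    group_sizes: tuple[tuple[str, int], ...] = (("SSL", 25), ("TV", 27), ("TA", 48))
    lanes_per_cartridge: int = 12
    study_lanes_per_cartridge: int = 10

    # per-gene baseline log2 means and dispersions
    endo_log2_range: tuple[float, float] = (4.0, 11.0)
    hk_log2_range: tuple[float, float] = (6.5, 10.0)
    bio_log2_means: tuple[float, ...] = (
        5.4, 5.6, 5.8, 5.9, 6.1, 7.8, 6.4, 6.2, 8.0, 8.3, 8.5,
    )
    dispersion_range: tuple[float, float] = (0.05, 0.15)

    # technical structure (log2 scale, uniform widths)
    size_factor_log2_width: float = 0.4
    batch_log2_width: float = 0.15
    batch_gene_sd: float = 0.8
    composition_log2_width: float = 0.5
    composition_gene_sd: float = 1.0

    # background model
    background_mean: float = 10.0  # negative-probe Poisson mean (counts)
    background_probe_sd: float = 0.25  # lognormal affinity spread of negatives
    bio_background_scale: float = 0.4  # biological nonspecific level vs lambda0

    # spike-in calibration: counts per fM at unit size factor
    spike_gain: float = 156.25

    # planted structure
    de_genes: tuple[tuple[str, str, float], ...] = ()  # (gene, group, log2fc)
    n_degraded: int = 0
    degradation_log2: float = -5.0
    degradation_jitter_sd: float = 0.0
    n_outliers: int = 0
    outlier_log2_shift: float = 5.0

    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in (self.n_endogenous, self.n_housekeeping,
                               self.n_bio_positive, self.n_neg_spike)):
            raise ConfigurationError("panel sizes must be non-negative")
        if list(self.pos_concentrations) != sorted(
            self.pos_concentrations, reverse=True
        ) or len(set(self.pos_concentrations)) != len(self.pos_concentrations):
            raise ConfigurationError("spike concentrations must strictly decrease")
        if self.n_degraded + self.n_outliers > self.n_samples:
            raise ConfigurationError("more planted samples than cohort size")

    @property
    def n_samples(self) -> int:
        return sum(n for _, n in self.group_sizes)

    @property
    def groups(self) -> list[str]:
        return [g for g, _ in self.group_sizes]


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    gene: pd.DataFrame  # baseline_log2, dispersion, batch_loading, per-group lfc
    sample: pd.DataFrame  # group, size_factor_log2, batch_log2, degraded, outlier
    config: SimConfig

    def log2fc(self, group: str, referent: str = "TA") -> pd.Series:
        """True log2 fold change of ``group`` vs ``referent`` per gene."""
        eff = self.gene[f"effect_{group}"] - self.gene[f"effect_{referent}"]
        return eff.rename(f"{group}_vs_{referent}")


def _probe_table(cfg: SimConfig) -> pd.DataFrame:
    names, classes, spike = [], [], []
    for i in range(cfg.n_endogenous):
        names.append(f"IMM{i + 1:03d}")
        classes.append(ProbeClass.ENDOGENOUS.value)
        spike.append(np.nan)
    for i in range(cfg.n_bio_positive):
        names.append(BIO_POSITIVE_GENES[i % len(BIO_POSITIVE_GENES)]
                     if i < len(BIO_POSITIVE_GENES) else f"BIO{i + 1:02d}")
        classes.append(ProbeClass.BIO_POSITIVE.value)
        spike.append(np.nan)
    for i in range(cfg.n_housekeeping):
        names.append(HOUSEKEEPING_GENES[i % len(HOUSEKEEPING_GENES)]
                     if i < len(HOUSEKEEPING_GENES) else f"HK{i + 1:02d}")
        classes.append(ProbeClass.HOUSEKEEPING.value)
        spike.append(np.nan)
    for i, conc in enumerate(cfg.pos_concentrations):
        names.append(f"POS_{chr(ord('A') + i)}({conc:g})")
        classes.append(ProbeClass.POSITIVE_SPIKE.value)
        spike.append(conc)
    for i in range(cfg.n_neg_spike):
        names.append(f"NEG_{chr(ord('A') + i)}")
        classes.append(ProbeClass.NEGATIVE_SPIKE.value)
        spike.append(np.nan)
    probes = pd.DataFrame(
        {"probe_class": classes, "accession": ["SYNTH"] * len(names),
         "spike_fm": spike},
        index=pd.Index(names, name="probe"),
    )
    if probes.index.has_duplicates:
        raise ConfigurationError("probe name collision in synthetic codeset")
    return probes


def _sample_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    ids, groups = [], []
    for gname, n in cfg.group_sizes:
        for _ in range(n):
            ids.append(f"S{len(ids) + 1:03d}")
            groups.append(gname)
    # interleave groups proportionally so cartridges are group-balanced,
    # mirroring the stratified randomization of the cohort design
    positions = np.concatenate(
        [(np.arange(ng) + 0.5) / ng for _, ng in cfg.group_sizes]
    )
    order = np.argsort(positions, kind="mergesort")
    ids = [ids[i] for i in order]
    groups = [groups[i] for i in order]

    per_cart = cfg.study_lanes_per_cartridge
    cartridges = [f"C{(i // per_cart) + 1:02d}" for i in range(len(ids))]
    lanes = [(i % per_cart) + 1 for i in range(len(ids))]

    size_mean = {"SSL": 8.4, "TV": 10.7, "TA": 8.5}
    size_sd = {"SSL": 4.1, "TV": 6.5, "TA": 3.7}
    sizes = [
        float(np.round(max(rng.normal(size_mean.get(g, 9.0), size_sd.get(g, 4.0)), 1.0), 1))
        for g in groups
    ]
    ages = np.round(rng.normal(58.0, 8.0, size=len(ids))).astype(float)
    sexes = np.where(rng.random(len(ids)) < 0.55, "M", "F")

    return pd.DataFrame(
        {
            "group": groups,
            "cartridge": cartridges,
            "lane_position": lanes,
            "size_mm": sizes,
            "age": ages,
            "sex": sexes,
            "fov_count": float(555),
            "fov_counted": 0.0,  # filled below
            "binding_density": 0.0,
        },
        index=pd.Index(ids, name="sample_id"),
    )


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray
) -> np.ndarray:
    """Negative binomial draws with mean/dispersion parametrization."""
    mean = np.maximum(mean, 1e-12)
    out = np.empty_like(mean)
    poisson_like = phi < 1e-8
    if np.any(poisson_like):
        out[poisson_like] = rng.poisson(mean[poisson_like])
    if np.any(~poisson_like):
        m = mean[~poisson_like]
        f = phi[~poisson_like]
        r = 1.0 / f
        p = r / (r + m)
        out[~poisson_like] = rng.negative_binomial(r, p)
    return out


def simulate_experiment(
    cfg: SimConfig | None = None, seed: int | None = None
) -> tuple[Experiment, SimTruth]:
    """Draw one synthetic experiment and its ground truth.

    Negatives are Poisson around probe-specific affinities; positive spikes
    are Poisson around gain x concentration x lane size factor; biological
    probes are negative binomial around
    ``2^(baseline + group effect + size + batch x loading + degradation +
    outlier shift)`` plus additive Poisson background.  Outlier lanes shift
    every probe (spikes included, as a lane-level artifact); degradation
    attenuates biological probes only.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    probes = _probe_table(cfg)
    samples = _sample_table(cfg, rng)
    n = len(samples)

    bio_mask = probes["probe_class"].isin(
        [ProbeClass.ENDOGENOUS.value, ProbeClass.BIO_POSITIVE.value,
         ProbeClass.HOUSEKEEPING.value]
    ).to_numpy()
    bio_names = probes.index[bio_mask]
    n_bio = bio_mask.sum()

    # per-gene baselines
    base = np.empty(n_bio)
    disp = rng.uniform(*cfg.dispersion_range, size=n_bio)
    loading = 1.0 + rng.normal(0.0, cfg.batch_gene_sd, size=n_bio)
    comp_loading = rng.normal(0.0, cfg.composition_gene_sd, size=n_bio)
    cls = probes.loc[bio_names, "probe_class"].to_numpy()
    endo_ix = cls == ProbeClass.ENDOGENOUS.value
    hk_ix = cls == ProbeClass.HOUSEKEEPING.value
    biopos_ix = cls == ProbeClass.BIO_POSITIVE.value
    base[endo_ix] = rng.uniform(*cfg.endo_log2_range, size=endo_ix.sum())
    base[hk_ix] = rng.uniform(*cfg.hk_log2_range, size=hk_ix.sum())
    bio_means = np.resize(np.asarray(cfg.bio_log2_means, float), biopos_ix.sum())
    base[biopos_ix] = bio_means

    # planted group effects
    effects = {g: np.zeros(n_bio) for g in cfg.groups}
    name_pos = {name: i for i, name in enumerate(bio_names)}
    for gene, group, lfc in cfg.de_genes:
        if gene not in probes.index:
            raise ValidationError(f"DE spec references unknown gene {gene!r}")
        if gene not in name_pos:
            raise ValidationError(
                f"DE spec references control probe {gene!r}; only biological "
                "probes may carry planted effects"
            )
        if group not in effects:
            raise ValidationError(f"DE spec references unknown group {group!r}")
        effects[group][name_pos[gene]] += lfc

    # per-sample latents (bounded technical variation)
    size_log2 = rng.uniform(
        -cfg.size_factor_log2_width, cfg.size_factor_log2_width, size=n
    )
    cartridges = samples["cartridge"].to_numpy()
    cart_levels = pd.unique(cartridges)
    batch_by_cart = dict(
        zip(
            cart_levels,
            rng.uniform(-cfg.batch_log2_width, cfg.batch_log2_width,
                        size=len(cart_levels)),
        )
    )
    batch_log2 = np.array([batch_by_cart[c] for c in cartridges])
    composition_log2 = rng.uniform(
        -cfg.composition_log2_width, cfg.composition_log2_width, size=n
    )

    planted = rng.choice(n, size=cfg.n_degraded + cfg.n_outliers, replace=False)
    degraded = np.zeros(n, dtype=bool)
    outlier = np.zeros(n, dtype=bool)
    degraded[planted[: cfg.n_degraded]] = True
    outlier[planted[cfg.n_degraded :]] = True
    deg_jitter = (
        rng.normal(0.0, cfg.degradation_jitter_sd, size=n_bio)
        if cfg.degradation_jitter_sd > 0
        else np.zeros(n_bio)
    )

    # background affinities
    neg_names = probes.index[
        probes["probe_class"] == ProbeClass.NEGATIVE_SPIKE.value
    ]
    neg_lambda = cfg.background_mean * np.exp(
        rng.normal(0.0, cfg.background_probe_sd, size=len(neg_names))
    )
    bio_lambda = cfg.bio_background_scale * cfg.background_mean

    group_arr = samples["group"].to_numpy()
    effect_mat = np.stack([effects[g] for g in group_arr], axis=1)  # genes x n

    log2_mu = (
        base[:, None]
        + effect_mat
        + size_log2[None, :]
        + batch_log2[None, :] * loading[:, None]
        + composition_log2[None, :] * comp_loading[:, None]
        + np.where(outlier[None, :], cfg.outlier_log2_shift, 0.0)
        + np.where(
            degraded[None, :],
            cfg.degradation_log2 * (1.0 + deg_jitter[:, None]),
            0.0,
        )
    )
    signal = _nb_draw(rng, 2.0 ** log2_mu, np.repeat(disp[:, None], n, axis=1))
    background = rng.poisson(bio_lambda, size=(n_bio, n))
    counts = pd.DataFrame(
        0, index=probes.index, columns=samples.index, dtype=np.int64
    )
    counts.loc[bio_names] = (signal + background).astype(np.int64)

    # spikes
    pos_rows = probes["spike_fm"].notna()
    conc = probes.loc[pos_rows, "spike_fm"].to_numpy(float)
    lane_scale = 2.0 ** (size_log2 + np.where(outlier, cfg.outlier_log2_shift, 0.0))
    pos_mean = cfg.spike_gain * conc[:, None] * lane_scale[None, :]
    counts.loc[pos_rows] = rng.poisson(pos_mean).astype(np.int64)
    counts.loc[neg_names] = rng.poisson(
        np.repeat(neg_lambda[:, None], n, axis=1)
    ).astype(np.int64)

    # technical lane attributes (clean by construction)
    samples = samples.copy()
    samples["fov_counted"] = np.round(555 * rng.uniform(0.97, 1.0, size=n))
    samples["binding_density"] = np.round(rng.uniform(0.4, 1.6, size=n), 3)

    gene_truth = pd.DataFrame(
        {
            "baseline_log2": base,
            "dispersion": disp,
            "batch_loading": loading,
            "composition_loading": comp_loading,
            **{f"effect_{g}": effects[g] for g in cfg.groups},
        },
        index=bio_names,
    )
    sample_truth = pd.DataFrame(
        {
            "group": group_arr,
            "size_factor_log2": size_log2,
            "batch_log2": batch_log2,
            "composition_log2": composition_log2,
            "degraded": degraded,
            "outlier": outlier,
        },
        index=samples.index,
    )
    exp = Experiment(counts=counts, probes=probes, samples=samples)
    return exp, SimTruth(gene=gene_truth, sample=sample_truth, config=cfg)


def null_experiment(
    cfg: SimConfig | None = None, seed: int | None = None
) -> tuple[Experiment, SimTruth]:
    """A cohort with no group effects, degradation or outliers.

    Group labels are attached but exchangeable by construction, which is
    the setting the permutation Type I simulation assumes.
    """
    cfg = cfg or SimConfig()
    cfg = replace(cfg, de_genes=(), n_degraded=0, n_outliers=0)
    return simulate_experiment(cfg, seed=seed)


def _reference_de_spec() -> tuple[tuple[str, str, float], ...]:
    """Planted differential expression echoing the lesion-biology pattern.

    SSL vs TA: mucin-program analogs over-expressed (including four of the
    biological positive controls) and WNT-program analogs under-expressed
    (including four more of the controls); TV vs TA: under-expression only.
    """
    spec: list[tuple[str, str, float]] = []
    # four bio-positive controls over-expressed in SSL
    spec += [("TFF1", "SSL", 1.0), ("MUC5AC", "SSL", 1.1),
             ("MUC2", "SSL", 0.8), ("CDH1", "SSL", 0.6)]
    # four under-expressed in SSL (assigned high baselines in SimConfig)
    spec += [("ITLN1", "SSL", -0.75), ("OLFM4", "SSL", -0.7),
             ("PIGR", "SSL", -0.6), ("SELENBP1", "SSL", -0.6)]
    # endogenous mucin-program analogs, over in SSL
    for i, idx in enumerate(range(1, 16)):
        spec.append((f"IMM{idx:03d}", "SSL", 0.6 + 0.04 * i))
    # endogenous WNT-program analogs, under in SSL
    for i, idx in enumerate(range(20, 36)):
        spec.append((f"IMM{idx:03d}", "SSL", -(0.6 + 0.025 * i)))
    # TV vs TA: widespread under-expression of immune genes
    for i, idx in enumerate(range(100, 132)):
        spec.append((f"IMM{idx:03d}", "TV", -(0.4 + 0.0125 * i)))
    return tuple(spec)


def reference_cohort(seed: int = 0) -> tuple[Experiment, SimTruth]:
    """Convenience preset: 100-sample cohort with planted QC structure.

    25 SSL / 27 TV / 48 TA samples, 2 planted global-shift outlier lanes,
    11 planted degraded samples whose biological probes are attenuated
    strongly enough to push at least 4 of the 11 positive-control genes
    below background, and planted differential expression (SSL vs TA in
    both directions, TV vs TA under-expression only).
    """
    cfg = SimConfig(
        de_genes=_reference_de_spec(),
        n_degraded=11,
        degradation_log2=-5.0,
        n_outliers=2,
        outlier_log2_shift=5.0,
        seed=seed,
    )
    return simulate_experiment(cfg)
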