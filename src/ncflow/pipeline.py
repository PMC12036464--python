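"""End-to-end run orchestration with a reproducibility manifest.

``run_all`` chains QC -> sample exclusion -> every requested
normalization x DE combination -> cross-method comparison -> optional
permutation Type I simulation, writing plain-text outputs plus a manifest
holding the full configuration, per-stage counts, content hashes of every
output file and wall-clock timings.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .codeset_io import read_counts
from .errors import ConfigurationError
from .evaluate import deg_overlap, run_de_pipeline, type_i_simulation, volcano_table
from .qc import QCConfig, run_qc


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    experiment: str  # path to the three-file bundle
    out_dir: str
    methods: tuple[str, ...] = ("ruvg+moderated", "nsolver+moderated")
    referent: str = "TA"
    contrasts: tuple[str, ...] = ("SSL", "TV")
    k: int = 1
    q_threshold: float = 0.05
    covariates: tuple[str, ...] = ()
    qc: QCConfig = field(default_factory=QCConfig)
    type1_method: str | None = None
    type1_B: int = 0
    type1_alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not self.methods:
            raise ConfigurationError("at least one method is required")
        if not self.contrasts:
            raise ConfigurationError("at least one contrast is required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        qc_cfg = QCConfig(**raw.pop("qc", {}))
        cfg = cls(qc=qc_cfg, **raw)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    stages: dict[str, float] = {}
    outputs: list[Path] = []

    exp = read_counts(cfg.experiment)
    n_input = exp.n_samples

    t0 = time.time()
    report = run_qc(exp, cfg.qc)
    report.table.to_csv(out / "qc_report.tsv", sep="\t")
    outputs.append(out / "qc_report.tsv")
    stages["qc"] = time.time() - t0

    retained = exp.subset_samples(report.retained)

    de_results: dict[str, dict] = {}
    for method in cfg.methods:
        t0 = time.time()
        _, results = run_de_pipeline(
            retained,
            method,
            referent=cfg.referent,
            k=cfg.k,
            covariates=list(cfg.covariates) or None,
            threshold=cfg.q_threshold,
        )
        de_results[method] = results
        for contrast_col, res in results.items():
            label = contrast_col.replace("group_", "")
            if label not in cfg.contrasts:
                continue
            stem = f"de_{method.replace('+', '_')}_{label}_vs_{cfg.referent}"
            res.table.to_csv(out / f"{stem}.tsv", sep="\t")
            volcano_table(res).to_csv(out / f"{stem}_volcano.tsv", sep="\t")
            outputs += [out / f"{stem}.tsv", out / f"{stem}_volcano.tsv"]
        stages[f"de:{method}"] = time.time() - t0

    t0 = time.time()
    comparison = {}
    for label in cfg.contrasts:
        col = f"group_{label}"
        per_method = [
            de_results[m][col] for m in cfg.methods if col in de_results[m]
        ]
        if len(per_method) >= 2:
            comp = deg_overlap(
                per_method, threshold=cfg.q_threshold, labels=list(cfg.methods)
            )
            comparison[f"{label}_vs_{cfg.referent}"] = comp.to_dict()
    (out / "comparison.json").write_text(json.dumps(comparison, indent=2))
    outputs.append(out / "comparison.json")
    stages["comparison"] = time.time() - t0

    type1 = None
    if cfg.type1_method and cfg.type1_B > 0:
        t0 = time.time()
        t1 = type_i_simulation(
            retained,
            cfg.type1_method,
            B=cfg.type1_B,
            alpha=cfg.type1_alpha,
            seed=cfg.seed,
            referent=cfg.referent,
            k=cfg.k,
        )
        type1 = t1.to_dict()
        (out / "type1.json").write_text(json.dumps(type1, indent=2))
        outputs.append(out / "type1.json")
        stages["type1"] = time.time() - t0

    manifest = {
        "ncflow_version": __version__,
        "config": {
            **{k: v for k, v in asdict(cfg).items() if k != "qc"},
            "qc": cfg.qc.to_dict(),
        },
        "seed": cfg.seed,
        "samples": {
            "input": n_input,
            "retained_for_de": len(report.retained),
            "excluded": report.excluded,
        },
        "genes_tested": int(
            next(iter(next(iter(de_results.values())).values())).table.shape[0]
        )
        if de_results
        else 0,
        "outputs": {p.name: _sha256(p) for p in outputs},
        "stage_seconds": {k: round(v, 3) for k, v in stages.items()},
        "wall_seconds": round(time.time() - t_start, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
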