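"""Core in-memory containers for nCounter-style experiments.

An :class:`Experiment` bundles the raw probe-by-sample count matrix with a
probe annotation table (probe class, spike concentration) and a sample
metadata table (lesion group, cartridge, lane attributes, covariates).
All downstream QC, normalization and differential-expression operations
consume this one object.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .errors import ValidationError


class ProbeClass(str, Enum):
    """Probe classes of an nCounter codeset.

    ``BIO_POSITIVE`` marks the biological (tissue-specific) positive-control
    genes.  These probes are endogenous biology — they carry real signal and
    take part in every endogenous analysis — but are tracked as a separate
    class because they additionally drive the sample-level missingness flag.
    """

    ENDOGENOUS = "endogenous"
    HOUSEKEEPING = "housekeeping"
    POSITIVE_SPIKE = "positive"
    NEGATIVE_SPIKE = "negative"
    BIO_POSITIVE = "bio_positive"

    @classmethod
    def from_code_class(cls, text: str) -> "ProbeClass":
        """Map an RCC ``CodeClass`` string (case-insensitive) to a class."""
        key = str(text).strip().lower()
        mapping = {
            "endogenous": cls.ENDOGENOUS,
            "housekeeping": cls.HOUSEKEEPING,
            "positive": cls.POSITIVE_SPIKE,
            "negative": cls.NEGATIVE_SPIKE,
            "bio_positive": cls.BIO_POSITIVE,
        }
        if key not in mapping:
            raise ValidationError(f"unknown probe CodeClass: {text!r}")
        return mapping[key]


#: Probe classes that carry biology (used for PCA, normalization output, DE).
BIOLOGICAL_CLASSES = (
    ProbeClass.ENDOGENOUS,
    ProbeClass.BIO_POSITIVE,
    ProbeClass.HOUSEKEEPING,
)

#: Probe classes tested for differential expression.
TESTED_CLASSES = (ProbeClass.ENDOGENOUS, ProbeClass.BIO_POSITIVE)


@dataclass
class LaneAttributes:
    """Technical attributes of one cartridge lane."""

    lane_id: str
    cartridge_id: str
    fov_count: int
    fov_counted: int
    binding_density: float

    def __post_init__(self) -> None:
        if self.fov_count < 0 or not (0 <= self.fov_counted <= self.fov_count):
            raise ValidationError(
                f"lane {self.lane_id}: need 0 <= fov_counted <= fov_count, "
                f"got {self.fov_counted}/{self.fov_count}"
            )
        if np.isfinite(self.binding_density) and self.binding_density < 0:
            raise ValidationError(
                f"lane {self.lane_id}: binding_density must be >= 0"
            )


# Sample-metadata columns holding lane attributes; optional, NaN when absent.
LANE_COLUMNS = ("fov_count", "fov_counted", "binding_density")


@dataclass(eq=False)
class Experiment:
    """A probe x sample count matrix plus probe and sample annotation.

    Parameters
    ----------
    counts
        Non-negative integer counts, rows indexed by probe name, columns by
        sample id.  Row/column order must match ``probes`` / ``samples``.
    probes
        Indexed by probe name; columns ``probe_class`` (a :class:`ProbeClass`
        value string), ``accession`` and ``spike_fm`` (spike concentration in
        fM, NaN except for positive spikes).
    samples
        Indexed by sample id; columns ``group``, ``cartridge``, optional
        covariates (``size_mm``, ``age``, ``sex``) and optional lane
        attributes (``fov_count``, ``fov_counted``, ``binding_density``).
    """

    counts: pd.DataFrame
    probes: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        if not self.counts.index.equals(self.probes.index):
            raise ValidationError("counts rows do not match probe annotation")
        if not self.counts.columns.equals(self.samples.index):
            raise ValidationError("counts columns do not match sample metadata")
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValidationError(f"duplicate probe names: {list(dups)}")
        if self.counts.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(values < 0):
            raise ValidationError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValidationError("counts must be integers")
        if "probe_class" not in self.probes.columns:
            raise ValidationError("probe annotation lacks a probe_class column")
        for value in self.probes["probe_class"]:
            ProbeClass(value)
        if not np.any(self.classes == ProbeClass.NEGATIVE_SPIKE.value):
            raise ValidationError(
                "experiment has no negative control probes; QC needs at least one"
            )

    # -- accessors -------------------------------------------------------

    @property
    def classes(self) -> pd.Series:
        """Per-probe class as a string series aligned with ``counts`` rows."""
        return self.probes["probe_class"]

    def names_of(self, *classes: ProbeClass) -> pd.Index:
        wanted = {c.value for c in classes}
        return self.probes.index[self.classes.isin(wanted)]

    def counts_of(self, *classes: ProbeClass) -> pd.DataFrame:
        """Sub-matrix of counts for probes of the given classes."""
        return self.counts.loc[self.names_of(*classes)]

    @property
    def biological_counts(self) -> pd.DataFrame:
        """Counts for endogenous + biological-positive + housekeeping probes."""
        return self.counts_of(*BIOLOGICAL_CLASSES)

    @property
    def n_probes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    # -- subsetting ------------------------------------------------------

    def subset_samples(self, sample_ids) -> "Experiment":
        """A new Experiment restricted to ``sample_ids`` (order preserved)."""
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.samples.index]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        return Experiment(
            counts=self.counts.loc[:, ids].copy(),
            probes=self.probes.copy(),
            samples=self.samples.loc[ids].copy(),
        )

    def subset_probes(self, probe_names) -> "Experiment":
        names = list(probe_names)
        missing = [p for p in names if p not in self.probes.index]
        if missing:
            raise ValidationError(f"unknown probes: {missing}")
        return Experiment(
            counts=self.counts.loc[names].copy(),
            probes=self.probes.loc[names].copy(),
            samples=self.samples.copy(),
        )

    def lane(self, sample_id: str) -> LaneAttributes:
        """Lane attributes of one sample (NaN-tolerant)."""
        row = self.samples.loc[sample_id]
        return LaneAttributes(
            lane_id=str(row.get("lane_id", sample_id)),
            cartridge_id=str(row.get("cartridge", "")),
            fov_count=int(row["fov_count"]) if pd.notna(row.get("fov_count")) else 0,
            fov_counted=int(row["fov_counted"]) if pd.notna(row.get("fov_counted")) else 0,
            binding_density=float(row.get("binding_density", np.nan))
            if pd.notna(row.get("binding_density", np.nan))
            else float("nan"),
        )

    # -- comparison ------------------------------------------------------

    def equals(self, other: "Experiment") -> bool:
        """Exact equality of counts, annotation and metadata."""
        if not isinstance(other, Experiment):
            return False
        return (
            self.counts.equals(other.counts)
            and self.probes.equals(other.probes)
            and self.samples.equals(other.samples)
        )
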