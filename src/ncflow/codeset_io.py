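"""Reading and writing nCounter-style data.

Covers the platform's per-lane RCC files (a sectioned CSV dialect), the
three-file plain-text experiment bundle (counts / probe annotation / sample
metadata TSVs) used by every other module, and the packaged codeset gene
lists: the 11 colon-specific biological positive-control genes and the 15
housekeeping genes of the immune panel this workflow was designed around.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CodesetMismatchError, RccFormatError, ValidationError
from .experiment import Experiment, LaneAttributes, ProbeClass

# ---------------------------------------------------------------------------
# Packaged codeset fixtures
# ---------------------------------------------------------------------------

#: Colon-specific biological positive-control genes (tissue-level canaries
#: used by the sample missingness flag).
BIO_POSITIVE_GENES: tuple[str, ...] = (
    "MUC5AC", "TFF1", "CDH1", "CDX2", "CTNNB1", "ITLN1",
    "B2M", "MUC2", "OLFM4", "PIGR", "SELENBP1",
)

#: Housekeeping genes used as the normalization anchor / standard QC set.
HOUSEKEEPING_GENES: tuple[str, ...] = (
    "ABCF1", "ALAS1", "EEF1G", "G6PD", "GAPDH", "GUSB", "HPRT1", "OAZ1",
    "POLR1B", "POLR2A", "PPIA", "RPL19", "SDHA", "TBP", "TUBB",
)

#: Common misprints of panel gene symbols, accepted as aliases and resolved
#: to the standard HGNC symbol.
SYMBOL_ALIASES: dict[str, str] = {
    "ALASI": "ALAS1",
    "LRG5": "LGR5",
    "OLMF4": "OLFM4",
}


def canonical_symbol(name: str) -> str:
    """Resolve a gene symbol, mapping known misprint aliases."""
    return SYMBOL_ALIASES.get(name, name)


def load_packaged_codeset() -> tuple[list[str], list[str]]:
    """The packaged (bio-positive, housekeeping) gene lists.

    Returns
    -------
    tuple of (list, list)
        11 colon-specific positive-control symbols and 15 housekeeping
        symbols, in panel order.
    """
    return list(BIO_POSITIVE_GENES), list(HOUSEKEEPING_GENES)


# ---------------------------------------------------------------------------
# RCC lane files
# ---------------------------------------------------------------------------

_POS_CONC_RE = re.compile(r"\(([\d.]+)\)")


@dataclass
class ProbeRecord:
    """One Code_Summary row of an RCC file."""

    name: str
    probe_class: ProbeClass
    accession: str
    count: int
    spike_fm: float  # NaN unless a positive spike


@dataclass
class RccLane:
    """Parsed content of one RCC lane file."""

    sample_id: str
    lane: LaneAttributes
    records: list[ProbeRecord]


def _split_sections(text: str) -> dict[str, str]:
    # Vendor files vary in line endings and may carry unknown sections;
    # both are tolerated.
    text = text.replace("\r\n", "\n").replace("\r", "\n")
    sections = {}
    for match in re.finditer(r"<(\w+)>\n?(.*?)</\1>", text, re.DOTALL):
        sections[match.group(1)] = match.group(2).strip("\n")
    return sections


def _section_kv(body: str) -> dict[str, str]:
    out = {}
    for row in csv.reader(io.StringIO(body)):
        if len(row) >= 2:
            out[row[0].strip()] = row[1].strip()
    return out


def read_rcc(path) -> RccLane:
    """Parse one RCC lane file.

    Parameters
    ----------
    path
        Path to a file in the RCC sectioned-CSV dialect with ``Header``,
        ``Sample_Attributes``, ``Lane_Attributes`` and ``Code_Summary``
        sections.

    Returns
    -------
    RccLane
        Sample id, lane attributes, and one :class:`ProbeRecord` per
        Code_Summary row.  Spike concentrations are parsed from positive
        probe names of the form ``POS_X(conc)``.

    Raises
    ------
    RccFormatError
        If the ``Code_Summary`` section is missing.
    ValueError
        If a count is negative or non-integer.
    """
    path = Path(path)
    sections = _split_sections(path.read_text())
    if "Code_Summary" not in sections:
        raise RccFormatError(f"{path.name}: missing Code_Summary section")

    sample_attrs = _section_kv(sections.get("Sample_Attributes", ""))
    lane_attrs = _section_kv(sections.get("Lane_Attributes", ""))
    sample_id = sample_attrs.get("ID", path.stem)
    lane = LaneAttributes(
        lane_id=lane_attrs.get("ID", path.stem),
        cartridge_id=lane_attrs.get("CartridgeID", ""),
        fov_count=int(float(lane_attrs.get("FovCount", 0) or 0)),
        fov_counted=int(float(lane_attrs.get("FovCounted", 0) or 0)),
        binding_density=float(lane_attrs.get("BindingDensity", "nan") or "nan"),
    )

    rows = list(csv.reader(io.StringIO(sections["Code_Summary"])))
    if not rows:
        raise RccFormatError(f"{path.name}: empty Code_Summary section")
    header = [h.strip().lower() for h in rows[0]]
    try:
        icls, iname = header.index("codeclass"), header.index("name")
        iacc, icnt = header.index("accession"), header.index("count")
    except ValueError as exc:
        raise RccFormatError(
            f"{path.name}: Code_Summary header must carry "
            "CodeClass,Name,Accession,Count"
        ) from exc

    records = []
    for row in rows[1:]:
        if not row or not any(field.strip() for field in row):
            continue
        name = row[iname].strip()
        raw_count = row[icnt].strip()
        try:
            count_f = float(raw_count)
        except ValueError as exc:
            raise ValueError(
                f"{path.name}: probe {name!r} has non-numeric count {raw_count!r}"
            ) from exc
        if count_f < 0 or count_f != int(count_f):
            raise ValueError(
                f"{path.name}: probe {name!r} has invalid count {raw_count!r} "
                "(must be a non-negative integer)"
            )
        probe_class = ProbeClass.from_code_class(row[icls])
        spike_fm = float("nan")
        if probe_class is ProbeClass.POSITIVE_SPIKE:
            match = _POS_CONC_RE.search(name)
            if match:
                spike_fm = float(match.group(1))
        records.append(
            ProbeRecord(
                name=name,
                probe_class=probe_class,
                accession=row[iacc].strip(),
                count=int(count_f),
                spike_fm=spike_fm,
            )
        )
    return RccLane(sample_id=sample_id, lane=lane, records=records)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble_experiment(
    lanes: list[RccLane],
    meta: pd.DataFrame,
    bio_positive_genes=None,
) -> Experiment:
    """Assemble parsed lanes and a sample-metadata table into an Experiment.

    Probes named in ``bio_positive_genes`` (aliases resolved) are
    reclassified from endogenous to biological-positive; all other probes
    keep their RCC class.  Probe rows are canonicalized to alphabetical
    order; sample columns follow the order of ``meta``.

    Raises
    ------
    CodesetMismatchError
        If lanes do not share an identical probe set (the symmetric
        difference is listed).
    ValidationError
        If a lane's sample id is absent from ``meta`` or a bio-positive
        gene is absent from the codeset.
    """
    if not lanes:
        raise ValidationError("no lanes to assemble")
    bio_positive_genes = [canonical_symbol(g) for g in (bio_positive_genes or [])]

    reference = {r.name for r in lanes[0].records}
    for lane in lanes[1:]:
        names = {r.name for r in lane.records}
        if names != reference:
            diff = sorted(names.symmetric_difference(reference))
            raise CodesetMismatchError(
                f"lane {lane.sample_id} probe set differs from lane "
                f"{lanes[0].sample_id}; symmetric difference: {diff}"
            )

    missing_meta = [l.sample_id for l in lanes if l.sample_id not in meta.index]
    if missing_meta:
        raise ValidationError(f"lanes without sample metadata: {missing_meta}")

    order = sorted(reference)
    first = {r.name: r for r in lanes[0].records}
    probes = pd.DataFrame(
        {
            "probe_class": [first[n].probe_class.value for n in order],
            "accession": [first[n].accession for n in order],
            "spike_fm": [first[n].spike_fm for n in order],
        },
        index=pd.Index(order, name="probe"),
    )
    for gene in bio_positive_genes:
        if gene not in probes.index:
            raise ValidationError(f"bio-positive gene {gene!r} not in codeset")
        if probes.at[gene, "probe_class"] == ProbeClass.ENDOGENOUS.value:
            probes.at[gene, "probe_class"] = ProbeClass.BIO_POSITIVE.value

    sample_ids = [s for s in meta.index if s in {l.sample_id for l in lanes}]
    by_id = {l.sample_id: l for l in lanes}
    counts = pd.DataFrame(
        {
            sid: [ {r.name: r.count for r in by_id[sid].records}[n] for n in order]
            for sid in sample_ids
        },
        index=probes.index,
        dtype=np.int64,
    )

    samples = meta.loc[sample_ids].copy()
    samples.index.name = "sample_id"
    for sid in sample_ids:
        lane = by_id[sid].lane
        samples.loc[sid, "cartridge"] = (
            lane.cartridge_id or samples.loc[sid].get("cartridge", "")
        )
        samples.loc[sid, "fov_count"] = lane.fov_count
        samples.loc[sid, "fov_counted"] = lane.fov_counted
        samples.loc[sid, "binding_density"] = lane.binding_density
    return Experiment(counts=counts, probes=probes, samples=samples)


# ---------------------------------------------------------------------------
# Experiment bundle (three TSV files)
# ---------------------------------------------------------------------------

_COUNTS_FILE = "counts.tsv"
_PROBES_FILE = "probes.tsv"
_SAMPLES_FILE = "samples.tsv"


def write_counts(exp: Experiment, path) -> Path:
    """Write an experiment as a three-file TSV bundle under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    exp.counts.to_csv(path / _COUNTS_FILE, sep="\t", index_label="probe")
    exp.probes.to_csv(path / _PROBES_FILE, sep="\t", index_label="probe")
    exp.samples.to_csv(path / _SAMPLES_FILE, sep="\t", index_label="sample_id")
    return path


def read_counts(path) -> Experiment:
    """Read a three-file TSV bundle written by :func:`write_counts`.

    ``write_counts`` followed by ``read_counts`` is the identity on the
    experiment (bitwise-equal counts, identical annotation and metadata).

    Raises
    ------
    ValidationError
        If the annotation lacks a probe present in the counts, or a count
        column has no sample-metadata row (the offender is named).
    """
    path = Path(path)
    counts = pd.read_csv(path / _COUNTS_FILE, sep="\t", index_col="probe")
    probes = pd.read_csv(path / _PROBES_FILE, sep="\t", index_col="probe")
    samples = pd.read_csv(path / _SAMPLES_FILE, sep="\t", index_col="sample_id")

    missing_probes = counts.index.difference(probes.index)
    if len(missing_probes):
        raise ValidationError(
            f"annotation missing probes present in counts: {list(missing_probes)}"
        )
    missing_samples = counts.columns.difference(samples.index)
    if len(missing_samples):
        raise ValidationError(
            f"metadata missing samples present in counts: {list(missing_samples)}"
        )
    probes = probes.loc[counts.index]
    samples = samples.loc[counts.columns]
    return Experiment(counts=counts.astype(np.int64), probes=probes, samples=samples)
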