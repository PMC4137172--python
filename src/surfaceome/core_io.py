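"""Input parsing, identification filtering and table I/O.

Supported input dialects:

* FASTA proteome (via Bio.SeqIO), ids taken from the first header token;
* the TMH scanner's one-line summary format, one protein per line with
  ``key=value`` fields (``len=``, ``PredHel=``, ``Topology=``), the topology
  string written as e.g. ``i98-117o`` (1-based inclusive residue coordinates,
  leading letter = side of the N-terminus);
* PSORTb-style and LocateP-style tab-separated tables with a header row and a
  localization column (the long and short PSORTb variants differ only in
  extra columns, which are ignored);
* hmmscan per-domain tables (whitespace-separated, ``#`` comments), with Pfam
  accession version suffixes stripped at parse time so ``PF01476.18`` and
  ``PF01476`` compare equal;
* plain UTF-8 TSV with a header row for identification tables, spectral-count
  matrices and dimethyl log-ratio tables.

Identification-level filtering follows the protein-threshold convention of
shotgun proteomics: a protein-level FDR cap (default 0.01) and a minimum
number of distinct peptides (default 2).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .localization import CanonicalCompartment, Tool, canonicalize_label

logger = logging.getLogger(__name__)

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

EXPERIMENTS = ("protoplast", "shaving", "shedding")
CONDITIONS = ("fermentation", "fe_reduction")


@dataclass(frozen=True)
class ProteinEntry:
    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _AA_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id}: non-amino-acid characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class IdentificationRecord:
    protein_id: str
    experiment: str
    condition: str
    replicate: str
    n_peptides: int
    protein_fdr: float | None = None
    spectral_count: int = 0

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.n_peptides < 0 or self.spectral_count < 0:
            raise ValueError("n_peptides and spectral_count must be >= 0")
        if self.protein_fdr is not None and not 0 <= self.protein_fdr <= 1:
            raise ValueError("protein_fdr must lie in [0, 1]")


@dataclass(frozen=True)
class TopologyRecord:
    protein_id: str
    n_helices: int
    segments: tuple[tuple[int, int], ...]
    n_term_side: str = "unknown"  # {in, out, unknown}

    def __post_init__(self) -> None:
        if self.n_helices != len(self.segments):
            raise ValueError(
                f"{self.protein_id}: n_helices={self.n_helices} but "
                f"{len(self.segments)} segments"
            )
        prev_end = 0
        for start, end in self.segments:
            if start > end:
                raise ValueError(f"{self.protein_id}: segment ({start},{end}) inverted")
            if start <= prev_end:
                raise ValueError(f"{self.protein_id}: segments overlap or unsorted")
            prev_end = end
        if self.n_term_side not in ("in", "out", "unknown"):
            raise ValueError(f"bad n_term_side {self.n_term_side!r}")


@dataclass(frozen=True)
class PredictorCall:
    protein_id: str
    tool: Tool
    raw_label: str
    canonical_label: CanonicalCompartment
    lipoprotein: bool = False
    secreted: bool = False


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    accession: str
    name: str
    ali_start: int
    ali_end: int
    i_evalue: float

    def __post_init__(self) -> None:
        if self.ali_start > self.ali_end:
            raise ValueError(f"{self.protein_id}: ali_start > ali_end")
        if self.i_evalue < 0:
            raise ValueError(f"{self.protein_id}: negative e-value")


class SampleKey(NamedTuple):
    """Identity of one MS sample: extraction experiment, growth condition,
    replicate label and (Fe(III)-reduction samples only) minutes of protoplast
    treatment, carried as metadata."""

    experiment: str
    condition: str
    replicate: str
    treatment_minutes: int | None = None

    def label(self) -> str:
        minutes = "-" if self.treatment_minutes is None else str(self.treatment_minutes)
        return f"{self.experiment}|{self.condition}|{self.replicate}|{minutes}"

    @classmethod
    def from_label(cls, label: str) -> "SampleKey":
        experiment, condition, replicate, minutes = label.split("|")
        return cls(
            experiment,
            condition,
            replicate,
            None if minutes == "-" else int(minutes),
        )


@dataclass
class SpectralCountMatrix:
    """Proteins x samples matrix of non-negative integer spectral counts.

    A protein absent from a sample has count 0 — absence is zero evidence
    under spectrum counting, not missing-at-random.
    """

    protein_ids: list[str]
    samples: list[SampleKey]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.protein_ids), len(self.samples)):
            raise ValueError("counts shape does not match protein_ids x samples")
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValueError("duplicate protein ids")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample keys")
        if (self.counts < 0).any():
            raise ValueError("negative spectral counts")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.protein_ids, name="protein_id"),
            columns=[s.label() for s in self.samples],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SpectralCountMatrix":
        return cls(
            protein_ids=list(frame.index),
            samples=[SampleKey.from_label(str(c)) for c in frame.columns],
            counts=frame.to_numpy(),
        )


RATIO_COLUMNS = ("protein_id", "log2_ratio", "intensity", "comparison", "label_swapped")


def validate_ratio_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a dimethyl log-ratio table against its schema and return it."""
    missing = [c for c in RATIO_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"ratio table missing columns {missing}")
    if not np.isfinite(table["log2_ratio"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite log2 ratios")
    if (table["intensity"].to_numpy(dtype=float) <= 0).any():
        raise ValueError("intensities must be positive")
    return table


# ---------------------------------------------------------------------------
# readers


def read_fasta(path) -> list[ProteinEntry]:
    """Read a FASTA proteome into validated entries.

    Ids are the first whitespace-delimited header token and must be unique;
    lowercase residues are upper-cased; sequences are restricted to the 20
    standard amino-acid letters plus X.  An empty file yields an empty list
    with a logged warning.
    """
    entries: list[ProteinEntry] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate FASTA id {record.id!r}")
        seen.add(record.id)
        description = record.description[len(record.id) :].strip()
        entries.append(
            ProteinEntry(
                id=record.id,
                description=description,
                sequence=str(record.seq).upper(),
            )
        )
    if not entries:
        logger.warning("no FASTA records found in %s", path)
    return entries


def write_fasta(entries: Iterable[ProteinEntry], path) -> None:
    with open(path, "w") as fh:
        for e in entries:
            header = f">{e.id} {e.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(e.sequence), 60):
                fh.write(e.sequence[i : i + 60] + "\n")


_TOPOLOGY_RE = re.compile(r"^[io](?:\d+-\d+[io])*$")


def parse_topology_string(protein_id: str, topology: str) -> TopologyRecord:
    """Expand a one-line topology string (e.g. ``i98-117o``) into segments."""
    topology = topology.strip()
    if not _TOPOLOGY_RE.match(topology):
        raise ValueError(f"{protein_id}: malformed topology string {topology!r}")
    segments = tuple(
        (int(a), int(b)) for a, b in re.findall(r"(\d+)-(\d+)", topology)
    )
    return TopologyRecord(
        protein_id=protein_id,
        n_helices=len(segments),
        segments=segments,
        n_term_side="in" if topology[0] == "i" else "out",
    )


def _parse_tmh_line(line: str, lineno: int) -> tuple[PredictorCall, TopologyRecord]:
    fields = line.split()
    protein_id = fields[0]
    kv = {}
    for token in fields[1:]:
        if "=" in token:
            key, value = token.split("=", 1)
            kv[key.lower()] = value
    if "predhel" not in kv:
        raise ValueError(f"line {lineno}: missing PredHel field")
    n_helices = int(kv["predhel"])
    topo_string = kv.get("topology", "i" if n_helices == 0 else "")
    topology = parse_topology_string(protein_id, topo_string)
    if topology.n_helices != n_helices:
        raise ValueError(
            f"line {lineno}: PredHel={n_helices} disagrees with topology "
            f"{topo_string!r}"
        )
    raw = f"PredHel={n_helices}"
    call = PredictorCall(
        protein_id=protein_id,
        tool=Tool.TMH_SCAN,
        raw_label=raw,
        canonical_label=canonicalize_label(Tool.TMH_SCAN, raw),
    )
    return call, topology


_TRUTHY = {"yes", "true", "1", "y"}


def parse_predictor_output(
    path, tool: Tool | str
) -> tuple[list[PredictorCall], list[TopologyRecord]]:
    """Parse one predictor's output file.

    Returns ``(calls, topologies)``; topologies are populated only for the
    TMH-scan dialect.  Every non-comment input row yields exactly one call,
    with the tool's raw label preserved verbatim and the canonical label
    assigned through :func:`canonicalize_label`.
    """
    tool = Tool(tool)
    calls: list[PredictorCall] = []
    topologies: list[TopologyRecord] = []
    if tool is Tool.TMH_SCAN:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                call, topo = _parse_tmh_line(line, lineno)
                calls.append(call)
                topologies.append(topo)
    else:
        table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        cols = {c.strip().lower(): c for c in table.columns}
        id_col = next(
            (cols[k] for k in ("protein_id", "seqid", "query") if k in cols), None
        )
        loc_col = next(
            (cols[k] for k in ("localization", "subcellular localization") if k in cols),
            None,
        )
        if id_col is None or loc_col is None:
            raise ValueError(
                f"{path}: expected a protein-id and a localization column, "
                f"found {list(table.columns)}"
            )
        for i, (_, row) in enumerate(table.iterrows(), start=2):
            raw = row[loc_col]
            pid = row[id_col]
            if pd.isna(raw) or str(raw).strip() == "":
                raise ValueError(f"{path} line {i}: missing localization value")
            lipoprotein = False
            secreted = False
            if tool is Tool.LOCATEP:
                if "lipoprotein" in cols:
                    lipoprotein = str(row[cols["lipoprotein"]]).strip().lower() in _TRUTHY
                if "secreted" in cols:
                    secreted = str(row[cols["secreted"]]).strip().lower() in _TRUTHY
            canonical = canonicalize_label(tool, str(raw))
            if canonical is CanonicalCompartment.EXTRACELLULAR and str(
                raw
            ).strip().lower() in ("secreted", "secretory"):
                secreted = True
            calls.append(
                PredictorCall(
                    protein_id=str(pid),
                    tool=tool,
                    raw_label=str(raw),
                    canonical_label=canonical,
                    lipoprotein=lipoprotein,
                    secreted=secreted,
                )
            )
    _require_one_call_per_protein(calls)
    return calls, topologies


def _require_one_call_per_protein(calls: Sequence[PredictorCall]) -> None:
    seen: set[tuple[str, Tool]] = set()
    for c in calls:
        key = (c.protein_id, c.tool)
        if key in seen:
            raise ValueError(f"duplicate call for {key}")
        seen.add(key)


_ACCESSION_VERSION_RE = re.compile(r"\.\d+$")


def parse_domain_hits(path) -> list[DomainHit]:
    """Parse an hmmscan per-domain table into domain hits.

    Comment lines are skipped.  Column layout follows hmmer's ``--domtblout``:
    target name, accession, tlen, query name, ..., with the independent
    e-value in column 13 and alignment coordinates in columns 18-19 (1-based
    columns).  Accession version suffixes are stripped.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 19:
                raise ValueError(f"line {lineno}: too few columns for domtblout")
            name = fields[0]
            accession = _ACCESSION_VERSION_RE.sub("", fields[1])
            protein_id = fields[3]
            try:
                i_evalue = float(fields[12])
            except ValueError as exc:
                raise ValueError(
                    f"line {lineno}: non-numeric e-value {fields[12]!r}"
                ) from exc
            ali_start, ali_end = int(fields[17]), int(fields[18])
            hits.append(
                DomainHit(
                    protein_id=protein_id,
                    accession=accession,
                    name=name,
                    ali_start=ali_start,
                    ali_end=ali_end,
                    i_evalue=i_evalue,
                )
            )
    return hits


def filter_identifications(
    records: Sequence[IdentificationRecord],
    min_peptides: int = 2,
    max_protein_fdr: float = 0.01,
) -> list[IdentificationRecord]:
    """Apply the protein-level identification filters, preserving order.

    Keeps records with at least ``min_peptides`` peptides whose protein FDR
    is absent or at most ``max_protein_fdr``.  Idempotent; output is a
    subsequence of the input.
    """
    if min_peptides < 0:
        raise ValueError("min_peptides must be >= 0")
    if not 0 <= max_protein_fdr <= 1:
        raise ValueError("max_protein_fdr must lie in [0, 1]")
    return [
        r
        for r in records
        if r.n_peptides >= min_peptides
        and (r.protein_fdr is None or r.protein_fdr <= max_protein_fdr)
    ]


# ---------------------------------------------------------------------------
# TSV round-trips

_FLOAT_FORMAT = "%.10g"


def write_count_matrix(matrix: SpectralCountMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


def read_count_matrix(path) -> SpectralCountMatrix:
    frame = pd.read_csv(path, sep="\t", index_col="protein_id")
    return SpectralCountMatrix.from_frame(frame)


def write_ratio_table(table: pd.DataFrame, path) -> None:
    validate_ratio_table(table)
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def read_ratio_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    table["label_swapped"] = table["label_swapped"].astype(bool)
    table["log2_ratio"] = table["log2_ratio"].astype(float)
    table["intensity"] = table["intensity"].astype(float)
    return validate_ratio_table(table)


def write_identifications(records: Sequence[IdentificationRecord], path) -> None:
    frame = pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in records],
            "experiment": [r.experiment for r in records],
            "condition": [r.condition for r in records],
            "replicate": [r.replicate for r in records],
            "n_peptides": [r.n_peptides for r in records],
            "protein_fdr": [
                "" if r.protein_fdr is None else repr(r.protein_fdr) for r in records
            ],
            "spectral_count": [r.spectral_count for r in records],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_identifications(path) -> list[IdentificationRecord]:
    frame = pd.read_csv(path, sep="\t", dtype={"replicate": str})
    records = []
    for row in frame.itertuples(index=False):
        fdr = row.protein_fdr
        if fdr is None or (isinstance(fdr, float) and math.isnan(fdr)):
            fdr = None
        else:
            fdr = float(fdr)
        records.append(
            IdentificationRecord(
                protein_id=str(row.protein_id),
                experiment=str(row.experiment),
                condition=str(row.condition),
                replicate=str(row.replicate),
                n_peptides=int(row.n_peptides),
                protein_fdr=fdr,
                spectral_count=int(row.spectral_count),
            )
        )
    return records
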