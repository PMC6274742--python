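"""Readers and writers for PSM reports, protein lengths, and pipeline tables.

The pipeline is search-engine agnostic: any delimited peptide-spectrum-match
(PSM) export can be adapted through a column mapping. Protein lengths, needed
for NSAF normalization, come either from a FASTA file (residues counted per
record) or from a plain two-column table.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import ConfigurationError, DataError, EmptyInputError

logger = logging.getLogger(__name__)

#: canonical internal column names of a PsmTable frame
PSM_COLUMNS = ("sample_id", "protein_accession", "peptide_sequence", "spectrum_id", "score")

#: default mapping from internal names to file header names
DEFAULT_COLUMN_MAP = {
    "sample_id": "sample",
    "protein_accession": "accession",
    "peptide_sequence": "peptide",
    "spectrum_id": "spectrum",
    "score": "score",
}

_REQUIRED = ("sample_id", "protein_accession")


@dataclass
class PsmTable:
    """Peptide-spectrum matches for a two-condition experiment.

    ``frame`` has the columns in :data:`PSM_COLUMNS` (optional ones may be
    absent). ``conditions`` are the two declared sample labels; every
    ``sample_id`` must be one of them.
    """

    frame: pd.DataFrame
    conditions: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        for col in _REQUIRED:
            if col not in self.frame.columns:
                raise ConfigurationError(f"PsmTable frame is missing required column {col!r}")
        if self.conditions is not None:
            a, b = self.conditions
            if a == b:
                raise ConfigurationError("condition labels must be distinct")
            extra = set(self.frame["sample_id"].unique()) - {a, b}
            if extra:
                raise DataError(
                    f"sample_id values {sorted(extra)} are not among the declared "
                    f"conditions {self.conditions}"
                )

    def __len__(self) -> int:
        return len(self.frame)


def read_psm_table(
    path: str | Path,
    dialect: str = "tsv",
    column_map: Mapping[str, str] | None = None,
    conditions: tuple[str, str] | None = None,
) -> PsmTable:
    """Read a delimited PSM report into a :class:`PsmTable`.

    Parameters
    ----------
    path
        The report file; one row per peptide-spectrum match.
    dialect
        ``"tsv"`` or ``"csv"``.
    column_map
        Mapping from internal names (``sample_id``, ``protein_accession``,
        ``peptide_sequence``, ``spectrum_id``, ``score``) to the file's
        header names. Defaults to :data:`DEFAULT_COLUMN_MAP`. Only
        ``sample_id`` and ``protein_accession`` are required.
    conditions
        If given, the two condition labels every sample_id must belong to.

    Rows with an empty sample or accession are dropped and reported with
    their 1-based file line numbers. Raises :class:`EmptyInputError` if no
    valid row remains.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"PSM file not found: {path}")
    if dialect not in ("tsv", "csv"):
        raise ConfigurationError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'")
    sep = "\t" if dialect == "tsv" else ","

    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    raw = pd.read_csv(path, sep=sep, dtype=str)
    for internal in _REQUIRED:
        if cmap[internal] not in raw.columns:
            raise ConfigurationError(
                f"PSM file {path} lacks required column {cmap[internal]!r} "
                f"(mapped to {internal})"
            )

    frame = pd.DataFrame(index=raw.index)
    for internal in PSM_COLUMNS:
        src = cmap.get(internal)
        if src is not None and src in raw.columns:
            frame[internal] = raw[src]
    if "score" in frame.columns:
        frame["score"] = pd.to_numeric(frame["score"], errors="coerce")

    blank = pd.Series(False, index=frame.index)
    for col in _REQUIRED:
        blank |= frame[col].isna() | (frame[col].astype(str).str.strip() == "")
    if blank.any():
        # +2: 1-based line numbers, header on line 1
        lines = [int(i) + 2 for i in frame.index[blank]]
        logger.warning("dropping %d malformed PSM row(s) at line(s) %s", len(lines), lines)
        frame = frame[~blank]

    if frame.empty:
        raise EmptyInputError(f"no valid PSM rows in {path}")
    return PsmTable(frame.reset_index(drop=True), conditions=conditions)


def write_psm_table(psm: PsmTable, path: str | Path, dialect: str = "tsv") -> None:
    """Write a PsmTable back to disk using the default header names."""
    sep = "\t" if dialect == "tsv" else ","
    out = psm.frame.rename(columns=DEFAULT_COLUMN_MAP)
    out.to_csv(path, sep=sep, index=False)


def read_lengths_fasta(
    path: str | Path, accession_pattern: str | None = None
) -> dict[str, int]:
    """Extract a protein→length (residues) map from a FASTA file.

    The accession is the first whitespace-delimited token of each header,
    or the first group of ``accession_pattern`` matched against the full
    header line. Duplicate accessions raise :class:`DataError`.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"FASTA file not found: {path}")
    regex = re.compile(accession_pattern) if accession_pattern else None

    lengths: dict[str, int] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if regex is not None:
            m = regex.search(record.description)
            if m is None:
                raise DataError(f"header {record.description!r} does not match accession pattern")
            acc = m.group(1)
        else:
            acc = record.id
        if acc in lengths:
            raise DataError(f"duplicate accession in FASTA: {acc}")
        if len(record.seq) < 1:
            raise DataError(f"zero-length sequence for {acc}")
        lengths[acc] = len(record.seq)
    if not lengths:
        raise EmptyInputError(f"no FASTA records in {path}")
    return lengths


def read_lengths_table(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV (accession, length in residues)."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"length table not found: {path}")
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] < 2:
        raise ConfigurationError(f"length table {path} needs two columns (accession, length)")
    acc_col, len_col = frame.columns[:2]
    lengths: dict[str, int] = {}
    for _, row in frame.iterrows():
        acc = str(row[acc_col])
        if acc in lengths:
            raise DataError(f"duplicate accession in length table: {acc}")
        length = int(row[len_col])
        if length < 1:
            raise DataError(f"non-positive length for {acc}")
        lengths[acc] = length
    if not lengths:
        raise EmptyInputError(f"no rows in length table {path}")
    return lengths


def write_lengths_table(lengths: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"accession": list(lengths), "length": list(lengths.values())}
    ).to_csv(path, sep="\t", index=False)


def read_annotation_table(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column TSV (accession, category) into an annotation map.

    An accession may appear on several rows, one per category.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"annotation table not found: {path}")
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] < 2:
        raise ConfigurationError(f"annotation table {path} needs two columns (accession, category)")
    acc_col, cat_col = frame.columns[:2]
    ann: dict[str, set[str]] = {}
    for _, row in frame.iterrows():
        cat = str(row[cat_col]).strip()
        if not cat:
            raise DataError("empty category label in annotation table")
        ann.setdefault(str(row[acc_col]), set()).add(cat)
    return ann
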