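"""Reading and writing the package's on-disk formats.

Formats handled here:

* FASTA protein records (via Biopython), validated against the 20
  standard residue letters;
* the dataset TSV schema used for labeled TA-protein tables (the same
  schema as the published supplementary table, so a user-supplied copy
  of that table drops straight in): columns ``id, name, organism,
  location, cterm_seq, tmd_start, tmd_end, source``, tab-delimited,
  ``#`` comment lines ignored;
* the feature TSV written by the feature-extraction pipeline;
* the bundled fixture dataset — a deterministic, versioned
  reconstruction shipped with the package so that every stage is
  testable without downloads (see ``data/fixture_dataset.tsv`` and the
  methods note for its provenance).

TMD coordinates in dataset tables are 1-based inclusive positions
*within the stored C-terminal fragment*, not within the full protein.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .physchem import AMINO_ACIDS, FeatureVector
from .segmentation import TMDSpan

__all__ = [
    "ProteinRecord",
    "DatasetEntry",
    "LOCATIONS",
    "SINGLE_LOCATIONS",
    "FIXTURE_VERSION",
    "read_fasta",
    "write_fasta",
    "read_dataset",
    "write_dataset",
    "write_features",
    "read_features",
    "load_fixture_dataset",
]

#: Closed vocabulary of localization labels (single and shared).
LOCATIONS = frozenset(
    {"PO", "MITO", "ER", "PO_MITO", "PO_MITO_ER", "MITO_ER"}
)
SINGLE_LOCATIONS = ("PO", "MITO", "ER")

#: Version string of the bundled fixture dataset.
FIXTURE_VERSION = "1.0"

FEATURE_COLUMNS = (
    "id",
    "tmd_start",
    "tmd_end",
    "tmd_gravy",
    "tail_charge",
    "tail_length",
    "upstream_charge",
    "upstream_gravy",
    "label",
)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence: the unit of all analysis.

    The sequence is upper-case folded on construction; any letter
    outside the 20 standard residues is rejected (hydropathy and charge
    are undefined for ambiguity codes such as B, Z, X, U).
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.seq:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        seq = self.seq.upper()
        bad = sorted(set(seq) - AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"record {self.id!r} contains non-standard residue letter(s): "
                + ", ".join(bad)
            )
        object.__setattr__(self, "seq", seq)


@dataclass(frozen=True)
class DatasetEntry:
    """One labeled TA protein: C-terminal fragment + organelle label.

    ``tmd_start``/``tmd_end`` (1-based inclusive within ``cterm_seq``)
    are optional; when present they are passed through to segmentation
    in place of de-novo TMD detection.
    """

    id: str
    name: str
    organism: str
    location: str
    cterm_seq: str
    tmd_start: int | None = None
    tmd_end: int | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("dataset entry id must be non-empty")
        if self.location not in LOCATIONS:
            raise ValueError(
                f"entry {self.id!r}: unknown location label {self.location!r} "
                f"(expected one of {sorted(LOCATIONS)})"
            )
        # Reuse ProteinRecord validation for the sequence letters.
        object.__setattr__(
            self, "cterm_seq", ProteinRecord(self.id, self.cterm_seq).seq
        )
        if (self.tmd_start is None) != (self.tmd_end is None):
            raise ValueError(f"entry {self.id!r}: give both TMD coordinates or neither")
        if self.tmd_start is not None:
            if not 1 <= self.tmd_start < self.tmd_end <= len(self.cterm_seq):
                raise ValueError(
                    f"entry {self.id!r}: TMD coordinates "
                    f"({self.tmd_start}, {self.tmd_end}) out of bounds for a "
                    f"{len(self.cterm_seq)}-residue fragment"
                )

    @property
    def tmd_span(self) -> TMDSpan | None:
        if self.tmd_start is None:
            return None
        from .physchem import gravy

        return TMDSpan(
            start=self.tmd_start,
            end=self.tmd_end,
            score=gravy(self.cterm_seq[self.tmd_start - 1 : self.tmd_end]),
        )


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (possibly line-wrapped, multi-record) FASTA file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(id=rec.id, seq=str(rec.seq), description=rec.description)
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description.startswith(rec.id) else rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


_REQUIRED_DATASET_COLUMNS = ("id", "name", "location", "cterm_seq")


def _parse_coord(value) -> int | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str):
        value = value.strip()
        if value in ("", "NA", "-"):
            return None
    return int(value)


def read_dataset(path: str | Path) -> list[DatasetEntry]:
    """Read a labeled TA-protein table (see module docstring for schema)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _REQUIRED_DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    def _text(row, column, default=""):
        value = getattr(row, column, default)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return default
        return str(value)

    entries = []
    for row in df.itertuples(index=False):
        entries.append(
            DatasetEntry(
                id=str(row.id),
                name=_text(row, "name", str(row.id)),
                organism=_text(row, "organism", "human"),
                location=str(row.location),
                cterm_seq=str(row.cterm_seq),
                tmd_start=_parse_coord(getattr(row, "tmd_start", None)),
                tmd_end=_parse_coord(getattr(row, "tmd_end", None)),
                source=_text(row, "source"),
            )
        )
    return entries


def write_dataset(entries: Sequence[DatasetEntry], path: str | Path) -> None:
    rows = [
        {
            "id": e.id,
            "name": e.name,
            "organism": e.organism,
            "location": e.location,
            "cterm_seq": e.cterm_seq,
            "tmd_start": "" if e.tmd_start is None else e.tmd_start,
            "tmd_end": "" if e.tmd_end is None else e.tmd_end,
            "source": e.source,
        }
        for e in entries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_features(
    rows: Sequence[tuple[str, TMDSpan, FeatureVector, str | None]],
    path: str | Path,
) -> None:
    """Write feature rows as TSV with a fixed column order, floats at 3 dp.

    Each row is ``(id, tmd_span, feature_vector, label-or-None)``.
    """
    if not rows:
        raise ValueError("no feature rows to write")
    table = []
    for rec_id, span, fv, label in rows:
        table.append(
            {
                "id": rec_id,
                "tmd_start": span.start,
                "tmd_end": span.end,
                "tmd_gravy": f"{fv.tmd_gravy:.3f}",
                "tail_charge": f"{fv.tail_charge:.3f}",
                "tail_length": fv.tail_length,
                "upstream_charge": f"{fv.upstream_charge:.3f}",
                "upstream_gravy": f"{fv.upstream_gravy:.3f}",
                "label": "" if label is None else label,
            }
        )
    pd.DataFrame(table, columns=list(FEATURE_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    """Read a feature TSV back into a DataFrame (inverse of write_features)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing feature column(s): {', '.join(missing)}")
    return df


def load_fixture_dataset() -> list[DatasetEntry]:
    """The bundled, versioned fixture dataset (pure function).

    A deterministic reconstruction of a labeled TA-protein table:
    the ACBD5 entry carries the experimentally used TMD-tail peptide;
    all other entries are synthetic sequences emulating the published
    group feature structure, flagged as such in their ``source`` column.
    """
    with resources.as_file(
        resources.files("tapredict").joinpath("data/fixture_dataset.tsv")
    ) as p:
        return read_dataset(p)
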