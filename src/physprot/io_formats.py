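"""Readers and writers for the external formats the pipeline touches.

FASTA protein sequences (via Biopython, with normalization), AAindex1
flat-file property tables, and TSV feature matrices.  All parsers fail
loudly with :class:`FormatError` rather than silently repairing input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

#: The canonical AAindex1 residue order: two rows of ten.
AAINDEX_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Sentinel for an amino acid with no value in a property table ("NA").
MISSING = float("nan")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class EncodingError(ValueError):
    """Raised when a sequence cannot be encoded under a property table."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein: identifier, free-text description, residue string.

    Residues are uppercase letters with gaps and stop characters removed;
    non-standard letters (B, Z, X, U, O, J) are retained and handled at
    encoding time.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"invalid sequence id: {self.id!r}")
        if not self.residues:
            raise FormatError(f"sequence {self.id!r} has no residues")
        if not self.residues.isalpha() or not self.residues.isupper():
            raise FormatError(
                f"sequence {self.id!r} contains non-letter residues"
            )


@dataclass(frozen=True)
class PropertyTable:
    """One AAindex1 entry: accession, title, and 20 per-residue values.

    ``values`` maps each one-letter amino acid code to a float; missing
    entries (literal ``NA`` in the flat file) are NaN.
    """

    accession: str
    values: dict[str, float]
    title: str = ""

    def __post_init__(self) -> None:
        if set(self.values) != set(AAINDEX_ORDER):
            raise FormatError(
                f"{self.accession}: property table must cover exactly the "
                f"20 standard amino acids"
            )
        if all(math.isnan(v) for v in self.values.values()):
            raise FormatError(f"{self.accession}: all 20 values are missing")

    def as_array(self) -> np.ndarray:
        """Values in canonical A R N D C Q E G H I L K M F P S T W Y V order."""
        return np.array([self.values[a] for a in AAINDEX_ORDER])


@dataclass
class FeatureMatrix:
    """An n-by-d real matrix with sample ids, feature ids and ±1 labels.

    ``y`` is None for unlabeled data (e.g. prediction input).
    """

    sample_ids: list[str]
    feature_ids: list[str]
    X: np.ndarray
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n, d = self.X.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids do not align with rows of X")
        if len(self.feature_ids) != d:
            raise ValueError("feature_ids do not align with columns of X")
        if len(set(self.feature_ids)) != d:
            raise ValueError("feature_ids must be unique")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains NaN or Inf entries")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=int)
            if self.y.shape != (n,):
                raise ValueError("labels do not align with rows")
            if not np.all(np.isin(self.y, (-1, 1))):
                raise ValueError("labels must be +1 or -1")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset_features(self, feature_ids: Iterable[str]) -> "FeatureMatrix":
        """Column-select the given features, in the given order."""
        wanted = list(feature_ids)
        index = {f: j for j, f in enumerate(self.feature_ids)}
        missing = [f for f in wanted if f not in index]
        if missing:
            raise KeyError(f"features not present in matrix: {missing}")
        cols = [index[f] for f in wanted]
        return FeatureMatrix(
            sample_ids=list(self.sample_ids),
            feature_ids=wanted,
            X=self.X[:, cols].copy(),
            y=None if self.y is None else self.y.copy(),
        )


# ---------------------------------------------------------------------------
# FASTA


def _normalize_residues(raw: str) -> str:
    return (
        raw.upper().replace("*", "").replace("-", "").replace(".", "")
        .replace(" ", "").replace("\t", "")
    )


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a protein FASTA file into :class:`SequenceRecord` objects.

    Sequence lines are concatenated, lowercased residues are uppercased and
    gap ('-', '.') and stop ('*') characters are stripped.  A header with an
    empty sequence is a format error naming that header.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty FASTA file")
    if not text.lstrip().startswith(">"):
        raise FormatError(f"{path}: no FASTA '>' header found")
    for line in text.splitlines():
        if line.startswith(";"):
            raise FormatError(f"{path}: ';' comment lines are not supported")
    records = []
    for rec in SeqIO.parse(StringIO(text), "fasta"):
        residues = _normalize_residues(str(rec.seq))
        if not residues:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(
            SequenceRecord(id=rec.id, residues=residues, description=rec.description)
        )
    if not records:
        raise FormatError(f"{path}: no sequence records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA, 60 residues per line."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            if not header.startswith(rec.id):
                header = f"{rec.id} {header}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), 60):
                fh.write(rec.residues[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# AAindex1


def parse_aaindex1(path: str | Path) -> list[PropertyTable]:
    """Parse an AAindex1 flat file into property tables.

    Records are delimited by ``//``.  The ``H`` line carries the accession,
    the ``D`` line the title, and the line after ``I`` holds two rows of ten
    values in the order A R N D C Q E G H I / L K M F P S T W Y V.  Literal
    ``NA`` becomes a missing value (NaN).
    """
    path = Path(path)
    tables: list[PropertyTable] = []
    accession = ""
    title = ""
    value_tokens: list[str] = []
    in_values = False

    def flush() -> None:
        nonlocal accession, title, value_tokens, in_values
        if not accession and not value_tokens:
            return
        if len(value_tokens) != 20:
            raise FormatError(
                f"{path}: record {accession or '<no accession>'} has "
                f"{len(value_tokens)} value slots, expected 20"
            )
        values = {}
        for aa, tok in zip(AAINDEX_ORDER, value_tokens):
            if tok.upper() == "NA":
                values[aa] = MISSING
            else:
                try:
                    values[aa] = float(tok)
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: record {accession}: bad value {tok!r}"
                    ) from exc
        tables.append(PropertyTable(accession=accession, values=values, title=title))
        accession, title, value_tokens, in_values = "", "", [], False

    for line in path.read_text().splitlines():
        if line.startswith("//"):
            flush()
        elif line.startswith("H "):
            accession = line[2:].strip()
            in_values = False
        elif line.startswith("D "):
            title = line[2:].strip()
            in_values = False
        elif line.startswith("I "):
            in_values = True
        elif in_values and line.startswith(" "):
            value_tokens.extend(line.split())
        elif line[:1].isalpha() and line[1:2] == " ":
            in_values = False
    flush()
    if not tables:
        raise FormatError(f"{path}: no AAindex1 records found")
    return tables


def write_aaindex1(tables: Iterable[PropertyTable], path: str | Path) -> None:
    """Write tables in AAindex1 flat format (used by the synthetic generator)."""
    with open(path, "w") as fh:
        for t in tables:
            fh.write(f"H {t.accession}\n")
            if t.title:
                fh.write(f"D {t.title}\n")
            fh.write("I    A/L     R/K     N/M     D/F     C/P     Q/S     "
                     "E/T     G/W     H/Y     I/V\n")
            vals = [t.values[a] for a in AAINDEX_ORDER]
            for row in (vals[:10], vals[10:]):
                cells = ["NA" if math.isnan(v) else repr(float(v)) for v in row]
                fh.write("  " + "  ".join(cells) + "\n")
            fh.write("//\n")


# ---------------------------------------------------------------------------
# TSV feature matrices


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write a feature matrix as TSV.

    Header row: ``sample_id``, ``label``, then the feature ids.  Floats use
    the shortest round-trip representation so read(write(m)) is exact.
    """
    with open(path, "w") as fh:
        fh.write("sample_id\tlabel\t" + "\t".join(matrix.feature_ids) + "\n")
        for i, sid in enumerate(matrix.sample_ids):
            label = "" if matrix.y is None else str(int(matrix.y[i]))
            row = "\t".join(repr(float(v)) for v in matrix.X[i])
            fh.write(f"{sid}\t{label}\t{row}\n")


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    """Read a TSV feature matrix written by :func:`write_feature_matrix`.

    Labels must be +1/-1 when present; an all-empty label column yields an
    unlabeled matrix.  Ragged rows and duplicate feature ids are errors.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty feature-matrix file")
    header = lines[0].split("\t")
    if len(header) < 3 or header[0] != "sample_id" or header[1] != "label":
        raise FormatError(f"{path}: bad header row")
    feature_ids = header[2:]
    if len(set(feature_ids)) != len(feature_ids):
        raise FormatError(f"{path}: duplicated feature id in header")
    sample_ids, labels, rows = [], [], []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise FormatError(
                f"{path}: row {lineno} has {len(cells)} fields, "
                f"expected {len(header)}"
            )
        sample_ids.append(cells[0])
        labels.append(cells[1])
        rows.append([float(v) for v in cells[2:]])
    has_labels = [lab != "" for lab in labels]
    if any(has_labels) and not all(has_labels):
        raise FormatError(f"{path}: mixture of labeled and unlabeled rows")
    y = None
    if all(has_labels):
        parsed = []
        for lineno, lab in enumerate(labels, start=2):
            if lab not in ("1", "+1", "-1"):
                raise FormatError(
                    f"{path}: row {lineno}: label {lab!r} must be +1 or -1"
                )
            parsed.append(int(lab))
        y = np.array(parsed)
    return FeatureMatrix(
        sample_ids=sample_ids, feature_ids=feature_ids,
        X=np.array(rows, dtype=float), y=y,
    )
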