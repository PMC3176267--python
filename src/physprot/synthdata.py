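"""Synthetic two-class protein sequence sets and property tables.

The generator emulates a binary protein-classification study: class -1
sequences are drawn i.i.d. from a base residue-frequency vector (uniform
over the 20 standard amino acids by default), class +1 from the same
vector with ``n_informative`` residues up-shifted by a total extra
probability mass ``delta`` (split evenly among them) and renormalized.
Because the sequence encoder measures exactly residue composition, the
separability of the two classes in feature space is analytically
controlled by ``delta``: at ``delta=0`` the classes are exchangeable and
any downstream accuracy above chance indicates leakage.

Synthetic property tables draw one standard-normal value per residue with
a configurable fraction of missing entries, exercising the encoder's
missing-value path; a configurable rate of 'X' residues exercises the
non-standard-residue path.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .encoder import encode_dataset
from .io_formats import (
    AAINDEX_ORDER,
    FeatureMatrix,
    PropertyTable,
    SequenceRecord,
)

#: Default training/test design: 300+300 train, 100+100 held out.
DEFAULT_N_POS = 300
DEFAULT_N_NEG = 300


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic two-class dataset."""

    n_pos: int = DEFAULT_N_POS
    n_neg: int = DEFAULT_N_NEG
    length_range: tuple[int, int] = (50, 300)
    n_tables: int = 100
    n_informative: int = 5
    delta: float = 0.3  # total extra mass moved onto informative residues
    seed: int = 0
    base_freqs: tuple[float, ...] | None = None  # default: uniform over 20
    x_rate: float = 0.005  # rate of non-standard 'X' residues
    missing_fraction: float = 0.02  # NA rate in synthetic property tables

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        if self.length_range[0] < 10 or self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range must satisfy 10 <= min <= max")
        if not 0 <= self.n_informative <= 20:
            raise ValueError("n_informative must be in [0, 20]")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if not 0 <= self.x_rate < 1:
            raise ValueError("x_rate must be in [0, 1)")
        if self.base_freqs is not None:
            f = np.asarray(self.base_freqs)
            if f.shape != (20,) or np.any(f < 0) or not np.isclose(f.sum(), 1.0):
                raise ValueError("base_freqs must be a 20-simplex vector")


def class_frequencies(spec: SynthSpec) -> tuple[np.ndarray, np.ndarray]:
    """(negative-class, positive-class) residue frequency vectors.

    The first ``n_informative`` residues of the canonical order carry the
    shift: each gains delta/n_informative before renormalization.
    """
    base = (
        np.full(20, 0.05)
        if spec.base_freqs is None
        else np.asarray(spec.base_freqs, dtype=float)
    )
    pos = base.copy()
    if spec.n_informative > 0 and spec.delta > 0:
        pos[: spec.n_informative] += spec.delta / spec.n_informative
        pos = pos / pos.sum()
    if np.any(pos < 0):
        raise ValueError("shifted frequencies left the simplex")
    return base, pos


def informative_residues(spec: SynthSpec) -> list[str]:
    """Residues whose frequency differs between classes (ground truth)."""
    if spec.delta == 0:
        return []
    return list(AAINDEX_ORDER[: spec.n_informative])


def synth_property_tables(
    n_tables: int, seed: int = 0, missing_fraction: float = 0.02
) -> list[PropertyTable]:
    """Synthetic AAindex1-like tables: standard-normal per-residue values.

    A ``missing_fraction`` of entries are NA (never all 20 of a table);
    accessions are SYN0001, SYN0002, ...  Deterministic per seed.
    """
    if n_tables < 1:
        raise ValueError("n_tables must be >= 1")
    rng = np.random.default_rng(seed)
    tables = []
    for t in range(n_tables):
        vals = rng.standard_normal(20)
        miss = rng.random(20) < missing_fraction
        if miss.all():
            miss[rng.integers(20)] = False
        values = {
            aa: (float("nan") if miss[j] else float(vals[j]))
            for j, aa in enumerate(AAINDEX_ORDER)
        }
        tables.append(
            PropertyTable(
                accession=f"SYN{t + 1:04d}",
                values=values,
                title=f"synthetic property {t + 1}",
            )
        )
    return tables


def synth_sequences(spec: SynthSpec) -> tuple[list[SequenceRecord], np.ndarray]:
    """Generate labeled sequences: n_neg of class -1 then n_pos of class +1.

    Lengths are uniform in ``length_range``; a rate ``x_rate`` of positions
    is replaced by 'X'.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    neg_freqs, pos_freqs = class_frequencies(spec)
    alphabet = np.array(list(AAINDEX_ORDER))
    records: list[SequenceRecord] = []
    labels: list[int] = []

    def draw(n: int, freqs: np.ndarray, label: int, prefix: str) -> None:
        for i in range(n):
            length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
            residues = rng.choice(alphabet, size=length, p=freqs)
            if spec.x_rate > 0:
                mask = rng.random(length) < spec.x_rate
                residues[mask] = "X"
            records.append(
                SequenceRecord(id=f"{prefix}{i + 1:04d}", residues="".join(residues))
            )
            labels.append(label)

    draw(spec.n_neg, neg_freqs, -1, "neg")
    draw(spec.n_pos, pos_freqs, +1, "pos")
    return records, np.array(labels)


def make_benchmark(
    spec: SynthSpec,
    n_test_pos: int = 100,
    n_test_neg: int = 100,
) -> tuple[FeatureMatrix, FeatureMatrix, list[PropertyTable], list[str]]:
    """Train/test feature matrices plus ground-truth informative properties.

    Training sequences follow ``spec``; test sequences are drawn from the
    same class distributions with a derived seed, so sample ids are
    disjoint.  Returns (train, test, tables, informative_accessions) where
    the last list names the synthetic properties whose value differs in
    expectation between classes (those with a non-missing value on at
    least one shifted residue).
    """
    tables = synth_property_tables(
        spec.n_tables, seed=spec.seed, missing_fraction=spec.missing_fraction
    )
    train_records, train_y = synth_sequences(spec)
    test_spec = replace(
        spec, n_pos=n_test_pos, n_neg=n_test_neg, seed=spec.seed + 1_000_003
    )
    test_records, test_y = synth_sequences(test_spec)
    test_records = [
        SequenceRecord(id="t_" + r.id, residues=r.residues) for r in test_records
    ]
    train = encode_dataset(train_records, tables, labels=train_y)
    test = encode_dataset(test_records, tables, labels=test_y)

    shifted = set(informative_residues(spec))
    informative = [
        t.accession
        for t in tables
        if any(aa in shifted and t.values[aa] == t.values[aa] for aa in t.values)
    ]
    return train, test, tables, informative
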