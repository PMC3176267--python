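"""Physicochemical sequence encoding and feature standardization.

Each protein sequence is mapped to a d-dimensional vector whose j-th entry
is the mean value of the j-th amino-acid property over the residues of the
sequence.  Because the encoding is a composition statistic, it is invariant
under residue permutation and bounded by the property's min and max.

Non-standard residues (B, Z, X, U, O, J) and residues whose value is
missing in a table contribute to neither the numerator nor the divisor, so
the encoded value is the unbiased mean over contributing residues.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import (
    AAINDEX_ORDER,
    EncodingError,
    FeatureMatrix,
    PropertyTable,
    SequenceRecord,
)


def _composition_counts(records: Sequence[SequenceRecord]) -> np.ndarray:
    """n x 20 residue counts in canonical AAindex order; others dropped."""
    counts = np.zeros((len(records), 20))
    col = {aa: j for j, aa in enumerate(AAINDEX_ORDER)}
    for i, rec in enumerate(records):
        for aa, c in Counter(rec.residues).items():
            j = col.get(aa)
            if j is not None:
                counts[i, j] = c
    return counts


def encode_sequence(record: SequenceRecord, table: PropertyTable) -> float:
    """Mean property value over the contributing residues of one sequence.

    Raises :class:`EncodingError` when no residue of the sequence has a
    value in the table (all non-standard, or all values missing).
    """
    total = 0.0
    n = 0
    for aa in record.residues:
        v = table.values.get(aa)
        if v is not None and v == v:  # present and not NaN
            total += v
            n += 1
    if n == 0:
        raise EncodingError(
            f"sequence {record.id!r} has no residue with a value in "
            f"property {table.accession!r}"
        )
    return total / n


def encode_dataset(
    records: Sequence[SequenceRecord],
    tables: Sequence[PropertyTable],
    labels: Sequence[int] | None = None,
) -> FeatureMatrix:
    """Encode every sequence under every property table.

    ``X[i, j] == encode_sequence(records[i], tables[j])``; feature ids are
    the table accessions in input order.  Vectorized over the composition
    counts, so it is fast for hundreds of tables.
    """
    if not records:
        raise ValueError("no sequences to encode")
    if not tables:
        raise ValueError("no property tables to encode with")
    counts = _composition_counts(records)  # n x 20
    V = np.stack([t.as_array() for t in tables])  # d x 20, NaN = missing
    valid = np.isfinite(V)
    V0 = np.where(valid, V, 0.0)
    num = counts @ V0.T  # n x d
    den = counts @ valid.T.astype(float)
    bad = np.argwhere(den == 0)
    if bad.size:
        i, j = bad[0]
        raise EncodingError(
            f"sequence {records[i].id!r} (row {i}) has no residue with a "
            f"value in property {tables[j].accession!r} (column {j})"
        )
    y = None if labels is None else np.asarray(labels, dtype=int)
    return FeatureMatrix(
        sample_ids=[r.id for r in records],
        feature_ids=[t.accession for t in tables],
        X=num / den,
        y=y,
    )


@dataclass(frozen=True)
class ScalingParams:
    """Per-feature z-score parameters fitted on training data.

    ``scale`` uses the sample standard deviation (n-1 denominator);
    zero-variance features get scale 1 so transformed columns are all-zero
    and feature indices stay aligned with their accessions.
    """

    feature_ids: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "scale", np.asarray(self.scale, dtype=float))
        d = len(self.feature_ids)
        if self.center.shape != (d,) or self.scale.shape != (d,):
            raise ValueError("center/scale do not align with feature_ids")
        if np.any(self.scale <= 0):
            raise ValueError("scale must be positive for every feature")


def fit_standardizer(matrix: FeatureMatrix) -> ScalingParams:
    """Fit z-score parameters on a training matrix (n >= 2 required)."""
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples to fit a standardizer")
    center = matrix.X.mean(axis=0)
    scale = matrix.X.std(axis=0, ddof=1)
    scale = np.where(scale > 0, scale, 1.0)
    return ScalingParams(
        feature_ids=tuple(matrix.feature_ids), center=center, scale=scale
    )


def apply_standardizer(matrix: FeatureMatrix, params: ScalingParams) -> FeatureMatrix:
    """Apply stored scaling parameters unchanged to any matrix."""
    if tuple(matrix.feature_ids) != params.feature_ids:
        raise ValueError(
            "feature ids of matrix do not match the standardizer's"
        )
    return FeatureMatrix(
        sample_ids=list(matrix.sample_ids),
        feature_ids=list(matrix.feature_ids),
        X=(matrix.X - params.center) / params.scale,
        y=None if matrix.y is None else matrix.y.copy(),
    )
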