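"""Labeled symmetric distance matrices and their TSV serialization."""

from __future__ import annotations

from pathlib import Path

import numpy as np

_SYMMETRY_TOL = 1e-9


class LabeledMatrix:
    """A labeled, symmetric, zero-diagonal matrix of non-negative reals.

    The container used for every pairwise-distance matrix in the pipeline
    (between individuals, population centroids, or summed over autosomes).
    Entries are aligned by label name, never by position, when matrices
    are combined.
    """

    def __init__(self, labels: list[str], values) -> None:
        labels = list(labels)
        values = np.asarray(values, dtype=float)
        if len(set(labels)) != len(labels):
            raise ValueError("matrix labels must be unique")
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("matrix must be square")
        if values.shape[0] != len(labels):
            raise ValueError(
                f"dimension {values.shape[0]} != label count {len(labels)}"
            )
        if not np.allclose(values, values.T, atol=_SYMMETRY_TOL, rtol=0):
            raise ValueError("matrix is not symmetric within 1e-9")
        if np.any(np.diag(values) != 0):
            raise ValueError("matrix diagonal must be exactly zero")
        if np.any(values < 0):
            raise ValueError("matrix entries must be non-negative")
        self.labels = labels
        # store exactly symmetric to avoid drift in downstream algebra
        self.values = (values + values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def reorder(self, labels: list[str]) -> "LabeledMatrix":
        """Return a copy with rows/columns permuted to the given label order."""
        idx = [self.labels.index(l) for l in labels]
        return LabeledMatrix(labels, self.values[np.ix_(idx, idx)])

    def drop(self, labels: set[str] | list[str]) -> "LabeledMatrix":
        """Return a copy without the given labels."""
        drop = set(labels)
        keep = [l for l in self.labels if l not in drop]
        return self.reorder(keep)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LabeledMatrix)
            and self.labels == other.labels
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        return f"LabeledMatrix(n={len(self)}, labels={self.labels[:4]}...)"


def read_matrix(path: str | Path) -> LabeledMatrix:
    """Read a tab-separated labeled matrix (first row/column are labels)."""
    with open(path) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    if len(rows) < 2:
        raise ValueError(f"no matrix data in {path}")
    labels = rows[0][1:]
    values = np.zeros((len(labels), len(labels)))
    for i, row in enumerate(rows[1:]):
        if row[0] != labels[i]:
            raise ValueError(
                f"row label {row[0]!r} does not match column label {labels[i]!r}"
            )
        values[i] = [float(x) for x in row[1:]]
    return LabeledMatrix(labels, values)


def write_matrix(matrix: LabeledMatrix, path: str | Path) -> None:
    """Write a labeled matrix as TSV at 12 significant digits."""
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(matrix.labels) + "\n")
        for label, row in zip(matrix.labels, matrix.values):
            fh.write(label + "\t" + "\t".join(f"{x:.12g}" for x in row) + "\n")
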