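"""Natural Vector (NV) and Divided Natural Vector (DNV) descriptors.

The natural vector maps a DNA sequence of length ``n`` to 12 numbers:
for each nucleotide class k in (A, C, G, T), the count ``n_k``, the mean
position ``mu_k`` (0-based offset from the first residue, regarded as the
origin), and the normalized second central moment

    D2_k = sum_i (s_ki - mu_k)^2 / (n_k * n)

where ``s_ki`` is the offset of the i-th occurrence of k. Counts capture
composition, means capture location, and the D2 terms capture spread; the
resulting point in R^12 identifies the sequence well enough that Euclidean
distance between vectors serves as an alignment-free dissimilarity.

The divided natural vector generalizes this by cutting the sequence into
k contiguous segments and concatenating the 12-dimensional natural
vectors of the segments (12*k numbers, segment-major), trading the purely
global statistic for local composition signal. With k = 1 the DNV is the
plain NV.

Conventions fixed here: offsets are 0-based (a global shift cancels in
every pairwise Euclidean distance, so the choice is immaterial for
trees); ambiguity codes (N etc.) belong to no class but occupy positions
and count toward ``n`` (set ``skip_ambiguous_length=True`` to exclude
them from ``n``); empty classes get mu_k = D2_k = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequences import NucleotideSequence

BASES = "ACGT"

#: column names of the flat 12-vector, in serialization order
NV_COMPONENTS = (
    ["n_" + b for b in BASES]
    + ["mu_" + b for b in BASES]
    + ["D2_" + b for b in BASES]
)


@dataclass(frozen=True)
class NaturalVector:
    """The 12-number natural vector of one sequence.

    Serialization order: (n_A, n_C, n_G, n_T, mu_A..mu_T, D2_A..D2_T).
    ``length`` is the sequence length n, retained as metadata (it is not
    one of the 12 components).
    """

    counts: tuple[float, float, float, float]
    means: tuple[float, float, float, float]
    d2: tuple[float, float, float, float]
    length: int

    def flat(self) -> np.ndarray:
        return np.array(self.counts + self.means + self.d2, dtype=float)


@dataclass(frozen=True)
class DividedNaturalVector:
    """Concatenation of the NVs of k contiguous segments (12*k numbers)."""

    k: int
    segments: tuple[NaturalVector, ...]

    def __post_init__(self) -> None:
        if len(self.segments) != self.k:
            raise ValueError("segment count does not match k")

    def flat(self) -> np.ndarray:
        return np.concatenate([s.flat() for s in self.segments])


def _residue_array(seq: NucleotideSequence | str) -> np.ndarray:
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq.upper()
    if not residues:
        raise ValueError("cannot compute a natural vector of an empty sequence")
    return np.frombuffer(residues.encode("ascii"), dtype=np.uint8)


def natural_vector(
    seq: NucleotideSequence | str, *, skip_ambiguous_length: bool = False
) -> NaturalVector:
    """Compute the 12-dimensional natural vector of a sequence.

    Parameters
    ----------
    seq
        Sequence (or raw residue string, case-insensitive).
    skip_ambiguous_length
        If True, the moment denominator ``n`` counts only unambiguous
        A/C/G/T residues instead of the full length. Offsets are always
        measured on the full sequence either way.
    """
    arr = _residue_array(seq)
    n = len(arr)
    counts, means, d2 = [], [], []
    n_unambig = 0
    positions = {}
    for base in BASES:
        pos = np.flatnonzero(arr == ord(base))
        positions[base] = pos
        n_unambig += len(pos)
    n_eff = n_unambig if skip_ambiguous_length else n
    for base in BASES:
        pos = positions[base]
        nk = len(pos)
        counts.append(float(nk))
        if nk == 0:
            means.append(0.0)
            d2.append(0.0)
        else:
            mu = float(pos.mean())
            means.append(mu)
            d2.append(float(np.sum((pos - mu) ** 2) / (nk * n_eff)))
    return NaturalVector(tuple(counts), tuple(means), tuple(d2), length=n)


def segment_bounds(n: int, k: int) -> list[tuple[int, int]]:
    """Half-open 0-based bounds of k contiguous, balanced segments.

    With n = q*k + r, the first r segments have length q+1 and the rest
    length q, left to right.
    """
    if k < 1:
        raise ValueError(f"segment count k must be >= 1, got {k}")
    if k > n:
        raise ValueError(f"cannot cut a length-{n} sequence into {k} segments")
    q, r = divmod(n, k)
    bounds = []
    start = 0
    for i in range(k):
        length = q + 1 if i < r else q
        bounds.append((start, start + length))
        start += length
    return bounds


def divided_natural_vector(
    seq: NucleotideSequence | str, k: int, *, skip_ambiguous_length: bool = False
) -> DividedNaturalVector:
    """Compute the divided natural vector with k segments.

    Each segment's NV uses offsets local to the segment. For k = 1 the
    flat view equals the plain natural vector of the whole sequence.
    """
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq.upper()
    segs = []
    for start, stop in segment_bounds(len(residues), k):
        segs.append(
            natural_vector(
                residues[start:stop], skip_ambiguous_length=skip_ambiguous_length
            )
        )
    return DividedNaturalVector(k, tuple(segs))


def average_vectors(vectors) -> np.ndarray:
    """Coordinate-wise arithmetic mean of equal-length real vectors."""
    vectors = [np.asarray(v, dtype=float) for v in vectors]
    if not vectors:
        raise ValueError("cannot average an empty list of vectors")
    lengths = {v.shape for v in vectors}
    if len(lengths) > 1 or vectors[0].ndim != 1:
        raise ValueError(f"vectors must be 1-D and equal length, got shapes {lengths}")
    return np.mean(vectors, axis=0)


def euclidean_distance(u, v) -> float:
    """Standard L2 distance between two equal-length real vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"vector length mismatch: {u.shape} vs {v.shape}")
    return float(np.linalg.norm(u - v))
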