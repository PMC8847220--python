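"""Averaging haplotype vectors into personal vectors, personal vectors
into population centroids, and centroids into distance matrices.

Averaging is the load-bearing idea of the pipeline: the two haplotypes of
a diploid chromosome get equal weight (their parental origin is unknown),
a population is represented by the centroid of its members' personal
vectors, and per-chromosome distance matrices are summed into a single
total-autosome matrix — summing rather than averaging changes distances
by a constant factor only, which leaves every distance-tree topology
unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .matrix import LabeledMatrix
from .nv import average_vectors, euclidean_distance

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PersonalVector:
    """One individual's vector for one chromosome: the mean of the two
    haplotype vectors, or the single haplotype's vector for haploid input."""

    sample: str
    chromosome: str
    vector: np.ndarray


@dataclass(frozen=True)
class PopulationCentroid:
    """Mean of a population's personal vectors for one chromosome."""

    population: str
    chromosome: str
    vector: np.ndarray
    member_count: int


def personal_vector(
    hap_vectors: Sequence, sample: str, chromosome: str = ""
) -> PersonalVector:
    """Average one or two haplotype vectors into a personal vector."""
    if len(hap_vectors) not in (1, 2):
        raise ValueError(
            f"expected 1 (haploid) or 2 (diploid) haplotype vectors, "
            f"got {len(hap_vectors)}"
        )
    return PersonalVector(sample, chromosome, average_vectors(hap_vectors))


def population_centroids(
    grouped: Mapping[str, Sequence[PersonalVector]]
) -> list[PopulationCentroid]:
    """One centroid per population from personal vectors grouped by label."""
    centroids = []
    for population, members in grouped.items():
        if not members:
            raise ValueError(f"population {population!r} has no members")
        chroms = {m.chromosome for m in members}
        if len(chroms) > 1:
            raise ValueError(
                f"population {population!r} mixes chromosomes {sorted(chroms)}"
            )
        vec = average_vectors([m.vector for m in members])
        centroids.append(
            PopulationCentroid(population, members[0].chromosome, vec, len(members))
        )
    return centroids


def group_by_population(
    vectors: Iterable[PersonalVector], panel: Mapping[str, str]
) -> dict[str, list[PersonalVector]]:
    """Group personal vectors by the panel's sample -> population mapping.

    Samples absent from the panel are dropped with a warning.
    """
    grouped: dict[str, list[PersonalVector]] = {}
    for pv in vectors:
        pop = panel.get(pv.sample)
        if pop is None:
            logger.warning("sample %s not in panel; dropped", pv.sample)
            continue
        grouped.setdefault(pop, []).append(pv)
    return grouped


def distance_matrix(centroids: Sequence[PopulationCentroid]) -> LabeledMatrix:
    """Pairwise Euclidean distances between population centroids."""
    if len(centroids) < 2:
        raise ValueError("need at least 2 centroids for a distance matrix")
    labels = [c.population for c in centroids]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate population labels in {labels}")
    n = len(centroids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = euclidean_distance(centroids[i].vector, centroids[j].vector)
            values[i, j] = values[j, i] = d
    return LabeledMatrix(labels, values)


def sum_matrices(matrices: Sequence[LabeledMatrix]) -> LabeledMatrix:
    """Entrywise sum of labeled matrices, aligned by label name.

    This is how per-autosome population matrices combine into the total
    autosome matrix; dividing by the matrix count gives the mean, which
    differs only by a constant and yields the same tree topologies.
    """
    if not matrices:
        raise ValueError("cannot sum an empty list of matrices")
    ref_labels = matrices[0].labels
    ref_set = set(ref_labels)
    total = np.zeros_like(matrices[0].values)
    for m in matrices:
        if set(m.labels) != ref_set:
            missing = ref_set ^ set(m.labels)
            raise ValueError(f"matrix label sets differ; symmetric difference {sorted(missing)}")
        total += m.reorder(ref_labels).values
    return LabeledMatrix(ref_labels, total)


def mean_matrix(matrices: Sequence[LabeledMatrix]) -> LabeledMatrix:
    """Entrywise mean of labeled matrices (sum / count)."""
    total = sum_matrices(matrices)
    return LabeledMatrix(total.labels, total.values / len(matrices))


def within_population_mean_distance(members: Sequence[PersonalVector]) -> float:
    """Mean pairwise Euclidean distance among one population's members.

    Larger values reflect higher within-population genomic diversity.
    """
    if len(members) < 2:
        raise ValueError("need at least 2 members for a within-population distance")
    dists = [
        euclidean_distance(a.vector, b.vector) for a, b in combinations(members, 2)
    ]
    return float(np.mean(dists))


def read_panel(path: str | Path) -> dict[str, str]:
    """Read a two-column sample<TAB>population panel file."""
    panel: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"panel line needs 2 columns: {line!r}")
            panel[parts[0]] = parts[1]
    return panel


def write_panel(panel: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, pop in panel.items():
            fh.write(f"{sample}\t{pop}\n")
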