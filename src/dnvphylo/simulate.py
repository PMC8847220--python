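"""Synthetic references, diploid VCF cohorts and population-structured
sequence sets.

Everything downstream of the generator is deterministic, so every
function here takes an explicit integer seed and produces byte-identical
output for a fixed seed (integer RNG draws only; no float-order
dependence in emitted text).

Two generators cover the two input shapes the pipeline accepts:

* ``simulate_vcf_cohort`` — a reference chromosome plus a VCF of phased
  diploid genotypes across populations. Population-private SNPs are
  carried at high frequency (default 0.9) inside the owning population
  and absent elsewhere, so population structure is recoverable from
  reconstructed haplotypes; shared SNPs segregate everywhere at
  intermediate frequency; optional small indels and symbolic structural
  records (``<CN0>`` with SVTYPE) exercise the exclusion path.
* ``simulate_population_sequences`` — sequence cohorts evolved from a
  common ancestor down a known two-level tree (superpopulation →
  population → individual) by random substitutions, with mutation counts
  proportional to branch lengths. The generating topology is returned
  alongside for structure-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequences import NucleotideSequence

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class CohortSpec:
    """Conditions for a synthetic diploid VCF cohort."""

    n_populations: int = 4
    samples_per_population: int = 20
    sequence_length: int = 10_000
    shared_snps: int = 40
    population_private_snps: int = 30
    indel_fraction: float = 0.1
    sv_fraction: float = 0.05
    private_freq: float = 0.9
    shared_freq: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_populations", "samples_per_population", "sequence_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("shared_snps", "population_private_snps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("indel_fraction", "sv_fraction", "private_freq", "shared_freq"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class PopulationTreeSpec:
    """Conditions for hierarchically diverged sequence cohorts.

    ``n_populations`` populations are grouped pairwise into
    superpopulations along a fixed two-level tree. Mutation counts are
    per-branch substitution numbers: every superpopulation ancestor
    differs from the root by ``superpop_mutations`` sites, every
    population ancestor from its superpopulation by ``pop_mutations``,
    and every individual from its population ancestor by
    ``individual_mutations``. Defaults (10 kb; 200/80/25 substitutions,
    i.e. 2%/0.8%/0.25% of sites) give a clear within- < between-
    population divergence hierarchy while keeping all sequences >97%
    identical.
    """

    n_populations: int = 4
    samples_per_population: int = 20
    sequence_length: int = 10_000
    superpop_mutations: int = 200
    pop_mutations: int = 80
    individual_mutations: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 2 or self.n_populations % 2:
            raise ValueError("n_populations must be an even number >= 2")
        if self.samples_per_population < 1:
            raise ValueError("samples_per_population must be >= 1")
        if self.sequence_length < 1:
            raise ValueError("sequence_length must be >= 1")


def simulate_reference(length: int, seed: int) -> NucleotideSequence:
    """Uniform-random A/C/G/T reference sequence, reproducible from seed."""
    if length < 1:
        raise ValueError(f"reference length must be >= 1, got {length}")
    rng = np.random.default_rng(seed)
    arr = _BASES[rng.integers(0, 4, size=length)]
    return NucleotideSequence("ref", arr.tobytes().decode("ascii"))


def _mutate(arr: np.ndarray, n_mut: int, rng: np.random.Generator) -> np.ndarray:
    """Substitute n_mut distinct random positions with a different base."""
    out = arr.copy()
    if n_mut == 0:
        return out
    pos = rng.choice(len(arr), size=min(n_mut, len(arr)), replace=False)
    for p in pos:
        choices = _BASES[_BASES != out[p]]
        out[p] = choices[rng.integers(0, len(choices))]
    return out


def simulate_population_sequences(spec: PopulationTreeSpec):
    """Sequence cohorts diverged along a known two-level population tree.

    Returns ``(sequences, panel, newick)`` where ``sequences`` is a list
    of :class:`NucleotideSequence` (one per sample, identifiers
    ``POP<i>_S<j>``), ``panel`` maps sample to population label
    ``POP<i>``, and ``newick`` is the generating population topology with
    unit-free branch lengths proportional to mutation counts.
    """
    rng = np.random.default_rng(spec.seed)
    ancestor = _BASES[rng.integers(0, 4, size=spec.sequence_length)]
    n_super = spec.n_populations // 2

    sequences: list[NucleotideSequence] = []
    panel: dict[str, str] = {}
    superpop_clades = []
    pop_index = 0
    for s in range(n_super):
        sp_anc = _mutate(ancestor, spec.superpop_mutations, rng)
        members = []
        for _ in range(2):
            pop_index += 1
            pop = f"POP{pop_index}"
            pop_anc = _mutate(sp_anc, spec.pop_mutations, rng)
            for j in range(spec.samples_per_population):
                sample = f"{pop}_S{j + 1}"
                seq = _mutate(pop_anc, spec.individual_mutations, rng)
                sequences.append(
                    NucleotideSequence(sample, seq.tobytes().decode("ascii"))
                )
                panel[sample] = pop
            members.append(f"{pop}:{spec.pop_mutations}")
        superpop_clades.append(
            f"({','.join(members)}):{spec.superpop_mutations}"
        )
    newick = f"({','.join(superpop_clades)});"
    return sequences, panel, newick


def simulate_vcf_cohort(
    reference: NucleotideSequence, spec: CohortSpec
) -> tuple[str, str]:
    """Synthetic phased diploid VCF plus a sample→population panel TSV.

    Variant sites get unique positions. ``sv_fraction`` of the records
    are symbolic structural records (ALT ``<CN0>``, SVTYPE=CNV in INFO)
    that downstream reconstruction must exclude; ``indel_fraction`` of
    the non-SV records are 1–3 bp insertions or deletions; the rest are
    SNPs. Private SNPs segregate at ``private_freq`` inside their
    population only.
    """
    rng = np.random.default_rng(spec.seed)
    n_pop = spec.n_populations
    n_per = spec.samples_per_population
    samples = [
        f"POP{p + 1}_S{j + 1}" for p in range(n_pop) for j in range(n_per)
    ]
    pop_of = {
        s: f"POP{p + 1}" for p in range(n_pop) for j in range(n_per)
        for s in [f"POP{p + 1}_S{j + 1}"]
    }

    n_sites = spec.shared_snps + n_pop * spec.population_private_snps
    n_sv = int(round(spec.sv_fraction * n_sites))
    total = n_sites + n_sv
    # positions on a stride-5 grid: REF alleles span at most 4 bases, so
    # gridded sites can never overlap; headroom at both ends
    grid = np.arange(2, spec.sequence_length - 3, 5)
    if total > len(grid):
        raise ValueError(
            f"{total} variant sites requested but only {len(grid)} positions available"
        )
    positions = np.sort(rng.choice(grid, size=total, replace=False))
    ref = reference.residues

    site_kinds: list[tuple[str, str | None]] = []  # (kind, owner population)
    for _ in range(spec.shared_snps):
        site_kinds.append(("shared", None))
    for p in range(n_pop):
        for _ in range(spec.population_private_snps):
            site_kinds.append(("private", f"POP{p + 1}"))
    for _ in range(n_sv):
        site_kinds.append(("sv", None))
    order = rng.permutation(len(site_kinds))
    site_kinds = [site_kinds[i] for i in order]

    lines = [
        "##fileformat=VCFv4.3",
        "##source=dnvphylo.simulate",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for pos, (kind, owner) in zip(positions, site_kinds):
        pos = int(pos)
        ref_base = ref[pos - 1]
        if kind == "sv":
            alt = "<CN0>"
            info = "SVTYPE=CNV"
            ref_allele = ref_base
            freq_of = {s: 0.2 for s in samples}
        else:
            info = "."
            if rng.random() < spec.indel_fraction:
                if rng.random() < 0.5:  # insertion after pos
                    ins = _BASES[rng.integers(0, 4, size=int(rng.integers(1, 4)))]
                    ref_allele = ref_base
                    alt = ref_base + ins.tobytes().decode("ascii")
                else:  # deletion of 1-3 bases following pos
                    dlen = int(rng.integers(1, 4))
                    ref_allele = ref[pos - 1 : pos + dlen]
                    alt = ref_base
            else:
                ref_allele = ref_base
                others = [b for b in "ACGT" if b != ref_base]
                alt = others[int(rng.integers(0, 3))]
            if kind == "shared":
                freq_of = {s: spec.shared_freq for s in samples}
            else:
                freq_of = {
                    s: (spec.private_freq if pop_of[s] == owner else 0.0)
                    for s in samples
                }
        gts = []
        for s in samples:
            f = freq_of[s]
            a = 1 if rng.random() < f else 0
            b = 1 if rng.random() < f else 0
            gts.append(f"{a}|{b}")
        lines.append(
            f"chrS\t{pos}\t.\t{ref_allele}\t{alt}\t.\tPASS\t{info}\tGT\t"
            + "\t".join(gts)
        )
    vcf_text = "\n".join(lines) + "\n"
    panel_text = "".join(f"{s}\t{pop_of[s]}\n" for s in samples)
    return vcf_text, panel_text
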