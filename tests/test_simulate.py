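"""Synthetic data generators: determinism, planted-signal fidelity."""

import numpy as np
import pytest

from dnvphylo import (
    CohortSpec,
    PopulationTreeSpec,
    distance_matrix,
    divided_natural_vector,
    euclidean_distance,
    group_by_population,
    is_structural,
    natural_vector,
    personal_vector,
    population_centroids,
    read_vcf,
    reconstruct_cohort,
    simulate_population_sequences,
    simulate_reference,
    simulate_vcf_cohort,
)


class TestReference:
    def test_seeded_determinism(self):
        a = simulate_reference(100, seed=7)
        b = simulate_reference(100, seed=7)
        assert a.residues == b.residues
        assert a.residues != simulate_reference(100, seed=8).residues

    def test_base_composition_near_uniform(self):
        seq = simulate_reference(100_000, seed=1).residues
        for base in "ACGT":
            assert seq.count(base) / len(seq) == pytest.approx(0.25, abs=0.01)

    def test_length_one_and_invalid(self):
        assert len(simulate_reference(1, seed=0)) == 1
        with pytest.raises(ValueError):
            simulate_reference(0, seed=0)


class TestVcfCohort:
    SPEC = CohortSpec(
        n_populations=2, samples_per_population=6, sequence_length=2_000,
        shared_snps=10, population_private_snps=8, indel_fraction=0.2,
        sv_fraction=0.1, seed=3,
    )

    def _build(self, tmp_path, spec=None):
        spec = spec or self.SPEC
        ref = simulate_reference(spec.sequence_length, spec.seed)
        vcf_text, panel_text = simulate_vcf_cohort(ref, spec)
        p = tmp_path / "c.vcf"
        p.write_text(vcf_text)
        return ref, read_vcf(p), panel_text

    def test_byte_identical_under_fixed_seed(self, tmp_path):
        ref = simulate_reference(2_000, 3)
        assert simulate_vcf_cohort(ref, self.SPEC) == simulate_vcf_cohort(ref, self.SPEC)

    def test_parses_and_positions_unique_sorted(self, tmp_path):
        _, records, _ = self._build(tmp_path)
        positions = [r.pos for r in records]
        assert positions == sorted(positions)
        assert len(set(positions)) == len(positions)

    def test_sv_fraction_zero_means_no_structural_records(self, tmp_path):
        spec = CohortSpec(
            n_populations=2, samples_per_population=4, sequence_length=2_000,
            shared_snps=10, population_private_snps=5, sv_fraction=0.0, seed=1,
        )
        _, records, _ = self._build(tmp_path, spec)
        assert not any(is_structural(r) for r in records)

    def test_round_trip_hamming_matches_planted_snps(self, tmp_path):
        # substitutions only: each haplotype's Hamming distance to the
        # reference equals its count of non-reference SNP alleles
        spec = CohortSpec(
            n_populations=2, samples_per_population=4, sequence_length=2_000,
            shared_snps=12, population_private_snps=6, indel_fraction=0.0,
            sv_fraction=0.0, seed=9,
        )
        ref, records, _ = self._build(tmp_path, spec)
        samples = sorted(records[0].genotypes)
        pairs = reconstruct_cohort(ref, records, samples)
        for pair in pairs:
            for hap_index, hap in ((0, pair.hap_a), (1, pair.hap_b)):
                planted = sum(
                    1
                    for r in records
                    if (r.genotypes[pair.sample][hap_index] or 0) > 0
                )
                hamming = sum(
                    a != b for a, b in zip(ref.residues, hap.residues)
                )
                assert hamming == planted

    def test_no_private_snps_no_population_signal(self, tmp_path):
        null = CohortSpec(
            n_populations=2, samples_per_population=30, sequence_length=4_000,
            shared_snps=30, population_private_snps=0, indel_fraction=0.0,
            sv_fraction=0.0, seed=5,
        )
        structured = CohortSpec(
            n_populations=2, samples_per_population=30, sequence_length=4_000,
            shared_snps=30, population_private_snps=30, indel_fraction=0.0,
            sv_fraction=0.0, seed=5,
        )
        gaps = []
        for spec in (null, structured):
            ref, records, panel_text = self._build(tmp_path, spec)
            panel = dict(
                line.split("\t") for line in panel_text.strip().split("\n")
            )
            pairs = reconstruct_cohort(ref, records, sorted(records[0].genotypes))
            pvs = [
                personal_vector(
                    [natural_vector(p.hap_a).flat(), natural_vector(p.hap_b).flat()],
                    p.sample,
                )
                for p in pairs
            ]
            cents = population_centroids(group_by_population(pvs, panel))
            gaps.append(euclidean_distance(cents[0].vector, cents[1].vector))
        assert gaps[0] < gaps[1] / 5  # null gap is noise, structured is signal


class TestPopulationSequences:
    SPEC = PopulationTreeSpec(
        n_populations=4, samples_per_population=5, sequence_length=2_000,
        superpop_mutations=60, pop_mutations=25, individual_mutations=8, seed=2,
    )

    def test_deterministic_and_labeled(self):
        seqs1, panel1, nwk1 = simulate_population_sequences(self.SPEC)
        seqs2, panel2, nwk2 = simulate_population_sequences(self.SPEC)
        assert [s.residues for s in seqs1] == [s.residues for s in seqs2]
        assert panel1 == panel2 and nwk1 == nwk2
        assert len(seqs1) == 20 and len(set(panel1.values())) == 4

    def test_zero_mutations_identical_sequences(self):
        spec = PopulationTreeSpec(
            n_populations=2, samples_per_population=3, sequence_length=500,
            superpop_mutations=0, pop_mutations=0, individual_mutations=0, seed=0,
        )
        seqs, _, _ = simulate_population_sequences(spec)
        assert len({s.residues for s in seqs}) == 1

    def test_within_population_divergence_below_between(self):
        seqs, panel, _ = simulate_population_sequences(self.SPEC)
        by_pop = {}
        for s in seqs:
            by_pop.setdefault(panel[s.identifier], []).append(s.residues)

        def ham(a, b):
            return sum(x != y for x, y in zip(a, b))

        within = np.mean([
            ham(m[0], m[1]) for m in by_pop.values()
        ])
        pops = sorted(by_pop)
        between = np.mean([
            ham(by_pop[pops[0]][0], by_pop[p][0]) for p in pops[1:]
        ])
        assert within < between

    def test_deeper_split_gives_larger_centroid_distance(self):
        gaps = []
        for pop_mut in (10, 40, 120):
            # two populations share one superpopulation ancestor, so their
            # divergence is governed by the population-branch mutation count
            spec = PopulationTreeSpec(
                n_populations=2, samples_per_population=8, sequence_length=2_000,
                superpop_mutations=30, pop_mutations=pop_mut,
                individual_mutations=5, seed=4,
            )
            seqs, panel, _ = simulate_population_sequences(spec)
            pvs = [
                personal_vector([divided_natural_vector(s, 4).flat()], s.identifier)
                for s in seqs
            ]
            cents = sorted(
                population_centroids(group_by_population(pvs, panel)),
                key=lambda c: c.population,
            )
            m = distance_matrix(cents)
            gaps.append(m[("POP1", "POP2")])
        assert gaps[0] < gaps[1] < gaps[2]
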