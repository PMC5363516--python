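"""Generator behavior: divergence model, contamination labels, the binomial
purity count model, artifact realization and determinism."""

import math

import numpy as np
import pytest

from xenosift import (
    ConfigurationError,
    SimulationConfig,
    generate_dual_reference,
    simulate_cohort,
    simulate_pileups,
    simulate_sample_reads,
)
from xenosift.somatic_filters import homopolymer_run_length
from xenosift.synthetic_data import score_read


def _mismatch_fraction(a: str, b: str) -> float:
    return sum(x != y for x, y in zip(a, b)) / len(a)


class TestDualReference:
    def test_zero_divergence_gives_identical_sequences(self):
        refs = generate_dual_reference(1000, 0.0, seed=3)
        assert refs.human == refs.mouse

    def test_divergence_fraction_within_binomial_noise(self):
        refs = generate_dual_reference(10_000, 0.15, seed=7)
        obs = _mismatch_fraction(refs.human, refs.mouse)
        sd = math.sqrt(0.15 * 0.85 / 10_000)
        assert abs(obs - 0.15) < 3 * sd

    def test_full_divergence_forces_every_substitution(self):
        refs = generate_dual_reference(10_000, 1.0, seed=5)
        assert _mismatch_fraction(refs.human, refs.mouse) == 1.0

    def test_non_positive_length_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_dual_reference(0, 0.1, seed=1)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"species_divergence": 1.5},
            {"contamination_fraction": -0.1},
            {"purity_primary": 2.0},
            {"genome_length": 500, "read_length": 100},
            {"read_length": 30_000},
            {"n_common": -1},
            {"artifact_spec": {"nonsense_class": 3}},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(seed=0, **kwargs)


class TestDeterminism:
    def test_identical_seed_reproduces_everything(self):
        config = SimulationConfig(
            seed=9, n_common=20, depth=50.0,
            artifact_spec={"strand_bias": 3, "homopolymer_indel": 2},
        )
        runs = []
        for _ in range(2):
            refs, truth = simulate_cohort(config)
            pileups = simulate_pileups(truth, config)
            reads, labels = simulate_sample_reads(refs, truth, config, "pdx")
            runs.append((refs.human, refs.mouse, truth.mutations,
                         [(r.read_id, r.start, r.sequence) for r in reads],
                         labels))
        assert runs[0] == runs[1]


class TestReadSimulation:
    def test_zero_contamination_labels_all_human(self):
        config = SimulationConfig(seed=2, contamination_fraction=0.0,
                                  depth=20.0, n_common=5)
        refs, truth = simulate_cohort(config)
        _, labels = simulate_sample_reads(refs, truth, config, "pdx")
        assert set(labels.values()) == {"human"}

    def test_contamination_fraction_recovered_in_labels(self):
        config = SimulationConfig(
            seed=4, contamination_fraction=0.10, genome_length=100_000,
            depth=20.0, n_common=5,
        )
        refs, truth = simulate_cohort(config)
        _, labels = simulate_sample_reads(refs, truth, config, "pdx")
        n = len(labels)
        assert n == 20_000
        frac = sum(v == "mouse" for v in labels.values()) / n
        sd = math.sqrt(0.10 * 0.90 / n)
        assert abs(frac - 0.10) < 3 * sd

    def test_truth_conservation_of_read_labels(self):
        config = SimulationConfig(seed=6, depth=15.0, n_common=5)
        refs, truth = simulate_cohort(config)
        reads, labels = simulate_sample_reads(refs, truth, config, "pdx")
        assert len(reads) == len(labels)
        assert {r.read_id for r in reads} == set(labels)

    def test_error_free_human_reads_score_higher_on_human(self):
        config = SimulationConfig(
            seed=8, error_rate=0.0, species_divergence=0.15,
            contamination_fraction=0.3, depth=10.0, n_common=0,
        )
        refs, truth = simulate_cohort(config)
        reads, _ = simulate_sample_reads(refs, truth, config, "pdx")
        for read in reads:
            s_h, s_m = score_read(read, refs)
            if read.species == "human":
                assert s_h > s_m
            else:
                assert s_m > s_h


class TestPileupModel:
    def test_purity_zero_yields_no_somatic_alt_reads(self):
        config = SimulationConfig(
            seed=10, purity_primary=0.0, purity_pdx=0.0, n_common=50,
            depth=100.0,
        )
        refs, truth = simulate_cohort(config)
        pileups = simulate_pileups(truth, config)
        for sample in ("primary", "pdx", "normal"):
            for m in truth.mutations:
                site = pileups[sample][(m.contig, m.position)]
                assert site.allele_count(m.alt) == 0

    def test_normal_sample_carries_no_somatic_alt(self, deep_cohort):
        _, _, truth, pileups = deep_cohort
        for m in truth.true_mutations():
            assert pileups["normal"][(m.contig, m.position)].allele_count(m.alt) == 0

    def test_hom_mean_alt_fraction_matches_purity(self):
        config = SimulationConfig(
            seed=12, hom_fraction=1.0, purity_primary=0.4, n_common=300,
            n_primary_only=0, n_pdx_only=0, depth=200.0,
        )
        refs, truth = simulate_cohort(config)
        pileups = simulate_pileups(truth, config)
        fracs = []
        for m in truth.mutations:
            site = pileups["primary"][(m.contig, m.position)]
            fracs.append(site.allele_count(m.alt) / site.coverage)
        mean = np.mean(fracs)
        sd = math.sqrt(0.4 * 0.6 / 200) / math.sqrt(len(fracs))
        assert abs(mean - 0.4) < 3 * sd

    def test_artifact_classes_realized_with_their_signatures(self):
        config = SimulationConfig(
            seed=14, n_common=10, depth=150.0,
            artifact_spec={
                "germline_leak": 5, "strand_bias": 5, "low_bq": 5,
                "low_mq": 5, "homopolymer_indel": 3,
            },
        )
        refs, truth = simulate_cohort(config)
        pileups = simulate_pileups(truth, config)
        for m in truth.artifacts("germline_leak"):
            assert pileups["normal"][(m.contig, m.position)].allele_count(m.alt) > 0
        for m in truth.artifacts("strand_bias"):
            obs = pileups["primary"][(m.contig, m.position)].obs(m.alt)
            assert obs.count > 0 and (obs.fwd == 0 or obs.rev == 0)
        for m in truth.artifacts("low_bq"):
            obs = pileups["primary"][(m.contig, m.position)].obs(m.alt)
            assert obs.base_qualities and max(obs.base_qualities) < 20
        for m in truth.artifacts("low_mq"):
            obs = pileups["primary"][(m.contig, m.position)].obs(m.alt)
            assert obs.mapping_qualities and max(obs.mapping_qualities) < 10
        for m in truth.artifacts("homopolymer_indel"):
            assert m.is_indel
            run = homopolymer_run_length(refs.human, m.position)  # first deleted base
            assert run >= 8

    def test_mutation_ledger_positions_unique_and_in_bounds(self, deep_cohort):
        config, refs, truth, _ = deep_cohort
        positions = [(m.contig, m.position) for m in truth.mutations]
        assert len(positions) == len(set(positions))
        for m in truth.mutations:
            assert 1 <= m.position <= len(refs.human)
            assert m.sharing in ("common", "primary_only", "pdx_only")
            assert m.zygosity in ("het", "hom")
            if not m.is_indel:
                assert refs.human[m.position - 1] == m.ref
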