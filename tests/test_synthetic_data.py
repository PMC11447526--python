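"""Ground-truth correctness of the satellite array / karyotype / read
generators."""

import numpy as np
import pytest

from cenbarcode.repeatio import write_fasta, write_fastq
from cenbarcode.synthetic_data import (
    ChromosomeSpec,
    ReadSimConfig,
    SimulationConfig,
    build_hor_array,
    build_karyotype,
    default_karyotype_specs,
    draw_consensus,
    simulate_qpcr_counts,
    simulate_reads,
)


class TestDrawConsensus:
    def test_deterministic_and_correct_length(self):
        a = draw_consensus(92, seed=1)
        assert len(a) == 92
        assert a == draw_consensus(92, seed=1)
        assert a != draw_consensus(92, seed=2)

    def test_boundary_length(self):
        assert len(draw_consensus(10, seed=2)) == 10

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            draw_consensus(9, seed=1)


class TestBuildHorArray:
    def test_zero_noise_concatenation(self):
        config = SimulationConfig(
            monomer_length=10, n_copies=3, sub_rate=0, variant_divergence=0, seed=1
        )
        seq, truth = build_hor_array(config, consensus="ACGTACGTAC")
        assert seq == "ACGTACGTAC" * 3
        assert [(r.start, r.end) for r in truth.records] == [(0, 10), (10, 20), (20, 30)]

    def test_empirical_substitution_rate(self, cons4):
        config = SimulationConfig(
            n_copies=100, sub_rate=0.05, hor_pattern=("A", "B"), seed=3
        )
        seq, truth = build_hor_array(config, consensus=cons4)
        # recompute each copy's mismatch rate against its variant template
        rng = np.random.default_rng(3)
        from cenbarcode.synthetic_data import make_variants

        variants = make_variants(cons4, ("A", "B"), 0.08, rng)
        mismatches = total = 0
        for rec in truth.records:
            template = variants[rec.label]
            copy = seq[rec.start : rec.end]
            assert len(copy) == len(template)
            mismatches += sum(a != b for a, b in zip(copy, template))
            total += len(copy)
        assert abs(mismatches / total - 0.05) < 0.01

    def test_truncated_copy_has_exact_prefix_length(self, cons4):
        config = SimulationConfig(
            n_copies=20,
            sub_rate=0,
            variant_divergence=0,
            truncation_fractions=(209 / 413,),
            truncation_count=1,
            seed=5,
        )
        _, truth = build_hor_array(config, consensus=cons4)
        truncated = [r for r in truth.records if r.truncated]
        assert len(truncated) == 1
        assert truncated[0].length == 209

    def test_records_sorted_nonoverlapping(self, noisy_array):
        _, truth = noisy_array
        starts = [r.start for r in truth.records]
        assert starts == sorted(starts)
        for a, b in zip(truth.records, truth.records[1:]):
            assert a.end == b.start

    def test_truncation_count_exceeding_copies_rejected(self):
        with pytest.raises(ValueError, match="truncation_count"):
            SimulationConfig(
                n_copies=2, truncation_count=3, truncation_fractions=(0.5,)
            )

    def test_hor_pattern_length_bounds(self):
        with pytest.raises(ValueError, match="hor_pattern"):
            SimulationConfig(hor_pattern=tuple("ABCDEF"))

    def test_same_seed_byte_identical(self, cons4, tmp_path):
        config = SimulationConfig(n_copies=10, seed=11)
        out = []
        for name in ("a.fa", "b.fa"):
            seq, _ = build_hor_array(config, consensus=cons4)
            from cenbarcode.repeatio import SeqRecord

            write_fasta([SeqRecord("x", seq)], tmp_path / name)
            out.append((tmp_path / name).read_bytes())
        assert out[0] == out[1]


class TestKaryotype:
    def test_two_chromosome_construction(self, consensus):
        specs = [
            ChromosomeSpec(name="c1", segments=(("A",),), n_copies=(12,)),
            ChromosomeSpec(name="c2", segments=(("A", "B"),), n_copies=(12,)),
        ]
        records, truth = build_karyotype(specs, consensus_by_family=consensus, seed=1)
        assert [r.id for r in records] == ["c1", "c2"]
        labels_c2 = {r.label for r in truth.for_chromosome("c2")}
        assert labels_c2 == {"A", "B"}
        assert {r.label for r in truth.for_chromosome("c1")} == {"A"}

    def test_default_karyotype_has_twenty_chromosomes(self):
        specs = default_karyotype_specs()
        assert len(specs) == 20
        classes = [s.hor_classes for s in specs]
        flat = [k for cls in classes for k in cls]
        # monomer most common, single pentamer, one two-variant chromosome
        assert flat.count(1) > flat.count(2) > flat.count(3) > flat.count(4)
        assert flat.count(5) == 1
        assert sum(len(c) == 2 for c in classes) == 1

    def test_flanks_surround_array(self, consensus):
        specs = [ChromosomeSpec(name="c1", segments=(("A",),), n_copies=(10,))]
        records, truth = build_karyotype(specs, consensus_by_family=consensus, seed=2)
        first = truth.records[0]
        last = truth.records[-1]
        assert first.start > 0
        assert last.end < len(records[0].sequence)

    def test_empty_karyotype_rejected(self):
        with pytest.raises(ValueError):
            build_karyotype([])

    def test_missing_family_consensus_rejected(self):
        specs = [ChromosomeSpec(name="c1", family="NoSuch")]
        with pytest.raises(ValueError, match="NoSuch"):
            build_karyotype(specs, consensus_by_family={"CentGm-4": "A" * 413})


@pytest.fixture(scope="module")
def small_genome(consensus):
    specs = [ChromosomeSpec(name="c1", segments=(("A",),), n_copies=(20,))]
    return build_karyotype(
        specs, consensus_by_family=consensus, flank_length=30000, seed=4
    )


class TestSimulateReads:
    def test_pair_count_and_length(self, small_genome):
        records, truth = small_genome
        r1, r2 = simulate_reads(
            records, truth, ReadSimConfig(n_pairs=10, seed=1), "input"
        )
        assert len(r1) == len(r2) == 10
        assert all(len(r.sequence) == 300 for r in r1 + r2)

    def test_null_enrichment_matches_input(self, small_genome):
        records, truth = small_genome
        cfg = ReadSimConfig(n_pairs=4000, enrichment=1.0, seed=7)
        chip_r1, _ = simulate_reads(records, truth, cfg, "chip")
        input_r1, _ = simulate_reads(
            records, truth, ReadSimConfig(n_pairs=4000, seed=8), "input"
        )

        def repeat_fraction(reads):
            return np.mean([r.id.split("rep=")[1][0] == "1" for r in reads])

        f_chip = repeat_fraction(chip_r1)
        f_input = repeat_fraction(input_r1)
        f = sum(r.length for r in truth.records) / sum(
            len(r.sequence) for r in records
        )
        se = np.sqrt(f * (1 - f) / 4000)
        assert abs(f_chip - f) < 3 * se
        assert abs(f_input - f) < 3 * se

    def test_weighted_sampling_expectation(self, small_genome):
        records, truth = small_genome
        rho = 8.0
        n = 50_000
        r1, _ = simulate_reads(
            records, truth, ReadSimConfig(n_pairs=n, enrichment=rho, seed=9), "chip"
        )
        observed = np.mean([r.id.split("rep=")[1][0] == "1" for r in r1])
        f = sum(r.length for r in truth.records) / sum(
            len(r.sequence) for r in records
        )
        expected = rho * f / (rho * f + (1 - f))
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 3 * se

    def test_same_seed_identical_fastq_bytes(self, small_genome, tmp_path):
        records, truth = small_genome
        cfg = ReadSimConfig(n_pairs=50, enrichment=2.0, seed=5)
        for name in ("a.fastq", "b.fastq"):
            r1, _ = simulate_reads(records, truth, cfg, "chip")
            write_fastq(r1, tmp_path / name)
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            ReadSimConfig(enrichment=0.0)

    def test_read_length_default_is_miseq_300(self):
        assert ReadSimConfig(n_pairs=1).read_length == 300


class TestQpcrCounts:
    def test_re_centered_on_configured_fold(self):
        df = simulate_qpcr_counts({"t": 7.3, "ctl": 1.0}, n_replicates=50, seed=1)
        sub = df[df["target"] == "t"]
        re = sub["antibody"] / sub["mock"]
        assert 6.5 < re.mean() < 8.1

    def test_invalid_fold_rejected(self):
        with pytest.raises(ValueError):
            simulate_qpcr_counts({"t": 0.0})
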