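import numpy as np
import pytest

from nrsmeta import (
    SimConfig,
    apply_deamination,
    apply_sequencing_errors,
    build_benchmark,
    fragment_reads,
    simulate_genomes,
)
from nrsmeta.adna_sim import read_truth_tsv, simulate_sample
from nrsmeta.seqio import SequenceRecord

from .conftest import record


class TestSimulateGenomes:
    def test_zero_genomes(self):
        assert simulate_genomes(0, 100, seed=1) == []

    def test_same_seed_identical(self):
        a = simulate_genomes(2, 500, seed=9)
        b = simulate_genomes(2, 500, seed=9)
        for x, y in zip(a, b):
            assert x.id == y.id and np.array_equal(x.symbols, y.symbols)

    def test_base_frequencies_near_uniform(self):
        (g,) = simulate_genomes(1, 100_000, seed=2)
        n = g.length
        sigma = np.sqrt(n * 0.25 * 0.75)
        for s in range(4):
            count = int((g.symbols == s).sum())
            assert abs(count - n * 0.25) < 4 * sigma


class TestFragmentReads:
    def test_read_count_formula(self):
        (g,) = simulate_genomes(1, 10_000, seed=3)
        reads, truth = fragment_reads(g, 100, 10.0, rng=3)
        assert len(reads) == 1000
        assert len(truth) == 1000

    def test_reads_are_exact_substrings_before_damage(self):
        (g,) = simulate_genomes(1, 2000, seed=4)
        reads, truth = fragment_reads(g, 60, 2.0, rng=4)
        for read, row in zip(reads, truth):
            frag = g.symbols[row.position : row.position + 60]
            if row.strand == "-":
                frag = (3 - frag[::-1]).astype(np.int8)
            assert np.array_equal(read.symbols, frag)

    def test_read_longer_than_genome_rejected(self):
        (g,) = simulate_genomes(1, 50, seed=5)
        with pytest.raises(ValueError):
            fragment_reads(g, 100, 1.0, rng=5)

    def test_single_read_case(self):
        (g,) = simulate_genomes(1, 100, seed=6)
        reads, _ = fragment_reads(g, 100, 1.0, rng=6)
        assert len(reads) == 1


class TestDeamination:
    def test_rate_zero_is_identity(self):
        read = record("CCGGCCGG")
        out, n = apply_deamination(read, 0.0, 3.0, rng=1)
        assert np.array_equal(out.symbols, read.symbols) and n == 0

    def test_certain_damage_with_infinite_halflife(self):
        out, n = apply_deamination(record("CCCC"), 1.0, np.inf, rng=1)
        assert out.sequence == "TTTT" and n == 4

    def test_three_prime_g_to_a(self):
        out, _ = apply_deamination(record("GGGG"), 1.0, np.inf, rng=1)
        assert out.sequence == "AAAA"

    def test_terminal_rate_calibration(self):
        # terminal (position 0) C->T probability is exactly d; binomial check
        d = 0.2
        rng = np.random.default_rng(777)
        n_terminal_c = 0
        n_converted = 0
        read_template = record("C" + "A" * 39)
        for _ in range(2500):
            out, _ = apply_deamination(read_template, d, 3.0, rng)
            n_terminal_c += 1
            if out.symbols[0] == 3:
                n_converted += 1
        sigma = np.sqrt(n_terminal_c * d * (1 - d))
        assert abs(n_converted - d * n_terminal_c) < 4 * sigma

    def test_decay_reduces_interior_damage(self):
        rng = np.random.default_rng(55)
        hits = np.zeros(40)
        for _ in range(2000):
            out, _ = apply_deamination(record("C" * 40), 0.3, 3.0, rng)
            hits += out.symbols == 3
        assert hits[0] > hits[10] > hits[19] - 50  # monotone-ish terminal bias
        assert hits[19] < hits[0] / 4


class TestSequencingErrors:
    def test_rate_zero_identity(self):
        read = record("ACGTACGT")
        out, n = apply_sequencing_errors(read, 0.0, rng=1)
        assert np.array_equal(out.symbols, read.symbols) and n == 0

    def test_substituted_base_always_differs(self):
        rng = np.random.default_rng(12)
        read = record("A" * 200)
        out, n = apply_sequencing_errors(read, 0.5, rng)
        changed = out.symbols != read.symbols
        assert int(changed.sum()) == n
        assert n > 0

    def test_empirical_rate_calibration(self):
        rng = np.random.default_rng(13)
        read = record("A" * 100_000)
        out, n = apply_sequencing_errors(read, 0.01, rng)
        sigma = np.sqrt(100_000 * 0.01 * 0.99)
        assert abs(n - 1000) < 4 * sigma


class TestBenchmark:
    def test_grid_cell_counts(self, tmp_path):
        refs = simulate_genomes(1, 400, seed=8)
        manifest = build_benchmark(
            refs, [], read_lengths=[20, 40], deamination_rates=[0.0, 0.1],
            depths=[1.0], out_dir=tmp_path, base_config=SimConfig(seed=8),
        )
        assert len(manifest) == 2 * 2 * 1
        assert (tmp_path / "manifest.tsv").exists()

    def test_factorial_design_size(self, tmp_path):
        # the full study grid: 5 lengths x 4 rates x 6 depths = 120 cells
        refs = simulate_genomes(1, 150, seed=8)
        manifest = build_benchmark(
            refs, [],
            read_lengths=[20, 40, 60, 80, 100],
            deamination_rates=[0.0, 0.1, 0.2, 0.3],
            depths=[0.2, 0.25, 0.3, 0.35, 0.4, 0.45],
            out_dir=tmp_path / "grid",
            base_config=SimConfig(seed=8),
        )
        assert len(manifest) == 120

    def test_truth_conservation(self, tmp_path):
        refs = simulate_genomes(2, 600, seed=9)
        manifest = build_benchmark(
            refs, [], [30], [0.1], [2.0], tmp_path, SimConfig(seed=9),
        )
        cell = manifest[0]
        truth = read_truth_tsv(cell["truth"])
        from nrsmeta import read_records

        reads = list(read_records(cell["reads"]))
        assert len(reads) == cell["n_reads"] == len(truth)
        assert {r.id for r in reads} == set(truth)

    def test_byte_determinism_under_fixed_seed(self, tmp_path):
        refs = simulate_genomes(1, 500, seed=10)
        for sub in ("a", "b"):
            build_benchmark(
                refs, [], [40], [0.2], [3.0], tmp_path / sub, SimConfig(seed=10),
            )
        for name in ("cell_L40_d0.2_x3.fq", "cell_L40_d0.2_x3.truth.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_undamaged_reads_map_back_exactly(self):
        refs = simulate_genomes(2, 800, seed=11)
        cfg = SimConfig(read_length=50, depth=1.0, deamination_rate=0.0,
                        error_rate=0.0, seed=11)
        reads, truth = simulate_sample(refs, [], cfg)
        by_id = {g.id: g for g in refs}
        for read, row in zip(reads, truth):
            g = by_id[row.source_label]
            frag = g.symbols[row.position : row.position + 50]
            if row.strand == "-":
                frag = (3 - frag[::-1]).astype(np.int8)
            assert np.array_equal(read.symbols, frag)

    def test_contaminant_reads_labeled_in_truth(self):
        refs = simulate_genomes(1, 1000, seed=12)
        contam = [SequenceRecord("ecoli", "", simulate_genomes(1, 1000, seed=99)[0].symbols)]
        cfg = SimConfig(read_length=50, depth=2.0, contaminant_fraction=0.5, seed=12)
        reads, truth = simulate_sample(refs, contam, cfg)
        labels = {t.source_label for t in truth}
        assert labels == {"genome_1", "ecoli"}
        n_contam = sum(1 for t in truth if t.source_label == "ecoli")
        assert n_contam == pytest.approx(len(truth) / 2, rel=0.1)

    def test_empty_grid_rejected(self, tmp_path):
        refs = simulate_genomes(1, 100, seed=1)
        with pytest.raises(ValueError):
            build_benchmark(refs, [], [], [0.0], [1.0], tmp_path)


class TestSimConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"deamination_rate": 1.5},
            {"error_rate": -0.1},
            {"depth": 0},
            {"read_length": 0},
            {"decay_halflife": 0},
        ],
    )
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)
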