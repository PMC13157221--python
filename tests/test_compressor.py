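import numpy as np
import pytest
from hypothesis import given, strategies as st

from nrsmeta import (
    FCMConfig,
    MixtureConfig,
    STMMConfig,
    build_bundle,
    default_mixture,
    relative_code_length,
    simulate_genomes,
)
from nrsmeta.compressor import (
    mixture_for_level,
    mixture_from_dict,
    mixture_to_dict,
    parameter_digest,
    relative_code_lengths,
    update_weights,
    mixture_probability,
)

from .conftest import record
from .oracle import oracle_code_length, oracle_train


class TestMixtureConfig:
    def test_needs_models_and_valid_gamma(self):
        with pytest.raises(ValueError):
            MixtureConfig(models=())
        with pytest.raises(ValueError):
            MixtureConfig(models=(FCMConfig(order=2),), gamma=1.0)

    def test_stmm_must_share_an_fcm_of_equal_order(self):
        with pytest.raises(ValueError):
            MixtureConfig(
                models=(FCMConfig(order=2),
                        STMMConfig(order=3, share_counts_with=0))
            )
        with pytest.raises(ValueError):
            MixtureConfig(
                models=(STMMConfig(order=2, share_counts_with=0),)
            )

    def test_roundtrip_through_dict_preserves_digest(self):
        cfg = default_mixture()
        again = mixture_from_dict(mixture_to_dict(cfg))
        assert parameter_digest(again) == parameter_digest(cfg)
        assert again == cfg

    def test_level_table(self, tmp_path):
        assert mixture_for_level(47) == mixture_for_level(3)
        assert len(mixture_for_level(1).models) == 1
        with pytest.raises(ValueError):
            mixture_for_level(999)
        table = tmp_path / "levels.json"
        table.write_text(
            '{"999": {"gamma": 0.9, "models": [{"type": "fcm", "order": 2}]}}'
        )
        custom = mixture_for_level(999, str(table))
        assert custom.gamma == 0.9 and custom.models[0].order == 2


class TestBuildBundle:
    def test_empty_reference_rejected(self, small_mixture):
        with pytest.raises(ValueError):
            build_bundle([], small_mixture)

    def test_counts_delegate_to_train_fcm(self, small_mixture):
        from nrsmeta import train_fcm

        rec = record("ACGTACGTGGTT")
        bundle = build_bundle([rec], small_mixture)
        direct = train_fcm(small_mixture.models[0], [rec])
        assert bundle.counts[0].table == direct.table

    def test_provenance_hash_deterministic(self, small_mixture):
        rec = record("ACGTACGT")
        b1 = build_bundle([rec], small_mixture)
        b2 = build_bundle([rec], small_mixture)
        assert b1.provenance["reference_hash"] == b2.provenance["reference_hash"]


class TestMixtureArithmetic:
    def test_convex_combination(self):
        assert mixture_probability([0.5, 0.5], [0.2, 0.6]) == pytest.approx(0.4)
        assert mixture_probability([1.0], [0.37]) == pytest.approx(0.37)
        assert mixture_probability([0.3, 0.7], [0.25, 0.25]) == pytest.approx(0.25)

    def test_gamma_zero_forgets_history(self):
        w = update_weights(np.array([0.9, 0.1]), np.array([0.2, 0.6]), gamma=0.0)
        assert w == pytest.approx([0.25, 0.75])

    def test_equal_probs_leave_uniform_weights_unchanged(self):
        # uniform weights are the fixed point of the forgetting update when
        # every model predicts the same probability
        w = update_weights(np.array([0.5, 0.5]), np.array([0.5, 0.5]), gamma=0.98)
        assert w == pytest.approx([0.5, 0.5])
        # with gamma < 1, equal probabilities contract unequal weights
        # toward uniform rather than leaving them fixed
        w = update_weights(np.array([0.3, 0.7]), np.array([0.5, 0.5]), gamma=0.98)
        assert 0.3 < w[0] < 0.5 < w[1] < 0.7

    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=6),
           st.lists(st.floats(1e-6, 1.0), min_size=6, max_size=6),
           st.floats(0.0, 0.999))
    def test_weights_stay_normalized(self, weights, probs, gamma):
        w = np.array(weights) / np.sum(weights)
        out = update_weights(w, np.array(probs[: len(weights)]), gamma)
        assert np.all(out > 0)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)


class TestRelativeCodeLength:
    def test_uniform_model_costs_two_bits_per_symbol(self):
        # an order-0 FCM with empty counts predicts 1/4 everywhere
        cfg = MixtureConfig(models=(FCMConfig(order=0, alpha=1.0),))
        bundle = build_bundle([record("ACGT")], cfg)
        bundle.counts[0].table.clear()
        bundle.counts[0].total_events = 0
        bundle.counts[0]._packed = None
        target = record("ACGTACGTAC", "t")
        res = relative_code_length(target, bundle)
        assert res.bits == pytest.approx(2.0 * target.length, abs=1e-9)

    def test_additivity_of_per_symbol_bits(self, small_bundle, two_genomes):
        res = relative_code_length(two_genomes[1], small_bundle, keep_profile=True)
        assert res.per_symbol_bits.size == res.length
        assert res.bits == pytest.approx(res.per_symbol_bits.sum(), rel=1e-6)
        assert np.all(res.per_symbol_bits > 0)
        assert np.all(np.isfinite(res.per_symbol_bits))

    def test_two_pass_determinism(self, small_bundle, two_genomes):
        r1 = relative_code_length(two_genomes[1], small_bundle)
        r2 = relative_code_length(two_genomes[1], small_bundle)
        assert r1.bits == r2.bits

    def test_self_trained_beats_random_trained(self):
        genomes = simulate_genomes(2, 1000, seed=5)
        target = genomes[0]
        own = build_bundle([genomes[0]])
        other = build_bundle([genomes[1]])
        assert (
            relative_code_length(target, own).bits
            < relative_code_length(target, other).bits
        )

    def test_counts_unchanged_by_encoding(self, small_mixture, two_genomes):
        bundle = build_bundle([two_genomes[0]], small_mixture)
        before = [{k: list(v) for k, v in c.table.items()} for c in bundle.counts]
        relative_code_length(two_genomes[1], bundle)
        assert [c.table for c in bundle.counts] == before

    def test_batch_matches_single_record_path(self, small_bundle):
        rng = np.random.default_rng(4)
        reads = [
            record("".join("ACGT"[i] for i in rng.integers(0, 4, 40)), f"r{j}")
            for j in range(10)
        ]
        batch = relative_code_lengths(reads, small_bundle)
        single = [relative_code_length(r, small_bundle).bits for r in reads]
        assert batch.tolist() == single

    def test_multi_record_target_is_record_order_invariant(self, small_bundle):
        a = record("ACGTACGTACGTGGTT", "a")
        b = record("TTGGCCAATTGGCCAA", "b")
        fwd = relative_code_length([a, b], small_bundle)
        rev = relative_code_length([b, a], small_bundle)
        assert fwd.bits == pytest.approx(rev.bits, rel=1e-12)


def _random_case(rng):
    """One random tiny oracle case: training text, mixture, target."""
    train_len = int(rng.integers(5, 40))
    train = rng.integers(0, 4, train_len)
    models = []
    n_fcm = int(rng.integers(1, 3))
    for _ in range(n_fcm):
        models.append(
            FCMConfig(
                order=int(rng.integers(0, 4)),
                alpha=float(rng.choice([1.0, 1 / 16, 0.5])),
                use_inverted_repeats=bool(rng.integers(0, 2)),
            )
        )
    if rng.integers(0, 2):
        share = int(rng.integers(0, n_fcm))
        models.append(
            STMMConfig(
                order=models[share].order,
                alpha=float(rng.choice([1.0, 1 / 16])),
                max_substitutions=int(rng.integers(0, 3)),
                window=int(rng.integers(3, 9)),
                share_counts_with=share,
            )
        )
    gamma = float(rng.choice([0.0, 0.5, 0.98]))
    target = rng.integers(0, 4, int(rng.integers(1, 31)))
    return train, MixtureConfig(models=tuple(models), gamma=gamma), target


def test_oracle_equivalence_on_random_small_cases():
    """The JIT encoder must reproduce the brute-force mixture, bit for bit
    (within 1e-6), on 200 random FCM+STMM cases with |x| <= 30, orders <= 3."""
    rng = np.random.default_rng(20240917)
    for _ in range(200):
        train, mixture, target = _random_case(rng)
        train_rec = record("".join("ACGT"[s] for s in train))
        bundle = build_bundle([train_rec], mixture)
        got = relative_code_length(
            record("".join("ACGT"[s] for s in target), "t"), bundle
        ).bits
        oracle_models = []
        for m in mixture.models:
            if isinstance(m, FCMConfig):
                oracle_models.append({
                    "order": m.order, "alpha": m.alpha, "stmm": False,
                    "table": oracle_train(m.order, [train], m.use_inverted_repeats),
                })
            else:
                shared = mixture.models[m.share_counts_with]
                oracle_models.append({
                    "order": m.order, "alpha": m.alpha, "stmm": True,
                    "max_subs": m.max_substitutions, "window": m.window,
                    "table": oracle_train(
                        shared.order, [train], shared.use_inverted_repeats
                    ),
                })
        expected, _ = oracle_code_length(target, oracle_models, mixture.gamma)
        assert got == pytest.approx(expected, abs=1e-6)
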