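"""Constrained sampling: decoding orders, tied logits, constraint satisfaction."""

import numpy as np
import pytest

import invfold as iv
from invfold.design import DesignConstraints, sample_decoding_order
from invfold.errors import ConstraintError

from conftest import make_tiny_chain


class TestDecodingOrder:
    def test_uniform_over_permutations_of_three(self):
        cons = DesignConstraints()
        counts = {}
        for i in range(6000):
            order = sample_decoding_order(cons, 3, seed=i)
            key = tuple(s[0] for s in order.slots)
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 6
        for k, c in counts.items():
            assert abs(c / 6000 - 1 / 6) < 0.02

    def test_fixed_positions_decoded_first(self):
        cons = DesignConstraints(fixed={2: "G"})
        for seed in range(50):
            order = sample_decoding_order(cons, 4, seed=seed)
            assert order.slots[0] == [2]

    def test_tied_group_single_slot(self):
        cons = DesignConstraints(tied_groups=[[(1, 1.0), (4, 1.0)]])
        order = sample_decoding_order(cons, 5, seed=0)
        joint = [s for s in order.slots if len(s) > 1]
        assert joint == [[1, 4]]

    def test_overlapping_fixed_tied_rejected(self):
        cons = DesignConstraints(fixed={1: "A"}, tied_groups=[[(1, 1.0), (2, 1.0)]])
        with pytest.raises(ConstraintError):
            sample_decoding_order(cons, 4, seed=0)

    def test_position_in_two_groups_rejected(self):
        cons = DesignConstraints(tied_groups=[[(0, 1.0), (1, 1.0)],
                                              [(1, 1.0), (2, 1.0)]])
        with pytest.raises(ConstraintError):
            cons.validate(4)

    def test_seed_determinism(self):
        cons = DesignConstraints(tied_groups=[[(0, 1.0), (3, 1.0)]])
        a = sample_decoding_order(cons, 6, seed=9)
        b = sample_decoding_order(cons, 6, seed=9)
        assert a.slots == b.slots


class TestCombineTiedLogits:
    def test_single_member_is_plain_softmax(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=21)
        p = iv.combine_tied_logits([logits], [1.0], temperature=0.7, omit=set())
        z = logits / 0.7
        expected = np.exp(z - z.max())
        expected /= expected.sum()
        assert np.allclose(p, expected, atol=1e-12)

    def test_averaging_identical_logits_idempotent(self):
        logits = np.random.default_rng(1).normal(size=21)
        single = iv.combine_tied_logits([logits], [1.0], 0.5, {"X"})
        double = iv.combine_tied_logits([logits, logits], [1.0, 1.0], 0.5, {"X"})
        assert np.allclose(single, double, atol=1e-12)

    def test_opposite_coefficients_give_uniform(self):
        logits = np.random.default_rng(2).normal(size=21)
        p = iv.combine_tied_logits([logits, logits], [1.0, -1.0], 0.1, {"X"})
        assert np.isclose(p[:20], 1 / 20).all() and p[20] == 0.0

    def test_omitted_letters_zero_probability(self):
        logits = np.zeros(21)
        p = iv.combine_tied_logits([logits], [1.0], 1.0, {"C", "W", "X"})
        from invfold.alphabet import AA_TO_INDEX

        assert p[AA_TO_INDEX["C"]] == 0 and p[AA_TO_INDEX["W"]] == 0
        assert np.isclose(p.sum(), 1.0)

    def test_all_zero_coefficients_rejected(self):
        with pytest.raises(ValueError):
            iv.combine_tied_logits([np.zeros(21)], [0.0], 0.1, set())

    def test_probability_averaging_mode(self):
        rng = np.random.default_rng(3)
        la, lb = rng.normal(size=21), rng.normal(size=21)
        p = iv.combine_tied_logits([la, lb], [1.0, 1.0], 1.0, {"X"}, mode="probs")

        def soft(l):
            m = l.copy()
            m[20] = -np.inf
            e = np.exp(m - m.max())
            return e / e.sum()

        expected = (soft(la) + soft(lb)) / 2
        assert np.allclose(p, expected / expected.sum(), atol=1e-12)


class TestSampling:
    def test_all_positions_fixed(self, tiny_params, tiny_config, helix10):
        seq = "ACDEFGHIKL"
        cons = DesignConstraints(fixed=dict(enumerate(seq)), n_samples=1, seed=0)
        res = iv.sample_sequence(tiny_params, tiny_config, helix10, cons)
        assert res.samples[0].sequence == seq
        assert np.isfinite(res.samples[0].avg_log_prob)

    def test_homodimer_tying(self, tiny_params, tiny_config):
        mono = iv.make_backbone(iv.SyntheticSpec(kind="helix", length=7))
        dimer = iv.make_cyclic_assembly(mono, 2, 9.0)
        groups = iv.tying_from_symmetry(dimer, "tie_chains")
        cons = DesignConstraints(tied_groups=groups, temperature=0.5,
                                 n_samples=3, seed=4)
        res = iv.sample_sequence(tiny_params, tiny_config, dimer, cons)
        for s in res.samples:
            assert s.chain_sequences[0] == s.chain_sequences[1]

    def test_low_temperature_equals_greedy(self, tiny_params, tiny_config, helix10):
        cons_cold = DesignConstraints(temperature=1e-6, n_samples=1, seed=3)
        order = [iv.sample_decoding_order(cons_cold, 10, seed=42)]
        cold = iv.sample_sequence(tiny_params, tiny_config, helix10, cons_cold,
                                  orders=order)
        cons_greedy = DesignConstraints(temperature=0.1, n_samples=1, seed=99)
        greedy = iv.sample_sequence(tiny_params, tiny_config, helix10, cons_greedy,
                                    orders=order, greedy=True)
        assert cold.samples[0].sequence == greedy.samples[0].sequence

    def test_untied_equals_singleton_tied(self, tiny_params, tiny_config, helix10):
        plain = DesignConstraints(n_samples=2, seed=8)
        tied = DesignConstraints(
            tied_groups=[[(i, 1.0)] for i in range(10)], n_samples=2, seed=8)
        # singleton groups shuffle identically to free positions only if the
        # slot structure matches; compare against explicitly shared orders
        orders = [iv.sample_decoding_order(plain, 10, seed=100 + i) for i in range(2)]
        a = iv.sample_sequence(tiny_params, tiny_config, helix10, plain, orders=orders)
        b = iv.sample_sequence(tiny_params, tiny_config, helix10, tied, orders=orders)
        assert [s.sequence for s in a.samples] == [s.sequence for s in b.samples]

    def test_fixed_letter_in_omit_set_rejected(self, helix10):
        with pytest.raises(ConstraintError):
            DesignConstraints(fixed={0: "C"}, omit={"C"}).validate(10)

    def test_sampling_probabilities_normalised(self, tiny_params, tiny_config, helix10):
        cons = DesignConstraints(omit={"C", "X"}, temperature=0.8, n_samples=1, seed=1)
        res = iv.sample_sequence(tiny_params, tiny_config, helix10, cons)
        probs = res.samples[0].per_position_probs
        assert np.allclose(probs.sum(axis=1), 1.0)
        from invfold.alphabet import AA_TO_INDEX

        assert np.all(probs[:, AA_TO_INDEX["C"]] == 0)

    def test_temperature_increases_entropy_and_diversity(self, tiny_params,
                                                         tiny_config, helix10):
        # entropy of the per-slot distribution is non-decreasing in T
        rng = np.random.default_rng(0)
        logits = rng.normal(size=21)
        ent = []
        for t in (0.1, 0.5, 1.0, 2.0):
            p = iv.combine_tied_logits([logits], [1.0], t, {"X"})
            nz = p[p > 0]
            ent.append(float(-(nz * np.log(nz)).sum()))
        assert all(b >= a for a, b in zip(ent, ent[1:]))

        def diversity(temp):
            cons = DesignConstraints(temperature=temp, n_samples=12, seed=5)
            res = iv.sample_sequence(tiny_params, tiny_config, helix10, cons)
            seqs = [s.tokens for s in res.samples]
            d = [np.mean(a != b) for i, a in enumerate(seqs) for b in seqs[i + 1:]]
            return float(np.mean(d))

        assert diversity(1.0) > diversity(0.1)


class TestTyingFromSymmetry:
    def test_trimer_tie_chains(self):
        mono = iv.make_backbone(iv.SyntheticSpec(kind="helix", length=10))
        trimer = iv.make_cyclic_assembly(mono, 3, 9.0)
        groups = iv.tying_from_symmetry(trimer, "tie_chains")
        assert len(groups) == 10 and all(len(g) == 3 for g in groups)

    def test_single_chain_repeats(self):
        s = iv.make_backbone(iv.SyntheticSpec(kind="helix", length=12))
        groups = iv.tying_from_symmetry(s, "tie_repeats", repeat_length=4)
        assert len(groups) == 4 and all(len(g) == 3 for g in groups)

    def test_trimer_repeats_both_symmetries(self):
        mono = iv.make_backbone(iv.SyntheticSpec(kind="helix", length=12))
        trimer = iv.make_cyclic_assembly(mono, 3, 9.0)
        groups = iv.tying_from_symmetry(trimer, "tie_repeats", repeat_length=4)
        assert len(groups) == 4 and all(len(g) == 9 for g in groups)

    def test_indivisible_length_rejected(self):
        s = iv.make_backbone(iv.SyntheticSpec(kind="helix", length=10))
        with pytest.raises(ConstraintError):
            iv.tying_from_symmetry(s, "tie_repeats", repeat_length=4)

    def test_none_mode_empty(self, helix10):
        assert iv.tying_from_symmetry(helix10, "none") == []


class TestMultiState:
    def test_equal_length_required(self, tiny_params, tiny_config, helix10):
        short = make_tiny_chain(6)
        with pytest.raises(ConstraintError):
            iv.sample_multistate(tiny_params, tiny_config, [helix10, short],
                                 [1.0, -0.5], DesignConstraints())

    def test_single_state_reduces_to_plain_sampling(self, tiny_params, tiny_config,
                                                    helix10):
        cons = DesignConstraints(n_samples=1, seed=2)
        orders = [iv.sample_decoding_order(cons, 10, seed=7)]
        a = iv.sample_sequence(tiny_params, tiny_config, helix10, cons, orders=orders)
        b = iv.sample_multistate(tiny_params, tiny_config, [helix10], [1.0],
                                 cons, orders=orders)
        assert a.samples[0].sequence == b.samples[0].sequence

    def test_negative_state_steers_away(self, tiny_params, tiny_config):
        # two distinct states; a strong negative coefficient on state B must
        # change the design relative to designing for A alone
        a = iv.make_backbone(iv.SyntheticSpec(kind="helix", length=10))
        b = iv.make_backbone(iv.SyntheticSpec(kind="strand", length=10))
        cons = DesignConstraints(n_samples=1, seed=0, temperature=1e-6)
        orders = [iv.sample_decoding_order(cons, 10, seed=3)]
        only_a = iv.sample_multistate(tiny_params, tiny_config, [a], [1.0],
                                      cons, orders=orders, greedy=True)
        steered = iv.sample_multistate(tiny_params, tiny_config, [a, b], [1.0, -1.0],
                                       cons, orders=orders, greedy=True)
        assert only_a.samples[0].sequence != steered.samples[0].sequence
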