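"""Tests for PW detection, joint sign probabilities, HPW selection and
credibility typing."""
import numpy as np
import pytest

import lassospace as ls
from lassospace.combined import EffectSet
from lassospace.inference import types_from_flags

from _oracles import hpw_bruteforce


def make_effects(draws, pairs=()):
    """EffectSet from an explicit draw matrix; ``pairs`` lists (j, k, is_sum)
    describing the trailing combined columns."""
    draws = np.asarray(draws, dtype=float)
    n_pairs = len(pairs)
    return EffectSet(
        draws=draws,
        n_single=draws.shape[1] - n_pairs,
        pair_j=np.array([p[0] for p in pairs], dtype=int),
        pair_k=np.array([p[1] for p in pairs], dtype=int),
        pair_is_sum=np.array([p[2] for p in pairs], dtype=bool),
    )


class TestPW:
    def test_strict_threshold_boundary(self):
        col_976 = np.r_[np.ones(976), -np.ones(24)]
        col_975 = np.r_[np.ones(975), -np.ones(25)]
        eff = make_effects(np.column_stack([col_976, col_975]))
        det = ls.pw_detect(eff, 0.975)
        assert det.q[0] == 0.976 and det.credible[0] and det.sign[0] == 1
        assert det.q[1] == 0.975 and not det.credible[1]

    def test_all_positive_credible_at_any_level(self):
        eff = make_effects(np.ones((10, 1)))
        assert ls.pw_detect(eff, 0.999).credible[0]

    def test_zero_draws_count_for_neither_sign(self):
        eff = make_effects(np.array([[1.0], [0.0], [1.0], [0.0]]))
        det = ls.pw_detect(eff, 0.4)
        assert det.q[0] == 0.5


class TestJointProbability:
    def test_single_effect_reduces_to_marginal(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0.5, 1, size=(200, 1))
        eff = make_effects(d)
        assert ls.joint_sign_probability(eff, [(0, 1)]) == (d[:, 0] > 0).mean()

    def test_identical_sign_patterns_give_joint_equal_marginal(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.5, 1, size=200)
        eff = make_effects(np.column_stack([a, 2 * a]))
        joint = ls.joint_sign_probability(eff, [(0, 1), (1, 1)])
        assert joint == (a > 0).mean()

    def test_hand_counted_example(self):
        d = np.array([[1, 1], [1, 1], [1, -1], [1, 1]], dtype=float)
        eff = make_effects(d)
        assert ls.joint_sign_probability(eff, [(0, 1), (1, 1)]) == 0.75

    def test_input_validation(self):
        eff = make_effects(np.ones((4, 2)))
        with pytest.raises(ValueError):
            ls.joint_sign_probability(eff, [])
        with pytest.raises(ValueError):
            ls.joint_sign_probability(eff, [(0, 1), (0, -1)])
        with pytest.raises(IndexError):
            ls.joint_sign_probability(eff, [(5, 1)])


class TestHPW:
    def test_four_draw_toy_selects_only_first(self):
        # joint probability of both positives is 0.75 <= 0.95, so only the
        # always-positive effect enters
        d = np.array([[1, 1], [1, 1], [1, -1], [1, 1]], dtype=float)
        det = ls.hpw_select(make_effects(d), 0.95)
        assert list(det.credible) == [True, False]
        assert det.joint_probability == 1.0

    def test_all_positive_effects_all_selected(self):
        d = np.abs(np.random.default_rng(2).normal(size=(30, 5))) + 0.01
        det = ls.hpw_select(make_effects(d), 0.95)
        assert det.credible.all()
        assert det.joint_probability == 1.0

    def test_exclusion_rule_blocks_member_single(self):
        # combined delta_01 has q=0.99 and is accepted first; the single
        # effect beta_0 (q=0.98) is then excluded even though the joint
        # probability would have allowed it
        S = 100
        b0 = np.ones(S)
        b1 = np.ones(S)
        b1[:40] = -0.5
        b0[97:99] = -0.1
        b1[97:99] = 0.5
        b0[99] = 0.4
        b1[99] = -1.0
        delta = b0 + b1
        assert (b0 > 0).sum() == 98 and (delta > 0).sum() == 99
        eff = make_effects(np.column_stack([b0, b1, delta]), pairs=[(0, 1, True)])
        det = ls.hpw_select(eff, 0.95)
        assert det.credible[2] and not det.credible[0] and not det.credible[1]
        # without the exclusion rule beta_0 would have been admissible
        assert ls.joint_sign_probability(eff, [(2, 1), (0, 1)]) > 0.95

    def test_combined_effects_sharing_a_locus_exclude_each_other(self):
        rng = np.random.default_rng(3)
        b = np.abs(rng.normal(size=(50, 3))) + 0.01
        eff = make_effects(
            np.column_stack([b, b[:, 0] + b[:, 1], b[:, 1] + b[:, 2]]),
            pairs=[(0, 1, True), (1, 2, True)],
        )
        det = ls.hpw_select(eff, 0.9)
        chosen_pairs = det.credible[3:]
        assert chosen_pairs.sum() == 1  # they share locus 1

    def test_matches_bruteforce_oracle_small(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n_single = rng.integers(2, 5)
            n_pairs = rng.integers(0, 4)
            S = 32
            beta = rng.normal(rng.normal(0, 1, n_single), 1.0, size=(S, n_single))
            pairs = []
            cols = [beta]
            for _ in range(n_pairs):
                j, k = sorted(rng.choice(n_single, size=2, replace=False))
                is_sum = bool(rng.integers(2))
                pairs.append((int(j), int(k), is_sum))
                col = beta[:, j] + beta[:, k] if is_sum else beta[:, j] - beta[:, k]
                cols.append(col[:, None])
            draws = np.hstack(cols)
            alpha = float(rng.choice([0.6, 0.8, 0.9]))
            det = ls.hpw_select(make_effects(draws, pairs), alpha)
            expect = hpw_bruteforce(draws, n_single, pairs, alpha)
            np.testing.assert_array_equal(det.credible, expect)


class TestCredibilityTypes:
    def test_single_credible_positive_gets_one(self):
        d = np.column_stack([np.ones(20), np.zeros(20) - 1.0])
        det = ls.pw_detect(make_effects(d), 0.9)
        types = ls.credibility_types(det)
        assert list(types) == [1.0, -1.0]

    def test_credible_sum_assigns_075_and_025(self):
        # sum credible, neither single credible; locus 0 has the higher
        # marginal sign probability
        rng = np.random.default_rng(4)
        b0 = rng.normal(0.8, 1, 2000)   # q ~ 0.79
        b1 = rng.normal(0.3, 1, 2000)   # q ~ 0.62
        delta = np.abs(b0 + b1) + 0.01  # force the sum credible
        eff = make_effects(np.column_stack([b0, b1, delta]), pairs=[(0, 1, True)])
        det = ls.pw_detect(eff, 0.975)
        assert not det.credible[0] and not det.credible[1] and det.credible[2]
        types = ls.credibility_types(det)
        assert types[0] == 0.75 and types[1] == 0.25

    def test_max_rule_when_single_also_credible(self):
        # locus 0 singly credible AND the weaker member of a credible sum:
        # the higher bar (1) wins
        S = 1000
        b0 = np.ones(S)
        b1 = np.full(S, 2.0)
        delta = b0 + b1
        # make locus 0 the weaker member: drop a few b0 draws negative
        b0[:5] = -0.1
        eff = make_effects(np.column_stack([b0, b1, delta]), pairs=[(0, 1, True)])
        det = ls.pw_detect(eff, 0.975)
        types = ls.credibility_types(det)
        assert types[0] == 1.0 and types[1] == 1.0

    def test_credibly_negative_difference_signs(self):
        # delta_01 = b0 - b1 credibly negative: locus 0 negative type,
        # locus 1 positive type
        S = 100
        b0 = np.full(S, -0.5)
        b1 = np.full(S, 2.0)
        b0[:30] = 0.5  # neither single credible at 0.975
        diff = b0 - b1
        eff = make_effects(np.column_stack([b0, b1, diff]), pairs=[(0, 1, False)])
        det = ls.pw_detect(eff, 0.975)
        assert det.credible[2] and det.sign[2] == -1
        types = ls.credibility_types(det)
        assert types[0] < 0 < types[1]

    def test_without_combined_effects_types_are_ternary(self, tiny_draws):
        eff = ls.effect_set(tiny_draws)
        for det in (ls.pw_detect(eff, 0.975), ls.hpw_select(eff, 0.95)):
            types = ls.credibility_types(det)
            assert set(np.unique(types)) <= {-1.0, 0.0, 1.0}

    def test_nonzero_only_for_involved_loci(self):
        rng = np.random.default_rng(9)
        d = rng.normal(size=(50, 4))
        det = ls.pw_detect(make_effects(d), 0.975)
        types = ls.credibility_types(det)
        for j in range(4):
            if not det.credible[j]:
                assert types[j] == 0.0

    def test_types_from_flags_matches_detection_route(self):
        rng = np.random.default_rng(10)
        b = rng.normal(0.5, 1, size=(500, 4))
        pairs = [(0, 1, True), (2, 3, False)]
        cols = [b, (b[:, 0] + b[:, 1])[:, None], (b[:, 2] - b[:, 3])[:, None]]
        eff = make_effects(np.hstack(cols), pairs)
        det = ls.pw_detect(eff, 0.6)
        direct = types_from_flags(
            4, eff.pair_j, eff.pair_k, eff.pair_is_sum,
            det.credible, det.sign, det.q,
        )
        np.testing.assert_array_equal(ls.credibility_types(det), direct)
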