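import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from ncddetect import detect
from ncddetect.detect import (
    DPCost,
    ScoreDistribution,
    batch_sample_distributions,
    bh_fdr,
    combine_samples,
    observed_score,
    p_value,
    qq_data,
    sample_background_distribution,
)
from ncddetect.detect import test_element as run_element_test
from ncddetect.scoring import ScoreMatrix, score_nmut, score_phylop


def _random_instance(rng, m, uniform_scores=True, smax=30):
    P = rng.dirichlet([12, 1, 1, 1], size=m)
    S = np.zeros((m, 4), dtype=np.int64)
    if uniform_scores:
        S[:, 1:] = rng.integers(0, smax, size=m)[:, None]
    else:
        S[:, 1:] = rng.integers(0, smax, size=(m, 3))
        S[:, 0] = rng.integers(0, 3, size=m)
    return P, S


class TestObservedScore:
    def test_top_two_of_three(self):
        assert observed_score([4, 7, 2]) == 11

    def test_no_mutations(self):
        assert observed_score([]) == 0

    def test_single_large(self):
        assert observed_score([215]) == 215

    def test_base_score_added(self):
        assert observed_score([4, 7, 2], base=3) == 14


class TestSampleDistribution:
    def test_one_position_enumeration(self):
        P = np.array([[0.98, 0.01, 0.005, 0.005]])
        S = np.array([[0, 3, 2, 2]])
        d = sample_background_distribution(P, S)
        assert d.as_dict() == pytest.approx({0: 0.98, 2: 0.01, 3: 0.01})

    def test_two_identical_positions_nmut(self):
        P = np.tile([0.98, 0.01, 0.005, 0.005], (2, 1))
        S = np.tile([0, 10, 10, 10], (2, 1))
        d = sample_background_distribution(P, S)
        assert d.as_dict() == pytest.approx({0: 0.9604, 10: 0.0392, 20: 0.0004})

    def test_three_positions_capped(self):
        P = np.tile([0.5, 0.5, 0.0, 0.0], (3, 1))
        S = np.tile([0, 10, 10, 10], (3, 1))
        d = sample_background_distribution(P, S, cap=2)
        assert d.as_dict() == pytest.approx({0: 0.125, 10: 0.375, 20: 0.5})

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            sample_background_distribution(np.zeros((2, 4)), np.zeros((3, 4), dtype=int))

    def test_oracle_equivalence_uniform_scores(self, rng):
        for _ in range(30):
            m = int(rng.integers(1, 7))
            P, S = _random_instance(rng, m, uniform_scores=True)
            for cap in (2, None):
                d = sample_background_distribution(P, S, cap=cap)
                ref = oracles.brute_force_sample_pmf(P, S, cap)
                assert oracles.total_variation(d.probs, ref) < 1e-12

    def test_oracle_equivalence_uncapped_heterogeneous(self, rng):
        for _ in range(20):
            m = int(rng.integers(1, 6))
            P, S = _random_instance(rng, m, uniform_scores=False)
            d = sample_background_distribution(P, S, cap=None)
            ref = oracles.brute_force_sample_pmf(P, S, None)
            assert oracles.total_variation(d.probs, ref) < 1e-12

    def test_capped_heterogeneous_discrepancy_bounded(self, rng):
        # with outcome-specific scores the capped DP retires events in
        # processing order, not by realized magnitude; the two statistics
        # can only differ on outcomes with >= 3 mutation events
        worst = 0.0
        for _ in range(25):
            m = int(rng.integers(2, 6))
            P, S = _random_instance(rng, m, uniform_scores=False)
            d = sample_background_distribution(P, S, cap=2)
            ref = oracles.brute_force_sample_pmf(P, S, 2)
            tv = oracles.total_variation(d.probs, ref)
            bound = oracles.prob_at_least_k_events(P, 3)
            assert tv <= bound + 1e-12
            worst = max(worst, tv)
        assert worst <= 1.0  # the per-instance bound above is the contract

    def test_normalization(self, rng):
        for _ in range(10):
            P, S = _random_instance(rng, int(rng.integers(1, 10)))
            for cap in (2, None):
                d = sample_background_distribution(P, S, cap=cap)
                assert d.total_mass == pytest.approx(1.0, abs=1e-12)


class TestBatchPath:
    def test_matches_general_path(self, rng):
        for _ in range(15):
            m, k = int(rng.integers(1, 12)), int(rng.integers(1, 5))
            P = rng.dirichlet([20, 1, 1, 1], size=(m, k))
            s = rng.integers(0, 40, size=m)
            S = np.zeros((m, k, 4), dtype=np.int64)
            S[:, :, 1:] = s[:, None, None]
            dists = batch_sample_distributions(P, s)
            for j in range(k):
                ref = sample_background_distribution(P[:, j, :], S[:, j, :], cap=2)
                n = max(dists[j].probs.size, ref.probs.size)
                a = np.pad(dists[j].probs, (0, n - dists[j].probs.size))
                b = np.pad(ref.probs, (0, n - ref.probs.size))
                assert np.abs(a - b).sum() < 1e-12


class TestCombineSamples:
    def test_two_sample_enumeration(self):
        d = ScoreDistribution.from_dict({0: 0.9, 10: 0.1})
        out = combine_samples([d, d])
        assert out.as_dict() == pytest.approx({0: 0.81, 10: 0.18, 20: 0.01})

    def test_single_sample_identity(self):
        d = ScoreDistribution.from_dict({0: 0.3, 5: 0.7})
        assert combine_samples([d]).as_dict() == d.as_dict()

    def test_point_masses(self):
        a = ScoreDistribution.from_dict({5: 1.0})
        b = ScoreDistribution.from_dict({7: 1.0})
        assert combine_samples([a, b]).as_dict() == {12: 1.0}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            combine_samples([])

    def test_matches_dict_convolution(self, rng):
        dists = []
        pmfs = []
        for _ in range(4):
            probs = rng.dirichlet(np.ones(6))
            pmf = {int(s): float(p) for s, p in zip(rng.choice(30, 6, replace=False), probs)}
            pmfs.append(pmf)
            dists.append(ScoreDistribution.from_dict(pmf))
        out = combine_samples(dists)
        ref = oracles.combine_pmfs(pmfs)
        assert oracles.total_variation(out.probs, ref) < 1e-12

    def test_eps_accumulates(self):
        a = ScoreDistribution.from_dict({0: 0.9}, eps=0.1)
        b = ScoreDistribution.from_dict({0: 0.95}, eps=0.05)
        out = combine_samples([a, b])
        assert out.eps == pytest.approx(0.15)


class TestPValue:
    def test_zero_observed_is_one(self):
        d = ScoreDistribution.from_dict({0: 0.5, 10: 0.5})
        assert p_value(d, 0) == 1.0

    def test_tail_sum(self):
        d = ScoreDistribution.from_dict({0: 0.9, 50: 0.1})
        assert p_value(d, 50) == pytest.approx(0.1)

    def test_above_support_returns_eps(self):
        d = ScoreDistribution.from_dict({0: 1.0}, eps=1e-9)
        assert p_value(d, 5) == pytest.approx(1e-9)

    def test_monotone_in_observed_score(self, rng):
        P, S = _random_instance(rng, 6)
        d = sample_background_distribution(P, S)
        ps = [p_value(d, s) for s in range(0, d.probs.size + 5)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_matches_oracle_tail(self, rng):
        P, S = _random_instance(rng, 5)
        d = sample_background_distribution(P, S)
        ref = oracles.brute_force_sample_pmf(P, S, 2)
        for s in (0, 1, 7, 23):
            assert p_value(d, s) == pytest.approx(min(oracles.tail_probability(ref, s), 1.0))


class TestBH:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1, 1, 1]), [1, 1, 1])

    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=30))
    @settings(max_examples=50)
    def test_matches_hand_rolled(self, pvals):
        np.testing.assert_allclose(bh_fdr(pvals), oracles.bh_by_hand(pvals), rtol=1e-12)

    def test_q_at_least_p(self, rng):
        p = rng.uniform(size=40)
        assert (bh_fdr(p) >= p - 1e-15).all()


class TestQQ:
    def test_worked_example(self):
        df = qq_data([0.2, 0.1, 0.4, 0.3])
        np.testing.assert_allclose(df["expected"], [0.125, 0.375, 0.625, 0.875])
        np.testing.assert_allclose(df["observed"], [0.1, 0.2, 0.3, 0.4])

    def test_all_ones(self):
        df = qq_data([1.0, 1.0, 1.0])
        assert (df["observed"] == 1.0).all()
        assert (df["neglog10_observed"] == 0.0).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            qq_data([])


class TestTestElement:
    def _inputs(self, m=5, k=3, mut=0.01):
        P = np.zeros((m, k, 4))
        P[:, :, 1:] = mut / 3
        P[:, :, 0] = 1 - mut
        S = score_phylop(np.linspace(0, 2, m), k)
        return P, S

    def test_unmutated_element_p_is_one(self):
        P, S = self._inputs()
        result = run_element_test(P, S, observed=[])
        assert result.p_value == 1.0
        assert result.observed_score == 0
        assert result.n_mut_expected == pytest.approx(P[:, :, 1:].sum())

    def test_unmutated_nmut_p_is_one(self):
        P, _ = self._inputs()
        result = run_element_test(P, score_nmut(P), observed=[])
        assert result.p_value == 1.0

    def test_zero_positions_rejected(self):
        with pytest.raises(ValueError, match="zero usable"):
            run_element_test(np.zeros((0, 1, 4)), ScoreMatrix(np.zeros((0, 1, 4)), "nmut"), [])

    def test_observed_mutations_lower_p(self):
        P, S = self._inputs()
        r0 = run_element_test(P, S, observed=[])
        r1 = run_element_test(P, S, observed=[(4, 0, 1)])
        r2 = run_element_test(P, S, observed=[(4, 0, 1), (3, 1, 2)])
        assert r2.p_value < r1.p_value < r0.p_value

    def test_per_sample_cap_in_observed_score(self):
        P, S = self._inputs()
        obs = [(0, 0, 1), (1, 0, 1), (2, 0, 1)]  # three mutations in one sample
        result = run_element_test(P, S, obs)
        scores = sorted(int(S.S[i, 0, 1]) for i, _, _ in obs)
        assert result.observed_score == sum(scores[-2:])
        assert result.n_mut_observed == 3

    def test_matches_full_oracle(self, rng):
        m, k = 4, 2
        P = rng.dirichlet([15, 1, 1, 1], size=(m, k))
        s = rng.integers(1, 20, size=m)
        S = np.zeros((m, k, 4), dtype=np.int64)
        S[:, :, 1:] = s[:, None, None]
        result = run_element_test(P, ScoreMatrix(S, "custom"), observed=[(2, 1, 3)])
        per_sample = [oracles.brute_force_sample_pmf(P[:, j], S[:, j], 2) for j in range(k)]
        ref = oracles.combine_pmfs(per_sample)
        assert oracles.total_variation(result.distribution.probs, ref) < 1e-10
        assert result.p_value == pytest.approx(
            min(oracles.tail_probability(ref, int(s[2])), 1.0), rel=1e-9
        )


class TestDPCost:
    def test_exact_cell_count_general_path(self, rng):
        P, S = _random_instance(rng, 6, smax=20)
        cost = DPCost()
        sample_background_distribution(P, S, cap=2, cost=cost)
        width = int(S.max(axis=1).sum()) + 1
        assert cost.cells == 6 * 3 * width

    def test_linear_in_positions_at_fixed_total_smax(self):
        # hold s_max (the score-axis width) fixed: cost scales linearly in m
        cells = {}
        for m in (8, 16):
            per_pos = 64 // m
            P = np.tile([0.99, 0.005, 0.0025, 0.0025], (m, 1))
            S = np.zeros((m, 4), dtype=np.int64)
            S[:, 1:] = per_pos
            cost = DPCost()
            sample_background_distribution(P, S, cap=2, cost=cost)
            cells[m] = cost.cells / (64 + 1)
        assert cells[16] == 2 * cells[8]

    def test_linear_in_smax(self):
        cells = {}
        for scale in (1, 2):
            P = np.tile([0.99, 0.005, 0.0025, 0.0025], (5, 1))
            S = np.zeros((5, 4), dtype=np.int64)
            S[:, 1:] = 10 * scale
            cost = DPCost()
            sample_background_distribution(P, S, cap=2, cost=cost)
            cells[scale] = cost.cells
        assert cells[2] / cells[1] == pytest.approx(2.0, rel=0.02)

    def test_linear_in_samples(self, rng):
        P, S = _random_instance(rng, 5)
        cost1, cost2 = DPCost(), DPCost()
        sample_background_distribution(P, S, cost=cost1)
        for _ in range(2):
            sample_background_distribution(P, S, cost=cost2)
        assert cost2.cells == 2 * cost1.cells


class TestScoreDistribution:
    def test_pruning_moves_mass_to_eps(self):
        d = ScoreDistribution.from_dict({0: 1 - 1e-18, 5: 1e-18})
        pruned = d.pruned()
        assert pruned.probs[5] == 0.0
        assert pruned.eps == pytest.approx(1e-18)
        assert pruned.total_mass == pytest.approx(1.0)

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError):
            ScoreDistribution(np.array([0.5, -0.1]))

    def test_finalize_groups_q_values_per_type(self):
        raw = []
        for i, (etype, p) in enumerate(
            [("promoter", 0.01), ("promoter", 0.5), ("utr3", 0.02), ("utr3", 0.8)]
        ):
            t = detect.ElementTest(0, p, 0, 0.0, np.zeros(1), ScoreDistribution(np.array([1.0])))
            raw.append((f"e{i}", etype, 100, t))
        results = detect.finalize_results(raw)
        by_id = {r.element_id: r for r in results}
        assert by_id["e0"].q_value == pytest.approx(0.02)  # n=2 within promoters
        assert by_id["e2"].q_value == pytest.approx(0.04)
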