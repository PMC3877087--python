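import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ecselect.cq import CqMatrix
from ecselect.errors import InputError, StatisticalError
from ecselect.genorm import (
    optimal_ec_count,
    pairwise_variation,
    pairwise_variation_matrix,
    stability_m,
    stepwise_ranking,
    to_relative_quantity,
)

from conftest import matrix_from_rows, random_matrix


# -- independent brute-force oracles ----------------------------------------

def naive_v(q, j, k):
    ratios = [math.log2(q.loc[j, s] / q.loc[k, s]) for s in q.columns]
    mean = sum(ratios) / len(ratios)
    return math.sqrt(sum((r - mean) ** 2 for r in ratios) / (len(ratios) - 1))


def naive_m(q):
    out = {}
    for j in q.index:
        vs = [naive_v(q, j, k) for k in q.index if k != j]
        out[j] = sum(vs) / len(vs)
    return out


def naive_nf_v_series(q, order):
    def nf(assays, s):
        logs = [math.log(q.loc[a, s]) for a in assays]
        return math.exp(sum(logs) / len(logs))

    series = {}
    for n in range(2, len(order)):
        ratios = [math.log2(nf(order[:n], s) / nf(order[: n + 1], s)) for s in q.columns]
        mean = sum(ratios) / len(ratios)
        series[n] = math.sqrt(sum((r - mean) ** 2 for r in ratios) / (len(ratios) - 1))
    return series


def random_q(rng, n_assays=None, n_samples=None):
    n_assays = n_assays or rng.integers(3, 7)
    n_samples = n_samples or rng.integers(3, 11)
    return to_relative_quantity(random_matrix(rng, n_assays, n_samples))


class TestRelativeQuantity:
    def test_anchor_gets_quantity_one(self, rng):
        q = random_q(rng)
        assert np.allclose(q.max(axis=1), 1.0)

    def test_one_cycle_above_anchor_halves(self):
        m = matrix_from_rows({"a": {"s1": 20.0, "s2": 21.0}, "b": {"s1": 20.0, "s2": 20.0}})
        q = to_relative_quantity(m)
        assert q.loc["a", "s2"] == pytest.approx(0.5)

    def test_ninety_percent_efficiency_two_cycles(self):
        m = matrix_from_rows({"a": {"s1": 20.0, "s2": 22.0}, "b": {"s1": 20.0, "s2": 20.0}})
        q = to_relative_quantity(m, efficiencies={"a": 90.0})
        assert q.loc["a", "s2"] == pytest.approx(1.9 ** -2)
        assert q.loc["a", "s2"] == pytest.approx(0.27701, abs=5e-6)

    def test_missing_cell_names_assay_and_sample(self):
        m = matrix_from_rows({"a": {"s1": 20.0, "s2": float("nan")}, "b": {"s1": 20.0, "s2": 21.0}})
        with pytest.raises(InputError, match=r"'a'.*'s2'"):
            to_relative_quantity(m)


class TestPairwiseVariationAndM:
    def test_proportional_assays_have_zero_v(self):
        m = matrix_from_rows(
            {"a": {"s1": 20.0, "s2": 23.0, "s3": 21.0}, "b": {"s1": 25.0, "s2": 28.0, "s3": 26.0}}
        )
        q = to_relative_quantity(m)
        assert pairwise_variation(q, "a", "b") == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_two_sample_v(self):
        # log2 ratios across the two samples are {1, 3}: SD = sqrt(2)
        q = pd.DataFrame({"s1": [2.0, 1.0], "s2": [8.0, 1.0]}, index=["a", "b"])
        assert pairwise_variation(q, "a", "b") == pytest.approx(math.sqrt(2), abs=1e-12)
        assert pairwise_variation(q, "a", "b") == pytest.approx(1.41421, abs=1e-5)

    def test_v_invariant_to_sample_scaling(self, rng):
        q = random_q(rng)
        scaled = q * rng.uniform(0.1, 10.0, size=q.shape[1])
        assert pairwise_variation(scaled, *q.index[:2]) == pytest.approx(
            pairwise_variation(q, *q.index[:2])
        )

    def test_m_matches_bruteforce(self, rng):
        for _ in range(25):
            q = random_q(rng)
            expected = naive_m(q)
            got = stability_m(q)
            for a, v in expected.items():
                assert got[a] == pytest.approx(v, abs=1e-10)

    def test_two_assays_share_m(self, rng):
        q = random_q(rng, n_assays=2)
        m = stability_m(q)
        assert m.iloc[0] == m.iloc[1] == pairwise_variation(q, *q.index)

    def test_identical_assays_all_zero(self):
        q = pd.DataFrame(
            [[1.0, 0.5, 0.25]] * 3, index=["a", "b", "c"], columns=["s1", "s2", "s3"]
        )
        assert np.allclose(stability_m(q), 0.0)

    def test_preconditions(self, rng):
        q = random_q(rng, n_assays=3, n_samples=4)
        with pytest.raises(InputError):
            pairwise_variation(q, "assay0", "assay0")
        with pytest.raises(StatisticalError):
            stability_m(q.iloc[:1])


class TestStepwiseRanking:
    def test_noisy_candidate_eliminated_first(self, rng):
        hits = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            loading = r.normal(0, 0.5, size=8)
            rows = {
                "A": 18 + loading + r.normal(0, 0.05, 8),
                "B": 20 + loading + r.normal(0, 0.05, 8),
                "C": 22 + loading + r.normal(0, 0.05, 8),
                "noisy": 21 + loading + r.normal(0, 1.5, 8),
            }
            m = CqMatrix(pd.DataFrame(rows, index=[f"s{i}" for i in range(8)]).T)
            ranking = stepwise_ranking(to_relative_quantity(m))
            if ranking.elimination[0][1] == "noisy":
                hits += 1
        assert hits >= 48  # eliminated first in >= 95% of seeds

    def test_stable_pair_survives(self, rng):
        loading = rng.normal(0, 0.5, size=10)
        rows = {
            "A": 18 + loading + rng.normal(0, 0.02, 10),
            "B": 20 + loading + rng.normal(0, 0.02, 10),
            "C": 21 + loading + rng.normal(0, 1.0, 10),
        }
        m = CqMatrix(pd.DataFrame(rows, index=[f"s{i}" for i in range(10)]).T)
        ranking = stepwise_ranking(to_relative_quantity(m))
        assert ranking.final_pair == ("A", "B")
        # the final two assays carry identical M by construction
        final_ms = ranking.m_by_round.iloc[:, -1].dropna()
        assert final_ms.iloc[0] == pytest.approx(final_ms.iloc[1])

    def test_invariant_to_assay_order(self, rng):
        q = random_q(rng, n_assays=5, n_samples=8)
        shuffled = q.sample(frac=1, random_state=1)
        a = stepwise_ranking(q)
        b = stepwise_ranking(shuffled)
        assert a.stability_order == b.stability_order

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_outputs_invariant_to_per_sample_cq_shift(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, 4, 6)
        shifted = CqMatrix(m.cq + rng.normal(0, 2, size=6))
        qa, qb = to_relative_quantity(m), to_relative_quantity(shifted)
        assert np.allclose(stability_m(qa), stability_m(qb))
        assert stepwise_ranking(qa).stability_order == stepwise_ranking(qb).stability_order

    def test_anchor_choice_cancels(self, rng):
        m = random_matrix(rng, 4, 6)
        q_min = to_relative_quantity(m, anchor="min")
        q_mean = to_relative_quantity(m, anchor="mean")
        assert np.allclose(stability_m(q_min), stability_m(q_mean))
        assert np.allclose(
            pairwise_variation_matrix(q_min), pairwise_variation_matrix(q_mean)
        )


class TestOptimalEcCount:
    def test_redundant_assay_adds_zero_v(self, rng):
        q = random_q(rng, n_assays=3, n_samples=6)
        # a fourth assay proportional to NF_3 adds no information
        nf3 = np.exp(np.log(q).mean(axis=0))
        q4 = pd.concat([q, pd.DataFrame({c: [v] for c, v in (0.5 * nf3).items()}, index=["prop"])])
        ranking = stepwise_ranking(q4)
        order = ranking.stability_order
        series = optimal_ec_count(q4, ranking)
        n_at = order.index("prop")  # 'prop' joins at position n_at+1
        if n_at == 3:
            assert series.v[3] == pytest.approx(0.0, abs=1e-12)

    def test_v_series_matches_bruteforce(self, rng):
        for _ in range(10):
            q = random_q(rng, n_assays=5, n_samples=8)
            ranking = stepwise_ranking(q)
            series = optimal_ec_count(q, ranking)
            expected = naive_nf_v_series(q, ranking.stability_order)
            for n, v in expected.items():
                assert series.v[n] == pytest.approx(v, abs=1e-10)

    def test_argmin_fallback_when_no_v_below_cutoff(self, rng):
        q = random_q(rng, n_assays=5, n_samples=8)
        series = optimal_ec_count(q, stepwise_ranking(q), v_cutoff=1e-9)
        assert series.rule == "argmin"
        assert series.recommended_n == int(series.v.idxmin())

    def test_below_cutoff_rule(self, rng):
        q = random_q(rng, n_assays=5, n_samples=8)
        series = optimal_ec_count(q, stepwise_ranking(q), v_cutoff=1e9)
        assert series.rule == "below_cutoff"
        assert series.recommended_n == 2
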