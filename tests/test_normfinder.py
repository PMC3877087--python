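import itertools

import numpy as np
import pandas as pd
import pytest

from ecselect.cq import CqMatrix, SampleSheet
from ecselect.errors import InputError, StatisticalError
from ecselect.normfinder import best_pair, normfinder_stability, pair_table

from conftest import two_group_sheet


def build_cohort(rng, sigmas, deltas, n_case=20, n_control=20, tau=0.5, baselines=None):
    names = [f"g{i}" for i in range(len(sigmas))]
    baselines = baselines or [18.0 + 2 * i for i in range(len(sigmas))]
    sheet = two_group_sheet(n_case, n_control)
    samples = sheet.sample_ids
    loading = rng.normal(0, tau, size=len(samples))
    case = np.array([g == "cancer" for g in sheet.table["group"]])
    rows = {}
    for name, b, s, d in zip(names, baselines, sigmas, deltas):
        rows[name] = b + loading + d * case + rng.normal(0, s, size=len(samples))
    cq = pd.DataFrame(rows, index=samples).T
    cq.index.name = "assay"
    return CqMatrix(cq), sheet


class TestStability:
    def test_noise_free_gene_is_most_stable(self, rng):
        m, sheet = build_cohort(rng, sigmas=[1e-9, 0.5, 0.7, 0.6], deltas=[0, 0, 0, 0])
        res = normfinder_stability(m, sheet, list(m.assay_ids))
        assert res.best_single == "g0"
        assert res.stability["g0"] == pytest.approx(0.0, abs=0.05)

    def test_degenerate_cohort_all_zero(self, rng):
        m, sheet = build_cohort(rng, sigmas=[0, 0, 0], deltas=[0, 0, 0], tau=0.0)
        res = normfinder_stability(m, sheet, list(m.assay_ids))
        assert np.allclose(res.stability, 0.0)

    def test_group_biased_gene_ranked_least_stable(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            m, sheet = build_cohort(
                rng, sigmas=[0.3, 0.3, 0.3, 0.3, 0.3], deltas=[0, 0, 0, 0, 1.0],
                n_case=40, n_control=20,
            )
            res = normfinder_stability(m, sheet, list(m.assay_ids))
            if res.stability.idxmax() == "g4":
                hits += 1
        assert hits >= 95

    def test_invariant_to_per_sample_shift(self, rng):
        m, sheet = build_cohort(rng, sigmas=[0.2, 0.4, 0.6], deltas=[0, 0.3, 0])
        shifted = CqMatrix(m.cq + rng.normal(0, 3, size=m.n_samples))
        a = normfinder_stability(m, sheet, list(m.assay_ids))
        b = normfinder_stability(shifted, sheet, list(m.assay_ids))
        assert np.allclose(a.stability, b.stability)

    def test_invariant_to_per_assay_location(self, rng):
        m, sheet = build_cohort(rng, sigmas=[0.2, 0.4, 0.6], deltas=[0, 0.3, 0])
        cq = m.cq.copy()
        cq.loc["g1"] += 5.0
        a = normfinder_stability(m, sheet, list(m.assay_ids))
        b = normfinder_stability(CqMatrix(cq), sheet, list(m.assay_ids))
        assert np.allclose(a.stability, b.stability)

    def test_group_differences_center_to_zero(self, rng):
        m, sheet = build_cohort(rng, sigmas=[0.2, 0.4, 0.6], deltas=[0.5, 0, -0.2])
        res = normfinder_stability(m, sheet, list(m.assay_ids))
        assert np.allclose(res.d.mean(axis=1), 0.0, atol=1e-12)

    def test_single_group_reduces_to_gene_sd(self, rng):
        names = ["g0", "g1", "g2", "g3"]
        sheet = SampleSheet(
            pd.DataFrame({"group": ["only"] * 30}, index=[f"s{i}" for i in range(30)])
        )
        loading = rng.normal(0, 0.5, 30)
        rows = {n: 20 + loading + rng.normal(0, 0.1 + 0.2 * i, 30) for i, n in enumerate(names)}
        m = CqMatrix(pd.DataFrame(rows, index=sheet.sample_ids).T)
        res = normfinder_stability(m, sheet, names)
        assert np.allclose(res.stability, np.sqrt(res.sigma2["only"]))

    def test_preconditions(self, rng):
        m, sheet = build_cohort(rng, sigmas=[0.2, 0.4], deltas=[0, 0])
        with pytest.raises(StatisticalError, match=">= 3 candidate"):
            normfinder_stability(m, sheet, list(m.assay_ids))
        m3, sheet3 = build_cohort(rng, sigmas=[0.2, 0.4, 0.3], deltas=[0, 0, 0])
        orphan = SampleSheet(
            pd.DataFrame({"group": ["cancer"]}, index=["cancer_0"])
        )
        with pytest.raises(InputError, match="without group labels"):
            normfinder_stability(m3, orphan, list(m3.assay_ids))
        cq = m3.cq.copy()
        cq.iloc[0, 0] = np.nan
        with pytest.raises(InputError, match="undetected"):
            normfinder_stability(CqMatrix(cq), sheet3, list(m3.assay_ids))


class TestBestPair:
    def test_opposite_bias_pair_beats_members(self, rng):
        m, sheet = build_cohort(
            rng, sigmas=[0.3, 0.3, 0.3, 0.3], deltas=[0.8, -0.8, 0.5, -0.5],
            n_case=40, n_control=40,
        )
        res = normfinder_stability(m, sheet, list(m.assay_ids))
        pairs = pair_table(res).set_index(["assay_1", "assay_2"])["stability"]
        combined = pairs.loc[("g0", "g1")]
        assert combined < res.stability["g0"]
        assert combined < res.stability["g1"]

    def test_duplicated_gene_pair_closed_form(self, rng):
        # duplicating a gene leaves its bias but halves its variance contribution
        m, sheet = build_cohort(rng, sigmas=[0.3, 0.4, 0.5], deltas=[0.4, 0, 0])
        cq = m.cq.copy()
        cq.loc["g0dup"] = cq.loc["g0"]
        res = normfinder_stability(CqMatrix(cq), sheet, ["g0", "g0dup", "g1", "g2"])
        pairs = pair_table(res).set_index(["assay_1", "assay_2"])["stability"]
        d = res.d_kept.loc["g0"]
        var_half = res.var_d.loc["g0"] / 2.0
        var_model_half = res.var_d_model.loc["g0"] / 2.0
        g2 = res.gamma2
        bias = (d * g2 / (g2 + var_half)).abs() if g2 > 0 else 0.0 * d
        expected = float((bias + np.sqrt(var_model_half)).mean())
        assert pairs.loc[("g0", "g0dup")] == pytest.approx(expected)

    def test_search_matches_bruteforce_enumeration(self, rng):
        m, sheet = build_cohort(
            rng, sigmas=[0.2, 0.3, 0.4, 0.5, 0.6, 0.7], deltas=[0, 0.2, 0, -0.3, 0, 0.1]
        )
        res = normfinder_stability(m, sheet, list(m.assay_ids))
        pairs = pair_table(res).set_index(["assay_1", "assay_2"])["stability"]

        def naive_pair(i, j):
            d_pair = (res.d_kept.loc[i] + res.d_kept.loc[j]) / 2.0
            var_pair = (res.var_d.loc[i] + res.var_d.loc[j]) / 4.0
            var_pair_m = (res.var_d_model.loc[i] + res.var_d_model.loc[j]) / 4.0
            sh = d_pair * (res.gamma2 / (res.gamma2 + var_pair)) if res.gamma2 > 0 else 0 * d_pair
            return float((sh.abs() + np.sqrt(var_pair_m)).mean())

        best, val = best_pair(res)
        naive = {
            tuple(sorted(p)): naive_pair(*sorted(p))
            for p in itertools.combinations(res.stability.index, 2)
        }
        assert val == pytest.approx(min(naive.values()))
        assert naive[tuple(sorted(best))] == pytest.approx(val)
        for p, v in naive.items():
            assert pairs.loc[p] == pytest.approx(v)


class TestVarianceRecovery:
    def test_sigma2_estimates_track_truth(self):
        """Median estimate over seeds within 25 % of the generating variance
        for moderately noisy genes (k = 5, n = 20 per group)."""
        sigmas = [0.4, 0.5, 0.6, 0.7, 0.8]
        draws = {n: [] for n in range(5)}
        for seed in range(150):
            rng = np.random.default_rng(seed)
            m, sheet = build_cohort(rng, sigmas=sigmas, deltas=[0] * 5, n_case=20, n_control=20)
            res = normfinder_stability(m, sheet, list(m.assay_ids))
            for i in range(5):
                draws[i].append(res.sigma2.loc[f"g{i}"].mean())
        for i, s in enumerate(sigmas):
            assert abs(np.median(draws[i]) - s**2) / s**2 < 0.25
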