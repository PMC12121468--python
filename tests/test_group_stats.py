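"""Cohort statistics: KW/Dunn, nested ANOVA, chi-square, Sholl contrasts."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from astromorph import (
    benjamini_hochberg,
    chi_square_distribution,
    cluster_proportions,
    complexity_score,
    dunn_bh,
    kruskal_wallis,
    nested_anova,
    sholl_profile_compare,
)
from astromorph.morphometry import ShollCurve


class TestKruskalWallis:
    def test_hand_evaluated_h(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2, abs=1e-9)
        assert res.df == 2

    def test_identical_groups_h_zero(self):
        res = kruskal_wallis([[2, 2], [2, 2], [2, 2]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_tie_correction_matches_definitional_formula(self):
        groups = [[1, 2, 2, 3], [2, 3, 3, 4], [4, 4, 5, 6]]
        res = kruskal_wallis(groups)
        pooled = np.concatenate(groups)
        ranks = sps.rankdata(pooled)
        N = len(pooled)
        sizes = [len(g) for g in groups]
        offsets = np.cumsum([0] + sizes)
        h = 12 / (N * (N + 1)) * sum(
            ranks[a:b].sum() ** 2 / n
            for a, b, n in zip(offsets[:-1], offsets[1:], sizes)
        ) - 3 * (N + 1)
        _, ties = np.unique(pooled, return_counts=True)
        correction = 1 - ((ties**3 - ties).sum()) / (N**3 - N)
        assert res.statistic == pytest.approx(h / correction, rel=1e-12)


class TestDunnBH:
    def test_three_groups_three_pairs(self):
        res = dunn_bh([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert len(res) == 3
        assert all(r.adjusted_p >= r.p_value - 1e-15 for r in res)

    def test_bh_step_up_hand_evaluation(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )

    def test_bh_monotone_in_rank(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=20)
        adj = benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_group_permutation_symmetry(self):
        groups = [[1.0, 3, 5], [2.0, 4, 9], [7.0, 8, 11]]
        res_a = dunn_bh(groups, names=["a", "b", "c"])
        res_b = dunn_bh(groups[::-1], names=["c", "b", "a"])
        pa = {frozenset(r.groups): round(r.p_value, 12) for r in res_a}
        pb = {frozenset(r.groups): round(r.p_value, 12) for r in res_b}
        assert pa == pb


class TestNestedAnova:
    @staticmethod
    def _balanced_toy(shift=5.0, mouse_sd=0.0, seed=0, cells=3):
        rng = np.random.default_rng(seed)
        values, geno, mouse = [], [], []
        for g, gname in enumerate(["WT", "TAU"]):
            for m in range(2):
                effect = rng.normal(0, mouse_sd)
                for _ in range(cells):
                    values.append(g * shift + effect + rng.normal())
                    geno.append(gname)
                    mouse.append(f"{gname}_m{m}")
        return np.array(values), np.array(geno), np.array(mouse)

    def test_matches_explicit_ss_arithmetic(self):
        y, geno, mouse = self._balanced_toy(seed=1)
        res = nested_anova(y, geno, mouse)
        grand = y.mean()
        ss_geno = sum(
            (geno == g).sum() * (y[geno == g].mean() - grand) ** 2
            for g in ("WT", "TAU")
        )
        ss_mouse = sum(
            (mouse == m).sum()
            * (y[mouse == m].mean() - y[geno == geno[mouse == m][0]].mean()) ** 2
            for m in np.unique(mouse)
        )
        f = (ss_geno / 1) / (ss_mouse / 2)
        assert res.statistic == pytest.approx(f, rel=1e-10)
        assert res.df == (1, 2)
        assert res.extra["ss_genotype"] == pytest.approx(ss_geno, rel=1e-10)

    def test_zero_mouse_variance_approaches_mouse_mean_anova(self):
        """With no mouse effect, F targets the one-way ANOVA on mouse means."""
        y, geno, mouse = self._balanced_toy(shift=2.0, seed=2, cells=200)
        res = nested_anova(y, geno, mouse)
        mouse_means = np.array([y[mouse == m].mean() for m in np.unique(mouse)])
        mouse_geno = np.array(
            [geno[mouse == m][0] for m in np.unique(mouse)]
        )
        f_ref, _ = sps.f_oneway(
            mouse_means[mouse_geno == "WT"], mouse_means[mouse_geno == "TAU"]
        )
        assert res.statistic == pytest.approx(f_ref, rel=0.05)

    def test_all_values_identical_reported_na(self):
        y = np.ones(12)
        geno = np.repeat(["WT", "TAU"], 6)
        mouse = np.repeat(["a", "b", "c", "d"], 3)
        res = nested_anova(y, geno, mouse)
        assert math.isnan(res.statistic)
        assert res.note is not None

    def test_cell_order_invariance(self):
        y, geno, mouse = self._balanced_toy(seed=3)
        res = nested_anova(y, geno, mouse)
        perm = np.random.default_rng(4).permutation(len(y))
        res2 = nested_anova(y[perm], geno[perm], mouse[perm])
        assert res2.statistic == pytest.approx(res.statistic, rel=1e-12)
        assert res2.extra["ss_mouse"] == pytest.approx(
            res.extra["ss_mouse"], rel=1e-12
        )

    def test_single_mouse_per_genotype_rejected(self):
        y = np.arange(6.0)
        geno = np.repeat(["WT", "TAU"], 3)
        mouse = np.repeat(["a", "b"], 3)
        with pytest.raises(ValueError, match="2 mice"):
            nested_anova(y, geno, mouse)

    def test_mouse_in_two_genotypes_rejected(self):
        y = np.arange(4.0)
        with pytest.raises(ValueError, match="genotype"):
            nested_anova(
                y, ["WT", "WT", "TAU", "TAU"], ["a", "b", "a", "c"]
            )


class TestChiSquare:
    def test_uniform_table_chi2_zero(self):
        res = chi_square_distribution(np.array([[10, 10], [10, 10]]))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_2x3_matches_definitional_sum(self):
        obs = np.array([[50, 40, 10], [10, 40, 50]])
        res = chi_square_distribution(obs)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        hand = ((obs - expected) ** 2 / expected).sum()
        assert res.statistic == pytest.approx(hand, rel=1e-12)
        assert res.statistic == pytest.approx(160 / 3, rel=1e-12)
        assert res.df == 2

    def test_doubling_counts_doubles_statistic(self):
        obs = np.array([[30, 20, 10], [10, 25, 25]])
        r1 = chi_square_distribution(obs)
        r2 = chi_square_distribution(2 * obs)
        assert r2.statistic == pytest.approx(2 * r1.statistic, rel=1e-12)

    def test_zero_margin_dropped(self):
        obs = np.array([[10, 0, 5], [8, 0, 7]])
        res = chi_square_distribution(obs)
        assert res.df == 1
        assert "dropped" in res.note


def _curves(counts_list):
    return [
        ShollCurve(
            radii=np.arange(1.0, len(c) + 1), counts=np.asarray(c, dtype=int)
        )
        for c in counts_list
    ]


class TestShollProfileCompare:
    def test_identical_distributions_nothing_significant(self):
        rng = np.random.default_rng(5)
        base = [rng.poisson(5, size=20) for _ in range(15)]
        out = sholl_profile_compare(
            {"WT": _curves(base), "TAU": _curves(base)}
        )
        assert out["significant_radii"] == []

    def test_localised_effect_detected_within_injected_radii(self):
        rng = np.random.default_rng(6)
        wt, tau = [], []
        for _ in range(40):
            profile = rng.poisson(6, size=25)
            wt.append(profile)
            boosted = profile.copy()
            boosted[13:19] += rng.poisson(6, size=6)  # radii 14..19
            tau.append(boosted)
        out = sholl_profile_compare({"WT": _curves(wt), "TAU": _curves(tau)})
        assert len(out["significant_radii"]) >= 5  # power at this effect size
        assert set(out["significant_radii"]) <= set(range(14, 20))

    def test_bonferroni_is_raw_p_times_radius_count(self):
        rng = np.random.default_rng(7)
        wt = [rng.poisson(5, size=10) for _ in range(10)]
        tau = [rng.poisson(5, size=10) for _ in range(10)]
        out = sholl_profile_compare({"WT": _curves(wt), "TAU": _curves(tau)})
        n = len(out["per_radius"])
        for res in out["per_radius"]:
            assert res.adjusted_p == pytest.approx(
                min(1.0, res.p_value * n), rel=1e-12
            )


class TestComplexityAndProportions:
    def test_complexity_orders_clusters(self):
        rng = np.random.default_rng(8)
        labels = np.repeat([1, 2], 30)
        z = pd.DataFrame(
            {
                "n_branching_points": np.repeat([1.0, -1.0], 30),
                "n_branches": np.repeat([1.0, -1.0], 30),
                "ramification_index": np.repeat([1.0, -1.0], 30),
            }
        ) + 0.05 * rng.standard_normal((60, 3))
        out = complexity_score(labels, z)
        assert out.loc[1, "complexity_label"] == "high"
        assert out.loc[2, "complexity_label"] == "low"

    def test_relabeling_clusters_permutes_ranks(self):
        rng = np.random.default_rng(9)
        labels = np.repeat([1, 2, 3], 20)
        z = pd.DataFrame(
            rng.standard_normal((60, 3)),
            columns=["n_branching_points", "n_branches", "ramification_index"],
        )
        out1 = complexity_score(labels, z)
        swap = {1: 3, 2: 1, 3: 2}
        out2 = complexity_score(np.array([swap[c] for c in labels]), z)
        for old, new in swap.items():
            assert out1.loc[old, "complexity_rank"] == out2.loc[new, "complexity_rank"]

    def test_proportions_sum_to_100(self):
        labels = np.array([1] * 95 + [2] * 3 + [3] * 2)
        meta = pd.DataFrame({"genotype": ["WT"] * 100})
        props = cluster_proportions(labels, meta)
        assert props["percent"].sum() == pytest.approx(100.0, abs=1e-9)
        assert props.loc[props["cluster"] == 1, "percent"].iloc[0] == 95.0

    def test_mixture_recovered_within_binomial_ci(self):
        rng = np.random.default_rng(10)
        mix = np.array([0.75, 0.18, 0.07])
        labels = rng.choice([1, 2, 3], p=mix, size=400)
        meta = pd.DataFrame({"genotype": ["WT"] * 400})
        props = cluster_proportions(labels, meta).set_index("cluster")
        for c, p in zip([1, 2, 3], mix):
            se = math.sqrt(p * (1 - p) / 400)
            assert abs(props.loc[c, "percent"] / 100 - p) < 1.96 * se * 1.5
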