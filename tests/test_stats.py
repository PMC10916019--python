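"""Kruskal-Wallis / Dunn group comparison and box summaries."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

import flagellabeat as fb


def kw_brute(groups):
    """Independent H computation: explicit midranks + tie correction."""
    pooled = np.concatenate(groups)
    n_total = pooled.size
    order = np.argsort(pooled, kind="mergesort")
    sorted_vals = pooled[order]
    r = np.empty(n_total)
    i = 0
    while i < n_total:
        j = i
        while j < n_total and sorted_vals[j] == sorted_vals[i]:
            j += 1
        r[i:j] = (i + j + 1) / 2.0  # midrank of the tied block
        i = j
    ranks = np.empty(n_total)
    ranks[order] = r
    h = 0.0
    start = 0
    for g in groups:
        mean_rank = np.mean(ranks[start: start + len(g)])
        h += len(g) * (mean_rank - (n_total + 1) / 2.0) ** 2
        start += len(g)
    h *= 12.0 / (n_total * (n_total + 1))
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n_total**3 - n_total)
    return h / correction


class TestKruskalWallis:
    def test_matches_brute_force_rank_computation(self):
        groups = [np.array([1.0, 2.0, 3.0]), np.array([101.0, 102.0, 103.0])]
        h, p = fb.kruskal_wallis(groups)
        assert h == pytest.approx(kw_brute(groups), rel=1e-12)
        assert h == pytest.approx(12.0 * 13.5 / 42.0, rel=1e-12)  # hand rank sums

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(0)
        groups = [rng.integers(0, 5, size=n).astype(float) for n in (8, 12, 5)]
        h, p = fb.kruskal_wallis(groups)
        assert h == pytest.approx(kw_brute(groups), rel=1e-10)
        assert p == pytest.approx(scipy.stats.chi2.sf(h, 2), rel=1e-12)

    def test_all_identical_observations_degenerate(self):
        h, p = fb.kruskal_wallis([np.array([2.0, 2.0]), np.array([2.0, 2.0])])
        assert (h, p) == (0.0, 1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.normal(0, 1, n) for n in (5, 7, 6)]
        h1, p1 = fb.kruskal_wallis(groups)
        h2, p2 = fb.kruskal_wallis([np.exp(g) for g in groups])
        assert h1 == pytest.approx(h2, rel=1e-9)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            fb.kruskal_wallis([np.array([1.0, 2.0])])
        with pytest.raises(ValueError):
            fb.kruskal_wallis([np.array([1.0]), np.array([])])
        with pytest.raises(ValueError):
            fb.kruskal_wallis([np.array([1.0]), np.array([2.0])])  # total n < 3

    def test_null_p_values_are_uniform(self):
        """Exchangeable groups: KS test cannot reject uniformity of p."""
        rng = np.random.default_rng(2024)
        pvals = []
        for _ in range(2000):
            pooled = rng.lognormal(0, 0.3, 43)
            _, p = fb.kruskal_wallis([pooled[:26], pooled[26:]])
            pvals.append(p)
        ks = scipy.stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestDunnPosthoc:
    def test_two_groups_reduce_to_rank_sum_normal_approximation(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 9)
        p_dunn = fb.dunn_posthoc([a, b], adjust="none")[(0, 1)]
        # normal-approximation rank-sum p computed from first principles
        pooled = np.concatenate([a, b])
        ranks = scipy.stats.rankdata(pooled)
        n1, n2 = len(a), len(b)
        n = n1 + n2
        w = ranks[:n1].sum()
        z = (w - n1 * (n + 1) / 2.0) / np.sqrt(n1 * n2 * (n + 1) / 12.0)
        p_ranksum = 2.0 * scipy.stats.norm.sf(abs(z))
        assert p_dunn == pytest.approx(p_ranksum, abs=1e-9)

    def test_identical_groups_give_p_one(self):
        same = np.array([1.0, 1.0, 1.0])
        out = fb.dunn_posthoc([same, same, same])
        assert all(p == 1.0 for p in out.values())

    def test_bonferroni_never_below_unadjusted(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1, 8) for m in (0, 0.5, 2.0)]
        raw = fb.dunn_posthoc(groups, adjust="none")
        adj = fb.dunn_posthoc(groups, adjust="bonferroni")
        for pair in raw:
            assert adj[pair] >= raw[pair]
        # with a single pair the two adjustments coincide
        raw2 = fb.dunn_posthoc(groups[:2], adjust="none")
        adj2 = fb.dunn_posthoc(groups[:2], adjust="bonferroni")
        assert raw2[(0, 1)] == adj2[(0, 1)]

    def test_large_shift_detected_only_in_shifted_pairs(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 15)
        b = rng.normal(0, 1, 15)
        c = rng.normal(50, 1, 15)  # far-shifted group
        out = fb.dunn_posthoc([a, b, c])
        assert out[(0, 2)] < 0.001 and out[(1, 2)] < 0.001
        assert out[(0, 1)] > 0.05

    def test_unknown_adjustment_rejected(self):
        with pytest.raises(ValueError):
            fb.dunn_posthoc([np.arange(3.0), np.arange(3.0)], adjust="holm")


class TestSummarizeBox:
    def test_symmetric_set(self):
        s = fb.summarize_box(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert (s.mean, s.median, s.q1, s.q3, s.min, s.max) == (3, 3, 2, 4, 1, 5)

    def test_singleton(self):
        s = fb.summarize_box(np.array([0.6]))
        assert s.mean == s.median == s.q1 == s.q3 == s.min == s.max == 0.6

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fb.summarize_box(np.array([]))

    def test_cohort_jitter_summaries_match_generator(self):
        """1000 jittered cells: low-band mean/CV reproduce 0.6 nN / 0.33."""
        tab = fb.simulate_band_force_table(
            {"linear": 1000}, {"linear": fb.default_linear_profile()}, seed=8
        )
        s = fb.summarize_box(tab.band_0_2_nN.to_numpy())
        assert s.mean == pytest.approx(0.6, rel=0.10)
        cv = tab.band_0_2_nN.std() / tab.band_0_2_nN.mean()
        assert cv == pytest.approx(0.33, rel=0.10)


class TestCompareBands:
    def test_linear_beats_circular_in_every_band(self):
        profiles = {
            "linear": fb.default_linear_profile(),
            "circular": fb.default_circular_profile(),
        }
        tab = fb.simulate_band_force_table({"linear": 26, "circular": 17}, profiles, seed=6)
        results = fb.compare_bands(tab, "group")
        assert len(results) == 10
        for res in results:
            by_name = {g.name: g for g in res.groups}
            comp_bands = {"0–2 Hz", "3–5 Hz", "6–8 Hz", "9–11 Hz", "12–14 Hz", "24–26 Hz"}
            if res.band_label in comp_bands:
                assert by_name["linear"].median > by_name["circular"].median
            for g in res.groups:
                assert g.q1 <= g.median <= g.q3
        low = [r for r in results if r.band_label == "0–2 Hz"][0]
        assert list(low.stars.values())[0] in ("*", "**", "***")

    def test_null_grouping_stars_at_alpha_rate(self):
        profiles = {"a": fb.default_linear_profile(), "b": fb.default_linear_profile()}
        starred = 0
        n_sims = 300
        for s in range(n_sims):
            tab = fb.simulate_band_force_table({"a": 26, "b": 17}, profiles, seed=s)
            ga = tab.loc[tab.group == "a", "band_0_2_nN"].to_numpy()
            gb = tab.loc[tab.group == "b", "band_0_2_nN"].to_numpy()
            if fb.dunn_posthoc([ga, gb])[(0, 1)] <= 0.05:
                starred += 1
        assert 0.01 < starred / n_sims < 0.10

    def test_degenerate_single_cell_groups_error_cleanly(self):
        tab = fb.simulate_band_force_table(
            {"a": 1, "b": 1}, {"a": fb.default_linear_profile(), "b": fb.default_linear_profile()},
            seed=0,
        )
        with pytest.raises(ValueError):
            fb.compare_bands(tab, "group")

    def test_missing_band_column_rejected(self):
        tab = fb.simulate_band_force_table(
            {"a": 3, "b": 3}, {"a": fb.default_linear_profile(), "b": fb.default_linear_profile()},
            seed=0,
        ).drop(columns=["band_27_29_nN"])
        with pytest.raises(ValueError, match="band_27_29_nN"):
            fb.compare_bands(tab, "group")

    def test_star_thresholds(self):
        assert fb.star_label(0.04) == "*"
        assert fb.star_label(0.009) == "**"
        assert fb.star_label(0.0005) == "***"
        assert fb.star_label(0.2) == "ns"
        assert fb.star_label(0.05) == "*"
        assert fb.star_label(0.01) == "**"
        assert fb.star_label(0.001) == "***"

    def test_results_frame_layout(self):
        profiles = {
            "linear": fb.default_linear_profile(),
            "circular": fb.default_circular_profile(),
        }
        tab = fb.simulate_band_force_table({"linear": 10, "circular": 10}, profiles, seed=1)
        frame = fb.results_to_frame(fb.compare_bands(tab, "group"))
        assert len(frame) == 10  # 10 bands x 1 pair
        assert {"band", "kw_H", "kw_p", "dunn_p_adj", "stars"} <= set(frame.columns)
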