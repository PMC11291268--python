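"""Normalization, ΔBRET, rank statistics and biomarker ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from gnao1kit.association import (
    PValueMethod,
    UndefinedCorrelationError,
    delta_bret,
    localization_ratio,
    mann_whitney,
    normalize_to_wildtype,
    rank_biomarkers,
    spearman,
)
from oracles import mann_whitney_oracle, spearman_oracle


class TestLocalizationRatio:
    def test_direct_and_identity(self):
        assert localization_ratio(50.0, 100.0) == 0.5
        assert localization_ratio(73.2, 73.2) == 1.0

    def test_batch_matches_hand_computed(self, rng):
        region = rng.uniform(0, 200, size=10)
        total = rng.uniform(50, 300, size=10)
        got = [localization_ratio(r, t) for r, t in zip(region, total)]
        np.testing.assert_allclose(got, region / total, rtol=1e-15)

    def test_nonpositive_total_rejected(self):
        with pytest.raises(ValueError):
            localization_ratio(10.0, 0.0)


class TestDeltaBret:
    def _series(self, step=0.0, offset=0.0):
        times = np.arange(0.0, 80.0, 1.6)
        ratios = np.full_like(times, 1.0 + offset)
        ratios[times > 30.0] += step
        return times, ratios

    def test_null_change(self):
        t, r = self._series()
        assert delta_bret(t, r, injection_time=30.0) == pytest.approx(0.0, abs=1e-15)

    def test_step_recovered(self):
        t, r = self._series(step=0.05)
        assert delta_bret(t, r, injection_time=30.0) == pytest.approx(0.05)

    def test_shift_invariance(self):
        t, r = self._series(step=0.05)
        _, r_shift = self._series(step=0.05, offset=0.37)
        assert delta_bret(t, r, 30.0) == pytest.approx(delta_bret(t, r_shift, 30.0))

    def test_empty_window_rejected(self):
        t, r = self._series()
        with pytest.raises(ValueError):
            delta_bret(t, r, injection_time=30.0, pre_window=0.5)


class TestNormalizeToWildtype:
    def _table(self):
        return pd.DataFrame(
            {"expression": [2.0, 0.7], "gbg_coip": [4.0, 1.0],
             "onset_median_days": [1000.0, 43.0]},
            index=pd.Index(["WT", "L199P"], name="variant"),
        )

    def test_reference_row_becomes_unity(self):
        out = normalize_to_wildtype(self._table(), "WT")
        assert (out.loc["WT", ["expression", "gbg_coip"]] == 1.0).all()
        assert out.loc["L199P", "expression"] == pytest.approx(0.35)
        # onset column untouched
        assert out["onset_median_days"].equals(self._table()["onset_median_days"])

    def test_idempotent(self):
        once = normalize_to_wildtype(self._table(), "WT")
        twice = normalize_to_wildtype(once, "WT")
        pd.testing.assert_frame_equal(once, twice)

    def test_zero_or_missing_reference_rejected(self):
        table = self._table()
        with pytest.raises(KeyError):
            normalize_to_wildtype(table, "nope")
        table.loc["WT", "expression"] = 0.0
        with pytest.raises(ValueError):
            normalize_to_wildtype(table, "WT")


class TestSpearman:
    def test_perfect_monotone(self):
        up = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert up.r_s == pytest.approx(1.0)
        down = spearman([1, 2, 3, 4], [40, 30, 20, 10])
        assert down.r_s == pytest.approx(-1.0)
        assert up.method is PValueMethod.EXACT_PERMUTATION

    def test_tied_input_matches_brute_force(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [2.0, 1.0, 4.0, 4.0, 6.0, 5.0]  # one tie pair
        res = spearman(x, y)
        r_ref, p_ref = spearman_oracle(x, y)
        assert res.r_s == pytest.approx(r_ref, abs=1e-12)
        assert res.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_monte_carlo_band_contains_exact_answer(self, rng):
        x = rng.normal(size=10)
        y = 0.8 * x + rng.normal(size=10)
        res = spearman(x, y)
        assert res.method is PValueMethod.MONTE_CARLO_PERMUTATION
        ref = sps.spearmanr(x, y)
        assert res.r_s == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, abs=0.02)

    def test_t_approximation_matches_reference(self, rng):
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20)
        res = spearman(x, y)
        assert res.method is PValueMethod.T_APPROXIMATION
        ref = sps.spearmanr(x, y)
        assert res.r_s == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    @given(
        st.lists(st.integers(-50, 50), min_size=5, max_size=5, unique=True),
        st.data(),
    )
    def test_invariant_under_monotone_transforms(self, x, data):
        y = data.draw(
            st.lists(st.integers(-50, 50), min_size=5, max_size=5, unique=True)
        )
        base = spearman(x, y)
        transformed = spearman(np.exp(np.asarray(x) / 25.0), 3.0 * np.asarray(y) + 7.0)
        assert transformed.r_s == pytest.approx(base.r_s, abs=1e-9)
        assert transformed.p_value == pytest.approx(base.p_value, abs=1e-9)


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.method is PValueMethod.EXACT_PERMUTATION
        assert res.p_value == 1.0

    def test_complete_separation_small_n(self):
        res = mann_whitney([1, 2, 3], [10, 20, 30])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2 of C(6,3)=20 assignments

    def test_exact_path_matches_scipy(self, rng):
        for _ in range(25):
            a = rng.integers(0, 6, size=rng.integers(2, 6)).astype(float)
            b = rng.integers(0, 6, size=rng.integers(2, 6)).astype(float)
            res = mann_whitney(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert res.statistic == pytest.approx(ref.statistic)
            if np.unique(np.concatenate([a, b])).size == a.size + b.size:
                # scipy's exact method is only exact without ties
                assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_matches_scipy(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(loc=0.5, size=25)
        res = mann_whitney(a, b)
        assert res.method is PValueMethod.NORMAL_APPROXIMATION
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_power_exceeds_alpha_under_shift(self, rng):
        # 1-s.d. location shift at n=15/group must reject more often than 5%
        hits = 0
        n_sim = 400
        for _ in range(n_sim):
            a = rng.normal(size=15)
            b = rng.normal(loc=1.0, size=15)
            if mann_whitney(a, b).p_value <= 0.05:
                hits += 1
        assert hits / n_sim > 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestSmallSampleOracles:
    @given(st.data())
    def test_spearman_matches_enumeration(self, data):
        n = data.draw(st.integers(min_value=3, max_value=6))
        pool = st.integers(min_value=0, max_value=8)
        x = data.draw(st.lists(pool, min_size=n, max_size=n))
        y = data.draw(st.lists(pool, min_size=n, max_size=n))
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        res = spearman(x, y)
        r_ref, p_ref = spearman_oracle(x, y)
        assert res.r_s == pytest.approx(r_ref, abs=1e-12)
        assert res.p_value == pytest.approx(p_ref, abs=1e-12)

    @given(st.data())
    def test_mann_whitney_matches_enumeration(self, data):
        n1 = data.draw(st.integers(min_value=1, max_value=5))
        n2 = data.draw(st.integers(min_value=1, max_value=5))
        pool = st.integers(min_value=0, max_value=6)
        a = np.array(data.draw(st.lists(pool, min_size=n1, max_size=n1)), float)
        b = np.array(data.draw(st.lists(pool, min_size=n2, max_size=n2)), float)
        res = mann_whitney(a, b)
        u_ref, p_ref = mann_whitney_oracle(a, b)
        assert res.statistic == pytest.approx(u_ref)
        assert res.p_value == pytest.approx(p_ref, abs=1e-12)


class TestRankBiomarkers:
    def _table(self, rng, n=8, informative="ric8b_coip"):
        onset = np.sort(rng.uniform(3, 900, size=n))
        data = {
            informative: 2.0 - onset / onset.max(),  # strictly decreasing
            "noise_a": rng.normal(size=n),
            "noise_b": rng.normal(size=n),
        }
        return pd.DataFrame(
            data | {"onset_median_days": onset},
            index=pd.Index([f"M{i}" for i in range(n)], name="variant"),
        )

    def test_noiseless_monotone_metric_ranks_first(self, rng):
        table = self._table(rng)
        ranking = rank_biomarkers(table)
        assert ranking[0].metric == "ric8b_coip"
        assert ranking[0].result.r_s == pytest.approx(-1.0)

    def test_invariant_to_row_and_column_order(self, rng):
        table = self._table(rng)
        shuffled = table.sample(frac=1.0, random_state=1)[list(table.columns)[::-1]]
        a = [(r.metric, r.abs_r) for r in rank_biomarkers(table)]
        b = [(r.metric, r.abs_r) for r in rank_biomarkers(shuffled)]
        assert a == b

    def test_constant_metric_flagged_not_dropped(self, rng):
        table = self._table(rng)
        table["flatline"] = 1.0
        ranking = rank_biomarkers(table)
        flat = [r for r in ranking if r.metric == "flatline"]
        assert len(flat) == 1 and flat[0].result is None and flat[0].error
        assert ranking[-1].metric == "flatline"

    def test_holm_adjustment_only_raises_p(self, rng):
        table = self._table(rng, n=14)
        plain = {r.metric: r.result.p_value for r in rank_biomarkers(table)}
        holm = {r.metric: r.result.p_value for r in rank_biomarkers(table, holm=True)}
        for metric in plain:
            assert holm[metric] >= plain[metric] - 1e-15
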