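"""Tests for psi averaging, ANOVA, post-hoc tests and the pooled
lateralization summary."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from psilat import stats as st_mod
from psilat.stats import (
    BONFERRONI_COMPARISONS,
    POSTHOC_ALPHA,
    LateralizationSummary,
    binomial_tail,
    count_favorable,
    electrode_stage_means,
    electrode_window_means,
    hemisphere_stage_means,
    lateralization_percent,
    mannwhitney_posthoc,
    summarize_lateralization,
    two_way_anova,
)

from _reference import balanced_anova_2way, mannwhitney_exact_enumeration


def make_profile(rows):
    return pd.DataFrame(rows, columns=["channel_id", "electrode", "hemisphere", "modality",
                                       "window_index", "stage", "psi", "excluded"])


class TestElectrodeMeans:
    def test_constant_channels(self):
        rows = [(f"E-b{c}", "EL", "L", "macro", w, "W", 0.7, False)
                for c in range(1, 4) for w in range(5)]
        sm = electrode_stage_means(make_profile(rows))
        assert sm["psi"].iloc[0] == pytest.approx(0.7)
        assert sm["sem"].iloc[0] == pytest.approx(0.0)

    def test_two_channels_average(self):
        rows = [("E-b1", "EL", "L", "macro", 0, "W", 0.0, False),
                ("E-b2", "EL", "L", "macro", 0, "W", 1.0, False)]
        wm = electrode_window_means(make_profile(rows))
        assert wm["psi"].iloc[0] == pytest.approx(0.5)

    def test_matches_nested_loop_average(self, rng):
        rows = []
        psis = {}
        for e in ("AL", "BL"):
            for c in range(1, 4):
                for w in range(6):
                    v = float(rng.normal())
                    psis[(e, c, w)] = v
                    rows.append((f"{e}-b{c}", e, "L", "macro", w, "N2", v, False))
        sm = electrode_stage_means(make_profile(rows))
        for e in ("AL", "BL"):
            per_window = [np.mean([psis[(e, c, w)] for c in range(1, 4)]) for w in range(6)]
            expected = np.mean(per_window)
            got = sm.loc[sm["electrode"] == e, "psi"].iloc[0]
            assert got == pytest.approx(expected, abs=1e-12)

    def test_excluded_windows_never_enter_means(self, rng):
        rows = [("E-b1", "EL", "L", "macro", w, "W", float(rng.normal()), False)
                for w in range(5)]
        base = electrode_stage_means(make_profile(rows))
        rows_extra = rows + [("E-b1", "EL", "L", "macro", 99, "W", 1e6, True)]
        with_excluded = electrode_stage_means(make_profile(rows_extra))
        assert with_excluded["psi"].iloc[0] == pytest.approx(base["psi"].iloc[0])


class TestHemisphereMeans:
    def test_simple_average(self):
        sm = pd.DataFrame({"electrode": ["AL", "BL"], "hemisphere": ["L", "L"],
                           "stage": ["W", "W"], "psi": [0.1, 0.3]})
        hm = hemisphere_stage_means(sm)
        assert hm["psi"].iloc[0] == pytest.approx(0.2)

    def test_unweighted_by_channel_count(self, rng):
        # hemisphere mean of electrode means differs from the pooled
        # channel mean when electrodes contribute unequal channel counts
        rows = []
        for c in range(1, 8):  # electrode A: 7 channels of psi = 1
            rows.append((f"A-b{c}", "AL", "L", "macro", 0, "W", 1.0, False))
        rows.append(("B-b1", "BL", "L", "macro", 0, "W", 0.0, False))  # 1 channel
        profile = make_profile(rows)
        sm = electrode_stage_means(profile).assign(modality="macro")
        hm = hemisphere_stage_means(sm)
        assert hm["psi"].iloc[0] == pytest.approx(0.5)      # (1 + 0) / 2
        pooled = profile["psi"].mean()                       # 7/8
        assert hm["psi"].iloc[0] != pytest.approx(pooled)


def make_anova_frame(y):
    a, b, n = y.shape
    rows = []
    for i, hemi in enumerate(("L", "R")[:a]):
        for j, stage in enumerate(("W", "REM", "N1", "N2", "N3")[:b]):
            for v in y[i, j]:
                rows.append({"hemisphere": hemi, "stage": stage, "psi": float(v)})
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_identical_observations(self):
        y = np.full((2, 5, 3), 0.25)
        ps = two_way_anova(make_anova_frame(y), "L")
        assert ps["location"] == ps["stage"] == ps["interaction"] == 1.0
        assert ps["F_location"] == 0.0

    def test_balanced_design_matches_closed_form(self, rng):
        cell_means = rng.normal(0.0, 0.5, size=(2, 5))
        y = cell_means[:, :, None] + rng.normal(0.0, 1.0, size=(2, 5, 50))
        got = two_way_anova(make_anova_frame(y), "L")
        ref = balanced_anova_2way(y)
        assert got["F_location"] == pytest.approx(ref["F_a"], abs=1e-8)
        assert got["F_stage"] == pytest.approx(ref["F_b"], abs=1e-8)
        assert got["F_interaction"] == pytest.approx(ref["F_ab"], abs=1e-8)
        assert got["location"] == pytest.approx(ref["p_a"], abs=1e-10)

    def test_large_location_effect(self, rng):
        y = rng.normal(0.0, 1.0, size=(2, 5, 40))
        y[0] += 5.0  # 5-sigma shift of the SOZ hemisphere
        ps = two_way_anova(make_anova_frame(y), "L")
        assert ps["location"] < 1e-10

    def test_empty_level_rejected(self, rng):
        df = make_anova_frame(rng.normal(size=(2, 5, 4)))
        df = df[df["hemisphere"] == "L"]
        with pytest.raises(ValueError, match="location"):
            two_way_anova(df, "L")

    def test_null_rejection_rate_calibrated(self, rng):
        # global null: location effect should reject at about the nominal
        # 5% rate
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            y = rng.normal(size=(2, 5, 8))
            ps = two_way_anova(make_anova_frame(y), "L")
            rejections += ps["location"] < 0.05
        rate = rejections / n_rep
        assert 0.05 - 0.025 <= rate <= 0.05 + 0.025


class TestMannWhitney:
    def test_bonferroni_threshold(self):
        assert BONFERRONI_COMPARISONS == 50
        assert POSTHOC_ALPHA == pytest.approx(0.001)

    def test_identical_groups(self):
        df = pd.DataFrame({
            "hemisphere": ["L"] * 25 + ["R"] * 25,
            "stage": ["W"] * 50,
            "psi": list(range(25)) * 2,
        })
        out = mannwhitney_posthoc(df, "L")
        row = out[out["stage"] == "W"].iloc[0]
        assert row["U"] == pytest.approx(25 * 25 / 2)
        assert row["p"] > 0.99
        assert not row["significant"]

    def test_extreme_groups_match_enumeration(self):
        df = pd.DataFrame({
            "hemisphere": ["L"] * 3 + ["R"] * 3,
            "stage": ["N2"] * 6,
            "psi": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        })
        out = mannwhitney_posthoc(df, "L")
        row = out[out["stage"] == "N2"].iloc[0]
        u_ref, p_ref = mannwhitney_exact_enumeration([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert row["U"] == pytest.approx(u_ref)
        assert row["p"] == pytest.approx(p_ref)

    def test_small_group_skipped(self):
        df = pd.DataFrame({"hemisphere": ["L", "R", "R"], "stage": ["W"] * 3,
                           "psi": [0.1, 0.2, 0.3]})
        out = mannwhitney_posthoc(df, "L")
        assert out.empty or "W" not in set(out["stage"])


class TestBinomialTail:
    @pytest.mark.parametrize("s,n,expected", [
        (95, 140, 1.4e-5),
        (93, 140, 6.3e-5),
        (19, 25, 7.3e-3),
        (23, 25, 9.7e-6),
    ])
    def test_pooled_comparison_probabilities(self, s, n, expected):
        p = binomial_tail(s, n)
        assert float(f"{p:.1e}") == pytest.approx(expected)

    def test_exact_fraction_23_of_25(self):
        # sum of C(25, k) for k = 23..25 is 300 + 25 + 1 = 326
        assert binomial_tail(23, 25) == 326 / 2**25

    def test_full_distribution(self):
        assert binomial_tail(0, 17) == 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(1, 60).flatmap(lambda n: st.tuples(st.just(n), st.integers(0, n - 1))))
    def test_point_mass_identity(self, sn):
        # tail(s) - tail(s+1) equals the point mass C(n,s)/2^n; the
        # subtraction of two floats near 1 limits attainable precision
        n, s = sn
        diff = binomial_tail(s, n) - binomial_tail(s + 1, n)
        assert diff == pytest.approx(comb(n, s) / 2**n, abs=1e-15)


class TestPercent:
    @pytest.mark.parametrize("s,n,expected", [
        (95, 140, 67.9), (93, 140, 66.4), (19, 25, 76.0), (23, 25, 92.0), (0, 10, 0.0),
    ])
    def test_printed_percentages(self, s, n, expected):
        assert lateralization_percent(s, n) == expected

    def test_half_up_rounding(self):
        assert lateralization_percent(1, 16) == 6.3  # 6.25 rounds up
        with pytest.raises(ValueError):
            lateralization_percent(0, 0)


class TestCountFavorable:
    def _stage_means(self):
        rows = []
        # two paired electrodes (AH, EC), five stages; SOZ side L greater
        # except EC during REM (tie) and EC during W (lower)
        for stage in ("W", "REM", "N1", "N2", "N3"):
            for label in ("AH", "EC"):
                left = 0.5
                right = 0.1
                if label == "EC" and stage == "REM":
                    left = right = 0.2
                if label == "EC" and stage == "W":
                    left, right = 0.1, 0.4
                rows.append({"electrode": f"{label}L", "hemisphere": "L", "stage": stage,
                             "psi": left, "modality": "macro"})
                rows.append({"electrode": f"{label}R", "hemisphere": "R", "stage": stage,
                             "psi": right, "modality": "macro"})
        return pd.DataFrame(rows)

    def test_manual_enumeration(self):
        sm = self._stage_means()
        fav, tot = count_favorable(sm, "L", level="electrode")
        # 10 comparisons; EC loses W, ties REM (tie counts unfavorable)
        assert (fav, tot) == (8, 10)

    def test_all_favorable(self):
        sm = self._stage_means()
        sm.loc[sm["hemisphere"] == "L", "psi"] = 9.0
        fav, tot = count_favorable(sm, "L", level="electrode")
        assert fav == tot == 10

    def test_hemisphere_level(self):
        sm = self._stage_means()
        fav, tot = count_favorable(sm, "L", level="hemisphere")
        assert tot == 5
        # hemisphere means: L beats R except in W ((0.5+0.1)/2 = 0.3 > 0.25 ok)
        assert fav == 5

    def test_unpaired_electrode_excluded(self):
        sm = self._stage_means()
        sm = pd.concat([sm, pd.DataFrame([{"electrode": "PHL", "hemisphere": "L",
                                           "stage": "W", "psi": 3.0, "modality": "macro"}])],
                       ignore_index=True)
        fav, tot = count_favorable(sm, "L", level="electrode")
        assert tot == 10  # the unpaired PHL adds no comparison


class TestSummary:
    def test_summary_fields(self):
        s = LateralizationSummary(level="electrode", modality="macro",
                                  n_favorable=95, n_total=140)
        assert s.percent == 67.9
        assert float(f"{s.p_binomial:.1e}") == pytest.approx(1.4e-5)

    def test_summarize_covers_levels_and_modalities(self):
        rows = []
        for modality in ("macro", "micro"):
            for stage in ("W", "N2"):
                for label in ("AH",):
                    rows.append({"electrode": f"{label}L", "hemisphere": "L", "stage": stage,
                                 "psi": 0.4, "modality": modality})
                    rows.append({"electrode": f"{label}R", "hemisphere": "R", "stage": stage,
                                 "psi": 0.1, "modality": modality})
        out = summarize_lateralization(pd.DataFrame(rows), "L")
        keys = {(s.level, s.modality) for s in out}
        assert keys == {("electrode", "macro"), ("electrode", "micro"),
                        ("hemisphere", "macro"), ("hemisphere", "micro")}
        assert all(s.n_favorable == s.n_total for s in out)
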