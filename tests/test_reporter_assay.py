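import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from miraudit import reporter_assay as ra
from miraudit.errors import ValidationError
from miraudit.io_formats import EMPTY_VECTOR

from conftest import make_plate

finite_floats = st.floats(min_value=-50, max_value=50, allow_nan=False,
                          width=32)


class TestRelativeActivity:
    def test_normalization_identity(self):
        # reporter ratios identical to control ratios -> activity 1.0
        plate = make_plate({"rep-a": ("miR-A-5p", 1.0)})
        act = ra.relative_activity(plate)
        assert np.allclose(act.per_bio["activity"], 1.0)

    def test_arithmetic(self):
        # control ratio 2.0, reporter ratio 0.4 -> relative activity 0.2
        plate = make_plate({"rep-a": ("miR-A-5p", 0.2)}, control_ratio=2.0)
        act = ra.relative_activity(plate)
        summary = act.summary.set_index("reporter_id")
        assert summary.loc["rep-a", "mean_activity"] == pytest.approx(0.2)

    def test_empty_vector_activity_exactly_one(self):
        plate = make_plate({"rep-a": ("miR-A-5p", 0.3)}, noise=0.1)
        act = ra.relative_activity(plate)
        ev = act.per_bio[act.per_bio["target_mirna"] == EMPTY_VECTOR]
        assert np.allclose(ev["activity"], 1.0)

    def test_scaling_a_bio_rep_changes_nothing(self):
        plate = make_plate({"rep-a": ("miR-A-5p", 0.4)}, noise=0.05)
        scaled = plate.measurements.copy()
        sel = scaled["bio_rep"] == 2
        scaled.loc[sel, ["firefly", "renilla"]] *= 7.5
        from miraudit.io_formats import ReporterDataset
        act1 = ra.relative_activity(plate)
        act2 = ra.relative_activity(ReporterDataset(measurements=scaled))
        pd.testing.assert_frame_equal(act1.per_bio, act2.per_bio)

    def test_bio_rep_without_control_errors(self):
        plate = make_plate({"rep-a": ("miR-A-5p", 0.4)})
        df = plate.measurements
        df = df[~((df["target_mirna"] == EMPTY_VECTOR) & (df["bio_rep"] == 3))]
        from miraudit.io_formats import ReporterDataset
        with pytest.raises(ValidationError, match=r"\[3\]"):
            ra.relative_activity(ReporterDataset(measurements=df.reset_index(drop=True)))

    def test_single_bio_rep_sem_unknown(self):
        plate = make_plate({"rep-a": ("miR-A-5p", 0.4)}, n_bio=1)
        act = ra.relative_activity(plate)
        s = act.summary.set_index("reporter_id").loc["rep-a"]
        assert s["n_bio"] == 1 and math.isnan(s["sem"])


class TestGroupControl:
    @pytest.fixture
    def activities(self):
        plate = make_plate(
            {
                "rep-low1": ("miR-low1", 0.8),
                "rep-low2": ("miR-low2", 1.1),
                "rep-low3": ("miR-low3", 0.95),
                "rep-hi": ("miR-hi", 0.1),
            }
        )
        return ra.relative_activity(plate)

    CPM = {"miR-low1": 3.0, "miR-low2": 12.0, "miR-low3": 19.9, "miR-hi": 5000.0}

    def test_band_is_min_max_of_member_means(self, activities):
        band = ra.build_group_control(activities, self.CPM)
        assert set(band.member_ids) == {"rep-low1", "rep-low2", "rep-low3"}
        assert band.lower == pytest.approx(0.8)
        assert band.upper == pytest.approx(1.1)

    def test_pooled_n_is_sum_of_member_bio_counts(self, activities):
        band = ra.build_group_control(activities, self.CPM)
        assert band.pooled.size == 3 * 3  # 3 members x 3 bio reps
        band_w = ra.build_group_control(activities, self.CPM, pooling="wells")
        assert band_w.pooled.size == 3 * 3 * 4

    def test_single_candidate_errors(self, activities):
        cpm = {**self.CPM, "miR-low2": 100.0, "miR-low3": 100.0}
        with pytest.raises(ValidationError, match="not constructible"):
            ra.build_group_control(activities, cpm)

    def test_missing_target_treated_as_zero_with_warning(self, activities):
        cpm = {k: v for k, v in self.CPM.items() if k != "miR-low1"}
        with pytest.warns(UserWarning, match="miR-low1"):
            band = ra.build_group_control(activities, cpm)
        assert "rep-low1" in band.member_ids

    def test_exclude_keeps_reporter_out(self, activities):
        band = ra.build_group_control(activities, self.CPM,
                                      exclude=["rep-low1"])
        assert "rep-low1" not in band.member_ids


def _pooled_t_oracle(a, b):
    # direct textbook formula for the pooled-variance two-sample t
    na, nb = len(a), len(b)
    va = np.var(a, ddof=1)
    vb = np.var(b, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


class TestStudentsT:
    def test_identical_samples(self):
        t, df, p = ra.students_t_unpaired([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0 and df == 4

    def test_large_shift_tiny_variance(self):
        a = [1.0, 2.0, 3.0]
        b = [1001.0, 1002.0, 1003.0]
        _, _, p = ra.students_t_unpaired(a, b)
        assert p < 1e-10

    def test_zero_variance_cases(self):
        t, _, p = ra.students_t_unpaired([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)
        with pytest.warns(UserWarning):
            _, _, p = ra.students_t_unpaired([2.0, 2.0], [3.0, 3.0])
        assert p == 0.0

    def test_small_samples_rejected(self):
        with pytest.raises(ValidationError):
            ra.students_t_unpaired([1.0], [1.0, 2.0])

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            a = rng.normal(size=rng.integers(2, 9))
            b = rng.normal(loc=rng.uniform(-1, 1), size=rng.integers(2, 9))
            t, df, p = ra.students_t_unpaired(a, b)
            t0, df0, p0 = _pooled_t_oracle(a, b)
            assert t == pytest.approx(t0, abs=1e-10)
            assert df == df0
            assert p == pytest.approx(p0, abs=1e-10)

    def test_welch_differs_under_variance_heterogeneity(self):
        a = [0.0, 0.1, -0.1, 0.05]
        b = [5.0, -5.0, 8.0, -8.0, 3.0]
        _, df_s, _ = ra.students_t_unpaired(a, b)
        _, df_w, _ = ra.students_t_unpaired(a, b, welch=True)
        assert df_s == 7 and df_w < 7

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.lists(finite_floats, min_size=3, max_size=6),
        b=st.lists(finite_floats, min_size=3, max_size=6),
        shift=st.floats(min_value=-10, max_value=10, allow_nan=False),
        scale=st.floats(min_value=0.1, max_value=10, allow_nan=False),
    )
    def test_location_scale_invariance(self, a, b, shift, scale):
        a, b = np.array(a), np.array(b)
        t1, _, p1 = ra.students_t_unpaired(a, b)
        t2, _, p2 = ra.students_t_unpaired(a * scale + shift,
                                           b * scale + shift)
        assert t1 == pytest.approx(t2, rel=1e-6, abs=1e-9)
        assert p1 == pytest.approx(p2, rel=1e-6, abs=1e-12)


class TestStarCode:
    @pytest.mark.parametrize(
        "p, stars",
        [
            (0.03, "*"),
            (0.05, "*"),        # inclusive boundary
            (0.01, "**"),
            (0.0009, "***"),
            (0.0001, "****"),
            (1e-9, "****"),
            (0.051, "NS"),
            (0.5, "NS"),
            (1.0, "NS"),
        ],
    )
    def test_coding(self, p, stars):
        assert ra.star_code(p) == stars

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            ra.star_code(1.5)

    @settings(derandomize=True, max_examples=100)
    @given(
        p1=st.floats(min_value=0, max_value=1),
        p2=st.floats(min_value=0, max_value=1),
    )
    def test_monotone(self, p1, p2):
        if p1 <= p2:
            assert ra.STAR_ORDER[ra.star_code(p1)] >= ra.STAR_ORDER[
                ra.star_code(p2)
            ]


class TestCallRepression:
    def _setup(self, extra):
        plate = make_plate(
            {
                "rep-low1": ("miR-low1", 0.85),
                "rep-low2": ("miR-low2", 1.05),
                "rep-low3": ("miR-low3", 1.0),
                **extra,
            },
            noise=0.03,
        )
        act = ra.relative_activity(plate)
        cpm = {"miR-low1": 3.0, "miR-low2": 12.0, "miR-low3": 15.0,
               "miR-in": 5000.0, "miR-strong": 9000.0, "miR-up": 400.0}
        band = ra.build_group_control(act, cpm)
        return act, band

    def test_mean_inside_band_never_detected(self):
        act, band = self._setup({"rep-in": ("miR-in", 0.95)})
        calls = ra.call_repression(act, band)
        row = calls.set_index("reporter_id").loc["rep-in"]
        assert band.lower < row["mean_activity"] < band.upper
        assert not row["detected"]

    def test_extreme_repression_detected(self):
        act, band = self._setup({"rep-strong": ("miR-strong", 0.05)})
        calls = ra.call_repression(
            act, band, seed_table={"rep-strong": (9000.0, 9100.0)}
        )
        row = calls.set_index("reporter_id").loc["rep-strong"]
        assert row["detected"]
        assert row["stars"] != "NS"
        assert row["seed_cpm"] == 9100.0

    def test_significant_upward_shift_not_called_repressed(self):
        act, band = self._setup({"rep-up": ("miR-up", 1.6)})
        calls = ra.call_repression(act, band)
        row = calls.set_index("reporter_id").loc["rep-up"]
        assert row["p_value"] <= 0.05
        assert not row["detected"]  # above the band, not repression

    def test_stars_consistent_with_p(self):
        act, band = self._setup({"rep-strong": ("miR-strong", 0.05),
                                 "rep-in": ("miR-in", 0.97)})
        calls = ra.call_repression(act, band)
        for row in calls.itertuples(index=False):
            assert row.stars == ra.star_code(row.p_value)

    def test_group_members_and_empty_vector_excluded(self):
        act, band = self._setup({"rep-in": ("miR-in", 0.95)})
        calls = ra.call_repression(act, band)
        assert set(calls["reporter_id"]) == {"rep-in"}


class TestDetectionVsExpression:
    def _calls(self):
        return pd.DataFrame(
            {
                "reporter_id": [f"r{i}" for i in range(6)],
                "seed_cpm": [50.0, 150.0, 200.0, 900.0, 1000.0, 8000.0],
                "detected": [False, False, False, True, True, True],
            }
        )

    def test_band_assignment_and_rates(self):
        out = ra.detection_vs_expression(self._calls())
        table = out.table.set_index("band")
        assert table.loc["<200", "n"] == 2
        assert table.loc["[200,1000]", "n"] == 3  # edges fall inside
        assert table.loc[">1000", "detection_rate"] == 1.0
        assert table.loc["<200", "detection_rate"] == 0.0

    def test_min_detected_dose(self):
        out = ra.detection_vs_expression(self._calls())
        assert out.min_detected_dose == 900.0

    def test_empty_calls(self):
        out = ra.detection_vs_expression(pd.DataFrame())
        assert out.table.empty and math.isnan(out.min_detected_dose)

    def test_all_detected_above_threshold_bounds_minimum(self):
        calls = self._calls()
        tau = 500.0
        assert (calls.loc[calls["detected"], "seed_cpm"] > tau).all()
        out = ra.detection_vs_expression(calls)
        assert out.min_detected_dose >= tau
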