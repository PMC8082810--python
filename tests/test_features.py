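"""Feature-engineering unit and property tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from swe_response.features import (
    ROIMeasurement,
    VisitRecord,
    aggregate_tumor_rois,
    change_scores_table,
    compute_change_scores,
    compute_f_mass,
    compute_visit_features,
    pe_mri_volume,
    sws_to_elasticity,
    visit_features_table,
)


def roi(mean, mn=None, mx=None, kind="tumor"):
    mn = mean if mn is None else mn
    mx = mean if mx is None else mx
    return ROIMeasurement(sws_mean=mean, sws_min=mn, sws_max=mx, kind=kind)


class TestSwsToElasticity:
    @pytest.mark.parametrize(
        "c,expected", [(0.0, 0.0), (1.0, 3.0), (2.7, 21.87)]
    )
    def test_known_values(self, c, expected):
        assert sws_to_elasticity(c) == pytest.approx(expected, abs=1e-12)

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError):
            sws_to_elasticity(-0.1)

    @given(
        c1=st.floats(0, 20, allow_nan=False),
        dc=st.floats(0.001, 5, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_speed(self, c1, dc):
        assert sws_to_elasticity(c1 + dc) > sws_to_elasticity(c1)


class TestAggregateRois:
    def test_identical_rois(self):
        agg = aggregate_tumor_rois([roi(2.7)] * 3)
        for key in ("mean_sws", "min_sws", "max_sws"):
            assert agg[key] == pytest.approx(2.7)

    def test_statistic_wise_average(self):
        rois = [
            roi(3.0, mn=2.5, mx=3.5),
            roi(4.0, mn=3.5, mx=4.5),
            roi(5.0, mn=4.5, mx=5.5),
        ]
        agg = aggregate_tumor_rois(rois)
        assert agg["mean_sws"] == pytest.approx(4.0)
        assert agg["min_sws"] == pytest.approx(3.5)
        assert agg["max_sws"] == pytest.approx(4.5)

    @pytest.mark.parametrize("n", [0, 2, 4])
    def test_requires_three_rois(self, n):
        with pytest.raises(ValueError, match="exactly 3"):
            aggregate_tumor_rois([roi(2.0)] * n)

    def test_roi_ordering_enforced(self):
        with pytest.raises(ValueError):
            ROIMeasurement(sws_mean=2.0, sws_min=3.0, sws_max=4.0)


class TestFMass:
    def test_worked_example(self):
        # 2.7 m/s averaged minimum over 28 mm rounds to 96 Hz
        f = compute_f_mass(2.7, 28.0)
        assert round(f) == 96
        assert f == pytest.approx(96.4285714, abs=1e-6)

    @pytest.mark.parametrize("v,d,expected", [(0.0, 10.0, 0.0), (3.0, 10.0, 300.0)])
    def test_exact_arithmetic(self, v, d, expected):
        assert compute_f_mass(v, d) == pytest.approx(expected)

    def test_invalid_mass_size(self):
        with pytest.raises(ValueError):
            compute_f_mass(2.0, 0.0)

    @given(
        v=st.floats(0.1, 10, allow_nan=False),
        d=st.floats(1, 100, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_halving_size_doubles_frequency(self, v, d):
        assert compute_f_mass(v, d / 2) == pytest.approx(
            2 * compute_f_mass(v, d), rel=1e-12
        )


class TestVisitFeatures:
    def make_visit(self, tumor_mean=4.0, normal_mean=2.0, **kw):
        tumor = tuple(
            roi(tumor_mean, mn=0.9 * tumor_mean, mx=1.2 * tumor_mean) for _ in range(3)
        )
        normal = roi(normal_mean, mn=0.9 * normal_mean, mx=1.2 * normal_mean,
                     kind="normal")
        defaults = dict(
            patient_id="P1", visit=1, mass_size_d=20.0, tumor_rois=tumor,
            normal_roi=normal,
        )
        defaults.update(kw)
        return VisitRecord(**defaults)

    def test_equal_tissues_give_unit_ratio(self):
        v = self.make_visit(tumor_mean=3.0, normal_mean=3.0)
        f = compute_visit_features(v)
        assert f.e_mean_ratio == pytest.approx(1.0)
        assert f.e_max_ratio == pytest.approx(1.0)

    def test_elasticity_ratio_is_squared_speed_ratio(self):
        f = compute_visit_features(self.make_visit(tumor_mean=4.0, normal_mean=2.0))
        assert f.e_mean_ratio == pytest.approx(4.0)
        f_speed = compute_visit_features(
            self.make_visit(tumor_mean=4.0, normal_mean=2.0), ratio_scale="speed"
        )
        assert f_speed.e_mean_ratio == pytest.approx(2.0)

    def test_mri_volume_is_product(self):
        v = self.make_visit(mri_ap=10.0, mri_trans=20.0, mri_si=30.0)
        assert compute_visit_features(v).v_mri == pytest.approx(6000.0)

    def test_e_max_at_least_e_mean(self):
        f = compute_visit_features(self.make_visit())
        assert f.e_max >= f.e_mean

    def test_zero_normal_elasticity_gives_missing_ratio(self):
        v = self.make_visit()
        v = VisitRecord(
            patient_id="P1", visit=1, mass_size_d=20.0, tumor_rois=v.tumor_rois,
            normal_roi=roi(0.0, kind="normal"),
        )
        f = compute_visit_features(v)
        assert math.isnan(f.e_mean_ratio) and math.isnan(f.e_max_ratio)
        assert not math.isnan(f.e_mean)


class TestChangeScores:
    def feat(self, visit, e_mean=float("nan"), f_mass=float("nan")):
        from swe_response.features import VisitFeatures

        return VisitFeatures(patient_id="P1", visit=visit, e_mean=e_mean,
                             f_mass=f_mass)

    def test_earlier_minus_later(self):
        cs = compute_change_scores(
            self.feat(1, e_mean=80.0), self.feat(2, e_mean=40.0), None
        )
        assert cs.e_mean_1_2 == pytest.approx(40.0)
        assert math.isnan(cs.e_mean_1_3)

    def test_negative_for_rising_f_mass(self):
        cs = compute_change_scores(
            self.feat(1, f_mass=100.0), None, self.feat(3, f_mass=250.0)
        )
        assert cs.f_mass_1_3 == pytest.approx(-150.0)
        assert math.isnan(cs.f_mass_1_2)

    def test_antisymmetry(self):
        a, b = self.feat(1, e_mean=70.0), self.feat(2, e_mean=55.0)
        fwd = compute_change_scores(a, b, None).e_mean_1_2
        swapped = compute_change_scores(
            self.feat(1, e_mean=55.0), self.feat(2, e_mean=70.0), None
        ).e_mean_1_2
        assert fwd == pytest.approx(-swapped)


class TestPeMriVolume:
    def test_no_enhancement(self):
        s0 = np.full(5, 100.0)
        assert pe_mri_volume(s0, s0, voxel_volume=1.0) == 0.0

    def test_boundary_inclusive(self):
        s0 = np.full(4, 100.0)
        s1 = np.array([160.0, 170.0, 175.0, 190.0])  # PE 60, 70, 75, 90
        assert pe_mri_volume(s0, s1, voxel_volume=2.0) == pytest.approx(6.0)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        s0 = rng.uniform(50, 150, size=100)
        s1 = s0 * rng.uniform(1.0, 2.5, size=100)
        vols = [pe_mri_volume(s0, s1, 1.0, threshold_pct=t) for t in (30, 50, 70, 90)]
        assert all(a >= b for a, b in zip(vols, vols[1:]))

    def test_nonpositive_precontrast_rejected(self):
        with pytest.raises(ValueError):
            pe_mri_volume(np.array([0.0]), np.array([1.0]), 1.0)


class TestTableApi:
    def test_duplicate_patient_visit_rejected(self):
        df = pd.DataFrame(
            {"patient_id": ["P1", "P1"], "visit": [1, 1], "mass_size_mm": [10, 12]}
        )
        with pytest.raises(ValueError, match="one record"):
            visit_features_table(df)

    def test_missing_visit_propagates(self, study_cohort):
        feats = visit_features_table(study_cohort.visits)
        changes = change_scores_table(feats)
        # a patient with missing visit-2 SWE has NaN 1-2 scores but may have 1-3
        merged = feats.pivot(index="patient_id", columns="visit", values="e_mean")
        pid = merged[merged[2].isna() & merged[1].notna() & merged[3].notna()].index
        if len(pid):
            row = changes.set_index("patient_id").loc[pid[0]]
            assert math.isnan(row["e_mean_1_2"])
            assert not math.isnan(row["e_mean_1_3"])
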