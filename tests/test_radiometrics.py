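import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from cvoplan.geometry import Circle, DegenerateGeometryError, Point, rotate_point
from cvoplan.radiometrics import (
    LandmarkError,
    LandmarkSet,
    actual_changes,
    canonicalize,
    compute_lhi,
    lhi_after_varus,
    load_landmarks,
    measure_hip,
    measure_vd_ld,
    neck_shaft_angle,
    records_to_dataframe,
    varus_angulation,
    write_landmarks,
)
from cvoplan.simulate import render_landmarks, simulate_cohort, CohortParams
from conftest import make_hip
from helpers import rigid_transform


def transform_set(ls: LandmarkSet, angle_deg, tx, ty, mirror=False) -> LandmarkSet:
    names = list(ls.landmarks)
    xy = np.array([[ls.landmarks[n].x, ls.landmarks[n].y] for n in names])
    out = rigid_transform(xy, angle_deg, tx, ty, mirror=mirror)
    return replace(ls, landmarks={n: Point(*p) for n, p in zip(names, out)}, frame="raw")


class TestLandmarkIO:
    def test_roundtrip_preserves_coordinates_exactly(self, noiseless_pair, tmp_path):
        path = tmp_path / "lm.csv"
        write_landmarks(noiseless_pair, path)
        back = load_landmarks(path)
        assert len(back) == 2
        for orig, re_read in zip(sorted(noiseless_pair, key=lambda s: s.stage),
                                 sorted(back, key=lambda s: s.stage)):
            assert orig.landmarks.keys() == re_read.landmarks.keys()
            for name in orig.landmarks:
                assert orig.landmarks[name] == re_read.landmarks[name]

    def test_missing_landmark_is_named_in_error(self, noiseless_pair, tmp_path):
        pre, post = noiseless_pair
        without_gt = {k: v for k, v in pre.landmarks.items() if k != "gt_tip"}
        path = tmp_path / "broken.csv"
        with pytest.raises(LandmarkError, match="gt_tip"):
            LandmarkSet(pre.hip_id, pre.stage, pre.side, without_gt)
        rows = [(pre.hip_id, "pre", pre.side, n, p.x, p.y)
                for n, p in pre.landmarks.items() if n != "gt_tip"]
        pd.DataFrame(rows, columns=["hip_id", "stage", "side", "name", "x_mm", "y_mm"]).to_csv(
            path, index=False)
        with pytest.raises(LandmarkError, match="gt_tip"):
            load_landmarks(path)

    def test_duplicate_and_nonnumeric_rows_rejected(self, noiseless_pair, tmp_path):
        pre, _ = noiseless_pair
        rows = [(pre.hip_id, "pre", pre.side, n, p.x, p.y) for n, p in pre.landmarks.items()]
        dup = pd.DataFrame(rows + [rows[0]], columns=["hip_id", "stage", "side", "name", "x_mm", "y_mm"])
        p1 = tmp_path / "dup.csv"
        dup.to_csv(p1, index=False)
        with pytest.raises(LandmarkError, match="duplicate"):
            load_landmarks(p1)
        bad = pd.DataFrame(rows, columns=["hip_id", "stage", "side", "name", "x_mm", "y_mm"])
        bad["x_mm"] = bad["x_mm"].astype(object)
        bad.loc[0, "x_mm"] = "oops"
        p2 = tmp_path / "bad.csv"
        bad.to_csv(p2, index=False)
        with pytest.raises(LandmarkError, match="non-numeric"):
            load_landmarks(p2)

    def test_unknown_stage_rejected(self, noiseless_pair):
        pre, _ = noiseless_pair
        with pytest.raises(LandmarkError, match="stage"):
            LandmarkSet(pre.hip_id, "mid", pre.side, pre.landmarks)


class TestCanonicalize:
    def test_already_canonical_set_unchanged(self, noiseless_pair):
        pre, _ = noiseless_pair  # right hip rendered directly in the canonical layout
        canon = canonicalize(pre)
        for name, p in pre.landmarks.items():
            q = canon.landmarks[name]
            assert math.hypot(p.x - q.x, p.y - q.y) < 1e-9

    def test_inverts_known_rigid_transform(self, noiseless_pair):
        pre, _ = noiseless_pair
        moved = transform_set(pre, angle_deg=17.0, tx=33.5, ty=-12.25)
        canon = canonicalize(moved)
        for name, p in canonicalize(pre).landmarks.items():
            q = canon.landmarks[name]
            assert math.hypot(p.x - q.x, p.y - q.y) < 1e-9

    def test_mirrored_left_hip_maps_onto_right_convention(self):
        right = render_landmarks(make_hip(side="right"), 0.0, seed=0)[0]
        left = render_landmarks(make_hip(side="left"), 0.0, seed=0)[0]
        cr, cl = canonicalize(right), canonicalize(left)
        for name in cr.landmarks:
            assert cr.landmarks[name].x == pytest.approx(cl.landmarks[name].x, abs=1e-9)
            assert cr.landmarks[name].y == pytest.approx(cl.landmarks[name].y, abs=1e-9)

    def test_coincident_teardrops_raise(self, noiseless_pair):
        pre, _ = noiseless_pair
        lm = dict(pre.landmarks)
        lm["teardrop_contra"] = lm["teardrop_ipsi"]
        with pytest.raises(DegenerateGeometryError, match="teardrop"):
            canonicalize(replace(pre, landmarks=lm))

    def test_distances_preserved(self, noiseless_pair):
        pre, _ = noiseless_pair
        moved = transform_set(pre, 63.0, -5.0, 81.0, mirror=True)
        canon = canonicalize(moved)
        a, b = pre.landmarks["gt_tip"], pre.landmarks["head_lateral"]
        ca, cb = canon.landmarks["gt_tip"], canon.landmarks["head_lateral"]
        assert math.hypot(a.x - b.x, a.y - b.y) == pytest.approx(
            math.hypot(ca.x - cb.x, ca.y - cb.y), abs=1e-9
        )


class TestAnglesAndDistances:
    def test_neck_shaft_angle_examples(self, canonical_pre):
        # The simulated scene is built with a 135 degree neck-shaft angle.
        assert neck_shaft_angle(canonical_pre) == pytest.approx(135.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_neck_shaft_angle_matches_vector_oracle(self, canonical_pre, seed):
        rng = np.random.default_rng(seed)
        lm = dict(canonical_pre.landmarks)
        s1, s2 = rng.normal(0, 50, 2), rng.normal(0, 50, 2)
        n1, n2 = rng.normal(0, 50, 2), rng.normal(0, 50, 2)
        lm.update(
            shaft_axis_1=Point(*s1), shaft_axis_2=Point(*s2),
            neck_axis_1=Point(*n1), neck_axis_2=Point(*n2),
        )
        ls = replace(canonical_pre, landmarks=lm)
        u, v = s2 - s1, n2 - n1
        expected = math.degrees(
            math.acos(np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1))
        )
        assert neck_shaft_angle(ls) == pytest.approx(expected, abs=1e-9)

    def test_perpendicular_axes_give_90(self, canonical_pre):
        lm = dict(canonical_pre.landmarks)
        lm.update(shaft_axis_1=Point(0, 0), shaft_axis_2=Point(0, -10),
                  neck_axis_1=Point(0, 0), neck_axis_2=Point(-10, 0))
        assert neck_shaft_angle(replace(canonical_pre, landmarks=lm)) == pytest.approx(90.0)

    def test_varus_angulation(self):
        assert varus_angulation(135.0, 113.3) == pytest.approx(21.7)
        assert varus_angulation(140.0, 140.0) == 0.0
        assert varus_angulation(130.0, 145.0) == pytest.approx(-15.0)
        with pytest.raises(ValueError):
            varus_angulation(0.0, 120.0)

    def test_vd_ld_read_off_canonical_coordinates(self, canonical_pre):
        vd, ld = measure_vd_ld(canonical_pre)
        assert vd == pytest.approx(canonical_pre["gt_tip"].y)
        assert ld == pytest.approx(canonical_pre["gt_lateral"].x)

    def test_vd_ld_requires_canonical_frame(self, noiseless_pair):
        with pytest.raises(ValueError, match="canonical"):
            measure_vd_ld(noiseless_pair[0])

    def test_actual_changes_zero_for_identical_stages(self, noiseless_pair):
        pre, _ = noiseless_pair
        fake_post = replace(pre, stage="pre")
        c = canonicalize(pre)
        assert actual_changes(c, canonicalize(fake_post)) == (0.0, 0.0)

    def test_actual_changes_rejects_hip_mismatch(self, noiseless_pair):
        pre, post = noiseless_pair
        other = replace(post, hip_id="H999")
        with pytest.raises(ValueError, match="mismatch"):
            actual_changes(canonicalize(pre), canonicalize(other))


class TestLHI:
    @staticmethod
    def with_extents(ls, medial_x, lateral_x, margin_x):
        lm = dict(ls.landmarks)
        lm["head_medial"] = Point(medial_x, 10.0)
        lm["head_lateral"] = Point(lateral_x, 10.0)
        if margin_x is None:
            lm.pop("necrosis_lateral_margin", None)
        else:
            lm["necrosis_lateral_margin"] = Point(margin_x, 10.0)
        ls2 = replace(ls, landmarks=lm)
        return ls2

    def test_definition_and_clamps(self, canonical_pre):
        assert compute_lhi(self.with_extents(canonical_pre, 0, 50, 40)).lhi == pytest.approx(20.0)
        assert compute_lhi(self.with_extents(canonical_pre, 0, 50, 55)).lhi == 0.0
        assert compute_lhi(self.with_extents(canonical_pre, 0, 50, -5)).lhi == 100.0
        assert compute_lhi(self.with_extents(canonical_pre, 0, 50, None)).lhi == 100.0

    def test_scale_invariance(self, canonical_pre):
        lhi0 = compute_lhi(canonical_pre).lhi
        lm = {n: Point(2.5 * p.x, 2.5 * p.y) for n, p in canonical_pre.landmarks.items()}
        assert compute_lhi(replace(canonical_pre, landmarks=lm)).lhi == pytest.approx(lhi0)

    def test_degenerate_head_width(self, canonical_pre):
        with pytest.raises(DegenerateGeometryError):
            compute_lhi(self.with_extents(canonical_pre, 50, 0, 25))

    def test_after_varus_zero_angle_is_identity(self, canonical_pre):
        arc = Circle(Point(45.3, 2.7), 22.5)
        assert lhi_after_varus(canonical_pre, arc, 0.0).lhi == pytest.approx(
            compute_lhi(canonical_pre).lhi
        )

    def test_after_varus_matches_two_step_oracle(self, canonical_pre):
        arc = Circle(Point(45.3, 2.7), 22.5)
        theta = 18.0
        got = lhi_after_varus(canonical_pre, arc, theta)
        med = rotate_point(canonical_pre["head_medial"], arc.center, theta)
        lat = rotate_point(canonical_pre["head_lateral"], arc.center, theta)
        mar = rotate_point(canonical_pre["necrosis_lateral_margin"], arc.center, theta)
        head_w = lat.x - med.x
        intact = min(max(lat.x - mar.x, 0.0), head_w)
        assert got.lhi == pytest.approx(100 * intact / head_w, abs=1e-12)

    @pytest.mark.parametrize("theta", [0, 10, 25, 45])
    def test_after_varus_stays_in_unit_range(self, canonical_pre, theta):
        arc = Circle(Point(45.3, 2.7), 22.5)
        assert 0.0 <= lhi_after_varus(canonical_pre, arc, theta).lhi <= 100.0

    def test_lhi_increases_with_varus_for_superolateral_margin(self, canonical_pre):
        hip = make_hip()
        arc = Circle(Point(42.0 + hip.A, 12.0 - hip.B), hip.arc_radius)
        values = [lhi_after_varus(canonical_pre, arc, t).lhi for t in (0, 10, 20, 30)]
        assert all(b > a for a, b in zip(values, values[1:]))


class TestMeasureHip:
    def test_noiseless_roundtrip_recovers_truth(self):
        hip = make_hip(A=7.5, B=14.0, theta=30.0, extent=0.75)
        pre, post = render_landmarks(hip, 0.0, seed=0)
        rec = measure_hip(pre, post)
        assert rec.theta == pytest.approx(hip.theta, abs=1e-6)
        assert rec.offsets.A == pytest.approx(hip.A, abs=1e-6)
        assert rec.offsets.B == pytest.approx(hip.B, abs=1e-6)
        assert rec.actual_shortening == pytest.approx(hip.true_shortening, abs=1e-6)
        assert rec.actual_lateralization == pytest.approx(hip.true_lateralization, abs=1e-6)
        assert abs(rec.residual_shortening) < 1e-6
        assert abs(rec.residual_lateralization) < 1e-6
        assert rec.lhi_pre == pytest.approx(100 * (1 - hip.necrosis_extent), abs=1e-6)
        assert rec.lhi_post > rec.lhi_pre

    def test_sham_osteotomy_changes_nothing(self):
        hip = make_hip(theta=0.0)
        pre, post = render_landmarks(hip, 0.0, seed=0)
        rec = measure_hip(pre, post)
        assert rec.theta == pytest.approx(0.0, abs=1e-9)
        assert rec.actual_shortening == pytest.approx(0.0, abs=1e-9)
        assert rec.actual_lateralization == pytest.approx(0.0, abs=1e-9)
        assert rec.predicted.shortening == pytest.approx(0.0, abs=1e-9)

    def test_cohort_mean_parameters_predict_1_88_mm(self, noiseless_pair):
        rec = measure_hip(*noiseless_pair)
        assert rec.predicted.shortening == pytest.approx(1.8793, abs=1e-4)

    def test_valgus_rotation_flagged(self):
        hip = make_hip(theta=-5.0)
        pre, post = render_landmarks(hip, 0.0, seed=0)
        rec = measure_hip(pre, post)
        assert any("valgus" in w for w in rec.warnings)

    def test_frame_invariance_under_rigid_transform_and_mirror(self):
        hip = make_hip(A=5.0, B=11.0, theta=24.0)
        pre, post = render_landmarks(hip, 0.0, seed=0)
        base = measure_hip(pre, post).to_dict()
        rng = np.random.default_rng(5)
        for mirror in (False, True):
            ang, tx, ty = rng.uniform(-180, 180), rng.uniform(-80, 80), rng.uniform(-80, 80)
            rec = measure_hip(
                transform_set(pre, ang, tx, ty, mirror),
                transform_set(post, -0.37 * ang, ty, tx, mirror),
            ).to_dict()
            for key, val in base.items():
                if isinstance(val, float):
                    assert rec[key] == pytest.approx(val, abs=1e-9), key

    def test_zero_noise_cohort_has_zero_residuals(self, noiseless_cohort):
        sets, truth = noiseless_cohort
        from cvoplan.radiometrics import measure_cohort

        records, errors = measure_cohort(sets)
        assert errors == []
        df = records_to_dataframe(records)
        assert np.abs(df.residual_shortening).max() < 1e-6
        assert np.abs(df.residual_lateralization).max() < 1e-6
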