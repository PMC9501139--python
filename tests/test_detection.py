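import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spineslip import (
    PhantomSpec,
    Thresholds,
    classify_grade,
    compute_ds,
    compute_pgrade,
    compute_psd,
    detect_case,
    generate_flexion_extension_pair,
    geometry_from_mask,
    psd_junction_flags,
)
from spineslip.detection import DegeneratePlateError, segment_angle
from spineslip.geometry import JUNCTIONS, VertebraQuad

from conftest import stacked_geometry


def quad_at(x0, y0, w, h, level="L1"):
    return VertebraQuad(level, (x0, y0), (x0 + w, y0), (x0 + w, y0 + h),
                        (x0, y0 + h))


class TestPGrade:
    def test_aligned_corners_give_zero(self):
        upper = VertebraQuad("L4", (0, 80), (100, 80), (100, 90), (0, 90))
        r = compute_pgrade(upper, ((0, 100), (100, 100)), k1=10)
        assert r.displacement == pytest.approx(0.0)
        assert r.pgrade == pytest.approx(0.0)
        assert not r.flag

    def test_projection_within_segment(self):
        upper = VertebraQuad("L4", (-25, 80), (75, 80), (75, 90), (-25, 90))
        r = compute_pgrade(upper, ((0, 100), (100, 100)), k1=10)
        assert r.projected_point == pytest.approx((75.0, 100.0))
        assert r.displacement == pytest.approx(25.0)
        assert r.pgrade == pytest.approx(25.0)
        assert r.flag and r.direction == -1

    def test_projection_beyond_segment_boundary_not_flagged(self):
        """A projection past the plate end is measured on the extended
        line; pgrade exactly at K1 stays silent under strict '>'."""
        upper = VertebraQuad("L4", (10, 80), (110, 80), (110, 95), (10, 95))
        r = compute_pgrade(upper, ((0, 100), (100, 100)), k1=10)
        assert r.projected_point == pytest.approx((110.0, 100.0))
        assert r.pgrade == pytest.approx(10.0)
        assert not r.flag
        assert r.direction == 1

    def test_degenerate_plate_raises(self):
        with pytest.raises(DegeneratePlateError):
            compute_pgrade(quad_at(0, 0, 10, 10), ((5, 5), (5, 5)))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        tx=st.floats(-200, 200), ty=st.floats(-200, 200),
        angle=st.floats(0, 2 * np.pi), scale=st.floats(0.1, 10),
    )
    def test_similarity_invariance(self, tx, ty, angle, scale):
        """P-grade is unchanged by translation, rotation and uniform
        scaling of all the points."""
        upper = VertebraQuad("L3", (12, 40), (108, 43), (105, 78), (9, 75))
        plate = ((11.0, 100.0), (109.0, 97.0))
        base = compute_pgrade(upper, plate).pgrade

        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])

        def tf(p):
            q = scale * (rot @ np.asarray(p, float)) + np.array([tx, ty])
            return (float(q[0]), float(q[1]))

        moved = VertebraQuad("L3", tf(upper.p1), tf(upper.p2), tf(upper.p3),
                             tf(upper.p4))
        got = compute_pgrade(moved, (tf(plate[0]), tf(plate[1]))).pgrade
        assert got == pytest.approx(base, abs=1e-8)

    def test_matches_dense_sampling_oracle(self):
        """Closed-form projection agrees with brute-force minimization of
        the distance over densely sampled line points."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            p3 = rng.uniform(-50, 150, 2)
            a = rng.uniform(0, 100, 2)
            direction = rng.normal(size=2)
            direction /= np.linalg.norm(direction)
            b = a + rng.uniform(20, 120) * direction
            # dense sampling + exact parabolic vertex (squared distance is
            # quadratic in the line parameter)
            ts = np.linspace(-15.0, 16.0, 2001)
            pts = a[None] + ts[:, None] * (b - a)[None]
            f = np.sum((pts - p3[None]) ** 2, axis=1)
            k = int(np.argmin(f))
            h = ts[1] - ts[0]
            t_star = ts[k] - 0.5 * h * (f[k + 1] - f[k - 1]) / (
                f[k + 1] - 2 * f[k] + f[k - 1])
            d_oracle = np.linalg.norm(a + t_star * (b - a) - b)
            quad = VertebraQuad("L2", (0, 0), (1, 0), tuple(p3), (0, 1))
            r = compute_pgrade(quad, (tuple(a), tuple(b)))
            rel = abs(r.displacement - d_oracle) / max(1.0, d_oracle)
            assert rel < 1e-6


class TestPSD:
    def test_all_vertical_segments_zero_angles(self):
        geom = stacked_geometry()
        alpha, beta = compute_psd(geom)
        assert np.allclose(alpha.angles, 0.0) and np.allclose(beta.angles, 0.0)
        assert not any(psd_junction_flags(alpha, beta).values())

    def test_known_gap_angle_sequence(self):
        """A gap segment running at 45 deg between vertical body segments
        produces the angle sequence (0, 45, 0) and flags at K2 = 37."""
        # offset across junction L2L3 equal to the gap height -> 45 deg
        geom = stacked_geometry(gap_offsets=(0.0, 12.0, 0.0, 0.0, 0.0))
        alpha, beta = compute_psd(geom, k2=37.0)
        assert alpha.angles[2] == pytest.approx(0.0, abs=1e-12)
        assert alpha.angles[3] == pytest.approx(45.0, abs=1e-12)
        assert alpha.angles[4] == pytest.approx(0.0, abs=1e-12)
        flags = psd_junction_flags(alpha, beta)
        assert flags["L2L3"] and sum(bool(v) for v in flags.values()) == 1

    def test_orthogonal_segment_angle(self):
        assert segment_angle(np.array([1.0, 0.0])) == pytest.approx(90.0)
        assert segment_angle(np.array([1.0, 1.0])) == pytest.approx(45.0)
        assert segment_angle(np.array([0.0, -2.0])) == pytest.approx(180.0)

    def test_flag_flips_exactly_at_threshold(self):
        geom = stacked_geometry(gap_offsets=(0.0, 0.0, 12.0, 0.0, 0.0))
        alpha, beta = compute_psd(geom, k2=45.0)  # diff == 45, strict '>'
        assert not psd_junction_flags(alpha, beta)["L3L4"]
        alpha, beta = compute_psd(geom, k2=44.999)
        assert psd_junction_flags(alpha, beta)["L3L4"]

    def test_l5s1_window_uses_last_segments(self):
        geom = stacked_geometry(gap_offsets=(0.0, 0.0, 0.0, 0.0, 12.0))
        alpha, beta = compute_psd(geom, k2=37.0)
        flags = psd_junction_flags(alpha, beta)
        assert flags["L5S1"] and sum(bool(v) for v in flags.values()) == 1

    def test_rotation_leaves_diffs_invariant(self):
        """A global rotation shifts every segment angle uniformly, so the
        consecutive differences (and flags) are unchanged.  This holds as
        long as no segment crosses the vertical axis: the cosine angle is
        unsigned, so the rotation must lean all segments to the same side
        (here the gap segment leans right, so we rotate rightward)."""
        geom = stacked_geometry(gap_offsets=(0.0, 12.0, 0.0, 0.0, 0.0))
        theta = np.deg2rad(-10.0)
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])

        def tf(p):
            q = rot @ np.asarray(p, float)
            return (float(q[0]), float(q[1]))

        from spineslip.geometry import SacrumPlate, SpineGeometry

        rotated = SpineGeometry(
            quads={
                lv: VertebraQuad(lv, tf(q.p1), tf(q.p2), tf(q.p3), tf(q.p4))
                for lv, q in geom.quads.items()
            },
            sacrum=SacrumPlate(tf(geom.sacrum.p1), tf(geom.sacrum.p2)),
        )
        a0, b0 = compute_psd(geom)
        a1, b1 = compute_psd(rotated)
        np.testing.assert_allclose(a1.diffs, a0.diffs, atol=1e-9)
        np.testing.assert_allclose(b1.diffs, b0.diffs, atol=1e-9)

    def test_missing_level_skips_junctions(self):
        geom = stacked_geometry()
        del geom.quads["L3"]
        with pytest.warns(UserWarning, match="skipped"):
            alpha, beta = compute_psd(geom)
        flags = psd_junction_flags(alpha, beta)
        assert flags["L2L3"] is None and flags["L3L4"] is None
        assert flags["L1L2"] is False


class TestDynamicShift:
    def test_identical_geometries_no_flags(self):
        geom = stacked_geometry()
        results = compute_ds(geom, geom)
        assert len(results) == 5
        assert all(r.difference == pytest.approx(0.0) for r in results)
        assert not any(r.flag for r in results)

    def test_phantom_pair_shift_above_threshold_flags(self):
        spec = PhantomSpec(slip_junction="L4L5", seed=3)
        flex, ext = generate_flexion_extension_pair(spec, 0.30, 0.10)
        gf = geometry_from_mask(flex.mask)
        ge = geometry_from_mask(ext.mask)
        by_junction = {r.junction: r for r in compute_ds(gf, ge, k3=0.14)}
        assert by_junction["L4L5"].difference == pytest.approx(0.20, abs=0.01)
        assert by_junction["L4L5"].flag
        assert not any(r.flag for j, r in by_junction.items() if j != "L4L5")

    def test_boundary_shift_not_flagged_under_strict_inequality(self):
        """A dynamic shift of exactly 0.14 sits on the decision boundary
        and must stay silent."""
        spec = PhantomSpec(slip_junction="L3L4", seed=3)
        flex, ext = generate_flexion_extension_pair(spec, 0.14, 0.0)
        gf = geometry_from_mask(flex.mask)
        ge = geometry_from_mask(ext.mask)
        by_junction = {r.junction: r for r in compute_ds(gf, ge, k3=0.14)}
        assert by_junction["L3L4"].difference == pytest.approx(0.14, abs=1e-9)
        assert not by_junction["L3L4"].flag

    def test_scale_invariance_of_normalized_shift(self):
        geom_f = stacked_geometry(gap_offsets=(0.0, 0.0, 30.0, 0.0, 0.0))
        geom_e = stacked_geometry()
        base = {r.junction: r.difference for r in compute_ds(geom_f, geom_e)}
        scaled_f = stacked_geometry(gap_offsets=(0.0, 0.0, 60.0, 0.0, 0.0),
                                    width=200.0, body_height=80.0, gap=24.0)
        scaled_e = stacked_geometry(width=200.0, body_height=80.0, gap=24.0)
        scaled = {r.junction: r.difference
                  for r in compute_ds(scaled_f, scaled_e)}
        for j in JUNCTIONS:
            assert scaled[j] == pytest.approx(base[j], abs=1e-12)


class TestClassifyGrade:
    @pytest.mark.parametrize(
        "pgrade,grade,severity",
        [
            (0.0, 1, "low grade"),
            (20.0, 1, "low grade"),
            (25.0, 1, "low grade"),
            (25.1, 2, "low grade"),
            (50.0, 2, "low grade"),
            (50.1, 3, "high grade"),
            (60.0, 3, "high grade"),
            (75.5, 4, "high grade"),
            (100.0, 4, "high grade"),
            (120.0, 5, "spondyloptosis"),
        ],
    )
    def test_grade_table(self, pgrade, grade, severity):
        assert classify_grade(pgrade) == (grade, severity)

    def test_negative_pgrade_rejected(self):
        with pytest.raises(ValueError):
            classify_grade(-1.0)


class TestDetectCase:
    def test_slipped_phantom_flags_exactly_its_junction(self, slipped_case):
        geom = geometry_from_mask(slipped_case.mask)
        report = detect_case(geom)
        assert report.junction_flags["L4L5"]
        assert report.case_positive
        assert report.grades["L4L5"][0] == 2  # 30% -> grade 2
        # P-grade is silent elsewhere; PSD may corroborate only at the slip
        assert all(
            not any(r.flag for r in report.pgrade[j])
            for j in JUNCTIONS if j != "L4L5"
        )

    def test_zero_slip_phantom_is_negative(self, clean_case):
        report = detect_case(geometry_from_mask(clean_case.mask))
        assert not report.case_positive
        assert not any(report.junction_flags.values())
        assert report.ds is None

    def test_pair_runs_dynamic_shift(self):
        spec = PhantomSpec(slip_junction="L4L5", seed=6)
        flex, ext = generate_flexion_extension_pair(spec, 0.30, 0.05)
        report = detect_case(
            (geometry_from_mask(flex.mask), geometry_from_mask(ext.mask))
        )
        assert report.ds is not None
        assert report.ds["L4L5"].flag
        assert report.case_positive

    def test_combined_mode_psd_silent_on_borderline_angle(self):
        """With the combined-mode thresholds (K1=10, K2=50) a 45-degree
        slope difference no longer trips PSD; the decision rests on the
        P-grade detector."""
        geom = stacked_geometry(gap_offsets=(0.0, 12.0, 0.0, 0.0, 0.0))
        combined = detect_case(geom, Thresholds.combined())
        assert not combined.psd_flags["L2L3"]
        # the 12 px offset over a 100 px plate is a 12% P-grade > K1
        assert combined.junction_flags["L2L3"]
        standalone = detect_case(geom, Thresholds())
        assert standalone.psd_flags["L2L3"]

    def test_thresholds_must_be_positive(self):
        with pytest.raises(ValueError):
            Thresholds(k1=0.0)
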