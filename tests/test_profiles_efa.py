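"""Engraving cross-section measurement and elliptic Fourier shape analysis."""

import numpy as np
import pytest

from lithotex.efa import efa, harmonic_power_threshold, normalize_efa, reconstruct
from lithotex.heightmap import HeightMap
from lithotex.profiles import (
    ProfileError,
    ProfileTrace,
    allometry_check,
    close_outline,
    detect_landmarks,
    extract_profile,
    measure_profile,
)
from lithotex.synth import generate_profile


@pytest.fixture
def v_profile():
    return generate_profile(depth=1.0, wis=2.0, shape="V", asymmetry=0.0, noise_rms=0.0)


class TestGenerateProfile:
    def test_symmetric_v_right_angle(self, v_profile):
        lm = detect_landmarks(v_profile)
        m = measure_profile(v_profile, lm)
        assert m.theta_deg == pytest.approx(90.0, abs=0.5)
        assert m.A < 0.01

    def test_noise_free_depth_exact(self, v_profile):
        lm = detect_landmarks(v_profile)
        m = measure_profile(v_profile, lm)
        assert m.D_um == pytest.approx(1000.0, abs=1e-6)

    def test_asymmetry_increases_score(self):
        sym = generate_profile(1.0, 2.0, "V", asymmetry=0.0, noise_rms=0.0)
        asym = generate_profile(1.0, 2.0, "V", asymmetry=0.5, noise_rms=0.0)
        a0 = measure_profile(sym, detect_landmarks(sym)).A
        a1 = measure_profile(asym, detect_landmarks(asym)).A
        assert a1 > a0

    @pytest.mark.parametrize("bad", [dict(depth=-1, wis=2), dict(depth=1, wis=0),
                                     dict(depth=1, wis=2, shape="W"),
                                     dict(depth=1, wis=2, asymmetry=1.5)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            generate_profile(**bad)


class TestExtractProfile:
    def test_flat_map_constant_trace(self, flat_map):
        tr = extract_profile(flat_map, (0.5, 0.5), (4.5, 4.5))
        assert np.allclose(tr.z, 0.0)

    def test_groove_crossed_perpendicular(self):
        n, spacing = 200, 0.025
        x = np.arange(n) * spacing
        X, Y = np.meshgrid(x, x)
        depth, half = 0.3, 0.5
        z = -np.clip(depth * (1 - np.abs(Y - 2.5) / half), 0, None)
        m = HeightMap(z, spacing)
        tr = extract_profile(m, (2.5, 0.5), (2.5, 4.5))
        assert tr.z.min() == pytest.approx(-depth, abs=spacing)

    def test_resolution_stability(self):
        n, spacing = 200, 0.025
        x = np.arange(n) * spacing
        X, Y = np.meshgrid(x, x)
        z = -np.clip(0.3 * (1 - np.abs(Y - 2.5) / 0.5), 0, None)
        m = HeightMap(z, spacing)
        res = {}
        for ov in (1.0, 2.0):
            tr = extract_profile(m, (2.5, 0.5), (2.5, 4.5), oversample=ov)
            meas = measure_profile(tr, detect_landmarks(tr))
            res[ov] = (meas.D_um, meas.WIS_um)
        assert res[2.0][0] == pytest.approx(res[1.0][0], rel=0.02)
        assert res[2.0][1] == pytest.approx(res[1.0][1], rel=0.02)

    def test_masked_exit_errors(self, flat_map):
        with pytest.raises(ProfileError):
            extract_profile(flat_map, (0.5, 0.5), (50.0, 50.0))


class TestLandmarks:
    def test_symmetric_shoulders(self, v_profile):
        lm = detect_landmarks(v_profile)
        xa = v_profile.x[lm.apex]
        assert (xa - lm.left_shoulder) == pytest.approx(lm.right_shoulder - xa, abs=2 * v_profile.spacing)

    def test_two_trough_trace_rejected(self):
        x = np.linspace(-2, 2, 200)
        z = -np.clip(1 - np.abs(x + 1) / 0.4, 0, None) - 0.9 * np.clip(1 - np.abs(x - 1) / 0.4, 0, None)
        with pytest.raises(ProfileError, match="dominance"):
            detect_landmarks(ProfileTrace(x, z))

    def test_u_profile_apex_at_plateau_centre(self):
        tr = generate_profile(1.0, 2.0, "U", asymmetry=0.0, noise_rms=0.0, n_points=401)
        lm = detect_landmarks(tr)
        assert tr.x[lm.apex] == pytest.approx(0.0, abs=2 * tr.spacing)

    def test_no_trough_rejected(self, flat_map):
        tr = ProfileTrace(np.linspace(0, 1, 50), np.zeros(50))
        with pytest.raises(ProfileError):
            detect_landmarks(tr)


class TestMeasurements:
    def test_similarity_scaling(self, v_profile):
        lm = detect_landmarks(v_profile)
        m1 = measure_profile(v_profile, lm)
        tr2 = ProfileTrace(2 * v_profile.x, 2 * v_profile.z)
        m2 = measure_profile(tr2, detect_landmarks(tr2))
        assert m2.D_um == pytest.approx(2 * m1.D_um, rel=1e-6)
        assert m2.WIS_um == pytest.approx(2 * m1.WIS_um, rel=1e-6)
        assert m2.theta_deg == pytest.approx(m1.theta_deg, abs=1e-6)

    def test_translation_invariance(self, v_profile):
        lm = detect_landmarks(v_profile)
        m1 = measure_profile(v_profile, lm)
        tr2 = ProfileTrace(v_profile.x + 5.0, v_profile.z)
        m2 = measure_profile(tr2, detect_landmarks(tr2))
        assert m2.D_um == pytest.approx(m1.D_um, abs=1e-9)
        assert m2.A == pytest.approx(m1.A, abs=1e-9)

    def test_mirror_reflection_preserves_asymmetry(self):
        tr = generate_profile(1.0, 2.5, "V", asymmetry=0.4, noise_rms=0.0)
        mirror = ProfileTrace(-tr.x[::-1], tr.z[::-1])
        a1 = measure_profile(tr, detect_landmarks(tr)).A
        a2 = measure_profile(mirror, detect_landmarks(mirror)).A
        assert a2 == pytest.approx(a1, abs=1e-9)


class TestOutline:
    def test_v_outline_area_matches_triangle(self, v_profile):
        lm = detect_landmarks(v_profile)
        out = close_outline(v_profile, lm)
        area = 0.5 * abs(np.sum(out[:, 0] * np.roll(out[:, 1], -1) - np.roll(out[:, 0], -1) * out[:, 1]))
        m = measure_profile(v_profile, lm)
        expect = 0.5 * (m.WIS_um / 1000) * (m.D_um / 1000)
        assert area == pytest.approx(expect, rel=0.02)

    def test_counter_clockwise_and_point_count(self, v_profile):
        out = close_outline(v_profile, detect_landmarks(v_profile))
        assert out.shape == (256, 2)
        signed = 0.5 * np.sum(out[:, 0] * np.roll(out[:, 1], -1) - np.roll(out[:, 0], -1) * out[:, 1])
        assert signed > 0


class TestEFA:
    def test_uniform_ellipse_single_harmonic(self):
        t = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        ell = np.column_stack([3 * np.cos(t), 1.5 * np.sin(t)])
        m = efa(ell, h=20, parametrization="uniform")
        assert m.harmonic_power[0] / m.harmonic_power.sum() >= 0.9999

    def test_power_nonnegative(self, v_profile):
        out = close_outline(v_profile, detect_landmarks(v_profile))
        assert np.all(efa(out, 10).harmonic_power >= 0)

    def test_reconstruction_round_trip(self):
        tr = generate_profile(0.8, 2.5, "V", asymmetry=0.3, noise_rms=0.005, seed=3)
        out = close_outline(tr, detect_landmarks(tr))
        model = efa(out, 20)
        rec = reconstruct(model, 512)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(out).query(rec)
        assert d.mean() < 0.005 * model.centroid_size

    def test_h_below_one_rejected(self, v_profile):
        out = close_outline(v_profile, detect_landmarks(v_profile))
        with pytest.raises(ValueError):
            efa(out, h=0)


class TestNormalization:
    def test_shape_variable_count(self, v_profile):
        out = close_outline(v_profile, detect_landmarks(v_profile))
        sv = normalize_efa(efa(out, 6)).shape_variables
        assert sv.size == 6 * 4 - 3

    def test_scale_rotation_startpoint_invariance(self):
        tr = generate_profile(0.8, 2.5, "V", asymmetry=0.3, noise_rms=0.01, seed=1)
        out = close_outline(tr, detect_landmarks(tr))
        sv0 = normalize_efa(efa(out, 6)).shape_variables
        ang = 0.7
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        transformed = 3.0 * (out @ R.T) + np.array([5.0, 7.0])
        sv1 = normalize_efa(efa(transformed, 6)).shape_variables
        sv2 = normalize_efa(efa(np.roll(out, 57, axis=0), 6)).shape_variables
        assert np.abs(sv1 - sv0).max() < 1e-6
        assert np.abs(sv2 - sv0).max() < 1e-6

    def test_identical_outlines_zero_distance(self, v_profile):
        out = close_outline(v_profile, detect_landmarks(v_profile))
        a = normalize_efa(efa(out, 6)).shape_variables
        b = normalize_efa(efa(out.copy(), 6)).shape_variables
        assert np.linalg.norm(a - b) == 0.0


class TestHarmonicThreshold:
    def test_ellipse_needs_one_harmonic(self):
        t = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        ell = np.column_stack([2 * np.cos(t), np.sin(t)])
        m = efa(ell, h=20, parametrization="uniform")
        assert harmonic_power_threshold(m, 98.0) == 1

    def test_full_threshold_returns_reference_count(self, v_profile):
        out = close_outline(v_profile, detect_landmarks(v_profile))
        m = efa(out, h=20)
        assert harmonic_power_threshold(m, 100.0) == 20

    def test_v_u_profiles_captured_by_six(self):
        rng = np.random.default_rng(0)
        counts = []
        for i in range(40):
            tr = generate_profile(
                rng.uniform(0.3, 1.5), rng.uniform(2, 4.5), "V" if i % 2 else "U",
                rng.uniform(0, 0.5), noise_rms=0.01, seed=i,
            )
            out = close_outline(tr, detect_landmarks(tr))
            counts.append(harmonic_power_threshold(efa(out, 20), 98.0))
        assert np.quantile(counts, 0.95) <= 6


class TestAllometry:
    def test_pure_scaling_is_isometric(self):
        rng = np.random.default_rng(2)
        base = generate_profile(1.0, 2.5, "V", asymmetry=0.3, noise_rms=0.0)
        out = close_outline(base, detect_landmarks(base))
        svs, sizes = [], []
        for s in rng.uniform(0.5, 3.0, 12):
            m = normalize_efa(efa(out * s, 6))
            svs.append(m.shape_variables + rng.normal(0, 1e-9, 21))
            sizes.append(m.centroid_size)
        table = allometry_check(np.array(svs), np.array(sizes))
        assert table.attrs["isometric"]

    def test_size_correlated_shape_flagged(self):
        rng = np.random.default_rng(3)
        svs, sizes = [], []
        for d in np.linspace(0.3, 2.0, 15):
            tr = generate_profile(d, 2.5, "V", asymmetry=0.0, noise_rms=0.0)
            m = normalize_efa(efa(close_outline(tr, detect_landmarks(tr)), 6))
            svs.append(m.shape_variables + rng.normal(0, 1e-6, 21))
            sizes.append(m.centroid_size)
        table = allometry_check(np.array(svs), np.array(sizes))
        assert not table.attrs["isometric"]

    def test_too_few_profiles_rejected(self):
        with pytest.raises(ProfileError):
            allometry_check(np.zeros((2, 5)), np.array([1.0, 2.0]))
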