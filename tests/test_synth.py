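"""Synthetic surface generator: operator contracts and study enumeration."""

import numpy as np
import pytest

from lithotex.areal import sq
from lithotex.furrows import direction_spectrum
from lithotex.heightmap import pretreat
from lithotex.synth import (
    SKILL_PRESETS,
    TOOLS,
    GeneratorConfig,
    Participant,
    StudyDesign,
    apply_engraving_groove,
    apply_pecking,
    apply_polishing,
    apply_sawing,
    apply_scraping,
    experimental_modalities,
    full_study_design,
    generate_study,
    make_base_substrate,
    synthesize_modality,
)
from lithotex.synth.tools import DesignError

SKILL = SKILL_PRESETS["intermediate"]


class TestSubstrate:
    def test_zero_amplitude_gives_flat_map(self):
        cfg = GeneratorConfig(size_mm=(3, 3), spacing=0.05, substrate_rms=0.0, noise_rms=0.0)
        m = make_base_substrate(cfg)
        assert sq(m) == 0.0

    def test_deterministic_under_seed(self, fast_cfg):
        a = make_base_substrate(fast_cfg, seed=42)
        b = make_base_substrate(fast_cfg, seed=42)
        np.testing.assert_array_equal(a.heights, b.heights)

    def test_rms_normalization(self):
        cfg = GeneratorConfig(size_mm=(5, 5), spacing=0.025, substrate_hurst=0.8,
                              substrate_rms=0.05, pore_density=0.0, noise_rms=0.0)
        vals = [make_base_substrate(cfg, seed=s).heights.std() for s in range(20)]
        assert np.mean(vals) == pytest.approx(0.05, rel=0.15)

    @pytest.mark.parametrize("bad", [
        dict(size_mm=(0, 5)), dict(spacing=-0.1), dict(substrate_hurst=1.5),
        dict(substrate_rms=0.001, noise_rms=0.002),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(Exception):
            GeneratorConfig(**bad)


class TestSawing:
    def test_zero_amplitude_identity(self, fast_cfg):
        m = make_base_substrate(fast_cfg)
        out = apply_sawing(m, groove_amplitude=0.0)
        np.testing.assert_array_equal(out.heights, m.heights)

    def test_orientation_recovered(self, fast_cfg):
        cfg = GeneratorConfig(size_mm=(5, 5), spacing=0.025, substrate_rms=0.002,
                              pore_density=0.0, noise_rms=0.0005)
        m = apply_sawing(make_base_substrate(cfg), orientation_deg=0.0,
                         groove_amplitude=0.05, period=0.5)
        spec = direction_spectrum(pretreat(m))
        found = spec.angles_deg[np.argmax(spec.power)]
        assert min(found, 180 - found) <= 2.0

    def test_anisotropy_increases(self, fast_cfg):
        from lithotex.areal import autocorrelation_params

        m = make_base_substrate(GeneratorConfig(size_mm=(5, 5), spacing=0.025, seed=1))
        sawed = apply_sawing(m, orientation_deg=30.0, groove_amplitude=0.05, period=0.5)
        _, str_before = autocorrelation_params(pretreat(m))
        _, str_after = autocorrelation_params(pretreat(sawed))
        assert str_after < str_before

    def test_aliasing_period_rejected(self, fast_cfg):
        m = make_base_substrate(fast_cfg)
        with pytest.raises(Exception):
            apply_sawing(m, period=2 * m.spacing)


class TestPecking:
    def test_zero_budget_identity(self, fast_cfg):
        m = make_base_substrate(fast_cfg)
        out = apply_pecking(m, TOOLS["pick_point"], SKILL, budget_min=0.0)
        np.testing.assert_array_equal(out.heights, m.heights)

    def test_single_crater_depth(self):
        from lithotex.synth.surfaces import _stamp_cap

        z = np.zeros((200, 200))
        _stamp_cap(z, 0.025, 2.5, 2.5, 0.5, 0.3, 0.2, 30.0)
        assert z.min() == pytest.approx(-0.2, abs=1e-9)

    def test_material_only_removed(self, fast_cfg):
        m = make_base_substrate(fast_cfg)
        out = apply_pecking(m, TOOLS["pick_point"], SKILL, seed=3)
        assert np.all(out.heights <= m.heights + 1e-12)

    def test_expert_orientations_more_concentrated(self, fast_cfg):
        m = make_base_substrate(fast_cfg)

        def circ_var(skill):
            out = apply_pecking(m, TOOLS["pick_point"], SKILL_PRESETS[skill], seed=5,
                                orientation_mean_deg=40.0)
            o = np.deg2rad(2 * np.asarray(out.meta["crater_orientations_deg"]))
            return 1 - np.hypot(np.sin(o).mean(), np.cos(o).mean())

        assert circ_var("expert") < circ_var("novice")

    def test_wrong_tool_rejected(self, fast_cfg):
        m = make_base_substrate(fast_cfg)
        with pytest.raises(Exception):
            apply_pecking(m, TOOLS["blade_edge"], SKILL)

    def test_zero_rate_warns(self, fast_cfg):
        m = make_base_substrate(fast_cfg)
        with pytest.warns(UserWarning):
            apply_pecking(m, TOOLS["pick_point"], SKILL, rate=0.0)


class TestScraping:
    def test_zero_budget_identity(self, fast_cfg):
        m = make_base_substrate(fast_cfg)
        out = apply_scraping(m, TOOLS["endscraper"], SKILL, budget_min=0.0)
        np.testing.assert_array_equal(out.heights, m.heights)

    def test_dominant_direction_follows_strokes(self):
        cfg = GeneratorConfig(size_mm=(5, 5), spacing=0.025, substrate_rms=0.002,
                              pore_density=0.0, noise_rms=0.0005)
        m = apply_scraping(make_base_substrate(cfg), TOOLS["endscraper"],
                           SKILL_PRESETS["expert"], seed=2, orientation_mean_deg=30.0,
                           cross_fraction=0.0)
        spec = direction_spectrum(pretreat(m))
        found = spec.angles_deg[np.argmax(spec.power)]
        assert min(abs(found - 30.0), 180 - abs(found - 30.0)) <= 6.0

    def test_sq_decreases_with_passes_on_pecked_substrate(self, fast_cfg):
        m = apply_pecking(make_base_substrate(fast_cfg, seed=2), TOOLS["pick_point"], SKILL, seed=1)
        values = [sq(pretreat(m))]
        for i in range(3):
            m = apply_scraping(m, TOOLS["endscraper"], SKILL, budget_min=2.0, seed=10 + i)
            values.append(sq(pretreat(m)))
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_material_only_removed(self, fast_cfg):
        m = make_base_substrate(fast_cfg)
        out = apply_scraping(m, TOOLS["blade_edge"], SKILL, seed=4)
        assert np.all(out.heights <= m.heights + 1e-12)


class TestPolishing:
    def test_zero_budget_identity(self, fast_cfg):
        m = make_base_substrate(fast_cfg)
        out = apply_polishing(m, TOOLS["skin"], budget_min=0.0)
        np.testing.assert_array_equal(out.heights, m.heights)

    def test_polish_of_scraped_raises_density_lowers_depth(self):
        from lithotex.furrows import detect_furrows, furrow_params

        cfg = GeneratorConfig(seed=3)
        sc = apply_scraping(make_base_substrate(cfg, seed=3), TOOLS["blade_edge"], SKILL,
                            seed=3, orientation_mean_deg=20.0)
        po = apply_polishing(sc, TOOLS["skin"], seed=4)
        f_sc = furrow_params(detect_furrows(pretreat(sc)))
        f_po = furrow_params(detect_furrows(pretreat(po)))
        assert f_po["furrow_density"] > f_sc["furrow_density"]
        assert f_po["furrow_mean_depth"] < f_sc["furrow_mean_depth"]

    def test_multidirectional_polish_raises_str_of_sawed(self):
        from lithotex.areal import autocorrelation_params

        cfg = GeneratorConfig(size_mm=(5, 5), spacing=0.025, seed=6)
        sawed = apply_sawing(make_base_substrate(cfg), orientation_deg=10.0,
                             groove_amplitude=0.05, period=0.5)
        polished = apply_polishing(sawed, TOOLS["cobble"], seed=6)
        _, str_before = autocorrelation_params(pretreat(sawed))
        _, str_after = autocorrelation_params(pretreat(polished))
        assert str_after > str_before

    def test_wrong_tool_rejected(self, fast_cfg):
        with pytest.raises(Exception):
            apply_polishing(make_base_substrate(fast_cfg), TOOLS["pick_point"])


class TestEngraving:
    def test_nonpositive_depth_rejected(self, fast_cfg):
        with pytest.raises(Exception):
            apply_engraving_groove(make_base_substrate(fast_cfg), depth=0.0)

    def test_single_stroke_recovers_depth_and_symmetry(self):
        from lithotex.profiles import detect_landmarks, extract_profile, measure_profile

        cfg = GeneratorConfig(size_mm=(10, 10), spacing=0.025, substrate_rms=0.002,
                              pore_density=0.0, noise_rms=0.0005)
        g = apply_engraving_groove(make_base_substrate(cfg, seed=5), depth=0.3, strokes=1, seed=6)
        tr = extract_profile(pretreat(g), (5.0, 1.0), (5.0, 9.0))
        m = measure_profile(tr, detect_landmarks(tr))
        assert m.D_um == pytest.approx(300.0, abs=30.0)
        assert m.A < 0.05

    def test_more_strokes_widen_groove(self):
        from lithotex.profiles import detect_landmarks, extract_profile, measure_profile

        cfg = GeneratorConfig(size_mm=(10, 10), spacing=0.025, substrate_rms=0.002,
                              pore_density=0.0, noise_rms=0.0005)
        wis = {}
        for strokes in (1, 5):
            g = apply_engraving_groove(make_base_substrate(cfg, seed=5), depth=0.3,
                                       strokes=strokes, seed=7)
            tr = extract_profile(pretreat(g), (5.0, 1.0), (5.0, 9.0))
            wis[strokes] = measure_profile(tr, detect_landmarks(tr)).WIS_um
        assert wis[5] > wis[1]


class TestStudy:
    def test_modalities_enumerate_design(self):
        mods = experimental_modalities()
        assert len(mods) == 19
        design = full_study_design()
        assert design.n_trials == 95  # 19 modalities x 5 participants

    def test_saw_composition_equals_direct_application(self, fast_cfg):
        from lithotex.synth.tools import ModalitySpec, ModalityStep

        spec = ModalitySpec("SAW", (ModalityStep("saw", TOOLS["pick_point"]),))
        m = synthesize_modality(spec, SKILL, fast_cfg, seed=11)
        assert m.meta["provenance"][-1]["step"] == "saw"

    def test_label_table_schema_and_determinism(self):
        cfg = GeneratorConfig(size_mm=(2, 2), spacing=0.1, seed=0)
        design = StudyDesign(
            experimental_modalities()[:2],
            [Participant("a", SKILL), Participant("b", SKILL_PRESETS["expert"])],
            seed=5,
        )
        maps1, labels1 = generate_study(design, cfg)
        maps2, labels2 = generate_study(design, cfg)
        assert len(maps1) == design.n_trials
        assert labels1.to_csv() == labels2.to_csv()
        np.testing.assert_array_equal(maps1[0].heights, maps2[0].heights)
        assert set(labels1.columns) >= {"modality", "technique_class", "tools", "skill",
                                        "participant", "seed"}

    def test_single_trial_design(self):
        cfg = GeneratorConfig(size_mm=(2, 2), spacing=0.1)
        design = StudyDesign(experimental_modalities()[:1], [Participant("solo", SKILL)])
        maps, labels = generate_study(design, cfg)
        assert len(maps) == 1 and len(labels) == 1

    def test_duplicate_participants_rejected(self):
        with pytest.raises(DesignError):
            StudyDesign(experimental_modalities()[:1],
                        [Participant("x", SKILL), Participant("x", SKILL)])
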