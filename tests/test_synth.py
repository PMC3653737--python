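"""Synthetic cohort generator: determinism, perturbation laws, calibration."""

import numpy as np
import pytest

from contourbench import (
    AnatomyConfig,
    AxisTransform,
    ObserverModel,
    align_structure_set,
    compare_structures,
    emulate_autoseg,
    intersection_volume,
    make_cohort,
    make_reference_anatomy,
    perturb_observer,
    scramble_coordinates,
    structure_volume,
    structure_z_extent,
    vertex_agreement,
    z_extent_diffs,
)
from contourbench.errors import ConfigError
from contourbench.io import structure_set_to_dict


class TestReferenceAnatomy:
    def test_deterministic_construction(self):
        a = make_reference_anatomy(AnatomyConfig(), vertices_per_contour=32)
        b = make_reference_anatomy(AnatomyConfig(), vertices_per_contour=32)
        assert structure_set_to_dict(a) == structure_set_to_dict(b)

    def test_expected_roles_and_fiducials(self, reference_anatomy):
        assert set(reference_anatomy.roles()) == {"CTV", "bladder", "rectum"}
        assert len(reference_anatomy.fiducials) == 4

    def test_prostate_volume_near_closed_form(self):
        ref = make_reference_anatomy(AnatomyConfig(include_seminal_vesicles=False))
        exact = 4 / 3 * np.pi * 2.0 * 1.5 * 1.8
        assert structure_volume(ref["CTV"]) == pytest.approx(exact, rel=0.03)

    def test_seminal_vesicles_extend_ctv_superiorly(self):
        cfg = AnatomyConfig()
        hr = make_reference_anatomy(cfg)
        prostate_only = make_reference_anatomy(
            AnatomyConfig(include_seminal_vesicles=False)
        )
        assert structure_z_extent(hr["CTV"])[1] > structure_z_extent(prostate_only["CTV"])[1]

    def test_organ_volumes_in_plausible_ranges(self, reference_anatomy):
        v = {r: structure_volume(s) for r, s in reference_anatomy.structures.items()}
        assert 20 < v["CTV"] < 40
        assert 120 < v["bladder"] < 220
        assert 30 < v["rectum"] < 130

    def test_too_few_slices_rejected(self):
        with pytest.raises(ConfigError):
            AnatomyConfig(slice_thickness=2.0)

    def test_all_contours_simple_and_ccw(self, reference_anatomy):
        from contourbench.model import signed_area

        for s in reference_anatomy.structures.values():
            for c in s.contours:
                assert signed_area(c.vertices) > 0


class TestPerturbObserver:
    def test_zero_model_is_identity(self, reference_anatomy):
        out = perturb_observer(
            reference_anatomy,
            ObserverModel(observer_id="A", radial_noise_sigma=0.0, global_scale=1.0),
        )
        assert structure_set_to_dict(out)["structures"] == (
            structure_set_to_dict(reference_anatomy)["structures"]
        )

    def test_seeded_determinism(self, reference_anatomy):
        m = ObserverModel(observer_id="A", seed=7)
        a = perturb_observer(reference_anatomy, m)
        b = perturb_observer(reference_anatomy, m)
        assert structure_set_to_dict(a) == structure_set_to_dict(b)

    def test_global_scale_cubes_volume(self):
        ref = make_reference_anatomy(AnatomyConfig(include_seminal_vesicles=False))
        obs = perturb_observer(
            ref, ObserverModel(observer_id="A", radial_noise_sigma=0.0, global_scale=1.26)
        )
        dv = compare_structures(obs["CTV"], ref["CTV"], "A").delta_v_pct
        # in-plane scaling is exact (1.26^2); the z extent is unchanged, so
        # the slab-sum volume grows slightly less than 1.26^3
        assert dv == pytest.approx(100.0 * (1.26**2 - 1), abs=5.0)

    def test_apex_shift_gives_exact_inferior_extent_difference(self, reference_anatomy):
        obs = perturb_observer(
            reference_anatomy,
            ObserverModel(observer_id="A", radial_noise_sigma=0.0, apex_shift_slices=-4),
        )
        dz_sup, dz_inf = z_extent_diffs(obs["CTV"], reference_anatomy["CTV"])
        assert dz_inf == pytest.approx(-1.2, abs=1e-9)
        assert dz_sup == pytest.approx(0.0, abs=1e-9)

    def test_rectum_superior_extension(self, reference_anatomy):
        obs = perturb_observer(
            reference_anatomy,
            ObserverModel(observer_id="A", radial_noise_sigma=0.0,
                          rectum_superior_extension_slices=3),
        )
        dz_sup, _ = z_extent_diffs(obs["rectum"], reference_anatomy["rectum"])
        assert dz_sup == pytest.approx(0.9, abs=1e-9)

    def test_perturbed_contours_remain_simple(self, reference_anatomy):
        # construction through Contour guarantees simplicity; re-assert on a
        # high-noise observer to exercise the repair path
        obs = perturb_observer(
            reference_anatomy, ObserverModel(observer_id="A", radial_noise_sigma=0.3, seed=3)
        )
        from shapely.geometry import Polygon

        for s in obs.structures.values():
            for c in s.contours:
                assert Polygon(c.vertices).is_valid


class TestAutosegSurrogate:
    def test_identity_bias(self, reference_anatomy):
        out = emulate_autoseg(reference_anatomy, bias_scale=1.0)
        assert structure_set_to_dict(out)["structures"] == (
            structure_set_to_dict(reference_anatomy)["structures"]
        )

    def test_volume_bias_follows_cube_law(self, reference_anatomy):
        auto = emulate_autoseg(reference_anatomy, bias_scale=0.78)
        for role in ("CTV", "bladder", "rectum"):
            ratio = structure_volume(auto[role]) / structure_volume(reference_anatomy[role])
            assert ratio == pytest.approx(0.78**3, rel=0.06)

    def test_observer_vs_autoseg_volume_excess(self, reference_anatomy):
        # unbiased observers vs a 0.78-scaled reference: dV ~ +110%
        auto = emulate_autoseg(reference_anatomy, bias_scale=0.78)
        rec = compare_structures(reference_anatomy["CTV"], auto["CTV"], "ref")
        assert rec.delta_v_pct == pytest.approx(100.0 * (1 / 0.78**3 - 1), abs=12.0)

    def test_anterior_shift_shows_in_surface_distance(self, reference_anatomy):
        auto = emulate_autoseg(
            reference_anatomy, bias_scale=1.0,
            bias_shift={"rectum": (0.0, 0.4, 0.0)},
        )
        rect = reference_anatomy["rectum"]
        mid = list(rect.slices())[len(rect.slices()) // 2]
        contour = rect.slices()[mid][0]
        anterior_vertex = contour.vertices[np.argmax(contour.vertices[:, 1])]
        d = vertex_agreement(anterior_vertex, mid, auto, "rectum", window=0)
        assert d == pytest.approx(0.4, abs=0.05)


class TestScrambleAndCohort:
    def test_identity_scramble_unchanged(self, reference_anatomy):
        out = scramble_coordinates(reference_anatomy, AxisTransform())
        assert structure_set_to_dict(out)["structures"] == (
            structure_set_to_dict(reference_anatomy)["structures"]
        )

    def test_different_transforms_differ(self, reference_anatomy):
        a = scramble_coordinates(reference_anatomy, AxisTransform(offsets=(1, 0, 0)))
        b = scramble_coordinates(reference_anatomy, AxisTransform(offsets=(2, 0, 0)))
        assert a.fiducials[0].x != b.fiducials[0].x

    def test_cohort_counts_and_manifest(self):
        cohort = make_cohort(n_observers=3, seed=5, vertices_per_contour=32)
        assert len(cohort.observers) == 3
        assert set(cohort.true_transforms) == {"A", "B", "C", "auto"}

    def test_cohort_deterministic(self):
        a = make_cohort(n_observers=2, seed=9, vertices_per_contour=32)
        b = make_cohort(n_observers=2, seed=9, vertices_per_contour=32)
        assert structure_set_to_dict(a.observers[0]) == structure_set_to_dict(b.observers[0])
        assert a.true_transforms == b.true_transforms

    def test_scramble_align_round_trip_preserves_dsc(self):
        cohort = make_cohort(n_observers=2, seed=11, vertices_per_contour=32)
        unscrambled = make_cohort(n_observers=2, seed=11, scramble=False,
                                  vertices_per_contour=32)
        for obs_s, obs_u in zip(cohort.observers, unscrambled.observers):
            aligned, _ = align_structure_set(obs_s, cohort.reference.fiducials)
            for role in ("CTV", "bladder", "rectum"):
                rec_a = compare_structures(aligned[role], cohort.reference[role], "a")
                rec_u = compare_structures(obs_u[role], unscrambled.reference[role], "u")
                assert rec_a.dsc == pytest.approx(rec_u.dsc, abs=1e-6)

    def test_bladder_agreement_exceeds_ctv_agreement(self, reference_anatomy):
        """Surface-to-volume effect: same noise hurts small organs more."""
        dscs = {"CTV": [], "bladder": []}
        for seed in range(8):
            obs = perturb_observer(
                reference_anatomy,
                ObserverModel(observer_id="x", radial_noise_sigma=0.15, seed=seed),
            )
            for role in dscs:
                rec = compare_structures(obs[role], reference_anatomy[role], "x")
                dscs[role].append(rec.dsc)
        assert np.mean(dscs["bladder"]) > np.mean(dscs["CTV"])
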