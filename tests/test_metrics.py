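"""Comparison statistics: volumes, dV/DSC/I, z extents, aggregation."""

import numpy as np
import pytest

from contourbench import (
    AnatomyConfig,
    Contour,
    MetricsRecord,
    RasterGrid,
    SlicePolygonSet,
    Structure,
    delta_v,
    dsc,
    intersection_fraction,
    intersection_volume,
    make_reference_anatomy,
    mask_area,
    metrics_table,
    rasterize,
    structure_volume,
    summarize_observers,
    union_structures,
    z_extent_diffs,
)
from contourbench.errors import (
    EmptyStructureError,
    GridMismatchError,
    InconsistentVolumesError,
    InsufficientObserversError,
    InvalidReferenceError,
)
from conftest import UNIT_SQUARE, cylinder_structure


def square_stack(n_slices, dz=0.3, z0=0.0, shift=(0.0, 0.0)):
    return Structure(
        "sq", "other",
        [Contour(z0 + k * dz, UNIT_SQUARE + np.asarray(shift)) for k in range(n_slices)],
        dz,
    )


@pytest.fixture(scope="module")
def ellipsoid():
    """Pure prostate ellipsoid, semi-axes 2.0 x 1.5 x 1.8 cm, 0.3 cm slices."""
    return make_reference_anatomy(AnatomyConfig(include_seminal_vesicles=False))["CTV"]


class TestVolume:
    def test_single_slice_slab(self):
        assert structure_volume(square_stack(1)) == pytest.approx(0.3)

    def test_ten_slice_stack(self):
        assert structure_volume(square_stack(10)) == pytest.approx(3.0)

    def test_empty_errors(self):
        with pytest.raises(EmptyStructureError):
            structure_volume(Structure("s", "other", [], 0.3))

    def test_ellipsoid_within_3pct_of_closed_form(self, ellipsoid):
        exact = 4.0 / 3.0 * np.pi * 2.0 * 1.5 * 1.8
        assert structure_volume(ellipsoid) == pytest.approx(exact, rel=0.03)


class TestIntersectionVolume:
    def test_self_intersection_is_own_volume(self, ellipsoid):
        assert intersection_volume(ellipsoid, ellipsoid) == pytest.approx(
            structure_volume(ellipsoid)
        )

    def test_z_disjoint_structures(self):
        a, b = square_stack(3, z0=0.0), square_stack(3, z0=3.0)
        assert intersection_volume(a, b) == 0.0

    def test_grid_offset_errors(self):
        a = square_stack(3, z0=0.0)
        b = square_stack(3, z0=0.1)
        with pytest.raises(GridMismatchError):
            intersection_volume(a, b)

    def test_thickness_mismatch_errors(self):
        with pytest.raises(GridMismatchError):
            intersection_volume(square_stack(3, dz=0.3), square_stack(3, dz=0.5))

    def test_overlapping_ellipsoids_match_raster_oracle(self, ellipsoid):
        shifted = Structure(
            "sq", "other", [c.translated(1.0, 0.0) for c in ellipsoid.contours],
            ellipsoid.slice_thickness,
        )
        v_clip = intersection_volume(ellipsoid, shifted)
        v_oracle = 0.0
        sl_a, sl_b = ellipsoid.slices(), shifted.slices()
        for z in sl_a:
            if z not in sl_b:
                continue
            pa = SlicePolygonSet(z, [c.vertices for c in sl_a[z]])
            pb = SlicePolygonSet(z, [c.vertices for c in sl_b[z]])
            grid = RasterGrid.covering([c.vertices for c in sl_a[z] + sl_b[z]], 0.01, pad=0.05)
            both = rasterize(pa, grid) & rasterize(pb, grid)
            v_oracle += mask_area(both, grid) * ellipsoid.slice_thickness
        assert v_clip == pytest.approx(v_oracle, rel=0.01)


class TestUnion:
    def test_union_with_self(self, ellipsoid):
        u = union_structures(ellipsoid, ellipsoid)
        assert structure_volume(u) == pytest.approx(structure_volume(ellipsoid))

    def test_z_disjoint_volumes_add(self):
        a, b = square_stack(3, z0=0.0), square_stack(4, z0=3.0)
        u = union_structures(a, b)
        assert structure_volume(u) == pytest.approx(
            structure_volume(a) + structure_volume(b)
        )

    def test_inclusion_exclusion(self, ellipsoid):
        shifted = Structure(
            "sq", "other", [c.translated(1.0, 0.0) for c in ellipsoid.contours],
            ellipsoid.slice_thickness,
        )
        lhs = structure_volume(ellipsoid) + structure_volume(shifted)
        rhs = structure_volume(union_structures(ellipsoid, shifted)) + intersection_volume(
            ellipsoid, shifted
        )
        assert lhs == pytest.approx(rhs, abs=1e-6)


class TestScalarFormulas:
    def test_delta_v_zero_and_double(self):
        assert delta_v(5.0, 5.0) == 0.0
        assert delta_v(10.0, 5.0) == 100.0

    def test_delta_v_published_row(self):
        # IR CTV observer F: printed inputs give 159.3, within rounding of
        # the printed 159.1 (the table's volumes are themselves rounded)
        assert delta_v(73.9, 28.5) == pytest.approx(159.1, abs=0.3)

    def test_delta_v_invalid_reference(self):
        with pytest.raises(InvalidReferenceError):
            delta_v(1.0, 0.0)

    def test_dsc_identity(self):
        assert dsc(3.0, 3.0, 3.0) == 1.0

    @pytest.mark.parametrize(
        "v_obs,v_ref,v_int,expected",
        [(50.2, 54.0, 40.3, 0.77), (158.8, 54.0, 54.0, 0.51)],
        ids=["typical-observer", "gross-outlier"],
    )
    def test_dsc_published_rows(self, v_obs, v_ref, v_int, expected):
        assert round(dsc(v_obs, v_ref, v_int), 2) == expected

    def test_dsc_symmetric(self):
        assert dsc(3.0, 7.0, 2.0) == dsc(7.0, 3.0, 2.0)

    def test_dsc_inconsistent_intersection(self):
        with pytest.raises(InconsistentVolumesError):
            dsc(3.0, 5.0, 4.0)

    def test_intersection_fraction_identity_and_zero(self):
        assert intersection_fraction(3.0, 3.0) == 1.0
        assert intersection_fraction(0.0, 3.0) == 0.0

    def test_intersection_fraction_published_row(self):
        assert round(intersection_fraction(31.1, 39.8), 2) == 0.78


class TestZExtentDiffs:
    def test_identical_extents(self):
        s = square_stack(5)
        assert z_extent_diffs(s, s) == (0.0, 0.0)

    def test_inferior_extension_sign_convention(self):
        ref = square_stack(5, z0=0.0)
        obs = square_stack(9, z0=-1.2)  # 4 extra inferior slices at 0.3 cm
        dz_sup, dz_inf = z_extent_diffs(obs, ref)
        assert dz_sup == pytest.approx(0.0)
        assert dz_inf == pytest.approx(-1.2)


def _records(values, role="CTV"):
    return [
        MetricsRecord(observer_id=f"o{i}", structure_role=role, v_obs=v)
        for i, v in enumerate(values)
    ]


class TestSummarize:
    # printed per-observer volume column of the published HR-case CTV table
    HR_CTV_VOLUMES = [50.2, 75.2, 60.0, 84.3, 41.2, 87.0, 78.6, 70.8, 158.8, 82.5, 62.8]

    def test_published_hr_ctv_mean_and_sd(self):
        s = summarize_observers(_records(self.HR_CTV_VOLUMES))
        assert round(s.means["v_obs"], 1) == 77.4
        assert round(s.sds["v_obs"], 1) == 30.7

    def test_published_ir_ctv_delta_v_mean(self):
        dv = [127.2, 118.6, 114.3, 124.9, 126.2, 159.1, 58.3]
        recs = [
            MetricsRecord(observer_id=f"o{i}", structure_role="CTV", delta_v_pct=v)
            for i, v in enumerate(dv)
        ]
        assert round(summarize_observers(recs).means["delta_v_pct"], 1) == 118.4

    def test_identical_records_have_zero_sd(self):
        s = summarize_observers(_records([10.0, 10.0]))
        assert s.sds["v_obs"] == 0.0

    def test_exclusion_applied_before_aggregation(self):
        s = summarize_observers(_records([10.0, 10.0, 100.0]), exclude=["o2"])
        assert s.means["v_obs"] == 10.0
        assert s.excluded_observers == ["o2"]

    def test_insufficient_observers(self):
        with pytest.raises(InsufficientObserversError):
            summarize_observers(_records([10.0]))


class TestMetricsTable:
    def test_footer_and_rounding(self):
        recs = [
            MetricsRecord("A", "CTV", v_obs=50.123, v_ref=54.0, delta_v_pct=-7.18,
                          v_intersect=40.31, dsc=0.7734, i_obs=0.8028, dz_sup=0.0, dz_inf=0.0),
            MetricsRecord("B", "CTV", v_obs=75.2, v_ref=54.0, delta_v_pct=39.4,
                          v_intersect=51.0, dsc=0.789, i_obs=0.678, dz_sup=0.3, dz_inf=-0.3),
        ]
        t = metrics_table(recs)
        assert list(t["observer"]) == ["A", "B", "mean", "sd"]
        assert t.loc[0, "V_obs_cm3"] == 50.1
        assert t.loc[0, "DSC"] == 0.77
        # footer mean computed from full precision, then rounded
        assert t.loc[2, "V_obs_cm3"] == round((50.123 + 75.2) / 2, 1)

    def test_missing_structure_rows_marked(self):
        recs = [
            MetricsRecord("A", "bladder", missing=True),
            MetricsRecord("B", "bladder", v_obs=10.0, v_ref=10.0, delta_v_pct=0.0,
                          v_intersect=10.0, dsc=1.0, i_obs=1.0, dz_sup=0.0, dz_inf=0.0),
        ]
        t = metrics_table(recs)
        assert t.loc[0, "DSC"] is None or np.isnan(t.loc[0, "DSC"])
        # one non-missing record -> no footer possible
        assert "mean" not in list(t["observer"])

    def test_record_invariant_validation(self):
        with pytest.raises(InconsistentVolumesError):
            MetricsRecord("A", "CTV", v_obs=5.0, v_ref=5.0, v_intersect=6.0)
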