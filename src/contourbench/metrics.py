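"""Quantitative comparison statistics for observer vs reference structures.

Scalar comparison of an observer-drawn structure against a reference
(typically auto-segmented) structure of the same role:

* slice-stack volume  V = sum over slices of (polygon area x slice thickness)
* percentage volume difference  dV = 100 (V_obs - V_ref) / V_ref
* Dice similarity coefficient  DSC = 2 V_int / (V_obs + V_ref)
* intersection fraction  I = V_int / V_obs
* superior/inferior extent differences dz_sup, dz_inf (positive = the
  observer's structure reaches a more superior slice)

plus multi-observer mean/SD aggregation with explicit outlier exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyStructureError,
    GridMismatchError,
    InconsistentVolumesError,
    InsufficientObserversError,
    InvalidReferenceError,
)
from .geometry import SlicePolygonSet, clip_intersection, clip_union
from .model import SLICE_TOL, Contour, Structure, StructureSet, structure_z_extent

_VOL_TOL = 1e-9


def structure_volume(s: Structure) -> float:
    """Slice-stack volume in cm^3: per-slice total polygon area x thickness.

    No end-cap tapering and no inter-slice interpolation: each occupied
    slice contributes a slab of constant cross-section.
    """
    if s.is_empty:
        raise EmptyStructureError(f"structure {s.name!r} has no contours")
    total = 0.0
    for _, contours in s.slices().items():
        total += sum(c.area for c in contours) * s.slice_thickness
    return total


def _check_compatible_grids(a: Structure, b: Structure) -> None:
    if abs(a.slice_thickness - b.slice_thickness) > SLICE_TOL:
        raise GridMismatchError(
            f"slice thickness mismatch: {a.slice_thickness} vs {b.slice_thickness} cm"
        )
    if a.is_empty or b.is_empty:
        return
    dz = a.contours[0].z - b.contours[0].z
    k = dz / a.slice_thickness
    if abs(k - round(k)) * a.slice_thickness > SLICE_TOL:
        raise GridMismatchError(
            f"slice grids of {a.name!r} and {b.name!r} are offset by a "
            "non-integer number of slices"
        )


def _paired_slices(a: Structure, b: Structure):
    """Yield (z, contours_a, contours_b) for slices occupied by both."""
    slices_b = b.slices()
    for za, ca in a.slices().items():
        for zb, cb in slices_b.items():
            if abs(za - zb) <= SLICE_TOL:
                yield za, ca, cb
                break


def intersection_volume(a: Structure, b: Structure) -> float:
    """Volume (cm^3) of the boolean intersection of two structures.

    Computed slice by slice on the common grid; slices occupied by only one
    structure contribute nothing.  Grids offset by less than the slice
    tolerance are snapped; larger offsets raise :class:`GridMismatchError`.
    """
    _check_compatible_grids(a, b)
    total = 0.0
    for z, ca, cb in _paired_slices(a, b):
        inter = clip_intersection(
            SlicePolygonSet(z, [c.vertices for c in ca]),
            SlicePolygonSet(z, [c.vertices for c in cb]),
        )
        total += inter.total_area * a.slice_thickness
    return total


def union_structures(a: Structure, b: Structure, name: str | None = None, role: str | None = None) -> Structure:
    """Boolean union of two structures on the same slice grid.

    Used e.g. to merge independent prostate and seminal-vesicle stacks into
    a single clinical target volume.  Satisfies inclusion-exclusion:
    V(a) + V(b) = V(a u b) + V(a n b).
    """
    _check_compatible_grids(a, b)
    slices_a, slices_b = a.slices(), b.slices()
    matched_b: set[float] = set()
    out: list[Contour] = []
    label = name or a.name
    for za, ca in slices_a.items():
        partner = None
        for zb in slices_b:
            if abs(za - zb) <= SLICE_TOL:
                partner = zb
                matched_b.add(zb)
                break
        if partner is None:
            out.extend(Contour(za, c.vertices, label) for c in ca)
        else:
            u = clip_union(
                SlicePolygonSet(za, [c.vertices for c in ca]),
                SlicePolygonSet(za, [c.vertices for c in slices_b[partner]]),
            )
            out.extend(Contour(za, v, label) for v in u.polygons)
    for zb, cb in slices_b.items():
        if zb not in matched_b:
            out.extend(Contour(zb, c.vertices, label) for c in cb)
    return Structure(label, role or a.role, out, a.slice_thickness)


def delta_v(v_obs: float, v_ref: float) -> float:
    """Percentage volume difference of observer relative to reference.

    ``100 * (v_obs - v_ref) / v_ref``; positive when the observer's
    structure is larger than the reference.
    """
    if v_ref <= 0:
        raise InvalidReferenceError(f"reference volume must be > 0, got {v_ref}")
    return 100.0 * (v_obs - v_ref) / v_ref


def dsc(v_obs: float, v_ref: float, v_int: float) -> float:
    """Dice similarity coefficient ``2 v_int / (v_obs + v_ref)``, in [0, 1]."""
    if v_obs <= 0 or v_ref <= 0:
        raise InvalidReferenceError("both volumes must be > 0")
    if v_int < -_VOL_TOL or v_int > min(v_obs, v_ref) + _VOL_TOL:
        raise InconsistentVolumesError(
            f"intersection volume {v_int} outside [0, min({v_obs}, {v_ref})]"
        )
    return 2.0 * v_int / (v_obs + v_ref)


def intersection_fraction(v_int: float, v_obs: float) -> float:
    """Fraction of the observer volume shared with the reference: v_int / v_obs."""
    if v_obs <= 0:
        raise InvalidReferenceError(f"observer volume must be > 0, got {v_obs}")
    if v_int < -_VOL_TOL or v_int > v_obs + _VOL_TOL:
        raise InconsistentVolumesError(f"intersection volume {v_int} outside [0, {v_obs}]")
    return v_int / v_obs


def z_extent_diffs(obs: Structure, ref: Structure) -> tuple[float, float]:
    """Extent differences (dz_sup, dz_inf) in cm, observer minus reference.

    Positive dz_sup: the observer's most superior slice is more superior
    than the reference's; positive dz_inf likewise at the inferior end (so
    an observer extending further inferiorly gives a negative dz_inf).
    """
    inf_o, sup_o = structure_z_extent(obs)
    inf_r, sup_r = structure_z_extent(ref)
    return (sup_o - sup_r, inf_o - inf_r)


@dataclass
class MetricsRecord:
    """One observer-vs-reference comparison row for a single structure role.

    Missing structures (a role the observer did not segment) yield a record
    with ``missing=True`` and all metric fields ``None``.
    """

    observer_id: str
    structure_role: str
    v_obs: float | None = None
    v_ref: float | None = None
    delta_v_pct: float | None = None
    v_intersect: float | None = None
    dsc: float | None = None
    i_obs: float | None = None
    dz_sup: float | None = None
    dz_inf: float | None = None
    missing: bool = False

    def __post_init__(self) -> None:
        if self.missing:
            return
        if self.v_intersect is not None and self.v_obs is not None and self.v_ref is not None:
            if self.v_intersect > min(self.v_obs, self.v_ref) + _VOL_TOL:
                raise InconsistentVolumesError(
                    f"V_int={self.v_intersect} exceeds min(V_obs, V_ref)"
                )
        for val, name in ((self.dsc, "DSC"), (self.i_obs, "I")):
            if val is not None and not (-_VOL_TOL <= val <= 1 + _VOL_TOL):
                raise InconsistentVolumesError(f"{name}={val} outside [0, 1]")


#: Metric fields aggregated by :func:`summarize_observers`.
METRIC_FIELDS = ("v_obs", "delta_v_pct", "v_intersect", "dsc", "i_obs", "dz_sup", "dz_inf")


@dataclass
class ObserverSummary:
    """Per-metric mean and sample SD across included observers."""

    structure_role: str
    n: int
    means: dict[str, float]
    sds: dict[str, float]
    excluded_observers: list[str] = field(default_factory=list)


def summarize_observers(
    records: Sequence[MetricsRecord], exclude: Iterable[str] = ()
) -> ObserverSummary:
    """Mean and sample SD (n-1 denominator) of each metric over observers.

    ``exclude`` lists observer ids dropped before aggregation (outlier
    handling); records flagged missing are skipped per metric.  At least
    two included records are required.
    """
    exclude = set(exclude)
    included = [r for r in records if r.observer_id not in exclude and not r.missing]
    if len(included) < 2:
        raise InsufficientObserversError(
            f"need >= 2 included observers, have {len(included)}"
        )
    role = included[0].structure_role
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for m in METRIC_FIELDS:
        vals = np.array([getattr(r, m) for r in included if getattr(r, m) is not None])
        if len(vals) == 0:
            continue
        means[m] = float(np.mean(vals))
        sds[m] = float(np.std(vals, ddof=1)) if len(vals) >= 2 else float("nan")
    return ObserverSummary(role, len(included), means, sds, sorted(exclude))


def compare_structures(obs: Structure, ref: Structure, observer_id: str) -> MetricsRecord:
    """Full scalar comparison of one observer structure against the reference."""
    v_o = structure_volume(obs)
    v_r = structure_volume(ref)
    v_i = intersection_volume(obs, ref)
    # clamp clipper round-off so ratios stay in range
    v_i = min(v_i, v_o, v_r)
    dzs, dzi = z_extent_diffs(obs, ref)
    return MetricsRecord(
        observer_id=observer_id,
        structure_role=obs.role,
        v_obs=v_o,
        v_ref=v_r,
        delta_v_pct=delta_v(v_o, v_r),
        v_intersect=v_i,
        dsc=dsc(v_o, v_r, v_i),
        i_obs=intersection_fraction(v_i, v_o),
        dz_sup=dzs,
        dz_inf=dzi,
    )


def compare_sets(
    observer: StructureSet, reference: StructureSet, roles: Sequence[str] | None = None
) -> list[MetricsRecord]:
    """Compare every requested role of an observer set against the reference.

    Roles absent from the observer set yield missing-marked records (the
    comparison continues); roles absent from the reference are skipped.
    """
    if roles is None:
        roles = reference.roles()
    out = []
    for role in roles:
        if role not in reference:
            continue
        if role not in observer:
            out.append(MetricsRecord(observer.observer_id, role, missing=True))
            continue
        out.append(compare_structures(observer[role], reference[role], observer.observer_id))
    return out


_ROUND = {"v_obs": 1, "v_ref": 1, "delta_v_pct": 1, "v_intersect": 1,
          "dsc": 2, "i_obs": 2, "dz_sup": 2, "dz_inf": 2}

_COLUMNS = ["observer", "role", "V_obs_cm3", "dV_pct", "V_int_cm3", "DSC", "I",
            "dz_sup_cm", "dz_inf_cm"]
_FIELD_FOR_COLUMN = {"V_obs_cm3": "v_obs", "dV_pct": "delta_v_pct",
                     "V_int_cm3": "v_intersect", "DSC": "dsc", "I": "i_obs",
                     "dz_sup_cm": "dz_sup", "dz_inf_cm": "dz_inf"}


def metrics_table(
    records: Sequence[MetricsRecord],
    exclude: Iterable[str] = (),
    rounded: bool = True,
) -> pd.DataFrame:
    """Report table: one row per observer plus mean/SD footer rows.

    Volumes and percentage differences are rounded to 1 decimal, DSC and
    intersection fraction to 2, matching the reporting convention; means
    are computed from full-precision values before rounding.  Missing
    structures appear as empty cells.
    """
    rows = []
    for r in records:
        row: dict[str, object] = {"observer": r.observer_id, "role": r.structure_role}
        for col, f in _FIELD_FOR_COLUMN.items():
            val = getattr(r, f)
            if val is None:
                row[col] = None
            else:
                row[col] = round(val, _ROUND[f]) if rounded else val
        rows.append(row)
    try:
        summ = summarize_observers(records, exclude)
        mean_row = {"observer": "mean", "role": summ.structure_role}
        sd_row = {"observer": "sd", "role": summ.structure_role}
        for col, f in _FIELD_FOR_COLUMN.items():
            nd = _ROUND[f]
            mean_row[col] = round(summ.means[f], nd) if f in summ.means and rounded else summ.means.get(f)
            sd_row[col] = round(summ.sds[f], nd) if f in summ.sds and rounded else summ.sds.get(f)
        rows.extend([mean_row, sd_row])
    except InsufficientObserversError:
        pass
    return pd.DataFrame(rows, columns=_COLUMNS)
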