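"""Planar-contour data model for radiotherapy structure sets.

A *structure* (prostate/CTV, bladder, rectum, ...) is the 3D object made of
closed planar polygons ("contours") drawn on successive axial CT slices.
All coordinates are centimetres; the axes follow the radiological
convention: x left-right, y anterior-posterior, z superior-inferior with
larger z more superior.  Slices sit on a regular grid with spacing equal to
the slice thickness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import (
    DegenerateContourError,
    EmptyStructureError,
    GridMismatchError,
    InvalidGeometryError,
)

#: Two contours are "on the same slice" if their z differ by less than this (cm).
SLICE_TOL = 0.01

#: Structure roles recognised throughout the package.
ROLES = ("CTV", "GTV", "bladder", "rectum", "other")


def signed_area(vertices: np.ndarray) -> float:
    """Shoelace signed area of an open vertex loop (positive = CCW)."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def normalize_contour(raw_vertices: Sequence[Sequence[float]]) -> np.ndarray:
    """Canonicalize a raw vertex list into an open, CCW, simple polygon.

    Drops an explicit closing repeat of the first vertex and any consecutive
    duplicates, enforces counter-clockwise orientation, and validates that
    the polygon is simple.

    Parameters
    ----------
    raw_vertices : sequence of (x, y)
        Ordered boundary points in cm.  May or may not repeat the first
        point at the end.

    Returns
    -------
    numpy.ndarray of shape (n, 2)
        Open CCW vertex loop (closure is implicit).

    Raises
    ------
    DegenerateContourError
        Fewer than 3 distinct points, or zero enclosed area.
    InvalidGeometryError
        Self-intersecting boundary.
    """
    v = np.asarray(raw_vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise DegenerateContourError(f"expected (n, 2) vertex array, got {v.shape}")
    # drop closing repeat(s) of the first vertex
    while len(v) > 1 and np.allclose(v[-1], v[0]):
        v = v[:-1]
    # drop consecutive duplicates
    if len(v) > 1:
        keep = np.ones(len(v), dtype=bool)
        keep[1:] = ~np.all(np.isclose(v[1:], v[:-1]), axis=1)
        v = v[keep]
    if len(v) < 3 or len(np.unique(v, axis=0)) < 3:
        raise DegenerateContourError("fewer than 3 distinct vertices")
    rel = v[1:] - v[0]
    cross = rel[:, 0, None] * rel[None, :, 1] - rel[:, 1, None] * rel[None, :, 0]
    if np.allclose(cross, 0.0):
        raise DegenerateContourError("contour encloses zero area (collinear vertices)")
    poly = _ShapelyPolygon(v)
    if not poly.is_valid:
        raise InvalidGeometryError("self-intersecting contour")
    if poly.area == 0.0:
        raise DegenerateContourError("contour encloses zero area (collinear vertices)")
    if signed_area(v) < 0.0:
        v = v[::-1].copy()
    return v


@dataclass(frozen=True)
class Contour:
    """One closed planar polygon at a fixed axial position.

    ``vertices`` is an open CCW loop in cm; ``z`` is the axial coordinate in
    cm; ``label`` names the structure the contour belongs to.
    """

    z: float
    vertices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "vertices", normalize_contour(self.vertices))

    @property
    def area(self) -> float:
        """Enclosed area in cm^2 (positive by the CCW convention)."""
        return signed_area(self.vertices)

    def translated(self, dx: float, dy: float) -> "Contour":
        return Contour(self.z, self.vertices + np.array([dx, dy]), self.label)


@dataclass
class Structure:
    """A named stack of contours with a fixed slice spacing.

    Multiple polygons may share one slice (e.g. seminal-vesicle lobes); their
    areas add.  Contour z positions must lie on a regular grid with spacing
    ``slice_thickness`` (tolerance :data:`SLICE_TOL`).
    """

    name: str
    role: str
    contours: list[Contour]
    slice_thickness: float

    def __post_init__(self) -> None:
        if self.slice_thickness <= 0:
            raise GridMismatchError(f"slice_thickness must be > 0, got {self.slice_thickness}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        self.contours = sorted(self.contours, key=lambda c: c.z)
        self._check_grid()

    def _check_grid(self) -> None:
        if not self.contours:
            return
        z = np.array([c.z for c in self.contours])
        k = (z - z[0]) / self.slice_thickness
        if np.any(np.abs(k - np.round(k)) * self.slice_thickness > SLICE_TOL):
            raise GridMismatchError(
                f"contour z positions of {self.name!r} do not lie on a regular "
                f"grid with spacing {self.slice_thickness} cm"
            )

    @property
    def is_empty(self) -> bool:
        return not self.contours

    def slices(self) -> dict[float, list[Contour]]:
        """Contours grouped by slice, keyed by representative z (ascending)."""
        groups: dict[float, list[Contour]] = {}
        for c in self.contours:
            for z0 in groups:
                if abs(c.z - z0) <= SLICE_TOL:
                    groups[z0].append(c)
                    break
            else:
                groups[c.z] = [c]
        return dict(sorted(groups.items()))

    def slice_index(self, z: float, origin: float) -> int:
        """Integer grid index of axial position ``z`` relative to ``origin``."""
        return int(round((z - origin) / self.slice_thickness))


def structure_z_extent(s: Structure) -> tuple[float, float]:
    """Most inferior and most superior slice positions (z_inf, z_sup), cm.

    Raises
    ------
    EmptyStructureError
        If the structure has no contours.
    """
    if s.is_empty:
        raise EmptyStructureError(f"structure {s.name!r} has no contours")
    z = [c.z for c in s.contours]
    return (min(z), max(z))


@dataclass(frozen=True)
class Fiducial:
    """A labelled radio-opaque marker point, cm."""

    label: str
    x: float
    y: float
    z: float

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class AxisTransform:
    """Per-axis sign flip (+1/-1) and translation, cm.

    Models the coordinate changes introduced by treatment-planning-system
    import/export round trips: a translation and/or inversion on each axis
    independently, never rotation or scaling.
    """

    signs: tuple[int, int, int] = (1, 1, 1)
    offsets: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(s not in (1, -1) for s in self.signs):
            raise ValueError(f"signs must be +1 or -1, got {self.signs}")

    @property
    def is_identity(self) -> bool:
        return self.signs == (1, 1, 1) and all(t == 0.0 for t in self.offsets)

    def apply_point(self, xyz: Sequence[float]) -> np.ndarray:
        s = np.array(self.signs, dtype=float)
        t = np.array(self.offsets, dtype=float)
        return s * np.asarray(xyz, dtype=float) + t

    def inverse(self) -> "AxisTransform":
        # x' = s x + t  =>  x = s x' - s t   (s is its own inverse)
        s = self.signs
        t = self.offsets
        return AxisTransform(s, tuple(-si * ti for si, ti in zip(s, t)))

    def to_dict(self) -> dict:
        return {"signs": list(self.signs), "offsets_cm": list(self.offsets)}

    @classmethod
    def from_dict(cls, d: dict) -> "AxisTransform":
        return cls(tuple(int(s) for s in d["signs"]), tuple(float(t) for t in d["offsets_cm"]))


@dataclass
class StructureSet:
    """All structures segmented by one observer on one patient.

    ``structures`` is keyed by role/name; ``fiducials`` are optional external
    markers used to recover coordinate-frame changes; ``transform_record``
    stores the parameters of any realignment applied to the set.
    """

    patient_id: str
    observer_id: str
    structures: dict[str, Structure] = field(default_factory=dict)
    fiducials: list[Fiducial] = field(default_factory=list)
    transform_record: AxisTransform | None = None

    def __post_init__(self) -> None:
        if not self.observer_id:
            raise ValueError("observer_id must be nonempty")

    def __getitem__(self, key: str) -> Structure:
        return self.structures[key]

    def __contains__(self, key: str) -> bool:
        return key in self.structures

    def roles(self) -> list[str]:
        return list(self.structures)

    def add(self, s: Structure) -> None:
        if s.name in self.structures:
            raise ValueError(f"duplicate structure name {s.name!r}")
        self.structures[s.name] = s


def apply_transform(ss: StructureSet, t: AxisTransform) -> StructureSet:
    """Map every vertex and fiducial through a sign/offset transform.

    Per axis, ``coordinate' = sign * coordinate + offset``.  Areas and
    volumes are preserved (the map is an isometry up to reflection), and the
    slice grid stays regular.  A reflection in-plane reverses vertex order,
    so contours are re-normalized to CCW by construction.
    """
    sx, sy, sz = t.signs
    tx, ty, tz = t.offsets
    new_structures = {}
    for name, s in ss.structures.items():
        new_contours = []
        for c in s.contours:
            v = c.vertices * np.array([sx, sy]) + np.array([tx, ty])
            new_contours.append(Contour(sz * c.z + tz, v, c.label))
        new_structures[name] = Structure(s.name, s.role, new_contours, s.slice_thickness)
    new_fids = [
        Fiducial(f.label, sx * f.x + tx, sy * f.y + ty, sz * f.z + tz) for f in ss.fiducials
    ]
    return StructureSet(
        patient_id=ss.patient_id,
        observer_id=ss.observer_id,
        structures=new_structures,
        fiducials=new_fids,
        transform_record=t,
    )
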