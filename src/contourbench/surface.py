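"""Per-vertex surface maps of observer-reference spatial disagreement.

For every vertex of the reference (typically auto-segmented) structure, the
map records the mean over observers of that observer's closest contour
distance within a slice window around the vertex's slice.  Vertices where
no observer has any contour inside the window are flagged undefined — these
show up as blank bands at the superior/inferior ends when observers stop
contouring short of the reference extent.

Two documented modelling assumptions, each switchable:

* the per-observer value is the *minimum* boundary distance over the slice
  window (``reduce="min"``; an identical observer then scores exactly 0);
  ``reduce="mean"`` averages over the window's slices instead.
* distances are in-plane 2D by default; ``distance_3d=True`` adds the
  out-of-plane offset in quadrature.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientObserversError, MissingStructureError
from .geometry import SlicePolygonSet, point_to_contours_distance
from .model import SLICE_TOL, Structure, StructureSet

#: Sentinel written for undefined vertices in exports (never 0).
UNDEFINED_SENTINEL = -1.0


@dataclass
class SurfaceMap:
    """Mean observer-distance field sampled at reference contour vertices.

    ``vertices`` is (n, 3) with the x, y, z of each reference vertex;
    ``values`` holds the mean distance in cm (NaN where undefined);
    ``observer_count`` gives the number of observers contributing per
    vertex (0 exactly where the value is undefined).
    """

    reference_role: str
    vertices: np.ndarray
    values: np.ndarray
    observer_count: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return self.observer_count > 0

    @property
    def max_defined(self) -> float:
        d = self.values[self.defined]
        return float(d.max()) if len(d) else 0.0


def _observer_slices(observer: StructureSet, role: str) -> dict[float, SlicePolygonSet]:
    if role not in observer:
        raise MissingStructureError(
            f"observer {observer.observer_id!r} has no {role!r} structure"
        )
    s = observer[role]
    return {
        z: SlicePolygonSet(z, [c.vertices for c in contours])
        for z, contours in s.slices().items()
    }


def vertex_agreement(
    point_xy,
    z: float,
    observer: StructureSet,
    role: str,
    window: int = 1,
    slice_thickness: float | None = None,
    reduce: str = "min",
    distance_3d: bool = False,
) -> float | None:
    """Distance (cm) from one reference vertex to an observer's structure.

    Considers the observer's contours on the vertex's slice and up to
    ``window`` slices on each side.  Returns ``None`` (no-contour signal)
    if the observer has no contour in that window.
    """
    slices = _observer_slices(observer, role)
    if slice_thickness is None:
        slice_thickness = observer[role].slice_thickness
    dists = []
    for zc, sps in slices.items():
        if abs(zc - z) <= window * slice_thickness + SLICE_TOL:
            d = point_to_contours_distance(point_xy, sps)
            if d is None:
                continue
            if distance_3d:
                d = float(np.hypot(d, zc - z))
            dists.append(d)
    if not dists:
        return None
    if reduce == "min":
        return min(dists)
    if reduce == "mean":
        return float(np.mean(dists))
    raise ValueError(f"unknown reduce mode {reduce!r}")


def surface_map(
    reference: Structure,
    observers: list[StructureSet],
    role: str | None = None,
    window: int = 1,
    exclude: list[str] | None = None,
    reduce: str = "min",
    distance_3d: bool = False,
) -> SurfaceMap:
    """Mean observer-distance map over the reference structure's vertices.

    Observers listed in ``exclude`` (e.g. a gross volume outlier) are
    dropped before averaging.  A vertex is undefined when every included
    observer returns the no-contour signal there.
    """
    role = role or reference.role
    exclude = set(exclude or ())
    included = [o for o in observers if o.observer_id not in exclude]
    if not included:
        raise InsufficientObserversError("all observers excluded from surface map")

    obs_slices = [_observer_slices(o, role) for o in included]
    dz = reference.slice_thickness

    verts, values, counts = [], [], []
    for z, contours in reference.slices().items():
        for c in contours:
            for vx, vy in c.vertices:
                per_obs = []
                for slices in obs_slices:
                    dists = []
                    for zc, sps in slices.items():
                        if abs(zc - z) <= window * dz + SLICE_TOL:
                            d = point_to_contours_distance((vx, vy), sps)
                            if d is None:
                                continue
                            if distance_3d:
                                d = float(np.hypot(d, zc - z))
                            dists.append(d)
                    if dists:
                        per_obs.append(min(dists) if reduce == "min" else float(np.mean(dists)))
                verts.append((vx, vy, z))
                counts.append(len(per_obs))
                values.append(float(np.mean(per_obs)) if per_obs else np.nan)
    return SurfaceMap(
        reference_role=role,
        vertices=np.array(verts, dtype=float),
        values=np.array(values, dtype=float),
        observer_count=np.array(counts, dtype=int),
    )


def export_surface_map(m: SurfaceMap, path, scale_max: float | None = None) -> float:
    """Write a surface map as per-vertex CSV rows; returns the scale maximum.

    Columns: x_cm, y_cm, z_cm, mean_distance_cm, n_observers, defined.
    Undefined vertices carry the sentinel value (never 0) and defined=0.
    ``scale_max`` is the global colour-scale maximum recorded in the header
    comment (defaults to this map's maximum defined value).
    """
    if scale_max is None:
        scale_max = m.max_defined
    with open(path, "w", newline="") as fh:
        fh.write(f"# role={m.reference_role} scale_max_cm={scale_max!r}\n")
        w = csv.writer(fh)
        w.writerow(["x_cm", "y_cm", "z_cm", "mean_distance_cm", "n_observers", "defined"])
        for (x, y, z), val, n in zip(m.vertices, m.values, m.observer_count):
            defined = int(n > 0)
            out = repr(float(val)) if defined else repr(UNDEFINED_SENTINEL)
            w.writerow([repr(float(x)), repr(float(y)), repr(float(z)), out, n, defined])
    return scale_max


def read_surface_map(path) -> SurfaceMap:
    """Round-trip reader for :func:`export_surface_map` output."""
    with open(path) as fh:
        header = fh.readline().strip()
        role = header.split("role=")[1].split()[0]
        rows = list(csv.DictReader(fh))
    verts = np.array([[float(r["x_cm"]), float(r["y_cm"]), float(r["z_cm"])] for r in rows])
    counts = np.array([int(r["n_observers"]) for r in rows])
    values = np.array(
        [float(r["mean_distance_cm"]) if int(r["defined"]) else np.nan for r in rows]
    )
    return SurfaceMap(role, verts, values, counts)
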