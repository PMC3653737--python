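"""Readers and writers for the package's native text dialects.

Formats (all UTF-8, all lengths cm):

* **Contour CSV** — one row per vertex, columns
  ``patient_id,observer_id,structure,role,z_cm,vertex_index,x_cm,y_cm``.
  Vertices of one contour are contiguous and ordered; a new contour starts
  whenever ``vertex_index`` does not increase.  One file may hold many
  observers' sets.
* **StructureSet JSON** — a nested object mirroring the data model, with
  fiducials and any recorded realignment transform.
* **Fiducial CSV** — ``label,x_cm,y_cm,z_cm``.
* **DICOM-RT Structure Set** (read-only, optional) — geometry of
  CLOSED_PLANAR contour items only; everything else in the file is
  ignored.  DICOM stores mm; coordinates are converted to cm on ingest.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .errors import ConfigError, GridMismatchError
from .model import AxisTransform, Contour, Fiducial, Structure, StructureSet

_CSV_COLUMNS = ["patient_id", "observer_id", "structure", "role", "z_cm",
                "vertex_index", "x_cm", "y_cm"]


def _infer_slice_thickness(z_values: list[float]) -> float | None:
    z = np.unique(np.round(np.asarray(z_values, dtype=float), 6))
    if len(z) < 2:
        return None
    return float(np.min(np.diff(z)))


def write_contour_csv(sets: list[StructureSet] | StructureSet, path) -> None:
    """Write one or more structure sets in the per-vertex contour dialect."""
    if isinstance(sets, StructureSet):
        sets = [sets]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_COLUMNS)
        for ss in sets:
            for name, s in ss.structures.items():
                for c in s.contours:
                    for i, (x, y) in enumerate(c.vertices):
                        w.writerow([ss.patient_id, ss.observer_id, name, s.role,
                                    repr(float(c.z)), i, repr(float(x)), repr(float(y))])


def read_contour_csv(path, slice_thickness: float | None = None) -> list[StructureSet]:
    """Read all structure sets from a contour CSV.

    ``slice_thickness`` overrides inference; otherwise it is taken as the
    smallest axial gap between contours of each structure (an error for a
    single-slice structure with no override).
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != _CSV_COLUMNS:
            raise ConfigError(f"unexpected contour CSV header in {path}: {reader.fieldnames}")
        rows = list(reader)

    sets: dict[tuple[str, str], dict[str, dict]] = {}
    order: list[tuple[str, str]] = []
    for row in rows:
        key = (row["patient_id"], row["observer_id"])
        if key not in sets:
            sets[key] = {}
            order.append(key)
        sname = row["structure"]
        st = sets[key].setdefault(sname, {"role": row["role"], "contours": []})
        idx = int(row["vertex_index"])
        if idx == 0 or not st["contours"] or idx <= st["contours"][-1]["last_idx"]:
            st["contours"].append({"z": float(row["z_cm"]), "verts": [], "last_idx": -1})
        cur = st["contours"][-1]
        cur["verts"].append((float(row["x_cm"]), float(row["y_cm"])))
        cur["last_idx"] = idx

    out = []
    for (pid, oid) in order:
        ss = StructureSet(patient_id=pid, observer_id=oid)
        for sname, st in sets[(pid, oid)].items():
            contours = [Contour(c["z"], np.array(c["verts"]), sname) for c in st["contours"]]
            dt = slice_thickness or _infer_slice_thickness([c.z for c in contours])
            if dt is None:
                raise GridMismatchError(
                    f"cannot infer slice thickness for single-slice structure {sname!r}; "
                    "pass slice_thickness explicitly"
                )
            ss.add(Structure(sname, st["role"], contours, dt))
        out.append(ss)
    return out


def structure_set_to_dict(ss: StructureSet) -> dict:
    return {
        "patient_id": ss.patient_id,
        "observer_id": ss.observer_id,
        "structures": [
            {
                "name": s.name,
                "role": s.role,
                "slice_thickness_cm": s.slice_thickness,
                "contours": [
                    {"z_cm": float(c.z), "vertices": [[float(x), float(y)] for x, y in c.vertices]}
                    for c in s.contours
                ],
            }
            for s in ss.structures.values()
        ],
        "fiducials": [
            {"label": f.label, "x_cm": f.x, "y_cm": f.y, "z_cm": f.z} for f in ss.fiducials
        ],
        "transform": ss.transform_record.to_dict() if ss.transform_record else None,
    }


def structure_set_from_dict(d: dict) -> StructureSet:
    ss = StructureSet(patient_id=d["patient_id"], observer_id=d["observer_id"])
    for sd in d["structures"]:
        contours = [
            Contour(c["z_cm"], np.array(c["vertices"]), sd["name"]) for c in sd["contours"]
        ]
        ss.add(Structure(sd["name"], sd["role"], contours, sd["slice_thickness_cm"]))
    ss.fiducials = [
        Fiducial(f["label"], f["x_cm"], f["y_cm"], f["z_cm"]) for f in d.get("fiducials", [])
    ]
    if d.get("transform"):
        ss.transform_record = AxisTransform.from_dict(d["transform"])
    return ss


def write_structure_set_json(ss: StructureSet, path) -> None:
    Path(path).write_text(json.dumps(structure_set_to_dict(ss), indent=1))


def read_structure_set_json(path) -> StructureSet:
    return structure_set_from_dict(json.loads(Path(path).read_text()))


def write_fiducial_csv(fiducials: list[Fiducial], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "x_cm", "y_cm", "z_cm"])
        for f in fiducials:
            w.writerow([f.label, repr(f.x), repr(f.y), repr(f.z)])


def read_fiducial_csv(path) -> list[Fiducial]:
    with open(path, newline="") as fh:
        return [
            Fiducial(r["label"], float(r["x_cm"]), float(r["y_cm"]), float(r["z_cm"]))
            for r in csv.DictReader(fh)
        ]


_ROLE_KEYWORDS = {"ctv": "CTV", "gtv": "GTV", "bladder": "bladder", "rectum": "rectum"}


def _guess_role(name: str) -> str:
    lname = name.lower()
    for key, role in _ROLE_KEYWORDS.items():
        if key in lname:
            return role
    return "other"


def read_dicom_rtstruct(path, patient_id: str | None = None,
                        observer_id: str = "dicom") -> StructureSet:
    """Read CLOSED_PLANAR contour geometry from a DICOM-RT Structure Set.

    Only the geometry is used: ROI names, contour points (converted mm to
    cm) and the inferred slice spacing.  Non-planar contour items and all
    other DICOM content are ignored.
    """
    import pydicom

    ds = pydicom.dcmread(path)
    names = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}
    ss = StructureSet(
        patient_id=patient_id or str(getattr(ds, "PatientID", "unknown")),
        observer_id=observer_id,
    )
    for roi in ds.ROIContourSequence:
        name = names.get(int(roi.ReferencedROINumber), f"ROI{roi.ReferencedROINumber}")
        contours = []
        for item in getattr(roi, "ContourSequence", []):
            if str(getattr(item, "ContourGeometricType", "")) != "CLOSED_PLANAR":
                continue
            pts = np.asarray(item.ContourData, dtype=float).reshape(-1, 3) / 10.0
            contours.append(Contour(float(np.mean(pts[:, 2])), pts[:, :2], name))
        if not contours:
            continue
        dt = _infer_slice_thickness([c.z for c in contours]) or 0.3
        ss.add(Structure(name, _guess_role(name), contours, dt))
    return ss
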