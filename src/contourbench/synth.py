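"""Synthetic pelvic benchmarking cohort with known ground truth.

Emulates a structure-set benchmarking exercise: one reference "patient"
with prostate/CTV, bladder and rectum contour stacks on a 3 mm slice grid,
several observer variants carrying realistic disagreement patterns (smooth
radial noise, global over/under-contouring, extra inferior slices at the
prostatic apex, variable superior rectal extent), one deterministic
auto-segmenter surrogate with a systematic volume bias, and coordinate
scrambling (axis inversions/translations) that is recoverable from the
bundled skin fiducials.

Organ shapes are analytic solids sliced on the axial grid:

* prostate — ellipsoid (default semi-axes 2.0 x 1.5 x 1.8 cm);
* seminal vesicles — two small ellipsoid lobes merged with the prostate to
  form an HR-style CTV;
* bladder — superellipsoid (rounded-square cross-sections), superior to the
  prostate and touching its base;
* rectum — a gently curving tube posterior to the prostate.

Axes: x left-right, y anterior-posterior (+y anterior), z superior-inferior
(+z superior).  All lengths cm.  Every public operation is deterministic
given its seed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, GenerationError, InvalidGeometryError, DegenerateContourError
from .model import AxisTransform, Contour, Fiducial, Structure, StructureSet
from .metrics import union_structures

_TWO_PI = 2.0 * np.pi


@dataclass
class AnatomyConfig:
    """Geometry of the reference patient.

    Defaults give a 3 mm slice grid and organ volumes in the range seen in
    multi-observer pelvic benchmarking studies (prostate ~23 cm^3, bladder
    ~165 cm^3, rectum ~55 cm^3); the patient separations default to a
    larger-habitus case (40.6 cm left-right, 25.1 cm anterior-posterior at
    the prostate centre) and position the four skin fiducials.
    """

    slice_thickness: float = 0.3
    prostate_semi_axes: tuple[float, float, float] = (2.0, 1.5, 1.8)
    prostate_centre: tuple[float, float, float] = (0.0, 0.0, 1.65)
    include_seminal_vesicles: bool = True
    sv_semi_axes: tuple[float, float, float] = (0.9, 0.7, 1.1)
    sv_lateral_offset: float = 1.2
    sv_centre_yz: tuple[float, float] = (-0.8, 3.0)
    bladder_semi_axes: tuple[float, float, float] = (3.5, 3.2, 3.3)
    bladder_exponent: float = 2.5
    bladder_centre_xy: tuple[float, float] = (0.0, 1.0)
    rectum_centre_y: float = -3.2
    rectum_radius: float = 1.5
    rectum_radius_ripple: float = 0.15
    rectum_sway: float = 0.3
    rectum_z_range: tuple[float, float] = (-1.5, 6.0)
    separation_lr: float = 40.6
    separation_ap: float = 25.1

    def __post_init__(self) -> None:
        if self.slice_thickness <= 0:
            raise ConfigError("slice_thickness must be > 0")
        for dims in (self.prostate_semi_axes, self.sv_semi_axes, self.bladder_semi_axes):
            if any(d <= 0 for d in dims):
                raise ConfigError("all organ dimensions must be positive")
        if self.rectum_radius <= self.rectum_radius_ripple:
            raise ConfigError("rectum radius must exceed its ripple amplitude")
        for cz, name in (
            (2 * self.prostate_semi_axes[2], "prostate"),
            (2 * self.bladder_semi_axes[2], "bladder"),
            (self.rectum_z_range[1] - self.rectum_z_range[0], "rectum"),
        ):
            if cz < 3 * self.slice_thickness:
                raise ConfigError(f"{name} spans fewer than 3 slices")


@dataclass
class ObserverModel:
    """Perturbation parameters for one simulated observer.

    ``radial_noise_sigma`` (cm) is the RMS of a smooth, band-limited radial
    displacement of each contour; ``global_scale`` multiplies every radius
    (linear over/under-contouring); ``apex_shift_slices`` < 0 extends the
    CTV inferiorly by that many extra (tapered) apex slices;
    ``rectum_superior_extension_slices`` > 0 likewise extends the rectum
    superiorly.  Deterministic per ``seed``.
    """

    observer_id: str = "obs"
    radial_noise_sigma: float = 0.15
    global_scale: float = 1.0
    apex_shift_slices: int = 0
    rectum_superior_extension_slices: int = 0
    seed: int = 0
    n_harmonics: int = 4

    def __post_init__(self) -> None:
        if self.radial_noise_sigma < 0:
            raise ConfigError("radial_noise_sigma must be >= 0")
        if self.global_scale <= 0:
            raise ConfigError("global_scale must be > 0")


def _grid_slices(z_lo: float, z_hi: float, dz: float) -> np.ndarray:
    """Grid positions k*dz strictly inside (z_lo, z_hi)."""
    k_lo = int(np.ceil(z_lo / dz - 1e-9))
    k_hi = int(np.floor(z_hi / dz + 1e-9))
    z = np.arange(k_lo, k_hi + 1) * dz
    return z[(z > z_lo + 1e-9) & (z < z_hi - 1e-9)]


def _radial_contour(centre_xy, radius_fn, z: float, n: int, label: str) -> Contour:
    theta = np.arange(n) / n * _TWO_PI
    r = radius_fn(theta)
    v = np.column_stack(
        [centre_xy[0] + r * np.cos(theta), centre_xy[1] + r * np.sin(theta)]
    )
    return Contour(z, v, label)


def _ellipsoid_structure(
    name: str, role: str, centre, semi_axes, dz: float, n: int, exponent: float = 2.0
) -> Structure:
    cx, cy, cz = centre
    a, b, c = semi_axes
    contours = []
    for z in _grid_slices(cz - c, cz + c, dz):
        f = np.sqrt(max(0.0, 1.0 - ((z - cz) / c) ** 2))
        az, bz = a * f, b * f
        if min(az, bz) < 0.02:
            continue

        def radius(theta, az=az, bz=bz):
            p = exponent
            return (np.abs(np.cos(theta) / az) ** p + np.abs(np.sin(theta) / bz) ** p) ** (
                -1.0 / p
            )

        contours.append(_radial_contour((cx, cy), radius, z, n, name))
    return Structure(name, role, contours, dz)


def make_reference_anatomy(cfg: AnatomyConfig | None = None, vertices_per_contour: int = 64) -> StructureSet:
    """Build the reference structure set: CTV, bladder, rectum + fiducials.

    The CTV is the prostate ellipsoid, merged per slice with the two
    seminal-vesicle lobes when ``include_seminal_vesicles`` is set (the
    high-risk-style target definition).  Four radio-opaque skin fiducials
    sit at the lateral/anterior/posterior skin surface at distinct axial
    positions.
    """
    cfg = cfg or AnatomyConfig()
    dz = cfg.slice_thickness
    n = vertices_per_contour

    prostate = _ellipsoid_structure(
        "CTV", "CTV", cfg.prostate_centre, cfg.prostate_semi_axes, dz, n
    )
    if prostate.is_empty or len(prostate.slices()) < 3:
        raise ConfigError("prostate spans fewer than 3 occupied slices")
    ctv = prostate
    if cfg.include_seminal_vesicles:
        y_sv, z_sv = cfg.sv_centre_yz
        for side in (-1.0, 1.0):
            lobe = _ellipsoid_structure(
                "CTV", "CTV",
                (side * cfg.sv_lateral_offset, y_sv, z_sv),
                cfg.sv_semi_axes, dz, n,
            )
            ctv = union_structures(ctv, lobe, name="CTV", role="CTV")

    z_top_prostate = cfg.prostate_centre[2] + cfg.prostate_semi_axes[2]
    bladder_centre = (
        cfg.bladder_centre_xy[0],
        cfg.bladder_centre_xy[1],
        z_top_prostate + cfg.bladder_semi_axes[2],
    )
    bladder = _ellipsoid_structure(
        "bladder", "bladder", bladder_centre, cfg.bladder_semi_axes, dz, n,
        exponent=cfg.bladder_exponent,
    )

    z_lo, z_hi = cfg.rectum_z_range
    rectum_contours = []
    for z in _grid_slices(z_lo, z_hi, dz):
        cx = cfg.rectum_sway * np.sin(_TWO_PI * (z - z_lo) / (4.0 * (z_hi - z_lo)))
        r0 = cfg.rectum_radius + cfg.rectum_radius_ripple * np.cos(_TWO_PI * z / 5.0)
        rectum_contours.append(
            _radial_contour((cx, cfg.rectum_centre_y), lambda th, r0=r0: np.full_like(th, r0),
                            z, n, "rectum")
        )
    rectum = Structure("rectum", "rectum", rectum_contours, dz)

    half_lr = cfg.separation_lr / 2.0
    half_ap = cfg.separation_ap / 2.0
    fiducials = [
        Fiducial("F_left", -half_lr, 0.0, 5 * dz),
        Fiducial("F_right", half_lr, 0.0, 7 * dz),
        Fiducial("F_ant", 0.0, half_ap, 3 * dz),
        Fiducial("F_post", 0.0, -half_ap, 9 * dz),
    ]

    ss = StructureSet(patient_id="synthetic", observer_id="reference", fiducials=fiducials)
    for s in (ctv, bladder, rectum):
        ss.add(s)
    return ss


def _outward_normals(v: np.ndarray) -> np.ndarray:
    """Unit outward normals of a CCW vertex loop (averaged edge normals)."""
    tang = np.roll(v, -1, axis=0) - np.roll(v, 1, axis=0)
    n = np.column_stack([tang[:, 1], -tang[:, 0]])
    length = np.hypot(n[:, 0], n[:, 1])
    length[length == 0] = 1.0
    return n / length[:, None]


def _perturb_contour(c: Contour, scale: float, sigma: float, n_harm: int, rng) -> Contour:
    """Global scale about the centroid + smooth band-limited normal noise.

    The noise is a low-order Fourier series in the vertex index applied
    along local outward normals, so it stays smooth along the contour and
    works for non-star shapes (e.g. prostate + seminal-vesicle unions).
    Its RMS is capped at a third of the smallest centroid distance so tiny
    apex/pole contours cannot be turned inside out.  A draw that pinches a
    narrow neck (e.g. where seminal-vesicle lobes join the prostate) into a
    self-crossing is repaired by keeping the largest simple component; only
    if repair also fails ten times is generation abandoned.
    """
    centre = c.vertices.mean(axis=0)
    scaled = centre + scale * (c.vertices - centre)
    if sigma == 0.0:
        return Contour(c.z, scaled, c.label)
    n = len(scaled)
    r_min = float(np.hypot(*(scaled - centre).T).min())
    sigma_eff = min(sigma, r_min / 3.0)
    normals = _outward_normals(scaled)
    idx = np.arange(n) / n * _TWO_PI
    for _ in range(10):
        amp = rng.normal(0.0, sigma_eff * np.sqrt(2.0 / n_harm), size=n_harm)
        phase = rng.uniform(0.0, _TWO_PI, size=n_harm)
        noise = np.zeros(n)
        for k in range(1, n_harm + 1):
            noise += amp[k - 1] * np.cos(k * idx + phase[k - 1])
        v = scaled + noise[:, None] * normals
        try:
            return Contour(c.z, v, c.label)
        except (InvalidGeometryError, DegenerateContourError):
            pass
        repaired = _largest_simple_component(v)
        if repaired is not None and len(repaired) >= 3:
            try:
                return Contour(c.z, repaired, c.label)
            except (InvalidGeometryError, DegenerateContourError):
                pass
    raise GenerationError(f"could not perturb contour at z={c.z} into a simple polygon")


def _largest_simple_component(v: np.ndarray) -> np.ndarray | None:
    """Repair a self-crossing loop: largest polygon of its valid decomposition."""
    from shapely import make_valid
    from shapely.geometry import MultiPolygon, Polygon

    fixed = make_valid(Polygon(v))
    parts = fixed.geoms if isinstance(fixed, MultiPolygon) else [fixed]
    polys = [p for p in parts if isinstance(p, Polygon) and p.area > 1e-9]
    if not polys:
        return None
    best = max(polys, key=lambda p: p.area)
    return np.asarray(best.exterior.coords)[:-1]


def _extend_stack(contours: list[Contour], n_extra: int, dz: float, end: str) -> list[Contour]:
    """Copy-and-taper the terminal contour ``n_extra`` slices past one end."""
    contours = sorted(contours, key=lambda c: c.z)
    terminal = contours[0] if end == "inferior" else contours[-1]
    centre = terminal.vertices.mean(axis=0)
    sign = -1.0 if end == "inferior" else 1.0
    extra = []
    for j in range(1, n_extra + 1):
        taper = max(0.2, np.sqrt(max(0.0, 1.0 - (j / (n_extra + 1.0)) ** 2)))
        v = centre + taper * (terminal.vertices - centre)
        extra.append(Contour(terminal.z + sign * j * dz, v, terminal.label))
    return contours + extra


def _crop_stack(contours: list[Contour], n_cut: int, end: str) -> list[Contour]:
    contours = sorted(contours, key=lambda c: c.z)
    if n_cut >= len(contours):
        raise GenerationError("extent shift would remove every slice")
    return contours[n_cut:] if end == "inferior" else contours[: len(contours) - n_cut]


def perturb_observer(ref: StructureSet, model: ObserverModel) -> StructureSet:
    """Simulate one observer's re-segmentation of the reference anatomy.

    Every contour is displaced radially (global scale plus smooth
    correlated noise); the CTV inferior extent and rectum superior extent
    are shifted by whole slices per the model.  With an all-zero model the
    output equals the input.  Deterministic per model seed.
    """
    rng = np.random.default_rng(model.seed)
    identity = model.global_scale == 1.0 and model.radial_noise_sigma == 0.0
    out = StructureSet(
        patient_id=ref.patient_id,
        observer_id=model.observer_id,
        fiducials=list(ref.fiducials),
    )
    for name, s in ref.structures.items():
        if identity:
            contours = list(s.contours)
        else:
            contours = [
                _perturb_contour(c, model.global_scale, model.radial_noise_sigma,
                                 model.n_harmonics, rng)
                for c in s.contours
            ]
        dz = s.slice_thickness
        if s.role == "CTV" and model.apex_shift_slices != 0:
            k = model.apex_shift_slices
            contours = (_extend_stack(contours, -k, dz, "inferior") if k < 0
                        else _crop_stack(contours, k, "inferior"))
        if s.role == "rectum" and model.rectum_superior_extension_slices != 0:
            k = model.rectum_superior_extension_slices
            contours = (_extend_stack(contours, k, dz, "superior") if k > 0
                        else _crop_stack(contours, -k, "superior"))
        out.add(Structure(s.name, s.role, contours, dz))
    return out


def _structure_centroid(s: Structure) -> np.ndarray:
    """Area-weighted 3D centroid of a contour stack."""
    total_a, acc = 0.0, np.zeros(3)
    for c in s.contours:
        a = c.area
        cx, cy = c.vertices.mean(axis=0)
        acc += a * np.array([cx, cy, c.z])
        total_a += a
    return acc / total_a


def emulate_autoseg(
    ref: StructureSet,
    bias_scale: float | dict[str, float] = 0.78,
    bias_shift: tuple[float, float, float] | dict[str, tuple] = (0.0, 0.0, 0.0),
    observer_id: str = "auto",
) -> StructureSet:
    """Deterministic affine surrogate for an atlas-based auto-segmenter.

    Each structure is scaled by ``bias_scale`` in 3D about its own centroid
    (atlas volume bias; a scale s changes the volume by ~s^3) and
    translated by ``bias_shift`` (systematic spatial offset).  Scale and
    shift may be given per role as dicts.  The axial extent is resampled
    onto the original slice grid by nearest-slice lookup, and the z
    component of the shift is snapped to a whole number of slices so the
    output stays on-grid.  No randomness is involved.
    """
    out = StructureSet(
        patient_id=ref.patient_id, observer_id=observer_id, fiducials=list(ref.fiducials)
    )
    for name, s in ref.structures.items():
        scale = bias_scale.get(s.role, 1.0) if isinstance(bias_scale, dict) else bias_scale
        shift = bias_shift.get(s.role, (0.0, 0.0, 0.0)) if isinstance(bias_shift, dict) else bias_shift
        dz = s.slice_thickness
        z_shift = round(shift[2] / dz) * dz
        if scale == 1.0:
            contours = [
                Contour(c.z + z_shift, c.vertices + np.array(shift[:2]), c.label)
                for c in s.contours
            ]
            out.add(Structure(s.name, s.role, contours, dz))
            continue
        centroid = _structure_centroid(s)
        slices = s.slices()
        src_z = np.array(list(slices))
        z_lo = centroid[2] + scale * (src_z.min() - centroid[2])
        z_hi = centroid[2] + scale * (src_z.max() - centroid[2])
        contours = []
        for z in np.arange(np.ceil(z_lo / dz - 1e-9), np.floor(z_hi / dz + 1e-9) + 1) * dz:
            z_src = centroid[2] + (z - centroid[2]) / scale
            nearest = src_z[np.argmin(np.abs(src_z - z_src))]
            for c in slices[nearest]:
                v = centroid[:2] + scale * (c.vertices - centroid[:2])
                contours.append(Contour(z + z_shift, v, c.label))
        out.add(Structure(s.name, s.role, contours, dz))
    return out


def scramble_coordinates(ss: StructureSet, t: AxisTransform) -> StructureSet:
    """Corrupt a set's frame as a TPS export would: signs/offsets per axis.

    The ground-truth transform is *not* recorded on the returned set (that
    is the caller's manifest); recovery goes through the fiducials.
    """
    from .model import apply_transform

    scrambled = apply_transform(ss, t)
    scrambled.transform_record = None
    return scrambled


@dataclass
class Cohort:
    """A full synthetic benchmarking dataset with its ground-truth manifest."""

    reference: StructureSet
    observers: list[StructureSet]
    autoseg: StructureSet
    observer_models: list[ObserverModel]
    true_transforms: dict[str, AxisTransform] = field(default_factory=dict)


def default_observer_models(n_observers: int, rng: np.random.Generator) -> list[ObserverModel]:
    """Observer population for the default benchmarking conditions.

    Smooth radial noise of 0.15 cm RMS, mild global over/under-contouring
    (log-normal around 1, ~6%), apex extension of 3-5 extra inferior slices
    (the documented tendency to contour the prostatic apex ~1.2 cm too far
    inferiorly on a 3 mm grid), and a variable rectal superior extent of
    +/-2 slices.
    """
    ids = list(string.ascii_uppercase)
    models = []
    for i in range(n_observers):
        models.append(
            ObserverModel(
                observer_id=ids[i % 26] * (1 + i // 26),
                radial_noise_sigma=0.15,
                global_scale=float(np.exp(rng.normal(0.0, 0.06))),
                apex_shift_slices=int(rng.integers(-5, -2)),
                rectum_superior_extension_slices=int(rng.integers(-2, 3)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return models


def _random_transform(rng: np.random.Generator) -> AxisTransform:
    signs = tuple(int(s) for s in rng.choice([1, -1], size=3))
    offsets = tuple(float(o) for o in rng.uniform(-8.0, 8.0, size=3))
    return AxisTransform(signs, offsets)


def make_cohort(
    cfg: AnatomyConfig | None = None,
    n_observers: int = 11,
    seed: int = 0,
    observer_models: list[ObserverModel] | None = None,
    autoseg_bias_scale: float | dict = None,
    scramble: bool = True,
    vertices_per_contour: int = 64,
) -> Cohort:
    """Generate reference + observers + auto-segmenter, optionally scrambled.

    Defaults follow the benchmarking-study conditions: 11 observers (the
    high-risk-case plan count; use 7 for an intermediate-risk-style
    cohort), and an auto-segmenter whose target volume is biased small
    (CTV linear scale 0.78, i.e. roughly half the observers' volume) while
    bladder and rectum are nearly unbiased.  When ``scramble`` is true each
    non-reference set is exported through a random translation/inversion,
    recorded in the manifest and recoverable from the fiducials.
    """
    rng = np.random.default_rng(seed)
    cfg = cfg or AnatomyConfig()
    reference = make_reference_anatomy(cfg, vertices_per_contour)
    if observer_models is None:
        observer_models = default_observer_models(n_observers, rng)
    observers = [perturb_observer(reference, m) for m in observer_models]
    if autoseg_bias_scale is None:
        autoseg_bias_scale = {"CTV": 0.78, "bladder": 0.98, "rectum": 0.95}
    autoseg = emulate_autoseg(reference, bias_scale=autoseg_bias_scale)
    true_transforms: dict[str, AxisTransform] = {}
    if scramble:
        scrambled = []
        for ss in observers + [autoseg]:
            t = _random_transform(rng)
            true_transforms[ss.observer_id] = t
            scrambled.append(scramble_coordinates(ss, t))
        observers, autoseg = scrambled[:-1], scrambled[-1]
    return Cohort(reference, observers, autoseg, observer_models, true_transforms)
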