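"""Fiducial-based recovery of coordinate translations and axis inversions.

Treatment-planning-system import/export round trips frequently shift the
coordinate origin and/or invert axes.  Because the corruption model is
exactly "translation and/or inversion" per axis — no rotation, no scaling —
each axis can be solved independently: choose the sign s in {+1, -1} and
offset t minimising sum((ref - (s*mov + t))^2), with t = mean(ref - s*mov).
External radio-opaque fiducials visible in both frames provide the matched
point pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AmbiguousAlignmentError, InsufficientFiducialsError
from .model import AxisTransform, Fiducial, StructureSet, apply_transform

#: Residual RMS (cm) above which the sign/offset model is rejected: the
#: discrepancy is then not a pure translation/inversion.
RESIDUAL_TOL = 0.1


@dataclass
class TransformFit:
    """Estimated transform plus its goodness of fit."""

    transform: AxisTransform
    residual_rms: float
    n_fiducials: int


def _matched_arrays(reference: list[Fiducial], moving: list[Fiducial]):
    ref_by_label = {f.label: f for f in reference}
    pairs = [(ref_by_label[m.label], m) for m in moving if m.label in ref_by_label]
    if len(pairs) < 2:
        raise InsufficientFiducialsError(
            f"need >= 2 label-matched fiducial pairs, have {len(pairs)}"
        )
    ref = np.array([p[0].xyz for p in pairs])
    mov = np.array([p[1].xyz for p in pairs])
    return ref, mov


def estimate_transform(
    reference: list[Fiducial],
    moving: list[Fiducial],
    residual_tol: float = RESIDUAL_TOL,
) -> TransformFit:
    """Least-squares sign and offset per axis mapping moving -> reference.

    Fiducials are matched by label.  Raises
    :class:`InsufficientFiducialsError` below 2 matched pairs, and
    :class:`AmbiguousAlignmentError` when the best fit leaves a residual
    RMS above ``residual_tol`` cm — the discrepancy then involves more than
    a translation/inversion and must not be silently "corrected".
    """
    ref, mov = _matched_arrays(reference, moving)
    signs, offsets, sse = [], [], 0.0
    for ax in range(3):
        best = None
        for s in (1, -1):
            t = float(np.mean(ref[:, ax] - s * mov[:, ax]))
            err = float(np.sum((ref[:, ax] - (s * mov[:, ax] + t)) ** 2))
            if best is None or err < best[0]:
                best = (err, s, t)
        sse += best[0]
        signs.append(best[1])
        offsets.append(best[2])
    rms = float(np.sqrt(sse / len(ref)))
    if rms > residual_tol:
        raise AmbiguousAlignmentError(
            f"fiducial residual RMS {rms:.3f} cm exceeds {residual_tol} cm: "
            "discrepancy is not a pure translation/inversion"
        )
    return TransformFit(AxisTransform(tuple(signs), tuple(offsets)), rms, len(ref))


def align_structure_set(
    ss: StructureSet, reference_fiducials: list[Fiducial], residual_tol: float = RESIDUAL_TOL
) -> tuple[StructureSet, TransformFit]:
    """Re-align a structure set onto the reference frame via its fiducials.

    Estimates the transform from the set's own fiducials to the reference
    fiducials, applies it to every contour vertex and fiducial, and records
    the transform parameters on the returned set.
    """
    if not ss.fiducials:
        raise InsufficientFiducialsError(
            f"structure set {ss.observer_id!r} carries no fiducials"
        )
    fit = estimate_transform(reference_fiducials, ss.fiducials, residual_tol)
    aligned = apply_transform(ss, fit.transform)
    return aligned, fit
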