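"""Femur deformation toolbox: anteversion and neck-shaft angle warps.

Pathological geometries (severe anteversion/retroversion, coxa vara/valga)
are produced by warping the existing mesh rather than remeshing: node
rotations are ramped smoothly (cosine blend) along the bone so torsion is
applied gradually, the greyscale field and patch memberships ride along
unchanged, and mesh quality is checked after every increment.

Angle measurement conventions (standard clinical definitions):

* neck-shaft angle (NSA): angle at the neck base between the neck axis
  (neck base -> head centre) and the distal shaft axis (neck base -> knee
  centre); ~127 deg normal, 115 deg coxa vara, 150 deg coxa valga.
* anteversion angle (AVA): signed angle, in the plane transverse to the
  shaft axis, between the neck-axis projection and the medial direction of
  the posterior condylar axis; positive anterior (anteversion), negative
  posterior (retroversion).

Because both measurements are pure functions of the landmark points, the
required warp angle is solved exactly on a landmark surrogate (scalar root
find) before the mesh is touched; the full warp is then applied in
``n_increments`` steps with an element-inversion check after each.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from femurbench.model import FemurModel, tet_volumes

__all__ = [
    "DeformitySpec",
    "MeshInversionError",
    "QualityReport",
    "apply_anteversion",
    "apply_neck_shaft",
    "measure_ava",
    "measure_nsa",
    "mesh_quality",
]


class MeshInversionError(RuntimeError):
    """A warp increment inverted elements; carries the QualityReport."""

    def __init__(self, message, report):
        super().__init__(message)
        self.report = report


@dataclass
class DeformitySpec:
    """Target angles and warp discretisation.

    ``blend_span`` is the axial span (mm) over which the rotation ramps from
    zero to its full value; ``None`` selects a warp-specific default (roughly
    half the shaft for anteversion, half the neck for neck-shaft).
    """

    target_ava_deg: float | None = None
    target_nsa_deg: float | None = None
    n_increments: int = 20
    blend_span: float | None = None

    def validate(self) -> None:
        if self.n_increments < 1:
            raise ValueError("n_increments must be >= 1")
        if self.blend_span is not None and self.blend_span <= 0:
            raise ValueError("blend_span must be positive")


@dataclass
class QualityReport:
    min_scaled_jacobian: float
    max_aspect_ratio: float
    n_inverted_elements: int
    volume_change_fraction: float


# ---------------------------------------------------------------------------
# measurement


def _shaft_axis(model: FemurModel) -> np.ndarray:
    lm = model.landmarks
    s = lm.neck_base - lm.knee_center
    n = np.linalg.norm(s)
    if n < 1e-9:
        raise ValueError("degenerate shaft axis")
    return s / n


def measure_nsa(model: FemurModel) -> float:
    """Neck-shaft angle in degrees (angle neck axis vs distal shaft axis)."""
    lm = model.landmarks
    return _nsa_from_points(lm.head_center, lm.neck_base, lm.knee_center)


def _nsa_from_points(head, neck_base, knee) -> float:
    n = head - neck_base
    q = knee - neck_base
    nn, nq = np.linalg.norm(n), np.linalg.norm(q)
    if nn < 1e-9 or nq < 1e-9:
        raise ValueError("degenerate neck or shaft axis")
    c = np.clip((n @ q) / (nn * nq), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def measure_ava(model: FemurModel) -> float:
    """Anteversion angle in degrees; positive = anterior (anteversion)."""
    lm = model.landmarks
    return _ava_from_points(
        lm.head_center,
        lm.neck_base,
        lm.knee_center,
        lm.post_condyle_medial,
        lm.post_condyle_lateral,
    )


def _ava_from_points(head, neck_base, knee, pc_med, pc_lat) -> float:
    s = neck_base - knee
    s = s / np.linalg.norm(s)
    n = head - neck_base
    pca = pc_lat - pc_med  # posterior condylar axis, pointing lateral
    n_proj = n - (n @ s) * s
    c_proj = pca - (pca @ s) * s
    if np.linalg.norm(n_proj) < 1e-9 or np.linalg.norm(c_proj) < 1e-9:
        raise ValueError("degenerate transverse projection for AVA")
    n_proj /= np.linalg.norm(n_proj)
    medial = -c_proj / np.linalg.norm(c_proj)
    return float(
        np.degrees(np.arctan2(np.cross(medial, n_proj) @ s, medial @ n_proj))
    )


# ---------------------------------------------------------------------------
# quality


def mesh_quality(model: FemurModel, reference_volume: float | None = None) -> QualityReport:
    """Scaled Jacobian, aspect ratio, inversions, total-volume change."""
    coords, tets = model.node_coords, model.tets
    vol = tet_volumes(coords, tets)
    p = coords[tets]
    edges = np.stack(
        [
            p[:, 1] - p[:, 0],
            p[:, 2] - p[:, 0],
            p[:, 3] - p[:, 0],
            p[:, 2] - p[:, 1],
            p[:, 3] - p[:, 1],
            p[:, 3] - p[:, 2],
        ],
        axis=1,
    )
    el = np.linalg.norm(edges, axis=2)
    l_rms = np.sqrt((el**2).mean(axis=1))
    scaled_jac = 6.0 * np.sqrt(2.0) * vol / l_rms**3
    # faces for the inradius: r_in = 3V / (sum of face areas)
    def farea(a, b, c):
        return 0.5 * np.linalg.norm(np.cross(p[:, b] - p[:, a], p[:, c] - p[:, a]), axis=1)

    areas = farea(0, 1, 2) + farea(0, 1, 3) + farea(1, 2, 3) + farea(0, 2, 3)
    r_in = 3.0 * np.abs(vol) / areas
    aspect = el.max(axis=1) / np.maximum(2.0 * np.sqrt(6.0) * r_in, 1e-30)
    total = float(np.abs(vol).sum())
    ref = reference_volume if reference_volume is not None else total
    return QualityReport(
        min_scaled_jacobian=float(scaled_jac.min()),
        max_aspect_ratio=float(aspect.max()),
        n_inverted_elements=int(np.sum(vol <= 0)),
        volume_change_fraction=float((total - ref) / ref),
    )


# ---------------------------------------------------------------------------
# warps


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _rotate_about_axis(points, origin, axis, angles):
    """Rodrigues rotation of each point by its own angle about (origin, axis)."""
    r = points - origin
    c = np.cos(angles)[:, None]
    s = np.sin(angles)[:, None]
    k = axis / np.linalg.norm(axis)
    kx = np.cross(np.broadcast_to(k, r.shape), r)
    kdot = (r @ k)[:, None]
    return origin + r * c + kx * s + k[None, :] * kdot * (1.0 - c)


def _apply_warp(model, origin, axis, weights, delta_rad, n_increments, reference_volume):
    out = model.copy()
    step = delta_rad / n_increments
    for _ in range(n_increments):
        out.node_coords = _rotate_about_axis(
            out.node_coords, origin, axis, weights * step
        )
        vol = tet_volumes(out.node_coords, out.tets)
        if np.any(vol <= 0):
            out.refresh_landmarks()
            report = mesh_quality(out, reference_volume)
            raise MeshInversionError(
                f"{int(np.sum(vol <= 0))} elements inverted during warp", report
            )
    out.refresh_landmarks()
    out.rebuild_frame()
    return out


def _solve_delta(measure_fn, target, bracket_half=120.0):
    """Root-find the warp angle on the landmark surrogate (exact measure)."""
    f = lambda d: measure_fn(d) - target  # noqa: E731
    d0 = 0.0
    lo, hi = d0 - 5.0, d0 + 5.0
    for _ in range(40):
        if f(lo) * f(hi) <= 0:
            break
        lo -= 5.0
        hi += 5.0
        if hi - d0 > bracket_half:
            raise ValueError(f"cannot reach target angle {target} by warping")
    return brentq(f, lo, hi, xtol=1e-10)


def apply_anteversion(
    model: FemurModel, spec: DeformitySpec
) -> tuple[FemurModel, QualityReport]:
    """Warp the femur to the target anteversion angle.

    Nodes rotate about the mechanical (head-knee) axis by an angle ramped
    (cosine blend over ``blend_span``) from zero at the distal condyles to
    the full delta just below the lesser-trochanter level, applied in
    ``n_increments`` steps; landmarks co-rotate.
    """
    spec.validate()
    if spec.target_ava_deg is None:
        raise ValueError("target_ava_deg not set")
    lm = model.landmarks
    current = measure_ava(model)
    if abs(spec.target_ava_deg - current) > 90.0:
        raise ValueError("anteversion change exceeds 90 degrees")
    ref_vol = float(np.abs(tet_volumes(model.node_coords, model.tets)).sum())
    if abs(spec.target_ava_deg - current) < 1e-9:
        return model.copy(), mesh_quality(model, ref_vol)
    axis = lm.head_center - lm.knee_center
    axis = axis / np.linalg.norm(axis)
    origin = lm.knee_center.copy()
    t = (model.node_coords - origin) @ axis
    t_nb = (lm.neck_base - origin) @ axis
    s1 = t_nb - 12.0  # fully rotated proximal to the lesser-trochanter level
    span = spec.blend_span if spec.blend_span is not None else 0.6 * s1
    s0 = max(s1 - span, 0.05 * s1)
    weights = _smoothstep((t - s0) / (s1 - s0))

    def measured(delta_deg):
        ang = np.radians(delta_deg)
        pts = {
            "head": (lm.head_center, _smoothstep((((lm.head_center - origin) @ axis) - s0) / (s1 - s0))),
            "nb": (lm.neck_base, _smoothstep((t_nb - s0) / (s1 - s0))),
        }
        rot = {
            k: _rotate_about_axis(
                p[None, :], origin, axis, np.array([w * ang])
            )[0]
            for k, (p, w) in pts.items()
        }
        return _ava_from_points(
            rot["head"], rot["nb"], lm.knee_center, lm.post_condyle_medial, lm.post_condyle_lateral
        )

    delta = _solve_delta(measured, spec.target_ava_deg)
    out = _apply_warp(
        model, origin, axis, weights, np.radians(delta), spec.n_increments, ref_vol
    )
    return out, mesh_quality(out, ref_vol)


def apply_neck_shaft(
    model: FemurModel, spec: DeformitySpec
) -> tuple[FemurModel, QualityReport]:
    """Warp the femur to the target neck-shaft angle.

    Rotation about the AP axis through the neck-base point, ramped along the
    neck axis so that only the neck and head move (the head rotates rigidly,
    preserving its sphericity).
    """
    spec.validate()
    if spec.target_nsa_deg is None:
        raise ValueError("target_nsa_deg not set")
    lm = model.landmarks
    current = measure_nsa(model)
    ref_vol = float(np.abs(tet_volumes(model.node_coords, model.tets)).sum())
    if abs(spec.target_nsa_deg - current) < 1e-9:
        return model.copy(), mesh_quality(model, ref_vol)
    neck_dir = lm.head_center - lm.neck_base
    neck_len = np.linalg.norm(neck_dir)
    neck_dir = neck_dir / neck_len
    axis = model.frame.ap_axis.copy()
    origin = lm.neck_base.copy()
    d = (model.node_coords - origin) @ neck_dir
    span = spec.blend_span if spec.blend_span is not None else 0.45 * neck_len
    weights = _smoothstep(d / span)

    def measured(delta_deg):
        ang = np.radians(delta_deg)
        w_head = _smoothstep(neck_len / span)
        head = _rotate_about_axis(
            lm.head_center[None, :], origin, axis, np.array([w_head * ang])
        )[0]
        return _nsa_from_points(head, lm.neck_base, lm.knee_center)

    delta = _solve_delta(measured, spec.target_nsa_deg)
    out = _apply_warp(
        model, origin, axis, weights, np.radians(delta), spec.n_increments, ref_vol
    )
    return out, mesh_quality(out, ref_vol)
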