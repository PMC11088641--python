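"""Outcome measures and comparison against the inertia-relief benchmark.

Three outcome families are computed per boundary-condition method and
geometry, across the seven stance instances:

* femoral head deflection (FHD): displacement of the hip joint centre
  relative to the knee joint centre, resolved onto the SI / ML / AP axes;
* peak von Mises stress (PVMS): element maximum outside artefact zones
  (elements close to load-application patch centroids or to Dirichlet
  constrained nodes are excluded symmetrically for every method);
* cortical strain: absolute principal strain (microstrain) sampled along
  four diaphyseal surface paths (medial, lateral, anterior, posterior),
  with a signed companion (tension +, compression -) for pattern checks.

Method series are compared to inertia relief through the coefficient of
determination R^2 (reference series as truth) and the RMS error normalised
to the reference's dynamic range (nRMSE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from femurbench.constraints import ConstraintSet
from femurbench.fe import FEResult
from femurbench.model import (
    AnatomicalFrame,
    FemurModel,
    LandmarkSet,
    surface_faces,
)

__all__ = [
    "ComparisonReport",
    "OutcomeSeries",
    "compare_report",
    "compute_outcomes",
    "cortical_strain_paths",
    "femoral_head_deflection",
    "interpolate_displacement",
    "nrmse",
    "peak_von_mises",
    "r_squared",
]

GEOMETRY_NAMES = ("normal", "ava45", "ava-10", "nsa115", "nsa150")


@dataclass
class OutcomeSeries:
    """Per-instance outcomes for one (geometry, method) run."""

    fhd_si: np.ndarray  # (7,) mm
    fhd_ml: np.ndarray
    fhd_ap: np.ndarray
    fhd_resultant: np.ndarray
    pvms: np.ndarray  # (7,) MPa
    strain_arc_length: dict = field(default_factory=dict)  # path -> (K,) mm
    strain_abs: dict = field(default_factory=dict)  # path -> (7, K) microstrain
    strain_signed: dict = field(default_factory=dict)  # path -> (7, K)

    def validate(self) -> None:
        for name in ("fhd_si", "fhd_ml", "fhd_ap", "fhd_resultant", "pvms"):
            if getattr(self, name).shape[0] != 7:
                raise ValueError(f"{name} must have 7 instances")
        res = np.sqrt(self.fhd_si**2 + self.fhd_ml**2 + self.fhd_ap**2)
        if not np.allclose(res, self.fhd_resultant, atol=1e-9):
            raise ValueError("resultant FHD inconsistent with components")
        if np.any(self.pvms < 0):
            raise ValueError("PVMS must be non-negative")


@dataclass
class ComparisonReport:
    """R^2 / nRMSE of every method vs inertia relief, per geometry+metric."""

    table: pd.DataFrame  # columns: geometry, method, metric, r_squared, nrmse

    def ranking(self, geometry: str, metric: str = "pvms") -> list[str]:
        sub = self.table[
            (self.table.geometry == geometry) & (self.table.metric == metric)
        ]
        return list(sub.sort_values("nrmse").method)


# ---------------------------------------------------------------------------
# interpolation


def interpolate_displacement(
    model: FemurModel, u: np.ndarray, point: np.ndarray
) -> np.ndarray:
    """Barycentric interpolation of a nodal field at an interior point.

    Falls back to the nearest node when the point lies (marginally) outside
    every tetrahedron, e.g. after a warp perturbs landmark positions.
    """
    coords, tets = model.node_coords, model.tets
    p = coords[tets]
    X = np.stack(
        [p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]], axis=2
    )
    rhs = point[None, :] - p[:, 0]
    try:
        lam = np.linalg.solve(X, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:  # pragma: no cover - inverted elements
        lam = None
    if lam is not None:
        bary = np.concatenate([1.0 - lam.sum(axis=1, keepdims=True), lam], axis=1)
        inside = np.all(bary >= -1e-9, axis=1)
        if np.any(inside):
            e = int(np.argmax(np.where(inside, bary.min(axis=1), -np.inf)))
            return bary[e] @ u[tets[e]]
    nearest = int(np.argmin(np.linalg.norm(coords - point, axis=1)))
    return u[nearest].copy()


# ---------------------------------------------------------------------------
# outcome measures


def femoral_head_deflection(
    result: FEResult, landmarks: LandmarkSet, frame: AnatomicalFrame, model: FemurModel
):
    """FHD components per instance: u(head) - u(knee) in (SI, ML, AP), mm."""
    k = result.n_instances
    comps = np.empty((k, 3))
    for i in range(k):
        u = result.displacements[i]
        du = interpolate_displacement(
            model, u, landmarks.head_center
        ) - interpolate_displacement(model, u, landmarks.knee_center)
        comps[i] = frame.matrix() @ du
    resultant = np.linalg.norm(comps, axis=1)
    return comps[:, 0], comps[:, 1], comps[:, 2], resultant


def _artefact_mask(model: FemurModel, csets, exclusion_radius: float) -> np.ndarray:
    """True for elements far enough from load patches and constrained nodes.

    ``csets`` may be a single constraint set, a sequence of them, or None.
    The guard should be built from the union of every compared method's
    constraint sets so the excluded region is identical across methods and
    peak comparisons are unbiased.
    """
    cent = model.element_centroids()
    keep = np.ones(cent.shape[0], bool)
    if exclusion_radius <= 0:
        return keep
    guard_points = [p.refpoint for p in model.attachment_patches.values()]
    if csets is None:
        csets = []
    elif isinstance(csets, ConstraintSet):
        csets = [csets]
    nodes: set = set()
    for cset in csets:
        nodes.update(int(n) for n, _, _ in cset.dirichlet)
        for rc in cset.rigid_couplings:
            nodes.update(int(n) for n in rc.nodes)
        for patch_nodes, _, _ in cset.avg_dirichlet:
            nodes.update(int(n) for n in patch_nodes)
        for patch_nodes, _, _ in cset.avg_rotations:
            nodes.update(int(n) for n in patch_nodes)
    if nodes:
        guard_points.extend(model.node_coords[sorted(nodes)])
    for gp in guard_points:
        keep &= np.linalg.norm(cent - gp, axis=1) > exclusion_radius
    return keep


def peak_von_mises(
    result: FEResult,
    model: FemurModel,
    csets=None,
    exclusion_radius: float = 5.0,
) -> np.ndarray:
    """Per-instance peak element von Mises stress outside artefact zones."""
    keep = _artefact_mask(model, csets, exclusion_radius)
    if not np.any(keep):
        raise ValueError("artefact exclusion removed every element")
    return result.von_mises[:, keep].max(axis=1)


def cortical_strain_paths(model: FemurModel, result: FEResult):
    """Sample principal strain along the diaphyseal surface paths.

    For each path node the nearest surface element supplies the strain.
    Returns (arc_length, absolute, signed) dicts keyed by path name; strains
    in microstrain, signed = principal strain of largest magnitude.
    """
    if not model.strain_paths:
        raise ValueError("model defines no strain paths")
    surf_nodes = np.unique(surface_faces(model.tets))
    # elements with >= 3 boundary nodes carry a boundary face
    surf_elems = np.nonzero(np.isin(model.tets, surf_nodes).sum(axis=1) >= 3)[0]
    cent = model.element_centroids()[surf_elems]
    principal = result.principal_strains  # (k, M, 3)
    idx_max = np.argmax(np.abs(principal), axis=2)
    signed_all = np.take_along_axis(principal, idx_max[..., None], axis=2)[..., 0]
    arc, absd, signed = {}, {}, {}
    for name, nodes in model.strain_paths.items():
        pts = model.node_coords[nodes]
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc[name] = np.concatenate([[0.0], np.cumsum(seg)])
        nearest = surf_elems[
            np.argmin(
                np.linalg.norm(pts[:, None, :] - cent[None, :, :], axis=2), axis=1
            )
        ]
        absd[name] = np.abs(signed_all[:, nearest]) * 1e6
        signed[name] = signed_all[:, nearest] * 1e6
    return arc, absd, signed


def compute_outcomes(
    model: FemurModel,
    result: FEResult,
    csets=None,
    exclusion_radius: float = 5.0,
) -> OutcomeSeries:
    """Bundle FHD, PVMS and strain-path outcomes for one run.

    ``csets``: constraint set(s) whose constrained nodes define the
    artefact-exclusion guard; pass every compared method's set so the guard
    is method-independent.
    """
    si, ml, ap, res = femoral_head_deflection(
        result, model.landmarks, model.frame, model
    )
    pv = peak_von_mises(result, model, csets, exclusion_radius)
    arc, absd, signed = cortical_strain_paths(model, result)
    series = OutcomeSeries(
        fhd_si=si,
        fhd_ml=ml,
        fhd_ap=ap,
        fhd_resultant=res,
        pvms=pv,
        strain_arc_length=arc,
        strain_abs=absd,
        strain_signed=signed,
    )
    series.validate()
    return series


# ---------------------------------------------------------------------------
# series comparison


def r_squared(series: np.ndarray, reference: np.ndarray) -> float:
    """1 - SS_res / SS_tot with the reference series as truth.

    Returns NaN for a constant reference (zero total sum of squares).
    """
    series = np.asarray(series, float)
    reference = np.asarray(reference, float)
    ss_tot = float(np.sum((reference - reference.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    ss_res = float(np.sum((series - reference) ** 2))
    return 1.0 - ss_res / ss_tot


def nrmse(series: np.ndarray, reference: np.ndarray) -> float:
    """RMSE normalised to the reference's dynamic range; NaN if range is 0."""
    series = np.asarray(series, float)
    reference = np.asarray(reference, float)
    rng = float(reference.max() - reference.min())
    if rng == 0.0:
        return float("nan")
    return float(np.sqrt(np.mean((series - reference) ** 2)) / rng)


_METRICS = ("pvms", "fhd_si", "fhd_ml", "fhd_ap", "fhd_resultant")


def series_to_frame(series: OutcomeSeries) -> pd.DataFrame:
    """Tidy (metric, instance, value) table of the scalar outcome series."""
    rows = []
    for metric in _METRICS:
        for i, v in enumerate(getattr(series, metric)):
            rows.append({"metric": metric, "instance": i, "value": float(v)})
    return pd.DataFrame(rows)


def frame_to_series(df: pd.DataFrame) -> OutcomeSeries:
    """Rebuild the scalar outcome series from :func:`series_to_frame` output."""
    data = {}
    for metric in _METRICS:
        sub = df[df.metric == metric].sort_values("instance")
        if sub.shape[0] != 7:
            raise ValueError(f"outcome table missing instances for {metric!r}")
        data[metric] = sub.value.to_numpy(float)
    return OutcomeSeries(
        fhd_si=data["fhd_si"],
        fhd_ml=data["fhd_ml"],
        fhd_ap=data["fhd_ap"],
        fhd_resultant=data["fhd_resultant"],
        pvms=data["pvms"],
    )


def strains_to_frame(series: OutcomeSeries) -> pd.DataFrame:
    """Tidy strain-path table (path, instance, arc_length, microstrain)."""
    rows = []
    for path, arc in series.strain_arc_length.items():
        for i in range(series.strain_abs[path].shape[0]):
            for j, s in enumerate(arc):
                rows.append(
                    {
                        "path": path,
                        "instance": i,
                        "arc_length_mm": float(s),
                        "abs_microstrain": float(series.strain_abs[path][i, j]),
                        "signed_microstrain": float(
                            series.strain_signed[path][i, j]
                        ),
                    }
                )
    return pd.DataFrame(rows)


def compare_report(
    outcomes: dict, reference_method: str = "inertia_relief"
) -> ComparisonReport:
    """Compare every non-reference method's series with inertia relief.

    ``outcomes`` maps (geometry, method) -> OutcomeSeries.
    """
    rows = []
    geometries = sorted({g for g, _ in outcomes})
    for geometry in geometries:
        ref = outcomes.get((geometry, reference_method))
        if ref is None:
            continue
        for (g, method), series in outcomes.items():
            if g != geometry or method == reference_method:
                continue
            for metric in _METRICS:
                s = getattr(series, metric)
                r = getattr(ref, metric)
                rows.append(
                    {
                        "geometry": geometry,
                        "method": method,
                        "metric": metric,
                        "r_squared": r_squared(s, r),
                        "nrmse": nrmse(s, r),
                    }
                )
    return ComparisonReport(table=pd.DataFrame(rows))
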