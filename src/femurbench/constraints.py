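"""The six boundary-condition formulations as declarative constraint sets.

Each builder returns a :class:`ConstraintSet` describing Dirichlet rows,
averaged-motion (slider) rows, grounded springs, rigid reference-point
couplings and load-inclusion rules; :func:`assemble_constraint_rows` lowers
the set to sparse multi-point-constraint rows over the (possibly extended)
DoF vector for the KKT solver.

Methods:
    inertia_relief   free body, inertial balancing, all loads applied
    fixed_knee       distal condylar region fully fixed; tibiofemoral and
                     patellofemoral contact forces excluded
    springs          weak grounded springs on neck, epicondylar and knee
                     node groups; no Dirichlet constraints
    isostatic        exactly 6 Dirichlet DoF: knee centre (3), femoral-head
                     pole ML + AP (2), lateral epicondyle AP (1; SI variant
                     selectable)
    mid_shaft        exactly 6 Dirichlet DoF: knee centre (3), epicondyle AP
                     (1), mid-diaphysis ML + AP (2)
    biomechanical    head centre slider along the head-knee axis (transverse
                     motion of the coupled head patch suppressed), knee
                     centre fixed (3), greater trochanter rigid coupling
                     fixed in ML, AP and rotation about SI
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from femurbench.model import FemurModel, surface_node_indices

__all__ = [
    "ConstraintSet",
    "METHOD_NAMES",
    "RigidCoupling",
    "assemble_constraint_rows",
    "build_biomechanical",
    "build_constraints",
    "build_fixed_knee",
    "build_inertia_relief",
    "build_isostatic",
    "build_mid_shaft",
    "build_springs",
]

METHOD_NAMES = (
    "inertia_relief",
    "fixed_knee",
    "springs",
    "isostatic",
    "mid_shaft",
    "biomechanical",
)

ALL_CONTACTS = frozenset({"hip", "tibiofemoral", "patellofemoral"})


@dataclass
class RigidCoupling:
    """Reference point rigidly coupled to a small patch, partially fixed."""

    refpoint: np.ndarray
    nodes: np.ndarray
    fixed_translations: list  # list of unit direction vectors
    fixed_rotations: list  # list of unit axis vectors


@dataclass
class ConstraintSet:
    method: str
    dirichlet: list = field(default_factory=list)  # (node, direction, value=0)
    avg_dirichlet: list = field(default_factory=list)  # (nodes, direction, 0)
    avg_rotations: list = field(default_factory=list)  # (nodes, center, axis)
    springs: list = field(default_factory=list)  # (nodes, k per node N/mm)
    rigid_couplings: list = field(default_factory=list)
    use_inertia_relief: bool = False
    load_rules: frozenset = ALL_CONTACTS

    @property
    def constrained_dof_count(self) -> int:
        """Explicitly constrained DoF (Dirichlet + slider + refpoint rows)."""
        n = len(self.dirichlet) + len(self.avg_dirichlet) + len(self.avg_rotations)
        for rc in self.rigid_couplings:
            n += len(rc.fixed_translations) + len(rc.fixed_rotations)
        return n

    @property
    def n_extra_dof(self) -> int:
        return 6 * len(self.rigid_couplings)


def _nearest_node(coords: np.ndarray, point: np.ndarray, subset=None) -> int:
    idx = np.arange(coords.shape[0]) if subset is None else np.asarray(subset)
    return int(idx[np.argmin(np.linalg.norm(coords[idx] - point, axis=1))])


# ---------------------------------------------------------------------------
# builders


def build_inertia_relief(model: FemurModel) -> ConstraintSet:
    """Free femur balanced by inertial loads; all contact forces included."""
    return ConstraintSet(
        method="inertia_relief", use_inertia_relief=True, load_rules=ALL_CONTACTS
    )


def build_fixed_knee(model: FemurModel) -> ConstraintSet:
    """Distal condylar region fully fixed; knee contact forces neglected.

    Fixing the translations of every node in a finite distal region removes
    all six rigid-body DoF of the solid mesh.
    """
    cset = ConstraintSet(
        method="fixed_knee",
        load_rules=frozenset({"hip"}),
    )
    eye = np.eye(3)
    for node in model.landmarks.condylar_patch:
        for c in range(3):
            cset.dirichlet.append((int(node), eye[c], 0.0))
    return cset


def build_springs(model: FemurModel, k_per_node: float = 8.0) -> ConstraintSet:
    """Weak grounded springs on neck, epicondylar, and knee-centre groups."""
    if k_per_node <= 0:
        raise ValueError("spring stiffness must be positive")
    lm = model.landmarks
    coords = model.node_coords
    surf = surface_node_indices(model.tets)
    sc = coords[surf]
    neck_mid = lm.neck_base + 0.45 * (lm.head_center - lm.neck_base)
    neck_band = surf[np.linalg.norm(sc - neck_mid, axis=1) <= 18.0]
    med_epi = lm.knee_center + (lm.knee_center - lm.lateral_epicondyle)
    epi_band = surf[
        (np.linalg.norm(sc - lm.lateral_epicondyle, axis=1) <= 16.0)
        | (np.linalg.norm(sc - med_epi, axis=1) <= 16.0)
    ]
    knee_patch = surf[np.linalg.norm(sc - lm.knee_center, axis=1) <= 30.0]
    cset = ConstraintSet(method="springs", load_rules=ALL_CONTACTS)
    for nodes in (neck_band, epi_band, knee_patch):
        cset.springs.append((np.asarray(nodes, int), float(k_per_node)))
    return cset


def build_isostatic(
    model: FemurModel,
    epicondyle_direction: str = "ap",
    head_mode: str = "refpoint",
) -> ConstraintSet:
    """Exactly six constrained translational DoF in local-frame directions.

    Knee-centre node: SI, ML, AP.  Femoral head centre: ML, AP -- so the
    head can deflect only along the femur's mechanical axis.  The head
    centre is the reference point coupled to the head cortex patch, so its
    motion is the patch average (``head_mode='refpoint'``, default); the
    ``'pole_node'`` variant instead pins the single surface node nearest
    the mechanical-axis-head intersection.  Lateral epicondyle node: AP by
    default; the SI variant (selectable) leaves rotation about the
    mechanical axis nearly unconstrained and produces a near-singular
    system.
    """
    if epicondyle_direction not in ("ap", "si"):
        raise ValueError("epicondyle_direction must be 'ap' or 'si'")
    if head_mode not in ("refpoint", "pole_node"):
        raise ValueError("head_mode must be 'refpoint' or 'pole_node'")
    lm, fr = model.landmarks, model.frame
    coords = model.node_coords
    knee_node = lm.node_ids["knee_center"]
    epi_node = lm.node_ids["lateral_epicondyle"]
    epi_dir = fr.ap_axis if epicondyle_direction == "ap" else fr.si_axis
    cset = ConstraintSet(method="isostatic", load_rules=ALL_CONTACTS)
    for d in (fr.si_axis, fr.ml_axis, fr.ap_axis):
        cset.dirichlet.append((knee_node, d.copy(), 0.0))
    if head_mode == "refpoint":
        head_patch = np.asarray(lm.head_surface_patch, int)
        cset.avg_dirichlet.append((head_patch, fr.ml_axis.copy(), 0.0))
        cset.avg_dirichlet.append((head_patch, fr.ap_axis.copy(), 0.0))
    else:
        pole = lm.head_center + model_head_radius(model) * fr.si_axis
        head_node = _nearest_node(coords, pole, lm.head_surface_patch)
        for d in (fr.ml_axis, fr.ap_axis):
            cset.dirichlet.append((head_node, d.copy(), 0.0))
    cset.dirichlet.append((epi_node, epi_dir.copy(), 0.0))
    return cset


def build_mid_shaft(model: FemurModel) -> ConstraintSet:
    """Knee centre (3), epicondyle AP (1), mid-diaphysis ML + AP (2)."""
    lm, fr = model.landmarks, model.frame
    cset = ConstraintSet(method="mid_shaft", load_rules=ALL_CONTACTS)
    knee_node = lm.node_ids["knee_center"]
    for d in (fr.si_axis, fr.ml_axis, fr.ap_axis):
        cset.dirichlet.append((knee_node, d.copy(), 0.0))
    cset.dirichlet.append(
        (lm.node_ids["lateral_epicondyle"], fr.ap_axis.copy(), 0.0)
    )
    mid_node = lm.node_ids["mid_diaphysis"]
    for d in (fr.ml_axis, fr.ap_axis):
        cset.dirichlet.append((mid_node, d.copy(), 0.0))
    return cset


def build_biomechanical(model: FemurModel, gt_mode: str = "rigid") -> ConstraintSet:
    """Head slider along the head-knee axis + fixed knee centre + GT coupling.

    The head reference point (distributing-coupled to the head surface patch,
    i.e. its motion is the patch average) may translate only along the
    undeformed head-knee axis: its two transverse displacement components are
    constrained, which reacts the transverse hip-contact force components
    like an acetabulum surrogate.  The greater trochanter reference point,
    coupled to its small patch, is fixed in ML and AP translation and in
    rotation about SI, emulating passive thigh soft tissue.  ``gt_mode``
    selects the coupling: "rigid" (default) makes the small patch move as a
    rigid body with the reference point; "distributing" constrains only the
    patch's average translation / rotation, leaving local cortex
    deformation free.  On the compliant trochanteric shell the two give
    nearly identical fields.
    """
    if gt_mode not in ("distributing", "rigid"):
        raise ValueError("gt_mode must be 'distributing' or 'rigid'")
    lm, fr = model.landmarks, model.frame
    axis = lm.head_center - lm.knee_center
    axis = axis / np.linalg.norm(axis)
    t1 = fr.ml_axis - (fr.ml_axis @ axis) * axis
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(axis, t1)
    cset = ConstraintSet(method="biomechanical", load_rules=ALL_CONTACTS)
    head_patch = np.asarray(lm.head_surface_patch, int)
    cset.avg_dirichlet.append((head_patch, t1, 0.0))
    cset.avg_dirichlet.append((head_patch, t2, 0.0))
    knee_node = lm.node_ids["knee_center"]
    for d in np.eye(3):
        cset.dirichlet.append((knee_node, d.copy(), 0.0))
    gt_nodes = np.asarray(lm.gt_patch, int)
    if gt_mode == "rigid":
        cset.rigid_couplings.append(
            RigidCoupling(
                refpoint=lm.greater_trochanter_lateral.copy(),
                nodes=gt_nodes,
                fixed_translations=[fr.ml_axis.copy(), fr.ap_axis.copy()],
                fixed_rotations=[fr.si_axis.copy()],
            )
        )
    else:
        cset.avg_dirichlet.append((gt_nodes, fr.ml_axis.copy(), 0.0))
        cset.avg_dirichlet.append((gt_nodes, fr.ap_axis.copy(), 0.0))
        cset.avg_rotations.append(
            (gt_nodes, lm.greater_trochanter_lateral.copy(), fr.si_axis.copy())
        )
    return cset


_BUILDERS = {
    "inertia_relief": build_inertia_relief,
    "fixed_knee": build_fixed_knee,
    "springs": build_springs,
    "isostatic": build_isostatic,
    "mid_shaft": build_mid_shaft,
    "biomechanical": build_biomechanical,
}


def build_constraints(model: FemurModel, method: str, **kwargs) -> ConstraintSet:
    """Dispatch to the builder for ``method`` (see :data:`METHOD_NAMES`)."""
    try:
        builder = _BUILDERS[method]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; expected one of {METHOD_NAMES}"
        ) from None
    return builder(model, **kwargs)


def model_head_radius(model: FemurModel) -> float:
    pts = model.node_coords[model.landmarks.head_surface_patch]
    return float(
        np.median(np.linalg.norm(pts - model.landmarks.head_center, axis=1))
    )


# ---------------------------------------------------------------------------
# lowering to MPC rows


def assemble_constraint_rows(cset: ConstraintSet, model: FemurModel):
    """Lower a constraint set to sparse rows C (m, n_ext) plus spring diagonal.

    Returns ``(C, spring_diagonal, n_extra_dof, labels)``.  Extended DoF
    layout: 3N nodal displacements followed by 6 DoF (3 translation, 3 small
    rotation) per rigid coupling.  All constraints are homogeneous.
    """
    n_base = 3 * model.node_coords.shape[0]
    n_ext = n_base + cset.n_extra_dof
    rows, cols, data, labels = [], [], [], []
    m = 0
    for node, d, _ in cset.dirichlet:
        for c in range(3):
            if d[c] != 0.0:
                rows.append(m)
                cols.append(3 * node + c)
                data.append(float(d[c]))
        labels.append(("dirichlet", int(node)))
        m += 1
    for nodes, d, _ in cset.avg_dirichlet:
        w = 1.0 / len(nodes)
        for node in nodes:
            for c in range(3):
                if d[c] != 0.0:
                    rows.append(m)
                    cols.append(3 * int(node) + c)
                    data.append(w * float(d[c]))
        labels.append(("slider", len(nodes)))
        m += 1
    for nodes, center, axis in cset.avg_rotations:
        # least-squares patch rotation about (center, axis) set to zero:
        # theta ~ sum (axis x r_i) . u_i, with normalised coefficients
        r = model.node_coords[np.asarray(nodes, int)] - center
        c = np.cross(np.broadcast_to(axis, r.shape), r)
        scale = np.sqrt((c**2).sum())
        if scale < 1e-12:
            raise ValueError("degenerate average-rotation patch")
        c = c / scale
        for j, node in enumerate(nodes):
            for comp in range(3):
                if c[j, comp] != 0.0:
                    rows.append(m)
                    cols.append(3 * int(node) + comp)
                    data.append(c[j, comp])
        labels.append(("avg_rotation", len(nodes)))
        m += 1
    for ic, rc in enumerate(cset.rigid_couplings):
        if rc.nodes.size == 0:
            raise ValueError("rigid coupling with empty patch")
        base = n_base + 6 * ic
        r = model.node_coords[rc.nodes] - rc.refpoint
        for j, node in enumerate(rc.nodes):
            rx, ry, rz = r[j]
            # u_i - u_p - theta x r_i = 0  (small rotations)
            cross_rows = [(0.0, rz, -ry), (-rz, 0.0, rx), (ry, -rx, 0.0)]
            for c in range(3):
                rows += [m, m]
                cols += [3 * int(node) + c, base + c]
                data += [1.0, -1.0]
                for k in range(3):
                    coef = -cross_rows[c][k]
                    if coef != 0.0:
                        rows.append(m)
                        cols.append(base + 3 + k)
                        data.append(coef)
                labels.append(("rigid_tie", int(node)))
                m += 1
        for d in rc.fixed_translations:
            for c in range(3):
                if d[c] != 0.0:
                    rows.append(m)
                    cols.append(base + c)
                    data.append(float(d[c]))
            labels.append(("refpoint_translation", ic))
            m += 1
        for d in rc.fixed_rotations:
            for c in range(3):
                if d[c] != 0.0:
                    rows.append(m)
                    cols.append(base + 3 + c)
                    data.append(float(d[c]))
            labels.append(("refpoint_rotation", ic))
            m += 1
    C = sp.coo_matrix((data, (rows, cols)), shape=(m, n_ext)).tocsr()
    spring_diag = np.zeros(n_ext)
    for nodes, k in cset.springs:
        for c in range(3):
            spring_diag[3 * np.asarray(nodes, int) + c] += k
    return C, spring_diag, cset.n_extra_dof, labels
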