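"""Synthetic femur model: tetrahedral mesh, pseudo-CT greyscale field, landmarks.

The generator builds a femur-like watertight solid from parametric primitives:
a distal condylar flare, a tapered hollow-cortex shaft with a cancellous core
encoded through the element greyscale field, an angled / anteverted neck, and
a spherical head.  The mesh is a deterministic extrusion of filled elliptical
cross-section disks along the shaft-neck-head centreline; each prism between
consecutive disks is split into three tetrahedra with globally consistent
diagonals, so the mesh is conforming and watertight by construction.

Coordinate conventions (right femur, undeformed):
    +z  proximal (superior-inferior axis), knee centre at the origin
    +x  lateral (medial-lateral axis)
    -y  anterior (the anterior-posterior axis is ml x si)
Units are mm throughout (mm-N-MPa-tonne unit system).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AnatomicalFrame",
    "AttachmentPatch",
    "FemurModel",
    "FemurParams",
    "LandmarkSet",
    "box_mesh",
    "build_frame",
    "euler_characteristic",
    "fit_head_sphere",
    "generate_femur",
    "surface_faces",
    "surface_node_indices",
    "tet_volumes",
]


class ConstructionError(ValueError):
    """Raised when a parameter combination cannot produce a valid femur."""


class DegenerateGeometryError(ValueError):
    """Raised for collinear landmarks or other degenerate geometric input."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class AnatomicalFrame:
    """Right-handed orthonormal anatomical frame.

    ``si_axis`` points proximal (head towards hip), ``ml_axis`` lateral,
    ``ap_axis = ml_axis x si_axis`` points anterior for a right femur.
    """

    si_axis: np.ndarray
    ml_axis: np.ndarray
    ap_axis: np.ndarray
    origin: np.ndarray

    def matrix(self) -> np.ndarray:
        """Rows (si, ml, ap): maps global vectors to local components."""
        return np.array([self.si_axis, self.ml_axis, self.ap_axis])


@dataclass
class LandmarkSet:
    """Anatomical landmark positions (mm) and key surface node sets.

    Landmarks coincide with mesh nodes (the ``*_node`` indices); deformity
    warps therefore carry them along automatically.
    """

    head_center: np.ndarray
    knee_center: np.ndarray
    lateral_epicondyle: np.ndarray
    greater_trochanter_lateral: np.ndarray
    mid_diaphysis: np.ndarray
    neck_base: np.ndarray
    post_condyle_medial: np.ndarray
    post_condyle_lateral: np.ndarray
    head_surface_patch: np.ndarray = field(default_factory=lambda: np.array([], int))
    condylar_patch: np.ndarray = field(default_factory=lambda: np.array([], int))
    gt_patch: np.ndarray = field(default_factory=lambda: np.array([], int))
    node_ids: dict = field(default_factory=dict)

    def validate(self) -> None:
        if np.linalg.norm(self.head_center - self.knee_center) <= 0:
            raise DegenerateGeometryError("head and knee centres coincide")
        si = self.head_center - self.knee_center
        v = self.lateral_epicondyle - self.knee_center
        if np.linalg.norm(np.cross(si, v)) < 1e-9 * np.linalg.norm(si) * max(
            np.linalg.norm(v), 1e-30
        ):
            raise DegenerateGeometryError(
                "lateral epicondyle collinear with the mechanical axis"
            )


@dataclass
class AttachmentPatch:
    """A muscle / contact attachment: reference point + surface node set."""

    refpoint: np.ndarray  # position, mm
    nodes: np.ndarray  # surface node indices


@dataclass
class FemurParams:
    """Parameters of the synthetic femur generator.

    Defaults emulate the proportions of an adolescent full-femur CT model:
    400 mm length, 24 mm head radius, neck-shaft angle 127 deg, anteversion
    15 deg.  ``cortical_gv`` / ``cancellous_gv`` are pseudo-CT greyscale
    levels chosen so that the greyscale->density->modulus mapping yields
    about 20 GPa cortical and about 12 GPa dense-trabecular moduli.
    """

    femur_length: float = 400.0
    head_radius: float = 24.0
    neck_length: float = 55.0
    neck_shaft_angle_deg: float = 127.0
    anteversion_deg: float = 15.0
    shaft_outer_radius: float = 15.0
    cortical_thickness: float = 5.5
    target_edge_length: float = 4.0
    cortical_gv: float = 1900.0
    cancellous_gv: float = 1350.0
    rng_seed: int = 0

    def validate(self) -> None:
        for name in (
            "femur_length",
            "head_radius",
            "neck_length",
            "shaft_outer_radius",
            "cortical_thickness",
            "target_edge_length",
        ):
            if getattr(self, name) <= 0:
                raise ConstructionError(f"{name} must be positive")
        if not 90.0 <= self.neck_shaft_angle_deg <= 160.0:
            raise ConstructionError("neck_shaft_angle_deg outside [90, 160]")
        if not -30.0 <= self.anteversion_deg <= 60.0:
            raise ConstructionError("anteversion_deg outside [-30, 60]")
        if self.neck_length <= self.head_radius:
            raise ConstructionError("neck shorter than head radius")
        if self.cortical_thickness >= 0.9 * self.shaft_outer_radius:
            raise ConstructionError("cortical thickness >= shaft radius")
        theta = np.radians(180.0 - self.neck_shaft_angle_deg)
        if self.femur_length - self.neck_length * np.cos(theta) < 0.6 * self.femur_length:
            raise ConstructionError("neck geometry places the junction too distal")


@dataclass
class FemurModel:
    """Tetrahedral femur model: geometry, greyscale field, landmarks, patches."""

    node_coords: np.ndarray  # (N, 3) mm
    tets: np.ndarray  # (M, 4) int, positive signed volume
    element_gv: np.ndarray  # (M,) greyscale
    landmarks: LandmarkSet
    frame: AnatomicalFrame
    attachment_patches: dict[str, AttachmentPatch]
    strain_paths: dict[str, np.ndarray] = field(default_factory=dict)
    params: FemurParams | None = None

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.tets.shape[0]

    def copy(self) -> "FemurModel":
        lm = dataclasses.replace(
            self.landmarks,
            **{
                f.name: (
                    np.array(getattr(self.landmarks, f.name))
                    if isinstance(getattr(self.landmarks, f.name), np.ndarray)
                    else dict(getattr(self.landmarks, f.name))
                )
                for f in dataclasses.fields(self.landmarks)
            },
        )
        return FemurModel(
            node_coords=self.node_coords.copy(),
            tets=self.tets.copy(),
            element_gv=self.element_gv.copy(),
            landmarks=lm,
            frame=AnatomicalFrame(
                self.frame.si_axis.copy(),
                self.frame.ml_axis.copy(),
                self.frame.ap_axis.copy(),
                self.frame.origin.copy(),
            ),
            attachment_patches={
                k: AttachmentPatch(v.refpoint.copy(), v.nodes.copy())
                for k, v in self.attachment_patches.items()
            },
            strain_paths={k: v.copy() for k, v in self.strain_paths.items()},
            params=self.params,
        )

    def refresh_landmarks(self) -> None:
        """Re-read landmark positions from their node indices (after a warp)."""
        ids = self.landmarks.node_ids
        for name, nid in ids.items():
            setattr(self.landmarks, name, self.node_coords[nid].copy())
        # attachment reference points follow their patch centroids, except the
        # hip refpoint which tracks the head centre and the tibiofemoral
        # refpoint which tracks the knee centre
        for name, patch in self.attachment_patches.items():
            if name == "hip_contact":
                patch.refpoint = self.landmarks.head_center.copy()
            elif name == "tf_contact":
                patch.refpoint = self.landmarks.knee_center.copy()
            else:
                patch.refpoint = self.node_coords[patch.nodes].mean(axis=0)

    def rebuild_frame(self) -> None:
        self.frame = build_frame(self.landmarks)

    def element_centroids(self) -> np.ndarray:
        return self.node_coords[self.tets].mean(axis=1)

    def element_volumes(self) -> np.ndarray:
        return tet_volumes(self.node_coords, self.tets)


# ---------------------------------------------------------------------------
# mesh utilities


def tet_volumes(coords: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed tetrahedron volumes under the fixed node-ordering convention."""
    p = coords[tets]
    return np.einsum(
        "ij,ij->i",
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
        p[:, 3] - p[:, 0],
    ) / 6.0


def surface_faces(tets: np.ndarray) -> np.ndarray:
    """Boundary faces: triangles that appear in exactly one tetrahedron."""
    faces = np.concatenate(
        [
            tets[:, [0, 2, 1]],
            tets[:, [0, 1, 3]],
            tets[:, [1, 2, 3]],
            tets[:, [0, 3, 2]],
        ]
    )
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


def surface_node_indices(tets: np.ndarray) -> np.ndarray:
    return np.unique(surface_faces(tets))


def euler_characteristic(faces: np.ndarray) -> int:
    """V - E + F of a triangle surface (2 for a closed 2-manifold sphere)."""
    v = np.unique(faces).size
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e = np.unique(np.sort(edges, axis=1), axis=0).shape[0]
    return v - e + faces.shape[0]


def _orient_positive(coords: np.ndarray, tets: np.ndarray) -> np.ndarray:
    vol = tet_volumes(coords, tets)
    flip = vol < 0
    tets = tets.copy()
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    return tets


# prism -> 3 tets with globally consistent quad diagonals (lowest-global-id
# rule); rotations keep the prism orientation (bottom triangle 0-1-2, top 3-4-5)
_PRISM_ROTATIONS = np.array(
    [
        [0, 1, 2, 3, 4, 5],
        [1, 2, 0, 4, 5, 3],
        [2, 0, 1, 5, 3, 4],
        [3, 5, 4, 0, 2, 1],
        [4, 3, 5, 1, 0, 2],
        [5, 4, 3, 2, 1, 0],
    ]
)


def split_prisms(prisms: np.ndarray) -> np.ndarray:
    """Split wedge elements (P, 6) into tetrahedra (3P, 4), conformingly.

    Quad-face diagonals always emanate from the lowest-numbered node of the
    face, so two prisms sharing a quad face choose the same diagonal.
    """
    prisms = np.asarray(prisms)
    rot = _PRISM_ROTATIONS[np.argmin(prisms, axis=1)]
    w = np.take_along_axis(prisms, rot, axis=1)
    a = np.minimum(w[:, 1], w[:, 5]) < np.minimum(w[:, 2], w[:, 4])
    tets = np.empty((prisms.shape[0], 3, 4), dtype=prisms.dtype)
    tets[a, 0] = w[a][:, [0, 1, 2, 5]]
    tets[a, 1] = w[a][:, [0, 1, 5, 4]]
    tets[a, 2] = w[a][:, [0, 4, 5, 3]]
    b = ~a
    tets[b, 0] = w[b][:, [0, 1, 2, 4]]
    tets[b, 1] = w[b][:, [0, 4, 2, 5]]
    tets[b, 2] = w[b][:, [0, 4, 5, 3]]
    return tets.reshape(-1, 4)


def box_mesh(
    lx: float, ly: float, lz: float, nx: int, ny: int, nz: int
) -> tuple[np.ndarray, np.ndarray]:
    """Structured tetrahedral box mesh (oracle / verification geometry).

    Returns (coords (N,3), tets (M,4)) with positive volumes; each grid cell
    is extruded as two triangles and split into 6 conforming tets.
    """
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    coords = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    i, j, k = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    # bottom quad split into 2 triangles, extruded in z into 2 prisms
    t1 = np.stack([nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k)], axis=1)
    t2 = np.stack([nid(i, j, k), nid(i + 1, j + 1, k), nid(i, j + 1, k)], axis=1)
    tris = np.concatenate([t1, t2])
    prisms = np.concatenate([tris, tris + 1], axis=1)  # +1 = next z level
    tets = split_prisms(prisms)
    return coords, _orient_positive(coords, tets)


# ---------------------------------------------------------------------------
# frame and sphere fit


def build_frame(landmarks: LandmarkSet) -> AnatomicalFrame:
    """Anatomical frame from head centre, knee centre and lateral epicondyle.

    si = unit(head - knee); ml = knee->epicondyle Gram-Schmidt orthogonalised
    against si (they are generally not perpendicular); ap = ml x si.  With
    this handedness ap points anterior on a right femur.
    """
    landmarks.validate()
    si = landmarks.head_center - landmarks.knee_center
    si = si / np.linalg.norm(si)
    v = landmarks.lateral_epicondyle - landmarks.knee_center
    ml = v - (v @ si) * si
    nml = np.linalg.norm(ml)
    if nml < 1e-12:
        raise DegenerateGeometryError("epicondyle lies on the mechanical axis")
    ml = ml / nml
    ap = np.cross(ml, si)
    return AnatomicalFrame(
        si_axis=si, ml_axis=ml, ap_axis=ap, origin=landmarks.knee_center.copy()
    )


def fit_head_sphere(model_or_points, patch: np.ndarray | None = None):
    """Least-squares sphere fit over the femoral-head surface patch.

    Accepts a :class:`FemurModel` (uses ``landmarks.head_surface_patch``) or a
    raw (K, 3) point array.  Returns ``(center, radius, rms_residual)``.
    Solves the linear system ``|x|^2 = 2 c.x + (r^2 - |c|^2)``.
    """
    if isinstance(model_or_points, FemurModel):
        pts = model_or_points.node_coords[model_or_points.landmarks.head_surface_patch]
    else:
        pts = np.asarray(model_or_points, float)
    if pts.shape[0] < 4:
        raise DegenerateGeometryError("need at least 4 points for a sphere fit")
    A = np.concatenate([2.0 * pts, np.ones((pts.shape[0], 1))], axis=1)
    b = np.einsum("ij,ij->i", pts, pts)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise DegenerateGeometryError("degenerate (coplanar) sphere-fit patch")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise DegenerateGeometryError("sphere fit produced non-positive radius")
    radius = float(np.sqrt(r2))
    rms = float(np.sqrt(np.mean((np.linalg.norm(pts - center, axis=1) - radius) ** 2)))
    return center, radius, rms


# ---------------------------------------------------------------------------
# generator


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def generate_femur(params: FemurParams | None = None) -> FemurModel:
    """Generate the synthetic femur model (deterministic given ``rng_seed``)."""
    p = params or FemurParams()
    p.validate()
    rng = np.random.default_rng(p.rng_seed)

    L = p.femur_length
    R = p.head_radius
    h = p.target_edge_length
    r_shaft = p.shaft_outer_radius
    neck_r = 0.72 * R  # real neck width is ~0.7 of the head diameter
    theta = np.radians(180.0 - p.neck_shaft_angle_deg)  # neck tilt from +z
    ava = np.radians(p.anteversion_deg)
    # transverse neck direction: medial with anterior tilt (anterior = -y)
    t_hat = np.array([-np.cos(ava), -np.sin(ava), 0.0])
    n_dir = np.cos(theta) * np.array([0.0, 0.0, 1.0]) + np.sin(theta) * t_hat
    z_nb = L - p.neck_length * np.cos(theta)
    neck_base = np.array([0.0, 0.0, z_nb])
    head_center = neck_base + p.neck_length * n_dir
    if z_nb - 2 * h <= 0.12 * L:
        raise ConstructionError("junction overlaps the condylar region")

    # resolution: azimuth count multiple of 4 (anatomical azimuths must exist)
    na = max(8, 4 * int(round(1.5 * np.pi * r_shaft / (4.0 * h))))
    nr = max(2, int(round(0.75 * r_shaft / h)))

    # --- section schedule: (s-parameter, center, normal) ---
    blend = max(4.0 * h, 24.0)
    d0 = np.sqrt(max(R**2 - neck_r**2, 1e-9))  # neck->sphere merge offset
    s_neck_end = z_nb + p.neck_length - d0
    n_shaft = max(4, int(round(z_nb / h)))
    s_shaft = np.linspace(0.0, z_nb, n_shaft + 1)
    n_neck = max(2, int(round((s_neck_end - z_nb) / h)))
    s_neck = np.linspace(z_nb, s_neck_end, n_neck + 1)[1:]
    # spherical head: uniform polar-angle spacing, includes the equator (phi=0)
    phi0 = -np.arcsin(np.clip(d0 / R, 0.0, 1.0))
    dphi = h / R
    phi_neg = np.arange(phi0 + dphi, 0.0, dphi)
    phi_last = np.arccos(np.clip(2.0 * h / R, 0.05, 0.95))
    phi_pos = np.arange(0.0, phi_last + 1e-12, dphi)
    phis = np.concatenate([phi_neg, phi_pos])

    sections = []  # (center, normal, a, b, kind, phi_or_s)
    for s in s_shaft:
        sections.append(("shaft", s))
    for s in s_neck:
        sections.append(("neck", s))
    for phi in phis:
        sections.append(("head", phi))

    z_cond = 0.10 * L
    a_cond, b_cond = 1.9, 1.55  # condylar ML / AP flare factors

    def section_geometry(kind, par):
        if kind in ("shaft", "neck"):
            s = par
            if s <= z_nb:
                center = np.array([0.0, 0.0, s])
            else:
                center = neck_base + (s - z_nb) * n_dir
            f = _smoothstep((s - (z_nb - blend)) / (2.0 * blend))
            ang = f * theta
            normal = np.cos(ang) * np.array([0.0, 0.0, 1.0]) + np.sin(ang) * t_hat
            if s <= z_nb:
                w = _smoothstep((z_cond - s) / z_cond)
                # metaphyseal flares: the shaft is narrowest at mid-diaphysis
                # and widens towards the subtrochanteric and supracondylar
                # regions, like a real femur
                prox = 1.0 + 0.55 * _smoothstep((s - 0.55 * L) / (0.95 * z_nb - 0.55 * L))
                dist = 1.0 + 0.18 * _smoothstep((0.35 * L - s) / (0.25 * L))
                a = r_shaft * prox * dist * (1.0 + (a_cond - 1.0) * w)
                b = r_shaft * prox * dist * (1.0 + (b_cond - 1.0) * w)
                # taper into the neck radius as the junction is approached
                fw = _smoothstep((s - (z_nb - blend)) / blend)
                a = a * (1 - fw) + neck_r * fw if s > z_nb - blend else a
                b = b * (1 - fw) + neck_r * fw if s > z_nb - blend else b
            else:
                a = b = neck_r
        else:  # head
            phi = par
            center = head_center + R * np.sin(phi) * n_dir
            normal = n_dir
            a = b = R * np.cos(phi)
        return center, normal, a, b

    # cortical thickness varies axially: full in the shaft, thinning over the
    # trochanteric (junction) region whose prominence is cancellous-filled
    # with a 1-2 mm shell, still substantial along the neck (thick calcar),
    # thin over the head
    def local_ct(kind, par):
        if kind == "shaft":
            s = par
            f = _smoothstep((s - (z_nb - 25.0)) / 25.0) if s > z_nb - 25.0 else 0.0
            return p.cortical_thickness * (1.0 - 0.6 * f)
        if kind == "neck":
            s = par
            g = _smoothstep((s - z_nb) / 20.0)  # trochanteric zone -> calcar
            return p.cortical_thickness * (0.4 + 0.35 * g)
        return 0.45 * p.cortical_thickness

    psis = 2.0 * np.pi * np.arange(na) / na

    coords: list[np.ndarray] = []
    section_offsets: list[int] = []
    section_info: list[tuple] = []
    fcs: list[float] = []
    for kind, par in sections:
        center, normal, a, b = section_geometry(kind, par)
        # in-plane axes: e1 as lateral as possible, e2 = normal x e1
        ex = np.array([1.0, 0.0, 0.0])
        e1 = ex - (ex @ normal) * normal
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(normal, e1)
        r_mean = 0.5 * (a + b)
        f_c = float(np.clip(1.0 - local_ct(kind, par) / r_mean, 0.3, 0.92))
        # nr rings: evenly spaced up to the cortical boundary f_c, outer at 1
        fracs = np.concatenate([np.linspace(0.0, f_c, nr)[1:], [1.0]])
        # greater-trochanter prominence near the junction (shaft/neck only):
        # a protruding, cancellous-filled lateral bump, so the "most lateral
        # region" sits on a compliant overhang as on a real femur
        if kind != "head":
            s = par
            g = 0.35 * np.exp(-(((s - z_nb) / 14.0) ** 2)) if s > z_nb - 30 else 0.0
        else:
            g = 0.0
        bump = 1.0 + g * np.maximum(0.0, np.cos(psis)) ** 3
        section_offsets.append(sum(c.shape[0] for c in coords))
        pts = [center]
        for f in fracs:
            ring = (
                center[None, :]
                + (f * a * np.cos(psis) * bump)[:, None] * e1[None, :]
                + (f * b * np.sin(psis) * bump)[:, None] * e2[None, :]
            )
            pts.append(ring)
        coords.append(np.concatenate([np.atleast_2d(pts[0])] + pts[1:]))
        section_info.append((kind, par, center))
        fcs.append(f_c)

    apex_id = sum(c.shape[0] for c in coords)
    node_coords = np.concatenate(coords + [np.atleast_2d(head_center + R * n_dir)])

    # --- disk triangulation (same topology for every section) ---
    j = np.arange(na)
    jn = (j + 1) % na
    fan = np.stack([np.zeros(na, int), 1 + j, 1 + jn], axis=1)
    tris = [fan]
    bands = [np.zeros(na, int)]
    for r in range(1, nr):
        lo = 1 + (r - 1) * na
        hi = 1 + r * na
        qa, qb, qc, qd = lo + j, lo + jn, hi + jn, hi + j
        tris.append(np.stack([qa, qb, qc], axis=1))
        tris.append(np.stack([qa, qc, qd], axis=1))
        bands.append(np.full(na, r))
        bands.append(np.full(na, r))
    disk_tris = np.concatenate(tris)
    disk_bands = np.concatenate(bands)
    n_sec = len(sections)

    # --- prisms between consecutive sections, split into tets ---
    all_tets = []
    all_bands = []
    for k in range(n_sec - 1):
        off0, off1 = section_offsets[k], section_offsets[k + 1]
        prisms = np.concatenate([disk_tris + off0, disk_tris + off1], axis=1)
        all_tets.append(split_prisms(prisms))
        all_bands.append(np.repeat(disk_bands, 3))
    # apex cone cap on the last section
    off = section_offsets[-1]
    cap = np.concatenate(
        [disk_tris + off, np.full((disk_tris.shape[0], 1), apex_id)], axis=1
    )
    all_tets.append(cap)
    all_bands.append(disk_bands)
    tets = np.concatenate(all_tets)
    bands_per_tet = np.concatenate(all_bands)
    tets = _orient_positive(node_coords, tets)
    vols = tet_volumes(node_coords, tets)
    if np.any(vols <= 0):
        raise ConstructionError(
            f"{int(np.sum(vols <= 0))} non-positive tetrahedra in generated mesh"
        )

    # --- greyscale field from radial band position ---
    # per-tet owning section (layer): layer k uses f_c of section k
    layer_fc = np.empty(tets.shape[0])
    pos = 0
    for k in range(n_sec - 1):
        cnt = disk_tris.shape[0] * 3
        layer_fc[pos : pos + cnt] = 0.5 * (fcs[k] + fcs[k + 1])
        pos += cnt
    layer_fc[pos:] = fcs[-1]
    # band mid radial fractions: bands 0..nr-2 tile [0, f_c], band nr-1 = cortex
    mids = np.empty(tets.shape[0])
    inner = np.linspace(0, 1, nr)
    for b in range(nr):
        mask = bands_per_tet == b
        if b < nr - 1:
            lo = inner[b] * layer_fc[mask]
            hi = inner[b + 1] * layer_fc[mask] if b + 1 < nr else layer_fc[mask]
        else:
            lo = layer_fc[mask]
            hi = np.ones(mask.sum())
        mids[mask] = 0.5 * (lo + hi)
    shape = _smoothstep((mids - 0.5 * layer_fc) / np.maximum(0.5 * layer_fc, 1e-9))
    gv = p.cancellous_gv + (p.cortical_gv - p.cancellous_gv) * shape
    gv = gv * (1.0 + 0.03 * rng.standard_normal(gv.shape))
    gv = np.clip(gv, 1250.0, 4095.0)

    # --- landmarks and patches ---
    def ring_node(sec_idx, psi_deg):
        jj = int(round((psi_deg % 360.0) / 360.0 * na)) % na
        return section_offsets[sec_idx] + 1 + (nr - 1) * na + jj

    s_values = np.array(
        [par if kind != "head" else np.nan for kind, par, _ in section_info]
    )

    def sec_near(s_target):
        return int(np.nanargmin(np.abs(s_values - s_target)))

    knee_node = section_offsets[0]  # centre of the first disk
    nb_node = section_offsets[sec_near(z_nb)]
    # head-centre node: centre of the phi = 0 head section
    head_sec = next(
        i
        for i, (kind, par, _) in enumerate(section_info)
        if kind == "head" and abs(par) < 1e-12
    )
    head_node = section_offsets[head_sec]
    epi_node = ring_node(sec_near(0.05 * L), 0.0)
    mid_node = ring_node(sec_near(0.5 * L), 0.0)
    pc_med_node = ring_node(sec_near(0.03 * L), 120.0)
    pc_lat_node = ring_node(sec_near(0.03 * L), 60.0)
    # greater trochanter: most lateral surface node near the junction
    cand = [
        ring_node(i, 0.0)
        for i, (kind, par, _) in enumerate(section_info)
        if kind != "head" and z_nb - 25 < par < z_nb + 30
    ]
    gt_node = cand[int(np.argmax([node_coords[c][0] for c in cand]))]

    surf_nodes = surface_node_indices(tets)
    surf_set_coords = node_coords[surf_nodes]

    def patch_near(point, radius):
        d = np.linalg.norm(surf_set_coords - point, axis=1)
        return surf_nodes[d <= radius]

    head_patch = surf_nodes[
        np.linalg.norm(surf_set_coords - head_center, axis=1) <= R * 1.02
    ]
    condylar_patch = surf_nodes[surf_set_coords[:, 2] <= 0.05 * L]
    # grow the patch until it has enough nodes for a well-posed coupling
    gt_radius = 12.0
    gt_patch = patch_near(node_coords[gt_node], gt_radius)
    while gt_patch.size < 6 and gt_radius < 30.0:
        gt_radius += 3.0
        gt_patch = patch_near(node_coords[gt_node], gt_radius)

    node_ids = {
        "head_center": head_node,
        "knee_center": knee_node,
        "lateral_epicondyle": epi_node,
        "greater_trochanter_lateral": gt_node,
        "mid_diaphysis": mid_node,
        "neck_base": nb_node,
        "post_condyle_medial": pc_med_node,
        "post_condyle_lateral": pc_lat_node,
    }
    landmarks = LandmarkSet(
        head_center=node_coords[head_node].copy(),
        knee_center=node_coords[knee_node].copy(),
        lateral_epicondyle=node_coords[epi_node].copy(),
        greater_trochanter_lateral=node_coords[gt_node].copy(),
        mid_diaphysis=node_coords[mid_node].copy(),
        neck_base=node_coords[nb_node].copy(),
        post_condyle_medial=node_coords[pc_med_node].copy(),
        post_condyle_lateral=node_coords[pc_lat_node].copy(),
        head_surface_patch=head_patch,
        condylar_patch=condylar_patch,
        gt_patch=gt_patch,
        node_ids=node_ids,
    )

    def seed_point(s_frac_or_s, psi_deg, absolute=False):
        s = s_frac_or_s if absolute else s_frac_or_s * L
        sec = sec_near(s)
        return node_coords[ring_node(sec, psi_deg)]

    # azimuth convention: 0 lateral, 90 posterior, 180 medial, 270 anterior
    muscle_seeds = {
        "gluteus_medius": (z_nb + 10.0, 30.0, 10.0, True),
        "gluteus_maximus": (0.72, 60.0, 15.0, False),
        "iliopsoas": (z_nb - 12.0, 150.0, 9.0, True),
        "vasti": (0.55, 270.0, 18.0, False),
        "adductors": (0.45, 135.0, 15.0, False),
        "biceps_femoris_short": (0.35, 60.0, 12.0, False),
        "gastroc_medial": (0.045, 120.0, 8.0, False),
        "gastroc_lateral": (0.045, 60.0, 8.0, False),
        "pf_contact": (0.07, 270.0, 10.0, False),
    }
    patches: dict[str, AttachmentPatch] = {}
    for name, (sv, psi, rad, absolute) in muscle_seeds.items():
        seed = seed_point(sv, psi, absolute)
        nodes = patch_near(seed, rad)
        patches[name] = AttachmentPatch(
            refpoint=node_coords[nodes].mean(axis=0), nodes=nodes
        )
    patches["hip_contact"] = AttachmentPatch(
        refpoint=head_center.copy(), nodes=head_patch
    )
    # tibiofemoral contact: the whole distal face (condylar plateau footprint),
    # so centre-of-pressure migration stays inside the patch hull
    bottom = surf_nodes[np.abs(surf_set_coords[:, 2]) < 1e-9]
    patches["tf_contact"] = AttachmentPatch(
        refpoint=node_coords[knee_node].copy(), nodes=bottom
    )

    # diaphyseal strain paths (surface polylines, 20-80 % of femur length)
    path_secs = [
        i
        for i, (kind, par, _) in enumerate(section_info)
        if kind == "shaft" and 0.2 * L <= par <= 0.8 * L
    ]
    strain_paths = {
        name: np.array([ring_node(i, psi) for i in path_secs])
        for name, psi in (
            ("lateral", 0.0),
            ("posterior", 90.0),
            ("medial", 180.0),
            ("anterior", 270.0),
        )
    }

    model = FemurModel(
        node_coords=node_coords,
        tets=tets,
        element_gv=gv,
        landmarks=landmarks,
        frame=build_frame(landmarks),
        attachment_patches=patches,
        strain_paths=strain_paths,
        params=p,
    )
    return model
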