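"""Linear-elastic 4-node tetrahedral finite-element engine.

Constant-strain tetrahedra (the C3D4 element), small-strain small-displacement
quasi-statics.  The engine provides sparse assembly, a KKT solver for general
homogeneous linear multi-point constraints (Dirichlet rows, averaged-motion
sliders, rigid couplings) with optional grounded springs, an inertia-relief
solve for fully free bodies, and stress / strain recovery.

Unit system: mm - N - MPa - tonne.  Voigt order (xx, yy, zz, xy, yz, zx) with
engineering shear strains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from femurbench.model import FemurModel

__all__ = [
    "AssembledSystem",
    "FEResult",
    "SingularSystemError",
    "assemble",
    "distribute_force",
    "element_stiffness",
    "isotropic_elasticity",
    "recover_fields",
    "rigid_modes",
    "solve_inertia_relief",
    "solve_static",
    "von_mises_stress",
]


class SingularSystemError(RuntimeError):
    """The constrained stiffness matrix is singular (unremoved rigid modes)."""


def isotropic_elasticity(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic elasticity matrix (engineering shear convention)."""
    if not 0.0 <= nu < 0.5:
        raise ValueError("Poisson's ratio must lie in [0, 0.5)")
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.diag_indices(3)] = lam + 2.0 * mu
    D[3, 3] = D[4, 4] = D[5, 5] = mu
    return D


def _b_matrices(coords: np.ndarray, tets: np.ndarray):
    """Per-element strain-displacement matrices B (M, 6, 12) and volumes."""
    p = coords[tets]  # (M, 4, 3)
    X = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]], axis=1)
    vol = np.linalg.det(X) / 6.0
    Xinv = np.linalg.inv(X)  # rows of Xinv.T are gradients of N1..N3
    g = np.empty((tets.shape[0], 4, 3))
    g[:, 1:, :] = np.transpose(Xinv, (0, 2, 1))
    g[:, 0, :] = -g[:, 1:, :].sum(axis=1)
    M = tets.shape[0]
    B = np.zeros((M, 6, 12))
    for a in range(4):
        gx, gy, gz = g[:, a, 0], g[:, a, 1], g[:, a, 2]
        c = 3 * a
        B[:, 0, c + 0] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c + 0] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c + 0] = gz
        B[:, 5, c + 2] = gx
    return B, vol


def element_stiffness(tet_coords: np.ndarray, E: float, nu: float) -> np.ndarray:
    """12x12 stiffness block of one constant-strain tetrahedron."""
    tet_coords = np.asarray(tet_coords, float).reshape(1, 4, 3)
    coords = tet_coords[0]
    B, vol = _b_matrices(coords, np.array([[0, 1, 2, 3]]))
    if vol[0] <= 0:
        raise ValueError("inverted tetrahedron (non-positive volume)")
    D = isotropic_elasticity(E, nu)
    return vol[0] * B[0].T @ D @ B[0]


@dataclass
class AssembledSystem:
    """Assembled sparse stiffness, lumped mass, and mesh bookkeeping."""

    stiffness: sp.csr_matrix  # (3N, 3N), N/mm
    mass: np.ndarray  # (3N,) lumped diagonal, tonne
    node_coords: np.ndarray
    tets: np.ndarray
    B: np.ndarray  # (M, 6, 12) strain-displacement operators
    volumes: np.ndarray  # (M,)
    D: np.ndarray  # (M, 6, 6) per-element elasticity

    @property
    def n_dof(self) -> int:
        return self.stiffness.shape[0]

    @property
    def total_mass(self) -> float:
        return float(self.mass.sum() / 3.0)


def assemble(model: FemurModel, materials) -> AssembledSystem:
    """Assemble global stiffness and lumped mass from binned materials."""
    coords, tets = model.node_coords, model.tets
    B, vol = _b_matrices(coords, tets)
    if np.any(vol <= 0):
        raise ValueError("mesh contains inverted elements")
    E = materials.element_modulus()
    nu = materials.poisson[materials.element_bin]
    M = tets.shape[0]
    D = np.empty((M, 6, 6))
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    D[:] = 0.0
    D[:, :3, :3] = lam[:, None, None]
    for i in range(3):
        D[:, i, i] = lam + 2.0 * mu
        D[:, 3 + i, 3 + i] = mu
    Ke = np.einsum("mji,mjk,mkl,m->mil", B, D, B, vol, optimize=True)
    edof = (3 * tets[:, :, None] + np.arange(3)[None, None, :]).reshape(M, 12)
    rows = np.repeat(edof, 12, axis=1).ravel()
    cols = np.tile(edof, (1, 12)).ravel()
    n = 3 * coords.shape[0]
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()

    rho = materials.element_mass_density()
    mass = np.zeros(n)
    nodal = np.repeat((rho * vol / 4.0)[:, None], 4, axis=1).ravel()
    for c in range(3):
        np.add.at(mass, 3 * tets.ravel() + c, nodal)
    return AssembledSystem(
        stiffness=K, mass=mass, node_coords=coords, tets=tets, B=B, volumes=vol, D=D
    )


def distribute_force(
    coords: np.ndarray, patch_nodes: np.ndarray, refpoint: np.ndarray, force: np.ndarray
) -> np.ndarray:
    """Moment-consistent distribution of a reference-point force over a patch.

    Nodal forces take the form ``f_i = a + b x r_i`` (r_i measured from the
    reference point) with (a, b) solved so that the nodal system is statically
    equivalent to ``force`` acting at the reference point: sum f_i = force and
    zero net moment about the reference point.
    """
    patch_nodes = np.asarray(patch_nodes, int)
    if patch_nodes.size == 0:
        raise ValueError("empty attachment patch")
    r = coords[patch_nodes] - refpoint
    if patch_nodes.size == 1:
        return force[None, :].copy()
    n = patch_nodes.size
    S = r.sum(axis=0)
    Sx = np.array(
        [[0, -S[2], S[1]], [S[2], 0, -S[0]], [-S[1], S[0], 0]]
    )
    # inertia-like operator: sum |r|^2 I - r r^T
    J = np.eye(3) * np.einsum("ij,ij->", r, r) - r.T @ r
    A = np.block([[n * np.eye(3), -Sx], [Sx, J]])
    rhs = np.concatenate([force, np.zeros(3)])
    # least squares handles degenerate (collinear / coplanar) patches, where
    # some couple directions carry no inertia but are not needed either
    ab, *_ = np.linalg.lstsq(A, rhs, rcond=1e-8)
    a, b = ab[:3], ab[3:]
    f = a[None, :] + np.cross(b[None, :], r)
    ref = max(np.linalg.norm(force), 1e-30)
    if np.linalg.norm(f.sum(axis=0) - force) > 1e-8 * ref or np.linalg.norm(
        np.cross(r, f).sum(axis=0)
    ) > 1e-6 * ref * max(np.abs(r).max(), 1.0):
        raise ValueError(
            "force distribution cannot be made statically equivalent on this patch"
        )
    return f


def rigid_modes(coords: np.ndarray, mass: np.ndarray) -> np.ndarray:
    """Six rigid-body mode columns (3N, 6) about the lumped-mass centroid."""
    n = coords.shape[0]
    m_nodal = mass.reshape(n, 3)[:, 0]
    total = m_nodal.sum()
    if total <= 0:
        raise SingularSystemError("zero total mass: inertia relief undefined")
    com = (m_nodal[:, None] * coords).sum(axis=0) / total
    R = np.zeros((3 * n, 6))
    for k in range(3):
        R[k::3, k] = 1.0
    rel = coords - com
    for k, e in enumerate(np.eye(3)):
        w = np.cross(np.broadcast_to(e, rel.shape), rel)
        R[:, 3 + k] = w.ravel()
    return R


@dataclass
class FEResult:
    """Displacements and recovered fields for one or more load instances."""

    displacements: np.ndarray  # (k, N, 3) mm
    element_strain: np.ndarray  # (k, M, 6) Voigt, engineering shear
    element_stress: np.ndarray  # (k, M, 6) MPa
    von_mises: np.ndarray  # (k, M) MPa
    principal_strains: np.ndarray  # (k, M, 3) ascending
    reactions: np.ndarray  # (k, n_constraint_rows) Lagrange multipliers, N
    constraint_labels: list = field(default_factory=list)
    rigid_accelerations: np.ndarray | None = None  # (k, 6) for inertia relief

    @property
    def n_instances(self) -> int:
        return self.displacements.shape[0]

    def abs_principal_strain(self) -> np.ndarray:
        """max |principal strain| per element, (k, M)."""
        return np.abs(self.principal_strains).max(axis=2)


def von_mises_stress(stress_voigt: np.ndarray) -> np.ndarray:
    s = stress_voigt
    sxx, syy, szz = s[..., 0], s[..., 1], s[..., 2]
    sxy, syz, szx = s[..., 3], s[..., 4], s[..., 5]
    return np.sqrt(
        0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
        + 3.0 * (sxy**2 + syz**2 + szx**2)
    )


def recover_fields(
    system: AssembledSystem,
    displacements: np.ndarray,
    reactions: np.ndarray | None = None,
    labels: list | None = None,
    rigid_accelerations: np.ndarray | None = None,
) -> FEResult:
    """Strain, stress, von Mises and principal strains from displacements.

    ``displacements``: (k, N, 3) or (N, 3).
    """
    u = np.asarray(displacements)
    if u.ndim == 2:
        u = u[None]
    k = u.shape[0]
    ue = u[:, system.tets, :].reshape(k, system.tets.shape[0], 12)
    strain = np.einsum("mij,kmj->kmi", system.B, ue, optimize=True)
    stress = np.einsum("mij,kmj->kmi", system.D, strain, optimize=True)
    vm = von_mises_stress(stress)
    # strain tensor eigenvalues (tensor shear = engineering shear / 2)
    T = np.empty(strain.shape[:2] + (3, 3))
    T[..., 0, 0] = strain[..., 0]
    T[..., 1, 1] = strain[..., 1]
    T[..., 2, 2] = strain[..., 2]
    T[..., 0, 1] = T[..., 1, 0] = 0.5 * strain[..., 3]
    T[..., 1, 2] = T[..., 2, 1] = 0.5 * strain[..., 4]
    T[..., 0, 2] = T[..., 2, 0] = 0.5 * strain[..., 5]
    principal = np.linalg.eigvalsh(T)
    if reactions is None:
        reactions = np.zeros((k, 0))
    return FEResult(
        displacements=u,
        element_strain=strain,
        element_stress=stress,
        von_mises=vm,
        principal_strains=principal,
        reactions=reactions,
        constraint_labels=labels or [],
        rigid_accelerations=rigid_accelerations,
    )


def _solve_kkt(
    K: sp.spmatrix,
    C: sp.spmatrix | None,
    loads: np.ndarray,
    residual_tol: float = 1e-8,
):
    """Solve [[K, C^T], [C, 0]] [u; lam] = [f; 0] for each load column."""
    n = K.shape[0]
    if C is not None and C.shape[0] > 0:
        KKT = sp.bmat([[K, C.T], [C, None]], format="csc")
        m = C.shape[0]
    else:
        KKT = sp.csc_matrix(K)
        m = 0
    try:
        lu = spla.splu(KKT)
    except RuntimeError as exc:  # exactly singular factorization
        raise SingularSystemError(
            "constrained stiffness is singular: the constraint set leaves "
            "unsuppressed rigid-body modes"
        ) from exc
    loads = np.atleast_2d(loads.reshape(-1, n))
    us = np.empty((loads.shape[0], n))
    lams = np.empty((loads.shape[0], m))
    for i, f in enumerate(loads):
        rhs = np.concatenate([f, np.zeros(m)])
        sol = lu.solve(rhs)
        u, lam = sol[:n], sol[n:]
        ref = max(np.linalg.norm(f), 1e-30)
        resid = K @ u - f
        if m:
            resid = resid + C.T @ lam
        if np.linalg.norm(resid) > residual_tol * ref or not np.all(
            np.isfinite(u)
        ):
            raise SingularSystemError(
                "solver residual too large: near-singular constrained system "
                f"(|r|/|f| = {np.linalg.norm(resid) / ref:.3e})"
            )
        us[i], lams[i] = u, lam
    return us, lams


def solve_static(
    system: AssembledSystem,
    loads: np.ndarray,
    constraint_rows: sp.spmatrix | None = None,
    spring_diagonal: np.ndarray | None = None,
    n_extra_dof: int = 0,
    labels: list | None = None,
    residual_tol: float = 1e-8,
) -> FEResult:
    """Static solve under homogeneous MPC rows and optional grounded springs.

    ``loads``: (k, 3N + n_extra_dof) or flat.  Constraint rows enforce
    C u = 0 via Lagrange multipliers; ``spring_diagonal`` adds grounded
    spring stiffness.  ``n_extra_dof`` appends zero-stiffness reference-point
    DoFs (tied to the mesh through rigid-coupling rows).
    """
    K = system.stiffness
    if n_extra_dof:
        K = sp.block_diag([K, sp.csr_matrix((n_extra_dof, n_extra_dof))])
    if spring_diagonal is not None and np.any(spring_diagonal):
        K = K + sp.diags(spring_diagonal, shape=K.shape)
    u, lam = _solve_kkt(K, constraint_rows, np.atleast_2d(loads), residual_tol)
    N = system.node_coords.shape[0]
    return recover_fields(
        system, u[:, : 3 * N].reshape(-1, N, 3), reactions=lam, labels=labels
    )


def solve_inertia_relief(
    system: AssembledSystem, loads: np.ndarray, residual_tol: float = 1e-8
) -> FEResult:
    """Inertia-relief solve of the fully free structure.

    Rigid-body accelerations a = (R^T M R)^-1 R^T f balance the applied load;
    the balanced load f_b = f - M R a has zero net force and moment, and the
    displacement is made unique by the mass-orthogonality gauge R^T M u = 0,
    enforced through the same KKT machinery with C = (M R)^T.
    """
    R = rigid_modes(system.node_coords, system.mass)
    MR = system.mass[:, None] * R
    G = R.T @ MR
    loads = np.atleast_2d(loads.reshape(-1, system.n_dof))
    a = np.linalg.solve(G, (loads @ R).T)  # (6, k)
    fb = loads - (MR @ a).T
    C = sp.csr_matrix(MR.T)
    u, lam = _solve_kkt(system.stiffness, C, fb, residual_tol)
    # the multipliers represent residual accelerations; they vanish because
    # f_b is orthogonal to the rigid modes
    N = system.node_coords.shape[0]
    res = recover_fields(
        system,
        u.reshape(-1, N, 3),
        reactions=lam,
        labels=[("inertia_relief_gauge", i) for i in range(6)],
        rigid_accelerations=a.T,
    )
    return res
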