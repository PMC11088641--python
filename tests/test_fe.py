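"""Finite-element core: element formulation, assembly, solves, recovery."""

import numpy as np
import pytest
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from femurbench.fe import (
    AssembledSystem,
    SingularSystemError,
    assemble,
    distribute_force,
    element_stiffness,
    recover_fields,
    rigid_modes,
    solve_inertia_relief,
    solve_static,
    von_mises_stress,
)
from femurbench.materials import MaterialTable, bin_materials
from femurbench.model import box_mesh, surface_node_indices

REGULAR_TET = np.array(
    [[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0], [0.5, np.sqrt(3) / 6, np.sqrt(2.0 / 3.0)]]
)


class _Mesh:
    def __init__(self, coords, tets):
        self.node_coords = coords
        self.tets = tets
        self.n_nodes = coords.shape[0]


def _const_materials(n_elem, E=1e4, nu=0.3):
    t = MaterialTable(
        density=np.array([1.0]),
        youngs_modulus=np.array([E]),
        poisson=np.array([0.3]),
        element_bin=np.zeros(n_elem, int),
        gv_edges=np.array([[0.0, 1.0]]),
        supra_physiological=np.array([False]),
    )
    t.poisson[:] = nu
    return t


def _dirichlet_rows(nodes, n_nodes):
    C = sp.lil_matrix((3 * len(nodes), 3 * n_nodes))
    for i, nd in enumerate(nodes):
        for c in range(3):
            C[3 * i + c, 3 * int(nd) + c] = 1.0
    return C.tocsr()


# ---------------------------------------------------------------------------
# element level


def test_element_stiffness_symmetric_psd_rigid_modes():
    K = element_stiffness(REGULAR_TET, E=1e4, nu=0.3)
    assert np.abs(K - K.T).max() < 1e-8 * np.abs(K).max()
    w = np.linalg.eigvalsh(K)
    assert np.sum(np.abs(w) < 1e-8 * np.abs(w).max()) == 6  # rigid modes
    assert np.all(w > -1e-8 * np.abs(w).max())
    u = np.tile([1.0, 1.0, 1.0], 4)
    assert np.abs(K @ u).max() < 1e-8 * np.abs(K).max()


def test_element_stiffness_rejects_inverted():
    bad = REGULAR_TET[[0, 2, 1, 3]]
    with pytest.raises(ValueError):
        element_stiffness(bad, 1e4, 0.3)


def test_patch_test_constant_strain():
    """Prescribed linear displacement field reproduces the exact strain."""
    coords, tets = box_mesh(2, 2, 2, 2, 2, 2)
    system = assemble(_Mesh(coords, tets), _const_materials(tets.shape[0]))
    A = np.array([[1e-3, 2e-4, 0.0], [0.0, -5e-4, 1e-4], [3e-4, 0.0, 2e-3]])
    res = recover_fields(system, coords @ A.T)
    eps = 0.5 * (A + A.T)
    expect = np.array(
        [eps[0, 0], eps[1, 1], eps[2, 2], 2 * eps[0, 1], 2 * eps[1, 2], 2 * eps[0, 2]]
    )
    assert np.abs(res.element_strain[0] - expect).max() < 1e-10


def test_assembly_matches_dense_oracle():
    """Sparse scatter-add equals an explicit dense two-tet assembly."""
    coords = np.array(
        [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1.2]], float
    )
    tets = np.array([[0, 1, 2, 3], [1, 2, 3, 4]])
    E, nu = 5e3, 0.3
    system = assemble(_Mesh(coords, tets), _const_materials(2, E=E))
    dense = np.zeros((15, 15))
    for t in tets:
        Ke = element_stiffness(coords[t], E, nu)
        dof = np.concatenate([[3 * n, 3 * n + 1, 3 * n + 2] for n in t])
        dense[np.ix_(dof, dof)] += Ke
    assert np.abs(system.stiffness.toarray() - dense).max() < 1e-9 * np.abs(dense).max()


def test_free_stiffness_has_six_rigid_modes(femur, materials, system):
    """Six near-zero eigenvalues of the unconstrained stiffness."""
    w = spla.eigsh(system.stiffness, k=8, sigma=0, which="LM",
                   return_eigenvectors=False)
    w = np.sort(np.abs(w))
    scale = system.stiffness.diagonal().max()
    assert np.all(w[:6] < 1e-9 * scale)
    # first elastic mode of the slender femur is soft but clearly separated
    assert w[6] > 1e-7 * scale


def test_total_mass_conserved(femur, materials, system):
    rho = materials.element_mass_density()
    assert system.total_mass == pytest.approx(
        float((rho * system.volumes).sum()), rel=1e-12
    )


# ---------------------------------------------------------------------------
# force distribution


def test_distribute_force_conserves_force_and_moment(rng):
    coords = rng.uniform(-10, 10, (40, 3))
    nodes = np.arange(40)
    refpoint = np.array([1.0, 2.0, 3.0])
    force = np.array([100.0, -50.0, 25.0])
    f = distribute_force(coords, nodes, refpoint, force)
    assert np.allclose(f.sum(axis=0), force, atol=1e-9)
    moments = np.cross(coords - refpoint, f).sum(axis=0)
    assert np.abs(moments).max() < 1e-6 * np.linalg.norm(force) * 10


def test_distribute_force_single_node_is_direct_load():
    coords = np.array([[5.0, 5.0, 5.0]])
    f = distribute_force(coords, np.array([0]), np.array([5.0, 5.0, 5.0]),
                         np.array([1.0, 2.0, 3.0]))
    assert np.allclose(f, [[1.0, 2.0, 3.0]])


def test_distribute_force_collinear_patch(rng):
    """Nearly collinear patches are handled without blow-up."""
    t = np.linspace(0, 20, 5)
    coords = np.stack([t, 0 * t, 0 * t], axis=1)
    coords += 1e-9 * rng.standard_normal(coords.shape)
    f = distribute_force(coords, np.arange(5), coords.mean(axis=0),
                         np.array([0.0, 10.0, 0.0]))
    assert np.linalg.norm(f, axis=1).max() < 100.0
    assert np.allclose(f.sum(axis=0), [0, 10, 0], atol=1e-6)


def test_distribute_force_empty_patch():
    with pytest.raises(ValueError):
        distribute_force(np.zeros((3, 3)), np.array([], int), np.zeros(3),
                         np.ones(3))


# ---------------------------------------------------------------------------
# static solve


@pytest.fixture(scope="module")
def cantilever():
    E = 1e4
    coords, tets = box_mesh(100, 10, 10, 60, 8, 8)
    system = assemble(_Mesh(coords, tets), _const_materials(tets.shape[0], E=E, nu=0.0))
    fixed = np.where(coords[:, 0] < 1e-9)[0]
    C = _dirichlet_rows(fixed, coords.shape[0])
    tip = np.where(coords[:, 0] > 100 - 1e-9)[0]
    f = np.zeros(3 * coords.shape[0])
    f[3 * tip + 1] = -100.0 / tip.size
    return coords, system, C, tip, f


def test_cantilever_tip_deflection(cantilever):
    """Euler-Bernoulli PL^3/3EI = 4.0 mm, recovered within 7%."""
    coords, system, C, tip, f = cantilever
    res = solve_static(system, f, constraint_rows=C)
    tip_def = res.displacements[0][tip, 1].mean()
    assert tip_def == pytest.approx(-4.0, rel=0.07)


def test_zero_load_zero_displacement(cantilever):
    coords, system, C, tip, f = cantilever
    res = solve_static(system, np.zeros_like(f), constraint_rows=C)
    assert np.abs(res.displacements).max() == 0.0


def test_linearity_and_superposition(cantilever, rng):
    coords, system, C, tip, f = cantilever
    g = np.zeros_like(f)
    some = rng.choice(coords.shape[0], 20, replace=False)
    g[3 * some] = rng.standard_normal(20)
    r1 = solve_static(system, f, constraint_rows=C)
    r2 = solve_static(system, g, constraint_rows=C)
    r12 = solve_static(system, f + g, constraint_rows=C)
    ref = np.abs(r12.displacements).max()
    assert np.abs(
        r12.displacements - r1.displacements - r2.displacements
    ).max() < 1e-9 * ref
    r2x = solve_static(system, 2.0 * f, constraint_rows=C)
    assert np.allclose(r2x.displacements, 2 * r1.displacements, atol=1e-9 * ref)


def test_unconstrained_static_solve_is_singular(cantilever):
    coords, system, C, tip, f = cantilever
    with pytest.raises(SingularSystemError):
        solve_static(system, f)


# ---------------------------------------------------------------------------
# stress recovery invariants


def test_von_mises_closed_forms():
    uniaxial = np.array([10.0, 0, 0, 0, 0, 0])
    assert von_mises_stress(uniaxial) == pytest.approx(10.0)
    hydro = np.array([7.0, 7.0, 7.0, 0, 0, 0])
    assert von_mises_stress(hydro) == pytest.approx(0.0, abs=1e-12)
    shear = np.array([0, 0, 0, 5.0, 0, 0])
    assert von_mises_stress(shear) == pytest.approx(5.0 * np.sqrt(3.0))


# ---------------------------------------------------------------------------
# inertia relief


@pytest.fixture(scope="module")
def free_bar():
    coords, tets = box_mesh(50, 10, 10, 10, 3, 3)
    system = assemble(_Mesh(coords, tets), bin_materials(np.full(tets.shape[0], 1800.0)))
    return coords, system


def test_inertia_relief_balances_any_load(free_bar, rng):
    """Balanced load has zero net force and moment for arbitrary loading."""
    coords, system = free_bar
    f = np.zeros(system.n_dof)
    some = rng.choice(coords.shape[0], 15, replace=False)
    f[3 * some + 1] = 100.0 * rng.standard_normal(15)
    R = rigid_modes(coords, system.mass)
    MR = system.mass[:, None] * R
    a = np.linalg.solve(R.T @ MR, R.T @ f)
    fb = (f - MR @ a).reshape(-1, 3)
    ref = np.linalg.norm(f)
    assert np.abs(fb.sum(axis=0)).max() < 1e-8 * ref
    assert np.abs(np.cross(coords, fb).sum(axis=0)).max() < 1e-8 * ref * 50


def test_inertia_relief_matches_gauge_fixed_static(free_bar):
    """Self-equilibrated load: IR stresses equal a 3-2-1 supported solve."""
    coords, system = free_bar
    left = np.where(coords[:, 0] < 1e-9)[0]
    right = np.where(coords[:, 0] > 50 - 1e-9)[0]
    f = np.zeros(system.n_dof)
    f[3 * left + 0] = -10.0 / left.size
    f[3 * right + 0] = 10.0 / right.size
    ir = solve_inertia_relief(system, f)
    assert np.abs(ir.rigid_accelerations).max() < 1e-10
    # minimal isostatic gauge (3-2-1 point supports)
    i0 = int(np.argmin(np.linalg.norm(coords - [0, 0, 0], axis=1)))
    i1 = int(np.argmin(np.linalg.norm(coords - [50, 0, 0], axis=1)))
    i2 = int(np.argmin(np.linalg.norm(coords - [0, 10, 0], axis=1)))
    C = sp.lil_matrix((6, system.n_dof))
    for r, (nd, c) in enumerate(
        [(i0, 0), (i0, 1), (i0, 2), (i1, 1), (i1, 2), (i2, 2)]
    ):
        C[r, 3 * nd + c] = 1.0
    st = solve_static(system, f, constraint_rows=C.tocsr())
    ref = np.abs(st.element_stress).max()
    assert np.abs(ir.element_stress - st.element_stress).max() < 1e-8 * ref
    assert np.abs(st.reactions).max() < 1e-8 * 10.0  # gauge carries no load


def test_inertia_relief_rigid_acceleration_of_free_block(free_bar):
    """Net force F on a free body gives rigid accelerations F/m, ~no stress."""
    coords, system = free_bar
    f = np.zeros(system.n_dof)
    nodes = np.arange(coords.shape[0])
    # uniform force density in +x, proportional to nodal mass: pure rigid push
    f[3 * nodes + 0] = system.mass[0::3] * 1.0e6
    res = solve_inertia_relief(system, f)
    total_f = f[0::3].sum()
    assert res.rigid_accelerations[0][0] == pytest.approx(
        total_f / system.total_mass, rel=1e-9
    )
    assert np.abs(res.rigid_accelerations[0][1:]).max() < 1e-6 * abs(
        res.rigid_accelerations[0][0]
    )
    assert np.abs(res.von_mises).max() < 1e-6 * total_f  # no elastic stress


def test_inertia_relief_translation_invariant_stress(free_bar, rng):
    """Rigidly pre-translating the mesh leaves IR strains unchanged."""
    coords, system = free_bar
    f = np.zeros(system.n_dof)
    some = rng.choice(coords.shape[0], 10, replace=False)
    f[3 * some + 2] = 50.0
    r1 = solve_inertia_relief(system, f)
    shifted = coords + np.array([123.0, -45.0, 6.0])
    tets = system.tets
    system2 = assemble(_Mesh(shifted, tets), bin_materials(np.full(tets.shape[0], 1800.0)))
    r2 = solve_inertia_relief(system2, f)
    ref = np.abs(r1.element_stress).max()
    assert np.abs(r1.element_stress - r2.element_stress).max() < 1e-8 * ref


def test_inertia_relief_requires_mass():
    coords, tets = box_mesh(2, 2, 2, 1, 1, 1)
    system = assemble(_Mesh(coords, tets), _const_materials(tets.shape[0]))
    system.mass[:] = 0.0
    with pytest.raises(SingularSystemError):
        solve_inertia_relief(system, np.ones(system.n_dof))
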