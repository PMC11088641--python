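"""Outcome measures: FHD, PVMS, strain paths, R^2 / nRMSE comparison."""

import numpy as np
import pytest

from femurbench import compare_report, nrmse, r_squared
from femurbench.fe import assemble, recover_fields, solve_static
from femurbench.materials import MaterialTable
from femurbench.model import AnatomicalFrame, FemurModel, LandmarkSet, box_mesh
from femurbench.outcomes import (
    OutcomeSeries,
    cortical_strain_paths,
    femoral_head_deflection,
    frame_to_series,
    interpolate_displacement,
    peak_von_mises,
    series_to_frame,
)
import scipy.sparse as sp


# ---------------------------------------------------------------------------
# R^2 and nRMSE


def test_r_squared_examples():
    ref = np.array([0.0, 1.0, 2.0, 3.0])
    assert r_squared(ref, ref) == pytest.approx(1.0)
    assert r_squared(ref + 1.0, ref) == pytest.approx(1.0 - 4.0 / 5.0)
    assert r_squared(np.full(4, ref.mean()), ref) == pytest.approx(0.0)
    assert np.isnan(r_squared(ref, np.full(4, 2.0)))


def test_nrmse_examples():
    ref = np.array([0.0, 1.0, 2.0, 3.0])
    assert nrmse(ref, ref) == 0.0
    assert nrmse(ref + 1.0, ref) == pytest.approx(1.0 / 3.0)
    assert np.isnan(nrmse(ref, np.zeros(4)))


def test_nrmse_scale_invariant(rng):
    ref = rng.standard_normal(7)
    ser = rng.standard_normal(7)
    assert nrmse(5.0 * ser, 5.0 * ref) == pytest.approx(nrmse(ser, ref))


# ---------------------------------------------------------------------------
# FHD


def test_fhd_invariant_to_rigid_translation(femur, solved):
    result, _ = solved["inertia_relief"]
    shifted = result.displacements + np.array([1.0, -2.0, 3.0])
    res2 = type(result)(
        displacements=shifted,
        element_strain=result.element_strain,
        element_stress=result.element_stress,
        von_mises=result.von_mises,
        principal_strains=result.principal_strains,
        reactions=result.reactions,
    )
    si0, ml0, ap0, r0 = femoral_head_deflection(
        result, femur.landmarks, femur.frame, femur
    )
    si1, ml1, ap1, r1 = femoral_head_deflection(
        res2, femur.landmarks, femur.frame, femur
    )
    assert np.allclose(si0, si1, atol=1e-9)
    assert np.allclose(r0, r1, atol=1e-9)


def test_fhd_arithmetic_example(femur):
    """u(head) = (0,0,-0.5), u(knee) = 0 -> SI component -0.5, resultant 0.5."""
    u = np.zeros((1, femur.n_nodes, 3))
    lm = femur.landmarks
    # pure SI displacement of every node in the head region
    head_region = np.linalg.norm(
        femur.node_coords - lm.head_center, axis=1
    ) <= femur.params.head_radius + 1e-9
    u[0, head_region] = -0.5 * femur.frame.si_axis
    fake = type("R", (), {"displacements": u, "n_instances": 1})()
    si, ml, ap, res = femoral_head_deflection(fake, lm, femur.frame, femur)
    assert si[0] == pytest.approx(-0.5, abs=1e-9)
    assert res[0] == pytest.approx(0.5, abs=1e-9)
    assert abs(ml[0]) < 1e-9 and abs(ap[0]) < 1e-9


def test_interpolation_matches_nodal_field(femur, rng):
    """Barycentric interpolation reproduces a linear field exactly."""
    A = rng.standard_normal((3, 3)) * 1e-3
    u = femur.node_coords @ A.T
    p = femur.landmarks.head_center
    assert np.allclose(interpolate_displacement(femur, u, p), A @ p, atol=1e-9)


def test_outcome_resultant_consistency(femur, solved):
    from femurbench.outcomes import compute_outcomes

    result, cset = solved["springs"]
    out = compute_outcomes(femur, result, cset)
    out.validate()
    assert np.all(out.pvms >= 0)


# ---------------------------------------------------------------------------
# PVMS


def test_pvms_uniform_state(femur):
    class R:
        von_mises = np.full((1, femur.n_elements), 10.0)
        n_instances = 1

    assert peak_von_mises(R(), femur, None, exclusion_radius=5.0)[0] == 10.0


def test_pvms_exclusion_only_matters_near_attachments(femur, solved):
    result, cset = solved["inertia_relief"]
    pv0 = peak_von_mises(result, femur, cset, exclusion_radius=0.0)
    pv5 = peak_von_mises(result, femur, cset, exclusion_radius=5.0)
    assert np.all(pv5 <= pv0 + 1e-12)


# ---------------------------------------------------------------------------
# strain paths on a bending-beam oracle


def _beam_model():
    """Box beam dressed as a minimal FemurModel with a top-surface path."""
    coords, tets = box_mesh(100.0, 10.0, 10.0, 40, 4, 4)  # grid hits y = 5
    top = np.where(
        (np.abs(coords[:, 2] - 10.0) < 1e-9) & (np.abs(coords[:, 1] - 5.0) < 1e-9)
    )[0]
    top = top[np.argsort(coords[top, 0])]
    lm = LandmarkSet(
        head_center=np.array([100.0, 5.0, 5.0]),
        knee_center=np.array([0.0, 5.0, 5.0]),
        lateral_epicondyle=np.array([0.0, 0.0, 5.0]),
        greater_trochanter_lateral=np.zeros(3),
        mid_diaphysis=np.zeros(3),
        neck_base=np.zeros(3),
        post_condyle_medial=np.zeros(3),
        post_condyle_lateral=np.zeros(3),
    )
    frame = AnatomicalFrame(
        si_axis=np.array([1.0, 0, 0]),
        ml_axis=np.array([0, 0, 1.0]),
        ap_axis=np.array([0, 1.0, 0]),
        origin=np.zeros(3),
    )
    model = FemurModel(
        node_coords=coords,
        tets=tets,
        element_gv=np.full(tets.shape[0], 2000.0),
        landmarks=lm,
        frame=frame,
        attachment_patches={},
        strain_paths={"top": top},
    )
    return model


def test_bending_beam_path_strain_matches_closed_form():
    """Tension-side path strain equals M c / (E I) within 10%."""
    model = _beam_model()
    E = 1.0e4
    table = MaterialTable(
        density=np.array([1.0]),
        youngs_modulus=np.array([E]),
        poisson=np.array([0.3]),
        element_bin=np.zeros(model.n_elements, int),
        gv_edges=np.array([[0.0, 1.0]]),
        supra_physiological=np.array([False]),
    )
    table.poisson[:] = 0.0
    system = assemble(model, table)
    coords = model.node_coords
    # pure end moments: +-F at z = 0 / 10 on both end faces (couple M = F * 10)
    f = np.zeros(system.n_dof)
    F = 50.0
    for x0, sign in ((100.0, 1.0), (0.0, -1.0)):
        topn = np.where(
            (np.abs(coords[:, 0] - x0) < 1e-9) & (coords[:, 2] > 10 - 1e-9)
        )[0]
        botn = np.where(
            (np.abs(coords[:, 0] - x0) < 1e-9) & (coords[:, 2] < 1e-9)
        )[0]
        f[3 * topn] += sign * F / topn.size
        f[3 * botn] -= sign * F / botn.size
    fixed = np.where(coords[:, 0] < 1e-9)[0]
    C = sp.lil_matrix((3 * fixed.size, system.n_dof))
    for i, nd in enumerate(fixed):
        for c in range(3):
            C[3 * i + c, 3 * nd + c] = 1.0
    res = solve_static(system, f, constraint_rows=C.tocsr())
    arc, absd, signed = cortical_strain_paths(model, res)
    M = F * 10.0
    I = 10.0 * 10.0**3 / 12.0
    # constant-strain elements sample the linear bending field at their
    # centroid depth z_bar (not the outer fibre c = 5); predict the closed
    # form at the centroid depth of the elements the path actually samples
    from femurbench.model import surface_faces

    surf_nodes = np.unique(surface_faces(model.tets))
    surf_elems = np.nonzero(
        np.isin(model.tets, surf_nodes).sum(axis=1) >= 3
    )[0]
    cent = model.node_coords[model.tets].mean(axis=1)[surf_elems]
    pts = model.node_coords[model.strain_paths["top"]]
    nearest = surf_elems[
        np.argmin(np.linalg.norm(pts[:, None] - cent[None], axis=2), axis=1)
    ]
    z_bar = model.node_coords[model.tets[nearest]].mean(axis=1)[:, 2] - 5.0
    expect = M * z_bar / (E * I) * 1e6
    mid = slice(10, 30)  # away from load/constraint ends
    vals = signed["top"][0, mid]
    assert np.all(vals > 0)  # tension side
    assert np.allclose(vals, expect[mid], rtol=0.10)


def test_zero_load_zero_path_strain(femur, system):
    res = recover_fields(system, np.zeros((1, femur.n_nodes, 3)))
    _, absd, signed = cortical_strain_paths(femur, res)
    for arr in absd.values():
        assert np.abs(arr).max() == 0.0


# ---------------------------------------------------------------------------
# comparison report


def test_compare_report_completeness(benchmark):
    tab = benchmark.comparison.table
    assert set(tab.geometry) == {"normal", "ava45", "ava-10", "nsa115", "nsa150"}
    assert set(tab.method) == {
        "fixed_knee",
        "springs",
        "isostatic",
        "mid_shaft",
        "biomechanical",
    }
    # 5 geometries x 5 non-reference methods x 5 metrics
    assert tab.shape[0] == 5 * 5 * 5
    assert np.all(tab.nrmse >= 0)
    assert np.all(tab.r_squared <= 1.0 + 1e-12)


def test_reference_vs_itself_is_perfect(benchmark):
    out = benchmark.outcomes[("normal", "inertia_relief")]
    assert r_squared(out.pvms, out.pvms) == pytest.approx(1.0)
    assert nrmse(out.pvms, out.pvms) == 0.0


def test_series_frame_roundtrip(benchmark):
    out = benchmark.outcomes[("normal", "springs")]
    back = frame_to_series(series_to_frame(out))
    assert np.allclose(back.pvms, out.pvms)
    assert np.allclose(back.fhd_resultant, out.fhd_resultant)


def test_benchmark_bookkeeping(benchmark):
    """5 geometries x 6 methods x 7 instances all solved and recorded."""
    assert len(benchmark.outcomes) == 30
    for (geom, method), series in benchmark.outcomes.items():
        assert series.pvms.shape == (7,)
        assert series.fhd_resultant.shape == (7,)
    assert len(benchmark.models) == 5
    assert len(benchmark.cases) == 5
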