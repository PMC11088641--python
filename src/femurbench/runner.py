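"""High-level orchestration: single-method solves and the full benchmark.

The benchmark pipeline mirrors the study design: generate the synthetic
femur, warp it to the pathological geometries (severe ante/retroversion,
coxa vara/valga), build the stance-load fixture per geometry, solve the
seven quasi-static instances under each boundary-condition method, compute
outcomes, and compare every constrained method with inertia relief.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from femurbench.constraints import (
    ConstraintSet,
    METHOD_NAMES,
    assemble_constraint_rows,
    build_constraints,
)
from femurbench.deformity import DeformitySpec, apply_anteversion, apply_neck_shaft
from femurbench.fe import (
    FEResult,
    assemble,
    solve_inertia_relief,
    solve_static,
)
from femurbench.loads import (
    GaitFixtureParams,
    LoadCase,
    assemble_load_vectors,
    generate_stance_loads,
)
from femurbench.materials import MaterialTable, bin_materials
from femurbench.model import FemurModel, FemurParams, generate_femur
from femurbench.outcomes import compare_report, compute_outcomes

__all__ = [
    "BenchmarkResult",
    "DEFAULT_GEOMETRIES",
    "make_geometry",
    "material_bin_sensitivity",
    "mesh_convergence",
    "run_benchmark",
    "solve_method",
    "spring_reaction_share",
]

# geometry name -> (warp kind, target degrees); the normal femur is unwarped
DEFAULT_GEOMETRIES = {
    "normal": None,
    "ava45": ("ava", 45.0),
    "ava-10": ("ava", -10.0),
    "nsa115": ("nsa", 115.0),
    "nsa150": ("nsa", 150.0),
}


def make_geometry(
    base: FemurModel, name: str, n_increments: int = 20
) -> FemurModel:
    """Produce one of the study geometries from the base (normal) femur."""
    spec = DEFAULT_GEOMETRIES[name]
    if spec is None:
        return base
    kind, target = spec
    if kind == "ava":
        warped, report = apply_anteversion(
            base, DeformitySpec(target_ava_deg=target, n_increments=n_increments)
        )
    else:
        warped, report = apply_neck_shaft(
            base, DeformitySpec(target_nsa_deg=target, n_increments=n_increments)
        )
    if report.n_inverted_elements:
        raise RuntimeError(f"warp to {name} inverted elements")
    return warped


def solve_method(
    model: FemurModel,
    materials: MaterialTable,
    case: LoadCase,
    method: str,
    method_options: dict | None = None,
    system=None,
) -> tuple[FEResult, ConstraintSet]:
    """Solve all load instances of one boundary-condition method."""
    if system is None:
        system = assemble(model, materials)
    cset = build_constraints(model, method, **(method_options or {}))
    loads = assemble_load_vectors(model, case, cset.load_rules, cset.n_extra_dof)
    if cset.use_inertia_relief:
        result = solve_inertia_relief(system, loads)
    else:
        C, spring_diag, n_extra, labels = assemble_constraint_rows(cset, model)
        result = solve_static(
            system,
            loads,
            constraint_rows=C if C.shape[0] else None,
            spring_diagonal=spring_diag,
            n_extra_dof=n_extra,
            labels=labels,
        )
    return result, cset


def spring_reaction_share(model, cset, result, case) -> dict:
    """Artificial-reaction share of the springs method.

    The grounding of the load residual is inherent to the method; what must
    stay small to avoid stress concentrations is the *deformation-driven*
    part of the spring forces.  Per instance the best-fit rigid motion of
    the spring nodes is subtracted; the share is the summed magnitude of
    the remaining spring forces over the summed magnitude of all applied
    muscle and contact forces.  Returns max/mean shares plus the total
    (drift-included) share for reference.
    """
    nodes = np.unique(np.concatenate([n for n, _ in cset.springs]))
    k_node = np.zeros(model.n_nodes)
    for n, k in cset.springs:
        k_node[np.asarray(n, int)] += k
    r = model.node_coords[nodes] - model.node_coords[nodes].mean(axis=0)
    A = np.zeros((3 * nodes.size, 6))
    for c in range(3):
        A[c::3, c] = 1.0
    A[:, 3:] = np.cross(
        np.repeat(np.eye(3)[None], nodes.size, axis=0).reshape(-1, 3),
        np.repeat(r, 3, axis=0),
    )
    applied = sum(
        np.linalg.norm(arr, axis=1) for arr in case.forces.values()
    ) + sum(np.linalg.norm(arr, axis=1) for arr in case.contact.values())
    shares, total_shares = [], []
    for i in range(result.n_instances):
        u = result.displacements[i][nodes]
        sol, *_ = np.linalg.lstsq(A, u.ravel(), rcond=None)
        u_def = u - (A @ sol).reshape(-1, 3)
        f_def = k_node[nodes][:, None] * u_def
        f_tot = k_node[nodes][:, None] * u
        shares.append(np.linalg.norm(f_def, axis=1).sum() / applied[i])
        total_shares.append(np.linalg.norm(f_tot, axis=1).sum() / applied[i])
    return {
        "max_share": float(np.max(shares)),
        "mean_share": float(np.mean(shares)),
        "max_total_share": float(np.max(total_shares)),
    }


def material_bin_sensitivity(
    model: FemurModel,
    case: LoadCase,
    method: str = "inertia_relief",
    bin_counts=(1, 2, 5, 10, 20),
):
    """Peak von Mises stress as a function of the number of material sets."""
    import pandas as pd

    rows = []
    for nb in bin_counts:
        table = bin_materials(model, n_bins=nb)
        result, cset = solve_method(model, table, case, method)
        pv = compute_outcomes(model, result, cset).pvms
        rows.append(
            {"n_bins": nb, "n_populated": table.n_bins, "pvms_max": float(pv.max())}
        )
    return pd.DataFrame(rows)


def mesh_convergence(
    edge_lengths=(10.0, 8.0, 6.0),
    method: str = "inertia_relief",
    femur_params: FemurParams | None = None,
    gait_params: GaitFixtureParams | None = None,
):
    """PVMS / FHD convergence under mesh refinement (edge length in mm)."""
    import pandas as pd

    base = femur_params or FemurParams()
    rows = []
    for h in sorted(edge_lengths, reverse=True):
        params = dataclasses.replace(base, target_edge_length=float(h))
        model = generate_femur(params)
        table = bin_materials(model)
        case = generate_stance_loads(model, gait_params)
        result, cset = solve_method(model, table, case, method)
        out = compute_outcomes(model, result, cset)
        rows.append(
            {
                "edge_length": h,
                "n_elements": model.n_elements,
                "pvms_max": float(out.pvms.max()),
                "fhd_resultant_max": float(out.fhd_resultant.max()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class BenchmarkResult:
    """Everything the benchmark produced, keyed by (geometry, method)."""

    models: dict  # geometry -> FemurModel
    cases: dict  # geometry -> LoadCase
    outcomes: dict  # (geometry, method) -> OutcomeSeries
    comparison: object  # ComparisonReport
    constraint_sets: dict = field(default_factory=dict)


def run_benchmark(
    femur_params: FemurParams | None = None,
    gait_params: GaitFixtureParams | None = None,
    geometries=tuple(DEFAULT_GEOMETRIES),
    methods=METHOD_NAMES,
    n_bins: int = 10,
    exclusion_radius: float = 5.0,
    method_options: dict | None = None,
    progress=None,
) -> BenchmarkResult:
    """Run the geometry x method benchmark and compare against inertia relief."""
    base = generate_femur(femur_params or FemurParams())
    models, cases, outcomes, csets = {}, {}, {}, {}
    for geometry in geometries:
        model = make_geometry(base, geometry)
        models[geometry] = model
        table = bin_materials(model, n_bins=n_bins)
        case = generate_stance_loads(model, gait_params)
        cases[geometry] = case
        system = assemble(model, table)
        # artefact-exclusion guard built from every method's constraints so
        # the excluded region is identical for all compared methods
        guard = [
            build_constraints(model, m, **((method_options or {}).get(m) or {}))
            for m in methods
        ]
        for method in methods:
            if progress:
                progress(f"{geometry}/{method}")
            opts = (method_options or {}).get(method)
            result, cset = solve_method(
                model, table, case, method, method_options=opts, system=system
            )
            outcomes[(geometry, method)] = compute_outcomes(
                model, result, guard, exclusion_radius
            )
            csets[(geometry, method)] = cset
    report = compare_report(outcomes)
    return BenchmarkResult(
        models=models,
        cases=cases,
        outcomes=outcomes,
        comparison=report,
        constraint_sets=csets,
    )
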