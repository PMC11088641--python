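"""Stance-phase gait load fixture and load-case I/O.

The fixture emulates the *outputs* of a neuromusculoskeletal (EMG-informed)
pipeline: per-instance muscle forces at named attachment patches and three
joint contact forces (hip, tibiofemoral, patellofemoral), expressed in the
local anatomical femur frame, at seven equally spaced instances of the
stance phase.  Magnitudes are physiologically scaled: the hip contact force
follows a bimodal stance waveform peaking at ``hip_peak_bw`` body weights
(default 2.4, consistent with instrumented-hip gait data), muscles follow
Gaussian activation bumps with peaks of 0.4-1.8 body weights, and the
tibiofemoral force balances most (default 95 %) of the remaining net force,
leaving a small inertial residual -- so the load system is deliberately not
self-equilibrated, which is exactly what inertia relief absorbs.

Local force components are ordered (SI, ML, AP): superior(+)/inferior(-),
lateral(+)/medial(-), anterior(+)/posterior(-).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from femurbench.model import AnatomicalFrame, FemurModel

__all__ = [
    "GRAVITY",
    "GaitFixtureParams",
    "LoadCase",
    "MuscleSpec",
    "assemble_load_vectors",
    "generate_stance_loads",
    "read_loadcase",
    "transform_from_frame",
    "transform_to_frame",
    "write_loadcase",
]

GRAVITY = 9.81  # m/s^2

CONTACT_NAMES = ("hip", "tibiofemoral", "patellofemoral")
CONTACT_PATCHES = {
    "hip": "hip_contact",
    "tibiofemoral": "tf_contact",
    "patellofemoral": "pf_contact",
}


@dataclass
class MuscleSpec:
    """One muscle group: peak force, activation timing, pull direction.

    ``direction`` is the (SI, ML, AP) unit line of action of the force the
    muscle exerts on its femoral attachment (a straight-line approximation
    from the attachment towards the muscle's other end).  ``centers`` /
    ``widths`` parameterise Gaussian activation bumps over stance fraction.
    """

    peak_bw: float
    centers: tuple
    widths: tuple
    direction: tuple  # (si, ml, ap) components


def _default_muscles() -> dict[str, MuscleSpec]:
    # directions: attachment -> origin/insertion straight lines, femur frame
    return {
        "gluteus_medius": MuscleSpec(1.5, (0.25, 0.75), (0.2, 0.2), (0.99, -0.15, 0.04)),
        "gluteus_maximus": MuscleSpec(0.8, (0.30,), (0.25,), (0.90, -0.18, -0.40)),
        "iliopsoas": MuscleSpec(0.8, (0.80,), (0.16,), (0.88, -0.18, 0.44)),
        "vasti": MuscleSpec(1.8, (0.20,), (0.18,), (-0.94, 0.0, 0.34)),
        "adductors": MuscleSpec(0.5, (0.45,), (0.30,), (0.90, -0.40, 0.15)),
        "biceps_femoris_short": MuscleSpec(0.45, (0.55,), (0.30,), (-0.85, 0.30, -0.43)),
        "gastroc_medial": MuscleSpec(1.6, (0.80,), (0.15,), (-0.96, 0.0, -0.29)),
        "gastroc_lateral": MuscleSpec(1.0, (0.80,), (0.15,), (-0.96, 0.0, -0.29)),
    }


@dataclass
class GaitFixtureParams:
    """Configuration of the stance-load fixture."""

    body_mass: float = 93.4  # kg
    hip_peak_bw: float = 2.4  # hip contact peak, body weights
    muscle_gain: float = 1.0
    balance_factor: float = 0.85  # share of the net wrench closed by the
    # joint contact forces; the ~15 % residual emulates segment dynamics and
    # model error in sequentially linked NMSK outputs -- the residual that
    # inertia relief is designed to neutralise
    pf_peak_bw: float = 0.9
    n_instances: int = 7
    rng_seed: int = 0
    muscles: dict = field(default_factory=_default_muscles)

    def validate(self) -> None:
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")
        if not 1.0 <= self.hip_peak_bw <= 6.0:
            raise ValueError("hip_peak_bw outside [1, 6] body weights")
        if self.n_instances != 7:
            raise ValueError("the stance fixture uses seven instances")

    @property
    def body_weight(self) -> float:
        return self.body_mass * GRAVITY  # N


@dataclass
class LoadCase:
    """Per-instance force system in the local femur frame (SI, ML, AP), N."""

    instances: np.ndarray  # (7,) stance fractions, strictly increasing
    forces: dict  # attachment name -> (7, 3)
    contact: dict  # 'hip' | 'tibiofemoral' | 'patellofemoral' -> (7, 3)
    body_weight: float
    contact_offsets: dict = field(default_factory=dict)  # name -> (7, 3) mm,
    # local application-point offset from the contact reference point
    # (centre-of-pressure migration)

    @property
    def n_instances(self) -> int:
        return self.instances.shape[0]

    def validate(self, model: FemurModel | None = None) -> None:
        t = self.instances
        if t.shape[0] != 7:
            raise ValueError("a load case has exactly 7 stance instances")
        dt = np.diff(t)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            raise ValueError("instances must be strictly increasing, equally spaced")
        for name, arr in {**self.forces, **self.contact}.items():
            if arr.shape != (7, 3) or not np.all(np.isfinite(arr)):
                raise ValueError(f"force table for {name!r} malformed or non-finite")
        for c in CONTACT_NAMES:
            if c not in self.contact:
                raise ValueError(f"missing contact force {c!r}")
        for name, arr in self.contact_offsets.items():
            if name not in self.contact:
                raise ValueError(f"offset for unknown contact {name!r}")
            if arr.shape != (7, 3) or not np.all(np.isfinite(arr)):
                raise ValueError(f"offset table for {name!r} malformed")
        if model is not None:
            for name in self.forces:
                if name not in model.attachment_patches:
                    raise ValueError(f"model has no attachment patch {name!r}")


def _bump(t: np.ndarray, centers, widths) -> np.ndarray:
    w = np.zeros_like(t)
    for c, s in zip(centers, widths):
        w += np.exp(-(((t - c) / s) ** 2))
    peak = w.max()
    return w / peak if peak > 0 else w


def generate_stance_loads(
    model: FemurModel, params: GaitFixtureParams | None = None
) -> LoadCase:
    """Deterministic stance-phase load fixture bound to the model's patches."""
    p = params or GaitFixtureParams()
    p.validate()
    rng = np.random.default_rng(p.rng_seed)
    for name in list(p.muscles) + list(CONTACT_PATCHES.values()):
        key = CONTACT_PATCHES.get(name, name)
        if key not in model.attachment_patches:
            raise ValueError(f"model is missing attachment patch {key!r}")
    t = np.linspace(0.0, 1.0, p.n_instances)
    bw = p.body_weight

    forces: dict[str, np.ndarray] = {}
    for name, spec in p.muscles.items():
        mag = p.muscle_gain * spec.peak_bw * bw * _bump(t, spec.centers, spec.widths)
        # small seeded activation variability, as EMG-informed outputs carry
        mag = mag * np.clip(1.0 + 0.02 * rng.standard_normal(t.shape), 0.5, 1.5)
        d = np.asarray(spec.direction, float)
        d = d / np.linalg.norm(d)
        forces[name] = mag[:, None] * d[None, :]

    # patellofemoral contact: the patella redirects the quadriceps tendon,
    # so its compression into the trochlear groove tracks the vasti force
    pf_mag = p.pf_peak_bw * bw * _bump(t, (0.20,), (0.18,))
    pf_dir = np.array([0.43, 0.0, -0.90])
    pf = pf_mag[:, None] * (pf_dir / np.linalg.norm(pf_dir))[None, :]

    # the joint contact forces are reactions: the hip contact force closes
    # the moment balance about the knee (its magnitude is the prescribed
    # bimodal waveform, its direction emerges from equilibrium, as in an
    # inverse-dynamics pipeline), the tibiofemoral force closes the net
    # force, and tibiofemoral centre-of-pressure migration mops up the
    # remaining moment; a ~2 % inertial residual is left open
    # bimodal with a shallow mid-stance trough (single support keeps the hip
    # loaded) and tapered double-support edges
    hip_shape = _bump(t, (0.25,), (0.26,)) + 0.92 * _bump(t, (0.75,), (0.26,))
    hip_shape = hip_shape * (0.55 + 0.45 * np.sin(np.pi * t))
    hip_mag = p.hip_peak_bw * bw * hip_shape / hip_shape.max()
    hip = _equilibrium_hip_force(model, forces, pf, hip_mag, p.balance_factor)
    net = hip + pf + sum(forces.values())
    tf = -p.balance_factor * net
    tf_offset, hip_offset = _balance_cop(model, forces, hip, pf, tf, p.balance_factor)
    contact = {"hip": hip, "tibiofemoral": tf, "patellofemoral": pf}
    case = LoadCase(
        instances=t,
        forces=forces,
        contact=contact,
        body_weight=bw,
        contact_offsets={"tibiofemoral": tf_offset, "hip": hip_offset},
    )
    case.validate(model)
    return case


_COP_EXCURSION_MM = 25.0  # bound on tibiofemoral centre-of-pressure travel


def _equilibrium_hip_force(model, forces, pf, hip_mag, closure=1.0):
    """Hip contact force closing the moment balance about the knee.

    With all muscle and patellofemoral moments about the knee summed to M,
    the transverse (to the head-knee lever) part of the hip force is fixed
    by r x F = -closure * M; the component along the lever is chosen so the
    resultant magnitude matches the prescribed waveform, pointing distally
    (compression into the head).  ``closure`` < 1 leaves part of the moment
    unbalanced, emulating the residual of a sequentially linked pipeline.
    Returns (k, 3) local components.
    """
    knee = model.landmarks.knee_center
    frame = model.frame
    r = model.attachment_patches["hip_contact"].refpoint - knee
    arm_pf = model.attachment_patches["pf_contact"].refpoint - knee
    arms = {
        name: model.attachment_patches[name].refpoint - knee for name in forces
    }
    k = pf.shape[0]
    hip = np.zeros((k, 3))
    r2 = r @ r
    r_hat = r / np.sqrt(r2)
    for i in range(k):
        M = np.cross(arm_pf, transform_from_frame(pf[i], frame))
        for name, f in forces.items():
            M += np.cross(arms[name], transform_from_frame(f[i], frame))
        F0 = np.cross(-closure * M, r) / r2  # r x F0 = -closure * M_perp
        mag = hip_mag[i]
        f0n = np.linalg.norm(F0)
        if f0n >= mag:  # waveform floor cannot close the moment; scale down
            F = F0 * (mag / max(f0n, 1e-30))
        else:
            F = F0 - np.sqrt(mag**2 - f0n**2) * r_hat  # distal axial part
        hip[i] = transform_to_frame(F, frame)
    return hip


_HIP_COP_EXCURSION_MM = 10.0  # acetabular contact-patch migration bound


def _balance_cop(model, forces, hip, pf, tf, balance_factor):
    """Contact centre-of-pressure offsets closing the residual knee moment.

    Least-squares offsets of the tibiofemoral contact point in the
    transverse plane (plateau excursion bound) and of the hip contact point
    on the head (acetabular patch migration bound, directions transverse to
    the hip force) cancel ``balance_factor`` of the axial torque about the
    head-knee axis -- the one moment component the hip-force direction
    cannot close.  Returns (tf_offsets, hip_offsets), local (SI, ML, AP).
    """
    knee = model.landmarks.knee_center
    frame = model.frame
    arms = {
        name: model.attachment_patches[name].refpoint - knee for name in forces
    }
    arm_hip = model.attachment_patches["hip_contact"].refpoint - knee
    arm_pf = model.attachment_patches["pf_contact"].refpoint - knee
    k = hip.shape[0]
    tf_off = np.zeros((k, 3))
    hip_off = np.zeros((k, 3))
    Q = frame.matrix()
    lever = arm_hip / np.linalg.norm(arm_hip)  # head-knee axis
    for i in range(k):
        m_net = np.cross(arm_hip, transform_from_frame(hip[i], frame))
        m_net += np.cross(arm_pf, transform_from_frame(pf[i], frame))
        for name, f in forces.items():
            m_net += np.cross(arms[name], transform_from_frame(f[i], frame))
        F_tf = transform_from_frame(tf[i], frame)
        F_hip = transform_from_frame(hip[i], frame)
        cols = [np.cross(frame.ml_axis, F_tf), np.cross(frame.ap_axis, F_tf)]
        nh = np.linalg.norm(F_hip)
        if nh > 1e-9:  # offset directions transverse to the hip force
            e1 = np.cross(F_hip / nh, frame.si_axis)
            if np.linalg.norm(e1) < 1e-6:
                e1 = np.cross(F_hip / nh, frame.ml_axis)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(F_hip / nh, e1)
            cols += [np.cross(e1, F_hip), np.cross(e2, F_hip)]
        else:
            e1 = e2 = np.zeros(3)
            cols += [np.zeros(3), np.zeros(3)]
        A = np.stack(cols, axis=1)
        m_axial = (m_net @ lever) * lever
        x, *_ = np.linalg.lstsq(A, -balance_factor * m_axial, rcond=None)
        x[:2] = np.clip(x[:2], -_COP_EXCURSION_MM, _COP_EXCURSION_MM)
        x[2:] = np.clip(x[2:], -_HIP_COP_EXCURSION_MM, _HIP_COP_EXCURSION_MM)
        tf_off[i] = np.array([0.0, x[0], x[1]])
        hip_off[i] = Q @ (x[2] * e1 + x[3] * e2)
    return tf_off, hip_off


# ---------------------------------------------------------------------------
# frame transforms


def _check_frame(frame: AnatomicalFrame) -> np.ndarray:
    Q = frame.matrix()
    if not np.allclose(Q @ Q.T, np.eye(3), atol=1e-9):
        raise ValueError("frame axes are not orthonormal")
    return Q


def transform_to_frame(vectors: np.ndarray, frame: AnatomicalFrame) -> np.ndarray:
    """Global (x, y, z) vectors -> local (SI, ML, AP) components."""
    Q = _check_frame(frame)
    return np.asarray(vectors, float) @ Q.T


def transform_from_frame(vectors: np.ndarray, frame: AnatomicalFrame) -> np.ndarray:
    """Local (SI, ML, AP) components -> global (x, y, z) vectors."""
    Q = _check_frame(frame)
    return np.asarray(vectors, float) @ Q


# ---------------------------------------------------------------------------
# load-vector assembly


def assemble_load_vectors(
    model: FemurModel,
    case: LoadCase,
    load_rules=frozenset(CONTACT_NAMES),
    n_extra_dof: int = 0,
) -> np.ndarray:
    """Nodal load vectors (k, 3N + n_extra) from a load case.

    Every force is applied at its attachment reference point and spread over
    the patch with the moment-consistent distribution; contact forces not in
    ``load_rules`` are omitted (e.g. the fixed-knee method neglects
    tibiofemoral and patellofemoral contact).
    """
    from femurbench.fe import distribute_force  # local import, no cycle

    case.validate(model)
    k = case.n_instances
    n = 3 * model.node_coords.shape[0]
    f = np.zeros((k, n + n_extra_dof))
    entries = [(name, arr, None) for name, arr in case.forces.items()]
    for cname, arr in case.contact.items():
        if cname in load_rules:
            entries.append(
                (CONTACT_PATCHES[cname], arr, case.contact_offsets.get(cname))
            )
    for patch_name, arr, offsets in entries:
        patch = model.attachment_patches[patch_name]
        glob = transform_from_frame(arr, model.frame)
        off = (
            transform_from_frame(offsets, model.frame)
            if offsets is not None
            else np.zeros((k, 3))
        )
        for i in range(k):
            if not np.any(glob[i]):
                continue
            nodal = distribute_force(
                model.node_coords, patch.nodes, patch.refpoint + off[i], glob[i]
            )
            idx = (3 * patch.nodes[:, None] + np.arange(3)[None, :]).ravel()
            np.add.at(f[i], idx, nodal.ravel())
    return f


# ---------------------------------------------------------------------------
# CSV / JSON round-trip

_COLUMNS = [
    "instance",
    "stance_fraction",
    "target",
    "kind",
    "f_si",
    "f_ml",
    "f_ap",
    "body_weight",
]


def write_loadcase(case: LoadCase, path) -> None:
    """Write a load case as CSV (or JSON if the path ends in .json)."""
    path = str(path)
    rows = []
    for name, arr in sorted(case.forces.items()):
        for i in range(case.n_instances):
            rows.append(
                (i, case.instances[i], name, "muscle", *arr[i], case.body_weight)
            )
    for name, arr in sorted(case.contact.items()):
        for i in range(case.n_instances):
            rows.append(
                (i, case.instances[i], name, "contact", *arr[i], case.body_weight)
            )
    for name, arr in sorted(case.contact_offsets.items()):
        for i in range(case.n_instances):
            rows.append(
                (i, case.instances[i], name, "cop_offset", *arr[i], case.body_weight)
            )
    df = pd.DataFrame(rows, columns=_COLUMNS)
    if path.endswith(".json"):
        df.to_json(path, orient="records", double_precision=15)
    else:
        df.to_csv(path, index=False, float_format="%.17g")


def read_loadcase(path) -> LoadCase:
    """Read a load case written by :func:`write_loadcase`; validates schema."""
    path = str(path)
    df = pd.read_json(path) if path.endswith(".json") else pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"load-case file missing columns: {missing}")
    forces, contact, offsets = {}, {}, {}
    instances = None
    for (name, kind), grp in df.groupby(["target", "kind"]):
        grp = grp.sort_values("instance")
        got = grp["instance"].to_numpy()
        expected = np.arange(7)
        if not np.array_equal(got, expected):
            gaps = sorted(int(v) for v in set(expected) - set(got))
            raise ValueError(
                f"target {name!r} missing instance rows {gaps}"
            )
        arr = grp[["f_si", "f_ml", "f_ap"]].to_numpy(float)
        if kind == "contact":
            contact[name] = arr
        elif kind == "cop_offset":
            offsets[name] = arr
        else:
            forces[name] = arr
        instances = grp["stance_fraction"].to_numpy(float)
    if instances is None:
        raise ValueError("empty load-case file")
    case = LoadCase(
        instances=instances,
        forces=forces,
        contact=contact,
        body_weight=float(df["body_weight"].iloc[0]),
        contact_offsets=offsets,
    )
    case.validate()
    return case
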