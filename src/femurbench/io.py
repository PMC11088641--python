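"""Model persistence: Abaqus-INP subset and ASCII VTU.

The INP subset covers ``*NODE``, ``*ELEMENT, TYPE=C3D4``, ``*ELSET``
(material bins), and named ``*NSET`` blocks for landmarks (``LM_<name>``,
single node), attachment patches (``PATCH_<name>``), key surface sets
(``SET_<name>``) and ordered strain paths (``PATH_<name>, UNSORTED``).
Per-element greyscale values are stored in ``**GV eid value`` comment lines
and patch reference points in ``** REFPOINT`` comments, so a write/read
round-trip is exact while the file stays loadable by standard FE tools
(which simply ignore comments).

The VTU writer/reader uses the ASCII XML UnstructuredGrid format with the
greyscale as cell data, landmarks and ordered paths as FieldData arrays,
and node sets as point-data masks; arbitrary result fields can be attached
as point/cell data for visualisation.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from femurbench.model import (
    AttachmentPatch,
    FemurModel,
    LandmarkSet,
    build_frame,
    tet_volumes,
)

__all__ = ["ParseError", "read_model", "write_model", "write_vtu", "read_vtu"]

_LANDMARK_NAMES = [
    "head_center",
    "knee_center",
    "lateral_epicondyle",
    "greater_trochanter_lateral",
    "mid_diaphysis",
    "neck_base",
    "post_condyle_medial",
    "post_condyle_lateral",
]
_SET_NAMES = ["head_surface_patch", "condylar_patch", "gt_patch"]


class ParseError(ValueError):
    """Malformed model file; the message names the offending line."""


def write_model(model: FemurModel, path, format: str | None = None) -> None:
    """Write a femur model as Abaqus-INP subset or VTU (by suffix)."""
    fmt = format or Path(path).suffix.lstrip(".").lower()
    if fmt == "inp":
        _write_inp(model, path)
    elif fmt in ("vtu", "vtk"):
        write_vtu(model, path)
    else:
        raise ValueError(f"unsupported model format {fmt!r}")


def read_model(path, format: str | None = None) -> FemurModel:
    """Read a femur model written by :func:`write_model`."""
    fmt = format or Path(path).suffix.lstrip(".").lower()
    if fmt == "inp":
        return _read_inp(path)
    if fmt in ("vtu", "vtk"):
        return read_vtu(path)
    raise ValueError(f"unsupported model format {fmt!r}")


# ---------------------------------------------------------------------------
# INP


def _write_ids(fh, ids, per_line=12):
    ids = np.asarray(ids, int) + 1  # 1-based
    for i in range(0, ids.size, per_line):
        fh.write(", ".join(str(v) for v in ids[i : i + per_line]) + "\n")


def _write_inp(model: FemurModel, path) -> None:
    lm = model.landmarks
    with open(path, "w") as fh:
        fh.write("*HEADING\nfemurbench synthetic femur model\n")
        fh.write("*NODE\n")
        for i, (x, y, z) in enumerate(model.node_coords, start=1):
            fh.write(f"{i}, {float(x)!r}, {float(y)!r}, {float(z)!r}\n")
        fh.write("*ELEMENT, TYPE=C3D4\n")
        for i, t in enumerate(model.tets, start=1):
            fh.write(f"{i}, {t[0] + 1}, {t[1] + 1}, {t[2] + 1}, {t[3] + 1}\n")
        for name in _LANDMARK_NAMES:
            nid = lm.node_ids.get(name)
            if nid is None:
                continue
            fh.write(f"*NSET, NSET=LM_{name.upper()}\n{int(nid) + 1}\n")
        for name in _SET_NAMES:
            fh.write(f"*NSET, NSET=SET_{name.upper()}\n")
            _write_ids(fh, getattr(lm, name))
        for name, patch in sorted(model.attachment_patches.items()):
            fh.write(f"*NSET, NSET=PATCH_{name.upper()}\n")
            _write_ids(fh, patch.nodes)
            rp = patch.refpoint
            fh.write(
                f"** REFPOINT PATCH_{name.upper()} {float(rp[0])!r} {float(rp[1])!r} {float(rp[2])!r}\n"
            )
        for name, nodes in sorted(model.strain_paths.items()):
            fh.write(f"*NSET, NSET=PATH_{name.upper()}, UNSORTED\n")
            _write_ids(fh, nodes)
        # material-bin element sets (10 equal-width greyscale bins)
        gv = model.element_gv
        edges = np.linspace(gv.min(), gv.max() + 1e-9, 11)
        bins = np.clip(np.searchsorted(edges, gv, side="right") - 1, 0, 9)
        for b in range(10):
            ids = np.nonzero(bins == b)[0]
            if ids.size:
                fh.write(f"*ELSET, ELSET=MAT_{b + 1}\n")
                _write_ids(fh, ids)
        fh.write("** per-element greyscale values\n")
        for i, v in enumerate(gv, start=1):
            fh.write(f"**GV {i} {float(v)!r}\n")


def _read_inp(path) -> FemurModel:
    nodes: dict[int, list[float]] = {}
    elements: dict[int, list[int]] = {}
    nsets: dict[str, list[int]] = {}
    refpoints: dict[str, np.ndarray] = {}
    gv_map: dict[int, float] = {}
    section = None
    current_set = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("**"):
                parts = line.split()
                if parts[0] == "**GV":
                    gv_map[int(parts[1])] = float(parts[2])
                elif len(parts) >= 6 and parts[1] == "REFPOINT":
                    refpoints[parts[2]] = np.array(
                        [float(parts[3]), float(parts[4]), float(parts[5])]
                    )
                continue
            if line.startswith("*"):
                key = line.split(",")[0].strip().upper()
                opts = {
                    kv.split("=")[0].strip().upper(): kv.split("=")[1].strip()
                    for kv in line.split(",")[1:]
                    if "=" in kv
                }
                if key == "*NODE":
                    section = "node"
                elif key == "*ELEMENT":
                    etype = opts.get("TYPE", "").upper()
                    if etype != "C3D4":
                        raise ParseError(
                            f"line {lineno}: unsupported element type "
                            f"{etype or '<missing>'}; only C3D4 is supported"
                        )
                    section = "element"
                elif key in ("*NSET", "*ELSET"):
                    section = key[1:].lower()
                    name = opts.get("NSET") or opts.get("ELSET")
                    if not name:
                        raise ParseError(f"line {lineno}: {key} without a name")
                    current_set = name.upper()
                    nsets.setdefault(current_set, [])
                else:
                    section = None  # *HEADING etc.: skip data lines
                continue
            fields = [f for f in line.replace(",", " ").split() if f]
            try:
                if section == "node":
                    nodes[int(fields[0])] = [float(v) for v in fields[1:4]]
                elif section == "element":
                    elements[int(fields[0])] = [int(v) for v in fields[1:5]]
                elif section in ("nset",):
                    nsets[current_set].extend(int(v) for v in fields)
                elif section == "elset":
                    pass  # material bins are re-derived from the GV field
            except (ValueError, IndexError) as exc:
                raise ParseError(f"line {lineno}: cannot parse {line!r}") from exc
    if not nodes or not elements:
        raise ParseError("file contains no nodes or no elements")
    order = sorted(nodes)
    remap = {nid: i for i, nid in enumerate(order)}
    coords = np.array([nodes[n] for n in order])
    eorder = sorted(elements)
    tets = np.array([[remap[n] for n in elements[e]] for e in eorder])
    if np.any(tet_volumes(coords, tets) <= 0):
        raise ParseError("mesh contains non-positively oriented tetrahedra")
    gv = np.array([gv_map.get(e, 0.0) for e in eorder])

    def node_set(name):
        key = name.upper()
        if key not in nsets:
            raise ParseError(f"missing required node set {key}")
        return np.array([remap[n] for n in nsets[key]], int)

    node_ids = {}
    lm_kwargs = {}
    for name in _LANDMARK_NAMES:
        ids = node_set(f"LM_{name}")
        node_ids[name] = int(ids[0])
        lm_kwargs[name] = coords[ids[0]].copy()
    for name in _SET_NAMES:
        lm_kwargs[name] = node_set(f"SET_{name}")
    landmarks = LandmarkSet(node_ids=node_ids, **lm_kwargs)
    patches = {}
    for key in nsets:
        if key.startswith("PATCH_"):
            name = key[len("PATCH_") :].lower()
            ids = node_set(key)
            rp = refpoints.get(key, coords[ids].mean(axis=0))
            patches[name] = AttachmentPatch(refpoint=rp, nodes=ids)
    paths = {
        key[len("PATH_") :].lower(): node_set(key)
        for key in nsets
        if key.startswith("PATH_")
    }
    return FemurModel(
        node_coords=coords,
        tets=tets,
        element_gv=gv,
        landmarks=landmarks,
        frame=build_frame(landmarks),
        attachment_patches=patches,
        strain_paths=paths,
    )


# ---------------------------------------------------------------------------
# VTU


def _ascii(a, fmt=None):
    a = np.asarray(a)
    if fmt == "{:d}":
        return " ".join(str(int(v)) for v in a.ravel())
    return " ".join(repr(float(v)) for v in a.ravel())


def write_vtu(
    model: FemurModel,
    path,
    point_data: dict | None = None,
    cell_data: dict | None = None,
) -> None:
    """ASCII VTU export with greyscale, landmarks, sets and result fields."""
    n, m = model.n_nodes, model.n_elements
    root = ET.Element(
        "VTKFile", type="UnstructuredGrid", version="0.1", byte_order="LittleEndian"
    )
    grid = ET.SubElement(root, "UnstructuredGrid")

    fd = ET.SubElement(grid, "FieldData")
    for name in _LANDMARK_NAMES:
        nid = model.landmarks.node_ids.get(name)
        if nid is None:
            continue
        arr = ET.SubElement(
            fd,
            "DataArray",
            type="Int64",
            Name=f"LM_{name}",
            NumberOfTuples="1",
            format="ascii",
        )
        arr.text = str(int(nid))
    for prefix, table in (
        ("PATH", model.strain_paths),
        ("PATCH", {k: v.nodes for k, v in model.attachment_patches.items()}),
        (
            "SET",
            {k: getattr(model.landmarks, k) for k in _SET_NAMES},
        ),
    ):
        for name, ids in sorted(table.items()):
            arr = ET.SubElement(
                fd,
                "DataArray",
                type="Int64",
                Name=f"{prefix}_{name}",
                NumberOfTuples=str(len(ids)),
                format="ascii",
            )
            arr.text = _ascii(np.asarray(ids, int), "{:d}")
    for name, patch in sorted(model.attachment_patches.items()):
        arr = ET.SubElement(
            fd,
            "DataArray",
            type="Float64",
            Name=f"REFPOINT_{name}",
            NumberOfTuples="3",
            format="ascii",
        )
        arr.text = _ascii(patch.refpoint)

    piece = ET.SubElement(grid, "Piece", NumberOfPoints=str(n), NumberOfCells=str(m))
    pts = ET.SubElement(piece, "Points")
    pa = ET.SubElement(
        pts, "DataArray", type="Float64", NumberOfComponents="3", format="ascii"
    )
    pa.text = _ascii(model.node_coords)
    cells = ET.SubElement(piece, "Cells")
    for name, data, typ in (
        ("connectivity", model.tets.ravel(), "Int64"),
        ("offsets", 4 * np.arange(1, m + 1), "Int64"),
        ("types", np.full(m, 10), "UInt8"),
    ):
        da = ET.SubElement(cells, "DataArray", type=typ, Name=name, format="ascii")
        da.text = _ascii(data, "{:d}")
    cd = ET.SubElement(piece, "CellData")
    all_cell = {"greyscale": model.element_gv, **(cell_data or {})}
    for name, data in all_cell.items():
        data = np.asarray(data)
        ncomp = 1 if data.ndim == 1 else data.shape[1]
        da = ET.SubElement(
            cd,
            "DataArray",
            type="Float64",
            Name=name,
            NumberOfComponents=str(ncomp),
            format="ascii",
        )
        da.text = _ascii(data)
    pd = ET.SubElement(piece, "PointData")
    for name, data in (point_data or {}).items():
        data = np.asarray(data)
        ncomp = 1 if data.ndim == 1 else data.shape[1]
        da = ET.SubElement(
            pd,
            "DataArray",
            type="Float64",
            Name=name,
            NumberOfComponents=str(ncomp),
            format="ascii",
        )
        da.text = _ascii(data)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def read_vtu(path) -> FemurModel:
    """Read a VTU file written by :func:`write_vtu` back into a model."""
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ParseError(f"malformed VTU: {exc}") from exc
    grid = root.find("UnstructuredGrid")
    if grid is None:
        raise ParseError("not an UnstructuredGrid VTU file")
    piece = grid.find("Piece")
    pts = np.fromstring(
        piece.find("Points/DataArray").text, sep=" "
    ).reshape(-1, 3)
    arrays = {
        da.get("Name"): da for da in piece.find("Cells").iter("DataArray")
    }
    conn = np.fromstring(arrays["connectivity"].text, sep=" ", dtype=int)
    types = np.fromstring(arrays["types"].text, sep=" ", dtype=int)
    if np.any(types != 10):
        raise ParseError("VTU contains non-tetrahedral cells")
    tets = conn.reshape(-1, 4)
    gv = None
    for da in piece.find("CellData").iter("DataArray"):
        if da.get("Name") == "greyscale":
            gv = np.fromstring(da.text, sep=" ")
    if gv is None:
        gv = np.zeros(tets.shape[0])
    fd = grid.find("FieldData")
    node_ids, paths, patch_nodes, sets, refpoints = {}, {}, {}, {}, {}
    if fd is not None:
        for da in fd.iter("DataArray"):
            name = da.get("Name")
            if name.startswith("LM_"):
                node_ids[name[3:]] = int(da.text.strip())
            elif name.startswith("PATH_"):
                paths[name[5:]] = np.fromstring(da.text, sep=" ", dtype=int)
            elif name.startswith("PATCH_"):
                patch_nodes[name[6:]] = np.fromstring(da.text, sep=" ", dtype=int)
            elif name.startswith("SET_"):
                sets[name[4:]] = np.fromstring(da.text, sep=" ", dtype=int)
            elif name.startswith("REFPOINT_"):
                refpoints[name[9:]] = np.fromstring(da.text, sep=" ")
    missing = [n for n in _LANDMARK_NAMES if n not in node_ids]
    if missing:
        raise ParseError(f"VTU FieldData missing landmarks: {missing}")
    lm_kwargs = {n: pts[node_ids[n]].copy() for n in _LANDMARK_NAMES}
    for n in _SET_NAMES:
        lm_kwargs[n] = sets.get(n, np.array([], int))
    landmarks = LandmarkSet(node_ids=node_ids, **lm_kwargs)
    patches = {
        name: AttachmentPatch(
            refpoint=refpoints.get(name, pts[ids].mean(axis=0)), nodes=ids
        )
        for name, ids in patch_nodes.items()
    }
    return FemurModel(
        node_coords=pts,
        tets=tets,
        element_gv=gv,
        landmarks=landmarks,
        frame=build_frame(landmarks),
        attachment_patches=patches,
        strain_paths=paths,
    )
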