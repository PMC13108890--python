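"""Serialization: legacy-VTK ASCII meshes and HDF5 containers.

The VTK writer emits version-3.0 ASCII unstructured grids (readable by
ParaView and by ``meshio``/``pyvista`` where available) with the region
labels, layer coordinates and fiber field attached as point/cell data.
HDF5 containers mirror the same arrays for programmatic round-tripping,
plus a results container holding the sampled potential, the ragged
activation-event lists and provenance metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .geometry import TissueModel
from .monodomain import SimulationResult

__all__ = [
    "write_vtk",
    "write_tree_vtk",
    "model_to_hdf5",
    "model_from_hdf5",
    "result_to_hdf5",
    "result_from_hdf5",
]

_VTK_CELL_TYPES = {1: 3, 2: 5, 3: 10}  # line, triangle, tetra

REGION_CODES = {"HZ": 0, "BZ": 1, "SZ": 2, "EHT": 3, "CS": 4, "EXCISED": 5}


def _pad3(coords: np.ndarray) -> np.ndarray:
    if coords.shape[1] == 3:
        return coords
    out = np.zeros((coords.shape[0], 3))
    out[:, : coords.shape[1]] = coords
    return out


def write_vtk(
    model: TissueModel,
    path: str | Path,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> Path:
    """Write the mesh with labels/coordinates/fibers as legacy VTK ASCII."""
    path = Path(path)
    pts = _pad3(model.nodes)
    cells = model.elements
    k = cells.shape[1]
    lines = [
        "# vtk DataFile Version 3.0",
        "ehtsim tissue model",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(pts)} float",
    ]
    lines += [" ".join(f"{v:.6g}" for v in p) for p in pts]
    lines.append(f"CELLS {len(cells)} {len(cells) * (k + 1)}")
    lines += [f"{k} " + " ".join(str(i) for i in c) for c in cells]
    lines.append(f"CELL_TYPES {len(cells)}")
    vtk_type = _VTK_CELL_TYPES[k - 1]
    lines += [str(vtk_type)] * len(cells)

    pdata = {"region": np.array([REGION_CODES.get(r, -1) for r in model.region])}
    if model.transmural_coord is not None:
        pdata["transmural_coord"] = model.transmural_coord
    if model.apicobasal_coord is not None:
        pdata["apicobasal_coord"] = model.apicobasal_coord
    pdata.update(point_data or {})
    lines.append(f"POINT_DATA {len(pts)}")
    for name, arr in pdata.items():
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{float(v):.6g}" for v in np.asarray(arr, dtype=float)]

    cdata = dict(cell_data or {})
    if model.fiber is not None:
        cdata["fiber"] = model.fiber
    if cdata:
        lines.append(f"CELL_DATA {len(cells)}")
        for name, arr in cdata.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 2:
                lines.append(f"VECTORS {name} float")
                lines += [" ".join(f"{v:.6g}" for v in _pad3(arr)[i]) for i in range(len(arr))]
            else:
                lines.append(f"SCALARS {name} float 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{float(v):.6g}" for v in arr]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_tree_vtk(tree, path: str | Path) -> Path:
    """Write a conduction-system tree as VTK line elements."""
    path = Path(path)
    pts = _pad3(tree.nodes)
    cells = tree.elements
    lines = [
        "# vtk DataFile Version 3.0",
        "ehtsim conduction-system tree",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(pts)} float",
    ]
    lines += [" ".join(f"{v:.6g}" for v in p) for p in pts]
    lines.append(f"CELLS {len(cells)} {len(cells) * 3}")
    lines += [f"2 {i} {j}" for i, j in cells]
    lines.append(f"CELL_TYPES {len(cells)}")
    lines += ["3"] * len(cells)
    lines.append(f"CELL_DATA {len(cells)}")
    lines.append("SCALARS d_long float 1")
    lines.append("LOOKUP_TABLE default")
    lines += [f"{float(v):.6g}" for v in tree.d_long]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_tree_edgelist(tree, path: str | Path) -> Path:
    """Plain-text edge list for a conduction-system tree: one line per
    element with node indices, endpoint coordinates and diffusion."""
    path = Path(path)
    lines = ["# i j xi yi xj yj d_long_cm2_ms"]
    for (i, j), d in zip(tree.elements, tree.d_long):
        xi, yi = tree.nodes[i][:2]
        xj, yj = tree.nodes[j][:2]
        lines.append(f"{i} {j} {xi:.4f} {yi:.4f} {xj:.4f} {yj:.4f} {d:.6g}")
    path.write_text("\n".join(lines) + "\n")
    return path


def model_to_hdf5(model: TissueModel, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("nodes", data=model.nodes)
        f.create_dataset("elements", data=model.elements)
        f.create_dataset("region", data=model.region.astype("S"))
        for name in ("fiber", "transmural_coord", "apicobasal_coord"):
            arr = getattr(model, name)
            if arr is not None:
                f.create_dataset(name, data=arr)
        for name in ("transmural_layer", "apicobasal_layer"):
            arr = getattr(model, name)
            if arr is not None:
                f.create_dataset(name, data=arr.astype("S"))
        if model.links:
            f.create_dataset("links", data=np.asarray(model.links, dtype=float))
        meta = {
            k: v
            for k, v in model.meta.items()
            if not isinstance(v, np.ndarray)
        }
        f.attrs["meta"] = json.dumps(meta, default=str)
        for key in ("line_elements", "line_d_long"):
            if key in model.meta:
                f.create_dataset(key, data=np.asarray(model.meta[key]))
    return path


def model_from_hdf5(path: str | Path) -> TissueModel:
    with h5py.File(path, "r") as f:
        kw = dict(
            nodes=f["nodes"][()],
            elements=f["elements"][()],
            region=f["region"][()].astype("<U8"),
        )
        for name in ("fiber", "transmural_coord", "apicobasal_coord"):
            if name in f:
                kw[name] = f[name][()]
        for name in ("transmural_layer", "apicobasal_layer"):
            if name in f:
                kw[name] = f[name][()].astype("<U6")
        links = []
        if "links" in f:
            links = [(int(i), int(j), float(g)) for i, j, g in f["links"][()]]
        meta = json.loads(f.attrs.get("meta", "{}"))
        for key in ("line_elements", "line_d_long"):
            if key in f:
                meta[key] = f[key][()]
        model = TissueModel(links=links, meta=meta, **kw)
    return model


def result_to_hdf5(result: SimulationResult, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=result.times)
        if result.u is not None:
            f.create_dataset("u", data=result.u, compression="gzip")
        flat = (
            np.concatenate(result.activations)
            if result.activations
            else np.empty(0)
        )
        offsets = np.cumsum([0] + [len(a) for a in result.activations])
        f.create_dataset("activations/events", data=flat)
        f.create_dataset("activations/offsets", data=offsets)
        f.attrs["meta"] = json.dumps(result.meta, default=str)
    return path


def result_from_hdf5(path: str | Path) -> SimulationResult:
    with h5py.File(path, "r") as f:
        times = f["times"][()]
        u = f["u"][()] if "u" in f else None
        flat = f["activations/events"][()]
        offsets = f["activations/offsets"][()]
        acts = [flat[offsets[i] : offsets[i + 1]] for i in range(len(offsets) - 1)]
        meta = json.loads(f.attrs.get("meta", "{}"))
    return SimulationResult(times=times, u=u, activations=acts, meta=meta)
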