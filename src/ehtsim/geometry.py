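"""Synthetic infarcted-tissue geometry.

Desk-scale stand-ins for image-derived biventricular anatomies: structured
simplicial sheets (2D triangles) and thin slabs (3D tetrahedra) carrying

* region labels — healthy zone (HZ), border zone (BZ), scar zone (SZ,
  later excised as an insulator), engineered-heart-tissue graft (EHT);
* two harmonic layer coordinates (transmural and apicobasal) obtained by
  solving the Laplace equation with Dirichlet 0/1 boundaries, thresholded
  into ENDO/MID/EPI (40:35:25) and APEX/MIDDLE/BASE (17:35:48 from the
  apex) layers;
* a per-element fiber field (constant or linearly rotating across the
  wall);
* the infarct (disk-shaped scar core plus border-zone annulus, optionally
  sub-transmural), scar excision with conservative node retagging, the
  epicardial EHT patch (centered L1 or half-overlapping L2), and
  equal-angle pacing-site rings around the infarct.

Coordinate convention, used everywhere: transmural_coord = 0 at the
endocardium and 1 at the epicardium; apicobasal_coord = 0 at the apex and
1 at the base.  In 2D-sheet mode the transmural axis is y and the
apicobasal axis is x; in 3D-slab mode they are z and x.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "TissueModel",
    "InfarctSpec",
    "EHTSpec",
    "LayerThresholds",
    "build_sheet",
    "label_infarct",
    "solve_layer_coordinates",
    "default_boundary_sets",
    "assign_layers",
    "excise_scar",
    "attach_eht",
    "generate_fibers",
    "select_pacing_sites",
]

REGIONS = ("HZ", "BZ", "SZ", "EHT", "CS", "EXCISED")


@dataclass
class TissueModel:
    """Unstructured simplicial tissue mesh with labels and fibers.

    ``nodes`` are coordinates in mm; ``elements`` index rows of ``nodes``
    (triangles in 2D, tetrahedra in 3D).  ``links`` are discrete resistive
    connections (i, j, conductance mm^3/ms) used for graft interlayer
    coupling and Purkinje–muscular junctions.
    """

    nodes: np.ndarray
    elements: np.ndarray
    region: np.ndarray
    fiber: np.ndarray | None = None
    transmural_coord: np.ndarray | None = None
    apicobasal_coord: np.ndarray | None = None
    transmural_layer: np.ndarray | None = None
    apicobasal_layer: np.ndarray | None = None
    links: list = field(default_factory=list)
    eht_host: np.ndarray | None = None  # host node index per EHT layer node
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def dim(self) -> int:
        return self.nodes.shape[1]

    @property
    def elem_dim(self) -> int:
        return self.elements.shape[1] - 1

    def copy(self) -> "TissueModel":
        return TissueModel(
            nodes=self.nodes.copy(),
            elements=self.elements.copy(),
            region=self.region.copy(),
            fiber=None if self.fiber is None else self.fiber.copy(),
            transmural_coord=None
            if self.transmural_coord is None
            else self.transmural_coord.copy(),
            apicobasal_coord=None
            if self.apicobasal_coord is None
            else self.apicobasal_coord.copy(),
            transmural_layer=None
            if self.transmural_layer is None
            else self.transmural_layer.copy(),
            apicobasal_layer=None
            if self.apicobasal_layer is None
            else self.apicobasal_layer.copy(),
            links=list(self.links),
            eht_host=None if self.eht_host is None else self.eht_host.copy(),
            meta=dict(self.meta),
        )

    def validate(self) -> None:
        if self.elements.size and self.elements.max() >= self.n_nodes:
            raise ValueError("element references a non-existent node")
        if self.fiber is not None and self.fiber.size:
            norms = np.linalg.norm(self.fiber, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise ValueError("fiber vectors must have unit norm")
        for name in ("transmural_coord", "apicobasal_coord"):
            c = getattr(self, name)
            if c is not None and c.size and (c.min() < -1e-9 or c.max() > 1 + 1e-9):
                raise ValueError(f"{name} outside [0, 1]")

    def infarct_center(self) -> np.ndarray:
        """In-plane centroid of the infarcted (SZ ∪ BZ) nodes."""
        mask = np.isin(self.region, ("SZ", "BZ"))
        plane = self.nodes[:, :2]
        if not mask.any():
            return 0.5 * (plane.min(axis=0) + plane.max(axis=0))
        return plane[mask].mean(axis=0)


@dataclass(frozen=True)
class InfarctSpec:
    """Disk scar core of radius ``sz_radius`` with a BZ annulus of width
    ``bz_width`` around it; ``transmural_depth`` is the wall fraction
    occupied by scar, measured from the epicardial side (1.0 = fully
    transmural)."""

    center: tuple[float, float]
    sz_radius: float
    bz_width: float = 0.0
    transmural_depth: float = 1.0
    # optional signed-distance override: f(xy) < 0 inside the scar core,
    # the BZ annulus is 0 <= f < bz_width
    signed_distance: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self):
        if self.sz_radius <= 0:
            raise ValueError("sz_radius must be positive")
        if self.bz_width < 0:
            raise ValueError("bz_width must be non-negative")
        if not (0.0 <= self.transmural_depth <= 1.0):
            raise ValueError("transmural_depth must lie in [0, 1]")


@dataclass(frozen=True)
class EHTSpec:
    """Epicardial graft patch.

    ``conductivity_fraction`` scales the healthy diffusion coefficient
    (0.10 = immature C10, 0.90 = mature C90).  ``embed_depth`` is how far
    the patch thickness projects into the host wall.
    """

    footprint: tuple[float, float] = (40.0, 40.0)
    thickness: float = 1.0
    location: str = "L1"
    embed_depth: float = 0.55
    conductivity_fraction: float = 0.10

    def __post_init__(self):
        if not (0.0 < self.conductivity_fraction <= 1.0):
            raise ValueError("conductivity_fraction must be in (0, 1]")
        if not (0.0 < self.embed_depth < self.thickness):
            raise ValueError("embed_depth must be positive and below thickness")
        if self.location not in ("L1", "L2"):
            raise ValueError("location must be 'L1' or 'L2'")


@dataclass(frozen=True)
class LayerThresholds:
    """Layer proportion triples (percent), endo:mid:epi and base:middle:apex."""

    transmural: tuple[float, float, float] = (40.0, 35.0, 25.0)
    apicobasal: tuple[float, float, float] = (48.0, 35.0, 17.0)

    def __post_init__(self):
        for triple in (self.transmural, self.apicobasal):
            if abs(sum(triple) - 100.0) > 1e-9:
                raise ValueError(f"proportions must sum to 100, got {triple}")

    @property
    def transmural_cuts(self) -> tuple[float, float]:
        endo, mid, _ = self.transmural
        return endo / 100.0, (endo + mid) / 100.0

    @property
    def apicobasal_cuts(self) -> tuple[float, float]:
        base, middle, apex = self.apicobasal
        return apex / 100.0, (apex + middle) / 100.0


# ---------------------------------------------------------------------------
# Mesh construction

# Kuhn decomposition of the unit cube into 6 tetrahedra; vertices indexed
# by coordinate bits (x + 2y + 4z).  Applied uniformly it yields a
# conforming tetrahedral mesh.
_KUHN_TETS = [
    (0, 1, 3, 7),
    (0, 3, 2, 7),
    (0, 2, 6, 7),
    (0, 6, 4, 7),
    (0, 4, 5, 7),
    (0, 5, 1, 7),
]


def build_sheet(extent: Sequence[float], resolution: float) -> TissueModel:
    """Structured simplicial sheet (2D) or slab (3D), all nodes healthy.

    ``extent`` gives the side lengths in mm (two or three values);
    ``resolution`` is the grid spacing.  Fibers default to the +x axis.
    """
    if resolution <= 0:
        raise ValueError(f"resolution must be positive, got {resolution}")
    extent = tuple(float(e) for e in extent)
    if any(e <= 0 for e in extent):
        raise ValueError(f"extent must be positive, got {extent}")
    dims = len(extent)
    if dims not in (2, 3):
        raise ValueError("extent must have 2 or 3 components")
    counts = []
    for e in extent:
        n = int(round(e / resolution))
        if abs(n * resolution - e) > 1e-6 * max(1.0, e):
            n = int(np.ceil(e / resolution - 1e-9))
        counts.append(n)

    if dims == 2:
        nx, ny = counts
        xs = np.linspace(0.0, extent[0], nx + 1)
        ys = np.linspace(0.0, extent[1], ny + 1)
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        nodes = np.column_stack([X.ravel(), Y.ravel()])

        def nid(i, j):
            return i * (ny + 1) + j

        tris = []
        for i in range(nx):
            for j in range(ny):
                a, b = nid(i, j), nid(i + 1, j)
                c, d = nid(i + 1, j + 1), nid(i, j + 1)
                tris.append((a, b, c))
                tris.append((a, c, d))
        elements = np.asarray(tris, dtype=np.int64)
        fiber = np.tile([1.0, 0.0], (len(elements), 1))
    else:
        nx, ny, nz = counts
        xs = np.linspace(0.0, extent[0], nx + 1)
        ys = np.linspace(0.0, extent[1], ny + 1)
        zs = np.linspace(0.0, extent[2], nz + 1)
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

        def nid(i, j, k):
            return (i * (ny + 1) + j) * (nz + 1) + k

        tets = []
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    corner = [
                        nid(i + (b & 1), j + ((b >> 1) & 1), k + ((b >> 2) & 1))
                        for b in range(8)
                    ]
                    for t in _KUHN_TETS:
                        tets.append(tuple(corner[v] for v in t))
        elements = np.asarray(tets, dtype=np.int64)
        fiber = np.tile([1.0, 0.0, 0.0], (len(elements), 1))

    region = np.full(nodes.shape[0], "HZ", dtype="<U8")
    model = TissueModel(
        nodes=nodes,
        elements=elements,
        region=region,
        fiber=fiber,
        meta={"grid": {"counts": counts, "resolution": resolution, "extent": extent}},
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Laplace layer coordinates


def _laplace_stiffness(model: TissueModel) -> sp.csr_matrix:
    from .monodomain import simplex_stiffness  # shared FEM kernels

    d = model.elem_dim
    n = model.dim
    iso = np.tile(np.eye(n), (len(model.elements), 1, 1))
    return simplex_stiffness(model.nodes, model.elements, iso)


def solve_layer_coordinates(
    model: TissueModel,
    boundary_sets: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
) -> TissueModel:
    """Fill the harmonic layer coordinates by solving Laplace problems.

    ``boundary_sets`` maps ``'transmural'`` / ``'apicobasal'`` to a pair of
    disjoint node-index sets receiving Dirichlet values 0 and 1 (endo/epi,
    apex/base).  Defaults to the opposing faces of a box mesh.
    """
    out = model.copy()
    if boundary_sets is None:
        boundary_sets = default_boundary_sets(model)
    K = _laplace_stiffness(model)
    n = model.n_nodes
    for name, (zero_set, one_set) in boundary_sets.items():
        zero_set = np.asarray(zero_set, dtype=np.int64)
        one_set = np.asarray(one_set, dtype=np.int64)
        if zero_set.size == 0 or one_set.size == 0:
            raise ValueError(f"{name}: boundary sets must be non-empty")
        if np.intersect1d(zero_set, one_set).size:
            raise ValueError(f"{name}: boundary sets overlap")
        fixed = np.zeros(n, dtype=bool)
        fixed[zero_set] = True
        fixed[one_set] = True
        g = np.zeros(n)
        g[one_set] = 1.0
        free = ~fixed
        K_ff = K[free][:, free]
        rhs = -K[free][:, fixed] @ g[fixed]
        sol = np.zeros(n)
        sol[fixed] = g[fixed]
        sol[free] = spla.spsolve(K_ff.tocsc(), rhs)
        sol = np.clip(sol, 0.0, 1.0)
        if name == "transmural":
            out.transmural_coord = sol
        elif name == "apicobasal":
            out.apicobasal_coord = sol
        else:
            raise KeyError(f"unknown coordinate {name!r}")
    return out


def default_boundary_sets(model: TissueModel) -> dict:
    """Opposing-face boundary sets for box meshes.

    Transmural axis: y in 2D, z in 3D (endocardium at the low face);
    apicobasal axis: x (apex at x = 0, base at x = max).
    """
    tol = 1e-9
    nodes = model.nodes
    t_axis = 1 if model.dim == 2 else 2
    lo, hi = nodes[:, t_axis].min(), nodes[:, t_axis].max()
    endo = np.nonzero(np.abs(nodes[:, t_axis] - lo) < tol + 1e-9 * abs(hi))[0]
    epi = np.nonzero(np.abs(nodes[:, t_axis] - hi) < tol + 1e-9 * abs(hi))[0]
    xlo, xhi = nodes[:, 0].min(), nodes[:, 0].max()
    apex = np.nonzero(np.abs(nodes[:, 0] - xlo) < tol + 1e-9 * abs(xhi))[0]
    base = np.nonzero(np.abs(nodes[:, 0] - xhi) < tol + 1e-9 * abs(xhi))[0]
    return {"transmural": (endo, epi), "apicobasal": (apex, base)}


def assign_layers(
    model: TissueModel, thresholds: LayerThresholds | None = None
) -> TissueModel:
    """Threshold the harmonic coordinates into wall/long-axis layers.

    Transmural (coordinate measured from the endocardium): ENDO below the
    first cut, MID between, EPI at or above the second.  Apicobasal
    (coordinate measured from the apex): APEX at or below the first cut,
    MIDDLE up to the second, BASE above.
    """
    thresholds = thresholds or LayerThresholds()
    out = model.copy()
    if out.transmural_coord is None and out.apicobasal_coord is None:
        raise ValueError("layer coordinates missing; run solve_layer_coordinates first")
    if out.transmural_coord is not None:
        c1, c2 = thresholds.transmural_cuts
        t = out.transmural_coord
        lab = np.full(model.n_nodes, "MID", dtype="<U6")
        lab[t < c1] = "ENDO"
        lab[t >= c2] = "EPI"
        out.transmural_layer = lab
    if out.apicobasal_coord is not None:
        c1, c2 = thresholds.apicobasal_cuts
        a = out.apicobasal_coord
        lab = np.full(model.n_nodes, "MIDDLE", dtype="<U6")
        lab[a <= c1] = "APEX"
        lab[a > c2] = "BASE"
        out.apicobasal_layer = lab
    return out


# ---------------------------------------------------------------------------
# Infarct


def label_infarct(model: TissueModel, spec: InfarctSpec) -> TissueModel:
    """Label the scar core and border-zone annulus.

    Distances are measured in the sheet plane (x, y).  A sub-transmural
    scar (``transmural_depth`` < 1) occupies only the epicardial fraction
    of the wall, gated on ``transmural_coord``; the BZ annulus is not
    gated (remodeling surrounds the scar through the wall).
    """
    out = model.copy()
    xy = model.nodes[:, :2]
    center = np.asarray(spec.center, dtype=float)
    if spec.signed_distance is not None:
        f = np.asarray(spec.signed_distance(xy), dtype=float)
        in_core = f < 0.0
        in_annulus = (f >= 0.0) & (f < spec.bz_width)
    else:
        dist = np.linalg.norm(xy - center, axis=1)
        in_core = dist <= spec.sz_radius
        in_annulus = (dist > spec.sz_radius) & (dist <= spec.sz_radius + spec.bz_width)
    if not (in_core.any() or in_annulus.any()):
        warnings.warn("infarct lies fully outside the domain; no labels changed")
        return out
    sz = in_core
    if spec.transmural_depth < 1.0:
        if model.transmural_coord is None:
            raise ValueError(
                "sub-transmural infarct requires transmural_coord; "
                "run solve_layer_coordinates first"
            )
        sz = sz & (model.transmural_coord >= 1.0 - spec.transmural_depth)
    editable = ~np.isin(out.region, ("EHT", "CS", "EXCISED"))
    out.region[sz & editable] = "SZ"
    out.region[in_annulus & editable & (out.region != "SZ")] = "BZ"
    # core nodes spared by the transmural gate stay/become border zone
    out.region[in_core & ~sz & editable] = "BZ"
    return out


# ---------------------------------------------------------------------------
# Scar excision


def excise_scar(model: TissueModel) -> TissueModel:
    """Remove the scar from the computational domain (insulator model).

    Elements made exclusively of SZ nodes are deleted.  SZ nodes shared
    with surviving elements are retagged to the most frequent non-SZ label
    among those elements' nodes (tie-break: BZ over HZ) — conservative, so
    narrow slow-conducting BZ isthmuses survive.  Nodes left unreferenced
    are marked EXCISED and excluded from the solve; the exposed surface
    naturally receives the monodomain zero-flux boundary.  Idempotent.
    """
    out = model.copy()
    region = out.region
    is_sz = region == "SZ"
    if not is_sz.any():
        return out
    elem_sz = is_sz[out.elements]
    keep = ~elem_sz.all(axis=1)
    out.elements = out.elements[keep]
    if out.fiber is not None:
        out.fiber = out.fiber[keep]

    # aggregate non-SZ labels seen by each surviving SZ node
    votes: dict[int, Counter] = {}
    for elem in out.elements:
        labels = region[elem]
        if not (labels == "SZ").any():
            continue
        non_sz = [l for l in labels if l != "SZ"]
        for nid, lab in zip(elem, labels):
            if lab == "SZ":
                votes.setdefault(int(nid), Counter()).update(non_sz)
    priority = {"BZ": 0, "HZ": 1, "EHT": 2, "CS": 3}
    for nid, counter in votes.items():
        best = max(counter)
        top = max(counter.values())
        cands = [l for l, c in counter.items() if c == top]
        region[nid] = min(cands, key=lambda l: priority.get(l, 9))

    referenced = np.zeros(out.n_nodes, dtype=bool)
    if out.elements.size:
        referenced[np.unique(out.elements)] = True
    for i, j, _ in out.links:
        referenced[i] = True
        referenced[j] = True
    region[(region == "SZ") & ~referenced] = "EXCISED"
    # any remaining SZ nodes are referenced but received no votes (cannot
    # happen for valid meshes) — retag conservatively to BZ
    region[region == "SZ"] = "BZ"
    out.region = region
    out.meta["scar_excised"] = True
    return out


# ---------------------------------------------------------------------------
# EHT attachment


def attach_eht(
    model: TissueModel,
    spec: EHTSpec,
    center: Sequence[float] | None = None,
) -> TissueModel:
    """Attach the engineered-heart-tissue patch over the infarct.

    2D bilayer mode: a second node layer is duplicated over the footprint
    and coupled to the host through per-node resistive interlayer links,
    representing complete engraftment over the contact area.  L1 centers
    the footprint on the infarct; L2 shifts it by half the footprint along
    +x so half overlies the infarct and half healthy tissue.  EHT
    conductivity is isotropic.  The graft is purely additive: deleting the
    EHT nodes recovers the host model.
    """
    if model.dim != 2:
        raise NotImplementedError(
            "EHT attachment is implemented for 2D sheets (bilayer mode)"
        )
    out = model.copy()
    c = np.asarray(center if center is not None else model.infarct_center(), dtype=float)
    fx, fy = spec.footprint
    if spec.location == "L2":
        c = c + np.array([fx / 2.0, 0.0])
    lo = c - np.array([fx / 2.0, fy / 2.0])
    hi = c + np.array([fx / 2.0, fy / 2.0])
    dom_lo = model.nodes.min(axis=0)[:2]
    dom_hi = model.nodes.max(axis=0)[:2]
    if (lo < dom_lo - 1e-9).any() or (hi > dom_hi + 1e-9).any():
        warnings.warn("EHT footprint exceeds the domain; clipped")
        lo = np.maximum(lo, dom_lo)
        hi = np.minimum(hi, dom_hi)

    xy = model.nodes[:, :2]
    tol = 1e-9
    in_fp = np.all((xy >= lo - tol) & (xy <= hi + tol), axis=1)
    in_fp &= model.region != "EXCISED"
    host_ids = np.nonzero(in_fp)[0]
    if host_ids.size == 0:
        warnings.warn("EHT footprint covers no host nodes; nothing attached")
        return out

    n0 = out.n_nodes
    new_index = -np.ones(model.n_nodes, dtype=np.int64)
    new_index[host_ids] = n0 + np.arange(host_ids.size)
    out.nodes = np.vstack([out.nodes, model.nodes[host_ids]])
    out.region = np.concatenate(
        [out.region, np.full(host_ids.size, "EHT", dtype="<U8")]
    )
    for name in ("transmural_coord", "apicobasal_coord"):
        arr = getattr(out, name)
        if arr is not None:
            setattr(out, name, np.concatenate([arr, arr[host_ids]]))
    for name in ("transmural_layer", "apicobasal_layer"):
        arr = getattr(out, name)
        if arr is not None:
            setattr(out, name, np.concatenate([arr, arr[host_ids]]))

    # graft elements: host triangles fully inside the footprint
    tri_in = in_fp[model.elements].all(axis=1)
    graft = new_index[model.elements[tri_in]]
    out.elements = np.vstack([out.elements, graft])
    if out.fiber is not None:
        # isotropic conductivity: the fiber direction is inert for EHT
        out.fiber = np.vstack([out.fiber, np.tile([1.0, 0.0], (len(graft), 1))])

    # per-node contact area = one third of the adjacent graft-element area
    area = _element_measure(model.nodes, model.elements[tri_in])
    node_area = np.zeros(model.n_nodes)
    np.add.at(node_area, model.elements[tri_in].ravel(), np.repeat(area / 3.0, 3))
    d_eht_mm2_ms = 100.0 * 0.0013 * spec.conductivity_fraction
    gap = spec.thickness - spec.embed_depth
    host_eht = np.full(out.n_nodes, -1, dtype=np.int64)
    for hid in host_ids:
        a = node_area[hid]
        if a <= 0:
            continue
        g = d_eht_mm2_ms * a / max(gap, 1e-3)
        out.links.append((int(hid), int(new_index[hid]), float(g)))
        host_eht[new_index[hid]] = hid
    out.eht_host = host_eht
    out.meta["eht"] = {
        "location": spec.location,
        "footprint": (float(hi[0] - lo[0]), float(hi[1] - lo[1])),
        "conductivity_fraction": spec.conductivity_fraction,
        "first_node": int(n0),
    }
    out.validate()
    return out


def _element_measure(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    """Length / area / volume of simplices (vectorized)."""
    if elements.size == 0:
        return np.zeros(0)
    X = nodes[elements]
    d = elements.shape[1] - 1
    edges = X[:, 1:, :] - X[:, :1, :]
    if d == 1:
        return np.linalg.norm(edges[:, 0, :], axis=1)
    if d == 2:
        if nodes.shape[1] == 2:
            cross = edges[:, 0, 0] * edges[:, 1, 1] - edges[:, 0, 1] * edges[:, 1, 0]
            return 0.5 * np.abs(cross)
        return 0.5 * np.linalg.norm(np.cross(edges[:, 0, :], edges[:, 1, :]), axis=1)
    if d == 3:
        return np.abs(np.einsum("ij,ij->i", edges[:, 0], np.cross(edges[:, 1], edges[:, 2]))) / 6.0
    raise ValueError(f"unsupported simplex dimension {d}")


# ---------------------------------------------------------------------------
# Fibers


def generate_fibers(
    model: TissueModel,
    rule: str = "constant",
    angle_endo: float = -60.0,
    angle_epi: float = 60.0,
    direction: Sequence[float] | None = None,
) -> TissueModel:
    """Per-element unit fiber vectors.

    ``constant`` sets every fiber to ``direction`` (default +x).
    ``rotating`` linearly interpolates the in-plane helix angle from
    ``angle_endo`` to ``angle_epi`` across the transmural coordinate, the
    usual rule-based stand-in for histological fiber rotation.
    """
    out = model.copy()
    n_el = len(model.elements)
    if rule == "constant":
        d = np.zeros(model.dim)
        if direction is None:
            d[0] = 1.0
        else:
            d[: len(direction)] = direction
        d = d / np.linalg.norm(d)
        out.fiber = np.tile(d, (n_el, 1))
    elif rule == "rotating":
        if model.transmural_coord is None:
            raise ValueError("rotating fibers require transmural_coord")
        t_el = model.transmural_coord[model.elements].mean(axis=1)
        ang = np.deg2rad(angle_endo + (angle_epi - angle_endo) * t_el)
        fib = np.zeros((n_el, model.dim))
        if model.dim == 2:
            fib[:, 0] = np.cos(ang)
            fib[:, 1] = np.sin(ang)
        else:
            # rotation in the sheet (x, y) plane; wall normal is z
            fib[:, 0] = np.cos(ang)
            fib[:, 1] = np.sin(ang)
        out.fiber = fib
    else:
        raise ValueError(f"unknown fiber rule {rule!r}")
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Pacing sites


def select_pacing_sites(
    model: TissueModel,
    n_sites: int,
    radius: float = 1.0,
    ring_margin: float = 2.0,
    center: Sequence[float] | None = None,
) -> list[np.ndarray]:
    """Equal-angle ring of pacing sites just outside the border zone.

    Seeds are placed at equal angles on a circle ``ring_margin`` mm outside
    the outermost infarcted node, snapped to the nearest viable
    (non-scar, non-graft) node; each site is the set of viable host nodes
    within ``radius`` of its seed.  Deterministic.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    xy = model.nodes[:, :2]
    c = np.asarray(center if center is not None else model.infarct_center(), dtype=float)
    infarcted = np.isin(model.region, ("SZ", "BZ"))
    if infarcted.any():
        r_out = np.linalg.norm(xy[infarcted] - c, axis=1).max()
    else:
        r_out = 0.25 * np.linalg.norm(xy.max(axis=0) - xy.min(axis=0))
    ring = r_out + ring_margin
    viable = ~np.isin(model.region, ("SZ", "EXCISED", "EHT", "CS"))
    viable_ids = np.nonzero(viable)[0]
    if viable_ids.size == 0:
        raise ValueError("no viable tissue for pacing")
    sites = []
    for k in range(n_sites):
        theta = 2.0 * np.pi * k / n_sites
        seed = c + ring * np.array([np.cos(theta), np.sin(theta)])
        d = np.linalg.norm(xy[viable_ids] - seed, axis=1)
        anchor = viable_ids[np.argmin(d)]
        members = viable_ids[np.linalg.norm(xy[viable_ids] - xy[anchor], axis=1) <= radius]
        sites.append(members)
    return sites
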