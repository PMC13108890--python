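"""Monodomain reaction–diffusion solver on labeled simplicial meshes.

P1 finite elements with lumped mass, orthotropic per-element conductivity
tensors built from the fiber field, zero-flux (natural Neumann)
boundaries, operator splitting (explicit reaction with exact exponential
gate update, implicit diffusion), stimulus delivery, activation-event
recording at full time-step resolution and 1 ms output sampling.

Units: geometry in mm, time in ms.  Diffusion coefficients are *specified*
in cm²/ms, the unit used throughout the cardiac-modelling literature, and
converted to mm²/ms (×100) in exactly one place (:data:`CM2_TO_MM2`);
velocities are reported in cm/s (1 mm/ms = 100 cm/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .cells import CellParams, CellState, stimulus_du
from .geometry import TissueModel, _element_measure

__all__ = [
    "CM2_TO_MM2",
    "MM_MS_TO_CM_S",
    "DEFAULT_D_LONG",
    "DEFAULT_RHO",
    "ConductivityField",
    "StimulusEvent",
    "SolverConfig",
    "SimulationResult",
    "assemble_operator",
    "run",
    "build_strand",
    "measure_strand_cv",
    "simplex_stiffness",
    "lumped_mass",
]

#: cm²/ms -> mm²/ms.  The single point of unit conversion for diffusion.
CM2_TO_MM2 = 100.0
#: mm/ms -> cm/s.
MM_MS_TO_CM_S = 100.0

#: Longitudinal diffusion coefficients, cm²/ms.
DEFAULT_D_LONG = {"HZ": 0.0013, "CS": 0.013, "BZ": 0.000882}
#: Transverse-to-longitudinal diffusion ratios; the graft is isotropic.
DEFAULT_RHO = {"HZ": 0.25, "BZ": 0.345, "EHT": 1.0, "CS": 1.0}


# ---------------------------------------------------------------------------
# FEM kernels


def simplex_stiffness(
    nodes: np.ndarray, elements: np.ndarray, tensors: np.ndarray
) -> sp.csr_matrix:
    """P1 stiffness matrix for full-dimensional simplices.

    ``tensors`` is (n_elements, dim, dim), symmetric positive definite.
    Row sums vanish (partition of unity), giving the natural zero-flux
    boundary everywhere no Dirichlet condition is imposed.
    """
    n = nodes.shape[0]
    if elements.size == 0:
        return sp.csr_matrix((n, n))
    d = elements.shape[1] - 1
    X = nodes[elements]  # (m, d+1, dim)
    E = X[:, 1:, :] - X[:, :1, :]  # (m, d, dim)
    if d != nodes.shape[1]:
        raise ValueError("simplex_stiffness expects full-dimensional elements")
    det = np.linalg.det(E)
    bad = np.nonzero(np.abs(det) < 1e-14)[0]
    if bad.size:
        raise ValueError(f"degenerate elements (zero measure): {bad[:20].tolist()}")
    Einv = np.linalg.inv(E)  # rows of Einv.T are gradients of phi_1..phi_d
    G = np.swapaxes(Einv, 1, 2)  # (m, d, d): G[:, k, :] = grad phi_{k+1}
    grads = np.concatenate([-G.sum(axis=1, keepdims=True), G], axis=1)  # (m, d+1, d)
    vol = np.abs(det) / np.prod(range(1, d + 1))
    DG = np.einsum("mij,mkj->mki", tensors, grads)  # D grad phi_k
    Ke = np.einsum("mki,mli->mkl", grads, DG) * vol[:, None, None]
    rows = np.repeat(elements, d + 1, axis=1).ravel()
    cols = np.tile(elements, (1, d + 1)).ravel()
    return sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def line_stiffness(
    nodes: np.ndarray, elements: np.ndarray, d_eff: np.ndarray, area: float
) -> sp.csr_matrix:
    """Stiffness of 1D cable elements embedded in any dimension.

    ``d_eff`` is the per-element diffusion along the cable in mm²/ms;
    ``area`` is the cable cross-section in mm² (source–sink weight).
    """
    n = nodes.shape[0]
    if elements.size == 0:
        return sp.csr_matrix((n, n))
    L = _element_measure(nodes, elements)
    k = area * np.asarray(d_eff) / L
    i, j = elements[:, 0], elements[:, 1]
    rows = np.concatenate([i, j, i, j])
    cols = np.concatenate([i, j, j, i])
    vals = np.concatenate([k, k, -k, -k])
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def lumped_mass(
    nodes: np.ndarray,
    elements: np.ndarray,
    line_elements: np.ndarray | None = None,
    line_area: float = 0.3,
) -> np.ndarray:
    """Diagonal (lumped) mass: each node takes measure/(d+1) of its elements."""
    m = np.zeros(nodes.shape[0])
    if elements.size:
        d = elements.shape[1] - 1
        meas = _element_measure(nodes, elements)
        np.add.at(m, elements.ravel(), np.repeat(meas / (d + 1), d + 1))
    if line_elements is not None and line_elements.size:
        meas = _element_measure(nodes, line_elements) * line_area
        np.add.at(m, line_elements.ravel(), np.repeat(meas / 2.0, 2))
    return m


# ---------------------------------------------------------------------------
# Conductivity


@dataclass
class ConductivityField:
    """Per-element longitudinal diffusion (cm²/ms) and transverse ratio.

    The element tensor is D = D_T I + (D_L − D_T) f fᵀ with D_T = ρ D_L,
    which is symmetric positive definite for ρ ∈ (0, 1].
    """

    d_long: np.ndarray
    rho: np.ndarray

    @classmethod
    def from_model(
        cls,
        model: TissueModel,
        eht_fraction: float = 0.10,
        d_long: Mapping[str, float] | None = None,
        rho: Mapping[str, float] | None = None,
    ) -> "ConductivityField":
        """Region-based conductivity.

        An element takes the *slowest* region among its nodes (priority
        EHT > BZ > HZ when the diffusion values tie), which preserves
        slow-conducting border-zone isthmuses at interfaces.
        """
        dmap = dict(DEFAULT_D_LONG)
        dmap["EHT"] = dmap["HZ"] * eht_fraction
        if d_long:
            dmap.update(d_long)
        rmap = dict(DEFAULT_RHO)
        if rho:
            rmap.update(rho)
        elem_regions = model.region[model.elements]
        n_el = len(model.elements)
        dl = np.empty(n_el)
        rh = np.empty(n_el)
        for e in range(n_el):
            labels = elem_regions[e]
            lab = min(
                (l for l in labels if l in dmap),
                key=lambda l: dmap[l],
                default="HZ",
            )
            # graft elements are built purely of EHT nodes; mixed elements
            # never carry the EHT label
            if "EHT" in labels and (labels == "EHT").all():
                lab = "EHT"
            dl[e] = dmap[lab]
            rh[e] = rmap.get(lab, 1.0)
        return cls(d_long=dl, rho=rh)

    def tensors(self, model: TissueModel) -> np.ndarray:
        """(n_elements, dim, dim) diffusion tensors in mm²/ms."""
        n_el = len(model.elements)
        dim = model.dim
        f = model.fiber
        if f is None:
            f = np.zeros((n_el, dim))
            f[:, 0] = 1.0
        dl = CM2_TO_MM2 * self.d_long
        dt_ = self.rho * dl
        eye = np.eye(dim)
        T = dt_[:, None, None] * eye[None] + (dl - dt_)[:, None, None] * np.einsum(
            "mi,mj->mij", f, f
        )
        return T


@dataclass(frozen=True)
class StimulusEvent:
    """Transmembrane current pulse on a node set."""

    nodes: np.ndarray
    start: float
    duration: float = 1.0
    amplitude: float = 80.0  # µA/cm²

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")
        if self.amplitude < 0:
            raise ValueError("stimulus amplitude must be non-negative")


@dataclass
class SolverConfig:
    """Time-integration settings.

    ``dt`` is fixed (default 0.05 ms) and must lie inside ``dt_bounds``
    (default [0.01, 0.1] ms).  ``capacitance`` (µF/cm²) and
    ``surface_to_volume`` (cm⁻¹) are the documentation constants relating
    diffusion coefficients to conductivities.  ``store_u`` disables the
    full sampled-potential matrix for long campaign runs (activation
    events are always recorded).
    """

    end_time: float = 100.0
    dt: float = 0.05
    dt_bounds: tuple[float, float] = (0.01, 0.1)
    sampling: float = 1.0
    capacitance: float = 1.0
    surface_to_volume: float = 1000.0
    activation_threshold: float = 0.5
    store_u: bool = True
    store_dtype: type = np.float32

    def __post_init__(self):
        lo, hi = self.dt_bounds
        if not (lo <= self.dt <= hi):
            raise ValueError(f"dt={self.dt} outside the allowed bounds {self.dt_bounds}")
        if self.sampling < self.dt:
            raise ValueError("output sampling must be >= dt")


@dataclass
class SimulationResult:
    """Sampled potentials and per-node activation events."""

    times: np.ndarray
    u: np.ndarray | None
    activations: list  # list of np.ndarray, one sorted array per node
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.activations)

    def first_activation(
        self, t_min: float = -np.inf, t_max: float = np.inf
    ) -> np.ndarray:
        """Per-node first activation time within a window; NaN if none."""
        out = np.full(self.n_nodes, np.nan)
        for i, a in enumerate(self.activations):
            sel = a[(a >= t_min) & (a <= t_max)]
            if sel.size:
                out[i] = sel[0]
        return out

    def activation_counts(self, t_min: float = -np.inf) -> np.ndarray:
        return np.array([(a >= t_min).sum() for a in self.activations])

    def last_activation_time(self) -> float:
        last = [a[-1] for a in self.activations if a.size]
        return max(last) if last else -np.inf


class DiffusionOperator:
    """Assembled stiffness + lumped mass with a cached implicit solver."""

    def __init__(self, K: sp.csr_matrix, M: np.ndarray, active: np.ndarray):
        self.K = K
        self.M = M
        self.active = active
        self._solver = None
        self._solver_dt = None

    def solver(self, dt: float):
        if self._solver is None or self._solver_dt != dt:
            Mdiag = np.where(self.M > 0, self.M, 1.0)
            A = sp.diags(Mdiag) + dt * self.K
            self._solver = spla.factorized(A.tocsc())
            self._solver_dt = dt
            self._Mdiag = Mdiag
        return self._solver

    def step(self, u: np.ndarray, dt: float) -> np.ndarray:
        solve = self.solver(dt)
        return solve(self._Mdiag * u)


def assemble_operator(
    model: TissueModel, cond: ConductivityField | None = None
) -> DiffusionOperator:
    """Assemble the sparse diffusion operator for a labeled mesh.

    Scar-excised regions are simply absent from the element set, so the
    excision surface automatically receives the zero-flux condition.
    Resistive links (graft interlayer coupling, Purkinje–muscular
    junctions) are added as discrete two-point conductances.
    """
    cond = cond or ConductivityField.from_model(model)
    K = simplex_stiffness(model.nodes, model.elements, cond.tensors(model))
    line_el = model.meta.get("line_elements")
    line_d = model.meta.get("line_d_long")
    line_area = model.meta.get("line_area", 0.3)
    if line_el is not None and len(line_el):
        K = K + line_stiffness(
            model.nodes, np.asarray(line_el), CM2_TO_MM2 * np.asarray(line_d), line_area
        )
    if model.links:
        li = np.array([l[0] for l in model.links], dtype=np.int64)
        lj = np.array([l[1] for l in model.links], dtype=np.int64)
        lg = np.array([l[2] for l in model.links], dtype=float)
        n = model.n_nodes
        rows = np.concatenate([li, lj, li, lj])
        cols = np.concatenate([li, lj, lj, li])
        vals = np.concatenate([lg, lg, -lg, -lg])
        K = K + sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    M = lumped_mass(
        model.nodes,
        model.elements,
        None if line_el is None else np.asarray(line_el),
        line_area,
    )
    active = model.region != "EXCISED"
    return DiffusionOperator(K.tocsr(), M, active)


# ---------------------------------------------------------------------------
# Per-node cell-parameter tables


def _resolve_cell_key(region: str, layer: str | None, cells: Mapping[str, CellParams]) -> str:
    if region == "HZ" and layer is not None:
        key = f"HZ_{layer}"
        if key in cells:
            return key
    if region in cells:
        return region
    if region.startswith("HZ") and "HZ" in cells:
        return "HZ"
    if region == "HZ" and "HZ_MID" in cells:
        return "HZ_MID"  # mid-wall kinetics for unlayered healthy tissue
    if region == "EXCISED":
        return next(iter(cells))
    raise KeyError(f"no cell parameters for region {region!r}")


class _NodeKinetics:
    """Vectorized per-node surrogate kinetics tables."""

    def __init__(self, model: TissueModel, cells: Mapping[str, CellParams]):
        n = model.n_nodes
        layers = (
            model.transmural_layer
            if model.transmural_layer is not None
            else [None] * n
        )
        keys = [
            _resolve_cell_key(r, l, cells) for r, l in zip(model.region, layers)
        ]
        self.keys = np.asarray(keys)
        grab = lambda attr: np.array([getattr(cells[k], attr) for k in keys])
        self.tau_in = grab("tau_in")
        self.tau_out = grab("tau_out")
        self.tau_open = grab("tau_open")
        self.tau_close = grab("tau_close")
        self.u_gate = grab("u_gate")
        self.scale = grab("excitability_scale")
        self.u_rest = np.array([cells[k].u_rest for k in keys])
        self.v_span = grab("v_span")
        self.auto_drift = np.array([cells[k].automaticity_drift for k in keys])
        self.auto_h_fire = np.array([cells[k].automaticity_h_fire for k in keys])

    def reaction(self, u: np.ndarray, h: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
        """One explicit reaction substep: Euler on u, exact update on h.

        Written in the rest-shifted variable so regions with an elevated
        diastolic potential rest at their own exact fixed point.
        """
        ur = self.u_rest
        v = (u - ur) / (1.0 - ur)
        j_in = self.scale * h * v * v * (1.0 - v) / self.tau_in
        du = (1.0 - ur) * (j_in - v / self.tau_out)
        if self.auto_drift.any():
            du = du + self.auto_drift * ((v < self.u_gate) & (h > self.auto_h_fire))
        closing = v >= self.u_gate
        h_new = np.where(
            closing,
            h * np.exp(-dt / self.tau_close),
            1.0 + (h - 1.0) * np.exp(-dt / self.tau_open),
        )
        return u + dt * du, h_new


# ---------------------------------------------------------------------------
# Time integration


def run(
    model: TissueModel,
    cond: ConductivityField | None,
    cells: Mapping[str, CellParams],
    stimuli: Sequence[StimulusEvent],
    config: SolverConfig,
    initial: Mapping[str, CellState] | tuple[np.ndarray, np.ndarray] | None = None,
    stop_nodes: np.ndarray | None = None,
    stop_margin: float = 5.0,
    operator: DiffusionOperator | None = None,
    stop_quiescent: float | None = 50.0,
) -> SimulationResult:
    """Integrate the monodomain equation.  Deterministic given its inputs.

    Godunov splitting per step: explicit reaction (+ stimulus), then an
    implicit lumped-mass diffusion solve.  Activation events (upward
    crossings of the threshold) are recorded at full dt resolution with
    linear interpolation; the potential is sampled every ``sampling`` ms
    when ``store_u`` is on.  If ``stop_nodes`` is given, integration ends
    ``stop_margin`` ms after all of them have activated.
    """
    op = operator if operator is not None else assemble_operator(model, cond)
    kin = _NodeKinetics(model, cells)
    n = model.n_nodes
    thr = config.activation_threshold
    dt = config.dt

    u = kin.u_rest.copy()
    h = np.ones(n)
    if initial is not None:
        if isinstance(initial, tuple):
            u, h = initial[0].copy(), initial[1].copy()
        else:
            for i, k in enumerate(kin.keys):
                st = initial.get(k)
                if st is not None:
                    u[i], h[i] = st.u, st.h
    inactive = ~op.active
    u[inactive] = kin.u_rest[inactive]

    j_stim = np.array(
        [stimulus_du(s.amplitude, CellParams(), config.capacitance) for s in stimuli]
    )
    n_steps = int(round(config.end_time / dt))
    stride = max(1, int(round(config.sampling / dt)))
    n_samples = n_steps // stride + 1
    u_store = (
        np.empty((n_samples, n), dtype=config.store_dtype) if config.store_u else None
    )
    sample_times = np.empty(n_samples)
    events_node: list[int] = []
    events_time: list[float] = []
    stop_deadline = np.inf
    last_stim_end = max((s.start + s.duration for s in stimuli), default=0.0)

    si = 0
    for k in range(n_steps + 1):
        t = k * dt
        if k % stride == 0 and si < n_samples:
            sample_times[si] = t
            if u_store is not None:
                u_store[si] = u
            si += 1
        if k == n_steps or t >= stop_deadline:
            break
        u_prev = u
        u, h = kin.reaction(u, h, dt)
        for s, js in zip(stimuli, j_stim):
            if s.start <= t < s.start + s.duration:
                u[s.nodes] += dt * js
        u[inactive] = kin.u_rest[inactive]
        u = op.step(u, dt)
        u[inactive] = kin.u_rest[inactive]
        crossed = (u_prev < thr) & (u >= thr)
        if crossed.any():
            ids = np.nonzero(crossed)[0]
            frac = (thr - u_prev[ids]) / (u[ids] - u_prev[ids])
            for nid, f in zip(ids, frac):
                events_node.append(int(nid))
                events_time.append(t + dt * f)
        if k % 200 == 0 and not np.isfinite(u).all():
            raise RuntimeError(f"solver diverged (non-finite potential) at t={t:.2f} ms")
        if (
            stop_quiescent is not None
            and k % stride == 0
            and t > last_stim_end + stop_quiescent
            and np.max(np.abs(u - kin.u_rest)) < 0.02
        ):
            # tissue fully at rest with no stimulus pending: nothing can
            # re-activate, so the remaining window is provably quiet
            break
        if stop_nodes is not None and np.isinf(stop_deadline) and k % stride == 0:
            acted = np.zeros(n, dtype=bool)
            if events_node:
                acted[np.asarray(events_node)] = True
            if acted[stop_nodes].all():
                stop_deadline = t + stop_margin

    activations: list[np.ndarray] = [np.empty(0)] * n
    if events_node:
        en = np.asarray(events_node)
        et = np.asarray(events_time)
        order = np.argsort(en, kind="stable")
        en, et = en[order], et[order]
        bounds = np.searchsorted(en, np.arange(n + 1))
        activations = [
            np.sort(et[bounds[i] : bounds[i + 1]]) for i in range(n)
        ]
    return SimulationResult(
        times=sample_times[:si],
        u=None if u_store is None else u_store[:si],
        activations=activations,
        meta={"dt": dt, "end_time": config.end_time, "n_nodes": n},
    )


# ---------------------------------------------------------------------------
# Strand harness


def build_strand(length: float = 20.0, dx: float = 0.1) -> TissueModel:
    """1D cable of healthy nodes used for CV calibration and measurement."""
    n = int(round(length / dx)) + 1
    nodes = np.linspace(0.0, length, n)[:, None]
    elements = np.column_stack([np.arange(n - 1), np.arange(1, n)]).astype(np.int64)
    region = np.full(n, "HZ", dtype="<U8")
    return TissueModel(nodes=nodes, elements=elements, region=region, fiber=None)


def _strand_operator(model: TissueModel, d_mm2_ms: float) -> DiffusionOperator:
    K = line_stiffness(
        model.nodes,
        model.elements,
        np.full(len(model.elements), d_mm2_ms),
        area=1.0,
    )
    M = np.zeros(model.n_nodes)
    L = _element_measure(model.nodes, model.elements)
    np.add.at(M, model.elements.ravel(), np.repeat(L / 2.0, 2))
    return DiffusionOperator(K, M, np.ones(model.n_nodes, dtype=bool))


def measure_strand_cv(
    params: CellParams,
    diffusion_cm2_ms: float,
    length: float = 20.0,
    dx: float = 0.1,
    probes: tuple[float, float] = (5.0, 15.0),
    dt: float = 0.02,
    end_time: float = 500.0,
    stim_amplitude: float = 80.0,
) -> float | None:
    """Planar conduction velocity on a 1D strand, in cm/s.

    Stimulates one end and divides the probe separation by the
    activation-time difference (1 mm/ms = 100 cm/s).  Returns ``None``
    when the wave fails to reach the distal probe (conduction block),
    which is an explicit outcome distinct from zero velocity.
    """
    model = build_strand(length, dx)
    op = _strand_operator(model, CM2_TO_MM2 * diffusion_cm2_ms)
    kin = _NodeKinetics(model, {"HZ": params})
    n = model.n_nodes
    x = model.nodes[:, 0]
    stim_nodes = np.nonzero(x <= 0.5 + 1e-9)[0]
    p1 = int(np.argmin(np.abs(x - probes[0])))
    p2 = int(np.argmin(np.abs(x - probes[1])))
    thr = 0.5
    j_stim = stimulus_du(stim_amplitude, params)

    u = kin.u_rest.copy()
    h = np.ones(n)
    t_act = {p1: None, p2: None}
    n_steps = int(round(end_time / dt))
    for k in range(n_steps):
        t = k * dt
        u_prev_p1, u_prev_p2 = u[p1], u[p2]
        u, h = kin.reaction(u, h, dt)
        if t < 1.0:
            u[stim_nodes] += dt * j_stim
        u = op.step(u, dt)
        for p, up in ((p1, u_prev_p1), (p2, u_prev_p2)):
            if t_act[p] is None and up < thr <= u[p]:
                t_act[p] = t + dt * (thr - up) / (u[p] - up)
        if t_act[p1] is not None and t_act[p2] is not None:
            break
        if k % 500 == 0:
            if not np.isfinite(u).all():
                return None
            if t > 20.0 and u.max() < 0.3:
                break  # wave extinguished: conduction block
    if t_act[p1] is None or t_act[p2] is None:
        return None
    delta_t = t_act[p2] - t_act[p1]
    if delta_t <= 0:
        return None
    cv_mm_ms = (x[p2] - x[p1]) / delta_t
    return float(MM_MS_TO_CM_S * cv_mm_ms)
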