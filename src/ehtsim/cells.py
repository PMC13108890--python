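"""Region-specific surrogate ionic kinetics.

A single two-variable excitable model family (Mitchell–Schaeffer class)
stands in for the detailed porcine, conduction-system and hiPSC-CM ionic
models.  The normalized transmembrane variable ``u`` rises from ~0 (rest)
to ~1 (plateau); a recovery gate ``h`` closes during the plateau and
reopens during diastole:

    du/dt = s * h * u^2 (1 - u) / tau_in  -  u / tau_out  +  J_stim
    dh/dt = (1 - h) / tau_open            if u <  u_gate
          = -h / tau_close                if u >= u_gate

``s`` (``excitability_scale``) multiplies the fast depolarizing current and
plays the role of the fast-Na conductance: the border zone uses s = 0.38,
mirroring post-infarct Na-current down-regulation.  ``tau_close`` sets the
action-potential duration and is calibrated per region so that the prepaced
APD90 hits the region's target (healthy 196-218 ms across wall layers,
border zone 384 ms, conduction system 310 ms, engineered heart tissue
405 ms).  Conduction velocity is calibrated at the tissue level by
adjusting the upstroke rate (see :func:`calibrate_cv`).

All acceptance is against emergent quantities (APD90, planar CV), never
against internal currents.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable

import numpy as np

__all__ = [
    "CellParams",
    "CellState",
    "PrepaceResult",
    "reaction_rate",
    "integrate_cell",
    "measure_apd90",
    "prepace",
    "calibrate_apd",
    "calibrate_cv",
    "default_params",
    "load_calibration",
    "HZ_LAYER_APD_TARGETS",
]

#: Default per-layer APD90 targets (ms) for healthy myocardium; the printed
#: healthy range spans 196-218 ms across transmural/apicobasal layers.
HZ_LAYER_APD_TARGETS = {"ENDO": 218.0, "MID": 207.0, "EPI": 196.0}


@dataclass(frozen=True)
class CellParams:
    """Surrogate membrane-kinetics parameters for one tissue region.

    Times in ms, voltages in mV.  ``excitability_scale`` is the
    dimensionless multiplier on the depolarizing current (1.0 = healthy
    default, 0.38 = border zone).  ``resting_potential_offset`` lifts the
    diastolic potential (conduction system only).  ``automaticity_cl``
    enables a slow intrinsic depolarizing drift with roughly that cycle
    length (immature-graft option, off by default).
    """

    region: str = "HZ"
    tau_in: float = 0.1
    tau_out: float = 3.0
    tau_open: float = 80.0
    tau_close: float = 70.0
    u_gate: float = 0.13
    excitability_scale: float = 1.0
    apd_target: float | None = None
    resting_potential_offset: float = 0.0
    automaticity_cl: float | None = None
    v_rest: float = -85.0
    v_peak: float = 25.0

    def __post_init__(self) -> None:
        if not (0.0 < self.excitability_scale <= 1.0):
            raise ValueError(
                f"excitability_scale must be in (0, 1], got {self.excitability_scale}"
            )
        if self.apd_target is not None and self.apd_target <= 0:
            raise ValueError("apd_target must be positive")
        for name in ("tau_in", "tau_out", "tau_open", "tau_close"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def v_span(self) -> float:
        return self.v_peak - self.v_rest

    @property
    def excitation_threshold(self) -> float:
        """Approximate foot of the excitation threshold: below
        tau_in / (s · tau_out) the resting leak dominates the regenerative
        current, so the rest state is locally stable.  Kept well below
        ``u_gate`` by tying tau_out to tau_in during calibration."""
        return self.tau_in / (self.excitability_scale * self.tau_out)

    @property
    def automaticity_drift(self) -> float:
        """Magnitude of the gate-weighted diastolic drift current.

        The drift is active only below ``u_gate`` and once the recovery
        gate has reopened past :attr:`automaticity_h_fire`, so the slow
        tau_open recovery sets the diastolic interval.  The mapping from
        ``automaticity_cl`` saturates for very long targets (the gate
        approaches 1 exponentially); the tested contract is a slow
        intrinsic rhythm (cycle length above the 600 ms pacing cycle)
        and overdrive suppression under pacing, not the exact rate.
        """
        if not self.automaticity_cl:
            return 0.0
        return 1.2 * self.u_gate / self.tau_out

    @property
    def automaticity_h_fire(self) -> float:
        """Gate-recovery level at which the diastolic drift switches on."""
        if not self.automaticity_cl:
            return 2.0  # sentinel: never reached
        apd = self.apd_target if self.apd_target else 2.0 * self.tau_close
        di = max(self.automaticity_cl - apd, 1.0)
        return min(1.0 - 0.8 * np.exp(-di / self.tau_open), 0.9999)

    @property
    def u_rest(self) -> float:
        """Normalized diastolic level implied by the resting offset."""
        return self.resting_potential_offset / self.v_span

    def to_mv(self, u: np.ndarray | float) -> np.ndarray | float:
        return self.v_rest + np.asarray(u) * self.v_span


@dataclass
class CellState:
    """Instantaneous state: normalized potential ``u`` and gate ``h``."""

    u: float = 0.0
    h: float = 1.0


@dataclass
class PrepaceResult:
    steady_state: CellState
    apd90: float | None
    beats_used: int
    converged: bool
    apd_history: list = field(default_factory=list)


def reaction_rate(
    u: np.ndarray | float,
    h: np.ndarray | float,
    params: CellParams,
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Time derivatives (du/dt, dh/dt) of the surrogate kinetics.

    Vectorized over ``u``/``h``.  At rest (u = u_rest, h = 1) both
    derivatives vanish unless automaticity is enabled.
    """
    u = np.asarray(u, dtype=float)
    h = np.asarray(h, dtype=float)
    # dynamics are written in the rest-shifted variable v so an elevated
    # diastolic potential (conduction system) is an exact fixed point
    ur = params.u_rest
    v = (u - ur) / (1.0 - ur)
    j_in = params.excitability_scale * h * v * v * (1.0 - v) / params.tau_in
    j_out = -v / params.tau_out
    du = (1.0 - ur) * (j_in + j_out)
    if params.automaticity_cl is not None:
        du = du + params.automaticity_drift * ((v < params.u_gate) & (h > params.automaticity_h_fire))
    closing = v >= params.u_gate
    dh = np.where(closing, -h / params.tau_close, (1.0 - h) / params.tau_open)
    if u.ndim == 0:
        return float(du), float(dh)
    return du, dh


def stimulus_du(amplitude_ua_cm2: float, params: CellParams, cm_uf_cm2: float = 1.0) -> float:
    """Convert a stimulus current density to a rate of change of ``u``.

    amplitude / Cm gives dV/dt in mV/ms; dividing by the voltage span
    (v_peak - v_rest) yields the normalized rate.
    """
    return amplitude_ua_cm2 / cm_uf_cm2 / params.v_span


try:  # optional acceleration; the pure-python path is numerically identical
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap(args[0]) if args and callable(args[0]) else wrap


@_njit(cache=True)
def _cell_loop(
    u: float,
    h: float,
    n_steps: int,
    dt: float,
    stride: int,
    tau_in: float,
    tau_out: float,
    tau_open: float,
    tau_close: float,
    u_gate: float,
    scale: float,
    u_rest: float,
    drift: float,
    h_fire: float,
    stim_starts: np.ndarray,
    stim_duration: float,
    j_stim: float,
    samples: np.ndarray,
):
    si = 0
    for k in range(n_steps + 1):
        t = k * dt
        if k % stride == 0:
            samples[si] = u
            si += 1
        if k == n_steps:
            break
        v = (u - u_rest) / (1.0 - u_rest)
        j_in = scale * h * v * v * (1.0 - v) / tau_in
        du = (1.0 - u_rest) * (j_in - v / tau_out)
        if drift > 0.0 and v < u_gate and h > h_fire:
            du += drift
        if v >= u_gate:
            dh = -h / tau_close
        else:
            dh = (1.0 - h) / tau_open
        for s in range(stim_starts.shape[0]):
            if stim_starts[s] <= t < stim_starts[s] + stim_duration:
                du += j_stim
                break
        u += dt * du
        h += dt * dh
        if h < 0.0:
            h = 0.0
        elif h > 1.0:
            h = 1.0
    return u, h


def integrate_cell(
    params: CellParams,
    duration: float,
    dt: float = 0.02,
    stim_times: tuple[float, ...] = (),
    stim_amplitude: float = 80.0,
    stim_duration: float = 1.0,
    initial: CellState | None = None,
    sample_every: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, CellState]:
    """Forward-Euler integration of a single cell.

    Returns (sample times, u samples, final state).  Deterministic.
    """
    state = initial or CellState(u=params.u_rest, h=1.0)
    n_steps = int(round(duration / dt))
    stride = max(1, int(round(sample_every / dt)))
    j_stim = stimulus_du(stim_amplitude, params)
    stim_arr = np.asarray(stim_times, dtype=np.float64)
    n_samples = n_steps // stride + 1
    samples = np.empty(n_samples)
    u, h = _cell_loop(
        float(state.u),
        float(state.h),
        n_steps,
        dt,
        stride,
        params.tau_in,
        params.tau_out,
        params.tau_open,
        params.tau_close,
        params.u_gate,
        params.excitability_scale,
        params.u_rest,
        params.automaticity_drift,
        params.automaticity_h_fire,
        stim_arr,
        stim_duration,
        j_stim,
        samples,
    )
    times = np.arange(n_samples) * (stride * dt)
    return times, samples, CellState(u=u, h=h)


def measure_apd90(
    trace: np.ndarray,
    times: np.ndarray | None = None,
    dt: float = 1.0,
    baseline: float | None = None,
) -> float | None:
    """APD at 90% repolarization from a sampled trace.

    Duration from upstroke onset to 90% return toward the pre-stimulus
    baseline, i.e. between the upward and downward crossings of the
    10%-of-amplitude level, with linear interpolation between samples.
    Returns None when no action potential is present.
    """
    trace = np.asarray(trace, dtype=float)
    if times is None:
        times = np.arange(trace.size) * dt
    if trace.size < 3:
        return None
    base = float(trace[0]) if baseline is None else baseline
    peak = float(np.max(trace))
    amplitude = peak - base
    if amplitude < 0.3:  # no full-amplitude AP in a normalized trace
        return None
    level = base + 0.1 * amplitude
    above = trace > level
    ups = np.nonzero(~above[:-1] & above[1:])[0]
    if ups.size == 0:
        return None
    i = ups[0]
    t_up = np.interp(level, [trace[i], trace[i + 1]], [times[i], times[i + 1]])
    downs = np.nonzero(above[:-1] & ~above[1:])[0]
    downs = downs[downs >= i]
    if downs.size == 0:
        return None
    j = downs[0]
    t_down = times[j] + (times[j + 1] - times[j]) * (trace[j] - level) / (
        trace[j] - trace[j + 1]
    )
    return float(t_down - t_up)


def prepace(
    params: CellParams,
    cycle_length: float = 600.0,
    stim_amplitude: float = 80.0,
    stim_duration: float = 1.0,
    tol: float = 0.1,
    max_beats: int = 50,
    dt: float = 0.02,
) -> PrepaceResult:
    """Pace a single cell until APD90 is constant across consecutive beats.

    The surrogate has no slow ion-concentration memory, so convergence
    takes a handful of beats rather than the thousands a biophysically
    detailed model needs.
    """
    state = CellState(u=params.u_rest, h=1.0)
    history: list[float] = []
    unmeasured_streak = 0
    for beat in range(1, max_beats + 1):
        times, trace, state = integrate_cell(
            params,
            cycle_length,
            dt=dt,
            stim_times=(0.0,),
            stim_amplitude=stim_amplitude,
            stim_duration=stim_duration,
            initial=state,
            sample_every=0.5,
        )
        apd = measure_apd90(trace, times)
        if apd is None:
            if np.max(trace) - trace[0] < 0.3:
                # stimulus never captured the cell
                return PrepaceResult(state, None, beat, False, history)
            # plateau outlasted the cycle window on this beat (long first
            # beats from fully recovered gates); keep pacing — the gate
            # keeps shortening subsequent beats
            unmeasured_streak += 1
            if unmeasured_streak >= 5:
                return PrepaceResult(state, None, beat, False, history)
            continue
        unmeasured_streak = 0
        history.append(apd)
        if len(history) >= 2 and abs(history[-1] - history[-2]) < tol:
            return PrepaceResult(state, apd, beat, True, history)
    return PrepaceResult(state, history[-1] if history else None, max_beats, False, history)


def calibrate_apd(
    params: CellParams,
    target: float,
    cycle_length: float = 600.0,
    tol: float = 1.0,
    bracket: tuple[float, float] | None = None,
    max_iter: int = 60,
) -> CellParams:
    """Bisection on ``tau_close`` so the prepaced APD90 equals ``target``.

    Deterministic; rejects targets outside the achievable bracket.  The
    default upper bracket stays below 0.75 × cycle length, where paced
    APD is monotone in tau_close; beyond it 2:1-like alternans sets in
    and the steady APD becomes non-monotone.
    """
    if target <= 0:
        raise ValueError("APD target must be positive")
    if bracket is None:
        bracket = (10.0, 0.75 * cycle_length)

    def apd_of(tau_close: float) -> float | None:
        p = replace(params, tau_close=tau_close, apd_target=target)
        return prepace(p, cycle_length=cycle_length).apd90

    lo, hi = bracket
    a_lo = apd_of(lo)
    if a_lo is None:
        raise ValueError(f"no capture at tau_close={lo}; cannot calibrate")
    # Walk the upper bracket out of the alternans regime: past a critical
    # tau_close the paced cell falls into 2:1-like rhythms whose measured
    # APD collapses below a_lo, breaking monotonicity.
    a_hi = apd_of(hi)
    for _ in range(15):
        if a_hi is not None and a_hi < a_lo:
            hi *= 0.85
            a_hi = apd_of(hi)
        else:
            break
    # a None APD at the upper end means the plateau outlasts the pacing
    # cycle, i.e. the achievable APD exceeds any measurable target
    if a_hi is None:
        a_hi = np.inf
    if not (a_lo <= target <= a_hi):
        raise ValueError(
            f"APD target {target} ms outside achievable bracket "
            f"[{a_lo}, {a_hi}] ms for tau_close in [{lo}, {hi}]"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        a_mid = apd_of(mid)
        if a_mid is None or a_mid > target or a_mid < a_lo:
            hi = mid
        elif abs(a_mid - target) < 0.5 * tol:
            break
        else:
            lo = mid
    else:
        mid = 0.5 * (lo + hi)
    return replace(params, tau_close=mid, apd_target=target)


def calibrate_cv(
    params: CellParams,
    diffusion_cm2_ms: float,
    target_cm_s: float,
    vary: str = "tau_in",
    tol_rel: float = 0.02,
    bracket: tuple[float, float] | None = None,
    max_iter: int = 40,
    **strand_kwargs,
) -> CellParams:
    """Root-find on the upstroke-rate parameter so planar strand CV hits
    ``target_cm_s`` at the given diffusion coefficient.

    ``vary='tau_in'`` adjusts the base upstroke time constant (used for
    the healthy calibration, keeping excitability_scale at 1 so the border
    zone's 38% scaling stays meaningful); ``vary='excitability_scale'``
    adjusts the Na-like multiplier directly.  CV is monotone decreasing in
    tau_in and increasing in excitability_scale.
    """
    from .monodomain import measure_strand_cv  # deferred: avoids cycle

    # varying tau_in keeps tau_out / tau_in fixed so the excitation
    # threshold tau_in/(s*tau_out) — and with it rest-state stability —
    # is preserved while the upstroke rate changes
    ratio = params.tau_out / params.tau_in

    def make(value: float) -> CellParams:
        if vary == "tau_in":
            return replace(params, tau_in=value, tau_out=ratio * value)
        return replace(params, **{vary: value})

    def cv_of(value: float) -> float | None:
        return measure_strand_cv(make(value), diffusion_cm2_ms, **strand_kwargs)

    if vary == "tau_in":
        lo, hi = bracket or (0.02, 2.0)
        increasing = False
    elif vary == "excitability_scale":
        lo, hi = bracket or (0.02, 1.0)
        increasing = True
    else:
        raise ValueError(f"cannot calibrate CV by varying {vary!r}")

    cv_lo, cv_hi = cv_of(lo), cv_of(hi)
    achievable = sorted(v for v in (cv_lo, cv_hi) if v is not None)
    lo_cv = min(achievable) if achievable else None
    hi_cv = max(achievable) if achievable else None
    if lo_cv is None or not (lo_cv <= target_cm_s <= hi_cv):
        raise ValueError(
            f"CV target {target_cm_s} cm/s unreachable; achieved range "
            f"[{cv_lo}, {cv_hi}] cm/s over {vary} in [{lo}, {hi}]"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        cv_mid = cv_of(mid)
        if cv_mid is not None and abs(cv_mid - target_cm_s) < tol_rel * target_cm_s * 0.5:
            break
        too_slow = cv_mid is None or cv_mid < target_cm_s
        if too_slow == increasing:
            lo = mid
        else:
            hi = mid
    else:
        mid = 0.5 * (lo + hi)
    return make(mid)


# ---------------------------------------------------------------------------
# Shipped default calibration


def load_calibration() -> dict[str, CellParams]:
    """Load the shipped default calibration (region -> CellParams).

    Regenerate from scratch with ``ehtsim calibrate``.
    """
    text = resources.files("ehtsim.data").joinpath("default_calibration.json").read_text()
    raw = json.loads(text)
    out = {}
    for region, kw in raw["regions"].items():
        out[region] = CellParams(**kw)
    return out


def default_params(region: str) -> CellParams:
    """Default calibrated parameters for a region label.

    Region labels: HZ (alias of HZ_MID), HZ_ENDO/HZ_MID/HZ_EPI, BZ, CS,
    EHT.
    """
    cal = load_calibration()
    key = "HZ_MID" if region == "HZ" else region
    if key not in cal:
        raise KeyError(f"no default calibration for region {region!r}")
    return cal[key]
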