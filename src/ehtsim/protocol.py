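"""Arrhythmia-inducibility protocol (AIP) and inducibility score.

Programmed stimulation from each pacing site: a train of S1 stimuli
(default 4 at 600 ms) followed by one premature extrastimulus S2 at a
configurable coupling interval (defaults 250/265/280/295 ms), delivered
on prepaced initial states.  Each trial is classified as

* NC   — the extrastimulus failed to capture (excluded from scoring);
* NR   — capture but no reentry (the wave expands and extinguishes);
* nsVT — reentrant activity that dies out before the sustainment horizon;
* sVT  — activity maintained 2 s after S2.

The inducibility score aggregates trials as IS = Σ c_i / (3 N) with c =
0 (NR), 1 (nsVT), 3 (sVT) over the N included (non-NC) trials, so IS
spans [0, 1]: 0 when nothing reenters, 0.33 when every trial is
non-sustained, 1 when every trial sustains.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cells import CellParams, CellState, prepace
from .geometry import TissueModel
from .monodomain import (
    ConductivityField,
    SimulationResult,
    SolverConfig,
    StimulusEvent,
    run,
)

__all__ = [
    "AIPConfig",
    "TrialOutcome",
    "ISReport",
    "run_trial",
    "detect_capture",
    "classify_outcome",
    "compute_is",
    "run_campaign",
    "prepaced_states",
]

C_VALUES = {"NR": 0, "nsVT": 1, "sVT": 3}


@dataclass(frozen=True)
class AIPConfig:
    n_s1: int = 4
    s1_cycle: float = 600.0
    s2_offsets: tuple[float, ...] = (250.0, 265.0, 280.0, 295.0)
    stim_amplitude: float = 80.0
    stim_duration: float = 1.0
    observe_window: float = 2500.0
    sustain_threshold: float = 2000.0
    capture_latency: float = 50.0
    reentry_fraction: float = 0.01
    dt: float = 0.05

    def __post_init__(self):
        if any(o >= self.s1_cycle for o in self.s2_offsets):
            raise ValueError("S2 offsets must be shorter than the S1 cycle")
        if self.observe_window < self.sustain_threshold:
            raise ValueError("observation window must cover the sustainment horizon")

    def s2_time(self, offset: float) -> float:
        return (self.n_s1 - 1) * self.s1_cycle + offset


@dataclass
class TrialOutcome:
    label: str  # NC, NR, nsVT, sVT (or INVALID on solver failure)
    site: int
    s2_offset: float
    c: int | None = None
    reactivated_fraction: float = 0.0
    last_activity: float = -np.inf
    scenario: str = ""
    note: str = ""

    def __post_init__(self):
        if self.label in C_VALUES:
            self.c = C_VALUES[self.label]
        else:
            self.c = None  # NC and INVALID are excluded from scoring


@dataclass
class ISReport:
    n_included: int
    score: float | None
    table: pd.DataFrame
    by_group: pd.DataFrame | None = None
    note: str = ""


def prepaced_states(cells: Mapping[str, CellParams], cycle: float = 600.0) -> dict[str, CellState]:
    """Single-cell steady states per region, used as tissue initial values."""
    return {k: prepace(p, cycle_length=cycle).steady_state for k, p in cells.items()}


def run_trial(
    model: TissueModel,
    cond: ConductivityField | None,
    cells: Mapping[str, CellParams],
    site: np.ndarray,
    s2_offset: float,
    config: AIPConfig = AIPConfig(),
    initial: Mapping[str, CellState] | None = None,
    site_id: int = 0,
    scenario: str = "",
    store_u: bool = False,
    operator=None,
) -> tuple[SimulationResult, TrialOutcome]:
    """One S1–S2 trial from one pacing site.  Deterministic.

    The S1 train is delivered at the tissue level on top of single-cell
    prepaced states (the surrogate kinetics carry no long-term pacing
    memory, so a short train reaches the tissue steady state).
    """
    if initial is None:
        initial = prepaced_states(cells, config.s1_cycle)
    s2_time = config.s2_time(s2_offset)
    stimuli = [
        StimulusEvent(
            nodes=site,
            start=k * config.s1_cycle,
            duration=config.stim_duration,
            amplitude=config.stim_amplitude,
        )
        for k in range(config.n_s1)
    ]
    stimuli.append(
        StimulusEvent(
            nodes=site,
            start=s2_time,
            duration=config.stim_duration,
            amplitude=config.stim_amplitude,
        )
    )
    solver = SolverConfig(
        end_time=s2_time + config.observe_window,
        dt=config.dt,
        store_u=store_u,
    )
    try:
        result = run(model, cond, cells, stimuli, solver, initial=initial, operator=operator)
    except RuntimeError as exc:
        return None, TrialOutcome(
            label="INVALID", site=site_id, s2_offset=s2_offset, scenario=scenario,
            note=str(exc),
        )
    outcome = classify_outcome(
        result, model, site, s2_time, config, site_id=site_id, scenario=scenario,
        s2_offset=s2_offset,
    )
    return result, outcome


def detect_capture(
    result: SimulationResult,
    model: TissueModel,
    site: np.ndarray,
    s2_time: float,
    config: AIPConfig = AIPConfig(),
    site_radius: float = 1.0,
) -> bool:
    """True when the extrastimulus elicited a propagated response.

    Captured iff nodes outside a guard radius (2× the pacing-site radius)
    around the site centroid show a fresh activation within the capture
    latency window after S2.
    """
    xy = model.nodes[:, :2]
    centroid = xy[site].mean(axis=0)
    guard = 2.0 * site_radius
    outside = np.linalg.norm(xy - centroid, axis=1) > guard
    outside &= model.region != "EXCISED"
    t0, t1 = s2_time, s2_time + config.capture_latency
    for i in np.nonzero(outside)[0]:
        a = result.activations[i]
        if a.size and ((a > t0) & (a <= t1)).any():
            return True
    return False


def classify_outcome(
    result: SimulationResult,
    model: TissueModel,
    site: np.ndarray,
    s2_time: float,
    config: AIPConfig = AIPConfig(),
    site_id: int = 0,
    scenario: str = "",
    s2_offset: float | None = None,
) -> TrialOutcome:
    """Classify a completed trial from its activation-event set only.

    Reentry detection: the direct S2 wavefront reaches everything within
    one tissue traversal, estimated as the 99th percentile of first
    post-S2 activation times; a node *re-activates* if it fires at least
    twice after S2 with activity beyond that horizon.  Reentry is called
    when at least ``reentry_fraction`` of the post-S2-activated nodes
    re-activate (robust to boundary echo); sustained (sVT) when any
    activity persists to the 2 s sustainment horizon.
    """
    off = s2_time if s2_offset is None else s2_offset
    if not detect_capture(result, model, site, s2_time, config):
        return TrialOutcome(label="NC", site=site_id, s2_offset=off, scenario=scenario)

    active_mask = model.region != "EXCISED"
    first_post = result.first_activation(t_min=s2_time + 1e-9)
    first_post[~active_mask] = np.nan
    activated = np.isfinite(first_post)
    if not activated.any():
        return TrialOutcome(label="NR", site=site_id, s2_offset=off, scenario=scenario)
    horizon = float(np.nanpercentile(first_post, 99.0))

    n_re = 0
    last_activity = -np.inf
    for i in np.nonzero(activated)[0]:
        a = result.activations[i]
        post = a[a > s2_time]
        if post.size:
            last_activity = max(last_activity, post[-1])
        if post.size >= 2 and post[-1] > horizon:
            n_re += 1
    frac = n_re / activated.sum()
    reentry = frac >= config.reentry_fraction

    if last_activity >= s2_time + config.sustain_threshold:
        label = "sVT"
    elif reentry:
        label = "nsVT"
    else:
        label = "NR"
    return TrialOutcome(
        label=label,
        site=site_id,
        s2_offset=off,
        reactivated_fraction=float(frac),
        last_activity=float(last_activity),
        scenario=scenario,
    )


def compute_is(outcomes: Sequence[TrialOutcome]) -> ISReport:
    """Aggregate the inducibility score, excluding NC (and INVALID) trials."""
    rows = [
        {
            "scenario": o.scenario,
            "site": o.site,
            "s2_offset": o.s2_offset,
            "label": o.label,
            "c": o.c,
            "reactivated_fraction": o.reactivated_fraction,
            "last_activity": o.last_activity,
        }
        for o in outcomes
    ]
    table = pd.DataFrame(rows)
    included = [o for o in outcomes if o.c is not None]
    if not included:
        return ISReport(
            n_included=0,
            score=None,
            table=table,
            note="no included trials (all NC/invalid); IS undefined",
        )
    score = Fraction(sum(o.c for o in included), 3 * len(included))
    by_group = None
    if len(table):
        inc = table[table["c"].notna()]
        if len(inc):
            by_group = (
                inc.groupby(["scenario", "s2_offset"])
                .apply(
                    lambda g: float(g["c"].sum()) / (3.0 * len(g)),
                    include_groups=False,
                )
                .rename("IS")
                .reset_index()
            )
    return ISReport(
        n_included=len(included),
        score=float(score),
        table=table,
        by_group=by_group,
    )


# ---------------------------------------------------------------------------
# Campaigns


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_campaign(
    variants: Mapping[str, tuple[TissueModel, ConductivityField | None, Mapping[str, CellParams]]],
    sites: Sequence[np.ndarray],
    config: AIPConfig = AIPConfig(),
    s2_offsets: Sequence[float] | None = None,
    cache_dir: str | Path | None = None,
) -> dict[str, ISReport]:
    """Deterministic sites × S2 × variant sweep with per-trial caching.

    Trials are cached (JSON) keyed by a hash of the variant name, site
    membership, offset and protocol config; reruns with an identical
    configuration reuse cached outcomes and mismatched caches are never
    mixed (the hash is the filename).
    """
    offsets = tuple(s2_offsets if s2_offsets is not None else config.s2_offsets)
    cache = Path(cache_dir) if cache_dir else None
    if cache:
        cache.mkdir(parents=True, exist_ok=True)
    reports: dict[str, ISReport] = {}
    for name, (model, cond, cells) in variants.items():
        initial = prepaced_states(cells, config.s1_cycle)
        from .monodomain import assemble_operator

        operator = assemble_operator(model, cond)
        outcomes = []
        for site_id, site in enumerate(sites):
            for off in offsets:
                key = _config_hash(
                    {
                        "variant": name,
                        "site": np.asarray(site).tolist(),
                        "offset": off,
                        "config": repr(config),
                        "n_nodes": model.n_nodes,
                    }
                )
                entry = cache / f"trial_{key}.json" if cache else None
                if entry and entry.exists():
                    data = json.loads(entry.read_text())
                    o = TrialOutcome(
                        label=data["label"],
                        site=site_id,
                        s2_offset=off,
                        scenario=name,
                    )
                    o.reactivated_fraction = data["reactivated_fraction"]
                    o.last_activity = data["last_activity"]
                else:
                    _, o = run_trial(
                        model,
                        cond,
                        cells,
                        np.asarray(site),
                        off,
                        config,
                        initial=initial,
                        site_id=site_id,
                        scenario=name,
                        operator=operator,
                    )
                    if entry:
                        entry.write_text(
                            json.dumps(
                                {
                                    "label": o.label,
                                    "reactivated_fraction": o.reactivated_fraction,
                                    "last_activity": o.last_activity,
                                }
                            )
                        )
                outcomes.append(o)
        reports[name] = compute_is(outcomes)
    return reports
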