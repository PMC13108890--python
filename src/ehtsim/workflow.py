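"""Scenario configuration, model building and provenance.

A scenario is a structured text (YAML) document describing the synthetic
geometry, infarct, optional graft and conduction system, pacing layout
and stimulation protocol.  ``build_scenario`` turns it into the runnable
objects; ``run_scenario`` executes the trial set and reports the
inducibility score.  Every artifact written carries the configuration
hash, package version and seed needed to regenerate it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .cells import CellParams, load_calibration
from .geometry import (
    EHTSpec,
    InfarctSpec,
    LayerThresholds,
    TissueModel,
    assign_layers,
    attach_eht,
    build_sheet,
    excise_scar,
    generate_fibers,
    label_infarct,
    select_pacing_sites,
    solve_layer_coordinates,
)
from .monodomain import ConductivityField
from .protocol import AIPConfig, compute_is, run_campaign
from .purkinje import couple_tree, generate_tree

__all__ = [
    "ScenarioSpec",
    "load_scenario",
    "shipped_scenario",
    "shipped_scenario_names",
    "build_scenario",
    "run_scenario",
    "config_hash",
]

_REQUIRED_TOP = ("name", "geometry")


@dataclass
class ScenarioSpec:
    """Validated scenario description."""

    name: str
    geometry: dict
    fibers: dict = field(default_factory=lambda: {"rule": "constant"})
    infarct: dict | None = None
    eht: dict | None = None
    cs: dict | None = None
    aip: dict = field(default_factory=dict)
    pacing: dict = field(default_factory=dict)
    expected_outcome: str | None = None
    seed: int = 0
    version: int = 1

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "ScenarioSpec":
        for key in _REQUIRED_TOP:
            if key not in raw:
                raise KeyError(f"scenario config missing required field {key!r}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown scenario fields: {sorted(unknown)}")
        return cls(**dict(raw))

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in self.__dataclass_fields__
            if getattr(self, k) is not None
        }


def config_hash(payload: Any) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def load_scenario(path: str | Path) -> ScenarioSpec:
    raw = yaml.safe_load(Path(path).read_text())
    return ScenarioSpec.from_dict(raw)


def shipped_scenario_names() -> list[str]:
    root = resources.files("ehtsim.data.scenarios")
    return sorted(p.name[: -len(".yaml")] for p in root.iterdir() if p.name.endswith(".yaml"))


def shipped_scenario(name: str) -> ScenarioSpec:
    text = resources.files("ehtsim.data.scenarios").joinpath(f"{name}.yaml").read_text()
    return ScenarioSpec.from_dict(yaml.safe_load(text))


def build_scenario(
    spec: ScenarioSpec,
) -> tuple[TissueModel, ConductivityField, dict[str, CellParams], list[np.ndarray], AIPConfig]:
    """Construct the labeled mesh, conductivity, kinetics and pacing sites."""
    geo = spec.geometry
    model = build_sheet(tuple(geo["extent"]), float(geo["resolution"]))
    if geo.get("layer_coordinates", False):
        model = solve_layer_coordinates(model)
        model = assign_layers(model, LayerThresholds())
    model = generate_fibers(model, **spec.fibers)

    infarct_center = None
    if spec.infarct:
        inf = dict(spec.infarct)
        shape = inf.pop("shape", "disk")
        sd = None
        if shape == "strip":
            # vertical transmural strip spanning the full sheet height
            x0, x1 = (float(v) for v in inf.pop("x_range"))
            inf.setdefault("center", ((x0 + x1) / 2.0, model.nodes[:, 1].mean()))
            inf.setdefault("sz_radius", (x1 - x0) / 2.0)
            sd = lambda xy: np.where((xy[:, 0] >= x0) & (xy[:, 0] <= x1), -1.0, 1.0)
        elif shape == "ellipse":
            a, b = (float(v) for v in inf.pop("semi_axes"))
            cx, cy = (float(v) for v in inf["center"])
            inf.setdefault("sz_radius", max(a, b))
            sd = lambda xy: (
                np.sqrt(((xy[:, 0] - cx) / a) ** 2 + ((xy[:, 1] - cy) / b) ** 2) - 1.0
            ) * min(a, b)
        elif shape == "channel_wall":
            # transmural wall pierced by a slow border-zone channel — the
            # classic protected-isthmus substrate
            x0, x1 = (float(v) for v in inf.pop("x_range"))
            y0, y1 = (float(v) for v in inf.pop("channel_y"))
            inf.setdefault("center", ((x0 + x1) / 2.0, model.nodes[:, 1].mean()))
            inf.setdefault("sz_radius", (x1 - x0) / 2.0)
            sd = lambda xy: np.where(
                (xy[:, 0] >= x0)
                & (xy[:, 0] <= x1)
                & ~((xy[:, 1] > y0) & (xy[:, 1] < y1)),
                -1.0,
                1.0,
            )
        elif shape != "disk":
            raise KeyError(f"unknown infarct shape {shape!r}")
        infarct_center = tuple(inf["center"])
        model = label_infarct(
            model,
            InfarctSpec(
                center=infarct_center,
                sz_radius=float(inf["sz_radius"]),
                bz_width=float(inf.get("bz_width", 0.0)),
                transmural_depth=float(inf.get("transmural_depth", 1.0)),
                signed_distance=sd,
            ),
        )
        if shape == "channel_wall":
            in_chan = (
                (model.nodes[:, 0] >= x0)
                & (model.nodes[:, 0] <= x1)
                & (model.nodes[:, 1] >= y0)
                & (model.nodes[:, 1] <= y1)
                & (model.region == "HZ")
            )
            model.region[in_chan] = "BZ"
        model = excise_scar(model)

    pacing = dict(spec.pacing)
    explicit_sites = pacing.pop("seeds", None)
    sites: list[np.ndarray]
    if explicit_sites is not None:
        radius = float(pacing.get("radius", 1.0))
        xy = model.nodes[:, :2]
        viable = ~np.isin(model.region, ("SZ", "EXCISED", "EHT", "CS"))
        ids = np.nonzero(viable)[0]
        sites = []
        for seed_xy in explicit_sites:
            d = np.linalg.norm(xy[ids] - np.asarray(seed_xy, dtype=float), axis=1)
            anchor = ids[np.argmin(d)]
            sites.append(ids[np.linalg.norm(xy[ids] - xy[anchor], axis=1) <= radius])
    else:
        sites = select_pacing_sites(
            model,
            int(pacing.get("n_sites", 1)),
            radius=float(pacing.get("radius", 1.0)),
            ring_margin=float(pacing.get("ring_margin", 2.0)),
            center=infarct_center,
        )

    eht_fraction = 0.10
    if spec.eht:
        patches = spec.eht if isinstance(spec.eht, list) else [spec.eht]
        for patch in patches:
            e = dict(patch)
            eht_fraction = float(e.get("conductivity_fraction", 0.10))
            center = e.get("center", infarct_center)
            model = attach_eht(
                model,
                EHTSpec(
                    footprint=tuple(e.get("footprint", (40.0, 40.0))),
                    thickness=float(e.get("thickness", 1.0)),
                    location=e.get("location", "L1"),
                    embed_depth=float(e.get("embed_depth", 0.55)),
                    conductivity_fraction=eht_fraction,
                ),
                center=tuple(center) if center is not None else None,
            )

    coupling = None
    if spec.cs and spec.cs.get("enabled", True):
        c = dict(spec.cs)
        c.pop("enabled", None)
        couple_kwargs = {
            k: c.pop(k) for k in ("weight_total", "radius", "taper") if k in c
        }
        tree = generate_tree(
            extent=tuple(spec.geometry["extent"]),
            root_xy=tuple(c.pop("root", (1.0, 1.0))),
            seed=int(c.pop("seed", spec.seed)),
            **c,
        )
        model, coupling = couple_tree(model, tree, **couple_kwargs)

    cond = ConductivityField.from_model(model, eht_fraction=eht_fraction)
    cells = load_calibration()
    aip = AIPConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in spec.aip.items()})
    model.meta["pmj_coupling"] = coupling
    model.meta["scenario"] = spec.name
    model.meta["config_hash"] = config_hash(spec.to_dict())
    return model, cond, cells, sites, aip


def run_scenario(
    spec: ScenarioSpec,
    s2_offsets: list[float] | None = None,
    cache_dir: str | Path | None = None,
):
    """Run the full trial set of one scenario and score it."""
    model, cond, cells, sites, aip = build_scenario(spec)
    reports = run_campaign(
        {spec.name: (model, cond, cells)},
        sites,
        config=aip,
        s2_offsets=s2_offsets,
        cache_dir=cache_dir,
    )
    report = reports[spec.name]
    report.note = json.dumps(
        {
            "config_hash": model.meta["config_hash"],
            "version": __version__,
            "seed": spec.seed,
        }
    )
    return report
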