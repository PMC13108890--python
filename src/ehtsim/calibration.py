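"""Default-calibration builder.

Pins each region's surrogate parameters to the printed emergent targets:

=======  ==========================  =========================================
region   APD90 target (600 ms CL)    conduction-velocity anchor
=======  ==========================  =========================================
HZ_ENDO  218 ms                      shared healthy upstroke rate, calibrated
HZ_MID   207 ms                      so a 1D strand at D = 0.0013 cm²/ms
HZ_EPI   196 ms                      conducts at 74.2 cm/s
BZ       384 ms                      healthy kinetics, excitability 38%
CS       310 ms                      fast cable (D = 0.013 cm²/ms); +3 mV rest
EHT      405 ms                      own upstroke rate: 12 cm/s at 10% HZ D
=======  ==========================  =========================================

The result ships as ``ehtsim/data/default_calibration.json``; regenerate
with ``ehtsim calibrate`` (deterministic bisection, no randomness).
"""

from __future__ import annotations

import json
from dataclasses import asdict, replace
from pathlib import Path

from .cells import (
    HZ_LAYER_APD_TARGETS,
    CellParams,
    calibrate_apd,
    calibrate_cv,
)

HZ_CV_TARGET = 74.2  # cm/s at D = 0.0013 cm²/ms
EHT_CV_TARGET = 12.0  # cm/s at D = 0.00013 cm²/ms (10% of healthy)
BZ_EXCITABILITY = 0.38
BZ_APD = 384.0
CS_APD = 310.0
EHT_APD = 405.0
CS_REST_OFFSET_MV = 3.0


def build_default_calibration(verbose: bool = False) -> dict[str, CellParams]:
    """Recompute the full default calibration from scratch."""
    log = print if verbose else (lambda *a, **k: None)

    base = CellParams()
    log("calibrating healthy upstroke rate to", HZ_CV_TARGET, "cm/s ...")
    hz = calibrate_cv(base, 0.0013, HZ_CV_TARGET, vary="tau_in")
    log(f"  tau_in = {hz.tau_in:.5f} ms")

    out: dict[str, CellParams] = {}
    for layer, apd in HZ_LAYER_APD_TARGETS.items():
        p = calibrate_apd(replace(hz, region=f"HZ_{layer}"), apd)
        out[f"HZ_{layer}"] = p
        log(f"  HZ_{layer}: tau_close = {p.tau_close:.2f} ms (APD {apd} ms)")

    bz = replace(hz, region="BZ", excitability_scale=BZ_EXCITABILITY)
    out["BZ"] = calibrate_apd(bz, BZ_APD)
    log(f"  BZ: tau_close = {out['BZ'].tau_close:.2f} ms")

    cs = replace(hz, region="CS", resting_potential_offset=CS_REST_OFFSET_MV)
    out["CS"] = calibrate_apd(cs, CS_APD)
    log(f"  CS: tau_close = {out['CS'].tau_close:.2f} ms")

    log("calibrating graft upstroke rate to", EHT_CV_TARGET, "cm/s ...")
    eht = calibrate_cv(replace(base, region="EHT"), 0.00013, EHT_CV_TARGET, vary="tau_in")
    out["EHT"] = calibrate_apd(eht, EHT_APD)
    log(
        f"  EHT: tau_in = {out['EHT'].tau_in:.5f} ms, "
        f"tau_close = {out['EHT'].tau_close:.2f} ms"
    )
    return out


def write_calibration(path: str | Path, cal: dict[str, CellParams]) -> None:
    payload = {"regions": {k: asdict(v) for k, v in cal.items()}}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def default_calibration_path() -> Path:
    return Path(__file__).parent / "data" / "default_calibration.json"
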