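"""Config parsing and CSV/JSON serialization of results.

Configs are flat key-value mappings (YAML or JSON) holding the model rates
(mu, beta, gamma, epsilon, p, q) and either N directly or the initial
compartments I0/S0/V0, from which N is summed.  Trajectories are written
as CSV with header t,I,S,V; scans as tidy CSV (param_value,
sample_index, I) with a JSON sidecar for periods, exponents and detected
thresholds.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .model import CompartmentState, ModelParams, Trajectory
from .stability import ScanResult

_RATE_KEYS = ("mu", "beta", "gamma", "epsilon", "p", "q")


def load_config(path: str | Path) -> dict:
    """Read a flat YAML or JSON config mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a flat key-value mapping")
    return cfg


def params_from_config(cfg: dict) -> tuple[ModelParams, CompartmentState | None]:
    """Build (ModelParams, optional initial state) from a flat config dict.

    N may be given directly or derived as I0+S0+V0.  The initial state is
    returned when I0 and S0 are present (V0 optional).
    """
    missing = [k for k in _RATE_KEYS if k not in cfg]
    if missing:
        raise ValueError(f"config missing keys: {', '.join(missing)}")
    kwargs = {k: float(cfg[k]) for k in _RATE_KEYS}
    init = None
    if "I0" in cfg and "S0" in cfg:
        I0, S0 = float(cfg["I0"]), float(cfg["S0"])
        V0 = float(cfg["V0"]) if "V0" in cfg else None
        init = CompartmentState(I=I0, S=S0, V=V0, t=0)
    if "N" in cfg:
        kwargs["N"] = float(cfg["N"])
    elif init is not None and init.V is not None:
        kwargs["N"] = init.total
    else:
        raise ValueError("config must give N or all of I0, S0, V0")
    return ModelParams(**kwargs), init


def params_to_dict(params: ModelParams) -> dict:
    return {k: getattr(params, k) for k in _RATE_KEYS + ("N",)}


def trajectory_to_frame(traj: Trajectory, N: float | None = None) -> pd.DataFrame:
    """Trajectory as a DataFrame with columns t,I,S,V (V derived if absent)."""
    rows = []
    for st in traj:
        V = st.V
        if V is None and N is not None:
            V = N - st.I - st.S
        rows.append({"t": st.t, "I": st.I, "S": st.S, "V": V})
    return pd.DataFrame(rows, columns=["t", "I", "S", "V"])


def write_trajectory_csv(traj: Trajectory, path: str | Path, N: float | None = None) -> None:
    trajectory_to_frame(traj, N=N).to_csv(path, index=False)


def scan_to_frame(scan: ScanResult) -> pd.DataFrame:
    """Tidy orbit samples: one row per (param_value, sample_index)."""
    rows = []
    for pt in scan.points:
        for k, val in enumerate(pt.samples):
            rows.append({"param_value": pt.value, "sample_index": k, "I": val})
    return pd.DataFrame(rows, columns=["param_value", "sample_index", "I"])


def write_scan(scan: ScanResult, csv_path: str | Path, json_path: str | Path,
               metadata: dict | None = None) -> None:
    """Write a scan as tidy CSV plus a JSON sidecar of summary diagnostics."""
    scan_to_frame(scan).to_csv(csv_path, index=False)
    sidecar = scan.summary_dict()
    if metadata:
        sidecar["metadata"] = metadata
    Path(json_path).write_text(json.dumps(sidecar, indent=2))


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2))
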