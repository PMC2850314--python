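"""Readers and writers for the package's plain-text formats.

Parameters travel as JSON (fixed values flagged), trial tables and TvD
tables as CSV with header rows, designs as YAML or JSON.  Densities are
serialized in linear units; log views are computed, never stored.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .model import CUED, HIGH, LOW, NONCUED, ChannelParams, TvDDataset
from .synthetic import ExperimentDesign

__all__ = [
    "params_to_dict",
    "params_from_dict",
    "write_params",
    "read_params",
    "write_trials",
    "read_trials",
    "write_design",
    "read_design",
    "config_hash",
]

_CUE_SAL_KEYS = {
    f"{CUED},{HIGH}": (CUED, HIGH),
    f"{CUED},{LOW}": (CUED, LOW),
    f"{NONCUED},{HIGH}": (NONCUED, HIGH),
    f"{NONCUED},{LOW}": (NONCUED, LOW),
}


def params_to_dict(params: ChannelParams) -> dict:
    return {
        "S_et": {f"{cue},{sal}": float(v)
                 for (cue, sal), v in dict(params.s_et).items()},
        "S_eb": float(params.s_eb),
        "S_it": {sal: float(v) for sal, v in dict(params.s_it).items()},
        "S_ib": float(params.s_ib),
        "z_prime": float(params.z_prime),
        "p": float(params.p),
        "q": {"value": float(params.q), "fixed": True},
        "anchor": {"key": f"{CUED},{HIGH}", "value": 1000.0, "fixed": True},
        "grouping": params.grouping,
    }


def params_from_dict(d: dict) -> ChannelParams:
    q = d.get("q", 2.0)
    if isinstance(q, dict):
        q = q["value"]
    return ChannelParams(
        s_et={_CUE_SAL_KEYS[k]: float(v) for k, v in d["S_et"].items()},
        s_eb=float(d["S_eb"]),
        s_it={k: float(v) for k, v in d["S_it"].items()},
        s_ib=float(d["S_ib"]),
        z_prime=float(d["z_prime"]),
        p=float(d["p"]),
        q=float(q),
        grouping=d.get("grouping", "separate"),
    )


def write_params(params: ChannelParams, path) -> None:
    with open(path, "w") as fh:
        json.dump(params_to_dict(params), fh, indent=2)


def read_params(path) -> ChannelParams:
    with open(path) as fh:
        return params_from_dict(json.load(fh))


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False, float_format="%.12g")


def read_trials(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_design(design: ExperimentDesign, path) -> None:
    path = Path(path)
    d = design.to_dict()
    with open(path, "w") as fh:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(d, fh, sort_keys=False)
        else:
            json.dump(d, fh, indent=2)


def read_design(path) -> ExperimentDesign:
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            d = yaml.safe_load(fh)
        else:
            d = json.load(fh)
    return ExperimentDesign.from_dict(d)


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable config object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
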