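"""Configuration serialization and tabular writers.

Run configurations round-trip losslessly through YAML; traces, metrics and
sweep tables are written as CSV (comma, header row, '.' decimal) with a
'#'-prefixed provenance header carrying the package version, the named
parameter set and a hash of every model parameter in play.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cable import StrandConfig
from .coupling import CouplingConfig, Trace
from .gapjunction import PHENOTYPES
from .membrane import PassiveFibroblastParams, StimulusProtocol

__all__ = [
    "RunConfig",
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "save_config",
    "parameter_hash",
    "write_table",
    "read_table",
    "write_trace",
]

_NESTED = {
    "passive_params": PassiveFibroblastParams,
    "stimulus": StimulusProtocol,
    "fm": CouplingConfig,
}


def config_to_dict(cfg) -> dict:
    """Dataclass config -> plain dict (recursively, YAML/JSON-safe)."""
    out = {}
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        if dataclasses.is_dataclass(v):
            v = config_to_dict(v)
        elif isinstance(v, tuple):
            v = list(v)
        out[f.name] = v
    return out


def config_from_dict(d: dict, cls):
    """Plain dict -> dataclass config, rebuilding nested sections."""
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        if f.name in _NESTED and isinstance(v, dict):
            v = config_from_dict(v, _NESTED[f.name])
        elif isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """One CLI run: scenario plus the module configurations it needs."""

    scenario: str = "pair"  # pair | sweep | cable | gj-curve
    pair: CouplingConfig = dataclasses.field(default_factory=CouplingConfig)
    cable: StrandConfig = dataclasses.field(default_factory=StrandConfig)
    phenotype: str = "Cx45"
    t_end: float = 450.0
    output_dt: float = 0.1
    ratios: tuple = (1, 2, 4, 6, 8)
    conductances: tuple = (0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0)
    outdir: str = "."

    def __post_init__(self) -> None:
        if self.scenario not in ("pair", "sweep", "cable", "gj-curve"):
            raise ValueError(f"unknown scenario {self.scenario!r}")

    def to_dict(self) -> dict:
        d = config_to_dict(self)
        d["pair"] = config_to_dict(self.pair)
        d["cable"] = config_to_dict(self.cable)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("pair"), dict):
            d["pair"] = config_from_dict(d["pair"], CouplingConfig)
        if isinstance(d.get("cable"), dict):
            d["cable"] = config_from_dict(d["cable"], StrandConfig)
        return config_from_dict(d, cls)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def load_config(path) -> RunConfig:
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def parameter_hash(extra: dict | None = None) -> str:
    """Hash of the shipped model parameters (isoform sets + any overrides).

    Changes to any default parameter flip the hash, which regression
    fixtures use to detect stale reference data.
    """
    payload = {
        name: {
            "A": dataclasses.asdict(pair[0]),
            "B": dataclasses.asdict(pair[1]),
        }
        for name, pair in PHENOTYPES.items()
    }
    payload["extra"] = extra or {}
    blob = json.dumps(payload, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _provenance_header(meta: dict | None = None) -> str:
    lines = [f"# fmgap {__version__}", f"# parameter_set_hash {parameter_hash()}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k} {v}")
    return "\n".join(lines) + "\n"


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """CSV with '#' provenance header; readable by :func:`read_table`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance_header(meta))
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_state(system, y, path) -> None:
    """Write a state-vector snapshot as labeled one-row CSV (for restart)."""
    df = pd.DataFrame([list(y)], columns=system.state_labels())
    write_table(df, path, {"snapshot": "state"})


def read_state(path) -> "pd.Series":
    """Read a state snapshot; pass ``.to_numpy()[...]`` back into simulate."""
    return read_table(path).iloc[0]


def write_trace(trace: Trace, path, meta: dict | None = None) -> None:
    m = {"scenario": "trace"}
    if trace.config is not None:
        m["gj_model"] = trace.config.gj_model
        m["N"] = trace.config.N
        m["G_j_max"] = trace.config.G_j_max
    m.update(meta or {})
    write_table(trace.to_frame(), path, m)
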