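"""Configuration handling and result serialization.

Configs are JSON or YAML key-value files validated against the known
parameter and protocol options (unknown keys are rejected by name).  Traces
export to CSV (time in ms, '.' decimal, UTF-8, header row); line-scan
matrices to CSV or 16-bit TIFF; results to JSON with embedded metadata
(package version, parameter-set hash, seed) sufficient to regenerate them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib

import numpy as np
import pandas as pd
import yaml

from .parameters import PARAM_ORDER, Parameters
from .simulate import SolverConfig, Trace

__all__ = [
    "RunConfig", "ConfigError", "load_config", "save_config",
    "write_trace_csv", "read_trace_csv", "write_linescan",
    "write_results", "trace_to_frame",
]

PROTOCOL_NAMES = ("simulate", "spontaneous", "paced", "block", "caffeine",
                  "injection", "ical-iv", "ncx-ramp", "apdr-ffr")


class ConfigError(ValueError):
    """Schema violation; the message names the offending key."""


@dataclasses.dataclass
class RunConfig:
    params: Parameters = dataclasses.field(default_factory=Parameters)
    protocol: str = "paced"
    options: dict = dataclasses.field(default_factory=dict)
    solver: SolverConfig = dataclasses.field(default_factory=SolverConfig)
    seed: int = 0
    out: str = "results"
    source_hash: str | None = None

    def to_dict(self) -> dict:
        return {
            "parameters": self.params.to_dict(),
            "protocol": self.protocol,
            "options": dict(self.options),
            "solver": dataclasses.asdict(self.solver),
            "seed": self.seed,
            "out": self.out,
        }


_OPTION_KEYS = {
    "frequency", "duration", "analysis_window", "save_last", "target",
    "fraction", "variant", "amplitude_multiple", "amplitude", "n", "ranges",
    "mode", "event_rate", "open_duration", "open_probability", "step_duration",
}


def load_config(path) -> RunConfig:
    """Read and validate a JSON/YAML run configuration.

    Empty files yield an all-defaults config; unknown keys raise
    :class:`ConfigError` naming the key.  The file hash is stored for
    provenance.
    """
    path = pathlib.Path(path)
    text = path.read_text()
    raw = yaml.safe_load(text) if text.strip() else {}
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    cfg = RunConfig()
    cfg.source_hash = hashlib.sha256(text.encode()).hexdigest()[:16]
    for key, val in raw.items():
        if key == "parameters":
            unknown = set(val) - set(PARAM_ORDER)
            if unknown:
                raise ConfigError(f"unknown parameter key(s): {sorted(unknown)}")
            cfg.params = Parameters(**{k: float(v) for k, v in val.items()})
        elif key == "protocol":
            if val not in PROTOCOL_NAMES:
                raise ConfigError(f"unknown protocol {val!r}; valid: {PROTOCOL_NAMES}")
            cfg.protocol = val
        elif key == "options":
            unknown = set(val) - _OPTION_KEYS
            if unknown:
                raise ConfigError(f"unknown option key(s): {sorted(unknown)}")
            cfg.options = dict(val)
        elif key == "solver":
            known = {f.name for f in dataclasses.fields(SolverConfig)}
            unknown = set(val) - known
            if unknown:
                raise ConfigError(f"unknown solver key(s): {sorted(unknown)}")
            cfg.solver = SolverConfig(**val)
        elif key == "seed":
            cfg.seed = int(val)
        elif key == "out":
            cfg.out = str(val)
        else:
            raise ConfigError(f"unknown top-level key {key!r}")
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    path = pathlib.Path(path)
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    else:
        path.write_text(json.dumps(cfg.to_dict(), indent=1, sort_keys=True))


def trace_to_frame(trace: Trace, currents: bool = True) -> pd.DataFrame:
    """Tabular view of a Trace: time, V_m, bulk/SR/per-site Ca, currents."""
    data = {"time_ms": trace.time, "v_m_mv": trace.v,
            "ca_bulk_mm": trace.ca_bulk, "ca_sr_mm": trace.ca_sr}
    n = trace.n_shells
    data["ca_sl_mm"] = trace.ca_shells[:, n - 1]
    data["ca_central_mm"] = trace.ca_shells[:, 0]
    if currents:
        for name, arr in trace.current_dict().items():
            data[name] = arr
    return pd.DataFrame(data)


def write_trace_csv(trace: Trace, path, currents: bool = True,
                    meta: dict | None = None) -> None:
    """CSV export with a commented metadata header line."""
    path = pathlib.Path(path)
    frame = trace_to_frame(trace, currents=currents)
    header = "# ipsccm trace"
    if meta:
        header += " " + json.dumps(meta, sort_keys=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        frame.to_csv(fh, index=False, float_format="%.10g")


def read_trace_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_linescan(trace: Trace, path, fmt: str = "csv") -> None:
    """Line-scan matrix (rows = radial shells, columns = time samples).

    ``fmt``: "csv" writes a plain matrix with a time header row; "tiff"
    writes a 16-bit grayscale image scaled to the Ca range.
    """
    mat = trace.ca_shells.T  # (n_shells, nt)
    path = pathlib.Path(path)
    if fmt == "csv":
        df = pd.DataFrame(mat, columns=[f"{t:.3f}" for t in trace.time])
        df.insert(0, "shell", np.arange(mat.shape[0]))
        df.to_csv(path, index=False)
    elif fmt == "tiff":
        import tifffile
        lo, hi = float(mat.min()), float(mat.max())
        scale = 65535.0 / (hi - lo) if hi > lo else 1.0
        img = ((mat - lo) * scale).astype(np.uint16)
        tifffile.imwrite(path, img)
    else:
        raise ValueError(f"unknown line-scan format {fmt!r}")


def write_results(payload: dict, path, params: Parameters | None = None,
                  seed: int | None = None) -> None:
    """JSON result file with embedded version/parameter-hash/seed metadata."""
    from . import __version__

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    meta = {"version": __version__}
    if params is not None:
        blob = json.dumps(params.to_dict(), sort_keys=True).encode()
        meta["params_hash"] = hashlib.sha256(blob).hexdigest()[:16]
    if seed is not None:
        meta["seed"] = seed
    doc = {"meta": meta, "results": _clean(payload)}
    pathlib.Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))
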