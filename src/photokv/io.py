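"""Delimited-text file formats, manifests, and the reproducible pipeline.

File conventions: time in ms, current in pA, voltage in mV, capacitance in
pF; every numeric column carries its unit in the header (``t_ms``,
``i_pA``, ``v_mV``, ``cm_pF``).  Stochastic outputs are traceable to the
seed recorded in the run manifest, which also stores the config snapshot,
its hash, and SHA-256 checksums of every artifact.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .traces import CapacitanceTrace, CurrentTrace, LightEvent, LineProfileStack

__all__ = [
    "FormatError",
    "read_trace",
    "write_trace",
    "read_events",
    "write_events",
    "RunManifest",
    "run_pipeline",
]

_SCHEMAS = {
    "current": ["t_ms", "i_pA", "v_mV"],
    "capacitance": ["t_ms", "cm_pF"],
}


class FormatError(ValueError):
    """Input file violates the expected schema or structure."""


def write_events(events: list[LightEvent], path: str | Path) -> None:
    payload = [
        {"t_on_ms": e.t_on_ms, "duration_ms": e.duration_ms, "kind": e.kind}
        for e in events
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_events(path: str | Path) -> list[LightEvent]:
    payload = json.loads(Path(path).read_text())
    return [LightEvent(e["t_on_ms"], e["duration_ms"], e["kind"]) for e in payload]


def write_trace(trace, path: str | Path, precision: int = 6) -> None:
    """Write a current/capacitance trace or profile stack as delimited text."""
    path = Path(path)
    ffmt = f"%.{precision}g"
    if isinstance(trace, CurrentTrace):
        df = pd.DataFrame(
            {"t_ms": trace.time_ms, "i_pA": trace.i_pA, "v_mV": trace.v_mV}
        )
        df.to_csv(path, index=False, float_format=ffmt)
    elif isinstance(trace, CapacitanceTrace):
        df = pd.DataFrame({"t_ms": trace.time_ms, "cm_pF": trace.cm_pF})
        df.to_csv(path, index=False, float_format=ffmt)
    elif isinstance(trace, LineProfileStack):
        np.savetxt(path, trace.frames, delimiter="\t", fmt=ffmt)
        meta = {
            "pixel_um": trace.pixel_um,
            "frame_ms": trace.frame_ms,
            "n_lines_averaged": trace.n_lines_averaged,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))
    else:
        raise TypeError(f"cannot serialize {type(trace).__name__}")


def read_trace(path: str | Path, schema: str, events: list[LightEvent] | None = None):
    """Read a typed record from delimited text.

    ``schema`` is "current", "capacitance" or "profiles".  Column headers
    must carry the expected units; the time base must be uniform (checked
    by the trace constructor, 1% jitter tolerance).
    """
    path = Path(path)
    if schema == "profiles":
        frames = np.loadtxt(path, delimiter="\t", ndmin=2)
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        if not meta_path.exists():
            raise FormatError(f"profile metadata file missing: {meta_path}")
        meta = json.loads(meta_path.read_text())
        return LineProfileStack(frames=frames, **meta)
    if schema not in _SCHEMAS:
        raise FormatError(f"unknown schema {schema!r}")
    df = pd.read_csv(path)
    missing = [c for c in _SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path.name}: header lacks required column(s) {missing}; found "
            f"{list(df.columns)} — units are part of the column name"
        )
    try:
        if schema == "current":
            return CurrentTrace(
                time_ms=df["t_ms"].to_numpy(),
                i_pA=df["i_pA"].to_numpy(),
                v_mV=df["v_mV"].to_numpy(),
                events=events or [],
            )
        return CapacitanceTrace(
            time_ms=df["t_ms"].to_numpy(),
            cm_pF=df["cm_pF"].to_numpy(),
            events=events or [],
        )
    except ValueError as err:
        raise FormatError(f"{path.name}: {err}") from err


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


@dataclass
class RunManifest:
    config: dict
    config_sha256: str
    seed: int
    version: str
    outputs: dict = field(default_factory=dict)   # stage -> {name: path}
    checksums: dict = field(default_factory=dict)  # path -> sha256
    reports: dict = field(default_factory=dict)    # stage -> result dict
    timings_s: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=str))


def run_pipeline(config: dict, out_dir: str | Path) -> RunManifest:
    """Execute the configured simulate→analyze→report stages in order.

    Idempotent given identical config + seed: analysis outputs are
    byte-identical across reruns.  Any stage failure aborts with the stage
    name attached.  Returns (and writes) the run manifest.
    """
    from . import pipeline  # deferred: pipeline imports the analysis modules

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = RunManifest(
        config=config, config_sha256=config_hash(config), seed=seed,
        version=__version__,
    )
    stages = config.get("stages", ["tension", "cm", "profiles", "single_channel", "iv"])
    runners = {
        "tension": pipeline.stage_tension,
        "cm": pipeline.stage_cm,
        "profiles": pipeline.stage_profiles,
        "single_channel": pipeline.stage_single_channel,
        "iv": pipeline.stage_iv,
    }
    for k, stage in enumerate(stages):
        if stage not in runners:
            raise ValueError(f"unknown pipeline stage {stage!r}")
        t0 = _time.perf_counter()
        try:
            report, paths = runners[stage](config, out, seed + 1000 * (k + 1))
        except Exception as err:
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err
        manifest.reports[stage] = report
        manifest.outputs[stage] = {name: str(p) for name, p in paths.items()}
        for p in paths.values():
            manifest.checksums[str(p)] = _sha256(Path(p))
        manifest.timings_s[stage] = round(_time.perf_counter() - t0, 4)
    manifest.save(out / "manifest.json")
    return manifest
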