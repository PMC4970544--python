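"""Readers and writers for the pipeline artifacts.

Formats are plain text and locale independent (UTF-8, dot decimal):
traces as TSV (``distance_nm``, ``force_pN``) with a JSON metadata
sidecar, rupture events and velocity summaries as CSV, fits as JSON, and
run configuration as TOML.  Every CLI run writes a manifest recording the
tool version, config snapshot, seeds and SHA-256 digests of inputs and
outputs, so a run can be re-executed and checked bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bsk import VelocitySummary
from .fdc import FDCTrace, RuptureEvent

EVENT_COLUMNS = ["force_pN", "keff_pN_nm", "velocity_nm_s", "loading_rate_pN_s"]


def write_trace_tsv(trace: FDCTrace, path: str | Path) -> Path:
    """Write one trace as TSV plus a ``.json`` metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame({"distance_nm": trace.distance, "force_pN": trace.force})
    df.to_csv(path, sep="\t", index=False)
    sidecar = {"velocity_nm_s": trace.velocity,
               "cantilever_k_pN_nm": trace.cantilever_k,
               "meta": trace.meta}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1))
    return path


def read_trace_tsv(path: str | Path) -> FDCTrace:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = {"distance_nm", "force_pN"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing trace columns {sorted(missing)}")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar_path}")
    side = json.loads(sidecar_path.read_text())
    return FDCTrace(distance=df["distance_nm"].to_numpy(),
                    force=df["force_pN"].to_numpy(),
                    velocity=float(side["velocity_nm_s"]),
                    cantilever_k=float(side["cantilever_k_pN_nm"]),
                    meta=side.get("meta", {}))


def write_events_csv(events: list[RuptureEvent], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [(e.force, e.keff, e.velocity, e.loading_rate) for e in events],
        columns=EVENT_COLUMNS,
    ).to_csv(path, index=False)
    return path


def read_events_csv(path: str | Path) -> list[RuptureEvent]:
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing event columns {sorted(missing)}")
    return [RuptureEvent(force=row.force_pN, keff=row.keff_pN_nm,
                         velocity=row.velocity_nm_s)
            for row in df.itertuples()]


def write_summaries_csv(summaries: list[VelocitySummary],
                        path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [(s.velocity, s.loading_rate, s.mu, s.sigma, s.n) for s in summaries],
        columns=["velocity_nm_s", "loading_rate_pN_s", "mu_pN", "sigma_pN",
                 "n_events"],
    ).to_csv(path, index=False)
    return path


def read_summaries_csv(path: str | Path) -> list[VelocitySummary]:
    df = pd.read_csv(path)
    need = {"velocity_nm_s", "loading_rate_pN_s", "mu_pN", "sigma_pN"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing summary columns {sorted(missing)}")
    return [VelocitySummary(velocity=r.velocity_nm_s,
                            loading_rate=r.loading_rate_pN_s,
                            mu=r.mu_pN, sigma=r.sigma_pN,
                            n=int(getattr(r, "n_events", 1)))
            for r in df.itertuples()]


def read_md_forces_csv(path: str | Path) -> list[tuple[float, float]]:
    """MD rupture table: columns force_pN, loading_rate_pN_s."""
    df = pd.read_csv(path)
    missing = {"force_pN", "loading_rate_pN_s"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing MD columns {sorted(missing)}")
    return [(float(r.force_pN), float(r.loading_rate_pN_s))
            for r in df.itertuples()]


def load_config(path: str | Path) -> dict:
    """Load a TOML run configuration."""
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=1, default=_default))
    return path


def write_manifest(out_dir: str | Path, config: dict, seed: int,
                   inputs: list[Path] | None = None,
                   outputs: list[Path] | None = None) -> Path:
    """Write the run manifest (version, config snapshot, seeds, digests)."""
    out_dir = Path(out_dir)
    manifest = {
        "tool": "vwforce",
        "version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config": config,
        "inputs": {str(p): sha256_file(p) for p in (inputs or [])},
        "outputs": {str(p): sha256_file(p) for p in (outputs or [])},
    }
    return write_json(manifest, out_dir / "manifest.json")
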