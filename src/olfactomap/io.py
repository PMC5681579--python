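"""File formats: delimited-text traces with metadata sidecars, geometry
configs, sensilla tables, and run manifests.

EAG data has no community standard format, so everything is plain
delimited text plus a small YAML/JSON sidecar, chosen for transparency and
diff-ability.  Decimal separators are normalized to "." on read.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import FuniculusGeometry
from .sensilla import MORPHOTYPES, DensityGrid, SensillaMap
from .signals import EAGRecording

__all__ = [
    "read_geometry",
    "write_geometry",
    "read_recording",
    "write_recording",
    "read_sensilla",
    "write_sensilla",
    "write_table",
    "write_density_grid",
    "write_manifest",
    "ValidationError",
]


class ValidationError(ValueError):
    """Input file fails the format contract (CLI exit code 2)."""


def _load_sidecar(path: Path) -> dict:
    text = path.read_text()
    try:
        return yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ValidationError(f"{path}: cannot parse sidecar: {exc}") from exc


def read_geometry(path) -> FuniculusGeometry:
    """Read a geometry config (YAML or JSON key-value file)."""
    path = Path(path)
    data = _load_sidecar(path)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: geometry config must be a mapping")
    try:
        return FuniculusGeometry(
            length_mm=float(data["length_mm"]),
            width_mm=float(data["width_mm"]),
            thickness_mm=float(data["thickness_mm"]),
            positions_norm=tuple(data.get("positions_norm", (0, 1 / 3, 2 / 3, 1))),
            sigma=float(data.get("sigma", 10.0)),
            species=data.get("species"),
        )
    except KeyError as exc:
        raise ValidationError(f"{path}: missing geometry key {exc}") from exc
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_geometry(geom: FuniculusGeometry, path) -> None:
    path = Path(path)
    data = {
        "species": geom.species,
        "length_mm": geom.length_mm,
        "width_mm": geom.width_mm,
        "thickness_mm": geom.thickness_mm,
        "positions_norm": list(geom.positions_norm),
        "sigma": geom.sigma,
    }
    path.write_text(yaml.safe_dump(data, sort_keys=False))


def _trace_columns(n: int) -> list[str]:
    return ["time_s"] + [f"v_pos{j}" for j in range(n)]


def write_recording(rec: EAGRecording, path, control_path=None) -> None:
    """Write a recording as TSV (columns time_s, v_pos0…) plus a JSON
    sidecar <path>.meta.json; the control goes to ``control_path`` when
    given."""
    path = Path(path)
    df = pd.DataFrame(rec.traces, columns=_trace_columns(rec.n_positions)[1:])
    df.insert(0, "time_s", rec.times_s)
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")
    meta = {
        "sampling_rate_hz": rec.sampling_rate_hz,
        "stimulus_onset_s": rec.stimulus_onset_s,
        "stimulus_duration_s": rec.stimulus_duration_s,
        "odorant": rec.odorant,
        "individual": rec.individual,
        "species": rec.species,
    }
    if rec.control_traces is not None and control_path is not None:
        control_path = Path(control_path)
        cdf = pd.DataFrame(
            rec.control_traces, columns=_trace_columns(rec.n_positions)[1:]
        )
        cdf.insert(0, "time_s", rec.times_s)
        cdf.to_csv(control_path, sep="\t", index=False, float_format="%.9g")
        meta["control_file"] = control_path.name
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2)
    )


def _read_trace_table(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", decimal=".")
    except Exception as exc:
        raise ValidationError(f"{path}: cannot parse trace file: {exc}") from exc
    if "time_s" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'time_s'")
    vcols = [c for c in df.columns if c.startswith("v_pos")]
    expect = [f"v_pos{j}" for j in range(len(vcols))]
    if vcols != expect:
        raise ValidationError(
            f"{path}: voltage columns must be contiguous v_pos0…v_pos{{N-1}}, "
            f"got {vcols}"
        )
    if not vcols:
        raise ValidationError(f"{path}: no voltage columns (v_pos0…) found")
    t = df["time_s"].to_numpy(float)
    if np.any(~np.isfinite(t)) or np.any(np.diff(t) <= 0):
        raise ValidationError(f"{path}: time_s must be finite and strictly increasing")
    v = df[vcols].to_numpy(float)
    if np.any(~np.isfinite(v)):
        bad = int(np.argwhere(~np.isfinite(v))[0][0]) + 2  # 1-based + header
        raise ValidationError(f"{path}: NaN/inf voltage near line {bad}")
    return df


def read_recording(path) -> EAGRecording:
    """Read a trace file and its sidecar; loads the referenced control file
    when present."""
    path = Path(path)
    df = _read_trace_table(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if not meta_path.exists():
        raise ValidationError(f"{path}: missing metadata sidecar {meta_path.name}")
    meta = _load_sidecar(meta_path)
    vcols = [c for c in df.columns if c.startswith("v_pos")]
    control = None
    if meta.get("control_file"):
        cdf = _read_trace_table(path.parent / meta["control_file"])
        if cdf.shape != df.shape:
            raise ValidationError(
                f"{path}: control file shape {cdf.shape} != trace shape {df.shape}"
            )
        control = cdf[vcols].to_numpy(float)
    t = df["time_s"].to_numpy(float)
    rate = meta.get("sampling_rate_hz") or 1.0 / np.median(np.diff(t))
    try:
        return EAGRecording(
            traces=df[vcols].to_numpy(float),
            sampling_rate_hz=float(rate),
            stimulus_onset_s=float(meta["stimulus_onset_s"]),
            stimulus_duration_s=float(meta.get("stimulus_duration_s", 0.2)),
            control_traces=control,
            odorant=meta.get("odorant", ""),
            individual=meta.get("individual", ""),
            species=meta.get("species", ""),
        )
    except (KeyError, ValueError) as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def read_sensilla(path) -> list[SensillaMap]:
    """Read a sensilla CSV (x_norm, y_norm, type[, individual, species])
    into one map per individual."""
    path = Path(path)
    try:
        df = pd.read_csv(path, decimal=".")
    except Exception as exc:
        raise ValidationError(f"{path}: cannot parse sensilla CSV: {exc}") from exc
    missing = {"x_norm", "y_norm", "type"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    bad = set(df["type"]) - set(MORPHOTYPES)
    if bad:
        raise ValidationError(
            f"{path}: unknown sensilla types {sorted(bad)}; expected {MORPHOTYPES}"
        )
    if "individual" not in df.columns:
        df = df.assign(individual="ind0")
    if "species" not in df.columns:
        df = df.assign(species="")
    maps = []
    for (species, individual), sub in df.groupby(["species", "individual"], sort=True):
        try:
            maps.append(
                SensillaMap(
                    records=sub.reset_index(drop=True),
                    species=str(species),
                    individual=str(individual),
                )
            )
        except ValueError as exc:
            raise ValidationError(f"{path}: {exc}") from exc
    return maps


def write_sensilla(maps: list[SensillaMap], path) -> None:
    frames = []
    for m in maps:
        df = m.records[["x_norm", "y_norm", "type"]].copy()
        df["individual"] = m.individual
        df["species"] = m.species
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.6g")


def write_table(df: pd.DataFrame, path) -> None:
    """Write any result table as TSV with '.' decimals."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def write_density_grid(grid: DensityGrid, path) -> None:
    """Delimited matrix (rows = y bins) plus a JSON sidecar with the
    lattice and kernel parameters."""
    path = Path(path)
    np.savetxt(path, grid.values, delimiter="\t", fmt="%.6g")
    meta = {
        "nx": int(grid.x_centers.size),
        "ny": int(grid.y_centers.size),
        "sigma_x": grid.sigma_x,
        "sigma_y": grid.sigma_y,
        "layout": "rows are y bins (ventral→dorsal), columns x bins (proximal→distal)",
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(out_dir, command: str, inputs: list, params: dict,
                   seed=None) -> Path:
    """Emit the run manifest (one per CLI run) recording the command, input
    hashes, parameters, and seed for reproducibility audits."""
    from datetime import datetime, timezone

    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "inputs": [
            {"path": str(p), "sha256": _sha256(Path(p))}
            for p in inputs
            if Path(p).is_file()
        ],
        "parameters": params,
        "seed": seed,
        "tool_version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
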