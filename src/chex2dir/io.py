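"""Readers and writers for the text formats the pipeline exchanges.

* 1D spectra: two-column delimited text (wavenumber cm^-1, absorbance)
  with '#'-prefixed header lines carrying the temperature and arbitrary
  metadata, or CSV with named "wavenumber"/"absorbance" columns.
* 2D IR series: one directory per temperature holding a YAML manifest
  (axis vectors, waiting times, temperature, mode) plus one matrix file
  per waiting time, rows = omega_t, columns = omega_tau.
* Trajectories: extended XYZ, one block per frame; the comment line
  carries frame index, time (ps) and box length; atom labels come from
  the fixed role vocabulary {OC, N, HN, OW, HW}.

Floats are written with 17 significant digits so every round trip is
bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .types import Spectrum1D, Spectrum2DSeries, Trajectory

__all__ = [
    "read_spectrum1d",
    "write_spectrum1d",
    "read_2dir_series",
    "write_2dir_series",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "write_report",
]

_FLOAT_FMT = "%.17g"
_MANIFEST_NAME = "manifest.yaml"


# --------------------------------------------------------------------------
# 1D spectra
# --------------------------------------------------------------------------

def write_spectrum1d(spectrum: Spectrum1D, path: Union[str, Path]) -> None:
    """Write a spectrum as two-column text with '#' metadata headers."""
    path = Path(path)
    lines = []
    if spectrum.temperature is not None:
        lines.append(f"# temperature_c = {spectrum.temperature!r}")
    for key, value in spectrum.metadata.items():
        lines.append(f"# {key} = {value!r}")
    lines.append("# wavenumber_cm1 absorbance")
    for w, a in zip(spectrum.wavenumber, spectrum.absorbance):
        lines.append(f"{w:.17g} {a:.17g}")
    path.write_text("\n".join(lines) + "\n")


def _parse_header_value(text: str):
    try:
        import ast
        return ast.literal_eval(text)
    except (ValueError, SyntaxError):
        return text


def read_spectrum1d(path: Union[str, Path],
                    temperature: Optional[float] = None) -> Spectrum1D:
    """Read a spectrum from two-column text or a named-column CSV.

    '#' headers of the form ``key = value`` populate the metadata; a
    ``temperature_c`` header (or the ``temperature`` argument, which
    takes precedence) sets the temperature.  Malformed data rows and
    non-monotonic grids raise with the offending line number.
    """
    path = Path(path)
    text = path.read_text()
    first_data = next(
        (ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")),
        "")
    if "," in first_data:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        cols = {c.strip().lower(): c for c in df.columns}
        if "wavenumber" not in cols or "absorbance" not in cols:
            raise ValueError(
                f"{path}: CSV must provide 'wavenumber' and 'absorbance' columns")
        wn = df[cols["wavenumber"]].to_numpy(dtype=float)
        ab = df[cols["absorbance"]].to_numpy(dtype=float)
        metadata = {}
    else:
        wn_list, ab_list, metadata = [], [], {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    metadata[key.strip()] = _parse_header_value(val.strip())
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, "
                                 f"got {len(parts)}")
            try:
                wn_list.append(float(parts[0]))
                ab_list.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric row") from exc
        wn = np.array(wn_list)
        ab = np.array(ab_list)

    if np.any(np.diff(wn) <= 0):
        bad = int(np.flatnonzero(np.diff(wn) <= 0)[0])
        raise ValueError(
            f"{path}: wavenumber grid not strictly increasing near row {bad + 1}")
    temp = temperature
    if temp is None:
        temp = metadata.pop("temperature_c", None)
    else:
        metadata.pop("temperature_c", None)
    return Spectrum1D(wavenumber=wn, absorbance=ab, temperature=temp,
                      metadata=metadata)


# --------------------------------------------------------------------------
# 2D IR series directories
# --------------------------------------------------------------------------

def write_2dir_series(series: Spectrum2DSeries, directory: Union[str, Path]) -> None:
    """Write a series as manifest.yaml + one matrix file per waiting time."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for i, (tw, m) in enumerate(zip(series.waiting_times, series.matrices)):
        name = f"tw_{i:03d}.txt"
        np.savetxt(directory / name, m, fmt=_FLOAT_FMT,
                   header=f"T_w = {float(tw)!r} ps; rows = omega_t, cols = omega_tau")
        files.append(name)
    manifest = {
        "format": "chex2dir-2dir-series",
        "version": 1,
        "temperature_c": series.temperature,
        "mode": series.metadata.get("mode"),
        "omega_tau_cm1": [float(v) for v in series.omega_tau],
        "omega_t_cm1": [float(v) for v in series.omega_t],
        "waiting_times_ps": [float(v) for v in series.waiting_times],
        "matrix_files": files,
    }
    (directory / _MANIFEST_NAME).write_text(yaml.safe_dump(manifest, sort_keys=False))


def read_2dir_series(directory: Union[str, Path]) -> Spectrum2DSeries:
    """Read a series directory written by :func:`write_2dir_series`.

    Shape mismatches and missing matrix files raise errors naming the
    offending file.
    """
    directory = Path(directory)
    manifest_path = directory / _MANIFEST_NAME
    if not manifest_path.exists():
        raise FileNotFoundError(f"no {_MANIFEST_NAME} in {directory}")
    manifest = yaml.safe_load(manifest_path.read_text())
    omega_tau = np.array(manifest["omega_tau_cm1"], dtype=float)
    omega_t = np.array(manifest["omega_t_cm1"], dtype=float)
    waiting = np.array(manifest["waiting_times_ps"], dtype=float)
    files = manifest["matrix_files"]
    if len(files) != waiting.size:
        raise ValueError(f"{manifest_path}: {len(files)} matrix files listed "
                         f"for {waiting.size} waiting times")
    matrices = []
    expected = (omega_t.size, omega_tau.size)
    for tw, name in zip(waiting, files):
        fp = directory / name
        if not fp.exists():
            raise FileNotFoundError(f"manifest lists missing matrix file {fp}")
        m = np.loadtxt(fp, ndmin=2)
        if m.shape != expected:
            raise ValueError(
                f"{fp}: matrix shape {m.shape} does not match manifest axes "
                f"{expected}")
        matrices.append(m)
    meta = {"mode": manifest.get("mode")} if manifest.get("mode") else {}
    return Spectrum2DSeries(
        omega_tau=omega_tau, omega_t=omega_t, waiting_times=waiting,
        matrices=matrices, temperature=manifest.get("temperature_c"),
        metadata=meta)


# --------------------------------------------------------------------------
# Extended XYZ trajectories
# --------------------------------------------------------------------------

def write_xyz_trajectory(traj: Trajectory, path: Union[str, Path]) -> None:
    """Write an extended-XYZ trajectory, one block per frame."""
    path = Path(path)
    box = "none" if traj.box_length is None else f"{traj.box_length:.17g}"
    with path.open("w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"frame={f} time_ps={traj.times[f]:.17g} box_A={box}\n")
            for label, (x, y, z) in zip(traj.labels, traj.coords[f]):
                fh.write(f"{label} {x:.17g} {y:.17g} {z:.17g}\n")


def read_xyz_trajectory(path: Union[str, Path]) -> Trajectory:
    """Read an extended-XYZ trajectory written by :func:`write_xyz_trajectory`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    frames, times = [], []
    labels: list = []
    box: Optional[float] = None
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"{path}:{i + 1}: expected atom count") from exc
        comment = lines[i + 1]
        fields = dict(tok.split("=", 1) for tok in comment.split() if "=" in tok)
        times.append(float(fields.get("time_ps", frame_no)))
        box_str = fields.get("box_A", "none")
        frame_box = None if box_str == "none" else float(box_str)
        if frame_no == 0:
            box = frame_box
        elif frame_box != box:
            raise ValueError(f"{path}: box length changes at frame {frame_no}")
        coords = np.empty((n_atoms, 3))
        frame_labels = []
        for a in range(n_atoms):
            parts = lines[i + 2 + a].split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{i + 3 + a}: expected 'label x y z'")
            frame_labels.append(parts[0])
            coords[a] = [float(v) for v in parts[1:]]
        if frame_no == 0:
            labels = frame_labels
        elif frame_labels != labels:
            raise ValueError(f"{path}: atom labels change at frame {frame_no}")
        frames.append(coords)
        i += 2 + n_atoms
        frame_no += 1
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return Trajectory(labels=labels, coords=np.stack(frames),
                      times=np.array(times), box_length=box)


# --------------------------------------------------------------------------
# Reports
# --------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_report(data: dict, path: Union[str, Path]) -> None:
    """Write a machine-readable JSON report (arrays become lists)."""
    Path(path).write_text(json.dumps(_jsonable(data), indent=2) + "\n")
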