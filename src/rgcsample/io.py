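"""Readers and writers for the package's plain-text interchange formats.

Arbors travel as standard 7-column SWC (µm; soma node type 1, dendrite
type 3) or as point-table CSV (x_um, y_um, z_um, is_soma); ChAT
annotations, retina samples and spike tables as tidy CSV; band surfaces
as gridded CSV with a JSON sidecar; specs as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .chat_surface import BandSurface, ChATAnnotation
from .core import ArborPointCloud, InvalidSpecError
from .synthetic import SpikeData

SWC_SOMA, SWC_DENDRITE = 1, 3


def write_swc(arbor: ArborPointCloud, path: str | Path) -> None:
    """Write an arbor as SWC.  Point clouds have no tree topology; every
    dendritic node's parent is the soma (or -1 without one)."""
    path = Path(path)
    lines = ["# index type x y z radius parent  (um)"]
    idx = 1
    parent_of_dendrites = -1
    if arbor.soma is not None:
        sx, sy, sz = arbor.soma
        lines.append(f"{idx} {SWC_SOMA} {sx:.4f} {sy:.4f} {sz:.4f} 5.0 -1")
        parent_of_dendrites = idx
        idx += 1
    for x, y, z in arbor.points:
        lines.append(f"{idx} {SWC_DENDRITE} {x:.4f} {y:.4f} {z:.4f} 0.5 {parent_of_dendrites}")
        idx += 1
    path.write_text("\n".join(lines) + "\n")


def read_swc(path: str | Path, **kwargs) -> ArborPointCloud:
    raw = np.loadtxt(path, comments="#", ndmin=2)
    if raw.shape[1] != 7:
        raise InvalidSpecError(f"SWC file must have 7 columns, got {raw.shape[1]}")
    types = raw[:, 1].astype(int)
    soma_rows = raw[types == SWC_SOMA]
    soma = soma_rows[0, 2:5] if soma_rows.size else None
    points = raw[types != SWC_SOMA][:, 2:5]
    return ArborPointCloud(points=points, soma=soma, **kwargs)


def write_point_table(arbor: ArborPointCloud, path: str | Path) -> None:
    pts = arbor.points
    is_soma = np.zeros(pts.shape[0], dtype=int)
    if arbor.soma is not None:
        pts = np.vstack([pts, arbor.soma])
        is_soma = np.append(is_soma, 1)
    pd.DataFrame({
        "x_um": pts[:, 0], "y_um": pts[:, 1], "z_um": pts[:, 2], "is_soma": is_soma,
    }).to_csv(path, index=False)


def read_point_table(path: str | Path, **kwargs) -> ArborPointCloud:
    frame = pd.read_csv(path)
    soma_rows = frame[frame["is_soma"] == 1]
    soma = soma_rows[["x_um", "y_um", "z_um"]].to_numpy()[0] if len(soma_rows) else None
    pts = frame[frame["is_soma"] == 0][["x_um", "y_um", "z_um"]].to_numpy()
    return ArborPointCloud(points=pts, soma=soma, **kwargs)


def write_chat_annotation(annotation: ChATAnnotation, path: str | Path) -> None:
    rows = []
    for band, pts in (("ON", annotation.on_points), ("OFF", annotation.off_points)):
        for x, y, z in pts:
            rows.append((band, x, y, z))
    pd.DataFrame(rows, columns=["band", "x_um", "y_um", "z_um"]).to_csv(path, index=False)


def read_chat_annotation(path: str | Path) -> ChATAnnotation:
    frame = pd.read_csv(path)
    cols = ["x_um", "y_um", "z_um"]
    return ChATAnnotation(
        on_points=frame[frame["band"] == "ON"][cols].to_numpy(),
        off_points=frame[frame["band"] == "OFF"][cols].to_numpy(),
    )


def write_band_surface(surface: BandSurface, csv_path: str | Path) -> None:
    csv_path = Path(csv_path)
    gx, gy = np.meshgrid(surface.x_grid, surface.y_grid, indexing="ij")
    pd.DataFrame({
        "x_um": gx.ravel(), "y_um": gy.ravel(), "z_um": surface.z_values.ravel(),
    }).to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "lambda": surface.smoothness,
        "grid_spacing_um": surface.grid_spacing_um,
        "rms_residual_um": surface.rms_residual_um,
    }, indent=2))


def read_band_surface(csv_path: str | Path) -> BandSurface:
    csv_path = Path(csv_path)
    frame = pd.read_csv(csv_path)
    xg = np.unique(frame["x_um"].to_numpy())
    yg = np.unique(frame["y_um"].to_numpy())
    z = frame["z_um"].to_numpy().reshape(len(xg), len(yg))
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    return BandSurface(
        x_grid=xg, y_grid=yg, z_values=z,
        smoothness=meta["lambda"], grid_spacing_um=meta["grid_spacing_um"],
        rms_residual_um=meta["rms_residual_um"],
    )


def write_retina_sample(sample: pd.DataFrame, path: str | Path) -> None:
    sample.to_csv(path, index=False)


def read_retina_sample(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    needed = {"retina_id", "circuit", "cluster", "count"}
    missing = needed - set(frame.columns)
    if missing:
        raise InvalidSpecError(f"retina sample CSV missing columns: {sorted(missing)}")
    return frame


def write_spike_data(spikes: SpikeData, path: str | Path) -> None:
    spikes.trials.to_csv(path, index=False)
    Path(path).with_suffix(".json").write_text(json.dumps({
        "duration_s": spikes.duration,
        "baseline_window_s": spikes.baseline_window,
        "n_trials_per_condition": spikes.n_trials_per_condition,
        "cell_id": spikes.cell_id,
    }, indent=2))


def read_spike_data(path: str | Path) -> SpikeData:
    path = Path(path)
    frame = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return SpikeData(
        trials=frame,
        duration=meta["duration_s"],
        baseline_window=meta["baseline_window_s"],
        n_trials_per_condition=meta["n_trials_per_condition"],
        cell_id=meta.get("cell_id", ""),
    )
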