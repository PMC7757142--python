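"""Reading and writing the pipeline's on-disk formats.

Images travel as NIfTI (via nibabel) or NPZ with a JSON sidecar carrying the
focus coordinates and hemisphere boundary; tables (fixtures, closure tables,
standards, traces) as CSV; sonication configs as YAML mirroring the
SonicationConfig field names; calibrations as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .controller import PressureTrace, SonicationConfig
from .evans_blue import EBCalibration
from .synthetic import ImageSeries


def save_image_series(series: ImageSeries, directory: str | Path, fmt: str = "npz") -> Path:
    """Write one mouse's series plus a JSON sidecar; returns the directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    timepoints = series.timepoints
    stack = np.stack([series.images[t] for t in timepoints])
    if fmt == "npz":
        np.savez(
            directory / "images.npz",
            images=stack,
            timepoints_h=np.array(timepoints),
            hemisphere_mask=series.hemisphere_mask,
        )
    elif fmt == "nifti":
        # stored (row, col, time) so each volume slice is one timepoint
        nib.save(
            nib.Nifti1Image(np.moveaxis(stack, 0, -1).astype(np.float32), np.eye(4)),
            directory / "images.nii.gz",
        )
        np.savez(directory / "mask.npz", hemisphere_mask=series.hemisphere_mask)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    sidecar = {
        "mouse_id": series.mouse_id,
        "group": series.group,
        "timepoints_h": list(map(float, timepoints)),
        "focus_coords": [list(map(int, c)) for c in series.focus_coords],
        "format": fmt,
    }
    (directory / "series.json").write_text(json.dumps(sidecar, indent=2))
    return directory


def load_image_series(directory: str | Path) -> ImageSeries:
    directory = Path(directory)
    sidecar = json.loads((directory / "series.json").read_text())
    timepoints = [float(t) for t in sidecar["timepoints_h"]]
    if sidecar.get("format", "npz") == "nifti":
        vol = np.asarray(nib.load(directory / "images.nii.gz").dataobj, dtype=float)
        stack = np.moveaxis(vol, -1, 0)
        mask = np.load(directory / "mask.npz")["hemisphere_mask"].astype(bool)
    else:
        data = np.load(directory / "images.npz")
        stack = data["images"]
        mask = data["hemisphere_mask"].astype(bool)
    return ImageSeries(
        images={t: stack[i] for i, t in enumerate(timepoints)},
        hemisphere_mask=mask,
        focus_coords=[tuple(c) for c in sidecar["focus_coords"]],
        mouse_id=sidecar["mouse_id"],
        group=sidecar["group"],
    )


def save_trace(trace: PressureTrace, path: str | Path, prf: float = 1.0) -> None:
    trace.to_frame(prf=prf).to_csv(path, index=False)


def save_config(config: SonicationConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config)))


def load_config(path: str | Path) -> SonicationConfig:
    return SonicationConfig(**yaml.safe_load(Path(path).read_text()))


def save_calibration(calibration: EBCalibration, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(calibration), indent=2))


def load_calibration(path: str | Path) -> EBCalibration:
    d = json.loads(Path(path).read_text())
    d["linear_range"] = tuple(d["linear_range"])
    d["radiance_span"] = tuple(d["radiance_span"])
    return EBCalibration(**d)
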