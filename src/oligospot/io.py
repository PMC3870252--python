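"""Readers and writers for the package's on-disk formats.

Image stacks are multi-page 16-bit TIFF files with a JSON sidecar carrying
acquisition metadata (pixel size, frame interval, camera model, simulation
ground truth).  Tables — cell ROIs, spot fits, stoichiometries, tracks, MSD
curves, spectra — are plain CSV with documented column names.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import CameraModel, ImageStack, Track, TrackSet
from .quantify import CellROI

__all__ = [
    "write_image_stack",
    "read_image_stack",
    "write_roi_table",
    "read_roi_table",
    "write_tracks",
    "read_tracks",
    "write_json",
    "read_json",
]

ROI_COLUMNS = [
    "row0", "col0", "row1", "col1",
    "cell_length_um", "constriction_class", "midcell_row", "midcell_col",
]
TRACK_COLUMNS = ["track_id", "frame", "x_um", "y_um"]


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, cls=_NumpyEncoder) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_image_stack(path: str | Path, stack: ImageStack, extra: dict | None = None) -> None:
    """Write counts as multi-page uint16 TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    data = np.clip(np.rint(stack.counts), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)
    meta = {
        "pixel_size_um": stack.pixel_size_um,
        "frame_interval_s": stack.frame_interval_s,
        "camera": {
            "offset": stack.camera.offset,
            "gain": stack.camera.gain,
            "read_noise_sd": stack.camera.read_noise_sd,
            "pixel_size_um": stack.camera.pixel_size_um,
        },
        "metadata": stack.metadata,
    }
    if extra:
        meta.update(extra)
    write_json(_sidecar(path), meta)


def read_image_stack(path: str | Path) -> ImageStack:
    """Read a TIFF stack; metadata comes from the JSON sidecar when present."""
    path = Path(path)
    counts = tifffile.imread(path).astype(float)
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = read_json(sidecar)
        camera = CameraModel(**meta["camera"])
        return ImageStack(
            counts=counts,
            pixel_size_um=float(meta["pixel_size_um"]),
            frame_interval_s=float(meta["frame_interval_s"]),
            camera=camera,
            metadata=meta.get("metadata", {}),
        )
    camera = CameraModel()
    return ImageStack(
        counts=counts,
        pixel_size_um=camera.pixel_size_um,
        frame_interval_s=0.0175,
        camera=camera,
    )


def write_roi_table(path: str | Path, rois: list[CellROI]) -> None:
    rows = []
    for roi in rois:
        mid = roi.midcell_rc or (np.nan, np.nan)
        rows.append(
            [roi.row0, roi.col0, roi.row1, roi.col1,
             roi.cell_length_um, roi.constriction_class, mid[0], mid[1]]
        )
    pd.DataFrame(rows, columns=ROI_COLUMNS).to_csv(path, index=False)


def read_roi_table(path: str | Path) -> list[CellROI]:
    df = pd.read_csv(path)
    missing = set(ROI_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise ValueError(f"ROI table {path} missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"ROI table {path} is empty")
    rois = []
    for _, row in df.iterrows():
        mid = None
        if "midcell_row" in df.columns and not pd.isna(row.get("midcell_row")):
            mid = (float(row["midcell_row"]), float(row["midcell_col"]))
        rois.append(
            CellROI(
                row0=int(row["row0"]), col0=int(row["col0"]),
                row1=int(row["row1"]), col1=int(row["col1"]),
                cell_length_um=float(row["cell_length_um"]),
                constriction_class=str(row["constriction_class"]),
                midcell_rc=mid,
            )
        )
    return rois


def write_tracks(path: str | Path, tracks: TrackSet) -> None:
    rows = []
    for track in tracks:
        for f, (x, y) in zip(track.frames, track.positions_um):
            rows.append([track.track_id, int(f), float(x), float(y)])
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, index=False)


def read_tracks(path: str | Path, dt_s: float) -> TrackSet:
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track table {path} missing columns {sorted(missing)}")
    tracks = []
    for tid, group in df.groupby("track_id"):
        group = group.sort_values("frame")
        tracks.append(
            Track(
                frames=group["frame"].to_numpy(),
                positions_um=group[["x_um", "y_um"]].to_numpy(),
                track_id=int(tid),
            )
        )
    return TrackSet(tracks=tracks, dt_s=dt_s)
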