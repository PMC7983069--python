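"""Image containers and well-series I/O.

A *well time series* is the ordered set of two-channel frames acquired from
one well: an NAD(P)H image and an FAD image per time point, sharing a field
of view.  Frames are described by a manifest CSV with columns
``well, time_h, channel, path, treatment`` pointing at single-plane TIFFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path


import numpy as np
import pandas as pd
import tifffile

NADH = "NADH"
FAD = "FAD"
CHANNELS = (NADH, FAD)

MANIFEST_COLUMNS = ("well", "time_h", "channel", "path", "treatment")


class ManifestError(ValueError):
    """Raised when a manifest row is missing, duplicated, or inconsistent."""


@dataclass(eq=False)
class ChannelImage:
    """A single-channel fluorescence frame.

    Parameters
    ----------
    pixels : 2D float array, non-negative intensities in arbitrary units.
    channel : ``"NADH"`` or ``"FAD"``.
    time_h : acquisition time in hours post-treatment (0 = pretreatment).
    well_id : identifier of the source well.
    """

    pixels: np.ndarray
    channel: str
    time_h: float
    well_id: str = "well"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(eq=False)
class WellTimeSeries:
    """Ordered two-channel frames for one well."""

    frames: list[tuple[ChannelImage, ChannelImage]]
    treatment: str = "control"
    well_id: str = "well"

    def __post_init__(self) -> None:
        shapes = {n.shape for n, f in self.frames} | {f.shape for n, f in self.frames}
        if len(shapes) > 1:
            raise ValueError(f"all frames must share dimensions, got {shapes}")
        times = self.times
        if np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([nadh.time_h for nadh, _ in self.frames])

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0][0].shape


def read_well_series(manifest: str | Path, well: str | None = None) -> WellTimeSeries:
    """Load one well's time series from a manifest CSV.

    Rows are paired by (well, time_h); both channels must be present for
    every time point and no (well, time, channel) may repeat.  Frames are
    returned sorted by time regardless of row order.
    """
    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ManifestError(f"manifest missing columns: {sorted(missing)}")
    if well is not None:
        df = df[df["well"] == well]
    wells = df["well"].unique()
    if len(wells) != 1:
        raise ManifestError(
            f"manifest must describe exactly one well (got {sorted(map(str, wells))}); "
            "pass well= to select one"
        )
    well_id = str(wells[0])

    dup = df.duplicated(subset=["well", "time_h", "channel"], keep=False)
    if dup.any():
        row = df[dup].iloc[0]
        raise ManifestError(
            f"duplicate (well,time,channel) row: {row['well']},{row['time_h']},{row['channel']}"
        )

    treatments = df["treatment"].unique()
    if len(treatments) != 1:
        raise ManifestError(f"well {well_id} has conflicting treatments {list(treatments)}")

    frames = []
    for time_h, group in df.sort_values("time_h").groupby("time_h", sort=True):
        by_channel = {row["channel"]: row for _, row in group.iterrows()}
        for channel in CHANNELS:
            if channel not in by_channel:
                raise ManifestError(
                    f"well {well_id} t={time_h} h: missing {channel} channel row"
                )
        pair = []
        for channel in CHANNELS:
            path = Path(by_channel[channel]["path"])
            if not path.is_absolute():
                path = manifest.parent / path
            if not path.exists():
                raise ManifestError(f"image file not found: {path}")
            pixels = tifffile.imread(path)
            pair.append(
                ChannelImage(pixels, channel=channel, time_h=float(time_h), well_id=well_id)
            )
        frames.append(tuple(pair))

    series = WellTimeSeries(frames, treatment=str(treatments[0]), well_id=well_id)
    return series


def write_well_series(
    series: WellTimeSeries, out_dir: str | Path, dtype=np.uint16
) -> pd.DataFrame:
    """Write a series to per-channel TIFFs plus a manifest; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (nadh, fad) in enumerate(series.frames):
        for img in (nadh, fad):
            name = f"{series.well_id}_t{i:03d}_{img.channel}.tif"
            pixels = img.pixels
            if np.issubdtype(dtype, np.integer):
                info = np.iinfo(dtype)
                pixels = np.clip(np.rint(pixels), info.min, info.max).astype(dtype)
            else:
                pixels = pixels.astype(dtype)
            tifffile.imwrite(out_dir / name, pixels)
            rows.append(
                {
                    "well": series.well_id,
                    "time_h": img.time_h,
                    "channel": img.channel,
                    "path": name,
                    "treatment": series.treatment,
                }
            )
    manifest = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    manifest.to_csv(out_dir / f"{series.well_id}_manifest.csv", index=False)
    return manifest
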