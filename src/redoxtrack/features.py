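"""Per-organoid quantification: 24 variables per organoid per time point.

Twelve metabolic variables (mean, min, max, standard deviation of the ORR,
NAD(P)H intensity and FAD intensity inside the organoid mask) and twelve
morphological variables (area, perimeter, solidity, extent, eccentricity,
circularity, min/max Feret diameter, minor/major ellipse axis, convex
area, equivalent diameter).  Intensity statistics are computed on the raw
registered pixel values -- no background subtraction -- to avoid coupling
the readout to medium autofluorescence variation.  Organoids whose mask
touches the image border at any time point are excluded from statistics.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from skimage import measure

from redoxtrack.segmentation import circularity, _hull_perimeter
from redoxtrack.tracking import OrganoidTrack

log = logging.getLogger(__name__)

METABOLIC_COLUMNS = [
    f"{stat}_{ch}"
    for ch in ("orr", "nadh", "fad")
    for stat in ("mean", "min", "max", "std")
]
MORPHOLOGICAL_COLUMNS = [
    "area",
    "perimeter",
    "solidity",
    "extent",
    "eccentricity",
    "circularity",
    "feret_min",
    "feret_max",
    "minor_axis",
    "major_axis",
    "convex_area",
    "equivalent_diameter",
]
FEATURE_COLUMNS = METABOLIC_COLUMNS + MORPHOLOGICAL_COLUMNS
KEY_COLUMNS = ["organoid_id", "well", "treatment", "time_h", "border_touching"]

#: physical pixel pitch of the acquisition camera, for optional unit conversion
MICRONS_PER_PIXEL = 1.625


def _pixel_corners(region_mask: np.ndarray) -> np.ndarray:
    ys, xs = np.nonzero(region_mask)
    return np.concatenate(
        [
            np.stack([ys - 0.5, xs - 0.5], axis=1),
            np.stack([ys - 0.5, xs + 0.5], axis=1),
            np.stack([ys + 0.5, xs - 0.5], axis=1),
            np.stack([ys + 0.5, xs + 0.5], axis=1),
        ]
    )


def feret_diameters(region_mask: np.ndarray) -> tuple[float, float]:
    """(min, max) Feret (caliper) diameter via the region's convex hull.

    Hull vertices are pixel corner points, so a 10x10 square has max Feret
    sqrt(200) and min Feret 10.  The minimum caliper width is attained
    perpendicular to some hull edge; the maximum is the hull diameter.
    """
    corners = _pixel_corners(region_mask)
    if corners.shape[0] == 0:
        raise ValueError("region is empty")
    try:
        hull = ConvexHull(corners)
        pts = corners[hull.vertices]
    except Exception:  # degenerate (collinear) region
        pts = corners
    d = pts[:, None, :] - pts[None, :, :]
    feret_max = float(np.sqrt((d**2).sum(axis=2).max()))
    edges = pts - np.roll(pts, 1, axis=0)
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    keep = lengths > 0
    if not keep.any():
        return 1.0, max(feret_max, 1.0)
    normals = np.stack([-edges[keep][:, 1], edges[keep][:, 0]], axis=1) / lengths[keep][:, None]
    proj = pts @ normals.T
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.min()), feret_max


def quantify_organoid(
    region_mask: np.ndarray,
    nadh: np.ndarray,
    fad: np.ndarray,
    orr: np.ndarray,
) -> dict[str, float]:
    """Compute the 24 variables for one organoid region.

    Undefined ORR pixels (NaN) are excluded from the ORR statistics; if the
    whole region is undefined the ORR statistics are NaN but the record is
    still produced.
    """
    region_mask = np.asarray(region_mask).astype(bool)
    if not region_mask.any():
        raise ValueError("region is empty")
    if not (region_mask.shape == nadh.shape == fad.shape == orr.shape):
        raise ValueError("mask and image shapes must match")

    record: dict[str, float] = {}
    orr_vals = orr[region_mask]
    orr_vals = orr_vals[np.isfinite(orr_vals)]
    for name, vals in (("orr", orr_vals), ("nadh", nadh[region_mask]), ("fad", fad[region_mask])):
        if vals.size == 0:
            record.update({f"mean_{name}": np.nan, f"min_{name}": np.nan,
                           f"max_{name}": np.nan, f"std_{name}": np.nan})
        else:
            record[f"mean_{name}"] = float(np.mean(vals))
            record[f"min_{name}"] = float(np.min(vals))
            record[f"max_{name}"] = float(np.max(vals))
            record[f"std_{name}"] = float(np.std(vals))

    props = measure.regionprops(region_mask.astype(np.uint8))[0]
    area = float(props.area)
    record["area"] = area
    record["perimeter"] = _hull_perimeter(region_mask)
    record["solidity"] = float(props.solidity)
    record["extent"] = float(props.extent)
    record["eccentricity"] = float(props.eccentricity)
    record["circularity"] = circularity(region_mask)
    fmin, fmax = feret_diameters(region_mask)
    record["feret_min"] = fmin
    record["feret_max"] = fmax
    record["minor_axis"] = float(props.axis_minor_length)
    record["major_axis"] = float(props.axis_major_length)
    record["convex_area"] = float(props.area_convex)
    record["equivalent_diameter"] = float(np.sqrt(4.0 * area / np.pi))
    return record


def build_feature_table(
    tracks: list[OrganoidTrack],
    masks: list[np.ndarray],
    nadh_frames: list[np.ndarray],
    fad_frames: list[np.ndarray],
    orr_frames: list[np.ndarray],
    times_h: list[float],
    *,
    well: str = "well",
    treatment: str = "control",
) -> pd.DataFrame:
    """Assemble the long-format table: one row per (track, detected frame).

    Gap frames produce no row.  ``border_touching`` flags rows whose region
    touches the frame border.
    """
    h, w = masks[0].shape
    rows = []
    for track in tracks:
        for frame_idx, label, _ in track.nodes:
            mask = masks[frame_idx] == label
            if not mask.any():
                raise ValueError(
                    f"track {track.track_id} references missing label {label} "
                    f"in frame {frame_idx}"
                )
            rec = quantify_organoid(
                mask, nadh_frames[frame_idx], fad_frames[frame_idx], orr_frames[frame_idx]
            )
            ys, xs = np.nonzero(mask)
            rec.update(
                organoid_id=track.track_id,
                well=well,
                treatment=treatment,
                time_h=times_h[frame_idx],
                border_touching=bool(
                    (ys.min() == 0) or (xs.min() == 0) or (ys.max() == h - 1) or (xs.max() == w - 1)
                ),
            )
            rows.append(rec)
    return pd.DataFrame(rows, columns=KEY_COLUMNS + FEATURE_COLUMNS)


def exclude_border_tracks(table: pd.DataFrame) -> pd.DataFrame:
    """Drop every track that touches the border at ANY time point.

    Longitudinal models need complete per-organoid series, so a single
    clipped frame invalidates the whole track.
    """
    if table.empty:
        return table.copy()
    touching = table.groupby("organoid_id")["border_touching"].any()
    dropped = touching[touching].index.tolist()
    if dropped:
        log.info("excluding border-touching tracks: %s", dropped)
    return table[~table["organoid_id"].isin(dropped)].reset_index(drop=True)
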