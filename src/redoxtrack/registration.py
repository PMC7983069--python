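"""Rigid XY registration of well time series and per-pixel redox ratio.

Frame-to-frame stage drift is corrected by integer-pixel translation found
by maximizing the normalized cross-correlation of the NAD(P)H images
against the pretreatment frame; the same shifts are applied to the paired
FAD frames.  After shifting, all frames are cropped to the rectangle common
to every frame, so no pixel outside the overlap enters downstream analysis.

The optical redox ratio is computed per pixel as

    ORR = NAD(P)H / (FAD + NAD(P)H)

on the raw registered intensities (no background subtraction).  Pixels with
zero intensity in both channels are undefined and carried as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from redoxtrack.io import ChannelImage, WellTimeSeries, NADH, FAD


class RegistrationError(RuntimeError):
    """Raised for degenerate registration inputs (constant images, empty overlap)."""


@dataclass(frozen=True)
class ShiftVector:
    """Integer displacement (dy, dx) moving a frame into the reference grid."""

    dy: int
    dx: int
    peak_ncc: float = 1.0
    low_confidence: bool = False


@dataclass
class RedoxImage:
    """Per-pixel optical redox ratio; NaN marks undefined (both-zero) pixels."""

    pixels: np.ndarray
    time_h: float = 0.0
    well_id: str = "well"


def estimate_shift(
    reference: ChannelImage | np.ndarray,
    moving: ChannelImage | np.ndarray,
    *,
    max_shift: int | None = None,
    ncc_threshold: float = 0.2,
) -> ShiftVector:
    """Integer shift (dy, dx) that best aligns ``moving`` onto ``reference``.

    The shift maximizes the normalized cross-correlation of overlapping
    pixels; ties are broken by smaller shift magnitude, then lexicographic
    (dy, dx).  A peak NCC below ``ncc_threshold`` flags the result as low
    confidence (the shift is still returned).
    """
    ref = reference.pixels if isinstance(reference, ChannelImage) else np.asarray(reference, float)
    mov = moving.pixels if isinstance(moving, ChannelImage) else np.asarray(moving, float)
    if ref.shape != mov.shape:
        raise RegistrationError(f"shape mismatch {ref.shape} vs {mov.shape}")
    if ref.std() == 0 or mov.std() == 0:
        raise RegistrationError("cannot register a constant image")

    h, w = ref.shape
    if max_shift is None:
        max_shift = min(h, w) // 2

    # Exact windowed NCC for every integer offset via FFT running sums:
    # over the overlap O(d), NCC = cov(r, m) / (sd(r) sd(m)), with all sums
    # (r, m, r^2, m^2, r*m over O(d)) computed as correlations with ones.
    ones = np.ones_like(ref)
    flip = mov[::-1, ::-1]
    n_overlap = signal.fftconvolve(ones, ones, mode="full")
    n_overlap = np.maximum(np.rint(n_overlap), 1.0)
    s_rm = signal.fftconvolve(ref, flip, mode="full")
    s_r = signal.fftconvolve(ref, np.ones_like(mov)[::-1, ::-1], mode="full")
    s_m = signal.fftconvolve(ones, flip, mode="full")
    s_r2 = signal.fftconvolve(ref**2, np.ones_like(mov)[::-1, ::-1], mode="full")
    s_m2 = signal.fftconvolve(ones, (mov**2)[::-1, ::-1], mode="full")
    cov = s_rm - s_r * s_m / n_overlap
    var_r = np.maximum(s_r2 - s_r**2 / n_overlap, 0.0)
    var_m = np.maximum(s_m2 - s_m**2 / n_overlap, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ncc = cov / np.sqrt(var_r * var_m)
    ncc = np.where(np.isfinite(ncc), ncc, -np.inf)

    # offset (dy, dx): moving shifted by (dy, dx) aligns with reference
    dys = np.arange(-(h - 1), h)
    dxs = np.arange(-(w - 1), w)
    valid = (np.abs(dys)[:, None] <= max_shift) & (np.abs(dxs)[None, :] <= max_shift)
    # require at least a quarter of the frame to overlap
    valid &= n_overlap >= 0.25 * ref.size
    ncc = np.where(valid, ncc, -np.inf)

    best = np.max(ncc)
    iy, ix = np.nonzero(ncc >= best - 1e-12)
    cand_dy, cand_dx = dys[iy], dxs[ix]
    order = np.lexsort((cand_dx, cand_dy, np.hypot(cand_dy, cand_dx)))
    dy, dx = int(cand_dy[order[0]]), int(cand_dx[order[0]])
    peak = float(best)
    return ShiftVector(dy, dx, peak_ncc=peak, low_confidence=peak < ncc_threshold)


def shift_and_crop(pixels: np.ndarray, shift: ShiftVector, region: tuple[int, int, int, int]) -> np.ndarray:
    """Apply an integer shift then crop to region (y0, y1, x0, x1) on the reference grid."""
    y0, y1, x0, x1 = region
    h, w = pixels.shape
    out = np.empty((y1 - y0, x1 - x0), dtype=pixels.dtype)
    src_y = slice(y0 - shift.dy, y1 - shift.dy)
    src_x = slice(x0 - shift.dx, x1 - shift.dx)
    if src_y.start < 0 or src_y.stop > h or src_x.start < 0 or src_x.stop > w:
        raise RegistrationError("crop region exceeds shifted frame bounds")
    out[:] = pixels[src_y, src_x]
    return out


def common_region(
    shifts: list[ShiftVector], shape: tuple[int, int]
) -> tuple[int, int, int, int]:
    """Intersection rectangle (y0, y1, x0, x1) of all shifted frames on the reference grid."""
    h, w = shape
    y0 = max(s.dy for s in shifts + [ShiftVector(0, 0)])
    y1 = min(s.dy + h for s in shifts + [ShiftVector(0, 0)])
    x0 = max(s.dx for s in shifts + [ShiftVector(0, 0)])
    x1 = min(s.dx + w for s in shifts + [ShiftVector(0, 0)])
    y0, x0 = max(y0, 0), max(x0, 0)
    y1, x1 = min(y1, h), min(x1, w)
    if y1 <= y0 or x1 <= x0:
        raise RegistrationError("registered frames have empty common region")
    return (y0, y1, x0, x1)


def register_series(
    series: WellTimeSeries, *, max_shift: int | None = None
) -> tuple[WellTimeSeries, tuple[int, int, int, int], list[ShiftVector]]:
    """Register all frames to the pretreatment frame and crop to the overlap.

    Shifts are estimated on the NAD(P)H channel only (frame 0 is the
    reference) and applied unchanged to the paired FAD frames.  Returns the
    cropped registered series, the common region on the reference grid, and
    the per-frame shifts.
    """
    if series.n_frames < 2:
        raise RegistrationError("need at least 2 frames to register")
    ref = series.frames[0][0]
    shifts = [ShiftVector(0, 0)]
    for nadh, _ in series.frames[1:]:
        shifts.append(estimate_shift(ref, nadh, max_shift=max_shift))
    region = common_region(shifts, series.shape)

    frames = []
    for (nadh, fad), s in zip(series.frames, shifts):
        frames.append(
            (
                ChannelImage(shift_and_crop(nadh.pixels, s, region), NADH, nadh.time_h, nadh.well_id),
                ChannelImage(shift_and_crop(fad.pixels, s, region), FAD, fad.time_h, fad.well_id),
            )
        )
    registered = WellTimeSeries(frames, treatment=series.treatment, well_id=series.well_id)
    return registered, region, shifts


def compute_orr(nadh: ChannelImage | np.ndarray, fad: ChannelImage | np.ndarray) -> RedoxImage:
    """Per-pixel ORR = NADH / (FAD + NADH); both-zero pixels are NaN."""
    time_h = nadh.time_h if isinstance(nadh, ChannelImage) else 0.0
    well_id = nadh.well_id if isinstance(nadh, ChannelImage) else "well"
    n = nadh.pixels if isinstance(nadh, ChannelImage) else np.asarray(nadh, float)
    f = fad.pixels if isinstance(fad, ChannelImage) else np.asarray(fad, float)
    if n.shape != f.shape:
        raise ValueError(f"channel shape mismatch {n.shape} vs {f.shape}")
    if np.any(n < 0) or np.any(f < 0):
        raise ValueError("intensities must be non-negative")
    total = n + f
    with np.errstate(invalid="ignore", divide="ignore"):
        orr = np.where(total > 0, n / np.where(total > 0, total, 1.0), np.nan)
    return RedoxImage(orr, time_h=time_h, well_id=well_id)
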