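"""Synthetic organoid phantom generator with ground truth.

Emulates wide-field one-photon autofluorescence image series of organoids
embedded in gel: two channels (NAD(P)H, FAD) per time point, a low
signal-to-background ratio (SBR ~ 2-3), slow growth and treatment-dependent
redox trajectories over 48 h, global stage drift between frames, and
camera-like noise.  Every frame comes with ground-truth label masks, true
tracks and true per-organoid area / mean-ORR trajectories, so segmentation,
tracking, quantification and statistics can all be validated end to end.

Organoids are rendered as disks with a low-order radial Fourier
perturbation (irregular but blobby, circularity well above 0.4).  Two
phenotypes are modelled after the solid/hollow dichotomy seen in colorectal
organoid cultures: *solid* organoids have an FAD-elevated core, so the core
ORR is below the rim ORR; *hollow* organoids are brighter in NAD(P)H with
the reverse radial ordering and a higher overall ORR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from redoxtrack.io import ChannelImage, WellTimeSeries, NADH, FAD

#: Acquisition schedule in hours; 20 min post-treatment is encoded as 0.33 h.
DEFAULT_TIMES_H = (0.0, 0.33, 12.0, 24.0, 36.0, 48.0)

#: Per-treatment (ORR multiplier, area multiplier) trajectories over
#: DEFAULT_TIMES_H.  Control area reaches +10% at 48 h; cyanide shows the
#: transient ORR spike at 20 min characteristic of electron-transport-chain
#: inhibition, followed by a decline; the chemotherapies keep growing until
#: ~24 h before falling behind control.
TREATMENTS: dict[str, dict[str, tuple[float, ...]]] = {
    "control": {
        "orr": (1.0, 1.0, 1.0, 1.0, 1.0, 1.0),
        "area": (1.0, 1.001, 1.03, 1.06, 1.085, 1.10),
    },
    "cyanide": {
        "orr": (1.0, 1.25, 1.05, 0.95, 0.88, 0.85),
        "area": (1.0, 1.0, 1.0, 1.0, 0.99, 0.98),
    },
    "2DG": {
        "orr": (1.0, 1.0, 0.90, 0.87, 0.85, 0.84),
        "area": (1.0, 1.0, 1.0, 0.99, 0.985, 0.98),
    },
    "cisplatin": {
        "orr": (1.0, 1.0, 0.98, 0.97, 0.95, 0.90),
        "area": (1.0, 1.0, 1.02, 1.03, 1.03, 1.02),
    },
    "paclitaxel": {
        "orr": (1.0, 1.0, 0.92, 0.88, 0.85, 0.82),
        "area": (1.0, 1.0, 1.03, 1.05, 1.02, 1.00),
    },
}

SOLID = "solid"
HOLLOW = "hollow"

#: Rim/core ORR per phenotype.  Solid: dead core rich in flavins, core ORR
#: below rim.  Hollow: fluid-filled lumen, core ORR above rim and a higher
#: overall ORR driven by brighter NAD(P)H.
PHENOTYPE_ORR = {SOLID: {"rim": 0.70, "core": 0.50}, HOLLOW: {"rim": 0.60, "core": 0.78}}
#: Relative total-intensity boost of hollow organoids (brighter NAD(P)H).
HOLLOW_BRIGHTNESS = 1.15


class PlacementError(RuntimeError):
    """Raised when non-overlapping organoid placement fails after retries."""


@dataclass
class PhantomConfig:
    """Configuration of a phantom well series.

    The defaults describe the working scale used throughout the test suite:
    512x512 frames (a 4x-downscaled stand-in for the 2048x2048 camera frame),
    organoid radii 25-60 px, six time points over 48 h, SBR drawn uniformly
    from [2, 3], and a global integer stage drift per frame.
    """

    image_size: tuple[int, int] = (512, 512)
    times_h: tuple[float, ...] = DEFAULT_TIMES_H
    n_organoids: int = 8
    hollow_fraction: float = 0.19
    radius_range: tuple[float, float] = (25.0, 60.0)
    treatment: str = "control"
    sbr_range: tuple[float, float] = (2.0, 3.0)
    background_level: float = 100.0
    drift_px: tuple[int, int] = (2, 2)
    read_noise_sigma: float = 5.0
    shot_noise_gain: float = 1.0
    min_gap_px: float = 12.0
    max_place_tries: int = 20000
    growth_model: tuple[float, ...] | None = None
    orr_model: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(
                f"unknown treatment {self.treatment!r}; choose from {sorted(TREATMENTS)}"
            )
        if len(self.times_h) != len(DEFAULT_TIMES_H):
            raise ValueError("times_h must have the standard six time points")
        if self.sbr_range[0] <= 1:
            raise ValueError("signal-to-background ratio must exceed 1")
        if self.radius_range[0] < 5:
            raise ValueError("minimum radius must be >= 5 px")
        if self.background_level <= 0:
            raise ValueError("background level must be positive")
        if not 0 <= self.hollow_fraction <= 1:
            raise ValueError("hollow_fraction must lie in [0, 1]")
        for model in (self.growth_model, self.orr_model):
            if model is not None:
                if len(model) != len(self.times_h):
                    raise ValueError("trajectory override must match times_h length")
                if any(m <= 0 for m in model):
                    raise ValueError("trajectory multipliers must be positive")


@dataclass
class PhantomTruth:
    """Ground truth of a generated series.

    masks : per-frame label images; label k marks organoid k at every frame.
    tracks : long table (organoid_id, frame, time_h, y, x).
    per_organoid : long table (organoid_id, time_h, phenotype, area_px,
        mean_orr, sbr) of noise-free truth values.
    drifts : cumulative (dy, dx) content shift applied at each frame.
    """

    masks: list[np.ndarray]
    tracks: pd.DataFrame
    per_organoid: pd.DataFrame
    drifts: list[tuple[int, int]]


def apply_treatment_model(
    treatment: str, times_h: Sequence[float] = DEFAULT_TIMES_H
) -> pd.DataFrame:
    """Return the (time, ORR multiplier, area multiplier) trajectory table."""
    if treatment not in TREATMENTS:
        raise ValueError(
            f"unknown treatment {treatment!r}; choose from {sorted(TREATMENTS)}"
        )
    traj = TREATMENTS[treatment]
    return pd.DataFrame(
        {
            "time_h": list(times_h),
            "orr_multiplier": traj["orr"],
            "area_multiplier": traj["area"],
        }
    )


def _radial_profile(
    shape: tuple[int, int], center: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(yy - center[0], xx - center[1]), np.arctan2(yy - center[0], xx - center[1])


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def render_organoid(
    center: tuple[float, float],
    radius: float,
    phenotype: str,
    *,
    rim_orr: float | None = None,
    core_orr: float | None = None,
    total_intensity: float = 500.0,
    background: float = 100.0,
    shape_coeffs: Sequence[tuple[float, float]] = (),
    patch_shape: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one organoid patch (noise-free).

    Returns ``(mask, nadh, fad)`` on a patch of ``patch_shape`` (default: a
    square comfortably containing the organoid).  The outline is a disk of
    the given radius perturbed by the low-order radial Fourier terms in
    ``shape_coeffs`` (pairs of (amplitude, phase) for harmonics 2, 3, ...).
    The per-pixel ORR ramps smoothly from ``core_orr`` inside to ``rim_orr``
    at the boundary; background pixels hold the flat background level in
    both channels (background ORR = 0.5).
    """
    if radius < 5:
        raise ValueError("organoid radius must be >= 5 px")
    if total_intensity <= 0 or background <= 0:
        raise ValueError("intensities must be positive")
    if phenotype not in (SOLID, HOLLOW):
        raise ValueError(f"phenotype must be {SOLID!r} or {HOLLOW!r}")
    defaults = PHENOTYPE_ORR[phenotype]
    rim = defaults["rim"] if rim_orr is None else rim_orr
    core = defaults["core"] if core_orr is None else core_orr
    for v in (rim, core):
        if not 0 < v < 1:
            raise ValueError("ORR levels must lie in (0, 1)")
    if (phenotype == SOLID) != (core < rim) and core != rim:
        raise ValueError("solid requires core ORR < rim ORR; hollow the reverse")

    if patch_shape is None:
        half = int(np.ceil(radius * 1.35)) + 3
        patch_shape = (2 * half + 1, 2 * half + 1)
    rr, theta = _radial_profile(patch_shape, center)

    boundary = np.full_like(rr, radius)
    for k, (amp, phase) in enumerate(shape_coeffs, start=2):
        boundary = boundary + radius * amp * np.cos(k * theta + phase)
    boundary = np.maximum(boundary, 1.0)

    # coverage ramps 1 -> 0 over ~2 px across the boundary (anti-aliasing)
    coverage = _smoothstep((boundary - rr) / 2.0 + 0.5)
    mask = coverage >= 0.5

    # radial ORR profile: core value inside 0.35*r, rim value beyond 0.75*r
    rho = rr / boundary
    t = _smoothstep((rho - 0.35) / 0.40)
    orr = core + (rim - core) * t

    nadh_fg = total_intensity * orr
    fad_fg = total_intensity * (1.0 - orr)
    nadh = background + coverage * (nadh_fg - background)
    fad = background + coverage * (fad_fg - background)
    return mask, nadh, fad


def _place_centers(
    rng: np.random.Generator, config: PhantomConfig, radii: np.ndarray, margin: float
) -> np.ndarray:
    h, w = config.image_size
    n = len(radii)
    centers = np.zeros((n, 2))
    placed: list[int] = []
    # biggest organoids first: greatly improves rejection-sampling success
    for i in sorted(range(n), key=lambda i: -radii[i]):
        r = radii[i]
        lo_y, hi_y = margin + r, h - margin - r
        lo_x, hi_x = margin + r, w - margin - r
        if lo_y >= hi_y or lo_x >= hi_x:
            raise PlacementError("image too small for requested organoid radii")
        for _ in range(config.max_place_tries):
            cy = rng.uniform(lo_y, hi_y)
            cx = rng.uniform(lo_x, hi_x)
            ok = all(
                np.hypot(cy - centers[j, 0], cx - centers[j, 1])
                >= r + radii[j] + config.min_gap_px
                for j in placed
            )
            if ok:
                centers[i] = (cy, cx)
                placed.append(i)
                break
        else:
            raise PlacementError(
                f"could not place organoid {i} without overlap after "
                f"{config.max_place_tries} tries"
            )
    return centers


def generate_phantom_series(config: PhantomConfig) -> tuple[WellTimeSeries, PhantomTruth]:
    """Generate a two-channel phantom well series plus ground truth.

    Identical config and seed yield bit-identical images and truth tables.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size
    n = config.n_organoids
    times = np.asarray(config.times_h)
    traj = apply_treatment_model(config.treatment, config.times_h)
    area_mult = (
        np.asarray(config.growth_model, float)
        if config.growth_model is not None
        else traj["area_multiplier"].to_numpy()
    )
    orr_mult = (
        np.asarray(config.orr_model, float)
        if config.orr_model is not None
        else traj["orr_multiplier"].to_numpy()
    )

    radii = rng.uniform(*config.radius_range, size=n)
    n_hollow = int(round(config.hollow_fraction * n))
    phenotypes = np.array([HOLLOW] * n_hollow + [SOLID] * (n - n_hollow))
    rng.shuffle(phenotypes)
    sbrs = rng.uniform(*config.sbr_range, size=n)
    # 3 radial harmonics (k = 2, 3, 4), small amplitudes keep blobs convex-ish
    shape_coeffs = [
        [(rng.uniform(0.02, 0.07), rng.uniform(0, 2 * np.pi)) for _ in range(3)]
        for _ in range(n)
    ]

    max_growth = float(np.sqrt(area_mult.max())) if n else 1.0
    total_drift = (
        abs(config.drift_px[0]) * (len(times) - 1),
        abs(config.drift_px[1]) * (len(times) - 1),
    )
    # unlucky radius draws can make a non-overlapping layout infeasible;
    # redraw radii and re-place for a bounded number of whole-layout restarts
    for restart in range(50):
        margin = max(total_drift) + 6 + (max_growth - 1.0) * (radii.max() if n else 0)
        try:
            centers0 = _place_centers(rng, config, radii * max_growth * 1.1, margin)
            break
        except PlacementError:
            if restart == 49:
                raise
            radii = rng.uniform(*config.radius_range, size=n)

    frames: list[tuple[ChannelImage, ChannelImage]] = []
    masks: list[np.ndarray] = []
    drifts: list[tuple[int, int]] = []
    track_rows, truth_rows = [], []

    bg = config.background_level
    for ti, t in enumerate(times):
        drift = (config.drift_px[0] * ti, config.drift_px[1] * ti)
        drifts.append(drift)
        nadh = np.full((h, w), bg, dtype=np.float64)
        fad = np.full((h, w), bg, dtype=np.float64)
        labels = np.zeros((h, w), dtype=np.int32)
        orr_map = np.zeros((h, w), dtype=np.float64)

        for i in range(n):
            r_t = radii[i] * np.sqrt(area_mult[ti])
            ph = str(phenotypes[i])
            levels = PHENOTYPE_ORR[ph]
            rim = float(np.clip(levels["rim"] * orr_mult[ti], 0.02, 0.98))
            core = float(np.clip(levels["core"] * orr_mult[ti], 0.02, 0.98))
            if ph == SOLID:
                core = min(core, rim - 1e-3)
            else:
                core = max(core, rim + 1e-3)
            brightness = HOLLOW_BRIGHTNESS if ph == HOLLOW else 1.0
            total = 2.0 * bg * sbrs[i] * brightness
            cy = centers0[i, 0] + drift[0]
            cx = centers0[i, 1] + drift[1]
            half = int(np.ceil(r_t * 1.35)) + 3
            y0, x0 = int(np.floor(cy)) - half, int(np.floor(cx)) - half
            pshape = (2 * half + 1, 2 * half + 1)
            mask, pn, pf = render_organoid(
                (cy - y0, cx - x0),
                r_t,
                ph,
                rim_orr=rim,
                core_orr=core,
                total_intensity=total,
                background=bg,
                shape_coeffs=shape_coeffs[i],
                patch_shape=pshape,
            )
            ys = slice(max(y0, 0), min(y0 + pshape[0], h))
            xs = slice(max(x0, 0), min(x0 + pshape[1], w))
            pys = slice(ys.start - y0, ys.stop - y0)
            pxs = slice(xs.start - x0, xs.stop - x0)
            sub = mask[pys, pxs]
            nadh[ys, xs] = np.where(sub, pn[pys, pxs], nadh[ys, xs])
            fad[ys, xs] = np.where(sub, pf[pys, pxs], fad[ys, xs])
            labels[ys, xs][sub] = i + 1

            with np.errstate(invalid="ignore"):
                po = pn / (pn + pf)
            area = int(sub.sum())
            mean_orr = float(po[pys, pxs][sub].mean()) if area else np.nan
            track_rows.append(
                {"organoid_id": i + 1, "frame": ti, "time_h": t, "y": cy, "x": cx}
            )
            truth_rows.append(
                {
                    "organoid_id": i + 1,
                    "time_h": t,
                    "phenotype": ph,
                    "area_px": area,
                    "mean_orr": mean_orr,
                    "sbr": sbrs[i],
                }
            )

        sigma = np.sqrt(
            config.read_noise_sigma**2 + config.shot_noise_gain * np.maximum(nadh, 0)
        )
        nadh_noisy = np.maximum(nadh + rng.normal(0, 1, (h, w)) * sigma, 0.0)
        sigma = np.sqrt(
            config.read_noise_sigma**2 + config.shot_noise_gain * np.maximum(fad, 0)
        )
        fad_noisy = np.maximum(fad + rng.normal(0, 1, (h, w)) * sigma, 0.0)

        frames.append(
            (
                ChannelImage(nadh_noisy, NADH, float(t), f"phantom-{config.seed}"),
                ChannelImage(fad_noisy, FAD, float(t), f"phantom-{config.seed}"),
            )
        )
        masks.append(labels)

    series = WellTimeSeries(
        frames, treatment=config.treatment, well_id=f"phantom-{config.seed}"
    )
    truth = PhantomTruth(
        masks=masks,
        tracks=pd.DataFrame(track_rows),
        per_organoid=pd.DataFrame(truth_rows),
        drifts=drifts,
    )
    return series, truth


def measure_sbr(series: WellTimeSeries, truth: PhantomTruth) -> float:
    """Mean foreground/background intensity ratio over frames and channels."""
    ratios = []
    for (nadh, fad), labels in zip(series.frames, truth.masks):
        fg = labels > 0
        if not fg.any() or fg.all():
            continue
        for img in (nadh, fad):
            ratios.append(img.pixels[fg].mean() / img.pixels[~fg].mean())
    return float(np.mean(ratios)) if ratios else np.nan
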