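"""End-to-end orchestration: images -> ORR -> masks -> tracks -> features -> stats.

``process_well`` runs the image-analysis chain for one well (registration,
per-frame ORR, segmentation, tracking, quantification, border exclusion).
``run_pipeline`` maps it over a set of wells (phantom-generated or read
from manifests), then runs the cross-well statistics (normalization, mixed
model, least-squares-means contrasts) and the PCA stage, writing every
stage artifact as CSV/TIFF plus a JSON-lines run log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from redoxtrack.io import WellTimeSeries, read_well_series
from redoxtrack.registration import register_series, compute_orr
from redoxtrack.segmentation import SegmentationParams, segment_frame
from redoxtrack.tracking import TrackingParams, extract_centroids, link_tracks
from redoxtrack.features import build_feature_table, exclude_border_tracks
from redoxtrack import stats as rstats
from redoxtrack import multivariate as mv
from redoxtrack.phantom import PhantomConfig, generate_phantom_series

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    Provide either ``phantom_configs`` (one per well) or ``manifests``
    (paths to per-well manifest CSVs).  ``stats_variables`` are the feature
    columns analyzed longitudinally.
    """

    out_dir: Path = Path("redoxtrack_run")
    phantom_configs: list[PhantomConfig] = field(default_factory=list)
    manifests: list[Path] = field(default_factory=list)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    segmentation_mode: str = "scaled"
    tracking: TrackingParams = field(default_factory=TrackingParams)
    stats_variables: tuple[str, ...] = ("mean_orr", "area")
    normalization: str = rstats.ORGANOID_LEVEL
    seed: int = 0
    write_images: bool = True


@dataclass
class WellResult:
    series: WellTimeSeries
    shifts: list
    region: tuple[int, int, int, int]
    orr_frames: list[np.ndarray]
    masks: list[np.ndarray]
    tracks: list
    features: pd.DataFrame  # border-excluded
    features_all: pd.DataFrame


def process_well(
    series: WellTimeSeries,
    *,
    seg_params: SegmentationParams | None = None,
    seg_mode: str = "scaled",
    track_params: TrackingParams | None = None,
) -> WellResult:
    """Run registration, ORR, segmentation, tracking and quantification."""
    registered, region, shifts = register_series(series)
    nadh_frames = [n.pixels for n, _ in registered.frames]
    fad_frames = [f.pixels for _, f in registered.frames]
    orr_frames = [
        compute_orr(n, f).pixels for n, f in zip(nadh_frames, fad_frames)
    ]
    masks = [
        segment_frame(img, seg_params, mode=seg_mode) for img in nadh_frames
    ]
    centroid_sets = [extract_centroids(m, i) for i, m in enumerate(masks)]
    tracks = link_tracks(centroid_sets, track_params)
    times = [n.time_h for n, _ in registered.frames]
    table = build_feature_table(
        tracks, masks, nadh_frames, fad_frames, orr_frames, times,
        well=series.well_id, treatment=series.treatment,
    )
    kept = exclude_border_tracks(table)
    return WellResult(
        series=registered, shifts=shifts, region=region, orr_frames=orr_frames,
        masks=masks, tracks=tracks, features=kept, features_all=table,
    )


def tracks_to_frame(result: WellResult) -> pd.DataFrame:
    times = [n.time_h for n, _ in result.series.frames]
    rows = []
    for t in result.tracks:
        for f, label, (y, x) in t.nodes:
            rows.append(
                {
                    "track_id": t.track_id,
                    "frame": f,
                    "time_h": times[f],
                    "label": label,
                    "y": y,
                    "x": x,
                }
            )
    return pd.DataFrame(rows, columns=["track_id", "frame", "time_h", "label", "y", "x"])


def tracks_from_frame(df: pd.DataFrame) -> list:
    """Inverse of :func:`tracks_to_frame`: rebuild OrganoidTrack objects."""
    from redoxtrack.tracking import OrganoidTrack

    tracks = []
    for tid, grp in df.sort_values(["track_id", "frame"]).groupby("track_id"):
        nodes = [
            (int(r["frame"]), int(r["label"]), (float(r["y"]), float(r["x"])))
            for _, r in grp.iterrows()
        ]
        tracks.append(OrganoidTrack(int(tid), nodes))
    return tracks


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Run every stage and write artifacts under ``config.out_dir``.

    Re-running with the same config and seed reproduces identical CSVs.
    Returns a manifest dict of the artifacts produced.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    events: list[dict] = []

    def event(stage: str, **kw):
        rec = {"stage": stage, **kw}
        events.append(rec)
        log.info("%s", rec)

    wells: list[tuple[WellTimeSeries, object]] = []
    if config.phantom_configs:
        for i, pc in enumerate(config.phantom_configs):
            pc = dataclasses.replace(pc, seed=pc.seed if pc.seed else config.seed + i)
            series, truth = generate_phantom_series(pc)
            wells.append((series, truth))
            event("phantom", well=series.well_id, treatment=pc.treatment, seed=pc.seed)
    for m in config.manifests:
        try:
            series = read_well_series(m)
        except Exception as exc:
            raise PipelineError("input", str(exc)) from exc
        wells.append((series, None))
        event("input", well=series.well_id, manifest=str(m))
    if not wells:
        raise PipelineError("input", "no phantom configs or manifests given")

    artifacts: dict[str, object] = {"wells": []}
    all_features = []
    for series, truth in wells:
        wid = series.well_id
        try:
            result = process_well(
                series,
                seg_params=config.segmentation,
                seg_mode=config.segmentation_mode,
                track_params=config.tracking,
            )
        except Exception as exc:
            raise PipelineError("image-analysis", f"well {wid}: {exc}") from exc
        event(
            "registration", well=wid,
            shifts=[(s.dy, s.dx) for s in result.shifts], region=result.region,
        )
        event(
            "segmentation", well=wid,
            organoids_per_frame=[int(m.max()) for m in result.masks],
        )
        dropped = sorted(
            set(result.features_all["organoid_id"]) - set(result.features["organoid_id"])
        )
        event("features", well=wid, n_tracks=len(result.tracks),
              border_excluded_tracks=dropped, reason_code="BORDER" if dropped else None)

        # make organoid ids globally unique across wells before pooling
        for table in (result.features, result.features_all):
            table["organoid_id"] = [f"{wid}:{tid}" for tid in table["organoid_id"]]

        wdir = out / wid
        wdir.mkdir(exist_ok=True)
        if config.write_images:
            for i, (orr, mask) in enumerate(zip(result.orr_frames, result.masks)):
                tifffile.imwrite(wdir / f"orr_t{i:03d}.tif", orr.astype(np.float32))
                tifffile.imwrite(wdir / f"mask_t{i:03d}.tif", mask.astype(np.uint16))
        tracks_to_frame(result).to_csv(wdir / "tracks.csv", index=False)
        result.features_all.to_csv(wdir / "features_all.csv", index=False)
        result.features.to_csv(wdir / "features.csv", index=False)
        all_features.append(result.features)
        artifacts["wells"].append(
            {"well": wid, "dir": str(wdir), "n_tracks": len(result.tracks)}
        )

    features = pd.concat(all_features, ignore_index=True) if all_features else pd.DataFrame()
    features.to_csv(out / "features.csv", index=False)
    artifacts["features"] = str(out / "features.csv")

    # longitudinal statistics (needs >= 2 treatment groups)
    n_groups = features["treatment"].nunique() if not features.empty else 0
    if n_groups >= 2:
        for variable in config.stats_variables:
            series_df = rstats.normalize(features, variable, config.normalization)
            try:
                fit = (
                    rstats.fit_lmm(series_df)
                    if config.normalization == rstats.ORGANOID_LEVEL
                    else rstats.fit_pooled(series_df)
                )
            except rstats.DesignError as exc:
                raise PipelineError("stats", str(exc)) from exc
            contrasts = rstats.lsmeans_contrasts(fit)
            contrasts.to_csv(out / f"contrasts_{variable}.csv", index=False)
            emm = rstats.estimated_marginal_means(fit)
            emm.to_csv(out / f"emmeans_{variable}.csv", index=False)
            event(
                "stats", variable=variable, rho=fit.rho, sigma_b2=fit.sigma_b2,
                sigma2=fit.sigma2, converged=fit.converged,
            )
            artifacts[f"contrasts_{variable}"] = str(out / f"contrasts_{variable}.csv")
    else:
        event("stats", skipped=True, reason_code="SINGLE_GROUP",
              detail="least-squares-means contrasts need >= 2 treatment groups")

    # PCA stage: pretreatment loadings, 24/48-h projection
    if not features.empty and features["time_h"].nunique() >= 1:
        t0 = features["time_h"].min()
        try:
            std, variables = mv.standardize_within_time(features)
            model = mv.fit_pca(std[std["time_h"] == t0], variables)
            scores = mv.project(model, std)
            scores["group"] = std["treatment"].to_numpy()
            scores.to_csv(out / "pca_scores.csv", index=False)
            model.loadings.to_csv(out / "pca_loadings.csv")
            mv.top_loadings(model).to_csv(out / "pca_top_loadings.csv", index=False)
            event("pca", n_variables=len(variables),
                  explained_pc12=float(model.explained_variance_ratio[:2].sum()))
            artifacts["pca_scores"] = str(out / "pca_scores.csv")
        except ValueError as exc:
            event("pca", skipped=True, reason_code="TOO_FEW_ROWS", detail=str(exc))

    with open(out / "run_log.jsonl", "w") as fh:
        for rec in events:
            fh.write(json.dumps(rec, default=str) + "\n")
    artifacts["run_log"] = str(out / "run_log.jsonl")
    return artifacts
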