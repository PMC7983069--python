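"""Frame-to-frame organoid linking with gap closing (LAP-style).

Segmented organoids are reduced to their centroids and linked across time
in two passes, following the linear-assignment-problem architecture of
single-particle trackers: (1) optimal frame-to-frame assignment minimizing
total squared displacement, with links beyond ``max_link_dist`` forbidden;
(2) a gap-closing pass joining track ends to later track starts within
``max_gap_dist`` and at most ``max_gap_frames`` skipped frames.  Defaults
(200 px link, 200 px gap, 2-frame gap) match slow organoid drift at the
acquisition scale.  Splits and merges are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

log = logging.getLogger(__name__)


@dataclass
class TrackingParams:
    max_link_dist: float = 200.0
    max_gap_dist: float = 200.0
    max_gap_frames: int = 2

    def __post_init__(self) -> None:
        if min(self.max_link_dist, self.max_gap_dist) <= 0 or self.max_gap_frames < 0:
            raise ValueError("tracking parameters must be positive")


@dataclass
class CentroidSet:
    """Centroids of one frame's label mask, keyed by source label."""

    frame_index: int
    points: np.ndarray  # (n, 2) of (y, x)
    labels: np.ndarray  # (n,) source mask labels


@dataclass
class OrganoidTrack:
    """One organoid identity across frames.

    nodes: list of (frame_index, label, (y, x)); frame indices strictly
    increasing.  ``gaps`` lists frame indices skipped inside the track.
    """

    track_id: int
    nodes: list[tuple[int, int, tuple[float, float]]] = field(default_factory=list)

    @property
    def frames(self) -> list[int]:
        return [f for f, _, _ in self.nodes]

    @property
    def gaps(self) -> list[int]:
        present = set(self.frames)
        return [f for f in range(self.frames[0], self.frames[-1] + 1) if f not in present]


def extract_centroids(mask: np.ndarray, frame_index: int = 0) -> CentroidSet:
    """Unweighted centroid of every labeled region, in (y, x) pixels."""
    mask = np.asarray(mask)
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        return CentroidSet(frame_index, np.zeros((0, 2)), np.zeros(0, dtype=int))
    centroids = ndimage.center_of_mass(np.ones_like(mask), mask, labels)
    return CentroidSet(frame_index, np.asarray(centroids, dtype=float), labels.astype(int))


def _pair_assignment(
    prev_pts: np.ndarray, next_pts: np.ndarray, max_dist: float
) -> list[tuple[int, int]]:
    """Min-cost matching between two point sets with a no-link alternative.

    Each potential link costs its squared distance; leaving a point
    unmatched costs ``max_dist**2``, so a link is made only when it is
    cheaper than abandoning both endpoints.  Implemented as the standard
    augmented square LAP matrix.  Returns (prev_idx, next_idx) pairs.
    """
    n, m = len(prev_pts), len(next_pts)
    if n == 0 or m == 0:
        return []
    d2 = np.sum((prev_pts[:, None, :] - next_pts[None, :, :]) ** 2, axis=2)
    b = max_dist**2
    big = 1e12
    cost = np.full((n + m, n + m), big)
    link = np.where(d2 <= b, d2, big)
    cost[:n, :m] = link
    cost[np.arange(n), m + np.arange(n)] = b  # prev unlinked (track end)
    cost[n + np.arange(m), np.arange(m)] = b  # next unlinked (track start)
    cost[n:, m:] = 0.0
    # deterministic tie-breaking: perturb by a hierarchy far below any real
    # squared-distance difference, favoring smaller (prev, next) indices
    eps = 1e-9
    tie = eps * (np.arange(n)[:, None] * (m + 1) + np.arange(m)[None, :])
    cost[:n, :m] = np.where(link < big, link + tie, big)
    rows, cols = linear_sum_assignment(cost)
    return [(int(r), int(c)) for r, c in zip(rows, cols) if r < n and c < m and cost[r, c] < big]


def link_tracks(
    centroid_sets: list[CentroidSet], params: TrackingParams | None = None
) -> list[OrganoidTrack]:
    """Two-pass LAP linking of per-frame centroid sets into tracks."""
    if params is None:
        params = TrackingParams()
    if len(centroid_sets) < 2:
        raise ValueError("need at least 2 frames to link tracks")
    centroid_sets = sorted(centroid_sets, key=lambda c: c.frame_index)

    tracks: list[OrganoidTrack] = []
    # active maps track list index -> last node, for tracks present in the previous frame
    active: list[int] = []
    first = centroid_sets[0]
    order = np.argsort(first.labels, kind="stable")
    for i in order:
        t = OrganoidTrack(len(tracks))
        t.nodes.append((first.frame_index, int(first.labels[i]), tuple(first.points[i])))
        tracks.append(t)
        active.append(t.track_id)

    for cs in centroid_sets[1:]:
        order = np.argsort(cs.labels, kind="stable")
        pts = cs.points[order]
        labs = cs.labels[order]
        prev_pts = np.array(
            [tracks[tid].nodes[-1][2] for tid in active], dtype=float
        ).reshape(-1, 2)
        pairs = _pair_assignment(prev_pts, pts, params.max_link_dist)
        matched_next = set()
        new_active = []
        for pi, ni in pairs:
            tid = active[pi]
            tracks[tid].nodes.append((cs.frame_index, int(labs[ni]), tuple(pts[ni])))
            new_active.append(tid)
            matched_next.add(ni)
        for ni in range(len(pts)):
            if ni not in matched_next:
                t = OrganoidTrack(len(tracks))
                t.nodes.append((cs.frame_index, int(labs[ni]), tuple(pts[ni])))
                tracks.append(t)
                new_active.append(t.track_id)
        active = sorted(new_active)

    # gap closing: join track ends to later track starts
    changed = True
    while changed:
        changed = False
        ends = [
            (t.track_id, t.nodes[-1]) for t in tracks if t.nodes
        ]
        starts = [(t.track_id, t.nodes[0]) for t in tracks if t.nodes]
        candidates = []
        for eid, (ef, _, ept) in ends:
            for sid, (sf, _, spt) in starts:
                if sid == eid:
                    continue
                skipped = sf - ef - 1
                if skipped < 1 or skipped > params.max_gap_frames:
                    continue
                d2 = (ept[0] - spt[0]) ** 2 + (ept[1] - spt[1]) ** 2
                if d2 <= params.max_gap_dist**2:
                    candidates.append((d2, eid, sid))
        if not candidates:
            break
        ne = {eid for _, eid, _ in candidates}
        ns = {sid for _, _, sid in candidates}
        eids = sorted(ne)
        sids = sorted(ns)
        cost = np.full((len(eids), len(sids)), np.inf)
        for d2, eid, sid in candidates:
            cost[eids.index(eid), sids.index(sid)] = d2
        b = params.max_gap_dist**2
        n, m = cost.shape
        big = 1e12
        aug = np.full((n + m, n + m), big)
        aug[:n, :m] = np.where(np.isfinite(cost), cost, big)
        aug[np.arange(n), m + np.arange(n)] = b
        aug[n + np.arange(m), np.arange(m)] = b
        aug[n:, m:] = 0.0
        rows, cols = linear_sum_assignment(aug)
        merges = [
            (eids[r], sids[c])
            for r, c in zip(rows, cols)
            if r < n and c < m and aug[r, c] < big
        ]
        consumed = set()
        for eid, sid in sorted(merges):
            if eid in consumed or sid in consumed:
                continue
            tracks[eid].nodes.extend(tracks[sid].nodes)
            tracks[sid].nodes = []
            consumed.add(sid)
            changed = True

    tracks = [t for t in tracks if t.nodes]
    for new_id, t in enumerate(sorted(tracks, key=lambda t: (t.frames[0], t.nodes[0][1]))):
        t.track_id = new_id
    return sorted(tracks, key=lambda t: t.track_id)


def match_tracks_to_truth(
    tracks: list[OrganoidTrack], truth_tracks, max_dist: float = 20.0
) -> float:
    """Fraction of detections assigned to their majority-matched truth identity.

    ``truth_tracks`` is a table with columns (organoid_id, frame, y, x).
    Each detection is matched to the nearest truth point in its frame
    (within ``max_dist``); a track's identity is the truth id it matches
    most often, and accuracy is the fraction of matched detections carrying
    their track's majority identity.
    """
    import pandas as pd

    truth = pd.DataFrame(truth_tracks)
    if not tracks or truth.empty:
        log.warning("empty tracks or truth; identity accuracy undefined, returning 0")
        return 0.0
    assigned = []  # (track_id, truth_id or None)
    for t in tracks:
        for f, _, (y, x) in t.nodes:
            frame_truth = truth[truth["frame"] == f]
            if frame_truth.empty:
                assigned.append((t.track_id, None))
                continue
            d = np.hypot(frame_truth["y"] - y, frame_truth["x"] - x)
            j = d.idxmin()
            assigned.append(
                (t.track_id, int(frame_truth.loc[j, "organoid_id"]) if d.loc[j] <= max_dist else None)
            )
    df = pd.DataFrame(assigned, columns=["track_id", "truth_id"])
    correct = 0
    for _, grp in df.groupby("track_id"):
        ids = grp["truth_id"].dropna()
        if ids.empty:
            continue
        majority = ids.mode().iloc[0]
        correct += int((grp["truth_id"] == majority).sum())
    return correct / len(df)
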