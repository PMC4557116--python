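"""Brightfield microcolony segmentation, tracking and GFP quantification.

Microcolonies appear as dark clumps on a brighter background in brightfield
time-lapse stacks.  Segmentation is threshold-based and scale-free: a pixel
is foreground if it is an intensity outlier (beyond mean +/- 2.5 s.d. of
its frame) or sits on a strong Sobel edge.  Foreground pixels are clustered
into connected components, component centroids are matched across
consecutive frames, and per-colony area/fluorescence time series are
extracted.  Colonies that fail to double in area are flagged (debris,
stalled cells); colonies that touch are truncated at the touch time since
their areas are no longer attributable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

DEFAULT_INTENSITY_K = 2.5  # brightfield outlier threshold, in frame s.d.
DEFAULT_GFP_K = 2.0  # fluorescence signal threshold, in frame s.d.
DEFAULT_SOBEL_K = 3.0  # edge threshold, in s.d. of the gradient magnitude
DEFAULT_MIN_AREA = 5  # px; single-pixel noise floor
DEFAULT_MAX_DISPLACEMENT = 15.0  # px between consecutive centroids

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class ImageStack:
    """Frames of one channel with strictly increasing timestamps (minutes)."""

    frames: np.ndarray  # (n_frames, rows, cols)
    timestamps: np.ndarray  # minutes from experiment start
    channel: str = "brightfield"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, rows, cols) array")
        if len(self.timestamps) != len(self.frames):
            raise ValueError("one timestamp per frame required")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite pixel intensities")


@dataclass
class ColonyCluster:
    """A connected foreground component in one frame."""

    frame_index: int
    pixels: np.ndarray  # (n, 2) 0-based (row, col)
    area: int = field(init=False)
    centroid: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int)
        self.area = len(self.pixels)
        if self.area == 0:
            raise ValueError("empty cluster")
        self.centroid = (
            float(self.pixels[:, 0].mean()),
            float(self.pixels[:, 1].mean()),
        )


@dataclass
class FluorescenceRecord:
    time_minutes: float
    total: float
    mean: float | None  # None when no pixel clears the GFP threshold
    max: float


@dataclass
class ColonyTrack:
    """One microcolony followed through time."""

    track_id: int
    times: list[float] = field(default_factory=list)
    areas: list[int] = field(default_factory=list)
    clusters: list[ColonyCluster] = field(default_factory=list)
    fluorescence: list[FluorescenceRecord] = field(default_factory=list)
    passed_doubling: bool | None = None
    truncated_at_touch: bool = False
    touch_time: float | None = None

    def append(self, time: float, cluster: ColonyCluster) -> None:
        if self.times and time <= self.times[-1]:
            raise ValueError("track times must be strictly increasing")
        self.times.append(time)
        self.areas.append(cluster.area)
        self.clusters.append(cluster)

    @property
    def n_records(self) -> int:
        return len(self.times)


def detect_foreground(
    frame: np.ndarray,
    intensity_k: float = DEFAULT_INTENSITY_K,
    sobel_k: float = DEFAULT_SOBEL_K,
) -> np.ndarray:
    """Boolean foreground mask for one brightfield frame.

    A pixel is foreground if at least one criterion holds: intensity above
    mean + ``intensity_k`` s.d. (brightest pixels), below mean -
    ``intensity_k`` s.d. (darkest pixels), or Sobel gradient magnitude above
    ``sobel_k`` s.d. of the frame's gradient magnitudes (cell boundaries).
    All thresholds are relative to per-frame statistics, so the mask is
    invariant under affine rescaling of the intensities.  A constant frame
    yields an empty mask.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    mu = frame.mean()
    sd = frame.std()
    if sd == 0:
        logger.debug("constant frame: empty foreground mask")
        return np.zeros(frame.shape, dtype=bool)
    mask = (frame > mu + intensity_k * sd) | (frame < mu - intensity_k * sd)
    gx = ndimage.sobel(frame, axis=0)
    gy = ndimage.sobel(frame, axis=1)
    grad = np.hypot(gx, gy)
    gsd = grad.std()
    if gsd > 0:
        mask |= grad > grad.mean() + sobel_k * gsd
    return mask


def cluster_pixels(
    pixels: np.ndarray | Sequence[tuple[int, int]],
    frame_shape: tuple[int, int],
    frame_index: int = 0,
    min_area: int = DEFAULT_MIN_AREA,
) -> list[ColonyCluster]:
    """Group foreground pixels into 8-connected components.

    Components smaller than ``min_area`` pixels are discarded as noise.
    Clusters are returned in scan order of their first pixel (deterministic).
    """
    mask = np.zeros(frame_shape, dtype=bool)
    pixels = np.asarray(pixels, dtype=int)
    if pixels.size:
        if (
            pixels[:, 0].min() < 0
            or pixels[:, 1].min() < 0
            or pixels[:, 0].max() >= frame_shape[0]
            or pixels[:, 1].max() >= frame_shape[1]
        ):
            raise ValueError("pixel coordinates outside the frame")
        mask[pixels[:, 0], pixels[:, 1]] = True
    return cluster_mask(mask, frame_index=frame_index, min_area=min_area)


def cluster_mask(
    mask: np.ndarray, frame_index: int = 0, min_area: int = DEFAULT_MIN_AREA
) -> list[ColonyCluster]:
    """Connected-component labelling of a boolean mask (8-connectivity)."""
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    clusters = []
    for lab, box in enumerate(ndimage.find_objects(labels), start=1):
        rows, cols = np.nonzero(labels[box] == lab)
        if len(rows) < min_area:
            continue
        rows = rows + box[0].start
        cols = cols + box[1].start
        clusters.append(ColonyCluster(frame_index, np.column_stack([rows, cols])))
    return clusters


def segment_stack(
    stack: ImageStack,
    intensity_k: float = DEFAULT_INTENSITY_K,
    sobel_k: float = DEFAULT_SOBEL_K,
    min_area: int = DEFAULT_MIN_AREA,
    closing: bool = False,
) -> list[list[ColonyCluster]]:
    """Per-frame foreground detection and clustering for a whole stack."""
    per_frame = []
    for i, frame in enumerate(stack.frames):
        mask = detect_foreground(frame, intensity_k=intensity_k, sobel_k=sobel_k)
        if closing:
            mask = ndimage.binary_closing(mask, structure=_STRUCT8)
        per_frame.append(cluster_mask(mask, frame_index=i, min_area=min_area))
    return per_frame


def _match_frames(
    prev: list[ColonyCluster], curr: list[ColonyCluster], max_displacement: float
) -> list[tuple[int, int]]:
    """Mutual-nearest-centroid matching between two frames.

    A pair (i, j) matches iff j is i's nearest current centroid, i is j's
    nearest previous centroid, and their distance is <= ``max_displacement``.
    Ties are broken by smaller distance, then smaller absolute area change
    (deterministic).
    """
    if not prev or not curr:
        return []
    pc = np.array([c.centroid for c in prev])
    cc = np.array([c.centroid for c in curr])
    d = np.linalg.norm(pc[:, None, :] - cc[None, :, :], axis=2)
    pa = np.array([c.area for c in prev], dtype=float)
    ca = np.array([c.area for c in curr], dtype=float)
    darea = np.abs(pa[:, None] - ca[None, :])
    # lexicographic argmin over (distance, |area change|, index)
    order = np.lexsort((np.arange(d.shape[1])[None, :].repeat(d.shape[0], 0).ravel(),
                        darea.ravel(), d.ravel()))
    nearest_of_prev = np.full(len(prev), -1)
    nearest_of_curr = np.full(len(curr), -1)
    for flat in order:
        i, j = divmod(int(flat), d.shape[1])
        if nearest_of_prev[i] == -1:
            nearest_of_prev[i] = j
        if nearest_of_curr[j] == -1:
            nearest_of_curr[j] = i
    matches = []
    for i in range(len(prev)):
        j = nearest_of_prev[i]
        if j != -1 and nearest_of_curr[j] == i and d[i, j] <= max_displacement:
            matches.append((i, j))
    return matches


def track_colonies(
    per_frame_clusters: list[list[ColonyCluster]],
    timestamps: Sequence[float],
    max_displacement: float = DEFAULT_MAX_DISPLACEMENT,
) -> list[ColonyTrack]:
    """Link clusters across consecutive frames into colony tracks.

    Matching is mutual-nearest-centroid with a displacement cap; unmatched
    clusters start new tracks.  Gap frames are not bridged: a colony absent
    in one frame ends its track there.
    """
    if len(per_frame_clusters) != len(timestamps):
        raise ValueError("one timestamp per frame required")
    tracks: list[ColonyTrack] = []
    active: dict[int, ColonyTrack] = {}  # cluster idx in previous frame -> track
    prev: list[ColonyCluster] = []
    for f, clusters in enumerate(per_frame_clusters):
        t = timestamps[f]
        matches = dict(
            (j, i) for i, j in _match_frames(prev, clusters, max_displacement)
        )
        new_active: dict[int, ColonyTrack] = {}
        for j, cluster in enumerate(clusters):
            if j in matches and matches[j] in active:
                track = active[matches[j]]
            else:
                track = ColonyTrack(track_id=len(tracks))
                tracks.append(track)
            track.append(t, cluster)
            new_active[j] = track
        active = new_active
        prev = clusters
    return tracks


def filter_doubling(tracks: list[ColonyTrack]) -> list[ColonyTrack]:
    """Flag tracks whose area at least doubled over the observation.

    ``passed_doubling`` is True iff final area >= 2 x initial area
    (inclusive).  Non-passing tracks are kept but excluded from growth
    statistics downstream.  Tracks with fewer than 2 records cannot pass.
    """
    for tr in tracks:
        if tr.n_records < 2:
            tr.passed_doubling = False
        else:
            tr.passed_doubling = tr.areas[-1] >= 2 * tr.areas[0]
    return tracks


def truncate_on_touch(
    tracks: list[ColonyTrack],
    per_frame_clusters: list[list[ColonyCluster]],
    frame_shape: tuple[int, int],
    timestamps: Sequence[float] | None = None,
) -> list[ColonyTrack]:
    """Cut tracks at the first frame where two colonies touch.

    Touching at frame t means either (a) the frame-t clusters of two
    distinct tracks are 8-adjacent, or (b) one frame-t cluster overlaps the
    dilated previous footprints of two or more distinct tracks (a merger —
    under 8-connected labelling merged colonies appear as one cluster).
    All involved tracks keep only records strictly before t and are flagged.
    """
    # map (frame, cluster identity) -> track
    cluster_track: dict[int, dict[int, ColonyTrack]] = {}
    for tr in tracks:
        for cl in tr.clusters:
            cluster_track.setdefault(cl.frame_index, {})[id(cl)] = tr

    touched_at: dict[int, float] = {}  # track_id -> touch time

    def mark(tr: ColonyTrack, t: float) -> None:
        if tr.track_id not in touched_at or t < touched_at[tr.track_id]:
            touched_at[tr.track_id] = t

    def pixel_sets(clusters: list[ColonyCluster]) -> list[set[tuple[int, int]]]:
        return [set(map(tuple, c.pixels)) for c in clusters]

    def dilate(pixset: set[tuple[int, int]]) -> set[tuple[int, int]]:
        return {
            (r + dr, c + dc)
            for r, c in pixset
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
        }

    def boxes_near(a: ColonyCluster, b: ColonyCluster, pad: int = 2) -> bool:
        ar0, ac0 = a.pixels.min(axis=0)
        ar1, ac1 = a.pixels.max(axis=0)
        br0, bc0 = b.pixels.min(axis=0)
        br1, bc1 = b.pixels.max(axis=0)
        return ar0 <= br1 + pad and br0 <= ar1 + pad and ac0 <= bc1 + pad and bc0 <= ac1 + pad

    n_frames = len(per_frame_clusters)
    prev_foot: dict[int, set[tuple[int, int]]] = {}  # track_id -> dilated footprint
    prev_tracks: dict[int, ColonyTrack] = {}
    for f in range(n_frames):
        clusters = per_frame_clusters[f]
        t = timestamps[f] if timestamps is not None else float(f)
        psets = pixel_sets(clusters)
        # (a) adjacency between clusters of distinct tracks in the same frame
        for i in range(len(clusters)):
            ti = cluster_track.get(f, {}).get(id(clusters[i]))
            if ti is None:
                continue
            for j in range(i + 1, len(clusters)):
                tj = cluster_track.get(f, {}).get(id(clusters[j]))
                if tj is None or tj is ti:
                    continue
                if not boxes_near(clusters[i], clusters[j]):
                    continue
                if not dilate(psets[i]).isdisjoint(psets[j]):
                    mark(ti, t)
                    mark(tj, t)
        # (b) merger: one cluster overlapping >= 2 previous track footprints
        if prev_foot:
            for c, pset in zip(clusters, psets):
                owners = {
                    tid
                    for tid, foot in prev_foot.items()
                    if not pset.isdisjoint(foot)
                }
                if len(owners) >= 2:
                    for tid in owners:
                        mark(prev_tracks[tid], t)
                    own = cluster_track.get(f, {}).get(id(c))
                    if own is not None:
                        mark(own, t)
        prev_foot = {}
        prev_tracks = {}
        for c, pset in zip(clusters, psets):
            tr = cluster_track.get(f, {}).get(id(c))
            if tr is not None:
                prev_foot[tr.track_id] = dilate(pset)
                prev_tracks[tr.track_id] = tr
    for tr in tracks:
        if tr.track_id in touched_at:
            t = touched_at[tr.track_id]
            keep = [i for i, ti in enumerate(tr.times) if ti < t]
            tr.times = [tr.times[i] for i in keep]
            tr.areas = [tr.areas[i] for i in keep]
            tr.clusters = [tr.clusters[i] for i in keep]
            tr.fluorescence = [r for r in tr.fluorescence if r.time_minutes < t]
            tr.truncated_at_touch = True
            tr.touch_time = t
    return tracks


def measure_fluorescence(
    gfp_frame: np.ndarray, cluster: ColonyCluster, gfp_k: float = DEFAULT_GFP_K
) -> tuple[float, float | None, float]:
    """(sum, mean, max) GFP intensity inside one colony.

    Signal pixels are those above mean + ``gfp_k`` s.d. of the whole GFP
    frame intersected with the colony's pixels; sum and mean are over the
    signal pixels (mean is None when no pixel qualifies).  The maximum is
    taken over the full colony area regardless of the threshold — a single
    bright focus (e.g. a Rad52 repair centre) registers there.
    """
    gfp_frame = np.asarray(gfp_frame, dtype=float)
    vals = gfp_frame[cluster.pixels[:, 0], cluster.pixels[:, 1]]
    mu, sd = gfp_frame.mean(), gfp_frame.std()
    candidates = vals[vals > mu + gfp_k * sd]
    total = float(candidates.sum()) if len(candidates) else 0.0
    mean = float(candidates.mean()) if len(candidates) else None
    return total, mean, float(vals.max())


def attach_fluorescence(
    tracks: list[ColonyTrack], gfp_stack: ImageStack, gfp_k: float = DEFAULT_GFP_K
) -> list[ColonyTrack]:
    """Measure GFP in every track cluster from the matching GFP frame."""
    for tr in tracks:
        tr.fluorescence = []
        for t, cl in zip(tr.times, tr.clusters):
            frame = gfp_stack.frames[cl.frame_index]
            total, mean, mx = measure_fluorescence(frame, cl, gfp_k=gfp_k)
            tr.fluorescence.append(FluorescenceRecord(t, total, mean, mx))
    return tracks


def run_imaging_pipeline(
    brightfield: ImageStack,
    gfp: ImageStack | None = None,
    intensity_k: float = DEFAULT_INTENSITY_K,
    sobel_k: float = DEFAULT_SOBEL_K,
    gfp_k: float = DEFAULT_GFP_K,
    min_area: int = DEFAULT_MIN_AREA,
    max_displacement: float = DEFAULT_MAX_DISPLACEMENT,
    closing: bool = False,
) -> list[ColonyTrack]:
    """Segment, track, doubling-filter and touch-truncate a full stack."""
    if gfp is not None and gfp.frames.shape != brightfield.frames.shape:
        raise ValueError("GFP stack shape differs from brightfield stack")
    per_frame = segment_stack(
        brightfield,
        intensity_k=intensity_k,
        sobel_k=sobel_k,
        min_area=min_area,
        closing=closing,
    )
    tracks = track_colonies(
        per_frame, brightfield.timestamps, max_displacement=max_displacement
    )
    if gfp is not None:
        attach_fluorescence(tracks, gfp, gfp_k=gfp_k)
    truncate_on_touch(
        tracks,
        per_frame,
        frame_shape=brightfield.frames.shape[1:],
        timestamps=brightfield.timestamps,
    )
    filter_doubling(tracks)
    return tracks
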