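"""End-anchored cell tracking and lineage reconstruction from movies.

The algorithm mirrors the analysis used for real flow-cell movies: cells are
segmented in the **last** frame and tracked **backwards** to the first frame,
so no track can exist that is absent from the final image.  Going backwards,
a daughter's region eventually merges into its mother's (at the moment its
nucleus appeared); the merge defines the mother-daughter link.

Event calling uses the two marker channels only:

* *nuclear separation* — the first frame at which the daughter's mean
  nuclear-marker intensity exceeds the detection threshold (background mean
  plus ``nuclear_k`` standard deviations of background);
* *cell birth* (cytokinesis) — the largest fractional drop of the bud-neck
  marker intensity, measured at the mother-daughter interface, within
  ``window_min`` minutes (default 30) after nuclear separation; the drop must
  exceed ``budneck_drop`` (default 50% after 3-frame median smoothing).
  Events with no qualifying drop are kept but flagged.

Segmentation never reads the ground-truth label mask: frames are thresholded
(Otsu) on the bright-field proxy and touching cells are split by
nuclear-marker-seeded watershed on the distance transform.  Cell size is the
segmented area in pixels (the bright-field size proxy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.signal import medfilt
from skimage.draw import disk as _disk
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

from .population_sim import (
    Cell,
    DivisionRecord,
    LineageTree,
    REGIMES,
    preset,
)
from .synthetic_microscopy import Movie

__all__ = [
    "TrackingConfig",
    "Track",
    "DivisionEvent",
    "segment_frame",
    "segment_final_frame",
    "track_backwards",
    "call_events",
    "build_tree",
    "reconstruct",
]


@dataclass(frozen=True)
class TrackingConfig:
    """Thresholds of the reconstruction; all configurable."""

    budneck_drop: float = 0.5  # "significant" fractional neck-intensity drop
    window_min: float = 30.0  # birth must follow separation within this
    symmetric_window: bool = False  # allow birth slightly before separation
    nuclear_k: float = 5.0  # nuclear threshold: bg mean + k * bg sd
    seed_rel_threshold: float = 0.3  # seed floor, fraction of peak nuclear signal
    smooth_sigma: float = 1.0  # Gaussian presmoothing (pixels)
    min_region_px: int = 12  # discard smaller segments
    neck_probe_radius: float = 4.0  # sampling disc at the neck (pixels)


@dataclass
class Track:
    """One cell tracked from the final frame back to its first appearance."""

    cell_label: int
    first_frame: int
    last_frame: int
    parent_label: int | None = None  # track it merged into, going backwards
    frames: list[int] = field(default_factory=list)
    centroids: list[tuple[float, float]] = field(default_factory=list)  # (y, x)
    areas: list[int] = field(default_factory=list)
    nuclear_mean: list[float] = field(default_factory=list)
    budneck_mean: list[float] = field(default_factory=list)
    warning: str | None = None

    def at(self, frame: int) -> int:
        return self.frames.index(frame)


@dataclass(frozen=True)
class DivisionEvent:
    """A mother-daughter division resolved from the marker channels."""

    mother_label: int
    daughter_label: int
    nuclear_separation_time: float
    birth_time: float | None
    flag: str | None = None


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _nuclear_threshold(nuclear: np.ndarray, fg: np.ndarray, k: float) -> float:
    bg = nuclear[~fg]
    if bg.size == 0:
        return float(nuclear.mean())
    return float(bg.mean() + k * bg.std())


def segment_frame(movie: Movie, frame: int, config: TrackingConfig | None = None) -> np.ndarray:
    """Segment one frame into cell regions (its own label numbering).

    Otsu threshold on the (smoothed) bright-field proxy gives the cell-body
    mask; nuclear-marker peaks seed a watershed on the distance transform to
    split touching cells.  Regions without a nuclear seed (pre-separation
    buds) remain part of their mother's region.
    """
    config = config or TrackingConfig()
    bf = movie.brightfield[frame].astype(float)
    nuc = movie.nuclear[frame].astype(float)
    if config.smooth_sigma > 0:
        bf = gaussian(bf, config.smooth_sigma, preserve_range=True)
        nuc = gaussian(nuc, config.smooth_sigma, preserve_range=True)
    if bf.max() - bf.min() < 1e-9:
        return np.zeros(bf.shape, dtype=np.int32)
    thr = threshold_otsu(bf)
    fg = bf > thr
    if not fg.any():
        return np.zeros(bf.shape, dtype=np.int32)
    nthr = _nuclear_threshold(nuc, fg, config.nuclear_k)
    # the relative floor keeps smoothing tails of adjacent nuclei from
    # bridging into a single seed on low-noise images
    floor = config.seed_rel_threshold * float(nuc.max())
    seeds = cc_label(nuc > max(nthr, floor, 1e-6))
    if seeds.max() == 0:
        return np.zeros(bf.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(fg)
    seg = watershed(-dist, markers=seeds, mask=fg).astype(np.int32)
    # drop fragments
    counts = np.bincount(seg.ravel())
    small = np.flatnonzero(counts < config.min_region_px)
    if small.size:
        seg[np.isin(seg, small[small > 0])] = 0
    return seg


def segment_final_frame(movie: Movie, config: TrackingConfig | None = None) -> np.ndarray:
    """Labels of the last frame (the anchor of backwards tracking)."""
    return segment_frame(movie, movie.n_frames - 1, config)


# ---------------------------------------------------------------------------
# backwards tracking
# ---------------------------------------------------------------------------

def _measure(track: Track, frame: int, idx: np.ndarray, shape: tuple[int, int],
             nuclear: np.ndarray, budneck: np.ndarray) -> None:
    ys, xs = np.unravel_index(idx, shape)
    track.frames.append(frame)
    track.centroids.append((float(ys.mean()), float(xs.mean())))
    track.areas.append(int(idx.size))
    track.nuclear_mean.append(float(nuclear.ravel()[idx].mean()))
    track.budneck_mean.append(float(budneck.ravel()[idx].mean()))


def track_backwards(
    movie: Movie,
    final_labels: np.ndarray | None = None,
    config: TrackingConfig | None = None,
) -> dict[int, Track]:
    """Propagate every final-frame segment back to its first appearance.

    Assignment is by maximal overlap with the previous frame's segments; when
    several tracks claim the same earlier region the one with the larger
    intersection-over-union wins (ties: smaller centroid displacement, then
    lower label), and the losers are recorded as having merged into the
    winner — the daughter's first frame is the frame after the merge.
    """
    config = config or TrackingConfig()
    if final_labels is None:
        final_labels = segment_final_frame(movie, config)
    n = movie.n_frames
    shape = final_labels.shape
    tracks: dict[int, Track] = {}
    active: dict[int, np.ndarray] = {}  # label -> flat pixel indices at current frame

    last = n - 1
    for lab in np.unique(final_labels):
        if lab == 0:
            continue
        idx = np.flatnonzero(final_labels.ravel() == lab)
        t = Track(cell_label=int(lab), first_frame=last, last_frame=last)
        _measure(t, last, idx, shape, movie.nuclear[last], movie.budneck[last])
        tracks[int(lab)] = t
        active[int(lab)] = idx

    for k in range(n - 2, -1, -1):
        if not active:
            break
        seg = segment_frame(movie, k, config)
        seg_flat = seg.ravel()
        seg_counts = np.bincount(seg_flat)
        claims: dict[int, list[tuple[float, float, int, np.ndarray]]] = {}
        vanished: list[int] = []
        for lab, idx in active.items():
            over = np.bincount(seg_flat[idx])
            over[0] = 0
            if over.sum() == 0:
                vanished.append(lab)
                continue
            best = int(over.argmax())
            inter = float(over[best])
            union = float(idx.size + seg_counts[best] - inter)
            iou = inter / union
            cand_idx = np.flatnonzero(seg_flat == best)
            ys, xs = np.unravel_index(cand_idx, shape)
            cy, cx = ys.mean(), xs.mean()
            py, px = tracks[lab].centroids[-1]
            disp = math.hypot(cy - py, cx - px)
            claims.setdefault(best, []).append((iou, disp, lab, cand_idx))
        for lab in vanished:
            tracks[lab].first_frame = k + 1
            tracks[lab].warning = "track lost (no overlap in previous frame)"
            del active[lab]
        for seg_lab, claimants in claims.items():
            claimants.sort(key=lambda c: (-c[0], c[1], c[2]))
            iou, disp, winner, cand_idx = claimants[0]
            _measure(tracks[winner], k, cand_idx, shape, movie.nuclear[k], movie.budneck[k])
            active[winner] = cand_idx
            for _, _, loser, _ in claimants[1:]:
                tracks[loser].first_frame = k + 1
                tracks[loser].parent_label = winner
                del active[loser]
    for lab in list(active):
        tracks[lab].first_frame = 0

    # measurements were appended backwards; flip to chronological order
    for t in tracks.values():
        t.frames.reverse()
        t.centroids.reverse()
        t.areas.reverse()
        t.nuclear_mean.reverse()
        t.budneck_mean.reverse()
    return tracks


# ---------------------------------------------------------------------------
# event calling
# ---------------------------------------------------------------------------

def _neck_trace(
    movie: Movie,
    mother: Track,
    daughter: Track,
    frames: list[int],
    probe_radius: float,
) -> np.ndarray:
    """Mean bud-neck intensity in a probe disc at the daughter's boundary
    point facing the mother, per requested frame."""
    vals = []
    shape = movie.budneck.shape[1:]
    for f in frames:
        if f in daughter.frames:
            i = daughter.at(f)
            dy, dx = daughter.centroids[i]
            r_d = math.sqrt(daughter.areas[i] / math.pi)
        else:  # before separation: probe from the first known position
            dy, dx = daughter.centroids[0]
            r_d = math.sqrt(daughter.areas[0] / math.pi)
        if f in mother.frames:
            j = mother.at(f)
            my, mx = mother.centroids[j]
        else:
            my, mx = mother.centroids[0]
        dist = math.hypot(my - dy, mx - dx)
        if dist < 1e-9:
            vals.append(0.0)
            continue
        uy, ux = (my - dy) / dist, (mx - dx) / dist
        py, px = dy + uy * r_d, dx + ux * r_d
        rr, cc = _disk((py, px), probe_radius, shape=shape)
        vals.append(float(movie.budneck[f][rr, cc].mean()))
    return np.asarray(vals)


def call_events(
    tracks: dict[int, Track],
    movie: Movie,
    config: TrackingConfig | None = None,
) -> list[DivisionEvent]:
    """Resolve division events for every track that merged into a mother."""
    config = config or TrackingConfig()
    dt = movie.frame_interval
    events: list[DivisionEvent] = []
    # nuclear detection threshold from the final frame's background
    last = movie.n_frames - 1
    fg = movie.brightfield[last].astype(float) > (
        float(movie.brightfield[last].min()) + 1
    )
    nthr = _nuclear_threshold(movie.nuclear[last].astype(float), fg, config.nuclear_k)

    for lab, tr in sorted(tracks.items()):
        if tr.parent_label is None:
            continue
        mother = tracks[tr.parent_label]
        # nuclear separation: first frame with nuclear signal above threshold
        nsep_frame = None
        for f, v in zip(tr.frames, tr.nuclear_mean):
            if v > nthr:
                nsep_frame = f
                break
        if nsep_frame is None:
            events.append(
                DivisionEvent(mother.cell_label, lab, tr.first_frame * dt, None,
                              flag="no nuclear signal above threshold")
            )
            continue
        nsep_t = nsep_frame * dt
        w_frames = int(math.ceil(config.window_min / dt))
        lo = nsep_frame - (w_frames if config.symmetric_window else 0)
        hi = min(movie.n_frames - 1, nsep_frame + w_frames + 1)
        lo = max(0, lo - 1)  # one frame of context for the first difference
        frames = list(range(lo, hi + 1))
        trace = _neck_trace(movie, mother, tr, frames, config.neck_probe_radius)
        if len(trace) >= 3:
            trace = medfilt(trace, kernel_size=3)
        drops = np.zeros(len(trace))
        for i in range(1, len(trace)):
            prev = trace[i - 1]
            if prev > 1e-9:
                drops[i] = (prev - trace[i]) / prev
        # largest drop restricted to the association window around separation
        lo_ok = -config.window_min if config.symmetric_window else 0.0
        in_window = [
            i
            for i in range(1, len(trace))
            if lo_ok - 1e-9 <= frames[i] * dt - nsep_t <= config.window_min + 1e-9
        ]
        if not in_window or drops[in_window].max() < config.budneck_drop:
            events.append(
                DivisionEvent(mother.cell_label, lab, nsep_t, None,
                              flag="no significant bud-neck drop in window")
            )
            continue
        best = in_window[int(np.argmax(drops[in_window]))]
        events.append(DivisionEvent(mother.cell_label, lab, nsep_t, frames[best] * dt))
    return events


# ---------------------------------------------------------------------------
# tree assembly
# ---------------------------------------------------------------------------

def build_tree(
    tracks: dict[int, Track],
    events: list[DivisionEvent],
    movie: Movie,
) -> LineageTree:
    """Assemble a lineage tree (same schema as the simulator's output).

    Cells are tracks with a resolved birth (founders: tracks reaching frame
    0, born at time 0); a cell is a mother iff it appears as the mother in at
    least one resolved event.  Sizes are segmented areas in pixels.
    """
    for e in events:
        if e.mother_label not in tracks or e.daughter_label not in tracks:
            raise ValueError(
                f"event references unknown track: {e.mother_label}->{e.daughter_label}"
            )
    dt = movie.frame_interval
    ok_events = [e for e in events if e.birth_time is not None]
    birth_of = {e.daughter_label: e.birth_time for e in ok_events}
    parent_of = {e.daughter_label: e.mother_label for e in ok_events}

    cells: dict[int, Cell] = {}
    for lab, tr in sorted(tracks.items()):
        if tr.first_frame == 0 and tr.parent_label is None:
            birth = 0.0
            parent = None
        elif lab in birth_of:
            birth = float(birth_of[lab])
            parent = parent_of[lab]
        else:
            continue  # unresolved track: no cell
        area0 = tr.areas[0] if tr.areas else 0
        area1 = tr.areas[-1] if tr.areas else 0
        cells[lab] = Cell(
            id=lab,
            parent_id=parent,
            birth_time=birth,
            birth_size=float(area0),
            size_cap=float(max(tr.areas, default=0)),
            growth_rate=0.0,
            growth_start=None,
            generation=0,
            born_pre_shift=birth <= 0.0,
            size=float(area1),
            resource=float("nan"),
        )
    # drop daughters whose mother was itself unresolved
    cells = {
        lab: c for lab, c in cells.items()
        if c.parent_id is None or c.parent_id in cells
    }
    divisions: list[DivisionRecord] = []
    for e in ok_events:
        if e.mother_label not in cells or e.daughter_label not in cells:
            continue
        cells[e.mother_label].division_times.append(float(e.birth_time))
        divisions.append(
            DivisionRecord(
                mother_id=e.mother_label,
                daughter_id=e.daughter_label,
                time=float(e.birth_time),
                resource_before=float("nan"),
                f_used=float("nan"),
                mother_after=float("nan"),
                daughter_at_birth=float("nan"),
            )
        )
    for c in cells.values():
        c.division_times.sort()
    # generations by walking up the parent chain
    def gen(lab: int) -> int:
        g, cur = 0, cells[lab]
        while cur.parent_id is not None:
            g += 1
            cur = cells[cur.parent_id]
        return g

    for lab, c in cells.items():
        c.generation = gen(lab)
    divisions.sort(key=lambda d: (d.time, d.mother_id))
    regime_name = movie.provenance.get("regime")
    regime = REGIMES.get(regime_name, preset("rich"))
    horizon = (movie.n_frames - 1) * dt
    return LineageTree(
        cells=cells, divisions=divisions, regime=regime,
        seed=movie.seed, duration=horizon,
    )


def reconstruct(
    movie: Movie, config: TrackingConfig | None = None
) -> tuple[LineageTree, dict[int, Track], list[DivisionEvent]]:
    """Full pipeline: segment the last frame, track backwards, call events,
    and assemble the lineage tree."""
    config = config or TrackingConfig()
    final = segment_final_frame(movie, config)
    tracks = track_backwards(movie, final, config)
    events = call_events(tracks, movie, config)
    tree = build_tree(tracks, events, movie)
    return tree, tracks, events
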