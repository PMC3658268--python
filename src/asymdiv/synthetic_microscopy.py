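"""Render a lineage tree into a synthetic dual-marker time-lapse movie.

The renderer produces exactly the visual cues the tracking algorithm in
:mod:`asymdiv.lineage_reconstruction` relies on:

* a **bright-field proxy** channel: uniform foreground intensity inside every
  cell body (cell size is estimated from this channel's segmented area);
* a **nuclear marker** channel: a bright disc at each cell centre; the
  daughter's nucleus switches on at nuclear separation, ``anaphase_offset``
  minutes (default 12) before cytokinesis;
* a **bud-neck marker** channel: a bright spot at the mother-bud neck, on
  from bud emergence and dropping by ``budneck_contrast`` at birth;
* a ground-truth **label mask** (cell ids, stable across frames), used only
  by tests.

Geometry: cells are non-overlapping discs with area proportional to cell
size.  A bud appears attached to its mother at cycle start and grows along
the mother-daughter axis into the daughter's reserved position.  Daughters
are placed at the first free angular position clockwise from the mother's
previous bud site, spiralling outward if the first ring is full; founders sit
on a regular grid.  The layout is planar and static (cells never migrate),
mimicking growth in a monolayer flow cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk

from .population_sim import Cell, LineageTree, cell_size_at

__all__ = ["RenderParams", "Movie", "LayoutError", "render_movie"]


class LayoutError(RuntimeError):
    """Raised when a daughter cannot be placed without overlap."""


@dataclass(frozen=True)
class RenderParams:
    """Rendering configuration (pixel units unless noted)."""

    frame_interval: float = 6.0  # minutes
    noise_sd: float = 0.0  # Gaussian intensity noise per pixel
    budneck_contrast: float = 5.0  # neck intensity ratio before/after birth
    nuclear_onset_frame_jitter: int = 0  # +- frames applied to nuclear onset
    cell_packing: str = "rings"  # daughter placement rule
    seed: int = 0
    area_scale: float = 220.0  # pixels^2 per size unit
    anaphase_offset: float = 12.0  # nuclear separation precedes birth (min)
    pixel_size: float = 0.25  # micrometres per pixel (nominal)
    nuclear_intensity: float = 3000.0
    budneck_intensity: float = 2000.0
    cell_intensity: float = 600.0
    background: float = 100.0
    margin_px: float = 2.0

    def __post_init__(self) -> None:
        if self.budneck_contrast <= 1:
            raise ValueError("budneck_contrast must be > 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")


@dataclass
class Movie:
    """A rendered stack: per-frame label mask plus intensity channels.

    ``labels`` holds cell id + 1 (0 is background).  All channel arrays have
    shape ``(n_frames, height, width)``.
    """

    labels: np.ndarray
    nuclear: np.ndarray
    budneck: np.ndarray
    brightfield: np.ndarray
    frame_interval: float
    pixel_size: float
    seed: int
    provenance: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    def frame_time(self, k: int) -> float:
        return k * self.frame_interval


def _radius(area: float) -> float:
    return math.sqrt(max(area, 1e-9) / math.pi)


def _layout(tree: LineageTree, params: RenderParams) -> dict[int, tuple[float, float]]:
    """Assign a static centre to every cell; raise LayoutError on failure."""
    r_cap = _radius(params.area_scale * tree.regime.critical_size)
    margin = params.margin_px
    founders = sorted(tree.founders(), key=lambda c: c.id)
    # colony reach estimate: packed discs of n cells fill radius ~ r*sqrt(n)*1.6
    colony_sizes = []
    for f in founders:
        n = 1
        stack = [f.id]
        while stack:
            cid = stack.pop()
            kids = [c.id for c in tree.children(cid)]
            n += len(kids)
            stack.extend(kids)
        colony_sizes.append(n)
    n_max = max(colony_sizes, default=1)
    pitch = 2 * r_cap * (1.6 * math.sqrt(n_max) + 1.5)
    grid = max(1, math.ceil(math.sqrt(len(founders))))

    centers: dict[int, tuple[float, float]] = {}
    last_bud_angle: dict[int, float] = {}
    for i, f in enumerate(founders):
        gx, gy = i % grid, i // grid
        centers[f.id] = (gx * pitch, gy * pitch)
        # deterministic initial bud site per founder
        last_bud_angle[f.id] = (f.id * 2.399963) % (2 * math.pi)  # golden angle

    # place daughters in birth order
    order = sorted(
        (c for c in tree.cells.values() if c.parent_id is not None),
        key=lambda c: (c.birth_time, c.id),
    )
    placed = list(centers.items())
    for c in order:
        mx, my = centers[c.parent_id]
        base = last_bud_angle.get(c.parent_id, 0.0)
        d0 = 2 * r_cap + margin
        ok = False
        for scale in (1.0, 1.35, 1.7, 2.2, 2.8, 3.5):
            for step in range(24):
                ang = base - step * (2 * math.pi / 24)  # clockwise search
                cx = mx + d0 * scale * math.cos(ang)
                cy = my + d0 * scale * math.sin(ang)
                if all(
                    math.hypot(cx - px, cy - py) >= 2 * r_cap + margin - 1e-6
                    for cid, (px, py) in placed
                    if cid != c.parent_id
                ) and math.hypot(cx - mx, cy - my) >= 2 * r_cap + margin - 1e-6:
                    centers[c.id] = (cx, cy)
                    placed.append((c.id, (cx, cy)))
                    last_bud_angle[c.parent_id] = ang
                    last_bud_angle[c.id] = ang  # bud site memory for the daughter
                    ok = True
                    break
            if ok:
                break
        if not ok:
            frame = int(c.birth_time // params.frame_interval)
            raise LayoutError(
                f"cannot place cell {c.id} without overlap (birth frame {frame})"
            )
    return centers


def _cycle_start(tree: LineageTree, mother: Cell, t_div: float) -> float:
    """Start of the mother cycle that ends with the division at t_div."""
    earlier = [t for t in mother.division_times if t < t_div]
    return max(earlier) if earlier else mother.birth_time


def render_movie(tree: LineageTree, params: RenderParams) -> Movie:
    """Rasterize ``tree`` into a :class:`Movie`; deterministic given seed."""
    interval = params.frame_interval
    n_frames = int(math.floor(tree.duration / interval)) + 1
    rng_master = np.random.default_rng([params.seed & 0x7FFFFFFF, 1])

    if tree.n_cells() == 0:
        shape = (n_frames, 64, 64)
        labels = np.zeros(shape, dtype=np.uint16)
        zeros = np.zeros(shape, dtype=np.float64)
        bf = np.full(shape, params.background, dtype=np.float64)
        movies = []
        for arr in (zeros.copy(), zeros.copy(), bf):
            if params.noise_sd > 0:
                arr = arr + rng_master.normal(0, params.noise_sd, size=shape)
            movies.append(np.clip(arr, 0, 65535).astype(np.uint16))
        return Movie(
            labels=labels,
            nuclear=movies[0],
            budneck=movies[1],
            brightfield=movies[2],
            frame_interval=interval,
            pixel_size=params.pixel_size,
            seed=params.seed,
            provenance={"tree_seed": tree.seed, "regime": tree.regime.name},
        )

    centers = _layout(tree, params)
    r_cap = _radius(params.area_scale * tree.regime.critical_size)
    xs = [p[0] for p in centers.values()]
    ys = [p[1] for p in centers.values()]
    pad = r_cap + 8
    x0, y0 = min(xs) - pad, min(ys) - pad
    width = int(math.ceil(max(xs) - x0 + pad))
    height = int(math.ceil(max(ys) - y0 + pad))
    centers = {cid: (x - x0, y - y0) for cid, (x, y) in centers.items()}

    # per-division geometry: (mother, daughter, cycle_start, birth, unit vector)
    div_geo = []
    for d in tree.divisions:
        mother = tree.cells[d.mother_id]
        t0 = _cycle_start(tree, mother, d.time)
        mx, my = centers[d.mother_id]
        dx, dy = centers[d.daughter_id]
        norm = math.hypot(dx - mx, dy - my)
        ux, uy = (dx - mx) / norm, (dy - my) / norm
        jitter = 0
        if params.nuclear_onset_frame_jitter > 0:
            jitter = int(
                rng_master.integers(
                    -params.nuclear_onset_frame_jitter,
                    params.nuclear_onset_frame_jitter + 1,
                )
            )
        onset = d.time - params.anaphase_offset + jitter * interval
        div_geo.append((d, t0, (mx, my), (dx, dy), (ux, uy), onset))

    by_daughter = {d.daughter_id: g for g in div_geo for d in [g[0]]}

    shape = (n_frames, height, width)
    labels = np.zeros(shape, dtype=np.uint16)
    nuclear = np.zeros(shape, dtype=np.float64)
    budneck = np.zeros(shape, dtype=np.float64)
    brightfield = np.zeros(shape, dtype=np.float64)

    for k in range(n_frames):
        t = k * interval
        lab = labels[k]
        nuc = nuclear[k]
        bnk = budneck[k]

        # body and bud discs
        for c in tree.cells.values():
            if c.birth_time <= t:
                r = _radius(params.area_scale * cell_size_at(c, t))
                cx, cy = centers[c.id]
                rr, cc = disk((cy, cx), r, shape=lab.shape)
                lab[rr, cc] = c.id + 1
        # buds (drawn after bodies so the growing bud owns its pixels)
        for d, t0, (mx, my), (dxy), (ux, uy), onset in div_geo:
            if t0 <= t < d.time:
                daughter = tree.cells[d.daughter_id]
                frac = (t - t0) / max(d.time - t0, 1e-9)
                full_r = _radius(params.area_scale * daughter.birth_size)
                r_bud = max(2.5, full_r * math.sqrt(0.1 + 0.9 * frac))
                r_m = _radius(
                    params.area_scale * cell_size_at(tree.cells[d.mother_id], t)
                )
                bx = mx + ux * (r_m + r_bud)
                by = my + uy * (r_m + r_bud)
                rr, cc = disk((by, bx), r_bud, shape=lab.shape)
                lab[rr, cc] = d.daughter_id + 1

        # nuclear discs: own nucleus from birth; daughter nucleus from onset
        for c in tree.cells.values():
            if c.birth_time <= t:
                r = _radius(params.area_scale * cell_size_at(c, t))
                cx, cy = centers[c.id]
                rr, cc = disk((cy, cx), max(2.0, 0.35 * r), shape=lab.shape)
                nuc[rr, cc] = params.nuclear_intensity
        for d, t0, (mx, my), (dx, dy), (ux, uy), onset in div_geo:
            if onset <= t < d.time:
                daughter = tree.cells[d.daughter_id]
                frac = (t - t0) / max(d.time - t0, 1e-9)
                full_r = _radius(params.area_scale * daughter.birth_size)
                r_bud = max(2.5, full_r * math.sqrt(0.1 + 0.9 * frac))
                r_m = _radius(
                    params.area_scale * cell_size_at(tree.cells[d.mother_id], t)
                )
                bx = mx + ux * (r_m + r_bud)
                by = my + uy * (r_m + r_bud)
                rr, cc = disk((by, bx), max(2.0, 0.35 * r_bud), shape=lab.shape)
                nuc[rr, cc] = params.nuclear_intensity

        # bud-neck spots
        for d, t0, (mx, my), (dx, dy), (ux, uy), onset in div_geo:
            r_m = _radius(params.area_scale * cell_size_at(tree.cells[d.mother_id], t))
            nx, ny = mx + ux * r_m, my + uy * r_m
            if t0 <= t < d.time:
                rr, cc = disk((ny, nx), 3.0, shape=lab.shape)
                bnk[rr, cc] = np.maximum(bnk[rr, cc], params.budneck_intensity)
            elif d.time <= t < d.time + 4 * interval:
                rr, cc = disk((ny, nx), 3.0, shape=lab.shape)
                bnk[rr, cc] = np.maximum(
                    bnk[rr, cc], params.budneck_intensity / params.budneck_contrast
                )

        brightfield[k] = np.where(lab > 0, params.cell_intensity, params.background)

    if params.noise_sd > 0:
        for k in range(n_frames):
            rng = np.random.default_rng([params.seed & 0x7FFFFFFF, 2, k])
            for arr in (nuclear, budneck, brightfield):
                arr[k] += rng.normal(0.0, params.noise_sd, size=arr[k].shape)

    return Movie(
        labels=labels,
        nuclear=np.clip(nuclear, 0, 65535).astype(np.uint16),
        budneck=np.clip(budneck, 0, 65535).astype(np.uint16),
        brightfield=np.clip(brightfield, 0, 65535).astype(np.uint16),
        frame_interval=interval,
        pixel_size=params.pixel_size,
        seed=params.seed,
        provenance={"tree_seed": tree.seed, "regime": tree.regime.name},
    )
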