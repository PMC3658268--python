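"""Readers and writers for trees, count series, tracks, events, and movies.

Formats:

* lineage tree — JSON (full cell records plus division records and the
  regime) and Newick (one tree per founder; every division becomes a
  bifurcation between the continuing mother branch and the daughter branch,
  branch lengths in minutes);
* count series / tracks / events — CSV with fixed column order and floats at
  6 significant digits (byte-deterministic for identical inputs);
* movies — one multi-frame TIFF per channel (labels, nuclear, budneck,
  brightfield) plus a JSON sidecar holding the frame interval, pixel size
  and seed; frames are 0-based with frame 0 at t = 0 min, and the sidecar is
  the sole owner of the frames-to-minutes conversion.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import tifffile

from .lineage_reconstruction import DivisionEvent, Track
from .population_sim import (
    Cell,
    CountSeries,
    DivisionRecord,
    LineageTree,
    RegimeParams,
)
from .resource_model import ResourceParams
from .synthetic_microscopy import Movie

__all__ = [
    "write_tree",
    "read_tree",
    "tree_to_newick",
    "write_newick",
    "write_counts",
    "read_counts",
    "write_tracks",
    "write_events",
    "write_movie",
    "read_movie",
    "parse_config_text",
    "format_config_text",
]

_SCHEMA = "asymdiv-tree/1"


def _g6(x: float | None) -> float | None:
    """Floats at 6 significant digits for deterministic text output."""
    if x is None:
        return None
    if isinstance(x, float) and (math.isnan(x) or math.isinf(x)):
        return x
    return float(f"{x:.6g}")


# ---------------------------------------------------------------------------
# tree JSON
# ---------------------------------------------------------------------------

def tree_to_dict(tree: LineageTree) -> dict:
    regime = dataclasses.asdict(tree.regime)
    regime["resource_params"] = dataclasses.asdict(tree.regime.resource_params)
    # full float precision: the tree JSON must round-trip losslessly
    # (resource conservation is checked at 1e-9 on re-read)
    cells = [
        dataclasses.asdict(c) for c in sorted(tree.cells.values(), key=lambda c: c.id)
    ]
    divisions = [dataclasses.asdict(r) for r in tree.divisions]
    return {
        "schema": _SCHEMA,
        "seed": tree.seed,
        "duration": tree.duration,
        "regime": regime,
        "cells": cells,
        "divisions": divisions,
    }


def tree_from_dict(data: dict) -> LineageTree:
    if data.get("schema") != _SCHEMA:
        raise ValueError(f"unexpected tree schema: {data.get('schema')!r}")
    for key in ("regime", "cells", "divisions", "seed", "duration"):
        if key not in data:
            raise ValueError(f"tree JSON missing field {key!r}")
    rdata = dict(data["regime"])
    rdata["resource_params"] = ResourceParams(**rdata["resource_params"])
    regime = RegimeParams(**rdata)
    cells = {}
    for cd in data["cells"]:
        cell = Cell(**cd)
        cells[cell.id] = cell
    divisions = [DivisionRecord(**dd) for dd in data["divisions"]]
    tree = LineageTree(
        cells=cells,
        divisions=divisions,
        regime=regime,
        seed=int(data["seed"]),
        duration=float(data["duration"]),
    )
    return tree


def write_tree(tree: LineageTree, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(tree_to_dict(tree), indent=1, sort_keys=False) + "\n"
    )


def read_tree(path: str | Path) -> LineageTree:
    return tree_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def tree_to_newick(tree: LineageTree) -> str:
    """One Newick tree per founder, branch lengths in minutes.

    Each division at time t splits the current branch into the continuing
    mother lineage and the newborn daughter lineage; leaf labels are
    ``c<id>`` and terminal branches run to the simulation horizon.
    """
    tl = dendropy.TreeList()
    horizon = tree.duration
    children_of: dict[int, list[Cell]] = {}
    for c in tree.cells.values():
        if c.parent_id is not None:
            children_of.setdefault(c.parent_id, []).append(c)

    def build(node: dendropy.Node, cell: Cell, start: float, tns) -> None:
        kids = sorted(
            (k for k in children_of.get(cell.id, []) if k.birth_time > start),
            key=lambda k: k.birth_time,
        )
        if not kids:
            node.edge.length = _g6(max(0.0, horizon - start))
            node.taxon = tns.require_taxon(label=f"c{cell.id}")
            return
        nxt = kids[0]
        node.edge.length = _g6(nxt.birth_time - start)
        mother_node = node.new_child()
        daughter_node = node.new_child()
        build(mother_node, cell, nxt.birth_time, tns)
        build(daughter_node, nxt, nxt.birth_time, tns)

    for founder in sorted(tree.founders(), key=lambda c: c.id):
        t = dendropy.Tree()
        build(t.seed_node, founder, founder.birth_time, t.taxon_namespace)
        tl.append(t)
    return tl.as_string(schema="newick")


def write_newick(tree: LineageTree, path: str | Path) -> None:
    Path(path).write_text(tree_to_newick(tree))


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

_COUNT_COLUMNS = ["time_min", "total", "mothers", "daughters", "imploded"]


def write_counts(series: CountSeries, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_min": series.times,
            "total": series.total,
            "mothers": series.mothers,
            "daughters": series.daughters,
            "imploded": series.imploded,
        }
    )
    df.to_csv(path, index=False, float_format="%.6g")


def read_counts(path: str | Path) -> CountSeries:
    df = pd.read_csv(path)
    missing = [c for c in _COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"counts CSV {path}: missing columns {missing}")
    times = df["time_min"].to_numpy(float)
    if np.any(np.diff(times) <= 0):
        raise ValueError(f"counts CSV {path}: time_min must be strictly increasing")
    if (df[["total", "mothers", "daughters", "imploded"]] < 0).any().any():
        raise ValueError(f"counts CSV {path}: negative counts")
    return CountSeries(
        times=times,
        total=df["total"].to_numpy(int),
        mothers=df["mothers"].to_numpy(int),
        daughters=df["daughters"].to_numpy(int),
        imploded=df["imploded"].to_numpy(int),
    )


def write_tracks(tracks: dict[int, Track], frame_interval: float, path: str | Path) -> None:
    rows = []
    for lab, tr in sorted(tracks.items()):
        for i, f in enumerate(tr.frames):
            rows.append(
                {
                    "cell_label": lab,
                    "frame": f,
                    "time_min": f * frame_interval,
                    "centroid_x": tr.centroids[i][1],
                    "centroid_y": tr.centroids[i][0],
                    "area_px": tr.areas[i],
                    "nuclear_mean": tr.nuclear_mean[i],
                    "budneck_mean": tr.budneck_mean[i],
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "cell_label", "frame", "time_min", "centroid_x", "centroid_y",
            "area_px", "nuclear_mean", "budneck_mean",
        ],
    ).to_csv(path, index=False, float_format="%.6g")


def write_events(events: list[DivisionEvent], path: str | Path) -> None:
    rows = [
        {
            "mother_label": e.mother_label,
            "daughter_label": e.daughter_label,
            "nuclear_separation_min": e.nuclear_separation_time,
            "birth_min": e.birth_time if e.birth_time is not None else "",
            "flag": e.flag or "",
        }
        for e in events
    ]
    pd.DataFrame(
        rows,
        columns=["mother_label", "daughter_label", "nuclear_separation_min",
                 "birth_min", "flag"],
    ).to_csv(path, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# movies
# ---------------------------------------------------------------------------

_CHANNELS = ("labels", "nuclear", "budneck", "brightfield")


def write_movie(movie: Movie, prefix: str | Path) -> list[Path]:
    """Write one multi-frame TIFF per channel plus a JSON sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    for ch in _CHANNELS:
        p = prefix.parent / f"{prefix.name}_{ch}.tif"
        tifffile.imwrite(p, getattr(movie, ch))
        paths.append(p)
    sidecar = prefix.parent / f"{prefix.name}_meta.json"
    sidecar.write_text(
        json.dumps(
            {
                "frame_interval": _g6(movie.frame_interval),
                "pixel_size": _g6(movie.pixel_size),
                "seed": movie.seed,
                "n_frames": movie.n_frames,
                "provenance": movie.provenance,
            },
            indent=1,
        )
        + "\n"
    )
    paths.append(sidecar)
    return paths


def read_movie(prefix: str | Path) -> Movie:
    prefix = Path(prefix)
    sidecar = prefix.parent / f"{prefix.name}_meta.json"
    if not sidecar.exists():
        raise FileNotFoundError(f"movie sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    arrays = {}
    for ch in _CHANNELS:
        p = prefix.parent / f"{prefix.name}_{ch}.tif"
        if not p.exists():
            raise FileNotFoundError(f"movie channel missing: {p}")
        arrays[ch] = tifffile.imread(p)
    return Movie(
        labels=arrays["labels"],
        nuclear=arrays["nuclear"],
        budneck=arrays["budneck"],
        brightfield=arrays["brightfield"],
        frame_interval=float(meta["frame_interval"]),
        pixel_size=float(meta["pixel_size"]),
        seed=int(meta["seed"]),
        provenance=meta.get("provenance", {}),
    )


# ---------------------------------------------------------------------------
# flat key=value configuration text
# ---------------------------------------------------------------------------

def parse_config_text(text: str) -> dict[str, str]:
    """Parse ``key=value`` lines (# comments and blank lines ignored)."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line {lineno}: expected key=value, got {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def format_config_text(values: dict[str, object]) -> str:
    lines = []
    for key in sorted(values):
        v = values[key]
        if isinstance(v, float):
            v = f"{v:.6g}"
        lines.append(f"{key}={v}")
    return "\n".join(lines) + "\n"
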