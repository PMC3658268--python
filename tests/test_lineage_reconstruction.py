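"""End-anchored tracking: segmentation, backwards propagation, event calling."""

import numpy as np
import pytest

from conftest import roundtrip_errors, truth_map

from asymdiv.lineage_reconstruction import (
    DivisionEvent,
    TrackingConfig,
    build_tree,
    call_events,
    reconstruct,
    segment_final_frame,
    track_backwards,
)
from asymdiv.population_sim import preset, simulate_population
from asymdiv.synthetic_microscopy import Movie, RenderParams, render_movie


def test_final_frame_segmentation_counts_cells(low_metal_tree, low_metal_movie):
    seg = segment_final_frame(low_metal_movie)
    n_true = sum(
        1 for c in low_metal_tree.cells.values() if c.birth_time <= low_metal_tree.duration
    )
    assert len(set(np.unique(seg)) - {0}) == n_true


def test_background_only_movie_yields_no_segments():
    tree = simulate_population(preset("rich"), 0, 60, seed=1)
    movie = render_movie(tree, RenderParams(seed=1))
    assert segment_final_frame(movie).max() == 0


def test_touching_cells_with_distinct_nuclei_are_split():
    """After a division the mother and daughter discs are adjacent; the
    nuclear-seeded watershed must separate them into two segments."""
    tree = simulate_population(preset("low_metal"), 1, 150, seed=1)
    movie = render_movie(tree, RenderParams(seed=2))
    seg = segment_final_frame(movie)
    assert len(set(np.unique(seg)) - {0}) == 2


def test_single_cell_track_spans_all_frames():
    regime = preset("low_metal", resource_params=preset("low_metal").resource_params)
    tree = simulate_population(regime, 1, 90, seed=1)  # too short to divide
    assert len(tree.divisions) == 0
    movie = render_movie(tree, RenderParams(seed=3))
    tracks = track_backwards(movie)
    assert len(tracks) == 1
    (tr,) = tracks.values()
    assert tr.first_frame == 0 and tr.last_frame == movie.n_frames - 1
    assert tr.parent_label is None
    assert all(a > 0 for a in tr.areas)


def test_no_spurious_tracks(low_metal_movie, low_metal_reconstruction):
    """Backwards tracking is anchored in the final frame: every track must
    correspond to a distinct real cell there."""
    _, tracks, _ = low_metal_reconstruction
    mapping = truth_map(low_metal_movie, tracks)
    assert None not in mapping.values()
    assert len(set(mapping.values())) == len(tracks)


@pytest.mark.parametrize("fixture", ["low_metal", "rich"])
def test_roundtrip_exact_on_noiseless_render(fixture, request):
    """Noiseless simulate -> render -> reconstruct recovers an isomorphic
    tree: every cell, birth times within one frame, classification exact."""
    tree = request.getfixturevalue(f"{fixture}_tree")
    movie = request.getfixturevalue(f"{fixture}_movie")
    if fixture == "low_metal":
        rec, tracks, events = request.getfixturevalue("low_metal_reconstruction")
    else:
        rec, tracks, events = reconstruct(movie)
    n_true, n_rec, birth_err, parent_err, class_err = roundtrip_errors(
        tree, movie, rec, tracks
    )
    assert n_rec == n_true
    assert birth_err == [] and parent_err == [] and class_err == []
    assert not any(e.flag for e in events)


def test_classification_robust_to_noise(low_metal_tree):
    """At pixel noise up to 20% of the cell-body signal, mother/daughter
    classification accuracy stays >= 95% (birth times may shift)."""
    params = RenderParams(seed=5, noise_sd=120.0)  # 20% of the 600-count body signal
    movie = render_movie(low_metal_tree, params)
    rec, tracks, _ = reconstruct(movie)
    n_true, n_rec, _, _, class_err = roundtrip_errors(low_metal_tree, movie, rec, tracks)
    assert n_rec == n_true
    assert (n_rec - len(class_err)) / n_rec >= 0.95


def _two_cell_movie(budneck_drop_frame, onset_frame=10, n_frames=25):
    """Hand-built movie: a mother and a separate daughter disc whose nucleus
    switches on at onset_frame; a neck spot between them drops at
    budneck_drop_frame."""
    from skimage.draw import disk

    h = w = 64
    labels = np.zeros((n_frames, h, w), np.uint16)
    nuclear = np.zeros((n_frames, h, w), np.uint16)
    budneck = np.zeros((n_frames, h, w), np.uint16)
    bf = np.full((n_frames, h, w), 100, np.uint16)
    m, d = (32, 20), (32, 44)
    for k in range(n_frames):
        for cid, (cy, cx) in enumerate([m, d], start=1):
            if cid == 2 and k < onset_frame:
                continue
            rr, cc = disk((cy, cx), 9, shape=(h, w))
            labels[k][rr, cc] = cid
            bf[k][rr, cc] = 600
            if cid == 1 or k >= onset_frame:
                nr, nc = disk((cy, cx), 3, shape=(h, w))
                nuclear[k][nr, nc] = 3000
        rr, cc = disk((32, 33), 3, shape=(h, w))
        budneck[k][rr, cc] = 2000 if k < budneck_drop_frame else 400
    return Movie(
        labels=labels, nuclear=nuclear, budneck=budneck, brightfield=bf,
        frame_interval=6.0, pixel_size=0.25, seed=0,
    )


def test_event_called_within_association_window():
    """Nuclear onset at 60 min, neck drop at 72 min -> event (60, 72)."""
    movie = _two_cell_movie(budneck_drop_frame=12, onset_frame=10)
    tracks = track_backwards(movie)
    daughter = [t for t in tracks.values() if t.first_frame > 0]
    assert len(daughter) == 1
    daughter[0].parent_label = [
        lab for lab, t in tracks.items() if t.first_frame == 0
    ][0]
    events = call_events(tracks, movie)
    assert len(events) == 1
    e = events[0]
    assert e.flag is None
    assert e.nuclear_separation_time == pytest.approx(60.0)
    assert e.birth_time == pytest.approx(72.0)


def test_event_rejected_beyond_window():
    """Neck drop 36 min after separation exceeds the 30-min window: the
    event is kept but its birth stays unresolved."""
    movie = _two_cell_movie(budneck_drop_frame=16, onset_frame=10)
    tracks = track_backwards(movie)
    daughter = [t for t in tracks.values() if t.first_frame > 0][0]
    daughter.parent_label = [
        lab for lab, t in tracks.items() if t.first_frame == 0
    ][0]
    events = call_events(tracks, movie)
    assert len(events) == 1
    assert events[0].birth_time is None
    assert events[0].flag is not None


def test_build_tree_rejects_unknown_tracks(low_metal_movie, low_metal_reconstruction):
    _, tracks, events = low_metal_reconstruction
    bogus = events + [DivisionEvent(99999, 99998, 0.0, 6.0)]
    with pytest.raises(ValueError, match="unknown track"):
        build_tree(tracks, bogus, low_metal_movie)


def test_no_events_yields_forest_of_daughters():
    tree = simulate_population(preset("low_metal"), 2, 90, seed=1)
    movie = render_movie(tree, RenderParams(seed=4))
    tracks = track_backwards(movie)
    rec = build_tree(tracks, [], movie)
    assert rec.n_cells() == 2
    assert all(c.parent_id is None for c in rec.cells.values())
    assert all(len(c.division_times) == 0 for c in rec.cells.values())
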