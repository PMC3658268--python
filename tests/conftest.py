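import numpy as np
import pytest
from hypothesis import settings

from asymdiv.lineage_reconstruction import reconstruct, segment_final_frame
from asymdiv.population_sim import preset, simulate_population
from asymdiv.synthetic_microscopy import RenderParams, render_movie

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def low_metal_tree():
    """Small direct-shift low-zinc colony: 3 founders, 8 h."""
    return simulate_population(preset("low_metal"), 3, 480, seed=11)


@pytest.fixture(scope="session")
def rich_tree():
    """Rich-medium colony with re-dividing daughters: 1 founder, 7 h."""
    return simulate_population(preset("rich"), 1, 420, seed=2)


@pytest.fixture(scope="session")
def low_metal_movie(low_metal_tree):
    return render_movie(low_metal_tree, RenderParams(seed=5))


@pytest.fixture(scope="session")
def rich_movie(rich_tree):
    return render_movie(rich_tree, RenderParams(seed=6))


@pytest.fixture(scope="session")
def low_metal_reconstruction(low_metal_movie):
    return reconstruct(low_metal_movie)


def truth_map(movie, tracks):
    """Map reconstructed track labels to ground-truth cell ids by majority
    overlap in the final frame (test-only use of the label mask)."""
    last = movie.labels[-1].ravel()
    seg = segment_final_frame(movie).ravel()
    mapping = {}
    for lab in tracks:
        idx = np.flatnonzero(seg == lab)
        vals = last[idx]
        vals = vals[vals > 0]
        mapping[lab] = int(np.bincount(vals).argmax()) - 1 if vals.size else None
    return mapping


def roundtrip_errors(tree, movie, rec_tree, tracks):
    """Compare a reconstructed tree against generator truth.

    Returns (n_true, n_rec, birth_errors, parent_errors, class_errors) where
    the error lists hold cell ids failing birth-within-one-frame, parent
    identity, or mother/daughter classification."""
    mapping = truth_map(movie, tracks)
    dt = movie.frame_interval
    birth_err, parent_err, class_err = [], [], []
    for lab, c in rec_tree.cells.items():
        tc = tree.cells[mapping[lab]]
        if abs(c.birth_time - tc.birth_time) > dt + 1e-9:
            birth_err.append(lab)
        ok_parent = (c.parent_id is None) == (tc.parent_id is None) and (
            c.parent_id is None or mapping[c.parent_id] == tc.parent_id
        )
        if not ok_parent:
            parent_err.append(lab)
        if (len(c.division_times) >= 1) != (len(tc.division_times) >= 1):
            class_err.append(lab)
    return tree.n_cells(), rec_tree.n_cells(), birth_err, parent_err, class_err
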