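import numpy as np
import pytest

from megfeedback import EpochWindow, make_synthetic_mesh


@pytest.fixture(scope="session")
def small_mesh():
    """60-vertex mesh, 5 parcels, no medial wall: a compact spatial lattice."""
    return make_synthetic_mesh(60, 5, seed=7, medial_wall_fraction=0.0)


@pytest.fixture(scope="session")
def coarse_window():
    """Short epoch axis (50 Hz) to keep space-time lattices small."""
    return EpochWindow(sfreq=50.0)


def make_chain_mesh(n, labels=None, medial=None):
    """Deterministic path-graph mesh with hand-chosen parcels for exact tests."""
    from megfeedback import Mesh

    coords = np.column_stack([np.arange(n), np.zeros(n), np.zeros(n)]).astype(float)
    edges = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    return Mesh(
        coords=coords,
        edges=edges,
        vertex_area_cm2=np.full(n, 0.1527),
        parcel_label=list(labels) if labels is not None else ["p0"] * n,
        medial_wall=np.asarray(medial, bool) if medial is not None
        else np.zeros(n, bool),
    )
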