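"""Adjacency lattices for cluster formation.

Three geometries are used: the space x time lattice (mesh adjacency at each
time sample plus each vertex's temporal neighbours; no diagonal space-time
edges), the time chain (consecutive samples) and the 4-connected
time x frequency grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .mesh import Mesh

__all__ = ["Lattice", "chain_lattice", "grid_lattice", "space_time_lattice"]


@dataclass
class Lattice:
    """Element set with symmetric adjacency and an optional grid shape.

    ``shape`` records how a multidimensional stat map ravels into element
    indices (C order), e.g. ``(n_vertices, n_times)`` for the space-time
    lattice — element ``i`` is vertex ``i // n_times`` at sample ``i % n_times``.
    """

    adjacency: sp.csr_matrix
    kind: str
    shape: tuple | None = None

    def __post_init__(self):
        a = self.adjacency.tocsr().astype(bool)
        if a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if (a != a.T).nnz:
            raise ValueError("adjacency must be symmetric")
        if a.diagonal().any():
            raise ValueError("adjacency must have no self-loops")
        self.adjacency = a
        if self.shape is not None and int(np.prod(self.shape)) != a.shape[0]:
            raise ValueError("shape does not match number of elements")

    @property
    def n_elements(self) -> int:
        return self.adjacency.shape[0]


def _chain(n: int) -> sp.csr_matrix:
    if n == 1:
        return sp.csr_matrix((1, 1), dtype=bool)
    i = np.arange(n - 1)
    a = sp.coo_matrix((np.ones(n - 1, dtype=bool), (i, i + 1)), shape=(n, n))
    return ((a + a.T) > 0).tocsr()


def chain_lattice(n_times: int) -> Lattice:
    """Consecutive-sample adjacency for purely temporal clustering."""
    if n_times < 1:
        raise ValueError("n_times must be >= 1")
    return Lattice(_chain(n_times), kind="time", shape=(n_times,))


def grid_lattice(n_rows: int, n_cols: int, kind: str = "time_frequency") -> Lattice:
    """4-connected grid, e.g. frequency x time for spectro-temporal clustering."""
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    eye_r = sp.eye(n_rows, dtype=bool, format="csr")
    eye_c = sp.eye(n_cols, dtype=bool, format="csr")
    adj = sp.kron(_chain(n_rows), eye_c) + sp.kron(eye_r, _chain(n_cols))
    return Lattice(adj.tocsr(), kind=kind, shape=(n_rows, n_cols))


def space_time_lattice(mesh: Mesh, n_times: int) -> Lattice:
    """Vertices adjacent per mesh edge at equal times; self-adjacency across
    neighbouring samples; no diagonal space-time edges."""
    if n_times < 1:
        raise ValueError("n_times must be >= 1")
    a_sp = mesh.adjacency()
    eye_v = sp.eye(mesh.n_vertices, dtype=bool, format="csr")
    eye_t = sp.eye(n_times, dtype=bool, format="csr")
    adj = sp.kron(a_sp, eye_t) + sp.kron(eye_v, _chain(n_times))
    return Lattice(adj.tocsr(), kind="space_time",
                   shape=(mesh.n_vertices, n_times))
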