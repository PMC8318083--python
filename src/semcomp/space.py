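"""Source-space geometry: adjacency graphs, region masks, spatiotemporal connectivity.

The pipeline never sees cortical coordinates; a source space is just an
undirected graph over source indices plus named masks (the analysis mask,
fROIs, control regions).  Real dSPM source spaces plug in by supplying their
source adjacency (e.g. from a cortical triangulation) and atlas masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp


@dataclass
class SourceSpace:
    """Undirected source adjacency graph with named region masks.

    Parameters
    ----------
    n_sources : int
        Number of sources (graph nodes), indexed ``0..n_sources-1``.
    edges : ndarray of shape (n_edges, 2)
        Undirected edge list over source indices.  No self-loops.
    region_masks : dict of str -> ndarray of int
        Named source-index sets.  By convention ``"language"`` is the
        analysis mask; fROIs and control regions are additional entries.
    time_axis_default : (start_ms, step_ms)
        Default epoch timing for tensors defined on this space.
    """

    n_sources: int
    edges: np.ndarray
    region_masks: dict[str, np.ndarray] = field(default_factory=dict)
    time_axis_default: tuple[float, float] = (-100.0, 1.0)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if self.edges.size:
            if self.edges.min() < 0 or self.edges.max() >= self.n_sources:
                raise ValueError("edge list references invalid source indices")
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise ValueError("adjacency graph must not contain self-loops")
        masks = {}
        for name, idx in self.region_masks.items():
            idx = np.asarray(idx, dtype=np.int64)
            if idx.size and (idx.min() < 0 or idx.max() >= self.n_sources):
                raise ValueError(f"mask {name!r} exceeds source range")
            masks[name] = np.unique(idx)
        self.region_masks = masks

    def mask(self, name: str) -> np.ndarray:
        try:
            return self.region_masks[name]
        except KeyError:
            raise KeyError(
                f"unknown region mask {name!r}; available: {sorted(self.region_masks)}"
            ) from None

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric sparse adjacency matrix."""
        if not self.edges.size:
            return sp.csr_matrix((self.n_sources, self.n_sources))
        u, v = self.edges[:, 0], self.edges[:, 1]
        data = np.ones(2 * len(u))
        a = sp.coo_matrix(
            (data, (np.r_[u, v], np.r_[v, u])), shape=(self.n_sources, self.n_sources)
        )
        a.sum_duplicates()
        a.data[:] = 1.0
        return a.tocsr()

    def neighbor_lists(self) -> list[np.ndarray]:
        """Sorted neighbor array per source (used by BFS searchlights)."""
        adj = self.adjacency()
        return [adj.indices[adj.indptr[i] : adj.indptr[i + 1]] for i in range(self.n_sources)]

    def subgraph_edges(self, mask: np.ndarray) -> np.ndarray:
        """Edges of the mask-induced subgraph, re-indexed to 0..len(mask)-1."""
        mask = np.asarray(mask, dtype=np.int64)
        lookup = np.full(self.n_sources, -1, dtype=np.int64)
        lookup[mask] = np.arange(len(mask))
        u = lookup[self.edges[:, 0]]
        v = lookup[self.edges[:, 1]]
        keep = (u >= 0) & (v >= 0)
        return np.column_stack([u[keep], v[keep]])


def spatiotemporal_edges(spatial_edges: np.ndarray, n_space: int, n_time: int) -> np.ndarray:
    """Connectivity of a (space x time) grid flattened C-order (node = s*n_time + t).

    Spatial graph neighbors at the same sample, plus the same source at adjacent
    samples; no diagonal space-time edges.
    """
    spatial_edges = np.asarray(spatial_edges, dtype=np.int64).reshape(-1, 2)
    t = np.arange(n_time, dtype=np.int64)
    # spatial edges replicated at every time sample
    su = (spatial_edges[:, 0:1] * n_time + t[None, :]).ravel()
    sv = (spatial_edges[:, 1:2] * n_time + t[None, :]).ravel()
    # temporal edges: (s, t) -- (s, t+1)
    s = np.arange(n_space, dtype=np.int64)
    tu = (s[:, None] * n_time + t[None, :-1]).ravel()
    tv = tu + 1
    return np.column_stack([np.r_[su, tu], np.r_[sv, tv]])


def lattice_edges(shape: tuple[int, int]) -> np.ndarray:
    """4-neighborhood edges of a 2-D lattice flattened C-order."""
    nr, nc = shape
    idx = np.arange(nr * nc).reshape(nr, nc)
    horiz = np.column_stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()])
    vert = np.column_stack([idx[:-1, :].ravel(), idx[1:, :].ravel()])
    return np.vstack([horiz, vert]).astype(np.int64)


def compact_edges(edges: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Restrict an edge list to valid nodes and re-index to the compact range."""
    valid = np.asarray(valid, dtype=bool)
    lookup = np.full(valid.size, -1, dtype=np.int64)
    lookup[valid] = np.arange(valid.sum())
    u = lookup[edges[:, 0]]
    v = lookup[edges[:, 1]]
    keep = (u >= 0) & (v >= 0)
    return np.column_stack([u[keep], v[keep]])


def save_space(space: SourceSpace, path) -> None:
    """Write a SourceSpace as JSON (edge list + masks + timing)."""
    import json
    from pathlib import Path

    payload = {
        "kind": "source_space",
        "n_sources": space.n_sources,
        "edges": space.edges.tolist(),
        "region_masks": {k: v.tolist() for k, v in space.region_masks.items()},
        "time_axis_default": list(space.time_axis_default),
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True) + "\n")


def load_space(path) -> SourceSpace:
    import json
    from pathlib import Path

    payload = json.loads(Path(path).read_text())
    return SourceSpace(
        n_sources=payload["n_sources"],
        edges=np.asarray(payload["edges"], dtype=np.int64).reshape(-1, 2),
        region_masks={k: np.asarray(v, dtype=np.int64) for k, v in payload["region_masks"].items()},
        time_axis_default=tuple(payload["time_axis_default"]),
    )


def demo_space(n_rows: int = 8, n_cols: int = 10, step_ms: float = 1.0) -> SourceSpace:
    """Small rectangular-lattice source space with the masks the pipeline expects.

    Layout (row, col blocks):

    * ``language`` — all sources (the analysis mask);
    * ``roi_A`` / ``roi_B`` — two disjoint interior blocks standing in for the
      anterior and middle temporal fROIs;
    * ``control_A`` / ``control_B`` — two disjoint edge blocks standing in for
      the somatosensory/motor negative-control pair.
    """
    if n_rows < 6 or n_cols < 8:
        raise ValueError("demo space needs at least a 6 x 8 lattice")
    idx = np.arange(n_rows * n_cols).reshape(n_rows, n_cols)
    masks = {
        "language": idx.ravel(),
        "roi_A": idx[2 : n_rows - 2, 1:4].ravel(),
        "roi_B": idx[2 : n_rows - 2, n_cols - 4 : n_cols - 1].ravel(),
        "roi_C": idx[2 : n_rows - 2, 4 : n_cols - 4].ravel(),
        "control_A": idx[0:2, 0:3].ravel(),
        "control_B": idx[n_rows - 2 :, n_cols - 3 :].ravel(),
    }
    return SourceSpace(
        n_sources=n_rows * n_cols,
        edges=lattice_edges((n_rows, n_cols)),
        region_masks=masks,
        time_axis_default=(-100.0, step_ms),
    )
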