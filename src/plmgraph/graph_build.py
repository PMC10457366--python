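"""Residue-level 3D graph construction.

A protein is a graph G = (V, E) whose N nodes carry 3D coordinates
x (CA positions, in angstroms) and rotation/translation-invariant scalar
features h (residue classes, and later language-model embeddings).
Three connectivity schemes are supported:

``knn``
    each node gets directed edges to its K nearest neighbours by
    Euclidean distance (default K = 10); ties broken by smaller node
    index.  Edges are NOT symmetrised unless requested.
``rball``
    undirected edges between all pairs strictly closer than a cutoff
    (default 8.0 angstroms), stored in both directions.
``fc``
    all N(N-1) ordered pairs.

Edge sets depend on coordinates only through pairwise distances, so they
are invariant under rotations, translations and reflections.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ShapeError, ValidationError
from .structure_io import AA_ALPHABET

__all__ = ["ProteinGraph", "build_graph", "attach_features", "residue_onehot"]

SCHEMES = ("knn", "rball", "fc")


@dataclass
class ProteinGraph:
    """N nodes with coordinates, scalar features, and a directed edge list."""

    coords: np.ndarray                # (N, 3), angstroms
    node_feats: np.ndarray            # (N, psi_h); psi_h may be 0
    edges: np.ndarray                 # (M, 2) int, directed (i, j)
    scheme: str
    params: dict = field(default_factory=dict)
    node_chain: np.ndarray | None = None   # optional per-node chain label

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in self.edges}

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        n = self.n_nodes
        if self.edges.size:
            if self.edges.min() < 0 or self.edges.max() >= n:
                raise ValidationError("edge index out of range")
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise ValidationError("self-loop in edge list")
        if self.node_feats.shape[0] != n:
            raise ShapeError("node_feats rows must equal node count")


def build_graph(
    coords: np.ndarray,
    scheme: str = "knn",
    *,
    k: int = 10,
    cutoff: float = 8.0,
    symmetrize: bool = False,
    node_chain: np.ndarray | None = None,
) -> ProteinGraph:
    """Build connectivity over a coordinate set.

    For multi-chain complexes pass the concatenated coordinates; chain
    membership is bookkeeping (``node_chain``), never a connectivity
    constraint.

    Parameters
    ----------
    coords : (N, 3) array, N >= 2, finite.
    scheme : 'knn' | 'rball' | 'fc'.
    k : neighbours per node for 'knn' (capped at N-1).
    cutoff : strict distance threshold in angstroms for 'rball'.
    symmetrize : for 'knn' only, add the reverse of every edge.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ShapeError(f"coords must be (N, 3), got {coords.shape}")
    n = coords.shape[0]
    if n < 2:
        raise ValidationError("graph construction requires at least 2 nodes")
    if not np.all(np.isfinite(coords)):
        raise ValidationError("non-finite coordinate")
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")

    if scheme == "fc":
        i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        mask = i != j
        edges = np.stack([i[mask], j[mask]], axis=1)
        params = {}
    elif scheme == "rball":
        if cutoff <= 0:
            raise ValidationError("rball cutoff must be positive")
        d = cdist(coords, coords)
        np.fill_diagonal(d, np.inf)
        i, j = np.nonzero(d < cutoff)          # strict inequality
        edges = np.stack([i, j], axis=1)
        params = {"cutoff": float(cutoff)}
    else:  # knn
        if k < 1:
            raise ValidationError("knn requires K >= 1")
        kk = min(k, n - 1)
        d = cdist(coords, coords)
        np.fill_diagonal(d, np.inf)
        # stable per-node order: distance first, then node index
        order = np.lexsort((np.broadcast_to(np.arange(n), (n, n)), d), axis=1)
        nbrs = order[:, :kk]
        src = np.repeat(np.arange(n), kk)
        edges = np.stack([src, nbrs.ravel()], axis=1)
        if symmetrize:
            edges = np.unique(
                np.concatenate([edges, edges[:, ::-1]], axis=0), axis=0
            )
        params = {"k": int(k), "symmetrize": bool(symmetrize)}

    return ProteinGraph(
        coords=coords,
        node_feats=np.zeros((n, 0)),
        edges=edges,
        scheme=scheme,
        params=params,
        node_chain=None if node_chain is None else np.asarray(node_chain),
    )


def attach_features(g: ProteinGraph, feats: np.ndarray) -> ProteinGraph:
    """Return a copy of ``g`` with node features replaced.

    Width zero is allowed (features may come entirely from embeddings
    later); row count must match the node count.
    """
    feats = np.asarray(feats, dtype=float)
    if feats.ndim != 2 or feats.shape[0] != g.n_nodes:
        raise ShapeError(
            f"feature matrix has {feats.shape[0] if feats.ndim == 2 else '?'} rows,"
            f" graph has {g.n_nodes} nodes"
        )
    return replace(g, node_feats=feats)


def residue_onehot(seq: str) -> np.ndarray:
    """One-hot residue-class features over the 21-letter alphabet (20 + X)."""
    idx = np.array([AA_ALPHABET.index(c if c in AA_ALPHABET else "X")
                    for c in seq.upper()])
    out = np.zeros((len(seq), len(AA_ALPHABET)))
    out[np.arange(len(seq)), idx] = 1.0
    return out
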