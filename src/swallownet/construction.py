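"""Thresholded network construction from connectivity matrices.

Two constructions are used.  The degree-targeted threshold keeps, per
subject, exactly the ``K * n / 2`` strongest connections so every network has
the same mean degree K (the study value is K = 48, i.e. 2160 edges on 90
nodes — conservative enough to stay connected without drowning structure in
weak links).  The sparsity sweep binarizes at fixed cutoffs r on a 0..1 grid
(step 0.05) to study how measures vary with threshold.

Edges are ranked by absolute connectivity magnitude, keeping strong negative
partial correlations; ties are broken by lexicographic (i, j) node order so
the edge count contract is exact and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Network",
    "threshold_to_mean_degree",
    "binarize_at",
    "sweep_grid",
    "STUDY_MEAN_DEGREE",
    "DEGREE_PRESETS",
]

#: Mean degree used for the headline network construction.
STUDY_MEAN_DEGREE = 48
#: Illustrative mean-degree presets (sparser / study / denser).
DEGREE_PRESETS = (36, 48, 60)


@dataclass(frozen=True)
class Network:
    """An undirected graph on the atlas nodes.

    ``adjacency`` is symmetric with zero diagonal; binary entries are
    {0, 1}, weighted entries lie in [0, 1].
    """

    adjacency: np.ndarray
    mode: str  # "binary" | "weighted"
    labels: tuple[str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=float)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
        if np.abs(adj - adj.T).max() > 1e-12:
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(adj) != 0):
            raise ValueError("self-loops are not allowed")
        if self.mode not in ("binary", "weighted"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "binary" and not np.isin(adj, (0.0, 1.0)).all():
            raise ValueError("binary adjacency entries must be 0 or 1")
        if self.mode == "weighted" and (adj.min() < 0 or adj.max() > 1):
            raise ValueError("weighted adjacency entries must lie in [0, 1]")
        object.__setattr__(self, "adjacency", adj)
        if self.labels is not None and len(self.labels) != adj.shape[0]:
            raise ValueError("labels length must match adjacency size")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, k=1)))

    def edge_list(self) -> list[tuple[int, int, float]]:
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return [(int(a), int(b), float(self.adjacency[a, b])) for a, b in zip(i, j)]


def _ranked_upper_edges(C: np.ndarray) -> list[tuple[int, int]]:
    """Upper-triangle pairs sorted by descending |C|, ties by (i, j)."""
    n = C.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    mags = np.abs(C[iu, ju])
    order = np.lexsort((ju, iu, -mags))
    return [(int(iu[k]), int(ju[k])) for k in order]


def threshold_to_mean_degree(
    C: np.ndarray,
    K: int = STUDY_MEAN_DEGREE,
    labels: tuple[str, ...] | None = None,
) -> tuple[Network, Network]:
    """Retain the ``K*n/2`` largest-|C| edges; return (binary, weighted) nets.

    The binary network marks retained edges 1; the weighted network carries
    the retained absolute magnitudes normalized by the largest retained
    magnitude, so weights fall in (0, 1] and both networks share one degree
    sequence.  The resulting mean degree is exactly K.
    """
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    if not 1 <= K <= n - 1:
        raise ValueError(f"K must lie in [1, {n - 1}], got {K}")
    if (K * n) % 2 != 0:
        raise ValueError(f"K*n = {K * n} is odd; no graph has that degree sum")
    n_edges = K * n // 2
    ranked = _ranked_upper_edges(C)
    kept = ranked[:n_edges]
    if any(C[i, j] == 0 for i, j in kept):
        n_nonzero = int(np.count_nonzero(np.triu(C, k=1)))
        raise ValueError(
            f"only {n_nonzero} nonzero connections available for {n_edges} edges"
        )
    binary = np.zeros((n, n))
    weighted = np.zeros((n, n))
    top = abs(C[kept[0][0], kept[0][1]])
    for i, j in kept:
        binary[i, j] = binary[j, i] = 1.0
        w = abs(C[i, j]) / top
        weighted[i, j] = weighted[j, i] = w
    return (
        Network(binary, "binary", labels),
        Network(weighted, "weighted", labels),
    )


def binarize_at(
    C: np.ndarray,
    r: float,
    labels: tuple[str, ...] | None = None,
    absolute: bool = True,
) -> Network:
    """Binary network with an edge wherever the connection exceeds cutoff r.

    With ``absolute`` (the default) the comparison is ``|C_ij| > r``, which
    keeps strong negative partial correlations; ``absolute=False`` compares
    the signed value.  The inequality is strict, so ``r = 1`` yields an empty
    network for any proper correlation matrix.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"threshold r must lie in [0, 1], got {r}")
    C = np.asarray(C, dtype=float)
    vals = np.abs(C) if absolute else C
    adj = (vals > r).astype(float)
    np.fill_diagonal(adj, 0.0)
    adj = np.maximum(adj, adj.T) if not absolute else adj
    return Network(adj, "binary", labels)


def sweep_grid(start: float = 0.0, stop: float = 1.0, step: float = 0.05) -> np.ndarray:
    """The sparsity-threshold grid, default 0 to 1 in steps of 0.05 (21 values)."""
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(round((stop - start) / step))
    grid = start + step * np.arange(n + 1)
    return np.clip(grid, start, stop)
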