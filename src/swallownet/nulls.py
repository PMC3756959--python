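"""Degree-preserving null models and small-world statistics.

A network's clustering and path length are only interpretable against
random networks with the same size, edge count and degree sequence.  The
reference ensemble is built by Markov-chain double-edge swaps: repeatedly
pick two edges (a, b) and (c, d) and replace them with (a, d) and (c, b)
whenever the move creates neither a self-loop nor a duplicate edge.  Each
accepted swap leaves every node's degree unchanged, so after enough swaps
the chain samples graphs that are random apart from the fixed degree
sequence.

Small-worldness is then gamma / lambda, with gamma = Cp / Crand and
lambda = Lp / Lrand (harmonic path lengths); a small-world network shows
gamma > 1 (much more clustered than random) while lambda stays near 1
(paths nearly as short as random), hence sigma > 1.

Connectivity of the rewired graphs is not enforced; the harmonic path
length remains finite on disconnected members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .construction import Network
from .metrics import NetworkSummary, characteristic_path_length, clustering

__all__ = [
    "rewire_degree_preserving",
    "null_ensemble",
    "small_worldness",
    "NullEnsemble",
    "SmallWorldResult",
    "DegenerateGraphWarning",
]


class DegenerateGraphWarning(UserWarning):
    """Emitted when a graph admits no valid degree-preserving swap."""


def rewire_degree_preserving(
    net: Network,
    swaps_per_edge: int = 10,
    seed: int | np.random.Generator | None = None,
) -> Network:
    """Randomize a binary network by double-edge swaps, degrees preserved.

    Performs ``swaps_per_edge * E`` accepted swaps (E = edge count).  If no
    valid swap can be found within a bounded number of attempts — e.g. a
    triangle plus isolated nodes, where every move would duplicate an edge —
    the original network is returned with a :class:`DegenerateGraphWarning`.
    The same seed yields the same rewiring.
    """
    if net.mode != "binary":
        raise ValueError("degree-preserving rewiring is defined for binary networks")
    edges = [(i, j) for i, j, _ in net.edge_list()]
    E = len(edges)
    if E < 2:
        warnings.warn("fewer than 2 edges; nothing to swap", DegenerateGraphWarning)
        return net
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edge_set = {frozenset(e) for e in edges}
    target = swaps_per_edge * E
    accepted = 0
    attempts = 0
    max_attempts = max(100 * target, 1000)
    stall_limit = 200 * E  # consecutive failures before declaring rigidity
    stalled = 0
    # buffered draws: one RNG call per block instead of three per attempt
    block = max(1024, min(4 * target, 1 << 18))
    pair_buf = np.empty((0, 2), dtype=np.int64)
    coin_buf = np.empty(0)
    cursor = 0
    while accepted < target and attempts < max_attempts:
        if cursor >= pair_buf.shape[0]:
            pair_buf = rng.integers(0, E, size=(block, 2))
            coin_buf = rng.random(block)
            cursor = 0
        ia, ic = pair_buf[cursor]
        flip = coin_buf[cursor]
        cursor += 1
        attempts += 1
        if ia == ic:
            continue
        a, b = edges[ia]
        c, d = edges[ic]
        if flip < 0.5:
            c, d = d, c
        # proposed replacement: (a, d) and (c, b)
        if a == d or c == b:
            stalled += 1
            if stalled >= stall_limit and accepted == 0:
                break
            continue
        new1, new2 = frozenset((a, d)), frozenset((c, b))
        if new1 in edge_set or new2 in edge_set:
            stalled += 1
            if stalled >= stall_limit and accepted == 0:
                break
            continue
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((c, d)))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[ia] = (a, d)
        edges[ic] = (c, b)
        accepted += 1
        stalled = 0
    if accepted == 0:
        warnings.warn(
            "no valid degree-preserving swap found; returning the original network",
            DegenerateGraphWarning,
        )
        return net
    adj = np.zeros_like(net.adjacency)
    for e in edge_set:
        i, j = tuple(e)
        adj[i, j] = adj[j, i] = 1.0
    return Network(adj, "binary", net.labels)


@dataclass(frozen=True)
class NullEnsemble:
    """Summary of a degree-matched random-network ensemble."""

    n_random: int
    Crand_mean: float
    Lrand_mean: float
    Cp_values: np.ndarray
    Lp_values: np.ndarray
    swaps_per_edge: int
    seed: int | None


def null_ensemble(
    net: Network,
    n_random: int = 1000,
    seed: int | None = None,
    swaps_per_edge: int = 10,
) -> NullEnsemble:
    """Generate ``n_random`` independent rewirings and their Cp / Lp.

    Path lengths use the harmonic definition so disconnected members
    contribute finite values.  ``swaps_per_edge=0`` degenerates to an
    ensemble of copies of the source network (useful as a self-comparison
    control).
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    rng = np.random.default_rng(seed)
    Cp_vals = np.empty(n_random)
    Lp_vals = np.empty(n_random)
    for m in range(n_random):
        member = (
            net
            if swaps_per_edge == 0
            else rewire_degree_preserving(net, swaps_per_edge=swaps_per_edge, seed=rng)
        )
        _, Cp_vals[m] = clustering(member)
        _, Lp_vals[m] = characteristic_path_length(member, kind="harmonic")
    return NullEnsemble(
        n_random=n_random,
        Crand_mean=float(Cp_vals.mean()),
        Lrand_mean=float(Lp_vals.mean()),
        Cp_values=Cp_vals,
        Lp_values=Lp_vals,
        swaps_per_edge=swaps_per_edge,
        seed=seed,
    )


@dataclass(frozen=True)
class SmallWorldResult:
    """Normalized small-world statistics against a degree-matched ensemble."""

    gamma: float  # Cp / Crand
    lam: float  # Lp / Lrand
    sigma: float  # gamma / lambda
    is_small_world: bool


def small_worldness(summary: NetworkSummary, ensemble: NullEnsemble) -> SmallWorldResult:
    """gamma = Cp/Crand, lambda = Lp/Lrand, sigma = gamma/lambda.

    Classified small-world when gamma > 1 and sigma > 1.  Requires positive
    ensemble means; the summary's path length should use the same (harmonic)
    convention as the ensemble.
    """
    if ensemble.Crand_mean <= 0 or ensemble.Lrand_mean <= 0:
        raise EstimationErrorFromNulls(
            f"null means must be positive, got Crand={ensemble.Crand_mean}, "
            f"Lrand={ensemble.Lrand_mean}"
        )
    gamma = summary.Cp / ensemble.Crand_mean
    lam = summary.Lp / ensemble.Lrand_mean
    sigma = gamma / lam
    return SmallWorldResult(
        gamma=float(gamma),
        lam=float(lam),
        sigma=float(sigma),
        is_small_world=bool(gamma > 1.0 and sigma > 1.0),
    )


class EstimationErrorFromNulls(RuntimeError):
    """Raised when ensemble statistics are degenerate (zero means)."""
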