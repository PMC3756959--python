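"""Swallowing-ROI versus whole-brain comparison across the threshold sweep.

For every subject and every sparsity threshold r on the 0..1 grid the six
network measures (Eglob, Lp, K_mean, Cp, Eloc, beta) are computed twice:
once on the full connectivity matrix and once on the submatrix restricted to
the swallowing-related regions.  The ROI submatrix is extracted *before*
thresholding, so both scopes are binarized on the same correlation scale;
the per-threshold samples are per-subject scalars.  Scope differences are
tested per threshold and metric with the two-sided Mann-Whitney rank-sum
test, uncorrected across the sweep.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .construction import Network, binarize_at
from .metrics import network_summary

__all__ = [
    "subgraph",
    "metric_sweep",
    "ranksum",
    "compare_scopes",
    "SweepResult",
    "RankSumResult",
    "SWEEP_METRICS",
]

SWEEP_METRICS = ("Eglob", "Lp", "K_mean", "Cp", "Eloc", "beta")

#: Largest product n1*n2 for which the exact rank-sum null is enumerated.
EXACT_LIMIT = 400


def subgraph(net: Network, nodes: Sequence[int]) -> Network:
    """Induced subgraph on ``nodes``; labels follow the selection."""
    nodes = sorted(int(v) for v in nodes)
    if len(nodes) < 2:
        raise ValueError("subgraph needs at least 2 nodes")
    if nodes[0] < 0 or nodes[-1] >= net.n_nodes:
        raise ValueError(f"node indices out of range 0..{net.n_nodes - 1}")
    if len(set(nodes)) != len(nodes):
        raise ValueError("duplicate node indices")
    idx = np.asarray(nodes)
    labels = tuple(net.labels[v] for v in nodes) if net.labels is not None else None
    return Network(net.adjacency[np.ix_(idx, idx)], net.mode, labels)


@dataclass(frozen=True)
class SweepResult:
    """Per-subject metric values over a sparsity-threshold grid.

    ``table`` has one row per subject x threshold with columns ``subject``,
    ``threshold`` and the six measures; hierarchy fits that are degenerate
    at a given threshold appear as NaN.
    """

    thresholds: np.ndarray
    scope: str  # "whole_brain" | "swallowing_roi"
    table: pd.DataFrame


def metric_sweep(
    matrices: Sequence[np.ndarray],
    scope: str,
    grid: np.ndarray,
    roi_nodes: Sequence[int] | None = None,
) -> SweepResult:
    """Binarize every subject's matrix at every threshold and measure it.

    For the ROI scope the connectivity submatrix on ``roi_nodes`` is taken
    first and then thresholded on its own entries.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing and nonempty")
    if grid[0] < 0 or grid[-1] > 1:
        raise ValueError("grid values must lie in [0, 1]")
    if scope not in ("whole_brain", "swallowing_roi"):
        raise ValueError(f"unknown scope {scope!r}")
    if scope == "swallowing_roi":
        if roi_nodes is None:
            raise ValueError("swallowing_roi scope requires roi_nodes")
        roi = np.asarray(sorted(roi_nodes), dtype=int)
    rows = []
    for subject, C in enumerate(matrices):
        C = np.asarray(C, dtype=float)
        if scope == "swallowing_roi":
            C = C[np.ix_(roi, roi)]
        for r in grid:
            net = binarize_at(C, float(r))
            s = network_summary(net)
            rows.append(
                {
                    "subject": subject,
                    "threshold": float(r),
                    "Eglob": s.Eglob,
                    "Lp": s.Lp,
                    "K_mean": s.K_mean,
                    "Cp": s.Cp,
                    "Eloc": s.Eloc,
                    "beta": np.nan if s.beta is None else s.beta,
                }
            )
    return SweepResult(thresholds=grid, scope=scope, table=pd.DataFrame(rows))


@dataclass(frozen=True)
class RankSumResult:
    """Two-sided Mann-Whitney rank-sum comparison of two samples."""

    U: float  # rank-sum statistic of the first sample
    z: float  # tie-corrected normal score with continuity correction
    p_two_sided: float
    degenerate: bool = False


def ranksum(a: Sequence[float], b: Sequence[float]) -> RankSumResult:
    """Mann-Whitney U test with midrank ties.

    The p-value comes from exact enumeration of the rank-assignment null
    when ``n1 * n2 <= 400`` and the pooled sample is tie-free, and otherwise
    from the normal approximation with tie-corrected variance and continuity
    correction.  Two samples with all values identical are flagged
    degenerate with p = 1.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    U = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    if bool(np.all(pooled == pooled[0])):  # also catches all-infinite samples
        return RankSumResult(U=U, z=0.0, p_two_sided=1.0, degenerate=True)
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # pragma: no cover - implies all values tied, handled above
        return RankSumResult(U=U, z=0.0, p_two_sided=1.0, degenerate=True)
    cc = 0.5 if U != mu else 0.0
    z = (U - mu - np.sign(U - mu) * cc) / np.sqrt(var)
    has_ties = bool((tie_counts > 1).any())
    if n1 * n2 <= EXACT_LIMIT and not has_ties:
        p = float(
            sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        )
    else:
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return RankSumResult(U=U, z=float(z), p_two_sided=p)


def compare_scopes(
    sweep_roi: SweepResult,
    sweep_whole: SweepResult,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-threshold, per-metric rank-sum comparison between the two scopes.

    Returns one row per threshold x metric with U, z, the two-sided p and a
    significance flag at ``alpha`` (no multiple-comparison correction).
    Subjects whose value is undefined (NaN) at a given threshold are dropped
    from that comparison; infinite path lengths participate through their
    ranks.
    """
    if not np.array_equal(sweep_roi.thresholds, sweep_whole.thresholds):
        raise ValueError("threshold grids differ between scopes")
    subj_roi = set(sweep_roi.table["subject"])
    if subj_roi != set(sweep_whole.table["subject"]):
        raise ValueError("subject sets differ between scopes")
    rows = []
    for r in sweep_roi.thresholds:
        at_roi = sweep_roi.table[sweep_roi.table["threshold"] == r]
        at_whole = sweep_whole.table[sweep_whole.table["threshold"] == r]
        for metric in SWEEP_METRICS:
            va = at_roi[metric].dropna().to_numpy()
            vb = at_whole[metric].dropna().to_numpy()
            if va.size == 0 or vb.size == 0:
                rows.append(
                    {"threshold": float(r), "metric": metric, "U": np.nan,
                     "z": np.nan, "p": np.nan, "significant": False}
                )
                continue
            res = ranksum(va, vb)
            rows.append(
                {
                    "threshold": float(r),
                    "metric": metric,
                    "U": res.U,
                    "z": res.z,
                    "p": res.p_two_sided,
                    "significant": bool(res.p_two_sided < alpha),
                }
            )
    return pd.DataFrame(rows)
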