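"""Preprocessing and quality control for regional BOLD time series.

The package operates on already-parcellated regional series (regions x time).
Image-space steps (realignment, coregistration, normalization, smoothing) are
assumed done upstream; what remains in scope here is dummy-volume discarding,
the head-motion summary statistic, the motion exclusion rule, and averaging
voxel series into regional means.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "RegionalTimeSeriesSet",
    "discard_initial_volumes",
    "motion_magnitude",
    "frame_displacements",
    "qc_exclude",
    "extract_mean_series",
]

#: Repetition time of the emulated acquisition, seconds.
DEFAULT_TR_SECONDS = 2.2


@dataclass(frozen=True)
class RegionalTimeSeriesSet:
    """One subject's regional BOLD series.

    ``series`` is an ``(n_regions, n_timepoints)`` float array; for
    study-shaped inputs that is 90 x 350 as acquired and 90 x 340 after the
    first 10 volumes are discarded for magnetic equilibration.
    """

    subject_id: str
    series: np.ndarray
    tr_seconds: float = DEFAULT_TR_SECONDS

    def __post_init__(self) -> None:
        arr = np.asarray(self.series, dtype=float)
        if arr.ndim != 2:
            raise ValueError("series must be a 2-D (regions x time) array")
        if not np.isfinite(arr).all():
            raise ValueError(f"subject {self.subject_id}: series contains non-finite values")
        object.__setattr__(self, "series", arr)

    @property
    def n_regions(self) -> int:
        return self.series.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[1]


def discard_initial_volumes(
    ts: RegionalTimeSeriesSet, n_discard: int = 10
) -> RegionalTimeSeriesSet:
    """Drop the first ``n_discard`` volumes (magnetic-equilibration dummies).

    With the study defaults this turns a 350-volume acquisition into the 340
    time points entering connectivity estimation.
    """
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= ts.n_timepoints:
        raise ValueError(
            f"cannot discard {n_discard} of {ts.n_timepoints} volumes"
        )
    if n_discard == 0:
        return ts
    return replace(ts, series=ts.series[:, n_discard:])


def _displacement_norms(channels: np.ndarray) -> np.ndarray:
    """Frame-to-frame Euclidean displacement of an (M, 3) coordinate trace."""
    channels = np.asarray(channels, dtype=float)
    if channels.ndim != 2 or channels.shape[1] != 3:
        raise ValueError("motion channels must be an (M, 3) array")
    if channels.shape[0] < 2:
        raise ValueError("motion summary needs at least 2 volumes")
    return np.linalg.norm(np.diff(channels, axis=0), axis=1)


def frame_displacements(trace) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame displacement magnitudes (translation mm, rotation deg)."""
    return (
        _displacement_norms(trace.translations),
        _displacement_norms(trace.rotations),
    )


def motion_magnitude(trace) -> tuple[float, float]:
    """Mean frame-to-frame head displacement, translations and rotations.

    For a trace of M volumes this is ``(1/(M-1)) * sum_i sqrt(dx_i^2 + dy_i^2
    + dz_i^2)`` over the M-1 successive differences, computed separately for
    the translation channels (mm) and the rotation channels (degrees).
    """
    trans, rot = frame_displacements(trace)
    return float(trans.mean()), float(rot.mean())


def qc_exclude(trace, limit_mm: float = 4.0) -> bool:
    """Excess-motion exclusion: any frame displacement strictly above the limit.

    Applied frame-wise to both the translation (mm) and rotation (degree)
    displacement magnitudes; a displacement exactly at the limit does not
    exclude.
    """
    trans, rot = frame_displacements(trace)
    return bool(trans.max() > limit_mm or rot.max() > limit_mm)


def extract_mean_series(
    voxel_matrix: np.ndarray,
    membership: np.ndarray,
    subject_id: str = "subject",
    tr_seconds: float = DEFAULT_TR_SECONDS,
) -> RegionalTimeSeriesSet:
    """Average voxel series into regional means.

    Parameters
    ----------
    voxel_matrix
        ``(n_voxels, n_timepoints)`` array of voxel series.
    membership
        Length ``n_voxels`` integer array assigning each voxel to a region
        ``0..n_regions-1``; every region must own at least one voxel.
    """
    voxel_matrix = np.asarray(voxel_matrix, dtype=float)
    membership = np.asarray(membership, dtype=int)
    if voxel_matrix.ndim != 2:
        raise ValueError("voxel_matrix must be 2-D (voxels x time)")
    if membership.shape != (voxel_matrix.shape[0],):
        raise ValueError("membership must assign exactly one region per voxel")
    n_regions = int(membership.max()) + 1
    counts = np.bincount(membership, minlength=n_regions)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise ValueError(f"regions without any member voxel: {empty.tolist()}")
    sums = np.zeros((n_regions, voxel_matrix.shape[1]))
    np.add.at(sums, membership, voxel_matrix)
    return RegionalTimeSeriesSet(
        subject_id=subject_id,
        series=sums / counts[:, None],
        tr_seconds=tr_seconds,
    )
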