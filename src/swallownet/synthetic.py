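"""Synthetic multi-subject regional fMRI cohorts.

The study cohort (22 subjects, 350 volumes, 90 cerebral regions) was never
deposited, so the package ships a generator that reproduces the statistical
structure the downstream analysis assumes: regional signals with

* *local* correlation blocks — groups of anatomically consecutive regions
  within one hemisphere sharing correlation ``local_rho``, emulating the
  short-range intra-hemispheric connectivity that dominates functional maps;
* *homologous* inter-hemispheric correlation — each left/right pair of the
  same structure correlated at ``homolog_rho``, emulating the strong
  bilaterally symmetric long-range connections;
* AR(1) temporal autocorrelation ``ar1_phi``, the simplest stationary model
  with fMRI-like smoothness.

Each subject is an independent draw from the same stationary Gaussian
process, so the analytic partial-correlation matrix implied by the planted
covariance (:func:`planted_partial_correlation`) is an exact recovery target
for the estimator.  Motion traces are smooth Gaussian random walks; the
amplitude is parameterized so fixtures can include subjects violating the
4.0 mm exclusion rule.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .atlas import load_region_table, region_labels
from .preprocess import DEFAULT_TR_SECONDS, RegionalTimeSeriesSet

__all__ = [
    "CohortSpec",
    "MotionTrace",
    "region_covariance",
    "generate_cohort",
    "planted_partial_correlation",
    "write_cohort",
]


class ParameterError(ValueError):
    """Raised when a cohort specification cannot yield a valid covariance."""


@dataclass(frozen=True)
class MotionTrace:
    """Six rigid-body motion parameters per volume.

    ``translations`` is ``(M, 3)`` in mm, ``rotations`` ``(M, 3)`` in degrees.
    """

    translations: np.ndarray
    rotations: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.translations, dtype=float)
        r = np.asarray(self.rotations, dtype=float)
        if t.shape != r.shape or t.ndim != 2 or t.shape[1] != 3:
            raise ValueError("translations and rotations must both be (M, 3)")
        object.__setattr__(self, "translations", t)
        object.__setattr__(self, "rotations", r)

    @property
    def n_volumes(self) -> int:
        return self.translations.shape[0]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults reproduce the study's dimensions (22 subjects x 350 volumes x
    90 regions).  Correlation strengths are package choices: ``local_rho``
    0.35 for blocks of 5 consecutive same-hemisphere regions, ``homolog_rho``
    0.6 for left/right homologues — strong enough that homologous pairs
    dominate the group connectivity map, as in real swallowing-task data.
    """

    n_subjects: int = 22
    n_volumes: int = 350
    n_regions: int = 90
    local_block_size: int = 5
    local_rho: float = 0.35
    homolog_rho: float = 0.6
    ar1_phi: float = 0.3
    noise_sd: float = 1.0
    motion_step_sd_mm: float = 0.04
    motion_step_sd_deg: float = 0.03
    n_high_motion: int = 0
    tr_seconds: float = DEFAULT_TR_SECONDS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_volumes < 2 or self.n_regions < 1:
            raise ParameterError("cohort dimensions must be positive")
        for name in ("local_rho", "homolog_rho"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ParameterError(f"{name} must lie in [0, 1), got {v}")
        if not 0.0 <= self.ar1_phi < 1.0:
            raise ParameterError("ar1_phi must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be positive")
        if self.local_block_size < 1:
            raise ParameterError("local_block_size must be >= 1")
        if not 0 <= self.n_high_motion <= self.n_subjects:
            raise ParameterError("n_high_motion must be in [0, n_subjects]")


def _local_blocks(spec: CohortSpec) -> list[list[int]]:
    """Intra-hemispheric blocks of consecutive structures.

    Regions follow the atlas interleaving (even index = left, odd = right);
    structure ``s`` occupies indices ``2s`` and ``2s+1``.  Each hemisphere's
    structures are chunked into runs of ``local_block_size``.
    """
    blocks: list[list[int]] = []
    for parity in (0, 1):
        hemi = [i for i in range(spec.n_regions) if i % 2 == parity]
        for start in range(0, len(hemi), spec.local_block_size):
            block = hemi[start : start + spec.local_block_size]
            if len(block) >= 2:
                blocks.append(block)
    return blocks


def region_covariance(spec: CohortSpec) -> np.ndarray:
    """Planted region-level correlation matrix.

    Assembled as: identity, then local blocks at ``local_rho``, then
    homologous pairs overwritten symmetrically at ``homolog_rho``, then
    diagonal loading (with renormalization to unit diagonal) until positive
    definite.
    """
    n = spec.n_regions
    sigma = np.eye(n)
    for block in _local_blocks(spec):
        idx = np.ix_(block, block)
        sigma[idx] = spec.local_rho
        sigma[block, block] = 1.0
    for s in range(n // 2):
        sigma[2 * s, 2 * s + 1] = spec.homolog_rho
        sigma[2 * s + 1, 2 * s] = spec.homolog_rho
    for _ in range(64):
        min_eig = float(np.linalg.eigvalsh(sigma)[0])
        if min_eig > 1e-8:
            return sigma
        load = abs(min_eig) + 1e-6
        sigma = (sigma + load * np.eye(n)) / (1.0 + load)
    raise ParameterError(
        "planted covariance is not positive definite after diagonal loading; "
        f"reduce local_rho={spec.local_rho} or homolog_rho={spec.homolog_rho}"
    )


def planted_partial_correlation(spec: CohortSpec) -> np.ndarray:
    """Analytic partial-correlation matrix implied by the planted covariance.

    Computed from the precision matrix P = Sigma^{-1} as
    ``-P_ij / sqrt(P_ii P_jj)`` with zero diagonal; this is the exact target
    the sample estimator converges to as the series lengthens.
    """
    sigma = region_covariance(spec)
    try:
        precision = np.linalg.inv(sigma)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - PD guaranteed above
        raise ParameterError("planted covariance is singular") from exc
    d = np.sqrt(np.diag(precision))
    pcor = -precision / np.outer(d, d)
    np.fill_diagonal(pcor, 0.0)
    return (pcor + pcor.T) / 2.0


def _simulate_subject(
    spec: CohortSpec, chol: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One stationary AR(1) draw, shape (n_regions, n_volumes)."""
    innovations = rng.standard_normal((spec.n_volumes, spec.n_regions)) @ chol.T
    phi = spec.ar1_phi
    x = np.empty_like(innovations)
    x[0] = innovations[0]
    scale = np.sqrt(1.0 - phi * phi)
    for t in range(1, spec.n_volumes):
        x[t] = phi * x[t - 1] + scale * innovations[t]
    return spec.noise_sd * x.T


def _simulate_motion(
    spec: CohortSpec, rng: np.random.Generator, high_motion: bool
) -> MotionTrace:
    steps_t = rng.normal(0.0, spec.motion_step_sd_mm, size=(spec.n_volumes, 3))
    steps_r = rng.normal(0.0, spec.motion_step_sd_deg, size=(spec.n_volumes, 3))
    steps_t[0] = steps_r[0] = 0.0
    if high_motion:
        # one abrupt translation jump well past the 4.0 mm exclusion limit
        jump_at = int(rng.integers(1, spec.n_volumes))
        steps_t[jump_at, 0] += 6.0
    return MotionTrace(
        translations=np.cumsum(steps_t, axis=0),
        rotations=np.cumsum(steps_r, axis=0),
    )


def generate_cohort(
    spec: CohortSpec,
) -> list[tuple[RegionalTimeSeriesSet, MotionTrace]]:
    """Draw a full cohort; the same spec (including seed) is bit-reproducible.

    The first ``n_high_motion`` subjects receive a motion trace exceeding the
    4.0 mm rule, so QC exclusion is exercised deterministically.
    """
    chol = np.linalg.cholesky(region_covariance(spec))
    root = np.random.SeedSequence(spec.seed)
    cohort: list[tuple[RegionalTimeSeriesSet, MotionTrace]] = []
    for subject, child in enumerate(root.spawn(spec.n_subjects)):
        rng = np.random.default_rng(child)
        series = _simulate_subject(spec, chol, rng)
        motion = _simulate_motion(spec, rng, high_motion=subject < spec.n_high_motion)
        ts = RegionalTimeSeriesSet(
            subject_id=f"sub-{subject + 1:02d}",
            series=series,
            tr_seconds=spec.tr_seconds,
        )
        cohort.append((ts, motion))
    return cohort


def _series_labels(spec: CohortSpec) -> list[str]:
    if spec.n_regions == 90:
        return region_labels(load_region_table())
    return [f"R{i:03d}" for i in range(spec.n_regions)]


def write_cohort(spec: CohortSpec, out_dir: str | Path) -> Path:
    """Write per-subject series/motion TSVs plus a manifest JSON.

    Series files have one row per volume and one column per region
    (abbreviation headers, ``PHG.L`` style); motion files carry the six
    rigid-body columns.  Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = _series_labels(spec)
    files = []
    for ts, motion in generate_cohort(spec):
        series_path = out / f"{ts.subject_id}_series.tsv"
        motion_path = out / f"{ts.subject_id}_motion.tsv"
        header = "\t".join(labels)
        np.savetxt(
            series_path, ts.series.T, delimiter="\t", header=header,
            comments="", fmt="%.15g",
        )
        motion_header = "\t".join(["tx_mm", "ty_mm", "tz_mm", "rx_deg", "ry_deg", "rz_deg"])
        np.savetxt(
            motion_path,
            np.hstack([motion.translations, motion.rotations]),
            delimiter="\t", header=motion_header, comments="", fmt="%.15g",
        )
        files.append(
            {"subject_id": ts.subject_id, "series": series_path.name, "motion": motion_path.name}
        )
    manifest = {
        "spec": dataclasses.asdict(spec),
        "subjects": files,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path
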