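"""The cortical asymmetry index (CAI).

For one subject-visit the 34 left- and 34 right-hemisphere regional mean
thickness values are each turned into a density estimate on a shared,
evenly spaced thickness grid.  The index is

    CAI = sqrt( JS(p, q) ),   JS(p, q) = 1/2 KL(p || m) + 1/2 KL(q || m),
    m = (p + q) / 2,          KL(p || q) = sum_i p_i ln(p_i / q_i),

where ``p`` and ``q`` are the grid-evaluated hemispheric density vectors.
Deliberately, the vectors are *not* renormalised to unit sum over grid
points before the divergence is taken (``DensitySettings.normalise`` is
False by default): the index therefore scales with grid resolution, so the
grid construction is fixed and versioned with the settings.  Raw thickness
values are used with no subject-level normalisation — the index is computed
within-subject, across hemispheres, which already removes inter-subject
offsets.  CAI is unitless, non-negative, and larger for more asymmetric
brains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .io import ThicknessRecord

__all__ = [
    "DensitySettings",
    "DensityEstimate",
    "CaiResult",
    "estimate_density",
    "shared_grid",
    "kld",
    "js_divergence",
    "compute_cai",
    "compute_cohort_cai",
    "silverman_bandwidth",
]


@dataclass(frozen=True)
class DensitySettings:
    """Controls how a 34-value thickness sample becomes a density vector.

    Parameters
    ----------
    estimator : {"kde_gaussian", "histogram"}
        Gaussian kernel density (default) or a bin-count histogram density.
    grid_points : int
        Number of evenly spaced grid points (>= 8).
    bandwidth_rule : {"silverman", "fixed"}
        Bandwidth selection for the Gaussian KDE.
    fixed_bandwidth : float or None
        Bandwidth in mm, used when ``bandwidth_rule="fixed"`` and as the
        fallback when a zero-variance sample defeats the Silverman rule.
    grid_padding_fraction : float
        Fraction of the pooled range added on each side of the shared grid.
    floor : float
        Densities are floored at this small positive constant before any
        logarithm is taken.
    normalise : bool
        If True, rescale density vectors to unit sum over grid points.
        Default False: the divergence is taken on the raw grid-evaluated
        densities.
    """

    estimator: str = "kde_gaussian"
    grid_points: int = 128
    bandwidth_rule: str = "silverman"
    fixed_bandwidth: float | None = None
    grid_padding_fraction: float = 0.10
    floor: float = 1e-12
    normalise: bool = False

    def __post_init__(self) -> None:
        if self.estimator not in ("kde_gaussian", "histogram"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.bandwidth_rule not in ("silverman", "fixed"):
            raise ValueError(f"unknown bandwidth rule {self.bandwidth_rule!r}")
        if self.grid_points < 8:
            raise ValueError("grid_points must be >= 8")
        if self.floor <= 0:
            raise ValueError("floor must be > 0")
        if not 0 <= self.grid_padding_fraction <= 1:
            raise ValueError("grid_padding_fraction must lie in [0, 1]")
        if self.bandwidth_rule == "fixed" and not self.fixed_bandwidth:
            raise ValueError("fixed bandwidth rule requires fixed_bandwidth > 0")


@dataclass(frozen=True)
class DensityEstimate:
    """A hemispheric thickness density evaluated on a common grid."""

    grid: np.ndarray
    values: np.ndarray
    settings: DensitySettings


@dataclass(frozen=True)
class CaiResult:
    """Per subject-visit scalar asymmetry index with its provenance."""

    subject_id: str
    visit: int
    cai: float
    settings: DensitySettings


def silverman_bandwidth(sample: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 min(sd, IQR/1.34) n^(-1/5)."""
    sample = np.sort(np.asarray(sample, dtype=float))
    n = sample.size
    sd = sample.std(ddof=1)
    q75, q25 = np.percentile(sample, [75, 25])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * n ** (-0.2)


def shared_grid(
    lh_sample: np.ndarray, rh_sample: np.ndarray, settings: DensitySettings
) -> np.ndarray:
    """Evenly spaced grid spanning the padded pooled range of both samples.

    The pad is ``grid_padding_fraction`` times the pooled range; for a
    degenerate (zero-range) pool the pooled mean is used instead so the
    grid still has positive extent.
    """
    pooled = np.concatenate([np.asarray(lh_sample, float), np.asarray(rh_sample, float)])
    lo, hi = pooled.min(), pooled.max()
    span = hi - lo
    pad = settings.grid_padding_fraction * (span if span > 0 else pooled.mean())
    if span == 0 and pad == 0:
        raise ValueError("cannot build a grid for a zero-range, zero-mean sample")
    return np.linspace(lo - pad, hi + pad, settings.grid_points)


def estimate_density(
    sample: np.ndarray, grid: np.ndarray, settings: DensitySettings
) -> DensityEstimate:
    """Evaluate the sample's density on ``grid`` under ``settings``.

    Gaussian KDE uses the configured bandwidth rule; a zero-variance sample
    falls back to ``fixed_bandwidth`` (hard error if that is unset).  The
    histogram estimator treats grid points as bin centres and reports
    counts / (n * bin width).  Values are floored at ``settings.floor``;
    only if ``settings.normalise`` are they rescaled to unit sum.
    """
    # sorting makes the estimate depend only on the multiset of values,
    # bit-for-bit, regardless of region order
    sample = np.sort(np.asarray(sample, dtype=float))
    grid = np.asarray(grid, dtype=float)
    if np.any(sample <= 0):
        raise ValueError("thickness samples must be strictly positive")
    if settings.estimator == "kde_gaussian":
        if settings.bandwidth_rule == "fixed":
            h = float(settings.fixed_bandwidth)
        else:
            h = silverman_bandwidth(sample)
            if h <= 0:
                if settings.fixed_bandwidth:
                    h = float(settings.fixed_bandwidth)
                else:
                    raise ValueError(
                        "zero-variance sample defeats the Silverman rule and no "
                        "fixed_bandwidth fallback is set"
                    )
        z = (grid[:, None] - sample[None, :]) / h
        values = np.exp(-0.5 * z * z).sum(axis=1) / (
            sample.size * h * np.sqrt(2.0 * np.pi)
        )
    else:  # histogram
        step = grid[1] - grid[0]
        edges = np.concatenate([[grid[0] - step / 2], grid + step / 2])
        counts, _ = np.histogram(sample, bins=edges)
        values = counts / (sample.size * step)
    values = np.maximum(values, settings.floor)
    if settings.normalise:
        values = values / values.sum()
        values = np.maximum(values, settings.floor)
    return DensityEstimate(grid=grid, values=values, settings=settings)


def _validate_pair(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise ValueError("non-finite density value")
    if np.any(p <= 0) or np.any(q <= 0):
        raise ValueError("density values must be positive (floored) before divergence")
    return p, q


def kld(p: np.ndarray, q: np.ndarray) -> float:
    """Kullback-Leibler divergence sum_i p_i ln(p_i/q_i), natural log.

    No renormalisation is applied to either vector.
    """
    p, q = _validate_pair(p, q)
    return float(np.sum(p * np.log(p / q)))


def js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence with the equal mixture m = (p+q)/2.

    Implemented symmetrically, so swapping the arguments produces the
    bitwise-identical result.
    """
    p, q = _validate_pair(p, q)
    m = 0.5 * (p + q)
    return 0.5 * kld(p, m) + 0.5 * kld(q, m)


def compute_cai(record: ThicknessRecord, settings: DensitySettings | None = None) -> CaiResult:
    """Square-root Jensen-Shannon divergence between the two hemispheric densities."""
    if settings is None:
        settings = DensitySettings()
    grid = shared_grid(record.lh_thickness, record.rh_thickness, settings)
    p = estimate_density(record.lh_thickness, grid, settings).values
    q = estimate_density(record.rh_thickness, grid, settings).values
    div = js_divergence(p, q)
    # tiny negative round-off from the floor is clipped, never propagated
    div = max(div, 0.0)
    return CaiResult(
        subject_id=record.subject_id,
        visit=record.visit,
        cai=float(np.sqrt(div)),
        settings=settings,
    )


def compute_cohort_cai(
    records: Iterable[ThicknessRecord], settings: DensitySettings | None = None
) -> pd.DataFrame:
    """Map :func:`compute_cai` over records -> DataFrame(subject_id, visit, cai)."""
    if settings is None:
        settings = DensitySettings()
    rows = []
    for record in records:
        try:
            result = compute_cai(record, settings)
        except Exception as exc:
            raise RuntimeError(
                f"CAI failed for subject {record.subject_id!r} visit {record.visit}: {exc}"
            ) from exc
        rows.append((result.subject_id, result.visit, result.cai))
    return pd.DataFrame(rows, columns=["subject_id", "visit", "cai"])
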