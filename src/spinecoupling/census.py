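"""Unbiased-brick counting and spine-density estimation.

Each synapse-bearing spine is reduced to one reference point (its PSD
centroid). A counting brick is an axis-aligned box with inclusion faces at
the origin-side minimum of each axis and exclusion faces at the opposite
maximum: a point is counted iff ``origin <= p < origin + dims`` on every
axis. With this half-open rule, abutting bricks tile space so that every
point is counted exactly once, which is what makes the estimator unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class BrickSpec:
    """Axis-aligned counting brick; all lengths in μm.

    ``origin`` is the inclusion corner; the three faces through it are
    inclusion faces, the three opposite faces are exclusion faces.
    """

    origin: tuple[float, float, float]
    dims: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.origin) != 3 or len(self.dims) != 3:
            raise ValueError("origin and dims must be 3-vectors")
        if any(not d > 0 for d in self.dims):
            raise ValueError(f"brick dims must all be > 0, got {self.dims}")

    @property
    def volume(self) -> float:
        """Brick volume in μm³."""
        w, h, d = self.dims
        return w * h * d


def brick_count(points: np.ndarray, brick: BrickSpec) -> int:
    """Number of reference points inside the brick (half-open membership).

    Points exactly on an inclusion face (minimum coordinate) are counted;
    points on an exclusion face (maximum coordinate) are not.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return 0
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"points must be (n, 3), got shape {pts.shape}")
    if not np.isfinite(pts).all():
        raise ValueError("points must be finite")
    lo = np.asarray(brick.origin, dtype=float)
    hi = lo + np.asarray(brick.dims, dtype=float)
    inside = np.all((pts >= lo) & (pts < hi), axis=1)
    return int(inside.sum())


def spine_density(counts: "list[int] | np.ndarray", brick_volume: float) -> float:
    """Mean spine density (μm⁻³) over bricks of one sample.

    The per-sample mean of ``count / brick_volume`` is the statistical unit
    for between-group density comparisons (n = samples, not bricks).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("spine_density requires >= 1 brick count")
    if not brick_volume > 0:
        raise ValueError(f"brick_volume must be > 0, got {brick_volume}")
    return float(np.mean(counts / brick_volume))
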