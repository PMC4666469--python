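"""Overall-geometry descriptors of a structure.

The molecular shape is summarized by the eigenvalues λ1 ≥ λ2 ≥ λ3 of the
3×3 covariance (second-moment) matrix of node positions about the center of
mass, and by two dimensionless ratios of their square roots:

* linearity  σ1 = √(λ1/λ2) — large for straightened molecules;
* line symmetry σ2 = √(λ3/λ2) — large (small) when the molecule forms a
  three(two)-dimensional curve with a wide (flat) envelope.

A ``root=False`` flag computes the bare eigenvalue ratios instead, for
sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ShapeDescriptor:
    lambda1: float
    lambda2: float
    lambda3: float
    sigma1: float
    sigma2: float


def covariance_eigenvalues(positions) -> tuple[float, float, float]:
    """Eigenvalues (descending) of the position covariance matrix.

    Population averages over all points; positions are centered on their
    mean (equal-mass center of mass) first.
    """
    pts = np.asarray(positions, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("positions must be an (n, 3) array")
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / pts.shape[0]
    lam = np.linalg.eigvalsh(cov)[::-1]
    lam = np.clip(lam, 0.0, None)
    return float(lam[0]), float(lam[1]), float(lam[2])


def shape_descriptors(
    lambda1: float, lambda2: float, lambda3: float, root: bool = True
) -> ShapeDescriptor:
    """Linearity σ1 and line-symmetry σ2 from sorted covariance eigenvalues."""
    if not lambda1 >= lambda2 >= lambda3 >= 0:
        raise ValueError("eigenvalues must satisfy λ1 ≥ λ2 ≥ λ3 ≥ 0")
    if lambda2 == 0:
        raise ValueError("λ2 = 0: degenerate (collinear) point cloud")
    if root:
        s1 = float(np.sqrt(lambda1 / lambda2))
        s2 = float(np.sqrt(lambda3 / lambda2))
    else:
        s1 = lambda1 / lambda2
        s2 = lambda3 / lambda2
    return ShapeDescriptor(lambda1, lambda2, lambda3, s1, s2)


def shape_of(positions, root: bool = True) -> ShapeDescriptor:
    """Convenience: covariance eigenvalues + σ ratios in one call."""
    return shape_descriptors(*covariance_eigenvalues(positions), root=root)
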