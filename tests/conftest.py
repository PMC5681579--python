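"""Shared fixtures and independent numerical oracles.

The quadrature oracle evaluates the forward-model surface integral by a
refined midpoint Riemann sum, with the cell containing the electrode
singularity handled by numerical polar integration (corner-split); it
shares no code path with the closed-form antiderivative used by the
implementation.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.integrate import quad

from olfactomap import CurrentSourceDensity, FuniculusGeometry, compartmentize


@pytest.fixture
def geom() -> FuniculusGeometry:
    return FuniculusGeometry(length_mm=0.6, width_mm=0.3, thickness_mm=0.25)


@pytest.fixture
def fitted(geom) -> CurrentSourceDensity:
    return CurrentSourceDensity(geom).fit()


def _corner_singular_integral(a: float, b: float) -> float:
    """∬ over [0,a]×[0,b] of 1/sqrt(x²+y²), singularity at the origin,
    by polar coordinates: ∫ R(θ) dθ with R the distance to the boundary."""
    if a <= 0 or b <= 0:
        return 0.0
    split = math.atan2(b, a)
    i1, _ = quad(lambda t: a / math.cos(t), 0.0, split)
    i2, _ = quad(lambda t: b / math.sin(t), split, math.pi / 2.0)
    return i1 + i2


def riemann_rect_integral(
    x_lo: float, x_hi: float, q: float, xj: float, n: int = 600
) -> float:
    """Oracle for ∬ over [x_lo,x_hi]×[−q,q] of dx dy / sqrt((x−xj)² + y²).

    If the electrode (xj, 0) lies inside or on the rectangle, split into
    four corner-singular sub-rectangles integrated in polar coordinates;
    otherwise use an n×n midpoint Riemann sum.
    """
    if x_lo - 1e-12 <= xj <= x_hi + 1e-12:
        total = 0.0
        for width in (xj - x_lo, x_hi - xj):
            for height in (q, q):  # symmetric halves y∈[−q,0] and [0,q]
                total += _corner_singular_integral(width, height)
        return total
    xs = x_lo + (np.arange(n) + 0.5) * (x_hi - x_lo) / n
    ys = -q + (np.arange(n) + 0.5) * (2 * q) / n
    dx = (x_hi - x_lo) / n
    dy = 2 * q / n
    r = np.sqrt((xs[:, None] - xj) ** 2 + ys[None, :] ** 2)
    return float((1.0 / r).sum() * dx * dy)


def oracle_forward_matrix(geom: FuniculusGeometry, n: int = 600) -> np.ndarray:
    """Electrode-major forward matrix computed entirely by the oracle."""
    comps = compartmentize(geom)
    pos = geom.positions_mm
    m = np.empty((len(pos), len(comps)))
    for j, xj in enumerate(pos):
        for i in range(len(comps)):
            m[j, i] = riemann_rect_integral(
                comps.x_lo_mm[i], comps.x_hi_mm[i], comps.q_mm, xj, n=n
            ) / (4.0 * np.pi * geom.sigma)
    return m


def random_geometry(rng: np.random.Generator) -> FuniculusGeometry:
    """Random but physically plausible funiculus dimensions."""
    width = rng.uniform(0.1, 1.0)
    return FuniculusGeometry(
        length_mm=rng.uniform(0.3, 3.0),
        width_mm=width,
        thickness_mm=width * rng.uniform(0.5, 1.0),
        sigma=rng.uniform(1.0, 50.0),
    )
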