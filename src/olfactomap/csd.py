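"""Current source density estimation on the unfolded funiculus surface.

A point current source I_c in a medium of conductivity σ generates the
potential φ = I_c / (4πσr) at distance r.  Integrating over a rectangular
source of uniform density C_i spanning [x_lo, x_hi] × [−q, q] gives the
potential it contributes at electrode (x_j, 0):

    ψ_ij = C_i / (4πσ) ∬ dx dy / sqrt((x − x_j)² + y²)

The double integral has the closed-form corner antiderivative
H(u, v) = u·asinh(v/|u|) + v·asinh(u/|v|), finite even when the electrode
lies inside or on the boundary of the rectangle (the 1/r singularity is
integrable).  Stacking the N compartments and N electrodes yields a square
forward matrix; the CSD is obtained by solving the linear system at each
time sample, i.e. this is a model-based inverse, not a numerical Laplacian.

`CurrentSourceDensity` packages the pipeline as a transformer: `fit` builds
the forward operator from a geometry, `transform` maps measured potentials
(time × positions, mV) to compartment source densities, and
`inverse_transform` is the forward map back to potentials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .geometry import CompartmentSet, FuniculusGeometry, compartmentize
from .signals import EAGRecording

__all__ = [
    "ForwardModel",
    "CSDResult",
    "forward_matrix",
    "forward_potentials",
    "invert_csd",
    "csd_timecourse",
    "csd_response_area",
    "csd_barycenter",
    "spatial_spread",
    "CurrentSourceDensity",
]

#: Condition-number ceiling beyond which the square inverse is refused.
COND_LIMIT = 1e8

#: Integration window for CSD response areas (s after stimulus onset).
AREA_WINDOW_S = 1.5


def _rect_integral(u1: np.ndarray, u2: np.ndarray, v1: float, v2: float) -> np.ndarray:
    """∬ du dv / sqrt(u² + v²) over [u1, u2] × [v1, v2], via the corner
    antiderivative H(u, v) = u·asinh(v/|u|) + v·asinh(u/|v|).

    Finite for rectangles containing or touching the origin: each term has
    limit 0 as its first argument → 0.
    """

    def term(u, v):
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        out = np.zeros(np.broadcast(u, v).shape)
        nz = np.abs(u) > 0
        uu = np.where(nz, u, 1.0)
        np.copyto(out, u * np.arcsinh(v / np.abs(uu)), where=nz)
        return out

    def H(u, v):
        return term(u, v) + term(v, u)

    return H(u2, v2) - H(u1, v2) - H(u2, v1) + H(u1, v1)


@dataclass(frozen=True)
class ForwardModel:
    """Linear operator mapping compartment source densities to electrode
    potentials.

    ``matrix`` is electrode-major: ``matrix[j, i]`` is the potential at
    electrode j per unit source density in compartment i, so
    φ = matrix @ C.  All entries are positive (a positive source raises the
    potential everywhere on the surface).
    """

    matrix: np.ndarray
    compartments: CompartmentSet
    positions_mm: np.ndarray
    sigma: float

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))


@dataclass(frozen=True)
class CSDResult:
    """Per-compartment source estimates for one recording.

    ``sources`` has shape (n_samples, n_compartments) on the recording's
    time base.  ``response_areas`` integrate each source over the 1.5 s
    window after onset, sign-flipped so odor-evoked activation is positive.
    ``barycenter_norm`` is the activation-weighted mean electrode position,
    the scalar summary of where an odor activates the antenna.
    """

    sources: np.ndarray
    times_s: np.ndarray
    response_areas: np.ndarray
    barycenter_norm: float
    positions_norm: np.ndarray


def forward_matrix(
    compartments: CompartmentSet,
    positions_mm: np.ndarray,
    sigma: float = 10.0,
) -> ForwardModel:
    """Assemble the N×N forward matrix for electrodes at y = 0.

    Entry (j, i) = 1/(4πσ) × ∬ over compartment i of dx dy / r with r the
    planar distance to electrode j.  End compartments already carry their
    corrected x-bounds from `compartmentize`.
    """
    positions_mm = np.asarray(positions_mm, dtype=float)
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    x_min, x_max = compartments.x_lo_mm[0], compartments.x_hi_mm[-1]
    if np.any(positions_mm < x_min - 1e-12) or np.any(positions_mm > x_max + 1e-12):
        raise ValueError(
            f"electrode positions {positions_mm} fall outside the funiculus "
            f"[{x_min}, {x_max}] mm"
        )
    q = compartments.q_mm
    # u-bounds of compartment i relative to electrode j: (n_elec, n_comp)
    u1 = compartments.x_lo_mm[None, :] - positions_mm[:, None]
    u2 = compartments.x_hi_mm[None, :] - positions_mm[:, None]
    m = _rect_integral(u1, u2, -q, q) / (4.0 * np.pi * sigma)
    if not np.all(np.isfinite(m)) or np.any(m <= 0):
        raise ArithmeticError("forward matrix has non-finite or non-positive entries")
    model = ForwardModel(
        matrix=m, compartments=compartments, positions_mm=positions_mm, sigma=sigma
    )
    return model


def forward_potentials(model: ForwardModel, sources: np.ndarray) -> np.ndarray:
    """Potentials φ_j = Σ_i F[i,j]·C_i for a source vector, or for a stack
    of source vectors indexed along the leading axes."""
    sources = np.asarray(sources, dtype=float)
    if sources.shape[-1] != model.n:
        raise ValueError(
            f"source vector length {sources.shape[-1]} != model size {model.n}"
        )
    return sources @ model.matrix.T


def invert_csd(model: ForwardModel, potentials: np.ndarray) -> np.ndarray:
    """Solve F C = φ for the source vector(s).

    Refuses ill-conditioned systems (condition number ≥ 1e8): those call
    for regularization or a geometry check, not a raw inverse.
    """
    potentials = np.asarray(potentials, dtype=float)
    if potentials.shape[-1] != model.n:
        raise ValueError(
            f"potential vector length {potentials.shape[-1]} != model size {model.n}"
        )
    cond = model.condition_number
    if not np.isfinite(cond) or cond >= COND_LIMIT:
        raise np.linalg.LinAlgError(
            f"forward matrix condition number {cond:.3g} ≥ {COND_LIMIT:.0e}; "
            "check the geometry (a regularized inverse is out of scope)"
        )
    return np.linalg.solve(model.matrix, potentials.T).T


def csd_timecourse(model: ForwardModel, rec: EAGRecording) -> np.ndarray:
    """Estimate the CSD at each time sample of a preprocessed recording.

    Returns sources with shape (n_samples, n_compartments) in mV per
    forward-model unit; the inversion is independent per sample.
    """
    if rec.n_positions != model.n:
        raise ValueError(
            f"recording has {rec.n_positions} positions but the model expects {model.n}"
        )
    return invert_csd(model, rec.traces)


def csd_response_area(
    sources: np.ndarray,
    times_s: np.ndarray,
    onset_s: float,
    window_s: float = AREA_WINDOW_S,
) -> np.ndarray:
    """Integrate each compartment's source over (onset, onset + 1.5 s].

    Trapezoidal rule on the recording's time base; the sign is flipped here,
    once, so canonical negative-going responses yield positive areas and all
    downstream quantities are positive-for-activation.
    """
    sources = np.asarray(sources, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    if times_s[-1] < onset_s + window_s - 1e-9:
        raise ValueError(
            f"need {window_s} s of signal after onset; trace ends at "
            f"{times_s[-1]:.3f} s with onset {onset_s:.3f} s"
        )
    sel = (times_s >= onset_s) & (times_s <= onset_s + window_s + 1e-12)
    return -np.trapezoid(sources[sel], times_s[sel], axis=0)


def csd_barycenter(areas: np.ndarray, positions_norm: np.ndarray) -> float:
    """Activation-weighted mean electrode position on [0, 1].

    Weights are the positive parts of the response areas; compartments with
    net suppression do not pull the barycenter.  Raises if no compartment
    shows activation.
    """
    areas = np.asarray(areas, dtype=float)
    positions_norm = np.asarray(positions_norm, dtype=float)
    w = np.clip(areas, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise ValueError("no detectable activation: all response areas are ≤ 0")
    return float((positions_norm * w).sum() / total)


def spatial_spread(weights: np.ndarray) -> float:
    """Participation ratio (Σ|w|)² / Σw² of a spatial activation pattern.

    1 for activity confined to a single position, N for perfectly uniform
    activity; used to compare how spatially restricted CSD responses are
    relative to the raw EAG amplitudes.
    """
    w = np.abs(np.asarray(weights, dtype=float))
    denom = (w**2).sum()
    if denom == 0:
        raise ValueError("all-zero pattern has no defined spread")
    return float(w.sum() ** 2 / denom)


class CurrentSourceDensity(BaseEstimator, TransformerMixin):
    """Model-based CSD transformer for multi-position EAG recordings.

    Parameters
    ----------
    geometry : FuniculusGeometry
        Funiculus dimensions and electrode layout; defines the compartment
        rectangles of the forward model.

    Attributes
    ----------
    compartments_ : CompartmentSet
    forward_ : ForwardModel
        φ = forward_.matrix @ C.
    condition_number_ : float

    Examples
    --------
    >>> from olfactomap.geometry import FuniculusGeometry
    >>> est = CurrentSourceDensity(FuniculusGeometry(0.4, 0.25, 0.2)).fit()
    >>> est.forward_.matrix.shape
    (4, 4)
    """

    def __init__(self, geometry: FuniculusGeometry | None = None):
        self.geometry = geometry

    def fit(self, X=None, y=None) -> "CurrentSourceDensity":
        """Build the forward operator. X and y are ignored (the model is
        fully determined by the geometry)."""
        if self.geometry is None:
            raise ValueError("CurrentSourceDensity requires a geometry")
        self.compartments_ = compartmentize(self.geometry)
        self.forward_ = forward_matrix(
            self.compartments_, self.geometry.positions_mm, self.geometry.sigma
        )
        self.condition_number_ = self.forward_.condition_number
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Map potentials (…, n_positions) to source densities."""
        self._check_fitted()
        return invert_csd(self.forward_, np.asarray(X, dtype=float))

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        """Map source densities back to electrode potentials."""
        self._check_fitted()
        return forward_potentials(self.forward_, np.asarray(X, dtype=float))

    def analyze(self, rec: EAGRecording) -> CSDResult:
        """Full reduction of a preprocessed recording: source time courses,
        response areas over the 1.5 s window, and the spatial barycenter."""
        self._check_fitted()
        sources = csd_timecourse(self.forward_, rec)
        areas = csd_response_area(sources, rec.times_s, rec.stimulus_onset_s)
        bary = csd_barycenter(areas, np.asarray(self.geometry.positions_norm))
        return CSDResult(
            sources=sources,
            times_s=rec.times_s,
            response_areas=areas,
            barycenter_norm=bary,
            positions_norm=np.asarray(self.geometry.positions_norm),
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "forward_"):
            raise AttributeError("CurrentSourceDensity is not fitted; call fit() first")
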