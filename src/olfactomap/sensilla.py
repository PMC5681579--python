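"""Sensilla point patterns, kernel density maps, and dominance profiles.

Sensilla positions are annotated on the lateral funiculus face in
normalized coordinates (x: proximo-distal on [0,1], y: ventro-dorsal on
[0,1]).  Density maps convolve the point pattern with an anisotropic 2D
Gaussian (σx = 2% of length, σy = 5% of width); the sensilla dominance
index (D_b + D_c − D_t)/(D_b + D_c + D_t) contrasts food-odor sensilla
(basiconic + clavate) against trichoid sensilla along the antenna.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "MORPHOTYPES",
    "SensillaMap",
    "DensityGrid",
    "density_map",
    "dominance_profile",
    "count_summary",
    "summarize_counts",
    "SensillaDensity",
]

MORPHOTYPES = ("trichoid", "basiconic", "clavate", "coeloconic")


@dataclass(frozen=True)
class SensillaMap:
    """Annotated sensilla point pattern for one individual.

    ``records`` is a DataFrame with columns x_norm, y_norm, type (from
    `MORPHOTYPES`); ``face_area_mm2`` enables per-mm² densities and is
    optional (counts never require it).
    """

    records: pd.DataFrame
    species: str = ""
    individual: str = ""
    face_area_mm2: float | None = None

    def __post_init__(self) -> None:
        df = self.records
        missing = {"x_norm", "y_norm", "type"} - set(df.columns)
        if missing:
            raise ValueError(f"sensilla records missing columns: {sorted(missing)}")
        xy = df[["x_norm", "y_norm"]].to_numpy(dtype=float)
        if xy.size and (xy.min() < 0 or xy.max() > 1):
            raise ValueError("sensilla coordinates must lie in [0, 1]²")
        bad = set(df["type"]) - set(MORPHOTYPES)
        if bad:
            raise ValueError(f"unknown morphotypes {sorted(bad)}; expected {MORPHOTYPES}")
        if self.face_area_mm2 is not None and self.face_area_mm2 <= 0:
            raise ValueError("face_area_mm2 must be positive when given")

    def points(self, morphotype: str) -> np.ndarray:
        """(n, 2) array of x_norm, y_norm for one morphotype."""
        if morphotype not in MORPHOTYPES:
            raise ValueError(f"unknown morphotype {morphotype!r}")
        sub = self.records[self.records["type"] == morphotype]
        return sub[["x_norm", "y_norm"]].to_numpy(dtype=float).reshape(-1, 2)

    def counts(self) -> dict[str, int]:
        c = self.records["type"].value_counts()
        return {m: int(c.get(m, 0)) for m in MORPHOTYPES}


@dataclass(frozen=True)
class DensityGrid:
    """Kernel density field on a regular lattice covering [0,1]².

    ``values[iy, ix]`` is the density at (x_centers[ix], y_centers[iy]) in
    sensilla per unit normalized area; dividing by a face area converts to
    per-mm².  Lattice-quadrature integral ≈ number of points (kernels are
    unit-mass, truncated at ±4σ and at the map boundary without
    renormalization, so border points lose a little mass).
    """

    values: np.ndarray
    x_centers: np.ndarray
    y_centers: np.ndarray
    sigma_x: float
    sigma_y: float

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("densities must be non-negative")

    def integral(self) -> float:
        dx = 1.0 / self.x_centers.size
        dy = 1.0 / self.y_centers.size
        return float(self.values.sum() * dx * dy)

    def x_profile(self) -> np.ndarray:
        """Density averaged over y, as a function of x."""
        return self.values.mean(axis=0)


def density_map(
    smap: SensillaMap,
    morphotype: str,
    grid_res: tuple[int, int] = (200, 100),
    sigma_x: float = 0.02,
    sigma_y: float = 0.05,
    truncate: float = 4.0,
) -> DensityGrid:
    """Kernel density map for one morphotype.

    Each sensillum contributes a unit-mass Gaussian kernel, truncated at
    ±``truncate``σ; the grid has ``grid_res`` = (nx, ny) cells with centers
    at (i + ½)/n.  Defaults match the standard choice of σx = 2% of the
    funiculus length and σy = 5% of its width.
    """
    nx, ny = grid_res
    if nx < 2 or ny < 2:
        raise ValueError(f"grid resolution must be ≥ 2 in each axis, got {grid_res}")
    if sigma_x <= 0 or sigma_y <= 0:
        raise ValueError("kernel standard deviations must be positive")
    xc = (np.arange(nx) + 0.5) / nx
    yc = (np.arange(ny) + 0.5) / ny
    pts = smap.points(morphotype)
    values = np.zeros((ny, nx))
    if pts.size:
        # separable kernel: outer product of truncated 1-D Gaussians
        dx = xc[None, :] - pts[:, 0][:, None]          # (n_pts, nx)
        dy = yc[None, :] - pts[:, 1][:, None]          # (n_pts, ny)
        gx = np.exp(-0.5 * (dx / sigma_x) ** 2) / (sigma_x * np.sqrt(2 * np.pi))
        gy = np.exp(-0.5 * (dy / sigma_y) ** 2) / (sigma_y * np.sqrt(2 * np.pi))
        gx[np.abs(dx) > truncate * sigma_x] = 0.0
        gy[np.abs(dy) > truncate * sigma_y] = 0.0
        values = np.einsum("py,px->yx", gy, gx)
    return DensityGrid(values=values, x_centers=xc, y_centers=yc,
                       sigma_x=sigma_x, sigma_y=sigma_y)


def dominance_profile(
    grid_b: DensityGrid, grid_c: DensityGrid, grid_t: DensityGrid
) -> np.ndarray:
    """Sensilla dominance index (D_b + D_c − D_t)/(D_b + D_c + D_t) vs x.

    D_* are the y-averaged densities at each x bin.  +1 where only
    basiconic + clavate sensilla occur, −1 where only trichoid; bins with
    no sensilla of any of the three types are NaN (undefined, not 0).
    """
    for g in (grid_c, grid_t):
        if g.values.shape != grid_b.values.shape or not np.allclose(
            g.x_centers, grid_b.x_centers
        ):
            raise ValueError("density grids must share one lattice")
    db, dc, dt = (g.x_profile() for g in (grid_b, grid_c, grid_t))
    total = db + dc + dt
    with np.errstate(invalid="ignore", divide="ignore"):
        index = np.where(total > 0, (db + dc - dt) / np.where(total > 0, total, 1.0), np.nan)
    return index


def summarize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Derived columns for a per-individual morphotype count table.

    Input columns: the four morphotypes (optionally density_* and
    identifier columns, passed through).  Adds basiconic_clavate, total and
    the (basiconic + clavate)/trichoid ratio (NaN where trichoid = 0, an
    undefined marker rather than an error).
    """
    missing = set(MORPHOTYPES) - set(counts.columns)
    if missing:
        raise ValueError(f"count table missing morphotype columns: {sorted(missing)}")
    out = counts.copy()
    out["basiconic_clavate"] = out["basiconic"] + out["clavate"]
    out["total"] = out[list(MORPHOTYPES)].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = out["basiconic_clavate"] / out["trichoid"]
    out["bc_over_t"] = ratio.where(out["trichoid"] > 0)
    return out


def count_summary(maps: list[SensillaMap]) -> dict[str, pd.DataFrame]:
    """Per-individual and aggregated sensilla counts.

    Returns ``{"individuals": ..., "aggregate": ...}``.  The aggregate
    carries mean and SD per column plus two ratio summaries that are easy to
    conflate: ``mean_of_ratios`` (the mean of per-individual (b+c)/t, the
    convention used for printed per-species ratios) and ``ratio_of_means``.
    Densities per mm² appear only for maps that supply a face area.
    """
    if not maps:
        raise ValueError("need at least one sensilla map")
    rows = []
    for m in maps:
        row: dict = {"species": m.species, "individual": m.individual}
        row.update(m.counts())
        if m.face_area_mm2 is not None:
            for k, v in m.counts().items():
                row[f"density_{k}"] = v / m.face_area_mm2
        rows.append(row)
    indiv = summarize_counts(pd.DataFrame(rows))
    num = indiv.select_dtypes("number")
    agg = pd.DataFrame({"mean": num.mean(), "sd": num.std(ddof=1)})
    agg.loc["bc_over_t", "mean_of_ratios"] = indiv["bc_over_t"].mean()
    agg.loc["bc_over_t", "ratio_of_means"] = (
        indiv["basiconic_clavate"].mean() / indiv["trichoid"].mean()
        if indiv["trichoid"].mean() > 0
        else np.nan
    )
    return {"individuals": indiv, "aggregate": agg}


class SensillaDensity(BaseEstimator):
    """Estimator wrapper for per-morphotype kernel density mapping.

    Parameters mirror `density_map`; `fit` stores a SensillaMap and builds
    one grid per morphotype in ``grids_``, plus the dominance-index profile
    in ``dominance_`` (basiconic + clavate vs trichoid).
    """

    def __init__(
        self,
        grid_res: tuple[int, int] = (200, 100),
        sigma_x: float = 0.02,
        sigma_y: float = 0.05,
        truncate: float = 4.0,
    ):
        self.grid_res = grid_res
        self.sigma_x = sigma_x
        self.sigma_y = sigma_y
        self.truncate = truncate

    def fit(self, X: SensillaMap, y=None) -> "SensillaDensity":
        self.grids_ = {
            m: density_map(X, m, self.grid_res, self.sigma_x, self.sigma_y, self.truncate)
            for m in MORPHOTYPES
        }
        self.dominance_ = dominance_profile(
            self.grids_["basiconic"], self.grids_["clavate"], self.grids_["trichoid"]
        )
        self.x_centers_ = self.grids_["trichoid"].x_centers
        return self
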