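"""Roost-proximity correction of activity surfaces.

Colonial bats commute between roosts and foraging grounds, so raw radar
detections are inflated near roosts by departing and returning animals
that are not foraging there. The correction down-weights each pixel by a
bounded exponential decay in distance to the nearest roost:

    factor(d) = 1 / (1 + A * exp(-d / lambda))

which equals 1/(1+A) at a roost and approaches 1 far away, so distant
pixels are untouched. ``A`` (amplitude, dimensionless) and ``lambda``
(scale, meters; the order of a nightly commute radius) are fixed a
priori, not estimated from the data being corrected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .grids import ActivityRaster, Grid
from .presence import to_rate


@dataclass(frozen=True)
class RoostSet:
    """Known roost locations in projected meters (N x 2 array of x, y)."""

    points: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.shape[0] < 1 or pts.shape[1] != 2:
            raise ValueError("RoostSet needs at least one (x, y) point")
        if not np.isfinite(pts).all():
            raise ValueError("roost coordinates must be finite")
        object.__setattr__(self, "points", pts)
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (pts.shape[0],) or (w < 0).any():
                raise ValueError("weights must be one non-negative value per roost")
            object.__setattr__(self, "weights", w)

    @classmethod
    def from_file(cls, path: str | Path) -> "RoostSet":
        """Load roosts from GeoJSON points or a CSV with x,y columns."""
        path = Path(path)
        if path.suffix.lower() in {".json", ".geojson"}:
            with open(path) as fh:
                gj = json.load(fh)
            pts = [f["geometry"]["coordinates"] for f in gj["features"]]
            return cls(points=np.asarray(pts, dtype=float))
        df = pd.read_csv(path)
        return cls(points=df[["x", "y"]].to_numpy(dtype=float))


@dataclass(frozen=True)
class DecayParams:
    """Parameters of the distance-decay correction."""

    amplitude: float = 1.0  # A >= 0, dimensionless
    scale: float = 5000.0  # lambda > 0, meters

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")


def distance_to_nearest_roost(grid: Grid, roosts: RoostSet) -> np.ndarray:
    """Euclidean distance (m) from each pixel center to the nearest roost."""
    x, y = grid.pixel_centers()
    d2 = np.full(grid.shape, np.inf)
    for rx, ry in roosts.points:
        d2 = np.minimum(d2, (x - rx) ** 2 + (y - ry) ** 2)
    return np.sqrt(d2)


def correction_factor(
    d: np.ndarray | float, params: DecayParams
) -> np.ndarray | float:
    """Multiplicative correction in (0, 1]; strictly increasing in d."""
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    out = 1.0 / (1.0 + params.amplitude * np.exp(-d / params.scale))
    return out if out.ndim else float(out)


def _sum_plume(grid: Grid, roosts: RoostSet, params: DecayParams) -> np.ndarray:
    """Summed roost plume A * sum_j exp(-d_j / lambda) over all roosts."""
    x, y = grid.pixel_centers()
    w = roosts.weights if roosts.weights is not None else np.ones(len(roosts.points))
    plume = np.zeros(grid.shape)
    for (rx, ry), wj in zip(roosts.points, w):
        d = np.hypot(x - rx, y - ry)
        plume += wj * np.exp(-d / params.scale)
    return params.amplitude * plume


def correct_activity(
    raster: ActivityRaster,
    roosts: RoostSet,
    params: DecayParams,
    mode: str = "nearest",
) -> np.ndarray:
    """Roost-corrected activity rate (occurrences·ha⁻¹·night⁻¹).

    ``mode='nearest'`` applies factor(d) with d the distance to the
    nearest roost; ``mode='sum'`` is a sensitivity variant that pools
    the decay over all roosts, 1/(1 + A·Σ_j exp(-d_j/λ)). Masked pixels
    stay missing (NaN).
    """
    rate = to_rate(raster)
    if mode == "nearest":
        d = distance_to_nearest_roost(raster.grid, roosts)
        factor = correction_factor(d, params)
    elif mode == "sum":
        factor = 1.0 / (1.0 + _sum_plume(raster.grid, roosts, params))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return rate * factor


class RoostCorrector(BaseEstimator, TransformerMixin):
    """Transformer applying the roost distance-decay correction.

    Parameters
    ----------
    roosts : RoostSet
    amplitude : float
        Decay amplitude A (>= 0); 0 disables the correction.
    scale : float
        Decay scale lambda in meters (> 0).
    mode : {'nearest', 'sum'}
        Nearest-roost distance (default) or summed plume over all roosts.
    """

    def __init__(
        self,
        roosts: RoostSet | None = None,
        amplitude: float = 1.0,
        scale: float = 5000.0,
        mode: str = "nearest",
    ):
        self.roosts = roosts
        self.amplitude = amplitude
        self.scale = scale
        self.mode = mode

    def _params(self) -> DecayParams:
        return DecayParams(amplitude=self.amplitude, scale=self.scale)

    def fit(self, X: ActivityRaster, y=None) -> "RoostCorrector":
        if self.roosts is None:
            raise ValueError("RoostCorrector requires a RoostSet")
        self._params()  # validate
        return self

    def transform(self, X: ActivityRaster) -> np.ndarray:
        self.fit(X)
        self.distance_ = distance_to_nearest_roost(X.grid, self.roosts)
        corrected = correct_activity(X, self.roosts, self._params(), mode=self.mode)
        self.corrected_ = corrected
        return corrected
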