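"""Seasonal aggregation of per-scan presence scenes.

Collapses a season of binary radar scenes into a single occurrence-count
surface and normalizes it to the standard activity unit, occurrences per
hectare per night: ``rate = count / (pixel_area_ha * n_nights)``. A 70 m
pixel covers 0.49 ha, so e.g. 7431 occurrences over a 152-night season
correspond to 7431 / (0.49 * 152) ≈ 99.77 occurrences·ha⁻¹·night⁻¹.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .grids import ActivityRaster, Grid, PresenceScene


def aggregate_scenes(
    scenes: Iterable[PresenceScene], n_nights: int
) -> ActivityRaster:
    """Sum binary scenes into per-pixel occurrence counts.

    Accepts any iterable (including a lazy generator) so a full season of
    scans never needs to be materialized at once.
    """
    counts: np.ndarray | None = None
    grid: Grid | None = None
    n_scenes = 0
    for i, scene in enumerate(scenes):
        if counts is None:
            grid = scene.grid
            counts = np.zeros(grid.shape, dtype=np.int64)
        elif scene.values.shape != counts.shape:
            raise ValueError(
                f"scene {i} has shape {scene.values.shape}, "
                f"expected {counts.shape}"
            )
        counts += scene.values
        n_scenes += 1
    if counts is None or grid is None:
        raise ValueError("at least one scene is required")
    return ActivityRaster(counts=counts, grid=grid, n_nights=n_nights, n_scenes=n_scenes)


def to_rate(raster: ActivityRaster) -> np.ndarray:
    """Per-pixel activity in occurrences·ha⁻¹·night⁻¹ (NaN where masked)."""
    if raster.n_nights < 1:
        raise ValueError("n_nights must be >= 1")
    area = raster.pixel_area_ha
    if area <= 0:
        raise ValueError("pixel area must be positive")
    rate = raster.counts / (area * raster.n_nights)
    rate = rate.astype(float)
    rate[~raster.valid] = np.nan
    return rate


def apply_mask(raster: ActivityRaster, mask: np.ndarray) -> ActivityRaster:
    """Restrict the raster to pixels where ``mask`` is truthy.

    Masked pixels become missing — they are excluded from every downstream
    statistic, never counted as zero activity.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != raster.counts.shape:
        raise ValueError("mask shape does not match raster")
    valid = raster.valid & mask
    if not valid.any():
        raise ValueError("mask removes every pixel; no statistics are defined")
    return ActivityRaster(
        counts=raster.counts.copy(),
        grid=raster.grid,
        n_nights=raster.n_nights,
        n_scenes=raster.n_scenes,
        valid=valid,
    )


def fraction_area_detected(raster: ActivityRaster) -> float:
    """Share of unmasked pixels with at least one detection over the season."""
    valid = raster.valid
    if not valid.any():
        raise ValueError("no unmasked pixels")
    return float((raster.counts[valid] >= 1).mean())


class SceneAggregator(BaseEstimator, TransformerMixin):
    """Transformer from a season of presence scenes to an activity raster.

    Parameters
    ----------
    n_nights : int
        Number of nights spanned by the scenes (normalization denominator).
    mask : ndarray of bool, optional
        Analysis mask (True = keep); e.g. a clutter/terrain mask.
    """

    def __init__(self, n_nights: int = 152, mask: np.ndarray | None = None):
        self.n_nights = n_nights
        self.mask = mask

    def fit(self, X: Iterable[PresenceScene], y=None) -> "SceneAggregator":
        return self

    def transform(self, X: Iterable[PresenceScene]) -> ActivityRaster:
        raster = aggregate_scenes(X, n_nights=self.n_nights)
        if self.mask is not None:
            raster = apply_mask(raster, self.mask)
        self.raster_ = raster
        self.rate_ = to_rate(raster)
        self.n_scenes_ = raster.n_scenes
        self.scenes_per_night_ = raster.n_scenes / self.n_nights
        return raster
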