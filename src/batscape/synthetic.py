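"""Synthetic landscape, radar-scene, and covariate generator.

No public archive of the radar-derived bat-presence product exists, so
every input the pipeline consumes can be simulated here with known
ground truth: a patch-tessellated land-cover layer, per-scan Bernoulli
presence scenes whose probability combines a class-specific foraging
weight with a roost commute plume, and co-registered temperature,
nighttime-lights and irrigated-area covariates.

Per-scan presence probability at a pixel of class k at distance d from
the nearest roost:

    p = clip( r * w_k * (1 + A_sim * exp(-d / lambda_sim)), 0, 1 )

so the simulated commute artifact has exactly the exponential shape the
roost correction is designed to remove: correcting with matched (A,
lambda) restores a distance-free surface. Defaults mirror the emulated
study season: 152 nights, 126 scans per night, 70 m pixels, 8 roosts,
rice foraging weight twice grassland's, and r chosen so a typical pixel
sits near 16 occurrences per hectare per night.

All randomness flows from one integer seed through per-stage child
streams; identical config + seed reproduces outputs bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Iterator

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import box
from shapely.ops import unary_union

from .grids import Grid, PresenceScene, ActivityRaster
from .landcover import CLASSES, LandCoverLayer, Parcel
from .roost import RoostSet, DecayParams, distance_to_nearest_roost

#: Default relative foraging intensity per class: rice elevated (2x
#: grassland), natural classes around 1, desert/shrub depressed.
DEFAULT_CLASS_WEIGHTS: dict[str, float] = {
    "rice": 2.0,
    "barren/other": 1.3,
    "herbaceous": 1.25,
    "conifer": 1.2,
    "hardwood": 1.15,
    "urban": 1.1,
    "grassland": 1.0,
    "miscellaneous": 0.95,
    "row/field crops": 0.9,
    "fruits/nuts/vineyards": 0.85,
    "water/wetland": 0.8,
    "desert": 0.5,
    "shrub": 0.45,
}


def _default_roosts(width_m: float, height_m: float) -> list[tuple[float, float]]:
    """Eight roosts spread over the landscape (fixed relative layout)."""
    rel = [
        (0.15, 0.2), (0.5, 0.12), (0.82, 0.25), (0.3, 0.5),
        (0.7, 0.55), (0.18, 0.8), (0.55, 0.85), (0.88, 0.75),
    ]
    return [(fx * width_m, fy * height_m) for fx, fy in rel]


@dataclass
class LandscapeConfig:
    """Ground-truth parameters of one synthetic landscape."""

    grid_width: int = 224  # pixels (desk-scale stand-in for the study box)
    grid_height: int = 224  # pixels
    pixel_size: float = 70.0  # meters
    n_nights: int = 152
    scans_per_night: int = 126
    class_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS)
    )
    roosts: list[tuple[float, float]] | None = None  # projected meters
    commute_amplitude: float = 1.0  # A_sim >= 0
    commute_scale: float = 5000.0  # lambda_sim, meters
    detection_rate: float = 0.06  # r, per scan per pixel
    mosquito_coupling: float = 0.5  # strength of the prey-density association
    n_patches: int = 150
    temp_lo: float = 10.0  # deg C clip bounds
    temp_hi: float = 35.0
    n_temp_steps: int = 6  # one per month, April-September
    constant_temperature: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.class_weights) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown land-cover classes: {sorted(unknown)}")
        w = np.array(list(self.class_weights.values()), dtype=float)
        if (w < 0).any() or not (w > 0).any():
            raise ValueError("class weights must be >= 0 with at least one > 0")
        if self.n_nights < 1 or self.scans_per_night < 1:
            raise ValueError("n_nights and scans_per_night must be >= 1")
        if not 0.0 <= self.detection_rate <= 1.0:
            raise ValueError("detection_rate must lie in [0, 1]")
        if self.commute_amplitude < 0:
            raise ValueError("commute_amplitude must be >= 0")
        if self.commute_scale <= 0:
            raise ValueError("commute_scale must be > 0")
        if self.temp_lo >= self.temp_hi:
            raise ValueError("temp_lo must be < temp_hi")
        if self.roosts is None:
            self.roosts = _default_roosts(
                self.grid_width * self.pixel_size, self.grid_height * self.pixel_size
            )

    @property
    def grid(self) -> Grid:
        return Grid(
            nrows=self.grid_height, ncols=self.grid_width, pixel_size=self.pixel_size
        )

    @property
    def roost_set(self) -> RoostSet:
        return RoostSet(points=np.asarray(self.roosts, dtype=float))

    @property
    def n_scenes(self) -> int:
        return self.n_nights * self.scans_per_night

    def _rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(4)[stage])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LandscapeConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if doc.get("roosts") is not None:
            doc["roosts"] = [tuple(p) for p in doc["roosts"]]
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["roosts"] = [list(p) for p in (self.roosts or [])]
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


# ----------------------------------------------------------------------
def simulate_landcover(config: LandscapeConfig) -> LandCoverLayer:
    """Voronoi-style patch tessellation labeled from the 13-class vocabulary.

    Patch seed points are uniform over the landscape; each pixel joins
    the nearest seed's patch, and each patch draws a class uniformly
    from the configured vocabulary — so patches are contiguous fields
    and parcel polygons are recoverable per patch.
    """
    rng = config._rng(0)
    grid = config.grid
    classes = [c for c, w in config.class_weights.items()]
    if len(classes) == 1:
        assign = np.zeros(grid.shape, dtype=np.int64)
        patch_classes = [classes[0]]
    else:
        n_patch = max(config.n_patches, 1)
        sx = rng.uniform(0, grid.ncols * grid.pixel_size, n_patch)
        sy = rng.uniform(0, grid.nrows * grid.pixel_size, n_patch)
        x, y = grid.pixel_centers()
        d2 = (x[..., None] - sx) ** 2 + (y[..., None] - sy) ** 2
        assign = np.argmin(d2, axis=-1)
        patch_classes = [classes[i] for i in rng.integers(0, len(classes), n_patch)]

    parcels: list[Parcel] = []
    ps = grid.pixel_size
    for patch_id in np.unique(assign):
        rows, cols = np.nonzero(assign == patch_id)
        boxes = [
            box(
                grid.x_origin + c * ps,
                grid.y_origin + (grid.nrows - r - 1) * ps,
                grid.x_origin + (c + 1) * ps,
                grid.y_origin + (grid.nrows - r) * ps,
            )
            for r, c in zip(rows, cols)
        ]
        geom = unary_union(boxes)
        cls = patch_classes[patch_id]
        parcels.append(Parcel(geometry=geom, raw_label=cls, lc_class=cls))
    return LandCoverLayer(parcels)


def _presence_probability(
    config: LandscapeConfig, landcover: LandCoverLayer
) -> np.ndarray:
    grid = config.grid
    codes = landcover.class_raster(grid)
    if (codes < 0).any():
        raise ValueError("land-cover layer does not cover the grid")
    weights = np.array(
        [config.class_weights.get(CLASSES[i], 0.0) for i in range(len(CLASSES))]
    )
    w = weights[codes]
    d = distance_to_nearest_roost(grid, config.roost_set)
    plume = 1.0 + config.commute_amplitude * np.exp(-d / config.commute_scale)
    raw = config.detection_rate * w * plume
    if config.mosquito_coupling != 0.0:
        # monotone (linear) association with the temperature-driven prey
        # proxy: pixels with above-average predicted mosquito abundance
        # attract proportionally more foraging
        from .tpc import AbundanceParams, abundance_raster

        temp, _, _ = simulate_covariates(config, landcover)
        m = abundance_raster(temp, AbundanceParams.default())
        rel = m / m.mean() if m.mean() > 0 else np.ones_like(m)
        raw = raw * np.clip(1.0 + config.mosquito_coupling * (rel - 1.0), 0.0, None)
    if raw.max() > 5.0:
        warnings.warn(
            "presence probability exceeds 5 before clipping; the Bernoulli "
            "regime is degenerate",
            stacklevel=3,
        )
    return np.clip(raw, 0.0, 1.0)


def simulate_scenes(
    config: LandscapeConfig, landcover: LandCoverLayer
) -> Iterator[PresenceScene]:
    """Lazily yield one binary presence scene per radar scan.

    Each pixel is present independently with the class-weight x roost-
    plume probability; scenes stream night by night so a full season
    never sits in memory.
    """
    p = _presence_probability(config, landcover)
    rng = config._rng(1)
    grid = config.grid
    for night in range(config.n_nights):
        draws = rng.random((config.scans_per_night, *grid.shape)) < p
        for scan in range(config.scans_per_night):
            yield PresenceScene(
                values=draws[scan].astype(np.uint8),
                grid=grid,
                timestamp=f"night{night:03d}_scan{scan:03d}",
            )


def simulate_activity(
    config: LandscapeConfig, landcover: LandCoverLayer
) -> ActivityRaster:
    """Season-aggregated counts drawn directly as Binomial(n_scenes, p).

    Distributionally identical to aggregating :func:`simulate_scenes`
    (scans are iid), and far cheaper for full-season problem sizes.
    """
    p = _presence_probability(config, landcover)
    rng = config._rng(1)
    counts = rng.binomial(config.n_scenes, p)
    return ActivityRaster(
        counts=counts.astype(np.int64),
        grid=config.grid,
        n_nights=config.n_nights,
        n_scenes=config.n_scenes,
    )


#: Irrigated fraction by class: flooded rice highest, other crops lower.
_IRRIGATION_FRACTION: dict[str, float] = {
    "rice": 0.9,
    "row/field crops": 0.7,
    "fruits/nuts/vineyards": 0.55,
    "miscellaneous": 0.25,
}


def simulate_covariates(
    config: LandscapeConfig, landcover: LandCoverLayer
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Temperature stack, nighttime-lights raster, irrigated-fraction raster.

    Temperature (deg C) is a smooth west-east gradient plus a seasonal
    sinusoid over the configured time steps and mild noise, clipped to
    [temp_lo, temp_hi]; lights are low everywhere but elevated over
    urban pixels; irrigated fraction follows agricultural classes.
    """
    rng = config._rng(2)
    grid = config.grid
    codes = landcover.class_raster(grid)

    n_t = config.n_temp_steps
    if config.constant_temperature is not None:
        temp = np.full((n_t, *grid.shape), float(config.constant_temperature))
    else:
        cols = np.linspace(0.0, 1.0, grid.ncols)[None, :] * np.ones(grid.shape)
        season = 22.0 + 6.0 * np.sin(
            np.pi * (np.arange(n_t) + 0.5) / n_t
        )  # warm mid-season
        temp = (
            season[:, None, None]
            + 4.0 * (cols - 0.5)[None, :, :]
            + rng.normal(0.0, 0.5, (n_t, *grid.shape))
        )
    temp = np.clip(temp, config.temp_lo, config.temp_hi)

    urban = codes == CLASSES.index("urban")
    lights = np.abs(rng.normal(0.5, 0.3, grid.shape))
    lights[urban] += 5.0

    irrigated = np.zeros(grid.shape)
    for cls, frac in _IRRIGATION_FRACTION.items():
        irrigated[codes == CLASSES.index(cls)] = frac
    irrigated = np.clip(irrigated + rng.normal(0.0, 0.03, grid.shape), 0.0, 1.0)
    return temp, lights, irrigated


# ----------------------------------------------------------------------
def simulate_pixel_records(
    n: int,
    seed: int = 0,
    mosquito_effect: Callable[[np.ndarray], np.ndarray] | None = None,
    lights_coef: float = 0.0,
    irrigated_coef: float = 0.0,
    class_offsets: dict[str, float] | None = None,
    spatial_field: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
    noise_sd: float = 1.0,
    intercept: float = 10.0,
    classes: tuple[str, ...] = ("miscellaneous", "rice", "grassland", "urban"),
) -> pd.DataFrame:
    """Directly simulate 1-km pixel records with a known regression truth.

    Used to test the association model in isolation: the response is
    intercept + f(mosquito) + lights*b + irrigated*b + class offset +
    spatial field + Gaussian noise, with every component under the
    caller's control (None/0 disables it).
    """
    rng = np.random.default_rng(seed)
    mosquito = rng.uniform(0.0, 1.0, n)
    lights = rng.uniform(0.0, 2.0, n)
    irrigated = rng.uniform(0.0, 50.0, n)
    lat = rng.uniform(38.0, 39.0, n)
    lon = rng.uniform(-122.5, -121.5, n)
    lc = np.array(classes)[rng.integers(0, len(classes), n)]
    y = intercept + rng.normal(0.0, noise_sd, n)
    if mosquito_effect is not None:
        y += mosquito_effect(mosquito)
    y += lights_coef * lights + irrigated_coef * irrigated
    if class_offsets:
        y += np.array([class_offsets.get(c, 0.0) for c in lc])
    if spatial_field is not None:
        y += spatial_field(lat, lon)
    return pd.DataFrame(
        {
            "pixel_id": np.arange(n),
            "lat": lat,
            "lon": lon,
            "bat_activity": y,
            "mosquito": mosquito,
            "lights": lights,
            "irrigated_ha": irrigated,
            "lc_class": lc,
        }
    )
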