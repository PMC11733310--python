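"""Land-cover harmonization and area-weighted foraging statistics.

Two sources describe the landscape: a natural-vegetation layer and a
crop-parcel layer with per-field crop labels. Their raw labels are
regrouped into 13 harmonized classes nested in 4 broad types
(agricultural, natural, urban/other, water). Where the layers overlap
the crop layer wins: it is field-validated for the study year, whereas
the natural layer's "agriculture" category is older and coarser — those
uncovered agricultural remnants (field margins, fallowed ground) become
the "miscellaneous" class.

Activity statistics are computed per parcel (the independent management
unit) and summarized per class as area-weighted means,

    mean_c = sum_i(m_i * a_i) / sum_i(a_i)

over parcels i in class c with parcel mean rate m_i and area a_i, with
95% confidence intervals from a seeded bootstrap over parcels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping as geom_mapping, shape as geom_shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union
from sklearn.base import BaseEstimator

from .grids import Grid

#: The 13 harmonized land-cover classes and the broad type each belongs to.
CLASS_TO_TYPE: dict[str, str] = {
    "barren/other": "urban/other",
    "conifer": "natural",
    "desert": "natural",
    "fruits/nuts/vineyards": "agricultural",
    "grassland": "natural",
    "hardwood": "natural",
    "herbaceous": "natural",
    "rice": "agricultural",
    "row/field crops": "agricultural",
    "shrub": "natural",
    "water/wetland": "water",
    "urban": "urban/other",
    "miscellaneous": "agricultural",
}

CLASSES: tuple[str, ...] = tuple(CLASS_TO_TYPE)

STUDY_WIDE = "study-wide"


@dataclass
class Parcel:
    geometry: BaseGeometry
    raw_label: str
    lc_class: str
    parcel_id: int = -1

    @property
    def lc_type(self) -> str:
        return CLASS_TO_TYPE[self.lc_class]

    @property
    def area_ha(self) -> float:
        return self.geometry.area / 1e4


class LandCoverLayer:
    """A set of labeled parcels covering (part of) the analysis grid."""

    def __init__(self, parcels: list[Parcel]):
        bad = {p.lc_class for p in parcels} - set(CLASSES)
        if bad:
            raise ValueError(f"classes outside the 13-class vocabulary: {sorted(bad)}")
        for i, p in enumerate(parcels):
            p.parcel_id = i
        self.parcels = parcels

    def __len__(self) -> int:
        return len(self.parcels)

    @property
    def total_area_ha(self) -> float:
        return sum(p.area_ha for p in self.parcels)

    def rasterize(self, grid: Grid) -> np.ndarray:
        """Parcel id per pixel by pixel-center containment (-1 = none).

        Pixel centers sit strictly inside parcels built from pixel
        boundaries, so center containment is unambiguous there; for
        arbitrary polygons a center on a shared edge goes to the
        lowest-id parcel touching it.
        """
        x, y = grid.pixel_centers()
        out = np.full(grid.shape, -1, dtype=np.int64)
        for p in reversed(self.parcels):
            shapely.prepare(p.geometry)
            inside = shapely.contains_xy(p.geometry, x, y)
            out[inside] = p.parcel_id
        return out

    def class_raster(self, grid: Grid) -> np.ndarray:
        """Class index per pixel (index into CLASSES; -1 = unassigned)."""
        pid = self.rasterize(grid)
        class_idx = np.array(
            [CLASSES.index(p.lc_class) for p in self.parcels], dtype=np.int64
        )
        out = np.full(grid.shape, -1, dtype=np.int64)
        assigned = pid >= 0
        out[assigned] = class_idx[pid[assigned]]
        return out

    def to_geojson(self, path: str | Path) -> None:
        feats = [
            {
                "type": "Feature",
                "geometry": geom_mapping(p.geometry),
                "properties": {
                    "parcel_id": p.parcel_id,
                    "raw_label": p.raw_label,
                    "class": p.lc_class,
                    "lc_type": p.lc_type,
                    "area_ha": p.area_ha,
                },
            }
            for p in self.parcels
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)

    @classmethod
    def from_geojson(cls, path: str | Path) -> "LandCoverLayer":
        with open(path) as fh:
            gj = json.load(fh)
        parcels = []
        for f in gj["features"]:
            props = f["properties"]
            parcels.append(
                Parcel(
                    geometry=geom_shape(f["geometry"]),
                    raw_label=props.get("raw_label", props["class"]),
                    lc_class=props["class"],
                )
            )
        return cls(parcels)


def default_mapping() -> dict[str, str]:
    """The shipped raw-label -> 13-class regrouping table (editable TSV)."""
    text = resources.files("batscape.data").joinpath("landcover_mapping.tsv").read_text()
    return _parse_mapping(text)


def load_mapping(path: str | Path) -> dict[str, str]:
    return _parse_mapping(Path(path).read_text())


def _parse_mapping(text: str) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        raw, cls = line.split("\t")
        if cls not in CLASSES:
            raise ValueError(f"mapping target {cls!r} is not one of the 13 classes")
        mapping[raw.strip().lower()] = cls
    return mapping


def _map_label(raw: str, mapping: dict[str, str], missing: set[str]) -> str | None:
    cls = mapping.get(raw.strip().lower())
    if cls is None:
        missing.add(raw)
    return cls


def harmonize(
    natural_layer: list[tuple[BaseGeometry, str]],
    crop_layer: list[tuple[BaseGeometry, str]],
    mapping: dict[str, str] | None = None,
) -> LandCoverLayer:
    """Merge natural and crop sources into one 13-class parcel layer.

    Crop parcels take precedence where the layers overlap; the remainder
    of each natural parcel keeps its (mapped) natural class. A natural
    "agriculture" remainder maps to "miscellaneous" via the mapping
    table. Raises on any raw label absent from the mapping.
    """
    mapping = default_mapping() if mapping is None else mapping
    missing: set[str] = set()
    parcels: list[Parcel] = []
    for geom, raw in crop_layer:
        cls = _map_label(raw, mapping, missing)
        if cls is not None:
            parcels.append(Parcel(geometry=geom, raw_label=raw, lc_class=cls))
    crop_union = unary_union([g for g, _ in crop_layer]) if crop_layer else None
    for geom, raw in natural_layer:
        cls = _map_label(raw, mapping, missing)
        if cls is None:
            continue
        remainder = geom if crop_union is None else geom.difference(crop_union)
        if not remainder.is_empty and remainder.area > 0:
            parcels.append(Parcel(geometry=remainder, raw_label=raw, lc_class=cls))
    if missing:
        raise ValueError(f"raw labels missing from the mapping table: {sorted(missing)}")
    return LandCoverLayer(parcels)


def extract_parcel_totals(
    rate: np.ndarray,
    grid: Grid,
    layer: LandCoverLayer,
    n_nights: int | None = None,
) -> pd.DataFrame:
    """Per-parcel zonal statistics of an activity-rate surface.

    Pixels are assigned to the parcel containing their center; a
    parcel's mean rate is the mean over its unmasked (non-NaN) pixels.
    Fully masked parcels get NaN and are excluded from class means.
    When ``n_nights`` is given, total occurrences per parcel are
    back-computed as mean_rate * area_ha * n_nights.
    """
    rate = np.asarray(rate, dtype=float)
    if rate.shape != grid.shape:
        raise ValueError("rate surface and grid are not co-registered")
    pid = layer.rasterize(grid)
    area = grid.pixel_area_ha
    rows = []
    for p in layer.parcels:
        sel = pid == p.parcel_id
        vals = rate[sel]
        finite = vals[np.isfinite(vals)]
        mean_rate = float(finite.mean()) if finite.size else np.nan
        area_ha = finite.size * area
        rows.append(
            {
                "parcel_id": p.parcel_id,
                "lc_class": p.lc_class,
                "lc_type": p.lc_type,
                "n_pixels": int(sel.sum()),
                "n_valid_pixels": int(finite.size),
                "area_ha": area_ha,
                "mean_rate": mean_rate,
                "total_occurrences": (
                    mean_rate * area_ha * n_nights if n_nights else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def _weighted_mean(means: np.ndarray, areas: np.ndarray) -> float:
    return float(np.sum(means * areas) / np.sum(areas))


def _bootstrap_ci(
    means: np.ndarray,
    areas: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap of the area-weighted mean over parcels."""
    n = means.size
    idx = rng.integers(0, n, size=(n_boot, n))
    bm = means[idx]
    ba = areas[idx]
    stats = np.sum(bm * ba, axis=1) / np.sum(ba, axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def class_summaries(
    parcel_table: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    min_parcels_ci: int = 2,
) -> pd.DataFrame:
    """Area-weighted class means with bootstrap 95% CIs, plus a study-wide row.

    Parcels (not pixels) are the resampled units. Classes with fewer
    than ``min_parcels_ci`` parcels report a mean but NaN CI bounds.
    """
    df = parcel_table[np.isfinite(parcel_table["mean_rate"])]
    if df.empty:
        raise ValueError("no parcels with valid pixels")
    rng = np.random.default_rng(seed)
    rows = []
    for cls, grp in df.groupby("lc_class", sort=True):
        m = grp["mean_rate"].to_numpy()
        a = grp["area_ha"].to_numpy()
        mean = _weighted_mean(m, a)
        if len(grp) >= min_parcels_ci:
            lo, hi = _bootstrap_ci(m, a, n_boot, rng)
            lo, hi = min(lo, mean), max(hi, mean)
        else:
            lo, hi = np.nan, np.nan
        rows.append(
            {
                "lc_class": cls,
                "lc_type": CLASS_TO_TYPE[cls],
                "mean_rate": mean,
                "ci_lo": lo,
                "ci_hi": hi,
                "area_ha": float(a.sum()),
                "n_parcels": int(len(grp)),
            }
        )
    m = df["mean_rate"].to_numpy()
    a = df["area_ha"].to_numpy()
    lo, hi = _bootstrap_ci(m, a, n_boot, rng)
    rows.append(
        {
            "lc_class": STUDY_WIDE,
            "lc_type": STUDY_WIDE,
            "mean_rate": _weighted_mean(m, a),
            "ci_lo": lo,
            "ci_hi": hi,
            "area_ha": float(a.sum()),
            "n_parcels": int(len(df)),
        }
    )
    return pd.DataFrame(rows)


def rank_and_ratios(summaries: pd.DataFrame) -> pd.DataFrame:
    """Classes in descending activity order with ratios to the study-wide
    mean and to the next-highest class (ties broken alphabetically)."""
    study = summaries[summaries["lc_class"] == STUDY_WIDE]
    study_mean = float(study["mean_rate"].iloc[0]) if len(study) else np.nan
    df = summaries[summaries["lc_class"] != STUDY_WIDE].copy()
    if df.empty:
        raise ValueError("no class summaries to rank")
    df = df.sort_values(
        ["mean_rate", "lc_class"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["ratio_to_study_mean"] = df["mean_rate"] / study_mean
    nxt = df["mean_rate"].shift(-1)
    df["ratio_to_next"] = df["mean_rate"] / nxt
    df.loc[df.index[-1], "ratio_to_next"] = 1.0
    return df


def plot_class_means(summaries: pd.DataFrame, path: str | Path) -> None:
    """Bar chart of area-weighted class means with 95% CI error bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = rank_and_ratios(summaries)
    fig, ax = plt.subplots(figsize=(9, 4.5))
    err = np.vstack(
        [
            (df["mean_rate"] - df["ci_lo"]).fillna(0.0),
            (df["ci_hi"] - df["mean_rate"]).fillna(0.0),
        ]
    )
    ax.bar(df["lc_class"], df["mean_rate"], yerr=err, capsize=3)
    ax.set_ylabel("bat occurrences · ha$^{-1}$ · night$^{-1}$")
    ax.set_xlabel("land cover class")
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


class LandCoverSummarizer(BaseEstimator):
    """Estimator computing per-class foraging statistics from a rate surface.

    fit(X=(rate, grid)) with a LandCoverLayer supplied at construction;
    fitted attributes: parcel_table_, summaries_, ranking_, study_mean_.
    """

    def __init__(
        self,
        layer: LandCoverLayer | None = None,
        n_boot: int = 1000,
        seed: int = 0,
        n_nights: int | None = None,
    ):
        self.layer = layer
        self.n_boot = n_boot
        self.seed = seed
        self.n_nights = n_nights

    def fit(self, X: tuple[np.ndarray, Grid], y=None) -> "LandCoverSummarizer":
        if self.layer is None:
            raise ValueError("LandCoverSummarizer requires a LandCoverLayer")
        rate, grid = X
        self.parcel_table_ = extract_parcel_totals(
            rate, grid, self.layer, n_nights=self.n_nights
        )
        self.summaries_ = class_summaries(
            self.parcel_table_, n_boot=self.n_boot, seed=self.seed
        )
        self.ranking_ = rank_and_ratios(self.summaries_)
        self.study_mean_ = float(
            self.summaries_.loc[
                self.summaries_["lc_class"] == STUDY_WIDE, "mean_rate"
            ].iloc[0]
        )
        return self
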