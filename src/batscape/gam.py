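"""Spatial GAM linking bat activity to the mosquito-abundance prey proxy.

All layers are first block-averaged to coarse cells (~1 km; mosquitos
disperse on that scale, so finer variation in the proxy is not
ecologically meaningful). Each cell becomes one record carrying mean
bat activity, mean mosquito abundance, mean nighttime lights, irrigated
area, its dominant land-cover class, and its centroid coordinates.

The model is a Gaussian additive model,

    activity ~ s(mosquito) + lights + irrigated + C(landcover)
               + s(lat) + s(lon)

with penalized cubic B-spline smooths: a flexible (possibly nonlinear)
mosquito effect, linear controls, a categorical land-cover effect
against a declared reference class, and spatial smooths absorbing
broad-scale autocorrelation. Smooth-term significance uses the
penalty-adjusted Wald test of the fitted spline block.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.gam.api import BSplines, GLMGam
import statsmodels.api as sm

from .grids import Grid
from .landcover import CLASSES

logger = logging.getLogger(__name__)

RECORD_COLUMNS = (
    "pixel_id",
    "lat",
    "lon",
    "bat_activity",
    "mosquito",
    "lights",
    "irrigated_ha",
    "lc_class",
)


def build_pixel_table(
    activity: np.ndarray,
    mosquito: np.ndarray,
    lights: np.ndarray,
    irrigation: np.ndarray,
    class_raster: np.ndarray,
    grid: Grid,
    cell_size: float = 980.0,
    min_valid_frac: float = 0.5,
) -> pd.DataFrame:
    """Aggregate co-registered base-resolution layers to coarse cells.

    ``cell_size`` (m) must be an integer multiple of the base pixel
    (980 m = 14 x 70 m pixels by default). A base pixel is valid when
    every layer is finite there and it falls inside a labeled parcel;
    cells with under ``min_valid_frac`` valid area are dropped (count
    logged). The dominant class is the modal class by area among valid
    pixels, ties broken alphabetically. ``irrigation`` is the irrigated
    fraction of each base pixel; it aggregates to hectares per cell.
    """
    layers = [np.asarray(a, dtype=float) for a in (activity, mosquito, lights, irrigation)]
    class_raster = np.asarray(class_raster)
    for a in layers + [class_raster]:
        if a.shape != grid.shape:
            raise ValueError("all layers must be co-registered with the grid")
    block = cell_size / grid.pixel_size
    if abs(block - round(block)) > 1e-9:
        raise ValueError(
            f"cell_size {cell_size} m is not an integer multiple of the "
            f"{grid.pixel_size} m base pixel"
        )
    block = int(round(block))
    valid = np.isfinite(layers[0])
    for a in layers[1:]:
        valid &= np.isfinite(a)
    valid &= class_raster >= 0

    lon, lat = grid.center_lonlat()
    n_cr = grid.nrows // block
    n_cc = grid.ncols // block
    rows = []
    n_dropped = 0
    for ci in range(n_cr):
        for cj in range(n_cc):
            sl = np.s_[ci * block : (ci + 1) * block, cj * block : (cj + 1) * block]
            v = valid[sl]
            if v.mean() < min_valid_frac:
                n_dropped += 1
                continue
            act, mosq, lgt, irr = (a[sl][v] for a in layers)
            cls_codes = class_raster[sl][v]
            # modal class by pixel area; alphabetical tie-break via CLASSES order
            counts = np.bincount(cls_codes, minlength=len(CLASSES))
            order = np.argsort([CLASSES[i] for i in range(len(CLASSES))], kind="mergesort")
            best = int(order[np.argmax(counts[order])])
            rows.append(
                {
                    "pixel_id": ci * n_cc + cj,
                    "lat": float(lat[sl].mean()),
                    "lon": float(lon[sl].mean()),
                    "bat_activity": float(act.mean()),
                    "mosquito": float(mosq.mean()),
                    "lights": float(lgt.mean()),
                    "irrigated_ha": float((irr * grid.pixel_area_ha).sum()),
                    "lc_class": CLASSES[best],
                }
            )
    if n_dropped:
        logger.info(
            "build_pixel_table: dropped %d of %d cells with < %.0f%% valid area",
            n_dropped,
            n_cr * n_cc,
            100 * min_valid_frac,
        )
    if not rows:
        raise ValueError("no cells meet the valid-area threshold")
    return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))


class BatMosquitoGAM(BaseEstimator, RegressorMixin):
    """Penalized-spline GAM of bat activity on the prey proxy and controls.

    Parameters
    ----------
    reference_class : str
        Land-cover class absorbed into the intercept (default
        "miscellaneous"); the report always names it.
    k_mosq, k_space : int
        Basis dimensions of the mosquito smooth and of each spatial
        coordinate's smooth.
    alpha_mosq, alpha_space : float
        Penalty weights for the smooths (fixed, not data-selected, so
        refits are deterministic).
    min_class_records : int
        Classes with fewer records are dropped with a warning
        (rank-deficiency guard).

    Fitted attributes: ``result_`` (statsmodels), ``coef_table_``,
    ``smooth_pvalues_``, ``r2_``, ``r2_adj_``, ``n_obs_``,
    ``reference_class_``, ``classes_``.
    """

    def __init__(
        self,
        reference_class: str = "miscellaneous",
        k_mosq: int = 10,
        k_space: int = 8,
        alpha_mosq: float = 1.0,
        alpha_space: float = 1.0,
        min_class_records: int = 2,
    ):
        self.reference_class = reference_class
        self.k_mosq = k_mosq
        self.k_space = k_space
        self.alpha_mosq = alpha_mosq
        self.alpha_space = alpha_space
        self.min_class_records = min_class_records

    # ------------------------------------------------------------------
    def _design(self, df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        cols = [np.ones(len(df)), df["lights"].to_numpy(), df["irrigated_ha"].to_numpy()]
        names = ["(Intercept)", "Nighttime lights", "Area irrigated"]
        for cls in self.classes_:
            if cls == self.reference_class_:
                continue
            cols.append((df["lc_class"] == cls).to_numpy(dtype=float))
            names.append(f"LULC: {cls}")
        return np.column_stack(cols), names

    def fit(self, X: pd.DataFrame, y=None) -> "BatMosquitoGAM":
        df = X.copy()
        missing_cols = set(RECORD_COLUMNS) - {"pixel_id"} - set(df.columns)
        if missing_cols:
            raise ValueError(f"records are missing columns: {sorted(missing_cols)}")
        num_cols = ["lat", "lon", "bat_activity", "mosquito", "lights", "irrigated_ha"]
        if df[num_cols].isna().any().any():
            raise ValueError("records contain missing covariates")

        counts = df["lc_class"].value_counts()
        thin = sorted(counts[counts < self.min_class_records].index)
        if thin:
            warnings.warn(
                f"dropping land-cover classes with < {self.min_class_records} "
                f"records: {thin}",
                stacklevel=2,
            )
            df = df[~df["lc_class"].isin(thin)]
        self.classes_ = sorted(df["lc_class"].unique())
        if not self.classes_:
            raise ValueError("no records left to fit")
        self.reference_class_ = (
            self.reference_class
            if self.reference_class in self.classes_
            else self.classes_[0]
        )

        yv = df["bat_activity"].to_numpy(dtype=float)
        exog, names = self._design(df)
        smooth_x = df[["mosquito", "lat", "lon"]].to_numpy(dtype=float)
        self.smoother_ = BSplines(
            smooth_x,
            df=[self.k_mosq, self.k_space, self.k_space],
            degree=[3, 3, 3],
            variable_names=["mosquito", "lat", "lon"],
        )
        alpha = [self.alpha_mosq, self.alpha_space, self.alpha_space]
        model = GLMGam(
            yv, exog=exog, smoother=self.smoother_, alpha=alpha,
            family=sm.families.Gaussian(),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            res = model.fit()
        self.result_ = res
        self.exog_names_ = names
        self.records_ = df.reset_index(drop=True)
        self.n_obs_ = len(df)

        fitted = np.asarray(res.fittedvalues)
        rss = float(np.sum((yv - fitted) ** 2))
        tss = float(np.sum((yv - yv.mean()) ** 2))
        self.r2_ = 1.0 - rss / tss if tss > 0 else np.nan
        edf = float(res.hat_matrix_trace)
        self.edf_ = edf
        denom = self.n_obs_ - edf - 1.0
        self.r2_adj_ = (
            1.0 - (1.0 - self.r2_) * (self.n_obs_ - 1.0) / denom if denom > 0 else np.nan
        )

        k = exog.shape[1]
        params = np.asarray(res.params)
        bse = np.asarray(res.bse)
        pvals = np.asarray(res.pvalues)
        z = 1.959963984540054
        self.coef_table_ = pd.DataFrame(
            {
                "term": names,
                "estimate": params[:k],
                "ci_lo": params[:k] - z * bse[:k],
                "ci_hi": params[:k] + z * bse[:k],
                "p": pvals[:k],
            }
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            p_mosq = float(np.squeeze(res.test_significance(0).pvalue))
            p_lat = float(np.squeeze(res.test_significance(1).pvalue))
            p_lon = float(np.squeeze(res.test_significance(2).pvalue))
        self.smooth_pvalues_ = {
            "mosquito": p_mosq,
            "lat": p_lat,
            "lon": p_lon,
            "space": min(1.0, 2.0 * min(p_lat, p_lon)),  # Bonferroni over axes
        }
        self._n_exog_ = k
        return self

    # ------------------------------------------------------------------
    def predict(self, X: pd.DataFrame) -> np.ndarray:
        df = X
        exog, _ = self._design(df)
        smooth_x = df[["mosquito", "lat", "lon"]].to_numpy(dtype=float)
        basis = self.smoother_.transform(smooth_x)
        params = np.asarray(self.result_.params)
        return exog @ params[: self._n_exog_] + basis @ params[self._n_exog_ :]

    def partial_mosquito(self, values: np.ndarray) -> np.ndarray:
        """Centered partial effect of the mosquito smooth at ``values``."""
        values = np.asarray(values, dtype=float)
        sm0 = self.smoother_.smoothers[0]
        basis = sm0.transform(values[:, None])
        params = np.asarray(self.result_.params)
        start = self._n_exog_
        stop = start + sm0.dim_basis
        eff = basis @ params[start:stop]
        return eff - eff.mean()


def fit_gam(records: pd.DataFrame, **kwargs) -> BatMosquitoGAM:
    """Fit the bat-activity GAM on a pixel-record table."""
    return BatMosquitoGAM(**kwargs).fit(records)


def summarize_fit(model: BatMosquitoGAM) -> tuple[str, dict]:
    """Human-readable table and JSON-serializable dict of a fitted GAM.

    Rows follow the conventional report order: intercept, linear
    controls, land-cover contrasts, then smooth-term p-values, with n,
    R² and the reference class stated explicitly.
    """
    rows = []
    for _, r in model.coef_table_.iterrows():
        rows.append(
            {
                "term": r["term"],
                "estimate": float(r["estimate"]),
                "ci_lo": float(r["ci_lo"]),
                "ci_hi": float(r["ci_hi"]),
                "p": float(r["p"]),
            }
        )
    doc = {
        "terms": rows,
        "smooth_terms": {
            "mosquito": model.smooth_pvalues_["mosquito"],
            "lat_lon": model.smooth_pvalues_["space"],
        },
        "n_observations": int(model.n_obs_),
        "r2": float(model.r2_),
        "r2_adjusted": float(model.r2_adj_),
        "reference_class": model.reference_class_,
    }
    lines = [
        f"{'Predictors':<30}{'Estimate':>12}{'CI':>24}{'p':>10}",
    ]
    for r in rows:
        ci = f"{r['ci_lo']:.2f} – {r['ci_hi']:.2f}"
        p = "< 0.001" if r["p"] < 0.001 else f"{r['p']:.3f}"
        lines.append(f"{r['term']:<30}{r['estimate']:>12.2f}{ci:>24}{p:>10}")
    for name, p in (
        ("Smooth term: mosquito abundance", doc["smooth_terms"]["mosquito"]),
        ("Smooth term: Lat./Long.", doc["smooth_terms"]["lat_lon"]),
    ):
        ps = "< 0.001" if p < 0.001 else f"{p:.3f}"
        lines.append(f"{name:<30}{'':>12}{'':>24}{ps:>10}")
    lines.append(f"Observations: {doc['n_observations']}")
    lines.append(f"R2 (adjusted): {doc['r2_adjusted']:.3f}   R2: {doc['r2']:.3f}")
    lines.append(f"Reference land-cover class: {doc['reference_class']}")
    return "\n".join(lines), doc


def write_report(doc: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
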