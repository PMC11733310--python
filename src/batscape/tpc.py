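"""Trait-based thermal model of relative mosquito abundance.

Mosquito life-history traits respond unimodally to temperature and are
commonly fit with two thermal-performance-curve (TPC) forms, both zero
outside their thermal limits [Tmin, Tmax]:

    Briere:     c * T * (T - Tmin) * sqrt(Tmax - T)
    quadratic:  c * (T - Tmin) * (Tmax - T)

Adult mortality is the reciprocal of a quadratic lifespan curve
("inverted-quadratic"). The relative abundance index composes four
traits — eggs per female per day (EFD), egg-to-adult survival (pEA),
mosquito development rate (MDR), and adult mortality mu:

    M(T) = EFD(T) * pEA(T) * MDR(T) / max(mu(T), floor)^2

M is unitless and only meaningful up to monotone rescaling; a mortality
floor (day^-1) keeps it finite where the lifespan curve collapses. The
shipped default parameters give Culex-tarsalis-style curves peaking in
the low-to-mid 20s deg C; any trait set honoring the structural
contract can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

FORMS = ("briere", "quadratic", "inverted-quadratic")
REQUIRED_TRAITS = ("EFD", "pEA", "MDR", "mu")


def briere(T, c: float, tmin: float, tmax: float):
    """Briere TPC: c*T*(T-Tmin)*sqrt(Tmax-T) on [Tmin, Tmax], else 0."""
    if tmin >= tmax:
        raise ValueError("Tmin must be < Tmax")
    T = np.asarray(T, dtype=float)
    inside = (T >= tmin) & (T <= tmax)
    out = np.zeros_like(T)
    Ti = T[inside]
    out[inside] = c * Ti * (Ti - tmin) * np.sqrt(tmax - Ti)
    return out if out.ndim else float(out)


def quadratic(T, c: float, tmin: float, tmax: float):
    """Concave quadratic TPC: c*(T-Tmin)*(Tmax-T) on [Tmin, Tmax], else 0."""
    if tmin >= tmax:
        raise ValueError("Tmin must be < Tmax")
    T = np.asarray(T, dtype=float)
    inside = (T >= tmin) & (T <= tmax)
    out = np.zeros_like(T)
    Ti = T[inside]
    out[inside] = c * (Ti - tmin) * (tmax - Ti)
    return out if out.ndim else float(out)


def inverted_quadratic(T, c: float, tmin: float, tmax: float):
    """Reciprocal of a quadratic lifespan: 1/(c*(T-Tmin)*(Tmax-T)).

    Used for mortality rates: infinite (instant death) outside the
    lifespan curve's support; the abundance floor caps the effect.
    """
    q = quadratic(T, c, tmin, tmax)
    q = np.asarray(q, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.where(q > 0, 1.0 / np.where(q > 0, q, 1.0), np.inf)
    return out if out.ndim else float(out)


_FORM_FUNCS = {
    "briere": briere,
    "quadratic": quadratic,
    "inverted-quadratic": inverted_quadratic,
}


@dataclass(frozen=True)
class TraitCurve:
    """One trait's thermal-performance curve."""

    name: str
    form: str
    c: float
    tmin: float
    tmax: float

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"form must be one of {FORMS}")
        if self.tmin >= self.tmax:
            raise ValueError("Tmin must be < Tmax")
        if self.c <= 0:
            raise ValueError("scale constant c must be > 0")

    def __call__(self, T):
        return _FORM_FUNCS[self.form](T, self.c, self.tmin, self.tmax)


@dataclass(frozen=True)
class AbundanceParams:
    """The trait set entering the abundance index, plus the mortality floor."""

    traits: dict[str, TraitCurve] = field(default_factory=dict)
    mu_floor: float = 0.01  # day^-1

    def __post_init__(self) -> None:
        missing = [t for t in REQUIRED_TRAITS if t not in self.traits]
        if missing:
            raise ValueError(f"missing required traits: {missing}")
        if self.mu_floor <= 0:
            raise ValueError("mortality floor must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AbundanceParams":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls._from_doc(doc)

    @classmethod
    def default(cls) -> "AbundanceParams":
        text = resources.files("batscape.data").joinpath("mosquito_traits.yaml").read_text()
        return cls._from_doc(yaml.safe_load(text))

    @classmethod
    def _from_doc(cls, doc: dict) -> "AbundanceParams":
        traits = {
            name: TraitCurve(
                name=name,
                form=entry["form"],
                c=float(entry["c"]),
                tmin=float(entry["tmin"]),
                tmax=float(entry["tmax"]),
            )
            for name, entry in doc["traits"].items()
        }
        return cls(traits=traits, mu_floor=float(doc.get("mu_floor", 0.01)))


def relative_abundance(T, params: AbundanceParams):
    """Unitless relative mosquito abundance M(T); 0 where any numerator
    trait is outside its thermal limits, NaN propagates."""
    T = np.asarray(T, dtype=float)
    efd = params.traits["EFD"](T)
    pea = params.traits["pEA"](T)
    mdr = params.traits["MDR"](T)
    mu = np.maximum(params.traits["mu"](T), params.mu_floor)
    with np.errstate(invalid="ignore"):
        m = efd * pea * mdr / mu**2
    m = np.asarray(m, dtype=float)
    m[np.isinf(np.asarray(mu))] = 0.0
    m[np.isnan(T)] = np.nan
    return m if m.ndim else float(m)


def abundance_raster(
    temperature_stack: np.ndarray, params: AbundanceParams
) -> np.ndarray:
    """Seasonal mean of M(T_t) per pixel over a (time, row, col) stack.

    A pixel missing (NaN) at any time step is missing in the output —
    a partial-season mean would not be comparable across pixels.
    """
    stack = np.asarray(temperature_stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("temperature stack must be a non-empty (time, row, col) array")
    m = relative_abundance(stack, params)
    return m.mean(axis=0)


class MosquitoAbundanceModel(BaseEstimator, TransformerMixin):
    """Transformer from a seasonal temperature stack to a relative
    mosquito-abundance surface (the flying-insect prey proxy)."""

    def __init__(self, params: AbundanceParams | None = None):
        self.params = params

    def _resolved(self) -> AbundanceParams:
        return self.params if self.params is not None else AbundanceParams.default()

    def fit(self, X: np.ndarray, y=None) -> "MosquitoAbundanceModel":
        self.params_ = self._resolved()
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        self.fit(X)
        self.abundance_ = abundance_raster(X, self.params_)
        return self.abundance_

    def curve(self, T) -> np.ndarray:
        """Evaluate M(T) on arbitrary temperatures (for inspection/plots)."""
        return relative_abundance(T, self._resolved())
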