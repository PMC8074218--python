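"""Release-kinetics fitting for dissolution time series.

A release experiment samples an aliquot (default 1 mL) from a stirred
vessel (default 50 mL) at each time point and replaces it with fresh
medium, so each later measurement is diluted by what earlier draws removed.
The standard replaced-aliquot correction restores the cumulative released
amount:

    Qt_i = C_i + (v/V) * sum_{j<i} C_j

with C the measured concentrations, v the aliquot volume and V the vessel
volume.

Four classical models are fitted on their linearized forms, exactly as
dissolution studies report them (a straight line y = a x + b with R^2):

* zero order      Qt = Q0 + k0 * t            (Qt vs t)
* first order     log10 Qt = log10 Q0 - k1 t  (log10 Qt vs t)
* Higuchi         Qt = Q0 + kH * sqrt(t)      (Qt vs sqrt t)
* Korsmeyer–Peppas  Qt = kKP * t**n           (log Qt vs log t)

The Korsmeyer–Peppas release exponent n classifies the transport mechanism
for spherical particles: n <= 0.43 Fickian diffusion, 0.43 < n < 0.85
anomalous (non-Fickian), n ~ 0.85 Case II, n > 0.85 Super Case II.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MODELS",
    "ReleaseSeries",
    "KineticFit",
    "volume_correction",
    "fit_model",
    "select_model",
    "classify_transport",
]

MODELS = ("zero-order", "first-order", "higuchi", "korsmeyer-peppas")

#: parameters per model, used for tie-breaking in the R^2 ranking
_N_PARAMS = {"zero-order": 2, "first-order": 2, "higuchi": 2, "korsmeyer-peppas": 2}

# slope-exponent thresholds for spherical geometry
_SPHERE_FICKIAN = 0.43
_SPHERE_CASE_II = 0.85


@dataclass
class ReleaseSeries:
    """A timed-draw release series with its volume bookkeeping.

    ``concentrations`` are the raw per-draw measurements; the corrected
    cumulative release is computed lazily via :meth:`cumulative`.
    """

    times_h: np.ndarray
    concentrations: np.ndarray
    sample: str = ""
    medium: str = ""
    ph: float | None = None
    aliquot_ml: float = 1.0
    vessel_ml: float = 50.0

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times_h.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must have equal length")
        if np.any(self.times_h <= 0) or np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing and positive")
        if not 0 <= self.aliquot_ml < self.vessel_ml:
            raise ValueError("aliquot volume must satisfy 0 <= v < V")

    def cumulative(self) -> np.ndarray:
        return volume_correction(
            self.concentrations, self.aliquot_ml, self.vessel_ml
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample,
                "medium": self.medium,
                "ph": self.ph,
                "time_h": self.times_h,
                "concentration": self.concentrations,
                "cumulative": self.cumulative(),
            }
        )


@dataclass
class KineticFit:
    """One linearized model fit: slope/intercept on the model's axes."""

    model: str
    slope: float
    intercept: float
    r2: float
    params: dict[str, float] = field(default_factory=dict)
    n_points: int = 0
    best: bool = False
    transport: str | None = None
    status: str = "ok"


def volume_correction(concentrations, aliquot_ml: float = 1.0,
                      vessel_ml: float = 50.0) -> np.ndarray:
    """Replaced-aliquot cumulative correction.

    ``Qt_i = C_i + (v/V) * sum_{j<i} C_j`` — each measured concentration is
    topped up by the fraction of previously withdrawn analyte.
    """
    C = np.asarray(concentrations, dtype=float)
    if np.any(C < 0):
        raise ValueError("concentrations must be non-negative")
    if not 0 <= aliquot_ml < vessel_ml:
        raise ValueError("aliquot volume must satisfy 0 <= v < V")
    ratio = aliquot_ml / vessel_ml
    prior = np.concatenate([[0.0], np.cumsum(C)[:-1]])
    return C + ratio * prior


def _linefit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    res = stats.linregress(x, y)
    # linregress rvalue is 0 for a flat response; define R^2 = 1 when the
    # residuals are exactly zero (perfect constant fit)
    resid = y - (res.slope * x + res.intercept)
    if np.allclose(resid, 0.0, atol=1e-12 * max(1.0, float(np.abs(y).max()))):
        r2 = 1.0
    else:
        r2 = float(res.rvalue**2)
    return float(res.slope), float(res.intercept), r2


def fit_model(
    series: ReleaseSeries,
    model: str,
    fix_q0_zero: bool = False,
    max_release_fraction: float | None = None,
) -> KineticFit:
    """Fit one kinetic model on its linearized axes by least squares.

    ``fix_q0_zero`` constrains the zero-order/Higuchi intercept to 0
    (regression through the origin). ``max_release_fraction`` optionally
    restricts the Korsmeyer–Peppas fit to the early part of the curve
    (e.g. 0.6 for the common first-60%-of-release rule); by default all
    points are used. Points with non-positive Qt are rejected for log
    models, with a warning; fewer than 3 usable points is an error.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    t = series.times_h
    Qt = series.cumulative()
    if t.size < 3:
        raise ValueError("need at least 3 time points")

    mask = np.ones(t.size, dtype=bool)
    if model in ("first-order", "korsmeyer-peppas"):
        bad = Qt <= 0
        if bad.any():
            warnings.warn(
                f"{model}: rejecting {int(bad.sum())} non-positive Qt point(s)",
                stacklevel=2,
            )
            mask &= ~bad
    if model == "korsmeyer-peppas" and max_release_fraction is not None:
        qmax = Qt[mask].max()
        mask &= Qt <= max_release_fraction * qmax
    if mask.sum() < 3:
        raise ValueError(f"{model}: fewer than 3 usable points remain")
    tm, qm = t[mask], Qt[mask]

    status = "ok"
    if model == "zero-order":
        x, y = tm, qm
    elif model == "higuchi":
        x, y = np.sqrt(tm), qm
    elif model == "first-order":
        x, y = tm, np.log10(qm)
    else:  # korsmeyer-peppas
        x, y = np.log10(tm), np.log10(qm)
        if np.allclose(qm, qm[0]):
            status = "degenerate: constant release, exponent undefined"
            warnings.warn("korsmeyer-peppas: " + status, stacklevel=2)

    if fix_q0_zero and model in ("zero-order", "higuchi"):
        slope = float(x @ y / (x @ x))
        intercept = 0.0
        resid = y - slope * x
        sst = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 1.0
    else:
        slope, intercept, r2 = _linefit(x, y)

    if model == "zero-order":
        params = {"k0": slope, "Q0": intercept}
    elif model == "higuchi":
        params = {"kH": slope, "Q0": intercept}
    elif model == "first-order":
        # printed form log10 Qt = log10 Q0 - k1 t: k1 is minus the slope
        params = {"k1": -slope, "Q0": 10.0**intercept}
    else:
        params = {"n": slope, "kKP": 10.0**intercept}

    fit = KineticFit(
        model=model,
        slope=slope,
        intercept=intercept,
        r2=r2,
        params=params,
        n_points=int(mask.sum()),
        status=status,
    )
    if model == "korsmeyer-peppas" and status == "ok" and slope > 0:
        fit.transport = classify_transport(slope)
    return fit


def select_model(
    series: ReleaseSeries,
    models: Sequence[str] = MODELS,
    fix_q0_zero: bool = False,
) -> list[KineticFit]:
    """Fit all candidate models and rank them by R^2 (descending).

    Ties are broken by fewer parameters, then by the fixed model order of
    ``MODELS``. Models that cannot be fitted (e.g. all-zero release under a
    log model) are ranked last with a status note. The winner has
    ``best=True``.
    """
    fits: list[KineticFit] = []
    for m in models:
        try:
            fits.append(fit_model(series, m, fix_q0_zero=fix_q0_zero))
        except ValueError as exc:
            fits.append(
                KineticFit(
                    model=m, slope=np.nan, intercept=np.nan, r2=-np.inf,
                    status=f"unfittable: {exc}",
                )
            )
    order = {m: i for i, m in enumerate(MODELS)}
    fits.sort(key=lambda f: (-f.r2, _N_PARAMS.get(f.model, 2), order[f.model]))
    for f in fits:
        f.best = False
    fits[0].best = True
    return fits


def classify_transport(n: float, geometry: str = "sphere",
                       case_ii_tol: float = 0.01) -> str:
    """Transport-mechanism class from the release exponent n.

    Thresholds are for spherical particles: n <= 0.43 Fickian diffusion,
    0.43 < n < 0.85 anomalous (non-Fickian) transport, n within
    ``case_ii_tol`` of 0.85 Case II (relaxation-controlled), larger Super
    Case II.
    """
    if geometry != "sphere":
        raise NotImplementedError("only spherical geometry thresholds are provided")
    if not n > 0:
        raise ValueError(f"release exponent must be positive, got {n}")
    if abs(n - _SPHERE_CASE_II) <= case_ii_tol:
        return "Case II transport"
    if n <= _SPHERE_FICKIAN:
        return "Fickian diffusion"
    if n < _SPHERE_CASE_II:
        return "anomalous (non-Fickian) transport"
    return "Super Case II transport"
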