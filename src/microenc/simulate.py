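"""Bundled study data and synthetic-data generators.

Two kinds of inputs drive the pipeline:

* the bundled quebracho-tannin microencapsulation dataset — a 13-run,
  two-factor central composite design (core:shell and maltodextrin:gum
  arabic ratios) with per-run response means and standard deviations;
* synthetic datasets with the statistical structure the analysis assumes:
  quadratic response surfaces with additive Gaussian noise at CCD design
  points, and release curves generated from each kinetic law with
  multiplicative Gaussian noise on the drawn concentrations.

All simulators are pure functions of their spec: the same spec (including
seed) yields byte-identical output.

The bundled response table keeps the values exactly as printed in the
study report, including one internally inconsistent cell: the run-7
encapsulation yield is tabulated as 39.75% but the report's text gives
29.75% for that formulation, and only the text value is consistent with
the published regression coefficients. ``quebracho_study`` exposes both;
``correct_run7_ey=True`` applies the text value.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .design import DesignSpec, DesignTable, FactorSpec
from .kinetics import MODELS, ReleaseSeries
from .rsm import quadratic_model_matrix, quadratic_terms

__all__ = [
    "QUEBRACHO_FACTORS",
    "quebracho_design_spec",
    "quebracho_study",
    "RUN7_EY_PRINTED",
    "RUN7_EY_TEXT",
    "SurfaceSimSpec",
    "simulate_surface",
    "ReleaseSimSpec",
    "simulate_release",
    "invert_volume_correction",
]

#: factor parameterization of the bundled study: each two-component ratio
#: (a:b with a+b effectively fixed) is represented by its first coordinate.
QUEBRACHO_FACTORS = (
    FactorSpec(
        name="core_shell",
        center=1.0,
        step=0.5,
        unit="core (quebracho extract) mass, shell fixed at 5",
    ),
    FactorSpec(
        name="md_ga",
        center=2.5,
        step=0.5,
        unit="maltodextrin mass, maltodextrin + gum arabic = 5",
    ),
)

RUN7_EY_PRINTED = 39.75
RUN7_EY_TEXT = 29.75


def quebracho_design_spec() -> DesignSpec:
    """DesignSpec matching the bundled 13-run rotatable CCD."""
    return DesignSpec(factors=QUEBRACHO_FACTORS, n_center=5, alpha="rotatable")


def _load_csv(name: str) -> pd.DataFrame:
    with resources.files("microenc.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def quebracho_study(correct_run7_ey: bool = False) -> tuple[DesignTable, pd.DataFrame]:
    """The bundled 13-run design and response table.

    Returns the design (coded and actual factor settings, with the axial
    maltodextrin:gum-arabic actuals stored exactly as published even though
    they disagree with the coded +/-1.414 — see ``validate_design``) and
    the response table with per-run means, standard deviations and
    passthrough quality columns (moisture, water activity, CIELAB color).

    With ``correct_run7_ey=True`` the run-7 encapsulation yield is replaced
    by the report-text value 29.75; the substitution is recorded in the
    frame's ``attrs["run7_ey_corrected"]``.
    """
    design = DesignTable(
        frame=_load_csv("quebracho_ccd_design.csv"),
        factor_names=tuple(f.name for f in QUEBRACHO_FACTORS),
    )
    responses = _load_csv("quebracho_responses.csv")
    responses.attrs["run7_ey_corrected"] = bool(correct_run7_ey)
    if correct_run7_ey:
        responses.loc[responses["run_id"] == 7, "ey"] = RUN7_EY_TEXT
    return design, responses


@dataclass(frozen=True)
class SurfaceSimSpec:
    """Quadratic-surface generator: y = full quadratic in coded x + noise.

    ``beta`` lists coefficients in canonical term order (intercept,
    linear..., interactions..., squares...). ``sigma`` is the additive
    Gaussian noise SD; ``n_replicates`` repeats every design point with
    independent noise.
    """

    beta: tuple[float, ...]
    design: DesignSpec
    sigma: float = 0.0
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", tuple(float(b) for b in self.beta))
        expected = len(quadratic_terms(self.design.factor_names))
        if len(self.beta) != expected:
            raise ValueError(
                f"beta has {len(self.beta)} entries, full quadratic for "
                f"k={self.design.k} needs {expected}"
            )
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def simulate_surface(spec: SurfaceSimSpec, design: DesignTable) -> pd.DataFrame:
    """Simulate a response column over a design table.

    Returns a frame with ``run_id``, ``replicate``, the coded columns and
    ``y``. Replicates share the design point and differ only in noise.
    """
    rng = np.random.default_rng(spec.seed)
    coded = design.coded
    mean = quadratic_model_matrix(coded) @ np.asarray(spec.beta)
    frames = []
    for rep in range(1, spec.n_replicates + 1):
        y = mean + rng.normal(0.0, spec.sigma, size=mean.size) if spec.sigma > 0 else mean.copy()
        f = pd.DataFrame({"run_id": design.frame["run_id"], "replicate": rep, "y": y})
        frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    for i, name in enumerate(design.factor_names):
        out[f"coded_{name}"] = np.tile(coded[:, i], spec.n_replicates)
    return out


@dataclass(frozen=True)
class ReleaseSimSpec:
    """Release-curve generator for one kinetic law.

    ``params`` supplies the law's constants: zero-order ``{"k0", "Q0"}``,
    first-order ``{"k1", "Q0"}`` (log10 Qt = log10 Q0 - k1 t), Higuchi
    ``{"kH", "Q0"}``, Korsmeyer–Peppas ``{"kKP", "n"}``. Noise is
    multiplicative Gaussian on the per-draw concentrations with fractional
    SD ``sigma``. Default time grid follows the standard in-vitro sampling
    scheme (draws at 0.5, 1, 2, 4, 8 and 24 h).
    """

    model: str
    params: dict[str, float]
    times_h: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0, 24.0)
    sigma: float = 0.0
    aliquot_ml: float = 1.0
    vessel_ml: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODELS}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        t = np.asarray(self.times_h, dtype=float)
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing and positive")
        object.__setattr__(self, "params", dict(self.params))


def _true_release(spec: ReleaseSimSpec) -> np.ndarray:
    t = np.asarray(spec.times_h, dtype=float)
    p = spec.params
    if spec.model == "zero-order":
        return p.get("Q0", 0.0) + p["k0"] * t
    if spec.model == "higuchi":
        return p.get("Q0", 0.0) + p["kH"] * np.sqrt(t)
    if spec.model == "first-order":
        return p["Q0"] * 10.0 ** (-p["k1"] * t)
    return p["kKP"] * t ** p["n"]


def invert_volume_correction(Qt, aliquot_ml: float = 1.0,
                             vessel_ml: float = 50.0) -> np.ndarray:
    """Per-draw concentrations whose replaced-aliquot correction is Qt.

    Exact inverse of :func:`microenc.kinetics.volume_correction`:
    ``C_i = Qt_i - (v/V) * sum_{j<i} C_j``, computed recursively.
    """
    Qt = np.asarray(Qt, dtype=float)
    ratio = aliquot_ml / vessel_ml
    C = np.empty_like(Qt)
    acc = 0.0
    for i, q in enumerate(Qt):
        C[i] = q - ratio * acc
        acc += C[i]
    return C


def simulate_release(spec: ReleaseSimSpec) -> ReleaseSeries:
    """Generate a seeded noisy release series from one kinetic law.

    The true cumulative curve is converted to per-draw concentrations (the
    inverse of the volume correction), multiplicative Gaussian noise is
    applied to each draw, and the result is packaged as a
    :class:`ReleaseSeries`; applying ``cumulative()`` recovers the noisy
    released amounts.
    """
    Qt_true = _true_release(spec)
    C_true = invert_volume_correction(Qt_true, spec.aliquot_ml, spec.vessel_ml)
    if np.any(C_true < 0):
        raise ValueError(
            f"{spec.model} parameters {spec.params} imply negative draw "
            "concentrations (release must not decrease faster than the "
            "dilution can explain)"
        )
    rng = np.random.default_rng(spec.seed)
    if spec.sigma > 0:
        C = C_true * (1.0 + rng.normal(0.0, spec.sigma, size=C_true.size))
        C = np.clip(C, 0.0, None)
    else:
        C = C_true.copy()
    return ReleaseSeries(
        times_h=np.asarray(spec.times_h, dtype=float),
        concentrations=C,
        sample=f"synthetic:{spec.model}",
        aliquot_ml=spec.aliquot_ml,
        vessel_ml=spec.vessel_ml,
    )
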