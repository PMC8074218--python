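"""Central composite designs (CCD) on coded factors.

A CCD for ``k`` factors is the union of a two-level full factorial (all
coded coordinates at +/-1), ``2k`` axial ("star") points at distance
``alpha`` along one axis, and ``n_center`` replicated center points. It is
the standard design for fitting a full second-order polynomial because it
supports estimation of all linear, interaction and pure-quadratic terms
while the replicated center points supply a pure-error estimate.

Coded and actual factor scales are linked by ``actual = center + step * coded``.
Two-component mixture ratios (a:b with a+b fixed) are parameterized by their
first coordinate; the ratio is rendered for display only.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignSpec",
    "DesignTable",
    "DesignValidationError",
    "generate_ccd",
    "rotatable_alpha",
    "code_to_actual",
    "actual_to_code",
    "validate_design",
    "ValidationReport",
]

POINT_CLASSES = ("factorial", "axial", "center")


class DesignValidationError(ValueError):
    """Raised when a factor or design specification is inconsistent."""


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor on a coded scale.

    Parameters
    ----------
    name:
        Label used for the coded/actual columns (``coded_<name>``,
        ``actual_<name>``).
    center:
        Actual value at coded 0.
    step:
        Actual increment per coded unit; must be positive.
    unit:
        Free-text unit or convention note, e.g. ``"core mass, shell fixed
        at 5"`` for a core:shell ratio parameterized by its numerator.
    """

    name: str
    center: float
    step: float
    unit: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.center):
            raise DesignValidationError(f"factor {self.name!r}: center must be finite")
        if not (self.step > 0 and math.isfinite(self.step)):
            raise DesignValidationError(
                f"factor {self.name!r}: step must be positive, got {self.step}"
            )


@dataclass(frozen=True)
class DesignSpec:
    """A central composite design specification.

    ``alpha`` is either a positive axial distance or the string
    ``"rotatable"``, meaning ``2**(k/4)`` — the distance that makes the
    prediction variance constant on spheres around the center.
    """

    factors: tuple[FactorSpec, ...]
    n_center: int = 5
    alpha: float | str = "rotatable"

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))
        if self.k < 2:
            raise DesignValidationError("a CCD needs at least 2 factors")
        if self.n_center < 1:
            raise DesignValidationError("n_center must be >= 1")
        if not isinstance(self.alpha, str) and not self.alpha > 0:
            raise DesignValidationError(f"alpha must be positive, got {self.alpha}")
        if isinstance(self.alpha, str) and self.alpha != "rotatable":
            raise DesignValidationError(f"unknown alpha rule {self.alpha!r}")

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def alpha_value(self) -> float:
        if self.alpha == "rotatable":
            return rotatable_alpha(self.k)
        return float(self.alpha)

    @property
    def n_runs(self) -> int:
        return 2**self.k + 2 * self.k + self.n_center

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)


def rotatable_alpha(k: int) -> float:
    """Axial distance ``2**(k/4)`` giving a rotatable CCD for k factors."""
    return 2.0 ** (k / 4.0)


@dataclass
class DesignTable:
    """An ordered run table with coded and actual factor settings.

    Wraps a DataFrame with columns ``run_id``, ``point_class``,
    ``coded_<factor>...`` and ``actual_<factor>...``.
    """

    frame: pd.DataFrame
    factor_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.factor_names = tuple(self.factor_names)
        missing = [
            c
            for name in self.factor_names
            for c in (f"coded_{name}", f"actual_{name}")
            if c not in self.frame.columns
        ]
        if missing:
            raise DesignValidationError(f"design table missing columns: {missing}")

    @property
    def k(self) -> int:
        return len(self.factor_names)

    @property
    def n_runs(self) -> int:
        return len(self.frame)

    @property
    def coded(self) -> np.ndarray:
        """(n_runs, k) array of coded coordinates."""
        return self.frame[[f"coded_{n}" for n in self.factor_names]].to_numpy(float)

    @property
    def actual(self) -> np.ndarray:
        return self.frame[[f"actual_{n}" for n in self.factor_names]].to_numpy(float)

    @property
    def point_class(self) -> pd.Series:
        return self.frame["point_class"]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DesignTable":
        frame = pd.read_csv(path)
        names = tuple(
            c[len("coded_") :] for c in frame.columns if c.startswith("coded_")
        )
        return cls(frame=frame, factor_names=names)


def generate_ccd(spec: DesignSpec) -> DesignTable:
    """Construct the CCD run table for *spec*.

    Runs are ordered factorial, axial, center, with run_id 1..n. Coded and
    actual settings are both populated; actual values follow
    ``center + step * coded`` exactly.
    """
    k = spec.k
    alpha = spec.alpha_value
    rows: list[tuple[str, np.ndarray]] = []
    for combo in itertools.product((-1.0, 1.0), repeat=k):
        rows.append(("factorial", np.array(combo)))
    for axis in range(k):
        for sign in (-1.0, 1.0):
            pt = np.zeros(k)
            pt[axis] = sign * alpha
            rows.append(("axial", pt))
    for _ in range(spec.n_center):
        rows.append(("center", np.zeros(k)))

    records = []
    for run_id, (cls_, coded) in enumerate(rows, start=1):
        rec: dict[str, object] = {"run_id": run_id, "point_class": cls_}
        actual = code_to_actual(spec, coded)
        for f, c, a in zip(spec.factors, coded, actual):
            rec[f"coded_{f.name}"] = c
            rec[f"actual_{f.name}"] = a
        records.append(rec)
    return DesignTable(frame=pd.DataFrame.from_records(records), factor_names=spec.factor_names)


def code_to_actual(spec: DesignSpec, coded_point: Sequence[float]) -> np.ndarray:
    """Map a coded point to actual factor values, ``center + step * coded``."""
    coded = np.asarray(coded_point, dtype=float)
    if coded.shape != (spec.k,):
        raise DesignValidationError(
            f"coded point has length {coded.size}, expected {spec.k}"
        )
    centers = np.array([f.center for f in spec.factors])
    steps = np.array([f.step for f in spec.factors])
    return centers + steps * coded


def actual_to_code(spec: DesignSpec, actual_point: Sequence[float]) -> np.ndarray:
    """Inverse of :func:`code_to_actual`: ``(actual - center) / step``."""
    actual = np.asarray(actual_point, dtype=float)
    if actual.shape != (spec.k,):
        raise DesignValidationError(
            f"actual point has length {actual.size}, expected {spec.k}"
        )
    centers = np.array([f.center for f in spec.factors])
    steps = np.array([f.step for f in spec.factors])
    return (actual - centers) / steps


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_design`.

    ``violations`` lists human-readable descriptions of failed invariants;
    ``orthogonality`` maps column-pair labels to their inner products.
    """

    violations: list[str] = field(default_factory=list)
    orthogonality: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_design(
    table: DesignTable,
    spec: DesignSpec | None = None,
    tol: float = 1e-9,
) -> ValidationReport:
    """Check the structural invariants of a CCD run table.

    Checks column balance (each coded column sums to 0), mutual
    orthogonality of the coded columns and of each column with the pairwise
    interaction columns, duplicated non-center runs, and — when *spec* is
    given — run count and the coded/actual mapping ``actual = center +
    step * coded`` (within the table's printed precision).
    Violations are reported, never raised.
    """
    report = ValidationReport()
    X = table.coded
    names = table.factor_names
    k = table.k

    for j, name in enumerate(names):
        s = float(X[:, j].sum())
        report.orthogonality[f"sum({name})"] = s
        if abs(s) > tol:
            report.violations.append(f"coded column {name} sums to {s:.3g}, not 0")
    for i, j in itertools.combinations(range(k), 2):
        ip = float(X[:, i] @ X[:, j])
        report.orthogonality[f"{names[i]}*{names[j]}"] = ip
        if abs(ip) > tol:
            report.violations.append(
                f"coded columns {names[i]} and {names[j]} not orthogonal "
                f"(inner product {ip:.3g})"
            )
        inter = X[:, i] * X[:, j]
        for m in range(k):
            ip3 = float(X[:, m] @ inter)
            report.orthogonality[f"{names[m]}*({names[i]}{names[j]})"] = ip3
            if abs(ip3) > tol:
                report.violations.append(
                    f"column {names[m]} not orthogonal to interaction "
                    f"{names[i]}*{names[j]} (inner product {ip3:.3g})"
                )

    noncenter = table.frame[table.frame["point_class"] != "center"]
    coded_cols = [f"coded_{n}" for n in names]
    dup = noncenter.duplicated(subset=coded_cols, keep=False)
    if dup.any():
        ids = noncenter.loc[dup, "run_id"].tolist()
        report.violations.append(f"duplicated non-center runs: {ids}")

    if spec is not None:
        if table.n_runs != spec.n_runs:
            report.violations.append(
                f"run count {table.n_runs} != 2^k + 2k + n_center = {spec.n_runs}"
            )
        expect = np.array([code_to_actual(spec, row) for row in X])
        # printed fixtures round actuals to ~2 decimals; allow that much slack
        mismatch = np.abs(expect - table.actual) > 5e-3 + 1e-6 * np.abs(expect)
        for i in range(table.n_runs):
            for j in range(k):
                if mismatch[i, j]:
                    report.violations.append(
                        f"run {table.frame['run_id'].iat[i]}: actual_{names[j]} "
                        f"{table.actual[i, j]:g} inconsistent with coded "
                        f"{X[i, j]:g} (expected {expect[i, j]:g})"
                    )
    return report
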