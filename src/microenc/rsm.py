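"""Second-order response-surface fits on coded factors.

The response surface model is the full quadratic polynomial

    y = b0 + sum_i b_i x_i + sum_{i<j} b_ij x_i x_j + sum_i b_ii x_i^2

fitted by ordinary least squares on the coded design coordinates. The fit
report carries coefficient standard errors, two-sided t-test p-values with
the residual degrees of freedom, significance marks, R^2 / adjusted R^2,
and an ANOVA that splits the residual sum of squares into lack-of-fit and
pure error. Pure error comes from replicated design points (in a CCD, the
center replicates); a non-significant lack-of-fit F test is the standard
evidence that the quadratic surface is adequate.

The full model is always reported; non-significant terms are marked, never
dropped.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .design import DesignTable

__all__ = [
    "QuadraticFit",
    "AnovaTable",
    "quadratic_terms",
    "quadratic_model_matrix",
    "fit_quadratic",
    "lack_of_fit_anova",
    "predict",
    "significance_marks",
    "surface_grid",
]


def quadratic_terms(factor_names: Sequence[str]) -> list[str]:
    """Term labels of the full quadratic model, in canonical order.

    Intercept, linear terms, pairwise interactions, pure quadratics — for
    two factors: ``1, x1, x2, x1:x2, x1^2, x2^2``.
    """
    names = list(factor_names)
    terms = ["Intercept"] + names
    terms += [f"{a}:{b}" for a, b in itertools.combinations(names, 2)]
    terms += [f"{n}^2" for n in names]
    return terms


def quadratic_model_matrix(coded: np.ndarray) -> np.ndarray:
    """Model matrix of the full quadratic for (n, k) coded coordinates."""
    X = np.asarray(coded, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    n, k = X.shape
    cols = [np.ones(n)]
    cols += [X[:, i] for i in range(k)]
    cols += [X[:, i] * X[:, j] for i, j in itertools.combinations(range(k), 2)]
    cols += [X[:, i] ** 2 for i in range(k)]
    return np.column_stack(cols)


def significance_marks(p_values) -> list[str]:
    """Conventional significance stars: * p<0.05, ** p<0.01, *** p<0.001."""
    marks = []
    for p in np.atleast_1d(np.asarray(p_values, dtype=float)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")
        if p < 0.001:
            marks.append("***")
        elif p < 0.01:
            marks.append("**")
        elif p < 0.05:
            marks.append("*")
        else:
            marks.append("")
    return marks


@dataclass
class AnovaTable:
    """Model / residual / lack-of-fit / pure-error decomposition.

    ``rows`` maps each source to (sum of squares, degrees of freedom,
    mean square). ``SS_residual = SS_lack_of_fit + SS_pure_error`` holds
    exactly by construction.
    """

    rows: dict[str, tuple[float, int, float]]
    f_model: float
    p_model: float
    f_lack_of_fit: float | None
    p_lack_of_fit: float | None
    status: str = "ok"

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for source, (ss, df, ms) in self.rows.items():
            f = p = np.nan
            if source == "model":
                f, p = self.f_model, self.p_model
            elif source == "lack_of_fit" and self.f_lack_of_fit is not None:
                f, p = self.f_lack_of_fit, self.p_lack_of_fit
            recs.append(
                {"source": source, "ss": ss, "df": df, "ms": ms, "F": f, "p": p}
            )
        return pd.DataFrame.from_records(recs)


@dataclass
class QuadraticFit:
    """A fitted full quadratic response surface on coded factors."""

    response_name: str
    factor_names: tuple[str, ...]
    terms: list[str]
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    marks: list[str]
    r2: float
    r2_adj: float
    nobs: int
    df_resid: int
    anova: AnovaTable | None = None
    residuals: np.ndarray = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return len(self.factor_names)

    def coef(self, term: str) -> float:
        return float(self.params[self.terms.index(term)])

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "coef": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
                "mark": self.marks,
            }
        )

    def to_dict(self) -> dict:
        d = {
            "response": self.response_name,
            "factors": list(self.factor_names),
            "coefficients": {t: float(c) for t, c in zip(self.terms, self.params)},
            "standard_errors": {t: float(s) for t, s in zip(self.terms, self.bse)},
            "p_values": {t: float(p) for t, p in zip(self.terms, self.pvalues)},
            "marks": dict(zip(self.terms, self.marks)),
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "nobs": self.nobs,
        }
        if self.anova is not None:
            d["anova"] = {
                "rows": {
                    s: {"ss": ss, "df": df, "ms": ms}
                    for s, (ss, df, ms) in self.anova.rows.items()
                },
                "f_model": self.anova.f_model,
                "p_model": self.anova.p_model,
                "f_lack_of_fit": self.anova.f_lack_of_fit,
                "p_lack_of_fit": self.anova.p_lack_of_fit,
                "status": self.anova.status,
            }
        return d


def _aliased_terms(M: np.ndarray, terms: list[str]) -> list[str]:
    # columns not adding rank, identified by pivoted QR
    from scipy.linalg import qr

    _, r, piv = qr(M, pivoting=True, mode="economic")
    rank = np.sum(np.abs(np.diag(r)) > 1e-10 * abs(r[0, 0]))
    return [terms[i] for i in sorted(piv[rank:])]


def fit_quadratic(
    design: DesignTable, y: Sequence[float], response_name: str = "y"
) -> QuadraticFit:
    """Fit the full second-order polynomial to a response by OLS.

    Coefficients are reported on the coded scale. Inference (standard
    errors, t statistics, two-sided p-values) uses the residual degrees of
    freedom ``N - p``. When the design contains replicated points a
    lack-of-fit ANOVA is attached; otherwise ``fit.anova`` records the
    model ANOVA with lack-of-fit unavailable.
    """
    yv = np.asarray(y, dtype=float)
    coded = design.coded
    n, k = coded.shape
    if yv.shape != (n,):
        raise ValueError(f"response has length {yv.size}, design has {n} runs")
    terms = quadratic_terms(design.factor_names)
    p = len(terms)
    if n < p:
        raise ValueError(f"need at least {p} runs to fit {p} terms, got {n}")
    for j, name in enumerate(design.factor_names):
        if np.unique(coded[:, j]).size < 2:
            raise ValueError(f"factor {name} has fewer than 2 distinct levels")

    M = quadratic_model_matrix(coded)
    if np.linalg.matrix_rank(M) < p:
        raise np.linalg.LinAlgError(
            "model matrix is rank deficient; aliased terms: "
            + ", ".join(_aliased_terms(M, terms))
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        res = sm.OLS(yv, M).fit()
        r2, r2_adj = float(res.rsquared), float(res.rsquared_adj)
    if not np.isfinite(r2):  # constant response: zero total variance
        r2 = 1.0 if np.allclose(res.resid, 0.0, atol=1e-10) else 0.0
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
    fit = QuadraticFit(
        response_name=response_name,
        factor_names=design.factor_names,
        terms=terms,
        params=np.asarray(res.params),
        bse=np.asarray(res.bse),
        tvalues=np.asarray(res.tvalues),
        pvalues=np.asarray(res.pvalues),
        marks=significance_marks(np.nan_to_num(res.pvalues, nan=1.0)),
        r2=r2,
        r2_adj=r2_adj,
        nobs=n,
        df_resid=int(res.df_resid),
        residuals=np.asarray(res.resid),
    )
    fit.anova = lack_of_fit_anova(fit, design, yv)
    return fit


def lack_of_fit_anova(
    fit: QuadraticFit, design: DesignTable, y: Sequence[float]
) -> AnovaTable:
    """Split residual variation into lack-of-fit and pure error.

    Pure error is the within-group sum of squares over replicated design
    points (runs with identical coded coordinates), with ``N - n_distinct``
    degrees of freedom; lack-of-fit takes the remainder with
    ``n_distinct - p`` degrees of freedom and is tested against pure error
    by an F ratio. Without replicates the decomposition is unavailable and
    the table says so.
    """
    yv = np.asarray(y, dtype=float)
    coded = design.coded
    n = len(yv)
    p = len(fit.terms)

    yhat_mean = float(np.mean(yv))
    ss_total = float(np.sum((yv - yhat_mean) ** 2))
    ss_resid = float(np.sum(fit.residuals**2))
    ss_model = ss_total - ss_resid
    df_model, df_resid = p - 1, n - p
    ms_model = ss_model / df_model
    ms_resid = ss_resid / df_resid if df_resid > 0 else np.nan
    f_model = ms_model / ms_resid if df_resid > 0 else np.nan
    p_model = float(stats.f.sf(f_model, df_model, df_resid)) if df_resid > 0 else np.nan

    # replicate groups: identical coded rows
    keys = [tuple(np.round(row, 10)) for row in coded]
    groups: dict[tuple, list[int]] = {}
    for i, key in enumerate(keys):
        groups.setdefault(key, []).append(i)
    n_distinct = len(groups)
    ss_pe = sum(
        float(np.sum((yv[idx] - np.mean(yv[idx])) ** 2))
        for idx in (np.array(g) for g in groups.values())
        if len(idx) > 1
    )
    df_pe = n - n_distinct

    rows = {
        "model": (ss_model, df_model, ms_model),
        "residual": (ss_resid, df_resid, ms_resid),
    }
    if df_pe < 1:
        rows["lack_of_fit"] = (np.nan, 0, np.nan)
        rows["pure_error"] = (np.nan, 0, np.nan)
        return AnovaTable(
            rows=rows,
            f_model=f_model,
            p_model=p_model,
            f_lack_of_fit=None,
            p_lack_of_fit=None,
            status="lack-of-fit unavailable: no replicated design points",
        )

    ss_lof = ss_resid - ss_pe
    df_lof = n_distinct - p
    ms_pe = ss_pe / df_pe
    ms_lof = ss_lof / df_lof if df_lof > 0 else np.nan
    status = "ok"
    if df_lof > 0 and ms_pe > 0:
        f_lof = ms_lof / ms_pe
        p_lof = float(stats.f.sf(f_lof, df_lof, df_pe))
    else:
        f_lof, p_lof = None, None
        if df_lof > 0:
            status = "lack-of-fit F undefined: pure error is zero"
    rows["lack_of_fit"] = (ss_lof, df_lof, ms_lof)
    rows["pure_error"] = (ss_pe, df_pe, ms_pe)
    return AnovaTable(
        rows=rows,
        f_model=f_model,
        p_model=p_model,
        f_lack_of_fit=f_lof,
        p_lack_of_fit=p_lof,
        status=status,
    )


def predict(fit: QuadraticFit, coded_points) -> np.ndarray | float:
    """Evaluate the fitted polynomial (all terms) at coded point(s)."""
    pts = np.asarray(coded_points, dtype=float)
    scalar = pts.ndim == 1
    if pts.ndim == 1:
        pts = pts[None, :]
    if pts.shape[1] != fit.k:
        raise ValueError(f"points have dimension {pts.shape[1]}, fit has k={fit.k}")
    out = quadratic_model_matrix(pts) @ fit.params
    return float(out[0]) if scalar else out


def surface_grid(
    fit: QuadraticFit,
    bounds: Sequence[tuple[float, float]] | None = None,
    resolution: int = 51,
) -> pd.DataFrame:
    """Predictions on a dense grid over a rectangular coded region.

    Returns a long-format frame with one coded column per factor plus a
    ``predicted`` column, suitable for contour/surface plotting or CSV
    export. Only implemented for two-factor fits (the plotting case).
    """
    if fit.k != 2:
        raise NotImplementedError("surface grids are defined for 2-factor fits")
    if bounds is None:
        bounds = [(-1.0, 1.0)] * 2
    (lo1, hi1), (lo2, hi2) = bounds
    if not (np.isfinite([lo1, hi1, lo2, hi2]).all() and lo1 < hi1 and lo2 < hi2):
        raise ValueError("bounds must be finite with lower < upper")
    g1 = np.linspace(lo1, hi1, resolution)
    g2 = np.linspace(lo2, hi2, resolution)
    G1, G2 = np.meshgrid(g1, g2, indexing="ij")
    pts = np.column_stack([G1.ravel(), G2.ravel()])
    pred = predict(fit, pts)
    return pd.DataFrame(
        {
            fit.factor_names[0]: pts[:, 0],
            fit.factor_names[1]: pts[:, 1],
            "predicted": pred,
        }
    )
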