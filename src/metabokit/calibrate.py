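"""Calibration-curve construction and inverse concentration estimation.

A calibration curve regresses instrument response on known standard
concentrations with a linear or quadratic form, optional 1/x or 1/x^2
weighting (for response noise growing with concentration), and iterative
outlier rejection by one of three rules: Cook's distance (> 4/n), the 95%
prediction interval, or back-calculation bias (> 20% relative error).
Every (form, weight, outlier-rule) scenario is fitted and ranked by
adjusted R^2, after which the chosen curve inverts a sample's response into
a concentration.

``CalibrationCurve(series).fit()`` runs the full scenario grid and returns
a results object in the model/results idiom; ``fit_wls`` exposes a single
weighted fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "StandardSeries",
    "CalibrationModel",
    "CalibrationResults",
    "CalibrationCurve",
    "fit_wls",
    "detect_outliers",
    "build_calibration",
    "estimate_concentration",
    "relative_error",
]

FORMS = ("linear", "quadratic")
WEIGHTS = ("1", "1/x", "1/x^2")
OUTLIER_METHODS = ("cooks_d", "ci", "bias")

#: minimum retained points by form (parameters + 2)
_MIN_POINTS = {"linear": 4, "quadratic": 5}


@dataclass
class StandardSeries:
    """Known standards: (concentration, response) pairs for one compound."""

    points: list[tuple[float, float]]
    compound: str = ""

    def __post_init__(self):
        for x, _y in self.points:
            if x <= 0:
                raise ValueError(f"{self.compound}: concentrations must be positive")

    @property
    def x(self) -> np.ndarray:
        return np.asarray([p[0] for p in self.points], dtype=float)

    @property
    def y(self) -> np.ndarray:
        return np.asarray([p[1] for p in self.points], dtype=float)

    @classmethod
    def read_tsv(cls, path, compound: str | None = None, sep: str = "\t"):
        """Standards TSV: columns compound, concentration, response."""
        df = pd.read_csv(path, sep=sep)
        out = []
        for name, grp in df.groupby("compound"):
            if compound is not None and name != compound:
                continue
            out.append(cls(list(zip(grp["concentration"].astype(float),
                                    grp["response"].astype(float))),
                           compound=str(name)))
        if compound is not None:
            if not out:
                raise KeyError(f"compound {compound!r} not in {path}")
            return out[0]
        return out


def _design(x: np.ndarray, form: str) -> np.ndarray:
    if form == "linear":
        return sm.add_constant(x)
    if form == "quadratic":
        return sm.add_constant(np.column_stack([x, x ** 2]))
    raise ValueError(f"unknown form {form!r}")


def _weights(x: np.ndarray, scheme: str) -> np.ndarray:
    if scheme in ("1", "unweighted", 1):
        return np.ones_like(x)
    if scheme == "1/x":
        return 1.0 / x
    if scheme in ("1/x^2", "1/x2"):
        return 1.0 / x ** 2
    raise ValueError(f"unknown weight scheme {scheme!r}")


@dataclass
class CalibrationModel:
    """One fitted scenario of the calibration grid."""

    form: str
    weight_scheme: str
    outlier_method: str | None
    coefficients: np.ndarray          # b0, b1[, b2]
    retained_x: list[float]
    removed_x: list[float]
    r2: float
    adj_r2: float
    x_range: tuple[float, float]
    y_range: tuple[float, float]
    feasible: bool = True
    compound: str = ""

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        b = self.coefficients
        out = b[0] + b[1] * x
        if self.form == "quadratic":
            out = out + b[2] * x ** 2
        return out


def fit_wls(series: StandardSeries, form: str = "linear",
            weight_scheme: str = "1") -> CalibrationModel:
    """Single weighted least-squares fit, no outlier pass.

    R^2 and adjusted R^2 are computed on the weighted scale (weighted TSS
    about the weighted mean), the statsmodels WLS convention.
    """
    x, y = series.x, series.y
    n_min = _MIN_POINTS[form]
    if len(x) < n_min:
        raise ValueError(
            f"{form} fit needs at least {n_min} points, got {len(x)}")
    X = _design(x, form)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design (too few distinct concentrations)")
    res = sm.WLS(y, X, weights=_weights(x, weight_scheme)).fit()
    return CalibrationModel(
        form=form, weight_scheme=weight_scheme, outlier_method=None,
        coefficients=np.asarray(res.params, dtype=float),
        retained_x=sorted(set(x)), removed_x=[],
        r2=float(res.rsquared), adj_r2=float(res.rsquared_adj),
        x_range=(float(x.min()), float(x.max())),
        y_range=(float(y.min()), float(y.max())),
        compound=series.compound,
    )


def detect_outliers(series: StandardSeries, form: str = "linear",
                    weight_scheme: str = "1", method: str = "cooks_d",
                    cooks_threshold: float | None = None,
                    ci_level: float = 0.95,
                    bias_max_pct: float = 20.0) -> list[int]:
    """Flag outlying standards under one rule; returns point indices.

    cooks_d: Cook's distance > 4/n. ci: response outside the
    ``ci_level`` prediction interval for a new observation at its
    concentration. bias: back-calculated concentration off by more than
    ``bias_max_pct`` percent.
    """
    x, y = series.x, series.y
    n = len(x)
    X = _design(x, form)
    if n <= X.shape[1] + 1:
        raise ValueError("too few points for influence diagnostics")
    w = _weights(x, weight_scheme)
    res = sm.WLS(y, X, weights=w).fit()
    # a (near-)perfect fit has no meaningful influence diagnostics
    scale = float(np.mean((np.sqrt(w) * y) ** 2)) or 1.0
    if float(res.ssr) <= 1e-12 * scale:
        return []
    if method == "cooks_d":
        thr = cooks_threshold if cooks_threshold is not None else 4.0 / n
        # Cook's D on the whitened (weighted) model: D_i =
        # e*_i^2 h_ii / (p sigma^2 (1 - h_ii)^2) with X* = sqrt(w) X
        sw = np.sqrt(w)
        Xw = X * sw[:, None]
        ew = sw * res.resid
        H = Xw @ np.linalg.inv(Xw.T @ Xw) @ Xw.T
        h = np.diag(H)
        k = X.shape[1]
        sigma2 = float(ew @ ew) / (n - k)
        with np.errstate(divide="ignore", invalid="ignore"):
            cooks = ew ** 2 * h / (k * sigma2 * (1.0 - h) ** 2)
        return [i for i in range(n) if np.isfinite(cooks[i]) and cooks[i] > thr]
    if method == "ci":
        pred = res.get_prediction(X, weights=w)
        lo, hi = pred.conf_int(obs=True, alpha=1 - ci_level).T
        return [i for i in range(n) if not (lo[i] <= y[i] <= hi[i])]
    if method == "bias":
        model = CalibrationModel(
            form=form, weight_scheme=weight_scheme, outlier_method=None,
            coefficients=np.asarray(res.params, dtype=float),
            retained_x=sorted(set(x)), removed_x=[],
            r2=float(res.rsquared), adj_r2=float(res.rsquared_adj),
            x_range=(float(x.min()), float(x.max())),
            y_range=(float(y.min()), float(y.max())),
        )
        flagged = []
        for i in range(n):
            try:
                back = estimate_concentration(model, y[i], warn_extrapolation=False)
            except ValueError:
                flagged.append(i)
                continue
            if abs(relative_error(back, x[i])) > bias_max_pct:
                flagged.append(i)
        return flagged
    raise ValueError(f"unknown outlier method {method!r}")


def _iterate_scenario(series: StandardSeries, form: str, weight: str,
                      method: str, max_iter: int) -> CalibrationModel:
    pts = list(series.points)
    removed: list[float] = []
    n_min = _MIN_POINTS[form]
    for _ in range(max_iter):
        sub = StandardSeries(pts, series.compound)
        flags = detect_outliers(sub, form, weight, method)
        if not flags:
            break
        # all-at-once removal, but never below the floor
        if len(pts) - len(flags) < n_min:
            flags = flags[: len(pts) - n_min]
        if not flags:
            break
        removed.extend(pts[i][0] for i in flags)
        pts = [p for i, p in enumerate(pts) if i not in set(flags)]
    model = fit_wls(StandardSeries(pts, series.compound), form, weight)
    model.outlier_method = method
    model.removed_x = sorted(removed)
    return model


@dataclass
class CalibrationResults:
    """Ranked scenario grid for one compound."""

    scenarios: list[CalibrationModel]
    compound: str = ""

    @property
    def best(self) -> CalibrationModel:
        feasible = [m for m in self.scenarios if m.feasible]
        if not feasible:
            raise ValueError("no feasible calibration scenario")
        return feasible[0]

    def table(self) -> pd.DataFrame:
        rows = [{
            "form": m.form, "weight": m.weight_scheme,
            "outlier_method": m.outlier_method,
            "retained": "; ".join(f"{v:g}" for v in m.retained_x),
            "removed": "; ".join(f"{v:g}" for v in m.removed_x),
            "r2": m.r2, "adj_r2": m.adj_r2, "feasible": m.feasible,
        } for m in self.scenarios]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        b = self.best
        return "\n".join([
            f"Calibration scenarios for {self.compound or 'compound'}: "
            f"{len(self.scenarios)} fitted",
            f"  best: {b.form}, weight {b.weight_scheme}, outliers by "
            f"{b.outlier_method}",
            f"  retained levels: {', '.join(f'{v:g}' for v in b.retained_x)}",
            f"  R2 = {b.r2:.4f}   adj R2 = {b.adj_r2:.4f}",
        ])


class CalibrationCurve:
    """Scenario-grid calibration model for one standard series."""

    def __init__(self, series: StandardSeries, forms=FORMS, weights=WEIGHTS,
                 methods=OUTLIER_METHODS, max_iter: int = 5):
        self.series = series
        self.forms = list(forms)
        self.weights = list(weights)
        self.methods = list(methods)
        self.max_iter = max_iter

    def fit(self) -> CalibrationResults:
        scenarios = []
        for form in self.forms:
            for weight in self.weights:
                for method in self.methods:
                    try:
                        m = _iterate_scenario(self.series, form, weight,
                                              method, self.max_iter)
                    except ValueError as exc:
                        warnings.warn(
                            f"scenario ({form}, {weight}, {method}) "
                            f"infeasible: {exc}")
                        m = CalibrationModel(
                            form, weight, method, np.array([]), [],
                            [], np.nan, -np.inf, (np.nan, np.nan),
                            (np.nan, np.nan), feasible=False,
                            compound=self.series.compound)
                    scenarios.append(m)
        form_rank = {f: i for i, f in enumerate(FORMS)}
        scenarios.sort(key=lambda m: (-m.adj_r2 if m.feasible else np.inf,
                                      len(m.removed_x),
                                      form_rank.get(m.form, 99)))
        return CalibrationResults(scenarios, self.series.compound)


def build_calibration(series: StandardSeries, forms=FORMS, weights=WEIGHTS,
                      methods=OUTLIER_METHODS,
                      max_iter: int = 5) -> list[CalibrationModel]:
    """Functional wrapper: ranked scenario list (adjusted R^2 descending;
    ties broken by fewer removed points, then simpler form)."""
    return CalibrationCurve(series, forms, weights, methods, max_iter).fit().scenarios


def estimate_concentration(model: CalibrationModel, response: float,
                           warn_extrapolation: bool = True) -> float:
    """Invert the calibration curve at an observed response.

    Linear: x = (y - b0)/b1. Quadratic: the real root of
    b2 x^2 + b1 x + (b0 - y) = 0 inside the fitted concentration range
    (ambiguous or absent roots raise). Responses outside the fitted
    response range are allowed with an extrapolation warning.
    """
    b = model.coefficients
    if warn_extrapolation and not (model.y_range[0] <= response <= model.y_range[1]):
        warnings.warn(
            f"response {response:g} outside fitted range {model.y_range}; "
            f"extrapolating")
    if model.form == "linear":
        if b[1] == 0:
            raise ValueError("zero slope: concentration undefined")
        return float((response - b[0]) / b[1])
    disc = b[1] ** 2 - 4.0 * b[2] * (b[0] - response)
    if disc < 0:
        raise ValueError(f"no real root for response {response:g}")
    sq = np.sqrt(disc)
    roots = [(-b[1] + sq) / (2 * b[2]), (-b[1] - sq) / (2 * b[2])]
    lo, hi = model.x_range
    span = (hi - lo) or 1.0
    inside = [r for r in roots if lo - 0.05 * span <= r <= hi + 0.05 * span]
    if len(inside) == 2 and not np.isclose(inside[0], inside[1]):
        raise ValueError(
            f"both roots {roots} fall inside the fitted range {model.x_range}")
    if not inside:
        raise ValueError(
            f"no root inside the fitted range {model.x_range}; roots {roots}")
    return float(inside[0])


def relative_error(estimated: float, nominal: float) -> float:
    """Signed percent error: (estimated - nominal)/nominal * 100."""
    if nominal <= 0:
        raise ValueError("nominal concentration must be positive")
    return (estimated - nominal) / nominal * 100.0
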