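"""Per-feature ANCOVA association and PLS / PLS-DA latent-variable models.

Two model classes in the statsmodels idiom:

``ANCOVA(table, trait, covariates).fit()``
    fits ``value ~ trait + covariates`` by least squares for every feature,
    returning the trait effect size (beta), its t statistic and p-value,
    Benjamini-Hochberg adjusted p across features, and the per-sample
    residuals. ``residualize`` fits the covariate-only model, producing the
    adjusted values fed to PLS.

``PLS(X, Y, n_components).fit()``
    NIPALS partial least squares (PLS1/PLS2); discriminant mode one-hot
    encodes class labels. The results object carries scores, weights,
    loadings, cumulative R2X/R2Y, VIP scores (Sum VIP^2 = number of
    predictors), and methods for seeded K-fold cross-validation (Q2Y =
    1 - PRESS/TSS) and RMSEE = sqrt(RSS / (n - A - 1)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

from .feature_table import FeatureTable

__all__ = [
    "ANCOVA",
    "AncovaResults",
    "ancova",
    "residualize",
    "PLS",
    "PLSResults",
    "pls_fit",
    "cross_validate",
    "vip",
    "dual_filter",
]


# --------------------------------------------------------------------------
# ANCOVA
# --------------------------------------------------------------------------

def _design(meta: pd.DataFrame, trait: str | None, covariates: list[str]):
    """Build the design matrix: intercept, trait (binary groups coded 0/1,
    numeric traits as-is), then covariates."""
    cols = [np.ones(len(meta))]
    names = ["const"]
    if trait is not None:
        tv = meta[trait]
        if tv.dtype == object or str(tv.dtype) == "category":
            # reference level = first observed; beta is the effect of the
            # second level relative to it
            levels = list(pd.unique(tv.dropna()))
            if len(levels) != 2:
                raise ValueError(
                    f"trait {trait!r} must be numeric or two-level; got {levels}")
            cols.append((tv == levels[1]).astype(float).to_numpy())
        else:
            cols.append(tv.astype(float).to_numpy())
        names.append(trait)
    for c in covariates:
        cols.append(meta[c].astype(float).to_numpy())
        names.append(c)
    return np.column_stack(cols), names


@dataclass
class AncovaResults:
    """Per-feature association results. ``table`` has one row per fitted
    feature: beta, se, t, p, p_fdr; ``residuals`` is features x samples."""

    table: pd.DataFrame
    residuals: pd.DataFrame
    trait: str
    covariates: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)

    def summary(self) -> str:
        n_sig = int((self.table["p_fdr"] < 0.05).sum())
        lines = [
            "ANCOVA per-feature association",
            f"  trait: {self.trait}   covariates: {self.covariates or 'none'}",
            f"  features fitted: {len(self.table)}   skipped: {len(self.skipped)}",
            f"  significant at pFDR < 0.05: {n_sig}",
        ]
        return "\n".join(lines)


class ANCOVA:
    """Feature-wise linear model ``value ~ trait + covariates``."""

    def __init__(self, table: FeatureTable, trait: str,
                 covariates: list[str] | None = None):
        if table.sample_meta is None:
            raise ValueError("ANCOVA requires sample metadata")
        self.table = table
        self.trait = trait
        self.covariates = list(covariates or [])

    def fit(self) -> AncovaResults:
        meta = self.table.sample_meta
        X_full, names = _design(meta, self.trait, self.covariates)
        p_design = X_full.shape[1]
        rows, resid_rows, skipped = [], {}, []
        for fid in self.table.values.index:
            y = self.table.values.loc[fid].to_numpy(dtype=float)
            ok = ~np.isnan(y)
            for j in range(X_full.shape[1]):
                ok &= ~np.isnan(X_full[:, j])
            if ok.sum() < p_design + 1:
                skipped.append(fid)
                warnings.warn(f"feature {fid!r}: too few complete samples; skipped")
                continue
            Xo, yo = X_full[ok], y[ok]
            if np.linalg.matrix_rank(Xo) < p_design:
                skipped.append(fid)
                warnings.warn(f"feature {fid!r}: rank-deficient design; skipped")
                continue
            beta_hat, _, _, _ = np.linalg.lstsq(Xo, yo, rcond=None)
            fitted = Xo @ beta_hat
            resid = yo - fitted
            dof = ok.sum() - p_design
            sigma2 = float(resid @ resid) / dof
            cov = sigma2 * np.linalg.inv(Xo.T @ Xo)
            j = names.index(self.trait)
            se = float(np.sqrt(cov[j, j]))
            t = float(beta_hat[j]) / se
            p = 2.0 * float(_sps.t.sf(abs(t), dof))
            rows.append((fid, float(beta_hat[j]), se, t, p))
            full = np.full(y.shape, np.nan)
            full[ok] = resid
            resid_rows[fid] = full
        tab = pd.DataFrame(rows, columns=["feature_id", "beta", "se", "t", "p"]
                           ).set_index("feature_id")
        if len(tab):
            tab["p_fdr"] = multipletests(tab["p"].to_numpy(), method="fdr_bh")[1]
        else:
            tab["p_fdr"] = []
        residuals = pd.DataFrame(resid_rows, index=self.table.sample_ids).T
        return AncovaResults(tab, residuals, self.trait, self.covariates, skipped)


def ancova(table: FeatureTable, trait: str,
           covariates: list[str] | None = None) -> AncovaResults:
    """Functional wrapper around :class:`ANCOVA`."""
    return ANCOVA(table, trait, covariates).fit()


def residualize(table: FeatureTable,
                covariates: list[str]) -> FeatureTable:
    """Per-feature residuals from ``value ~ covariates`` (trait excluded).

    With no covariates this reduces to mean-centering. Residuals are
    orthogonal to every covariate by OLS construction.
    """
    if table.sample_meta is None and covariates:
        raise ValueError("residualize requires sample metadata")
    meta = table.sample_meta if table.sample_meta is not None else pd.DataFrame(
        index=table.sample_ids)
    X, _ = _design(meta, None, covariates)
    out = table.values.copy().astype(float)
    for fid in out.index:
        y = out.loc[fid].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        for j in range(X.shape[1]):
            ok &= ~np.isnan(X[:, j])
        if ok.sum() <= X.shape[1]:
            warnings.warn(f"feature {fid!r}: too few samples to residualize; NaN")
            out.loc[fid] = np.nan
            continue
        beta_hat, _, _, _ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
        res = np.full(y.shape, np.nan)
        res[ok] = y[ok] - X[ok] @ beta_hat
        out.loc[fid] = res
    return table.with_values(out)


# --------------------------------------------------------------------------
# PLS / PLS-DA
# --------------------------------------------------------------------------

def _one_hot(labels) -> tuple[np.ndarray, list]:
    classes = sorted(pd.unique(pd.Series(labels)))
    Y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        Y[i, classes.index(lab)] = 1.0
    return Y, classes


def _nipals(E: np.ndarray, F: np.ndarray, A: int, tol: float = 1e-12,
            max_iter: int = 1000):
    """NIPALS decomposition of centered/scaled X (E) and Y (F).

    Returns T, W, P, Q with deflation by X scores. Handles PLS1 (single
    response) and PLS2.
    """
    n, p = E.shape
    m = F.shape[1]
    T = np.zeros((n, A)); W = np.zeros((p, A))
    P = np.zeros((p, A)); Q = np.zeros((m, A))
    for a in range(A):
        u = F[:, int(np.argmax(F.var(axis=0)))].copy()
        t_old = None
        for _ in range(max_iter):
            w = E.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w /= nw
            t = E @ w
            q = F.T @ t / float(t @ t)
            if m == 1:
                u = F[:, 0]
            else:
                nq = float(q @ q)
                u = F @ q / nq if nq > 0 else F[:, 0]
            if t_old is not None and np.linalg.norm(t - t_old) < tol * max(
                    1.0, np.linalg.norm(t)):
                break
            t_old = t
        tt = float(t @ t)
        if tt == 0:
            break
        p_a = E.T @ t / tt
        q_a = F.T @ t / tt
        E = E - np.outer(t, p_a)
        F = F - np.outer(t, q_a)
        T[:, a], W[:, a], P[:, a], Q[:, a] = t, w, p_a, q_a
    return T, W, P, Q


@dataclass
class PLSResults:
    """Fitted PLS(-DA) model: latent scores, weights/loadings, fit metrics."""

    n_components: int
    scores: np.ndarray          # n x A
    weights: np.ndarray         # p x A (x-weights, unit norm)
    x_loadings: np.ndarray      # p x A
    y_loadings: np.ndarray      # m x A
    coef: np.ndarray            # p x m, on the scaled space
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray
    r2x: float
    r2y: float
    r2y_per_component: np.ndarray
    predictor_names: list
    response_names: list
    classes: list | None = None  # discriminant mode only
    q2y: float | None = None
    rmsee: float | None = None
    _X: np.ndarray | None = None
    _Y: np.ndarray | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.x_mean) / self.x_std
        return Xs @ self.coef * self.y_std + self.y_mean

    def predict_class(self, X: np.ndarray):
        """Max predicted dummy column wins; ties break to the first class."""
        if self.classes is None:
            raise ValueError("not a discriminant model")
        Yhat = self.predict(X)
        return [self.classes[int(np.argmax(row))] for row in Yhat]

    def vip(self) -> pd.Series:
        """Variable importance in projection; Sum VIP^2 = n predictors."""
        return pd.Series(vip(self), index=self.predictor_names)

    def score_table(self) -> pd.DataFrame:
        """Plot-ready score table (t1, t2, ...) for score plots."""
        cols = {f"t{a + 1}": self.scores[:, a]
                for a in range(self.n_components)}
        return pd.DataFrame(cols)

    def summary(self) -> str:
        lines = [
            "PLS" + ("-DA" if self.classes is not None else "") + " model",
            f"  components: {self.n_components}   predictors: {len(self.predictor_names)}"
            f"   responses: {len(self.response_names)}",
            f"  R2X = {self.r2x:.4f}   R2Y = {self.r2y:.4f}",
        ]
        if self.q2y is not None:
            lines.append(f"  Q2Y = {self.q2y:.4f}   RMSEE = {self.rmsee:.4f}")
        return "\n".join(lines)


class PLS:
    """NIPALS PLS / PLS-DA model builder.

    Parameters
    ----------
    X : array or DataFrame, samples x predictors
    Y : array, DataFrame or label sequence. Non-numeric input (or
        ``discriminant=True``) switches to PLS-DA via one-hot encoding.
    n_components : int
        Number of latent variables (default 2, the score-plot convention).
    scale : bool
        Center and unit-variance scale X and Y internally (default True).
    """

    def __init__(self, X, Y, n_components: int = 2, scale: bool = True,
                 discriminant: bool | None = None):
        if isinstance(X, pd.DataFrame):
            self.predictor_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.predictor_names = [f"x{j}" for j in range(X.shape[1])]
        y_arr = np.asarray(Y)
        if discriminant is None:
            discriminant = y_arr.dtype.kind in "USOb"
        self.classes = None
        if discriminant:
            Ymat, self.classes = _one_hot(list(np.ravel(y_arr)))
            self.response_names = [str(c) for c in self.classes]
        else:
            Ymat = y_arr.astype(float)
            if Ymat.ndim == 1:
                Ymat = Ymat[:, None]
            self.response_names = (list(Y.columns)
                                   if isinstance(Y, pd.DataFrame)
                                   else [f"y{j}" for j in range(Ymat.shape[1])])
        if X.shape[0] != Ymat.shape[0]:
            raise ValueError("X and Y sample counts differ")
        self.X, self.Y = X, Ymat
        self.n_components = n_components
        self.scale = scale

    def fit(self) -> PLSResults:
        X, Y = self.X.copy(), self.Y.copy()
        x_mean, y_mean = X.mean(axis=0), Y.mean(axis=0)
        if self.scale:
            x_std = X.std(axis=0, ddof=1)
            y_std = Y.std(axis=0, ddof=1)
            y_std[y_std == 0] = 1.0
        else:
            x_std = np.ones(X.shape[1]); y_std = np.ones(Y.shape[1])
        keep = np.ones(X.shape[1], dtype=bool)
        zero_var = x_std == 0
        if zero_var.any():
            warnings.warn(
                f"dropping zero-variance predictors: "
                f"{[self.predictor_names[j] for j in np.where(zero_var)[0]]}")
            keep = ~zero_var
        names = [n for n, k in zip(self.predictor_names, keep) if k]
        Xs = (X[:, keep] - x_mean[keep]) / x_std[keep]
        Ys = (Y - y_mean) / y_std
        A = self.n_components
        max_A = int(np.linalg.matrix_rank(Xs))
        if A > max_A:
            warnings.warn(f"n_components {A} exceeds rank {max_A}; truncated")
            A = max_A
        T, W, P, Q = _nipals(Xs.copy(), Ys.copy(), A)
        # drop trailing all-zero components (early NIPALS exit)
        nz = [a for a in range(A) if np.any(T[:, a] != 0)]
        A = len(nz)
        T, W, P, Q = T[:, nz], W[:, nz], P[:, nz], Q[:, nz]
        coef = W @ np.linalg.pinv(P.T @ W) @ Q.T
        ssx = float((Xs ** 2).sum())
        ssy = float((Ys ** 2).sum())
        Ex = Xs - T @ P.T
        r2x = 1.0 - float((Ex ** 2).sum()) / ssx if ssx > 0 else 0.0
        # per-component Y sum of squares explained (for VIP weighting)
        ss_a = np.array([float(T[:, a] @ T[:, a]) * float(Q[:, a] @ Q[:, a])
                         for a in range(A)])
        Fy = Ys - T @ Q.T
        r2y = 1.0 - float((Fy ** 2).sum()) / ssy if ssy > 0 else 0.0
        return PLSResults(
            n_components=A, scores=T, weights=W, x_loadings=P, y_loadings=Q,
            coef=coef, x_mean=x_mean[keep], x_std=x_std[keep],
            y_mean=y_mean, y_std=y_std, r2x=r2x, r2y=r2y,
            r2y_per_component=ss_a, predictor_names=names,
            response_names=self.response_names, classes=self.classes,
            _X=X[:, keep], _Y=Y,
        )


def pls_fit(X, Y, n_components: int = 2, **kwargs) -> PLSResults:
    """Functional wrapper around :class:`PLS`."""
    return PLS(X, Y, n_components=n_components, **kwargs).fit()


def vip(model: PLSResults) -> np.ndarray:
    """Standard VIP: VIP_j = sqrt(p * Sum_a SS_a (w_ja/||w_a||)^2 / Sum SS_a)."""
    W = model.weights
    p, A = W.shape
    ss = model.r2y_per_component
    denom = float(ss.sum())
    if denom == 0:
        return np.ones(p)
    wn2 = np.zeros((p, A))
    for a in range(A):
        norm = float(W[:, a] @ W[:, a])
        if norm > 0:
            wn2[:, a] = W[:, a] ** 2 / norm
    return np.sqrt(p * (wn2 @ ss) / denom)


def cross_validate(X, Y, n_components: int = 2, folds: int = 7,
                   seed: int = 0, scale: bool = True,
                   discriminant: bool | None = None):
    """Seeded K-fold cross-validation of a PLS(-DA) model.

    Returns ``(q2y, rmsee)``: Q2Y = 1 - PRESS/TSS over held-out predictions
    (folds stratified by class in discriminant mode), RMSEE computed on the
    full fit with denominator n - A - 1.
    """
    model = PLS(X, Y, n_components=n_components, scale=scale,
                discriminant=discriminant)
    n = model.X.shape[0]
    if not 2 <= folds <= n:
        raise ValueError(f"folds must be in [2, {n}]")
    rng = np.random.default_rng(seed)
    if model.classes is not None:
        # stratified assignment: shuffle within class, deal out round-robin
        fold_of = np.empty(n, dtype=int)
        labels = model.Y.argmax(axis=1)
        offset = 0
        for c in range(model.Y.shape[1]):
            idx = np.where(labels == c)[0]
            rng.shuffle(idx)
            for i, s in enumerate(idx):
                fold_of[s] = (i + offset) % folds
            offset += len(idx)
        for f in range(folds):
            train_lab = labels[fold_of != f]
            if len(np.unique(train_lab)) < model.Y.shape[1]:
                raise ValueError("a fold leaves a class unrepresented; "
                                 "reduce folds")
    else:
        perm = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        fold_of[perm] = np.arange(n) % folds
    press = 0.0
    tss = 0.0
    for f in range(folds):
        test = fold_of == f
        train = ~test
        sub = PLS(model.X[train], model.Y[train],
                  n_components=n_components, scale=scale, discriminant=False)
        res = sub.fit()
        pred = res.predict(model.X[test])
        press += float(((model.Y[test] - pred) ** 2).sum())
        ybar = model.Y[train].mean(axis=0)
        tss += float(((model.Y[test] - ybar) ** 2).sum())
    q2y = 1.0 - press / tss if tss > 0 else np.nan
    full = model.fit()
    resid = model.Y - full.predict(model.X)
    A = full.n_components
    dof = n - A - 1
    rmsee = float(np.sqrt((resid ** 2).sum() / dof)) if dof > 0 else np.nan
    return q2y, rmsee


def dual_filter(ancova_results: AncovaResults, vip_scores: pd.Series,
                p_fdr_max: float = 0.05, top_k: int = 10) -> list[str]:
    """Intersect FDR-significant features with the top-k by VIP.

    Ties at the top-k VIP boundary and ordering are broken by feature id
    (ascending) for determinism. An empty intersection warns.
    """
    sig = set(ancova_results.table.index[
        ancova_results.table["p_fdr"] < p_fdr_max])
    ranked = sorted(vip_scores.items(), key=lambda kv: (-kv[1], kv[0]))
    top = {fid for fid, _ in ranked[:top_k]}
    selected = sorted(sig & top)
    if not selected:
        warnings.warn("dual filter selected no features")
    return selected
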