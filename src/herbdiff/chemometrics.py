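"""OPLS-DA marker screening: orthogonal PLS, VIP scores, univariate tests.

Orthogonal projections to latent structures discriminant analysis (OPLS-DA)
splits the autoscaled peak-area matrix X into one predictive latent
component (covarying with the binary class vector y) and k orthogonal
components (systematic variation in X uncorrelated with y).  Variable
importance in projection (VIP) on the predictive component, combined with
a per-variable two-sample Student's t-test, screens the peaks that
discriminate the two species: a peak is a candidate marker when VIP > 1.0
and p < 0.05 (strict inequalities, no multiplicity correction by default,
a Benjamini-Hochberg option is available).

The estimator follows scikit-learn conventions (fit/transform/predict,
fitted attributes with trailing underscores) and composes with sklearn
model selection.  The single-y NIPALS orthogonal-filtering algorithm is
implemented here; cross-validation folds come from sklearn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.model_selection import StratifiedKFold

from .errors import NumericalError, ValidationError

__all__ = [
    "autoscale",
    "OPLSDA",
    "opls_da_fit",
    "vip_scores",
    "ttest_screen",
    "MarkerPanel",
    "select_markers",
]

_EPS = 1e-12


def autoscale(X):
    """Center to mean 0 and scale to unit SD (ddof=1) per column.

    Constant columns are centered, given scale 1, and flagged.  Returns
    ``(scaled, mean, scale, constant_flags)``; the inverse transform is
    ``scaled * scale + mean``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("autoscale needs a 2-D matrix with >= 2 rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    constant = sd <= _EPS * np.maximum(1.0, np.abs(mean))
    scale = np.where(constant, 1.0, sd)
    return (X - mean) / scale, mean, scale, constant


def _unit(v, what):
    norm = np.linalg.norm(v)
    if norm <= _EPS:
        raise NumericalError(f"{what} degenerated to zero norm (rank-deficient X or n_ortho too large)")
    return v / norm


def _opls_core(Xs, yc, n_ortho):
    """Single-y orthogonal-filtering NIPALS on pre-scaled X, centered y."""
    w = _unit(Xs.T @ yc, "predictive weight")
    W_o, P_o, T_o = [], [], []
    Xd = Xs
    for _ in range(n_ortho):
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        w_o = _unit(w_o, "orthogonal weight")
        t_o = Xd @ w_o
        if t_o @ t_o <= _EPS:
            raise NumericalError("orthogonal score collapsed; reduce n_ortho")
        p_o = Xd.T @ t_o / (t_o @ t_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)
        Xd = Xd - np.outer(t_o, p_o)
    t = Xd @ w
    if t @ t <= _EPS:
        raise NumericalError("predictive score collapsed")
    p = Xd.T @ t / (t @ t)
    q = yc @ t / (t @ t)
    return w, p, q, t, (np.array(W_o), np.array(P_o), np.array(T_o)), Xd


class OPLSDA(BaseEstimator, TransformerMixin, ClassifierMixin):
    """Two-class OPLS-DA with one predictive component.

    Parameters
    ----------
    n_ortho : int
        Number of orthogonal components removed before the predictive
        component (default 1, the two-class convention).
    n_folds : int
        Folds for the cross-validated Q2 (default 7), reduced to the
        smaller class count when necessary; folds are stratified by class
        and seeded by ``random_state``.
    scale : bool
        Autoscale X columns (unit variance) before fitting.
    random_state : int
        Seed for the CV fold assignment (the only randomness in the fit).

    Attributes
    ----------
    classes_ : ndarray of the two class labels; the second is coded y=1.
    weights_, loadings_, scores_ : predictive component vectors.
    ortho_weights_, ortho_loadings_, ortho_scores_ : orthogonal components.
    r2x_, r2y_, q2_ : explained-variance and cross-validated fractions.
    vip_ : VIP score per variable (mean of squared VIPs is 1).
    """

    def __init__(self, n_ortho: int = 1, n_folds: int = 7, scale: bool = True, random_state: int = 0):
        self.n_ortho = n_ortho
        self.n_folds = n_folds
        self.scale = scale
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------
    def _encode(self, y):
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValidationError(f"OPLS-DA needs exactly two classes, got {list(classes)}")
        # fix the CM/CI convention (CM = 0, CI = 1) when those labels are used
        if set(classes) == {"CM", "CI"}:
            classes = np.array(["CM", "CI"])
        return classes, (y == classes[1]).astype(float)

    def _fit_arrays(self, X, y01):
        if self.scale:
            Xs, x_mean, x_scale, _ = autoscale(X)
        else:
            X = np.asarray(X, dtype=float)
            x_mean = X.mean(axis=0)
            x_scale = np.ones(X.shape[1])
            Xs = X - x_mean
        y_mean = y01.mean()
        yc = y01 - y_mean
        w, p, q, t, ortho, Xd = _opls_core(Xs, yc, self.n_ortho)
        return dict(x_mean=x_mean, x_scale=x_scale, y_mean=y_mean,
                    w=w, p=p, q=q, t=t, ortho=ortho, Xs=Xs, yc=yc, Xd=Xd)

    @staticmethod
    def _project(fit, X):
        Xs = (np.asarray(X, dtype=float) - fit["x_mean"]) / fit["x_scale"]
        W_o, P_o, _ = fit["ortho"]
        for w_o, p_o in zip(W_o, P_o):
            t_o = Xs @ w_o
            Xs = Xs - np.outer(t_o, p_o)
        return Xs @ fit["w"]

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValidationError("X must be a 2-D samples x variables matrix")
        self.classes_, y01 = self._encode(y)
        counts = [int((y01 == v).sum()) for v in (0.0, 1.0)]
        if min(counts) < 3:
            raise ValidationError(f"each class needs >= 3 samples, got counts {counts}")
        max_rank = min(X.shape[0] - 1, X.shape[1])
        if self.n_ortho < 0 or self.n_ortho >= max_rank:
            raise ValidationError(f"n_ortho must be in [0, {max_rank - 1}] for this matrix")

        fit = self._fit_arrays(X, y01)
        self.x_mean_, self.x_scale_ = fit["x_mean"], fit["x_scale"]
        self.y_mean_ = fit["y_mean"]
        self.weights_, self.loadings_, self.q_ = fit["w"], fit["p"], fit["q"]
        self.scores_ = fit["t"]
        W_o, P_o, T_o = fit["ortho"]
        self.ortho_weights_, self.ortho_loadings_, self.ortho_scores_ = W_o, P_o, T_o

        Xs, yc, t = fit["Xs"], fit["yc"], fit["t"]
        ssx = float((Xs ** 2).sum())
        residual = fit["Xd"] - np.outer(t, fit["p"])
        self.r2x_ = 1.0 - float((residual ** 2).sum()) / ssx
        ssy = float((yc ** 2).sum())
        self.r2y_ = 1.0 - float(((yc - t * fit["q"]) ** 2).sum()) / ssy

        # VIP over the single predictive component: sqrt(p_vars) * |w|
        n_vars = X.shape[1]
        self.vip_ = np.sqrt(n_vars) * np.abs(fit["w"])

        self.q2_ = self._cross_validate(X, y01)
        return self

    def _cross_validate(self, X, y01):
        n_folds = min(self.n_folds, min(int((y01 == 0).sum()), int((y01 == 1).sum())))
        if n_folds < 2:
            return float("nan")
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=self.random_state)
        press = 0.0
        for train, test in skf.split(X, y01):
            fit = self._fit_arrays(X[train], y01[train])
            t_test = self._project(fit, X[test])
            yhat = t_test * fit["q"] + fit["y_mean"]
            press += float(((y01[test] - yhat) ** 2).sum())
        ss = float(((y01 - y01.mean()) ** 2).sum())
        return 1.0 - press / ss

    def _check_fitted(self):
        if not hasattr(self, "weights_"):
            raise ValidationError("model is not fitted")

    def transform(self, X):
        """Predictive score t for new samples, shape (n, 1)."""
        self._check_fitted()
        fit = dict(x_mean=self.x_mean_, x_scale=self.x_scale_, w=self.weights_,
                   ortho=(self.ortho_weights_, self.ortho_loadings_, None))
        return self._project(fit, X).reshape(-1, 1)

    def decision_function(self, X):
        self._check_fitted()
        t = self.transform(X).ravel()
        return t * self.q_ + self.y_mean_ - 0.5

    def predict(self, X):
        return self.classes_[(self.decision_function(X) >= 0).astype(int)]


def opls_da_fit(x, y, n_ortho: int = 1, **kwargs) -> OPLSDA:
    """Functional wrapper: fit an :class:`OPLSDA` model."""
    return OPLSDA(n_ortho=n_ortho, **kwargs).fit(x, y)


def vip_scores(model: OPLSDA) -> np.ndarray:
    """VIP per variable from a fitted model (mean of squared VIPs is 1)."""
    model._check_fitted()
    return model.vip_


def ttest_screen(x, y, equal_var: bool = True) -> np.ndarray:
    """Two-sided two-sample Student's t-test p-value per variable.

    Pooled-variance by default (``equal_var=False`` gives Welch).  Columns
    that are constant and identical in both groups get p = 1; constant
    columns with different group means get p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValidationError("t-test screen needs exactly two classes")
    a, b = x[y == classes[0]], x[y == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each class needs >= 2 samples")
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # columns that are (near-)constant in both groups are handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        same_mean = np.isclose(a.mean(axis=0), b.mean(axis=0))
        p[degenerate & same_mean] = 1.0
        p[degenerate & ~same_mean] = 0.0
    return p


@dataclass
class MarkerPanel:
    """Screened peaks with their VIP and p-values and the selection flags."""

    peak_ids: list[int]
    vip: np.ndarray
    p: np.ndarray
    selected: np.ndarray      # bool per peak

    @property
    def selected_ids(self) -> list[int]:
        return [pid for pid, s in zip(self.peak_ids, self.selected) if s]


def select_markers(
    vip,
    p,
    peak_ids: list[int] | None = None,
    vip_threshold: float = 1.0,
    alpha: float = 0.05,
    adjust: str | None = None,
) -> MarkerPanel:
    """Combine VIP and t-test screens: selected iff VIP > 1.0 AND p < 0.05.

    Both thresholds are strict.  ``adjust="bh"`` applies Benjamini-Hochberg
    to the p-values before thresholding (off by default: the screening
    convention uses raw p-values).
    """
    vip = np.asarray(vip, dtype=float)
    p = np.asarray(p, dtype=float)
    if vip.shape != p.shape:
        raise ValidationError("vip and p must have equal length")
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests
        p = multipletests(p, method="fdr_bh")[1]
    elif adjust is not None:
        raise ValidationError(f"unknown adjustment {adjust!r}")
    if peak_ids is None:
        peak_ids = list(range(1, len(vip) + 1))
    selected = (vip > vip_threshold) & (p < alpha)
    return MarkerPanel(list(peak_ids), vip, p, selected)
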