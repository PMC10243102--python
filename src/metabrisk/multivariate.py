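"""Latent-variable discriminant models: PCA, PLS-DA and two-class OPLS-DA.

OPLS-DA (orthogonal projections to latent structures, discriminant analysis)
splits the scaled predictor matrix into exactly one class-predictive
component and ``k_ortho`` components orthogonal to the class response. It is
fitted by the NIPALS construction: at each orthogonal round the current PLS
weight vector ``w = X'y / ||X'y||`` is computed, the part of the loading
``p`` orthogonal to ``w`` is extracted as an orthogonal component and
deflated from ``X``; a final one-component PLS on the deflated matrix gives
the predictive component. With ``k_ortho = 0`` the model is exactly a
one-component PLS regression on the class indicator.

Class labels are coded 0/1 (first class -> 0); a sample is predicted as the
second class when its continuous response exceeds the decision threshold
(default 0.5), with ties going to the first class. All fits are
deterministic: there is no internal randomness, and PCA signs are fixed so
repeated fits are identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .profiles import ProfileMatrix, ScaledMatrix

__all__ = [
    "PcaResults",
    "OPLSDA",
    "OPLSDAResults",
    "PLSDA",
    "PLSDAResults",
    "OplsDaSpec",
    "fit_pca",
    "fit_oplsda",
    "fit_plsda",
    "predict",
    "select_components",
    "min_components_at_max",
]

_EPS = 1e-12


def _as_array(x) -> np.ndarray:
    if isinstance(x, ScaledMatrix):
        return np.asarray(x.values, dtype=float)
    if isinstance(x, ProfileMatrix):
        return x.values.to_numpy(dtype=float)
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float)
    return np.asarray(x, dtype=float)


def _column_names(x) -> "list[str] | None":
    if isinstance(x, ScaledMatrix):
        return list(x.metabolite_names) or None
    if isinstance(x, ProfileMatrix):
        return x.metabolite_names
    if isinstance(x, pd.DataFrame):
        return [str(c) for c in x.columns]
    return None


def _safe_scale_params(arr: np.ndarray, method: "str | None"):
    """Centre/scale parameters for internal fits.

    Constant columns get unit scale (they carry no information and would
    otherwise poison a cross-validation fold).
    """
    n, m = arr.shape
    if method is None:
        return np.zeros(m), np.ones(m)
    center = arr.mean(axis=0)
    if method == "center":
        return center, np.ones(m)
    sd = arr.std(axis=0, ddof=1)
    sd = np.where(sd < _EPS, 1.0, sd)
    if method == "unit-variance":
        return center, sd
    if method == "pareto":
        return center, np.sqrt(sd)
    raise ValueError(f"unknown scaling method {method!r}")


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaResults:
    """Principal components of a scaled matrix.

    ``loadings`` has one orthonormal column per component; ``scores`` are the
    projections; ``explained_variance_ratio`` sums to at most 1 and is
    nonincreasing. Signs are fixed so that each component's largest-magnitude
    loading is positive.
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    n_components: int
    column_names: "list[str] | None" = None

    def summary(self) -> str:
        lines = ["PCA", "=" * 32, f"components: {self.n_components}"]
        for i, ev in enumerate(self.explained_variance_ratio, 1):
            lines.append(f"PC{i}: {100 * ev:6.2f}% of variance")
        return "\n".join(lines)


def fit_pca(x, k: int) -> PcaResults:
    """Fit PCA with ``k`` components via SVD of the (already scaled) matrix."""
    arr = _as_array(x)
    n, m = arr.shape
    if not 1 <= k <= min(n - 1, m):
        raise ValueError(f"k must be in [1, min(n-1, m)] = [1, {min(n - 1, m)}], got {k}")
    centered = arr - arr.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for i in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    total_var = float((centered**2).sum())
    evr = (s**2) / total_var if total_var > 0 else np.zeros_like(s)
    return PcaResults(
        scores=u[:, :k] * s[:k],
        loadings=vt[:k].T,
        explained_variance_ratio=evr[:k],
        n_components=k,
        column_names=_column_names(x),
    )


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------


class OPLSDA:
    """Two-class OPLS-DA model builder.

    Parameters
    ----------
    x
        Training predictors: ProfileMatrix, DataFrame, ScaledMatrix or array.
        Unless a pre-scaled ScaledMatrix is given, columns are scaled inside
        ``fit`` using ``scaling`` (so cross-validation folds re-estimate the
        scaling from their own training samples).
    y
        Per-sample class labels with exactly two distinct values, or 0/1.
    classes
        Optional (negative, positive) label pair fixing the 0/1 coding;
        default is order of first appearance in ``y``.
    scaling
        'unit-variance' (default), 'center', 'pareto' or None.
    threshold
        Decision threshold on the continuous response (default 0.5).
    """

    def __init__(self, x, y, *, classes: "tuple | None" = None,
                 scaling: "str | None" = "unit-variance", threshold: float = 0.5):
        if isinstance(x, ScaledMatrix):
            self._arr = np.asarray(x.values, dtype=float)
            self._center = np.asarray(x.center, dtype=float)
            self._scale = np.asarray(x.scale_, dtype=float)
            self._prescaled = True
            self.scaling = x.method
        else:
            self._arr = _as_array(x)
            self._prescaled = False
            self.scaling = scaling
        self.column_names = _column_names(x)
        y = np.asarray(y)
        if classes is None:
            # sorted order so numeric labels 0/1 code to 0/1 regardless of
            # which class happens to appear first in y
            classes = tuple(np.unique(y).tolist())
        if len(classes) != 2:
            raise ValueError(f"OPLS-DA requires exactly 2 classes, got {list(classes)}")
        if set(np.unique(y)) != set(classes):
            raise ValueError("y must contain both classes and no others")
        self.classes = classes
        self._y01 = (y == classes[1]).astype(float)
        self.threshold = float(threshold)
        if self._arr.shape[0] != self._y01.shape[0]:
            raise ValueError("x and y have different numbers of samples")

    def fit(self, k_ortho: int = 0, max_iter: int = 500, tol: float = 1e-10) -> "OPLSDAResults":
        if k_ortho < 0:
            raise ValueError(f"k_ortho must be >= 0, got {k_ortho}")
        arr = self._arr
        n, m = arr.shape
        if k_ortho > max(0, min(n - 1, m) - 1):
            raise ValueError(
                f"k_ortho={k_ortho} too large for data of rank <= {min(n - 1, m)}"
            )
        if self._prescaled:
            center, scl = self._center, self._scale
            xs = arr.copy()
        else:
            center, scl = _safe_scale_params(arr, self.scaling)
            xs = (arr - center) / scl
        y = self._y01
        y_mean = float(y.mean())
        yc = y - y_mean

        w_ortho = np.zeros((m, k_ortho))
        p_ortho = np.zeros((m, k_ortho))
        t_ortho = np.zeros((n, k_ortho))
        X = xs.copy()
        for j in range(k_ortho):
            w = X.T @ yc
            nw = np.linalg.norm(w)
            if nw < _EPS:
                raise ValueError("response has no covariance with predictors; "
                                 f"cannot extract orthogonal component {j + 1}")
            w /= nw
            t = X @ w
            p = X.T @ t / max(t @ t, _EPS)
            wo = p - (w @ p) * w
            nwo = np.linalg.norm(wo)
            if nwo < 1e-10:
                raise ValueError(
                    f"k_ortho={k_ortho} exceeds the orthogonal variation in the data "
                    f"(failed at component {j + 1})"
                )
            wo /= nwo
            to = X @ wo
            po = X.T @ to / max(to @ to, _EPS)
            X = X - np.outer(to, po)
            w_ortho[:, j], p_ortho[:, j], t_ortho[:, j] = wo, po, to

        w = X.T @ yc
        nw = np.linalg.norm(w)
        if nw < _EPS:
            raise ValueError("response has no covariance with predictors")
        w /= nw
        t = X @ w
        tt = max(t @ t, _EPS)
        p = X.T @ t / tt
        q = float(yc @ t / tt)

        # linear coefficient vector equivalent to sequential deflation + projection
        M = np.eye(m)
        for j in range(k_ortho):
            M = M @ (np.eye(m) - np.outer(w_ortho[:, j], p_ortho[:, j]))
        coef = M @ w * q

        return OPLSDAResults(
            classes=self.classes,
            threshold=self.threshold,
            scaling=self.scaling,
            center=center,
            scale_=scl,
            weights=w,
            loadings=p,
            scores=t,
            y_loading=q,
            y_mean=y_mean,
            ortho_weights=w_ortho,
            ortho_loadings=p_ortho,
            ortho_scores=t_ortho,
            coef=coef,
            column_names=self.column_names,
        )


@dataclass
class OPLSDAResults:
    """A fitted two-class OPLS-DA model.

    ``n_components_total`` is 1 predictive + ``k_ortho`` orthogonal
    components. ``predict`` projects new samples using the stored scaling
    parameters, deflates the orthogonal components, and thresholds the
    continuous response.
    """

    classes: tuple
    threshold: float
    scaling: "str | None"
    center: np.ndarray
    scale_: np.ndarray
    weights: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    y_loading: float
    y_mean: float
    ortho_weights: np.ndarray
    ortho_loadings: np.ndarray
    ortho_scores: np.ndarray
    coef: np.ndarray
    column_names: "list[str] | None" = None

    @property
    def k_ortho(self) -> int:
        return self.ortho_weights.shape[1]

    @property
    def n_components_total(self) -> int:
        return 1 + self.k_ortho

    def _prepare(self, x_new) -> np.ndarray:
        names = _column_names(x_new)
        if names is not None and self.column_names is not None:
            if names != list(self.column_names):
                raise ValueError("metabolite columns of new data do not match training data")
        arr = _as_array(x_new)
        if arr.ndim == 1:
            arr = arr[None, :]
        if arr.shape[1] != self.center.shape[0]:
            raise ValueError(
                f"expected {self.center.shape[0]} metabolites, got {arr.shape[1]}"
            )
        return (arr - self.center) / self.scale_

    def decision_function(self, x_new) -> np.ndarray:
        """Continuous predicted response on the 0/1 class-code scale."""
        xs = self._prepare(x_new)
        for j in range(self.k_ortho):
            to = xs @ self.ortho_weights[:, j]
            xs = xs - np.outer(to, self.ortho_loadings[:, j])
        return (xs @ self.weights) * self.y_loading + self.y_mean

    def predictive_scores(self, x_new) -> np.ndarray:
        xs = self._prepare(x_new)
        for j in range(self.k_ortho):
            to = xs @ self.ortho_weights[:, j]
            xs = xs - np.outer(to, self.ortho_loadings[:, j])
        return xs @ self.weights

    def predict(self, x_new, return_response: bool = False):
        """Predict class labels; ties at the threshold go to the first class."""
        resp = self.decision_function(x_new)
        labels = np.where(resp > self.threshold, self.classes[1], self.classes[0])
        if return_response:
            return labels, resp
        return labels

    def summary(self) -> str:
        lines = [
            "OPLS-DA",
            "=" * 40,
            f"classes (0/1 coding): {self.classes[0]} / {self.classes[1]}",
            f"components: 1 predictive + {self.k_ortho} orthogonal",
            f"scaling: {self.scaling}",
            f"decision threshold: {self.threshold}",
            f"y-loading (q): {self.y_loading:.6g}",
        ]
        if self.column_names:
            order = np.argsort(-np.abs(self.coef))[:10]
            lines.append("top |coefficient| metabolites:")
            for i in order:
                lines.append(f"  {self.column_names[i]:<28s} {self.coef[i]:+.4g}")
        return "\n".join(lines)

    # -- JSON serialization so ensemble runs are resumable ------------------

    def to_json(self, path: "str | Path | None" = None) -> str:
        payload = {
            "classes": list(self.classes),
            "threshold": self.threshold,
            "scaling": self.scaling,
            "center": self.center.tolist(),
            "scale": self.scale_.tolist(),
            "weights": self.weights.tolist(),
            "loadings": self.loadings.tolist(),
            "y_loading": self.y_loading,
            "y_mean": self.y_mean,
            "ortho_weights": self.ortho_weights.tolist(),
            "ortho_loadings": self.ortho_loadings.tolist(),
            "column_names": self.column_names,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: "str | Path") -> "OPLSDAResults":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(text).read_text()
        d = json.loads(text)
        w = np.asarray(d["weights"], dtype=float)
        wo = np.asarray(d["ortho_weights"], dtype=float).reshape(len(w), -1)
        po = np.asarray(d["ortho_loadings"], dtype=float).reshape(len(w), -1)
        m = len(w)
        M = np.eye(m)
        for j in range(wo.shape[1]):
            M = M @ (np.eye(m) - np.outer(wo[:, j], po[:, j]))
        return cls(
            classes=tuple(d["classes"]),
            threshold=float(d["threshold"]),
            scaling=d["scaling"],
            center=np.asarray(d["center"], dtype=float),
            scale_=np.asarray(d["scale"], dtype=float),
            weights=w,
            loadings=np.asarray(d["loadings"], dtype=float),
            scores=np.empty(0),
            y_loading=float(d["y_loading"]),
            y_mean=float(d["y_mean"]),
            ortho_weights=wo,
            ortho_loadings=po,
            ortho_scores=np.empty((0, wo.shape[1])),
            coef=M @ w * float(d["y_loading"]),
            column_names=d.get("column_names"),
        )


def fit_oplsda(x, y, k_ortho: int = 0, *, classes=None,
               scaling: "str | None" = "unit-variance",
               threshold: float = 0.5) -> OPLSDAResults:
    """Convenience wrapper: build and fit an :class:`OPLSDA` in one call."""
    return OPLSDA(x, y, classes=classes, scaling=scaling, threshold=threshold).fit(k_ortho)


# ---------------------------------------------------------------------------
# PLS-DA (multi-class, multi-component NIPALS PLS2 on one-hot responses)
# ---------------------------------------------------------------------------


class PLSDA:
    """Multi-class PLS-DA: NIPALS PLS2 against one-hot class indicators."""

    def __init__(self, x, y, *, scaling: "str | None" = "unit-variance"):
        self._arr = _as_array(x)
        self.column_names = _column_names(x)
        self.scaling = scaling
        y = np.asarray(y)
        self.classes = tuple(pd.unique(y))
        if len(self.classes) < 2:
            raise ValueError("PLS-DA requires at least 2 classes")
        self._Y = np.stack([(y == c).astype(float) for c in self.classes], axis=1)

    def fit(self, n_components: int = 2, max_iter: int = 500, tol: float = 1e-10) -> "PLSDAResults":
        arr = self._arr
        n, m = arr.shape
        if not 1 <= n_components <= min(n - 1, m):
            raise ValueError(f"n_components must be in [1, {min(n - 1, m)}]")
        center, scl = _safe_scale_params(arr, self.scaling)
        X = (arr - center) / scl
        Y = self._Y - self._Y.mean(axis=0)
        y_mean = self._Y.mean(axis=0)

        W = np.zeros((m, n_components))
        P = np.zeros((m, n_components))
        Q = np.zeros((Y.shape[1], n_components))
        T = np.zeros((n, n_components))
        for a in range(n_components):
            u = Y[:, int(np.argmax(Y.var(axis=0)))]
            t_old = np.zeros(n)
            for _ in range(max_iter):
                w = X.T @ u
                w /= max(np.linalg.norm(w), _EPS)
                t = X @ w
                q = Y.T @ t / max(t @ t, _EPS)
                u = Y @ q / max(q @ q, _EPS)
                if np.linalg.norm(t - t_old) < tol * max(np.linalg.norm(t), 1.0):
                    break
                t_old = t
            p = X.T @ t / max(t @ t, _EPS)
            X = X - np.outer(t, p)
            Y = Y - np.outer(t, q)
            W[:, a], P[:, a], Q[:, a], T[:, a] = w, p, q, t
        # regression coefficients B = W (P'W)^-1 Q'
        B = W @ np.linalg.solve(P.T @ W, Q.T)
        return PLSDAResults(
            classes=self.classes, center=center, scale_=scl, coef=B,
            y_mean=y_mean, scores=T, weights=W, loadings=P, y_loadings=Q,
            column_names=self.column_names,
        )


@dataclass
class PLSDAResults:
    classes: tuple
    center: np.ndarray
    scale_: np.ndarray
    coef: np.ndarray
    y_mean: np.ndarray
    scores: np.ndarray
    weights: np.ndarray
    loadings: np.ndarray
    y_loadings: np.ndarray
    column_names: "list[str] | None" = None

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def decision_function(self, x_new) -> np.ndarray:
        names = _column_names(x_new)
        if names is not None and self.column_names is not None and names != list(self.column_names):
            raise ValueError("metabolite columns of new data do not match training data")
        arr = _as_array(x_new)
        if arr.ndim == 1:
            arr = arr[None, :]
        xs = (arr - self.center) / self.scale_
        return xs @ self.coef + self.y_mean

    def predict(self, x_new, return_response: bool = False):
        resp = self.decision_function(x_new)
        labels = np.asarray([self.classes[i] for i in np.argmax(resp, axis=1)])
        if return_response:
            return labels, resp
        return labels

    def summary(self) -> str:
        return "\n".join([
            "PLS-DA",
            "=" * 40,
            f"classes: {list(self.classes)}",
            f"components: {self.n_components}",
        ])


def fit_plsda(x, y, n_components: int = 2, *, scaling="unit-variance") -> PLSDAResults:
    return PLSDA(x, y, scaling=scaling).fit(n_components)


def predict(model, x_new):
    """Predict class labels from a fitted OPLS-DA or PLS-DA results object."""
    return model.predict(x_new)


# ---------------------------------------------------------------------------
# Model specification + component selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OplsDaSpec:
    """Refittable OPLS-DA specification for cross-validation loops.

    ``fit(x, y)`` re-estimates scaling from the training samples and returns
    a fitted :class:`OPLSDAResults`.
    """

    k_ortho: int = 0
    scaling: "str | None" = "unit-variance"
    threshold: float = 0.5
    classes: "tuple | None" = None

    def fit(self, x, y) -> OPLSDAResults:
        return OPLSDA(x, y, classes=self.classes, scaling=self.scaling,
                      threshold=self.threshold).fit(self.k_ortho)


def min_components_at_max(accuracies: Sequence[float]) -> int:
    """Smallest component count (1-based) attaining the maximal accuracy."""
    accs = list(accuracies)
    if not accs:
        raise ValueError("empty accuracy profile")
    best = max(accs)
    return accs.index(best) + 1


def select_components(x, y, max_total: int, criterion: "Callable[[int], float] | None" = None,
                      *, seed: int = 0, n_iterations: int = 20,
                      train_fraction: float = 0.9,
                      scaling: "str | None" = "unit-variance") -> int:
    """Choose the total component count: fewest components at maximal accuracy.

    ``criterion(n_total)`` returns an accuracy for a model with ``n_total``
    components (1 predictive + ``n_total - 1`` orthogonal); the default is
    mean Monte-Carlo cross-validated accuracy.
    """
    if max_total < 1:
        raise ValueError("max_total must be >= 1")
    if criterion is None:
        from .validation import monte_carlo_cv

        def criterion(n_total: int) -> float:
            spec = OplsDaSpec(k_ortho=n_total - 1, scaling=scaling)
            res = monte_carlo_cv(x, y, spec, n_iterations=n_iterations,
                                 train_fraction=train_fraction, seed=seed)
            return res.mean_performance.accuracy

    return min_components_at_max([criterion(n) for n in range(1, max_total + 1)])
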