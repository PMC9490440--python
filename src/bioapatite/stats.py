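"""The chemometric battery: scaling, regression against PMI, PCA, LDA and
MANOVA with pairwise multivariate post hoc comparisons.

Implementation notes.  Wilks' lambda is computed from the within/between
scatter determinant ratio with Rao's F approximation (exact for <= 2
features or <= 3 groups); pairwise comparisons are two-group Hotelling T^2
tests with Holm adjustment across pairs (Bonferroni switchable).  The
regression p-value is two-sided by default even though the stated null is
directional, because significant negative correlations are reported as
rejections in this literature; a one-sided mode is available.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA as _SkPCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .errors import (
    DegenerateDesignError,
    InsufficientClassError,
    InsufficientDataError,
    SingularDesignError,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

def zscore_scale(matrix) -> np.ndarray | pd.DataFrame:
    """Column-wise z-scoring with the n-1 SD.

    Zero-variance columns pass through as zeros with a warning.
    """
    X = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InsufficientDataError("scaling needs at least 2 rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = sd == 0
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} zero-variance column(s) scaled to zeros",
                      stacklevel=2)
    safe_sd = np.where(zero, 1.0, sd)
    Z = (X - mean) / safe_sd
    Z[:, zero] = 0.0
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(Z, index=matrix.index, columns=matrix.columns)
    return Z


# ---------------------------------------------------------------------------
# regression vs PMI
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p: float
    n: int


def linregress_vs_pmi(
    x,
    y,
    alternative: Literal["two-sided", "greater", "less"] = "two-sided",
    unit: Literal["sample", "group_mean"] = "sample",
) -> RegressionResult:
    """OLS of a parameter on PMI days; r is the Pearson correlation.

    ``unit="group_mean"`` collapses replicate observations at each PMI to
    their mean first (the group-level reading of small-N designs).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if unit == "group_mean":
        levels = np.unique(x)
        y = np.array([y[x == lv].mean() for lv in levels])
        x = levels
    if x.size < 3:
        raise InsufficientDataError("regression needs n >= 3")
    if np.all(x == x[0]):
        raise DegenerateDesignError("PMI predictor is constant")
    res = sps.linregress(x, y, alternative=alternative)
    return RegressionResult(
        slope=float(res.slope), intercept=float(res.intercept),
        r=float(res.rvalue), p=float(res.pvalue), n=int(x.size),
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    explained_pct: np.ndarray  # per component, sums to 100 over all
    loadings: pd.DataFrame     # features x components, unit-norm columns
    scores: np.ndarray         # samples x components
    feature_names: list[str] = field(default_factory=list)


def pca(matrix, n_components: int | None = None) -> PcaResult:
    """PCA of (already scaled) data with a deterministic sign convention:
    the largest-magnitude loading of each component is positive."""
    names = list(matrix.columns) if isinstance(matrix, pd.DataFrame) else None
    X = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InsufficientDataError("PCA needs at least 2 rows")
    model = _SkPCA(n_components=n_components)
    scores = model.fit_transform(X)
    components = model.components_  # (k, p), rows unit norm
    for i in range(components.shape[0]):
        j = np.argmax(np.abs(components[i]))
        if components[i, j] < 0:
            components[i] *= -1.0
            scores[:, i] *= -1.0
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    loadings = pd.DataFrame(
        components.T, index=names,
        columns=[f"PC{i + 1}" for i in range(components.shape[0])],
    )
    return PcaResult(
        explained_pct=model.explained_variance_ratio_ * 100.0,
        loadings=loadings, scores=scores, feature_names=names,
    )


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

@dataclass
class LdaResult:
    classes: np.ndarray
    coefficients: pd.DataFrame   # features x discriminants (scalings)
    scores: np.ndarray           # samples x discriminants
    posteriors: np.ndarray       # samples x classes, rows sum to 1
    predictions: np.ndarray
    accuracy: float
    model: LinearDiscriminantAnalysis


def lda(matrix, labels, ridge: float | None = None) -> LdaResult:
    """Fisher discriminants with pooled-covariance Gaussian posteriors.

    A singular within-class scatter is handled by refitting with a small
    ridge shrinkage on the pooled covariance.
    """
    names = list(matrix.columns) if isinstance(matrix, pd.DataFrame) else None
    X = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise InsufficientClassError("LDA needs >= 2 classes")
    if np.any(counts < 2):
        small = classes[counts < 2].tolist()
        raise InsufficientClassError(f"class(es) with < 2 samples: {small}")
    try:
        model = LinearDiscriminantAnalysis(solver="svd")
        model.fit(X, y)
        scores = model.transform(X)
    except np.linalg.LinAlgError:
        shrink = ridge if ridge is not None else 1e-6
        log.warning("singular within-class scatter; refitting with shrinkage %.2g", shrink)
        model = LinearDiscriminantAnalysis(solver="eigen", shrinkage=shrink)
        model.fit(X, y)
        scores = model.transform(X)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    coef = pd.DataFrame(
        model.scalings_[:, : scores.shape[1]], index=names,
        columns=[f"LD{i + 1}" for i in range(scores.shape[1])],
    )
    posteriors = model.predict_proba(X)
    predictions = model.predict(X)
    return LdaResult(
        classes=model.classes_, coefficients=coef, scores=scores,
        posteriors=posteriors, predictions=predictions,
        accuracy=float(np.mean(predictions == y)), model=model,
    )


# ---------------------------------------------------------------------------
# MANOVA + pairwise MCT
# ---------------------------------------------------------------------------

@dataclass
class ManovaResult:
    wilks_lambda: float
    f_stat: float
    df1: float
    df2: float
    p: float
    pairwise: pd.DataFrame  # group_a, group_b, t2, p_raw, p_adj
    alpha: float


def _scatter_matrices(X: np.ndarray, y: np.ndarray):
    grand = X.mean(axis=0)
    classes = np.unique(y)
    p = X.shape[1]
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for c in classes:
        sub = X[y == c]
        mu = sub.mean(axis=0)
        d = sub - mu
        W += d.T @ d
        g = (mu - grand)[:, None]
        B += sub.shape[0] * (g @ g.T)
    return W, B, classes


def wilks_lambda(X, y) -> float:
    """det(W) / det(W + B) — the likelihood-ratio MANOVA statistic."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    W, B, _ = _scatter_matrices(X, y)
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(W + B)
    if sign_w <= 0 or sign_t <= 0:
        raise SingularDesignError(
            "within-group scatter is singular; reduce features or add samples"
        )
    return float(np.exp(logdet_w - logdet_t))


def hotelling_t2(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample Hotelling T^2 with its exact F-distribution p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.shape[0], b.shape[0]
    p = a.shape[1]
    if n1 + n2 - p - 1 <= 0:
        raise InsufficientDataError("too few samples for Hotelling T^2")
    d = a.mean(axis=0) - b.mean(axis=0)
    S = ((n1 - 1) * np.cov(a, rowvar=False, ddof=1)
         + (n2 - 1) * np.cov(b, rowvar=False, ddof=1)) / (n1 + n2 - 2)
    S = np.atleast_2d(S)
    try:
        sol = np.linalg.solve(S, d)
    except np.linalg.LinAlgError:
        raise SingularDesignError("pooled covariance is singular") from None
    t2 = (n1 * n2 / (n1 + n2)) * float(d @ sol)
    f = t2 * (n1 + n2 - p - 1) / (p * (n1 + n2 - 2))
    p_val = float(sps.f.sf(f, p, n1 + n2 - p - 1))
    return t2, p_val


def _holm(p_raw: np.ndarray) -> np.ndarray:
    order = np.argsort(p_raw)
    m = p_raw.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p_raw[idx])
        adj[idx] = min(1.0, running)
    return adj


def manova_with_mct(
    matrix,
    groups,
    alpha: float = 0.05,
    method: Literal["holm", "bonferroni"] = "holm",
) -> ManovaResult:
    """Wilks'-lambda MANOVA (Rao's F) plus pairwise Hotelling T^2 post hocs.

    Adjusted p-values use Holm's step-down procedure by default.
    """
    X = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    y = np.asarray(groups)
    classes = np.unique(y)
    g = classes.size
    n, p = X.shape
    if g < 2:
        raise InsufficientDataError("MANOVA needs >= 2 groups")
    if n <= p + g:
        raise InsufficientDataError("MANOVA needs total n > features + groups")
    lam = wilks_lambda(X, y)
    q = g - 1
    v = n - g
    if p * p + q * q - 5 > 0:
        s = np.sqrt((p * p * q * q - 4.0) / (p * p + q * q - 5.0))
    else:
        s = 1.0
    df1 = p * q
    w = n - 1 - (p + g) / 2.0
    df2 = w * s - (p * q - 2.0) / 2.0
    lam_s = lam ** (1.0 / s)
    f_stat = ((1.0 - lam_s) / lam_s) * (df2 / df1)
    p_global = float(sps.f.sf(f_stat, df1, df2))

    rows = []
    for a, b in itertools.combinations(classes, 2):
        try:
            t2, pv = hotelling_t2(X[y == a], X[y == b])
        except (InsufficientDataError, SingularDesignError) as exc:
            # tiny groups cannot support a p-dimensional T^2; report nan
            log.warning("pair (%s, %s): %s; p set to nan", a, b, exc)
            t2, pv = np.nan, np.nan
        rows.append({"group_a": a, "group_b": b, "t2": t2, "p_raw": pv})
    pairwise = pd.DataFrame(rows)
    feasible = pairwise["p_raw"].notna().to_numpy()
    p_adj = np.full(len(pairwise), np.nan)
    if feasible.any():
        p_raw_arr = pairwise.loc[feasible, "p_raw"].to_numpy()
        if method == "holm":
            p_adj[feasible] = _holm(p_raw_arr)
        elif method == "bonferroni":
            p_adj[feasible] = np.minimum(1.0, p_raw_arr * p_raw_arr.size)
        else:
            raise ValueError(f"unknown MCT method {method!r}")
    pairwise["p_adj"] = p_adj
    pairwise["significant"] = pairwise["p_adj"] < alpha
    return ManovaResult(
        wilks_lambda=lam, f_stat=float(f_stat), df1=float(df1), df2=float(df2),
        p=p_global, pairwise=pairwise, alpha=alpha,
    )
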