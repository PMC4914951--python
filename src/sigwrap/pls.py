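"""PLS-DA with a NIPALS engine, automatic component selection and VIP.

The binary response is coded numerically (+0.5 / -0.5), features are
mean-centered and unit-variance scaled, and PLS1 components are extracted
sequentially by NIPALS with deflation.  A new component h is admitted while

* R2Y_h >= 1% of the response variance, and
* Q2Y_h = 1 - PRESS_h / RSS_{h-1} >= 0 (>= 0.05 when n < 100),

with PRESS_h estimated by stratified 7-fold cross-validation and
RSS_0 = (n - 1) * var(y).  The cumulative predictive metric is
Q2Y = 1 - prod_h (1 - Q2Y_h) over the admitted components.

When no component at all is admitted the model is flagged non-informative:
a single component is still extracted so feature ranking (VIP) remains
defined, but predictions fall back to the training majority class and the
reported Q2Y is the (typically negative) Q2Y_1 of that forced component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BinaryLabels, FeatureTable, encode_labels

__all__ = ["ScalingParams", "PlsModel", "fit_plsda", "predict_plsda", "vip"]

MAX_COMPONENTS = 10  # hard cap; the admission rule stops far earlier in practice


@dataclass(frozen=True)
class ScalingParams:
    """Per-feature mean and sd estimated on a training set.

    Zero-variance features keep divisor 1 so scaling stays defined on
    degenerate inputs; their indices are recorded in ``constant``.
    """

    mean: np.ndarray
    sd: np.ndarray
    constant: tuple[int, ...] = ()

    @classmethod
    def fit(cls, values: np.ndarray) -> "ScalingParams":
        mean = values.mean(axis=0)
        sd = values.std(axis=0, ddof=1) if values.shape[0] > 1 else np.zeros(values.shape[1])
        constant = tuple(int(j) for j in np.flatnonzero(sd == 0.0))
        sd = np.where(sd == 0.0, 1.0, sd)
        return cls(mean=mean, sd=sd, constant=constant)

    def apply(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mean) / self.sd


@dataclass
class PlsModel:
    """Fitted PLS-DA model (see module docstring for the component rule)."""

    r: int
    weights: np.ndarray        # p x r, unit-norm NIPALS weight vectors w_h
    loadings: np.ndarray       # p x r, x-loadings p_h
    scores: np.ndarray         # n x r, scores t_h
    y_loadings: np.ndarray     # r, y-loadings c_h
    coef: np.ndarray           # p, regression coefficients on the scaled space
    r2y: np.ndarray            # r, per-component R2Y_h
    q2y: np.ndarray            # r, per-component Q2Y_h
    press: np.ndarray          # r, per-component PRESS_h
    rss: np.ndarray            # r + 1, RSS_0 .. RSS_r
    q2y_cum: float             # cumulative Q2Y (see module docstring)
    scaling: ScalingParams = None  # type: ignore[assignment]
    y_mean: float = 0.0
    informative: bool = True
    majority_positive: bool = False  # majority fallback predicts the positive level
    feature_ids: tuple[str, ...] = ()
    positive_level: str = ""
    negative_level: str = ""

    @property
    def vip_(self) -> np.ndarray:
        return vip(self)


def _stratified_folds(y01: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment (0..k-1) stratified by class; every class with >= 2
    members spans >= 2 folds, so each training split keeps both classes."""
    n = len(y01)
    fold = np.empty(n, dtype=int)
    offset = 0
    for cls in (0, 1):
        idx = np.flatnonzero(y01 == cls)
        idx = rng.permutation(idx)
        for pos, i in enumerate(idx):
            fold[i] = (offset + pos) % k
        offset += len(idx)
    return fold


def _nipals(Xd: np.ndarray, yd: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """One PLS1 component on (deflated) data: returns (w, t, p, c).

    With a univariate response NIPALS converges in a single pass:
    w = X'y / ||X'y||.
    """
    w = Xd.T @ yd
    norm = np.linalg.norm(w)
    if norm == 0.0:
        # No covariance left (degenerate, e.g. constant features): arbitrary
        # but deterministic unit direction.
        w = np.zeros(Xd.shape[1])
        w[0] = 1.0
    else:
        w = w / norm
    t = Xd @ w
    tt = float(t @ t)
    if tt == 0.0:
        return w, t, np.zeros(Xd.shape[1]), 0.0
    p = Xd.T @ t / tt
    c = float(t @ yd / tt)
    return w, t, p, c


def _fit_components(Xs: np.ndarray, yc: np.ndarray, r: int):
    """Extract r PLS1 components with deflation of X and y."""
    n, p = Xs.shape
    W = np.zeros((p, r))
    P = np.zeros((p, r))
    T = np.zeros((n, r))
    C = np.zeros(r)
    Xd = Xs.copy()
    yd = yc.copy()
    for h in range(r):
        w, t, pl, c = _nipals(Xd, yd)
        W[:, h] = w
        T[:, h] = t
        P[:, h] = pl
        C[h] = c
        Xd = Xd - np.outer(t, pl)
        yd = yd - c * t
    return W, P, T, C


def _coefficients(W: np.ndarray, P: np.ndarray, C: np.ndarray) -> np.ndarray:
    """B = W (P'W)^-1 C for the scaled space."""
    r = W.shape[1]
    if r == 0:
        return np.zeros(W.shape[0])
    M = P.T @ W
    return W @ np.linalg.solve(M, C[:r])


def _cv_press(
    Xs: np.ndarray, yc: np.ndarray, h: int, fold: np.ndarray, k: int
) -> float:
    """PRESS for an h-component model by k-fold cross-validation on the
    globally scaled matrix (scaling is estimated once on the full training
    set, as in the standard workflow)."""
    press = 0.0
    for f in range(k):
        test = fold == f
        train = ~test
        y_tr = yc[train]
        mu = float(y_tr.mean())
        W, P, _, C = _fit_components(Xs[train], y_tr - mu, h)
        coef = _coefficients(W, P, C)
        pred = Xs[test] @ coef + mu
        press += float(np.sum((yc[test] - pred) ** 2))
    return press


def fit_plsda(
    train: FeatureTable,
    labels: BinaryLabels,
    *,
    n_folds: int = 7,
    seed: int = 0,
) -> PlsModel:
    """Fit a PLS-DA model with automatic component selection.

    ``seed`` drives the stratification of the cross-validation folds only;
    the NIPALS fit itself is fully deterministic.
    """
    if train.p < 1:
        raise ValueError("cannot fit PLS-DA on a zero-feature table")
    n = train.n
    y = encode_labels(labels)
    y01 = labels.as_binary()
    # fold stratification keys on lexicographic level order so the fit (and
    # hence Q2Y) is invariant to which class is declared positive
    hi_level = sorted(set(labels.labels))[1]
    strat = np.asarray([1 if x == hi_level else 0 for x in labels.labels])
    scaling = ScalingParams.fit(train.values)
    Xs = scaling.apply(train.values)
    y_mean = float(y.mean())
    yc = y - y_mean
    ssy0 = float(np.sum(yc**2))  # = (n - 1) var(y) = RSS_0

    k = min(n_folds, n)
    rng = np.random.default_rng(seed)
    fold = _stratified_folds(strat, k, rng)

    q2_threshold = 0.0 if n >= 100 else 0.05
    max_r = min(MAX_COMPONENTS, n - 1, train.p)

    r2y_list: list[float] = []
    q2y_list: list[float] = []
    press_list: list[float] = []
    rss_list: list[float] = [ssy0]
    r = 0
    while r < max_r:
        h = r + 1
        W, P, T, C = _fit_components(Xs, yc, h)
        ss_h = C[r] ** 2 * float(T[:, r] @ T[:, r])
        r2y_h = ss_h / ssy0 if ssy0 > 0 else 0.0
        press_h = _cv_press(Xs, yc, h, fold, k)
        rss_prev = rss_list[-1]
        q2y_h = 1.0 - press_h / rss_prev if rss_prev > 0 else -np.inf
        if r2y_h >= 0.01 and q2y_h >= q2_threshold:
            coef = _coefficients(W, P, C)
            rss_h = float(np.sum((yc - Xs @ coef) ** 2))
            r2y_list.append(r2y_h)
            q2y_list.append(q2y_h)
            press_list.append(press_h)
            rss_list.append(rss_h)
            r = h
        else:
            break

    informative = r >= 1
    if informative:
        W, P, T, C = _fit_components(Xs, yc, r)
        q2y_arr = np.array(q2y_list)
        q2y_cum = float(1.0 - np.prod(1.0 - q2y_arr))
        r2y_arr = np.array(r2y_list)
        press_arr = np.array(press_list)
    else:
        # Forced single component: keeps VIP ranking defined; predictions
        # will use the majority fallback.
        r = 1
        W, P, T, C = _fit_components(Xs, yc, 1)
        ss_1 = C[0] ** 2 * float(T[:, 0] @ T[:, 0])
        r2y_arr = np.array([ss_1 / ssy0 if ssy0 > 0 else 0.0])
        press_1 = _cv_press(Xs, yc, 1, fold, k)
        q2_1 = 1.0 - press_1 / ssy0 if ssy0 > 0 else -np.inf
        q2y_arr = np.array([q2_1])
        press_arr = np.array([press_1])
        coef = _coefficients(W, P, C)
        rss_list = [ssy0, float(np.sum((yc - Xs @ coef) ** 2))]
        q2y_cum = float(q2_1)

    coef = _coefficients(W, P, C)
    n_pos = int(y01.sum())
    return PlsModel(
        r=r,
        weights=W,
        loadings=P,
        scores=T,
        y_loadings=C,
        coef=coef,
        r2y=r2y_arr,
        q2y=q2y_arr,
        press=press_arr,
        rss=np.array(rss_list),
        q2y_cum=q2y_cum,
        scaling=scaling,
        y_mean=y_mean,
        informative=informative,
        majority_positive=2 * n_pos >= n,  # tie -> positive level
        feature_ids=train.feature_ids,
        positive_level=labels.positive_level,
        negative_level=labels.negative_level,
    )


def decision_values(model: PlsModel, values: np.ndarray) -> np.ndarray:
    """Continuous predictions y_hat on the +-0.5 scale."""
    Xs = model.scaling.apply(values)
    return Xs @ model.coef + model.y_mean


def predict_plsda(model: PlsModel, test: FeatureTable) -> tuple[str, ...]:
    """Predicted class labels; y_hat > 0 maps to the positive level (an exact
    0 maps to the negative level).  Non-informative models predict the
    training majority class."""
    if test.feature_ids != model.feature_ids:
        raise ValueError("test features do not match the training features")
    if not model.informative:
        level = model.positive_level if model.majority_positive else model.negative_level
        return tuple(level for _ in range(test.n))
    yhat = decision_values(model, test.values)
    return tuple(
        model.positive_level if v > 0 else model.negative_level for v in yhat
    )


def vip(model: PlsModel) -> np.ndarray:
    """Variable Importance in Projection.

    VIP_j = sqrt( p * sum_h SS_h (w_jh / ||w_h||)^2 / sum_h SS_h ) with
    SS_h = c_h^2 (t_h' t_h), the response sum of squares explained by
    component h.  By construction sum_j VIP_j^2 = p.
    """
    if model.r < 1:
        raise ValueError("VIP requires at least one component")
    p = model.weights.shape[0]
    ss = model.y_loadings[: model.r] ** 2 * np.einsum(
        "ij,ij->j", model.scores[:, : model.r], model.scores[:, : model.r]
    )
    wnorm = np.linalg.norm(model.weights[:, : model.r], axis=0)
    wnorm = np.where(wnorm == 0.0, 1.0, wnorm)
    w2 = (model.weights[:, : model.r] / wnorm) ** 2
    denom = float(ss.sum())
    if denom == 0.0:
        return np.ones(p)
    return np.sqrt(p * (w2 @ ss) / denom)
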