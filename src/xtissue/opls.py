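"""Orthogonal projections to latent structures (OPLS) regression and OPLS-DA.

Single predictive component plus ``n_ortho`` response-orthogonal components,
fit by orthogonal signal deflation: the predictive weight is w ∝ X'y; each
orthogonal component removes from X the part of the loading p* = X't/(t't)
that is orthogonal to w.  Variable importance (VIP) is computed on the
predictive component, so mean(VIP^2) = 1 exactly.  Model validation uses
Monte-Carlo cross-validation (random holdouts) with a permutation ``q-value``
on Q^2, and AUROC for the discriminant case.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "OPLSModel",
    "CVResult",
    "ROCResult",
    "fit_opls",
    "fit_oplsda",
    "vip",
    "cross_validate",
    "auroc",
]


@dataclass
class OPLSModel:
    predictor_ids: list[str]
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    w: np.ndarray                 # predictive weights, unit norm
    p_load: np.ndarray            # predictive loadings
    t: np.ndarray                 # predictive scores (training)
    b: float                      # regression coefficient of y on t
    w_ortho: np.ndarray           # (p, n_ortho)
    p_ortho: np.ndarray           # (p, n_ortho)
    t_ortho: np.ndarray           # (n, n_ortho)
    n_ortho: int
    r2x: float
    r2y: float
    vip: np.ndarray
    is_discriminant: bool = False
    dropped_predictors: list[str] = field(default_factory=list)

    def transform(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        """Predictive scores t for new samples (after orthogonal filtering)."""
        Z = np.asarray(X, dtype=float)
        Z = (Z - self.x_mean) / self.x_scale
        for k in range(self.n_ortho):
            t_o = Z @ self.w_ortho[:, k]
            Z = Z - np.outer(t_o, self.p_ortho[:, k])
        return Z @ self.w

    def predict(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        return self.y_mean + self.b * self.transform(X)

    def decision_scores(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        """Classification scores (t * b) for the discriminant case."""
        return self.b * self.transform(X)


@dataclass
class CVResult:
    q2: float
    n_repeats: int
    q_value: float
    q2_null_mean: float
    q2_null_sd: float
    q2_null_quantiles: dict[str, float]
    n_permutations: int
    seed: int
    n_degenerate_resampled: int = 0


@dataclass
class ROCResult:
    auroc: float
    n_pos: int
    n_neg: int


def _prepare_xy(X, y):
    if isinstance(X, pd.DataFrame):
        ids = [str(c) for c in X.columns]
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        ids = [f"x{j}" for j in range(Xv.shape[1])]
    yv = np.asarray(y, dtype=float).ravel()
    if Xv.shape[0] != yv.size:
        raise ValueError("X and y have incompatible shapes")
    return Xv, yv, ids


def fit_opls(X, y, n_ortho: int = 1) -> OPLSModel:
    """Fit an OPLS model with one predictive and ``n_ortho`` orthogonal components.

    X is centered and unit-variance scaled; y is centered.  Constant
    predictors are dropped with a warning.
    """
    Xv, yv, ids = _prepare_xy(X, y)
    n, p = Xv.shape
    if n < 5:
        raise ValueError("need at least 5 samples")
    if np.std(yv) == 0:
        raise ValueError("y has zero variance")
    if n_ortho < 0:
        raise ValueError("n_ortho must be >= 0")
    if n_ortho >= min(n - 1, p):
        raise ValueError(f"n_ortho={n_ortho} is not below the rank bound min(n-1, p)")

    scale_full = Xv.std(axis=0, ddof=1)
    keep = scale_full > 0
    dropped = [ids[j] for j in np.flatnonzero(~keep)]
    if dropped:
        logger.warning("dropping %d constant predictor(s)", len(dropped))
        Xv = Xv[:, keep]
        ids = [ids[j] for j in np.flatnonzero(keep)]
        p = Xv.shape[1]
        if p == 0:
            raise ValueError("all predictors are constant")

    x_mean = Xv.mean(axis=0)
    x_scale = Xv.std(axis=0, ddof=1)
    Z0 = (Xv - x_mean) / x_scale
    y_mean = float(yv.mean())
    yc = yv - y_mean

    w = Z0.T @ yc
    w = w / np.linalg.norm(w)

    Z = Z0
    W_o = np.zeros((p, n_ortho))
    P_o = np.zeros((p, n_ortho))
    T_o = np.zeros((n, n_ortho))
    for k in range(n_ortho):
        t = Z @ w
        p_star = Z.T @ t / (t @ t)
        w_o = p_star - (w @ p_star) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            raise ValueError(
                f"no orthogonal variation left for component {k + 1}; reduce n_ortho"
            )
        w_o = w_o / norm
        t_o = Z @ w_o
        p_o = Z.T @ t_o / (t_o @ t_o)
        Z = Z - np.outer(t_o, p_o)
        W_o[:, k], P_o[:, k], T_o[:, k] = w_o, p_o, t_o

    t = Z @ w
    b = float(t @ yc / (t @ t))
    p_load = Z.T @ t / (t @ t)
    resid = yc - b * t
    r2y = float(1.0 - (resid @ resid) / (yc @ yc))

    X_hat = np.outer(t, p_load) + T_o @ P_o.T
    ssx = float(np.sum(Z0**2))
    r2x = float(1.0 - np.sum((Z0 - X_hat) ** 2) / ssx) if ssx > 0 else 0.0

    vip_vec = np.sqrt(p) * np.abs(w)  # ||w|| = 1, so mean(vip^2) = 1
    return OPLSModel(
        predictor_ids=ids,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        w=w,
        p_load=p_load,
        t=t,
        b=b,
        w_ortho=W_o,
        p_ortho=P_o,
        t_ortho=T_o,
        n_ortho=n_ortho,
        r2x=r2x,
        r2y=r2y,
        vip=vip_vec,
        dropped_predictors=dropped,
    )


def fit_oplsda(X, class_labels, n_ortho: int = 1) -> OPLSModel:
    """OPLS discriminant analysis: binary classes encoded as a 0/1 dummy response."""
    labels = np.asarray(class_labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"OPLS-DA needs exactly 2 classes, got {classes.size}")
    y = (labels == classes[1]).astype(float)
    if y.sum() < 3 or (1 - y).sum() < 3:
        raise ValueError("each class needs at least 3 samples")
    model = fit_opls(X, y, n_ortho=n_ortho)
    model.is_discriminant = True
    return model


def vip(model: OPLSModel) -> pd.Series:
    """Variable Importance in Projection of the predictive component.

    VIP_j = sqrt(p) * |w_j| / ||w||, hence sum(VIP^2) = p exactly.
    """
    return pd.Series(model.vip, index=model.predictor_ids, name="vip")


def _mc_cv_q2_batch(
    X: np.ndarray,
    Y: np.ndarray,
    splits: list[np.ndarray],
    n_ortho: int,
) -> np.ndarray:
    """Q^2 per response column of Y under shared Monte-Carlo holdout splits.

    Vectorized over columns for n_ortho in {0, 1} (deflation never needs the
    per-column deflated X explicitly: with one orthogonal component the
    predictive score is t = Xw - t_o * (p_o'w), for training and test alike).
    """
    n = X.shape[0]
    press = np.zeros(Y.shape[1])
    tss = np.zeros(Y.shape[1])
    for test_idx in splits:
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        Xtr, Xte = X[mask], X[test_idx]
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Ztr = (Xtr - mu) / sd
        Zte = (Xte - mu) / sd
        Ytr = Y[mask]
        Yte = Y[test_idx]
        ym = Ytr.mean(axis=0)
        Yc = Ytr - ym

        W = Ztr.T @ Yc                                  # (p, B)
        norms = np.linalg.norm(W, axis=0)
        norms[norms == 0] = 1.0
        W = W / norms
        T = Ztr @ W                                     # (ntr, B)
        Tte = Zte @ W
        if n_ortho == 1:
            c2 = np.einsum("ij,ij->j", T, T)
            Pstar = Ztr.T @ T / c2
            Wo = Pstar - W * np.einsum("ij,ij->j", W, Pstar)
            onorm = np.linalg.norm(Wo, axis=0)
            ok = onorm > 1e-12
            onorm[~ok] = 1.0
            Wo = Wo / onorm
            To = Ztr @ Wo
            to2 = np.einsum("ij,ij->j", To, To)
            to2[to2 == 0] = 1.0
            Po = Ztr.T @ To / to2
            alpha = np.einsum("ij,ij->j", Po, W)
            alpha[~ok] = 0.0
            T = T - To * alpha
            Tte = Tte - (Zte @ Wo) * alpha
        b = np.einsum("ij,ij->j", T, Yc) / np.einsum("ij,ij->j", T, T)
        Yhat = ym + Tte * b
        press += np.sum((Yte - Yhat) ** 2, axis=0)
        tss += np.sum((Yte - ym) ** 2, axis=0)
    return 1.0 - press / tss


def cross_validate(
    X,
    y,
    n_repeats: int = 1000,
    holdout_fraction: float = 1.0 / 7.0,
    n_permutations: int = 1000,
    seed: int = 0,
    n_ortho: int = 1,
) -> CVResult:
    """Monte-Carlo cross-validation with a permutation q-value on Q^2.

    ``n_repeats`` random holdouts of ``holdout_fraction`` of the samples;
    Q^2 = 1 - PRESS/TSS aggregated over repeats.  The q-value is the
    add-one-smoothed fraction of y-permutations whose Q^2 (under the same
    holdout splits) reaches the observed Q^2.
    """
    Xv, yv, _ = _prepare_xy(X, y)
    n = Xv.shape[0]
    h = max(2, int(round(n * holdout_fraction)))
    if h >= n:
        raise ValueError("holdout would contain every sample")
    rng = np.random.default_rng(seed)

    splits = []
    n_degenerate = 0
    while len(splits) < n_repeats:
        idx = rng.permutation(n)[:h]
        if np.ptp(np.delete(yv, idx)) == 0:
            n_degenerate += 1
            if n_degenerate > 100 * n_repeats:
                raise ValueError("could not draw holdouts with non-constant training y")
            warnings.warn("resampled a holdout that left training y constant")
            continue
        splits.append(idx)

    perms = np.column_stack([yv] + [rng.permutation(yv) for _ in range(n_permutations)])
    if n_ortho in (0, 1):
        q2_all = _mc_cv_q2_batch(Xv, perms, splits, n_ortho)
    else:  # general n_ortho: per-column model fits
        press = np.zeros(perms.shape[1])
        tss = np.zeros(perms.shape[1])
        for test_idx in splits:
            mask = np.ones(n, dtype=bool)
            mask[test_idx] = False
            for j in range(perms.shape[1]):
                m = fit_opls(Xv[mask], perms[mask, j], n_ortho=n_ortho)
                yhat = m.predict(Xv[test_idx])
                press[j] += np.sum((perms[test_idx, j] - yhat) ** 2)
                tss[j] += np.sum((perms[test_idx, j] - perms[mask, j].mean()) ** 2)
        q2_all = 1.0 - press / tss

    q2 = float(q2_all[0])
    null = q2_all[1:]
    if n_permutations > 0:
        q_value = float((1 + np.sum(null >= q2)) / (1 + n_permutations))
        qs = np.quantile(null, [0.05, 0.5, 0.95])
        null_summary = (float(null.mean()), float(null.std(ddof=1)),
                        {"q05": float(qs[0]), "q50": float(qs[1]), "q95": float(qs[2])})
    else:
        q_value = float("nan")
        null_summary = (float("nan"), float("nan"), {})
    return CVResult(
        q2=q2,
        n_repeats=n_repeats,
        q_value=q_value,
        q2_null_mean=null_summary[0],
        q2_null_sd=null_summary[1],
        q2_null_quantiles=null_summary[2],
        n_permutations=n_permutations,
        seed=seed,
        n_degenerate_resampled=n_degenerate,
    )


def auroc(scores, labels) -> ROCResult:
    """Area under the ROC curve via the Mann-Whitney identity (ties count 1/2)."""
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    classes = np.unique(lab)
    if classes.size != 2:
        raise ValueError("AUROC needs exactly 2 classes")
    pos = lab == classes[1]
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(s)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return ROCResult(auroc=float(u / (n_pos * n_neg)), n_pos=n_pos, n_neg=n_neg)
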