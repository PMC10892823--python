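"""PCA, PCA-LDA classification and NIPALS PLSR with replicate-based validation.

The validation scheme throughout is *leave-one-replicate-out*: samples
were prepared in triplicate, and the three cross-validation folds are
defined by the replicate index (train on two replicates, predict the
third, rotate), so fold assignment is deterministic and no fold ever
mixes preparations of the same mixture.

PLSR is single-response (PLS1) NIPALS with deflation; the regression
vector is b = W (PᵀW)⁻¹ q on centered data. PCA-LDA uses a pooled
within-class covariance discriminant on the leading PCA scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .preprocess import PretreatmentChain
from .simulate import SpectralDataset

__all__ = [
    "PCAModel",
    "LDAResult",
    "PLSRModel",
    "fit_pca",
    "lda_classify",
    "fit_plsr",
    "cross_validate_plsr",
    "test_set_predict",
    "optimize_model",
]

logger = logging.getLogger(__name__)

_RANK_TOL = 1e-12


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAModel:
    mean: np.ndarray
    loadings: np.ndarray  # wavelengths × components, orthonormal columns
    scores: np.ndarray  # samples × components
    explained_variance_ratio: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) @ self.loadings


def fit_pca(X: np.ndarray, n_components: int) -> PCAModel:
    """Mean-centered PCA by singular value decomposition.

    Sign convention: in each loading vector the element of largest
    magnitude is made positive, so decompositions are deterministic.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples-1, n_features)"
            f"={min(n - 1, p)}"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: flip so the largest-|.| loading entry is positive
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    var = s**2 / max(n - 1, 1)
    total = var.sum()
    ratios = var / total if total > 0 else np.zeros_like(var)
    V = Vt[:n_components].T
    return PCAModel(
        mean=mean,
        loadings=V,
        scores=U[:, :n_components] * s[:n_components],
        explained_variance_ratio=ratios[:n_components],
    )


# ---------------------------------------------------------------------------
# PCA-LDA with replicate-stratified cross-validation


@dataclass
class LDAResult:
    n_pcs: int
    classes: np.ndarray
    confusion_calibration: np.ndarray
    confusion_cv: np.ndarray
    recognition_pct: float  # calibration accuracy, sample-weighted
    prediction_pct: float  # cross-validated accuracy, sample-weighted
    scores: np.ndarray | None = None


class _PooledLDA:
    """Linear discriminant with pooled within-class covariance."""

    def fit(self, Z: np.ndarray, labels: np.ndarray) -> "_PooledLDA":
        self.classes_ = np.unique(labels)
        n, d = Z.shape
        means = np.vstack([Z[labels == c].mean(axis=0) for c in self.classes_])
        Sw = np.zeros((d, d))
        for c, mu in zip(self.classes_, means):
            R = Z[labels == c] - mu
            Sw += R.T @ R
        dof = n - len(self.classes_)
        if dof <= 0:
            raise ValueError("not enough samples per class for LDA")
        Sw /= dof
        try:
            Sw_inv = np.linalg.inv(Sw)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular within-class scatter; reduce n_pcs below the "
                "per-class sample count"
            ) from exc
        cond = np.linalg.cond(Sw)
        if not np.isfinite(cond) or cond > 1e12:
            raise ValueError(
                "near-singular within-class scatter; reduce n_pcs"
            )
        priors = np.array([(labels == c).mean() for c in self.classes_])
        self.coef_ = means @ Sw_inv  # k × d
        self.intercept_ = -0.5 * np.einsum("kd,kd->k", self.coef_, means) + np.log(priors)
        return self

    def decision(self, Z: np.ndarray) -> np.ndarray:
        return Z @ self.coef_.T + self.intercept_

    def predict(self, Z: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.decision(Z), axis=1)]


def _confusion(classes: np.ndarray, y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    M = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        M[idx[t], idx[p]] += 1
    return M


def lda_classify(
    dataset: SpectralDataset,
    labels: Sequence | None = None,
    n_pcs: int = 15,
    chain: PretreatmentChain | None = None,
) -> LDAResult:
    """PCA-LDA with replicate-stratified 3-fold cross-validation.

    The default grouping is the adulteration level (0–6, seven classes).
    Calibration (recognition) refits and predicts on all samples; the
    cross-validated (prediction) accuracy pools the three held-out
    replicate folds, so every sample appears in both training and test
    roles across the rotation.
    """
    ds = chain.apply(dataset) if chain is not None else dataset
    y = np.asarray(labels if labels is not None else ds.meta["level"].to_numpy())
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes")
    classes = np.unique(y)
    reps = ds.meta["replicate"].to_numpy()

    # calibration: fit and predict on the full set
    pca = fit_pca(ds.X, n_pcs)
    lda = _PooledLDA().fit(pca.scores, y)
    pred_cal = lda.predict(pca.scores)
    conf_cal = _confusion(classes, y, pred_cal)

    # replicate-stratified CV: hold out one replicate at a time
    pred_cv = np.empty_like(y)
    for rep in np.unique(reps):
        test = reps == rep
        train = ~test
        pca_f = fit_pca(ds.X[train], n_pcs)
        lda_f = _PooledLDA().fit(pca_f.scores, y[train])
        pred_cv[test] = lda_f.predict(pca_f.transform(ds.X[test]))
    conf_cv = _confusion(classes, y, pred_cv)

    return LDAResult(
        n_pcs=n_pcs,
        classes=classes,
        confusion_calibration=conf_cal,
        confusion_cv=conf_cv,
        recognition_pct=100.0 * np.trace(conf_cal) / len(y),
        prediction_pct=100.0 * np.trace(conf_cv) / len(y),
        scores=pca.scores,
    )


# ---------------------------------------------------------------------------
# NIPALS PLSR (single response)


@dataclass
class PLSRModel:
    """A fitted PLS1 model with its validation metrics.

    ``b`` maps a centered spectrum to a centered prediction:
    ŷ = y_mean + (x − x_mean)·b.
    """

    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray  # wavelength weights, p × n_lv
    P: np.ndarray  # X loadings, p × n_lv
    q: np.ndarray  # y loadings, n_lv
    T: np.ndarray  # scores, n × n_lv
    b: np.ndarray  # regression vector, p
    wavelengths: np.ndarray | None = None
    pretreatment: str = ""
    response: str = ""
    rmsec: float = float("nan")
    r2c: float = float("nan")
    rmsecv: float = float("nan")
    r2cv: float = float("nan")
    rmsep: float = float("nan")
    r2p: float = float("nan")

    def coefficients(self, n_lv: int | None = None) -> np.ndarray:
        """Regression vector using the first ``n_lv`` latent variables."""
        k = self.n_lv if n_lv is None else n_lv
        if not 1 <= k <= self.n_lv:
            raise ValueError(f"n_lv must be in 1..{self.n_lv}")
        Wk, Pk, qk = self.W[:, :k], self.P[:, :k], self.q[:k]
        return Wk @ np.linalg.solve(Pk.T @ Wk, qk)

    def predict(self, X: np.ndarray, n_lv: int | None = None) -> np.ndarray:
        b = self.b if n_lv is None else self.coefficients(n_lv)
        return self.y_mean + (np.asarray(X, dtype=float) - self.x_mean) @ b


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> PLSRModel:
    """NIPALS PLS1: iterative extraction of latent variables with deflation.

    Each round takes the weight vector w ∝ Xᵀu (u initialised to the
    centered response), scores t = Xw, loadings p = Xᵀt/tᵀt and
    q = yᵀt/tᵀt, then deflates X; for a single response the inner loop
    converges immediately but is iterated to ``tol`` for generality.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y row counts differ")
    if np.std(y) == 0:
        raise ValueError("zero-variance response")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    T = np.zeros((n, n_lv))
    q = np.zeros(n_lv)
    Xd, yd = Xc.copy(), yc.copy()
    for k in range(n_lv):
        u = yd
        w_old = None
        for _ in range(max_iter):
            w = Xd.T @ u
            norm = np.linalg.norm(w)
            if norm < _RANK_TOL:
                raise ValueError(
                    f"rank exhausted at latent variable {k + 1}: "
                    "reduce n_lv"
                )
            w /= norm
            t = Xd @ w
            tt = t @ t
            if tt < _RANK_TOL:
                raise ValueError(
                    f"degenerate score at latent variable {k + 1}: reduce n_lv"
                )
            qk = (yd @ t) / tt
            u_new = yd * qk
            if w_old is not None and np.linalg.norm(w - w_old) < tol:
                break
            w_old = w
            u = u_new
        else:
            raise RuntimeError(f"NIPALS failed to converge at LV {k + 1}")
        pk = Xd.T @ t / tt
        W[:, k], P[:, k], T[:, k], q[k] = w, pk, t, qk
        Xd = Xd - np.outer(t, pk)
        yd = yd - qk * t

    b = W @ np.linalg.solve(P.T @ W, q)
    model = PLSRModel(
        n_lv=n_lv, x_mean=x_mean, y_mean=y_mean, W=W, P=P, q=q, T=T, b=b
    )
    resid = yc - Xc @ b
    model.rmsec = float(np.sqrt(np.mean(resid**2)))
    sst = float(np.sum(yc**2))
    model.r2c = 1.0 - float(np.sum(resid**2)) / sst
    return model


def _fold_predictions(
    X: np.ndarray, y: np.ndarray, reps: np.ndarray, n_lv: int
) -> np.ndarray:
    """Held-out predictions for each LV count, leave-one-replicate-out.

    Returns an (n_samples, n_lv) array: column k−1 holds the prediction
    of each sample by the model trained without its replicate, using k
    latent variables.
    """
    preds = np.empty((len(y), n_lv))
    for rep in np.unique(reps):
        test = reps == rep
        model = fit_plsr(X[~test], y[~test], n_lv)
        for k in range(1, n_lv + 1):
            preds[test, k - 1] = model.predict(X[test], n_lv=k)
    return preds


def cross_validate_plsr(
    dataset: SpectralDataset,
    response: str,
    n_lv: int,
    chain: PretreatmentChain | None = None,
) -> tuple[float, float]:
    """Leave-one-replicate-out RMSECV and R²CV for one response.

    RMSECV pools the squared errors of all held-out predictions; R²CV is
    1 − SSE/SST with SST taken about the grand mean of the response.
    """
    ds = chain.apply(dataset) if chain is not None else dataset
    if "replicate" not in ds.meta.columns:
        raise ValueError("replicate metadata required for leave-one-replicate-out CV")
    y = ds.Y[response].to_numpy(dtype=float)
    if np.std(y) == 0:
        raise ValueError("constant response: R2CV undefined")
    reps = ds.meta["replicate"].to_numpy()
    preds = _fold_predictions(ds.X, y, reps, n_lv)[:, n_lv - 1]
    sse = float(np.sum((preds - y) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    return float(np.sqrt(sse / len(y))), 1.0 - sse / sst


def test_set_predict(
    dataset: SpectralDataset,
    response: str,
    n_lv: int,
    chain: PretreatmentChain | None = None,
    test_replicate: int = 3,
) -> dict:
    """Replicate-split external validation: train on two replicates,
    predict the designated held-out replicate.

    Returns RMSEP, R²P (about the test-set response mean), the observed/
    predicted pairs and the regression vector on the pretreated grid.
    """
    ds = chain.apply(dataset) if chain is not None else dataset
    reps = ds.meta["replicate"].to_numpy()
    test = reps == test_replicate
    if not test.any() or test.all():
        raise ValueError(f"replicate {test_replicate} does not split the data")
    y = ds.Y[response].to_numpy(dtype=float)
    model = fit_plsr(ds.X[~test], y[~test], n_lv)
    y_hat = model.predict(ds.X[test])
    y_test = y[test]
    sse = float(np.sum((y_hat - y_test) ** 2))
    sst = float(np.sum((y_test - y_test.mean()) ** 2))
    return {
        "rmsep": float(np.sqrt(sse / len(y_test))),
        "r2p": 1.0 - sse / sst,
        "y_observed": y_test,
        "y_predicted": y_hat,
        "regression_vector": model.b,
        "wavelengths": ds.wavelengths,
        "model": model,
    }


def optimize_model(
    dataset: SpectralDataset,
    response: str,
    chain_candidates: Sequence[PretreatmentChain | str],
    lv_range: Iterable[int] = range(1, 13),
) -> PLSRModel:
    """Grid search over pretreatment chains × latent-variable counts.

    Minimises leave-one-replicate-out RMSECV. Ties break toward fewer
    latent variables, then toward the earlier chain in candidate order.
    The chosen model is refit on the full calibration set with its CV
    metrics attached; every grid evaluation is logged.
    """
    chains = [
        PretreatmentChain.from_string(c) if isinstance(c, str) else c
        for c in chain_candidates
    ]
    lvs = sorted(set(int(k) for k in lv_range))
    if not chains or not lvs:
        raise ValueError("empty search grid")
    best = None  # (rmsecv, lv, chain_idx)
    reps = dataset.meta["replicate"].to_numpy()
    y_all = dataset.Y[response].to_numpy(dtype=float)
    sst = float(np.sum((y_all - y_all.mean()) ** 2))
    for ci, chain in enumerate(chains):
        ds = chain.apply(dataset)
        max_lv = lvs[-1]
        preds = _fold_predictions(ds.X, y_all, reps, max_lv)
        for lv in lvs:
            sse = float(np.sum((preds[:, lv - 1] - y_all) ** 2))
            rmsecv = float(np.sqrt(sse / len(y_all)))
            logger.info(
                "grid response=%s chain=%s lv=%d rmsecv=%.6g",
                response, chain.format(), lv, rmsecv,
            )
            key = (rmsecv, lv, ci)
            if best is None or key < best[0]:
                best = (key, chain, lv, 1.0 - sse / sst)
    key, chain, lv, r2cv = best
    rmsecv = key[0]
    ds = chain.apply(dataset)
    model = fit_plsr(ds.X, dataset.Y[response].to_numpy(dtype=float), lv)
    model.rmsecv, model.r2cv = rmsecv, r2cv
    model.pretreatment = chain.format()
    model.response = response
    model.wavelengths = ds.wavelengths
    return model
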