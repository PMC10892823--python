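"""Multivariate limit of detection and quantification for PLS1 models.

The detection limit of a latent-variable regression depends on where a
blank sits in the calibration score space, so it is interval-valued: each
calibration sample's score vector is extrapolated to zero analyte
concentration, its leverage h0 in that space is computed, and the LOD is
evaluated at the smallest and largest h0:

    LOD(h0) = 3.3 · [ (1 + h0) · SEN⁻² · var(x) + h0 · var(y_cal) ]^½

where SEN = 1/‖b‖₂ is the multivariate sensitivity, var(x) the
instrumental signal variance and var(y_cal) the variance of the
calibration concentrations. LOQ = 3 × LOD elementwise.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .chemometrics import PLSRModel
from .simulate import SpectralDataset

__all__ = [
    "LodReport",
    "sensitivity",
    "zero_analyte_leverages",
    "lod_interval",
    "loq_interval",
    "lod_report",
]

LOD_FACTOR = 3.3
LOQ_FACTOR = 3.0


@dataclass
class LodReport:
    """Detection/quantification summary for one fitted PLSR model."""

    sen: float  # response units per AU
    var_x: float  # AU²
    var_ycal: float  # (g/100 g)²
    h0_min: float
    h0_max: float
    lod_min: float
    lod_max: float
    loq_min: float
    loq_max: float

    def as_dict(self) -> dict:
        return asdict(self)


def sensitivity(b: np.ndarray) -> float:
    """Multivariate sensitivity: the inverse Euclidean norm of the
    regression vector."""
    norm = float(np.linalg.norm(np.asarray(b, dtype=float)))
    if norm == 0:
        raise ValueError("zero regression vector has no sensitivity")
    return 1.0 / norm


def zero_analyte_leverages(
    T: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Leverages of calibration scores extrapolated to zero concentration.

    Each score column is regressed on the calibration concentrations
    (slope s_j = Σᵢ t_ij·yᵢ / Σᵢ yᵢ²) and the analyte-correlated part is
    removed: t0ᵢ = tᵢ − yᵢ·s. The leverage of the extrapolated point in
    the calibration score space is h0ᵢ = t0ᵢᵀ (TᵀT)⁻¹ t0ᵢ; a control
    sample (y = 0) keeps its ordinary leverage.

    Returns (h0 per sample, h0_min, h0_max).
    """
    T = np.atleast_2d(np.asarray(T, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if T.shape[0] != y.shape[0]:
        raise ValueError("T and y row counts differ")
    yy = y @ y
    if yy == 0:
        raise ValueError("all calibration concentrations are zero")
    s = (T.T @ y) / yy  # per-column slope of scores on concentration
    T0 = T - np.outer(y, s)
    G = T.T @ T
    if not np.any(G):
        raise ValueError("zero score Gram matrix TᵀT")
    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError:
        # rank-deficient score space (e.g. scores proportional to y);
        # the pseudo-inverse gives the leverage within the spanned space
        Ginv = np.linalg.pinv(G)
    h0 = np.einsum("ij,jk,ik->i", T0, Ginv, T0)
    h0 = np.maximum(h0, 0.0)  # clip tiny negative round-off
    return h0, float(h0.min()), float(h0.max())


def lod_interval(
    sen: float,
    var_x: float,
    var_ycal: float,
    h0_min: float,
    h0_max: float,
) -> tuple[float, float]:
    """Evaluate LOD(h0) at the extreme zero-analyte leverages."""
    for name, v in (("var_x", var_x), ("var_ycal", var_ycal),
                    ("h0_min", h0_min), ("h0_max", h0_max)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    if sen <= 0:
        raise ValueError("sensitivity must be positive")

    def _lod(h0: float) -> float:
        return LOD_FACTOR * np.sqrt(
            (1.0 + h0) * var_x / sen**2 + h0 * var_ycal
        )

    return float(_lod(h0_min)), float(_lod(h0_max))


def loq_interval(lod_min: float, lod_max: float) -> tuple[float, float]:
    """LOQ interval: three times the LOD interval, elementwise."""
    if lod_min < 0 or lod_max < 0:
        raise ValueError("LOD values must be non-negative")
    return LOQ_FACTOR * lod_min, LOQ_FACTOR * lod_max


def _var_x_residual(model: PLSRModel, X: np.ndarray) -> float:
    """Mean squared element of the X-residual after the retained scores."""
    Xc = np.asarray(X, dtype=float) - model.x_mean
    resid = Xc - model.T @ model.P.T
    return float(np.mean(resid**2))


def _var_x_replicate(dataset: SpectralDataset) -> float:
    """Pooled replicate-to-replicate spectral variance.

    Residuals of each spectrum about its (protein, combo, level) group
    mean, pooled with n − n_groups degrees of freedom.
    """
    keys = dataset.meta[["protein", "combo", "level"]].astype(str).agg("|".join, axis=1)
    X = dataset.X
    sse = 0.0
    dof = 0
    for key in keys.unique():
        rows = X[(keys == key).to_numpy()]
        if rows.shape[0] < 2:
            continue
        sse += float(np.sum((rows - rows.mean(axis=0)) ** 2))
        dof += (rows.shape[0] - 1) * rows.shape[1]
    if dof == 0:
        raise ValueError("no replicated groups to pool variance from")
    return sse / dof


def lod_report(
    model: PLSRModel,
    dataset: SpectralDataset,
    response: str | None = None,
    var_x_estimator: str = "residual",
) -> LodReport:
    """Assemble the full LOD/LOQ report for a fitted model.

    ``var_x_estimator`` selects the instrumental-variance estimate:
    ``"residual"`` (default) uses the mean squared element of the X
    residual after the retained latent variables; ``"replicate"`` pools
    the replicate-to-replicate spectral variance. The dataset must be on
    the same (pretreated) grid the model was fit on.
    """
    resp = response or model.response
    y = dataset.Y[resp].to_numpy(dtype=float)
    if var_x_estimator == "residual":
        var_x = _var_x_residual(model, dataset.X)
    elif var_x_estimator == "replicate":
        var_x = _var_x_replicate(dataset)
    else:
        raise ValueError(f"unknown var_x estimator {var_x_estimator!r}")
    sen = sensitivity(model.b)
    var_ycal = float(np.var(y, ddof=1))
    _, h0_min, h0_max = zero_analyte_leverages(model.T, y)
    lod_min, lod_max = lod_interval(sen, var_x, var_ycal, h0_min, h0_max)
    loq_min, loq_max = loq_interval(lod_min, lod_max)
    return LodReport(
        sen=sen,
        var_x=var_x,
        var_ycal=var_ycal,
        h0_min=h0_min,
        h0_max=h0_max,
        lod_min=lod_min,
        lod_max=lod_max,
        loq_min=loq_min,
        loq_max=loq_max,
    )
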