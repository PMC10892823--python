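"""Composable spectral pretreatments.

Savitzky–Golay smoothing/derivatives, standard normal variate (SNV),
multiplicative scatter correction (MSC), polynomial detrending and
wavelength-range restriction, applied row-wise to a spectra matrix, plus
a small string DSL ("SG(21,2,0)+SNV") for naming pretreatment chains in
model reports.

Savitzky–Golay edges are trimmed, not padded: the output loses
(window−1)/2 points on each side and the wavelength axis is shortened to
match, so regression vectors never see fabricated boundary values.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .simulate import SpectralDataset

__all__ = [
    "savitzky_golay",
    "snv",
    "msc",
    "detrend",
    "restrict_range",
    "PretreatmentChain",
    "parse_chain",
]

logger = logging.getLogger(__name__)


def _as_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return X[None, :] if X.ndim == 1 else X


def _uniform_step(wavelengths: np.ndarray) -> float:
    steps = np.diff(wavelengths)
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ValueError(
            "non-uniform wavelength grid; resample first (restrict_range does this)"
        )
    return float(steps[0])


def savitzky_golay(
    X: np.ndarray,
    window: int,
    polyorder: int = 2,
    deriv: int = 0,
    step: float = 1.0,
) -> np.ndarray:
    """Row-wise Savitzky–Golay filtering with trimmed edges.

    Derivatives are returned per wavelength unit (scaled by 1/step^deriv).
    The output has ``window − 1`` fewer columns than the input; callers
    must trim the wavelength axis by (window−1)/2 on each side.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    X = _as_matrix(X)
    if X.shape[1] < window:
        raise ValueError("spectra shorter than the filter window")
    half = (window - 1) // 2
    out = savgol_filter(
        X, window_length=window, polyorder=polyorder, deriv=deriv, delta=step, axis=1
    )
    return out[:, half : X.shape[1] - half] if half else out


def snv(X: np.ndarray) -> np.ndarray:
    """Standard normal variate: each row to mean 0, sample (n−1) sd 1."""
    X = _as_matrix(X)
    if X.shape[1] < 2:
        raise ValueError("SNV needs at least two points per spectrum")
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant spectrum: SNV undefined (zero variance)")
    return (X - mean) / sd


def msc(X: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Each row x is regressed as x ≈ a + b·reference (ordinary least
    squares); the corrected row is (x − a)/b. The default reference is
    the column-mean spectrum of ``X``.
    """
    X = _as_matrix(X)
    ref = X.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    if ref.shape[0] != X.shape[1]:
        raise ValueError("reference length does not match spectra")
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise ValueError("constant reference spectrum")
    b = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    if np.any(b == 0):
        raise ValueError("zero slope: spectrum orthogonal to reference")
    a = X.mean(axis=1) - b * ref.mean()
    return (X - a[:, None]) / b[:, None]


def detrend(X: np.ndarray, wavelengths: np.ndarray, degree: int = 2) -> np.ndarray:
    """Subtract a per-row least-squares polynomial in wavelength.

    Output rows are orthogonal to the polynomial basis up to ``degree``;
    degree 0 is plain row-centering.
    """
    X = _as_matrix(X)
    if X.shape[1] <= degree:
        raise ValueError("row length must exceed polynomial degree")
    lam = np.asarray(wavelengths, dtype=float)
    # scale to [-1, 1] for conditioning; projection is basis-invariant
    t = 2.0 * (lam - lam.min()) / max(lam.max() - lam.min(), 1e-300) - 1.0
    B = np.polynomial.polynomial.polyvander(t, degree)
    coef, *_ = np.linalg.lstsq(B, X.T, rcond=None)
    return X - (B @ coef).T


def restrict_range(
    dataset: SpectralDataset, lo: float, hi: float, resample_step: float = 2.0
) -> SpectralDataset:
    """Keep wavelengths in [lo, hi]; resample non-uniform grids.

    Uniform grids are simply column-subset. A non-uniform grid (the FT
    instrument stored on nm-converted wavenumbers) is linearly resampled
    to uniform ``resample_step`` nm spacing inside the interval.
    """
    if lo >= hi:
        raise ValueError(f"invalid interval [{lo}, {hi}]")
    wl = dataset.wavelengths
    steps = np.diff(wl)
    uniform = np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9)
    if uniform:
        keep = (wl >= lo - 1e-9) & (wl <= hi + 1e-9)
        if not keep.any():
            raise ValueError("no wavelengths in the requested interval")
        return dataset.with_spectra(dataset.X[:, keep], wl[keep])
    start = max(lo, float(np.ceil(wl[0])))
    stop = min(hi, float(np.floor(wl[-1])))
    new_wl = np.arange(start, stop + resample_step / 2, resample_step)
    if new_wl.size == 0:
        raise ValueError("no wavelengths in the requested interval")
    newX = np.vstack([np.interp(new_wl, wl, row) for row in dataset.X])
    return dataset.with_spectra(newX, new_wl)


# ---------------------------------------------------------------------------
# Chain DSL


@dataclass(frozen=True)
class _Op:
    kind: str
    args: tuple[float, ...] = ()

    def format(self) -> str:
        if not self.args:
            return self.kind
        rendered = ",".join(
            str(int(a)) if float(a).is_integer() else f"{a:g}" for a in self.args
        )
        return f"{self.kind}({rendered})"


_OP_RE = re.compile(r"^([A-Za-z]+)(?:\(([^)]*)\))?$")

#: "SC" appears as a pretreatment label in the source tables without a
#: definition; it is aliased to plain SG smoothing and flagged in logs.
_SC_DEFAULT = ("SG", (21.0, 2.0, 0.0))


def parse_chain(spec: str) -> "PretreatmentChain":
    """Parse a chain label such as ``"RANGE(1100,2200)+SG(15,2,0)+SNV"``.

    Operators apply left to right. Recognised ops: SG(window, polyorder,
    deriv), SNV, MSC, DETREND(degree), RANGE(lo, hi), and the alias SC
    (smoothing-only SG, logged as an assumption).
    """
    ops: list[_Op] = []
    for token in spec.replace(" ", "").split("+"):
        if not token:
            continue
        m = _OP_RE.match(token)
        if not m:
            raise ValueError(f"cannot parse pretreatment token {token!r}")
        kind = m.group(1).upper()
        args = tuple(float(a) for a in m.group(2).split(",")) if m.group(2) else ()
        if kind == "SC":
            logger.warning(
                "pretreatment label 'SC' is undefined in the source tables; "
                "interpreting as smoothing-only SG%s", _SC_DEFAULT[1]
            )
            kind, args = _SC_DEFAULT[0], args or _SC_DEFAULT[1]
        if kind == "SG":
            if len(args) == 1:
                args = (args[0], 2.0, 0.0)
            elif len(args) == 2:
                args = (args[0], args[1], 0.0)
            window, polyorder, _d = args
            if int(window) % 2 == 0 or not 5 <= int(window) <= 41:
                raise ValueError(f"SG window must be odd and in 5..41, got {window}")
            if window <= polyorder:
                raise ValueError("SG window must exceed polyorder")
        elif kind == "RANGE":
            if len(args) != 2 or args[0] >= args[1]:
                raise ValueError(f"RANGE needs lo < hi, got {args}")
        elif kind == "DETREND":
            args = args or (2.0,)
        elif kind in ("SNV", "MSC"):
            args = ()
        elif kind == "NONE":
            continue
        else:
            raise ValueError(f"unknown pretreatment {kind!r}")
        ops.append(_Op(kind, args))
    return PretreatmentChain(tuple(ops), label=spec.strip())


@dataclass(frozen=True)
class PretreatmentChain:
    """An ordered pretreatment pipeline applied to a SpectralDataset."""

    ops: tuple[_Op, ...]
    label: str = ""

    @classmethod
    def from_string(cls, spec: str) -> "PretreatmentChain":
        return parse_chain(spec)

    def format(self) -> str:
        return "+".join(op.format() for op in self.ops) or "NONE"

    def apply(self, dataset: SpectralDataset) -> SpectralDataset:
        ds = dataset
        for op in self.ops:
            if op.kind == "RANGE":
                ds = restrict_range(ds, *op.args)
            elif op.kind == "SG":
                window, polyorder, deriv = (int(a) for a in op.args)
                step = _uniform_step(ds.wavelengths)
                half = (window - 1) // 2
                newX = savitzky_golay(ds.X, window, polyorder, deriv, step)
                ds = ds.with_spectra(newX, ds.wavelengths[half:-half] if half else ds.wavelengths)
            elif op.kind == "SNV":
                ds = ds.with_spectra(snv(ds.X), ds.wavelengths)
            elif op.kind == "MSC":
                ds = ds.with_spectra(msc(ds.X), ds.wavelengths)
            elif op.kind == "DETREND":
                ds = ds.with_spectra(
                    detrend(ds.X, ds.wavelengths, int(op.args[0])), ds.wavelengths
                )
        return ds
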