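"""Synthetic diffuse-reflectance NIR spectra for designed powder samples.

A Beer–Lambert-style linear mixing model: every component (the four
adulterants and the three protein matrices) has a non-negative absorbance
profile per unit mass fraction on a fine master wavelength grid, built as
a sum of Gaussian bands anchored at the compounds' known NIR absorbance
features (melamine ~1480 nm; urea ~1490/1530/1980 nm; taurine's S–H
first-overtone cluster in 1650–1750 nm; a broad weak glycine band near
1200 nm shared with taurine). A sample's noiseless spectrum is the
mass-fraction-weighted sum of its component profiles.

Acquisition on a given instrument interpolates the master spectrum onto
the device grid and injects per-scan artifacts: multiplicative scatter, an
additive baseline (offset + tilt, emulating the baseline shift of
non-contact handheld measurements), and i.i.d. Gaussian detector noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import SampleRecord, design_to_frame

__all__ = [
    "ComponentLibrary",
    "InstrumentProfile",
    "Spectrum",
    "SpectralDataset",
    "DEFAULT_INSTRUMENTS",
    "default_library",
    "mix_spectrum",
    "acquire",
    "wavenumber_to_nm",
    "nm_to_wavenumber",
    "build_dataset",
    "write_spectra_csv",
    "read_spectra_csv",
]

MASTER_GRID_NM = np.arange(400.0, 2500.0 + 0.25, 0.5)

RESPONSE_COLUMNS = (
    "conc_melamine",
    "conc_urea",
    "conc_glycine",
    "conc_taurine",
    "conc_protein",
)

META_COLUMNS = ("sample_id", "protein", "combo", "level", "replicate")


@dataclass(frozen=True)
class ComponentLibrary:
    """Per-component absorbance profiles on the master wavelength grid.

    ``profiles[name]`` is absorbance per unit mass fraction (AU per
    (g/100 g)/100, i.e. the profile is multiplied by mass_fraction/100).
    """

    master_grid: np.ndarray
    profiles: Mapping[str, np.ndarray]
    peaks: Mapping[str, tuple[tuple[float, float, float], ...]]

    def __post_init__(self) -> None:
        for name, prof in self.profiles.items():
            if prof.shape != self.master_grid.shape:
                raise ValueError(f"profile {name!r} not on master grid")
            if np.any(prof < 0):
                raise ValueError(f"profile {name!r} has negative absorbance")


@dataclass(frozen=True)
class InstrumentProfile:
    """One spectrometer arm: wavelength grid plus artifact parameters.

    ``grid`` is in nm and strictly increasing; for the FT device it is the
    nm-conversion of a uniform wavenumber grid and therefore non-uniform.
    """

    name: str
    grid: np.ndarray
    noise_sd: float = 0.001
    baseline_offset: float = 0.0
    baseline_slope: float = 0.0
    scatter_sd: float = 0.02
    n_scans: int = 3

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("instrument grid must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_scans < 1:
            raise ValueError("n_scans must be >= 1")


@dataclass(frozen=True)
class Spectrum:
    """A single absorbance vector with its wavelength axis and provenance."""

    sample_id: str
    instrument: str
    wavelengths: np.ndarray
    absorbance: np.ndarray
    scan: int | str = "averaged"

    def __post_init__(self) -> None:
        if self.wavelengths.shape != self.absorbance.shape:
            raise ValueError("wavelengths and absorbance length mismatch")


@dataclass
class SpectralDataset:
    """Spectra matrix with aligned sample metadata and response columns.

    ``X`` is samples × wavelengths (AU), ``meta`` carries the design keys
    (sample_id, protein, combo, level, replicate) and ``Y`` the five
    concentration responses in g/100 g.
    """

    X: np.ndarray
    wavelengths: np.ndarray
    meta: pd.DataFrame
    Y: pd.DataFrame
    instrument: str = ""

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        if len(self.meta) != n or len(self.Y) != n:
            raise ValueError("X, meta and Y row counts differ")
        if self.X.shape[1] != len(self.wavelengths):
            raise ValueError("X column count != wavelength count")

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, mask: np.ndarray) -> "SpectralDataset":
        """Row subset preserving alignment (mask is boolean or index)."""
        return SpectralDataset(
            X=self.X[mask],
            wavelengths=self.wavelengths.copy(),
            meta=self.meta.iloc[mask].reset_index(drop=True)
            if np.asarray(mask).dtype == bool
            else self.meta.iloc[np.asarray(mask)].reset_index(drop=True),
            Y=self.Y.iloc[mask].reset_index(drop=True)
            if np.asarray(mask).dtype == bool
            else self.Y.iloc[np.asarray(mask)].reset_index(drop=True),
            instrument=self.instrument,
        )

    def with_spectra(self, X: np.ndarray, wavelengths: np.ndarray) -> "SpectralDataset":
        """Same samples, new spectral matrix (after a pretreatment)."""
        return SpectralDataset(
            X=X,
            wavelengths=np.asarray(wavelengths, dtype=float),
            meta=self.meta,
            Y=self.Y,
            instrument=self.instrument,
        )


def _gaussian(grid: np.ndarray, center: float, width: float, height: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((grid - center) / width) ** 2)


def _profile_from_peaks(
    grid: np.ndarray, peaks: Sequence[tuple[float, float, float]]
) -> np.ndarray:
    prof = np.zeros_like(grid)
    for center, width, height in peaks:
        prof += _gaussian(grid, center, width, height)
    return prof


# (center nm, sd nm, height AU per unit mass fraction) per component.
# Adulterant heights put a 0.13 g/100 g dose within a few noise sd of the
# benchtop noise floor so detection-limit estimates are non-trivial.
_ADULTERANT_PEAKS: dict[str, tuple[tuple[float, float, float], ...]] = {
    "melamine": ((1480.0, 9.0, 2.2), (2010.0, 25.0, 0.9), (2240.0, 30.0, 0.5)),
    "urea": (
        (1490.0, 10.0, 1.6),
        (1530.0, 10.0, 1.8),
        (1980.0, 18.0, 2.0),
        (2160.0, 30.0, 0.6),
    ),
    "taurine": (
        (1660.0, 11.0, 1.1),
        (1700.0, 11.0, 1.3),
        (1740.0, 11.0, 1.0),
        (1200.0, 30.0, 0.45),
        (2060.0, 35.0, 0.35),
    ),
    # deliberately broad and weak: the least distinct adulterant
    "glycine": ((1200.0, 45.0, 0.30), (1570.0, 60.0, 0.18), (2120.0, 70.0, 0.14)),
}

# Protein matrices share broad N-H and combination bands but with
# per-protein coefficients and small center shifts so the three types
# separate in score space.
_PROTEIN_PEAKS: dict[str, tuple[tuple[float, float, float], ...]] = {
    "whey": (
        (1190.0, 60.0, 0.18),
        (1450.0, 55.0, 0.42),
        (1510.0, 45.0, 0.30),
        (1730.0, 40.0, 0.16),
        (1940.0, 55.0, 0.55),
        (2060.0, 50.0, 0.38),
        (2180.0, 55.0, 0.30),
        (2310.0, 60.0, 0.22),
    ),
    "beef": (
        (1195.0, 60.0, 0.22),
        (1455.0, 55.0, 0.36),
        (1520.0, 45.0, 0.40),
        (1735.0, 40.0, 0.24),
        (1940.0, 55.0, 0.42),
        (2055.0, 50.0, 0.48),
        (2175.0, 55.0, 0.24),
        (2305.0, 60.0, 0.30),
    ),
    "pea": (
        (1185.0, 60.0, 0.28),
        (1445.0, 55.0, 0.50),
        (1505.0, 45.0, 0.24),
        (1725.0, 40.0, 0.30),
        (1935.0, 55.0, 0.48),
        (2065.0, 50.0, 0.30),
        (2185.0, 55.0, 0.40),
        (2315.0, 60.0, 0.18),
    ),
}

#: Flat pedestal added to protein profiles (powder base reflectance loss).
_PROTEIN_PEDESTAL = 0.25


def default_library(seed: int | None = None) -> ComponentLibrary:
    """The default component library on the 400–2500 nm master grid.

    Profiles are deterministic sums of Gaussian bands at the compounds'
    characteristic NIR features; ``seed`` is accepted for interface
    symmetry but the default bands are fixed.
    """
    grid = MASTER_GRID_NM.copy()
    peaks = dict(_ADULTERANT_PEAKS)
    profiles: dict[str, np.ndarray] = {
        name: _profile_from_peaks(grid, p) for name, p in peaks.items()
    }
    for protein, ppeaks in _PROTEIN_PEAKS.items():
        profiles[protein] = _profile_from_peaks(grid, ppeaks) + _PROTEIN_PEDESTAL
        peaks[protein] = ppeaks
    return ComponentLibrary(master_grid=grid, profiles=profiles, peaks=peaks)


def mix_spectrum(sample: SampleRecord, lib: ComponentLibrary) -> Spectrum:
    """Noiseless master-grid spectrum: mass-fraction-weighted profile sum.

    absorbance = Σ_c (mass_fraction_c / 100) × profile_c, with the protein
    component taken from the sample's matrix type. Linear in concentrations;
    a control sample returns the pure protein profile.
    """
    absorbance = np.zeros_like(lib.master_grid)
    for component, fraction in sample.mass_fractions.items():
        if fraction == 0.0:
            continue
        key = sample.protein if component == "protein" else component
        if key not in lib.profiles:
            raise KeyError(f"component {key!r} missing from library")
        absorbance = absorbance + (fraction / 100.0) * lib.profiles[key]
    return Spectrum(
        sample_id=sample.sample_id,
        instrument="master",
        wavelengths=lib.master_grid,
        absorbance=absorbance,
    )


def wavenumber_to_nm(wavenumbers: np.ndarray | Sequence[float]) -> np.ndarray:
    """Convert wavenumbers (cm⁻¹) to wavelengths (nm), sorted ascending."""
    nu = np.asarray(wavenumbers, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("wavenumbers must be positive")
    return np.sort(1.0e7 / nu)


def nm_to_wavenumber(nm: np.ndarray | Sequence[float]) -> np.ndarray:
    lam = np.asarray(nm, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelengths must be positive")
    return np.sort(1.0e7 / lam)


def _default_instruments() -> dict[str, InstrumentProfile]:
    nirs6500 = np.arange(400.0, 2498.0 + 1.0, 2.0)
    metrinir = np.arange(740.0, 1700.0 + 1.0, 2.0)
    mpa = wavenumber_to_nm(np.arange(4000.0, 12000.0 + 4.0, 8.0))
    g1 = np.arange(900.0, 1700.0 + 1.5, 3.0)
    return {
        "NIRS6500": InstrumentProfile("NIRS6500", nirs6500, noise_sd=0.001),
        "MetriNIR": InstrumentProfile("MetriNIR", metrinir, noise_sd=0.001),
        "MPA": InstrumentProfile("MPA", mpa, noise_sd=0.001),
        "NIRS-G1-cuvette": InstrumentProfile(
            "NIRS-G1-cuvette", g1, noise_sd=0.003, baseline_offset=0.15,
            baseline_slope=0.02,
        ),
        "NIRS-G1-bag": InstrumentProfile(
            "NIRS-G1-bag", g1, noise_sd=0.003, baseline_offset=0.04,
            baseline_slope=0.005,
        ),
    }


#: The five study arms with their printed grids and artifact defaults.
DEFAULT_INSTRUMENTS: dict[str, InstrumentProfile] = _default_instruments()


def acquire(
    spectrum: Spectrum,
    instrument: InstrumentProfile,
    seed: int | np.random.Generator | None = None,
) -> list[Spectrum]:
    """Simulate ``n_scans`` acquisitions of one sample on one instrument.

    Interpolates the master-grid spectrum onto the device grid, then per
    scan multiplies by a scatter factor 1 + N(0, scatter_sd), adds the
    baseline offset + slope·(λ−λmin)/1000 and i.i.d. N(0, noise_sd) noise,
    clamping at zero absorbance. Reproducible under a fixed seed.
    """
    lo, hi = spectrum.wavelengths[0], spectrum.wavelengths[-1]
    if instrument.grid[0] < lo - 1e-9 or instrument.grid[-1] > hi + 1e-9:
        raise ValueError(
            f"instrument grid [{instrument.grid[0]}, {instrument.grid[-1]}] "
            f"outside master grid [{lo}, {hi}]"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = np.interp(instrument.grid, spectrum.wavelengths, spectrum.absorbance)
    baseline = instrument.baseline_offset + instrument.baseline_slope * (
        (instrument.grid - instrument.grid[0]) / 1000.0
    )
    scans: list[Spectrum] = []
    for k in range(instrument.n_scans):
        scatter = 1.0 + rng.normal(0.0, instrument.scatter_sd) if instrument.scatter_sd > 0 else 1.0
        noise = (
            rng.normal(0.0, instrument.noise_sd, size=base.shape)
            if instrument.noise_sd > 0
            else 0.0
        )
        ab = np.maximum(scatter * base + baseline + noise, 0.0)
        scans.append(
            Spectrum(
                sample_id=spectrum.sample_id,
                instrument=instrument.name,
                wavelengths=instrument.grid,
                absorbance=ab,
                scan=k + 1,
            )
        )
    return scans


def build_dataset(
    design: pd.DataFrame | list[SampleRecord],
    instrument: InstrumentProfile | str,
    lib: ComponentLibrary | None = None,
    seed: int | None = None,
    average_scans: bool = True,
) -> SpectralDataset:
    """Simulate the full spectra table for a design on one instrument.

    One averaged spectrum (mean of the triplicate scans) per sample by
    default; with ``average_scans=False`` each scan becomes its own row
    and ``meta`` gains a ``scan`` column.
    """
    if isinstance(instrument, str):
        instrument = DEFAULT_INSTRUMENTS[instrument]
    if lib is None:
        lib = default_library()
    if isinstance(design, pd.DataFrame):
        records = _records_from_frame(design)
    else:
        records = design
    rng = np.random.default_rng(seed)
    rows: list[np.ndarray] = []
    meta_rows: list[dict] = []
    y_rows: list[dict] = []
    for rec in records:
        pure = mix_spectrum(rec, lib)
        scans = acquire(pure, instrument, rng)
        meta = {
            "sample_id": rec.sample_id,
            "protein": rec.protein,
            "combo": rec.combo.label if rec.combo is not None else "",
            "level": rec.level,
            "replicate": rec.replicate,
        }
        y = {
            "conc_melamine": rec.mass_fractions.get("melamine", 0.0),
            "conc_urea": rec.mass_fractions.get("urea", 0.0),
            "conc_glycine": rec.mass_fractions.get("glycine", 0.0),
            "conc_taurine": rec.mass_fractions.get("taurine", 0.0),
            "conc_protein": rec.mass_fractions.get("protein", 100.0),
        }
        if average_scans:
            rows.append(np.mean([s.absorbance for s in scans], axis=0))
            meta_rows.append(meta)
            y_rows.append(y)
        else:
            for s in scans:
                rows.append(s.absorbance)
                meta_rows.append({**meta, "scan": s.scan})
                y_rows.append(y)
    return SpectralDataset(
        X=np.asarray(rows),
        wavelengths=instrument.grid.copy(),
        meta=pd.DataFrame(meta_rows),
        Y=pd.DataFrame(y_rows),
        instrument=instrument.name,
    )


def _records_from_frame(df: pd.DataFrame) -> list[SampleRecord]:
    from .design import MixtureCombo  # local to avoid re-export confusion

    records = []
    for _, row in df.iterrows():
        combo_label = str(row.get("combo", "") or "")
        combo = MixtureCombo.from_label(combo_label) if combo_label else None
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                protein=str(row["protein"]),
                combo=combo,
                level=int(row["level"]),
                replicate=int(row["replicate"]),
                mass_fractions={
                    "melamine": float(row.get("conc_melamine", 0.0)),
                    "urea": float(row.get("conc_urea", 0.0)),
                    "glycine": float(row.get("conc_glycine", 0.0)),
                    "taurine": float(row.get("conc_taurine", 0.0)),
                    "protein": float(row.get("conc_protein", 100.0)),
                },
            )
        )
    return records


def write_spectra_csv(dataset: SpectralDataset, path: str | Path) -> None:
    """Wide CSV: metadata + responses, then one column per wavelength (nm, 1 d.p.)."""
    wl_cols = [f"{w:.1f}" for w in dataset.wavelengths]
    frame = pd.concat(
        [
            dataset.meta.reset_index(drop=True),
            dataset.Y.reset_index(drop=True),
            pd.DataFrame(dataset.X, columns=wl_cols),
        ],
        axis=1,
    )
    frame.insert(0, "instrument", dataset.instrument)
    frame.to_csv(path, index=False, float_format="%.12g")


def read_spectra_csv(path: str | Path) -> SpectralDataset:
    df = pd.read_csv(path, dtype={"combo": str}, keep_default_na=False)
    wl_cols = [c for c in df.columns if c.replace(".", "", 1).isdigit()]
    meta_cols = [c for c in META_COLUMNS if c in df.columns]
    if "scan" in df.columns:
        meta_cols.append("scan")
    y_cols = [c for c in RESPONSE_COLUMNS if c in df.columns]
    meta = df[meta_cols].copy()
    meta["level"] = meta["level"].astype(int)
    meta["replicate"] = meta["replicate"].astype(int)
    return SpectralDataset(
        X=df[wl_cols].to_numpy(dtype=float),
        wavelengths=np.array([float(c) for c in wl_cols]),
        meta=meta,
        Y=df[y_cols].astype(float),
        instrument=str(df["instrument"].iloc[0]) if "instrument" in df.columns else "",
    )
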