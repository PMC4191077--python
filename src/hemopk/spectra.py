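"""Multi-component spectral speciation of plasma heme.

A blank-corrected visible absorbance spectrum is decomposed into heme
species (ferrous oxy/deoxy, ferric, hemichrome) by non-negative least
squares against per-species extinction coefficient curves, and the species
concentrations are summed to total heme.

The packaged extinction table is synthetic: smooth Gaussian-mixture basis
curves anchored at literature single-wavelength millimolar coefficients of
the corresponding species (oxyHb Q-bands near 542/577 nm, aquo-met ferric
bands near 500/630 nm, hemichrome bands near 535/565 nm).  Only the
round-trip consistency of the forward model and the fit depends on the
table; any table on the same layout can be swapped in from CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "Spectrum",
    "ExtinctionTable",
    "HemeSpeciation",
    "blank_correct",
    "fit_species",
    "forward_spectrum",
    "total_heme",
    "SpectralFitError",
]

DEFAULT_WINDOW_NM = (500.0, 650.0)


class SpectralFitError(ValueError):
    """Raised when the extinction matrix is unusable over the chosen window."""


@dataclass
class Spectrum:
    """Absorbance vs wavelength for one plasma sample (1 cm path default)."""

    wavelengths_nm: np.ndarray
    absorbance_AU: np.ndarray
    pathlength_cm: float = 1.0

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.absorbance_AU = np.asarray(self.absorbance_AU, dtype=float)
        if self.wavelengths_nm.shape != self.absorbance_AU.shape:
            raise ValueError("wavelength and absorbance vectors must match in length")
        if self.wavelengths_nm.size < 2:
            raise ValueError("a spectrum needs at least two points")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.pathlength_cm <= 0:
            raise ValueError("pathlength must be > 0")

    @classmethod
    def from_csv(cls, path, pathlength_cm: float = 1.0) -> "Spectrum":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), pathlength_cm)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"wavelength_nm": self.wavelengths_nm, "absorbance": self.absorbance_AU}
        ).to_csv(path, index=False)


def _gauss(lam, mu, sigma):
    return np.exp(-0.5 * ((lam - mu) / sigma) ** 2)


# Gaussian components (amplitude mM^-1 cm^-1 per heme, center nm, width nm)
# of the synthetic basis curves.
_SYNTHETIC_BASIS = {
    "ferrous": ((15.4, 577.0, 9.0), (14.1, 542.0, 11.0), (0.9, 510.0, 25.0)),
    "ferric": ((9.0, 500.0, 22.0), (3.9, 630.0, 13.0), (1.5, 578.0, 15.0)),
    "hemichrome": ((10.5, 535.0, 14.0), (8.5, 565.0, 16.0), (1.0, 610.0, 30.0)),
}
# Optional split of the ferrous pool into oxy and deoxy basis curves.
_SYNTHETIC_BASIS_4 = {
    "oxy": ((15.4, 577.0, 9.0), (14.4, 542.0, 10.0)),
    "deoxy": ((12.9, 555.0, 16.0), (1.0, 510.0, 30.0)),
    "ferric": _SYNTHETIC_BASIS["ferric"],
    "hemichrome": _SYNTHETIC_BASIS["hemichrome"],
}


@dataclass
class ExtinctionTable:
    """Per-species extinction coefficients epsilon(lambda), L/(mmol*cm).

    ``epsilon`` maps species name to a coefficient vector on
    ``wavelengths_nm``; curves are linearly interpolable to any spectrum
    grid inside their range.
    """

    wavelengths_nm: np.ndarray
    epsilon: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        for name, eps in self.epsilon.items():
            eps = np.asarray(eps, dtype=float)
            if eps.shape != self.wavelengths_nm.shape:
                raise ValueError(f"extinction curve {name!r} length mismatch")
            if np.any(eps < 0):
                raise ValueError(f"extinction curve {name!r} has negative values")
            self.epsilon[name] = eps

    @property
    def species(self) -> tuple:
        return tuple(self.epsilon)

    @classmethod
    def default(cls, four_species: bool = False) -> "ExtinctionTable":
        """Synthetic table on a 1 nm grid over 450-700 nm (see module docs)."""
        lam = np.arange(450.0, 701.0, 1.0)
        basis = _SYNTHETIC_BASIS_4 if four_species else _SYNTHETIC_BASIS
        eps = {
            name: sum(a * _gauss(lam, mu, s) for a, mu, s in comps)
            for name, comps in basis.items()
        }
        return cls(lam, eps)

    @classmethod
    def from_csv(cls, path) -> "ExtinctionTable":
        df = pd.read_csv(path)
        lam = df.iloc[:, 0].to_numpy(dtype=float)
        eps = {c: df[c].to_numpy(dtype=float) for c in df.columns[1:]}
        return cls(lam, eps)

    def to_csv(self, path) -> None:
        out = {"wavelength_nm": self.wavelengths_nm}
        out.update(self.epsilon)
        pd.DataFrame(out).to_csv(path, index=False)

    def interpolate(self, wavelengths_nm) -> dict:
        lam = np.asarray(wavelengths_nm, dtype=float)
        if lam.min() < self.wavelengths_nm[0] or lam.max() > self.wavelengths_nm[-1]:
            raise ValueError("requested wavelengths fall outside the extinction table")
        return {
            name: np.interp(lam, self.wavelengths_nm, eps)
            for name, eps in self.epsilon.items()
        }


@dataclass
class HemeSpeciation:
    """Fitted per-species concentrations (uM heme) and their sum."""

    conc_uM: dict
    total_heme_uM: float
    residual_AU: float = 0.0

    def __post_init__(self) -> None:
        for name, c in self.conc_uM.items():
            if c < 0:
                raise ValueError(f"negative concentration for {name!r}")


def total_heme(speciation: HemeSpeciation) -> float:
    """Total heme (uM) as the arithmetic sum of the species concentrations."""
    return float(sum(speciation.conc_uM.values()))


def blank_correct(sample: Spectrum, blank: Spectrum) -> Spectrum:
    """Subtract the pre-dose (baseline) plasma blank from a sample spectrum.

    The blank is interpolated onto the sample grid when the grids differ
    (clamped at its endpoints); disjoint wavelength ranges are rejected.
    Small negative values from noise pass through untouched.
    """
    s_lo, s_hi = sample.wavelengths_nm[0], sample.wavelengths_nm[-1]
    b_lo, b_hi = blank.wavelengths_nm[0], blank.wavelengths_nm[-1]
    if b_hi < s_lo or b_lo > s_hi:
        raise ValueError("sample and blank wavelength ranges do not overlap")
    blank_on_sample = np.interp(sample.wavelengths_nm,
                                blank.wavelengths_nm, blank.absorbance_AU)
    return Spectrum(sample.wavelengths_nm,
                    sample.absorbance_AU - blank_on_sample,
                    sample.pathlength_cm)


def _design_matrix(spectrum: Spectrum, table: ExtinctionTable, window_nm):
    lo, hi = window_nm
    mask = (spectrum.wavelengths_nm >= lo) & (spectrum.wavelengths_nm <= hi)
    lam = spectrum.wavelengths_nm[mask]
    if lam.size < len(table.species):
        raise SpectralFitError(
            f"only {lam.size} wavelengths in window {window_nm}, "
            f"need >= {len(table.species)}"
        )
    eps = table.interpolate(lam)
    # A = eps [L/(mmol cm)] * c [uM]/1000 * path [cm]
    M = np.column_stack([eps[s] for s in table.species]) * (
        spectrum.pathlength_cm / 1000.0
    )
    return M, spectrum.absorbance_AU[mask]


def fit_species(spectrum: Spectrum, table: ExtinctionTable | None = None,
                window_nm=DEFAULT_WINDOW_NM) -> HemeSpeciation:
    """Non-negative least-squares heme speciation of a blank-corrected spectrum.

    Solves ``A(lambda) = sum_s eps_s(lambda) c_s * path`` for the species
    concentrations ``c_s >= 0`` (uM heme) over the fitting window and sums
    them to total heme.  A rank-deficient extinction matrix over the window
    is rejected with its condition number.
    """
    if table is None:
        table = ExtinctionTable.default()
    M, y = _design_matrix(spectrum, table, window_nm)
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > 1e8:
        raise SpectralFitError(
            f"extinction matrix is rank-deficient over window {window_nm} "
            f"(condition number {cond:.3g})"
        )
    conc, rnorm = nnls(M, y)
    conc_map = dict(zip(table.species, (float(c) for c in conc)))
    return HemeSpeciation(conc_map, float(sum(conc)), residual_AU=float(rnorm))


def forward_spectrum(conc_uM: dict, table: ExtinctionTable | None = None,
                     pathlength_cm: float = 1.0) -> Spectrum:
    """Noiseless forward model: absorbance from species concentrations (uM)."""
    if table is None:
        table = ExtinctionTable.default()
    unknown = set(conc_uM) - set(table.species)
    if unknown:
        raise ValueError(f"species not in table: {sorted(unknown)}")
    absorb = np.zeros_like(table.wavelengths_nm)
    for name, c in conc_uM.items():
        if c < 0:
            raise ValueError(f"negative concentration for {name!r}")
        absorb = absorb + table.epsilon[name] * (c / 1000.0) * pathlength_cm
    return Spectrum(table.wavelengths_nm.copy(), absorb, pathlength_cm)
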