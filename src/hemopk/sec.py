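"""Size-exclusion chromatography: peak integration and free/bound partition.

Free Hb and the larger Hb:Hp complex separate on an SEC column and are
detected at 405 nm (Soret band).  Peak areas inside fixed, named elution
windows are integrated after subtracting a linear baseline connecting the
window endpoints, and the percent free Hb is

    percent free = area_free / (area_free + area_bound) * 100.

Total heme from the spectral assay is then partitioned as
free = total * pct_free / 100 and bound = total - free, so the two species
sum to the total exactly.

The forward generator produces Gaussian peaks at phenotype-specific
retention times: free Hb at 20.7 min; the dog Hb:Hp complex at 17.7 min;
the human dimeric complex 0.5 min earlier (17.2 min); the human multimeric
complex as an equal pair of broader peaks at 14.7 and 15.1 min.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Chromatogram",
    "PeakAreas",
    "SpeciesConcentrations",
    "integrate_peaks",
    "percent_free",
    "speciate_concentration",
    "generate_chromatogram",
    "default_windows",
    "RETENTION_MIN",
]

#: Apex retention times (min) of the forward model.
RETENTION_MIN = {
    "free_hb": 20.7,
    "dog": 17.7,
    "human_dimeric": 17.2,
    "human_multimeric": (14.7, 15.1),
}

#: Peak standard deviations (min).
PEAK_SIGMA_MIN = {"free_hb": 0.25, "dog": 0.25, "human_dimeric": 0.25,
                  "human_multimeric": 0.55}

#: A405 response: peak area (AU*min) per uM heme, identical for free and
#: complexed heme (the partition formulas assume an equal molar response).
RESPONSE_AU_MIN_PER_UM = 0.002

_FREE_WINDOW = (19.7, 21.7)
_BOUND_WINDOWS = {
    "dog": (16.2, 18.7),
    "human_dimeric": (16.2, 18.7),
    # wide enough to hold the full tails of the 14.7/15.1 min pair
    "human_multimeric": (12.0, 17.0),
}


def default_windows(phenotype: str) -> dict:
    """Named integration windows {free_hb, bound_hb} for a phenotype."""
    if phenotype not in _BOUND_WINDOWS:
        raise ValueError(f"unknown phenotype {phenotype!r}; "
                         f"expected one of {sorted(_BOUND_WINDOWS)}")
    return {"free_hb": _FREE_WINDOW, "bound_hb": _BOUND_WINDOWS[phenotype]}


@dataclass
class Chromatogram:
    """A405 trace vs elution time with named integration windows."""

    elution_min: np.ndarray
    a405_AU: np.ndarray
    windows: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.elution_min = np.asarray(self.elution_min, dtype=float)
        self.a405_AU = np.asarray(self.a405_AU, dtype=float)
        if self.elution_min.shape != self.a405_AU.shape:
            raise ValueError("elution and absorbance vectors must match in length")
        if np.any(np.diff(self.elution_min) <= 0):
            raise ValueError("elution times must be strictly increasing")
        lo, hi = self.elution_min[0], self.elution_min[-1]
        items = sorted(self.windows.items(), key=lambda kv: kv[1][0])
        for name, (a, b) in items:
            if not (lo <= a < b <= hi):
                raise ValueError(f"window {name!r}=({a}, {b}) outside elution range")
        for (n1, w1), (n2, w2) in zip(items, items[1:]):
            if w1[1] > w2[0]:
                raise ValueError(f"windows {n1!r} and {n2!r} overlap")

    @classmethod
    def from_csv(cls, path, windows: dict | None = None) -> "Chromatogram":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(),
                   windows or {})

    def to_csv(self, path) -> None:
        pd.DataFrame({"elution_min": self.elution_min,
                      "a405": self.a405_AU}).to_csv(path, index=False)


@dataclass
class PeakAreas:
    """Baseline-corrected peak areas (AU*min); clipped at zero."""

    area_free: float
    area_bound: float

    def __post_init__(self) -> None:
        if self.area_free < 0 or self.area_bound < 0:
            raise ValueError("peak areas must be >= 0")


@dataclass
class SpeciesConcentrations:
    """Percent split and absolute free/bound heme concentrations (uM)."""

    pct_free: float
    pct_bound: float
    free_uM: float
    bound_uM: float


def _window_area(t, y, a, b) -> float:
    inside = (t > a) & (t < b)
    ya, yb = np.interp([a, b], t, y)
    tt = np.concatenate([[a], t[inside], [b]])
    yy = np.concatenate([[ya], y[inside], [yb]])
    if tt.size < 2:
        raise ValueError(f"empty integration window ({a}, {b})")
    baseline = ya + (yb - ya) * (tt - a) / (b - a)
    return float(max(np.trapezoid(yy - baseline, tt), 0.0))


def integrate_peaks(chrom: Chromatogram) -> PeakAreas:
    """Trapezoidal peak areas inside the named windows.

    Within each window a straight baseline connecting the signal at the
    window endpoints is subtracted; negative net areas are clipped to 0.
    """
    if "free_hb" not in chrom.windows or "bound_hb" not in chrom.windows:
        raise ValueError("chromatogram needs 'free_hb' and 'bound_hb' windows")
    t, y = chrom.elution_min, chrom.a405_AU
    return PeakAreas(
        area_free=_window_area(t, y, *chrom.windows["free_hb"]),
        area_bound=_window_area(t, y, *chrom.windows["bound_hb"]),
    )


def percent_free(areas: PeakAreas) -> float:
    """Percent free Hb = area_free / (area_free + area_bound) * 100.

    Returns NaN (missing sample) when both areas are zero.
    """
    total = areas.area_free + areas.area_bound
    if total <= 0:
        return float("nan")
    return areas.area_free / total * 100.0


def speciate_concentration(total_heme_uM: float,
                           pct_free: float) -> SpeciesConcentrations:
    """Partition total heme into free and bound concentrations.

    free = total * pct_free/100; bound = total - free, so conservation is
    exact by construction.
    """
    if not 0.0 <= pct_free <= 100.0:
        raise ValueError(f"pct_free must be in [0, 100], got {pct_free}")
    if total_heme_uM < 0:
        raise ValueError(f"total heme must be >= 0, got {total_heme_uM}")
    free = total_heme_uM * pct_free / 100.0
    return SpeciesConcentrations(
        pct_free=pct_free,
        pct_bound=100.0 - pct_free,
        free_uM=free,
        bound_uM=total_heme_uM - free,
    )


def generate_chromatogram(free_uM: float, bound_uM: float, phenotype: str,
                          noise_sd: float = 0.0, seed: int | None = None,
                          t_min: float = 0.0, t_max: float = 30.0,
                          dt_min: float = 0.01) -> Chromatogram:
    """Forward chromatogram model used by the simulation pipeline.

    The trace is a sum of Gaussian peaks at the phenotype retention times
    (the multimeric complex is an equal-weight pair with wider sigma), with
    peak area proportional to concentration through a fixed response factor,
    plus additive Gaussian baseline noise.
    """
    if phenotype not in _BOUND_WINDOWS:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    if free_uM < 0 or bound_uM < 0:
        raise ValueError("concentrations must be >= 0")
    t = np.arange(t_min, t_max + dt_min / 2, dt_min)
    y = np.zeros_like(t)

    def add_peak(center, sigma, area):
        nonlocal y
        amp = area / (sigma * np.sqrt(2.0 * np.pi))
        y = y + amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)

    add_peak(RETENTION_MIN["free_hb"], PEAK_SIGMA_MIN["free_hb"],
             free_uM * RESPONSE_AU_MIN_PER_UM)
    bound_area = bound_uM * RESPONSE_AU_MIN_PER_UM
    centers = RETENTION_MIN[phenotype]
    sigma = PEAK_SIGMA_MIN[phenotype]
    if isinstance(centers, tuple):
        for c in centers:
            add_peak(c, sigma, bound_area / len(centers))
    else:
        add_peak(centers, sigma, bound_area)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, t.shape)
    return Chromatogram(t, y, default_windows(phenotype))
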