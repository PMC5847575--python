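"""SWATH acquisition-scheme arithmetic.

A SWATH method tiles a precursor m/z range with fixed-width isolation
windows; each cycle records one MS/MS spectrum per window (accumulation
time ``t_acc``) plus a survey scan, so the cycle time bounds how densely a
chromatographic peak is sampled.  With a Gaussian peak of a given FWHM the
base width is 4σ = FWHM × 2/√(2 ln 2) ≈ 1.699 × FWHM, which also sets the
chromatographic peak capacity of a gradient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

#: 4σ base width of a Gaussian peak, in units of FWHM: 4 / (2 sqrt(2 ln 2))
GAUSSIAN_BASE_FACTOR = 4.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class PeakModel:
    """Chromatographic peak: FWHM in seconds, base width in FWHM units."""

    fwhm: float = 12.0
    base_width_factor: float = GAUSSIAN_BASE_FACTOR

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")

    @property
    def base_width(self) -> float:
        return self.fwhm * self.base_width_factor


@dataclass
class AcquisitionScheme:
    """Isolation-window tiling plus timing of one SWATH cycle."""

    mz_low: float
    mz_high: float
    window_width: float
    t_acc: float                     # seconds per isolation window
    t_survey: float = 0.1            # seconds, survey-scan overhead
    overlap: float = 0.0             # Th, inter-window overlap (default none)
    windows: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.window_width <= 0:
            raise ValueError("window width must be positive")
        if self.mz_high <= self.mz_low:
            raise ValueError("mz_high must exceed mz_low")
        if not self.windows:
            step = self.window_width - self.overlap
            lo = self.mz_low
            while lo < self.mz_high:
                self.windows.append((lo, lo + self.window_width))
                lo += step

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def t_cycle(self) -> float:
        return self.n_windows * self.t_acc + self.t_survey

    def window_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.windows, columns=["mz_start", "mz_end"])

    def to_dict(self) -> dict:
        return {
            "mz_low": self.mz_low, "mz_high": self.mz_high,
            "window_width": self.window_width, "n_windows": self.n_windows,
            "t_acc": self.t_acc, "t_survey": self.t_survey,
            "t_cycle": self.t_cycle,
        }


def design_windows(mz_low: float, mz_high: float, width: float,
                   t_acc: float = 0.040, t_survey: float = 0.1,
                   overlap: float = 0.0) -> AcquisitionScheme:
    """Tile [mz_low, mz_high] gaplessly with fixed-width isolation windows.

    ``n_windows = ceil(span / (width − overlap))``; the last window may
    overshoot ``mz_high``.
    """
    return AcquisitionScheme(mz_low, mz_high, width, t_acc, t_survey, overlap)


def points_per_peak(scheme: AcquisitionScheme, peak: PeakModel) -> float:
    """How many acquisition cycles sample one chromatographic peak base."""
    if scheme.t_cycle <= 0:
        raise ValueError("cycle time must be positive")
    return peak.base_width / scheme.t_cycle


def peak_capacity(gradient_length: float, mean_fwhm: float,
                  base_width_factor: float = GAUSSIAN_BASE_FACTOR) -> float:
    """Peaks separable in a gradient: 1 + gradient / (FWHM × 1.699)."""
    if gradient_length <= 0 or mean_fwhm <= 0:
        raise ValueError("gradient length and FWHM must be positive")
    return 1.0 + gradient_length / (mean_fwhm * base_width_factor)


def mass_range_coverage(library: pd.DataFrame, mz_low: float, mz_high: float
                        ) -> dict[str, float]:
    """Share of library precursors and proteins inside an m/z range.

    ``library`` needs columns ``precursor_mz`` and ``protein_id``.  A protein
    counts as covered if at least one of its precursors is in range.
    """
    if len(library) == 0:
        raise ValueError("empty spectral library")
    in_range = library["precursor_mz"].between(mz_low, mz_high)
    precursor_fraction = float(in_range.mean())
    covered = library.loc[in_range, "protein_id"].nunique()
    total = library["protein_id"].nunique()
    return {
        "precursor_fraction": precursor_fraction,
        "protein_fraction": covered / total,
    }
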