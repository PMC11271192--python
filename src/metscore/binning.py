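"""Fixed-width bucketing of 1D urine NMR spectra.

A 1D proton spectrum is reduced to 290 fixed-width buckets of 0.03 ppm
spanning 0.5–9.5 ppm with the water region (4.7–5.0 ppm) removed:
140 bins cover [0.5, 4.7) and 150 cover [5.0, 9.5].  Each bin is named
by its centre and collects the sum of the spectral point intensities
falling in its half-open interval [centre − 0.015, centre + 0.015); the
last bin of each segment is closed so coverage is exhaustive.  Intensities
are normalised to unit total over the retained (non-water) region before
bucketing, so bin intensities are relative abundances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PPM_MIN = 0.5
PPM_MAX = 9.5
WATER_LOW = 4.7
WATER_HIGH = 5.0
BIN_WIDTH = 0.03
N_BINS = 290  # 140 below water + 150 above


@dataclass
class Spectrum:
    """A 1D spectrum as (ppm, intensity) arrays on a strictly monotone grid."""

    ppm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.size == 0:
            raise ValueError("spectrum axis is empty")
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise ValueError("ppm and intensity must be equal-length 1D arrays")
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm grid must be strictly monotone")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be nonnegative")

    def ascending(self) -> "Spectrum":
        if self.ppm[0] > self.ppm[-1]:
            return Spectrum(self.ppm[::-1].copy(), self.intensity[::-1].copy())
        return self


def _segment_edges() -> tuple[np.ndarray, np.ndarray]:
    """Bin edges for the two retained segments, [0.5, 4.7) and [5.0, 9.5]."""
    low = PPM_MIN + BIN_WIDTH * np.arange(141)      # 140 bins
    high = WATER_HIGH + BIN_WIDTH * np.arange(151)  # 150 bins
    return low, high


def bin_edges() -> np.ndarray:
    """All 290 (lo, hi) bin intervals as an array of shape (290, 2)."""
    low, high = _segment_edges()
    segs = [np.column_stack([e[:-1], e[1:]]) for e in (low, high)]
    return np.vstack(segs)


def bin_centers() -> np.ndarray:
    edges = bin_edges()
    return edges.mean(axis=1)


def bin_names() -> list[str]:
    return [f"{c:.3f}" for c in bin_centers()]


def _retained_mask(ppm: np.ndarray) -> np.ndarray:
    in_range = (ppm >= PPM_MIN) & (ppm <= PPM_MAX)
    in_water = (ppm >= WATER_LOW) & (ppm < WATER_HIGH)
    return in_range & ~in_water


def normalize_total_intensity(spectrum: Spectrum) -> Spectrum:
    """Scale so the retained-region (non-water, 0.5–9.5 ppm) total is 1.

    The water region is discarded from all downstream analysis, so it is
    excluded from the normalisation total as well.
    """
    mask = _retained_mask(spectrum.ppm)
    total = float(spectrum.intensity[mask].sum())
    if total <= 0:
        raise ValueError("cannot normalize: retained-region total intensity is zero")
    return Spectrum(spectrum.ppm.copy(), spectrum.intensity / total)


def bin_spectrum(spectrum: Spectrum, normalize: bool = False) -> pd.DataFrame:
    """Bucket a spectrum into the 290 fixed bins.

    Parameters
    ----------
    spectrum
        Must cover [0.5, 9.5] ppm.
    normalize
        Apply :func:`normalize_total_intensity` first.

    Returns
    -------
    DataFrame with columns ``bin_name``, ``ppm_low``, ``ppm_high``,
    ``center`` and ``intensity`` (sum of point intensities per bin).
    """
    spec = spectrum.ascending()
    if spec.ppm[0] > PPM_MIN or spec.ppm[-1] < PPM_MAX:
        raise ValueError(
            f"spectrum grid [{spec.ppm[0]:.3f}, {spec.ppm[-1]:.3f}] does not "
            f"cover the binning range [{PPM_MIN}, {PPM_MAX}] ppm"
        )
    if normalize:
        spec = normalize_total_intensity(spec)

    edges = bin_edges()
    intens = np.zeros(N_BINS)
    for i, (lo, hi) in enumerate(edges):
        if i == N_BINS - 1:  # final bin is closed so 9.5 ppm is retained
            mask = (spec.ppm >= lo) & (spec.ppm <= hi)
        else:  # half-open; the bin ending at 4.7 keeps the water edge excluded
            mask = (spec.ppm >= lo) & (spec.ppm < hi)
        intens[i] = spec.intensity[mask].sum()
    return pd.DataFrame(
        {
            "bin_name": bin_names(),
            "ppm_low": edges[:, 0],
            "ppm_high": edges[:, 1],
            "center": bin_centers(),
            "intensity": intens,
        }
    )


def bin_table_to_row(bins: pd.DataFrame, sample_id: str) -> pd.DataFrame:
    """One wide row per sample with bin names as column headers."""
    row = pd.DataFrame([bins["intensity"].to_numpy()], columns=list(bins["bin_name"]))
    row.insert(0, "sample_id", sample_id)
    return row
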