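"""Spectrum preprocessing: baseline normalization, four-level discretization,
window denoising, and m/z region assignment.

Two intensity views are maintained: the continuous baseline-normalized
intensities (used by ion matching and final scoring) and the discrete
four-level intensities (used by the probabilistic tag inference).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import Spectrum

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS: tuple[float, float, float] = (1.0, 3.0, 10.0)
DEFAULT_WINDOW_WIDTH: float = 100.0
DEFAULT_WINDOW_TOP_N: int = 6
N_LEVELS: int = 4
N_REGIONS: int = 5


@dataclass
class ProcessedSpectrum:
    """A spectrum together with its derived per-peak annotations."""

    spectrum: Spectrum
    norm_intensity: np.ndarray  # continuous view, baseline-normalized
    level: np.ndarray  # discrete view, int in {0,1,2,3}
    region: np.ndarray  # int in {0..n_regions-1}
    kept: np.ndarray  # bool, survived window filter and level-0 drop
    n_regions: int = N_REGIONS

    @property
    def precursor_neutral_mass(self) -> float:
        return self.spectrum.precursor_neutral_mass

    def kept_indices(self) -> np.ndarray:
        return np.flatnonzero(self.kept)

    def region_of_mz(self, mz: float) -> int:
        """Region index for an arbitrary m/z under this spectrum's binning."""
        return assign_region_for_mz(
            mz, self.spectrum.precursor_neutral_mass, self.n_regions
        )

    def level_at(self, mz: float, tolerance: float) -> int:
        """Discrete level of the nearest kept peak within tolerance, else 0."""
        idx = self.kept_indices()
        if idx.size == 0:
            return 0
        mzs = np.array([self.spectrum.peaks[i].mz for i in idx])
        j = int(np.argmin(np.abs(mzs - mz)))
        if abs(mzs[j] - mz) <= tolerance:
            return int(self.level[idx[j]])
        return 0

    def intensity_at(self, mz: float, tolerance: float) -> float:
        """Continuous normalized intensity of the nearest kept peak, else 0."""
        idx = self.kept_indices()
        if idx.size == 0:
            return 0.0
        mzs = np.array([self.spectrum.peaks[i].mz for i in idx])
        j = int(np.argmin(np.abs(mzs - mz)))
        if abs(mzs[j] - mz) <= tolerance:
            return float(self.norm_intensity[idx[j]])
        return 0.0


def normalize(spectrum: Spectrum, baseline_method: str = "median") -> np.ndarray:
    """Divide raw intensities by a baseline (median of nonzero intensities)."""
    raw = np.asarray(spectrum.intensity_array(), dtype=float)
    nonzero = raw[raw > 0]
    if nonzero.size == 0:
        raise ValueError("no signal: all peak intensities are zero")
    if baseline_method == "median":
        baseline = float(np.median(nonzero))
    elif baseline_method == "mean":
        baseline = float(np.mean(nonzero))
    else:
        raise ValueError(f"unknown baseline_method {baseline_method!r}")
    return raw / baseline


def discretize(
    norm_intensities: np.ndarray,
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
) -> np.ndarray:
    """Map normalized intensities to levels {0..3}.

    The level of a value is the number of thresholds strictly below it, so
    the output domain has exactly ``len(thresholds) + 1 == 4`` levels.
    """
    t = np.asarray(thresholds, dtype=float)
    if t.size != 3 or not np.all(np.diff(t) > 0):
        raise ValueError("thresholds must be 3 strictly ascending values")
    v = np.asarray(norm_intensities, dtype=float)
    return (v[:, None] > t[None, :]).sum(axis=1).astype(int)


def window_filter(
    spectrum: Spectrum,
    norm_intensities: np.ndarray,
    window_width: float = DEFAULT_WINDOW_WIDTH,
    top_n: int = DEFAULT_WINDOW_TOP_N,
) -> np.ndarray:
    """Keep at most ``top_n`` peaks per ``window_width``-Th window.

    Windows are consecutive bins [k*w, (k+1)*w); within each, the top_n
    most intense peaks (by normalized intensity) are kept. Idempotent.
    """
    if window_width <= 0:
        raise ValueError("window_width must be positive")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    mzs = np.asarray(spectrum.mz_array(), dtype=float)
    v = np.asarray(norm_intensities, dtype=float)
    kept = np.zeros(len(mzs), dtype=bool)
    bins = np.floor(mzs / window_width).astype(int)
    for b in np.unique(bins):
        idx = np.flatnonzero(bins == b)
        if idx.size <= top_n:
            kept[idx] = True
        else:
            order = idx[np.argsort(v[idx])[::-1]]
            kept[order[:top_n]] = True
    return kept


def assign_region_for_mz(mz: float, precursor_neutral_mass: float, n_regions: int = N_REGIONS) -> int:
    """Region of an m/z over [0, singly-protonated precursor mass]."""
    from .chem import PROTON

    upper = precursor_neutral_mass + PROTON
    width = upper / n_regions
    r = int(mz // width)
    return min(max(r, 0), n_regions - 1)


def assign_regions(
    spectrum: Spectrum, n_regions: int = N_REGIONS, tolerance: float = 1.0
) -> np.ndarray:
    """Per-peak region indices; the last bin is closed at the upper bound."""
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    from .chem import PROTON

    upper = spectrum.precursor_neutral_mass + PROTON
    out = np.empty(len(spectrum.peaks), dtype=int)
    for i, p in enumerate(spectrum.peaks):
        if p.mz > upper + tolerance:
            logger.warning(
                "%s: peak m/z %.3f beyond precursor bound %.3f; assigned last region",
                spectrum.identifier,
                p.mz,
                upper,
            )
        out[i] = assign_region_for_mz(p.mz, spectrum.precursor_neutral_mass, n_regions)
    return out


def preprocess(
    spectrum: Spectrum,
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
    window_width: float = DEFAULT_WINDOW_WIDTH,
    window_top_n: int = DEFAULT_WINDOW_TOP_N,
    n_regions: int = N_REGIONS,
    baseline_method: str = "median",
    drop_level0: bool = True,
) -> ProcessedSpectrum:
    """Run the full preprocessing chain on one spectrum.

    Peaks at level 0 ("no signal") after discretization are dropped before
    graph construction when ``drop_level0`` is set.
    """
    norm = normalize(spectrum, baseline_method)
    level = discretize(norm, thresholds)
    kept = window_filter(spectrum, norm, window_width, window_top_n)
    if drop_level0:
        kept &= level > 0
    region = assign_regions(spectrum, n_regions)
    return ProcessedSpectrum(
        spectrum=spectrum,
        norm_intensity=norm,
        level=level,
        region=region,
        kept=kept,
        n_regions=n_regions,
    )
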