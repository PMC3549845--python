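"""Theoretical fragmentation and correlation scoring.

Candidate peptides are fragmented in silico into 9 ion types with fixed
empirical intensities (b+/y+ = 100, b2+/y2+ = 50, a+ and all water/ammonia
losses = 20), aligned to the experimental spectrum, and scored by
Sc = Nb! * Ny! * sum(I_i * P_i), evaluated in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import gammaln

from .chem import AMMONIA, CO, PROTON, WATER, RESIDUE_MASS
from .preprocess import ProcessedSpectrum

#: Empirical relative intensities of the modeled ion types.
ION_INTENSITY: dict[str, float] = {
    "b": 100.0,
    "y": 100.0,
    "b2": 50.0,
    "y2": 50.0,
    "a": 20.0,
    "b-H2O": 20.0,
    "y-H2O": 20.0,
    "b-NH3": 20.0,
    "y-NH3": 20.0,
}

B_SERIES = ("b", "b2")
Y_SERIES = ("y", "y2")

DEFAULT_FRAGMENT_TOLERANCE = 0.5


@dataclass(frozen=True)
class TheoreticalPeak:
    mz: float
    intensity: float
    ion_type: str
    ordinal: int  # fragment index, 1-based (b3 has ordinal 3)


@dataclass
class TheoreticalSpectrum:
    peaks: list[TheoreticalPeak]
    peptide: str
    charge: int


@dataclass
class MatchResult:
    theo: TheoreticalSpectrum
    I: list[float]  # experimental intensities aligned to theo.peaks, 0 if unmatched
    Nb: int
    Ny: int
    matched: list[tuple[int, int, float]]  # (theo index, exp peak index, mass error)


def theoretical_spectrum(
    peptide: str, charge: int, emit_doubly_charged: bool | None = None
) -> TheoreticalSpectrum:
    """All theoretical fragments of a peptide.

    Doubly charged b/y ions are emitted only for precursor charge >= 2
    (or as forced by ``emit_doubly_charged``).
    """
    if len(peptide) < 2:
        raise ValueError("peptide must have at least 2 residues")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    doubly = charge >= 2 if emit_doubly_charged is None else emit_doubly_charged
    total = sum(RESIDUE_MASS[a] for a in peptide)
    peaks: list[TheoreticalPeak] = []
    prefix = 0.0
    for i in range(1, len(peptide)):
        prefix += RESIDUE_MASS[peptide[i - 1]]
        suffix = total - prefix
        b = prefix + PROTON
        y = suffix + WATER + PROTON
        series = [
            ("b", b, i),
            ("a", b - CO, i),
            ("b-H2O", b - WATER, i),
            ("b-NH3", b - AMMONIA, i),
            ("y", y, len(peptide) - i),
            ("y-H2O", y - WATER, len(peptide) - i),
            ("y-NH3", y - AMMONIA, len(peptide) - i),
        ]
        if doubly:
            series.append(("b2", (prefix + 2 * PROTON) / 2, i))
            series.append(("y2", (suffix + WATER + 2 * PROTON) / 2, len(peptide) - i))
        for ion, mz, ordinal in series:
            peaks.append(TheoreticalPeak(mz, ION_INTENSITY[ion], ion, ordinal))
    peaks.sort(key=lambda p: (p.mz, p.ion_type))
    return TheoreticalSpectrum(peaks=peaks, peptide=peptide, charge=charge)


def match(
    spectrum: ProcessedSpectrum,
    theo: TheoreticalSpectrum,
    tolerance: float = DEFAULT_FRAGMENT_TOLERANCE,
) -> MatchResult:
    """Greedy closest-pair-first assignment of experimental to theoretical peaks.

    Each experimental peak is used at most once; I carries the continuous
    normalized intensities, 0 where no peak matched. Nb/Ny count matched
    primary-series ions (b+, b2+ / y+, y2+).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    exp_idx = [int(i) for i in spectrum.kept_indices()]
    pairs: list[tuple[float, int, int]] = []  # (|error|, theo index, exp index)
    for t, tp in enumerate(theo.peaks):
        for e in exp_idx:
            err = abs(spectrum.spectrum.peaks[e].mz - tp.mz)
            if err <= tolerance:
                pairs.append((err, t, e))
    pairs.sort()
    I = [0.0] * len(theo.peaks)
    used_exp: set[int] = set()
    used_theo: set[int] = set()
    matched: list[tuple[int, int, float]] = []
    for err, t, e in pairs:
        if t in used_theo or e in used_exp:
            continue
        used_theo.add(t)
        used_exp.add(e)
        I[t] = float(spectrum.norm_intensity[e])
        matched.append((t, e, err))
    # a fragment position counts once even when both charge states match
    Nb = len({theo.peaks[t].ordinal for t, _, _ in matched if theo.peaks[t].ion_type in B_SERIES})
    Ny = len({theo.peaks[t].ordinal for t, _, _ in matched if theo.peaks[t].ion_type in Y_SERIES})
    return MatchResult(theo=theo, I=I, Nb=Nb, Ny=Ny, matched=matched)


def correlation_score(result: MatchResult) -> tuple[float, bool]:
    """Log-space correlation score.

    Returns (Sc_log, no_match). Sc_log = logGamma(Nb+1) + logGamma(Ny+1)
    + log(sum I_i * P_i); when the dot product is zero the score is 0 and
    the no_match flag is set. exp(Sc_log) equals the literal product
    Nb! * Ny! * dot exactly within floating range.
    """
    if any(v < 0 for v in result.I):
        raise ValueError("negative experimental intensity")
    dot = sum(i * p.intensity for i, p in zip(result.I, result.theo.peaks))
    if dot == 0.0:
        return 0.0, True
    sc = float(gammaln(result.Nb + 1) + gammaln(result.Ny + 1) + math.log(dot))
    return sc, False
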