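"""Monoisotopic mass constants and residue mass tables.

All masses are in Daltons, monoisotopic. Fragment-ion m/z arithmetic
throughout the package is built on the constants defined here.
"""

from __future__ import annotations

PROTON: float = 1.007276
WATER: float = 18.010565
AMMONIA: float = 17.026549
CO: float = 27.994915

#: Monoisotopic residue (not amino acid) masses for the 20 standard letters.
RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "W": 186.07931,
    "Y": 163.06333,
}

STANDARD_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"

#: Mass gap below which Q and K cannot be told apart by a fragment tolerance.
QK_MASS_GAP: float = RESIDUE_MASS["K"] - RESIDUE_MASS["Q"]


def peptide_residue_mass(sequence: str) -> float:
    """Sum of residue masses of ``sequence`` (no water, no proton)."""
    try:
        return sum(RESIDUE_MASS[a] for a in sequence)
    except KeyError as exc:  # X or other non-standard letters carry no mass
        raise ValueError(f"residue without defined mass: {exc}") from exc


def peptide_neutral_mass(sequence: str) -> float:
    """Neutral monoisotopic mass of the intact peptide (residues + water)."""
    return peptide_residue_mass(sequence) + WATER


def precursor_mz(sequence: str, charge: int) -> float:
    """m/z of the protonated peptide at the given charge state."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (peptide_neutral_mass(sequence) + charge * PROTON) / charge


def neutral_mass_from_mz(mz: float, charge: int) -> float:
    """Neutral mass implied by an observed precursor m/z and charge."""
    return mz * charge - charge * PROTON
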