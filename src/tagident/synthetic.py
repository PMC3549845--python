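"""Synthetic spectra and databases for training and evaluation.

The generator emulates b/y fragment ladders of tryptic peptides with
ion-type-dependent intensity levels, per-ion detection probabilities,
Gaussian m/z jitter, and uniform noise peaks, and records full per-peak
annotations so every pipeline stage can be validated without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bayes_model import ION_TYPES, ion_mz
from .chem import PROTON, peptide_residue_mass, precursor_mz
from .io_formats import Peak, PeptideRecord, ProteinRecord, Spectrum, digest

#: Raw-intensity bands per discrete level; the level-1 band doubles as the
#: chemical-baseline population the median normalization anchors on.
DEFAULT_LEVEL_INTENSITY: dict[int, tuple[float, float]] = {
    1: (150.0, 250.0),
    2: (400.0, 900.0),
    3: (1200.0, 3000.0),
}


def _default_detection() -> dict[str, float]:
    return {
        "b": 0.95,
        "y": 0.95,
        "a": 0.5,
        "b2": 0.4,
        "y2": 0.4,
        "b-H2O": 0.4,
        "y-H2O": 0.4,
        "b-NH3": 0.4,
        "y-NH3": 0.4,
    }


def _default_level_dist() -> dict[str, tuple[float, float, float, float]]:
    return {
        "b": (0.0, 0.1, 0.4, 0.5),
        "y": (0.0, 0.1, 0.4, 0.5),
        "a": (0.3, 0.5, 0.2, 0.0),
        "b2": (0.2, 0.4, 0.3, 0.1),
        "y2": (0.2, 0.4, 0.3, 0.1),
        "b-H2O": (0.3, 0.5, 0.2, 0.0),
        "y-H2O": (0.3, 0.5, 0.2, 0.0),
        "b-NH3": (0.3, 0.5, 0.2, 0.0),
        "y-NH3": (0.3, 0.5, 0.2, 0.0),
    }


@dataclass
class SimulationParams:
    """All knobs of the spectrum/database generator; the seed fixes every draw."""

    n_proteins: int = 500
    protein_length_mean: int = 300
    seed: int = 0
    charge: int = 2
    detection: dict[str, float] = field(default_factory=_default_detection)
    level_dist: dict[str, tuple[float, float, float, float]] = field(
        default_factory=_default_level_dist
    )
    level_intensity: dict[int, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LEVEL_INTENSITY)
    )
    noise_mean: float = 30.0  # Poisson mean of the noise-peak count
    noise_intensity: tuple[float, float] = (60.0, 140.0)
    noise_mz_min: float = 100.0
    mass_jitter_sd: float = 0.0  # Dalton

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def noise_free_params(seed: int = 0) -> SimulationParams:
    """Deterministic-ladder preset: every ion detected, no jitter, no noise.

    Secondary ions sit in the level-1 band and double as the baseline
    population, so the primary b/y ladder lands above it after median
    normalization.
    """
    detection = {ion: 1.0 for ion in ION_TYPES}
    detection["b2"] = detection["y2"] = 0.0
    level_dist = {
        "b": (0.0, 0.0, 0.5, 0.5),
        "y": (0.0, 0.0, 0.5, 0.5),
        "a": (0.0, 1.0, 0.0, 0.0),
        "b2": (1.0, 0.0, 0.0, 0.0),
        "y2": (1.0, 0.0, 0.0, 0.0),
        "b-H2O": (0.0, 1.0, 0.0, 0.0),
        "y-H2O": (0.0, 1.0, 0.0, 0.0),
        "b-NH3": (0.0, 1.0, 0.0, 0.0),
        "y-NH3": (0.0, 1.0, 0.0, 0.0),
    }
    return SimulationParams(
        seed=seed,
        detection=detection,
        level_dist=level_dist,
        # the level-1 secondary ions sit exactly on the median baseline so
        # they discretize to level 0 and only the b/y ladder enters the graph
        level_intensity={1: (100.0, 100.0), 2: (400.0, 900.0), 3: (1200.0, 3000.0)},
        noise_mean=0.0,
        mass_jitter_sd=0.0,
    )


def generate_fasta(params: SimulationParams, rng: np.random.Generator | None = None) -> list[ProteinRecord]:
    """Reproducible random proteins, uniform over the 20 standard residues.

    Uniform residue usage puts K/R at 10% joint frequency, giving tryptic
    peptides of usable (~10 residue) mean length.
    """
    rng = rng if rng is not None else params.rng()
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    proteins = []
    for i in range(params.n_proteins):
        length = max(int(rng.poisson(params.protein_length_mean)), 20)
        seq = "".join(rng.choice(letters, size=length))
        proteins.append(
            ProteinRecord(
                accession=f"SYN{i:05d}", description="synthetic protein", sequence=seq
            )
        )
    return proteins


def simulate_spectrum(
    peptide: str,
    charge: int,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
    identifier: str = "",
) -> tuple[Spectrum, dict]:
    """Simulate one annotated spectrum of a peptide.

    Returns the spectrum and an annotation dict with the true peptide and
    per-fragment-peak labels ``(mz, ion_type, site)``.
    """
    if len(peptide) < 2:
        raise ValueError("peptide must have at least 2 residues")
    rng = rng if rng is not None else params.rng()
    total = peptide_residue_mass(peptide)
    prec_mz = precursor_mz(peptide, charge)

    peaks: list[Peak] = []
    labels: list[tuple[float, str, int]] = []
    prefix = 0.0
    for site in range(1, len(peptide)):
        prefix += peptide_residue_mass(peptide[site - 1])
        for ion in ION_TYPES:
            if ion in ("b2", "y2") and charge < 2:
                continue
            if rng.random() >= params.detection.get(ion, 0.0):
                continue
            level = int(rng.choice(4, p=params.level_dist[ion]))
            if level == 0:
                continue
            lo, hi = params.level_intensity[level]
            intensity = float(rng.uniform(lo, hi))
            mz = ion_mz(ion, prefix, total)
            if params.mass_jitter_sd > 0:
                mz += float(rng.normal(0.0, params.mass_jitter_sd))
            if mz <= 0:
                continue
            peaks.append(Peak(mz, intensity))
            labels.append((mz, ion, site))

    n_noise = int(rng.poisson(params.noise_mean)) if params.noise_mean > 0 else 0
    mz_hi = total + PROTON + 18.010565
    for _ in range(n_noise):
        mz = float(rng.uniform(params.noise_mz_min, mz_hi))
        intensity = float(rng.uniform(*params.noise_intensity))
        peaks.append(Peak(mz, intensity))

    spectrum = Spectrum(
        peaks=peaks,
        precursor_mz=prec_mz,
        precursor_charge=charge,
        identifier=identifier or f"sim|{peptide}",
    )
    annotation = {"peptide": peptide, "charge": charge, "fragments": labels}
    return spectrum, annotation


def sample_tryptic_peptides(
    proteins: list[ProteinRecord],
    n: int,
    rng: np.random.Generator,
    min_len: int = 7,
    max_len: int = 20,
) -> list[PeptideRecord]:
    """Draw n fully tryptic peptides (0 missed cleavages) uniformly."""
    pool: list[PeptideRecord] = []
    for prot in proteins:
        pool.extend(digest(prot, missed_cleavages=0, min_len=min_len, max_len=max_len))
    pool = [p for p in pool if "X" not in p.sequence]
    if not pool:
        raise ValueError("no tryptic peptides available in the database")
    idx = rng.choice(len(pool), size=min(n, len(pool)), replace=False)
    return [pool[int(i)] for i in idx]


def generate_benchmark(
    params: SimulationParams, n_spectra: int
) -> tuple[list[ProteinRecord], list[tuple[Spectrum, str]]]:
    """A synthetic database plus annotated spectra of peptides drawn from it."""
    rng = params.rng()
    proteins = generate_fasta(params, rng)
    peptides = sample_tryptic_peptides(proteins, n_spectra, rng)
    annotated = []
    for i, pep in enumerate(peptides):
        spec, _ = simulate_spectrum(
            pep.sequence, params.charge, params, rng, identifier=f"sim_{i:04d}"
        )
        annotated.append((spec, pep.sequence))
    return proteins, annotated
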