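"""Trainable probabilistic fragmentation model for vertex scoring.

Each candidate cleavage mass is scored by a likelihood ratio comparing the
hypothesis that the surrounding peaks are genuine fragment ions against the
hypothesis that they arise at random. The fragment hypothesis is a small
Bayesian network over ion-type nodes: the primary b+ and y+ ions are root
observables, and each secondary ion (a+, doubly charged, water/ammonia
losses) is conditioned on its primary parent. Every conditional table is
additionally indexed by the spectrum region R and by coarse chemical
classes of the residues flanking the cleavage (NT, CT).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem import AMMONIA, CO, PROTON, WATER, peptide_residue_mass
from .io_formats import Spectrum
from .preprocess import N_LEVELS, N_REGIONS, ProcessedSpectrum, preprocess

MODEL_FORMAT_VERSION = 1

#: Ion-type nodes of the network; parents map secondary ions to primaries.
ION_TYPES: tuple[str, ...] = (
    "b", "y", "a", "b2", "y2", "b-H2O", "y-H2O", "b-NH3", "y-NH3",
)
PARENTS: dict[str, str] = {
    "a": "b",
    "b2": "b",
    "b-H2O": "b",
    "b-NH3": "b",
    "y2": "y",
    "y-H2O": "y",
    "y-NH3": "y",
}
ROOTS: tuple[str, ...] = ("b", "y")

#: Coarse flanking-residue chemistry classes.
FLANK_CLASSES: tuple[str, ...] = ("KR", "H", "P", "G", "other")
N_FLANK = len(FLANK_CLASSES)


def flank_class(residue: str) -> int:
    if residue in ("K", "R"):
        return 0
    if residue == "H":
        return 1
    if residue == "P":
        return 2
    if residue == "G":
        return 3
    return 4


def ion_mz(ion: str, prefix_mass: float, total_residue_mass: float) -> float:
    """Theoretical m/z of an ion type at a cleavage prefix mass."""
    s = total_residue_mass - prefix_mass
    if ion == "b":
        return prefix_mass + PROTON
    if ion == "a":
        return prefix_mass + PROTON - CO
    if ion == "b2":
        return (prefix_mass + 2 * PROTON) / 2
    if ion == "b-H2O":
        return prefix_mass + PROTON - WATER
    if ion == "b-NH3":
        return prefix_mass + PROTON - AMMONIA
    if ion == "y":
        return s + WATER + PROTON
    if ion == "y2":
        return (s + WATER + 2 * PROTON) / 2
    if ion == "y-H2O":
        return s + PROTON
    if ion == "y-NH3":
        return s + WATER + PROTON - AMMONIA
    raise ValueError(f"unknown ion type {ion!r}")


def active_ions(charge: int) -> tuple[str, ...]:
    """Doubly charged fragments are only modeled for charge >= 2 precursors."""
    if charge >= 2:
        return ION_TYPES
    return tuple(i for i in ION_TYPES if i not in ("b2", "y2"))


@dataclass
class CPTModel:
    """Conditional probability tables of the fragmentation network.

    ``root_counts[ion]`` has shape (R, NT, CT, level); ``child_counts[ion]``
    has shape (R, NT, CT, parent_level, level). Probabilities are computed
    with Laplace smoothing so every table row is a proper distribution with
    strictly positive entries.
    """

    smoothing: float = 1.0
    root_counts: dict[str, np.ndarray] = field(default_factory=dict)
    child_counts: dict[str, np.ndarray] = field(default_factory=dict)
    fragment_tolerance: float = 0.5
    trained: bool = False

    def __post_init__(self) -> None:
        for ion in ROOTS:
            self.root_counts.setdefault(
                ion, np.zeros((N_REGIONS, N_FLANK, N_FLANK, N_LEVELS))
            )
        for ion in PARENTS:
            self.child_counts.setdefault(
                ion, np.zeros((N_REGIONS, N_FLANK, N_FLANK, N_LEVELS, N_LEVELS))
            )

    def prob(
        self,
        ion: str,
        level: int,
        region: int,
        nt: int | None,
        ct: int | None,
        parent_level: int | None = None,
    ) -> float:
        """Smoothed conditional probability of observing ``level`` at ``ion``.

        ``nt``/``ct`` of None marginalize the empirical counts over the
        corresponding flanking class (used when flanks are unknown at
        scoring time).
        """
        if ion in ROOTS:
            c = self.root_counts[ion][region]
        else:
            if parent_level is None:
                raise ValueError(f"ion {ion} requires a parent level")
            c = self.child_counts[ion][region, ..., parent_level, :]
        if nt is None:
            c = c.sum(axis=0)
        else:
            c = c[nt]
        if ct is None:
            c = c.sum(axis=0)
        else:
            c = c[ct]
        row = c + self.smoothing
        return float(row[level] / row.sum())

    def marginal(self, ion: str) -> np.ndarray:
        """Marginal level distribution of an ion type over all contexts."""
        if ion in ROOTS:
            c = self.root_counts[ion].sum(axis=(0, 1, 2))
        else:
            c = self.child_counts[ion].sum(axis=(0, 1, 2, 3))
        row = c + self.smoothing
        return row / row.sum()

    def to_dict(self) -> dict:
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "smoothing": self.smoothing,
            "fragment_tolerance": self.fragment_tolerance,
            "trained": self.trained,
            "root_counts": {k: v.tolist() for k, v in self.root_counts.items()},
            "child_counts": {k: v.tolist() for k, v in self.child_counts.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CPTModel":
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model format version")
        m = cls(smoothing=d["smoothing"], fragment_tolerance=d["fragment_tolerance"])
        m.trained = d["trained"]
        m.root_counts = {k: np.asarray(v, float) for k, v in d["root_counts"].items()}
        m.child_counts = {k: np.asarray(v, float) for k, v in d["child_counts"].items()}
        return m


@dataclass
class NoiseModel:
    """Per-region level distribution of peaks unexplained by any fragment."""

    counts: np.ndarray = field(
        default_factory=lambda: np.zeros((N_REGIONS, N_LEVELS))
    )
    smoothing: float = 1.0

    def prob(self, region: int, level: int) -> float:
        row = self.counts[region] + self.smoothing
        return float(row[level] / row.sum())

    def to_dict(self) -> dict:
        return {"counts": self.counts.tolist(), "smoothing": self.smoothing}

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseModel":
        return cls(counts=np.asarray(d["counts"], float), smoothing=d["smoothing"])


def save_models(model: CPTModel, noise: NoiseModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"cpt": model.to_dict(), "noise": noise.to_dict()}, fh)


def load_models(path: str | Path) -> tuple[CPTModel, NoiseModel]:
    with open(path) as fh:
        d = json.load(fh)
    return CPTModel.from_dict(d["cpt"]), NoiseModel.from_dict(d["noise"])


def train(
    annotated: list[tuple[Spectrum, str]],
    smoothing: float = 1.0,
    fragment_tolerance: float = 0.5,
    preprocess_kwargs: dict | None = None,
) -> tuple[CPTModel, NoiseModel]:
    """Estimate CPTs and the noise model from annotated spectra.

    For every cleavage site of every annotated peptide, the discrete level
    observed at each ion type's theoretical m/z is recorded under its
    context (region of that m/z, flanking-residue classes, parent level).
    Kept peaks matching no theoretical fragment feed the noise model; the
    noise "no signal" mass is estimated from the number of unoccupied
    tolerance-sized slots per region.
    """
    if not annotated:
        raise ValueError("empty training set")
    if smoothing <= 0:
        raise ValueError("smoothing must be > 0")
    model = CPTModel(smoothing=smoothing, fragment_tolerance=fragment_tolerance)
    noise = NoiseModel(smoothing=smoothing)
    pk = preprocess_kwargs or {}

    for spectrum, peptide in annotated:
        proc = preprocess(spectrum, **pk)
        total = peptide_residue_mass(peptide)
        ions = active_ions(spectrum.precursor_charge)
        fragment_mzs: list[float] = []
        prefix = 0.0
        for j in range(1, len(peptide)):
            prefix += peptide_residue_mass(peptide[j - 1])
            nt = flank_class(peptide[j - 1])
            ct = flank_class(peptide[j])
            levels = {}
            for ion in ions:
                mz = ion_mz(ion, prefix, total)
                fragment_mzs.append(mz)
                levels[ion] = proc.level_at(mz, fragment_tolerance)
            for ion in ions:
                mz = ion_mz(ion, prefix, total)
                region = proc.region_of_mz(mz)
                if ion in ROOTS:
                    model.root_counts[ion][region, nt, ct, levels[ion]] += 1
                else:
                    parent = levels[PARENTS[ion]]
                    model.child_counts[ion][region, nt, ct, parent, levels[ion]] += 1

        # noise: kept peaks not explained by any theoretical fragment
        frag = np.asarray(sorted(fragment_mzs))
        upper = proc.precursor_neutral_mass + PROTON
        slot = 2 * fragment_tolerance
        occupied = np.zeros(N_REGIONS)
        for i in proc.kept_indices():
            p = proc.spectrum.peaks[int(i)]
            j = int(np.searchsorted(frag, p.mz))
            near = min(
                abs(frag[k] - p.mz) for k in (j - 1, j) if 0 <= k < len(frag)
            ) if len(frag) else math.inf
            region = int(proc.region[i])
            if near > fragment_tolerance:
                noise.counts[region, int(proc.level[i])] += 1
                occupied[region] += 1
        # remaining slots in each region observed as "no signal"
        region_width = upper / N_REGIONS
        for r in range(N_REGIONS):
            free = max(region_width / slot - occupied[r], 0.0)
            noise.counts[r, 0] += free

    model.trained = True
    return model, noise


def p_real(
    vertex_mass: float,
    proc: ProcessedSpectrum,
    model: CPTModel,
    nt: int | None = None,
    ct: int | None = None,
) -> float:
    """Probability of the observed levels around ``vertex_mass`` under the
    fragment hypothesis: the product of the network's conditionals."""
    if not model.trained:
        raise ValueError("model is untrained; call train() first")
    total = proc.precursor_neutral_mass - WATER
    tol = model.fragment_tolerance
    ions = active_ions(proc.spectrum.precursor_charge)
    levels = {
        ion: proc.level_at(ion_mz(ion, vertex_mass, total), tol) for ion in ions
    }
    p = 1.0
    for ion in ions:
        region = proc.region_of_mz(ion_mz(ion, vertex_mass, total))
        parent = levels[PARENTS[ion]] if ion in PARENTS else None
        p *= model.prob(ion, levels[ion], region, nt, ct, parent)
    return p


def p_random(
    vertex_mass: float, proc: ProcessedSpectrum, noise: NoiseModel,
    fragment_tolerance: float = 0.5, charge: int | None = None,
) -> float:
    """Probability of the same observations under the random-peak hypothesis:
    the product of per-position noise probabilities."""
    total = proc.precursor_neutral_mass - WATER
    ions = active_ions(charge if charge is not None else proc.spectrum.precursor_charge)
    p = 1.0
    for ion in ions:
        mz = ion_mz(ion, vertex_mass, total)
        level = proc.level_at(mz, fragment_tolerance)
        p *= noise.prob(proc.region_of_mz(mz), level)
    return p


def score_vertex(
    vertex_mass: float,
    proc: ProcessedSpectrum,
    model: CPTModel,
    noise: NoiseModel,
    nt: int | None = None,
    ct: int | None = None,
) -> float:
    """Likelihood-ratio vertex score: log(p_real / p_random), natural log."""
    num = p_real(vertex_mass, proc, model, nt, ct)
    den = p_random(vertex_mass, proc, noise, model.fragment_tolerance)
    return math.log(num / den)


def score_graph(graph, proc: ProcessedSpectrum, model: CPTModel, noise: NoiseModel) -> None:
    """Fill in the score of every non-terminal vertex of a spectrum graph."""
    for v in graph.vertices:
        if v.interpretation in ("source", "sink"):
            v.score = 0.0
        else:
            v.score = score_vertex(v.prefix_mass, proc, model, noise)
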