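"""Error-tolerant tag-versus-database search.

Tags are aligned locally (affine-gap Smith-Waterman) against candidate
database peptides using a BLOSUM62 variant tailored to mass spectrometry:
isobaric residue pairs (L/I exactly, Q/K within typical tolerance) are made
mutually interchangeable, undefined residues (X) score zero, and a
cleavage-anchor symbol scoring like K/R marks tryptic boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from .chem import peptide_neutral_mass
from .io_formats import PeptideRecord
from .tag_inference import SequenceTag

#: Symbol anchoring a tryptic cleavage site preceding a peptide.
CLEAVAGE_ANCHOR = "#"

ISOBARIC_PAIRS: tuple[tuple[str, str], ...] = (("L", "I"), ("Q", "K"))

DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0
DEFAULT_MAX_HITS = 50
DEFAULT_MASS_WINDOW = 2.5


@dataclass
class SubstitutionMatrix:
    """Symmetric substitution scores over residues + X + cleavage anchor."""

    alphabet: str
    scores: np.ndarray
    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND

    def __post_init__(self) -> None:
        self._index = {a: i for i, a in enumerate(self.alphabet)}

    def score(self, a: str, b: str) -> float:
        return float(self.scores[self._index[a], self._index[b]])


@dataclass
class QueryHit:
    peptide: PeptideRecord
    Ss: float
    tag_span: tuple[int, int]  # 0-based half-open on the tag
    peptide_span: tuple[int, int]
    tag: SequenceTag


def build_matrix(
    gap_open: float = DEFAULT_GAP_OPEN, gap_extend: float = DEFAULT_GAP_EXTEND
) -> SubstitutionMatrix:
    """BLOSUM62 modified for MS tag search.

    For each isobaric pair {a, b}: the 2x2 block s(a,a), s(a,b), s(b,a),
    s(b,b) is set to the average of the two original diagonal entries, and
    for every other residue x the pair's off-block scores are averaged
    (s(a,x) = s(b,x)), making a and b fully interchangeable. The X row and
    column are zeroed, and the cleavage-anchor symbol scores the K/R
    diagonal average against K and R (zero elsewhere).
    """
    blosum = substitution_matrices.load("BLOSUM62")
    residues = "ACDEFGHIKLMNPQRSTVWY"
    alphabet = residues + "X" + CLEAVAGE_ANCHOR
    n = len(alphabet)
    m = np.zeros((n, n))
    for i, a in enumerate(residues):
        for j, b in enumerate(residues):
            m[i, j] = blosum[a, b]

    idx = {a: i for i, a in enumerate(alphabet)}
    group = {a: (a,) for a in residues}
    for a, b in ISOBARIC_PAIRS:
        group[a] = group[b] = (a, b)
    for a in residues:
        for b in residues:
            ga, gb = group[a], group[b]
            if len(ga) == 1 and len(gb) == 1:
                continue
            if ga == gb:
                # within a pair: the average of the two original diagonals
                m[idx[a], idx[b]] = sum(blosum[x, x] for x in ga) / len(ga)
            else:
                # against anything else: average over the pair's members so
                # the members are fully interchangeable
                m[idx[a], idx[b]] = sum(
                    blosum[x, y] for x in ga for y in gb
                ) / (len(ga) * len(gb))

    m[idx["X"], :] = 0.0
    m[:, idx["X"]] = 0.0
    kr = (blosum["K", "K"] + blosum["R", "R"]) / 2.0
    ianch = idx[CLEAVAGE_ANCHOR]
    m[ianch, :] = 0.0
    m[:, ianch] = 0.0
    for x in "KR":
        m[ianch, idx[x]] = m[idx[x], ianch] = kr
    m[ianch, ianch] = kr
    return SubstitutionMatrix(alphabet, m, gap_open, gap_extend)


def smith_waterman(
    a: str, b: str, matrix: SubstitutionMatrix
) -> tuple[float, tuple[int, int], tuple[int, int]]:
    """Affine-gap local alignment score and aligned spans (half-open).

    Gotoh three-state DP; opening a gap costs gap_open + gap_extend,
    extending costs gap_extend.
    """
    la, lb = len(a), len(b)
    open_cost = matrix.gap_open + matrix.gap_extend
    ext = matrix.gap_extend
    NEG = float("-inf")
    H = np.zeros((la + 1, lb + 1))
    E = np.full((la + 1, lb + 1), NEG)  # gap in a (moving along b)
    F = np.full((la + 1, lb + 1), NEG)  # gap in b
    best, best_pos = 0.0, (0, 0)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            E[i, j] = max(H[i, j - 1] - open_cost, E[i, j - 1] - ext)
            F[i, j] = max(H[i - 1, j] - open_cost, F[i - 1, j] - ext)
            h = max(
                0.0,
                H[i - 1, j - 1] + matrix.score(a[i - 1], b[j - 1]),
                E[i, j],
                F[i, j],
            )
            H[i, j] = h
            if h > best:
                best, best_pos = h, (i, j)
    if best == 0.0:
        return 0.0, (0, 0), (0, 0)
    # traceback for spans only (score path reconstruction not needed)
    i, j = best_pos
    end_a, end_b = i, j
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            if i == 0 or j == 0 or H[i, j] == 0:
                break
            diag = H[i - 1, j - 1] + matrix.score(a[i - 1], b[j - 1])
            if H[i, j] == diag:
                i, j = i - 1, j - 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            if j == 0:
                break
            if E[i, j] == H[i, j - 1] - open_cost:
                state = "H"
            j -= 1
        else:
            if i == 0:
                break
            if F[i, j] == H[i - 1, j] - open_cost:
                state = "H"
            i -= 1
    return float(best), (i, end_a), (j, end_b)


def encode_peptide(peptide: str) -> str:
    """Database-side encoding: anchor prepended; internal K rewritten to Q.

    K is reserved for the tryptic C-terminus; internal lysines score through
    the averaged isobaric code (Q), which the modified matrix makes
    score-identical anyway.
    """
    if not peptide:
        return CLEAVAGE_ANCHOR
    body = peptide[:-1].replace("K", "Q") + peptide[-1]
    return CLEAVAGE_ANCHOR + body


@dataclass
class PeptideIndex:
    """Database peptides sorted by neutral mass for windowed lookup."""

    peptides: list[PeptideRecord]

    def __post_init__(self) -> None:
        keyed = []
        for p in self.peptides:
            try:
                mass = peptide_neutral_mass(p.sequence.replace("X", "G"))
            except ValueError:
                continue
            keyed.append((mass, p))
        keyed.sort(key=lambda t: (t[0], t[1].sequence, t[1].parent_accession))
        self._masses = np.array([t[0] for t in keyed])
        self._sorted = [t[1] for t in keyed]

    def __len__(self) -> int:
        return len(self._sorted)

    def in_mass_window(self, neutral_mass: float, window: float) -> list[PeptideRecord]:
        lo = int(np.searchsorted(self._masses, neutral_mass - window, side="left"))
        hi = int(np.searchsorted(self._masses, neutral_mass + window, side="right"))
        return self._sorted[lo:hi]

    def all(self) -> list[PeptideRecord]:
        return list(self._sorted)


def query(
    tags: list[SequenceTag],
    index: PeptideIndex,
    matrix: SubstitutionMatrix,
    max_hits: int = DEFAULT_MAX_HITS,
    precursor_neutral_mass: float | None = None,
    mass_window: float = DEFAULT_MASS_WINDOW,
) -> list[QueryHit]:
    """Search all tags of one spectrum against the peptide index.

    Candidates are prefiltered by the precursor mass window when a
    precursor mass is given (the tag's own gaps imply the same mass).
    Per-peptide hits from multiple tags are merged keeping the maximum Ss;
    at most ``max_hits`` hits are returned, ranked by Ss descending.
    """
    if max_hits < 1:
        raise ValueError("max_hits must be >= 1")
    if not tags or len(index) == 0:
        return []
    best: dict[tuple[str, str, int], QueryHit] = {}
    for tag in tags:
        mass = precursor_neutral_mass
        if mass is None:
            mass = tag.implied_neutral_mass()
        candidates = (
            index.in_mass_window(mass, mass_window) if mass_window > 0 else index.all()
        )
        for pep in candidates:
            encoded = encode_peptide(pep.sequence)
            score, span_t, span_p = smith_waterman(tag.residues, encoded, matrix)
            if score <= 0:
                continue
            # shift spans back past the prepended anchor
            pspan = (max(span_p[0] - 1, 0), max(span_p[1] - 1, 0))
            key = (pep.sequence, pep.parent_accession, pep.start)
            hit = QueryHit(peptide=pep, Ss=score, tag_span=span_t, peptide_span=pspan, tag=tag)
            if key not in best or score > best[key].Ss:
                best[key] = hit
    hits = sorted(best.values(), key=lambda h: (-h.Ss, h.peptide.sequence))
    return hits[:max_hits]
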