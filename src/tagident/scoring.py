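"""Final scoring: combine similarity and correlation evidence, rank
candidates, compute delta scores, target-decoy FDR, and the sequence
inference accuracy metric.

The printed combination S = W*Ss * (1-W)*Sc is a pure product in which the
weight cannot change relative ranking, so the default mode is the weighted
sum of per-spectrum min-max-normalized scores; the literal product remains
available behind ``mode="literal_product"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chem import QK_MASS_GAP, RESIDUE_MASS
from .io_formats import PeptideRecord
from .tag_inference import SequenceTag

DEFAULT_W_DENOVO = 0.5
DECOY_PREFIX = "DECOY_"


@dataclass
class PSM:
    spectrum_id: str
    peptide: PeptideRecord
    Ss: float
    Sc_log: float
    S: float = 0.0
    D: float | None = None
    rank: int = 0
    is_decoy: bool = False
    tags_used: list[SequenceTag] = field(default_factory=list)


def minmax_normalize(values: list[float]) -> list[float]:
    """Per-spectrum min-max normalization; degenerate spread maps to 1.0."""
    if not values:
        return []
    lo, hi = min(values), max(values)
    if hi == lo:
        return [1.0] * len(values)
    return [(v - lo) / (hi - lo) for v in values]


def final_score(
    Ss_norm: float, Sc_norm: float, W: float = DEFAULT_W_DENOVO, mode: str = "weighted_sum"
) -> float:
    """Combine normalized de novo and database evidence into S."""
    if not 0.0 <= W <= 1.0:
        raise ValueError("W must be in [0, 1]")
    if mode == "weighted_sum":
        return W * Ss_norm + (1.0 - W) * Sc_norm
    if mode == "literal_product":
        return W * Ss_norm * (1.0 - W) * Sc_norm
    raise ValueError(f"unknown mode {mode!r}")


def delta_score(scores: list[float]) -> float | None:
    """D = (S_max - S_2nd) / S_max over a descending candidate score list.

    A single candidate yields D = 1 (S_2nd treated as 0); nonpositive S_max
    yields None (undefined).
    """
    if not scores:
        raise ValueError("need at least one candidate")
    s = sorted(scores, reverse=True)
    s_max = s[0]
    if s_max <= 0:
        return None
    s_2nd = s[1] if len(s) > 1 else 0.0
    return (s_max - s_2nd) / s_max


def score_candidates(
    spectrum_id: str,
    candidates: list[tuple[PeptideRecord, float, float, bool, list[SequenceTag]]],
    W: float = DEFAULT_W_DENOVO,
    mode: str = "weighted_sum",
) -> list[PSM]:
    """Normalize per-spectrum, combine, rank, and attach delta scores.

    ``candidates`` rows are (peptide, Ss, Sc_log, is_decoy, tags). Ties in S
    are broken by Sc_log, then lexicographic peptide sequence. S_2nd for
    the delta score is taken over distinct peptide sequences.
    """
    if not candidates:
        return []
    ss_norm = minmax_normalize([c[1] for c in candidates])
    sc_norm = minmax_normalize([c[2] for c in candidates])
    psms = []
    for (pep, ss, sc, dec, tags), sn, cn in zip(candidates, ss_norm, sc_norm):
        psms.append(
            PSM(
                spectrum_id=spectrum_id,
                peptide=pep,
                Ss=ss,
                Sc_log=sc,
                S=final_score(sn, cn, W, mode),
                is_decoy=dec,
                tags_used=tags,
            )
        )
    psms.sort(key=lambda p: (-p.S, -p.Sc_log, p.peptide.sequence))
    for r, p in enumerate(psms, 1):
        p.rank = r
    distinct: dict[str, float] = {}
    for p in psms:
        if p.peptide.sequence not in distinct:
            distinct[p.peptide.sequence] = p.S
    d = delta_score(list(distinct.values()))
    for p in psms:
        p.D = d if p.rank == 1 else None
    return psms


def rank_and_report(psms: list[PSM]) -> list[dict]:
    """Flatten ranked PSMs into table rows (see io_formats.PSM_COLUMNS)."""
    rows = []
    for p in psms:
        rows.append(
            {
                "spectrum_id": p.spectrum_id,
                "peptide": p.peptide.sequence,
                "protein": p.peptide.parent_accession,
                "Ss": f"{p.Ss:.4f}",
                "Sc_log": f"{p.Sc_log:.4f}",
                "S": f"{p.S:.6f}",
                "D": "" if p.D is None else f"{p.D:.6f}",
                "rank": p.rank,
                "is_decoy": int(p.is_decoy),
                "tags": ";".join(t.residues for t in p.tags_used),
            }
        )
    return rows


def protein_rollup(psms: list[PSM]) -> dict[str, float]:
    """Best peptide S per protein accession (rank-1 PSMs only)."""
    out: dict[str, float] = {}
    for p in psms:
        if p.rank != 1:
            continue
        acc = p.peptide.parent_accession
        if acc not in out or p.S > out[acc]:
            out[acc] = p.S
    return out


def estimate_fdr(rank1_psms: list[PSM], threshold: float) -> float | None:
    """Target-decoy FDR at a score threshold: #decoys / #targets above it."""
    decoys = sum(1 for p in rank1_psms if p.S >= threshold and p.is_decoy)
    targets = sum(1 for p in rank1_psms if p.S >= threshold and not p.is_decoy)
    if targets == 0:
        return None
    return decoys / targets


def q_values(rank1_psms: list[PSM]) -> list[float]:
    """Monotone q-values for rank-1 PSMs sorted by S descending."""
    psms = sorted(rank1_psms, key=lambda p: -p.S)
    fdrs: list[float] = []
    decoys = targets = 0
    for p in psms:
        if p.is_decoy:
            decoys += 1
        else:
            targets += 1
        fdrs.append(decoys / targets if targets else math.inf)
    # cumulative minimum from the low-score end
    q = fdrs[:]
    for i in range(len(q) - 2, -1, -1):
        q[i] = min(q[i], q[i + 1])
    return q


def reverse_decoys(proteins: list) -> list:
    """Reversed-sequence decoy copies of protein records."""
    from .io_formats import ProteinRecord

    return [
        ProteinRecord(
            accession=DECOY_PREFIX + p.accession,
            description="reversed decoy",
            sequence=p.sequence[::-1],
        )
        for p in proteins
    ]


def _equivalent(a: str, b: str, tolerance: float) -> bool:
    if a == b:
        return True
    pair = {a, b}
    if pair == {"I", "L"}:
        return True
    if pair == {"Q", "K"} and tolerance >= QK_MASS_GAP:
        return True
    return False


def sequence_accuracy(
    inferred: str,
    truth: str,
    tolerance: float = 0.5,
    inferred_offset: float = 0.0,
    inferred_suffix_offset: float = 0.0,
) -> float:
    """Fraction of inferred residues that are correct.

    A residue is correct when its letter matches a residue of the true
    peptide (under I/L and, tolerance permitting, Q/K equivalence) at the
    position implied by its mass: either its N-terminal prefix mass or its
    C-terminal suffix mass must agree with the true boundary within the
    fragment tolerance, so residues downstream of a mass-shifting error are
    still creditable from the other terminus.
    """
    if not inferred or not truth:
        raise ValueError("sequences must be non-empty")
    inf_pref = [inferred_offset]
    for a in inferred:
        inf_pref.append(inf_pref[-1] + RESIDUE_MASS.get(a, 0.0))
    tru_pref = [0.0]
    for a in truth:
        tru_pref.append(tru_pref[-1] + RESIDUE_MASS[a])
    inf_total = inf_pref[-1] + inferred_suffix_offset
    tru_total = tru_pref[-1]

    correct = 0
    for i, a in enumerate(inferred):
        ok = False
        for j, b in enumerate(truth):
            if not _equivalent(a, b, tolerance):
                continue
            n_anchor = abs(tru_pref[j] - inf_pref[i]) <= tolerance
            c_anchor = (
                abs((tru_total - tru_pref[j + 1]) - (inf_total - inf_pref[i + 1]))
                <= tolerance
            )
            if n_anchor or c_anchor:
                ok = True
                break
        if ok:
            correct += 1
    return correct / len(inferred)
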