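"""Sequence tag inference from a scored spectrum graph.

Top-k sub-optimal antisymmetric source-to-sink paths are enumerated with a
best-first search guided by an exact completion bound; their residue
strings are progressively aligned; and maximal unanimous alignment runs
are extracted as sequence tags with flanking mass gaps.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass

from .chem import RESIDUE_MASS
from .spectrum_graph import SpectrumGraph

GAP = "-"

DEFAULT_K = 20
DEFAULT_TAG_MIN_LEN = 3
DEFAULT_TAG_MAX_LEN = 7
DEFAULT_MIN_SUPPORT_FRACTION = 0.5

MATCH_SCORE = 1.0
MISMATCH_SCORE = -1.0
GAP_PENALTY = -2.0


@dataclass
class CandidatePath:
    """One antisymmetric source-to-sink path with its residue spelling."""

    vertex_ids: list[int]
    residues: str
    score: float
    prefix_masses: list[float]  # per vertex, ascending; len == len(residues) + 1
    vertex_scores: list[float]
    precursor_neutral_mass: float


@dataclass
class SequenceTag:
    residues: str
    prefix_gap: float
    suffix_gap: float
    support: int
    score: float

    def implied_neutral_mass(self) -> float:
        return self.prefix_gap + sum(RESIDUE_MASS[a] for a in self.residues) + self.suffix_gap


def top_k_paths(
    graph: SpectrumGraph, k: int = DEFAULT_K, max_expansions: int = 200_000
) -> list[CandidatePath]:
    """The k highest-scoring antisymmetric source->sink paths, descending.

    Antisymmetry: no two vertices on a path may be backed by the same peak
    (a peak's b- and y-interpretations are mutually exclusive). Best-first
    search over partial edge-paths with an admissible bound given by the
    unconstrained max completion score; ties broken by residue string.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(graph.vertices)
    # exact max completion score ignoring the antisymmetry constraint;
    # vertices are in ascending prefix-mass order, so reverse order is
    # a reverse-topological order.
    NEG = float("-inf")
    h = [NEG] * n
    h[graph.sink] = 0.0
    for v in range(n - 1, -1, -1):
        for e in graph.successors(v):
            u = e.to_vertex
            if h[u] > NEG:
                cand = graph.vertices[u].score + h[u]
                if cand > h[v]:
                    h[v] = cand
    if h[graph.source] == NEG:
        return []

    counter = itertools.count()
    src = graph.source
    g0 = graph.vertices[src].score
    # heap entries: (-f, residues, tiebreak, vertex_path, g, used_peaks)
    heap = [(-(g0 + h[src]), "", next(counter), [src], g0, graph.vertices[src].origin_peaks)]
    out: list[CandidatePath] = []
    pops = 0
    # collect past k through score ties so the final lexicographic ordering
    # is exact even when completion bounds differ from path sums in the
    # last float bits
    while heap and pops < max_expansions:
        if len(out) >= k:
            kth = sorted((p.score for p in out), reverse=True)[k - 1]
            if -heap[0][0] < kth - 1e-9 or len(out) >= 4 * k:
                break
        neg_f, residues, _, vpath, g, used = heapq.heappop(heap)
        pops += 1
        last = vpath[-1]
        if last == graph.sink:
            out.append(_make_path(graph, vpath, residues, g))
            continue
        for e in graph.successors(last):
            v = graph.vertices[e.to_vertex]
            if h[e.to_vertex] == NEG:
                continue
            if used & v.origin_peaks:
                continue  # would reuse a peak under its other interpretation
            g2 = g + v.score
            heapq.heappush(
                heap,
                (
                    -(g2 + h[e.to_vertex]),
                    residues + e.residue,
                    next(counter),
                    vpath + [e.to_vertex],
                    g2,
                    used | v.origin_peaks,
                ),
            )
    out.sort(key=lambda p: (-p.score, p.residues))
    return out[:k]


def _make_path(graph: SpectrumGraph, vpath: list[int], residues: str, score: float) -> CandidatePath:
    return CandidatePath(
        vertex_ids=list(vpath),
        residues=residues,
        score=score,
        prefix_masses=[graph.vertices[v].prefix_mass for v in vpath],
        vertex_scores=[graph.vertices[v].score for v in vpath],
        precursor_neutral_mass=graph.precursor_neutral_mass,
    )


def _pairwise_profile_align(profile: list[str], seq: str) -> tuple[list[str], str]:
    """Needleman-Wunsch of a sequence against an alignment profile.

    Column-vs-residue score is the mean of match/mismatch scores against
    the column's non-gap residues; existing gaps contribute 0. Gaps opened
    in the profile are propagated to every existing row.
    """
    ncol = len(profile[0])
    nseq = len(seq)

    def col_score(c: int, ch: str) -> float:
        total, cnt = 0.0, 0
        for row in profile:
            r = row[c]
            if r != GAP:
                total += MATCH_SCORE if r == ch else MISMATCH_SCORE
                cnt += 1
        return total / cnt if cnt else 0.0

    # DP over (columns+1) x (seq+1)
    dp = [[0.0] * (nseq + 1) for _ in range(ncol + 1)]
    back = [[0] * (nseq + 1) for _ in range(ncol + 1)]  # 0 diag, 1 up (col/gap-in-seq), 2 left
    for i in range(1, ncol + 1):
        dp[i][0] = dp[i - 1][0] + GAP_PENALTY
        back[i][0] = 1
    for j in range(1, nseq + 1):
        dp[0][j] = dp[0][j - 1] + GAP_PENALTY
        back[0][j] = 2
    for i in range(1, ncol + 1):
        for j in range(1, nseq + 1):
            diag = dp[i - 1][j - 1] + col_score(i - 1, seq[j - 1])
            up = dp[i - 1][j] + GAP_PENALTY
            left = dp[i][j - 1] + GAP_PENALTY
            best = max(diag, up, left)
            dp[i][j] = best
            back[i][j] = 0 if best == diag else (1 if best == up else 2)

    new_profile = [""] * len(profile)
    new_seq = ""
    i, j = ncol, nseq
    while i > 0 or j > 0:
        move = back[i][j]
        if i > 0 and j > 0 and move == 0:
            for r in range(len(profile)):
                new_profile[r] = profile[r][i - 1] + new_profile[r]
            new_seq = seq[j - 1] + new_seq
            i, j = i - 1, j - 1
        elif i > 0 and (move == 1 or j == 0):
            for r in range(len(profile)):
                new_profile[r] = profile[r][i - 1] + new_profile[r]
            new_seq = GAP + new_seq
            i -= 1
        else:
            for r in range(len(profile)):
                new_profile[r] = GAP + new_profile[r]
            new_seq = seq[j - 1] + new_seq
            j -= 1
    return new_profile, new_seq


def align_candidates(paths: list[CandidatePath]) -> list[str]:
    """Progressive multiple alignment of path residue strings.

    Rows are returned in input order, which should be descending path score
    (the guide order). Columns preserve the residue order of every input.
    """
    if not paths:
        raise ValueError("need at least one path")
    rows = [paths[0].residues]
    for p in paths[1:]:
        rows, aligned = _pairwise_profile_align(rows, p.residues)
        rows.append(aligned)
    return rows


def extract_tags(
    msa: list[str],
    paths: list[CandidatePath],
    min_len: int = DEFAULT_TAG_MIN_LEN,
    max_len: int = DEFAULT_TAG_MAX_LEN,
    min_support_fraction: float = DEFAULT_MIN_SUPPORT_FRACTION,
) -> list[SequenceTag]:
    """Extract maximal high-consensus gap-free runs of the alignment as tags.

    The consensus residue of a column is the residue carried there by the
    best-scoring path that is not gapped; the column qualifies when at
    least ``min_support_fraction`` of all rows agree with it. Runs longer
    than ``max_len`` are clipped to the best-scoring window; runs shorter
    than ``min_len`` are discarded. Flanking gaps come from the supporting
    path's vertex masses, so every tag is a substring of a candidate path.
    """
    if not (1 <= min_len <= max_len):
        raise ValueError("need 1 <= min_len <= max_len")
    nrows = len(msa)
    ncols = len(msa[0]) if msa else 0
    min_support = max(1, math.ceil(min_support_fraction * nrows))

    # residue index within each path for every non-gap cell
    residue_idx: list[list[int | None]] = []
    for r in range(nrows):
        k = 0
        idxs: list[int | None] = []
        for c in range(ncols):
            if msa[r][c] == GAP:
                idxs.append(None)
            else:
                idxs.append(k)
                k += 1
        residue_idx.append(idxs)

    consensus: list[str] = []
    support_count: list[int] = []
    for c in range(ncols):
        ch = next((msa[r][c] for r in range(nrows) if msa[r][c] != GAP), GAP)
        consensus.append(ch)
        support_count.append(sum(1 for r in range(nrows) if msa[r][c] == ch))

    def column_ok(c: int) -> bool:
        return consensus[c] != GAP and support_count[c] >= min_support

    tags: list[SequenceTag] = []
    c = 0
    while c < ncols:
        if not column_ok(c):
            c += 1
            continue
        start = c
        while c < ncols and column_ok(c):
            c += 1
        run = list(range(start, c))
        tag = _run_to_tag(run, msa, paths, residue_idx, consensus, support_count, max_len)
        if tag is not None and len(tag.residues) >= min_len:
            tags.append(tag)
    tags.sort(key=lambda t: (-t.score, t.residues))
    return tags


def _run_to_tag(
    run: list[int],
    msa: list[str],
    paths: list[CandidatePath],
    residue_idx: list[list[int | None]],
    consensus: list[str],
    support_count: list[int],
    max_len: int,
) -> SequenceTag | None:
    nrows = len(msa)
    # representative: the best-scoring row matching the consensus over the
    # longest contiguous stretch of the run (usually the whole run)
    rep, rep_cols = None, []
    for r in range(nrows):
        best_stretch: list[int] = []
        cur: list[int] = []
        for c in run:
            if msa[r][c] == consensus[c]:
                cur.append(c)
                if len(cur) > len(best_stretch):
                    best_stretch = list(cur)
            else:
                cur = []
        if len(best_stretch) > len(rep_cols):
            rep, rep_cols = r, best_stretch
        if len(rep_cols) == len(run):
            break
    if rep is None or not rep_cols:
        return None
    path = paths[rep]
    support = min(support_count[c] for c in rep_cols)
    idxs = [residue_idx[rep][c] for c in rep_cols]  # consecutive residue indices

    # per-column score: mean of the flanking vertex scores of that residue
    col_scores = [
        (path.vertex_scores[i] + path.vertex_scores[i + 1]) / 2 for i in idxs
    ]
    if len(idxs) > max_len:
        best_off, best_sum = 0, float("-inf")
        for off in range(len(idxs) - max_len + 1):
            s = sum(col_scores[off : off + max_len])
            if s > best_sum:
                best_off, best_sum = off, s
        idxs = idxs[best_off : best_off + max_len]

    i0, i1 = idxs[0], idxs[-1]
    residues = path.residues[i0 : i1 + 1]
    prefix_gap = path.prefix_masses[i0]
    suffix_gap = path.precursor_neutral_mass - path.prefix_masses[i1 + 1]
    span_scores = path.vertex_scores[i0 : i1 + 2]
    return SequenceTag(
        residues=residues,
        prefix_gap=prefix_gap,
        suffix_gap=suffix_gap,
        support=support,
        score=sum(span_scores) / len(span_scores),
    )


#: Residues a tryptic peptide may end with; Q stands in for K whenever the
#: fragment tolerance collapses the Q/K mass gap at graph level.
TRYPTIC_ENDS = frozenset("KRQ")


def infer_tags(
    graph: SpectrumGraph,
    k: int = DEFAULT_K,
    min_len: int = DEFAULT_TAG_MIN_LEN,
    max_len: int = DEFAULT_TAG_MAX_LEN,
    min_support_fraction: float = DEFAULT_MIN_SUPPORT_FRACTION,
    prefer_tryptic_paths: bool = True,
) -> list[SequenceTag]:
    """Full tag-inference step: k-best paths -> alignment -> tags.

    With ``prefer_tryptic_paths``, candidate paths ending in a tryptic
    residue are preferred when any exist; this suppresses the mirrored
    (b/y-swapped) readings of a spectrum, which never end in K/R.
    """
    paths = top_k_paths(graph, k)
    if prefer_tryptic_paths:
        tryptic = [p for p in paths if p.residues and p.residues[-1] in TRYPTIC_ENDS]
        if tryptic:
            paths = tryptic
    if not paths:
        return []
    msa = align_candidates(paths)
    return extract_tags(msa, paths, min_len, max_len, min_support_fraction)
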