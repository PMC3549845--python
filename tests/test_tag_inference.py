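import math

import numpy as np
import pytest

from tagident import synthetic
from tagident.chem import RESIDUE_MASS
from tagident.preprocess import preprocess
from tagident.spectrum_graph import Edge, SpectrumGraph, Vertex, build_graph
from tagident.tag_inference import (
    CandidatePath,
    align_candidates,
    extract_tags,
    infer_tags,
    top_k_paths,
)
from tagident import bayes_model


def make_graph(masses, scores, edges, conflicts=None, precursor_neutral=None):
    """Hand-build a SpectrumGraph: masses ascending, edges (i, j, residue)."""
    conflicts = conflicts or {}
    vertices = []
    for i, (m, s) in enumerate(zip(masses, scores)):
        interp = "source" if i == 0 else ("sink" if i == len(masses) - 1 else "b")
        vertices.append(Vertex(m, frozenset(conflicts.get(i, [])), interp, s))
    g = SpectrumGraph(
        vertices=vertices,
        edges=[Edge(a, b, r) for a, b, r in edges],
        fragment_tolerance=0.5,
        precursor_neutral_mass=precursor_neutral if precursor_neutral is not None else masses[-1] + 18.010565,
        source=0,
        sink=len(masses) - 1,
    )
    g.finalize()
    return g


def enumerate_paths_oracle(graph, k):
    """Exhaustive enumeration of all antisymmetric edge-paths (oracle)."""
    results = []

    def walk(v, residues, score, used):
        if v == graph.sink:
            results.append((score, residues))
            return
        for e in graph.successors(v):
            vert = graph.vertices[e.to_vertex]
            if used & vert.origin_peaks:
                continue
            walk(
                e.to_vertex,
                residues + e.residue,
                score + vert.score,
                used | vert.origin_peaks,
            )

    walk(graph.source, "", graph.vertices[graph.source].score, graph.vertices[graph.source].origin_peaks)
    results.sort(key=lambda t: (-t[0], t[1]))
    return results[:k]


def random_graph(rng):
    n = int(rng.integers(3, 11))
    masses = np.sort(rng.uniform(0, 1000, n))
    masses[0] = 0.0
    scores = rng.normal(0, 2, n)
    scores[0] = scores[-1] = 0.0
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.45:
                for _ in range(1 + (rng.random() < 0.1)):
                    edges.append((i, j, "ACDEFGHLMNPQRSTVWY"[int(rng.integers(18))]))
    conflicts = {}
    for i in range(1, n - 1):
        if rng.random() < 0.5:
            conflicts[i] = [int(rng.integers(4))]
    return make_graph(list(masses), list(scores), edges, conflicts)


class TestTopKPaths:
    def test_linear_chain_single_path(self):
        g = make_graph([0, 100, 200], [0, 1, 0], [(0, 1, "A"), (1, 2, "G")])
        for k in (1, 5, 50):
            paths = top_k_paths(g, k)
            assert len(paths) == 1
            assert paths[0].residues == "AG"

    def test_k1_is_optimal(self):
        g = make_graph(
            [0, 100, 150, 300],
            [0, 5.0, 1.0, 0],
            [(0, 1, "A"), (0, 2, "B"), (1, 3, "C"), (2, 3, "D")],
        )
        (best,) = top_k_paths(g, 1)
        assert best.residues == "AC"
        assert math.isclose(best.score, 5.0)

    def test_no_path_returns_empty(self):
        g = make_graph([0, 100, 200], [0, 1, 0], [(0, 1, "A")])
        assert top_k_paths(g, 3) == []

    def test_antisymmetry_respected(self):
        # vertices 1 and 2 derive from the same peak: no path may use both
        g = make_graph(
            [0, 100, 200, 300],
            [0, 1.0, 1.0, 0],
            [(0, 1, "A"), (1, 2, "B"), (2, 3, "C"), (0, 2, "D"), (1, 3, "E")],
            conflicts={1: [7], 2: [7]},
        )
        paths = top_k_paths(g, 10)
        strings = {p.residues for p in paths}
        assert "ABC" not in strings
        assert strings == {"AE", "DC"}

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            g = random_graph(rng)
            for k in (1, 3, 10):
                got = [(round(p.score, 9), p.residues) for p in top_k_paths(g, k)]
                want = [(round(s, 9), r) for s, r in enumerate_paths_oracle(g, k)]
                assert got == want


def pairwise_nw_oracle(a, b, match=1.0, mismatch=-1.0, gap=-2.0):
    """Independent global-alignment DP returning the optimal score."""
    la, lb = len(a), len(b)
    dp = np.zeros((la + 1, lb + 1))
    dp[:, 0] = np.arange(la + 1) * gap
    dp[0, :] = np.arange(lb + 1) * gap
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            sub = match if a[i - 1] == b[j - 1] else mismatch
            dp[i, j] = max(dp[i - 1, j - 1] + sub, dp[i - 1, j] + gap, dp[i, j - 1] + gap)
    return dp[la, lb]


def path_of(residues, score=1.0):
    masses = [0.0]
    for aa in residues:
        masses.append(masses[-1] + RESIDUE_MASS[aa])
    return CandidatePath(
        vertex_ids=list(range(len(residues) + 1)),
        residues=residues,
        score=score,
        prefix_masses=masses,
        vertex_scores=[1.0] * (len(residues) + 1),
        precursor_neutral_mass=masses[-1] + 18.010565,
    )


class TestAlignCandidates:
    def test_identical_sequences_no_gaps(self):
        msa = align_candidates([path_of("PEPTIDE"), path_of("PEPTIDE", 0.5)])
        assert msa == ["PEPTIDE", "PEPTIDE"]

    def test_deletion_introduces_two_gaps(self):
        msa = align_candidates([path_of("PEPTIDE"), path_of("PEPDE", 0.5)])
        assert msa[0] == "PEPTIDE"
        assert msa[1].replace("-", "") == "PEPDE"
        assert msa[1].count("-") == 2
        # pairwise DP oracle: 5 matches (+5) and one 2-column gap (-4)
        assert pairwise_nw_oracle("PEPTIDE", "PEPDE") == 1.0

    def test_single_path_trivial(self):
        msa = align_candidates([path_of("ACDK")])
        assert msa == ["ACDK"]

    def test_columns_preserve_residue_order(self):
        msa = align_candidates([path_of("ACDEFG"), path_of("ADFG", 0.6), path_of("CDEG", 0.4)])
        for row, original in zip(msa, ["ACDEFG", "ADFG", "CDEG"]):
            assert row.replace("-", "") == original


class TestExtractTags:
    def test_full_agreement_yields_full_tag(self):
        paths = [path_of("PEPTLDE"), path_of("PEPTLDE", 0.5)]
        msa = align_candidates(paths)
        tags = extract_tags(msa, paths, min_len=3, max_len=10)
        assert len(tags) == 1
        assert tags[0].residues == "PEPTLDE"
        assert tags[0].support == 2

    def test_disagreement_splits_runs(self):
        paths = [path_of("AAAGAAA"), path_of("AAACAAA", 0.5)]
        msa = ["AAAGAAA", "AAACAAA"]
        tags = extract_tags(msa, paths, min_len=3, max_len=10, min_support_fraction=1.0)
        assert sorted(t.residues for t in tags) == ["AAA", "AAA"]

    def test_clipping_to_max_len(self):
        p = path_of("ACDEFGHLMN")
        p.vertex_scores = [0, 0, 0, 1, 5, 5, 5, 1, 0, 0, 0]
        tags = extract_tags(["ACDEFGHLMN"], [p], min_len=3, max_len=4)
        assert len(tags) == 1
        assert len(tags[0].residues) == 4
        assert tags[0].residues in "ACDEFGHLMN"
        assert "EFG" in tags[0].residues  # covers the high-scoring vertices

    def test_mass_closure(self):
        paths = [path_of("PEPTLDEK")]
        tags = extract_tags(["PEPTLDEK"], paths, min_len=3, max_len=5)
        for t in tags:
            assert math.isclose(
                t.implied_neutral_mass(), paths[0].precursor_neutral_mass, abs_tol=1.0
            )


class TestInferTagsEndToEnd:
    def test_top_tag_is_substring_of_truth(self, trained_models):
        model, noise = trained_models
        params = synthetic.noise_free_params(seed=31)
        params.n_proteins = 200
        _, annotated = synthetic.generate_benchmark(params, 200)
        hits = 0
        usable = 0
        for spectrum, pep in annotated:
            proc = preprocess(spectrum)
            g = build_graph(proc, 0.5)
            bayes_model.score_graph(g, proc, model, noise)
            tags = infer_tags(g)
            if not tags:
                continue
            usable += 1
            canonical = pep.replace("I", "L").replace("K", "Q")
            if tags[0].residues in canonical:
                hits += 1
        assert usable >= 190
        assert hits / usable >= 0.95

    def test_tags_substring_of_candidate_paths(self, trained_models, small_benchmark):
        model, noise = trained_models
        _, annotated = small_benchmark
        for spectrum, _ in annotated[:10]:
            proc = preprocess(spectrum)
            g = build_graph(proc, 0.5)
            bayes_model.score_graph(g, proc, model, noise)
            paths = top_k_paths(g, 20)
            if not paths:
                continue
            msa = align_candidates(paths)
            tags = extract_tags(msa, paths)
            for t in tags:
                assert any(t.residues in p.residues for p in paths)

    def test_tag_mass_closure_on_simulated(self, trained_models, small_benchmark):
        model, noise = trained_models
        _, annotated = small_benchmark
        for spectrum, _ in annotated[:10]:
            proc = preprocess(spectrum)
            g = build_graph(proc, 0.5)
            bayes_model.score_graph(g, proc, model, noise)
            for t in infer_tags(g):
                assert math.isclose(
                    t.implied_neutral_mass(),
                    spectrum.precursor_neutral_mass,
                    abs_tol=2 * 0.5 * (len(t.residues) + 2),
                )
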