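"""End-to-end identification pipeline and its declarative run configuration."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import bayes_model, ion_match, preprocess, scoring, spectrum_graph, tag_inference, tag_query
from .io_formats import ProteinRecord, Spectrum, digest_database
from .scoring import DECOY_PREFIX, PSM

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters in one declarative document (JSON on disk)."""

    fragment_tolerance: float = 0.5
    discretize_thresholds: tuple[float, float, float] = (1.0, 3.0, 10.0)
    window_width: float = 100.0
    window_top_n: int = 6
    n_regions: int = 5
    baseline_method: str = "median"
    degradation_edges: bool = False
    k_paths: int = 20
    tag_min_len: int = 3
    tag_max_len: int = 7
    min_support_fraction: float = 0.5
    prefer_tryptic_paths: bool = True
    max_hits: int = 50
    mass_window: float = 2.5
    gap_open: float = 11.0
    gap_extend: float = 1.0
    missed_cleavages: int = 2
    digest_min_len: int = 6
    digest_max_len: int = 30
    w_denovo: float = 0.5
    score_mode: str = "weighted_sum"
    add_decoys: bool = False
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if isinstance(cfg.discretize_thresholds, list):
            cfg.discretize_thresholds = tuple(cfg.discretize_thresholds)
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def preprocess_spectrum(spectrum: Spectrum, config: RunConfig) -> preprocess.ProcessedSpectrum:
    return preprocess.preprocess(
        spectrum,
        thresholds=config.discretize_thresholds,
        window_width=config.window_width,
        window_top_n=config.window_top_n,
        n_regions=config.n_regions,
        baseline_method=config.baseline_method,
    )


def tags_for_spectrum(
    spectrum: Spectrum,
    config: RunConfig,
    model: bayes_model.CPTModel,
    noise: bayes_model.NoiseModel,
) -> list[tag_inference.SequenceTag]:
    """Preprocess, build and score the graph, and infer tags for one spectrum."""
    proc = preprocess_spectrum(spectrum, config)
    graph = spectrum_graph.build_graph(
        proc, config.fragment_tolerance, config.degradation_edges
    )
    bayes_model.score_graph(graph, proc, model, noise)
    return tag_inference.infer_tags(
        graph,
        k=config.k_paths,
        min_len=config.tag_min_len,
        max_len=config.tag_max_len,
        min_support_fraction=config.min_support_fraction,
        prefer_tryptic_paths=config.prefer_tryptic_paths,
    )


def build_index(proteins: list[ProteinRecord], config: RunConfig) -> tag_query.PeptideIndex:
    if config.add_decoys:
        proteins = proteins + scoring.reverse_decoys(proteins)
    peptides = digest_database(
        proteins,
        missed_cleavages=config.missed_cleavages,
        min_len=config.digest_min_len,
        max_len=config.digest_max_len,
    )
    return tag_query.PeptideIndex(peptides)


def identify_spectrum(
    spectrum: Spectrum,
    index: tag_query.PeptideIndex,
    matrix: tag_query.SubstitutionMatrix,
    config: RunConfig,
    model: bayes_model.CPTModel,
    noise: bayes_model.NoiseModel,
) -> list[PSM]:
    """Run the full five-stage pipeline on one spectrum."""
    proc = preprocess_spectrum(spectrum, config)
    graph = spectrum_graph.build_graph(
        proc, config.fragment_tolerance, config.degradation_edges
    )
    bayes_model.score_graph(graph, proc, model, noise)
    tags = tag_inference.infer_tags(
        graph,
        k=config.k_paths,
        min_len=config.tag_min_len,
        max_len=config.tag_max_len,
        min_support_fraction=config.min_support_fraction,
        prefer_tryptic_paths=config.prefer_tryptic_paths,
    )
    if not tags:
        return []
    hits = tag_query.query(
        tags,
        index,
        matrix,
        max_hits=config.max_hits,
        precursor_neutral_mass=spectrum.precursor_neutral_mass,
        mass_window=config.mass_window,
    )
    candidates = []
    for hit in hits:
        seq = hit.peptide.sequence
        if "X" in seq or len(seq) < 2:
            continue
        theo = ion_match.theoretical_spectrum(seq, spectrum.precursor_charge)
        result = ion_match.match(proc, theo, config.fragment_tolerance)
        sc_log, _ = ion_match.correlation_score(result)
        is_decoy = hit.peptide.parent_accession.startswith(DECOY_PREFIX)
        candidates.append((hit.peptide, hit.Ss, sc_log, is_decoy, [hit.tag]))
    return scoring.score_candidates(
        spectrum.identifier, candidates, W=config.w_denovo, mode=config.score_mode
    )


def identify(
    spectra: list[Spectrum],
    proteins: list[ProteinRecord],
    config: RunConfig,
    model: bayes_model.CPTModel,
    noise: bayes_model.NoiseModel,
) -> tuple[list[PSM], list[dict]]:
    """Identify a batch of spectra; returns PSMs and report table rows.

    Spectra yielding no tags contribute an empty row flagged ``no_tags``.
    """
    index = build_index(proteins, config)
    matrix = tag_query.build_matrix(config.gap_open, config.gap_extend)
    all_psms: list[PSM] = []
    rows: list[dict] = []
    for spectrum in spectra:
        psms = identify_spectrum(spectrum, index, matrix, config, model, noise)
        if not psms:
            rows.append({"spectrum_id": spectrum.identifier, "rank": 0, "tags": "no_tags"})
            continue
        all_psms.extend(psms)
        rows.extend(scoring.rank_and_report(psms))
        logger.info(
            "%s: %d candidates, top=%s",
            spectrum.identifier,
            len(psms),
            psms[0].peptide.sequence,
        )
    return all_psms, rows
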