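"""Spectrum graph construction.

Every kept peak contributes two vertices — its b-ion and its y-ion
interpretation — both expressed as a neutral prefix residue mass measured
from the N-terminus. Edges connect vertex pairs whose prefix-mass
difference matches one residue mass within the fragment tolerance, so any
source-to-sink path spells a candidate peptide sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chem import AMMONIA, PROTON, QK_MASS_GAP, RESIDUE_MASS, WATER
from .preprocess import ProcessedSpectrum

SOURCE = "source"
SINK = "sink"


@dataclass
class Vertex:
    prefix_mass: float
    origin_peaks: frozenset[int]  # peak indices backing this mass (empty for terminals)
    interpretation: str  # b | y | merged | source | sink
    score: float = 0.0


@dataclass(frozen=True)
class Edge:
    from_vertex: int
    to_vertex: int
    residue: str
    offset_type: str = "plain"  # plain | water_loss | ammonia_loss


@dataclass
class SpectrumGraph:
    vertices: list[Vertex]
    edges: list[Edge]
    fragment_tolerance: float
    precursor_neutral_mass: float
    source: int
    sink: int

    @property
    def total_residue_mass(self) -> float:
        return self.precursor_neutral_mass - WATER

    def successors(self, v: int) -> list[Edge]:
        return self._adj.get(v, [])

    def finalize(self) -> None:
        adj: dict[int, list[Edge]] = {}
        for e in self.edges:
            adj.setdefault(e.from_vertex, []).append(e)
        self._adj = adj

    def is_dag(self) -> bool:
        """Edges must strictly increase prefix mass, hence acyclicity."""
        return all(
            self.vertices[e.to_vertex].prefix_mass > self.vertices[e.from_vertex].prefix_mass
            for e in self.edges
        )

    def to_dot(self) -> str:
        """DOT export of small graphs for debugging."""
        lines = ["digraph spectrum {"]
        for i, v in enumerate(self.vertices):
            lines.append(
                f'  v{i} [label="{v.interpretation}\\n{v.prefix_mass:.2f}\\n{v.score:.2f}"];'
            )
        for e in self.edges:
            lines.append(f'  v{e.from_vertex} -> v{e.to_vertex} [label="{e.residue}"];')
        lines.append("}")
        return "\n".join(lines)


def edge_labels(tolerance: float) -> list[tuple[str, float]]:
    """Residue labels usable as edge labels at the given tolerance.

    I/L are collapsed to L (identical mass); Q/K are collapsed to Q unless
    the tolerance resolves their 0.036 Da gap.
    """
    labels: list[tuple[str, float]] = []
    for aa, m in RESIDUE_MASS.items():
        if aa == "I":
            continue
        if aa == "K" and tolerance >= QK_MASS_GAP:
            continue
        labels.append((aa, m))
    return labels


def build_graph(
    proc: ProcessedSpectrum,
    tolerance: float = 0.5,
    degradation_edges: bool = False,
) -> SpectrumGraph:
    """Build the spectrum graph from the kept peaks of a processed spectrum.

    Vertices closer than the tolerance in prefix mass are merged (their
    origin-peak sets are unioned). Optionally, edges for residue-mass
    offsets minus water/ammonia are added for degraded-ion ladders.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    M = proc.precursor_neutral_mass
    total_residue = M - WATER

    raw: list[tuple[float, int, str]] = []  # (prefix_mass, peak index, interpretation)
    for i in proc.kept_indices():
        mz = proc.spectrum.peaks[int(i)].mz
        b_prefix = mz - PROTON
        y_prefix = total_residue - (mz - PROTON - WATER)
        for prefix, interp in ((b_prefix, "b"), (y_prefix, "y")):
            if -tolerance < prefix < total_residue + tolerance:
                raw.append((prefix, int(i), interp))

    raw.sort()
    vertices: list[Vertex] = [Vertex(0.0, frozenset(), SOURCE)]
    # merge near-duplicate masses into one vertex backed by all origin peaks
    cluster: list[tuple[float, int, str]] = []

    def flush() -> None:
        if not cluster:
            return
        mass = sum(c[0] for c in cluster) / len(cluster)
        peaks = frozenset(c[1] for c in cluster)
        interps = {c[2] for c in cluster}
        interp = interps.pop() if len(interps) == 1 else "merged"
        if mass > tolerance / 2 and mass < total_residue - tolerance / 2:
            vertices.append(Vertex(mass, peaks, interp))
        cluster.clear()

    for item in raw:
        if cluster and item[0] - cluster[-1][0] > tolerance:
            flush()
        cluster.append(item)
    flush()

    sink = Vertex(total_residue, frozenset(), SINK)
    vertices.append(sink)
    source_idx, sink_idx = 0, len(vertices) - 1

    offsets: list[tuple[float, str]] = [(0.0, "plain")]
    if degradation_edges:
        offsets += [(-WATER, "water_loss"), (-AMMONIA, "ammonia_loss")]

    labels = edge_labels(tolerance)
    edges: list[Edge] = []
    for i, u in enumerate(vertices):
        for j in range(i + 1, len(vertices)):
            v = vertices[j]
            delta = v.prefix_mass - u.prefix_mass
            if delta <= 0:
                continue
            if delta > max(m for _, m in labels) + tolerance:
                break
            for off, off_type in offsets:
                for aa, m in labels:
                    if abs(delta - (m + off)) <= tolerance:
                        edges.append(Edge(i, j, aa, off_type))

    g = SpectrumGraph(
        vertices=vertices,
        edges=edges,
        fragment_tolerance=tolerance,
        precursor_neutral_mass=M,
        source=source_idx,
        sink=sink_idx,
    )
    g.finalize()
    return g
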