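"""Feature-based molecular networking: modified cosine and graph building.

Spectra become nodes; an edge links two spectra whose fragmentation is
similar under the *modified cosine*: peaks may pair either directly
(|dm/z| <= tol) or offset by the precursor mass difference, which lets
structural analogs differing by one modification align their shifted
fragment series. Intensities are square-root scaled (standard practice
for dot-product spectral similarity), pairing is greedy one-to-one by
descending intensity product, and

    cosine = sum(paired products) / (||s1|| * ||s2||).

Edges require a minimum cosine and matched-peak count; oversized
connected components are pruned back by deleting their weakest edges.
Precursor pairs further apart than the analog cap are never linked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .spectra import Spectrum

__all__ = [
    "NetworkEdge",
    "SpectralNetwork",
    "modified_cosine",
    "build_network",
    "export_graphml",
]

DEFAULT_COSINE_MIN = 0.7
DEFAULT_MIN_MATCHED = 3
DEFAULT_FRAG_TOL = 0.02
DEFAULT_MAX_COMPONENT = 100
DEFAULT_ANALOG_MAX_DELTA = 300.0


@dataclass(frozen=True)
class NetworkEdge:
    node_a: str
    node_b: str
    cosine: float
    matched_peaks: int
    precursor_delta: float


@dataclass
class SpectralNetwork:
    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[NetworkEdge]:
        return [
            NetworkEdge(a, b, d["cosine"], d["matched_peaks"], d["delta"])
            for a, b, d in self.graph.edges(data=True)
        ]

    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]


def modified_cosine(
    s1: Spectrum,
    s2: Spectrum,
    frag_tol: float = DEFAULT_FRAG_TOL,
    allow_shift: bool = True,
) -> tuple[float, int]:
    """Modified cosine similarity and matched-peak count.

    Peaks pair if |dm/z| <= frag_tol or, when ``allow_shift``,
    |dm/z - (prec1 - prec2)| <= frag_tol. One-to-one pairing is greedy
    by descending square-root intensity product, ties toward the
    smaller |dm/z| deviation, then the lower peak indices.
    """
    if len(s1) == 0 or len(s2) == 0:
        raise ValueError("cannot score an empty spectrum")
    w1 = np.sqrt(s1.intensity)
    w2 = np.sqrt(s2.intensity)
    norm = float(np.linalg.norm(w1) * np.linalg.norm(w2))
    if norm == 0.0:
        return 0.0, 0

    shift = s1.precursor_mz - s2.precursor_mz
    offsets = [0.0] + ([shift] if allow_shift and abs(shift) > 1e-12 else [])
    candidates: list[tuple[float, float, int, int]] = []
    for off in offsets:
        # peak i of s1 pairs with peak j of s2 when mz1[i] - mz2[j] ~ off
        for i, mz1 in enumerate(s1.mz):
            lo = np.searchsorted(s2.mz, mz1 - off - frag_tol, side="left")
            hi = np.searchsorted(s2.mz, mz1 - off + frag_tol, side="right")
            for j in range(int(lo), int(hi)):
                prod = float(w1[i] * w2[j])
                if prod > 0.0:
                    dev = abs(mz1 - s2.mz[j] - off)
                    candidates.append((-prod, dev, i, j))
    candidates.sort()

    used1: set[int] = set()
    used2: set[int] = set()
    total = 0.0
    matched = 0
    for negprod, _dev, i, j in candidates:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        total += -negprod
        matched += 1
    return min(total / norm, 1.0), matched


def build_network(
    spectra: Sequence[Spectrum],
    cosine_min: float = DEFAULT_COSINE_MIN,
    min_matched: int = DEFAULT_MIN_MATCHED,
    frag_tol: float = DEFAULT_FRAG_TOL,
    max_component: int = DEFAULT_MAX_COMPONENT,
    analog_max_delta: float = DEFAULT_ANALOG_MAX_DELTA,
) -> SpectralNetwork:
    """All-pairs modified-cosine network with topology filtering.

    Pairs whose precursor difference exceeds ``analog_max_delta`` are not
    linked; within the cap the shifted pairing is allowed. Edges must
    reach ``cosine_min`` with at least ``min_matched`` matched peaks.
    Components larger than ``max_component`` are reduced by repeatedly
    deleting the lowest-cosine edge in the oversized component (ties:
    larger precursor delta, then lexicographically smaller node pair);
    nodes are never deleted.
    """
    g = nx.Graph()
    for s in spectra:
        g.add_node(
            s.id,
            precursor_mz=float(s.precursor_mz),
            charge=int(s.precursor_charge),
            intensity=float(s.intensity.sum()) if len(s) else 0.0,
        )
    for i in range(len(spectra)):
        for j in range(i + 1, len(spectra)):
            s1, s2 = spectra[i], spectra[j]
            delta = abs(s1.precursor_mz - s2.precursor_mz)
            if delta > analog_max_delta:
                continue
            if len(s1) == 0 or len(s2) == 0:
                continue
            cos, matched = modified_cosine(s1, s2, frag_tol=frag_tol,
                                           allow_shift=True)
            if cos >= cosine_min and matched >= min_matched:
                g.add_edge(s1.id, s2.id, cosine=float(cos),
                           matched_peaks=int(matched), delta=float(delta))

    _prune_components(g, max_component)
    return SpectralNetwork(g)


def _prune_components(g: nx.Graph, max_component: int) -> None:
    while True:
        oversized = [c for c in nx.connected_components(g)
                     if len(c) > max_component]
        if not oversized:
            return
        comp = oversized[0]
        edges = []
        for a, b, d in g.subgraph(comp).edges(data=True):
            pair = tuple(sorted((a, b)))
            edges.append((d["cosine"], -d["delta"], pair))
        # weakest first: lowest cosine, then larger delta, then smaller pair
        edges.sort(key=lambda e: (e[0], e[1], e[2]))
        _, _, (a, b) = edges[0]
        g.remove_edge(a, b)


def export_graphml(net: SpectralNetwork, path) -> None:
    """GraphML export (node: precursor m/z, charge, intensity; edge:
    cosine, matched_peaks, delta); re-importable with networkx."""
    nx.write_graphml(net.graph, str(path))


def read_graphml(path) -> SpectralNetwork:
    return SpectralNetwork(nx.read_graphml(str(path)))


def edges_table(net: SpectralNetwork) -> str:
    lines = ["node_a\tnode_b\tcosine\tmatched_peaks\tprecursor_delta"]
    for e in sorted(net.edges, key=lambda e: (e.node_a, e.node_b)):
        lines.append(
            f"{e.node_a}\t{e.node_b}\t{e.cosine:.4f}\t{e.matched_peaks}\t"
            f"{e.precursor_delta:.4f}"
        )
    return "\n".join(lines) + "\n"
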