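"""Compartment importance scores and interaction confidence weights.

Subcellular compartments differ in how strongly interactions concentrate in
them, and a compartment's importance tracks how many interacting proteins it
hosts. Each compartment I is scored

    SC(I) = C_X(I) / C_M

where C_X(I) is the number of interacted proteins (network degree >= 1)
annotated to I and C_M is the count of the largest compartment, so
SC in (0, 1] with the largest compartment scoring exactly 1. An interaction
(u, v) is then weighted by the best compartment the two proteins share:

    W(u, v) = max over SC(SLoc(u, v))   if SLoc(u, v) = Loc(u) ∩ Loc(v) ≠ ∅
    W(u, v) = SC(C_N)                   otherwise

with C_N the smallest-count compartment, so missing or disjoint annotation
falls back to the global minimum score rather than zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .io import LocalizationMap

logger = logging.getLogger(__name__)


def count_interacted_proteins(
    network: nx.Graph,
    locmap: LocalizationMap,
    vocabulary: Iterable[str] | None = None,
) -> dict[str, int]:
    """Count, per compartment, the distinct proteins that both carry the
    annotation and touch at least one edge of ``network``.

    Compartments from ``vocabulary`` (default: every label appearing in
    ``locmap``) with no such protein are reported with count 0.
    """
    if vocabulary is not None:
        labels = set(vocabulary)
    else:
        labels = set().union(*locmap.values()) if locmap else set()
    counts = {label: 0 for label in labels}
    for protein, compartments in locmap.items():
        if protein in network and network.degree(protein) >= 1:
            for compartment in compartments:
                if compartment in counts:
                    counts[compartment] += 1
    return counts


@dataclass(frozen=True)
class CompartmentScoreTable:
    """Importance score per compartment, normalized to max 1.0.

    Compartments with zero interacted proteins are excluded (not scored 0),
    so every score is positive and the missing-annotation fallback weight
    ``SC(C_N)`` never erases an interaction.
    """

    scores: dict[str, float]
    largest_compartment: str
    smallest_compartment: str

    @property
    def min_score(self) -> float:
        """SC of C_N, the fallback weight for unannotated/disjoint pairs."""
        return self.scores[self.smallest_compartment]

    def __getitem__(self, compartment: str) -> float:
        return self.scores[compartment]


def score_compartments(counts: Mapping[str, int]) -> CompartmentScoreTable:
    """Build the score table SC(I) = C_X(I) / C_M from interacted-protein
    counts. Zero-count compartments are dropped; ties for largest/smallest
    break toward the lexicographically smallest label."""
    positive = {label: c for label, c in counts.items() if c > 0}
    if not positive:
        raise ValueError("no annotated interacted proteins")
    c_max = max(positive.values())
    c_min = min(positive.values())
    largest = min(label for label, c in positive.items() if c == c_max)
    smallest = min(label for label, c in positive.items() if c == c_min)
    scores = {label: c / c_max for label, c in positive.items()}
    logger.info(
        "scored %d compartments (dropped %d empty); C_M=%s (%d), C_N=%s (%d)",
        len(positive), len(counts) - len(positive), largest, c_max, smallest, c_min,
    )
    return CompartmentScoreTable(scores, largest, smallest)


def weight_edges(
    network: nx.Graph,
    locmap: LocalizationMap,
    table: CompartmentScoreTable,
) -> nx.Graph:
    """Return a copy of ``network`` with a confidence ``weight`` on every edge.

    A protein absent from ``locmap`` has an empty localization set; the
    fallback branch then applies, as it does when both proteins are annotated
    but share no scored compartment.
    """
    scored = set(table.scores)
    weighted = nx.Graph()
    weighted.add_nodes_from(network.nodes())
    empty: frozenset[str] = frozenset()
    for u, v in network.edges():
        shared = (locmap.get(u, empty) & locmap.get(v, empty)) & scored
        if shared:
            weight = max(table.scores[c] for c in shared)
        else:
            weight = table.min_score
        weighted.add_edge(u, v, weight=weight)
    return weighted


def build_weighted_network(
    network: nx.Graph,
    locmap: LocalizationMap,
    vocabulary: Iterable[str] | None = None,
) -> tuple[nx.Graph, CompartmentScoreTable, dict[str, int]]:
    """Convenience: count -> score -> weight on the full input network."""
    counts = count_interacted_proteins(network, locmap, vocabulary)
    table = score_compartments(counts)
    return weight_edges(network, locmap, table), table, counts
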