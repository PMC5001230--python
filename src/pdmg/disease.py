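"""Disease-specific subnetwork construction by one-hop seed expansion.

The disease network consists of the seed proteins found in the weighted PPI
network, their direct neighbors (the candidates), and every weighted edge
with at least one seed endpoint. Candidate-candidate edges are excluded;
seed-seed edges are kept by default (each seed is a direct neighbor of the
other) but can be dropped to reproduce the stricter seed-candidate-only
reading.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .io import SeedSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiseaseNetwork:
    """One-hop weighted subnetwork around the seeds.

    ``graph`` carries the inherited edge weights; its node set is
    ``seeds | candidates`` and every edge touches at least one seed.
    """

    graph: nx.Graph
    seeds: frozenset[str]
    candidates: frozenset[str]
    n_seed_seed_edges: int

    @property
    def n_seeds_found(self) -> int:
        return len(self.seeds)

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def expand(
    weighted: nx.Graph,
    seeds: SeedSet,
    *,
    include_seed_seed_edges: bool = True,
) -> DiseaseNetwork:
    """Build the disease-specific network by nearest-neighbor expansion.

    Seeds absent from ``weighted`` are dropped with a warning; if none
    remain, a ``ValueError`` lists the missing seeds. Edge weights are
    inherited unchanged from the parent network.
    """
    present = frozenset(s for s in seeds if s in weighted)
    missing = sorted(set(seeds.proteins) - present)
    if missing:
        logger.warning("%d seeds absent from the network: %s",
                       len(missing), ", ".join(missing))
    if not present:
        raise ValueError(
            "no seed protein present in the network; missing: " + ", ".join(missing)
        )

    subgraph = nx.Graph()
    subgraph.add_nodes_from(present)
    n_seed_seed = 0
    for u, v, attrs in weighted.edges(data=True):
        u_seed, v_seed = u in present, v in present
        if not (u_seed or v_seed):
            continue
        if u_seed and v_seed:
            n_seed_seed += 1
            if not include_seed_seed_edges:
                continue
        subgraph.add_edge(u, v, weight=attrs["weight"])
    candidates = frozenset(subgraph.nodes()) - present
    logger.info(
        "disease network: %d seeds found, %d candidates, %d edges "
        "(%d seed-seed edges %s)",
        len(present), len(candidates), subgraph.number_of_edges(),
        n_seed_seed, "included" if include_seed_seed_edges else "excluded",
    )
    return DiseaseNetwork(subgraph, present, candidates, n_seed_seed)
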