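"""Candidate prioritization by weighted degree centrality.

Every protein u in the disease-specific network is scored by the sum of its
incident edge weights there,

    SPD(u) = sum over neighbors v of W(u, v),

and proteins are ranked in descending SPD. A candidate connected to a single
seed therefore scores exactly that edge's confidence weight, while hubs that
touch many seeds accumulate large scores.
"""

from __future__ import annotations

import math
from typing import Mapping

import pandas as pd

from .disease import DiseaseNetwork
from .io import SeedSet


def score_proteins(disease_net: DiseaseNetwork) -> dict[str, float]:
    """Weighted degree SPD(u) for every node of the disease network.

    Uses correctly-rounded summation (math.fsum) so the score is independent
    of neighbor iteration order.
    """
    graph = disease_net.graph
    return {
        node: math.fsum(attrs["weight"] for attrs in graph[node].values())
        for node in graph.nodes()
    }


def rank(scores: Mapping[str, float], seeds: SeedSet) -> pd.DataFrame:
    """Rank proteins by descending SPD into a table with columns
    ``rank, protein, score, seed_flag``.

    Ties break by protein symbol ascending; ranks are consecutive 1..n.
    Seeds are flagged ``Known``, other proteins ``Novel``.
    """
    if not scores:
        raise ValueError("no scores to rank")
    ordered = sorted(scores.items(), key=lambda item: (-item[1], item[0]))
    return pd.DataFrame(
        {
            "rank": range(1, len(ordered) + 1),
            "protein": [protein for protein, _ in ordered],
            "score": [score for _, score in ordered],
            "seed_flag": ["Known" if p in seeds else "Novel" for p, _ in ordered],
        }
    )


def evaluate_topk(
    ranked: pd.DataFrame, known: set[str], k: int
) -> tuple[int, float]:
    """Recovery of known disease proteins in the top k rows:
    (hits, precision) with hits = |top-k ∩ known| and precision = hits / k."""
    if not 1 <= k <= len(ranked):
        raise ValueError(f"k={k} out of range 1..{len(ranked)}")
    top = set(ranked["protein"].head(k))
    hits = len(top & known)
    return hits, hits / k
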