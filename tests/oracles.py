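"""Independent brute-force re-implementations used as test oracles.

Everything here works on plain edge lists and dicts with explicit loops —
no networkx, no calls into the package — so agreement with the package is a
genuine dual-route check.
"""

import math


def brute_counts(edges, locmap, vocabulary):
    """Interacted-protein count per compartment by explicit enumeration."""
    counts = {label: 0 for label in vocabulary}
    touched = set()
    for u, v in edges:
        touched.add(u)
        touched.add(v)
    for label in vocabulary:
        n = 0
        for protein, compartments in locmap.items():
            if protein in touched and label in compartments:
                n += 1
        counts[label] = n
    return counts


def brute_scores(counts):
    """SC(I) = C_X(I) / C_M over positive-count compartments only."""
    positive = {k: v for k, v in counts.items() if v > 0}
    c_max = max(positive.values())
    return {k: v / c_max for k, v in positive.items()}


def brute_weights(edges, locmap, scores):
    """Edge weight by looping over every compartment for every edge."""
    fallback = min(scores.values())
    weights = {}
    for u, v in edges:
        best = None
        for compartment, score in scores.items():
            if (
                compartment in locmap.get(u, set())
                and compartment in locmap.get(v, set())
            ):
                if best is None or score > best:
                    best = score
        weights[frozenset((u, v))] = fallback if best is None else best
    return weights


def brute_disease_edges(edges, seeds):
    """Edges with at least one seed endpoint (seed-seed included)."""
    return [
        (u, v) for u, v in edges if u in seeds or v in seeds
    ]


def brute_spd(disease_edges, weights):
    """SPD by a double loop over nodes and edges, fsum for exactness."""
    nodes = set()
    for u, v in disease_edges:
        nodes.update((u, v))
    spd = {}
    for node in nodes:
        incident = []
        for u, v in disease_edges:
            if node in (u, v):
                incident.append(weights[frozenset((u, v))])
        spd[node] = math.fsum(incident)
    return spd
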