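# Methods

## Model and assumptions

`pdmg` ranks candidate disease proteins by guilt by association: proteins
causing similar diseases cluster in the interactome, so the direct neighbors
of known disease proteins are the candidate pool, and the strength of a
candidate's weighted connectivity to that pool is its evidence. Two modeling
assumptions do the work:

1. **Interactions are only credible in a shared compartment.** Physical
   interaction requires co-localization, so an edge whose endpoints share no
   compartment (or lack annotation) is down-weighted to the minimum
   compartment score rather than trusted at face value.
2. **Compartment importance scales with occupancy.** A compartment hosting
   many interacting proteins is treated as proportionally more important:
   `SC(I) = C_X(I) / C_M`, where `C_X(I)` is the number of proteins with
   degree ≥ 1 annotated to compartment `I` and `C_M` the largest such count.
   Edges are weighted by the best shared compartment,
   `W(u,v) = max SC(SLoc(u,v))`, falling back to `SC(C_N)` (the smallest
   compartment's score) when `SLoc(u,v) = ∅`.

Candidates are ranked by weighted degree centrality inside the one-hop
disease network, `SPD(u) = Σ_v W(u,v)`. No propagation, random walk, or
statistical significance model is attached; the method is deliberately a
single deterministic pass.

## Procedure and conventions

- **Identifier normalization.** Symbols are uppercased and
  whitespace-stripped; an optional two-column alias file handles gene
  renames. This makes the joins across the three input files deterministic.
- **Network hygiene.** Self-loops are dropped (no formula uses them) and
  duplicate pairs collapse; both are logged with counts.
- **Interacted proteins.** `C_X` counts only proteins that touch at least
  one edge of the loaded network; annotated proteins absent from the network
  contribute nothing.
- **Zero-count compartments are excluded** from the score table rather than
  scored 0. A zero `SC(C_N)` would give weight 0 to every unannotated
  interaction and silently delete it from every SPD sum; keeping the
  fallback positive preserves those edges at minimal confidence.
- **Score table scope.** Compartment scores are computed once on the full
  input network, before the disease-specific restriction, so weights mean
  the same thing across diseases analyzed against the same interactome.
- **Seed–seed edges** are kept in the disease network by default: a seed is
  a direct neighbor of another seed, and dropping those edges would deflate
  the SPD of interconnected seeds. The stricter seed–candidate-only
  convention is available via `--exclude-seed-seed-edges`, and the count of
  seed–seed edges is always reported so both conventions are auditable.
- **Ties.** Ranking ties break by protein symbol ascending; ties for the
  largest/smallest compartment break by lexicographically smallest label.
  Neither choice affects any score, only the deterministic ordering and the
  recorded `C_M`/`C_N` labels.
- **Missing seeds** (not in the network) are dropped with a warning; only an
  entirely absent seed set is an error.
- **Numerics.** SPD uses `math.fsum` (correctly rounded summation), so
  scores are independent of neighbor iteration order and satisfy the
  handshake identity `Σ_u SPD(u) = 2 Σ_e W(e)` to well below 1e-9. Scores
  are kept at full precision internally and rendered to two decimals only in
  the output table.

## Tunable parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| `dialect` | `plain-tsv` | Edge-list format; `biogrid-tab` parses BioGRID tab files by official symbol. |
| `taxon` | `9606` | Organism filter for BioGRID rows (both interactors). |
| `strict` vocabulary | off | Strict mode pins the 11 COMPARTMENTS labels; lenient mode accepts any label as data. |
| `include_seed_seed_edges` | on | Disease-network edge convention (see above). |
| `top_k` | number of seeds found | Evaluation cutoff for known-protein recovery. |

## Synthetic benchmark

`pdmg.synthetic` generates the three inputs plus ground truth so the
pipeline can be exercised and benchmarked without external downloads. It
emulates:

- an Erdős–Rényi background interactome (default 500 proteins at edge
  density 0.02, mean degree ~10 — the same order of magnitude as the human
  interactome's mean degree);
- a planted disease module of 60 proteins whose internal edge probability is
  multiplied by `module_edge_boost` (default 5) and whose members always
  carry the largest compartment, mimicking a co-localized disease module;
  20 module members serve as seeds, the rest are the signal to recover;
- skewed compartment sizes: each of the 11 labels gets exactly
  `round(n · pᵢ)` members with geometric proportions `0.6 · 0.75^i`, so the
  SC values spread over (0, 1] instead of collapsing to 1; a protein left
  with no compartment receives one size-biased label;
- missing annotation: a fraction (default 0.1) of proteins loses all
  annotation, exercising the fallback weight branch.

One integer seed drives a single `numpy` Generator through all stages in
fixed order, so instances are bit-reproducible. In the
`module_edge_boost = 1` null case the compartment enrichment of module
members is also disabled, so the module carries no signal at all — this is
the negative control used in the tests.

What the generator does *not* emulate: the heavy-tailed degree distribution
of real interactomes, correlated multi-compartment annotation patterns, or
annotation evidence scores. Passing the planted-module benchmark therefore
shows the method recovers densely co-localized modules under idealized
noise, not that it reproduces performance on any particular curated dataset.

## Problem sizes used in tests

The test suite and `scripts/acceptance.py` run entirely on generated data:
100 instances of ≤ 30 proteins for the exact brute-force cross-check, 20
replicates of the default 500-protein benchmark for planted-module recovery,
one 2000-protein instance for the annotation-proportion check, and the
shipped 7-protein toy star for the hand-verified worked example. These sizes
keep every check deterministic and fast while being large enough for the
rank statistics to be meaningful.

## Known limitations

- Weighted degree is a local statistic: a candidate two hops from every seed
  scores zero by construction, so recall is bounded by the one-hop design.
- Hub proteins (e.g. ubiquitin in real data) accumulate SPD from sheer
  degree; the method makes no degree correction.
- Compartment importance is occupancy-based; rare but biologically decisive
  compartments are down-weighted by design.
- The fallback weight treats "annotation missing" and "annotation disjoint"
  identically; the two cases are biologically different but indistinguishable
  to the scoring rule.
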