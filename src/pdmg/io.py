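"""Readers and writers for the three PDMG inputs and its tabular outputs.

The pipeline joins three files on protein symbols: an undirected PPI edge
list (plain two-column TSV or a BioGRID tab-delimited interaction file), a
protein-to-compartment annotation table, and a plain-text seed list.
Symbols are normalized (uppercased, whitespace-stripped, optional alias map
for HGNC renames) so the joins are deterministic.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: The 11 subcellular compartment labels of the COMPARTMENTS database,
#: the default vocabulary for strict annotation parsing.
DEFAULT_COMPARTMENTS: tuple[str, ...] = (
    "Nucleus",
    "Golgi apparatus",
    "Cytosol",
    "Cytoskeleton",
    "Peroxisome",
    "Lysosome",
    "Endoplasmic reticulum",
    "Mitochondrion",
    "Endosome",
    "Extracellular space",
    "Plasma membrane",
)

#: Default NCBI taxon identifier used to filter BioGRID rows (human).
HUMAN_TAXON = "9606"

LocalizationMap = dict[str, set[str]]


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


def normalize_symbol(symbol: str, alias_map: Mapping[str, str] | None = None) -> str:
    """Canonicalize a protein/gene symbol: strip whitespace, uppercase,
    then apply the optional alias map (keyed on the normalized form)."""
    token = symbol.strip().upper()
    if not token:
        raise ValueError("empty protein symbol")
    if alias_map:
        token = alias_map.get(token, token)
    return token


def read_alias_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV of symbol renames (old<TAB>new)."""
    aliases: dict[str, str] = {}
    for lineno, fields in _tsv_rows(path):
        if len(fields) < 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 columns")
        aliases[fields[0].strip().upper()] = fields[1].strip().upper()
    return aliases


def _tsv_rows(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    """Yield (line_number, fields) for non-empty, non-comment TSV lines."""
    with open(path, newline="") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def _add_edge(
    graph: nx.Graph, a: str, b: str, counts: dict[str, int]
) -> None:
    if a == b:
        counts["self_loops"] += 1
        return
    if graph.has_edge(a, b):
        counts["duplicates"] += 1
        return
    graph.add_edge(a, b)
    counts["kept"] += 1


def read_edge_list(
    path: str | Path,
    dialect: str = "plain-tsv",
    *,
    taxon: str = HUMAN_TAXON,
    interaction_type: str | None = None,
    alias_map: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Read an undirected PPI network, deduplicated and self-loop free.

    Parameters
    ----------
    path:
        Input file.
    dialect:
        ``"plain-tsv"`` (two columns per line, ``#`` comments allowed) or
        ``"biogrid-tab"`` (BioGRID tab-delimited format with a header naming
        the official-symbol and organism columns of both interactors).
    taxon:
        For the BioGRID dialect, keep only rows where both organism columns
        equal this taxon identifier (default human, 9606).
    interaction_type:
        For the BioGRID dialect, optionally keep only ``"physical"`` or
        ``"genetic"`` rows; ``None`` keeps all.
    alias_map:
        Optional symbol rename table applied during normalization.
    """
    if dialect == "plain-tsv":
        graph = _read_plain_tsv(path, alias_map)
    elif dialect == "biogrid-tab":
        graph = _read_biogrid(path, taxon, interaction_type, alias_map)
    else:
        raise ValueError(f"unknown edge-list dialect: {dialect!r}")
    if graph.number_of_edges() == 0:
        raise ParseError(f"{path}: no interactions parsed")
    return graph


def _read_plain_tsv(path, alias_map) -> nx.Graph:
    graph = nx.Graph()
    counts = {"kept": 0, "self_loops": 0, "duplicates": 0}
    for lineno, fields in _tsv_rows(path):
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ParseError(f"{path}: line {lineno}: expected 2 tab-separated symbols")
        a = normalize_symbol(fields[0], alias_map)
        b = normalize_symbol(fields[1], alias_map)
        _add_edge(graph, a, b, counts)
    logger.info(
        "read %s: %d edges kept, %d self-loops dropped, %d duplicate pairs dropped",
        path, counts["kept"], counts["self_loops"], counts["duplicates"],
    )
    return graph


def _read_biogrid(path, taxon, interaction_type, alias_map) -> nx.Graph:
    def _find(header: list[str], name: str) -> int:
        lowered = [h.strip().lstrip("#").strip().lower() for h in header]
        try:
            return lowered.index(name.lower())
        except ValueError:
            raise ParseError(f"{path}: header lacks column {name!r}") from None

    graph = nx.Graph()
    counts = {"kept": 0, "self_loops": 0, "duplicates": 0, "organism_filtered": 0}
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        col_a = _find(header, "Official Symbol Interactor A")
        col_b = _find(header, "Official Symbol Interactor B")
        org_a = _find(header, "Organism Interactor A")
        org_b = _find(header, "Organism Interactor B")
        type_col = None
        if interaction_type is not None:
            type_col = _find(header, "Experimental System Type")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            needed = max(col_a, col_b, org_a, org_b, type_col or 0)
            if len(row) <= needed:
                raise ParseError(f"{path}: line {lineno}: too few columns")
            if row[org_a].strip() != taxon or row[org_b].strip() != taxon:
                counts["organism_filtered"] += 1
                continue
            if type_col is not None and row[type_col].strip().lower() != interaction_type.lower():
                continue
            a = normalize_symbol(row[col_a], alias_map)
            b = normalize_symbol(row[col_b], alias_map)
            _add_edge(graph, a, b, counts)
    logger.info(
        "read %s (biogrid): %d edges kept, %d self-loops, %d duplicates, "
        "%d rows dropped by organism filter",
        path, counts["kept"], counts["self_loops"], counts["duplicates"],
        counts["organism_filtered"],
    )
    return graph


def read_localization(
    path: str | Path,
    *,
    strict: bool = False,
    vocabulary: Iterable[str] = DEFAULT_COMPARTMENTS,
    alias_map: Mapping[str, str] | None = None,
) -> LocalizationMap:
    """Read protein<TAB>compartment rows into a protein -> compartment-set map.

    Duplicate (protein, compartment) rows collapse. In strict mode a
    compartment label outside ``vocabulary`` is an error; in lenient mode
    (default) it is accepted and added to the effective vocabulary.
    """
    vocab = set(vocabulary)
    assignments: LocalizationMap = {}
    for lineno, fields in _tsv_rows(path):
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ParseError(f"{path}: line {lineno}: expected protein<TAB>compartment")
        protein = normalize_symbol(fields[0], alias_map)
        compartment = fields[1].strip()
        if strict and compartment not in vocab:
            raise ParseError(
                f"{path}: line {lineno}: unknown compartment {compartment!r}"
            )
        assignments.setdefault(protein, set()).add(compartment)
    logger.info("read %s: %d annotated proteins", path, len(assignments))
    return assignments


@dataclass(frozen=True)
class SeedSet:
    """Known disease proteins used as the expansion starting point."""

    proteins: frozenset[str]
    disease_name: str = "disease"

    def __post_init__(self):
        if not self.proteins:
            raise ValueError("seed set is empty")

    def __iter__(self):
        return iter(self.proteins)

    def __contains__(self, item) -> bool:
        return item in self.proteins

    def __len__(self) -> int:
        return len(self.proteins)


def read_seeds(
    path: str | Path,
    disease_name: str = "disease",
    alias_map: Mapping[str, str] | None = None,
) -> SeedSet:
    """Read a seed list: one symbol per line, ``#`` comments allowed."""
    seeds: set[str] = set()
    with open(path) as handle:
        for line in handle:
            token = line.split("#", 1)[0].strip()
            if token:
                seeds.add(normalize_symbol(token, alias_map))
    if not seeds:
        raise ParseError(f"{path}: no seed proteins parsed")
    logger.info("read %s: %d seed proteins", path, len(seeds))
    return SeedSet(frozenset(seeds), disease_name)


# ---------------------------------------------------------------------------
# writers


def write_edge_list(graph: nx.Graph, path: str | Path, *, weighted: bool = False) -> None:
    """Write a TSV edge list, sorted for byte-stable output; weights at
    full precision when ``weighted``."""
    with open(path, "w") as handle:
        if weighted:
            handle.write("protein_a\tprotein_b\tweight\n")
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges()):
            if weighted:
                handle.write(f"{u}\t{v}\t{graph[u][v]['weight']!r}\n")
            else:
                handle.write(f"{u}\t{v}\n")


def write_ranked_table(ranked: pd.DataFrame, path: str | Path) -> None:
    """Write a ranked candidate table: rank, protein, score (2 decimals),
    seed_flag in {Known, Novel}."""
    with open(path, "w") as handle:
        handle.write("rank\tprotein\tscore\tseed_flag\n")
        for row in ranked.itertuples(index=False):
            handle.write(f"{row.rank}\t{row.protein}\t{row.score:.2f}\t{row.seed_flag}\n")


def write_node_roles(
    seeds: Iterable[str], candidates: Iterable[str], path: str | Path
) -> None:
    """Write the disease-network node table: protein, role in {seed, candidate}."""
    with open(path, "w") as handle:
        handle.write("protein\trole\n")
        for protein in sorted(seeds):
            handle.write(f"{protein}\tseed\n")
        for protein in sorted(candidates):
            handle.write(f"{protein}\tcandidate\n")


def write_score_report(counts: Mapping[str, int], scores: Mapping[str, float],
                       path: str | Path) -> None:
    """Write the compartment report: compartment, interacted-protein count,
    importance score (blank when the compartment is excluded)."""
    with open(path, "w") as handle:
        handle.write("compartment\tcount\tscore\n")
        for compartment in sorted(counts):
            score = scores.get(compartment)
            rendered = "" if score is None else repr(score)
            handle.write(f"{compartment}\t{counts[compartment]}\t{rendered}\n")
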