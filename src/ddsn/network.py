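"""Tripartite drug–gene–disease graph and its projection to the DDSN.

The tripartite graph G = (Vm ∪ Vg ∪ Vd, Eg ∪ Ed) has directed drug→gene
edges (Eg) and gene→disease edges (Ed).  Projecting onto the drug layer
yields the weighted, undirected drug–drug similarity network (DDSN)
Gs = (Vm, Es): drugs i and j are linked iff at least one disease is
reachable from both via a drug→gene→disease path, and the edge weight is
the *number of distinct diseases* reachable from both.  Multiple genes
connecting the same drug to the same disease count that disease once —
the weight counts diseases, not paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator

from .errors import GraphIntegrityError, ParameterError, UnknownDrugError
from .io_formats import DrugGeneRecord, GeneDiseaseRecord

__all__ = [
    "TripartiteGraph",
    "SimilarityNetwork",
    "build_tripartite",
    "reachable_diseases",
    "project_ddsn",
    "oracle_project",
]


@dataclass(frozen=True)
class TripartiteGraph:
    """Immutable tripartite graph over disjoint drug/gene/disease vertex sets."""

    drugs: frozenset[str]
    genes: frozenset[str]
    diseases: frozenset[str]
    drug_gene_edges: frozenset[tuple[str, str]]
    gene_disease_edges: frozenset[tuple[str, str]]

    def __post_init__(self):
        overlap = (self.drugs & self.genes) | (self.drugs & self.diseases) | (
            self.genes & self.diseases
        )
        if overlap:
            raise GraphIntegrityError(
                f"identifier(s) occur in two vertex roles: {sorted(overlap)[:5]}"
            )
        for d, g in self.drug_gene_edges:
            if d not in self.drugs or g not in self.genes:
                raise GraphIntegrityError(f"drug-gene edge ({d!r}, {g!r}) has a foreign endpoint")
        for g, dis in self.gene_disease_edges:
            if g not in self.genes or dis not in self.diseases:
                raise GraphIntegrityError(
                    f"gene-disease edge ({g!r}, {dis!r}) has a foreign endpoint"
                )


@dataclass(frozen=True)
class SimilarityNetwork:
    """Weighted undirected drug–drug similarity network Gs = (Vm, Es).

    ``weights`` maps each unordered drug pair (a 2-element frozenset) to a
    positive integer disease count.  Isolated drugs are legitimate nodes.
    """

    drugs: frozenset[str]
    weights: dict[frozenset[str], int] = field(default_factory=dict)

    def __post_init__(self):
        for pair, w in self.weights.items():
            if len(pair) != 2:
                raise GraphIntegrityError(f"self-loop or malformed pair: {set(pair)}")
            if not pair <= self.drugs:
                raise GraphIntegrityError(f"edge endpoint outside node set: {set(pair)}")
            if w < 1:
                raise GraphIntegrityError(f"non-positive weight {w} on {set(pair)}")

    @property
    def n_edges(self) -> int:
        return len(self.weights)

    def weight(self, a: str, b: str) -> int:
        """Edge weight between two drugs, 0 if unlinked."""
        return self.weights.get(frozenset((a, b)), 0)

    def iter_edges(self) -> Iterator[tuple[str, str, int]]:
        """Yield each edge once as (drug_a, drug_b, weight), a < b."""
        for pair, w in self.weights.items():
            a, b = sorted(pair)
            yield a, b, w

    def neighbors(self, drug: str) -> dict[str, int]:
        if drug not in self.drugs:
            raise UnknownDrugError(drug)
        out: dict[str, int] = {}
        for pair, w in self.weights.items():
            if drug in pair:
                (other,) = pair - {drug}
                out[other] = w
        return out

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.drugs)
        for a, b, w in self.iter_edges():
            g.add_edge(a, b, weight=w)
        return g


def build_tripartite(
    drug_gene: Iterable[DrugGeneRecord], gene_disease: Iterable[GeneDiseaseRecord]
) -> TripartiteGraph:
    """Assemble the tripartite graph from the two association tables.

    Vertex sets are exactly the identifiers occurring in the records; edges
    are deduplicated.  Genes appearing in only one table are retained as
    vertices even though no drug→gene→disease path crosses them.
    """
    eg = {(r.drug_id, r.gene_symbol) for r in drug_gene}
    ed = {(r.gene_symbol, r.disease_id) for r in gene_disease}
    drugs = frozenset(d for d, _ in eg)
    genes = frozenset(g for _, g in eg) | frozenset(g for g, _ in ed)
    diseases = frozenset(d for _, d in ed)
    return TripartiteGraph(drugs, genes, diseases, frozenset(eg), frozenset(ed))


def _adjacency(graph: TripartiteGraph) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    drug_to_genes: dict[str, set[str]] = {d: set() for d in graph.drugs}
    gene_to_diseases: dict[str, set[str]] = {g: set() for g in graph.genes}
    for d, g in graph.drug_gene_edges:
        drug_to_genes[d].add(g)
    for g, dis in graph.gene_disease_edges:
        gene_to_diseases[g].add(dis)
    return drug_to_genes, gene_to_diseases


def reachable_diseases(graph: TripartiteGraph, drug: str) -> frozenset[str]:
    """All diseases reachable from *drug* via some drug→gene→disease path."""
    if drug not in graph.drugs:
        raise UnknownDrugError(drug)
    drug_to_genes, gene_to_diseases = _adjacency(graph)
    out: set[str] = set()
    for gene in drug_to_genes[drug]:
        out |= gene_to_diseases[gene]
    return frozenset(out)


def project_ddsn(graph: TripartiteGraph, min_weight: int = 1) -> SimilarityNetwork:
    """Project the tripartite graph onto the drug layer.

    weight(i, j) = |reachable(i) ∩ reachable(j)|; pairs below *min_weight*
    (default 1, i.e. "at least one shared disease") are omitted.  All drugs
    remain as nodes, so downstream community filtering — not the projection —
    decides the fate of isolated drugs.
    """
    if min_weight < 1:
        raise ParameterError(f"min_weight must be >= 1, got {min_weight}")
    drug_to_genes, gene_to_diseases = _adjacency(graph)
    reach: dict[str, frozenset[str]] = {}
    for drug, genes in drug_to_genes.items():
        acc: set[str] = set()
        for g in genes:
            acc |= gene_to_diseases[g]
        reach[drug] = frozenset(acc)

    # Accumulate pair counts disease-by-disease: each disease contributes 1
    # to every pair of drugs that reach it.
    disease_to_drugs: dict[str, list[str]] = {}
    for drug, diseases in reach.items():
        for dis in diseases:
            disease_to_drugs.setdefault(dis, []).append(drug)
    counts: dict[frozenset[str], int] = {}
    for members in disease_to_drugs.values():
        members.sort()
        for a, b in combinations(members, 2):
            pair = frozenset((a, b))
            counts[pair] = counts.get(pair, 0) + 1
    weights = {pair: w for pair, w in counts.items() if w >= min_weight}
    return SimilarityNetwork(drugs=graph.drugs, weights=weights)


def oracle_project(graph: TripartiteGraph, guard: int = 10**6) -> SimilarityNetwork:
    """Reference projection by exhaustive path enumeration (test oracle).

    For every drug pair and every disease, enumerates all drug→gene→disease
    paths to decide whether the disease is reachable from both drugs.
    Intentionally naive and independent of :func:`project_ddsn`; guarded to
    small graphs (|Vm|·|Vd| ≤ *guard*).
    """
    if len(graph.drugs) * len(graph.diseases) > guard:
        raise ParameterError(
            f"oracle guard exceeded: |Vm|*|Vd| = {len(graph.drugs) * len(graph.diseases)}"
        )

    def reaches(drug: str, disease: str) -> bool:
        for d, g in graph.drug_gene_edges:
            if d != drug:
                continue
            for g2, dis in graph.gene_disease_edges:
                if g2 == g and dis == disease:
                    return True
        return False

    weights: dict[frozenset[str], int] = {}
    for a, b in combinations(sorted(graph.drugs), 2):
        w = sum(
            1 for dis in graph.diseases if reaches(a, dis) and reaches(b, dis)
        )
        if w >= 1:
            weights[frozenset((a, b))] = w
    return SimilarityNetwork(drugs=graph.drugs, weights=weights)
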