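"""Shared test utilities: fixture builders and frame→record conversion."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ddsn.io_formats import DrugGeneRecord, GeneDiseaseRecord
from ddsn.network import SimilarityNetwork, TripartiteGraph, build_tripartite, project_ddsn


def records_from_frames(drug_gene: pd.DataFrame, gene_disease: pd.DataFrame):
    dg = [
        DrugGeneRecord(r.drug_id, r.drug_name, r.gene_symbol, r.relation_type)
        for r in drug_gene.itertuples(index=False)
    ]
    gd = [
        GeneDiseaseRecord(r.gene_symbol, r.disease_id, r.disease_name)
        for r in gene_disease.itertuples(index=False)
    ]
    return dg, gd


def tripartite_from_edges(eg: list[tuple[str, str]], ed: list[tuple[str, str]]) -> TripartiteGraph:
    """Build a tripartite graph directly from raw (drug, gene) and (gene, disease) pairs."""
    dg = [DrugGeneRecord(d, d, g, "target") for d, g in eg]
    gd = [GeneDiseaseRecord(g, dis, dis) for g, dis in ed]
    return build_tripartite(dg, gd)


def fig2_style_graph() -> TripartiteGraph:
    """A small tripartite graph in which drugs M1 and M7 share gene-mediated
    paths to exactly three diseases (and M1 reaches one more on its own)."""
    return tripartite_from_edges(
        eg=[
            ("M1", "ADRA1A"),
            ("M1", "ADRA1B"),
            ("M7", "ADRA1A"),
            ("M2", "HTR2A"),
        ],
        ed=[
            ("ADRA1A", "Paraganglioma"),
            ("ADRA1A", "Pheochromocytoma"),
            ("ADRA1A", "Adrenocortical carcinoma"),
            ("ADRA1B", "Hypertension"),
            ("HTR2A", "Schizophrenia"),
        ],
    )


def random_tripartite(rng: np.random.Generator, max_drugs=15, max_genes=10, max_diseases=10) -> TripartiteGraph:
    """A random tripartite graph for oracle-equivalence and property tests."""
    nd = int(rng.integers(1, max_drugs + 1))
    ng = int(rng.integers(1, max_genes + 1))
    nx_ = int(rng.integers(1, max_diseases + 1))
    drugs = [f"D{i}" for i in range(nd)]
    genes = [f"G{i}" for i in range(ng)]
    diseases = [f"X{i}" for i in range(nx_)]
    eg = [(d, g) for d in drugs for g in genes if rng.random() < 0.3]
    ed = [(g, x) for g in genes for x in diseases if rng.random() < 0.3]
    # Guarantee every drug appears in the drug-gene table so Vm is stable.
    present = {d for d, _ in eg}
    for d in drugs:
        if d not in present:
            eg.append((d, genes[int(rng.integers(0, ng))]))
    return tripartite_from_edges(eg, ed)


def network_from_weights(weights: dict[tuple[str, str], int], extra_nodes=()) -> SimilarityNetwork:
    drugs = set(extra_nodes)
    fs = {}
    for (a, b), w in weights.items():
        drugs |= {a, b}
        fs[frozenset((a, b))] = w
    return SimilarityNetwork(drugs=frozenset(drugs), weights=fs)


def clique_bridge_network() -> SimilarityNetwork:
    """Two unit-weight 4-cliques joined by a single weight-1 bridge."""
    w = {}
    left = ["a1", "a2", "a3", "a4"]
    right = ["b1", "b2", "b3", "b4"]
    for grp in (left, right):
        for i in range(4):
            for j in range(i + 1, 4):
                w[(grp[i], grp[j])] = 1
    w[("a1", "b1")] = 1
    return network_from_weights(w)


def project_tables(drug_gene: pd.DataFrame, gene_disease: pd.DataFrame, min_weight=1) -> SimilarityNetwork:
    dg, gd = records_from_frames(drug_gene, gene_disease)
    return project_ddsn(build_tripartite(dg, gd), min_weight=min_weight)


#: The twelve per-cluster accuracy rows of the reference analysis
#: (cluster number, size, % predominant, % literature-confirmed), used as
#: printed inputs to the accuracy aggregation.
TABLE2_ROWS = [
    (1, 105, 52.4, 26.7),
    (2, 88, 52.3, 14.8),
    (3, 95, 35.8, 13.7),
    (4, 85, 52.9, 30.6),
    (5, 51, 54.9, 17.6),
    (6, 51, 60.8, 23.5),
    (7, 51, 64.7, 15.7),
    (8, 44, 61.4, 20.4),
    (9, 31, 61.3, 16.1),
    (10, 24, 87.5, 4.2),
    (11, 15, 40.0, 13.3),
    (12, 13, 30.8, 46.1),
]
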