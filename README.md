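# ddsn — drug repositioning from drug–gene–disease network communities

`ddsn` is a pipeline for generating drug-repositioning hints by
guilt-by-association on a **drug–drug similarity network (DDSN)** derived
from public drug–gene and gene–disease association data. It is aimed at
computational pharmacology groups who want a transparent, fully scripted
alternative to black-box repurposing tools: every stage — network
construction, community detection, ATC labeling, candidate calling,
literature-query generation — is an ordinary Python function with a TSV
in/TSV out contract.

## The method

1. **Tripartite graph.** Drug→gene interaction records and gene→disease
   association records define a directed tripartite graph
   G = (Vm ∪ Vg ∪ Vd, Eg ∪ Ed) over drugs, genes and diseases.
2. **Projection.** G is projected onto the drug layer: drugs *i* and *j*
   are joined iff some disease is reachable from both via a
   drug→gene→disease path, and the edge weight
   w(i, j) = |R(i) ∩ R(j)| counts the *distinct* diseases reachable from
   both (R(i) is drug *i*'s reachable-disease set). Multiple genes leading
   to the same disease count it once.
3. **Communities.** The weighted DDSN is clustered by hierarchical
   agglomeration on a structural-equivalence cosine vertex similarity
   (average linkage, never across connected components); the dendrogram is
   cut at the prefix maximizing weighted Newman–Girvan modularity
   Q = (1/2m) Σᵢⱼ [Aᵢⱼ − kᵢkⱼ/2m] δ(cᵢ, cⱼ).
   Communities outside the main connected component, or with fewer than 8
   drugs, are excluded; survivors are numbered by descending size.
4. **ATC labeling.** Each surviving community is labeled with its dominant
   WHO ATC level-1 code (the code carried by most members). Drugs whose
   own codes all disagree with the label — or that have no codes — become
   **repositioning candidates** for the label's therapeutic area. Within
   the label-matching drugs, level 2–4 histograms identify the dominant
   mechanisms of action; the top-3 level-4 codes (ties expand the list)
   map to biological target sets for downstream docking prioritization.
5. **Literature validation.** For every candidate, a deterministic Boolean
   PubMed query (`"<drug>"[MeSH Terms] AND ("<ATC category>"[MeSH Terms]
   OR synonyms…) AND (clinicaltrial[Filter] OR classicalarticle[Filter])`)
   is emitted. Externally screened evidence can be folded back to promote
   candidates to *literature-confirmed*; the per-community accuracy is
   % predominant-in-database + % literature-confirmed.

Because the real sources (DrugBank, DisGeNET) are licensed, the package
ships a planted-structure synthetic generator that emulates their
statistical shape — gene-sharing drug communities with dominant ATC
profiles and a controlled fraction of planted mislabeled drugs — so the
whole pipeline is testable offline, including parameter recovery.

## Worked example

Generate a synthetic dataset of 4 communities × 12 drugs with 25 % planted
mislabeled drugs, and run the pipeline:

```python
from pathlib import Path
from ddsn import GeneratorConfig, generate_dataset, PipelineConfig, run_pipeline

out = Path("demo"); out.mkdir()
dg, gd, da, at, truth = generate_dataset(
    GeneratorConfig(n_clusters=4, drugs_per_cluster=12, mislabel_fraction=0.25, seed=7)
)
for frame, name in [(dg, "drug_gene"), (gd, "gene_disease"),
                    (da, "drug_atc"), (at, "atc_target")]:
    frame.to_csv(out / f"{name}.tsv", sep="\t", index=False)

manifest = run_pipeline(PipelineConfig(
    drug_gene_path=str(out / "drug_gene.tsv"),
    gene_disease_path=str(out / "gene_disease.tsv"),
    drug_atc_path=str(out / "drug_atc.tsv"),
    atc_target_path=str(out / "atc_target.tsv"),
    output_dir=str(out / "results"),
))
```

The manifest reports (abridged):

```
n_drugs 48, n_genes 32, n_diseases 96, n_ddsn_edges 396
n_clusters_prefilter 4, n_clusters_postfilter 4, modularity 0.574
n_candidates 12, weighted_pct_predominant 75.0, pct_candidates 25.0
```

All four planted communities are recovered intact; the 12 planted
mislabeled drugs (3 per community of 12, i.e. exactly 25 %) are flagged as
candidates and 75 % of drugs match their community label. The emitted
`results/cluster_report.tsv` mirrors that per community:

```
cluster_number  size  atc_level1  pct_predominant  pct_confirmed  pct_accuracy
             1    12           N             75.0            0.0          75.0
             2    12           B             75.0            0.0          75.0
             ...
```

and `results/hints.tsv` lists each drug's status (`db-matched` /
`candidate`), the community's top level-4 codes and their mapped targets,
while `results/query_log.tsv` holds one PubMed query per candidate, e.g.

```
"DR01_001"[MeSH Terms] AND "Nervous system"[MeSH Terms] AND (clinicaltrial[Filter] OR classicalarticle[Filter])
```

The same flow is available from the shell:

```sh
ddsn synth --n-clusters 4 --drugs-per-cluster 12 --seed 7 --out-dir demo
ddsn project --drug-gene demo/drug_gene.tsv --gene-disease demo/gene_disease.tsv --out demo/edges.tsv
ddsn cluster --edges demo/edges.tsv --min-size 8 --out demo/partition.tsv
ddsn run --config config.yaml            # full pipeline from a YAML config
```

## Input formats

All tables are UTF-8 TSV with a header row (column names configurable via
`TableDialect`): `drug_gene` (drug_id, drug_name, gene_symbol,
relation_type ∈ {target, enzyme, transporter, carrier}), `gene_disease`
(gene_symbol, disease_id, disease_name, optional score ∈ [0,1]),
`drug_atc` (drug_id, atc_code; one row per pair), `atc_target`
(atc_code level-4, target). The DDSN is exported as an edge-list TSV and
GraphML.

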