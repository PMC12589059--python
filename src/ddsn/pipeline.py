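"""End-to-end orchestration: tables → tripartite → DDSN → communities →
labels → repositioning hints → query log → reports.

Every stage is a thin call into the corresponding module; the value of
this layer is ordering, artifact persistence (all TSV/GraphML under one
output directory) and a run manifest with the headline counts.  Identical
config + inputs give identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import communities as comm
from . import io_formats as iof
from . import labeling as lab
from . import litquery as lq
from . import network as net
from .errors import ConfigError, StageError

logger = logging.getLogger("ddsn.pipeline")

__all__ = ["PipelineConfig", "RepositioningHint", "run_pipeline", "ATC_LEVEL1_NAMES"]

#: WHO level-1 anatomical main group names, used for query construction.
ATC_LEVEL1_NAMES: dict[str, str] = {
    "A": "Alimentary tract and metabolism",
    "B": "Blood and blood forming organs",
    "C": "Cardiovascular system",
    "D": "Dermatologicals",
    "G": "Genito-urinary system and sex hormones",
    "H": "Systemic hormonal preparations",
    "J": "Antiinfectives for systemic use",
    "L": "Antineoplastic and immunomodulating agents",
    "M": "Musculo-skeletal system",
    "N": "Nervous system",
    "P": "Antiparasitic products",
    "R": "Respiratory system",
    "S": "Sensory organs",
    "V": "Various",
}


@dataclass(frozen=True)
class RepositioningHint:
    """One drug's predicted property and its validation status."""

    drug_id: str
    cluster_number: int
    predicted_level1: str
    status: str  # "db-matched" | "literature-confirmed" | "candidate"
    top_level4: tuple[str, ...] = ()
    targets: frozenset[str] = frozenset()


@dataclass(frozen=True)
class PipelineConfig:
    """Paths and parameters of one pipeline run."""

    drug_gene_path: str
    gene_disease_path: str
    drug_atc_path: str
    atc_target_path: str
    output_dir: str
    dialect: iof.TableDialect = iof.DEFAULT_DIALECT
    score_threshold: float | None = None
    min_weight: int = 1
    min_size: int = 8
    require_main_component: bool = True
    top_k_level4: int = 3
    seed: int = 0
    evidence_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        dialect = iof.TableDialect(**raw.pop("dialect", {}))
        try:
            return cls(dialect=dialect, **raw)
        except TypeError as exc:
            raise ConfigError(f"bad config key: {exc}") from exc

    def validate(self) -> None:
        for name in ("drug_gene_path", "gene_disease_path", "drug_atc_path", "atc_target_path"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ConfigError(f"{name}: no such file {p}")
        if self.evidence_path is not None and not Path(self.evidence_path).exists():
            raise ConfigError(f"evidence_path: no such file {self.evidence_path}")


def _read_evidence(path: str | Path) -> list[lq.EvidenceRecord]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        pmids = tuple(p for p in row.pmids.split(";") if p) if row.pmids else ()
        out.append(
            lq.EvidenceRecord(
                drug_id=row.drug_id,
                cluster_number=int(row.cluster_number),
                pmids=pmids,
                confirmed=row.confirmed.strip().lower() in {"1", "true", "yes"},
            )
        )
    return out


def _stage(name: str):
    """Decorator-free stage wrapper: re-raises with the stage name."""

    class _Ctx:
        def __init__(self):
            self.t0 = 0.0

        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %-12s done in %.2fs", name, dt)
                return False
            if isinstance(exc, StageError):
                return False
            raise StageError(name, str(exc)) from exc

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the whole pipeline and return the manifest dictionary.

    Emits under ``config.output_dir``: ``ddsn.graphml``, ``ddsn_edges.tsv``,
    ``partition.tsv``, ``excluded_clusters.tsv``, ``cluster_report.tsv``,
    ``hints.tsv``, ``query_log.tsv`` and ``manifest.json``.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("ingest"):
        drug_gene = iof.read_drug_gene_table(config.drug_gene_path, config.dialect)
        gene_disease = iof.read_gene_disease_table(
            config.gene_disease_path, config.score_threshold, config.dialect
        )
        annotations = iof.read_drug_atc_table(config.drug_atc_path, config.dialect)
        atc_targets = iof.read_atc_target_table(config.atc_target_path, config.dialect)

    with _stage("tripartite"):
        if not drug_gene:
            raise ConfigError("drug-gene table contains no usable rows")
        graph = net.build_tripartite(drug_gene, gene_disease)

    with _stage("projection"):
        network = net.project_ddsn(graph, min_weight=config.min_weight)
        iof.write_edge_list(network, out / "ddsn_edges.tsv")

    with _stage("communities"):
        partition = comm.hierarchical_communities(network, seed=config.seed)

    with _stage("filtering"):
        filtered = comm.filter_communities(
            partition,
            network,
            min_size=config.min_size,
            require_main_component=config.require_main_component,
        )
        membership = filtered.membership()
        iof.write_ddsn_graphml(network, out / "ddsn.graphml", clusters=membership)
        iof.write_table(
            [{"drug_id": d, "cluster_number": c} for d, c in sorted(membership.items())],
            out / "partition.tsv",
            ["drug_id", "cluster_number"],
        )
        iof.write_table(
            [
                {"cluster_number": e.number, "size": e.size, "exclusion_reason": e.reason}
                for e in filtered.excluded
            ],
            out / "excluded_clusters.tsv",
            ["cluster_number", "size", "exclusion_reason"],
        )

    with _stage("labeling"):
        reports = [
            lab.build_cluster_report(
                num, members, annotations, atc_targets, top_k=config.top_k_level4
            )
            for num, members in enumerate(filtered.clusters, start=1)
        ]

    with _stage("hints"):
        hints: list[RepositioningHint] = []
        for rep in reports:
            if rep.label is None:
                continue
            flat_targets = frozenset().union(*rep.targets.values()) if rep.targets else frozenset()
            for drug in sorted(rep.members):
                status = "db-matched" if drug in rep.matched_drugs else "candidate"
                hints.append(
                    RepositioningHint(
                        drug_id=drug,
                        cluster_number=rep.cluster_number,
                        predicted_level1=rep.label,
                        status=status,
                        top_level4=rep.top_level4,
                        targets=flat_targets,
                    )
                )

    with _stage("validation"):
        if config.evidence_path is not None:
            evidence = _read_evidence(config.evidence_path)
            hints, confirmed_counts = lq.apply_validation(hints, evidence)
        else:
            confirmed_counts = {}

    with _stage("queries"):
        query_rows = []
        for h in hints:
            if h.status == "db-matched":
                continue
            cat = ATC_LEVEL1_NAMES.get(h.predicted_level1, h.predicted_level1)
            spec = lq.QuerySpec(drug_term=h.drug_id, category_terms=(cat,))
            query_rows.append({"drug_id": h.drug_id, "query": lq.build_query(spec)})
        iof.write_table(query_rows, out / "query_log.tsv", ["drug_id", "query"])

    with _stage("reports"):
        acc_rows = []
        labels = {}
        for rep in reports:
            n_conf = confirmed_counts.get(rep.cluster_number, 0)
            acc_rows.append(
                (
                    rep.cluster_number,
                    rep.size,
                    100.0 * len(rep.matched_drugs) / rep.size,
                    100.0 * n_conf / rep.size,
                )
            )
            labels[rep.cluster_number] = rep.label or ""
        summary = lab.accuracy_summary(acc_rows, labels) if acc_rows else None
        if summary is not None:
            iof.write_table(
                [
                    {
                        "cluster_number": r.cluster_number,
                        "size": r.size,
                        "atc_level1": r.label,
                        "pct_predominant": r.pct_predominant,
                        "pct_confirmed": r.pct_confirmed,
                        "pct_accuracy": r.pct_accuracy,
                    }
                    for r in summary.rows
                ],
                out / "cluster_report.tsv",
                ["cluster_number", "size", "atc_level1", "pct_predominant", "pct_confirmed", "pct_accuracy"],
            )
        iof.write_table(
            [
                {
                    "drug_id": h.drug_id,
                    "cluster_number": h.cluster_number,
                    "predicted_level1": h.predicted_level1,
                    "status": h.status,
                    "top_level4_codes": ";".join(h.top_level4),
                    "targets": ";".join(sorted(h.targets)),
                }
                for h in hints
            ],
            out / "hints.tsv",
            ["drug_id", "cluster_number", "predicted_level1", "status", "top_level4_codes", "targets"],
        )

    n_candidates = sum(1 for h in hints if h.status == "candidate")
    manifest = {
        "n_drugs": len(graph.drugs),
        "n_genes": len(graph.genes),
        "n_diseases": len(graph.diseases),
        "n_ddsn_edges": network.n_edges,
        "n_clusters_prefilter": len(partition.clusters),
        "n_clusters_postfilter": len(filtered.clusters),
        "modularity": partition.modularity,
        "n_hints": len(hints),
        "n_candidates": n_candidates,
        "weighted_pct_predominant": summary.weighted_pct_predominant if summary else None,
        "weighted_pct_confirmed": summary.weighted_pct_confirmed if summary else None,
        "total_accuracy": summary.total_accuracy if summary else None,
        "pct_candidates": summary.pct_candidates if summary else None,
        "artifacts": {
            "graphml": str(out / "ddsn.graphml"),
            "edges": str(out / "ddsn_edges.tsv"),
            "partition": str(out / "partition.tsv"),
            "excluded": str(out / "excluded_clusters.tsv"),
            "cluster_report": str(out / "cluster_report.tsv"),
            "hints": str(out / "hints.tsv"),
            "query_log": str(out / "query_log.tsv"),
        },
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
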