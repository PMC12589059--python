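"""Flat-file I/O: strict TSV readers for the four input tables and GraphML export.

All tables are UTF-8, tab-separated, one header row, no quoting (a tab may
not occur inside a field).  Column names are configurable through
:class:`TableDialect`; the defaults are documented in the README.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .atc import validate_atc
from .errors import RowFormatError, TableFormatError

logger = logging.getLogger("ddsn.io")

__all__ = [
    "TableDialect",
    "DrugGeneRecord",
    "GeneDiseaseRecord",
    "DrugAnnotation",
    "read_drug_gene_table",
    "read_gene_disease_table",
    "read_drug_atc_table",
    "read_atc_target_table",
    "write_ddsn_graphml",
    "read_ddsn_graphml",
    "write_edge_list",
]

#: Relation types a drug-gene interaction row may declare.  DrugBank
#: distinguishes pharmacological targets from metabolizing enzymes,
#: transporters and carriers; all four count as interactions by default.
RELATION_TYPES = frozenset({"target", "enzyme", "transporter", "carrier"})


@dataclass(frozen=True)
class TableDialect:
    """Column-name mapping for the input tables, plus row filters.

    ``relation_whitelist`` restricts which drug-gene relation types are
    ingested; ``None`` keeps all of :data:`RELATION_TYPES`.
    """

    drug_id_col: str = "drug_id"
    drug_name_col: str = "drug_name"
    gene_col: str = "gene_symbol"
    relation_col: str = "relation_type"
    disease_id_col: str = "disease_id"
    disease_name_col: str = "disease_name"
    score_col: str = "score"
    atc_col: str = "atc_code"
    target_col: str = "target"
    relation_whitelist: frozenset[str] | None = None


DEFAULT_DIALECT = TableDialect()


@dataclass(frozen=True)
class DrugGeneRecord:
    """One drug→gene interaction edge (a member of Eg)."""

    drug_id: str
    drug_name: str
    gene_symbol: str
    relation_type: str


@dataclass(frozen=True)
class GeneDiseaseRecord:
    """One gene→disease association edge (a member of Ed)."""

    gene_symbol: str
    disease_id: str
    disease_name: str
    score: float | None = None


@dataclass(frozen=True)
class DrugAnnotation:
    """A drug together with its (possibly empty) set of ATC codes."""

    drug_id: str
    atc_codes: frozenset[str] = field(default_factory=frozenset)


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise TableFormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, quoting=3)
    for col in required:
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing required column {col!r}")
    return df


def read_drug_gene_table(
    path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> list[DrugGeneRecord]:
    """Read drug→gene interaction records from a TSV file.

    Rows are returned in file order.  Exact duplicates of
    ``(drug_id, gene_symbol, relation_type)`` collapse to the first
    occurrence with a logged warning — the downstream projection counts
    sets of diseases, so duplicated edges must not inflate weights.
    """
    d = dialect
    df = _read_tsv(path, [d.drug_id_col, d.drug_name_col, d.gene_col, d.relation_col])
    whitelist = d.relation_whitelist if d.relation_whitelist is not None else RELATION_TYPES
    records: list[DrugGeneRecord] = []
    seen: set[tuple[str, str, str]] = set()
    dupes = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        drug = getattr(row, d.drug_id_col).strip()
        gene = getattr(row, d.gene_col).strip()
        rel = getattr(row, d.relation_col).strip()
        if not drug:
            raise RowFormatError("empty drug_id", line=i)
        if not gene:
            raise RowFormatError("empty gene_symbol", line=i)
        if rel not in RELATION_TYPES:
            raise RowFormatError(f"unknown relation_type {rel!r}", line=i)
        if rel not in whitelist:
            continue
        key = (drug, gene, rel)
        if key in seen:
            dupes += 1
            continue
        seen.add(key)
        records.append(
            DrugGeneRecord(drug, getattr(row, d.drug_name_col).strip(), gene, rel)
        )
    if dupes:
        logger.warning("%s: collapsed %d duplicate drug-gene row(s)", path, dupes)
    return records


def read_gene_disease_table(
    path: str | Path,
    score_threshold: float | None = None,
    dialect: TableDialect = DEFAULT_DIALECT,
) -> list[GeneDiseaseRecord]:
    """Read gene→disease association records from a TSV file.

    When *score_threshold* is given, rows with ``score < score_threshold``
    are dropped (rows without a score survive any threshold).  The score
    column itself is optional; when present each value must lie in [0, 1].
    """
    d = dialect
    df = _read_tsv(path, [d.gene_col, d.disease_id_col, d.disease_name_col])
    has_score = d.score_col in df.columns
    records: list[GeneDiseaseRecord] = []
    seen: set[tuple[str, str]] = set()
    dupes = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        gene = getattr(row, d.gene_col).strip()
        disease = getattr(row, d.disease_id_col).strip()
        if not gene:
            raise RowFormatError("empty gene_symbol", line=i)
        if not disease:
            raise RowFormatError("empty disease_id", line=i)
        score: float | None = None
        if has_score:
            raw = getattr(row, d.score_col).strip()
            if raw:
                try:
                    score = float(raw)
                except ValueError:
                    raise RowFormatError(f"non-numeric score {raw!r}", line=i) from None
                if math.isnan(score) or not 0.0 <= score <= 1.0:
                    raise RowFormatError(f"score {score} outside [0, 1]", line=i)
        if score_threshold is not None and score is not None and score < score_threshold:
            continue
        key = (gene, disease)
        if key in seen:
            dupes += 1
            continue
        seen.add(key)
        records.append(
            GeneDiseaseRecord(gene, disease, getattr(row, d.disease_name_col).strip(), score)
        )
    if dupes:
        logger.warning("%s: collapsed %d duplicate gene-disease row(s)", path, dupes)
    return records


def read_drug_atc_table(
    path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> dict[str, DrugAnnotation]:
    """Read one-row-per-(drug, ATC code) annotations, grouped per drug.

    A drug may appear with an empty code cell to declare "no ATC codes";
    it then maps to an annotation with an empty set.  A non-empty code
    that fails ATC syntax validation is a row-level error.
    """
    d = dialect
    df = _read_tsv(path, [d.drug_id_col, d.atc_col])
    codes: dict[str, set[str]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        drug = getattr(row, d.drug_id_col).strip()
        if not drug:
            raise RowFormatError("empty drug_id", line=i)
        raw = getattr(row, d.atc_col).strip()
        bucket = codes.setdefault(drug, set())
        if raw:
            norm = raw.upper()
            if not validate_atc(norm):
                raise RowFormatError(f"invalid ATC code {raw!r}", line=i)
            bucket.add(norm)
    return {
        drug: DrugAnnotation(drug, frozenset(members)) for drug, members in codes.items()
    }


def read_atc_target_table(
    path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> dict[str, frozenset[str]]:
    """Read the ATC level-4 → biological-target mapping (one pair per row)."""
    d = dialect
    df = _read_tsv(path, [d.atc_col, d.target_col])
    mapping: dict[str, set[str]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        code = getattr(row, d.atc_col).strip().upper()
        target = getattr(row, d.target_col).strip()
        if not validate_atc(code) or len(code) != 5:
            raise RowFormatError(f"invalid ATC level-4 code {code!r}", line=i)
        if not target:
            raise RowFormatError("empty target", line=i)
        mapping.setdefault(code, set()).add(target)
    return {code: frozenset(ts) for code, ts in mapping.items()}


# --- writers -----------------------------------------------------------------


def write_table(records: Iterable[Mapping], path: str | Path, columns: Sequence[str]) -> None:
    """Write dict-like records as a headered TSV with the given column order."""
    df = pd.DataFrame(list(records), columns=list(columns))
    df.to_csv(path, sep="\t", index=False)


def write_ddsn_graphml(network, path: str | Path, clusters: Mapping[str, int] | None = None) -> None:
    """Export a similarity network as GraphML.

    Each node carries its ``drug_id`` attribute (and ``cluster`` when a
    partition mapping is supplied); each edge carries its integer ``weight``.
    Re-reading the file reproduces an isomorphic weighted graph.
    """
    g = nx.Graph()
    for drug in sorted(network.drugs):
        attrs = {"drug_id": drug}
        if clusters is not None and drug in clusters:
            attrs["cluster"] = int(clusters[drug])
        g.add_node(drug, **attrs)
    for a, b, w in network.iter_edges():
        g.add_edge(a, b, weight=int(w))
    nx.write_graphml(g, str(path))


def read_ddsn_graphml(path: str | Path):
    """Read a GraphML file written by :func:`write_ddsn_graphml`."""
    from .network import SimilarityNetwork

    g = nx.read_graphml(str(path))
    weights = {
        frozenset((a, b)): int(data["weight"]) for a, b, data in g.edges(data=True)
    }
    return SimilarityNetwork(drugs=frozenset(g.nodes), weights=weights)


def write_edge_list(network, path: str | Path) -> None:
    """Write the similarity network as a (drug_a, drug_b, weight) TSV."""
    rows = [
        {"drug_a": a, "drug_b": b, "weight": w}
        for a, b, w in sorted(network.iter_edges())
    ]
    write_table(rows, path, ["drug_a", "drug_b", "weight"])
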