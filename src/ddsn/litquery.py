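"""PubMed literature-validation queries and evidence folding.

For each repositioning candidate, a Boolean PubMed query correlates the
drug name with its community's ATC level-1 category name (AND) and the
category's synonyms (OR), restricted to research articles and clinical
trials.  The fixed template is::

    "<drug>"[MeSH Terms] AND ("<cat>"[MeSH Terms] OR "<syn1>"[Title/Abstract]
        OR ...) AND (clinicaltrial[Filter] OR classicalarticle[Filter])

(one line; the parenthesised category group collapses to a single clause
when there are no synonyms).  Which publication-type filter tags best
capture "research articles and clinical trials" is configuration — the
defaults are PubMed's ``clinicaltrial`` and ``classicalarticle`` tags.

Live E-utilities access is optional and sits behind the
:class:`QueryFetcher` protocol; tests use mocks.  The downstream expert
screening of retrieved articles is modeled as the externally supplied
``confirmed`` flag on :class:`EvidenceRecord`, not automated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Protocol, Sequence

from .errors import ParameterError

logger = logging.getLogger("ddsn.litquery")

__all__ = [
    "DEFAULT_FILTERS",
    "QuerySpec",
    "EvidenceRecord",
    "QueryFetcher",
    "StaticFetcher",
    "EntrezFetcher",
    "build_query",
    "apply_validation",
]

#: Publication-type filter tags appended to every query (AND-joined group).
DEFAULT_FILTERS: tuple[str, ...] = ("clinicaltrial", "classicalarticle")


@dataclass(frozen=True)
class QuerySpec:
    """One drug's validation query: drug name, category name, synonyms."""

    drug_term: str
    category_terms: tuple[str, ...]
    filters: tuple[str, ...] = DEFAULT_FILTERS

    def __post_init__(self):
        if not self.drug_term.strip():
            raise ParameterError("drug_term must be non-empty")
        if not self.category_terms:
            raise ParameterError("category_terms must be non-empty")


@dataclass(frozen=True)
class EvidenceRecord:
    """Externally screened literature evidence for one (drug, cluster) pair."""

    drug_id: str
    cluster_number: int
    pmids: tuple[str, ...] = ()
    confirmed: bool = False

    def __post_init__(self):
        if self.confirmed and not self.pmids:
            raise ParameterError(
                f"{self.drug_id}: confirmed evidence requires at least one PMID"
            )


def build_query(spec: QuerySpec) -> str:
    """Render a QuerySpec as the fixed Boolean PubMed query string.

    Pure and deterministic: the first category term is treated as the MeSH
    category name, subsequent terms as Title/Abstract synonyms; filter tags
    are OR-joined in one trailing group.
    """
    drug = f'"{spec.drug_term}"[MeSH Terms]'
    cat, *syns = spec.category_terms
    cat_clause = f'"{cat}"[MeSH Terms]'
    if syns:
        joined = " OR ".join([cat_clause] + [f'"{s}"[Title/Abstract]' for s in syns])
        cat_clause = f"({joined})"
    parts = [drug, cat_clause]
    if spec.filters:
        filt = " OR ".join(f"{f}[Filter]" for f in spec.filters)
        parts.append(f"({filt})" if len(spec.filters) > 1 else f"{spec.filters[0]}[Filter]")
    return " AND ".join(parts)


class QueryFetcher(Protocol):
    """Anything that can run a PubMed query and return PMIDs."""

    def search(self, query: str) -> list[str]: ...


@dataclass
class StaticFetcher:
    """Offline fetcher returning canned PMIDs per query (testing/replay)."""

    responses: dict[str, list[str]] = field(default_factory=dict)
    queries_seen: list[str] = field(default_factory=list)

    def search(self, query: str) -> list[str]:
        self.queries_seen.append(query)
        return list(self.responses.get(query, []))


class EntrezFetcher:
    """Live NCBI E-utilities esearch client (requires network + biopython).

    Identifies itself with *email* per NCBI courtesy rules and caps result
    counts at *retmax*.  Not used anywhere in the offline pipeline or tests.
    """

    def __init__(self, email: str, retmax: int = 20):
        self.email = email
        self.retmax = retmax

    def search(self, query: str) -> list[str]:
        from Bio import Entrez  # deferred: optional dependency

        Entrez.email = self.email
        with Entrez.esearch(db="pubmed", term=query, retmax=self.retmax) as handle:
            record = Entrez.read(handle)
        return list(record.get("IdList", []))


def apply_validation(
    hints: Sequence, evidence: Iterable[EvidenceRecord]
) -> tuple[list, dict[int, int]]:
    """Fold screened evidence back into hint statuses.

    Candidate hints with confirmed evidence become ``literature-confirmed``;
    everything else is untouched (statuses never demote).  Returns the
    updated hints and per-cluster confirmed counts for the accuracy summary.
    Evidence aimed at a db-matched hint is a consistency warning, not an
    error; evidence for an unknown (drug, cluster) pair raises.
    """
    by_key = {(h.drug_id, h.cluster_number): i for i, h in enumerate(hints)}
    updated = list(hints)
    confirmed_counts: dict[int, int] = {}
    for ev in evidence:
        key = (ev.drug_id, ev.cluster_number)
        if key not in by_key:
            raise ParameterError(
                f"evidence for unknown hint: drug {ev.drug_id!r} cluster {ev.cluster_number}"
            )
        idx = by_key[key]
        hint = updated[idx]
        if hint.status == "db-matched":
            logger.warning(
                "evidence supplied for db-matched drug %s (cluster %d); ignored",
                ev.drug_id,
                ev.cluster_number,
            )
            continue
        if ev.confirmed and hint.status == "candidate":
            updated[idx] = replace(hint, status="literature-confirmed")
    for h in updated:
        if h.status == "literature-confirmed":
            confirmed_counts[h.cluster_number] = confirmed_counts.get(h.cluster_number, 0) + 1
    return updated, confirmed_counts
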