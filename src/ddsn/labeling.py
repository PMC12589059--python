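"""ATC-histogram community labeling, candidate classification and accuracy.

Each surviving community is labeled with its *dominant* level-1 ATC code:
the code carried by the largest number of member drugs.  Drugs whose own
ATC codes all disagree with the label (or that have no codes) become
repositioning candidates — the guilt-by-association step.  Within the
label-matching drugs, level 2–4 histograms locate the community's dominant
mechanisms of action, whose level-4 codes map to biological targets.

Percentages are reported to one decimal, rounded half away from zero.  The
accuracy aggregation reconstructs integer drug counts from per-cluster
percentages (nearest integer) and weights by cluster size; the summary's
total accuracy is the sum of the two rounded weighted totals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .atc import LEVEL_LENGTHS, atc_prefix, validate_atc
from .errors import InconsistencyError, ParameterError
from .io_formats import DrugAnnotation

logger = logging.getLogger("ddsn.labeling")

__all__ = [
    "Histogram",
    "ClusterReport",
    "AccuracyRow",
    "AccuracySummary",
    "round1",
    "nearest_int",
    "level_histogram",
    "dominant_code",
    "classify_cluster",
    "accuracy_summary",
    "top_level4",
    "targets_for_codes",
    "build_cluster_report",
]


def round1(x: float) -> float:
    """Round to one decimal, half away from zero (Table-style presentation)."""
    import math

    return math.floor(abs(x) * 10.0 + 0.5) / 10.0 * (1 if x >= 0 else -1)


def nearest_int(x: float) -> int:
    """Nearest integer, half away from zero."""
    import math

    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class Histogram:
    """Per-cluster drug counts over distinct ATC prefixes at one level."""

    level: int
    counts: dict[str, int]

    def __post_init__(self):
        if self.level not in (1, 2, 3, 4):
            raise ParameterError(f"histogram level must be 1..4, got {self.level}")
        for k, v in self.counts.items():
            if v < 1:
                raise ParameterError(f"non-positive count {v} for {k!r}")

    @property
    def n_codes(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class AccuracyRow:
    cluster_number: int
    size: int
    pct_predominant: float
    pct_confirmed: float
    pct_accuracy: float
    label: str | None = None


@dataclass(frozen=True)
class AccuracySummary:
    """Per-cluster accuracy rows plus size-weighted totals (all %, 1 decimal)."""

    rows: tuple[AccuracyRow, ...]
    weighted_pct_predominant: float
    weighted_pct_confirmed: float
    total_accuracy: float
    pct_candidates: float


@dataclass(frozen=True)
class ClusterReport:
    """Everything the pipeline derives about one community."""

    cluster_number: int
    members: frozenset[str]
    label: str | None
    histograms: dict[int, Histogram]
    matched_drugs: frozenset[str]
    candidate_drugs: frozenset[str]
    pct_predominant: float
    top_level4: tuple[str, ...]
    targets: dict[str, frozenset[str]]

    @property
    def size(self) -> int:
        return len(self.members)


def level_histogram(
    cluster: Iterable[str],
    annotations: Mapping[str, DrugAnnotation],
    level: int,
    restrict_to_label: str | None = None,
) -> Histogram:
    """Count, for each ATC prefix at *level*, the drugs carrying it.

    Each drug contributes at most 1 per distinct prefix, regardless of how
    many of its codes share it.  With *restrict_to_label* (used for levels
    2–4), only codes under that level-1 letter are counted.  Drugs without
    annotations (or without codes) contribute nothing.
    """
    if level not in (1, 2, 3, 4):
        raise ParameterError(f"level must be 1..4, got {level}")
    counts: dict[str, int] = {}
    for drug in cluster:
        ann = annotations.get(drug)
        if ann is None:
            continue
        prefixes: set[str] = set()
        for code in ann.atc_codes:
            if len(code) < LEVEL_LENGTHS[level]:
                continue  # code does not carry this level
            if restrict_to_label is not None and atc_prefix(code, 1) != restrict_to_label:
                continue
            prefixes.add(atc_prefix(code, level))
        for p in prefixes:
            counts[p] = counts.get(p, 0) + 1
    return Histogram(level=level, counts=counts)


def dominant_code(histogram: Histogram) -> str:
    """The prefix with the maximal count; lexicographic on ties (logged)."""
    if not histogram.counts:
        raise ParameterError("cannot take the dominant code of an empty histogram")
    best = max(histogram.counts.values())
    tied = sorted(k for k, v in histogram.counts.items() if v == best)
    if len(tied) > 1:
        logger.warning("dominant-code tie between %s; choosing %s", tied, tied[0])
    return tied[0]


def classify_cluster(
    cluster: Iterable[str],
    annotations: Mapping[str, DrugAnnotation],
    label: str,
) -> tuple[frozenset[str], frozenset[str]]:
    """Split a cluster into (matched, candidates) against its level-1 label.

    A drug is *matched* if any of its ATC codes starts with the label
    letter; every other member — including drugs with no codes at all — is
    a repositioning candidate for the label's therapeutic property.
    """
    if not (len(label) == 1 and validate_atc(label)):
        raise ParameterError(f"label must be a level-1 ATC letter, got {label!r}")
    matched: set[str] = set()
    candidates: set[str] = set()
    for drug in cluster:
        ann = annotations.get(drug)
        codes = ann.atc_codes if ann is not None else frozenset()
        if any(atc_prefix(c, 1) == label for c in codes):
            matched.add(drug)
        else:
            candidates.add(drug)
    return frozenset(matched), frozenset(candidates)


def accuracy_summary(
    rows: Sequence[tuple[int, int, float, float]],
    labels: Mapping[int, str] | None = None,
) -> AccuracySummary:
    """Aggregate per-cluster (number, size, %predominant, %confirmed) rows.

    Counts are reconstructed as nearest integers of size·pct/100; per-row
    accuracy is 100·(n_pred + n_conf)/size to one decimal.  Weighted totals
    divide summed reconstructed counts by summed size; the total accuracy
    is the sum of the two rounded weighted percentages, and the candidate
    percentage is its complement to 100.
    """
    out_rows: list[AccuracyRow] = []
    tot_size = tot_pred = tot_conf = 0
    for num, size, pct_pred, pct_conf in rows:
        if size < 1:
            raise ParameterError(f"cluster {num}: size must be >= 1, got {size}")
        if not (0.0 <= pct_pred <= 100.0 and 0.0 <= pct_conf <= 100.0):
            raise ParameterError(f"cluster {num}: percentages must lie in [0, 100]")
        n_pred = nearest_int(size * pct_pred / 100.0)
        n_conf = nearest_int(size * pct_conf / 100.0)
        if n_pred + n_conf > size:
            raise InconsistencyError(
                f"cluster {num}: reconstructed counts {n_pred}+{n_conf} exceed size {size}"
            )
        out_rows.append(
            AccuracyRow(
                cluster_number=num,
                size=size,
                pct_predominant=round1(pct_pred),
                pct_confirmed=round1(pct_conf),
                pct_accuracy=round1(100.0 * (n_pred + n_conf) / size),
                label=labels.get(num) if labels else None,
            )
        )
        tot_size += size
        tot_pred += n_pred
        tot_conf += n_conf
    if tot_size == 0:
        raise ParameterError("no rows to aggregate")
    w_pred = round1(100.0 * tot_pred / tot_size)
    w_conf = round1(100.0 * tot_conf / tot_size)
    total = round1(w_pred + w_conf)
    return AccuracySummary(
        rows=tuple(out_rows),
        weighted_pct_predominant=w_pred,
        weighted_pct_confirmed=w_conf,
        total_accuracy=total,
        pct_candidates=round1(100.0 - total),
    )


def top_level4(
    cluster: Iterable[str],
    annotations: Mapping[str, DrugAnnotation],
    label: str,
    k: int = 3,
) -> tuple[str, ...]:
    """The k most frequent label-matching level-4 codes in the cluster.

    Codes are ranked by descending drug count, then lexicographically.
    Rank is *dense* over count levels: codes sharing a count share a rank,
    and every code ranked ≤ k is returned — ties never truncate, so the
    list may exceed k (logged when it does).
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    hist = level_histogram(cluster, annotations, level=4, restrict_to_label=label)
    if not hist.counts:
        return ()
    ranked = sorted(hist.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    kept_counts = sorted({cnt for _, cnt in ranked}, reverse=True)[:k]
    cutoff = kept_counts[-1]
    out = tuple(code for code, cnt in ranked if cnt >= cutoff)
    if len(out) > k:
        logger.info("top-%d level-4 ties expand the list to %d codes", k, len(out))
    return out


def targets_for_codes(
    codes: Sequence[str], atc_target_map: Mapping[str, frozenset[str]]
) -> dict[str, frozenset[str]]:
    """Restrict the level-4→targets map to *codes*; unknown codes map to ∅."""
    out: dict[str, frozenset[str]] = {}
    for code in codes:
        if code in atc_target_map:
            out[code] = frozenset(atc_target_map[code])
        else:
            logger.warning("no targets known for ATC level-4 code %s", code)
            out[code] = frozenset()
    return out


def build_cluster_report(
    cluster_number: int,
    members: Iterable[str],
    annotations: Mapping[str, DrugAnnotation],
    atc_target_map: Mapping[str, frozenset[str]],
    top_k: int = 3,
) -> ClusterReport:
    """Run the full labeling sequence for one community.

    Level-1 histogram → dominant label → matched/candidate split →
    restricted level 2–4 histograms → top-k level-4 codes → target map.
    A cluster whose members carry no ATC codes at all is reported
    unlabeled, with every member a candidate.
    """
    members = frozenset(members)
    h1 = level_histogram(members, annotations, level=1)
    if not h1.counts:
        logger.warning("cluster %d has no ATC codes; reported unlabeled", cluster_number)
        return ClusterReport(
            cluster_number=cluster_number,
            members=members,
            label=None,
            histograms={1: h1},
            matched_drugs=frozenset(),
            candidate_drugs=members,
            pct_predominant=0.0,
            top_level4=(),
            targets={},
        )
    label = dominant_code(h1)
    matched, candidates = classify_cluster(members, annotations, label)
    histograms = {1: h1}
    for level in (2, 3, 4):
        histograms[level] = level_histogram(
            members, annotations, level=level, restrict_to_label=label
        )
    top4 = top_level4(members, annotations, label, k=top_k)
    return ClusterReport(
        cluster_number=cluster_number,
        members=members,
        label=label,
        histograms=histograms,
        matched_drugs=matched,
        candidate_drugs=candidates,
        pct_predominant=round1(100.0 * len(matched) / len(members)),
        top_level4=top4,
        targets=targets_for_codes(top4, atc_target_map),
    )
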