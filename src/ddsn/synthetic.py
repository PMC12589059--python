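"""Planted-structure synthetic data: the four input tables plus ground truth.

The generator emulates the statistical structure the pipeline assumes in
its sources: groups of drugs that hit the same genes (and hence reach the
same diseases) and share a dominant ATC profile, plus a controlled
fraction of "mislabeled" drugs — planted repositioning candidates whose
ATC codes come from a *different* cluster's profile while their gene
interactions keep them embedded in their home cluster.

Construction, per cluster c with g genes and d diseases per gene:

* each gene owns d cluster-private diseases (clusters share no diseases);
* each drug links to each own-cluster gene with probability ``p_within``
  and to each foreign gene with probability ``p_between`` (independent
  Bernoulli draws), so a same-cluster drug pair shares each own gene with
  probability p_within² and the projected edge weight has closed-form
  expectation g·d·(p_within² + (n−1)·p_between²);
* every drug receives one or two ATC codes sampled from its cluster's
  level-4 profile — except the planted candidates, which sample from a
  foreign profile (their level-1 letter therefore disagrees with the home
  cluster's dominant letter);
* every level-4 code maps to one distinct synthetic target name.

Randomness comes exclusively from ``numpy.random.default_rng(seed)``
(PCG64, stable across platforms); identical configs give byte-identical
tables.  Mislabeled drugs are the lexicographically first
nearest-int(mislabel_fraction · size) ids of each cluster — deterministic
rather than binomially sampled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .atc import atc_prefix, validate_atc
from .errors import ConfigError
from .labeling import nearest_int

__all__ = [
    "DEFAULT_CLUSTER_LETTERS",
    "GeneratorConfig",
    "PlantedTruth",
    "default_level4_profile",
    "generate_dataset",
    "expected_weight_bounds",
    "cluster_roster_example",
]

#: Distinct dominant level-1 letters assigned to clusters, in order.
DEFAULT_CLUSTER_LETTERS: tuple[str, ...] = (
    "N", "B", "C", "L", "D", "M", "G", "H", "J", "A", "R", "S", "P", "V",
)


def default_level4_profile(letter: str) -> tuple[tuple[str, float], ...]:
    """Three level-4 codes under *letter* with 0.5/0.3/0.2 sampling weights."""
    return (
        (f"{letter}01AA", 0.5),
        (f"{letter}01AB", 0.3),
        (f"{letter}02BA", 0.2),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the planted-structure generator.

    Defaults mirror the study conditions at desk scale: 12 communities
    (the number surviving the filter in the reference analysis) of 16
    drugs each, a quarter of each community planted as repositioning
    candidates, and link probabilities separable enough for recovery
    (p_within 0.6 vs p_between 0.02).
    """

    n_clusters: int = 12
    drugs_per_cluster: int | Sequence[int] = 16
    genes_per_cluster: int = 8
    diseases_per_gene: int = 3
    p_within: float = 0.6
    p_between: float = 0.02
    mislabel_fraction: float = 0.25
    dominant_atc_per_cluster: tuple[str, ...] | None = None
    level4_profile: tuple[tuple[tuple[str, float], ...], ...] | None = None
    seed: int = 0

    def cluster_sizes(self) -> tuple[int, ...]:
        if isinstance(self.drugs_per_cluster, int):
            return (self.drugs_per_cluster,) * self.n_clusters
        return tuple(self.drugs_per_cluster)

    def letters(self) -> tuple[str, ...]:
        if self.dominant_atc_per_cluster is not None:
            return tuple(self.dominant_atc_per_cluster)
        if self.n_clusters > len(DEFAULT_CLUSTER_LETTERS):
            raise ConfigError(
                f"{self.n_clusters} clusters need explicit dominant_atc_per_cluster"
            )
        return DEFAULT_CLUSTER_LETTERS[: self.n_clusters]

    def profiles(self) -> tuple[tuple[tuple[str, float], ...], ...]:
        if self.level4_profile is not None:
            return tuple(self.level4_profile)
        return tuple(default_level4_profile(x) for x in self.letters())

    def validate(self) -> None:
        if self.n_clusters < 1:
            raise ConfigError("n_clusters must be >= 1")
        sizes = self.cluster_sizes()
        if len(sizes) != self.n_clusters or any(s < 1 for s in sizes):
            raise ConfigError("drugs_per_cluster must give a positive size per cluster")
        if self.genes_per_cluster < 1 or self.diseases_per_gene < 1:
            raise ConfigError("genes_per_cluster and diseases_per_gene must be >= 1")
        for name in ("p_within", "p_between", "mislabel_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.p_between >= self.p_within:
            raise ConfigError("p_between must be < p_within for recoverable structure")
        letters = self.letters()
        if len(set(letters)) != len(letters):
            raise ConfigError("dominant letters must be distinct across clusters")
        profiles = self.profiles()
        if len(profiles) != self.n_clusters:
            raise ConfigError("need one level-4 profile per cluster")
        for letter, profile in zip(letters, profiles):
            if not profile:
                raise ConfigError(f"empty level-4 profile for cluster letter {letter}")
            for code, weight in profile:
                if not (validate_atc(code) and len(code) == 5):
                    raise ConfigError(f"profile entry {code!r} is not a level-4 ATC code")
                if atc_prefix(code, 1) != letter:
                    raise ConfigError(
                        f"profile code {code} does not sit under dominant letter {letter}"
                    )
                if weight <= 0:
                    raise ConfigError(f"profile weight for {code} must be positive")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth emitted alongside the tables."""

    drug_cluster: dict[str, int]
    is_candidate: dict[str, bool]
    cluster_label: dict[int, str]
    cluster_profile: dict[int, tuple[tuple[str, float], ...]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "drug_id": d,
                "cluster": c,
                "is_planted_candidate": str(self.is_candidate[d]).lower(),
                "cluster_label": self.cluster_label[c],
            }
            for d, c in sorted(self.drug_cluster.items())
        ]
        return pd.DataFrame(rows, columns=["drug_id", "cluster", "is_planted_candidate", "cluster_label"])


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Emit (drug_gene, gene_disease, drug_atc, atc_target, truth).

    The four DataFrames use the default TSV dialect's column names, so they
    round-trip through :mod:`ddsn.io_formats` unchanged.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sizes = config.cluster_sizes()
    letters = config.letters()
    profiles = config.profiles()

    drugs: dict[int, list[str]] = {}
    genes: dict[int, list[str]] = {}
    gene_disease_rows: list[dict] = []
    for c in range(1, config.n_clusters + 1):
        drugs[c] = [f"DR{c:02d}_{i:03d}" for i in range(1, sizes[c - 1] + 1)]
        genes[c] = [f"G{c:02d}_{k:02d}" for k in range(1, config.genes_per_cluster + 1)]
        for gene in genes[c]:
            for m in range(1, config.diseases_per_gene + 1):
                disease = f"DIS_{gene}_{m}"
                gene_disease_rows.append(
                    {
                        "gene_symbol": gene,
                        "disease_id": disease,
                        "disease_name": f"synthetic disease {disease}",
                        "score": "",
                    }
                )

    drug_gene_rows: list[dict] = []
    for c in range(1, config.n_clusters + 1):
        for drug in drugs[c]:
            for c2 in range(1, config.n_clusters + 1):
                p = config.p_within if c2 == c else config.p_between
                links = rng.random(len(genes[c2])) < p
                for gene, hit in zip(genes[c2], links):
                    if hit:
                        drug_gene_rows.append(
                            {
                                "drug_id": drug,
                                "drug_name": f"drug {drug}",
                                "gene_symbol": gene,
                                "relation_type": "target",
                            }
                        )

    drug_cluster: dict[str, int] = {}
    is_candidate: dict[str, bool] = {}
    drug_atc_rows: list[dict] = []
    for c in range(1, config.n_clusters + 1):
        n_mis = nearest_int(config.mislabel_fraction * sizes[c - 1])
        planted = set(sorted(drugs[c])[:n_mis])
        for drug in drugs[c]:
            drug_cluster[drug] = c
            is_candidate[drug] = drug in planted
            if drug in planted:
                others = [c2 for c2 in range(1, config.n_clusters + 1) if c2 != c]
                source = int(rng.choice(others)) if others else c
            else:
                source = c
            profile = profiles[source - 1]
            codes = [entry[0] for entry in profile]
            weights = np.array([entry[1] for entry in profile], dtype=float)
            weights /= weights.sum()
            n_codes = 1 + int(rng.random() < 0.3)
            chosen = rng.choice(len(codes), size=min(n_codes, len(codes)), replace=False, p=weights)
            for idx in sorted(chosen):
                drug_atc_rows.append({"drug_id": drug, "atc_code": codes[idx]})

    atc_target_rows = [
        {"atc_code": code, "target": f"T_{code}"}
        for profile in profiles
        for code, _ in profile
    ]

    truth = PlantedTruth(
        drug_cluster=drug_cluster,
        is_candidate=is_candidate,
        cluster_label={c: letters[c - 1] for c in range(1, config.n_clusters + 1)},
        cluster_profile={c: profiles[c - 1] for c in range(1, config.n_clusters + 1)},
    )
    return (
        pd.DataFrame(drug_gene_rows, columns=["drug_id", "drug_name", "gene_symbol", "relation_type"]),
        pd.DataFrame(gene_disease_rows, columns=["gene_symbol", "disease_id", "disease_name", "score"]),
        pd.DataFrame(drug_atc_rows, columns=["drug_id", "atc_code"]),
        pd.DataFrame(atc_target_rows, columns=["atc_code", "target"]),
        truth,
    )


def cluster_roster_example():
    """A 34-community roster emulating the reference analysis' filter input.

    Communities 15–21 and 23–31 lie outside the main connected component;
    communities 13, 14, 22 and 32–34 sit inside it but have fewer than
    eight drugs.  Applying the standard exclusion rules (main component +
    minimum size 8) therefore leaves exactly the first twelve communities,
    whose sizes are those of the reference clustering.

    Returns ``(network, partition)`` ready for
    :func:`ddsn.communities.filter_communities`.
    """
    from .communities import CommunityPartition
    from .network import SimilarityNetwork

    sizes = {
        **dict(enumerate([105, 95, 88, 85, 51, 51, 51, 44, 31, 24, 15, 13], start=1)),
        13: 7, 14: 7, 22: 5, 32: 4, 33: 3, 34: 2,
        **{num: 10 for num in range(15, 22)},
        **{num: 9 for num in range(23, 32)},
    }
    in_main = set(range(1, 15)) | {22, 32, 33, 34}
    clusters: list[frozenset[str]] = []
    weights: dict[frozenset[str], int] = {}
    drugs: set[str] = set()
    for num in range(1, 35):
        members = [f"C{num:02d}_{i:03d}" for i in range(1, sizes[num] + 1)]
        drugs.update(members)
        clusters.append(frozenset(members))
        for a, b in zip(members, members[1:]):  # path keeps each cluster connected
            weights[frozenset((a, b))] = 1
        if num in in_main and num != 1:
            weights[frozenset((members[0], "C01_001"))] = 1
    network = SimilarityNetwork(drugs=frozenset(drugs), weights=weights)
    partition = CommunityPartition(clusters=tuple(clusters), modularity=0.0)
    return network, partition


def expected_weight_bounds(config: GeneratorConfig) -> tuple[float, float]:
    """Closed-form expected projected edge weights (within, between clusters).

    A disease is reachable from a drug iff the drug links the disease's
    owning gene, so the projected weight of a drug pair is d × (number of
    genes linked by both).  Under independent Bernoulli links:

    * same-cluster pair:  g·d·(p_within² + (n−1)·p_between²)
    * cross-cluster pair: g·d·(2·p_within·p_between + (n−2)·p_between²)
    """
    config.validate()
    g = config.genes_per_cluster
    d = config.diseases_per_gene
    n = config.n_clusters
    pw, pb = config.p_within, config.p_between
    within = g * d * (pw**2 + (n - 1) * pb**2)
    between = g * d * (2 * pw * pb + max(n - 2, 0) * pb**2) if n >= 2 else 0.0
    return within, between
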