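"""Representative-function coherence of clusters (AIC-MICA).

For a cluster of proteins and a coverage level f (say 0.6), the metric finds
a small set of ancestral GO terms such that at least ceil(f * n) of the
cluster's annotated proteins carry one of them, and reports the Average
Information Content (AIC) of that set.  A functionally coherent cluster can
be covered by few, specific (high-IC) terms; an incoherent one is only
covered by terms near the root, whose IC approaches zero.  Sweeping the
coverage grid 40%..90% exposes the coverage/specificity trade-off.

Term selection is greedy: at each step the term maximising
IC(t) x (number of newly covered annotated proteins) is added, ties broken
by larger new coverage and then lexicographic term id.  This reduces to the
single most-informative common ancestor when one informative term suffices,
and falls back to the root (always covering everyone) when nothing else can
meet the quota.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .mcl import Clustering
from .ontology import AnnotationCorpus, ICTable

logger = logging.getLogger(__name__)

#: default coverage grid: 10% increments from 40% to 90%
DEFAULT_COVERAGES = (0.40, 0.50, 0.60, 0.70, 0.80, 0.90)


def term_cover(
    cluster: Iterable[str], term: str, corpus: AnnotationCorpus
) -> frozenset[str]:
    """Cluster members whose propagated annotation contains ``term``."""
    return frozenset(
        p for p in cluster if term in corpus.propagated.get(p, frozenset())
    )


@dataclass(frozen=True)
class ClusterRepresentation:
    """The representative term set of one cluster at one coverage level."""

    cluster_id: str
    coverage: float
    selected_terms: tuple[str, ...]
    covered_proteins: frozenset[str]
    aic: float
    n_annotated: int
    quota: int


def representative_terms(
    cluster: Iterable[str],
    coverage: float,
    ic: ICTable,
    corpus: AnnotationCorpus,
    cluster_id: str = "",
    denominator: Literal["annotated", "all"] = "annotated",
    single_term: bool = False,
    coverage_weighted: bool = False,
) -> ClusterRepresentation | None:
    """Greedy representative-term selection for one cluster.

    Returns ``None`` when the cluster has no annotated protein (ineligible)
    or, under ``denominator="all"``, when the quota exceeds the annotated
    count (unreachable).

    Parameters
    ----------
    coverage:
        Required fraction in (0, 1]; the quota is ceil(coverage * n) with n
        the annotated-protein count (or the full cluster size under
        ``denominator="all"``).
    single_term:
        Restrict the selection to one term: the maximal-IC term whose cover
        alone meets the quota.  This variant is monotone non-increasing in
        coverage.
    coverage_weighted:
        Weight each term's IC by its newly covered protein count in the AIC
        instead of the default unweighted mean.
    """
    if not 0 < coverage <= 1:
        raise ValueError(f"coverage must lie in (0, 1], got {coverage}")
    members = frozenset(cluster)
    annotated = corpus.annotated_in(members)
    if not annotated:
        return None
    base = len(members) if denominator == "all" else len(annotated)
    quota = math.ceil(coverage * base)
    if quota > len(annotated):
        return None  # unreachable under denominator="all"

    # candidate terms: any term carried by an annotated member, with known IC
    candidates: set[str] = set()
    for p in annotated:
        candidates |= corpus.propagated[p]
    candidates &= set(ic.ic)
    covers = {t: term_cover(annotated, t, corpus) for t in candidates}

    if single_term:
        feasible = [t for t, c in covers.items() if len(c) >= quota]
        if not feasible:
            return None
        best = min(feasible, key=lambda t: (-ic.ic[t], t))
        return ClusterRepresentation(
            cluster_id=cluster_id, coverage=coverage, selected_terms=(best,),
            covered_proteins=covers[best], aic=ic.ic[best],
            n_annotated=len(annotated), quota=quota,
        )

    selected: list[str] = []
    covered: set[str] = set()
    new_counts: list[int] = []
    remaining = set(candidates)
    while len(covered) < quota and remaining:
        def key(t: str) -> tuple[float, int, str]:
            new = len(covers[t] - covered)
            return (-ic.ic[t] * new, -new, t)

        best = min(remaining, key=key)
        gain = covers[best] - covered
        if not gain:
            break  # nothing can extend coverage (should not happen: root covers all)
        selected.append(best)
        new_counts.append(len(gain))
        covered |= gain
        remaining.discard(best)

    if len(covered) < quota:
        logger.warning(
            "cluster %s: coverage quota %d not reachable (covered %d)",
            cluster_id, quota, len(covered),
        )
    ics = [ic.ic[t] for t in selected]
    if coverage_weighted:
        aic = float(np.average(ics, weights=new_counts))
    else:
        aic = float(np.mean(ics))
    return ClusterRepresentation(
        cluster_id=cluster_id, coverage=coverage,
        selected_terms=tuple(selected), covered_proteins=frozenset(covered),
        aic=aic, n_annotated=len(annotated), quota=quota,
    )


@dataclass(frozen=True)
class CoverageSummary:
    """Cross-cluster AIC statistics at one coverage level."""

    coverage: float
    mean_aic: float
    q25: float
    q75: float
    n_clusters: int


@dataclass(frozen=True)
class ProfileSummary:
    """AIC-MICA profile of a clustering over a coverage grid."""

    levels: tuple[CoverageSummary, ...]
    n_eligible_clusters: int
    n_proteins_in_eligible: int
    fraction_proteins_in_eligible: float
    per_cluster: dict[float, tuple[ClusterRepresentation, ...]]


def aic_mica_profile(
    clustering: Clustering,
    ic: ICTable,
    corpus: AnnotationCorpus,
    coverages: Sequence[float] = DEFAULT_COVERAGES,
    min_cluster_size: int = 2,
    denominator: Literal["annotated", "all"] = "annotated",
    size_weighted: bool = False,
) -> ProfileSummary:
    """Summarise AIC-MICA across the eligible clusters of a partition.

    Eligible clusters have at least ``min_cluster_size`` members and at least
    one annotated protein.  Per level, the mean and the 25th/75th percentiles
    of the per-cluster AIC are reported (unweighted across clusters by
    default; ``size_weighted`` weights the mean by cluster size).
    """
    eligible = [
        (f"C{i}", c) for i, c in enumerate(clustering)
        if len(c) >= min_cluster_size and corpus.annotated_in(c)
    ]
    total_nodes = len(clustering.nodes)
    n_in_eligible = sum(len(c) for _, c in eligible)
    per_cluster: dict[float, tuple[ClusterRepresentation, ...]] = {}
    levels: list[CoverageSummary] = []
    if not eligible:
        logger.warning("no eligible clusters; empty AIC-MICA profile")
    for cov in coverages:
        reps = [
            r for _, (cid, c) in enumerate(eligible)
            if (r := representative_terms(
                c, cov, ic, corpus, cluster_id=cid, denominator=denominator
            )) is not None
        ]
        per_cluster[cov] = tuple(reps)
        if reps:
            aics = np.array([r.aic for r in reps])
            if size_weighted:
                weights = np.array([len(r.covered_proteins) + 0.0 for r in reps])
                mean = float(np.average(aics, weights=weights))
            else:
                mean = float(aics.mean())
            levels.append(CoverageSummary(
                coverage=cov, mean_aic=mean,
                q25=float(np.percentile(aics, 25)),
                q75=float(np.percentile(aics, 75)),
                n_clusters=len(reps),
            ))
    return ProfileSummary(
        levels=tuple(levels),
        n_eligible_clusters=len(eligible),
        n_proteins_in_eligible=n_in_eligible,
        fraction_proteins_in_eligible=(
            n_in_eligible / total_nodes if total_nodes else 0.0
        ),
        per_cluster=per_cluster,
    )
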