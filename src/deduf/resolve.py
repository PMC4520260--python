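"""Per-method hit filtering and decision-tree resolution.

After filtering, each method's surviving hits for one query are clustered
into domain-region groups (single linkage on 60 % mutual-overlap of either
region) and each group is collapsed to a single superfamily verdict:

* E-value methods (enriched-database HMM searches, library hmmscan,
  HMM–HMM search) use the hit-count cascade: unanimous superfamily ->
  best hit; one fold -> modal superfamily; several folds -> modal
  superfamily only with a hit-count lead strictly greater than ten.
* The profile–profile Z-score method replaces the count margin by
  best-Z margins: >= 4 across folds within one class, >= 6 across classes.
* Threading simply takes the modal superfamily.

Frequency ties are conservatively unresolved.  Indirect family ->
superfamily mappings are derived one hop through qualifying
family–family links (Z >= 9, both coverages >= 80 %).
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .config import DEFAULT_THRESHOLDS, Thresholds
from .search_io import SCORE_KIND, DomainHit, FamilyLink, Method

__all__ = [
    "Status",
    "MethodAssignment",
    "query_coverage",
    "passes_filter",
    "filter_hits",
    "group_regions",
    "resolve_evalue_tree",
    "resolve_zscore_tree",
    "resolve_frequency",
    "resolve_group",
    "resolve_method",
    "derive_indirect",
]


class Status(str, enum.Enum):
    ASSIGNED = "assigned"
    UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class MethodAssignment:
    """One method's resolved verdict for a query domain region."""

    query_id: str
    method: Method
    region: tuple[int, int]
    superfamily_id: Optional[str]
    n_support: int
    best_score: Optional[float]
    status: Status
    provenance: tuple[str, ...] = ()
    origin: str = "direct"  # "direct" from hits, "indirect" via family links

    def __post_init__(self) -> None:
        if self.status is Status.ASSIGNED:
            if self.superfamily_id is None or self.n_support < 1:
                raise ValueError(
                    "assigned verdict requires a superfamily and >= 1 supporting hit"
                )


def query_coverage(hit: DomainHit) -> float:
    """Fraction of the query spanned by the hit region (1-based inclusive)."""
    start, end = hit.region
    return (end - start + 1) / hit.query_length


def passes_filter(hit: DomainHit, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> bool:
    """Apply the method's acceptance criteria; boundary values pass.

    E-value methods require E <= 0.001; the enriched-database search
    additionally demands >= 60 % query coverage.  The Z-score method
    requires Z >= 7.5 and >= 60 % coverage.  Threading hits must satisfy
    P <= 1e-5 *and* carry the CERTAIN confidence tag.
    """
    method = hit.method
    if method in (Method.NRICHD, Method.SUPERFAMILY_DB, Method.HHSEARCH):
        if hit.evalue is None:
            raise ValueError(f"{method} hit lacks an E-value")
        ok = hit.evalue <= thresholds.evalue_max
        if method is Method.NRICHD:
            ok = ok and query_coverage(hit) >= thresholds.coverage_min
        return ok
    if method is Method.SUPFAM_PLUS:
        if hit.zscore is None:
            raise ValueError("profile-profile hit lacks a Z-score")
        return (
            hit.zscore >= thresholds.zscore_min
            and query_coverage(hit) >= thresholds.coverage_min
        )
    if method is Method.PDOMTHREADER:
        if hit.pvalue is None:
            raise ValueError("threading hit lacks a P-value")
        return hit.pvalue <= thresholds.pvalue_max and hit.source_pass == "CERTAIN"
    raise ValueError(f"unknown method {method}")  # pragma: no cover


def filter_hits(
    hits: Iterable[DomainHit], thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> list[DomainHit]:
    return [h for h in hits if passes_filter(h, thresholds)]


def _overlap_len(r1: tuple[int, int], r2: tuple[int, int]) -> int:
    return min(r1[1], r2[1]) - max(r1[0], r2[0]) + 1


def _regions_linked(
    r1: tuple[int, int], r2: tuple[int, int], frac: float
) -> bool:
    ov = _overlap_len(r1, r2)
    if ov <= 0:
        return False
    len1 = r1[1] - r1[0] + 1
    len2 = r2[1] - r2[0] + 1
    return ov >= frac * len1 or ov >= frac * len2


def group_regions(
    hits: Sequence[DomainHit], overlap_frac: float = 0.60
) -> list[list[DomainHit]]:
    """Single-linkage clustering of hits into domain-region groups.

    Two hits link when their regions overlap by at least ``overlap_frac``
    of the length of *either* region; chained overlaps merge
    transitively.  Groups are returned ordered by envelope start, hits
    within a group in input order.
    """
    n = len(hits)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _regions_linked(hits[i].region, hits[j].region, overlap_frac):
                parent[find(i)] = find(j)

    groups: dict[int, list[DomainHit]] = {}
    for i, hit in enumerate(hits):
        groups.setdefault(find(i), []).append(hit)
    return sorted(groups.values(), key=lambda g: min(h.region[0] for h in g))


def _envelope(hits: Sequence[DomainHit]) -> tuple[int, int]:
    return (min(h.region[0] for h in hits), max(h.region[1] for h in hits))


def _check_group(group: Sequence[DomainHit], kind: str) -> None:
    if not group:
        raise ValueError("cannot resolve an empty hit group")
    if len({(h.query_id, h.method) for h in group}) != 1:
        raise ValueError("a resolution group must share one query and one method")
    if SCORE_KIND[group[0].method] != kind:
        raise ValueError(
            f"{group[0].method} hits are {SCORE_KIND[group[0].method]}-scored, "
            f"not {kind}-scored"
        )


def _unresolved(group: Sequence[DomainHit]) -> MethodAssignment:
    return MethodAssignment(
        query_id=group[0].query_id,
        method=group[0].method,
        region=_envelope(group),
        superfamily_id=None,
        n_support=0,
        best_score=None,
        status=Status.UNRESOLVED,
        provenance=tuple(sorted(h.hit_id for h in group)),
    )


def _assignment(
    group: Sequence[DomainHit], superfamily_id: str, representative: DomainHit
) -> MethodAssignment:
    supporting = [h for h in group if h.lineage.superfamily_id == superfamily_id]
    return MethodAssignment(
        query_id=group[0].query_id,
        method=group[0].method,
        region=_envelope(supporting),
        superfamily_id=superfamily_id,
        n_support=len(supporting),
        best_score=representative.score,
        status=Status.ASSIGNED,
        provenance=tuple(sorted(h.hit_id for h in supporting)),
    )


def _best_by_evalue(hits: Sequence[DomainHit]) -> DomainHit:
    # lowest E-value, ties to larger coverage, then lexicographic hit id
    return min(hits, key=lambda h: (h.evalue, -query_coverage(h), h.hit_id))


def _best_by_zscore(hits: Sequence[DomainHit]) -> DomainHit:
    # highest Z, ties to larger coverage, then lexicographic hit id
    return min(hits, key=lambda h: (-h.zscore, -query_coverage(h), h.hit_id))


def _best_by_pvalue(hits: Sequence[DomainHit]) -> DomainHit:
    return min(hits, key=lambda h: (h.pvalue, -query_coverage(h), h.hit_id))


def _modal_superfamily(group: Sequence[DomainHit]) -> Optional[str]:
    """Most frequent superfamily, or None on a tie for the mode."""
    counts = Counter(h.lineage.superfamily_id for h in group)
    ranked = counts.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return None
    return ranked[0][0]


def resolve_evalue_tree(
    group: Sequence[DomainHit], thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> MethodAssignment:
    """Hit-count decision cascade for E-value-scored region groups.

    (i) a single superfamily -> its best-E hit; (ii) several
    superfamilies within one fold -> the modal superfamily; (iii) several
    folds (or classes) -> the modal superfamily only if its hit count
    leads the runner-up by strictly more than the count margin.
    """
    _check_group(group, "evalue")
    superfamilies = {h.lineage.superfamily_id for h in group}
    if len(superfamilies) == 1:
        best = _best_by_evalue(group)
        return _assignment(group, best.lineage.superfamily_id, best)
    folds = {h.lineage.fold_id for h in group}
    if len(folds) == 1:
        winner = _modal_superfamily(group)
        if winner is None:
            return _unresolved(group)
        supporting = [h for h in group if h.lineage.superfamily_id == winner]
        return _assignment(group, winner, _best_by_evalue(supporting))
    counts = Counter(h.lineage.superfamily_id for h in group).most_common()
    if len(counts) > 1 and counts[0][1] - counts[1][1] > thresholds.evalue_count_margin:
        winner = counts[0][0]
        supporting = [h for h in group if h.lineage.superfamily_id == winner]
        return _assignment(group, winner, _best_by_evalue(supporting))
    return _unresolved(group)


def resolve_zscore_tree(
    group: Sequence[DomainHit], thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> MethodAssignment:
    """Z-score decision cascade for profile–profile region groups.

    A single superfamily takes its highest-Z hit; several superfamilies
    within one fold take the modal superfamily; across folds the compared
    quantities are each superfamily's *best* Z, with an inclusive margin
    of >= 4 within a class and >= 6 across classes.
    """
    _check_group(group, "zscore")
    superfamilies = {h.lineage.superfamily_id for h in group}
    if len(superfamilies) == 1:
        best = _best_by_zscore(group)
        return _assignment(group, best.lineage.superfamily_id, best)
    folds = {h.lineage.fold_id for h in group}
    if len(folds) == 1:
        winner = _modal_superfamily(group)
        if winner is None:
            return _unresolved(group)
        supporting = [h for h in group if h.lineage.superfamily_id == winner]
        return _assignment(group, winner, _best_by_zscore(supporting))
    classes = {h.lineage.class_id for h in group}
    margin = (
        thresholds.zscore_fold_margin
        if len(classes) == 1
        else thresholds.zscore_class_margin
    )
    best_z: dict[str, float] = {}
    for hit in group:
        sf = hit.lineage.superfamily_id
        best_z[sf] = max(best_z.get(sf, float("-inf")), hit.zscore)
    ranked = sorted(best_z.items(), key=lambda kv: (-kv[1], kv[0]))
    if ranked[0][1] - ranked[1][1] >= margin:
        winner = ranked[0][0]
        supporting = [h for h in group if h.lineage.superfamily_id == winner]
        return _assignment(group, winner, _best_by_zscore(supporting))
    return _unresolved(group)


def resolve_frequency(group: Sequence[DomainHit]) -> MethodAssignment:
    """Modal-superfamily rule for threading region groups (ties unresolved)."""
    _check_group(group, "pvalue")
    winner = _modal_superfamily(group)
    if winner is None:
        return _unresolved(group)
    supporting = [h for h in group if h.lineage.superfamily_id == winner]
    return _assignment(group, winner, _best_by_pvalue(supporting))


_RESOLVERS = {
    "evalue": resolve_evalue_tree,
    "zscore": resolve_zscore_tree,
    "pvalue": lambda group, thresholds: resolve_frequency(group),
}


def resolve_group(
    group: Sequence[DomainHit], thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> MethodAssignment:
    """Dispatch a region group to its method's decision tree."""
    if not group:
        raise ValueError("cannot resolve an empty hit group")
    return _RESOLVERS[SCORE_KIND[group[0].method]](group, thresholds)


def resolve_method(
    hits: Iterable[DomainHit], thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> list[MethodAssignment]:
    """Filter, region-group and resolve one method's pooled hits.

    Hits may span multiple query families; returns one assignment
    (possibly unresolved) per (query, region group), ordered by query id
    then region.
    """
    by_query: dict[str, list[DomainHit]] = {}
    method: Optional[Method] = None
    for hit in hits:
        if method is None:
            method = hit.method
        elif hit.method is not method:
            raise ValueError("resolve_method expects hits from a single method")
        by_query.setdefault(hit.query_id, []).append(hit)
    assignments: list[MethodAssignment] = []
    for query_id in sorted(by_query):
        surviving = filter_hits(by_query[query_id], thresholds)
        for group in group_regions(surviving, thresholds.overlap_frac):
            assignments.append(resolve_group(group, thresholds))
    return assignments


def derive_indirect(
    direct: Mapping[str, str],
    links: Iterable[FamilyLink],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> dict[str, str]:
    """One-hop indirect family -> superfamily mappings via family links.

    A link qualifies at Z >= 9 with both coverages >= 80 %.  A family
    without a direct mapping inherits a superfamily when all its
    qualifying links into directly-mapped families agree on exactly one
    superfamily; conflicting neighbours yield no assignment.  No
    transitive chaining.
    """
    candidates: dict[str, set[str]] = {}
    for link in links:
        if link.zscore < thresholds.link_zscore_min:
            continue
        if (
            link.coverage_a < thresholds.link_coverage_min
            or link.coverage_b < thresholds.link_coverage_min
        ):
            continue
        for fam, other in (
            (link.family_a, link.family_b),
            (link.family_b, link.family_a),
        ):
            if fam in direct or other not in direct:
                continue
            candidates.setdefault(fam, set()).add(direct[other])
    return {
        fam: next(iter(sfs)) for fam, sfs in sorted(candidates.items()) if len(sfs) == 1
    }
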