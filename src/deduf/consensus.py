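"""Cross-method consensus: merge per-method verdicts and tier confidence.

Per query family, assigned verdicts are clustered into domain-region
groups (single linkage on the 60 %-of-either-region overlap rule).  Within
a group, all methods must name the same superfamily; the single tolerated
exception is four methods against one, where the majority superfamily is
kept and the dissenter recorded.  Any other disagreement excludes the
region as ambiguous (with a flag for conflicts confined to one fold, which
still constrain the likely topology).  Confidence tiers follow method
count: >= 4 high, 2–3 medium, 1 low.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .resolve import MethodAssignment, Status, _regions_linked
from .scop import fold_of_superfamily
from .search_io import Method

__all__ = [
    "Confidence",
    "ConsensusRecord",
    "ExclusionRecord",
    "RunSummary",
    "regions_overlap",
    "tier",
    "combine",
    "combine_all",
    "tally",
]


class Confidence(str, enum.Enum):
    HIGH = "high"
    MEDIUM = "medium"
    LOW = "low"


def tier(n_methods: int) -> Confidence:
    """Confidence from the number of agreeing methods (1–5)."""
    if not 1 <= n_methods <= 5:
        raise ValueError(f"n_methods must be 1..5, got {n_methods}")
    if n_methods >= 4:
        return Confidence.HIGH
    if n_methods >= 2:
        return Confidence.MEDIUM
    return Confidence.LOW


def regions_overlap(
    r1: tuple[int, int], r2: tuple[int, int], overlap_frac: float = 0.60
) -> bool:
    """True when the overlap covers >= 60 % of the length of either region."""
    return _regions_linked(r1, r2, overlap_frac)


@dataclass(frozen=True)
class ConsensusRecord:
    """Merged cross-method superfamily verdict for one query domain region."""

    query_id: str
    region: tuple[int, int]
    superfamily_id: str
    methods: tuple[Method, ...]
    n_methods: int
    confidence: Confidence
    outvoted_method: Optional[Method] = None
    # for the 4-vs-1 case: did the dissenting superfamily share the fold?
    fold_consistent_conflict: bool = False

    def __post_init__(self) -> None:
        if self.n_methods != len(self.methods):
            raise ValueError("n_methods must equal the number of agreeing methods")
        if tier(self.n_methods) is not self.confidence:
            raise ValueError("confidence tier inconsistent with method count")


@dataclass(frozen=True)
class ExclusionRecord:
    """A region dropped as ambiguous, with the conflicting superfamilies."""

    query_id: str
    region: tuple[int, int]
    superfamilies_in_conflict: tuple[str, ...]
    same_fold: bool
    methods: tuple[Method, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.superfamilies_in_conflict)) < 2:
            raise ValueError("an exclusion requires >= 2 distinct superfamilies")


def _group_assignments(
    assignments: Sequence[MethodAssignment], overlap_frac: float
) -> list[list[MethodAssignment]]:
    n = len(assignments)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _regions_linked(
                assignments[i].region, assignments[j].region, overlap_frac
            ):
                parent[find(i)] = find(j)
    groups: dict[int, list[MethodAssignment]] = {}
    for i, a in enumerate(assignments):
        groups.setdefault(find(i), []).append(a)
    return sorted(groups.values(), key=lambda g: min(a.region[0] for a in g))


def combine(
    assignments: Sequence[MethodAssignment], overlap_frac: float = 0.60
) -> tuple[list[ConsensusRecord], list[ExclusionRecord]]:
    """Merge one query family's assigned verdicts across methods.

    Non-overlapping regions yield independent records.  Within an
    overlapping group: unanimity keeps the region; exactly four agreeing
    methods against one dissenter keeps the majority superfamily with the
    dissenter noted; every other disagreement excludes the region.
    Two verdicts from the same method in one group indicate an upstream
    resolution failure and raise.
    """
    assignments = [a for a in assignments if a.status is Status.ASSIGNED]
    if not assignments:
        return [], []
    if len({a.query_id for a in assignments}) != 1:
        raise ValueError("combine() handles one query family at a time")
    records: list[ConsensusRecord] = []
    exclusions: list[ExclusionRecord] = []
    for group in _group_assignments(assignments, overlap_frac):
        methods = [a.method for a in group]
        if len(set(methods)) != len(methods):
            dup = [m for m, c in Counter(methods).items() if c > 1]
            raise ValueError(
                f"{group[0].query_id}: method {dup[0].value} contributed two verdicts "
                "to one region group"
            )
        envelope = (
            min(a.region[0] for a in group),
            max(a.region[1] for a in group),
        )
        counts = Counter(a.superfamily_id for a in group).most_common()
        if len(counts) == 1:
            sf = counts[0][0]
            agreeing = tuple(sorted((a.method for a in group), key=lambda m: m.value))
            records.append(
                ConsensusRecord(
                    query_id=group[0].query_id,
                    region=envelope,
                    superfamily_id=sf,
                    methods=agreeing,
                    n_methods=len(agreeing),
                    confidence=tier(len(agreeing)),
                )
            )
        elif len(group) == 5 and counts[0][1] == 4:
            sf = counts[0][0]
            majority = [a for a in group if a.superfamily_id == sf]
            dissenter = next(a for a in group if a.superfamily_id != sf)
            agreeing = tuple(sorted((a.method for a in majority), key=lambda m: m.value))
            records.append(
                ConsensusRecord(
                    query_id=group[0].query_id,
                    region=envelope,
                    superfamily_id=sf,
                    methods=agreeing,
                    n_methods=4,
                    confidence=Confidence.HIGH,
                    outvoted_method=dissenter.method,
                    fold_consistent_conflict=(
                        fold_of_superfamily(dissenter.superfamily_id)
                        == fold_of_superfamily(sf)
                    ),
                )
            )
        else:
            sfs = tuple(sorted({a.superfamily_id for a in group}))
            folds = {fold_of_superfamily(sf) for sf in sfs}
            exclusions.append(
                ExclusionRecord(
                    query_id=group[0].query_id,
                    region=envelope,
                    superfamilies_in_conflict=sfs,
                    same_fold=len(folds) == 1,
                    methods=tuple(sorted((a.method for a in group), key=lambda m: m.value)),
                )
            )
    return records, exclusions


def combine_all(
    assignments: Iterable[MethodAssignment], overlap_frac: float = 0.60
) -> tuple[list[ConsensusRecord], list[ExclusionRecord]]:
    """Run :func:`combine` per query family over a mixed assignment list."""
    by_query: dict[str, list[MethodAssignment]] = {}
    for a in assignments:
        by_query.setdefault(a.query_id, []).append(a)
    records: list[ConsensusRecord] = []
    exclusions: list[ExclusionRecord] = []
    for query_id in sorted(by_query):
        recs, excl = combine(by_query[query_id], overlap_frac)
        records.extend(recs)
        exclusions.extend(excl)
    return records, exclusions


@dataclass
class RunSummary:
    """Bookkeeping over one consensus run."""

    total_families: int
    families_by_tier: dict[str, int]
    records_by_n_methods: dict[int, int]
    per_method: dict[str, dict[str, int]]
    unique_to_method: dict[str, int]
    n_records: int
    n_exclusion_regions: int
    n_exclusion_families: int
    n_same_fold_exclusions: int
    distinct_superfamilies: int
    distinct_folds: int
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def tally(
    records: Sequence[ConsensusRecord], exclusions: Sequence[ExclusionRecord]
) -> RunSummary:
    """Aggregate counts: totals, tiers, per-method retention, uniqueness.

    A family's tier is that of its best (largest method-count) record.
    Per method: retained = appearances among agreeing record methods;
    discarded = appearances in exclusions or as the outvoted dissenter;
    assigned-pre-consensus is their sum.
    """
    best_n: dict[str, int] = {}
    for rec in records:
        best_n[rec.query_id] = max(best_n.get(rec.query_id, 0), rec.n_methods)
    families_by_tier = Counter(tier(n).value for n in best_n.values())

    retained: Counter = Counter()
    discarded: Counter = Counter()
    unique: Counter = Counter()
    for rec in records:
        for m in rec.methods:
            retained[m.value] += 1
        if rec.outvoted_method is not None:
            discarded[rec.outvoted_method.value] += 1
        if rec.n_methods == 1:
            unique[rec.methods[0].value] += 1
    for excl in exclusions:
        for m in excl.methods:
            discarded[m.value] += 1

    per_method = {
        m.value: {
            "n_assigned_pre_consensus": retained[m.value] + discarded[m.value],
            "n_discarded_as_ambiguous": discarded[m.value],
            "n_retained": retained[m.value],
        }
        for m in Method
    }
    superfamilies = {rec.superfamily_id for rec in records}
    return RunSummary(
        total_families=len(best_n),
        families_by_tier={
            t.value: families_by_tier.get(t.value, 0) for t in Confidence
        },
        records_by_n_methods=dict(
            sorted(Counter(rec.n_methods for rec in records).items())
        ),
        per_method=per_method,
        unique_to_method={m.value: unique.get(m.value, 0) for m in Method},
        n_records=len(records),
        n_exclusion_regions=len(exclusions),
        n_exclusion_families=len({e.query_id for e in exclusions}),
        n_same_fold_exclusions=sum(1 for e in exclusions if e.same_fold),
        distinct_superfamilies=len(superfamilies),
        distinct_folds=len({fold_of_superfamily(sf) for sf in superfamilies}),
    )
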