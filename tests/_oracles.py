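"""Independent brute-force interpreters of the decision rules.

These deliberately avoid the package's cascade implementation: each rule
is evaluated by naive enumeration over the hit multiset (explicit loops,
list.count, no Counter/most_common), so agreement between the two is a
meaningful cross-check rather than a tautology.
"""

from __future__ import annotations

from typing import Optional, Sequence

from deduf.search_io import DomainHit


def _coverage(h: DomainHit) -> float:
    return (h.region[1] - h.region[0] + 1) / h.query_length


def _distinct(values: Sequence[str]) -> list[str]:
    out: list[str] = []
    for v in values:
        if v not in out:
            out.append(v)
    return out


def _mode_by_count(group: Sequence[DomainHit]) -> Optional[str]:
    """Superfamily with strictly the most hits, None on any tie for the top."""
    sfs = [h.lineage.superfamily_id for h in group]
    best_sf, best_n = None, -1
    tied = False
    for sf in sorted(_distinct(sfs)):
        n = sfs.count(sf)
        if n > best_n:
            best_sf, best_n, tied = sf, n, False
        elif n == best_n:
            tied = True
    return None if tied else best_sf


def oracle_evalue_tree(group: Sequence[DomainHit], count_margin: int = 10) -> Optional[str]:
    """Expected superfamily from the hit-count cascade, None if unresolved."""
    sfs = [h.lineage.superfamily_id for h in group]
    folds = [h.lineage.fold_id for h in group]
    if len(_distinct(sfs)) == 1:
        return sfs[0]
    if len(_distinct(folds)) == 1:
        return _mode_by_count(group)
    counts = sorted((sfs.count(sf) for sf in _distinct(sfs)), reverse=True)
    if counts[0] - counts[1] > count_margin:
        return _mode_by_count(group)
    return None


def oracle_zscore_tree(
    group: Sequence[DomainHit], fold_margin: float = 4.0, class_margin: float = 6.0
) -> Optional[str]:
    """Expected superfamily from the Z-score cascade, None if unresolved."""
    sfs = [h.lineage.superfamily_id for h in group]
    folds = [h.lineage.fold_id for h in group]
    classes = [h.lineage.class_id for h in group]
    if len(_distinct(sfs)) == 1:
        return sfs[0]
    if len(_distinct(folds)) == 1:
        return _mode_by_count(group)
    margin = fold_margin if len(_distinct(classes)) == 1 else class_margin
    best_per_sf = {}
    for h in group:
        sf = h.lineage.superfamily_id
        if sf not in best_per_sf or h.zscore > best_per_sf[sf]:
            best_per_sf[sf] = h.zscore
    ordered = sorted(best_per_sf.items(), key=lambda kv: (-kv[1], kv[0]))
    if ordered[0][1] - ordered[1][1] >= margin:
        return ordered[0][0]
    return None


def oracle_frequency(group: Sequence[DomainHit]) -> Optional[str]:
    """Expected superfamily from the plain modal rule, None on a tie."""
    if len(_distinct([h.lineage.superfamily_id for h in group])) == 1:
        return group[0].lineage.superfamily_id
    return _mode_by_count(group)


def oracle_representative_evalue(hits: Sequence[DomainHit]) -> DomainHit:
    """Best hit by (lowest E, largest coverage, hit id), by full scan."""
    best = hits[0]
    for h in hits[1:]:
        key_h = (h.evalue, -_coverage(h), h.hit_id)
        key_b = (best.evalue, -_coverage(best), best.hit_id)
        if key_h < key_b:
            best = h
    return best


def iter_tree_cases(method_kind: str, max_hits: int = 15, seed: int = 0):
    """Systematic hit-group sweep for one decision tree.

    Covers every lineage-relation pattern across up to 3 superfamilies
    and every hit-count composition up to ``max_hits`` hits; Z-score
    groups additionally get margin-boundary score patterns (lead exactly
    at, and just below, the applicable margin).  Yields hit groups.
    """
    import itertools

    import numpy as np

    from deduf.search_io import Method

    from _factories import make_hit

    method = {
        "evalue": Method.NRICHD,
        "zscore": Method.SUPFAM_PLUS,
        "pvalue": Method.PDOMTHREADER,
    }[method_kind]
    scenarios = [
        ("a.1.1.1",),
        ("a.1.1.1", "a.1.2.1"),  # same fold
        ("a.1.1.1", "a.2.1.1"),  # same class, different fold
        ("a.1.1.1", "b.1.1.1"),  # different class
        ("a.1.1.1", "a.1.2.1", "a.2.1.1"),
        ("a.1.1.1", "a.2.1.1", "a.3.1.1"),
        ("a.1.1.1", "a.2.1.1", "b.1.1.1"),
        ("a.1.1.1", "a.1.2.1", "b.1.1.1"),
    ]
    rng = np.random.default_rng(seed)

    def build(sccs_counts, scores):
        group = []
        i = 0
        for sccs, count in sccs_counts:
            for _ in range(count):
                group.append(
                    make_hit(
                        sccs,
                        method,
                        score=float(scores[i]),
                        hit_id=f"h{i:03d}",
                    )
                )
                i += 1
        return group

    for sccs_set in scenarios:
        k = len(sccs_set)
        for counts in itertools.product(range(1, max_hits + 1), repeat=k):
            if sum(counts) > max_hits:
                continue
            n = sum(counts)
            pairs = list(zip(sccs_set, counts))
            if method_kind == "evalue":
                scores = 10.0 ** -rng.uniform(4, 30, size=n)
            elif method_kind == "pvalue":
                scores = 10.0 ** -rng.uniform(5.5, 12, size=n)
            else:
                scores = rng.uniform(7.5, 25, size=n)
            yield build(pairs, scores)
            if method_kind == "zscore" and k > 1:
                classes = {s.split(".")[0] for s in sccs_set}
                margin = 4.0 if len(classes) == 1 else 6.0
                for lead in (margin, margin - 0.5):
                    # first superfamily's best Z leads the rest by `lead`
                    scores = []
                    for j, (sccs, count) in enumerate(pairs):
                        top = 20.0 if j == 0 else 20.0 - lead - 0.5 * (j - 1)
                        scores.extend([top - 0.1 * t for t in range(count)])
                    yield build(pairs, scores)


def oracle_consensus_pattern(superfamilies: Sequence[str]) -> str:
    """Outcome for one region group's per-method superfamilies.

    Returns 'consensus', 'outvoted' (4-vs-1 kept) or 'excluded', by
    direct enumeration of the agreement pattern.
    """
    distinct = _distinct(list(superfamilies))
    if len(distinct) == 1:
        return "consensus"
    if len(superfamilies) == 5:
        for sf in distinct:
            if list(superfamilies).count(sf) == 4:
                return "outvoted"
    return "excluded"
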