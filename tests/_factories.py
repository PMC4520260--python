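"""Shared test-object factories."""

from __future__ import annotations

from deduf.scop import parse_sccs
from deduf.search_io import SCORE_KIND, DomainHit, Method


def make_hit(
    sccs: str,
    method: Method = Method.NRICHD,
    *,
    score: float = 1e-10,
    region: tuple[int, int] = (1, 80),
    query_length: int = 100,
    hit_id: str = "d0000a_",
    query_id: str = "DUF0001",
    source_pass: str = "",
) -> DomainHit:
    """DomainHit factory with the method's score slot filled from ``score``."""
    if method is Method.PDOMTHREADER and not source_pass:
        source_pass = "CERTAIN"
    return DomainHit(
        query_id=query_id,
        method=method,
        hit_id=hit_id,
        lineage=parse_sccs(sccs),
        region=region,
        query_length=query_length,
        source_pass=source_pass,
        **{SCORE_KIND[method]: score},
    )
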