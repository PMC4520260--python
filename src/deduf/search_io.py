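"""Readers for the five search methods' hit files and mapping flat files.

Every reader is *total and threshold-free*: it returns one
:class:`DomainHit` per data row (minus hits whose target lacks a SCOP
mapping, which are dropped with a logged count).  Significance and
coverage filtering is a later, explicit stage.

Dialects consumed
-----------------
* HMMER3 per-domain tables (``--domtblout``), in both the hmmsearch
  orientation (query = profile HMM, SCOP-NrichD searches) and the hmmscan
  orientation (query = sequence, SUPERFAMILY searches) — via Biopython's
  SearchIO.
* HHsearch ``.hhr`` result files — hits are taken from the summary table,
  one per row, preserving file order.
* Tab-delimited score tables for profile–profile (Z-score) and threading
  (P-value) hits.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SearchIO

from .scop import ScopCatalog, ScopLineage

logger = logging.getLogger(__name__)

__all__ = [
    "Method",
    "SCORE_KIND",
    "DomainHit",
    "FamilyRecord",
    "FamilyLink",
    "ReadError",
    "read_domtbl",
    "read_hhr",
    "read_hhr_dir",
    "read_score_table",
    "pool_hits",
    "read_family_table",
    "write_family_table",
    "read_link_table",
    "read_direct_map",
]


class Method(str, enum.Enum):
    """The five remote-similarity detection strategies."""

    NRICHD = "nrichd"  # hmmsearch/jackhmmer vs linker-enriched SCOP sequences
    SUPFAM_PLUS = "supfam_plus"  # profile-profile (AlignHUSH) vs SCOP family profiles
    SUPERFAMILY_DB = "superfamily_db"  # hmmscan vs SUPERFAMILY HMM library
    PDOMTHREADER = "pdomthreader"  # threading vs fold library
    HHSEARCH = "hhsearch"  # HMM-HMM search vs SCOP95 model library

    def __str__(self) -> str:
        return self.value


#: score field each method populates
SCORE_KIND: dict[Method, str] = {
    Method.NRICHD: "evalue",
    Method.SUPFAM_PLUS: "zscore",
    Method.SUPERFAMILY_DB: "evalue",
    Method.PDOMTHREADER: "pvalue",
    Method.HHSEARCH: "evalue",
}


class ReadError(ValueError):
    """Raised for malformed hit files / flat files (message names the line)."""


@dataclass(frozen=True)
class DomainHit:
    """One filtered-format search hit against a structural domain.

    Coordinates are 1-based inclusive on the query family, never
    converted.  Exactly one of ``evalue``/``zscore``/``pvalue`` is set and
    must match the method's score kind.
    """

    query_id: str
    method: Method
    hit_id: str
    lineage: ScopLineage
    region: tuple[int, int]
    query_length: int
    evalue: Optional[float] = None
    zscore: Optional[float] = None
    pvalue: Optional[float] = None
    source_pass: str = ""

    def __post_init__(self) -> None:
        start, end = self.region
        if not (1 <= start <= end <= self.query_length):
            raise ValueError(
                f"bad region {self.region} for query {self.query_id} "
                f"(length {self.query_length})"
            )
        populated = [
            k for k in ("evalue", "zscore", "pvalue") if getattr(self, k) is not None
        ]
        expected = SCORE_KIND[self.method]
        if populated != [expected]:
            raise ValueError(
                f"method {self.method} requires exactly the {expected!r} score, "
                f"got {populated}"
            )
        if self.evalue is not None and self.evalue < 0:
            raise ValueError("E-value must be >= 0")
        if self.pvalue is not None and not (0.0 < self.pvalue <= 1.0):
            raise ValueError("P-value must be in (0, 1]")

    @property
    def score_kind(self) -> str:
        return SCORE_KIND[self.method]

    @property
    def score(self) -> float:
        return getattr(self, self.score_kind)

    def with_lineage(self, lineage: ScopLineage) -> "DomainHit":
        return replace(self, lineage=lineage)


@dataclass
class FamilyRecord:
    """Query family metadata: length of the representative query and members."""

    family_id: str
    query_length: int
    member_taxa: list[int] = field(default_factory=list)
    clan_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.query_length <= 0:
            raise ValueError(f"query_length must be positive for {self.family_id}")


@dataclass(frozen=True)
class FamilyLink:
    """Undirected family–family profile match (stored in canonical order)."""

    family_a: str
    family_b: str
    zscore: float
    coverage_a: float
    coverage_b: float

    def __post_init__(self) -> None:
        for cov in (self.coverage_a, self.coverage_b):
            if not (0.0 <= cov <= 1.0):
                raise ValueError(f"coverage {cov} outside [0, 1]")

    @staticmethod
    def canonical(
        family_a: str, family_b: str, zscore: float, coverage_a: float, coverage_b: float
    ) -> "FamilyLink":
        if family_b < family_a:
            family_a, family_b = family_b, family_a
            coverage_a, coverage_b = coverage_b, coverage_a
        return FamilyLink(family_a, family_b, zscore, coverage_a, coverage_b)

    def partner(self, family_id: str) -> str:
        return self.family_b if family_id == self.family_a else self.family_a


def _require_family(
    query_id: str, family_index: Mapping[str, FamilyRecord], where: str
) -> FamilyRecord:
    try:
        return family_index[query_id]
    except KeyError:
        raise ReadError(f"{where}: unknown query family {query_id!r}") from None


def _make_hit(
    *,
    query_id: str,
    method: Method,
    hit_id: str,
    catalog: ScopCatalog,
    region: tuple[int, int],
    query_length: int,
    score: float,
    source_pass: str,
    unmapped: list[str],
) -> Optional[DomainHit]:
    lineage = catalog.lookup(hit_id)
    if lineage is None:
        unmapped.append(hit_id)
        return None
    kwargs = {SCORE_KIND[method]: score}
    return DomainHit(
        query_id=query_id,
        method=method,
        hit_id=hit_id,
        lineage=lineage,
        region=region,
        query_length=query_length,
        source_pass=source_pass,
        **kwargs,
    )


_DOMTAB_DIALECT = {
    # hmmsearch: query is the family HMM, target a database sequence;
    # hmmscan: query is the family sequence, target a library HMM.
    Method.NRICHD: "hmmsearch3-domtab",
    Method.SUPERFAMILY_DB: "hmmscan3-domtab",
}


def read_domtbl(
    path: str | Path,
    method: Method,
    family_index: Mapping[str, FamilyRecord],
    catalog: ScopCatalog,
    source_pass: str = "",
) -> list[DomainHit]:
    """Read an HMMER3 ``--domtblout`` table into DomainHits.

    One hit per domain line; the region is the query-side alignment span
    and the score is the *full-sequence* E-value (the per-domain
    c-Evalue/i-Evalue are never used for filtering).  Targets without a
    catalog mapping are dropped and counted.
    """
    if method not in _DOMTAB_DIALECT:
        raise ValueError(f"method {method} does not produce HMMER domain tables")
    path = Path(path)
    source_pass = source_pass or path.stem
    hits: list[DomainHit] = []
    unmapped: list[str] = []
    try:
        results = list(SearchIO.parse(str(path), _DOMTAB_DIALECT[method]))
    except Exception as exc:  # SearchIO raises assorted ValueError subclasses
        raise ReadError(f"{path}: cannot parse HMMER domain table: {exc}") from exc
    for qresult in results:
        family = _require_family(qresult.id, family_index, str(path))
        for hit_obj in qresult:
            for hsp in hit_obj:
                # SearchIO coordinates are 0-based half-open; restore 1-based.
                region = (hsp.query_start + 1, hsp.query_end)
                made = _make_hit(
                    query_id=family.family_id,
                    method=method,
                    hit_id=hit_obj.id,
                    catalog=catalog,
                    region=region,
                    query_length=family.query_length,
                    score=float(hit_obj.evalue),
                    source_pass=source_pass,
                    unmapped=unmapped,
                )
                if made is not None:
                    hits.append(made)
    if unmapped:
        logger.info(
            "%s: dropped %d hits without SCOP mapping", path, len(unmapped)
        )
    return hits


def read_hhr(
    path: str | Path,
    family_index: Mapping[str, FamilyRecord],
    catalog: ScopCatalog,
) -> list[DomainHit]:
    """Read an HHsearch ``.hhr`` result file (one query per file).

    One hit per summary-table row, preserving file order; the E-value
    comes from the summary E-value column and the region from the
    ``Query HMM`` column.  No thresholds are applied here.
    """
    path = Path(path)
    query_id: Optional[str] = None
    hits: list[DomainHit] = []
    unmapped: list[str] = []
    in_table = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not in_table:
                if line.startswith("Query"):
                    parts = line.split()
                    if len(parts) >= 2:
                        query_id = parts[1]
                elif line.lstrip().startswith("No Hit"):
                    if query_id is None:
                        raise ReadError(f"{path}:{lineno}: summary table before Query line")
                    in_table = True
                continue
            if not line.strip():
                break  # blank line terminates the summary table
            hits_before = len(hits) + len(unmapped)
            toks = line.split()
            # right-anchored: ... Prob E-value P-value Score SS Cols Query Template (tlen)
            ok = (
                len(toks) >= 11
                and toks[0].isdigit()
                and toks[-1].startswith("(")
                and toks[-1].endswith(")")
            )
            if not ok:
                raise ReadError(f"{path}:{lineno}: malformed summary row: {line!r}")
            hit_id = toks[1]
            try:
                evalue = float(toks[-8])
                qfrom, qto = toks[-3].split("-")
                region = (int(qfrom), int(qto))
            except ValueError as exc:
                raise ReadError(f"{path}:{lineno}: malformed summary row: {exc}") from exc
            family = _require_family(query_id, family_index, f"{path}:{lineno}")
            made = _make_hit(
                query_id=family.family_id,
                method=Method.HHSEARCH,
                hit_id=hit_id,
                catalog=catalog,
                region=region,
                query_length=family.query_length,
                score=evalue,
                source_pass="hhsearch",
                unmapped=unmapped,
            )
            if made is not None:
                hits.append(made)
            del hits_before
    if query_id is None:
        raise ReadError(f"{path}: no Query line found (truncated file?)")
    if unmapped:
        logger.info("%s: dropped %d hits without SCOP mapping", path, len(unmapped))
    return hits


def read_hhr_dir(
    directory: str | Path,
    family_index: Mapping[str, FamilyRecord],
    catalog: ScopCatalog,
) -> list[DomainHit]:
    """Read every ``*.hhr`` file in a directory (sorted by filename)."""
    hits: list[DomainHit] = []
    for path in sorted(Path(directory).glob("*.hhr")):
        hits.extend(read_hhr(path, family_index, catalog))
    return hits


def read_score_table(
    path: str | Path,
    method: Method,
    family_index: Mapping[str, FamilyRecord],
    catalog: ScopCatalog,
) -> list[DomainHit]:
    """Read a tab-delimited hit table with a Z-score or P-value column.

    Columns: ``query_id  hit_id  score  qstart  qend  [tag]``; ``#`` lines
    are comments.  For threading hits the confidence tag (e.g. CERTAIN)
    is kept in ``source_pass``.
    """
    if method not in (Method.SUPFAM_PLUS, Method.PDOMTHREADER):
        raise ValueError(f"method {method} does not produce plain score tables")
    path = Path(path)
    hits: list[DomainHit] = []
    unmapped: list[str] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ReadError(
                    f"{path}:{lineno}: expected >= 5 tab-delimited columns, "
                    f"got {len(parts)}"
                )
            query_id, hit_id = parts[0], parts[1]
            try:
                score = float(parts[2])
                region = (int(parts[3]), int(parts[4]))
            except ValueError as exc:
                raise ReadError(f"{path}:{lineno}: non-numeric field: {exc}") from exc
            if not math.isfinite(score):
                raise ReadError(f"{path}:{lineno}: non-finite score {parts[2]!r}")
            tag = parts[5] if len(parts) > 5 else ""
            family = _require_family(query_id, family_index, f"{path}:{lineno}")
            made = _make_hit(
                query_id=family.family_id,
                method=method,
                hit_id=hit_id,
                catalog=catalog,
                region=region,
                query_length=family.query_length,
                score=score,
                source_pass=tag if method is Method.PDOMTHREADER else (tag or method.value),
                unmapped=unmapped,
            )
            if made is not None:
                hits.append(made)
    if unmapped:
        logger.info("%s: dropped %d hits without SCOP mapping", path, len(unmapped))
    return hits


def pool_hits(*bundles: Sequence[DomainHit]) -> list[DomainHit]:
    """Concatenate hit lists from multiple search passes of one method.

    No deduplication: the decision trees are frequency-based over the
    pooled hits, so a domain found by both hmmsearch and jackhmmer counts
    twice.  Mixing methods is an error.
    """
    pooled: list[DomainHit] = []
    methods = set()
    for bundle in bundles:
        for hit in bundle:
            methods.add(hit.method)
            pooled.append(hit)
    if len(methods) > 1:
        raise ValueError(f"cannot pool hits from different methods: {sorted(m.value for m in methods)}")
    return pooled


# ---------------------------------------------------------------------------
# flat-file tables


def read_family_table(path: str | Path) -> dict[str, FamilyRecord]:
    """Read the family metadata TSV: family_id, query_length, clan_id, taxids.

    ``clan_id`` may be ``-`` (absent); taxids are comma-separated (may be
    empty).
    """
    path = Path(path)
    index: dict[str, FamilyRecord] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ReadError(f"{path}:{lineno}: expected >= 2 columns")
            family_id = parts[0]
            if family_id in index:
                raise ReadError(f"{path}:{lineno}: duplicate family {family_id!r}")
            try:
                qlen = int(parts[1])
            except ValueError as exc:
                raise ReadError(f"{path}:{lineno}: bad query length: {exc}") from exc
            clan = parts[2] if len(parts) > 2 and parts[2] not in ("", "-") else None
            taxa: list[int] = []
            if len(parts) > 3 and parts[3].strip():
                try:
                    taxa = [int(t) for t in parts[3].split(",") if t.strip()]
                except ValueError as exc:
                    raise ReadError(f"{path}:{lineno}: bad taxid list: {exc}") from exc
            index[family_id] = FamilyRecord(family_id, qlen, taxa, clan)
    return index


def write_family_table(families: Iterable[FamilyRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("# family_id\tquery_length\tclan_id\tmember_taxa\n")
        for fam in families:
            taxa = ",".join(str(t) for t in fam.member_taxa)
            fh.write(f"{fam.family_id}\t{fam.query_length}\t{fam.clan_id or '-'}\t{taxa}\n")


def read_link_table(path: str | Path) -> list[FamilyLink]:
    """Read the family–family link TSV (family_a, family_b, Z, cov_a, cov_b)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["family_a", "family_b", "zscore", "coverage_a", "coverage_b"],
        dtype={"family_a": str, "family_b": str},
    )
    links: list[FamilyLink] = []
    for row in df.itertuples(index=False):
        links.append(
            FamilyLink.canonical(
                row.family_a,
                row.family_b,
                float(row.zscore),
                float(row.coverage_a),
                float(row.coverage_b),
            )
        )
    return links


def read_direct_map(path: str | Path) -> dict[str, str]:
    """Read the direct family -> superfamily mapping TSV."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["family_id", "superfamily_id"],
        dtype=str,
    )
    mapping: dict[str, str] = {}
    for row in df.itertuples(index=False):
        if row.family_id in mapping and mapping[row.family_id] != row.superfamily_id:
            raise ReadError(
                f"{path}: conflicting direct mappings for {row.family_id!r}"
            )
        mapping[row.family_id] = row.superfamily_id
    return mapping
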