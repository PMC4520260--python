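"""SCOP hierarchy model: concise classification strings (sccs) and catalogs.

SCOP organises structural domains as class > fold > superfamily > family,
written as dotted codes, e.g. ``a.1.1.2`` is family 2 of superfamily
``a.1.1`` in fold ``a.1`` of the all-alpha class ``a``.  The decision
trees downstream only ever need equality tests between levels, so the
model is purely lexical: no sunid integers, no ASTRAL handling.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

logger = logging.getLogger(__name__)

__all__ = [
    "ScopLineage",
    "ScopCatalog",
    "Relation",
    "ScopParseError",
    "parse_sccs",
    "lineage_relation",
    "fold_of_superfamily",
]


class ScopParseError(ValueError):
    """Raised for malformed sccs codes or catalog lines."""


@dataclass(frozen=True, order=True)
class ScopLineage:
    """Parsed class/fold/superfamily(/family) identity of a structural domain.

    ``family_id`` may be ``None``: hits are sometimes resolved only to
    superfamily level (e.g. SUPERFAMILY database models).
    """

    class_id: str
    fold_id: str
    superfamily_id: str
    family_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (len(self.class_id) == 1 and self.class_id.isalpha()):
            raise ScopParseError(
                f"class identifier must be one letter, got {self.class_id!r}"
            )
        if not self.fold_id.startswith(self.class_id + "."):
            raise ScopParseError(
                f"fold {self.fold_id!r} does not extend class {self.class_id!r}"
            )
        if not self.superfamily_id.startswith(self.fold_id + "."):
            raise ScopParseError(
                f"superfamily {self.superfamily_id!r} does not extend "
                f"fold {self.fold_id!r}"
            )
        if self.family_id is not None and not self.family_id.startswith(
            self.superfamily_id + "."
        ):
            raise ScopParseError(
                f"family {self.family_id!r} does not extend "
                f"superfamily {self.superfamily_id!r}"
            )

    @property
    def sccs(self) -> str:
        """The concise classification string this lineage round-trips to."""
        return self.family_id if self.family_id is not None else self.superfamily_id

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.sccs


class Relation(enum.Enum):
    """Finest shared SCOP level between two lineages."""

    SAME_SUPERFAMILY = "same_superfamily"
    SAME_FOLD_DIFF_SUPERFAMILY = "same_fold_diff_superfamily"
    SAME_CLASS_DIFF_FOLD = "same_class_diff_fold"
    DIFF_CLASS = "diff_class"


def parse_sccs(code: str) -> ScopLineage:
    """Parse an sccs code like ``a.1.1.1`` (or ``a.1.1``) into a lineage.

    Raises :class:`ScopParseError` naming the offending field for codes
    with the wrong number of fields, a non-alphabetic class, or
    non-integer level numbers.
    """
    fields = code.strip().split(".")
    if len(fields) not in (3, 4):
        raise ScopParseError(
            f"sccs {code!r}: expected 3 or 4 dot-separated fields, got {len(fields)}"
        )
    cls = fields[0]
    if not (len(cls) == 1 and cls.isalpha()):
        raise ScopParseError(f"sccs {code!r}: class field {cls!r} must be one letter")
    for level, value in zip(("fold", "superfamily", "family"), fields[1:]):
        if not value.isdigit() or int(value) <= 0:
            raise ScopParseError(
                f"sccs {code!r}: {level} field {value!r} is not a positive integer"
            )
    fold = f"{cls}.{fields[1]}"
    superfamily = f"{fold}.{fields[2]}"
    family = f"{superfamily}.{fields[3]}" if len(fields) == 4 else None
    return ScopLineage(cls, fold, superfamily, family)


def fold_of_superfamily(superfamily_id: str) -> str:
    """Drop the last level of a superfamily code: ``a.1.1`` -> ``a.1``."""
    fold, _, last = superfamily_id.rpartition(".")
    if not fold or not last.isdigit():
        raise ScopParseError(f"not a superfamily code: {superfamily_id!r}")
    return fold


def lineage_relation(a: ScopLineage, b: ScopLineage) -> Relation:
    """Finest level shared by two lineages; symmetric in its arguments."""
    if a.superfamily_id == b.superfamily_id:
        return Relation.SAME_SUPERFAMILY
    if a.fold_id == b.fold_id:
        return Relation.SAME_FOLD_DIFF_SUPERFAMILY
    if a.class_id == b.class_id:
        return Relation.SAME_CLASS_DIFF_FOLD
    return Relation.DIFF_CLASS


@dataclass
class ScopCatalog:
    """Map from structural-domain identifier (domain sid or PDB chain) to lineage.

    Unmapped lookups are an expected outcome, not an error: threading hits
    whose template has no SCOP mapping are dropped upstream with a logged
    count, mirroring how such templates are excluded from analysis.
    """

    entries: dict[str, ScopLineage]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, domain_id: str) -> bool:
        return domain_id in self.entries

    def lookup(self, domain_id: str) -> Optional[ScopLineage]:
        """Return the lineage for ``domain_id``, or ``None`` if unmapped."""
        return self.entries.get(domain_id)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "ScopCatalog":
        """Build a catalog from ``{domain_id: sccs}`` pairs."""
        return cls({k: parse_sccs(v) for k, v in mapping.items()})

    @classmethod
    def from_file(cls, path: str | Path) -> "ScopCatalog":
        """Read a dir.cla-style classification flat file.

        Tab-delimited columns ``(domain_sid, pdb_id, chain:range, sccs)``;
        lines starting with ``#`` are comments.  Duplicate identifiers are
        rejected.
        """
        entries: dict[str, ScopLineage] = {}
        path = Path(path)
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ScopParseError(
                        f"{path}:{lineno}: expected 4 tab-delimited columns, "
                        f"got {len(parts)}"
                    )
                sid, _pdb, _chain, sccs = parts[0], parts[1], parts[2], parts[3]
                if sid in entries:
                    raise ScopParseError(f"{path}:{lineno}: duplicate domain id {sid!r}")
                entries[sid] = parse_sccs(sccs)
        logger.info("loaded SCOP catalog %s: %d domains", path, len(entries))
        return cls(entries)

    def write(self, path: str | Path) -> None:
        """Write the catalog back in the dir.cla-style dialect."""
        with Path(path).open("w") as fh:
            fh.write("# domain_sid\tpdb_id\tchain:range\tsccs\n")
            for sid, lin in self.entries.items():
                pdb = sid[1:5] if len(sid) >= 5 else "0000"
                fh.write(f"{sid}\t{pdb}\tA:\t{lin.sccs}\n")


def drop_unmapped(
    ids: Iterable[str], catalog: ScopCatalog
) -> tuple[list[str], int]:
    """Partition identifiers into catalog-mapped ones and a dropped count."""
    kept = [i for i in ids if i in catalog]
    n_dropped = sum(1 for i in ids if i not in catalog)
    if n_dropped:
        logger.info("dropped %d identifiers without SCOP mapping", n_dropped)
    return kept, n_dropped
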