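"""Functional annotation transfer: GO terms, EC numbers, kingdoms.

Consensus superfamilies inherit candidate functions from three external
mappings:

* a domain-centric GO table (superfamily -> GO term with information
  content); only terms with IC >= 1.5 are transferred, highest IC first;
* EC numbers of single-domain PDB chains whose sole domain belongs to
  the superfamily (multi-domain chains are ignored because the enzyme
  activity cannot be attributed to one domain);
* the taxonomic kingdoms (Archaea / Bacteria / Eukaryota / Viruses)
  spanned by the query family's member sequences, resolved through the
  NCBI-style taxonomy dump.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .search_io import FamilyRecord

logger = logging.getLogger(__name__)

__all__ = [
    "GoAnnotation",
    "EnzymeLink",
    "Taxonomy",
    "KINGDOMS",
    "read_dcgo_table",
    "read_pdb_ec_table",
    "read_pdb_scop_table",
    "go_for_superfamily",
    "ec_for_superfamily",
    "kingdoms_for_family",
]

KINGDOMS = ("Archaea", "Bacteria", "Eukaryota", "Viruses")

_NAMESPACES = {"molecular_function", "biological_process", "cellular_component"}


@dataclass(frozen=True)
class GoAnnotation:
    superfamily_id: str
    go_id: str
    namespace: str
    information_content: float

    def __post_init__(self) -> None:
        if self.namespace not in _NAMESPACES:
            raise ValueError(f"unknown GO namespace {self.namespace!r}")
        if not self.information_content == self.information_content:  # NaN
            raise ValueError("information content must be finite")


@dataclass(frozen=True)
class EnzymeLink:
    superfamily_id: str
    ec_number: str

    def __post_init__(self) -> None:
        top = self.ec_number.split(".")[0]
        if not top.isdigit() or not 1 <= int(top) <= 7:
            raise ValueError(f"EC class must be 1..7, got {self.ec_number!r}")


def read_dcgo_table(path: str | Path) -> pd.DataFrame:
    """Flat dcGO-style TSV: superfamily_id, go_id, namespace, IC."""
    return pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["superfamily_id", "go_id", "namespace", "information_content"],
        dtype={"superfamily_id": str, "go_id": str, "namespace": str},
    )


def read_pdb_ec_table(path: str | Path) -> pd.DataFrame:
    """TSV of (pdb_chain, ec_number)."""
    return pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["pdb_chain", "ec_number"],
        dtype=str,
    )


def read_pdb_scop_table(path: str | Path) -> pd.DataFrame:
    """TSV of (pdb_chain, domain_sid, sccs)."""
    return pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["pdb_chain", "domain_sid", "sccs"],
        dtype=str,
    )


def go_for_superfamily(
    superfamily_id: str, dcgo_table: pd.DataFrame, ic_threshold: float = 1.5
) -> list[GoAnnotation]:
    """High-information GO terms for a superfamily, descending IC.

    The IC cutoff is boundary-inclusive; unknown superfamilies yield an
    empty list.  Ties in IC are ordered by GO id for determinism.
    """
    rows = dcgo_table[
        (dcgo_table["superfamily_id"] == superfamily_id)
        & (dcgo_table["information_content"] >= ic_threshold)
    ]
    rows = rows.sort_values(
        ["information_content", "go_id"], ascending=[False, True]
    )
    return [
        GoAnnotation(
            superfamily_id=r.superfamily_id,
            go_id=r.go_id,
            namespace=r.namespace,
            information_content=float(r.information_content),
        )
        for r in rows.itertuples(index=False)
    ]


def ec_for_superfamily(
    superfamily_id: str, pdb_ec_table: pd.DataFrame, pdb_scop_table: pd.DataFrame
) -> list[EnzymeLink]:
    """EC numbers inherited from single-domain chains of the superfamily.

    A chain contributes only when it carries exactly one SCOP domain and
    that domain's superfamily matches; the result is deduplicated and
    sorted.
    """
    domains_per_chain = pdb_scop_table.groupby("pdb_chain").size()
    single = set(domains_per_chain[domains_per_chain == 1].index)
    sf_of_sccs = pdb_scop_table["sccs"].str.rsplit(".", n=1).str[0]
    chains = set(
        pdb_scop_table.loc[
            pdb_scop_table["pdb_chain"].isin(single) & (sf_of_sccs == superfamily_id),
            "pdb_chain",
        ]
    )
    ecs = sorted(
        set(pdb_ec_table.loc[pdb_ec_table["pdb_chain"].isin(chains), "ec_number"])
    )
    return [EnzymeLink(superfamily_id, ec) for ec in ecs]


class Taxonomy:
    """Parent-pointer taxonomy with kingdom resolution.

    Loaded from the nodes/names dump dialect (``taxid | parent | rank``
    and ``taxid | name``).  "Kingdom" means the superkingdom/domain-rank
    ancestor, with Viruses treated as its own division.  The parent
    chain must be acyclic with a single root (a node whose parent is
    itself).
    """

    def __init__(
        self, parents: dict[int, int], ranks: dict[int, str], names: dict[int, str]
    ):
        self.parents = parents
        self.ranks = ranks
        self.names = names
        self._kingdom_cache: dict[int, Optional[str]] = {}
        self._validate()

    def _validate(self) -> None:
        roots = [t for t, p in self.parents.items() if p == t]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {len(roots)}")
        for start in self.parents:
            seen = set()
            node = start
            while self.parents[node] != node:
                if node in seen:
                    raise ValueError(f"cyclic taxonomy at taxid {start}")
                seen.add(node)
                node = self.parents[node]
                if node not in self.parents:
                    raise ValueError(f"dangling parent {node} reached from {start}")

    @classmethod
    def from_dump(cls, nodes_path: str | Path, names_path: str | Path) -> "Taxonomy":
        parents: dict[int, int] = {}
        ranks: dict[int, str] = {}
        names: dict[int, str] = {}
        with Path(nodes_path).open() as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                fields = [f.strip() for f in line.split("|")]
                taxid, parent, rank = int(fields[0]), int(fields[1]), fields[2]
                parents[taxid] = parent
                ranks[taxid] = rank
        with Path(names_path).open() as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                fields = [f.strip() for f in line.split("|")]
                names[int(fields[0])] = fields[1]
        return cls(parents, ranks, names)

    def kingdom_of(self, taxid: int) -> Optional[str]:
        """Kingdom name for a taxid, or None when unplaced/unknown."""
        if taxid in self._kingdom_cache:
            return self._kingdom_cache[taxid]
        node: Optional[int] = taxid
        result: Optional[str] = None
        while node is not None and node in self.parents:
            name = self.names.get(node, "")
            if self.ranks.get(node) in ("superkingdom", "domain") and name in KINGDOMS:
                result = name
                break
            if name == "Viruses":
                result = "Viruses"
                break
            parent = self.parents[node]
            node = None if parent == node else parent
        self._kingdom_cache[taxid] = result
        return result


def kingdoms_for_family(
    family: FamilyRecord, taxonomy: Taxonomy
) -> set[str]:
    """Union of kingdoms over the family's member taxa.

    Members whose taxid is absent from the taxonomy are skipped (with a
    logged count), matching how unplaceable sequence identifiers are
    handled.
    """
    kingdoms: set[str] = set()
    skipped = 0
    for taxid in family.member_taxa:
        if taxid not in taxonomy.parents:
            skipped += 1
            continue
        kingdom = taxonomy.kingdom_of(taxid)
        if kingdom is not None:
            kingdoms.add(kingdom)
    if skipped:
        logger.info(
            "family %s: %d member taxids absent from taxonomy", family.family_id, skipped
        )
    return kingdoms


def annotate_records(
    records: Iterable,
    families: dict[str, FamilyRecord],
    dcgo_table: Optional[pd.DataFrame] = None,
    pdb_ec_table: Optional[pd.DataFrame] = None,
    pdb_scop_table: Optional[pd.DataFrame] = None,
    taxonomy: Optional[Taxonomy] = None,
    ic_threshold: float = 1.5,
) -> pd.DataFrame:
    """Annotated consensus table: GO ids, EC numbers and kingdoms per record."""
    rows = []
    for rec in records:
        go_ids = ec_numbers = kingdoms = ""
        if dcgo_table is not None:
            go_ids = ";".join(
                g.go_id for g in go_for_superfamily(rec.superfamily_id, dcgo_table, ic_threshold)
            )
        if pdb_ec_table is not None and pdb_scop_table is not None:
            ec_numbers = ";".join(
                e.ec_number
                for e in ec_for_superfamily(rec.superfamily_id, pdb_ec_table, pdb_scop_table)
            )
        if taxonomy is not None and rec.query_id in families:
            kingdoms = ";".join(
                sorted(kingdoms_for_family(families[rec.query_id], taxonomy))
            )
        rows.append(
            {
                "family_id": rec.query_id,
                "start": rec.region[0],
                "end": rec.region[1],
                "superfamily_id": rec.superfamily_id,
                "methods": ";".join(m.value for m in rec.methods),
                "n_methods": rec.n_methods,
                "confidence": rec.confidence.value,
                "go_ids": go_ids,
                "ec_numbers": ec_numbers,
                "kingdoms": kingdoms,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "family_id",
            "start",
            "end",
            "superfamily_id",
            "methods",
            "n_methods",
            "confidence",
            "go_ids",
            "ec_numbers",
            "kingdoms",
        ],
    )
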