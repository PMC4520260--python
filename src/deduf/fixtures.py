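"""Deterministic synthetic input bundles for the whole pipeline.

The generator writes every file dialect the pipeline consumes — per-method
hit files, SCOP catalog, family table, mapping and annotation tables —
together with a ground-truth manifest of the outcome each family is
constructed to produce.  Agreement structure is controllable: how many
methods support a family, which families carry cross-method conflicts,
and how many indirect mappings are derivable through family links.

Scores and regions are sampled only to sit robustly on the intended side
of each filter; there is no attempt at realistic score distributions or
sequence content.  Each output file draws from its own pseudo-random
stream keyed by (seed, filename), so adding a file never shifts the
content of the others, and identical specs yield byte-identical bundles.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .scop import ScopCatalog, parse_sccs
from .search_io import FamilyRecord, Method

__all__ = ["FixtureSpec", "FixtureManifest", "PlannedFamily", "generate", "perturb"]

METHODS: tuple[Method, ...] = tuple(Method)

# kingdom -> representative species taxids in the generated taxonomy
_SPECIES = {
    "Bacteria": [511145, 1280],
    "Eukaryota": [9606, 559292],
    "Archaea": [2287, 2190],
    "Viruses": [10359, 2697049],
}

_TAX_NODES = [
    # taxid, parent, rank, name
    (1, 1, "no rank", "root"),
    (2, 1, "superkingdom", "Bacteria"),
    (2157, 1, "superkingdom", "Archaea"),
    (2759, 1, "superkingdom", "Eukaryota"),
    (10239, 1, "superkingdom", "Viruses"),
    (511145, 2, "species", "Escherichia coli K-12"),
    (1280, 2, "species", "Staphylococcus aureus"),
    (9606, 2759, "species", "Homo sapiens"),
    (559292, 2759, "species", "Saccharomyces cerevisiae"),
    (2287, 2157, "species", "Saccharolobus solfataricus"),
    (2190, 2157, "species", "Methanocaldococcus jannaschii"),
    (10359, 10239, "species", "Human cytomegalovirus"),
    (2697049, 10239, "species", "SARS-CoV-2"),
]


class FixtureError(ValueError):
    """Inconsistent fixture specification."""


@dataclass
class FixtureSpec:
    """Declarative description of a synthetic input bundle.

    tier_histogram        n_agreeing_methods (1–5) -> number of families
                          built to reach consensus with that many methods
    per_method_assigned   method -> families given an assignment by that
                          method (beyond the tier families)
    per_method_conflicting  method -> how many of those additionally get a
                          dissenting overlapping verdict from a partner
                          method, so the region is excluded as ambiguous
    n_outvoted            families built as four agreeing methods vs one
                          dissenter (kept, high confidence)
    link_spec             (n_direct, n_indirect): size of the direct
                          family->superfamily table and number of families
                          given a qualifying link for indirect assignment
    kingdom_mix           "Bacteria+Eukaryota"-style combo -> family count
                          (cycled over families; default all Bacteria)
    """

    seed: int = 0
    n_families: Optional[int] = None
    scop_catalog_size: int = 96
    tier_histogram: dict[int, int] = field(default_factory=dict)
    per_method_assigned: dict[str, int] = field(default_factory=dict)
    per_method_conflicting: dict[str, int] = field(default_factory=dict)
    n_outvoted: int = 0
    link_spec: tuple[int, int] = (0, 0)
    kingdom_mix: Optional[dict[str, int]] = None

    def __post_init__(self) -> None:
        self.tier_histogram = {int(k): int(v) for k, v in self.tier_histogram.items()}
        self.link_spec = tuple(self.link_spec)  # type: ignore[assignment]
        self.validate()

    @property
    def demand(self) -> int:
        """Families required by the structured parts of the spec."""
        return (
            sum(self.tier_histogram.values())
            + self.n_outvoted
            + sum(self.per_method_assigned.values())
            + self.link_spec[1]
        )

    @property
    def total_families(self) -> int:
        return self.n_families if self.n_families is not None else self.demand

    def validate(self) -> None:
        if any(v < 0 for v in self.tier_histogram.values()) or self.n_outvoted < 0:
            raise FixtureError("family counts must be >= 0")
        if any(n not in range(1, 6) for n in self.tier_histogram):
            raise FixtureError("tier histogram keys must be 1..5")
        for m, c in self.per_method_conflicting.items():
            if c < 0 or c > self.per_method_assigned.get(m, 0):
                raise FixtureError(
                    f"conflicting count for {m} exceeds its assigned count"
                )
        for m in list(self.per_method_assigned) + list(self.per_method_conflicting):
            Method(m)  # raises on unknown method tags
        if any(v < 0 for v in self.link_spec):
            raise FixtureError("link_spec counts must be >= 0")
        if self.n_families is not None and self.n_families < self.demand:
            raise FixtureError(
                f"n_families={self.n_families} below required {self.demand}"
            )
        if self.kingdom_mix:
            for combo in self.kingdom_mix:
                for kingdom in combo.split("+"):
                    if kingdom not in _SPECIES:
                        raise FixtureError(f"unknown kingdom {kingdom!r}")
        if self.scop_catalog_size < 48:
            raise FixtureError("scop_catalog_size must be >= 48")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FixtureSpec":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        if "link_spec" in raw:
            raw["link_spec"] = tuple(raw["link_spec"])
        return cls(**raw)


@dataclass
class PlannedHit:
    """One hit the generator intends to write."""

    method: Method
    hit_id: str
    sccs: str
    region: tuple[int, int]
    score: float
    source_pass: str
    passes: bool  # constructed to pass the method's filter?
    coverage_sensitive: bool = False


@dataclass
class PlannedFamily:
    """Ground truth for one generated family."""

    family_id: str
    query_length: int
    superfamily_id: Optional[str]
    hits: list[PlannedHit] = field(default_factory=list)
    indirect_via: Optional[str] = None  # direct-mapped family providing the hop
    kingdoms: tuple[str, ...] = ()
    member_taxa: tuple[int, ...] = ()

    def expected_outcome(self) -> dict:
        """Predict the consensus outcome from the planned passing support.

        Mirrors the published merge rules at the planning level: one
        superfamily -> consensus; exactly 4 vs 1 -> consensus with a
        dissenter; any other mix -> excluded.
        """
        support: dict[Method, str] = {}
        for hit in self.hits:
            if hit.passes:
                support.setdefault(hit.method, parse_sccs(hit.sccs).superfamily_id)
        if self.indirect_via is not None and self.superfamily_id is not None:
            support.setdefault(Method.SUPFAM_PLUS, self.superfamily_id)
        if not support:
            return {"outcome": "none", "n_methods": 0, "superfamily_id": None}
        sfs = list(support.values())
        distinct = sorted(set(sfs))
        if len(distinct) == 1:
            return {
                "outcome": "consensus",
                "n_methods": len(support),
                "superfamily_id": distinct[0],
                "methods": sorted(m.value for m in support),
            }
        top = max(distinct, key=lambda sf: (sfs.count(sf), sf))
        if len(support) == 5 and sfs.count(top) == 4:
            dissenter = next(m for m, sf in support.items() if sf != top)
            return {
                "outcome": "consensus",
                "n_methods": 4,
                "superfamily_id": top,
                "methods": sorted(m.value for m, sf in support.items() if sf == top),
                "outvoted_method": dissenter.value,
            }
        return {
            "outcome": "excluded",
            "n_methods": 0,
            "superfamily_id": None,
            "superfamilies_in_conflict": distinct,
            "methods": sorted(m.value for m in support),
        }


@dataclass
class FixtureManifest:
    """What the generator wrote and what the pipeline should conclude."""

    spec: FixtureSpec
    families: list[PlannedFamily]
    per_method_hits: dict[str, int]
    n_direct: int
    n_indirect_expected: int
    outdir: Path

    def expected(self) -> dict[str, dict]:
        return {f.family_id: f.expected_outcome() for f in self.families}

    def to_json_dict(self) -> dict:
        spec_dict = asdict(self.spec)
        spec_dict["link_spec"] = list(self.spec.link_spec)
        return {
            "spec": spec_dict,
            "per_method_hits": self.per_method_hits,
            "n_direct": self.n_direct,
            "n_indirect_expected": self.n_indirect_expected,
            "families": [
                {
                    "family_id": f.family_id,
                    "query_length": f.query_length,
                    "superfamily_id": f.superfamily_id,
                    "indirect_via": f.indirect_via,
                    "kingdoms": list(f.kingdoms),
                    "expected": f.expected_outcome(),
                }
                for f in self.families
            ],
        }


def _rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


def _sf_pool() -> list[str]:
    # 4 classes x 3 folds x 2 superfamilies = 24 codes; consecutive pairs
    # share a fold, +6 steps change class.
    return [
        f"{c}.{fold}.{sf}"
        for c in "abcd"
        for fold in (1, 2, 3)
        for sf in (1, 2)
    ]


def _build_catalog(size: int) -> tuple[ScopCatalog, dict[str, list[str]]]:
    pool = _sf_pool()
    entries: dict[str, str] = {}
    by_sf: dict[str, list[str]] = {sf: [] for sf in pool}
    for i in range(size):
        sf = pool[i % len(pool)]
        sid = f"d{i:04d}a_"
        entries[sid] = f"{sf}.1"
        by_sf[sf].append(sid)
    return ScopCatalog.from_mapping(entries), by_sf


def _conflict_sf(sf: str, pool: Sequence[str]) -> str:
    # a superfamily from a different class (hence different fold)
    return pool[(pool.index(sf) + 6) % len(pool)]


def _plan_families(spec: FixtureSpec, by_sf: dict[str, list[str]]) -> list[PlannedFamily]:
    pool = list(by_sf)
    rng_fam = _rng(spec.seed, "families.tsv")
    qlens = rng_fam.integers(100, 300, size=max(spec.total_families, 1))

    combos: list[tuple[str, ...]] = []
    if spec.kingdom_mix:
        for combo, count in spec.kingdom_mix.items():
            combos.extend([tuple(sorted(combo.split("+")))] * count)
    families: list[PlannedFamily] = []

    def new_family(sf: Optional[str]) -> PlannedFamily:
        i = len(families)
        kingdoms = combos[i % len(combos)] if combos else ("Bacteria",)
        taxa = tuple(t for k in kingdoms for t in _SPECIES[k])
        fam = PlannedFamily(
            family_id=f"DUF{i + 1:04d}",
            query_length=int(qlens[i]),
            superfamily_id=sf,
            kingdoms=kingdoms,
            member_taxa=taxa,
        )
        families.append(fam)
        return fam

    def base_region(fam: PlannedFamily, offset: int = 0) -> tuple[int, int]:
        start = 1 + 2 * offset
        end = max(int(0.85 * fam.query_length), start + int(0.7 * fam.query_length))
        return (start, min(end, fam.query_length))

    def add_support(fam: PlannedFamily, method: Method, offset: int, sf: str, passes: bool = True) -> None:
        domains = by_sf[sf]
        i = len(families) - 1
        region = base_region(fam, offset)
        mi = METHODS.index(method)
        if method is Method.NRICHD:
            # two pooled hits from distinct domains of the superfamily
            for k, src in enumerate(("nrichd_hmmsearch", "nrichd_jackhmmer")):
                fam.hits.append(
                    PlannedHit(
                        method=method,
                        hit_id=domains[(i + k) % len(domains)],
                        sccs=f"{sf}.1",
                        region=region,
                        score=-1.0,  # drawn later from the file's stream
                        source_pass=src,
                        passes=passes,
                        coverage_sensitive=True,
                    )
                )
        else:
            source = "CERTAIN" if method is Method.PDOMTHREADER else method.value
            fam.hits.append(
                PlannedHit(
                    method=method,
                    hit_id=domains[(i + mi) % len(domains)],
                    sccs=f"{sf}.1",
                    region=region,
                    score=-1.0,
                    source_pass=source,
                    passes=passes,
                    coverage_sensitive=method is Method.SUPFAM_PLUS,
                )
            )

    # 1. tier families: n agreeing methods, rotated so every method occurs
    for n_methods in (5, 4, 3, 2, 1):
        for j in range(spec.tier_histogram.get(n_methods, 0)):
            sf = pool[len(families) % len(pool)]
            fam = new_family(sf)
            start = j % 5
            for k in range(n_methods):
                method = METHODS[(start + k) % 5]
                add_support(fam, method, offset=METHODS.index(method), sf=sf)

    # 2. four-against-one families (kept at high confidence)
    for j in range(spec.n_outvoted):
        sf = pool[len(families) % len(pool)]
        fam = new_family(sf)
        dissenter = METHODS[j % 5]
        for method in METHODS:
            target = _conflict_sf(sf, pool) if method is dissenter else sf
            add_support(fam, method, offset=METHODS.index(method), sf=target)

    # 3. per-method families; the leading ones carry a 1-vs-1 conflict
    for method in METHODS:
        assigned = spec.per_method_assigned.get(method.value, 0)
        conflicting = spec.per_method_conflicting.get(method.value, 0)
        for j in range(assigned):
            sf = pool[len(families) % len(pool)]
            fam = new_family(sf)
            add_support(fam, method, offset=METHODS.index(method), sf=sf)
            if j < conflicting:
                partners = [m for m in METHODS if m is not method]
                partner = partners[j % len(partners)]
                add_support(
                    fam, partner, offset=METHODS.index(partner),
                    sf=_conflict_sf(sf, pool),
                )

    # 4. families assigned only through an indirect family link
    for j in range(spec.link_spec[1]):
        sf = pool[j % len(pool)]
        fam = new_family(sf)
        fam.indirect_via = f"PFD{j + 1:05d}"

    # 5. padding families with no hits at all
    while len(families) < spec.total_families:
        new_family(None)

    # 6. sub-threshold decoys on each method's first supported family:
    # they must be read, then removed by the acceptance filters.
    decoy_scores = {
        Method.NRICHD: 0.01,
        Method.SUPERFAMILY_DB: 0.5,
        Method.HHSEARCH: 0.9,
        Method.SUPFAM_PLUS: 5.0,
        Method.PDOMTHREADER: 1e-3,
    }
    for method in METHODS:
        target = next(
            (f for f in families if any(h.method is method for h in f.hits)), None
        )
        if target is None:
            continue
        # HMMER tables are keyed by (query, target): the decoy must not
        # reuse a domain id this family already hits, or rows would merge
        used = {h.hit_id for h in target.hits}
        decoy_id, decoy_sf = next(
            (d, s) for s in pool for d in by_sf[s] if d not in used
        )
        target.hits.append(
            PlannedHit(
                method=method,
                hit_id=decoy_id,
                sccs=f"{decoy_sf}.1",
                region=base_region(target),
                score=decoy_scores[method],
                source_pass="GUESS" if method is Method.PDOMTHREADER else "decoy",
                passes=False,
            )
        )
    return families


def _draw_scores(spec: FixtureSpec, families: list[PlannedFamily]) -> None:
    """Fill in pass-side scores, one stream per output file."""
    streams = {
        "nrichd_hmmsearch": _rng(spec.seed, "hits/nrichd_hmmsearch.domtbl"),
        "nrichd_jackhmmer": _rng(spec.seed, "hits/nrichd_jackhmmer.domtbl"),
        Method.SUPERFAMILY_DB.value: _rng(spec.seed, "hits/superfamily_db.domtbl"),
        Method.SUPFAM_PLUS.value: _rng(spec.seed, "hits/supfam_plus.tsv"),
        Method.PDOMTHREADER.value: _rng(spec.seed, "hits/pdomthreader.tsv"),
        Method.HHSEARCH.value: _rng(spec.seed, "hits/hhsearch"),
    }
    for fam in families:
        for hit in fam.hits:
            if hit.score >= 0:  # decoys keep their fixed failing score
                continue
            if hit.method is Method.NRICHD:
                rng = streams[hit.source_pass]
            else:
                rng = streams[hit.method.value]
            if hit.method is Method.SUPFAM_PLUS:
                hit.score = round(float(rng.uniform(9.0, 18.0)), 1)
            elif hit.method is Method.PDOMTHREADER:
                hit.score = float(f"{10 ** -rng.uniform(6.5, 11.0):.2e}")
            else:
                hit.score = float(f"{10 ** -rng.uniform(8.0, 30.0):.2e}")


# ---------------------------------------------------------------------------
# file writers


_DOMTBL_HEADER = (
    "# target name        accession   tlen query name           accession   qlen"
    "   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to"
    "  from    to  from    to  acc description of target\n"
    "#------------------- ---------- ----- -------------------- ---------- -----"
    " --------- ------ ----- --- --- --------- --------- ------ ----- ----- -----"
    " ----- ----- ----- ----- ---- ---------------------\n"
)


def _write_domtbl(
    path: Path, rows: list[tuple[PlannedFamily, PlannedHit]], hmm_query: bool
) -> None:
    """Write an HMMER3 per-domain table.

    ``hmm_query=True`` is the hmmsearch orientation (query = family HMM,
    region in the hmm-coordinate columns); ``False`` the hmmscan one
    (query = family sequence, region in the ali-coordinate columns).
    """
    with path.open("w") as fh:
        fh.write(_DOMTBL_HEADER)
        for fam, hit in rows:
            start, end = hit.region
            tlen = end - start + 30
            if hmm_query:
                hmm = (start, end)
                ali = (1, end - start + 1)
            else:
                hmm = (1, end - start + 1)
                ali = (start, end)
            fh.write(
                f"{hit.hit_id:<20s} -          {tlen:5d} {fam.family_id:<20s} "
                f"-          {fam.query_length:5d} {hit.score:9.3g} {55.0:6.1f} "
                f"{0.1:5.1f}   1   1 {hit.score / 10:9.3g} {hit.score:9.3g} "
                f"{54.0:6.1f} {0.1:5.1f} {hmm[0]:5d} {hmm[1]:5d} {ali[0]:5d} "
                f"{ali[1]:5d} {max(ali[0] - 1, 1):5d} {ali[1] + 1:5d} 0.95 "
                f"synthetic {hit.sccs}\n"
            )


def _write_score_table(path: Path, rows: list[tuple[PlannedFamily, PlannedHit]]) -> None:
    with path.open("w") as fh:
        fh.write("# query_id\thit_id\tscore\tqstart\tqend\ttag\n")
        for fam, hit in rows:
            fh.write(
                f"{fam.family_id}\t{hit.hit_id}\t{hit.score}\t"
                f"{hit.region[0]}\t{hit.region[1]}\t{hit.source_pass}\n"
            )


def _write_hhr(path: Path, fam: PlannedFamily, hits: list[PlannedHit]) -> None:
    with path.open("w") as fh:
        fh.write(
            f"Query         {fam.family_id}\n"
            f"Match_columns {fam.query_length}\n"
            "No_of_seqs    1 out of 1\n"
            "Neff          1.0\n"
            "Searched_HMMs 19247\n"
            "Date          Mon Jan  1 00:00:00 2024\n"
            "Command       hhsearch -i query.a3m\n"
            "\n"
            " No Hit                             Prob E-value P-value  Score    SS"
            " Cols Query HMM  Template HMM\n"
        )
        for i, hit in enumerate(hits, start=1):
            start, end = hit.region
            cols = end - start + 1
            tlen = cols + 20
            fh.write(
                f"{i:3d} {hit.hit_id + ' ' + hit.sccs:<33s} 99.9 {hit.score:.2g} "
                f"{hit.score / 1000:.2g} {180.0:6.1f}   0.0 {cols:4d} "
                f"{start}-{end} {1}-{cols} ({tlen})\n"
            )
        fh.write("\n")
        for i, hit in enumerate(hits, start=1):
            start, end = hit.region
            cols = end - start + 1
            fh.write(
                f"No {i}\n"
                f">{hit.hit_id} {hit.sccs}\n"
                f"Probab=99.90  E-value={hit.score:.2g}  Score=180.00  "
                f"Aligned_cols={cols}  Identities=25%  Similarity=0.40  "
                f"Sum_probs={cols * 0.8:.1f}\n\n"
                f"Q {fam.family_id:<15s} {start} {'X' * 10} {end} ({fam.query_length})\n"
                f"T {hit.hit_id:<15s} 1 {'X' * 10} {cols} ({cols + 20})\n\n"
            )
        fh.write("Done!\n")


def _write_links(outdir: Path, spec: FixtureSpec, families: list[PlannedFamily]) -> tuple[int, int]:
    pool = _sf_pool()
    n_direct, n_indirect = spec.link_spec
    mapdir = outdir / "mappings"
    mapdir.mkdir(exist_ok=True)
    with (mapdir / "direct_map.tsv").open("w") as fh:
        fh.write("# family_id\tsuperfamily_id\n")
        for i in range(n_direct):
            fh.write(f"PFD{i + 1:05d}\t{pool[i % len(pool)]}\n")
    rng = _rng(spec.seed, "mappings/family_links.tsv")
    indirect_fams = [f for f in families if f.indirect_via is not None]
    with (mapdir / "family_links.tsv").open("w") as fh:
        fh.write("# family_a\tfamily_b\tzscore\tcoverage_a\tcoverage_b\n")
        for fam in indirect_fams:
            z = round(float(rng.uniform(9.0, 15.0)), 1)
            cov_a = round(float(rng.uniform(0.80, 0.99)), 2)
            cov_b = round(float(rng.uniform(0.80, 0.99)), 2)
            fh.write(f"{fam.family_id}\t{fam.indirect_via}\t{z}\t{cov_a}\t{cov_b}\n")
        if indirect_fams:
            # sub-threshold decoy link: must not create or break anything
            fam = indirect_fams[0]
            other = f"PFD{min(2, n_direct):05d}"
            fh.write(f"{fam.family_id}\t{other}\t8.0\t0.95\t0.95\n")
    return n_direct, n_indirect


def _write_annotations(outdir: Path) -> None:
    pool = _sf_pool()
    anndir = outdir / "annotations"
    anndir.mkdir(exist_ok=True)
    namespaces = ("molecular_function", "biological_process", "cellular_component")
    with (anndir / "dcgo.tsv").open("w") as fh:
        fh.write("# superfamily_id\tgo_id\tnamespace\tic\n")
        for i, sf in enumerate(pool):
            for j, ic in enumerate((2.5, 1.8, 1.5, 1.2)):
                go = f"GO:{i * 10 + j:07d}"
                fh.write(f"{sf}\t{go}\t{namespaces[(i + j) % 3]}\t{ic}\n")
    with (anndir / "pdb_scop.tsv").open("w") as fh, (
        anndir / "pdb_ec.tsv"
    ).open("w") as fe:
        fh.write("# pdb_chain\tdomain_sid\tsccs\n")
        fe.write("# pdb_chain\tec_number\n")
        for i, sf in enumerate(pool):
            single = f"{1000 + i}X_A"
            fh.write(f"{single}\te{i:04d}a_\t{sf}.1\n")
            fe.write(f"{single}\t{(i % 7) + 1}.1.1.{(i % 9) + 1}\n")
            multi = f"{1000 + i}X_B"
            fh.write(f"{multi}\te{i:04d}b_\t{sf}.1\n")
            fh.write(f"{multi}\te{i:04d}c_\t{pool[(i + 1) % len(pool)]}.1\n")
            fe.write(f"{multi}\t{(i % 7) + 1}.2.1.1\n")
    with (anndir / "tax_nodes.dmp").open("w") as fh:
        for taxid, parent, rank, _name in _TAX_NODES:
            fh.write(f"{taxid}\t|\t{parent}\t|\t{rank}\n")
    with (anndir / "tax_names.dmp").open("w") as fh:
        for taxid, _parent, _rank, name in _TAX_NODES:
            fh.write(f"{taxid}\t|\t{name}\n")


def _write_bundle(spec: FixtureSpec, families: list[PlannedFamily], outdir: Path) -> FixtureManifest:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalog, _ = _build_catalog(spec.scop_catalog_size)
    catalog.write(outdir / "scop_catalog.tsv")

    from .search_io import write_family_table

    write_family_table(
        [
            FamilyRecord(f.family_id, f.query_length, list(f.member_taxa))
            for f in families
        ],
        outdir / "families.tsv",
    )

    hitdir = outdir / "hits"
    hitdir.mkdir(exist_ok=True)
    per_file: dict[str, list[tuple[PlannedFamily, PlannedHit]]] = {
        "nrichd_hmmsearch": [],
        "nrichd_jackhmmer": [],
        "superfamily_db": [],
        "supfam_plus": [],
        "pdomthreader": [],
    }
    hh_by_family: dict[str, list[PlannedHit]] = {}
    per_method_hits: dict[str, int] = {m.value: 0 for m in METHODS}
    for fam in families:
        for hit in fam.hits:
            per_method_hits[hit.method.value] += 1
            if hit.method is Method.NRICHD:
                key = hit.source_pass if hit.source_pass in per_file else "nrichd_hmmsearch"
                per_file[key].append((fam, hit))
            elif hit.method is Method.HHSEARCH:
                hh_by_family.setdefault(fam.family_id, []).append(hit)
            else:
                per_file[hit.method.value].append((fam, hit))

    _write_domtbl(hitdir / "nrichd_hmmsearch.domtbl", per_file["nrichd_hmmsearch"], hmm_query=True)
    _write_domtbl(hitdir / "nrichd_jackhmmer.domtbl", per_file["nrichd_jackhmmer"], hmm_query=True)
    _write_domtbl(hitdir / "superfamily_db.domtbl", per_file["superfamily_db"], hmm_query=False)
    _write_score_table(hitdir / "supfam_plus.tsv", per_file["supfam_plus"])
    _write_score_table(hitdir / "pdomthreader.tsv", per_file["pdomthreader"])
    hh_dir = hitdir / "hhsearch"
    hh_dir.mkdir(exist_ok=True)
    fam_by_id = {f.family_id: f for f in families}
    for family_id in sorted(hh_by_family):
        _write_hhr(hh_dir / f"{family_id}.hhr", fam_by_id[family_id], hh_by_family[family_id])

    n_direct, n_indirect = _write_links(outdir, spec, families)
    _write_annotations(outdir)

    manifest = FixtureManifest(
        spec=spec,
        families=families,
        per_method_hits=per_method_hits,
        n_direct=n_direct,
        n_indirect_expected=n_indirect,
        outdir=outdir,
    )
    with (outdir / "manifest.json").open("w") as fh:
        json.dump(manifest.to_json_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    with (outdir / "manifest.tsv").open("w") as fh:
        fh.write(
            "# family_id\tsuperfamily_id\texpected_outcome\tn_methods\tmethods"
            "\ttier\tkingdoms\n"
        )
        for fam in families:
            exp = fam.expected_outcome()
            tier = {5: "high", 4: "high", 3: "medium", 2: "medium", 1: "low", 0: "-"}[
                exp["n_methods"]
            ]
            fh.write(
                f"{fam.family_id}\t{exp['superfamily_id'] or '-'}\t{exp['outcome']}\t"
                f"{exp['n_methods']}\t{';'.join(exp.get('methods', []))}\t{tier}\t"
                f"{'+'.join(fam.kingdoms)}\n"
            )
    return manifest


def _build(spec: FixtureSpec) -> list[PlannedFamily]:
    _, by_sf = _build_catalog(spec.scop_catalog_size)
    families = _plan_families(spec, by_sf)
    _draw_scores(spec, families)
    return families


def generate(spec: FixtureSpec, outdir: str | Path) -> FixtureManifest:
    """Write a complete, deterministic input bundle and its manifest."""
    spec.validate()
    return _write_bundle(spec, _build(spec), Path(outdir))


def perturb(
    manifest: FixtureManifest,
    kind: str,
    fraction: float,
    seed: int,
    outdir: str | Path,
) -> FixtureManifest:
    """Rewrite a bundle with targeted corruption and an updated manifest.

    ``flip_superfamily``  dissenting hits of conflicted/outvoted families
                          are flipped to the family's intended superfamily
    ``shrink_region``     coverage-filtered methods' hits shrink below the
                          60 % coverage floor and stop passing
    ``inflate_evalue``    enriched-database hits get E = 0.01 and stop
                          passing the E-value filter

    ``fraction`` of eligible families (rounded up, deterministic under
    ``seed``) are perturbed; fraction 0 reproduces the bundle unchanged.
    """
    if kind not in ("flip_superfamily", "shrink_region", "inflate_evalue"):
        raise ValueError(f"unknown perturbation kind {kind!r}")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    families = _build(manifest.spec)  # fresh deterministic copy
    rng = np.random.default_rng([seed, zlib.crc32(kind.encode())])

    def eligible(fam: PlannedFamily) -> bool:
        if kind == "inflate_evalue":
            return any(h.method is Method.NRICHD for h in fam.hits)
        if kind == "shrink_region":
            return any(h.coverage_sensitive and h.passes for h in fam.hits)
        intended = fam.superfamily_id
        return intended is not None and any(
            h.passes and parse_sccs(h.sccs).superfamily_id != intended for h in fam.hits
        )

    candidates = [f for f in families if eligible(f)]
    n_pick = int(np.ceil(fraction * len(candidates))) if fraction > 0 else 0
    picked = set(
        rng.choice(len(candidates), size=min(n_pick, len(candidates)), replace=False)
    ) if candidates else set()
    _, by_sf = _build_catalog(manifest.spec.scop_catalog_size)
    for idx in picked:
        fam = candidates[idx]
        if kind == "inflate_evalue":
            for hit in fam.hits:
                if hit.method is Method.NRICHD:
                    hit.score = 0.01
                    hit.passes = False
        elif kind == "shrink_region":
            for hit in fam.hits:
                if hit.coverage_sensitive:
                    start = hit.region[0]
                    hit.region = (start, start + int(0.3 * fam.query_length))
                    if hit.passes:
                        hit.passes = False
        else:  # flip_superfamily
            intended = fam.superfamily_id
            for hit in fam.hits:
                if hit.passes and parse_sccs(hit.sccs).superfamily_id != intended:
                    hit.sccs = f"{intended}.1"
                    hit.hit_id = by_sf[intended][0]
    return _write_bundle(manifest.spec, families, Path(outdir))
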