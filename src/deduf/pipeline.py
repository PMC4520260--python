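"""End-to-end orchestration: read -> filter -> resolve -> combine -> annotate.

The pipeline is a pure function of its inputs: rerunning on identical
files produces identical outputs.  Every stage logs its counts; the
machine-readable summary lands in ``summary.json`` under the output
directory next to the stage TSVs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import annotation as ann
from .config import RunConfig, Thresholds
from .consensus import ConsensusRecord, ExclusionRecord, RunSummary, combine_all, tally
from .resolve import (
    MethodAssignment,
    Status,
    derive_indirect,
    resolve_method,
)
from .scop import ScopCatalog
from .search_io import (
    DomainHit,
    FamilyRecord,
    Method,
    pool_hits,
    read_direct_map,
    read_domtbl,
    read_family_table,
    read_hhr_dir,
    read_link_table,
    read_score_table,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "config_for_bundle", "read_method_hits"]


@dataclass
class PipelineResult:
    assignments: list[MethodAssignment]
    records: list[ConsensusRecord]
    exclusions: list[ExclusionRecord]
    summary: RunSummary
    hits_by_method: dict[Method, list[DomainHit]] = field(default_factory=dict)


def read_method_hits(
    config: RunConfig,
    families: dict[str, FamilyRecord],
    catalog: ScopCatalog,
) -> dict[Method, list[DomainHit]]:
    """Read every configured hit file into per-method pooled hit lists."""
    hits: dict[Method, list[DomainHit]] = {}
    if config.nrichd_domtbl:
        bundles = [
            read_domtbl(path, Method.NRICHD, families, catalog)
            for path in config.nrichd_domtbl
        ]
        hits[Method.NRICHD] = pool_hits(*bundles)
    if config.superfamily_domtbl is not None:
        hits[Method.SUPERFAMILY_DB] = read_domtbl(
            config.superfamily_domtbl, Method.SUPERFAMILY_DB, families, catalog
        )
    if config.hhsearch_dir is not None:
        hits[Method.HHSEARCH] = read_hhr_dir(config.hhsearch_dir, families, catalog)
    if config.supfam_plus_table is not None:
        hits[Method.SUPFAM_PLUS] = read_score_table(
            config.supfam_plus_table, Method.SUPFAM_PLUS, families, catalog
        )
    if config.pdomthreader_table is not None:
        hits[Method.PDOMTHREADER] = read_score_table(
            config.pdomthreader_table, Method.PDOMTHREADER, families, catalog
        )
    for method, bundle in hits.items():
        logger.info("read %d %s hits (pre-filter)", len(bundle), method.value)
    return hits


def _indirect_assignments(
    config: RunConfig,
    families: dict[str, FamilyRecord],
    assignments: list[MethodAssignment],
    thresholds: Thresholds,
) -> tuple[list[MethodAssignment], dict[str, int]]:
    """Superfamily assignments inherited through qualifying family links.

    Only families with no direct profile–profile verdict are eligible;
    the assignment spans the whole query (links are whole-profile
    matches, not local alignments).
    """
    if config.direct_map is None or config.family_links is None:
        return [], {}
    direct = read_direct_map(config.direct_map)
    links = read_link_table(config.family_links)
    indirect = derive_indirect(direct, links, thresholds)
    have_direct = {
        a.query_id
        for a in assignments
        if a.method is Method.SUPFAM_PLUS and a.status is Status.ASSIGNED
    }
    extra: list[MethodAssignment] = []
    for family_id, superfamily_id in indirect.items():
        if family_id not in families or family_id in have_direct:
            continue
        fam = families[family_id]
        via = sorted(
            link.partner(family_id)
            for link in links
            if family_id in (link.family_a, link.family_b)
            and link.partner(family_id) in direct
        )
        extra.append(
            MethodAssignment(
                query_id=family_id,
                method=Method.SUPFAM_PLUS,
                region=(1, fam.query_length),
                superfamily_id=superfamily_id,
                n_support=len(via),
                best_score=None,
                status=Status.ASSIGNED,
                provenance=tuple(via),
                origin="indirect",
            )
        )
    counts = {
        "n_direct_mappings": len(direct),
        "n_indirect_mappings": len(indirect),
        "n_total_mappings": len(direct) + len(indirect),
        "n_indirect_assignments": len(extra),
    }
    logger.info(
        "family->superfamily mapping ledger: %d direct + %d indirect = %d",
        len(direct), len(indirect), len(direct) + len(indirect),
    )
    return extra, counts


def _write_assignments(path: Path, assignments: list[MethodAssignment]) -> None:
    with path.open("w") as fh:
        fh.write(
            "# query_id\tmethod\tstart\tend\tsuperfamily_id\tn_support\t"
            "best_score\tstatus\torigin\n"
        )
        for a in assignments:
            score = "" if a.best_score is None else repr(a.best_score)
            fh.write(
                f"{a.query_id}\t{a.method.value}\t{a.region[0]}\t{a.region[1]}\t"
                f"{a.superfamily_id or '-'}\t{a.n_support}\t{score}\t"
                f"{a.status.value}\t{a.origin}\n"
            )


def _write_consensus(path: Path, records: list[ConsensusRecord]) -> None:
    with path.open("w") as fh:
        fh.write(
            "# family_id\tstart\tend\tsuperfamily_id\tmethods\tn_methods\t"
            "confidence\toutvoted_method\n"
        )
        for r in records:
            outvoted = r.outvoted_method.value if r.outvoted_method else "-"
            fh.write(
                f"{r.query_id}\t{r.region[0]}\t{r.region[1]}\t{r.superfamily_id}\t"
                f"{';'.join(m.value for m in r.methods)}\t{r.n_methods}\t"
                f"{r.confidence.value}\t{outvoted}\n"
            )


def _write_exclusions(path: Path, exclusions: list[ExclusionRecord]) -> None:
    with path.open("w") as fh:
        fh.write("# family_id\tstart\tend\tsuperfamilies\tsame_fold\tmethods\n")
        for e in exclusions:
            fh.write(
                f"{e.query_id}\t{e.region[0]}\t{e.region[1]}\t"
                f"{';'.join(e.superfamilies_in_conflict)}\t"
                f"{str(e.same_fold).lower()}\t"
                f"{';'.join(m.value for m in e.methods)}\n"
            )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full stage pipeline and write all outputs.

    Stages: read hit files -> per-method filter + decision trees ->
    indirect mappings -> cross-method consensus -> annotation -> tally.
    """
    config.validate()
    logger.info("effective thresholds: %s", config.thresholds)
    catalog = ScopCatalog.from_file(config.catalog)
    families = read_family_table(config.families)
    thresholds = config.thresholds

    hits = read_method_hits(config, families, catalog)
    assignments: list[MethodAssignment] = []
    for method in Method:
        if method in hits:
            resolved = resolve_method(hits[method], thresholds)
            n_assigned = sum(1 for a in resolved if a.status is Status.ASSIGNED)
            logger.info(
                "%s: %d region verdicts (%d assigned, %d unresolved)",
                method.value, len(resolved), n_assigned, len(resolved) - n_assigned,
            )
            assignments.extend(resolved)

    indirect_extra, mapping_counts = _indirect_assignments(
        config, families, assignments, thresholds
    )
    assignments.extend(indirect_extra)

    assigned = [a for a in assignments if a.status is Status.ASSIGNED]
    records, exclusions = combine_all(assigned, thresholds.overlap_frac)
    summary = tally(records, exclusions)
    summary.extras.update(mapping_counts)
    summary.extras["pre_filter_hits"] = {
        m.value: len(bundle) for m, bundle in hits.items()
    }
    summary.extras["n_unresolved"] = len(assignments) - len(assigned)

    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    _write_assignments(out / "assignments.tsv", assignments)
    _write_consensus(out / "consensus.tsv", records)
    _write_exclusions(out / "exclusions.tsv", exclusions)

    annotated = _maybe_annotate(config, families, records)
    if annotated is not None:
        annotated.to_csv(out / "annotated.tsv", sep="\t", index=False)

    with (out / "summary.json").open("w") as fh:
        json.dump(summary.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    logger.info(
        "consensus: %d families (%d records), %d ambiguous regions excluded",
        summary.total_families, summary.n_records, summary.n_exclusion_regions,
    )
    return PipelineResult(assignments, records, exclusions, summary, hits)


def _maybe_annotate(
    config: RunConfig,
    families: dict[str, FamilyRecord],
    records: list[ConsensusRecord],
):
    dcgo = ec = scop_tbl = taxonomy = None
    if config.dcgo_table is not None:
        dcgo = ann.read_dcgo_table(config.dcgo_table)
    if config.pdb_ec_table is not None and config.pdb_scop_table is not None:
        ec = ann.read_pdb_ec_table(config.pdb_ec_table)
        scop_tbl = ann.read_pdb_scop_table(config.pdb_scop_table)
    if config.tax_nodes is not None and config.tax_names is not None:
        taxonomy = ann.Taxonomy.from_dump(config.tax_nodes, config.tax_names)
    if dcgo is None and ec is None and taxonomy is None:
        return None
    return ann.annotate_records(
        records,
        families,
        dcgo_table=dcgo,
        pdb_ec_table=ec,
        pdb_scop_table=scop_tbl,
        taxonomy=taxonomy,
        ic_threshold=config.thresholds.ic_min,
    )


def config_for_bundle(
    bundle_dir: str | Path,
    out_dir: Optional[str | Path] = None,
    thresholds: Optional[Thresholds] = None,
    with_annotations: bool = True,
) -> RunConfig:
    """RunConfig for a synthetic bundle laid out by :mod:`deduf.fixtures`."""
    bundle = Path(bundle_dir)
    out = Path(out_dir) if out_dir is not None else bundle / "out"
    kwargs = {}
    if with_annotations:
        kwargs = dict(
            dcgo_table=bundle / "annotations" / "dcgo.tsv",
            pdb_ec_table=bundle / "annotations" / "pdb_ec.tsv",
            pdb_scop_table=bundle / "annotations" / "pdb_scop.tsv",
            tax_nodes=bundle / "annotations" / "tax_nodes.dmp",
            tax_names=bundle / "annotations" / "tax_names.dmp",
        )
    return RunConfig(
        catalog=bundle / "scop_catalog.tsv",
        families=bundle / "families.tsv",
        out_dir=out,
        nrichd_domtbl=[
            bundle / "hits" / "nrichd_hmmsearch.domtbl",
            bundle / "hits" / "nrichd_jackhmmer.domtbl",
        ],
        superfamily_domtbl=bundle / "hits" / "superfamily_db.domtbl",
        hhsearch_dir=bundle / "hits" / "hhsearch",
        supfam_plus_table=bundle / "hits" / "supfam_plus.tsv",
        pdomthreader_table=bundle / "hits" / "pdomthreader.tsv",
        family_links=bundle / "mappings" / "family_links.tsv",
        direct_map=bundle / "mappings" / "direct_map.tsv",
        thresholds=thresholds or Thresholds(),
        **kwargs,
    )
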