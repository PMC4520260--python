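# Methods

## Scope and model of the data

`deduf` is a post-processing engine: it never runs a search program.  Its
unit of evidence is a *hit* — one alignment of a query family against a
structural domain of known SCOP classification — read from the native
output of five search strategies (HMMER3 per-domain tables in both the
hmmsearch and hmmscan orientations, HHsearch `.hhr` summary tables, and
tab-delimited Z-score / P-value tables).  Readers are total and
threshold-free: every data row becomes a `DomainHit` except hits whose
target has no SCOP mapping, which are dropped with a logged count (such
templates cannot contribute a superfamily and are excluded before any
filtering, so they never distort frequency-based rules).

Coordinates are 1-based inclusive on the query throughout and are never
converted.  For HMMER tables the query-side alignment span is taken from
whichever coordinate pair lies on the query in that dialect (the hmm
columns for hmmsearch, where the query is the profile; the ali columns
for hmmscan, where the query is the sequence) — Biopython's SearchIO
resolves this.  For `.hhr` files, hits are taken one per summary-table
row in file order, with the E-value column and the Query-HMM span; a
malformed or truncated summary row is a read error naming the line.
HMMER's *full-sequence* E-value is the filtering score; the per-domain
conditional E-values are never used.  Pooled passes of one method
(hmmsearch + jackhmmer, enriched + natural database) are concatenated
without deduplication, because the decision trees below count hit
frequencies over the pool.  Only the final-iteration jackhmmer table is
consumed.

## Acceptance filters

Per hit, boundary-inclusive, exact decimal comparisons (thresholds are
contracts on parsed decimals, not approximate quantities):

| parameter | default | unit | applies to |
|---|---|---|---|
| `evalue_max` | 0.001 | E-value | nrichd, superfamily_db, hhsearch |
| `zscore_min` | 7.5 | Z | supfam_plus |
| `pvalue_max` | 1e-5 | P (with tag CERTAIN, conjunctive) | pdomthreader |
| `coverage_min` | 0.60 | fraction of query length | nrichd, supfam_plus |
| `link_zscore_min` / `link_coverage_min` | 9.0 / 0.80 | Z, fraction (both sides) | family links |
| `evalue_count_margin` | 10 (strict >) | hit count | E-value tree rule (iii) |
| `zscore_fold_margin` / `zscore_class_margin` | 4.0 / 6.0 (inclusive ≥) | Z | Z tree rules 3–4 |
| `overlap_frac` | 0.60 | fraction of either region | region grouping and consensus |
| `ic_min` | 1.5 | information content | GO transfer |

The asymmetry between the strict count margin and the inclusive Z
margins mirrors the protocol as published ("more than ten" vs. "≥ 4",
"≥ 6") and is kept deliberately.

## Decision trees

Hits for one (query, method) are clustered into domain-region groups by
single-linkage on the 60 %-of-either-region overlap rule; chained
overlaps merge transitively.  Each group resolves independently
("different domain regions, both predictions retained"):

* **E-value cascade** — (i) one superfamily → assigned, representative =
  lowest E, ties broken by larger coverage then lexicographic hit id;
  (ii) several superfamilies, one fold → modal superfamily; (iii)
  several folds or classes → modal superfamily iff its count leads the
  runner-up by > 10, else unresolved.
* **Z cascade** — (1) one superfamily → highest-Z hit; (2) one fold →
  modal; (3) several folds, one class → the superfamily with the top
  best-Z iff its lead over the runner-up best-Z is ≥ 4; (4) any
  cross-class pair present → same with margin ≥ 6.
* **Frequency rule** (threading) — modal superfamily.

Design choices where the published wording is open:

* Ties for the mode are left **unresolved** (conservative; the protocol
  never adjudicates ties).
* "Lowest E-value and maximum coverage" can conflict; E-value is
  primary — it is the method's significance measure — coverage
  secondary, hit id a deterministic tertiary tie-break.
* Groups mixing shared and unshared folds fall to the most general
  applicable rule: any fold heterogeneity invokes the margin rules, any
  cross-class pair invokes the class margin.
* The E-value tree uses one margin for fold- and class-level
  disagreement, as printed; only the Z tree distinguishes the two.
* Indirect mappings are **one hop**: an unmapped family inherits a
  superfamily only when all its qualifying links into directly-mapped
  families agree on exactly one superfamily.  No chaining through other
  indirect families (minimal reading of "direct or indirect").
  Pipeline-level indirect assignments span the whole query, since
  family links are whole-profile matches without local coordinates.

Every assigned superfamily is the superfamily of at least one supporting
hit; `n_support`, the supporting hit ids and the envelope of supporting
regions are carried for audit.

## Consensus and confidence

Per query, assigned verdicts merge by the same overlap rule.  Within a
group: unanimity → a consensus record (region = min-start/max-end
envelope, preserving all evidence); exactly four methods against one →
the majority superfamily is kept, the dissenter recorded (with a flag
when the dissenting superfamily shares the majority fold); anything else
(1v1, 2v1, 3v1, 2v2, 3v2) → an exclusion record listing the conflicting
superfamilies, flagged `same_fold` when they all share a fold.
Agreement is tested at **superfamily** level: same-fold conflicts are
still excluded, only reported separately.  Two verdicts from one method
in one region group indicate an upstream failure and abort the run.
Confidence is purely the count of agreeing methods: ≥ 4 high, 2–3
medium, 1 low.

The tally reports records and exclusions at both granularities (region
groups and distinct families), since ambiguity can reasonably be counted
either way; per-method bookkeeping satisfies
`assigned_pre_consensus = retained + discarded` by construction, with
the outvoted dissenter counting as discarded.

## Benchmark statistics

Correctness is scored at fold level: a predicted superfamily whose fold
matches any known fold of the benchmark family counts as TP (permissive
matching for multi-domain truth), otherwise FP.  N_total is the size of
the truth set, so missing predictions lower the success rate but not the
precision; with no predictions at all, precision and error are reported
as not-applicable rather than zero.  Benchmark queries lacking SCOP
definitions are excluded from the truth set and logged.  The identities
`precision + error = 100` and `success = precision·(TP+FP)/N_total` hold
exactly whenever defined and are property-tested.

## Annotation transfer

GO terms come from a flat domain-centric table (superfamily, GO id,
namespace, IC); only IC ≥ 1.5 terms transfer, sorted by descending IC
(GO id breaks ties deterministically).  The ontology-graph reasoning
that produces the table is upstream and out of scope.  EC numbers
transfer only from PDB chains carrying exactly one SCOP domain in the
superfamily — on a multi-domain chain the activity cannot be attributed
to one domain.  "Kingdom" is the superkingdom/domain-rank ancestor in an
NCBI-style taxonomy dump, with Viruses as its own division
(Archaea/Bacteria/Eukaryota/Viruses); member taxids missing from the
taxonomy are skipped and counted, and a cyclic or multi-rooted taxonomy
is rejected at load.

## The synthetic-data generator

`deduf.fixtures` emulates a complete study's *bookkeeping structure*:
which methods support which family, where conflicts sit, how many
mappings are direct vs. indirect, and which kingdoms a family spans.  It
writes every input dialect (both HMMER orientations, `.hhr` with summary
table and alignment blocks, score tables, catalog, family/mapping/
annotation tables) plus a manifest predicting each family's outcome.

What it deliberately does **not** emulate: sequence content, realistic
score or length distributions (scores are sampled only to sit robustly
on the intended side of each filter), SCOP's real size and shape (the
generated catalog is a balanced 4-class × 3-fold × 2-superfamily grid so
every lineage relation the decision trees branch on is represented), or
correlated errors between methods.  Passing tests on these bundles
therefore demonstrate that the *rules* are implemented faithfully — the
arithmetic of filtering, resolution, exclusion and tiering — not that
the upstream searches would achieve any particular sensitivity on real
sequences.

Determinism: every output file draws from its own pseudo-random stream
keyed by (seed, filename), so adding a file never shifts the others, and
identical specs produce byte-identical bundles.  Supporting hits for one
family share a region (start jitter ≤ 8 residues at ≥ 70 % coverage), so
they always satisfy the 60 % overlap rule; conflicting hits use a
different-class superfamily so the conflict is unambiguous.  Each
method's file also carries one sub-threshold decoy hit (and the link
table one sub-threshold link) that must be read and then removed by the
filters — exercising the reader/filter separation without affecting
outcomes.  `perturb` rebuilds a bundle with targeted corruption
(flipping dissenting superfamilies, shrinking regions below the coverage
floor, inflating E-values past the cutoff) and updates the manifest's
predictions accordingly.

## Problem sizes used in tests and the acceptance script

The published headline counts depend on live searches against the full
Pfam/SCOP-era databases and cannot be recomputed from raw data here;
what *can* be recomputed exactly is the bookkeeping that turns
per-method verdicts into those counts.  The test suite and
`scripts/acceptance.py` therefore run the full pipeline over bundles
encoding the published marginals — the 614-family tier histogram
(15/39/50/89/421), the four per-method (assigned, conflicting) pairs,
and the 5,002 + 278 mapping ledger — and additionally sweep all three
decision trees against a brute-force rule interpreter over ~10⁴ hit
multisets (every superfamily/fold/class relation pattern, all hit-count
compositions up to 15 hits, Z-margin boundary score patterns), and check
manifest fidelity end-to-end over 100 randomly specified bundles.  All
of this completes in well under a minute.

## Known limitations

* One SCOP catalog per run; reconciling hit identifiers across catalog
  versions is the caller's responsibility.
* `.hhr` hits are taken per summary row, not best-per-template.
* The consensus never re-adjudicates exclusions by score magnitude, and
  clan information is carried as metadata only.
* The generator's manifest predictor operates at the level of intended
  per-method support; it is meaningful because the pipeline must
  reproduce it from the *written files* through independent code paths
  (parsers, filters, trees, merge), but it shares the rule definitions
  with the package and is not an external reference.
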