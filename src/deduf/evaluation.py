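"""Benchmark scoring of fold assignments against families of known structure.

Correctness is judged at the SCOP *fold* level: a predicted superfamily
is a correct assignment when its fold matches the fold of the family's
known domain (any known fold, for multi-domain truth).  Three statistics
are reported as percentages:

    success rate = 100 * TP / N_total
    precision    = 100 * TP / (TP + FP)
    error rate   = 100 * FP / (TP + FP)

where N_total counts all benchmark queries, so queries with no prediction
lower the success rate but not the precision.  With no predictions at
all, precision and error are undefined (reported as not-applicable,
never as zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from .scop import ScopLineage, parse_sccs

__all__ = [
    "EvaluationResult",
    "score_fold",
    "evaluate",
    "read_predictions",
    "read_truth",
]

TruthValue = Union[ScopLineage, Sequence[ScopLineage]]


@dataclass(frozen=True)
class EvaluationResult:
    """TP/FP tallies and the three benchmark percentages."""

    tp: int
    fp: int
    n_total: int
    success_rate: float
    precision: Optional[float]
    error_rate: Optional[float]

    def row(self, label: str = "") -> str:
        """A report-table row: label, TP, FP, N, success, precision, error."""
        prec = "N/A" if self.precision is None else f"{self.precision:.1f}"
        err = "N/A" if self.error_rate is None else f"{self.error_rate:.1f}"
        return (
            f"{label}\t{self.tp}\t{self.fp}\t{self.n_total}\t"
            f"{self.success_rate:.1f}\t{prec}\t{err}"
        )


def score_fold(prediction: ScopLineage, truth: ScopLineage) -> bool:
    """True when prediction and truth share a SCOP fold (superfamily may differ)."""
    return prediction.fold_id == truth.fold_id


def _truth_folds(value: TruthValue) -> set[str]:
    if isinstance(value, ScopLineage):
        return {value.fold_id}
    return {lin.fold_id for lin in value}


def evaluate(
    predictions: Mapping[str, Optional[ScopLineage]],
    truth: Mapping[str, TruthValue],
) -> EvaluationResult:
    """Score fold predictions against known-structure families.

    ``truth`` defines the benchmark: N_total = len(truth).  A query may
    map to several known folds (multi-domain families); matching any of
    them counts as correct.  Predictions for queries absent from the
    truth set are an error.  ``None`` predictions are treated as absent.
    """
    unknown = [q for q in predictions if q not in truth]
    if unknown:
        raise ValueError(f"predictions for queries outside the truth set: {sorted(unknown)[:5]}")
    tp = fp = 0
    for query, predicted in predictions.items():
        if predicted is None:
            continue
        if predicted.fold_id in _truth_folds(truth[query]):
            tp += 1
        else:
            fp += 1
    n_total = len(truth)
    success = 100.0 * tp / n_total if n_total else 0.0
    if tp + fp > 0:
        precision: Optional[float] = 100.0 * tp / (tp + fp)
        error: Optional[float] = 100.0 * fp / (tp + fp)
    else:
        precision = error = None
    return EvaluationResult(tp, fp, n_total, success, precision, error)


def read_predictions(path: str | Path) -> dict[str, Optional[ScopLineage]]:
    """Predictions TSV: family_id, sccs (``-`` for an explicit no-call)."""
    predictions: dict[str, Optional[ScopLineage]] = {}
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            predictions[parts[0]] = None if parts[1] in ("-", "") else parse_sccs(parts[1])
    return predictions


def read_truth(path: str | Path) -> dict[str, list[ScopLineage]]:
    """Truth TSV: family_id followed by one sccs per known domain."""
    truth: dict[str, list[ScopLineage]] = {}
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            truth[parts[0]] = [parse_sccs(p) for p in parts[1:] if p and p != "-"]
    return truth
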