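"""Score detector predictions against the planted insertion.

The classification scheme: a non-reference prediction is "within-N" of the
truth when it matches the truth's chromosome, family, and strand, and both its
start and its end lie within N bp of the truth TSD interval's start and end
respectively. Within-0 therefore means identical coordinates. Per replicate,
at most one within-N prediction counts as the true positive; every other
non-reference prediction is a false positive; a replicate with no within-N
prediction is the (single) false negative. Across replicates,
recall = TP/(TP+FN) and precision = TP/(TP+FP).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .core_io import MetricsRow, Prediction, TruthRecord

__all__ = [
    "MatchTally",
    "ReplicateResult",
    "classify_within_n",
    "tally_replicate",
    "metrics_from_tallies",
    "precision_recall_curve",
]


def classify_within_n(
    truth: TruthRecord,
    prediction: Prediction,
    n: int,
    ignore_strand: bool = False,
) -> bool:
    """True iff the prediction is a within-N call for the planted insertion.

    Both endpoints are tested symmetrically against the truth TSD interval.
    A "." strand on the prediction is a mismatch unless ``ignore_strand``.
    """
    if n < 0:
        raise ValueError("window size must be >= 0")
    if prediction.chrom != truth.chrom:
        return False
    if prediction.family != truth.family:
        return False
    if not ignore_strand and prediction.strand != truth.strand:
        return False
    return (
        abs(prediction.start - truth.tsd_start) <= n
        and abs(prediction.end - truth.tsd_end) <= n
    )


@dataclass
class MatchTally:
    """Per-window TP/FP/FN for one replicate, plus raw prediction counts."""

    tp: dict[int, int]
    fp: dict[int, int]
    fn: dict[int, int]
    matched: dict[int, Optional[Prediction]]
    n_nonref: int
    n_ref: int


@dataclass
class ReplicateResult:
    replicate: int
    coverage: float
    truth: TruthRecord
    tally: MatchTally
    failed: bool = False


def tally_replicate(
    truth: TruthRecord,
    predictions: Sequence[Prediction],
    windows: Sequence[int],
    ignore_strand: bool = False,
) -> MatchTally:
    """Classify one replicate's predictions at every window size.

    Only non-reference predictions enter TP/FP/FN; reference-category calls
    are counted for the mean-count summaries only. When several predictions
    match within-N, the nearest by start is recorded as the match but only one
    is the TP — the rest are FPs.
    """
    if not windows:
        raise ValueError("windows must be non-empty")
    nonref = [p for p in predictions if p.category == "non-reference"]
    n_ref = sum(1 for p in predictions if p.category == "reference")
    tp: dict[int, int] = {}
    fp: dict[int, int] = {}
    fn: dict[int, int] = {}
    matched: dict[int, Optional[Prediction]] = {}
    for n in windows:
        hits = [p for p in nonref if classify_within_n(truth, p, n, ignore_strand)]
        if hits:
            tp[n] = 1
            fn[n] = 0
            matched[n] = min(hits, key=lambda p: (abs(p.start - truth.tsd_start), p.start))
        else:
            tp[n] = 0
            fn[n] = 1
            matched[n] = None
        fp[n] = len(nonref) - tp[n]
    return MatchTally(tp, fp, fn, matched, n_nonref=len(nonref), n_ref=n_ref)


def metrics_from_tallies(
    tallies: Sequence[MatchTally], windows: Optional[Sequence[int]] = None
) -> list[MetricsRow]:
    """Pool replicate tallies into recall/precision per window size.

    Precision is undefined (None, written as an empty CSV cell) when no
    positive call was made at all, never silently zero.
    """
    if not tallies:
        raise ValueError("at least one replicate is required")
    if windows is None:
        windows = sorted(tallies[0].tp)
    n_rep = len(tallies)
    mean_nonref = sum(t.n_nonref for t in tallies) / n_rep
    mean_ref = sum(t.n_ref for t in tallies) / n_rep
    rows = []
    for n in windows:
        tp = sum(t.tp[n] for t in tallies)
        fp = sum(t.fp[n] for t in tallies)
        fn = sum(t.fn[n] for t in tallies)
        recall = tp / (tp + fn) if tp + fn > 0 else None
        precision = tp / (tp + fp) if tp + fp > 0 else None
        rows.append(
            MetricsRow(
                window=n,
                tp=tp,
                fp=fp,
                fn=fn,
                recall=recall,
                precision=precision,
                mean_nonref=mean_nonref,
                mean_ref=mean_ref,
            )
        )
    return rows


def precision_recall_curve(results: Sequence[ReplicateResult]) -> pd.DataFrame:
    """Long-format table of metrics per (coverage, window).

    One row per combination, sorted by coverage then window; failed replicates
    are excluded from the pooling and counted in the ``n_failed`` column.
    """
    if not results:
        raise ValueError("no replicate results")
    frames = []
    for coverage in sorted({r.coverage for r in results}):
        group = [r for r in results if r.coverage == coverage]
        ok = [r for r in group if not r.failed]
        n_failed = len(group) - len(ok)
        if not ok:
            continue
        for row in metrics_from_tallies([r.tally for r in ok]):
            frames.append(
                {
                    "coverage": coverage,
                    "window": row.window,
                    "TP": row.tp,
                    "FP": row.fp,
                    "FN": row.fn,
                    "recall": math.nan if row.recall is None else row.recall,
                    "precision": math.nan if row.precision is None else row.precision,
                    "mean_nonref": row.mean_nonref,
                    "mean_ref": row.mean_ref,
                    "n_replicates": len(ok),
                    "n_failed": n_failed,
                }
            )
    return pd.DataFrame(frames)
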