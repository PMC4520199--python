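"""Ground-truth benchmarking of a contig ranking.

Given contig-vs-reference alignments, each contig receives an evaluation
score: the harmonic mean of its percent identity (pIdent) and its query
coverage (qcovhsp), both in percent. Contigs are grouped high/low quality at
a cutoff on that score, and a predicted ranking is judged by the ROC curve
obtained from sweeping a threshold over the contig scores, plus Pearson and
Spearman correlations between the contig scores and the evaluation score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .formats_io import PslRecord
from .reference_scoring import percent_identity, query_coverage, select_hits

DEFAULT_GROUP_CUTOFF = 95.0

EVAL_COLUMNS = ["contig_id", "pIdent", "qcovhsp", "eval_score", "quality_group"]


def harmonic_mean(p: float, q: float) -> float:
    return 2.0 * p * q / (p + q) if p + q > 0 else 0.0


def evaluation_scores(
    psl_records: Sequence[PslRecord],
    contig_ids: Sequence[str],
    group_cutoff: float = DEFAULT_GROUP_CUTOFF,
) -> pd.DataFrame:
    """Per-contig pIdent, qcovhsp, their harmonic mean and a high/low group.

    The primary hit per contig is chosen with the same rule as the scoring
    stage; contigs with no accepted hit score zero and land in the low group.
    """
    if not 0.0 < group_cutoff < 100.0:
        raise ValueError("group cutoff must be in (0, 100)")
    hits_by_contig: dict[str, list[PslRecord]] = {}
    for rec in psl_records:
        hits_by_contig.setdefault(rec.qName, []).append(rec)
    rows = []
    for cid in contig_ids:
        primary, _ = select_hits(hits_by_contig.get(cid, []))
        if primary is None:
            p = q = 0.0
        else:
            p = percent_identity(primary)
            q = query_coverage(primary)
        e = harmonic_mean(p, q)
        rows.append({
            "contig_id": cid, "pIdent": p, "qcovhsp": q, "eval_score": e,
            "quality_group": "high" if e >= group_cutoff else "low",
        })
    return pd.DataFrame(rows, columns=EVAL_COLUMNS)


@dataclass
class RocResult:
    """ROC points (threshold, TPR, FPR) and trapezoidal AUC.

    Thresholds sweep the distinct score values, predicted-high = score >= t;
    tied scores are grouped at a single operating point.
    """

    points: list[tuple[float, float, float]]
    auc: float


def roc_curve(labels: Sequence[int], scores: Sequence[float]) -> RocResult:
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores differ in length")
    if len(np.unique(y)) < 2:
        raise ValueError("ROC undefined: labels contain a single class")
    fpr, tpr, thresholds = _sk_roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(points=list(zip(thresholds.tolist(), tpr.tolist(), fpr.tolist())),
                     auc=auc)


def correlations(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """(Pearson, Spearman) correlation; Spearman uses midranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    pearson = float(stats.pearsonr(x, y).statistic)
    spearman = float(stats.spearmanr(x, y).statistic)
    return pearson, spearman


def roc_table(result: RocResult) -> pd.DataFrame:
    return pd.DataFrame(result.points, columns=["threshold", "tpr", "fpr"])
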