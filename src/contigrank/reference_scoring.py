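"""Reference-based single scores and their class thresholds.

Training contigs aligned to a known reference (BLAT PSL hits) are turned into
a vector of non-negative "deviation" scores — 0 is perfect for every score —
covering the whole contig (identity, query coverage, per-kb mismatch and indel
rates under different normalizations), the contig ends (end-window identity,
unaligned overhangs) and fragmentation across multiple hits.

Each score is then split into two classes, good (1) and bad (0), at the
q-quantile of an exponential distribution fitted to the training scores by
maximum likelihood; the class labels are the targets of the per-score
classifiers. Histograms of the scores are exported so a user can override any
threshold manually.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import ContigRecord, PslRecord

logger = logging.getLogger(__name__)

SCORE_NAMES = [
    "identity_dev", "qcov_dev",
    "mismatch_per_kb_aln", "mismatch_per_kb_contig", "indel_bases_per_kb_aln",
    "end_identity_dev_left", "end_identity_dev_right",
    "end_overhang_left", "end_overhang_right",
    "fragmentation",
]

SCORE_COLUMNS = ["contig_id"] + SCORE_NAMES

DEFAULT_MIN_MATCH_FRACTION = 0.05
DEFAULT_END_WINDOW = 100
DEFAULT_QUANTILE = 0.95


def select_hits(
    hits: Sequence[PslRecord],
    min_match_fraction: float = DEFAULT_MIN_MATCH_FRACTION,
) -> tuple[PslRecord | None, list[PslRecord]]:
    """Accept hits with enough matched bases; pick the primary hit among them.

    Accepted: matches >= min_match_fraction * qSize (filters spurious
    micro-hits that would inflate the fragmentation score). Primary: most
    matches, ties broken by larger query span, then lexicographically smallest
    tName, then smallest tStart.
    """
    if not hits:
        return None, []
    qnames = {h.qName for h in hits}
    if len(qnames) > 1:
        raise ValueError(f"select_hits got hits for multiple contigs: {sorted(qnames)}")
    accepted = [h for h in hits if h.matches >= min_match_fraction * h.qSize]
    if not accepted:
        return None, []
    primary = min(
        accepted,
        key=lambda h: (-h.matches, -(h.qEnd - h.qStart), h.tName, h.tStart),
    )
    return primary, accepted


def percent_identity(rec: PslRecord) -> float:
    """100 x (matches+repMatches) / (matches+repMatches+misMatches).

    Gap bases are excluded from the denominator; gaps are scored separately.
    """
    m = rec.matches + rec.repMatches
    denom = m + rec.misMatches
    return 100.0 * m / denom if denom else 0.0


def query_coverage(rec: PslRecord) -> float:
    """100 x aligned query span / query size (qStart/qEnd are plus-strand)."""
    return 100.0 * (rec.qEnd - rec.qStart) / rec.qSize


def _window_identity_dev(rec: PslRecord, window: tuple[int, int]) -> float:
    """100 - identity within a contig-end window, from the hit's blocks.

    PSL does not localize mismatches, so window identity is the product of the
    window's aligned fraction and the hit's global match fraction (both in
    [0,1]), scaled to percent: a fully aligned, mismatch-free window scores
    dev 0; a window with no aligned bases scores dev 100.
    """
    w_start, w_end = window
    w_len = w_end - w_start
    aligned = 0
    for s, e in rec.query_blocks_plus():
        aligned += max(0, min(e, w_end) - max(s, w_start))
    if aligned == 0 or w_len == 0:
        return 100.0
    m = rec.matches + rec.repMatches
    match_fraction = m / (m + rec.misMatches) if (m + rec.misMatches) else 0.0
    return 100.0 * (1.0 - (aligned / w_len) * match_fraction)


def sentinel_scores(contig_id: str, contig_length: int) -> dict:
    """Worst-case score vector for a contig with no accepted reference hit."""
    return {
        "contig_id": contig_id,
        "identity_dev": 100.0,
        "qcov_dev": 100.0,
        "mismatch_per_kb_aln": 1000.0,
        "mismatch_per_kb_contig": 1000.0,
        "indel_bases_per_kb_aln": 1000.0,
        "end_identity_dev_left": 100.0,
        "end_identity_dev_right": 100.0,
        "end_overhang_left": float(contig_length),
        "end_overhang_right": float(contig_length),
        "fragmentation": 0.0,
    }


def compute_single_scores(
    contig: ContigRecord,
    primary: PslRecord | None,
    accepted: Sequence[PslRecord],
    end_window: int = DEFAULT_END_WINDOW,
) -> dict:
    """Deviation scores for one contig from its primary and accepted PSL hits."""
    if end_window < 1:
        raise ValueError("end window must be >= 1")
    if primary is None:
        return sentinel_scores(contig.contig_id, contig.length_padded)

    r = primary
    W = end_window
    if W >= r.qSize:
        logger.warning(
            "end window %d >= contig %s length %d; windows clipped to whole contig",
            W, contig.contig_id, r.qSize,
        )
        W = r.qSize
    # aligned query span including query-side gap bases
    aln_len = r.matches + r.misMatches + r.repMatches + r.nCount + r.qBaseInsert
    return {
        "contig_id": contig.contig_id,
        "identity_dev": 100.0 - percent_identity(r),
        "qcov_dev": 100.0 - query_coverage(r),
        "mismatch_per_kb_aln": 1000.0 * r.misMatches / aln_len,
        "mismatch_per_kb_contig": 1000.0 * r.misMatches / r.qSize,
        "indel_bases_per_kb_aln": 1000.0 * (r.qBaseInsert + r.tBaseInsert) / aln_len,
        "end_identity_dev_left": _window_identity_dev(r, (0, W)),
        "end_identity_dev_right": _window_identity_dev(r, (r.qSize - W, r.qSize)),
        "end_overhang_left": float(r.qStart),
        "end_overhang_right": float(r.qSize - r.qEnd),
        "fragmentation": float(len(accepted) - 1),
    }


def score_table(
    contigs: Sequence[ContigRecord],
    psl_records: Sequence[PslRecord],
    min_match_fraction: float = DEFAULT_MIN_MATCH_FRACTION,
    end_window: int = DEFAULT_END_WINDOW,
) -> pd.DataFrame:
    """One score row per contig, in input contig order."""
    hits_by_contig: dict[str, list[PslRecord]] = {}
    for rec in psl_records:
        hits_by_contig.setdefault(rec.qName, []).append(rec)
    rows = []
    for contig in contigs:
        primary, accepted = select_hits(
            hits_by_contig.get(contig.contig_id, []), min_match_fraction
        )
        rows.append(compute_single_scores(contig, primary, accepted, end_window))
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


# ---------------------------------------------------------------------------
# Class thresholds


@dataclass
class ScoreThreshold:
    lambda_hat: float       # fitted exponential rate, 1/score-units
    q: float                # quantile level in (0, 1)
    threshold: float        # class boundary in score units
    method: str = "auto"    # "auto" (exponential quantile) or "manual"
    degenerate: bool = False  # all training values zero: nothing to learn


@dataclass
class ThresholdSet:
    per_score: dict[str, ScoreThreshold] = field(default_factory=dict)

    def __getitem__(self, name: str) -> ScoreThreshold:
        return self.per_score[name]

    def degenerate_scores(self) -> list[str]:
        return [n for n, t in self.per_score.items() if t.degenerate]


MIN_TRAINING_ROWS = 20


def fit_class_thresholds(
    scores: pd.DataFrame,
    q: float = DEFAULT_QUANTILE,
    manual: Mapping[str, float] | None = None,
) -> ThresholdSet:
    """Fit an exponential to each score column and take its q-quantile.

    The ML estimate for the rate is 1/mean over all values, zeros included;
    the class boundary is the closed-form quantile t = -ln(1-q)/lambda. An
    all-zero score column gets t = 0 and is flagged degenerate. ``manual``
    overrides individual thresholds (method recorded as "manual").
    """
    if not 0.0 < q < 1.0:
        raise ValueError("quantile level must be in (0, 1)")
    if len(scores) < MIN_TRAINING_ROWS:
        raise ValueError(
            f"threshold fitting needs >= {MIN_TRAINING_ROWS} contigs, got {len(scores)}"
        )
    manual = dict(manual or {})
    out = ThresholdSet()
    for name in SCORE_NAMES:
        if name not in scores.columns:
            raise ValueError(f"score column {name!r} missing from table")
        values = scores[name].to_numpy(dtype=float)
        if np.any(values < 0):
            raise ValueError(f"score {name!r} has negative values")
        mean = float(values.mean())
        if name in manual:
            t = float(manual[name])
            if t < 0:
                raise ValueError(f"manual threshold for {name!r} must be >= 0")
            lam = 1.0 / mean if mean > 0 else math.inf
            out.per_score[name] = ScoreThreshold(lam, q, t, method="manual")
        elif mean == 0.0:
            logger.warning("score %s is 0 for every training contig (degenerate)", name)
            out.per_score[name] = ScoreThreshold(math.inf, q, 0.0, degenerate=True)
        else:
            lam = 1.0 / mean
            out.per_score[name] = ScoreThreshold(lam, q, -math.log(1.0 - q) / lam)
    return out


def assign_classes(scores: pd.DataFrame, thresholds: ThresholdSet) -> pd.DataFrame:
    """Binary class per score: 1 (good) iff value <= threshold, else 0 (bad)."""
    out = {"contig_id": scores["contig_id"].to_numpy()}
    for name in SCORE_NAMES:
        if name not in scores.columns:
            raise ValueError(f"score column {name!r} missing from table")
        if name not in thresholds.per_score:
            raise ValueError(f"no threshold for score {name!r}")
        t = thresholds[name].threshold
        out[name] = (scores[name].to_numpy(dtype=float) <= t).astype(int)
    return pd.DataFrame(out, columns=SCORE_COLUMNS)


def export_score_histograms(scores: pd.DataFrame, bins: int = 30) -> pd.DataFrame:
    """Per-score histogram table (score, bin_left, bin_right, count).

    Machine-readable so a user can inspect the score distributions and choose
    manual thresholds in a config file.
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    rows = []
    for name in SCORE_NAMES:
        values = scores[name].to_numpy(dtype=float)
        counts, edges = np.histogram(values, bins=bins)
        for c, lo, hi in zip(counts, edges[:-1], edges[1:]):
            rows.append({"score": name, "bin_left": lo, "bin_right": hi, "count": int(c)})
    return pd.DataFrame(rows, columns=["score", "bin_left", "bin_right", "count"])


def thresholds_to_frame(thresholds: ThresholdSet) -> pd.DataFrame:
    rows = [
        {"score": n, "lambda_hat": t.lambda_hat, "q": t.q,
         "threshold": t.threshold, "method": t.method, "degenerate": t.degenerate}
        for n, t in thresholds.per_score.items()
    ]
    return pd.DataFrame(rows)
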