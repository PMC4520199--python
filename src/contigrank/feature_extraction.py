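"""Per-contig predictor extraction (the feature stage of the pipeline).

From a contig's sequence (and optional per-base qualities) together with its
read alignments, compute a fixed vector of predictors: padded/unpadded length,
pileup-depth statistics, core depth, coverage confirmation, coverage drops,
read count/length/quality statistics and contig base-quality statistics.

Quality fields use the sentinel -1 (an impossible Phred value) when qualities
are unavailable, so downstream classifiers need no missing-data handling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .formats_io import ContigRecord, ReadAlignmentRecord

logger = logging.getLogger(__name__)

SENTINEL = -1.0

FEATURE_COLUMNS = [
    "contig_id",
    "length_padded", "length_unpadded",
    "depth_mean", "depth_sd", "depth_min", "depth_max",
    "zero_depth_fraction", "core_depth_mean",
    "coverage_confirmation", "coverage_drops_per_kb",
    "read_count", "reads_per_kb",
    "read_length_mean", "read_length_sd", "read_quality_mean",
    "contig_quality_mean", "contig_quality_min", "contig_quality_q10",
]

#: names of the numeric predictors (everything except the id column)
FEATURE_SCHEMA = FEATURE_COLUMNS[1:]


@dataclass
class FeatureParams:
    """Tunables of the coverage-drop detector.

    A junction (i, i+1) counts as a drop when depth falls to at most
    ``drop_factor`` of its left neighbour and the left depth is at least
    ``min_depth`` (drops out of near-zero coverage carry no signal).
    """

    drop_factor: float = 0.5
    min_depth: int = 5


@dataclass
class DepthProfile:
    contig_id: str
    depth: np.ndarray  # one non-negative count per contig position


def compute_depth(contig_length: int, alignments: Sequence[ReadAlignmentRecord]) -> np.ndarray:
    """Pileup depth: depth[i] = number of reads with an aligned block covering i.

    Uses a difference array over block boundaries, so cost is O(reads + length).
    """
    if contig_length <= 0:
        raise ValueError("contig length must be positive")
    diff = np.zeros(contig_length + 1, dtype=np.int64)
    for aln in alignments:
        for s, e in aln.aligned_blocks:
            if s < 0 or e > contig_length:
                raise ValueError(
                    f"read {aln.read_id!r}: block [{s},{e}) outside contig of length {contig_length}"
                )
            diff[s] += 1
            diff[e] -= 1
    return np.cumsum(diff[:-1])


def _junction_confirmation(contig_length: int, alignments: Sequence[ReadAlignmentRecord]) -> float:
    """Fraction of the L-1 inter-position junctions spanned by >=1 single block.

    A junction (i, i+1) is confirmed when one aligned block covers both i and
    i+1 — a contiguity signal a raw depth profile cannot give (two abutting
    blocks produce depth without confirming the join).
    """
    n_junctions = contig_length - 1
    if n_junctions == 0:
        return 1.0
    confirmed = np.zeros(n_junctions, dtype=bool)
    for aln in alignments:
        for s, e in aln.aligned_blocks:
            if e - s >= 2:
                confirmed[s:e - 1] = True
    return float(confirmed.sum()) / n_junctions


def extract_features(
    contig: ContigRecord,
    alignments: Sequence[ReadAlignmentRecord],
    params: FeatureParams | None = None,
) -> dict:
    """Compute the full feature vector for one contig.

    With no reads, read statistics take the sentinel -1 and depth statistics
    are those of the all-zero profile.
    """
    params = params or FeatureParams()
    L = contig.length_padded
    if L == 0:
        raise ValueError(f"contig {contig.contig_id!r} has length 0")
    for aln in alignments:
        if aln.contig_id != contig.contig_id:
            raise ValueError(
                f"alignment of read {aln.read_id!r} refers to {aln.contig_id!r}, "
                f"not {contig.contig_id!r}"
            )

    depth = compute_depth(L, alignments)
    read_count = len(alignments)

    if read_count == 0:
        logger.warning("contig %s has no aligned reads", contig.contig_id)
        read_length_mean = read_length_sd = read_quality_mean = SENTINEL
    else:
        lengths = np.array([a.read_length for a in alignments], dtype=float)
        read_length_mean = float(lengths.mean())
        read_length_sd = float(lengths.std())
        quals = [a.mean_read_quality for a in alignments]
        if all(q is not None for q in quals):
            read_quality_mean = float(np.mean(quals))
        else:
            read_quality_mean = SENTINEL

    # core depth: drop a margin of ~one mean read length at each end, where
    # depth is depressed by construction; cap at L/4 to keep a non-empty core
    if read_count == 0:
        core_depth_mean = 0.0
    else:
        m = min(int(round(read_length_mean)), L // 4)
        core = depth[m:L - m] if L > 2 * m else depth
        core_depth_mean = float(core.mean())

    # coverage drops: junctions where depth falls to <= drop_factor of the
    # left side, counted only where the left side has real coverage
    if L > 1:
        left, right = depth[:-1], depth[1:]
        drops = int(np.sum((right <= params.drop_factor * left) & (left >= params.min_depth)))
    else:
        drops = 0

    if contig.base_qualities is not None:
        cq = np.asarray(contig.base_qualities, dtype=float)
        contig_quality_mean = float(cq.mean())
        contig_quality_min = float(cq.min())
        contig_quality_q10 = float(np.percentile(cq, 10))
    else:
        contig_quality_mean = contig_quality_min = contig_quality_q10 = SENTINEL

    return {
        "contig_id": contig.contig_id,
        "length_padded": L,
        "length_unpadded": contig.length_unpadded,
        "depth_mean": float(depth.mean()),
        "depth_sd": float(depth.std()),
        "depth_min": int(depth.min()),
        "depth_max": int(depth.max()),
        "zero_depth_fraction": float(np.mean(depth == 0)),
        "core_depth_mean": core_depth_mean,
        "coverage_confirmation": _junction_confirmation(L, alignments),
        "coverage_drops_per_kb": 1000.0 * drops / L,
        "read_count": read_count,
        "reads_per_kb": 1000.0 * read_count / L,
        "read_length_mean": read_length_mean,
        "read_length_sd": read_length_sd,
        "read_quality_mean": read_quality_mean,
        "contig_quality_mean": contig_quality_mean,
        "contig_quality_min": contig_quality_min,
        "contig_quality_q10": contig_quality_q10,
    }


def extract_feature_table(
    contigs: Sequence[ContigRecord],
    alignment_stream: Iterable[ReadAlignmentRecord],
    params: FeatureParams | None = None,
) -> pd.DataFrame:
    """One feature row per contig (including read-free contigs), in input contig order."""
    by_contig: dict[str, list[ReadAlignmentRecord]] = {c.contig_id: [] for c in contigs}
    for aln in alignment_stream:
        if aln.contig_id not in by_contig:
            raise ValueError(f"alignment references unknown contig {aln.contig_id!r}")
        by_contig[aln.contig_id].append(aln)
    rows = [extract_features(c, by_contig[c.contig_id], params) for c in contigs]
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
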