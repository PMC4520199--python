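import numpy as np
import pandas as pd
import pytest

from contigrank.formats_io import PslRecord, ReadAlignmentRecord
from contigrank.reference_scoring import SCORE_NAMES


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_read(read_id, contig_id, blocks, read_length=None, mean_q=30.0):
    blocks = [tuple(b) for b in blocks]
    if read_length is None:
        read_length = sum(e - s for s, e in blocks)
    return ReadAlignmentRecord(
        read_id=read_id, contig_id=contig_id, start=blocks[0][0],
        aligned_blocks=blocks, read_length=read_length, mean_read_quality=mean_q,
    )


def make_psl(qname="c1", qsize=1000, matches=None, mismatches=0,
             qstart=0, qend=None, tname="ref", tsize=100000, tstart=0,
             q_insert=(0, 0), t_insert=(0, 0), blocks=None, strand="+"):
    """Single- or multi-block plus-strand PSL hit with consistent fields.

    If ``blocks`` is None a single gapless block spanning [qstart, qend) is
    built; matches defaults to block span minus mismatches.
    """
    if qend is None:
        qend = qsize
    if blocks is None:
        size = qend - qstart
        blocks = [(qstart, tstart, size)]
    sizes = [b[2] for b in blocks]
    if matches is None:
        matches = sum(sizes) - mismatches
    else:
        mismatches = sum(sizes) - matches  # keep the PSL block-sum invariant
    qstarts = [b[0] for b in blocks]
    tstarts = [b[1] for b in blocks]
    rec = PslRecord(
        matches=matches, misMatches=mismatches, repMatches=0, nCount=0,
        qNumInsert=q_insert[0], qBaseInsert=q_insert[1],
        tNumInsert=t_insert[0], tBaseInsert=t_insert[1],
        strand=strand, qName=qname, qSize=qsize,
        qStart=qstarts[0], qEnd=qstarts[-1] + sizes[-1],
        tName=tname, tSize=tsize,
        tStart=tstarts[0], tEnd=tstarts[-1] + sizes[-1],
        blockCount=len(blocks), blockSizes=sizes, qStarts=qstarts, tStarts=tstarts,
    )
    rec.validate()
    return rec


def score_frame(values_by_name=None, n=30, fill=0.0, ids=None):
    """Score table with every score column; unspecified columns get ``fill``."""
    values_by_name = values_by_name or {}
    lengths = [len(v) for v in values_by_name.values()]
    if lengths:
        n = lengths[0]
    data = {"contig_id": ids if ids is not None else [f"c{i}" for i in range(n)]}
    for name in SCORE_NAMES:
        v = values_by_name.get(name)
        data[name] = np.asarray(v, dtype=float) if v is not None else np.full(n, fill)
    return pd.DataFrame(data)
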