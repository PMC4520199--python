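"""Readers and writers for the formats the pipeline touches.

FASTA/FASTQ (contigs and their per-base qualities), SAM/BAM (read-to-contig
alignments), BLAT PSL (contig-to-reference alignments) and the tool's
tab-separated intermediate tables.

All coordinates are normalized to a single internal convention: 0-based,
half-open intervals. Conversions (SAM's 1-based POS, PSL's already 0-based
half-open fields) happen only at parse/serialize boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

GAP_CHARS = frozenset("*-")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ContigRecord:
    """A contig's sequence and optional per-base Phred qualities.

    ``bases`` may contain gap characters (``*`` or ``-``) from padded
    consensus output; these are retained (padded view) and all read-alignment
    coordinates refer to the padded sequence as given.
    """

    contig_id: str
    bases: str
    base_qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.contig_id:
            raise FormatError("contig id must be non-empty")
        if self.base_qualities is not None and len(self.base_qualities) != len(self.bases):
            raise FormatError(
                f"contig {self.contig_id!r}: quality length {len(self.base_qualities)} "
                f"!= sequence length {len(self.bases)}"
            )

    @property
    def length_padded(self) -> int:
        return len(self.bases)

    @property
    def length_unpadded(self) -> int:
        return sum(1 for b in self.bases if b not in GAP_CHARS)


@dataclass
class ReadAlignmentRecord:
    """One read placed on a contig, reduced to aligned blocks and read stats.

    ``aligned_blocks`` are the contig-consuming stretches of the alignment:
    half-open ``[start, end)`` intervals, sorted and pairwise disjoint.
    ``read_length`` is the query length including soft-clipped bases.
    """

    read_id: str
    contig_id: str
    start: int
    aligned_blocks: list[tuple[int, int]]
    read_length: int
    mean_read_quality: float | None = None

    def __post_init__(self) -> None:
        blocks = self.aligned_blocks
        for (s, e) in blocks:
            if not (0 <= s < e):
                raise FormatError(f"read {self.read_id!r}: invalid block [{s},{e})")
        for (_, e0), (s1, _) in zip(blocks, blocks[1:]):
            if s1 < e0:
                raise FormatError(f"read {self.read_id!r}: blocks overlap or unsorted")


def cigar_to_blocks(start: int, cigartuples: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Turn a CIGAR into half-open aligned blocks on the contig.

    M/=/X extend the current block; D/N close it and skip contig positions;
    I/S/H/P consume no contig positions and do not close the block.
    """
    # pysam op codes: 0=M 1=I 2=D 3=N 4=S 5=H 6=P 7== 8=X
    blocks: list[tuple[int, int]] = []
    pos = start
    block_start: int | None = None
    for op, length in cigartuples:
        if op in (0, 7, 8):  # M, =, X
            if block_start is None:
                block_start = pos
            pos += length
        elif op in (2, 3):  # D, N
            if block_start is not None:
                blocks.append((block_start, pos))
                block_start = None
            pos += length
        elif op in (1, 4, 5, 6):  # I, S, H, P
            continue
        else:
            raise FormatError(f"unknown CIGAR op code {op}")
    if block_start is not None:
        blocks.append((block_start, pos))
    return blocks


def read_contigs(fasta_path: str | Path, fastq_path: str | Path | None = None) -> list[ContigRecord]:
    """Read assembly contigs from FASTA, optionally attaching FASTQ qualities.

    Sequences are case-folded to uppercase; gap characters are retained.
    Duplicate ids, a contig missing from the FASTQ, or a FASTA/FASTQ length
    mismatch are hard errors.
    """
    quals: dict[str, list[int]] = {}
    if fastq_path is not None:
        for rec in SeqIO.parse(str(fastq_path), "fastq"):
            quals[rec.id] = list(rec.letter_annotations["phred_quality"])

    contigs: list[ContigRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate contig id {rec.id!r} in {fasta_path}")
        seen.add(rec.id)
        bases = str(rec.seq).upper()
        q: list[int] | None = None
        if fastq_path is not None:
            if rec.id not in quals:
                raise FormatError(f"contig {rec.id!r} has no FASTQ entry in {fastq_path}")
            q = quals[rec.id]
            if len(q) != len(bases):
                raise FormatError(
                    f"contig {rec.id!r}: FASTA length {len(bases)} != FASTQ length {len(q)}"
                )
        contigs.append(ContigRecord(rec.id, bases, q))
    return contigs


def read_read_alignments(sam_or_bam_path: str | Path) -> Iterator[ReadAlignmentRecord]:
    """Stream mapped, primary read alignments from SAM or BAM.

    Unmapped, secondary and supplementary records are skipped (a depth profile
    must count each sequenced read at most once); the counts are logged.
    SAM's 1-based POS becomes a 0-based ``start``.
    """
    n_skipped = {"unmapped": 0, "secondary": 0, "supplementary": 0, "no_cigar": 0}
    with pysam.AlignmentFile(str(sam_or_bam_path), check_sq=True) as fh:
        for aln in fh:
            if aln.is_unmapped:
                n_skipped["unmapped"] += 1
                continue
            if aln.is_secondary:
                n_skipped["secondary"] += 1
                continue
            if aln.is_supplementary:
                n_skipped["supplementary"] += 1
                continue
            if not aln.cigartuples:
                n_skipped["no_cigar"] += 1
                logger.warning("mapped read %s has no CIGAR; skipped", aln.query_name)
                continue
            if aln.reference_name is None:
                raise FormatError(f"read {aln.query_name!r}: contig missing from header")
            quals = aln.query_qualities
            mean_q = float(sum(quals)) / len(quals) if quals is not None and len(quals) else None
            # query length including soft clips (pysam's infer_read_length also
            # counts hard clips, which are not part of the stored query)
            read_length = aln.query_length or aln.infer_query_length() or 0
            yield ReadAlignmentRecord(
                read_id=aln.query_name,
                contig_id=aln.reference_name,
                start=aln.reference_start,
                aligned_blocks=cigar_to_blocks(aln.reference_start, aln.cigartuples),
                read_length=read_length,
                mean_read_quality=mean_q,
            )
    if any(n_skipped.values()):
        logger.info("skipped alignments: %s", n_skipped)


# ---------------------------------------------------------------------------
# PSL


@dataclass
class PslRecord:
    """One line of BLAT's 21-column PSL format.

    Coordinates follow the PSL convention: 0-based, half-open; qStart/qEnd are
    always given in plus-strand query coordinates, while per-block qStarts are
    in reverse-complement coordinates when strand is '-'.
    """

    matches: int
    misMatches: int
    repMatches: int
    nCount: int
    qNumInsert: int
    qBaseInsert: int
    tNumInsert: int
    tBaseInsert: int
    strand: str
    qName: str
    qSize: int
    qStart: int
    qEnd: int
    tName: str
    tSize: int
    tStart: int
    tEnd: int
    blockCount: int
    blockSizes: list[int] = field(default_factory=list)
    qStarts: list[int] = field(default_factory=list)
    tStarts: list[int] = field(default_factory=list)

    def validate(self) -> None:
        r = self
        if not (0 <= r.qStart < r.qEnd <= r.qSize):
            raise FormatError(f"PSL {r.qName!r}->{r.tName!r}: bad query coords "
                              f"qStart={r.qStart} qEnd={r.qEnd} qSize={r.qSize}")
        if not (0 <= r.tStart < r.tEnd <= r.tSize):
            raise FormatError(f"PSL {r.qName!r}->{r.tName!r}: bad target coords")
        if r.strand not in ("+", "-"):
            raise FormatError(f"PSL {r.qName!r}: strand must be '+' or '-', got {r.strand!r}")
        expected = r.matches + r.misMatches + r.repMatches + r.nCount
        if sum(r.blockSizes) != expected:
            raise FormatError(
                f"PSL {r.qName!r}->{r.tName!r}: sum(blockSizes)={sum(r.blockSizes)} "
                f"!= matches+misMatches+repMatches+nCount={expected}"
            )
        if not (len(r.blockSizes) == len(r.qStarts) == len(r.tStarts) == r.blockCount):
            raise FormatError(f"PSL {r.qName!r}: block list lengths disagree with blockCount")

    def query_blocks_plus(self) -> list[tuple[int, int]]:
        """Aligned blocks on the query in plus-strand coordinates, half-open."""
        out = []
        for qs, size in zip(self.qStarts, self.blockSizes):
            if self.strand == "-":
                out.append((self.qSize - qs - size, self.qSize - qs))
            else:
                out.append((qs, qs + size))
        return sorted(out)


def _int_list(text: str) -> list[int]:
    return [int(x) for x in text.rstrip(",").split(",") if x]


def read_psl(psl_path: str | Path) -> list[PslRecord]:
    """Parse a 21-column PSL file; a leading 5-line 'psLayout' header is skipped."""
    lines = Path(psl_path).read_text().splitlines()
    if lines and lines[0].startswith("psLayout"):
        lines = lines[5:]
    records: list[PslRecord] = []
    for i, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 21:
            raise FormatError(f"{psl_path}: line {i}: expected 21 fields, got {len(fields)}")
        try:
            rec = PslRecord(
                matches=int(fields[0]), misMatches=int(fields[1]),
                repMatches=int(fields[2]), nCount=int(fields[3]),
                qNumInsert=int(fields[4]), qBaseInsert=int(fields[5]),
                tNumInsert=int(fields[6]), tBaseInsert=int(fields[7]),
                strand=fields[8], qName=fields[9], qSize=int(fields[10]),
                qStart=int(fields[11]), qEnd=int(fields[12]),
                tName=fields[13], tSize=int(fields[14]),
                tStart=int(fields[15]), tEnd=int(fields[16]),
                blockCount=int(fields[17]),
                blockSizes=_int_list(fields[18]),
                qStarts=_int_list(fields[19]),
                tStarts=_int_list(fields[20]),
            )
        except ValueError as exc:
            raise FormatError(f"{psl_path}: line {i}: {exc}") from exc
        rec.validate()
        records.append(rec)
    return records


def write_psl(records: Iterable[PslRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write("\t".join(str(x) for x in (
                r.matches, r.misMatches, r.repMatches, r.nCount,
                r.qNumInsert, r.qBaseInsert, r.tNumInsert, r.tBaseInsert,
                r.strand, r.qName, r.qSize, r.qStart, r.qEnd,
                r.tName, r.tSize, r.tStart, r.tEnd, r.blockCount,
                ",".join(map(str, r.blockSizes)) + ",",
                ",".join(map(str, r.qStarts)) + ",",
                ",".join(map(str, r.tStarts)) + ",",
            )) + "\n")


# ---------------------------------------------------------------------------
# Tab-separated intermediate tables


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a tab-separated table with header; numerics keep >=12 significant digits."""
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_table(path: str | Path, schema: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a tab-separated table; if ``schema`` is given, columns must match it."""
    df = pd.read_csv(path, sep="\t")
    if schema is not None:
        unknown = [c for c in df.columns if c not in schema]
        missing = [c for c in schema if c not in df.columns]
        if unknown or missing:
            raise FormatError(
                f"{path}: columns do not match declared schema "
                f"(unknown: {unknown}, missing: {missing})"
            )
        df = df[list(schema)]
    return df
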