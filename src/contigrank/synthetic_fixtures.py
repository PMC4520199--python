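"""Truth-labeled synthetic assemblies for testing and benchmarking.

Generates a random reference genome, derives contigs from it with injected
consensus errors (substitutions, small indels, chimeric mis-joins of distant
loci), emits the TRUE contig-vs-reference alignments as PSL directly from the
known edit script (no aligner involved), and simulates reads over the contigs
as SAM. Every file carries a known ground truth, so the whole
feature→score→train→predict pipeline is testable without external data.

Two error modes mirror real mis-assemblies:

* chimeras — a contig concatenating two reference loci at least
  ``min_chimera_distance`` apart; reads are sampled within each source
  segment only, so no read spans the false join and coverage collapses there
  exactly as it does when a mapper is run against a chimeric contig;
* hypermutated contigs — consensus substitution rates well above baseline;
  reads overlapping k consensus errors are retained with probability
  (1 - read_loss_per_mismatch)^k, emulating mapper dropout over bad sequence.

A contig's truth label is ``bad`` iff it is chimeric or its realized
substitution density exceeds ``bad_rate_cutoff``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .formats_io import ContigRecord, PslRecord, write_psl

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))

REFERENCE_NAME = "reference"


@dataclass
class SimulationParams:
    """Study conditions of a synthetic assembly.

    Rates are per base. ``substitution_rate`` is the upper end of the
    baseline (good-contig) consensus error band; hypermutated contigs draw
    their rate from [1.5 * bad_rate_cutoff, hyper_substitution_rate] so they
    sit clearly above the bad-label cutoff.
    """

    seed: int = 0
    genome_length: int = 200_000
    gc_fraction: float = 0.5
    n_contigs: int = 400
    contig_length_range: tuple[int, int] = (1_000, 6_000)
    substitution_rate: float = 0.005
    insertion_rate: float = 0.0005
    deletion_rate: float = 0.0005
    p_chimera: float = 0.15
    min_chimera_distance: int = 20_000
    p_hypermutated: float = 0.18
    hyper_substitution_rate: float = 0.04
    bad_rate_cutoff: float = 0.02
    read_length: int = 100
    mean_depth: float = 25.0
    read_substitution_rate: float = 0.005
    read_loss_per_mismatch: float = 0.15

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "insertion_rate", "deletion_rate",
                     "hyper_substitution_rate", "read_substitution_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        for name in ("p_chimera", "p_hypermutated", "gc_fraction",
                     "read_loss_per_mismatch"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.genome_length <= 0 or self.read_length <= 0:
            raise ValueError("lengths must be positive")
        if self.min_chimera_distance >= self.genome_length:
            raise ValueError("min_chimera_distance must be < genome_length")
        lo, hi = self.contig_length_range
        if not 0 < lo <= hi:
            raise ValueError("invalid contig_length_range")


@dataclass
class ContigTruth:
    contig_id: str
    source_intervals: list[tuple[int, int]]   # [start, end) on the reference
    is_chimera: bool
    junction: int | None                      # contig position where part 2 starts
    n_substitutions: int
    n_insertions: int
    n_deletions: int
    substitution_positions: list[int]         # contig coordinates
    label: str                                # "good" | "bad"
    true_pident: float                        # of the dominant (primary) hit
    true_qcov: float


@dataclass
class SyntheticTruth:
    per_contig: dict[str, ContigTruth] = field(default_factory=dict)


def _stage_rng(params: SimulationParams, stage: int) -> np.random.Generator:
    # independent, reproducible stream per pipeline stage
    return np.random.default_rng(np.random.SeedSequence([params.seed, stage]))


def simulate_reference(params: SimulationParams) -> str:
    """I.i.d. reference sequence with P(G)+P(C) = gc_fraction."""
    rng = _stage_rng(params, 0)
    g = params.gc_fraction / 2.0
    a = (1.0 - params.gc_fraction) / 2.0
    idx = rng.choice(4, size=params.genome_length, p=[a, g, g, a])  # A C G T
    return "".join(BASES[idx])


def _edit_walk(
    ref_segment: str,
    sub_rate: float,
    ins_rate: float,
    del_rate: float,
    rng: np.random.Generator,
) -> tuple[str, list[tuple[int, int, int]], int, list[int]]:
    """Apply random edits to a reference segment.

    Returns (contig_part, blocks, n_mismatches, substitution_positions) where
    blocks are (q_start, t_start, size) triplets in segment-local
    coordinates. Substitutions stay inside blocks; insertions/deletions split
    them.
    """
    out: list[str] = []
    blocks: list[tuple[int, int, int]] = []
    sub_positions: list[int] = []
    qpos = 0
    b_q = b_t = b_len = 0
    n_mismatch = 0

    n = len(ref_segment)
    # draw all event randomness vectorized; per-base python loop only assembles
    u_ins = rng.random(n) < ins_rate
    u_del = rng.random(n) < del_rate
    u_sub = rng.random(n) < sub_rate
    ins_base = rng.integers(0, 4, size=n)
    sub_shift = rng.integers(1, 4, size=n)  # substitution: shift to a different base
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}

    def close_block(tpos: int) -> None:
        nonlocal b_len
        if b_len > 0:
            blocks.append((b_q, b_t, b_len))
            b_len = 0

    for t in range(n):
        if u_ins[t]:
            close_block(t)
            out.append(BASES[ins_base[t]])
            qpos += 1
        if u_del[t]:
            close_block(t)
            continue
        if b_len == 0:
            b_q, b_t = qpos, t
        if u_sub[t]:
            new = (base_index[ref_segment[t]] + sub_shift[t]) % 4
            out.append(BASES[new])
            sub_positions.append(qpos)
            n_mismatch += 1
        else:
            out.append(ref_segment[t])
        qpos += 1
        b_len += 1
    close_block(n)
    return "".join(out), blocks, n_mismatch, sub_positions


def _psl_from_blocks(
    contig_id: str,
    qsize: int,
    tsize: int,
    blocks: list[tuple[int, int, int]],
    n_mismatch: int,
    q_offset: int,
    t_offset: int,
) -> PslRecord:
    """Build a plus-strand PSL record from known alignment blocks.

    Gap counts are derived from the inter-block gaps, so the record is
    internally consistent by construction.
    """
    qs = [q_offset + b[0] for b in blocks]
    ts = [t_offset + b[1] for b in blocks]
    sizes = [b[2] for b in blocks]
    q_num = q_base = t_num = t_base = 0
    for i in range(1, len(blocks)):
        qgap = qs[i] - (qs[i - 1] + sizes[i - 1])
        tgap = ts[i] - (ts[i - 1] + sizes[i - 1])
        if qgap > 0:
            q_num += 1
            q_base += qgap
        if tgap > 0:
            t_num += 1
            t_base += tgap
    total = sum(sizes)
    rec = PslRecord(
        matches=total - n_mismatch, misMatches=n_mismatch, repMatches=0, nCount=0,
        qNumInsert=q_num, qBaseInsert=q_base, tNumInsert=t_num, tBaseInsert=t_base,
        strand="+", qName=contig_id, qSize=qsize,
        qStart=qs[0], qEnd=qs[-1] + sizes[-1],
        tName=REFERENCE_NAME, tSize=tsize,
        tStart=ts[0], tEnd=ts[-1] + sizes[-1],
        blockCount=len(blocks), blockSizes=sizes, qStarts=qs, tStarts=ts,
    )
    rec.validate()
    return rec


def derive_contigs(
    reference: str,
    params: SimulationParams,
) -> tuple[list[ContigRecord], list[PslRecord], SyntheticTruth]:
    """Sample contigs from the reference with injected errors.

    Each contig is a (possibly edited) substring; chimeric contigs
    concatenate two substrings at least ``min_chimera_distance`` apart and
    yield two PSL records. All PSL records are emitted from the known edit
    script, never from an aligner.
    """
    rng = _stage_rng(params, 1)
    G = len(reference)
    lo, hi = params.contig_length_range
    if hi > G:
        raise ValueError(f"contig length up to {hi} exceeds genome length {G}")

    contigs: list[ContigRecord] = []
    psl: list[PslRecord] = []
    truth = SyntheticTruth()

    for i in range(params.n_contigs):
        cid = f"contig_{i:04d}"
        target_len = int(rng.integers(lo, hi + 1))
        is_chimera = rng.random() < params.p_chimera
        if is_chimera:
            sub_rate = rng.uniform(0.0, params.substitution_rate)
        elif rng.random() < params.p_hypermutated:
            sub_rate = rng.uniform(1.5 * params.bad_rate_cutoff,
                                   params.hyper_substitution_rate)
        else:
            sub_rate = rng.uniform(0.0, params.substitution_rate)

        if is_chimera:
            # mis-join breakpoint anywhere in the middle 70% of the contig;
            # both parts stay comfortably longer than a read
            len1 = int(round(rng.uniform(0.15, 0.85) * target_len))
            len1 = max(2 * params.read_length, min(target_len - 2 * params.read_length, len1))
            len2 = target_len - len1
            # two source loci at least min_chimera_distance apart
            for _ in range(1000):
                g1 = int(rng.integers(0, G - len1 + 1))
                g2 = int(rng.integers(0, G - len2 + 1))
                if abs(g1 - g2) >= params.min_chimera_distance:
                    break
            else:
                raise ValueError("cannot place chimera segments; genome too small")
            segments = [(g1, len1), (g2, len2)]
        else:
            g1 = int(rng.integers(0, G - target_len + 1))
            segments = [(g1, target_len)]

        parts, part_blocks, part_mm, part_subs = [], [], [], []
        for g0, seg_len in segments:
            part, blocks, mm, subs = _edit_walk(
                reference[g0:g0 + seg_len], sub_rate,
                params.insertion_rate, params.deletion_rate, rng,
            )
            parts.append(part)
            part_blocks.append(blocks)
            part_mm.append(mm)
            part_subs.append(subs)

        bases = "".join(parts)
        qsize = len(bases)
        contigs.append(ContigRecord(cid, bases))

        q_off = 0
        recs = []
        for (g0, _), part, blocks, mm in zip(segments, parts, part_blocks, part_mm):
            recs.append(_psl_from_blocks(cid, qsize, G, blocks, mm, q_off, g0))
            q_off += len(part)
        psl.extend(recs)

        # dominant hit = most matches (mirrors the published selection rule)
        primary = max(recs, key=lambda r: (r.matches, r.qEnd - r.qStart))
        denom = primary.matches + primary.misMatches
        true_pident = 100.0 * primary.matches / denom if denom else 0.0
        true_qcov = 100.0 * (primary.qEnd - primary.qStart) / qsize

        sub_positions = list(part_subs[0])
        if is_chimera:
            off = len(parts[0])
            sub_positions += [off + p for p in part_subs[1]]
        n_sub = sum(part_mm)
        n_ins = sum(r.qBaseInsert for r in recs)
        n_del = sum(r.tBaseInsert for r in recs)
        bad = is_chimera or (n_sub / qsize) > params.bad_rate_cutoff
        truth.per_contig[cid] = ContigTruth(
            contig_id=cid,
            source_intervals=[(g0, g0 + seg_len) for g0, seg_len in segments],
            is_chimera=is_chimera,
            junction=len(parts[0]) if is_chimera else None,
            n_substitutions=n_sub, n_insertions=n_ins, n_deletions=n_del,
            substitution_positions=sub_positions,
            label="bad" if bad else "good",
            true_pident=true_pident, true_qcov=true_qcov,
        )
    return contigs, psl, truth


@dataclass
class SimulatedRead:
    read_id: str
    contig_id: str
    start: int          # 0-based on the contig
    sequence: str
    quality_char: str = "?"  # constant Phred 30


def simulate_reads(
    contigs: list[ContigRecord],
    params: SimulationParams,
    truth: SyntheticTruth | None = None,
) -> list[SimulatedRead]:
    """Uniform all-M reads along each contig at the requested mean depth.

    When ``truth`` is given, mapping effects of consensus errors are
    emulated: reads are confined to single source segments of chimeras and
    thinned where they overlap substituted positions (see module docstring).
    """
    rng = _stage_rng(params, 2)
    rl = params.read_length
    keep_base = 1.0 - params.read_loss_per_mismatch
    reads: list[SimulatedRead] = []
    n_read = 0
    for contig in contigs:
        L = contig.length_padded
        if rl > L:
            raise ValueError(f"read length {rl} exceeds contig {contig.contig_id} length {L}")
        info = truth.per_contig.get(contig.contig_id) if truth else None
        if info is not None and info.is_chimera and info.junction is not None:
            segments = [(0, info.junction), (info.junction, L)]
        else:
            segments = [(0, L)]
        sub_pos = np.asarray(info.substitution_positions) if info else np.empty(0)

        for seg_start, seg_end in segments:
            seg_len = seg_end - seg_start
            if seg_len < rl:
                continue
            n_target = rng.poisson(params.mean_depth * seg_len / rl)
            if n_target == 0:
                continue
            starts = rng.integers(seg_start, seg_end - rl + 1, size=n_target)
            if len(sub_pos):
                k = np.searchsorted(sub_pos, starts + rl) - np.searchsorted(sub_pos, starts)
                keep = rng.random(n_target) < keep_base ** k
            else:
                keep = np.ones(n_target, dtype=bool)
            n_err = rng.binomial(rl, params.read_substitution_rate, size=n_target)
            for j, (pos, ok) in enumerate(zip(starts, keep)):
                if not ok:
                    continue
                seq = contig.bases[pos:pos + rl]
                if n_err[j]:
                    chars = list(seq)
                    for p in rng.integers(0, rl, size=n_err[j]):
                        chars[p] = str(rng.choice(BASES))
                    seq = "".join(chars)
                reads.append(SimulatedRead(f"read_{n_read:07d}", contig.contig_id,
                                           int(pos), seq))
                n_read += 1
    return reads


def write_sam(reads: list[SimulatedRead], contigs: list[ContigRecord], path: str | Path) -> None:
    """Emit reads as plain-text SAM (all-M CIGAR, constant base quality)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for c in contigs:
            fh.write(f"@SQ\tSN:{c.contig_id}\tLN:{c.length_padded}\n")
        for r in reads:
            rl = len(r.sequence)
            fh.write("\t".join((
                r.read_id, "0", r.contig_id, str(r.start + 1), "60", f"{rl}M",
                "*", "0", "0", r.sequence, r.quality_char * rl,
            )) + "\n")


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


FIXTURE_FILES = ("ref.fasta", "contigs.fasta", "reads.sam", "truth.psl",
                 "truth.tsv", "manifest.json")


def truth_table_rows(truth: SyntheticTruth) -> list[dict]:
    rows = []
    for t in truth.per_contig.values():
        rows.append({
            "contig_id": t.contig_id,
            "label": t.label,
            "is_chimera": int(t.is_chimera),
            "n_substitutions": t.n_substitutions,
            "n_insertions": t.n_insertions,
            "n_deletions": t.n_deletions,
            "true_pident": t.true_pident,
            "true_qcov": t.true_qcov,
        })
    return rows


def make_fixture(params: SimulationParams, out_dir: str | Path, force: bool = False) -> dict:
    """Write a complete, mutually consistent fixture to ``out_dir``.

    Files: ref.fasta, contigs.fasta, reads.sam, truth.psl, truth.tsv and a
    manifest.json recording the parameters. Refuses to overwrite unless
    ``force``.
    """
    import pandas as pd

    from .formats_io import write_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    existing = [f for f in FIXTURE_FILES if (out / f).exists()]
    if existing and not force:
        raise FileExistsError(f"fixture files already present in {out}: {existing}")

    reference = simulate_reference(params)
    contigs, psl, truth = derive_contigs(reference, params)
    reads = simulate_reads(contigs, params, truth)

    write_fasta([(REFERENCE_NAME, reference)], out / "ref.fasta")
    write_fasta([(c.contig_id, c.bases) for c in contigs], out / "contigs.fasta")
    write_sam(reads, contigs, out / "reads.sam")
    write_psl(psl, out / "truth.psl")
    write_table(pd.DataFrame(truth_table_rows(truth)), out / "truth.tsv")

    manifest = {"params": dataclasses.asdict(params), "n_reads": len(reads)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("fixture written to %s (%d contigs, %d reads)", out, len(contigs), len(reads))
    return manifest
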