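"""Alignment of reads/consensus sequences to the amplicon reference.

Provides a self-contained anchor-chaining aligner tuned for long amplicon
reads carrying large deletions/insertions, event normalization
(left-alignment and junction merging), and ingestion of external SAM
alignments including split (supplementary) reads.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import Align

from ._seq import seq_to_array
from .reference import AmpliconReference


@dataclass
class DeletionEvent:
    """A deleted reference interval, optionally with inserted junction bases."""

    ref_start: int
    ref_end: int
    junction_insertion: str = ""

    @property
    def size(self) -> int:
        return self.ref_end - self.ref_start

    def __post_init__(self) -> None:
        if self.ref_end <= self.ref_start:
            raise ValueError("deletion must have ref_end > ref_start")


@dataclass
class InsertionEvent:
    """Bases inserted at a reference gap coordinate."""

    ref_pos: int
    inserted_sequence: str

    @property
    def ref_start(self) -> int:  # uniform sort key with deletions
        return self.ref_pos

    @property
    def size(self) -> int:
        return len(self.inserted_sequence)


@dataclass
class ReadAlignment:
    read_id: str
    aligned: bool
    events: list = field(default_factory=list)
    substitutions: int = 0
    ref_spans: list[tuple[int, int]] = field(default_factory=list)
    query_clips: tuple[int, int] = (0, 0)

    def deletions(self) -> list[DeletionEvent]:
        return [e for e in self.events if isinstance(e, DeletionEvent)]

    def insertions(self) -> list[InsertionEvent]:
        return [e for e in self.events if isinstance(e, InsertionEvent)]


# ---------------------------------------------------------------------------
# anchor-chaining aligner


@functools.lru_cache(maxsize=8)
def _unique_kmer_index(sequence: str, k: int) -> dict:
    counts: dict[str, int] = {}
    for i in range(len(sequence) - k + 1):
        kmer = sequence[i : i + k]
        counts[kmer] = counts.get(kmer, 0) + 1
    return {
        sequence[i : i + k]: i
        for i in range(len(sequence) - k + 1)
        if counts[sequence[i : i + k]] == 1
    }


def _lis_chain(anchors: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain with strictly increasing reference positions.

    Anchors arrive sorted by query position; patience algorithm, O(n log n).
    """
    import bisect

    tails: list[int] = []  # ref positions of chain tails
    tail_idx: list[int] = []
    parent = [-1] * len(anchors)
    for i, (_, r) in enumerate(anchors):
        pos = bisect.bisect_left(tails, r)
        if pos == len(tails):
            tails.append(r)
            tail_idx.append(i)
        else:
            tails[pos] = r
            tail_idx[pos] = i
        parent[i] = tail_idx[pos - 1] if pos > 0 else -1
    chain = []
    i = tail_idx[-1]
    while i != -1:
        chain.append(anchors[i])
        i = parent[i]
    return chain[::-1]


_ALIGNER = Align.PairwiseAligner()
_ALIGNER.mode = "global"
_ALIGNER.match_score = 2
_ALIGNER.mismatch_score = -4
_ALIGNER.open_gap_score = -8
_ALIGNER.extend_gap_score = -0.2


def _close_gap(qseg: str, rseg: str, r_off: int) -> tuple[list, int]:
    """Align an inter-anchor segment, returning (events, substitutions).

    ``r_off`` is the reference coordinate of the start of ``rseg``.
    """
    if not qseg and not rseg:
        return [], 0
    if not qseg:
        return [DeletionEvent(r_off, r_off + len(rseg))], 0
    if not rseg:
        return [InsertionEvent(r_off, qseg)], 0
    if len(qseg) == len(rseg):
        mism = int(np.count_nonzero(seq_to_array(qseg) != seq_to_array(rseg)))
        if mism <= max(2, len(qseg) // 2):
            return [], mism
    aln = _ALIGNER.align(rseg, qseg)[0]
    rblocks, qblocks = aln.aligned
    events: list = []
    subs = 0
    prev_r, prev_q = 0, 0
    for (rs, re), (qs, qe) in zip(rblocks, qblocks):
        dr, dq = rs - prev_r, qs - prev_q
        if dr > 0:
            events.append(
                DeletionEvent(r_off + prev_r, r_off + rs, qseg[prev_q:qs] if dq > 0 else "")
            )
        elif dq > 0:
            events.append(InsertionEvent(r_off + rs, qseg[prev_q:qs]))
        subs += int(np.count_nonzero(seq_to_array(rseg[rs:re]) != seq_to_array(qseg[qs:qe])))
        prev_r, prev_q = re, qe
    dr, dq = len(rseg) - prev_r, len(qseg) - prev_q
    if dr > 0:
        events.append(
            DeletionEvent(r_off + prev_r, r_off + len(rseg), qseg[prev_q:] if dq > 0 else "")
        )
    elif dq > 0:
        events.append(InsertionEvent(r_off + len(rseg), qseg[prev_q:]))
    return events, subs


def _extend_end(seq: str, ref: str, q: int, r: int, direction: int) -> tuple[int, int]:
    """Greedy ungapped end extension from an anchor boundary.

    Returns (#bases extended, #mismatches). Stops once the running mismatch
    count exceeds ``2 + 0.2 * extended``.
    """
    ext = mism = 0
    while True:
        if direction > 0:
            qi, ri = q + ext, r + ext
            if qi >= len(seq) or ri >= len(ref):
                break
        else:
            qi, ri = q - ext - 1, r - ext - 1
            if qi < 0 or ri < 0:
                break
        nm = mism + (seq[qi] != ref[ri])
        if nm > 2 + 0.2 * (ext + 1):
            break
        mism = nm
        ext += 1
    return ext, mism


def align_to_amplicon(
    seq: str,
    ref: AmpliconReference,
    k: int = 15,
    stride: int = 4,
    read_id: str = "read",
) -> ReadAlignment:
    """Align a read to the amplicon by unique k-mer anchor chaining.

    Anchors are unique reference k-mers sampled every ``stride`` query
    positions, chained collinearly; inter-anchor gaps are closed by pairwise
    alignment. Reads with less than half their bases covered by the chained
    region come back with ``aligned=False``.
    """
    seq = seq.upper()
    if not seq:
        raise ValueError("empty query sequence")
    index = _unique_kmer_index(ref.sequence, k)
    anchors = []
    for q in range(0, max(len(seq) - k, 0) + 1, stride):
        r = index.get(seq[q : q + k])
        if r is not None:
            anchors.append((q, r))
    if not anchors:
        return ReadAlignment(read_id, aligned=False)
    chain = _lis_chain(anchors)
    # keep only anchors that are diagonal-consistent or cleanly separated
    filtered = [chain[0]]
    for q, r in chain[1:]:
        pq, pr = filtered[-1]
        if (q - pq == r - pr) or (q >= pq + k and r >= pr + k):
            filtered.append((q, r))
    chain = filtered
    q0, r0 = chain[0]
    qn, rn = chain[-1]
    if (qn + k - q0) / len(seq) < 0.5:
        return ReadAlignment(read_id, aligned=False)

    events: list = []
    subs = 0
    for (aq, ar), (bq, br) in zip(chain, chain[1:]):
        if bq - aq == br - ar:
            seg_q, seg_r = seq[aq + k : bq + k], ref.sequence[ar + k : br + k]
            subs += int(np.count_nonzero(seq_to_array(seg_q) != seq_to_array(seg_r))) if seg_q else 0
            continue
        ev, s = _close_gap(seq[aq + k : bq], ref.sequence[ar + k : br], ar + k)
        events.extend(ev)
        subs += s

    lext, lmism = _extend_end(seq, ref.sequence, q0, r0, -1)
    rext, rmism = _extend_end(seq, ref.sequence, qn + k, rn + k, +1)
    subs += lmism + rmism
    span = (r0 - lext, rn + k + rext)
    clips = (q0 - lext, len(seq) - (qn + k + rext))
    events.sort(key=lambda e: (e.ref_start, isinstance(e, InsertionEvent)))
    return ReadAlignment(read_id, True, events, subs, [span], clips)


# ---------------------------------------------------------------------------
# event normalization


def _left_align_deletion(ref: str, ev: DeletionEvent) -> DeletionEvent:
    start, end = ev.ref_start, ev.ref_end
    while start > 0 and ref[start - 1] == ref[end - 1]:
        start -= 1
        end -= 1
    if start == ev.ref_start:
        return ev
    return DeletionEvent(start, end, ev.junction_insertion)


def _left_align_insertion(ref: str, ev: InsertionEvent) -> InsertionEvent:
    pos, ins = ev.ref_pos, ev.inserted_sequence
    while pos > 0 and ins[-1] == ref[pos - 1]:
        ins = ref[pos - 1] + ins[:-1]
        pos -= 1
    if pos == ev.ref_pos:
        return ev
    return InsertionEvent(pos, ins)


def normalize_events(alignment: ReadAlignment, ref: AmpliconReference, min_spacer: int = 3) -> ReadAlignment:
    """Left-align INDELs and merge near-adjacent deletions.

    Deletions separated by fewer than ``min_spacer`` matched bases are
    merged; the spacer bases are recorded as junction context. Idempotent.
    """
    if not alignment.aligned:
        return alignment
    refseq = ref.sequence
    dels = [_left_align_deletion(refseq, e) for e in alignment.deletions()]
    inss = [_left_align_insertion(refseq, e) for e in alignment.insertions()]
    dels.sort(key=lambda e: e.ref_start)
    merged: list[DeletionEvent] = []
    for ev in dels:
        if merged and ev.ref_start - merged[-1].ref_end < min_spacer:
            prev = merged[-1]
            spacer = refseq[prev.ref_end : ev.ref_start]
            merged[-1] = DeletionEvent(
                prev.ref_start,
                ev.ref_end,
                prev.junction_insertion + spacer + ev.junction_insertion,
            )
        else:
            merged.append(ev)
    events = sorted(
        merged + inss, key=lambda e: (e.ref_start, isinstance(e, InsertionEvent))
    )
    return replace(alignment, events=events)


def apply_events(ref_seq: str, events: list) -> str:
    """Reconstruct the query implied by ``events`` over the full reference."""
    out = []
    pos = 0
    for ev in sorted(events, key=lambda e: (e.ref_start, isinstance(e, InsertionEvent))):
        if isinstance(ev, DeletionEvent):
            out.append(ref_seq[pos : ev.ref_start])
            out.append(ev.junction_insertion)
            pos = ev.ref_end
        else:
            out.append(ref_seq[pos : ev.ref_pos])
            out.append(ev.inserted_sequence)
            pos = ev.ref_pos
    out.append(ref_seq[pos:])
    return "".join(out)


# ---------------------------------------------------------------------------
# external SAM alignments


def parse_external_alignment(records, ref: AmpliconReference) -> ReadAlignment:
    """Convert the SAM records of one read into a ReadAlignment.

    CIGAR D/I runs become events. A primary + supplementary pair on the
    same strand with disjoint reference intervals yields one deletion
    spanning the inter-segment gap, with unaligned query bases recorded as
    junction insertion. Opposite-strand splits are excluded
    (``aligned=False``).
    """
    records = [r for r in records if not r.is_unmapped]
    if not records:
        return ReadAlignment("?", aligned=False)
    names = {r.query_name for r in records}
    if len(names) != 1:
        raise ValueError(f"records span multiple reads: {sorted(names)}")
    read_id = records[0].query_name
    for r in records:
        if r.reference_name != ref.name:
            raise ValueError(
                f"record {read_id} aligned to {r.reference_name}, expected {ref.name}"
            )
        if r.cigartuples is None:
            raise ValueError(f"record {read_id} has no CIGAR")
    if len({r.is_reverse for r in records}) > 1:
        return ReadAlignment(read_id, aligned=False)

    segments = []  # (ref_start, ref_end, query_start, query_end, events, subs)
    for r in records:
        rpos = r.reference_start
        qpos = 0
        q_start = None
        q_end = 0
        events: list = []
        subs = 0
        for op, length in r.cigartuples:
            if op in (0, 7, 8):  # M, =, X
                if q_start is None:
                    q_start = qpos
                if op == 8:
                    subs += length
                rpos += length
                qpos += length
                q_end = qpos
            elif op in (2, 3):  # D, N
                events.append(DeletionEvent(rpos, rpos + length))
                rpos += length
            elif op == 1:  # I
                events.append(InsertionEvent(rpos, r.query_sequence[qpos : qpos + length] if r.query_sequence else "N" * length))
                qpos += length
                q_end = qpos
            elif op in (4, 5):  # S, H
                qpos += length
            elif op == 6:  # P
                continue
            else:
                raise ValueError(f"unsupported CIGAR op {op} in record {read_id}")
        segments.append((r.reference_start, rpos, q_start or 0, q_end, events, subs, r.query_sequence))

    segments.sort(key=lambda s: s[0])
    for (s1, e1, *_), (s2, *_rest) in zip(segments, segments[1:]):
        if s2 < e1:
            # overlapping split segments: ambiguous, reject
            return ReadAlignment(read_id, aligned=False)

    events: list = []
    subs = 0
    spans = []
    for seg in segments:
        events.extend(seg[4])
        subs += seg[5]
        spans.append((seg[0], seg[1]))
    for a, b in zip(segments, segments[1:]):
        junction = ""
        qseq = a[6]
        if qseq is not None:
            # query bases between the two aligned segments (by query coords)
            gap_lo, gap_hi = a[3], b[2]
            if gap_hi > gap_lo:
                junction = qseq[gap_lo:gap_hi]
        if b[0] > a[1]:
            events.append(DeletionEvent(a[1], b[0], junction))
        elif junction:
            events.append(InsertionEvent(a[1], junction))
    events.sort(key=lambda e: (e.ref_start, isinstance(e, InsertionEvent)))
    return ReadAlignment(read_id, True, events, subs, spans)


def read_sam(path: str, ref: AmpliconReference) -> list[ReadAlignment]:
    """Parse a SAM file, grouping records by read name."""
    import pysam

    groups: dict[str, list] = {}
    order: list[str] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.query_name not in groups:
                groups[rec.query_name] = []
                order.append(rec.query_name)
            groups[rec.query_name].append(rec)
    return [parse_external_alignment(groups[name], ref) for name in order]
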