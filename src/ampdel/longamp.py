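"""Long-amplicon short-read (paired-end) pipeline.

Merges read pairs by ungapped overlap, keeps only reads whose alignment
spans the cut site (across deletion gaps included), quantifies the
large-deletion read fraction, and computes control-normalized coverage
depletion profiles.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._seq import revcomp, seq_to_array
from .align import ReadAlignment, align_to_amplicon, normalize_events
from .reference import AmpliconReference
from .variants import ClassificationConfig, classify_variant


@dataclass
class MergedRead:
    read_id: str
    sequence: str
    merged: bool
    overlap: int = 0


@dataclass
class SpanningSet:
    spanning: list[ReadAlignment]
    dropped: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return len(self.spanning) + sum(self.dropped.values())


@dataclass
class CoverageProfile:
    treated_depth: np.ndarray
    control_depth: np.ndarray
    ratio: np.ndarray  # nan where masked
    masked: np.ndarray  # bool


def merge_pairs(
    r1: str,
    r2: str,
    read_id: str = "pair",
    min_overlap: int = 10,
    max_len: int = 600,
    max_mismatch_frac: float = 0.10,
) -> MergedRead:
    """Merge a read pair by its best ungapped overlap.

    ``r2`` is given in sequencing orientation and reverse-complemented
    internally. Overlap disagreements resolve to the base from the mate
    whose position lies farther from its own 3' end. Unmergeable pairs
    (no acceptable overlap, or a merged length above ``max_len``) come
    back with ``merged=False`` and the bare r1 sequence.
    """
    if not r1 or not r2:
        raise ValueError("empty read in pair")
    a = r1.upper()
    b = revcomp(r2.upper())
    aa, bb = seq_to_array(a), seq_to_array(b)
    best = None  # (score, overlap, mismatches)
    for ov in range(min_overlap, min(len(a), len(b)) + 1):
        mism = int(np.count_nonzero(aa[len(a) - ov :] != bb[:ov]))
        if mism > max_mismatch_frac * ov:
            continue
        score = ov - 4 * mism
        if best is None or score > best[0]:
            best = (score, ov, mism)
    if best is None:
        return MergedRead(read_id, a, False)
    ov = best[1]
    merged_len = len(a) + len(b) - ov
    if merged_len > max_len:
        return MergedRead(read_id, a, False)
    overlap = []
    for j in range(ov):
        ca = a[len(a) - ov + j]
        cb = b[j]
        if ca == cb:
            overlap.append(ca)
        else:
            dist_a = ov - j  # distance to r1's 3' end
            dist_b = j + 1  # distance to r2's 3' end (left edge of b)
            overlap.append(ca if dist_a > dist_b else cb)
    seq = a[: len(a) - ov] + "".join(overlap) + b[ov:]
    return MergedRead(read_id, seq, True, ov)


def merge_pair_records(r1_records, r2_records, **kwargs) -> list[MergedRead]:
    if len(r1_records) != len(r2_records):
        raise ValueError("R1/R2 record counts differ")
    out = []
    for a, b in zip(r1_records, r2_records):
        if a.read_id != b.read_id:
            raise ValueError(f"mate id mismatch: {a.read_id} vs {b.read_id}")
        out.append(merge_pairs(a.sequence, b.sequence, read_id=a.read_id, **kwargs))
    return out


def _covers(alignment: ReadAlignment, lo: int, hi: int) -> bool:
    """Does the union of aligned spans plus deletion gaps cover [lo, hi)?"""
    intervals = list(alignment.ref_spans) + [
        (e.ref_start, e.ref_end) for e in alignment.deletions()
    ]
    intervals.sort()
    covered_to = lo
    for s, e in intervals:
        if s > covered_to:
            break
        covered_to = max(covered_to, e)
        if covered_to >= hi:
            return True
    return covered_to >= hi


def filter_spanning(
    alignments: list[ReadAlignment],
    ref: AmpliconReference,
    min_flank: int = 10,
    n_unmerged: int = 0,
) -> SpanningSet:
    """Keep alignments covering cut_site +/- min_flank; count the rest."""
    lo = ref.cut_site - min_flank
    hi = ref.cut_site + min_flank
    out = SpanningSet([], Counter({"unmerged": n_unmerged} if n_unmerged else {}))
    for aln in alignments:
        if not aln.aligned:
            out.dropped["unaligned"] += 1
        elif _covers(aln, lo, hi):
            out.spanning.append(aln)
        else:
            out.dropped["not_spanning"] += 1
    return out


def quantify_ld_fraction(
    spanning: SpanningSet, cfg: ClassificationConfig | None = None
) -> dict:
    """Fraction of spanning reads carrying a large deletion.

    Also reports intermediate-deletion and small-INDEL read fractions and
    the raw category counts.
    """
    cfg = cfg or ClassificationConfig()
    if not spanning.spanning:
        raise ValueError("no spanning reads; LD fraction undefined")
    counts = Counter()
    for aln in spanning.spanning:
        counts[classify_variant(aln, cfg).category] += 1
    n = len(spanning.spanning)
    return {
        "n_spanning": n,
        "counts": dict(counts),
        "ld_fraction": counts["large_deletion"] / n,
        "intermediate_fraction": counts["intermediate_deletion"] / n,
        "small_indel_fraction": counts["small_indel"] / n,
        "unmodified_fraction": counts["unmodified"] / n,
    }


def _depth(alignments: list[ReadAlignment], length: int) -> np.ndarray:
    depth = np.zeros(length)
    for aln in alignments:
        if not aln.aligned:
            continue
        gaps = [(e.ref_start, e.ref_end) for e in aln.deletions()]
        for s, e in aln.ref_spans:
            depth[s:e] += 1
            # spans may or may not include deletion gaps (internal aligner
            # vs split-read segments); subtract only the overlap
            for gs, ge in gaps:
                lo, hi = max(s, gs), min(e, ge)
                if lo < hi:
                    depth[lo:hi] -= 1
    return np.clip(depth, 0, None)


def coverage_depletion(
    treated: list[ReadAlignment],
    control: list[ReadAlignment],
    ref: AmpliconReference,
) -> CoverageProfile:
    """Per-position treated/control depth ratio, flank-normalized.

    Each sample's depth is scaled by its median depth over the outer 10%
    of the amplicon (5% per end); positions with zero control depth are
    masked (ratio nan).
    """
    L = len(ref.sequence)
    flank = max(1, L // 20)
    idx = np.r_[0:flank, L - flank : L]
    td = _depth(treated, L)
    cd = _depth(control, L)
    c_norm = np.median(cd[idx])
    if c_norm == 0 or cd.sum() == 0:
        raise ValueError("control sample has no flank coverage")
    t_norm = np.median(td[idx])
    if t_norm == 0:
        t_norm = 1.0  # empty treated sample: report raw (zero) ratios
    masked = cd == 0
    ratio = np.full(L, np.nan)
    ratio[~masked] = (td[~masked] / t_norm) / (cd[~masked] / c_norm)
    return CoverageProfile(td, cd, ratio, masked)


def longamp_pipeline(
    r1_records,
    r2_records,
    ref: AmpliconReference,
    min_flank: int = 10,
    cfg: ClassificationConfig | None = None,
    min_overlap: int = 10,
    max_len: int = 600,
):
    """merge -> align -> spanning filter -> LD quantification."""
    merged = merge_pair_records(r1_records, r2_records, min_overlap=min_overlap, max_len=max_len)
    kept = [m for m in merged if m.merged]
    alignments = [
        normalize_events(align_to_amplicon(m.sequence, ref, read_id=m.read_id), ref)
        for m in kept
    ]
    spanning = filter_spanning(
        alignments, ref, min_flank=min_flank, n_unmerged=len(merged) - len(kept)
    )
    report = quantify_ld_fraction(spanning, cfg)
    return spanning, report
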