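"""Dual-UMI extraction, binning, chimera filtering, and consensus calling.

Reads are expected to carry an 18-nt patterned UMI (default
``NNNYRNNNYRNNNYRNNN``) immediately inside each flanking primer:

    [primer5][umi5][insert][revcomp(umi3)][revcomp(primer3)]

A molecule is identified by its (umi5, umi3) pair; PCR duplicates collapse
into one bin and cross-molecule chimeras show up as low-count bins whose
ends each match a dominant bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import fuzzy_find, hamming, matches_iupac, revcomp, seq_to_array

DEFAULT_UMI_PATTERN = "NNNYRNNNYRNNNYRNNN"


@dataclass
class UmiSpec:
    """Patterned dual-UMI layout with flanking primer anchors."""

    primer5: str
    primer3: str
    pattern: str = DEFAULT_UMI_PATTERN
    max_primer_edits: int = 2

    def __post_init__(self) -> None:
        self.primer5 = self.primer5.upper()
        self.primer3 = self.primer3.upper()
        self.pattern = self.pattern.upper()
        if len(self.pattern) != 18:
            raise ValueError("UMI pattern must be 18 nt")
        if set(self.pattern) - set("NYR"):
            raise ValueError("UMI pattern may only use IUPAC codes N, Y, R")

    @property
    def umi_length(self) -> int:
        return len(self.pattern)


@dataclass
class TaggedRead:
    read_id: str
    umi5: str
    umi3: str
    insert: str


@dataclass
class InvalidRead:
    read_id: str
    reason: str  # no_anchor | bad_pattern | too_short


@dataclass
class UmiBin:
    umi5: str
    umi3: str
    members: list[TaggedRead] = field(default_factory=list)
    chimera_flag: bool = False
    consensus: str | None = None

    @property
    def key(self) -> str:
        return self.umi5 + self.umi3

    @property
    def read_count(self) -> int:
        return len(self.members)

    @property
    def read_ids(self) -> list[str]:
        return [m.read_id for m in self.members]


def extract_umi_pair(read_seq: str, spec: UmiSpec, read_id: str = "read"):
    """Extract the dual UMI pair and trimmed insert from one read.

    Both orientations are tried; the returned ``umi5`` is always the UMI
    adjacent to the 5' target primer. Returns a TaggedRead or an
    InvalidRead with a reason.
    """
    read_seq = read_seq.upper()
    L = spec.umi_length
    min_len = 2 * (len(spec.primer5) + L)
    if len(read_seq) < min_len:
        return InvalidRead(read_id, "too_short")
    for oriented in (read_seq, revcomp(read_seq)):
        hit5 = fuzzy_find(oriented, spec.primer5, spec.max_primer_edits)
        if hit5 is None:
            continue
        hit3 = fuzzy_find(oriented, revcomp(spec.primer3), spec.max_primer_edits)
        if hit3 is None:
            continue
        u5_end = hit5[1] + L
        u3_start = hit3[0] - L
        if u3_start - u5_end < 0:
            continue
        umi5 = oriented[hit5[1] : u5_end]
        umi3 = revcomp(oriented[u3_start : hit3[0]])
        if not (matches_iupac(umi5, spec.pattern) and matches_iupac(umi3, spec.pattern)):
            return InvalidRead(read_id, "bad_pattern")
        return TaggedRead(read_id, umi5, umi3, oriented[u5_end:u3_start])
    return InvalidRead(read_id, "no_anchor")


def bin_by_umi(tagged: list[TaggedRead], merge_hamming: int = 2) -> list[UmiBin]:
    """Group reads by exact UMI pair, then absorb near-miss bins.

    A bin is absorbed into another when their concatenated 36-mer keys are
    within ``merge_hamming`` mismatches and the absorber holds at least 3x
    the reads (sequencing errors in the UMI, not distinct molecules).
    Output is sorted by descending read count.
    """
    exact: dict[tuple[str, str], list[TaggedRead]] = {}
    for t in tagged:
        exact.setdefault((t.umi5, t.umi3), []).append(t)
    keys = sorted(exact, key=lambda k: (-len(exact[k]), k))
    if merge_hamming > 0 and len(keys) > 1:
        counts = np.array([len(exact[k]) for k in keys])
        mat = np.vstack([seq_to_array(k5 + k3) for k5, k3 in keys])
        target = {}  # index -> absorber index
        # small bins scan larger bins; process smallest first
        for i in range(len(keys) - 1, 0, -1):
            bigger = np.nonzero(counts[:i] >= 3 * counts[i])[0]
            if not len(bigger):
                continue
            dists = np.count_nonzero(mat[bigger] != mat[i], axis=1)
            ok = np.nonzero(dists <= merge_hamming)[0]
            if len(ok):
                best = ok[np.argmin(dists[ok])]
                target[i] = int(bigger[best])
        for i, j in sorted(target.items(), reverse=True):
            while j in target:  # follow chains to the final absorber
                j = target[j]
            exact[keys[j]].extend(exact[keys[i]])
            del exact[keys[i]]
    bins = [UmiBin(k5, k3, members) for (k5, k3), members in exact.items()]
    bins.sort(key=lambda b: (-b.read_count, b.key))
    return bins


def filter_chimeric_bins(bins: list[UmiBin], dominance: float = 10) -> list[UmiBin]:
    """Flag bins whose two UMI ends each belong to a distinct dominant bin.

    Bin B is chimeric when some bin X shares B's umi5 with
    >= dominance * B.read_count reads AND some different bin Y shares B's
    umi3 at the same dominance. Flags are set in place; the list is
    returned for chaining.
    """
    by5: dict[str, list[UmiBin]] = {}
    by3: dict[str, list[UmiBin]] = {}
    for b in bins:
        by5.setdefault(b.umi5, []).append(b)
        by3.setdefault(b.umi3, []).append(b)
    for b in bins:
        xs = [x for x in by5[b.umi5] if x is not b and x.read_count >= dominance * b.read_count]
        ys = [y for y in by3[b.umi3] if y is not b and y.read_count >= dominance * b.read_count]
        # X and Y are necessarily different bins: sharing both ends with B
        # would collide with B's own key
        b.chimera_flag = bool(xs and ys)
    return bins


def _medoid(seqs: list[str]) -> int:
    """Index of the member with minimal summed distance to the others."""
    lengths = {len(s) for s in seqs}
    if len(lengths) == 1:
        mat = np.vstack([seq_to_array(s) for s in seqs])
        # pairwise hamming via broadcasting; member counts are small
        diffs = (mat[:, None, :] != mat[None, :, :]).sum(axis=2)
        return int(np.argmin(diffs.sum(axis=1)))
    from ._seq import edit_distance

    n = len(seqs)
    totals = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            d = edit_distance(seqs[i], seqs[j], band=abs(len(seqs[i]) - len(seqs[j])) + 16)
            totals[i] += d
            totals[j] += d
    return int(np.argmin(totals))


def call_consensus(bin_: UmiBin, min_reads: int = 3) -> str | None:
    """Medoid + per-column plurality consensus for one UMI bin.

    Bins with fewer than ``min_reads`` members or a chimera flag are
    rejected (returns None). Ties at a column resolve to the medoid base.
    """
    if bin_.chimera_flag or bin_.read_count < min_reads:
        return None
    seqs = [m.insert for m in bin_.members]
    mi = _medoid(seqs)
    medoid = seqs[mi]
    same_len = [s for s in seqs if len(s) == len(medoid)]
    if len(same_len) == len(seqs):
        aligned = seqs
    else:
        aligned = _align_members_to_medoid(seqs, medoid)
    mat = np.vstack([seq_to_array(s) for s in aligned])
    med = seq_to_array(medoid)
    out = med.copy()
    counts = np.zeros((4, len(medoid)), dtype=np.int32)
    for ci, code in enumerate((65, 67, 71, 84)):
        counts[ci] = (mat == code).sum(axis=0)
    best = counts.max(axis=0)
    med_counts = np.take_along_axis(
        counts, np.searchsorted([65, 67, 71, 84], med)[None, :], axis=0
    )[0]
    argbest = counts.argmax(axis=0)
    strict = best > med_counts  # plurality strictly beats the medoid base
    out[strict] = np.array([65, 67, 71, 84], dtype=np.uint8)[argbest[strict]]
    consensus = out.tobytes().decode("ascii")
    bin_.consensus = consensus
    return consensus


def _align_members_to_medoid(seqs: list[str], medoid: str) -> list[str]:
    """Project each member onto medoid coordinates (gaps -> medoid base).

    Members whose length differs from the medoid are banded-aligned; only
    their matched columns vote, unmatched columns fall back to the medoid
    base. Rare path: the simulator introduces substitutions only.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    out = []
    for s in seqs:
        if len(s) == len(medoid):
            out.append(s)
            continue
        aln = aligner.align(medoid, s)[0]
        proj = list(medoid)
        for (ms, me), (ss, se) in zip(*aln.aligned):
            proj[ms:me] = s[ss:se]
        out.append("".join(proj))
    return out


def consensus_pipeline(
    tagged: list[TaggedRead],
    min_reads: int = 3,
    merge_hamming: int = 2,
    dominance: float = 10,
) -> list[UmiBin]:
    """bin -> chimera filter -> consensus; returns all bins (flags set)."""
    bins = bin_by_umi(tagged, merge_hamming=merge_hamming)
    filter_chimeric_bins(bins, dominance=dominance)
    for b in bins:
        call_consensus(b, min_reads=min_reads)
    return bins
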