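"""Classification and profiling of editing outcomes.

Implements the four-way outcome grouping (small INDEL / intermediate
deletion / large deletion / large insertion, with combined
insertion+deletion folded into the insertion group), tolerance-based
clustering of large-deletion patterns, cut-site symmetry labeling,
microhomology detection, insertion-origin mapping against a candidate
sequence set, and small-INDEL tabulation around the cut site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import revcomp, seq_to_array
from .align import DeletionEvent, InsertionEvent, ReadAlignment
from .reference import AmpliconReference


@dataclass
class ClassificationConfig:
    small_max: int = 50  # exclusive upper bound for small INDELs
    ld_min: int = 200  # deletions >= this are large deletions
    large_insertion_min: int = 50
    cluster_size_tol: int = 10
    cluster_start_tol: int = 10
    symmetry_delta_max: float = 0.05
    mmej_min_del: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.small_max <= self.ld_min):
            raise ValueError("require 0 < small_max <= ld_min")
        for name in ("cluster_size_tol", "cluster_start_tol", "symmetry_delta_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


CATEGORIES = (
    "unmodified",
    "small_indel",
    "intermediate_deletion",
    "large_deletion",
    "large_insertion",
    "insertion_with_deletion",
    "invalid",
)


@dataclass
class VariantCall:
    read_id: str
    category: str
    events: list = field(default_factory=list)
    largest_deletion_size: int = 0
    largest_insertion_size: int = 0
    substitutions: int = 0

    def largest_deletion(self) -> DeletionEvent | None:
        dels = [e for e in self.events if isinstance(e, DeletionEvent)]
        return max(dels, key=lambda e: e.size) if dels else None


@dataclass
class LDPattern:
    rep_start: int
    rep_size: int
    member_ids: list[str]
    count: int
    delta: float = float("nan")
    side: str = ""

    @property
    def midpoint(self) -> float:
        return self.rep_start + self.rep_size / 2


@dataclass
class InsertionOriginHit:
    candidate: str
    offset: int
    strand: str  # forward | inverted
    mismatch_fraction: float


@dataclass
class IndelProfile:
    histogram: dict[int, int]
    position_frequency: np.ndarray
    mmej_fraction: float | None
    n_calls: int


def classify_variant(alignment: ReadAlignment, cfg: ClassificationConfig | None = None) -> VariantCall:
    """Assign one alignment to an outcome category.

    Precedence: invalid (unaligned) > insertion_with_deletion >
    large_insertion > large_deletion > intermediate_deletion > small_indel
    > unmodified. A deletion's junction insertion counts toward the
    largest-insertion size.
    """
    cfg = cfg or ClassificationConfig()
    if not alignment.aligned:
        return VariantCall(alignment.read_id, "invalid")
    del_sizes = [e.size for e in alignment.events if isinstance(e, DeletionEvent)]
    ins_sizes = [e.size for e in alignment.events if isinstance(e, InsertionEvent)]
    ins_sizes += [
        len(e.junction_insertion)
        for e in alignment.events
        if isinstance(e, DeletionEvent) and e.junction_insertion
    ]
    ld = max(del_sizes, default=0)
    li = max(ins_sizes, default=0)
    if li >= cfg.large_insertion_min and ld >= cfg.small_max:
        cat = "insertion_with_deletion"
    elif li >= cfg.large_insertion_min:
        cat = "large_insertion"
    elif ld >= cfg.ld_min:
        cat = "large_deletion"
    elif ld >= cfg.small_max:
        cat = "intermediate_deletion"
    elif alignment.events:
        cat = "small_indel"
    else:
        cat = "unmodified"
    return VariantCall(
        alignment.read_id, cat, list(alignment.events), ld, li, alignment.substitutions
    )


def cluster_ld_patterns(calls: list[VariantCall], cfg: ClassificationConfig | None = None) -> list[LDPattern]:
    """Greedy clustering of large deletions by (start, size) tolerance.

    Unique (start, size) pairs are visited in order of decreasing
    abundance; a pair joins an existing cluster when both its start and
    size are within the configured tolerances of the cluster
    representative (the seed, its most abundant member). Ties go to the
    more abundant cluster, then the lower representative start.
    """
    cfg = cfg or ClassificationConfig()
    groups: dict[tuple[int, int], list[str]] = {}
    for call in calls:
        dele = call.largest_deletion()
        if dele is None or dele.size < cfg.ld_min:
            raise ValueError(f"call {call.read_id} is not a large deletion")
        groups.setdefault((dele.ref_start, dele.size), []).append(call.read_id)
    order = sorted(groups, key=lambda k: (-len(groups[k]), k))
    clusters: list[LDPattern] = []
    for start, size in order:
        members = groups[(start, size)]
        best = None
        for cl in clusters:
            if (
                abs(start - cl.rep_start) <= cfg.cluster_start_tol
                and abs(size - cl.rep_size) <= cfg.cluster_size_tol
            ):
                key = (-cl.count, cl.rep_start)
                if best is None or key < (-best.count, best.rep_start):
                    best = cl
        if best is None:
            clusters.append(LDPattern(start, size, list(members), len(members)))
        else:
            best.member_ids.extend(members)
            best.count += len(members)
    clusters.sort(key=lambda c: (-c.count, c.rep_start, c.rep_size))
    return clusters


def classify_symmetry(
    pattern: LDPattern, ref: AmpliconReference, cfg: ClassificationConfig | None = None
) -> str:
    """Label a deletion pattern symmetric/upstream/downstream of the cut.

    delta = |midpoint - cut_site| / size; symmetric when delta <= the
    configured maximum (boundary inclusive), else the side of the midpoint
    in reference coordinates.
    """
    cfg = cfg or ClassificationConfig()
    delta = abs(pattern.midpoint - ref.cut_site) / pattern.rep_size
    pattern.delta = delta
    if delta <= cfg.symmetry_delta_max:
        pattern.side = "symmetric"
    elif pattern.midpoint < ref.cut_site:
        pattern.side = "upstream"
    else:
        pattern.side = "downstream"
    return pattern.side


def detect_microhomology(ref_seq: str, deletion: DeletionEvent) -> tuple[str, int]:
    """Microhomology at a deletion junction.

    Longest m with ref[start:start+m] == ref[end:end+m] after
    left-alignment: the deleted prefix matching the retained right flank.
    """
    if deletion.junction_insertion:
        raise ValueError("microhomology is undefined for junctions with insertions")
    start, end = deletion.ref_start, deletion.ref_end
    m = 0
    limit = min(deletion.size, len(ref_seq) - end)
    while m < limit and ref_seq[start + m] == ref_seq[end + m]:
        m += 1
    return ref_seq[start : start + m], m


def classify_mmej(call: VariantCall, cfg: ClassificationConfig | None = None) -> bool:
    """True for pure small deletions of >= mmej_min_del bases."""
    cfg = cfg or ClassificationConfig()
    if call.category != "small_indel":
        raise ValueError("MMEJ classification applies to small_indel calls only")
    dels = [e for e in call.events if isinstance(e, DeletionEvent)]
    inss = [e for e in call.events if isinstance(e, InsertionEvent)]
    if inss or len(dels) != 1:
        return False
    d = dels[0]
    return d.size >= cfg.mmej_min_del and not d.junction_insertion


def map_insertion_origin(
    inserted_sequence: str,
    candidates: dict[str, str],
    max_mismatch_frac: float = 0.10,
) -> InsertionOriginHit | None:
    """Ungapped scan of an inserted sequence against candidate sources.

    Both strands of every candidate are scanned at every offset; the best
    hit (lowest mismatch fraction, ties to the forward strand then the
    lowest offset, then candidate name) is returned, or None when every
    placement exceeds ``max_mismatch_frac``.
    """
    if not candidates:
        import warnings

        warnings.warn("empty candidate set for insertion-origin mapping")
        return None
    ins = inserted_sequence.upper()
    n = len(ins)
    ins_arr = seq_to_array(ins)
    best: tuple | None = None
    for name in sorted(candidates):
        seq = candidates[name].upper()
        for strand, text in (("forward", seq), ("inverted", revcomp(seq))):
            if len(text) < n:
                continue
            arr = seq_to_array(text)
            windows = np.lib.stride_tricks.sliding_window_view(arr, n)
            mism = (windows != ins_arr).sum(axis=1)
            off = int(mism.argmin())
            frac = mism[off] / n
            if frac > max_mismatch_frac:
                continue
            if strand == "inverted":
                off = len(text) - n - off  # report on forward coordinates
            key = (frac, strand != "forward", off, name)
            if best is None or key < best[0]:
                best = (key, InsertionOriginHit(name, off, strand, float(frac)))
    return best[1] if best else None


def tabulate_small_indels(
    calls: list[VariantCall],
    ref: AmpliconReference,
    window: int = 30,
    cfg: ClassificationConfig | None = None,
) -> IndelProfile:
    """Histogram of signed INDEL sizes in a window around the cut site.

    Only unmodified/small_indel calls are accepted. Deletions count with
    negative sign, insertions positive; per-position modification
    frequency covers deletion footprints and insertion anchor points.
    """
    cfg = cfg or ClassificationConfig()
    for c in calls:
        if c.category not in ("unmodified", "small_indel"):
            raise ValueError(f"call {c.read_id} has category {c.category}")
    lo, hi = ref.cut_site - window, ref.cut_site + window
    hist: dict[int, int] = {}
    posfreq = np.zeros(len(ref.sequence))
    n_indel_calls = 0
    n_mmej = 0
    for c in calls:
        in_window = False
        for ev in c.events:
            if isinstance(ev, DeletionEvent):
                if ev.ref_end <= lo or ev.ref_start >= hi:
                    continue
                hist[-ev.size] = hist.get(-ev.size, 0) + 1
                posfreq[ev.ref_start : ev.ref_end] += 1
                in_window = True
            else:
                if not (lo <= ev.ref_pos < hi):
                    continue
                hist[ev.size] = hist.get(ev.size, 0) + 1
                posfreq[min(ev.ref_pos, len(ref.sequence) - 1)] += 1
                in_window = True
        if c.category == "small_indel" and in_window:
            n_indel_calls += 1
            if classify_mmej(c, cfg):
                n_mmej += 1
    mmej_fraction = n_mmej / n_indel_calls if n_indel_calls else None
    return IndelProfile(hist, posfreq / max(len(calls), 1), mmej_fraction, n_indel_calls)
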