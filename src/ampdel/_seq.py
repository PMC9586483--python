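"""Small sequence utilities shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtnYRyr", "TGCANtgcanRYry")

#: IUPAC code -> allowed bases (only the codes used by patterned UMIs plus ACGT)
IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "N": "ACGT",
    "Y": "CT",
    "R": "AG",
}

BASES = "ACGT"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_array(seq: str) -> np.ndarray:
    """Encode a sequence as a uint8 array of ASCII codes."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return int(np.count_nonzero(seq_to_array(a) != seq_to_array(b)))


def matches_iupac(seq: str, pattern: str) -> bool:
    """True if ``seq`` matches the IUPAC ``pattern`` position by position."""
    if len(seq) != len(pattern):
        return False
    return all(base in IUPAC[code] for base, code in zip(seq, pattern))


def random_from_pattern(pattern: str, rng: np.random.Generator) -> str:
    """Draw a random sequence conforming to an IUPAC pattern."""
    return "".join(IUPAC[code][rng.integers(len(IUPAC[code]))] for code in pattern)


def edit_distance(a: str, b: str, band: int | None = None) -> int:
    """Levenshtein distance, optionally banded around the main diagonal.

    The band must be at least ``|len(a) - len(b)|`` for the result to be
    exact; callers comparing near-identical sequences pass a small band for
    speed.
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return max(n, m)
    if band is None:
        band = max(n, m)
    band = max(band, abs(n - m) + 1)
    aa = seq_to_array(a)
    bb = seq_to_array(b)
    big = n + m + 1
    prev = np.arange(m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        lo = max(1, i - band)
        hi = min(m, i + band)
        cur = np.full(m + 1, big, dtype=np.int64)
        if lo == 1:
            cur[0] = i
        sub = prev[lo - 1 : hi] + (aa[i - 1] != bb[lo - 1 : hi])
        dele = prev[lo : hi + 1] + 1
        cur[lo : hi + 1] = np.minimum(sub, dele)
        # insertions propagate left-to-right inside the band
        for j in range(lo, hi + 1):
            if cur[j - 1] + 1 < cur[j]:
                cur[j] = cur[j - 1] + 1
        prev = cur
    return int(prev[m])


def _semiglobal_end_costs(pattern: str, text: str) -> np.ndarray:
    """Edit cost of aligning the whole pattern ending at each text position.

    Returns an array of length ``len(text) + 1`` where entry ``j`` is the
    minimum edit distance between ``pattern`` and some suffix of
    ``text[:j]`` (free start, fixed end at ``j``).
    """
    tt = seq_to_array(text)
    row = np.zeros(len(text) + 1, dtype=np.int64)
    for ch in pattern:
        nxt = np.empty_like(row)
        nxt[0] = row[0] + 1
        sub = row[:-1] + (tt != ord(ch))
        dele = row[1:] + 1
        best = np.minimum(sub, dele)
        nxt[1:] = best
        # insertion (consume a text base) propagates left to right; a
        # prefix-min over (cost - j) implements unit-cost propagation
        j_idx = np.arange(len(nxt), dtype=np.int64)
        nxt = np.minimum.accumulate(nxt - j_idx) + j_idx
        row = nxt
    return row


def fuzzy_find(text: str, pattern: str, max_edits: int = 2) -> tuple[int, int, int] | None:
    """Locate the best occurrence of ``pattern`` inside ``text``.

    Returns ``(start, end, edits)`` for the leftmost minimum-edit match with
    ``edits <= max_edits``, or None. An exact substring search is tried
    first.
    """
    idx = text.find(pattern)
    if idx >= 0:
        return idx, idx + len(pattern), 0
    if len(text) == 0 or len(pattern) == 0:
        return None
    costs = _semiglobal_end_costs(pattern, text)
    best = int(costs.min())
    if best > max_edits:
        return None
    end = int(np.argmin(costs))
    # recover the start by aligning the reversed pattern against the
    # reversed window preceding ``end``
    w0 = max(0, end - len(pattern) - max_edits)
    window = text[w0:end][::-1]
    rcosts = _semiglobal_end_costs(pattern[::-1], window)
    rend = int(np.argmin(rcosts))
    start = end - rend
    return start, end, best
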