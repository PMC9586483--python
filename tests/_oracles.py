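"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: plain dynamic
programming, enumeration, and direct counting only.
"""

from __future__ import annotations


def dp_edit_distance(a: str, b: str) -> int:
    """Full O(nm) Levenshtein, no banding."""
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j - 1] + (a[i - 1] != b[j - 1]),
                prev[j] + 1,
                cur[j - 1] + 1,
            )
        prev = cur
    return prev[m]


def leftmost_deletion_start(ref: str, start: int, end: int) -> int:
    """Smallest start' such that removing [start', start'+size) from ref
    yields the same sequence as removing [start, end)."""
    size = end - start
    target = ref[:start] + ref[end:]
    best = start
    for s in range(start - 1, -1, -1):
        if ref[:s] + ref[s + size :] == target:
            best = s
    return best


def max_right_flank_overlap(ref: str, start: int, end: int) -> int:
    """Brute-force microhomology: longest m with ref[start:start+m] == ref[end:end+m]."""
    best = 0
    limit = min(end - start, len(ref) - end)
    for m in range(limit + 1):
        if ref[start : start + m] == ref[end : end + m]:
            best = m
    return best


def seed_linkage_clusters(pairs_with_counts, start_tol=10, size_tol=10):
    """Brute-force re-statement of abundance-seeded tolerance clustering.

    pairs_with_counts: list of ((start, size), count). Returns a list of
    frozensets of (start, size) pairs.
    """
    order = sorted(pairs_with_counts, key=lambda pc: (-pc[1], pc[0]))
    clusters = []  # [ (seed, members set, count) ]
    for (start, size), count in order:
        candidates = []
        for idx, (seed, members, ccount) in enumerate(clusters):
            if abs(start - seed[0]) <= start_tol and abs(size - seed[1]) <= size_tol:
                candidates.append(((-ccount, seed[0]), idx))
        if candidates:
            idx = min(candidates)[1]
            clusters[idx][1].add((start, size))
            clusters[idx] = (clusters[idx][0], clusters[idx][1], clusters[idx][2] + count)
        else:
            clusters.append(((start, size), {(start, size)}, count))
    return [frozenset(members) for _, members, _ in clusters]


def scan_best_ungapped_hit(insert: str, candidates: dict[str, str]):
    """Exhaustive ungapped scan oracle for insertion-origin mapping."""
    from ampdel._seq import revcomp

    best = None
    n = len(insert)
    for name in sorted(candidates):
        seq = candidates[name]
        for strand, text in (("forward", seq), ("inverted", revcomp(seq))):
            for off in range(len(text) - n + 1):
                mism = sum(a != b for a, b in zip(insert, text[off : off + n]))
                rep_off = off if strand == "forward" else len(text) - n - off
                key = (mism / n, strand != "forward", rep_off, name)
                if best is None or key < best:
                    best = key
    return best
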