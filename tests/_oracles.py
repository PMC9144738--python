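"""Independent reference implementations used only to check the package.

These are deliberately naive (full dynamic programming, exhaustive scans,
dict-based union-find) and share no code with the implementation paths they
validate.
"""

from __future__ import annotations

import re

_COMP = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def smith_waterman(a: str, b: str, match=2, mismatch=-3, gap=-5):
    """Full local-alignment DP with traceback.

    Returns (score, alignment_length, percent_identity, a_span, b_span)
    for the best local alignment, or None when the best score is 0.
    """
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    best, best_pos = 0, None
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = H[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            h = max(0, diag, H[i - 1][j] + gap, H[i][j - 1] + gap)
            H[i][j] = h
            if h > best:
                best, best_pos = h, (i, j)
    if best_pos is None:
        return None
    i, j = best_pos
    cols = matches = 0
    end_a, end_b = i, j
    while i > 0 and j > 0 and H[i][j] > 0:
        diag = H[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
        if H[i][j] == diag:
            matches += a[i - 1] == b[j - 1]
            cols += 1
            i, j = i - 1, j - 1
        elif H[i][j] == H[i - 1][j] + gap:
            cols += 1
            i -= 1
        else:
            cols += 1
            j -= 1
    identity = 100.0 * matches / cols
    return best, cols, identity, (i, end_a), (j, end_b)


def union_find_partition(ids, edges):
    """Connected components via a plain dict union-find."""
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        parent[find(a)] = find(b)
    groups = {}
    for i in ids:
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


def digest_by_restriction_oracle(sequence: str, sites: dict[str, int]):
    """Fragment lengths from a plain regex scan-and-split.

    ``sites`` maps recognition sequence -> cut offset.  Returns the sorted
    cut positions and the fragment length list.
    """
    cuts = set()
    for site, offset in sites.items():
        for m in re.finditer(f"(?={site})", sequence):
            cuts.add(m.start() + offset)
    bounds = [0] + sorted(c for c in cuts if 0 < c < len(sequence)) + [len(sequence)]
    lengths = [b - a for a, b in zip(bounds, bounds[1:])]
    return sorted(cuts), lengths


def hamming_positions(seq: str, pattern: str, max_mm: int):
    """All window positions where pattern matches with <= max_mm substitutions."""
    out = []
    for i in range(len(seq) - len(pattern) + 1):
        mm = sum(x != y for x, y in zip(seq[i : i + len(pattern)], pattern))
        if mm <= max_mm:
            out.append(i)
    return out
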