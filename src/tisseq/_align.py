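"""Pairwise alignment primitives shared by the clustering and long-read modules.

All inter-sequence comparisons in the pipeline reduce to one question: is the
shorter of two sequences contained in the longer one at high identity, and over
what span?  That containment alignment is computed with edlib (bit-parallel
Myers edit distance, infix/"HW" mode), on both strands, and summarised as an
:class:`AlignmentHit` carrying percent identity, alignment length and the two
coverage values qCOV and sCOV (alignment span as a percentage of query and
subject length respectively).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, slots=True)
class AlignmentHit:
    """A qualifying alignment between two distinct sequences.

    qcov and scov are the alignment span expressed as a percentage of the
    query and subject lengths; self-pairs are never emitted.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    qcov: float
    scov: float
    strand: str  # '+' or '-'


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """Return (alignment columns, match columns) from an extended cigar."""
    cols = 0
    matches = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        cols += n
        if op == "=":
            matches += n
    return cols, matches


def containment_alignment(
    query: str, subject: str, max_distance_fraction: float = 0.35
) -> tuple[float, int, str] | None:
    """Best infix alignment of ``query`` within ``subject``, both strands.

    Returns ``(percent_identity, alignment_length, strand)`` or ``None`` when
    no alignment within the distance budget exists.  ``query`` must be the
    shorter (or equal-length) sequence.  Identity is computed over alignment
    columns from the extended cigar, so indels count as non-matches.
    """
    if not query or not subject:
        return None
    k = max(1, int(len(query) * max_distance_fraction))
    best = None
    for strand, q in (("+", query), ("-", revcomp(query))):
        res = edlib.align(q, subject, mode="HW", task="path", k=k)
        if res["editDistance"] < 0:
            continue
        cols, matches = _cigar_stats(res["cigar"])
        identity = 100.0 * matches / cols if cols else 0.0
        if best is None or identity > best[0] or (
            identity == best[0] and strand == "+" and best[2] == "-"
        ):
            best = (identity, cols, strand)
    return best


def pair_hit(
    id_a: str,
    seq_a: str,
    id_b: str,
    seq_b: str,
    min_identity: float = 80.0,
    min_length: int = 20,
) -> AlignmentHit | None:
    """Alignment hit for the ordered pair (query=a, subject=b).

    The shorter sequence is aligned into the longer one; the alignment span is
    reported symmetrically, so the hit for (a, b) mirrors the hit for (b, a)
    with query/subject coverage swapped.
    """
    if not seq_a or not seq_b:
        return None
    if len(seq_a) <= len(seq_b):
        aln = containment_alignment(seq_a, seq_b)
    else:
        aln = containment_alignment(seq_b, seq_a)
    if aln is None:
        return None
    identity, length, strand = aln
    if identity < min_identity or length < min_length:
        return None
    qcov = min(100.0, 100.0 * length / len(seq_a))
    scov = min(100.0, 100.0 * length / len(seq_b))
    return AlignmentHit(id_a, id_b, identity, length, qcov, scov, strand)


def edge_qualifies(
    hit: AlignmentHit, cov_threshold: float = 70.0, identity_threshold: float = 90.0
) -> bool:
    """The pipeline's same-locus rule: (qCOV >= t OR sCOV >= t) AND identity floor."""
    return (
        hit.percent_identity >= identity_threshold
        and (hit.qcov >= cov_threshold or hit.scov >= cov_threshold)
    )


class DisjointSet:
    """Union-find over hashable items; used for single-linkage clustering."""

    def __init__(self, items=()):
        self._parent = {x: x for x in items}

    def add(self, item) -> None:
        self._parent.setdefault(item, item)

    def find(self, item):
        parent = self._parent
        root = item
        while parent[root] != root:
            root = parent[root]
        while parent[item] != root:
            parent[item], item = root, parent[item]
        return root

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self._parent[rb] = ra

    def groups(self) -> list[list]:
        out: dict[object, list] = {}
        for item in self._parent:
            out.setdefault(self.find(item), []).append(item)
        return list(out.values())
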