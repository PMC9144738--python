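"""Module 5 of the pipeline: compare ISS sets between two treatments.

After a last artefact filter (representatives still containing an adapter
variant are discarded), the two non-redundant ISS sets are matched by
reciprocal best hit under the same coverage/identity edge rule used for
clustering.  Each record ends up either in exactly one shared pair or in its
set's unique list, which yields the Venn-diagram counts
(|shared|, |unique to A|, |unique to B|).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from ._align import edge_qualifies, pair_hit, revcomp
from .redundancy import (
    DEFAULT_COV_THRESHOLD,
    DEFAULT_IDENTITY_THRESHOLD,
    ISSRecord,
    _canonical_kmers,
)
from .trimming import best_match


@dataclass(frozen=True)
class ComparisonResult:
    shared_pairs: tuple[tuple[str, str], ...]
    unique_a: tuple[str, ...]
    unique_b: tuple[str, ...]

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.shared_pairs), len(self.unique_a), len(self.unique_b))


def adapter_variation_filter(
    records: Sequence[ISSRecord],
    adapters: Sequence[str],
    max_mismatch: int = 2,
) -> tuple[list[ISSRecord], int]:
    """Drop records whose representative still contains an adapter variant.

    The scan allows substitutions only, on both strands.  Returns the kept
    records and the number removed.
    """
    kept, removed = [], 0
    for rec in records:
        seq = rec.representative_sequence
        hit = any(
            best_match(seq, pattern, max_mismatch)
            for adapter in adapters
            for pattern in (adapter, revcomp(adapter))
        )
        if hit:
            removed += 1
        else:
            kept.append(rec)
    return kept, removed


def _best_hits(
    queries: Sequence[ISSRecord],
    subjects: Sequence[ISSRecord],
    cov_threshold: float,
    identity_threshold: float,
) -> dict[str, str]:
    """Best qualifying subject per query (identity, then alignment length, then id)."""
    subj_index: dict[str, list[int]] = {}
    for j, s in enumerate(subjects):
        for kmer in _canonical_kmers(s.representative_sequence):
            subj_index.setdefault(kmer, []).append(j)
    best: dict[str, str] = {}
    for q in queries:
        candidates = set()
        for kmer in _canonical_kmers(q.representative_sequence):
            candidates.update(subj_index.get(kmer, ()))
        scored = []
        for j in sorted(candidates):
            s = subjects[j]
            hit = pair_hit(
                q.representative_id,
                q.representative_sequence,
                s.representative_id,
                s.representative_sequence,
                min_identity=identity_threshold,
                min_length=1,
            )
            if hit and edge_qualifies(hit, cov_threshold, identity_threshold):
                scored.append(
                    (-hit.percent_identity, -hit.alignment_length, s.representative_id)
                )
        if scored:
            best[q.representative_id] = min(scored)[2]
    return best


def cross_compare(
    set_a: Sequence[ISSRecord],
    set_b: Sequence[ISSRecord],
    cov_threshold: float = DEFAULT_COV_THRESHOLD,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> ComparisonResult:
    """Reciprocal-best matching between two non-redundant ISS sets.

    A pair is shared iff each record is the other's best qualifying hit,
    which makes the matching one-to-one and symmetric in (A, B).
    """
    a_best = _best_hits(set_a, set_b, cov_threshold, identity_threshold)
    b_best = _best_hits(set_b, set_a, cov_threshold, identity_threshold)
    shared = tuple(
        sorted(
            (a_id, b_id)
            for a_id, b_id in a_best.items()
            if b_best.get(b_id) == a_id
        )
    )
    shared_a = {a for a, _ in shared}
    shared_b = {b for _, b in shared}
    unique_a = tuple(
        sorted(r.representative_id for r in set_a if r.representative_id not in shared_a)
    )
    unique_b = tuple(
        sorted(r.representative_id for r in set_b if r.representative_id not in shared_b)
    )
    return ComparisonResult(shared, unique_a, unique_b)
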