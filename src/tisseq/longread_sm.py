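"""Long-read detection of somatic mobilization (SM) events.

Low-coverage long reads give direct presence/absence evidence of mosaicism:
a genomic region observed in some reads *with* the element and in other reads
*without* it has undergone excision or insertion in part of the cell
population.  The analysis proceeds in five steps:

1. find element-bearing reads (containment alignment of the element, both
   strands, multiple copies per read, read-edge truncation as soft clipping);
2. extract ~2 kb flanks on the element-forward orientation;
3. group flanks into genomic regions by single-linkage over a pairwise
   similarity matrix (exported for heatmap rendering);
4. check each region's uniqueness against the reference genome — a region
   with multiple genomic copies (e.g. a tandem gene cluster) cannot support a
   presence/absence argument;
5. scan all reads for each region and call an SM event when a unique region
   is seen both with and without the element.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from ._align import _cigar_stats, revcomp
from .trimming import RawRead

DEFAULT_FLANK_LEN = 2000
DEFAULT_ADJACENCY = 50


@dataclass(frozen=True)
class ElementHit:
    """One element copy located on a long read (coordinates on the read as stored)."""

    read_id: str
    read_start: int
    read_end: int
    strand: str
    percent_identity: float
    element_coverage: float


@dataclass
class FlankPair:
    """Element-forward upstream/downstream flanks extracted around one hit."""

    read_id: str
    upstream: str
    downstream: str
    upstream_truncated: bool
    downstream_truncated: bool

    @property
    def signature(self) -> str:
        return self.upstream + self.downstream


@dataclass
class RegionGroup:
    region_id: str
    read_ids: tuple[str, ...]
    flanks: dict[str, FlankPair]
    genome_assignment: str = "unplaced"
    unique_in_genome: bool = False

    @property
    def representative_flank_info(self) -> tuple[str, str]:
        """The longest single flank among members and its side (the region query).

        The insertion junction sits at the 3' end of an upstream flank and at
        the 5' start of a downstream flank (element-forward orientation).
        """
        candidates = [(p.upstream, "upstream") for p in self.flanks.values()]
        candidates += [(p.downstream, "downstream") for p in self.flanks.values()]
        return max(candidates, key=lambda c: len(c[0]))

    @property
    def representative_flank(self) -> str:
        return self.representative_flank_info[0]


@dataclass
class SMEvent:
    region_id: str
    reads_with_element: tuple[str, ...]
    reads_without_element: tuple[str, ...]
    verdict: str  # 'supported' | 'unsupported'


_CIGAR_OPS = re.compile(r"(\d+)([=XIDM])")


_MIN_ANCHOR = 10  # a run of >= this many matches ends a boundary clip


def _clipped_stats(
    cigar: str, query_len: int, clip_head: bool = False, clip_tail: bool = False
) -> tuple[float, float]:
    """(identity, query coverage) with boundary overhangs treated as clips.

    A query overhanging the target (element running off a read end) shows up
    as a terminal run of insertion and/or mismatch columns, since both cost
    one edit each.  When the alignment touches the corresponding target
    boundary, that run — everything before the first solid match anchor — is
    query sequence with no real counterpart: it reduces the reported
    coverage, not the identity.
    """
    ops = []
    for n, op in _CIGAR_OPS.findall(cigar):
        n = int(n)
        if op == "=" and n < _MIN_ANCHOR:
            op = "x"  # chance matches inside a clip are not anchors
        ops.append((n, op))
    lo, hi = 0, len(ops)
    while lo < hi and ops[lo][1] in ("I" if not clip_head else "IxXD"):
        lo += 1
    while hi > lo and ops[hi - 1][1] in ("I" if not clip_tail else "IxXD"):
        hi -= 1
    clipped = sum(n for n, op in ops[:lo] + ops[hi:] if op != "D")
    cols = sum(n for n, _ in ops[lo:hi])
    matches = sum(n for n, op in ops[lo:hi] if op in "=x")
    identity = 100.0 * matches / cols if cols else 0.0
    coverage = 100.0 * (query_len - clipped) / query_len
    return identity, coverage


def _hit_coverage(start: int, end: int, query_len: int, boundary: bool, clip_cov: float) -> float:
    """Element coverage of a hit.

    For a boundary-truncated copy the aligned target span measures the
    surviving element directly (the missing part lies beyond the read end);
    interior hits use the clip-corrected query coverage.
    """
    if boundary:
        return min(100.0, 100.0 * (end - start) / query_len)
    return clip_cov


def _iter_matches(query: str, target: str, max_dist: int):
    """Iteratively locate non-overlapping occurrences of query in target."""
    masked = target
    while True:
        res = edlib.align(query, masked, mode="HW", task="path", k=max_dist)
        if res["editDistance"] < 0:
            return
        start, end = res["locations"][0]
        end += 1
        cols, matches = _cigar_stats(res["cigar"])
        identity = 100.0 * matches / cols if cols else 0.0
        yield start, end, identity, res["cigar"]
        masked = masked[:start] + "X" * (end - start) + masked[end:]


def find_element_reads(
    reads: Sequence[RawRead],
    element: str,
    min_identity: float = 80.0,
    min_element_cov: float = 80.0,
) -> list[ElementHit]:
    """Locate every qualifying element copy on every read.

    Copies are found on both strands with iterative masking, so multiple
    copies per read are each reported.  A copy truncated by a read boundary
    aligns its overhang as terminal insertion columns; those are treated as
    clipping, reducing the reported element coverage instead of the identity,
    so boundary copies down to ``min_element_cov`` percent are still found.
    """
    if not element:
        raise ValueError("element sequence is empty")
    hits: list[ElementHit] = []
    # the distance budget must absorb both mismatches and boundary clipping
    budget = max(1 - min_identity / 100.0, 1 - min_element_cov / 100.0)
    max_dist = int(len(element) * min(0.45, budget + 0.05))
    for read in reads:
        seq = read.sequence
        for strand, query in (("+", element), ("-", revcomp(element))):
            for start, end, _raw_identity, cigar in _iter_matches(query, seq, max_dist):
                boundary = start == 0 or end == len(seq)
                identity, clip_cov = _clipped_stats(
                    cigar, len(element),
                    clip_head=start == 0, clip_tail=end == len(seq),
                )
                coverage = _hit_coverage(start, end, len(element), boundary, clip_cov)
                if identity >= min_identity and coverage >= min_element_cov:
                    hits.append(
                        ElementHit(read.id, start, end, strand, identity, coverage)
                    )
    return hits


def extract_flanks(
    read: RawRead, hit: ElementHit, flank_len: int = DEFAULT_FLANK_LEN
) -> FlankPair:
    """Flanking sequence on each side of a hit, on the element-forward strand.

    Flanks shorter than ``flank_len`` (element near a read boundary) are
    flagged truncated; a hit at the very read edge yields an empty flank.
    """
    seq = read.sequence
    left = seq[max(0, hit.read_start - flank_len) : hit.read_start]
    right = seq[hit.read_end : hit.read_end + flank_len]
    if hit.strand == "+":
        up, down = left, right
    else:
        up, down = revcomp(right), revcomp(left)
    return FlankPair(
        read.id, up, down,
        upstream_truncated=len(up) < flank_len,
        downstream_truncated=len(down) < flank_len,
    )


def similarity_matrix(
    pairs: Sequence[FlankPair], max_distance_fraction: float = 0.6
) -> pd.DataFrame:
    """Pairwise percent identity between flank signatures (100 on the diagonal).

    Identity comes from the best containment alignment of the shorter
    signature in the longer one, on either strand; pairs with no alignment
    within the distance budget score 0.
    """
    ids = [p.read_id for p in pairs]
    n = len(ids)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = pairs[i].signature, pairs[j].signature
            if len(a) > len(b):
                a, b = b, a
            best = 0.0
            if a and b:
                k = max(1, int(len(a) * max_distance_fraction))
                for q in (a, revcomp(a)):
                    res = edlib.align(q, b, mode="HW", task="path", k=k)
                    if res["editDistance"] >= 0:
                        cols, matches = _cigar_stats(res["cigar"])
                        best = max(best, 100.0 * matches / cols if cols else 0.0)
            mat[i, j] = mat[j, i] = best
    return pd.DataFrame(mat, index=ids, columns=ids)


def group_regions(
    pairs: Sequence[FlankPair],
    min_identity: float = 90.0,
    min_mutual_cov: float = 50.0,
) -> tuple[list[RegionGroup], pd.DataFrame]:
    """Single-linkage grouping of flank pairs into genomic regions.

    An edge requires identity at or above ``min_identity`` over a span of at
    least ``min_mutual_cov`` percent of both signatures; the shorter-sequence
    containment alignment makes the span equal the shorter signature, so the
    mutual-coverage condition reduces to a length-ratio check.
    """
    from ._align import DisjointSet

    matrix = similarity_matrix(pairs)
    by_id = {p.read_id: p for p in pairs}
    ids = list(by_id)
    ds = DisjointSet(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            la, lb = len(by_id[a].signature), len(by_id[b].signature)
            if min(la, lb) == 0:
                continue
            span_ok = 100.0 * min(la, lb) / max(la, lb) >= min_mutual_cov
            if span_ok and matrix.loc[a, b] >= min_identity:
                ds.union(a, b)
    groups = sorted(ds.groups(), key=lambda g: (-len(g), min(g)))
    regions = [
        RegionGroup(
            region_id=f"region{i + 1}",
            read_ids=tuple(sorted(g)),
            flanks={rid: by_id[rid] for rid in sorted(g)},
        )
        for i, g in enumerate(groups)
    ]
    return regions, matrix


def region_uniqueness(
    flank: str,
    scaffolds: Mapping[str, str],
    min_identity: float = 90.0,
    min_cov: float = 80.0,
) -> tuple[str, str | None]:
    """Count qualifying genome alignments of a region query.

    Returns ``("unique", scaffold)`` for exactly one alignment,
    ``("multicopy", scaffold)`` for more than one, and ``("unplaced", None)``
    for none.  The containment search aligns the full query, so coverage is
    100 by construction; ``min_cov`` is kept for interface compatibility with
    plugged-in local aligners.
    """
    if not flank:
        return "unplaced", None
    max_dist = int(len(flank) * (1 - min_identity / 100.0))
    n_hits = 0
    first_scaffold = None
    for name, seq in scaffolds.items():
        for strand_query in (flank, revcomp(flank)):
            for _start, _end, identity, _cigar in _iter_matches(strand_query, seq, max_dist):
                if identity >= min_identity:
                    n_hits += 1
                    if first_scaffold is None:
                        first_scaffold = name
                if n_hits > 1:
                    return "multicopy", first_scaffold
    if n_hits == 0:
        return "unplaced", None
    return "unique", first_scaffold


def detect_sm_events(
    region: RegionGroup,
    reads: Sequence[RawRead],
    scaffolds: Mapping[str, str],
    element: str,
    adjacency: int = DEFAULT_ADJACENCY,
    min_identity: float = 90.0,
    element_hits: Sequence[ElementHit] | None = None,
) -> SMEvent:
    """Classify every read carrying the region as with- or without-element.

    The region's longest flank is the query.  A matching read is
    "with element" when an element hit lies within ``adjacency`` bases of the
    region match (alignment clipping tolerance), and "without element" only
    when the region aligns contiguously *and* the read continues at least
    ``adjacency`` bases beyond the insertion junction with no element there —
    a read broken at the junction is evidence for neither state.  The verdict
    is ``supported`` only when the region is unique in the genome and both
    read classes are non-empty; multicopy or unplaced regions are always
    ``unsupported`` regardless of read evidence.
    """
    rep, rep_kind = region.representative_flank_info
    status, scaffold = region_uniqueness(rep, scaffolds, min_identity)
    region.genome_assignment = scaffold if scaffold is not None else "unplaced"
    region.unique_in_genome = status == "unique"

    if element_hits is None:
        element_hits = find_element_reads(reads, element)
    hits_by_read: dict[str, list[ElementHit]] = {}
    for h in element_hits:
        hits_by_read.setdefault(h.read_id, []).append(h)

    max_dist = int(len(rep) * (1 - min_identity / 100.0))
    with_el, without_el = [], []
    for read in reads:
        matched = None
        for forward, query in ((True, rep), (False, revcomp(rep))):
            for start, end, identity, _cigar in _iter_matches(query, read.sequence, max_dist):
                if identity >= min_identity:
                    matched = (start, end, forward)
                    break
            if matched:
                break
        if not matched:
            continue
        start, end, forward = matched
        adjacent = any(
            h.read_start - adjacency <= end and start <= h.read_end + adjacency
            for h in hits_by_read.get(read.id, ())
        )
        if adjacent:
            with_el.append(read.id)
            continue
        # the junction lies at the match end for a forward upstream flank
        # (or a reverse-complemented downstream one), else at the match start
        junction_at_end = (rep_kind == "upstream") == forward
        margin = len(read.sequence) - end if junction_at_end else start
        if margin >= adjacency:
            without_el.append(read.id)

    supported = region.unique_in_genome and with_el and without_el
    return SMEvent(
        region.region_id,
        tuple(sorted(with_el)),
        tuple(sorted(without_el)),
        "supported" if supported else "unsupported",
    )


@dataclass
class LongReadReport:
    hits: list[ElementHit]
    flank_pairs: list[FlankPair]
    regions: list[RegionGroup]
    matrix: pd.DataFrame
    events: list[SMEvent] = field(default_factory=list)


def analyze_long_reads(
    reads: Sequence[RawRead],
    element: str,
    scaffolds: Mapping[str, str],
    flank_len: int = DEFAULT_FLANK_LEN,
    min_identity: float = 80.0,
    min_element_cov: float = 80.0,
    min_signature_len: int = 200,
) -> LongReadReport:
    """Run the full long-read SM analysis and return every intermediate."""
    reads_by_id = {r.id: r for r in reads}
    hits = find_element_reads(reads, element, min_identity, min_element_cov)
    pairs = []
    seen = set()
    for h in hits:
        if h.read_id in seen:  # one flank pair per read: first (best) hit
            continue
        seen.add(h.read_id)
        pair = extract_flanks(reads_by_id[h.read_id], h, flank_len)
        if len(pair.signature) >= min_signature_len:
            pairs.append(pair)
    regions, matrix = group_regions(pairs)
    report = LongReadReport(hits, pairs, regions, matrix)
    for region in regions:
        report.events.append(
            detect_sm_events(
                region, reads, scaffolds, element, element_hits=hits
            )
        )
    return report


def write_similarity_heatmap(matrix: pd.DataFrame, path) -> None:
    """Render the region similarity matrix as a PNG heatmap."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix.values, cmap="Greens", vmin=0, vmax=100)
    ax.set_xticks(range(len(matrix)), matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(matrix)), matrix.index, fontsize=6)
    fig.colorbar(im, label="% identity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
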