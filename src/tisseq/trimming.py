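"""Module 1 of the pipeline: read selection, trimming and length filtering.

Element-anchored reads are recognised by a subterminal primer match
(substitutions only, both strands, bounded mismatch count), normalised onto
the amplicon-forward orientation (adapter at 5', primer complement at 3'),
stripped of their adapter prefix and primer/element suffix, cut back at any
internal adapter occurrence (adapter chimeras), and finally length-filtered.
What survives is the putative genomic flank of one element end.

Every read dropped at any step is counted, and the counts are conserved:
input = tagged + untagged + both-primer-chimeric; tagged = flanks + empty.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._align import revcomp

DEFAULT_MIN_LEN = 25
DEFAULT_MAX_MISMATCH = 2


@dataclass(frozen=True)
class RawRead:
    id: str
    sequence: str
    quality: str | None = None
    sample: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty read sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError("quality length mismatch")


@dataclass(frozen=True)
class TaggedRead:
    """A read matched to one subterminal primer, in amplicon-forward orientation.

    ``strand`` records which strand of the original read the primer matched
    ('-' means the read already carried the primer's reverse complement, i.e.
    it was amplicon-forward as sequenced).  ``primer_span`` is the half-open
    interval of the primer occurrence on the normalised sequence.
    """

    id: str
    sequence: str
    sample: str
    end_tag: str  # 'upstream' | 'downstream'
    primer_span: tuple[int, int]
    strand: str
    primer_mismatches: int = 0


@dataclass(frozen=True)
class FlankSeq:
    """An adapter/primer-free genomic flank of one element end."""

    id: str
    sequence: str
    end_tag: str
    sample: str
    chimera_trimmed: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_fastq(path, sample: str | None = None) -> list[RawRead]:
    path = Path(path)
    sample = sample or path.stem
    return [
        RawRead(rec.id, str(rec.seq).upper(),
                None, sample)
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def hamming_profile(seq: str, pattern: str) -> np.ndarray:
    """Mismatch count of ``pattern`` against every window of ``seq``."""
    n, m = len(seq), len(pattern)
    if m > n:
        return np.empty(0, dtype=int)
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    p = np.frombuffer(pattern.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(a, m)
    return (windows != p).sum(axis=1)


def best_match(seq: str, pattern: str, max_mismatch: int) -> tuple[int, int] | None:
    """Earliest minimal-mismatch occurrence (position, mismatches), or None."""
    profile = hamming_profile(seq, pattern)
    if profile.size == 0:
        return None
    i = int(profile.argmin())
    if profile[i] <= max_mismatch:
        return i, int(profile[i])
    return None


def best_match_both_strands(
    seq: str, pattern: str, max_mismatch: int
) -> tuple[int, int, str] | None:
    """Best substitution-only occurrence of pattern or its reverse complement."""
    fwd = best_match(seq, pattern, max_mismatch)
    rev = best_match(seq, revcomp(pattern), max_mismatch)
    candidates = []
    if fwd:
        candidates.append((fwd[1], "+", fwd[0]))
    if rev:
        candidates.append((rev[1], "-", rev[0]))
    if not candidates:
        return None
    mm, strand, pos = min(candidates)
    return pos, mm, strand


@dataclass
class SelectStats:
    n_input: int = 0
    n_tagged: int = 0
    n_untagged: int = 0
    n_both_primers: int = 0


def select_element_reads(
    reads: Iterable[RawRead],
    primers: Mapping[str, str],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> tuple[list[TaggedRead], SelectStats]:
    """Keep reads matching exactly one subterminal primer; tag their element end.

    Reads matching both primers are chimeric artefacts and are excluded (and
    counted separately); reads matching neither are dropped.  Matching allows
    substitutions only.  Tagged reads are reverse complemented where needed so
    that the primer complement sits 3' (amplicon-forward orientation).
    """
    if not primers.get("upstream") or not primers.get("downstream"):
        raise ValueError("both upstream and downstream primers are required")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    stats = SelectStats()
    tagged: list[TaggedRead] = []
    for read in reads:
        stats.n_input += 1
        matches = {}
        for end, primer in primers.items():
            hit = best_match_both_strands(read.sequence, primer, max_mismatch)
            if hit:
                matches[end] = hit
        if not matches:
            stats.n_untagged += 1
            continue
        if len(matches) > 1:
            stats.n_both_primers += 1
            continue
        (end, (pos, mm, strand)), = matches.items()
        m = len(primers[end])
        if strand == "+":
            # read carries the primer itself: it is the reverse strand of the
            # amplicon, so flip it onto the amplicon-forward orientation
            seq = revcomp(read.sequence)
            pos = len(seq) - pos - m
        else:
            seq = read.sequence
        tagged.append(
            TaggedRead(read.id, seq, read.sample, end, (pos, pos + m), strand, mm)
        )
        stats.n_tagged += 1
    return tagged, stats


@dataclass
class TrimStats:
    n_input: int = 0
    n_flanks: int = 0
    n_empty: int = 0
    n_chimera_trimmed: int = 0
    n_missing_adapter: int = 0


def trim_known_segments(
    tagged: Iterable[TaggedRead],
    adapters: Sequence[str],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> tuple[list[FlankSeq], TrimStats]:
    """Strip the adapter prefix and everything from the primer onward.

    An adapter occurring *inside* the putative flank marks an adapter chimera:
    only the segment between the terminal adapter and the internal one is
    retained and the flank is flagged.  Reads reduced to nothing are dropped.
    """
    stats = TrimStats()
    flanks: list[FlankSeq] = []
    for read in tagged:
        stats.n_input += 1
        start = 0
        for adapter in adapters:
            if len(read.sequence) >= len(adapter):
                mm = hamming_profile(read.sequence[: len(adapter)], adapter)
                if mm.size and mm[0] <= max_mismatch:
                    start = len(adapter)
                    break
        else:
            stats.n_missing_adapter += 1
        flank = read.sequence[start : read.primer_span[0]]
        chimera = False
        internal_positions = []
        for adapter in adapters:
            for pattern in (adapter, revcomp(adapter)):
                hit = best_match(flank, pattern, max_mismatch)
                if hit:
                    internal_positions.append(hit[0])
        if internal_positions:
            flank = flank[: min(internal_positions)]
            chimera = True
            stats.n_chimera_trimmed += 1
        if not flank:
            stats.n_empty += 1
            continue
        flanks.append(FlankSeq(read.id, flank, read.end_tag, read.sample, chimera))
        stats.n_flanks += 1
    return flanks, stats


def length_filter(
    flanks: Iterable[FlankSeq], min_len: int = DEFAULT_MIN_LEN
) -> list[FlankSeq]:
    """Keep flanks of at least ``min_len`` bases (boundary kept at equality)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [f for f in flanks if f.length >= min_len]


def run_trimming(
    reads: Sequence[RawRead],
    primers: Mapping[str, str],
    adapters: Sequence[str],
    min_len: int = DEFAULT_MIN_LEN,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> tuple[list[FlankSeq], pd.DataFrame]:
    """Select, trim and length-filter; return flanks plus the step ledger."""
    tagged, sel = select_element_reads(reads, primers, max_mismatch)
    flanks, trim = trim_known_segments(tagged, adapters, max_mismatch)
    kept = length_filter(flanks, min_len)
    sample = reads[0].sample if reads else ""
    ledger = pd.DataFrame(
        [
            {"sample": sample, "step": "select", "reads_in": sel.n_input,
             "reads_out": sel.n_tagged, "dropped_untagged": sel.n_untagged,
             "dropped_both_primers": sel.n_both_primers},
            {"sample": sample, "step": "trim", "reads_in": trim.n_input,
             "reads_out": trim.n_flanks, "dropped_empty": trim.n_empty,
             "chimera_trimmed": trim.n_chimera_trimmed},
            {"sample": sample, "step": "length_filter", "reads_in": trim.n_flanks,
             "reads_out": len(kept),
             "dropped_short": trim.n_flanks - len(kept)},
        ]
    )
    return kept, ledger
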