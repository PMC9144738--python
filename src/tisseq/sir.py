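"""In-silico restriction digestion and somatic insertion rate (SIR) estimation.

The amplicon protocol can only reach insertions that sit within sequencing
range of an EcoRI or HindIII site, so the detected insertion count must be
scaled by the accessible genome fraction *P*:

    P = (b + c * L) * 100 / (b + d)

where, after discarding fragments shorter than ``min_len``, *b* is the total
length of fragments no longer than the cut-off *L* (default 600 bp, i.e. both
fragment ends within a 300 bp read's reach), *c* is the number of fragments
longer than *L*, and *d* is their total length.  Every base of a short
fragment is reachable; a long fragment contributes only *L* reachable bases.

The per-genome rate follows the two-step arithmetic: detected-per-genome =
ISS count / number of pooled individuals; estimated-per-genome scales the
detected rate by 100 / P.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class InputError(ValueError):
    """Invalid user input (empty genome, non-positive lengths, ...)."""


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme as an exact top-strand recognition site plus cut offset."""

    name: str
    site: str
    cut_offset: int

    def __post_init__(self):
        if not self.site or not set(self.site) <= set("ACGT"):
            raise InputError(f"recognition site must be ACGT-only, got {self.site!r}")
        if not 0 <= self.cut_offset <= len(self.site):
            raise InputError("cut offset outside recognition site")


ECORI = Enzyme("EcoRI", "GAATTC", 1)
HINDIII = Enzyme("HindIII", "AAGCTT", 1)
DEFAULT_ENZYMES = (ECORI, HINDIII)

FRAGMENT_COLUMNS = ["scaffold", "start", "end", "length", "left_site", "right_site"]


def cut_positions(sequence: str, enzymes: Iterable[Enzyme]) -> list[tuple[int, str]]:
    """Sorted (cut position, enzyme name) for every exact top-strand site.

    Matching is exact and case-insensitive on A/C/G/T, so sites overlapping an
    N run never match.  Overlapping occurrences are all reported.
    """
    seq = sequence.upper()
    cuts: list[tuple[int, str]] = []
    for enz in enzymes:
        pattern = re.compile(f"(?={re.escape(enz.site)})")
        for m in pattern.finditer(seq):
            cuts.append((m.start() + enz.cut_offset, enz.name))
    cuts.sort()
    return cuts


def digest(
    scaffolds: Mapping[str, str], enzymes: Iterable[Enzyme] = DEFAULT_ENZYMES
) -> pd.DataFrame:
    """Cleave linear scaffolds at every recognition site; return the fragment table.

    Fragments tile each scaffold exactly: half-open [start, end) intervals
    between consecutive cut positions and the scaffold ends, with the bounding
    feature (enzyme name or ``"scaffold-end"``) recorded on each side.
    """
    if not scaffolds:
        raise InputError("empty genome")
    enzymes = list(enzymes)
    rows = []
    for name, seq in scaffolds.items():
        if not seq:
            raise InputError(f"scaffold {name!r} is empty")
        bounds = [(0, "scaffold-end")] + cut_positions(seq, enzymes) + [
            (len(seq), "scaffold-end")
        ]
        for (start, left), (end, right) in zip(bounds, bounds[1:]):
            if end > start:  # a cut at position 0 or len(seq) yields no fragment
                rows.append((name, start, end, end - start, left, right))
    table = pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)
    # tiling invariant: fragment lengths sum to scaffold length
    sums = table.groupby("scaffold")["length"].sum()
    for name, seq in scaffolds.items():
        assert sums.get(name, 0) == len(seq), f"tiling broken on {name}"
    return table


@dataclass
class AccessibilityEstimate:
    """Binned digestion totals and the accessible-fraction computation.

    b: total bases of fragments with min_len <= length <= cut_len.
    c: count of fragments longer than cut_len.
    d: total bases of fragments longer than cut_len.
    n_excluded: count of fragments shorter than min_len (dropped entirely).
    """

    b: int
    c: int
    d: int
    n_excluded: int = 0
    min_len: int = 50
    cut_len: int = 600

    @property
    def P(self) -> float:
        return accessible_fraction(self)

    def to_dict(self) -> dict:
        return {
            "b": self.b,
            "c": self.c,
            "d": self.d,
            "n_excluded": self.n_excluded,
            "min_len": self.min_len,
            "cut_len": self.cut_len,
            "P": self.P,
        }


def tabulate(
    fragments: pd.DataFrame, min_len: int = 50, cut_len: int = 600
) -> AccessibilityEstimate:
    """Bin digestion fragments into the accessibility quantities b, c, d.

    Fragments shorter than ``min_len`` are excluded before tabulation and
    contribute to neither numerator nor denominator.
    """
    lengths = fragments["length"]
    excluded = lengths < min_len
    small = (~excluded) & (lengths <= cut_len)
    large = lengths > cut_len
    return AccessibilityEstimate(
        b=int(lengths[small].sum()),
        c=int(large.sum()),
        d=int(lengths[large].sum()),
        n_excluded=int(excluded.sum()),
        min_len=min_len,
        cut_len=cut_len,
    )


def accessible_fraction(est: AccessibilityEstimate) -> float:
    """Accessible genome percentage P = (b + c*cut_len) * 100 / (b + d)."""
    denom = est.b + est.d
    if denom <= 0:
        raise InputError("no fragments survive the length filter (b + d = 0)")
    return (est.b + est.c * est.cut_len) * 100.0 / denom


def detectable_fraction(
    fragments: pd.DataFrame, min_flank: int = 25, max_flank: int = 258
) -> float:
    """Percent of genome positions whose one-sided cut distance is sequenceable.

    An insertion is detected from one element end when the genomic flank
    running from the insertion point to the bounding restriction cut has a
    length in ``[min_flank, max_flank]`` (the trimming length filter and the
    read-length budget after adapter and primer).  Within a fragment of
    length L the one-sided cut distance takes the values 0..L-1, of which
    ``max(0, min(L-1, max_flank) - min_flank + 1)`` are detectable.  This is
    the exact per-end counterpart of the accessible-fraction approximation,
    used to calibrate simulation-recovery estimates to the library design.
    """
    lengths = fragments["length"].to_numpy()
    detectable = np.clip(
        np.minimum(lengths - 1, max_flank) - min_flank + 1, 0, None
    )
    return 100.0 * detectable.sum() / lengths.sum()


def round1(x: float) -> float:
    """Round to one decimal, halves away from zero (reporting convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class SIREstimate:
    """Somatic insertion rate from an ISS count.

    ``detected_per_genome`` and ``estimated_per_genome`` hold the unrounded
    chain; the ``*_rounded`` properties apply the one-decimal reporting
    convention to each final quantity independently.
    """

    iss_count: float
    n_flies: int
    accessible_percent: float
    detected_per_genome: float = field(init=False)
    estimated_per_genome: float = field(init=False)

    def __post_init__(self):
        if self.n_flies < 1:
            raise InputError("n_flies must be >= 1")
        if not 0 < self.accessible_percent <= 100:
            raise InputError("accessible_percent must be in (0, 100]")
        self.detected_per_genome = self.iss_count / self.n_flies
        self.estimated_per_genome = (
            self.detected_per_genome * 100.0 / self.accessible_percent
        )

    @property
    def detected_rounded(self) -> float:
        return round1(self.detected_per_genome)

    @property
    def estimated_rounded(self) -> float:
        return round1(self.estimated_per_genome)


def estimate_sir(
    iss_count: float, accessible_percent: float, n_flies: int = 30
) -> SIREstimate:
    """Scale an ISS count to detected- and estimated-per-genome rates."""
    return SIREstimate(iss_count, n_flies, accessible_percent)


def sir_table(
    iss_counts: Mapping[str, float], accessible_percent: float, n_flies: int = 30
) -> pd.DataFrame:
    """Per-condition rate table (one row per labelled ISS count)."""
    rows = []
    for label, count in iss_counts.items():
        est = estimate_sir(count, accessible_percent, n_flies)
        rows.append(
            {
                "condition": label,
                "iss_count": count,
                "detected_per_genome": est.detected_rounded,
                "estimated_per_genome": est.estimated_rounded,
            }
        )
    return pd.DataFrame(rows)


def accessibility_report(
    scaffolds: Mapping[str, str],
    enzymes: Iterable[Enzyme] = DEFAULT_ENZYMES,
    min_len: int = 50,
    cut_len: int = 600,
) -> AccessibilityEstimate:
    """Digest a genome and compute its accessible fraction in one call."""
    return tabulate(digest(scaffolds, enzymes), min_len=min_len, cut_len=cut_len)


def write_report(est: AccessibilityEstimate, path) -> None:
    with open(path, "w") as fh:
        json.dump(est.to_dict(), fh, indent=2)
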