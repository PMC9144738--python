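"""Synthetic genomes, planted transposon insertions, and simulated libraries.

This module emulates the element-anchored amplicon protocol end to end so the
pipeline can be exercised with known truth and no external downloads:

* a random reference genome stands in for the fly assembly;
* germline (cell fraction 1.0) and somatic (fraction in (0, 1]) insertions of
  a mariner-like element are planted at uniform positions;
* the library simulation performs the in-silico double digestion (EcoRI +
  HindIII, neither cutting the element), ligates a cohesive adapter to the
  bounding cut, and emits single-end reads of the form
  ``adapter + genomic flank + reverse-complemented subterminal primer``
  for the upstream and downstream element ends, mixed with adapter-chimera
  and element-free contaminant amplicons at configurable rates;
* long reads are drawn from per-cell haplotypes that carry or lack each
  somatic insertion according to its cell fraction.

A site is *accessible* from one end when a restriction cut lies within the
flank budget (``max_read_len`` minus adapter and primer lengths) on the
corresponding genomic side; inaccessible site/ends yield no reads and are
recorded as such in the site table.  Every emitted read is reconstructable
from its truth-table row at error rate 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._align import revcomp
from .sir import DEFAULT_ENZYMES, Enzyme, InputError, digest
from .trimming import RawRead

DNA = np.array(list("ACGT"))

# Fixed 20-nt cohesive-end adapters, one per enzyme.  The exact strings are
# immaterial to the computation; they are site-free and mutually dissimilar.
ECO_ADAPTER = "ACCTGCCAGTTGATCGGTCA"
HIND_ADAPTER = "TGGACGATCTGCTGAGCCTA"
PRIMER_LEN = 22
DEFAULT_ELEMENT_LEN = 1286  # Mos1-like mariner length
DEFAULT_TIR_LEN = 28


class DesignError(ValueError):
    """A library design violating the protocol premise (e.g. enzyme cuts the element)."""


@dataclass
class SyntheticGenome:
    """A reference genome as named scaffolds of A/C/G/T (plus optional N)."""

    scaffolds: dict[str, str]
    seed: int

    def __post_init__(self):
        if len(set(self.scaffolds)) != len(self.scaffolds):
            raise InputError("scaffold names must be unique")
        for name, seq in self.scaffolds.items():
            if set(seq) - set("ACGTN"):
                raise InputError(f"scaffold {name!r} has non-IUPAC letters")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.scaffolds.values())


@dataclass(frozen=True)
class InsertionRecord:
    """One planted element insertion with its known truth."""

    scaffold: str
    position: int  # 0-based insertion point between position-1 and position
    orientation: str  # '+' or '-'
    cell_fraction: float
    label: str  # 'germline' | 'somatic'
    sample: str = ""


def truth_frame(truth: Sequence[InsertionRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) | {"site_index": i} for i, r in enumerate(truth)])


def generate_genome(
    scaffold_lengths: Sequence[int], gc_fraction: float = 0.42, seed: int = 0
) -> SyntheticGenome:
    """Random genome with the requested scaffold lengths and GC content.

    The default GC fraction (0.42) matches a drosophilid genome, which also
    reproduces its EcoRI/HindIII fragment-length statistics (mean ~1.6 kb).
    """
    if not scaffold_lengths:
        raise InputError("at least one scaffold required")
    if any(n < 1 for n in scaffold_lengths):
        raise InputError("scaffold lengths must be positive")
    if not 0 <= gc_fraction <= 1:
        raise InputError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    at, gc = (1 - gc_fraction) / 2, gc_fraction / 2
    probs = [at, gc, gc, at]  # A C G T
    scaffolds = {
        f"scf{i + 1}": "".join(rng.choice(DNA, size=n, p=probs))
        for i, n in enumerate(scaffold_lengths)
    }
    return SyntheticGenome(scaffolds, seed)


def _scrub_sites(seq: list[str], enzymes: Sequence[Enzyme], rng) -> None:
    """Destroy every enzyme recognition site in ``seq`` by point substitution."""
    text = "".join(seq)
    for enz in enzymes:
        start = 0
        while (pos := text.find(enz.site, start)) != -1:
            mid = pos + len(enz.site) // 2
            seq[mid] = rng.choice([b for b in "ACGT" if b != seq[mid]])
            text = "".join(seq)
            start = pos + 1


def make_element(
    length: int = DEFAULT_ELEMENT_LEN,
    tir_len: int = DEFAULT_TIR_LEN,
    gc_fraction: float = 0.37,
    seed: int = 97,
    enzymes: Sequence[Enzyme] = DEFAULT_ENZYMES,
) -> str:
    """A mariner-like element: AT-rich body with imperfect terminal inverted repeats.

    The TIRs are inverted copies of each other with a handful of substitutions
    (as in the natural element), which keeps the two subterminal primers
    distinguishable; recognition sites of the supplied enzymes are scrubbed so
    the digestion never cuts inside the element.
    """
    rng = np.random.default_rng(seed)
    at, gc = (1 - gc_fraction) / 2, gc_fraction / 2
    seq = list(rng.choice(DNA, size=length, p=[at, gc, gc, at]))
    seq[-tir_len:] = list(revcomp("".join(seq[:tir_len])))
    # imperfect TIR: mutate spread positions in the right repeat
    for off in (-27, -23, -19, -15, -11, -7, -3):
        seq[off] = rng.choice([b for b in "ACGT" if b != seq[off]])
    _scrub_sites(seq, enzymes, rng)
    element = "".join(seq)
    for enz in enzymes:
        assert enz.site not in element
    return element


@dataclass
class LibraryDesign:
    """Everything the molecular protocol fixes: enzymes, adapters, primers, rates.

    ``primers`` are the outward-facing subterminal primers; an emitted read
    carries the reverse complement of the matching primer at its 3' end.
    ``error_rate`` is a per-base substitution probability (constant-Q30 model).
    """

    enzymes: tuple[Enzyme, ...] = DEFAULT_ENZYMES
    adapters: Mapping[str, str] = field(
        default_factory=lambda: {"EcoRI": ECO_ADAPTER, "HindIII": HIND_ADAPTER}
    )
    primers: Mapping[str, str] = field(default_factory=dict)
    max_read_len: int = 300
    depth: int = 10_000
    error_rate: float = 0.001
    chimera_rate: float = 0.10
    contaminant_rate: float = 0.30
    end_ratio: float = 0.5  # upstream share of element reads (two PCRs merged 1:1)
    pcr_length_bias: float = 0.0  # per-bp geometric down-weighting, off by default

    def __post_init__(self):
        for rate in (self.error_rate, self.chimera_rate, self.contaminant_rate):
            if not 0 <= rate <= 1:
                raise InputError("rates must lie in [0, 1]")
        if self.chimera_rate + self.contaminant_rate > 1:
            raise InputError("artifact rates exceed 1")
        for enz in self.enzymes:
            if enz.name not in self.adapters:
                raise InputError(f"no adapter configured for {enz.name}")

    @classmethod
    def for_element(cls, element: str, **kwargs) -> "LibraryDesign":
        """Derive the two subterminal primers from an element sequence."""
        design = cls(
            primers={
                "upstream": revcomp(element[:PRIMER_LEN]),
                "downstream": element[-PRIMER_LEN:],
            },
            **kwargs,
        )
        check_element_compatible(element, design)
        return design

    def flank_budget(self, enzyme_name: str) -> int:
        return self.max_read_len - len(self.adapters[enzyme_name]) - PRIMER_LEN

    def element_segment(self, end: str) -> str:
        """The element-derived 3' segment of a read for the given end."""
        return revcomp(self.primers[end])


def check_element_compatible(element: str, design: LibraryDesign) -> None:
    if not element:
        raise InputError("element sequence is empty")
    for enz in design.enzymes:
        if enz.site in element or enz.site in revcomp(element):
            raise DesignError(f"{enz.name} site present in element")


def uniform_fraction_sampler(low: float = 0.05, high: float = 1.0) -> Callable:
    def sample(rng, n):
        return rng.uniform(low, high, n)

    return sample


def plant_insertions(
    genome: SyntheticGenome,
    element: str,
    n_germline: int,
    n_somatic: int,
    fraction_sampler: Callable | None = None,
    seed: int = 0,
    sample: str = "",
    design: LibraryDesign | None = None,
) -> list[InsertionRecord]:
    """Plant insertions at uniform positions drawn without replacement.

    Germline records get cell fraction 1.0; somatic fractions come from
    ``fraction_sampler(rng, n)`` (default uniform on [0.05, 1]).  Records are
    returned sorted by (scaffold, position).
    """
    if design is not None:
        check_element_compatible(element, design)
    elif not element:
        raise InputError("element sequence is empty")
    n_total = n_germline + n_somatic
    if n_total > genome.total_length:
        raise InputError("more insertions than genome positions")
    rng = np.random.default_rng(seed)
    names = list(genome.scaffolds)
    offsets = np.cumsum([0] + [len(genome.scaffolds[n]) for n in names])
    flat = rng.choice(genome.total_length, size=n_total, replace=False)
    orientations = rng.choice(["+", "-"], size=n_total)
    sampler = fraction_sampler or uniform_fraction_sampler()
    fractions = np.concatenate(
        [np.ones(n_germline), np.asarray(sampler(rng, n_somatic), dtype=float)]
    )
    if n_somatic and not np.all((fractions[n_germline:] > 0) & (fractions[n_germline:] <= 1)):
        raise InputError("somatic cell fractions must lie in (0, 1]")
    records = []
    for i in range(n_total):
        scf_idx = int(np.searchsorted(offsets, flat[i], side="right") - 1)
        records.append(
            InsertionRecord(
                scaffold=names[scf_idx],
                position=int(flat[i] - offsets[scf_idx]),
                orientation=str(orientations[i]),
                cell_fraction=float(fractions[i]),
                label="germline" if i < n_germline else "somatic",
                sample=sample,
            )
        )
    records.sort(key=lambda r: (r.scaffold, r.position))
    return records


# ---------------------------------------------------------------------------
# amplicon geometry


@dataclass(frozen=True)
class FlankInfo:
    """The amplicon flank of one (site, end): sequence as it appears in the read."""

    end: str
    side: str  # 'left' | 'right' genomic side of the insertion point
    enzyme: str | None
    flank_len: int
    accessible: bool
    sequence: str | None


def _cut_arrays(genome: SyntheticGenome, enzymes) -> dict[str, tuple[np.ndarray, list]]:
    table = digest(genome.scaffolds, enzymes)
    out = {}
    for name in genome.scaffolds:
        sub = table[table.scaffold == name]
        positions, names = [], []
        for _, row in sub.iterrows():
            if row.left_site != "scaffold-end":
                positions.append(row.start)
                names.append(row.left_site)
        out[name] = (np.asarray(positions, dtype=int), names)
    return out


def site_flank(
    genome: SyntheticGenome,
    cuts: dict,
    record: InsertionRecord,
    end: str,
    design: LibraryDesign,
) -> FlankInfo:
    """Geometry of the amplicon flank for one insertion end.

    The upstream end of the element adjoins the left genomic side when the
    insertion orientation is '+', the right side when it is '-' (and vice
    versa for the downstream end).  Right-side flanks are reported reverse
    complemented, matching the strand the amplicon is read on.
    """
    positions, names = cuts[record.scaffold]
    seq = genome.scaffolds[record.scaffold]
    p = record.position
    side = "left" if (end == "upstream") == (record.orientation == "+") else "right"
    if side == "left":
        idx = int(np.searchsorted(positions, p, side="right")) - 1
        if idx < 0:
            return FlankInfo(end, side, None, 0, False, None)
        cut, enzyme = int(positions[idx]), names[idx]
        flank = seq[cut:p]
    else:
        idx = int(np.searchsorted(positions, p, side="left"))
        if idx >= len(positions):
            return FlankInfo(end, side, None, 0, False, None)
        cut, enzyme = int(positions[idx]), names[idx]
        flank = revcomp(seq[p:cut])
    accessible = 1 <= len(flank) <= design.flank_budget(enzyme) and "N" not in flank
    return FlankInfo(end, side, enzyme, len(flank), accessible, flank if accessible else None)


def site_accessibility_table(
    genome: SyntheticGenome, truth: Sequence[InsertionRecord], design: LibraryDesign
) -> pd.DataFrame:
    """Per-(site, end) accessibility truth, computed from the digestion geometry."""
    cuts = _cut_arrays(genome, design.enzymes)
    rows = []
    for i, rec in enumerate(truth):
        for end in ("upstream", "downstream"):
            info = site_flank(genome, cuts, rec, end, design)
            rows.append(
                {
                    "site_index": i,
                    "scaffold": rec.scaffold,
                    "position": rec.position,
                    "orientation": rec.orientation,
                    "label": rec.label,
                    "cell_fraction": rec.cell_fraction,
                    "end": end,
                    "accessible": info.accessible,
                    "flank_len": info.flank_len,
                    "enzyme": info.enzyme,
                }
            )
    columns = [
        "site_index", "scaffold", "position", "orientation", "label",
        "cell_fraction", "end", "accessible", "flank_len", "enzyme",
    ]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# short-read library simulation

TRUTH_COLUMNS = [
    "read_id", "class", "scaffold", "position", "end", "cell_fraction",
    "strand", "flank_len", "enzyme", "label", "site_index",
    "scaffold2", "position2", "end2", "keep_len",
]


def _mutate(seq: str, rng, error_rate: float) -> str:
    if error_rate <= 0 or not seq:
        return seq
    n = rng.binomial(len(seq), error_rate)
    if n == 0:
        return seq
    arr = list(seq)
    for pos in rng.choice(len(seq), size=n, replace=False):
        arr[pos] = rng.choice([b for b in "ACGT" if b != arr[pos]])
    return "".join(arr)


def simulate_tisseq_library(
    genome: SyntheticGenome,
    truth: Sequence[InsertionRecord],
    design: LibraryDesign,
    sample_id: str = "s1",
    seed: int = 0,
    stochastic_depth: bool = False,
) -> tuple[list[RawRead], pd.DataFrame, pd.DataFrame]:
    """Simulate one single-end amplicon library.

    Returns ``(reads, read_truth, site_table)``.  Element reads are allocated
    to accessible (site, end) pairs with probability proportional to the
    site's cell fraction (times the configured end ratio); chimera and
    contaminant reads are emitted at their configured rates.  In fixed mode
    exactly ``design.depth`` reads are emitted whenever at least one
    accessible site exists; in stochastic mode the total is Poisson.
    """
    if not design.primers:
        raise InputError("design has no primers; build it with LibraryDesign.for_element")
    rng = np.random.default_rng(seed)
    cuts = _cut_arrays(genome, design.enzymes)
    fragments = digest(genome.scaffolds, design.enzymes)
    site_table = site_accessibility_table(genome, truth, design)

    acc = site_table[site_table.accessible]
    flank_cache: dict[tuple[int, str], FlankInfo] = {
        (int(r.site_index), r.end): site_flank(genome, cuts, truth[int(r.site_index)], r.end, design)
        for r in acc.itertuples()
    }
    keys = list(flank_cache)
    weights = np.array(
        [
            truth[i].cell_fraction
            * (design.end_ratio if end == "upstream" else 1 - design.end_ratio)
            * (1 - design.pcr_length_bias) ** flank_cache[(i, end)].flank_len
            for i, end in keys
        ]
    )

    depth = int(rng.poisson(design.depth)) if stochastic_depth else design.depth
    n_chim, n_cont, n_elem = rng.multinomial(
        depth,
        [
            design.chimera_rate,
            design.contaminant_rate,
            1 - design.chimera_rate - design.contaminant_rate,
        ],
    )
    if not keys or weights.sum() == 0:
        n_elem = 0
        n_chim = min(n_chim, depth)

    # eligible contaminant fragments: enzyme-bounded and short enough to sequence
    max_frag = design.max_read_len - 2 * min(len(a) for a in design.adapters.values())
    elig = fragments[
        (fragments.length <= max_frag)
        & (fragments.left_site != "scaffold-end")
        & (fragments.right_site != "scaffold-end")
    ].reset_index(drop=True)

    reads: list[RawRead] = []
    rows: list[dict] = []

    def emit(seq: str, row: dict) -> None:
        strand = rng.choice(["+", "-"])
        seq = _mutate(seq, rng, design.error_rate)
        if strand == "-":
            seq = revcomp(seq)
        rid = f"{sample_id}_r{len(reads):06d}"
        reads.append(RawRead(rid, seq, "?" * len(seq), sample_id))
        rows.append({"read_id": rid, "strand": strand} | row)

    if n_elem:
        alloc = rng.multinomial(n_elem, weights / weights.sum())
        for (key, count) in zip(keys, alloc):
            i, end = key
            info = flank_cache[key]
            rec = truth[i]
            core = (
                design.adapters[info.enzyme] + info.sequence + design.element_segment(end)
            )
            for _ in range(count):
                emit(
                    core,
                    {
                        "class": "element",
                        "scaffold": rec.scaffold,
                        "position": rec.position,
                        "end": end,
                        "cell_fraction": rec.cell_fraction,
                        "flank_len": info.flank_len,
                        "enzyme": info.enzyme,
                        "label": rec.label,
                        "site_index": i,
                    },
                )

    for _ in range(n_cont):
        if len(elig):
            frag = elig.iloc[int(rng.integers(len(elig)))]
            body = genome.scaffolds[frag.scaffold][frag.start : frag.end]
            core = design.adapters[frag.left_site] + body + revcomp(
                design.adapters[frag.right_site]
            )
            meta = {"scaffold": frag.scaffold, "position": int(frag.start),
                    "flank_len": int(frag.length)}
        else:
            name = list(genome.scaffolds)[0]
            seq = genome.scaffolds[name]
            start = int(rng.integers(max(1, len(seq) - 100)))
            body = seq[start : start + 100]
            core = (ECO_ADAPTER + body + revcomp(HIND_ADAPTER))[: design.max_read_len]
            meta = {"scaffold": name, "position": start, "flank_len": len(body)}
        emit(core[: design.max_read_len], {"class": "contaminant"} | meta)

    for _ in range(n_chim):
        if len(keys) >= 2:
            ia, ib = rng.choice(len(keys), size=2, replace=False)
        elif len(keys) == 1:
            ia = ib = 0
        else:
            continue  # no element amplicons to chimerise; under-emit
        (si_a, end_a), (si_b, end_b) = keys[ia], keys[ib]
        fa, fb = flank_cache[keys[ia]], flank_cache[keys[ib]]
        keep = int(rng.integers(1, min(fa.flank_len, 60) + 1))
        ad_a = design.adapters[fa.enzyme]
        ad_b = design.adapters[fb.enzyme]
        avail = design.max_read_len - len(ad_a) - keep - len(ad_b) - PRIMER_LEN
        if avail < 5:
            keep = max(1, keep + avail - 5)
            avail = design.max_read_len - len(ad_a) - keep - len(ad_b) - PRIMER_LEN
        core = (
            ad_a
            + fa.sequence[:keep]
            + ad_b
            + fb.sequence[: max(0, avail)]
            + design.element_segment(end_b)
        )
        emit(
            core,
            {
                "class": "chimera",
                "scaffold": truth[si_a].scaffold,
                "position": truth[si_a].position,
                "end": end_a,
                "cell_fraction": truth[si_a].cell_fraction,
                "flank_len": fa.flank_len,
                "enzyme": fa.enzyme,
                "label": truth[si_a].label,
                "site_index": si_a,
                "scaffold2": truth[si_b].scaffold,
                "position2": truth[si_b].position,
                "end2": end_b,
                "keep_len": keep,
            },
        )

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth_df = (
        pd.DataFrame([rows[i] for i in order]).reindex(columns=TRUTH_COLUMNS)
        if rows
        else pd.DataFrame(columns=TRUTH_COLUMNS)
    )
    return reads, truth_df, site_table


def reconstruct_read(
    row, genome: SyntheticGenome, truth: Sequence[InsertionRecord], design: LibraryDesign
) -> str | None:
    """Rebuild an element read's error-free sequence from its truth row.

    ``row`` is a mapping (e.g. an element of ``truth_df.to_dict("records")``).
    Only the 'element' class is rebuilt; artifact classes return None.
    """
    if row["class"] != "element":
        return None
    cuts = _cut_arrays(genome, design.enzymes)
    rec = truth[int(row["site_index"])]
    info = site_flank(genome, cuts, rec, row["end"], design)
    core = design.adapters[info.enzyme] + info.sequence + design.element_segment(row["end"])
    return core if row["strand"] == "+" else revcomp(core)


# ---------------------------------------------------------------------------
# long-read simulation


def simulate_long_reads(
    genome: SyntheticGenome,
    truth: Sequence[InsertionRecord],
    element: str,
    mean_len: int = 8000,
    len_sd: int = 800,
    error_rate: float = 0.0,
    depth: int = 400,
    seed: int = 0,
    sample_id: str = "lr",
) -> tuple[list[RawRead], pd.DataFrame, pd.DataFrame]:
    """Simulate ``depth`` long reads from mosaic haplotypes.

    Each read samples a genomic window (Gaussian length, uniform start); every
    insertion locus interior to the window carries the element with
    probability equal to its cell fraction (germline loci always do).
    Returns ``(reads, read_table, span_table)`` where the span table lists one
    row per (read, interior locus) with the element-presence truth.
    """
    if mean_len < 2 * 500:
        raise InputError("mean_len too short for flank analysis")
    rng = np.random.default_rng(seed)
    names = list(genome.scaffolds)
    lengths = np.array([len(genome.scaffolds[n]) for n in names], dtype=float)
    by_scaffold: dict[str, list[tuple[int, InsertionRecord]]] = {n: [] for n in names}
    for i, rec in enumerate(truth):
        by_scaffold[rec.scaffold].append((i, rec))

    reads: list[RawRead] = []
    read_rows, span_rows = [], []
    for serial in range(depth):
        scf = names[int(rng.choice(len(names), p=lengths / lengths.sum()))]
        seq = genome.scaffolds[scf]
        span = max(500, int(rng.normal(mean_len, len_sd)))
        start = int(rng.integers(0, max(1, len(seq) - 1)))
        end = min(len(seq), start + span)
        interior = [
            (i, rec) for i, rec in by_scaffold[scf] if start < rec.position < end
        ]
        pieces, cursor = [], start
        rid = f"{sample_id}_r{serial:05d}"
        for i, rec in sorted(interior, key=lambda t: t[1].position):
            present = rec.label == "germline" or rng.random() < rec.cell_fraction
            span_rows.append(
                {
                    "read_id": rid,
                    "site_index": i,
                    "scaffold": scf,
                    "position": rec.position,
                    "cell_fraction": rec.cell_fraction,
                    "label": rec.label,
                    "element_present": bool(present),
                }
            )
            if present:
                pieces.append(seq[cursor : rec.position])
                pieces.append(element if rec.orientation == "+" else revcomp(element))
                cursor = rec.position
        pieces.append(seq[cursor:end])
        read_seq = _mutate("".join(pieces), rng, error_rate)
        strand = rng.choice(["+", "-"])
        if strand == "-":
            read_seq = revcomp(read_seq)
        reads.append(RawRead(rid, read_seq, None, sample_id))
        read_rows.append(
            {
                "read_id": rid,
                "scaffold": scf,
                "start": start,
                "end": end,
                "strand": strand,
                "n_sites": len(interior),
            }
        )
    return reads, pd.DataFrame(read_rows), pd.DataFrame(span_rows)


# ---------------------------------------------------------------------------
# helpers tying the simulator to observed summary statistics


def poisson_rate_for_coverage_fraction(target: float = 0.13) -> float:
    """Poisson mean lambda such that P(X >= 2 | X >= 1) equals ``target``.

    The with-coverage fraction of detected insertion sites (sites supported
    by at least two reads among those seen at all) is this conditional tail
    under per-site Poisson sampling; ~13% corresponds to lambda ~0.27.
    """
    if not 0 < target < 1:
        raise InputError("target fraction must be in (0, 1)")

    def f(lam):
        p0 = np.exp(-lam)
        return (1 - p0 - lam * p0) / (1 - p0) - target

    return float(brentq(f, 1e-9, 50.0))


# ---------------------------------------------------------------------------
# text-format output


def write_fastq(reads: Sequence[RawRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.quality or "?" * len(r.sequence)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


def write_fasta(entries, path) -> None:
    """Write (id, sequence) pairs, RawReads, or a mapping as FASTA."""
    if isinstance(entries, Mapping):
        entries = list(entries.items())
    with open(path, "w") as fh:
        for entry in entries:
            if isinstance(entry, RawRead):
                name, seq = entry.id, entry.sequence
            else:
                name, seq = entry
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
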