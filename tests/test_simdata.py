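"""Synthetic-data generator: determinism, protocol consistency, truth tables."""

import re

import numpy as np
import pandas as pd
import pytest

import tisseq as t
from tisseq.simdata import (
    DesignError,
    InsertionRecord,
    reconstruct_read,
    site_accessibility_table,
    truth_frame,
)
from tisseq.sir import InputError


def _scrub(seq: str, sites=("GAATTC", "AAGCTT")) -> str:
    out = list(seq)
    for site in sites:
        for m in re.finditer(f"(?={site})", "".join(out)):
            out[m.start() + 3] = "C" if out[m.start() + 3] != "C" else "G"
    return "".join(out)


class TestGenerateGenome:
    def test_length_contract(self):
        g = t.generate_genome([1000], 0.5, seed=1)
        assert g.total_length == 1000 and len(g.scaffolds) == 1

    def test_degenerate_length_rejected(self):
        with pytest.raises(InputError):
            t.generate_genome([0], 0.5, 1)

    def test_gc_fraction_realised(self):
        g = t.generate_genome([50_000], 0.35, seed=7)
        seq = g.scaffolds["scf1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.32 <= gc <= 0.38

    def test_deterministic_for_fixed_seed(self):
        a = t.generate_genome([5000, 3000], 0.4, seed=9)
        b = t.generate_genome([5000, 3000], 0.4, seed=9)
        assert a.scaffolds == b.scaffolds


class TestElementAndDesign:
    def test_element_has_no_recognition_sites(self, element):
        assert "GAATTC" not in element and "AAGCTT" not in element

    def test_terminal_repeats_are_imperfect_inversions(self, element):
        left = element[:28]
        right = t.revcomp(element[-28:])
        mismatches = sum(a != b for a, b in zip(left, right))
        assert 3 <= mismatches <= 10  # distinguishable primers, recognisable TIR

    def test_primer_derivation(self, element, design):
        assert design.primers["upstream"] == t.revcomp(element[:22])
        assert design.primers["downstream"] == element[-22:]

    def test_element_with_site_is_rejected(self, design):
        bad = "ACGT" * 20 + "GAATTC" + "ACGT" * 20
        with pytest.raises(DesignError):
            t.plant_insertions(
                t.generate_genome([1000], 0.5, 0), bad, 0, 1, design=design
            )


class TestPlantInsertions:
    def test_empty_truth(self, small_genome, element):
        assert t.plant_insertions(small_genome, element, 0, 0, seed=1) == []

    def test_count_and_fraction_contract(self, small_genome, element):
        truth = t.plant_insertions(small_genome, element, 2, 10, seed=5)
        assert len(truth) == 12
        assert sum(r.cell_fraction == 1.0 for r in truth) >= 2
        assert all(r.cell_fraction == 1.0 for r in truth if r.label == "germline")
        assert all(0 < r.cell_fraction <= 1 for r in truth)
        keys = [(r.scaffold, r.position) for r in truth]
        assert keys == sorted(keys)

    def test_same_seed_gives_identical_truth(self, small_genome, element):
        a = truth_frame(t.plant_insertions(small_genome, element, 2, 10, seed=5))
        b = truth_frame(t.plant_insertions(small_genome, element, 2, 10, seed=5))
        pd.testing.assert_frame_equal(a, b)


class TestTisseqLibrary:
    def test_empty_truth_yields_only_artifacts(self, small_genome, design):
        reads, truth_df, _ = t.simulate_tisseq_library(
            small_genome, [], design, "empty", seed=1
        )
        classes = set(truth_df["class"])
        assert "element" not in classes
        n_expected = round(design.depth * (design.chimera_rate + design.contaminant_rate))
        # chimeras need element amplicons to recombine, so only contaminants appear
        assert classes <= {"contaminant"}
        assert len(reads) == pytest.approx(design.depth * design.contaminant_rate, rel=0.1)

    def test_known_flank_recovered_exactly(self, element):
        # one insertion exactly 100 bp downstream of an EcoRI cut
        rng = np.random.default_rng(42)
        body = _scrub("".join(rng.choice(list("ACGT"), size=1000)))
        seq = body[:500] + "GAATTC" + body[500:]
        genome = t.SyntheticGenome({"scf1": seq}, seed=0)
        cut = 500 + 1  # EcoRI cuts after the leading G
        pos = cut + 100
        truth = [InsertionRecord("scf1", pos, "+", 1.0, "germline")]
        design = t.LibraryDesign.for_element(
            element, error_rate=0.0, chimera_rate=0.0, contaminant_rate=0.0, depth=10
        )
        reads, truth_df, site_table = t.simulate_tisseq_library(
            genome, truth, design, "s", seed=2
        )
        expected_flank = seq[cut:pos]
        assert len(expected_flank) == 100
        up = truth_df[truth_df.end == "upstream"]
        assert len(up) > 0
        for row in up.itertuples():
            read = next(r for r in reads if r.id == row.read_id)
            oriented = read.sequence if row.strand == "+" else t.revcomp(read.sequence)
            assert oriented == (
                design.adapters["EcoRI"] + expected_flank + element[:22]
            )

    def test_fixed_mode_emits_exactly_depth_reads(self, library, design):
        reads, _, _ = library
        assert len(reads) == design.depth == 10_000

    def test_deterministic_output(self, small_genome, small_truth, design):
        a, ta, _ = t.simulate_tisseq_library(small_genome, small_truth, design, "x", 9)
        b, tb, _ = t.simulate_tisseq_library(small_genome, small_truth, design, "x", 9)
        assert [(r.id, r.sequence) for r in a] == [(r.id, r.sequence) for r in b]
        pd.testing.assert_frame_equal(ta, tb)

    def test_no_element_read_exceeds_max_length(self, library, design):
        reads, truth_df, _ = library
        lengths = {r.id: len(r.sequence) for r in reads}
        elem = truth_df[truth_df["class"] == "element"]
        assert all(lengths[rid] <= design.max_read_len for rid in elem.read_id)

    def test_reads_reconstructable_from_truth_at_zero_error(
        self, small_genome, small_truth, clean_library, clean_design
    ):
        reads, truth_df, _ = clean_library
        by_id = {r.id: r.sequence for r in reads}
        elem = truth_df[truth_df["class"] == "element"]
        assert len(elem) > 0
        for row in elem.to_dict("records"):
            rebuilt = reconstruct_read(row, small_genome, small_truth, clean_design)
            assert rebuilt == by_id[row["read_id"]]

    def test_accessibility_flags_match_brute_force_cut_scan(
        self, small_genome, small_truth, design
    ):
        table = site_accessibility_table(small_genome, small_truth, design)
        seq = small_genome.scaffolds["scf1"]
        cuts = sorted(
            m.start() + 1 for pat in ("GAATTC", "AAGCTT") for m in re.finditer(pat, seq)
        )
        budget = design.flank_budget("EcoRI")
        for row in table.itertuples():
            p = row.position
            side = "left" if (row.end == "upstream") == (row.orientation == "+") else "right"
            if side == "left":
                dists = [p - c for c in cuts if c <= p]
                expected = bool(dists) and 1 <= min(dists) <= budget
            else:
                dists = [c - p for c in cuts if c >= p]
                expected = bool(dists) and 1 <= min(dists) <= budget
            assert row.accessible == expected


class TestLongReads:
    def test_full_fraction_locus_always_carries_element(self, small_genome, element):
        truth = [InsertionRecord("scf1", 100_000, "+", 1.0, "germline")]
        reads, _, spans = t.simulate_long_reads(
            small_genome, truth, element, depth=150, seed=3
        )
        spanning = spans[spans.site_index == 0]
        assert len(spanning) > 0
        assert spanning.element_present.all()

    def test_half_fraction_locus_splits_binomially(self, small_genome, element):
        truth = [InsertionRecord("scf1", 100_000, "+", 0.5, "somatic")]
        reads, _, spans = t.simulate_long_reads(
            small_genome, truth, element, depth=2000, seed=4
        )
        spanning = spans[spans.site_index == 0]
        frac = spanning.element_present.mean()
        n = len(spanning)
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_error_free_reads_contain_element_exactly(self, small_genome, element):
        truth = [InsertionRecord("scf1", 100_000, "-", 1.0, "germline")]
        reads, read_tab, spans = t.simulate_long_reads(
            small_genome, truth, element, error_rate=0.0, depth=100, seed=5
        )
        with_el = set(spans[spans.element_present].read_id)
        for r in reads:
            if r.id in with_el:
                assert element in r.sequence or t.revcomp(element) in r.sequence


def test_poisson_rate_reproduces_conditional_coverage():
    lam = t.poisson_rate_for_coverage_fraction(0.13)
    p0 = np.exp(-lam)
    conditional = (1 - p0 - lam * p0) / (1 - p0)
    assert conditional == pytest.approx(0.13, abs=1e-9)
    assert 0.2 < lam < 0.35
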