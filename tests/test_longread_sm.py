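"""Long-read element discovery, region grouping and SM-event calling."""

import numpy as np
import pytest

import tisseq as t
from _oracles import union_find_partition
from tisseq.longread_sm import (
    FlankPair,
    extract_flanks,
    find_element_reads,
    group_regions,
    region_uniqueness,
    similarity_matrix,
)
from tisseq.simdata import InsertionRecord
from tisseq.trimming import RawRead


def _rand(n, seed):
    return "".join(np.random.default_rng(seed).choice(list("ACGT"), size=n))


@pytest.fixture(scope="module")
def sm_world(element):
    """A genome with one tandem-duplicated segment and four insertion loci."""
    g = t.generate_genome([300_000], 0.42, seed=5)
    seq = g.scaffolds["scf1"]
    dup = seq[50_000:55_000]
    g.scaffolds["scf1"] = seq[:200_000] + dup + seq[200_000 + len(dup):]
    truth = [
        InsertionRecord("scf1", 20_000, "+", 1.0, "germline"),
        InsertionRecord("scf1", 52_500, "+", 0.5, "somatic"),  # inside the dup
        InsertionRecord("scf1", 120_000, "-", 0.5, "somatic"),
        InsertionRecord("scf1", 260_000, "+", 0.6, "somatic"),
    ]
    reads, read_tab, span_tab = t.simulate_long_reads(
        g, truth, element, mean_len=8000, len_sd=800, error_rate=0.0, depth=500, seed=9
    )
    return g, truth, reads, span_tab


class TestFindElementReads:
    def test_reads_without_element_yield_nothing(self, element):
        reads = [RawRead(f"r{i}", _rand(5000, i), None, "lr") for i in range(5)]
        assert find_element_reads(reads, element) == []

    def test_planted_element_found_at_full_identity(self, element):
        read = RawRead("r", _rand(2000, 1) + element + _rand(2000, 2), None, "lr")
        hits = find_element_reads([read], element)
        assert len(hits) == 1
        h = hits[0]
        assert (h.read_start, h.read_end) == (2000, 2000 + len(element))
        assert h.percent_identity == 100.0 and h.element_coverage == 100.0
        assert h.strand == "+"

    def test_reverse_strand_copy_detected(self, element):
        read = RawRead("r", _rand(1000, 3) + t.revcomp(element) + _rand(1000, 4), None, "lr")
        (h,) = find_element_reads([read], element)
        assert h.strand == "-"

    def test_twenty_planted_copies_give_twenty_hits(self, element):
        reads = [
            RawRead(f"r{i:02d}", _rand(2500, 10 + i) + element + _rand(2500, 40 + i), None, "lr")
            for i in range(20)
        ]
        hits = find_element_reads(reads, element)
        assert len(hits) == 20
        assert len({h.read_id for h in hits}) == 20

    def test_two_copies_on_one_read(self, element):
        read = RawRead(
            "r", _rand(1000, 5) + element + _rand(3000, 6) + element + _rand(1000, 7),
            None, "lr",
        )
        hits = find_element_reads([read], element)
        assert len(hits) == 2

    def test_edge_truncated_copy_probed_with_reduced_coverage(self, element):
        # read begins 15% into the element: 85% coverage, above the 80% floor
        cut = int(len(element) * 0.15)
        read = RawRead("r", element[cut:] + _rand(3000, 8), None, "lr")
        hits = find_element_reads([read], element)
        assert len(hits) == 1
        assert hits[0].element_coverage < 100.0
        assert hits[0].read_start == 0


class TestExtractFlanks:
    def test_centered_element_yields_full_flanks(self, element):
        left, right = _rand(2500, 11), _rand(2500, 12)
        read = RawRead("r", left + element + right, None, "lr")
        (hit,) = find_element_reads([read], element)
        pair = extract_flanks(read, hit, 2000)
        assert pair.upstream == left[-2000:]
        assert pair.downstream == right[:2000]
        assert not pair.upstream_truncated and not pair.downstream_truncated

    def test_element_near_read_start_truncates_upstream(self, element):
        read = RawRead("r", _rand(500, 13) + element + _rand(2500, 14), None, "lr")
        (hit,) = find_element_reads([read], element)
        pair = extract_flanks(read, hit, 2000)
        assert len(pair.upstream) == 500 and pair.upstream_truncated

    def test_minus_strand_flanks_equal_revcomp_construction(self, element):
        left, right = _rand(2500, 15), _rand(2500, 16)
        read = RawRead("r", left + t.revcomp(element) + right, None, "lr")
        (hit,) = find_element_reads([read], element)
        pair = extract_flanks(read, hit, 2000)
        # element-forward: upstream of the element is the revcomp of `right`
        assert pair.upstream == t.revcomp(right[:2000])
        assert pair.downstream == t.revcomp(left[-2000:])


class TestGroupRegions:
    @staticmethod
    def _locus_pairs(locus_seed, n_reads, start_idx):
        """Flank pairs as extract_flanks yields them: anchored at the element
        junction, truncated only on the outer side (read boundaries)."""
        locus = _rand(6000, locus_seed)
        junction = 3000
        pairs = []
        rng = np.random.default_rng(locus_seed + 1)
        for k in range(n_reads):
            up_len = 2000 - int(rng.integers(0, 800))
            down_len = 2000 - int(rng.integers(0, 800))
            pairs.append(
                FlankPair(
                    f"r{start_idx + k:03d}",
                    locus[junction - up_len : junction],
                    locus[junction : junction + down_len],
                    up_len < 2000,
                    down_len < 2000,
                )
            )
        return pairs

    def test_single_locus_forms_one_group(self):
        pairs = self._locus_pairs(100, 5, 0)
        regions, _ = group_regions(pairs)
        assert len(regions) == 1
        assert len(regions[0].read_ids) == 5

    def test_four_locus_fixture_recovers_group_sizes(self):
        pairs = (
            self._locus_pairs(200, 13, 0)
            + self._locus_pairs(300, 1, 13)
            + self._locus_pairs(400, 3, 14)
            + self._locus_pairs(500, 3, 17)
        )
        regions, matrix = group_regions(pairs)
        assert sorted(len(r.read_ids) for r in regions) == [1, 3, 3, 13]
        assert np.allclose(matrix.values, matrix.values.T)
        assert np.all(np.diag(matrix.values) == 100.0)

    def test_partition_matches_union_find_oracle(self):
        pairs = self._locus_pairs(600, 4, 0) + self._locus_pairs(700, 3, 4)
        regions, matrix = group_regions(pairs)
        edges = []
        ids = [p.read_id for p in pairs]
        by_id = {p.read_id: p for p in pairs}
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                la, lb = len(by_id[a].signature), len(by_id[b].signature)
                cov_ok = 100 * min(la, lb) / max(la, lb) >= 50
                if cov_ok and matrix.loc[a, b] >= 90:
                    edges.append((a, b))
        expected = union_find_partition(ids, edges)
        assert {frozenset(r.read_ids) for r in regions} == expected


class TestRegionUniqueness:
    def test_single_copy_flank_is_unique(self, sm_world):
        g, *_ = sm_world
        flank = g.scaffolds["scf1"][118_000:120_000]
        status, scaffold = region_uniqueness(flank, g.scaffolds)
        assert status == "unique" and scaffold == "scf1"

    def test_tandem_duplicated_flank_is_multicopy(self, sm_world):
        g, *_ = sm_world
        flank = g.scaffolds["scf1"][51_000:53_000]
        status, _ = region_uniqueness(flank, g.scaffolds)
        assert status == "multicopy"

    def test_foreign_sequence_is_unplaced(self, sm_world):
        g, *_ = sm_world
        status, scaffold = region_uniqueness(_rand(2000, 77), g.scaffolds)
        assert status == "unplaced" and scaffold is None


class TestDetectSmEvents:
    def test_verdicts_match_simulation_truth_with_no_false_positives(
        self, sm_world, element
    ):
        g, truth, reads, span_tab = sm_world
        report = t.analyze_long_reads(reads, element, g.scaffolds)
        # map each region back to a truth locus via its reads' spanned sites
        verdicts = {}
        for region, event in zip(report.regions, report.events):
            spanned = span_tab[
                span_tab.read_id.isin(region.read_ids) & span_tab.element_present
            ]
            locus = int(spanned.site_index.mode().iloc[0])
            verdicts[locus] = event.verdict
        # unique somatic loci (mosaic) are supported; germline and multicopy are not
        assert verdicts[0] == "unsupported"  # germline, fraction 1.0
        assert verdicts[1] == "unsupported"  # somatic but in the duplicated segment
        assert verdicts[2] == "supported"
        assert verdicts[3] == "supported"

    def test_full_fraction_locus_lacks_without_element_reads(self, element):
        g = t.generate_genome([120_000], 0.42, seed=55)
        truth = [InsertionRecord("scf1", 60_000, "+", 1.0, "germline")]
        reads, _, _ = t.simulate_long_reads(
            g, truth, element, error_rate=0.0, depth=200, seed=56
        )
        report = t.analyze_long_reads(reads, element, g.scaffolds)
        assert len(report.regions) == 1
        event = report.events[0]
        assert event.verdict == "unsupported"
        assert event.reads_without_element == ()
        assert len(event.reads_with_element) > 0

    def test_similarity_matrix_is_symmetric_with_unit_diagonal(self, element):
        pairs = [
            FlankPair(f"r{i}", _rand(1500, 80 + i), _rand(1500, 90 + i), False, False)
            for i in range(4)
        ]
        m = similarity_matrix(pairs)
        assert np.allclose(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 100.0)
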