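"""Taxonomy resolution, ranges, diversity, per-capita rates, comparisons."""

import math

import numpy as np
import pytest

from stratmine.kb import KBTuple
from stratmine.macroevo import (
    GenusRange,
    apply_taxonomy,
    first_difference_spearman,
    foote_rates,
    genus_ranges,
    range_offsets,
    rangethrough_diversity,
    resolve_taxonomy,
)
from stratmine.probkb import OccurrenceRecord


def _op(rel, a, b, year=None):
    return KBTuple(rel, a, b, pub_year=year)


class TestResolveTaxonomy:
    def test_most_recent_opinion_governs(self):
        tax = resolve_taxonomy([
            _op("opinion_belongs", "Aus", "F1idae", 1990),
            _op("opinion_belongs", "Aus", "F2idae", 2000),
        ])
        assert tax.parent_of["Aus"] == "F2idae"

    def test_year_tie_broken_by_majority_then_name(self):
        tax = resolve_taxonomy([
            _op("opinion_belongs", "Aus", "F1idae", 2000),
            _op("opinion_belongs", "Aus", "F2idae", 2000),
            _op("opinion_belongs", "Aus", "F2idae", 1990),
        ])
        assert tax.parent_of["Aus"] == "F2idae"
        tax2 = resolve_taxonomy([
            _op("opinion_belongs", "Aus", "F1idae", 2000),
            _op("opinion_belongs", "Aus", "F2idae", 2000),
        ])
        assert tax2.parent_of["Aus"] == "F1idae"

    def test_synonymy_resolves_transitively(self):
        tax = resolve_taxonomy([
            _op("opinion_synonym", "A", "B", 1990),
            _op("opinion_synonym", "B", "C", 1995),
        ])
        assert tax.senior("A") == "C"
        assert tax.senior("B") == "C"
        assert tax.senior("C") == "C"

    def test_cycle_broken_by_dropping_most_recent(self):
        tax = resolve_taxonomy([
            _op("opinion_synonym", "A", "B", 1990),
            _op("opinion_synonym", "B", "A", 2000),
        ])
        # the 2000 opinion closes the cycle and is dropped: A -> B survives
        assert tax.senior("A") == "B"
        assert tax.senior("B") == "B"
        assert len(tax.dropped_opinions) == 1
        assert tax.dropped_opinions[0].subject == "B"

    def test_apply_taxonomy_rekeys_occurrences(self):
        tax = resolve_taxonomy([_op("opinion_synonym", "Jr", "Sr", 1990)])
        occ = OccurrenceRecord("Jr", None, "F", "Silurian", "", "d", 1.0)
        out = apply_taxonomy([occ], tax)
        assert out[0].genus == "Sr"


class TestGenusRanges:
    def _occ(self, genus, iv):
        return OccurrenceRecord(genus, None, "F", iv, "", "d", 1.0)

    def test_single_occurrence_single_bin(self, table):
        ranges, dropped = genus_ranges([self._occ("Aus", "Serpukhovian")], table)
        assert dropped == 0
        r = ranges[0]
        assert r.first_bin == r.last_bin == table.bin_index("Mississippian")
        assert r.first_age == pytest.approx(table.bins[r.first_bin].midpoint)

    def test_two_occurrences_span_range(self, table):
        occs = [self._occ("Aus", "Serpukhovian"), self._occ("Aus", "Wuchiapingian")]
        ranges, _ = genus_ranges(occs, table)
        r = ranges[0]
        assert r.first_bin == table.bin_index("Mississippian")
        assert r.last_bin == table.bin_index("Lopingian")

    def test_multibin_interval_occurrence_dropped_and_counted(self, table):
        # the Namurian straddles two epoch bins
        occs = [self._occ("Aus", "Namurian"), self._occ("Aus", "Serpukhovian")]
        ranges, dropped = genus_ranges(occs, table)
        assert dropped == 1
        assert ranges[0].first_bin == ranges[0].last_bin


class TestDiversityAndRates:
    RANGES = [
        GenusRange("A", 1, 3, 0, 0),
        GenusRange("B", 2, 2, 0, 0),
        GenusRange("C", 2, 4, 0, 0),
        GenusRange("D", 1, 4, 0, 0),
    ]

    def test_no_genera_all_zero(self):
        assert rangethrough_diversity([], 5).tolist() == [0] * 5

    def test_single_range_counts_inclusive(self):
        div = rangethrough_diversity([GenusRange("A", 2, 5, 0, 0)], 8)
        assert div.tolist() == [0, 0, 1, 1, 1, 1, 0, 0]

    def test_hand_counted_diversity(self):
        div = rangethrough_diversity(self.RANGES, 6)
        assert div[2] == 4

    def test_extinction_rate_hand_count(self):
        # bin 3: bottom crossers {A, C, D}, of which {C, D} also cross the top
        counts = foote_rates(self.RANGES, 6)
        assert counts.N_b[3] == 3 and counts.N_bt[3] == 2
        assert counts.q_rate[3] == pytest.approx(-math.log(2 / 3), abs=1e-12)

    def test_origination_rate_hand_count(self):
        # bin 2: top crossers {A, C, D}, of which {A, D} also cross the bottom
        counts = foote_rates(self.RANGES, 6)
        assert counts.N_t[2] == 3 and counts.N_bt[2] == 2
        assert counts.p_rate[2] == pytest.approx(-math.log(2 / 3), abs=1e-12)

    def test_full_range_genus_gives_zero_interior_rates(self):
        counts = foote_rates([GenusRange("A", 0, 4, 0, 0)], 5)
        for i in (1, 2, 3):
            assert counts.p_rate[i] == 0.0
            assert counts.q_rate[i] == 0.0

    def test_rates_undefined_without_crossers(self):
        counts = foote_rates([GenusRange("A", 2, 2, 0, 0)], 5)
        assert math.isnan(counts.p_rate[2]) and math.isnan(counts.q_rate[2])

    def test_singletons_counted_in_diversity_not_rates(self):
        base = foote_rates(self.RANGES, 6)
        with_singleton = foote_rates(
            self.RANGES + [GenusRange("S", 3, 3, 0, 0)], 6
        )
        assert with_singleton.diversity[3] == base.diversity[3] + 1
        assert with_singleton.q_rate[3] == base.q_rate[3]
        assert with_singleton.p_rate[3] == base.p_rate[3]

    def test_per_myr_divides_by_duration(self):
        per_interval = foote_rates(self.RANGES, 6)
        per_myr = foote_rates(self.RANGES, 6, durations=[10.0] * 6)
        assert per_myr.q_rate[3] == pytest.approx(per_interval.q_rate[3] / 10)

    def test_conservation_of_first_and_last_bins(self):
        rng = np.random.default_rng(4)
        ranges = _random_ranges(rng, 200, 20)
        firsts = np.zeros(20, dtype=int)
        lasts = np.zeros(20, dtype=int)
        for r in ranges:
            firsts[r.first_bin] += 1
            lasts[r.last_bin] += 1
        assert firsts.sum() == len(ranges) == lasts.sum()
        counts = foote_rates(ranges, 20)
        # genera originating in bin i = N_Ft + N_FL there
        assert (counts.N_Ft + counts.N_FL == firsts).all()
        assert (counts.N_bL + counts.N_FL == lasts).all()

    def test_brute_force_membership_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            ranges = _random_ranges(rng, int(rng.integers(1, 60)), 12)
            counts = foote_rates(ranges, 12)
            div = rangethrough_diversity(ranges, 12)
            bf = _brute_force_counts(ranges, 12)
            assert (div == bf["div"]).all()
            for key in ("N_bt", "N_bL", "N_Ft", "N_FL"):
                assert (getattr(counts, key) == bf[key]).all()


def _random_ranges(rng, n, n_bins):
    out = []
    for i in range(n):
        a, b = sorted(rng.integers(0, n_bins, size=2))
        out.append(GenusRange(f"G{i}", int(a), int(b), 0, 0))
    return out


def _brute_force_counts(ranges, n_bins):
    """Independent per-genus membership scan of the boundary-crosser classes."""
    out = {k: np.zeros(n_bins, dtype=int) for k in
           ("div", "N_bt", "N_bL", "N_Ft", "N_FL")}
    for i in range(n_bins):
        for r in ranges:
            present = r.first_bin <= i <= r.last_bin
            if not present:
                continue
            out["div"][i] += 1
            bottom = r.first_bin < i
            top = r.last_bin > i
            key = {(True, True): "N_bt", (True, False): "N_bL",
                   (False, True): "N_Ft", (False, False): "N_FL"}[(bottom, top)]
            out[key][i] += 1
    return out


class TestComparisons:
    def test_identical_ranges_zero_offsets(self):
        ranges = [GenusRange("A", 1, 3, 400.0, 300.0)]
        df = range_offsets(ranges, ranges)
        assert df["first_offset_myr"].tolist() == [0.0]
        assert df["last_offset_myr"].tolist() == [0.0]

    def test_one_bin_shift_gives_bin_width_offset(self):
        a = [GenusRange("A", 1, 3, 400.0, 300.0)]
        b = [GenusRange("A", 1, 4, 400.0, 290.0)]
        df = range_offsets(a, b)
        assert df["last_offset_myr"].tolist() == [10.0]
        df2 = range_offsets(a, b, sign="b_minus_a")
        assert df2["last_offset_myr"].tolist() == [-10.0]

    def test_only_shared_genera_compared(self):
        a = [GenusRange("A", 1, 2, 10, 5), GenusRange("B", 1, 2, 10, 5)]
        b = [GenusRange("B", 1, 2, 10, 5), GenusRange("C", 1, 2, 10, 5)]
        assert range_offsets(a, b)["genus"].tolist() == ["B"]


class TestFirstDifferenceSpearman:
    def test_identical_series(self):
        x = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0]
        rho, _ = first_difference_spearman(x, x)
        assert rho == pytest.approx(1.0)

    def test_negated_series(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
        rho, _ = first_difference_spearman(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_known_rank_example(self):
        # series whose first differences are (1,2,3,4,5) vs (2,1,4,3,5):
        # rank formula rho = 1 - 6*4 / (5*24) = 0.8
        a = np.concatenate([[0.0], np.cumsum([1, 2, 3, 4, 5])])
        b = np.concatenate([[0.0], np.cumsum([2, 1, 4, 3, 5])])
        rho, _ = first_difference_spearman(a, b)
        d = np.array([1, 2, 3, 4, 5]) - np.array([2, 1, 4, 3, 5])
        oracle = 1 - 6 * (d ** 2).sum() / (5 * (25 - 1))
        assert rho == pytest.approx(oracle) == pytest.approx(0.8)

    def test_nan_bins_excluded_pairwise(self):
        a = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 7.0, 8.0])
        b = np.array([1.0, 3.0, 2.0, 4.0, 6.0, 7.0, 9.0])
        rho, _ = first_difference_spearman(a, b)
        assert math.isfinite(rho)

    def test_insufficient_overlap_raises(self):
        with pytest.raises(ValueError):
            first_difference_spearman([1.0, 2.0], [2.0, 1.0])
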