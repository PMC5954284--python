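"""Token extraction, thresholding, accumulation sums and location filtering."""

import numpy as np
import pytest

from seedfilter.filter_core import (
    FilterConfig,
    ReadSequence,
    accumulation_sum,
    accumulation_sums_all_bins,
    allowable_errors,
    compute_threshold,
    extract_tokens,
    filter_bin_window,
    filter_read_locations,
    write_bitmask_tsv,
)
from seedfilter.genome_index import (
    GenomeSequence,
    TokenCodec,
    bin_of_location,
    build_index,
    make_binning,
)
from seedfilter.synthetic_data import random_genome

CFG = FilterConfig(token_size=5, error_tolerance=0.05)


class TestExtractTokens:
    def test_sliding_window(self):
        occs = extract_tokens(ReadSequence("r", "GACAGT"), 5)
        assert [o.token for o in occs] == ["GACAG", "ACAGT"]
        assert [o.position for o in occs] == [0, 1]

    def test_homopolymer_duplicates_counted_per_occurrence(self):
        occs = extract_tokens(ReadSequence("r", "A" * 104), 5)
        assert len(occs) == 100
        assert all(o.token == "AAAAA" for o in occs)

    def test_count_formula(self):
        read = ReadSequence("r", random_genome(83, 5).seq)
        assert len(extract_tokens(read, 5)) == 83 - (5 - 1)

    def test_ambiguous_tagging(self):
        occs = extract_tokens(ReadSequence("r", "ACGTNACGT"), 5)
        assert [o.ambiguous for o in occs] == [True] * 5

    def test_short_read_rejected(self):
        with pytest.raises(ValueError):
            extract_tokens(ReadSequence("r", "ACG"), 5)


class TestThreshold:
    @pytest.mark.parametrize(
        "L,e,expected", [(100, 0.05, 5), (100, 0.0, 0), (104, 0.05, 6), (77, 0.05, 4)]
    )
    def test_allowable_errors(self, L, e, expected):
        assert allowable_errors(L, e) == expected

    def test_allowable_errors_float_artifact(self):
        # 60 * 0.1 is fractionally above 6 in binary floats; the exact
        # product is an integer and must not be rounded up
        assert allowable_errors(60, 0.1) == 6

    @pytest.mark.parametrize(
        "L,n,e,expected",
        [
            (100, 5, 0.05, 71),  # (100 - 4) - 5*5
            (100, 5, 0.0, 96),   # zero tolerance: every token must exist
            (80, 4, 0.0, 77),
            (100, 5, 0.2, 0),    # raw -4, clamped to pass-all
            (104, 5, 0.05, 70),
        ],
    )
    def test_values(self, L, n, e, expected):
        assert compute_threshold(L, n, e) == expected

    def test_worst_case_destruction_oracle(self):
        """k errors at disjoint positions each destroy <= n tokens, so a
        true match retains >= threshold tokens; enumerate small cases."""
        for L, n, e in [(30, 3, 0.1), (50, 4, 0.05), (100, 5, 0.05)]:
            k = allowable_errors(L, e)
            surviving_lower_bound = (L - n + 1) - k * n
            assert compute_threshold(L, n, e) == max(0, surviving_lower_bound)

    def test_monotone_nonincreasing_in_e(self):
        grid = [i / 100 for i in range(0, 30)]
        th = [compute_threshold(100, 5, e) for e in grid]
        assert all(a >= b for a, b in zip(th, th[1:]))

    def test_short_read_rejected(self):
        with pytest.raises(ValueError):
            compute_threshold(4, 5, 0.05)


class TestAccumulationSum:
    def test_all_a_read_vs_single_aaaaa_bin(self):
        """A 104-A read against a bin holding one AAAAA run: every one of
        the 100 token occurrences finds the single existence bit, so the
        sum is 100 and passes the threshold of 70."""
        genome = GenomeSequence(name="g", seq="G" * 95 + "AAAAA" + "G" * 100)
        index = build_index(genome, make_binning(genome.length, 1, 0), TokenCodec(5))
        res = accumulation_sum(ReadSequence("r", "A" * 104), index, 0, CFG)
        assert (res.sum, res.threshold, res.passed) == (100, 70, True)

    def test_exact_containment_is_maximal_and_passes_any_e(self, small_genome, small_index):
        read = ReadSequence("r", small_genome.seq[500:600])
        b = bin_of_location(500, small_index.binning)
        for e in (0.0, 0.05, 0.3):
            res = accumulation_sum(
                read, small_index, b, FilterConfig(5, e)
            )
            assert res.sum == 100 - 5 + 1
            assert res.passed

    def test_disjoint_content_rejected(self):
        genome = GenomeSequence(name="g", seq="G" * 200)
        index = build_index(genome, make_binning(200, 1, 0), TokenCodec(5))
        res = accumulation_sum(ReadSequence("r", "A" * 100), index, 0, CFG)
        assert res.sum == 0 and not res.passed

    def test_matches_naive_count_oracle(
        self, small_genome, small_binning, small_index, naive_accumulation
    ):
        rng = np.random.default_rng(11)
        for _ in range(20):
            z = int(rng.integers(0, small_genome.length - 100))
            seq = list(small_genome.seq[z : z + 100])
            for p in rng.integers(0, 100, size=int(rng.integers(0, 6))):
                seq[p] = "ACGT"[rng.integers(0, 4)]
            read = ReadSequence("r", "".join(seq))
            for b in rng.integers(0, small_binning.num_bins, size=3):
                res = accumulation_sum(read, small_index, int(b), CFG)
                assert res.sum == naive_accumulation(
                    read, small_genome, small_binning, int(b), 5
                )

    def test_sum_bounds(self, small_index):
        read = ReadSequence("r", random_genome(100, 99).seq)
        for b in range(small_index.num_bins):
            res = accumulation_sum(read, small_index, b, CFG)
            assert 0 <= res.sum <= 96

    def test_all_bins_vector_agrees_with_scalar(self, small_index):
        read = ReadSequence("r", random_genome(100, 3).seq)
        sums, threshold = accumulation_sums_all_bins(read, small_index, CFG)
        for b in range(small_index.num_bins):
            res = accumulation_sum(read, small_index, b, CFG)
            assert (res.sum, res.threshold) == (int(sums[b]), threshold)


class TestAmbiguousReads:
    def test_each_n_charged_as_substitution(self, small_genome, small_index):
        z = 700
        seq = list(small_genome.seq[z : z + 100])
        seq[40] = "N"
        read = ReadSequence("r", "".join(seq))
        b = bin_of_location(z, small_index.binning)
        res = accumulation_sum(read, small_index, b, CFG)
        # threshold drops by n per ambiguous base: (71) - 5
        assert res.threshold == 66
        assert res.passed  # true location still passes with an N in the read

    def test_all_n_read_passes_nothing_but_threshold_zero(self, small_index):
        read = ReadSequence("r", "N" * 100)
        res = accumulation_sum(read, small_index, 0, CFG)
        assert res.sum == 0 and res.threshold == 0 and res.passed


class TestFilterReadLocations:
    def test_planted_read_passes(self, small_genome, small_index):
        read = ReadSequence("r", small_genome.seq[1000:1100])
        mask = filter_read_locations(read, [1000], small_index, CFG)
        assert mask.pass_bits() == [1]

    def test_same_bin_locations_share_result(self, small_genome, small_index):
        read = ReadSequence("r", random_genome(100, 21).seq)
        stride = small_index.binning.stride
        mask = filter_read_locations(read, [10, 20, stride + 3], small_index, CFG)
        (z0, b0, r0), (z1, b1, r1), (_, b2, _) = mask.entries
        assert b0 == b1 and r0 is r1 and b2 == b0 + 1
        assert [z for z, _, _ in mask.entries] == [10, 20, stride + 3]

    def test_agrees_with_per_location_evaluation(self, small_genome, small_index):
        rng = np.random.default_rng(5)
        read = ReadSequence("r", small_genome.seq[200:300])
        locs = [int(z) for z in rng.integers(0, small_genome.length, size=50)]
        mask = filter_read_locations(read, locs, small_index, CFG)
        for z, b, res in mask.entries:
            direct = accumulation_sum(
                read, small_index, bin_of_location(z, small_index.binning), CFG
            )
            assert (b, res.sum, res.passed) == (direct.bin, direct.sum, direct.passed)

    def test_invalid_location_names_offender(self, small_index):
        read = ReadSequence("r", "ACGT" * 25)
        with pytest.raises(ValueError, match="99999"):
            filter_read_locations(read, [0, 99999], small_index, CFG)

    def test_passing_set_nondecreasing_in_e(self, small_genome, small_index):
        rng = np.random.default_rng(17)
        read = ReadSequence("r", small_genome.seq[40:140])
        locs = [int(z) for z in rng.integers(0, small_genome.length, size=40)]
        prev: set[int] = set()
        for e in (0.0, 0.02, 0.05, 0.1, 0.2):
            mask = filter_read_locations(
                read, locs, small_index, FilterConfig(5, e)
            )
            passing = set(mask.passing_locations())
            assert prev <= passing
            prev = passing


class TestFilterBinWindow:
    @pytest.mark.parametrize("w", [1, 3, 7])
    def test_results_independent_of_w(self, small_genome, small_index, w):
        read = ReadSequence("r", small_genome.seq[333:433])
        t = small_index.num_bins
        for start in range(0, t - w + 1, w):
            window = filter_bin_window(read, small_index, start, w, CFG)
            for res in window:
                direct = accumulation_sum(read, small_index, res.bin, CFG)
                assert (res.sum, res.threshold, res.passed) == (
                    direct.sum, direct.threshold, direct.passed,
                )

    def test_window_bounds_checked(self, small_index):
        read = ReadSequence("r", "ACGT" * 25)
        with pytest.raises(ValueError):
            filter_bin_window(read, small_index, 0, small_index.num_bins + 1, CFG)


def test_bitmask_tsv_export(small_genome, small_index, tmp_path):
    read = ReadSequence("readA", small_genome.seq[100:200])
    mask = filter_read_locations(read, [100, 2000], small_index, CFG)
    out = tmp_path / "mask.tsv"
    write_bitmask_tsv([mask], str(out))
    lines = out.read_text().strip().split("\n")
    assert lines[0] == "read_id\tlocation\tbin\tsum\tthreshold\tpass"
    assert len(lines) == 3
    first = lines[1].split("\t")
    assert first[0] == "readA" and first[1] == "100" and first[5] == "1"
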