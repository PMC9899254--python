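"""Ka/Ks/4DTv estimation, block summaries, rates and rank tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allophylo import molevo
from allophylo._codon import CODONS, STOP_CODONS
from allophylo.synteny import AnchorPair, CollinearBlock

from .oracles import fourdtv_literal, ng86_literal

NONSTOP = [c for c in CODONS if c not in STOP_CODONS]


def random_cds(rng, n_codons=40):
    return "ATG" + "".join(rng.choice(NONSTOP) for _ in range(n_codons - 1))


class TestEstimateKsKa:
    def test_identical_sequences_have_zero_distances(self, rng):
        seq = random_cds(np.random.default_rng(1))
        est = molevo.estimate_ks_ka(seq, seq)
        assert est.ks == pytest.approx(0.0)
        assert est.ka == pytest.approx(0.0)
        assert est.ka_ks is None  # undefined at Ks = 0

    def test_single_synonymous_codon_change(self):
        # Phe TTT -> TTC: synonymous only; a single codon saturates the
        # correction, so the raw proportion is reported with a flag
        est = molevo.estimate_ks_ka("TTT", "TTC")
        assert est.ka == pytest.approx(0.0)
        assert est.ks > 0
        assert est.saturated

    def test_agrees_with_independent_transcription(self):
        rng = np.random.RandomState(42)
        for _ in range(100):
            a = "".join(rng.choice(NONSTOP) for _ in range(30))
            b = "".join(
                rng.choice(NONSTOP) if rng.rand() < 0.3 else a[i * 3 : i * 3 + 3]
                for i in range(30)
            )
            mine = molevo.estimate_ks_ka(a, b)
            ks, ka, S, N, sd, nd = ng86_literal(a, b)
            assert mine.syn_sites == pytest.approx(S)
            assert mine.nonsyn_sites == pytest.approx(N)
            assert mine.syn_diffs == pytest.approx(sd)
            assert mine.nonsyn_diffs == pytest.approx(nd)
            assert mine.ks == pytest.approx(ks)
            assert mine.ka == pytest.approx(ka)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_symmetric_in_arguments(self, seed):
        rng = np.random.default_rng(seed)
        a = random_cds(rng, 20)
        b = random_cds(rng, 20)
        ab = molevo.estimate_ks_ka(a, b)
        ba = molevo.estimate_ks_ka(b, a)
        assert ab.ks == pytest.approx(ba.ks)
        assert ab.ka == pytest.approx(ba.ka)
        assert (ab.fourdtv is None) == (ba.fourdtv is None)
        if ab.fourdtv is not None:
            assert ab.fourdtv == pytest.approx(ba.fourdtv)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="differ"):
            molevo.estimate_ks_ka("ATGAAA", "ATG")
        with pytest.raises(ValueError, match="multiple of 3"):
            molevo.estimate_ks_ka("ATGA", "ATGA")
        with pytest.raises(ValueError, match="stop"):
            molevo.estimate_ks_ka("ATGTAAAAA", "ATGAAAAAA")
        with pytest.raises(ValueError, match="non-ACGT"):
            molevo.estimate_ks_ka("ATG-AA", "ATGAAA")


class Test4DTv:
    def test_identical_is_zero(self):
        assert molevo.compute_4dtv("ATGGGGCCC", "ATGGGGCCC") == 0.0

    def test_all_transverted_is_one(self):
        # GGT vs GGG and CCA vs CCC: fourfold third positions, transversions
        assert molevo.compute_4dtv("GGTCCA", "GGGCCC") == 1.0

    def test_no_fourfold_sites_is_undefined(self):
        assert molevo.compute_4dtv("ATGAAA", "ATGAAG") is None

    def test_matches_codon_table_enumeration(self, rng):
        for _ in range(20):
            a = random_cds(rng, 10)
            b = random_cds(rng, 10)
            assert molevo.compute_4dtv(a, b) == pytest.approx(
                fourdtv_literal(a, b), nan_ok=True
            ) or (molevo.compute_4dtv(a, b) is None and fourdtv_literal(a, b) is None)


def _block(pair_ks: list[float], bid=0):
    anchors = [AnchorPair(f"a{i}", f"b{i}", "c1", "c2", i, i) for i in range(len(pair_ks))]
    blk = CollinearBlock(bid, "c1", "c2", "+", anchors, len(anchors))
    ests = {
        (f"a{i}", f"b{i}"): molevo.KsKaEstimate(
            ks=k, ka=0.0, fourdtv=0.5, syn_sites=1, nonsyn_sites=1,
            syn_diffs=0, nonsyn_diffs=0,
        )
        for i, k in enumerate(pair_ks)
    }
    return blk, ests


class TestBlockSummaries:
    def test_filters_before_median(self):
        blk, ests = _block([0.0, 0.3, 0.5, 7.0])
        out, dropped = molevo.summarize_blocks([blk], ests)
        assert dropped == 0
        assert out[0].median_ks == pytest.approx(0.4)  # median of {0.3, 0.5}
        assert out[0].n_pairs == 2

    def test_fully_filtered_block_dropped(self):
        blk, ests = _block([0.0, 6.0])
        out, dropped = molevo.summarize_blocks([blk], ests)
        assert out == [] and dropped == 1


class TestKsPeaks:
    def test_unimodal_peak_recovered(self, rng):
        x = rng.normal(0.4, 0.05, size=400)
        peaks = molevo.detect_ks_peaks(x)
        bw = 0.05 * (len(x) ** (-1 / 5))  # Silverman order of magnitude
        assert len(peaks) == 1
        assert abs(peaks[0] - 0.4) < 0.05

    def test_bimodal_mixture_gives_two_peaks(self, rng):
        x = np.concatenate([rng.normal(0.4, 0.05, 500), rng.normal(1.9, 0.2, 500)])
        peaks = molevo.detect_ks_peaks(x)
        assert len(peaks) == 2
        assert abs(peaks[0] - 0.4) < 0.1 and abs(peaks[1] - 1.9) < 0.25

    def test_constant_input_single_peak(self):
        assert molevo.detect_ks_peaks([0.7] * 25) == [0.7]

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            molevo.detect_ks_peaks([0.1] * 19)


class TestRates:
    def test_exact_division(self):
        assert molevo.substitution_rate(0.085, 85e6).r == pytest.approx(1.0e-9)
        assert molevo.substitution_rate(0.0, 1e6).r == 0.0

    def test_rhoiptelea_consistency(self):
        # inverting r = Ks/t at the printed rate 0.55e-9 and t = 85 Myr
        assert molevo.substitution_rate(0.04675, 85e6).r == pytest.approx(0.55e-9)

    def test_rate_roundtrip_is_identity(self):
        est = molevo.substitution_rate(0.123, 44e6)
        assert est.r * est.t_years == pytest.approx(est.ks)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            molevo.substitution_rate(0.1, 0.0)


class TestRelativeRate:
    def test_linear_system_solution(self):
        res = molevo.relative_rate_decompose(0.30, 0.40, 0.50)
        assert res.ks_a == pytest.approx(0.10)
        assert res.ks_b == pytest.approx(0.20)
        assert res.ks_a + res.ks_b == pytest.approx(res.d_ab)

    def test_symmetric_distances(self):
        res = molevo.relative_rate_decompose(0.3, 0.3, 0.3)
        assert res.ks_a == pytest.approx(0.15)
        assert res.ks_b == pytest.approx(0.15)

    def test_exact_on_additive_inputs(self, rng):
        for _ in range(20):
            a, b, o = rng.uniform(0.01, 0.5, size=3)
            res = molevo.relative_rate_decompose(a + b, a + o, b + o)
            assert res.ks_a == pytest.approx(a)
            assert res.ks_b == pytest.approx(b)
            assert res.ks_outgroup == pytest.approx(o)

    def test_inconsistent_distances_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            molevo.relative_rate_decompose(0.1, 0.1, 0.5)

    def test_tiny_negative_clamped(self):
        res = molevo.relative_rate_decompose(0.2, 0.1, 0.3 + 1e-12)
        assert res.ks_a == 0.0
        assert res.clamped


class TestSlowdown:
    def test_printed_bounds(self):
        assert round(molevo.slowdown_ratio(0.17, 85e6, 1.70, 120e6)) == 22
        assert round(molevo.slowdown_ratio(0.48, 85e6, 2.01, 120e6), 1) == 7.7

    def test_numerator_linearity(self):
        base = molevo.slowdown_ratio(0.2, 85e6, 1.0, 120e6)
        doubled = molevo.slowdown_ratio(0.2, 85e6, 1.8, 120e6)
        assert doubled == pytest.approx(2 * base)

    def test_constant_rate_gives_unity(self):
        # Ks strictly proportional to age: no slowdown
        assert molevo.slowdown_ratio(0.85, 85e6, 1.20, 120e6) == pytest.approx(1.0)

    def test_ordering_violations_rejected(self):
        with pytest.raises(ValueError):
            molevo.slowdown_ratio(0.5, 120e6, 1.0, 85e6)
        with pytest.raises(ValueError):
            molevo.slowdown_ratio(1.0, 85e6, 0.5, 120e6)


class TestNe:
    def test_exact_arithmetic(self):
        assert molevo.effective_population_size(1.2e-3, 1e-9, 30).ne == pytest.approx(10_000)
        assert molevo.effective_population_size(0.0, 1e-9, 30).ne == 0.0

    def test_doubling_generation_time_halves_ne(self):
        a = molevo.effective_population_size(1e-3, 1e-9, 30).ne
        b = molevo.effective_population_size(1e-3, 1e-9, 60).ne
        assert a == pytest.approx(2 * b)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            molevo.effective_population_size(1e-3, 0.0, 30)


class TestCompareDistributions:
    def test_identical_samples(self):
        res = molevo.compare_distributions([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.pvalue == pytest.approx(1.0)

    def test_exact_disjoint_p(self):
        res = molevo.compare_distributions(range(1, 6), range(6, 11))
        assert res.pvalue == pytest.approx(2 / 252)

    def test_power_at_one_sd_shift(self, rng):
        hits = 0
        for _ in range(100):
            x = rng.normal(0, 1, 100)
            y = rng.normal(1, 1, 100)
            if molevo.compare_distributions(x, y).pvalue < 0.05:
                hits += 1
        assert hits >= 95

    def test_ks_matching_filter(self):
        x = [1.0, 2.0, 3.0, 10.0]
        y = [1.1, 2.1, 3.1, 0.5]
        res = molevo.compare_distributions(
            x, y, ks_x=[0.1, 0.1, 0.1, 0.9], ks_y=[0.1, 0.1, 0.1, 0.1],
            ks_matching_tolerance=0.05,
        )
        assert res.n_x == 3  # the mismatched-Ks pair is excluded

    def test_too_small_samples_rejected(self):
        with pytest.raises(ValueError):
            molevo.compare_distributions([1, 2], [3, 4, 5])
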