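"""Ploidy likelihoods, Hampel filtering, crossover search, origin patterns."""

import numpy as np
import pandas as pd
import pytest

from cfdeconv.fetal_fraction import ff_from_snp
from cfdeconv.genetics import Hypothesis
from cfdeconv.ploidy import (
    best_double_crossover,
    best_single_crossover,
    call_ploidy,
    classify_meiotic_pattern,
    delta_loglik,
    hampel_filter,
    locus_loglik,
    locus_patterns_from_af,
    loglik_table,
    prepare_chromosome,
)
from cfdeconv.simulate import Scenario, simulate_sample

TRISOMIES = [Hypothesis.MI, Hypothesis.MII, Hypothesis.PI, Hypothesis.PII]


class TestHampel:
    def test_constant_series_untouched(self):
        keep = hampel_filter(np.full(50, 0.5))
        assert keep.all()

    def test_single_outlier_flagged(self):
        rng = np.random.default_rng(0)
        x = 0.5 + rng.uniform(-0.01, 0.01, size=60)
        x[30] = 0.9
        keep = hampel_filter(x, window=11)
        assert not keep[30]
        assert keep.sum() >= 58

    def test_short_series_warns_and_passes(self):
        with pytest.warns(UserWarning, match="shorter"):
            keep = hampel_filter(np.arange(5.0), window=11)
        assert keep.all()

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            hampel_filter(np.zeros(20), window=10)


def _loglik_df(n_alt, depth, p=0.5, gt="AB"):
    return pd.DataFrame(
        {"n_alt": [n_alt], "depth": [depth], "p": [p], "maternal_gt": [gt]}
    )


class TestLocusLoglik:
    def test_pmf_normalizes(self):
        """Sum over all NA of exp(loglik) is 1 (N <= 200, brute force)."""
        for gt, h in (("AB", Hypothesis.D), ("BB", Hypothesis.MII), ("AA", Hypothesis.PI)):
            n = 200
            df = pd.DataFrame(
                {
                    "n_alt": np.arange(n + 1),
                    "depth": n,
                    "p": 0.4,
                    "maternal_gt": gt,
                }
            )
            ll = loglik_table(df, ff=0.1, hypotheses=(h,))
            total = np.exp(ll[h.value].to_numpy()).sum()
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_single_component_symmetric_at_half(self):
        # the fetal-AB component sits at pA = 0.5 where alpha = beta, so
        # its pmf is symmetric: logpmf(NA) = logpmf(N - NA).  (The full
        # mixture is not A<->B symmetric: beta = alpha/pA - alpha gives
        # mirrored components different concentrations by construction.)
        from cfdeconv.ploidy import _betabinom_logpmf

        a = _betabinom_logpmf(np.array([300]), np.array([1000]), 3000.0, 3000.0)
        b = _betabinom_logpmf(np.array([700]), np.array([1000]), 3000.0, 3000.0)
        assert a[0] == pytest.approx(b[0], rel=1e-12)

    def test_uniform_pmf_at_unit_shapes(self):
        # BetaBinom(n=2, a=1, b=1) is uniform on {0,1,2}
        from cfdeconv.ploidy import _betabinom_logpmf

        lp = _betabinom_logpmf(np.array([0, 1, 2]), np.array([2, 2, 2]), 1.0, 1.0)
        assert np.allclose(np.exp(lp), 1.0 / 3.0)

    def test_mode_dominates_tail(self):
        near = locus_loglik(500, 1000, 0.5, "AB", 0.1, Hypothesis.D)
        far = locus_loglik(950, 1000, 0.5, "AB", 0.1, Hypothesis.D)
        assert near > far

    def test_finite_at_extremes(self):
        for x in (0, 1000):
            for gt in ("AA", "AB", "BB"):
                v = locus_loglik(x, 1000, 0.3, gt, 0.05, Hypothesis.MII)
                assert np.isfinite(v)


class TestDeltaLoglik:
    def test_single_locus_identity(self):
        df = _loglik_df(480, 1000)
        ll = loglik_table(df, 0.1)
        want = float(ll["D"].iloc[0] - ll["MI"].iloc[0])
        assert delta_loglik(ll, Hypothesis.MI) == pytest.approx(want)

    def test_zero_loci_guarded(self):
        ll = loglik_table(pd.DataFrame(columns=["n_alt", "depth", "p", "maternal_gt"]), 0.1)
        with pytest.raises(ValueError):
            delta_loglik(ll, Hypothesis.MI)

    def test_euploid_data_favor_disomy(self):
        sc = Scenario(fetal_fraction=0.1, mean_depth=1000, n_target_snps=200,
                      n_reference_snps=0, seed=0)
        loci = prepare_chromosome(simulate_sample(sc), "chr21")
        ll = loglik_table(loci, 0.1)
        assert delta_loglik(ll, Hypothesis.MI) > 0

    def test_mii_data_favor_mii_over_mi(self):
        sc = Scenario(ploidy_hypothesis=Hypothesis.MII, fetal_fraction=0.1,
                      mean_depth=1000, n_target_snps=200, n_reference_snps=0, seed=0)
        loci = prepare_chromosome(simulate_sample(sc), "chr21")
        ll = loglik_table(loci, 0.1)
        d_mii = delta_loglik(ll, Hypothesis.MII)
        assert d_mii < 0
        assert d_mii < delta_loglik(ll, Hypothesis.MI)

    def test_evidence_grows_with_ff_and_depth(self):
        """|deltaL| of a true trisomy increases along an FF/depth grid."""
        vals = []
        for ff, depth in [(0.05, 400), (0.10, 800), (0.16, 1500)]:
            dls = []
            for seed in range(3):
                sc = Scenario(ploidy_hypothesis=Hypothesis.MII, fetal_fraction=ff,
                              mean_depth=depth, n_target_snps=150,
                              n_reference_snps=0, seed=seed)
                loci = prepare_chromosome(simulate_sample(sc), "chr21")
                dls.append(delta_loglik(loglik_table(loci, ff), Hypothesis.MII))
            vals.append(np.mean(dls))
        assert vals[0] > vals[1] > vals[2]  # more negative = stronger


def _brute_single(ll, pair, ms):
    d = ll["D"].to_numpy()
    d1 = d - ll[pair[0].value].to_numpy()
    d2 = d - ll[pair[1].value].to_numpy()
    m = len(d)
    best = (None, None, np.inf)
    for k in range(ms, m - ms + 1):
        t12 = d1[:k].sum() + d2[k:].sum()
        t21 = d2[:k].sum() + d1[k:].sum()
        if t12 < best[2]:
            best = (k, (pair[0], pair[1]), t12)
        if t21 < best[2]:
            best = (k, (pair[1], pair[0]), t21)
    return best


def _brute_double(ll, pair, ms):
    d = ll["D"].to_numpy()
    diffs = {h: d - ll[h.value].to_numpy() for h in pair}
    m = len(d)
    best = ((0, 0), pair, np.inf)
    for outer, inner in (pair, pair[::-1]):
        do, di = diffs[outer], diffs[inner]
        for b1 in range(ms, m - 2 * ms + 1):
            for b2 in range(b1 + ms, m - ms + 1):
                tot = do[:b1].sum() + di[b1:b2].sum() + do[b2:].sum()
                if tot < best[2]:
                    best = ((b1, b2), (outer, inner), tot)
    return best


class TestCrossoverSearch:
    @pytest.fixture(scope="class")
    def small_ll(self):
        sc = Scenario(ploidy_hypothesis=Hypothesis.MI, crossover_breakpoints=(25,),
                      fetal_fraction=0.12, mean_depth=800, n_target_snps=50,
                      n_reference_snps=0, seed=1)
        loci = prepare_chromosome(simulate_sample(sc), "chr21")
        return loglik_table(loci, 0.12)

    def test_single_matches_brute_force(self, small_ll):
        pair = (Hypothesis.MI, Hypothesis.MII)
        got = best_single_crossover(small_ll, pair, min_segment=5)
        want = _brute_single(small_ll, pair, 5)
        assert got[0] == want[0]
        assert got[2] == pytest.approx(want[2])

    def test_double_matches_brute_force(self, small_ll):
        pair = (Hypothesis.MI, Hypothesis.MII)
        got = best_double_crossover(small_ll, pair, min_segment=5)
        want = _brute_double(small_ll, pair, 5)
        assert got[0] == want[0]
        assert got[2] == pytest.approx(want[2])

    def test_paternal_pair_brute_force(self):
        sc = Scenario(ploidy_hypothesis=Hypothesis.PI, crossover_breakpoints=(20,),
                      fetal_fraction=0.1, mean_depth=600, n_target_snps=40,
                      n_reference_snps=0, seed=2)
        ll = loglik_table(prepare_chromosome(simulate_sample(sc), "chr21"), 0.1)
        pair = (Hypothesis.PI, Hypothesis.PII)
        got = best_single_crossover(ll, pair, min_segment=5)
        want = _brute_single(ll, pair, 5)
        assert got[0] == want[0] and got[2] == pytest.approx(want[2])

    def test_breakpoint_recovered_at_midpoint(self):
        """50 MI + 50 MII loci at FF 0.15, depth 1000: split found near 50."""
        sc = Scenario(ploidy_hypothesis=Hypothesis.MI, crossover_breakpoints=(50,),
                      fetal_fraction=0.15, mean_depth=1000, n_target_snps=100,
                      n_reference_snps=300, seed=0)
        ds = simulate_sample(sc)
        loci = prepare_chromosome(ds, "chr21")
        ll = loglik_table(loci, ff_from_snp(ds).ff)
        k, (lead, _), _ = best_single_crossover(ll, (Hypothesis.MI, Hypothesis.MII))
        k_orig = int(loci["locus_index"].iloc[min(k, len(loci) - 1)])
        assert lead is Hypothesis.MI
        assert abs(k_orig - 50) <= 3

    def test_homogeneous_data_yield_no_crossover_call(self):
        sc = Scenario(ploidy_hypothesis=Hypothesis.MII, fetal_fraction=0.12,
                      mean_depth=1000, n_target_snps=200, n_reference_snps=300, seed=4)
        ds = simulate_sample(sc)
        call = call_ploidy(ds, ff_from_snp(ds).ff, candidates=TRISOMIES)
        assert call.hypothesis == "MII"
        assert call.n_crossovers == 0

    def test_too_few_loci_errors(self):
        df = pd.DataFrame({"n_alt": [5], "depth": [10], "p": [0.5], "maternal_gt": ["AB"]})
        ll = loglik_table(df, 0.1)
        with pytest.raises(ValueError):
            best_single_crossover(ll, (Hypothesis.MI, Hypothesis.MII))
        with pytest.raises(ValueError):
            best_double_crossover(ll, (Hypothesis.MI, Hypothesis.MII))


class TestCallPloidy:
    def test_euploid_called_euploid(self):
        sc = Scenario(fetal_fraction=0.1, mean_depth=800, n_target_snps=300,
                      n_reference_snps=500, seed=0)
        ds = simulate_sample(sc)
        call = call_ploidy(ds, ff_from_snp(ds).ff)
        assert not call.is_aneuploid
        assert call.hypothesis == "D"

    def test_mii_trisomy_called(self, mii_trisomy_sample):
        ds = mii_trisomy_sample
        call = call_ploidy(ds, ff_from_snp(ds).ff)
        assert call.is_aneuploid
        assert call.hypothesis == "MII"
        assert call.n_crossovers == 0
        assert call.best_delta_l < 0

    def test_recombinant_trisomy_with_breakpoint(self):
        sc = Scenario(ploidy_hypothesis=Hypothesis.MI, crossover_breakpoints=(150,),
                      fetal_fraction=0.15, mean_depth=1000, n_target_snps=300,
                      n_reference_snps=300, seed=3)
        ds = simulate_sample(sc)
        call = call_ploidy(ds, ff_from_snp(ds).ff, candidates=TRISOMIES)
        assert call.is_aneuploid
        assert call.n_crossovers == 1
        # single-draw precision is limited by the spacing of informative
        # maternal-het/fetal-hom marker loci (~1 in 5 panel loci)
        assert abs(call.breakpoints[0] - 150) <= 5
        assert call.origin == "MI"

    def test_delta_table_reported_for_all_candidates(self, mii_trisomy_sample):
        ds = mii_trisomy_sample
        call = call_ploidy(ds, ff_from_snp(ds).ff)
        for h in ("MI", "MII", "PI", "PII", "LM", "LP"):
            assert h in call.delta_l


class TestMeioticPattern:
    def test_long_het_run_is_mi(self):
        res = classify_meiotic_pattern(["het"] * 25)
        assert res["origin"] == "MI"
        assert res["n_crossovers"] == 0

    def test_interspersed_hom_is_mii(self):
        pats = (["het", "het", "hom"] * 20)
        res = classify_meiotic_pattern(pats)
        assert res["origin"] == "MII"

    def test_het_block_then_hom_block_is_recombinant(self):
        rng = np.random.default_rng(0)
        tail = ["hom" if rng.random() < 0.5 else "het" for _ in range(40)]
        res = classify_meiotic_pattern(["het"] * 40 + tail)
        assert res["origin"] == "MI/MII recombinant"
        assert res["n_crossovers"] >= 1
        assert res["segments"][0][2] == "MI"

    def test_too_few_loci_undetermined(self):
        assert classify_meiotic_pattern(["het"] * 9)["origin"] == "undetermined"

    def test_false_mi_rate_of_run_rule(self):
        """Under MII each locus is heterozygous w.p. 1/2, so a 10-locus
        all-het run has probability 2**-10: the rule's analytic false-MI
        rate per window."""
        from cfdeconv.genetics import heterozygosity_probability

        p_het = heterozygosity_probability(Hypothesis.MII, 0.5)
        assert p_het**10 == pytest.approx(2.0**-10)

    def test_patterns_from_af_separate_hom_and_het(self):
        ff = 0.15
        from cfdeconv.ploidy import expected_af

        af = [expected_af(1, k, 3, ff) for k in range(4)]
        pats = locus_patterns_from_af(np.array(af), ff)
        assert pats == ["hom", "het", "het", "hom"]
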