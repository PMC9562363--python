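"""Monogenic-variant screen: beta-binomial CDF, ACD and FMID filters."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cfdeconv.simulate import simulate_snv_reads
from cfdeconv.snv import (
    VariantCandidate,
    acd_filter,
    betabinom_cdf,
    fmid_calibrate,
    fmid_test,
    screen_variants,
    write_vcf,
)


def _cdf_oracle(x, n, a, b):
    """Direct log-gamma summation, independent of scipy's pmf."""
    tot = 0.0
    for i in range(int(math.floor(x)) + 1):
        tot += math.exp(
            math.lgamma(n + 1) - math.lgamma(i + 1) - math.lgamma(n - i + 1)
            + math.lgamma(i + a) + math.lgamma(n - i + b) - math.lgamma(n + a + b)
            - (math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b))
        )
    return tot


class TestBetabinomCdf:
    def test_uniform_case(self):
        # BetaBinom(n=2, a=1, b=1) is uniform on {0,1,2}: F(1) = 2/3
        assert betabinom_cdf(1, 2, 1, 1) == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_upper_bound_exactly_one(self):
        assert betabinom_cdf(500, 500, 2.5, 7.1) == 1.0

    @pytest.mark.parametrize(
        "n,a,b", [(50, 2.0, 3.0), (200, 12.5, 240.0), (500, 0.4, 0.9), (500, 160.0, 2900.0)]
    )
    def test_matches_lgamma_summation_oracle(self, n, a, b):
        for x in (0, 1, n // 4, n // 2, n - 1):
            assert betabinom_cdf(x, n, a, b) == pytest.approx(
                _cdf_oracle(x, n, a, b), abs=1e-10
            )

    def test_monotone_in_x(self):
        vals = [betabinom_cdf(x, 100, 3.0, 17.0) for x in range(101)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            betabinom_cdf(1, 10, 0.0, 1.0)
        with pytest.raises(ValueError):
            betabinom_cdf(-1, 10, 1.0, 1.0)


class TestAcdFilter:
    # d_avg = d_v = 1000, m = 4000, f = 0.1: fetal-het expectation n*f/2 = 50
    CFG = dict(f=0.1, d_avg=1000.0, d_v=1000.0, m=4000.0)

    def test_count_at_fetal_expectation_passes(self):
        ok, stat = acd_filter(50, 1000, **self.CFG)
        assert ok and 0.001 <= stat <= 10

    def test_zero_count_fails_low(self):
        ok, stat = acd_filter(0, 1000, **self.CFG)
        assert not ok and stat > 10

    def test_full_count_fails_high(self):
        ok, stat = acd_filter(1000, 1000, **self.CFG)
        assert not ok and stat < 0.001

    def test_maternal_het_count_fails(self):
        # x ~ n/2 is far above the fetal expectation: CDF ~ 1
        ok, stat = acd_filter(500, 1000, **self.CFG)
        assert not ok and stat < 0.001

    def test_requires_ff(self):
        with pytest.raises(ValueError, match="fetal fraction"):
            acd_filter(10, 100, f=0.0, d_avg=1000.0)


class TestFmidCalibrate:
    def test_forced_nearest_removal(self):
        assert fmid_calibrate([150, 160, 170], [160]) == [150, 170]

    def test_tie_removes_larger(self):
        assert fmid_calibrate([150, 160], [155]) == [150]

    def test_survivor_count(self):
        rng = np.random.default_rng(0)
        ref = rng.integers(100, 400, size=500).tolist()
        alt = rng.integers(100, 400, size=100).tolist()
        surv = fmid_calibrate(ref, alt)
        assert len(surv) == 400

    def test_alt_exceeding_ref_warns_empty(self):
        with pytest.warns(UserWarning, match="survivor"):
            surv = fmid_calibrate([150, 160], [150, 155, 160])
        assert surv == []

    def test_matches_quadratic_greedy_oracle(self):
        rng = np.random.default_rng(1)
        ref = sorted(int(v) for v in rng.normal(166, 25, size=500))
        alt = sorted(int(v) for v in rng.normal(156, 25, size=100))
        got = fmid_calibrate(ref, alt)
        # O(n^2) oracle: same ascending alt order, nearest ref removed,
        # ties broken toward the larger value
        pool = [min(max(v, 20), 600) for v in ref]
        for a in sorted(min(max(v, 20), 600) for v in alt):
            best_i, best_key = None, None
            for i, r in enumerate(pool):
                key = (abs(r - a), -r)
                if best_key is None or key < best_key:
                    best_i, best_key = i, key
            pool.pop(best_i)
        assert got == sorted(pool)

    @given(
        st.lists(st.integers(20, 600), min_size=5, max_size=60),
        st.lists(st.integers(20, 600), min_size=1, max_size=4),
    )
    @settings(deadline=None, max_examples=50)
    def test_ref_order_invariance(self, ref, alt):
        rng = np.random.default_rng(0)
        shuffled = list(ref)
        rng.shuffle(shuffled)
        assert fmid_calibrate(ref, alt) == fmid_calibrate(shuffled, alt)


class TestFmidTest:
    def test_shifted_alt_detected(self):
        rng = np.random.default_rng(0)
        alt = rng.normal(156, 20, size=200).astype(int)
        ref = rng.normal(166, 20, size=200).astype(int)
        minp, shorter, verdict = fmid_test(ref, alt)
        assert minp <= 0.001 and shorter and verdict

    def test_null_controls_alpha(self):
        """Identical distributions: positive in <= 1% of seeded draws."""
        rng = np.random.default_rng(0)
        hits = 0
        n = 1000
        for _ in range(n):
            a = rng.normal(166, 20, size=60).astype(int)
            b = rng.normal(166, 20, size=60).astype(int)
            _, _, verdict = fmid_test(a, b)
            hits += verdict
        assert hits / n <= 0.01

    def test_longer_alt_median_negative(self):
        rng = np.random.default_rng(2)
        alt = rng.normal(180, 10, size=100).astype(int)
        ref = rng.normal(160, 10, size=100).astype(int)
        minp, shorter, verdict = fmid_test(ref, alt)
        assert minp <= 0.001 and not shorter and not verdict

    def test_identical_constants_minp_one(self):
        minp, _, verdict = fmid_test([150] * 20, [150] * 20)
        assert minp == 1.0 and not verdict

    def test_small_groups_not_evaluable(self):
        minp, _, verdict = fmid_test([150, 160, 170], [140, 150, 155])
        assert minp == 1.0 and not verdict


def _candidate(vid, reads, chrom="chr1", pos=100, in_repeat=False):
    alt = reads.loc[reads["allele"] == "alt", "insert_size"].tolist()
    ref = reads.loc[reads["allele"] == "ref", "insert_size"].tolist()
    return VariantCandidate(
        variant_id=vid, chrom=chrom, pos=pos, depth=len(reads),
        alt_count=len(alt), ref_insert_sizes=ref, alt_insert_sizes=alt,
        in_repeat=in_repeat,
    )


class TestScreenVariants:
    def test_repeat_masked_excluded_before_filters(self):
        reads = simulate_snv_reads("fetal", ff=0.1, depth=1000, seed=0)
        dec = screen_variants(
            [_candidate("v1", reads, in_repeat=True)], ff=0.1, d_avg=1000
        )[0]
        assert not dec.gates_passed and "repeat" in dec.gate_reason

    def test_outside_roi_excluded(self):
        reads = simulate_snv_reads("fetal", ff=0.1, depth=1000, seed=0)
        dec = screen_variants(
            [_candidate("v1", reads, chrom="chr2")], ff=0.1, d_avg=1000,
            roi=[("chr1", 0, 1000)],
        )[0]
        assert not dec.gates_passed and "ROI" in dec.gate_reason

    def test_simulated_fetal_variant_positive(self):
        reads = simulate_snv_reads("fetal", ff=0.1, depth=1000, seed=0)
        dec = screen_variants([_candidate("v1", reads)], ff=0.1, d_avg=1000)[0]
        assert dec.positive

    def test_maternal_het_site_filtered_out(self):
        reads = simulate_snv_reads("maternal-het", ff=0.1, depth=1000, seed=0)
        dec = screen_variants([_candidate("v1", reads)], ff=0.1, d_avg=1000)[0]
        assert not dec.acd_pass and not dec.fmid_pass and not dec.positive

    def test_type_one_control_on_maternal_variants(self):
        """<= 1% of maternal-only variants survive both filters."""
        hits, n = 0, 300
        for seed in range(n):
            reads = simulate_snv_reads("maternal-het", ff=0.1, depth=600, seed=seed)
            dec = screen_variants([_candidate("v", reads)], ff=0.1, d_avg=600)[0]
            hits += dec.positive
        assert hits / n <= 0.01

    def test_filters_raise_ppv_keep_sensitivity(self):
        """On a fetal/maternal/absent mixture the ACD+FMID union keeps
        sensitivity within 1% of no-filter while strictly improving PPV."""
        cands, truth = [], []
        k = 0
        for seed in range(120):
            origin = ("fetal", "maternal-het", "absent")[seed % 3]
            reads = simulate_snv_reads(
                origin, ff=0.1, depth=800, error_rate=0.002, seed=seed
            )
            if (reads["allele"] == "alt").sum() == 0:
                continue
            cands.append(_candidate(f"v{k}", reads))
            truth.append(origin == "fetal")
            k += 1
        decs = screen_variants(cands, ff=0.1, d_avg=800)
        pos = np.array([d.positive for d in decs])
        truth = np.array(truth)
        sens = pos[truth].mean()
        ppv = truth[pos].mean()
        ppv_nofilter = truth.mean()  # no filter calls everything positive
        assert sens >= 1.0 - 0.01
        assert ppv > ppv_nofilter

    def test_vcf_written(self, tmp_path):
        reads = simulate_snv_reads("fetal", ff=0.1, depth=1000, seed=0)
        cand = _candidate("v1", reads)
        decs = screen_variants([cand], ff=0.1, d_avg=1000)
        out = tmp_path / "out.vcf"
        write_vcf(decs, [cand], str(out))
        text = out.read_text()
        assert "##fileformat=VCFv4.2" in text
        assert "ACD_LOG10CDF=" in text
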