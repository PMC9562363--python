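"""De novo / paternally inherited fetal SNV screening from cfDNA.

Two filter-in tests examine each candidate variant after region gating:

* **ACD** (allele count distribution): the alt-read count x at depth n is
  scored with a beta-binomial CDF parameterized by the pre-PCR effective
  molecule counts, alpha = d_v*m*f/(2*d_avg) and beta = d_v*m*(2-f)/(2*d_avg)
  with f the fetal fraction.  A variant passes when the signed log10 CDF
  falls in [-10, -0.001]: counts too low for a fetal heterozygote push the
  CDF below 1e-10 (noise) and counts near or above the maternal
  heterozygote expectation push it toward 1 (|log10| < 0.001).

* **FMID** (fetal-maternal insert-size distribution): for each
  alt-supporting read the single nearest-sized ref-supporting read is
  removed (binary search, without replacement), leaving a ref set of
  putatively maternal fragments; the surviving ref and the alt insert
  sizes are then compared with Welch's t, Kolmogorov-Smirnov,
  Kruskal-Wallis, and Mann-Whitney tests.  The variant passes when the
  minimum of the four P-values is <= 0.001 and the alt median is shorter.

A candidate is reported positive when either filter passes -- the filters
exclude a variant only when every exclusion criterion is met.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import betabinom, kruskal, ks_2samp, mannwhitneyu, ttest_ind

__all__ = [
    "VariantCandidate",
    "ScreenDecision",
    "betabinom_cdf",
    "acd_filter",
    "fmid_calibrate",
    "fmid_test",
    "screen_variants",
    "write_vcf",
]

INSERT_BOUNDS = (20, 600)
ACD_WINDOW = (0.001, 10.0)     # bounds on |log10 CDF|
FMID_MINP = 0.001
DEFAULT_M = 4000.0             # effective pre-PCR molecule count (empirical)
MIN_GROUP = 5                  # minimum reads per group for the FMID tests


@dataclass
class VariantCandidate:
    variant_id: str
    chrom: str
    pos: int
    depth: int                      # n: total reads at the site
    alt_count: int                  # x: alt-supporting reads
    ref_insert_sizes: Sequence[int] = field(default_factory=list)
    alt_insert_sizes: Sequence[int] = field(default_factory=list)
    in_repeat: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.alt_count <= self.depth:
            raise ValueError("alt count outside 0..depth")

    @property
    def af(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0


@dataclass
class ScreenDecision:
    variant_id: str
    gates_passed: bool
    gate_reason: str = ""
    acd_pass: bool = False
    acd_log10_cdf: float = float("nan")
    fmid_pass: bool = False
    fmid_min_p: float = float("nan")
    ref_insert_median: float = float("nan")
    alt_insert_median: float = float("nan")
    positive: bool = False


def betabinom_cdf(x: float, n: int, alpha: float, beta: float) -> float:
    """Beta-binomial CDF F(x | n, alpha, beta) = P(X <= floor(x)).

    Summed in log space from the log pmf for stability at extreme
    parameters; monotone nondecreasing in x with F(n) = 1.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    if n < 0 or x < 0:
        raise ValueError("need n >= 0 and x >= 0")
    k = min(int(np.floor(x)), n)
    if k >= n:
        return 1.0
    i = np.arange(0, k + 1)
    return float(min(np.exp(logsumexp(betabinom.logpmf(i, n, alpha, beta))), 1.0))


def acd_filter(
    x: int,
    n: int,
    f: float,
    d_avg: float,
    d_v: Optional[float] = None,
    m: float = DEFAULT_M,
    window: Tuple[float, float] = ACD_WINDOW,
) -> Tuple[bool, float]:
    """Allele-count-distribution verdict for one variant.

    alpha = d_v*m*f/(2*d_avg), beta = d_v*m*(2-f)/(2*d_avg); passes when
    ``window[0] <= |log10 F(x)| <= window[1]``.  ``d_v`` defaults to the
    site depth ``n``.
    """
    if not 0.0 < f < 1.0:
        raise ValueError("fetal fraction required in (0,1) for the ACD filter")
    if d_avg <= 0 or m <= 0:
        raise ValueError("d_avg and m must be positive")
    d_v = float(n) if d_v is None else float(d_v)
    alpha = d_v * m * f / (2.0 * d_avg)
    beta = d_v * m * (2.0 - f) / (2.0 * d_avg)
    cdf = betabinom_cdf(x, n, alpha, beta)
    # guard log10(0): CDF below ~1e-300 is far outside the window anyway
    stat = float(abs(np.log10(max(cdf, 1e-300))))
    lo, hi = window
    return bool(lo <= stat <= hi), stat


def _clamp(sizes: Sequence[int]) -> List[int]:
    lo, hi = INSERT_BOUNDS
    return [min(max(int(s), lo), hi) for s in sizes]


def fmid_calibrate(
    ref_sizes: Sequence[int], alt_sizes: Sequence[int]
) -> List[int]:
    """Remove, for each alt insert size, the single nearest ref insert size.

    Alt sizes are processed in ascending order; each removes exactly one
    ref value by binary search without replacement.  Distance ties remove
    the larger ref value, biasing the survivor set short and making the
    shorter-alt test conservative.  Returns the surviving ref sizes
    (sorted); if there are at least as many alt as ref reads the survivor
    set is empty and FMID is not evaluable.
    """
    if len(ref_sizes) == 0 or len(alt_sizes) == 0:
        raise ValueError("both read groups must be nonempty")
    ref = sorted(_clamp(ref_sizes))
    alts = sorted(_clamp(alt_sizes))
    if len(alts) >= len(ref):
        warnings.warn("as many alt as ref reads: no maternal survivor set")
    for a in alts:
        if not ref:
            break
        j = bisect.bisect_left(ref, a)
        if j == 0:
            pick = 0
        elif j == len(ref):
            pick = len(ref) - 1
        else:
            lo, hi = ref[j - 1], ref[j]
            # tie -> remove the larger value
            pick = j if (hi - a) <= (a - lo) else j - 1
        ref.pop(pick)
    return ref


def _two_sample_pvalues(a: np.ndarray, b: np.ndarray) -> Dict[str, float]:
    """Welch t, KS, Kruskal-Wallis and Mann-Whitney P-values (ties corrected)."""
    out: Dict[str, float] = {}
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        # identical constants: no evidence of any difference
        return {k: 1.0 for k in ("welch_t", "ks", "kruskal", "mannwhitney")}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            out["welch_t"] = float(ttest_ind(a, b, equal_var=False).pvalue)
        except Exception:
            out["welch_t"] = 1.0
        try:
            out["ks"] = float(ks_2samp(a, b).pvalue)
        except Exception:
            out["ks"] = 1.0
        try:
            out["kruskal"] = float(kruskal(a, b).pvalue)
        except Exception:
            out["kruskal"] = 1.0
        try:
            out["mannwhitney"] = float(mannwhitneyu(a, b).pvalue)
        except Exception:
            out["mannwhitney"] = 1.0
    return {k: (1.0 if np.isnan(v) else v) for k, v in out.items()}


def fmid_test(
    surviving_ref: Sequence[int],
    alt_sizes: Sequence[int],
    min_p: float = FMID_MINP,
) -> Tuple[float, bool, bool]:
    """(MinP, median_shorter, verdict) for the calibrated insert-size test.

    Verdict is positive iff MinP <= ``min_p`` AND median(alt) < median(ref).
    Not evaluable (fail-safe negative, MinP = 1) when either group has
    fewer than 5 reads or when the survivors are outnumbered by the alt
    reads: calibration removes one ref read per alt read, so at allele
    fractions near 0.5 the few survivors are the extreme tails of the ref
    distribution, not a representative maternal sample.
    """
    ref = np.asarray(_clamp(surviving_ref), dtype=float)
    alt = np.asarray(_clamp(alt_sizes), dtype=float)
    if len(ref) < MIN_GROUP or len(alt) < MIN_GROUP or len(ref) < len(alt):
        return 1.0, False, False
    pvals = _two_sample_pvalues(alt, ref)
    minp = min(pvals.values())
    median_shorter = bool(np.median(alt) < np.median(ref))
    return float(minp), median_shorter, bool(minp <= min_p and median_shorter)


def _in_intervals(chrom: str, pos: int, intervals: Optional[Sequence[Tuple[str, int, int]]]) -> bool:
    if intervals is None:
        return False
    return any(c == chrom and s <= pos < e for c, s, e in intervals)


def screen_variants(
    candidates: Sequence[VariantCandidate],
    ff: float,
    d_avg: float,
    m: float = DEFAULT_M,
    roi: Optional[Sequence[Tuple[str, int, int]]] = None,
    repeat_mask: Optional[Sequence[Tuple[str, int, int]]] = None,
    min_depth: int = 200,
    min_af: float = 0.01,
) -> List[ScreenDecision]:
    """Screen candidates: region gates, then ACD OR FMID (filter-in union).

    A candidate is dropped when it lies in a repeat-masked region, falls
    outside the ROI (when one is given), or fails the usable-site gate
    (depth >= ``min_depth`` or AF >= ``min_af``).  Survivors are positive
    when either filter passes.
    """
    decisions: List[ScreenDecision] = []
    for v in candidates:
        dec = ScreenDecision(variant_id=v.variant_id, gates_passed=True)
        if v.in_repeat or _in_intervals(v.chrom, v.pos, repeat_mask):
            dec.gates_passed, dec.gate_reason = False, "repeat-masked region"
        elif roi is not None and not _in_intervals(v.chrom, v.pos, roi):
            dec.gates_passed, dec.gate_reason = False, "outside ROI"
        elif not (v.depth >= min_depth or v.af >= min_af):
            dec.gates_passed, dec.gate_reason = False, "below depth/AF gate"
        if not dec.gates_passed:
            decisions.append(dec)
            continue

        dec.acd_pass, dec.acd_log10_cdf = acd_filter(
            v.alt_count, v.depth, ff, d_avg, d_v=v.depth, m=m
        )
        if len(v.ref_insert_sizes) and len(v.alt_insert_sizes):
            surv = fmid_calibrate(v.ref_insert_sizes, v.alt_insert_sizes)
            dec.fmid_min_p, _, dec.fmid_pass = fmid_test(surv, v.alt_insert_sizes)
            if surv:
                dec.ref_insert_median = float(np.median(_clamp(surv)))
            dec.alt_insert_median = float(np.median(_clamp(v.alt_insert_sizes)))
        dec.positive = dec.acd_pass or dec.fmid_pass
        decisions.append(dec)
    return decisions


def write_vcf(
    decisions: Sequence[ScreenDecision],
    candidates: Sequence[VariantCandidate],
    path: str,
) -> None:
    """Minimal VCF 4.2 with the per-variant screening evidence as INFO keys."""
    by_id = {c.variant_id: c for c in candidates}
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=ACD_LOG10CDF,Number=1,Type=Float,Description="ACD |log10 CDF|">',
        '##INFO=<ID=FMID_MINP,Number=1,Type=Float,Description="FMID minimum P-value">',
        '##INFO=<ID=REF_INS_MED,Number=1,Type=Float,Description="median ref insert">',
        '##INFO=<ID=ALT_INS_MED,Number=1,Type=Float,Description="median alt insert">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for d in decisions:
        c = by_id[d.variant_id]
        if not d.gates_passed:
            filt = "GATE"
        else:
            filt = "PASS" if d.positive else "FILTERED"
        info = (
            f"ACD_LOG10CDF={d.acd_log10_cdf:.4g};FMID_MINP={d.fmid_min_p:.4g};"
            f"REF_INS_MED={d.ref_insert_median:.4g};ALT_INS_MED={d.alt_insert_median:.4g}"
        )
        lines.append(f"{c.chrom}\t{c.pos}\t{c.variant_id}\tN\tN\t.\t{filt}\t{info}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
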