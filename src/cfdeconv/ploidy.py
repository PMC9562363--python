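"""Beta-binomial ploidy likelihoods, recombination search, and origin calls.

Per locus, the A-allele read count NA is modeled as a mixture of
beta-binomial distributions over the fetal genotypes compatible with a
ploidy hypothesis H.  The concentration is anchored by a fixed alpha (3000
by default) with beta = alpha/pA - alpha, so the mixture component mean is
the expected mixture allele fraction pA for that maternal/fetal genotype
combination at the sample's fetal fraction.  Mixture weights pi_k come from
the meiotic transmission model with the paternal genotype marginalized
under Hardy-Weinberg priors.

Chromosome-level evidence is the summed log-likelihood difference

    deltaL(H) = sum_i [log L(D_i) - log L(H_i)]

(negative favors the aneuploidy H).  Meiotic recombination is modeled as a
switch between the two nondisjunction sub-states of the same parent (MI/MII
or PI/PII); the one- and two-breakpoint searches minimize the segmented sum
with prefix sums in O(M) / O(M) time (brute force kept as a test oracle).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .fetal_fraction import GenotypeThresholds, classify_maternal_genotypes
from .genetics import Hypothesis, PARENTAL_PAIRS, COPY_NUMBER
from .simulate import SampleDataset

__all__ = [
    "PloidyCall",
    "hampel_filter",
    "loglik_table",
    "locus_loglik",
    "delta_loglik",
    "best_single_crossover",
    "best_double_crossover",
    "call_ploidy",
    "classify_meiotic_pattern",
    "locus_patterns_from_af",
]

_EPS_P = 1e-6
DEFAULT_ALPHA = 3000.0
#: minimum informative loci per recombinant segment (matches the 10-locus
#: run rule used for MI/MII pattern classification)
MIN_SEGMENT = 10
#: a recombinant composite must beat the best pure hypothesis by a margin
#: before it is reported.  The minimized composite deltaL is a scan
#: statistic -- the optimum over ~2M (one breakpoint) / ~M^2 (two
#: breakpoints) segmentations -- so under a pure hypothesis it improves on
#: the pure fit by selection alone.  The defaults are the 99th percentile
#: of that null improvement, calibrated by euploid simulation at the
#: design panel scale (M ~ 500 loci at the fetal-fraction x depth QC
#: floor); a true crossover segment of more than a few dozen loci clears
#: them by a wide margin.  ``complexity_margin`` (per breakpoint)
#: overrides both when given.
SINGLE_SCAN_MARGIN = 17.0
DOUBLE_SCAN_MARGIN = 23.0
COMPLEXITY_MARGIN: Optional[float] = None
#: the winning aneuploid deltaL must clear this margin below zero (about
#: 20:1 odds against disomy) before a call is made; guards the union
#: decision against near-tie degeneracies such as LM vs D at low FF
DECISION_MARGIN = 3.0

_GT_ALT = {"BB": 0, "AB": 1, "AA": 2}


@dataclass
class PloidyCall:
    chromosome: str
    hypothesis: str                      # "D", "MII", "MI+MII", ...
    is_aneuploid: bool
    delta_l: Dict[str, float] = field(default_factory=dict)
    best_delta_l: float = 0.0
    origin: str = "none"
    n_crossovers: int = 0
    breakpoints: Tuple[int, ...] = ()
    n_loci: int = 0


# ---------------------------------------------------------------------------
# Hampel filter


def hampel_filter(
    values: np.ndarray,
    window: int = 11,
    nsigma: float = 3.0,
    scale: str = "mad",
    mad_floor: float = 1e-4,
) -> np.ndarray:
    """Keep-mask flagging points > nsigma robust SDs from the rolling median.

    ``scale='mad'`` uses 1.4826 x rolling MAD (floored at ``mad_floor``);
    ``scale='std'`` uses the rolling standard deviation around the rolling
    mean, for depth series where the classical variant is wanted.  Series
    shorter than the window are returned unfiltered with a warning.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < window:
        warnings.warn("series shorter than Hampel window; not filtered")
        return np.ones(n, dtype=bool)
    s = pd.Series(x)
    if scale == "mad":
        med = s.rolling(window, center=True, min_periods=1).median().to_numpy()
        mad = (
            (s - pd.Series(med))
            .abs()
            .rolling(window, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
        sigma = np.maximum(1.4826 * mad, mad_floor)
        center = med
    elif scale == "std":
        center = s.rolling(window, center=True, min_periods=1).mean().to_numpy()
        sigma = s.rolling(window, center=True, min_periods=1).std().fillna(0.0).to_numpy()
        sigma = np.maximum(sigma, mad_floor)
    else:
        raise ValueError("scale must be 'mad' or 'std'")
    return np.abs(x - center) <= nsigma * sigma


# ---------------------------------------------------------------------------
# likelihoods


def _maternal_gamete(g_alt: int, h: Hypothesis) -> List[Tuple[int, float]]:
    pa = g_alt / 2.0
    if h in (Hypothesis.MI,):
        return [(g_alt, 1.0)]
    if h in (Hypothesis.MII,):
        return [(c, w) for c, w in ((2, pa), (0, 1.0 - pa)) if w > 0]
    if h is Hypothesis.LM:
        return [(0, 1.0)]
    return [(c, w) for c, w in ((1, pa), (0, 1.0 - pa)) if w > 0]


def _paternal_gamete(h: Hypothesis, p: np.ndarray) -> List[Tuple[int, np.ndarray]]:
    """Paternal gamete A-count distribution with HWE-marginalized genotype."""
    if h is Hypothesis.PI:
        return [(2, p * p), (1, 2.0 * p * (1.0 - p)), (0, (1.0 - p) ** 2)]
    if h is Hypothesis.PII:
        return [(2, p), (0, 1.0 - p)]
    if h is Hypothesis.LP:
        return [(0, np.ones_like(p))]
    return [(1, p), (0, 1.0 - p)]


def _mixture_components(
    mat_alt: int, h: Hypothesis, p: np.ndarray
) -> List[Tuple[int, np.ndarray]]:
    """Fetal A-count mixture: list of (fetal n_alt, weight array over loci)."""
    comp: Dict[int, np.ndarray] = {}
    for mc, mw in _maternal_gamete(mat_alt, h):
        for pc, pw in _paternal_gamete(h, p):
            k = mc + pc
            w = mw * pw
            comp[k] = comp.get(k, 0.0) + w
    return sorted(comp.items())


def expected_af(mat_alt: int, fet_alt: int, fet_copies: int, ff: float) -> float:
    num = (1.0 - ff) * mat_alt + ff * fet_alt
    den = 2.0 * (1.0 - ff) + ff * fet_copies
    return num / den


def _betabinom_logpmf(
    i: np.ndarray, n: np.ndarray, a: float, b: float
) -> np.ndarray:
    """Beta-binomial log pmf via the rising-factorial product form.

    log pmf = log C(n,i) + sum_{j<i} log(a+j) + sum_{j<n-i} log(b+j)
              - sum_{j<n} log(a+b+j).

    Unlike the log-gamma difference form this stays accurate when one
    shape parameter is extreme (the clamped homozygous mixture components
    have b ~ a/eps), because each term is computed directly rather than as
    a difference of two huge gammaln values.
    """
    i = np.asarray(i, dtype=int)
    n = np.asarray(n, dtype=int)
    nmax = int(n.max()) if n.size else 0
    j = np.arange(nmax, dtype=float)
    cum_a = np.concatenate([[0.0], np.cumsum(np.log(a + j))])
    cum_b = np.concatenate([[0.0], np.cumsum(np.log(b + j))])
    cum_ab = np.concatenate([[0.0], np.cumsum(np.log(a + b + j))])
    log_c = gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
    return log_c + cum_a[i] + cum_b[n - i] - cum_ab[n]


def loglik_table(
    df: pd.DataFrame,
    ff: float,
    alpha: float = DEFAULT_ALPHA,
    hypotheses: Sequence[Hypothesis] = tuple(Hypothesis),
) -> pd.DataFrame:
    """Per-locus log-likelihood under each hypothesis.

    ``df`` needs columns n_alt, depth, p and maternal_gt in {AA, AB, BB}
    (see :func:`cfdeconv.fetal_fraction.classify_maternal_genotypes`).
    Returns a DataFrame indexed like ``df`` with one column per hypothesis.
    """
    if not 0.0 < ff < 1.0:
        raise ValueError("ff must be in (0,1)")
    n_alt = df["n_alt"].to_numpy()
    depth = df["depth"].to_numpy()
    p = df["p"].to_numpy(dtype=float)
    mat = df["maternal_gt"].to_numpy()
    out = pd.DataFrame(index=df.index, dtype=float)
    for h in hypotheses:
        col = np.full(len(df), np.nan)
        c = COPY_NUMBER[h]
        for gt, g_alt in _GT_ALT.items():
            idx = np.flatnonzero(mat == gt)
            if len(idx) == 0:
                continue
            comps = _mixture_components(g_alt, h, p[idx])
            terms = []
            for k, w in comps:
                pa = expected_af(g_alt, k, c, ff)
                pa = min(max(pa, _EPS_P), 1.0 - _EPS_P)
                beta = alpha / pa - alpha
                lp = _betabinom_logpmf(n_alt[idx], depth[idx], alpha, beta)
                logw = np.log(np.clip(np.broadcast_to(w, lp.shape), 1e-300, None))
                terms.append(logw + lp)
            col[idx] = logsumexp(np.vstack(terms), axis=0)
        out[h.value] = col
    return out


def locus_loglik(
    n_alt: int,
    depth: int,
    p: float,
    maternal_gt: str,
    ff: float,
    h: Hypothesis,
    alpha: float = DEFAULT_ALPHA,
) -> float:
    """Scalar convenience wrapper around :func:`loglik_table`."""
    df = pd.DataFrame(
        {"n_alt": [n_alt], "depth": [depth], "p": [p], "maternal_gt": [maternal_gt]}
    )
    return float(loglik_table(df, ff, alpha, (h,)).iloc[0, 0])


# ---------------------------------------------------------------------------
# chromosome-level aggregation and crossover search


def delta_loglik(ll: pd.DataFrame, h: Hypothesis) -> float:
    """deltaL = sum_i [log L(D_i) - log L(H_i)]; negative favors H."""
    if len(ll) == 0:
        raise ValueError("no informative loci")
    return float((ll[Hypothesis.D.value] - ll[h.value]).sum())


def _diff_arrays(ll: pd.DataFrame, pair: Tuple[Hypothesis, Hypothesis]):
    d = ll[Hypothesis.D.value].to_numpy()
    return d - ll[pair[0].value].to_numpy(), d - ll[pair[1].value].to_numpy()


def best_single_crossover(
    ll: pd.DataFrame,
    pair: Tuple[Hypothesis, Hypothesis],
    min_segment: int = MIN_SEGMENT,
) -> Tuple[int, Tuple[Hypothesis, Hypothesis], float]:
    """Minimize sum_{1..k}(logLD - logLH1) + sum_{k+1..M}(logLD - logLH2).

    Returns (k, (leading, trailing), deltaL) where the first k loci follow
    the leading hypothesis.  Both segments must contain at least
    ``min_segment`` loci.  O(M) via prefix sums.
    """
    m = len(ll)
    if m < 2:
        raise ValueError("need at least 2 loci")
    ms = max(1, min(min_segment, m // 2))
    d1, d2 = _diff_arrays(ll, pair)
    p1 = np.concatenate([[0.0], np.cumsum(d1)])
    p2 = np.concatenate([[0.0], np.cumsum(d2)])
    s1, s2 = p1[-1], p2[-1]
    best = (None, None, np.inf)
    ks = np.arange(ms, m - ms + 1)
    if len(ks) == 0:
        ks = np.array([m // 2])
    tot12 = p1[ks] + (s2 - p2[ks])  # pair[0] leads
    tot21 = p2[ks] + (s1 - p1[ks])  # pair[1] leads
    i12, i21 = int(np.argmin(tot12)), int(np.argmin(tot21))
    if tot12[i12] <= tot21[i21]:
        best = (int(ks[i12]), (pair[0], pair[1]), float(tot12[i12]))
    else:
        best = (int(ks[i21]), (pair[1], pair[0]), float(tot21[i21]))
    return best


def best_double_crossover(
    ll: pd.DataFrame,
    pair: Tuple[Hypothesis, Hypothesis],
    min_segment: int = MIN_SEGMENT,
) -> Tuple[Tuple[int, int], Tuple[Hypothesis, Hypothesis], float]:
    """Minimize the three-segment (H1 | H2 | H1) sum over b1 < b2.

    Returns ((b1, b2), (outer, inner), deltaL); segments are loci 1..b1,
    b1+1..b2, b2+1..M and must each hold ``min_segment`` loci.  O(M) with a
    running minimum over the prefix-sum differences.
    """
    m = len(ll)
    if m < 3:
        raise ValueError("need at least 3 loci")
    ms = max(1, min(min_segment, m // 3))
    d1, d2 = _diff_arrays(ll, pair)
    best: Tuple[Tuple[int, int], Tuple[Hypothesis, Hypothesis], float] = (
        (0, 0),
        pair,
        np.inf,
    )
    for outer, inner, do, di in ((pair[0], pair[1], d1, d2), (pair[1], pair[0], d2, d1)):
        po = np.concatenate([[0.0], np.cumsum(do)])
        pi = np.concatenate([[0.0], np.cumsum(di)])
        so = po[-1]
        # total(b1,b2) = so + (pi-po)[b2] - (pi-po)[b1]:
        # minimized by the running maximum of g[b1] for each b2
        g = pi - po
        run_max, run_arg = -np.inf, -1
        for b2 in range(2 * ms, m - ms + 1):
            b1 = b2 - ms
            if g[b1] > run_max:
                run_max, run_arg = g[b1], b1
            tot = so + g[b2] - run_max
            if tot < best[2]:
                best = ((run_arg, b2), (outer, inner), float(tot))
    return best


def prepare_chromosome(
    sample: SampleDataset | pd.DataFrame,
    chrom: str,
    thresholds: GenotypeThresholds = GenotypeThresholds(),
    hampel_window: int = 11,
    af_mad_floor: float = 0.05,
) -> pd.DataFrame:
    """Classify maternal genotypes on one chromosome and Hampel-filter AFs.

    The outlier filter runs within each maternal genotype class.  Its MAD
    floor must exceed the legitimate fetal-allele excursion (up to ~FF/2 on
    the homozygous side, where most loci sit at AF ~ 0 and the raw MAD
    collapses), so only gross assay outliers are removed; 0.05 keeps fetal
    signal for FF well above typical clinical levels.
    """
    snp = sample.snp if isinstance(sample, SampleDataset) else sample
    sub = snp[snp["chrom"] == chrom].reset_index(drop=True)
    sub["locus_index"] = np.arange(len(sub))
    cls = classify_maternal_genotypes(sub, thresholds)
    cls = cls[cls["maternal_gt"] != "NA"].reset_index(drop=True)
    if len(cls) == 0:
        return cls
    keep = np.ones(len(cls), dtype=bool)
    for gt in ("AA", "AB", "BB"):
        idx = np.flatnonzero((cls["maternal_gt"] == gt).to_numpy())
        if len(idx) >= hampel_window:
            keep[idx] = hampel_filter(
                cls["af"].to_numpy()[idx], window=hampel_window,
                mad_floor=af_mad_floor,
            )
    return cls[keep].reset_index(drop=True)


def call_ploidy(
    sample: SampleDataset | pd.DataFrame,
    ff: float,
    chrom: str = "chr21",
    alpha: float = DEFAULT_ALPHA,
    min_segment: int = MIN_SEGMENT,
    complexity_margin: Optional[float] = COMPLEXITY_MARGIN,
    decision_margin: float = DECISION_MARGIN,
    thresholds: GenotypeThresholds = GenotypeThresholds(),
    candidates: Optional[Sequence[Hypothesis]] = None,
) -> PloidyCall:
    """Maximum-likelihood fetal ploidy call for one chromosome.

    Evaluates deltaL for every pure hypothesis and for one- and
    two-breakpoint recombinant composites within each parental pair.  The
    winner is the most negative deltaL; if none is negative the chromosome
    is called euploid.  A recombinant composite is only reported when it
    beats the best pure hypothesis by ``complexity_margin`` log-units and
    every segment holds at least ``min_segment`` loci.

    ``candidates`` restricts the hypothesis space (default: all six
    aneuploid states).  Restricting to the four trisomies is the intended
    mode for meiotic-origin classification once a dosage gain has been
    established from read depth, where the monosomy states are off the
    table; at a maternal heterozygous locus the allele-fraction mixtures of
    a trisomy and the same-parent monosomy are almost indistinguishable.
    """
    loci = prepare_chromosome(sample, chrom, thresholds)
    if len(loci) == 0:
        raise ValueError(f"no usable loci on {chrom}")
    ll = loglik_table(loci, ff, alpha)
    m = len(ll)

    if candidates is None:
        candidates_h = [h for h in Hypothesis if h is not Hypothesis.D]
    else:
        candidates_h = [h for h in candidates if h is not Hypothesis.D]
    pure: Dict[str, float] = {h.value: delta_loglik(ll, h) for h in candidates_h}
    best_pure = min(pure, key=pure.get)

    cand_table: Dict[str, Tuple[float, int, Tuple[int, ...], str]] = {
        hv: (dl, 0, (), hv) for hv, dl in pure.items()
    }
    pairs = [
        pair for pair in PARENTAL_PAIRS
        if pair[0] in candidates_h and pair[1] in candidates_h
    ]
    if m >= 2 * min_segment:
        for pair in pairs:
            k, (lead, trail), dl = best_single_crossover(ll, pair, min_segment)
            name = f"{lead.value}+{trail.value}"
            cand_table[name] = (dl, 1, (k,), lead.value)
    if m >= 3 * min_segment:
        for pair in pairs:
            (b1, b2), (outer, inner), dl = best_double_crossover(ll, pair, min_segment)
            name = f"{outer.value}+{inner.value}+{outer.value}"
            cand_table[name] = (dl, 2, (b1, b2), outer.value)

    # recombinants must beat the best pure hypothesis by the margin
    def _margin(n_breakpoints: int) -> float:
        if complexity_margin is not None:
            return complexity_margin * n_breakpoints
        return SINGLE_SCAN_MARGIN if n_breakpoints == 1 else DOUBLE_SCAN_MARGIN

    admissible = {
        name: v
        for name, v in cand_table.items()
        if v[1] == 0 or v[0] <= pure[best_pure] - _margin(v[1])
    }
    winner = min(admissible, key=lambda k: admissible[k][0])
    dl, ncx, bps, lead = admissible[winner]
    # report breakpoints as original per-chromosome locus indices
    if bps and "locus_index" in loci.columns:
        li = loci["locus_index"].to_numpy()
        bps = tuple(int(li[min(b, len(li) - 1)]) for b in bps)

    delta_all = {name: v[0] for name, v in cand_table.items()}
    if dl > -decision_margin:
        return PloidyCall(
            chromosome=chrom,
            hypothesis="D",
            is_aneuploid=False,
            delta_l=delta_all,
            best_delta_l=min(delta_all.values()),
            origin="none",
            n_loci=m,
        )
    return PloidyCall(
        chromosome=chrom,
        hypothesis=winner,
        is_aneuploid=True,
        delta_l=delta_all,
        best_delta_l=dl,
        origin=lead,
        n_crossovers=ncx,
        breakpoints=bps,
        n_loci=m,
    )


# ---------------------------------------------------------------------------
# meiotic-origin pattern classification


def locus_patterns_from_af(
    af: np.ndarray, ff: float, maternal_gt: str = "AB"
) -> List[str]:
    """Classify maternal-het trisomy loci as fetal 'het' or 'hom' by nearest
    expected allele fraction among fetal A-dosages 0..3."""
    if maternal_gt != "AB":
        raise ValueError("pattern classification uses maternal heterozygous loci")
    exp = np.array([expected_af(1, k, 3, ff) for k in range(4)])
    assign = np.argmin(np.abs(np.asarray(af)[:, None] - exp[None, :]), axis=1)
    return ["hom" if k in (0, 3) else "het" for k in assign]


def classify_meiotic_pattern(
    patterns: Sequence[str], min_run: int = 10
) -> Dict[str, object]:
    """Segment maternal-het locus patterns into MI / MII origin stretches.

    Runs of at least ``min_run`` consecutive fetal-heterozygous loci mark an
    MI segment (under MII the chance of such a run is 0.5**min_run); regions
    containing fetal-homozygous loci mark MII.  Segment transitions are
    crossovers.  Fewer than ``min_run`` informative loci -> undetermined.
    """
    pats = [p if p in ("het", "hom") else "het" for p in patterns]
    n = len(pats)
    if n < min_run:
        return {"origin": "undetermined", "segments": [], "n_crossovers": 0}
    labels = ["MII"] * n
    run_start = None
    for i in range(n + 1):
        if i < n and pats[i] == "het":
            if run_start is None:
                run_start = i
        else:
            if run_start is not None and i - run_start >= min_run:
                for j in range(run_start, i):
                    labels[j] = "MI"
            run_start = None
    segments: List[Tuple[int, int, str]] = []
    start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start]:
            segments.append((start, i - 1, labels[start]))
            start = i
    kinds = {s[2] for s in segments}
    if kinds == {"MI"}:
        origin = "MI"
    elif kinds == {"MII"}:
        origin = "MII"
    else:
        origin = "MI/MII recombinant"
    return {
        "origin": origin,
        "segments": segments,
        "n_crossovers": len(segments) - 1,
    }
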