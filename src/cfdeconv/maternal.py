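"""Maternal confounder detection: germline CNV, absence of heterozygosity
(AOH), and dizygotic-twin / non-maternity signals.

These screens run before any fetal calling because each confounder mimics
or masks a fetal chromosomal signal: a maternal duplication inflates read
depth like a fetal trisomy, maternal AOH removes the heterozygous loci the
allele-fraction caller needs, and a dizygotic co-twin adds a second fetal
genome whose extra SNPs and dispersed implied fetal fractions violate the
singleton mixture model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import MeanShift

from .fetal_fraction import FFEstimate, GenotypeThresholds, classify_maternal_genotypes
from .simulate import SampleDataset

__all__ = [
    "MaternalFinding",
    "detect_maternal_cnv",
    "detect_aoh",
    "detect_dizygotic_twin",
    "maternal_screen",
]

AOH_MIN_RUN = 75
CNV_Z_CUTOFF = 3.0
#: maternal mosaic CNV below this cell fraction is treated as beyond the
#: depth Z-score detection limit and never called
MOSAIC_DETECTION_LIMIT = 0.6
#: flag thresholds for the dizygotic-twin screen.  With a shared father
#: the co-twin's gamete is correlated with the proband's, so the
#: fetal-SNP count rises by at most ~1.3x over the singleton expectation
#: (p=0.5 locus: 1-(1/2)^2 = 3/4 detection via a heterozygous father vs
#: 1/2 for a singleton); singletons concentrate tightly at ratio 1.0, so
#: the flag threshold sits between the two populations.  Both signals
#: must fire.
TWIN_EXCESS_RATIO = 1.15
TWIN_FF_CV = 0.28
TWIN_MIN_FF = 0.02


@dataclass
class MaternalFinding:
    kind: str                      # CNV-gain | CNV-loss | AOH | twin
    chrom: str = ""
    start_locus: int = 0
    end_locus: int = 0             # inclusive
    span_bp: int = 0
    evidence: Dict[str, float] = field(default_factory=dict)

    def overlaps(self, other: "MaternalFinding") -> bool:
        return (
            self.chrom == other.chrom
            and self.start_locus <= other.end_locus
            and other.start_locus <= self.end_locus
        )


# ---------------------------------------------------------------------------
# maternal CNV


def _het_af_consistent(kind: str, het_afs: np.ndarray, rule: str) -> bool:
    """AF consistency for a candidate CNV segment.

    ``rule='as-printed'`` applies the published windows verbatim (deletion:
    heterozygous AF > 0.6 or < 0.4; duplication: AF between 0.4 and 0.6);
    ``rule='dosage'`` applies the allelic-dosage expectation instead
    (deletion pushes het AF to 0/1, duplication toward 1/3 or 2/3).  The
    call is rejected on any conflicting heterozygous locus.
    """
    if len(het_afs) == 0:
        return True  # nothing to conflict with
    if rule == "as-printed":
        if kind == "CNV-loss":
            ok = (het_afs > 0.6) | (het_afs < 0.4)
        else:
            ok = (het_afs >= 0.4) & (het_afs <= 0.6)
    elif rule == "dosage":
        if kind == "CNV-loss":
            ok = (het_afs > 0.75) | (het_afs < 0.25)
        else:
            ok = ((het_afs > 0.25) & (het_afs < 0.45)) | (
                (het_afs > 0.55) & (het_afs < 0.75)
            )
    else:
        raise ValueError("rule must be 'as-printed' or 'dosage'")
    return bool(np.all(ok))


def detect_maternal_cnv(
    zscores: np.ndarray,
    afs: np.ndarray,
    maternal_gt: Sequence[str],
    chrom: str = "",
    positions: Optional[np.ndarray] = None,
    bandwidth: float = 1.0,
    smooth_window: int = 25,
    z_cutoff: float = CNV_Z_CUTOFF,
    af_rule: str = "as-printed",
    min_loci: int = 5,
) -> List[MaternalFinding]:
    """Mean-shift segmentation of per-locus depth Z-scores into CNV calls.

    Z-scores are smoothed with a rolling mean, clustered with a mean-shift
    (bandwidth in Z units), and consecutive-locus runs of one cluster whose
    center exceeds +-``z_cutoff`` become CNV candidates; each candidate is
    then checked against the heterozygous allele fractions inside the
    segment and rejected on any conflict.
    """
    z = np.asarray(zscores, dtype=float)
    af = np.asarray(afs, dtype=float)
    gt = np.asarray(maternal_gt, dtype=object)
    n = len(z)
    if n == 0:
        return []
    smooth = pd.Series(z).rolling(smooth_window, center=True, min_periods=1).mean().to_numpy()
    ms = MeanShift(bandwidth=bandwidth, bin_seeding=False)
    labels = ms.fit_predict(smooth.reshape(-1, 1))
    centers = ms.cluster_centers_.ravel()

    findings: List[MaternalFinding] = []
    start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start]:
            center = centers[labels[start]]
            length = i - start
            if abs(center) > z_cutoff and length >= min_loci:
                kind = "CNV-gain" if center > 0 else "CNV-loss"
                seg = slice(start, i)
                het = af[seg][gt[seg] == "AB"]
                if _het_af_consistent(kind, het, af_rule):
                    span = 0
                    if positions is not None:
                        span = int(positions[i - 1] - positions[start])
                    findings.append(
                        MaternalFinding(
                            kind=kind,
                            chrom=chrom,
                            start_locus=start,
                            end_locus=i - 1,
                            span_bp=span,
                            evidence={"z_center": float(center), "n_loci": length},
                        )
                    )
            start = i
    return _merge_adjacent(findings, positions)


def _merge_adjacent(
    findings: List[MaternalFinding], positions: Optional[np.ndarray]
) -> List[MaternalFinding]:
    """Merge touching same-kind segments (mean-shift may split one CNV
    into adjacent clusters along its smoothed Z ramp)."""
    merged: List[MaternalFinding] = []
    for f in findings:
        if (
            merged
            and merged[-1].kind == f.kind
            and f.start_locus <= merged[-1].end_locus + 1
        ):
            prev = merged[-1]
            n = prev.evidence["n_loci"] + f.evidence["n_loci"]
            zc = (
                prev.evidence["z_center"] * prev.evidence["n_loci"]
                + f.evidence["z_center"] * f.evidence["n_loci"]
            ) / n
            span = prev.span_bp
            if positions is not None:
                span = int(positions[f.end_locus] - positions[prev.start_locus])
            merged[-1] = MaternalFinding(
                kind=prev.kind,
                chrom=prev.chrom,
                start_locus=prev.start_locus,
                end_locus=f.end_locus,
                span_bp=span,
                evidence={"z_center": zc, "n_loci": n},
            )
        else:
            merged.append(f)
    return merged


# ---------------------------------------------------------------------------
# maternal AOH


def detect_aoh(
    maternal_gt: Sequence[str],
    chrom: str = "",
    positions: Optional[np.ndarray] = None,
    min_run: int = AOH_MIN_RUN,
) -> List[MaternalFinding]:
    """Maximal runs of >= ``min_run`` consecutive maternal homozygous loci.

    A run resets at any locus that is not homozygous (heterozygous or
    unclassified).
    """
    gt = list(maternal_gt)
    findings: List[MaternalFinding] = []
    run_start: Optional[int] = None
    for i in range(len(gt) + 1):
        hom = i < len(gt) and gt[i] in ("AA", "BB")
        if hom:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None and i - run_start >= min_run:
                span = 0
                if positions is not None:
                    span = int(positions[i - 1] - positions[run_start])
                findings.append(
                    MaternalFinding(
                        kind="AOH",
                        chrom=chrom,
                        start_locus=run_start,
                        end_locus=i - 1,
                        span_bp=span,
                        evidence={"n_consecutive_hom": i - run_start},
                    )
                )
            run_start = None
    return findings


# ---------------------------------------------------------------------------
# dizygotic twin / non-maternity


def detect_dizygotic_twin(
    sample: SampleDataset | pd.DataFrame,
    ff_estimate: FFEstimate | float,
    thresholds: GenotypeThresholds = GenotypeThresholds(),
    excess_ratio: float = TWIN_EXCESS_RATIO,
    cv_threshold: float = TWIN_FF_CV,
    min_loci: int = 50,
) -> Optional[MaternalFinding]:
    """Flag a dizygotic twin (or non-maternity) from two AF signals.

    (a) the fraction of maternal homozygous loci showing a fetal allele,
    compared with the singleton expectation derived from the panel's
    population allele frequencies (a second fetal genome raises it toward
    1-(1-q)^2 per locus), and (b) the coefficient of variation of the
    implied per-locus fetal fraction (two fetuses at different FFs spread
    it).  Both must exceed their thresholds.  Returns None when not
    flagged; FF below 0.02 is an undetermined regime (kind
    ``undetermined``).
    """
    ff = ff_estimate.ff if isinstance(ff_estimate, FFEstimate) else float(ff_estimate)
    snp = sample.snp if isinstance(sample, SampleDataset) else sample
    snp = snp[~snp["chrom"].isin(("chrX", "chrY"))]
    if ff < TWIN_MIN_FF:
        return MaternalFinding(kind="undetermined", evidence={"ff": ff})
    cls = classify_maternal_genotypes(snp, thresholds)
    hom = cls[cls["maternal_gt"].isin(("AA", "BB"))]
    if len(hom) < min_loci:
        return MaternalFinding(kind="undetermined", evidence={"n_hom": len(hom)})
    minor = np.where(hom["maternal_gt"] == "AA", 1.0 - hom["af"], hom["af"])
    detected = minor >= thresholds.fetal_window[0]
    observed_frac = float(np.mean(detected))
    # singleton expectation: paternal transmitted allele differs from the
    # maternal homozygous allele
    p = hom["p"].to_numpy(dtype=float)
    q = np.where(hom["maternal_gt"] == "AA", 1.0 - p, p)
    expected_frac = float(np.mean(q))
    ratio = observed_frac / expected_frac if expected_frac > 0 else np.inf
    implied_ff = 2.0 * minor[detected]
    cv = float(np.std(implied_ff) / np.mean(implied_ff)) if detected.sum() >= 2 else 0.0
    evidence = {
        "fetal_snp_fraction": observed_frac,
        "singleton_expectation": expected_frac,
        "excess_ratio": ratio,
        "implied_ff_cv": cv,
    }
    if ratio >= excess_ratio and cv >= cv_threshold:
        return MaternalFinding(kind="twin", evidence=evidence)
    return None


def maternal_screen(
    sample: SampleDataset,
    ff_estimate: FFEstimate | float,
    chrom: str,
    zscores: Optional[np.ndarray] = None,
    thresholds: GenotypeThresholds = GenotypeThresholds(),
    cnv_af_rule: str = "dosage",
) -> List[MaternalFinding]:
    """Run all maternal screens on one chromosome; AOH findings overlapping
    a CNV finding are dropped (the CNV explains the evidence).

    The screen checks CNV candidates against the allelic-dosage AF windows
    by default (a duplicated heterozygous locus reads ~1/3 or ~2/3); pass
    ``cnv_af_rule='as-printed'`` for the published windows.
    """
    sub = classify_maternal_genotypes(sample.loci(chrom), thresholds)
    findings: List[MaternalFinding] = []
    if zscores is not None:
        findings += detect_maternal_cnv(
            zscores,
            sub["af"].to_numpy(),
            sub["maternal_gt"],
            chrom=chrom,
            positions=sub["pos"].to_numpy(),
            af_rule=cnv_af_rule,
        )
    cnvs = list(findings)
    for aoh in detect_aoh(
        sub["maternal_gt"], chrom=chrom, positions=sub["pos"].to_numpy()
    ):
        if not any(aoh.overlaps(c) for c in cnvs):
            findings.append(aoh)
    twin = detect_dizygotic_twin(sample, ff_estimate, thresholds)
    if twin is not None and twin.kind == "twin":
        findings.append(twin)
    return findings
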