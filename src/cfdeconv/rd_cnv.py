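"""Read-depth normalization, PCA batch adjustment, chromosome Z-scores,
QC gates, and the combined read-depth + allele-fraction decision.

Depth normalization follows the median-of-chromosome-medians convention:
each sample is scaled so the median of its per-chromosome median depths is
1, after which a Hampel step (standard-deviation scale) masks loci that
stray more than 3 SDs from the moving average.  Chromosome dosage is tested
with Z_i = (R_i - mu_i)/sigma_i where R_i is the target/reference read
ratio and mu_i, sigma_i come from the other samples of the same processing
batch (leave-one-out, so the tested sample never contaminates its own
null).

Two QC levels gate the callers: level 1 requires the fetal-fraction x
mean-depth product to reach 48 and no twin / large maternal-CNV flag;
level 2 requires more than 60 informative SNPs and no AOH wiping out the
target region's heterozygous loci.  The final call is the union of the
read-depth and allele-fraction evidence, each contributing only when its
QC level passed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .ploidy import PloidyCall, hampel_filter

__all__ = [
    "QCResult",
    "DEFAULT_REFERENCE_EXCLUDE",
    "normalize_depth",
    "pca_adjust",
    "chromosome_zscore",
    "qc_gates",
    "combined_call",
    "CombinedCall",
]

#: chromosomes never used as the dosage reference (targets + sex chromosomes)
DEFAULT_REFERENCE_EXCLUDE = ("chr13", "chr18", "chr21", "chr22", "chrX", "chrY")

FF_RD_PRODUCT_MIN = 48.0
INFORMATIVE_MIN = 60      # strict: must be > 60
Z_THRESHOLD = 3.0


@dataclass
class QCResult:
    level1_pass: bool
    level2_pass: bool
    reasons: List[str] = field(default_factory=list)


@dataclass
class CombinedCall:
    positive: bool
    evidence: List[str] = field(default_factory=list)
    no_call: bool = False


def _chrom_of(dm: pd.DataFrame) -> np.ndarray:
    if "chrom" in dm.attrs:
        return np.asarray(dm.attrs["chrom"])
    return np.array([c.split(":")[0] for c in dm.columns])


def normalize_depth(
    raw: pd.DataFrame,
    hampel_window: int = 11,
    mode: str = "median-of-medians",
    reference_exclude: Sequence[str] = DEFAULT_REFERENCE_EXCLUDE,
) -> pd.DataFrame:
    """Normalize a samples x loci depth matrix.

    ``mode='median-of-medians'`` divides each sample by the median of its
    per-chromosome median depths (the chromosome-dosage convention);
    ``mode='reference'`` divides by the median depth over
    reference-chromosome loci only, which keeps the scale insensitive to a
    large event on a target chromosome and is the convention for the
    per-locus maternal-CNV screen.  After scaling, loci deviating > 3 SD
    from the moving average within a sample are masked to NaN.  All-zero
    samples raise.
    """
    chrom = _chrom_of(raw)
    ref_cols = ~np.isin(chrom, list(reference_exclude))
    if mode == "reference" and ref_cols.sum() == 0:
        raise ValueError("no reference-chromosome loci for normalization")
    out = raw.astype(float).copy()
    for sid, row in out.iterrows():
        x = row.to_numpy(dtype=float)
        if mode == "reference":
            scale = float(np.median(x[ref_cols]))
        else:
            med = [np.median(x[chrom == c]) for c in pd.unique(chrom)]
            scale = float(np.median(med))
        if scale <= 0:
            raise ValueError(f"sample {sid} has zero coverage")
        x = x / scale
        if len(x) >= hampel_window:
            keep = hampel_filter(x, window=hampel_window, scale="std")
            x[~keep] = np.nan
        out.loc[sid] = x
    out.attrs["chrom"] = chrom
    return out


def pca_adjust(
    dm: pd.DataFrame,
    n_components: int = 3,
    reference_exclude: Sequence[str] = DEFAULT_REFERENCE_EXCLUDE,
) -> pd.DataFrame:
    """Project out the leading depth components unrelated to copy number.

    Component loadings per sample are estimated on reference-chromosome
    loci only, so a true fetal dosage change confined to a target
    chromosome cannot be absorbed; the matching locus profiles are obtained
    by regressing every locus on the loadings and subtracted everywhere.
    Too few samples -> returned unchanged with a warning.
    """
    if n_components <= 0:
        return dm
    n_samples = dm.shape[0]
    if n_samples < n_components + 2:
        warnings.warn("too few samples for PCA adjustment; skipped")
        return dm
    chrom = _chrom_of(dm)
    x = dm.to_numpy(dtype=float)
    col_mean = np.nanmean(x, axis=0)
    xc = np.where(np.isnan(x), 0.0, x - col_mean)
    ref_cols = ~np.isin(chrom, list(reference_exclude))
    if ref_cols.sum() < n_components:
        warnings.warn("too few reference loci for PCA adjustment; skipped")
        return dm
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(xc[:, ref_cols])  # (samples, k)
    # least-squares locus profiles for all loci
    w, *_ = np.linalg.lstsq(scores, xc, rcond=None)
    adj = x - scores @ w
    out = pd.DataFrame(adj, index=dm.index, columns=dm.columns)
    out.attrs["chrom"] = chrom
    return out


def chromosome_zscore(
    dm: pd.DataFrame,
    target: str,
    reference_exclude: Sequence[str] = DEFAULT_REFERENCE_EXCLUDE,
    min_batch: int = 8,
) -> pd.Series:
    """Per-sample Z-score of the target/reference read ratio.

    mu and sigma are computed leave-one-out across the processing batch.
    """
    if dm.shape[0] < 3:
        raise ValueError("need at least 3 samples for batch Z-scores")
    if dm.shape[0] < min_batch:
        warnings.warn(f"batch of {dm.shape[0]} < {min_batch}; Z-scores unstable")
    chrom = _chrom_of(dm)
    x = dm.to_numpy(dtype=float)
    t_cols = chrom == target
    r_cols = ~np.isin(chrom, list(reference_exclude))
    if t_cols.sum() == 0:
        raise ValueError(f"no loci on target {target}")
    if r_cols.sum() == 0:
        raise ValueError("no reference-chromosome loci")
    ratio = np.nansum(x[:, t_cols], axis=1) / np.nansum(x[:, r_cols], axis=1)
    n = len(ratio)
    z = np.empty(n)
    for i in range(n):
        others = np.delete(ratio, i)
        mu, sd = float(np.mean(others)), float(np.std(others, ddof=1))
        if sd == 0.0:
            if ratio[i] == mu:
                z[i] = 0.0  # all samples identical: no dosage deviation
                continue
            raise ValueError("degenerate batch: zero variance of depth ratios")
        z[i] = (ratio[i] - mu) / sd
    return pd.Series(z, index=dm.index, name=f"z_{target}")


def qc_gates(
    ff: float,
    mean_depth: float,
    informative_count: int,
    twin_flag: bool = False,
    maternal_cnv_flag: bool = False,
    aoh_flag: bool = False,
    ff_rd_min: float = FF_RD_PRODUCT_MIN,
    informative_min: int = INFORMATIVE_MIN,
) -> QCResult:
    """Two-level QC: depth/FF sufficiency and confounders (Lv1), then
    informative-locus count and AOH (Lv2, only evaluated if Lv1 passes)."""
    reasons: List[str] = []
    product = ff * mean_depth
    lv1 = True
    if product < ff_rd_min:
        lv1 = False
        reasons.append(f"FF x depth product {product:.1f} < {ff_rd_min:g}")
    if twin_flag:
        lv1 = False
        reasons.append("dizygotic twin / non-singleton signal")
    if maternal_cnv_flag:
        lv1 = False
        reasons.append("maternal CNV >= 3 Mb on a target region")
    if not lv1:
        return QCResult(level1_pass=False, level2_pass=False, reasons=reasons)
    lv2 = True
    if informative_count <= informative_min:
        lv2 = False
        reasons.append(
            f"informative SNPs {informative_count} <= {informative_min}"
        )
    if aoh_flag:
        lv2 = False
        reasons.append("maternal AOH eliminates target heterozygous loci")
    return QCResult(level1_pass=True, level2_pass=lv2, reasons=reasons)


def combined_call(
    rd_z: Optional[float],
    af_call: Optional[PloidyCall],
    qc: QCResult,
    z_threshold: float = Z_THRESHOLD,
) -> CombinedCall:
    """Union decision: positive if RD (|Z| >= threshold, Lv1 passed) or AF
    (winning aneuploid deltaL, Lv2 passed) evidence fires."""
    if not qc.level1_pass:
        return CombinedCall(positive=False, no_call=True, evidence=["QC level 1 failed"])
    evidence: List[str] = []
    if rd_z is not None and abs(rd_z) >= z_threshold:
        evidence.append(f"RD |Z|={abs(rd_z):.2f} >= {z_threshold:g}")
    if qc.level2_pass and af_call is not None and af_call.is_aneuploid:
        evidence.append(
            f"AF deltaL={af_call.best_delta_l:.1f} ({af_call.hypothesis})"
        )
    return CombinedCall(positive=bool(evidence), evidence=evidence)
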