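"""Fetal-fraction estimation from informative SNPs and from chrY/chrX depth.

At a locus where the mother is homozygous and the fetus heterozygous, the
minor-allele read fraction is FF/2, so each such locus yields a fetal
fraction estimate: FF_AAi = 2(1 - NA_i/N) for maternal AA, FF_BBi = 2NA_i/N
for maternal BB.  The sample estimate is the mean of the two per-side
medians, FF = (FF_AA + FF_BB)/2.  For male fetuses an orthogonal estimate is
the ratio of median normalized chrY to chrY+chrX depths.

Maternal genotypes are classified from cfDNA allele fractions with hard
cut-points (BB below 0.3, AB in [0.3, 0.7], AA above 0.7), and a homozygous
locus counts as informative when its minor-side AF falls inside the fetal
heterozygote window (default [0.005, 0.25]).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .simulate import SampleDataset

__all__ = [
    "FFEstimate",
    "GenotypeThresholds",
    "classify_maternal_genotypes",
    "ff_from_snp",
    "ff_from_chry",
    "central_allelic_fraction",
]


@dataclass(frozen=True)
class GenotypeThresholds:
    hom_low: float = 0.3       # AF below -> maternal BB
    hom_high: float = 0.7      # AF above -> maternal AA
    fetal_window: tuple = (0.005, 0.25)  # minor-side AF window for informativeness
    min_depth: int = 100


@dataclass
class FFEstimate:
    ff: float
    ff_aa: Optional[float] = None
    ff_bb: Optional[float] = None
    n_informative: int = 0
    method: str = "snp"

    def __post_init__(self) -> None:
        self.ff = float(min(max(self.ff, 0.0), 1.0))


def classify_maternal_genotypes(
    snp: pd.DataFrame, thresholds: GenotypeThresholds = GenotypeThresholds()
) -> pd.DataFrame:
    """Per-locus maternal genotype ('AA'/'AB'/'BB') and informative flag.

    Loci below the minimum depth are excluded (genotype 'NA').  Accepts a
    SNP table with n_alt / n_ref / depth columns.
    """
    out = snp.copy()
    depth = out["depth"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(depth > 0, out["n_alt"].to_numpy(dtype=float) / depth, np.nan)
    out["af"] = af

    gt = np.full(len(out), "NA", dtype=object)
    usable = depth >= thresholds.min_depth
    gt[usable & (af < thresholds.hom_low)] = "BB"
    gt[usable & (af >= thresholds.hom_low) & (af <= thresholds.hom_high)] = "AB"
    gt[usable & (af > thresholds.hom_high)] = "AA"
    out["maternal_gt"] = gt

    lo, hi = thresholds.fetal_window
    minor = np.where(gt == "AA", 1.0 - af, af)
    informative = (
        ((gt == "AA") | (gt == "BB")) & (minor >= lo) & (minor <= hi)
    )
    out["informative"] = informative
    return out


#: chromosomes excluded from FF estimation by default: the screened target
#: chromosomes (where a fetal aneuploidy would distort the per-locus FF)
#: and the sex chromosomes
FF_EXCLUDE_CHROMS = ("chr13", "chr18", "chr21", "chr22", "chrX", "chrY")


def ff_from_snp(
    sample: SampleDataset | pd.DataFrame,
    thresholds: GenotypeThresholds = GenotypeThresholds(),
    exclude_chroms: tuple = FF_EXCLUDE_CHROMS,
) -> FFEstimate:
    """SNP-based fetal fraction: FF = (median FF_AAi + median FF_BBi)/2.

    Estimation uses reference-chromosome loci only (falling back to all
    autosomal loci if the panel has none), so that a fetal aneuploidy on a
    screened chromosome cannot bias the estimate.
    """
    snp = sample.snp if isinstance(sample, SampleDataset) else sample
    kept = snp[~snp["chrom"].isin(exclude_chroms)]
    if len(kept) == 0:
        kept = snp[~snp["chrom"].isin(("chrX", "chrY"))]
    snp = kept
    cls = classify_maternal_genotypes(snp, thresholds)
    inf = cls[cls["informative"]]
    aa = inf[inf["maternal_gt"] == "AA"]
    bb = inf[inf["maternal_gt"] == "BB"]
    if len(aa) == 0 or len(bb) == 0:
        raise ValueError(
            "FF not estimable: no informative loci on the "
            + ("AA" if len(aa) == 0 else "BB")
            + " side"
        )
    ff_aa = float(np.median(2.0 * (1.0 - aa["af"])))
    ff_bb = float(np.median(2.0 * bb["af"]))
    return FFEstimate(
        ff=(ff_aa + ff_bb) / 2.0,
        ff_aa=ff_aa,
        ff_bb=ff_bb,
        n_informative=len(inf),
        method="snp",
    )


def ff_from_chry(sample: SampleDataset | pd.DataFrame, doubled: bool = False) -> FFEstimate:
    """Depth-based fetal fraction for male fetuses: RDchrY/(RDchrY + RDchrX).

    Depths are normalized per locus by the sample's autosomal median depth.
    ``doubled`` switches to the 2x variant some pipelines use; default off,
    matching the plain ratio convention.
    """
    snp = sample.snp if isinstance(sample, SampleDataset) else sample
    ychr = snp[snp["chrom"] == "chrY"]
    xchr = snp[snp["chrom"] == "chrX"]
    if len(ychr) == 0:
        raise ValueError("no chrY loci: chrY-based FF needs a male-fetus panel")
    if len(xchr) == 0:
        raise ValueError("no chrX loci")
    auto = snp[~snp["chrom"].isin(("chrX", "chrY"))]
    scale = float(np.median(auto["depth"])) if len(auto) else 1.0
    scale = scale if scale > 0 else 1.0
    rd_y = float(np.median(ychr["depth"])) / scale
    rd_x = float(np.median(xchr["depth"])) / scale
    if rd_y + rd_x == 0:
        raise ValueError("zero chrX+chrY coverage")
    ff = rd_y / (rd_y + rd_x)
    if doubled:
        ff = min(2.0 * ff, 1.0)
    return FFEstimate(ff=ff, n_informative=len(ychr), method="chry")


def central_allelic_fraction(
    sample: SampleDataset | pd.DataFrame,
    thresholds: GenotypeThresholds = GenotypeThresholds(),
) -> float:
    """CAF: median allele fraction across maternal heterozygous loci.

    A probe panel with residual allelic hybridization bias shows CAF < 0.5;
    allele-balanced (COATE) panels sit close to 0.5.
    """
    snp = sample.snp if isinstance(sample, SampleDataset) else sample
    cls = classify_maternal_genotypes(snp, thresholds)
    het = cls[cls["maternal_gt"] == "AB"]
    if len(het) == 0:
        raise ValueError("no maternal heterozygous loci")
    return float(np.median(het["af"]))
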