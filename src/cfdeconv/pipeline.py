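"""End-to-end orchestration: simulate or load a batch, run QC, fetal
fraction, read-depth and allele-fraction calling, and the SNV screen.

The flow mirrors the two-level QC design: level-1 QC (depth sufficiency,
fetal fraction, twin and maternal-CNV screens) gates the read-depth
analysis; level-2 QC (informative-locus count, maternal AOH) gates the
allele-fraction analysis; the final chromosome call is the union of the
two evidence channels.  Samples failing level 2 but passing level 1 keep
their read-depth-only call; excluded samples are reported with reasons,
never silently dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import rd_cnv
from .fetal_fraction import GenotypeThresholds, ff_from_snp
from .maternal import maternal_screen
from .ploidy import call_ploidy
from .rd_cnv import (
    chromosome_zscore,
    combined_call,
    normalize_depth,
    pca_adjust,
    qc_gates,
)
from .simulate import Scenario, SampleDataset, simulate_batch

__all__ = ["RunConfig", "run_pipeline"]

MATERNAL_CNV_EXCLUSION_BP = 3_000_000


@dataclass
class RunConfig:
    scenarios: Sequence[Scenario]
    target_chromosome: str = "chr21"
    seed: int = 0
    pca_components: int = 3
    z_threshold: float = rd_cnv.Z_THRESHOLD
    ff_rd_min: float = rd_cnv.FF_RD_PRODUCT_MIN
    informative_min: int = rd_cnv.INFORMATIVE_MIN
    genotype_thresholds: GenotypeThresholds = field(default_factory=GenotypeThresholds)
    batch_effect: float = 0.0
    #: AF-consistency windows for the maternal-CNV screen; 'dosage' matches
    #: the physical allelic-dosage expectation, 'as-printed' the published
    #: windows (see maternal.detect_maternal_cnv)
    cnv_af_rule: str = "dosage"
    #: optional monogenic-variant screen; needs ROI intervals when enabled
    snv_screen_enabled: bool = False
    snv_roi: Optional[Sequence[Tuple[str, int, int]]] = None

    def thresholds_echo(self) -> Dict[str, float]:
        return {
            "alpha": 3000.0,
            "ff_rd_product_min": self.ff_rd_min,
            "informative_min": self.informative_min,
            "aoh_min_run": 75,
            "meiotic_min_run": 10,
            "fmid_min_p": 0.001,
            "acd_window": [0.001, 10.0],
            "insert_bounds": [20, 600],
            "gc_range": [0.30, 0.70],
            "z_threshold": self.z_threshold,
        }


def _per_locus_zscores(dm: pd.DataFrame, sample_id: str) -> np.ndarray:
    """Leave-one-out per-locus depth Z for one sample against the batch."""
    x = dm.to_numpy(dtype=float)
    i = list(dm.index).index(sample_id)
    others = np.delete(x, i, axis=0)
    mu = np.nanmean(others, axis=0)
    sd = np.nanstd(others, axis=0, ddof=1)
    sd = np.where(sd > 0, sd, np.nan)
    return (x[i] - mu) / sd


def run_pipeline(cfg: RunConfig) -> Dict:
    """Run the full screening flow on a (simulated) processing batch.

    Two passes: first, fetal fraction, maternal confounder screens, and
    level-1 QC for every sample; then chromosome Z-scores computed on the
    level-1 survivors only (a sample excluded for, e.g., a large maternal
    CNV would otherwise contaminate the batch null), followed by level-2
    QC, the allele-fraction call, and the combined decision.
    """
    if cfg.snv_screen_enabled and cfg.snv_roi is None:
        raise ValueError("SNV screen enabled but no ROI intervals configured")
    samples, raw = simulate_batch(
        list(cfg.scenarios), batch_effect=cfg.batch_effect
    )
    dm = normalize_depth(raw)
    dm = pca_adjust(dm, n_components=cfg.pca_components)
    # reference-normalized matrix for the per-locus maternal-CNV screen
    dm_ref = normalize_depth(raw, mode="reference")

    chrom_cols = np.asarray(dm.attrs["chrom"])
    target_cols = chrom_cols == cfg.target_chromosome

    report: Dict = {
        "config": cfg.thresholds_echo(),
        "target": cfg.target_chromosome,
        "n_samples": len(samples),
        "samples": [],
    }

    # ---- pass 1: FF, maternal screens, level-1 QC
    entries: Dict[str, Dict] = {}
    qcs: Dict[str, "object"] = {}
    for ds in samples:
        entry: Dict = {"sample_id": ds.sample_id}
        entries[ds.sample_id] = entry
        try:
            ffe = ff_from_snp(ds, cfg.genotype_thresholds)
        except ValueError as exc:
            entry["status"] = "excluded"
            entry["reasons"] = [str(exc)]
            continue
        entry["fetal_fraction"] = round(ffe.ff, 4)
        entry["_ff"] = ffe.ff

        locus_z = _per_locus_zscores(dm_ref, ds.sample_id)[target_cols]
        findings = maternal_screen(
            ds,
            ffe,
            cfg.target_chromosome,
            zscores=np.where(np.isfinite(locus_z), locus_z, 0.0),
            thresholds=cfg.genotype_thresholds,
            cnv_af_rule=cfg.cnv_af_rule,
        )
        entry["maternal_findings"] = [
            {
                "kind": f.kind,
                "span_bp": f.span_bp,
                **{k: round(float(v), 4) for k, v in f.evidence.items()},
            }
            for f in findings
        ]
        twin_flag = any(f.kind == "twin" for f in findings)
        cnv_flag = any(
            f.kind.startswith("CNV") and f.span_bp >= MATERNAL_CNV_EXCLUSION_BP
            for f in findings
        )
        aoh_flag = any(f.kind == "AOH" for f in findings)
        qc = qc_gates(
            ffe.ff,
            float(ds.loci(cfg.target_chromosome)["depth"].mean()),
            ff_informative_count(ds, cfg.genotype_thresholds),
            twin_flag=twin_flag,
            maternal_cnv_flag=cnv_flag,
            aoh_flag=aoh_flag,
            ff_rd_min=cfg.ff_rd_min,
            informative_min=cfg.informative_min,
        )
        qcs[ds.sample_id] = qc
        entry["qc"] = {
            "level1_pass": qc.level1_pass,
            "level2_pass": qc.level2_pass,
            "reasons": qc.reasons,
        }
        if not qc.level1_pass:
            entry["status"] = "excluded"
            entry["reasons"] = qc.reasons

    # ---- pass 2: RD Z-scores on level-1 survivors, AF calls, union
    passing = [
        ds for ds in samples
        if entries[ds.sample_id].get("status") != "excluded"
    ]
    z = None
    if len(passing) >= 3:
        z = chromosome_zscore(
            dm.loc[[ds.sample_id for ds in passing]], cfg.target_chromosome
        )
    for ds in passing:
        entry = entries[ds.sample_id]
        qc = qcs[ds.sample_id]
        ffe_ff = entry.pop("_ff")
        rd_z = float(z[ds.sample_id]) if z is not None else None
        if rd_z is not None:
            entry["rd_z"] = round(rd_z, 3)
        af_call = None
        if qc.level2_pass:
            af_call = call_ploidy(
                ds, ffe_ff, chrom=cfg.target_chromosome,
                thresholds=cfg.genotype_thresholds,
            )
            entry["af_call"] = {
                "hypothesis": af_call.hypothesis,
                "delta_l": round(af_call.best_delta_l, 2),
                "n_crossovers": af_call.n_crossovers,
                "breakpoints": list(af_call.breakpoints),
            }
        final = combined_call(rd_z, af_call, qc, z_threshold=cfg.z_threshold)
        entry["status"] = "positive" if final.positive else "negative"
        entry["evidence"] = final.evidence
    for ds in samples:
        entries[ds.sample_id].pop("_ff", None)
        report["samples"].append(entries[ds.sample_id])

    report["n_positive"] = sum(
        1 for s in report["samples"] if s.get("status") == "positive"
    )
    report["n_excluded"] = sum(
        1 for s in report["samples"] if s.get("status") == "excluded"
    )
    return report


def ff_informative_count(
    ds: SampleDataset, thresholds: GenotypeThresholds = GenotypeThresholds()
) -> int:
    """Number of informative SNPs (maternal homozygous, fetal allele seen)."""
    from .fetal_fraction import classify_maternal_genotypes

    snp = ds.snp[~ds.snp["chrom"].isin(("chrX", "chrY"))]
    cls = classify_maternal_genotypes(snp, thresholds)
    return int(cls["informative"].sum())


def write_report(report: Dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)
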