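"""Synthetic maternal-plasma cfDNA cohorts with the statistical structure the
deconvolution method assumes.

A simulated sample is a per-SNP table of A/B allele read counts plus optional
per-read records for monogenic-variant candidates.  The generator draws
parental genotypes from Hardy-Weinberg equilibrium, transmits fetal genotypes
through the meiotic model (optionally switching nondisjunction sub-state at
crossover breakpoints), and adds beta-binomial allele-count noise anchored at
the ploidy model's empirical concentration (alpha = 3000).  Fetal cfDNA
fragments are drawn ~10 bp shorter than maternal ones, truncated to the
20-600 bp window used for insert-size smoothing.

Depth noise is negative-binomial with a default per-locus coefficient of
variation of 0.10 (pinned by the maternal-CNV mosaic detection limit; see
``Scenario.depth_cv``); insert sizes are Normal(166, 25) maternal and
Normal(156, 25) fetal.
Truth labels (parental and fetal genotypes, hypothesis segments, breakpoints)
ride along in a sidecar ``truth`` dict that downstream callers never read.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genetics import (
    AA,
    AB,
    BB,
    Genotype,
    Hypothesis,
    PARENTAL_PAIRS,
    fetal_genotype_distribution,
)

__all__ = [
    "InsertModel",
    "MaternalCnv",
    "AohSegment",
    "TwinSpec",
    "Scenario",
    "SampleDataset",
    "simulate_sample",
    "simulate_snv_reads",
    "simulate_batch",
]

_EPS = 1e-6


@dataclass(frozen=True)
class InsertModel:
    """cfDNA insert-size model: maternal Normal(mean, sd), fetal shifted."""

    maternal_mean: float = 166.0
    maternal_sd: float = 25.0
    fetal_offset: float = -10.0
    bounds: Tuple[int, int] = (20, 600)


@dataclass(frozen=True)
class MaternalCnv:
    """A maternal germline CNV segment on the target chromosome.

    ``copy_state`` is the total maternal copy number in the affected cells
    (3 = duplication, 1 = deletion); ``mosaic_level`` the affected-cell
    fraction (1.0 = constitutional).
    """

    start: int
    length: int
    copy_state: int = 3
    mosaic_level: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.mosaic_level <= 1.0:
            raise ValueError("mosaic level must be in (0,1]")
        if self.copy_state not in (0, 1, 3, 4):
            raise ValueError("copy_state must be a non-diploid count")


@dataclass(frozen=True)
class AohSegment:
    """A maternal absence-of-heterozygosity run (start index, length in loci)."""

    start: int
    length: int


@dataclass(frozen=True)
class TwinSpec:
    """A dizygotic co-twin: an independent fetal genome at its own FF."""

    fetal_fraction: float


@dataclass(frozen=True)
class Scenario:
    """Study conditions for one simulated plasma sample."""

    ploidy_hypothesis: Hypothesis = Hypothesis.D
    target_chromosome: str = "chr21"
    crossover_breakpoints: Tuple[int, ...] = ()
    fetal_fraction: float = 0.10
    mean_depth: float = 600.0
    n_target_snps: int = 500
    n_reference_snps: int = 500
    maternal_cnv: Optional[MaternalCnv] = None
    aoh_segment: Optional[AohSegment] = None
    twin: Optional[TwinSpec] = None
    allele_freq_range: Tuple[float, float] = (0.1, 0.9)
    overdispersion_alpha: float = 3000.0
    # depth noise pinned by the maternal-CNV detection limit: a mosaic
    # duplication at cell fraction 0.6 sits exactly at the |Z| = 3 cutoff
    # when the per-locus relative depth SD is 0.10 (constitutional CNV
    # then scores |Z| ~ 5)
    depth_cv: float = 0.10
    insert_model: InsertModel = field(default_factory=InsertModel)
    male_fetus: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fetal_fraction < 1.0:
            raise ValueError("fetal fraction must be in (0,1)")
        bps = tuple(self.crossover_breakpoints)
        if bps:
            if self.ploidy_hypothesis in (Hypothesis.D, Hypothesis.LM, Hypothesis.LP):
                raise ValueError("crossover requires trisomy hypothesis")
            if len(bps) > 2:
                raise ValueError("at most two crossover breakpoints supported")
            if list(bps) != sorted(set(bps)):
                raise ValueError("breakpoints must be strictly increasing")
            if bps[0] < 1 or bps[-1] >= self.n_target_snps:
                raise ValueError("breakpoints must lie inside the target SNP range")

    def partner_hypothesis(self) -> Hypothesis:
        for h1, h2 in PARENTAL_PAIRS:
            if self.ploidy_hypothesis == h1:
                return h2
            if self.ploidy_hypothesis == h2:
                return h1
        raise ValueError("no recombination partner for " + self.ploidy_hypothesis.value)

    def hypothesis_track(self) -> List[Hypothesis]:
        """Per-locus hypothesis on the target chromosome, switching at breakpoints."""
        track = [self.ploidy_hypothesis] * self.n_target_snps
        if not self.crossover_breakpoints:
            return track
        other = self.partner_hypothesis()
        bps = list(self.crossover_breakpoints)
        segs = [0] + bps + [self.n_target_snps]
        for j in range(len(segs) - 1):
            h = self.ploidy_hypothesis if j % 2 == 0 else other
            for i in range(segs[j], segs[j + 1]):
                track[i] = h
        return track


@dataclass
class SampleDataset:
    """One plasma sample: SNP read-count table plus optional SNV read records.

    ``snp`` columns: chrom, pos, p (population A-allele frequency), n_alt,
    n_ref, depth (n_alt + n_ref).  ``truth`` carries simulation labels for
    testing only.
    """

    snp: pd.DataFrame
    snv_reads: Optional[pd.DataFrame] = None
    truth: Dict = field(default_factory=dict)
    sample_id: str = "sample"
    batch_id: str = "batch0"

    def loci(self, chrom: str) -> pd.DataFrame:
        return self.snp[self.snp["chrom"] == chrom].reset_index(drop=True)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.snp.to_csv(outdir / f"{self.sample_id}.snp.tsv", sep="\t", index=False)
        if self.snv_reads is not None:
            self.snv_reads.to_csv(
                outdir / f"{self.sample_id}.snv_reads.tsv", sep="\t", index=False
            )
        with open(outdir / f"{self.sample_id}.truth.json", "w") as fh:
            json.dump(_jsonable(self.truth), fh, indent=1)

    @classmethod
    def read(cls, snp_tsv: str | Path, snv_tsv: str | Path | None = None) -> "SampleDataset":
        snp = pd.read_csv(snp_tsv, sep="\t")
        if "depth" not in snp.columns:
            snp["depth"] = snp["n_alt"] + snp["n_ref"]
        reads = pd.read_csv(snv_tsv, sep="\t") if snv_tsv else None
        return cls(snp=snp, snv_reads=reads, sample_id=Path(snp_tsv).stem.split(".")[0])


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (Genotype, Hypothesis)):
        return str(obj)
    return obj


# ---------------------------------------------------------------------------
# core draws


def _draw_hwe(rng: np.random.Generator, p: np.ndarray) -> np.ndarray:
    """Vector of diploid A-allele counts drawn from HWE at frequencies p."""
    return rng.binomial(2, p)


def _draw_fetal(
    rng: np.random.Generator,
    mat_alt: np.ndarray,
    pat_alt: np.ndarray,
    hyps: Sequence[Hypothesis],
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-locus fetal (n_alt, copies) drawn from the transmission model."""
    n = len(mat_alt)
    f_alt = np.zeros(n, dtype=int)
    f_cop = np.zeros(n, dtype=int)
    for i in range(n):
        dist = fetal_genotype_distribution(
            Genotype(int(mat_alt[i])), Genotype(int(pat_alt[i])), hyps[i]
        )
        gts = list(dist.keys())
        probs = np.array([dist[g] for g in gts])
        g = gts[rng.choice(len(gts), p=probs / probs.sum())]
        f_alt[i], f_cop[i] = g.n_alt, g.copies
    return f_alt, f_cop


def _neg_binomial_depth(
    rng: np.random.Generator, mean: np.ndarray, cv: float
) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if cv <= 0:
        return rng.poisson(mean)
    r = 1.0 / (cv * cv)
    return rng.negative_binomial(r, r / (r + mean))


def _beta_binomial_counts(
    rng: np.random.Generator, depth: np.ndarray, p_alt: np.ndarray, alpha: float
) -> np.ndarray:
    """A-allele counts with beta-binomial noise: alpha fixed, beta = alpha/pA - alpha."""
    p_alt = np.clip(np.asarray(p_alt, dtype=float), _EPS, 1.0 - _EPS)
    beta = alpha / p_alt - alpha
    theta = rng.beta(alpha, beta)
    return rng.binomial(depth, theta)


def _clamp_inserts(sizes: np.ndarray, bounds: Tuple[int, int]) -> np.ndarray:
    return np.clip(np.rint(sizes).astype(int), bounds[0], bounds[1])


# ---------------------------------------------------------------------------
# operations


def simulate_sample(scenario: Scenario, panel: Optional[pd.DataFrame] = None) -> SampleDataset:
    """Simulate one plasma sample under ``scenario``.

    ``panel``, if given, fixes the SNP panel (chrom, pos, p) so that several
    samples share loci (see :func:`simulate_batch`); otherwise a panel is
    drawn from the scenario's allele-frequency range.  Deterministic under
    ``scenario.seed``.
    """
    rng = np.random.default_rng(scenario.seed)
    ff = scenario.fetal_fraction
    alpha = scenario.overdispersion_alpha

    if panel is None:
        panel = make_panel(scenario)
    chrom = panel["chrom"].to_numpy()
    p = panel["p"].to_numpy(dtype=float)
    n = len(panel)
    on_target = chrom == scenario.target_chromosome

    mat_alt = _draw_hwe(rng, p)
    pat_alt = _draw_hwe(rng, p)

    # maternal AOH: force homozygosity over the segment (target chromosome)
    if scenario.aoh_segment is not None:
        t_idx = np.flatnonzero(on_target)
        seg = t_idx[scenario.aoh_segment.start : scenario.aoh_segment.start + scenario.aoh_segment.length]
        mat_alt[seg] = 2 * rng.binomial(1, p[seg])

    hyps: List[Hypothesis] = [Hypothesis.D] * n
    track = scenario.hypothesis_track()
    ti = 0
    for i in range(n):
        if on_target[i]:
            hyps[i] = track[ti]
            ti += 1

    fet_alt, fet_cop = _draw_fetal(rng, mat_alt, pat_alt, hyps)

    # dizygotic co-twin: an independent euploid fetal genome from a second
    # paternal gamete (same mother, same father, independent meioses)
    twin_alt = twin_cop = None
    ff2 = 0.0
    if scenario.twin is not None:
        ff2 = scenario.twin.fetal_fraction
        twin_alt, twin_cop = _draw_fetal(
            rng, mat_alt, pat_alt, [Hypothesis.D] * n
        )

    # maternal copy number per locus (mosaic CNV changes effective dosage)
    mat_copies = np.full(n, 2.0)
    mat_dose_alt = mat_alt.astype(float)
    if scenario.maternal_cnv is not None:
        cnv = scenario.maternal_cnv
        t_idx = np.flatnonzero(on_target)
        seg = t_idx[cnv.start : cnv.start + cnv.length]
        delta = cnv.copy_state - 2  # +1 duplication, -1 deletion
        # the gained/lost homolog carries the A allele w.p. g_m/2
        hom_alt = rng.binomial(1, mat_alt[seg] / 2.0)
        mat_copies[seg] = 2.0 + cnv.mosaic_level * delta
        mat_dose_alt[seg] = mat_alt[seg] + cnv.mosaic_level * delta * hom_alt

    ff_m = 1.0 - ff - ff2
    dose_num = ff_m * mat_dose_alt + ff * fet_alt
    dose_den = ff_m * mat_copies + ff * fet_cop
    if twin_alt is not None:
        dose_num = dose_num + ff2 * twin_alt
        dose_den = dose_den + ff2 * twin_cop
    p_alt = dose_num / dose_den

    rel_depth = dose_den / 2.0
    depth = _neg_binomial_depth(rng, scenario.mean_depth * rel_depth, scenario.depth_cv)
    depth = np.maximum(depth, 1)
    n_a = _beta_binomial_counts(rng, depth, p_alt, alpha)

    snp = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": panel["pos"].to_numpy(),
            "p": p,
            "n_alt": n_a,
            "n_ref": depth - n_a,
            "depth": depth,
        }
    )

    if scenario.male_fetus:
        snp = pd.concat([snp, _sex_chromosome_depths(rng, scenario)], ignore_index=True)

    truth = {
        "hypothesis": scenario.ploidy_hypothesis.value,
        "breakpoints": list(scenario.crossover_breakpoints),
        "fetal_fraction": ff,
        "maternal_genotype": mat_alt.tolist(),
        "paternal_genotype": pat_alt.tolist(),
        "fetal_n_alt": fet_alt.tolist(),
        "fetal_copies": fet_cop.tolist(),
        "target_chromosome": scenario.target_chromosome,
        "twin_ff": ff2,
    }
    return SampleDataset(snp=snp, truth=truth, sample_id=f"s{scenario.seed}")


def make_panel(scenario: Scenario, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Draw a shared SNP panel (chrom, pos, p) for a scenario.

    The panel stream is decorrelated from the per-sample stream (which is
    seeded with the bare scenario seed): reusing one stream for both the
    allele frequencies and the genotype draws conditioned on them induces
    spurious frequency-genotype dependence.
    """
    if rng is None:
        rng = np.random.default_rng([scenario.seed, 9_999_991])
    lo, hi = scenario.allele_freq_range
    nt, nr = scenario.n_target_snps, scenario.n_reference_snps
    chrom = np.array([scenario.target_chromosome] * nt + ["chrRef"] * nr)
    pos = np.concatenate(
        [np.arange(1, nt + 1) * 10_000, np.arange(1, nr + 1) * 10_000]
    )
    p = rng.uniform(lo, hi, size=nt + nr)
    return pd.DataFrame({"chrom": chrom, "pos": pos, "p": p})


def _sex_chromosome_depths(rng: np.random.Generator, sc: Scenario) -> pd.DataFrame:
    """chrX / chrY depth-only loci for a male fetus (no allele counts used)."""
    ff = sc.fetal_fraction + (sc.twin.fetal_fraction if sc.twin else 0.0)
    nx, ny = 100, 50
    dx = _neg_binomial_depth(rng, np.full(nx, sc.mean_depth * (1.0 - ff / 2.0)), sc.depth_cv)
    dy = _neg_binomial_depth(rng, np.full(ny, sc.mean_depth * ff), sc.depth_cv)
    frames = []
    for chrom, d in (("chrX", dx), ("chrY", dy)):
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": np.arange(1, len(d) + 1) * 10_000,
                    "p": 0.5,
                    "n_alt": 0,
                    "n_ref": d,
                    "depth": d,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_snv_reads(
    origin: str,
    ff: float,
    depth: int,
    error_rate: float = 0.0,
    insert_model: InsertModel = InsertModel(),
    seed: int = 0,
    variant_id: str = "var1",
) -> pd.DataFrame:
    """Per-read records (variant_id, allele, insert_size) for one SNV candidate.

    ``origin`` is one of ``fetal`` (paternally inherited or de novo fetal
    heterozygote: expected alt fraction ff/2), ``maternal-het`` (expected
    0.5), or ``absent`` (alt reads only from error at ``error_rate``).
    Fetal-origin reads draw the shifted insert distribution.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    im = insert_model
    if origin == "fetal":
        af = ff / 2.0
    elif origin == "maternal-het":
        af = 0.5
    elif origin == "absent":
        af = error_rate
    else:
        raise ValueError(f"unknown origin {origin!r}")
    if error_rate >= ff / 2.0 and origin == "fetal":
        warnings.warn("error rate >= ff/2: variant in an undetectable regime")

    n_alt = rng.binomial(depth, af)
    n_ref = depth - n_alt

    def draw(n: int, fetal: bool) -> np.ndarray:
        mean = im.maternal_mean + (im.fetal_offset if fetal else 0.0)
        return _clamp_inserts(rng.normal(mean, im.maternal_sd, size=n), im.bounds)

    if origin == "fetal":
        alt_ins = draw(n_alt, fetal=True)
        # fetus is heterozygous, so a share of ref reads is fetal too
        p_ref_fetal = (ff / 2.0) / max(1.0 - ff / 2.0, _EPS)
        ref_fetal = rng.binomial(1, min(p_ref_fetal, 1.0), size=n_ref).astype(bool)
    else:
        alt_ins = draw(n_alt, fetal=False)
        ref_fetal = rng.binomial(1, ff, size=n_ref).astype(bool)
    ref_ins = np.empty(n_ref, dtype=int)
    ref_ins[ref_fetal] = draw(int(ref_fetal.sum()), fetal=True)
    ref_ins[~ref_fetal] = draw(int((~ref_fetal).sum()), fetal=False)

    return pd.DataFrame(
        {
            "variant_id": variant_id,
            "allele": ["alt"] * n_alt + ["ref"] * n_ref,
            "insert_size": np.concatenate([alt_ins, ref_ins]),
        }
    )


def simulate_batch(
    scenarios: Sequence[Scenario],
    batch_effect: float = 0.0,
    batch_id: str = "batch0",
) -> Tuple[List[SampleDataset], pd.DataFrame]:
    """Simulate a processing batch sharing one SNP panel.

    Returns the sample list and the raw depth matrix (samples x loci).  A
    nonzero ``batch_effect`` injects a common rank-1 multiplicative depth
    wave (sample loading x locus profile) to exercise PCA adjustment.
    """
    if len(scenarios) == 0:
        raise ValueError("need at least one scenario")
    base = scenarios[0]
    panel = make_panel(base)
    samples: List[SampleDataset] = []
    for i, sc in enumerate(scenarios):
        ds = simulate_sample(sc, panel=panel)
        ds.sample_id = f"s{i:02d}"
        ds.batch_id = batch_id
        samples.append(ds)

    if batch_effect > 0.0:
        rng = np.random.default_rng(base.seed + 104729)
        wave = np.sin(np.linspace(0.0, 6.0 * np.pi, len(panel)))
        load = rng.uniform(-1.0, 1.0, size=len(samples))
        for s, ds in enumerate(samples):
            mask = ds.snp["chrom"].isin(panel["chrom"].unique()).to_numpy()
            mult = 1.0 + batch_effect * load[s] * wave
            d = ds.snp.loc[mask, "depth"].to_numpy() * mult
            d = np.maximum(np.rint(d).astype(int), 1)
            af = ds.snp.loc[mask, "n_alt"] / ds.snp.loc[mask, "depth"]
            na = np.rint(af.to_numpy() * d).astype(int)
            ds.snp.loc[mask, "depth"] = d
            ds.snp.loc[mask, "n_alt"] = na
            ds.snp.loc[mask, "n_ref"] = d - na

    loci = panel["chrom"].astype(str) + ":" + panel["pos"].astype(str)
    mat = pd.DataFrame(
        [s.snp.loc[: len(panel) - 1, "depth"].to_numpy() for s in samples],
        index=[s.sample_id for s in samples],
        columns=loci,
    )
    mat.attrs["chrom"] = panel["chrom"].to_numpy()
    return samples, mat
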