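"""Genotype conventions, Hardy-Weinberg priors, and meiotic transmission models.

Conventions follow the A/B notation common in SNP-based NIPT: A is the
alternative (population-variant) allele, B the reference allele.  A fetal
ploidy state at a locus is one of seven hypotheses:

* ``D``    -- disomy (normal biparental inheritance),
* ``MI``   -- trisomy from a maternal meiosis-I nondisjunction (the gamete
  carries both maternal homologs),
* ``MII``  -- trisomy from a maternal meiosis-II nondisjunction (the gamete
  carries two copies of a single homolog),
* ``PI``/``PII`` -- the paternal mirror images,
* ``LM``/``LP``  -- monosomy missing the maternal / paternal contribution.

All fetal-genotype distributions are produced by explicit gamete
enumeration, which reproduces the classical Punnett square under ``D`` and
the textbook MI/MII heterozygosity probabilities (1 and 0.5 at a maternal
heterozygous locus) under the trisomy hypotheses.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, Mapping, Tuple

import pandas as pd

__all__ = [
    "Genotype",
    "Hypothesis",
    "COPY_NUMBER",
    "DIPLOID_GENOTYPES",
    "hwe_genotype_priors",
    "fetal_genotype_distribution",
    "mixture_weights",
    "expected_allele_fraction",
    "heterozygosity_probability",
    "origin_posterior",
    "transmission_table",
]


@dataclass(frozen=True, order=True)
class Genotype:
    """An unphased genotype: number of A (alternative) alleles out of ``copies``."""

    n_alt: int
    copies: int = 2

    def __post_init__(self) -> None:
        if not (0 <= self.n_alt <= self.copies):
            raise ValueError(f"n_alt={self.n_alt} outside 0..{self.copies}")
        if self.copies not in (0, 1, 2, 3):
            raise ValueError(f"unsupported copy number {self.copies}")

    @property
    def n_ref(self) -> int:
        return self.copies - self.n_alt

    @property
    def is_heterozygous(self) -> bool:
        """True if both alleles are present (e.g. AB, AAB, ABB)."""
        return 0 < self.n_alt < self.copies

    def __str__(self) -> str:
        return "A" * self.n_alt + "B" * self.n_ref if self.copies else "-"


#: Diploid genotypes in the fixed order BB, AB, AA.
BB, AB, AA = Genotype(0), Genotype(1), Genotype(2)
DIPLOID_GENOTYPES: Tuple[Genotype, ...] = (AA, AB, BB)


class Hypothesis(str, Enum):
    """Fetal ploidy / meiotic-origin hypotheses at a chromosome."""

    D = "D"
    MI = "MI"
    MII = "MII"
    PI = "PI"
    PII = "PII"
    LM = "LM"
    LP = "LP"

    @property
    def copy_number(self) -> int:
        return COPY_NUMBER[self]

    @property
    def is_trisomy(self) -> bool:
        return COPY_NUMBER[self] == 3

    @property
    def is_maternal(self) -> bool:
        return self in (Hypothesis.MI, Hypothesis.MII, Hypothesis.LM)


COPY_NUMBER: Dict[Hypothesis, int] = {
    Hypothesis.D: 2,
    Hypothesis.MI: 3,
    Hypothesis.MII: 3,
    Hypothesis.PI: 3,
    Hypothesis.PII: 3,
    Hypothesis.LM: 1,
    Hypothesis.LP: 1,
}

#: Recombination is modeled as a switch between the two nondisjunction
#: sub-states of the same parent, so crossover search only ever pairs these.
PARENTAL_PAIRS: Tuple[Tuple[Hypothesis, Hypothesis], ...] = (
    (Hypothesis.MI, Hypothesis.MII),
    (Hypothesis.PI, Hypothesis.PII),
)


def hwe_genotype_priors(p: float) -> Dict[Genotype, float]:
    """Hardy-Weinberg genotype priors {AA: p^2, AB: 2p(1-p), BB: (1-p)^2}.

    ``p`` is the population frequency of the A (alternative) allele.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"allele frequency must be in (0,1), got {p}")
    return {AA: p * p, AB: 2.0 * p * (1.0 - p), BB: (1.0 - p) * (1.0 - p)}


# ---------------------------------------------------------------------------
# Gamete enumeration

Dist = Dict[int, float]  # n_alt count -> probability


def _normal_gamete(parent: Genotype) -> Dist:
    # one allele drawn uniformly from the two homologs
    pa = parent.n_alt / 2.0
    d: Dist = {}
    if pa > 0:
        d[1] = pa
    if pa < 1:
        d[0] = d.get(0, 0.0) + (1.0 - pa)
    return d


def _mi_gamete(parent: Genotype) -> Dist:
    # meiosis-I error: both homologs end up in the gamete
    return {parent.n_alt: 1.0}


def _mii_gamete(parent: Genotype) -> Dist:
    # meiosis-II error: two copies of one homolog, each homolog w.p. 1/2
    d: Dist = {}
    pa = parent.n_alt / 2.0
    if pa > 0:
        d[2] = pa
    if pa < 1:
        d[0] = d.get(0, 0.0) + (1.0 - pa)
    return d


_NULL: Dist = {0: 1.0}  # nullisomic gamete (whole contribution lost)


def fetal_genotype_distribution(
    mat: Genotype, pat: Genotype, h: Hypothesis
) -> Dict[Genotype, float]:
    """Distribution over fetal genotypes given parental genotypes and hypothesis.

    Enumerate the maternal and paternal gamete distributions implied by the
    hypothesis and convolve them.  The resulting genotypes carry
    ``h.copy_number`` alleles.
    """
    if mat.copies != 2 or pat.copies != 2:
        raise ValueError("parental genotypes must be diploid")
    c = COPY_NUMBER[h]
    if h is Hypothesis.D:
        mg, pg, m_sz, p_sz = _normal_gamete(mat), _normal_gamete(pat), 1, 1
    elif h is Hypothesis.MI:
        mg, pg, m_sz, p_sz = _mi_gamete(mat), _normal_gamete(pat), 2, 1
    elif h is Hypothesis.MII:
        mg, pg, m_sz, p_sz = _mii_gamete(mat), _normal_gamete(pat), 2, 1
    elif h is Hypothesis.PI:
        mg, pg, m_sz, p_sz = _normal_gamete(mat), _mi_gamete(pat), 1, 2
    elif h is Hypothesis.PII:
        mg, pg, m_sz, p_sz = _normal_gamete(mat), _mii_gamete(pat), 1, 2
    elif h is Hypothesis.LM:
        mg, pg, m_sz, p_sz = _NULL, _normal_gamete(pat), 0, 1
    elif h is Hypothesis.LP:
        mg, pg, m_sz, p_sz = _normal_gamete(mat), _NULL, 1, 0
    else:  # pragma: no cover
        raise ValueError(h)
    assert m_sz + p_sz == c
    out: Dict[Genotype, float] = {}
    for ma, mp in mg.items():
        for pa, pp in pg.items():
            g = Genotype(ma + pa, c)
            out[g] = out.get(g, 0.0) + mp * pp
    return out


def mixture_weights(
    mat: Genotype, p: float, h: Hypothesis
) -> Dict[Genotype, float]:
    """Fetal-genotype weights pi_k = sum_PAT p(FET | mat, PAT, h) * p(PAT).

    The paternal genotype is marginalized under Hardy-Weinberg priors at
    population allele frequency ``p``; the weights sum to one.
    """
    priors = hwe_genotype_priors(p)
    out: Dict[Genotype, float] = {}
    for pat, w in priors.items():
        for fet, q in fetal_genotype_distribution(mat, pat, h).items():
            out[fet] = out.get(fet, 0.0) + w * q
    return out


def expected_allele_fraction(mat: Genotype, fet: Genotype, ff: float) -> float:
    """Expected A-allele read fraction pA in the maternal/fetal cfDNA mixture.

    pA = [(1-ff)*g_m + ff*g_f] / [2*(1-ff) + ff*c], where g_m and g_f count
    the A alleles of the maternal and fetal genotypes and c is the fetal
    copy number.  Reads are assumed proportional to genomic copies in each
    compartment, so a fetal trisomy also inflates the denominator.
    """
    if not 0.0 <= ff < 1.0:
        raise ValueError(f"fetal fraction must be in [0,1), got {ff}")
    num = (1.0 - ff) * mat.n_alt + ff * fet.n_alt
    den = 2.0 * (1.0 - ff) + ff * fet.copies
    return num / den


def heterozygosity_probability(h: Hypothesis, p_paternal_alt: float = 0.5) -> float:
    """P(fetus carries both alleles) at a maternal heterozygous locus under ``h``.

    The paternal transmitted allele is A with probability ``p_paternal_alt``
    (uniform by default).  Under MI this is exactly 1 (the gamete carries
    both maternal homologs); under MII it is 0.5 regardless of the paternal
    allele distribution's symmetry.
    """
    q = p_paternal_alt
    # enumerate over a synthetic paternal genotype transmitting A w.p. q
    mg: Dist
    if h is Hypothesis.MI:
        mg, c = _mi_gamete(AB), 3
    elif h is Hypothesis.MII:
        mg, c = _mii_gamete(AB), 3
    elif h is Hypothesis.D:
        mg, c = _normal_gamete(AB), 2
    else:
        raise ValueError("heterozygosity probability defined for D/MI/MII")
    total = 0.0
    for ma, mp in mg.items():
        for pa, pp in ((1, q), (0, 1.0 - q)):
            if pp == 0.0:
                continue
            g = Genotype(ma + pa, c)
            if g.is_heterozygous:
                total += mp * pp
    return total


def origin_posterior(
    observed_pattern: str, priors: Tuple[float, float] = (0.5, 0.5)
) -> Dict[str, float]:
    """Posterior over {MI, MII} origin from a single informative locus pattern.

    At a maternal heterozygous locus, a heterozygous fetal genotype has
    likelihood 1 under MI and 0.5 under MII; a homozygous fetal genotype has
    likelihood 0 under MI (absent recombination) and 0.5 under MII.  With
    equal incidence priors a detectable heterozygous locus therefore gives
    P(MI) = 2/3 and P(MII) = 1/3.
    """
    pr_mi, pr_mii = priors
    if pr_mi < 0 or pr_mii < 0 or pr_mi + pr_mii <= 0:
        raise ValueError("priors must be nonnegative and not both zero")
    if observed_pattern in ("heterozygous", "het", "het-compatible"):
        lik_mi, lik_mii = 1.0, 0.5
    elif observed_pattern in ("homozygous", "hom", "hom-discordant"):
        lik_mi, lik_mii = 0.0, 0.5
    else:
        raise ValueError(f"unknown pattern {observed_pattern!r}")
    num_mi = pr_mi * lik_mi
    num_mii = pr_mii * lik_mii
    z = num_mi + num_mii
    if z == 0.0:
        raise ValueError("observed pattern has zero likelihood under both priors")
    return {"MI": num_mi / z, "MII": num_mii / z}


def transmission_table(hypotheses: Iterable[Hypothesis] = tuple(Hypothesis)) -> pd.DataFrame:
    """Tabulate p(FET | mat, pat, H) for inspection/export (one row per entry)."""
    rows = []
    for h in hypotheses:
        for mat in DIPLOID_GENOTYPES:
            for pat in DIPLOID_GENOTYPES:
                for fet, q in sorted(
                    fetal_genotype_distribution(mat, pat, h).items()
                ):
                    rows.append(
                        {
                            "hypothesis": h.value,
                            "maternal": str(mat),
                            "paternal": str(pat),
                            "fetal": str(fet),
                            "probability": q,
                        }
                    )
    return pd.DataFrame(rows)
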