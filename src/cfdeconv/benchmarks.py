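"""Seeded benchmark procedures for caller calibration claims.

These functions re-run the full simulate -> call chain under fixed study
conditions and measure operating characteristics: the combined
read-depth + allele-fraction caller's sensitivity at the QC design floor
(fetal fraction x depth product of 48 with >60 informative SNPs), the
meiotic-origin classification accuracy, and recombination-breakpoint
recovery error.  They are deliberately deterministic given a seed so that
the same numbers are reproducible from the command line and from tests.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np

from .fetal_fraction import ff_from_snp
from .genetics import Hypothesis
from .ploidy import best_single_crossover, call_ploidy, loglik_table, prepare_chromosome
from .rd_cnv import chromosome_zscore, normalize_depth, qc_gates, combined_call
from .simulate import Scenario, simulate_batch, simulate_sample

TRISOMIES = (Hypothesis.MI, Hypothesis.MII, Hypothesis.PI, Hypothesis.PII)


def combined_caller_detects(
    hyp: Hypothesis,
    ff: float,
    depth: float,
    seed: int,
    n_target: int = 500,
    n_reference: int = 500,
    batch_size: int = 8,
    z_threshold: float = 3.0,
) -> bool:
    """Simulate one trisomy inside a euploid batch; True if the combined
    caller flags it.

    The batch mates share the SNP panel and the same study conditions; the
    QC gates are evaluated with the design fetal fraction (the simulation
    condition defining the experiment) while the allele-fraction
    likelihoods use the FF estimated from the sample's reference loci, as
    the caller would in production.
    """
    rng = np.random.default_rng([seed, 77_003])
    seeds = rng.integers(0, 2**31 - 1, size=batch_size)
    common = dict(
        fetal_fraction=ff,
        mean_depth=depth,
        n_target_snps=n_target,
        n_reference_snps=n_reference,
    )
    scenarios = [
        Scenario(ploidy_hypothesis=Hypothesis.D, seed=int(s), **common)
        for s in seeds[:-1]
    ]
    scenarios.append(Scenario(ploidy_hypothesis=hyp, seed=int(seeds[-1]), **common))
    samples, raw = simulate_batch(scenarios)
    z = chromosome_zscore(normalize_depth(raw), "chr21")
    ds = samples[-1]
    ff_hat = ff_from_snp(ds).ff
    call = call_ploidy(ds, ff_hat, chrom="chr21")
    from .pipeline import ff_informative_count

    qc = qc_gates(
        ff,  # the design condition of the experiment
        float(ds.loci("chr21")["depth"].mean()),
        ff_informative_count(ds),
    )
    rd_z = float(z[ds.sample_id])
    return combined_call(rd_z, call, qc, z_threshold=z_threshold).positive


def combined_sensitivity(
    n_reps: int,
    ff: float,
    depth: float,
    seed: int,
    hypotheses: Sequence[Hypothesis] = (Hypothesis.MI, Hypothesis.MII),
    **kwargs,
) -> float:
    """Fraction of seeded trisomy replicates the combined caller flags."""
    hits = 0
    for rep in range(n_reps):
        hyp = hypotheses[rep % len(hypotheses)]
        hits += combined_caller_detects(hyp, ff, depth, seed * 1_000_003 + rep, **kwargs)
    return hits / n_reps


def origin_classification_accuracy(
    n_reps: int,
    ff: float,
    depth: float,
    seed: int,
    n_target: int = 500,
    n_reference: int = 500,
) -> float:
    """Fraction of trisomy replicates whose meiotic origin (MI/MII/PI/PII)
    is correctly classified, conditioning the candidate set on trisomy
    (the dosage gain is taken as established by the read-depth channel)."""
    ok = 0
    for rep in range(n_reps):
        hyp = TRISOMIES[rep % 4]
        sc = Scenario(
            ploidy_hypothesis=hyp,
            fetal_fraction=ff,
            mean_depth=depth,
            n_target_snps=n_target,
            n_reference_snps=n_reference,
            seed=(seed * 99_991 + rep) % 2**31,
        )
        ds = simulate_sample(sc)
        call = call_ploidy(ds, ff_from_snp(ds).ff, chrom="chr21", candidates=TRISOMIES)
        ok += call.origin == hyp.value
    return ok / n_reps


def breakpoint_recovery_errors(
    n_reps: int,
    seed: int,
    true_breakpoint: int = 50,
    n_target: int = 100,
    ff: float = 0.15,
    depth: float = 1000.0,
) -> List[int]:
    """Signed breakpoint errors for seeded MI->MII recombinant trisomies."""
    errors = []
    for rep in range(n_reps):
        sc = Scenario(
            ploidy_hypothesis=Hypothesis.MI,
            crossover_breakpoints=(true_breakpoint,),
            fetal_fraction=ff,
            mean_depth=depth,
            n_target_snps=n_target,
            n_reference_snps=300,
            seed=(seed * 7_919 + rep) % 2**31,
        )
        ds = simulate_sample(sc)
        loci = prepare_chromosome(ds, "chr21")
        ll = loglik_table(loci, ff_from_snp(ds).ff)
        k, _, _ = best_single_crossover(ll, (Hypothesis.MI, Hypothesis.MII))
        k_orig = int(loci["locus_index"].iloc[min(k, len(loci) - 1)])
        errors.append(k_orig - true_breakpoint)
    return errors
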