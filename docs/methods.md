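# Methods

This note documents the models implemented in `cfdeconv`, the parameters
that matter, what the synthetic-data generator does and does not emulate,
and the numerical and design choices made where the method description
left the design open.

## The mixture model

A plasma sample is a two-genome mixture: maternal cfDNA at weight
`1 − FF` and fetal cfDNA at weight `FF`. At a biallelic SNP with maternal
genotype carrying `g_m` copies of the A (alternative) allele and fetal
genotype carrying `g_f` of `c` copies, reads are assumed proportional to
genomic copies in each compartment, so the expected A-allele read fraction
is

    pA = [(1 − FF)·g_m + FF·g_f] / [2(1 − FF) + FF·c].

The same dosage term `[2(1 − FF) + FF·c]/2` scales the expected read
depth, which is what the read-depth (RD) channel detects.

### Transmission model

Fetal genotypes are produced by explicit gamete enumeration:

* `D` (disomy): one allele drawn uniformly from each parent (the Punnett
  square).
* `MI` / `PI` (meiosis-I nondisjunction): the error-parent gamete carries
  **both homologs**; at a heterozygous error-parent locus the trisomic
  fetus is therefore heterozygous with probability 1.
* `MII` / `PII` (meiosis-II): the gamete carries **two copies of one
  homolog**, each homolog with probability 1/2; with the other parent's
  transmitted allele marginalized uniformly the fetal heterozygosity
  probability at an error-parent heterozygous locus is 0.5.
* `LM` / `LP` (monosomy): the corresponding parental contribution is
  absent.

The other parent's genotype is marginalized under Hardy–Weinberg priors
`(p², 2p(1−p), (1−p)²)` at the locus's population allele frequency,
yielding the mixture weights `π_k` over fetal genotypes (they sum to 1 by
construction). MI gametes are modeled without intra-gamete crossover;
recombination is handled at the chromosome-segment level (below).

### Locus likelihood

The A-allele count `NA` at depth `N` is scored with a beta-binomial
mixture,

    p(NA | N, FF, H) = Σ_k π_k · BetaBinom(NA; N, α, β_k),
    β_k = α / pA_k − α,   α = 3000 (default),

i.e. the concentration is anchored by a fixed `α` so the component mean is
exactly `pA_k`. This parameterization is intentionally **not** symmetric
under allele relabeling (mirrored components get different concentrations);
only the `pA = 0.5` component is symmetric. Homozygous components
(`pA ∈ {0,1}`) are clamped to `[ε, 1−ε]` with `ε = 10⁻⁶`, standing in for
un-modeled sequencing error. The log pmf is computed with the
rising-factorial product form
(`log pmf = log C(N,NA) + Σ_{j<NA} log(α+j) + Σ_{j<N−NA} log(β+j) −
Σ_{j<N} log(α+β+j)`) because the log-gamma difference form loses ~10⁻⁶ of
normalization when `β ~ α/ε ≈ 3·10⁹`; the product form keeps
`Σ_NA pmf = 1` to 10⁻⁸ on all components (verified by brute-force
summation in the tests).

### Chromosome statistic and decision rule

Evidence for aneuploidy `H` is the summed log-likelihood difference
`ΔL(H) = Σ_i [log L(D_i) − log L(H_i)]` over usable loci (negative favors
`H`). Before aggregation, allele fractions are Hampel-filtered within each
maternal genotype class (window 11, 3 robust SDs). The MAD floor for this
AF filter is 0.05: in the homozygous classes most loci sit at AF ≈ 0, the
raw MAD collapses, and a smaller floor would flag exactly the informative
loci carrying a fetal allele (excursions up to ~FF/2).

The caller evaluates all six pure aneuploid states plus recombinant
composites and calls the most negative ΔL, subject to two margins:

* **Decision margin** (default 3 log-units, ~20:1 odds): the winner must
  satisfy `ΔL ≤ −3`, guarding against near-tie degeneracies. The clearest
  of these is trisomy vs same-parent monosomy (e.g. MI vs LM), whose AF
  mixtures at maternal-heterozygous loci are almost identical — the read
  **depth** separates them (gain vs loss), which is one reason the final
  decision is a union of the RD and AF channels.
* **Scan margins** for recombinants (below).

For meiotic-origin classification the candidate set is restricted to the
four trisomies (`candidates=` argument), i.e. origin is classified
conditional on a dosage gain established by the RD channel.

### Recombination search

A recombinant chromosome switches between the two nondisjunction
sub-states of the same parent (MI↔MII or PI↔PII). The one-breakpoint
search minimizes `Σ_{1..k}(logL_D − logL_{H1}) + Σ_{k+1..M}(logL_D −
logL_{H2})` over `k` and the leading state; the two-breakpoint search
minimizes the three-segment (H1 | H2 | H1) sum over `b1 < b2`. Both run in
O(M) with prefix sums and a running extremum (total = S + g[b2] − g[b1]
is minimized by the running **maximum** of g[b1]); exhaustive enumeration
is kept as a test oracle. Every segment must contain at least 10 loci,
aligned with the 10-consecutive-heterozygous-locus rule for MI (the
probability of such a run under MII is 2⁻¹⁰ per window).

Because the minimized composite ΔL is a scan statistic (an optimum over
~2M or ~M² segmentations), it beats the pure fit under a pure hypothesis
by selection alone. A composite is therefore only reported when it beats
the best pure hypothesis by a **null-calibrated scan margin**: 17
log-units (one breakpoint) / 23 log-units (two), the 99th percentile of
the null improvement measured on euploid simulations at the design panel
scale (M ≈ 500 loci at the FF × depth QC floor). A true crossover segment
of a few dozen loci clears these margins by an order of magnitude; a flat
2-unit margin admitted spurious recombinants on ~15% of euploid samples.
Reported breakpoints are indices into the chromosome's original locus
order (the Hampel filter drops loci, so search indices are mapped back).
Single-draw breakpoint precision is limited by the spacing of informative
markers — maternal-het loci where the fetus drew a homozygous genotype,
roughly every fifth panel locus — so ±3-locus recovery holds in the
median, not in every draw.

## Read-depth channel and QC

Depths are normalized per sample by the median of per-chromosome median
depths; loci straying > 3 SD from a moving average are masked. For the
**maternal-CNV** per-locus Z-track the normalization is instead by the
reference-chromosome median only: with a compact panel, a CNV spanning
over half a target chromosome would drag the sample-level scale.

PCA batch adjustment estimates per-sample loadings on
reference-chromosome loci only and regresses every locus on those
loadings, so a genuine target-chromosome dosage gain cannot be absorbed.
Default 3 components; the adjustment is for batches with structured depth
noise and is skipped for very small batches.

Chromosome dosage is `Z_i = (R_i − μ_i)/σ_i` with `R_i` the
target/reference read ratio and `μ_i, σ_i` computed leave-one-out across
the processing batch (the tested sample never contaminates its own null).
In the orchestrated pipeline, Z-scores are computed on level-1-QC
survivors only — an excluded maternal-CNV sample otherwise inflates the
batch σ and masks a real trisomy.

QC is two-level: level 1 requires the FF × mean-depth product to reach 48
and no twin or ≥ 3 Mb maternal-CNV flag; level 2 (evaluated only after
level 1 passes) requires more than 60 informative SNPs and no AOH
stripping the target's heterozygous loci. The final call is the union:
RD-positive (|Z| ≥ 3) or AF-positive (winning negative ΔL), each channel
gated by its QC level; samples failing level 2 keep an RD-only call.

## Maternal confounders

* **CNV**: per-locus Z smoothed over a 25-locus rolling mean, clustered
  by mean-shift (bandwidth 1 Z-unit); consecutive-locus cluster runs with
  |center| > 3 become candidates, then an AF consistency check either
  accepts or rejects. Two AF-window rules are provided behind a config
  key: `as-printed` (deletion: het AF > 0.6 or < 0.4; duplication:
  0.4–0.6) and `dosage` (deletion pushes het AF toward 0/1; duplication
  toward 1/3 and 2/3). The physical dosage of a duplicated heterozygous
  locus is 1/3 or 2/3, which the printed windows reject, so the pipeline
  defaults to `dosage`; the printed windows remain available and are the
  default of the low-level detector. Mosaic CNVs below cell fraction 0.6
  are treated as beyond the Z detection limit and are not called.
* **AOH**: maximal runs of ≥ 75 consecutive maternal-homozygous loci;
  runs reset at any non-homozygous locus. AOH findings overlapping a CNV
  finding are dropped (the CNV explains the evidence).
* **Dizygotic twin / non-maternity**: two signals must fire — the
  fraction of maternal-homozygous loci showing a fetal allele must exceed
  1.15× the singleton expectation derived from the panel's allele
  frequencies, and the coefficient of variation of the implied per-locus
  FF must exceed 0.28. With a shared father the co-twin's gamete is
  correlated with the proband's, capping the excess at ~1.3× (at a
  p = 0.5 locus: 3/4 vs 1/2 detection probability), while singletons
  concentrate tightly at 1.0 — hence thresholds between the two
  populations rather than at a hypothetical independent-allele 1.5×.
  FF < 0.02 is an undetermined regime.

## Monogenic-variant screen

Candidates are gated (repeat-mask, ROI, depth ≥ 200 or AF ≥ 1%), then two
filter-in tests run; a variant is positive if **either** passes
(filtering out requires every exclusion criterion to be met):

* **ACD**: `F(x | n, α, β)` with `α = d_v·m·f/(2·d_avg)`,
  `β = d_v·m·(2−f)/(2·d_avg)` — the pre-PCR effective molecule counts
  under a fetal-heterozygote origin (`f` = FF, `m` = effective molecule
  count, default 4000, configurable; `d_v` defaults to site depth). Pass
  when `0.001 ≤ |log₁₀ F(x)| ≤ 10`: counts too low for a fetal variant
  drive `F` below 10⁻¹⁰ (noise), counts at or above the maternal-het
  expectation drive `F → 1`. This is the only reading under which both
  printed bounds act as rejections.
* **FMID**: insert sizes clamped to [20, 600] bp; for each alt read
  (ascending) the nearest surviving ref insert size is removed by binary
  search, distance ties removing the larger value (biasing the survivor
  set short, which makes the shorter-alt test conservative). Survivors are
  compared with alt sizes by Welch's t, Kolmogorov–Smirnov,
  Kruskal–Wallis and Mann–Whitney; positive iff the minimum P ≤ 0.001 and
  the alt median is shorter. The test is not evaluable when either group
  has < 5 reads **or when survivors are outnumbered by alt reads**: near
  AF 0.5 the calibration leaves only the extreme tails of the ref
  distribution, which the rank tests flag spuriously (a 4% false-positive
  path closed by this guard; the ACD filter handles that regime).

## Probe thermodynamics

Melting temperatures use the nearest-neighbor model,
`Tm = 1000·ΔH/(ΔS + R·ln(C_T/4)) − 273.15`, summing stacked-pair ΔH/ΔS
over the duplex with initiation terms at both ends and the entropy salt
correction `0.368·(L−1)·ln[Na⁺]`. The bundled table carries the 10 unified
Watson–Crick stacks and the published internal single-mismatch stacks
(G·T, G·A, C·T, A·C and like-with-like); a context without an entry falls
back to the mean mismatch penalty with a warning. Defaults: C_T = 0.25 µM,
50 mM monovalent salt; one internal mismatch, no dangling ends or loops.
The allele-balanced base is `argmin_N |Tm(N vs ref) − Tm(N vs alt)|`, ties
broken A < C < G < T; probes outside 30–70% GC are excluded.

## Synthetic-data generator

The generator emulates exactly the statistical structure the callers
assume — which makes parameter-recovery tests meaningful but means
passing them shows model-consistency, not robustness to real-assay
artifacts (GC bias, mapping artifacts, UMI errors, sequence-context error
profiles are all out of scope, as is read-level FASTQ/BAM simulation).

Defaults and their rationale:

* Allele-count noise: beta-binomial with the ploidy model's own
  parameterization (`α = 3000`, `β = α/pA − α`), so simulation and
  likelihood agree by construction.
* Depth: negative-binomial, CV 0.10 per locus. The CV is pinned by the
  maternal-CNV detection limit: a duplication at mosaic fraction 0.6
  should sit at the |Z| = 3 cutoff, which implies a per-locus relative SD
  of 0.10 (a constitutional duplication then scores |Z| ≈ 5).
* Insert sizes: maternal Normal(166, 25) bp, fetal offset −10 bp, rounded
  and truncated to [20, 600].
* Panel: per-locus population frequencies uniform on [0.1, 0.9],
  10-kb-spaced positions; ~20% of panel loci end up informative for FF,
  so a 500-SNP target chromosome carries ~100 informative SNPs.
* Trisomy/monosomy scale target-chromosome depth by `1 ± FF/2`; maternal
  CNVs scale both depth and allelic dosage by the mosaic fraction, with
  the gained/lost homolog drawn per locus; dizygotic twins add an
  independent euploid genome sharing both parents; AOH forces homozygous
  maternal genotypes over a segment.
* Seeding: each sample's draws come from its scenario seed; the shared
  SNP panel uses a decorrelated stream (sequence seed), because reusing
  one stream for both the frequencies and the genotypes conditioned on
  them induces spurious dependence.
* Truth labels ride in a sidecar `truth` dict that callers never read.

## Benchmark problem sizes

The packaged benchmarks run at deliberately desk-scale sizes: sensitivity
at the QC floor uses batches of 8 samples × 1000 loci and 300 trisomy
replicates (~1 minute); origin classification uses 60 replicates;
breakpoint recovery uses the 100-locus, FF 0.15, depth-1000 setting with
the median error reported over 9 replicates. The low-FF sensitivity
slope is probed at depth 1200 so that FF 0.04 sits exactly at the
FF × depth = 48 QC floor, with FF 0.02 below it and FF 0.08 above.

## Known limitations

* No mosaic-fetus or triploidy model; no mitotic-origin trisomy; at most
  two crossovers per chromosome.
* The AF channel alone cannot reliably distinguish a trisomy from the
  same-parent monosomy at low FF; the combined decision relies on depth.
* `ff_from_chry` implements the plain ratio convention
  `RDchrY/(RDchrY + RDchrX)`; under the generator's coverage model it
  underestimates FF by ~FF²/2 (a doubled variant is available but off by
  default).
* Maternal-CNV AF windows: both published and dosage-based rules are
  implemented; which one matches the original intent is genuinely
  ambiguous, so the choice is a named config key rather than a guess
  hidden in code.
* The monogenic screen treats post-deduplication depth as effective
  depth, and `m` (pre-PCR molecule count) as a configurable constant.
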