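"""Nearest-neighbor melting temperatures and allele-balanced probe design.

A capture probe that perfectly matches the reference allele binds reference
fragments more tightly than variant fragments, skewing allele fractions at
the few percent level that matters for fetal signal in cfDNA.  The
allele-balanced design picks, at the SNP position of the probe, the base N
minimizing the melting-temperature difference between the probe-reference
and probe-alternative duplexes:

    argmin_N |Tm(N vs ref) - Tm(N vs alt)|,  N in {A, C, G, T}

Tm is computed with the nearest-neighbor model,

    Tm = 1000 * dH / (dS + R ln(C_T/4)) - 273.15,

summing stacked-pair dH/dS over the duplex (initiation terms at both ends,
salt correction 0.368 * (L-1) * ln[Na+] added to dS).  The bundled table
carries the 10 Watson-Crick stacks plus the published internal
single-mismatch stacks; a mismatch context without an entry falls back to
the mean mismatch penalty and is flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "NNParameterTable",
    "HybridizationConditions",
    "ProbeContext",
    "load_default_table",
    "melting_temperature",
    "select_coate_base",
    "design_panel",
]

R_GAS = 1.9872  # cal / (mol K)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


@dataclass(frozen=True)
class HybridizationConditions:
    """Solution conditions for the Tm computation.

    ``oligo_conc`` is the total strand concentration C_T in mol/L (the
    non-self-complementary convention C_T/4 is used); ``monovalent_salt``
    in mol/L enters the entropy salt correction.  The hybridization
    temperature of the wet protocol (65/68 C) is informational only.
    """

    oligo_conc: float = 0.25e-6
    monovalent_salt: float = 0.05
    hybridization_temp: float = 65.0


class NNParameterTable:
    """dH/dS lookup for Watson-Crick and single-mismatch stacks.

    Keys are ``top/bottom`` dinucleotides, top read 5'->3' and bottom
    3'->5'.  Lookup tries the key and its 180-degree rotation; unresolved
    mismatch stacks fall back to the mean mismatch penalty unless
    ``allow_fallback`` is off.
    """

    def __init__(self, entries: Dict[str, Tuple[float, float]],
                 init_at: Tuple[float, float], init_gc: Tuple[float, float],
                 mismatch_keys: Optional[set] = None,
                 allow_fallback: bool = True) -> None:
        self.entries = dict(entries)
        self.init_at = init_at
        self.init_gc = init_gc
        self.mismatch_keys = mismatch_keys or set()
        self.allow_fallback = allow_fallback
        mm = [entries[k] for k in self.mismatch_keys] or [(0.0, 0.0)]
        self._mm_mean = (
            float(np.mean([v[0] for v in mm])),
            float(np.mean([v[1] for v in mm])),
        )

    @staticmethod
    def _rotate(key: str) -> str:
        top, bottom = key.split("/")
        return bottom[::-1] + "/" + top[::-1]

    def stack(self, top: str, bottom: str) -> Tuple[float, float]:
        key = f"{top}/{bottom}"
        if key in self.entries:
            return self.entries[key]
        rot = self._rotate(key)
        if rot in self.entries:
            return self.entries[rot]
        if self.allow_fallback:
            warnings.warn(f"no nearest-neighbor entry for stack {key}; "
                          "using mean mismatch penalty")
            return self._mm_mean
        raise KeyError(f"unresolvable nearest-neighbor context {key}")

    def initiation(self, top_base: str, bottom_base: str) -> Tuple[float, float]:
        pair = {top_base, bottom_base}
        if pair <= {"G", "C"}:
            return self.init_gc
        return self.init_at


_DEFAULT: Optional[NNParameterTable] = None


def load_default_table(allow_fallback: bool = True) -> NNParameterTable:
    global _DEFAULT
    if _DEFAULT is not None and _DEFAULT.allow_fallback == allow_fallback:
        return _DEFAULT
    src = resources.files("cfdeconv.data").joinpath("nn_params.tsv")
    df = pd.read_csv(src, sep="\t", comment="#")
    entries: Dict[str, Tuple[float, float]] = {}
    mm_keys = set()
    init_at = init_gc = (0.0, 0.0)
    for _, row in df.iterrows():
        if row["kind"] == "init":
            if row["step"] == "init_AT":
                init_at = (row["dH"], row["dS"])
            else:
                init_gc = (row["dH"], row["dS"])
            continue
        entries[row["step"]] = (float(row["dH"]), float(row["dS"]))
        if row["kind"] == "mm":
            mm_keys.add(row["step"])
    table = NNParameterTable(entries, init_at, init_gc, mm_keys, allow_fallback)
    _DEFAULT = table
    return table


def _validate_seq(seq: str, name: str) -> str:
    seq = seq.upper()
    if any(b not in _COMP for b in seq):
        raise ValueError(f"{name} contains non-ACGT characters")
    return seq


def melting_temperature(
    probe: str,
    target: str,
    conditions: HybridizationConditions = HybridizationConditions(),
    table: Optional[NNParameterTable] = None,
) -> float:
    """Nearest-neighbor Tm (deg C) of a probe-target duplex.

    ``probe`` and ``target`` are both given 5'->3' and hybridize
    antiparallel; they must be equal length >= 8 with at most one internal
    mismatch (terminal base pairs must match).
    """
    table = table or load_default_table()
    probe = _validate_seq(probe, "probe")
    target = _validate_seq(target, "target")
    if len(probe) != len(target):
        raise ValueError("probe and target must have equal length")
    n = len(probe)
    if n < 8:
        raise ValueError("duplex shorter than 8 bp")
    bottom = target[::-1]  # aligned 3'->5' under the probe
    mismatches = [i for i in range(n) if _COMP[probe[i]] != bottom[i]]
    if len(mismatches) > 1:
        raise ValueError(f"{len(mismatches)} mismatches; at most 1 supported")
    if mismatches and (mismatches[0] == 0 or mismatches[0] == n - 1):
        raise ValueError("terminal mismatch not supported")

    dh, ds = 0.0, 0.0
    for i in range(n - 1):
        h, s = table.stack(probe[i : i + 2], bottom[i : i + 2])
        dh += h
        ds += s
    for end in (0, n - 1):
        h, s = table.initiation(probe[end], bottom[end])
        dh += h
        ds += s
    ds_salt = ds + 0.368 * (n - 1) * np.log(conditions.monovalent_salt)
    denom = ds_salt + R_GAS * np.log(conditions.oligo_conc / 4.0)
    return 1000.0 * dh / denom - 273.15


@dataclass(frozen=True)
class ProbeContext:
    """Sequence context of one SNP on the target strand (all 5'->3')."""

    upstream: str
    ref: str
    alt: str
    downstream: str

    def __post_init__(self) -> None:
        for name, s in (("upstream", self.upstream), ("downstream", self.downstream)):
            _validate_seq(s, name)
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        for b in (self.ref, self.alt):
            if b not in _COMP:
                raise ValueError(f"allele {b!r} not a base")
        if len(self.upstream) + len(self.downstream) + 1 < 8:
            raise ValueError("context too short for a duplex")

    def target(self, allele: str) -> str:
        return self.upstream + allele + self.downstream

    def probe(self, n_base: str) -> str:
        """Probe with base ``n_base`` opposite the SNP (reverse-complement
        of the context elsewhere)."""
        return _revcomp(self.downstream) + n_base + _revcomp(self.upstream)


def select_coate_base(
    ctx: ProbeContext,
    conditions: HybridizationConditions = HybridizationConditions(),
    table: Optional[NNParameterTable] = None,
) -> Tuple[str, Dict[str, float]]:
    """Pick the probe base minimizing |Tm(vs ref) - Tm(vs alt)|.

    Returns (chosen base, {base: delta Tm}).  Ties break in the fixed order
    A < C < G < T.
    """
    table = table or load_default_table()
    deltas: Dict[str, float] = {}
    for n_base in "ACGT":
        probe = ctx.probe(n_base)
        tm_ref = melting_temperature(probe, ctx.target(ctx.ref), conditions, table)
        tm_alt = melting_temperature(probe, ctx.target(ctx.alt), conditions, table)
        deltas[n_base] = tm_ref - tm_alt
    chosen = min("ACGT", key=lambda b: (abs(deltas[b]), b))
    return chosen, deltas


def _gc_fraction(seq: str) -> float:
    return sum(b in "GC" for b in seq) / len(seq)


def design_panel(
    bed: Sequence[Tuple],
    sequences: Dict[str, str],
    flank: int = 10,
    gc_range: Tuple[float, float] = (0.30, 0.70),
    conditions: HybridizationConditions = HybridizationConditions(),
) -> pd.DataFrame:
    """Design one allele-balanced probe per target SNP.

    ``bed`` rows are (chrom, start, end, snp_id, ref, alt) with 0-based
    half-open single-base intervals; ``sequences`` maps chromosome name to
    sequence.  Probes whose GC content falls outside ``gc_range`` are
    excluded (kept in the table with ``excluded`` set and the reason
    logged).  Raises if an interval is not covered by its sequence.
    """
    rows: List[Dict] = []
    for rec in bed:
        chrom, start, end, snp_id, ref, alt = rec[:6]
        start, end = int(start), int(end)
        if end - start != 1:
            raise ValueError(f"{snp_id}: expected a single-base SNP interval")
        if chrom not in sequences:
            raise ValueError(f"{snp_id}: chromosome {chrom} not in FASTA")
        seq = sequences[chrom].upper()
        if start - flank < 0 or end + flank > len(seq):
            raise ValueError(f"{snp_id}: interval {chrom}:{start}-{end} "
                             "outside the supplied sequence")
        up = seq[start - flank : start]
        down = seq[end : end + flank]
        fasta_ref = seq[start]
        if ref.upper() != fasta_ref:
            raise ValueError(f"{snp_id}: ref {ref} != FASTA base {fasta_ref}")
        ctx = ProbeContext(up, ref.upper(), alt.upper(), down)
        chosen, deltas = select_coate_base(ctx, conditions)
        probe = ctx.probe(chosen)
        gc = _gc_fraction(probe)
        excluded = not (gc_range[0] <= gc <= gc_range[1])
        rows.append(
            {
                "snp_id": snp_id,
                "chrom": chrom,
                "pos": start,
                "probe": probe,
                "chosen_base": chosen,
                "dTm_A": deltas["A"],
                "dTm_C": deltas["C"],
                "dTm_G": deltas["G"],
                "dTm_T": deltas["T"],
                "gc": gc,
                "excluded": excluded,
            }
        )
        if excluded:
            warnings.warn(f"{snp_id}: probe GC {gc:.2f} outside "
                          f"[{gc_range[0]:.2f}, {gc_range[1]:.2f}]; excluded")
    return pd.DataFrame(rows)
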