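"""Codon usage, start/stop classification, GC3s and Wright's effective
number of codons under the invertebrate mitochondrial code.

The effective number of codons (Nc) measures how far codon usage departs
from uniformity: Nc ranges from the number of amino-acid families (one
codon per amino acid, maximal bias) up to the number of sense codons (no
bias). For each synonymous family with n codons and within-family
frequencies p̂_i, the codon homozygosity is

    F̂ = (n·Σ p̂_i² − 1) / (n − 1)

and Nc sums, over the degeneracy classes k of the code's family
partition, (number of k-fold families) / (mean F̂ of that class).

Under the invertebrate mitochondrial code (translation table 5) the
default partition keeps Leu (6 codons) and Ser (8 codons: UCN + AGN) as
single families, giving 12 two-fold, 6 four-fold, one six-fold and one
eight-fold family — 20 families, 62 sense codons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.Data import CodonTable
from scipy import stats

INVERTEBRATE_MITO_TABLE_ID = 5

_TABLE = CodonTable.unambiguous_dna_by_id[INVERTEBRATE_MITO_TABLE_ID]
ALL_CODONS = tuple("".join(c) for c in product("TCAG", repeat=3))
STOP_CODONS = tuple(_TABLE.stop_codons)            # TAA, TAG under table 5
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)
CODON_TO_AA = {c: _TABLE.forward_table[c] for c in SENSE_CODONS}

START_CODONS = ("ATA", "ATG", "ATT", "ATC", "TTG", "GTG")


def family_partition(split_leu_ser: bool = False) -> dict[str, tuple[str, ...]]:
    """Synonymous-family partition of the sense codons.

    By default the six-codon Leu and eight-codon Ser families stay whole.
    With ``split_leu_ser`` they are split by first-two-base block
    (Leu → TTR 2-fold + CTN 4-fold; Ser → TCN 4-fold + AGN 4-fold), the
    other convention ENC implementations use.
    """
    fams: dict[str, list[str]] = {}
    for codon, aa in CODON_TO_AA.items():
        if split_leu_ser and aa in ("L", "S"):
            key = f"{aa}_{codon[:2]}"
        else:
            key = aa
        fams.setdefault(key, []).append(codon)
    return {k: tuple(sorted(v)) for k, v in fams.items()}


# ---------------------------------------------------------------------------
# codon usage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonUsageTable:
    counts: Mapping[str, int]
    percents: Mapping[str, float]
    n_codons: int


def iter_codons(cds: str) -> Iterable[str]:
    """Complete in-frame codons of one CDS (trailing partial codon dropped)."""
    s = cds.upper()
    for i in range(0, len(s) - len(s) % 3, 3):
        yield s[i:i + 3]


def codon_counts(cds_set: Sequence[str], include_stops: bool = False) -> dict[str, int]:
    counts = {c: 0 for c in ALL_CODONS}
    for cds in cds_set:
        for codon in iter_codons(cds):
            if codon in counts:   # skips N-containing codons
                counts[codon] += 1
    if not include_stops:
        for c in STOP_CODONS:
            counts[c] = 0
    return counts


def codon_usage(cds_set: Sequence[str]) -> CodonUsageTable:
    """Pooled codon usage over the CDS of one genome.

    Stop codons and incomplete trailing codons are excluded; percents are
    100·count/total over sense codons.
    """
    if not cds_set:
        raise ValueError("empty CDS set")
    counts = codon_counts(cds_set)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no complete sense codons in CDS set")
    percents = {c: 100.0 * n / total for c, n in counts.items()}
    return CodonUsageTable(counts=counts, percents=percents, n_codons=total)


def classify_start_stop(cds: str) -> tuple[str, str, bool, bool]:
    """(start codon, stop, start_is_standard, stop_is_truncated) for one CDS.

    A CDS whose length is not a multiple of 3 ends in a truncated stop
    (T or TA) completed post-transcriptionally by polyadenylation. An
    internal stop raises a warning but does not reject the CDS.
    """
    s = cds.upper()
    if len(s) < 4:
        raise ValueError("CDS shorter than 4 nt")
    start = s[:3]
    rem = len(s) % 3
    if rem == 0:
        stop, truncated = s[-3:], False
        body = s[3:-3]
    else:
        stop, truncated = s[-rem:], True
        body = s[3:len(s) - rem]
    if any(c in STOP_CODONS for c in iter_codons(body)):
        warnings.warn("internal stop codon in CDS")
    return start, stop, start in START_CODONS, truncated


# ---------------------------------------------------------------------------
# Wright's effective number of codons and GC3s
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EncResult:
    nc: float
    gc3s: float
    family_homozygosity: Mapping[int, float]
    n_codons: int


def _family_f_hat(counts: Sequence[int]) -> Optional[float]:
    n = sum(counts)
    if n < 2:
        return None
    p = np.asarray(counts, dtype=float) / n
    return (n * float(np.sum(p * p)) - 1.0) / (n - 1.0)


def enc(cds_set: Sequence[str], split_leu_ser: bool = False) -> EncResult:
    """Wright's Nc and GC3s from the pooled codon counts of a CDS set.

    Families with fewer than 2 codons take the mean homozygosity of their
    degeneracy class; a class with no measurable family falls back to the
    reciprocal of its degeneracy (the uniform-usage value). Nc is capped
    at the number of sense codons.
    """
    counts = codon_counts(cds_set)
    if sum(counts.values()) < 2:
        raise ValueError("fewer than 2 sense codons")
    fams = family_partition(split_leu_ser)
    by_class: dict[int, list[Optional[float]]] = {}
    for codons in fams.values():
        k = len(codons)
        by_class.setdefault(k, []).append(_family_f_hat([counts[c] for c in codons]))
    nc = 0.0
    class_means: dict[int, float] = {}
    for k, fhats in sorted(by_class.items()):
        measured = [f for f in fhats if f is not None and f > 0]
        mean_f = float(np.mean(measured)) if measured else 1.0 / k
        class_means[k] = mean_f
        nc += len(fhats) / mean_f
    nc = min(nc, float(len(SENSE_CODONS)))
    return EncResult(nc=nc, gc3s=gc3s(cds_set), family_homozygosity=class_means,
                     n_codons=sum(counts.values()))


def gc3s(cds_set: Sequence[str], synonymous_only: bool = True) -> float:
    """G+C fraction at third codon positions.

    ``synonymous_only`` restricts to codons of synonymous (≥2-fold)
    families and excludes stops — under translation table 5 every
    amino-acid family is at least two-fold, so the restriction only
    removes stop codons.
    """
    counts = codon_counts(cds_set, include_stops=not synonymous_only)
    if synonymous_only:
        usable = {c: n for c, n in counts.items()
                  if c in CODON_TO_AA and len([x for x in CODON_TO_AA
                                               if CODON_TO_AA[x] == CODON_TO_AA[c]]) >= 2}
    else:
        usable = counts
    total = sum(usable.values())
    if total == 0:
        raise ValueError("no usable codons for GC3s")
    gc = sum(n for c, n in usable.items() if c[2] in "GC")
    return gc / total


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int


def enc_gc3s_correlation(results: Sequence[EncResult]) -> CorrelationResult:
    """Pearson correlation between Nc and GC3s across genomes."""
    if len(results) < 3:
        raise ValueError("need at least 3 genomes")
    nc = np.array([r.nc for r in results])
    g3 = np.array([r.gc3s for r in results])
    if np.ptp(nc) == 0 or np.ptp(g3) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, _ = stats.pearsonr(nc, g3)
    return CorrelationResult(r=float(r), n=len(results))
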