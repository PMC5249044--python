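"""Base-composition statistics: AT/GC skew, AT content, codon-position AT
content and sliding-window profiles.

Skews follow the usual strand-asymmetry definitions
``AT-skew = (A−T)/(A+T)`` and ``GC-skew = (G−C)/(G+C)``; both flip sign
under reverse complement. N bases are excluded from every count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .genome_io import MitoGenome, gene_sequence


@dataclass(frozen=True)
class CompositionStats:
    n_A: int
    n_C: int
    n_G: int
    n_T: int

    @property
    def total(self) -> int:
        return self.n_A + self.n_C + self.n_G + self.n_T

    @property
    def at_percent(self) -> Optional[float]:
        t = self.total
        return 100.0 * (self.n_A + self.n_T) / t if t else None

    @property
    def gc_percent(self) -> Optional[float]:
        t = self.total
        return 100.0 * (self.n_G + self.n_C) / t if t else None

    @property
    def at_skew(self) -> Optional[float]:
        d = self.n_A + self.n_T
        return (self.n_A - self.n_T) / d if d else None

    @property
    def gc_skew(self) -> Optional[float]:
        d = self.n_G + self.n_C
        return (self.n_G - self.n_C) / d if d else None


@dataclass(frozen=True)
class SkewProfile:
    window: int
    step: int
    metric: str
    positions: tuple[float, ...]
    values: tuple[Optional[float], ...]


def composition_stats(seq: str) -> CompositionStats:
    """Exact base counts and ratio statistics for one sequence.

    N (and any ambiguity code) is ignored; an empty or all-N sequence is
    an error. A skew whose denominator is zero is reported as None.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    stats = CompositionStats(s.count("A"), s.count("C"), s.count("G"), s.count("T"))
    if stats.total == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return stats


_METRICS = ("at_skew", "gc_skew", "at_percent")


def sliding_window_profile(seq: str, window: int = 100, step: int = 10,
                           metric: str = "at_skew", circular: bool = False) -> SkewProfile:
    """Windowed composition profile along a sequence.

    Windows start at 0, step, 2·step, …; for a linear sequence the last
    partial window is dropped; for a circular one windows wrap the origin
    so every start position up to len(seq) is covered. Positions are
    window midpoints on the input coordinate system.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    L = len(seq)
    if window > L:
        raise ValueError(f"window {window} exceeds sequence length {L}")
    if step < 1:
        raise ValueError("step must be >= 1")
    s = seq.upper()
    starts = range(0, L if circular else L - window + 1, step)
    positions, values = [], []
    for start in starts:
        if start + window <= L:
            win = s[start:start + window]
        else:
            win = s[start:] + s[:start + window - L]
        try:
            st = composition_stats(win)
            values.append(getattr(st, metric))
        except ValueError:  # all-N window
            values.append(None)
        positions.append(start + window / 2.0)
    return SkewProfile(window=window, step=step, metric=metric,
                       positions=tuple(positions), values=tuple(values))


def genome_partition_stats(genome: MitoGenome) -> pd.DataFrame:
    """Composition per annotation category.

    One row per category in {whole, PCGs, rRNAs, tRNAs, CRs, spacers};
    gene-bearing categories are measured on coding-sense sequences, so a
    (−)-strand gene contributes its mRNA-like composition. Empty
    categories get zero length and missing statistics.
    """
    cats = {"whole": [genome.sequence],
            "PCGs": [], "rRNAs": [], "tRNAs": [], "CRs": [], "spacers": []}
    kind_to_cat = {"PCG": "PCGs", "rRNA": "rRNAs", "tRNA": "tRNAs",
                   "CR": "CRs", "spacer": "spacers"}
    for f in genome.features:
        cats[kind_to_cat[f.kind]].append(gene_sequence(genome, f))
    rows = []
    for cat, seqs in cats.items():
        joined = "".join(seqs)
        if joined:
            st = composition_stats(joined)
            rows.append({"category": cat, "length": len(joined),
                         "at_percent": st.at_percent, "gc_percent": st.gc_percent,
                         "at_skew": st.at_skew, "gc_skew": st.gc_skew})
        else:
            rows.append({"category": cat, "length": 0, "at_percent": None,
                         "gc_percent": None, "at_skew": None, "gc_skew": None})
    return pd.DataFrame(rows).set_index("category")


def per_gene_stats(genome: MitoGenome) -> pd.DataFrame:
    """Composition of every annotated feature on its coding sense."""
    rows = []
    for f in genome.features:
        seq = gene_sequence(genome, f)
        st = composition_stats(seq)
        rows.append({"gene": f.label, "copy_index": f.copy_index, "kind": f.kind,
                     "strand": f.strand, "length": f.length(len(genome)),
                     "at_percent": st.at_percent, "at_skew": st.at_skew,
                     "gc_skew": st.gc_skew})
    return pd.DataFrame(rows)


def at_by_codon_position(cds_set: Sequence[str]) -> tuple[float, float, float]:
    """Pooled AT% at codon positions 1, 2 and 3 over a set of CDS.

    Each CDS is framed from its first base; the 1–2 trailing nucleotides
    of a truncated-stop CDS fall outside any complete codon and are
    excluded.
    """
    counts = [[0, 0], [0, 0], [0, 0]]  # per position: [AT, total]
    for cds in cds_set:
        if len(cds) < 3:
            raise ValueError("CDS shorter than one codon")
        s = cds.upper()
        for i in range(0, len(s) - len(s) % 3, 3):
            for pos in range(3):
                b = s[i + pos]
                if b == "N":
                    continue
                counts[pos][1] += 1
                if b in "AT":
                    counts[pos][0] += 1
    if any(t == 0 for _, t in counts):
        raise ValueError("no countable codons")
    return tuple(100.0 * at / t for at, t in counts)
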