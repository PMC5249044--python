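"""Intergenic spacers and control-region feature detection.

The mitochondrial control region (CR) carries replication/transcription
signals and, in invertebrates, is recognized indirectly through four
sequence features: a poly-T stretch, tandemly repeated sequence, hairpin
(inverted-repeat) structures, and elevated AT content. Candidate regions
are the unannotated intervals of a genome; each is scanned for the four
feature classes and ranked by how many are present.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from .composition import composition_stats
from .genome_io import MitoGenome, revcomp
from .trna_dup import IdentityResult, pairwise_identity

POLY_T_MIN = 10          # smallest run length that counts as a CR poly-T
REPEAT_SEED = 12         # exact-match seed length for tandem repeats
REPEAT_MIN_PERIOD = 10
REPEAT_MAX_PERIOD = 200
REPEAT_MIN_COPIES = 2.0
REPEAT_MIN_MATCH = 0.8   # adjacent-copy agreement
HAIRPIN_MIN_STEM = 6     # perfect Watson-Crick pairs
HAIRPIN_LOOP_RANGE = (3, 30)
CANDIDATE_MIN_LEN = 50
AT_EXCESS_MIN = 5.0      # percentage points above genome AT%


@dataclass(frozen=True)
class NoncodingRegion:
    start: int
    end: int            # half-open; start > end encodes a wrap
    length: int
    at_percent: Optional[float]
    flanking: tuple[str, str]   # (upstream label, downstream label)
    annotated_cr: bool = False


@dataclass(frozen=True)
class CRCandidate:
    region: NoncodingRegion
    poly_t: int
    repeats: tuple[tuple[int, float, tuple[int, int]], ...]  # (period, copies, (start, end))
    hairpins: tuple[tuple[int, int, int], ...]               # (stem, loop, position)
    at_excess: Optional[float]
    score: int


def region_sequence(genome: MitoGenome, region: NoncodingRegion) -> str:
    if region.start > region.end:
        return genome.sequence[region.start:] + genome.sequence[:region.end]
    return genome.sequence[region.start:region.end]


def noncoding_regions(genome: MitoGenome, include_annotated_cr: bool = True
                      ) -> list[NoncodingRegion]:
    """Maximal unannotated intervals between consecutive features.

    On a circular genome the gap spanning the origin is included. Regions
    the input annotates as CR are reported with ``annotated_cr=True``;
    spacer annotations are treated as unannotated sequence (they are
    exactly what this operation recovers).
    """
    n = len(genome)
    out: list[NoncodingRegion] = []

    def _mk(start: int, end: int, up: str, down: str, is_cr: bool = False):
        seq = (genome.sequence[start:end] if end > start
               else genome.sequence[start:] + genome.sequence[:end])
        if not seq:
            return
        try:
            at = composition_stats(seq).at_percent
        except ValueError:
            at = None
        out.append(NoncodingRegion(start=start, end=end, length=len(seq),
                                   at_percent=at, flanking=(up, down),
                                   annotated_cr=is_cr))

    if include_annotated_cr:
        for f in genome.features:
            if f.kind == "CR":
                _mk(f.start, f.end, "", "", is_cr=True)

    # occupied intervals: genes, rRNAs, tRNAs and (when reported separately)
    # annotated CRs; spacer annotations are what this operation recovers
    occ: list[tuple[int, int, str]] = []
    for f in genome.features:
        if f.kind == "spacer":
            continue
        if f.wraps:
            occ.append((f.start, n, f.label))
            occ.append((0, f.end, f.label))
        else:
            occ.append((f.start, f.end, f.label))
    if not occ:
        if not out:
            _mk(0, n, "", "")
        return out
    occ.sort()
    merged: list[list] = [list(occ[0])]
    for s, e, lab in occ[1:]:
        if s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1][1] = e
                merged[-1][2] = lab
        else:
            merged.append([s, e, lab])
    for i, (s, e, lab) in enumerate(merged):
        if i + 1 < len(merged):
            nxt_s, nxt_lab = merged[i + 1][0], merged[i + 1][2]
            if nxt_s > e:
                _mk(e, nxt_s, lab, nxt_lab)
        else:  # closure after the last interval
            first_s, first_lab = merged[0][0], merged[0][2]
            if genome.circular:
                if e < n or first_s > 0:
                    gap_start = e % n
                    if gap_start != first_s:
                        _mk(gap_start, first_s, lab, first_lab)
                    elif e < n and first_s == 0:
                        pass
            else:
                if e < n:
                    _mk(e, n, lab, "")
                if first_s > 0:
                    _mk(0, first_s, "", first_lab)
    return out


def poly_t_runs(seq: str, min_len: int = POLY_T_MIN) -> list[tuple[int, int, str]]:
    """Maximal T-homopolymers of length ≥ min_len on either strand.

    Returns (position, length, strand); an A-run on the given strand is a
    T-run on the complementary strand and is reported with strand '−'.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    s = seq.upper()
    runs = []
    for base, strand in (("T", "+"), ("A", "-")):
        for m in re.finditer(f"{base}{{{min_len},}}", s):
            runs.append((m.start(), m.end() - m.start(), strand))
    return sorted(runs)


def tandem_repeats(seq: str, seed: int = REPEAT_SEED,
                   min_period: int = REPEAT_MIN_PERIOD,
                   max_period: int = REPEAT_MAX_PERIOD,
                   min_copies: float = REPEAT_MIN_COPIES,
                   min_match: float = REPEAT_MIN_MATCH
                   ) -> list[tuple[int, float, tuple[int, int]]]:
    """Seed-and-extend tandem repeat detection.

    For each candidate period p, positions where the sequence matches
    itself p letters downstream are found; an exact seed (min(seed, p)
    consecutive matches) is extended in both directions while the overall
    adjacent-copy agreement stays ≥ min_match. Overlapping calls are
    merged, keeping the longest span. Returns (period, copies, (start,
    end)) tuples with copies = span/period.
    """
    s = seq.upper()
    L = len(s)
    calls: list[tuple[int, float, tuple[int, int]]] = []
    for p in range(min_period, min(max_period, L // 2) + 1):
        k = min(seed, p)
        eq = [s[i] == s[i + p] for i in range(L - p)]
        i = 0
        used_until = -1
        while i < len(eq):
            if not eq[i]:
                i += 1
                continue
            j = i
            while j < len(eq) and eq[j]:
                j += 1
            if j - i >= k and i > used_until:
                # greedy extension with mismatch tolerance
                lo, hi = i, j          # [lo, hi) matched stretch in eq-space
                matches, total = j - i, j - i
                h = j
                while h < len(eq) and (matches + (1 if eq[h] else 0)) / (total + 1) >= min_match:
                    matches += 1 if eq[h] else 0
                    total += 1
                    h += 1
                    if eq[h - 1]:
                        hi = h
                g = lo
                while g > used_until + 1 and (matches + (1 if eq[g - 1] else 0)) / (total + 1) >= min_match:
                    matches += 1 if eq[g - 1] else 0
                    total += 1
                    g -= 1
                    if eq[g]:
                        lo = g
                span = (hi - lo) + p
                copies = span / p
                if copies >= min_copies:
                    calls.append((p, round(copies, 2), (lo, lo + span)))
                used_until = hi - 1
                i = hi
            else:
                i = j
    # merge overlapping calls; prefer most copies (a period harmonic spans
    # as long as the fundamental but has proportionally fewer copies),
    # then longest span, then smallest period
    calls.sort(key=lambda c: (-c[1], -(c[2][1] - c[2][0]), c[0]))
    kept: list[tuple[int, float, tuple[int, int]]] = []
    for c in calls:
        s0, e0 = c[2]
        overlap = False
        for kc in kept:
            s1, e1 = kc[2]
            inter = max(0, min(e0, e1) - max(s0, s1))
            if inter > 0.5 * min(e0 - s0, e1 - s1):
                overlap = True
                break
        if not overlap:
            kept.append(c)
    return sorted(kept, key=lambda c: c[2][0])


_PAIR = {"A": "T", "T": "A", "G": "C", "C": "G"}


def hairpins(seq: str, min_stem: int = HAIRPIN_MIN_STEM,
             loop_range: tuple[int, int] = HAIRPIN_LOOP_RANGE
             ) -> list[tuple[int, int, int]]:
    """Perfect inverted Watson-Crick repeats: (stem, loop, position).

    Position is the first base of the left stem arm; stems are maximal
    (a reported hairpin is not a sub-stem of a longer one with the same
    loop).
    """
    s = seq.upper()
    L = len(s)
    lo, hi = loop_range
    found = []
    for loop in range(lo, hi + 1):
        for i1 in range(L):          # i1 = index of last base of left arm
            i2 = i1 + loop + 1       # first base of right arm
            if i2 >= L:
                break
            # maximal only: the pair just inside the loop must not extend
            a, b = i1, i2
            stem = 0
            while a >= 0 and b < L and _PAIR.get(s[a]) == s[b]:
                stem += 1
                a -= 1
                b += 1
            if stem >= min_stem:
                # skip if extendable inward (handled by a smaller loop)
                found.append((stem, loop, a + 1))
    # deduplicate: same arms found once
    return sorted(set(found), key=lambda h: (h[2], h[1]))


def scan_region(genome: MitoGenome, region: NoncodingRegion,
                poly_t_min: int = POLY_T_MIN,
                at_excess_min: float = AT_EXCESS_MIN) -> CRCandidate:
    """Score one noncoding region for the four CR feature classes.

    Regions containing N runs are scanned per contiguous N-free block.
    """
    seq = region_sequence(genome, region)
    genome_at = composition_stats(genome.sequence).at_percent
    blocks = [b for b in re.split("N+", seq.upper()) if b]
    best_t, reps, hps = 0, [], []
    offset = 0
    for block in blocks:
        pos = seq.upper().find(block, offset)
        for (p, ln, strand) in poly_t_runs(block, min_len=1):
            best_t = max(best_t, ln)
        for (per, cop, (s0, e0)) in tandem_repeats(block):
            reps.append((per, cop, (pos + s0, pos + e0)))
        for (stem, loop, hpos) in hairpins(block):
            hps.append((stem, loop, pos + hpos))
        offset = pos + len(block)
    at_excess = (region.at_percent - genome_at) if region.at_percent is not None else None
    score = sum([best_t >= poly_t_min, len(reps) > 0, len(hps) > 0,
                 at_excess is not None and at_excess >= at_excess_min])
    return CRCandidate(region=region, poly_t=best_t, repeats=tuple(reps),
                       hairpins=tuple(hps), at_excess=at_excess, score=score)


def rank_cr_candidates(genome: MitoGenome, min_len: int = CANDIDATE_MIN_LEN
                       ) -> list[CRCandidate]:
    """Noncoding regions ranked as control-region candidates.

    Score counts the feature classes present (poly-T ≥ 10, any tandem
    repeat, any hairpin, AT ≥ 5 points above genome); ties break by
    length. Regions shorter than ``min_len`` are excluded from candidacy
    (but still reported by noncoding_regions).
    """
    regions = [r for r in noncoding_regions(genome) if r.length >= min_len]
    if not regions:
        warnings.warn(f"{genome.id}: no noncoding region >= {min_len} b.p.")
        return []
    cands = [scan_region(genome, r) for r in regions]
    return sorted(cands, key=lambda c: (-c.score, -c.region.length))


def region_identity(a: str, b: str) -> IdentityResult:
    """Percent identity of two (non-coding) region sequences; same global
    alignment and scoring as tRNA identity."""
    return pairwise_identity(a, b)
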