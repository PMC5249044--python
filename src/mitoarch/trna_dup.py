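"""Duplicated tRNA genes, pairwise identity and remolding calls.

tRNA remolding is the switch of a duplicated tRNA's identity via
anticodon mutation; it leaves a sequence more similar to a non-cognate
isoacceptor than its own label suggests. Detection here is nucleotide
level: every copy of a duplicated label is globally aligned against all
other tRNA genes of the genome, and a copy whose best non-self donor
exceeds an identity threshold is called a remolding candidate.

Global alignment uses fixed, documented scoring (match +1, mismatch −1,
gap −2, linear gaps) with a deterministic high-road traceback (on score
ties: diagonal, then gap in the second sequence, then gap in the first);
identity is matches over alignment columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .genome_io import GeneFeature, MitoGenome, gene_sequence

DEFAULT_MATCH = 1
DEFAULT_MISMATCH = -1
DEFAULT_GAP = -2

DONOR_IDENTITY_THRESHOLD = 65.0   # percent; remolded-candidate cut-off
WITHIN_IDENTITY_THRESHOLD = 85.0  # percent; recent-duplicate cut-off


def needleman_wunsch(a: str, b: str, match: int = DEFAULT_MATCH,
                     mismatch: int = DEFAULT_MISMATCH,
                     gap: int = DEFAULT_GAP) -> tuple[str, str, int]:
    """Global alignment with linear gap costs.

    Returns (aligned_a, aligned_b, score). Traceback is deterministic:
    on ties prefer the diagonal, then the move consuming ``a`` (gap in
    ``b``), then the move consuming ``b``.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1), dtype=np.int64)
    score[:, 0] = gap * np.arange(n + 1)
    score[0, :] = gap * np.arange(m + 1)
    eq = (np.frombuffer(a.encode(), dtype=np.uint8)[:, None]
          == np.frombuffer(b.encode(), dtype=np.uint8)[None, :])
    sub = np.where(eq, match, mismatch)
    for i in range(1, n + 1):
        row_prev = score[i - 1]
        diag = row_prev[:-1] + sub[i - 1]
        row = score[i]
        row[0] = gap * i
        for j in range(1, m + 1):
            row[j] = max(diag[j - 1], row_prev[j] + gap, row[j - 1] + gap)
    # traceback
    out_a, out_b = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + sub[i - 1, j - 1]:
            out_a.append(a[i - 1]); out_b.append(b[j - 1]); i -= 1; j -= 1
        elif i > 0 and score[i, j] == score[i - 1, j] + gap:
            out_a.append(a[i - 1]); out_b.append("-"); i -= 1
        else:
            out_a.append("-"); out_b.append(b[j - 1]); j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), int(score[n, m])


@dataclass(frozen=True)
class IdentityResult:
    seq_a: str
    seq_b: str
    percent_identity: float
    aligned_length: int
    matches: int


def pairwise_identity(a: str, b: str, match: int = DEFAULT_MATCH,
                      mismatch: int = DEFAULT_MISMATCH,
                      gap: int = DEFAULT_GAP) -> IdentityResult:
    """Percent identity from a global alignment (matches / columns, 2 d.p.)."""
    aa, ab, _ = needleman_wunsch(a.upper(), b.upper(), match, mismatch, gap)
    matches = sum(x == y and x != "-" for x, y in zip(aa, ab))
    pid = round(100.0 * matches / len(aa), 2)
    return IdentityResult(seq_a=a, seq_b=b, percent_identity=pid,
                          aligned_length=len(aa), matches=matches)


# ---------------------------------------------------------------------------
# duplicate detection and remolding calls
# ---------------------------------------------------------------------------

def find_duplicates(genome: MitoGenome) -> dict[str, list[GeneFeature]]:
    """tRNA labels present in ≥2 copies, with their features."""
    by_label: dict[str, list[GeneFeature]] = {}
    for f in genome.features_of_kind("tRNA"):
        by_label.setdefault(f.label, []).append(f)
    return {lab: feats for lab, feats in by_label.items() if len(feats) >= 2}


@dataclass(frozen=True)
class RemoldingCall:
    duplicated_label: str
    copies: tuple[GeneFeature, ...]
    within_identity: float
    best_donor: Optional[str]
    donor_identity: Optional[float]
    call: str  # recent-duplicate | remolded-candidate | ambiguous


def remolding_scan(genome: MitoGenome,
                   donor_threshold: float = DONOR_IDENTITY_THRESHOLD,
                   within_threshold: float = WITHIN_IDENTITY_THRESHOLD) -> list[RemoldingCall]:
    """Classify each duplicated tRNA label of a genome.

    Each copy is aligned against every other tRNA gene; the best non-self
    donor identity of either copy decides the call: remolded-candidate if
    it reaches ``donor_threshold``, else recent-duplicate if the copies'
    mutual identity reaches ``within_threshold``, else ambiguous.
    """
    trnas = genome.features_of_kind("tRNA")
    calls = []
    for label, copies in sorted(find_duplicates(genome).items()):
        seqs = [gene_sequence(genome, f) for f in copies]
        within = min(pairwise_identity(x, y).percent_identity
                     for i, x in enumerate(seqs) for y in seqs[i + 1:])
        best_donor, donor_id = None, None
        for other in trnas:
            if other.label == label:
                continue
            oseq = gene_sequence(genome, other)
            for s in seqs:
                pid = pairwise_identity(s, oseq).percent_identity
                if donor_id is None or pid > donor_id:
                    best_donor, donor_id = other.label, pid
        if donor_id is not None and donor_id >= donor_threshold:
            call = "remolded-candidate"
        elif within >= within_threshold or (donor_id is None or within >= donor_id):
            call = "recent-duplicate"
        else:
            call = "ambiguous"
        calls.append(RemoldingCall(duplicated_label=label, copies=tuple(copies),
                                   within_identity=within, best_donor=best_donor,
                                   donor_identity=donor_id, call=call))
    return calls


def identity_matrix(genome: MitoGenome):
    """All-against-all percent identity of a genome's tRNA genes as a
    labelled DataFrame (rows/columns = tRNA features)."""
    import pandas as pd
    trnas = genome.features_of_kind("tRNA")
    labels = [f.label if f.copy_index == 1 else f"{f.label}/{f.copy_index}" for f in trnas]
    seqs = [gene_sequence(genome, f) for f in trnas]
    k = len(seqs)
    mat = np.full((k, k), 100.0)
    for i in range(k):
        for j in range(i + 1, k):
            pid = pairwise_identity(seqs[i], seqs[j]).percent_identity
            mat[i, j] = mat[j, i] = pid
    return pd.DataFrame(mat, index=labels, columns=labels)
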