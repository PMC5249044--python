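"""Per-gene nucleotide diversity (π) from multiple alignments.

π is the average proportion of differing sites over all sequence pairs.
Sites containing a gap or N in any row are excluded before counting
("complete deletion", the DnaSP default), and no sample-size correction
is applied, matching DnaSP's per-site π.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO

from .trna_dup import needleman_wunsch

log = logging.getLogger("mitoarch")

_BASES = "ACGT"


@dataclass(frozen=True)
class GeneAlignment:
    gene: str
    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows have unequal lengths")
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def subset(self, taxa: Sequence[str]) -> "GeneAlignment":
        keep = [i for i, t in enumerate(self.taxa) if t in set(taxa)]
        return GeneAlignment(gene=self.gene,
                             taxa=tuple(self.taxa[i] for i in keep),
                             rows=tuple(self.rows[i] for i in keep))


@dataclass(frozen=True)
class PiResult:
    gene: str
    pi: float
    n_taxa: int
    n_sites: int


def read_alignment(path, gene: Optional[str] = None) -> GeneAlignment:
    """Read one per-gene alignment from aligned FASTA."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if gene is None:
        gene = str(path).rsplit("/", 1)[-1].split(".")[0]
    return GeneAlignment(gene=gene,
                         taxa=tuple(r.id for r in records),
                         rows=tuple(str(r.seq).upper() for r in records))


def pi(alignment: GeneAlignment, pairwise_deletion: bool = False) -> PiResult:
    """Average pairwise per-site nucleotide difference.

    With complete deletion (default) every column containing a non-ACGT
    character in any row is dropped, then π is the plain mean over all
    C(n,2) pairs of (differing sites)/(used sites). With pairwise
    deletion each pair uses its own gap/N-free columns.
    """
    mat = np.array([list(r.upper()) for r in alignment.rows])
    valid = np.isin(mat, list(_BASES))
    n = len(alignment.rows)
    diffs = []
    if pairwise_deletion:
        for i, j in combinations(range(n), 2):
            use = valid[i] & valid[j]
            if not use.any():
                continue
            diffs.append(np.mean(mat[i, use] != mat[j, use]))
        n_sites = alignment.length
        if not diffs:
            raise ValueError("no usable sites in any pair")
    else:
        use = valid.all(axis=0)
        n_sites = int(use.sum())
        if n_sites == 0:
            raise ValueError("no gap/N-free sites under complete deletion")
        sub = mat[:, use]
        for i, j in combinations(range(n), 2):
            diffs.append(np.mean(sub[i] != sub[j]))
    return PiResult(gene=alignment.gene, pi=float(np.mean(diffs)),
                    n_taxa=n, n_sites=n_sites)


def panel_pi(alignments: Sequence[GeneAlignment], panel: Optional[Sequence[str]] = None,
             pairwise_deletion: bool = False) -> list[PiResult]:
    """π per gene over a taxon panel; genes with <2 panel taxa are skipped."""
    if panel is not None and len(panel) == 0:
        raise ValueError("empty panel")
    out = []
    for aln in alignments:
        if panel is not None:
            present = [t for t in aln.taxa if t in set(panel)]
            if len(present) < 2:
                warnings.warn(f"gene {aln.gene}: fewer than 2 panel taxa, skipped")
                continue
            sub = aln.subset(present)
        else:
            sub = aln
        out.append(pi(sub, pairwise_deletion=pairwise_deletion))
    return out


# ---------------------------------------------------------------------------
# minimal codon-aware aligner (translate – align – back-translate)
# ---------------------------------------------------------------------------

from Bio.Seq import Seq  # noqa: E402


def _translate(cds: str) -> str:
    trimmed = cds[: len(cds) - len(cds) % 3]
    return str(Seq(trimmed).translate(table=5)).rstrip("*")


def codon_aware_align(gene: str, sequences: dict[str, str]) -> GeneAlignment:
    """Star alignment of coding sequences at the codon level.

    Each sequence is translated (table 5), its protein aligned to the
    first sequence's protein by global alignment, and the gaps
    back-translated as codon triplets. Adequate for desk-scale panels of
    homologous mitochondrial genes; externally produced alignments remain
    first-class input.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    taxa = list(sequences)
    ref_taxon = taxa[0]
    ref_prot = _translate(sequences[ref_taxon])
    # collect, per reference position, the maximum insertion length after it
    aligned_prot: dict[str, tuple[str, str]] = {}
    for t in taxa[1:]:
        a, b, _ = needleman_wunsch(ref_prot, _translate(sequences[t]),
                                   match=1, mismatch=-1, gap=-4)
        aligned_prot[t] = (a, b)
    ins_after = {i: 0 for i in range(-1, len(ref_prot))}
    for a, _ in aligned_prot.values():
        pos, run = -1, 0
        for ch in a:
            if ch == "-":
                run += 1
            else:
                ins_after[pos] = max(ins_after[pos], run)
                pos, run = pos + 1, 0
        ins_after[pos] = max(ins_after[pos], run)

    def project(a: str, b: str) -> str:
        """b's residues laid onto the master coordinate system."""
        out, pos, run = [], -1, []
        for ca, cb in zip(a, b):
            if ca == "-":
                run.append(cb)
            else:
                out.append("".join(run) + "-" * (ins_after[pos] - len(run)))
                out.append(cb)
                pos, run = pos + 1, []
        out.append("".join(run) + "-" * (ins_after[pos] - len(run)))
        return "".join(out)

    master: dict[str, str] = {}
    ref_self = "".join("-" * ins_after[-1]) + "".join(
        ch + "-" * ins_after[i] for i, ch in enumerate(ref_prot))
    master[ref_taxon] = ref_self
    for t in taxa[1:]:
        master[t] = project(*aligned_prot[t])

    rows = []
    for t in taxa:
        cds = sequences[t]
        codons = [cds[i:i + 3] for i in range(0, len(cds) - len(cds) % 3, 3)]
        row, k = [], 0
        for ch in master[t]:
            if ch == "-":
                row.append("---")
            else:
                row.append(codons[k])
                k += 1
        rows.append("".join(row))
    width = max(len(r) for r in rows)
    rows = [r.ljust(width, "-") for r in rows]
    return GeneAlignment(gene=gene, taxa=tuple(taxa), rows=tuple(rows))
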