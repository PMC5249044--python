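"""Signed gene-order signatures and rearrangement comparison.

A genome's gene order is reduced to a circular sequence of signed labels
(sign = coding strand), linearized at an anchor gene (cox1 by default)
with the anchor reading ``+`` — reflecting the whole order if needed —
so that rotations and full reflections of the same arrangement give one
canonical signature. Two signatures are compared by their signed gene
adjacencies: the breakpoint count is the number of adjacencies of one
arrangement absent from the other (circular closure included), a
standard rearrangement dissimilarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome_io import GeneFeature, MitoGenome

# The pancrustacean ground pattern: the inferred ancestral arrangement of
# the 37 mitochondrial genes plus the control region, used as the
# reference for rearrangement analysis. Transcribed once, versioned here.
GROUND_PATTERN_VERSION = "1.0"
GROUND_PATTERN: tuple[tuple[str, str], ...] = (
    ("trnI", "+"), ("trnQ", "-"), ("trnM", "+"), ("nad2", "+"),
    ("trnW", "+"), ("trnC", "-"), ("trnY", "-"), ("cox1", "+"),
    ("trnL2", "+"), ("cox2", "+"), ("trnK", "+"), ("trnD", "+"),
    ("atp8", "+"), ("atp6", "+"), ("cox3", "+"), ("trnG", "+"),
    ("nad3", "+"), ("trnA", "+"), ("trnR", "+"), ("trnN", "+"),
    ("trnS1", "+"), ("trnE", "+"), ("trnF", "-"), ("nad5", "-"),
    ("trnH", "-"), ("nad4", "-"), ("nad4l", "-"), ("trnT", "+"),
    ("trnP", "-"), ("nad6", "+"), ("cytB", "+"), ("trnS2", "+"),
    ("nad1", "-"), ("trnL1", "-"), ("rrnL", "-"), ("trnV", "-"),
    ("rrnS", "-"), ("CR", "+"),
)

SCOPES = ("PCG", "PCG+rRNA", "all")
_SCOPE_KINDS = {"PCG": {"PCG"}, "PCG+rRNA": {"PCG", "rRNA"},
                "all": {"PCG", "rRNA", "tRNA", "CR"}}


@dataclass(frozen=True)
class GeneOrderSignature:
    anchor: str
    scope: str
    elements: tuple[tuple[str, str], ...]  # ((label[, /copy]), sign)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.elements)


def _element_key(f: GeneFeature) -> str:
    return f.label if f.copy_index == 1 else f"{f.label}/{f.copy_index}"


def _normalize(elements: Sequence[tuple[str, str]], anchor: str) -> tuple[tuple[str, str], ...]:
    labels = [lab for lab, _ in elements]
    if anchor not in labels:
        candidates = ", ".join(labels[:5])
        raise ValueError(f"anchor {anchor!r} not in arrangement; "
                         f"try an alternate anchor (e.g. {candidates})")
    i = labels.index(anchor)
    rotated = list(elements[i:]) + list(elements[:i])
    if rotated[0][1] == "-":
        # reflect and complement so the anchor reads +
        rotated = [(lab, "+" if s == "-" else "-") for lab, s in reversed(rotated)]
        rotated = rotated[-1:] + rotated[:-1]
    return tuple(rotated)


def signature(genome: MitoGenome, scope: str = "PCG",
              anchor: str = "cox1") -> GeneOrderSignature:
    """Rotation/reflection-normalized signed gene order of one genome."""
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}")
    feats = [f for f in genome.features if f.kind in _SCOPE_KINDS[scope]]
    feats.sort(key=lambda f: (f.start, f.end))
    elements = [(_element_key(f), f.strand) for f in feats]
    return GeneOrderSignature(anchor=anchor, scope=scope,
                              elements=_normalize(elements, anchor))


def ground_pattern_signature(scope: str = "PCG", anchor: str = "cox1") -> GeneOrderSignature:
    """The pancrustacean ground pattern, projected to a scope."""
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}")
    kinds = _SCOPE_KINDS[scope]
    keep = []
    for lab, s in GROUND_PATTERN:
        kind = ("CR" if lab == "CR" else "rRNA" if lab.startswith("rrn")
                else "tRNA" if lab.startswith("trn") else "PCG")
        if kind in kinds:
            keep.append((lab, s))
    return GeneOrderSignature(anchor=anchor, scope=scope,
                              elements=_normalize(keep, anchor))


def signature_to_text(sig: GeneOrderSignature) -> str:
    return ";".join(f"{lab},{s}" for lab, s in sig.elements)


def signature_from_text(text: str, scope: str = "PCG",
                        anchor: Optional[str] = None) -> GeneOrderSignature:
    elements = []
    for item in text.strip().split(";"):
        lab, s = item.rsplit(",", 1)
        elements.append((lab, s))
    anchor = anchor or elements[0][0]
    return GeneOrderSignature(anchor=anchor, scope=scope,
                              elements=_normalize(elements, anchor))


# ---------------------------------------------------------------------------
# comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RearrangementReport:
    translocated: frozenset[str]
    inverted: frozenset[str]
    breakpoints: int
    identical: bool
    only_in_sig: frozenset[str]
    only_in_ref: frozenset[str]


def _signed_adjacencies(elements: Sequence[tuple[str, str]]) -> set[tuple]:
    """Canonical signed adjacencies with circular closure.

    An adjacency a→b read on one strand equals b̄→ā read on the other;
    each is stored under the lexicographically smaller orientation.
    """
    adj = set()
    n = len(elements)
    for i in range(n):
        a, b = elements[i], elements[(i + 1) % n]
        flip = {"+": "-", "-": "+"}
        rev = ((b[0], flip[b[1]]), (a[0], flip[a[1]]))
        adj.add(min((a, b), rev))
    return adj


def _unsigned_adjacencies(elements: Sequence[tuple[str, str]]) -> set[frozenset]:
    labels = [lab for lab, _ in elements]
    n = len(labels)
    return {frozenset((labels[i], labels[(i + 1) % n])) for i in range(n)}


def compare(sig: GeneOrderSignature, ref: GeneOrderSignature) -> RearrangementReport:
    """Rearrangement report of ``sig`` against a reference arrangement.

    Both arrangements are restricted to their shared labels before
    comparison; labels unique to either side are reported but excluded
    from the distance. A gene is called translocated when both of its
    neighbor adjacencies (strand-blind) are absent from the reference —
    the operational reading of a gene moved to a novel neighborhood.
    """
    if sig.scope != ref.scope:
        raise ValueError("signatures have different scopes")
    set_s, set_r = set(sig.labels), set(ref.labels)
    shared = set_s & set_r
    if not shared:
        raise ValueError("signatures share no labels")
    es = [(lab, s) for lab, s in sig.elements if lab in shared]
    er = [(lab, s) for lab, s in ref.elements if lab in shared]
    es = _normalize(es, sig.anchor if sig.anchor in shared else es[0][0])
    er = _normalize(er, sig.anchor if sig.anchor in shared else es[0][0])

    sign_s = dict(es)
    sign_r = dict(er)
    inverted = frozenset(lab for lab in shared if sign_s[lab] != sign_r[lab])

    adj_s, adj_r = _signed_adjacencies(es), _signed_adjacencies(er)
    breakpoints = len(adj_s - adj_r)

    u_s, u_r = _unsigned_adjacencies(es), _unsigned_adjacencies(er)
    novel = u_s - u_r
    labels_s = [lab for lab, _ in es]
    n = len(labels_s)
    translocated = set()
    for i, lab in enumerate(labels_s):
        left = frozenset((labels_s[i - 1], lab))
        right = frozenset((lab, labels_s[(i + 1) % n]))
        if left in novel and right in novel:
            translocated.add(lab)
    return RearrangementReport(
        translocated=frozenset(translocated), inverted=inverted,
        breakpoints=breakpoints,
        identical=(breakpoints == 0 and not inverted),
        only_in_sig=frozenset(set_s - set_r), only_in_ref=frozenset(set_r - set_s))


def batch_compare(genomes: Sequence[MitoGenome], ref: Optional[GeneOrderSignature] = None,
                  scope: str = "PCG", anchor: str = "cox1"):
    """Per-genome reports against a reference plus pairwise breakpoint matrix."""
    if not genomes:
        raise ValueError("need at least one genome")
    if ref is None:
        ref = ground_pattern_signature(scope, anchor)
    sigs = {g.id: signature(g, scope, anchor) for g in genomes}
    reports = {gid: compare(s, ref) for gid, s in sigs.items()}
    ids = list(sigs)
    mat = np.zeros((len(ids), len(ids)), dtype=int)
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i < j:
                d = compare(sigs[a], sigs[b]).breakpoints
                mat[i, j] = mat[j, i] = d
    return reports, pd.DataFrame(mat, index=ids, columns=ids)
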