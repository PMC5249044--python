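"""Synthetic annotated mitogenomes and gene alignments with known ground
truth.

The generator emulates the statistical structure of an amphipod-like
mitochondrial genome: a circular molecule carrying the 37-gene
pancrustacean ground pattern plus a control region, strand-asymmetric
base composition (configurable AT/GC skew on the (+) strand),
codon-position-structured protein-coding genes, optional rearrangement
edits (translocations/inversions), duplicated tRNA genes mutated to a
target identity (optionally relabelled, the remolding scenario), and a
control region assembled from a poly-T run, a tandem repeat, a hairpin
and AT-rich filler. Every planted fact is recorded in a ground-truth
dictionary so each analysis stage can be checked against it.

Defaults mirror the study system: whole-genome AT fraction ≈ 0.65,
(+)-strand AT-skew ≈ 0 and GC-skew ≈ −0.3, third codon positions more
AT-rich than first/second, ~15.5 kb genomes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .diversity import GeneAlignment
from .gene_order import GROUND_PATTERN
from .genome_io import GeneFeature, MitoGenome, label_kind, revcomp

# typical coding-gene lengths (b.p.) for an amphipod mitogenome
GENE_LENGTHS = {
    "cox1": 1536, "cox2": 684, "cox3": 786, "nad1": 924, "nad2": 1008,
    "nad3": 351, "nad4": 1330, "nad4l": 297, "nad5": 1695, "nad6": 498,
    "atp6": 672, "atp8": 156, "cytB": 1135, "rrnL": 980, "rrnS": 624,
}
TRNA_LENGTH = 64
DEFAULT_CR_LENGTH = 700

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class CRFeatureSpec:
    poly_t: int = 13                 # length of the planted T run
    repeat_period: int = 51          # tandem-repeat unit length
    repeat_copies: int = 4
    repeat_noise: float = 0.02      # per-base mutation rate between copies
    hairpin_stem: int = 8
    hairpin_loop: int = 6
    at_excess: float = 8.0          # percentage points above genome AT%


@dataclass(frozen=True)
class TrnaDuplicationSpec:
    label: str                       # source tRNA copied
    target_identity: float = 78.0    # percent, ungapped planted identity
    relabel_to: Optional[str] = None  # remolding scenario: new label of the copy


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic mitogenome; defaults are the emulated
    study conditions."""

    seed: int = 0
    at_fraction: float = 0.65
    at_skew: float = 0.0
    gc_skew: float = -0.30
    at3_targets: tuple[float, float, float] = (0.55, 0.62, 0.80)
    gene_order: tuple[tuple[str, str], ...] = GROUND_PATTERN
    translocate: tuple[tuple[str, int], ...] = ()   # (label, new index in order)
    invert: tuple[str, ...] = ()
    trna_duplications: tuple[TrnaDuplicationSpec, ...] = ()
    cr_features: CRFeatureSpec = field(default_factory=CRFeatureSpec)
    cr_length: int = DEFAULT_CR_LENGTH
    spacer_length: int = 10          # between consecutive genes (0 = tiled)
    long_spacers: tuple[tuple[str, int], ...] = ()  # (after-label, length)
    # per-gene alignment simulations: (gene, n_taxa, expected pairwise p)
    alignment_specs: tuple[tuple[str, int, float], ...] = ()
    genome_id: str = "SYN0001"

    def __post_init__(self):
        if not (-1.0 <= self.at_skew <= 1.0) or not (-1.0 <= self.gc_skew <= 1.0):
            raise ValueError("skew targets must lie in [-1, 1]")
        if not (0.0 < self.at_fraction < 1.0):
            raise ValueError("at_fraction must lie in (0, 1)")
        labels = {lab for lab, _ in self.gene_order}
        for lab, _ in self.translocate:
            if lab not in labels:
                raise ValueError(f"translocation target {lab!r} not in gene order")
        for lab in self.invert:
            if lab not in labels:
                raise ValueError(f"inversion target {lab!r} not in gene order")
        for d in self.trna_duplications:
            if d.label not in labels:
                raise ValueError(f"duplication source {d.label!r} not in gene order")
            if not (0.0 < d.target_identity <= 100.0):
                raise ValueError("target identity must be in (0, 100]")


def base_probs(at_fraction: float, at_skew: float, gc_skew: float) -> np.ndarray:
    """(+)-strand base probabilities (A, C, G, T) realizing the targets.

    With AT fraction f and skews s_AT, s_GC:
    p_A = f(1+s_AT)/2, p_T = f(1−s_AT)/2,
    p_G = (1−f)(1+s_GC)/2, p_C = (1−f)(1−s_GC)/2.
    """
    f = at_fraction
    p = np.array([f * (1 + at_skew) / 2, (1 - f) * (1 - gc_skew) / 2,
                  (1 - f) * (1 + gc_skew) / 2, f * (1 - at_skew) / 2])
    assert abs(p.sum() - 1.0) < 1e-12
    return p


def _sample(rng: np.random.Generator, probs: np.ndarray, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n, p=probs))


def _position_probs(at3: float, at_skew: float, gc_skew: float) -> np.ndarray:
    return base_probs(at3, at_skew, gc_skew)


def _sample_cds(rng: np.random.Generator, length: int,
                at3_targets: Sequence[float], at_skew: float, gc_skew: float) -> str:
    """A CDS with position-specific AT targets, a planted start codon and
    a full terminal stop."""
    n_codons = length // 3
    probs = [_position_probs(t, at_skew, gc_skew) for t in at3_targets]
    starts = ("ATA", "ATG", "ATT", "ATC", "TTG", "GTG")
    codons = [starts[rng.integers(len(starts))]]
    # interior codons are sampled i.i.d. from the position distributions;
    # any avoid-the-stop rule would bias the planted composition targets,
    # so occasional in-frame stop triplets are accepted (downstream codon
    # statistics exclude stop codons from counts regardless)
    for k in range(3):
        interior = rng.choice(_BASES, size=n_codons - 2, p=probs[k])
        if k == 0:
            cols = [interior]
        else:
            cols.append(interior)
    codons.extend("".join(t) for t in zip(*cols))
    codons.append("TAA" if rng.random() < 0.5 else "TAG")
    return "".join(codons)


def _mutate_to_identity(rng: np.random.Generator, seq: str,
                        target_identity: float) -> tuple[str, float, int]:
    """Copy-and-mutate to a target percent identity (substitutions only).

    Identity is the package's own measure (global alignment); because a
    gapped optimum can exceed the plain substitution-count identity at
    high divergence, substitutions are added one at a time until the
    measured identity reaches the target (within ~1 point). Returns
    (mutated sequence, achieved identity, substitution count).
    """
    from .trna_dup import pairwise_identity
    L = len(seq)
    order = rng.permutation(L)
    s = list(seq)
    k0 = max(0, int(round(L * (1.0 - target_identity / 100.0))) - 2)
    for p in order[:k0]:
        s[p] = rng.choice([b for b in _BASES if b != s[p]])
    best = ("".join(s), pairwise_identity(seq, "".join(s)).percent_identity, k0)
    k = k0
    while best[1] > target_identity + 1.0 and k < L:
        p = order[k]
        s[p] = rng.choice([b for b in _BASES if b != s[p]])
        k += 1
        cand = "".join(s)
        pid = pairwise_identity(seq, cand).percent_identity
        if abs(pid - target_identity) < abs(best[1] - target_identity):
            best = (cand, pid, k)
        if pid <= target_identity:
            break
    return best


def _make_cr(rng: np.random.Generator, spec: SyntheticSpec,
             probs: np.ndarray) -> tuple[str, dict]:
    cf = spec.cr_features
    at_rich = min(0.98, spec.at_fraction + cf.at_excess / 100.0)
    rich_probs = base_probs(at_rich, spec.at_skew, 0.0)

    def filler(n: int) -> str:
        return _sample(rng, rich_probs, max(n, 0))

    unit = _sample(rng, rich_probs, cf.repeat_period)
    copies = []
    for _ in range(cf.repeat_copies):
        c = list(unit)
        for i in range(len(c)):
            if rng.random() < cf.repeat_noise:
                c[i] = rng.choice([b for b in _BASES if b != c[i]])
        copies.append("".join(c))
    repeat = "".join(copies)
    # a stem of C/G-biased bases keeps the hairpin from matching filler by chance
    stem = "".join(rng.choice(_BASES, size=cf.hairpin_stem,
                              p=np.array([0.15, 0.35, 0.35, 0.15])))
    loop = filler(cf.hairpin_loop)
    hairpin = stem + loop + revcomp(stem)
    polyt = "T" * cf.poly_t
    parts = [polyt, filler(40), repeat, filler(40), hairpin]
    core = "".join(parts)
    pad = spec.cr_length - len(core)
    cr = core + filler(pad)
    truth = {"poly_t": cf.poly_t,
             "repeat": {"period": cf.repeat_period, "copies": cf.repeat_copies,
                        "start": len(polyt) + 40, "span": len(repeat)},
             "hairpin": {"stem": cf.hairpin_stem, "loop": cf.hairpin_loop,
                         "position": len(polyt) + 40 + len(repeat) + 40},
             "at_excess_target": cf.at_excess, "length": len(cr)}
    return cr, truth


def generate_genome(spec: SyntheticSpec) -> tuple[MitoGenome, dict]:
    """Build an annotated synthetic mitogenome and its ground-truth record.

    Protein-coding genes are sampled on their coding sense (codon
    structure, planted start/stop, position-specific AT), so the pooled
    PCG coding-sense composition realizes the skew targets exactly in
    expectation; every other element (tRNA, rRNA, CR, spacers) is sampled
    directly on the (+) strand. A (−)-strand PCG therefore shows flipped
    skews on the (+) strand, as in real strand-asymmetric mitogenomes.
    Rearrangement edits are applied to the gene order before assembly;
    duplicated tRNAs are copy-and-mutate products inserted downstream of
    their source.
    """
    rng = np.random.default_rng(spec.seed)
    probs = base_probs(spec.at_fraction, spec.at_skew, spec.gc_skew)

    order = [list(x) for x in spec.gene_order]
    for lab in spec.invert:
        for el in order:
            if el[0] == lab:
                el[1] = "-" if el[1] == "+" else "+"
    moved = []
    for lab, new_idx in spec.translocate:
        el = next(e for e in order if e[0] == lab)
        order.remove(el)
        order.insert(new_idx % (len(order) + 1), el)
        moved.append(lab)

    # coding-sense sequences per element
    seqs: dict[str, str] = {}
    truth: dict = {"spec_seed": spec.seed,
                   "skew_targets": {"at_fraction": spec.at_fraction,
                                    "at_skew": spec.at_skew, "gc_skew": spec.gc_skew},
                   "at3_targets": list(spec.at3_targets),
                   "translocated": moved, "inverted": list(spec.invert),
                   "duplications": [], "gene_order": [tuple(e) for e in order]}
    cr_truth = None
    # exact expected pooled PCG coding-sense base counts: interior codons
    # follow the position distributions; planted start codons are uniform
    # over the six standard starts and stops are TAA/TAG half-and-half
    expected = dict.fromkeys(_BASES, 0.0)
    start_exp = {0: {"A": 4 / 6, "T": 1 / 6, "G": 1 / 6, "C": 0.0},
                 1: {"T": 1.0, "A": 0.0, "G": 0.0, "C": 0.0},
                 2: {"A": 1 / 6, "C": 1 / 6, "G": 3 / 6, "T": 1 / 6}}
    stop_exp = {0: {"T": 1.0, "A": 0.0, "G": 0.0, "C": 0.0},
                1: {"A": 1.0, "T": 0.0, "G": 0.0, "C": 0.0},
                2: {"A": 0.5, "G": 0.5, "T": 0.0, "C": 0.0}}
    pos_probs = [base_probs(t, spec.at_skew, spec.gc_skew)
                 for t in spec.at3_targets]
    for lab, strand in order:
        if lab == "CR":
            seq, cr_truth = _make_cr(rng, spec, probs)
        elif lab in GENE_LENGTHS and label_kind(lab) == "PCG":
            seq = _sample_cds(rng, GENE_LENGTHS[lab], spec.at3_targets,
                              spec.at_skew, spec.gc_skew)
            n_codons = GENE_LENGTHS[lab] // 3
            for k in range(3):
                for bi, base in enumerate(_BASES):
                    expected[base] += (n_codons - 2) * pos_probs[k][bi]
                for base in _BASES:
                    expected[base] += start_exp[k][base] + stop_exp[k][base]
        elif lab in GENE_LENGTHS:   # rRNA
            seq = _sample(rng, probs, GENE_LENGTHS[lab])
        else:                        # tRNA
            seq = _sample(rng, probs, TRNA_LENGTH)
        seqs[lab] = seq
    truth["cr"] = cr_truth
    truth["expected_pcg_counts"] = expected

    # duplicated tRNA copies, inserted right after their source element
    extra: dict[str, tuple[str, str, str]] = {}  # placed-after-label -> (label, seq, strand)
    for dup in spec.trna_duplications:
        src_seq = seqs[dup.label]
        mutated, planted, k = _mutate_to_identity(rng, src_seq, dup.target_identity)
        new_label = dup.relabel_to or dup.label
        src_strand = next(s for l, s in order if l == dup.label)
        extra[dup.label] = (new_label, mutated, src_strand)
        truth["duplications"].append({"source": dup.label, "label": new_label,
                                      "target_identity": dup.target_identity,
                                      "planted_identity": planted,
                                      "n_substitutions": k,
                                      "remolded": dup.relabel_to is not None})

    # assemble the (+) strand with spacers
    chunks: list[str] = []
    features: list[GeneFeature] = []
    seen: dict[str, int] = {}
    long_after = dict(spec.long_spacers)
    pos = 0

    def _emit(lab: str, strand: str, seq: str):
        # PCGs were sampled on coding sense; everything else on (+)
        nonlocal pos
        kind = label_kind(lab) or "spacer"
        plus = revcomp(seq) if (strand == "-" and kind == "PCG") else seq
        seen[lab] = seen.get(lab, 0) + 1
        features.append(GeneFeature(label=lab, kind=kind, start=pos,
                                    end=pos + len(plus), strand=strand,
                                    copy_index=seen[lab]))
        chunks.append(plus)
        pos += len(plus)

    def _spacer(n: int):
        nonlocal pos
        if n > 0:
            sp = _sample(rng, probs, n)
            chunks.append(sp)
            pos += len(sp)

    planted_idx: list[int] = []
    for lab, strand in order:
        _emit(lab, strand, seqs[lab])
        if lab in extra:
            new_label, mseq, mstrand = extra[lab]
            _spacer(spec.spacer_length)
            _emit(new_label, mstrand, mseq)
            planted_idx.append(len(features) - 1)
        _spacer(long_after.get(lab, 0))
        _spacer(spec.spacer_length)

    # a planted duplicate always numbers after the original copy, even when
    # it was emitted first
    from dataclasses import replace as _replace
    for pi_ in planted_idx:
        dup_f = features[pi_]
        partners = [k for k, f in enumerate(features)
                    if f.label == dup_f.label and k != pi_]
        if partners:
            counter = 1
            for k in partners:
                features[k] = _replace(features[k], copy_index=counter)
                counter += 1
            features[pi_] = _replace(dup_f, copy_index=counter)

    genome = MitoGenome(id=spec.genome_id, sequence="".join(chunks),
                        circular=True, features=features)
    truth["genome_length"] = len(genome)
    return genome, truth


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def branch_substitution_prob(p: float) -> float:
    """Per-branch substitution probability q with expected pairwise
    difference p under a star tree.

    Each taxon mutates independently from the ancestor; a site differs
    between two taxa with probability 2q(1−q) + (2/3)q² = 2q − (4/3)q²
    (two mutated sequences agree with probability 1/3). Solving for q:
    q = (3 − sqrt(9 − 12p)) / 4.
    """
    if not (0.0 <= p <= 0.75):
        raise ValueError("p must lie in [0, 0.75]")
    return (3.0 - math.sqrt(9.0 - 12.0 * p)) / 4.0


def generate_alignment(gene: str, n_taxa: int, p: float, length: int,
                       seed: int = 0, at_fraction: float = 0.65) -> GeneAlignment:
    """Star-tree alignment with expected pairwise per-site difference p.

    Sites are i.i.d.; every taxon's sequence is the common ancestor with
    independent substitutions at per-site probability q (see
    branch_substitution_prob), each to a uniformly chosen other base.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    q = branch_substitution_prob(p)
    probs = base_probs(at_fraction, 0.0, 0.0)
    ancestor = np.array(list(_sample(rng, probs, length)))
    rows = []
    for _ in range(n_taxa):
        taxon = ancestor.copy()
        hits = rng.random(length) < q
        idx = np.flatnonzero(hits)
        for i in idx:
            taxon[i] = rng.choice([b for b in _BASES if b != taxon[i]])
        rows.append("".join(taxon))
    taxa = tuple(f"taxon{i + 1}" for i in range(n_taxa))
    return GeneAlignment(gene=gene, taxa=taxa, rows=tuple(rows))


def generate_alignments(spec: SyntheticSpec) -> dict[str, GeneAlignment]:
    """Per-gene star-tree alignments requested by spec.alignment_specs."""
    out = {}
    for i, (gene, n_taxa, p) in enumerate(spec.alignment_specs):
        length = GENE_LENGTHS.get(gene, 900) // 3 * 3
        out[gene] = generate_alignment(gene, n_taxa, p, length,
                                       seed=spec.seed + i + 1,
                                       at_fraction=spec.at_fraction)
    return out


def random_spec(seed: int) -> SyntheticSpec:
    """A randomized SyntheticSpec for recovery testing.

    Draws one translocation, an optional inversion, one tRNA duplication
    (half the time a remolding relabel), randomized CR features and
    skew/AT targets within the realistic mitogenomic range.
    """
    rng = np.random.default_rng(seed)
    labels = [lab for lab, _ in GROUND_PATTERN]
    pcgs = [l for l in labels if label_kind(l) == "PCG"]
    trnas = [l for l in labels if l.startswith("trn")]
    mover = pcgs[rng.integers(len(pcgs))]
    # the new position must give the moved gene two novel neighbours,
    # otherwise nothing was rearranged
    i = labels.index(mover)
    n = len(labels)
    old_neighbors = {labels[(i - 1) % n], labels[(i + 1) % n]}
    rest = labels[:i] + labels[i + 1:]
    while True:
        new_idx = int(rng.integers(len(rest) + 1))
        left = rest[(new_idx - 1) % len(rest)]
        right = rest[new_idx % len(rest)]
        if not ({left, right} & old_neighbors):
            break
    # never invert the anchor gene: a circular signed order is only defined
    # up to reflection, so "cox1 flipped" is indistinguishable from
    # "everything else flipped"
    invertible = [l for l in pcgs if l != "cox1"]
    invert = (invertible[rng.integers(len(invertible))],) if rng.random() < 0.5 else ()
    src = trnas[rng.integers(len(trnas))]
    if rng.random() < 0.5:
        others = [t for t in trnas if t != src]
        relabel = others[rng.integers(len(others))]
    else:
        relabel = None
    dup = TrnaDuplicationSpec(label=src,
                              target_identity=float(rng.uniform(68, 92)),
                              relabel_to=relabel)
    cr = CRFeatureSpec(poly_t=int(rng.integers(10, 16)),
                       repeat_period=int(rng.integers(15, 60)),
                       repeat_copies=int(rng.integers(3, 6)),
                       hairpin_stem=int(rng.integers(7, 11)),
                       hairpin_loop=int(rng.integers(4, 12)),
                       at_excess=float(rng.uniform(6, 12)))
    spacers = tuple((pcgs[int(rng.integers(len(pcgs)))], int(rng.integers(100, 400)))
                    for _ in range(2))
    return SyntheticSpec(seed=int(rng.integers(2 ** 31)),
                         at_fraction=float(rng.uniform(0.60, 0.70)),
                         at_skew=float(rng.uniform(-0.05, 0.05)),
                         gc_skew=float(rng.uniform(-0.35, -0.15)),
                         translocate=((mover, new_idx),),
                         invert=invert,
                         trna_duplications=(dup,),
                         cr_features=cr,
                         long_spacers=spacers,
                         genome_id=f"SYN{seed:04d}")


def write_ground_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
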