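import numpy as np
import pytest

from mitoarch import (GROUND_PATTERN, SyntheticSpec, batch_compare, compare,
                      generate_genome, ground_pattern_signature, signature,
                      signature_from_text, signature_to_text)
from mitoarch.gene_order import GeneOrderSignature, _signed_adjacencies

from conftest import make_genome


def brute_breakpoints(es, er):
    """Exhaustive adjacency enumeration: walk both circles in both
    directions and count sig adjacencies absent from ref."""
    def adjacency_set(elements):
        flip = {"+": "-", "-": "+"}
        n = len(elements)
        out = set()
        for i in range(n):
            a, b = elements[i], elements[(i + 1) % n]
            out.add((a, b))
            out.add(((b[0], flip[b[1]]), (a[0], flip[a[1]])))
        return out
    ref = adjacency_set(er)
    count = 0
    n = len(es)
    for i in range(n):
        if (es[i], es[(i + 1) % n]) not in ref:
            count += 1
    return count


def test_ground_pattern_pcg_signature_frozen():
    """PCG-only projection of the ground pattern, anchored at cox1:
    all 13 protein-coding genes, with nad2 wrapping around last."""
    sig = ground_pattern_signature("PCG")
    assert sig.elements == (
        ("cox1", "+"), ("cox2", "+"), ("atp8", "+"), ("atp6", "+"),
        ("cox3", "+"), ("nad3", "+"), ("nad5", "-"), ("nad4", "-"),
        ("nad4l", "-"), ("nad6", "+"), ("cytB", "+"), ("nad1", "-"),
        ("nad2", "+"))


def test_ground_pattern_has_37_genes_plus_cr():
    labels = [lab for lab, _ in GROUND_PATTERN]
    assert len(labels) == 38 and len(set(labels)) == 38
    assert sum(1 for l in labels if l.startswith("trn")) == 22
    assert "CR" in labels


def genome_from_order(order, gene_len=30):
    feats = []
    pos = 0
    for lab, strand in order:
        kind = ("CR" if lab == "CR" else "rRNA" if lab.startswith("rrn")
                else "tRNA" if lab.startswith("trn") else "PCG")
        feats.append((lab, kind, pos, pos + gene_len, strand))
        pos += gene_len
    return make_genome("A" * pos, feats)


def test_rotation_invariance():
    order = list(GROUND_PATTERN)
    base = signature(genome_from_order(order), "all")
    for k in (5, 17, 30):
        rotated = signature(genome_from_order(order[k:] + order[:k]), "all")
        assert rotated.elements == base.elements


def test_reflection_invariance():
    """The same circular molecule annotated from the other strand yields
    an identical signature."""
    order = list(GROUND_PATTERN)
    flip = {"+": "-", "-": "+"}
    reflected = [(lab, flip[s]) for lab, s in reversed(order)]
    a = signature(genome_from_order(order), "all")
    b = signature(genome_from_order(reflected), "all")
    assert a.elements == b.elements


def test_compare_identical():
    rep = compare(ground_pattern_signature("PCG"), ground_pattern_signature("PCG"))
    assert rep.identical and rep.breakpoints == 0
    assert not rep.translocated and not rep.inverted


def test_single_translocation_detected():
    genome, truth = generate_genome(SyntheticSpec(seed=2, translocate=(("nad1", 10),)))
    rep = compare(signature(genome, "all"), ground_pattern_signature("all"))
    assert "nad1" in rep.translocated
    assert not rep.identical


def test_single_inversion_detected():
    genome, _ = generate_genome(SyntheticSpec(seed=2, invert=("nad3",)))
    rep = compare(signature(genome, "all"), ground_pattern_signature("all"))
    assert set(rep.inverted) == {"nad3"}
    assert rep.breakpoints > 0


def test_breakpoints_match_exhaustive_enumeration():
    """Breakpoint counts agree with brute-force adjacency enumeration on
    random signed signatures of up to 12 genes."""
    rng = np.random.default_rng(8)
    labels = [f"g{i}" for i in range(12)]
    for _ in range(50):
        n = int(rng.integers(4, 13))
        labs = labels[:n]
        def rand_sig():
            perm = rng.permutation(n)
            els = [(labs[i], "+" if rng.random() < 0.7 else "-") for i in perm]
            # anchor on labs[0] reading +
            sig = GeneOrderSignature(anchor=labs[0], scope="PCG", elements=tuple(els))
            return signature_from_text(signature_to_text(sig), anchor=labs[0])
        s, r = rand_sig(), rand_sig()
        rep = compare(s, r)
        assert rep.breakpoints == brute_breakpoints(list(s.elements), list(r.elements))


def test_breakpoint_distance_pseudo_metric():
    rng = np.random.default_rng(4)
    labels = [f"g{i}" for i in range(8)]
    def rand_sig():
        perm = rng.permutation(8)
        els = [(labels[i], "+" if rng.random() < 0.7 else "-") for i in perm]
        sig = GeneOrderSignature(anchor=labels[0], scope="PCG", elements=tuple(els))
        return signature_from_text(signature_to_text(sig), anchor=labels[0])
    for _ in range(20):
        x, y, z = rand_sig(), rand_sig(), rand_sig()
        assert compare(x, x).breakpoints == 0
        dxy = compare(x, y).breakpoints
        assert dxy == compare(y, x).breakpoints
        assert dxy <= compare(x, z).breakpoints + compare(z, y).breakpoints


def test_batch_compare_matrix(default_genome):
    g1, _ = default_genome
    g2, _ = generate_genome(SyntheticSpec(seed=21, translocate=(("nad6", 3),),
                                          genome_id="SYNB"))
    reports, dist = batch_compare([g1, g2], scope="PCG")
    assert reports[g1.id].identical          # ground pattern, unrearranged
    assert not reports["SYNB"].identical
    assert (dist.values == dist.values.T).all()
    assert (np.diag(dist.values) == 0).all()


def test_missing_anchor_and_disjoint_labels():
    g = genome_from_order([("nad2", "+"), ("nad3", "+")])
    with pytest.raises(ValueError, match="anchor"):
        signature(g, "PCG")
    a = GeneOrderSignature(anchor="x", scope="PCG",
                           elements=(("x", "+"), ("y", "+")))
    b = GeneOrderSignature(anchor="u", scope="PCG",
                           elements=(("u", "+"), ("v", "+")))
    with pytest.raises(ValueError, match="no labels"):
        compare(a, b)


def test_signature_text_roundtrip():
    sig = ground_pattern_signature("PCG+rRNA")
    back = signature_from_text(signature_to_text(sig), scope="PCG+rRNA",
                               anchor="cox1")
    assert back.elements == sig.elements
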