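import numpy as np
import pytest

from mitoarch import (SyntheticSpec, generate_genome, hairpins,
                      noncoding_regions, poly_t_runs, rank_cr_candidates,
                      region_identity, region_sequence, revcomp,
                      tandem_repeats)

from conftest import make_genome


def test_fully_tiled_genome_has_no_spacers(tiled_genome):
    genome, _ = tiled_genome
    regions = [r for r in noncoding_regions(genome) if not r.annotated_cr]
    assert regions == []


def test_planted_gaps_recovered_exactly():
    """Three unannotated gaps between features come back as exactly those
    intervals, including the circular closure."""
    seq = "ACGT" * 50   # 200 bp
    feats = [("trnA", "tRNA", 10, 40, "+"), ("trnC", "tRNA", 60, 100, "+"),
             ("trnD", "tRNA", 130, 190, "+")]
    g = make_genome(seq, feats)
    regions = noncoding_regions(g)
    spans = sorted((r.start, r.end) for r in regions)
    assert spans == [(40, 60), (100, 130), (190, 10)]
    wrap = [r for r in regions if r.start == 190][0]
    assert wrap.length == 20
    assert wrap.flanking == ("trnD", "trnA")


def test_noncoding_plus_features_tile_genome(default_genome):
    genome, _ = default_genome
    n = len(genome)
    feat_len = sum(f.length(n) for f in genome.features)
    noncod = sum(r.length for r in noncoding_regions(genome)
                 if not r.annotated_cr)
    assert feat_len + noncod == n


def test_poly_t_hand_count():
    runs = poly_t_runs("AATTTTTTTTTTTTTG", min_len=10)
    assert [(p, l) for p, l, s in runs if s == "+"] == [(2, 13)]


def test_poly_t_both_strands():
    runs = poly_t_runs("AAAAAAAAAAAACCTTTTTTTTTT", min_len=10)
    assert ( (0, 12, "-") in runs ) and ( (14, 10, "+") in runs )
    assert poly_t_runs("ACGT" * 10, min_len=10) == []


def test_tandem_repeat_trivial():
    calls = tandem_repeats("ACGTACGTACGT", seed=4, min_period=2, max_period=6)
    assert len(calls) == 1
    period, copies, span = calls[0]
    assert period == 4 and copies == pytest.approx(3.0)


def test_tandem_repeat_planted_with_noise():
    """A period-17 repeat with 4 copies and 5% per-base noise is found
    with period 17 ± 1."""
    rng = np.random.default_rng(10)
    unit = "".join(rng.choice(list("ACGT"), 17))
    copies = []
    for _ in range(4):
        c = list(unit)
        for i in range(len(c)):
            if rng.random() < 0.05:
                c[i] = rng.choice([b for b in "ACGT" if b != c[i]])
        copies.append("".join(c))
    flank1 = "".join(rng.choice(list("ACGT"), 60))
    flank2 = "".join(rng.choice(list("ACGT"), 60))
    calls = tandem_repeats(flank1 + "".join(copies) + flank2)
    assert any(abs(p - 17) <= 1 for p, _, _ in calls)


def test_hairpin_trivial_and_empty():
    calls = hairpins("GGGGGG" + "AAAA" + "CCCCCC")
    assert (6, 4, 0) in calls
    assert hairpins("A" * 40 + "G" * 5 + "A" * 40) == []


def brute_hairpins(seq, min_stem=6, loop_range=(3, 30)):
    """All (i, j) stem scans by direct enumeration."""
    pair = {"A": "T", "T": "A", "G": "C", "C": "G"}
    found = set()
    L = len(seq)
    for loop in range(loop_range[0], loop_range[1] + 1):
        for i1 in range(L):
            i2 = i1 + loop + 1
            if i2 >= L:
                break
            a, b, stem = i1, i2, 0
            while a >= 0 and b < L and pair.get(seq[a]) == seq[b]:
                stem += 1
                a -= 1
                b += 1
            if stem >= min_stem:
                found.add((stem, loop, a + 1))
    return sorted(found, key=lambda h: (h[2], h[1]))


def test_hairpins_match_enumeration_oracle():
    rng = np.random.default_rng(11)
    seq = "".join(rng.choice(list("ACGT"), 1000, p=[0.3, 0.2, 0.2, 0.3]))
    assert hairpins(seq) == brute_hairpins(seq)


def test_detectors_mirror_under_revcomp():
    rng = np.random.default_rng(12)
    seq = ("".join(rng.choice(list("ACGT"), 80)) + "T" * 12
           + "".join(rng.choice(list("ACGT"), 80)))
    rc = revcomp(seq)
    fwd = {(l, s) for _, l, s in poly_t_runs(seq, 10)}
    rev = {(l, "+" if s == "-" else "-") for _, l, s in poly_t_runs(rc, 10)}
    assert fwd == rev
    assert (sorted(s for s, _, _ in hairpins(seq))
            == sorted(s for s, _, _ in hairpins(rc)))


def test_rank_planted_cr_first():
    spec = SyntheticSpec(seed=13, long_spacers=(("cox1", 250), ("nad4", 300)))
    genome, _ = generate_genome(spec)
    cands = rank_cr_candidates(genome)
    assert len(cands) == 3
    assert cands[0].region.annotated_cr
    assert cands[0].score >= 3


def test_rank_featureless_spacers_by_length():
    """Spacers carrying none of the four CR feature classes all score 0
    and rank purely by length. Purine-only spacers cannot form
    Watson-Crick stems; the seed gives runs, repeats and AT content
    below every feature threshold."""
    rng = np.random.default_rng(1)
    sp = ["".join(rng.choice(list("AG"), n)) for n in (150, 100, 60)]
    trna = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(3)]
    seq = trna[0] + sp[0] + trna[1] + sp[1] + trna[2] + sp[2]
    g = make_genome(seq, [("trnA", "tRNA", 0, 30, "+"),
                          ("trnC", "tRNA", 180, 210, "+"),
                          ("trnD", "tRNA", 310, 340, "+")])
    cands = rank_cr_candidates(g)
    assert [c.score for c in cands] == [0, 0, 0]
    lengths = [c.region.length for c in cands]
    assert lengths == sorted(lengths, reverse=True)


def test_short_spacers_excluded_with_warning():
    g = make_genome("GC" * 40, [("trnA", "tRNA", 0, 30, "+"),
                                ("trnC", "tRNA", 40, 80, "+")])
    with pytest.warns(UserWarning, match="no noncoding region"):
        assert rank_cr_candidates(g) == []


def test_region_identity_planted_substitutions():
    rng = np.random.default_rng(14)
    a = "".join(rng.choice(list("ACGT"), 102))
    b = list(a)
    for p in (10, 60):
        b[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[p]]
    assert region_identity(a, "".join(b)).percent_identity == pytest.approx(98.04, abs=0.01)
    assert region_identity(a, a).percent_identity == 100.00


def test_region_sequence_wrap(default_genome):
    genome, _ = default_genome
    regions = noncoding_regions(genome)
    for r in regions:
        assert len(region_sequence(genome, r)) == r.length
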