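import numpy as np
import pytest

from mitoarch import (classify_start_stop, codon_usage, enc,
                      enc_gc3s_correlation, family_partition, gc3s,
                      pcg_sequences)
from mitoarch.codon_enc import ALL_CODONS, CODON_TO_AA, SENSE_CODONS, STOP_CODONS


def wright_nc_oracle(counts, fams):
    """Direct spreadsheet-style evaluation of Wright's formula."""
    by_class = {}
    for codons in fams.values():
        k = len(codons)
        n = sum(counts.get(c, 0) for c in codons)
        if n >= 2:
            fhat = (n * sum((counts.get(c, 0) / n) ** 2 for c in codons) - 1) / (n - 1)
        else:
            fhat = None
        by_class.setdefault(k, []).append(fhat)
    nc = 0.0
    for k, fhats in by_class.items():
        measured = [f for f in fhats if f is not None and f > 0]
        mean_f = sum(measured) / len(measured) if measured else 1.0 / k
        nc += len(fhats) / mean_f
    return min(nc, len(SENSE_CODONS))


def cds_from_counts(counts):
    return ["".join(c * n for c, n in sorted(counts.items()))]


def test_table5_partition_structure():
    """Invertebrate mitochondrial code: 20 families (12 two-fold, 6
    four-fold, Leu six-fold, Ser eight-fold), 62 sense codons."""
    fams = family_partition()
    sizes = sorted(len(v) for v in fams.values())
    assert sizes == [2] * 12 + [4] * 6 + [6, 8]
    assert len(SENSE_CODONS) == 62
    assert set(STOP_CODONS) == {"TAA", "TAG"}
    split = family_partition(split_leu_ser=True)
    assert len(split) == 22


def test_codon_usage_simple():
    usage = codon_usage(["TTTTTA"])
    assert usage.percents["TTT"] == pytest.approx(50.0)
    assert usage.percents["TTA"] == pytest.approx(50.0)
    assert usage.n_codons == 2


def test_codon_usage_known_multiset():
    counts = {"ATT": 7, "GGC": 3, "TGA": 5}   # TGA = Trp under table 5
    usage = codon_usage(cds_from_counts(counts))
    for c, n in counts.items():
        assert usage.counts[c] == n
    assert sum(usage.percents.values()) == pytest.approx(100.0)


def test_codon_usage_drops_trailing_partial_and_stops():
    usage = codon_usage(["TTTAA"])            # TTT + partial AA
    assert usage.n_codons == 1
    usage2 = codon_usage(["TTTTAA"])          # TTT + stop
    assert usage2.counts["TAA"] == 0
    assert usage2.n_codons == 1
    with pytest.raises(ValueError):
        codon_usage([])


@pytest.mark.parametrize("cds, start, stop, standard, truncated", [
    ("ATGAAATAA", "ATG", "TAA", True, False),
    ("GTGAAAT", "GTG", "T", True, True),
    ("ATTAAAAATA", "ATT", "A", True, True),
    ("CTGAAATAG", "CTG", "TAG", False, False),
])
def test_classify_start_stop(cds, start, stop, standard, truncated):
    assert classify_start_stop(cds) == (start, stop, standard, truncated)


def test_internal_stop_warns_but_counts():
    with pytest.warns(UserWarning, match="internal stop"):
        classify_start_stop("ATGTAAAAATAA")


def test_synthetic_pcgs_use_standard_starts(default_genome):
    genome, _ = default_genome
    for cds in pcg_sequences(genome).values():
        _, _, standard, _ = classify_start_stop(cds)
        assert standard


def test_enc_one_codon_per_family_equals_family_count():
    """Extreme bias: every family uses a single codon, so every F̂ = 1 and
    Nc equals the number of families (20)."""
    fams = family_partition()
    cds = ["".join(codons[0] * 50 for codons in fams.values())]
    assert enc(cds).nc == pytest.approx(len(fams))


def test_enc_uniform_usage_approaches_sense_codon_count():
    cds = ["".join(SENSE_CODONS) * 30]
    assert enc(cds).nc == pytest.approx(len(SENSE_CODONS), abs=1e-9)


def test_enc_matches_direct_formula_oracle():
    rng = np.random.default_rng(42)
    for _ in range(10):
        counts = {c: int(rng.integers(0, 40)) for c in SENSE_CODONS}
        result = enc(cds_from_counts(counts))
        expected = wright_nc_oracle(counts, family_partition())
        assert result.nc == pytest.approx(expected)


def test_enc_invariances():
    rng = np.random.default_rng(3)
    counts = {c: int(rng.integers(1, 30)) for c in SENSE_CODONS}
    base = enc(cds_from_counts(counts)).nc
    # concatenation order
    parts = sorted(counts.items())
    shuffled = ["".join(c * n for c, n in parts[::-1])]
    assert enc(shuffled).nc == pytest.approx(base)
    # scaling all counts k -> m*k converges (finite-n F-hat bias shrinks)
    def nc_at(m):
        return enc(cds_from_counts({c: m * n for c, n in counts.items()})).nc
    d_small = abs(nc_at(2) - nc_at(1))
    d_large = abs(nc_at(8) - nc_at(4))
    assert d_large < d_small
    # synonymous relabeling within a family
    fams = family_partition()
    leu = list(fams["L"])
    relabeled = dict(counts)
    relabeled[leu[0]], relabeled[leu[1]] = counts[leu[1]], counts[leu[0]]
    assert enc(cds_from_counts(relabeled)).nc == pytest.approx(base)


def test_enc_errors():
    with pytest.raises(ValueError):
        enc(["TT"])


def test_gc3s_hand_computable():
    # third positions: C, G, A, T over GCN codons (all Ala, one family)
    cds = ["GCCGCGGCAGCT"]
    assert gc3s(cds) == pytest.approx(0.5)


def test_gc3s_binomial_recovery():
    rng = np.random.default_rng(9)
    third = rng.choice(list("GC") + list("AT"), size=5000, p=[0.15, 0.15, 0.35, 0.35])
    cds = ["".join("GC" + b for b in third)]  # GCN = Ala family
    se = np.sqrt(0.3 * 0.7 / 5000)
    assert gc3s(cds) == pytest.approx(0.30, abs=3 * se)


def test_correlation_perfect_line_and_null():
    from mitoarch.codon_enc import EncResult
    res = [EncResult(nc=40 + i, gc3s=0.1 + 0.02 * i, family_homozygosity={}, n_codons=100)
           for i in range(5)]
    assert enc_gc3s_correlation(res).r == pytest.approx(1.0)
    # permutation null centred at zero
    rng = np.random.default_rng(0)
    nc = rng.normal(size=30)
    g3 = rng.normal(size=30)
    rs = []
    for _ in range(2000):
        perm = rng.permutation(30)
        rs.append(np.corrcoef(nc, g3[perm])[0, 1])
    assert abs(np.mean(rs)) < 0.02


def test_correlation_errors():
    from mitoarch.codon_enc import EncResult
    res = [EncResult(nc=50.0, gc3s=0.2, family_homozygosity={}, n_codons=10)] * 4
    with pytest.raises(ValueError, match="zero variance"):
        enc_gc3s_correlation(res)
    with pytest.raises(ValueError, match="at least 3"):
        enc_gc3s_correlation(res[:2])
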