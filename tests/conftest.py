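import pytest

from mitoarch import MitoGenome, GeneFeature, SyntheticSpec, generate_genome


def make_genome(seq, feats, circular=True, gid="TEST1"):
    """Tiny hand-built genome: feats = (label, kind, start, end, strand)."""
    features = [GeneFeature(label=l, kind=k, start=s, end=e, strand=st)
                for l, k, s, e, st in feats]
    return MitoGenome(id=gid, sequence=seq, circular=circular, features=features)


@pytest.fixture(scope="session")
def default_genome():
    """One deterministic full-size synthetic mitogenome (ground pattern)."""
    genome, truth = generate_genome(SyntheticSpec(seed=11))
    return genome, truth


@pytest.fixture(scope="session")
def tiled_genome():
    """Synthetic mitogenome with no spacers: annotation tiles the genome."""
    genome, truth = generate_genome(SyntheticSpec(seed=12, spacer_length=0))
    return genome, truth
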