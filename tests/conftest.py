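import pytest

import tracerrbs as t

# toy genome with exactly two CCGG sites flanking one 10 bp fragment:
# positions 0-17, motifs at 2 and 12, cut points 3 and 13
TOY_SEQ = "TTCCGGAACGTACCGGTT"


@pytest.fixture(scope="session")
def toy_genome():
    return t.GenomeSequence("toy", TOY_SEQ)


@pytest.fixture(scope="session")
def toy_fragment(toy_genome):
    (frag,) = t.digest(toy_genome)
    return frag


@pytest.fixture(scope="session")
def toy_bundle(toy_genome):
    """Reference over the toy genome with a short adapter, size range wide
    open so the single 10 bp fragment is retained."""
    return t.build_reference(
        [toy_genome], s_min=1, s_max=1000, adapter="AGATCGGAAG", spacer="A"
    )


@pytest.fixture(scope="session")
def small_genome():
    """~60 kb synthetic genome with planted CCGG sites, used for round-trip
    simulation tests."""
    return t.synthetic_genome(60_000, seed=42, site_spacing=(20, 200))


def make_fragment(length, chrom="c", start=100, seed_char="A"):
    """Fabricate a fragment of a given cut-to-cut length for size tests."""
    seq = ("CGG" + seed_char * max(0, length - 4) + "C")[:length]
    return t.MspFragment(chrom, start, start + length, seq)
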