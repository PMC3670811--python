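"""Shared fixtures: synthetic genomes at the scale of the study phages."""

import pytest

from phagekit import synthgen as sg

JA1_LENGTH = 69_278
JA1_GC = 0.346
JA1_N_CDS = 79
JA1_DTR = 1_974


@pytest.fixture(scope="session")
def ja1_like():
    """A 69,278 bp, 34.6% G+C, 79-CDS genome with a 1,974 bp terminal repeat
    and planted homopolymer tracts up to 12 nt."""
    spec = sg.GenomeSpec(
        length=JA1_LENGTH, gc=JA1_GC, n_cds=JA1_N_CDS, dtr_length=JA1_DTR,
        seed=1, homopolymers=((12, "A"), (8, "T"), (7, "C")),
    )
    return sg.make_genome(spec)


@pytest.fixture(scope="session")
def small_genome():
    """A fast 12 kb annotated genome for unit-scale tests."""
    spec = sg.GenomeSpec(length=12_000, gc=0.40, n_cds=8, dtr_length=0, seed=11)
    return sg.make_genome(spec)
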