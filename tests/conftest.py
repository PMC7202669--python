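"""Shared fixtures: the CD2 worked example and small synthetic corpora."""

from __future__ import annotations

import pytest

from sscnn import GeneratorConfig, simulate_corpus
from sscnn.labels import SSDisRecord, write_ss_dis

# The published worked example for PDB entry 1A64 chain A (rat CD2 adhesion
# domain): the combined DSSP-disorder label string as printed.  The printed
# sequence is one character longer than the printed combined string (a
# character was lost at a line wrap in the source); the fixture record is
# truncated to the 96 positions the combined string covers so that the two
# are aligned, and is synthetic in that sense.
CD2_COMBINED = (
    "XXXCEEEEETTCCEEECCTTCCCCTTEEEEEEEETTEEEEEEESSCEESSTTEEECTTSCEEESSCCGGGCEEEE"
    "EEEEETTSCEEEEEEEEEEEE"
)
CD2_SEQUENCE_FULL = (
    "RDSGTVWGALGHGINLNIPNFQMTDDIDEVRWERGSTLVAEFKRKPFLKSGAFEILANGDLKIKNLTRDDSGTYN"
    "VTVYSTNGTRILDKALDLRILE"
)
CD2_SEQUENCE = CD2_SEQUENCE_FULL[: len(CD2_COMBINED)]


def make_cd2_record() -> SSDisRecord:
    """Reconstruct the raw ss_dis triple that combines into CD2_COMBINED."""
    secstr = "".join(" " if c in "CX" else c for c in CD2_COMBINED)
    disorder = "".join("X" if c == "X" else "-" for c in CD2_COMBINED)
    return SSDisRecord(
        pdb_id="1A64", chain_id="A", sequence=CD2_SEQUENCE,
        secstr=secstr, disorder=disorder,
    )


@pytest.fixture(scope="session")
def cd2_record() -> SSDisRecord:
    return make_cd2_record()


@pytest.fixture(scope="session")
def cd2_ss_dis_text() -> str:
    return write_ss_dis([make_cd2_record()])


@pytest.fixture(scope="session")
def small_corpus():
    """A 30-chain corpus with planted signal, shared across test modules."""
    config = GeneratorConfig(n_chains=30, max_length=150)
    return simulate_corpus(config, seed=20123)


@pytest.fixture(scope="session")
def corpus_samples(small_corpus):
    """Featurized samples per chain of the shared corpus."""
    from sscnn import featurize_chain

    out = {}
    for chain in small_corpus.chains:
        pset = small_corpus.profiles[chain.key]
        out[chain.key] = featurize_chain(chain, pset.pssm1, pset.pssm2, pset.hhm)
    return out
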