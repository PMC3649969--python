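import pytest

from snapvelcro import SimulationConfig

# Toy contig with one perfect and one singly-degenerate endonuclease site on
# the plus strand (T-run at 6..15, then A, G) and none on the minus strand.
TOY_SEQ = "CCCCCCTTTTTTTTTTAGCC"


@pytest.fixture
def toy_seq() -> str:
    return TOY_SEQ


@pytest.fixture
def toy_fasta(tmp_path):
    path = tmp_path / "toy.fa"
    path.write_text(f">toy\n{TOY_SEQ}\n")
    return path


@pytest.fixture
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=1)
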