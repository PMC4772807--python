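import hypothesis
import pytest

from neuropep import MaturePeptide

hypothesis.settings.register_profile(
    "deterministic", derandomize=True, max_examples=60, deadline=None
)
hypothesis.settings.load_profile("deterministic")

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


def make_peptide(seq: str, amide: bool = True, pyro: bool = False) -> MaturePeptide:
    """Build a mature peptide record directly (bypassing excision) for classifier tests."""
    return MaturePeptide(
        seq=seq,
        precursor_coords=(1, len(seq)),
        cterm_amide=amide,
        nterm_pyroglu=pyro,
        cys_positions=[i + 1 for i, c in enumerate(seq) if c == "C"],
    )


@pytest.fixture
def peptide_factory():
    return make_peptide
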