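import pytest

from tsscan.synthetic import ToySystemSpec, make_dszc_like_case, make_toy_pair


@pytest.fixture(scope="session")
def toy():
    """Default dipolar toy system: (StatePair, oracle answer sheet)."""
    return make_toy_pair(ToySystemSpec())


@pytest.fixture(scope="session")
def toy_pair(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_answers(toy):
    return toy[1]


@pytest.fixture(scope="session")
def case():
    """Full synthetic end-to-end case with planted ground truth."""
    return make_dszc_like_case(seed=3)


@pytest.fixture(scope="session")
def case_on_disk(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("case_bundle")
    return make_dszc_like_case(seed=3, outdir=outdir)
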