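import pytest

import phosbe as pb


@pytest.fixture(scope="session")
def toy_proteome():
    return pb.generate_toy_proteome(
        n_proteins=10, n_designable_sites=12, n_undesignable_sites=4,
        seed=7, editor_name="CBE",
    )


@pytest.fixture(scope="session")
def toy_library(toy_proteome):
    return pb.design_library(
        toy_proteome.sites, toy_proteome.records, pb.get_editor("CBE"),
        n_controls=50, seed=1,
    )


make_synthetic_library = pb.make_abstract_library


@pytest.fixture(scope="session")
def screen_library():
    return make_synthetic_library(n_sites=200, guides_per_site=10, n_controls=100)
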