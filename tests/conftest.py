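import pytest

import novoscreen as nv


@pytest.fixture(scope="session")
def registry():
    return nv.packaged_registry()


@pytest.fixture(scope="session")
def library(registry):
    return nv.enumerate_library(registry)


@pytest.fixture(scope="session")
def pbmc():
    return nv.pbmc_panel()


@pytest.fixture(scope="session")
def u937():
    cells, _, _ = nv.default_panel()
    return next(c for c in cells if c.name == "U937_like")


@pytest.fixture(scope="session")
def donors(registry):
    return nv.make_donors(3, registry.receptors, seed=1)


@pytest.fixture(scope="session")
def constructs_by_id(library):
    return {c.construct_id: c for c in library}
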