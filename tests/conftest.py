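import pytest

import mutlineage as ml


@pytest.fixture(scope="session")
def yeast():
    return ml.builtin_karyotype("yeast_s288c")


@pytest.fixture(scope="session")
def human():
    return ml.builtin_karyotype("human_grch38")


@pytest.fixture(scope="session")
def toy_chromset():
    """Two chromosomes, fractions 0.25 / 0.75."""
    return ml.ChromosomeSet(("chrA", "chrB"), (100, 300), ploidy=2)


@pytest.fixture(scope="session")
def small_lineage():
    """A clean 10-division pedigree at study conditions, with truth."""
    return ml.generate_lineage(10, mu=138.0, theta=60.42, seed=1)


@pytest.fixture(scope="session")
def small_called(small_lineage):
    lineage, _ = small_lineage
    return ml.call_lineage(lineage, detect_errors=False)
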