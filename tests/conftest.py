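import pytest

import mutscan as ms


@pytest.fixture(scope="session")
def paper_family():
    """Seeded 155-sequence synthetic family with planted conservation."""
    fam, truth = ms.generate_family(ms.paper_family_config(seed=20))
    return fam, truth


@pytest.fixture(scope="session")
def paper_profile(paper_family):
    fam, _ = paper_family
    return ms.compute_profile(fam)


@pytest.fixture()
def toy_family():
    """Hand-built 4-sequence alignment used across module tests.

    Columns: 1=P invariant, 2=target/ref difference (L vs M),
    3=gap column, 4=A invariant, 5=T invariant.
    """
    return ms.AlignedFamily(
        [
            ms.AlignedRecord("target", "known", "PL-AT"),
            ms.AlignedRecord("reference", "known", "PMKAT"),
            ms.AlignedRecord("p1", "plant", "PLKAT"),
            ms.AlignedRecord("f1", "ascomycete", "PLKAT"),
        ]
    )


@pytest.fixture(scope="session")
def table1():
    return ms.table1_fixture()
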