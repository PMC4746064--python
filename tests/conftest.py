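import pandas as pd
import pytest

from funcodak.globalmapper import TaxonAbundanceTable
from funcodak.reference import CopyNumberTable, PathwayHierarchy, TaxonKey
from funcodak.synth import SynthSpec, make_reference


@pytest.fixture
def hand_table() -> CopyNumberTable:
    """Two genera with known enzyme dosages, plus a family-level profile for
    fallback resolution."""
    return CopyNumberTable(
        profiles={
            TaxonKey("Alphagenus", "genus"): {"1.1.1.1": 2.0, "1.1.1.3": 1.0},
            TaxonKey("Betagenus", "genus"): {"1.1.1.2": 3.0},
            TaxonKey("Gammaceae", "family"): {"1.1.1.1": 1.0, "1.1.1.2": 1.0},
        },
        parents={
            TaxonKey("Alphagenus", "genus"): TaxonKey("Gammaceae", "family"),
        },
    )


@pytest.fixture
def hand_hierarchy() -> PathwayHierarchy:
    """One 3-enzyme pathway, one single-enzyme blacklisted pathway."""
    return PathwayHierarchy(
        ec_to_l3={
            "1.1.1.1": {"pwA"},
            "1.1.1.2": {"pwA"},
            "1.1.1.3": {"pwA", "pwEuk"},
        },
        l3_enzymes={"pwA": {"1.1.1.1", "1.1.1.2", "1.1.1.3"}, "pwEuk": {"1.1.1.3"}},
        l3_to_l2={"pwA": "clA", "pwEuk": "clB"},
        l2_to_l1={"clA": "sc1", "clB": "sc1"},
        eukaryote_l3={"pwEuk"},
        l3_names={"pwA": "Pathway A", "pwEuk": "Eukaryotic pathway"},
    )


@pytest.fixture
def hand_abundance() -> TaxonAbundanceTable:
    return TaxonAbundanceTable(
        data=pd.DataFrame(
            {"Alphagenus": [50.0], "Betagenus": [50.0]}, index=["s1"]
        )
    )


@pytest.fixture(scope="session")
def synth_bundle():
    """A default-conditions synthetic bundle shared across tests."""
    spec = SynthSpec(seed=1)
    table, genomes, hierarchy = make_reference(spec)
    return spec, table, genomes, hierarchy
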