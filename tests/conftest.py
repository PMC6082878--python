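import numpy as np
import pytest
from hypothesis import settings

import hybridscan as hs

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def quartet_model():
    """The standard asymmetric 4-taxon species tree (coalescent units)."""
    return hs.SpeciesTreeModel("(((P1:1,P2:1):1,P3:2):1,O:3);")


@pytest.fixture(scope="session")
def quartet():
    return hs.QuartetSelection("P1", "P2", "P3", "O")


@pytest.fixture(scope="session")
def singleton_groups():
    return hs.GroupAssignment(
        {"P1": {"P1"}, "P2": {"P2"}, "P3": {"P3"}, "O": {"O"}}
    )


def make_alignment(rows: dict[str, str], locus_id: str = "toy") -> hs.LocusAlignment:
    return hs.LocusAlignment(locus_id, list(rows), list(rows.values()))


@pytest.fixture(scope="session")
def eight_taxon_low_ils():
    """A deep (low-ILS) 8-taxon species tree plus one simulated dataset."""
    model = hs.SpeciesTreeModel(
        "((((A:1,B:1):4,(C:2,D:2):3):5,((E:3,F:3):4,G:7):3):5,H:15);"
    )
    cfg = hs.SimConfig(n_loci=60, locus_length=200, theta=0.01, seed=11,
                       missing_fraction=0.0)
    ds = hs.simulate_dataset(model, [], cfg)
    reference = hs.read_newick("((((A,B),(C,D)),((E,F),G)),H);")
    return model, ds, reference


def random_toy_alignment(rng: np.random.Generator, n_sites: int | None = None,
                         taxa=("P1", "P2", "P3", "O")) -> hs.LocusAlignment:
    """Random small alignment over ACGT plus gaps/missing/ambiguity."""
    chars = np.array(list("ACGTACGTACGT-N?R"))
    n = n_sites if n_sites is not None else int(rng.integers(4, 51))
    rows = {
        t: "".join(rng.choice(chars, size=n)) for t in taxa
    }
    return make_alignment(rows, locus_id=f"rand{rng.integers(1e9)}")
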