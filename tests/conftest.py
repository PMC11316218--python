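import numpy as np
import pytest

from pks3.io import (
    ReferenceProfile,
    SequenceRecord,
    TriadSite,
    DiagnosticSite,
    load_default_profiles,
)
from pks3.simulate import SyntheticFamilySpec, make_reference_scaffold

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def default_profiles():
    return load_default_profiles()


@pytest.fixture(scope="session")
def scaffolds():
    """Synthetic per-class reference scaffolds at a fixed seed."""
    return make_reference_scaffold(SyntheticFamilySpec(seed=11))


@pytest.fixture(scope="session")
def small_profile():
    """A short hand-checkable reference profile.

    40 residues; triad C5/H20/N30, motif at 34, one ASCL-style diagnostic
    G at 10 and A/V at 15.
    """
    seq = list("MKTAYIAKQRQISFVKSHFS" "RQLEERLGLIEVQNAGFGPG")
    seq[4] = "C"
    seq[19] = "H"
    seq[29] = "N"
    seq[9] = "G"
    seq[14] = "A"
    record = SequenceRecord(id="mini_ref", residues="".join(seq))
    return ReferenceProfile(
        name="mini_ref",
        record=record,
        class_tag="ASCL",
        triad_positions=(TriadSite(5, "C"), TriadSite(20, "H"), TriadSite(30, "N")),
        diagnostic_positions=(
            DiagnosticSite(10, frozenset("G"), "ASCL"),
            DiagnosticSite(15, frozenset("AV"), "ASCL"),
        ),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_protein(rng, length):
    return "".join(rng.choice(list(AA), size=length))
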