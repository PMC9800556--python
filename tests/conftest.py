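import numpy as np
import pytest

from proofkin.core import Mechanism, RateConstant, RateConstantSet, Reaction, Species
from proofkin.protocols import ProtocolSimulator


@pytest.fixture(scope="session")
def two_state():
    """Minimal reversible E + D <-> ED network with its rates."""
    mech = Mechanism(
        name="two_state",
        species=(
            Species("E", "enzyme", enzyme_units=1),
            Species("D", "free-DNA", primer_length=27, fluorescence_class="free",
                    dna_units=1, nucleotide_units=27),
            Species("ED", "enzyme-bound-complex", primer_length=27, site="exo",
                    fluorescence_class="high", enzyme_units=1, dna_units=1,
                    nucleotide_units=27),
        ),
        reactions=(Reaction((("E", 1), ("D", 1)), (("ED", 1),), "kon", "koff"),),
    )
    rates = RateConstantSet(
        [
            RateConstant("kon", 1100.0, "uM-1 s-1"),
            RateConstant("koff", 44.1, "s-1"),
        ]
    )
    return mech, rates


@pytest.fixture(scope="session")
def fit_simulator():
    """Shared simulator at fitting tolerances (mechanism cache reused)."""
    return ProtocolSimulator(rtol=1e-6, atol=1e-10)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
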