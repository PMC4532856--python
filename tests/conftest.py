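import numpy as np
import pytest

from gcgrflex import synth, xlms


@pytest.fixture(scope="session")
def helix20():
    return synth.make_ideal_helix(20)


@pytest.fixture(scope="session")
def xl_pair():
    """The engineered-disulfide peptide pair joining the ECD and ECL3."""
    return xlms.crosslink_mass("YLPWHCK", "AFVTDECAQGTLR")


@pytest.fixture()
def flat_scenario():
    return synth.HingeScenario(
        theta=np.full(5, 20.0), phi=np.full(5, 30.0), d=np.full(5, 45.0)
    )


@pytest.fixture()
def small_hinge(flat_scenario):
    traj, truth, domains = synth.make_hinge_trajectory(flat_scenario)
    return traj, truth, domains
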