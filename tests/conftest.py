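"""Shared fixtures.

Trained networks are expensive (tens of seconds each), so they are built once
per session and shared across test modules.  Fixture seeds are fixed so every
run exercises the same networks.
"""

import numpy as np
import pytest

from sahnet import SampleHoldModel, TaskConfig
from sahnet.network import NetworkSpec, build_network


@pytest.fixture(scope="session")
def run_a0():
    """Full 13,500-epoch reduction run on the dual task at alpha = 0."""
    return SampleHoldModel.from_alpha(0.0).fit(seed=101, reduce=True)


@pytest.fixture(scope="session")
def run_a05():
    """Full reduction run at alpha = 0.5 (common-differential regime)."""
    return SampleHoldModel.from_alpha(0.5).fit(seed=105, reduce=True)


@pytest.fixture(scope="session")
def run_a07():
    """Full reduction run at alpha = 0.7 (transition to averaging)."""
    return SampleHoldModel.from_alpha(0.7).fit(seed=107, reduce=True)


@pytest.fixture(scope="session")
def net5000_a03():
    """Unreduced 5000-epoch network at alpha = 0.3."""
    return SampleHoldModel.from_alpha(0.3).fit(n_epochs=5000, seed=103)


@pytest.fixture(scope="session")
def net5000_a06():
    """Unreduced 5000-epoch network at alpha = 0.6."""
    return SampleHoldModel.from_alpha(0.6).fit(n_epochs=5000, seed=106)


@pytest.fixture(scope="session")
def net5000_a09():
    """Unreduced 5000-epoch network at alpha = 0.9 (averaging regime)."""
    return SampleHoldModel.from_alpha(0.9).fit(n_epochs=5000, seed=109)


@pytest.fixture(scope="session")
def sah1_run():
    """Single-input sample-and-hold network trained for 5000 epochs."""
    task = TaskConfig(alpha=0.0, n_signals=1)
    spec = NetworkSpec(n_task_inputs=2, n_outputs=1)
    return SampleHoldModel(task=task, spec=spec).fit(n_epochs=5000, seed=111)


@pytest.fixture
def fresh_default_net():
    return build_network(NetworkSpec(), rng_state=0)


# Seed trios for statistics that are defined as medians/majorities across
# independently trained networks.  The first seed of each trio matches the
# corresponding single-run fixture above so those networks are reused.
TRIO_SEEDS = {
    0.0: (101, 301, 302),
    0.3: (103, 331, 332),
    0.5: (105, 351, 352),
    0.6: (106, 361, 362),
}


@pytest.fixture(scope="session")
def unreduced_trios(run_a0, net5000_a03, run_a05, net5000_a06):
    """Three epoch-5000 (unreduced) networks per common-mode level."""
    first = {0.0: run_a0.unreduced, 0.3: net5000_a03.network,
             0.5: run_a05.unreduced, 0.6: net5000_a06.network}
    trios = {}
    for alpha, seeds in TRIO_SEEDS.items():
        nets = [first[alpha]]
        for seed in seeds[1:]:
            nets.append(
                SampleHoldModel.from_alpha(alpha).fit(n_epochs=5000, seed=seed).network)
        trios[alpha] = nets
    return trios


@pytest.fixture(scope="session")
def reduced_a05_trio(run_a05):
    """Three fully reduced networks trained at alpha = 0.5."""
    nets = [run_a05.reduced]
    for seed in (355, 356):
        nets.append(SampleHoldModel.from_alpha(0.5).fit(seed=seed, reduce=True).reduced)
    return nets
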