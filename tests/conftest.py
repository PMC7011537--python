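import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from delphiscales import (
    RatingsPanel,
    SimulatorConfig,
    builtin_scales,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def registry():
    return builtin_scales()


def make_panel(rows, goals=None):
    """Panel from (participant, round, goal, scale, rating) tuples."""
    return RatingsPanel.from_records(rows, goals=goals)


@pytest.fixture
def tiny_three_panel():
    """Two participants, one goal, three-point scale, both rounds."""
    rows = [
        ("p1", 1, "pain", "three_point", "main goal"),
        ("p1", 2, "pain", "three_point", "main goal"),
        ("p2", 1, "pain", "three_point", "main goal"),
        ("p2", 2, "pain", "three_point", "secondary goal"),
    ]
    return make_panel(rows, goals=["pain"])


def single_goal_config(
    rho=0.97,
    tau=(0.0654, 0.0904, 0.1246),
    beta=0.0,
    n=87,
    seed=0,
    round2_shift=0.0,
    participant_sd=0.7,
):
    """Default-like config restricted to one goal."""
    return SimulatorConfig(
        n_participants=n,
        goal_effects={"pain": beta},
        participant_sd=participant_sd,
        retest_correlation=rho,
        scale_noise={"three_point": tau[0], "five_point": tau[1], "nine_point": tau[2]},
        cutpoints={
            "three_point": (-1.4860, -0.9065),
            "five_point": (-2.2491, -1.6405, -1.0842, -0.4111),
            "nine_point": (-3.0009, -2.6261, -2.2030, -1.9145, -1.6196, -1.3695, -0.9594, -0.3493),
        },
        round2_shift=round2_shift,
        seed=seed,
    )
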