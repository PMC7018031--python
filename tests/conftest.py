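"""Shared fixtures: small simulations and rendered stacks reused across tests.

Session-scoped so the expensive renders happen once; all seeds are fixed so
the suite is deterministic.
"""

from __future__ import annotations

import warnings

import pytest

from motortraffic import (
    KineticParams,
    LatticeConfig,
    OpticsConfig,
    background_subtract,
    make_kymograph,
    parametric_trajectories,
    render_stack,
    simulate,
    summarize,
)


@pytest.fixture(scope="session")
def kinesin2_params() -> KineticParams:
    """The kinesin-II (PEM12) parameter set — the package defaults."""
    return KineticParams()


@pytest.fixture(scope="session")
def dilute_sim(kinesin2_params):
    """Long dilute-limit simulation: 20 um, 13 lanes, ~0.2 motors/um."""
    cfg = LatticeConfig(
        lattice_length=20.0,
        duration=2500.0,
        concentration=0.2,
        seed=101,
    )
    ts = simulate(kinesin2_params, cfg)
    obs = summarize(ts)
    return ts, obs


@pytest.fixture(scope="session")
def corr_fixture():
    """Low-density rendered stack emulating the experimental acquisition.

    1000 frames, 200 ms exposure, 80 nm pixels; parametric trajectories with
    the kinesin-II dilute-limit kinetics (v = 0.3 um/s, omega_D = 0.25 /s),
    ~0.5 labeled motors/um on a 20 um microtubule.
    """
    traj = parametric_trajectories(
        v=0.3,
        omega_D=0.25,
        binding_rate_per_um=0.125,
        length=20.0,
        duration=210.0,
        seed=5,
    )
    optics = OpticsConfig(n_frames=1000, seed=6)
    stack = render_stack(traj, optics)
    kymo = background_subtract(make_kymograph(stack))
    return traj, stack, kymo


@pytest.fixture(scope="session")
def spt_fixture():
    """Single-molecule stack with the single-particle fixture kinetics.

    v = 0.33 um/s, mean run length 1.18 um, sparse enough for tracking.
    """
    v, rl = 0.33, 1.18
    traj = parametric_trajectories(
        v=v,
        omega_D=v / rl,
        binding_rate_per_um=4.0 / 30.0,
        length=30.0,
        duration=210.0,
        seed=11,
    )
    optics = OpticsConfig(n_frames=1000, seed=12)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stack = render_stack(traj, optics)
    return traj, stack


@pytest.fixture(scope="session")
def spt_tracks(spt_fixture):
    from motortraffic import detect_and_link

    _, stack = spt_fixture
    return detect_and_link(stack, intensity_threshold=25.0, max_disp_per_frame=0.4)
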