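"""Shared fixtures: converged steady-state runs are expensive, so each
preset/variant combination is simulated once per session and reused."""

import pytest

import minicvs as m
from minicvs import simulator


def _steady(preset_name, variant):
    p = m.preset(preset_name)
    p.variant = variant
    return m.run_to_steady_state(p)


@pytest.fixture(scope="session")
def healthy_dyn():
    """Healthy preset, dynamic-aperture mitral valve, converged cycle."""
    return _steady("healthy", "dynamic_mv")


@pytest.fixture(scope="session")
def healthy_hv():
    """Healthy preset, Heaviside diode mitral valve, converged cycle."""
    return _steady("healthy", "heaviside")


@pytest.fixture(scope="session")
def imi_dyn():
    """Ischemic-mitral-insufficiency preset, dynamic valve, converged cycle."""
    return _steady("imi", "dynamic_mv")


@pytest.fixture(scope="session")
def imi_hv():
    """IMI preset with the Heaviside valve law, converged cycle."""
    return _steady("imi", "heaviside")


@pytest.fixture(scope="session")
def thirty_cycle_runs():
    """30-cycle dense trajectories for every preset/variant combination."""
    runs = {}
    for preset_name in ("healthy", "imi"):
        for variant in ("heaviside", "dynamic_mv"):
            p = m.preset(preset_name)
            p.variant = variant
            runs[(preset_name, variant)] = m.simulate(p, n_cycles=30)
    return runs
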