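import numpy as np
import pytest

from mectopo import synthio


@pytest.fixture(scope="session")
def arena():
    return synthio.ArenaSpec()


@pytest.fixture(scope="session")
def traj600(arena):
    """Ten-minute foraging path shared across tests."""
    return synthio.simulate_trajectory(600.0, arena, seed=11)


@pytest.fixture(scope="session")
def traj1200(arena):
    """Twenty-minute foraging path (coverage-level tests)."""
    return synthio.simulate_trajectory(1200.0, arena, seed=12)


@pytest.fixture(scope="session")
def grid_cell():
    return synthio.GroundTruthCell(
        "g0", "grid",
        {"spacing_cm": 40.0, "orientation_deg": 10.0, "phase_x_cm": 5.0, "phase_y_cm": 5.0},
        peak_rate=2.0, anat_x_um=100.0, anat_y_um=100.0,
    )


@pytest.fixture(scope="session")
def hd_cell():
    return synthio.GroundTruthCell(
        "h0", "hd", {"preferred_deg": 135.0, "concentration": 6.0},
        peak_rate=2.0, anat_x_um=200.0, anat_y_um=200.0,
    )


@pytest.fixture(scope="session")
def border_cell():
    return synthio.GroundTruthCell(
        "b0", "border", {"wall": 0, "depth_cm": 6.0},
        peak_rate=2.0, anat_x_um=300.0, anat_y_um=300.0,
    )


@pytest.fixture(scope="session")
def untuned_cell():
    return synthio.GroundTruthCell(
        "u0", "untuned", {}, peak_rate=1.0, anat_x_um=50.0, anat_y_um=400.0,
    )
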