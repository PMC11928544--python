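import numpy as np
import pytest

from gaitwork.synthetic_gait import (
    SyntheticConfig,
    generate_planar_linkage,
    generate_point_mass,
)


@pytest.fixture(scope="session")
def point_mass_trial():
    """Symmetric point-mass walker, zero noise, 6 strides at 120 Hz."""
    return generate_point_mass(SyntheticConfig(seed=1, n_strides=6))


@pytest.fixture(scope="session")
def point_mass_fast():
    """Point-mass walker generated at 1200 Hz for differentiation-sensitive
    energy checks."""
    return generate_point_mass(
        SyntheticConfig(seed=1, n_strides=3, kinematic_rate=1200.0)
    )


@pytest.fixture(scope="session")
def linkage_trial():
    """Planar-linkage walker with anthropometric segment masses."""
    return generate_planar_linkage(
        SyntheticConfig(seed=1, model="planar_linkage", n_strides=4)
    )


@pytest.fixture(scope="session")
def rigid_ankle_trial():
    """Massless-foot linkage at 1200 Hz: the exact-equivalence oracle for
    unified-deformable vs ankle rotational power."""
    return generate_planar_linkage(
        SyntheticConfig(
            seed=1, model="planar_linkage", n_strides=3,
            foot_mass_scale=0.0, kinematic_rate=1200.0,
        )
    )


@pytest.fixture(scope="session")
def socket_trial():
    """Compliant-socket linkage with 50% interface energy dissipation."""
    return generate_planar_linkage(
        SyntheticConfig(
            seed=1, model="planar_linkage", n_strides=4,
            socket_compliance=2e-5, socket_dissipation_frac=0.5,
        )
    )


def limb_arrays(trial, limb):
    grf = trial.grf[limb][["fx", "fy", "fz"]].to_numpy()
    cop = trial.grf[limb][["copx", "copy", "copz"]].to_numpy()
    return grf, cop


def segment(trial, name):
    return next(s for s in trial.segments if s.name == name)
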