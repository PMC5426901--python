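import numpy as np
import pytest

from ubnmr.synthetic import SyntheticConfig, generate_bead_system


@pytest.fixture(scope="session")
def bead_fixture():
    """20-bead two-group system with 5 designated active beads per group,
    shared by all restraint tests (3 replicas)."""
    cfg = SyntheticConfig(seed=2024, noise_sd=0.0)
    frames, groups, model_distances = generate_bead_system(
        cfg, 20, (list(range(5)), list(range(10, 15))), n_replicas=3
    )
    return frames, groups, model_distances


@pytest.fixture()
def fresh_beads():
    """Factory for mutable bead systems (integration tests move them)."""

    def make(seed=2024, n_beads=20, n_replicas=3):
        cfg = SyntheticConfig(seed=seed, noise_sd=0.0)
        return generate_bead_system(
            cfg, n_beads, (list(range(5)), list(range(10, 15))), n_replicas=n_replicas
        )

    return make


def finite_difference_forces(energy_fn, frames, h=1e-6, stride=5):
    """Central-difference forces for a frames -> (energy, forces) function.

    Checks a strided subset of coordinates to keep runtime modest; returns
    (analytic, numeric) flat arrays over the checked components.
    """
    _, forces = energy_fn(frames)
    ana, num = [], []
    for m, frame in enumerate(frames):
        for i in range(0, frame.n_atoms, stride):
            for d in range(3):
                frame.positions[i, d] += h
                ep, _ = energy_fn(frames)
                frame.positions[i, d] -= 2 * h
                em, _ = energy_fn(frames)
                frame.positions[i, d] += h
                num.append(-(ep - em) / (2 * h))
                ana.append(forces[m][i, d])
    return np.array(ana), np.array(num)
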