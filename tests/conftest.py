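"""Shared fixtures: small hand-built models and the calibrated presets."""

from __future__ import annotations

import numpy as np
import pytest

from photorelax.vibronic import DiabaticModel, build_preset


@pytest.fixture(scope="session")
def chla_model():
    return build_preset("chla")


@pytest.fixture(scope="session")
def chlb_model():
    return build_preset("chlb")


def make_two_state_model(coupling: float = 0.05, displacement: float = 1.0) -> DiabaticModel:
    """Two shifted-harmonic diabats on one mode with a constant coupling.

    The diabats cross where ``E2 - omega*d2*q = E1 - omega*d1*q``.
    """
    return DiabaticModel(
        species="toy2",
        state_energies=np.array([1.0, 1.2]),
        mode_freqs=np.array([0.1]),
        displacements=np.array([[0.0], [displacement]]),
        couplings=np.array([[0.0, coupling], [coupling, 0.0]]),
        transition_dipoles=np.array([1.0, 0.5]),
    )


def make_random_model(rng: np.random.Generator, n_states: int = 3, n_modes: int = 2) -> DiabaticModel:
    """Random small model for finite-difference and property tests."""
    lam = 0.05 * rng.standard_normal((n_states, n_states))
    lam = 0.5 * (lam + lam.T)
    np.fill_diagonal(lam, 0.0)
    lin = 0.02 * rng.standard_normal((n_states, n_states, n_modes))
    lin = 0.5 * (lin + np.swapaxes(lin, 0, 1))
    return DiabaticModel(
        species="toy-random",
        state_energies=1.0 + rng.random(n_states),
        mode_freqs=0.05 + 0.1 * rng.random(n_modes),
        displacements=rng.standard_normal((n_states, n_modes)),
        couplings=lam,
        linear_couplings=lin,
        transition_dipoles=rng.random(n_states) + 0.1,
    )
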