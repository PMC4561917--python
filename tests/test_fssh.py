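"""Surface-hopping engine unit tests."""

from __future__ import annotations

import numpy as np
import pytest

from photorelax._constants import HBAR_EV_FS
from photorelax.fssh import (
    CoefficientCollapseError,
    SimParams,
    Trajectory,
    apply_hop,
    hop_probability,
    landau_zener_probability,
    propagate_trajectory,
    track_state_identity,
)
from photorelax.sampling import PhaseSpaceSample
from photorelax.vibronic import LinearCrossingModel, adiabatic_solve, build_preset


# -- SimParams ------------------------------------------------------------


def test_simparams_validation():
    with pytest.raises(ValueError):
        SimParams(dt_classical=0.0)
    with pytest.raises(ValueError):
        SimParams(n_quantum_substeps=0)
    with pytest.raises(ValueError):
        SimParams(friction=-1.0)
    with pytest.raises(ValueError):
        SimParams(decoherence="sometimes")
    with pytest.raises(ValueError):
        SimParams(frustrated_hop_policy="bounce")


# -- hop probability ------------------------------------------------------


def test_hop_probability_arithmetic():
    # |c_a|^2 = 0.5, Re(c_a* c_b) = 0.1, flux 0.05 fs^-1, dt_q = 0.025 fs
    ca = np.sqrt(0.5)
    cb = 0.1 / ca  # real coefficients: Re(ca* cb) = ca*cb = 0.1
    coeffs = np.array([ca, cb], dtype=complex)
    flux = np.array([0.0, 0.05])
    g = hop_probability(coeffs, flux, 0.025, active=0)
    assert g[0] == 0.0
    assert g[1] == pytest.approx(2 * 0.025 * 0.1 * 0.05 / 0.5, rel=1e-12)  # 5e-4


def test_hop_probability_zero_flux_and_clamping():
    coeffs = np.array([0.8, 0.6], dtype=complex)
    assert np.all(hop_probability(coeffs, np.zeros(2), 0.1, 0) == 0.0)
    # negative flux makes the expression negative -> clamped to exactly 0
    g = hop_probability(coeffs, np.array([0.0, -1.0]), 0.1, 0)
    assert g[1] == 0.0
    # enormous flux clamps to 1
    g = hop_probability(coeffs, np.array([0.0, 1e9]), 0.1, 0)
    assert g[1] == 1.0


def test_hop_probability_collapse_error():
    coeffs = np.array([1e-9, 1.0], dtype=complex)
    with pytest.raises(CoefficientCollapseError):
        hop_probability(coeffs, np.ones(2), 0.1, active=0)


# -- momentum rescaling ---------------------------------------------------


def test_apply_hop_zero_gap_keeps_momentum():
    E = np.array([1.0, 1.0])
    d = np.array([1.0, 0.0])
    P = np.array([3.0, -2.0])
    m = np.ones(2)
    P2, allowed = apply_hop(E, d, P, m, 0, 1)
    assert allowed
    np.testing.assert_allclose(P2, P, atol=1e-12)


def test_apply_hop_conserves_energy():
    rng = np.random.default_rng(8)
    m = np.array([2.0, 3.0, 1.5])
    for _ in range(20):
        E = np.sort(rng.random(2) + 1.0)
        d = rng.standard_normal(3)
        P = 3.0 * rng.standard_normal(3)
        # downward hop (gain > 0) is always allowed
        P2, allowed = apply_hop(E, d, P, m, 1, 0)
        assert allowed
        ke1 = np.sum(P * P / (2 * m)) + E[1]
        ke2 = np.sum(P2 * P2 / (2 * m)) + E[0]
        assert ke2 == pytest.approx(ke1, abs=1e-9)


def test_apply_hop_frustrated_policies():
    E = np.array([1.0, 5.0])  # upward hop needing 4 eV
    d = np.array([1.0, 0.0])
    P = np.array([0.5, 2.0])  # tiny projected kinetic energy
    m = np.ones(2)
    P_keep, allowed = apply_hop(E, d, P, m, 0, 1, policy="keep")
    assert not allowed
    np.testing.assert_allclose(P_keep, P)
    P_rev, allowed = apply_hop(E, d, P, m, 0, 1, policy="reverse")
    assert not allowed
    np.testing.assert_allclose(P_rev, np.array([-0.5, 2.0]), atol=1e-12)


def test_apply_hop_zero_nac_falls_back_to_momentum_rescale():
    E = np.array([2.0, 1.0])
    P = np.array([1.0, 1.0])
    m = np.ones(2)
    P2, allowed = apply_hop(E, np.zeros(2), P, m, 0, 1)
    assert allowed
    ke1 = np.sum(P * P / (2 * m)) + E[0]
    ke2 = np.sum(P2 * P2 / (2 * m)) + E[1]
    assert ke2 == pytest.approx(ke1, abs=1e-12)
    # direction preserved
    np.testing.assert_allclose(P2 / np.linalg.norm(P2), P / np.linalg.norm(P))


def test_apply_hop_same_state_rejected():
    with pytest.raises(ValueError):
        apply_hop(np.ones(2), np.ones(2), np.ones(2), np.ones(2), 1, 1)


# -- state-identity tracking ----------------------------------------------


def test_track_identity_on_identical_sets():
    V = np.linalg.qr(np.random.default_rng(0).standard_normal((4, 4)))[0]
    np.testing.assert_array_equal(track_state_identity(V, V), np.arange(4))


def test_track_identity_transposition():
    V = np.eye(3)
    W = V[:, [1, 0, 2]]
    np.testing.assert_array_equal(track_state_identity(V, W), [1, 0, 2])


def test_track_identity_small_perturbation_brute_force():
    from itertools import permutations

    rng = np.random.default_rng(77)
    V = np.linalg.qr(rng.standard_normal((4, 4)))[0]
    for _ in range(5):
        A = 1e-3 * rng.standard_normal((4, 4))
        W, _ = np.linalg.qr(V + A)
        perm = track_state_identity(V, W)
        np.testing.assert_array_equal(perm, np.arange(4))
        # brute force: the assignment maximises the total overlap
        overlap = np.abs(V.T @ W)
        best = max(permutations(range(4)), key=lambda p: sum(overlap[i, p[i]] for i in range(4)))
        np.testing.assert_array_equal(perm, best)


def test_track_identity_shape_mismatch():
    with pytest.raises(ValueError):
        track_state_identity(np.eye(3), np.eye(4))


# -- propagation ----------------------------------------------------------


def _still_sample(n_modes):
    return PhaseSpaceSample(R=np.zeros(n_modes), P=np.zeros(n_modes), harvest_time=0.0)


def test_decoupled_state_never_hops():
    model = build_preset("chla", {"couplings": {"constant": [], "linear": []}})
    params = SimParams(total_time=0.05, friction=0.0, seed=1)
    sample = PhaseSpaceSample(
        R=0.1 * np.ones(model.n_modes), P=np.zeros(model.n_modes), harvest_time=0.0
    )
    tr = propagate_trajectory(model, sample, 0, params)
    assert len(tr.hops) == 0
    assert np.all(tr.active_state == 0)
    pops = np.abs(tr.quantum_coeffs[:, 0]) ** 2
    np.testing.assert_allclose(pops, 1.0, atol=1e-9)


def test_energy_conservation_without_thermostat():
    model = build_preset("chla", {"couplings": {"constant": [], "linear": []}})
    params = SimParams(total_time=0.1, friction=0.0, seed=2, store_stride=10)
    rng = np.random.default_rng(3)
    sample = PhaseSpaceSample(
        R=0.2 * rng.standard_normal(model.n_modes),
        P=0.05 * rng.standard_normal(model.n_modes),
        harvest_time=0.0,
    )
    tr = propagate_trajectory(model, sample, 2, params)
    m = model.masses()
    energies = []
    for k in range(tr.R.shape[0]):
        pt = adiabatic_solve(model, tr.R[k])
        ke = float(np.sum(tr.P[k] ** 2 / (2 * m)))
        a = int(tr.active_state[k * tr.store_stride])
        energies.append(ke + model.ground_energy(tr.R[k]) + pt.energies[a])
    drift = max(energies) - min(energies)
    assert drift < 1e-5  # eV over 0.1 ps at dt = 0.1 fs


def test_quantum_norm_conserved(chla_model):
    params = SimParams(total_time=0.02, seed=4, store_stride=5)
    sample = _still_sample(chla_model.n_modes)
    tr = propagate_trajectory(chla_model, sample, 4, params, np.random.default_rng(5))
    norms = np.sum(np.abs(tr.quantum_coeffs) ** 2, axis=1)
    assert np.max(np.abs(norms - 1.0)) < 1e-6


def test_trajectory_bookkeeping(chla_model):
    params = SimParams(total_time=0.02, seed=6, store_stride=2)
    tr = propagate_trajectory(
        chla_model, _still_sample(chla_model.n_modes), 3, params, np.random.default_rng(7)
    )
    assert tr.times[0] == 0.0 and tr.times[-1] == pytest.approx(20.0)
    assert len(tr.active_state) == len(tr.times)
    assert tr.R.shape[0] == len(tr.times[::2])
    assert tr.initial_state == 3
    bands = tr.band_series()
    assert bands[0] == "B"
    assert set(tr.band_entry_times) <= {"Qy", "Qx", "B"}
    for ev in tr.hops:
        assert 0.0 < ev.time <= tr.times[-1]
        assert ev.from_state != ev.to_state


def test_invalid_initial_state(chla_model):
    with pytest.raises(ValueError):
        propagate_trajectory(
            chla_model, _still_sample(chla_model.n_modes), 10, SimParams(total_time=0.01)
        )


# -- Landau-Zener ---------------------------------------------------------


def test_landau_zener_closed_form_value():
    lam, slope, v = 0.06, 0.05, 0.5
    expected = np.exp(-2 * np.pi * lam**2 / (HBAR_EV_FS * v * 2 * slope))
    assert landau_zener_probability(lam, 2 * slope, v) == pytest.approx(expected, rel=1e-12)


def test_linear_crossing_single_sweep_transfers_population():
    """One fast diabatic sweep on the two-level model moves upper-state
    population close to the Landau-Zener prediction (ensemble version is the
    acceptance suite's 2000-trajectory check)."""
    model = LinearCrossingModel(slope=0.05, lam=0.06, mass=1000.0)
    v = 0.5
    params = SimParams(
        dt_classical=0.25, total_time=0.032, friction=0.0, store_stride=16
    )
    p_lz = landau_zener_probability(model.lam, 2 * model.slope, v)
    rng = np.random.default_rng(11)
    n = 60
    ups = 0
    for _ in range(n):
        sample = PhaseSpaceSample(
            R=np.array([-8.0]), P=np.array([model.mass * v]), harvest_time=0.0
        )
        tr = propagate_trajectory(model, sample, 0, params, rng)
        ups += int(tr.active_state[-1] == 1)
    frac = ups / n
    sigma = np.sqrt(p_lz * (1 - p_lz) / n)
    assert abs(frac - p_lz) < 4 * sigma + 0.02
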