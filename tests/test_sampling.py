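"""Ground-state sampling, spectra and Franck-Condon selection tests."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import chisquare

from photorelax._constants import HBAR_EV_FS, KB_EV_K
from photorelax.sampling import (
    LaserPulse,
    OffResonantError,
    absorption_spectrum,
    franck_condon_select,
    franck_condon_weights,
    run_ground_sampling,
)
from photorelax.vibronic import AdiabaticPoint, DiabaticModel, adiabatic_solve

from conftest import make_two_state_model


def one_mode_model():
    return DiabaticModel(
        species="toy1",
        state_energies=np.array([1.0]),
        mode_freqs=np.array([0.05]),
        displacements=np.zeros((1, 1)),
        couplings=np.zeros((1, 1)),
        transition_dipoles=np.ones(1),
    )


def fake_point(energies, strengths):
    energies = np.asarray(energies, dtype=float)
    strengths = np.asarray(strengths, dtype=float)
    n = len(energies)
    return AdiabaticPoint(
        position=np.zeros(1),
        energies=energies,
        gradients=np.zeros((n, 1)),
        nac=np.zeros((n, n, 1)),
        oscillator_strengths=strengths,
        eigenvectors=np.eye(n),
    )


# -- Langevin harvesting --------------------------------------------------


def test_equipartition_coordinate_variance():
    m = one_mode_model()
    n = 400
    samples = run_ground_sampling(
        m, n_configs=n, equilibration=2.0, spacing=0.5, seed=42
    )
    q = np.array([s.R[0] for s in samples])
    var = q.var()
    target = KB_EV_K * 300.0 / m.mode_freqs[0]  # kT / omega
    # 3 standard errors of a sample variance of ~n (weakly correlated) draws
    tol = 3.0 * target * np.sqrt(2.0 / n)
    assert abs(var - target) < tol


def test_momentum_variance_matches_mass():
    m = one_mode_model()
    n = 400
    samples = run_ground_sampling(
        m, n_configs=n, equilibration=2.0, spacing=0.5, seed=43
    )
    p = np.array([s.P[0] for s in samples])
    target = m.masses()[0] * KB_EV_K * 300.0  # <p^2> = m kT
    assert abs(p.var() - target) < 3.0 * target * np.sqrt(2.0 / n)


def test_sampling_deterministic_under_seed(chla_model):
    a = run_ground_sampling(chla_model, n_configs=10, equilibration=0.5, spacing=0.1, seed=5)
    b = run_ground_sampling(chla_model, n_configs=10, equilibration=0.5, spacing=0.1, seed=5)
    for sa, sb in zip(a, b):
        np.testing.assert_array_equal(sa.R, sb.R)
        np.testing.assert_array_equal(sa.P, sb.P)


def test_harvest_schedule_and_count():
    m = one_mode_model()
    samples = run_ground_sampling(
        m, n_configs=12, equilibration=1.0, spacing=1.0, seed=0, n_runs=5
    )
    assert len(samples) == 12
    # round-robin across runs: harvest times 1, 1, 1, 1, 1, 2, 2, ... ps
    times = [s.harvest_time for s in samples]
    assert times == [1.0] * 5 + [2.0] * 5 + [3.0] * 2
    assert min(times) >= 1.0  # nothing harvested before equilibration
    runs = [s.run for s in samples]
    assert runs[:5] == [0, 1, 2, 3, 4]


def test_sampling_input_validation():
    m = one_mode_model()
    with pytest.raises(ValueError):
        run_ground_sampling(m, n_configs=0)
    with pytest.raises(ValueError):
        run_ground_sampling(m, dt=-1.0)
    with pytest.raises(ValueError):
        run_ground_sampling(m, temperature=0.0)
    with pytest.raises(ValueError, match="stiffest"):
        run_ground_sampling(m, dt=1e4)


# -- spectra --------------------------------------------------------------


def test_frozen_ensemble_peaks_at_reference_energies(chla_model):
    # zero-displacement geometry: every sample at q = 0 -> peaks at the
    # reference vertical energies (no broadening source beyond the kernel)
    pts = [adiabatic_solve(chla_model, np.zeros(chla_model.n_modes))] * 5
    spec = absorption_spectrum(pts, chla_model)
    e = pts[0].energies
    assert spec.band_peaks["Qy"] == pytest.approx(e[0], abs=2e-4)
    assert spec.band_peaks["Qx"] == pytest.approx(e[1], abs=2e-4)
    # Soret peak falls at the strongest B state (B1 here by construction)
    assert spec.band_peaks["B"] == pytest.approx(e[2], abs=2e-3)
    assert spec.peak_gap() == pytest.approx(e[2] - e[0], abs=2e-3)


def test_spectrum_integral_equals_mean_total_strength(chla_model):
    samples = run_ground_sampling(
        chla_model, n_configs=25, equilibration=0.5, spacing=0.1, seed=9
    )
    pts = [adiabatic_solve(chla_model, s.R) for s in samples]
    spec = absorption_spectrum(pts, chla_model)
    integral = np.trapezoid(spec.total_intensity, spec.energy_grid)
    mean_f = np.mean([pt.oscillator_strengths.sum() for pt in pts])
    assert integral == pytest.approx(mean_f, rel=1e-6)
    for trace in spec.band_intensity.values():
        assert np.all(trace >= 0)


def test_peak_gap_stable_under_reseeding(chla_model):
    gaps = []
    for seed in (0, 1):
        samples = run_ground_sampling(chla_model, n_configs=500, seed=seed)
        gaps.append(absorption_spectrum(samples, chla_model).peak_gap())
    assert abs(gaps[0] - gaps[1]) < 0.02  # less than the kernel bandwidth


def test_empty_ensemble_rejected(chla_model):
    with pytest.raises(ValueError, match="empty"):
        absorption_spectrum([], chla_model)


# -- Franck-Condon window -------------------------------------------------


def test_pulse_width_conversion():
    pulse = LaserPulse(e_laser=2.9, gamma=0.14)
    assert pulse.T == pytest.approx(2.0 * np.sqrt(np.log(2.0)) * HBAR_EV_FS / 0.14)
    with pytest.raises(ValueError):
        LaserPulse(e_laser=2.9, gamma=0.0)


def test_half_fwhm_detuning_halves_the_weight():
    pulse = LaserPulse(e_laser=2.0, gamma=0.2)
    pt = fake_point([2.0, 2.0 + pulse.gamma / 2.0], [1.0, 1.0])
    w = franck_condon_weights(pt, pulse)
    # g at detuning = half the spectral FWHM is exactly half the peak value
    assert w[1] / w[0] == pytest.approx(0.5, rel=1e-12)


def test_resonant_state_dominates():
    pulse = LaserPulse(e_laser=2.0, gamma=0.1)
    pt = fake_point([2.0, 3.0, 3.2], [1.0, 1.0, 1.0])
    w = franck_condon_weights(pt, pulse)
    assert w[0] > 0.999


def test_equal_states_split_evenly():
    pulse = LaserPulse(e_laser=2.0, gamma=0.1)
    pt = fake_point([2.0, 2.0], [0.7, 0.7])
    rng = np.random.default_rng(101)
    n = 10_000
    picks = np.array([franck_condon_select(pt, pulse, rng) for _ in range(n)])
    frac = (picks == 0).mean()
    sigma = 0.5 / np.sqrt(n)
    assert abs(frac - 0.5) < 3 * sigma


def test_selection_frequencies_match_weights_chisquare():
    pulse = LaserPulse(e_laser=2.0, gamma=0.3)
    pt = fake_point([1.9, 2.0, 2.1], [0.5, 1.0, 2.0])
    w = franck_condon_weights(pt, pulse)
    assert w.sum() == pytest.approx(1.0, rel=1e-12)
    rng = np.random.default_rng(202)
    n = 10_000
    picks = np.array([franck_condon_select(pt, pulse, rng) for _ in range(n)])
    counts = np.bincount(picks, minlength=3)
    stat, p = chisquare(counts, f_exp=n * w)
    assert p > 1e-3


def test_off_resonant_pulse_raises():
    pulse = LaserPulse(e_laser=2.0, gamma=0.01)
    pt = fake_point([5.0, 6.0], [1.0, 1.0])
    with pytest.raises(OffResonantError):
        franck_condon_weights(pt, pulse)


def test_two_state_weights_on_model_point():
    m = make_two_state_model()
    pt = adiabatic_solve(m, np.array([0.3]))
    pulse = LaserPulse(e_laser=float(pt.energies[0]), gamma=0.2)
    w = franck_condon_weights(pt, pulse)
    assert w.shape == (2,)
    assert w.sum() == pytest.approx(1.0)
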