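"""Ground-state sampling, ensemble absorption spectra, and pulse selection.

Ground-state Langevin dynamics on the surrogate ground surface harvests an
ensemble of phase-space points; vertical excitation energies and oscillator
strengths of the ensemble build the band-resolved absorption histogram; and
a Gaussian Franck-Condon window weighted by oscillator strength picks the
initially photoexcited state for each configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._constants import HBAR_EV_FS, KB_EV_K
from .vibronic import AdiabaticPoint, adiabatic_solve, band_of

__all__ = [
    "LaserPulse",
    "OffResonantError",
    "PhaseSpaceSample",
    "SpectrumHistogram",
    "absorption_spectrum",
    "franck_condon_select",
    "franck_condon_weights",
    "run_ground_sampling",
]


@dataclass
class PhaseSpaceSample:
    """One harvested ground-state configuration (coordinates + momenta)."""

    R: np.ndarray
    P: np.ndarray
    harvest_time: float  # ps, within its run
    run: int = 0


@dataclass
class LaserPulse:
    """Gaussian pump pulse described by its spectral centre and width.

    ``gamma`` is the spectral FWHM of the Franck-Condon window
    ``g(E) = exp[-(T * (E_laser - E) / hbar)**2]``; the time-domain width
    ``T = 2 sqrt(ln 2) hbar / gamma`` follows from that reading.
    """

    e_laser: float  # eV
    gamma: float  # eV, spectral FWHM

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("pulse width must be positive")

    @property
    def T(self) -> float:
        """Gaussian time-domain width parameter, fs."""
        return 2.0 * math.sqrt(math.log(2.0)) * HBAR_EV_FS / self.gamma


class OffResonantError(ValueError):
    """The pulse window gives zero weight to every state."""


def run_ground_sampling(
    model,
    temperature: float = 300.0,
    dt: float = 0.5,
    equilibration: float = 10.0,
    spacing: float = 1.0,
    n_configs: int = 500,
    friction: float = 2.0,
    seed=None,
    n_runs: int = 5,
) -> list[PhaseSpaceSample]:
    """Harvest phase-space points from ground-surface Langevin dynamics.

    ``n_runs`` independent trajectories are propagated in parallel (BAOAB
    splitting with the exact Ornstein-Uhlenbeck friction/noise step) and
    harvested round-robin: after ``equilibration`` ps, one configuration per
    run every ``spacing`` ps until ``n_configs`` samples are collected.

    Parameters use the package's working units: ``dt`` in fs,
    ``equilibration``/``spacing`` in ps, ``friction`` in ps^-1.
    """
    if n_configs < 1:
        raise ValueError("n_configs must be >= 1")
    if dt <= 0 or temperature <= 0:
        raise ValueError("dt and temperature must be positive")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)

    omega = model.mode_freqs
    m = model.masses()
    nm = len(omega)
    kT = KB_EV_K * temperature

    # dt stability on the stiffest mode (angular frequency omega/hbar rad/fs)
    if np.max(omega) / HBAR_EV_FS * dt > 1.0:
        raise ValueError("dt too large for the stiffest mode")

    gamma_fs = friction * 1e-3
    c1 = math.exp(-gamma_fs * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * m * kT)

    # thermal start, then equilibrate
    q = rng.normal(0.0, np.sqrt(kT / omega), size=(n_runs, nm))
    p = rng.normal(0.0, np.sqrt(m * kT), size=(n_runs, nm))

    per_run = math.ceil(n_configs / n_runs)
    n_eq = round(equilibration * 1e3 / dt)
    n_sp = round(spacing * 1e3 / dt)

    samples: list[PhaseSpaceSample] = []
    half = 0.5 * dt

    def steps(n):
        nonlocal q, p
        for _ in range(n):
            p = p - half * (omega * q)  # B: force -dV0/dq = -omega q
            q = q + half * (p / m)  # A
            p = c1 * p + c2 * rng.standard_normal((n_runs, nm))  # O
            q = q + half * (p / m)  # A
            p = p - half * (omega * q)  # B

    steps(n_eq)
    t_ps = equilibration
    for k in range(per_run):
        if k > 0:
            steps(n_sp)
            t_ps += spacing
        for r in range(n_runs):
            if len(samples) < n_configs:
                samples.append(
                    PhaseSpaceSample(R=q[r].copy(), P=p[r].copy(), harvest_time=t_ps, run=r)
                )
    return samples


@dataclass
class SpectrumHistogram:
    """Band-resolved oscillator-strength-weighted energy density."""

    energy_grid: np.ndarray  # eV
    band_intensity: dict[str, np.ndarray]
    total_intensity: np.ndarray
    band_peaks: dict[str, float] = field(default_factory=dict)

    def peak_gap(self, band_hi: str = "B", band_lo: str = "Qy") -> float:
        return self.band_peaks[band_hi] - self.band_peaks[band_lo]


def _refined_peak(grid: np.ndarray, y: np.ndarray) -> float:
    """Sub-bin peak location via quadratic interpolation around the argmax."""
    i = int(np.argmax(y))
    if 0 < i < len(y) - 1:
        denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
        if denom < 0:
            return float(grid[i] + 0.5 * (y[i - 1] - y[i + 1]) / denom * (grid[1] - grid[0]))
    return float(grid[i])


def absorption_spectrum(
    samples: list[PhaseSpaceSample] | list[AdiabaticPoint],
    model,
    broadening: float = 0.02,
    grid_step: float = 0.005,
) -> SpectrumHistogram:
    """Ensemble absorption histogram from vertical energies and strengths.

    Each (state, sample) pair contributes a Gaussian of area ``f / n_samples``
    centred at its vertical energy, accumulated per band; the integral of the
    total trace therefore equals the ensemble-mean total oscillator strength.
    """
    if len(samples) == 0:
        raise ValueError("empty ensemble")
    points = [
        s if isinstance(s, AdiabaticPoint) else adiabatic_solve(model, s.R)
        for s in samples
    ]
    energies = np.array([pt.energies for pt in points])  # (n, ne)
    strengths = np.array([pt.oscillator_strengths for pt in points])

    lo = energies.min() - 5 * broadening
    hi = energies.max() + 5 * broadening
    grid = np.arange(lo, hi + grid_step, grid_step)

    ne = energies.shape[1]
    bands = {"Qy": np.zeros_like(grid), "Qx": np.zeros_like(grid), "B": np.zeros_like(grid)}
    norm = 1.0 / (len(points) * broadening * math.sqrt(2.0 * math.pi))
    for a in range(ne):
        b = band_of(a, model.band_map)
        z = (grid[None, :] - energies[:, a, None]) / broadening
        bands[b] += norm * (strengths[:, a, None] * np.exp(-0.5 * z * z)).sum(axis=0)
    total = bands["Qy"] + bands["Qx"] + bands["B"]
    peaks = {b: _refined_peak(grid, y) for b, y in bands.items() if y.max() > 0}
    return SpectrumHistogram(
        energy_grid=grid, band_intensity=bands, total_intensity=total, band_peaks=peaks
    )


def franck_condon_weights(point: AdiabaticPoint, pulse: LaserPulse) -> np.ndarray:
    """Normalised selection probabilities g_a * f_a / sum(g * f)."""
    arg = pulse.T * (pulse.e_laser - point.energies) / HBAR_EV_FS
    w = np.exp(-arg * arg) * point.oscillator_strengths
    tot = w.sum()
    if tot <= 0 or not np.isfinite(tot):
        raise OffResonantError("pulse off-resonant: all Franck-Condon weights zero")
    return w / tot


def franck_condon_select(point: AdiabaticPoint, pulse: LaserPulse, rng) -> int:
    """Draw the initial excited state (0-based index) for one configuration."""
    w = franck_condon_weights(point, pulse)
    return int(rng.choice(len(w), p=w))
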