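"""Transient-absorption simulation and global lifetime/SADS analysis.

A two-compartment sequential kinetic scheme (a free-lifetime initially
excited compartment feeding a quasi-stationary one, fixed 5 ns lifetime)
convolved with a Gaussian instrument response function generates synthetic
pump-probe surfaces; the same model is fitted back by variable projection:
for trial lifetimes the species-associated difference spectra (SADS) follow
from per-wavelength linear least squares, and the nonlinear search runs only
over the free lifetimes (optionally the time origin, IRF width and chirp).

The concentration of a compartment decaying at rate ``k`` under a Gaussian
IRF of width sigma is the exponentially modified Gaussian

    c(t) = 1/2 exp(k (sigma^2 k / 2 - (t - t0))) erfc((sigma k - (t-t0)/sigma)/sqrt(2))

and a sequential chain is the standard linear combination of these terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import erfc

from ._constants import FWHM_PER_SIGMA

__all__ = [
    "GlobalFitResult",
    "RankDeficientError",
    "TASurface",
    "concentration_profiles",
    "global_fit",
    "sads_templates",
    "simulate_ta",
]

#: Quasi-stationary emitting-state lifetime held fixed in the fits, fs (5 ns).
FIXED_S1_LIFETIME_FS = 5e6

#: Instrument-response FWHM of the study conditions, fs.
DEFAULT_IRF_FWHM_FS = 55.0


class RankDeficientError(RuntimeError):
    """The linear SADS step is not identifiable for the requested model."""


@dataclass
class TASurface:
    """A synthetic differential-absorption surface dA(wavelength, delay)."""

    wavelengths: np.ndarray  # nm
    delays: np.ndarray  # fs
    delta_a: np.ndarray  # mOD, shape (n_wavelengths, n_delays)
    irf_fwhm: float = DEFAULT_IRF_FWHM_FS
    t0: float = 0.0
    chirp: np.ndarray = field(default_factory=lambda: np.zeros(1))  # fs/nm^k coeffs
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.delta_a.shape != (len(self.wavelengths), len(self.delays)):
            raise ValueError("surface shape must match the axis grids")
        if self.irf_fwhm <= 0:
            raise ValueError("IRF FWHM must be positive")

    def t0_at(self, wavelength: float) -> float:
        """Per-wavelength time origin including the chirp polynomial."""
        dl = wavelength - self.wavelengths.mean()
        return self.t0 + float(np.polyval(self.chirp[::-1], dl)) - float(self.chirp[0])


def _emg(t: np.ndarray, k: float, t0: float, sigma: float) -> np.ndarray:
    x = t - t0
    if sigma == 0.0:
        return np.where(x >= 0, np.exp(-k * x), 0.0)
    arg = k * (0.5 * sigma * sigma * k - x)
    # guard the pre-pulse tail where exp overflows but the product vanishes
    arg = np.minimum(arg, 700.0)
    return 0.5 * np.exp(arg) * erfc((sigma * k - x / sigma) / np.sqrt(2.0))


def concentration_profiles(
    lifetimes, irf_fwhm: float, t0: float, delays
) -> np.ndarray:
    """Sequential-chain compartment concentrations under a Gaussian IRF.

    ``lifetimes`` orders the chain from the initially populated compartment
    onward.  Returns an array of shape (n_delays, n_compartments).
    """
    taus = np.asarray(lifetimes, dtype=float)
    if np.any(taus <= 0):
        raise ValueError("lifetimes must be positive")
    if irf_fwhm <= 0:
        raise ValueError("IRF FWHM must be positive")
    t = np.asarray(delays, dtype=float)
    sigma = irf_fwhm / FWHM_PER_SIGMA
    ks = 1.0 / taus
    n = len(ks)
    out = np.empty((len(t), n))
    for j in range(n):
        kj = ks[: j + 1]
        prefac = np.prod(kj[:-1]) if j > 0 else 1.0
        cj = np.zeros(len(t))
        for i in range(j + 1):
            denom = np.prod(np.delete(kj, i) - kj[i]) if j > 0 else 1.0
            cj += _emg(t, kj[i], t0, sigma) / denom
        out[:, j] = prefac * cj
    return out


def sads_templates(species: str, wavelengths) -> np.ndarray:
    """Chlorophyll-like SADS pair on a wavelength grid, mOD.

    The initial (higher-excited-state) spectrum is a weaker, blue-shifted
    bleach; the emitting-state spectrum is a deeper, red-shifted bleach with
    an excited-state absorption shoulder to the blue.
    """
    wl = np.asarray(wavelengths, dtype=float)
    centers = {"chla": (664.0, 670.0), "chlb": (647.0, 650.0)}
    try:
        c1, c2 = centers[species]
    except KeyError as err:
        raise ValueError(f"unknown species {species!r}") from err

    def g(c, w):
        return np.exp(-0.5 * ((wl - c) / w) ** 2)

    sads1 = -6.0 * g(c1, 9.0)
    sads2 = -10.0 * g(c2, 8.0) + 2.5 * g(c2 - 45.0, 12.0)
    return np.column_stack([sads1, sads2])


def simulate_ta(
    lifetimes,
    sads: np.ndarray,
    wavelengths,
    delays,
    irf_fwhm: float = DEFAULT_IRF_FWHM_FS,
    t0: float = 0.0,
    chirp=None,
    noise_sd: float = 0.0,
    seed=None,
) -> TASurface:
    """Build dA(wavelength, delay) = sum_i c_i(t) SADS_i(wavelength) + noise.

    ``chirp`` gives polynomial coefficients (fs per nm^k, ascending, constant
    term ignored) shifting the per-wavelength time origin.
    """
    wl = np.asarray(wavelengths, dtype=float)
    t = np.asarray(delays, dtype=float)
    sads = np.asarray(sads, dtype=float)
    if sads.shape[0] != len(wl):
        raise ValueError("SADS templates must live on the wavelength grid")
    if sads.shape[1] != len(np.atleast_1d(lifetimes)):
        raise ValueError("one SADS per compartment required")
    chirp_arr = np.zeros(1) if chirp is None else np.asarray(chirp, dtype=float)

    rng = np.random.default_rng(seed)
    dA = np.empty((len(wl), len(t)))
    if len(chirp_arr) > 1 and np.any(chirp_arr[1:] != 0):
        dl = wl - wl.mean()
        for i in range(len(wl)):
            shift = float(np.polyval(chirp_arr[::-1], dl[i])) - float(chirp_arr[0])
            C = concentration_profiles(lifetimes, irf_fwhm, t0 + shift, t)
            dA[i] = C @ sads[i]
    else:
        C = concentration_profiles(lifetimes, irf_fwhm, t0, t)
        dA = sads @ C.T
    if noise_sd > 0:
        dA = dA + rng.normal(0.0, noise_sd, size=dA.shape)
    return TASurface(
        wavelengths=wl,
        delays=t,
        delta_a=dA,
        irf_fwhm=irf_fwhm,
        t0=t0,
        chirp=chirp_arr,
        noise_sd=noise_sd,
    )


@dataclass
class GlobalFitResult:
    """Variable-projection global-analysis result."""

    lifetimes: np.ndarray  # fs, free then fixed
    n_free: int
    sads: np.ndarray  # (n_wavelengths, n_compartments), mOD
    residual: np.ndarray
    standard_errors: np.ndarray  # per free lifetime, fs
    t0: float
    irf_fwhm: float

    @property
    def free_lifetimes(self) -> np.ndarray:
        return self.lifetimes[: self.n_free]


def _solve_sads(surface: TASurface, lifetimes, t0: float) -> tuple[np.ndarray, np.ndarray]:
    """Linear SADS solve for given lifetimes; returns (sads, residual)."""
    wl = surface.wavelengths
    chirped = len(surface.chirp) > 1 and np.any(surface.chirp[1:] != 0)
    if not chirped:
        C = concentration_profiles(lifetimes, surface.irf_fwhm, t0, surface.delays)
        cond = np.linalg.cond(C.T @ C)
        if not np.isfinite(cond) or cond > 1e12:
            raise RankDeficientError(
                "concentration profiles are collinear; free lifetime unidentifiable"
            )
        sads, *_ = np.linalg.lstsq(C, surface.delta_a.T, rcond=None)
        resid = surface.delta_a.T - C @ sads
        return sads.T, resid.T
    dl = wl - wl.mean()
    sads = np.empty((len(wl), len(np.atleast_1d(lifetimes))))
    resid = np.empty_like(surface.delta_a)
    for i in range(len(wl)):
        shift = float(np.polyval(surface.chirp[::-1], dl[i])) - float(surface.chirp[0])
        C = concentration_profiles(lifetimes, surface.irf_fwhm, t0 + shift, surface.delays)
        cond = np.linalg.cond(C.T @ C)
        if not np.isfinite(cond) or cond > 1e12:
            raise RankDeficientError("rank-deficient linear step at one wavelength")
        s, *_ = np.linalg.lstsq(C, surface.delta_a[i], rcond=None)
        sads[i] = s
        resid[i] = surface.delta_a[i] - C @ s
    return sads, resid


def global_fit(
    surface: TASurface,
    n_free_lifetimes: int = 1,
    fixed_lifetimes=(FIXED_S1_LIFETIME_FS,),
    initial_free_lifetimes=None,
    fit_t0: bool = False,
) -> GlobalFitResult:
    """Variable-projection global fit of lifetimes and SADS.

    Free lifetimes are searched in log space; at every trial the SADS are
    the exact per-wavelength linear least-squares solution.  Standard errors
    of the free lifetimes come from the Jacobian of the reduced problem.
    """
    fixed = np.atleast_1d(np.asarray(fixed_lifetimes, dtype=float))
    if initial_free_lifetimes is None:
        span = surface.delays[-1] - surface.delays[0]
        initial_free_lifetimes = np.full(n_free_lifetimes, 0.05 * span)
    x0 = np.log(np.atleast_1d(np.asarray(initial_free_lifetimes, dtype=float)))
    if fit_t0:
        x0 = np.append(x0, surface.t0)

    def unpack(x):
        taus = np.concatenate([np.exp(x[:n_free_lifetimes]), fixed])
        t0 = x[n_free_lifetimes] if fit_t0 else surface.t0
        return taus, t0

    def residuals(x):
        taus, t0 = unpack(x)
        _, resid = _solve_sads(surface, taus, t0)
        return resid.ravel()

    sol = least_squares(residuals, x0=x0, method="lm" if len(x0) <= 2 else "trf")
    if not sol.success:
        raise RuntimeError("global fit did not converge")
    taus, t0 = unpack(sol.x)
    sads, resid = _solve_sads(surface, taus, t0)

    scale = np.linalg.norm(surface.delta_a) / np.sqrt(surface.delta_a.size)
    free_amp = np.abs(sads[:, :n_free_lifetimes]).max() if scale > 0 else 0.0
    if scale > 0 and free_amp < 1e-6 * np.abs(sads).max():
        raise RankDeficientError(
            "free compartment carries no amplitude; its lifetime is unidentifiable"
        )

    # a population-conserving chain can reproduce a quasi-stationary surface
    # exactly for any free lifetime (equal SADS amplitudes); the residual is
    # then insensitive to the lifetime and the fit must be rejected
    jac_norms = np.linalg.norm(sol.jac[:, :n_free_lifetimes], axis=0)
    if scale > 0 and np.any(jac_norms < 1e-8 * np.linalg.norm(surface.delta_a)):
        raise RankDeficientError(
            "residual is insensitive to a free lifetime; it is unidentifiable"
        )

    dof = max(resid.size - len(sol.x) - sads.size, 1)
    s2 = 2.0 * sol.cost / dof
    JTJ = sol.jac.T @ sol.jac
    try:
        cov_log = s2 * np.linalg.inv(JTJ)
        se = np.sqrt(np.diag(cov_log))[:n_free_lifetimes] * taus[:n_free_lifetimes]
    except np.linalg.LinAlgError:
        se = np.full(n_free_lifetimes, np.nan)

    return GlobalFitResult(
        lifetimes=taus,
        n_free=n_free_lifetimes,
        sads=sads,
        residual=resid,
        standard_errors=se,
        t0=float(t0),
        irf_fwhm=surface.irf_fwhm,
    )
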