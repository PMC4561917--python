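"""Fewest-switches surface hopping with a Langevin thermostat.

Classical nuclei move on one adiabatic surface of the surrogate vibronic
model (velocity-Verlet/BAOAB with an exact Ornstein-Uhlenbeck friction and
noise step); the electronic amplitudes are propagated in the adiabatic basis
on a sub-stepped grid with an adaptive embedded Runge-Kutta integrator; hops
are attempted at every quantum substep from the fewest-switches probability,
with momentum rescaling along the nonadiabatic coupling vector at allowed
hops.  State identities are tracked through trivial (unavoided) crossings by
maximum-overlap assignment of consecutive eigenvector sets.

Energies follow the convention of :mod:`photorelax.vibronic`: adiabatic
``energies`` are vertical excitation energies, gradients are of the total
surface, so the conserved quantity (thermostat off) is
``kinetic + ground_energy(q) + energies[active]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from ._constants import HBAR_EV_FS, KB_EV_K
from .sampling import PhaseSpaceSample
from .vibronic import adiabatic_solve, band_of

__all__ = [
    "CoefficientCollapseError",
    "HopEvent",
    "QuantumNormError",
    "SimParams",
    "Trajectory",
    "apply_hop",
    "hop_probability",
    "landau_zener_probability",
    "propagate_trajectory",
    "track_state_identity",
]


class QuantumNormError(RuntimeError):
    """Electronic-amplitude norm drifted beyond tolerance."""


class CoefficientCollapseError(RuntimeError):
    """Active-state amplitude fell below the numerical floor."""


@dataclass
class SimParams:
    """Surface-hopping run parameters (defaults match the study conditions)."""

    dt_classical: float = 0.1  # fs
    n_quantum_substeps: int = 4
    n_states_propagated: int = 10
    total_time: float = 1.0  # ps
    temperature: float = 300.0  # K
    friction: float = 2.0  # ps^-1
    seed: int | None = None
    decoherence: str = "none"  # or "instantaneous"
    frustrated_hop_policy: str = "keep"  # or "reverse"
    store_stride: int = 1
    rk_atol: float = 1e-8

    def __post_init__(self) -> None:
        if min(self.dt_classical, self.total_time, self.temperature) <= 0:
            raise ValueError("time step, total time and temperature must be positive")
        if self.n_quantum_substeps < 1:
            raise ValueError("need at least one quantum substep")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")
        if self.decoherence not in ("none", "instantaneous"):
            raise ValueError("decoherence must be 'none' or 'instantaneous'")
        if self.frustrated_hop_policy not in ("keep", "reverse"):
            raise ValueError("frustrated_hop_policy must be 'keep' or 'reverse'")


@dataclass
class HopEvent:
    """One attempted surface hop (allowed or frustrated)."""

    time: float  # fs
    from_state: int  # adiabatic rank (0-based, 0 = S1)
    to_state: int
    from_band: str
    to_band: str
    delta_e: float  # eV, donor minus acceptor at the hop geometry
    nac_magnitude: float
    allowed: bool
    effective: bool = False


@dataclass
class Trajectory:
    """One surface-hopping run."""

    times: np.ndarray  # fs, per classical step
    active_state: np.ndarray  # adiabatic rank per step
    quantum_coeffs: np.ndarray  # (n_stored, n_states) complex, strided
    R: np.ndarray  # (n_stored, n_modes)
    P: np.ndarray
    store_stride: int
    hops: list[HopEvent]
    band_entry_times: dict[str, float]
    params: SimParams
    initial_state: int
    band_map: dict[int, str] = field(default_factory=dict)

    def band_series(self) -> np.ndarray:
        """Active band label at every classical step."""
        lut = np.array(
            [band_of(i, self.band_map or None) for i in range(int(self.active_state.max()) + 1)]
        )
        return lut[self.active_state]


def hop_probability(coeffs: np.ndarray, nac_flux: np.ndarray, dt_q: float, active: int) -> np.ndarray:
    """Fewest-switches hopping probabilities out of the active state.

    ``g_b = max(0, 2 dt_q Re(c_a^* c_b) sigma_ab / |c_a|^2)`` with
    ``sigma_ab = Rdot . d_ab`` (the ``nac_flux`` row for the active state),
    clamped to [0, 1].
    """
    pa = abs(coeffs[active]) ** 2
    if pa < 1e-12:
        raise CoefficientCollapseError("active-state population below 1e-12")
    g = 2.0 * dt_q * np.real(np.conj(coeffs[active]) * coeffs) * nac_flux / pa
    g[active] = 0.0
    return np.clip(g, 0.0, 1.0)


def apply_hop(
    energies: np.ndarray,
    nac_vector: np.ndarray,
    P: np.ndarray,
    masses: np.ndarray,
    from_state: int,
    to_state: int,
    policy: str = "keep",
) -> tuple[np.ndarray, bool]:
    """Rescale momentum along the coupling vector to conserve total energy.

    Solves ``P' = P + gamma * d`` such that the kinetic-energy change equals
    ``E_from - E_to`` (root of smaller magnitude).  If no real root exists the
    hop is frustrated: momentum is kept, or its component along ``d``
    reversed under the ``reverse`` policy.  A zero coupling vector falls back
    to rescaling along the momentum direction.
    """
    if from_state == to_state:
        raise ValueError("hop requires distinct states")
    gain = float(energies[from_state] - energies[to_state])
    u = np.asarray(nac_vector, dtype=float)
    unorm = np.linalg.norm(u)
    if unorm < 1e-12:
        # degenerate coupling direction: isotropic rescale along momentum
        ke = float(np.sum(P * P / (2.0 * masses)))
        if ke + gain < 0:
            return P.copy(), False
        if ke == 0.0:
            return P.copy(), gain >= 0
        return P * math.sqrt((ke + gain) / ke), True

    a = float(np.sum(u * u / (2.0 * masses)))
    b = float(np.sum(P * u / masses))
    disc = b * b + 4.0 * a * gain
    if disc < 0:
        if policy == "reverse":
            uhat = u / unorm
            P = P - 2.0 * np.dot(P, uhat) * uhat
        return P.copy(), False
    s = math.sqrt(disc)
    g1 = (-b + s) / (2.0 * a)
    g2 = (-b - s) / (2.0 * a)
    gamma = g1 if abs(g1) <= abs(g2) else g2
    return P + gamma * u, True


def track_state_identity(prev_eigvecs: np.ndarray, new_eigvecs: np.ndarray) -> np.ndarray:
    """Match new eigenvectors to previous ones by maximum total |overlap|.

    Returns ``perm`` with ``perm[l]`` the new-basis column assigned to
    previous column ``l`` (always a bijection).
    """
    if prev_eigvecs.shape != new_eigvecs.shape:
        raise ValueError("eigenvector matrices must share a shape")
    overlap = np.abs(prev_eigvecs.T @ new_eigvecs)
    rows, cols = linear_sum_assignment(-overlap)
    perm = np.empty(len(rows), dtype=int)
    perm[rows] = cols
    return perm


def landau_zener_probability(coupling: float, slope_diff: float, velocity: float) -> float:
    """Closed-form diabatic-passage probability for a linear crossing,
    ``exp(-2 pi lambda^2 / (hbar v |dF|))``."""
    return math.exp(
        -2.0 * math.pi * coupling**2 / (HBAR_EV_FS * abs(velocity) * abs(slope_diff))
    )


# Dormand-Prince RK5(4) tableau
_DP_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_DP_A = [
    [],
    [1 / 5],
    [3 / 40, 9 / 40],
    [44 / 45, -56 / 15, 32 / 9],
    [19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729],
    [9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656],
    [35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84],
]
_DP_B5 = np.array([35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84, 0.0])
_DP_B4 = np.array(
    [5179 / 57600, 0.0, 7571 / 16695, 393 / 640, -92097 / 339200, 187 / 2100, 1 / 40]
)
_DP_A_ROWS = [np.array(row) for row in _DP_A]
_DP_ERR = _DP_B5 - _DP_B4
# Shampine's 4th-order continuous extension of the 5(4) pair:
# y(t + theta h) = y + h * (P @ [theta, theta^2, theta^3, theta^4]) . k
_DP_P = np.array(
    [
        [1.0, -8048581381 / 2820520608, 8663915743 / 2820520608, -12715105075 / 11282082432],
        [0.0, 0.0, 0.0, 0.0],
        [0.0, 131558114200 / 32700410799, -68118460800 / 10900136933, 87487479700 / 32700410799],
        [0.0, -1754552775 / 470086768, 14199869525 / 1410260304, -10690763975 / 1880347072],
        [0.0, 127303824393 / 49829197408, -318862633887 / 49829197408, 701980252875 / 199316789632],
        [0.0, -282668133 / 205662961, 2019193451 / 616988883, -1453857185 / 822651844],
        [0.0, 40617522 / 29380423, -110615467 / 29380423, 69997945 / 29380423],
    ]
)


def _integrate_coeffs(c, t0, t1, rhs, atol):
    """Adaptive Dormand-Prince 5(4) integration of the amplitude ODE."""
    t = t0
    h = t1 - t0
    k = np.empty((7, len(c)), dtype=complex)
    for _ in range(10000):
        if t >= t1 - 1e-14:
            return c
        h = min(h, t1 - t)
        k[0] = rhs(t, c)
        for i in range(1, 7):
            ci = c + h * (_DP_A_ROWS[i] @ k[:i])
            k[i] = rhs(t + _DP_C[i] * h, ci)
        y5 = c + h * (_DP_B5 @ k)
        err = float(np.max(np.abs(h * (_DP_ERR @ k))))
        if err <= atol:
            t += h
            c = y5
            h *= min(2.0, max(0.2, 0.9 * (atol / max(err, 1e-300)) ** 0.2))
        else:
            h *= max(0.1, 0.9 * (atol / err) ** 0.2)
    raise RuntimeError("quantum integrator failed to reach the substep end")


def _integrate_substep_values(c, t0, t_end, boundaries, rhs, atol):
    """Adaptive 5(4) integration of ``[t0, t_end]`` returning the solution at
    each boundary time via the 4th-order continuous extension (one adaptive
    pass per classical step instead of one per quantum substep)."""
    t = t0
    h = t_end - t0
    n = len(c)
    k = np.empty((7, n), dtype=complex)
    out = np.empty((len(boundaries), n), dtype=complex)
    nb = 0
    for _ in range(10000):
        if nb >= len(boundaries):
            return out
        h = min(h, t_end - t)
        k[0] = rhs(t, c)
        for i in range(1, 7):
            ci = c + h * (_DP_A_ROWS[i] @ k[:i])
            k[i] = rhs(t + _DP_C[i] * h, ci)
        y5 = c + h * (_DP_B5 @ k)
        err = float(np.max(np.abs(h * (_DP_ERR @ k))))
        if err <= atol:
            t_new = t + h
            while nb < len(boundaries) and boundaries[nb] <= t_new + 1e-12:
                theta = (boundaries[nb] - t) / h
                w = _DP_P @ np.array([theta, theta**2, theta**3, theta**4])
                out[nb] = c + h * (w @ k)
                nb += 1
            t = t_new
            c = y5
            h *= min(2.0, max(0.2, 0.9 * (atol / max(err, 1e-300)) ** 0.2))
        else:
            h *= max(0.1, 0.9 * (atol / err) ** 0.2)
    raise RuntimeError("quantum integrator failed to reach the step end")


def propagate_trajectory(
    model,
    sample: PhaseSpaceSample,
    initial_state: int,
    params: SimParams,
    rng=None,
) -> Trajectory:
    """Run one FSSH trajectory from a harvested ground-state configuration.

    ``initial_state`` is a 0-based adiabatic index (0 = S1).  Between
    classical steps the label-basis energies and coupling scalars are
    linearly interpolated over the quantum substeps.
    """
    ne = min(model.n_excited, params.n_states_propagated)
    if not 0 <= initial_state < ne:
        raise ValueError("initial state outside the propagated set")
    if rng is None:
        rng = np.random.default_rng(params.seed)

    m = model.masses()
    nm = model.n_modes
    dt = params.dt_classical
    n_steps = round(params.total_time * 1e3 / dt)
    nq = params.n_quantum_substeps
    dt_q = dt / nq
    kT = KB_EV_K * params.temperature
    gamma_fs = params.friction * 1e-3
    c1 = math.exp(-gamma_fs * dt) if gamma_fs > 0 else 1.0
    c2 = np.sqrt((1.0 - c1 * c1) * m * kT)
    thermostat = gamma_fs > 0

    q = np.asarray(sample.R, dtype=float).copy()
    p = np.asarray(sample.P, dtype=float).copy()

    pt = adiabatic_solve(model, q)
    V_lab = pt.eigenvectors[:, :ne].copy()
    E_lab = pt.energies[:ne].copy()
    nac_lab = pt.nac[:ne, :ne, :].copy()
    grad_lab = pt.gradients[:ne].copy()
    rank_of_label = np.arange(ne)

    active = int(initial_state)  # label index; equals rank at t=0
    coeffs = np.zeros(ne, dtype=complex)
    coeffs[active] = 1.0

    stride = max(1, params.store_stride)
    n_stored = n_steps // stride + 1
    times = np.arange(n_steps + 1) * dt
    active_hist = np.empty(n_steps + 1, dtype=np.int16)
    coeff_hist = np.empty((n_stored, ne), dtype=complex)
    R_hist = np.empty((n_stored, nm))
    P_hist = np.empty((n_stored, nm))
    active_hist[0] = rank_of_label[active]
    coeff_hist[0] = coeffs
    R_hist[0] = q
    P_hist[0] = p

    hops: list[HopEvent] = []
    band_entry: dict[str, float] = {band_of(rank_of_label[active], model.band_map): 0.0}

    v0 = p / m
    sigma0 = np.einsum("abm,m->ab", nac_lab, v0)
    half = 0.5 * dt

    for step in range(1, n_steps + 1):
        force = -grad_lab[active]
        p = p + half * force  # B
        q = q + half * (p / m)  # A
        if thermostat:
            p = c1 * p + c2 * rng.standard_normal(nm)  # O
        q = q + half * (p / m)  # A

        pt = adiabatic_solve(model, q)
        Vn = pt.eigenvectors[:, :ne]
        perm = track_state_identity(V_lab, Vn)
        V_new = Vn[:, perm].copy()
        signs = np.ones(ne)
        for l in range(ne):
            if np.dot(V_lab[:, l], V_new[:, l]) < 0:
                V_new[:, l] = -V_new[:, l]
                signs[l] = -1.0
        E_new = pt.energies[perm].copy()
        nac_new = pt.nac[np.ix_(perm, perm)] * (signs[:, None, None] * signs[None, :, None])
        grad_new = pt.gradients[perm].copy()
        rank_of_label = perm.copy()

        p = p + half * (-grad_new[active])  # B with the new force

        v1 = p / m
        sigma1 = np.einsum("abm,m->ab", nac_new, v1)

        t_prev = times[step - 1]
        E0, dE = E_lab, E_new - E_lab
        S0, dS = sigma0, sigma1 - sigma0

        # Interaction picture: the diagonal phase of the linearly interpolated
        # energies is integrated analytically, so the adaptive RK only has to
        # follow the slow NAC-driven mixing (norm drift stays far below the
        # 1e-6 budget at the default tolerance).
        def phase(tau, _E0=E0, _dE=dE, _dt=dt):
            return (_E0 * tau + 0.5 * _dE * tau * tau / _dt) / HBAR_EV_FS

        def rhs(t, a, _t0=t_prev, _dt=dt, _S0=S0, _dS=dS):
            tau = t - _t0
            S = _S0 + _dS * (tau / _dt)
            e = np.exp(1j * phase(tau))
            return -((S * (e[:, None] * np.conj(e)[None, :])) @ a)

        amps = coeffs  # a(tau=0) = c (zero phase at the step start)
        sub = 0
        while sub < nq:
            bounds = t_prev + dt_q * np.arange(sub + 1, nq + 1)
            vals = _integrate_substep_values(
                amps, t_prev + sub * dt_q, t_prev + dt, bounds, rhs, params.rk_atol
            )
            collapsed = False
            for j, tb in enumerate(bounds):
                wb = (sub + j + 1) / nq
                coeffs = vals[j] * np.exp(-1j * phase(wb * dt))
                sigma_b = S0 + dS * wb
                g = hop_probability(coeffs, sigma_b[active], dt_q, active)
                u = rng.random()
                cum = np.cumsum(g)
                if cum[-1] > 0 and u < cum[-1]:
                    target = int(np.searchsorted(cum, u, side="right"))
                    p_new, allowed = apply_hop(
                        E_new,
                        nac_new[active, target],
                        p,
                        m,
                        active,
                        target,
                        params.frustrated_hop_policy,
                    )
                    ev = HopEvent(
                        time=float(tb),
                        from_state=int(rank_of_label[active]),
                        to_state=int(rank_of_label[target]),
                        from_band=band_of(rank_of_label[active], model.band_map),
                        to_band=band_of(rank_of_label[target], model.band_map),
                        delta_e=float(E_new[active] - E_new[target]),
                        nac_magnitude=float(np.linalg.norm(nac_new[active, target])),
                        allowed=allowed,
                    )
                    hops.append(ev)
                    p = p_new
                    if allowed:
                        active = target
                        band = ev.to_band
                        if band not in band_entry:
                            band_entry[band] = float(tb)
                        if params.decoherence == "instantaneous":
                            coeffs = np.zeros(ne, dtype=complex)
                            coeffs[active] = 1.0
                            amps = coeffs * np.exp(1j * phase(wb * dt))
                            sub = sub + j + 1
                            collapsed = True
                            break
            if not collapsed:
                amps = vals[-1]
                sub = nq

        norm = float(np.sum(np.abs(coeffs) ** 2))
        if abs(norm - 1.0) > 1e-6:
            raise QuantumNormError(
                f"norm drifted to {norm:.8f} at t = {times[step]:.2f} fs"
            )

        V_lab, E_lab, nac_lab, grad_lab = V_new, E_new, nac_new, grad_new
        sigma0 = sigma1
        active_hist[step] = rank_of_label[active]
        if step % stride == 0:
            k = step // stride
            coeff_hist[k] = coeffs
            R_hist[k] = q
            P_hist[k] = p

    return Trajectory(
        times=times,
        active_state=active_hist,
        quantum_coeffs=coeff_hist,
        R=R_hist,
        P=P_hist,
        store_stride=stride,
        hops=hops,
        band_entry_times=band_entry,
        params=params,
        initial_state=initial_state,
        band_map=dict(model.band_map),
    )
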