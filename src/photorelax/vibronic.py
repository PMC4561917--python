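"""Surrogate electronic structure: a diabatic multi-state vibronic Hamiltonian.

The model is a set of shifted harmonic diabatic surfaces over a handful of
dimensionless normal-mode coordinates, coupled by constant (and optionally
linear) diabatic couplings.  Diagonalising the diabatic potential matrix on
the fly yields adiabatic energies, Hellmann-Feynman gradients, nonadiabatic
coupling vectors and oscillator strengths -- everything the surface-hopping
engine and the spectral analyses need, without any quantum chemistry.

Working units: energies in eV, time in fs, coordinates dimensionless.  Each
mode carries an effective mass ``hbar**2 / omega`` so that a free mode
oscillates at the angular frequency ``omega / hbar`` and the classical thermal
coordinate variance is ``kT / omega``.

State indexing is 0-based over the excited manifold: state 0 is S1 (Qy),
state 1 is S2 (Qx), states 2..9 are S3..S10 (the Soret/B manifold).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from ._constants import EV_PER_CM1, HBAR_EV_FS

BANDS = ("Qy", "Qx", "B")

__all__ = [
    "BANDS",
    "AdiabaticPoint",
    "DiabaticModel",
    "LinearCrossingModel",
    "adiabatic_solve",
    "band_of",
    "build_preset",
    "default_band_map",
]


def default_band_map(n_excited: int) -> dict[int, str]:
    """Map 0-based excited-state indices to bands: S1=Qy, S2=Qx, rest=B."""
    bm = {0: "Qy", 1: "Qx"}
    for i in range(2, n_excited):
        bm[i] = "B"
    return bm


def band_of(state: int, band_map: dict[int, str] | None = None) -> str:
    if band_map is not None:
        return band_map[state]
    return "Qy" if state == 0 else ("Qx" if state == 1 else "B")


@dataclass
class DiabaticModel:
    """Shifted-harmonic diabatic Hamiltonian for one chlorophyll-like species.

    Parameters
    ----------
    state_energies
        Vertical diabatic energies at the reference geometry (q = 0), eV,
        one per excited state.
    mode_freqs
        Harmonic mode quanta, eV.
    mode_masses
        Effective masses conjugate to the dimensionless coordinates,
        eV * fs**2.  Defaults to ``hbar**2 / omega``.
    displacements
        Dimensionless equilibrium shifts, shape (n_excited, n_modes).
    couplings
        Constant diabatic couplings, symmetric with zero diagonal, eV.
    linear_couplings
        Optional coordinate-linear coupling slopes,
        shape (n_excited, n_excited, n_modes), eV per coordinate unit.
    transition_dipoles
        Diabatic transition dipole magnitudes from the ground state
        (arbitrary units), one per excited state.
    """

    species: str
    state_energies: np.ndarray
    mode_freqs: np.ndarray
    displacements: np.ndarray
    couplings: np.ndarray
    transition_dipoles: np.ndarray
    mode_masses: np.ndarray | None = None
    linear_couplings: np.ndarray | None = None
    band_map: dict[int, str] = field(default_factory=dict)
    nac_cap: float = 50.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.state_energies = np.asarray(self.state_energies, dtype=float)
        self.mode_freqs = np.asarray(self.mode_freqs, dtype=float)
        self.displacements = np.asarray(self.displacements, dtype=float)
        self.couplings = np.asarray(self.couplings, dtype=float)
        self.transition_dipoles = np.asarray(self.transition_dipoles, dtype=float)
        ne, nm = self.n_excited, self.n_modes
        if np.any(self.mode_freqs <= 0):
            raise ValueError("mode frequencies must be positive")
        if self.displacements.shape != (ne, nm):
            raise ValueError("displacements must have shape (n_excited, n_modes)")
        if self.couplings.shape != (ne, ne):
            raise ValueError("coupling matrix must be square over excited states")
        if not np.allclose(self.couplings, self.couplings.T):
            raise ValueError("coupling matrix must be symmetric")
        if self.mode_masses is None:
            self.mode_masses = HBAR_EV_FS**2 / self.mode_freqs
        else:
            self.mode_masses = np.asarray(self.mode_masses, dtype=float)
            if np.any(self.mode_masses <= 0):
                raise ValueError("mode masses must be positive")
        if self.linear_couplings is not None:
            self.linear_couplings = np.asarray(self.linear_couplings, dtype=float)
            if self.linear_couplings.shape != (ne, ne, nm):
                raise ValueError("linear couplings must have shape (ne, ne, n_modes)")
            if not np.allclose(
                self.linear_couplings, np.swapaxes(self.linear_couplings, 0, 1)
            ):
                raise ValueError("linear couplings must be symmetric in the state pair")
        if not self.band_map:
            self.band_map = default_band_map(ne)

    @property
    def n_excited(self) -> int:
        return len(self.state_energies)

    @property
    def n_states(self) -> int:
        """Ground plus excited states."""
        return self.n_excited + 1

    @property
    def n_modes(self) -> int:
        return len(self.mode_freqs)

    # -- diabatic surfaces ----------------------------------------------

    def ground_energy(self, q: np.ndarray) -> float:
        q = np.asarray(q, dtype=float)
        return float(0.5 * np.dot(self.mode_freqs, q * q))

    def ground_gradient(self, q: np.ndarray) -> np.ndarray:
        return self.mode_freqs * np.asarray(q, dtype=float)

    def excited_hamiltonian(self, q: np.ndarray) -> np.ndarray:
        """Diabatic potential matrix (excited block) at coordinates q, eV.

        Energies are measured from the ground-state surface at the same
        geometry, so the diagonal entries are vertical excitation energies.
        """
        q = np.asarray(q, dtype=float)
        dq = q[None, :] - self.displacements
        # (omega/2) * [(q-d)^2 - d^2 - q^2] = -omega * d * q  relative to ground
        diag = self.state_energies - (self.mode_freqs * self.displacements * q).sum(
            axis=1
        )
        H = self.couplings.copy()
        if self.linear_couplings is not None:
            H = H + self.linear_couplings @ q
        np.fill_diagonal(H, diag)
        return H

    def hamiltonian_gradients(self, q: np.ndarray) -> np.ndarray:
        """dH/dq_m of the *total* potential (excited surface incl. ground
        harmonic part), shape (n_modes, ne, ne)."""
        q = np.asarray(q, dtype=float)
        nm, ne = self.n_modes, self.n_excited
        if self.linear_couplings is not None:
            dH = np.transpose(self.linear_couplings, (2, 0, 1)).copy()
        else:
            dH = np.zeros((nm, ne, ne))
        # total excited surface V_i = V_ground + H_ii -> dV_i/dq_m = omega_m (q_m - d_im)
        diag = self.mode_freqs[:, None] * (q[:, None] - self.displacements.T)
        idx = np.arange(ne)
        dH[:, idx, idx] = diag
        return dH

    def masses(self) -> np.ndarray:
        return self.mode_masses


@dataclass
class LinearCrossingModel:
    """Two linear diabats with a constant coupling: a Landau-Zener benchmark.

    ``V1 = slope * q``, ``V2 = -slope * q``, off-diagonal coupling ``lam``.
    Used to check the surface-hopping engine against the closed-form
    Landau-Zener transition probability on a constant-velocity sweep.
    """

    slope: float
    lam: float
    mass: float = 100.0
    nac_cap: float = 1e6
    species: str = "landau-zener"
    band_map: dict[int, str] = field(default_factory=lambda: {0: "Qy", 1: "Qx"})
    metadata: dict = field(default_factory=dict)

    n_excited: int = 2
    n_modes: int = 1

    @property
    def transition_dipoles(self) -> np.ndarray:
        return np.ones(2)

    def ground_energy(self, q: np.ndarray) -> float:
        return 0.0

    def ground_gradient(self, q: np.ndarray) -> np.ndarray:
        return np.zeros(1)

    def excited_hamiltonian(self, q: np.ndarray) -> np.ndarray:
        x = float(np.asarray(q).reshape(-1)[0])
        return np.array([[self.slope * x, self.lam], [self.lam, -self.slope * x]])

    def hamiltonian_gradients(self, q: np.ndarray) -> np.ndarray:
        return np.array([[[self.slope, 0.0], [0.0, -self.slope]]])

    def masses(self) -> np.ndarray:
        return np.array([self.mass])


@dataclass
class AdiabaticPoint:
    """Adiabatic electronic structure at one nuclear geometry.

    ``energies`` ascend; ``nac[a, b, m]`` is the m-th component of the
    derivative coupling d_ab = <a| dH/dq_m |b> / (E_b - E_a), antisymmetric
    in (a, b).  Near-degenerate components are clamped at the model's
    ``nac_cap`` and flagged.
    """

    position: np.ndarray
    energies: np.ndarray
    gradients: np.ndarray
    nac: np.ndarray
    oscillator_strengths: np.ndarray
    eigenvectors: np.ndarray
    nac_capped: bool = False


def _eigh2(H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Analytic eigendecomposition of a symmetric 2x2 (speed path)."""
    a, b, c = H[0, 0], H[1, 1], H[0, 1]
    t = 0.5 * (a + b)
    s = np.hypot(0.5 * (b - a), c)
    e = np.array([t - s, t + s])
    v2 = np.array([c, e[1] - a])
    n = np.hypot(v2[0], v2[1])
    if n < 1e-300:
        V = np.eye(2)
    else:
        v2 /= n
        V = np.column_stack([np.array([-v2[1], v2[0]]), v2])
    return e, V


def adiabatic_solve(model, R: np.ndarray) -> AdiabaticPoint:
    """Diagonalise the diabatic potential at R.

    Gradients come from the Hellmann-Feynman theorem, derivative couplings
    from ``<a|dH|b> / (E_b - E_a)`` with near-degenerate components capped
    at ``model.nac_cap``, and oscillator strengths from the eigenvector-
    rotated diabatic transition dipoles, ``f_a = E_a * |mu_a|**2``.
    """
    q = np.asarray(R, dtype=float)
    if q.shape != (model.n_modes,):
        raise ValueError(f"R must have one value per mode ({model.n_modes})")
    H = model.excited_hamiltonian(q)
    if not np.all(np.isfinite(H)):
        raise FloatingPointError("non-finite diabatic Hamiltonian")
    if model.n_excited == 2:
        energies, V = _eigh2(H)
    else:
        energies, V = np.linalg.eigh(H)
    # deterministic sign gauge: largest-|component| entry positive
    k = np.argmax(np.abs(V), axis=0)
    V *= np.where(V[k, np.arange(V.shape[1])] < 0, -1.0, 1.0)

    dH = model.hamiltonian_gradients(q)  # (nm, ne, ne)
    # M[m, a, b] = <a| dH_m |b>
    M = np.matmul(V.T, np.matmul(dH, V))
    ne = model.n_excited
    idx = np.arange(ne)
    gradients = M[:, idx, idx].T.copy()  # (ne, nm)

    gap = energies[None, :] - energies[:, None]  # E_b - E_a
    capped = False
    with np.errstate(divide="ignore", invalid="ignore"):
        nac = np.transpose(M, (1, 2, 0)) / gap[:, :, None]
    nac[idx, idx, :] = 0.0
    cap = float(model.nac_cap)
    over = ~np.isfinite(nac) | (np.abs(nac) > cap)
    if np.any(over):
        capped = True
        signs = np.sign(np.transpose(M, (1, 2, 0))[over])
        signs[signs == 0] = 1.0
        nac[over] = signs * cap
    # enforce exact antisymmetry against cap/rounding asymmetries
    nac = 0.5 * (nac - np.transpose(nac, (1, 0, 2)))

    mu = V.T @ np.asarray(model.transition_dipoles, dtype=float)
    osc = energies * mu**2

    return AdiabaticPoint(
        position=q,
        energies=energies,
        gradients=gradients,
        nac=nac,
        oscillator_strengths=osc,
        eigenvectors=V,
        nac_capped=capped,
    )


# -- presets -------------------------------------------------------------


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_preset_config(species: str) -> dict:
    try:
        text = (
            resources.files("photorelax")
            .joinpath(f"presets/{species}.yaml")
            .read_text()
        )
    except FileNotFoundError as err:
        raise ValueError(f"unknown species {species!r}") from err
    return yaml.safe_load(text)


def build_preset(species: str, overrides: dict | None = None) -> DiabaticModel:
    """Build the chla/chlb surrogate model.

    The diabatic energies of Qy, Qx and B1 are calibrated iteratively so that
    the *adiabatic* vertical gaps at the reference geometry reproduce the
    configured values exactly (coupling-induced level repulsion included);
    B2..B8 ride at a fixed spacing above B1.
    """
    cfg = load_preset_config(species)
    if overrides:
        cfg = _deep_merge(cfg, overrides)

    ne = int(cfg["n_excited"])
    freqs = np.asarray(cfg["modes"]["freqs_cm1"], dtype=float) * EV_PER_CM1
    nm = len(freqs)

    disp = np.zeros((ne, nm))
    dcfg = cfg["displacements"]
    disp[0] = dcfg["qy"]
    disp[1] = dcfg["qx"]
    # B1 gets its own (small) displacement so the Soret ensemble peak stays
    # sharp; B2 and up share a base displacement plus an alternating
    # component, so adjacent Soret diabats cross as the tuning modes move
    # (intra-band relaxation funnel): d_Bj = b + (-1)^(j+1) * b_alternation.
    b_base = np.asarray(dcfg["b"], dtype=float)
    b_alt = np.asarray(dcfg.get("b_alternation", np.zeros(nm)), dtype=float)
    disp[2] = np.asarray(dcfg.get("b1", b_base), dtype=float)
    for i in range(3, ne):
        disp[i] = b_base + (1 if (i - 2) % 2 == 1 else -1) * b_alt

    lam = np.zeros((ne, ne))
    for i, j, v in cfg["couplings"].get("constant", []):
        lam[i - 1, j - 1] = lam[j - 1, i - 1] = float(v)
    lin = None
    lin_entries = cfg["couplings"].get("linear") or []
    if lin_entries:
        lin = np.zeros((ne, ne, nm))
        for i, j, m, s in lin_entries:
            lin[i - 1, j - 1, m] = lin[j - 1, i - 1, m] = float(s)

    ref = cfg["reference_energies"]
    e_qy = float(ref["qy_vertical_ev"])
    targets = np.array(
        [e_qy, e_qy + ref["gap_qx_qy_ev"], e_qy + ref["gap_qx_qy_ev"] + ref["gap_b1_qx_ev"]]
    )
    spacing = float(ref["b_spacing_ev"])

    energies = np.empty(ne)
    energies[:3] = targets
    energies[3:] = targets[2] + spacing * np.arange(1, ne - 2)

    model = DiabaticModel(
        species=cfg["species"],
        state_energies=energies,
        mode_freqs=freqs,
        displacements=disp,
        couplings=lam,
        transition_dipoles=np.asarray(cfg["dipoles"], dtype=float),
        linear_couplings=lin,
        nac_cap=float(cfg.get("nac_cap", 50.0)),
        metadata={
            "laser": dict(cfg.get("laser_metadata", {})),
            "reference_energies": dict(ref),
        },
    )

    q0 = np.zeros(nm)
    for _ in range(200):
        pt = adiabatic_solve(model, q0)
        err = targets - pt.energies[:3]
        if np.max(np.abs(err)) < 1e-12:
            break
        model.state_energies[:3] += err
        model.state_energies[3:] = model.state_energies[2] + spacing * np.arange(
            1, ne - 2
        )
    else:
        raise RuntimeError("preset gap calibration did not converge")
    return model
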