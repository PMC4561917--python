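# Surrogate vibronic-model preset: chlorophyll a.
#
# A shifted-harmonic diabatic Hamiltonian with constant (plus optional linear)
# inter-state couplings.  Only the inter-band vertical gaps and the qualitative
# ordering of couplings and oscillator strengths are calibrated to the
# chlorophyll literature; mode frequencies, displacements and the Soret-band
# substructure are model choices (see docs/methods.md).
species: chla
n_excited: 10

reference_energies:
  # Vertical Qy energy at the reference geometry (sets the absolute scale,
  # chosen so that B1 lands near the semiempirical-scale Soret position).
  qy_vertical_ev: 1.70
  # Calibrated adiabatic vertical gaps at the reference geometry.
  gap_qx_qy_ev: 0.82
  gap_b1_qx_ev: 0.42
  # Spacing of B2..B8 above B1 (free model choice; the Soret substructure
  # is not constrained by the calibration references).
  b_spacing_ev: 0.12

modes:
  # Eight harmonic modes, logarithmically spaced over the chlorin
  # skeletal-vibration range.
  freqs_cm1: [200, 269, 362, 488, 656, 883, 1189, 1600]

# Dimensionless excited-state displacements per mode.  The structure builds
# the internal-conversion funnels (see docs/methods.md): Qy stays weakly
# displaced (sharp ensemble Qy peak); Qx carries a large low-frequency-mode
# displacement opposite in sign to the B band, so the B->Qx diabatic gap
# closes near the B-state minimum; the B band adds an alternating
# high-frequency component (b_alternation, applied as +/- on successive B
# states) so adjacent Soret diabats cross and the intra-band cascade runs.
displacements:
  qy: [0.186, -0.150, 0.132, 0.090, -0.072, 0.060, 0.036, 0.024]
  qx: [-3.60, -2.95, -2.30, -1.65, 0.10, -0.08, 0.05, 0.03]
  b1: [0.45, 0.38, 0.30, 0.20, 0.05, 0.04, -0.03, 0.02]
  b: [1.20, 1.00, 0.80, 0.50, 0.08, 0.06, -0.05, 0.03]
  b_alternation: [0.0, 0.0, 0.0, 0.0, 0.45, 0.38, 0.32, 0.25]

couplings:
  # Constant diabatic couplings in eV, [state_i, state_j, value] with
  # 1-based S-indices (S1 = Qy, S2 = Qx, S3..S10 = Soret manifold).
  constant:
    - [1, 2, 0.045]
    - [2, 3, 0.025]
    - [3, 4, 0.030]
    - [4, 5, 0.030]
    - [5, 6, 0.030]
    - [6, 7, 0.030]
    - [7, 8, 0.030]
    - [8, 9, 0.030]
    - [9, 10, 0.030]
  # Linear diabatic couplings, [state_i, state_j, mode_index, slope_eV]:
  # coordinate-dependent mixing that modulates the nonadiabatic coupling.
  linear:
    - [1, 2, 2, 0.010]
    - [2, 3, 1, 0.012]

# Diabatic transition dipole magnitudes (arbitrary units), per excited state.
# Chosen so f(Qy) > f(Qx) and B1 dominates the Soret band.
dipoles: [1.00, 0.45, 1.60, 0.40, 0.30, 0.22, 0.22, 0.22, 0.22, 0.22]

# Cap applied to near-degenerate nonadiabatic-coupling components
# (coordinate units^-1).
nac_cap: 50.0

# Pump-pulse bookkeeping on the semiempirical energy scale; stored as
# metadata only, the working pulse centre defaults to the ensemble-mean B1.
laser_metadata:
  e_laser_ev: 2.94
  gamma_ev: 0.14
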