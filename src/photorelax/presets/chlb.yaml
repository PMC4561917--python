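# Surrogate vibronic-model preset: chlorophyll b.
#
# Differs from the chlorophyll-a preset in its vertical gaps (smaller B/Qx,
# larger Qx/Qy separation), a weaker Qy/Qx coupling and a stronger B1/Qx
# coupling, and a lower Qy transition dipole.
species: chlb
n_excited: 10

reference_energies:
  qy_vertical_ev: 1.80
  gap_qx_qy_ev: 0.86
  gap_b1_qx_ev: 0.26
  b_spacing_ev: 0.12

modes:
  freqs_cm1: [200, 269, 362, 488, 656, 883, 1189, 1600]

displacements:
  qy: [0.186, -0.150, 0.132, 0.090, -0.072, 0.060, 0.036, 0.024]
  # Shallower Qx funnel than chlorophyll a: the Qx minimum sits farther from
  # the Qx/Qy intersection seam, so the final internal-conversion step is
  # rarer per funnel passage and the Qy rise is slower overall.
  qx: [-2.50, -2.05, -1.60, -1.15, 0.10, -0.08, 0.05, 0.03]
  b1: [0.45, 0.38, 0.30, 0.20, 0.05, 0.04, -0.03, 0.02]
  b: [1.20, 1.00, 0.80, 0.50, 0.08, 0.06, -0.05, 0.03]
  b_alternation: [0.0, 0.0, 0.0, 0.0, 0.45, 0.38, 0.32, 0.25]

couplings:
  constant:
    # Weaker Qx/Qy mixing than chlorophyll a; stronger B1/Qx mixing
    # (the B -> Qx funnel runs closer to the intersection seam).
    - [1, 2, 0.028]
    - [2, 3, 0.035]
    - [3, 4, 0.030]
    - [4, 5, 0.030]
    - [5, 6, 0.030]
    - [6, 7, 0.030]
    - [7, 8, 0.030]
    - [8, 9, 0.030]
    - [9, 10, 0.030]
  linear:
    - [1, 2, 2, 0.007]
    - [2, 3, 1, 0.015]

dipoles: [0.80, 0.50, 1.55, 0.40, 0.30, 0.22, 0.22, 0.22, 0.22, 0.22]

nac_cap: 50.0

laser_metadata:
  e_laser_ev: 2.92
  gamma_ev: 0.14
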