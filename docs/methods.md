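# Methods

This document records the model construction, unit conventions, algorithms
and known limitations of the `photorelax` surrogate pipeline.

## Units and constants

Everything runs in a consistent eV/fs system:

- energy: eV; time: fs (API totals in ps where noted); ħ = 0.6582119569 eV·fs;
  k_B = 8.617333262 × 10⁻⁵ eV/K; 1 cm⁻¹ = 1.239841984 × 10⁻⁴ eV.
- Mode coordinates q are dimensionless displacements; each mode carries a
  mass m = ħ²/ω (ω in eV) so that the classical thermal variances are
  ⟨q²⟩ = k_BT/ω and ⟨p²⟩ = m·k_BT.
- Gaussian width conversion: FWHM = 2·sqrt(2·ln 2)·σ ≈ 2.3548·σ.

## Surrogate vibronic model (`vibronic`)

A linear-vibronic-coupling (LVC) Hamiltonian with N = 10 excited diabatic
states over M = 8 harmonic modes:

- ground surface V₀(q) = ½ Σ_m ω_m q_m²;
- excited diabats H_αα(q) = E_α + ½ Σ_m ω_m (q_m − d_{α,m})² − ½ Σ_m ω_m d_{α,m}²
  + E_α-offset such that the *vertical* energy at q = 0 is the configured
  value (shifted-harmonic form);
- off-diagonals H_αβ(q) = c_αβ + Σ_m λ_{αβ,m} q_m (constant plus linear).

State 0 is Qy (S1), state 1 is Qx (S2), states 2–9 form the Soret/B band
(S3–S10). `adiabatic_solve` diagonalises H(q), applies a smooth sign gauge,
and returns energies, eigenvectors, nonadiabatic-coupling (NAC) components
(capped near degeneracies) and oscillator strengths f ∝ E·μ² from the
diabatic transition dipoles rotated into the adiabatic basis.

`build_preset` reads `presets/chla.yaml` / `chlb.yaml` and runs a small
calibration loop so the *adiabatic* vertical gaps at q = 0 match the
configured values exactly (Qx−Qy 0.82 / 0.86 eV, B1−Qx 0.42 / 0.26 eV for
chla / chlb) even in the presence of the couplings.

### Funnel design

Displacements are the model's only handle on internal-conversion dynamics
(they never change the q = 0 spectrum). The presets use three structural
ideas:

1. **B → Qx funnel**: the Qx diabat is strongly displaced along the four
   low-frequency modes, *opposite* in sign to the B-band displacement, so
   the B–Qx diabatic gap closes near the B minimum and trajectories reach
   the crossing seam while vibrationally hot.
2. **Intra-Soret cascade**: B states share a moderate displacement plus an
   alternating high-frequency component (d = b ± b_alternation on
   successive states), which makes adjacent Soret diabats cross.
3. **Qx → Qy step**: Qy keeps small displacements (sharp ensemble Qy peak);
   the species contrast is set by the Qx displacement depth. The chla Qx
   funnel reaches the Qx/Qy seam ballistically, while the chlb Qx minimum
   sits ≈ 3 thermal standard deviations from the seam, making the last
   step the chlb bottleneck. In 1 ps ensembles the chlb preset relaxes to
   Qy markedly slower than chla (overall timescale roughly 2× longer),
   reproducing the qualitative species ordering; absolute trajectory
   timescales are not calibrated.

## Ground-state sampling and spectra (`sampling`)

`run_ground_sampling` integrates BAOAB Langevin dynamics on V₀ (exact
Ornstein–Uhlenbeck friction/noise step) with five independent runs harvested
round-robin: after an equilibration period (default 10 ps) one configuration
per run every 1 ps until n_configs are collected (defaults: 300 K, friction
2 ps⁻¹, dt 0.5 fs).

`absorption_spectrum` builds a band-resolved histogram: each (state,
sample) pair contributes a Gaussian (default bandwidth 0.02 eV) of area
f/n on a 0.005 eV grid. Band peaks are refined below the grid by quadratic
interpolation around the maximum; the headline observable is the Soret−Qy
peak gap (1.24 eV chla, 1.12 eV chlb, tolerance ±0.01 eV = half the kernel
bandwidth).

**Franck–Condon window convention**: the excitation weight is
g_α = f_α · exp[−(T·(E_laser − E_α)/ħ)²] with T = 2·sqrt(ln 2)·ħ/Γ, i.e.
Γ (default 0.14 eV) is the *spectral* FWHM of the window exp-term. The
initial state is drawn per configuration from the normalised g_α.

## Surface hopping (`fssh`)

Classical nuclei follow the active adiabatic surface with BAOAB Langevin
steps (or plain velocity Verlet when friction = 0). Electronic amplitudes
are propagated in the interaction picture: the diagonal phase of the
linearly interpolated adiabatic energies is integrated analytically, and an
adaptive Dormand–Prince 5(4) pair (atol 10⁻⁸) with its 4th-order continuous
extension follows only the NAC-driven mixing — one adaptive pass per
classical step supplies all quantum substeps (default 4). Norm drift is
~10⁻¹⁴/ps.

Hops use the fewest-switches probability
g_{a→b} = max(0, 2·dt_q·Re(c_a* c_b)·σ_ab / |c_a|²), clamped to [0, 1],
with σ_ab the velocity–NAC contraction; the target is drawn by cumulative
comparison with one uniform variate. Accepted hops rescale momentum along
the NAC direction (smaller-|γ| root; energy conserved to machine
precision); frustrated hops keep or reverse the projected momentum
(configurable). State identity across steps is tracked by maximum-overlap
assignment (Hungarian algorithm on |V_prevᵀ V_new|).

`LinearCrossingModel` (two diabats ∓slope·x with constant coupling λ)
provides the analytic benchmark: a single sweep at velocity v transfers
diabatic population P_LZ = exp(−2πλ²/(ħ·v·Δ|F|)). For quantitative
agreement the sweep must start far enough out that the adiabatic and
diabatic bases coincide (the constant coupling leaves a λ/(2·slope·|x|)
mixing angle at the endpoints); the validation uses x₀ = −16.

## Sequential kinetics (`kinetics`)

Closed-form irreversible two-step model
B →(k1) Qx →(k2) Qy with arbitrary initial populations, including the
continuous equal-rate limit k·t·e^{−kt}. Band populations come either from
trajectory band series or from two-column waiting-time samples (B while
t < t₁, Qy from t₁+t₂). `fit_sequential` is a multistart trust-region
least-squares fit in log-rate space with covariance from the Jacobian;
flat inputs (min B > 0.9·B₀) raise `FlatInputError`. `convergence_analysis`
splits n trajectories into batches of 100 and fits all combinations of
1..n/100 batches — for 500 trajectories the combination counts are
(5, 10, 10, 5, 1) — reporting mean and sd of τ₁/τ₂ versus pool size.

## Effective hops (`hops`)

The *effective* hop of a trajectory for a channel (B→Qx or Qx→Qy) is the
last donor→acceptor crossing not followed by a return to the donor band;
frustrated hops never qualify, and each trajectory contributes at most one
event per channel. Event times are measured from the most recent entry
into the donor band. Events are classed near-conical-intersection when the
adiabatic gap at the hop is ≤ 0.1 eV (inclusive); summaries report the
near-CI percentage, per-class mean times and cumulative counts.

## Transition-density fragments (`tdfrag`)

Scheme files (`schemes/chla.yaml`, `chlb.yaml`) assign the 33/34 heavy
atoms of the chlorin core to groups: Mg, the four nitrogens, the carbonyl
oxygens (the b species adds the formyl O7_1), inner (12 atoms) and outer
macrocycle, and four quadrant fragments that exactly partition the molecule
(the four meso carbons are split 0.5/0.5 between adjacent fragments, Mg
0.25 to each). Synthetic per-atom weights are band-dependent templates
(Soret more outer-ring weight, Qy more inner-ring weight) with
multiplicative lognormal noise (cv 0.2), renormalised to Σ = 1 per frame.
Fragment fractions are weighted sums; ensemble traces are frame-wise means
across trajectories on a common time grid.

## Transient absorption (`tafit`)

Two-compartment sequential scheme Sn → S1 with the S1 lifetime fixed at
5 ns (quasi-stationary). Concentration profiles are the exact
exponential ⊗ Gaussian-IRF closed form (exponentially modified Gaussian via
erfc; default IRF FWHM 55 fs), with Bateman feeding for the second
compartment. Surfaces are ΔA(λ, t) = Σ_i c_i(t)·SADS_i(λ) on a 600–700 nm
× (−200 fs…2.5 ps) grid, optionally with per-wavelength t₀ chirp and
Gaussian noise. `global_fit` is a variable projection: SADS are solved by
linear least squares at each trial lifetime; the free lifetime (and
optionally t₀) is optimised in log space; standard errors come from the
reduced Jacobian. Degenerate problems raise `RankDeficientError`, both when
the concentration columns are collinear and when the residual is insensitive
to a free lifetime (a population-conserving chain fits a quasi-stationary
surface exactly for any free lifetime).

## Pipeline and reproducibility (`pipeline`, `cli`)

`run_pipeline` chains sampling → Franck–Condon selection → FSSH ensemble →
kinetics → hop statistics → transition-density traces, with one master
`SeedSequence` spawning independent streams per stage and per trajectory;
the JSON manifest stores the config and per-trajectory seed words, making
every artifact reproducible byte-for-byte. `make_fixtures` writes
deterministic synthetic datasets (two-step hop times, TD frames, TA
surfaces) used by the tests and docs.

## Statistical test design

Stochastic test tolerances were sized *before* the tests were first run,
from null-distribution Monte Carlos with disjoint seeds: the 500-trajectory
rate-recovery bands are 3× the measured estimator sd (chla τ₁/τ₂:
±14.9/±19.1 fs; chlb: ±8.8/±30.6 fs), the noisy-TA 20-seed mean band is
±0.5 fs, and the Landau–Zener band is the 3σ binomial width at 2000
trajectories (±0.0305). Fixed seeds derive from a single date-based
`SeedSequence` chosen a priori.

## Limitations

- The surrogate's FSSH trajectory timescales are qualitative: the
  literature rate constants enter only the synthetic kinetics/TA
  generators, not the vibronic model, and no attempt is made to match the
  absolute B→Qy relaxation time.
- Only per-atom diagonal transition-density contributions are modeled (the
  fragment weights are synthetic templates, not electronic-structure
  densities).
- Decoherence corrections beyond optional instantaneous collapse are not
  implemented; FSSH is used in its standard form.
- The coherent-artifact basis in `tafit` is optional and off by default;
  chirp is a quadratic polynomial in wavelength.
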