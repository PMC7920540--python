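# Model and methods

`vmtc` implements a conductance-based multicompartment model of a
thalamocortical (TC) relay neuron of the basal-ganglia-receiving motor
thalamus (ventromedial/ventroanterior nuclei), together with the virtual
current-clamp experiments and trace-analysis procedures used to
characterize its intrinsic excitability. The model's scientific focus is
the role of the M-type (Kv7) potassium current in TC excitability: its
loss — combined with an increase of the hyperpolarization-activated
cation current IH — converts the control phenotype into a
hyperexcitable, strongly rebound-bursting, high-sag phenotype like that
seen after chronic dopamine depletion.

## Geometry

The cell is a tree of cylindrical sections: a single-compartment soma of
fixed surface area (293 µm²), an axon initial segment kept to its first
70 µm at 1.5 µm diameter, and a dendritic tree. Real SWC reconstructions
can be loaded (`morphology.load_swc`; the axon is truncated and
relabelled, the soma replaced by the fixed-area compartment). The
default build uses a parametric surrogate: five dendritic stems with
symmetric binary branching to third order, 40 µm sections, and diameters
assigned top-down by the Rall 3/2-power branch rule
(d_parent^{3/2} = Σ d_child^{3/2}, equal siblings, clamped at 0.3 µm).
Spines and distal axon are not modelled.

Sections map to five channel-density columns — AIS, soma and three
dendritic classes. The dendritic sub-headers of the density table do not
define the three classes unambiguously, so the mapping is a configurable
scheme; the default assigns proximal first-order sections to class 2,
higher orders to class 3, and anything beyond a 100 µm path-distance
cutoff to class 1 ("distal").

Cable discretization splits each section into ⌈L/40 µm⌉ compartments
(38 compartments for the calibrated default; ~0.06 λ per compartment),
conserving membrane area exactly and coupling compartments through
half-cylinder axial resistances at ri = 60 Ω·cm.

## Membrane mechanisms

Ten conductance classes are distributed over the morphology with the
model's fixed density table (S/cm²; the T-type entries are GHK
permeabilities in cm/s — see below): fast sodium NaF, persistent sodium
NaP, delayed-rectifier KDR, transient A-type KA, M-type KM, L-type
calcium CaL, SK, calcium-activated chloride ANO2, T-type calcium CaT and
IH. All rate functions are evaluated at 27 °C via per-channel Q10
factors.

Three currents are defined by the study itself:

* **KM**: activation m(v) = 0.025 + 1/(1 + exp(−(v + 36.7)/9.48)). The
  additive 0.025 raises the resting open fraction (this is what lowers
  the resting potential), so the curve tops out at 1.025 and is
  deliberately not clamped. The time constant is an Adams/Yamada-type
  bell (peak ≈ 46 ms at −35 mV at 27 °C); a fast parameterization is
  used so that even partial M-current clips low-threshold bursts, which
  reproduces the all-or-none character of the rebound effect (full block
  increases burst spike counts, 50 % block does not).
* **NaP** is NaF with both gating curves translated 14 mV
  hyperpolarized (half-activation 14 mV below NaF's), giving a
  persistent inward current near threshold. The shift sign is a
  convention choice and is exposed as a signed parameter.
* **IH** carries a −11 mV translation of its (falling,
  "inactivation-shaped") gating curve. Without the shift the sag
  saturates by −150 pA; with it the sag percentage grows monotonically
  over −50…−200 pA steps. The IH time constant uses the classic
  double-exponential rate form with a 100 ms floor so that deep
  hyperpolarizations do not make activation unphysically fast (the floor
  is what preserves a well-formed passive trough, and hence monotone
  sag, at −200 pA).

The remaining kinetics form a documented, swappable catalogue of
standard published parameterizations: Traub-style NaF (vtraub = −63 mV;
inactivation recovers near rest so the cell fires tonically from
depolarized holds), a steep high-threshold Kv3-family n² delayed
rectifier (essentially closed below −40 mV — required by the 10:1
KDR:NaF somatic density ratio), Korngreen–Sakmann-type m⁴h transient K,
a Destexhe-type GHK T-current (half-activation −55 mV, half-inactivation
−79 mV after a +2 mV screening shift for 2 mM external calcium), a
Reuveni-type high-voltage-activated L-current and Hill-gated SK
(n = 4, EC50 0.3 µM) and ANO2 (n = 2, EC50 1 µM, fixed reversal
−86 mV). Reversals: E_Na = +50, E_K = −85, E_h = −35 mV, all
configurable. E_K/E_h sit at the depolarized edge of their conventional
ranges; with this catalogue they are what balances the resting KM
current (two-thirds of which comes from the high-density AIS) so that
the calibration targets are reachable with a leak reversal near the
resting potential — which in turn is what keeps a stable quiet resting
state in *every* pharmacological condition, including full M-current
block.

**Calcium handling.** CaT current uses the GHK flux equation with
[Ca]ₒ = 2 mM (matching the recording solution); its table entries are
permeabilities (cm/s), the only reading consistent with their
magnitudes. CaL is implemented as an ohmic conductance (S/cm²,
E_Ca = +120 mV) with calmodulin-like calcium-dependent inactivation
(open fraction × EC50/(EC50 + [Ca]), EC50 1 µM): a GHK reading of the
printed CaL density yields mA/cm²-scale sustained currents and stable
pathological calcium plateaus, and CDI is the physiological brake that
L-type channels possess. Calcium influx feeds three first-order
microdomains: CaL flux splits 25.8 %/74.2 % between an SK-coupled pool
(τ = 14 ms) and an ANO2-coupled pool (τ = 50 ms); CaT flux feeds a third
50 ms pool that gates nothing (bookkeeping). Influx is converted to free
concentration through a 0.1 µm submembrane shell with a 1 % free-calcium
fraction (rapid-buffer approximation); without buffering, the resting
CaL flux tonically opens the large ANO2 conductance and the cell cannot
fire.

## Numerics

The cable equation is integrated with a fixed-step implicit (backward
Euler) scheme, default dt = 0.025 ms: gates advance by exponential Euler
using steady-state and per-step decay-factor lookup tables
(0.05 mV grid, −180…+60 mV) built from the Python-level kinetics, then
the voltage solve runs a Hines elimination over the compartment tree.
The GHK T-current is linearized around the current voltage with a
non-negative slope so the solve stays unconditionally stable. The kernel
(numba) operates on a forest of trees, so whole cohorts integrate in one
call. Determinism: identical inputs give bit-identical traces.

Accuracy: passive responses match closed-form RC and two-compartment
eigen-solutions to < 0.1 % of the deflection; gate updates match the
exponential closed form to < 10⁻⁶ under voltage clamp. The scheme is
first order in time, so spike *times* drift by ~0.25 ms per interspike
interval between dt = 0.025 and 0.0125 ms while spike counts, latencies
and rates are stable; the reference analysis quantities (rates, counts,
sag, passive constants) are insensitive to this.

**Initialization.** States start from the steady-state gate values at a
slightly depolarized potential (−65 mV) and relax for ≥ 2 s before every
protocol. Like real TC neurons, the model can be bistable between a
quiet rest and a low-threshold burst limit cycle; initializing with the
T-current inactivated finds the quiet attractor, mirroring how a
recorded cell sits at rest.

**Holding currents** are found by a secant search on the bias current,
starting from an analytic uniform-voltage estimate, with the voltage
read as the median over the last 200 ms of a settle (robust when the
target is suprathreshold for M-current-blocked cells, which fire
tonically at −64 mV; the search then sets the interspike baseline).

## Passive calibration

`calibrate_passive` tunes three knobs — dendritic stem diameter
(membrane load), specific membrane resistance rm, and the effective
reversal e_pas of the lumped background/leak conductance — by
sequential 1-D secant passes until the model, *measured with its own
protocols*, reproduces the four target constants: Rin = 218.2 MΩ
(±5 %), τ = 19.1 ms (±10 %, slowest double-exponential term),
C = τ/Rin = 87.4 pF (±10 %) and V_rest = −77.3 mV (±1.5 mV). The
shipped defaults are the calibrated values (stem 3.08 µm,
rm = 88.8 kΩ·cm², e_pas = −70.5 mV) and give Rin 218.6 MΩ, τ 18.4 ms,
C 84.2 pF, V_rest −77.4 mV. rm ends well above its nominal passive
value because roughly half of the resting membrane conductance is
carried by active channels (KM offset, IH, KDR/KA tails); channel
densities themselves are never touched by calibration.

## Protocols and feature extraction

The protocol suite mirrors the experimental design: F-I (2 s steps,
30–360 pA in 30 pA increments, bias hold near −64 mV), rebound (−100 pA
steps of 200/500/2000 ms from ~−71 mV with ≥ 1 s post-step window), sag
(2 s steps, −50…−200 pA, from rest, no bias) and the fixed passive
pulses (−10 pA/100 ms; −1 nA/0.5 ms).

Feature conventions: spikes are upward dV/dt ≥ 10 mV/ms crossings
followed by a > −10 mV peak within 5 ms (2 ms merge window), with the
threshold voltage taken at the crossing sample; firing rates exclude the
first 50 ms after step onset; rheobase inverts a Boltzmann fit of the
F-I relation at 3 Hz (10 Hz alternative; linear interpolation on raw
points available under a method flag — for cells firing above target at
every tested current the fitted rheobase extrapolates below the tested
range); sag% = 100·(1 − V_ss/V_peak) with deflections from a 100 ms
pre-onset baseline and V_ss at the step end, classified as
sag-expressing strictly above 15 %; rebound spikes are counted in a
500 ms post-offset window and binned by the end-of-step
hyperpolarization ([0,20), [20,40), [40,60) mV); τ is either the raw
33 %-decay time or the slowest term of a double-exponential fit
(both emitted, method-tagged). The liquid junction potential uses the
stationary Henderson equation with a bundled limiting-conductance table
(gluconate and large organic anions at ~⅓ of K⁺ mobility, the dominant
uncertainty); the computed 14.3 mV correction is reported but, following
the experimental convention, never subtracted from voltages.

## Synthetic cohorts

`cohort` emulates the two experimental groups at desk scale: each cell
multiplies every channel density by an independent log-normal factor
(median 1, CV 0.15 by default), then applies the condition scalings —
control (KM × 1, IH × 1) or lesioned (KM × 0, IH × 2; IH × 3 is the
documented alternative). This generator reproduces broad, overlapping
feature distributions and the *directions* of the group differences
(rheobase ↓, V_rest ↑, rebound count ↑, sag ↑ in the lesioned group); it
does not model correlated channel regulation, morphological variability
or measurement noise, so quantitative experimental effect sizes and
p-values are outside its claims. The reduced resolution used for
multi-seed replication (six 1 s F-I amplitudes, one sag and one rebound
step, dt = 0.05 ms) preserves the effect directions at ~¼ the cost of
the full suite; direction recovery is verified over 20 seed replicates
with n = 8 cells per group, alongside a null configuration (identical
scalings in both groups) checked with a two-sided sign test.

## Known limitations

* The seven imported channel kinetics are re-derived from standard
  published parameterizations, not from the original source model, so
  absolute rheobases, firing rates and holding currents differ from the
  reference figures; the package asserts the reproducible quantities
  (passive constants, junction potential, and the signs/orderings of
  every pharmacological effect).
* Voltage clamp, synaptic input and network context are out of scope.
* The first-order integrator trades spike-time accuracy for robustness
  and determinism (see Numerics).
* The surrogate morphology is electrotonically compact; real
  reconstructions with long dendrites would place more membrane in the
  "distal" density class than the surrogate does.
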