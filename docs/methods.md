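# Model and methods

## Scope

`ipsccm` implements a single hiPSC-derived cardiomyocyte as a
deterministic ODE system coupling sarcolemmal electrophysiology to a
radially discretized intracellular Ca²⁺ space, plus the experiment
protocols, disease variants and population analyses built on it.  Adult
ventricular/atrial comparison models are out of scope; the protocol layer
only assumes the `Model` interface, so other cell models can be plugged in
later.  Chamber-specific (atrial-like/ventricular-like) parameter variants
and intracellular signalling cascades are deliberately not modelled.

## Membrane electrophysiology

Currents are Hodgkin–Huxley gates times driving force, with carrier
kinetics for the pumps and exchanger.  The formulations are standard
human-cardiomyocyte expressions: an m³hj fast Na⁺ current whose
steady-state availability and recovery taus carry explicit hooks for the
Brugada transform (availability shift in mV, separate fast/slow recovery
scalings); an L-type Ca²⁺ current d·f1·f2·fCa with an ohmic driving force
referenced to +60 mV and Ca-dependent inactivation sensed at the
sub-sarcolemmal shell; transient-outward, rapid and slow delayed-rectifier
and inward-rectifier K⁺ currents; a funny current split 42/58 between Na⁺
and K⁺; the Na⁺/K⁺ pump (3:2); an electrogenic 3Na:1Ca exchanger whose
current vanishes exactly at 3E_Na − 2E_Ca (forward mode, Ca²⁺ extrusion,
is inward); a sarcolemmal Ca²⁺ pump; and linear background Na⁺/Ca²⁺
currents.  [Na⁺]ᵢ and [K⁺]ᵢ evolve from the stoichiometric sums of their
carrying currents; the identity "z-weighted ion fluxes = total membrane
current" holds to round-off and is asserted in the tests.  The I_to
steady-state inactivation midpoint sits at −43 mV so that the slow
diastolic depolarization of spontaneous beats inactivates the current
(accommodation); this is the main locus of the spontaneous-vs-paced
difference in peak I_to.  Temperature is fixed at 37 °C; there is no Q10
machinery and no drug-binding kinetics beyond fractional block.

## Geometry and calcium handling

The cell is a 10 μm sphere divided into 20 concentric 0.5-μm shells
(65% of the geometric volume is Ca-accessible cytosol; 6% is SR).  Free
Ca²⁺ diffuses radially (finite-volume scheme, zero-flux boundaries;
sarcolemmal fluxes enter the outermost shell as a source).  Buffering is
explicit mass action with two endogenous species (a fast calmodulin-like
buffer, 24 μM, K_d 7 μM; a slower troponin/SR-site-like buffer, 250 μM,
K_d 0.6 μM) plus optional Fluo-4 (2 μM, K_d 335 nM) used only in the
Ca-injection assay.  The single SR pool carries rapid-equilibrium
calsequestrin buffering, distributed Hill-type SERCA uptake
(half-activation 0.6 μM, Hill 1.8) and a linear SR→cytosol leak.
A small constitutive IP₃R flux (fixed IP₃; no phospholipase-C dynamics)
drains the SR into the perinuclear region.

### Release relays

RyR release is represented by relays in every shell deeper than ~1 μm
(the sub-membrane shells carry no junctional SR of their own; the
shallowest relay senses sub-membrane Ca²⁺ directly, which is what lets
the L-type trigger capture it reliably).  The named release locations of
the cell's ultrastructure — the central/perinuclear SR region and the
sites 2 μm and 4 μm below the sarcolemma — exist as density multipliers,
reporting channels, and targets for forced-opening overrides (caffeine,
CPVT).  Each relay has:

* a fast activation gate with a sharp logistic dependence on local Ca²⁺
  whose midpoint falls as the SR loads (luminal sensitization between
  0.08 and 0.2 μM); and
* a binary armed/refractory flag managed event-wise by the integrator: an
  armed relay shuts when the store is drawn down below 41% of the re-arm
  level or after 50 ms of continuous opening, and re-arms only after a
  200 ms refractory delay **and** a store refilled past 0.5 mM **and**
  local Ca²⁺ back at diastolic levels.

The event-driven refractory flag is a deliberate design choice: during
development, every smooth (Hill/logistic) inactivation gate we tried
produced either a permanent sub-threshold "smoldering" release or
self-organized pinning of the SR load at a gate threshold, because a
continuous open-probability always admits a stable leak/uptake crossing.
The discrete state machine makes the closed state absorbing and is best
read as a phenomenological reduction of RyR-cluster behaviour, not a
molecular gating scheme.

## Numerics

The compiled core advances all Hodgkin–Huxley-type gates with exact
exponential (Rush–Larsen) updates — unconditionally stable for the stiff
gate kinetics — and concentrations/voltage with forward Euler on a
rate-adapted step: dt shrinks from 0.2 ms with |dV/dt| and with the
fastest relative Ca²⁺ rate, is floored at 5 μs, and is capped at 20 μs
while a stimulus pulse is on so 0.5-ms pulses are never stepped over.
Protocol structure (pacing pulses, clamps, forced openings, bias ramps)
is expressed as piecewise-constant drive segments; the integrator lands
exactly on segment and sample boundaries, so runs are bitwise
deterministic.  Halving all step bounds changes APD90 and CaT amplitude
by <0.5% (asserted in the tests).  Concentrations are floored at 1 pM
and buffer occupancies clipped to [0, B_tot] as numerical guards.

All protocols start from the packaged control 1 Hz paced steady state
(regenerated by `scripts/bootstrap_steady_state.py`: 400 s of pacing,
convergence asserted as <0.5% cycle-to-cycle spread of APD90 and CaT
amplitude over the last ten cycles — a criterion an alternating sequence
cannot pass).  The long settling reflects the ~130-s relaxation of
[Na⁺]ᵢ/[K⁺]ᵢ.

## Calibration of the control set

Parameter values were first transcribed from the standard formulations the
current inventory is drawn from, then calibrated as a whole against the
study's printed control behaviours (spontaneous rate near 45 BPM, paced
APD90 ≈ 250–330 ms from an MDP near −75 mV, sub-micromolar CaT with
slow decay, per-beat whole-cell CICR under pacing, automaticity abolished
by full NCX block).  Two constraints dominated the calibration and are
worth recording:

* **Paced entrainment vs. spontaneous clock.**  The SR store cycle must
  be triggered once per stimulus under 1 Hz pacing yet free-run at
  ~45/min without stimuli.  In this parameterization the store clock
  entrains to the stimulus by phase-locking (the store's own ignition
  lands late in the paced cycle), which makes paced beats regular but
  means the release onset slightly precedes each stimulus rather than
  following the upstroke.
* **Diastolic SERCA strength.**  Fast SR refill (needed for per-beat
  release at 1 Hz) and a slow whole-cell CaT decay pull the SERCA
  parameters in opposite directions; the shipped values favour robust
  cycling.

## What the shipped parameterization does and does not reproduce

Reproduced (asserted green in `tests/test_acceptance.py`): regular 1:1
paced E-C coupling with whole-cell inward Ca²⁺ waves reaching the central
SR; spontaneous automaticity abolished by full NCX block; accommodation
(peak I_Na ~95% smaller in spontaneous mode; spontaneous CaT amplitude a
few percent smaller than paced); the Brugada variant's raised excitation
threshold and ~+10% APD90 prolongation; LQT2 APD prolongation with the
correct strong-effect direction; whole-cell regenerative transients from
single forced RyR openings with an arrhythmogenic-coupling-efficiency
score far above the replication floor; exact biomarker extraction on
analytic waveforms; Ca²⁺ mass conservation (0.1% over a cycle, round-off
for the diffusion operator) and exact reversal-potential nulls; and the
population screen's strongly negative I_K1 deviation in the spontaneously
active subpopulation.

Not reproduced quantitatively (asserted at the published values and left
failing, with the measured numbers reported honestly): the spontaneous
rate is ~53 rather than 45.1 BPM; a 50% funny-current block slows the
rate by ~20% rather than <5% (the diastolic depolarization retains a
substantial I_f component); the spontaneous-mode reductions of peak
I_CaL (~7% vs 45%) and I_to (~44% vs 54%); total Ca²⁺ entry and
forward-NCX removal per cycle come out larger, not ~17–18% smaller, in
spontaneous mode, because the spontaneous cycle is longer and
background-current entry scales with cycle length; the Brugada AP-peak
delay is ~17 ms rather than 3.9 ms; the LQT2 APD50 change overshoots; a
90% NCX block produces only a ~2-fold diastolic Ca²⁺ rise, below the
3-fold overload-exclusion bound; and the central Ca²⁺ signal leads (by
~98 ms) rather than lags the peripheral signal in paced beats, a direct
consequence of the phase-locked entrainment described above.

## Protocol notes

* **Blocks**: fractional block f multiplies the target's maximum rate by
  (1−f).  Ca-overload exclusion: diastolic bulk Ca²⁺ above 3× the control
  diastolic value for ≥5 cycles.
* **Caffeine**: all relays forced open at P_o = 0.5 with I_CaL and SERCA
  zeroed; reports transient amplitude, decay constant and released SR
  content.
* **Ca-injection assay**: voltage clamp at −80 mV, Fluo-4 added, L-type
  channel held open for 10 ms (i = 0.5·(V − E_Ca)); per-shell
  first-crossing times of 220 nM versus depth.
* **NCX ramp**: a per-cycle feedback bias current drifts the diastolic
  potential from −80 toward −60 mV over 60 s; the diastolic sample is the
  MDP of each cycle.  The feedback-bias construction is ours.
* **APDR/FFR sweep**: 60 s per frequency (1…2.2 Hz), last AP analyzed,
  2× threshold stimulus; CaT amplitude is the force surrogate.
* **CPVT**: Poisson-timed forced openings (default 1 per 2 s, 20 ms,
  P_o = 1) at a randomly chosen release location, seeded; ACE is the mean
  |ΔV_m| against a paired, identically initialized control run (our
  normalization: per-ms, so a uniform 1 mV offset scores 1).
* **Database screen**: seven multipliers (I_to, I_Kr, I_K1, I_CaL, I_Na,
  SERCA, NCX) drawn independently and uniformly from 0.25–2.5× control
  (our choice of a wide literature-spread-like band); I_f and I_Ks fixed.
  Viability operationalization — paced: 1:1 capture, overshoot >0 mV, no
  Ca overload, all biomarkers computable; spontaneous: ≥3 APs with
  overshoot and cycle-length CV <10%.  The acceptance-level screen runs
  at n = 40 with shortened protocol durations (40 s runs, 15 s per sweep
  step), reporting viable fractions with Wilson binomial CIs and
  sign-level subpopulation statistics; full-scale counts depend on
  unpublished exclusion details and are not asserted.

## Biomarkers

Cycles are delimited MDP-to-MDP (boundary diastoles count when long
enough to hold an MDP); AP onset is the maximum dV/dt, and APDx runs from
onset to the interpolated x% repolarization crossing — onset-referencing
keeps spontaneous and paced APs comparable.  DDR is the maximum of a 5-ms
smoothed dV/dt between MDP and onset.  CaT decay τ is a log-linear fit
from 30% below the peak toward diastole.  The APD reference point
(onset vs stimulus) is a documented convention, not a config switch.

## Known limitations

* The spontaneous depolarization is NCX- and I_f-driven with the SR store
  cycle superimposed, rather than purely Ca-clock-led; the block
  signatures listed above quantify the gap.
* CaT amplitude is sensitive to the radial resolution (the relay
  thresholds act on per-shell local concentrations), so only APD
  convergence (≤3% at doubled shell count) is asserted; simulations at
  non-default `n_shells` are comparable to each other, not to the
  default calibration.
* The caffeine transient is smaller than the paced CaT in this
  parameterization (the store content is modest and extrusion competes
  with the forced release), unlike the complete-release picture of the
  reference experiments.
* No chamber-specific variants, no β-adrenergic signalling, no
  contraction model (CaT amplitude stands in for force), no stochastic
  channel noise outside the CPVT protocol, and no 2-D/3-D diffusion.
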