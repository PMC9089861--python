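# Methods

## Scope and design

`ca3burst` models the two principal-cell phenotypes of hippocampal CA3 —
regular-spiking (thorny) and intrinsically bursting (a-thorny) pyramidal
neurons — as reduced multicompartment conductance-based models, and
implements the downstream analyses that link their biophysics to function:
evolutionary parameter fitting against feature targets, dendritic
input-resistance and spine amplitude-ratio maps, NMDA-dependent synaptic
cooperativity, currentscape decomposition, and CTW-based entropy/mutual
information of output spike trains.  Everything is reproducible from seeds;
no binary data ships with the package.

## Morphologies

Morphologies are abstract cylinder trees (lengths, tapering diameters,
region labels); 3-D coordinates from SWC files are collapsed to path
lengths and retained only for round-tripping, since every downstream
computation depends solely on electrotonic structure.  The reduced
generator emulates the structural contrast between the phenotypes: a
20 × 20 µm soma, a 400 µm apical trunk tapering 3→1 µm, basal dendrites
(~180 µm), a two-compartment 2 × 30 µm axon stub, and apical side branches
— obliques distributed along the trunk for the thorny template, terminal
branches fanning out from the trunk's end (and no obliques) for the
a-thorny template, whose dendrites are slightly thicker.  Branch lengths
are jittered (15% SD) under a fixed seed.  Branch diameters (0.8→0.5 µm
thorny, 1.1→0.7 µm a-thorny) put distal-branch input resistance in the
hundreds of MΩ, which is the regime in which spines compartmentalize
strongly and clustered inputs can ignite NMDA-dependent nonlinearities.
Detailed reconstructions load from standard 7-column SWC; any existing axon
is replaced by the stereotypical two-section stub so axon detail does not
vary across cells.

## Channels and parameters

Eleven mechanisms: transient and persistent Na, delayed-rectifier / A-type /
M-type K, SK-type Ca-activated K, T/L/N-type Ca, Ih, and leak.  Kinetics
are parametric Hodgkin–Huxley forms — Boltzmann steady states
`x∞ = 1/(1+exp(−(V−V½)/k))` and bell-shaped time constants
`τ = τmin + τamp/(exp((V−Vτ)/k₁)+exp(−(V−Vτ)/k₂))` — with values in the
range of published hippocampal pyramidal-cell models, stated at 34 °C
(a Q10 divisor is applied if the simulation temperature differs).  The
SK gate follows submembrane calcium with a Hill function (Kd 0.6 µM,
exponent 4, τ 20 ms), so it engages only on calcium influx.  These
formulations are this package's own; they reproduce the qualitative channel
roles (spike generation, repolarization, adaptation, burst termination)
rather than any specific published rate constants, and the registry is data
so alternatives can be dropped in.

Fixed quantities: reversals Na +50, K −90, Ca +130 mV (Ih −30 mV),
Cm = 1 µF/cm², resting [Ca]i = 50 nM.  The 24 free parameters are 18
maximal conductances partitioned by channel × region (somatic / axonal /
dendritic / somatodendritic; the partition is configuration, the default
totals 18), leak reversal EL and axial resistivity Ra each split axon vs
rest, the calcium decay time constant, and the free-calcium fraction γ.
Calcium dynamics use a single 0.1 µm submembrane shell:
`d[Ca]/dt = −10⁻³ γ I_Ca/(2F·depth) − ([Ca] − 50 nM)/τ`, integrated by its
exact exponential solution per step; outward calcium current does not
deplete the shell below rest.

In spine experiments the apical fast-Na density follows
`g(x) = g_soma (0.5 + 0.5 e^{−x/100 µm})` — continuous at the soma, half
the somatic density distally.

## Numerical integration

Fixed-step semi-implicit scheme, dt = 0.025 ms by default: gates and
calcium advance by exponential Euler; voltage by backward Euler with ionic
conductances evaluated at the updated gate states, so every ohmic current
is implicit in V (the NMDA magnesium factor is the one explicit term).
The linear solve uses the Hines ordering (parents precede children):
elimination from leaves to root, back-substitution root to leaves, O(N)
per step.  Gate curves are evaluated through lookup tables of x∞(V) and
1−exp(−dt/τ(V)) on a 0.05 mV grid (linear interpolation; error ~1e−5),
which is what makes multi-minute biological runs practical on one CPU.
Spine necks attach at the parent compartment's node — NEURON's convention —
rather than center-to-center; otherwise the parent half-cylinder's axial
resistance (tens of MΩ on thin branches) would corrupt the amplitude
ratio.  Divergence (|V| > 200 mV) aborts with the offending compartment
named.  Accuracy is certified by convergence (halving dt moves every spike
of a bursting reference run by < 0.5 ms) rather than by solver identity
with any adaptive-step reference.

## Reference phenotypes

The package ships two hand-tuned parameter sets standing in for optimized
model populations.  Relative to the thorny set, the a-thorny set lowers the
potassium conductances (KDR 0.009 vs 0.015, KA 0.003 vs 0.01, KM 0.0008 vs
0.004 S/cm² somatic), raises fast and persistent sodium, halves the T-type
calcium density, slows calcium clearance roughly threefold (τ 350 vs
120 ms) and strengthens the SK pathway (0.06 vs 0.008 S/cm² somatic), and
uses the larger axial resistivity (340 vs 150 Ω·cm) measured for that cell
type.  The interplay
of fast spike currents with the slow calcium/SK variable produces bursts of
3–4 spikes at ~150–300 Hz terminated by the calcium-activated
after-hyperpolarization, with a rheobase several-fold below the thorny
cell's — the defining contrast between the phenotypes.  Burst termination
here runs through a strong free-calcium/SK pathway, i.e. a *larger*
free-calcium fraction than the thorny set; this is a known alternative
realization of the same slow–fast burst mechanism and one deliberate
departure from hand-matching every parameter trend.

Under somatic Ornstein–Uhlenbeck drive calibrated to ~5 spikes/s the two
sets separate exactly as intended: the a-thorny model fires noise-triggered
bursts (ISI CV ≈ 1.0–1.35, entropy ≈ 0.5–0.62 of the Poisson maximum),
the thorny model fires irregular single spikes (CV ≈ 0.5–0.65, entropy
near the maximum).  A property worth knowing: the burster's rate-vs-drive
curve is *non-monotone* — weak drive triggers long bursts, strong tonic
drive keeps the calcium/SK system engaged and sparsifies firing — so the
calibration brackets (per cell type, in `celltypes`) select a branch that
crosses the 5 spikes/s operating point, and the bisection accepts either
direction of monotonicity across its bracket.

## Stimuli and calibration

DC steps default to 500 ms.  EPSP-shaped currents are normalized double
exponentials (rise 1, decay 10 ms).  The OU background current uses the
exact AR(1) discretization with stationary initialization; defaults τ =
3 ms and σ = 0.3 × mean, both configurable — the literature this mimics
does not pin them, and they are the study conditions for every
information-transfer result here.  Presynaptic burst trains: burst onsets
homogeneous Poisson (2 Hz), spikes per burst uniform on {2..8} (a
documented choice; the source protocol implies variable burst length
without stating its law), within-burst gaps exponential at the intra-burst
rate; overlapping bursts merge under the earlier onset by default.
Rate calibration bisects the OU mean (σ tied at the fixed ratio) until the
measured somatic rate is within tolerance (default ±0.5 spikes/s) of the
5 spikes/s target.

## Fitting

Twelve features per DC protocol (resting Vm, AP amplitude/threshold/
half-width/rise/fall rates, ISI CV, spike count, inverse first ISI, AHP
voltage, times to first and last spike), extracted with documented
conventions: spikes are interpolated upward 0 mV crossings with a 1 ms
refractory rule; threshold is the onset of the rising phase (walking back
from the steepest upstroke point to where dV/dt < 20 V/s); half-width is
time above threshold + amplitude/2; AHP is the post-spike minimum within
50 ms; resting Vm averages the last 100 ms before stimulus onset.  Missing
features map to a large finite penalty (250 SD) so broken candidates stay
ordered.  Errors are |value − mean|/SD per feature × protocol (36
objectives); IBEA uses the additive-epsilon indicator (κ = 0.05), binary
tournament mating on the scalar fitness, SBX crossover (η = 10) and bounded
polynomial mutation (η = 20, rate 1/24), with bounds enforced by clipping
and the best-ever individual retained.  Acceptance: every feature error
< 6 SD.  The closed-loop workflow (`make_reference_targets`: targets from
ground-truth simulations, SD = 10% of |mean| floored at 0.02) recovers
accepted individuals whose f-I curves match ground truth within 20% per
amplitude at population 24 / 20 generations on a reduced morphology — the
scale used in the tests.

## Synapses and the magnesium block

AMPA 0.1/1 ms; NMDA 1/50 ms (thorny) or 1/100 ms (a-thorny), both
bi-exponential with reversal 0 mV.  The magnesium unblock is
`B(V) = 1/(1 + ([Mg]o/Kd) exp(γ(sh − V)))` with [Mg]o = 1 mM,
Kd = 9.888 mM, sh = −7.778 mV; the slope defaults to γ = 0.1 mV⁻¹ (e-fold
per 10 mV, half-unblock ≈ −31 mV, ~2% unblocked at −70 mV), inside the
canonical electro-diffusion range — shallower readings of the slope make
the block voltage-independent and steeper ones keep NMDA shut at
subthreshold voltages, and neither supports the NMDA plateau phenomena
these models exist to study.  Weight calibration scales AMPA and NMDA
jointly (ratio preserved) until a single event deflects the spine head by
~20 mV; the default ratio is NMDA:AMPA = 2:1 in peak conductance — with
1:1, passive driving-force saturation dominates and no supralinearity
occurs at any tested weight or geometry, so the NMDA-dominant ratio
standard for these synapses is the default (configurable).  With it, the
NMDA-off control sums linearly (≤ 1.05 × the linear prediction for up to
nine inputs) and both cell types cross the supralinearity margin (measured
> 1.1 × linear), the a-thorny configuration at n = 4 inputs and the thorny
at n = 6.

## Information estimation

Output trains are binarized at 4 ms (bit = 1 iff ≥ 1 spike).  The CTW
estimator implements the standard weighted recursion over all tree sources
up to depth D (default 10 bins = 40 ms) with Krichevsky–Trofimov ½
pseudo-counts and ½/½ node weighting, entirely in log₂ domain; contexts
before the sequence start are zero-padded.  The tests pin it to an
independent explicit-tree rational-arithmetic oracle exactly (≤ 1e−9 on
every string up to length 12).  Per-symbol entropy is clipped at the 1-bit
binary maximum, which the raw estimate can exceed by the O(log n/n) model
cost.  Conditional entropy H(x|y) interleaves current-and-past y with past
x in the context, (y_t, x_{t−1}, y_{t−1}, …); MI = H(x) − H(x|y), floored
at zero.  Normalized entropy divides the bits/s estimate by the Poisson
maximum r·log₂(e/(rΔt)) at the measured rate — the small-occupancy limit
of the exact per-bin Bernoulli entropy, against which it is verified.

## Synthetic data: what it does and does not show

All experiments run on generated morphologies and hand-tuned reference
parameters, so passing tests demonstrate the *mechanisms* — burst
generation, spine compartmentalization, NMDA cooperativity, the
entropy/CV signature of bursting — and the correctness of every estimator
against oracles.  They do not certify quantitative agreement with any real
reconstruction: absolute Rin, AR and rheobase values are
morphology-dependent, and the feature-target workflow substitutes
ground-truth-derived tables for experimental ones.  Real SWC files and
measured target tables drop into the same interfaces.

## Problem sizes and defaults

Default discretization 20–25 µm per compartment (~80–140 compartments with
spines); dt 0.025 ms; information experiments default to 300 s of
biological time per condition in the campaign configuration, with 120–200 s
used by the test suite and the acceptance script — at ~5 spikes/s this is
600–1000 spikes, comfortably above the few hundred the CTW estimator
needs.  OU calibration probes use 15–20 s windows.  All stochastic
components are pure functions of (parameters, seed), with named substreams
derived from one master seed.

## Known limitations

Single-shell calcium with one decay constant (no buffers or pumps); ohmic
calcium current (no GHK); no stochastic gating; spine membrane is passive;
the kinetics registry is a standard-form substitute, not a reproduction of
any specific published channel set; the CTW side-information variant is one
documented construction among several in the literature, isolated behind
`conditional_entropy_rate` so alternatives can be swapped.
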