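# Methods

## The model

Each unit in the chain stands for an ensemble of hippocampal-style time
cells, reduced to a single spikeless integrate-and-fire neuron:

    C_m dv/dt = -(I_L + I_D + I_Exc + I_Inh) + I_input + I_noise

with leak `I_L = g_L (v - E_L)`, a slowly inactivating D-type potassium
current `I_D = g_D m_d h_d^2 (v - E_K)` (fast activation gate m_d,
tau = 0.6 ms; slow inactivation gate h_d, tau = h_d_tau = 1500 ms by
default), synaptic excitation `I_Exc = (g_Exc s_pre + g_Excr s_self)(v -
E_Exc)`, and accumulated inhibition `I_Inh = N g_Inh (v - E_Inh)`, where N
counts the chain cells that have fired so far.  A threshold crossing
(v >= V_T = -50 mV) is a recorded event plus a reset (v -> v_R = -85 mV,
s -> 1); no spike waveform is synthesized.  Gate steady states are
`m_inf(v) = 1 - 1/(1 + exp((v+65)/2))` (activation, opens with
depolarization) and `h_inf(v) = 1/(1 + exp(v+65))` (inactivation, recharges
under hyperpolarization).

The timing mechanism: at rest the D-current is tonically active, and the
cell can only reach threshold under sustained excitatory drive once h_d has
decayed far enough to stop compensating the total hyperpolarizing load.
Because the load grows linearly with N while h_d decays exponentially, the
delay-to-spike grows super-linearly with N — and the slower late phase of
the exponential makes the delay increasingly sensitive to perturbations,
which is where the scalar variability comes from.

## Interpretation choices the equations force

Three published ingredients are mutually inconsistent with the printed
constants, and this package resolves them as follows (each resolution is a
design decision of this implementation, stated here openly):

1. **The input is a conductance, not a current.**  An additive current of
   amplitude 4 can never fire the cell: the leak alone at threshold is
   g_L (V_T - E_L) = 120.  The stimulus is therefore implemented as an
   excitatory conductance step, `I_input = A (v - E_Exc)` with the printed
   amplitude A = 4.  With no further adjustment this reproduces the
   published single-cell delays (~600/800/1200 ms at N = 20/40/60 within
   ±20%).

2. **The stimulus is held until the first spike.**  A 10 ms pulse leaves the
   slow D-current no time to inactivate, so it can neither produce a
   delayed spike nor start the chain wave.  The step is held from onset
   until the target cell's first spike, then released; a fixed-duration
   pulse remains available (`StimulusProtocol(duration=...)`).

3. **Ensemble-rate persistent firing and mean-field coupling.**  Literal
   self-excitation (g_Excr = 50, beta = 0.2/ms) would make a single unit
   refire every ~2 ms; the feedforward sawtooth would then average
   g_Exc * 0.82 ≈ 12 and the chain would traverse 40 cells in ~0.3 s with
   ~7 ms intervals — inconsistent with the wave's demonstrated tens-of-
   seconds range and with any dependence of wave speed on h_d_tau.  In this
   package a unit that has fired enters a *persistent-firing regime*
   (`CellState.firing`): it emits spikes at the ensemble rate
   1/persistent_period (default 16 ms, i.e. 62.5 Hz — a persistent-activity
   rate, not a single-cell burst rate), and its feedforward synaptic output
   is the asynchronous-population average of the reset-decay sawtooth,
   s̄ = (1 - exp(-beta T_p))/(beta T_p) ≈ 0.27, held while the ensemble is
   active and decaying naturally once it is silenced.  The resulting mean
   feedforward drive g_Exc s̄ ≈ 4.1 coincides with the amplitude-4 input
   step of the single-cell protocol, which makes that protocol an exact
   single-cell picture of chain transmission.  Single-unit sawtooth
   coupling is retained (`NetworkConfig(coupling="sawtooth")`); it
   quantizes delays to the emission grid and is not the default.

   `persistent_period` is the one constant of this reduction with no
   printed value.  It was fixed once by a small viability study (chain
   completion fraction, CV flatness, SD-mean linearity at the published
   noise levels) around the drive-matching anchor above, and not revisited.

Further choices: v_R = -85 mV with v_init = -75 mV (the two published
statements conflict; both are configurable); h_d_tau is a duration in ms;
all printed numerals are used verbatim as one consistent arbitrary-unit
system (mV, ms) with no unit conversion.

## Chain bookkeeping

N increments once per cell, at its first spike (otherwise persistent firing
would make N explode); the same event silences the predecessor: its
persistent-firing flag is cleared, its synaptic variable decays naturally
from s̄, and it emits no further spikes.  The slow inhibitory cells of the
architecture are not simulated as dynamical units; their published
reduction N g_Inh (v - E_Inh) is used directly.  Cell indices are 1-based
("TC 30", "TC 40").  A trial ends at the target cell's first spike, at the
horizon, or when no new cell has fired for `stall_window` (10 s) — wave
death, reported as data (`SpikeRecord.status == "stalled"`), never raised.

## Noise model

Two sources, both seeded from one base seed per batch (trial i uses
base_seed + i for the conductance draws and a decoupled offset seed for the
bombardment, so any trial is reproducible in isolation):

* **Conductance jitter** — per trial, g_D ~ Normal(4, 1) and
  g_Exc ~ Normal(15, 5), truncated at 0.  The default draw is shared by all
  cells of the trial (`draw_mode="per_trial"`): a chain-wide excitability
  state.  Independent per-cell draws are available
  (`draw_mode="per_cell"`), but at the published SDs they place at least
  one cell below the wave-propagation boundary in essentially every
  60-cell trial (the critical sustained drive rises from ~2.4 at N=0 to
  ~3.6 at N=60, while per-cell drive scatter is ±1.35), so per-cell mode is
  useful only for short chains or reduced SDs.

* **Poisson bombardment** — each cell receives n_presyn = 100 independent
  50 Hz Poisson trains; each event sets that synapse's variable to 1, all
  decay at beta_n = 0.1/ms, and the current is
  `I_noise = (g_noise/n_presyn) * sum_n s_n * (v - E_Exc)`.  The 1/n_presyn
  normalization keeps the mean noise conductance (~g_noise/3) perturbative;
  without it the summed conductance (~33) would fire every cell
  unconditionally.  The bombardment has a depolarizing mean (it speeds the
  wave) plus fluctuations with ~10 ms correlation time.

The default statistics condition uses both sources; the g_noise sweep uses
the bombardment alone (conductance SDs zeroed), isolating the non-trivial
route to scalar variability.

## What the trial generator emulates — and what passing tests show

With shared per-trial draws, the linear growth of SD with mean across cells
is partly structural (a trial that draws a slow chain is slow everywhere),
so the flat CV of the default condition should be read as the model
operating coherently under its published noise, not as a parameter-free
prediction.  The non-trivial content is carried by (a) the single-cell
delay curve and its super-linear growth with N, (b) the Poisson-only
condition, where variability is independent across cells and the D-current
sensitivity amplification must fight the 1/sqrt(k) compression, and (c) the
null models.  On (b) the reconstruction is honest about a shortfall: CV at
a matched cell index does increase with g_noise, but the curves are not
flat — per-interval noise independence across disjoint time windows forces
CV to fall unless per-interval variance grows ∝ (elapsed time × interval),
and the measured sensitivity growth at the operating margin is weaker than
that.  The corresponding acceptance test asserts the published direction
and is expected to fail on the flatness half; see the test suite.

No in-vivo data enters anywhere; nothing is fit to recordings.  The
synthetic records exercise the statistics layer with known ground truth
(e.g. spike time of cell k ~ Normal(100k, 10k) must yield a flat CV of
0.1).

## Null models

`sum_of_normals_null(n, mu, sd)` returns the closed form (n mu, sqrt(n) sd,
sd/(mu sqrt(n))): summing independent identical intervals compresses CV by
1/sqrt(n).  `increasing_isi_null(means, cv)` Monte-Carlos cumulative sums
of independent Normal(mu_k, cv*mu_k) intervals and carries its own closed
form cv*sqrt(sum mu^2)/sum mu: even per-interval scalar noise with growing
means still compresses.  The simulator's flat CV therefore requires the
correlated mechanism, not just lengthening intervals.

## Numerics

Fixed-step integration at dt = 0.05 ms: gates advance by exact exponential
relaxation toward their frozen-voltage targets (the stiff pair
m_d_tau = 0.6 ms vs h_d_tau = 1500 ms makes explicit gate updates
wasteful), the synaptic variable by its exact decay factor, the voltage by
an explicit Euler step.  A spike is registered at the first step end with
v >= V_T; there is no sub-step interpolation.  Halving dt moves the
single-cell delays and mean-field chain spike times by well under 1 ms
(asserted in tests; the sawtooth variant converges only to within one
emission period, since near-tangent crossings can hop the ripple grid).
Identical state, inputs and seeds give bit-identical trajectories; the
hot loops are compiled with numba, and the pure-python reference
implementation in `model_core` is cross-checked against them step for step.

Degenerate inputs: g_Exc = 0 leaves only the stimulated cell firing;
g_Inh = 0 produces near-constant intervals; zero noise collapses repeated
trials to bit-identical records.  Gates and synaptic variables remain in
[0, 1] for any admissible input (property-tested).

## Study sizes

The default suite runs the published protocols at 50 trials × 60 cells,
both for the main statistics and for each sweep value (the published study
used 200 trials; the asserted properties are stable in the trial count and
200 is available via `--trials`), with flatness judged over the last half
of the chain (cells 31–60).  Shorter chains truncate the CV convergence of
the fast h_d_tau = 500 condition and are not used for sweeps.  Stalled or
horizon-hit trials are excluded from statistics with their count reported
in every manifest — at the published noise levels roughly a fifth to a
third of trials stall, which is itself a property of operating a
near-critical wave under heavy parameter noise.

## Known limitations

* The converged CV level of the default condition (~1.3) is large —
  first-spike-time SDs are comparable to their means.  The published study
  does not print its converged CV, so only flatness and the robustness
  directions are comparable, and they are what the tests assert.
* The g_D sweep's effect on interval length runs opposite to the published
  verbal account (larger g_D lengthens delays here: escape requires h_d to
  fall to sqrt(margin/(g_D m (v - E_K))), which is smaller — i.e. later —
  for larger g_D).  The CV-level direction across the g_D sweep
  nevertheless matches (larger g_D, smaller CV).
* Poisson-only CV curves are not flat (see above).
* The persistent-firing regime abstracts the within-ensemble attractor; it
  does not model the ensemble's internal spike statistics, and the raster's
  within-episode spikes are placed on the regular ensemble period.
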