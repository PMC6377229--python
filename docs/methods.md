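# Model and methods

`dscircuit` implements a conductance-based model of a direction-selective
retinal ganglion cell (DSGC) driven by the starburst-amacrine/bipolar-cell
synaptic circuit, together with the analysis statistics used to quantify
direction selectivity in electrophysiological recordings, and a
synthetic-recording generator for estimator validation. This note documents
the model, its assumptions, the parameters that matter, and the design
choices made where the design was genuinely open.

## Circuit model

**Geometry.** The cell is a planar dendritic arbor: a spherical soma (15 µm)
at the origin with `n_primary = 6` trunks that bifurcate through
`branch_order = 4` levels out to a nominal dendritic-field radius of 150 µm.
The arbor is procedural and seeded, standing in for a reconstructed
morphology: the mechanisms under study depend on where synapses sit in the
plane, not on the exact branch geometry. Branches of the final order are
single *terminal dendrite* compartments (leaves of the cable tree); all
earlier branches are chains of ~15 µm *primary dendrite* segments.

**Synapses.** Tri-receptor synapses (AMPA, nicotinic ACh, GABA_A) are placed
every ~10 µm along terminal branches (~172 sites on the default arbor). Each
receptor is a bi-exponential conductance normalized so one release event
peaks at its nominal conductance:

| receptor  | rise (ms) | decay (ms) | peak g (nS) | reversal (mV) |
|-----------|-----------|------------|-------------|----------------|
| AMPA      | 0.5       | 40         | 2.5         | 0              |
| nicotinic | 1         | 25         | 2.5         | 0              |
| GABA_A    | 0.5       | 60         | 10          | −60            |

The kinetics are *effective* macroscopic time courses, not miniature-event
fits: the AMPA decay subsumes the sustained bipolar drive (including its
NMDA component), and the GABA_A decay reflects the slow IPSC time course of
DSGCs. They were calibrated against the model's qualitative targets
(direction-selective spiking with null-direction suppression at standard
velocities, leak-through only at the lowest velocity, sustained firing
during slow sweeps). The summed peak-conductance E:I ratio of the defaults
is 1:2; `apply_ei_ratio` re-imposes that ratio exactly for the fixed-ratio
velocity experiment.

**Directional tuning.** A moving bar (leading edge perpendicular to motion)
activates each synapse when the edge crosses the synapse position, advanced
by a receptive-field *spatial offset* toward the stimulus entry side
(activation time = crossing − offset/velocity). Release is one Bernoulli
draw per site, transmitter and sweep. Release probability and offset follow
sigmoids of the angular distance `a` from the preferred axis (0° preferred,
180° null):

    Pr(a)     = pPr + (nPr − pPr) · (1 − 0.98 / (1 + e^((a − 91.0)/25.0)))
    offset(a) = pOff − (pOff − nOff) · (1 − 0.98 / (1 + e^((a − 74.69)/24.36)))

Defaults: glutamate Pr 0.5, no offset; ACh Pr 0.5, isotropic 50 µm offset
(at 1 mm/s a 50 ms cholinergic lead); GABA pPr 0.012 → nPr 0.5 and
pOff 0 → nOff 50 µm. Three switches map onto the experimental
manipulations: *non-DS starburst* clamps GABA Pr at 0.5; *offsets off*
zeroes every spatial offset (all receptive fields co-extensive — this is the
amplitude-asymmetry-only model, in which nothing can precede the
glutamatergic entry and early responses disappear); *cholinergic off* zeroes
the nicotinic conductance.

## Biophysics

Passive: 1 µF/cm², 100 Ωcm, leak reversing at −60 mV with a default density
of 0.05 mS/cm² (membrane time constant 20 ms). Active conductances per
region (mS/cm², soma/primary/terminal): Na 150/150/30, K rectifier
70/70/35, slow delayed K 3/0.8/0.4. Rate functions are canonical
squid-axon kinetics with two calibrations, both needed because the original
model's channel mechanism specifies densities but the rate functions were
open choices here:

* a **+13 mV global gate shift** so the complement's zero-current point sits
  near the leak reversal — the cell rests at ≈ −64 mV (squid kinetics at
  these densities would rest at −73 mV, below the GABA_A reversal, turning
  inhibition excitatory) and spikes from ≈ −42 mV;
* the **K-rectifier activation sits 5 mV right of the squid values**: at the
  printed Na:K density ratio the unshifted rectifier produces exactly one
  onset spike followed by a depolarized plateau; the shift restores tonic
  firing (~20–100 Hz over the relevant drive range).

The slow delayed rectifier is a first-order non-inactivating K conductance
(half-activation −35 mV on the shifted axis, τ = 50 ms) providing spike
adaptation. Channel/membrane noise is an additive Ornstein–Uhlenbeck
current per compartment (τ 5 ms, SD 0.005 mA/cm² scaled by area), calibrated
to zero spontaneous firing and a bar-response spike-count CV of ~15–20%;
a hard off switch gives deterministic runs.

**Integration.** Fixed-step (dt = 0.025 ms) backward-Euler voltage solve on
the cable tree (Hines elimination, O(N) per step, numba-compiled) with
exponential-Euler gating. Halving dt changes bar-evoked spike counts by at
most one spike and clamp-current peaks by <2%.

**Recording modes.** Current clamp detects somatic spikes by upward
crossing of −20 mV with a 1 ms lockout; dendrites are active, so distal
input is relayed via dendritic spikes. Voltage clamp blocks Na/K and holds
the *entire* cell at the command potential (an ideal space clamp). The
idealization is deliberate: with only the soma clamped, dendritic
excitatory conductances produce space-clamp artifacts at 0 mV that swamp
the sparse preferred-direction GABA signal, whereas the ideal clamp makes
the driving-force nulls exact — holding at the inhibitory reversal isolates
the EPSC and holding at 0 mV isolates the IPSC, which is the premise of the
isolation protocol. A useful corollary: the clamp current is linear in
release events, so an N-trial average is obtained from a single simulation
fed all N schedules (divided by N).

## Analysis statistics

* **Firing rate**: spike trains convolved with a unit-area Gaussian kernel
  (σ = 25 ms); the trace integral equals the spike count.
* **DSI / preferred angle**: magnitude of the response-weighted vector sum
  over stimulus directions divided by summed responses (0 symmetric, 1
  single-direction); the angle is the resultant's direction. Reported both
  on trial-summed responses (headline) and per trial (variability; circular
  SD for angles).
* **Onset latency**: a least-squares line through all samples between the
  20% and 80% amplitude crossings of the rise, extrapolated back to the
  baseline (mean of a pre-stimulus window). Amplitude is measured
  baseline-to-first-peak by default (`anchor="first_peak"`), so slow late
  components cannot contaminate the fit of an early component. For
  ensemble bar-sweep currents — slow ramps with release-noise bumps and no
  clean first peak — two variants exist: `anchor="rise"` locates the
  crossing levels by *first* upward crossing referenced to the window
  maximum, and `t_max_ms` confines the analysis to the initial response.
  The all-samples least-squares choice (rather than a two-point fit) and
  the first-crossing tie-break for non-monotone rises are deliberate.
* **E/I temporal offset**: inhibitory minus excitatory onset; positive
  when excitation leads. Negative offsets are clamped to zero before any
  DSI computation on offsets.
* **Phase tuning**: trials aligned to the time the stimulus enters the
  glutamatergic receptive field (earliest offset-free synapse crossing);
  the *early* window is the 50 ms before entry, the *peak* window is 50 ms
  centred on the peak of the trial-averaged smoothed rate in the preferred
  direction (the placement rule for "close to the peak" was open;
  centred-on-peak is used).

**The bar-sweep E/I offset protocol** (`measure_ei_offset`) positions the
bar to leave a 200 ms quiet baseline, averages EPSC/IPSC traces over many
release seeds (default 200; the preferred-direction IPSC has only ~6 release
events per sweep at Pr 0.034, so trace averaging — which recovers the
expected conductance profile — is essential), smooths with a 10 ms
zero-phase Gaussian, and fits each current over its *own* initial response
(2%-of-max crossing + 50 ms). Confining both fits to the same early-rise
geometry makes their back-extrapolation biases cancel in the difference;
this was validated against an analytic expected-trace oracle with known
activation feet (46.8 ms geometric E/I difference at 1 mm/s), which
whole-trace fits missed by ~+17 ms (the excitatory fit window was
contaminated by the later glutamatergic rise).

## Synthetic-recording generator

`synthetic_data` produces EPSC/IPSC pairs and spike trains with configured
ground truth, independent of the simulator. Onsets are tied to the bar
geometry (excitation advanced isotropically by 50 µm, inhibition by the
direction-tuned offset; onset differences are exactly offset/velocity);
inhibition amplitude follows the same sigmoid shape as the release
probability, renormalized so the preferred/null endpoints are met exactly.
Spike trains are inhomogeneous Poisson draws from a piecewise-constant
rectified excitation-minus-inhibition rate (gain 100 Hz per drive unit;
rectification threshold 0), so early-window rates depend only on the offset
mechanism and sustained rates only on the amplitude mechanism, and expected
counts have a closed form. The generator assumes trial independence, white
noise and noise-free onsets — it validates estimators, not biological
variability structure; passing recovery tests demonstrates estimator
correctness, not realism of the circuit model.

## Degenerate inputs and tie-breaks

All-zero direction series raise an explicit no-response error rather than
0/0; traces without a qualifying peak raise the same error; terminal
branches shorter than the synapse spacing still receive one site; a branch
order of 1 yields unbranched primaries that are all terminal; bar start
positions inside the arbor (plus the largest offset) are rejected.

## Known limitations

* The arbor is planar and procedural; ON/OFF stratification, the
  photoreceptor/bipolar front end, NMDA receptors, gap junctions and
  paracrine ACh diffusion are all outside scope (cholinergic transmission
  uses fast kinetics with a fixed spatial offset).
* The ideal space clamp removes the voltage-clamp errors that complicate
  the corresponding experiments; simulated and experimental current
  amplitudes are therefore not directly comparable.
* The amplitude mechanism in this parameterization suppresses the
  peak-phase null response essentially completely, so peak-window tuning
  stays as sharp as (or sharper than) early-window tuning — unlike
  recordings from real DSGCs, where residual null-phase responses broaden
  the peak tuning and make the early phase the more sharply tuned one.
  Softening inhibition enough to broaden the peak phase (lower GABA
  conductance, faster decay, depolarized reversal) destroyed the
  null-direction suppression and the velocity-sweep behaviour, which are
  more central model properties, so the discrepancy is documented rather
  than patched.
* Rate-function details (gate shifts, slow-K τ), synaptic conductances and
  the noise magnitude are calibrated substitutions, not measured values;
  conclusions should rest on the qualitative mechanism structure, not on
  absolute spike counts or current amplitudes.

## Problem sizes used by the test and acceptance protocols

Mechanism dissection runs 8 directions × 4 trials × 3 settings and the
velocity sweep {150, 300, 600, 1200, 2400} µm/s × 8 directions × 3 trials,
both with membrane noise on; the E/I offset protocol averages 100–200
release seeds (one merged clamp simulation per holding potential). These
sizes give stable statistics for every quantity checked while keeping a
full run in the minutes range on one CPU.
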