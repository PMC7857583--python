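# Methods

`hhlsim` simulates the sound-evoked activity of a population of type I
spiral ganglion neuron (SGN) peripheral axons and the compound action
potential (CAP) they generate, in order to contrast two mechanisms of
hidden hearing loss: loss of inner-hair-cell (IHC) synapses
(*synaptopathy*, a binary per-fiber mask) and disruption of the
myelination geometry at the fiber terminal (*myelinopathy*, lengthening
and/or randomizing the unmyelinated terminal segment L_u and the
heminode L_h).

## Pipeline

A pure tone (frequency, dB SPL, duration) is processed per cochlear
channel and fiber class:

1. **Middle ear** — second-order Butterworth bandpass (corners 12.5 and
   22 kHz as configured; note the 10 kHz standard stimulus lies below
   the lower corner and is correspondingly attenuated — the corner
   values are kept as configured rather than "fixed", and the overall
   transduction gain absorbs the attenuation).
2. **Basilar membrane** — a dual-resonance nonlinear (DRNL) channel per
   best frequency (BF): a broad linear gammatone path (cascade length
   3/3/1 for LT/MT/HT fiber classes) plus a nonlinear path
   (gammatone cascade, broken-stick compression
   `y = sign(x) min(a|x|, b|x|^c)`, gammatone cascade).  21 BFs span
   5.6-32 kHz on the Greenwood map.
3. **IHC transduction** — cilia displacement (first-order lag of BM
   velocity), three-state Boltzmann apical conductance, passive
   basolateral membrane, m^3-gated calcium current low-pass filtered
   into a near-synapse calcium concentration.
4. **Release** — per-vesicle hazard `k(t) = max(([Ca]^3 - thr^3) z, 0)`
   feeding a three-pool ribbon synapse (quantal immediate store of
   capacity M = 10, continuous cleft and reprocessing stores).  Release
   events are sampled stochastically per synapse per trial
   (`release_model: pools`), or as an inhomogeneous Poisson process
   from the expected rate q(t)k(t) (`release_model: poisson`).
5. **SGN fiber** — each release event applies a double-exponential
   synaptic conductance (peak A = 0.12 nS, tau 0.1/0.3 ms, reversal
   0 mV) at the start of the unmyelinated segment of a compartmental
   Hodgkin-Huxley cable (Table of constants in
   `cable/morphology.py`); spikes are upward -20 mV crossings at the
   heminode center with a 0.7 ms dead time.
6. **CAP** — every spike is convolved with the unitary extracellular
   response U(t) (damped 0.994 kHz sinusoid, 0.16 uV scale, support
   [-0.215, 2.785] ms; leading lobe negative) and summed; 50 trial
   CAPs are averaged before reading amplitude |p - b|, latency
   t_p - t_onset and width 2|t_p - t_w|.

## Numerical scheme

The cable PDE is advanced fully implicitly (backward Euler, 5 us step):
per step the gating variables are updated by their exact exponential
(Rush-Larsen) solution at the pre-step voltage, ionic and synaptic
currents are then linear in the unknown voltage, and the resulting
tridiagonal system is solved by the Thomas algorithm.  This is
validated against a dense matrix-exponential oracle on a 3-compartment
passive cable (0.1%), against analytic steady-state cable attenuation
exp(-x/lambda) (2%), and by time-step and mesh refinement (spike times
shift < 10 us when halving dt or dx).

Spatial resolution: <= 1 um compartments in the unmyelinated segment
(at 2 um the single-release spike-threshold scan in L_u is off by one
0.1 um grid step), <= 10 um in myelin; heminode and nodes are single
1-um compartments.  Axial coupling sums half-compartment resistances
computed from the local diameter.

The IHC chain uses an explicit first-order update on the same 5 us
grid (fastest time constant 0.1 ms).  Quantal transitions use exact
per-vesicle exponential hazards `1 - exp(-rate dt)`, so the onset
hazard may exceed 1/dt without any step-size restriction.

Randomness: each (master seed, trial, synapse) triple seeds an
independent stream, so changing the population composition never
perturbs other fibers' draws, and every result is a pure function of
(configuration, master seed).

## Synaptic event normalization

The literature form of the double-exponential event current carries a
printed prefactor 0.39 whose literal reading gives a peak conductance
of ~0.15 A ~= 0.018 nS — far below the single-event spike threshold of
this fiber (no L_u value would ever spike).  The package therefore
normalizes the waveform so its peak conductance equals A (0.12 nS
default), which reproduces the documented single-release behavior: one
release yields exactly one spike on a normal fiber, spike failure
begins at L_u = 11.6 um, and the critical L_u grows with A
(10.4 / 11.6 / 12.8 / 13.9 um at 0.11-0.14 nS).  The literal prefactor
remains available (`SynapticPulse(norm="printed")`).  At A = 0.10 nS
the model's single-event threshold is not reached even at the control
length; the monotone growth of the critical length with A is therefore
demonstrated from 0.11 nS upward.

## Conduction velocity

With the tabulated constants the 215-um fiber spans only ~0.2
electrotonic length constants of its myelinated run, so the action
potential peaks are near-simultaneous along the fiber and peak-time
differences between nodes measure local loading, not propagation
(~50 m/s, and not monotone in distance).  The package therefore times
the arrival of the AP *foot* — the first upward crossing of
rest + 18 mV — between the centers of nodes 1 and 4; this front
propagates at 3.2 m/s, in the measured 3-5 m/s band for these axons,
and slows monotonically with axial resistance.  The peak-based reading
remains selectable (`method="peak"`).

## Front-end parameterization and calibration

`src/hhlsim/data/frontend_params.yaml` is the single source of truth.
Constants that are not tabulated for this exact chain are adopted from
the guinea-pig middle-ear/DRNL/IHC model family (Boltzmann offsets,
IHC membrane constants, pool rates).  Four quantities are explicit
calibration constants, fixed once against the *defining class
behaviors* of the three fiber types — never against CAP outcomes:

- `z` (release-rate scale): set so the LT spontaneous release rate is
  18.5 spikes/s, the low end of the LT class range (18-100 sp/s).  The
  low end is chosen because the spontaneous hazard also scales the
  driven hazard, and the class definition is the only printed
  constraint on it.
- `ca_thr` per class: set from the MT (0.5-18 sp/s; target 0.8) and HT
  (< 0.5 sp/s; target 0.015) spontaneous ranges; LT releases
  spontaneously with zero threshold.
- cilia gain: bisected so the LT sustained calcium drive at 30 dB SPL
  reaches the hazard (~100/s per vesicle) that saturates vesicle
  turnover — LT fibers "reach maximum discharge within ~30 dB" because
  release becomes replenishment-limited, not because transduction
  saturates.
- DRNL bandwidths: 0.09 BF (ERB scale), which fixes both tuning width
  and the cochlear group delay.

With these fixed, the rate-intensity profiles come out as defined
(LT saturating by 30 dB at ~350 sp/s, MT intermediate, HT threshold
near 20 dB with the widest dynamic range), and the population-level
CAP properties are *emergent*: control amplitude ~65 uV at 70 dB,
control latency ~1.45 ms at 80 dB, myelinopathy amplitude drops of
~60% (homogeneous L_u = 15 um) and ~50% (heterogeneous L_u in
[10, 20] um) with latency increases, synaptopathy drops of ~30%
(random third) and ~10% (all HT) with unchanged latencies, and
per-release spike probabilities > 40% for subcritical L_u versus ~20%
for the heterogeneous population.

The optional threshold modification (`s1_threshold_mod`) zeroes HT
drive below 30 dB and MT drive below 15 dB to sharpen class threshold
separation; it is off by default.

## Scenario battery

Registered scenarios: control; homogeneous L_u in {11, 15, 20} um and
L_h in {2, 6} um; heterogeneous L_u ~ U[10, 20] um and L_h ~ U[1, 6]
um; HT and random-third synaptopathy; and the combined cases
1 = HT synaptopathy, 2 = heterogeneous L_u, 3 = 1 + 2,
4 = heterogeneous L_u and L_h (the L_h range [1, 6] um matches the
largest homogeneous L_h simulated).  Myelinopathy is applied before
synaptopathy; lesions mutate fiber specs and never remove them.  Under
the default channel-scaling convention, lengthening L_u keeps channel
density constant and lengthening L_h keeps channel number constant;
`convention="reversed"` swaps both assumptions.

## Problem sizes

The CAP is a plain sum over fibers, so a uniform tonotopic subsample
rescaled by its sampling factor estimates the full 6300-fiber waveform
without bias.  The package's desk-scale defaults are 16 fibers per
type per BF (1008 fibers, x6.25 rescaling) with 32 trials for CAP
endpoints, and 4 per type with 10 trials for spike-probability
endpoints; the test suite uses smaller subsamples.  Full-size runs
(100 per type, 50 trials) are a CLI flag away and change only sampling
noise.

## What the synthetic conditions do and do not show

The generator *is* the study design: pure tones at a single frequency,
a fixed tonotopic span, three discrete fiber classes, one private
synapse per fiber, binary synapse loss, and geometric myelin lesions.
Passing tests therefore show that the implemented mechanisms produce
the documented population signatures under these idealized conditions;
they do not speak to real cochlear heterogeneity (continuous
spontaneous-rate distributions, efferent feedback, outer-hair-cell
involvement, partial synapse damage) or to far-field ABR head-volume
conduction (the computed CAP is treated as ABR wave 1).

## Known limitations

- The near-critical single-release delay grows only to ~0.6 ms before
  failure (the membrane time constant of the terminal is 85 us), so
  myelinopathy latency shifts, while robustly positive, sit at the low
  end of their documented ranges.
- Welch two-sample tests stand in for the unnamed significance test
  behind published group comparisons and are labeled as such in
  reports.
- HT fibers saturate by ~60-70 dB rather than growing strictly
  linearly to 80 dB; class ordering and thresholds are preserved.
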