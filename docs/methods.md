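# Methods

## Model

`prfield` simulates a reduced hippocampal CA3 pyramidal neuron exposed to a
weak sinusoidal extracellular electric field. The cell is the classic
two-compartment reduction: a soma carrying the fast spiking currents
(transient Na⁺ with instantaneous activation m∞(Vs), delayed-rectifier K⁺,
leak) electrically coupled, with conductance g_c, to a dendrite carrying the
slow currents (high-threshold Ca²⁺, the calcium- and voltage-dependent fast
K⁺ current K_C, the slow calcium-activated afterhyperpolarisation current
K_AHP, leak, and NMDA/AMPA synaptic currents). Dendritic calcium integrates
the Ca²⁺ current and decays first-order; the K_C current is additionally
scaled by the saturating factor χ(Ca) = min(Ca/250, 1).

All voltages live in a frame referenced to −60 mV, so rest sits near 0 mV;
nothing in the package converts to absolute millivolts. Units are mV, ms,
mS/cm², µA/cm², µF/cm²; extracellular resistances are MΩ, loop currents nA.

Membrane equations (p = somatic fraction of membrane area):

    Cm dVs/dt = −Is,leak − I_Na − I_KDR + I_DS,in/p + Is/p
    Cm dVd/dt = −Id,leak − I_Ca − I_KAHP − I_KC − I_syn − I_DS,in/(1−p) + Id/(1−p)

The only nonstandard term is the coupling current

    I_DS,in = g_c · (Vd + V_DS,out − Vs),

where V_DS,out is the instantaneous voltage across the *extracellular*
dendrite–soma resistance, supplied by the circuit described next. With
V_DS,out = 0 the model reduces exactly to the isolated two-compartment cell
(this reduction is enforced by a test against an independently coded
integrator).

### Rate functions

The gating kinetics are the original Pinsky–Rinzel rate functions in the
−60 mV frame (α_m = 0.32(13.1−Vs)/(exp((13.1−Vs)/4)−1),
β_h = 4/(1+exp((40−Vs)/5)), and so on). Two published renderings of these
expressions circulate with flipped signs inside α_m and β_h; those variants
put Na⁺ inactivation at h∞(0) ≈ 0.08 at rest and yield a cell that cannot
fire at all, so this package uses the original forms (h∞(0) ≈ 0.996, the
cell fires repetitive spikes under the default 0.7 µA/cm² dendritic drive).
Expressions of the form k·x/(exp(x/b)−1) have a removable singularity at
x = 0; they are evaluated through `expm1` with a series fallback inside
|x/b| < 1e−9, so α_n(35.1) = 0.08 exactly in the limit sense, α_m(13.1) =
1.28, β_m(40.1) = 1.4, β_s(51.1) = 0.1.

The K_C rate functions take the standard piecewise form with the branch
split at Vd = 50 mV; α_c is continuous across the split and β_c vanishes
above it.

### Synapse

The NMDA/AMPA gates are driven by a Heaviside step on the presynaptic
somatic voltage (thresholds 10 and 20 mV, decay constants 150 and 2 ms).
The model is a single cell, so the presynaptic sum collapses to the cell's
own soma (`synapse_mode="self"`, the default): the neuron recurrently
excites its own dendrite, which is the natural single-neuron reading of the
synaptic equations. `synapse_mode="off"` ablates the synaptic current
entirely for comparison; in the regimes explored here the two differ only
modestly (≲2% in mean rate under the default drive).

## Extracellular circuit

The extracellular medium between dendrite and soma is a purely resistive
two-loop network: intracellular dendro-somatic resistance
R_DS,in = 1/(g_c·Area) ≈ 79.4 MΩ, extracellular counterpart R_DS,out, and
terminal resistors R_TD = R_SG = R_DS,out/2 connecting a sinusoidal source
V_E(t) = A·sin(2πft) to the dendrite node and the soma node to ground.
Capacitive components of the medium are neglected (quasi-static
approximation at ≤100 Hz), so the network is solved algebraically at every
derivative evaluation. The two-loop Kirchhoff system

    i1(R_DS,in + R_DS,out) + i2·R_DS,out = Vs − Vd
    i1·R_DS,out + i2(R_TD + R_SG + R_DS,out) = V_E

yields V_DS,out = (i1 + i2)·R_DS,out, equal in closed form to

    V_DS,out = (R_DS,out·(Vs − Vd) + R_DS,in·V_E) / (2·R_DS,in + R_DS,out).

The simulator uses the closed form; a test verifies it against the generic
2×2 linear solve to 1e−10 over 1000 random draws. The first Kirchhoff
right-hand side is Vs − Vd exactly as the loop equations are written — no
sign adjustment is applied anywhere.

R_DS,out is set either directly in MΩ (the 8–12 MΩ sweeps; the ratio
r = R_DS,out/R_DS,in is back-computed for reporting) or from extracellular
potassium through r = 0.1 + ([K⁺]_o − 3.5 mM)·0.01, which maps the
physiological 3.5–8.5 mM span onto r ∈ [0.1, 0.15], i.e. roughly 8–12 MΩ.

### A structural caveat on R_out sensitivity

An analysis worth recording: in this network the field-induced part of
V_DS,out is V_E·R_DS,in/(2R_DS,in + R_DS,out) ≈ V_E/2, varying by only
about −2% as R_out goes from 8 to 12 MΩ. The membrane path between the two
extracellular nodes presents ~GΩ impedance below 100 Hz, so the
extracellular divider is essentially unloaded and R_out-independent; the
feedback term R_DS,out·(Vs−Vd)/(2R_DS,in+R_DS,out) grows with R_out but
only modulates the effective inter-compartment coupling by ~2%. As a
consequence, quantities that depend on a *strong* R_out sensitivity of the
field drive (large rate differences between 8 and 12 MΩ at fixed amplitude)
are structurally muted in this circuit: reference values derived from
implementations with a much stronger effective R_out leverage will not be
matched quantitatively, and the acceptance checks report whatever the
equations actually produce. No unpublished coupling variant was introduced
to compensate.

## Numerical protocol

Integration uses SciPy's BDF stiff solver with rel_tol 1e−6, abs_tol 1e−8
and a 0.5 ms maximum step, sampled on a uniform 0.01 ms grid over
0–5000 ms (defaults; all configurable). The Heaviside synaptic drive makes
the right-hand side discontinuous; no event location is used — the bounded
step keeps the induced error small, and halving the tolerances changes the
analysis-window mean rate by well under 2% (enforced by a test). The state
order is fixed: (Vs, Vd, h, n, s, c, q, Ca, Si, Wi).

Initial conditions are not part of the published protocol; the package
starts from a deterministic rest state — Vs = Vd = 0, gates at their
steady state for 0 mV (q at its steady state for the initial calcium 0.2),
synaptic weights 0 — and discards the first 1000 ms as burn-in, which is
ample for the ~1 s slowest relaxation (the q gate). Every component is
overridable. Runs are bitwise deterministic.

Sampled gate series may exit [0, 1] only within interpolation error
(tolerance 1e−6); larger excursions raise an integration error rather than
being silently clipped.

## Spike analysis

Spikes are detected on the somatic voltage in the half-open window
[burn_in, t_end): local maxima above min + 0.5·(max − min) of the window's
voltage range, with prominence ≥ 0.25·range and a 3 ms minimum inter-peak
interval (the higher of any closer pair wins). Fractional thresholds make
detection independent of the voltage-frame offset; both fractions and the
interval are configurable. Bursts are counted spike by spike, subject only
to the 3 ms rule. The mean firing rate is the count divided by the window
length; the phase-locking ratio is that rate divided by the applied field
frequency.

The synthetic-trace generator (`make_synthetic_trace`) exists so the
analysis layer can be validated without the simulator: Gaussian spike
templates (~2 ms footprint, 100 mV amplitude by default) on a flat
baseline plus seeded white noise, with ground-truth times attached. It
emulates the amplitude and width of somatic action potentials but none of
the biophysics — no bursts, no adaptation, no field coupling — so passing
detection tests on it demonstrates correctness of the peak-finding logic,
not robustness to every waveform the model can produce. Detection is exact
(recall = precision = 1) on these fixtures down to 20:1
amplitude-to-noise.

## Sweeps

The sweep engine runs one simulation + spike analysis per cell of a one- or
two-axis grid over field amplitude, field frequency, R_out, [K⁺]_o, V_K or
the dendritic drive I_d. Cells are content-addressed by a SHA-256 hash of
the fully resolved configuration, so an interrupted or repeated sweep
re-simulates nothing that is already cached; solver failures are recorded
as missing cells (never interpolated) without aborting the sweep. Surfaces
are exported as long-format CSV plus a JSON run manifest.

Default grids, chosen once for the study protocol: amplitude 0–200 mV in
10 mV steps; frequency 5–100 Hz in 5 Hz steps (5–60 Hz for the V_K
experiments); R_out {8, 9, 10, 11, 12} MΩ; V_K {−90, −80, −70, −50, −40,
−20} mV (model frame — the same frame as the default −38.56). Non-swept
parameters default to R_out = 10 MΩ for V_K experiments, V_K = −38.56 mV
for R_out experiments, f = 10 Hz for amplitude scans, A = 100 mV for
frequency scans. Published mean values over such scans are grid-dependent;
the grids above are what the acceptance script uses.

The V_K values are interpreted in the model voltage frame throughout. It
is worth noting that the default V_K = −38.56 is, to three figures, the
Nernst potential of potassium at [K⁺]_o = 3.5 mM / [K⁺]_i = 140 mM
expressed in this frame.

## Known limitations

- Single cell only: no network coupling, no channel noise, no temperature
  dependence, and the extracellular network has exactly two nodes.
- The R_out sensitivity caveat above: the printed circuit transmits the
  field almost independently of R_out, so R_out-contrast figures are
  qualitative at best.
- Detection thresholds are fractions of the window's voltage range; on a
  window with no spikes but visible subthreshold oscillation, ripple peaks
  can be reported as events. In the study protocol the cell always fires,
  so the range is set by true spikes and the thresholds sit far above the
  ripple.
- The 3 ms minimum interval caps countable instantaneous rates at ~333 Hz.
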