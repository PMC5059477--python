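# Methods

## Scope and approach

`bapflux` models a single dendritic compartment whose membrane potential is
*forced* to follow a voltage command (the playback situation of a
voltage-clamp or dynamic-clamp experiment). There is no free membrane
integration: capacitance, axial resistance and leak are recorded as
provenance constants but never enter the computation. Everything the package
computes therefore reduces to (1) constructing voltage commands, (2)
evolving Hodgkin–Huxley gate variables along them, (3) converting open
probability into calcium current through a GHK flux term, and (4)
quantifying charge.

## The synthetic bAP generator

Recorded granule-cell bAP waveform pairs are not publicly deposited, so the
generator provides a parametric stand-in with the documented, printed
properties of the recorded pairs. One spike is

    V(t) = B + r(t)·(S(t) − B)

with a logistic rise `r(t)` (midpoint at the maximum rate of rise, t = 0)
and a falling phase `S(t)` that relaxes from the peak onto an
afterdepolarization (ADP) shoulder with a *compressed exponential*
`exp(−(u/τ_f)^q)`, q ≈ 1.56. The ADP shoulder is an absolute voltage shared
by both states; it decays to the state baseline with a 40-ms slow tau plus
a small alpha-function bump.

The two somatic states differ only in:

- baseline: −64.6 mV (depolarized) vs −77.2 mV (hyperpolarized);
- repolarization speed: the hyperpolarized state scales τ_f down by
  `repol_speedup`;
- distal peak deficit: `(1 − c(d))·ΔB`, with the compensation fraction
  `c(d)` a logistic in distance (≈1 below 75 µm, ≈0 beyond 120 µm), and the
  repolarization speed-up scaled by the same `c(d)` so distal pairs have
  shape-identical repolarization relative to their peaks.

**Calibration.** `decay_fast_tau_ms = 0.6915`, `repol_speedup = 0.0913` and
`fall_sharpness = 1.5618` were solved (Gauss–Newton on the generator itself)
so that the default proximal (24 µm) pair's difference trace reproduces the
recorded statistics: extremum −5 mV, 0.67 ms after the peak, half-duration
1.04 ms. A plain exponential fall cannot reach that width/latency ratio
(≈1.55; a difference of exponentials gives ≥2.4), which is why the fall is
sigmoidal. The somatic family used for the conductance-clamp pair
(baseline −68.7 mV, peak +40.6 mV, q ≈ 1.30, time-compression 0.0713) was
calibrated the same way against its comparison (−3.2 mV, 0.75 ms, 1.35 ms).

**Free defaults.** Absolute peak voltages away from the soma are not
printed anywhere usable, so the somatic peak (+45 mV) and the exponential
peak-attenuation length (200 µm) are plausible granule-cell choices fixed
once; they put the proximal peak (~+32 mV) well above activation saturation
and the 150-µm peak (~−13 mV) on the steep limb of the activation curve.
All are configurable.

The generator is noise-free; identical inputs give bit-identical traces.

## Channel models

The gating equations could not be carried over numerically, so the shipped
coefficients are the package's own, pinned by two hard anchors and a set of
qualitative constraints that the experiments must reproduce:

| quantity | value | status |
|---|---|---|
| HI τ_m(0 mV) | 1.137 ms | anchor, exact by construction |
| HN τ_m(0 mV) | 0.825 ms | anchor, exact by construction |
| HI h∞: mostly unavailable at −60 mV, mostly rested below −75 mV | half −68 mV, slope 4 | constraint |
| HI recovery at −80 mV | τ_h ≈ 400 ms | constraint (recovery experiments) |
| HI inactivation at spike voltages | τ_h ≈ 0.6–4 ms | constraint (repolarization-speed effect) |
| HI inactivation above +10 mV | τ_h ≈ 10 ms | constraint (plateau-extension experiment) |

Activation time constants use a two-sided exponential "bell" whose
amplitude is derived from the 0-mV anchor, so the anchor holds exactly
whatever the other shape coefficients are. The HI inactivation tau is a
two-limb curve: a large hyperpolarized limb (slow recovery at rest), a fast
floor through the spike-repolarization range, and a small depolarized limb
that slows inactivation again above ≈+10 mV. The fast floor is what makes
a lingering (slowly repolarizing) command lose availability while a fast
command escapes — the mechanism behind the positive repolarization-speed
effect; the depolarized limb is what lets a pre-peak voltage plateau extend
activation without destroying the current. Both features are needed
simultaneously and neither conflicts with the anchors.

Consequences worth knowing: (a) the model HI inactivates during a 0-mV step
much faster than the recorded ensemble currents decay (the printed 8.3/46-ms
biexponential describes the recorded currents; here those values appear as
generator inputs for the fit-recovery test, not as model output); (b) in a
0-mV step the composite scenario's peak current is carried almost entirely
by HN, so paired-pulse recovery is measured on `HI_only` (the `HN_only`
control is flat at ratio 1). The fitted recovery τ of 398 ms falls inside
the recorded 362–422 ms range because τ_h(−80) was designed there.

GHK flux: concentrations 5 mM external / 100 nM internal free calcium
(internal value conventional, not printed; all reported outputs are ratios
and insensitive to it), 24 °C, valence 2, amplitude factor 1. The removable
singularity at V = 0 is replaced by a second-order series for
|zFV/RT| < 1e−4; the guarded curve is continuous to <1e−6 relative.

Conductance clamp: ohmic `g·m·h·(V − V_rev)` with an A-type potassium
parameter set (g_max 7 nS within the 4–10 nS range, V_rev −90 mV) and a
passive control (instantaneous saturated activation, inactivation τ 1e9 ms,
V_rev −70 mV so the injected current vanishes at rest).

## Integration

The command is treated as sample-and-hold (constant over each dt), under
which the per-sample update `x ← x∞ + (x − x∞)·exp(−dt/τ)` is the exact
solution of the gate equation — integrator error does not exist, only
command-representation error, so "dt convergence" tests how finely the
waveform is sampled. Constant-voltage runs (holding baselines) are advanced
with the closed form in one stride; smooth stretches use a blocked
cumulative-product scan of the same recurrence (block 256 bounds
underflow). `strict=True` replays every sample through the scan; the two
paths agree to ~1e−13. Gates initialize at steady state for the first
command sample, which is what the long experimental holding baselines were
for; the 4-s default baseline is therefore truncatable without loss.

Sampling defaults: 0.5 µs for waveform-difference experiments, 2.5 µs for
step protocols, 12.5 µs for theta protocols (the second-long oscillation
only sets availability, which changes on hundreds of ms).

## Quantification

- AP metrics: peak, max rate of rise, apparent threshold (first sample with
  dV/dt > 20 mV/ms — descriptive only, configurable), baseline (mean over
  the 2 ms before threshold), half-duration at half of peak−baseline with
  interpolated crossings; ties break earliest.
- Charge: trapezoid integral of baseline-subtracted current over
  [peak+0.35, peak+1.35] ms (5-ms length for kinetics scans). The baseline
  is the mean current over the 2 ms before the spike onset (the exact
  experimental baseline window is unstated; this choice is documented and
  configurable). The peak reference is the *last* sample at the command
  maximum so that plateau-extended commands anchor the window to the start
  of repolarization. More negative charge = more influx; comparisons use
  magnitudes: `100·(|q_hyper| − |q_depol|)/|q_depol|`.
- Difference-trace statistics search the 5 ms after the peak (the fast
  transient; the slow drift of the two traces toward their different
  baselines is excluded by construction) and measure the width of the
  contiguous stretch beyond half the extremum.
- Exponential fits: variable projection (amplitudes solved linearly at
  fixed taus) with three deterministic log-spaced starts, bounded
  least-squares on log-taus; components ordered fast→slow, weights from
  amplitude magnitudes; flat inputs flagged degenerate rather than fitted.

## Experiments

All experiments are pure functions of their configuration; result tables
are bit-identical across reruns.

- **offset_scan**: +6 to −30 mV in 2-mV steps, charge in percent of the
  zero-offset value per command.
- **kinetics_scan**: on a pair equalized at −80 mV, activation-tau scale
  × inactivation-tau grid (log-spaced, ×0.25–4 and 0.5–500 ms;
  the inactivation value is referenced at −30 mV, the middle of the
  repolarization range). Cells whose peak open probability under the
  slower command is <1 % of a non-inactivating reference with the same
  activation kinetics are masked — a concrete instantiation of the
  "unrealistic kinetics" exclusion (the original criterion is not public).
- **state_comparison**: native / equalized −80 / occluded −60 preceding
  modes, 1-ms window.
- **completeness_scan**: 0.75–5-ms pre-peak plateau extensions.
- **theta_scan**: 5.2-Hz sinusoid between −62.2 and −83.9 mV, ≥5 cycles,
  spike spliced at a phase of the final cycle (sine convention, 90° =
  cycle peak); the spike template is generated at the instantaneous
  oscillation baseline so its waveform carries the state dependence, and
  its onset voltage equals the sinusoid value at that phase by
  construction. Reference is the flat −73.3 mV rest protocol. Proximal and
  distal locations run under the same scenario.
- **recovery_scan**: paired 3-ms pulses to 0 mV from −80 mV,
  second/first peak ratio vs interval, monoexponential recovery fit.

## What the synthetic data do and do not show

The generator reproduces the *documented statistics* of the recorded
waveforms, not the waveforms themselves: no channel noise, no
sweep-to-sweep variability, no electrode artefacts, and smooth parametric
rises/falls instead of biological ones. Passing tests therefore demonstrate
that the channel-level mechanism (fast inactivation turning a −5 mV/1-ms
repolarization difference into a charge difference, availability effects,
distal peak sensitivity, theta-phase readout) is internally consistent and
robust at the printed waveform statistics — not that the specific percent
changes equal those measured in cells. Experimental effect magnitudes from
imaging (e.g. the proximal ~+12 % enhancement) are not targets; only signs
and orderings are asserted.

## Known limitations

- LVA (T-type) currents, calcium-dependent inactivation, multicompartment
  cable effects and closed-loop dynamic clamp are out of scope.
- The HI inactivation speed at 0 mV is a model construction (see above);
  step-response decay of the composite does not reproduce the recorded
  ensemble biexponential.
- The distal peak attenuation profile is a single exponential with a free
  length constant; real attenuation profiles are cell-specific.
- The kinetics-scan exclusion rule is this package's own concrete stand-in
  for an unpublished criterion.
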