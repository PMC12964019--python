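# mhqpeldor

Planning and analysis toolkit for **microsecond freeze-hyperquenching
(MHQ)** coupled with **PELDOR/DEER** spectroscopy.

MHQ traps a protein–ligand reaction on the microsecond timescale: the two
solutions are mixed in a micromixer and sprayed as a ~20 µm jet onto a
liquid-nitrogen-cooled rotating cylinder (the *cold-plate*), where the
mixture freezes within ~40 µs. The reaction ("aging") time of each sample
is set by the nozzle-to-cold-plate flight distance. Pulsed dipolar EPR
(PELDOR/DEER) on spin-labeled samples then reads out the conformational
state at each aging time: the dipolar coupling frequency

ν<sub>dip</sub>(r, θ) = μ₀/(4πh) · g₁g₂β<sub>e</sub>² / r³ · (1 − 3cos²θ)

encodes the interspin distance r, so ligand-free (*apo*, r ≈ 4.0 nm) and
ligand-bound (*holo*, r ≈ 2.2 nm) conformations produce distinct
time-domain signatures. Because a mixed sample's background-corrected
dipolar trace is a linear combination of the pure-state traces,

**MHQ**(t) = a·**Apo**(t) + b·**Holo**(t),  a + b = 1,

the state populations follow directly from a least-squares solve, without
distance-domain regularization. Fitting the populations across aging times
with y(t<sub>a</sub>) = y₀ + A·e<sup>−k·t<sub>a</sub></sup> yields the
transition rate k and the average dwell time 1/k of the bound
pre-transition state.

The package implements, with a seeded synthetic-data generator standing in
for the instrument:

- **`instrument`** — jet transport/aging times, tubing dead volume,
  mixer-arm synchronisation (wait-time optimisation), the parabolic dye
  dilution model, cold-plate deposition (layers, film thickness) and the
  step-motor command format;
- **`dipolar`** — powder-averaged dipolar kernel K(t, r), trace
  simulation with modulation depth, exponential background and two-channel
  noise, SNR = Δ/σ, and acquisition-planning arithmetic (trace length,
  abscissa points, measurement duration, ESEEM-suppression increments);
- **`deconvolve`** — log-domain modulation-depth scaling (with coprime
  downsampling alignment for mixed time increments), linear-combination
  fitting with optional sum and non-negativity constraints, and residual
  diagnostics;
- **`cwepr`** — double integration for spin counting/labeling efficiency
  and high-/low-spin Fe(III) state fractions with an empirical
  normalization factor;
- **`kinetics`** — mono- and bi-exponential state-fraction fits with
  multi-start peeling initialisation, dwell times, pseudo-first-order
  checks;
- **`synthetic`** — seeded generation of every input the pipeline needs.

## Worked example

```python
import numpy as np
from mhqpeldor import instrument as inst, synthetic as syn
from mhqpeldor import deconvolve as dc, kinetics as kin

# --- plan the freeze-quench series on the reference instrument ---------
geom = inst.MhqGeometry()
flow = inst.FlowSettings.from_total_ml_per_min(2.0)
print(inst.aging_time_table(geom, flow).head(4).to_string(index=False))
w = inst.optimal_wait_time(geom, flow, sample_volume=200.0)
print(f"arm velocity : {w.arm_velocity_mm_s:.1f} mm/s")
print(f"wait-time    : {w.wait_time_s:.1f} s")

# --- simulate a full aging series and recover the kinetics -------------
spec = syn.FixtureSpec(seed=42, noise_sd=0.005)
apo, holo, _ = syn.make_reference_pair(syn.FixtureSpec(seed=42, noise_sd=0.0))
as_ff = lambda tr: dc.CorrectedTrace(t_ns=np.round(tr.t_us * 1e3), values=tr.real)
apo_c, holo_c = as_ff(apo), as_ff(holo)
fracs = [dc.linear_combination_fit(as_ff(tr), apo_c, holo_c).a_apo
         for _, tr, _ in syn.make_mhq_series(spec)]
fit = kin.fit_monoexponential(
    kin.KineticSeries(np.asarray(spec.aging_times_s), np.clip(fracs, -0.05, 1.05)))
tau, dtau = kin.dwell_time(fit)
print(f"k = {fit.k:.0f} 1/s, dwell time = {tau:.0f} +/- {dtau:.0f} us")
```

Output:

```
 distance_mm  tt_us  ta_us
           3     47     82
           5     66     99
           7     85    116
          10    113    142
arm velocity : 16.5 mm/s
wait-time    : 4.5 s
k = 7637 1/s, dwell time = 131 +/- 6 us
```

The table lists the jet transport time t<sub>t</sub> and aging time
t<sub>a</sub> = 0.9·t<sub>t</sub> + t<sub>c</sub> per nozzle distance; the
wait-time report synchronises sample arrival with the mixer-arm sweep
(16.5 mm/s, 4.5 s for a 200 µL sample at 2 mL/min). The simulated series
(generated with k = 7398 1/s) is deconvolved trace by trace and the
mono-exponential fit recovers the rate within its confidence interval; the
dwell time is 1/k with the propagated 2σ uncertainty.

The same operations are available from the shell:

```bash
mhqpeldor mhq-plan
mhqpeldor simulate --center 2.2 --noise-sd 0.01 --out holo.dat
mhqpeldor deconvolve mix.dat apo.dat holo.dat --report
mhqpeldor kinetics fractions.tsv --model mono
mhqpeldor fixtures --outdir demo --seed 1
```

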