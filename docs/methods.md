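# Methods

## Instrument model

The freeze-quench instrument is described by a small set of geometric and
timing constants (`MhqGeometry`), defaulting to the reference device:
20 µm orifice diameter, 1.85 m of 0.254 mm-bore tubing per channel
(dead volume πr²h ≈ 94 µL), a cold-plate of 65 mm inner radius rotating at
7000 rpm, a mixer-arm travel span of 49.6 mm inside the cold-plate and an
18.6 mm approach from the start position to its top, and a cryofixation
time of 40 µs. The in-mixer residence time is below 1 µs and is set to 0.

**Aging time.** t_a = t_m + 0.9·t_t + t_c, with the transport time
t_t = (d + d_off)/v_jet. The jet's linear velocity is the total volumetric
flow divided by the orifice cross-section (≈ 1.06·10⁵ mm/s at 2 mL/min),
which fixes the slope of t_t against the nozzle distance d at
9.42 µs/mm. Measured transport times carry a ≈ 18.6 µs intercept not
explained by the flight path alone; it is absorbed into a calibrated
pre-nozzle path length `internal_jet_offset` (default 2.0 mm, recoverable
by `calibrate_jet_offset` from a measured (distance, t_t) table). Table
emission rounds half-up to integer µs, matching how planning tables are
printed; unrounded values are always available from the functions.

**Mixer-arm synchronisation.** The sample reaches the mixer after
t_s→m = V_d/f_channel (5.62 s at 16.7 µL/s). The arm must sweep the
coverage span down and up while the sample volume V_s is expelled, giving
v_m = 2·d_c·f_total/V_s; note that the *total* flow enters here — only that
choice reproduces the 16.5 mm/s working value for 200 µL at 2 mL/min. The
dead time to reach the cold-plate top is t_d = d_m→c/v_m and the optimal
wait-time is t_w = t_s→m − t_d. Since t_d grows linearly with V_s, t_w
*decreases* with sample volume; for large samples (≳ 1 mL at 2 mL/min) the
theoretical optimum is negative — the arm cannot be in position in time —
and the report flags the setting as unreachable rather than failing.
Step-motor conversion is exactly 10⁵ µsteps per 12.4 mm.

**Dilution model.** The dye tracer experiment measures the absorbance
ratio of collected vs stock dye as a function of wait-time. The model is
the inverse parabola f(t_w) = V_total/(V_dye − k(t₀−t_w)²); the measured
ratio 1/f has its maximum V_dye/V_total at t_w = t₀ and falls to zero
where the parabola's denominator would change sign. Outside that domain no
dye is collected, so the ratio model is clamped at 0 (the unclamped
dilution factor raises an out-of-model error there). The fit treats only
t₀ as free — k is pinned to the per-channel flow — and is initialised by a
0.01 s grid search so the flat clamped region cannot trap the optimiser;
the 2σ interval comes from the Jacobian at the optimum.

**Deposition.** The jet is modelled as a cylinder of length
l_jet = V_s/(πr_jet²); the wall moves at v_dep = (rpm/60)·2πr_cold-plate.
Laying the full jet down as one layer would take l_jet/v_dep, the sample is
actually expelled in V_s/f_total, and the ratio is the layer count —
proportional to the flow rate and independent of sample volume. The film
thickness treats the deposit as a cuboid over the circumference times the
*deposited band height* (43.4 mm), a separate geometry field from the
49.6 mm mixer travel span: the jet paints the wall over less than the full
sweep, and only the band height reproduces the ≈ 11 µm working value for
200 µL.

## Dipolar physics

Frequencies derive from CODATA constants with free-electron g-factors; the
perpendicular coupling is 52.04 MHz·nm³/r³. The corresponding planning
constants — 1.92·10⁻⁵ µs/Å³ per oscillation period and 1.5× that for the
minimum trace length — agree with the conventionally quoted figures
(1.926·10⁻⁵, 2.889·10⁻⁵) to ~0.2 %, the difference being the g-factor
assumed in the quoted values.

**Powder kernel.** K(t, r) = ∫₀¹ cos(2πν⊥(r)(1−3z²)t) dz with z = cos θ,
evaluated by Gauss–Legendre quadrature in z. The integrand's total phase
grows as 6πν⊥t, so a fixed node count cannot serve all grids; the order is
scaled automatically to half the maximum phase plus a margin (floor 129
nodes). Against a 10⁵-node Riemann-sum reference the kernel agrees to
~10⁻¹¹ over t ≤ 8 µs, r ≥ 1.5 nm. Weights are normalised so K(0, r) = 1
exactly, and K depends on |t| only.

**Trace simulation.** V(t) = [(1−Δ) + Δ·∫K(t,r)P(r)dr]·e^(−λt) plus white
Gaussian noise of equal sd on the real and imaginary channels; the
imaginary channel is pure noise, which is exactly the assumption behind
the SNR definition Δ/σ(imag). Distributions live on a uniform grid with a
1 nm lower bound (point-dipole validity) and must integrate to unity.
Internal time unit is µs; file I/O accepts ns or µs with an explicit flag,
ns being the default on disk.

**Acquisition arithmetic.** dim5 = (d1 + d2 − 2·d3)/d30 must divide
exactly; on failure the error suggests the nearest valid evolution time.
Measurement duration is SRT·PC·m·h·n·dim5 with the shot-repetition time
either in absolute µs or in spectrometer units (srtu = 1.02 µs). The
nuclear-modulation-averaging increment is (1/ν_Larmor)/m.

## Two-state deconvolution

Input traces must be background-corrected form factors with strictly
positive values on integer-ns grids (positivity because the scaling works
on logarithms; integer ns so grid alignment is exact arithmetic).

**Modulation-depth scaling.** The exponent
f^λ = Σ(ln V₁)²/Σ(ln V₁ ln V₂) is computed over the time points shared by
both traces: with increments Δt₁, Δt₂ and α_i = Δt_i/gcd(Δt₁, Δt₂), the
common times are multiples of the lcm, reached by indexing each trace with
its partner's α. The index starts at the first non-zero time (the t = 0
point is log 1 = 0 and carries no information). The scaled trace is the
elementwise power V₂^(f^λ) — log-domain multiplication, the natural
application rule for an exponent defined by log-domain regression. For
V₂ = V₁^c the exponent is exactly 1/c; for identical increments the
formula reduces to the classic two-trace scaling, which serves as the
oracle in the tests. Note the formula is the regression of ln V₁ on ln V₂
written with the numerator squared in V₁; both orientations coincide
exactly when one trace is a power of the other, and differ only through
noise otherwise.

**Linear combination.** With the sum constraint, the one-parameter
projection a = ⟨MHQ−Holo, Apo−Holo⟩/‖Apo−Holo‖² gives populations
directly; unconstrained and non-negative (active-set NNLS) variants are
available, the unconstrained result carrying a flag to normalise before
interpretation. Nearly collinear components (condition number > 10⁸)
raise a conditioning error — the two states cannot be resolved. Traces on
different grids are linearly interpolated onto the coarsest common grid;
linear interpolation is the least-assuming choice on smooth decays.
Negative fitted weights trigger a warning pointing at incomplete
background correction. Because the pipeline always applies the scaling
step (as the interactive workflow does), even equal-depth mixtures are
perturbed at the ~1 % level — a mixture is not an exact power of either
reference; exact recovery (< 10⁻⁸) holds for the linear solve on aligned
traces.

**Residual diagnostics.** A first-order polynomial is fitted to the
residual; the verdict passes when |slope| and |intercept| are both within
two of their own standard errors. Per coefficient this passes white noise
~95 % of the time; jointly the rate is ~92 %, which is the operative
false-alarm rate of the verdict.

## CW-EPR quantification

Double integration subtracts a linear baseline anchored in two signal-free
windows at the sweep ends, then integrates twice by cumulative trapezoid;
adding any first-order polynomial to the raw spectrum leaves the result
unchanged by construction. A non-monotone double-integral trace over the
signal region triggers a warning (baseline or phase problem). Absolute
spin counting needs a resonator calibration constant (area per µM), which
the user supplies; the instrument vendor's internal calibration is not
reproduced. State fractions use peak-to-peak amplitudes of the high-spin
(g ≈ 5.8) and low-spin (g ≈ 2.2) Fe(III) marker features inside
user-chosen field windows, with %apo = I_hs/(I_hs + NF·I_ls)·100 and the
empirical NF = I_hs/I_ls measured on equal-spin-count references
(instrument- and settings-dependent; re-derive per setup).

## Kinetics

Mono-exponential fits keep the offset y₀ free — incomplete conversion
leaves a residual apo population. Bi-exponential fits are initialised by
peeling (tail log-regression for the slow rate, remainder regression for
the fast) with four jittered restarts; amplitudes are bounded in [0, 1.2]
and rates in (0, 10⁷ s⁻¹], the physical window for 10⁻⁵–10⁻³ s aging
times. Replicate errors, when present, enter as 1/sd² weights. Rates
within 10 % of each other trigger a "mono-exponential suffices" warning. A
component faster than the first sampled aging time is fundamentally
unidentifiable: fits to single-exponential data may park a small amplitude
at a huge rate, so nested-model consistency is asserted on the fitted
curves, not on raw parameters. The dwell time is 1/k with uncertainty
Δk/k². The pseudo-first-order check defaults to a 50-fold ligand excess
threshold, inclusive.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the study conditions: Gaussian apo/holo distance
peaks at 4.0 and 2.2 nm, 0.15 nm widths (not an experimentally determined
value; chosen once so the oscillatory parts of the two references have a
design condition number below 10), modulation depth 0.30, white noise of
sd 0.015 per channel (SNR 20, the recommended floor), apo fractions
following y₀ = 0.12, A = 0.96, k = 7398 s⁻¹, and the standard aging-time
grid 82–668 µs. Kinetic data points are means of 3 replicate draws with
the spread set so the 2σ error bars are 0.04, the experimental scale.
Mixed traces combine the *noiseless* references with fresh seeded noise;
all streams are spawned from one master seed, making the full pipeline
bit-reproducible. By default traces are emitted as background-corrected
form factors (background rate 0); a nonzero rate emulates raw traces.

Passing tests on this data demonstrate correct arithmetic, unbiased
coefficient recovery at realistic SNR, and rate recovery under the stated
noise model. They do not demonstrate robustness to the features real data
add: imperfect background correction, zero-time and phase errors,
orientation selection, multi-spin effects, label rotamer distributions, or
non-Gaussian conformational heterogeneity. Distance-domain inversion is
out of scope by design; established analysis suites handle it.

## Problem sizes used in the test suite

Kernel/oracle comparisons run on an 81×10 (t, r) grid against a 10⁵-node
quadrature; deconvolution recovery uses 200 noise realisations on 313-point
traces; kinetic coverage uses 500 simulated series of 7 points; the
end-to-end pipeline check runs the full 11-point aging series. These sizes
give Monte-Carlo standard errors comfortably below the asserted margins.
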