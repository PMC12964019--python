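"""Synthetic data emulating the full freeze-quench / PELDOR study.

Everything the analysis stages consume can be generated here without any
measurement: Gaussian apo/holo distance distributions centred near 4.0 and
2.2 nm (a 1.8 nm ligand-induced distance change), their simulated dipolar
traces at ~30 % modulation depth with white Gaussian noise on both
channels, mixed traces whose apo fraction follows the mono-exponential law
y0 + A exp(-k t_a) over a realistic aging-time grid, dye dilution-series
tables, and derivative-of-Gaussian CW-EPR spectra.

All stochastic output is seeded: a :class:`FixtureSpec` carries one master
seed, and per-trace streams are spawned from it, so a fixed spec is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import dipolar, instrument
from .cwepr import Spectrum
from .dipolar import DipolarTrace, DistanceDistribution
from .exceptions import MhqError
from .instrument import DilutionSeries
from .kinetics import KineticSeries

__all__ = [
    "FixtureSpec",
    "make_reference_pair",
    "make_mhq_series",
    "make_kinetic_series",
    "make_dilution_table",
    "make_cw_spectrum",
    "TABLE_AGING_TIMES_S",
    "TABLE_WAIT_TIMES_S",
]

#: Aging times (s) of the standard nozzle-distance table.
TABLE_AGING_TIMES_S = tuple(
    t * 1e-6 for t in (82, 99, 116, 142, 201, 252, 303, 405, 498, 574, 668)
)

#: Wait-time grid (s) of the dye dilution series.
TABLE_WAIT_TIMES_S = (2.5, 3.5, 4.5, 6.5, 8.5, 10.5)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study.

    Defaults are the study conditions: apo/holo distance peaks at 4.0 and
    2.2 nm (width 0.15 nm, chosen so the two reference traces are far from
    collinear), modulation depth 0.30, noise sd 0.015 on each channel
    (SNR = 0.3/0.015 = 20, the minimum recommended for deconvolution),
    mono-exponential kinetics y0 = 0.12, A = 0.96, k = 7398 1/s, and the
    standard aging-time grid.  ``background_rate`` defaults to 0 because the
    deconvolution consumes background-corrected traces; set it > 0 to
    emulate raw traces with an intermolecular decay.
    """

    apo_center_nm: float = 4.0
    holo_center_nm: float = 2.2
    width_nm: float = 0.15
    modulation_depth: float = 0.30
    background_rate: float = 0.0         # 1/us
    noise_sd: float = 0.015
    kinetic_y0: float = 0.12
    kinetic_A: float = 0.96
    kinetic_k: float = 7398.0            # 1/s
    aging_times_s: tuple = TABLE_AGING_TIMES_S
    t_max_us: float = 2.5
    dt_us: float = 0.008
    seed: int = 0

    def __post_init__(self) -> None:
        for c in (self.apo_center_nm, self.holo_center_nm):
            if not (1.5 <= c <= 8.0):
                raise MhqError("distance centers must lie within [1.5, 8] nm")
        if self.seed is None:
            raise MhqError("a seed is mandatory for stochastic fixtures")

    @property
    def t_grid_us(self) -> np.ndarray:
        return np.arange(0.0, self.t_max_us + self.dt_us / 2, self.dt_us)


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# noiseless reference signals are deterministic in the distribution/trace
# parameters; memoise them so seed sweeps do not recompute the kernel
_REF_CACHE: dict = {}


def _noiseless_references(spec: FixtureSpec):
    key = (spec.apo_center_nm, spec.holo_center_nm, spec.width_nm,
           spec.modulation_depth, spec.background_rate,
           spec.t_max_us, spec.dt_us)
    if key not in _REF_CACHE:
        apo_d = DistanceDistribution.gaussian(spec.apo_center_nm, spec.width_nm)
        holo_d = DistanceDistribution.gaussian(spec.holo_center_nm, spec.width_nm)
        t = spec.t_grid_us
        apo = dipolar.simulate_trace(apo_d, t, spec.modulation_depth,
                                     spec.background_rate)
        holo = dipolar.simulate_trace(holo_d, t, spec.modulation_depth,
                                      spec.background_rate)
        _REF_CACHE[key] = (apo.real, holo.real, (apo_d, holo_d))
    return _REF_CACHE[key]


def make_reference_pair(spec: FixtureSpec):
    """Apo and holo reference traces plus their true distributions.

    Returns ``(apo_trace, holo_trace, (apo_dist, holo_dist))``.  Noise (sd
    ``spec.noise_sd``) is drawn from two independent streams spawned from
    the master seed; pass a spec with ``noise_sd=0`` for noiseless
    references.  Warns when the two distributions overlap so strongly that
    deconvolution cannot resolve them.
    """
    import warnings

    if abs(spec.apo_center_nm - spec.holo_center_nm) < 2 * spec.width_nm:
        warnings.warn(
            "apo and holo distributions overlap within 2 widths; "
            "the two states may be unresolvable",
            stacklevel=2,
        )
    apo_v, holo_v, (apo_d, holo_d) = _noiseless_references(spec)
    rng_a, rng_h = _spawn_rngs(spec.seed, 2)
    t = spec.t_grid_us
    traces = []
    for v, rng, state in ((apo_v, rng_a, "apo"), (holo_v, rng_h, "holo")):
        if spec.noise_sd > 0:
            real = v + rng.normal(0.0, spec.noise_sd, t.size)
            imag = rng.normal(0.0, spec.noise_sd, t.size)
        else:
            real, imag = v.copy(), np.zeros_like(v)
        traces.append(DipolarTrace(
            t_us=t.copy(), real=real, imag=imag,
            modulation_depth=spec.modulation_depth,
            meta={"state": state,
                  "bg_rate_per_us": spec.background_rate,
                  "noise_sd": spec.noise_sd},
        ))
    return traces[0], traces[1], (apo_d, holo_d)


def true_apo_fraction(spec: FixtureSpec, t_a_s) -> np.ndarray:
    """Mono-exponential apo fraction y0 + A exp(-k t_a)."""
    t_a_s = np.asarray(t_a_s, dtype=float)
    return spec.kinetic_y0 + spec.kinetic_A * np.exp(-spec.kinetic_k * t_a_s)


def make_mhq_series(spec: FixtureSpec):
    """Mixed traces over the aging-time grid.

    For each aging time the true apo fraction follows the mono-exponential
    law; the mixture is the fraction-weighted sum of the *noiseless*
    references plus fresh seeded noise on both channels.  Returns a list of
    ``(aging_time_s, trace, true_fraction)`` tuples.
    """
    clean = replace(spec, noise_sd=0.0)
    apo_t, holo_t, _ = make_reference_pair(clean)
    t = spec.t_grid_us
    n = len(spec.aging_times_s)
    rngs = _spawn_rngs(spec.seed + 1, n)
    out = []
    for t_a, rng in zip(spec.aging_times_s, rngs):
        frac = float(true_apo_fraction(spec, t_a))
        v = frac * apo_t.real + (1.0 - frac) * holo_t.real
        if spec.noise_sd > 0:
            real = v + rng.normal(0.0, spec.noise_sd, t.size)
            imag = rng.normal(0.0, spec.noise_sd, t.size)
        else:
            real, imag = v, np.zeros_like(v)
        tr = DipolarTrace(
            t_us=t.copy(), real=real, imag=imag,
            modulation_depth=spec.modulation_depth,
            meta={"aging_time_s": t_a, "true_apo_fraction": frac},
        )
        out.append((t_a, tr, frac))
    return out


def make_kinetic_series(spec: FixtureSpec, aging_times_s=None,
                        point_sd: float = 0.02,
                        n_replicates: int = 3) -> KineticSeries:
    """State-fraction series with replicate-averaged Gaussian noise.

    Each plotted fraction is the mean of ``n_replicates`` replicate draws
    whose spread is chosen so the sd of the mean equals ``point_sd``
    (default 0.02, i.e. 2-sigma error bars of 0.04, the experimental
    scale).  Returns a :class:`KineticSeries` with ``sd_2sigma`` filled in.
    """
    t_a = np.asarray(aging_times_s if aging_times_s is not None
                     else spec.aging_times_s, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed + 2))
    truth = true_apo_fraction(spec, t_a)
    rep_sd = point_sd * np.sqrt(n_replicates)
    reps = truth[:, None] + rng.normal(0.0, rep_sd, (t_a.size, n_replicates))
    fractions = np.clip(reps.mean(axis=1), -0.05, 1.05)
    return KineticSeries(
        aging_times=t_a, fractions=fractions,
        sd_2sigma=np.full(t_a.size, 2.0 * point_sd),
        n_replicates=n_replicates,
    )


def make_dilution_table(spec: FixtureSpec, t0_s: float = 5.33,
                        k_ul_s: float = 16.67, V_dye: float = 100.0,
                        V_total: float = 200.0,
                        noise_sd: float = 0.02,
                        wait_times_s=TABLE_WAIT_TIMES_S) -> DilutionSeries:
    """Dye dilution series over the standard wait-time grid.

    Ratios follow the clamped inverse-parabola model (minimum dilution 2,
    i.e. peak ratio 0.5, at t_w = t0) plus seeded Gaussian noise; pass
    ``noise_sd=0`` for the noiseless model curve.
    """
    tw = np.asarray(wait_times_s, dtype=float)
    ratios = instrument.dilution_ratio(tw, t0_s, k_ul_s, V_dye, V_total)
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed + 3))
        ratios = ratios + rng.normal(0.0, noise_sd, tw.size)
        sd = np.full(tw.size, noise_sd)
    else:
        sd = None
    return DilutionSeries(wait_times=tw, dilution_ratios=ratios,
                          replicate_sd=sd)


def make_cw_spectrum(lines, field_min_G: float = 500.0,
                     field_max_G: float = 4000.0, n_points: int = 2048,
                     baseline_drift: tuple[float, float] = (0.0, 0.0),
                     noise_sd: float = 0.0, seed: int = 0) -> Spectrum:
    """First-derivative CW-EPR spectrum from derivative-of-Gaussian lines.

    ``lines`` is a list of ``(center_G, width_G, amplitude)``; each line is
    -A (B - B0)/w exp(-(B - B0)^2 / 2 w^2), whose double integral is
    A w^2 sqrt(2 pi).  ``baseline_drift`` adds slope and offset; baseline
    regions are assigned to the outer 10 % of the sweep on each side.
    """
    B = np.linspace(field_min_G, field_max_G, n_points)
    y = np.zeros_like(B)
    for c, w, a in lines:
        if not (field_min_G < c < field_max_G):
            raise MhqError("line center outside the field axis")
        x = (B - c) / w
        y += -a * x * np.exp(-0.5 * x * x)
    slope, offset = baseline_drift
    y += slope * B + offset
    if noise_sd > 0:
        y += np.random.default_rng(seed).normal(0.0, noise_sd, B.size)
    span = field_max_G - field_min_G
    regions = (
        (field_min_G, field_min_G + 0.1 * span),
        (field_max_G - 0.1 * span, field_max_G),
    )
    return Spectrum(field_G=B, intensity=y, baseline_regions=regions)
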