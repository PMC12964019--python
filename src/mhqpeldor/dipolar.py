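"""Dipolar-coupling physics, PELDOR trace simulation and acquisition planning.

PELDOR/DEER measures the magnetic dipole-dipole coupling between two
unpaired electron spins.  The coupling frequency

    nu_dip(r, theta) = mu0 / (4 pi h) * g1 g2 beta_e^2 / r^3 * (1 - 3 cos^2 theta)

depends on the interspin distance r (as r^-3) and the angle theta between
the interspin vector and the external field.  In a frozen solution all
orientations contribute, and averaging cos(2 pi nu t) over the sphere gives
the powder kernel K(t, r); the time-domain signal of a distance
distribution P(r) is the kernel integral, damped by an exponential
intermolecular background and scaled by the modulation depth Delta.

This module provides the frequency/period arithmetic used to plan an
acquisition (trace length, abscissa points, measurement duration, nuclear
modulation averaging) and a simulator that produces realistic two-channel
(real/imaginary) dipolar traces for testing the downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import constants as _const

from .exceptions import MhqError, TraceError

__all__ = [
    "PhysicalConstants",
    "DistanceDistribution",
    "DipolarTrace",
    "AcquisitionPlan",
    "nu_dip",
    "nu_perp",
    "dipolar_period",
    "min_evolution_time",
    "kernel",
    "simulate_trace",
    "snr",
    "plan_dim5",
    "acquisition_time",
    "nucmod_increment",
    "SRTU_US",
]

#: Spectrometer shot-repetition time unit, us.
SRTU_US = 1.02


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants entering the dipolar frequency (CODATA by default).

    The g-factors default to the free-electron value; override them to
    reproduce coefficients printed with slightly different assumptions.
    """

    mu0: float = _const.mu_0
    planck_h: float = _const.h
    bohr_magneton_betae: float = _const.value("Bohr magneton")
    g1: float = 2.00231930436256
    g2: float = 2.00231930436256


_DEFAULT_CONSTANTS = PhysicalConstants()


def nu_perp(r_nm: float, consts: PhysicalConstants = _DEFAULT_CONSTANTS) -> float:
    """Perpendicular (theta = 90 deg) dipolar frequency in MHz, r in nm.

    About 52.04 MHz at r = 1 nm for free-electron g-factors.
    """
    r_nm = np.asarray(r_nm, dtype=float)
    if np.any(r_nm <= 0):
        raise MhqError("interspin distance must be > 0")
    hz = (
        consts.mu0
        / (4.0 * np.pi * consts.planck_h)
        * consts.g1
        * consts.g2
        * consts.bohr_magneton_betae**2
        / (r_nm * 1e-9) ** 3
    )
    return hz / 1e6


def nu_dip(r_nm: float, theta: float,
           consts: PhysicalConstants = _DEFAULT_CONSTANTS) -> float:
    """Dipolar frequency nu(r, theta) in MHz; vanishes at the magic angle."""
    return nu_perp(r_nm, consts) * (1.0 - 3.0 * np.cos(theta) ** 2)


def dipolar_period(r_max_angstrom: float,
                   consts: PhysicalConstants = _DEFAULT_CONSTANTS) -> float:
    """Period of one perpendicular dipolar oscillation, us, r_max in Angstrom.

    Equals c * r_max^3 with c ~ 1.92e-5 us/A^3 for free-electron g-factors.
    """
    if np.any(np.asarray(r_max_angstrom) <= 0):
        raise MhqError("r_max must be > 0")
    return float(np.asarray(r_max_angstrom)**3 / (1e3 * nu_perp(1.0, consts)))


def min_evolution_time(r_max_angstrom: float,
                       consts: PhysicalConstants = _DEFAULT_CONSTANTS) -> float:
    """Minimum dipolar evolution time (us) resolving 1.5 oscillation periods."""
    return 1.5 * dipolar_period(r_max_angstrom, consts)


def kernel(t_us, r_nm, consts: PhysicalConstants = _DEFAULT_CONSTANTS,
           n_nodes: int | None = None) -> np.ndarray:
    """Powder-averaged dipolar kernel K(t, r).

    K(t, r) = integral_0^1 cos(2 pi nu_perp(r) (1 - 3 z^2) t) dz with
    z = cos(theta), evaluated by Gauss-Legendre quadrature in z.  The node
    count scales with the largest dimensionless phase on the requested grids
    (floor 129) so the quadrature stays accurate for long traces and short
    distances; the column at t = 0 is exactly 1.

    Parameters
    ----------
    t_us, r_nm : array_like
        Uniform time grid (us) and distance grid (nm).
    n_nodes : int, optional
        Override the automatic quadrature order.
    """
    t = np.atleast_1d(np.asarray(t_us, dtype=float))
    r = np.atleast_1d(np.asarray(r_nm, dtype=float))
    nu = nu_perp(r, consts)  # MHz
    if n_nodes is None:
        phi_max = 6.0 * np.pi * float(np.max(nu)) * float(np.max(np.abs(t)))
        n_nodes = max(129, int(phi_max / 2.0) + 100)
    z, w = leggauss(n_nodes)
    z = 0.5 * (z + 1.0)          # map to [0, 1]
    w = 0.5 * w                  # weights sum to 1 -> K(0, r) = 1 exactly
    K = np.empty((t.size, r.size))
    ang = 1.0 - 3.0 * z * z
    for j in range(r.size):
        K[:, j] = np.cos(2.0 * np.pi * nu[j] * np.outer(np.abs(t), ang)) @ w
    return K


@dataclass
class DistanceDistribution:
    """Probability density over interspin distance on a uniform grid.

    ``density`` integrates (trapezoid) to 1 within 1e-6; distances in nm,
    minimum 1.0 nm (below that, exchange coupling invalidates the point-
    dipole picture).
    """

    r_grid: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.r_grid = np.asarray(self.r_grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.r_grid.ndim != 1 or self.r_grid.shape != self.density.shape:
            raise MhqError("r_grid and density must be 1-D and equal length")
        dr = np.diff(self.r_grid)
        if np.any(dr <= 0):
            raise MhqError("r_grid must be strictly increasing")
        if not np.allclose(dr, dr[0], rtol=1e-8, atol=1e-12):
            raise MhqError("r_grid must be uniformly spaced")
        if self.r_grid[0] < 1.0:
            raise MhqError("distances below 1.0 nm are outside the model")
        if np.any(self.density < 0):
            raise MhqError("density must be non-negative")
        area = float(np.trapezoid(self.density, self.r_grid))
        if abs(area - 1.0) > 1e-6:
            raise MhqError(f"density must integrate to 1 (got {area:.8f})")

    @classmethod
    def gaussian(cls, center_nm: float, width_nm: float,
                 r_min: float = 1.0, r_max: float = 8.0,
                 dr: float = 0.02) -> "DistanceDistribution":
        """Normalised Gaussian distribution on a default [1, 8] nm grid."""
        r = np.arange(r_min, r_max + dr / 2, dr)
        p = np.exp(-0.5 * ((r - center_nm) / width_nm) ** 2)
        p /= np.trapezoid(p, r)
        return cls(r_grid=r, density=p)


@dataclass
class DipolarTrace:
    """Time-domain PELDOR signal with real and imaginary channels.

    Times in us on a uniform grid starting at 0; the real channel is
    normalised to 1 at t = 0 (background-corrected convention), the
    imaginary channel carries only noise when the receiver phase is set
    correctly.
    """

    t_us: np.ndarray
    real: np.ndarray
    imag: np.ndarray | None = None
    modulation_depth: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_us = np.asarray(self.t_us, dtype=float)
        self.real = np.asarray(self.real, dtype=float)
        if self.imag is not None:
            self.imag = np.asarray(self.imag, dtype=float)
            if self.imag.shape != self.t_us.shape:
                raise TraceError("imaginary channel length mismatch")
        if self.t_us.shape != self.real.shape:
            raise TraceError("time grid and real channel length mismatch")
        dt = np.diff(self.t_us)
        if dt.size and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise TraceError("time grid must be uniform and increasing")

    @property
    def dt_us(self) -> float:
        return float(self.t_us[1] - self.t_us[0])


def simulate_trace(dist: DistanceDistribution, t_us, delta: float,
                   bg_rate: float = 0.0, noise_sd: float = 0.0,
                   seed=None,
                   consts: PhysicalConstants = _DEFAULT_CONSTANTS) -> DipolarTrace:
    """Simulate a two-channel dipolar trace for a distance distribution.

    V(t) = [(1 - Delta) + Delta * S(t)] * exp(-bg_rate * t) + noise, with
    S(t) the kernel integral of P(r).  Gaussian noise of sd ``noise_sd`` is
    added independently to both channels; the imaginary channel is pure
    noise.  ``seed`` may be an int or a :class:`numpy.random.Generator`.

    Parameters
    ----------
    delta : float
        Modulation depth, 0 < Delta <= 1 (~0.3 at Q-band).
    bg_rate : float
        Mono-exponential intermolecular background rate, 1/us (0 for a
        background-corrected form factor).
    """
    if not (0.0 <= delta <= 1.0):
        raise MhqError("modulation depth must be in [0, 1]")
    if noise_sd < 0:
        raise MhqError("noise_sd must be >= 0")
    t = np.asarray(t_us, dtype=float)
    K = kernel(t, dist.r_grid, consts)
    dr = dist.r_grid[1] - dist.r_grid[0]
    # trapezoid weights on the uniform r grid
    wts = np.full(dist.r_grid.size, dr)
    wts[0] = wts[-1] = dr / 2
    s = K @ (dist.density * wts)
    v = ((1.0 - delta) + delta * s) * np.exp(-bg_rate * t)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if noise_sd > 0:
        real = v + rng.normal(0.0, noise_sd, t.size)
        imag = rng.normal(0.0, noise_sd, t.size)
    else:
        real = v
        imag = np.zeros_like(v)
    return DipolarTrace(
        t_us=t, real=real, imag=imag, modulation_depth=delta,
        meta={"bg_rate_per_us": bg_rate, "noise_sd": noise_sd},
    )


def snr(trace: DipolarTrace) -> float:
    """Signal-to-noise ratio Delta / sigma.

    sigma is the standard deviation of the imaginary channel (noise-only
    when the receiver phase is correct).  Returns ``inf`` for a noiseless
    trace.  Values above ~20 are adequate for two-state deconvolution of
    well-separated distributions.
    """
    if trace.imag is None:
        raise TraceError(
            "no imaginary channel: supply the noise sigma manually "
            "(snr = modulation_depth / sigma)"
        )
    if trace.modulation_depth is None:
        raise TraceError("trace has no modulation depth recorded")
    sigma = float(np.std(trace.imag))
    if sigma == 0.0:
        return float("inf")
    return trace.modulation_depth / sigma


# ---------------------------------------------------------------------------
# acquisition planning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionPlan:
    """Pulse-program timing parameters of a 4-pulse DEER acquisition.

    Delays in ns except ``srt_us``; ``m`` nuclear-modulation-averaging
    steps, ``h`` shots per point, ``n`` scans, ``pc`` phase-cycling steps.
    """

    d1_tau1: int
    d2_tau2: int
    d3_dead: int
    d30_increment: int
    srt_us: float
    h_shots: int = 10
    n_scans: int = 1
    m_nucmod_steps: int = 8
    d31_nucmod_increment: float = 16.0
    pc_phasecycle: int = 2

    @property
    def dim5(self) -> int:
        return plan_dim5(self.d1_tau1, self.d2_tau2, self.d3_dead, self.d30_increment)

    @classmethod
    def with_srtu(cls, srtu_multiples: float, **kw) -> "AcquisitionPlan":
        """Build with the shot-repetition time given in srtu units (1.02 us)."""
        return cls(srt_us=srtu_multiples * SRTU_US, **kw)


def plan_dim5(d1: int, d2: int, d3: int, d30: int) -> int:
    """Number of abscissa points dim5 = (d1 + d2 - 2 d3) / d30, exactly.

    Raises with the nearest valid dipolar evolution time d2 when the window
    is not divisible by the increment.
    """
    if d30 <= 0:
        raise MhqError("d30 must be > 0")
    window = d1 + d2 - 2 * d3
    q, rem = divmod(window, d30)
    if rem:
        d2_lo = d2 - rem
        d2_hi = d2 + (d30 - rem)
        raise MhqError(
            f"window {window} ns not divisible by d30 = {d30} ns; "
            f"nearest valid d2: {d2_lo} or {d2_hi} ns"
        )
    return int(q)


def acquisition_time(plan: AcquisitionPlan) -> float:
    """Total measurement duration SRT * PC * m * h * n * dim5, in seconds."""
    return (
        plan.srt_us * 1e-6
        * plan.pc_phasecycle
        * plan.m_nucmod_steps
        * plan.h_shots
        * plan.n_scans
        * plan.dim5
    )


def nucmod_increment(larmor_freq_mhz: float, m: int) -> float:
    """Time increment (ns) for nuclear modulation averaging, (1/nu)/m.

    Averaging m steps over one nuclear Larmor period suppresses ESEEM from
    that nucleus (e.g. ~16 ns for deuterium at Q-band with m = 8).
    """
    if larmor_freq_mhz <= 0:
        raise MhqError("Larmor frequency must be > 0")
    if m < 1:
        raise MhqError("m must be >= 1")
    return 1.0 / larmor_freq_mhz * 1e3 / m
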