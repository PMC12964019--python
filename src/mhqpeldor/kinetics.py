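"""Kinetic parameterization of freeze-quenched state-fraction time courses.

Under pseudo-first-order conditions (ligand in large excess) the apo-state
fraction decays exponentially with the aging time.  Two models are used:

* bi-exponential, f_apo(t) = A exp(-k1 t) + B exp(-k2 t), for the
  metmyoglobin-azide molecular-timer calibration (two binding modes);
* mono-exponential with offset, y(t) = y0 + A exp(-k t), for the
  ligand-induced conformational transition; the offset y0 accounts for
  incomplete conversion, and 1/k is the average dwell time of the bound
  pre-transition state.

Fits are nonlinear least squares with multi-start initialisation: the slow
rate is seeded by a log-linear regression on the tail, the fast rate by
peeling (subtracting the slow component and regressing the remainder), and
a few jittered restarts guard against local minima.  Replicate standard
deviations, when available, enter as 1/sd^2 weights.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import FitError, MhqError

__all__ = [
    "KineticSeries",
    "BiExpFit",
    "MonoExpFit",
    "fit_biexponential",
    "fit_monoexponential",
    "dwell_time",
    "pseudo_first_order_check",
]

_K_MAX = 1e7  # s^-1; aging times are 1e-5..1e-3 s
_AMP_MAX = 1.2


@dataclass
class KineticSeries:
    """State fractions vs aging time, optionally with replicate errors.

    ``sd_2sigma`` are the 2-sigma uncertainties of the fraction estimates
    (as plotted error bars); ``n_replicates`` documents how many replicate
    measurements each point averages.
    """

    aging_times: np.ndarray      # s
    fractions: np.ndarray        # [0, 1] up to noise
    sd_2sigma: np.ndarray | None = None
    n_replicates: int = 1

    def __post_init__(self) -> None:
        self.aging_times = np.asarray(self.aging_times, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.aging_times.shape != self.fractions.shape:
            raise MhqError("aging_times and fractions must have equal length")
        if np.any(np.diff(self.aging_times) <= 0):
            raise MhqError("aging_times must be strictly increasing")
        if np.any(self.fractions < -0.05) or np.any(self.fractions > 1.05):
            raise MhqError("fractions must lie in [-0.05, 1.05]")
        if self.sd_2sigma is not None:
            self.sd_2sigma = np.asarray(self.sd_2sigma, dtype=float)
            if self.sd_2sigma.shape != self.aging_times.shape:
                raise MhqError("sd_2sigma length mismatch")
            if np.any(self.sd_2sigma <= 0):
                raise MhqError("sd_2sigma must be > 0")


@dataclass(frozen=True)
class BiExpFit:
    """f(t) = A exp(-k1 t) + B exp(-k2 t) with k1 >= k2 (fast first)."""

    A: float
    B: float
    k1: float
    k2: float
    covariance: np.ndarray
    r_squared: float

    def __call__(self, t):
        return self.A * np.exp(-self.k1 * np.asarray(t)) + \
            self.B * np.exp(-self.k2 * np.asarray(t))

    @property
    def two_sigma(self) -> tuple[float, float, float, float]:
        """2-sigma intervals for (A, k1, B, k2)."""
        se = np.sqrt(np.diag(self.covariance))
        return tuple(2.0 * se)  # type: ignore[return-value]


@dataclass(frozen=True)
class MonoExpFit:
    """y(t) = y0 + A exp(-k t)."""

    y0: float
    A: float
    k: float
    covariance: np.ndarray
    r_squared: float

    def __call__(self, t):
        return self.y0 + self.A * np.exp(-self.k * np.asarray(t))

    @property
    def two_sigma(self) -> tuple[float, float, float]:
        """2-sigma intervals for (y0, A, k)."""
        se = np.sqrt(np.diag(self.covariance))
        return tuple(2.0 * se)  # type: ignore[return-value]

    @property
    def dwell_time_us(self) -> float:
        return 1.0 / self.k * 1e6


def _weights(series: KineticSeries):
    if series.sd_2sigma is None:
        return None
    return series.sd_2sigma / 2.0  # curve_fit sigma = 1-sigma errors


def _r_squared(y, fit) -> float:
    ss = float(np.sum((y - fit) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss / tss if tss > 0 else math.nan


def _tail_log_rate(t, y, frac=0.5):
    """Slope of ln(y) on the latest ``frac`` of points with y > 0."""
    n = max(3, int(len(t) * frac))
    tt, yy = t[-n:], y[-n:]
    m = yy > 1e-12
    if m.sum() < 2:
        return None, None
    s, b = np.polyfit(tt[m], np.log(yy[m]), 1)
    return max(-s, 1.0), math.exp(b)


def fit_monoexponential(series: KineticSeries) -> MonoExpFit:
    """Fit y = y0 + A exp(-k t); y0 is free (incomplete conversion)."""
    t, y = series.aging_times, series.fractions
    if t.size < 4:
        raise FitError("need at least 4 points for a mono-exponential fit")
    if float(np.ptp(y)) < 1e-12:
        raise FitError("constant series: rate constant unidentifiable")

    def model(t, y0, A, k):
        return y0 + A * np.exp(-k * t)

    y0_init = float(np.clip(y[-1], -0.2, 1.0))
    k_init, A_init = _tail_log_rate(t, np.clip(y - y0_init, 1e-12, None))
    if k_init is None:
        k_init, A_init = 1.0 / float(np.median(t)), float(max(y[0] - y0_init, 0.1))
    starts = [(y0_init, float(np.clip(y[0] - y0_init, 0.01, _AMP_MAX)), k_init)]
    rng = np.random.default_rng(0)
    for _ in range(4):
        starts.append((
            y0_init + rng.normal(0, 0.05),
            float(np.clip(starts[0][1] * rng.lognormal(0, 0.3), 0.01, _AMP_MAX)),
            float(np.clip(k_init * rng.lognormal(0, 0.5), 1.0, _K_MAX)),
        ))
    sigma = _weights(series)
    best = None
    for p0 in starts:
        try:
            popt, pcov = curve_fit(
                model, t, y, p0=p0, sigma=sigma,
                bounds=([-0.2, 0.0, 1e-12], [_AMP_MAX, _AMP_MAX, _K_MAX]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        ss = float(np.sum((y - model(t, *popt)) ** 2))
        if best is None or ss < best[0]:
            best = (ss, popt, pcov)
    if best is None:
        raise FitError("mono-exponential fit failed to converge from all starts")
    _, popt, pcov = best
    return MonoExpFit(
        y0=float(popt[0]), A=float(popt[1]), k=float(popt[2]),
        covariance=pcov, r_squared=_r_squared(y, model(t, *popt)),
    )


def fit_biexponential(series: KineticSeries,
                      force_unit_sum: bool = False) -> BiExpFit:
    """Fit f = A exp(-k1 t) + B exp(-k2 t), returned with k1 >= k2.

    ``force_unit_sum`` constrains A + B = 1 (two-state normalisation);
    default is unconstrained.  Warns when the two rates differ by less than
    10 %, in which case a mono-exponential model suffices.
    """
    t, y = series.aging_times, series.fractions
    if t.size < 6:
        raise FitError("need at least 6 points spanning both decay regimes")
    if float(np.ptp(y)) < 1e-12:
        raise FitError("constant series: rate constants unidentifiable")

    # peeling initialisation: slow from the tail, fast from the remainder
    k2_init, B_init = _tail_log_rate(t, np.clip(y, 1e-12, None))
    if k2_init is None:
        k2_init, B_init = 1.0 / float(t[-1]), float(y[-1])
    rem = y - B_init * np.exp(-k2_init * t)
    k1_init, A_init = _tail_log_rate(t[: max(3, t.size // 2)],
                                     np.clip(rem[: max(3, t.size // 2)], 1e-12, None),
                                     frac=1.0)
    if k1_init is None or k1_init <= k2_init:
        k1_init, A_init = 10.0 * k2_init, float(max(y[0] - B_init, 0.1))
    A_init = float(np.clip(A_init, 0.01, _AMP_MAX))
    B_init = float(np.clip(B_init, 0.01, _AMP_MAX))
    sigma = _weights(series)
    rng = np.random.default_rng(0)
    starts = [(A_init, k1_init, B_init, k2_init)]
    for _ in range(4):
        starts.append((
            float(np.clip(A_init * rng.lognormal(0, 0.3), 0.01, _AMP_MAX)),
            float(np.clip(k1_init * rng.lognormal(0, 0.6), 1.0, _K_MAX)),
            float(np.clip(B_init * rng.lognormal(0, 0.3), 0.01, _AMP_MAX)),
            float(np.clip(k2_init * rng.lognormal(0, 0.6), 1.0, _K_MAX)),
        ))
    best = None
    for A0, k10, B0, k20 in starts:
        try:
            if force_unit_sum:
                def model(t, A, k1, k2):
                    return A * np.exp(-k1 * t) + (1.0 - A) * np.exp(-k2 * t)
                popt, pcov = curve_fit(
                    model, t, y, p0=[A0, k10, k20], sigma=sigma,
                    bounds=([0.0, 1e-12, 1e-12], [1.0, _K_MAX, _K_MAX]),
                    maxfev=40000,
                )
                A, k1, k2 = popt
                B = 1.0 - A
                # covariance expanded to (A, k1, B, k2) with var(B) = var(A)
                pcov4 = np.zeros((4, 4))
                idx = [0, 1, 2]
                sub = pcov
                pcov4[0, 0] = sub[0, 0]
                pcov4[1, 1] = sub[1, 1]
                pcov4[2, 2] = sub[0, 0]
                pcov4[3, 3] = sub[2, 2]
                params, cov = (A, B, k1, k2), pcov4
                fitvals = model(t, *popt)
            else:
                def model(t, A, k1, B, k2):
                    return A * np.exp(-k1 * t) + B * np.exp(-k2 * t)
                popt, pcov = curve_fit(
                    model, t, y, p0=[A0, k10, B0, k20], sigma=sigma,
                    bounds=([0.0, 1e-12, 0.0, 1e-12],
                            [_AMP_MAX, _K_MAX, _AMP_MAX, _K_MAX]),
                    maxfev=40000,
                )
                A, k1, B, k2 = popt
                params, cov = (A, B, k1, k2), pcov
                fitvals = model(t, *popt)
        except (RuntimeError, ValueError):
            continue
        ss = float(np.sum((y - fitvals) ** 2))
        if best is None or ss < best[0]:
            best = (ss, params, cov, fitvals)
    if best is None:
        raise FitError("bi-exponential fit failed to converge from all starts")
    _, (A, B, k1, k2), cov, fitvals = best
    cov = np.asarray(cov)
    if k1 < k2:  # fast component first, by convention
        A, B, k1, k2 = B, A, k2, k1
        perm = [2, 3, 0, 1]  # (A,k1,B,k2) -> (B,k2,A,k1)
        cov = cov[np.ix_(perm, perm)]
    if k2 > 0 and abs(k1 - k2) / k2 < 0.10:
        warnings.warn(
            "rate constants agree within 10%: a mono-exponential model "
            "suffices for this series",
            stacklevel=2,
        )
    return BiExpFit(A=float(A), B=float(B), k1=float(k1), k2=float(k2),
                    covariance=np.asarray(cov),
                    r_squared=_r_squared(y, fitvals))


def dwell_time(fit: MonoExpFit) -> tuple[float, float]:
    """Average dwell time 1/k in us, with propagated uncertainty.

    The uncertainty is Delta(1/k) = Delta(k)/k^2 using the fit's 2-sigma
    interval for k (e.g. k = 7398 s^-1 -> 135 us).
    """
    if fit.k <= 0:
        raise MhqError("rate constant must be > 0")
    dk = fit.two_sigma[2]
    return 1.0 / fit.k * 1e6, dk / fit.k**2 * 1e6


def pseudo_first_order_check(ligand_conc: float, protein_conc: float,
                             min_ratio: float = 50.0) -> tuple[bool, float]:
    """Check the ligand excess required for pseudo-first-order kinetics.

    Returns ``(passes, ratio)``; passes when ligand/protein >= min_ratio
    (inclusive).  A large excess keeps the effective rate constant
    time-independent during the aging window.
    """
    if ligand_conc <= 0 or protein_conc <= 0:
        raise MhqError("concentrations must be > 0")
    ratio = ligand_conc / protein_conc
    return ratio >= min_ratio, ratio
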