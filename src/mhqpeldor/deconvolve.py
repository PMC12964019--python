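"""Two-state deconvolution of background-corrected dipolar traces.

A freeze-quenched sample at aging time t_a contains a mixture of the
ligand-free (apo) and ligand-bound (holo) conformations.  Because the two
states have well-separated interspin distances, the background-corrected
dipolar trace of the mixture is a linear combination of the pure-state
traces,

    MHQ(t) = a * Apo(t) + b * Holo(t),

and the coefficients a, b are the state populations (when constrained to
sum to 1).  Before fitting, all traces are brought to a common modulation
depth by the log-domain scaling exponent f_lambda: raising a trace
elementwise to the power f_lambda that minimises the log-domain mismatch
with the reference.  Traces recorded with different time increments are
compared only at mutually aligned time points, given by the coprime
downsampling factors alpha_i = dt_i / gcd(dt_1, dt_2).

The residual of the linear-combination fit should be thermal noise; a
first-order polynomial fit of the residual with slope and intercept both
indistinguishable from zero (within two standard errors) is the pass
criterion used here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import nnls

from .exceptions import ConditioningError, MhqError, TraceError

__all__ = [
    "CorrectedTrace",
    "ScalingBranch",
    "ScalingResult",
    "DeconvolutionResult",
    "downsampling_factors",
    "modulation_scale",
    "apply_scaling",
    "resample_to_grid",
    "linear_combination_fit",
    "residual_diagnostics",
    "deconvolute",
    "deconvolution_report",
]


@dataclass
class CorrectedTrace:
    """Background-corrected form factor on an integer-ns time grid.

    Values must be strictly positive (the modulation-depth scaling works in
    the log domain) and the first point, at t = 0, is 1 by normalisation.
    """

    t_ns: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.t_ns = np.asarray(self.t_ns)
        self.values = np.asarray(self.values, dtype=float)
        if self.t_ns.shape != self.values.shape or self.t_ns.ndim != 1:
            raise TraceError("t_ns and values must be 1-D and equal length")
        if not np.allclose(self.t_ns, np.round(self.t_ns), atol=1e-9):
            raise TraceError(
                "time grid must be integer-representable in ns; resample first"
            )
        self.t_ns = np.round(self.t_ns).astype(np.int64)
        d = np.diff(self.t_ns)
        if d.size == 0 or np.any(d != d[0]) or d[0] <= 0:
            raise TraceError("time grid must be uniform, increasing, >= 2 points")
        if np.any(self.values <= 0):
            raise TraceError("trace values must be > 0 (log-domain scaling)")

    @property
    def dt_ns(self) -> int:
        return int(self.t_ns[1] - self.t_ns[0])


class ScalingBranch(Enum):
    V2_COARSER = "V2_coarser"
    V1_COARSER = "V1_coarser"
    EQUAL = "equal"


@dataclass(frozen=True)
class ScalingResult:
    f_lambda: float
    alpha_pair: tuple[int, int]
    branch_used: ScalingBranch


@dataclass
class DeconvolutionResult:
    """Apo/holo coefficients with residual diagnostics."""

    a_apo: float
    b_holo: float
    a_2sigma: float
    b_2sigma: float
    forced_sum: bool
    residual: np.ndarray
    fitted: np.ndarray
    t_ns: np.ndarray
    residual_slope: float = math.nan
    residual_intercept: float = math.nan
    residual_slope_se: float = math.nan
    residual_intercept_se: float = math.nan
    r_squared: float = math.nan
    meta: dict = field(default_factory=dict)


def downsampling_factors(dt1: int, dt2: int) -> tuple[int, int]:
    """Coprime alignment factors alpha_i = dt_i / gcd(dt_1, dt_2)."""
    for dt in (dt1, dt2):
        if isinstance(dt, bool) or (not float(dt).is_integer()) or dt <= 0:
            raise TraceError(
                "time increments must be positive integer ns; "
                "resample the traces to an integer-ns grid first"
            )
    g = math.gcd(int(dt1), int(dt2))
    return int(dt1) // g, int(dt2) // g


def _aligned_log_samples(v1: CorrectedTrace, v2: CorrectedTrace):
    """Log-values of both traces at mutually aligned times t = k * lcm(dt)."""
    a1, a2 = downsampling_factors(v1.dt_ns, v2.dt_ns)
    if v1.t_ns[0] != 0 or v2.t_ns[0] != 0:
        raise TraceError("traces must start at t = 0")
    # aligned times are multiples of lcm(dt1, dt2); trace 1 is indexed by
    # a2 (its own partner's factor) and vice versa.  k starts at 1: the
    # first non-zero aligned time point.
    kmax = min((v1.t_ns.size - 1) // a2, (v2.t_ns.size - 1) // a1)
    if kmax < 1:
        raise TraceError("no overlapping aligned time points after t = 0")
    k = np.arange(1, kmax + 1)
    return np.log(v1.values[k * a2]), np.log(v2.values[k * a1]), (a1, a2)


def modulation_scale(v1: CorrectedTrace, v2: CorrectedTrace) -> ScalingResult:
    """Log-domain modulation-depth scaling exponent of v2 onto v1.

    f_lambda = sum(ln V1)^2 / sum(ln V1 ln V2) over the aligned subsample;
    raising v2 elementwise to f_lambda matches its modulation depth to the
    reference v1.  For identical traces f_lambda = 1; for v2 = v1^c it is
    exactly 1/c.
    """
    lv1, lv2, (a1, a2) = _aligned_log_samples(v1, v2)
    denom = float(np.sum(lv1 * lv2))
    if denom == 0.0:
        raise MhqError("degenerate traces: cannot determine scaling exponent")
    f = float(np.sum(lv1 * lv1)) / denom
    if f <= 0:
        raise MhqError(f"non-physical scaling exponent {f:.4g}")
    if v2.dt_ns > v1.dt_ns:
        branch = ScalingBranch.V2_COARSER
    elif v1.dt_ns > v2.dt_ns:
        branch = ScalingBranch.V1_COARSER
    else:
        branch = ScalingBranch.EQUAL
    return ScalingResult(f_lambda=f, alpha_pair=(a1, a2), branch_used=branch)


def apply_scaling(trace: CorrectedTrace, f_lambda: float) -> CorrectedTrace:
    """Elementwise power: the scaled trace is V^f_lambda."""
    return CorrectedTrace(t_ns=trace.t_ns.copy(), values=trace.values**f_lambda)


def resample_to_grid(trace: CorrectedTrace, t_ns: np.ndarray) -> CorrectedTrace:
    """Linear interpolation of a trace onto a target integer-ns grid."""
    t_ns = np.asarray(t_ns, dtype=np.int64)
    if t_ns[0] < trace.t_ns[0] or t_ns[-1] > trace.t_ns[-1]:
        raise TraceError("target grid extends beyond the trace support")
    vals = np.interp(t_ns, trace.t_ns, trace.values)
    return CorrectedTrace(t_ns=t_ns, values=vals)


def linear_combination_fit(mhq: CorrectedTrace, apo: CorrectedTrace,
                           holo: CorrectedTrace, force_sum: bool = True,
                           nonneg: bool = False) -> DeconvolutionResult:
    """Least-squares coefficients of MHQ = a*Apo + b*Holo.

    All three traces must already share a common grid and modulation depth
    (see :func:`deconvolute` for the full pipeline).  With ``force_sum`` the
    one-parameter problem a*Apo + (1-a)*Holo is solved and a, b are direct
    populations; otherwise both coefficients are free and must be
    normalised before interpretation (a warning flag is set in ``meta``).
    ``nonneg`` activates a non-negativity constraint on (a, b).
    """
    if not (mhq.t_ns.shape == apo.t_ns.shape == holo.t_ns.shape) or \
            np.any(mhq.t_ns != apo.t_ns) or np.any(mhq.t_ns != holo.t_ns):
        raise TraceError("traces must share one common time grid; resample first")
    y = mhq.values
    X = np.column_stack([apo.values, holo.values])
    # collinearity guard: unresolvable distributions give a rank-deficient fit
    cond = np.linalg.cond(X)
    if cond > 1e8:
        raise ConditioningError(
            f"apo and holo traces are nearly collinear (cond = {cond:.3g}); "
            "the two states cannot be resolved"
        )
    n = y.size
    if force_sum:
        d = apo.values - holo.values
        a = float((y - holo.values) @ d / (d @ d))
        b = 1.0 - a
        fitted = a * apo.values + b * holo.values
        resid = y - fitted
        dof = max(n - 1, 1)
        s2 = float(resid @ resid) / dof
        var_a = s2 / float(d @ d)
        a_2s = b_2s = 2.0 * math.sqrt(var_a)
    else:
        if nonneg:
            coef, _ = nnls(X, y)
        else:
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        a, b = (float(coef[0]), float(coef[1]))
        fitted = X @ coef
        resid = y - fitted
        dof = max(n - 2, 1)
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(X.T @ X)
        a_2s = 2.0 * math.sqrt(cov[0, 0])
        b_2s = 2.0 * math.sqrt(cov[1, 1])
    if (not nonneg) and (a < 0 or b < 0):
        warnings.warn(
            "negative fitted weight: check that the input traces are "
            "background-corrected, or enable the non-negativity constraint",
            stacklevel=2,
        )
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else math.nan
    result = DeconvolutionResult(
        a_apo=a, b_holo=b, a_2sigma=a_2s, b_2sigma=b_2s,
        forced_sum=force_sum, residual=resid, fitted=fitted,
        t_ns=mhq.t_ns.copy(), r_squared=r2,
        meta={} if force_sum else {"normalize_before_interpretation": True},
    )
    residual_diagnostics(result)
    return result


def residual_diagnostics(result: DeconvolutionResult) -> tuple[float, float, bool]:
    """First-order polynomial fit of the residual vs time.

    Returns ``(slope, intercept, verdict)`` where the verdict passes when
    both the slope and the intercept are below twice their own standard
    errors, i.e. statistically indistinguishable from zero -- the signature
    of a residual dominated by thermal noise.  Slope is per us.
    """
    t = result.t_ns * 1e-3  # us
    y = result.residual
    n = y.size
    X = np.column_stack([t, np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fit = X @ coef
    dof = max(n - 2, 1)
    s2 = float(np.sum((y - fit) ** 2)) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    slope, intercept = float(coef[0]), float(coef[1])
    se_slope, se_intercept = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    verdict = abs(slope) <= 2 * se_slope and abs(intercept) <= 2 * se_intercept
    result.residual_slope = slope
    result.residual_intercept = intercept
    result.residual_slope_se = se_slope
    result.residual_intercept_se = se_intercept
    return slope, intercept, verdict


def deconvolute(mhq: CorrectedTrace, apo: CorrectedTrace, holo: CorrectedTrace,
                force_sum: bool = True, nonneg: bool = False) -> DeconvolutionResult:
    """Full deconvolution pipeline.

    1. scale the holo and mixture traces to the modulation depth of the apo
       reference (log-domain exponent over aligned subsamples);
    2. resample everything onto the coarsest common grid (linear
       interpolation);
    3. solve the linear combination and attach residual diagnostics.
    """
    s_holo = modulation_scale(apo, holo)
    s_mhq = modulation_scale(apo, mhq)
    holo_sc = apply_scaling(holo, s_holo.f_lambda)
    mhq_sc = apply_scaling(mhq, s_mhq.f_lambda)
    dt = max(apo.dt_ns, holo.dt_ns, mhq.dt_ns)
    t_end = min(apo.t_ns[-1], holo.t_ns[-1], mhq.t_ns[-1])
    grid = np.arange(0, t_end + 1, dt, dtype=np.int64)
    res = linear_combination_fit(
        resample_to_grid(mhq_sc, grid),
        resample_to_grid(apo, grid),
        resample_to_grid(holo_sc, grid),
        force_sum=force_sum, nonneg=nonneg,
    )
    res.meta["f_lambda_holo"] = s_holo.f_lambda
    res.meta["f_lambda_mhq"] = s_mhq.f_lambda
    return res


def deconvolution_report(result: DeconvolutionResult, inputs: dict,
                         outdir, save_ascii: bool = False,
                         save_plots: bool = False,
                         report: bool = False) -> list:
    """Write deconvolution artifacts to ``outdir``.

    ``inputs`` maps names ('apo', 'holo', 'mhq') to the (scaled, common-grid)
    :class:`CorrectedTrace` objects used in the fit.  With all toggles off,
    nothing is written and the in-memory result stands alone.  Returns the
    list of paths written.
    """
    from pathlib import Path

    outdir = Path(outdir)
    written: list = []
    if save_ascii or save_plots or report:
        outdir.mkdir(parents=True, exist_ok=True)
    if save_ascii:
        # four artifacts: scaled components, in-silico mix, residual
        for name in ("apo", "holo"):
            tr = inputs[name]
            p = outdir / f"{name}_scaled.dat"
            np.savetxt(p, np.column_stack([tr.t_ns, tr.values]),
                       header="t_ns value", fmt="%d %.10g")
            written.append(p)
        p = outdir / "mix_insilico.dat"
        np.savetxt(p, np.column_stack([result.t_ns, result.fitted]),
                   header="t_ns value", fmt="%d %.10g")
        written.append(p)
        p = outdir / "residual.dat"
        np.savetxt(p, np.column_stack([result.t_ns, result.residual]),
                   header="t_ns residual", fmt="%d %.10g")
        written.append(p)
    if save_plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(6, 6))
        t = result.t_ns * 1e-3
        for name, style in (("apo", "C0-"), ("holo", "C1-"), ("mhq", "k.")):
            ax1.plot(inputs[name].t_ns * 1e-3, inputs[name].values, style,
                     label=name, ms=3)
        ax1.plot(t, result.fitted, "r--", label="in-silico mix")
        ax1.set_ylabel("form factor")
        ax1.legend(fontsize=8)
        ax2.plot(t, result.residual, "k-", lw=0.8)
        ax2.axhline(0.0, color="r", lw=0.8)
        ax2.set_xlabel("t (us)")
        ax2.set_ylabel("residual")
        p = outdir / "deconvolution.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(p)
    if report:
        p = outdir / "deconvolution_report.txt"
        lines = [
            "Two-state deconvolution report",
            "==============================",
            f"a (apo)  = {result.a_apo:.4f} +/- {result.a_2sigma:.4f} (2 sigma)",
            f"b (holo) = {result.b_holo:.4f} +/- {result.b_2sigma:.4f} (2 sigma)",
            f"a + b forced to 1: {result.forced_sum}",
            f"R^2 = {result.r_squared:.6f}",
            f"residual slope     = {result.residual_slope:.4g} per us "
            f"(SE {result.residual_slope_se:.4g})",
            f"residual intercept = {result.residual_intercept:.4g} "
            f"(SE {result.residual_intercept_se:.4g})",
        ]
        for k, v in result.meta.items():
            lines.append(f"{k} = {v}")
        p.write_text("\n".join(lines) + "\n")
        written.append(p)
    return written
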