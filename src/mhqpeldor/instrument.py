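"""Physical model of the microsecond freeze-hyperquenching (MHQ) instrument.

The MHQ device mixes a protein solution with a ligand solution in a
micromixer and sprays the mixture as a thin jet onto the wall of a
liquid-nitrogen-cooled rotating cylinder ("cold-plate"), where it freezes
within tens of microseconds.  The elapsed reaction ("aging") time is set by
the flight distance between the nozzle and the cold-plate wall.  This module
implements the arithmetic that plans such an experiment:

* jet velocity, transport time and aging time as a function of the
  nozzle-to-cold-plate distance;
* dead volume of the tubing between the sample loops and the mixer, and the
  resulting loop-to-mixer transit time;
* the mixer-arm velocity, dead time and optimal wait-time that synchronise
  sample ejection with the vertical sweep of the mixer arm;
* the parabolic dilution profile measured with a dye tracer, and a
  one-parameter least-squares fit of its symmetry axis;
* a cylinder model of sample deposition (number of layers, film thickness);
* the command-string format understood by the step-motor control software.

Units follow the instrument conventions: lengths in mm, volumes in uL
(1 mm^3 = 1 uL), flows in uL/s, aging times in us, wait times in s.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .exceptions import FitError, InvalidFlowError, InvalidGeometryError, OutOfModelError
from ._utils import round_half_up

__all__ = [
    "MhqGeometry",
    "FlowSettings",
    "DilutionSeries",
    "DilutionFit",
    "DepositionReport",
    "WaitTimeReport",
    "jet_velocity",
    "transport_time",
    "aging_time",
    "aging_time_table",
    "calibrate_jet_offset",
    "dead_volume",
    "loop_to_mixer_time",
    "mixer_arm_velocity",
    "mixer_dead_time",
    "optimal_wait_time",
    "dilution_factor",
    "dilution_ratio",
    "fit_dilution_profile",
    "deposition_model",
    "lincontrol_command",
    "stock_concentration",
    "TABLE_DISTANCES_MM",
]

#: Nozzle-to-cold-plate distances (mm) of the standard aging-time table.
TABLE_DISTANCES_MM = (3, 5, 7, 10, 17, 23, 29, 41, 52, 61, 72)


@dataclass(frozen=True)
class MhqGeometry:
    """All fixed dimensions and timing constants of the MHQ device.

    Defaults reproduce the reference instrument.

    Attributes
    ----------
    orifice_radius : float
        Radius of the mixer orifice in mm (20 um diameter orifice -> 0.01).
    tubing_length_h : float
        Length of the tubing from sample loop to mixer, mm.
    tubing_radius_r : float
        Inner radius of that tubing, mm.
    coldplate_inner_radius : float
        Inner radius of the cold-plate cylinder, mm.
    coldplate_coverage_dc : float
        Vertical travel span of the mixer arm inside the cold-plate, mm.
    deposition_height : float
        Height of the deposited sample band on the cold-plate wall, mm.
        Distinct from (and smaller than) the mixer travel span because the
        jet only paints the wall over part of the sweep.
    approach_distance_dmc : float
        Distance from the mixer-arm start position to the top of the
        cold-plate, mm.
    microsteps_per_span : float
        Step-motor microsteps corresponding to ``microstep_span_mm`` of
        travel (1e5 usteps per 12.4 mm).
    microstep_span_mm : float
        Travel corresponding to ``microsteps_per_span`` microsteps, mm.
    internal_jet_offset : float
        Effective extra flight path (mm) before the nozzle exit, calibrated
        once from the measured transport-time table; accounts for the
        nonzero intercept of transport time vs distance.
    cryofixation_time_tc : float
        Freezing time on the cold-plate, us.
    mixing_time_tm : float
        Residence time in the micromixer, us (negligible, < 1 us).
    coldplate_rpm : float
        Cold-plate rotation rate, revolutions per minute.
    """

    orifice_radius: float = 0.01
    tubing_length_h: float = 1.85e3
    tubing_radius_r: float = 1.27e-1
    coldplate_inner_radius: float = 65.0
    coldplate_coverage_dc: float = 49.6
    deposition_height: float = 43.4
    approach_distance_dmc: float = 18.6
    microsteps_per_span: float = 1.0e5
    microstep_span_mm: float = 12.4
    internal_jet_offset: float = 2.0
    cryofixation_time_tc: float = 40.0
    mixing_time_tm: float = 0.0
    coldplate_rpm: float = 7000.0

    def __post_init__(self) -> None:
        for name in (
            "orifice_radius",
            "tubing_length_h",
            "tubing_radius_r",
            "coldplate_inner_radius",
            "coldplate_coverage_dc",
            "deposition_height",
            "approach_distance_dmc",
            "microsteps_per_span",
            "microstep_span_mm",
        ):
            if getattr(self, name) <= 0:
                raise InvalidGeometryError(f"{name} must be strictly positive")
        if self.cryofixation_time_tc < 0 or self.mixing_time_tm < 0:
            raise InvalidGeometryError("timing constants must be >= 0")
        if self.internal_jet_offset < 0:
            raise InvalidGeometryError("internal_jet_offset must be >= 0")

    @property
    def microsteps_per_mm(self) -> float:
        """Step-motor conversion factor, usteps per mm."""
        return self.microsteps_per_span / self.microstep_span_mm


@dataclass(frozen=True)
class FlowSettings:
    """HPLC pump settings.

    Attributes
    ----------
    per_channel_flow : float
        Volumetric flow per channel, uL/s.
    n_channels : int
        Number of channels (protein + ligand = 2).
    """

    per_channel_flow: float
    n_channels: int = 2

    def __post_init__(self) -> None:
        if self.per_channel_flow <= 0:
            raise InvalidFlowError("per_channel_flow must be > 0")
        if self.n_channels < 1:
            raise InvalidFlowError("n_channels must be >= 1")

    @property
    def total_flow(self) -> float:
        """Combined flow of all channels, uL/s."""
        return self.n_channels * self.per_channel_flow

    @classmethod
    def from_total_ml_per_min(cls, total_ml_min: float, n_channels: int = 2) -> "FlowSettings":
        """Build from a combined flow in mL/min (instrument display units)."""
        per_channel = total_ml_min * 1000.0 / 60.0 / n_channels
        return cls(per_channel_flow=per_channel, n_channels=n_channels)


@dataclass
class DilutionSeries:
    """Measured dye dilution series: absorbance ratio vs mixer-arm wait-time.

    ``dilution_ratios`` holds the ratio A280(collected)/A280(stock), i.e. the
    *inverse* of a dilution factor, bounded by [0, 1].
    """

    wait_times: np.ndarray
    dilution_ratios: np.ndarray
    replicate_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wait_times = np.asarray(self.wait_times, dtype=float)
        self.dilution_ratios = np.asarray(self.dilution_ratios, dtype=float)
        if self.wait_times.shape != self.dilution_ratios.shape:
            raise ValueError("wait_times and dilution_ratios must have equal length")
        if self.replicate_sd is not None:
            self.replicate_sd = np.asarray(self.replicate_sd, dtype=float)
            if self.replicate_sd.shape != self.wait_times.shape:
                raise ValueError("replicate_sd length mismatch")


@dataclass(frozen=True)
class DilutionFit:
    """Result of the one-parameter dilution-profile fit."""

    t0: float
    t0_2sigma: float
    residuals: np.ndarray
    fitted: np.ndarray


@dataclass(frozen=True)
class DepositionReport:
    """Cylinder-model summary of sample deposition on the cold-plate."""

    jet_length: float          # mm
    circumference_U: float     # mm
    deposition_speed: float    # mm/s
    n_layers: float            # dimensionless
    film_thickness_x: float    # um


@dataclass(frozen=True)
class WaitTimeReport:
    """Optimal mixer-arm wait-time with its ingredients."""

    wait_time_s: float
    loop_to_mixer_s: float
    mixer_dead_time_s: float
    arm_velocity_mm_s: float
    arm_velocity_usteps_s: float
    reachable: bool            # False if the arm cannot be in position in time


# ---------------------------------------------------------------------------
# jet transport and aging times
# ---------------------------------------------------------------------------

def jet_velocity(geom: MhqGeometry, flow: FlowSettings) -> float:
    """Linear jet velocity in mm/s.

    The jet carries the total volumetric flow through the orifice
    cross-section, so v = f_total / (pi * r_orifice^2).  With 2 mL/min
    through a 20 um orifice this is about 1.06e5 mm/s (~106 m/s).
    """
    if geom.orifice_radius <= 0:
        raise InvalidGeometryError("orifice radius must be > 0")
    return flow.total_flow / (math.pi * geom.orifice_radius**2)


def transport_time(geom: MhqGeometry, flow: FlowSettings, nozzle_distance: float) -> float:
    """Jet flight time from mixer to cold-plate wall, us.

    ``nozzle_distance`` is the measured nozzle-outlet to cold-plate distance
    in mm; the calibrated ``internal_jet_offset`` (pre-nozzle path) is added
    before dividing by the jet velocity.
    """
    if nozzle_distance < 0:
        raise InvalidGeometryError("nozzle_distance must be >= 0")
    path_mm = nozzle_distance + geom.internal_jet_offset
    return path_mm / jet_velocity(geom, flow) * 1e6


def aging_time(geom: MhqGeometry, flow: FlowSettings, nozzle_distance: float) -> float:
    """Aging time t_a = t_m + 0.9 t_t + t_c, in us (unrounded).

    The 0.9 prefactor on the transport time is an empirical slip factor from
    laser Doppler anemometry; t_m is the (negligible) mixing time and t_c the
    cryofixation time on the cold-plate (40 us).
    """
    t_t = transport_time(geom, flow, nozzle_distance)
    return geom.mixing_time_tm + 0.9 * t_t + geom.cryofixation_time_tc


def aging_time_table(
    geom: MhqGeometry,
    flow: FlowSettings,
    distances_mm=TABLE_DISTANCES_MM,
):
    """Aging-time table for a list of nozzle distances.

    Returns a :class:`pandas.DataFrame` with columns ``distance_mm``,
    ``tt_us`` and ``ta_us``, both times rounded half-up to integer us, as the
    planning table is printed.
    """
    import pandas as pd

    rows = []
    for d in distances_mm:
        tt = transport_time(geom, flow, d)
        ta = aging_time(geom, flow, d)
        rows.append(
            {
                "distance_mm": d,
                "tt_us": int(round_half_up(tt)),
                "ta_us": int(round_half_up(ta)),
            }
        )
    return pd.DataFrame(rows)


def calibrate_jet_offset(distances_mm, transport_times_us, geom: MhqGeometry,
                         flow: FlowSettings) -> float:
    """Calibrate ``internal_jet_offset`` from a measured transport-time table.

    A straight line through (distance, t_t) has slope 1/v_jet and an
    intercept attributed to the pre-nozzle path; the offset is the intercept
    converted back to mm with the model jet velocity.
    """
    d = np.asarray(distances_mm, dtype=float)
    t = np.asarray(transport_times_us, dtype=float)
    if d.size < 2:
        raise FitError("need at least two calibration points")
    slope, intercept = np.polyfit(d, t, 1)
    return float(intercept * jet_velocity(geom, flow) * 1e-6)


# ---------------------------------------------------------------------------
# dead volume, mixer-arm synchronisation
# ---------------------------------------------------------------------------

def dead_volume(geom: MhqGeometry) -> float:
    """Tubing dead volume per channel, V_d = pi r^2 h, in uL."""
    return math.pi * geom.tubing_radius_r**2 * geom.tubing_length_h


def loop_to_mixer_time(geom: MhqGeometry, flow: FlowSettings) -> float:
    """Transit time of the sample from loop to mixer, V_d / f_channel, in s."""
    if flow.per_channel_flow <= 0:
        raise InvalidFlowError("per-channel flow must be > 0")
    return dead_volume(geom) / flow.per_channel_flow


def mixer_arm_velocity(geom: MhqGeometry, flow: FlowSettings,
                       sample_volume: float) -> tuple[float, float]:
    """Optimal mixer-arm vertical velocity.

    The arm must traverse the coverage span down and up (2 d_c) during the
    time the whole sample volume is expelled (V_s / f_total), so
    v_m = 2 d_c f_total / V_s.  Returns ``(mm_per_s, usteps_per_s)``.
    """
    if sample_volume <= 0:
        raise InvalidFlowError("sample_volume must be > 0")
    v_mm = 2.0 * geom.coldplate_coverage_dc * flow.total_flow / sample_volume
    return v_mm, v_mm * geom.microsteps_per_mm


def mixer_dead_time(geom: MhqGeometry, v_m: float) -> float:
    """Time for the arm to reach the top of the cold-plate, d_m->c / v_m, s."""
    if v_m <= 0:
        raise InvalidFlowError("mixer-arm velocity must be > 0")
    return geom.approach_distance_dmc / v_m


def optimal_wait_time(geom: MhqGeometry, flow: FlowSettings,
                      sample_volume: float) -> WaitTimeReport:
    """Optimal mixer-arm wait-time t_w = t_s->m - t_d.

    If the result is negative the arm cannot reach position before the
    sample arrives; a warning is issued and the (negative) value returned
    with ``reachable=False``.
    """
    t_sm = loop_to_mixer_time(geom, flow)
    v_mm, v_usteps = mixer_arm_velocity(geom, flow, sample_volume)
    t_d = mixer_dead_time(geom, v_mm)
    t_w = t_sm - t_d
    reachable = t_w >= 0
    if not reachable:
        warnings.warn(
            "negative wait-time: the mixer arm cannot reach position before "
            "the sample arrives at the mixer",
            stacklevel=2,
        )
    return WaitTimeReport(
        wait_time_s=t_w,
        loop_to_mixer_s=t_sm,
        mixer_dead_time_s=t_d,
        arm_velocity_mm_s=v_mm,
        arm_velocity_usteps_s=v_usteps,
        reachable=reachable,
    )


# ---------------------------------------------------------------------------
# dilution profile
# ---------------------------------------------------------------------------

def dilution_factor(t_w: float, t_0: float, k: float, V_dye: float,
                    V_total: float) -> float:
    """Dilution factor f(t_w) = V_total / (V_dye - k (t_0 - t_w)^2).

    A parabola in the denominator: the minimum dilution V_total/V_dye occurs
    at t_w = t_0; moving away from t_0 loses dye and increases dilution.
    Outside the domain where the denominator is positive the model does not
    apply (all dye lost) and :class:`OutOfModelError` is raised.
    """
    if V_dye <= 0 or V_total <= 0:
        raise InvalidFlowError("volumes must be > 0")
    denom = V_dye - k * (t_0 - t_w) ** 2
    if denom <= 0:
        raise OutOfModelError(
            "wait-time too far from t_0: dilution model denominator <= 0"
        )
    return V_total / denom


def dilution_ratio(t_w, t_0: float, k: float, V_dye: float, V_total: float):
    """Absorbance-ratio representation 1/f(t_w), clamped to >= 0.

    This is what is actually measured (collected A280 over stock A280); far
    from t_0 no dye is collected and the ratio floors at zero.
    """
    t_w = np.asarray(t_w, dtype=float)
    return np.clip((V_dye - k * (t_0 - t_w) ** 2) / V_total, 0.0, None)


def fit_dilution_profile(series: DilutionSeries, k_fixed: float,
                         V_dye: float, V_total: float) -> DilutionFit:
    """Least-squares fit of the parabola symmetry axis t_0.

    Only t_0 is free; the flow constant k is fixed to the per-channel flow.
    The fit is performed on the measured absorbance-ratio representation.
    A coarse grid search initialises the refinement so the clamped (zero)
    region cannot trap the optimiser.  The 2-sigma interval comes from the
    Jacobian at the solution.
    """
    tw = series.wait_times
    y = series.dilution_ratios
    if tw.size < 3:
        raise FitError("need at least 3 dilution points")
    if np.ptp(tw) == 0:
        raise FitError("degenerate series: all wait-times equal")

    def model(t0):
        return dilution_ratio(tw, t0, k_fixed, V_dye, V_total)

    grid = np.arange(tw.min() - 2.0, tw.max() + 2.0, 0.01)
    sse = [float(np.sum((model(g) - y) ** 2)) for g in grid]
    t0_init = float(grid[int(np.argmin(sse))])
    res = least_squares(lambda p: model(p[0]) - y, x0=[t0_init])
    if not res.success:
        raise FitError(f"dilution fit did not converge: {res.message}")
    dof = max(tw.size - 1, 1)
    s2 = 2.0 * res.cost / dof
    jtj = res.jac.T @ res.jac
    if jtj[0, 0] <= 0:
        raise FitError("dilution fit Jacobian is singular")
    se = math.sqrt(s2 / jtj[0, 0])
    fitted = model(res.x[0])
    return DilutionFit(
        t0=float(res.x[0]),
        t0_2sigma=2.0 * se,
        residuals=y - fitted,
        fitted=fitted,
    )


# ---------------------------------------------------------------------------
# deposition model
# ---------------------------------------------------------------------------

def deposition_model(geom: MhqGeometry, flow: FlowSettings,
                     sample_volume: float) -> DepositionReport:
    """Cylinder model of sample deposition on the rotating cold-plate.

    The jet is modelled as a cylinder of length l_jet = V_s / (pi r_jet^2).
    The wall moves under the jet at v_deposition = (rpm/60) * U with
    U = 2 pi r_cold-plate, so depositing the jet as a single layer would take
    t_theory = l_jet / v_deposition, while the sample is actually expelled in
    t_sample = V_s / f_total; their ratio is the number of layers.  The total
    film thickness treats the deposit as a cuboid of area U x deposition
    height: x = V_s / (U * d_dep).
    """
    if sample_volume <= 0:
        raise InvalidFlowError("sample_volume must be > 0")
    l_jet = sample_volume / (math.pi * geom.orifice_radius**2)  # mm
    U = 2.0 * math.pi * geom.coldplate_inner_radius              # mm
    v_dep = geom.coldplate_rpm / 60.0 * U                        # mm/s
    t_theory = l_jet / v_dep                                     # s
    t_sample = sample_volume / flow.total_flow                   # s
    n_layers = t_theory / t_sample
    x_um = sample_volume / (U * geom.deposition_height) * 1e3    # mm -> um
    return DepositionReport(
        jet_length=l_jet,
        circumference_U=U,
        deposition_speed=v_dep,
        n_layers=n_layers,
        film_thickness_x=x_um,
    )


# ---------------------------------------------------------------------------
# step-motor command formatting, sample-prep arithmetic
# ---------------------------------------------------------------------------

def lincontrol_command(wait_ms: int, down_pos: int, home_pos: int) -> str:
    """Format a mixer-arm program string for the step-motor software.

    ``/1H04M{wait}A{down}A{home}R``: controller address 1, trigger on the
    injector signal, wait ``wait_ms`` milliseconds, move to the absolute
    down position, return to the home position.
    """
    for name, v in (("wait_ms", wait_ms), ("down_pos", down_pos), ("home_pos", home_pos)):
        if isinstance(v, bool) or not isinstance(v, (int, np.integer)):
            raise TypeError(f"{name} must be an integer, got {v!r}")
    if wait_ms < 0:
        raise ValueError("wait_ms must be >= 0")
    return f"/1H04M{int(wait_ms)}A{int(down_pos)}A{int(home_pos)}R"


def stock_concentration(mass_mg: float, molar_mass_g_mol: float,
                        volume_ml: float) -> float:
    """Concentration of a dissolved stock in mM (e.g. the dye tracer)."""
    if molar_mass_g_mol <= 0 or volume_ml <= 0:
        raise ValueError("molar mass and volume must be > 0")
    return mass_mg / molar_mass_g_mol / (volume_ml / 1000.0)
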