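"""Continuous-wave EPR quantification.

Covers the two CW-EPR bookkeeping tasks of the freeze-quench workflow:

* spin counting by double integration of the first-derivative spectrum
  (labeling efficiency of a doubly spin-labeled construct), and
* high-spin / low-spin Fe(III) state fractions of the molecular-timer
  reaction, using peak-to-peak amplitudes with an empirical normalization
  factor NF that equalises high- and low-spin intensities for equal spin
  counts.

Absolute spin concentrations require an instrument calibration constant
(area per uM for the given resonator and settings); quantification here is
relative, with the calibration factor supplied by the user.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import constants as _const
from scipy.integrate import cumulative_trapezoid

from .exceptions import MhqError

__all__ = [
    "Spectrum",
    "StateAmplitudes",
    "double_integral",
    "peak_to_peak",
    "labeling_efficiency",
    "apo_fraction",
    "normalization_factor",
    "g_to_field",
    "spins_from_area",
]


@dataclass
class Spectrum:
    """First-derivative CW-EPR spectrum with signal-free baseline regions.

    ``baseline_regions`` is a pair of (low, high) field windows in G, one at
    each end of the sweep, used to anchor the linear baseline (record 10-20 G
    of baseline on either side of the signal).
    """

    field_G: np.ndarray
    intensity: np.ndarray
    baseline_regions: tuple[tuple[float, float], tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.field_G = np.asarray(self.field_G, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.field_G.shape != self.intensity.shape or self.field_G.ndim != 1:
            raise MhqError("field and intensity must be 1-D and equal length")
        if np.any(np.diff(self.field_G) <= 0):
            raise MhqError("field axis must be strictly increasing")
        if self.baseline_regions is not None:
            (l1, h1), (l2, h2) = self.baseline_regions
            lo, hi = self.field_G[0], self.field_G[-1]
            for a, b in ((l1, h1), (l2, h2)):
                if a >= b or a < lo - 1e-9 or b > hi + 1e-9:
                    raise MhqError("baseline regions must lie within the sweep")
            if max(l1, l2) < min(h1, h2):
                raise MhqError("baseline regions must not overlap each other")


def _baseline_mask(spec: Spectrum) -> np.ndarray:
    (l1, h1), (l2, h2) = spec.baseline_regions
    B = spec.field_G
    return ((B >= l1) & (B <= h1)) | ((B >= l2) & (B <= h2))


def double_integral(spec: Spectrum) -> tuple[float, np.ndarray]:
    """Double integral of a baseline-corrected first-derivative spectrum.

    A first-order (linear) baseline is fitted to the two signal-free regions
    and subtracted; the corrected derivative is then integrated twice by
    cumulative trapezoid.  Returns ``(area, cumulative_trace)`` where area is
    the final value of the cumulative double-integral trace (a.u. * G^2),
    proportional to the number of spins.

    A warning is issued when the double-integral trace decreases noticeably
    between the baseline regions, which indicates a poor baseline or phase
    error (the trace should increase continuously over the signal region).
    """
    if spec.baseline_regions is None:
        raise MhqError("baseline regions must be defined for double integration")
    mask = _baseline_mask(spec)
    if mask.sum() < 4:
        raise MhqError("baseline regions contain too few points")
    coef = np.polyfit(spec.field_G[mask], spec.intensity[mask], 1)
    corrected = spec.intensity - np.polyval(coef, spec.field_G)
    absorption = cumulative_trapezoid(corrected, spec.field_G, initial=0.0)
    di = cumulative_trapezoid(absorption, spec.field_G, initial=0.0)
    area = float(di[-1])
    inner = ~mask
    if inner.any():
        steps = np.diff(di[inner])
        drop = float(-steps[steps < 0].sum()) if steps.size else 0.0
        if area != 0 and drop > 0.02 * abs(area):
            warnings.warn(
                "double-integral trace is not monotonically non-decreasing "
                "over the signal region; verify baseline and signal phase",
                stacklevel=2,
            )
    return area, di


def peak_to_peak(spec: Spectrum, window: tuple[float, float]) -> float:
    """Peak-to-peak amplitude (max - min) of the derivative signal in a window."""
    lo, hi = window
    m = (spec.field_G >= lo) & (spec.field_G <= hi)
    if not m.any():
        raise MhqError("amplitude window contains no points")
    return float(spec.intensity[m].max() - spec.intensity[m].min())


def labeling_efficiency(spin_conc_uM: float, protein_conc_uM: float,
                        n_sites: int = 2) -> float:
    """Spin-labeling efficiency in percent: c(spins) / (n * c(protein)) * 100.

    ``n_sites`` is the number of labeling sites per protein (2 for a doubly
    labeled construct).  Warns below 75 %, the recommended minimum for
    good-quality dipolar data.
    """
    if protein_conc_uM <= 0:
        raise MhqError("protein concentration must be > 0")
    if spin_conc_uM < 0 or n_sites < 1:
        raise MhqError("invalid spin concentration or site count")
    eff = spin_conc_uM / (n_sites * protein_conc_uM) * 100.0
    if eff < 75.0:
        warnings.warn(
            f"labeling efficiency {eff:.1f}% is below the recommended 75%",
            stacklevel=2,
        )
    return eff


@dataclass(frozen=True)
class StateAmplitudes:
    """Peak-to-peak amplitudes of the two Fe(III) marker features.

    ``i_hs_apo``: the g_perp ~ 5.8 feature of high-spin Fe(III) (apo state);
    ``i_ls_holo``: the g_yy ~ 2.2 feature of low-spin Fe(III) (holo state);
    ``nf``: normalization factor equalising the two for equal spin counts.
    """

    i_hs_apo: float
    i_ls_holo: float
    nf: float

    def __post_init__(self) -> None:
        if self.i_hs_apo < 0 or self.i_ls_holo < 0:
            raise MhqError("amplitudes must be >= 0")
        if self.nf <= 0:
            raise MhqError("normalization factor must be > 0")


def apo_fraction(amps: StateAmplitudes) -> float:
    """High-spin (apo) state percentage.

    %hs_apo = I(hs) / (I(hs) + NF * I(ls)) * 100; the complementary holo
    fraction is 100 - %hs_apo since the two states sum to unity.
    """
    denom = amps.i_hs_apo + amps.nf * amps.i_ls_holo
    if denom == 0:
        raise MhqError("both amplitudes are zero: fraction undefined")
    return amps.i_hs_apo / denom * 100.0


def normalization_factor(i_hs_ref: float, i_ls_ref: float) -> float:
    """NF = I(hs) / I(ls) measured on calibration samples of equal spin count.

    Depends on spectrometer and measurement settings (relaxation and
    saturation differ between the spin states); derive it case by case.
    """
    if i_ls_ref == 0:
        raise MhqError("low-spin reference amplitude must be non-zero")
    if i_hs_ref <= 0 or i_ls_ref < 0:
        raise MhqError("reference amplitudes must be > 0")
    return i_hs_ref / i_ls_ref


def g_to_field(g: float, freq_GHz: float) -> float:
    """Resonance field in G for a given g-value and microwave frequency."""
    if g <= 0 or freq_GHz <= 0:
        raise MhqError("g and frequency must be > 0")
    tesla = _const.h * freq_GHz * 1e9 / (g * _const.value("Bohr magneton"))
    return tesla * 1e4


def spins_from_area(area: float, calibration_area_per_uM: float) -> float:
    """Relative spin concentration (uM) from a double-integral area.

    ``calibration_area_per_uM`` is the instrument/resonator calibration
    constant measured on a concentration standard under identical settings.
    """
    if calibration_area_per_uM <= 0:
        raise MhqError("calibration constant must be > 0")
    return area / calibration_area_per_uM
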