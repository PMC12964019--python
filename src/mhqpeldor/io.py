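"""Plain-text readers and writers.

Dipolar traces travel as two- or three-column ASCII (time, real[, imag])
with '#' comment headers carrying units and modulation depth; CW spectra as
two-column (field G, intensity); kinetic tables and dilution series as
delimited tables.  Readers tolerate comma or whitespace delimiters.  Trace
times may be in ns or us, declared either in the header (``# units: ns``)
or by the ``units`` argument.
"""

from __future__ import annotations

import io as _io
import re
from pathlib import Path

import numpy as np
import yaml

from .cwepr import Spectrum
from .dipolar import DipolarTrace
from .exceptions import TraceError
from .instrument import DilutionSeries, FlowSettings, MhqGeometry
from .kinetics import KineticSeries

__all__ = [
    "read_trace",
    "write_trace",
    "read_spectrum",
    "write_spectrum",
    "read_kinetic_table",
    "read_dilution_table",
    "load_config",
]


def _read_columns(path):
    """Numeric columns from a '#'-commented ASCII file; header dict too."""
    header = {}
    rows = []
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            m = re.match(r"#\s*([\w.\-]+)\s*[:=]\s*(.+)$", s)
            if m:
                header[m.group(1).lower()] = m.group(2).strip()
            continue
        rows.append([float(x) for x in re.split(r"[,\s]+", s) if x])
    if not rows:
        raise TraceError(f"no data rows in {path}")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise TraceError(f"ragged columns in {path}")
    return np.asarray(rows, dtype=float), header


def read_trace(path, units: str | None = None) -> DipolarTrace:
    """Read a dipolar trace from two/three-column ASCII.

    ``units`` ('ns' or 'us') overrides the header declaration; without
    either, ns is assumed (the common convention for exported traces).
    """
    data, header = _read_columns(path)
    if data.shape[1] not in (2, 3):
        raise TraceError("trace files must have 2 or 3 columns")
    unit = (units or header.get("units", "ns")).lower()
    if unit not in ("ns", "us"):
        raise TraceError(f"unknown time unit {unit!r}")
    t = data[:, 0] * (1e-3 if unit == "ns" else 1.0)
    imag = data[:, 2] if data.shape[1] == 3 else None
    delta = float(header["delta"]) if "delta" in header else None
    return DipolarTrace(t_us=t, real=data[:, 1], imag=imag,
                        modulation_depth=delta, meta={"source": str(path)})


def write_trace(trace: DipolarTrace, path, units: str = "ns") -> None:
    """Write a trace with a self-describing header."""
    scale = 1e3 if units == "ns" else 1.0
    cols = [trace.t_us * scale, trace.real]
    if trace.imag is not None:
        cols.append(trace.imag)
    lines = [f"# units: {units}"]
    if trace.modulation_depth is not None:
        lines.append(f"# delta: {trace.modulation_depth}")
    for k, v in trace.meta.items():
        lines.append(f"# {k}: {v}")
    buf = _io.StringIO()
    np.savetxt(buf, np.column_stack(cols), fmt="%.10g")
    Path(path).write_text("\n".join(lines) + "\n" + buf.getvalue())


def read_spectrum(path, baseline_regions=None) -> Spectrum:
    """Read a first-derivative spectrum (field G, intensity)."""
    data, _ = _read_columns(path)
    if data.shape[1] != 2:
        raise TraceError("spectrum files must have 2 columns")
    return Spectrum(field_G=data[:, 0], intensity=data[:, 1],
                    baseline_regions=baseline_regions)


def write_spectrum(spec: Spectrum, path) -> None:
    np.savetxt(path, np.column_stack([spec.field_G, spec.intensity]),
               header="field_G intensity", fmt="%.10g")


def read_kinetic_table(path) -> KineticSeries:
    """Read (aging_time_s, fraction[, sd_2sigma]) from a delimited table."""
    data, header = _read_columns(path)
    if data.shape[1] < 2:
        raise TraceError("kinetic tables need at least 2 columns")
    sd = data[:, 2] if data.shape[1] >= 3 else None
    n_rep = int(header.get("n_replicates", 1))
    return KineticSeries(aging_times=data[:, 0], fractions=data[:, 1],
                         sd_2sigma=sd, n_replicates=n_rep)


def read_dilution_table(path) -> DilutionSeries:
    """Read (wait_time_s, ratio[, sd]) from a delimited table."""
    data, _ = _read_columns(path)
    sd = data[:, 2] if data.shape[1] >= 3 else None
    return DilutionSeries(wait_times=data[:, 0], dilution_ratios=data[:, 1],
                          replicate_sd=sd)


def load_config(path) -> tuple[MhqGeometry, FlowSettings, dict]:
    """Load instrument configuration from a flat-section YAML file.

    Sections: ``geometry`` (field names of :class:`MhqGeometry`), ``flow``
    (``per_channel_flow_ul_s`` or ``total_ml_min``, ``n_channels``) and
    ``sample`` (free keys, e.g. ``volume_ul``).  Omitted geometry fields
    keep the reference-instrument defaults.
    """
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    geom = MhqGeometry(**(cfg.get("geometry") or {}))
    fl = cfg.get("flow") or {}
    if "per_channel_flow_ul_s" in fl:
        flow = FlowSettings(per_channel_flow=fl["per_channel_flow_ul_s"],
                            n_channels=fl.get("n_channels", 2))
    else:
        flow = FlowSettings.from_total_ml_per_min(
            fl.get("total_ml_min", 2.0), n_channels=fl.get("n_channels", 2))
    return geom, flow, cfg.get("sample") or {}
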