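"""Plate-reader growth curves: I/O, specific growth rates, and wavelet denoising.

A growth experiment is a 96-well plate read at fixed intervals (10 min is
typical).  The on-disk format is a wide CSV with a ``time`` column in hours
and one column per well; a separate layout file maps wells to
(strain, condition) labels.  Internally every curve is a :class:`GrowthCurve`
with strictly increasing, uniformly spaced times.

The specific growth rate mu(t) = (1/OD) dOD/dt is estimated with central
differences of the optical densities, which is the discrete counterpart of
the per-capita growth rate and the quantity all downstream signature analysis
operates on.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pywt

from .exceptions import DomainError, FormatError, ValidationError

__all__ = [
    "GrowthCurve",
    "GrowthRateSeries",
    "read_plate_csv",
    "write_plate_csv",
    "load_layout",
    "compute_growth_rate",
    "denoise_curve",
]

logger = logging.getLogger(__name__)

_DT_RTOL = 1e-9


def _check_uniform_times(times: np.ndarray) -> float:
    """Validate strict monotonicity and uniform spacing; return the step."""
    diffs = np.diff(times)
    if np.any(diffs <= 0):
        raise ValidationError("time vector must be strictly increasing")
    dt = float(diffs[0])
    if np.any(np.abs(diffs - dt) > _DT_RTOL * abs(dt)):
        raise ValidationError("time vector must be uniformly spaced")
    return dt


@dataclass(frozen=True)
class GrowthCurve:
    """A labeled optical-density time series from one well.

    Parameters
    ----------
    times : ndarray
        Sampling times in hours, strictly increasing, uniform spacing.
    od : ndarray
        Optical density readings (dimensionless, >= 0), same length as
        ``times`` and at least 5 points.
    strain, condition, well : str
        Sample labels.
    """

    times: np.ndarray
    od: np.ndarray
    strain: str = ""
    condition: str = ""
    well: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "od", od)
        if times.ndim != 1 or od.ndim != 1 or len(times) != len(od):
            raise ValidationError("times and od must be 1-D arrays of equal length")
        if len(times) < 5:
            raise ValidationError("a growth curve needs at least 5 samples")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(od)):
            raise ValidationError("times and od must be finite")
        if np.any(od < 0):
            raise ValidationError("optical density must be non-negative")
        _check_uniform_times(times)

    @property
    def dt(self) -> float:
        """Sampling interval in hours."""
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class GrowthRateSeries:
    """Specific growth rate mu (1/hour) at the interior points of a curve."""

    times: np.ndarray
    mu: np.ndarray
    strain: str = ""
    condition: str = ""
    well: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        mu = np.asarray(self.mu, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "mu", mu)
        if len(times) != len(mu):
            raise ValidationError("times and mu must have equal length")
        _check_uniform_times(times)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def load_layout(path) -> dict:
    """Read a plate layout mapping ``well -> (strain, condition)``.

    Accepts JSON or YAML.  Entries may be ``[strain, condition]`` pairs or
    ``{"strain": ..., "condition": ...}`` mappings.
    """
    text = open(path).read()
    try:
        raw = json.loads(text)
    except json.JSONDecodeError:
        import yaml

        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise FormatError("layout must be a mapping of well -> (strain, condition)")
    layout = {}
    for well, entry in raw.items():
        if isinstance(entry, dict):
            layout[well] = (str(entry["strain"]), str(entry.get("condition", "")))
        else:
            strain, condition = entry
            layout[well] = (str(strain), str(condition))
    return layout


def read_plate_csv(path, layout: dict) -> list[GrowthCurve]:
    """Read a wide plate CSV into one :class:`GrowthCurve` per mapped well.

    Parameters
    ----------
    path : str or file-like
        CSV with a ``time`` column (hours) plus one column per well.
    layout : dict
        ``well -> (strain, condition)`` mapping.  Columns without a layout
        entry are skipped with a logged warning.

    Raises
    ------
    FormatError
        If the ``time`` column is missing.
    ValidationError
        If times are non-monotone or non-uniform.
    """
    df = pd.read_csv(path)
    time_cols = [c for c in df.columns if c.strip().lower() == "time"]
    if not time_cols:
        raise FormatError("plate CSV must contain a 'time' column (hours)")
    times = df[time_cols[0]].to_numpy(dtype=float)
    _check_uniform_times(times)

    curves = []
    for col in df.columns:
        if col in time_cols:
            continue
        if col not in layout:
            logger.warning("well column %r has no layout entry; skipped", col)
            continue
        strain, condition = layout[col]
        curves.append(
            GrowthCurve(
                times=times,
                od=df[col].to_numpy(dtype=float),
                strain=strain,
                condition=condition,
                well=col,
            )
        )
    return curves


def write_plate_csv(path, curves: list[GrowthCurve]) -> None:
    """Write curves back to the wide CSV format (inverse of :func:`read_plate_csv`)."""
    if not curves:
        raise ValidationError("no curves to write")
    times = curves[0].times
    for c in curves[1:]:
        if len(c.times) != len(times) or not np.allclose(c.times, times, rtol=0, atol=1e-12):
            raise ValidationError("all curves must share the same time grid")
    data = {"time": times}
    for c in curves:
        data[c.well] = c.od
    pd.DataFrame(data).to_csv(path, index=False)


def compute_growth_rate(
    curve: GrowthCurve,
    log_od: bool = False,
    permissive: bool = False,
) -> GrowthRateSeries:
    """Specific growth rate by central differences of the optical densities.

    At interior points ``mu_i = (od[i+1] - od[i-1]) / (2 dt od[i])``; the two
    endpoints are dropped.  With ``log_od=True`` the central difference is
    taken on ln OD instead, ``mu_i = (ln od[i+1] - ln od[i-1]) / (2 dt)``,
    which is an alternative reading of "specific growth rate"; the OD-based
    form is the default.

    Raises
    ------
    DomainError
        If any interior OD is <= 0 (or, for ``log_od``, any OD used is <= 0),
        unless ``permissive=True``, in which case the affected values are NaN.
    """
    od = curve.od
    dt = curve.dt
    interior = od[1:-1]
    if log_od:
        bad = (od[2:] <= 0) | (od[:-2] <= 0)
    else:
        bad = interior <= 0
    if np.any(bad) and not permissive:
        raise DomainError(
            "optical density <= 0 at interior points; "
            "use permissive=True to mask the affected values"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        if log_od:
            mu = (np.log(od[2:]) - np.log(od[:-2])) / (2.0 * dt)
        else:
            mu = (od[2:] - od[:-2]) / (2.0 * dt * interior)
    mu = np.where(bad, np.nan, mu)
    return GrowthRateSeries(
        times=curve.times[1:-1],
        mu=mu,
        strain=curve.strain,
        condition=curve.condition,
        well=curve.well,
    )


def denoise_curve(
    series: np.ndarray,
    wavelet: str = "db4",
    level: int | None = None,
    mode: str = "symmetric",
) -> np.ndarray:
    """Wavelet-shrinkage denoising with a soft universal threshold.

    A multilevel discrete wavelet decomposition of the signal is
    soft-thresholded at the universal threshold ``sigma * sqrt(2 ln N)``,
    with a single global noise scale ``sigma`` estimated once from the
    finest-level detail coefficients as ``MAD / 0.6745``, then reconstructed.
    The default depth is ``floor(log2 N) - 2`` levels; boundary handling uses
    symmetric extension.

    Parameters
    ----------
    series : ndarray
        1-D signal, length >= 8, finite.
    wavelet, level, mode :
        Decomposition wavelet, depth, and signal-extension mode.

    Returns
    -------
    ndarray
        Denoised signal with the same length as the input.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 8:
        raise ValidationError("denoise_curve expects a 1-D signal of length >= 8")
    if not np.all(np.isfinite(x)):
        raise ValidationError("denoise_curve expects a finite signal")
    n = len(x)
    if level is None:
        level = max(1, int(math.floor(math.log2(n))) - 2)
    level = min(level, pywt.dwt_max_level(n, pywt.Wavelet(wavelet).dec_len))
    coeffs = pywt.wavedec(x, wavelet, mode=mode, level=level)
    finest = coeffs[-1]
    sigma = float(np.median(np.abs(finest))) / 0.6745
    thr = sigma * math.sqrt(2.0 * math.log(n))
    if thr == 0.0:
        return x.copy()
    denoised = [coeffs[0]] + [pywt.threshold(c, thr, mode="soft") for c in coeffs[1:]]
    return pywt.waverec(denoised, wavelet, mode=mode)[:n]


def denoised_curve(curve: GrowthCurve, **kwargs) -> GrowthCurve:
    """Convenience wrapper returning a new :class:`GrowthCurve` with denoised OD."""
    od = np.maximum(denoise_curve(curve.od, **kwargs), 0.0)
    return replace(curve, od=od)
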