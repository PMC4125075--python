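"""Continuous-style wavelet signatures of growth-rate and expression series.

A signature is the matrix of absolute wavelet-coefficient amplitudes over a
(period, time) grid — a scaleogram — computed by convolving the signal with a
discretized Daubechies-4 wavelet at a range of scales.  db4 has no
closed-form continuous mother function, so psi is materialised with the
cascade algorithm at high refinement and resampled at each scale; periods map
to scales through the wavelet's spectral center frequency.  Coefficients use
L1 (amplitude-preserving) normalization, under which a sinusoid's response
peaks at its own period within one grid step.

Two feature reductions are provided:

* ``signature_vector`` — the coefficient row at a single period, the
  fingerprint used to cluster strains;
* ``expression_features`` — the (time, period) location at which the summed
  coefficient mass ``C_total`` is maximal, a two-number summary used for
  promoter-activity profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pywt

from .exceptions import ParameterError, ValidationError
from .growth_io import GrowthRateSeries

__all__ = [
    "WaveletSignature",
    "FeaturePair",
    "default_period_grid",
    "wavelet_transform",
    "signature_vector",
    "expression_features",
    "multiplex",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WaveletSignature:
    """Absolute wavelet-coefficient map over (period, time).

    Attributes
    ----------
    periods : ndarray
        Increasing period grid in hours.
    times : ndarray
        Sample times in hours.
    coef : ndarray, shape (len(periods), len(times))
        Non-negative coefficient amplitudes.
    boundary : ndarray of bool, same shape as ``coef``
        True where the wavelet support at that scale overlaps the record
        boundary; those cells are retained but flagged.
    strain, condition : str
        Source labels.
    """

    periods: np.ndarray
    times: np.ndarray
    coef: np.ndarray
    boundary: np.ndarray | None = None
    strain: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        periods = np.asarray(self.periods, dtype=float)
        times = np.asarray(self.times, dtype=float)
        coef = np.asarray(self.coef, dtype=float)
        object.__setattr__(self, "periods", periods)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "coef", coef)
        if coef.shape != (len(periods), len(times)):
            raise ValidationError("coef must have shape (len(periods), len(times))")
        if not np.all(np.isfinite(coef)) or np.any(coef < 0):
            raise ValidationError("coefficient map must be finite and non-negative")
        if np.any(np.diff(periods) <= 0):
            raise ValidationError("period grid must be increasing")


@dataclass(frozen=True)
class FeaturePair:
    """The (time, period) of maximal summed wavelet-coefficient mass.

    ``t_star`` is the time at which the column sums ``C_total,t`` peak and
    ``p_star`` the period at which the row sums ``C_total,f`` peak.  For an
    all-zero profile both argmaxes are the first grid point and
    ``degenerate`` is set.
    """

    t_star: float
    p_star: float
    degenerate: bool = False


def default_period_grid(dt: float, duration: float, n: int = 64) -> np.ndarray:
    """Logarithmically spaced periods from ``4 dt`` to the record duration."""
    return np.geomspace(4.0 * dt, duration, n)


@lru_cache(maxsize=8)
def _mother(wavelet: str, level: int):
    """Discretized mother wavelet (support grid x, values psi)."""
    try:
        w = pywt.Wavelet(wavelet)
        out = w.wavefun(level=level)
        psi, x = out[1], out[-1]
    except ValueError:
        w = pywt.ContinuousWavelet(wavelet)
        psi, x = w.wavefun(level=level)
        psi = np.real(psi)
    return np.asarray(x, float), np.asarray(psi, float)


def wavelet_transform(
    signal,
    dt: float | None = None,
    periods=None,
    wavelet: str = "db4",
    refinement_level: int = 10,
    times=None,
    strain: str = "",
    condition: str = "",
) -> WaveletSignature:
    """Continuous-style wavelet transform of a uniformly sampled series.

    For each period ``p`` the scale is ``a = p * f_c / dt`` with ``f_c`` the
    wavelet center frequency; the coefficient row is the absolute value of
    the convolution of the signal with ``psi(t/a)/a`` (L1 normalization),
    aligned so that column ``t`` corresponds to the wavelet centered at
    sample ``t``.  Zero-padding is used at the boundaries; boundary-affected
    cells are flagged in ``WaveletSignature.boundary``.

    Parameters
    ----------
    signal : ndarray or GrowthRateSeries
        Series of length >= 16.  When a :class:`GrowthRateSeries` is given,
        ``dt``, ``times`` and the labels are taken from it.
    dt : float
        Sampling interval in hours (required for a bare array).
    periods : ndarray, optional
        Requested period grid in hours; defaults to
        :func:`default_period_grid`.  Periods outside
        ``[2 dt, duration]`` raise :class:`ParameterError`.
    wavelet : str
        ``"db4"`` (default, cascade-discretized) or any continuous wavelet
        known to PyWavelets (e.g. ``"morl"``) as a cross-check dialect.
    """
    if isinstance(signal, GrowthRateSeries):
        times = signal.times
        dt = signal.dt
        strain = strain or signal.strain
        condition = condition or signal.condition
        signal = signal.mu
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or len(x) < 16:
        raise ValidationError("wavelet_transform expects a 1-D signal of length >= 16")
    if not np.all(np.isfinite(x)):
        raise ValidationError("wavelet_transform expects a finite signal")
    if dt is None or dt <= 0:
        raise ParameterError("a positive sampling interval dt is required")
    n = len(x)
    duration = n * dt
    if periods is None:
        periods = default_period_grid(dt, duration)
    periods = np.asarray(periods, dtype=float)
    if np.any(periods < 2.0 * dt - 1e-12) or np.any(periods > duration + 1e-12):
        raise ParameterError(
            f"periods must lie within [2*dt, duration] = [{2*dt:.4g}, {duration:.4g}] h"
        )
    if times is None:
        times = np.arange(n) * dt
    times = np.asarray(times, dtype=float)

    xs, psi = _mother(wavelet, refinement_level)
    fc = pywt.central_frequency(wavelet)
    scales = periods * fc / dt

    coef = np.empty((len(scales), n))
    boundary = np.zeros((len(scales), n), dtype=bool)
    for i, a in enumerate(scales):
        j = np.arange(int(np.ceil(xs[-1] * a)) + 1)
        kernel = np.interp(j / a, xs, psi) / a
        conv = np.convolve(x, kernel[::-1], mode="full")
        center = int(round(xs[-1] * a / 2.0))
        start = len(kernel) - 1 - center
        coef[i] = np.abs(conv[start : start + n])
        half = len(kernel) - 1
        lo = min(half - center, n)
        hi = min(center, n)
        boundary[i, :lo] = True
        if hi > 0:
            boundary[i, n - hi :] = True
    return WaveletSignature(
        periods=periods,
        times=times,
        coef=coef,
        boundary=boundary,
        strain=strain,
        condition=condition,
    )


def signature_vector(sig: WaveletSignature, period: float) -> np.ndarray:
    """Coefficient row at (or snapped to) a period on the signature's grid.

    If the requested period falls between grid points the nearest row is
    returned and a warning is logged.
    """
    idx = int(np.argmin(np.abs(sig.periods - period)))
    if not np.isclose(sig.periods[idx], period, rtol=1e-9, atol=0):
        logger.warning(
            "period %.4g h snapped to nearest grid point %.4g h", period, sig.periods[idx]
        )
    return sig.coef[idx].copy()


def expression_features(
    profile,
    dt: float | None = None,
    periods=None,
    **kwargs,
) -> FeaturePair:
    """Two-feature summary of an expression (or growth-rate) profile.

    Computes the full wavelet map, sums coefficients over time per period
    (``C_total,f``) and over periods per time point (``C_total,t``), and
    returns the location of each maximum.  Ties break toward the smaller
    period and the earlier time.
    """
    sig = profile if isinstance(profile, WaveletSignature) else wavelet_transform(
        profile, dt=dt, periods=periods, **kwargs
    )
    c_total_f = sig.coef.sum(axis=1)
    c_total_t = sig.coef.sum(axis=0)
    degenerate = not (np.any(c_total_f > 0) and np.any(c_total_t > 0))
    p_star = float(sig.periods[int(np.argmax(c_total_f))])
    t_star = float(sig.times[int(np.argmax(c_total_t))])
    return FeaturePair(t_star=t_star, p_star=p_star, degenerate=degenerate)


def multiplex(series_list, dts=None) -> np.ndarray:
    """Concatenate per-condition series into one multiplexed series.

    The conditions must be supplied in a fixed order shared by all strains so
    that multiplexed series are comparable.  Accepts bare arrays (optionally
    with a parallel ``dts`` sequence to validate) or
    :class:`~phenosig.growth_io.GrowthRateSeries` objects, whose sampling
    intervals must agree.

    Raises
    ------
    ValidationError
        If the sampling intervals are mismatched or the list is empty.
    """
    if len(series_list) == 0:
        raise ValidationError("multiplex requires at least one series")
    arrays = []
    steps = []
    for i, s in enumerate(series_list):
        if isinstance(s, GrowthRateSeries):
            arrays.append(s.mu)
            steps.append(s.dt)
        else:
            arrays.append(np.asarray(s, dtype=float))
            if dts is not None:
                steps.append(float(dts[i]))
    if steps and not np.allclose(steps, steps[0], rtol=1e-9):
        raise ValidationError("all series must share the same sampling interval")
    return np.concatenate(arrays)
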