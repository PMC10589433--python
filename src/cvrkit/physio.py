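"""End-tidal CO2 processing: peak extraction, volume-grid resampling, delay shifts.

The end-tidal CO2 (EtCO2) partial pressure, measured at each expiration, is
the vasodilatory stimulus regressor for CVR estimation.  This module turns a
raw capnograph recording into a breath-resolved EtCO2 trace and aligns it to
the BOLD volume acquisition grid, including the time shifts scanned during
hemodynamic delay optimization.

Sign convention: a *positive* delay shifts the EtCO2 profile later in time,
i.e. the BOLD response lags the stimulus — the physiologically expected
direction for a hemodynamic lag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

from cvrkit.errors import (
    EmptyTraceError,
    InsufficientTraceError,
    InvalidArgumentError,
)

__all__ = [
    "EtCO2Trace",
    "VolumeRegressor",
    "detect_end_tidal_peaks",
    "resample_to_volumes",
    "sample_trace",
    "shift_regressor",
    "volume_times",
]

_MMHG_LO, _MMHG_HI = 0.0, 150.0


@dataclass(frozen=True)
class EtCO2Trace:
    """Breath-resolved end-tidal CO2 values (mmHg) at strictly increasing times."""

    times_s: np.ndarray
    values_mmHg: np.ndarray
    source: str = "measured"  # measured | end_tidal_extracted | simulated

    def __post_init__(self) -> None:
        times = np.asarray(self.times_s, dtype=float)
        values = np.asarray(self.values_mmHg, dtype=float)
        object.__setattr__(self, "times_s", times)
        object.__setattr__(self, "values_mmHg", values)
        if times.ndim != 1 or times.shape != values.shape:
            raise InvalidArgumentError("times and values must be 1-D and equal length")
        if times.size < 2:
            raise InvalidArgumentError("an EtCO2 trace needs at least 2 samples")
        if np.any(np.diff(times) <= 0):
            raise InvalidArgumentError("trace times must be strictly increasing")
        if np.any(times < 0):
            raise InvalidArgumentError("trace times must be non-negative")
        if np.any(values <= _MMHG_LO) or np.any(values >= _MMHG_HI):
            raise InvalidArgumentError("EtCO2 values must lie in (0, 150) mmHg")

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0])


@dataclass(frozen=True)
class VolumeRegressor:
    """EtCO2 regressor sampled on the BOLD volume grid (one value per volume)."""

    values_mmHg: np.ndarray
    tr_s: float
    applied_delay_s: float = 0.0
    volume_timing: str = "middle"  # middle | start

    def __post_init__(self) -> None:
        values = np.asarray(self.values_mmHg, dtype=float)
        object.__setattr__(self, "values_mmHg", values)
        if not np.all(np.isfinite(values)):
            raise InvalidArgumentError("regressor values must be finite")
        if self.tr_s <= 0:
            raise InvalidArgumentError("tr_s must be positive")

    @property
    def n_volumes(self) -> int:
        return int(self.values_mmHg.size)

    @property
    def times_s(self) -> np.ndarray:
        return volume_times(self.n_volumes, self.tr_s, self.volume_timing)


def volume_times(n_volumes: int, tr_s: float, volume_timing: str = "middle") -> np.ndarray:
    """Nominal acquisition timestamps of the BOLD volumes.

    ``middle`` places volume k at k*TR + TR/2 (symmetric sampling assumption);
    ``start`` at k*TR.
    """
    if volume_timing not in ("middle", "start"):
        raise InvalidArgumentError(f"unknown volume_timing {volume_timing!r}")
    offset = tr_s / 2.0 if volume_timing == "middle" else 0.0
    return np.arange(n_volumes) * tr_s + offset


def sample_trace(trace: EtCO2Trace, times_s: np.ndarray) -> np.ndarray:
    """Linearly interpolate the trace at arbitrary times, holding the edge
    values constant outside the recorded span."""
    return np.interp(np.asarray(times_s, dtype=float), trace.times_s, trace.values_mmHg)


def detect_end_tidal_peaks(
    raw_times_s: np.ndarray,
    raw_co2_mmHg: np.ndarray,
    min_breath_interval_s: float = 1.5,
    prominence_mmHg: float = 1.0,
) -> EtCO2Trace:
    """Extract one end-tidal value per breath from a raw capnograph waveform.

    End-tidal CO2 is the local maximum of the expiratory waveform; peaks must
    be separated by at least ``min_breath_interval_s`` and exceed
    ``prominence_mmHg`` prominence to count as breaths.
    """
    t = np.asarray(raw_times_s, dtype=float)
    y = np.asarray(raw_co2_mmHg, dtype=float)
    if t.size != y.size or t.size < 4:
        raise InvalidArgumentError("raw recording too short")
    dt = np.median(np.diff(t))
    if dt <= 0:
        raise InvalidArgumentError("raw times must be increasing")
    if 1.0 / dt < 2.0:
        raise InvalidArgumentError("raw sampling rate must be at least 2 Hz")
    distance = max(1, int(round(min_breath_interval_s / dt)))
    idx, _ = find_peaks(y, distance=distance, prominence=prominence_mmHg)
    if idx.size == 0:
        raise EmptyTraceError("no end-tidal peaks found in recording")
    if idx.size < 2:
        raise EmptyTraceError("fewer than 2 breaths detected")
    return EtCO2Trace(times_s=t[idx], values_mmHg=y[idx], source="end_tidal_extracted")


def resample_to_volumes(
    trace: EtCO2Trace,
    n_volumes: int,
    tr_s: float,
    volume_timing: str = "middle",
    min_coverage: float = 0.5,
) -> VolumeRegressor:
    """Resample a breath-resolved trace onto the BOLD volume grid.

    Linear interpolation at the volume timestamps with constant extrapolation
    beyond the trace endpoints.  The trace must overlap at least
    ``min_coverage`` of the scan window [0, n_volumes*TR].
    """
    if n_volumes < 2 or tr_s <= 0:
        raise InvalidArgumentError("need n_volumes >= 2 and tr_s > 0")
    scan_len = n_volumes * tr_s
    overlap = min(trace.times_s[-1], scan_len) - max(trace.times_s[0], 0.0)
    if overlap < min_coverage * scan_len:
        raise InsufficientTraceError(
            f"trace covers {max(overlap, 0.0):.1f}s of a {scan_len:.1f}s scan "
            f"(< {min_coverage:.0%})"
        )
    times = volume_times(n_volumes, tr_s, volume_timing)
    return VolumeRegressor(
        values_mmHg=sample_trace(trace, times),
        tr_s=tr_s,
        applied_delay_s=0.0,
        volume_timing=volume_timing,
    )


def shift_regressor(regressor: VolumeRegressor, delay_s: float) -> VolumeRegressor:
    """Shift a volume-grid regressor by ``delay_s`` seconds.

    The value at volume k becomes the regressor evaluated at t_k - delay_s
    (positive delay: the profile arrives later), with constant-edge extension
    so every volume stays usable at every candidate delay.
    """
    scan_len = regressor.n_volumes * regressor.tr_s
    if abs(delay_s) >= scan_len:
        raise InvalidArgumentError(
            f"|delay| {abs(delay_s):.1f}s must be smaller than the scan ({scan_len:.1f}s)"
        )
    times = regressor.times_s
    shifted = np.interp(times - delay_s, times, regressor.values_mmHg)
    return replace(
        regressor,
        values_mmHg=shifted,
        applied_delay_s=regressor.applied_delay_s + delay_s,
    )
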