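"""Extraction of dark-adapted ERG parameters.

Measurement conventions
-----------------------
* baseline: mean voltage over the pre-flash segment.
* pSTR: baseline to the maximum post-flash peak of the averaged
  dim-flash (scotopic threshold response) trace.
* a-wave: baseline to the minimum within a post-flash search window
  (default 50 ms); reported signed (negative for a normal response).
* b-wave: trough of the a-wave to the maximum occurring after it
  (trough-to-peak, hence >= 0 by construction).
* Oscillatory potentials (OPs): the trace is band-pass filtered
  (60–235 Hz, zero phase) to suppress the slow a-/b-wave components;
  each OP amplitude is the difference between a post-flash peak and its
  preceding trough, and the total OP response is OP1 + OP2 + OP3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy import signal as sps

from .exceptions import (
    BoundaryPeakWarning,
    DegenerateWaveformWarning,
    IncompatibleTracesError,
    InsufficientBaselineError,
    InvalidParameterError,
    NyquistError,
    PartialOpWarning,
    QualityWarning,
)
from .types import ErgFeatures, ErgTrace

DEFAULT_BAND_HZ: tuple[float, float] = (60.0, 235.0)
#: Post-flash window searched for the a-wave trough (ms).
DEFAULT_A_WINDOW_MS = 50.0
#: Post-flash window searched for OP peaks (ms).
DEFAULT_OP_WINDOW_MS = 120.0
#: OP peaks must clear this fraction of the filtered-trace maximum.
DEFAULT_OP_PROMINENCE_FRAC = 0.05
#: Minimum separation between OP peaks; half of one cycle at the
#: geometric centre of the 60–235 Hz band (~119 Hz), so that noise
#: wiggles riding on a single OP are not double-counted.
DEFAULT_OP_MIN_DISTANCE_MS = 4.0
#: Gaussian smoothing (σ, ms) applied before locating the slow-component
#: extrema (a-trough, b-peak, pSTR peak), emulating the low-pass display
#: filtering under which such cursor measurements are made.  The σ is far
#: below the slow components' time scales (their amplitudes change by
#: < 0.1 %) but suppresses sample-level noise at the extrema.  The
#: Gaussian kernel has a monotone step response, so step-like inputs are
#: not overshot.  Set to 0 to measure on raw samples.
DEFAULT_SMOOTH_MS = 4.0


def _smoothed(trace: ErgTrace, smooth_ms: float) -> np.ndarray:
    if smooth_ms and smooth_ms > 0:
        sigma = smooth_ms / trace.dt_ms
        return ndi.gaussian_filter1d(trace.samples, sigma, mode="nearest")
    return trace.samples


def baseline(trace: ErgTrace) -> float:
    """Mean pre-flash voltage; subtracting it re-zeroes the trace."""
    idx = trace.flash_index
    if idx < 1:
        raise InsufficientBaselineError("no pre-flash samples in trace")
    if trace.flash_time < 10.0:
        warnings.warn(
            f"only {trace.flash_time:.1f} ms of pre-flash baseline",
            QualityWarning,
            stacklevel=2,
        )
    return float(np.mean(trace.samples[:idx]))


def average_traces(traces: list[ErgTrace]) -> ErgTrace:
    """Pointwise mean of repeated sweeps (e.g. the 30 dim flashes)."""
    if not traces:
        raise IncompatibleTracesError("no traces to average")
    first = traces[0]
    for t in traces[1:]:
        if (
            t.n != first.n
            or t.sampling_rate != first.sampling_rate
            or t.flash_time != first.flash_time
        ):
            raise IncompatibleTracesError(
                "traces differ in length, sampling rate or flash time"
            )
    mean = np.mean([t.samples for t in traces], axis=0)
    return first.copy_with(mean)


def measure_pstr(trace: ErgTrace, smooth_ms: float = DEFAULT_SMOOTH_MS) -> float:
    """Baseline-to-peak amplitude of the (averaged) STR trace, μV.

    The baseline is the raw pre-flash mean; the peak is located on the
    smoothed copy (see :data:`DEFAULT_SMOOTH_MS`).
    """
    b0 = baseline(trace)
    post = _smoothed(trace, smooth_ms)[trace.flash_index:]
    if post.size == 0:
        raise InvalidParameterError("no post-flash samples")
    amp = float(np.max(post) - b0)
    if amp <= 0:
        warnings.warn(
            f"non-positive pSTR amplitude ({amp:.2f} μV)",
            QualityWarning,
            stacklevel=2,
        )
    return amp


@dataclass
class ABResult:
    a_amp: float  # signed, trough relative to baseline
    b_amp: float  # trough-to-peak, >= 0
    a_trough_time: float  # ms
    b_peak_time: float  # ms


def measure_ab(
    trace: ErgTrace,
    a_window_ms: float = DEFAULT_A_WINDOW_MS,
    smooth_ms: float = DEFAULT_SMOOTH_MS,
) -> ABResult:
    """a-wave (baseline-to-trough, signed) and b-wave (trough-to-peak).

    The a-trough is the minimum within ``a_window_ms`` after the flash;
    the b-peak is the maximum anywhere after the trough.  Both extrema
    are taken on the smoothed copy (see :data:`DEFAULT_SMOOTH_MS`); the
    baseline is the raw pre-flash mean.
    """
    b0 = baseline(trace)
    smooth = _smoothed(trace, smooth_ms)
    i0 = trace.flash_index
    i1 = min(trace.n, i0 + int(round(a_window_ms / trace.dt_ms)) + 1)
    window = smooth[i0:i1]
    if window.size == 0:
        raise InvalidParameterError("no post-flash samples in a-window")
    it = i0 + int(np.argmin(window))
    if it in (i0, i1 - 1):
        warnings.warn(
            "a-wave trough at edge of its search window",
            BoundaryPeakWarning,
            stacklevel=2,
        )
    trough = float(smooth[it])
    post = smooth[it:]
    ip = it + int(np.argmax(post))
    peak = float(smooth[ip])
    a_amp = trough - b0
    b_amp = peak - trough
    if a_amp > 0 or ip == it:
        warnings.warn(
            "waveform lacks the expected negative-then-positive morphology; "
            "best-effort a-/b-wave values",
            DegenerateWaveformWarning,
            stacklevel=2,
        )
    return ABResult(
        a_amp=a_amp,
        b_amp=b_amp,
        a_trough_time=it * trace.dt_ms,
        b_peak_time=ip * trace.dt_ms,
    )


def design_op_filter(
    sampling_rate: float, band_hz: tuple[float, float] = DEFAULT_BAND_HZ
) -> np.ndarray:
    """Second-order sections of the OP band-pass (4th-order Butterworth)."""
    lo, hi = band_hz
    if sampling_rate <= 2.0 * hi:
        raise NyquistError(
            f"sampling rate {sampling_rate} Hz too low for a {hi} Hz band edge"
        )
    return sps.butter(2, [lo, hi], btype="bandpass", fs=sampling_rate, output="sos")


def isolate_ops(
    trace: ErgTrace, band_hz: tuple[float, float] = DEFAULT_BAND_HZ
) -> ErgTrace:
    """Zero-phase band-pass copy of the trace isolating the OPs.

    Forward-backward filtering avoids latency distortion of the OP peak
    positions; the pass band rejects both the slow a-/b-wave lobes and
    any DC offset.
    """
    sos = design_op_filter(trace.sampling_rate, band_hz)
    filtered = sps.sosfiltfilt(sos, trace.samples)
    return trace.copy_with(filtered, label=trace.label + "/op-filtered")


def measure_ops(
    filtered: ErgTrace,
    n_ops: int = 3,
    op_window_ms: float = DEFAULT_OP_WINDOW_MS,
    prominence_frac: float = DEFAULT_OP_PROMINENCE_FRAC,
    min_distance_ms: float = DEFAULT_OP_MIN_DISTANCE_MS,
) -> tuple[tuple[float, ...], float]:
    """Peak-to-preceding-trough amplitudes of the first ``n_ops`` OPs.

    Peaks are searched in the post-flash window, must clear a prominence
    floor (a fraction of the filtered-trace maximum) and be separated by
    at least ``min_distance_ms``.  When more candidates qualify than
    ``n_ops`` — filter precursor ripple or residual noise wiggles — the
    ``n_ops`` most prominent are kept and reported in temporal order,
    mirroring how an examiner labels the conspicuous wavelets OP1–OP3.
    Each amplitude is peak minus its preceding trough — the nearest
    qualified local minimum before the peak (falling back to the plain
    minimum since the previous kept peak); the total is the exact sum of
    the returned tuple.
    """
    if n_ops < 1:
        raise InvalidParameterError("n_ops must be >= 1")
    i0 = filtered.flash_index
    i1 = min(filtered.n, i0 + int(round(op_window_ms / filtered.dt_ms)) + 1)
    seg = filtered.samples[i0:i1]
    if seg.size < 3:
        raise InvalidParameterError("post-flash OP window too short")
    top = float(np.max(seg))
    if top <= 0 or np.ptp(seg) == 0:
        warnings.warn("no positive OP peaks in window", PartialOpWarning, stacklevel=2)
        return tuple([0.0] * n_ops), 0.0
    distance = max(1, int(round(min_distance_ms / filtered.dt_ms)))
    peaks, props = sps.find_peaks(
        seg, prominence=prominence_frac * top, distance=distance
    )
    if peaks.size > n_ops:
        keep = np.sort(np.argsort(props["prominences"])[::-1][:n_ops])
        peaks = peaks[keep]
    troughs, _ = sps.find_peaks(
        -seg, prominence=prominence_frac * top, distance=distance
    )

    def vertex(idx: int) -> float:
        # 3-point parabolic vertex value: quantifies the extremum from the
        # local curvature instead of the single most extreme sample, which
        # also averages out part of the in-band noise at the extremum
        if 0 < idx < seg.size - 1:
            ym, y0, yp = seg[idx - 1], seg[idx], seg[idx + 1]
            denom = ym - 2.0 * y0 + yp
            if denom != 0:
                return float(y0 - (ym - yp) ** 2 / (8.0 * denom))
        return float(seg[idx])

    amps: list[float] = []
    prev = 0
    for pk in peaks:
        before = troughs[troughs < pk]
        t_idx = int(before[-1]) if before.size else int(np.argmin(seg[prev:pk + 1]) + prev)
        amps.append(vertex(pk) - vertex(t_idx))
        prev = pk
    if len(amps) < n_ops:
        warnings.warn(
            f"only {len(amps)} of {n_ops} OP peaks found; total over those",
            PartialOpWarning,
            stacklevel=2,
        )
        amps += [0.0] * (n_ops - len(amps))
    return tuple(amps), float(sum(amps))


def extract_features(
    bright: ErgTrace,
    str_traces: list[ErgTrace],
    a_window_ms: float = DEFAULT_A_WINDOW_MS,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    n_ops: int = 3,
    op_window_ms: float = DEFAULT_OP_WINDOW_MS,
) -> ErgFeatures:
    """Full feature set of one recording session.

    Averages the dim-flash sweeps and measures the pSTR on the mean
    trace; measures a-/b-waves on the bright-flash trace; band-passes
    the bright-flash trace and measures the OPs.
    """
    try:
        pstr = measure_pstr(average_traces(str_traces))
        ab = measure_ab(bright, a_window_ms=a_window_ms)
        filtered = isolate_ops(bright, band_hz=band_hz)
        op_amps, _ = measure_ops(
            filtered, n_ops=n_ops, op_window_ms=op_window_ms
        )
    except Exception as exc:
        raise type(exc)(f"{exc} [trace label: {bright.label}]") from exc
    op3 = tuple(list(op_amps)[:3] + [0.0] * max(0, 3 - len(op_amps)))
    return ErgFeatures(
        a_amp=ab.a_amp,
        b_amp=ab.b_amp,
        pstr_amp=pstr,
        op_amps=op3,  # type: ignore[arg-type]
        a_trough_time=ab.a_trough_time,
        b_peak_time=ab.b_peak_time,
    )
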