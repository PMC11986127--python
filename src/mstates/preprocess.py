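"""Signal conditioning: bandpass, downsample, spherical-spline interpolation,
average reference, global field power and its peaks.

The canonical order is filter -> downsample -> interpolate -> re-reference;
each step appends to the recording's history so provenance is inspectable.
GFP uses the population (divide-by-N) standard deviation, the dominant
convention in the microstate literature.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from numpy.polynomial import legendre as npleg
from scipy import signal

from .core import Recording


@dataclass
class FilterParams:
    low_hz: float = 1.0
    high_hz: float = 40.0
    order: int = 2
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("need 0 < low_hz < high_hz")


def bandpass(recording: Recording, params: FilterParams | None = None) -> Recording:
    """Zero-phase Butterworth bandpass (order per edge; -12 dB/octave at order 2).

    Applied forward and backward (``sosfiltfilt``) with reflection padding, so
    the phase response is flat and the effective attenuation doubles.
    """
    params = params or FilterParams()
    nyquist = recording.sampling_rate / 2
    if params.high_hz >= nyquist:
        raise ValueError(
            f"high cutoff {params.high_hz} Hz violates Nyquist "
            f"({nyquist} Hz at {recording.sampling_rate} Hz sampling)"
        )
    sos = signal.butter(params.order, [params.low_hz, params.high_hz],
                        btype="bandpass", fs=recording.sampling_rate, output="sos")
    if params.zero_phase:
        # pad generously: the 1 Hz edge's transient spans seconds
        padlen = min(recording.n_samples - 1,
                     int(3 * recording.sampling_rate / params.low_hz))
        filtered = signal.sosfiltfilt(sos, recording.data, axis=1,
                                      padtype="even", padlen=padlen)
    else:
        filtered = signal.sosfilt(sos, recording.data, axis=1)
    return recording.with_data(
        filtered, note=f"bandpass({params.low_hz}-{params.high_hz} Hz, "
                       f"order {params.order}, zero_phase={params.zero_phase})")


def downsample(recording: Recording, target_hz: float = 250.0) -> Recording:
    """Anti-aliased resampling to ``target_hz`` (polyphase; any rational ratio)."""
    if target_hz > recording.sampling_rate:
        raise ValueError(
            f"target rate {target_hz} Hz exceeds source rate "
            f"{recording.sampling_rate} Hz"
        )
    if target_hz == recording.sampling_rate:
        return recording
    ratio = Fraction(target_hz / recording.sampling_rate).limit_denominator(1000)
    out = signal.resample_poly(recording.data, ratio.numerator, ratio.denominator,
                               axis=1, padtype="line")
    return recording.with_data(out, sampling_rate=target_hz,
                               note=f"downsample({target_hz:g} Hz)")


# ---------------------------------------------------------------------------
# Spherical spline interpolation (Perrin-style)
# ---------------------------------------------------------------------------

def _spline_g(cosang: np.ndarray, order_m: int, n_terms: int) -> np.ndarray:
    """g(cos gamma) = (1/4pi) sum_{n=1}^{N} (2n+1) / (n(n+1))^m * P_n(x)."""
    coefs = np.zeros(n_terms + 1)
    for n in range(1, n_terms + 1):
        coefs[n] = (2 * n + 1) / (n * (n + 1)) ** order_m
    return npleg.legval(np.clip(cosang, -1.0, 1.0), coefs) / (4 * np.pi)


def spherical_spline_interpolate(recording: Recording,
                                 bad_channels: list[str] | None = None,
                                 order_m: int = 4, n_terms: int = 7,
                                 regularization: float = 1e-5) -> Recording:
    """Replace bad-channel rows with spherical-spline estimates from good ones.

    Solves the thin-plate-on-sphere system on the good sensors (with an
    optional ridge on the kernel diagonal) and evaluates at the bad sensor
    positions; good channels are untouched.
    """
    bads = list(bad_channels) if bad_channels is not None else list(recording.bad_channels)
    if not bads:
        return recording.with_data(recording.data.copy(), note="interpolate(none)")
    if recording.montage is None:
        raise ValueError("interpolation requires a montage")
    good = [c for c in recording.channel_names if c not in bads]
    if len(good) < 4:
        raise ValueError("spherical spline interpolation needs >= 4 good channels")
    if len(good) == 0 or len(bads) == len(recording.channel_names):
        raise ValueError("cannot interpolate: all channels bad")

    pos = recording.montage.positions
    gi = recording.montage.index_of(good)
    bi = recording.montage.index_of(bads)
    g_gg = _spline_g(pos[gi] @ pos[gi].T, order_m, n_terms)
    g_bg = _spline_g(pos[bi] @ pos[gi].T, order_m, n_terms)

    n_good = len(good)
    system = np.zeros((n_good + 1, n_good + 1))
    system[:n_good, :n_good] = g_gg + regularization * np.eye(n_good)
    system[:n_good, n_good] = 1.0
    system[n_good, :n_good] = 1.0
    rhs = np.zeros((n_good + 1, recording.n_samples))
    rhs[:n_good] = recording.data[gi]
    sol = np.linalg.solve(system, rhs)
    weights, intercept = sol[:n_good], sol[n_good]

    out = recording.data.copy()
    out[bi] = g_bg @ weights + intercept
    rec = recording.with_data(out, note=f"interpolate({bads})")
    rec.bad_channels = []
    return rec


def average_reference(recording: Recording) -> Recording:
    """Re-project the reference to the average: per-frame channel mean -> 0."""
    out = recording.data - recording.data.mean(axis=0, keepdims=True)
    return recording.with_data(out, note="average_reference")


@dataclass
class GfpSeries:
    values: np.ndarray  # (n_frames,), µV, >= 0
    sampling_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12):
            raise ValueError("GFP values must be non-negative")


def gfp(recording: Recording) -> GfpSeries:
    """Global field power: per-frame spatial SD (population convention).

    For average-referenced data this equals the RMS over channels; it is
    invariant to a polarity flip of the frame.
    """
    values = recording.data.std(axis=0, ddof=0)
    return GfpSeries(values=values, sampling_rate=recording.sampling_rate)


def gfp_peaks(series: GfpSeries, min_separation_frames: int = 0) -> np.ndarray:
    """Indices of strict local GFP maxima; close peaks resolved to the larger."""
    if series.values.size < 3:
        raise ValueError("GFP series too short for peak detection")
    distance = max(1, int(min_separation_frames))
    peaks, _ = signal.find_peaks(series.values, distance=distance)
    return peaks
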