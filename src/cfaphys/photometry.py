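"""Fibre-photometry preprocessing and event-locked quantification.

Two excitation channels are recorded: an isosbestic 405-nm signal that is
insensitive to sensor activity (capturing bleaching and motion) and an
activity-dependent 488-nm signal.  Calcium (GCaMP) recordings are
debleached by regressing the filtered isosbestic channel onto the activity
channel and subtracting the fit; the ratiometric PKA sensor (AKAR2) is
debleached by dividing the two channels.  Filters are zero-phase
second-order Butterworth low-passes (corner recorded in the output
provenance); both channels are downsampled to 100 Hz after filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import InvalidInputError
from .simulate import PhotometryTrace

TARGET_FS = 100.0


@dataclass
class ProcessedSignal:
    time: np.ndarray
    value: np.ndarray
    fs: float
    provenance: dict


def _lowpass_and_decimate(trace: PhotometryTrace, corner_hz: float) -> tuple[np.ndarray, ...]:
    trace.validate()
    if trace.fs < TARGET_FS:
        raise InvalidInputError(f"photometry must be sampled at >= {TARGET_FS:g} Hz")
    factor = int(round(trace.fs / TARGET_FS))
    if abs(trace.fs / factor - TARGET_FS) > 1e-6:
        raise InvalidInputError("sampling rate must be an integer multiple of 100 Hz")
    sos = signal.butter(2, corner_hz, btype="low", fs=trace.fs, output="sos")
    iso = signal.sosfiltfilt(sos, trace.iso405)
    act = signal.sosfiltfilt(sos, trace.act488)
    return trace.time[::factor], iso[::factor], act[::factor]


def preprocess_gcamp(trace: PhotometryTrace, corner_hz: float = 2.0) -> ProcessedSignal:
    """Debleached activity-dependent GCaMP signal.

    Both channels are low-pass filtered (2 Hz, zero-phase second order) and
    downsampled to 100 Hz; a least-squares linear map of the isosbestic
    channel onto the activity channel is fitted over the whole recording and
    the fitted isosbestic signal is subtracted from the activity signal.
    """
    t, iso, act = _lowpass_and_decimate(trace, corner_hz)
    if np.ptp(iso) < 1e-12:
        raise InvalidInputError("isosbestic channel is constant; debleaching fit is degenerate")
    a, b = np.polyfit(iso, act, 1)
    return ProcessedSignal(
        time=t,
        value=act - (a * iso + b),
        fs=TARGET_FS,
        provenance={"method": "gcamp", "filter": "butter2-zero-phase", "corner_hz": corner_hz,
                    "fit": {"slope": float(a), "intercept": float(b)}},
    )


def preprocess_akar2(trace: PhotometryTrace, corner_hz: float = 1.0) -> ProcessedSignal:
    """Ratiometric PKA signal: filtered, downsampled 488/405 ratio."""
    t, iso, act = _lowpass_and_decimate(trace, corner_hz)
    if np.min(np.abs(iso)) < 1e-6:
        raise InvalidInputError("isosbestic channel approaches zero; ratio undefined")
    return ProcessedSignal(
        time=t,
        value=act / iso,
        fs=TARGET_FS,
        provenance={"method": "akar2", "filter": "butter2-zero-phase", "corner_hz": corner_hz},
    )


def injection_peth(
    sig: ProcessedSignal,
    t_inj: float,
    window_min: tuple[float, float] = (10.0, 30.0),
) -> np.ndarray:
    """Minute-smoothed, z-scored response to an injection.

    The window spans ``window_min[0]`` minutes before to ``window_min[1]``
    minutes after the injection; the trace is z-scored by the full
    pre-injection mean/s.d., downsampled to 1 Hz, and smoothed with a 1-min
    centred moving average.  A constant signal (zero pre-injection s.d.) is
    flagged and returns zeros.
    """
    pre, post = 60.0 * window_min[0], 60.0 * window_min[1]
    i0 = int(round((t_inj - pre - sig.time[0]) * sig.fs))
    i1 = int(round((t_inj + post - sig.time[0]) * sig.fs))
    i_inj = int(round((t_inj - sig.time[0]) * sig.fs))
    if i0 < 0:
        raise InvalidInputError("insufficient pre-injection data")
    x = sig.value[i0 : min(i1, sig.value.size)]
    base = sig.value[i0:i_inj]
    mu, sd = base.mean(), base.std()
    if sd == 0:
        warnings.warn("pre-injection signal has zero variance; returning zeros",
                      RuntimeWarning, stacklevel=2)
        z = np.zeros_like(x)
    else:
        z = (x - mu) / sd
    one_hz = z[: (z.size // int(sig.fs)) * int(sig.fs)].reshape(-1, int(sig.fs)).mean(axis=1)
    kernel = np.ones(60) / 60.0
    pad = 30
    padded = np.pad(one_hz, pad, mode="edge")
    return np.convolve(padded, kernel, mode="same")[pad:-pad]


def reward_peth_pka(
    sig: ProcessedSignal,
    event_times_by_port: dict[str, np.ndarray],
    window: tuple[float, float] = (10.0, 30.0),
    baseline_window: tuple[float, float] = (-5.0, -1.0),
    response_window: tuple[float, float] = (5.0, 15.0),
) -> dict[str, dict]:
    """Per-port event-normalized PKA PETHs and scalar responses.

    Each event's PETH is centred by its own baseline mean (-5 to -1 s before
    delivery) and divided by the s.d. of the concatenated baseline epochs of
    ALL events from both ports (one normalization per recording); PETHs are
    averaged per port and the scalar response is the mean over +5 to +15 s.
    """
    fs = int(sig.fs)
    pre_n, post_n = int(window[0] * fs), int(window[1] * fs)

    def segment(t0: float, a: float, b: float) -> np.ndarray | None:
        i0 = int(round((t0 + a - sig.time[0]) * fs))
        i1 = int(round((t0 + b - sig.time[0]) * fs))
        if i0 < 0 or i1 > sig.value.size:
            return None
        return sig.value[i0:i1]

    baselines = []
    peths: dict[str, list[np.ndarray]] = {}
    for port, times in event_times_by_port.items():
        if len(times) == 0:
            raise InvalidInputError(f"no events for port {port!r}")
        peths[port] = []
        for t0 in np.asarray(times, dtype=float):
            full = segment(t0, -window[0], window[1])
            base = segment(t0, baseline_window[0], baseline_window[1])
            if full is None or base is None:
                continue
            peths[port].append(full - base.mean())
            baselines.append(base - base.mean())
    if not baselines:
        raise InvalidInputError("no event window fits inside the recording")
    sd = np.concatenate(baselines).std()
    sd = sd if sd > 0 else 1.0
    out = {}
    lags = (np.arange(pre_n + post_n) - pre_n) / fs
    r0, r1 = int((window[0] + response_window[0]) * fs), int((window[0] + response_window[1]) * fs)
    for port, segs in peths.items():
        if not segs:
            raise InvalidInputError(f"no usable events for port {port!r}")
        avg = np.mean(segs, axis=0) / sd
        out[port] = {
            "lags": lags,
            "peth": avg,
            "scalar": float(avg[r0:r1].mean()),
            "n_events": len(segs),
        }
    return out
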