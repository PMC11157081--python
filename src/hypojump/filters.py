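"""Zero-phase Butterworth filtering and sliding-window averaging.

All named cutoff frequencies in the pipeline (25 Hz kinetics/markers,
5-450 Hz EMG band, 1 Hz onset-gate smoother, 6 Hz muscle length) are
realized as 4th-order Butterworth filters applied forward-backward, so
the filtering itself introduces no phase delay into onset timing.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal

FILTER_ORDER = 4


def lowpass(
    x: np.ndarray, fs: float, cutoff: float, order: int = FILTER_ORDER, padtype: str = "odd"
) -> np.ndarray:
    """Zero-phase Butterworth lowpass.

    ``padtype='even'`` (mirror extension) is used when the corner period is
    comparable to the signal length — e.g. the 1 Hz burst-shape smoother on a
    sub-second aerial window — where odd extension can invert the edge slope.
    """
    x = np.asarray(x, dtype=float)
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, padlen=_padlen(sos, x.shape[-1]), padtype=padtype)


def bandpass(
    x: np.ndarray, fs: float, low: float, high: float, order: int = FILTER_ORDER
) -> np.ndarray:
    """Zero-phase Butterworth bandpass (``low``..``high`` Hz)."""
    x = np.asarray(x, dtype=float)
    sos = signal.butter(order, [low, high], btype="band", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, padlen=_padlen(sos, x.shape[-1]))


def emg_band(x: np.ndarray, fs: float, low: float = 5.0, high: float = 450.0) -> np.ndarray:
    """EMG conditioning band. The upper corner is clamped to 0.45*fs when the
    sampling rate cannot support 450 Hz (fs <= 900 Hz), with a warning."""
    if fs <= 2 * high:
        clamped = 0.45 * fs
        warnings.warn(
            f"EMG lowpass corner {high} Hz not supported at fs={fs} Hz; "
            f"clamped to {clamped:.1f} Hz",
            stacklevel=2,
        )
        high = clamped
    return bandpass(x, fs, low, high)


def gaussian_lowpass(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    """Zero-phase Gaussian FIR smoother with -3 dB point at ``cutoff`` Hz.

    The kernel is truncated at 3 sigma and renormalized by its in-window
    mass, so the smoother has no edge transients — the appropriate
    realization of a very low corner (e.g. the 1 Hz burst-shape gate) on a
    window shorter than the corner period, where an IIR zero-phase filter
    is dominated by its initial-condition transient.
    """
    x = np.asarray(x, dtype=float)
    sigma_s = np.sqrt(np.log(np.sqrt(2.0)) / (2.0 * np.pi**2)) / cutoff
    r = max(1, int(round(3.0 * sigma_s * fs)))
    k = np.exp(-0.5 * (np.arange(-r, r + 1) / (sigma_s * fs)) ** 2)
    n = x.size
    num = np.convolve(x, k, mode="full")[r : r + n]
    den = np.convolve(np.ones(n), k, mode="full")[r : r + n]
    return num / den


def _padlen(sos: np.ndarray, n: int) -> int:
    default = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(), (sos[:, 5] == 0).sum()))
    return min(default, n - 1)


def sliding_average(x: np.ndarray, fs: float, window_s: float = 0.1) -> np.ndarray:
    """Centered moving average of width ``window_s`` seconds.

    At the edges the window is truncated to the available samples, so the
    output has the same length as the input. The window length in samples is
    round(window_s * fs); a single-sample impulse of height h therefore maps
    to a plateau of height h / round(window_s * fs).
    """
    x = np.asarray(x, dtype=float)
    w = int(round(window_s * fs))
    if w < 1:
        raise ValueError("window shorter than one sample")
    if w == 1:
        return x.copy()
    kernel = np.ones(w)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den
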