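"""Morlet wavelet time-frequency decomposition and dB normalization.

The decomposition uses complex Morlet wavelets with a fixed number of
cycles (default 5), an integer 1-Hz frequency grid from 3 to 30 Hz (28
bins), and decimation of the convolution output to a 0.02-s time step.
Power is amplitude squared; dB normalization is relative to the average
power across the epoch, per channel and frequency:
``10 * log10(P / mean_t P)``.

Timepoints where the wavelet support extends beyond the epoch are flagged
invalid in ``TimeFrequencyCube.valid`` rather than silently zero-padded;
the dB epoch mean excludes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.fft as sfft


@dataclass
class TimeFrequencyCube:
    """Power over (... x channels x frequencies x timepoints).

    ``data`` may carry a leading trials axis.  ``valid`` is a boolean
    (frequencies x timepoints) mask marking where the wavelet fully fits
    inside the epoch.
    """

    data: np.ndarray
    freqs_hz: np.ndarray
    times_s: np.ndarray
    scale: str = "linear"  # "linear" | "db"
    valid: np.ndarray | None = None
    channel_names: list[str] | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_freqs(self) -> int:
        return len(self.freqs_hz)

    @property
    def time_step_s(self) -> float:
        return float(self.times_s[1] - self.times_s[0])

    def time_indices(self, window: tuple[float, float]) -> np.ndarray:
        """Indices of timepoints in [start_s, end_s)."""
        lo, hi = window
        return np.flatnonzero((self.times_s >= lo - 1e-9) & (self.times_s < hi - 1e-9))


def morlet_wavelet(sfreq: float, freq: float, n_cycles: float = 5.0) -> np.ndarray:
    """Zero-mean complex Morlet wavelet, L2-normalized as in MNE/FieldTrip."""
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    t = np.arange(0.0, 5.0 * sigma_t, 1.0 / sfreq)
    t = np.concatenate([-t[::-1], t[1:]])
    osc = np.exp(2j * np.pi * freq * t) - np.exp(-2.0 * (np.pi * freq * sigma_t) ** 2)
    w = osc * np.exp(-(t**2) / (2.0 * sigma_t**2))
    w /= np.sqrt(0.5) * np.linalg.norm(w)
    return w


def morlet_coefficients(
    data: np.ndarray,
    sfreq: float,
    freqs: np.ndarray,
    n_cycles: float = 5.0,
    decim: int = 1,
    dtype=np.complex64,
) -> np.ndarray:
    """Complex wavelet coefficients of ``data`` (..., n_samples).

    Batched FFT convolution; the output time axis is ``data``'s sliced by
    ``decim``.  Shared by the power transform and the coherence analysis so
    both see the same wavelet family.
    """
    data = np.asarray(data)
    if data.ndim < 1:
        raise ValueError("data must have a trailing sample axis")
    lead = data.shape[:-1]
    n_t = data.shape[-1]
    flat = data.reshape(-1, n_t)
    wavelets = [morlet_wavelet(sfreq, f, n_cycles) for f in freqs]
    longest = max(len(w) for w in wavelets)
    if longest > 2 * n_t:
        raise ValueError(
            f"epoch too short: lowest frequency {min(freqs)} Hz needs "
            f"{longest} samples of support, epoch has {n_t}"
        )
    nfft = sfft.next_fast_len(n_t + longest - 1)
    X = sfft.fft(flat.astype(np.complex64 if dtype == np.complex64 else complex), nfft, axis=-1)
    out_idx = range(0, n_t, decim)
    out = np.empty((flat.shape[0], len(freqs), len(out_idx)), dtype)
    for k, w in enumerate(wavelets):
        spec = sfft.fft(w.astype(X.dtype), nfft)
        conv = sfft.ifft(X * spec, axis=-1)
        start = (len(w) - 1) // 2
        out[:, k, :] = conv[:, start : start + n_t : decim]
    return out.reshape(*lead, len(freqs), len(out_idx))


def edge_validity(
    times_s: np.ndarray, freqs: np.ndarray, n_cycles: float = 5.0
) -> np.ndarray:
    """(n_freqs, n_times) mask: True where a wavelet of ``n_cycles`` cycles
    fits fully inside the epoch (half support = n_cycles / (2 f))."""
    half = np.asarray(n_cycles / (2.0 * np.asarray(freqs, float)))
    t0, t1 = times_s[0], times_s[-1]
    return (times_s[None, :] >= t0 + half[:, None]) & (
        times_s[None, :] <= t1 - half[:, None]
    )


def morlet_transform(
    data: np.ndarray,
    sfreq: float,
    freq_lo: float = 3.0,
    freq_hi: float = 30.0,
    n_cycles: float = 5.0,
    time_step_s: float = 0.02,
    t_start_s: float = -0.5,
    channel_names: list[str] | None = None,
) -> TimeFrequencyCube:
    """Morlet power of epochs (..., n_channels, n_samples).

    Frequencies run on an integer 1-Hz grid from ``freq_lo`` to ``freq_hi``
    inclusive (28 bins for 3-30 Hz).  The convolution output is decimated by
    stride round(time_step_s * sfreq); edge timepoints where the wavelet
    support exceeds the epoch are flagged in ``valid``.
    """
    if freq_lo <= 0 or freq_hi < freq_lo:
        raise ValueError("require 0 < freq_lo <= freq_hi")
    freqs = np.arange(float(freq_lo), float(freq_hi) + 0.5, 1.0)
    decim = int(round(time_step_s * sfreq))
    if decim < 1 or abs(decim - time_step_s * sfreq) > 1e-6:
        raise ValueError(
            f"time step {time_step_s}s is not an integer number of samples "
            f"at {sfreq} Hz"
        )
    coeffs = morlet_coefficients(data, sfreq, freqs, n_cycles, decim)
    power = (coeffs.real.astype(np.float64)) ** 2 + (coeffs.imag.astype(np.float64)) ** 2
    n_out = power.shape[-1]
    times = t_start_s + np.arange(n_out) * decim / sfreq
    return TimeFrequencyCube(
        data=power,
        freqs_hz=freqs,
        times_s=times,
        scale="linear",
        valid=edge_validity(times, freqs, n_cycles),
        channel_names=channel_names,
    )


def db_normalize(cube: TimeFrequencyCube) -> TimeFrequencyCube:
    """dB relative to the average power across the epoch, per channel and
    frequency.  The epoch mean runs over edge-valid timepoints only."""
    if cube.scale != "linear":
        raise ValueError("cube must be linear-scale power")
    valid = (
        cube.valid
        if cube.valid is not None
        else np.ones((cube.n_freqs, cube.data.shape[-1]), bool)
    )
    w = valid.astype(float)
    denom = w.sum(axis=-1)  # per frequency
    mean = (cube.data * w).sum(axis=-1) / denom  # (..., ch, freq)
    bad = ~(mean > 0)
    if np.any(bad):
        idx = np.argwhere(bad)
        raise ValueError(
            f"zero epoch-mean power at (channel, frequency) index {tuple(idx[0][-2:])}"
        )
    db = 10.0 * np.log10(cube.data / mean[..., None])
    return replace(cube, data=db, scale="db")


def db_to_linear(cube: TimeFrequencyCube, epoch_mean: np.ndarray | None = None) -> TimeFrequencyCube:
    """Inverse of :func:`db_normalize` up to the (lost) epoch-mean scale."""
    if cube.scale != "db":
        raise ValueError("cube must be dB-scale")
    lin = 10.0 ** (cube.data / 10.0)
    if epoch_mean is not None:
        lin = lin * epoch_mean[..., None]
    return replace(cube, data=lin, scale="linear")
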