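"""Morlet wavelet time-frequency analysis and the time-resolved SSVEP SNR.

The analysis grid is 1-15 Hz in 0.5 Hz steps (29 bands), 7-cycle complex
Morlet wavelets, over a -1000..2500 ms window around image onset.  The
SNR at a band f is the band's power at each time point divided by the
noise proxy — the average over the four neighboring bands (f-2, f-1,
f+1, f+2 Hz) of their time-averaged power over the full wavelet window —
minus one, so 0 marks the noise floor.

Wavelets are amplitude-normalized: a unit-amplitude stationary sinusoid
at a grid frequency yields envelope 1 (power 1) at that band.  The SNR
is a ratio of powers, so this global normalization cancels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sig
from scipy import stats as sps

from .errors import ConfigurationError, DegenerateInputError
from .montage import MASTOIDS
from .preprocess import EpochSet


def frequency_grid(fmin: float, fmax: float, step: float) -> np.ndarray:
    """Inclusive arithmetic frequency grid; the span must be an integer
    number of steps."""
    if step <= 0 or fmax < fmin:
        raise ConfigurationError("need fmin <= fmax and step > 0")
    n = (fmax - fmin) / step
    if abs(n - round(n)) > 1e-9:
        raise ConfigurationError(
            f"span {fmax - fmin} Hz is not an integer multiple of step {step} Hz"
        )
    return fmin + step * np.arange(int(round(n)) + 1)


@dataclass(frozen=True)
class AnalysisParams:
    """Spectral analysis settings (frequencies in Hz, windows in seconds)."""

    f0: float = 4.0
    fmin: float = 1.0
    fmax: float = 15.0
    fstep: float = 0.5
    n_cycles: float = 7.0
    tfr_window: tuple[float, float] = (-1.0, 2.5)
    neighbor_offsets: tuple[float, ...] = (-2.0, -1.0, 1.0, 2.0)
    image_window: tuple[float, float] = (0.0, 2.0)
    decim: int = 1

    @property
    def freqs(self) -> np.ndarray:
        return frequency_grid(self.fmin, self.fmax, self.fstep)

    def __post_init__(self):
        freqs = self.freqs
        on_grid = lambda f: np.any(np.abs(freqs - f) < 1e-9)
        if not on_grid(self.f0):
            raise ConfigurationError("f0 must lie on the frequency grid")
        for off in self.neighbor_offsets:
            if not on_grid(self.f0 + off):
                raise ConfigurationError(
                    f"neighbor frequency f0{off:+g} Hz not on the grid"
                )


def morlet_wavelet(freq: float, fs: float, n_cycles: float = 7.0) -> np.ndarray:
    """Complex Morlet wavelet, amplitude-normalized.

    sigma_t = n_cycles / (2 pi f); support +-5 sigma_t.  Normalization
    divides by half the Gaussian envelope area so that convolution with a
    unit sinusoid at ``freq`` returns envelope 1.
    """
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(5.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    gauss = np.exp(-(t**2) / (2.0 * sigma_t**2))
    wav = gauss * np.exp(2j * np.pi * freq * t)
    return wav * (2.0 / gauss.sum())


@dataclass
class TFR:
    """Time-frequency array: (freqs, times, channels), or with a leading
    epoch axis in per-epoch mode.  ``values`` holds power (uV^2) or
    amplitude (uV) depending on ``kind``; ``edge_mask`` marks, per
    frequency, time points within half a wavelet duration of an epoch
    edge."""

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channels: tuple[str, ...]
    kind: str  # "evoked_power" | "evoked_amplitude" | "epoch_amplitude"
    edge_mask: np.ndarray = field(default=None)  # (freqs, times), True = valid
    #: fraction of wavelet energy inside the epoch per (freq, time) — the
    #: expected attenuation of stationary-noise power near the edges
    edge_gain: np.ndarray = field(default=None)

    def freq_index(self, f: float) -> int:
        i = int(np.argmin(np.abs(self.freqs - f)))
        if abs(self.freqs[i] - f) > 1e-9:
            raise ConfigurationError(f"{f} Hz not on the TFR grid")
        return i


def _convolve_freqs(
    data: np.ndarray, freqs: np.ndarray, fs: float, n_cycles: float
) -> np.ndarray:
    """|wavelet * data| for each frequency; output (n_freqs, ..., n_times)."""
    out = np.empty((freqs.size, *data.shape))
    for i, f in enumerate(freqs):
        wav = morlet_wavelet(f, fs, n_cycles)
        shape = (1,) * (data.ndim - 1) + (wav.size,)
        conv = sig.fftconvolve(data, wav.reshape(shape), mode="same", axes=-1)
        out[i] = np.abs(conv)
    return out


def morlet_tfr(
    epochs: EpochSet,
    params: AnalysisParams = AnalysisParams(),
    mode: str = "evoked",
    kind: str = "power",
    freqs: np.ndarray | None = None,
    rows: np.ndarray | None = None,
) -> TFR:
    """Morlet time-frequency transform of an epoch set.

    ``mode="evoked"`` averages epochs (per condition is the caller's
    responsibility via ``rows``) before transforming; ``mode="per_epoch"``
    transforms each epoch.  The result is cropped to ``params.tfr_window``.
    """
    if mode not in ("evoked", "per_epoch"):
        raise ConfigurationError(f"unknown TFR mode {mode!r}")
    if kind not in ("power", "amplitude"):
        raise ConfigurationError(f"unknown TFR kind {kind!r}")
    freqs = params.freqs if freqs is None else np.atleast_1d(freqs)
    t = epochs.times
    lo, hi = params.tfr_window
    if lo < t[0] - 1e-9 or hi > t[-1] + 1.0 / epochs.fs + 1e-9:
        raise ConfigurationError("tfr_window extends beyond the epoch window")
    data = epochs.data if rows is None else epochs.data[rows]
    if data.shape[0] == 0:
        raise DegenerateInputError("no epochs to transform")
    if mode == "evoked":
        data = data.mean(axis=0)  # (channels, samples)
    amp = _convolve_freqs(data, freqs, epochs.fs, params.n_cycles)
    keep = (t >= lo - 1e-9) & (t < hi - 1e-9)
    amp = amp[..., keep]
    times = t[keep]
    if params.decim > 1:
        amp = amp[..., :: params.decim]
        times = times[:: params.decim]
    # move time to the middle axis: (freq, [epoch,] channel, time) ->
    # (freq, [epoch,] time, channel)
    amp = np.swapaxes(amp, -1, -2)
    if mode == "per_epoch":
        amp = np.moveaxis(amp, 1, 0)  # (epoch, freq, time, channel)
    values = amp**2 if kind == "power" else amp
    half_dur = params.n_cycles / (2.0 * freqs)
    edge_mask = (times[None, :] - t[0] >= half_dur[:, None]) & (
        t[-1] - times[None, :] >= half_dur[:, None]
    )
    n_full = epochs.data.shape[2]
    gain = np.empty((freqs.size, times.size))
    keep_idx = np.flatnonzero(keep)[:: params.decim if params.decim > 1 else 1]
    for i, f in enumerate(freqs):
        w = morlet_wavelet(f, epochs.fs, params.n_cycles)
        energy = np.abs(w) ** 2
        g = sig.fftconvolve(np.ones(n_full), energy / energy.sum(), mode="same")
        gain[i] = np.clip(g[keep_idx], 1e-12, 1.0)
    tfr_kind = ("evoked_" if mode == "evoked" else "epoch_") + kind
    return TFR(
        values=values,
        freqs=freqs,
        times=times,
        channels=epochs.channels,
        kind=tfr_kind,
        edge_mask=edge_mask,
        edge_gain=gain,
    )


@dataclass
class SNRMap:
    """Time-resolved SNR at the target frequency: (times, channels)."""

    values: np.ndarray
    times: np.ndarray
    channels: tuple[str, ...]
    f0: float

    def channel_indices(self, labels) -> np.ndarray:
        idx = {ch: i for i, ch in enumerate(self.channels)}
        return np.array([idx[ch] for ch in labels], dtype=int)


def _noise_floor(tfr: TFR, f_target: float, offsets) -> np.ndarray:
    """Per-channel noise proxy: neighbor-band power averaged over time.

    Each time point is first divided by the band's deterministic edge
    attenuation (the fraction of wavelet energy falling inside the
    epoch), so the time average over the full wavelet window estimates
    the stationary noise power without the edge-deflation bias.
    """
    neigh = []
    for off in offsets:
        f = f_target + off
        if np.any(np.abs(tfr.freqs - f) < 1e-9):
            i = tfr.freq_index(f)
            vals = tfr.values[i]
            if tfr.edge_gain is not None:
                g = tfr.edge_gain[i]
                if "amplitude" in tfr.kind:
                    g = np.sqrt(g)
                vals = vals / g[:, None]
            neigh.append(vals.mean(axis=0))
    if not neigh:
        raise DegenerateInputError(f"no neighbor bands on grid around {f_target} Hz")
    return np.mean(neigh, axis=0)  # (channels,)


def snr_timeresolved(tfr: TFR, params: AnalysisParams = AnalysisParams()) -> SNRMap:
    """SNR(ch, t) = P(ch, f0, t) / N(ch) - 1 at the stimulation frequency."""
    if tfr.values.ndim != 3:
        raise ConfigurationError("snr_timeresolved expects an evoked (3-d) TFR")
    noise = _noise_floor(tfr, params.f0, params.neighbor_offsets)
    if np.any(noise <= 0):
        raise DegenerateInputError("zero noise floor on some channel")
    p0 = tfr.values[tfr.freq_index(params.f0)]
    return SNRMap(
        values=p0 / noise[None, :] - 1.0,
        times=tfr.times,
        channels=tfr.channels,
        f0=params.f0,
    )


def snr_spectrum(tfr: TFR, params: AnalysisParams = AnalysisParams()) -> np.ndarray:
    """SNR for every band on the grid (freqs, times, channels).

    Each band uses its own four neighbors; bands whose neighbors fall off
    the grid use the neighbors that remain (grid edges).
    """
    if tfr.values.ndim != 3:
        raise ConfigurationError("snr_spectrum expects an evoked (3-d) TFR")
    out = np.empty_like(tfr.values)
    for i, f in enumerate(tfr.freqs):
        noise = _noise_floor(tfr, f, params.neighbor_offsets)
        if np.any(noise <= 0):
            raise DegenerateInputError("zero noise floor on some channel")
        out[i] = tfr.values[i] / noise[None, :] - 1.0
    return out


def aggregate_snr(
    snr_map: SNRMap,
    channel_set,
    time_window: tuple[float, float] | None = None,
) -> float:
    """Mean SNR over a channel set and time window (flat rectangle mean).

    Mastoids are excluded from channel averages by caller convention;
    this function only requires a non-empty channel set.
    """
    channel_set = tuple(channel_set)
    if not channel_set:
        raise ConfigurationError("empty channel set")
    idx = snr_map.channel_indices(channel_set)
    t = snr_map.times
    if time_window is None:
        tmask = np.ones_like(t, dtype=bool)
    else:
        tmask = (t >= time_window[0] - 1e-9) & (t < time_window[1] - 1e-9)
    if not tmask.any():
        raise ConfigurationError(f"empty time window {time_window}")
    return float(snr_map.values[np.ix_(tmask, idx)].mean())


def grand_mean(maps: list[SNRMap]) -> SNRMap:
    """Element-wise mean over subjects."""
    if not maps:
        raise ConfigurationError("no SNR maps to average")
    first = maps[0]
    for m in maps[1:]:
        if m.values.shape != first.values.shape or m.channels != first.channels:
            raise ConfigurationError("SNR maps have inconsistent grids")
    return SNRMap(
        values=np.mean([m.values for m in maps], axis=0),
        times=first.times,
        channels=first.channels,
        f0=first.f0,
    )


@dataclass(frozen=True)
class OneSampleTResult:
    t: float
    df: int
    p: float
    mean: float
    degenerate: bool = False


def snr_vs_noise_test(values: np.ndarray) -> OneSampleTResult:
    """One-sample t-test of per-subject SNR scalars against the noise level 0."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DegenerateInputError("need at least 2 subjects")
    sd = x.std(ddof=1)
    if sd == 0.0:
        t = 0.0 if np.isclose(x.mean(), 0) else float(np.sign(x.mean()) * np.inf)
        return OneSampleTResult(
            t=t, df=x.size - 1, p=1.0 if t == 0 else 0.0, mean=float(x.mean()),
            degenerate=True,
        )
    t, p = sps.ttest_1samp(x, 0.0)
    return OneSampleTResult(
        t=float(t), df=x.size - 1, p=float(p), mean=float(x.mean())
    )


def scalp_channels(channels, exclude=MASTOIDS) -> tuple[str, ...]:
    """Channel tuple with mastoids removed (SNR/AEC averaging convention)."""
    return tuple(ch for ch in channels if ch not in exclude)
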