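"""Amplitude-envelope correlation (AEC) between infant and mother.

For each mutual epoch, the per-epoch Morlet amplitude at the stimulation
frequency is baseline-corrected (mean over 500-200 ms before image
onset subtracted per channel), averaged across scalp channels (mastoids
excluded), and the two members' envelopes are Pearson-correlated over
the image window.  Per-epoch correlations are Fisher z-transformed,
averaged within condition per dyad, and reported back on the r scale via
the inverse transform — averaging happens in z space, never on raw r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DegenerateInputError
from .preprocess import EpochSet
from .schedule import CONDITIONS
from .spectral import AnalysisParams, morlet_tfr, scalp_channels

ENVELOPE_BASELINE_S = (-0.5, -0.2)
DEFAULT_CORR_WINDOW_S = (0.0, 2.0)

_Z_CLIP = 1.0 - 1e-7


@dataclass
class EnvelopeSet:
    """Per-epoch amplitude envelopes at f0, channel-averaged.

    ``envelopes`` is (n_epochs, n_times); ``epoch_rows`` records which
    rows of the source epoch set these are (mutual epochs), so the two
    members of a dyad can be aligned.
    """

    envelopes: np.ndarray
    times: np.ndarray
    epoch_rows: np.ndarray
    channel_set: tuple[str, ...]
    baseline: tuple[float, float]
    per_channel: np.ndarray | None = None  # (n_epochs, n_times, n_channels)


def epoch_envelopes(
    epochs: EpochSet,
    params: AnalysisParams = AnalysisParams(),
    channel_set=None,
    baseline: tuple[float, float] = ENVELOPE_BASELINE_S,
    rows: np.ndarray | None = None,
    keep_channels: bool = False,
) -> EnvelopeSet:
    """Per-epoch wavelet amplitude at f0, baseline-corrected, channel-averaged.

    ``rows`` selects the (mutual) epochs to transform; ``channel_set``
    defaults to all scalp channels without mastoids.
    """
    if rows is None:
        rows = np.arange(epochs.n_epochs)
    rows = np.asarray(rows, dtype=int)
    if rows.size == 0:
        raise DegenerateInputError("empty mutual epoch set")
    channel_set = (
        scalp_channels(epochs.channels) if channel_set is None else tuple(channel_set)
    )
    if not channel_set:
        raise ConfigurationError("empty channel set")
    tfr = morlet_tfr(
        epochs, params, mode="per_epoch", kind="amplitude",
        freqs=np.array([params.f0]), rows=rows,
    )
    amp = tfr.values[:, 0]  # (n_epochs, n_times, n_channels)
    t = tfr.times
    bmask = (t >= baseline[0] - 1e-9) & (t < baseline[1] - 1e-9)
    if not bmask.any():
        raise ConfigurationError(f"baseline window {baseline} outside TFR window")
    amp = amp - amp[:, bmask, :].mean(axis=1, keepdims=True)
    idx = epochs.channel_indices(channel_set)
    env = amp[:, :, idx].mean(axis=2)
    return EnvelopeSet(
        envelopes=env,
        times=t,
        epoch_rows=rows,
        channel_set=channel_set,
        baseline=baseline,
        per_channel=amp[:, :, idx] if keep_channels else None,
    )


def epoch_aec(
    env_infant: EnvelopeSet,
    env_mother: EnvelopeSet,
    corr_window: tuple[float, float] = DEFAULT_CORR_WINDOW_S,
) -> tuple[np.ndarray, int]:
    """Pearson r of the two channel-averaged envelopes, one per epoch.

    Epochs with a zero-variance envelope are dropped (their count is
    returned alongside the correlations).
    """
    if not np.array_equal(env_infant.epoch_rows, env_mother.epoch_rows):
        raise ConfigurationError("envelope sets cover different epochs")
    t = env_infant.times
    mask = (t >= corr_window[0] - 1e-9) & (t < corr_window[1] - 1e-9)
    if mask.sum() < 3:
        raise ConfigurationError(f"correlation window {corr_window} too short")
    a = env_infant.envelopes[:, mask]
    b = env_mother.envelopes[:, mask]
    sa = a.std(axis=1)
    sb = b.std(axis=1)
    ok = (sa > 0) & (sb > 0)
    n_dropped = int(np.sum(~ok))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} zero-variance epochs from AEC")
    a = a[ok] - a[ok].mean(axis=1, keepdims=True)
    b = b[ok] - b[ok].mean(axis=1, keepdims=True)
    r = (a * b).sum(axis=1) / (
        np.sqrt((a**2).sum(axis=1)) * np.sqrt((b**2).sum(axis=1))
    )
    return np.clip(r, -1.0, 1.0), n_dropped


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilizing transform z = atanh(r); |r|=1 is clipped to
    keep z finite."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1.0 + 1e-12):
        raise ConfigurationError("correlations must satisfy |r| <= 1")
    z = np.arctanh(np.clip(r, -_Z_CLIP, _Z_CLIP))
    return float(z) if z.ndim == 0 else z


def fisher_inv(z: np.ndarray | float) -> np.ndarray | float:
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


@dataclass
class AECResult:
    """Per-dyad synchrony summary: z-mean per condition and the r-scale
    report value tanh(mean z)."""

    mean_z: dict[str, float]
    mean_r: dict[str, float]
    n_epochs: dict[str, int]
    epoch_z: dict[str, np.ndarray]


def dyad_aec(
    r_by_condition: dict[str, np.ndarray],
    min_epochs: int = 5,
) -> AECResult:
    """Condition-level AEC for one dyad: Fisher z, average, transform back."""
    mean_z, mean_r, n_ep, epoch_z = {}, {}, {}, {}
    for cond, r in r_by_condition.items():
        r = np.asarray(r, dtype=float)
        if r.size < min_epochs:
            raise DegenerateInputError(
                f"condition {cond}: {r.size} epochs < min_mutual {min_epochs}"
            )
        z = fisher_z(r)
        epoch_z[cond] = z
        mean_z[cond] = float(np.mean(z))
        mean_r[cond] = float(np.tanh(mean_z[cond]))
        n_ep[cond] = int(r.size)
    return AECResult(mean_z=mean_z, mean_r=mean_r, n_epochs=n_ep, epoch_z=epoch_z)


def channelpair_aec(
    epochs_infant: EpochSet,
    epochs_mother: EpochSet,
    params: AnalysisParams = AnalysisParams(),
    corr_window: tuple[float, float] = DEFAULT_CORR_WINDOW_S,
    baseline: tuple[float, float] = ENVELOPE_BASELINE_S,
) -> dict[str, np.ndarray]:
    """Channel-by-channel AEC z matrices per condition.

    Entry (i, j) correlates infant channel i with mother channel j per
    mutual epoch (no channel averaging), z-transforms, and averages over
    epochs.  Roles differ, so the matrix is not symmetric.  Mastoids are
    excluded.
    """
    out = {}
    cond_i = epochs_infant.metadata["condition"].to_numpy()
    mutual = epochs_infant.metadata["mutual"].to_numpy() & epochs_mother.metadata[
        "mutual"
    ].to_numpy()
    chans = scalp_channels(epochs_infant.channels)
    for cond in CONDITIONS:
        rows = np.flatnonzero(mutual & (cond_i == cond))
        if rows.size == 0:
            raise DegenerateInputError(f"no mutual epochs in condition {cond}")
        envs = []
        for ep in (epochs_infant, epochs_mother):
            es = epoch_envelopes(
                ep, params, channel_set=chans, baseline=baseline,
                rows=rows, keep_channels=True,
            )
            t = es.times
            mask = (t >= corr_window[0] - 1e-9) & (t < corr_window[1] - 1e-9)
            e = es.per_channel[:, mask, :]  # (epochs, times, channels)
            e = e - e.mean(axis=1, keepdims=True)
            sd = e.std(axis=1, keepdims=True)
            sd[sd == 0] = np.inf  # zero-variance channel -> r = 0
            envs.append(e / sd)
        ei, em = envs
        n_t = ei.shape[1]
        r = np.einsum("eti,etj->eij", ei, em) / n_t
        z = fisher_z(np.clip(r, -1.0, 1.0))
        out[cond] = z.mean(axis=0)
    return out
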