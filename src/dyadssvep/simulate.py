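"""Synthetic two-person EEG with the statistical structure the pipeline assumes.

Each simulated dyad consists of an infant and a mother recording sharing
one stimulus schedule.  Per channel, the signal is

    x(t) = sum_images gate(t) * w(ch) * A(role, cond) * (1 + m * e(t)) * sin(2*pi*f0*(t - onset))
           + pink_noise(alpha, RMS)

where ``gate`` is a cosine-ramped window over the 2-s image presentation,
``w`` a role-specific scalp topography weight, ``A`` the condition- and
role-dependent evoked amplitude (microvolt), and ``e`` a slow (low-pass)
amplitude envelope restarted at each image onset.  Infant and mother
envelopes of the same epoch are correlated with a condition-dependent
coupling coefficient rho — the ground-truth quantity the inter-brain
amplitude-envelope correlation is designed to detect.

Gaze attendance and artifact occurrence are Bernoulli per image; epochs
carrying an artifact also receive a large transient so the downstream
peak-to-peak rejection flags exactly those epochs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import h5py
import numpy as np
from scipy import fft as sfft
from scipy import signal as sig

from .errors import ConfigurationError, DataIOError, ScheduleError
from .montage import CHANNELS, COP_CHANNELS, MASTOIDS
from .schedule import CONDITIONS, GazeTrack, StimulusSchedule

ROLES = ("infant", "mother")

_CENTRAL = ("C3", "C4", "CPz", "Cz")


def default_topo_weights() -> dict[str, dict[str, float]]:
    """Role-specific scalp weights of the evoked response.

    Infants: central-occipital-parietal emphasis; mothers: central
    emphasis.  Remaining scalp channels get a weak projection and the
    mastoids almost none.
    """
    weights = {}
    for role, emphasis in (("infant", COP_CHANNELS), ("mother", _CENTRAL)):
        w = {}
        for ch in CHANNELS:
            if ch in emphasis:
                w[ch] = 1.0
            elif ch in MASTOIDS:
                w[ch] = 0.1
            else:
                w[ch] = 0.3
        weights[role] = w
    return weights


@dataclass
class SynthConfig:
    """Generator parameters (amplitudes in microvolt, frequencies in Hz)."""

    f0: float = 4.0
    fs: float = 500.0
    amplitude: dict = field(
        default_factory=lambda: {
            "infant": {"JA": 6.0, "JW": 5.0},
            "mother": {"JA": 4.8, "JW": 4.0},
        }
    )
    topo_weights: dict = field(default_factory=default_topo_weights)
    envelope_coupling: dict = field(default_factory=lambda: {"JA": 0.0, "JW": 0.0})
    envelope_mod_depth: float = 0.3
    envelope_cutoff_hz: float = 1.0
    noise_exponent: float = 1.0
    noise_rms: float = 20.0
    attend_prob: dict = field(
        default_factory=lambda: {
            "infant": {"JA": 0.65, "JW": 0.54},
            "mother": {"JA": 0.78, "JW": 0.79},
        }
    )
    artifact_prob: dict = field(
        default_factory=lambda: {
            "infant": {"JA": 0.50, "JW": 0.50},
            "mother": {"JA": 0.40, "JW": 0.19},
        }
    )
    ramp_ms: float = 100.0
    waveform: str = "sine"
    phase_jitter_sd: float = 0.0
    envelope_mode: str = "per_epoch"
    artifact_amplitude: float = 600.0
    rng_seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not (0 <= self.envelope_mod_depth < 1):
            raise ConfigurationError("envelope_mod_depth must be in [0, 1)")
        for cond, rho in self.envelope_coupling.items():
            if not (0.0 <= rho <= 1.0):
                raise ConfigurationError(f"coupling rho[{cond}] outside [0, 1]")
        for table in (self.attend_prob, self.artifact_prob):
            for role in ROLES:
                for cond in CONDITIONS:
                    p = table[role][cond]
                    if not (0.0 <= p <= 1.0):
                        raise ConfigurationError("probabilities must be in [0, 1]")
        for role in ROLES:
            for cond in CONDITIONS:
                if self.amplitude[role][cond] < 0:
                    raise ConfigurationError("amplitudes must be >= 0")
        if self.waveform not in ("sine", "square"):
            raise ConfigurationError(f"unknown waveform {self.waveform!r}")
        if self.envelope_mode not in ("per_epoch", "continuous"):
            raise ConfigurationError(f"unknown envelope_mode {self.envelope_mode!r}")
        if self.noise_rms < 0 or self.ramp_ms < 0:
            raise ConfigurationError("noise_rms and ramp_ms must be >= 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "SynthConfig":
        return cls(**json.loads(s))

    def replace(self, **kw) -> "SynthConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# noise and envelopes
# ---------------------------------------------------------------------------

def pink_noise(
    shape: tuple[int, ...],
    n_samples: int,
    fs: float,
    rms: float,
    exponent: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """1/f^alpha Gaussian noise, sampled directly in the spectral domain.

    Returns an array of ``shape + (n_samples,)`` whose population RMS per
    trace equals ``rms``.  DC and Nyquist bins are zero.
    """
    rng = rng or np.random.default_rng()
    if rms <= 0:
        return np.zeros((*shape, n_samples))
    nfft = int(2 ** np.ceil(np.log2(max(n_samples, 2))))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    amp[-1] = 0.0
    sigma = np.sqrt(2.0 * np.sum(amp[:-1] ** 2)) / nfft
    amp *= rms / sigma
    # float32 draws + complex64 transform: precision is ample at microvolt
    # scale and the transform dominates generator cost
    re = rng.standard_normal((*shape, freqs.size), dtype=np.float32)
    im = rng.standard_normal((*shape, freqs.size), dtype=np.float32)
    spec = (re + 1j * im) * (amp / np.sqrt(2.0)).astype(np.float32)
    x = sfft.irfft(spec, nfft, axis=-1)
    return np.ascontiguousarray(x[..., :n_samples], dtype=np.float64)


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _lowpass_noise(
    shape: tuple[int, ...],
    n_samples: int,
    cutoff_hz: float,
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Low-pass filtered white noise, standardized per trace."""
    pad = int(round(2.0 * fs / max(cutoff_hz, 0.25)))
    w = rng.standard_normal((*shape, n_samples + 2 * pad))
    sos = sig.butter(4, cutoff_hz, btype="low", fs=fs, output="sos")
    e = sig.sosfiltfilt(sos, w, axis=-1)[..., pad : pad + n_samples]
    return _standardize(e)


def simulate_envelope_pair(
    rho: float,
    cutoff_hz: float,
    duration_s: float,
    fs: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Two coupled slow envelopes with population correlation ``rho``.

    Built as ``e = sqrt(rho) * shared + sqrt(1 - rho) * own`` from
    independent standardized low-pass Gaussian processes.
    """
    if not (0.0 <= rho <= 1.0):
        raise ConfigurationError("rho must be in [0, 1]")
    n = int(round(duration_s * fs))
    e = _lowpass_noise((3,), n, cutoff_hz, fs, rng)
    shared, own_i, own_m = e
    a, b = np.sqrt(rho), np.sqrt(1.0 - rho)
    return a * shared + b * own_i, a * shared + b * own_m


def _envelope_pairs_batch(
    rhos: np.ndarray,
    cutoff_hz: float,
    n_samples: int,
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_epochs, 2, n_samples) coupled envelope pairs, one rho per epoch."""
    n_ep = rhos.size
    e = _lowpass_noise((n_ep, 3), n_samples, cutoff_hz, fs, rng)
    a = np.sqrt(rhos)[:, None]
    b = np.sqrt(1.0 - rhos)[:, None]
    out = np.empty((n_ep, 2, n_samples))
    out[:, 0] = a * e[:, 0] + b * e[:, 1]
    out[:, 1] = a * e[:, 0] + b * e[:, 2]
    return out


# ---------------------------------------------------------------------------
# evoked response
# ---------------------------------------------------------------------------

def _gate(n: int, fs: float, ramp_ms: float) -> np.ndarray:
    """Cosine-ramped on/off window over the image presentation."""
    g = np.ones(n)
    nr = int(round(ramp_ms / 1000.0 * fs))
    if nr > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
        g[:nr] = ramp
        g[-nr:] = ramp[::-1]
    return g


def _carrier(t: np.ndarray, f0: float, phase: float, waveform: str) -> np.ndarray:
    s = np.sin(2 * np.pi * f0 * t + phase)
    if waveform == "square":
        s = np.sign(s)
    return s


def draw_epoch_flags(
    config: SynthConfig, schedule: StimulusSchedule, rng: np.random.Generator
) -> dict[str, dict[str, np.ndarray]]:
    """Bernoulli attendance and artifact flags per role for every image."""
    conds = schedule.conditions
    flags: dict[str, dict[str, np.ndarray]] = {}
    for role in ROLES:
        p_att = np.array([config.attend_prob[role][c] for c in conds])
        p_art = np.array([config.artifact_prob[role][c] for c in conds])
        flags[role] = {
            "attended": rng.random(conds.size) < p_att,
            "artifact": rng.random(conds.size) < p_art,
        }
    return flags


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

@dataclass
class DyadDataset:
    """Continuous two-subject recording plus schedule, gaze and ground truth."""

    signals: dict[str, np.ndarray]  # role -> (n_channels, n_samples), microvolt
    fs: float
    channels: tuple[str, ...]
    schedule: StimulusSchedule
    gaze: dict[str, GazeTrack]
    ground_truth: dict

    @property
    def n_samples(self) -> int:
        return self.signals["infant"].shape[1]


@dataclass
class EpochSim:
    """Directly epoched simulation output (both roles share envelope draws)."""

    data: dict[str, np.ndarray]  # role -> (n_selected, n_channels, n_samples)
    times: np.ndarray  # seconds relative to image onset
    meta: "object"  # pandas DataFrame over all images
    indices: np.ndarray  # rows of ``meta`` that were materialized
    envelopes: np.ndarray  # (n_selected, 2, n_image_samples) ground truth
    fs: float
    channels: tuple[str, ...]


def _weights_matrix(config: SynthConfig, role: str) -> np.ndarray:
    return np.array([config.topo_weights[role][ch] for ch in CHANNELS])


def _evoked_epoch_matrix(
    config: SynthConfig,
    conds: np.ndarray,
    envelopes: np.ndarray,
    role_idx: int,
    role: str,
    phases: np.ndarray,
    times: np.ndarray,
) -> np.ndarray:
    """Evoked contribution for a batch of epochs, (n_ep, n_ch, n_t)."""
    n_ep = conds.size
    img_mask = (times >= 0) & (times < StimulusSchedule.image_duration_s)
    t_img = times[img_mask]
    n_img = t_img.size
    gate = _gate(n_img, config.fs, config.ramp_ms)
    amps = np.array([config.amplitude[role][c] for c in conds])
    w = _weights_matrix(config, role)
    out = np.zeros((n_ep, len(CHANNELS), times.size))
    m = config.envelope_mod_depth
    for k in range(n_ep):
        carrier = _carrier(t_img, config.f0, phases[k], config.waveform)
        env = 1.0 + m * envelopes[k, role_idx, :n_img]
        wave = gate * env * carrier * amps[k]
        out[k, :, img_mask.nonzero()[0]] = (w[:, None] * wave[None, :]).T
    return out


def simulate_epochs(
    config: SynthConfig,
    schedule: StimulusSchedule,
    rng: np.random.Generator | int | None = None,
    window: tuple[float, float] = (-1.5, 3.5),
    indices: np.ndarray | None = None,
    inject_artifacts: bool = True,
    flags: dict | None = None,
) -> EpochSim:
    """Simulate epoched data directly around image onsets.

    Statistically equivalent to cutting the continuous simulation into
    epochs (epochs are independent by construction: noise carries no
    dependence across the inter-stimulus interval at the analyzed
    frequencies).  ``indices`` restricts which image events are
    materialized — flags and metadata always cover the full schedule.
    """
    import pandas as pd

    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(config.rng_seed if rng is None else rng)
    fs = config.fs
    times = np.arange(round(window[0] * fs), round(window[1] * fs)) / fs
    images = schedule.images
    conds = schedule.conditions
    n_images = conds.size

    if flags is None:
        flags = draw_epoch_flags(config, schedule, rng)
    meta = pd.DataFrame(
        {
            "onset_s": images["time_s"].to_numpy(),
            "condition": conds,
            "block": images["block"].to_numpy(),
            "image_id": images["image_id"].to_numpy(),
            "attended_infant": flags["infant"]["attended"],
            "artifact_infant": flags["infant"]["artifact"],
            "attended_mother": flags["mother"]["attended"],
            "artifact_mother": flags["mother"]["artifact"],
        }
    )

    if indices is None:
        indices = np.arange(n_images)
    indices = np.asarray(indices, dtype=int)
    sel_conds = conds[indices]
    n_sel = indices.size

    n_img = int(round(StimulusSchedule.image_duration_s * fs))
    rhos = np.array([config.envelope_coupling[c] for c in sel_conds])
    envelopes = _envelope_pairs_batch(rhos, config.envelope_cutoff_hz, n_img, fs, rng)
    phases = (
        rng.normal(0.0, config.phase_jitter_sd, n_sel)
        if config.phase_jitter_sd > 0
        else np.zeros(n_sel)
    )

    data = {}
    for role_idx, role in enumerate(ROLES):
        x = pink_noise(
            (n_sel, len(CHANNELS)),
            times.size,
            fs,
            config.noise_rms,
            config.noise_exponent,
            rng,
        )
        x += _evoked_epoch_matrix(
            config, sel_conds, envelopes, role_idx, role, phases, times
        )
        if inject_artifacts:
            art = flags[role]["artifact"][indices]
            for k in np.flatnonzero(art):
                x[k] += _artifact_bump(times, config, rng)[None, :]
        data[role] = x
    return EpochSim(
        data=data,
        times=times,
        meta=meta,
        indices=indices,
        envelopes=envelopes,
        fs=fs,
        channels=CHANNELS,
    )


def _artifact_bump(
    times: np.ndarray, config: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    """Large slow transient inside the image window (rejection stand-in)."""
    t0 = rng.uniform(0.2, 1.8)
    return config.artifact_amplitude * np.exp(-((times - t0) ** 2) / (2 * 0.05**2))


def _gaze_from_flags(
    role: str,
    onsets: np.ndarray,
    attended: np.ndarray,
    rng: np.random.Generator,
    image_duration: float = 2.0,
) -> GazeTrack:
    """Turn Bernoulli attendance into plausible on-screen gaze intervals."""
    iv = []
    for on, att in zip(onsets, attended):
        off = on + image_duration
        if att:
            if rng.random() < 0.25:  # attends via the grace window
                start = on + rng.uniform(0.05, 0.45)
            else:
                start = on - rng.uniform(0.2, 0.8)
            iv.append((start, off + rng.uniform(0.05, 0.3)))
        elif rng.random() < 0.5:  # late, non-qualifying look
            iv.append((on + rng.uniform(0.6, 1.5), off + rng.uniform(0.0, 0.2)))
    iv.sort()
    merged: list[list[float]] = []
    for s, e in iv:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return GazeTrack(role=role, intervals=np.array(merged).reshape(-1, 2))


def simulate_dyad(
    config: SynthConfig,
    schedule: StimulusSchedule,
    rng_seed: int | None = None,
    duration_s: float | None = None,
) -> DyadDataset:
    """Simulate one dyad as two continuous 24-channel recordings.

    The recording spans the schedule plus a 1-s tail; ``duration_s`` may
    request a longer recording but not one shorter than the schedule.
    """
    rng = np.random.default_rng(config.rng_seed if rng_seed is None else rng_seed)
    fs = config.fs
    needed = schedule.end_time_s + 1.0
    if duration_s is None:
        duration_s = needed
    elif duration_s < needed:
        raise ScheduleError(
            f"schedule needs {needed:.1f}s but only {duration_s:.1f}s requested"
        )
    n = int(round(duration_s * fs))
    t_axis_n_img = int(round(StimulusSchedule.image_duration_s * fs))

    flags = draw_epoch_flags(config, schedule, rng)
    onsets = schedule.onsets
    conds = schedule.conditions
    rhos = np.array([config.envelope_coupling[c] for c in conds])

    if config.envelope_mode == "per_epoch":
        envelopes = _envelope_pairs_batch(
            rhos, config.envelope_cutoff_hz, t_axis_n_img, fs, rng
        )
    else:  # one continuous pair per condition, epochs read segments
        cont = {
            c: simulate_envelope_pair(
                config.envelope_coupling[c], config.envelope_cutoff_hz, duration_s, fs, rng
            )
            for c in CONDITIONS
        }
        envelopes = np.empty((onsets.size, 2, t_axis_n_img))
        for k, (on, c) in enumerate(zip(onsets, conds)):
            i0 = int(round(on * fs))
            for r in range(2):
                envelopes[k, r] = cont[c][r][i0 : i0 + t_axis_n_img]

    phases = (
        rng.normal(0.0, config.phase_jitter_sd, onsets.size)
        if config.phase_jitter_sd > 0
        else np.zeros(onsets.size)
    )
    gate = _gate(t_axis_n_img, fs, config.ramp_ms)
    t_img = np.arange(t_axis_n_img) / fs
    m = config.envelope_mod_depth

    signals = {}
    for role_idx, role in enumerate(ROLES):
        x = pink_noise(
            (len(CHANNELS),), n, fs, config.noise_rms, config.noise_exponent, rng
        )
        w = _weights_matrix(config, role)
        for k, (on, c) in enumerate(zip(onsets, conds)):
            i0 = int(round(on * fs))
            carrier = _carrier(t_img, config.f0, phases[k], config.waveform)
            wave = (
                gate
                * (1.0 + m * envelopes[k, role_idx])
                * carrier
                * config.amplitude[role][c]
            )
            x[:, i0 : i0 + t_axis_n_img] += w[:, None] * wave[None, :]
            if flags[role]["artifact"][k]:
                bump_t = np.arange(n) / fs - on
                win = (bump_t > -0.5) & (bump_t < 2.5)
                bump = _artifact_bump(bump_t[win], config, rng)
                x[:, win] += bump[None, :]
        signals[role] = x

    gaze = {
        role: _gaze_from_flags(role, onsets, flags[role]["attended"], rng)
        for role in ROLES
    }
    ground_truth = {
        "config_json": config.to_json(),
        "seed": int(config.rng_seed if rng_seed is None else rng_seed),
        "rho": {c: float(config.envelope_coupling[c]) for c in CONDITIONS},
        "envelopes": envelopes,
        "phases": phases,
        "attended": {r: flags[r]["attended"] for r in ROLES},
        "artifact": {r: flags[r]["artifact"] for r in ROLES},
    }
    return DyadDataset(
        signals=signals,
        fs=fs,
        channels=CHANNELS,
        schedule=schedule,
        gaze=gaze,
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# container I/O (HDF5)
# ---------------------------------------------------------------------------

def write_dyad(dataset: DyadDataset, path, compress: bool = False) -> None:
    """Write a dyad dataset to an HDF5 container (signals stored float32).

    ``compress=True`` additionally quantizes signals to 0.01 microvolt
    (far below the noise floor) and gzips them — used for small on-disk
    fixtures; the default store is plain float32.
    """
    sig_kw = (
        {"compression": "gzip", "shuffle": True, "scaleoffset": 2}
        if compress
        else {}
    )
    try:
        with h5py.File(path, "w") as f:
            g = f.create_group("signals")
            for role in ROLES:
                g.create_dataset(
                    role, data=dataset.signals[role].astype(np.float32), **sig_kw
                )
            f.attrs["fs"] = dataset.fs
            f.attrs["channels"] = list(dataset.channels)
            ev = dataset.schedule.events
            sg = f.create_group("schedule")
            for col in ev.columns:
                vals = ev[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S")
                sg.create_dataset(col, data=vals)
            gg = f.create_group("gaze")
            for role in ROLES:
                gg.create_dataset(role, data=dataset.gaze[role].intervals)
            gt = dataset.ground_truth
            tg = f.create_group("ground_truth")
            tg.attrs["config_json"] = gt["config_json"]
            tg.attrs["seed"] = gt["seed"]
            for c, v in gt["rho"].items():
                tg.attrs[f"rho_{c}"] = v
            tg.create_dataset("envelopes", data=gt["envelopes"])
            tg.create_dataset("phases", data=gt["phases"])
            for r in ROLES:
                tg.create_dataset(f"attended_{r}", data=gt["attended"][r])
                tg.create_dataset(f"artifact_{r}", data=gt["artifact"][r])
    except OSError as err:
        raise DataIOError(f"cannot write dyad container {path}: {err}") from err


def read_dyad(path) -> DyadDataset:
    """Read a dyad dataset written by :func:`write_dyad`."""
    import pandas as pd

    try:
        with h5py.File(path, "r") as f:
            signals = {role: f["signals"][role][()].astype(float) for role in ROLES}
            fs = float(f.attrs["fs"])
            channels = tuple(
                c.decode() if isinstance(c, bytes) else str(c)
                for c in f.attrs["channels"]
            )
            cols = {}
            for col in SCHEDULE_COLUMNS_H5:
                vals = f["schedule"][col][()]
                if vals.dtype.kind == "S":
                    vals = vals.astype(str)
                cols[col] = vals
            schedule = StimulusSchedule(events=pd.DataFrame(cols))
            gaze = {
                role: GazeTrack(role=role, intervals=f["gaze"][role][()])
                for role in ROLES
            }
            tg = f["ground_truth"]
            gt = {
                "config_json": str(tg.attrs["config_json"]),
                "seed": int(tg.attrs["seed"]),
                "rho": {c: float(tg.attrs[f"rho_{c}"]) for c in CONDITIONS},
                "envelopes": tg["envelopes"][()],
                "phases": tg["phases"][()],
                "attended": {r: tg[f"attended_{r}"][()].astype(bool) for r in ROLES},
                "artifact": {r: tg[f"artifact_{r}"][()].astype(bool) for r in ROLES},
            }
    except (OSError, KeyError) as err:
        raise DataIOError(f"cannot read dyad container {path}: {err}") from err
    return DyadDataset(
        signals=signals,
        fs=fs,
        channels=channels,
        schedule=schedule,
        gaze=gaze,
        ground_truth=gt,
    )


SCHEDULE_COLUMNS_H5 = ["time_s", "kind", "condition", "block", "image_id", "duration_s"]
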