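"""Replicate studies: statistical calibration and parameter recovery.

These functions run the analysis pipeline many times over independent
simulated cohorts to measure operating characteristics: type-I error of
the cluster permutation, mixed-model and FDR machinery under the null,
and detection power for the effects the generator can inject (an infant
JA amplitude boost; condition-dependent envelope coupling).

For speed, cohort replicates materialize only the epochs that survive
attendance/artifact attrition — the Bernoulli survival flags are drawn
for the full schedule first, and discarded epochs never influence any
downstream statistic, so the shortcut is distribution-preserving.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import preprocess as prep
from . import spectral, stats, synchrony
from .montage import COP_CHANNELS, REGIONS, build_montage
from .schedule import CONDITIONS, generate_schedule, inclusion_decision
from .simulate import SynthConfig, simulate_epochs
from .spectral import AnalysisParams


def _sub_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(c) for c in np.random.SeedSequence(seed).spawn(n)]


def _surviving_indices(meta: pd.DataFrame, role: str) -> np.ndarray:
    ok = meta[f"attended_{role}"].to_numpy() & ~meta[f"artifact_{role}"].to_numpy()
    return np.flatnonzero(ok)


def _mutual_indices(meta: pd.DataFrame) -> np.ndarray:
    ok = np.ones(len(meta), dtype=bool)
    for role in ("infant", "mother"):
        ok &= meta[f"attended_{role}"].to_numpy() & ~meta[
            f"artifact_{role}"
        ].to_numpy()
    return np.flatnonzero(ok)


def _neighbor_freqs(params: AnalysisParams) -> np.ndarray:
    return np.array(sorted({params.f0, *(params.f0 + np.array(params.neighbor_offsets))}))


def _infant_cop_snr(
    config: SynthConfig,
    params: AnalysisParams,
    rng: np.random.Generator,
    channel_set=COP_CHANNELS,
    min_epochs: int = 5,
) -> dict[str, float] | None:
    sched = generate_schedule(
        first_condition=CONDITIONS[int(rng.integers(2))], rng_seed=rng
    )
    from .simulate import draw_epoch_flags

    flags = draw_epoch_flags(config, sched, rng)
    ok = flags["infant"]["attended"] & ~flags["infant"]["artifact"]
    conds = sched.conditions
    counts = {c: int(np.sum(ok & (conds == c))) for c in CONDITIONS}
    if not inclusion_decision(counts, min_epochs):
        return None
    idx = np.flatnonzero(ok)
    sim = simulate_epochs(
        config, sched, rng=rng, indices=idx, inject_artifacts=False, flags=flags
    )
    epochs = prep.from_simulated(sim, "infant")
    epochs = prep.baseline_correct(epochs)
    epochs = prep.rereference_average(epochs)
    cond = epochs.metadata["condition"].to_numpy()
    freqs = _neighbor_freqs(params)
    out = {}
    for c in CONDITIONS:
        rows = np.flatnonzero(cond == c)
        tfr = spectral.morlet_tfr(
            epochs, params, mode="evoked", kind="power", rows=rows, freqs=freqs
        )
        snr = spectral.snr_timeresolved(tfr, params)
        out[c] = spectral.aggregate_snr(snr, channel_set, params.image_window)
    return out


@dataclass
class PowerStudyResult:
    rate: float
    n_replicates: int
    detections: np.ndarray
    per_replicate_t: np.ndarray


def intra_cop_power(
    n_subjects: int = 37,
    n_replicates: int = 20,
    boost: float = 1.2,
    base_amplitude: float = 5.0,
    alpha: float = 0.05,
    one_sided: bool = False,
    seed: int = 0,
    synth_overrides: dict | None = None,
    params: AnalysisParams | None = None,
) -> PowerStudyResult:
    """Detection rate of an infant JA amplitude boost at the COP channels.

    Each replicate simulates ``n_subjects`` infants with
    A(JA) = boost * A(JW) on the default infant topography, runs the
    pipeline to COP-averaged SNR per condition, and applies a paired
    t-test (JA vs JW) at level ``alpha``.
    """
    params = params or AnalysisParams()
    config = SynthConfig(
        amplitude={
            "infant": {"JA": base_amplitude * boost, "JW": base_amplitude},
            "mother": {"JA": 4.0, "JW": 4.0},
        },
        **(synth_overrides or {}),
    )
    detections = np.zeros(n_replicates, dtype=bool)
    tvals = np.zeros(n_replicates)
    for rep, rng in enumerate(_sub_rngs(seed, n_replicates)):
        ja, jw = [], []
        while len(ja) < n_subjects:
            res = _infant_cop_snr(config, params, rng)
            if res is None:
                continue
            ja.append(res["JA"])
            jw.append(res["JW"])
        res_t = stats.paired_t(np.array(ja), np.array(jw))
        tvals[rep] = res_t.t
        if one_sided:
            detections[rep] = res_t.t > 0 and res_t.p / 2 <= alpha
        else:
            detections[rep] = res_t.p <= alpha
    return PowerStudyResult(
        rate=float(detections.mean()),
        n_replicates=n_replicates,
        detections=detections,
        per_replicate_t=tvals,
    )


def _dyad_aec_z(
    config: SynthConfig,
    params: AnalysisParams,
    rng: np.random.Generator,
    min_mutual: int = 5,
    channel_set=None,
) -> dict[str, float] | None:
    """One dyad's condition-level mean Fisher z (all-scalp-channel AEC)."""
    sched = generate_schedule(
        first_condition=CONDITIONS[int(rng.integers(2))], rng_seed=rng
    )
    from .simulate import draw_epoch_flags

    flags = draw_epoch_flags(config, sched, rng)
    ok = np.ones(sched.n_images, dtype=bool)
    for role in ("infant", "mother"):
        ok &= flags[role]["attended"] & ~flags[role]["artifact"]
    conds = sched.conditions
    counts = {c: int(np.sum(ok & (conds == c))) for c in CONDITIONS}
    if not inclusion_decision(counts, min_mutual):
        return None
    idx = np.flatnonzero(ok)
    sim = simulate_epochs(
        config, sched, rng=rng, indices=idx, inject_artifacts=False, flags=flags
    )
    out = {}
    eps = {}
    for role in ("infant", "mother"):
        e = prep.from_simulated(sim, role)
        e = prep.baseline_correct(e)
        eps[role] = prep.rereference_average(e)
    cond = eps["infant"].metadata["condition"].to_numpy()
    for c in CONDITIONS:
        rows = np.flatnonzero(cond == c)
        env_i = synchrony.epoch_envelopes(
            eps["infant"], params, channel_set=channel_set, rows=rows
        )
        env_m = synchrony.epoch_envelopes(
            eps["mother"], params, channel_set=channel_set, rows=rows
        )
        r, _ = synchrony.epoch_aec(env_i, env_m)
        res = synchrony.dyad_aec({c: r}, min_epochs=min_mutual)
        out[c] = res.mean_z[c]
    return out


def aec_condition_power(
    n_dyads: int = 31,
    n_replicates: int = 20,
    rho_ja: float = 0.8,
    rho_jw: float = 0.0,
    mod_depth: float = 0.9,
    noise_rms: float = 5.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> PowerStudyResult:
    """Detection rate of a condition difference in envelope coupling.

    Strong modulation depth and low noise keep the envelope estimate
    informative at the per-epoch level; the test is the paired t on
    per-dyad mean Fisher z (JA vs JW).
    """
    config = SynthConfig(
        envelope_coupling={"JA": rho_ja, "JW": rho_jw},
        envelope_mod_depth=mod_depth,
        noise_rms=noise_rms,
    )
    params = AnalysisParams()
    detections = np.zeros(n_replicates, dtype=bool)
    tvals = np.zeros(n_replicates)
    for rep, rng in enumerate(_sub_rngs(seed, n_replicates)):
        za, zb = [], []
        while len(za) < n_dyads:
            res = _dyad_aec_z(config, params, rng)
            if res is None:
                continue
            za.append(res["JA"])
            zb.append(res["JW"])
        res_t = stats.paired_t(np.array(za), np.array(zb))
        tvals[rep] = res_t.t
        detections[rep] = res_t.p <= alpha
    return PowerStudyResult(
        rate=float(detections.mean()),
        n_replicates=n_replicates,
        detections=detections,
        per_replicate_t=tvals,
    )


def aec_null_rate(
    n_dyads: int = 31,
    n_replicates: int = 20,
    rho: float = 0.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> PowerStudyResult:
    """False-positive rate of the AEC condition test when coupling is
    identical across conditions (the expected null pattern)."""
    return aec_condition_power(
        n_dyads=n_dyads,
        n_replicates=n_replicates,
        rho_ja=rho,
        rho_jw=rho,
        mod_depth=0.3,
        noise_rms=20.0,
        alpha=alpha,
        seed=seed,
    )


def cluster_type1_rate(
    n_replicates: int = 100,
    n_subjects: int = 37,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of pure-noise replicates with any cluster p <= alpha.

    Uses the real electrode adjacency over the 22 scalp channels and
    standard-normal subject x channel condition data with no effect.
    """
    montage = build_montage()
    adj = stats.channel_adjacency(montage)
    n_ch = adj.shape[0]
    hits = 0
    for rng in _sub_rngs(seed, n_replicates):
        a = rng.standard_normal((n_subjects, n_ch))
        b = rng.standard_normal((n_subjects, n_ch))
        res = stats.cluster_perm(
            a, b, adj, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        hits += res.min_p <= alpha
    return hits / n_replicates


def lmm_type1_rate(
    n_replicates: int = 200,
    n_subjects: int = 37,
    alpha: float = 0.05,
    sigma_subject: float = 0.5,
    seed: int = 0,
) -> float:
    """Condition-effect rejection rate of the mixed model under the null.

    Balanced tables of ``n_subjects`` x 22 channels x 2 conditions with a
    random subject intercept and no condition effect.
    """
    montage = build_montage()
    scalp = [ch for ch in montage.labels if ch not in ("M1", "M2")]
    region_of = {ch: reg for reg, chs in REGIONS.items() for ch in chs}
    base = pd.DataFrame(
        [
            {"subject": f"s{s}", "condition": c, "region": region_of[ch], "channel": ch}
            for s in range(n_subjects)
            for c in CONDITIONS
            for ch in scalp
        ]
    )
    subj_codes = base["subject"].astype("category").cat.codes.to_numpy()
    hits = 0
    for rng in _sub_rngs(seed, n_replicates):
        intercepts = rng.normal(0, sigma_subject, n_subjects)
        df = base.copy()
        df["snr"] = intercepts[subj_codes] + rng.standard_normal(len(base))
        res = stats.fit_lmm(df, response="snr", seed=int(rng.integers(2**31)))
        p_cond = res.anova.set_index("term").filter(like="condition", axis=0)["p"]
        p = float(p_cond.iloc[0])
        hits += p <= alpha
    return hits / n_replicates


def fdr_null_rate(
    n_tests: int = 1000,
    n_replicates: int = 500,
    q: float = 0.05,
    seed: int = 0,
) -> float:
    """Any-rejection rate of BH-FDR on uniform p values (global null)."""
    hits = 0
    for rng in _sub_rngs(seed, n_replicates):
        p = rng.uniform(size=n_tests)
        reject, _ = stats.fdr_bh(p, q)
        hits += bool(reject.any())
    return hits / n_replicates


def null_grand_mean_snr(
    n_subjects: int = 50,
    seed: int = 0,
    params: AnalysisParams | None = None,
) -> float:
    """Grand-mean SNR at f0 with zero evoked amplitude (noise-only check).

    Averages the window-mean SNR over all 24 channels and ``n_subjects``
    simulated infants on white-noise epochs.  A flat spectrum makes the
    neighbor-band noise proxy unbiased, so the expectation is 0; with
    1/f background noise the statistic itself sits below 0 (about -0.17
    at 4 Hz for exponent 1) because the average of a convex spectrum's
    neighbors exceeds its center value.
    """
    params = params or AnalysisParams()
    config = SynthConfig(
        amplitude={"infant": {"JA": 0.0, "JW": 0.0},
                   "mother": {"JA": 0.0, "JW": 0.0}},
        noise_exponent=0.0,
    )
    from .montage import CHANNELS

    rng = np.random.default_rng(seed)
    vals = []
    while len(vals) < n_subjects:
        res = _infant_cop_snr(config, params, rng, channel_set=CHANNELS)
        if res is None:
            continue
        vals.append(np.mean([res[c] for c in CONDITIONS]))
    return float(np.mean(vals))


def envelope_pair_mean_r(
    rho: float,
    n_epochs: int = 500,
    epoch_s: float = 2.0,
    cutoff_hz: float = 1.0,
    fs: float = 500.0,
    seed: int = 0,
) -> float:
    """Monte-Carlo expectation of the per-epoch Pearson r of the envelope
    generator (attenuated relative to rho because a 2-s window holds few
    effective samples of a 1 Hz-limited process)."""
    from .simulate import _envelope_pairs_batch

    rng = np.random.default_rng(seed)
    n = int(round(epoch_s * fs))
    env = _envelope_pairs_batch(np.full(n_epochs, rho), cutoff_hz, n, fs, rng)
    a = env[:, 0] - env[:, 0].mean(axis=1, keepdims=True)
    b = env[:, 1] - env[:, 1].mean(axis=1, keepdims=True)
    r = (a * b).sum(axis=1) / np.sqrt((a**2).sum(axis=1) * (b**2).sum(axis=1))
    return float(r.mean())
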