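"""End-to-end orchestration: simulate -> preprocess -> spectral/synchrony -> stats.

``run_intra`` mirrors the within-subject SSVEP analysis: per-condition
evoked SNR maps, grand-mean SNR vs noise tests, all-channel and
region-of-interest paired tests, a condition-by-region mixed model with
contrasts, and cluster-based permutation tests in the channel, time and
channel-time dimensions.  ``run_inter`` mirrors the inter-brain path:
mutual-epoch selection, per-epoch amplitude envelopes, AEC per region
with Fisher-z aggregation, epoch-level mixed models, and the
channel-pair max-t permutation with FDR.

Every stochastic step draws from a child seed spawned deterministically
from the master seed, so a run is reproducible end to end.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import preprocess as prep
from . import spectral, stats, synchrony
from .errors import ConfigurationError
from .montage import CFP_CHANNELS, COP_CHANNELS, REGIONS, build_montage
from .schedule import CONDITIONS, attendance_flags, generate_schedule, inclusion_decision
from .simulate import ROLES, SynthConfig, simulate_dyad, simulate_epochs, write_dyad
from .spectral import AnalysisParams

ROI_BY_ROLE = {"infant": ("cop", COP_CHANNELS), "mother": ("cfp", CFP_CHANNELS)}


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    seed: int = 0
    n_dyads: int = 8
    synth: SynthConfig = field(default_factory=SynthConfig)
    params: AnalysisParams = field(default_factory=AnalysisParams)
    reject_uv: float = 250.0
    min_epochs: int = 5
    min_mutual: int = 5
    n_perm: int = 1000
    cluster_p: float = 0.05
    alpha_channel: float = 0.25  # printed critical alpha for the channel dimension
    alpha_time: float = 0.025
    time_decim: int = 10
    continuous: bool = False  # continuous simulation + full epoching path
    analysis: str = "both"

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "RunConfig":
        d = json.loads(s)
        d["synth"] = SynthConfig(**d["synth"])
        p = d["params"]
        for key in ("tfr_window", "neighbor_offsets", "image_window"):
            p[key] = tuple(p[key])
        d["params"] = AnalysisParams(**p)
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha1(self.to_json().encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# per-subject processing
# ---------------------------------------------------------------------------

def preprocess_continuous(
    dataset, role: str, config: RunConfig
) -> prep.EpochSet:
    """Full preprocessing chain on a continuous recording."""
    rec = prep.bandpass(dataset.signals[role].astype(np.float32), 1.0, 48.0, dataset.fs)
    att = attendance_flags(dataset.gaze[role], dataset.schedule)
    epochs = prep.cut_epochs(
        rec, dataset.schedule, dataset.fs, dataset.channels, attended=att
    )
    epochs = prep.baseline_correct(epochs)
    epochs = prep.reject_epochs(epochs, config.reject_uv)
    return prep.rereference_average(epochs)


def preprocess_epochsim(sim, role: str, config: RunConfig) -> prep.EpochSet:
    """Preprocessing chain on directly simulated epochs."""
    epochs = prep.from_simulated(sim, role)
    epochs = prep.baseline_correct(epochs)
    epochs = prep.reject_epochs(epochs, config.reject_uv)
    return prep.rereference_average(epochs)


def subject_snr_maps(
    epochs: prep.EpochSet,
    params: AnalysisParams,
    kind: str = "power",
    rows_by_condition: dict[str, np.ndarray] | None = None,
    freqs: np.ndarray | None = None,
) -> dict[str, spectral.SNRMap]:
    """Evoked TFR and time-resolved SNR per condition (clean epochs only)."""
    if rows_by_condition is None:
        clean = epochs.clean_mask()
        cond = epochs.metadata["condition"].to_numpy()
        rows_by_condition = {
            c: np.flatnonzero(clean & (cond == c)) for c in CONDITIONS
        }
    maps = {}
    for c, rows in rows_by_condition.items():
        tfr = spectral.morlet_tfr(
            epochs, params, mode="evoked", kind=kind, rows=rows, freqs=freqs
        )
        maps[c] = spectral.snr_timeresolved(tfr, params)
    return maps


def _simulate_cohort(config: RunConfig):
    """Yield (dyad_id, epochs_infant, epochs_mother) for the configured cohort."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_dyads)
    for d in range(config.n_dyads):
        rng = np.random.default_rng(children[d])
        first = CONDITIONS[d % 2]  # counterbalanced starting condition
        sched = generate_schedule(first_condition=first, rng_seed=rng)
        if config.continuous:
            seed_d = int(children[d].generate_state(1)[0] % (2**31))
            ds = simulate_dyad(config.synth, sched, rng_seed=seed_d)
            ei = preprocess_continuous(ds, "infant", config)
            em = preprocess_continuous(ds, "mother", config)
        else:
            sim = simulate_epochs(config.synth, sched, rng=rng)
            ei = preprocess_epochsim(sim, "infant", config)
            em = preprocess_epochsim(sim, "mother", config)
        yield d, ei, em


# ---------------------------------------------------------------------------
# intra-brain report
# ---------------------------------------------------------------------------

@dataclass
class IntraReport:
    config_hash: str
    seed: int
    grand_snr: pd.DataFrame  # role, condition, mean SNR, t, df, p vs noise
    paired: pd.DataFrame  # role, channel_set, t, df, p
    lmm: dict[str, stats.LMMResult]
    clusters: dict[str, stats.ClusterResult]
    snr_spectrum_mean: pd.DataFrame  # role-averaged SNR per frequency band
    peak_frequency_hz: float
    epoch_counts: pd.DataFrame
    topographies: pd.DataFrame  # role, condition, channel, window-mean SNR

    def write(self, out_dir) -> None:
        _write_report_tables(
            out_dir,
            self.config_hash,
            self.seed,
            {
                "grand_snr": self.grand_snr,
                "paired_tests": self.paired,
                "epoch_counts": self.epoch_counts,
                "snr_spectrum": self.snr_spectrum_mean,
                "topographies": self.topographies,
            },
            extra={
                "peak_frequency_hz": self.peak_frequency_hz,
                "clusters": {
                    k: [
                        {"mass": c.mass, "p": c.p, "sign": c.sign,
                         "n_units": int(c.units.size)}
                        for c in v.clusters
                    ]
                    for k, v in self.clusters.items()
                },
                "lmm": {
                    k: v.anova.to_dict(orient="records")
                    for k, v in self.lmm.items()
                },
            },
        )


def run_intra(config: RunConfig) -> IntraReport:
    """Within-subject SSVEP SNR analysis on a simulated cohort."""
    params = config.params
    montage = build_montage()
    scalp = spectral.scalp_channels(montage.labels)

    per_role: dict[str, dict] = {r: {"maps": [], "spectra": []} for r in ROLES}
    counts_rows = []
    for d, ei, em in _simulate_cohort(config):
        for role, epochs in (("infant", ei), ("mother", em)):
            counts = epochs.counts_by_condition()
            included = inclusion_decision(counts, config.min_epochs)
            counts_rows.append(
                {"dyad": d, "role": role, **counts, "included": included}
            )
            if not included:
                continue
            clean = epochs.clean_mask()
            cond = epochs.metadata["condition"].to_numpy()
            rows_by_cond = {
                c: np.flatnonzero(clean & (cond == c)) for c in CONDITIONS
            }
            maps = {}
            spectra = {}
            for c, rows in rows_by_cond.items():
                tfr = spectral.morlet_tfr(
                    epochs, params, mode="evoked", kind="power", rows=rows
                )
                maps[c] = spectral.snr_timeresolved(tfr, params)
                spectra[c] = spectral.snr_spectrum(tfr, params)
            per_role[role]["maps"].append(maps)
            per_role[role]["spectra"].append(spectra)

    grand_rows, paired_rows, topo_rows = [], [], []
    lmm_results: dict[str, stats.LMMResult] = {}
    cluster_results: dict[str, stats.ClusterResult] = {}
    spec_accum = []
    img_win = params.image_window
    ch_adj = stats.channel_adjacency(montage)
    peak = np.nan

    for role in ROLES:
        maps_list = per_role[role]["maps"]
        if not maps_list:
            continue
        n_sub = len(maps_list)
        # grand mean SNR vs noise level per condition (all 24 channels)
        for c in CONDITIONS:
            subj_vals = np.array(
                [
                    spectral.aggregate_snr(m[c], m[c].channels, img_win)
                    for m in maps_list
                ]
            )
            res = spectral.snr_vs_noise_test(subj_vals)
            grand_rows.append(
                {"role": role, "condition": c, "mean_snr": res.mean,
                 "t": res.t, "df": res.df, "p": res.p}
            )
        # paired condition tests on channel-set averages (mastoids excluded)
        roi_name, roi_chs = ROI_BY_ROLE[role]
        sets = {"all": scalp, roi_name: roi_chs, **REGIONS}
        for set_name, chs in sets.items():
            a = np.array(
                [spectral.aggregate_snr(m["JA"], chs, img_win) for m in maps_list]
            )
            b = np.array(
                [spectral.aggregate_snr(m["JW"], chs, img_win) for m in maps_list]
            )
            res = stats.paired_t(a, b)
            paired_rows.append(
                {"role": role, "channel_set": set_name, "mean_JA": a.mean(),
                 "mean_JW": b.mean(), "t": res.t, "df": res.df, "p": res.p}
            )
        # per-channel window means -> topographies, LMM table, channel cluster
        per_ch = {
            c: np.array(
                [
                    [spectral.aggregate_snr(m[c], [ch], img_win) for ch in scalp]
                    for m in maps_list
                ]
            )
            for c in CONDITIONS
        }
        for c in CONDITIONS:
            for j, ch in enumerate(scalp):
                topo_rows.append(
                    {"role": role, "condition": c, "channel": ch,
                     "snr": per_ch[c][:, j].mean()}
                )
        region_of = {
            ch: reg for reg, chs in REGIONS.items() for ch in chs
        }
        records = []
        for c in CONDITIONS:
            for s in range(n_sub):
                for j, ch in enumerate(scalp):
                    records.append(
                        {"subject": f"{role}{s}", "condition": c,
                         "region": region_of[ch], "channel": ch,
                         "snr": per_ch[c][s, j]}
                    )
        lmm_results[role] = stats.fit_lmm(
            pd.DataFrame(records), response="snr", seed=config.seed
        )
        cluster_results[f"{role}_channel"] = stats.cluster_perm(
            per_ch["JA"], per_ch["JW"], ch_adj,
            n_perm=config.n_perm, cluster_p=config.cluster_p,
            cluster_alpha=config.alpha_channel, seed=config.seed,
        )
        # time dimension per channel set (channel-averaged, decimated)
        t = maps_list[0]["JA"].times
        tmask = (t >= img_win[0] - 1e-9) & (t < img_win[1] - 1e-9)
        dec = slice(None, None, config.time_decim)
        for set_name, chs in sets.items():
            idx = maps_list[0]["JA"].channel_indices(chs)
            tc = {
                cnd: np.array(
                    [m[cnd].values[tmask][dec][:, idx].mean(axis=1) for m in maps_list]
                )
                for cnd in CONDITIONS
            }
            n_t = tc["JA"].shape[1]
            cluster_results[f"{role}_time_{set_name}"] = stats.cluster_perm(
                tc["JA"], tc["JW"], stats.temporal_adjacency(n_t),
                n_perm=config.n_perm, cluster_p=config.cluster_p,
                cluster_alpha=config.alpha_time, seed=config.seed,
            )
        # channel-time dimension
        scalp_idx = maps_list[0]["JA"].channel_indices(scalp)
        ct = {
            c: np.array(
                [m[c].values[tmask][dec][:, scalp_idx].reshape(-1) for m in maps_list]
            )
            for c in CONDITIONS
        }
        n_t = maps_list[0]["JA"].values[tmask][dec].shape[0]
        ct_adj = stats.channel_time_adjacency(ch_adj, int(n_t))
        cluster_results[f"{role}_channel_time"] = stats.cluster_perm(
            ct["JA"], ct["JW"], ct_adj,
            n_perm=config.n_perm, cluster_p=config.cluster_p,
            cluster_alpha=config.alpha_channel, seed=config.seed,
        )
        # SNR spectrum (for the stimulation-frequency peak)
        spectra_list = per_role[role]["spectra"]
        spec_mean = np.mean(
            [
                np.mean([sp[c] for c in CONDITIONS], axis=0)
                for sp in spectra_list
            ],
            axis=0,
        )  # (freq, time, channel)
        spec_accum.append(spec_mean)

    freqs = params.freqs
    t_axis = per_role["infant"]["maps"][0]["JA"].times if per_role["infant"]["maps"] else None
    spec_tbl = pd.DataFrame({"freq_hz": freqs})
    if spec_accum:
        overall = np.mean(spec_accum, axis=0)
        tmask = (t_axis >= img_win[0] - 1e-9) & (t_axis < img_win[1] - 1e-9)
        band_mean = overall[:, tmask, :].mean(axis=(1, 2))
        spec_tbl["snr"] = band_mean
        peak = float(freqs[int(np.argmax(band_mean))])

    return IntraReport(
        config_hash=config.config_hash,
        seed=config.seed,
        grand_snr=pd.DataFrame(grand_rows),
        paired=pd.DataFrame(paired_rows),
        lmm=lmm_results,
        clusters=cluster_results,
        snr_spectrum_mean=spec_tbl,
        peak_frequency_hz=peak,
        epoch_counts=pd.DataFrame(counts_rows),
        topographies=pd.DataFrame(topo_rows),
    )


# ---------------------------------------------------------------------------
# inter-brain report
# ---------------------------------------------------------------------------

@dataclass
class InterReport:
    config_hash: str
    seed: int
    aec_table: pd.DataFrame  # Table-1 shaped: region x condition stats + t, p
    lmm: dict[str, stats.LMMResult]
    pair_perm: stats.MaxTResult | None
    mutual_counts: pd.DataFrame
    n_dyads_included: int

    def write(self, out_dir) -> None:
        _write_report_tables(
            out_dir,
            self.config_hash,
            self.seed,
            {"aec_table": self.aec_table, "mutual_counts": self.mutual_counts},
            extra={
                "n_dyads_included": self.n_dyads_included,
                "lmm": {
                    k: v.anova.to_dict(orient="records") for k, v in self.lmm.items()
                },
                "pair_perm": None
                if self.pair_perm is None
                else {
                    "n_rejected_fdr": int(self.pair_perm.reject.sum()),
                    "min_p": float(self.pair_perm.p.min()),
                },
            },
        )


AEC_REGION_SETS: dict[str, tuple] = {
    "all": None,  # filled at runtime with all scalp channels
    "central": REGIONS["central"],
    "frontal": REGIONS["frontal"],
    "occipital": REGIONS["occipital"],
    "parietal": REGIONS["parietal"],
}


def run_inter(config: RunConfig) -> InterReport:
    """Inter-brain AEC analysis on a simulated cohort of dyads."""
    if config.n_dyads < 2:
        raise ConfigurationError("need at least 2 dyads")
    params = config.params
    montage = build_montage()
    scalp = spectral.scalp_channels(montage.labels)
    region_sets = {k: (scalp if v is None else v) for k, v in AEC_REGION_SETS.items()}

    dyad_rows = []  # per dyad per region: mean_z per condition
    epoch_records = {"all": [], "occipital": []}
    pair_z: dict[str, list[np.ndarray]] = {c: [] for c in CONDITIONS}
    mutual_rows = []
    for d, ei, em in _simulate_cohort(config):
        indices, included, ei, em = prep.select_mutual(ei, em, config.min_mutual)
        mutual_rows.append(
            {"dyad": d, **{f"mutual_{c}": len(indices[c]) for c in CONDITIONS},
             "included": included}
        )
        if not included:
            continue
        row = {"dyad": d}
        for reg, chs in region_sets.items():
            r_by_cond = {}
            for c in CONDITIONS:
                env_i = synchrony.epoch_envelopes(
                    ei, params, channel_set=chs, rows=indices[c]
                )
                env_m = synchrony.epoch_envelopes(
                    em, params, channel_set=chs, rows=indices[c]
                )
                r, _ = synchrony.epoch_aec(env_i, env_m)
                r_by_cond[c] = r
            res = synchrony.dyad_aec(r_by_cond, min_epochs=config.min_mutual)
            for c in CONDITIONS:
                row[f"{reg}_z_{c}"] = res.mean_z[c]
                if reg in epoch_records:
                    for z in res.epoch_z[c]:
                        epoch_records[reg].append(
                            {"dyad": f"d{d}", "condition": c, "z": z}
                        )
        # cross-role set: mother central envelope vs infant COP envelope
        r_by_cond = {}
        for c in CONDITIONS:
            env_i = synchrony.epoch_envelopes(
                ei, params, channel_set=COP_CHANNELS, rows=indices[c]
            )
            env_m = synchrony.epoch_envelopes(
                em, params, channel_set=REGIONS["central"], rows=indices[c]
            )
            r, _ = synchrony.epoch_aec(env_i, env_m)
            r_by_cond[c] = r
        res = synchrony.dyad_aec(r_by_cond, min_epochs=config.min_mutual)
        for c in CONDITIONS:
            row[f"cross_role_z_{c}"] = res.mean_z[c]
        dyad_rows.append(row)
        z_mats = synchrony.channelpair_aec(ei, em, params)
        for c in CONDITIONS:
            pair_z[c].append(z_mats[c].reshape(-1))

    dyads = pd.DataFrame(dyad_rows)
    table_rows = []
    for reg in [*region_sets, "cross_role"]:
        za = dyads[f"{reg}_z_JA"].to_numpy()
        zb = dyads[f"{reg}_z_JW"].to_numpy()
        res = stats.paired_t(za, zb)
        ra, rb = np.tanh(za), np.tanh(zb)
        table_rows.append(
            {
                "region": reg,
                "JA_mean": ra.mean(), "JA_sd": ra.std(ddof=1),
                "JA_min": ra.min(), "JA_max": ra.max(),
                "JW_mean": rb.mean(), "JW_sd": rb.std(ddof=1),
                "JW_min": rb.min(), "JW_max": rb.max(),
                "t": res.t, "df": res.df, "p": res.p,
            }
        )
    lmm_results = {
        reg: stats.fit_lmm(
            pd.DataFrame(recs), response="z", region=None, group="dyad",
            seed=config.seed,
        )
        for reg, recs in epoch_records.items()
        if recs
    }
    pair_res = None
    if len(pair_z["JA"]) >= 2:
        pair_res = stats.maxT_pair_perm(
            np.array(pair_z["JA"]), np.array(pair_z["JW"]),
            n_perm=config.n_perm, seed=config.seed,
        )
    return InterReport(
        config_hash=config.config_hash,
        seed=config.seed,
        aec_table=pd.DataFrame(table_rows),
        lmm=lmm_results,
        pair_perm=pair_res,
        mutual_counts=pd.DataFrame(mutual_rows),
        n_dyads_included=len(dyad_rows),
    )


def peak_snr_frequency(
    seed: int,
    synth: SynthConfig | None = None,
    params: AnalysisParams | None = None,
    reps_per_block: int = 4,
    reject_uv: float = 250.0,
) -> tuple[float, int]:
    """Grand-mean SNR-spectrum peak frequency of one simulated dyad.

    Simulates a continuous dyad recording (``reps_per_block=4`` doubles
    the session so both members keep well over 40 clean epochs per
    condition after attrition), runs the full preprocessing chain, the
    evoked Morlet transform per condition and role, and the per-band SNR.
    Returns the frequency with the highest SNR averaged over channels,
    image-window time points, conditions and roles, plus the number of
    clean epochs that entered the average.
    """
    synth = synth or SynthConfig(rng_seed=seed)
    params = params or AnalysisParams()
    rc = RunConfig(seed=seed, synth=synth, params=params, reject_uv=reject_uv)
    sched = generate_schedule(reps_per_block=reps_per_block, rng_seed=seed)
    ds = simulate_dyad(synth, sched, rng_seed=seed)
    spectra = []
    n_epochs = 0
    t_axis = None
    for role in ROLES:
        epochs = preprocess_continuous(ds, role, rc)
        clean = epochs.clean_mask()
        cond = epochs.metadata["condition"].to_numpy()
        for c in CONDITIONS:
            rows = np.flatnonzero(clean & (cond == c))
            n_epochs += rows.size
            tfr = spectral.morlet_tfr(epochs, params, mode="evoked", rows=rows)
            spectra.append(spectral.snr_spectrum(tfr, params))
            t_axis = tfr.times
    mean_spec = np.mean(spectra, axis=0)
    win = params.image_window
    tmask = (t_axis >= win[0] - 1e-9) & (t_axis < win[1] - 1e-9)
    band = mean_spec[:, tmask, :].mean(axis=(1, 2))
    return float(params.freqs[int(np.argmax(band))]), int(n_epochs)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

FIXTURE_PROFILES = ("null", "intra_effect", "coupling", "tiny")


def make_fixtures(profile: str, seed: int, out_dir) -> dict:
    """Write a small on-disk dataset with documented ground truth.

    Profiles: ``tiny`` (2 dyads, 12 images each), ``null`` (no condition
    differences anywhere), ``intra_effect`` (default generator: infant
    JA amplitude boost), ``coupling`` (strong envelope coupling in JA
    only).
    """
    from pathlib import Path

    if profile not in FIXTURE_PROFILES:
        raise ConfigurationError(f"unknown fixture profile {profile!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    synth = SynthConfig(rng_seed=seed)
    sched_kw = {}
    n_dyads = 2
    if profile == "tiny":
        sched_kw = dict(n_images=3, reps_per_block=2, n_blocks=2)
    elif profile == "null":
        synth = synth.replace(
            amplitude={"infant": {"JA": 5.0, "JW": 5.0},
                       "mother": {"JA": 4.0, "JW": 4.0}},
        )
    elif profile == "coupling":
        synth = synth.replace(
            envelope_coupling={"JA": 0.8, "JW": 0.0},
            envelope_mod_depth=0.9,
            noise_rms=5.0,
        )
    paths = []
    ss = np.random.SeedSequence(seed)
    for d, child in enumerate(ss.spawn(n_dyads)):
        rng = np.random.default_rng(child)
        sched = generate_schedule(
            first_condition=CONDITIONS[d % 2], rng_seed=rng, **sched_kw
        )
        seed_d = int(child.generate_state(1)[0] % (2**31))
        ds = simulate_dyad(synth, sched, rng_seed=seed_d)
        path = out / f"{profile}_dyad{d}.h5"
        write_dyad(ds, path, compress=True)
        sched.to_csv(out / f"{profile}_dyad{d}_schedule.csv")
        for role in ROLES:
            ds.gaze[role].to_csv(out / f"{profile}_dyad{d}_gaze_{role}.csv")
        paths.append(str(path))
    manifest = {
        "profile": profile,
        "seed": seed,
        "config": json.loads(synth.to_json()),
        "paths": paths,
    }
    (out / f"{profile}_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _write_report_tables(out_dir, config_hash, seed, tables, extra=None) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    meta = {"config_hash": config_hash, "seed": seed}
    if extra:
        meta.update(extra)
    (out / "report.json").write_text(json.dumps(meta, indent=2, default=float))
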