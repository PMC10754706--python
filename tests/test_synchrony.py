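"""Amplitude envelopes, AEC, Fisher-z aggregation, channel-pair matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadssvep import (
    SynthConfig,
    dyad_aec,
    epoch_aec,
    epoch_envelopes,
    fisher_inv,
    fisher_z,
    generate_schedule,
    simulate_epochs,
)
from dyadssvep.errors import ConfigurationError, DegenerateInputError
from dyadssvep.montage import CHANNELS, REGIONS
from dyadssvep.preprocess import EpochSet, baseline_correct, from_simulated
from dyadssvep.synchrony import EnvelopeSet, channelpair_aec

FS = 500.0


def _epochset(data, conditions=None):
    n_ep, n_ch, _ = data.shape
    meta = pd.DataFrame(
        {
            "onset_s": np.arange(n_ep, dtype=float),
            "condition": conditions if conditions is not None else ["JA"] * n_ep,
            "block": 1,
            "image_id": 1,
            "attended": True,
            "artifact": False,
            "mutual": True,
        }
    )
    return EpochSet(
        data=data, fs=FS, tmin=-1.0, channels=CHANNELS[:n_ch], metadata=meta
    )


def _envset(env, times=None):
    n_ep, n_t = env.shape
    return EnvelopeSet(
        envelopes=env,
        times=np.linspace(0, 2, n_t, endpoint=False) if times is None else times,
        epoch_rows=np.arange(n_ep),
        channel_set=("Cz",),
        baseline=(-0.5, -0.2),
    )


class TestEpochEnvelopes:
    def test_gated_sinusoid_envelope_near_one_in_window(self, params):
        t = np.arange(-1.0, 3.0, 1 / FS)
        gate = (t >= 0) & (t < 2.0)
        data = (np.sin(2 * np.pi * 4 * t) * gate)[None, None, :].repeat(3, 1)
        env = epoch_envelopes(_epochset(data), params, channel_set=["C3", "C4"])
        tt = env.times
        mid = (tt >= 0.6) & (tt < 1.4)  # away from onset/offset transients
        # the 7-cycle wavelet bleeds the onset into the -500..-200 ms
        # baseline (~0.12 of the plateau), so the corrected plateau sits
        # slightly below 1
        assert np.all(env.envelopes[:, mid] > 0.8)
        assert np.all(env.envelopes[:, mid] < 1.0)
        base = (tt >= -0.5) & (tt < -0.2)
        assert abs(env.envelopes[:, base].mean()) < 1e-9  # zero-mean baseline
        # with a baseline window clear of the onset bleed the plateau is 1
        env_far = epoch_envelopes(
            _epochset(data), params, channel_set=["C3"], baseline=(-0.95, -0.9)
        )
        assert np.allclose(env_far.envelopes[:, mid], 1.0, atol=0.02)

    def test_constant_signal_envelope_zero_after_baseline(self, params):
        data = np.full((2, 3, 2000), 4.2)
        env = epoch_envelopes(_epochset(data), params, channel_set=["C3"])
        tt = env.times
        valid = (tt >= -0.1) & (tt < 2.1)  # clear of epoch-edge transients
        assert np.abs(env.envelopes[:, valid]).max() < 0.1 * 4.2 / 4.2
        assert abs(env.envelopes[:, (tt >= -0.5) & (tt < -0.2)].mean()) < 1e-9

    def test_empty_mutual_set_rejected(self, params):
        with pytest.raises(DegenerateInputError):
            epoch_envelopes(
                _epochset(np.zeros((2, 3, 2000))), params, rows=np.array([], int)
            )

    def test_envelope_tracks_ground_truth_modulation(self, params):
        """With modulation 1 + 0.5 e(t) and no noise, the measured envelope
        must track the generator's envelope with R^2 > 0.9 in-window."""
        cfg = SynthConfig(
            noise_rms=0.0,
            envelope_mod_depth=0.5,
            artifact_prob={"infant": {"JA": 0.0, "JW": 0.0},
                           "mother": {"JA": 0.0, "JW": 0.0}},
            attend_prob={"infant": {"JA": 1.0, "JW": 1.0},
                         "mother": {"JA": 1.0, "JW": 1.0}},
        )
        sched = generate_schedule(n_images=3, reps_per_block=2, n_blocks=2,
                                  rng_seed=3)
        sim = simulate_epochs(cfg, sched, rng=3)
        eps = baseline_correct(from_simulated(sim, "infant", filtered=False))
        env = epoch_envelopes(eps, params, channel_set=["POz"])
        tt = env.times
        win = (tt >= 0.5) & (tt < 1.5)  # clear of wavelet-smoothed ramps
        n_img = sim.envelopes.shape[-1]
        t_img = np.arange(n_img) / FS
        # the wavelet measures the envelope through its Gaussian window;
        # compare against the ground truth seen through the same kernel
        sigma_t = params.n_cycles / (2 * np.pi * params.f0)
        half = int(4 * sigma_t * FS)
        kernel = np.exp(-np.arange(-half, half + 1) ** 2 / (2 * (sigma_t * FS) ** 2))
        kernel /= kernel.sum()
        r2s = []
        for k in range(eps.n_epochs):
            truth_full = 1.0 + 0.5 * np.interp(
                np.arange(-half, n_img + half) / FS, t_img, sim.envelopes[k, 0]
            )
            truth = np.convolve(truth_full, kernel, mode="valid")
            truth_w = np.interp(tt[win], t_img[: truth.size], truth)
            meas = env.envelopes[k, win]
            r = np.corrcoef(truth_w, meas)[0, 1]
            r2s.append(r**2)
        assert np.mean(r2s) > 0.9


class TestEpochAEC:
    def test_identical_envelopes_give_r_one(self, rng):
        env = _envset(rng.standard_normal((4, 1000)))
        r, dropped = epoch_aec(env, env)
        assert dropped == 0
        assert np.allclose(r, 1.0)

    def test_negated_envelope_gives_r_minus_one(self, rng):
        e = rng.standard_normal((4, 1000))
        r, _ = epoch_aec(_envset(e), _envset(-e))
        assert np.allclose(r, -1.0)

    def test_zero_variance_epochs_dropped_with_warning(self, rng):
        e = rng.standard_normal((3, 1000))
        e[1] = 5.0
        with pytest.warns(UserWarning, match="zero-variance"):
            r, dropped = epoch_aec(_envset(e), _envset(e.copy()))
        assert dropped == 1
        assert r.size == 2

    def test_independent_envelopes_rarely_exceed_point_one(self):
        """|r| < 0.1 for independent white 1000-sample envelopes in about
        99.8% of draws; allow the binomial wiggle at 200 draws."""
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(200):
            r, _ = epoch_aec(
                _envset(rng.standard_normal((1, 1000))),
                _envset(rng.standard_normal((1, 1000))),
            )
            hits += abs(r[0]) < 0.1
        assert hits >= 190  # >= 95% of 200 seeded draws


class TestFisher:
    def test_known_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)
        z1 = fisher_z(1.0)
        assert np.isfinite(z1) and z1 == pytest.approx(np.arctanh(1 - 1e-7))

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            fisher_z(1.2)

    @given(st.floats(-0.999999, 0.999999))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip(self, r):
        assert fisher_inv(fisher_z(r)) == pytest.approx(r, abs=1e-9)


class TestDyadAEC:
    def test_zero_correlations_stay_zero(self):
        res = dyad_aec({"JA": np.zeros(6), "JW": np.zeros(6)})
        assert res.mean_z == {"JA": 0.0, "JW": 0.0}
        assert res.mean_r == {"JA": 0.0, "JW": 0.0}

    def test_averaging_happens_in_z_space(self):
        res = dyad_aec({"JA": np.array([0.5, -0.5, 0.5, -0.5, 0.5, -0.5])})
        assert res.mean_z["JA"] == pytest.approx(0.0)
        assert res.mean_r["JA"] == pytest.approx(0.0)
        # asymmetric input: z-mean differs from naive r-mean
        r = np.array([0.9, 0.9, 0.9, 0.1, 0.1])
        res = dyad_aec({"JA": r})
        assert res.mean_r["JA"] > r.mean()

    def test_insufficient_epochs_rejected(self):
        with pytest.raises(DegenerateInputError):
            dyad_aec({"JA": np.zeros(4)}, min_epochs=5)


class TestChannelPairAEC:
    def _mutual_pair(self, rng, n_ep=6):
        data = rng.standard_normal((n_ep, 24, 2000)) * 5
        conds = ["JA", "JW"] * (n_ep // 2)
        return _epochset(data, conds), _epochset(
            rng.standard_normal((n_ep, 24, 2000)) * 5, conds
        )

    def test_duplicated_recording_maximizes_diagonal(self, params, rng):
        ei, _ = self._mutual_pair(rng)
        em = _epochset(ei.data.copy(), list(ei.metadata["condition"]))
        z = channelpair_aec(ei, em, params)
        for c in ("JA", "JW"):
            diag = np.diag(z[c])
            off = z[c][~np.eye(22, dtype=bool)]
            assert diag.min() > off.mean()
            assert diag.max() == pytest.approx(np.arctanh(1 - 1e-7))

    def test_independent_noise_mean_near_zero(self, params):
        rng = np.random.default_rng(31)
        ei, em = self._mutual_pair(rng, n_ep=40)
        z = channelpair_aec(ei, em, params)
        pooled = np.concatenate([z[c].reshape(-1) for c in ("JA", "JW")])
        assert abs(pooled.mean()) < 0.05

    def test_occipital_only_coupling_shows_in_occipital_block(self, params):
        """Envelope coupling projected through occipital-only topography
        must raise occipital-pair AEC above the rest of the matrix."""
        occ = REGIONS["occipital"]
        weights = {
            role: {ch: (1.0 if ch in occ else 0.0) for ch in CHANNELS}
            for role in ("infant", "mother")
        }
        cfg = SynthConfig(
            topo_weights=weights,
            envelope_coupling={"JA": 0.9, "JW": 0.9},
            envelope_mod_depth=0.9,
            noise_rms=3.0,
            attend_prob={"infant": {"JA": 1.0, "JW": 1.0},
                         "mother": {"JA": 1.0, "JW": 1.0}},
            artifact_prob={"infant": {"JA": 0.0, "JW": 0.0},
                           "mother": {"JA": 0.0, "JW": 0.0}},
        )
        sched = generate_schedule(n_images=5, reps_per_block=3, n_blocks=2,
                                  rng_seed=2)
        sim = simulate_epochs(cfg, sched, rng=2)
        eis, ems = (from_simulated(sim, role, filtered=False)
                    for role in ("infant", "mother"))
        eis, ems = baseline_correct(eis), baseline_correct(ems)
        for e in (eis, ems):
            e.metadata["mutual"] = True
        z = channelpair_aec(eis, ems, params)
        scalp = [ch for ch in CHANNELS if ch not in ("M1", "M2")]
        occ_idx = [scalp.index(ch) for ch in occ]
        mask = np.zeros((22, 22), bool)
        mask[np.ix_(occ_idx, occ_idx)] = True
        pooled = np.mean([z[c] for c in ("JA", "JW")], axis=0)
        assert pooled[mask].mean() > pooled[~mask].mean() + 0.2


class TestInvariances:
    def test_aec_invariant_to_scaling_and_channel_offset(self, params, rng):
        t = np.arange(-1.0, 3.0, 1 / FS)
        base = rng.standard_normal((4, 3, t.size)) + 2 * np.sin(
            2 * np.pi * 4 * t
        )
        a1 = _epochset(base)
        b1 = _epochset(rng.standard_normal((4, 3, t.size)) + base)
        env_a = epoch_envelopes(a1, params, channel_set=["C3", "C4"])
        env_b = epoch_envelopes(b1, params, channel_set=["C3", "C4"])
        r_ref, _ = epoch_aec(env_a, env_b)
        # global scaling is exactly invariant
        env_a2 = epoch_envelopes(
            _epochset(3.0 * base), params, channel_set=["C3", "C4"]
        )
        r_scaled, _ = epoch_aec(env_a2, env_b)
        assert np.allclose(r_ref, r_scaled, atol=1e-9)
        # a channel-constant offset only leaves tiny wavelet edge
        # transients (the offset has no 4 Hz content)
        env_a3 = epoch_envelopes(
            _epochset(base + 10.0), params, channel_set=["C3", "C4"]
        )
        r_offset, _ = epoch_aec(env_a3, env_b)
        assert np.allclose(r_ref, r_offset, atol=0.01)
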