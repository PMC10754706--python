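"""Paired t, mixed model, cluster and max-t permutation, FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse
from scipy import stats as sps

from dyadssvep.errors import ConfigurationError, DegenerateInputError
from dyadssvep.montage import REGIONS
from dyadssvep.stats import (
    channel_time_adjacency,
    cluster_perm,
    cluster_perm_exact,
    fdr_bh,
    fit_lmm,
    maxT_pair_perm,
    paired_t,
    temporal_adjacency,
    _find_clusters,
    _t_map,
)


class TestPairedT:
    def test_equal_samples_give_zero(self):
        res = paired_t(np.arange(5.0), np.arange(5.0))
        assert res.t == 0.0 and res.p == 1.0 and res.degenerate

    def test_closed_form_differences(self):
        # differences {1, 2, 3}: t = mean/(sd/sqrt(3)) = 2*sqrt(3)
        res = paired_t(np.array([2.0, 4.0, 6.0]), np.array([1.0, 2.0, 3.0]))
        assert res.t == pytest.approx(2 * np.sqrt(3))
        assert res.df == 2

    def test_single_pair_rejected(self):
        with pytest.raises(DegenerateInputError):
            paired_t(np.array([1.0]), np.array([2.0]))

    def test_antisymmetric_under_condition_swap(self, rng):
        a, b = rng.standard_normal((2, 12))
        assert paired_t(a, b).t == pytest.approx(-paired_t(b, a).t)


def _lmm_table(seed=42, n_subjects=8, delta=0.3):
    """Balanced condition x region table with an occipital JA offset."""
    rng = np.random.default_rng(seed)
    scalp = [ch for chs in REGIONS.values() for ch in chs]
    region_of = {ch: reg for reg, chs in REGIONS.items() for ch in chs}
    rows = []
    for s in range(n_subjects):
        u = rng.normal(0, 0.7)
        for c in ("JA", "JW"):
            for ch in scalp:
                rows.append(
                    {
                        "subject": f"s{s}",
                        "condition": c,
                        "region": region_of[ch],
                        "snr": u
                        + delta * (c == "JA") * (region_of[ch] == "occipital")
                        + rng.standard_normal(),
                    }
                )
    return pd.DataFrame(rows)


class TestLMM:
    def test_matches_lmerTest_oracle_frozen_values(self):
        """F statistics, denominator df and contrasts on a frozen dataset,
        cross-checked against R lmerTest (type-III, Satterthwaite) and
        emmeans; values frozen from that run."""
        res = fit_lmm(_lmm_table(), response="snr", seed=1)
        anova = res.anova.set_index("term")
        cond = anova.loc["C(condition, Sum)"]
        inter = anova.loc["C(condition, Sum):C(region, Sum)"]
        assert cond["df_den"] == 335
        assert cond["F"] == pytest.approx(0.9800, abs=2e-3)
        assert cond["p"] == pytest.approx(0.32292, abs=2e-3)
        assert inter["F"] == pytest.approx(3.0638, abs=2e-3)
        assert inter["p"] == pytest.approx(0.01682, abs=2e-3)
        central = res.contrasts.set_index("region").loc["central"]
        assert central["estimate"] == pytest.approx(0.69731, abs=2e-4)
        assert central["se"] == pytest.approx(0.23633, abs=2e-4)
        assert central["t"] == pytest.approx(2.9506, abs=2e-3)
        assert central["df"] == 335

    def test_adjusted_p_never_below_unadjusted(self):
        res = fit_lmm(_lmm_table(seed=3), response="snr", seed=1)
        c = res.contrasts
        assert (c["p_adjusted"] >= c["p_unadjusted"] - 1e-12).all()

    def test_occipital_contrast_recovers_injected_effect(self):
        """95% CI of the occipital JA-JW contrast must cover the injected
        delta in at least ~90% of replicates."""
        delta = 0.3
        covered = 0
        n_rep = 40
        for rep in range(n_rep):
            res = fit_lmm(
                _lmm_table(seed=100 + rep, delta=delta), response="snr", seed=1
            )
            occ = res.contrasts.set_index("region").loc["occipital"]
            half = sps.t.ppf(0.975, occ["df"]) * occ["se"]
            covered += occ["estimate"] - half <= delta <= occ["estimate"] + half
        assert covered / n_rep >= 0.85

    def test_single_subject_reports_singular_fit(self):
        df = _lmm_table(n_subjects=1)
        res = fit_lmm(df, response="snr", seed=1)
        assert res.singular
        assert res.notes

    def test_condition_only_model(self):
        df = _lmm_table()
        res = fit_lmm(df, response="snr", region=None, group="subject", seed=1)
        assert len(res.anova) == 1
        assert res.contrasts is None


def _enumerate_cluster_p(diffs, adjacency_sets, threshold):
    """Independent exhaustive sign-flip oracle with its own BFS clustering."""
    n_sub, n_units = diffs.shape

    def tmap(d):
        m = d.mean(0)
        sd = d.std(0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = m / (sd / np.sqrt(n_sub))
        return np.where(sd == 0, 0.0, t)

    def max_mass(t):
        best = 0.0
        for sign in (1, -1):
            supra = set(np.flatnonzero(sign * t > threshold))
            seen = set()
            for start in supra:
                if start in seen:
                    continue
                stack, comp = [start], []
                while stack:
                    u = stack.pop()
                    if u in seen:
                        continue
                    seen.add(u)
                    comp.append(u)
                    stack.extend(v for v in adjacency_sets[u] if v in supra)
                best = max(best, abs(t[comp].sum()))
        return best

    obs = tmap(diffs)
    obs_masses = []
    for sign in (1, -1):
        supra = set(np.flatnonzero(sign * obs > threshold))
        seen = set()
        for start in supra:
            if start in seen:
                continue
            stack, comp = [start], []
            while stack:
                u = stack.pop()
                if u in seen:
                    continue
                seen.add(u)
                comp.append(u)
                stack.extend(v for v in adjacency_sets[u] if v in supra)
            obs_masses.append(obs[comp].sum())
    null = np.array(
        [
            max_mass(tmap(((1 - 2 * ((code >> np.arange(n_sub)) & 1))[:, None]) * diffs))
            for code in range(2**n_sub)
        ]
    )
    return {m: float(np.mean(null >= abs(m))) for m in obs_masses}


class TestClusterPerm:
    def _chain_adj(self, n):
        return temporal_adjacency(n)

    def test_cluster_mass_is_sum_of_member_t(self):
        t_map = np.array([2.5, 3.0, 2.2, 0.5, -1.0])
        adj = sparse.csr_matrix(np.ones((5, 5)) - np.eye(5))
        clusters = _find_clusters(t_map, 2.0, adj)
        assert len(clusters) == 1
        units, sign, mass = clusters[0]
        assert sorted(units) == [0, 1, 2]
        assert mass == pytest.approx(7.7)

    def test_monte_carlo_agrees_with_exhaustive_oracle(self, rng):
        n_sub, n_units = 6, 8
        diffs = rng.standard_normal((n_sub, n_units)) + 0.8
        adj = self._chain_adj(n_units)
        res = cluster_perm(
            diffs, np.zeros_like(diffs), adj, n_perm=10000, seed=3
        )
        adjacency_sets = {
            i: set(np.flatnonzero(adj.toarray()[i])) for i in range(n_units)
        }
        exact = _enumerate_cluster_p(diffs, adjacency_sets, res.threshold)
        assert res.clusters
        for cl in res.clusters:
            match = min(exact, key=lambda m: abs(m - cl.mass))
            assert match == pytest.approx(cl.mass, abs=1e-9)
            assert cl.p == pytest.approx(exact[match], abs=0.02)
        # package's own enumeration agrees too
        pkg_exact = cluster_perm_exact(diffs, np.zeros_like(diffs), adj)
        for mass, p in pkg_exact.items():
            assert p == pytest.approx(exact[mass], abs=1e-12)

    def test_p_values_in_unit_interval_never_zero(self, rng):
        diffs = rng.standard_normal((8, 10)) + 2.0
        res = cluster_perm(diffs, np.zeros_like(diffs), self._chain_adj(10),
                           n_perm=500, seed=0)
        for cl in res.clusters:
            assert 0.0 < cl.p <= 1.0

    def test_reproducible_from_seed_and_stable_in_n_perm(self, rng):
        diffs = rng.standard_normal((10, 6)) + 0.7
        adj = self._chain_adj(6)
        a = cluster_perm(diffs, np.zeros_like(diffs), adj, n_perm=1000, seed=5)
        b = cluster_perm(diffs, np.zeros_like(diffs), adj, n_perm=1000, seed=5)
        assert [c.p for c in a.clusters] == [c.p for c in b.clusters]
        c = cluster_perm(diffs, np.zeros_like(diffs), adj, n_perm=2000, seed=6)
        assert abs(a.min_p - c.min_p) < 2 / np.sqrt(1000)

    def test_edgeless_adjacency_degenerates_to_max_t(self, rng):
        """With no edges, each supra-threshold channel is its own cluster
        and the cluster p equals the max-t permutation p (same seed)."""
        a = rng.standard_normal((12, 5)) + 1.2
        b = rng.standard_normal((12, 5))
        adj = sparse.csr_matrix((5, 5))
        res_c = cluster_perm(a, b, adj, n_perm=2000, seed=9)
        res_m = maxT_pair_perm(a, b, n_perm=2000, seed=9)
        thr = res_c.threshold
        for cl in res_c.clusters:
            (unit,) = cl.units
            assert abs(res_m.t_obs[unit]) > thr
            assert cl.p == pytest.approx(res_m.p[unit], abs=1e-12)

    def test_channel_time_adjacency_structure(self):
        adj_ch = sparse.csr_matrix(np.array([[0, 1], [1, 0]], dtype=float))
        ct = channel_time_adjacency(adj_ch, 3).toarray()
        # (time, channel) flat C-order: unit 2*t + ch
        assert ct[0, 1] == 1  # same time, adjacent channel
        assert ct[0, 2] == 1  # adjacent time, same channel
        assert ct[0, 3] == 0  # diagonal neighbors are not adjacent
        assert np.array_equal(ct, ct.T)

    def test_mismatched_adjacency_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            cluster_perm(
                rng.standard_normal((5, 4)), rng.standard_normal((5, 4)),
                self._chain_adj(7),
            )


class TestMaxT:
    def test_identical_conditions_give_p_one(self, rng):
        x = rng.standard_normal((8, 6))
        res = maxT_pair_perm(x, x.copy(), n_perm=500, seed=1)
        assert np.all(res.t_obs == 0.0)
        assert np.all(res.p == 1.0)
        assert np.all(res.p_fdr == 1.0)
        assert not res.reject.any()

    def test_agrees_with_exhaustive_enumeration(self, rng):
        n_dyads, n_pairs = 5, 3
        a = rng.standard_normal((n_dyads, n_pairs)) + 1.0
        b = rng.standard_normal((n_dyads, n_pairs))
        res = maxT_pair_perm(a, b, n_perm=10000, seed=2)
        diffs = a - b
        null = np.empty(2**n_dyads)
        for code in range(2**n_dyads):
            signs = 1 - 2 * ((code >> np.arange(n_dyads)) & 1)
            null[code] = np.abs(_t_map(signs[:, None] * diffs)).max()
        exact = np.array(
            [np.mean(null >= abs(t)) for t in res.t_obs]
        )
        assert np.allclose(res.p, exact, atol=0.03)

    def test_injected_shift_detected_with_fdr_control(self):
        """A large shift on one pair is rejected after FDR in most
        replicates while the clean pairs stay below a 10% FP rate."""
        n_rep, n_dyads, n_pairs = 30, 31, 6
        rng = np.random.default_rng(17)
        hit, fp = 0, 0
        for _ in range(n_rep):
            a = rng.standard_normal((n_dyads, n_pairs))
            b = rng.standard_normal((n_dyads, n_pairs))
            a[:, 2] += 1.5  # ~1.06 sd of the paired difference
            res = maxT_pair_perm(a, b, n_perm=1000,
                                 seed=int(rng.integers(2**31)))
            hit += bool(res.reject[2])
            fp += int(res.reject[[0, 1, 3, 4, 5]].sum() > 0)
        assert hit / n_rep >= 0.8
        assert fp / n_rep <= 0.10


class TestFDR:
    def test_step_up_hand_example(self):
        reject, p_adj = fdr_bh(np.array([0.01, 0.02, 0.04, 0.5]), 0.05)
        assert list(reject) == [True, True, False, False]

    def test_all_ones_reject_nothing(self):
        reject, _ = fdr_bh(np.ones(10), 0.05)
        assert not reject.any()

    def test_empty_input(self):
        reject, p_adj = fdr_bh(np.array([]), 0.05)
        assert reject.size == 0 and p_adj.size == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(ConfigurationError):
            fdr_bh(np.array([0.5, 1.2]), 0.05)
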