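"""Paired tests, mixed models, and nonparametric permutation statistics.

Cluster-based permutation tests operate on within-subject condition
differences: the observed map of paired t values is thresholded (two-
sided, per-unit p < .05), supra-threshold units are grouped into
connected clusters under a supplied adjacency (electrode neighbor graph,
temporal contiguity, or their product for channel-time data), and the
cluster mass (sum of member t values) is referred to the permutation
distribution of the maximum absolute cluster mass under random
within-subject condition swaps (sign flips of the differences).  The
channel-pair test uses the maximum single t statistic instead of cluster
mass, followed by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats as sps
from scipy.sparse.csgraph import connected_components

from .errors import ConfigurationError, DegenerateInputError


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    mean_diff: float
    degenerate: bool = False


def paired_t(x: np.ndarray, y: np.ndarray) -> PairedTResult:
    """Classical dependent t-test on paired samples (df = n - 1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("paired_t expects two equal-length 1-d samples")
    if x.size < 2:
        raise DegenerateInputError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0.0:
        t = 0.0 if np.isclose(d.mean(), 0) else float(np.sign(d.mean()) * np.inf)
        return PairedTResult(
            t=t, df=d.size - 1, p=1.0 if t == 0 else 0.0,
            mean_diff=float(d.mean()), degenerate=True,
        )
    t, p = sps.ttest_rel(x, y)
    return PairedTResult(
        t=float(t), df=d.size - 1, p=float(p), mean_diff=float(d.mean())
    )


def _t_map(diffs: np.ndarray) -> np.ndarray:
    """Vectorized one-sample t over the subject axis (axis 0)."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(sd == 0, 0.0, t)


def _t_from_signs(signs: np.ndarray, diffs: np.ndarray) -> np.ndarray:
    """Paired t maps for sign-flip permutations, (n_perm, n_units).

    The observed map must be computed through this same arithmetic (an
    all-ones sign row) so that permutations reproducing the identity tie
    the observed statistic exactly.
    """
    n = diffs.shape[0]
    ss = (diffs**2).sum(axis=0)  # invariant under sign flips
    mean_p = (signs @ diffs) / n
    var_p = (ss / n - mean_p**2) * (n / (n - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_p / np.sqrt(var_p / n)
    return np.nan_to_num(t)


# ---------------------------------------------------------------------------
# linear mixed model
# ---------------------------------------------------------------------------

@dataclass
class LMMResult:
    """Fixed-effect F tests, contrasts, and fit diagnostics."""

    anova: pd.DataFrame  # term, F, df_num, df_den, p
    contrasts: pd.DataFrame | None
    params: pd.Series
    converged: bool
    singular: bool
    notes: tuple[str, ...] = field(default_factory=tuple)


def _within_ddf(n_obs: int, n_groups: int, rank: int) -> int:
    """Denominator df for within-group fixed effects in a balanced
    random-intercept model: n - groups - rank + 1 (matches the
    Satterthwaite estimate in the balanced case; e.g. reduces to the
    paired-t df for two conditions)."""
    return int(n_obs - n_groups - rank + 1)


def fit_lmm(
    data: pd.DataFrame,
    response: str,
    condition: str = "condition",
    region: str | None = "region",
    group: str = "subject",
    n_mvt_draws: int = 20000,
    seed: int = 0,
) -> LMMResult:
    """Random-intercept LMM with condition (x region) fixed effects.

    F tests per fixed term use Wald statistics on the REML fit with the
    balanced-design denominator df.  When ``region`` is given, pairwise
    JA-JW contrasts within each region are returned with p values
    adjusted by the multivariate-t (max-|t|) method over the contrast
    family.
    """
    import statsmodels.formula.api as smf

    for col in filter(None, (response, condition, region, group)):
        if col not in data.columns:
            raise ConfigurationError(f"data table lacks column {col!r}")
    notes: list[str] = []
    n_groups = data[group].nunique()
    if n_groups < 2:
        return LMMResult(
            anova=pd.DataFrame(columns=["term", "F", "df_num", "df_den", "p"]),
            contrasts=None,
            params=pd.Series(dtype=float),
            converged=False,
            singular=True,
            notes=("singular fit: fewer than 2 grouping levels",),
        )
    # sum-to-zero coding so per-term Wald slices are Type-III main effects
    fixed = f"C({condition}, Sum)"
    if region is not None:
        fixed = f"C({condition}, Sum) * C({region}, Sum)"
    formula = f"{response} ~ {fixed}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=data, groups=data[group])
        fit = model.fit(reml=True)
    converged = bool(getattr(fit, "converged", True))
    singular = bool(fit.cov_re.values.ravel()[0] <= 1e-10)
    if singular:
        notes.append("random-intercept variance estimated at zero (singular fit)")

    exog_names = model.exog_names
    beta = fit.fe_params
    cov = fit.cov_params().loc[exog_names, exog_names]
    rank = len(exog_names)
    ddf = _within_ddf(len(data), n_groups, rank)

    design_info = getattr(model.data, "design_info", None)
    rows = []
    slices = (
        design_info.term_name_slices
        if design_info is not None
        else {name: slice(i, i + 1) for i, name in enumerate(exog_names)}
    )
    for term, sl in slices.items():
        if term == "Intercept":
            continue
        idx = list(range(*sl.indices(rank)))
        L = np.zeros((len(idx), rank))
        for r, i in enumerate(idx):
            L[r, i] = 1.0
        est = L @ beta.values
        vc = L @ cov.values @ L.T
        fstat = float(est @ np.linalg.solve(vc, est) / len(idx))
        p = float(sps.f.sf(fstat, len(idx), ddf))
        rows.append({"term": term, "F": fstat, "df_num": len(idx), "df_den": ddf, "p": p})
    anova = pd.DataFrame(rows)

    contrasts = None
    if region is not None and design_info is not None:
        conds = sorted(data[condition].unique())
        if len(conds) == 2:
            regions = sorted(data[region].unique())
            cvecs, ests = [], []
            from patsy import dmatrix

            for reg in regions:
                rows_df = pd.DataFrame(
                    {condition: conds, region: [reg, reg]}
                )
                X = np.asarray(dmatrix(design_info, rows_df))
                cvecs.append(X[0] - X[1])
            C = np.array(cvecs)
            est = C @ beta.values
            vc = C @ cov.values @ C.T
            se = np.sqrt(np.diag(vc))
            tvals = est / se
            corr = vc / np.outer(se, se)
            p_adj = _mvt_maxabs_adjust(tvals, corr, ddf, n_mvt_draws, seed)
            p_raw = 2 * sps.t.sf(np.abs(tvals), ddf)
            contrasts = pd.DataFrame(
                {
                    "region": regions,
                    "contrast": f"{conds[0]} - {conds[1]}",
                    "estimate": est,
                    "se": se,
                    "t": tvals,
                    "df": ddf,
                    "p_unadjusted": p_raw,
                    "p_adjusted": p_adj,
                }
            )
    return LMMResult(
        anova=anova,
        contrasts=contrasts,
        params=beta,
        converged=converged,
        singular=singular,
        notes=tuple(notes),
    )


def _mvt_maxabs_adjust(
    tvals: np.ndarray,
    corr: np.ndarray,
    ddf: int,
    n_draws: int,
    seed: int,
) -> np.ndarray:
    """Multivariate-t max-|t| adjustment: p_i = P(max_j |T_j| >= |t_i|)."""
    rng = np.random.default_rng(seed)
    # stabilize the correlation matrix before factorization
    w, V = np.linalg.eigh(corr)
    L = V * np.sqrt(np.clip(w, 1e-12, None))
    z = rng.standard_normal((n_draws, corr.shape[0])) @ L.T
    s = np.sqrt(rng.chisquare(ddf, n_draws) / ddf)
    max_abs = np.abs(z / s[:, None]).max(axis=1)
    return np.array([np.mean(max_abs >= abs(t)) for t in tvals])


# ---------------------------------------------------------------------------
# adjacency builders
# ---------------------------------------------------------------------------

def channel_adjacency(montage, labels=None) -> sparse.csr_matrix:
    """Sparse electrode adjacency from the montage neighbor graph."""
    labels = tuple(labels) if labels is not None else montage.scalp_labels
    return sparse.csr_matrix(montage.adjacency_matrix(labels))


def temporal_adjacency(n_times: int) -> sparse.csr_matrix:
    """Contiguous-sample adjacency on a time axis."""
    if n_times < 1:
        raise ConfigurationError("need at least one time point")
    return sparse.diags(
        [1.0, 1.0], offsets=[-1, 1], shape=(n_times, n_times)
    ).tocsr()


def channel_time_adjacency(
    adj_channels: sparse.spmatrix, n_times: int
) -> sparse.csr_matrix:
    """Product adjacency on the (time, channel) grid, flattened C-order:
    (same channel, adjacent time) union (adjacent channel, same time)."""
    n_ch = adj_channels.shape[0]
    eye_t = sparse.identity(n_times, format="csr")
    eye_c = sparse.identity(n_ch, format="csr")
    adj_t = temporal_adjacency(n_times)
    return (sparse.kron(adj_t, eye_c) + sparse.kron(eye_t, adj_channels)).tocsr()


# ---------------------------------------------------------------------------
# cluster-based permutation
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    units: np.ndarray  # flat unit indices
    sign: int
    mass: float
    p: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_obs: np.ndarray
    threshold: float
    n_perm: int
    cluster_alpha: float
    null_max_mass: np.ndarray
    seed: int

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p <= self.cluster_alpha]

    @property
    def min_p(self) -> float:
        return min((c.p for c in self.clusters), default=1.0)


def _find_clusters(
    t_map: np.ndarray, threshold: float, adjacency: sparse.spmatrix
) -> list[tuple[np.ndarray, int, float]]:
    """Connected supra-threshold components, separately per sign."""
    out = []
    for sign in (1, -1):
        mask = (sign * t_map) > threshold
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        sub = adjacency[np.ix_(idx, idx)]
        n_comp, labels = connected_components(sub, directed=False)
        for c in range(n_comp):
            units = idx[labels == c]
            out.append((units, sign, float(t_map[units].sum())))
    return out


def cluster_perm(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    adjacency: sparse.spmatrix,
    n_perm: int = 1000,
    cluster_p: float = 0.05,
    cluster_alpha: float = 0.05,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-based permutation test of paired condition data.

    ``cond_a``/``cond_b`` are (n_subjects, n_units); the null swaps
    conditions within subject (sign flips of the differences) and
    records the maximum absolute cluster mass per permutation over both
    signs (a combined two-sided null).  Minimum cluster size is one
    unit.  Permutation p values use the add-one convention and are never
    exactly zero.
    """
    cond_a = np.asarray(cond_a, dtype=float)
    cond_b = np.asarray(cond_b, dtype=float)
    if cond_a.shape != cond_b.shape or cond_a.ndim != 2:
        raise ConfigurationError("expected matching (n_subjects, n_units) arrays")
    n_sub, n_units = cond_a.shape
    if adjacency.shape != (n_units, n_units):
        raise ConfigurationError("adjacency does not match the unit dimension")
    if n_sub < 2:
        raise DegenerateInputError("need at least 2 subjects")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low for stable cluster p values")
    adjacency = sparse.csr_matrix(adjacency)
    diffs = cond_a - cond_b
    threshold = float(sps.t.ppf(1.0 - cluster_p / 2.0, n_sub - 1))
    t_obs = _t_from_signs(np.ones((1, n_sub), dtype=int), diffs)[0]
    observed = _find_clusters(t_obs, threshold, adjacency)

    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, n_sub)) * 2 - 1
    t_perm = _t_from_signs(signs, diffs)

    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        clusters = _find_clusters(t_perm[i], threshold, adjacency)
        if clusters:
            null_max[i] = max(abs(m) for _, _, m in clusters)
    clusters = [
        Cluster(
            units=units,
            sign=sign,
            mass=mass,
            p=float((1 + np.sum(null_max >= abs(mass))) / (1 + n_perm)),
        )
        for units, sign, mass in observed
    ]
    clusters.sort(key=lambda c: -abs(c.mass))
    return ClusterResult(
        clusters=clusters,
        t_obs=t_obs,
        threshold=threshold,
        n_perm=n_perm,
        cluster_alpha=cluster_alpha,
        null_max_mass=null_max,
        seed=seed,
    )


def cluster_perm_exact(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    adjacency: sparse.spmatrix,
    cluster_p: float = 0.05,
) -> dict[float, float]:
    """Exhaustive sign-flip enumeration oracle for small n (<= ~12 subjects).

    Returns {observed cluster mass: exact p}, where p is the fraction of
    all 2^n sign assignments whose maximum |cluster mass| reaches |mass|.
    Intended as an independent check of :func:`cluster_perm`.
    """
    diffs = np.asarray(cond_a, dtype=float) - np.asarray(cond_b, dtype=float)
    n_sub, n_units = diffs.shape
    if n_sub > 14:
        raise ConfigurationError("exhaustive enumeration limited to n <= 14")
    adjacency = sparse.csr_matrix(adjacency)
    threshold = float(sps.t.ppf(1.0 - cluster_p / 2.0, n_sub - 1))
    observed = _find_clusters(_t_map(diffs), threshold, adjacency)
    null_max = np.empty(2**n_sub)
    for code in range(2**n_sub):
        signs = 1 - 2 * ((code >> np.arange(n_sub)) & 1)
        t = _t_map(signs[:, None] * diffs)
        clusters = _find_clusters(t, threshold, adjacency)
        null_max[code] = max((abs(m) for _, _, m in clusters), default=0.0)
    return {
        mass: float(np.mean(null_max >= abs(mass))) for _, _, mass in observed
    }


# ---------------------------------------------------------------------------
# max-t permutation over channel pairs + FDR
# ---------------------------------------------------------------------------

@dataclass
class MaxTResult:
    t_obs: np.ndarray
    p: np.ndarray
    p_fdr: np.ndarray
    reject: np.ndarray
    null_max_t: np.ndarray
    n_perm: int
    seed: int


def maxT_pair_perm(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    n_perm: int = 1000,
    q: float = 0.05,
    seed: int = 0,
) -> MaxTResult:
    """Max-statistic permutation test over paired comparisons.

    ``cond_a``/``cond_b`` are (n_dyads, n_pairs) condition values per
    electrode pair.  The null distribution of the maximum |t| over pairs
    is built from within-dyad condition shuffles; per-pair p values use
    the add-one convention, then Benjamini-Hochberg FDR at level ``q``.
    """
    cond_a = np.asarray(cond_a, dtype=float)
    cond_b = np.asarray(cond_b, dtype=float)
    if cond_a.shape != cond_b.shape or cond_a.ndim != 2:
        raise ConfigurationError("expected matching (n_dyads, n_pairs) arrays")
    n_dyads = cond_a.shape[0]
    if n_dyads < 2:
        raise DegenerateInputError("need at least 2 dyads")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low for stable p values")
    diffs = cond_a - cond_b
    t_obs = _t_from_signs(np.ones((1, n_dyads), dtype=int), diffs)[0]
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, n_dyads)) * 2 - 1
    t_perm = _t_from_signs(signs, diffs)
    null_max = np.abs(t_perm).max(axis=1)
    p = (1 + (null_max[:, None] >= np.abs(t_obs)[None, :]).sum(axis=0)) / (1 + n_perm)
    reject, p_fdr = fdr_bh(p, q)
    return MaxTResult(
        t_obs=t_obs,
        p=p,
        p_fdr=p_fdr,
        reject=reject,
        null_max_t=null_max,
        n_perm=n_perm,
        seed=seed,
    )


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection mask, adjusted p values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ConfigurationError("p values must lie in [0, 1]")
    if not (0 < q < 1):
        raise ConfigurationError("q must lie in (0, 1)")
    from statsmodels.stats.multitest import multipletests

    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj
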