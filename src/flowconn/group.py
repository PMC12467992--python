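"""Group-level aggregation of per-participant flow matrices.

Covers the spatial (mean matrix, active connections, top-k ranking),
magnitude (pooled |tau| distributions, descriptive statistics, two-sample
tests, effect size) and significance (transmitter-permutation null) analyses,
plus the subsample shape-feature clouds used to compare distribution shapes
between groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .flow import FlowMatrix, ROITimeSeries, _moment_matrices, _tau_from_moments

ACTIVE_THRESHOLD = 0.05


def _stack_abs(matrices) -> np.ndarray:
    if not matrices:
        raise ValueError("empty group")
    r = matrices[0].n_rois
    labels = matrices[0].roi_labels
    for m in matrices:
        if m.n_rois != r or m.roi_labels != labels:
            raise ValueError("matrices differ in size or ROI ordering")
    return np.stack([m.abs_tau for m in matrices])


def mean_group_matrix(matrices, group_name: str = "") -> FlowMatrix:
    """Elementwise mean of |tau| over participants (masked cells excluded pairwise)."""
    arr = _stack_abs(matrices)
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)  # all-NaN diagonal
        mean = np.nanmean(arr, axis=0)
    return FlowMatrix(tau=mean, roi_labels=matrices[0].roi_labels,
                      participant_id=group_name or "group-mean")


def active_connections(mean_matrix: FlowMatrix,
                       threshold: float = ACTIVE_THRESHOLD) -> set:
    """Ordered (transmitter, receiver) label pairs with mean |tau| above threshold."""
    labels = mean_matrix.roi_labels
    a = mean_matrix.abs_tau
    out = set()
    for i in range(mean_matrix.n_rois):
        for j in range(mean_matrix.n_rois):
            if i != j and np.isfinite(a[i, j]) and a[i, j] > threshold:
                out.add((labels[i], labels[j]))
    return out


def top_k(mean_matrix: FlowMatrix, k: int = 10) -> list:
    """The k strongest connections as (transmitter, receiver, mean |tau|), descending.

    Ties are broken lexicographically on the fixed (transmitter, receiver)
    index pair so that the ranking is deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    labels = mean_matrix.roi_labels
    a = mean_matrix.abs_tau
    entries = [(a[i, j], i, j)
               for i in range(mean_matrix.n_rois)
               for j in range(mean_matrix.n_rois)
               if i != j and np.isfinite(a[i, j])]
    entries.sort(key=lambda e: (-e[0], e[1], e[2]))
    return [(labels[i], labels[j], float(v)) for v, i, j in entries[:k]]


@dataclass
class NullDistribution:
    """Pooled transmitter-permutation |tau| values and their percentiles."""

    values: np.ndarray
    p5: float
    p95: float
    n_perm: int
    seed: int

    def significant(self, mean_matrix: FlowMatrix) -> set:
        """Mean connections exceeding the p95 permutation threshold."""
        return active_connections(mean_matrix, threshold=self.p95)


def permutation_null(group, n_perm: int = 100, seed: int = 0,
                     diff_step: int = 1) -> NullDistribution:
    """Group-level permutation null for |tau|.

    For every participant, connection and permutation the transmitter's
    samples are shuffled uniformly at random (the receiver is untouched) and
    |tau| recomputed; all values are pooled across participants and
    connections into one group-level null whose 5th/95th percentiles set the
    significance thresholds.
    """
    if not group:
        raise ValueError("empty group")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    pooled = []
    for ts in group:
        if not isinstance(ts, ROITimeSeries):
            raise TypeError("permutation_null expects ROITimeSeries inputs")
        vals = ts.values
        dt = ts.dt
        d = (vals[:, diff_step:] - vals[:, :-diff_step]) / (diff_step * dt)
        x = vals[:, :-diff_step]
        m = x.shape[1]
        xc = x - x.mean(axis=1, keepdims=True)
        dc = d - d.mean(axis=1, keepdims=True)
        var = np.einsum("ij,ij->i", xc, xc) / m
        var_d = np.einsum("ij,ij->i", dc, dc) / m
        c_j_dj = np.einsum("ij,ij->i", xc, dc) / m
        mask = ~np.eye(ts.n_rois, dtype=bool)
        for _ in range(n_perm):
            # independent shuffle per transmitter row
            perm = np.argsort(rng.random(xc.shape), axis=1)
            xp = np.take_along_axis(xc, perm, axis=1)
            c_perm = xp @ xc.T / m        # cov(perm x_i, x_j)
            cxd_perm = xp @ dc.T / m      # cov(perm x_i, dx_j)
            tau = _null_tau(c_perm, cxd_perm, var, var_d, c_j_dj, dt)
            pooled.append(np.abs(tau[mask]))
    pooled = np.concatenate(pooled)
    pooled = pooled[np.isfinite(pooled)]
    p5, p95 = np.percentile(pooled, [5, 95])
    return NullDistribution(values=pooled, p5=float(p5), p95=float(p95),
                            n_perm=n_perm, seed=seed)


def _null_tau(c, cxd, var, var_d, c_j_dj, dt, eps=1e-10):
    """tau matrix where the transmitter rows have been permuted.

    ``c[i, j] = cov(perm x_i, x_j)``, ``cxd[i, j] = cov(perm x_i, dx_j)``;
    the receiver's own moments (var, var_d, c_j_dj) are unchanged by the
    permutation.
    """
    sigma = np.sqrt(var)
    denom = np.outer(sigma, sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.clip(c / denom, -1.0, 1.0)
        r_xd = cxd / denom
        r_dd = c_j_dj / var
        one_minus = 1.0 - r * r
        collinear = np.abs(r) >= 1.0 - eps
        T = r / np.where(collinear, np.nan, one_minus) * (r_xd - r * r_dd[None, :])
        det = np.outer(var, var) - c * c
        det = np.where(det > 0, det, np.nan)
        a_jj = (var[:, None] * c_j_dj[None, :] - c * cxd) / det
        a_ij = (var[None, :] * cxd - c * c_j_dj[None, :]) / det
        mse = np.clip(var_d[None, :] - a_ij * cxd - a_jj * c_j_dj[None, :], 0.0, None)
        noise = dt * mse / (2.0 * var[None, :])
        Z = np.abs(T) + np.abs(a_jj) + np.abs(noise)
        tau = np.where(Z > 0, T / Z, 0.0)
    tau[~np.isfinite(T)] = np.nan
    np.fill_diagonal(tau, np.nan)
    return tau


@dataclass
class PooledDistribution:
    """All per-individual off-diagonal |tau| values of one group, plus shape stats.

    ``sd`` is the sample (ddof=1) standard deviation; ``cov = sd / mean``;
    skewness is the Fisher-Pearson moment coefficient and kurtosis is
    reported raw (Pearson; normal = 3) with the excess value alongside.
    """

    values: np.ndarray
    group_name: str = ""

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1))

    @property
    def cov(self) -> float:
        return self.sd / self.mean

    @property
    def skewness(self) -> float:
        return float(sps.skew(self.values, bias=True))

    @property
    def kurtosis(self) -> float:
        return float(sps.kurtosis(self.values, fisher=False, bias=True))

    @property
    def excess_kurtosis(self) -> float:
        return self.kurtosis - 3.0

    def summary(self) -> dict:
        return {"n": int(self.values.size), "mean": self.mean,
                "median": self.median, "sd": self.sd, "cov": self.cov,
                "skewness": self.skewness, "kurtosis": self.kurtosis,
                "excess_kurtosis": self.excess_kurtosis}


def pool_group_values(matrices, group_name: str = "") -> PooledDistribution:
    """Concatenate every participant's off-diagonal |tau| values."""
    if not matrices:
        raise ValueError("empty group")
    vals = np.concatenate([m.offdiag_abs_values() for m in matrices])
    return PooledDistribution(values=vals, group_name=group_name)


@dataclass
class GroupComparison:
    ks_stat: float
    ks_p: float
    kw_stat: float
    kw_p: float
    cohens_d: float


def cohens_d(a, b) -> float:
    """Two-sample Cohen's d with pooled standard deviation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    va = np.var(a, ddof=1) if na > 1 else 0.0
    vb = np.var(b, ddof=1) if nb > 1 else 0.0
    pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / max(na + nb - 2, 1))
    if pooled == 0:
        return 0.0
    return float((np.mean(a) - np.mean(b)) / pooled)


def compare_groups(a: PooledDistribution, b: PooledDistribution) -> GroupComparison:
    """Two-sample K-S and Kruskal-Wallis tests plus Cohen's d on pooled |tau|."""
    if a.values.size == 0 or b.values.size == 0:
        raise ValueError("empty distribution")
    ks = sps.ks_2samp(a.values, b.values)
    kw = sps.kruskal(a.values, b.values)
    return GroupComparison(ks_stat=float(ks.statistic), ks_p=float(ks.pvalue),
                           kw_stat=float(kw.statistic), kw_p=float(kw.pvalue),
                           cohens_d=cohens_d(a.values, b.values))


@dataclass
class SubsampleFeatures:
    """(COV, skewness, kurtosis) of pooled |tau| over many participant subsamples."""

    triplets: np.ndarray  # (reps, 3)
    k: int
    reps: int
    seed: int


def subsample_shape_features(matrices, k: int = 6, reps: int = 100_000,
                             seed: int = 0) -> SubsampleFeatures:
    """Shape-feature cloud from random k-participant subsamples.

    Each rep draws ``k`` participants without replacement, pools their
    off-diagonal |tau| values, and records (COV, skewness, kurtosis) with the
    same conventions as :class:`PooledDistribution`.  Vectorized via
    per-participant power sums, so the default 100,000 reps are cheap.
    """
    n = len(matrices)
    if k > n:
        raise ValueError(f"k = {k} exceeds group size {n}")
    if k < 1 or reps < 1:
        raise ValueError("k and reps must be positive")
    per = [m.offdiag_abs_values() for m in matrices]
    counts = np.array([v.size for v in per], dtype=float)
    pows = np.stack([[v.sum(), (v ** 2).sum(), (v ** 3).sum(), (v ** 4).sum()]
                     for v in per])

    rng = np.random.default_rng(seed)
    # reps independent k-subsets without replacement
    idx = np.argsort(rng.random((reps, n)), axis=1)[:, :k]
    m_tot = counts[idx].sum(axis=1)
    s = pows[idx].sum(axis=1)  # (reps, 4)
    s1, s2, s3, s4 = s.T
    mu = s1 / m_tot
    m2 = s2 / m_tot - mu ** 2
    m3 = s3 / m_tot - 3 * mu * s2 / m_tot + 2 * mu ** 3
    m4 = (s4 / m_tot - 4 * mu * s3 / m_tot + 6 * mu ** 2 * s2 / m_tot
          - 3 * mu ** 4)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd_sample = np.sqrt(m2 * m_tot / (m_tot - 1))
        cov = sd_sample / mu
        skew = m3 / m2 ** 1.5
        kurt = m4 / m2 ** 2
    return SubsampleFeatures(triplets=np.column_stack([cov, skew, kurt]),
                             k=k, reps=reps, seed=seed)
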