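"""Liang-Kleeman information flow rate between ROI source time series.

The information flow rate ``T_{i->j}`` quantifies, in nats per unit time,
the rate at which the transmitter series ``v_i`` contributes to the entropy
evolution of the receiver series ``v_j`` under a linear stochastic model of
the receiver's dynamics.  In correlation form,

    T_{i->j} = r_ij / (1 - r_ij^2) * (r_{i,dj} - r_ij * r_{j,dj})

where ``r_ij`` is the Pearson correlation between the two series and
``r_{i,dj}`` the cross-correlation between ``v_i`` and the temporal
derivative of ``v_j``, normalized by the product of the *series* standard
deviations (not the derivative's own).  The normalized flow

    tau_{i->j} = T_{i->j} / Z_{i->j}

divides T by the total magnitude of the receiver's entropy-rate budget,
``Z = |T| + |self| + |noise|``, so that ``|tau| <= 1`` and ``|tau|`` is
comparable across pairs and participants.  ``|tau| > 0.05`` is the
conventional "active connection" criterion used downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

#: Canonical ordering of the ten cortical regions of interest:
#: frontal, central, parietal, temporal, occipital x left/right.
DEFAULT_ROI_LABELS = ("LF", "RF", "LC", "RC", "LP", "RP", "LT", "RT", "LO", "RO")


@dataclass
class ROITimeSeries:
    """One participant's regional source signals at a fixed sampling interval.

    Parameters
    ----------
    values : ndarray of shape (n_rois, n_samples)
        Row ``i`` is the summed source magnitude of region ``roi_labels[i]``.
    roi_labels : tuple of str
        Unique region names, one per row.
    dt : float
        Sampling interval in seconds (e.g. ``0.004`` for 250 Hz).
    participant_id : str
    """

    values: np.ndarray
    roi_labels: tuple = DEFAULT_ROI_LABELS
    dt: float = 0.004
    participant_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.roi_labels = tuple(self.roi_labels)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (n_rois, n_samples) array")
        r, n = self.values.shape
        if r < 2:
            raise ValueError(f"need at least 2 ROIs, got {r}")
        if n < 3:
            raise ValueError(f"need at least 3 samples, got {n}")
        if len(self.roi_labels) != r:
            raise ValueError(
                f"{len(self.roi_labels)} labels for {r} rows"
            )
        if len(set(self.roi_labels)) != r:
            raise ValueError("roi_labels must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class PairStats:
    """Sample moments of one ordered (transmitter i, receiver j) pair."""

    C_ij: float
    C_ii: float
    C_jj: float
    C_i_dj: float
    C_j_dj: float
    sigma_i: float
    sigma_j: float
    r_ij: float
    r_i_dj: float
    r_j_dj: float
    var_dj: float
    dt: float


@dataclass
class FlowEstimate:
    """Normalized information flow for one ordered pair."""

    T: float
    Z: float
    self_term: float
    noise_term: float
    tau: float
    degenerate: bool = False

    @property
    def abs_tau(self) -> float:
        return abs(self.tau)


@dataclass
class FlowMatrix:
    """All ordered-pair normalized flows for one participant.

    ``tau[i, j]`` is the flow from transmitter ``i`` (row) to receiver ``j``
    (column).  The diagonal is undefined and stored as NaN; degenerate pairs
    are also NaN.
    """

    tau: np.ndarray
    roi_labels: tuple = DEFAULT_ROI_LABELS
    participant_id: str = ""

    def __post_init__(self):
        self.tau = np.asarray(self.tau, dtype=float)
        r = self.tau.shape[0]
        if self.tau.shape != (r, r):
            raise ValueError("tau must be square")
        if len(self.roi_labels) != r:
            raise ValueError("label count must match matrix size")

    @property
    def abs_tau(self) -> np.ndarray:
        return np.abs(self.tau)

    @property
    def n_rois(self) -> int:
        return self.tau.shape[0]

    def offdiag_abs_values(self) -> np.ndarray:
        """All defined off-diagonal |tau| values (row-major order)."""
        mask = ~np.eye(self.n_rois, dtype=bool)
        vals = self.abs_tau[mask]
        return vals[np.isfinite(vals)]


class DegenerateInputError(ValueError):
    """Raised when a pair is too degenerate (zero variance, |r| -> 1)."""


def sample_cross_covariance(x, y) -> float:
    """Population cross-covariance ``mean(x*y) - mean(x)*mean(y)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite input")
    return float(np.mean(x * y) - np.mean(x) * np.mean(y))


def pearson_correlation(x, y) -> float:
    """Pearson correlation; raises :class:`DegenerateInputError` on zero variance."""
    cxy = sample_cross_covariance(x, y)
    sx = np.sqrt(sample_cross_covariance(x, x))
    sy = np.sqrt(sample_cross_covariance(y, y))
    if sx == 0.0 or sy == 0.0:
        raise DegenerateInputError("zero variance in correlation input")
    return float(np.clip(cxy / (sx * sy), -1.0, 1.0))


def forward_difference(x, dt: float, step: int = 1) -> np.ndarray:
    """Forward-difference derivative ``(x[n+step] - x[n]) / (step*dt)``.

    Returns a series of length ``N - step``.
    """
    x = np.asarray(x, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if step < 1:
        raise ValueError("step must be >= 1")
    if x.size < step + 1:
        raise ValueError("series too short for the requested step")
    return (x[step:] - x[:-step]) / (step * dt)


def pair_stats(x_i, x_j, dt: float, diff_step: int = 1,
               deriv_norm: str = "series") -> PairStats:
    """All sample moments entering the flow formula for one ordered pair.

    Both series are truncated to the first ``N - diff_step`` samples so that
    every moment is estimated on the index set where the forward-difference
    derivative of the receiver is defined.

    ``deriv_norm`` selects the denominator of the derivative
    cross-correlations: ``"series"`` uses ``sigma_i * sigma_j`` (the printed
    convention), ``"derivative"`` uses ``sigma_i * sd(dx_j)``.
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.shape != x_j.shape or x_i.ndim != 1:
        raise ValueError("series must be equal-length and 1-D")
    if x_i.size < diff_step + 2:
        raise ValueError("series too short")
    if deriv_norm not in ("series", "derivative"):
        raise ValueError("deriv_norm must be 'series' or 'derivative'")

    dxj = forward_difference(x_j, dt, diff_step)
    xi = x_i[: -diff_step]
    xj = x_j[: -diff_step]

    C_ij = sample_cross_covariance(xi, xj)
    C_ii = sample_cross_covariance(xi, xi)
    C_jj = sample_cross_covariance(xj, xj)
    C_i_dj = sample_cross_covariance(xi, dxj)
    C_j_dj = sample_cross_covariance(xj, dxj)
    var_dj = sample_cross_covariance(dxj, dxj)
    sigma_i = float(np.sqrt(C_ii))
    sigma_j = float(np.sqrt(C_jj))
    if sigma_i == 0.0 or sigma_j == 0.0:
        raise DegenerateInputError("zero-variance series")

    r_ij = float(np.clip(C_ij / (sigma_i * sigma_j), -1.0, 1.0))
    if deriv_norm == "series":
        denom_i = sigma_i * sigma_j
        denom_j = sigma_j * sigma_j
    else:
        sd_dj = float(np.sqrt(var_dj))
        if sd_dj == 0.0:
            sd_dj = np.inf  # constant derivative -> correlations 0
        denom_i = sigma_i * sd_dj
        denom_j = sigma_j * sd_dj
    r_i_dj = float(C_i_dj / denom_i)
    r_j_dj = float(C_j_dj / denom_j)

    return PairStats(C_ij=C_ij, C_ii=C_ii, C_jj=C_jj, C_i_dj=C_i_dj,
                     C_j_dj=C_j_dj, sigma_i=sigma_i, sigma_j=sigma_j,
                     r_ij=r_ij, r_i_dj=r_i_dj, r_j_dj=r_j_dj,
                     var_dj=float(var_dj), dt=dt)


def liang_T(stats: PairStats, eps: float = 1e-10) -> float:
    """Information flow rate T (nats per unit time) from the pair moments."""
    r = stats.r_ij
    if abs(r) >= 1.0 - eps:
        raise DegenerateInputError(
            f"|r_ij| = {abs(r):.12g} too close to 1: collinear series"
        )
    return float(r / (1.0 - r * r) * (stats.r_i_dj - r * stats.r_j_dj))


def normalize_tau(stats: PairStats, T: float, dt: float | None = None) -> FlowEstimate:
    """Normalize T by the receiver's entropy-rate budget.

    The receiver's derivative is fitted by least squares on the pair,
    ``dx_j ~ a_ij x_i + a_jj x_j``; the self term of the budget is ``a_jj``,
    and the noise term is ``g_j / (2 C_jj)`` with noise intensity
    ``g_j = dt * mse`` of that fit.  ``Z = |T| + |self| + |noise|``
    guarantees ``|tau| <= 1`` and ``sign(tau) = sign(T)``.
    """
    if dt is None:
        dt = stats.dt
    det = stats.C_ii * stats.C_jj - stats.C_ij ** 2
    if det <= 0:
        raise DegenerateInputError("singular pair covariance")
    a_jj = (stats.C_ii * stats.C_j_dj - stats.C_ij * stats.C_i_dj) / det
    a_ij = (stats.C_jj * stats.C_i_dj - stats.C_ij * stats.C_j_dj) / det
    # residual variance of the centered least-squares fit
    mse = stats.var_dj - a_ij * stats.C_i_dj - a_jj * stats.C_j_dj
    mse = max(mse, 0.0)
    g_j = dt * mse
    noise_term = g_j / (2.0 * stats.C_jj)
    Z = abs(T) + abs(a_jj) + abs(noise_term)
    if Z == 0.0:
        return FlowEstimate(T=T, Z=0.0, self_term=a_jj, noise_term=noise_term,
                            tau=0.0, degenerate=True)
    return FlowEstimate(T=T, Z=Z, self_term=a_jj, noise_term=noise_term,
                        tau=T / Z)


def flow_pair(x_i, x_j, dt: float, diff_step: int = 1,
              deriv_norm: str = "series", eps: float = 1e-10) -> FlowEstimate:
    """Convenience: normalized flow from transmitter ``x_i`` to receiver ``x_j``."""
    st = pair_stats(x_i, x_j, dt, diff_step=diff_step, deriv_norm=deriv_norm)
    T = liang_T(st, eps=eps)
    return normalize_tau(st, T, dt)


def _moment_matrices(values: np.ndarray, dt: float, diff_step: int):
    """Vectorized covariance matrices shared by all ordered pairs.

    Returns (C, Cxd, var_d) where ``C[i, j] = cov(x_i, x_j)``,
    ``Cxd[i, j] = cov(x_i, dx_j)`` and ``var_d[j] = var(dx_j)``, all on the
    common truncated index set.
    """
    D = (values[:, diff_step:] - values[:, :-diff_step]) / (diff_step * dt)
    X = values[:, :-diff_step]
    m = X.shape[1]
    Xc = X - X.mean(axis=1, keepdims=True)
    Dc = D - D.mean(axis=1, keepdims=True)
    C = Xc @ Xc.T / m
    Cxd = Xc @ Dc.T / m
    var_d = np.einsum("ij,ij->i", Dc, Dc) / m
    return C, Cxd, var_d


def _tau_from_moments(C, Cxd, var_d, dt, eps=1e-10):
    """Full tau matrix from the shared moment matrices (NaN where degenerate)."""
    var = np.diag(C).copy()
    good = var > 0
    sigma = np.sqrt(np.where(good, var, np.nan))
    denom = np.outer(sigma, sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.clip(C / denom, -1.0, 1.0)
        r_xd = Cxd / denom                      # r_xd[i, j] = r_{i, dj}
        r_dd = np.diag(Cxd) / var               # r_{j, dj}

        one_minus = 1.0 - r * r
        collinear = np.abs(r) >= 1.0 - eps
        T = r / np.where(collinear, np.nan, one_minus) * (r_xd - r * r_dd[None, :])

        det = np.outer(var, var) - C * C
        det = np.where(det > 0, det, np.nan)
        C_j_dj = np.diag(Cxd)
        a_jj = (var[:, None] * C_j_dj[None, :] - C * Cxd) / det
        a_ij = (var[None, :] * Cxd - C * C_j_dj[None, :]) / det
        mse = var_d[None, :] - a_ij * Cxd - a_jj * C_j_dj
        mse = np.clip(mse, 0.0, None)
        noise = dt * mse / (2.0 * var[None, :])
        Z = np.abs(T) + np.abs(a_jj) + np.abs(noise)
        tau = np.where(Z > 0, T / Z, 0.0)
    tau[~np.isfinite(T)] = np.nan
    np.fill_diagonal(tau, np.nan)
    return tau


def ifr_matrix(ts: ROITimeSeries, diff_step: int = 1,
               deriv_norm: str = "series", eps: float = 1e-10) -> FlowMatrix:
    """Normalized information flow for every ordered ROI pair of a participant.

    Row = transmitter, column = receiver; diagonal masked as NaN.  Degenerate
    pairs (zero variance, collinearity) become NaN with a warning rather than
    aborting the participant.
    """
    if deriv_norm == "series":
        C, Cxd, var_d = _moment_matrices(ts.values, ts.dt, diff_step)
        tau = _tau_from_moments(C, Cxd, var_d, ts.dt, eps=eps)
    else:
        # alternative normalization is pair-at-a-time (rarely used)
        r_count = ts.n_rois
        tau = np.full((r_count, r_count), np.nan)
        for i in range(r_count):
            for j in range(r_count):
                if i == j:
                    continue
                try:
                    est = flow_pair(ts.values[i], ts.values[j], ts.dt,
                                    diff_step=diff_step, deriv_norm=deriv_norm,
                                    eps=eps)
                    tau[i, j] = est.tau
                except DegenerateInputError:
                    pass
    mask = ~np.eye(ts.n_rois, dtype=bool)
    n_bad = int(np.sum(~np.isfinite(tau[mask])))
    if n_bad:
        warnings.warn(
            f"{n_bad} degenerate pair(s) masked for participant "
            f"'{ts.participant_id}'", RuntimeWarning, stacklevel=2)
    return FlowMatrix(tau=tau, roi_labels=ts.roi_labels,
                      participant_id=ts.participant_id)


class InformationFlow(BaseEstimator, TransformerMixin):
    """Per-participant Liang-Kleeman flow estimator, sklearn-style.

    ``transform`` maps a list of :class:`ROITimeSeries` (or bare
    ``(n_rois, n_samples)`` arrays, with ``dt`` taken from the constructor)
    to a stacked ``(n_participants, R, R)`` array of normalized flows.

    Parameters
    ----------
    diff_step : int
        Forward-difference step of the derivative estimator (1 or 2).
    deriv_norm : {"series", "derivative"}
        Denominator convention of the derivative cross-correlation.
    dt : float
        Sampling interval used for bare-array inputs.
    """

    def __init__(self, diff_step: int = 1, deriv_norm: str = "series",
                 dt: float = 0.004, eps: float = 1e-10):
        self.diff_step = diff_step
        self.deriv_norm = deriv_norm
        self.dt = dt
        self.eps = eps

    def fit(self, X=None, y=None):
        self.n_features_in_ = None if X is None else len(X)
        return self

    def matrix(self, ts: ROITimeSeries) -> FlowMatrix:
        return ifr_matrix(ts, diff_step=self.diff_step,
                          deriv_norm=self.deriv_norm, eps=self.eps)

    def transform(self, X) -> np.ndarray:
        out = []
        for item in X:
            if not isinstance(item, ROITimeSeries):
                item = ROITimeSeries(values=np.asarray(item, dtype=float),
                                     roi_labels=tuple(
                                         f"R{k}" for k in range(len(item))),
                                     dt=self.dt)
            out.append(self.matrix(item).tau)
        return np.stack(out)

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X, y).transform(X)
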