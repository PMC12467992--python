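"""Unit and property tests of the information-flow estimator chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flowconn.flow import (DegenerateInputError, FlowMatrix, InformationFlow,
                           ROITimeSeries, flow_pair, forward_difference,
                           ifr_matrix, liang_T, normalize_tau, pair_stats,
                           pearson_correlation, sample_cross_covariance)


def brute_force_pair(x_i, x_j, dt):
    """Independent literal transcription of the moment formulas as loops."""
    dxj = [(x_j[n + 1] - x_j[n]) / dt for n in range(len(x_j) - 1)]
    xi = list(x_i[:-1])
    xj = list(x_j[:-1])
    m = len(xi)

    def mean(v):
        return sum(v) / len(v)

    def cov(a, b):
        return mean([ai * bi for ai, bi in zip(a, b)]) - mean(a) * mean(b)

    C_ij = cov(xi, xj)
    C_ii = cov(xi, xi)
    C_jj = cov(xj, xj)
    C_i_dj = cov(xi, dxj)
    C_j_dj = cov(xj, dxj)
    si = C_ii ** 0.5
    sj = C_jj ** 0.5
    r_ij = C_ij / (si * sj)
    r_i_dj = C_i_dj / (si * sj)
    r_j_dj = C_j_dj / (sj * sj)
    T = r_ij / (1 - r_ij ** 2) * (r_i_dj - r_ij * r_j_dj)
    det = C_ii * C_jj - C_ij ** 2
    a_jj = (C_ii * C_j_dj - C_ij * C_i_dj) / det
    a_ij = (C_jj * C_i_dj - C_ij * C_j_dj) / det
    mse = cov(dxj, dxj) - a_ij * C_i_dj - a_jj * C_j_dj
    noise = dt * max(mse, 0.0) / (2 * C_jj)
    Z = abs(T) + abs(a_jj) + abs(noise)
    tau = T / Z if Z > 0 else 0.0
    return {"C_ij": C_ij, "C_ii": C_ii, "C_jj": C_jj, "C_i_dj": C_i_dj,
            "C_j_dj": C_j_dj, "r_ij": r_ij, "r_i_dj": r_i_dj,
            "r_j_dj": r_j_dj, "T": T, "Z": Z, "tau": tau}


@pytest.mark.parametrize("x, y, expected", [
    ((1, 2, 3, 4), (1, 2, 3, 4), 1.25),
    ((1, 2, 3, 4), (4, 3, 2, 1), -1.25),
    ((5, 5, 5, 5), (0.3, -2, 7, 1), 0.0),
])
def test_sample_cross_covariance_values(x, y, expected):
    assert sample_cross_covariance(x, y) == pytest.approx(expected, abs=1e-12)


def test_cross_covariance_rejects_bad_input():
    with pytest.raises(ValueError):
        sample_cross_covariance([1, 2], [1, 2, 3])
    with pytest.raises(ValueError):
        sample_cross_covariance([1, np.nan], [1, 2])


def test_pearson_correlation_reference_points():
    x = np.array([0.3, -1.2, 2.2, 0.7])
    assert pearson_correlation(x, x) == pytest.approx(1.0)
    assert pearson_correlation(x, -x) == pytest.approx(-1.0)
    assert pearson_correlation([1, -1, 1, -1], [1, 1, -1, -1]) == pytest.approx(0.0)
    with pytest.raises(DegenerateInputError):
        pearson_correlation([2, 2, 2], [1, 2, 3])


@pytest.mark.parametrize("x, dt, expected", [
    ((0, 1, 2, 3), 1.0, (1.0, 1.0, 1.0)),
    ((7, 7, 7), 0.5, (0.0, 0.0)),
    ((0, 0.004), 0.004, (1.0,)),
])
def test_forward_difference(x, dt, expected):
    np.testing.assert_allclose(forward_difference(x, dt), expected)


def test_forward_difference_rejects_nonpositive_dt():
    with pytest.raises(ValueError):
        forward_difference([1, 2, 3], 0.0)


def test_pair_stats_fixed_vectors_match_brute_force():
    """Nine moment fields on fixed 6-point vectors match the loop oracle."""
    x_i = np.array([0.2, -0.1, 0.4, 0.0, -0.3, 0.1])
    x_j = np.array([0.0, 0.3, -0.2, 0.1, 0.2, -0.1])
    st_ = pair_stats(x_i, x_j, dt=1.0)
    ref = brute_force_pair(x_i, x_j, 1.0)
    for name in ("C_ij", "C_ii", "C_jj", "C_i_dj", "C_j_dj", "r_ij",
                 "r_i_dj", "r_j_dj"):
        assert getattr(st_, name) == pytest.approx(ref[name], abs=1e-12)
    assert st_.sigma_i == pytest.approx(ref["C_ii"] ** 0.5, abs=1e-12)


def test_pair_stats_linear_ramp_receiver_gives_zero_derivative_corr(rng):
    x_i = rng.standard_normal(50)
    x_j = 0.25 * np.arange(50) + 3.0
    st_ = pair_stats(x_i, x_j, dt=0.1)
    assert st_.C_i_dj == pytest.approx(0.0, abs=1e-9)
    assert st_.r_i_dj == pytest.approx(0.0, abs=1e-9)


def test_pair_stats_amplitude_scale_invariance(rng):
    x_i = rng.standard_normal(200)
    x_j = rng.standard_normal(200)
    a = pair_stats(x_i, x_j, dt=0.01)
    b = pair_stats(5.0 * x_i, x_j, dt=0.01)
    assert b.r_ij == pytest.approx(a.r_ij, rel=1e-12)
    assert b.r_i_dj == pytest.approx(a.r_i_dj, rel=1e-12)


def test_liang_T_zero_when_uncorrelated():
    """r_ij = 0 forces T = 0 regardless of the derivative correlations."""
    from flowconn.flow import PairStats

    st_ = PairStats(C_ij=0.0, C_ii=1.0, C_jj=1.0, C_i_dj=0.4, C_j_dj=-0.2,
                    sigma_i=1.0, sigma_j=1.0, r_ij=0.0, r_i_dj=0.4,
                    r_j_dj=-0.2, var_dj=1.0, dt=1.0)
    assert liang_T(st_) == 0.0


def test_liang_T_identical_series_degenerate(rng):
    x = rng.standard_normal(100)
    with pytest.raises(DegenerateInputError):
        liang_T(pair_stats(x, x.copy(), dt=0.01))


def test_normalize_tau_zero_flow(rng):
    x = rng.standard_normal(500)
    y = rng.standard_normal(500)
    st_ = pair_stats(x, y, dt=0.01)
    est = normalize_tau(st_, 0.0)
    assert est.tau == 0.0
    assert est.Z == pytest.approx(abs(est.self_term) + abs(est.noise_term))


@given(st.integers(0, 10_000))
@settings(max_examples=200)
def test_tau_bounded_and_sign_matches_T(seed):
    """|tau| <= 1 and sign(tau) = sign(T) for arbitrary random pairs."""
    r = np.random.default_rng(seed)
    n = int(r.integers(10, 200))
    x = r.standard_normal(n)
    y = r.standard_normal(n) + r.uniform(-0.9, 0.9) * x
    est = flow_pair(x, y, dt=float(r.uniform(0.001, 1.0)))
    assert abs(est.tau) <= 1.0 + 1e-12
    if est.Z > 0 and est.T != 0:
        assert np.sign(est.tau) == np.sign(est.T)
    assert est.Z == pytest.approx(
        abs(est.T) + abs(est.self_term) + abs(est.noise_term))


def test_ifr_matrix_has_90_offdiagonal_estimates(rng):
    ts = ROITimeSeries(values=rng.standard_normal((10, 500)), dt=0.004)
    fm = ifr_matrix(ts)
    assert np.all(np.isnan(np.diag(fm.tau)))
    assert np.isfinite(fm.tau[~np.eye(10, dtype=bool)]).sum() == 90
    np.testing.assert_allclose(fm.abs_tau[~np.eye(10, dtype=bool)],
                               np.abs(fm.tau[~np.eye(10, dtype=bool)]))


def test_ifr_matrix_matches_pairwise_path(rng):
    """The vectorized matrix equals the scalar pair-at-a-time chain."""
    ts = ROITimeSeries(values=rng.standard_normal((4, 300)),
                       roi_labels=("A", "B", "C", "D"), dt=0.01)
    fm = ifr_matrix(ts)
    for i in range(4):
        for j in range(4):
            if i != j:
                est = flow_pair(ts.values[i], ts.values[j], ts.dt)
                assert fm.tau[i, j] == pytest.approx(est.tau, rel=1e-10)


def test_ifr_matrix_row_permutation_equivariance(rng):
    values = rng.standard_normal((5, 400))
    labels = ("A", "B", "C", "D", "E")
    perm = np.array([3, 0, 4, 1, 2])
    fm = ifr_matrix(ROITimeSeries(values=values, roi_labels=labels, dt=0.01))
    fm_p = ifr_matrix(ROITimeSeries(values=values[perm],
                                    roi_labels=tuple(labels[k] for k in perm),
                                    dt=0.01))
    np.testing.assert_allclose(fm_p.tau, fm.tau[np.ix_(perm, perm)],
                               rtol=1e-10)


def test_ifr_matrix_masks_degenerate_roi(rng):
    values = rng.standard_normal((3, 200))
    values[1] = 2.5  # constant row
    ts = ROITimeSeries(values=values, roi_labels=("A", "B", "C"), dt=0.01)
    with pytest.warns(RuntimeWarning, match="degenerate"):
        fm = ifr_matrix(ts)
    assert np.isnan(fm.tau[1, 0]) and np.isnan(fm.tau[0, 1])
    assert np.isfinite(fm.tau[0, 2])


def test_roi_series_validation():
    with pytest.raises(ValueError):
        ROITimeSeries(values=np.zeros((1, 100)), roi_labels=("A",))
    with pytest.raises(ValueError):
        ROITimeSeries(values=np.full((2, 100), np.inf),
                      roi_labels=("A", "B"))
    with pytest.raises(ValueError):
        ROITimeSeries(values=np.zeros((2, 100)), roi_labels=("A", "A"))


def test_information_flow_sklearn_interface(rng):
    est = InformationFlow(dt=0.01)
    assert est.get_params()["diff_step"] == 1
    X = [rng.standard_normal((4, 300)) for _ in range(3)]
    out = est.fit_transform(X)
    assert out.shape == (3, 4, 4)
    est2 = InformationFlow(dt=0.01).set_params(diff_step=2)
    assert est2.diff_step == 2


def test_diff_step_two_is_supported(rng):
    x = rng.standard_normal(400)
    y = rng.standard_normal(400)
    est = flow_pair(x, y, dt=0.01, diff_step=2)
    assert np.isfinite(est.tau) and abs(est.tau) <= 1.0


def test_derivative_normalization_variant(rng):
    """The alternative sigma_i * sd(dx_j) convention rescales but keeps |tau| <= 1."""
    x = rng.standard_normal(500)
    y = 0.4 * x + rng.standard_normal(500)
    a = flow_pair(x, y, dt=0.01, deriv_norm="series")
    b = flow_pair(x, y, dt=0.01, deriv_norm="derivative")
    assert abs(b.tau) <= 1.0
    assert np.sign(b.T) == np.sign(a.T)
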