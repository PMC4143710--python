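import math

import numpy as np
import pytest
from scipy.stats import chi2

from famt2 import (
    CaseControlDesign,
    LongitudinalCovariates,
    TestSpec,
    asymptotic_pvalue,
    build_response,
    pooled_covariance,
    t2_statistic,
)
from famt2.engine import read_longitudinal
from famt2.simulate import write_long_csv

from conftest import blocks_from, make_design


# ---------------------------------------------------------------- response


def test_any_time_response():
    out = np.array([[0, 0, 1], [0, 0, 0], [1, 0, 0], [0, 0, 0]])
    d = build_response(out, "any-time")
    case = {0, 2}
    assert set(d.order[: d.n_c].tolist()) == case
    assert d.n_c == 2 and d.n_d == 2


def test_time_k_response():
    out = np.array([[0, 0, 1], [1, 0, 0], [0, 1, 0], [1, 1, 1]])
    d = build_response(out, "time-1")
    assert set(d.order[: d.n_c].tolist()) == {1, 3}
    d3 = build_response(out, 3)
    assert set(d3.order[: d3.n_c].tolist()) == {0, 3}


def test_response_order_is_stable():
    out = np.array([[1], [0], [1], [0], [1], [0]])
    d = build_response(out)
    assert d.order.tolist() == [0, 2, 4, 1, 3, 5]


def test_all_control_errors():
    with pytest.raises(ValueError, match="all-case or all-control"):
        build_response(np.zeros((5, 3), dtype=int))


def test_too_few_cases_errors():
    out = np.array([[1], [0], [0], [0]])
    with pytest.raises(ValueError, match="at least two"):
        build_response(out)


def test_bad_mode_errors():
    out = np.array([[1], [0], [1], [0]])
    with pytest.raises(ValueError):
        build_response(out, "sometimes")
    with pytest.raises(ValueError):
        build_response(out, "time-9")


# ---------------------------------------------------- pooled covariance


def test_pooled_covariance_hand_example():
    # 1-D: cases {0, 2}, controls {0, 0, 2, 2}
    # SS_cases = 2, SS_controls = 4, divisor n-2 = 4 -> 1.5
    X = np.array([[0.0], [2.0], [0.0], [0.0], [2.0], [2.0]])
    S = pooled_covariance(X, make_design(2, 4))
    assert S[0, 0] == pytest.approx(1.5)


def test_pooled_covariance_identical_rows():
    X = np.vstack([np.ones((3, 2)), np.zeros((4, 2))])
    S = pooled_covariance(X, make_design(3, 4))
    assert np.allclose(S, 0.0)


def test_pooled_covariance_matches_textbook(rng):
    X = rng.normal(size=(14, 3))
    nc = 6
    S = pooled_covariance(X, make_design(nc, 8))
    Sc = np.cov(X[:nc].T, ddof=1)
    Sd = np.cov(X[nc:].T, ddof=1)
    ref = ((nc - 1) * Sc + (14 - nc - 1) * Sd) / (14 - 2)
    assert np.allclose(S, ref, atol=1e-12)


# ------------------------------------------------------------- statistic


def _hotelling(X, nc):
    n = X.shape[0]
    xc, xd = X[:nc].mean(0), X[nc:].mean(0)
    S = pooled_covariance(X, make_design(nc, n - nc))
    return (nc * (n - nc) / n) * (xc - xd) @ np.linalg.solve(S, xc - xd)


def test_hotelling_reduction(rng):
    X = rng.normal(size=(20, 3))
    design = make_design(8, 12)
    res = t2_statistic(blocks_from(X), None, design, np.eye(20), TestSpec("T2"))
    assert res.t2 == pytest.approx(_hotelling(X, 8), abs=1e-10)


def test_equal_means_zero_statistic():
    half = np.arange(12, dtype=float).reshape(6, 2)
    X = np.vstack([half, half])
    res = t2_statistic(
        blocks_from(X), None, make_design(6, 6), np.eye(12), TestSpec("T2")
    )
    assert res.t2 == pytest.approx(0.0, abs=1e-20)


def test_doubling_phi_halves_genetic_term(rng):
    X = rng.normal(size=(16, 2))
    design = make_design(7, 9)
    r1 = t2_statistic(blocks_from(X), None, design, np.eye(16), TestSpec("T2"))
    r2 = t2_statistic(blocks_from(X), None, design, 2 * np.eye(16), TestSpec("T2"))
    assert r2.genetic_term == pytest.approx(r1.genetic_term / 2, rel=1e-12)


def test_q_identity_closed_form():
    for nc, nd in [(2, 2), (3, 9), (10, 5), (50, 51)]:
        d = make_design(nc, nd)
        c = d.contrast()
        assert c @ c == pytest.approx(nc * nd / (nc + nd), rel=1e-12)


def test_contrast_matrix_identity(rng):
    # The full contrast matrix built with Kronecker products applied to the
    # stacked column vector must equal (nc*nd/n) * (mean differences).
    n, T, S_, CJ = 10, 2, 1, 4
    nc = 4
    Z = rng.normal(size=(n, T))
    V = rng.normal(size=(n, S_))
    A = rng.normal(size=(n, CJ))
    u = np.array([1.0] * nc + [0.0] * (n - nc))
    c = u - nc / n
    eta = np.concatenate([Z.ravel(order="F"), V.ravel(order="F"), A.ravel(order="F")])
    H = np.zeros((T + S_ + CJ, n * (T + S_ + CJ)))
    H[:T, : n * T] = np.kron(np.eye(T), c)
    H[T:T + S_, n * T: n * (T + S_)] = np.kron(np.eye(S_), c)
    H[T + S_:, n * (T + S_):] = np.kron(np.eye(CJ), c)
    direct = (nc * (n - nc) / n) * np.concatenate([
        Z[:nc].mean(0) - Z[nc:].mean(0),
        V[:nc].mean(0) - V[nc:].mean(0),
        A[:nc].mean(0) - A[nc:].mean(0),
    ])
    assert np.allclose(H @ eta, direct, atol=1e-12)


def test_block_contributions_sum(rng):
    X = rng.normal(size=(24, 3))
    A = rng.normal(size=(24, 4))
    covs = LongitudinalCovariates(A, n_covariates=2, n_times=2)
    design = make_design(10, 14)
    res = t2_statistic(
        blocks_from(X, n_common=2), covs, design, np.eye(24), TestSpec("T2.longi")
    )
    assert res.t2 == pytest.approx(res.genetic_term + res.covariate_term)
    assert res.covariate_term > 0


def test_invariance_under_linear_maps(rng):
    X = rng.normal(size=(30, 4))
    design = make_design(12, 18)
    M = rng.normal(size=(4, 4)) + 4 * np.eye(4)  # well conditioned
    r1 = t2_statistic(blocks_from(X), None, design, np.eye(30), TestSpec("T2"))
    r2 = t2_statistic(blocks_from(X @ M), None, design, np.eye(30), TestSpec("T2"))
    assert r2.t2 == pytest.approx(r1.t2, rel=1e-9)


def test_phi_star_switch_scales_covariate_term(rng):
    from famt2 import compute_kinship, make_pedigree

    ped = make_pedigree(2, 3, 2)
    n = ped.n
    kin = compute_kinship(ped)
    nc = n // 3
    X = rng.normal(size=(n, 2))
    A = rng.normal(size=(n, 3))
    covs = LongitudinalCovariates(A, n_covariates=1, n_times=3)
    design = make_design(nc, n - nc)
    r_id = t2_statistic(
        blocks_from(X), covs, design, kin,
        TestSpec("T2.longi", phi_star="identity"),
    )
    r_kin = t2_statistic(
        blocks_from(X), covs, design, kin,
        TestSpec("T2.longi", phi_star="kinship"),
    )
    assert r_id.genetic_term == pytest.approx(r_kin.genetic_term, rel=1e-12)
    q_i = nc * (n - nc) / n
    assert r_kin.covariate_term == pytest.approx(
        r_id.covariate_term * q_i / r_kin.q_phi, rel=1e-9
    )


def test_separate_covariance_split(rng):
    Z = rng.normal(size=(20, 2))
    V = rng.normal(size=(20, 2))
    design = make_design(8, 12)
    joint = t2_statistic(
        blocks_from(np.hstack([Z, V]), n_common=2), None, design, np.eye(20),
        TestSpec("T2"),
    )
    sep = t2_statistic(
        blocks_from(np.hstack([Z, V]), n_common=2), None, design, np.eye(20),
        TestSpec("CMC.ZXpaper"),
    )
    qz = _hotelling(Z, 8)
    qv = _hotelling(V, 8)
    assert sep.t2 == pytest.approx(qz + qv, rel=1e-9)
    assert sep.t2 != pytest.approx(joint.t2)


def test_longi_method_requires_covariates(rng):
    X = rng.normal(size=(10, 2))
    with pytest.raises(ValueError, match="covariates"):
        t2_statistic(
            blocks_from(X), None, make_design(4, 6), np.eye(10),
            TestSpec("T2.longi"),
        )


def test_empty_genetic_block_errors():
    design = make_design(3, 3)
    with pytest.raises(ValueError, match="no testable"):
        t2_statistic(blocks_from(np.empty((6, 0))), None, design, np.eye(6),
                     TestSpec("T2"))


def test_non_psd_phi_errors(rng):
    X = rng.normal(size=(8, 1))
    with pytest.raises(np.linalg.LinAlgError):
        t2_statistic(blocks_from(X), None, make_design(4, 4), -np.eye(8),
                     TestSpec("T2"))


def test_invalid_spec():
    with pytest.raises(ValueError):
        TestSpec("T3")
    with pytest.raises(ValueError):
        TestSpec("T2", phi_star="diagonal")
    with pytest.raises(ValueError):
        TestSpec("T2", df_mode="aic")


# --------------------------------------------------------------- p-values


def _chi2_sf_oracle(x: float, df: int) -> float:
    # upper tail by the even/odd closed-form recursion, independent of scipy:
    # sf(2) = exp(-x/2); sf(1) = erfc(sqrt(x/2));
    # sf(k) = sf(k-2) + (x/2)^(k/2-1) exp(-x/2) / Gamma(k/2)
    if df % 2 == 0:
        return math.exp(-x / 2) * sum(
            (x / 2) ** j / math.factorial(j) for j in range(df // 2)
        )
    acc = math.erfc(math.sqrt(x / 2))
    for k in range(3, df + 1, 2):
        acc += (x / 2) ** (k / 2 - 1) * math.exp(-x / 2) / math.gamma(k / 2)
    return acc


@pytest.mark.parametrize("df", [1, 2, 3, 5, 8])
def test_chi2_survival_oracle(df):
    x = float(df)  # statistic equal to its df
    from famt2.engine import _chi2_sf

    assert _chi2_sf(x, df) == pytest.approx(_chi2_sf_oracle(x, df), rel=1e-12)


def test_zero_statistic_p_one(rng):
    X = np.vstack([np.eye(3), np.eye(3)])
    res = t2_statistic(blocks_from(X), None, make_design(3, 3), np.eye(6),
                       TestSpec("T2"))
    assert res.t2 == pytest.approx(0.0, abs=1e-18)
    assert res.p_asym == pytest.approx(1.0)


def test_df_modes_on_rank_deficient_block(rng):
    X = rng.normal(size=(20, 2))
    X3 = np.hstack([X, X[:, :1]])  # duplicated column
    design = make_design(8, 12)
    r_rank = t2_statistic(blocks_from(X3), None, design, np.eye(20),
                          TestSpec("T2", df_mode="rank"))
    r_nvar = t2_statistic(blocks_from(X3), None, design, np.eye(20),
                          TestSpec("T2", df_mode="n_variables"))
    assert r_rank.df == 2
    assert r_nvar.df == 3
    assert r_rank.t2 == pytest.approx(r_nvar.t2)
    assert asymptotic_pvalue(r_nvar, "rank") == pytest.approx(
        chi2.sf(r_nvar.t2, 2)
    )


def test_asymptotic_pvalue_validation(rng):
    X = rng.normal(size=(10, 1))
    res = t2_statistic(blocks_from(X), None, make_design(4, 6), np.eye(10),
                       TestSpec("T2"))
    with pytest.raises(ValueError):
        asymptotic_pvalue(res, "bic")
    res.t2 = -1.0
    with pytest.raises(ValueError):
        asymptotic_pvalue(res)


# ----------------------------------------------------------- file loading


def test_read_longitudinal_roundtrip(tmp_path, rng):
    ids = [f"i{k}" for k in range(5)]
    out = rng.integers(0, 2, size=(5, 3))
    out[0] = [1, 0, 0]
    A = rng.normal(size=(5, 6)).round(4)
    path = tmp_path / "ph.csv"
    write_long_csv(ids, out, A, n_covariates=2, n_times=3, path=str(path))
    ids2, out2, covs = read_longitudinal(str(path))
    assert ids2 == ids
    assert np.array_equal(out2, out)
    assert covs.n_covariates == 2 and covs.n_times == 3
    assert np.allclose(covs.values, A)


def test_read_longitudinal_incomplete(tmp_path):
    path = tmp_path / "ph.csv"
    path.write_text(
        "individual,time,outcome,cov1\n"
        "a,1,0,0.5\na,2,1,0.1\nb,1,0,0.2\n"
    )
    with pytest.raises(ValueError, match="incomplete"):
        read_longitudinal(str(path))
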