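"""Design and residual-variance matrices versus naive dense oracles.

The oracle implementations below transcribe each matrix formula from first
principles with explicit elementwise loops and plain `np.linalg.inv`,
sharing no code with the package; agreement is required to ~1e-10 relative
error on small trees.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rategls as rg
from rategls import rate_models as rm


# ------------------------------------------------------------------ oracles

def hadamard(A, B):
    n, m = A.shape
    out = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            out[i, j] = A[i, j] * B[i, j]
    return out


def emat(c, T):
    """[e^{c t_a} - 1] built entry by entry."""
    n = T.shape[0]
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = np.exp(c * T[i, j]) - 1.0
    return out


def oracle_m1_design_col(T, x):
    n = T.shape[0]
    return (np.eye(n) - 0.5 * hadamard(T, T) @ np.linalg.inv(T)) @ x


def oracle_m1_vr(T, a, b, s2, v_y, v_x):
    TT = hadamard(T, T)
    Ti = np.linalg.inv(T)
    return (
        4 * a * v_y * T
        + 2 * (a ** 2 + b ** 2 * v_x) * TT
        + b ** 2 * s2 * (hadamard(TT, T) - 0.25 * TT @ Ti @ TT)
    )


def oracle_m2_design_col(T, x, s2):
    n = T.shape[0]
    A = emat(1.5 * s2, T)
    B = emat(s2, T)
    M = (2.0 / s2) * (
        np.eye(n)
        - (2.0 / 3.0) * np.exp(-0.5 * s2) * A @ np.linalg.inv(B)
    )
    return M @ x


def oracle_m2_vr(T, a, b, s2, v_y, v_lnx):
    ev = np.exp(0.5 * v_lnx)
    t1 = 4 * a * v_y * T
    t2 = (8 * b * v_y * ev / s2) * emat(0.5 * s2, T)
    t3 = 2 * a ** 2 * hadamard(T, T)
    t4 = (8 * a * b * ev / s2) * hadamard(T, emat(0.5 * s2, T))
    E32 = emat(1.5 * s2, T)
    t5 = (2 * b ** 2 * np.exp(2 * v_lnx) / s2 ** 2) * (
        (8.0 / 3.0) * (emat(2 * s2, T) - emat(0.5 * s2, T))
        - emat(2 * s2, T)
        - (8.0 / 9.0) * E32 @ np.linalg.inv(emat(s2, T)) @ E32
    )
    return t1 + t2 + t3 + t4 + t5


def oracle_m3_dev_devvar(V, y, ybar):
    """Leave-one-out conditional-normal prediction, species by species."""
    n = V.shape[0]
    dev = np.empty(n)
    for i in range(n):
        rest = [j for j in range(n) if j != i]
        Vrr = V[np.ix_(rest, rest)]
        cond_mean = ybar + V[i, rest] @ np.linalg.inv(Vrr) @ (
            y[rest] - ybar
        )
        dev[i] = y[i] - cond_mean
    Vi = np.linalg.inv(V)
    d = np.diag(1.0 / np.diag(Vi))
    dev_var = d @ Vi @ d  # = (d(V^-1) V d(V^-1))^-1
    return dev, dev_var


def oracle_m3_design(V, x, Vmac):
    Vi = np.linalg.inv(V)
    dinv = np.diag(1.0 / np.diag(Vi))
    P = dinv @ Vi
    slope = hadamard(P, P) @ (x - x.mean())
    icol = np.diag(dinv @ Vi @ Vi @ dinv)
    offset = np.diag(P @ Vmac @ P.T)
    return icol, slope, offset


# ------------------------------------------------------------------ Model 1

class TestM1:
    def test_star_tree_halves_x(self, rng):
        T = np.eye(4)
        x = rng.standard_normal(4)
        D = rm.m1_design(T, x).D
        np.testing.assert_allclose(D[:, 1], x / 2)
        np.testing.assert_allclose(D[:, 0], 1.0)

    def test_zero_x_gives_zero_column(self, T3):
        D = rm.m1_design(T3, np.zeros(3)).D
        np.testing.assert_allclose(D[:, 1], 0.0, atol=1e-14)

    @pytest.mark.parametrize("treename", ["T3", "T5"])
    def test_design_matches_oracle(self, treename, request, rng):
        T = request.getfixturevalue(treename)
        x = rng.standard_normal(T.shape[0])
        D = rm.m1_design(T, x).D
        np.testing.assert_allclose(
            D[:, 1], oracle_m1_design_col(T, x), rtol=1e-10, atol=1e-12
        )

    def test_vr_limit_b0_vy0(self, T3):
        spec = rm.ModelSpec("M1", a=0.7, b=0.0, sigma2=1.0, v_y=0.0)
        np.testing.assert_allclose(
            rm.m1_residual_variance(T3, spec).Vr,
            2 * 0.7 ** 2 * T3 * T3,
            rtol=1e-12,
        )

    def test_vr_star_tree_b0(self):
        T = np.eye(3)
        spec = rm.ModelSpec("M1", a=2.0, b=0.0, sigma2=1.0, v_y=0.5)
        np.testing.assert_allclose(
            rm.m1_residual_variance(T, spec).Vr,
            (4 * 2.0 * 0.5 + 2 * 4.0) * np.eye(3),
            rtol=1e-12,
        )

    @pytest.mark.parametrize("treename", ["T3", "T5"])
    def test_vr_matches_oracle(self, treename, request):
        T = request.getfixturevalue(treename)
        a, b, s2, v_y, v_x = 1.2, 0.4, 0.8, 0.3, 0.2
        spec = rm.ModelSpec("M1", a=a, b=b, sigma2=s2, v_y=v_y, v_x=v_x)
        np.testing.assert_allclose(
            rm.m1_residual_variance(T, spec).Vr,
            oracle_m1_vr(T, a, b, s2, v_y, v_x),
            rtol=1e-10,
        )


# ------------------------------------------------------------------ Model 2

class TestM2:
    def test_small_sigma2_guard(self, T3):
        with pytest.raises(rg.SmallSigma2Error):
            rm.m2_design(T3, np.ones(3), sigma2=0.01)
        with pytest.raises(rg.SmallSigma2Error):
            rm.m2_design(T3, np.ones(3), sigma2=0.0)
        with pytest.warns(RuntimeWarning, match="Model 1"):
            rm.m2_design(T3, np.ones(3), sigma2=0.3)

    def test_zero_x_gives_zero_column(self, T3):
        D = rm.m2_design(T3, np.zeros(3), sigma2=1.0).D
        np.testing.assert_allclose(D[:, 1], 0.0, atol=1e-14)

    @pytest.mark.parametrize("s2", [0.6, 1.0, 2.0])
    def test_design_matches_oracle(self, T5, rng, s2):
        x = rng.standard_normal(5)
        D = rm.m2_design(T5, x, sigma2=s2).D
        np.testing.assert_allclose(
            D[:, 1], oracle_m2_design_col(T5, x, s2), rtol=1e-10,
            atol=1e-12,
        )

    def test_vr_limit_b0_vy0(self, T3):
        spec = rm.ModelSpec("M2", a=0.7, b=0.0, sigma2=1.0)
        np.testing.assert_allclose(
            rm.m2_residual_variance(T3, spec).Vr,
            2 * 0.7 ** 2 * T3 * T3,
            rtol=1e-12,
        )

    def test_star_tree_offdiagonals_vanish(self):
        # t_a = 0 off-diagonal: every bracketed matrix entry e^0 - 1 = 0
        T = np.eye(3)
        spec = rm.ModelSpec("M2", a=1.0, b=0.5, sigma2=1.0, v_y=0.1,
                            v_lnx=0.2)
        Vr = rm.m2_residual_variance(T, spec).Vr
        off = Vr - np.diag(np.diag(Vr))
        np.testing.assert_allclose(off, 0.0, atol=1e-12)

    @pytest.mark.parametrize("s2", [0.6, 1.0])
    def test_vr_matches_oracle(self, T5, s2):
        a, b, v_y, v_lnx = 0.9, 0.3, 0.2, 0.15
        spec = rm.ModelSpec("M2", a=a, b=b, sigma2=s2, v_y=v_y,
                            v_lnx=v_lnx)
        np.testing.assert_allclose(
            rm.m2_residual_variance(T5, spec).Vr,
            oracle_m2_vr(T5, a, b, s2, v_y, v_lnx),
            rtol=1e-10,
        )

    def test_nonpositive_x_rejected(self):
        with pytest.raises(rg.NonPositivePredictorError):
            rm.require_positive_predictor(
                np.array([1.0, -2.0, 3.0]), labels=["A", "B", "C"]
            )


# ------------------------------------------------------------------ Model 3

class TestM3:
    def test_variance_assembly(self, T3):
        spec = rm.ModelSpec("M3", a=0.5, b=0.0, macro_sigma2=2.0)
        V = rm.m3_variance(T3, spec, x=np.zeros(3)).V
        np.testing.assert_allclose(V, 2.0 * T3 + 0.5 * np.eye(3))

    def test_variance_diagonal_when_no_macro(self, T3):
        spec = rm.ModelSpec("M3", a=0.5, b=0.2, macro_sigma2=0.0)
        V = rm.m3_variance(T3, spec, x=np.array([1.0, 2.0, 3.0])).V
        np.testing.assert_allclose(V, np.diag(0.5 + 0.2 * np.arange(1, 4)))

    def test_negative_micro_variance_names_species(self, T3):
        spec = rm.ModelSpec("M3", a=0.1, b=1.0, macro_sigma2=1.0)
        with pytest.raises(rg.NegativeRateError, match="B"):
            rm.m3_variance(T3, spec, x=np.array([0.0, -1.0, 0.0]),
                           labels=["A", "B", "C"])

    def test_measurement_variance_on_diagonal(self, T3):
        spec = rm.ModelSpec("M3", a=0.5, b=0.0, macro_sigma2=1.0)
        mv = np.array([0.1, 0.2, 0.3])
        V = rm.m3_variance(T3, spec, x=np.zeros(3),
                           measurement_var=mv).V
        np.testing.assert_allclose(np.diag(V), 1.0 + 0.5 + mv)

    def test_predict_diagonal_V_is_mean_deviation(self, rng):
        V = np.diag(rng.uniform(0.5, 2.0, 4))
        y = rng.standard_normal(4)
        dec = rm.m3_predict(V, y)
        ybar = y.mean()
        np.testing.assert_allclose(dec.y_hat, ybar, atol=1e-12)
        np.testing.assert_allclose(dec.dev, y - ybar, atol=1e-12)
        np.testing.assert_allclose(dec.dev_var, V, atol=1e-12)

    def test_predict_constant_y_zero_dev(self, T3):
        V = 1.0 * T3 + 0.5 * np.eye(3)
        dec = rm.m3_predict(V, np.full(3, 2.5), ybar=2.5)
        np.testing.assert_allclose(dec.dev, 0.0, atol=1e-12)

    def test_predict_matches_conditional_normal_oracle(self, T3, rng):
        V = 1.0 * T3 + 0.5 * np.eye(3)
        y = rng.standard_normal(3)
        ybar = float(y.mean())
        dec = rm.m3_predict(V, y)
        dev_o, dev_var_o = oracle_m3_dev_devvar(V, y, ybar)
        np.testing.assert_allclose(dec.dev, dev_o, rtol=1e-10)
        np.testing.assert_allclose(dec.dev_var, dev_var_o, rtol=1e-10)

    def test_design_diagonal_V_collapses(self, rng):
        V = np.diag(np.full(4, 1.3))
        x = rng.standard_normal(4)
        dm, offset = rm.m3_design(V, x, V_macro=np.zeros((4, 4)))
        np.testing.assert_allclose(dm.D[:, 1], x - x.mean(), atol=1e-12)
        np.testing.assert_allclose(dm.D[:, 0], 1.0, atol=1e-12)
        np.testing.assert_allclose(offset, 0.0, atol=1e-12)

    def test_design_constant_x_zero_slope_column(self, T3):
        V = 1.0 * T3 + 0.5 * np.eye(3)
        dm, _ = rm.m3_design(V, np.full(3, 7.0), V_macro=T3)
        np.testing.assert_allclose(dm.D[:, 1], 0.0, atol=1e-12)

    def test_design_matches_oracle(self, T5, rng):
        Vmac = 0.8 * T5
        V = Vmac + np.diag(rng.uniform(0.3, 1.0, 5))
        x = rng.standard_normal(5)
        dm, offset = rm.m3_design(V, x, V_macro=Vmac)
        icol_o, slope_o, offset_o = oracle_m3_design(V, x, Vmac)
        np.testing.assert_allclose(dm.D[:, 0], icol_o, rtol=1e-10)
        np.testing.assert_allclose(dm.D[:, 1], slope_o, rtol=1e-10)
        np.testing.assert_allclose(offset, offset_o, rtol=1e-10)

    def test_residual_variance_identities(self, T3, rng):
        # diagonal V: Vr = 2 V.V ; any V: Vr_ii = 2 dev_var_ii^2
        Vd = np.diag(rng.uniform(0.5, 2.0, 3))
        np.testing.assert_allclose(
            rm.m3_residual_variance(Vd).Vr, 2.0 * Vd * Vd, atol=1e-12
        )
        V = 1.0 * T3 + 0.5 * np.eye(3)
        Vr = rm.m3_residual_variance(V).Vr
        dev_var = rm.m3_predict(V, np.zeros(3), ybar=0.0).dev_var
        np.testing.assert_allclose(Vr, 2.0 * dev_var * dev_var,
                                   rtol=1e-10)


# ------------------------------------------------------- misc operations

@pytest.mark.parametrize(
    "se,expected", [(0.0, 0.0), (1.0, 2.0), (0.5, 0.125)]
)
def test_obs_variance_of_squared_mean(se, expected):
    assert rm.obs_variance_of_squared_mean(se) == pytest.approx(expected)


def test_obs_variance_rejects_negative_se():
    with pytest.raises(rg.ValidationError):
        rm.obs_variance_of_squared_mean(-0.1)


def test_rate_function_is_affine():
    r = rm.rate_function(2.0, 3.0, np.array([0.0, 1.0, -1.0]))
    np.testing.assert_allclose(r, [2.0, 5.0, -1.0])


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    a=st.floats(0.05, 3.0),
    b=st.floats(-0.5, 0.5),
    s2=st.floats(0.5, 2.0),
    v_y=st.floats(0.0, 0.5),
    seed=st.integers(0, 10 ** 6),
)
def test_residual_variances_symmetric_psd(a, b, s2, v_y, seed):
    """Both path-model residual variance matrices stay symmetric PSD over
    admissible parameters on a random small tree."""
    tree = rg.make_fixture_tree(6, seed)
    T = rg.shared_branch_matrix(tree).T
    for model, extra in (("M1", {"v_x": v_y}), ("M2", {"v_lnx": v_y})):
        spec = rm.ModelSpec(model, a=a, b=b, sigma2=s2, v_y=v_y, **extra)
        Vr = (rm.m1_residual_variance(T, spec).Vr if model == "M1"
              else rm.m2_residual_variance(T, spec).Vr)
        np.testing.assert_allclose(Vr, Vr.T, atol=1e-10)
        assert np.linalg.eigvalsh(Vr).min() > -1e-8 * max(
            1.0, np.abs(Vr).max()
        )
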