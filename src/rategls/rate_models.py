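"""Design matrices and residual variance matrices for the three rate models.

All three models regress a squared trait deviation on an evolving predictor
to estimate how the predictor influences the trait's rate (variance) of
evolution.  The response variance is linear in the predictor,
``Var[dy] = (a + b*x) dt``, and the models differ in the assumed dynamics of
the predictor x:

* Model 1 (``M1``): x evolves as a Brownian motion (interval-scale
  predictors, e.g. log body size or an allometric residual).
* Model 2 (``M2``): x evolves as a geometric Brownian motion (strictly
  positive ratio-scale predictors whose causal effect is linear on the
  original scale).
* Model 3 (``M3``): only the *current* value of x matters; it scales the
  variance of a recent "microevolutionary" white-noise deviation layered on
  top of a Brownian macroevolutionary process.

Because the response is a squared Gaussian-like quantity, the residual
covariances involve Hadamard (elementwise) squares of the underlying
covariance matrices; these are assembled here, term by term, so diagnostics
can inspect each additive piece.

Matrix convention: ``[f(t_a)]`` denotes the matrix whose (i, j) entry is f
evaluated at the shared branch length of the tip pair (i, j); the diagonal
uses the full tree height (1 on a unit-height tree).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    NegativeRateError,
    NonPositivePredictorError,
    SmallSigma2Error,
    ValidationError,
)
from .treeio import SharedBranchMatrix, chol_solve, chol_with_jitter

#: below this predictor diffusion variance the geometric model is numerically
#: degenerate and Model 1 is the right tool
SIGMA2_MIN = 0.05
#: below this a warning suggests Model 1 (multiplicative dynamics with
#: moderate variation are well approximated by additive dynamics)
SIGMA2_WARN = 0.5


@dataclass
class ModelSpec:
    """Parameter bundle for one of the three rate models.

    ``a`` is the baseline rate variance (units y^2 per unit tree height),
    ``b`` the effect of the predictor on the rate (units y^2/x), ``sigma2``
    the Brownian diffusion of the predictor (of ln x for M2), and
    ``v_y``/``v_x``/``v_lnx`` the error variances of the root predictions
    used to center/standardize the variables.  ``macro_sigma2`` is the
    Brownian rate of the macroevolutionary component (M3 only).
    """

    model: str
    a: float = 0.0
    b: float = 0.0
    sigma2: float = 0.0
    v_y: float = 0.0
    v_x: float = 0.0
    v_lnx: float = 0.0
    macro_sigma2: float = 0.0

    def __post_init__(self):
        if self.model not in ("M1", "M2", "M3"):
            raise ValidationError(f"unknown model {self.model!r}")
        if self.sigma2 < 0 or self.macro_sigma2 < 0:
            raise ValidationError("diffusion variances must be nonnegative")


@dataclass
class DesignMatrix:
    """Two-column GLS design matrix with a record of the x-transform used."""

    D: np.ndarray
    transform_meta: dict = field(default_factory=dict)


@dataclass
class ResidualVariance:
    """Residual variance matrix with its additive components kept for
    diagnostics."""

    Vr: np.ndarray
    components: dict = field(default_factory=dict)


@dataclass
class MicroDecomposition:
    """Model 3 working quantities.

    ``V`` is the total tip covariance (macro + micro + measurement),
    ``y_hat`` the leave-one-out best linear predictions, ``dev = y - y_hat``
    the microevolutionary deviations whose squares form the regression
    response, and ``dev_var = Var[dev]``.
    """

    V: np.ndarray
    y_hat: np.ndarray = None
    dev: np.ndarray = None
    dev_var: np.ndarray = None


def _as_T(T) -> np.ndarray:
    return T.T if isinstance(T, SharedBranchMatrix) else np.asarray(T)


def rate_function(a: float, b: float, x) -> np.ndarray:
    """Predicted rate variance ``a + b*x`` of the response trait.

    This is the quantity with direct biological meaning: the expected
    disparity (among-species variance) accrued per unit tree height by a
    lineage with predictor value x.  Negative values mean the linear-rate
    approximation has been pushed outside its valid range.
    """
    return a + b * np.asarray(x, dtype=float)


def check_rates_nonnegative(a, b, x, labels=None, action="warn"):
    """Warn (or raise) if ``a + b*x`` is negative for any observed x."""
    r = rate_function(a, b, x)
    bad = np.where(r < 0)[0]
    if bad.size:
        who = ([labels[i] for i in bad] if labels is not None
               else bad.tolist())
        msg = (f"a + b*x is negative for {bad.size} species ({who[:5]}...); "
               "the linear-rate model is an approximation valid only where "
               "rates stay positive")
        if action == "raise":
            raise NegativeRateError(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    return bad


# ---------------------------------------------------------------- Model 1

def m1_design(T, x: np.ndarray) -> DesignMatrix:
    """Model 1 design matrix ``[1, (I - (1/2)(T.T) T^-1) x]``.

    ``x`` must already be centered on its predicted root value.  The slope
    column is the best-linear-predictor regressor of the squared response on
    the Brownian predictor; on a star tree it collapses to ``x/2``.
    """
    Tm = _as_T(T)
    x = np.asarray(x, dtype=float)
    n = Tm.shape[0]
    L, _ = chol_with_jitter(Tm)
    TT = Tm * Tm
    col = x - 0.5 * TT @ chol_solve(L, x)
    D = np.column_stack([np.ones(n), col])
    return DesignMatrix(D=D, transform_meta={"model": "M1"})


def m1_residual_variance(T, spec: ModelSpec) -> ResidualVariance:
    """Model 1 residual variance of the squared, root-centered response.

    Three additive pieces: uncertainty in the root prediction of y
    (``4 a v_y T``), the chi-square variance of a squared Gaussian
    (``2 (a^2 + b^2 v_x) T.T``), and the extra variance injected by the
    stochastically varying rate
    (``b^2 s2 (T.T.T - (1/4)(T.T) T^-1 (T.T))``).
    """
    Tm = _as_T(T)
    a, b, s2 = spec.a, spec.b, spec.sigma2
    L, _ = chol_with_jitter(Tm)
    TT = Tm * Tm
    t1 = 4.0 * a * spec.v_y * Tm
    t2 = 2.0 * (a * a + b * b * spec.v_x) * TT
    t3 = b * b * s2 * (TT * Tm - 0.25 * TT @ chol_solve(L, TT))
    Vr = t1 + t2 + t3
    return ResidualVariance(
        Vr=Vr, components={"root_y": t1, "chi_square": t2, "rate_path": t3}
    )


# ---------------------------------------------------------------- Model 2

def _check_sigma2_m2(sigma2: float):
    if sigma2 <= 0:
        raise SmallSigma2Error(
            "sigma2 must be positive for the geometric model"
        )
    if sigma2 < SIGMA2_MIN:
        raise SmallSigma2Error(
            f"sigma2 = {sigma2:.4g} < {SIGMA2_MIN}: the geometric model is "
            "numerically degenerate; use Model 1 (additive dynamics "
            "approximate multiplicative dynamics at low variance)"
        )
    if sigma2 < SIGMA2_WARN:
        warnings.warn(
            f"sigma2 = {sigma2:.4g} < {SIGMA2_WARN}: Model 1 may be the "
            "better choice for a predictor with this little multiplicative "
            "variation",
            RuntimeWarning,
            stacklevel=3,
        )


def m2_design(T, x: np.ndarray, sigma2: float) -> DesignMatrix:
    """Model 2 design matrix; slope column
    ``(2/s2)(I - (2/3) e^{-s2/2} [e^{1.5 s2 t_a}-1][e^{s2 t_a}-1]^-1) x``.

    ``x`` must be standardized by the (exponentiated) predicted log-root
    value and centered on its predicted mean; ``sigma2`` is the Brownian
    rate of ln x per unit tree height.
    """
    Tm = _as_T(T)
    _check_sigma2_m2(sigma2)
    x = np.asarray(x, dtype=float)
    n = Tm.shape[0]
    A = np.expm1(1.5 * sigma2 * Tm)
    B = np.expm1(sigma2 * Tm)
    LB, _ = chol_with_jitter(B)
    col = (2.0 / sigma2) * (
        x - (2.0 / 3.0) * np.exp(-0.5 * sigma2) * (A @ chol_solve(LB, x))
    )
    D = np.column_stack([np.ones(n), col])
    return DesignMatrix(D=D, transform_meta={"model": "M2", "sigma2": sigma2})


def m2_residual_variance(T, spec: ModelSpec) -> ResidualVariance:
    """Model 2 residual variance, assembled from its five additive terms.

    The bracketed matrices are built elementwise from the shared branch
    lengths; off-diagonal entries vanish on a star tree because
    ``e^{c*0} - 1 = 0``.
    """
    Tm = _as_T(T)
    a, b, s2 = spec.a, spec.b, spec.sigma2
    _check_sigma2_m2(s2)
    v_y, v_lnx = spec.v_y, spec.v_lnx
    e_half_vlnx = np.exp(0.5 * v_lnx)

    E_half = np.expm1(0.5 * s2 * Tm)     # [e^{s2 t_a / 2} - 1]
    E_one = np.expm1(s2 * Tm)            # [e^{s2 t_a} - 1]
    E_three_half = np.expm1(1.5 * s2 * Tm)
    E_two = np.expm1(2.0 * s2 * Tm)

    t1 = 4.0 * a * v_y * Tm
    t2 = (8.0 * b * v_y * e_half_vlnx / s2) * E_half
    t3 = 2.0 * a * a * (Tm * Tm)
    t4 = (8.0 * a * b * e_half_vlnx / s2) * (Tm * E_half)
    LB, _ = chol_with_jitter(E_one)
    sandwich = E_three_half @ chol_solve(LB, E_three_half)
    t5 = (2.0 * b * b * np.exp(2.0 * v_lnx) / s2 ** 2) * (
        (8.0 / 3.0) * (E_two - E_half)
        - E_two
        - (8.0 / 9.0) * sandwich
    )
    Vr = t1 + t2 + t3 + t4 + t5
    return ResidualVariance(
        Vr=Vr,
        components={
            "root_y": t1,
            "root_y_by_rate": t2,
            "chi_square": t3,
            "rate_cross": t4,
            "rate_path": t5,
        },
    )


# ---------------------------------------------------------------- Model 3

def m3_variance(
    T,
    spec: ModelSpec,
    x: np.ndarray,
    measurement_var: np.ndarray | None = None,
    labels=None,
    V_macro: np.ndarray | None = None,
) -> MicroDecomposition:
    """Total tip covariance ``V = V_macro + V_micro + V_measurement``.

    ``V_macro = macro_sigma2 * T`` under Brownian macroevolution (a
    user-supplied ``V_macro``, e.g. from an Ornstein-Uhlenbeck fit, may
    replace it), ``V_micro = a I + diag(b x)`` is the white-noise
    microevolutionary layer whose dependence on x is the target of
    inference, and ``measurement_var`` adds per-species observation
    variances to the diagonal.
    """
    Tm = _as_T(T)
    x = np.asarray(x, dtype=float)
    micro = rate_function(spec.a, spec.b, x)
    bad = np.where(micro < 0)[0]
    if bad.size:
        who = [labels[i] for i in bad] if labels is not None else bad.tolist()
        raise NegativeRateError(
            f"negative microevolutionary variance a + b*x for species {who}"
        )
    if V_macro is None:
        V_macro = spec.macro_sigma2 * Tm
    V = V_macro + np.diag(micro)
    if measurement_var is not None:
        mv = np.asarray(measurement_var, dtype=float)
        if np.any(mv < 0):
            raise ValidationError("measurement variances must be >= 0")
        V = V + np.diag(mv)
    return MicroDecomposition(V=V)


def _dinv_Vinv(V: np.ndarray):
    """Return (Vinv, dinv) with dinv = 1/diag(V^-1)."""
    L, _ = chol_with_jitter(V)
    Vinv = chol_solve(L, np.eye(V.shape[0]))
    return Vinv, 1.0 / np.diag(Vinv)


def m3_predict(
    V: np.ndarray, y: np.ndarray, ybar: float | np.ndarray | None = None
) -> MicroDecomposition:
    """Leave-one-out best linear predictions and deviations under Model 3.

    Each species' trait is predicted from all other species through the
    covariance V: ``y_hat = ybar + (V - d(V^-1)^-1) V^-1 (y - ybar)``, where
    the d-function zeroes the off-diagonal entries of its argument.  The
    deviation ``y - y_hat = d(V^-1)^-1 V^-1 (y - ybar)`` isolates the recent
    (non-phylogenetic) component; its covariance is
    ``(d(V^-1) V d(V^-1))^-1``.  With diagonal V the predictions collapse to
    the grand mean and the deviations to ordinary mean deviations.
    """
    y = np.asarray(y, dtype=float)
    if ybar is None:
        ybar = float(np.mean(y))
    Vinv, dinv = _dinv_Vinv(V)
    dev = dinv * (Vinv @ (y - ybar))
    y_hat = y - dev
    dev_var = dinv[:, None] * Vinv * dinv[None, :]
    return MicroDecomposition(V=V, y_hat=y_hat, dev=dev, dev_var=dev_var)


def m3_design(
    V: np.ndarray, x: np.ndarray, V_macro: np.ndarray
) -> tuple[DesignMatrix, np.ndarray]:
    """Model 3 design matrix and the macro-leakage offset.

    The slope column is ``(P.P)(x - xbar)`` with ``P = d(V^-1)^-1 V^-1``
    (Hadamard square of the deviation-forming operator); the intercept
    regressor is ``diag[d(V^-1)^-1 V^-2 d(V^-1)^-1]``.  Because the row
    sums of ``P.P`` equal that same regressor, the intercept coefficient
    estimates the micro variance at the mean predictor, ``a + b*xbar``;
    subtract ``b*xbar`` to recover the raw-scale a.  The returned offset
    vector
    ``diag[P V_macro P']`` is the part of the expected squared deviation
    contributed by macroevolution leaking through the leave-one-out
    prediction; it must be subtracted from the response before fitting.
    """
    x = np.asarray(x, dtype=float)
    xc = x - np.mean(x)
    Vinv, dinv = _dinv_Vinv(V)
    P = dinv[:, None] * Vinv
    slope_col = (P * P) @ xc
    Vinv2 = Vinv @ Vinv
    intercept_col = dinv * np.diag(Vinv2) * dinv
    offset = np.einsum("ik,kl,il->i", P, V_macro, P)
    D = np.column_stack([intercept_col, slope_col])
    return DesignMatrix(D=D, transform_meta={"model": "M3"}), offset


def m3_residual_variance(V: np.ndarray) -> ResidualVariance:
    """Residual variance of squared Model 3 deviations.

    Squares of zero-mean Gaussians follow a multivariate chi-square with one
    degree of freedom, whose covariance is twice the elementwise square of
    the underlying covariance: ``Vr = 2 * dev_var . dev_var``.
    """
    Vinv, dinv = _dinv_Vinv(V)
    dev_var = dinv[:, None] * Vinv * dinv[None, :]
    Vr = 2.0 * dev_var * dev_var
    return ResidualVariance(Vr=Vr, components={"chi_square": Vr})


def obs_variance_of_squared_mean(se) -> np.ndarray:
    """Observation variance of a squared species mean: ``2 se^4``.

    If a species mean carries a normally distributed observation error with
    standard error ``se``, the square of that mean has sampling variance
    ``2 se^4``; these values go on the diagonal of the residual variance
    matrix when fitting squared responses.
    """
    se = np.asarray(se, dtype=float)
    if np.any(se < 0):
        raise ValidationError("standard errors must be >= 0")
    return 2.0 * se ** 4


def require_positive_predictor(x, labels=None):
    """Model 2 needs a strictly positive, ratio-scale predictor."""
    x = np.asarray(x, dtype=float)
    bad = np.where(~(x > 0))[0]
    if bad.size:
        who = [labels[i] for i in bad] if labels is not None else bad.tolist()
        raise NonPositivePredictorError(
            f"Model 2 requires x > 0; offending species: {who}"
        )
    return x
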