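"""Iterated generalized least squares for the three rate models.

The estimation problem is linear in disguise: each model supplies a response
vector Y of squared trait deviations, a two-column design matrix D, and a
residual variance matrix Vr that itself depends on the parameters (a, b)
being estimated.  The fit therefore iterates: solve the GLS normal equations
for (A, b) given the current Vr, back-transform the intercept to the rate
parameter a, rebuild Vr, and repeat until (a, b) stabilize.  Such schemes
typically settle in a handful of iterations.

Standard errors come from the GLS covariance (D' Vr^-1 D)^-1; because the
residuals of squared Gaussian-like quantities are far from normal these
cannot be turned into exact confidence intervals, and the parametric
bootstrap (see :mod:`rategls.bootstrap`) is the recommended uncertainty
route.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import minimize_scalar

from .errors import ValidationError
from . import rate_models as rm
from .treeio import (
    Phylogeny,
    SharedBranchMatrix,
    chol_solve,
    chol_with_jitter,
    root_predictor,
    scale_to_unit_height,
    shared_branch_matrix,
)

#: relative floor used to keep the weighting matrix positive definite when
#: the running estimate of a dips to or below zero
A_FLOOR_REL = 1e-12


@dataclass
class GLSFit:
    """Result of an iterated GLS fit of one rate model.

    ``a_hat`` and ``b_hat`` are on the scale of the analysis variables
    (units y^2 and y^2/x per unit tree height); ``se`` holds the analytic
    standard errors; ``R2`` is the package's weighted variance-explained
    diagnostic.  The arrays used in the final iteration (``Y``, ``D``,
    ``Vr_final``) are retained for diagnostics and residual checks.
    """

    model: str
    a_hat: float
    b_hat: float
    beta_hat: dict
    se: dict
    cov_beta: np.ndarray
    Vr_final: np.ndarray
    n_iter: int
    converged: bool
    R2: float
    sigma2_hat: float
    macro_sigma2: float
    n_e: float
    v_y: float
    v_x: float
    v_lnx: float
    root_y: float
    root_x: float
    tip_labels: list
    Y: np.ndarray = field(repr=False, default=None)
    D: np.ndarray = field(repr=False, default=None)
    x_analysis: np.ndarray = field(repr=False, default=None)
    x_raw: np.ndarray = field(repr=False, default=None)
    trace: list = field(default_factory=list, repr=False)
    extra_beta: np.ndarray = None
    options: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "a_hat": self.a_hat,
            "b_hat": self.b_hat,
            "beta_hat": self.beta_hat,
            "se": self.se,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "R2": self.R2,
            "sigma2_hat": self.sigma2_hat,
            "macro_sigma2": self.macro_sigma2,
            "n_e": self.n_e,
            "v_y": self.v_y,
            "v_x": self.v_x,
            "v_lnx": self.v_lnx,
            "root_y": self.root_y,
            "root_x": self.root_x,
            "n_species": len(self.tip_labels),
            "tip_labels": list(self.tip_labels),
            "trace": [list(map(float, t)) for t in self.trace],
            "options": self.options,
        }

    def to_json(self, path=None, **kw) -> str:
        s = json.dumps(self.to_dict(), indent=2, **kw)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def estimate_sigma2_bm(T, z: np.ndarray) -> tuple[float, float]:
    """ML estimate of a Brownian rate from tip values alone.

    Under Brownian motion the tips are jointly Gaussian,
    ``z ~ N(m 1, sigma2 T)``; profiling out the root value m (the GLS mean)
    gives the closed-form ML estimate
    ``sigma2 = (z - m)' T^-1 (z - m) / n``.  On a star tree this is the
    ML (1/n-denominator) variance of z.  Returns ``(sigma2, m)``; for the
    geometric model pass ``z = ln x`` and ``sigma2`` is then the predicted
    variance of ln x across the tips of a unit-height tree.
    """
    Tm = T.T if isinstance(T, SharedBranchMatrix) else np.asarray(T)
    z = np.asarray(z, dtype=float)
    n = z.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 species to estimate sigma2")
    m = root_predictor(Tm, z).m
    L, _ = chol_with_jitter(Tm)
    resid = z - m
    sigma2 = float(resid @ chol_solve(L, resid)) / n
    return sigma2, m


def gls_solve(D: np.ndarray, Y: np.ndarray, Vr: np.ndarray):
    """Generalized least squares via Cholesky whitening.

    Solves ``beta = (D' Vr^-1 D)^-1 D' Vr^-1 Y`` without ever forming
    ``Vr^-1`` explicitly: the system is whitened by the Cholesky factor of
    Vr and solved as an ordinary least-squares problem.  Returns
    ``(beta, cov)`` with ``cov = (D' Vr^-1 D)^-1``.
    """
    D = np.atleast_2d(np.asarray(D, dtype=float))
    Y = np.asarray(Y, dtype=float)
    L, _ = chol_with_jitter(np.asarray(Vr, dtype=float))
    Dw = solve_triangular(L, D, lower=True)
    Yw = solve_triangular(L, Y, lower=True)
    q, r = np.linalg.qr(Dw)
    if np.min(np.abs(np.diag(r))) < 1e-12 * np.max(np.abs(np.diag(r))):
        raise ValidationError("design matrix is rank deficient")
    beta = np.linalg.solve(r, q.T @ Yw)
    rinv = solve_triangular(r, np.eye(r.shape[0]), lower=False)
    cov = rinv @ rinv.T
    return beta, cov


def r_squared_theoretical(a: float, b: float, x_mean: float,
                          x_var: float) -> float:
    """Closed-form ceiling on the variance in y^2 explainable by x.

    When ``Var[y|x] = a + b x`` and y is mean-centered,

        R^2 = b^2 Var[x] / (2 a^2 + 4 a b xbar + 2 b^2 xbar^2
                            + 3 b^2 Var[x])  <  1/3.

    Pass ``b = inf`` for the limiting value ``Var[x]/(2 xbar^2 + 3 Var[x])``.
    Even a strong causal effect on the rate of evolution explains only a few
    percent of observed disparity, which is why large species samples are
    needed.
    """
    if x_var < 0:
        raise ValidationError("x_var must be >= 0")
    if np.isinf(b):
        den = 2.0 * x_mean ** 2 + 3.0 * x_var
        if den <= 0:
            raise ValidationError("degenerate denominator")
        return x_var / den
    den = (2.0 * a ** 2 + 4.0 * a * b * x_mean
           + 2.0 * b ** 2 * x_mean ** 2 + 3.0 * b ** 2 * x_var)
    if den <= 0:
        raise ValidationError("degenerate denominator")
    return b ** 2 * x_var / den


def fit_r_squared(fit: "GLSFit" = None, Y=None, D=None, beta=None,
                  Vr=None) -> float:
    """Weighted variance-explained diagnostic for a GLS fit.

    Defined as ``1 - (r' W r) / ((Y - mu)' W (Y - mu))`` with ``W = Vr^-1``,
    residuals from the fitted model and ``mu`` the GLS (weighted) mean of Y.
    This is this package's definition of a phylogenetically weighted R^2 for
    squared-deviation regressions; expect small values even for real
    effects (see :func:`r_squared_theoretical`).
    """
    if fit is not None:
        Y = fit.Y if Y is None else Y
        D = fit.D if D is None else D
        Vr = fit.Vr_final if Vr is None else Vr
        if beta is None:
            beta = np.array(
                [fit.beta_hat["A_hat"], fit.beta_hat["b_hat"]]
                + ([] if fit.extra_beta is None else list(fit.extra_beta))
            )
    Y = np.asarray(Y, dtype=float)
    L, _ = chol_with_jitter(np.asarray(Vr, dtype=float))
    r = Y - np.asarray(D) @ np.asarray(beta)
    ones = np.ones_like(Y)
    w1 = chol_solve(L, ones)
    mu = float(w1 @ Y) / float(w1 @ ones)
    tot = Y - mu
    tss = float(tot @ chol_solve(L, tot))
    if tss <= 0:
        raise ValidationError("zero weighted total variance in the response")
    rss = float(r @ chol_solve(L, r))
    return 1.0 - rss / tss


def estimate_macro_sigma2(T, y: np.ndarray) -> tuple[float, float, float]:
    """ML fit of the Brownian + white-noise mixed model for the response.

    ``y ~ N(mu 1, s2_macro T + s2_resid I)``.  The likelihood is profiled
    over mu and the total scale, leaving a one-dimensional search over the
    noise-to-signal ratio.  Returns ``(s2_macro, s2_resid, mu)``.  The ratio
    of ``s2_macro`` to the total among-species variance is the phylogenetic
    heritability of the trait.
    """
    Tm = T.T if isinstance(T, SharedBranchMatrix) else np.asarray(T)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    ones = np.ones(n)

    def profile_neg_loglik(log_rho: float):
        rho = np.exp(log_rho)
        V0 = Tm + rho * np.eye(n)
        L, _ = chol_with_jitter(V0)
        V0i_1 = chol_solve(L, ones)
        mu = float(V0i_1 @ y) / float(V0i_1 @ ones)
        resid = y - mu
        q = float(resid @ chol_solve(L, resid))
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        s2 = q / n
        return 0.5 * (n * np.log(max(s2, 1e-300)) + logdet + n), s2, mu

    res = minimize_scalar(
        lambda lr: profile_neg_loglik(lr)[0],
        bounds=(-12.0, 12.0), method="bounded",
        options={"xatol": 1e-8},
    )
    _, s2, mu = profile_neg_loglik(res.x)
    rho = float(np.exp(res.x))
    # compare against the pure white-noise boundary model
    nll_wn = 0.5 * n * (np.log(max(np.var(y), 1e-300)) + 1.0)
    if nll_wn < res.fun:
        return 0.0, float(np.var(y)), float(np.mean(y))
    return s2, s2 * rho, mu


def _a_floor(Y: np.ndarray) -> float:
    v = float(np.var(Y))
    return A_FLOOR_REL * v if v > 0 else 1e-12


def fit_rate_model(
    tree: Phylogeny,
    y: np.ndarray,
    x: np.ndarray,
    model: str,
    se_y: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 50,
    macro_sigma2: float | None = None,
    V_macro: np.ndarray | None = None,
    extra_cols: np.ndarray | None = None,
) -> GLSFit:
    """Fit one of the three rate-of-evolution models by iterated GLS.

    Parameters
    ----------
    tree : Phylogeny
        Rooted ultrametric phylogeny; rescaled internally to unit height if
        needed (rates are then per tree length).
    y, x : arrays aligned to the tree's canonical tip order
        Response and predictor species values on their raw scales; all
        model-specific centering and standardization happens internally.
    model : {"M1", "M2", "M3"}
    se_y : optional per-species standard errors of the response means;
        their squares enter Model 3's covariance and ``2 se^4`` is added to
        the residual variance of every model's squared response.
    macro_sigma2 / V_macro : Model 3 macroevolutionary rate (estimated by ML
        from y when not given) or a full user-supplied macro covariance.
    extra_cols : optional additional fixed-effect design columns, passed
        through untransformed.

    Notes
    -----
    Each iteration solves the GLS problem at the current residual variance,
    back-transforms the intercept to a (adding the root-prediction variance
    v_y for Models 1 and 2, and subtracting Model 2's mean-path term), then
    rebuilds the residual variance.  If the running ``a`` goes nonpositive
    the *weighting* matrices use a small positive floor while the reported
    estimate stays unclamped, keeping the linear estimator unbiased.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if model not in ("M1", "M2", "M3"):
        raise ValidationError(f"unknown model {model!r}")
    if y.shape != x.shape or y.ndim != 1:
        raise ValidationError("y and x must be 1-D arrays of equal length")
    if y.shape[0] != tree.n_tips:
        raise ValidationError(
            f"{y.shape[0]} trait values for {tree.n_tips} tips"
        )
    if abs(tree.height - 1.0) > 1e-8:
        tree = scale_to_unit_height(tree)
    sbm = shared_branch_matrix(tree)
    T = sbm.T
    labels = tree.tip_labels
    obs_var = None
    if se_y is not None:
        obs_var = rm.obs_variance_of_squared_mean(se_y)

    if model == "M3":
        return _fit_m3(
            T, y, x, labels, se_y, obs_var, tol, max_iter,
            macro_sigma2, V_macro, extra_cols,
        )
    return _fit_m12(
        model, T, y, x, labels, obs_var, tol, max_iter, extra_cols
    )


def _append_extra(D: np.ndarray, extra_cols) -> np.ndarray:
    if extra_cols is None:
        return D
    E = np.atleast_2d(np.asarray(extra_cols, dtype=float))
    if E.shape[0] != D.shape[0]:
        E = E.T
    return np.column_stack([D, E])


def _fit_m12(model, T, y, x, labels, obs_var, tol, max_iter, extra_cols):
    n = T.shape[0]
    if model == "M1":
        sigma2, m_x = estimate_sigma2_bm(T, x)
        rp_x = root_predictor(T, x, sigma2)
        n_e = rp_x.n_e
        v_x, v_lnx = rp_x.v, 0.0
        xc = x - m_x
        dm = rm.m1_design(T, xc)
    else:
        rm.require_positive_predictor(x, labels)
        lnx = np.log(x)
        sigma2, m_lnx = estimate_sigma2_bm(T, lnx)
        rp = root_predictor(T, lnx, sigma2)
        n_e = rp.n_e
        v_x, v_lnx = 0.0, rp.v
        m_x = m_lnx
        x_std = x / np.exp(m_lnx)
        # predicted tip mean of the standardized geometric predictor:
        # E[exp(ln x_i - m_hat)] = exp((sigma2 - v_lnx)/2)
        mu_x = np.exp(0.5 * (sigma2 - v_lnx))
        xc = x_std - mu_x
        dm = rm.m2_design(T, xc, sigma2)
        # mean-path term linking the intercept back to a: the expected
        # squared response at the centered predictor's origin includes the
        # rate accrued along the mean predictor path (see docs/methods.md)
        L, _ = chol_with_jitter(T)
        w = chol_solve(L, np.ones(n)) / n_e
        G = np.expm1(0.5 * sigma2 * T)
        Gw = G @ w
        path = (2.0 / sigma2) * np.exp(0.5 * v_lnx) * (
            np.diag(G) - 2.0 * Gw + float(w @ Gw)
        )
        c_path = float(np.mean(path))

    m_y = root_predictor(T, y).m
    Y = (y - m_y) ** 2
    D = _append_extra(dm.D, extra_cols)
    floor = _a_floor(Y)

    # initial guess: ordinary least squares on (Y, D)
    beta = np.linalg.lstsq(D, Y, rcond=None)[0]
    A, b = float(beta[0]), float(beta[1])
    a = A * n_e / (n_e - 1.0) if n_e > 1 else A
    if model == "M2":
        a -= b * c_path * n_e / (n_e - 1.0) if n_e > 1 else b * c_path

    trace = [(a, b)]
    converged = False
    cov = None
    for it in range(1, max_iter + 1):
        a_w = max(a, floor)
        v_y = a_w / n_e
        spec = rm.ModelSpec(
            model=model, a=a_w, b=b, sigma2=sigma2,
            v_y=v_y, v_x=v_x, v_lnx=v_lnx,
        )
        if model == "M1":
            Vr = rm.m1_residual_variance(T, spec).Vr
        else:
            Vr = rm.m2_residual_variance(T, spec).Vr
        if obs_var is not None:
            Vr = Vr + np.diag(obs_var)
        beta, cov = gls_solve(D, Y, Vr)
        A = float(beta[0])
        b_new = float(beta[1])
        a_new = A + v_y
        if model == "M2":
            a_new -= b_new * c_path
        step = np.hypot(a_new - a, b_new - b)
        scale = max(np.hypot(a, b), 1e-12)
        a, b = a_new, b_new
        trace.append((a, b))
        if step < tol * scale:
            converged = True
            break

    rm.check_rates_nonnegative(a, b, xc, labels)
    se = np.sqrt(np.diag(cov))
    fit = GLSFit(
        model=model,
        a_hat=a,
        b_hat=b,
        beta_hat={"A_hat": A, "b_hat": b},
        se={"A_hat": float(se[0]), "b_hat": float(se[1])},
        cov_beta=cov,
        Vr_final=Vr,
        n_iter=it,
        converged=converged,
        R2=np.nan,
        sigma2_hat=sigma2,
        macro_sigma2=0.0,
        n_e=n_e,
        v_y=a / n_e if a > 0 else 0.0,
        v_x=v_x,
        v_lnx=v_lnx,
        root_y=m_y,
        root_x=m_x,
        tip_labels=list(labels),
        Y=Y,
        D=D,
        x_analysis=xc,
        x_raw=x,
        trace=trace,
        extra_beta=None if extra_cols is None else np.asarray(
            beta[2:], dtype=float),
        options={"tol": tol, "max_iter": max_iter},
    )
    fit.R2 = fit_r_squared(Y=Y, D=D, beta=beta, Vr=Vr)
    return fit


def _m3_V(T, a_w, b, x, macro_sigma2, V_macro, meas_var, floor):
    """Weighting covariance for Model 3 with the micro variance floored."""
    micro = np.maximum(a_w + b * x, floor)
    Vmac = macro_sigma2 * T if V_macro is None else V_macro
    V = Vmac + np.diag(micro)
    Vmac_eff = Vmac.copy()
    if meas_var is not None:
        V = V + np.diag(meas_var)
        # measurement noise leaks into the deviation exactly as
        # macroevolution does, so it joins the offset's covariance
        Vmac_eff = Vmac_eff + np.diag(meas_var)
    return V, Vmac_eff


def _fit_m3(T, y, x, labels, se_y, obs_var, tol, max_iter,
            macro_sigma2, V_macro, extra_cols):
    n = T.shape[0]
    meas_var = None if se_y is None else np.asarray(se_y, float) ** 2
    if macro_sigma2 is None and V_macro is None:
        macro_sigma2, resid_var, mu_y = estimate_macro_sigma2(T, y)
        a0 = max(resid_var, 1e-4 * np.var(y))
    else:
        if macro_sigma2 is None:
            macro_sigma2 = 0.0
        a0 = max(float(np.var(y)) - macro_sigma2, 1e-4 * np.var(y))
        # grand mean = GLS mean under the working covariance, consistent
        # with how the mixed-model branch estimates it
        Vmac0 = macro_sigma2 * T if V_macro is None else V_macro
        L0, _ = chol_with_jitter(Vmac0 + a0 * np.eye(n))
        w0 = chol_solve(L0, np.ones(n))
        mu_y = float(w0 @ y) / float(w0 @ np.ones(n))

    x_bar = float(np.mean(x))
    a, b = a0, 0.0
    floor = _a_floor((y - mu_y) ** 2)
    trace = [(a, b)]
    converged = False
    cov = None
    for it in range(1, max_iter + 1):
        a_w = max(a, floor)
        V, Vmac_eff = _m3_V(T, a_w, b, x, macro_sigma2, V_macro,
                            meas_var, floor)
        dec = rm.m3_predict(V, y, ybar=mu_y)
        dm, offset = rm.m3_design(V, x, Vmac_eff)
        D = _append_extra(dm.D, extra_cols)
        Y = dec.dev ** 2 - offset
        Vr = 2.0 * dec.dev_var * dec.dev_var
        if obs_var is not None:
            Vr = Vr + np.diag(obs_var)
        beta, cov = gls_solve(D, Y, Vr)
        # the slope column is built from mean-centered x, and the Hadamard
        # square of the deviation operator has row sums equal to the
        # intercept regressor, so the intercept coefficient estimates the
        # micro variance at the mean predictor: beta0 = a + b*xbar
        b_new = float(beta[1])
        a_new = float(beta[0]) - b_new * x_bar
        step = np.hypot(a_new - a, b_new - b)
        scale = max(np.hypot(a, b), 1e-12)
        a, b = a_new, b_new
        trace.append((a, b))
        if step < tol * scale:
            converged = True
            break

    rm.check_rates_nonnegative(a, b, x - np.mean(x), labels)
    se = np.sqrt(np.diag(cov))
    fit = GLSFit(
        model="M3",
        a_hat=a,
        b_hat=b,
        beta_hat={"A_hat": float(beta[0]), "b_hat": b},
        se={"A_hat": float(se[0]), "b_hat": float(se[1])},
        cov_beta=cov,
        Vr_final=Vr,
        n_iter=it,
        converged=converged,
        R2=np.nan,
        sigma2_hat=0.0,
        macro_sigma2=float(macro_sigma2),
        n_e=float(n),
        v_y=0.0,
        v_x=0.0,
        v_lnx=0.0,
        root_y=mu_y,
        root_x=float(np.mean(x)),
        tip_labels=list(labels),
        Y=Y,
        D=D,
        x_analysis=x - np.mean(x),
        x_raw=x,
        trace=trace,
        extra_beta=None if extra_cols is None else np.asarray(
            beta[2:], dtype=float),
        options={"tol": tol, "max_iter": max_iter},
    )
    fit.R2 = fit_r_squared(Y=Y, D=D, beta=beta, Vr=Vr)
    return fit
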