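"""Parametric bootstrap for fitted rate models.

Each replicate re-simulates tip data under the fitted model at the point
estimates (both predictor and response evolve for Models 1 and 2; for
Model 3 the predictor is fixed at its observed values, matching its
fixed-x residual theory), refits with the same options, and collects the
(a, b) estimates.  The spread of the draws gives distribution-free standard
errors and percentile intervals — the recommended route to uncertainty
here, since the analytic GLS standard errors assume more about the residual
distribution than these squared responses can deliver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .gls_engine import GLSFit, fit_rate_model
from .simulator import simulate_m1, simulate_m2, simulate_m3
from .treeio import Phylogeny


@dataclass
class BootstrapResult:
    """Draws of (a_hat, b_hat) over bootstrap replicates with summaries.

    ``draws`` has one row per converged replicate; ``n_failed`` counts
    replicates dropped for non-convergence (they are never imputed).
    """

    draws: pd.DataFrame
    se_boot: dict
    ci: dict
    ci_level: float
    n_failed: int
    seed: int
    point: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "point": self.point,
            "mean": {c: float(self.draws[c].mean()) for c in self.draws},
            "se_boot": self.se_boot,
            "ci_level": self.ci_level,
            "ci": self.ci,
            "n_reps": int(len(self.draws)),
            "n_failed": self.n_failed,
            "seed": self.seed,
        }


def _rep_seed(seed: int, rep: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(rep,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def bootstrap_fit(
    fit: GLSFit,
    tree: Phylogeny,
    n_reps: int,
    seed: int,
    ci_level: float = 0.95,
    n_steps: int = 1000,
    require_converged: bool = True,
) -> BootstrapResult:
    """Parametric bootstrap of a fitted rate model.

    Simulation parameters are taken from ``fit`` (a clamped at 0 if the
    point estimate is negative, since the generative models need a
    nonnegative baseline rate).  Reproducible given ``seed``: replicate r
    uses a child seed derived from ``(seed, r)``.
    """
    if n_reps < 2:
        raise ValidationError("need at least 2 bootstrap replicates")
    if require_converged and not fit.converged:
        raise ValidationError("refusing to bootstrap a non-converged fit")
    if tree.n_tips != len(fit.tip_labels):
        raise ValidationError(
            f"tree has {tree.n_tips} tips but the fit used "
            f"{len(fit.tip_labels)}"
        )
    a = max(fit.a_hat, 0.0)
    b = fit.b_hat
    rows = []
    n_failed = 0
    for rep in range(n_reps):
        rs = _rep_seed(seed, rep)
        if fit.model == "M1":
            sim = simulate_m1(tree, a, b, fit.sigma2_hat, seed=rs,
                              n_steps=n_steps)
        elif fit.model == "M2":
            sim = simulate_m2(tree, a, b, fit.sigma2_hat, seed=rs,
                              n_steps=n_steps)
        else:
            sim = simulate_m3(tree, fit.macro_sigma2, a, b, seed=rs,
                              x=fit.x_raw)
        try:
            refit = fit_rate_model(
                tree, sim.y_tips, sim.x_tips, fit.model,
                tol=fit.options.get("tol", 1e-6),
                max_iter=fit.options.get("max_iter", 50),
                macro_sigma2=fit.macro_sigma2 if fit.model == "M3" else None,
            )
        except Exception:
            n_failed += 1
            continue
        if not refit.converged:
            n_failed += 1
            continue
        rows.append({"a_hat": refit.a_hat, "b_hat": refit.b_hat})
    if not rows:
        raise ValidationError("all bootstrap replicates failed")
    draws = pd.DataFrame(rows)
    alpha = (1.0 - ci_level) / 2.0
    ci = {
        c: [float(draws[c].quantile(alpha)),
            float(draws[c].quantile(1.0 - alpha))]
        for c in draws
    }
    se_boot = {c: float(draws[c].std(ddof=1)) for c in draws}
    return BootstrapResult(
        draws=draws,
        se_boot=se_boot,
        ci=ci,
        ci_level=ci_level,
        n_failed=n_failed,
        seed=seed,
        point={"a_hat": fit.a_hat, "b_hat": fit.b_hat},
    )
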