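"""Simulators for the three generative rate models, plus a fixture-tree
generator.

Models 1 and 2 are coupled diffusions: the predictor x advances by exact
Gaussian increments (Brownian motion, or Brownian motion of ln x for the
geometric model), while the response y advances by Euler-Maruyama with the
state-dependent rate variance ``max(a + b*x, 0)`` per step.  The clamp at
zero is counted and reported, since the linear-rate model is only an
approximation wherever ``a + b*x`` goes negative.  Model 3 is Gaussian and
is drawn exactly: a multivariate-normal macroevolutionary component with
covariance ``macro_sigma2 * T`` plus independent per-species
microevolutionary noise with variance ``a + b*x_i``.

Randomness: every branch consumes its own substream derived
deterministically from ``(seed, node_index)``, so tip values do not depend
on traversal order, and simulations are reproducible bit-for-bit given
``(seed, params, tree, n_steps)``.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .errors import NegativeRateError, ValidationError
from .treeio import Phylogeny, _from_dendropy, scale_to_unit_height, \
    shared_branch_matrix, chol_with_jitter

DEFAULT_N_STEPS = 1000


@dataclass
class SimResult:
    """Simulated tip data.

    ``x_tips`` and ``y_tips`` are aligned to the tree's canonical tip order;
    shape ``(n_tips,)`` for a single replicate or ``(n_reps, n_tips)`` when
    ``n_reps > 1``.  ``n_clamped`` counts Euler steps at which the rate
    ``a + b*x`` had to be clamped at zero.
    """

    x_tips: np.ndarray
    y_tips: np.ndarray
    model: str
    params: dict
    seed: int
    n_steps: int | None = None
    n_clamped: int = 0
    tip_labels: list = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        if self.y_tips.ndim != 1:
            raise ValidationError(
                "to_frame supports single-replicate results only"
            )
        return pd.DataFrame(
            {"species": self.tip_labels, "x": self.x_tips, "y": self.y_tips}
        )


def _branch_rng(seed: int, node_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(node_index,))
    )


def _check_unit_height(tree: Phylogeny):
    if abs(tree.height - 1.0) > 1e-6:
        raise ValidationError(
            "simulators expect a tree scaled to unit height; "
            "use scale_to_unit_height first"
        )


def _simulate_diffusion(tree, a, b, sigma2, seed, n_steps, n_reps,
                        geometric):
    """Shared Euler machinery for Models 1 and 2.

    The state carried down the tree is (u, y) where u = x for Model 1 and
    u = ln x for Model 2 (driftless, because the geometric model's
    0.5*sigma2*x dt drift exactly cancels the Ito correction of the
    logarithm).
    """
    _check_unit_height(tree)
    if a < 0 or sigma2 < 0:
        raise ValidationError("a and sigma2 must be nonnegative")
    if n_steps < 100:
        raise ValidationError("n_steps must be >= 100 per unit tree height")
    sigma = np.sqrt(sigma2)
    n_clamped = 0
    # per-node states, each an array over replicates
    u_state = {0: np.zeros(n_reps)}
    y_state = {0: np.zeros(n_reps)}
    # preorder indexing guarantees parent[k] < k
    for k in range(1, tree.n_nodes):
        par = tree.parent[k]
        u = u_state[par].copy()
        yv = y_state[par].copy()
        bl = tree.edge_length[k]
        m = max(1, int(np.ceil(n_steps * bl)))
        dt = bl / m
        sdt = np.sqrt(dt)
        rng = _branch_rng(seed, int(k))
        for _ in range(m):
            xval = np.exp(u) if geometric else u
            rate = a + b * xval
            neg = rate < 0
            if np.any(neg):
                n_clamped += int(np.count_nonzero(neg))
                rate = np.maximum(rate, 0.0)
            yv = yv + np.sqrt(rate) * sdt * rng.standard_normal(n_reps)
            u = u + sigma * sdt * rng.standard_normal(n_reps)
        u_state[k] = u
        y_state[k] = yv
    x_tips = np.empty((n_reps, tree.n_tips))
    y_tips = np.empty((n_reps, tree.n_tips))
    for i, nd in enumerate(tree.tip_node):
        u = u_state[int(nd)]
        x_tips[:, i] = np.exp(u) if geometric else u
        y_tips[:, i] = y_state[int(nd)]
    if n_reps == 1:
        x_tips, y_tips = x_tips[0], y_tips[0]
    return x_tips, y_tips, n_clamped


def simulate_m1(
    tree: Phylogeny,
    a: float,
    b: float,
    sigma2: float,
    seed: int,
    n_steps: int = DEFAULT_N_STEPS,
    n_reps: int = 1,
) -> SimResult:
    """Simulate Model 1: ``dy = sqrt(a + b x) dW1``, ``dx = sigma dW2``.

    Initial conditions are ``y0 = x0 = 0`` at the root.  With ``b = 0`` the
    tips of y are exactly Brownian with covariance ``a * T``.
    """
    x, y, nc = _simulate_diffusion(
        tree, a, b, sigma2, seed, n_steps, n_reps, geometric=False
    )
    return SimResult(
        x_tips=x, y_tips=y, model="M1",
        params={"a": a, "b": b, "sigma2": sigma2},
        seed=seed, n_steps=n_steps, n_clamped=nc,
        tip_labels=list(tree.tip_labels),
    )


def simulate_m2(
    tree: Phylogeny,
    a: float,
    b: float,
    sigma2: float,
    seed: int,
    n_steps: int = DEFAULT_N_STEPS,
    n_reps: int = 1,
) -> SimResult:
    """Simulate Model 2: geometric Brownian predictor, ``x0 = 1``.

    ``dx = (1/2) sigma2 x dt + sigma x dW2`` is simulated exactly as
    driftless Brownian motion of ln x; y advances by Euler with rate
    ``max(a + b x, 0)``.
    """
    x, y, nc = _simulate_diffusion(
        tree, a, b, sigma2, seed, n_steps, n_reps, geometric=True
    )
    return SimResult(
        x_tips=x, y_tips=y, model="M2",
        params={"a": a, "b": b, "sigma2": sigma2},
        seed=seed, n_steps=n_steps, n_clamped=nc,
        tip_labels=list(tree.tip_labels),
    )


def simulate_m3(
    tree: Phylogeny,
    macro_sigma2: float,
    a: float,
    b: float,
    seed: int,
    x: np.ndarray | None = None,
    sigma2_x: float = 1.0,
    n_reps: int = 1,
) -> SimResult:
    """Simulate Model 3 exactly (no discretization).

    ``y = y_macro + y_micro`` with ``y_macro ~ N(0, macro_sigma2 * T)`` and
    independent ``y_micro,i ~ N(0, a + b x_i)``.  The predictor may be
    supplied (it is then treated as fixed across replicates) or is itself
    drawn as Brownian motion with rate ``sigma2_x`` on the tree.
    """
    _check_unit_height(tree)
    if macro_sigma2 < 0 or a < 0:
        raise ValidationError("variances must be nonnegative")
    n = tree.n_tips
    T = shared_branch_matrix(tree).T
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    if x is None:
        Lx, _ = chol_with_jitter(sigma2_x * T + 1e-12 * np.eye(n))
        x_tips = (Lx @ rng.standard_normal((n, n_reps))).T
    else:
        x = np.asarray(x, dtype=float)
        if x.shape[0] != n:
            raise ValidationError("x length must equal tip count")
        x_tips = np.tile(x, (n_reps, 1))
    micro = a + b * x_tips
    if np.any(micro < 0):
        raise NegativeRateError(
            "a + b*x is negative for some species; Model 3 requires a "
            "nonnegative microevolutionary variance"
        )
    if macro_sigma2 > 0:
        Lm, _ = chol_with_jitter(macro_sigma2 * T + 1e-12 * np.eye(n))
        y_macro = (Lm @ rng.standard_normal((n, n_reps))).T
    else:
        y_macro = np.zeros((n_reps, n))
    y_tips = y_macro + np.sqrt(micro) * rng.standard_normal((n_reps, n))
    if n_reps == 1:
        x_tips, y_tips = x_tips[0], y_tips[0]
    return SimResult(
        x_tips=x_tips, y_tips=y_tips, model="M3",
        params={"macro_sigma2": macro_sigma2, "a": a, "b": b,
                "sigma2_x": sigma2_x, "x_fixed": x is not None},
        seed=seed, n_steps=None,
        tip_labels=list(tree.tip_labels),
    )


def simulate(tree, model, seed, **params) -> SimResult:
    """Dispatch to the simulator for ``model`` in {"M1", "M2", "M3"}."""
    if model == "M1":
        return simulate_m1(tree, seed=seed, **params)
    if model == "M2":
        return simulate_m2(tree, seed=seed, **params)
    if model == "M3":
        return simulate_m3(tree, seed=seed, **params)
    raise ValidationError(f"unknown model {model!r}")


def make_fixture_tree(n_tips: int, seed: int) -> Phylogeny:
    """Random Kingman-coalescent ultrametric tree scaled to unit height.

    Deterministic given ``seed``; tips are labeled ``t1..tn``.  Useful as a
    neutral, reproducible phylogeny for simulation studies and tests.
    """
    if n_tips < 2:
        raise ValidationError("need at least 2 tips")
    taxa = dendropy.TaxonNamespace(
        [f"t{i + 1}" for i in range(n_tips)]
    )
    dtree = treesim.pure_kingman_tree(
        taxon_namespace=taxa, pop_size=1,
        rng=_pyrandom.Random(int(seed)),
    )
    tree = _from_dendropy(dtree)
    return scale_to_unit_height(tree)
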