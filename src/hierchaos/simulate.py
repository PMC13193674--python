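"""Iterate the network map and measure order parameters from trajectories.

The dynamics is the discrete-time rate model ``x(t+1) = phi(J x(t))`` with an
odd saturating activation.  Hierarchy-resolved statistics come from nested
averages: the level-``j`` mean activity is the average of ``x`` over all
indices below level ``j``, and the order parameter ``q_j(t)`` is the variance
(mean square) of those level-``j`` means.  In the two-level case ``q_1 = q_m``
(macroscopic variance of population means) and ``q_2 = q`` (total variance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, HierarchySpec
from .gaussian import ERF, ActivationModel, QuadratureRule, expect_affine

__all__ = [
    "Trajectory",
    "OrderParameterSeries",
    "initial_state",
    "step",
    "run",
    "level_means",
    "order_parameters",
    "effective_macroscopic_run",
]


@dataclass
class Trajectory:
    """Post-burn-in time series of all ``N`` activities.

    ``states`` has shape ``(T - burn_in, N)``; row ``t`` is the state at time
    ``burn_in + 1 + t`` (the initial condition itself is not stored).
    """

    states: np.ndarray
    burn_in: int
    spec: HierarchySpec | None = None
    seed: int | None = None
    x0: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_steps(self) -> int:
        return self.states.shape[0]

    @property
    def n_units(self) -> int:
        return self.states.shape[1]


@dataclass
class OrderParameterSeries:
    """Per-time-step hierarchy of order parameters ``q_1(t) <= ... <= q_L(t)``."""

    values: np.ndarray  # (T, L)
    spec: HierarchySpec | None = None

    @property
    def levels(self) -> int:
        return self.values.shape[1]

    @property
    def qm(self) -> np.ndarray:
        """Two-level convenience: macroscopic variance ``q_m(t) = q_1(t)``."""
        return self.values[:, 0]

    @property
    def q(self) -> np.ndarray:
        """Total variance ``q(t) = q_L(t)``."""
        return self.values[:, -1]

    def summary(self) -> np.ndarray:
        """Steady-state estimate: time average over the retained window."""
        return self.values.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"q_{j}" for j in range(1, self.levels + 1)]
        return pd.DataFrame(self.values, columns=cols)


def initial_state(n: int, seed: int) -> np.ndarray:
    """Generic initial condition: i.i.d. uniform(-0.5, 0.5) entries."""
    return np.random.default_rng(seed).uniform(-0.5, 0.5, size=n)


def step(Jm: ConnectivityMatrix | np.ndarray, x: np.ndarray, act: ActivationModel = ERF) -> np.ndarray:
    """One application of the map ``x -> phi(J x)``."""
    W = Jm.weights if isinstance(Jm, ConnectivityMatrix) else np.asarray(Jm)
    x = np.asarray(x, dtype=float)
    if x.shape != (W.shape[0],):
        raise ValueError(f"state has shape {x.shape}, expected ({W.shape[0]},)")
    return act.phi(W @ x)


def run(
    Jm: ConnectivityMatrix,
    x0: np.ndarray | None = None,
    T: int = 1000,
    burn_in: int = 0,
    act: ActivationModel = ERF,
    seed: int = 0,
) -> Trajectory:
    """Iterate the map for ``T`` steps, discarding the first ``burn_in``.

    Deterministic given ``(Jm, x0)``; when ``x0`` is omitted it is drawn
    uniformly from ``(-0.5, 0.5)^N`` with the given seed.
    """
    if T <= burn_in or burn_in < 0:
        raise ValueError("need T > burn_in >= 0")
    N = Jm.n_units
    if x0 is None:
        x0 = initial_state(N, seed)
    x = np.asarray(x0, dtype=float)
    W = Jm.weights
    kept = np.empty((T - burn_in, N))
    for t in range(T):
        x = act.phi(W @ x)
        if t >= burn_in:
            kept[t - burn_in] = x
    return Trajectory(states=kept, burn_in=burn_in, spec=Jm.spec, seed=seed, x0=np.asarray(x0))


def level_means(x: np.ndarray, spec: HierarchySpec, j: int) -> np.ndarray:
    """Average activity over all indices below level ``j``.

    Returns the ``N_j`` level-``j`` means; ``j = L`` returns ``x`` itself.
    """
    if not 1 <= j <= spec.levels:
        raise ValueError(f"level must be in 1..{spec.levels}")
    x = np.asarray(x, dtype=float)
    shaped = x.reshape(spec.sizes)
    if j < spec.levels:
        shaped = shaped.mean(axis=tuple(range(j, spec.levels)))
    return shaped.reshape(-1)


def order_parameters(traj: Trajectory) -> OrderParameterSeries:
    """Hierarchy of order parameters ``q_j(t) = (1/N_j) sum (level-j means)^2``.

    The nesting ``q_1(t) <= ... <= q_L(t)`` holds exactly at every step: each
    coarser mean square is a variance decomposition of the finer one.
    """
    if traj.spec is None:
        raise ValueError("trajectory carries no hierarchy spec")
    spec = traj.spec
    T = traj.n_steps
    if T < 1:
        raise ValueError("trajectory is empty")
    L = spec.levels
    out = np.empty((T, L))
    shaped = traj.states.reshape((T,) + spec.sizes)
    # average from the finest level inward; q_j is the mean square of means
    current = shaped
    for j in range(L, 0, -1):
        flat = current.reshape(T, -1)
        out[:, j - 1] = np.mean(flat * flat, axis=1)
        if j > 1:
            current = current.mean(axis=j)
    return OrderParameterSeries(values=out, spec=spec)


def effective_macroscopic_run(
    mu_matrix: np.ndarray,
    q: float,
    sigma: float,
    T: int = 1000,
    burn_in: int = 0,
    x0: np.ndarray | None = None,
    act: ActivationModel = ERF,
    rule: QuadratureRule | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Iterate the closed ``P``-dimensional map for the population means.

    In the large-``n`` limit the means obey
    ``m(t+1) = phi_a(g(a) mu m(t))`` with ``a = sigma sqrt(q)``, i.e. each
    population applies the activation smeared by the microscopic fluctuations
    it averages over:  ``m_a(t+1) = int Dz phi(sum_b mu_ab m_b(t) + a z)``.
    Pass the realized mean-coupling matrix (``ConnectivityMatrix.mu_matrix``)
    to compare against the corresponding full network.
    """
    if q < 0:
        raise ValueError("q must be nonnegative")
    mu = np.asarray(mu_matrix, dtype=float)
    P = mu.shape[0]
    if x0 is None:
        x0 = initial_state(P, seed)
    a = sigma * np.sqrt(q)
    m = np.asarray(x0, dtype=float)
    kept = np.empty((T - burn_in, P))
    for t in range(T):
        m = np.asarray(expect_affine(act.phi, mu @ m, a, rule))
        if t >= burn_in:
            kept[t - burn_in] = m
    return kept
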