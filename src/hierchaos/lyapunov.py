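"""Lyapunov spectra, attractor dimensions, and theoretical expansion rates.

Numerical diagnostics (QR/Benettin spectra, two-replica maximal exponent,
participation-ratio dimension) work on any realized network; the theoretical
rates evaluate the mean-field one-step expansion of a perturbation within
each hierarchy subspace.  For the two-level network the squared perturbation
amplitudes in the macroscopic (block-constant) and microscopic (zero
block-mean) subspaces evolve by the lower-triangular matrix

    ``D = [[R_coherent^2, 0], [C, R_random^2]]``,

with ``C = (sigma_mu^2/sigma^2 + 1) R_random^2 - R_coherent^2 >= 0``: a
macroscopic kick feeds the microscopic residuals, but a microscopic kick
averages away before it can move any population mean.  The maximal Lyapunov
exponent is ``max(ln R_coherent, ln R_random)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .connectivity import ConnectivityMatrix
from .gaussian import ERF, ActivationModel, QuadratureRule, _base_rule
from .mean_field import _double_expect_sq
from .simulate import Trajectory, initial_state

__all__ = [
    "StabilityReport",
    "SpectrumReport",
    "jacobian",
    "tangent_apply",
    "lyapunov_spectrum",
    "mle_direct",
    "theory_rates",
    "multilevel_rates",
    "ky_dimension",
    "pr_dimension",
    "subspace_mle",
]


@dataclass
class StabilityReport:
    """Theoretical per-subspace expansion rates at a mean-field fixed point.

    ``rates_sq`` holds ``R_1^2 .. R_L^2`` (two-level: coherent then random);
    ``lambdas`` are ``(1/2) ln R^2``.  ``D`` and ``C`` are populated only for
    the two-level network.
    """

    rates_sq: np.ndarray
    lambdas: np.ndarray
    lambda_max: float
    D: np.ndarray | None = None
    C: float | None = None

    @property
    def rate_sq_coherent(self) -> float:
        return float(self.rates_sq[0])

    @property
    def rate_sq_random(self) -> float:
        return float(self.rates_sq[-1])

    @property
    def lambda_coherent(self) -> float:
        return float(self.lambdas[0])

    @property
    def lambda_random(self) -> float:
        return float(self.lambdas[-1])


@dataclass
class SpectrumReport:
    """Leading Lyapunov exponents estimated by QR re-orthonormalization."""

    exponents: np.ndarray  # sorted descending
    n_steps: int
    burn_in: int
    n_units: int


def jacobian(Jm: ConnectivityMatrix | np.ndarray, x: np.ndarray, act: ActivationModel = ERF) -> np.ndarray:
    """Jacobian of the map at state ``x``: ``diag(phi'(J x)) J``."""
    W = Jm.weights if isinstance(Jm, ConnectivityMatrix) else np.asarray(Jm)
    x = np.asarray(x, dtype=float)
    if x.shape != (W.shape[0],):
        raise ValueError(f"state has shape {x.shape}, expected ({W.shape[0]},)")
    return act.phi_prime(W @ x)[:, None] * W


def tangent_apply(W: np.ndarray, x: np.ndarray, V: np.ndarray, act: ActivationModel = ERF) -> np.ndarray:
    """Apply the Jacobian at ``x`` to tangent vectors ``V`` without forming it."""
    return act.phi_prime(W @ x)[:, None] * (W @ V)


def lyapunov_spectrum(
    Jm: ConnectivityMatrix,
    x0: np.ndarray | None = None,
    k: int | None = None,
    T: int = 1000,
    burn_in: int = 200,
    act: ActivationModel = ERF,
    seed: int = 0,
) -> SpectrumReport:
    """Leading ``k`` Lyapunov exponents by the QR (Benettin) method.

    Tangent vectors are re-orthonormalized at every step (the map's one-step
    expansion rates are O(1), so no renormalization interval is needed) and
    the exponents are time averages of ``ln |diag R|`` over the post-burn-in
    window.
    """
    N = Jm.n_units
    if k is None:
        k = N
    if not 1 <= k <= N:
        raise ValueError("need 1 <= k <= N")
    if T <= burn_in:
        raise ValueError("need T > burn_in")
    W = Jm.weights
    rng = np.random.default_rng(seed)
    x = initial_state(N, seed) if x0 is None else np.asarray(x0, dtype=float)
    Q = np.linalg.qr(rng.standard_normal((N, k)))[0]
    sums = np.zeros(k)
    steps = 0
    for t in range(T):
        V = tangent_apply(W, x, Q, act)
        x = act.phi(W @ x)
        Q, R = np.linalg.qr(V)
        diag = np.abs(np.diag(R))
        if np.any(diag == 0.0):
            raise FloatingPointError(
                "tangent volume underflow; re-orthonormalization interval too long"
            )
        if t >= burn_in:
            sums += np.log(diag)
            steps += 1
    exps = np.sort(sums / steps)[::-1]
    return SpectrumReport(exponents=exps, n_steps=steps, burn_in=burn_in, n_units=N)


def mle_direct(
    Jm: ConnectivityMatrix,
    x0: np.ndarray | None = None,
    T: int = 1000,
    burn_in: int = 200,
    eps0: float = 1e-7,
    act: ActivationModel = ERF,
    seed: int = 0,
) -> float:
    """Maximal Lyapunov exponent from two co-evolved replicas.

    A perturbation of norm ``eps0`` rides along the reference trajectory and
    is renormalized to ``eps0`` after every step; the exponent is the average
    log growth rate over the post-burn-in window.
    """
    if eps0 <= 0:
        raise ValueError("eps0 must be positive")
    N = Jm.n_units
    W = Jm.weights
    rng = np.random.default_rng(seed)
    x = initial_state(N, seed) if x0 is None else np.asarray(x0, dtype=float)
    u = rng.standard_normal(N)
    y = x + eps0 * u / np.linalg.norm(u)
    total = 0.0
    steps = 0
    for t in range(T):
        x = act.phi(W @ x)
        y = act.phi(W @ y)
        delta = y - x
        growth = np.linalg.norm(delta) / eps0
        if t >= burn_in:
            total += np.log(growth)
            steps += 1
        y = x + delta / growth
    return total / steps


def multilevel_rates(
    qs,
    sigmas,
    act: ActivationModel = ERF,
    rule: QuadratureRule | None = None,
) -> StabilityReport:
    """Per-level squared expansion rates at a multilevel fixed point:

    ``R_j^2 = sigma_j^2 int Dzt [ int Dz phi'(sqrt(A_j) zt + sqrt(A_L-A_j) z) ]^2``.
    """
    qs = np.asarray(qs, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    if qs.shape != sigmas.shape:
        raise ValueError("qs and sigmas must have equal length")
    if np.any(qs < -1e-12) or np.any(np.diff(qs) < -1e-12):
        raise ValueError("order parameters must be nonnegative and nondecreasing")
    rule = _base_rule(rule)
    A = np.cumsum(sigmas**2 * np.clip(qs, 0.0, None))
    AL = A[-1]
    rates = np.empty_like(qs)
    for j in range(len(qs)):
        b = np.sqrt(A[j])
        a = np.sqrt(max(AL - A[j], 0.0))
        rates[j] = sigmas[j] ** 2 * _double_expect_sq(act.phi_prime, b, a, rule)
    with np.errstate(divide="ignore"):
        lambdas = 0.5 * np.log(rates)
    return StabilityReport(rates_sq=rates, lambdas=lambdas, lambda_max=float(np.max(lambdas)))


def theory_rates(
    sigma: float,
    sigma_mu: float,
    q: float,
    qm: float,
    act: ActivationModel = ERF,
    rule: QuadratureRule | None = None,
) -> StabilityReport:
    """Two-level expansion rates, perturbation-propagation matrix, and MLE.

    Evaluates ``R_coherent^2`` and ``R_random^2`` at the fixed point
    ``(q, qm)`` and assembles the lower-triangular ``D`` with off-diagonal
    ``C = (sigma_mu^2/sigma^2 + 1) R_random^2 - R_coherent^2`` (undefined for
    ``sigma = 0``).
    """
    if qm > q + 1e-12:
        raise ValueError("q_m cannot exceed q")
    report = multilevel_rates([qm, q], [sigma_mu, sigma], act, rule)
    rc2, rr2 = report.rates_sq
    C = None
    if sigma > 0:
        C = float((sigma_mu**2 / sigma**2 + 1.0) * rr2 - rc2)
    D = np.array([[rc2, 0.0], [C if C is not None else np.nan, rr2]])
    report.D = D
    report.C = C
    return report


def ky_dimension(exponents) -> float:
    """Kaplan-Yorke dimension from a descending Lyapunov spectrum.

    The largest ``j`` with nonnegative partial sum ``S_j``, plus the linear
    interpolation ``S_j / |lambda_{j+1}|``; zero when even the leading
    exponent is negative.
    """
    lam = np.asarray(exponents, dtype=float)
    if np.any(np.diff(lam) > 1e-12):
        raise ValueError("exponents must be sorted in descending order")
    if lam[0] < 0:
        return 0.0
    S = np.cumsum(lam)
    nonneg = np.nonzero(S >= 0)[0]
    j = int(nonneg[-1]) + 1  # 1-based count of exponents in the sum
    if j == len(lam):
        warnings.warn(
            "all partial sums are nonnegative; KY dimension is truncated at "
            "the number of computed exponents", RuntimeWarning, stacklevel=2,
        )
        return float(j)
    return float(j + S[j - 1] / abs(lam[j]))


def pr_dimension(traj: Trajectory | np.ndarray) -> float:
    """Participation-ratio dimension of steady-state activity.

    ``(sum nu)^2 / sum nu^2`` over the eigenvalues ``nu`` of the
    time-sampled, per-neuron mean-subtracted activity covariance.  Counts the
    number of effectively occupied directions: ``N`` for isotropic activity,
    1 for a single dominant mode.
    """
    X = traj.states if isinstance(traj, Trajectory) else np.asarray(traj, dtype=float)
    T, N = X.shape
    if T < 10 * N:
        warnings.warn(
            f"covariance window ({T} samples for {N} units) is short; "
            "PR estimate may be biased", RuntimeWarning, stacklevel=2,
        )
    Xc = X - X.mean(axis=0)
    # eigenvalues of the covariance via the smaller Gram matrix
    if T < N:
        G = (Xc @ Xc.T) / T
    else:
        G = (Xc.T @ Xc) / T
    nu = np.linalg.eigvalsh(G)
    nu = np.clip(nu, 0.0, None)
    total = nu.sum()
    if total <= 0.0:
        warnings.warn("zero-variance trajectory; PR dimension set to 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    return float(total**2 / np.sum(nu**2))


def _macro_project(v: np.ndarray, P: int, n: int) -> np.ndarray:
    """Project onto the P-dimensional block-constant subspace."""
    means = v.reshape(P, n).mean(axis=1)
    return np.repeat(means, n)


def subspace_mle(
    Jm: ConnectivityMatrix,
    x0: np.ndarray | None = None,
    T: int = 1000,
    burn_in: int = 200,
    act: ActivationModel = ERF,
    seed: int = 0,
) -> tuple[float, float]:
    """Simulated growth rates of macroscopic and microscopic perturbations.

    Two tangent vectors co-evolve with the trajectory; after every Jacobian
    application each is re-projected onto its subspace — block-constant
    (macroscopic, dimension ``P``) or zero block-mean (microscopic, dimension
    ``N - P``) — and renormalized.  Returns ``(lambda_macro, lambda_micro)``.
    """
    if Jm.spec.levels != 2:
        raise ValueError("subspace decomposition requires a two-level spec")
    P, n = Jm.spec.sizes
    N = Jm.n_units
    W = Jm.weights
    rng = np.random.default_rng(seed)
    x = initial_state(N, seed) if x0 is None else np.asarray(x0, dtype=float)

    u_mac = _macro_project(rng.standard_normal(N), P, n)
    u_mic = rng.standard_normal(N)
    u_mic -= _macro_project(u_mic, P, n)
    u_mac /= np.linalg.norm(u_mac)
    u_mic /= np.linalg.norm(u_mic)

    tot_mac = tot_mic = 0.0
    steps = 0
    for t in range(T):
        V = tangent_apply(W, x, np.column_stack([u_mac, u_mic]), act)
        x = act.phi(W @ x)
        w_mac = _macro_project(V[:, 0], P, n)
        w_mic = V[:, 1] - _macro_project(V[:, 1], P, n)
        g_mac = np.linalg.norm(w_mac)
        g_mic = np.linalg.norm(w_mic)
        if t >= burn_in:
            tot_mac += np.log(g_mac)
            tot_mic += np.log(g_mic)
            steps += 1
        u_mac = w_mac / g_mac
        u_mic = w_mic / g_mic
    return tot_mac / steps, tot_mic / steps
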