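"""Self-consistent mean-field theory of the modular and hierarchical network.

In the limit of many large populations the quenched-disorder average closes
the dynamics on the order parameters.  For the two-level network the update is

    ``q_m(t+1) = int Dzt [ int Dz phi(sigma_mu sqrt(q_m) zt + sigma sqrt(q) z) ]^2``
    ``q(t+1)   = int Dz  [ phi( sqrt(sigma_mu^2 q_m + sigma^2 q) z ) ]^2``

and for ``L`` levels, with cumulative field variances
``A_j = sum_{i<=j} sigma_i^2 q_i``,

    ``q_j(t+1) = int Dzt [ int Dz phi( sqrt(A_j) zt + sqrt(A_L - A_j) z ) ]^2``.

Fixed points of these maps label the dynamical phases.  For the erf
activation all Gaussian integrals evaluate in closed form, giving both an
explicit inverse design map (strengths realizing a prescribed admissible
profile ``0 = q_0 <= q_1 <= ... <= q_L < 1``) and closed-form per-level
expansion rates; the solvers here always work by quadrature so that the
closed forms remain an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gaussian import ERF, ActivationModel, QuadratureRule, _base_rule, g_factor

__all__ = [
    "MFTSolution",
    "two_level_step",
    "multilevel_step",
    "fixed_point",
    "multilevel_fixed_point",
    "quiescent_stable",
    "sigma_mu_star",
    "design_sigmas",
    "rate_sq_closed_form",
    "level_mle_closed_form",
]

#: numerical zero for deciding that a solved order parameter sits on the
#: incoherent branch (damped iteration leaves tiny residuals)
QM_ZERO_TOL = 1e-8


@dataclass
class MFTSolution:
    """Converged (or flagged) fixed point of the mean-field map.

    ``qs`` holds ``q_1..q_L``; for two-level solutions ``qm`` and ``q`` are
    aliases for the two components.  ``branch`` is the label of the solution
    actually found: ``quiescent`` (all zero), ``incoherent`` (coarsest level
    pinned to zero), or ``coherent``.
    """

    qs: np.ndarray
    sigmas: np.ndarray
    branch: str
    converged: bool
    iterations: int
    residual: float
    activation: str = "erf"

    @property
    def levels(self) -> int:
        return len(self.qs)

    @property
    def qm(self) -> float:
        return float(self.qs[0])

    @property
    def q(self) -> float:
        return float(self.qs[-1])

    def to_dict(self) -> dict:
        return {
            "qs": [float(v) for v in self.qs],
            "sigmas": [float(v) for v in self.sigmas],
            "branch": self.branch,
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
            "residual": float(self.residual),
            "activation": self.activation,
        }


class ConvergenceError(RuntimeError):
    """Raised when a solver is asked to guarantee convergence and cannot."""


def _double_expect_sq(
    f, b: float, a: float, rule: QuadratureRule
) -> float:
    """``int Dzt [ int Dz f(b zt + a z) ]^2`` with per-axis scale-adapted rules."""
    outer = rule.for_scale(abs(b))
    inner = rule.for_scale(abs(a))
    vals = f(b * outer.nodes[:, None] + a * inner.nodes[None, :]) @ inner.weights
    return float(outer.weights @ (vals * vals))


def multilevel_step(
    qs,
    sigmas,
    act: ActivationModel = ERF,
    rule: QuadratureRule | None = None,
) -> np.ndarray:
    """One synchronous update of the multilevel order parameters.

    Preserves ``0 <= q_1 <= ... <= q_L < 1`` for any admissible input.
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
    out = np.empty_like(qs)
    for j in range(len(qs)):
        b = np.sqrt(A[j])
        a = np.sqrt(max(AL - A[j], 0.0))
        out[j] = _double_expect_sq(act.phi, b, a, rule)
    return out


def two_level_step(
    qm: float,
    q: float,
    sigma: float,
    sigma_mu: float,
    act: ActivationModel = ERF,
    rule: QuadratureRule | None = None,
) -> tuple[float, float]:
    """One update of ``(q_m, q)`` for the two-level network."""
    if qm > q + 1e-12:
        raise ValueError("q_m cannot exceed q")
    nxt = multilevel_step([qm, q], [sigma_mu, sigma], act, rule)
    return float(nxt[0]), float(nxt[1])


def _damped_solve(step_fn, q0, tol, max_iter, damping):
    q = np.asarray(q0, dtype=float)
    residual = np.inf
    for it in range(1, max_iter + 1):
        nxt = step_fn(q)
        residual = float(np.max(np.abs(nxt - q)))
        q = (1.0 - damping) * nxt + damping * q
        if residual < tol:
            return q, True, it, residual
    return q, False, max_iter, residual


def multilevel_fixed_point(
    sigmas,
    act: ActivationModel = ERF,
    rule: QuadratureRule | None = None,
    tol: float = 1e-10,
    max_iter: int = 10000,
    damping: float = 0.5,
    q0=None,
) -> MFTSolution:
    """Damped iteration of the multilevel map to a fixed point.

    Starts from a generic coherent profile (``q_j = 0.9 j / L``) unless an
    explicit start is given.  Non-convergence is flagged in the result, not
    silently ignored.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    sigmas = np.asarray(sigmas, dtype=float)
    L = len(sigmas)
    if q0 is None:
        q0 = 0.9 * np.arange(1, L + 1) / L
    qs, ok, it, res = _damped_solve(
        lambda q: multilevel_step(q, sigmas, act, rule), q0, tol, max_iter, damping
    )
    if qs[-1] < 10 * tol:
        branch = "quiescent"
        qs = np.zeros_like(qs)
    elif qs[0] < QM_ZERO_TOL:
        branch = "incoherent"
    else:
        branch = "coherent"
    return MFTSolution(
        qs=qs, sigmas=sigmas, branch=branch, converged=ok,
        iterations=it, residual=res, activation=act.name,
    )


def _incoherent_q(
    sigma: float,
    act: ActivationModel,
    rule: QuadratureRule | None,
    tol: float = 1e-12,
    max_iter: int = 100000,
    damping: float = 0.5,
):
    """Scalar solve of ``q = int Dz phi(sigma sqrt(q) z)^2`` (incoherent branch)."""
    rule = _base_rule(rule)

    from scipy.optimize import brentq

    def one(q):
        a = sigma * np.sqrt(max(q, 0.0))
        r = rule.for_scale(abs(a))
        vals = act.phi(a * r.nodes)
        return float(r.weights @ (vals * vals))

    # the update is concave with slope sigma^2 at 0, so the active branch is
    # the unique sign change of one(q) - q; plain iteration stalls at the
    # critical point (algebraic decay), a bracketed root solve does not
    eps = 1e-10
    if one(eps) - eps <= 0.0:
        return 0.0, True, 1, 0.0
    root, info = brentq(
        lambda q: one(q) - q, eps, 1.0 - 1e-12, xtol=1e-15, full_output=True
    )
    res = abs(one(root) - root)
    return float(root), bool(info.converged) and res < tol, info.iterations, res


def fixed_point(
    sigma: float,
    sigma_mu: float,
    branch: str = "coherent",
    act: ActivationModel = ERF,
    rule: QuadratureRule | None = None,
    tol: float = 1e-10,
    max_iter: int = 10000,
    damping: float = 0.5,
) -> MFTSolution:
    """Solve the two-level fixed point on the requested branch.

    ``branch='coherent'`` starts from ``(q_m, q) = (0.45, 0.9)`` and lets the
    damped iteration settle wherever the stable fixed point lies (so the
    returned branch label may differ from the start, e.g. when the coherent
    start collapses onto ``q_m = 0``).  ``branch='incoherent'`` pins
    ``q_m = 0`` and iterates ``q`` alone; ``branch='quiescent'`` returns the
    trivial fixed point.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    sigmas = np.array([sigma_mu, sigma], dtype=float)
    if branch == "quiescent":
        return MFTSolution(
            qs=np.zeros(2), sigmas=sigmas, branch="quiescent",
            converged=True, iterations=0, residual=0.0, activation=act.name,
        )
    if branch == "incoherent":
        q, ok, it, res = _incoherent_q(sigma, act, rule, tol=tol, max_iter=max_iter,
                                       damping=damping)
        if q < 10 * tol:
            q, label = 0.0, "quiescent"
        else:
            label = "incoherent"
        return MFTSolution(
            qs=np.array([0.0, q]), sigmas=sigmas, branch=label,
            converged=ok, iterations=it, residual=res, activation=act.name,
        )
    if branch != "coherent":
        raise ValueError("branch must be one of quiescent/incoherent/coherent")
    return multilevel_fixed_point(
        sigmas, act, rule, tol=tol, max_iter=max_iter, damping=damping,
        q0=np.array([0.45, 0.9]),
    )


def quiescent_stable(sigma: float, sigma_mu: float) -> bool:
    """Linear stability of the quiescent state ``q = q_m = 0``.

    The linearized map is triangular with multipliers ``sigma_mu^2`` and
    ``sigma^2``, so the quiescent state is stable iff ``sigma < 1`` and
    ``sigma_mu < 1`` (strict; the marginal boundary is reported unstable).
    """
    return bool(sigma < 1.0 and sigma_mu < 1.0)


def sigma_mu_star(
    sigma: float,
    act: ActivationModel = ERF,
    rule: QuadratureRule | None = None,
) -> float:
    """Coherence onset ``sigma_mu* = 1 / g(sigma sqrt(q))``.

    ``q`` is the incoherent-branch fixed point at strength ``sigma``; for
    ``sigma <= 1`` that branch is quiescent (``q = 0``) and the onset sits at
    ``sigma_mu* = 1``.  Nondecreasing in ``sigma`` and always ``>= 1``.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    q, ok, _, res = _incoherent_q(sigma, act, rule)
    if not ok:
        raise ConvergenceError(
            f"incoherent-branch solve failed at sigma={sigma} (residual {res:.2e})"
        )
    if q < 1e-10:
        q = 0.0
    return 1.0 / g_factor(sigma * np.sqrt(q), act, rule)


# ---------------------------------------------------------------------------
# erf-activation closed forms
# ---------------------------------------------------------------------------

def design_sigmas(qs) -> np.ndarray:
    """Invert the steady state: strengths realizing an admissible profile.

    For the erf activation the fixed-point conditions solve exactly, giving

        ``sigma_j^2 = [2/(pi q_j)] [sin(pi q_j/2) - sin(pi q_{j-1}/2)]
                      / [1 - sin(pi q_L/2)]``

    for any admissible ``0 = q_0 <= q_1 <= ... <= q_L < 1``.  Levels with a
    zero gap get ``sigma_j = 0``.
    """
    qs = np.asarray(qs, dtype=float)
    if qs.ndim != 1 or len(qs) < 1:
        raise ValueError("qs must be a nonempty 1-d sequence")
    if np.any(qs < 0) or np.any(np.diff(qs) < 0) or qs[-1] >= 1.0:
        raise ValueError("profile must satisfy 0 <= q_1 <= ... <= q_L < 1")
    s = np.sin(0.5 * np.pi * qs)
    s_prev = np.concatenate([[0.0], s[:-1]])
    denom = 1.0 - s[-1]
    out = np.zeros_like(qs)
    active = qs > 0
    out[active] = (2.0 / (np.pi * qs[active])) * (s[active] - s_prev[active]) / denom
    return np.sqrt(out)


def rate_sq_closed_form(q_j: float, q_prev: float = 0.0) -> float:
    """Per-level squared expansion rate at an erf-activation fixed point:

        ``R_j^2 = [2/(pi q_j)] [sin(pi q_j/2) - sin(pi q_{j-1}/2)]
                  / cos(pi q_j/2)``.
    """
    if not 0.0 <= q_prev <= q_j or q_j >= 1.0:
        raise ValueError("need 0 <= q_prev <= q_j < 1")
    if q_j == 0.0:
        return 1.0  # marginal limit of a vanishing gap
    u, u_prev = 0.5 * np.pi * q_j, 0.5 * np.pi * q_prev
    return float((np.sin(u) - np.sin(u_prev)) / (u * np.cos(u)))


def level_mle_closed_form(q_k: float, q_prev: float = 0.0) -> float:
    """Closed-form level Lyapunov exponent ``lambda = (1/2) ln R^2``.

    For the first active level (``q_prev = 0``) this reduces to
    ``(1/2) ln[ tan(pi q/2) / (pi q/2) ]``, which is positive for any
    ``q in (0, 1)`` and behaves as ``pi^2 q^2 / 24`` for small ``q``: a
    barely active level is barely chaotic.
    """
    return 0.5 * float(np.log(rate_sq_closed_form(q_k, q_prev)))
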