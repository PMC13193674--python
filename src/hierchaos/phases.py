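"""Phase classification and parameter sweeps for the two-level network.

Four phases, decided from the mean-field fixed point and the per-subspace
expansion rates:

* quiescent — ``sigma < 1`` and ``sigma_mu < 1``; activity decays to zero.
* micro (mu) — active but incoherent (``q_m = 0``): high-dimensional chaos of
  individual neurons with silent population means.
* multiscale (mu+M) — coherent (``q_m > 0``) with ``R_random^2 > 1``: chaotic
  population means coexist with expanding microscopic residuals.
* macro (M) — coherent with ``R_random^2 < 1``: chaos confined to the
  low-dimensional manifold of population means.

The two transition lines are the coherence onset ``sigma_mu*(sigma)`` and the
edge of high-dimensional chaos ``sigma_mu^EoHC(sigma)`` where
``R_random^2 = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mean_field
from .connectivity import build_two_level
from .gaussian import ERF, ActivationModel, QuadratureRule
from .lyapunov import mle_direct, theory_rates
from .simulate import order_parameters, run

__all__ = [
    "PhasePoint",
    "SimPlan",
    "classify",
    "sigma_mu_eohc",
    "transition_lines",
    "sweep",
]


@dataclass
class PhasePoint:
    """Classification of a single ``(sigma, sigma_mu)`` parameter point."""

    sigma: float
    sigma_mu: float
    phase: str  # quiescent | micro | multiscale | macro
    q: float
    qm: float
    lambda_coherent: float
    lambda_random: float
    lambda_max: float


@dataclass
class SimPlan:
    """Simulation settings attached to a sweep (validation columns)."""

    n: int = 100
    P: int = 40
    T: int = 1500
    burn_in: int = 500
    seed: int = 0
    with_mle: bool = True


def classify(
    sigma: float,
    sigma_mu: float,
    act: ActivationModel = ERF,
    rule: QuadratureRule | None = None,
    qm_zero_tol: float = mean_field.QM_ZERO_TOL,
) -> PhasePoint:
    """Assign a parameter point to one of the four phases.

    Quiescence is decided by the linear criterion; otherwise the fixed point
    is solved from a coherent start and the phase follows from ``q_m`` and
    the microscopic expansion rate.
    """
    if sigma < 0 or sigma_mu < 0:
        raise ValueError("strengths must be nonnegative")
    if mean_field.quiescent_stable(sigma, sigma_mu):
        report = theory_rates(sigma, sigma_mu, 0.0, 0.0, act, rule)
        return PhasePoint(
            sigma=sigma, sigma_mu=sigma_mu, phase="quiescent", q=0.0, qm=0.0,
            lambda_coherent=report.lambda_coherent,
            lambda_random=report.lambda_random,
            lambda_max=report.lambda_max,
        )
    sol = mean_field.fixed_point(sigma, sigma_mu, "coherent", act, rule)
    if not sol.converged:
        raise mean_field.ConvergenceError(
            f"mean-field solve did not converge at sigma={sigma}, sigma_mu={sigma_mu}"
        )
    qm = 0.0 if sol.qm < qm_zero_tol else sol.qm
    report = theory_rates(sigma, sigma_mu, sol.q, qm, act, rule)
    if qm == 0.0:
        phase = "micro"
    elif report.rate_sq_random > 1.0:
        phase = "multiscale"
    else:
        phase = "macro"
    return PhasePoint(
        sigma=sigma, sigma_mu=sigma_mu, phase=phase, q=sol.q, qm=qm,
        lambda_coherent=report.lambda_coherent,
        lambda_random=report.lambda_random,
        lambda_max=report.lambda_max,
    )


def sigma_mu_eohc(
    sigma: float,
    act: ActivationModel = ERF,
    rule: QuadratureRule | None = None,
    xtol: float = 1e-6,
    bracket_max: float = 64.0,
) -> float:
    """Edge of high-dimensional chaos: ``sigma_mu`` where ``R_random^2 = 1``.

    Bisection along the coherent branch at fixed ``sigma``; returns ``nan``
    when microscopic chaos never develops (``R_random^2 < 1`` already at the
    coherence onset) or when no bracket exists below ``bracket_max``.
    """
    if sigma <= 1.0:
        # R_random^2 = sigma^2 E[phi'(.)^2] <= sigma^2 <= 1: the microscopic
        # subspace never expands, so there is no edge to locate
        return float("nan")

    def rr2(sm: float) -> float:
        pt = classify(sigma, sm, act, rule)
        return theory_rates(sigma, sm, pt.q, pt.qm, act, rule).rate_sq_random

    lo = mean_field.sigma_mu_star(sigma, act, rule)
    # at the onset itself the coherent solve is critically slow; the fixed
    # point there is the incoherent one, so evaluate that branch directly
    inc = mean_field.fixed_point(sigma, lo, "incoherent", act, rule)
    rr2_lo = theory_rates(sigma, lo, inc.q, 0.0, act, rule).rate_sq_random
    if rr2_lo <= 1.0:
        return float("nan")
    hi = max(2.0 * lo, 4.0)
    while rr2(hi) > 1.0:
        hi *= 2.0
        if hi > bracket_max:
            return float("nan")
    while hi - lo > xtol:
        mid = 0.5 * (lo + hi)
        if rr2(mid) > 1.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def transition_lines(
    sigma_grid,
    act: ActivationModel = ERF,
    rule: QuadratureRule | None = None,
    xtol: float = 1e-6,
) -> pd.DataFrame:
    """Both transition lines over a grid of ``sigma`` values.

    Columns: ``sigma``, ``sigma_mu_star``, ``sigma_mu_eohc`` (``NaN`` where
    the edge of high-dimensional chaos does not exist).
    """
    rows = []
    for s in np.asarray(sigma_grid, dtype=float):
        rows.append({
            "sigma": s,
            "sigma_mu_star": mean_field.sigma_mu_star(s, act, rule),
            "sigma_mu_eohc": sigma_mu_eohc(s, act, rule, xtol=xtol),
        })
    return pd.DataFrame(rows)


def sweep(
    axis: str,
    values,
    fixed: float,
    act: ActivationModel = ERF,
    rule: QuadratureRule | None = None,
    sim: SimPlan | None = None,
) -> pd.DataFrame:
    """Sweep one control parameter, collecting theory (and optionally
    simulation) columns per point.

    ``axis`` is ``"sigma"`` or ``"sigma_mu"``; ``fixed`` is the other
    parameter.  Theory columns come from :func:`classify`; with a
    :class:`SimPlan` each row also gets time-averaged simulated ``q``,
    ``q_m`` and (optionally) the direct MLE.  Individual row failures are
    recorded in the ``error`` column rather than aborting the sweep.
    """
    if axis not in ("sigma", "sigma_mu"):
        raise ValueError("axis must be 'sigma' or 'sigma_mu'")
    rows = []
    for v in np.asarray(values, dtype=float):
        sigma, sigma_mu = (v, fixed) if axis == "sigma" else (fixed, v)
        row: dict = {"sigma": sigma, "sigma_mu": sigma_mu, "error": ""}
        try:
            pt = classify(sigma, sigma_mu, act, rule)
            row.update(
                phase=pt.phase, q=pt.q, qm=pt.qm,
                lambda_coherent=pt.lambda_coherent,
                lambda_random=pt.lambda_random,
                lambda_max=pt.lambda_max,
            )
            if sim is not None:
                Jm = build_two_level(sim.n, sim.P, sigma, sigma_mu, seed=sim.seed)
                traj = run(Jm, T=sim.T, burn_in=sim.burn_in, act=act, seed=sim.seed)
                ops = order_parameters(traj).summary()
                row.update(qm_sim=float(ops[0]), q_sim=float(ops[1]))
                if sim.with_mle:
                    row["mle_sim"] = mle_direct(
                        Jm, T=sim.T, burn_in=sim.burn_in, act=act, seed=sim.seed
                    )
        except Exception as exc:  # noqa: BLE001 - per-row failures are data
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)
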