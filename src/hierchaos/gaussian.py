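"""Activation functions and standard-normal expectation machinery.

Every mean-field quantity in this package is an expectation over the standard
Gaussian measure, written ``int Dz f(z)`` with ``Dz = dz exp(-z^2/2)/sqrt(2 pi)``.
This module provides

* the saturating error-function activation ``phi_inf(x) = erf(sqrt(pi)/2 x)``,
  normalized so that ``phi_inf'(0) = 1`` and ``phi_inf(inf) = 1``, together
  with a :class:`ActivationModel` container that also covers ``tanh``;
* :class:`QuadratureRule` objects for ``int Dz``: a probabilists'
  Gauss-Hermite rule for generic smooth integrands, and a trimmed
  uniform-grid rule that stays accurate when the integrand varies on a scale
  much finer than the unit Gaussian (large disorder strengths push the
  effective argument scale ``a`` in ``f(c + a z)`` well past the resolution
  of any fixed-order Gauss-Hermite rule);
* the Gaussian-smoothing constructions used by the theory: the suppression
  factor ``g(a) = int Dz phi'(a z)`` and the effective population-level
  transfer function ``phi_a`` with unit slope at the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import erf

__all__ = [
    "ActivationModel",
    "QuadratureRule",
    "DEFAULT_RULE",
    "ERF",
    "TANH",
    "phi_inf",
    "phi_inf_prime",
    "gauss_expect",
    "expect_affine",
    "g_factor",
    "phi_effective",
]

#: slope normalization of the erf activation: phi_inf(x) = erf(_K * x)
_K = np.sqrt(np.pi) / 2.0


def phi_inf(x):
    """Saturating activation ``phi_inf(x) = erf((sqrt(pi)/2) x)``.

    Odd, strictly increasing, bounded by 1, with unit slope at the origin.
    """
    return erf(_K * np.asarray(x, dtype=float))


def phi_inf_prime(x):
    """Exact derivative of :func:`phi_inf`: ``exp(-pi x^2 / 4)``."""
    x = np.asarray(x, dtype=float)
    return np.exp(-np.pi * x * x / 4.0)


def _tanh_prime(x):
    c = np.cosh(np.asarray(x, dtype=float))
    return 1.0 / (c * c)


@dataclass(frozen=True)
class ActivationModel:
    """An odd, bounded, nondecreasing activation with unit slope at 0.

    Attributes
    ----------
    name : str
        Label used in reports and manifests.
    phi : callable
        The activation, applied elementwise.
    phi_prime : callable
        Its derivative, applied elementwise.
    """

    name: str
    phi: Callable[[np.ndarray], np.ndarray]
    phi_prime: Callable[[np.ndarray], np.ndarray]

    def __repr__(self) -> str:  # keep reprs short in manifests
        return f"ActivationModel({self.name!r})"


ERF = ActivationModel("erf", phi_inf, phi_inf_prime)
TANH = ActivationModel("tanh", np.tanh, _tanh_prime)

_ACTIVATIONS = {"erf": ERF, "tanh": TANH}


def get_activation(name: str) -> ActivationModel:
    try:
        return _ACTIVATIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown activation {name!r}; available: {sorted(_ACTIVATIONS)}"
        ) from None


@dataclass(frozen=True)
class QuadratureRule:
    """Nodes and weights for expectations over the standard normal measure.

    ``sum(weights) == 1`` and ``sum(weights * nodes**2) == 1`` so that the
    rule integrates the measure and its variance exactly.  ``max_scale``
    records the finest feature scale the rule resolves: the rule is accurate
    for integrands of the form ``f(c + a z)`` with smooth, order-one ``f``
    as long as ``a <= max_scale``.
    """

    nodes: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)
    order: int
    max_scale: float = 1.0

    @classmethod
    def gauss_hermite(cls, order: int = 101) -> "QuadratureRule":
        """Probabilists' Gauss-Hermite rule, exact for polynomials of degree
        ``2*order - 1`` under ``Dz``."""
        if order < 1:
            raise ValueError("quadrature order must be >= 1")
        z, w = hermegauss(order)
        w = w / w.sum()
        return cls(nodes=z, weights=w, order=order, max_scale=1.0)

    @classmethod
    def gaussian_grid(
        cls,
        scale: float,
        points_per_width: float = 6.0,
        half_width: float = 12.0,
    ) -> "QuadratureRule":
        """Uniform trapezoidal rule on ``[-half_width, half_width]``.

        The grid spacing resolves features of width ``1/scale``; for analytic
        integrands with Gaussian envelope the trapezoid rule converges
        exponentially, so this reaches machine precision already at a few
        points per feature width.
        """
        if scale <= 0:
            raise ValueError("scale must be positive")
        delta = min(1.0, 1.0 / scale) / points_per_width
        n = int(np.ceil(2.0 * half_width / delta)) | 1
        z = np.linspace(-half_width, half_width, n)
        w = np.exp(-0.5 * z * z)
        w /= w.sum()
        return cls(nodes=z, weights=w, order=n, max_scale=float(scale))

    def for_scale(self, scale: float) -> "QuadratureRule":
        """Return this rule if it resolves feature scale ``1/scale``,
        otherwise a uniform-grid rule that does."""
        if scale <= self.max_scale:
            return self
        return QuadratureRule.gaussian_grid(scale)


DEFAULT_RULE = QuadratureRule.gauss_hermite(101)


def _base_rule(rule: QuadratureRule | None) -> QuadratureRule:
    return DEFAULT_RULE if rule is None else rule


def gauss_expect(f: Callable, rule: QuadratureRule | None = None) -> float:
    """Compute ``int Dz f(z)`` with the given rule.

    Raises ``ValueError`` if the integrand is non-finite on any node.
    """
    rule = _base_rule(rule)
    vals = np.asarray(f(rule.nodes), dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("integrand is non-finite on a quadrature node")
    return float(rule.weights @ vals)


def expect_affine(
    f: Callable,
    c,
    a: float,
    rule: QuadratureRule | None = None,
) -> np.ndarray | float:
    """Compute ``int Dz f(c + a z)``, vectorized over ``c``.

    The rule is automatically refined when ``|a|`` exceeds the feature scale
    it resolves, which happens routinely in the rate integrals at large
    disorder strengths.
    """
    a = float(a)
    rule = _base_rule(rule).for_scale(abs(a))
    c_arr = np.asarray(c, dtype=float)
    vals = f(c_arr[..., None] + a * rule.nodes)
    out = vals @ rule.weights
    if np.isscalar(c) or c_arr.ndim == 0:
        return float(out)
    return out


def g_factor(a: float, act: ActivationModel = ERF, rule: QuadratureRule | None = None) -> float:
    """Gaussian suppression factor ``g(a) = int Dz phi'(a z)``.

    ``g(0) = 1`` and, for concave-saturating activations, ``g`` decreases
    with ``a``: stronger fluctuations spend more time in the saturated
    region, flattening the average slope.  For the erf activation
    ``g(a) = (1 + pi a^2 / 2)**-0.5``.
    """
    if a < 0:
        raise ValueError("a must be nonnegative")
    return float(expect_affine(act.phi_prime, 0.0, a, rule))


def phi_effective(
    a: float,
    x,
    act: ActivationModel = ERF,
    rule: QuadratureRule | None = None,
) -> np.ndarray | float:
    """Effective population-level transfer function ``phi_a(x)``.

    Population means see their recurrent input smeared by within-population
    Gaussian fluctuations of amplitude ``a``; the resulting transfer function
    is ``int Dz phi(x/g(a) + a z)``, normalized so that its slope at the
    origin is exactly 1 (the raw smeared slope is ``g(a)``).
    """
    if a < 0:
        raise ValueError("a must be nonnegative")
    g = g_factor(a, act, rule)
    return expect_affine(act.phi, np.asarray(x, dtype=float) / g, a, rule)
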