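"""Hierarchical random connectivity matrices and their spectra.

The two-level modular network couples ``P`` populations of ``n`` neurons each
through

    ``J = sigma_mu Xi(P) (x) O(n) + sigma Xi(N)``,    ``N = n P``,

where ``Xi(m)`` has i.i.d. ``N(0, 1/m)`` entries, ``O(n)`` is the rank-1
projector onto the uniform direction (all entries ``1/n``), and ``(x)`` is the
Kronecker product.  The first term assigns every population pair a random mean
efficacy; the second adds neuron-level disorder.  The multilevel
generalization applies the same construction recursively,

    ``J[i] = J[i-1] (x) O(P_i) + sigma_i Xi(N_i)``,  ``N_i = prod_{j<=i} P_j``,

so that level ``i`` contributes disorder at the granularity of its blocks.
Neurons are flattened so that the level-1 index varies slowest; blocks are
contiguous, which makes the Kronecker structure literal in memory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "HierarchySpec",
    "ConnectivityMatrix",
    "random_bulk",
    "mean_projector",
    "build_two_level",
    "build_multilevel",
    "spectrum",
]


@dataclass(frozen=True)
class HierarchySpec:
    """Branching sizes ``P_1..P_L`` and disorder strengths ``sigma_1..sigma_L``.

    Level 1 is the coarsest: ``N_i = P_1 * ... * P_i`` units exist at level
    ``i`` and the full network has ``N = N_L`` neurons.  The two-level
    special case identifies ``P_1 = P`` (populations), ``P_2 = n`` (neurons
    per population), ``sigma_1 = sigma_mu``, ``sigma_2 = sigma``.
    """

    sizes: tuple[int, ...]
    strengths: tuple[float, ...]

    def __post_init__(self):
        sizes = tuple(int(p) for p in self.sizes)
        strengths = tuple(float(s) for s in self.strengths)
        object.__setattr__(self, "sizes", sizes)
        object.__setattr__(self, "strengths", strengths)
        if len(sizes) != len(strengths):
            raise ValueError("sizes and strengths must have equal length")
        if len(sizes) < 1:
            raise ValueError("at least one level is required")
        if any(p < 1 for p in sizes):
            raise ValueError("all level sizes must be >= 1")
        if any(s < 0 for s in strengths):
            raise ValueError("all strengths must be nonnegative")

    @property
    def levels(self) -> int:
        return len(self.sizes)

    @property
    def level_sizes(self) -> tuple[int, ...]:
        """``N_i = P_1 * ... * P_i`` for i = 1..L."""
        return tuple(np.cumprod(self.sizes).astype(int))

    @property
    def n_units(self) -> int:
        return self.level_sizes[-1]

    @classmethod
    def two_level(cls, n: int, P: int, sigma: float, sigma_mu: float) -> "HierarchySpec":
        return cls(sizes=(P, n), strengths=(sigma_mu, sigma))

    def to_dict(self) -> dict:
        return {"sizes": list(self.sizes), "strengths": list(self.strengths)}

    @classmethod
    def from_dict(cls, d: dict) -> "HierarchySpec":
        return cls(sizes=tuple(d["sizes"]), strengths=tuple(d["strengths"]))


@dataclass
class ConnectivityMatrix:
    """A realized ``N x N`` weight matrix together with its generating data.

    ``level_draws`` holds the raw ``Xi(N_i)`` draws for the structured levels
    ``i = 1..L-1`` (these are small); the finest-level draw is recoverable
    from ``weights`` via :meth:`bulk_draw`.  Regenerating with the same spec
    and seed reproduces the matrix bit-exactly.
    """

    weights: np.ndarray
    spec: HierarchySpec
    seed: int
    level_draws: tuple[np.ndarray, ...]

    @property
    def n_units(self) -> int:
        return self.spec.n_units

    def structured_parent(self) -> np.ndarray:
        """Recompute ``J[L-1]``, the recursion value before the finest level."""
        J = np.zeros((1, 1))
        for i in range(self.spec.levels - 1):
            J = np.kron(J, mean_projector(self.spec.sizes[i]))
            J = J + self.spec.strengths[i] * self.level_draws[i]
        return J

    def bulk_draw(self) -> np.ndarray | None:
        """Recover the finest-level draw ``Xi(N_L)``; ``None`` if
        ``sigma_L == 0`` (the draw then leaves no trace in the weights)."""
        s = self.spec.strengths[-1]
        if s == 0.0:
            return None
        parent = np.kron(self.structured_parent(), mean_projector(self.spec.sizes[-1]))
        return (self.weights - parent) / s

    @property
    def mu_matrix(self) -> np.ndarray:
        """Population-mean coupling ``sigma_1 * Xi(P_1)`` (two-level: the
        matrix of mean efficacies ``mu_ab`` scaled by block averaging)."""
        if self.spec.levels < 2:
            raise ValueError("mu_matrix requires at least two levels")
        return self.spec.strengths[0] * self.level_draws[0]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(
            path.with_suffix(".npz"),
            weights=self.weights,
            **{f"level_draw_{i}": d for i, d in enumerate(self.level_draws)},
        )
        sidecar = {"spec": self.spec.to_dict(), "seed": self.seed}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ConnectivityMatrix":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        spec = HierarchySpec.from_dict(sidecar["spec"])
        with np.load(path.with_suffix(".npz")) as data:
            weights = data["weights"]
            draws = tuple(
                data[f"level_draw_{i}"] for i in range(spec.levels - 1)
            )
        return cls(weights=weights, spec=spec, seed=sidecar["seed"], level_draws=draws)


def random_bulk(m: int, seed) -> np.ndarray:
    """Random ``m x m`` matrix with i.i.d. ``N(0, 1/m)`` entries.

    ``seed`` may be an integer, a ``SeedSequence``, or a ``Generator``.
    """
    if m < 1:
        raise ValueError("matrix size must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.normal(0.0, 1.0 / np.sqrt(m), size=(m, m))


def mean_projector(n: int) -> np.ndarray:
    """Rank-1 orthogonal projector onto the uniform direction: all entries
    ``1/n``.  Idempotent and symmetric; acting on a vector replaces every
    entry by the mean."""
    if n < 1:
        raise ValueError("projector size must be >= 1")
    return np.full((n, n), 1.0 / n)


def build_multilevel(spec: HierarchySpec, seed: int) -> ConnectivityMatrix:
    """Realize the recursive hierarchy ``J[i] = J[i-1] (x) O(P_i) + sigma_i Xi(N_i)``.

    One child random stream is spawned per level from the master seed, so the
    ``Xi`` draws at different levels are mutually independent and each level's
    draw is reproducible independently of the others.
    """
    streams = np.random.SeedSequence(seed).spawn(spec.levels)
    J = np.zeros((1, 1))
    draws: list[np.ndarray] = []
    for i in range(spec.levels):
        Ni = spec.level_sizes[i]
        J = np.kron(J, mean_projector(spec.sizes[i]))
        xi = random_bulk(Ni, np.random.default_rng(streams[i]))
        J = J + spec.strengths[i] * xi
        if i < spec.levels - 1:
            draws.append(xi)
    return ConnectivityMatrix(weights=J, spec=spec, seed=int(seed), level_draws=tuple(draws))


def build_two_level(
    n: int, P: int, sigma: float, sigma_mu: float, seed: int
) -> ConnectivityMatrix:
    """Two-level modular matrix ``J = sigma_mu Xi(P) (x) O(n) + sigma Xi(N)``.

    Exactly the ``L = 2`` case of :func:`build_multilevel`; the stored level-1
    draw is ``Xi(P)``, so block ``(a, b)`` of the structured term is constant
    with value ``sigma_mu * Xi(P)_ab / n``.
    """
    return build_multilevel(HierarchySpec.two_level(n, P, sigma, sigma_mu), seed)


def spectrum(Jm: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """All ``N`` complex eigenvalues of the weight matrix, unsorted."""
    W = Jm.weights if isinstance(Jm, ConnectivityMatrix) else np.asarray(Jm)
    if not np.all(np.isfinite(W)):
        raise ValueError("weight matrix has non-finite entries")
    return np.linalg.eigvals(W)
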