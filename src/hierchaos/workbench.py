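"""Reproducible experiments: configuration, dispatch, persistence, fixtures.

An :class:`ExperimentConfig` fully determines one run — including the master
seed, from which every random stream is derived — and round-trips through
YAML unchanged.  :func:`run_experiment` dispatches to the library modules and
writes all numeric outputs (``.npz`` arrays, CSV summaries, JSON records)
plus a manifest sufficient to regenerate them exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import mean_field
from .connectivity import ConnectivityMatrix, HierarchySpec, build_multilevel, spectrum
from .gaussian import QuadratureRule, get_activation
from .lyapunov import ky_dimension, lyapunov_spectrum, mle_direct, pr_dimension
from .phases import SimPlan, classify, sweep
from .simulate import Trajectory, order_parameters, run

__all__ = [
    "ExperimentConfig",
    "ConfigError",
    "Fixture",
    "run_experiment",
    "make_fixtures",
]

log = logging.getLogger("hierchaos")

KINDS = ("build", "simulate", "mft", "lyapunov", "classify", "sweep", "design", "fixtures")


class ConfigError(ValueError):
    """Invalid experiment configuration; lists the offending fields."""


@dataclass
class ExperimentConfig:
    kind: str = "mft"
    # hierarchy
    sizes: tuple[int, ...] = (10, 20)
    strengths: tuple[float, ...] = (0.5, 0.5)
    activation: str = "erf"
    # simulation protocol
    T: int = 1000
    burn_in: int = 200
    n_exponents: int | None = None
    # solver settings
    tol: float = 1e-10
    max_iter: int = 10000
    quad_order: int = 101
    # sweep settings
    sweep_axis: str = "sigma_mu"
    sweep_values: tuple[float, ...] = ()
    simulate_sweep: bool = False
    # design settings
    q_profile: tuple[float, ...] = ()
    # bookkeeping
    seed: int = 0
    out_dir: str = "hierchaos_out"

    def __post_init__(self):
        self.sizes = tuple(int(p) for p in self.sizes)
        self.strengths = tuple(float(s) for s in self.strengths)
        self.sweep_values = tuple(float(v) for v in self.sweep_values)
        self.q_profile = tuple(float(q) for q in self.q_profile)

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        bad: list[str] = []
        if self.kind not in KINDS:
            bad.append(f"kind: {self.kind!r} not in {KINDS}")
        if len(self.sizes) != len(self.strengths):
            bad.append("sizes/strengths: unequal lengths")
        if any(p < 1 for p in self.sizes):
            bad.append("sizes: all entries must be >= 1")
        if any(s < 0 for s in self.strengths):
            bad.append("strengths: all entries must be nonnegative")
        if self.T <= self.burn_in or self.burn_in < 0:
            bad.append("T/burn_in: need T > burn_in >= 0")
        if self.tol <= 0:
            bad.append("tol: must be positive")
        if self.quad_order < 1:
            bad.append("quad_order: must be >= 1")
        if self.activation not in ("erf", "tanh"):
            bad.append(f"activation: {self.activation!r} not in ('erf', 'tanh')")
        if self.kind == "sweep" and not self.sweep_values:
            bad.append("sweep_values: empty")
        if self.kind == "design" and not self.q_profile:
            bad.append("q_profile: empty")
        if bad:
            raise ConfigError("; ".join(bad))

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("sizes", "strengths", "sweep_values", "q_profile"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "ExperimentConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(yaml.safe_load(text))

    @property
    def spec(self) -> HierarchySpec:
        return HierarchySpec(sizes=self.sizes, strengths=self.strengths)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class Fixture:
    """A small pre-seeded instance with its expected-statistic ranges."""

    name: str
    spec: HierarchySpec
    seed: int
    connectivity: ConnectivityMatrix
    trajectory: Trajectory
    expected: dict = field(default_factory=dict)

    def digest(self) -> str:
        h = hashlib.sha256()
        h.update(self.connectivity.weights.tobytes())
        h.update(self.trajectory.states.tobytes())
        return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def _write_manifest(out: Path, config: ExperimentConfig, extra: dict) -> None:
    from . import __version__

    manifest = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "seed": config.seed,
        "version": __version__,
        **extra,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_experiment(config: ExperimentConfig) -> dict[str, Path]:
    """Run one experiment and write its artifacts; returns output paths."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    act = get_activation(config.activation)
    rule = QuadratureRule.gauss_hermite(config.quad_order)
    paths: dict[str, Path] = {"manifest": out / "manifest.json", "log": out / "run.log"}
    try:
        log.info("experiment kind=%s digest=%s", config.kind, config.digest())
        if config.kind in ("build", "simulate", "lyapunov"):
            Jm = build_multilevel(config.spec, config.seed)
            Jm.save(out / "connectivity")
            paths["connectivity"] = out / "connectivity.npz"
            eig = spectrum(Jm)
            np.savetxt(out / "eigenvalues.csv",
                       np.column_stack([eig.real, eig.imag]),
                       delimiter=",", header="re,im", comments="")
            paths["eigenvalues"] = out / "eigenvalues.csv"
            if config.kind == "simulate":
                traj = run(Jm, T=config.T, burn_in=config.burn_in, act=act, seed=config.seed)
                np.savez(out / "trajectory.npz", states=traj.states)
                ops = order_parameters(traj)
                ops.to_frame().to_csv(out / "order_parameters.csv", index=False)
                paths["trajectory"] = out / "trajectory.npz"
                paths["order_parameters"] = out / "order_parameters.csv"
            if config.kind == "lyapunov":
                rep = lyapunov_spectrum(
                    Jm, k=config.n_exponents, T=config.T,
                    burn_in=config.burn_in, act=act, seed=config.seed,
                )
                np.savetxt(out / "exponents.csv", rep.exponents,
                           delimiter=",", header="lambda", comments="")
                traj = run(Jm, T=config.T, burn_in=config.burn_in, act=act, seed=config.seed)
                summary = {
                    "mle_qr": float(rep.exponents[0]),
                    "mle_direct": mle_direct(Jm, T=config.T, burn_in=config.burn_in,
                                             act=act, seed=config.seed),
                    "ky_dimension": ky_dimension(rep.exponents),
                    "pr_dimension": pr_dimension(traj),
                }
                (out / "lyapunov.json").write_text(json.dumps(summary, indent=2))
                paths["exponents"] = out / "exponents.csv"
                paths["lyapunov"] = out / "lyapunov.json"
        elif config.kind == "mft":
            sol = mean_field.multilevel_fixed_point(
                config.strengths, act, rule, tol=config.tol, max_iter=config.max_iter
            )
            if not sol.converged:
                raise mean_field.ConvergenceError(
                    f"mean-field solve did not converge (residual {sol.residual:.2e})"
                )
            (out / "mft.json").write_text(json.dumps(sol.to_dict(), indent=2))
            paths["mft"] = out / "mft.json"
        elif config.kind == "classify":
            sigma_mu, sigma = config.strengths
            pt = classify(sigma, sigma_mu, act, rule)
            (out / "phase.json").write_text(json.dumps(dataclasses.asdict(pt), indent=2))
            paths["phase"] = out / "phase.json"
        elif config.kind == "sweep":
            sigma_mu, sigma = config.strengths
            fixed = sigma if config.sweep_axis == "sigma_mu" else sigma_mu
            plan = None
            if config.simulate_sweep:
                P, n = config.sizes
                plan = SimPlan(n=n, P=P, T=config.T, burn_in=config.burn_in,
                               seed=config.seed)
            table = sweep(config.sweep_axis, config.sweep_values, fixed, act, sim=plan)
            table.to_csv(out / "sweep.csv", index=False)
            if (table["error"] != "").any():
                raise mean_field.ConvergenceError(
                    "sweep rows failed: " + "; ".join(table.loc[table["error"] != "", "error"])
                )
            paths["sweep"] = out / "sweep.csv"
        elif config.kind == "design":
            qs = np.asarray(config.q_profile)
            sigmas = mean_field.design_sigmas(qs)
            sol = mean_field.multilevel_fixed_point(
                sigmas, act, rule, tol=config.tol, max_iter=config.max_iter
            )
            record = {
                "q_profile": [float(v) for v in qs],
                "sigmas": [float(v) for v in sigmas],
                "verification": sol.to_dict(),
                "verification_residual": float(np.max(np.abs(sol.qs - qs))),
            }
            (out / "design.json").write_text(json.dumps(record, indent=2))
            paths["design"] = out / "design.json"
        elif config.kind == "fixtures":
            fixtures = make_fixtures(config.seed)
            manifest_rows = []
            for fx in fixtures.values():
                fx.connectivity.save(out / f"fixture_{fx.name}")
                np.savez(out / f"fixture_{fx.name}_traj.npz", states=fx.trajectory.states)
                manifest_rows.append({
                    "name": fx.name, "seed": fx.seed,
                    "spec": fx.spec.to_dict(), "digest": fx.digest(),
                    "expected": fx.expected,
                })
            (out / "fixtures.json").write_text(json.dumps(manifest_rows, indent=2))
            paths["fixtures"] = out / "fixtures.json"
        _write_manifest(out, config, {"outputs": {k: str(v) for k, v in paths.items()}})
        log.info("experiment complete: %s", sorted(paths))
    finally:
        log.removeHandler(handler)
        handler.close()
    return paths


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

#: the four two-level reference points (sigma, sigma_mu), one per phase
PHASE_POINTS = {
    "quiescent": (0.5, 0.5),
    "micro": (4.0, 0.5),
    "multiscale": (4.0, 6.0),
    "macro": (1.0, 5.0),
}


def make_fixtures(master_seed: int = 0, n: int = 20, P: int = 10,
                  T: int = 400, burn_in: int = 100) -> dict[str, Fixture]:
    """One small seeded instance per phase, plus a three-level example.

    Expected-statistic ranges are deliberately loose: at ``N = 200`` the
    order parameters fluctuate at the few-percent level around their
    mean-field values.
    """
    streams = np.random.SeedSequence(master_seed).spawn(5)
    fixtures: dict[str, Fixture] = {}
    for (name, (sigma, sigma_mu)), ss in zip(PHASE_POINTS.items(), streams):
        seed = int(ss.generate_state(1)[0] % (2**31))
        spec = HierarchySpec.two_level(n, P, sigma, sigma_mu)
        Jm = build_multilevel(spec, seed)
        traj = run(Jm, T=T, burn_in=burn_in, seed=seed)
        expected: dict = {"phase": name}
        if name == "quiescent":
            expected["final_q_below"] = 1e-6
        else:
            expected["q_above"] = 0.05
        fixtures[name] = Fixture(
            name=name, spec=spec, seed=seed, connectivity=Jm,
            trajectory=traj, expected=expected,
        )
    seed = int(streams[4].generate_state(1)[0] % (2**31))
    spec3 = HierarchySpec(sizes=(4, 5, 10), strengths=(1.5, 1.2, 1.0))
    Jm3 = build_multilevel(spec3, seed)
    traj3 = run(Jm3, T=T, burn_in=burn_in, seed=seed)
    fixtures["multilevel"] = Fixture(
        name="multilevel", spec=spec3, seed=seed, connectivity=Jm3,
        trajectory=traj3, expected={"levels": 3},
    )
    return fixtures
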