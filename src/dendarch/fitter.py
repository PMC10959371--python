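"""Feature-based parameter optimization with an evolutionary strategy.

Unknown membrane parameters (for the passive problem: cm, g_pas, e_pas,
gmax_H, fastRatio_H) are fitted so that features extracted from simulated
current-step responses match reference means, using the error

    error = sum over features |model - mean| / max(SD, floor)

minimized by a classical (mu + lambda) evolutionary strategy with
self-adaptive, log-normally mutated per-parameter step sizes.  Runs are
bitwise reproducible under a seed, and the best-so-far error never
increases across generations.  Multiple independent restarts are the
standard usage (the best of 20 runs is kept for each cell).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ParamSpec", "OptimizerConfig", "FitResult", "feature_error",
           "optimize", "multi_start"]


@dataclass(frozen=True)
class ParamSpec:
    """Named parameters with box bounds and optional log-scale search."""

    names: tuple
    lower: tuple
    upper: tuple
    log_scale: tuple = ()

    def __post_init__(self):
        if not (len(self.names) == len(self.lower) == len(self.upper)):
            raise ValueError("names, lower and upper must have equal length")
        for n, lo, hi in zip(self.names, self.lower, self.upper):
            if not lo < hi:
                raise ValueError(f"bounds for {n} must satisfy lower < upper")
            if n in self.log_scale and lo <= 0:
                raise ValueError(f"log-scale parameter {n} needs lower > 0")

    @property
    def dim(self) -> int:
        return len(self.names)

    def to_internal(self, x: np.ndarray) -> np.ndarray:
        z = np.array(x, float)
        for i, n in enumerate(self.names):
            if n in self.log_scale:
                z[i] = np.log(z[i])
        return z

    def from_internal(self, z: np.ndarray) -> np.ndarray:
        x = np.array(z, float)
        for i, n in enumerate(self.names):
            if n in self.log_scale:
                x[i] = np.exp(x[i])
        return x

    def internal_bounds(self):
        lo = self.to_internal(np.asarray(self.lower, float))
        hi = self.to_internal(np.asarray(self.upper, float))
        return lo, hi

    def as_dict(self, x) -> dict:
        return dict(zip(self.names, np.asarray(x, float)))


@dataclass(frozen=True)
class OptimizerConfig:
    """(mu + lambda) ES settings; defaults follow the study convention of
    population 128 over 100 generations (scale down for small problems)."""

    population: int = 128
    generations: int = 100
    seed: int = 0
    sigma_init: float = 0.2        # initial step, as a fraction of range
    sigma_floor: float = 1e-4

    def __post_init__(self):
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")


@dataclass
class FitResult:
    """Best parameters with the optimization trajectory."""

    best_params: dict
    best_error: float
    trajectory: np.ndarray          # best-so-far error per generation
    evaluations: int
    residuals: dict = field(default_factory=dict)
    seed: int = 0


def feature_error(model_features: dict, targets: dict,
                  sd_floor_frac: float = 1e-3,
                  missing_penalty: float = 250.0) -> float:
    """Sum of |model - mean| / SD over target features.

    ``targets`` maps name -> (mean, sd).  The SD is floored at
    ``sd_floor_frac * |mean|`` (and at an absolute 1e-9) to avoid division
    blow-ups.  A feature the model does not produce contributes a fixed
    penalty so candidates that fail to spike or diverge are strongly but
    finitely disfavoured.
    """
    err = 0.0
    for name, (mean, sd) in targets.items():
        v = model_features.get(name)
        if v is None or not np.isfinite(v):
            err += missing_penalty
            continue
        floor = max(abs(mean) * sd_floor_frac, 1e-9)
        err += abs(v - mean) / max(sd, floor)
    return err


def optimize(spec: ParamSpec, error_fn, cfg: OptimizerConfig | None = None
             ) -> FitResult:
    """Minimize ``error_fn(params_dict)`` with a (mu + lambda) ES.

    lambda = population, mu = population // 2.  Each individual carries a
    per-parameter step size mutated log-normally (self-adaptation); means
    are mutated with Gaussian noise and clipped to the bounds.  Evaluation
    failures are caught and assigned a large finite penalty.
    """
    cfg = cfg or OptimizerConfig()
    rng = np.random.default_rng(cfg.seed)
    lo, hi = spec.internal_bounds()
    span = hi - lo
    d = spec.dim
    lam = cfg.population
    mu = max(lam // 2, 1)
    tau = 1.0 / np.sqrt(2.0 * d)
    tau_i = 1.0 / np.sqrt(2.0 * np.sqrt(d))

    def evaluate(z):
        x = spec.from_internal(z)
        try:
            e = float(error_fn(spec.as_dict(x)))
        except Exception:
            return 1e12
        return e if np.isfinite(e) else 1e12

    # initial population uniform in the (internal) box
    pop_z = lo + rng.uniform(0.0, 1.0, (lam, d)) * span
    pop_s = np.full((lam, d), cfg.sigma_init) * span
    pop_e = np.array([evaluate(z) for z in pop_z])

    best_traj = np.empty(cfg.generations + 1)
    order = np.argsort(pop_e, kind="stable")
    best_z, best_e = pop_z[order[0]].copy(), pop_e[order[0]]
    best_traj[0] = best_e
    evals = lam

    for gen in range(cfg.generations):
        parents = order[:mu]
        idx = rng.integers(0, mu, lam)
        g_noise = rng.normal(size=lam)
        i_noise = rng.normal(size=(lam, d))
        m_noise = rng.normal(size=(lam, d))
        off_s = pop_s[parents][idx] * np.exp(
            tau * g_noise[:, None] + tau_i * i_noise)
        off_s = np.maximum(off_s, cfg.sigma_floor * span)
        off_z = np.clip(pop_z[parents][idx] + off_s * m_noise, lo, hi)
        off_e = np.array([evaluate(z) for z in off_z])
        evals += lam
        # (mu + lambda): survivors from parents plus offspring
        all_z = np.vstack([pop_z[parents], off_z])
        all_s = np.vstack([pop_s[parents], off_s])
        all_e = np.concatenate([pop_e[parents], off_e])
        keep = np.argsort(all_e, kind="stable")[:lam]
        pop_z, pop_s, pop_e = all_z[keep], all_s[keep], all_e[keep]
        order = np.argsort(pop_e, kind="stable")
        if pop_e[order[0]] < best_e:
            best_e = pop_e[order[0]]
            best_z = pop_z[order[0]].copy()
        best_traj[gen + 1] = best_e

    best_x = spec.from_internal(best_z)
    return FitResult(best_params=spec.as_dict(best_x), best_error=float(best_e),
                     trajectory=best_traj, evaluations=evals, seed=cfg.seed)


def multi_start(spec: ParamSpec, error_fn, runs: int = 20,
                cfg: OptimizerConfig | None = None, base_seed: int = 0
                ) -> tuple[FitResult, list[FitResult]]:
    """Independent restarts; returns (best result, all results).

    Seeds are ``base_seed + run index`` so the whole family is reproducible.
    """
    cfg = cfg or OptimizerConfig()
    results = []
    for r in range(runs):
        c = OptimizerConfig(population=cfg.population,
                            generations=cfg.generations,
                            seed=base_seed + r,
                            sigma_init=cfg.sigma_init,
                            sigma_floor=cfg.sigma_floor)
        results.append(optimize(spec, error_fn, c))
    best = min(results, key=lambda f: f.best_error)
    return best, results
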