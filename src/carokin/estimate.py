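"""Bounded particle-swarm estimation of the network rate constants.

The objective is a per-experiment weighted least squares: for every
experiment and observed species, residuals are weighted by the inverse
mean squared observation ("mean square" normalisation), which makes each
species' contribution invariant to its concentration scale.

k_cat values span four decades, so they are searched in log10 space;
binding constants are searched linearly.  The swarm uses the standard
constriction coefficients (inertia 0.729, cognitive = social = 1.494)
with reflecting bounds, and is fully determined by its seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pathway import KineticParameters, ReactionNetwork
from .simulate import AssaySpec, IntegrationError, TimeCourse

__all__ = [
    "FitConfig",
    "FitResult",
    "DEFAULT_BOUNDS",
    "default_bounds",
    "parameter_names",
    "objective",
    "fit_pso",
    "derive_constants",
    "profile_identifiability",
]

#: Fitting bounds on each rate-constant class (natural units).
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "k_f": (0.1, 1.0),  # µM^-1 s^-1
    "k_r": (1.0, 10.0),  # s^-1
    "k_cat": (1e-5, 0.1),  # s^-1
}

Experiment = tuple[AssaySpec, TimeCourse]


@dataclass(frozen=True)
class FitConfig:
    """Configuration of one particle-swarm fit."""

    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    iterations: int = 2000
    swarm_size: int = 50
    seed: int = 0
    weighting: str = "mean_square"
    inertia: float = 0.729
    cognitive: float = 1.494
    social: float = 1.494
    log10_kcat: bool = True
    polish: bool = True
    polish_max_nfev: int = 200

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        for key, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"bounds for {key}: lower must be < upper")

    @classmethod
    def from_dict(cls, data: Mapping) -> "FitConfig":
        data = dict(data)
        if "bounds" in data:
            data["bounds"] = {k: tuple(v) for k, v in data["bounds"].items()}
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "iterations": self.iterations,
            "swarm_size": self.swarm_size,
            "seed": self.seed,
            "weighting": self.weighting,
            "inertia": self.inertia,
            "cognitive": self.cognitive,
            "social": self.social,
            "log10_kcat": self.log10_kcat,
            "polish": self.polish,
            "polish_max_nfev": self.polish_max_nfev,
        }


def parameter_names(network: ReactionNetwork) -> list[str]:
    """Free-parameter names in packing order: k_f, k_r, then k_cat."""
    m = network.n_steps + 1
    return (
        [f"k_f[{i}]" for i in range(m)]
        + [f"k_r[{i}]" for i in range(m)]
        + [f"k_cat[{i}]" for i in range(m - 1)]
    )


def default_bounds(
    network: ReactionNetwork, bounds: Mapping[str, tuple[float, float]] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Expand per-class bounds to per-parameter (lower, upper) arrays."""
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    m = network.n_steps + 1
    lo = np.array([b["k_f"][0]] * m + [b["k_r"][0]] * m + [b["k_cat"][0]] * (m - 1))
    hi = np.array([b["k_f"][1]] * m + [b["k_r"][1]] * m + [b["k_cat"][1]] * (m - 1))
    return lo, hi


def _transform(vector: np.ndarray, n_steps: int, log10_kcat: bool) -> np.ndarray:
    """Natural units -> search space (log10 on the k_cat block)."""
    v = np.array(vector, dtype=float)
    if log10_kcat:
        v[2 * (n_steps + 1) :] = np.log10(v[2 * (n_steps + 1) :])
    return v


def _untransform(vector: np.ndarray, n_steps: int, log10_kcat: bool) -> np.ndarray:
    v = np.array(vector, dtype=float)
    if log10_kcat:
        v[2 * (n_steps + 1) :] = 10.0 ** v[2 * (n_steps + 1) :]
    return v


_WEIGHTINGS: dict[str, Callable[[np.ndarray], float]] = {
    # per-(experiment, species) weight from the observation vector
    "mean_square": lambda obs: 1.0 / float(np.mean(obs**2)),
    "squared_mean": lambda obs: 1.0 / float(np.mean(obs)) ** 2,
    "variance": lambda obs: 1.0 / float(np.var(obs)),
}


class _ObjectiveCache:
    """Precomputed observation matrices and weights for repeated evaluation.

    Evaluation integrates the ODEs and accumulates the weighted misfit
    without constructing TimeCourse objects — the hot path of the swarm.
    """

    def __init__(
        self,
        network: ReactionNetwork,
        experiments: Sequence[Experiment],
        weighting: str = "mean_square",
        *,
        fast: bool = True,
        rtol: float = 1e-6,
        atol: float = 1e-9,
    ) -> None:
        if not experiments:
            raise ValueError("experiments must be non-empty")
        try:
            weight_fn = _WEIGHTINGS[weighting]
        except KeyError:
            raise ValueError(f"unknown weighting scheme {weighting!r}") from None
        self.network = network
        self.fast = fast and not network.branches
        self.rtol = rtol
        self.atol = atol
        observables = network.observable_names
        self.entries = []
        for idx, (assay, obs_tc) in enumerate(experiments):
            if not np.array_equal(np.asarray(assay.sampling_times), obs_tc.times):
                raise ValueError(
                    f"experiment {idx}: time course does not match assay"
                )
            cols, obs_list, weights = [], [], []
            for name, obs in obs_tc.totals.items():
                if name not in observables:
                    raise ValueError(
                        f"experiment {idx}: unknown species {name!r}"
                    )
                if not obs.any():
                    continue  # uninformative under mean-square weighting
                cols.append(observables.index(name))
                obs_list.append(obs)
                weights.append(weight_fn(obs))
            self.entries.append(
                {
                    "y0": network.initial_state(
                        assay.initial_phytoene, assay.enzyme_total
                    ),
                    "t_s": assay.times_seconds,
                    "cols": np.array(cols, dtype=int),
                    "obs": np.array(obs_list).T if obs_list else np.empty((0, 0)),
                    "w": np.array(weights),
                    "id": idx,
                }
            )

    def _totals(self, ys: np.ndarray) -> np.ndarray:
        net = self.network
        n_sp = len(net.species)
        out = np.empty((ys.shape[0], n_sp + len(net.branches)))
        out[:, :n_sp] = ys[:, :n_sp] + ys[:, net.enzyme_index + 1 :]
        if net.branches:
            out[:, n_sp:] = ys[:, n_sp : net.enzyme_index]
        return out

    def eval_arrays(self, k_f: np.ndarray, k_r: np.ndarray, k_cat: np.ndarray) -> float:
        """Evaluate from raw rate-constant arrays (hot path, no validation)."""
        from . import _fastode
        from .simulate import integrate_states  # local to avoid cycle at import

        use_compiled = self.fast and _fastode.NUMBA_AVAILABLE
        total = 0.0
        for entry in self.entries:
            if use_compiled:
                ys, status = _fastode.integrate_chain(
                    entry["y0"], entry["t_s"], k_f, k_r, k_cat,
                    self.rtol, self.atol,
                )
                if status != 0:
                    raise IntegrationError(
                        f"experiment {entry['id']}: compiled integrator failed"
                    )
            else:
                params = KineticParameters(k_f, k_r, k_cat)
                try:
                    ys = integrate_states(
                        self.network, params, entry["y0"], entry["t_s"],
                        rtol=self.rtol, atol=self.atol, fast=self.fast,
                    )
                except IntegrationError as exc:
                    raise IntegrationError(
                        f"experiment {entry['id']}: {exc}"
                    ) from exc
            if entry["obs"].size:
                sim = self._totals(ys)[:, entry["cols"]]
                total += float(
                    np.sum(entry["w"] * np.sum((sim - entry["obs"]) ** 2, axis=0))
                )
        return total

    def residuals(self, k_f: np.ndarray, k_r: np.ndarray, k_cat: np.ndarray) -> np.ndarray:
        """Weighted residual vector; its squared norm equals eval_arrays."""
        from . import _fastode
        from .simulate import integrate_states

        use_compiled = self.fast and _fastode.NUMBA_AVAILABLE
        parts = []
        for entry in self.entries:
            if use_compiled:
                ys, status = _fastode.integrate_chain(
                    entry["y0"], entry["t_s"], k_f, k_r, k_cat,
                    self.rtol, self.atol,
                )
                if status != 0:
                    raise IntegrationError(
                        f"experiment {entry['id']}: compiled integrator failed"
                    )
            else:
                ys = integrate_states(
                    self.network, KineticParameters(k_f, k_r, k_cat),
                    entry["y0"], entry["t_s"],
                    rtol=self.rtol, atol=self.atol, fast=self.fast,
                )
            if entry["obs"].size:
                sim = self._totals(ys)[:, entry["cols"]]
                parts.append(
                    (np.sqrt(entry["w"]) * (sim - entry["obs"])).ravel()
                )
        return np.concatenate(parts) if parts else np.zeros(0)

    def __call__(self, params: KineticParameters) -> float:
        return self.eval_arrays(params.k_f, params.k_r, params.k_cat)


def objective(
    params: KineticParameters,
    experiments: Sequence[Experiment],
    network: ReactionNetwork,
    weighting: str = "mean_square",
    *,
    fast: bool = True,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> float:
    """Weighted sum-of-squares misfit between simulation and observations.

    For every experiment and species, residuals over the sampling grid are
    weighted by 1/mean(obs^2) (default scheme), making each species'
    contribution invariant to its concentration scale.  Species whose
    observations are all zero carry no information under mean-square
    weighting and are skipped.
    """
    cache = _ObjectiveCache(
        network, experiments, weighting, fast=fast, rtol=rtol, atol=atol
    )
    return cache(params)


@dataclass
class FitResult:
    """Outcome of a particle-swarm fit."""

    best_params: KineticParameters
    objective_value: float
    trace: np.ndarray  # best objective per iteration, monotone non-increasing
    derived_constants: pd.DataFrame
    seed: int
    config: FitConfig
    n_failed_evaluations: int = 0

    def to_dict(self) -> dict:
        return {
            "k_f": self.best_params.k_f.tolist(),
            "k_r": self.best_params.k_r.tolist(),
            "k_cat": self.best_params.k_cat.tolist(),
            "objective_value": self.objective_value,
            "trace": np.asarray(self.trace).tolist(),
            "derived_constants": self.derived_constants.to_dict(orient="list"),
            "seed": self.seed,
            "config": self.config.to_dict(),
            "n_failed_evaluations": self.n_failed_evaluations,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FitResult":
        d = json.loads(Path(path).read_text())
        params = KineticParameters(
            np.array(d["k_f"]), np.array(d["k_r"]), np.array(d["k_cat"])
        )
        return cls(
            best_params=params,
            objective_value=d["objective_value"],
            trace=np.array(d["trace"]),
            derived_constants=pd.DataFrame(d["derived_constants"]),
            seed=d["seed"],
            config=FitConfig.from_dict(d["config"]),
            n_failed_evaluations=d.get("n_failed_evaluations", 0),
        )


def derive_constants(params: KineticParameters) -> pd.DataFrame:
    """Per-step table of K_d (µM), K_m (µM) and k_cat (s^-1).

    K_d = k_r/k_f for every complex; K_m = (k_r + k_cat)/k_f and k_cat for
    catalytic steps only (NaN on the terminal dead-end complex).
    """
    m = len(params.k_f)
    kd = params.dissociation_constants()
    km = np.full(m, np.nan)
    kcat = np.full(m, np.nan)
    km[:-1] = params.michaelis_constants()
    kcat[:-1] = params.k_cat
    return pd.DataFrame(
        {"step": np.arange(m), "K_d_uM": kd, "K_m_uM": km, "k_cat_per_s": kcat}
    )


def _reflect(x: np.ndarray, v: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> None:
    """Reflect positions at the bounds in place, reversing velocity."""
    for _ in range(8):  # repeated reflection for large overshoots
        below = x < lo
        above = x > hi
        if not (below.any() or above.any()):
            break
        x[below] = 2 * lo[below] - x[below]
        v[below] *= -1.0
        x[above] = 2 * hi[above] - x[above]
        v[above] *= -1.0
    np.clip(x, lo, hi, out=x)


def _polish(
    cache: _ObjectiveCache,
    expand_vec: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    score0: float,
    lo: np.ndarray,
    hi: np.ndarray,
    m: int,
    config: FitConfig,
) -> tuple[np.ndarray, float]:
    """Deterministic bounded least-squares refinement of the swarm's best.

    The swarm locates the global basin but crawls along the curved
    K_m-compensation valley; a trust-region Gauss-Newton descent from the
    best particle reaches the basin floor in a few hundred evaluations.
    Residuals are integrated at tighter tolerance than the swarm's and the
    finite-difference step is kept well above the integration noise so the
    Jacobian stays informative near the optimum.
    """
    from scipy.optimize import least_squares

    tight = _ObjectiveCache.__new__(_ObjectiveCache)
    tight.__dict__.update(cache.__dict__)
    tight.rtol, tight.atol = 1e-8, 1e-10

    def resid(x_free: np.ndarray) -> np.ndarray:
        vec = expand_vec(x_free)
        return tight.residuals(vec[:m], vec[m : 2 * m], vec[2 * m :])

    try:
        n_res = resid(x0).size
        if n_res == 0:
            return x0, score0

        def safe_resid(x_free: np.ndarray) -> np.ndarray:
            try:
                return resid(x_free)
            except IntegrationError:
                return np.full(n_res, 1e6)

        sol = least_squares(
            safe_resid,
            np.clip(x0, lo, hi),
            bounds=(lo, hi),
            method="trf",
            x_scale="jac",
            diff_step=1e-5,
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=config.polish_max_nfev,
        )
        val = float(np.sum(sol.fun**2))
        if np.isfinite(val) and val < score0:
            return sol.x, val
    except (IntegrationError, FloatingPointError) as exc:
        warnings.warn(f"polish failed: {exc}", stacklevel=2)
    return x0, score0


def fit_pso(
    network: ReactionNetwork,
    experiments: Sequence[Experiment],
    config: FitConfig,
    *,
    fixed: Mapping[str, float] | None = None,
    initial_guess: KineticParameters | None = None,
) -> FitResult:
    """Minimise the weighted objective with a bounded particle swarm.

    Parameters listed in ``fixed`` (by name, e.g. ``"k_cat[1]"``) are held
    at the given natural-unit values and excluded from the search.
    ``initial_guess`` seeds one particle (useful for warm starts).
    """
    if not experiments:
        raise ValueError("experiments must be non-empty")
    n = network.n_steps
    names = parameter_names(network)
    lo_nat, hi_nat = default_bounds(network, config.bounds)
    lo = _transform(lo_nat, n, config.log10_kcat)
    hi = _transform(hi_nat, n, config.log10_kcat)

    fixed = dict(fixed or {})
    unknown = set(fixed) - set(names)
    if unknown:
        raise KeyError(f"unknown fixed parameter(s): {sorted(unknown)}")
    free = np.array([nm not in fixed for nm in names])
    full_nat = (lo_nat + hi_nat) / 2.0
    for nm, val in fixed.items():
        full_nat[names.index(nm)] = val

    base = _transform(full_nat, n, config.log10_kcat)
    m = n + 1

    def expand_vec(x_free: np.ndarray) -> np.ndarray:
        full = base.copy()
        full[free] = x_free
        return _untransform(full, n, config.log10_kcat)

    n_failed = 0
    cache = _ObjectiveCache(network, experiments, config.weighting)

    def evaluate(x_free: np.ndarray) -> float:
        nonlocal n_failed
        try:
            vec = expand_vec(x_free)
            val = cache.eval_arrays(vec[:m], vec[m : 2 * m], vec[2 * m :])
        except (IntegrationError, FloatingPointError) as exc:
            n_failed += 1
            warnings.warn(f"particle evaluation failed: {exc}", stacklevel=2)
            return np.inf
        if not np.isfinite(val):
            n_failed += 1
            warnings.warn("non-finite objective; particle discarded", stacklevel=2)
            return np.inf
        return val

    rng = np.random.default_rng(config.seed)
    d = int(free.sum())
    lo_f, hi_f = lo[free], hi[free]
    span = hi_f - lo_f

    X = lo_f + rng.uniform(size=(config.swarm_size, d)) * span
    if initial_guess is not None:
        X[0] = _transform(initial_guess.to_vector(), n, config.log10_kcat)[free]
    V = np.zeros_like(X)

    scores = np.array([evaluate(x) for x in X])
    if not np.isfinite(scores).any():
        raise RuntimeError("all particles failed evaluation at initialization")
    pbest, pbest_scores = X.copy(), scores.copy()
    g = int(np.argmin(pbest_scores))
    gbest, gbest_score = pbest[g].copy(), float(pbest_scores[g])

    trace = np.empty(config.iterations)
    for it in range(config.iterations):
        r1 = rng.uniform(size=(config.swarm_size, d))
        r2 = rng.uniform(size=(config.swarm_size, d))
        V = (
            config.inertia * V
            + config.cognitive * r1 * (pbest - X)
            + config.social * r2 * (gbest - X)
        )
        X = X + V
        for k in range(config.swarm_size):
            _reflect(X[k], V[k], lo_f, hi_f)
            s = evaluate(X[k])
            if s < pbest_scores[k]:
                pbest_scores[k] = s
                pbest[k] = X[k]
                if s < gbest_score:
                    gbest_score = float(s)
                    gbest = X[k].copy()
        trace[it] = gbest_score

    if config.polish:
        gbest, gbest_score = _polish(
            cache, expand_vec, gbest, gbest_score, lo_f, hi_f, m, config
        )
        trace = np.append(trace, gbest_score)

    best = KineticParameters.from_vector(expand_vec(gbest), n)
    return FitResult(
        best_params=best,
        objective_value=gbest_score,
        trace=trace,
        derived_constants=derive_constants(best),
        seed=config.seed,
        config=config,
        n_failed_evaluations=n_failed,
    )


def profile_identifiability(
    network: ReactionNetwork,
    experiments: Sequence[Experiment],
    config: FitConfig,
    parameter: str,
    grid: Sequence[float],
) -> pd.DataFrame:
    """Objective profile of one parameter: re-fit all others at each grid value.

    A flat profile signals weak identifiability of the parameter.
    """
    if parameter not in parameter_names(network):
        raise KeyError(f"unknown parameter {parameter!r}")
    rows = []
    for value in grid:
        res = fit_pso(network, experiments, config, fixed={parameter: float(value)})
        rows.append({"value": float(value), "objective": res.objective_value})
    return pd.DataFrame(rows)
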