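"""Synthetic assays and noisy time courses for testing and benchmarking.

Presets emulate purified-enzyme desaturation assays: ~10 µM phytoene
(5 nmol in 0.5 mL), 25 µg enzyme in 0.5 mL (0.83 µM at an assumed 60 kDa),
and the two sampling schedules used for purified enzymes, plus crude-extract
end points.  Two kinetic archetypes are shipped — a fast one (intermediates
peak within tens of minutes, terminal product accumulates) and a slow one
(phytoene barely depleted after two hours).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .estimate import FitConfig, default_bounds, fit_pso, parameter_names
from .pathway import KineticParameters, ReactionNetwork, build_network
from .simulate import AssaySpec, IntegrationError, TimeCourse, simulate

__all__ = [
    "NoiseSpec",
    "ScenarioPreset",
    "enzyme_micromolar",
    "preset_assay",
    "preset_scenario",
    "generate_timecourse",
    "recovery_suite",
    "in_vivo_scenario",
]

#: Sampling schedules (minutes) used for purified-enzyme kinetics.
DENSE_SCHEDULE = (0.0, 2.5, 5.0, 7.5, 10.0, 20.0, 30.0, 40.0, 60.0, 120.0)
SPARSE_SCHEDULE = (0.0, 10.0, 20.0, 40.0, 60.0, 80.0, 100.0, 120.0)

DEFAULT_PHYTOENE_UM = 10.0  # 5 nmol substrate in 0.5 mL assay volume
DEFAULT_ENZYME_UG = 25.0
DEFAULT_VOLUME_ML = 0.5
DEFAULT_ENZYME_KDA = 60.0


def enzyme_micromolar(
    micrograms: float = DEFAULT_ENZYME_UG,
    volume_ml: float = DEFAULT_VOLUME_ML,
    molar_mass_kda: float = DEFAULT_ENZYME_KDA,
) -> float:
    """Convert an enzyme mass per assay volume to µM."""
    if micrograms < 0 or volume_ml <= 0 or molar_mass_kda <= 0:
        raise ValueError("mass >= 0, volume > 0 and molar mass > 0 required")
    mol = micrograms * 1e-6 / (molar_mass_kda * 1e3)
    return mol / (volume_ml * 1e-3) * 1e6


@dataclass(frozen=True)
class NoiseSpec:
    """Proportional-Gaussian measurement noise with a reporting floor."""

    model: str = "proportional-normal"
    cv: float = 0.1
    floor: float = 0.01  # µM; values below report as 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model != "proportional-normal":
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.cv < 0 or self.floor < 0:
            raise ValueError("cv and floor must be non-negative")


@dataclass(frozen=True)
class ScenarioPreset:
    """A fully specified synthetic experiment."""

    label: str
    true_params: KineticParameters
    assay: AssaySpec
    noise: NoiseSpec = NoiseSpec()
    network: ReactionNetwork = field(default_factory=build_network)
    phytoene_influx: float = 0.0  # µM/s, zeroth-order synthase surrogate


def preset_assay(kind: str, enzyme_molar_mass_kda: float = DEFAULT_ENZYME_KDA) -> AssaySpec:
    """Named assay designs: dense_schedule, sparse_schedule, crude_2h, crude_60h."""
    e_total = enzyme_micromolar(molar_mass_kda=enzyme_molar_mass_kda)
    schedules = {
        "dense_schedule": DENSE_SCHEDULE,
        "sparse_schedule": SPARSE_SCHEDULE,
        "crude_2h": (0.0, 120.0),
        "crude_60h": (0.0, 3600.0),
    }
    try:
        times = schedules[kind]
    except KeyError:
        raise ValueError(
            f"unknown assay kind {kind!r}; expected one of {sorted(schedules)}"
        ) from None
    return AssaySpec(
        initial_phytoene=DEFAULT_PHYTOENE_UM,
        enzyme_total=e_total,
        sampling_times=times,
    )


# Archetype rate constants, all inside the fitting bounds.  The fast set
# converts most phytoene within ~20 min; the slow set leaves it largely
# intact at 120 min (>5x less depletion).
_FAST_PARAMS = dict(
    k_f=[0.5, 0.5, 0.5, 0.5, 0.5],
    k_r=[5.0, 5.0, 5.0, 5.0, 5.0],
    k_cat=[0.05, 0.04, 0.03, 0.02],
)
_SLOW_PARAMS = dict(
    k_f=[0.5, 0.5, 0.5, 0.5, 0.5],
    k_r=[5.0, 5.0, 5.0, 5.0, 5.0],
    k_cat=[5e-4, 4e-4, 3e-4, 2e-4],
)


def preset_scenario(label: str, seed: int = 0, cv: float = 0.1) -> ScenarioPreset:
    """Shipped kinetic archetypes: fast_archetype, slow_archetype, crude_extract."""
    noise = NoiseSpec(cv=cv, seed=seed)
    if label == "fast_archetype":
        return ScenarioPreset(
            label, KineticParameters(**_FAST_PARAMS), preset_assay("dense_schedule"),
            noise,
        )
    if label == "slow_archetype":
        return ScenarioPreset(
            label, KineticParameters(**_SLOW_PARAMS), preset_assay("sparse_schedule"),
            noise,
        )
    if label == "crude_extract":
        return ScenarioPreset(
            label, KineticParameters(**_FAST_PARAMS), preset_assay("crude_60h"),
            noise,
        )
    raise ValueError(f"unknown scenario label {label!r}")


def generate_timecourse(scenario: ScenarioPreset) -> TimeCourse:
    """Simulate a scenario and apply its noise model; reproducible from seed."""
    clean = simulate(
        scenario.network,
        scenario.true_params,
        scenario.assay,
        influx=scenario.phytoene_influx,
    )
    rng = np.random.default_rng(scenario.noise.seed)
    noisy: dict[str, np.ndarray] = {}
    for name, values in clean.totals.items():
        if scenario.noise.cv > 0:
            v = values * (1.0 + scenario.noise.cv * rng.standard_normal(values.shape))
            v = np.clip(v, 0.0, None)
        else:
            v = values.copy()
        if scenario.noise.floor > 0:
            v = np.where(v < scenario.noise.floor, 0.0, v)
        noisy[name] = v
    meta = {
        "assay_id": scenario.label,
        "enzyme": scenario.label,
        "seed": scenario.noise.seed,
        "cv": scenario.noise.cv,
        "true_k_f": scenario.true_params.k_f.tolist(),
        "true_k_r": scenario.true_params.k_r.tolist(),
        "true_k_cat": scenario.true_params.k_cat.tolist(),
    }
    return TimeCourse(clean.times.copy(), noisy, meta)


def draw_parameters(
    network: ReactionNetwork, rng: np.random.Generator, bounds: dict | None = None
) -> KineticParameters:
    """Draw rate constants uniformly inside the fitting bounds (log-uniform k_cat)."""
    lo, hi = default_bounds(network, bounds)
    n = network.n_steps
    m = n + 1
    vec = np.empty(2 * m + n)
    vec[: 2 * m] = rng.uniform(lo[: 2 * m], hi[: 2 * m])
    vec[2 * m :] = 10 ** rng.uniform(np.log10(lo[2 * m :]), np.log10(hi[2 * m :]))
    return KineticParameters.from_vector(vec, n)


def recovery_suite(
    n_draws: int,
    seed: int,
    config: FitConfig,
    *,
    network: ReactionNetwork | None = None,
    kcat_floor: float | None = 1e-3,
) -> pd.DataFrame:
    """Parameter-recovery benchmark on noise-free dense-schedule data.

    Draws true parameter sets inside the bounds, simulates the dense
    schedule without noise, fits with the swarm, and reports per-parameter
    relative errors (one row per draw x parameter).  ``kcat_floor``
    optionally keeps drawn k_cat above a floor so the draw produces
    measurable turnover within the two-hour assay; fit failures are counted
    in the ``failed`` column, not raised.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    network = network or build_network(4)
    assay = preset_assay("dense_schedule")
    rng = np.random.default_rng(seed)
    names = parameter_names(network)
    rows = []
    for draw in range(n_draws):
        bounds = dict(config.bounds)
        if kcat_floor is not None:
            lo, hi = bounds.get("k_cat", (1e-5, 0.1))
            bounds["k_cat"] = (max(lo, kcat_floor), hi)
        true = draw_parameters(network, rng, bounds)
        scenario = ScenarioPreset(
            f"recovery-{draw}", true, assay, NoiseSpec(cv=0.0, floor=0.0, seed=0),
        )
        data = generate_timecourse(scenario)
        fit_config = replace(config, seed=int(rng.integers(2**31)))
        result = None
        try:
            result = fit_pso(network, [(assay, data)], fit_config)
        except (RuntimeError, IntegrationError):
            pass
        failed = result is None
        true_vec = true.to_vector()
        est_vec = (
            result.best_params.to_vector()
            if result is not None
            else np.full_like(true_vec, np.nan)
        )
        for i, name in enumerate(names):
            rows.append(
                {
                    "draw": draw,
                    "parameter": name,
                    "true": true_vec[i],
                    "estimated": est_vec[i],
                    "rel_error": abs(est_vec[i] - true_vec[i]) / abs(true_vec[i]),
                    "objective": result.objective_value if not failed else np.nan,
                    "failed": failed,
                }
            )
    return pd.DataFrame(rows)


def in_vivo_scenario(with_cyclase: bool = False, seed: int = 0) -> ScenarioPreset:
    """In-vivo-like preset: constant phytoene influx, optional cyclisation.

    The network is the extended 5-step chain (through didehydrolycopene);
    with the cyclase on, branches drain lycopene (-> gamma- -> beta-carotene)
    and didehydrolycopene (-> torulene).  Exploratory only — excluded from
    fitting.
    """
    branches = None
    if with_cyclase:
        branches = [
            ("lycopene", "gamma-carotene", 0.002, 1.0),
            ("gamma-carotene", "beta-carotene", 0.002, 1.0),
            ("didehydrolycopene", "torulene", 0.002, 1.0),
        ]
    network = build_network(5, extended=True, branch_spec=branches)
    params = KineticParameters(
        k_f=[0.5] * 6, k_r=[5.0] * 6, k_cat=[0.05, 0.04, 0.03, 0.02, 0.005]
    )
    assay = AssaySpec(
        initial_phytoene=1.0,
        enzyme_total=enzyme_micromolar(),
        sampling_times=tuple(np.linspace(0, 48 * 60, 25)),
    )
    return ScenarioPreset(
        label="in_vivo_cyclase" if with_cyclase else "in_vivo_plain",
        true_params=params,
        assay=assay,
        noise=NoiseSpec(cv=0.0, floor=0.0, seed=seed),
        network=network,
        phytoene_influx=2e-4,
    )
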