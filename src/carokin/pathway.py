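"""Carotene species registry and the mass-action desaturation network.

The network couples a chain of carotene species S_0..S_n (phytoene up to
tetradehydrolycopene) to a single multifunctional desaturase E through one
enzyme-ligand complex per chain species:

    E + S_i  <-> ES_i          (k_f[i], k_r[i])       i = 0..n
    ES_i      -> E + S_{i+1}   (k_cat[i])             i = 0..n-1

The terminal complex ES_n has no catalytic outflow (dead-end product
inhibition).  The mechanism is distributive: every turnover releases the
product, which re-binds through its own equilibrium.  Optional irreversible
cyclisation branches (Michaelis-Menten rate laws with per-branch Vmax/Km)
drain chain species into cyclised pools in "extended" mode.

Internal units are µM and seconds throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "CaroteneSpecies",
    "CyclisationBranch",
    "KineticParameters",
    "ReactionNetwork",
    "SystemState",
    "CHAIN_SPECIES_NAMES",
    "CYCLISED_SPECIES",
    "species_registry",
    "build_network",
    "rhs",
    "conservation_residuals",
]


class NetworkError(ValueError):
    """Raised for invalid network construction requests."""


class UnknownSpeciesError(KeyError):
    """Raised when a referenced species is not part of the network."""


#: Acyclic desaturation chain, ordered by number of added double bonds.
CHAIN_SPECIES_NAMES: tuple[str, ...] = (
    "phytoene",
    "phytofluene",
    "zeta-carotene",
    "neurosporene",
    "lycopene",
    "didehydrolycopene",
    "tetradehydrolycopene",
)

#: Cyclised species: name -> (canonical source, desaturation_index, cycle_count).
CYCLISED_SPECIES: dict[str, tuple[str, int, int]] = {
    "beta-zeacarotene": ("neurosporene", 3, 1),
    "dihydro-beta-carotene": ("beta-zeacarotene", 3, 2),
    "gamma-carotene": ("lycopene", 4, 1),
    "beta-carotene": ("gamma-carotene", 4, 2),
    "torulene": ("didehydrolycopene", 5, 1),
    "dehydro-beta-carotene": ("torulene", 5, 2),
}


@dataclass(frozen=True)
class CaroteneSpecies:
    """A carotene identified by its desaturation and cyclisation state."""

    name: str
    desaturation_index: int
    cycle_count: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.desaturation_index <= 6:
            raise ValueError(
                f"desaturation_index must be in 0..6, got {self.desaturation_index}"
            )
        if self.cycle_count not in (0, 1, 2):
            raise ValueError(f"cycle_count must be 0, 1 or 2, got {self.cycle_count}")


def species_registry() -> dict[str, CaroteneSpecies]:
    """All known carotenes (chain + cyclised) keyed by name."""
    reg = {
        name: CaroteneSpecies(name, i, 0)
        for i, name in enumerate(CHAIN_SPECIES_NAMES)
    }
    for name, (_, des, cyc) in CYCLISED_SPECIES.items():
        reg[name] = CaroteneSpecies(name, des, cyc)
    return reg


@dataclass(frozen=True)
class CyclisationBranch:
    """Irreversible cyclisation flux source -> product, v = vmax*S/(km+S)."""

    source: str
    product: str
    vmax: float = 0.0  # µM/s
    km: float = 1.0  # µM

    def __post_init__(self) -> None:
        if self.vmax < 0 or self.km <= 0:
            raise ValueError("branch requires vmax >= 0 and km > 0")


@dataclass(frozen=True)
class KineticParameters:
    """Per-step rate constants of the desaturation network.

    Attributes
    ----------
    k_f : binding rate constants, µM^-1 s^-1, one per complex (n+1 values).
    k_r : unbinding rate constants, s^-1, one per complex (n+1 values).
    k_cat : catalytic rate constants, s^-1, one per catalytic step (n values).
    """

    k_f: np.ndarray
    k_r: np.ndarray
    k_cat: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "k_f", np.asarray(self.k_f, dtype=float))
        object.__setattr__(self, "k_r", np.asarray(self.k_r, dtype=float))
        object.__setattr__(self, "k_cat", np.asarray(self.k_cat, dtype=float))
        if self.k_f.ndim != 1 or self.k_r.ndim != 1 or self.k_cat.ndim != 1:
            raise ValueError("rate constants must be 1-D arrays")
        if len(self.k_f) != len(self.k_r):
            raise ValueError("k_f and k_r must have one entry per complex")
        if len(self.k_cat) != len(self.k_f) - 1:
            raise ValueError("k_cat must have one entry per catalytic step (n)")
        if (self.k_f < 0).any() or (self.k_r < 0).any() or (self.k_cat < 0).any():
            raise ValueError("rate constants must be non-negative")

    @property
    def n_steps(self) -> int:
        return len(self.k_cat)

    @property
    def n_parameters(self) -> int:
        return 2 * len(self.k_f) + len(self.k_cat)

    def dissociation_constants(self) -> np.ndarray:
        """K_d[i] = k_r[i]/k_f[i], µM, one per complex."""
        if (self.k_f == 0).any():
            raise ZeroDivisionError("K_d undefined where k_f = 0")
        return self.k_r / self.k_f

    def michaelis_constants(self) -> np.ndarray:
        """K_m[i] = (k_r[i]+k_cat[i])/k_f[i], µM, catalytic steps only."""
        kf = self.k_f[:-1]
        if (kf == 0).any():
            raise ZeroDivisionError("K_m undefined where k_f = 0")
        return (self.k_r[:-1] + self.k_cat) / kf

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.k_f, self.k_r, self.k_cat])

    @classmethod
    def from_vector(cls, vector: np.ndarray, n_steps: int) -> "KineticParameters":
        vector = np.asarray(vector, dtype=float)
        m = n_steps + 1
        if vector.shape != (2 * m + n_steps,):
            raise ValueError(
                f"expected vector of length {2 * m + n_steps}, got {vector.shape}"
            )
        return cls(vector[:m], vector[m : 2 * m], vector[2 * m :])


@dataclass(frozen=True)
class ReactionNetwork:
    """Topology of the desaturation chain with one complex per chain species."""

    species: tuple[CaroteneSpecies, ...]
    branches: tuple[CyclisationBranch, ...] = ()
    enzyme: str = "CrtI"
    extended: bool = False

    @property
    def n_steps(self) -> int:
        return len(self.species) - 1

    @property
    def chain_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    @property
    def branch_product_names(self) -> tuple[str, ...]:
        return tuple(b.product for b in self.branches)

    @property
    def complex_names(self) -> tuple[str, ...]:
        return tuple(f"{self.enzyme}:{s.name}" for s in self.species)

    @property
    def observable_names(self) -> tuple[str, ...]:
        """Carotene species reported by the observable convention."""
        return self.chain_names + self.branch_product_names

    # ---- state-vector layout: [S_0..S_n, B_0..B_m-1, E, ES_0..ES_n] ----

    @property
    def n_state(self) -> int:
        return 2 * len(self.species) + len(self.branches) + 1

    @property
    def enzyme_index(self) -> int:
        return len(self.species) + len(self.branches)

    @property
    def complex_slice(self) -> slice:
        return slice(self.enzyme_index + 1, self.n_state)

    def state_index(self, name: str) -> int:
        """Index of a free-species, branch-product or enzyme entry."""
        names = self.chain_names + self.branch_product_names + (self.enzyme,)
        try:
            return names.index(name)
        except ValueError:
            raise UnknownSpeciesError(name) from None

    def initial_state(
        self, phytoene: float, enzyme_total: float
    ) -> np.ndarray:
        """All carotene as phytoene, all enzyme free."""
        if phytoene < 0 or enzyme_total < 0:
            raise ValueError("initial concentrations must be non-negative")
        y0 = np.zeros(self.n_state)
        y0[0] = phytoene
        y0[self.enzyme_index] = enzyme_total
        return y0

    def carotene_total(self, y: np.ndarray) -> np.ndarray:
        """Total carotene backbone: free chain + branch products + complexes."""
        y = np.atleast_2d(y)
        n_car = len(self.species) + len(self.branches)
        return y[:, :n_car].sum(axis=1) + y[:, self.complex_slice].sum(axis=1)

    def enzyme_total_of(self, y: np.ndarray) -> np.ndarray:
        y = np.atleast_2d(y)
        return y[:, self.enzyme_index] + y[:, self.complex_slice].sum(axis=1)

    def stoichiometry_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Column-per-reaction stoichiometry over the full state vector.

        Binding reactions are returned in their forward direction; the
        reverse direction is the negated column and conserves trivially.
        """
        n_sp = len(self.species)
        cols: list[np.ndarray] = []
        labels: list[str] = []
        e = self.enzyme_index
        for i in range(n_sp):
            col = np.zeros(self.n_state)
            col[i] -= 1.0
            col[e] -= 1.0
            col[e + 1 + i] += 1.0
            cols.append(col)
            labels.append(f"bind[{i}]")
        for i in range(n_sp - 1):
            col = np.zeros(self.n_state)
            col[e + 1 + i] -= 1.0
            col[e] += 1.0
            col[i + 1] += 1.0
            cols.append(col)
            labels.append(f"cat[{i}]")
        names = self.chain_names + self.branch_product_names
        for b in self.branches:
            col = np.zeros(self.n_state)
            col[names.index(b.source)] -= 1.0
            col[names.index(b.product)] += 1.0
            cols.append(col)
            labels.append(f"cyclise[{b.source}->{b.product}]")
        return np.column_stack(cols), labels

    def summary(self) -> str:
        """Plain-text reaction listing with rate expressions."""
        lines = [f"# desaturation network: {self.n_steps} catalytic steps"]
        e = self.enzyme
        for i, s in enumerate(self.species):
            lines.append(
                f"{e} + {s.name} <-> {e}:{s.name}"
                f"    v = k_f[{i}]*[{e}]*[{s.name}] - k_r[{i}]*[{e}:{s.name}]"
            )
        for i in range(self.n_steps):
            prod = self.species[i + 1].name
            lines.append(
                f"{e}:{self.species[i].name} -> {e} + {prod}"
                f"    v = k_cat[{i}]*[{e}:{self.species[i].name}]"
            )
        for b in self.branches:
            lines.append(
                f"{b.source} -> {b.product}"
                f"    v = {b.vmax}*[{b.source}]/({b.km}+[{b.source}])"
            )
        return "\n".join(lines)

    def with_branch_rates(
        self, rates: Mapping[str, tuple[float, float]]
    ) -> "ReactionNetwork":
        """Return a copy with (vmax, km) set per branch product name."""
        new = []
        for b in self.branches:
            if b.product in rates:
                vmax, km = rates[b.product]
                new.append(replace(b, vmax=vmax, km=km))
            else:
                new.append(b)
        return replace(self, branches=tuple(new))


@dataclass
class SystemState:
    """Snapshot of the full concentration vector at one time point."""

    y: np.ndarray
    time: float = 0.0  # seconds

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if (self.y < 0).any():
            raise ValueError("concentrations must be non-negative")


def _resolve_branch(
    item: Sequence, chain: tuple[str, ...]
) -> CyclisationBranch:
    if isinstance(item, CyclisationBranch):
        branch = item
    elif len(item) == 2:
        branch = CyclisationBranch(item[0], item[1])
    elif len(item) == 4:
        branch = CyclisationBranch(item[0], item[1], float(item[2]), float(item[3]))
    else:
        raise NetworkError(f"branch spec must be (source, product[, vmax, km]): {item!r}")
    return branch


def build_network(
    n_steps: int = 4,
    extended: bool = False,
    branch_spec: Iterable | None = None,
) -> ReactionNetwork:
    """Construct the desaturation network with ``n_steps`` catalytic steps.

    The default 4-step chain runs phytoene -> lycopene; extended mode may
    lengthen the chain (up to 6 steps, tetradehydrolycopene) and/or attach
    irreversible cyclisation branches.

    Parameters
    ----------
    n_steps : number of catalytic desaturation steps (1..6).
    extended : enable chain steps 5-6 and cyclisation branches.
    branch_spec : iterable of ``(source, product)`` or
        ``(source, product, vmax, km)`` tuples; requires ``extended``.
    """
    if n_steps < 1:
        raise NetworkError(f"n_steps must be >= 1, got {n_steps}")
    if n_steps > 6:
        raise NetworkError(f"the chain has at most 6 desaturation steps, got {n_steps}")
    if n_steps > 4 and not extended:
        raise NetworkError("chains beyond lycopene (n_steps > 4) require extended mode")
    if branch_spec and not extended:
        raise NetworkError("cyclisation branches require extended mode")

    chain = tuple(
        CaroteneSpecies(name, i, 0)
        for i, name in enumerate(CHAIN_SPECIES_NAMES[: n_steps + 1])
    )
    chain_names = tuple(s.name for s in chain)

    branches: list[CyclisationBranch] = []
    if branch_spec:
        for item in branch_spec:
            branches.append(_resolve_branch(item, chain_names))
        known = set(chain_names)
        for b in branches:
            if b.source not in known:
                raise UnknownSpeciesError(
                    f"branch source {b.source!r} is not in the network"
                )
            known.add(b.product)
    return ReactionNetwork(species=chain, branches=tuple(branches), extended=extended)


def _rhs_core(
    y: np.ndarray,
    network: ReactionNetwork,
    params: KineticParameters,
    influx: float = 0.0,
) -> np.ndarray:
    """Unchecked mass-action derivative; layout per ReactionNetwork."""
    n_sp = len(network.species)
    n_br = len(network.branches)
    e = network.enzyme_index
    E = y[e]
    S = y[:n_sp]
    ES = y[e + 1 :]

    bind = params.k_f * E * S - params.k_r * ES  # net binding flux per complex
    cat = params.k_cat * ES[:-1]  # catalytic flux per step

    dy = np.zeros_like(y)
    dy[:n_sp] = -bind
    dy[1:n_sp] += cat
    dy[e + 1 :] = bind
    dy[e + 1 : e + 1 + n_sp - 1] -= cat
    dy[e] = -bind.sum() + cat.sum()
    dy[0] += influx

    if n_br:
        names = network.chain_names + network.branch_product_names
        for k, b in enumerate(network.branches):
            src = names.index(b.source)
            v = b.vmax * y[src] / (b.km + y[src])
            dy[src] -= v
            dy[n_sp + k] += v
    return dy


def rhs(
    state: SystemState | np.ndarray,
    params: KineticParameters,
    network: ReactionNetwork,
    influx: float = 0.0,
) -> np.ndarray:
    """Mass-action time derivative of the full state vector, µM/s.

    Raises
    ------
    ValueError : on dimension mismatch or negative concentrations.
    """
    y = state.y if isinstance(state, SystemState) else np.asarray(state, dtype=float)
    if y.shape != (network.n_state,):
        raise ValueError(
            f"state has shape {y.shape}, network expects ({network.n_state},)"
        )
    if len(params.k_f) != len(network.species):
        raise ValueError("parameter dimensions do not match the network")
    if (y < 0).any():
        raise ValueError("negative concentration in state")
    return _rhs_core(y, network, params, influx=influx)


def conservation_residuals(
    trajectory: np.ndarray | Sequence[SystemState],
    network: ReactionNetwork,
) -> tuple[float, float]:
    """Max relative drift of (total carotene, total enzyme) along a trajectory."""
    if isinstance(trajectory, np.ndarray):
        ys = np.atleast_2d(trajectory)
    else:
        states = list(trajectory)
        if not states:
            raise ValueError("empty trajectory")
        ys = np.vstack([s.y for s in states])
    car = network.carotene_total(ys)
    enz = network.enzyme_total_of(ys)
    if car[0] <= 0 or enz[0] <= 0:
        raise ZeroDivisionError("initial conserved totals must be positive")
    car_drift = float(np.max(np.abs(car - car[0])) / car[0])
    enz_drift = float(np.max(np.abs(enz - enz[0])) / enz[0])
    return car_drift, enz_drift
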