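"""Exact stochastic simulation (Gillespie direct method) of a ReactionNetwork.

Propensity model
----------------
Unimolecular reactions fire at ``k * N``.  Bimolecular reactions fire at
``k_eff * N_A * N_B`` (``k_eff * N * (N-1) / 2`` for identical reactants)
with

    k_eff = base_k * sqrt(T / mu) / V * T_mult * C_mult

where ``mu`` is the reduced mass of the reactants (collision-theory
prefactor; masses default to nuclearity x ``mass_per_mo``), ``T_mult`` is
the template acceleration (``template_factor``, default 10.0, applied while
at least one template molecule is present), and ``C_mult`` is the
completion bias ``1 + k_nano / (1 + free_sites(product))`` favouring
products with few free bonding sites.  Model units set k_B = 1.

The production integrator is a numba-compiled direct-method loop; a pure
Python reference stepper (:func:`step`) implements the identical dynamics
and backs the unit tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from .network import Reaction, ReactionNetwork, Species

__all__ = [
    "RateParams",
    "SimState",
    "Trajectory",
    "EnsembleResult",
    "CompiledNetwork",
    "effective_rate_constant",
    "propensity",
    "step",
    "run",
    "run_ensemble",
]

COMPLETION_FORMS = ("hyperbolic", "exponential")
TEMPLATE_MODES = ("presence", "proportional")


@dataclass(frozen=True)
class RateParams:
    """All tunable model parameters (phenomenological units, k_B = 1).

    D is the corner : edge dimerization-rate ratio (the model's proxy for
    pH / reduction potential); k_nano the completion-bias strength; k_d the
    small degradation constant of the stable giant clusters.
    """

    k_uni_default: float = 1.0
    k_bi_base: float = 5.0
    D: float = 1.0
    k_nano: float = 1000.0
    template_factor: float = 10.0
    k_d: float = 0.05
    temperature: float = 1.0
    volume: float = 1.0
    mass_per_mo: float = 1.0
    template_mode: str = "presence"
    completion_form: str = "hyperbolic"

    def __post_init__(self) -> None:
        for name in ("k_uni_default", "k_bi_base", "temperature", "volume", "mass_per_mo"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.D <= 0:
            raise ValueError("D must be > 0")
        if self.k_nano < 0:
            raise ValueError("k_nano must be >= 0")
        if self.k_d < 0:
            raise ValueError("k_d must be >= 0")
        if self.template_factor < 1:
            raise ValueError("template_factor must be >= 1")
        if self.template_mode not in TEMPLATE_MODES:
            raise ValueError(f"template_mode must be one of {TEMPLATE_MODES}")
        if self.completion_form not in COMPLETION_FORMS:
            raise ValueError(f"completion_form must be one of {COMPLETION_FORMS}")

    def replace(self, **kw) -> "RateParams":
        return replace(self, **kw)


def _species_mass(sp: Species, params: RateParams) -> float:
    return sp.mass if sp.mass is not None else sp.nuclearity * params.mass_per_mo


def completion_multiplier(free_sites: int, params: RateParams) -> float:
    """Bias toward products with few free bonding sites (1 when k_nano=0)."""
    if params.completion_form == "hyperbolic":
        return 1.0 + params.k_nano / (1.0 + free_sites)
    return 1.0 + params.k_nano * math.exp(-float(free_sites))


def effective_rate_constant(
    reaction: Reaction,
    network: ReactionNetwork,
    params: RateParams,
    counts: Mapping[str, int] | None = None,
) -> float:
    """Effective rate constant of one reaction.

    For bimolecular synthesis this includes the collision prefactor
    sqrt(T/mu)/V, the completion bias of the product, and (when ``counts``
    shows the template present) the template acceleration.
    """
    if reaction.plain_rate or reaction.kind == "degradation":
        return reaction.base_k
    idx = network.species_by_id
    a, b = (idx[s] for s in reaction.reactants)
    ma, mb = _species_mass(a, params), _species_mass(b, params)
    mu = ma * mb / (ma + mb)
    k = reaction.base_k * math.sqrt(params.temperature / mu) / params.volume
    prod = idx[reaction.products[0]]
    # completion bias applies only to products whose completion is defined
    # (assembly-path species and targets); amorphous aggregates have no
    # countable missing pieces
    if prod.is_target or prod.lineage != "generic":
        k *= completion_multiplier(prod.free_sites, params)
    if reaction.template_id is not None and counts is not None:
        tc = counts.get(reaction.template_id, 0)
        if tc >= 1:
            if params.template_mode == "presence":
                k *= params.template_factor
            else:
                k *= 1.0 + (params.template_factor - 1.0) * tc
    return k


def propensity(
    reaction: Reaction,
    counts: Mapping[str, int],
    network: ReactionNetwork,
    params: RateParams,
) -> float:
    """Mass-action propensity of one reaction in a given state."""
    k = effective_rate_constant(reaction, network, params, counts)
    if len(reaction.reactants) == 1:
        return k * counts.get(reaction.reactants[0], 0)
    a, b = reaction.reactants
    if a == b:
        n = counts.get(a, 0)
        return k * n * (n - 1) / 2.0
    return k * counts.get(a, 0) * counts.get(b, 0)


# ---------------------------------------------------------------------------
# compiled representation
# ---------------------------------------------------------------------------


class CompiledNetwork:
    """Array form of (network, params) consumed by the integrators."""

    def __init__(self, network: ReactionNetwork, params: RateParams) -> None:
        self.network = network
        self.params = params
        self.species_ids = network.species_ids()
        self.sindex = {sid: i for i, sid in enumerate(self.species_ids)}
        self.nuclearity = np.array(
            [sp.nuclearity for sp in network.species], dtype=np.int64
        )
        R = len(network.reactions)
        self.r_type = np.zeros(R, dtype=np.int8)  # 0 uni, 1 bi distinct, 2 bi same
        self.i1 = np.zeros(R, dtype=np.int64)
        self.i2 = np.zeros(R, dtype=np.int64)
        self.d_idx = np.zeros((R, 3), dtype=np.int64)
        self.d_val = np.zeros((R, 3), dtype=np.int64)
        self.k_static = np.zeros(R, dtype=np.float64)
        self.t_idx = np.full(R, -1, dtype=np.int64)
        for r, rx in enumerate(network.reactions):
            # static part of k_eff: everything except template presence
            self.k_static[r] = effective_rate_constant(rx, network, params, None)
            deltas: dict[int, int] = {}
            for s in rx.reactants:
                deltas[self.sindex[s]] = deltas.get(self.sindex[s], 0) - 1
            for s in rx.products:
                deltas[self.sindex[s]] = deltas.get(self.sindex[s], 0) + 1
            for j, (si, dv) in enumerate(deltas.items()):
                self.d_idx[r, j] = si
                self.d_val[r, j] = dv
            if len(rx.reactants) == 1:
                self.r_type[r] = 0
                self.i1[r] = self.sindex[rx.reactants[0]]
            else:
                a, b = rx.reactants
                self.i1[r] = self.sindex[a]
                self.i2[r] = self.sindex[b]
                self.r_type[r] = 2 if a == b else 1
            if rx.template_id is not None and not rx.plain_rate:
                self.t_idx[r] = self.sindex[rx.template_id]
        self.t_mode = 0 if params.template_mode == "presence" else 1
        self.tfac = params.template_factor

    def counts_vector(self, init_counts: Mapping[str, int]) -> np.ndarray:
        v = np.zeros(len(self.species_ids), dtype=np.int64)
        for sid, n in init_counts.items():
            if sid not in self.sindex:
                raise KeyError(f"unknown species {sid!r} in initial counts")
            if n < 0:
                raise ValueError(f"negative initial count for {sid!r}")
            v[self.sindex[sid]] = n
        return v

    def propensities(self, counts: np.ndarray) -> np.ndarray:
        """Vectorized propensities for one state (reference path)."""
        c1 = counts[self.i1].astype(np.float64)
        c2 = counts[self.i2].astype(np.float64)
        a = np.where(
            self.r_type == 0,
            c1,
            np.where(self.r_type == 1, c1 * c2, c1 * (c1 - 1) * 0.5),
        ) * self.k_static
        has_t = self.t_idx >= 0
        if has_t.any():
            tc = counts[np.where(has_t, self.t_idx, 0)]
            if self.t_mode == 0:
                mult = np.where(has_t & (tc >= 1), self.tfac, 1.0)
            else:
                mult = np.where(has_t & (tc >= 1), 1.0 + (self.tfac - 1.0) * tc, 1.0)
            a = a * mult
        return a


# ---------------------------------------------------------------------------
# states and results
# ---------------------------------------------------------------------------


@dataclass
class SimState:
    """Instantaneous simulation state (counts indexed like the compiled net)."""

    time: float
    counts: np.ndarray

    def as_dict(self, compiled: CompiledNetwork) -> dict[str, int]:
        return {
            sid: int(self.counts[i]) for sid, i in compiled.sindex.items()
        }


@dataclass
class Trajectory:
    """Species counts sampled on a fixed time grid."""

    grid: np.ndarray
    counts: np.ndarray  # species x time
    species_ids: list[str]
    events: int
    seed: int
    truncated: bool = False

    def series(self, species_id: str) -> np.ndarray:
        return self.counts[self.species_ids.index(species_id)]

    def mass(self, nuclearity: np.ndarray) -> np.ndarray:
        return nuclearity @ self.counts

    def to_dataframe(self, replicate: int | None = None) -> "pd.DataFrame":
        import pandas as pd

        frames = []
        for i, sid in enumerate(self.species_ids):
            frames.append(
                pd.DataFrame(
                    {
                        "time": self.grid,
                        "species": sid,
                        "count": self.counts[i],
                    }
                )
            )
        df = pd.concat(frames, ignore_index=True)
        if replicate is not None:
            df["replicate"] = replicate
        return df


@dataclass
class EnsembleResult:
    """Replicate-averaged simulation summaries."""

    species_ids: list[str]
    grid: np.ndarray
    n_replicates: int
    seeds: list[int]
    mean: np.ndarray  # species x time
    var: np.ndarray
    time_averaged_abundance: dict[str, float]
    time_avg_per_rep: np.ndarray  # replicate x species
    window: tuple[float, float]

    def mean_series(self, species_id: str) -> np.ndarray:
        return self.mean[self.species_ids.index(species_id)]

    def sem_time_avg(self, species_id: str) -> float:
        """Standard error of the replicate time-averaged abundance."""
        col = self.time_avg_per_rep[:, self.species_ids.index(species_id)]
        if len(col) < 2:
            return float("nan")
        return float(np.std(col, ddof=1) / math.sqrt(len(col)))


# ---------------------------------------------------------------------------
# integrators
# ---------------------------------------------------------------------------


@njit(cache=True)
def _ssa_kernel(
    seed, horizon, grid, counts0,
    r_type, i1, i2, d_idx, d_val, k_static, t_idx, tfac, t_mode,
    max_events,
):  # pragma: no cover - exercised via run()
    np.random.seed(seed)
    S = counts0.shape[0]
    G = grid.shape[0]
    R = r_type.shape[0]
    counts = counts0.copy()
    out = np.zeros((S, G), dtype=np.int64)
    props = np.empty(R, dtype=np.float64)
    t = 0.0
    g = 0
    events = 0
    truncated = False
    while True:
        total = 0.0
        for r in range(R):
            c1 = counts[i1[r]]
            if r_type[r] == 0:
                a = k_static[r] * c1
            elif r_type[r] == 1:
                a = k_static[r] * c1 * counts[i2[r]]
            else:
                a = k_static[r] * c1 * (c1 - 1) * 0.5
            if a > 0.0 and t_idx[r] >= 0:
                tc = counts[t_idx[r]]
                if tc >= 1:
                    if t_mode == 0:
                        a *= tfac
                    else:
                        a *= 1.0 + (tfac - 1.0) * tc
            props[r] = a
            total += a
        if total <= 0.0:
            break
        t_new = t + np.random.exponential(1.0 / total)
        while g < G and grid[g] <= t_new:
            out[:, g] = counts
            g += 1
        if t_new > horizon or g >= G:
            t = t_new
            break
        u = np.random.random() * total
        acc = 0.0
        chosen = R - 1
        for r in range(R):
            acc += props[r]
            if u < acc:
                chosen = r
                break
        for j in range(3):
            if d_val[chosen, j] != 0:
                counts[d_idx[chosen, j]] += d_val[chosen, j]
        t = t_new
        events += 1
        if events >= max_events:
            truncated = True
            break
    while g < G:
        out[:, g] = counts
        g += 1
    return out, events, truncated


def step(
    state: SimState,
    compiled: CompiledNetwork | ReactionNetwork,
    params: RateParams | None = None,
    rng: np.random.Generator | None = None,
    horizon: float = math.inf,
) -> tuple[SimState, int | None]:
    """One direct-method event (pure Python reference implementation).

    Returns the advanced state and the fired reaction index, or ``None``
    when total propensity is zero (time then jumps to ``horizon``).
    """
    if isinstance(compiled, ReactionNetwork):
        compiled = CompiledNetwork(compiled, params or RateParams())
    if rng is None:
        rng = np.random.default_rng()
    props = compiled.propensities(state.counts)
    total = float(props.sum())
    if total <= 0.0:
        return SimState(horizon, state.counts.copy()), None
    dt = rng.exponential(1.0 / total)
    u = rng.random() * total
    chosen = int(np.searchsorted(np.cumsum(props), u, side="right"))
    chosen = min(chosen, len(props) - 1)
    counts = state.counts.copy()
    for j in range(3):
        dv = compiled.d_val[chosen, j]
        if dv != 0:
            counts[compiled.d_idx[chosen, j]] += dv
    if (counts < 0).any():  # pragma: no cover - must be unreachable
        raise RuntimeError("negative count after update")
    return SimState(state.time + dt, counts), chosen


def _resolve_grid(horizon: float, grid) -> np.ndarray:
    if grid is None:
        grid = 201
    if np.isscalar(grid):
        return np.linspace(0.0, horizon, int(grid))
    g = np.asarray(grid, dtype=float)
    if g.ndim != 1 or len(g) < 1 or (np.diff(g) <= 0).any() or g[-1] > horizon:
        raise ValueError("grid must be 1-D, strictly increasing, within horizon")
    return g


def run(
    network: ReactionNetwork | CompiledNetwork,
    params: RateParams | None = None,
    init_counts: Mapping[str, int] | None = None,
    horizon: float = 10.0,
    grid=None,
    seed: int = 0,
    backend: str = "numba",
    max_events: int = 50_000_000,
    check_mass: bool = True,
) -> Trajectory:
    """Simulate one trajectory; deterministic given (config, seed, backend)."""
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    if isinstance(network, CompiledNetwork):
        compiled = network
    else:
        compiled = CompiledNetwork(network, params or RateParams())
    if init_counts is None:
        raise ValueError("init_counts required")
    c0 = compiled.counts_vector(init_counts)
    g = _resolve_grid(horizon, grid)
    seed = int(seed) % (2**31)
    if backend == "numba":
        counts, events, truncated = _ssa_kernel(
            seed, float(horizon), g, c0,
            compiled.r_type, compiled.i1, compiled.i2,
            compiled.d_idx, compiled.d_val, compiled.k_static,
            compiled.t_idx, float(compiled.tfac), compiled.t_mode,
            max_events,
        )
    elif backend == "python":
        rng = np.random.default_rng(seed)
        state = SimState(0.0, c0.copy())
        counts = np.zeros((len(c0), len(g)), dtype=np.int64)
        gi = 0
        events = 0
        truncated = False
        while True:
            new_state, fired = step(state, compiled, rng=rng, horizon=horizon)
            while gi < len(g) and g[gi] <= new_state.time:
                counts[:, gi] = state.counts
                gi += 1
            if fired is None or new_state.time > horizon or gi >= len(g):
                state = new_state
                break
            state = new_state
            events += 1
            if events >= max_events:
                truncated = True
                break
        while gi < len(g):
            counts[:, gi] = state.counts
            gi += 1
    else:
        raise ValueError(f"unknown backend {backend!r}")
    traj = Trajectory(g, counts, compiled.species_ids, int(events), seed, bool(truncated))
    if check_mass:
        masses = traj.mass(compiled.nuclearity)
        if not (masses == masses[0]).all():  # pragma: no cover - kernel guard
            raise RuntimeError("Mo mass not conserved along trajectory")
    return traj


def run_ensemble(
    network: ReactionNetwork | CompiledNetwork,
    params: RateParams | None = None,
    init_counts: Mapping[str, int] | None = None,
    horizon: float = 10.0,
    n_reps: int = 1,
    seed_base: int = 0,
    grid=None,
    window: float = 0.5,
    backend: str = "numba",
    max_events: int = 50_000_000,
) -> EnsembleResult:
    """Replicate ensemble; replicate r uses seed ``seed_base + r``.

    ``window`` is the trailing fraction of the grid used for time averaging
    (default: second half, discarding burn-in).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if isinstance(network, CompiledNetwork):
        compiled = network
    else:
        compiled = CompiledNetwork(network, params or RateParams())
    g = _resolve_grid(horizon, grid)
    S = len(compiled.species_ids)
    mean = np.zeros((S, len(g)))
    m2 = np.zeros((S, len(g)))
    w0 = int(math.floor(len(g) * (1.0 - window)))
    w0 = min(max(w0, 0), len(g) - 1)
    tavg = np.zeros((n_reps, S))
    seeds = [int(seed_base) + r for r in range(n_reps)]
    for r, s in enumerate(seeds):
        traj = run(
            compiled, init_counts=init_counts, horizon=horizon, grid=g,
            seed=s, backend=backend, max_events=max_events,
        )
        x = traj.counts.astype(float)
        delta = x - mean
        mean += delta / (r + 1)
        m2 += delta * (x - mean)
        tavg[r] = x[:, w0:].mean(axis=1)
    var = m2 / n_reps
    time_avg = {
        sid: float(tavg[:, i].mean()) for i, sid in enumerate(compiled.species_ids)
    }
    return EnsembleResult(
        compiled.species_ids, g, n_reps, seeds, mean, var,
        time_avg, tavg, (float(g[w0]), float(g[-1])),
    )
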