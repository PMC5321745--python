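"""Stochastic patch occupancy simulator with annual discrete-time dynamics.

Each year, every occupied patch goes extinct with probability
``1 - exp(-E_i)`` and every empty patch is colonized with probability
``1 - exp(-c*S_i)``, where connectivity ``S_i`` is computed from the
PREVIOUS year's occupancy (synchronous update; a patch flips at most once
per year and there is no within-year rescue).  An optional genotype layer
propagates the frequency of a dispersive genotype: colonized patches
inherit the immigrant-pool frequency of their sources, occupied patches
relax toward it at a configurable mixing rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .capacity import SpomParams, kernel, patch_connectivity
from .landscape import Landscape, OccupancyHistory, QualityIndex
from .genetics import emigrant_freq


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings.

    ``init_occupancy`` is a 0/1 vector or one of the presets
    ``"all-occupied"``, ``"random-p"`` (Bernoulli(p) with ``init_p``) or
    ``"single-patch"``.  ``external_connectivity`` adds a constant to every
    S_i, emulating immigration from outside the simulated network.  The
    seed is mandatory: every run is a pure function of (config, seed).
    """

    params: SpomParams
    years: int = 22
    init_occupancy: str | np.ndarray = "all-occupied"
    init_p: float = 0.5
    seed: int = 0
    track_genetics: bool = False
    init_f: float | np.ndarray = 0.3
    genetic_mixing: float = 0.1
    external_connectivity: float = 0.0

    def __post_init__(self) -> None:
        if self.years < 1:
            raise ValueError("years must be >= 1")


@dataclass(frozen=True)
class SimResult:
    """Simulated history plus per-year summaries and the event log."""

    history: OccupancyHistory
    fraction_occupied: np.ndarray
    extinct_year: int | None
    events: "np.ndarray" = field(repr=False)  # structured: patch, year_from, state_from, event
    f_disp: np.ndarray | None = field(default=None, repr=False)


def _initial_state(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    init = config.init_occupancy
    if isinstance(init, str):
        if init == "all-occupied":
            return np.ones(n, dtype=bool)
        if init == "random-p":
            return rng.random(n) < config.init_p
        if init == "single-patch":
            state = np.zeros(n, dtype=bool)
            state[0] = True
            return state
        raise ValueError(f"unknown init preset {init!r}")
    state = np.asarray(init)
    if state.shape != (n,):
        raise ValueError("init_occupancy vector has wrong length")
    return state.astype(bool)


def extinction_rates(landscape: Landscape, q: QualityIndex, params: SpomParams) -> np.ndarray:
    """Annual extinction rate E_i = e * A_i^-ex * exp(-y*Q_i)."""
    return (params.e * landscape.areas ** (-params.ex)
            * np.exp(-params.y * np.asarray(q.q_tilde, dtype=float)))


def simulate(landscape: Landscape, q: QualityIndex, config: SimConfig) -> SimResult:
    """Run the annual SPOM for ``config.years`` years.

    Returns the full occupancy history (first year is the initial state),
    the per-year fraction occupied, the turnover event log, the first
    all-empty year (if any), and the genotype-frequency trajectory when
    ``track_genetics`` is on.
    """
    rng = np.random.default_rng(config.seed)
    n = landscape.n_patches
    params = config.params
    E = extinction_rates(landscape, q, params)
    P_ext = 1.0 - np.exp(-E)
    A_em = landscape.areas ** params.em
    A_im = landscape.areas ** params.im
    K = kernel(landscape.distance_matrix, params.alpha)
    np.fill_diagonal(K, 0.0)

    state = _initial_state(config, n, rng)
    occ = np.empty((n, config.years), dtype=float)
    occ[:, 0] = state
    track = config.track_genetics
    if track:
        f = np.broadcast_to(np.asarray(config.init_f, dtype=float), (n,)).copy()
        f[~state] = np.nan
        f_traj = np.full((n, config.years), np.nan)
        f_traj[:, 0] = f
    events = []
    for t in range(1, config.years):
        S = A_im * (K @ (state * A_em)) + config.external_connectivity
        P_col = 1.0 - np.exp(-params.c * S)
        u = rng.random(n)
        # monotone coupling: occupied-next iff u >= threshold, with a lower
        # threshold for occupied patches whenever P_ext + P_col <= 1, so
        # elementwise-larger states stay larger under shared random numbers
        new_state = np.where(state, u >= P_ext, u >= 1.0 - P_col)
        events.append((np.arange(n), np.full(n, t - 1), state.astype(int),
                       (state != new_state).astype(int)))
        if track:
            f_em = emigrant_freq(np.nan_to_num(f), params.Delta)
            contrib = K * (state * A_em)[None, :]
            tot = contrib.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                f_pool = np.where(tot > 0, contrib @ f_em / np.maximum(tot, 1e-300), np.nan)
            f_new = f.copy()
            colonized = ~state & new_state
            f_new[colonized] = f_pool[colonized]
            stay = state & new_state & ~np.isnan(f_pool)
            f_new[stay] = ((1 - config.genetic_mixing) * f[stay]
                           + config.genetic_mixing * f_pool[stay])
            f_new[~new_state] = np.nan
            f = f_new
            f_traj[:, t] = f
        state = new_state
        occ[:, t] = state
    frac = occ.mean(axis=0)
    empty_years = np.flatnonzero(frac == 0)
    extinct_year = int(empty_years[0]) if empty_years.size else None
    ev = np.zeros(n * (config.years - 1), dtype=[("patch", int), ("year_from", int),
                                                 ("state_from", int), ("event", int)])
    if events:
        ev["patch"] = np.concatenate([e[0] for e in events])
        ev["year_from"] = np.concatenate([e[1] for e in events])
        ev["state_from"] = np.concatenate([e[2] for e in events])
        ev["event"] = np.concatenate([e[3] for e in events])
    years = np.arange(config.years)
    history = OccupancyHistory(years=years, occupied=occ)
    return SimResult(history=history, fraction_occupied=frac,
                     extinct_year=extinct_year, events=ev,
                     f_disp=f_traj if track else None)


def persistence_experiment(
    landscape: Landscape,
    q: QualityIndex,
    params: SpomParams,
    replicates: int = 200,
    years: int = 100,
    seed: int = 0,
    init_occupancy: str | np.ndarray = "all-occupied",
    external_connectivity: float = 0.0,
    weights: np.ndarray | None = None,
) -> dict:
    """Replicate simulations of one network: persistence probability at the
    horizon and quasi-equilibrium weighted occupancy.

    The quasi-equilibrium p_lambda is averaged over the final third of the
    horizon in the replicates still extant at the horizon.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    from .capacity import build_M, metapop_capacity, p_lambda_series

    if weights is None:
        weights = metapop_capacity(build_M(landscape, q, params)).weights
    rng = np.random.default_rng(seed)
    surviving = 0
    tail = max(1, years // 3)
    tail_means = []
    for _ in range(replicates):
        cfg = SimConfig(params=params, years=years, seed=int(rng.integers(2**31)),
                        init_occupancy=init_occupancy,
                        external_connectivity=external_connectivity)
        res = simulate(landscape, q, cfg)
        if res.fraction_occupied[-1] > 0 and res.extinct_year is None:
            surviving += 1
            pl = p_lambda_series(res.history, weights)
            tail_means.append(float(np.nanmean(pl[-tail:])))
    return {
        "persistence_prob": surviving / replicates,
        "quasi_equilibrium_p_lambda": float(np.mean(tail_means)) if tail_means else np.nan,
        "n_surviving": surviving,
    }
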