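"""Exact stochastic simulation (SSA) and chemical Langevin counterpart.

Trajectories are statistically exact samples of the jump process defined by
the CME; the direct method is used, with the pending reaction re-drawn at
every signal switch (exact by memorylessness).  Ensembles of independent
cells derive per-cell seeds from the scenario's master seed, so runs are
reproducible and invariant to how cells are chunked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .scenarios import Scenario
from .units import RateSet, to_molecules


class ConsistencyError(RuntimeError):
    pass


@dataclass(frozen=True)
class CountTrajectory:
    """Event-compressed molecule-count trajectory of one cell.

    ``times[i]`` is when the state switched to ``states[i]``; the state
    holds until ``times[i+1]`` (left-hold).  Query with :meth:`at` or
    resample on a grid with :meth:`sample`.
    """

    times: np.ndarray
    states: np.ndarray  # (E, S) int64
    species: tuple
    seed: int
    scenario: str

    def __post_init__(self) -> None:
        if self.states.shape[0] != len(self.times):
            raise ValueError("event count mismatch")
        if np.any(self.states < 0):
            raise ConsistencyError("negative molecule count in trajectory")

    def at(self, t: float) -> np.ndarray:
        i = int(np.searchsorted(self.times, t, side="right")) - 1
        if i < 0:
            raise ValueError(f"t={t} before trajectory start")
        return self.states[i]

    def sample(self, times) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        idx = np.clip(np.searchsorted(self.times, times, side="right") - 1, 0, None)
        return self.states[idx]

    def series(self, species: str) -> np.ndarray:
        return self.states[:, self.species.index(species)]


@dataclass(frozen=True)
class EnsembleSummary:
    """Mean and variance across an ensemble of independent cells."""

    times: np.ndarray
    mean: np.ndarray       # (T, S)
    variance: np.ndarray   # (T, S)
    population_size: int
    species: tuple

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError("population size must be >= 1")
        if np.any(self.variance < -1e-9):
            raise ValueError("negative variance")

    def mean_series(self, species: str) -> np.ndarray:
        return self.mean[:, self.species.index(species)]


def _kernel_args(scenario: Scenario, t_max: float | None = None):
    net = scenario.network
    stoich = net.stoichiometry()
    react = net.reactant_orders()
    c = net.stochastic_rate_constants(scenario.context)
    sig_mult = net.signal_flags()
    boundaries = scenario.signal.boundaries.astype(float)
    levels = scenario.signal.levels.astype(float)
    if t_max is not None and t_max < boundaries[-1]:
        # integrate no further than the last requested sample
        k = max(int(np.searchsorted(boundaries, t_max, side="left")), 1)
        boundaries = np.concatenate([boundaries[:k], [max(t_max, boundaries[k - 1])]])
        levels = levels[:k]
    if net.signal_species is None:
        sig_idx = -1
        level_counts = np.zeros(len(levels), dtype=np.int64)
    else:
        sig_idx = net.species_index(net.signal_species)
        level_counts = np.array(
            [to_molecules(lev, scenario.context) for lev in levels], dtype=np.int64)
    x0 = np.asarray(scenario.initial_counts, dtype=np.int64)
    return stoich, react, c, sig_mult, sig_idx, boundaries, levels, level_counts, x0


def ssa_run(scenario: Scenario, cell_index: int = 0, max_events: int = 2_000_000
            ) -> CountTrajectory:
    """One exact SSA trajectory over the scenario's signal."""
    (stoich, react, c, sig_mult, sig_idx, boundaries, levels, level_counts,
     x0) = _kernel_args(scenario)
    seed = scenario.cell_seed(cell_index)
    times, states, n = _kernels.ssa_events(
        stoich, react, c, sig_mult, sig_idx, boundaries, levels, level_counts,
        x0, seed, max_events)
    if n < 0:
        raise ConsistencyError(
            f"event storage overflow (> {max_events} events); raise max_events")
    return CountTrajectory(times=times[:n].copy(), states=states[:n].copy(),
                           species=scenario.network.species, seed=seed,
                           scenario=scenario.name)


def ensemble_counts(scenario: Scenario, n_cells: int, sample_times=None) -> np.ndarray:
    """(n_cells, T, S) copy numbers of independent seeded cells on a grid."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    ts = scenario.sample_times if sample_times is None else np.asarray(sample_times, float)
    args = _kernel_args(scenario, t_max=float(ts[-1]))
    out = np.empty((n_cells, len(ts), scenario.network.n_species), dtype=np.int64)
    for i in range(n_cells):
        out[i] = _kernels.ssa_sample(*args[:5], *args[5:8], ts, args[8],
                                     scenario.cell_seed(i))
    return out


def ensemble_mean(scenario: Scenario, n_cells: int, sample_times=None
                  ) -> EnsembleSummary:
    """Mean/variance over ``n_cells`` independent runs at the grid times."""
    ts = scenario.sample_times if sample_times is None else np.asarray(sample_times, float)
    counts = ensemble_counts(scenario, n_cells, ts)
    return EnsembleSummary(times=ts, mean=counts.mean(axis=0),
                           variance=counts.var(axis=0), population_size=n_cells,
                           species=scenario.network.species)


def snapshot_sample(scenario: Scenario, n_cells: int, t_star: float) -> np.ndarray:
    """Scheme A: independent cells, each observed once at the same time T*.

    Returns an (n_cells, S) array of copy numbers.  ``t_star`` should lie
    beyond the relaxation time of the scenario; that is the caller's call.
    """
    return ensemble_counts(scenario, n_cells, np.array([t_star]))[:, 0, :]


def timeseries_sample(scenario: Scenario, t_star: float, dt: float, n_points: int,
                      cell_index: int = 0) -> np.ndarray:
    """Scheme B: one cell observed at equally spaced times beyond T*.

    Returns an (n_points, S) array sampled at t_star + k*dt.
    """
    ts = t_star + dt * np.arange(n_points)
    if ts[-1] > scenario.signal.t_end + 1e-9:
        raise ValueError("sampling window extends beyond the signal support")
    args = _kernel_args(scenario, t_max=float(ts[-1]))
    return _kernels.ssa_sample(*args[:5], *args[5:8], ts, args[8],
                               scenario.cell_seed(cell_index))


def cle_run(scenario: Scenario, dt: float = 1e-3, sample_times=None,
            n_paths: int = 1, path_offset: int = 0) -> np.ndarray:
    """Euler-Maruyama chemical Langevin paths of the linear model.

    Returns an (n_paths, T, 2) real-valued array.  The drift is linear, so
    the ensemble first moment coincides with the ODE solution; the six
    noise channels carry sqrt-propensity amplitudes with propensity
    arguments clamped at zero.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rates = scenario.rates
    if not isinstance(rates, RateSet):
        raise TypeError("cle_run applies to the linear two-state model")
    fastest = max(rates.kf + rates.ka * scenario.signal.levels.max(),
                  rates.kr + rates.dPm, rates.dP, 1e-300)
    if dt > 0.1 / fastest:
        warnings.warn(
            f"CLE step dt={dt} exceeds a tenth of the fastest timescale "
            f"(1/{fastest:g}); results may be biased", stacklevel=2)
    ts = scenario.sample_times if sample_times is None else np.asarray(sample_times, float)
    boundaries, levels = _kernel_args(scenario, t_max=float(ts[-1]))[5:7]
    ks_mol = rates.ks * scenario.context.molecules_per_micromolar
    x0 = np.asarray(scenario.initial_counts, dtype=float)
    return _kernels.cle_paths(
        boundaries, levels,
        ks_mol, rates.ka, rates.kf, rates.kr, rates.dP, rates.dPm, x0, dt, ts,
        n_paths, scenario.cell_seed(path_offset))
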