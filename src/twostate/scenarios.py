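"""Stimulation protocols, output grids and bundled study scenarios.

Every input used in the analyses is constructed here: the five-level step
protocol A = S*F_i, the doubling fold profiles A1/A2 for fold-change
detection, the logarithmically refined per-interval output grid, and named
scenario presets bundling network variant, rates, signal, initial counts and
seeding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np

from .units import (
    DEFAULT_CONTEXT,
    MediatorRateSet,
    RateSet,
    ReactionNetwork,
    VolumeContext,
    build_mediator_network,
    build_two_state_network,
    to_molecules,
)

#: scale factors of the step protocol, F = (0.01, 0.1, 1, 10, 100)
SIGNAL_SCALE_FACTORS = (0.01, 0.1, 1.0, 10.0, 100.0)

#: S levels of the step protocol on consecutive 50-unit intervals
STEP_LEVELS = (0.0, 1.0, 0.0, 1.0, 2.0, 3.0, 4.0)

INTERVAL_LENGTH = 50.0

#: per-interval output offsets (time units from each interval start)
GRID_OFFSETS = tuple(INTERVAL_LENGTH / 2 ** k for k in (14, 12, 10, 8, 6, 4, 2)) + (25.0, 50.0)


@dataclass(frozen=True)
class StepSignal:
    """Piecewise-constant signal A(t) in uM, half-open intervals [t0, t1)."""

    intervals: tuple  # ((t_start, t_end, level), ...)

    def __post_init__(self) -> None:
        prev_end = None
        for t0, t1, lev in self.intervals:
            if t1 <= t0:
                raise ValueError(f"empty interval [{t0}, {t1})")
            if lev < 0:
                raise ValueError(f"negative signal level {lev}")
            if prev_end is not None and not np.isclose(t0, prev_end):
                raise ValueError("intervals must be contiguous")
            prev_end = t1

    @classmethod
    def from_levels(cls, levels, duration: float = INTERVAL_LENGTH, t_start: float = 0.0
                    ) -> "StepSignal":
        iv, t = [], t_start
        for lev in levels:
            iv.append((t, t + duration, float(lev)))
            t += duration
        return cls(tuple(iv))

    @property
    def t_start(self) -> float:
        return self.intervals[0][0]

    @property
    def t_end(self) -> float:
        return self.intervals[-1][1]

    @property
    def boundaries(self) -> np.ndarray:
        return np.array([iv[0] for iv in self.intervals] + [self.t_end])

    @property
    def levels(self) -> np.ndarray:
        return np.array([iv[2] for iv in self.intervals])

    def level_at(self, t: float) -> float:
        if not (self.t_start <= t < self.t_end):
            raise ValueError(f"t={t} outside signal support [{self.t_start}, {self.t_end})")
        k = int(np.searchsorted(self.boundaries, t, side="right")) - 1
        return float(self.levels[k])

    def scaled(self, factor: float) -> "StepSignal":
        return StepSignal(tuple((t0, t1, lev * factor) for t0, t1, lev in self.intervals))


@dataclass(frozen=True)
class TimeGrid:
    """Output offsets within each stimulation interval."""

    offsets: tuple = GRID_OFFSETS

    def __post_init__(self) -> None:
        arr = np.asarray(self.offsets)
        if not np.all(np.diff(arr) > 0):
            raise ValueError("grid offsets must be strictly increasing")

    def absolute_times(self, signal: StepSignal) -> np.ndarray:
        """Absolute output times over every interval of ``signal``."""
        times = []
        for t0, t1, _ in signal.intervals:
            for off in self.offsets:
                t = t0 + off
                if t <= t1 + 1e-12:
                    times.append(min(t, t1))
        return np.array(times)


def paper_step_signal(Fi: float = 1.0) -> StepSignal:
    """The step protocol A = S*F_i on seven 50-unit intervals.

    S = 0 on [0,50) and [100,150); 1 on [50,100) and [150,200); then 2, 3, 4
    on the last three intervals.  Levels are returned in uM.
    """
    if Fi <= 0:
        raise ValueError(f"scale factor must be positive, got {Fi}")
    return StepSignal.from_levels(np.array(STEP_LEVELS) * Fi)


def fold_profiles(interval: float = INTERVAL_LENGTH, gap: float = 0.0,
                  n_folds: int = 11) -> tuple[StepSignal, StepSignal]:
    """The doubling fold profiles A1 = [2^0 ... 2^10] uM and A2 = 2*A1.

    Both profiles run through their levels on identical consecutive
    stimulation intervals, preceded by one zero-level interval so that a
    pre-stimulus equilibrium exists.  A relaxation ``gap`` (level 0) can be
    inserted between fold steps; the study protocol uses none.
    """
    a1 = [0.0]
    for j in range(n_folds):
        a1.append(2.0 ** j)
        if gap > 0 and j < n_folds - 1:
            a1.append(0.0)
    if gap > 0:
        lv1, t = [], 0.0
        iv1, iv2 = [], []
        for lev in a1:
            dur = interval if lev > 0 or t == 0.0 else gap
            iv1.append((t, t + dur, lev))
            iv2.append((t, t + dur, 2 * lev))
            t += dur
        return StepSignal(tuple(iv1)), StepSignal(tuple(iv2))
    s1 = StepSignal.from_levels(a1, duration=interval)
    return s1, s1.scaled(2.0)


def paper_time_grid() -> TimeGrid:
    """The nine per-interval output offsets, 50/2^14 up to the endpoint."""
    return TimeGrid(GRID_OFFSETS)


@dataclass(frozen=True)
class Scenario:
    """A fully specified run: network, signal, grid, initials and seeding."""

    name: str
    network: ReactionNetwork
    signal: StepSignal
    grid: TimeGrid = field(default_factory=TimeGrid)
    initial_counts: tuple = (60, 6)
    context: VolumeContext = DEFAULT_CONTEXT
    seed: int = 2011
    population_size: int = 1
    rates: object = None  # RateSet | MediatorRateSet for the record

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.initial_counts):
            raise ValueError("initial counts must be non-negative")
        if self.population_size < 1:
            raise ValueError("population size must be >= 1")
        if len(self.initial_counts) != self.network.n_species:
            raise ValueError("initial counts do not match species count")

    def cell_seed(self, cell_index: int) -> int:
        """Per-cell stream seed: master seed plus cell index, mod 2^31."""
        return int((self.seed + cell_index) % (2 ** 31))

    @property
    def sample_times(self) -> np.ndarray:
        return self.grid.absolute_times(self.signal)

    def with_seed(self, seed: int) -> "Scenario":
        return replace(self, seed=int(seed))

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "signal": [list(iv) for iv in self.signal.intervals],
            "grid_offsets": list(self.grid.offsets),
            "initial_counts": list(self.initial_counts),
            "volume": self.context.volume,
            "seed": self.seed,
            "population_size": self.population_size,
        }
        if self.rates is not None:
            d["rates"] = self.rates.to_dict()
            d["network"] = "mediator" if isinstance(self.rates, MediatorRateSet) else "linear"
        return d


SCENARIO_NAMES = (
    "perfect_adaptation",
    "near_perfect",
    "unstimulated",
    "fcd_A1",
    "fcd_A2",
    "mediator_kinase",
    "mediator_trapping",
)


def _linear_initial(rates: RateSet, ctx: VolumeContext) -> tuple:
    # the printed initials: P = 0.1 uM, Pm = 0.01 uM
    return (to_molecules(0.1, ctx), to_molecules(0.01, ctx))


def paper_scenario(name: str, Fi: float = 1.0, seed: int = 2011,
                   population_size: int | None = None,
                   ctx: VolumeContext = DEFAULT_CONTEXT) -> Scenario:
    """Named presets reproducing the study configurations.

    ``perfect_adaptation`` / ``near_perfect``: linear model under the step
    protocol with dP = 0 / 0.01.  ``unstimulated``: the A = 0 control of the
    same length, used for noise floors.  ``fcd_A1`` / ``fcd_A2``: the fold
    profiles.  ``mediator_kinase``: the kinase-signal mediator model;
    ``mediator_trapping``: its (ka1, ka2, ka3) = (1e3, 0.1, 0.1) variant in
    which kinase binding traps P.
    """
    if name not in SCENARIO_NAMES:
        raise KeyError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    if population_size is None:
        population_size = 1

    if name in ("perfect_adaptation", "near_perfect", "unstimulated"):
        rates = RateSet(dP=0.0) if name == "perfect_adaptation" else RateSet()
        net = build_two_state_network(rates)
        signal = paper_step_signal(Fi)
        if name == "unstimulated":
            signal = StepSignal.from_levels([0.0] * len(STEP_LEVELS))
        return Scenario(name=name, network=net, signal=signal,
                        initial_counts=_linear_initial(rates, ctx), context=ctx,
                        seed=seed, population_size=population_size, rates=rates)

    if name in ("fcd_A1", "fcd_A2"):
        rates = RateSet(dP=0.0)
        net = build_two_state_network(rates)
        a1, a2 = fold_profiles()
        return Scenario(name=name, network=net, signal=a1 if name == "fcd_A1" else a2,
                        initial_counts=_linear_initial(rates, ctx), context=ctx,
                        seed=seed, population_size=population_size, rates=rates)

    rates = (MediatorRateSet() if name == "mediator_kinase"
             else MediatorRateSet(ka1=1e3, ka2=0.1, ka3=0.1))
    net = build_mediator_network(rates)
    signal = paper_step_signal(Fi)
    # P, Pm at the uncoupled linear equilibrium; phosphatase D(0) = 0.1 uM;
    # unbound kinase is set by the signal itself, complexes start empty.
    p0 = rates.ks / (rates.dP + rates.dPm * rates.kf / (rates.kr + rates.dPm))
    pm0 = p0 * rates.kf / (rates.kr + rates.dPm)
    init = (to_molecules(p0, ctx), to_molecules(pm0, ctx), 0, to_molecules(0.1, ctx), 0, 0)
    return Scenario(name=name, network=net, signal=signal, initial_counts=init,
                    context=ctx, seed=seed, population_size=population_size, rates=rates)
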