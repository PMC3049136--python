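"""Adaptation metrics, verdicts, and the ergodicity-rupture diagnosis.

Adaptation is quantified per stimulation interval by *sensitivity* (the
largest excursion of the response from its pre-stimulus equilibrium) and
*precision* (how closely the post-stimulus equilibrium returns to the
pre-stimulus one).  Equilibria are trailing-window means over the final
fraction of an interval; the same trailing-window smoothing is applied to
the trace before peak extraction, which suppresses the upward bias a raw
max-of-samples statistic picks up from molecular noise.

The biological-ergodicity question is whether the statistics of one cell
over time match the statistics of a population at one time.  Two sampling
schemes make this operational: (A) many independent cells observed once at
a common time T*, and (B) one cell observed at equally spaced times beyond
T*.  Under a constant signal both histograms converge to the stationary
CME law; under the stepping signal they need not, and adaptation can be a
property of the population mean that almost no single cell displays.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .scenarios import Scenario, StepSignal
from .ssa import ensemble_counts

ADAPTIVE = "adaptive"
NON_RESPONSIVE = "non-responsive"
RESPONSIVE_NON_ADAPTING = "responsive-non-adapting"

#: default trailing-window length as a fraction of the interval length
WINDOW_FRACTION = 0.1


@dataclass(frozen=True)
class AdaptationMetrics:
    """Per-stimulation-interval sensitivity and precision gap."""

    intervals: tuple          # indices into the signal's interval list
    sensitivity: np.ndarray   # |peak - pre-stimulus equilibrium|
    precision_gap: np.ndarray  # |post-stimulus - pre-stimulus equilibrium|
    window: float             # trailing-window length (time units)
    unit: str = "molecules"

    def __post_init__(self) -> None:
        if np.any(self.sensitivity < 0) or np.any(self.precision_gap < 0):
            raise ValueError("metrics must be non-negative")


@dataclass(frozen=True)
class ErgodicityReport:
    """Comparison of the two sampling schemes plus adaptation verdicts."""

    support: np.ndarray
    snapshot_histogram: np.ndarray
    timeseries_histogram: np.ndarray
    distance: float  # total variation
    population_verdict: str
    single_cell_fractions: dict
    noise_floor_single: float
    noise_floor_population: float
    parameters: dict

    def to_dict(self) -> dict:
        return {
            "support": self.support.tolist(),
            "snapshot_histogram": self.snapshot_histogram.tolist(),
            "timeseries_histogram": self.timeseries_histogram.tolist(),
            "distance": float(self.distance),
            "population_verdict": self.population_verdict,
            "single_cell_fractions": {k: float(v) for k, v in self.single_cell_fractions.items()},
            "noise_floor_single": float(self.noise_floor_single),
            "noise_floor_population": float(self.noise_floor_population),
            "parameters": self.parameters,
        }


def trailing_mean(values, times, window: float) -> np.ndarray:
    """Trailing-window mean of a uniformly sampled series."""
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    dt = times[1] - times[0]
    k = max(1, int(round(window / dt)))
    cs = np.concatenate([[0.0], np.cumsum(values)])
    i = np.arange(len(values))
    j = np.maximum(0, i + 1 - k)
    return (cs[i + 1] - cs[j]) / (i + 1 - j)


def adaptation_metrics(times, values, signal: StepSignal,
                       window_frac: float = WINDOW_FRACTION,
                       unit: str = "molecules") -> AdaptationMetrics:
    """Sensitivity and precision per stimulation (non-zero-level) interval.

    ``values`` must be sampled on a uniform grid covering the signal.  The
    trace is smoothed with a trailing mean of length ``window_frac`` times
    the interval length; the pre-stimulus equilibrium is the smoothed value
    at the interval start (a window reaching back into the previous
    interval), the post-stimulus equilibrium the smoothed value at the end.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    idxs, sens, prec = [], [], []
    for k, (t0, t1, lev) in enumerate(signal.intervals):
        if lev == 0:
            continue
        window = window_frac * (t1 - t0)
        if window > (t1 - t0):
            raise ValueError("smoothing window exceeds the interval length")
        sm = trailing_mean(values, times, window)
        i0 = int(np.searchsorted(times, t0 - 1e-9))
        i1 = int(np.searchsorted(times, t1 - 1e-9, side="right")) - 1
        if i0 >= len(times) or times[i0] > t0 + 1e-9 or times[i1] < t1 - 1e-9 - (times[1] - times[0]):
            raise ValueError(f"trace does not cover interval [{t0}, {t1})")
        pre = sm[i0]
        idxs.append(k)
        sens.append(float(np.abs(sm[i0:i1 + 1] - pre).max()))
        prec.append(float(abs(sm[i1] - pre)))
    return AdaptationMetrics(intervals=tuple(idxs), sensitivity=np.array(sens),
                             precision_gap=np.array(prec),
                             window=window_frac * (signal.intervals[0][1] - signal.intervals[0][0]),
                             unit=unit)


def estimate_noise_floor(values, n_sigma: float = 2.0) -> float:
    """Noise floor as ``n_sigma`` standard deviations of an unstimulated trace."""
    return float(n_sigma * np.std(np.asarray(values, dtype=float)))


def adaptation_verdict(metrics: AdaptationMetrics, noise_floor: float) -> dict:
    """Label each interval and the trace as a whole.

    Per interval: *adaptive* if the sensitivity clears the noise floor and
    the precision gap stays within it; *non-responsive* if the sensitivity
    does not clear the floor; *responsive-non-adapting* otherwise.  The
    trace-level ``first_episode`` label is the verdict of the first
    stimulation interval (the canonical step-response test); ``majority``
    is the modal label across intervals.
    """
    if noise_floor < 0:
        raise ValueError("noise floor must be non-negative")
    labels = []
    for s, p in zip(metrics.sensitivity, metrics.precision_gap):
        if s <= noise_floor:
            labels.append(NON_RESPONSIVE)
        elif p <= noise_floor:
            labels.append(ADAPTIVE)
        else:
            labels.append(RESPONSIVE_NON_ADAPTING)
    if not labels:
        raise ValueError("no stimulation intervals to judge")
    majority = max(set(labels), key=labels.count)
    return {"per_interval": labels, "majority": majority, "first_episode": labels[0]}


def _unstimulated(scenario: Scenario) -> Scenario:
    sig = StepSignal(tuple((t0, t1, 0.0) for t0, t1, _ in scenario.signal.intervals))
    return replace(scenario, name=scenario.name + "_unstimulated", signal=sig,
                   seed=scenario.cell_seed(986_527))


def population_study(scenario: Scenario, n_cells: int | None = None,
                     population_size: int | None = None,
                     species: str = "Pm", grid_dt: float = 0.1,
                     window_frac: float = WINDOW_FRACTION) -> dict:
    """Classify single cells and the population mean of one scenario.

    Simulates ``n_cells`` cells on a uniform grid and judges each one,
    plus the mean over the first ``population_size`` of them (default: the
    scenario's population size).  A matched unstimulated ensemble sets the
    noise floors: the single-cell floor is two pooled standard deviations
    of the raw unstimulated trace, the population floor two standard
    deviations of the matched unstimulated population-mean trace.  Returns
    per-cell labels, their fractions, and the population-mean verdict.
    """
    n_cells = n_cells or scenario.population_size
    population_size = min(population_size or scenario.population_size, n_cells)
    ts = np.arange(scenario.signal.t_start, scenario.signal.t_end + grid_dt / 2, grid_dt)
    sp = scenario.network.species_index(species)
    counts = ensemble_counts(scenario, n_cells, ts)[:, :, sp]
    ref = ensemble_counts(_unstimulated(scenario), n_cells, ts)[:, :, sp]
    floor_single = estimate_noise_floor(ref.reshape(-1))
    floor_pop = estimate_noise_floor(ref[:population_size].mean(axis=0))
    cell_verdicts = []
    for i in range(n_cells):
        m = adaptation_metrics(ts, counts[i], scenario.signal, window_frac)
        cell_verdicts.append(adaptation_verdict(m, floor_single))
    pm = adaptation_metrics(ts, counts[:population_size].mean(axis=0),
                            scenario.signal, window_frac)
    pop_verdict = adaptation_verdict(pm, floor_pop)
    labels = [v["first_episode"] for v in cell_verdicts]
    fractions = {lab: labels.count(lab) / n_cells
                 for lab in (ADAPTIVE, NON_RESPONSIVE, RESPONSIVE_NON_ADAPTING)}
    return {
        "cell_verdicts": cell_verdicts,
        "single_cell_fractions": fractions,
        "population_verdict": pop_verdict,
        "noise_floor_single": floor_single,
        "noise_floor_population": floor_pop,
        "population_metrics": pm,
    }


def total_variation(h1: np.ndarray, h2: np.ndarray) -> float:
    return float(0.5 * np.abs(np.asarray(h1, float) - np.asarray(h2, float)).sum())


def compare_sampling_schemes(scenario: Scenario, t_star: float, n: int, dt: float,
                             species: str = "Pm",
                             window_frac: float = WINDOW_FRACTION) -> ErgodicityReport:
    """Build both sampling schemes, histogram them, and judge adaptation.

    Scheme A draws ``n`` independent cells at T*; scheme B samples one cell
    at ``n`` equally spaced times from T*.  Histograms share an integer
    support; the report carries their total-variation distance together
    with the population-mean and single-cell adaptation verdicts of the
    scenario (see :func:`population_study`).
    """
    from .ssa import snapshot_sample, timeseries_sample

    sp = scenario.network.species_index(species)
    snap = snapshot_sample(scenario, n, t_star)[:, sp]
    series = timeseries_sample(replace(scenario, seed=scenario.cell_seed(1_299_709)),
                               t_star, dt, n)[:, sp]
    hi = int(max(snap.max(), series.max()))
    support = np.arange(hi + 1)
    h_a = np.bincount(snap, minlength=hi + 1) / n
    h_b = np.bincount(series, minlength=hi + 1) / n
    if any(lev > 0 for _, _, lev in scenario.signal.intervals):
        study = population_study(scenario, species=species, window_frac=window_frac)
        pop_verdict = study["population_verdict"]["first_episode"]
        fractions = study["single_cell_fractions"]
        floors = (study["noise_floor_single"], study["noise_floor_population"])
    else:  # stationary control: nothing to judge
        pop_verdict, fractions, floors = "stationary", {}, (0.0, 0.0)
    return ErgodicityReport(
        support=support, snapshot_histogram=h_a, timeseries_histogram=h_b,
        distance=total_variation(h_a, h_b),
        population_verdict=pop_verdict,
        single_cell_fractions=fractions,
        noise_floor_single=floors[0],
        noise_floor_population=floors[1],
        parameters={"t_star": t_star, "n": n, "dt": dt, "species": species,
                    "window_frac": window_frac, "seed": scenario.seed},
    )
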