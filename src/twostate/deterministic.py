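"""Deterministic (macroscopic) solutions of the two-state model.

Over each constant-signal interval the concentration vector x = (P, Pm)
obeys the affine-linear system dx/dt = M(A) x + b with

    M(A) = [[-(dP + kf + ka*A),  kr       ],
            [  kf + ka*A,       -(kr + dPm)]],    b = (ks, 0),

whose exact solution is x(t) = x* + exp(M t) (x0 - x*) with x* = -M^{-1} b.
Piecewise-constant signals are handled interval by interval with state
continuity, so no numerical integrator is involved.

At equilibrium,

    P*  = ks (kr + dPm) / (dP kr + dPm (dP + kf + ka A)),
    Pm* = ks (kf + ka A) / (dP kr + dPm (dP + kf + ka A)),

and when dP = 0 the modified-state level Pm* = ks/dPm is independent of the
signal: the system adapts perfectly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .fcd import ResponseMetrics
from .scenarios import StepSignal
from .units import RateSet

SPECIES = ("P", "Pm")


@dataclass(frozen=True)
class Equilibrium:
    """Steady-state concentrations (uM) at a constant signal level."""

    P: float
    Pm: float
    A: float

    def as_array(self) -> np.ndarray:
        return np.array([self.P, self.Pm])


@dataclass(frozen=True)
class ConcTrajectory:
    """Concentration time series (uM) for the two species."""

    times: np.ndarray
    values: np.ndarray  # shape (T, 2), columns (P, Pm)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.times), 2):
            raise ValueError("trajectory shape mismatch")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")

    def series(self, species: str) -> np.ndarray:
        if species not in SPECIES:
            raise KeyError(f"unknown species {species!r}")
        return self.values[:, SPECIES.index(species)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "time": np.repeat(self.times, 2),
            "species": np.tile(SPECIES, len(self.times)),
            "value": self.values.reshape(-1),
            "unit": "uM",
        })


def coefficient_matrix(rates: RateSet, A: float) -> np.ndarray:
    return np.array([
        [-(rates.dP + rates.kf + rates.ka * A), rates.kr],
        [rates.kf + rates.ka * A, -(rates.kr + rates.dPm)],
    ])


def equilibrium(rates: RateSet, A: float) -> Equilibrium:
    """Closed-form steady state at signal level A (uM)."""
    den = rates.dP * rates.kr + rates.dPm * (rates.dP + rates.kf + rates.ka * A)
    if den <= 0:
        raise ZeroDivisionError("equilibrium undefined: zero denominator (all-zero rates)")
    return Equilibrium(
        P=rates.ks * (rates.kr + rates.dPm) / den,
        Pm=rates.ks * (rates.kf + rates.ka * A) / den,
        A=A,
    )


def _segment_solution(rates: RateSet, A: float, x0: np.ndarray, taus: np.ndarray
                      ) -> np.ndarray:
    """Exact solution at offsets ``taus`` from the segment start."""
    M = coefficient_matrix(rates, A)
    b = np.array([rates.ks, 0.0])
    try:
        xs = equilibrium(rates, A).as_array()
        w, V = np.linalg.eig(M)
        if np.abs(w[0] - w[1]) < 1e-10 * max(1.0, np.abs(w).max()):
            raise np.linalg.LinAlgError  # defective/near-defective: fall back
        c = np.linalg.solve(V, x0 - xs)
        out = (V @ (c[:, None] * np.exp(np.multiply.outer(w, taus)))).real.T + xs
        return out
    except (ZeroDivisionError, np.linalg.LinAlgError):
        # degenerate rate sets (e.g. all-zero): step with expm on each offset
        out = np.empty((len(taus), 2))
        for i, tau in enumerate(taus):
            E = scipy.linalg.expm(M * tau)
            # particular solution via integral of expm; handle singular M
            if abs(np.linalg.det(M)) > 1e-300:
                xs = -np.linalg.solve(M, b)
                out[i] = xs + E @ (x0 - xs)
            else:
                # M singular: integrate b through the semigroup numerically
                quad = np.zeros(2)
                n = 200
                for s in np.linspace(0, tau, n, endpoint=False) + tau / (2 * n):
                    quad += scipy.linalg.expm(M * (tau - s)) @ b * (tau / n)
                out[i] = E @ x0 + quad
        return out


def solve_piecewise(rates: RateSet, signal: StepSignal, init, times) -> ConcTrajectory:
    """Exact trajectory of the ODE system over a piecewise-constant signal.

    ``init`` is (P0, Pm0) in uM; ``times`` an increasing array within the
    signal support.  State is continuous across signal switches.
    """
    times = np.asarray(times, dtype=float)
    if times.size and (times[0] < signal.t_start - 1e-12 or times[-1] > signal.t_end + 1e-12):
        raise ValueError("requested times outside signal support")
    x = np.asarray(init, dtype=float)
    if np.any(x < 0):
        raise ValueError("initial concentrations must be non-negative")
    out = np.empty((len(times), 2))
    pos = 0
    for t0, t1, lev in signal.intervals:
        sel = (times >= t0 - 1e-12) & (times <= t1 + 1e-12) if t1 == signal.t_end \
            else (times >= t0 - 1e-12) & (times < t1 - 1e-12)
        taus = times[sel] - t0
        if taus.size:
            out[pos:pos + taus.size] = _segment_solution(rates, lev, x, taus)
            pos += taus.size
        x = _segment_solution(rates, lev, x, np.array([t1 - t0]))[0]
    return ConcTrajectory(times=times, values=out)


def dense_times(signal: StepSignal, per_interval: int = 4000) -> np.ndarray:
    """A dense evaluation grid: ``per_interval`` points in every interval."""
    parts = [np.linspace(t0, t1, per_interval, endpoint=False)
             for t0, t1, _ in signal.intervals]
    return np.concatenate(parts + [np.array([signal.t_end])])


def interval_peaks(traj: ConcTrajectory, signal: StepSignal, species: str = "Pm",
                   responsive_only: bool = True) -> ResponseMetrics:
    """Per-stimulation-interval peak value, peak time and boundary values.

    Peaks should be located on a dense grid (see :func:`dense_times`); the
    nine-point output grid can miss maxima.  With ``responsive_only`` the
    metrics cover the intervals with a non-zero signal level (stimulation
    intervals); otherwise every interval is reported.
    """
    y = traj.series(species)
    t = traj.times
    idxs, peaks, ptimes, pres, ends = [], [], [], [], []
    for k, (t0, t1, lev) in enumerate(signal.intervals):
        if responsive_only and lev == 0:
            continue
        sel = (t >= t0 - 1e-12) & (t <= t1 + 1e-12)
        if not np.any(sel):
            raise ValueError(f"trajectory does not cover interval [{t0}, {t1})")
        seg = y[sel]
        tseg = t[sel]
        imax = int(np.argmax(seg))
        idxs.append(k)
        peaks.append(seg[imax])
        ptimes.append(tseg[imax])
        pres.append(seg[0])
        ends.append(seg[-1])
    return ResponseMetrics(species=species, unit="uM", intervals=tuple(idxs),
                           peaks=np.array(peaks), peak_times=np.array(ptimes),
                           pre_values=np.array(pres), end_values=np.array(ends))


def equilibrium_convergence(rates_near: RateSet, rates_perfect: RateSet,
                            profile: StepSignal) -> list:
    """Per-fold-level equilibrium pairs (A, Pm*_near, Pm*_perfect, gap).

    With increasing fold level the signal term dominates the equilibrium
    denominator and the near-perfect steady states converge onto the
    perfect-adaptation value Pm* = ks/dPm.
    """
    out = []
    for _, _, lev in profile.intervals:
        if lev == 0:
            continue
        e_near = equilibrium(rates_near, lev)
        e_perf = equilibrium(rates_perfect, lev)
        out.append((lev, e_near.Pm, e_perf.Pm, abs(e_near.Pm - e_perf.Pm)))
    return out
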