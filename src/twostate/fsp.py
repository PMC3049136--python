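"""Finite state projection (FSP) solution of the chemical master equation.

The CME of the linear two-state model evolves the probability p_{n,m}(t) of
holding n copies of P and m copies of Pm.  Restricting to the rectangle
0 <= n <= MP, 0 <= m <= MPm yields a finite linear system dp/dt = G p whose
solution is a matrix exponential; with piecewise-constant signals one
generator per signal level suffices and the solution is exact within the
projection.  Diagonal entries of G retain the *full* outflow of each state,
so probability transitioning out of the rectangle is lost and 1 - sum(p)
bounds the truncation error: retained mass is the solution's certificate.

Columns of G sum to zero for interior states and to a negative value only
on the truncation boundary (convention dp/dt = G p; the alternative
row-convention describes the transposed operator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import expm_multiply

from .scenarios import StepSignal
from .units import DEFAULT_CONTEXT, RateSet, VolumeContext

_NEG_FLOOR = -1e-12


class TruncationError(RuntimeError):
    """Raised when retained probability mass falls below the threshold."""

    def __init__(self, time: float, mass: float, threshold: float):
        self.time, self.mass, self.threshold = time, mass, threshold
        super().__init__(
            f"FSP mass {mass:.6f} below threshold {threshold} at t={time:g}; "
            "enlarge the state-space bounds or lower mass_threshold"
        )


@dataclass(frozen=True)
class StateSpace:
    """Rectangular truncation bounds: P in [0, MP], Pm in [0, MPm]."""

    max_p: int = 110
    max_pm: int = 30

    def __post_init__(self) -> None:
        if self.max_p < 0 or self.max_pm < 0:
            raise ValueError("state-space bounds must be non-negative")

    @property
    def n_states(self) -> int:
        return (self.max_p + 1) * (self.max_pm + 1)


def state_index(i: int, j: int, space: StateSpace) -> int:
    """1-based enumeration of state (i copies of P, j copies of Pm).

    States are numbered j*(MP+1) + i + 1, rows of constant Pm laid out
    consecutively.
    """
    if not (0 <= i <= space.max_p and 0 <= j <= space.max_pm):
        raise ValueError(f"state ({i}, {j}) outside {space}")
    return j * (space.max_p + 1) + i + 1


def state_of_index(index: int, space: StateSpace) -> tuple[int, int]:
    """Inverse of :func:`state_index`."""
    if not (1 <= index <= space.n_states):
        raise ValueError(f"index {index} outside 1..{space.n_states}")
    j, i = divmod(index - 1, space.max_p + 1)
    return i, j


@dataclass(frozen=True)
class ProbabilityVector:
    """Probability mass over the enumerated states at one time point."""

    time: float
    p: np.ndarray
    space: StateSpace

    def __post_init__(self) -> None:
        if self.p.shape != (self.space.n_states,):
            raise ValueError("probability vector length mismatch")
        if self.p.min() < _NEG_FLOOR or self.p.sum() > 1 + 1e-9:
            raise ValueError("invalid probability vector")

    @property
    def mass(self) -> float:
        return float(self.p.sum())

    def grid(self) -> np.ndarray:
        """(MPm+1, MP+1) array, entry [m, n] = P(n copies of P, m of Pm)."""
        return self.p.reshape(self.space.max_pm + 1, self.space.max_p + 1)


def point_mass_vector(space: StateSpace, n: int, m: int, time: float = 0.0
                      ) -> ProbabilityVector:
    p = np.zeros(space.n_states)
    p[state_index(n, m, space) - 1] = 1.0
    return ProbabilityVector(time=time, p=p, space=space)


def poisson_product_vector(space: StateSpace, mean_p: float, mean_pm: float,
                           time: float = 0.0) -> ProbabilityVector:
    """Product of truncated Poisson marginals, the stationary-shape initializer."""
    from scipy.stats import poisson

    mp = poisson.pmf(np.arange(space.max_p + 1), mean_p)
    mm = poisson.pmf(np.arange(space.max_pm + 1), mean_pm)
    p = np.outer(mm, mp).reshape(-1)
    return ProbabilityVector(time=time, p=p, space=space)


def build_generator(rates: RateSet, A: float, space: StateSpace,
                    ctx: VolumeContext = DEFAULT_CONTEXT) -> sp.csc_matrix:
    """Sparse CME generator for one constant signal level A (uM).

    Outflow of state (n, m): ks_mol + n*(dP + kf + ka*A) + m*(kr + dPm),
    with ks_mol = ks * V * Av.  Inflows follow the six CME terms; jumps that
    leave the rectangle are dropped from the off-diagonal but kept in the
    outflow, producing the FSP mass leak.
    """
    if A < 0:
        raise ValueError(f"signal level must be non-negative, got {A}")
    MP, MPM = space.max_p, space.max_pm
    ks_mol = rates.ks * ctx.molecules_per_micromolar
    conv = rates.kf + rates.ka * A  # per-molecule P -> Pm rate

    n = np.tile(np.arange(MP + 1), MPM + 1)
    m = np.repeat(np.arange(MPM + 1), MP + 1)
    j = m * (MP + 1) + n  # 0-based state index

    rows, cols, vals = [], [], []

    def add(mask, target_rows, rate):
        rows.append(target_rows[mask])
        cols.append(j[mask])
        rate = np.broadcast_to(np.asarray(rate, dtype=float), j.shape)
        vals.append(rate[mask])

    # synthesis (n, m) -> (n+1, m)
    add(n < MP, j + 1, ks_mol)
    # degradation of P (n, m) -> (n-1, m)
    if rates.dP > 0:
        add(n > 0, j - 1, rates.dP * n)
    # conversion P -> Pm (n, m) -> (n-1, m+1)
    add((n > 0) & (m < MPM), j - 1 + (MP + 1), conv * n)
    # reverse conversion Pm -> P (n, m) -> (n+1, m-1)
    add((m > 0) & (n < MP), j + 1 - (MP + 1), rates.kr * m)
    # degradation of Pm (n, m) -> (n, m-1)
    add(m > 0, j - (MP + 1), rates.dPm * m)

    # full outflow on the diagonal, including jumps that leave the rectangle
    outflow = ks_mol + n * (rates.dP + conv) + m * (rates.kr + rates.dPm)
    rows.append(j)
    cols.append(j)
    vals.append(-outflow.astype(float))

    G = sp.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(space.n_states, space.n_states),
    )
    return G


def propagate(p0: ProbabilityVector, rates: RateSet, signal: StepSignal,
              times, ctx: VolumeContext = DEFAULT_CONTEXT,
              mass_threshold: float = 0.9999) -> list[ProbabilityVector]:
    """Propagate the CME through a piecewise-constant signal.

    Within each constant-signal interval p(t + dt) = expm(dt * G_level) p(t);
    a probability vector is emitted at every requested time.  Raises
    :class:`TruncationError` if retained mass falls below ``mass_threshold``
    at any output time (the error names the worst time point).
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return []
    if times[0] < p0.time - 1e-12 or times[-1] > signal.t_end + 1e-12:
        raise ValueError("requested times outside signal support")
    space = p0.space
    gens: dict[float, sp.csc_matrix] = {}
    out: list[ProbabilityVector] = []
    p = p0.p.copy()
    tcur = p0.time
    worst = (None, 1.0)
    for t in times:
        while True:
            # current interval and its end
            k = int(np.searchsorted(signal.boundaries, tcur, side="right")) - 1
            k = min(max(k, 0), len(signal.levels) - 1)
            t_end = signal.boundaries[k + 1]
            lev = float(signal.levels[k])
            step_end = min(t, t_end)
            dt = step_end - tcur
            if dt > 1e-14:
                if lev not in gens:
                    gens[lev] = build_generator(rates, lev, space, ctx)
                p = expm_multiply(gens[lev] * dt, p)
            tcur = step_end
            if tcur >= t - 1e-14:
                break
        pv = ProbabilityVector(time=float(t), p=np.maximum(p, 0.0) * 1.0, space=space)
        if pv.mass < worst[1]:
            worst = (float(t), pv.mass)
        out.append(pv)
    if worst[0] is not None and worst[1] < mass_threshold:
        raise TruncationError(worst[0], worst[1], mass_threshold)
    return out


def marginal(pv: ProbabilityVector, species: str) -> np.ndarray:
    """Marginal copy-number distribution of 'P' or 'Pm' (sums to the mass)."""
    g = pv.grid()
    if species == "P":
        return g.sum(axis=0)
    if species == "Pm":
        return g.sum(axis=1)
    raise KeyError(f"unknown species {species!r}")


def set_probability(pv: ProbabilityVector, species: str, lo: int, hi: int) -> float:
    """Raw probability that the copy number of ``species`` lies in [lo, hi]."""
    if lo > hi:
        raise ValueError(f"inverted bounds [{lo}, {hi}]")
    marg = marginal(pv, species)
    if lo < 0 or hi > len(marg) - 1:
        raise ValueError(f"bounds [{lo}, {hi}] outside the truncated support")
    return float(marg[lo:hi + 1].sum())


def first_moment(pv: ProbabilityVector) -> tuple[float, float]:
    """Mean copy numbers (P, Pm), renormalized by the retained mass."""
    mass = pv.mass
    if mass <= 0:
        raise ZeroDivisionError("zero probability mass")
    g = pv.grid()
    mean_p = float((g.sum(axis=0) * np.arange(pv.space.max_p + 1)).sum() / mass)
    mean_pm = float((g.sum(axis=1) * np.arange(pv.space.max_pm + 1)).sum() / mass)
    return mean_p, mean_pm


def poisson_distance(marg: np.ndarray, lam: float) -> float:
    """Total-variation distance between a truncated marginal and Poisson(lam).

    The Poisson tail beyond the truncated support counts fully as
    discrepancy, as does any mass the marginal lost to truncation.
    """
    from scipy.stats import poisson

    if lam < 0:
        raise ValueError(f"Poisson mean must be non-negative, got {lam}")
    k = np.arange(len(marg))
    pois = poisson.pmf(k, lam) if lam > 0 else (k == 0).astype(float)
    tail = 1.0 - pois.sum()
    return float(0.5 * (np.abs(np.asarray(marg) - pois).sum() + abs(tail)))
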