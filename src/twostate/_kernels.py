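"""Numba kernels for the stochastic simulators.

The SSA kernel implements Gillespie's direct method over piecewise-constant
signal intervals.  Because exponential waiting times are memoryless, the
pending reaction time is simply discarded and re-drawn at every signal
switch, which keeps the sampling exact under the time-varying input.  Two
signal mechanisms are supported: a rate-modulated channel (the flagged
propensities are multiplied by the signal level in uM) and a species-valued
signal (the unbound signal species is reset to the interval's molecule
count at each switch, leaving complexes untouched).
"""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True)
def _propensities(x, c, react, sig_mult, level, a):
    R, S = react.shape
    a0 = 0.0
    for r in range(R):
        v = c[r]
        if sig_mult[r] == 1:
            v *= level
        for s in range(S):
            o = react[r, s]
            if o == 1:
                v *= x[s]
            elif o == 2:
                v *= x[s] * (x[s] - 1) * 0.5
        if v < 0.0:
            v = 0.0
        a[r] = v
        a0 += v
    return a0


@numba.njit(cache=True)
def ssa_sample(stoich, react, c, sig_mult, sig_species, boundaries, levels,
               level_counts, sample_times, x0, seed):
    """Direct-method SSA, recording the state at the given sample times.

    Samples exactly at a switch time reflect the pre-switch state.  Returns
    an (T, S) int64 array of copy numbers (left-hold interpolation).
    """
    np.random.seed(seed)
    R, S = stoich.shape
    x = x0.copy()
    T = sample_times.shape[0]
    out = np.zeros((T, S), dtype=np.int64)
    a = np.zeros(R)
    si = 0
    t = boundaries[0]
    for k in range(levels.shape[0]):
        lev = levels[k]
        tend = boundaries[k + 1]
        while si < T and sample_times[si] <= t:
            out[si] = x
            si += 1
        if sig_species >= 0:
            x[sig_species] = level_counts[k]
        while True:
            a0 = _propensities(x, c, react, sig_mult, lev, a)
            tnext = tend + 1.0 if a0 <= 0.0 else t + np.random.exponential(1.0 / a0)
            bound = tnext if tnext < tend else tend
            while si < T and sample_times[si] <= bound:
                out[si] = x
                si += 1
            t = bound
            if tnext >= tend:
                break
            u = np.random.random() * a0
            acc = 0.0
            rsel = R - 1
            for r in range(R):
                acc += a[r]
                if acc >= u:
                    rsel = r
                    break
            for s in range(S):
                x[s] += stoich[rsel, s]
    while si < T:
        out[si] = x
        si += 1
    return out


@numba.njit(cache=True)
def ssa_events(stoich, react, c, sig_mult, sig_species, boundaries, levels,
               level_counts, x0, seed, max_events):
    """Direct-method SSA recording every state change (events and switches).

    Returns (times, states, n) where rows 0..n-1 of ``states`` hold the
    state from ``times[i]`` until ``times[i+1]`` (left-hold).
    """
    np.random.seed(seed)
    R, S = stoich.shape
    x = x0.copy()
    times = np.empty(max_events, dtype=np.float64)
    states = np.empty((max_events, S), dtype=np.int64)
    a = np.zeros(R)
    t = boundaries[0]
    n = 0
    times[n] = t
    states[n] = x
    n += 1
    for k in range(levels.shape[0]):
        lev = levels[k]
        tend = boundaries[k + 1]
        if sig_species >= 0 and x[sig_species] != level_counts[k]:
            x[sig_species] = level_counts[k]
            if n < max_events:
                times[n] = t
                states[n] = x
                n += 1
        while True:
            a0 = _propensities(x, c, react, sig_mult, lev, a)
            if a0 <= 0.0:
                t = tend
                break
            tnext = t + np.random.exponential(1.0 / a0)
            if tnext >= tend:
                t = tend
                break
            u = np.random.random() * a0
            acc = 0.0
            rsel = R - 1
            for r in range(R):
                acc += a[r]
                if acc >= u:
                    rsel = r
                    break
            for s in range(S):
                x[s] += stoich[rsel, s]
            t = tnext
            if n < max_events:
                times[n] = t
                states[n] = x
                n += 1
            else:
                return times, states, -1  # overflow sentinel
    return times, states, n


@numba.njit(cache=True)
def cle_paths(boundaries, levels, ks_mol, ka, kf, kr, dP, dPm, x0, dt,
              sample_times, n_paths, seed):
    """Euler-Maruyama chemical Langevin paths of the linear two-state model.

    Six independent noise channels (synthesis, degradation of P, signal
    conversion, basal conversion, reverse conversion, degradation of Pm)
    with sqrt-propensity amplitudes.  Propensity arguments are clamped at
    zero; sampled states are left continuous (no reflection).  Returns an
    (n_paths, T, 2) array sampled by left-hold at ``sample_times``.
    """
    np.random.seed(seed)
    T = sample_times.shape[0]
    out = np.zeros((n_paths, T, 2))
    sq = np.sqrt(dt)
    for ip in range(n_paths):
        P = x0[0]
        Pm = x0[1]
        t = boundaries[0]
        si = 0
        for k in range(levels.shape[0]):
            lev = levels[k]
            conv = kf + ka * lev
            tend = boundaries[k + 1]
            while t < tend - 1e-12:
                while si < T and sample_times[si] <= t + 1e-12:
                    out[ip, si, 0] = P
                    out[ip, si, 1] = Pm
                    si += 1
                h = dt if t + dt <= tend else tend - t
                # land exactly on the next sample time: a left-hold lag of
                # up to dt would bias fast transients
                if si < T and sample_times[si] < t + h - 1e-12:
                    h = sample_times[si] - t
                sh = sq if h == dt else np.sqrt(h)
                Pc = P if P > 0.0 else 0.0
                Pmc = Pm if Pm > 0.0 else 0.0
                a_syn = ks_mol
                a_dp = dP * Pc
                a_sig = ka * lev * Pc
                a_fwd = kf * Pc
                a_rev = kr * Pmc
                a_dpm = dPm * Pmc
                w1 = np.random.normal(0.0, 1.0) * sh
                w2 = np.random.normal(0.0, 1.0) * sh
                w3 = np.random.normal(0.0, 1.0) * sh
                w4 = np.random.normal(0.0, 1.0) * sh
                w5 = np.random.normal(0.0, 1.0) * sh
                w6 = np.random.normal(0.0, 1.0) * sh
                dPdt = ks_mol - (dP + conv) * Pc + kr * Pmc
                dPmdt = conv * Pc - (kr + dPm) * Pmc
                P += dPdt * h + np.sqrt(a_syn) * w1 - np.sqrt(a_dp) * w2 \
                    - np.sqrt(a_sig) * w3 - np.sqrt(a_fwd) * w4 + np.sqrt(a_rev) * w5
                Pm += dPmdt * h + np.sqrt(a_sig) * w3 + np.sqrt(a_fwd) * w4 \
                    - np.sqrt(a_rev) * w5 - np.sqrt(a_dpm) * w6
                t += h
        while si < T:
            out[ip, si, 0] = P
            out[ip, si, 1] = Pm
            si += 1
    return out
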