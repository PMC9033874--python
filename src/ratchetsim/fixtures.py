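"""Synthetic inputs with known ground truth for the analysis stack.

Every generator returns its own ground truth next to the data so estimator
tests never depend on production simulation runs: exact Gillespie trajectories
of the eight-state kinetic graph (oracle for the counting estimator and the
cycle-affinity analysis), ring-index random walks with a recorded winding
number (oracle for cycle counting), Poisson event streams with labelled
pathways (oracle for the pathway split), and the closed-form birth-death
occupancy of an ideal chemostatted species (oracle for GCMC).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .events import EventRecord, _CycleCounter
from .markov import build_generator, stationary_distribution


def make_ctmc_trajectory(rates_or_Q, t_obs: float, dt: float,
                         rng: np.random.Generator):
    """Exact Gillespie simulation discretised to dt samples.

    ``rates_or_Q`` is the seven-rate dict (mapped onto the eight-state graph)
    or an explicit rate matrix.  Returns (series of 1-based state ids, info)
    where info carries the true generator and jump log.
    """
    if isinstance(rates_or_Q, dict):
        Q = build_generator(rates_or_Q)
    else:
        Q = np.asarray(rates_or_Q, dtype=float)
    n = Q.shape[0]
    n_samples = int(round(t_obs / dt))
    p0 = stationary_distribution(Q) if n > 1 else np.ones(1)
    state = int(rng.choice(n, p=p0))
    series = np.empty(n_samples, dtype=np.int64)
    t = 0.0
    next_sample = 0
    jumps = []
    while next_sample < n_samples:
        out = -Q[state, state]
        if out <= 0.0:
            if n > 1 and np.any(Q > 0):
                raise ValueError(f"absorbing state {state + 1} in generator")
            series[next_sample:] = state + 1
            break
        tau = rng.exponential(1.0 / out)
        t_jump = t + tau
        while next_sample < n_samples and next_sample * dt < t_jump:
            series[next_sample] = state + 1
            next_sample += 1
        probs = Q[state].copy()
        probs[state] = 0.0
        probs /= probs.sum()
        state = int(rng.choice(n, p=probs))
        jumps.append((t_jump, state + 1))
        t = t_jump
    return series, {"Q": Q, "jumps": jumps, "p0": p0}


def make_index_walk(drift: float, noise: float, length: int,
                    rng: np.random.Generator, n_ring: int = 30):
    """Integer walk on Z wrapped onto the ring, with recorded true winding.

    Per-step increments are round(drift + noise * N(0,1)), kept within the
    unambiguous window (|inc| <= n_ring/2).  Ground truth applies the
    turn-crossing rule to the exact unwrapped increments.
    """
    inc = np.rint(drift + noise * rng.standard_normal(length - 1)).astype(np.int64)
    half = n_ring // 2
    np.clip(inc, -(half - 1), half, out=inc)
    unwrapped = np.concatenate([[0], np.cumsum(inc)])
    series = unwrapped % n_ring
    ctr = _CycleCounter(n_ring)
    for d in inc:
        ctr.push(int(d))
    return series, {"unwrapped": unwrapped, "n_cw": ctr.n_cw, "n_ccw": ctr.n_ccw,
                    "net": ctr.n_cw - ctr.n_ccw}


def make_event_stream(rate_C: float, rate_TC: float, duration: float,
                      rng: np.random.Generator,
                      mode_C: float = 5.0, mode_TC: float = 0.8,
                      spread: float = 0.15, kind: str = "ATTACH",
                      site: int = 1):
    """Poisson ATTACH/CLEAVE events with labelled ground-truth pathways.

    C-mediated events draw r_tet_min around ``mode_C`` (no cluster nearby),
    cluster-mediated ones around ``mode_TC``; spreads are Gaussian truncated
    at zero.  Returns (EventRecords sorted by time, truth dict).
    """
    events, labels = [], []
    for label, rate, mode in (("C", rate_C, mode_C), ("TC", rate_TC, mode_TC)):
        t = 0.0
        while rate > 0:
            t += rng.exponential(1.0 / rate)
            if t >= duration:
                break
            r = -1.0
            while r <= 0:
                r = mode + spread * rng.standard_normal()
            events.append(EventRecord(time=t, kind=kind, site=site, r_tet_min=float(r)))
            labels.append(label)
    order = np.argsort([e.time for e in events])
    events = [events[i] for i in order]
    labels = [labels[i] for i in order]
    return events, {"labels": labels,
                    "n_C": labels.count("C"), "n_TC": labels.count("TC")}


# ---------------------------------------------------------------------------
# birth-death oracle for an ideal chemostatted species
# ---------------------------------------------------------------------------

def ideal_occupancy_pmf(mu_prime: float, kT: float, n_max: int = 60):
    """Closed-form stationary occupancy of one ideal chemostatted species.

    With the shifted-chemical-potential acceptance rule the add/remove chain
    satisfies detailed balance with P(N+1)/P(N) = lambda/(N+1) where
    lambda = exp(mu'/kT): a Poisson distribution, truncated here at n_max.
    """
    lam = np.exp(mu_prime / kT)
    pmf = stats.poisson.pmf(np.arange(n_max + 1), lam)
    return pmf / pmf.sum()


def birth_death_chain(mu_prime: float, kT: float, n_sweeps: int,
                      rng: np.random.Generator, p_attempt: float = 1.0 / 6.0):
    """Direct birth-death oracle chain on N alone (no configurations).

    Mirrors the GCMC proposal exactly: each sweep attempts an addition with
    probability ``p_attempt``, a removal with the same probability, else does
    nothing.  Returns the visited N series.
    """
    lam = np.exp(mu_prime / kT)
    N = 0
    out = np.empty(n_sweeps, dtype=np.int64)
    u = rng.random(n_sweeps)
    v = rng.random(n_sweeps)
    for s in range(n_sweeps):
        if u[s] < p_attempt:
            if v[s] < min(1.0, lam / (N + 1)):
                N += 1
        elif u[s] < 2 * p_attempt:
            if N > 0 and v[s] < min(1.0, N / lam):
                N -= 1
        out[s] = N
    return out
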