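"""Eight-state Markov rate model of the motor.

The motor's configuration is coarse-grained onto three bits: which half of
the large ring holds the shuttling ring (the 15-bead arcs centred on the two
binding sites), and whether each catalytic site is blocked by a free C.  The
eight states are numbered so that the far-cleavage transitions are exactly
2->1, 3->4, 5->6 and 8->7:

    id : (half, b1, b2)
    1  : (1, 0, 0)      5 : (2, 1, 0)
    2  : (1, 0, 1)      6 : (2, 0, 0)
    3  : (1, 1, 1)      7 : (2, 0, 1)
    4  : (1, 1, 0)      8 : (2, 1, 1)

Site ``h`` is the *close* site when the shuttle occupies half ``h`` (walking
clockwise out of a binding site immediately crosses its own catalytic site),
so a blocked close site forbids clockwise departure.  By the model's two-fold
symmetry there are seven rates: attach/cleave at the close and far sites,
CW/CCW ring moves past a single blocked site, and the symmetric ring move
k_sym when neither site is blocked (both-blocked ring moves are not part of
the graph).  Rates follow the counting estimator

    k_AB = N_AB / (t_obs p_ss(A)),

with symmetry-equivalent transitions pooled, e.g. k_cleave,far =
(N_21 + N_34 + N_56 + N_87) / (t_obs (p_1... sources 2,3,5,8)).

The graph decomposes into four fundamental cycles.  The one-blocked cycles
share the ratio R = (k_att,far / k_att,close)(k_cl,close / k_cl,far)
(k_CW / k_CCW); its logarithm is the cycle affinity, whose sign fixes the
direction of every steady-state cycle current.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# ---------------------------------------------------------------------------
# state space and transition classes
# ---------------------------------------------------------------------------

STATES = {1: (1, 0, 0), 2: (1, 0, 1), 3: (1, 1, 1), 4: (1, 1, 0),
          5: (2, 1, 0), 6: (2, 0, 0), 7: (2, 0, 1), 8: (2, 1, 1)}
STATE_ID = {v: k for k, v in STATES.items()}

RATE_NAMES = ("attach_close", "cleave_close", "attach_far", "cleave_far",
              "cw", "ccw", "sym")


def _edge_class(a: int, b: int) -> str | None:
    """Rate class of the ordered transition a -> b, or None if disconnected."""
    ha, b1a, b2a = STATES[a]
    hb, b1b, b2b = STATES[b]
    nflips = (ha != hb) + (b1a != b1b) + (b2a != b2b)
    if nflips != 1:
        return None
    if ha != hb:
        nblocked = b1a + b2a
        if nblocked == 0:
            return "sym"
        if nblocked == 2:
            return None                       # both blocked: ring cannot pass
        close_blocked = (b1a if ha == 1 else b2a) == 1
        return "ccw" if close_blocked else "cw"
    site = 1 if b1a != b1b else 2
    attach = (b1b > b1a) if site == 1 else (b2b > b2a)
    close = (site == ha)
    return (("attach_" if attach else "cleave_") + ("close" if close else "far"))


#: ordered (A, B) -> rate class for every edge of the kinetic graph
EDGE_CLASS = {}
for _a in STATES:
    for _b in STATES:
        if _a != _b:
            _c = _edge_class(_a, _b)
            if _c is not None:
                EDGE_CLASS[(_a, _b)] = _c

#: rate class -> list of ordered transitions it pools
CLASS_EDGES = {name: sorted(k for k, v in EDGE_CLASS.items() if v == name)
               for name in RATE_NAMES}


def coarse_state(shuttle_idx: int, b1: bool, b2: bool, n_large: int = 30,
                 binding_indices=(0, 15)) -> int:
    """Map (shuttle index, blocking flags) to the state id 1..8.

    Half 1 is the 15-bead arc centred on the first binding site (indices
    23..29 and 0..7 for the default layout); the boundary bead 7 belongs to
    half 1 and bead 8 to half 2.
    """
    half_span = n_large // 2
    b0 = binding_indices[0]
    offset = (shuttle_idx - b0 + half_span // 2) % n_large
    half = 1 if offset < half_span else 2
    return STATE_ID[(half, int(bool(b1)), int(bool(b2)))]


def coarse_series(shuttle_idx, blocked, n_large: int = 30) -> np.ndarray:
    """Vectorised coarse_state over per-step arrays."""
    shuttle_idx = np.asarray(shuttle_idx)
    blocked = np.asarray(blocked)
    half_span = n_large // 2
    offset = (shuttle_idx + half_span // 2) % n_large
    half = np.where(offset < half_span, 1, 2)
    lut = np.zeros((3, 2, 2), dtype=np.int64)
    for sid, (h, b1, b2) in STATES.items():
        lut[h, b1, b2] = sid
    return lut[half, blocked[:, 0].astype(int), blocked[:, 1].astype(int)]


# ---------------------------------------------------------------------------
# estimation: Model / Results
# ---------------------------------------------------------------------------

@dataclass
class RateResults:
    """Pooled seven-rate parameterisation plus populations and diagnostics."""
    rates: dict                        # name -> rate or None
    stderr: dict                       # name -> SE across replicas (or None)
    p_ss: np.ndarray                   # (8,) occupancy, index = id - 1
    N: np.ndarray                      # (8, 8) raw ordered transition counts
    t_obs: float
    n_disconnected: int = 0
    n_replicas: int = 1

    def __getitem__(self, name):
        return self.rates[name]

    def cycle_report(self):
        return cycle_ratio(self)

    def entropy_rate(self) -> float:
        return markov_entropy_rate(self.rates, self.p_ss)

    def summary(self) -> str:
        lines = ["Eight-state rate model (pooled counting estimator)",
                 "=" * 52,
                 f"observation time: {self.t_obs:g}   replicas: {self.n_replicas}"
                 f"   disconnected transitions dropped: {self.n_disconnected}",
                 f"{'rate':>14} {'estimate':>12} {'std err':>12}"]
        for name in RATE_NAMES:
            k = self.rates[name]
            se = self.stderr.get(name)
            ks = f"{k:.6g}" if k is not None else "--"
            ses = f"{se:.3g}" if se is not None else "--"
            lines.append(f"{name:>14} {ks:>12} {ses:>12}")
        lines.append("state populations p_ss:")
        lines.append("  " + "  ".join(f"{i + 1}:{p:.4f}" for i, p in enumerate(self.p_ss)))
        rep = self.cycle_report()
        if rep is not None:
            lines.append(f"R = {rep.R:.4g}   affinity A = {rep.affinity:.4g}"
                         f"   predicted direction: {rep.direction}")
        return "\n".join(lines)


class EightStateModel:
    """Counting-estimator model for the eight-state kinetic graph.

    Parameters
    ----------
    series : array or list of arrays
        Per-step coarse-state ids (1..8); a list is treated as independent
        replicas whose counts are pooled (standard errors across replicas).
    dt : float
        Sampling interval of the series.
    """

    def __init__(self, series, dt: float):
        if isinstance(series, np.ndarray) and series.ndim == 1:
            series = [series]
        self.series = [np.asarray(s, dtype=np.int64) for s in series]
        for s in self.series:
            if s.size and (s.min() < 1 or s.max() > 8):
                raise ValueError("state ids must be in 1..8")
        self.dt = float(dt)

    @classmethod
    def from_series(cls, series, dt: float) -> "EightStateModel":
        return cls(series, dt)

    @classmethod
    def from_segments(cls, shuttle_idx, blocked, dt: float,
                      n_large: int = 30) -> "EightStateModel":
        return cls(coarse_series(shuttle_idx, blocked, n_large), dt)

    @staticmethod
    def _counts(s: np.ndarray):
        N = np.zeros((8, 8), dtype=np.int64)
        occ = np.zeros(8, dtype=np.int64)
        if s.size == 0:
            return N, occ, 0.0
        np.add.at(occ, s - 1, 1)
        a, b = s[:-1], s[1:]
        mask = a != b
        np.add.at(N, (a[mask] - 1, b[mask] - 1), 1)
        return N, occ, s.size

    @staticmethod
    def _pooled(N: np.ndarray, occ: np.ndarray, t_obs: float):
        rates = {}
        n_total = occ.sum()
        for name in RATE_NAMES:
            edges = CLASS_EDGES[name]
            num = sum(N[a - 1, b - 1] for a, b in edges)
            sources = sorted({a for a, _ in edges})
            p_src = sum(occ[a - 1] for a in sources) / n_total if n_total else 0.0
            rates[name] = (num / (t_obs * p_src)) if p_src > 0 else None
        return rates

    def fit(self) -> RateResults:
        per_rep = []
        N_tot = np.zeros((8, 8), dtype=np.int64)
        occ_tot = np.zeros(8, dtype=np.int64)
        t_tot = 0.0
        for s in self.series:
            N, occ, nsamp = self._counts(s)
            t = nsamp * self.dt
            per_rep.append(self._pooled(N, occ, t) if t > 0 else None)
            N_tot += N
            occ_tot += occ
            t_tot += t
        rates = self._pooled(N_tot, occ_tot, t_tot)
        stderr = {}
        for name in RATE_NAMES:
            vals = [r[name] for r in per_rep if r is not None and r[name] is not None]
            stderr[name] = (float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
                            if len(vals) > 1 else None)
        n_disc = int(N_tot.sum() - sum(N_tot[a - 1, b - 1] for a, b in EDGE_CLASS))
        p_ss = occ_tot / occ_tot.sum() if occ_tot.sum() else np.zeros(8)
        return RateResults(rates=rates, stderr=stderr, p_ss=p_ss, N=N_tot,
                           t_obs=t_tot, n_disconnected=n_disc,
                           n_replicas=len(self.series))


def estimate_rates(series, dt: float) -> RateResults:
    """Functional wrapper: fit the eight-state model to a coarse series."""
    return EightStateModel(series, dt).fit()


# ---------------------------------------------------------------------------
# cycle analysis
# ---------------------------------------------------------------------------

@dataclass
class CycleReport:
    R: float
    affinity: float
    R_approx: float | None = None

    @property
    def direction(self) -> str:
        return "CW" if self.R > 1 else ("CCW" if self.R < 1 else "none")


def cycle_ratio(est: RateResults) -> CycleReport | None:
    """Rate ratio R and affinity of the one-blocked fundamental cycles.

    Returns None when any of the six involved rates is missing or zero.
    """
    r = est.rates
    needed = ("attach_far", "attach_close", "cleave_close", "cleave_far", "cw", "ccw")
    if any(r.get(n) is None or r[n] <= 0 for n in needed):
        return None
    R = (r["attach_far"] / r["attach_close"]) * \
        (r["cleave_close"] / r["cleave_far"]) * (r["cw"] / r["ccw"])
    return CycleReport(R=R, affinity=float(np.log(R)))


def r_approx(est_at_N: RateResults, est_at_0: RateResults) -> float | None:
    """Approximate R from the fuel-dependent attachment rates alone.

    Uses the equilibrium identity (R = 1 when the fuel is absent) to replace
    the cleave and ring rates by the reference attachment ratio.
    """
    kf_N, kc_N = est_at_N.rates["attach_far"], est_at_N.rates["attach_close"]
    kf_0, kc_0 = est_at_0.rates["attach_far"], est_at_0.rates["attach_close"]
    if any(v is None or v <= 0 for v in (kf_N, kc_N, kf_0, kc_0)):
        return None
    return (kf_N / kf_0) * (kc_0 / kc_N)


def fundamental_cycles():
    """The four fundamental cycles of the kinetic graph, as state sequences.

    Computed from a spanning-tree cycle basis of the undirected graph; each
    cycle is rotated/oriented to a canonical form.  FC1 -- the fully ratcheted
    cycle -- is the unique basis cycle that uses both one-blocked ring edges
    and avoids the symmetric edge.
    """
    import networkx as nx
    G = nx.Graph()
    for (a, b) in EDGE_CLASS:
        G.add_edge(a, b)
    return [list(c) for c in nx.cycle_basis(G)]


def _ring_edges(cycle):
    out = []
    n = len(cycle)
    for i in range(n):
        a, b = cycle[i], cycle[(i + 1) % n]
        if EDGE_CLASS[(a, b)] in ("cw", "ccw", "sym"):
            out.append((a, b))
    return out


def fc1_cycle() -> list:
    """State sequence of the fully ratcheted fundamental cycle, oriented CW."""
    import networkx as nx
    G = nx.Graph()
    for (a, b), cls in EDGE_CLASS.items():
        G.add_edge(a, b, cls=cls)
    best = None
    for cyc in nx.simple_cycles(G):
        edges = [EDGE_CLASS[(cyc[i], cyc[(i + 1) % len(cyc)])] for i in range(len(cyc))]
        if "sym" in edges or edges.count("cw") + edges.count("ccw") != 2:
            continue
        # the fully ratcheted cycle alternates gating: it never visits a
        # state with both sites blocked (nor the fully open states' sym edge)
        if any(STATES[s][1] + STATES[s][2] == 2 for s in cyc):
            continue
        if len(cyc) == 6:
            best = cyc
            break
    if best is None:
        raise RuntimeError("fully ratcheted cycle not found in graph")
    # orient so that ring moves are traversed in the CW direction
    edges = [EDGE_CLASS[(best[i], best[(i + 1) % len(best)])] for i in range(len(best))]
    if "cw" not in edges:
        best = best[::-1]
        edges = [EDGE_CLASS[(best[i], best[(i + 1) % len(best)])] for i in range(len(best))]
    assert edges.count("cw") == 2
    return best


def max_coupling_fc1() -> float:
    """Maximum coupling of a tightly coupled CW traversal of FC1.

    One traversal crosses two CW ring edges (= one full shuttle cycle) and
    requires one catalyzed attachment at each of the two catalytic sites;
    the coupling observable (net cycles per catalyzed reaction) is evaluated
    on exactly that stoichiometry.
    """
    from .events import CycleCounts, observables
    cyc = fc1_cycle()
    n = len(cyc)
    classes = [EDGE_CLASS[(cyc[i], cyc[(i + 1) % n])] for i in range(n)]
    n_cw_edges = classes.count("cw")
    n_cat = sum(1 for c in classes if c.startswith("attach"))
    counts = CycleCounts(n_CW=n_cw_edges // 2, n_CCW=0, n_cat=n_cat, t_obs=1.0)
    _, _, coupling = observables(counts)
    return float(coupling)


# ---------------------------------------------------------------------------
# pathway-resolved refinement
# ---------------------------------------------------------------------------

@dataclass
class PathwayResolvedRates:
    """Attachment/cleavage rates split into C-mediated and cluster-mediated."""
    threshold: float
    n_attach_C: int
    n_attach_TC: int
    n_cleave_C: int
    n_cleave_TC: int
    k_attach: float | None = None
    k_attach_C: float | None = None
    k_attach_TC: float | None = None
    k_cleave: float | None = None
    k_cleave_C: float | None = None
    k_cleave_TC: float | None = None
    r_tet_attach: np.ndarray = field(default_factory=lambda: np.zeros(0))
    r_tet_cleave: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def attach_fraction_TC(self) -> float | None:
        tot = self.n_attach_C + self.n_attach_TC
        return self.n_attach_TC / tot if tot else None


def resolve_pathways(events, threshold: float = 1.0,
                     k_attach: float | None = None,
                     k_cleave: float | None = None) -> PathwayResolvedRates:
    """Partition ATTACH/CLEAVE events by the recorded r_tet_min.

    Events with r_tet_min < threshold are cluster-mediated (TC); the component
    rates are the pooled rates scaled by the count fractions, so
    k^C + k^TC = k exactly.
    """
    ra = np.array([e.r_tet_min for e in events
                   if e.kind == "ATTACH" and e.r_tet_min is not None])
    rc = np.array([e.r_tet_min for e in events
                   if e.kind == "CLEAVE" and e.r_tet_min is not None])
    na_tc = int(np.sum(ra < threshold))
    nc_tc = int(np.sum(rc < threshold))
    out = PathwayResolvedRates(
        threshold=threshold,
        n_attach_C=len(ra) - na_tc, n_attach_TC=na_tc,
        n_cleave_C=len(rc) - nc_tc, n_cleave_TC=nc_tc,
        r_tet_attach=ra, r_tet_cleave=rc)
    if k_attach is not None and len(ra):
        out.k_attach = k_attach
        out.k_attach_TC = k_attach * na_tc / len(ra)
        out.k_attach_C = k_attach - out.k_attach_TC
    if k_cleave is not None and len(rc):
        out.k_cleave = k_cleave
        out.k_cleave_TC = k_cleave * nc_tc / len(rc)
        out.k_cleave_C = k_cleave - out.k_cleave_TC
    return out


# ---------------------------------------------------------------------------
# entropy production
# ---------------------------------------------------------------------------

def build_generator(rates: dict) -> np.ndarray:
    """8x8 rate matrix Q from the seven pooled rates (Q[a-1, b-1] = k_AB)."""
    Q = np.zeros((8, 8))
    for (a, b), cls in EDGE_CLASS.items():
        k = rates.get(cls)
        if k is None:
            raise ValueError(f"missing rate {cls}")
        Q[a - 1, b - 1] = k
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    n = Q.shape[0]
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    p, *_ = np.linalg.lstsq(A, b, rcond=None)
    return np.clip(p, 0.0, None) / np.clip(p, 0.0, None).sum()


def entropy_production_rate(edges, p=None) -> float:
    """Steady-state entropy production of a (multi)graph Markov model.

    ``edges`` is an iterable of channels (a, b, k_ab, k_ba) with 1-based
    states; parallel channels between the same pair are treated separately
    (the pathway-resolved refinement).  If ``p`` is None the stationary
    distribution of the summed generator is used.  A channel with one zero
    rate but nonzero flux gives +inf.
    """
    edges = list(edges)
    nmax = max(max(a, b) for a, b, *_ in edges)
    if p is None:
        Q = np.zeros((nmax, nmax))
        for a, b, kf, kr in edges:
            Q[a - 1, b - 1] += kf
            Q[b - 1, a - 1] += kr
        np.fill_diagonal(Q, -Q.sum(axis=1))
        p = stationary_distribution(Q)
    p = np.asarray(p, dtype=float)
    sigma = 0.0
    for a, b, kf, kr in edges:
        jf = p[a - 1] * kf
        jr = p[b - 1] * kr
        if jf == jr:
            continue
        if jf == 0.0 or jr == 0.0:
            return float("inf")
        sigma += (jf - jr) * np.log(jf / jr)
    return float(sigma)


def markov_entropy_rate(rates_or_Q, p_ss=None) -> float:
    """Entropy production rate of the pooled eight-state model.

    Accepts either the seven-rate dict or a full rate matrix.  Uses the given
    occupancies if provided (the estimator's p_ss), else the stationary
    distribution of the generator.
    """
    if isinstance(rates_or_Q, dict):
        Q = build_generator(rates_or_Q)
    else:
        Q = np.asarray(rates_or_Q, dtype=float)
    edges = []
    n = Q.shape[0]
    seen = set()
    for a in range(1, n + 1):
        for b in range(1, n + 1):
            if a != b and (b, a) not in seen and (Q[a - 1, b - 1] or Q[b - 1, a - 1]):
                edges.append((a, b, Q[a - 1, b - 1], Q[b - 1, a - 1]))
                seen.add((a, b))
    return entropy_production_rate(edges, p=p_ss)
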