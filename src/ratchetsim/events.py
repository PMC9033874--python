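"""Event detection and motor observables.

Chemistry is tracked through the cluster reaction coordinate r (distance of
the central particle from its tetrahedral shell's center of mass).  A cluster
is FTC when r <= r_ftc, ETC (+ free C) when r >= r_etc and in a fleeting
intermediate otherwise.  Event detection latches the FTC/ETC label with
two-threshold hysteresis so that chatter around a single threshold cannot
double-count reactions: a DECOMPOSITION fires at the first upward crossing of
r_etc from an FTC episode (flagged catalyzed when the cluster's center of
mass is within r_catalyzed of a catalytic particle at that instant) and a
RECOMBINATION on the reverse crossing of r_ftc.

Motion is tracked through the shuttle index -- the large-ring bead nearest
the shuttling ring's center of mass -- which is intrinsically ring-local, so
rigid motion of the whole motor produces no spurious cycles.  Completed
clockwise / counterclockwise turns are scored by accumulating minimum-image
index increments and crossing +-N_large marks.

The three performance observables are
    bias     = n_CW / (n_CW + n_CCW)
    current  = (n_CW - n_CCW) / t_obs
    coupling = (n_CW - n_CCW) / n_cat
with undefined cases (no cycles / no catalyzed reactions) reported as None.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forcefield import ParticleType


@dataclass(frozen=True)
class Thresholds:
    r_ftc: float = 0.25
    r_etc: float = 0.8
    r_catalyzed: float = 2.0
    r_block: float = 1.2

    def __post_init__(self):
        if not self.r_ftc < self.r_etc:
            raise ValueError("require r_ftc < r_etc")


def classify_r(r: float, th: Thresholds = Thresholds()) -> str:
    if r <= th.r_ftc:
        return "FTC"
    if r >= th.r_etc:
        return "ETC"
    return "INTERMEDIATE"


def classify_cluster(tet_coords, cent_coord, th: Thresholds = Thresholds(),
                     cell=None) -> str:
    """Classify one cluster from coordinates (ETC when no CENT is tracked)."""
    if cent_coord is None:
        return "ETC"
    tet_coords = np.asarray(tet_coords, dtype=float)
    ref = tet_coords[0]
    d = tet_coords - ref
    if cell is not None:
        d = cell.min_image(d)
    com = ref + d.mean(axis=0)
    dv = np.asarray(cent_coord, dtype=float) - com
    if cell is not None:
        dv = cell.min_image(dv)
    return classify_r(float(np.linalg.norm(dv)), th)


@dataclass
class EventRecord:
    time: float
    kind: str                     # DECOMPOSITION RECOMBINATION ATTACH CLEAVE CYCLE
    mol_id: int = -1
    catalyzed: bool | None = None
    site: int | None = None       # 1 or 2 for ATTACH/CLEAVE
    direction: str | None = None  # CW or CCW for CYCLE
    r_tet_min: float | None = None

    def to_dict(self):
        d = {"time": self.time, "kind": self.kind}
        if self.mol_id >= 0:
            d["mol_id"] = self.mol_id
        for k in ("catalyzed", "site", "direction", "r_tet_min"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        return d


@dataclass
class CycleCounts:
    n_CW: int = 0
    n_CCW: int = 0
    n_cat: int = 0
    t_obs: float = 0.0


def observables(counts: CycleCounts):
    """(bias, current, coupling); undefined entries are None."""
    if counts.t_obs <= 0:
        raise ValueError("t_obs must be positive")
    tot = counts.n_CW + counts.n_CCW
    bias = counts.n_CW / tot if tot > 0 else None
    current = (counts.n_CW - counts.n_CCW) / counts.t_obs
    coupling = ((counts.n_CW - counts.n_CCW) / counts.n_cat
                if counts.n_cat > 0 else None)
    return bias, current, coupling


# ---------------------------------------------------------------------------
# standalone state queries
# ---------------------------------------------------------------------------

def shuttle_index(state, n_large: int = 30) -> int:
    """Large-ring index nearest the shuttle COM; ties break to lowest index."""
    n_shut = state.n_motor - n_large
    com = state.positions[n_large:n_large + n_shut].mean(axis=0)
    d2 = np.sum((state.positions[:n_large] - com) ** 2, axis=1)
    return int(np.argmin(d2))


def blocking_state(state, th: Thresholds = Thresholds(), cell=None):
    """(site1_blocked, site2_blocked): any free C within r_block of each CAT1."""
    from .chemostat import free_c_ids
    from .topology import SimulationCell
    if cell is None:
        cell = SimulationCell()
    cat1 = np.nonzero(state.types[:state.n_motor] == int(ParticleType.CAT1))[0]
    free = free_c_ids(state, th, cell)
    flags = []
    for c1 in cat1:
        hit = False
        for cid in free:
            d = np.linalg.norm(cell.min_image(state.positions[cid] - state.positions[c1]))
            if d < th.r_block:
                hit = True
                break
        flags.append(hit)
    while len(flags) < 2:
        flags.append(False)
    return tuple(flags[:2])


# ---------------------------------------------------------------------------
# cycle counting
# ---------------------------------------------------------------------------

def _ring_increments(idx: np.ndarray, n_ring: int) -> np.ndarray:
    d = np.diff(idx.astype(np.int64))
    half = n_ring // 2
    return (d + half - 1) % n_ring - half + 1  # mapped to (-half, +half]


def count_cycles(index_series, n_ring: int = 30):
    """Completed CW / CCW turns of a ring-index series.

    Increments are unwrapped to (-n_ring/2, +n_ring/2]; every time the
    accumulated winding coordinate advances +n_ring past the last completed
    turn a CW cycle is scored (likewise -n_ring for CCW).
    """
    idx = np.asarray(index_series)
    if idx.size < 2:
        return 0, 0
    inc = _ring_increments(idx, n_ring)
    ctr = _CycleCounter(n_ring)
    for d in inc:
        ctr.push(int(d))
    return ctr.n_cw, ctr.n_ccw


class _CycleCounter:
    """Streaming turn counter used both by count_cycles and the detector."""

    def __init__(self, n_ring: int):
        self.n_ring = n_ring
        self.w = 0            # winding coordinate relative to last turn mark
        self.n_cw = 0
        self.n_ccw = 0

    def push(self, inc: int):
        self.w += inc
        out = []
        while self.w >= self.n_ring:
            self.n_cw += 1
            self.w -= self.n_ring
            out.append("CW")
        while self.w <= -self.n_ring:
            self.n_ccw += 1
            self.w += self.n_ring
            out.append("CCW")
        return out


# ---------------------------------------------------------------------------
# streaming detector over simulation segments
# ---------------------------------------------------------------------------

@dataclass
class EventDetector:
    """Accumulates EventRecords across consecutive simulation segments.

    Holds the per-cluster FTC/ETC hysteresis latch, per-site blocking flags
    and the cycle winding coordinate, so detection is exact at full (per-step)
    resolution even though the simulation advances segment by segment.
    """
    thresholds: Thresholds = field(default_factory=Thresholds)
    n_ring: int = 30
    events: list = field(default_factory=list)
    counts: CycleCounts = field(default_factory=CycleCounts)
    _latch: dict = field(default_factory=dict)        # mol_id -> "FTC"/"ETC"
    _blocked: list = field(default_factory=lambda: [None, None])
    _last_idx: int | None = None
    _cycler: _CycleCounter | None = None

    def __post_init__(self):
        if self._cycler is None:
            self._cycler = _CycleCounter(self.n_ring)

    def process_segment(self, t0: float, dt: float, seg: dict, mol_ids):
        """Consume one run_md_segment output dict.

        ``mol_ids`` gives the molecule id of each cluster column of
        ``seg['r_clu']``.  Latches for new molecules initialise from the first
        sample's side of the hysteresis window.
        """
        th = self.thresholds
        r = seg["r_clu"]
        dcat = seg["d_cat"]
        S = r.shape[0]
        if S == 0:
            return
        for col, mol in enumerate(mol_ids):
            rs = r[:, col]
            latch = self._latch.get(mol)
            if latch is None:
                latch = "FTC" if rs[0] <= th.r_etc else "ETC"
            # fast path: no threshold crossed anywhere in the segment
            if ((latch == "FTC" and rs.max() < th.r_etc)
                    or (latch == "ETC" and rs.min() > th.r_ftc)):
                self._latch[mol] = latch
                continue
            for s in range(S):
                if latch == "FTC":
                    if rs[s] >= th.r_etc:
                        latch = "ETC"
                        cat = bool(dcat[s, col] <= th.r_catalyzed)
                        self.events.append(EventRecord(
                            time=t0 + (s + 1) * dt, kind="DECOMPOSITION",
                            mol_id=mol, catalyzed=cat))
                        if cat:
                            self.counts.n_cat += 1
                elif rs[s] <= th.r_ftc:
                    latch = "FTC"
                    self.events.append(EventRecord(
                        time=t0 + (s + 1) * dt, kind="RECOMBINATION", mol_id=mol))
            self._latch[mol] = latch

        blocked = seg["blocked"]
        rtet = seg["r_tet"]
        for site in range(blocked.shape[1]):
            col = blocked[:, site]
            prev = self._blocked[site]
            if prev is None:
                prev = bool(col[0])
                changes = 1 + np.nonzero(col[1:] != col[:-1])[0]
            else:
                changes = np.nonzero(np.diff(
                    np.concatenate([[np.uint8(prev)], col])) != 0)[0]
            for s in changes:
                cur = bool(col[s])
                if cur:
                    self.events.append(EventRecord(
                        time=t0 + (s + 1) * dt, kind="ATTACH", site=site + 1,
                        r_tet_min=float(rtet[s, site])))
                else:
                    self.events.append(EventRecord(
                        time=t0 + (s + 1) * dt, kind="CLEAVE", site=site + 1,
                        r_tet_min=float(rtet[max(s - 1, 0), site])))
            self._blocked[site] = bool(col[-1]) if S else prev

        sidx = seg["shuttle_idx"]
        if S and sidx[0] >= 0:
            half = self.n_ring // 2
            if self._last_idx is None:
                series = sidx
            else:
                series = np.concatenate([[self._last_idx], sidx])
            inc = (np.diff(series) + half - 1) % self.n_ring - half + 1
            for s in np.nonzero(inc)[0]:
                for d in self._cycler.push(int(inc[s])):
                    off = 1 if self._last_idx is not None else 0
                    self.events.append(EventRecord(
                        time=t0 + (s + 1 - off + 1) * dt, kind="CYCLE", direction=d))
                    if d == "CW":
                        self.counts.n_CW += 1
                    else:
                        self.counts.n_CCW += 1
            self._last_idx = int(sidx[-1])
        self.counts.t_obs += S * dt

    def latch_of(self, mol_id: int):
        return self._latch.get(mol_id)

    def sync_latches(self, clusters):
        """Push hysteresis latches back onto ClusterRecords (and read new ones)."""
        for c in clusters:
            if c.mol_id in self._latch:
                c.latched = self._latch[c.mol_id]
            else:
                self._latch[c.mol_id] = c.latched


def detect_reaction_events(r_series, dcat_series, dt, th: Thresholds = Thresholds(),
                           mol_id: int = 0, t0: float = 0.0,
                           initial: str | None = None):
    """Reaction events for a single cluster's per-step r trace.

    Convenience wrapper over the streaming detector for one column.
    ``initial`` forces the starting latch; by default it derives from the
    first sample.
    """
    r_series = np.asarray(r_series, dtype=float).reshape(-1, 1)
    dcat_series = np.asarray(dcat_series, dtype=float).reshape(-1, 1)
    det = EventDetector(thresholds=th)
    if initial is not None:
        det._latch[mol_id] = initial
    seg = {"r_clu": r_series, "d_cat": dcat_series,
           "blocked": np.zeros((len(r_series), 0), dtype=np.uint8),
           "r_tet": np.zeros((len(r_series), 0)),
           "shuttle_idx": np.full(len(r_series), -1, dtype=np.int64)}
    det.process_segment(t0, dt, seg, [mol_id])
    return det.events
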