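"""Simulation orchestration, configuration and serialization.

A production run interleaves segments of ``move_period`` Langevin steps with
one GCMC trial move, detecting events online at full per-step resolution.
Outputs are plain text: extended-XYZ trajectory frames, JSON-lines event and
GCMC-move logs, a run-length-encoded coarse-state series (for rate
estimation) and a JSON observables summary.  Runs are deterministic per seed
and can be checkpointed/resumed bit-exactly at segment boundaries.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from .forcefield import ForceFieldTables, TYPE_NAMES, TYPE_BY_NAME, default_tables, tables_from_config
from .topology import (MotorLayout, SimulationCell, SystemState, build_system,
                       ClusterRecord)
from .dynamics import DynamicsParams, run_md_segment
from .chemostat import (ChemostatSpec, generate_reservoir, gcmc_sweep,
                        associate_free_c)
from .events import Thresholds, EventDetector, CycleCounts, observables
from .markov import EightStateModel, coarse_series, resolve_pathways


@dataclass
class RunConfig:
    """Validated configuration; all defaults are the model's standard values."""
    n_steps: int = 100_000
    seed: int = 0
    replicas: int = 1
    gamma: float = 0.5
    dt: float = 5e-3
    kT: float = 0.5
    move_period: int = 100
    mu_prime: dict = field(default_factory=lambda: {"FTC": 0.5, "ETC": -10.0, "C": -10.0})
    L_inner: float = 30.0
    L_outer: float = 34.0
    traj_stride: int = 1000
    checkpoint_stride: int = 0          # segments between checkpoints; 0 = off
    reservoir_size: int = 10_000
    pre_equilibration_steps: int = 10_000
    include_motor: bool = True
    tet_bond_k: float = 150.0
    pair_overrides: dict = field(default_factory=dict)
    thresholds: Thresholds = field(default_factory=Thresholds)
    outdir: str | None = None

    def __post_init__(self):
        if self.n_steps < 0 or self.move_period < 1 or self.replicas < 1:
            raise ValueError("invalid run sizes")
        if self.dt <= 0 or self.kT <= 0 or self.gamma < 0:
            raise ValueError("invalid dynamics parameters")
        for sp in ("FTC", "ETC", "C"):
            if sp not in self.mu_prime:
                raise ValueError(f"mu_prime missing species {sp}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls.from_dict(cfg)

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        kw = {}
        run = cfg.get("run", {})
        for k in ("n_steps", "seed", "replicas", "traj_stride", "checkpoint_stride",
                  "reservoir_size", "pre_equilibration_steps", "outdir",
                  "include_motor"):
            if k in run:
                kw[k] = run[k]
        dyn = cfg.get("dynamics", {})
        for k in ("gamma", "dt", "kT"):
            if k in dyn:
                kw[k] = dyn[k]
        chem = cfg.get("chemostat", {})
        if "move_period" in chem:
            kw["move_period"] = chem["move_period"]
        mu = dict(cls.__dataclass_fields__["mu_prime"].default_factory())
        for key, sp in (("mu_prime_ftc", "FTC"), ("mu_prime_etc", "ETC"),
                        ("mu_prime_c", "C")):
            if key in chem:
                mu[sp] = float(chem[key])
        kw["mu_prime"] = mu
        cell = cfg.get("cell", {})
        for k in ("L_inner", "L_outer"):
            if k in cell:
                kw[k] = cell[k]
        if "bonds" in cfg and "tet_k" in cfg["bonds"]:
            kw["tet_bond_k"] = cfg["bonds"]["tet_k"]
        pov = {}
        for entry in cfg.get("pairs", []):
            pov[(entry["i"], entry["j"])] = {k: float(v) for k, v in entry.items()
                                             if k in ("eps_R", "eps_A")}
        kw["pair_overrides"] = pov
        obj = cls(**kw)
        obj._raw_cfg = cfg
        return obj

    def make_tables(self) -> ForceFieldTables:
        raw = getattr(self, "_raw_cfg", None)
        if raw is not None:
            return tables_from_config(raw)
        return default_tables(pair_overrides=self.pair_overrides,
                              L_inner=self.L_inner, L_outer=self.L_outer)


# ---------------------------------------------------------------------------
# extended-XYZ trajectory I/O
# ---------------------------------------------------------------------------

def write_frame(fh, state: SystemState, L_outer: float, L_inner: float):
    """Append one extended-XYZ frame (species, position, momentum, molecule)."""
    fh.write(f"{state.n}\n")
    fh.write(f'Lattice="{L_outer:g} 0 0 0 {L_outer:g} 0 0 0 {L_outer:g}" '
             f'Properties=species:S:1:pos:R:3:momenta:R:3:mol:I:1 '
             f'Time={state.time:.17g} Step={state.step} L_inner={L_inner:g}\n')
    for i in range(state.n):
        p = state.positions[i]
        m = state.momenta[i]
        fh.write(f"{TYPE_NAMES[state.types[i]]} "
                 f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g} "
                 f"{m[0]:.17g} {m[1]:.17g} {m[2]:.17g} "
                 f"{state.mol_of[i]}\n")


class FrameParseError(ValueError):
    pass


def read_frames(path):
    """Read all extended-XYZ frames; yields dicts with arrays and metadata."""
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    out = []
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i])
        except ValueError as e:
            raise FrameParseError(f"line {i + 1}: expected particle count") from e
        comment = lines[i + 1]
        meta = {}
        for tok in ("Time=", "Step="):
            if tok in comment:
                meta[tok[:-1].lower()] = float(comment.split(tok)[1].split()[0])
        pos = np.empty((n, 3))
        mom = np.empty((n, 3))
        types = np.empty(n, dtype=np.int64)
        mol = np.empty(n, dtype=np.int64)
        for k in range(n):
            parts = lines[i + 2 + k].split()
            if len(parts) != 8:
                raise FrameParseError(f"line {i + 3 + k}: expected 8 columns")
            types[k] = TYPE_BY_NAME[parts[0]]
            pos[k] = [float(x) for x in parts[1:4]]
            mom[k] = [float(x) for x in parts[4:7]]
            mol[k] = int(parts[7])
        out.append({"positions": pos, "momenta": mom, "types": types,
                    "mol": mol, **meta})
        i += 2 + n
    return out


def _rle_encode(series: np.ndarray) -> str:
    if len(series) == 0:
        return ""
    change = np.nonzero(np.diff(series))[0]
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [len(series)]])
    return "\n".join(f"{int(series[s])} {int(e - s)}" for s, e in zip(starts, ends))


def _rle_decode(text: str) -> np.ndarray:
    vals, reps = [], []
    for line in text.splitlines():
        if line.strip():
            v, r = line.split()
            vals.append(int(v))
            reps.append(int(r))
    return np.repeat(np.array(vals, dtype=np.int64), reps)


# ---------------------------------------------------------------------------
# run
# ---------------------------------------------------------------------------

@dataclass
class ReplicaResult:
    counts: CycleCounts
    events: list
    moves: list
    coarse: np.ndarray
    state: SystemState
    diagnostics: dict


def _run_replica(config: RunConfig, tables: ForceFieldTables,
                 reservoirs: dict, seed_seq: np.random.SeedSequence,
                 outdir: pathlib.Path | None, tag: str) -> ReplicaResult:
    md_ss, gc_ss = seed_seq.spawn(2)
    rng_md = np.random.default_rng(md_ss)
    rng_gc = np.random.default_rng(gc_ss)
    cell = SimulationCell(config.L_inner, config.L_outer)
    params = DynamicsParams(gamma=config.gamma, dt=config.dt, kT=config.kT)
    th = config.thresholds
    layout = MotorLayout()
    state, tables = build_system(layout=layout, cell=cell, tables=tables,
                                 tet_bond_k=config.tet_bond_k,
                                 include_motor=config.include_motor)
    spec = ChemostatSpec(mu_prime=dict(config.mu_prime),
                         move_period=config.move_period,
                         reservoirs=reservoirs)

    # short equilibration of the bare motor before the chemostat switches on
    n_pre = config.pre_equilibration_steps
    while n_pre > 0:
        chunk = min(n_pre, 1000)
        run_md_segment(state, tables, params, chunk, rng_md, cell=cell, thresholds=th)
        n_pre -= chunk
    state.step = 0
    state.time = 0.0

    detector = EventDetector(thresholds=th)
    moves = []
    coarse_chunks = []
    sidx_chunks = []
    blocked_chunks = []
    traj_fh = None
    if outdir is not None:
        traj_fh = open(outdir / f"traj_{tag}.extxyz", "w")
        write_frame(traj_fh, state, config.L_outer, config.L_inner)
        ev_fh = open(outdir / f"events_{tag}.jsonl", "w")
        mv_fh = open(outdir / f"moves_{tag}.jsonl", "w")
        n_ev_written = 0

    n_segments = config.n_steps // config.move_period
    temp_sum = 0.0
    ke_n = 0
    ftc_sum = 0.0
    for seg_i in range(n_segments):
        mol_ids = [c.mol_id for c in state.clusters]
        seg = run_md_segment(state, tables, params, config.move_period,
                             rng_md, cell=cell, thresholds=th)
        detector.process_segment(state.time - config.move_period * config.dt,
                                 config.dt, seg, mol_ids)
        sidx_chunks.append(seg["shuttle_idx"])
        blocked_chunks.append(seg["blocked"])
        if state.n:
            temp_sum += 2.0 * seg["kinetic"].sum() / (3.0 * state.n)
        ke_n += len(seg["kinetic"])
        ftc_sum += sum(1 for c in state.clusters
                       if c.has_cent() and detector.latch_of(c.mol_id) != "ETC")
        associate_free_c(state, th, cell)
        detector.sync_latches(state.clusters)
        tables, move = gcmc_sweep(state, tables, spec, rng_gc,
                                  thresholds=th, cell=cell, params=params)
        moves.append(move)
        if outdir is not None:
            mv_fh.write(json.dumps(move.to_dict()) + "\n")
            while n_ev_written < len(detector.events):
                ev_fh.write(json.dumps(detector.events[n_ev_written].to_dict()) + "\n")
                n_ev_written += 1
            if traj_fh and (seg_i + 1) * config.move_period % config.traj_stride == 0:
                write_frame(traj_fh, state, config.L_outer, config.L_inner)

    sidx = np.concatenate(sidx_chunks) if sidx_chunks else np.zeros(0, dtype=np.int64)
    blocked = (np.concatenate(blocked_chunks, axis=0) if blocked_chunks
               else np.zeros((0, 2), dtype=np.uint8))
    coarse = (coarse_series(sidx, blocked) if config.include_motor and len(sidx)
              else np.zeros(0, dtype=np.int64))
    diag = {"mean_kinetic_temperature": temp_sum / ke_n if ke_n else None,
            "mean_n_ftc": ftc_sum / max(n_segments, 1),
            "final_n_particles": state.n,
            "n_clusters": len(state.clusters)}
    if outdir is not None:
        while n_ev_written < len(detector.events):
            ev_fh.write(json.dumps(detector.events[n_ev_written].to_dict()) + "\n")
            n_ev_written += 1
        for fh in (traj_fh, ev_fh, mv_fh):
            fh.close()
        (outdir / f"coarse_{tag}.rle").write_text(_rle_encode(coarse))
    return ReplicaResult(counts=detector.counts, events=detector.events,
                         moves=moves, coarse=coarse, state=state,
                         diagnostics=diag)


def run(config: RunConfig, tables: ForceFieldTables | None = None,
        reservoirs: dict | None = None):
    """Execute ``config.replicas`` independent runs; returns list of results.

    Reservoir ensembles are generated once (seeded from the run seed) and
    shared across replicas; replicas differ only by spawned seeds.  When
    ``config.outdir`` is set, trajectory/event/move/coarse files and an
    observables summary are written there.
    """
    root_ss = np.random.SeedSequence(config.seed)
    res_ss, *rep_ss = root_ss.spawn(1 + config.replicas)
    if tables is None:
        tables = config.make_tables()
    if reservoirs is None:
        rng_res = np.random.default_rng(res_ss)
        reservoirs = {}
        for sp in ("FTC", "ETC"):
            reservoirs[sp] = generate_reservoir(
                sp, config.reservoir_size, config.kT, rng_res, tables=tables,
                tet_bond_k=config.tet_bond_k, r_ftc=config.thresholds.r_ftc)
    outdir = None
    if config.outdir is not None:
        outdir = pathlib.Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
    results = []
    for i, ss in enumerate(rep_ss):
        results.append(_run_replica(config, tables, reservoirs, ss, outdir,
                                    tag=f"r{i}"))
    if outdir is not None:
        report = analyze(results, dt=config.dt)
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return results


# ---------------------------------------------------------------------------
# mid-level segment loop and checkpointing
# ---------------------------------------------------------------------------

def simulate(state, tables, spec, params, detector, rng_md, rng_gc,
             n_segments: int, thresholds=None, cell=None):
    """Advance n_segments of (move_period MD steps + one GCMC trial).

    The building block behind ``run``; operates purely in memory so it can be
    checkpointed and resumed bit-exactly.  Returns (tables, move records).
    """
    if thresholds is None:
        thresholds = Thresholds()
    if cell is None:
        cell = SimulationCell(tables.L_inner, tables.L_outer)
    moves = []
    for _ in range(n_segments):
        mol_ids = [c.mol_id for c in state.clusters]
        seg = run_md_segment(state, tables, params, spec.move_period,
                             rng_md, cell=cell, thresholds=thresholds)
        detector.process_segment(state.time - spec.move_period * params.dt,
                                 params.dt, seg, mol_ids)
        associate_free_c(state, thresholds, cell)
        detector.sync_latches(state.clusters)
        tables, move = gcmc_sweep(state, tables, spec, rng_gc,
                                  thresholds=thresholds, cell=cell, params=params)
        moves.append(move)
    return tables, moves


def reconstruct_tables(state: SystemState, base: ForceFieldTables,
                       layout: MotorLayout = MotorLayout()) -> ForceFieldTables:
    """Rebuild bonded-term lists and the wall mask from a SystemState."""
    from .topology import build_motor, tet_bond_terms
    if state.n_motor:
        (_, _, fene_idx, fene_k, fene_rmax,
         angle_idx, angle_k, angle_t0) = build_motor(layout)
    else:
        fene_idx = np.zeros((0, 2), dtype=np.int64)
        fene_k = fene_rmax = np.zeros(0)
        angle_idx = np.zeros((0, 3), dtype=np.int64)
        angle_k = angle_t0 = np.zeros(0)
    bidx_list, bk_list = [], []
    for c in state.clusters:
        bi, bk = tet_bond_terms(c.tet_ids, state.tet_bond_k)
        bidx_list.append(bi)
        bk_list.append(bk)
    bidx = np.vstack(bidx_list) if bidx_list else np.zeros((0, 2), dtype=np.int64)
    bk = np.concatenate(bk_list) if bk_list else np.zeros(0)
    mask = np.zeros(state.n, dtype=np.bool_)
    mask[:state.n_motor] = True
    return base.replace_bonded(bond_idx=bidx, bond_k=bk,
                               fene_idx=fene_idx, fene_k=fene_k,
                               fene_rmax=fene_rmax, angle_idx=angle_idx,
                               angle_k=angle_k, angle_t0=angle_t0,
                               wall_mask=mask)


def save_checkpoint(path, state: SystemState, rng_md, rng_gc,
                    detector: EventDetector):
    """Serialize full state, RNG streams and detector state as JSON text."""
    doc = {
        "state": {
            "positions": state.positions.tolist(),
            "momenta": state.momenta.tolist(),
            "types": state.types.tolist(),
            "mol_of": state.mol_of.tolist(),
            "clusters": [{"tet_ids": c.tet_ids.tolist(), "cent_id": int(c.cent_id),
                          "mol_id": int(c.mol_id), "latched": c.latched}
                         for c in state.clusters],
            "free_c": list(map(int, state.free_c)),
            "time": state.time, "step": state.step,
            "n_motor": state.n_motor, "next_mol_id": state.next_mol_id,
            "tet_bond_k": state.tet_bond_k,
        },
        "rng_md": rng_md.bit_generator.state,
        "rng_gc": rng_gc.bit_generator.state,
        "detector": {
            "counts": dataclasses.asdict(detector.counts),
            "latch": {str(k): v for k, v in detector._latch.items()},
            "blocked": detector._blocked,
            "last_idx": detector._last_idx,
            "cycler": {"w": detector._cycler.w, "n_cw": detector._cycler.n_cw,
                       "n_ccw": detector._cycler.n_ccw},
            "events": [e.to_dict() for e in detector.events],
        },
    }
    pathlib.Path(path).write_text(json.dumps(doc))


def load_checkpoint(path, base_tables: ForceFieldTables,
                    layout: MotorLayout = MotorLayout()):
    """Inverse of save_checkpoint: (state, tables, rng_md, rng_gc, detector)."""
    from .events import EventRecord
    doc = json.loads(pathlib.Path(path).read_text())
    s = doc["state"]
    state = SystemState(
        positions=np.array(s["positions"], dtype=np.float64).reshape(-1, 3),
        momenta=np.array(s["momenta"], dtype=np.float64).reshape(-1, 3),
        types=np.array(s["types"], dtype=np.int64),
        mol_of=np.array(s["mol_of"], dtype=np.int64),
        clusters=[ClusterRecord(tet_ids=np.array(c["tet_ids"], dtype=np.int64),
                                cent_id=c["cent_id"], mol_id=c["mol_id"],
                                latched=c["latched"]) for c in s["clusters"]],
        free_c=list(s["free_c"]), time=s["time"], step=s["step"],
        n_motor=s["n_motor"], next_mol_id=s["next_mol_id"],
        tet_bond_k=s["tet_bond_k"])
    tables = reconstruct_tables(state, base_tables, layout)
    rng_md = np.random.default_rng()
    rng_md.bit_generator.state = doc["rng_md"]
    rng_gc = np.random.default_rng()
    rng_gc.bit_generator.state = doc["rng_gc"]
    d = doc["detector"]
    detector = EventDetector()
    detector.counts = CycleCounts(**d["counts"])
    detector._latch = {int(k): v for k, v in d["latch"].items()}
    detector._blocked = d["blocked"]
    detector._last_idx = d["last_idx"]
    detector._cycler.w = d["cycler"]["w"]
    detector._cycler.n_cw = d["cycler"]["n_cw"]
    detector._cycler.n_ccw = d["cycler"]["n_ccw"]
    detector.events = [EventRecord(
        time=e["time"], kind=e["kind"], mol_id=e.get("mol_id", -1),
        catalyzed=e.get("catalyzed"), site=e.get("site"),
        direction=e.get("direction"), r_tet_min=e.get("r_tet_min"))
        for e in d["events"]]
    return state, tables, rng_md, rng_gc, detector


# ---------------------------------------------------------------------------
# analysis
# ---------------------------------------------------------------------------

def _mean_se(vals):
    vals = [v for v in vals if v is not None]
    if not vals:
        return None, None
    m = float(np.mean(vals))
    se = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return m, se


def analyze(results, dt: float, pathway_threshold: float = 1.0) -> dict:
    """Observables, pooled rates, cycle report and pathway split for a bundle.

    ``results`` is a list of ReplicaResult (or a directory path written by
    ``run``).  Per-replica observables are averaged with standard errors;
    rates pool all replicas through the eight-state model.
    """
    if isinstance(results, (str, pathlib.Path)):
        results = load_bundle(results)
    per = {"bias": [], "current": [], "coupling": []}
    missing = {"bias": 0, "coupling": 0}
    for r in results:
        if r.counts.t_obs <= 0 and len(r.coarse):
            r.counts.t_obs = len(r.coarse) * dt
        if r.counts.t_obs <= 0:
            b = c = q = None
        else:
            b, c, q = observables(r.counts)
        per["bias"].append(b)
        per["current"].append(c)
        per["coupling"].append(q)
        missing["bias"] += b is None
        missing["coupling"] += q is None
    report = {"n_replicas": len(results)}
    for key in ("bias", "current", "coupling"):
        m, se = _mean_se(per[key])
        report[key] = {"mean": m, "se": se, "per_replica": per[key]}
    report["excluded"] = missing

    series = [r.coarse for r in results if len(r.coarse)]
    if series:
        fit = EightStateModel(series, dt).fit()
        report["rates"] = {k: fit.rates[k] for k in fit.rates}
        report["rate_stderr"] = {k: fit.stderr[k] for k in fit.stderr}
        report["p_ss"] = list(fit.p_ss)
        report["n_disconnected"] = fit.n_disconnected
        rep = fit.cycle_report()
        if rep is not None:
            report["R"] = rep.R
            report["affinity"] = rep.affinity
        all_events = [e for r in results for e in r.events]
        pw = resolve_pathways(all_events, threshold=pathway_threshold,
                              k_attach=(fit.rates["attach_close"]
                                        if fit.rates["attach_close"] else None))
        report["pathways"] = {
            "n_attach_C": pw.n_attach_C, "n_attach_TC": pw.n_attach_TC,
            "n_cleave_C": pw.n_cleave_C, "n_cleave_TC": pw.n_cleave_TC}
    ncat = [r.counts.n_cat for r in results]
    ntot = [sum(1 for e in r.events if e.kind == "DECOMPOSITION") for r in results]
    report["decompositions"] = {"catalyzed": ncat, "total": ntot}
    return report


class _LoadedReplica:
    def __init__(self, counts, events, coarse):
        self.counts = counts
        self.events = events
        self.moves = []
        self.coarse = coarse
        self.state = None
        self.diagnostics = {}


def load_bundle(outdir) -> list:
    """Re-load a written output bundle into ReplicaResult-like objects."""
    from .events import EventRecord
    outdir = pathlib.Path(outdir)
    out = []
    for evp in sorted(outdir.glob("events_*.jsonl")):
        tag = evp.stem.split("_", 1)[1]
        events = []
        with open(evp) as fh:
            for line in fh:
                d = json.loads(line)
                events.append(EventRecord(
                    time=d["time"], kind=d["kind"], mol_id=d.get("mol_id", -1),
                    catalyzed=d.get("catalyzed"), site=d.get("site"),
                    direction=d.get("direction"), r_tet_min=d.get("r_tet_min")))
        coarse = _rle_decode((outdir / f"coarse_{tag}.rle").read_text()) \
            if (outdir / f"coarse_{tag}.rle").exists() else np.zeros(0, dtype=np.int64)
        counts = CycleCounts(
            n_CW=sum(1 for e in events if e.kind == "CYCLE" and e.direction == "CW"),
            n_CCW=sum(1 for e in events if e.kind == "CYCLE" and e.direction == "CCW"),
            n_cat=sum(1 for e in events if e.kind == "DECOMPOSITION" and e.catalyzed),
            t_obs=0.0)
        out.append(_LoadedReplica(counts, events, coarse))
    return out
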