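"""Motor, fuel-cluster and simulation-cell construction.

The motor is a catenane: a large 30-bead track ring carrying two
binding/catalytic motifs on opposite sides, and a 12-bead shuttling ring
threaded through it (Gauss linking number +-1).  The ring layout, walking the
large ring in the clockwise (index-increasing) direction, is

    index 0          BIND
    indices 1-3      CAT2, CAT1, CAT3   (catalytic site 1)
    indices 4-14     INERT
    index 15         BIND
    indices 16-18    CAT2, CAT1, CAT3   (catalytic site 2)
    indices 19-29    INERT

Fuel species are tetrahedral clusters: four TET particles bonded along all six
edges with zero-rest-length harmonic springs, optionally caging a single CENT
particle (filled cluster, FTC).  The empty cluster (ETC) is the bare shell and
C is a lone CENT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forcefield import (ForceFieldTables, ParticleType, TET_TYPES,
                         DEFAULT_TET_BOND_K, DEFAULT_FENE_K, DEFAULT_FENE_RMAX,
                         DEFAULT_ANGLE_K)

MOTOR_MOL_ID = 0


@dataclass(frozen=True)
class MotorLayout:
    """Site layout of the large ring and size of the shuttling ring."""
    N_large: int = 30
    N_shuttle: int = 12
    binding_indices: tuple = (0, 15)
    fene_k: float = DEFAULT_FENE_K
    fene_rmax: float = DEFAULT_FENE_RMAX
    angle_k: float = DEFAULT_ANGLE_K

    def large_ring_types(self) -> np.ndarray:
        types = np.full(self.N_large, int(ParticleType.INERT), dtype=np.int64)
        for b in self.binding_indices:
            types[b] = ParticleType.BIND
            types[(b + 1) % self.N_large] = ParticleType.CAT2
            types[(b + 2) % self.N_large] = ParticleType.CAT1
            types[(b + 3) % self.N_large] = ParticleType.CAT3
        return types

    @property
    def cat1_indices(self) -> tuple:
        return tuple((b + 2) % self.N_large for b in self.binding_indices)


@dataclass(frozen=True)
class SimulationCell:
    """Concentric cubic boxes centred at the origin; the outer box is periodic."""
    L_inner: float = 30.0
    L_outer: float = 34.0

    def __post_init__(self):
        if self.L_outer <= self.L_inner:
            raise ValueError("L_outer must exceed L_inner")

    @property
    def shell_volume(self) -> float:
        return self.L_outer ** 3 - self.L_inner ** 3

    def wrap(self, positions: np.ndarray) -> np.ndarray:
        L = self.L_outer
        return positions - L * np.rint(positions / L)

    def min_image(self, d: np.ndarray) -> np.ndarray:
        L = self.L_outer
        return d - L * np.rint(d / L)


def region_of(position, cell: SimulationCell) -> str:
    """INNER iff every coordinate lies strictly inside the inner cube."""
    p = np.asarray(position, dtype=float)
    return "INNER" if np.all(np.abs(p) < 0.5 * cell.L_inner) else "SHELL"


@dataclass
class ClusterRecord:
    """One tetrahedral shell and (optionally) its tracked central particle."""
    tet_ids: np.ndarray            # 4 particle ids
    cent_id: int = -1              # -1 when no CENT is associated
    mol_id: int = -1
    latched: str = "ETC"           # hysteresis latch used by event detection

    def has_cent(self) -> bool:
        return self.cent_id >= 0


@dataclass
class SystemState:
    """Positions/momenta/types of all particles plus molecule bookkeeping.

    The single mutable object that dynamics and the chemostat act on.  Motor
    particles always occupy indices 0..41 (large ring then shuttle ring); free
    species follow and may appear/disappear under GCMC moves.
    """
    positions: np.ndarray
    momenta: np.ndarray
    types: np.ndarray
    mol_of: np.ndarray                    # molecule id per particle
    clusters: list = field(default_factory=list)
    free_c: list = field(default_factory=list)   # particle ids of free CENTs never in a cluster
    time: float = 0.0
    step: int = 0
    n_motor: int = 0
    next_mol_id: int = 1
    tet_bond_k: float = DEFAULT_TET_BOND_K

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "SystemState":
        import copy as _copy
        return SystemState(
            positions=self.positions.copy(), momenta=self.momenta.copy(),
            types=self.types.copy(), mol_of=self.mol_of.copy(),
            clusters=[_copy.deepcopy(c) for c in self.clusters],
            free_c=list(self.free_c), time=self.time, step=self.step,
            n_motor=self.n_motor, next_mol_id=self.next_mol_id,
            tet_bond_k=self.tet_bond_k)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _ring_coords(n: int, radius: float) -> np.ndarray:
    ang = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(n)])


def build_motor(layout: MotorLayout = MotorLayout(),
                cell: SimulationCell = SimulationCell()):
    """Construct motor coordinates and bonded-term lists.

    The large ring is a regular planar polygon with neighbour spacing ~= 1
    (radius N/(2 pi)); the shuttle ring is threaded around the large-ring bead
    midway through the second inert segment, its plane perpendicular to the
    local tangent.  Returns (coords, types, fene_idx, fene_k, fene_rmax,
    angle_idx, angle_k, angle_t0).
    """
    NL, NS = layout.N_large, layout.N_shuttle
    R_large = NL / (2.0 * np.pi)
    R_shut = NS / (2.0 * np.pi)
    large = _ring_coords(NL, R_large)

    # thread the shuttle around bead `pivot` (mid inert segment opposite site 1)
    pivot = 24
    center = large[pivot]
    tangent = large[(pivot + 1) % NL] - large[(pivot - 1) % NL]
    tangent /= np.linalg.norm(tangent)
    radial = center / np.linalg.norm(center)
    normal = np.cross(tangent, radial)
    normal /= np.linalg.norm(normal)
    ang = 2.0 * np.pi * np.arange(NS) / NS
    shuttle = (center[None, :]
               + R_shut * np.cos(ang)[:, None] * radial[None, :]
               + R_shut * np.sin(ang)[:, None] * normal[None, :])

    coords = np.vstack([large, shuttle])
    types = np.concatenate([
        layout.large_ring_types(),
        np.full(NS, int(ParticleType.SHUTTLE), dtype=np.int64)])

    fene, angles, t0s = [], [], []
    for base, nring in ((0, NL), (NL, NS)):
        theta0 = np.pi * (1.0 - 2.0 / nring)
        for i in range(nring):
            j = (i + 1) % nring
            fene.append((base + i, base + j))
            k = (i + 2) % nring
            angles.append((base + j, base + i, base + k))  # center first
            t0s.append(theta0)
    fene_idx = np.array(fene, dtype=np.int64)
    angle_idx = np.array(angles, dtype=np.int64)
    n_terms = len(fene)
    out = (coords, types, fene_idx,
           np.full(n_terms, layout.fene_k), np.full(n_terms, layout.fene_rmax),
           angle_idx, np.full(n_terms, layout.angle_k), np.array(t0s))
    if abs(abs(linking_number(coords[:NL], coords[NL:]))) < 0.5:
        raise RuntimeError("motor construction failed: rings are not interlocked")
    return out


def linking_number(ring_a: np.ndarray, ring_b: np.ndarray) -> float:
    """Gauss double integral over the two closed polygonal centerlines."""
    na, nb = len(ring_a), len(ring_b)
    da = np.roll(ring_a, -1, axis=0) - ring_a
    db = np.roll(ring_b, -1, axis=0) - ring_b
    mid_a = ring_a + 0.5 * da
    mid_b = ring_b + 0.5 * db
    total = 0.0
    for i in range(na):
        diff = mid_a[i] - mid_b                     # (nb, 3)
        cr = np.cross(da[i], db)                    # (nb, 3)
        r3 = np.linalg.norm(diff, axis=1) ** 3
        total += np.sum(np.einsum("ij,ij->i", cr, diff) / r3)
    return total / (4.0 * np.pi)


TET_EDGES = [(0, 1), (0, 2), (0, 3), (1, 2), (2, 3), (1, 3)]

#: Regular tetrahedron vertices (unit circumradius).
_TET_VERTS = np.array([[1.0, 1.0, 1.0], [1.0, -1.0, -1.0],
                       [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]) / np.sqrt(3.0)


def cluster_coords(species: str, edge: float = 0.95) -> np.ndarray:
    """Template coordinates for one cluster, COM at the origin.

    ``edge`` is the tetrahedron edge length (the default is near the minimum
    of the shipped harmonic-bond/LJ balance).  FTC = 4 TET + CENT at the
    center; ETC = shell only; C = single particle.
    """
    shell = _TET_VERTS * (edge * np.sqrt(3.0 / 8.0))
    if species == "FTC":
        return np.vstack([shell, np.zeros(3)])
    if species == "ETC":
        return shell.copy()
    if species == "C":
        return np.zeros((1, 3))
    raise ValueError(f"unknown species {species!r}")


def species_types(species: str) -> np.ndarray:
    tets = np.array([int(t) for t in TET_TYPES], dtype=np.int64)
    if species == "FTC":
        return np.concatenate([tets, [int(ParticleType.CENT)]])
    if species == "ETC":
        return tets
    if species == "C":
        return np.array([int(ParticleType.CENT)], dtype=np.int64)
    raise ValueError(f"unknown species {species!r}")


def build_cluster(species: str, placement: np.ndarray | None = None,
                  rotation: np.ndarray | None = None, edge: float = 0.95):
    """Coordinates and types for a placed cluster.

    Returns (coords, types).  ``placement`` translates the COM; ``rotation``
    (3x3) is applied about the COM first.
    """
    coords = cluster_coords(species, edge=edge)
    if rotation is not None:
        coords = coords @ rotation.T
    if placement is not None:
        coords = coords + np.asarray(placement, dtype=float)[None, :]
    return coords, species_types(species)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform SO(3) rotation matrix via a random unit quaternion."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])


def tet_bond_terms(tet_ids, k: float = DEFAULT_TET_BOND_K):
    """Harmonic bond list for one tetrahedral shell (complete graph K4)."""
    idx = np.array([(tet_ids[a], tet_ids[b]) for a, b in TET_EDGES], dtype=np.int64)
    return idx, np.full(len(TET_EDGES), k)


# ---------------------------------------------------------------------------
# whole-system assembly
# ---------------------------------------------------------------------------

def build_system(layout: MotorLayout = MotorLayout(),
                 cell: SimulationCell = SimulationCell(),
                 tables: ForceFieldTables | None = None,
                 tet_bond_k: float = DEFAULT_TET_BOND_K,
                 include_motor: bool = True,
                 rng: np.random.Generator | None = None):
    """Assemble an initial SystemState (motor only) and matching tables.

    The motor sits at the center of the inner box with zero momenta; the
    chemostat populates free species during the run.  Returns
    (state, tables) where ``tables`` carries the motor's bonded terms and
    wall mask.
    """
    from .forcefield import default_tables
    if tables is None:
        tables = default_tables(L_inner=cell.L_inner, L_outer=cell.L_outer)
    if include_motor:
        (coords, types, fene_idx, fene_k, fene_rmax,
         angle_idx, angle_k, angle_t0) = build_motor(layout, cell)
        n_motor = len(coords)
        mol = np.full(n_motor, MOTOR_MOL_ID, dtype=np.int64)
    else:
        coords = np.zeros((0, 3))
        types = np.zeros(0, dtype=np.int64)
        fene_idx = np.zeros((0, 2), dtype=np.int64)
        fene_k = fene_rmax = np.zeros(0)
        angle_idx = np.zeros((0, 3), dtype=np.int64)
        angle_k = angle_t0 = np.zeros(0)
        n_motor = 0
        mol = np.zeros(0, dtype=np.int64)

    tables = tables.replace_bonded(
        bond_idx=np.zeros((0, 2), dtype=np.int64), bond_k=np.zeros(0),
        fene_idx=fene_idx, fene_k=fene_k, fene_rmax=fene_rmax,
        angle_idx=angle_idx, angle_k=angle_k, angle_t0=angle_t0,
        wall_mask=np.concatenate([np.ones(n_motor, dtype=np.bool_)]),
        L_inner=cell.L_inner, L_outer=cell.L_outer)

    state = SystemState(positions=coords.astype(np.float64),
                        momenta=np.zeros_like(coords, dtype=np.float64),
                        types=types, mol_of=mol, n_motor=n_motor,
                        tet_bond_k=tet_bond_k)
    return state, tables


def add_cluster_to_state(state: SystemState, tables: ForceFieldTables,
                         species: str, coords: np.ndarray):
    """Append one cluster's particles; returns (new tables, record-or-cid).

    Bonded terms and the wall mask grow accordingly (free species never feel
    the wall).  For species C the new free CENT id is recorded in
    ``state.free_c``.
    """
    n0 = state.n
    types = np.ascontiguousarray(species_types(species))
    mol_id = state.next_mol_id
    state.next_mol_id += 1
    state.positions = np.vstack([state.positions, coords])
    state.momenta = np.vstack([state.momenta, np.zeros_like(coords)])
    state.types = np.concatenate([state.types, types])
    state.mol_of = np.concatenate([state.mol_of, np.full(len(types), mol_id, dtype=np.int64)])
    new_mask = np.concatenate([tables.wall_mask, np.zeros(len(types), dtype=np.bool_)])

    if species == "C":
        state.free_c.append(n0)
        tables = tables.replace_bonded(wall_mask=new_mask)
        return tables, n0

    tet_ids = np.arange(n0, n0 + 4, dtype=np.int64)
    k = getattr(state, "tet_bond_k", DEFAULT_TET_BOND_K)
    bidx, bk = tet_bond_terms(tet_ids, k)
    tables = tables.replace_bonded(
        bond_idx=np.vstack([tables.bond_idx, bidx]),
        bond_k=np.concatenate([tables.bond_k, bk]),
        wall_mask=new_mask)
    cent = n0 + 4 if species == "FTC" else -1
    rec = ClusterRecord(tet_ids=tet_ids, cent_id=cent, mol_id=mol_id,
                        latched="FTC" if species == "FTC" else "ETC")
    state.clusters.append(rec)
    return tables, rec


def remove_particles(state: SystemState, tables: ForceFieldTables, ids):
    """Delete particles by id, remapping all bookkeeping; returns new tables."""
    ids = sorted(set(int(i) for i in ids))
    keep = np.ones(state.n, dtype=bool)
    keep[ids] = False
    remap = np.cumsum(keep) - 1          # old id -> new id (valid where keep)

    state.positions = state.positions[keep]
    state.momenta = state.momenta[keep]
    state.types = state.types[keep]
    state.mol_of = state.mol_of[keep]

    removed = set(ids)
    new_clusters = []
    orphaned = []
    for c in state.clusters:
        if any(int(t) in removed for t in c.tet_ids):
            # the whole shell goes; a still-associated CENT becomes a free C
            if c.has_cent() and c.cent_id not in removed:
                orphaned.append(int(remap[c.cent_id]))
            continue
        c.tet_ids = remap[c.tet_ids]
        if c.has_cent():
            c.cent_id = -1 if c.cent_id in removed else int(remap[c.cent_id])
            if c.cent_id < 0:
                c.latched = "ETC"
        new_clusters.append(c)
    state.clusters = new_clusters
    state.free_c = ([int(remap[i]) for i in state.free_c if i not in removed]
                    + orphaned)

    bond_keep = np.array([not (i in removed or j in removed)
                          for i, j in tables.bond_idx], dtype=bool) \
        if len(tables.bond_idx) else np.zeros(0, dtype=bool)
    new_bidx = remap[tables.bond_idx[bond_keep]] if len(tables.bond_idx) else tables.bond_idx
    tables = tables.replace_bonded(
        bond_idx=new_bidx.astype(np.int64).reshape(-1, 2),
        bond_k=tables.bond_k[bond_keep] if len(tables.bond_k) else tables.bond_k,
        fene_idx=remap[tables.fene_idx].astype(np.int64).reshape(-1, 2) if len(tables.fene_idx) else tables.fene_idx,
        angle_idx=remap[tables.angle_idx].astype(np.int64).reshape(-1, 3) if len(tables.angle_idx) else tables.angle_idx,
        wall_mask=tables.wall_mask[keep])
    return tables
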