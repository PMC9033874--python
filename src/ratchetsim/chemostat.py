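"""Grand-canonical Monte Carlo chemostats for the FTC / ETC / C species.

Every ``move_period`` Langevin steps one trial move is drawn uniformly from
six options (insertion or deletion of each species), restricted to the shell
between the inner and outer boxes.  Deletion of a copy of species i is
accepted with probability

    min[1, N_i exp(-beta (U(r') - U(r) + U_i0)) exp(-beta mu'_i)]

and insertion of a reservoir-drawn, uniformly rotated, uniformly placed copy
with

    min[1, (1/N_i(r')) exp(-beta (U(r') - U(r) - U_i0)) exp(+beta mu'_i)],

where N_i counts copies of the species in the shell, U_i0 is the copy's
internal potential energy and mu'_i = mu_i - A_i0 is the shifted chemical
potential (the standard-state free energy A_i0 is never evaluated).  Because
FTC and ETC have internal degrees of freedom, insertions draw configurations
from a pre-generated single-cluster canonical (reservoir) ensemble, so the
internal Boltzmann factor cancels exactly and only the cross-interaction
energy decides acceptance.

Species identity is classification-based: a cluster is removable as FTC only
while its reaction coordinate r <= r_ftc, as ETC only when its central
particle is absent or escaped (r >= r_etc); intermediates are ineligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .forcefield import (ForceFieldTables, ParticleType, total_energy_forces,
                         TET_TYPES)
from .topology import (SystemState, SimulationCell, ClusterRecord,
                       cluster_coords, species_types, random_rotation,
                       add_cluster_to_state, remove_particles, TET_EDGES,
                       region_of)

SPECIES = ("FTC", "ETC", "C")


@dataclass
class ChemostatSpec:
    mu_prime: dict = field(default_factory=lambda: {"FTC": 0.5, "ETC": -10.0, "C": -10.0})
    move_period: int = 100
    reservoirs: dict = field(default_factory=dict)   # species -> ReservoirEnsemble

    def __post_init__(self):
        if self.move_period < 1:
            raise ValueError("move_period >= 1")


@dataclass
class MoveRecord:
    step: int
    species: str
    direction: str          # ADD or REMOVE
    accepted: bool
    acceptance_prob: float
    N_before: int

    def to_dict(self):
        return {"step": self.step, "species": self.species,
                "direction": self.direction, "accepted": self.accepted,
                "acceptance_prob": self.acceptance_prob, "N_before": self.N_before}


# ---------------------------------------------------------------------------
# single-cluster internal energy and reservoir generation
# ---------------------------------------------------------------------------

@njit(cache=True)
def _internal_energy(coords, types, sigma_ij, eps_R, eps_A, rc2, ushift,
                     bond_i, bond_j, bond_k):
    n = coords.shape[0]
    u = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            ti = types[i]
            tj = types[j]
            if r2 < rc2[ti, tj] and r2 > 0.0:
                s2 = sigma_ij[ti, tj] ** 2 / r2
                s6 = s2 * s2 * s2
                u += 4.0 * eps_R[ti, tj] * s6 * s6 - 4.0 * eps_A[ti, tj] * s6 - ushift[ti, tj]
    for b in range(bond_i.shape[0]):
        i = bond_i[b]
        j = bond_j[b]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        u += 0.5 * bond_k[b] * (dx * dx + dy * dy + dz * dz)
    return u


def cluster_internal_energy(coords, species: str, tables: ForceFieldTables,
                            tet_bond_k: float) -> float:
    """Internal potential energy of one isolated cluster configuration."""
    types = species_types(species)
    sij, eR, eA, rc2, ush = tables.pair_tables()
    if species == "C":
        return 0.0
    bi = np.array([a for a, _ in TET_EDGES], dtype=np.int64)
    bj = np.array([b for _, b in TET_EDGES], dtype=np.int64)
    bk = np.full(len(TET_EDGES), tet_bond_k)
    return float(_internal_energy(np.ascontiguousarray(coords, dtype=np.float64),
                                  types, sij, eR, eA, rc2, ush, bi, bj, bk))


@njit(cache=True)
def _mc_sweeps(coords, types, sigma_ij, eps_R, eps_A, rc2, ushift,
               bond_i, bond_j, bond_k, kT, step_size, n_sweeps, seed):
    np.random.seed(seed)
    n = coords.shape[0]
    u = _internal_energy(coords, types, sigma_ij, eps_R, eps_A, rc2, ushift,
                         bond_i, bond_j, bond_k)
    acc = 0
    for sweep in range(n_sweeps):
        for i in range(n):
            old0 = coords[i, 0]
            old1 = coords[i, 1]
            old2 = coords[i, 2]
            coords[i, 0] += step_size * (np.random.random() - 0.5)
            coords[i, 1] += step_size * (np.random.random() - 0.5)
            coords[i, 2] += step_size * (np.random.random() - 0.5)
            u_new = _internal_energy(coords, types, sigma_ij, eps_R, eps_A,
                                     rc2, ushift, bond_i, bond_j, bond_k)
            if u_new <= u or np.random.random() < np.exp(-(u_new - u) / kT):
                u = u_new
                acc += 1
            else:
                coords[i, 0] = old0
                coords[i, 1] = old1
                coords[i, 2] = old2
    return u, acc


@dataclass
class ReservoirEnsemble:
    """Pre-generated canonical ensemble of single-cluster configurations."""
    species: str
    configs: np.ndarray      # (n_configs, n_particles, 3), COM at origin
    U0: np.ndarray           # (n_configs,)

    def __len__(self):
        return len(self.configs)


def _reaction_coordinate(coords) -> float:
    return float(np.linalg.norm(coords[4] - coords[:4].mean(axis=0)))


def generate_reservoir(species: str, n_configs: int, kT: float,
                       rng: np.random.Generator,
                       tables: ForceFieldTables | None = None,
                       tet_bond_k: float = 150.0,
                       sweeps_between: int = 20, step_size: float = 0.25,
                       r_ftc: float = 0.25) -> ReservoirEnsemble:
    """Metropolis sampling of a single isolated FTC or ETC cluster.

    Single-particle displacement moves at temperature kT; a configuration is
    stored every ``sweeps_between`` sweeps with its internal energy.  For the
    FTC species any stored configuration must still cage its central particle
    (r <= r_ftc); chains that escape are restarted from the last valid member.
    """
    if species not in ("FTC", "ETC"):
        raise ValueError("reservoirs exist only for species with internal structure")
    from .forcefield import default_tables
    if tables is None:
        tables = default_tables()
    types = species_types(species)
    sij, eR, eA, rc2, ush = tables.pair_tables()
    bi = np.array([a for a, _ in TET_EDGES], dtype=np.int64)
    bj = np.array([b for _, b in TET_EDGES], dtype=np.int64)
    bk = np.full(len(TET_EDGES), tet_bond_k)

    coords = cluster_coords(species)
    last_valid = coords.copy()
    configs = np.empty((n_configs, len(types), 3))
    U0 = np.empty(n_configs)
    stored = 0
    # burn-in
    _mc_sweeps(coords, types, sij, eR, eA, rc2, ush, bi, bj, bk,
               kT, step_size, 50, int(rng.integers(2 ** 31 - 1)))
    while stored < n_configs:
        u, _ = _mc_sweeps(coords, types, sij, eR, eA, rc2, ush, bi, bj, bk,
                          kT, step_size, sweeps_between,
                          int(rng.integers(2 ** 31 - 1)))
        if species == "FTC" and _reaction_coordinate(coords) > r_ftc:
            coords[:] = last_valid          # escaped: restart from a valid member
            continue
        com = coords.mean(axis=0)
        configs[stored] = coords - com
        U0[stored] = u
        last_valid = coords.copy()
        stored += 1
    return ReservoirEnsemble(species=species, configs=configs, U0=U0)


# ---------------------------------------------------------------------------
# species accounting
# ---------------------------------------------------------------------------

def _cluster_r(state: SystemState, c: ClusterRecord, cell: SimulationCell) -> float:
    tc = state.positions[c.tet_ids]
    ref = tc[0]
    com = ref + cell.min_image(tc - ref).mean(axis=0)
    if not c.has_cent():
        return np.inf
    return float(np.linalg.norm(cell.min_image(state.positions[c.cent_id] - com)))


def _cluster_com(state: SystemState, c: ClusterRecord, cell: SimulationCell,
                 include_cent: bool) -> np.ndarray:
    ids = list(map(int, c.tet_ids))
    if include_cent and c.has_cent():
        ids.append(c.cent_id)
    pts = state.positions[ids]
    ref = pts[0]
    return cell.wrap(ref + cell.min_image(pts - ref).mean(axis=0))


def free_c_ids(state: SystemState, thresholds, cell: SimulationCell) -> list:
    """Particle ids of CENTs currently classified free (never caged or escaped)."""
    out = list(state.free_c)
    for c in state.clusters:
        if c.has_cent() and _cluster_r(state, c, cell) >= thresholds.r_etc:
            out.append(int(c.cent_id))
    return sorted(out)


def removable_copies(state: SystemState, species: str, thresholds,
                     cell: SimulationCell) -> list:
    """Copies of ``species`` removable from the shell, as particle-id lists."""
    out = []
    if species == "C":
        for cid in free_c_ids(state, thresholds, cell):
            if region_of(cell.wrap(state.positions[cid]), cell) == "SHELL":
                out.append([cid])
        return out
    for c in state.clusters:
        r = _cluster_r(state, c, cell)
        if species == "FTC":
            if not (c.has_cent() and r <= thresholds.r_ftc):
                continue
            ids = list(map(int, c.tet_ids)) + [int(c.cent_id)]
            com = _cluster_com(state, c, cell, include_cent=True)
        else:
            if c.has_cent() and r < thresholds.r_etc:
                continue
            ids = list(map(int, c.tet_ids))
            com = _cluster_com(state, c, cell, include_cent=False)
        if region_of(com, cell) == "SHELL":
            out.append(ids)
    return out


def shell_counts(state: SystemState, thresholds, cell: SimulationCell) -> dict:
    return {sp: len(removable_copies(state, sp, thresholds, cell)) for sp in SPECIES}


# ---------------------------------------------------------------------------
# acceptance probabilities (exact total-energy differences)
# ---------------------------------------------------------------------------

def removal_acceptance(state: SystemState, tables: ForceFieldTables,
                       species: str, ids: list, N_shell: int,
                       mu_prime: float, kT: float,
                       cell: SimulationCell) -> float:
    """Eq.-style deletion acceptance for the copy given by particle ids."""
    if N_shell == 0:
        return 0.0
    beta = 1.0 / kT
    u_before, _ = total_energy_forces(state.positions, state.types, tables)
    trial = state.copy()
    trial_tables = remove_particles(trial, tables, ids)
    u_after, _ = total_energy_forces(trial.positions, trial.types, trial_tables)
    if species == "C":
        u0 = 0.0
    else:
        pts = state.positions[np.array(ids)]
        ref = pts[0]
        local = cell.min_image(pts - ref) + ref
        u0 = cluster_internal_energy(local, species, tables, state.tet_bond_k)
    arg = -beta * (u_after - u_before + u0) - beta * mu_prime
    return float(min(1.0, N_shell * np.exp(arg)))


def addition_acceptance(state: SystemState, tables: ForceFieldTables,
                        species: str, coords: np.ndarray, u0: float,
                        N_after: int, mu_prime: float, kT: float) -> float:
    """Insertion acceptance for a fully placed trial cluster."""
    beta = 1.0 / kT
    u_before, _ = total_energy_forces(state.positions, state.types, tables)
    trial = state.copy()
    trial_tables, _ = add_cluster_to_state(trial, tables, species, coords)
    u_after, _ = total_energy_forces(trial.positions, trial.types, trial_tables)
    arg = -beta * (u_after - u_before - u0) + beta * mu_prime
    return float(min(1.0, np.exp(arg) / N_after))


# ---------------------------------------------------------------------------
# one sweep
# ---------------------------------------------------------------------------

def _uniform_shell_point(cell: SimulationCell, rng: np.random.Generator) -> np.ndarray:
    while True:
        p = (rng.random(3) - 0.5) * cell.L_outer
        if region_of(p, cell) == "SHELL":
            return p


def gcmc_sweep(state: SystemState, tables: ForceFieldTables,
               spec: ChemostatSpec, rng: np.random.Generator,
               thresholds=None, cell: SimulationCell | None = None,
               params=None):
    """One uniformly chosen trial among {add, remove} x {FTC, ETC, C}.

    Mutates ``state`` (and returns possibly new ``tables``) on acceptance;
    bookkeeping (cluster records, molecule ids, free-C list, wall mask) is
    updated atomically.  Returns (tables, MoveRecord).
    """
    from .events import Thresholds
    from .dynamics import DynamicsParams
    if thresholds is None:
        thresholds = Thresholds()
    if cell is None:
        cell = SimulationCell(L_inner=tables.L_inner, L_outer=tables.L_outer)
    if params is None:
        params = DynamicsParams()
    kT = params.kT

    choice = int(rng.integers(6))
    species = SPECIES[choice % 3]
    direction = "ADD" if choice < 3 else "REMOVE"
    mu = spec.mu_prime[species]

    if direction == "REMOVE":
        copies = removable_copies(state, species, thresholds, cell)
        n_shell = len(copies)
        if n_shell == 0:
            return tables, MoveRecord(state.step, species, direction, False, 0.0, 0)
        ids = copies[int(rng.integers(n_shell))]
        p_acc = removal_acceptance(state, tables, species, ids, n_shell, mu, kT, cell)
        accepted = rng.random() < p_acc
        if accepted:
            tables = remove_particles(state, tables, ids)
        return tables, MoveRecord(state.step, species, direction, accepted, p_acc, n_shell)

    # ADD
    n_before = len(removable_copies(state, species, thresholds, cell))
    if species == "C":
        coords = _uniform_shell_point(cell, rng)[None, :]
        u0 = 0.0
    else:
        res = spec.reservoirs.get(species)
        if res is None or len(res) == 0:
            raise RuntimeError(f"no reservoir ensemble available for {species}")
        k = int(rng.integers(len(res)))
        conf = res.configs[k]
        u0 = float(res.U0[k])
        rot = random_rotation(rng)
        coords = conf @ rot.T + _uniform_shell_point(cell, rng)[None, :]
        coords = cell.wrap(coords)
    p_acc = addition_acceptance(state, tables, species, coords, u0,
                                n_before + 1, mu, kT)
    accepted = rng.random() < p_acc
    if accepted:
        n0 = state.n
        tables, _ = add_cluster_to_state(state, tables, species, coords)
        n_new = state.n - n0
        masses = tables.masses_for(state.types[n0:])
        state.momenta[n0:] = (np.sqrt(masses * kT)[:, None]
                              * rng.standard_normal((n_new, 3)))
    return tables, MoveRecord(state.step, species, direction, accepted, p_acc, n_before)


def associate_free_c(state: SystemState, thresholds, cell: SimulationCell):
    """Attach any free C that has been captured by an empty shell.

    A free central particle within r_ftc of an ETC's shell center becomes that
    cluster's tracked CENT (a recombination will then be scored by event
    detection).  Rare, checked at chemostat boundaries.
    """
    for c in state.clusters:
        if c.has_cent():
            continue
        tc = state.positions[c.tet_ids]
        ref = tc[0]
        com = ref + cell.min_image(tc - ref).mean(axis=0)
        for cid in list(state.free_c):
            d = np.linalg.norm(cell.min_image(state.positions[cid] - com))
            if d <= thresholds.r_ftc:
                c.cent_id = int(cid)
                c.latched = "ETC"       # recombination scored on the r series
                state.free_c.remove(cid)
                break
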