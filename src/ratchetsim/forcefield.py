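"""Potential-energy terms and force evaluation for the motor/fuel model.

All interactions are expressed in the model's non-dimensional units
(sigma_INERT = m_INERT = eps_R(INERT,INERT) = 1, with k_B T carried by the
integrator).  Five kinds of terms exist:

* a split Lennard-Jones pair potential with independent repulsive and
  attractive strengths,  U = 4 eps_R (s/r)^12 - 4 eps_A (s/r)^6,
  truncated-and-shifted at ``rcut_factor * sigma_ij``;
* zero-rest-length harmonic bonds holding tetrahedral-cluster edges together,
  U = k r^2 / 2;
* FENE bonds between adjacent ring beads;
* harmonic angle terms on consecutive ring triples, with the regular-polygon
  rest angle theta0 = pi (1 - 2/N_ring);
* a one-body r^-12 Lennard-Jones wall confining motor particles to the inner
  box.

The per-term functions are plain NumPy (convenient for tests and for the
chemostat's single-cluster energies); `total_energy_forces` dispatches to a
fused numba kernel that evaluates everything in one O(N^2) pass with
minimum-image displacements in the periodic outer box.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from numba import njit


class ParticleType(IntEnum):
    INERT = 0
    BIND = 1
    CAT1 = 2
    CAT2 = 3
    CAT3 = 4
    SHUTTLE = 5
    TET1 = 6
    TET2 = 7
    TET3 = 8
    TET4 = 9
    CENT = 10


NUM_TYPES = len(ParticleType)
TYPE_NAMES = [t.name for t in ParticleType]
TYPE_BY_NAME = {t.name: t for t in ParticleType}

TET_TYPES = (ParticleType.TET1, ParticleType.TET2, ParticleType.TET3, ParticleType.TET4)
CAT_TYPES = (ParticleType.CAT1, ParticleType.CAT2, ParticleType.CAT3)


class OverstretchError(RuntimeError):
    """A FENE bond reached its maximum extension (integrator instability)."""


@dataclass
class ForceFieldTables:
    """Symmetric per-type pair tables plus bonded-term lists.

    Pair parameters are stored as dense (ntypes, ntypes) arrays; undeclared
    pairs default to eps_R = 1, eps_A = 0.  ``sigma_pair[i, j]`` is the mean of
    the two particle radii.  Bonded terms are index lists into the particle
    arrays of the owning system and are filled in by the topology builders.
    """

    sigma: np.ndarray          # (ntypes,) per-type radius
    mass: np.ndarray           # (ntypes,)
    eps_R: np.ndarray          # (ntypes, ntypes)
    eps_A: np.ndarray          # (ntypes, ntypes)
    rcut_factor: float = 2.5

    # bonded terms (set by topology; empty by default)
    bond_idx: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=np.int64))
    bond_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    fene_idx: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=np.int64))
    fene_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    fene_rmax: np.ndarray = field(default_factory=lambda: np.zeros(0))
    angle_idx: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), dtype=np.int64))
    angle_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    angle_t0: np.ndarray = field(default_factory=lambda: np.zeros(0))

    # wall
    wall_mask: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.bool_))
    eps_wall: float = 1.0
    sigma_wall: float = 1.0
    L_inner: float = 30.0
    L_outer: float = 34.0

    def __post_init__(self) -> None:
        if np.any(self.sigma <= 0) or np.any(self.mass <= 0):
            raise ValueError("sigma and mass must be positive for every type")
        if np.any(np.diag(self.eps_R) <= 0):
            raise ValueError("all particles are volume-excluding: eps_R > 0 on the diagonal")

    @property
    def sigma_pair(self) -> np.ndarray:
        return 0.5 * (self.sigma[:, None] + self.sigma[None, :])

    def pair_tables(self):
        """Precomputed (sigma_ij, eps_R, eps_A, rcut^2, shift) dense tables."""
        sij = self.sigma_pair
        rc = self.rcut_factor * sij
        s6 = (sij / rc) ** 6
        ushift = 4.0 * self.eps_R * s6 * s6 - 4.0 * self.eps_A * s6
        return sij, self.eps_R, self.eps_A, rc * rc, ushift

    def masses_for(self, types: np.ndarray) -> np.ndarray:
        return self.mass[types]

    def replace_bonded(self, **kw) -> "ForceFieldTables":
        import dataclasses
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# per-term reference implementations (NumPy; used directly by tests/chemostat)
# ---------------------------------------------------------------------------

def pair_energy_force(r_vec, eps_R, eps_A, sigma, rcut_factor=2.5):
    """Split-LJ energy and force on particle i for displacement r_i - r_j.

    Truncated and shifted to zero at rcut_factor * sigma.  Raises on zero
    separation.
    """
    r_vec = np.asarray(r_vec, dtype=float)
    r2 = float(r_vec @ r_vec)
    if r2 == 0.0:
        raise ZeroDivisionError("pair interaction at zero separation")
    rc = rcut_factor * sigma
    if r2 >= rc * rc:
        return 0.0, np.zeros_like(r_vec)
    s2 = sigma * sigma / r2
    s6 = s2 * s2 * s2
    s12 = s6 * s6
    sc6 = (sigma / rc) ** 6
    u = 4.0 * eps_R * s12 - 4.0 * eps_A * s6 - (4.0 * eps_R * sc6 * sc6 - 4.0 * eps_A * sc6)
    # f = -dU/dr rhat = (48 eps_R s12 - 24 eps_A s6)/r2 * r_vec
    fscal = (48.0 * eps_R * s12 - 24.0 * eps_A * s6) / r2
    return u, fscal * r_vec


def harmonic_energy_force(r_vec, k):
    """Zero-rest-length harmonic bond: U = k r^2 / 2, force on i = -k r_vec."""
    r_vec = np.asarray(r_vec, dtype=float)
    return 0.5 * k * float(r_vec @ r_vec), -k * r_vec


def fene_energy_force(r_vec, k_F, r_max):
    """FENE bond U = -k_F r_max^2 log(1 - (r/r_max)^2) / 2; diverges at r_max."""
    r_vec = np.asarray(r_vec, dtype=float)
    r2 = float(r_vec @ r_vec)
    x = r2 / (r_max * r_max)
    if x >= 1.0:
        raise OverstretchError(f"FENE bond stretched to r={np.sqrt(r2):.4f} >= r_max={r_max}")
    u = -0.5 * k_F * r_max * r_max * np.log1p(-x)
    return u, -(k_F / (1.0 - x)) * r_vec


def angle_energy_force(r_i, r_j, r_k, k_A, theta0):
    """Harmonic angle about center particle i: U = k_A (theta - theta0)^2 / 2.

    Returns (U, (F_i, F_j, F_k)).  Collinear configurations are handled by
    clamping cos(theta) into [-1, 1] and flooring sin(theta).
    """
    r_i, r_j, r_k = (np.asarray(v, dtype=float) for v in (r_i, r_j, r_k))
    u = r_j - r_i
    v = r_k - r_i
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ZeroDivisionError("degenerate angle: zero bond vector")
    c = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    theta = np.arccos(c)
    s = max(np.sqrt(max(1.0 - c * c, 0.0)), 1e-12)
    dU = k_A * (theta - theta0)
    uh, vh = u / nu, v / nv
    dth_dj = (c * uh - vh) / (nu * s)
    dth_dk = (c * vh - uh) / (nv * s)
    F_j = -dU * dth_dj
    F_k = -dU * dth_dk
    F_i = -(F_j + F_k)
    return 0.5 * k_A * (theta - theta0) ** 2, (F_i, F_j, F_k)


def wall_energy_force(r, eps_wall, sigma_wall, L_inner):
    """One-body r^-12 wall confining a motor particle to the inner box."""
    r = np.asarray(r, dtype=float)
    h = 0.5 * L_inner
    dplus = r - h
    dminus = r + h
    if np.any(dplus == 0.0) or np.any(dminus == 0.0):
        raise ZeroDivisionError("particle exactly on a wall face")
    sp = (sigma_wall / dplus) ** 12
    sm = (sigma_wall / dminus) ** 12
    u = 4.0 * eps_wall * float(np.sum(sp + sm))
    f = 4.0 * eps_wall * 12.0 * (sp / dplus + sm / dminus)
    return u, f


# ---------------------------------------------------------------------------
# fused numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _ff_kernel(pos, types, sigma_ij, eps_R, eps_A, rc2, ushift,
               bond_idx, bond_k, fene_idx, fene_k, fene_rmax,
               ang_idx, ang_k, ang_t0,
               wall_mask, eps_wall, sigma_wall, L_inner, L_outer):
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    utot = 0.0
    status = 0  # 1 = FENE overstretch

    # nonbonded pairs, minimum image in the outer box
    for i in range(n):
        ti = types[i]
        for j in range(i + 1, n):
            tj = types[j]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= L_outer * np.rint(dx / L_outer)
            dy -= L_outer * np.rint(dy / L_outer)
            dz -= L_outer * np.rint(dz / L_outer)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rc2[ti, tj] and r2 > 0.0:
                s2 = sigma_ij[ti, tj] * sigma_ij[ti, tj] / r2
                s6 = s2 * s2 * s2
                s12 = s6 * s6
                utot += 4.0 * eps_R[ti, tj] * s12 - 4.0 * eps_A[ti, tj] * s6 - ushift[ti, tj]
                fs = (48.0 * eps_R[ti, tj] * s12 - 24.0 * eps_A[ti, tj] * s6) / r2
                forces[i, 0] += fs * dx
                forces[i, 1] += fs * dy
                forces[i, 2] += fs * dz
                forces[j, 0] -= fs * dx
                forces[j, 1] -= fs * dy
                forces[j, 2] -= fs * dz

    # harmonic bonds (tetrahedron edges): zero rest length
    for b in range(bond_idx.shape[0]):
        i = bond_idx[b, 0]
        j = bond_idx[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= L_outer * np.rint(dx / L_outer)
        dy -= L_outer * np.rint(dy / L_outer)
        dz -= L_outer * np.rint(dz / L_outer)
        k = bond_k[b]
        utot += 0.5 * k * (dx * dx + dy * dy + dz * dz)
        forces[i, 0] -= k * dx
        forces[i, 1] -= k * dy
        forces[i, 2] -= k * dz
        forces[j, 0] += k * dx
        forces[j, 1] += k * dy
        forces[j, 2] += k * dz

    # FENE bonds (ring neighbours); motor never crosses the periodic boundary
    for b in range(fene_idx.shape[0]):
        i = fene_idx[b, 0]
        j = fene_idx[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        rm2 = fene_rmax[b] * fene_rmax[b]
        x = r2 / rm2
        if x >= 1.0:
            status = 1
            x = 0.999999
        utot += -0.5 * fene_k[b] * rm2 * np.log(1.0 - x)
        fs = -fene_k[b] / (1.0 - x)
        forces[i, 0] += fs * dx
        forces[i, 1] += fs * dy
        forces[i, 2] += fs * dz
        forces[j, 0] -= fs * dx
        forces[j, 1] -= fs * dy
        forces[j, 2] -= fs * dz

    # angles: center particle listed first
    for a in range(ang_idx.shape[0]):
        ic = ang_idx[a, 0]
        jj = ang_idx[a, 1]
        kk = ang_idx[a, 2]
        ux = pos[jj, 0] - pos[ic, 0]
        uy = pos[jj, 1] - pos[ic, 1]
        uz = pos[jj, 2] - pos[ic, 2]
        vx = pos[kk, 0] - pos[ic, 0]
        vy = pos[kk, 1] - pos[ic, 1]
        vz = pos[kk, 2] - pos[ic, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        s = np.sqrt(max(1.0 - c * c, 0.0))
        if s < 1e-12:
            s = 1e-12
        dU = ang_k[a] * (theta - ang_t0[a])
        utot += 0.5 * ang_k[a] * (theta - ang_t0[a]) ** 2
        pref = -dU / s
        # dtheta/dr_j = (c*uhat - vhat)/(nu*s); force = -dU * dtheta/dr
        fjx = pref * (c * ux / nu - vx / nv) / nu
        fjy = pref * (c * uy / nu - vy / nv) / nu
        fjz = pref * (c * uz / nu - vz / nv) / nu
        fkx = pref * (c * vx / nv - ux / nu) / nv
        fky = pref * (c * vy / nv - uy / nu) / nv
        fkz = pref * (c * vz / nv - uz / nu) / nv
        forces[jj, 0] += fjx
        forces[jj, 1] += fjy
        forces[jj, 2] += fjz
        forces[kk, 0] += fkx
        forces[kk, 1] += fky
        forces[kk, 2] += fkz
        forces[ic, 0] -= fjx + fkx
        forces[ic, 1] -= fjy + fky
        forces[ic, 2] -= fjz + fkz

    # LJ wall on motor particles only
    h = 0.5 * L_inner
    sw12 = sigma_wall ** 12
    for i in range(n):
        if wall_mask[i]:
            for ax in range(3):
                dp = pos[i, ax] - h
                dm = pos[i, ax] + h
                sp = sw12 / dp ** 12
                sm = sw12 / dm ** 12
                utot += 4.0 * eps_wall * (sp + sm)
                forces[i, ax] += 48.0 * eps_wall * (sp / dp + sm / dm)

    return utot, forces, status


def total_energy_forces(positions, types, tables: ForceFieldTables):
    """Total potential energy and per-particle forces (-grad U).

    Minimum-image displacements use the periodic outer box.  Raises
    OverstretchError if any FENE bond is at or beyond r_max.
    """
    positions = np.ascontiguousarray(positions, dtype=np.float64)
    types = np.ascontiguousarray(types, dtype=np.int64)
    sij, eR, eA, rc2, ush = tables.pair_tables()
    wall_mask = tables.wall_mask
    if wall_mask.shape[0] != positions.shape[0]:
        raise ValueError("wall_mask length does not match particle count")
    u, f, status = _ff_kernel(
        positions, types, sij, eR, eA, rc2, ush,
        tables.bond_idx, tables.bond_k,
        tables.fene_idx, tables.fene_k, tables.fene_rmax,
        tables.angle_idx, tables.angle_k, tables.angle_t0,
        wall_mask, tables.eps_wall, tables.sigma_wall,
        tables.L_inner, tables.L_outer)
    if status == 1:
        raise OverstretchError("FENE bond at or beyond maximum extension")
    return u, f


# ---------------------------------------------------------------------------
# default ("Motor II-like") parameter set
# ---------------------------------------------------------------------------

#: Default pair overrides beyond (eps_R, eps_A) = (1, 0).  Chosen to satisfy the
#: model's qualitative constraints: the filled cluster is metastable (a stiff,
#: tight tetrahedral cage around a weakly repelled central particle gives bulk
#: lifetimes of order 10^3 time units), the shuttling ring binds the BIND
#: sites, catalytic particles attract the cluster particles (lowering the
#: escape barrier locally), CENT binds CAT1 strongly enough to act as a
#: blocking group but weakly enough to cleave on simulation timescales, and
#: CENT strongly repels SHUTTLE so blocking is effective.
DEFAULT_PAIR_OVERRIDES = {
    ("SHUTTLE", "BIND"): {"eps_A": 0.8},
    ("CAT1", "CENT"): {"eps_A": 2.0},
    ("CAT2", "CENT"): {"eps_A": 0.8},
    ("CAT3", "CENT"): {"eps_A": 0.8},
    ("SHUTTLE", "CENT"): {"eps_R": 5.0},
}
for _cat in ("CAT1", "CAT2", "CAT3"):
    for _tet in ("TET1", "TET2", "TET3", "TET4"):
        DEFAULT_PAIR_OVERRIDES[(_cat, _tet)] = {"eps_A": 2.0}
for _tet in ("TET1", "TET2", "TET3", "TET4"):
    DEFAULT_PAIR_OVERRIDES[(_tet, "CENT")] = {"eps_R": 0.1}

DEFAULT_TET_BOND_K = 150.0
DEFAULT_FENE_K = 30.0
DEFAULT_FENE_RMAX = 1.5
DEFAULT_ANGLE_K = 10.0


def default_tables(rcut_factor: float = 2.5,
                   pair_overrides: dict | None = None,
                   L_inner: float = 30.0, L_outer: float = 34.0) -> ForceFieldTables:
    """Build the shipped default parameter tables (no bonded terms yet)."""
    sigma = np.ones(NUM_TYPES)
    sigma[ParticleType.CENT] = 0.45
    mass = np.ones(NUM_TYPES)
    eps_R = np.ones((NUM_TYPES, NUM_TYPES))
    eps_A = np.zeros((NUM_TYPES, NUM_TYPES))
    overrides = dict(DEFAULT_PAIR_OVERRIDES)
    if pair_overrides:
        for key, val in pair_overrides.items():
            a, b = key
            k = (a, b) if isinstance(a, str) else (TYPE_NAMES[a], TYPE_NAMES[b])
            overrides[k] = {**overrides.get(k, {}), **val}
    for (a, b), par in overrides.items():
        ia, ib = TYPE_BY_NAME[a], TYPE_BY_NAME[b]
        if "eps_R" in par:
            eps_R[ia, ib] = eps_R[ib, ia] = par["eps_R"]
        if "eps_A" in par:
            eps_A[ia, ib] = eps_A[ib, ia] = par["eps_A"]
    return ForceFieldTables(sigma=sigma, mass=mass, eps_R=eps_R, eps_A=eps_A,
                            rcut_factor=rcut_factor, L_inner=L_inner, L_outer=L_outer)


def tables_from_config(cfg: dict) -> ForceFieldTables:
    """Construct tables from a structured config dict.

    Recognised sections: ``types`` (per-type sigma/mass), ``pairs`` (entries
    like ``{i: CAT1, j: CENT, eps_A: 1.6}``), ``wall`` (eps_wall, sigma_wall)
    and ``cutoff`` (rcut_factor).  Unspecified values take the shipped
    defaults.
    """
    overrides = {}
    for entry in cfg.get("pairs", []):
        key = (entry["i"], entry["j"])
        overrides[key] = {k: float(v) for k, v in entry.items() if k in ("eps_R", "eps_A")}
    t = default_tables(rcut_factor=float(cfg.get("cutoff", {}).get("rcut_factor", 2.5)),
                       pair_overrides=overrides,
                       L_inner=float(cfg.get("cell", {}).get("L_inner", 30.0)),
                       L_outer=float(cfg.get("cell", {}).get("L_outer", 34.0)))
    for entry in cfg.get("types", []):
        it = TYPE_BY_NAME[entry["name"]]
        if "sigma" in entry:
            t.sigma[it] = float(entry["sigma"])
        if "mass" in entry:
            t.mass[it] = float(entry["mass"])
    wall = cfg.get("wall", {})
    t.eps_wall = float(wall.get("eps_wall", t.eps_wall))
    t.sigma_wall = float(wall.get("sigma_wall", t.sigma_wall))
    return t
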