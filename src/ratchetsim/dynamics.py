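"""Langevin propagation of the particle model.

The equations of motion  dr = p/m dt,  dp = (-grad U - (gamma/m) p) dt + noise
are integrated with a symmetric splitting: an exponential-friction half-kick
with additive Gaussian noise, a full free drift, then a second half-kick,

    p^{j+1/2} = p^j e^{-gamma dt / 2m} + f^j dt/2 + eta
    r^{j+1}   = r^j + p^{j+1/2} dt / m
    p^{j+1}   = [p^{j+1/2} + f^{j+1} dt/2] e^{-gamma dt / 2m} + eta'

where every noise component is an independent zero-mean Gaussian with variance
m (1 - exp(-gamma dt / m)) k_B T -- the exact Ornstein-Uhlenbeck variance for
a half step, so the scheme reduces to velocity Verlet at gamma = 0 and samples
the Maxwell distribution exactly for a free particle.

Two entry points are provided: :func:`langevin_step` is a small generic NumPy
step (any force callback; used by tests and for single-particle studies) and
:func:`run_md_segment` is the production path, a numba kernel fused with the
force evaluation that also records the per-step observables event detection
needs (shuttle index, cluster reaction coordinates, blocking flags).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .forcefield import _ff_kernel, ForceFieldTables, ParticleType, OverstretchError
from .topology import SystemState, SimulationCell


class InstabilityError(RuntimeError):
    """Non-finite positions or momenta encountered during integration."""


@dataclass(frozen=True)
class DynamicsParams:
    gamma: float = 0.5
    dt: float = 5e-3
    kT: float = 0.5

    def __post_init__(self):
        if self.dt <= 0 or self.gamma < 0 or self.kT <= 0:
            raise ValueError("require dt > 0, gamma >= 0, kT > 0")

    def friction_factor(self, masses):
        return np.exp(-self.gamma * self.dt / (2.0 * np.asarray(masses)))

    def noise_std(self, masses):
        m = np.asarray(masses, dtype=float)
        return np.sqrt(m * (1.0 - np.exp(-self.gamma * self.dt / m)) * self.kT)


def langevin_step(positions, momenta, masses, forces, force_fn,
                  params: DynamicsParams, rng: np.random.Generator):
    """One splitting step with an arbitrary force callback.

    ``forces`` are the forces at the current positions; returns
    (positions, momenta, forces) at the next step.  Noise is drawn per
    particle per half-kick in particle-index order.
    """
    m = np.asarray(masses, dtype=float).reshape(-1, 1)
    c = np.exp(-params.gamma * params.dt / (2.0 * m))
    std = np.sqrt(m * (1.0 - np.exp(-params.gamma * params.dt / m)) * params.kT)
    h = 0.5 * params.dt

    p_half = momenta * c + forces * h + std * rng.standard_normal(momenta.shape)
    r_new = positions + p_half * params.dt / m
    f_new = force_fn(r_new)
    p_new = (p_half + f_new * h) * c + std * rng.standard_normal(momenta.shape)
    if not (np.all(np.isfinite(r_new)) and np.all(np.isfinite(p_new))):
        raise InstabilityError("non-finite positions or momenta")
    return r_new, p_new, f_new


# ---------------------------------------------------------------------------
# production kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _md_kernel(pos, mom, types, mass_pp, cfric, nstd, noise, dt, n_steps,
               sigma_ij, eps_R, eps_A, rc2, ushift,
               bond_idx, bond_k, fene_idx, fene_k, fene_rmax,
               ang_idx, ang_k, ang_t0, wall_mask, eps_wall, sigma_wall,
               L_inner, L_outer,
               NL, NS, cat_idx, cat1_idx, clu_tets, clu_cents, freec_ids,
               r_free, r_block,
               out_sidx, out_rclu, out_dcat, out_blocked, out_rtet, out_ke):
    n = pos.shape[0]
    nc = clu_tets.shape[0]
    nf = freec_ids.shape[0]
    ncands = nf + nc

    u, forces, status = _ff_kernel(pos, types, sigma_ij, eps_R, eps_A, rc2, ushift,
                                   bond_idx, bond_k, fene_idx, fene_k, fene_rmax,
                                   ang_idx, ang_k, ang_t0, wall_mask,
                                   eps_wall, sigma_wall, L_inner, L_outer)
    if status != 0:
        return -1

    tcomx = np.zeros(nc)
    tcomy = np.zeros(nc)
    tcomz = np.zeros(nc)

    for s in range(n_steps):
        # half-kick A
        for i in range(n):
            for ax in range(3):
                mom[i, ax] = (mom[i, ax] * cfric[i] + 0.5 * dt * forces[i, ax]
                              + nstd[i] * noise[s, 0, i, ax])
        # drift
        for i in range(n):
            inv_m = 1.0 / mass_pp[i]
            pos[i, 0] += mom[i, 0] * dt * inv_m
            pos[i, 1] += mom[i, 1] * dt * inv_m
            pos[i, 2] += mom[i, 2] * dt * inv_m
        # recompute forces
        u, forces, status = _ff_kernel(pos, types, sigma_ij, eps_R, eps_A, rc2, ushift,
                                       bond_idx, bond_k, fene_idx, fene_k, fene_rmax,
                                       ang_idx, ang_k, ang_t0, wall_mask,
                                       eps_wall, sigma_wall, L_inner, L_outer)
        if status != 0:
            return s + 1
        # half-kick B
        ke = 0.0
        for i in range(n):
            for ax in range(3):
                mom[i, ax] = ((mom[i, ax] + 0.5 * dt * forces[i, ax]) * cfric[i]
                              + nstd[i] * noise[s, 1, i, ax])
                ke += 0.5 * mom[i, ax] * mom[i, ax] / mass_pp[i]
        out_ke[s] = ke
        if not np.isfinite(ke):
            return -(s + 2)

        # ---- observables ------------------------------------------------
        if NL > 0:
            scx = 0.0
            scy = 0.0
            scz = 0.0
            for i in range(NL, NL + NS):
                scx += pos[i, 0]
                scy += pos[i, 1]
                scz += pos[i, 2]
            scx /= NS
            scy /= NS
            scz /= NS
            best = 0
            bestd = 1e300
            for i in range(NL):
                dx = pos[i, 0] - scx
                dy = pos[i, 1] - scy
                dz = pos[i, 2] - scz
                d2 = dx * dx + dy * dy + dz * dz
                if d2 < bestd:
                    bestd = d2
                    best = i
            out_sidx[s] = best
        else:
            out_sidx[s] = -1

        # cluster reaction coordinates and catalytic proximity
        for c in range(nc):
            cx = 0.0
            cy = 0.0
            cz = 0.0
            t0 = clu_tets[c, 0]
            for kk in range(4):
                t = clu_tets[c, kk]
                dx = pos[t, 0] - pos[t0, 0]
                dy = pos[t, 1] - pos[t0, 1]
                dz = pos[t, 2] - pos[t0, 2]
                dx -= L_outer * np.rint(dx / L_outer)
                dy -= L_outer * np.rint(dy / L_outer)
                dz -= L_outer * np.rint(dz / L_outer)
                cx += pos[t0, 0] + dx
                cy += pos[t0, 1] + dy
                cz += pos[t0, 2] + dz
            cx *= 0.25
            cy *= 0.25
            cz *= 0.25
            tcomx[c] = cx
            tcomy[c] = cy
            tcomz[c] = cz
            cid = clu_cents[c]
            if cid >= 0:
                dx = pos[cid, 0] - cx
                dy = pos[cid, 1] - cy
                dz = pos[cid, 2] - cz
                dx -= L_outer * np.rint(dx / L_outer)
                dy -= L_outer * np.rint(dy / L_outer)
                dz -= L_outer * np.rint(dz / L_outer)
                out_rclu[s, c] = np.sqrt(dx * dx + dy * dy + dz * dz)
                # species COM includes the central particle (all unit masses)
                wx = cx + 0.2 * dx
                wy = cy + 0.2 * dy
                wz = cz + 0.2 * dz
            else:
                out_rclu[s, c] = 1e9
                wx = cx
                wy = cy
                wz = cz
            dmin = 1e300
            for q in range(cat_idx.shape[0]):
                ci = cat_idx[q]
                dx = wx - pos[ci, 0]
                dy = wy - pos[ci, 1]
                dz = wz - pos[ci, 2]
                dx -= L_outer * np.rint(dx / L_outer)
                dy -= L_outer * np.rint(dy / L_outer)
                dz -= L_outer * np.rint(dz / L_outer)
                d2 = dx * dx + dy * dy + dz * dz
                if d2 < dmin:
                    dmin = d2
            out_dcat[s, c] = np.sqrt(dmin) if cat_idx.shape[0] > 0 else 1e9

        # blocking state: any free C within r_block of a site's CAT1
        for site in range(cat1_idx.shape[0]):
            c1 = cat1_idx[site]
            blocked = 0
            dbest = 1e300
            cand_best = -1
            for q in range(ncands):
                if q < nf:
                    cid = freec_ids[q]
                else:
                    c = q - nf
                    cid = clu_cents[c]
                    if cid < 0 or out_rclu[s, c] < r_free:
                        continue      # caged CENT is not free
                dx = pos[cid, 0] - pos[c1, 0]
                dy = pos[cid, 1] - pos[c1, 1]
                dz = pos[cid, 2] - pos[c1, 2]
                dx -= L_outer * np.rint(dx / L_outer)
                dy -= L_outer * np.rint(dy / L_outer)
                dz -= L_outer * np.rint(dz / L_outer)
                d2 = dx * dx + dy * dy + dz * dz
                if d2 < dbest:
                    dbest = d2
                    cand_best = cid
            if dbest < r_block * r_block:
                blocked = 1
            out_blocked[s, site] = blocked
            # distance from that candidate C to the nearest tetrahedral shell
            rt = 1e9
            if cand_best >= 0:
                for c in range(nc):
                    dx = pos[cand_best, 0] - tcomx[c]
                    dy = pos[cand_best, 1] - tcomy[c]
                    dz = pos[cand_best, 2] - tcomz[c]
                    dx -= L_outer * np.rint(dx / L_outer)
                    dy -= L_outer * np.rint(dy / L_outer)
                    dz -= L_outer * np.rint(dz / L_outer)
                    d2 = dx * dx + dy * dy + dz * dz
                    if d2 < rt * rt:
                        rt = np.sqrt(d2)
            out_rtet[s, site] = rt
    return 0


def run_md_segment(state: SystemState, tables: ForceFieldTables,
                   params: DynamicsParams, n_steps: int,
                   rng: np.random.Generator,
                   cell: SimulationCell | None = None,
                   thresholds=None):
    """Propagate ``n_steps`` Langevin steps in place, recording observables.

    Returns a dict with per-step arrays: ``shuttle_idx`` (int), ``r_clu``
    (reaction coordinate per tracked cluster), ``d_cat`` (cluster-COM distance
    to nearest catalytic particle), ``blocked`` (two site flags), ``r_tet``
    (nearest-candidate-C distance to the nearest tetrahedral shell, per site)
    and ``kinetic`` (total kinetic energy).  Free species are wrapped through
    the periodic outer box at the end of the segment; motor particles are
    never wrapped (the wall confines them).
    """
    from .events import Thresholds
    if thresholds is None:
        thresholds = Thresholds()
    if cell is None:
        cell = SimulationCell(L_inner=tables.L_inner, L_outer=tables.L_outer)
    n = state.n
    if n_steps == 0:
        return {"shuttle_idx": np.zeros(0, dtype=np.int64),
                "r_clu": np.zeros((0, len(state.clusters))),
                "d_cat": np.zeros((0, len(state.clusters))),
                "blocked": np.zeros((0, 2), dtype=np.uint8),
                "r_tet": np.zeros((0, 2)),
                "kinetic": np.zeros(0)}

    masses = tables.masses_for(state.types)
    cfric = np.exp(-params.gamma * params.dt / (2.0 * masses))
    nstd = params.noise_std(masses)
    noise = rng.standard_normal((n_steps, 2, n, 3))

    sij, eR, eA, rc2, ush = tables.pair_tables()
    NL = 30 if state.n_motor else 0
    NS = state.n_motor - NL if state.n_motor else 0
    cat_mask = np.isin(state.types[:state.n_motor],
                       [int(ParticleType.CAT1), int(ParticleType.CAT2), int(ParticleType.CAT3)])
    cat_idx = np.nonzero(cat_mask)[0].astype(np.int64)
    cat1_idx = np.nonzero(state.types[:state.n_motor] == int(ParticleType.CAT1))[0].astype(np.int64)

    nc = len(state.clusters)
    clu_tets = (np.array([c.tet_ids for c in state.clusters], dtype=np.int64).reshape(nc, 4)
                if nc else np.zeros((0, 4), dtype=np.int64))
    clu_cents = (np.array([c.cent_id for c in state.clusters], dtype=np.int64)
                 if nc else np.zeros(0, dtype=np.int64))
    freec_ids = np.array(sorted(state.free_c), dtype=np.int64)

    out_sidx = np.zeros(n_steps, dtype=np.int64)
    out_rclu = np.zeros((n_steps, nc))
    out_dcat = np.zeros((n_steps, nc))
    out_blocked = np.zeros((n_steps, 2), dtype=np.uint8)
    out_rtet = np.zeros((n_steps, 2))
    out_ke = np.zeros(n_steps)

    status = _md_kernel(state.positions, state.momenta, state.types, masses,
                        cfric, nstd, noise, params.dt, n_steps,
                        sij, eR, eA, rc2, ush,
                        tables.bond_idx, tables.bond_k,
                        tables.fene_idx, tables.fene_k, tables.fene_rmax,
                        tables.angle_idx, tables.angle_k, tables.angle_t0,
                        tables.wall_mask, tables.eps_wall, tables.sigma_wall,
                        tables.L_inner, tables.L_outer,
                        NL, NS, cat_idx, cat1_idx, clu_tets, clu_cents, freec_ids,
                        thresholds.r_etc, thresholds.r_block,
                        out_sidx, out_rclu, out_dcat, out_blocked, out_rtet, out_ke)
    if status != 0:
        raise InstabilityError(f"integrator instability at step {state.step + abs(status)}"
                               if status < 0 else
                               f"FENE overstretch at step {state.step + status}")

    # wrap free species only
    if state.n_motor < n:
        free = slice(state.n_motor, n)
        state.positions[free] = cell.wrap(state.positions[free])
    state.step += n_steps
    state.time += n_steps * params.dt
    return {"shuttle_idx": out_sidx, "r_clu": out_rclu, "d_cat": out_dcat,
            "blocked": out_blocked, "r_tet": out_rtet, "kinetic": out_ke}
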