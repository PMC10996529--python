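"""Langevin dynamics driver: forces, propagation, squeeze-and-slab.

The propagation protocol mirrors the study workflow: chains are placed
at low density, the box is squeezed to a cube to condense the system,
the box is then extended along z into a slab so dense and dilute phases
can coexist, and the system is propagated with Langevin dynamics at a
0.01 ps time step.  Analysis uses the final part of the run.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np

from . import _kernels
from .forcefield import InteractionModel
from .system import SimConfig, SystemState, Trajectory

__all__ = [
    "compute_forces",
    "potential_energy",
    "langevin_propagate",
    "squeeze_and_slab",
    "pair_interaction_records",
]

_SKIN = 0.3  # nm, Verlet-list skin


def _bond_arrays(state: SystemState):
    cid = state.chain_id
    i = np.arange(state.n_beads - 1)
    mask = cid[:-1] == cid[1:]
    return i[mask].astype(np.int64), (i[mask] + 1).astype(np.int64)


def _charged_pair_arrays(state: SystemState, model: InteractionModel):
    """All non-bonded pairs of charged beads, with charge products."""
    q = state.charges * model.charge_scale
    idx = np.flatnonzero(q != 0.0)
    if idx.size < 2:
        e = np.empty(0, dtype=np.int64)
        return e, e.copy(), np.empty(0)
    ii, jj = np.triu_indices(idx.size, k=1)
    ci, cj = idx[ii], idx[jj]
    cid = state.chain_id
    bonded = (cid[ci] == cid[cj]) & (np.abs(cj - ci) == 1)
    ci, cj = ci[~bonded], cj[~bonded]
    return ci.astype(np.int64), cj.astype(np.int64), q[ci] * q[cj]


def _model_scalars(model: InteractionModel):
    return (model.coulomb_prefactor, model.kappa, model.epsilon,
            model.lambda_scale, model.cutoff_elec, model.cutoff_mlj,
            model.bond_k, model.bond_r0)


def _build_pairs_numpy(state: SystemState, rlist: float):
    """Reference O(N^2) pair builder (used for brute-force checks)."""
    pos = state.positions
    box = state.box
    cid = state.chain_id
    d = pos[None, :, :] - pos[:, None, :]
    d -= box * np.round(d / box)
    r2 = np.einsum("ijk,ijk->ij", d, d)
    i, j = np.triu_indices(state.n_beads, k=1)
    keep = r2[i, j] <= rlist * rlist
    i, j = i[keep], j[keep]
    bonded = (cid[i] == cid[j]) & (j - i == 1)
    return i[~bonded].astype(np.int64), j[~bonded].astype(np.int64)


def compute_forces(state: SystemState, model: InteractionModel,
                   brute_force: bool = False,
                   return_energy: bool = False):
    """Total force on every bead (kJ mol^-1 nm^-1).

    ``brute_force=True`` replaces the cell-list pair search with a full
    O(N^2) scan; the results must agree to machine precision.
    """
    kpref, kappa, eps, lam_scale, rc_e, rc_m, bond_k, r0 = _model_scalars(model)
    bond_i, bond_j = _bond_arrays(state)
    ci, cj, qq = _charged_pair_arrays(state, model)
    pos = np.ascontiguousarray(state.positions)
    sig, lam = state.sizes, state.hydropathies
    if brute_force:
        pi, pj = _build_pairs_numpy(state, rc_m)
        npairs = pi.size
        s_ij = 0.5 * (sig[pi] + sig[pj])
        ps2 = s_ij * s_ij
        pl = 0.5 * (lam[pi] + lam[pj])
    else:
        cap = max(state.n_beads * 220, 40000)
        npairs = -1
        while npairs < 0:
            pi = np.empty(cap, dtype=np.int64)
            pj = np.empty(cap, dtype=np.int64)
            ps2 = np.empty(cap)
            pl = np.empty(cap)
            npairs = _kernels.build_pairs(pos, state.box, state.chain_id,
                                          sig, lam, rc_m + _SKIN, pi, pj,
                                          ps2, pl)
            cap *= 2
    forces = np.empty((state.n_beads, 3))
    scratch = [np.empty(pi.size) for _ in range(4)]
    pe = _kernels.compute_forces_kernel(
        pos, state.box, forces, bond_i, bond_j, bond_k, r0,
        pi, pj, ps2, pl, npairs, lam_scale, eps, rc_m,
        ci, cj, qq, kpref, kappa, rc_e, *scratch)
    if return_energy:
        return forces, pe
    return forces


def potential_energy(state: SystemState, model: InteractionModel) -> float:
    """Total potential energy, kJ/mol."""
    _, pe = compute_forces(state, model, return_energy=True)
    return pe


def langevin_propagate(state: SystemState, model: InteractionModel,
                       sim: SimConfig, duration: float,
                       record: bool = True) -> Trajectory:
    """Propagate *state* in place for *duration* ps; return sampled frames.

    BAOAB splitting with per-bead friction zeta_i = m_i / damping_time
    (damping_time <= 0 disables the thermostat and yields velocity
    Verlet).  Frames are emitted every ``sim.frame_interval``;
    *duration* must be a whole number of frame intervals when recording.
    Deterministic given ``sim.seed`` (the RNG stream is re-seeded from
    the seed and the current step count, so successive segments use
    fresh noise but remain reproducible).
    """
    dt = sim.timestep
    n_steps = int(round(duration / dt))
    if n_steps <= 0:
        raise ValueError("duration shorter than one timestep")
    if record:
        stride = int(round(sim.frame_interval / dt))
        if stride <= 0 or abs(stride * dt - sim.frame_interval) > 1e-9:
            raise ValueError("frame_interval must be a positive multiple of the timestep")
        if n_steps % stride != 0:
            raise ValueError("duration must be a multiple of frame_interval")
        n_frames = n_steps // stride
    else:
        stride, n_frames = 0, 0

    kpref, kappa, eps, lam_scale, rc_e, rc_m, bond_k, r0 = _model_scalars(model)
    bond_i, bond_j = _bond_arrays(state)
    ci, cj, qq = _charged_pair_arrays(state, model)
    frames = np.empty((n_frames, state.n_beads, 3))
    seed = (int(sim.seed) * 1000003 + state.step) % (2**31 - 1)
    pos = np.ascontiguousarray(state.positions)
    vel = np.ascontiguousarray(state.velocities)
    ret = _kernels.run_langevin(
        pos, vel, state.box, state.masses, state.sizes, state.hydropathies,
        state.chain_id, bond_i, bond_j, ci, cj, qq,
        dt, n_steps, sim.damping_time, sim.thermostat_interval, model.kT,
        kpref, kappa, eps, lam_scale, rc_e, rc_m, bond_k, r0,
        rc_m + _SKIN, _SKIN, seed, stride, frames)
    if ret < 0:
        raise FloatingPointError(
            f"numerical blow-up: non-finite coordinate at step {state.step - ret} "
            f"(box {state.box}, dt {dt} ps)")
    t0 = state.step * dt
    state.positions = pos
    state.velocities = vel
    state.step += n_steps
    times = t0 + dt * stride * np.arange(1, n_frames + 1) if record else np.empty(0)
    return Trajectory(
        times=times, frames=frames, box=state.box.copy(),
        chain=state.chain, n_chains=state.n_chains,
        provenance={"model": model.to_dict(), "sim": asdict(sim),
                    "variant_id": state.chain.variant_id,
                    "n_chains": state.n_chains})


def squeeze_and_slab(state: SystemState, model: InteractionModel,
                     sim: SimConfig) -> SystemState:
    """Condense the box to a cube, then extend z into the slab geometry.

    The box is compressed linearly (per edge) from its current size to
    the cube whose edge is the slab cross-section, over
    ``sim.squeeze_steps`` Langevin steps split into
    ``sim.squeeze_segments`` affine rescale-then-relax segments.  The z
    edge is then set to the slab length instantaneously, leaving
    coordinates fixed with the condensed system centered at the origin.
    """
    target = np.array([sim.slab_box[0], sim.slab_box[1], sim.slab_box[0]],
                      dtype=float)
    box0 = state.box.copy()
    nseg = sim.squeeze_segments
    seg_steps = max(sim.squeeze_steps // nseg, 1)
    relax = SimConfig(timestep=sim.timestep, total_time=sim.total_time,
                      equilibration_time=sim.equilibration_time, seed=sim.seed,
                      damping_time=sim.damping_time,
                      thermostat_interval=sim.thermostat_interval,
                      frame_interval=sim.frame_interval)
    try:
        for k in range(1, nseg + 1):
            new_box = box0 + (target - box0) * (k / nseg)
            state.wrap_chains_to_box()
            state.positions *= new_box / state.box
            state.box = new_box
            langevin_propagate(state, model, relax, seg_steps * sim.timestep,
                               record=False)
    except FloatingPointError as err:
        raise RuntimeError(f"instability during compression: {err}") from err
    # Wrap whole chains (never individual beads: a bead-wise wrap would split
    # chains across the z boundary, which becomes a ~cube-length bond stretch
    # once the box is extended).  Beads of edge chains may overhang the cube
    # by up to a chain extent; the slab interface is fuzzy at that scale.
    state.wrap_chains_to_box()
    state.box = np.array([sim.slab_box[0], sim.slab_box[1], sim.slab_box[2]],
                         dtype=float)
    return state


def pair_interaction_records(state: SystemState, model: InteractionModel):
    """Per-pair force decomposition for every interacting bead pair.

    Returns a dict of arrays (i, j, r, f_elec, f_hydro, f_rep_mlj,
    f_bond) over all pairs within the larger cutoff plus all bonds.
    Intended for small systems (O(N^2) in numpy); the scalar components
    are signed radial forces, positive = repulsive, and their sum
    reconstructs the pair contribution to :func:`compute_forces`.
    """
    from .forcefield import bond_term, mlj_force_components, yukawa_term

    pos, box, cid = state.positions, state.box, state.chain_id
    d = pos[None, :, :] - pos[:, None, :]
    d -= box * np.round(d / box)
    r_all = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
    i, j = np.triu_indices(state.n_beads, k=1)
    r = r_all[i, j]
    bonded = (cid[i] == cid[j]) & (j - i == 1)
    rmax = max(model.cutoff_elec, model.cutoff_mlj)
    keep = bonded | (r <= rmax)
    i, j, r, bonded = i[keep], j[keep], r[keep], bonded[keep]

    q = state.charges * model.charge_scale
    sig = state.sizes
    lam = state.hydropathies
    f_elec = np.zeros_like(r)
    f_hydro = np.zeros_like(r)
    f_rep = np.zeros_like(r)
    f_bond = np.zeros_like(r)
    nb = ~bonded
    qq = q[i] * q[j]
    _, fe = yukawa_term(r, 1.0, model)
    f_elec[nb] = (qq * fe)[nb]
    s_ij = 0.5 * (sig[i] + sig[j])
    l_ij = 0.5 * (lam[i] + lam[j]) * model.lambda_scale
    rep, hyd = mlj_force_components(r, s_ij, l_ij, model.epsilon,
                                    model.cutoff_mlj)
    f_rep[nb] = rep[nb]
    f_hydro[nb] = hyd[nb]
    _, fb = bond_term(r, model)
    f_bond[bonded] = fb[bonded]
    return {"i": i, "j": j, "r": r, "bonded": bonded, "f_elec": f_elec,
            "f_hydro": f_hydro, "f_rep_mlj": f_rep, "f_bond": f_bond}
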