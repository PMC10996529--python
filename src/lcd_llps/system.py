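"""System state, trajectories, configuration builders and file IO.

Coordinates are stored *unwrapped* (continuous across periodic images)
so that diffusion and chain geometry are trivially available; wrapped
coordinates for a given orthorhombic box are computed on demand.  The
minimum-image convention used throughout is independent of wrapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .chain import ChainSpec, build_variant
from .constants import LITRE_PER_NM3, N_AVOGADRO, kt

__all__ = [
    "SimConfig",
    "SystemState",
    "Trajectory",
    "chains_for_concentration",
    "concentration_of_chains",
    "initialize_system",
    "write_xyz",
    "read_xyz",
]


@dataclass
class SimConfig:
    """Run-control parameters (times in ps, lengths in nm).

    Defaults follow the study protocol: 0.01 ps Langevin steps, 5 us
    total with the first 4 us discarded as equilibration, and a
    60 x 60 x 1200 nm slab box.  The damping time and frame interval
    are free method choices (see docs/methods.md).
    """

    timestep: float = 0.01
    total_time: float = 5.0e6
    equilibration_time: float = 4.0e6
    seed: int = 0
    damping_time: float = 1.0
    thermostat_interval: int = 1
    frame_interval: float = 1000.0
    initial_box: tuple[float, float, float] = (120.0, 120.0, 120.0)
    slab_box: tuple[float, float, float] = (60.0, 60.0, 1200.0)
    squeeze_steps: int = 100_000
    squeeze_segments: int = 100

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if not self.equilibration_time < self.total_time:
            raise ValueError("equilibration_time must be < total_time")
        for b in (self.initial_box, self.slab_box):
            if min(b) <= 0:
                raise ValueError("box edges must be positive")

    @property
    def analysis_time(self) -> float:
        return self.total_time - self.equilibration_time


def chains_for_concentration(c_protein: float, box) -> int:
    """Number of chains realising a molar protein concentration in *box* (nm)."""
    if c_protein <= 0:
        raise ValueError("protein concentration must be positive")
    volume_l = float(np.prod(np.asarray(box, dtype=float))) * LITRE_PER_NM3
    n = int(round(c_protein * N_AVOGADRO * volume_l))
    if n == 0:
        raise ValueError(
            f"{c_protein:g} M in this box rounds to zero chains; enlarge the box")
    return n


def concentration_of_chains(n_chains: int, box) -> float:
    """Inverse mapping: molar concentration of *n_chains* in *box* (nm)."""
    volume_l = float(np.prod(np.asarray(box, dtype=float))) * LITRE_PER_NM3
    return n_chains / (N_AVOGADRO * volume_l)


@dataclass
class SystemState:
    """Positions/velocities for N identical chains in a periodic box."""

    chain: ChainSpec
    n_chains: int
    box: np.ndarray                  # (3,) nm
    positions: np.ndarray            # (n_beads, 3) nm, unwrapped
    velocities: np.ndarray           # (n_beads, 3) nm/ps
    step: int = 0

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float).copy()
        n = self.n_chains * self.chain.length
        if self.positions.shape != (n, 3) or self.velocities.shape != (n, 3):
            raise ValueError("positions/velocities shape mismatch with chain count")

    @property
    def n_beads(self) -> int:
        return self.n_chains * self.chain.length

    @property
    def chain_id(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_chains), self.chain.length)

    @property
    def residue_index(self) -> np.ndarray:
        """0-based position within the chain for every bead."""
        return np.tile(np.arange(self.chain.length), self.n_chains)

    # Tiled per-bead parameter arrays.
    @property
    def masses(self) -> np.ndarray:
        return np.tile(self.chain.masses, self.n_chains)

    @property
    def charges(self) -> np.ndarray:
        return np.tile(self.chain.charges, self.n_chains)

    @property
    def hydropathies(self) -> np.ndarray:
        return np.tile(self.chain.hydropathies, self.n_chains)

    @property
    def sizes(self) -> np.ndarray:
        return np.tile(self.chain.sizes, self.n_chains)

    def wrapped_positions(self) -> np.ndarray:
        """Positions folded into the centered box [-L/2, L/2)."""
        L = self.box
        return self.positions - L * np.round(self.positions / L)

    def wrap_chains_to_box(self) -> None:
        """Translate each chain by whole box vectors so its COM is in the box."""
        L = self.chain.length
        m = self.chain.masses[:, None]
        pos = self.positions.reshape(self.n_chains, L, 3)
        com = (pos * m).sum(axis=1) / m.sum()
        shift = self.box * np.round(com / self.box)
        self.positions = (pos - shift[:, None, :]).reshape(-1, 3)

    def copy(self) -> "SystemState":
        return SystemState(self.chain, self.n_chains, self.box.copy(),
                           self.positions.copy(), self.velocities.copy(), self.step)

    def kinetic_temperature(self) -> float:
        """Instantaneous kinetic temperature, K."""
        from .constants import KB
        ke = 0.5 * float(np.sum(self.masses[:, None] * self.velocities**2))
        return 2.0 * ke / (3.0 * self.n_beads * KB)


def _draw_velocities(rng, masses, temperature):
    sigma = np.sqrt(kt(temperature) / masses)
    return rng.standard_normal((masses.size, 3)) * sigma[:, None]


def initialize_system(chain: ChainSpec, n_chains: int, box, seed: int,
                      temperature: float = 298.0,
                      min_sep_factor: float = 0.7,
                      max_retries: int = 200) -> SystemState:
    """Place chains as self-avoiding random walks with bond length r0.

    Consecutive beads are separated by exactly the bond rest length
    (0.38 nm); a candidate bead is rejected if it comes closer than
    ``min_sep_factor * sigma_ij`` to any bead already placed (minimum
    image).  Velocities are Maxwell–Boltzmann at *temperature*.
    Deterministic for a given *seed*.
    """
    if n_chains < 1:
        raise ValueError("need at least one chain")
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    L = chain.length
    sig = chain.sizes
    r0 = 0.38

    placed = np.empty((0, 3))
    placed_sig = np.empty(0)
    chains_done = []
    for _ in range(n_chains):
        for attempt in range(max_retries):
            pts = _grow_chain(rng, box, placed, placed_sig, sig, r0, min_sep_factor)
            if pts is not None:
                break
        else:
            raise RuntimeError(
                f"packing failure: could not place chain after {max_retries} retries "
                "(box too small for this chain count)")
        chains_done.append(pts)
        placed = np.vstack([placed, pts])
        placed_sig = np.concatenate([placed_sig, sig])

    positions = np.vstack(chains_done)
    masses = np.tile(chain.masses, n_chains)
    velocities = _draw_velocities(rng, masses, temperature)
    return SystemState(chain, n_chains, box, positions, velocities)


def _grow_chain(rng, box, placed, placed_sig, sig, r0, f):
    """One self-avoiding-walk attempt; returns (L,3) points or None."""
    L = sig.size
    pts = np.empty((L, 3))
    pts[0] = (rng.random(3) - 0.5) * box
    if not _clear(pts[0], sig[0], placed, placed_sig, box, f):
        return None
    for i in range(1, L):
        for _ in range(60):
            v = rng.standard_normal(3)
            cand = pts[i - 1] + v / np.linalg.norm(v) * r0
            others = np.vstack([placed, pts[: max(i - 1, 0)]]) if i > 1 else placed
            osig = np.concatenate([placed_sig, sig[: max(i - 1, 0)]]) if i > 1 else placed_sig
            if _clear(cand, sig[i], others, osig, box, f):
                pts[i] = cand
                break
        else:
            return None
    return pts


def _clear(p, s, others, osig, box, f):
    if others.shape[0] == 0:
        return True
    d = others - p
    d -= box * np.round(d / box)
    r2 = np.einsum("ij,ij->i", d, d)
    min_allowed = f * 0.5 * (osig + s)
    return bool(np.all(r2 >= min_allowed**2))


@dataclass
class Trajectory:
    """Time-ordered position snapshots plus provenance."""

    times: np.ndarray                # (n_frames,) ps
    frames: np.ndarray               # (n_frames, n_beads, 3) nm, unwrapped
    box: np.ndarray                  # (3,) nm
    chain: ChainSpec
    n_chains: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.frames.shape[:2] != (self.times.size, self.n_chains * self.chain.length):
            raise ValueError("frames shape inconsistent with times/chains")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def chain_id(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_chains), self.chain.length)

    def window(self, analysis_window: float) -> "Trajectory":
        """The final *analysis_window* ps of the trajectory."""
        if self.n_frames == 0:
            raise ValueError("empty trajectory")
        t_start = self.times[-1] - analysis_window
        keep = self.times > t_start + 1e-9   # half-open (t_end - w, t_end]
        if not keep.any():
            raise ValueError("analysis window contains no frames")
        return Trajectory(self.times[keep], self.frames[keep], self.box,
                          self.chain, self.n_chains, dict(self.provenance))

    def concatenate(self, other: "Trajectory") -> "Trajectory":
        if other.n_frames == 0:
            return self
        return Trajectory(
            np.concatenate([self.times, other.times]),
            np.concatenate([self.frames, other.frames]),
            self.box, self.chain, self.n_chains, dict(self.provenance))


def write_xyz(traj: Trajectory, path) -> None:
    """Write an extended-XYZ trajectory plus a JSON topology sidecar."""
    path = Path(path)
    species = list(traj.chain.sequence) * traj.n_chains
    lat = traj.box
    with open(path, "w") as fh:
        for t, frame in zip(traj.times, traj.frames):
            fh.write(f"{frame.shape[0]}\n")
            fh.write(
                f'Lattice="{lat[0]} 0 0 0 {lat[1]} 0 0 0 {lat[2]}" '
                f'Properties=species:S:1:pos:R:3 time={t}\n')
            for s, (x, y, z) in zip(species, frame):
                fh.write(f"{s} {x:.6f} {y:.6f} {z:.6f}\n")
    sidecar = path.with_suffix(path.suffix + ".top.json")
    with open(sidecar, "w") as fh:
        json.dump({
            "variant_id": traj.chain.variant_id,
            "sequence": traj.chain.sequence,
            "n_chains": traj.n_chains,
            "chain_length": traj.chain.length,
            "box_nm": traj.box.tolist(),
            "provenance": _jsonable(traj.provenance),
        }, fh, indent=1)


def read_xyz(path) -> Trajectory:
    """Read a trajectory written by :func:`write_xyz`."""
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".top.json")) as fh:
        top = json.load(fh)
    if top["variant_id"] in ("WT", "2PM", "4PM", "4PM_A326P", "4PM_W334G"):
        chain = build_variant(top["variant_id"])
    else:
        chain = build_variant("custom", top["sequence"])
    times, frames = [], []
    with open(path) as fh:
        while True:
            line = fh.readline()
            if not line:
                break
            n = int(line)
            comment = fh.readline()
            t = float(comment.rsplit("time=", 1)[1].split()[0])
            coords = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                coords[i] = [float(v) for v in parts[1:4]]
            times.append(t)
            frames.append(coords)
    return Trajectory(np.array(times), np.array(frames),
                      np.array(top["box_nm"]), chain, top["n_chains"],
                      top.get("provenance", {}))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
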