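"""Cluster-based phase classification and phase-diagram assembly.

A simulation cell is called *phase separated* when chains stay
clustered through the whole analysis window: chain centers of mass
within 10 nm (minimum image) belong to one cluster (single linkage /
connected components), a chain's neighbour count is its cluster size
minus one, and the mean neighbour count over chains must exceed 2 at
every analysed frame.  Otherwise the cell is *dissolved*.

Per salt concentration, binary calls over a protein-concentration
column are made monotone by the fill rule: everything above the lowest
phase-separated concentration is phase separated, everything below is
dissolved; the saturation concentration c_sat is that lowest
phase-separated concentration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .chain import ChainSpec
from .system import Trajectory

__all__ = [
    "PhaseCall",
    "PhaseDiagram",
    "chain_centers_of_mass",
    "cluster_chains",
    "classify_run",
    "assemble_phase_diagram",
    "DEFAULT_CLUSTER_CUTOFF",
]

DEFAULT_CLUSTER_CUTOFF = 10.0  # nm, center-of-mass linkage distance
NEIGHBOR_THRESHOLD = 2.0       # mean neighbours per chain must exceed this


def chain_centers_of_mass(positions: np.ndarray, box: np.ndarray,
                          chain: ChainSpec, n_chains: int) -> np.ndarray:
    """PBC-aware center of mass of every chain, wrapped into the box.

    Each chain is first made whole by unwrapping bead-to-bead bond
    vectors with the minimum-image convention starting from its first
    bead (chains are short relative to the box), then the mass-weighted
    center is computed and folded into the centered box.
    """
    L = chain.length
    box = np.asarray(box, dtype=float)
    pos = positions.reshape(n_chains, L, 3)
    steps = np.diff(pos, axis=1)
    steps -= box * np.round(steps / box)
    unwrapped = np.concatenate(
        [pos[:, :1, :], pos[:, :1, :] + np.cumsum(steps, axis=1)], axis=1)
    m = chain.masses[:, None]
    com = (unwrapped * m).sum(axis=1) / chain.masses.sum()
    return com - box * np.round(com / box)


def cluster_chains(positions: np.ndarray, box: np.ndarray, chain: ChainSpec,
                   n_chains: int,
                   cutoff: float = DEFAULT_CLUSTER_CUTOFF):
    """Cluster chains by center-of-mass proximity.

    Returns ``(labels, neighbor_counts)``: cluster label per chain
    (connected components of the graph linking centers within *cutoff*
    under minimum image) and each chain's cluster size minus one.
    """
    com = chain_centers_of_mass(positions, box, chain, n_chains)
    d = com[None, :, :] - com[:, None, :]
    d -= box * np.round(d / box)
    r2 = np.einsum("ijk,ijk->ij", d, d)
    adj = csr_matrix(r2 <= cutoff * cutoff)
    n_comp, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    return labels, sizes[labels] - 1


@dataclass
class PhaseCall:
    """Binary phase call plus the per-frame series behind it."""

    label: str                                   # 'phase_separated' | 'dissolved'
    mean_neighbors_series: np.ndarray
    largest_cluster_fraction_series: np.ndarray
    times: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def phase_separated(self) -> bool:
        return self.label == "phase_separated"


def classify_run(traj: Trajectory, analysis_window: float,
                 cutoff: float = DEFAULT_CLUSTER_CUTOFF,
                 threshold: float = NEIGHBOR_THRESHOLD,
                 mode: str = "mean") -> PhaseCall:
    """Classify a trajectory as phase separated or dissolved.

    ``phase_separated`` iff the neighbour criterion holds at *every*
    frame of the final *analysis_window* ps.  ``mode='mean'`` (default)
    requires the mean neighbour count over chains to exceed
    *threshold*; ``mode='min'`` is the stricter per-chain variant
    requiring every single chain to exceed it.
    """
    if mode not in ("mean", "min"):
        raise ValueError("mode must be 'mean' or 'min'")
    win = traj.window(analysis_window)
    n = win.n_chains
    means = np.empty(win.n_frames)
    largest = np.empty(win.n_frames)
    ok = True
    for k, frame in enumerate(win.frames):
        labels, nb = cluster_chains(frame, win.box, win.chain, n, cutoff)
        means[k] = nb.mean()
        largest[k] = np.bincount(labels).max() / n
        crit = nb.mean() if mode == "mean" else nb.min()
        ok = ok and (crit > threshold)
    return PhaseCall(
        label="phase_separated" if ok else "dissolved",
        mean_neighbors_series=means,
        largest_cluster_fraction_series=largest,
        times=win.times.copy())


@dataclass
class PhaseDiagram:
    """Grid of binary calls over (NaCl x protein concentration).

    ``calls[i, j]`` is the (fill-rule-adjusted) call at salt ``salts[i]``
    (molar) and protein concentration ``proteins[j]`` (molar, ascending);
    ``c_sat[i]`` is the lowest phase-separated protein concentration at
    that salt, or +inf when the whole column is dissolved ("above grid").
    """

    salts: np.ndarray
    proteins: np.ndarray
    calls: np.ndarray          # bool, shape (n_salts, n_proteins)
    raw_calls: np.ndarray      # bool, before the fill rule
    c_sat: np.ndarray          # molar, +inf = above grid

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.salts):
            for j, p in enumerate(self.proteins):
                rows.append({
                    "salt_mM": s * 1e3,
                    "protein_uM": p * 1e6,
                    "call": "phase_separated" if self.calls[i, j] else "dissolved",
                    "c_sat_uM": self.c_sat[i] * 1e6,
                })
        return pd.DataFrame(rows)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(outdir / "phase_diagram.tsv", sep="\t", index=False)
        np.savetxt(outdir / "call_matrix.tsv", self.calls.astype(int),
                   fmt="%d", delimiter="\t")
        with open(outdir / "phase_diagram.json", "w") as fh:
            json.dump({
                "salt_mM": (self.salts * 1e3).tolist(),
                "protein_uM": (self.proteins * 1e6).tolist(),
                "c_sat_uM": [None if np.isinf(c) else c * 1e6 for c in self.c_sat],
            }, fh, indent=1)


def _fill_column(col: np.ndarray) -> np.ndarray:
    """Monotonic fill rule along ascending protein concentration."""
    out = np.zeros_like(col)
    hits = np.flatnonzero(col)
    if hits.size:
        out[hits[0]:] = True
    return out


def assemble_phase_diagram(salts, proteins, calls) -> PhaseDiagram:
    """Apply the fill rule per salt column and extract c_sat per salt.

    *calls* may be booleans, PhaseCall objects or label strings, in a
    (n_salts, n_proteins) grid ordered by ascending protein
    concentration.
    """
    salts = np.asarray(salts, dtype=float)
    proteins = np.asarray(proteins, dtype=float)
    if salts.size == 0 or proteins.size == 0:
        raise ValueError("phase diagram needs at least one salt and one protein level")
    if np.any(np.diff(proteins) <= 0):
        raise ValueError("protein concentrations must be strictly increasing")
    raw = np.empty((salts.size, proteins.size), dtype=bool)
    grid = np.asarray(calls, dtype=object)
    if grid.shape != raw.shape:
        raise ValueError(f"calls grid shape {grid.shape} != {raw.shape}")
    for idx, c in np.ndenumerate(grid):
        if isinstance(c, PhaseCall):
            raw[idx] = c.phase_separated
        elif isinstance(c, str):
            raw[idx] = c == "phase_separated"
        else:
            raw[idx] = bool(c)
    filled = np.vstack([_fill_column(raw[i]) for i in range(salts.size)])
    c_sat = np.full(salts.size, np.inf)
    for i in range(salts.size):
        hits = np.flatnonzero(filled[i])
        if hits.size:
            c_sat[i] = proteins[hits[0]]
    return PhaseDiagram(salts=salts, proteins=proteins, calls=filled,
                        raw_calls=raw, c_sat=c_sat)
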