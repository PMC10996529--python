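"""Time-averaged intermolecular force analysis.

For every intermolecular bead pair within cutoff, the signed radial
electrostatic force and the hydrophobic (lambda-weighted attractive
MLJ) force component are accumulated, frame by frame, into L x L
sequence-position maps and into per-frame scalar totals.  Negative
values are attractive, positive repulsive; the "force between two
amino acids" is the signed magnitude of the radial pair force (vector
pair forces over a symmetric condensate would cancel).

Uncertainties on the time-averaged totals come from a block bootstrap
over frames: the series is cut into contiguous equal blocks (the
remainder joins the last block), blocks are resampled with
replacement, and a percentile interval is reported.  Blocks are
contiguous in time to respect autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._kernels import accumulate_pair_forces
from .forcefield import InteractionModel
from .system import Trajectory

__all__ = [
    "ForceMaps",
    "BootstrapCI",
    "pairwise_time_averaged_forces",
    "total_force",
    "block_bootstrap",
]


@dataclass
class BootstrapCI:
    """Point estimate with a percentile block-bootstrap interval."""

    estimate: float
    lower: float
    upper: float
    n_blocks: int = 50
    n_resamples: int = 1000

    def __post_init__(self) -> None:
        if not (self.lower <= self.estimate <= self.upper):
            raise ValueError("bootstrap interval must bracket the estimate")


@dataclass
class ForceMaps:
    """Residue-pairwise time-averaged intermolecular force maps.

    ``elec_map``/``hydro_map`` are L x L symmetric matrices: cell (i, j)
    holds the time-averaged sum of signed radial forces over all
    intermolecular bead pairs mapping to the unordered sequence-position
    pair {i, j} (mirrored across the diagonal; diagonal cells count each
    self-pair once, so ``(map.sum() + trace) / 2`` equals the scalar
    total).  Per-frame totals (each unordered pair once) are retained
    for bootstrapping.
    """

    elec_map: np.ndarray
    hydro_map: np.ndarray
    elec_series: np.ndarray
    hydro_series: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.elec_series.size

    @property
    def length(self) -> int:
        return self.elec_map.shape[0]

    def total(self, kind: str) -> float:
        series = {"electrostatic": self.elec_series,
                  "hydrophobic": self.hydro_series}[kind]
        return float(series.mean())

    def write(self, outdir, prefix: str = "") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.savetxt(outdir / f"{prefix}elec_map.tsv", self.elec_map, delimiter="\t")
        np.savetxt(outdir / f"{prefix}hydro_map.tsv", self.hydro_map, delimiter="\t")
        np.savetxt(outdir / f"{prefix}totals_series.tsv",
                   np.column_stack([self.elec_series, self.hydro_series]),
                   delimiter="\t", header="total_elec\ttotal_hydro")


def pairwise_time_averaged_forces(traj: Trajectory, model: InteractionModel,
                                  analysis_window: float | None = None) -> ForceMaps:
    """Accumulate intermolecular pair forces over trajectory frames.

    Only bead pairs on different chains are counted.  If
    *analysis_window* is given, only the final window of the trajectory
    is used.  Raises if the trajectory's recorded provenance points to
    a different variant or salt concentration than *model*.
    """
    prov_model = traj.provenance.get("model")
    if prov_model is not None and "c_nacl" in prov_model:
        if abs(prov_model["c_nacl"] - model.c_nacl) > 1e-12:
            raise ValueError(
                f"trajectory was produced at c_NaCl={prov_model['c_nacl']} M "
                f"but the analysis model has {model.c_nacl} M")
    win = traj.window(analysis_window) if analysis_window is not None else traj
    if win.n_frames == 0:
        raise ValueError("no frames in the analysis window")
    L = win.chain.length
    elec_map = np.zeros((L, L))
    hydro_map = np.zeros((L, L))
    elec_series = np.empty(win.n_frames)
    hydro_series = np.empty(win.n_frames)
    chain_id = win.chain_id
    resid = np.tile(np.arange(L), win.n_chains)
    sig = np.tile(win.chain.sizes, win.n_chains)
    lam = np.tile(win.chain.hydropathies, win.n_chains)
    q = np.tile(win.chain.charges, win.n_chains) * model.charge_scale
    for k, frame in enumerate(win.frames):
        te, th = accumulate_pair_forces(
            np.ascontiguousarray(frame), win.box, chain_id, resid, sig, lam, q,
            model.coulomb_prefactor, model.kappa, model.epsilon,
            model.lambda_scale, model.cutoff_elec, model.cutoff_mlj,
            elec_map, hydro_map)
        elec_series[k] = te
        hydro_series[k] = th
    elec_map /= win.n_frames
    hydro_map /= win.n_frames
    meta = {"variant_id": win.chain.variant_id, "n_chains": win.n_chains,
            "c_nacl": model.c_nacl, "n_frames": win.n_frames,
            "box_nm": win.box.tolist()}
    return ForceMaps(elec_map, hydro_map, elec_series, hydro_series, meta)


def block_bootstrap(series, n_blocks: int = 50, n_resamples: int = 1000,
                    seed: int = 0, ci: float = 0.95) -> BootstrapCI:
    """Percentile CI for the mean of a correlated per-frame series.

    The series is split into *n_blocks* contiguous blocks of equal
    length (any remainder joins the last block); block means are
    resampled with replacement, weighting by block length, and the
    percentile interval of the resampled series means is returned.
    Deterministic given *seed*.
    """
    series = np.asarray(series, dtype=float)
    if series.size < n_blocks:
        raise ValueError(f"series of length {series.size} is shorter than "
                         f"{n_blocks} blocks")
    size = series.size // n_blocks
    bounds = [(k * size, (k + 1) * size if k < n_blocks - 1 else series.size)
              for k in range(n_blocks)]
    block_sums = np.array([series[a:b].sum() for a, b in bounds])
    block_lens = np.array([b - a for a, b in bounds], dtype=float)
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, n_blocks, size=(n_resamples, n_blocks))
    means = block_sums[picks].sum(axis=1) / block_lens[picks].sum(axis=1)
    alpha = 0.5 * (1.0 - ci)
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    est = float(series.mean())
    return BootstrapCI(estimate=est, lower=min(float(lo), est),
                       upper=max(float(hi), est),
                       n_blocks=n_blocks, n_resamples=n_resamples)


def total_force(maps: ForceMaps, kind: str, n_blocks: int = 50,
                n_resamples: int = 1000, seed: int = 0) -> BootstrapCI:
    """Scalar total (sum of the map / per-frame pair sum) with its CI.

    *kind* is ``'electrostatic'`` or ``'hydrophobic'``; the sign is
    meaningful (negative = net attractive).
    """
    if kind not in ("electrostatic", "hydrophobic"):
        raise ValueError("kind must be 'electrostatic' or 'hydrophobic'")
    series = maps.elec_series if kind == "electrostatic" else maps.hydro_series
    return block_bootstrap(series, n_blocks=n_blocks, n_resamples=n_resamples,
                           seed=seed)
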