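"""Scenario orchestration: grids of (variant x salt x protein) cells.

Scale presets
-------------
``study``
    The full study conditions: chain count from the protein
    concentration, squeeze to a 60 nm cube, 60 x 60 x 1200 nm slab,
    5 us runs with the last 1 us analysed.  A cluster recipe — hours
    per cell on one CPU.
``reduced``
    Same protocol at desk scale: up to 10 chains, a 20 nm cube /
    20 x 20 x 100 nm slab, 40 ns runs (30 ns equilibration).
``smoke``
    Plumbing checks in seconds: 2 chains, 100 ps.

Besides the grid runner, :func:`condensed_run` builds a dense cubic
system directly (no squeeze/slab) emulating the interior of a
condensate; the scaled-down force-balance analyses use it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .chain import build_variant
from .cluster import PhaseDiagram, assemble_phase_diagram, classify_run
from .forcefield import InteractionModel
from .forcemaps import ForceMaps, pairwise_time_averaged_forces
from .simulate import langevin_propagate, squeeze_and_slab
from .system import (SimConfig, SystemState, Trajectory,
                     chains_for_concentration, initialize_system, write_xyz)

__all__ = [
    "ScalePreset", "PRESETS", "Scenario", "CellResult",
    "run_cell", "run_scenario", "compare_constant_epsilon",
    "condensed_run", "condensed_box_edge",
]

log = logging.getLogger("lcd_llps")

AMU_TO_G = 1.66053906660e-24
CM3_PER_NM3 = 1e-21


@dataclass(frozen=True)
class ScalePreset:
    name: str
    cube_edge: float            # nm, squeeze target / slab cross-section
    slab_z: float               # nm
    initial_box_factor: float   # initial cube edge = factor * cube_edge
    total_time: float           # ps
    equilibration_time: float   # ps
    frame_interval: float       # ps
    squeeze_steps: int
    damping_time: float         # ps
    n_chains_cap: int | None    # cap on chain count (None = uncapped)


PRESETS: dict[str, ScalePreset] = {
    "study": ScalePreset("study", 60.0, 1200.0, 2.0, 5.0e6, 4.0e6, 1000.0,
                         100_000, 1.0, None),
    "reduced": ScalePreset("reduced", 20.0, 100.0, 2.0, 40_000.0, 30_000.0,
                           100.0, 20_000, 10.0, 10),
    "smoke": ScalePreset("smoke", 15.0, 45.0, 1.5, 100.0, 50.0, 10.0,
                         2_000, 1.0, 2),
}


def condensed_box_edge(variant: str, n_chains: int,
                       density_g_cm3: float = 0.25) -> float:
    """Cubic box edge (nm) putting *n_chains* at a condensed mass density."""
    chain = build_variant(variant)
    mass_g = n_chains * chain.molecular_weight * AMU_TO_G
    return float((mass_g / density_g_cm3 / CM3_PER_NM3) ** (1.0 / 3.0))


def condensed_run(variant: str = "WT", c_nacl: float = 0.0, seed: int = 1,
                  n_chains: int = 4, density_g_cm3: float = 0.25,
                  equilibration: float = 1000.0, analysis: float = 500.0,
                  frame_interval: float = 10.0, damping_time: float = 10.0,
                  thermostat_interval: int = 5,
                  model: InteractionModel | None = None) -> tuple[Trajectory, InteractionModel]:
    """Simulate the interior of a condensed phase at desk scale.

    Chains are packed directly into a cubic periodic box at a
    condensate-like density (default 0.25 g/cm^3), equilibrated, and
    sampled.  Returns the analysis-window trajectory and the model.
    This is the scaled-down stand-in for the slab-interior force
    analyses; see docs/methods.md for what it does and does not probe.
    """
    model = (model or InteractionModel()).at_salt(c_nacl)
    edge = condensed_box_edge(variant, n_chains, density_g_cm3)
    chain = build_variant(variant)
    state = initialize_system(chain, n_chains, (edge, edge, edge), seed,
                              temperature=model.temperature)
    sim = SimConfig(seed=seed, damping_time=damping_time,
                    thermostat_interval=thermostat_interval,
                    frame_interval=frame_interval,
                    total_time=equilibration + analysis,
                    equilibration_time=equilibration,
                    initial_box=(edge, edge, edge))
    langevin_propagate(state, model, sim, equilibration, record=False)
    traj = langevin_propagate(state, model, sim, analysis, record=True)
    return traj, model


@dataclass
class Scenario:
    """A (variant x salt x protein) grid at a given scale."""

    variants: list[str] = field(default_factory=lambda: ["WT"])
    salts_mM: list[float] = field(default_factory=lambda: [
        0.0, 50.0, 100.0, 150.0, 200.0, 300.0, 500.0, 750.0, 1000.0, 1250.0])
    proteins_uM: list[float] = field(default_factory=lambda: list(
        np.round(np.linspace(9.6, 20.8, 8), 2)))
    preset: str | ScalePreset = "reduced"
    seed: int = 1
    n_chains: int | None = None          # explicit override of the mapping
    salt_dependent_epsilon: bool = True
    large_system: bool = False
    lambda_scale: float = 1.0
    charge_scale: float = 1.0
    with_force_maps: bool = False
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not self.variants or not self.salts_mM or not self.proteins_uM:
            raise ValueError("scenario grids must be non-empty")
        if not isinstance(self.preset, ScalePreset) and self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")

    def scale(self) -> ScalePreset:
        return (self.preset if isinstance(self.preset, ScalePreset)
                else PRESETS[self.preset])

    def model(self, c_nacl: float) -> InteractionModel:
        kw = dict(lambda_scale=self.lambda_scale, charge_scale=self.charge_scale)
        if self.large_system:
            m = InteractionModel.large_system(c_nacl=c_nacl, **kw)
        else:
            m = InteractionModel(c_nacl=c_nacl, **kw)
        if not self.salt_dependent_epsilon:
            m = InteractionModel.constant_epsilon_control(c_nacl=c_nacl, **kw)
        return m

    def config_hash(self) -> str:
        return hashlib.md5(json.dumps(asdict(self), sort_keys=True)
                           .encode()).hexdigest()[:12]


@dataclass
class CellResult:
    variant: str
    salt_mM: float
    protein_uM: float
    n_chains: int
    call: object                 # PhaseCall
    maps: ForceMaps | None
    wall_time_s: float


def run_cell(scenario: Scenario, variant: str, salt_mM: float,
             protein_uM: float, write_traj_to: Path | None = None) -> CellResult:
    """Simulate and classify one grid cell (squeeze -> slab -> analyse)."""
    t0 = time.perf_counter()
    preset = scenario.scale()
    chain = build_variant(variant)
    model = scenario.model(salt_mM * 1e-3)
    slab = (preset.cube_edge, preset.cube_edge, preset.slab_z)
    if scenario.n_chains is not None:
        n_chains = scenario.n_chains
    else:
        try:
            n_chains = chains_for_concentration(protein_uM * 1e-6, slab)
        except ValueError:
            # tiny desk-scale boxes can round a uM grid point to zero
            # chains; floor at one so plumbing presets stay runnable
            n_chains = 1
            log.warning("%g uM rounds to zero chains in %s box; using 1",
                        protein_uM, preset.name)
    if preset.n_chains_cap is not None:
        n_chains = min(n_chains, preset.n_chains_cap)
    edge0 = preset.cube_edge * preset.initial_box_factor
    sim = SimConfig(
        seed=scenario.seed, damping_time=preset.damping_time,
        frame_interval=preset.frame_interval,
        total_time=preset.total_time,
        equilibration_time=preset.equilibration_time,
        initial_box=(edge0, edge0, edge0), slab_box=slab,
        squeeze_steps=preset.squeeze_steps)
    state = initialize_system(chain, n_chains, sim.initial_box, scenario.seed,
                              temperature=model.temperature)
    squeeze_and_slab(state, model, sim)
    langevin_propagate(state, model, sim, sim.equilibration_time, record=False)
    traj = langevin_propagate(state, model, sim, sim.analysis_time, record=True)
    call = classify_run(traj, sim.analysis_time)
    maps = (pairwise_time_averaged_forces(traj, model)
            if scenario.with_force_maps else None)
    if write_traj_to is not None:
        write_xyz(traj, write_traj_to)
    dt = time.perf_counter() - t0
    log.info("cell %s salt=%g mM protein=%g uM N=%d -> %s (%.1f s, "
             "mean neighbours %.2f)", variant, salt_mM, protein_uM, n_chains,
             call.label, dt, call.mean_neighbors_series.mean())
    return CellResult(variant, salt_mM, protein_uM, n_chains, call, maps, dt)


def run_scenario(scenario: Scenario) -> dict[str, PhaseDiagram]:
    """Run every cell of the grid; returns a phase diagram per variant.

    With an ``outdir``, per-cell provenance and summary TSVs are
    written, and completed cells (matching config hash) are skipped on
    re-run.
    """
    out = Path(scenario.outdir) if scenario.outdir else None
    chash = scenario.config_hash()
    diagrams: dict[str, PhaseDiagram] = {}
    failures = []
    for variant in scenario.variants:
        grid = np.empty((len(scenario.salts_mM), len(scenario.proteins_uM)),
                        dtype=object)
        for i, s in enumerate(scenario.salts_mM):
            for j, p in enumerate(scenario.proteins_uM):
                cell_dir = (out / variant / f"salt{s:g}_prot{p:g}") if out else None
                marker = cell_dir / "done.json" if cell_dir else None
                if marker and marker.exists():
                    rec = json.loads(marker.read_text())
                    if rec.get("config_hash") == chash:
                        grid[i, j] = rec["call"]
                        continue
                try:
                    res = run_cell(scenario, variant, s, p)
                except Exception as err:   # isolate per-cell failures
                    log.error("cell %s salt=%g prot=%g failed: %s",
                              variant, s, p, err)
                    failures.append((variant, s, p, str(err)))
                    grid[i, j] = "dissolved"
                    continue
                grid[i, j] = res.call.label
                if cell_dir:
                    cell_dir.mkdir(parents=True, exist_ok=True)
                    marker.write_text(json.dumps({
                        "config_hash": chash, "call": res.call.label,
                        "n_chains": res.n_chains,
                        "wall_time_s": res.wall_time_s,
                        "mean_neighbors": res.call.mean_neighbors_series.tolist(),
                    }))
        diag = assemble_phase_diagram(
            np.asarray(scenario.salts_mM) * 1e-3,
            np.asarray(scenario.proteins_uM) * 1e-6, grid)
        diagrams[variant] = diag
        if out:
            diag.write(out / variant)
            (out / variant / "provenance.json").write_text(json.dumps({
                "scenario": asdict(scenario), "config_hash": chash,
                "package": _version()}, indent=1))
    if failures:
        raise RuntimeError(f"{len(failures)} cell(s) failed: {failures}")
    return diagrams


def compare_constant_epsilon(scenario: Scenario):
    """Run the grid with salt-dependent eps on and off (same seeds/cells).

    Returns ``(diagrams_salt_dep, diagrams_const, difference)`` where
    *difference* lists per-variant boolean matrices of changed calls.
    """
    import dataclasses
    s_on = dataclasses.replace(scenario, salt_dependent_epsilon=True,
                               outdir=f"{scenario.outdir}/salt_eps" if scenario.outdir else None)
    s_off = dataclasses.replace(scenario, salt_dependent_epsilon=False,
                                outdir=f"{scenario.outdir}/const_eps" if scenario.outdir else None)
    d_on = run_scenario(s_on)
    d_off = run_scenario(s_off)
    diff = {v: d_on[v].calls != d_off[v].calls for v in d_on}
    return d_on, d_off, diff


def _version() -> str:
    from . import __version__
    return __version__
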