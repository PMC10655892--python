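"""Experiment orchestration: compaction, pulling cycles, scenario runs.

The central protocol mirrors mitotic chromosome self-assembly: a
bottlebrush polymer (BBP) is first equilibrated while bridging
condensins interact with it only sterically; at ``t = 0`` the
bridge-chromatin attraction is switched on and the polymer compacts
into a self-assembled cylinder (SAC).  Phases run in chunks and stop
early once the radius of gyration plateaus (relative change of the
windowed mean below 1% between consecutive windows), so the same code
path serves production-scale and reduced desk-scale runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .dynamics import PullingConfig, SimulationState, Trajectory, langevin_run
from .forcefield import ForceField
from .observables import (
    bridge_valence,
    cluster_bridges,
    extension_and_width,
    gyration_tensor_shape,
    local_stiffness,
    probe_distance,
)
from .topology import (
    ChromosomeTopology,
    ScenarioSpec,
    apply_cfs_perturbation,
    apply_knockout,
    build_poisson_bottlebrush,
    build_sister_chromatids,
    build_uniform_bottlebrush,
    initial_bottlebrush_coords,
    place_bridges,
)

#: box side as a multiple of the initial bottlebrush extent; keeps the
#: polymer clear of its periodic images while bridges stay dilute
BOX_FACTOR = 1.3
BOX_MARGIN = 20.0

PLATEAU_WINDOW = 3
PLATEAU_RTOL = 0.01


@dataclass
class ProtocolResult:
    """Trajectory plus aligned observable time series and phase marks."""

    trajectory: Trajectory
    phase_marks: dict[str, float]
    series: pd.DataFrame
    topology: ChromosomeTopology
    config: RunConfig
    extras: dict = field(default_factory=dict)


def build_topology(config: RunConfig) -> ChromosomeTopology:
    if config.loop_mode == "uniform":
        return build_uniform_bottlebrush(config.n_loops, config.L_loop_beads)
    return build_poisson_bottlebrush(
        config.n_loops, config.L_loop_beads, seed=config.seed + 101
    )


def forcefield_from_config(config: RunConfig) -> ForceField:
    return ForceField(
        A=config.A_kBT,
        eps_weak=config.eps_weak_kBT,
        eps_strong=config.eps_strong_kBT,
        eps_bridge_bridge=config.eps_bridge_bridge_kBT,
    )


def end_beads(topo: ChromosomeTopology) -> tuple[int, int]:
    """The two terminal backbone anchors of the first chromatid."""
    per = topo.beads_per_chromatid
    anchors = topo.anchors
    first = anchors[anchors < per]
    if first.size == 0:
        return 0, per - 1
    return int(first[0]), int(first[-1])


def assemble_system(
    config: RunConfig,
    topo: ChromosomeTopology | None = None,
) -> tuple[ChromosomeTopology, SimulationState, ForceField]:
    """Topology + initial state (polymer geometry, dilute bridges)."""
    if topo is None:
        topo = build_topology(config)
    pos = initial_bottlebrush_coords(topo, seed=config.seed + 7)
    extent = float(np.ptp(pos, axis=0).max())
    box = config.box_side_sigma or max(
        BOX_FACTOR * extent, extent + BOX_MARGIN
    )
    bridges = place_bridges(
        config.n_bridges, box, seed=config.seed + 23, near=pos
    )
    allpos = np.vstack([pos, bridges]) if config.n_bridges else pos
    state = SimulationState.create(allpos, box=box, seed=config.seed)
    return topo, state, forcefield_from_config(config)


def observable_series(
    traj: Trajectory,
    topo: ChromosomeTopology,
    ends: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-frame shape, extension and cluster observables."""
    n = topo.n_beads
    ends = ends or end_beads(topo)
    rows = []
    for frame, t in zip(traj.frames, traj.times):
        chrom = frame[:n]
        shape = gyration_tensor_shape(chrom)
        ext, width = extension_and_width(chrom, ends)
        row = {
            "time": t, "Rg": shape.Rg, "Ac": shape.Ac,
            "extension": ext, "width": width,
        }
        if frame.shape[0] > n:
            stats = cluster_bridges(frame[n:])
            row.update(
                N_c=stats.N_c, S_c=stats.S_c,
                valence=bridge_valence(frame[n:], chrom),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _run_phase(
    state: SimulationState,
    topo: ChromosomeTopology,
    ff: ForceField,
    budget_tau: float,
    config: RunConfig,
    pulling: PullingConfig | None = None,
    detect_plateau: bool = True,
) -> tuple[Trajectory | None, bool]:
    """Chunked run with optional R_g plateau detection; returns converged."""
    dt = config.dt_tau
    stride_tau = min(config.snapshot_stride_tau, budget_tau)
    if budget_tau <= 0:
        return None, True
    n_chunks = 20
    chunk_tau = max(budget_tau / n_chunks, stride_tau)
    chunk_steps = max(int(round(chunk_tau / dt)), 1)
    stride = max(int(round(stride_tau / dt)), 1)
    total_steps = int(round(budget_tau / dt))

    traj: Trajectory | None = None
    rg_hist: list[float] = []
    done = 0
    converged = False
    n = topo.n_beads
    while done < total_steps:
        steps = min(chunk_steps, total_steps - done)
        part = langevin_run(
            state, topo, ff, steps, dt=dt, gamma=config.gamma,
            stride=stride, pulling=pulling,
        )
        traj = part if traj is None else traj.concatenate(part)
        done += steps
        rg_hist.append(gyration_tensor_shape(state.positions[:n]).Rg)
        if detect_plateau and len(rg_hist) >= 2 * PLATEAU_WINDOW:
            recent = np.mean(rg_hist[-PLATEAU_WINDOW:])
            previous = np.mean(rg_hist[-2 * PLATEAU_WINDOW : -PLATEAU_WINDOW])
            if abs(recent - previous) / max(previous, 1e-12) < PLATEAU_RTOL:
                converged = True
                break
    else:
        converged = not detect_plateau
    return traj, converged


def run_compaction(
    config: RunConfig,
    topo: ChromosomeTopology | None = None,
    attraction: bool = True,
) -> ProtocolResult:
    """BBP equilibration -> bridge switch-on -> SAC.

    Phase 1 runs with purely steric bridge-polymer interactions until
    the bottlebrush R_g plateaus (or the ``equilibration`` budget is
    spent); the bridge-chromatin attraction is then enabled and phase 2
    runs until the compacting R_g plateaus (or the ``compaction`` budget
    is spent).  ``attraction=False`` keeps the steric force field
    throughout (negative control: no compaction drive).
    """
    topo, state, ff = assemble_system(config, topo)
    equil_tau = config.phase_durations.get("equilibration", 0.0)
    compact_tau = config.phase_durations.get("compaction", 0.0)

    traj1, conv1 = _run_phase(state, topo, ff.steric(), equil_tau, config)
    t_on = state.time
    ff2 = ff if attraction else ff.steric()
    traj2, conv2 = _run_phase(state, topo, ff2, compact_tau, config)
    if not conv2:
        warnings.warn(
            "compaction phase hit its budget without an R_g plateau; "
            "returning the partial result", stacklevel=2,
        )

    parts = [t for t in (traj1, traj2) if t is not None]
    traj = parts[0]
    for p in parts[1:]:
        traj = traj.concatenate(p)
    series = observable_series(traj, topo)
    return ProtocolResult(
        trajectory=traj,
        phase_marks={"bridge_on": t_on, "end": state.time},
        series=series,
        topology=topo,
        config=config,
        extras={
            "state": state,
            "equilibration_converged": conv1,
            "compaction_converged": conv2,
        },
    )


def run_extension_retraction(
    state: SimulationState,
    topo: ChromosomeTopology,
    ff: ForceField,
    pulling: PullingConfig,
    config: RunConfig,
) -> ProtocolResult:
    """Constant-force extension then force-free retraction of a SAC.

    Equal and opposite forces of ``pulling.force_magnitude`` (kBT/sigma)
    act on the two terminal backbone anchors for ``extension_phase``
    tau; the force is then removed for ``relaxation_phase`` tau.  The
    state is advanced in place.
    """
    if pulling.bead_a < 0 or pulling.bead_b < 0:
        a, b = end_beads(topo)
        pulling = PullingConfig(
            pulling.force_magnitude, a, b,
            pulling.extension_phase, pulling.relaxation_phase,
        )
    t_start = state.time
    traj1, _ = _run_phase(
        state, topo, ff, pulling.extension_phase, config,
        pulling=pulling, detect_plateau=False,
    )
    t_off = state.time
    traj2, _ = _run_phase(
        state, topo, ff, pulling.relaxation_phase, config,
        detect_plateau=False,
    )
    parts = [t for t in (traj1, traj2) if t is not None]
    traj = parts[0]
    for p in parts[1:]:
        traj = traj.concatenate(p)
    series = observable_series(
        traj, topo, ends=(pulling.bead_a, pulling.bead_b)
    )
    return ProtocolResult(
        trajectory=traj,
        phase_marks={"force_on": t_start, "force_off": t_off,
                     "end": state.time},
        series=series,
        topology=topo,
        config=config,
        extras={"state": state, "pulling": pulling},
    )


def default_scenario_spec(config: RunConfig, name: str) -> ScenarioSpec:
    """Canonical perturbation recipe for each named scenario."""
    n_loops = config.n_loops
    locus = n_loops // 2
    if name in ("cfs_removal", "cfs_merge"):
        return ScenarioSpec(name=name, perturbed_locus=locus)
    return ScenarioSpec(name=name)


def _probe_regions_for(
    topo: ChromosomeTopology, locus: int, span: int
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Simulated FISH probe intervals around a perturbed locus.

    One probe sits on the loop immediately before the perturbed region
    and the other on its middle loop (bead indices taken before the
    perturbation, so the same intervals apply to the control).  In a
    normal cylinder these adjacent sequences lie close together; when
    the region is merged into one oversized loop, the interior sequence
    is expelled from the cylinder body and the probes separate.
    """
    table = topo.loop_table
    left = table[locus - 1]
    mid = table[locus + span // 2]
    return (
        (int(left[0]), int(left[0] + left[1])),
        (int(mid[0]), int(mid[0] + mid[1])),
    )


def run_scenario(
    config: RunConfig,
    scenario: ScenarioSpec | str | None = None,
) -> ProtocolResult:
    """Apply a scenario transformation, compact, and add scenario outputs.

    Knockouts rescale loops and bridge numbers globally; CFS scenarios
    perturb loops locally while bridges stay unchanged; ``sisters``
    duplicates the chromatid with centromeric springs and doubles the
    bridge pool.  Extras carry the steady-state width, local backbone
    stiffness and (for CFS runs) the simulated FISH probe distance.
    """
    if scenario is None or isinstance(scenario, str):
        scenario = default_scenario_spec(config, scenario or config.scenario)
    name = scenario.name

    topo = None
    probes = scenario.probe_regions
    if name in ("condI_KO", "condII_KO"):
        config = apply_knockout(config, name)
    elif name in ("cfs_removal", "cfs_merge"):
        base = build_topology(config)
        locus = scenario.perturbed_locus
        if locus is None:
            locus = config.n_loops // 2
        kind = "removal" if name == "cfs_removal" else "merge"
        span = 2 if kind == "removal" else 3
        if probes is None:
            probes = _probe_regions_for(base, locus, span)
        topo = apply_cfs_perturbation(base, kind, locus)
    elif name == "sisters":
        base = build_topology(config)
        n_loops = base.loop_table.shape[0]
        centromere = (n_loops // 2 - 1, n_loops // 2 + 1)
        topo = build_sister_chromatids(base, centromere, n_springs=10)
        config = config.replace(n_bridges=config.n_bridges * 2)
    elif name != "control":
        raise ValueError(f"unknown scenario {name!r}")

    result = run_compaction(config, topo=topo)

    n = result.topology.n_beads
    tail = result.trajectory.frames[
        -max(1, result.trajectory.n_frames // 4) :
    ]
    widths, stiffs = [], []
    anchors = result.topology.anchors
    for frame in tail:
        _, w = extension_and_width(frame[:n], end_beads(result.topology))
        widths.append(w)
        if anchors.size >= 16:
            stiffs.append(local_stiffness(frame[anchors], stride=5))
    result.extras["width"] = float(np.mean(widths))
    if stiffs:
        result.extras["local_stiffness"] = float(np.mean(stiffs))
    if probes is not None:
        result.extras["probe_distance"] = probe_distance(
            tail[:, :n], probes[0], probes[1]
        )
        result.extras["probe_regions"] = probes
    return result
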