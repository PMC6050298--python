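"""Simulated-annealing Monte Carlo over fragment selections.

Each trajectory starts from a random fragment recombination with a fully
designed sequence; at every step one segment is replaced by a random
fragment from its conformation database, the swapped segment plus every
residue within the design shell is redesigned, and the move is accepted by
the Metropolis criterion under a geometrically decreasing temperature.
A campaign runs many independent trajectories, ranks the finals by surrogate
energy and clusters them by backbone conformation to yield conformationally
unique designs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .assembly_design import (
    AssemblyState,
    DesignParams,
    assemble,
    design_sequence,
    design_shell,
    score,
)
from .family_db import ConformationDB
from .geometry import superpose


@dataclass
class SamplerConfig:
    """n_starts trajectories of n_steps fragment swaps each; temperature
    decays geometrically from T_start to T_end (surrogate-energy units)."""

    n_starts: int = 50
    n_steps: int = 30
    T_start: float = 2.0
    T_end: float = 0.01
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not (self.T_start >= self.T_end > 0):
            raise ValueError("need T_start >= T_end > 0")

    def temperature(self, step: int) -> float:
        """Geometric interpolation over steps 0..n_steps-1."""
        if self.n_steps == 1:
            return self.T_start
        f = step / (self.n_steps - 1)
        return self.T_start * (self.T_end / self.T_start) ** f


@dataclass
class StepRecord:
    step: int
    segment: str
    fragment_index: int
    delta_e: float
    temperature: float
    uniform_draw: float
    accepted: bool


@dataclass
class Trajectory:
    seed: int
    start: AssemblyState
    steps: list[StepRecord]
    final: AssemblyState


@dataclass
class DesignResult:
    trajectory_index: int
    seed: int
    state: AssemblyState
    energy_trace: list[float]
    cluster: int | None = None


def metropolis_accept(delta_e: float, temperature: float, u: float) -> bool:
    """Accept a move: always if delta_e <= 0, else with probability
    exp(-delta_e / T) against the supplied uniform(0,1) draw."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if delta_e <= 0:
        return True
    return u < math.exp(-delta_e / temperature)


def _random_selection(db: ConformationDB, rng: np.random.Generator) -> dict[str, int]:
    return {name: int(rng.integers(len(db.fragments[name]))) for name in db.segment_names}


def run_trajectory(
    db: ConformationDB,
    params: DesignParams,
    config: SamplerConfig,
    seed: int,
) -> Trajectory:
    """One annealing trajectory, bit-replayable from its seed.

    The proposal is uniform over segments, then uniform over that segment's
    fragments (self-swaps count as steps); a uniform draw is consumed at
    every step regardless of the sign of the energy change, keeping the
    random stream aligned for replay.
    """
    rng = np.random.default_rng(seed)
    selection = _random_selection(db, rng)
    state = assemble(db, selection, catalytic=params.catalytic)
    state = design_sequence(state, params)
    start = state.copy()

    names = db.segment_names
    steps: list[StepRecord] = []
    for k in range(config.n_steps):
        T = config.temperature(k)
        seg = names[int(rng.integers(len(names)))]
        fi = int(rng.integers(len(db.fragments[seg])))
        u = float(rng.random())
        cand_sel = dict(state.selection)
        cand_sel[seg] = fi
        cand = assemble(db, cand_sel, constant_source=state.constant_source, catalytic=params.catalytic)
        # carry the current sequence (and fallback records) over the
        # unchanged blocks
        cur_by_block = {(b[0], b[1]): b for b in state.blocks}
        cat_idx = cand.catalytic_indices(params)
        for name, ri, s0, e0 in cand.blocks:
            if name == seg:
                continue
            old = cur_by_block.get((name, ri))
            if old is not None and old[3] - old[2] == e0 - s0:
                for off in range(e0 - s0 + 1):
                    i = s0 + off
                    j = old[2] + off
                    if i not in cat_idx:
                        cand.sequence[i] = state.sequence[j]
                        cand.backbone.residues[i].aa = state.sequence[j]
                    if j in state.fallback_positions:
                        cand.fallback_positions.add(i)
        changed = {
            i for name, ri, s0, e0 in cand.blocks if name == seg for i in range(s0, e0 + 1)
        }
        shell = design_shell(cand, changed, params.shell_radius, params)
        cand = design_sequence(cand, params, positions=shell)
        if math.isnan(state.energy):
            state.energy, state.energy_terms = score(state, params)
        delta = cand.energy - state.energy
        acc = metropolis_accept(delta, T, u)
        steps.append(StepRecord(k, seg, fi, float(delta), T, u, acc))
        if acc:
            state = cand
    return Trajectory(seed=seed, start=start, steps=steps, final=state)


def run_campaign(
    db: ConformationDB,
    params: DesignParams,
    config: SamplerConfig,
) -> list[DesignResult]:
    """Run ``n_starts`` independent trajectories and rank finals by energy
    ascending (ties broken by trajectory index)."""
    master = np.random.default_rng(config.rng_seed)
    seeds = [int(s) for s in master.integers(0, 2**31 - 1, size=config.n_starts)]
    results = []
    for ti, seed in enumerate(seeds):
        traj = run_trajectory(db, params, config, seed)
        trace = [traj.start.energy] + [
            traj.start.energy + sum(s.delta_e for s in traj.steps[: k + 1] if s.accepted)
            for k in range(len(traj.steps))
        ]
        results.append(DesignResult(ti, seed, traj.final, trace))
    results.sort(key=lambda r: (r.state.energy, r.trajectory_index))
    return results


def cluster_designs(results: list[DesignResult], threshold: float = 2.0) -> list[DesignResult]:
    """Greedy leader clustering of design backbones on full-chain CA RMSD,
    processed in energy order so each representative is its cluster's
    lowest-energy member; designs of unequal length never co-cluster.
    Assigns ``cluster`` ids in place and returns the representatives."""
    if not results:
        raise ValueError("cluster_designs needs at least one result")
    reps: list[tuple[int, np.ndarray]] = []
    out: list[DesignResult] = []
    for r in results:  # results are already energy-ranked
        ca = r.state.backbone.ca_coords()
        for cid, rep_ca in reps:
            if len(rep_ca) != len(ca):
                continue
            if superpose(rep_ca, ca)[2] <= threshold:
                r.cluster = cid
                break
        else:
            cid = len(reps)
            reps.append((cid, ca))
            r.cluster = cid
            out.append(r)
    return out


def nearest_family_distance(
    state: AssemblyState,
    family_sequences: dict[str, dict[int, str]],
) -> tuple[str, int]:
    """Minimum Hamming distance between a design and the family, on aligned
    reference positions (gaps count as mismatches).

    family_sequences maps member id -> {reference position -> residue}.
    Returns (closest member id, mutation count).
    """
    if not family_sequences:
        raise ValueError("empty family")
    design = {
        p: aa for p, aa in zip(state.positions, state.sequence) if p is not None
    }
    best = None
    for mid, seq in sorted(family_sequences.items()):
        positions = set(design) | set(seq)
        d = sum(1 for p in positions if design.get(p) != seq.get(p))
        if best is None or d < best[1]:
            best = (mid, d)
    return best
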