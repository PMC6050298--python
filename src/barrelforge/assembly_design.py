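"""Backbone assembly from fragment selections and PSSM-constrained design.

``assemble`` splices the torsion records of one fragment per segment (plus
the constant region) in reference order and rebuilds Cartesian coordinates,
anchored at the reference frame.  At block junctions the peptide-link bond
length and angles come from the downstream fragment's stored incoming-link
record; torsions stay with the residue that owns them, so reassembling all
fragments of one source reproduces that source exactly.

``design_sequence`` performs identity-level sequence design: at each
designable position the amino acid maximizing (PSSM log-odds minus a
representative-atom clash penalty) among identities passing the PSSM cutoff,
iterated to convergence.  This is a deliberately simplified surrogate for
all-atom design: it keeps the method's architecture — clash avoidance, PSSM
likelihood, chain integrity — while remaining exactly testable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy.spatial.distance import cdist

from .family_db import ConformationDB
from .geometry import place_atom
from .structure_io import (
    AA1,
    IDEAL_C_N,
    IDEAL_CA_C_N,
    IDEAL_C_N_CA,
    IDEAL_CA_CB,
    IDEAL_N_CA_CB,
    IDEAL_CB_TORSION,
    BackboneStructure,
    from_internal,
)

logger = logging.getLogger(__name__)


@dataclass
class Weights:
    w_clash: float = 1.0
    w_pssm: float = 1.0
    w_junction: float = 10.0


@dataclass
class DesignParams:
    """Design-stage parameters.

    shell_radius: Å radius around a replaced segment within which residues
    are redesigned (representative-atom distances).  pssm_cutoff: minimum
    PSSM log-odds (bits) for an identity to be designable at a position.
    catalytic: reference position -> fixed one-letter identity; these
    positions are never designed.  d_clash: representative-atom distance
    below which the soft steric penalty turns on.
    """

    shell_radius: float = 6.0
    pssm_cutoff: float = 0.0
    catalytic: dict[int, str] = field(default_factory=dict)
    weights: Weights = field(default_factory=Weights)
    d_clash: float = 4.0

    def __post_init__(self):
        if self.shell_radius <= 0:
            raise ValueError("shell_radius must be > 0")

    @classmethod
    def from_db(cls, db: ConformationDB, **kw) -> "DesignParams":
        cat = dict(db.scheme.catalytic)
        return cls(catalytic=cat, **kw)


@dataclass
class AssemblyState:
    """One assembled backbone with its designed sequence and surrogate energy."""

    selection: dict[str, int]
    constant_source: str
    backbone: BackboneStructure
    sequence: list[str]
    positions: list[int | None]  # reference position per residue
    pssm: np.ndarray  # (n, 20); NaN rows where no PSSM column exists
    blocks: list[tuple[str, int, int, int]]  # (segment, range_idx, start, end) 0-based incl.
    junctions: list[int]  # residue i such that i|i+1 is a block junction
    cb_coords: np.ndarray  # (n, 3) ideal CB for every residue (incl. Gly)
    energy: float = math.nan
    energy_terms: dict = field(default_factory=dict)
    fallback_positions: set[int] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.sequence)

    def rep_coords(self) -> np.ndarray:
        """Representative atoms under the current sequence: CB, CA for Gly."""
        ca = self.backbone.ca_coords()
        out = self.cb_coords.copy()
        gly = np.array([aa == "G" for aa in self.sequence])
        out[gly] = ca[gly]
        return out

    def catalytic_indices(self, params: DesignParams) -> set[int]:
        return {
            i for i, p in enumerate(self.positions)
            if p is not None and p in params.catalytic
        }

    def designable_indices(self, params: DesignParams) -> set[int]:
        cat = self.catalytic_indices(params)
        return {
            i for i in range(len(self))
            if i not in cat and not math.isnan(self.pssm[i, 0])
        }

    def copy(self) -> "AssemblyState":
        return dc_replace(
            self,
            selection=dict(self.selection),
            sequence=list(self.sequence),
            energy_terms=dict(self.energy_terms),
            fallback_positions=set(self.fallback_positions),
        )


def assemble(
    db: ConformationDB,
    selection: dict[str, int],
    constant_source: str | None = None,
    catalytic: dict[int, str] | None = None,
) -> AssemblyState:
    """Splice the selected fragments into a full backbone.

    selection maps every sampled segment name to a fragment index; constant
    blocks come from ``constant_source`` (default: the reference).  The
    returned state carries the fragments' native sequence, with configured
    catalytic identities enforced.
    """
    missing = [n for n in db.segment_names if n not in selection]
    if missing:
        raise ValueError(f"selection missing segments: {missing}")
    if constant_source is None:
        constant_source = db.reference_id
    if catalytic is None:
        catalytic = dict(db.scheme.catalytic)

    order = db.block_order()
    chosen = []
    for name, ri in order:
        if name in db.fragments:
            frag = db.fragments[name][selection[name]]
        else:
            cands = [f for f in db.constant[name] if f.source_id == constant_source]
            if not cands:
                raise ValueError(f"{name}: no constant block from source {constant_source!r}")
            frag = cands[0]
        chosen.append((name, ri, frag))

    internal = []
    positions: list[int | None] = []
    pssm_rows: list[np.ndarray] = []
    blocks: list[tuple[str, int, int, int]] = []
    junctions: list[int] = []
    nan_row = np.full(20, np.nan)
    for bi, (name, ri, frag) in enumerate(chosen):
        res = [dc_replace(r) for r in frag.range_residues[ri]]
        if bi + 1 < len(chosen):
            nxt = chosen[bi + 1][2]
            inc = nxt.range_incoming[chosen[bi + 1][1]]
            last = res[-1]
            if inc is not None:
                last.d_c_n, last.a_ca_c_n, last.a_c_n_ca = inc.d_c_n, inc.a_ca_c_n, inc.a_c_n_ca
                if math.isnan(last.psi):
                    last.psi = inc.psi_prev
                if math.isnan(last.omega):
                    last.omega = inc.omega_prev
            if math.isnan(last.d_c_n):
                last.d_c_n, last.a_ca_c_n, last.a_c_n_ca = IDEAL_C_N, IDEAL_CA_C_N, IDEAL_C_N_CA
            if math.isnan(last.omega):
                last.omega = 180.0
            junctions.append(sum(len(c[2].range_residues[c[1]]) for c in chosen[: bi + 1]) - 1)
        start = len(internal)
        internal.extend(res)
        blocks.append((name, ri, start, len(internal) - 1))
        positions.extend(frag.range_positions[ri])
        frag_off = sum(len(frag.range_residues[j]) for j in range(ri))
        for j in range(len(res)):
            if frag.pssm_slice is not None:
                pssm_rows.append(frag.pssm_slice.scores[frag_off + j])
            else:
                pssm_rows.append(nan_row)

    backbone = from_internal(internal, anchor=db.anchor, structure_id="assembly")
    backbone.ref_map = {
        i + 1: p for i, p in enumerate(positions) if p is not None
    }
    sequence = [r.aa for r in internal]
    for i, p in enumerate(positions):
        if p is not None and p in catalytic:
            sequence[i] = catalytic[p]
            backbone.residues[i].aa = catalytic[p]

    cb = np.empty((len(internal), 3))
    for i, r in enumerate(backbone.residues):
        if "CB" in r.coords:
            cb[i] = r.coords["CB"]
        else:
            cb[i] = place_atom(
                r.atom("C"), r.atom("N"), r.atom("CA"),
                IDEAL_CA_CB, IDEAL_N_CA_CB, IDEAL_CB_TORSION,
            )
    return AssemblyState(
        selection=dict(selection),
        constant_source=constant_source,
        backbone=backbone,
        sequence=sequence,
        positions=positions,
        pssm=np.array(pssm_rows),
        blocks=blocks,
        junctions=junctions,
        cb_coords=cb,
    )


def design_shell(
    state: AssemblyState,
    changed: set[int],
    radius: float,
    params: DesignParams,
) -> set[int]:
    """Residues to redesign after a segment swap: the changed residues plus
    every residue whose representative atom lies within ``radius`` Å of a
    changed residue's; catalytic positions excluded."""
    if radius <= 0:
        raise ValueError("shell radius must be > 0")
    if not changed:
        return set()
    reps = state.rep_coords()
    ch = sorted(changed)
    d = cdist(reps, reps[ch])
    near = set(np.nonzero((d <= radius).any(axis=1))[0].tolist())
    return (near | set(changed)) - state.catalytic_indices(params)


def score(state: AssemblyState, params: DesignParams) -> tuple[float, dict[str, float]]:
    """Surrogate energy: soft steric clash + negative PSSM log-odds +
    junction peptide-bond strain; terms reported separately and additive."""
    w = params.weights
    reps = state.rep_coords()
    n = len(reps)
    d = cdist(reps, reps)
    ii, jj = np.triu_indices(n, 3)  # pairs separated by > 2 in sequence
    overlap = np.clip(params.d_clash - d[ii, jj], 0.0, None)
    clash = float((overlap**2).sum())

    pssm_term = 0.0
    for i, aa in enumerate(state.sequence):
        col = state.pssm[i]
        if not math.isnan(col[0]) and aa in AA1:
            pssm_term -= float(col[AA1.index(aa)])

    junction = 0.0
    for j in state.junctions:
        dcn = float(np.linalg.norm(
            state.backbone.residues[j].atom("C") - state.backbone.residues[j + 1].atom("N")
        ))
        junction += (dcn - IDEAL_C_N) ** 2

    terms = {
        "clash": w.w_clash * clash,
        "pssm": w.w_pssm * pssm_term,
        "junction": w.w_junction * junction,
    }
    return sum(terms.values()), terms


def _position_clash(reps: np.ndarray, cand: np.ndarray, i: int, d_clash: float) -> float:
    d = np.linalg.norm(reps - cand, axis=1)
    mask = np.abs(np.arange(len(reps)) - i) > 2
    overlap = np.clip(d_clash - d[mask], 0.0, None)
    return float((overlap**2).sum())


def design_sequence(
    state: AssemblyState,
    params: DesignParams,
    positions: set[int] | None = None,
    max_sweeps: int = 5,
) -> AssemblyState:
    """Greedy coordinate-descent identity design over ``positions``.

    At each position the identity minimizing
    ``w_pssm * (-pssm) + w_clash * clash_contribution`` among identities with
    PSSM score >= cutoff is installed (positions are swept repeatedly, at
    most ``max_sweeps`` times, because clash contributions couple
    neighbours).  A position where no identity passes the cutoff falls back
    to the PSSM argmax with a logged warning.  Catalytic identities are never
    altered; requesting one logs a warning.  The state is modified in place
    (energy recomputed) and returned.
    """
    designable = state.designable_indices(params)
    if positions is None:
        positions = set(designable)
    cat = state.catalytic_indices(params)
    for p in sorted(positions & cat):
        logger.warning("design_sequence: position %d is catalytic, identity kept", p)
    targets = sorted((positions & designable) - cat)
    w = params.weights
    ca = state.backbone.ca_coords()

    for _ in range(max_sweeps):
        changed = False
        reps = state.rep_coords()
        for i in targets:
            col = state.pssm[i]
            allowed = [a for a in range(20) if col[a] >= params.pssm_cutoff]
            if not allowed:
                best_aa = AA1[int(np.argmax(col))]
                if i not in state.fallback_positions:
                    logger.warning(
                        "design_sequence: no identity passes cutoff %.2f at residue %d; "
                        "falling back to PSSM argmax %s", params.pssm_cutoff, i, best_aa,
                    )
                state.fallback_positions.add(i)
                allowed = [AA1.index(best_aa)]
            clash_cb = _position_clash(reps, state.cb_coords[i], i, params.d_clash)
            clash_ca = _position_clash(reps, ca[i], i, params.d_clash)
            best, best_e = None, math.inf
            for a in allowed:
                cl = clash_ca if AA1[a] == "G" else clash_cb
                e = -w.w_pssm * float(col[a]) + w.w_clash * cl
                if e < best_e - 1e-12:
                    best, best_e = a, e
            new_aa = AA1[best]
            if new_aa != state.sequence[i]:
                state.sequence[i] = new_aa
                state.backbone.residues[i].aa = new_aa
                reps = state.rep_coords()
                changed = True
        if not changed:
            break
    state.energy, state.energy_terms = score(state, params)
    return state
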