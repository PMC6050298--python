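"""Family conformation databases.

Pipeline: align family members onto a reference numbering (by MSA or by
pairwise sequence alignment) and superpose them rigidly; profile per-position
structural conservation; cut the chain into segments at conservation minima
inside the beta strands; extract each member's torsion-space fragment per
segment together with a conformation-dependent PSSM (built from the sequences
of members whose local conformation lies within an RMSD radius of the
fragment's).  The result is a serializable :class:`ConformationDB` that the
assembly and sampling stages consume.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from Bio import Align
from Bio.Align import substitution_matrices

from .geometry import superpose
from .structure_io import (
    AA1,
    BackboneStructure,
    InternalResidue,
    StructureError,
    from_internal,
    to_internal,
)

logger = logging.getLogger(__name__)

DB_FORMAT = "barrelforge-db"
DB_VERSION = 1

UNIFORM_BACKGROUND = np.full(20, 0.05)
# Robinson & Robinson amino-acid frequencies (the BLOSUM-era standard
# background), selectable instead of the uniform default.
BLOSUM_BACKGROUND = np.array([
    0.078, 0.019, 0.054, 0.063, 0.039, 0.073, 0.022, 0.052, 0.058, 0.091,
    0.022, 0.045, 0.052, 0.043, 0.051, 0.068, 0.059, 0.066, 0.014, 0.032,
])
BLOSUM_BACKGROUND /= BLOSUM_BACKGROUND.sum()


# ---------------------------------------------------------------------------
# segmentation scheme
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    """One sampled segment: a name plus one or more inclusive reference-
    numbering ranges (several ranges = a discontinuous segment whose parts
    are always exchanged together)."""

    name: str
    ranges: list[tuple[int, int]]

    def positions(self) -> list[int]:
        out: list[int] = []
        for s, e in self.ranges:
            out.extend(range(s, e + 1))
        return out


@dataclass
class SegmentationScheme:
    reference_id: str
    segments: list[Segment]
    constant_ranges: list[tuple[int, int]] | None = None
    catalytic: list[tuple[int, str]] = field(default_factory=list)

    def validate(self) -> None:
        seen: set[int] = set()
        for seg in self.segments:
            if seg.ranges != sorted(seg.ranges):
                raise ValueError(f"segment {seg.name}: ranges not sorted")
            for s, e in seg.ranges:
                if e < s:
                    raise ValueError(f"segment {seg.name}: empty range {s}-{e}")
                ps = set(range(s, e + 1))
                if ps & seen:
                    raise ValueError(f"segment {seg.name}: overlapping ranges")
                seen |= ps

    def sampled_positions(self) -> set[int]:
        return {p for seg in self.segments for p in seg.positions()}

    def to_dict(self) -> dict:
        return {
            "reference_id": self.reference_id,
            "segments": [{"name": s.name, "ranges": [list(r) for r in s.ranges]} for s in self.segments],
            "constant_ranges": [list(r) for r in self.constant_ranges] if self.constant_ranges else None,
            "catalytic": [{"position": p, "aa": a} for p, a in self.catalytic],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentationScheme":
        try:
            scheme = cls(
                reference_id=d["reference_id"],
                segments=[
                    Segment(s["name"], [tuple(int(x) for x in r) for r in s["ranges"]])
                    for s in d["segments"]
                ],
                constant_ranges=[tuple(int(x) for x in r) for r in d["constant_ranges"]]
                if d.get("constant_ranges")
                else None,
                catalytic=[(int(c["position"]), str(c["aa"])) for c in d.get("catalytic") or []],
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"malformed segmentation scheme: {exc}") from exc
        scheme.validate()
        return scheme

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "SegmentationScheme":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def _msa_ref_map(ref_row: str, member_row: str) -> dict[int, int]:
    """Map member res_index -> reference res_index from two gapped MSA rows."""
    if len(ref_row) != len(member_row):
        raise ValueError("MSA rows differ in length")
    rm: dict[int, int] = {}
    ri = mi = 0
    for rc, mc in zip(ref_row, member_row):
        r_has = rc not in "-."
        m_has = mc not in "-."
        if r_has:
            ri += 1
        if m_has:
            mi += 1
        if r_has and m_has:
            rm[mi] = ri
    return rm


def _pairwise_ref_map(reference: BackboneStructure, member: BackboneStructure) -> dict[int, int]:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    ref_seq = reference.sequence.replace("X", "A")
    mem_seq = member.sequence.replace("X", "A")
    aln = aligner.align(ref_seq, mem_seq)[0]
    rm: dict[int, int] = {}
    for (rs, re_), (ms, me) in zip(*aln.aligned):
        for k in range(re_ - rs):
            rm[ms + k + 1] = rs + k + 1
    return rm


def align_family(
    members: list[BackboneStructure],
    reference: BackboneStructure,
    msa: dict[str, str] | None = None,
    trim_cutoff: float = 3.0,
    max_iter: int = 10,
    min_mapped: int = 20,
) -> list[BackboneStructure]:
    """Attach reference maps and superpose every member onto the reference.

    Members are mapped to reference numbering through the MSA when given
    (rows keyed by structure id; the reference id must be present), otherwise
    by global pairwise sequence alignment.  Superposition is iterative
    trimmed Kabsch on mapped CA pairs: pairs deviating by more than
    ``trim_cutoff`` Å are dropped and the fit repeated until the pair set is
    stable (at most ``max_iter`` rounds).  Members with fewer than
    ``min_mapped`` mapped positions are excluded with a warning.
    """
    if msa is not None and reference.id not in msa:
        raise ValueError(f"MSA lacks the reference row {reference.id!r}")
    aligned: list[BackboneStructure] = []
    for m in members:
        if msa is not None:
            if m.id not in msa:
                logger.warning("align_family: %s missing from MSA, excluded", m.id)
                continue
            rm = _msa_ref_map(msa[reference.id], msa[m.id])
        elif m.id == reference.id:
            rm = {i: i for i in range(1, len(m) + 1)}
        else:
            rm = _pairwise_ref_map(reference, m)
        if len(rm) < min_mapped:
            logger.warning("align_family: %s has only %d mapped positions, excluded", m.id, len(rm))
            continue
        ref_ca = {r.res_index: r.atom("CA") for r in reference.residues}
        mem_ca = {r.res_index: r.atom("CA") for r in m.residues}
        pairs = [(mi, ri) for mi, ri in sorted(rm.items()) if ri in ref_ca and mi in mem_ca]
        a = np.array([ref_ca[ri] for _, ri in pairs])
        b = np.array([mem_ca[mi] for mi, _ in pairs])
        keep = np.ones(len(pairs), bool)
        rot = np.eye(3)
        trans = np.zeros(3)
        for _ in range(max_iter):
            if keep.sum() < 3:
                break
            rot, trans, _ = superpose(a[keep], b[keep])
            dev = np.linalg.norm((b @ rot.T + trans) - a, axis=1)
            new_keep = dev <= trim_cutoff
            if new_keep.sum() < 3:
                break
            if np.array_equal(new_keep, keep):
                break
            keep = new_keep
        out = m.transformed(rot, trans)
        out.ref_map = dict(rm)
        aligned.append(out)
    return aligned


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------

@dataclass
class ConservationProfile:
    """Per reference position: mean pairwise CA deviation (Å) among covering
    members (NaN where coverage < min_coverage) and coverage fraction."""

    positions: np.ndarray
    mean_dev: np.ndarray
    coverage: np.ndarray
    min_coverage: float = 0.5


def conservation_profile(
    aligned: list[BackboneStructure],
    reference_length: int,
    min_coverage: float = 0.5,
) -> ConservationProfile:
    if len(aligned) < 2:
        raise ValueError("conservation profile needs at least 2 aligned members")
    n = len(aligned)
    positions = np.arange(1, reference_length + 1)
    mean_dev = np.full(reference_length, np.nan)
    coverage = np.zeros(reference_length)
    per_member = []
    for m in aligned:
        ca = {}
        for r in m.residues:
            p = m.ref_map.get(r.res_index) if m.ref_map else None
            if p is not None:
                ca[p] = r.atom("CA")
        per_member.append(ca)
    for i, p in enumerate(positions):
        pts = np.array([ca[p] for ca in per_member if p in ca])
        coverage[i] = len(pts) / n
        if len(pts) >= 2 and coverage[i] >= min_coverage:
            diffs = pts[:, None, :] - pts[None, :, :]
            d = np.sqrt((diffs**2).sum(-1))
            iu = np.triu_indices(len(pts), 1)
            mean_dev[i] = d[iu].mean()
    return ConservationProfile(positions, mean_dev, coverage, min_coverage)


def propose_boundaries(
    profile: ConservationProfile,
    strand_ranges: list[tuple[int, int]],
    n_segments: int | None = None,
    groups: list[list[int]] | None = None,
    reference_id: str = "reference",
) -> SegmentationScheme:
    """Cut the chain at the conservation minimum of each strand range.

    One cut per strand (ties resolved to the lowermost position); consecutive
    cuts bound contiguous segments, the last segment running to the final
    covered position.  ``n_segments`` may merge trailing segments down to the
    requested count; ``groups`` (lists of segment indices) merges segments
    into discontinuous sampling groups.  The region before the first cut
    becomes the constant region.
    """
    cuts: list[int] = []
    for s, e in strand_ranges:
        idx = (profile.positions >= s) & (profile.positions <= e) & ~np.isnan(profile.mean_dev)
        if not idx.any():
            raise ValueError(f"strand range {s}-{e}: no covered positions in profile")
        sub_pos = profile.positions[idx]
        sub_dev = profile.mean_dev[idx]
        cuts.append(int(sub_pos[int(np.argmin(sub_dev))]))
    cuts.sort()
    if n_segments is not None and n_segments > len(cuts):
        raise ValueError(f"requested {n_segments} segments but only {len(cuts)} strand ranges")
    last_cov = int(profile.positions[~np.isnan(profile.mean_dev)].max())
    bounds = cuts + [last_cov + 1]
    raw = [(bounds[i], bounds[i + 1] - 1) for i in range(len(cuts))]
    if n_segments is not None and n_segments < len(raw):
        head = raw[: n_segments - 1]
        tail = (raw[n_segments - 1][0], raw[-1][1])
        raw = head + [tail]
    segments = [Segment(f"seg{i + 1}", [r]) for i, r in enumerate(raw)]
    if groups:
        grouped = []
        used: set[int] = set()
        for gi, g in enumerate(groups):
            rs = sorted(r for i in g for r in segments[i].ranges)
            grouped.append(Segment(f"grp{gi + 1}", rs))
            used |= set(g)
        grouped.extend(s for i, s in enumerate(segments) if i not in used)
        segments = sorted(grouped, key=lambda s: s.ranges[0][0])
    first = int(profile.positions[~np.isnan(profile.mean_dev)].min())
    const = [(first, cuts[0] - 1)] if cuts[0] > first else []
    scheme = SegmentationScheme(reference_id, segments, constant_ranges=const or None)
    scheme.validate()
    return scheme


# ---------------------------------------------------------------------------
# PSSM
# ---------------------------------------------------------------------------

@dataclass
class PSSM:
    """Position-specific scoring matrix: log2 odds (bits) over the 20
    standard amino acids, columns indexed by position within the fragment."""

    scores: np.ndarray  # (L, 20)
    background: np.ndarray  # (20,)

    def score(self, pos: int, aa: str) -> float:
        return float(self.scores[pos, AA1.index(aa)])

    def argmax(self, pos: int) -> str:
        return AA1[int(np.argmax(self.scores[pos]))]

    def __len__(self) -> int:
        return len(self.scores)


def build_pssm(
    sequences: list[str],
    background: np.ndarray | None = None,
    pseudocount: float = 1.0,
) -> PSSM:
    """Log-odds PSSM with background-proportional pseudocounts:

        score(pos, aa) = log2( ((count + pc * bg_aa) / (N + pc)) / bg_aa )

    With Σ bg = 1 the implied column distribution renormalizes exactly, so a
    single-sequence column is finite everywhere.
    """
    if not sequences:
        raise ValueError("build_pssm needs at least one sequence")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise ValueError("sequences differ in length")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    if bg.shape != (20,) or not math.isclose(float(bg.sum()), 1.0, rel_tol=1e-6):
        raise ValueError("background must be 20 frequencies summing to 1")
    counts = np.zeros((L, 20))
    for s in sequences:
        for i, aa in enumerate(s):
            if aa in AA1:
                counts[i, AA1.index(aa)] += 1
    n = np.array([[len(sequences)]] * L, float)
    freq = (counts + pseudocount * bg) / (n + pseudocount)
    return PSSM(scores=np.log2(freq / bg), background=bg.copy())


# ---------------------------------------------------------------------------
# fragments and the conformation DB
# ---------------------------------------------------------------------------

@dataclass
class IncomingLink:
    """Peptide-link geometry from the residue preceding a fragment range in
    its source structure; used at assembly junctions."""

    d_c_n: float
    a_ca_c_n: float
    a_c_n_ca: float
    psi_prev: float
    omega_prev: float


@dataclass
class Fragment:
    source_id: str
    segment_name: str
    ranges: list[tuple[int, int]]
    range_residues: list[list[InternalResidue]]
    range_positions: list[list[int | None]]  # reference position per residue; None = insertion
    range_incoming: list[IncomingLink | None]
    pssm_slice: PSSM | None = None

    @property
    def sequence(self) -> str:
        return "".join(r.aa for rr in self.range_residues for r in rr)

    @property
    def length_profile(self) -> tuple[int, ...]:
        return tuple(len(rr) for rr in self.range_residues)

    def __len__(self) -> int:
        return sum(self.length_profile)

    def range_ca(self, i: int) -> np.ndarray:
        """CA coordinates of range ``i`` rebuilt in a canonical local frame."""
        return from_internal(self.range_residues[i]).ca_coords()


def fragment_rmsd(a: Fragment, b: Fragment) -> float:
    """Local CA RMSD between two same-length fragments: each range is
    superposed independently; ranges combine as a length-weighted RMS."""
    if a.length_profile != b.length_profile:
        raise ValueError("fragment RMSD undefined for different length profiles")
    ss = 0.0
    n = 0
    for i in range(len(a.ranges)):
        ca, cb = a.range_ca(i), b.range_ca(i)
        if len(ca) < 3:
            d = ca - cb  # too short to superpose; compare in build frame
            r = math.sqrt((d * d).sum() / len(ca))
        else:
            _, _, r = superpose(ca, cb)
        ss += r * r * len(ca)
        n += len(ca)
    return math.sqrt(ss / n)


@dataclass
class ConformationDB:
    scheme: SegmentationScheme
    fragments: dict[str, list[Fragment]]  # sampled segments
    constant: dict[str, list[Fragment]]  # unsampled blocks, reference fragment first
    reference_id: str
    anchor: np.ndarray  # (3,3) N/CA/C frame of the first assembled residue

    @property
    def segment_names(self) -> list[str]:
        return [s.name for s in self.scheme.segments]

    def block_order(self) -> list[tuple[str, int]]:
        """All (segment_name, range_index) blocks sorted by reference start,
        across sampled and constant segments."""
        blocks = []
        for name, frs in list(self.fragments.items()) + list(self.constant.items()):
            for ri, rng in enumerate(frs[0].ranges):
                blocks.append((rng[0], name, ri))
        blocks.sort()
        return [(name, ri) for _, name, ri in blocks]

    def fragment_for(self, name: str, index: int) -> Fragment:
        if name in self.fragments:
            return self.fragments[name][index]
        return self.constant[name][index]


def _slice_fragment(
    member: BackboneStructure,
    internal: list[InternalResidue],
    inv: dict[int, int],
    seg_name: str,
    ranges: list[tuple[int, int]],
) -> Fragment | None:
    """Cut one member's internal coordinates along reference ranges;
    None if the member does not cover every range boundary."""
    rres: list[list[InternalResidue]] = []
    rpos: list[list[int | None]] = []
    rinc: list[IncomingLink | None] = []
    ref_of = member.ref_map or {}
    for s, e in ranges:
        if s not in inv or e not in inv:
            return None
        i0, i1 = inv[s], inv[e]
        if i1 < i0:
            return None
        rres.append([internal[i - 1] for i in range(i0, i1 + 1)])
        rpos.append([ref_of.get(i) for i in range(i0, i1 + 1)])
        if i0 > 1:
            prev = internal[i0 - 2]
            rinc.append(
                IncomingLink(prev.d_c_n, prev.a_ca_c_n, prev.a_c_n_ca, prev.psi, prev.omega)
            )
        else:
            rinc.append(None)
    return Fragment(member.id, seg_name, list(ranges), rres, rpos, rinc)


def constant_blocks(scheme: SegmentationScheme, reference_length: int) -> list[tuple[int, int]]:
    """Contiguous reference ranges not claimed by any sampled segment."""
    if scheme.constant_ranges is not None:
        return list(scheme.constant_ranges)
    sampled = scheme.sampled_positions()
    blocks: list[tuple[int, int]] = []
    start = None
    for p in range(1, reference_length + 1):
        if p not in sampled:
            if start is None:
                start = p
        elif start is not None:
            blocks.append((start, p - 1))
            start = None
    if start is not None:
        blocks.append((start, reference_length))
    return blocks


def extract_fragments(
    aligned: list[BackboneStructure],
    reference: BackboneStructure,
    scheme: SegmentationScheme,
    conf_radius: float = 1.5,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
) -> ConformationDB:
    """Build the conformation database.

    Each member contributes one Fragment per segment it fully covers.  A
    fragment's PSSM is conformation-dependent: built only from the sequences
    of fragments (same length profile) within ``conf_radius`` Å local CA RMSD
    of it — including itself, so every column is defined.  Constant blocks
    are stored per member as unsampled segments, the reference's copy first.
    """
    scheme.validate()
    ref_aligned = next((m for m in aligned if m.id == reference.id), None)
    if ref_aligned is None:
        raise ValueError("aligned family must include the reference structure")
    internals = {m.id: to_internal(m) for m in aligned}
    invs = {m.id: m.inv_ref_map() for m in aligned}

    fragments: dict[str, list[Fragment]] = {}
    for seg in scheme.segments:
        frs = []
        for m in aligned:
            fr = _slice_fragment(m, internals[m.id], invs[m.id], seg.name, seg.ranges)
            if fr is not None:
                frs.append(fr)
        if not frs:
            raise ValueError(f"segment {seg.name}: no extractable fragments")
        frs.sort(key=lambda f: f.source_id)
        fragments[seg.name] = frs

    constant: dict[str, list[Fragment]] = {}
    for bi, rng in enumerate(constant_blocks(scheme, len(reference))):
        name = f"__const_{bi}"
        frs = []
        for m in aligned:
            fr = _slice_fragment(m, internals[m.id], invs[m.id], name, [rng])
            if fr is not None:
                frs.append(fr)
        frs.sort(key=lambda f: (f.source_id != reference.id, f.source_id))
        if not frs or frs[0].source_id != reference.id:
            raise ValueError(f"constant block {rng}: reference does not cover it")
        constant[name] = frs

    for group in list(fragments.values()) + list(constant.values()):
        _attach_pssms(group, conf_radius, pseudocount, background)

    first_pos = min(rng[0] for seg in scheme.segments for rng in seg.ranges)
    for blocks in constant.values():
        first_pos = min(first_pos, blocks[0].ranges[0][0])
    inv_ref = invs[reference.id]
    r0 = ref_aligned.residues[inv_ref[first_pos] - 1]
    anchor = np.array([r0.atom("N"), r0.atom("CA"), r0.atom("C")])
    return ConformationDB(scheme, fragments, constant, reference.id, anchor)


def _attach_pssms(frs: list[Fragment], radius: float, pseudocount: float, background) -> None:
    by_profile: dict[tuple, list[Fragment]] = {}
    for f in frs:
        by_profile.setdefault(f.length_profile, []).append(f)
    for group in by_profile.values():
        n = len(group)
        dm = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dm[i, j] = dm[j, i] = fragment_rmsd(group[i], group[j])
        for i, f in enumerate(group):
            neighbours = [group[j].sequence for j in range(n) if dm[i, j] <= radius]
            f.pssm_slice = build_pssm(neighbours, background=background, pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# serialization (versioned JSON-lines; arrays inlined as JSON numbers so the
# round trip is byte-exact)
# ---------------------------------------------------------------------------

_IC_FIELDS = ("phi", "psi", "omega", "d_n_ca", "d_ca_c", "d_c_n", "a_n_ca_c", "a_ca_c_n", "a_c_n_ca")


def _fragment_to_record(f: Fragment, sampled: bool) -> dict:
    rec = {
        "segment": f.segment_name,
        "source_id": f.source_id,
        "sampled": sampled,
        "ranges": [list(r) for r in f.ranges],
        "range_lengths": list(f.length_profile),
        "aa": f.sequence,
        "positions": [p for rp in f.range_positions for p in rp],
        "incoming": [
            None
            if inc is None
            else [inc.d_c_n, inc.a_ca_c_n, inc.a_c_n_ca, inc.psi_prev, inc.omega_prev]
            for inc in f.range_incoming
        ],
    }
    flat = [r for rr in f.range_residues for r in rr]
    for name in _IC_FIELDS:
        rec[name] = [getattr(r, name) for r in flat]
    if f.pssm_slice is not None:
        rec["pssm"] = {
            "scores": f.pssm_slice.scores.tolist(),
            "background": f.pssm_slice.background.tolist(),
        }
    return rec


def _fragment_from_record(rec: dict) -> tuple[Fragment, bool]:
    lens = rec["range_lengths"]
    seq = rec["aa"]
    flat = []
    for i in range(len(seq)):
        flat.append(
            InternalResidue(
                aa=seq[i], **{name: float(rec[name][i]) for name in _IC_FIELDS}
            )
        )
    rres, rpos = [], []
    off = 0
    for ln in lens:
        rres.append(flat[off : off + ln])
        rpos.append(rec["positions"][off : off + ln])
        off += ln
    rinc = [None if v is None else IncomingLink(*v) for v in rec["incoming"]]
    pssm = None
    if "pssm" in rec:
        pssm = PSSM(np.array(rec["pssm"]["scores"]), np.array(rec["pssm"]["background"]))
    f = Fragment(
        rec["source_id"], rec["segment"], [tuple(r) for r in rec["ranges"]],
        rres, rpos, rinc, pssm_slice=pssm,
    )
    return f, bool(rec["sampled"])


def save_db(db: ConformationDB, path) -> None:
    header = {
        "format": DB_FORMAT,
        "version": DB_VERSION,
        "reference_id": db.reference_id,
        "anchor": db.anchor.tolist(),
        "scheme": db.scheme.to_dict(),
    }
    with open(path, "w") as fh:
        fh.write(json.dumps(header) + "\n")
        for name in db.segment_names:
            for f in db.fragments[name]:
                fh.write(json.dumps(_fragment_to_record(f, True)) + "\n")
        for name in sorted(db.constant):
            for f in db.constant[name]:
                fh.write(json.dumps(_fragment_to_record(f, False)) + "\n")


def load_db(path) -> ConformationDB:
    with open(path) as fh:
        header = json.loads(fh.readline())
        if header.get("format") != DB_FORMAT:
            raise ValueError(f"{path}: not a {DB_FORMAT} file")
        if header.get("version") != DB_VERSION:
            raise ValueError(f"{path}: unsupported version {header.get('version')}")
        scheme = SegmentationScheme.from_dict(header["scheme"])
        fragments: dict[str, list[Fragment]] = {}
        constant: dict[str, list[Fragment]] = {}
        for line in fh:
            if not line.strip():
                continue
            f, sampled = _fragment_from_record(json.loads(line))
            (fragments if sampled else constant).setdefault(f.segment_name, []).append(f)
    return ConformationDB(
        scheme, fragments, constant, header["reference_id"], np.array(header["anchor"])
    )
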