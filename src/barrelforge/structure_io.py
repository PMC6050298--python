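"""Backbone structures: PDB I/O, internal-coordinate extraction and rebuild.

A chain is represented at two equivalent levels:

* Cartesian — :class:`BackboneStructure`, ordered N/CA/C(/O/CB) coordinates;
* internal — a list of :class:`InternalResidue`, per-residue (phi, psi, omega)
  torsions plus the *actual* bond lengths and angles of the source structure.

Storing actual rather than idealized covalent geometry makes
``from_internal(to_internal(s))`` an exact inverse, which is the correctness
oracle for fragment assembly: reassembling all fragments of one source must
reproduce that source bit-for-bit (to numerical precision).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .geometry import GeometryError, bond_angle, dihedral, place_atom

logger = logging.getLogger(__name__)

UNDEF = math.nan  # sentinel for undefined torsions / terminal link geometry

# idealized covalent geometry, used only where source geometry is unavailable
IDEAL_N_CA = 1.458
IDEAL_CA_C = 1.525
IDEAL_C_N = 1.329
IDEAL_N_CA_C = 111.0
IDEAL_CA_C_N = 116.6
IDEAL_C_N_CA = 121.7
IDEAL_C_O = 1.231
IDEAL_CA_C_O = 120.8
IDEAL_CA_CB = 1.521
IDEAL_N_CA_CB = 110.4
# improper torsion C-N-CA-CB fixing L-chirality of the CB position
IDEAL_CB_TORSION = -122.6

AA1 = "ACDEFGHIKLMNPQRSTVWY"


class StructureError(ValueError):
    """Invalid or unusable backbone structure."""


@dataclass
class BackboneResidue:
    """One residue's backbone atoms.

    coords maps atom name (N, CA, C, O, CB) to a length-3 float array in Å.
    """

    res_index: int
    aa: str
    coords: dict[str, np.ndarray]

    def atom(self, name: str) -> np.ndarray:
        return self.coords[name]

    def rep_atom(self) -> np.ndarray:
        """Representative sidechain atom: CB, or CA for glycine / CB-less."""
        if self.aa != "G" and "CB" in self.coords:
            return self.coords["CB"]
        return self.coords["CA"]


@dataclass
class BackboneStructure:
    """An ordered single-chain backbone.

    ref_map maps res_index -> reference-numbering position (injective);
    chain_breaks holds res_index values after which the chain is broken.
    """

    id: str
    residues: list[BackboneResidue]
    ref_map: dict[int, int] | None = None
    chain_breaks: set[int] = field(default_factory=set)
    author_ids: list[int] | None = None

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        return np.array([r.atom("CA") for r in self.residues])

    def backbone_coords(self, atoms=("N", "CA", "C", "O")) -> np.ndarray:
        out = []
        for r in self.residues:
            for a in atoms:
                if a in r.coords:
                    out.append(r.coords[a])
        return np.array(out)

    def inv_ref_map(self) -> dict[int, int]:
        if self.ref_map is None:
            raise StructureError(f"{self.id}: no reference mapping")
        return {v: k for k, v in self.ref_map.items()}

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "BackboneStructure":
        res = [
            BackboneResidue(r.res_index, r.aa, {k: rotation @ v + translation for k, v in r.coords.items()})
            for r in self.residues
        ]
        return replace(self, residues=res)

    def validate(self) -> None:
        prev = None
        for r in self.residues:
            for name in ("N", "CA", "C"):
                if name not in r.coords:
                    raise StructureError(f"{self.id} residue {r.res_index}: missing {name}")
                if not np.all(np.isfinite(r.coords[name])):
                    raise StructureError(f"{self.id} residue {r.res_index}: non-finite {name}")
            for name, d in (("N", _dist(r.atom("CA"), r.atom("N"))), ("C", _dist(r.atom("CA"), r.atom("C")))):
                if not 1.2 < d < 1.8:
                    raise StructureError(
                        f"{self.id} residue {r.res_index}: CA-{name} distance {d:.2f} Å out of range"
                    )
            if prev is not None and prev.res_index not in self.chain_breaks:
                d = _dist(prev.atom("C"), r.atom("N"))
                if not 1.2 < d < 1.5:
                    raise StructureError(
                        f"{self.id}: broken peptide bond {prev.res_index}->{r.res_index} ({d:.2f} Å)"
                    )
            if prev is not None and r.res_index <= prev.res_index:
                raise StructureError(f"{self.id}: residues not strictly ordered at {r.res_index}")
            prev = r
        if self.ref_map is not None and len(set(self.ref_map.values())) != len(self.ref_map):
            raise StructureError(f"{self.id}: ref_map not injective")


@dataclass
class InternalResidue:
    """Internal coordinates of one residue and its link to the next.

    phi/psi/omega in degrees, (-180, 180]; NaN marks undefined (phi of the
    first residue, psi/omega and link geometry of the last).  d_c_n,
    a_ca_c_n and a_c_n_ca describe the peptide link to the following residue.
    """

    aa: str
    phi: float
    psi: float
    omega: float
    d_n_ca: float
    d_ca_c: float
    d_c_n: float
    a_n_ca_c: float
    a_ca_c_n: float
    a_c_n_ca: float


def _dist(a, b) -> float:
    d = np.asarray(a, float) - np.asarray(b, float)
    return float(math.sqrt((d * d).sum()))


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def read_pdb(path, chain: str | None = None, structure_id: str | None = None) -> BackboneStructure:
    """Read one chain of a PDB file into a BackboneStructure.

    Only the first model is used; altloc '' or 'A' kept.  Residues missing a
    mandatory backbone atom (N, CA, C) are excluded with a warning; a file
    with zero complete residues is an error.  Author residue numbers are
    retained in ``author_ids`` (insertion codes flattened into the sequential
    1-based res_index).
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    model = st[0]
    if len(model) == 0:
        raise StructureError(f"{path}: no chains")
    ch = None
    if chain is None:
        ch = model[0]
    else:
        for c in model:
            if c.name == chain:
                ch = c
                break
        if ch is None:
            raise StructureError(f"{path}: chain {chain!r} not found")

    residues: list[BackboneResidue] = []
    author_ids: list[int] = []
    n_skipped = 0
    for res in ch:
        info = gemmi.find_tabulated_residue(res.name)
        if info is None or not info.is_amino_acid():  # waters/ligands skipped silently
            continue
        coords: dict[str, np.ndarray] = {}
        for atom in res:
            if atom.altloc.strip("\x00 ") not in ("", "A"):
                continue
            if atom.name in ("N", "CA", "C", "O", "CB") and atom.name not in coords:
                coords[atom.name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
        if any(a not in coords for a in ("N", "CA", "C")):
            n_skipped += 1
            logger.warning("%s %s%s: incomplete backbone, residue excluded", path, res.name, res.seqid.num)
            continue
        one = info.one_letter_code.upper()
        if one not in AA1:
            one = "X"
        residues.append(BackboneResidue(len(residues) + 1, one, coords))
        author_ids.append(res.seqid.num)
    if not residues:
        raise StructureError(f"{path}: no parsable residues ({n_skipped} incomplete)")

    # flag breaks where the peptide bond is absent
    breaks: set[int] = set()
    for a, b in zip(residues, residues[1:]):
        if not 1.2 < _dist(a.atom("C"), b.atom("N")) < 1.5:
            breaks.add(a.res_index)
    sid = structure_id
    if sid is None:
        sid = st.name or str(path)
    return BackboneStructure(id=sid, residues=residues, chain_breaks=breaks, author_ids=author_ids)


def write_pdb(s: BackboneStructure, path) -> None:
    """Write ATOM records (8.3 coordinate fields, element column set)."""
    if not s.residues:
        raise StructureError("refusing to write an empty structure")
    st = gemmi.Structure()
    st.name = s.id[:40]
    model = gemmi.Model("1")
    ch = gemmi.Chain("A")
    three = {o: t for t, o in _THREE_TO_ONE.items()}
    for r in s.residues:
        res = gemmi.Residue()
        res.name = three.get(r.aa, "ALA")
        res.seqid = gemmi.SeqId(r.res_index, " ")
        for name in ("N", "CA", "C", "O", "CB"):
            if name not in r.coords:
                continue
            at = gemmi.Atom()
            at.name = name
            x, y, z = (float(v) for v in r.coords[name])
            at.pos = gemmi.Position(x, y, z)
            at.element = gemmi.Element(name[0])
            at.occ = 1.0
            at.b_iso = 0.0
            res.add_atom(at)
        ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)


_THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}


# ---------------------------------------------------------------------------
# internal <-> Cartesian
# ---------------------------------------------------------------------------

def to_internal(s: BackboneStructure) -> list[InternalResidue]:
    """Extract per-residue (phi, psi, omega) and actual covalent geometry.

    phi of the first residue and psi/omega/link fields of the last are NaN
    sentinels.  A chain break inside the converted span is an error.
    """
    if len(s.residues) < 2:
        raise StructureError("need at least 2 residues for internal coordinates")
    if any(b < s.residues[-1].res_index for b in s.chain_breaks if b >= s.residues[0].res_index):
        raise StructureError(f"{s.id}: chain break inside converted span")
    out: list[InternalResidue] = []
    res = s.residues
    for i, r in enumerate(res):
        N, CA, C = r.atom("N"), r.atom("CA"), r.atom("C")
        nxt = res[i + 1] if i + 1 < len(res) else None
        prv = res[i - 1] if i > 0 else None
        phi = dihedral(prv.atom("C"), N, CA, C) if prv is not None else UNDEF
        if nxt is not None:
            Nn, CAn = nxt.atom("N"), nxt.atom("CA")
            psi = dihedral(N, CA, C, Nn)
            omega = dihedral(CA, C, Nn, CAn)
            d_c_n = _dist(C, Nn)
            a_ca_c_n = bond_angle(CA, C, Nn)
            a_c_n_ca = bond_angle(C, Nn, CAn)
        else:
            psi = omega = d_c_n = a_ca_c_n = a_c_n_ca = UNDEF
        out.append(
            InternalResidue(
                aa=r.aa, phi=phi, psi=psi, omega=omega,
                d_n_ca=_dist(N, CA), d_ca_c=_dist(CA, C), d_c_n=d_c_n,
                a_n_ca_c=bond_angle(N, CA, C), a_ca_c_n=a_ca_c_n, a_c_n_ca=a_c_n_ca,
            )
        )
    return out


def default_anchor(ic0: InternalResidue) -> np.ndarray:
    """Canonical frame for the first residue: N at origin, CA on +x, C in xy."""
    n = (0.0, 0.0, 0.0)
    ca = (ic0.d_n_ca, 0.0, 0.0)
    th = math.radians(ic0.a_n_ca_c)
    c = (ic0.d_n_ca - ic0.d_ca_c * math.cos(th), ic0.d_ca_c * math.sin(th), 0.0)
    return np.array([n, ca, c])


def nerf_backbone(ic: list[InternalResidue], anchor: np.ndarray) -> list[tuple]:
    """Sequentially place N/CA/C for every residue; returns [(N, CA, C), ...]
    as float tuples.  The anchor supplies the first residue's three atoms."""
    a = np.asarray(anchor, float)
    N = (float(a[0, 0]), float(a[0, 1]), float(a[0, 2]))
    CA = (float(a[1, 0]), float(a[1, 1]), float(a[1, 2]))
    C = (float(a[2, 0]), float(a[2, 1]), float(a[2, 2]))
    chain = [(N, CA, C)]
    for i in range(1, len(ic)):
        prev, cur = ic[i - 1], ic[i]
        for name, v in (("psi", prev.psi), ("omega", prev.omega), ("d_c_n", prev.d_c_n),
                        ("phi", cur.phi)):
            if math.isnan(v):
                raise StructureError(f"residue {i}: undefined {name} needed for reconstruction")
        Nn = place_atom(N, CA, C, prev.d_c_n, prev.a_ca_c_n, prev.psi)
        CAn = place_atom(CA, C, Nn, cur.d_n_ca, prev.a_c_n_ca, prev.omega)
        Cn = place_atom(C, Nn, CAn, cur.d_ca_c, cur.a_n_ca_c, cur.phi)
        N, CA, C = Nn, CAn, Cn
        chain.append((N, CA, C))
    return chain


def from_internal(
    ic: list[InternalResidue],
    anchor: np.ndarray | None = None,
    structure_id: str = "rebuilt",
) -> BackboneStructure:
    """Rebuild a Cartesian backbone from internal coordinates.

    anchor is a (3, 3) array giving N, CA, C of the first residue; defaults
    to a canonical frame.  O is placed from ideal sp2 geometry (anti to the
    next N, i.e. torsion N-CA-C-O = psi + 180; 0 for the final residue) and
    CB from ideal tetrahedral geometry for non-glycine residues, so these
    derived atoms are deterministic functions of the backbone.
    """
    if not ic:
        raise StructureError("empty internal-coordinate list")
    if anchor is None:
        anchor = default_anchor(ic[0])
    chain = nerf_backbone(ic, anchor)
    residues: list[BackboneResidue] = []
    for i, ((N, CA, C), r) in enumerate(zip(chain, ic)):
        coords = {"N": np.array(N), "CA": np.array(CA), "C": np.array(C)}
        o_torsion = (r.psi + 180.0) if not math.isnan(r.psi) else 0.0
        coords["O"] = np.array(place_atom(N, CA, C, IDEAL_C_O, IDEAL_CA_C_O, o_torsion))
        if r.aa != "G":
            coords["CB"] = np.array(place_atom(C, N, CA, IDEAL_CA_CB, IDEAL_N_CA_CB, IDEAL_CB_TORSION))
        residues.append(BackboneResidue(i + 1, r.aa, coords))
    return BackboneStructure(id=structure_id, residues=residues)
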