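"""Molecular data model, PDB I/O, contact geometry and rigid superposition.

The model is a light three-level hierarchy (Structure -> Subunit -> Residue
-> Atom) holding heavy-atom coordinates in angstroms. Contacts between two
subunits are defined on heavy atoms with a strict distance cutoff (default
6 A): two residues are interface residues if any heavy-atom pair, one atom
from each residue, is closer than the cutoff.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: residue key: (chain_id, seq_id-with-insertion-code)
ResidueKey = tuple[str, str]

CONTACT_CUTOFF = 6.0

#: parent mapping for common modified residues; unmapped non-standard
#: residues are dropped with a warning.
NONSTANDARD_PARENTS = {
    "MSE": "MET",
    "SEC": "CYS",
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
    "HYP": "PRO",
    "CSO": "CYS",
    "KCX": "LYS",
    "MLY": "LYS",
}

STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

_WATERS = frozenset({"HOH", "WAT", "DOD", "H2O"})

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class PDBParseError(ValueError):
    """Raised when PDB text cannot be parsed; carries the offending line number."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: tuple[float, float, float]
    is_heavy: bool

    def __post_init__(self):
        if not all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinate for atom {self.name}")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coord, dtype=float)


@dataclass
class Residue:
    chain_id: str
    seq_id: str
    res_type: str
    atoms: list[Atom]

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_id)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def ca(self) -> Atom | None:
        return self.atom("CA")


@dataclass
class Subunit:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self):
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError(f"duplicate residue keys in subunit {self.id}")

    def residue(self, key: ResidueKey) -> Residue:
        for r in self.residues:
            if r.key == key:
                return r
        raise KeyError(key)

    def heavy_coords(self) -> tuple[np.ndarray, list[tuple[ResidueKey, int]]]:
        """All heavy-atom coordinates with (residue key, atom index) owners."""
        coords, owners = [], []
        for r in self.residues:
            for i, a in enumerate(r.atoms):
                if a.is_heavy:
                    coords.append(a.coord)
                    owners.append((r.key, i))
        return np.asarray(coords, dtype=float).reshape(-1, 3), owners


@dataclass
class Structure:
    subunits: list[Subunit]

    def subunit(self, sid: str) -> Subunit:
        for s in self.subunits:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def residues(self):
        for s in self.subunits:
            yield from s.residues

    def residue(self, key: ResidueKey) -> Residue:
        for s in self.subunits:
            if s.id == key[0]:
                return s.residue(key)
        raise KeyError(key)


@dataclass(frozen=True, order=True)
class ContactPair:
    res_a: ResidueKey
    res_b: ResidueKey
    min_dist: float


def _validate_pdb_lines(pdb_text: str) -> None:
    """Fail fast with a line number on records gemmi would silently mangle."""
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: truncated {rec} record ({len(line)} chars, need >= 54)")
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
        except ValueError:
            raise PDBParseError(f"line {lineno}: unparseable coordinates in {rec} record") from None


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties resolved toward altloc 'A' (blank sorts first)
    return max(atoms, key=lambda a: (a.occ, -ord(a.altloc or "A")))


def read_structure(pdb_text: str, chain_selection: set[str] | None = None) -> Structure:
    """Parse PDB text into a Structure with one Subunit per selected chain.

    Hydrogens are retained but flagged; waters and HETATM ligands are
    excluded; modified residues with a known parent (e.g. MSE) are mapped to
    it; the first MODEL is used when several are present; alternate
    conformers are resolved to the highest-occupancy one.
    """
    _validate_pdb_lines(pdb_text)
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise PDBParseError("no models found in PDB text")
    model = st[0]
    present = {ch.name for ch in model}
    if chain_selection is not None:
        missing = set(chain_selection) - present
        if missing:
            raise ValueError(f"chains not present in structure: {sorted(missing)}")
        if not chain_selection:
            raise ValueError("empty chain selection")
        selected = chain_selection
    else:
        selected = present

    subunits = []
    for chain in model:
        if chain.name not in selected:
            continue
        residues = []
        for res in chain:
            name = res.name.strip()
            if name in _WATERS:
                continue
            res_type = name
            if name not in STANDARD_RESIDUES:
                if name in NONSTANDARD_PARENTS:
                    res_type = NONSTANDARD_PARENTS[name]
                else:
                    logger.warning("excluding unmapped non-standard residue %s %s%s",
                                   name, chain.name, res.seqid)
                    continue
            seq_id = f"{res.seqid.num}{(res.seqid.icode or '').strip()}"
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                by_name.setdefault(atom.name, []).append(atom)
            atoms = []
            for aname, group in by_name.items():
                g = _pick_altloc(group)
                elem = g.element.name.upper()
                atoms.append(Atom(
                    name=aname,
                    element=elem,
                    coord=(g.pos.x, g.pos.y, g.pos.z),
                    is_heavy=elem not in ("H", "D"),
                ))
            if not any(a.is_heavy for a in atoms):
                continue
            residues.append(Residue(chain.name, seq_id, res_type, atoms))
        if residues:
            subunits.append(Subunit(chain.name, residues))
    if not subunits:
        raise ValueError("no protein residues found for the selected chains")
    return Structure(subunits)


def write_pdb(structure: Structure) -> str:
    """Serialize to minimal PDB text (ATOM/TER/END records, 3-decimal coords)."""
    lines = []
    serial = 1
    for sub in structure.subunits:
        for res in sub.residues:
            # split trailing insertion code back out of the seq id
            seq = res.seq_id
            icode = " "
            if seq and seq[-1].isalpha():
                icode = seq[-1]
                seq = seq[:-1]
            for atom in res.atoms:
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                x, y, z = atom.coord
                lines.append(
                    f"ATOM  {serial:>5d} {name}{'':1s}{res.res_type:>3s} {sub.id:1s}"
                    f"{int(seq):>4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:>5d}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def _pairwise_min_dists(sub_a: Subunit, sub_b: Subunit, cutoff: float,
                        heavy_only: bool = True, inclusive: bool = False) -> dict:
    """Residue-pair -> min inter-atomic distance, for pairs within cutoff."""
    def collect(sub):
        coords, owners = [], []
        for r in sub.residues:
            for a in r.atoms:
                if heavy_only and not a.is_heavy:
                    continue
                coords.append(a.coord)
                owners.append(r.key)
        return np.asarray(coords, dtype=float).reshape(-1, 3), owners

    ca, oa = collect(sub_a)
    cb, ob = collect(sub_b)
    if len(ca) == 0 or len(cb) == 0:
        return {}
    tree_a, tree_b = cKDTree(ca), cKDTree(cb)
    dmat = tree_a.sparse_distance_matrix(tree_b, max_distance=cutoff, output_type="coo_matrix")
    best: dict[tuple, float] = {}
    for i, j, d in zip(dmat.row, dmat.col, dmat.data):
        ok = d <= cutoff if inclusive else d < cutoff
        if not ok:
            continue
        key = (oa[i], ob[j])
        if d < best.get(key, np.inf):
            best[key] = d
    return best


def heavy_atom_contacts(sub_a: Subunit, sub_b: Subunit, cutoff: float = CONTACT_CUTOFF) -> set[ContactPair]:
    """Residue pairs with some heavy-atom pair strictly closer than cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not sub_a.residues or not sub_b.residues:
        raise ValueError("both subunits must be non-empty")
    best = _pairwise_min_dists(sub_a, sub_b, cutoff, heavy_only=True, inclusive=False)
    return {ContactPair(ka, kb, d) for (ka, kb), d in best.items()}


def interface_residues(sub_a: Subunit, sub_b: Subunit, cutoff: float = CONTACT_CUTOFF
                       ) -> tuple[set[ResidueKey], set[ResidueKey]]:
    """Projections of the heavy-atom contact-pair set onto each side."""
    contacts = heavy_atom_contacts(sub_a, sub_b, cutoff)
    return {c.res_a for c in contacts}, {c.res_b for c in contacts}


def superpose(coords_ref: np.ndarray, coords_mov: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch) of mov onto ref.

    Returns (rotation, translation, rmsd) such that
    ``coords_mov @ rotation.T + translation`` best matches ``coords_ref``,
    with det(rotation) = +1.
    """
    ref = np.asarray(coords_ref, dtype=float)
    mov = np.asarray(coords_mov, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("coordinate arrays must be matched N x 3")
    n = ref.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 points")
    cr, cm = ref.mean(axis=0), mov.mean(axis=0)
    p, q = ref - cr, mov - cm
    if np.linalg.matrix_rank(np.vstack([p, q]), tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) configuration")
    h = q.T @ p
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cr - rot @ cm
    diff = (mov @ rot.T + trans) - ref
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return rot, trans, rmsd


def contacts_to_tsv(contacts: set[ContactPair]) -> str:
    lines = ["chain_a\tresid_a\tchain_b\tresid_b\tmin_dist"]
    for c in sorted(contacts):
        lines.append(f"{c.res_a[0]}\t{c.res_a[1]}\t{c.res_b[0]}\t{c.res_b[1]}\t{c.min_dist:.3f}")
    return "\n".join(lines) + "\n"
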