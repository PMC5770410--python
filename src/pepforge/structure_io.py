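"""Molecular structures: PDB/mol2 I/O, bond inference, ideal peptide builder.

The in-memory container is :class:`MolecularSystem` — a flat atom table plus
residue grouping and an undirected covalent bond set keyed by atom serials.
Internal units are Angstrom and elementary charges; angles are degrees.
Hydrogens are excluded by default everywhere; a flag re-enables them.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from . import _tables, geometry
from .errors import GeometryError, PepforgeError, SelectionError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    serial: int
    name: str
    element: str
    position: np.ndarray          # (3,) Angstrom
    vdw_radius: float             # Angstrom
    partial_charge: float = 0.0   # elementary charges
    residue_index: int = 0        # 0-based internal index

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("atom position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")
        if self.vdw_radius <= 0:
            raise ValueError("vdw radius must be positive")


@dataclass
class Residue:
    index: int                    # 0-based internal index
    name: str                     # 3-letter code
    atom_serials: list[int]
    label: int | None = None      # original PDB resSeq, if any
    nonstandard: bool = False


@dataclass
class MolecularSystem:
    atoms: list[Atom]
    residues: list[Residue]
    bonds: set[tuple[int, int]] = field(default_factory=set)
    chain_id: str = "A"

    def __post_init__(self):
        self.bonds = {_bond_key(a, b) for a, b in self.bonds}
        serials = {a.serial for a in self.atoms}
        for a, b in self.bonds:
            if a == b:
                raise ValueError("self-bond")
            if a not in serials or b not in serials:
                raise ValueError(f"bond endpoint {a, b} not among atoms")

    # -- lookups ----------------------------------------------------------
    @property
    def atom_by_serial(self) -> dict[int, Atom]:
        return {a.serial: a for a in self.atoms}

    def atom(self, residue_index: int, name: str) -> Atom | None:
        for s in self.residues[residue_index].atom_serials:
            a = self.atom_by_serial[s]
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def serial_index(self) -> dict[int, int]:
        return {a.serial: i for i, a in enumerate(self.atoms)}

    def with_coords(self, coords: np.ndarray) -> "MolecularSystem":
        coords = np.asarray(coords, float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, position=coords[i]) for i, a in enumerate(self.atoms)]
        return MolecularSystem(atoms, self.residues, set(self.bonds), self.chain_id)

    def sequence(self) -> str:
        rev = {k: v["one_letter"] for k, v in _tables.residue_templates().items()}
        return "".join(rev.get(r.name, "X") for r in self.residues)


def _bond_key(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a < b else (b, a)


# ---------------------------------------------------------------------------
# Bond inference
# ---------------------------------------------------------------------------

PEPTIDE_BOND_MAX = 1.8  # Angstrom; larger C-N gaps are chain breaks


def infer_bonds(system: MolecularSystem) -> set[tuple[int, int]]:
    """Covalent bonds from residue templates plus inter-residue peptide bonds.

    Standard residues use the bundled bond template (only pairs whose atoms
    are both present); hydrogens attach to the nearest heavy atom of the same
    residue; non-template residues fall back to a covalent-radius distance
    rule.  Consecutive residues are joined C(i)-N(i+1) when the distance is
    below ``PEPTIDE_BOND_MAX``; larger gaps are logged as chain breaks.
    """
    templates = _tables.residue_templates()
    bonds: set[tuple[int, int]] = set()
    lookup = system.atom_by_serial
    for res in system.residues:
        named = {}
        hydrogens = []
        for s in res.atom_serials:
            a = lookup[s]
            if a.element == "H":
                hydrogens.append(s)
            else:
                named[a.name] = s
        tpl = templates.get(res.name)
        if tpl is not None:
            for n1, n2 in tpl["bonds"]:
                if n1 in named and n2 in named:
                    bonds.add(_bond_key(named[n1], named[n2]))
        else:
            heavies = list(named.values())
            for i in range(len(heavies)):
                for j in range(i + 1, len(heavies)):
                    ai, aj = lookup[heavies[i]], lookup[heavies[j]]
                    cutoff = 1.3 * (_tables.COVALENT_RADIUS.get(ai.element, 0.8)
                                    + _tables.COVALENT_RADIUS.get(aj.element, 0.8))
                    if np.linalg.norm(ai.position - aj.position) < cutoff:
                        bonds.add(_bond_key(heavies[i], heavies[j]))
        for hs in hydrogens:
            h = lookup[hs]
            heavies = [s for s in res.atom_serials if lookup[s].element != "H"]
            if heavies:
                nearest = min(heavies, key=lambda s: np.linalg.norm(lookup[s].position - h.position))
                bonds.add(_bond_key(hs, nearest))
    for r1, r2 in zip(system.residues, system.residues[1:]):
        c = system.atom(r1.index, "C")
        n = system.atom(r2.index, "N")
        if c is None or n is None:
            continue
        d = float(np.linalg.norm(c.position - n.position))
        if d < PEPTIDE_BOND_MAX:
            bonds.add(_bond_key(c.serial, n.serial))
        else:
            log.warning("chain break between residues %d and %d (C-N %.2f A)",
                        r1.index, r2.index, d)
    return bonds


# ---------------------------------------------------------------------------
# PDB reading / writing (gemmi-backed)
# ---------------------------------------------------------------------------

def read_pdb(path, chain: str | None = None,
             residue_range: tuple[float, float] | None = None,
             include_hydrogens: bool = False) -> MolecularSystem:
    """Read a single-chain selection from a PDB file.

    Only the first MODEL is used; for alternate locations the highest-
    occupancy conformer is kept.  ``residue_range`` selects an inclusive
    1-based sequential span along the chain; a half-integral end (e.g.
    ``(1, 3.5)``) keeps only the backbone atoms (N, CA, C, O) of the last
    residue.  Partial charges come from the bundled residue tables, van der
    Waals radii from the element table.  CONECT records, when present, are
    merged with template-inferred bonds.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise SelectionError(f"no models in {path}")
    model = st[0]
    names = [ch.name for ch in model]
    if chain is None:
        if len(names) != 1:
            raise SelectionError(f"file has chains {names}; specify one")
        chain = names[0]
    if chain not in names:
        raise SelectionError(f"chain {chain!r} not found; available: {names}")
    gchain = model[chain]

    half_last = False
    lo = hi = None
    if residue_range is not None:
        lo, hi = residue_range
        if float(hi) != int(hi):
            if abs(hi - int(hi) - 0.5) > 1e-9:
                raise SelectionError("residue_range end must be integral or half-integral")
            half_last = True
            hi = int(hi) + 1
        lo, hi = int(lo), int(hi)

    templates = _tables.residue_templates()
    atoms: list[Atom] = []
    residues: list[Residue] = []
    serial = 0
    warned: set[str] = set()
    gres_list = [r for r in gchain if not r.is_water()]
    for pos, gres in enumerate(gres_list, start=1):
        if lo is not None and not (lo <= pos <= hi):
            continue
        backbone_only = half_last and pos == hi
        tpl = templates.get(gres.name)
        if tpl is None and gres.name not in warned:
            warned.add(gres.name)
            log.warning("residue %s has no charge template; charges set to 0", gres.name)
        # highest-occupancy altloc per atom name
        best: dict[str, gemmi.Atom] = {}
        for ga in gres:
            prev = best.get(ga.name)
            if prev is None or ga.occ > prev.occ:
                best[ga.name] = ga
        res_serials: list[int] = []
        ridx = len(residues)
        for ga in gres:
            if best[ga.name] is not ga:
                continue
            el = ga.element.name.capitalize()
            if el == "H" and not include_hydrogens:
                continue
            if backbone_only and ga.name not in ("N", "CA", "C", "O"):
                continue
            charge = 0.0
            if tpl is not None:
                charge = tpl["charges"].get(ga.name, 0.0)
            serial += 1
            atoms.append(Atom(
                serial=serial, name=ga.name, element=el,
                position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                vdw_radius=_tables.vdw_radius(el),
                partial_charge=charge, residue_index=ridx))
            res_serials.append(serial)
        if res_serials:
            residues.append(Residue(index=ridx, name=gres.name,
                                    atom_serials=res_serials,
                                    label=gres.seqid.num,
                                    nonstandard=tpl is None))
    if not atoms:
        raise SelectionError("selection matched no atoms")
    system = MolecularSystem(atoms, residues, set(), chain_id=chain)
    system.bonds = infer_bonds(system)
    system.bonds |= _read_conect(path, system)
    return system


def _read_conect(path, system: MolecularSystem) -> set[tuple[int, int]]:
    """CONECT records mapped onto kept atoms via coordinates are not
    recoverable in general (serials are renumbered); honor them only when the
    original serial set matches ours one-to-one, which holds for files this
    package writes."""
    pairs: set[tuple[int, int]] = set()
    known = set(system.atom_by_serial)
    try:
        with open(path) as fh:
            for line in fh:
                if line.startswith("CONECT"):
                    fields = [line[6:11], line[11:16], line[16:21], line[21:26], line[26:31]]
                    nums = [int(f) for f in fields if f.strip()]
                    if len(nums) >= 2 and all(n in known for n in nums):
                        for other in nums[1:]:
                            if other != nums[0]:
                                pairs.add(_bond_key(nums[0], other))
    except OSError:
        pass
    return pairs


def write_pdb(system: MolecularSystem, path, coordinates: np.ndarray | None = None) -> None:
    """Write a single-model PDB preserving atom order; residues labeled 1..n
    (or the original PDB numbering when it was retained)."""
    if not system.atoms:
        raise PepforgeError("refusing to write an empty system")
    coords = system.coords() if coordinates is None else np.asarray(coordinates, float)
    if coords.shape != (len(system.atoms), 3):
        raise ValueError("coordinate array shape mismatch")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    st = gemmi.Structure()
    st.name = "pepforge"
    model = gemmi.Model("1")
    ch = gemmi.Chain(system.chain_id or "A")
    idx = system.serial_index()
    for res in system.residues:
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.label if res.label is not None else res.index + 1, " ")
        for s in res.atom_serials:
            a = system.atom_by_serial[s]
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            x, y, z = coords[idx[s]]
            ga.pos = gemmi.Position(x, y, z)
            ga.occ = 1.0
            gres.add_atom(ga)
        ch.add_residue(gres)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# TRIPOS mol2 reading
# ---------------------------------------------------------------------------

def read_mol2(path) -> MolecularSystem:
    """Read a TRIPOS mol2 file: atoms, verbatim BOND records, and the charge
    column when present.  A missing BOND section falls back to
    :func:`infer_bonds` with a warning."""
    sections: dict[str, list[str]] = {}
    current = None
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\r\n")
            if line.startswith("@<TRIPOS>"):
                current = line[9:].strip().upper()
                sections[current] = []
            elif current is not None:
                sections[current].append(line)
    if "ATOM" not in sections:
        raise PepforgeError(f"{path}: no @<TRIPOS>ATOM section")

    atoms: list[Atom] = []
    res_map: dict[int, Residue] = {}
    serial_remap: dict[int, int] = {}
    templates = _tables.residue_templates()
    for line in sections["ATOM"]:
        parts = line.split()
        if len(parts) < 6:
            continue
        orig = int(parts[0])
        name = parts[1]
        x, y, z = (float(v) for v in parts[2:5])
        sybyl = parts[5]
        element = sybyl.split(".")[0].capitalize()
        subst_id = int(parts[6]) if len(parts) > 6 else 1
        subst_name = parts[7] if len(parts) > 7 else "LIG"
        charge = float(parts[8]) if len(parts) > 8 else 0.0
        if subst_id not in res_map:
            rname = "".join(c for c in subst_name if not c.isdigit()) or "LIG"
            res_map[subst_id] = Residue(index=len(res_map), name=rname,
                                        atom_serials=[], label=subst_id,
                                        nonstandard=rname not in templates)
        res = res_map[subst_id]
        serial = len(atoms) + 1
        serial_remap[orig] = serial
        atoms.append(Atom(serial=serial, name=name, element=element,
                          position=np.array([x, y, z]),
                          vdw_radius=_tables.vdw_radius(element),
                          partial_charge=charge, residue_index=res.index))
        res.atom_serials.append(serial)

    system = MolecularSystem(atoms, [res_map[k] for k in sorted(res_map)],
                             set(), chain_id="A")
    if "BOND" in sections and any(l.split() for l in sections["BOND"]):
        bonds = set()
        for line in sections["BOND"]:
            parts = line.split()
            if len(parts) >= 3:
                bonds.add(_bond_key(serial_remap[int(parts[1])],
                                    serial_remap[int(parts[2])]))
        system.bonds = bonds
    else:
        log.warning("%s: no BOND records; inferring bonds", path)
        system.bonds = infer_bonds(system)
    return system


# ---------------------------------------------------------------------------
# Ideal-geometry peptide builder
# ---------------------------------------------------------------------------

DEFAULT_PHI = -135.0
DEFAULT_PSI = 135.0
DEFAULT_OMEGA = 180.0

_H_LENGTH = {"C": 1.09, "N": 1.01, "O": 0.96, "S": 1.34}

# sp2 carbons get 3 substituents; everything else follows element valence.
_SP2_CARBONS = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "CD2", "CE1"},
    "ASP": {"CG"}, "ASN": {"CG"}, "GLU": {"CD"}, "GLN": {"CD"}, "ARG": {"CZ"},
}
# explicit hydrogen counts where valence rules are wrong for the pH-7 state
_N_HYDROGENS = {
    ("HIS", "ND1"): 0, ("HIS", "NE2"): 1, ("TRP", "NE1"): 1,
    ("ASN", "ND2"): 2, ("GLN", "NE2"): 2, ("LYS", "NZ"): 3,
    ("ARG", "NE"): 1, ("ARG", "NH1"): 2, ("ARG", "NH2"): 2, ("PRO", "N"): 0,
}
_O_HYDROGENS = {
    ("SER", "OG"): 1, ("THR", "OG1"): 1, ("TYR", "OH"): 1,
}


def _torsion_value(expr, context: dict[str, float]) -> float:
    if isinstance(expr, (int, float)):
        return float(expr)
    s = expr.strip()
    for key in sorted(context, key=len, reverse=True):
        if s.startswith(key):
            rest = s[len(key):].replace(" ", "")
            offset = float(rest) if rest else 0.0
            return context[key] + offset
    raise PepforgeError(f"unresolvable torsion expression {expr!r}")


def build_ideal_peptide(sequence: str,
                        torsions: dict[int, dict[str, float]] | None = None,
                        include_hydrogens: bool = False) -> MolecularSystem:
    """Build a peptide with ideal bond lengths/angles from a 1-letter sequence.

    ``torsions`` maps 1-based residue numbers to per-residue angle overrides,
    e.g. ``{2: {"phi": -60.0, "psi": -45.0}}``.  Accepted keys are ``phi``,
    ``psi``, ``omega`` and ``chi1``..``chi4`` (the latter only for residues
    that define them).  Unspecified backbone angles default to an extended
    chain (phi = -135, psi = 135, omega = 180); chi angles default to the
    template rotamer.  Measured torsions of the output equal the requested
    values to well below 1e-6 degrees (exact up to floating point, since the
    chain is constructed from those internal coordinates).
    """
    torsions = torsions or {}
    one_to_three = _tables.one_letter_map()
    templates = _tables.residue_templates()
    bb = _tables.backbone_geometry()
    L, A = bb["lengths"], bb["angles"]

    res_names = []
    for letter in sequence:
        if letter.upper() not in one_to_three:
            raise PepforgeError(f"unknown amino-acid letter {letter!r}")
        res_names.append(one_to_three[letter.upper()])

    for num, overrides in torsions.items():
        if not 1 <= num <= len(res_names):
            raise PepforgeError(f"torsion override for residue {num} out of range")
        tpl = templates[res_names[num - 1]]
        for key in overrides:
            if key.startswith("chi") and key not in tpl["chi"]:
                raise PepforgeError(
                    f"{res_names[num - 1]} has no {key} (residue {num})")
            if not key.startswith("chi") and key not in ("phi", "psi", "omega"):
                raise PepforgeError(f"unknown torsion key {key!r}")

    def angle_for(num: int, key: str, default: float) -> float:
        return float(torsions.get(num, {}).get(key, default))

    atoms: list[Atom] = []
    residues: list[Residue] = []
    pos: dict[tuple[int, str], np.ndarray] = {}
    serial = 0

    def add_atom(ridx: int, name: str, element: str, p: np.ndarray, charge: float):
        nonlocal serial
        serial += 1
        atoms.append(Atom(serial=serial, name=name, element=element, position=p,
                          vdw_radius=_tables.vdw_radius(element),
                          partial_charge=charge, residue_index=ridx))
        residues[ridx].atom_serials.append(serial)
        pos[(ridx, name)] = np.asarray(p, float)

    for i, rname in enumerate(res_names):
        tpl = templates[rname]
        num = i + 1
        residues.append(Residue(index=i, name=rname, atom_serials=[], label=num))
        phi = angle_for(num, "phi", DEFAULT_PHI)
        psi = angle_for(num, "psi", DEFAULT_PSI)
        omega = angle_for(num, "omega", DEFAULT_OMEGA)
        charges = tpl["charges"]
        if i == 0:
            n = np.zeros(3)
            ca = np.array([L["N-CA"], 0.0, 0.0])
            ang = np.radians(A["N-CA-C"])
            c = ca + L["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
        else:
            prev_psi = angle_for(i, "psi", DEFAULT_PSI)
            n = geometry.place_atom(pos[(i - 1, "C")], pos[(i - 1, "CA")],
                                    pos[(i - 1, "N")], L["C-N"], A["CA-C-N"], prev_psi)
            ca = geometry.place_atom(n, pos[(i - 1, "C")], pos[(i - 1, "CA")],
                                     L["N-CA"], A["C-N-CA"], omega)
            c = geometry.place_atom(ca, n, pos[(i - 1, "C")],
                                    L["CA-C"], A["N-CA-C"], phi)
        add_atom(i, "N", "N", n, charges["N"])
        add_atom(i, "CA", "C", ca, charges["CA"])
        add_atom(i, "C", "C", c, charges["C"])
        # carbonyl O trans to the downstream N: dihedral N-CA-C-O = psi + 180
        o = geometry.place_atom(c, ca, n, L["C-O"], A["CA-C-O"],
                                geometry.normalize_angle(psi + 180.0))
        add_atom(i, "O", "O", o, charges["O"])
        chi_ctx = {k: angle_for(num, k, v) for k, v in tpl["chi_defaults"].items()}
        for row in tpl["z"]:
            name, pb, pa, pt, length, angle, tor = row
            value = _torsion_value(tor, chi_ctx)
            p = geometry.place_atom(pos[(i, pb)], pos[(i, pa)], pos[(i, pt)],
                                    length, angle, value)
            add_atom(i, name, name[0], p, charges[name])

    system = MolecularSystem(atoms, residues, set(), chain_id="A")
    system.bonds = infer_bonds(system)
    if include_hydrogens:
        _add_hydrogens(system)
    return system


def _hydrogen_count(res: str, atom: Atom, degree: int) -> int:
    if atom.element == "C":
        valence = 3 if atom.name in _SP2_CARBONS.get(res, ()) or atom.name == "C" else 4
        return max(0, valence - degree)
    if atom.element == "N":
        if (res, atom.name) in _N_HYDROGENS:
            return _N_HYDROGENS[(res, atom.name)]
        return max(0, 3 - degree)  # backbone amide N (terminal N gets 2)
    if atom.element == "O":
        return _O_HYDROGENS.get((res, atom.name), 0)
    if atom.element == "S":
        return 1 if degree == 1 else 0
    return 0


def _add_hydrogens(system: MolecularSystem) -> None:
    """Geometric hydrogen completion (tetrahedral/trigonal).  Ionizable-group
    proton counts follow the bundled pH-7 convention; no optimization of
    rotatable hydroxyl/methyl orientations beyond staggering."""
    lookup = system.atom_by_serial
    adjacency: dict[int, list[int]] = {a.serial: [] for a in system.atoms}
    for a, b in system.bonds:
        adjacency[a].append(b)
        adjacency[b].append(a)
    serial = max(lookup) if lookup else 0
    new_atoms: list[tuple[Atom, int]] = []
    for atom in list(system.atoms):
        if atom.element == "H":
            continue
        res = system.residues[atom.residue_index]
        nbrs = [lookup[s].position for s in adjacency[atom.serial]]
        n_h = _hydrogen_count(res.name, atom, len(nbrs))
        if n_h == 0:
            continue
        dirs = _complete_directions(atom.position, nbrs, n_h)
        length = _H_LENGTH.get(atom.element, 1.0)
        for k, d in enumerate(dirs, start=1):
            serial += 1
            name = f"H{atom.name[1:] or ''}{k if n_h > 1 else ''}".strip() or "H"
            h = Atom(serial=serial, name=name, element="H",
                     position=atom.position + length * d,
                     vdw_radius=_tables.vdw_radius("H"),
                     partial_charge=0.0, residue_index=atom.residue_index)
            new_atoms.append((h, atom.serial))
            res.atom_serials.append(serial)
    for h, parent in new_atoms:
        system.atoms.append(h)
        system.bonds.add(_bond_key(h.serial, parent))


def _complete_directions(center: np.ndarray, neighbors: list[np.ndarray],
                         count: int) -> list[np.ndarray]:
    units = [(p - center) / np.linalg.norm(p - center) for p in neighbors]
    if not units:  # isolated atom: arbitrary reference frame
        units = [np.array([1.0, 0.0, 0.0])]
    out: list[np.ndarray] = []
    if len(units) >= 3:
        d = -sum(units)
        out.append(d / np.linalg.norm(d))
    elif len(units) == 2:
        bis = -(units[0] + units[1])
        nb = np.linalg.norm(bis)
        bis = bis / nb if nb > 1e-9 else np.array([0.0, 0.0, 1.0])
        perp = np.cross(units[0], units[1])
        np_ = np.linalg.norm(perp)
        perp = perp / np_ if np_ > 1e-9 else _any_perp(units[0])
        if count == 1:
            out.append(bis)
        else:
            half = np.radians(54.75)
            for sign in (1, -1):
                d = np.cos(half) * bis + sign * np.sin(half) * perp
                out.append(d / np.linalg.norm(d))
    else:
        u = units[0]
        perp = _any_perp(u)
        ang = np.radians(109.47)
        for k in range(count):
            rot, _ = geometry.rotation_about_axis(np.zeros(3), u, 120.0 * k + 60.0)
            d = np.cos(ang) * u + np.sin(ang) * (rot @ perp)
            out.append(d / np.linalg.norm(d))
    return out[:count]


def _any_perp(u: np.ndarray) -> np.ndarray:
    v = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(u, v)
    return p / np.linalg.norm(p)
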