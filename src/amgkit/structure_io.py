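"""Coordinate-file IO, atom classification, selections and the domain split.

Parsing and writing of PDB/mmCIF goes through :mod:`gemmi`; the in-memory
model here is a deliberately small chain/residue/atom hierarchy that the
geometric routines in :mod:`amgkit.structure_analysis` operate on directly.

The viral chitosanase V-Csn folds into two non-contiguous structural domains:
Domain-1 is residues 1-36 plus 109-224 (the double-psi beta-barrel) and
Domain-2 is the inserted residues 37-108.  :func:`split_domains` encodes that
split, excluding N-terminal expression-tag residues.
"""

from __future__ import annotations

import math
import urllib.request
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE",  # selenomethionine counts as polymer
}
WATER_NAMES = {"HOH", "WAT", "DOD"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M",
}

RCSB_URL = "https://files.rcsb.org/download/{code}.{ext}"


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    alt_loc: str
    res_name: str
    chain_id: str
    res_seq: int
    icode: str
    xyz: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    record_kind: str = "polymer"  # polymer | water | ligand

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")

    @property
    def residue_key(self):
        return (self.chain_id, self.res_seq, self.icode, self.res_name)


@dataclass
class Residue:
    name: str
    seq: int
    icode: str
    chain_id: str
    atoms: list = field(default_factory=list)

    @property
    def record_kind(self) -> str:
        return classify_residue(self.name)

    def atom(self, name: str):
        """First atom with this name (primary conformer preferred)."""
        hits = [a for a in self.atoms if a.name == name]
        if not hits:
            return None
        hits.sort(key=lambda a: (-a.occupancy, a.alt_loc))
        return hits[0]

    def centroid(self, names=None) -> np.ndarray:
        atoms = [a for a in primary_conformer(self.atoms)
                 if names is None or a.name in names]
        if not atoms:
            raise ValueError(f"no atoms {names} in {self.name}{self.seq}")
        return np.mean([a.xyz for a in atoms], axis=0)


@dataclass
class Chain:
    id: str
    residues: list = field(default_factory=list)

    def polymer_residues(self) -> list:
        return [r for r in self.residues if r.record_kind == "polymer"]


@dataclass
class Structure:
    id: str
    chains: list = field(default_factory=list)
    space_group: str = ""
    cell: tuple = ()

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.id}")

    def atoms(self):
        for c in self.chains:
            for r in c.residues:
                yield from r.atoms

    def residues(self):
        for c in self.chains:
            yield from c.residues


@dataclass
class Selection:
    """An ordered set of atom references plus the expression that made it."""

    atoms: list
    expression: str = ""

    def __len__(self):
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float).reshape(-1, 3)

    def residue_keys(self) -> list:
        seen, keys = set(), []
        for a in self.atoms:
            if a.residue_key not in seen:
                seen.add(a.residue_key)
                keys.append(a.residue_key)
        return keys


@dataclass(frozen=True)
class DomainSplit:
    """Author-numbered residue ranges of the two structural domains."""

    domain1: tuple = ((1, 36), (109, 224))
    domain2: tuple = ((37, 108),)


def classify_residue(res_name: str) -> str:
    if res_name in WATER_NAMES:
        return "water"
    if res_name in STANDARD_AA:
        return "polymer"
    return "ligand"


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _from_gemmi(st: gemmi.Structure) -> Structure:
    st.setup_entities()
    model = st[0]
    chains = []
    serial = 0
    for ch in model:
        residues = []
        for res in ch:
            r = Residue(res.name, res.seqid.num, res.seqid.icode.strip(),
                        ch.name)
            kind = classify_residue(res.name)
            for at in res:
                serial += 1
                r.atoms.append(Atom(
                    serial=at.serial or serial,
                    name=at.name,
                    element=at.element.name.upper(),
                    alt_loc=at.altloc.replace("\x00", "").strip(),
                    res_name=res.name,
                    chain_id=ch.name,
                    res_seq=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=min(max(at.occ, 0.0), 1.0),
                    b_factor=at.b_iso,
                    record_kind=kind,
                ))
            residues.append(r)
        chains.append(Chain(ch.name, residues))
    cell = st.cell
    return Structure(
        id=st.name or "",
        chains=chains,
        space_group=st.spacegroup_hm or "",
        cell=(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma),
    )


def read_structure(source, fmt: str | None = None) -> Structure:
    """Read a PDB or mmCIF file (path or raw text) into a :class:`Structure`.

    ``fmt`` may be ``"pdb"`` or ``"cif"``; when omitted it is inferred from
    the file extension or, for raw text, from the content (mmCIF starts with
    a ``data_`` block).  All ATOM/HETATM records are captured; waters and
    ligands are classified by residue name; alternate locations are retained.
    """
    text = None
    path = None
    src = str(source)
    if "\n" in src or src.lstrip().startswith(("ATOM", "HETATM", "data_", "HEADER",
                                               "CRYST1", "MODEL", "REMARK")):
        text = src
    else:
        path = src
    try:
        if path is not None:
            st = gemmi.read_structure(path)
        else:
            if fmt is None:
                fmt = "cif" if text.lstrip().startswith("data_") else "pdb"
            if fmt == "cif":
                block = gemmi.cif.read_string(text).sole_block()
                st = gemmi.make_structure_from_block(block)
            else:
                st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"failed to parse coordinate input: {exc}") from exc
    return _from_gemmi(st)


def fetch_pdb(code: str, cache_dir: str = "scratch/pdb", fmt: str = "cif",
              timeout: float = 30.0) -> str:
    """Download a deposited entry from the RCSB into ``cache_dir``.

    Returns the local path; a cached copy is reused.  Requires network
    access.
    """
    import os
    ext = "cif" if fmt == "cif" else "pdb"
    os.makedirs(cache_dir, exist_ok=True)
    dest = os.path.join(cache_dir, f"{code.upper()}.{ext}")
    if not os.path.exists(dest):
        url = RCSB_URL.format(code=code.upper(), ext=ext)
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            data = resp.read()
        with open(dest, "wb") as fh:
            fh.write(data)
    return dest


# ---------------------------------------------------------------------------
# Writing (PDB fixed columns, used for fixtures and cross-tool checks)
# ---------------------------------------------------------------------------

def _pdb_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1 and len(name) <= 3:
        return f" {name:<3}"
    return f"{name:<4}"


def write_pdb(structure: Structure, path_or_handle) -> None:
    """Write the structure in PDB fixed-column format."""
    close = False
    if hasattr(path_or_handle, "write"):
        fh = path_or_handle
    else:
        fh = open(path_or_handle, "w")
        close = True
    try:
        if structure.cell:
            a, b, c, al, be, ga = structure.cell
            if a * b * c > 0 and (a, b, c) != (1.0, 1.0, 1.0):
                fh.write(f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}"
                         f"{al:7.2f}{be:7.2f}{ga:7.2f} "
                         f"{structure.space_group or 'P 1':<11s}\n")
        serial = 0
        for chain in structure.chains:
            last_polymer = None
            for res in chain.residues:
                for a in res.atoms:
                    serial += 1
                    record = "ATOM  " if res.record_kind == "polymer" else "HETATM"
                    x, y, z = a.xyz
                    fh.write(
                        f"{record}{serial:5d} {_pdb_atom_name(a.name, a.element)}"
                        f"{a.alt_loc or ' '}{a.res_name:>3s} {a.chain_id[:1] or 'A'}"
                        f"{a.res_seq:4d}{a.icode or ' '}   "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}"
                        f"{a.b_factor:6.2f}          {a.element:>2s}\n")
                if res.record_kind == "polymer":
                    last_polymer = res
            if last_polymer is not None:
                serial += 1
                fh.write(f"TER   {serial:5d}      {last_polymer.name:>3s} "
                         f"{chain.id[:1] or 'A'}{last_polymer.seq:4d}\n")
        fh.write("END\n")
    finally:
        if close:
            fh.close()


def to_pdb_string(structure: Structure) -> str:
    import io
    buf = io.StringIO()
    write_pdb(structure, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Alt-loc policy, selections, model content
# ---------------------------------------------------------------------------

def primary_conformer(atoms) -> list:
    """Keep one conformer per atom: highest occupancy, ties by alt_loc."""
    best = {}
    order = []
    for a in atoms:
        key = (a.chain_id, a.res_seq, a.icode, a.res_name, a.name)
        if key not in best:
            best[key] = a
            order.append(key)
        else:
            b = best[key]
            # strictly higher occupancy wins; ties go to the alphabetically
            # earlier alt_loc
            if a.occupancy > b.occupancy or (
                    a.occupancy == b.occupancy
                    and (a.alt_loc or "~") < (b.alt_loc or "~")):
                best[key] = a
    return [best[k] for k in order]


def _parse_resi_spec(spec: str):
    """Parse '37-108,150' into a membership predicate."""
    ranges = []
    for part in spec.split(","):
        part = part.strip()
        if "-" in part[1:]:  # allow negative single numbers
            lo, hi = part.rsplit("-", 1)
            ranges.append((int(lo), int(hi)))
        else:
            v = int(part)
            ranges.append((v, v))
    return lambda n: any(lo <= n <= hi for lo, hi in ranges)


def select(structure: Structure, expression: str) -> Selection:
    """Evaluate a small selection language over the structure.

    Clauses joined by ``and``: ``chain A``, ``resi 37-108,150``, ``name CA``,
    ``resn GCS``, ``elem C``, and the bare kinds ``polymer`` / ``water`` /
    ``ligand``.  Atom order follows the file; the result is stable for a
    given structure and expression.
    """
    predicates = []
    for clause in expression.split(" and "):
        tokens = clause.strip().split()
        if not tokens:
            continue
        kw = tokens[0].lower()
        if kw in {"polymer", "water", "ligand"} and len(tokens) == 1:
            predicates.append(lambda a, k=kw: a.record_kind == k)
        elif kw == "chain" and len(tokens) == 2:
            predicates.append(lambda a, v=tokens[1]: a.chain_id == v)
        elif kw == "resi" and len(tokens) == 2:
            pred = _parse_resi_spec(tokens[1])
            predicates.append(lambda a, p=pred: p(a.res_seq))
        elif kw == "name" and len(tokens) == 2:
            names = set(tokens[1].split("+"))
            predicates.append(lambda a, v=names: a.name in v)
        elif kw == "resn" and len(tokens) == 2:
            names = set(tokens[1].split("+"))
            predicates.append(lambda a, v=names: a.res_name in v)
        elif kw == "elem" and len(tokens) == 2:
            predicates.append(lambda a, v=tokens[1].upper(): a.element == v)
        else:
            raise ValueError(f"cannot parse selection clause {clause!r}")
    atoms = [a for a in structure.atoms() if all(p(a) for p in predicates)]
    return Selection(atoms, expression)


def count_model_content(structure: Structure) -> dict:
    """Model-content statistics: protein atoms, waters, ligand groups.

    ``protein_atoms`` counts atoms in standard amino-acid residues with
    alternate locations counted once (highest occupancy);
    ``protein_atoms_all_conformers`` counts every conformer.  ``waters`` is
    the number of water residues; ``ligand_groups`` maps hetero residue names
    to multiplicities.
    """
    protein_atoms = []
    waters = set()
    ligand_groups: dict = {}
    n_all = 0
    for res in structure.residues():
        kind = res.record_kind
        if kind == "polymer":
            protein_atoms.extend(res.atoms)
            n_all += len(res.atoms)
        elif kind == "water":
            waters.add((res.chain_id, res.seq, res.icode))
        else:
            key = (res.chain_id, res.seq, res.icode, res.name)
            ligand_groups.setdefault(res.name, set()).add(key)
    return {
        "protein_atoms": len(primary_conformer(protein_atoms)),
        "protein_atoms_all_conformers": n_all,
        "waters": len(waters),
        "ligand_groups": {name: len(keys)
                          for name, keys in sorted(ligand_groups.items())},
    }


def split_domains(structure: Structure, split: DomainSplit = DomainSplit(),
                  chain_id: str | None = None,
                  tag_residues=()) -> tuple:
    """Split one chain into the two structural domains.

    Residue ranges are author-numbered and inclusive.  Expression-tag
    residues (author number < 1, or listed in ``tag_residues``) belong to
    neither domain.  Overlapping domain definitions are an error.
    """
    covered = {}
    for dom, ranges in (("domain1", split.domain1), ("domain2", split.domain2)):
        for lo, hi in ranges:
            for n in range(lo, hi + 1):
                if n in covered and covered[n] != dom:
                    raise ValueError(f"domain ranges overlap at residue {n}")
                covered[n] = dom
    chain = (structure.chain(chain_id) if chain_id is not None
             else next(c for c in structure.chains if c.polymer_residues()))
    tag = set(tag_residues)
    d1, d2 = [], []
    for res in chain.polymer_residues():
        if res.seq < 1 or res.seq in tag:
            continue
        dom = covered.get(res.seq)
        atoms = primary_conformer(res.atoms)
        if dom == "domain1":
            d1.extend(atoms)
        elif dom == "domain2":
            d2.extend(atoms)
    expr1 = " or ".join(f"resi {lo}-{hi}" for lo, hi in split.domain1)
    expr2 = " or ".join(f"resi {lo}-{hi}" for lo, hi in split.domain2)
    return Selection(d1, expr1), Selection(d2, expr2)


# ---------------------------------------------------------------------------
# Rigid-body transforms (also used by the synthetic generator)
# ---------------------------------------------------------------------------

def rotation_from_euler(rx: float, ry: float, rz: float) -> np.ndarray:
    """Proper rotation from XYZ Euler angles in degrees."""
    from scipy.spatial.transform import Rotation
    return Rotation.from_euler("xyz", [rx, ry, rz], degrees=True).as_matrix()


def apply_rigid_transform(obj, rotation=None, translation=None):
    """Return a copy of a Structure/Selection with transformed coordinates."""
    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
    if not math.isclose(float(np.linalg.det(R)), 1.0, abs_tol=1e-6):
        raise ValueError("rotation must be proper (det = +1)")

    def new_atom(a: Atom) -> Atom:
        return replace(a, xyz=R @ a.xyz + t)

    if isinstance(obj, Selection):
        return Selection([new_atom(a) for a in obj.atoms], obj.expression)
    if isinstance(obj, Structure):
        chains = [Chain(c.id, [Residue(r.name, r.seq, r.icode, r.chain_id,
                                       [new_atom(a) for a in r.atoms])
                               for r in c.residues])
                  for c in obj.chains]
        return Structure(obj.id, chains, obj.space_group, obj.cell)
    raise TypeError(f"cannot transform {type(obj).__name__}")
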