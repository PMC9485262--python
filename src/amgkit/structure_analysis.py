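"""Geometric and physico-chemical analysis of chitosanase structures.

This module is the analytical engine applied to the V-Csn crystal forms and
their synthetic stand-ins:

* least-squares rigid superposition (Kabsch) and RMSD,
* Shrake-Rupley solvent-accessible surface area and dimer interface burial,
* heavy-atom hydrogen-bond detection (X-ray models lack hydrogens),
* backbone phi/psi dihedrals and coarse Ramachandran classification,
* Kabsch-Sander-style secondary structure with beta-bridge annotation,
* psi-motif / double-psi beta-barrel (DPBB) detection,
* acidic-cluster (active site) finding,
* glycosidase substrate subsite mapping, and
* Henderson-Hasselbalch per-residue charge versus pH.

All tie-breaking is lexicographic on (chain, residue number, atom name) so
results are deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import (
    Atom,
    Selection,
    Structure,
    primary_conformer,
    select,
)

# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------


@dataclass
class SuperpositionResult:
    rotation: np.ndarray      # 3x3 proper orthogonal, applied to the mobile set
    translation: np.ndarray   # Angstrom
    n_pairs: int
    rmsd: float               # Angstrom over the matched pairs

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _as_ca_coords(obj):
    """Coordinates + residue keys from a Selection/Structure/array."""
    if isinstance(obj, np.ndarray):
        return np.asarray(obj, dtype=float), None
    if isinstance(obj, Structure):
        obj = select(obj, "polymer and name CA")
    if isinstance(obj, Selection):
        atoms = sorted(primary_conformer(obj.atoms),
                       key=lambda a: (a.chain_id, a.res_seq, a.icode, a.name))
        keys = [(a.chain_id, a.res_seq, a.icode) for a in atoms]
        return np.array([a.xyz for a in atoms], dtype=float), keys
    raise TypeError(f"cannot extract coordinates from {type(obj).__name__}")


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Optimal proper rotation + translation mapping ``mobile`` onto ``reference``.

    Solves the orthogonal Procrustes problem by SVD of the covariance matrix,
    with the determinant correction that forbids improper rotations.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    n = len(P)
    if n < 3:
        raise ValueError("need at least 3 paired positions")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        raise ValueError("mobile coordinates are collinear")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return SuperpositionResult(R, t, n, rmsd)


def kabsch_superpose(mobile, reference, pairing: dict | None = None
                     ) -> SuperpositionResult:
    """Superpose C-alpha sets of two structures/selections.

    By default atoms are paired by identical author residue numbers (the
    mutant and apo crystals are isomorphous).  ``pairing`` may map mobile
    residue keys ``(chain, seq, icode)`` to reference keys for non-isomorphous
    pairs (e.g. comparing predicted models).
    """
    P, pkeys = _as_ca_coords(mobile)
    Q, qkeys = _as_ca_coords(reference)
    if pkeys is None or qkeys is None:  # raw arrays: positional pairing
        return kabsch(P, Q)
    qindex = {k: i for i, k in enumerate(qkeys)}
    pairs = []
    for i, k in enumerate(pkeys):
        target = pairing.get(k, None) if pairing is not None else k
        if target is None and pairing is not None:
            continue
        j = qindex.get(target)
        if j is None and pairing is None:
            # fall back to matching on residue number alone across chains
            j = next((jj for jj, qk in enumerate(qkeys) if qk[1:] == k[1:]), None)
        if j is not None:
            pairs.append((i, j))
    if len(pairs) < 3:
        raise ValueError(f"only {len(pairs)} residue pairs matched")
    ii, jj = zip(*pairs)
    return kabsch(P[list(ii)], Q[list(jj)])


# ---------------------------------------------------------------------------
# Solvent accessible surface area (Shrake-Rupley)
# ---------------------------------------------------------------------------

#: Chothia-style van der Waals radii (Angstrom).
SASA_RADII = {
    "C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85,
    "P": 1.80, "SE": 1.90, "H": 1.00,
}
DEFAULT_PROBE = 1.4
DEFAULT_SPHERE_POINTS = 960


@dataclass
class SasaResult:
    probe_radius: float
    n_sphere_points: int
    atoms: list
    per_atom: np.ndarray      # Angstrom^2, parallel to ``atoms``

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())

    def per_residue(self) -> dict:
        agg: dict = {}
        for a, area in zip(self.atoms, self.per_atom):
            agg[a.residue_key] = agg.get(a.residue_key, 0.0) + float(area)
        return agg


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform sphere lattice (Fibonacci spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i     # golden-angle increments
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _atom_radii(atoms, radii_override) -> np.ndarray:
    table = dict(SASA_RADII)
    if radii_override:
        table.update({k.upper(): v for k, v in radii_override.items()})
    radii = np.empty(len(atoms))
    for i, a in enumerate(atoms):
        try:
            radii[i] = table[a.element.upper()]
        except KeyError:
            raise KeyError(
                f"no van der Waals radius for element {a.element!r}; "
                "supply radii_override") from None
    return radii


def shrake_rupley_sasa(sel, probe: float = DEFAULT_PROBE,
                       n_points: int = DEFAULT_SPHERE_POINTS,
                       radii_override: dict | None = None) -> SasaResult:
    """Per-atom solvent-accessible surface area by sphere-point sampling.

    Each atom's solvent sphere (vdW radius + probe) is sampled on a
    deterministic spiral lattice; a point is accessible when it lies outside
    every neighbouring atom's solvent sphere.  Deterministic for fixed
    ``n_points``.
    """
    if isinstance(sel, Structure):
        atoms = primary_conformer(list(sel.atoms()))
    elif isinstance(sel, Selection):
        atoms = primary_conformer(sel.atoms)
    else:
        atoms = primary_conformer(list(sel))
    atoms = sorted(atoms, key=lambda a: (a.chain_id, a.res_seq, a.icode, a.name))
    if not atoms:
        return SasaResult(probe, n_points, [], np.zeros(0))
    xyz = np.array([a.xyz for a in atoms])
    radii = _atom_radii(atoms, radii_override) + probe
    unit = sphere_points(n_points)
    tree = cKDTree(xyz)
    rmax = radii.max()
    areas = np.zeros(len(atoms))
    for i in range(len(atoms)):
        neighbours = tree.query_ball_point(xyz[i], radii[i] + rmax)
        neighbours = [j for j in neighbours if j != i
                      and np.linalg.norm(xyz[j] - xyz[i]) < radii[i] + radii[j]]
        pts = xyz[i] + radii[i] * unit
        if neighbours:
            d2 = np.sum((pts[:, None, :] - xyz[neighbours][None, :, :]) ** 2,
                        axis=2)
            buried = (d2 < (radii[neighbours] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * math.pi * radii[i] ** 2 * frac
    return SasaResult(probe, n_points, atoms, areas)


@dataclass
class InterfaceReport:
    """Surface burial on dimer formation, per monomer."""

    buried_area: dict          # chain id -> Angstrom^2
    buried_fraction: dict      # chain id -> buried / SASA(alone)
    contact_residues: dict     # chain id -> ordered residue keys
    probe_radius: float
    n_sphere_points: int


def interface_burial(structure: Structure, chain_a: str, chain_b: str,
                     probe: float = DEFAULT_PROBE,
                     n_points: int = DEFAULT_SPHERE_POINTS,
                     contact_cutoff: float = 4.0) -> InterfaceReport:
    """Buried surface area per monomer: SASA(alone) - SASA(in complex).

    Only non-water atoms of the two chains enter the calculation.  Contact
    residues are those losing accessible area or having a heavy atom within
    ``contact_cutoff`` of the partner chain.
    """
    if chain_a == chain_b:
        raise ValueError("interface requires two distinct chains")

    def chain_atoms(cid):
        ch = structure.chain(cid)
        return primary_conformer(
            [a for r in ch.residues if r.record_kind != "water" for a in r.atoms])

    atoms = {chain_a: chain_atoms(chain_a), chain_b: chain_atoms(chain_b)}
    complex_sasa = shrake_rupley_sasa(atoms[chain_a] + atoms[chain_b],
                                      probe, n_points)
    complex_by_atom = {id(a): area for a, area in
                       zip(complex_sasa.atoms, complex_sasa.per_atom)}
    buried, fraction, contacts = {}, {}, {}
    trees = {cid: cKDTree(np.array([a.xyz for a in ats]))
             for cid, ats in atoms.items()}
    for cid, other in ((chain_a, chain_b), (chain_b, chain_a)):
        alone = shrake_rupley_sasa(atoms[cid], probe, n_points)
        lost_by_res: dict = {}
        for a, area in zip(alone.atoms, alone.per_atom):
            lost = float(area) - complex_by_atom[id(a)]
            if lost > 1e-9:
                lost_by_res[a.residue_key] = lost_by_res.get(a.residue_key, 0) + lost
        total_alone = alone.total
        b = total_alone - sum(complex_by_atom[id(a)] for a in alone.atoms)
        buried[cid] = float(b)
        fraction[cid] = float(b / total_alone) if total_alone > 0 else 0.0
        near = set()
        for a in atoms[cid]:
            if trees[other].query_ball_point(a.xyz, contact_cutoff):
                near.add(a.residue_key)
        contacts[cid] = sorted(set(lost_by_res) | near,
                               key=lambda k: (k[0], k[1], k[2]))
    return InterfaceReport(buried, fraction, contacts, probe, n_points)


# ---------------------------------------------------------------------------
# Hydrogen bonds (heavy-atom criterion; crystal structures lack hydrogens)
# ---------------------------------------------------------------------------

#: sidechain donor atom -> antecedent atom, per residue type
SIDECHAIN_DONORS = {
    "SER": {"OG": "CB"}, "THR": {"OG1": "CB"}, "TYR": {"OH": "CZ"},
    "ASN": {"ND2": "CG"}, "GLN": {"NE2": "CD"}, "LYS": {"NZ": "CE"},
    "ARG": {"NE": "CD", "NH1": "CZ", "NH2": "CZ"},
    "HIS": {"ND1": "CG", "NE2": "CD2"}, "TRP": {"NE1": "CD1"},
    "CYS": {"SG": "CB"},
}
SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"}, "MET": {"SD"},
}

HBOND_DMAX = 3.5
HBOND_ANGLE_MIN = 90.0


@dataclass
class HydrogenBond:
    donor: Atom
    acceptor: Atom
    distance: float
    angle: float | None        # antecedent-donor-acceptor, degrees
    hb_class: str

    def involves(self, chain_id, res_seq, atom_name=None) -> bool:
        for a in (self.donor, self.acceptor):
            if a.chain_id == chain_id and a.res_seq == res_seq and (
                    atom_name is None or a.name == atom_name):
                return True
        return False


def _atom_role(a: Atom) -> str:
    if a.record_kind == "water":
        return "water"
    if a.record_kind == "ligand":
        return "ligand"
    return "mainchain" if a.name in {"N", "O", "OXT"} else "sidechain"


def _classify_hbond(donor: Atom, acceptor: Atom) -> str:
    roles = {_atom_role(donor), _atom_role(acceptor)}
    if "water" in roles:
        return "to-water"
    if "ligand" in roles:
        return "to-ligand"
    if roles == {"mainchain"}:
        return "mainchain-mainchain"
    if roles == {"sidechain"}:
        return "sidechain-sidechain"
    return "sidechain-mainchain"


def _donor_acceptor_atoms(atoms):
    """Donor (with antecedent) and acceptor atom lists for a heavy-atom scan."""
    by_res: dict = {}
    for a in atoms:
        by_res.setdefault(a.residue_key, {})[a.name] = a
    donors, acceptors = [], []
    for key, res_atoms in by_res.items():
        res_name = key[3]
        kind = next(iter(res_atoms.values())).record_kind
        if kind == "polymer":
            if "N" in res_atoms and res_name != "PRO":
                donors.append((res_atoms["N"], res_atoms.get("CA")))
            for name in ("O", "OXT"):
                if name in res_atoms:
                    acceptors.append(res_atoms[name])
            for name, ante in SIDECHAIN_DONORS.get(res_name, {}).items():
                if name in res_atoms:
                    donors.append((res_atoms[name], res_atoms.get(ante)))
            for name in SIDECHAIN_ACCEPTORS.get(res_name, set()):
                if name in res_atoms:
                    acceptors.append(res_atoms[name])
        elif kind == "water":
            for a in res_atoms.values():
                if a.element == "O":
                    donors.append((a, None))
                    acceptors.append(a)
        else:  # ligand: polar atoms act as both donor and acceptor; the
            # antecedent is the nearest bonded heavy atom in the residue
            heavy = [a for a in res_atoms.values() if a.element != "H"]
            for a in heavy:
                if a.element in {"N", "O"}:
                    bonded = [b for b in heavy if b is not a
                              and np.linalg.norm(b.xyz - a.xyz) < 1.8]
                    ante = min(bonded, key=lambda b: np.linalg.norm(b.xyz - a.xyz),
                               default=None)
                    donors.append((a, ante))
                    acceptors.append(a)
    return donors, acceptors


def detect_hbonds(sel, d_max: float = HBOND_DMAX,
                  angle_min: float = HBOND_ANGLE_MIN) -> list:
    """Geometric hydrogen-bond detection without explicit hydrogens.

    A donor-acceptor pair is bonded when the heavy-atom distance is at most
    ``d_max`` and the antecedent-donor-acceptor angle is at least
    ``angle_min`` (the angle test is skipped when the donor has no antecedent,
    e.g. waters).  Same-residue pairs, covalently close pairs (< 2.2 A) and
    mainchain-mainchain pairs of adjacent residues are excluded.
    """
    if isinstance(sel, Structure):
        atoms = primary_conformer(list(sel.atoms()))
    elif isinstance(sel, Selection):
        atoms = primary_conformer(sel.atoms)
    else:
        atoms = primary_conformer(list(sel))
    donors, acceptors = _donor_acceptor_atoms(atoms)
    if not donors or not acceptors:
        return []
    acc_tree = cKDTree(np.array([a.xyz for a in acceptors]))
    bonds = []
    for donor, ante in donors:
        for j in acc_tree.query_ball_point(donor.xyz, d_max):
            acc = acceptors[j]
            if acc is donor or acc.residue_key == donor.residue_key:
                continue
            dist = float(np.linalg.norm(acc.xyz - donor.xyz))
            if dist < 2.2:
                continue
            mm = (_atom_role(donor) == "mainchain"
                  and _atom_role(acc) == "mainchain")
            if mm and donor.chain_id == acc.chain_id and \
                    abs(donor.res_seq - acc.res_seq) <= 1:
                continue
            angle = None
            if ante is not None:
                v1 = ante.xyz - donor.xyz
                v2 = acc.xyz - donor.xyz
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
                if angle < angle_min:
                    continue
            bonds.append(HydrogenBond(donor, acc, dist, angle,
                                      _classify_hbond(donor, acc)))
    bonds.sort(key=lambda h: (h.donor.chain_id, h.donor.res_seq, h.donor.name,
                              h.acceptor.chain_id, h.acceptor.res_seq,
                              h.acceptor.name))
    return bonds


# ---------------------------------------------------------------------------
# Backbone dihedrals and Ramachandran classes
# ---------------------------------------------------------------------------

CHAIN_BREAK_CN = 2.0  # Angstrom


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees, in (-180, 180]."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1u = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 else ang


@dataclass
class RamaRecord:
    chain_id: str
    res_seq: int
    res_name: str
    phi: float | None
    psi: float | None
    residue_class: str     # general | glycine | proline | pre-proline
    region: str = ""       # favored | allowed | outlier (set on classification)


def _backbone_residues(chain):
    """Polymer residues with complete (N, CA, C) backbones, in chain order."""
    out = []
    for res in chain.polymer_residues():
        if all(res.atom(n) is not None for n in ("N", "CA", "C")):
            out.append(res)
    return out


def compute_phi_psi(chain) -> list:
    """Backbone phi/psi for one chain, honouring chain breaks.

    phi(i) = dihedral(C[i-1], N[i], CA[i], C[i]); psi(i) = dihedral(N[i],
    CA[i], C[i], N[i+1]).  Residues across a break (C-N distance >= 2 A) are
    treated as chain termini and lack the corresponding angle.
    """
    residues = _backbone_residues(chain)
    records = []
    for i, res in enumerate(residues):
        phi = psi = None
        prev_res = residues[i - 1] if i > 0 else None
        next_res = residues[i + 1] if i + 1 < len(residues) else None
        if prev_res is not None:
            d = np.linalg.norm(res.atom("N").xyz - prev_res.atom("C").xyz)
            if d < CHAIN_BREAK_CN:
                phi = dihedral(prev_res.atom("C").xyz, res.atom("N").xyz,
                               res.atom("CA").xyz, res.atom("C").xyz)
        if next_res is not None:
            d = np.linalg.norm(next_res.atom("N").xyz - res.atom("C").xyz)
            if d < CHAIN_BREAK_CN:
                psi = dihedral(res.atom("N").xyz, res.atom("CA").xyz,
                               res.atom("C").xyz, next_res.atom("N").xyz)
        if res.name == "GLY":
            rclass = "glycine"
        elif res.name == "PRO":
            rclass = "proline"
        elif next_res is not None and next_res.name == "PRO":
            rclass = "pre-proline"
        else:
            rclass = "general"
        records.append(RamaRecord(res.chain_id, res.seq, res.name,
                                  phi, psi, rclass))
    return records


# Coarse rectangular Ramachandran contours per residue class.  Each region is
# a list of (phi_lo, phi_hi, psi_lo, psi_hi) boxes; "allowed" boxes are in
# addition to the favored ones.  These are deliberately coarse outlines of the
# standard density-based contours, adequate for classifying well-refined
# models to about a percentage point.
RAMA_REGIONS = {
    "general": {
        "favored": [(-170, -45, 100, 180), (-170, -45, -180, -160),
                    (-140, -35, -70, -5)],
        "allowed": [(-180, -30, 60, 180), (-180, -30, -180, -140),
                    (-180, -20, -90, 60), (30, 100, -20, 90)],
    },
    "glycine": {
        "favored": [(-170, -45, 100, 180), (-140, -35, -70, -5),
                    (35, 140, -20, 80), (45, 170, 160, 180),
                    (45, 170, -180, -100)],
        "allowed": [(-180, 180, 120, 180), (-180, 180, -180, -120),
                    (-180, -20, -100, 60), (20, 180, -60, 100)],
    },
    "proline": {
        "favored": [(-100, -40, 100, 180), (-100, -40, -60, 0)],
        "allowed": [(-110, -30, 60, 180), (-110, -30, -70, 20),
                    (-110, -30, -180, -160)],
    },
    "pre-proline": {
        "favored": [(-170, -45, 100, 180), (-170, -45, -180, -160),
                    (-140, -35, -70, -5)],
        "allowed": [(-180, -30, 40, 180), (-180, -30, -180, -140),
                    (-180, -20, -90, 40), (30, 100, -20, 90)],
    },
}


def classify_rama_region(record: RamaRecord,
                         region_definition: dict | None = None) -> str:
    """Assign favored/allowed/outlier from the coarse contour boxes."""
    regions = (region_definition or RAMA_REGIONS)[record.residue_class]
    if record.phi is None or record.psi is None:
        return ""

    def inside(boxes):
        return any(lo <= record.phi <= hi and plo <= record.psi <= phi_hi
                   for lo, hi, plo, phi_hi in boxes)

    if inside(regions["favored"]):
        return "favored"
    if inside(regions.get("allowed", [])):
        return "allowed"
    return "outlier"


def rama_percentages(records, region_definition: dict | None = None) -> dict:
    """Percentages of favored/allowed/outlier residues.

    Terminal residues (missing one angle) are excluded from the denominator.
    ``preferred`` = favored + allowed, matching the convention of reporting
    "residues in preferred regions".
    """
    scored = []
    for r in records:
        if r.phi is None or r.psi is None:
            continue
        r.region = classify_rama_region(r, region_definition)
        scored.append(r)
    n = len(scored)
    if n == 0:
        return {"favored": 0.0, "allowed": 0.0, "outlier": 0.0,
                "preferred": 0.0, "n": 0}
    counts = {"favored": 0, "allowed": 0, "outlier": 0}
    for r in scored:
        counts[r.region] += 1
    pct = {k: 100.0 * v / n for k, v in counts.items()}
    pct["preferred"] = pct["favored"] + pct["allowed"]
    pct["n"] = n
    return pct


# ---------------------------------------------------------------------------
# Secondary structure (Kabsch-Sander-style) and beta-bridges
# ---------------------------------------------------------------------------

DSSP_HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
_DSSP_Q1Q2F = 0.084 * 332.0


@dataclass
class StrandElement:
    name: str           # beta1, beta2, ... in sequence order
    start: int          # indices into the backbone residue list
    end: int            # inclusive

    def indices(self):
        return range(self.start, self.end + 1)


@dataclass
class PsiMotif:
    """One psi-motif: a long bent strand, a long partner and a short strand."""

    bent: str
    long_partner: str
    short: str

    def strands(self):
        return {self.bent, self.long_partner, self.short}


@dataclass
class MotifAssignment:
    """Secondary structure plus strand/helix bookkeeping for one chain.

    ``ss`` holds one character per backbone residue: H (alpha), G (3-10),
    E (strand), B (isolated beta-bridge), ``-`` (coil).  Strands are named
    beta1..betaN and helices alpha1..alphaM in sequence order (single-turn
    3-10 helices share the alpha numbering, as is conventional for this
    enzyme family).
    """

    residues: list                    # (chain_id, res_seq, res_name)
    ss: str
    ca: np.ndarray                    # (n, 3) C-alpha coordinates
    strands: list = field(default_factory=list)    # StrandElement
    helices: list = field(default_factory=list)    # (name, start, end, kind)
    beta_bridges: list = field(default_factory=list)  # residue indices, 'B'
    bridge_pairs: list = field(default_factory=list)  # (i, j, type)
    psi_motifs: list = field(default_factory=list)    # PsiMotif
    dpbb: list = field(default_factory=list)          # strand names (6)
    pseudo_twofold_rmsd: float | None = None

    def strand(self, name: str) -> StrandElement:
        for s in self.strands:
            if s.name == name:
                return s
        raise KeyError(name)

    def bridge_residues(self) -> list:
        """(res_name, res_seq) of isolated beta-bridge residues."""
        return [(self.residues[i][2], self.residues[i][1])
                for i in self.beta_bridges]


def _dssp_hbond_matrix(residues) -> np.ndarray:
    """hbond[i, j]: the CO of residue i accepts the NH of residue j.

    Amide hydrogens are reconstructed along the preceding peptide C=O
    direction; the Kabsch-Sander electrostatic energy below -0.5 kcal/mol
    defines a bond.  Prolines donate nothing.
    """
    n = len(residues)
    N = np.array([r.atom("N").xyz for r in residues])
    C = np.array([r.atom("C").xyz for r in residues])
    O = np.array([r.atom("O").xyz if r.atom("O") is not None
                  else r.atom("C").xyz for r in residues])
    H = np.full_like(N, np.nan)
    for j in range(1, n):
        if np.linalg.norm(N[j] - C[j - 1]) < CHAIN_BREAK_CN \
                and residues[j].name != "PRO":
            co = C[j - 1] - O[j - 1]
            H[j] = N[j] + co / np.linalg.norm(co)
    hbond = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if abs(i - j) < 2 or np.isnan(H[j]).any():
                continue
            r_on = np.linalg.norm(O[i] - N[j])
            if r_on > 5.2:
                continue
            r_ch = np.linalg.norm(C[i] - H[j])
            r_oh = np.linalg.norm(O[i] - H[j])
            r_cn = np.linalg.norm(C[i] - N[j])
            energy = _DSSP_Q1Q2F * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if energy < DSSP_HBOND_ENERGY_CUTOFF:
                hbond[i, j] = True
    return hbond


def assign_secondary_structure(chain) -> MotifAssignment:
    """Kabsch-Sander-style secondary structure assignment.

    Accepts a single chain or a whole structure (all polymer chains are
    considered together, so inter-chain beta-ladders are found).  Two
    consecutive i -> i+4 turns define an alpha-helix, i -> i+3 turns a 3-10
    helix; beta-bridges are detected from the parallel/antiparallel
    hydrogen-bond patterns, chained into ladders (E) or left as isolated
    bridges (B).
    """
    if isinstance(chain, Structure):
        residues = [r for c in chain.chains for r in _backbone_residues(c)]
    else:
        residues = _backbone_residues(chain)
    n = len(residues)
    info = [(r.chain_id, r.seq, r.name) for r in residues]
    ca = np.array([r.atom("CA").xyz for r in residues]).reshape(-1, 3)
    if n < 3:
        return MotifAssignment(info, "-" * n, ca)
    hb = _dssp_hbond_matrix(residues)

    def turn(i, k):
        return i + k < n and hb[i, i + k]

    ss = ["-"] * n
    # bridges first (strand/bridge detection)
    bridge_type = {}
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (hb[i - 1, j] and hb[j, i + 1]) or (hb[j - 1, i] and hb[i, j + 1])
            anti = (hb[i, j] and hb[j, i]) or (hb[i - 1, j + 1] and hb[j - 1, i + 1])
            if para:
                bridge_type[(i, j)] = "parallel"
            elif anti:
                bridge_type[(i, j)] = "antiparallel"
    # chain bridges into ladders
    ladder_member = set()
    for (i, j), kind in bridge_type.items():
        succ = ((i + 1, j + 1) if kind == "parallel" else (i + 1, j - 1))
        pred = ((i - 1, j - 1) if kind == "parallel" else (i - 1, j + 1))
        if bridge_type.get(succ) == kind or bridge_type.get(pred) == kind:
            ladder_member.add((i, j))
    for (i, j), kind in sorted(bridge_type.items()):
        if (i, j) in ladder_member:
            ss[i] = ss[j] = "E"
        else:
            for k in (i, j):
                if ss[k] == "-":
                    ss[k] = "B"
    # helices overwrite coil but not strand
    for i in range(1, n):
        if turn(i - 1, 4) and turn(i, 4):
            for k in range(i, min(i + 4, n)):
                ss[k] = "H"
    for i in range(1, n):
        if turn(i - 1, 3) and turn(i, 3):
            for k in range(i, min(i + 3, n)):
                if ss[k] == "-" or ss[k] == "B":
                    ss[k] = "G"
    bridges_isolated = sorted(i for i in range(n) if ss[i] == "B")

    motif = MotifAssignment(info, "".join(ss), ca)
    motif.bridge_pairs = [(i, j, k) for (i, j), k in sorted(bridge_type.items())]
    motif.beta_bridges = bridges_isolated
    # name elements in sequence order
    idx = 0
    nb = nh = 0
    while idx < n:
        c = ss[idx]
        if c in "EHG":
            start = idx
            while idx + 1 < n and ss[idx + 1] == c:
                idx += 1
            if c == "E":
                nb += 1
                motif.strands.append(StrandElement(f"beta{nb}", start, idx))
            else:
                nh += 1
                kind = "alpha" if c == "H" else "3-10"
                motif.helices.append((f"alpha{nh}", start, idx, kind))
        idx += 1
    return motif


# ---------------------------------------------------------------------------
# psi-motif and double-psi beta-barrel detection
# ---------------------------------------------------------------------------

PSI_BEND_RANGE = (60.0, 120.0)     # inter-segment axis angle of the bent strand
PSI_PARALLEL_MAX = 30.0            # short strand vs C-terminal segment
PSI_ANTIPARALLEL_MIN = 140.0       # long-pair and short-pair opposition
PSI_CONTACT_DMAX = 7.0             # strand adjacency (min CA-CA distance)


def _axis(coords: np.ndarray) -> np.ndarray:
    v = coords[-1] - coords[0]
    return v / np.linalg.norm(v)


def _vec_angle(u, v) -> float:
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(np.clip(c, -1.0, 1.0)))


def _bend_split(coords: np.ndarray):
    """Best split of a strand CA trace into two sub-segments; returns
    (angle_between_axes, split_index) at the most bent split."""
    nres = len(coords)
    best = (0.0, None)
    for k in range(2, nres - 2):
        a1 = _axis(coords[: k + 1])
        a2 = _axis(coords[k:])
        ang = _vec_angle(a1, a2)
        if ang > best[0]:
            best = (ang, k)
    return best


def _min_ca_distance(c1: np.ndarray, c2: np.ndarray) -> float:
    d = np.linalg.norm(c1[:, None, :] - c2[None, :, :], axis=2)
    return float(d.min())


def detect_psi_dpbb(motif: MotifAssignment) -> MotifAssignment:
    """Find psi-motifs and a double-psi beta-barrel among assigned strands.

    A psi-motif is one long strand bent roughly 90 degrees (sub-segment axis
    angle within 60-120 degrees), one long strand running antiparallel to its
    C-terminal half, and one short strand parallel to that same half.  Two
    disjoint psi-motifs whose short strands form an adjacent antiparallel
    pair constitute the barrel; the pseudo-twofold RMSD comes from
    superposing one motif's C-alphas onto the other's.  Absence of candidates
    yields an empty result, not an error.
    """
    motif.psi_motifs = []
    motif.dpbb = []
    motif.pseudo_twofold_rmsd = None
    strands = motif.strands
    if len(strands) < 6:
        return motif
    coords = {s.name: motif.ca[s.start:s.end + 1] for s in strands}
    lengths = {s.name: s.end - s.start + 1 for s in strands}
    bends = {}
    for s in strands:
        if lengths[s.name] >= 6:
            ang, k = _bend_split(coords[s.name])
            if k is not None and PSI_BEND_RANGE[0] <= ang <= PSI_BEND_RANGE[1]:
                bends[s.name] = k
    candidates = []
    for bent in sorted(bends):
        cterm = coords[bent][bends[bent]:]
        ax_c = _axis(cterm)
        for partner in strands:
            if partner.name == bent or lengths[partner.name] < 3:
                continue
            if _vec_angle(_axis(coords[partner.name]), ax_c) < PSI_ANTIPARALLEL_MIN:
                continue
            for short in strands:
                if short.name in {bent, partner.name}:
                    continue
                if lengths[short.name] > lengths[partner.name]:
                    continue
                if _vec_angle(_axis(coords[short.name]), ax_c) > PSI_PARALLEL_MAX:
                    continue
                group = [coords[bent], coords[partner.name], coords[short.name]]
                adjacent = all(
                    min(_min_ca_distance(group[i], group[j])
                        for j in range(3) if j != i) <= PSI_CONTACT_DMAX
                    for i in range(3))
                if adjacent:
                    candidates.append(PsiMotif(bent, partner.name, short.name))
    # pair two disjoint motifs with adjacent antiparallel short strands
    for a in candidates:
        for b in candidates:
            if a.strands() & b.strands():
                continue
            sa, sb = coords[a.short], coords[b.short]
            if _vec_angle(_axis(sa), _axis(sb)) < PSI_ANTIPARALLEL_MIN:
                continue
            if _min_ca_distance(sa, sb) > PSI_CONTACT_DMAX:
                continue
            motif.psi_motifs = [a, b]
            names = sorted(a.strands() | b.strands(),
                           key=lambda nm: int(nm.replace("beta", "")))
            motif.dpbb = names
            motif.pseudo_twofold_rmsd = _psi_pair_rmsd(a, b, coords)
            return motif
    if candidates:
        motif.psi_motifs = [candidates[0]]
    return motif


def _psi_pair_rmsd(a: PsiMotif, b: PsiMotif, coords: dict) -> float:
    pa, pb = [], []
    for ra, rb in ((a.bent, b.bent), (a.long_partner, b.long_partner),
                   (a.short, b.short)):
        ca, cb = coords[ra], coords[rb]
        m = min(len(ca), len(cb))
        pa.append(ca[:m])
        pb.append(cb[:m])
    return kabsch(np.vstack(pa), np.vstack(pb)).rmsd


# ---------------------------------------------------------------------------
# Acidic cluster (active-site) detection
# ---------------------------------------------------------------------------

CARBOXYLATE_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


def find_acidic_cluster(structure: Structure, d_max: float = 6.0) -> list:
    """Single-linkage clusters of Asp/Glu carboxylate groups.

    The carboxylate centroid (mean of the two carboxyl oxygens) represents
    each residue; residues within ``d_max`` are linked.  Clusters are ranked
    by size, then compactness (mean pairwise distance), then lexicographic
    residue order.  Returns a list of clusters, each a sorted list of
    ``(chain_id, res_seq, res_name)``.
    """
    acidic = []
    for res in structure.residues():
        if res.name in CARBOXYLATE_ATOMS and res.record_kind == "polymer":
            names = CARBOXYLATE_ATOMS[res.name]
            atoms = [res.atom(nm) for nm in names]
            atoms = [a for a in atoms if a is not None]
            if atoms:
                centroid = np.mean([a.xyz for a in atoms], axis=0)
                acidic.append(((res.chain_id, res.seq, res.name), centroid))
    if not acidic:
        return []
    keys = [k for k, _ in acidic]
    pts = np.array([c for _, c in acidic])
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components
    tree = cKDTree(pts)
    pairs = tree.query_pairs(d_max)
    rows = [p[0] for p in pairs] + [p[1] for p in pairs]
    cols = [p[1] for p in pairs] + [p[0] for p in pairs]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)),
                     shape=(len(keys), len(keys)))
    n_comp, labels = connected_components(adj, directed=False)
    clusters = []
    for c in range(n_comp):
        members = [i for i in range(len(keys)) if labels[i] == c]
        if len(members) > 1:
            sub = pts[members]
            d = np.linalg.norm(sub[:, None] - sub[None, :], axis=2)
            compact = float(d.sum() / (len(members) * (len(members) - 1)))
        else:
            compact = 0.0
        clusters.append((sorted(keys[i] for i in members), compact))
    clusters.sort(key=lambda t: (-len(t[0]), t[1], t[0]))
    return [members for members, _ in clusters]


# ---------------------------------------------------------------------------
# Substrate subsite mapping
# ---------------------------------------------------------------------------

SUGAR_RESNAMES = {"GCS", "NAG", "BGC", "GLC", "PA1"}  # GCS = beta-D-glucosamine
GLYCOSIDIC_BOND_MAX = 1.8
CONTACT_DMAX = 4.0


@dataclass
class SubsiteMap:
    """Sugar residues labelled by glycosidase subsite with their contacts."""

    order: list        # residue keys from the reducing end: GlcN-1, GlcN-2, ...
    subsites: dict     # residue key -> signed subsite label (-1 flanks cleavage)
    contacts: dict     # residue key -> {"hbonds": [...], "near": [residue keys]}


def _sugar_residues(structure: Structure, resnames) -> list:
    return [r for r in structure.residues()
            if r.record_kind == "ligand" and r.name in resnames]


def _order_sugars(sugars) -> list:
    """Order beta-1,4-linked sugars starting at the reducing end.

    The glycosidic bond links C1 of one residue to O4 of the next toward the
    reducing end; the reducing-end sugar is the one whose C1 is not bonded to
    any partner O4 (it keeps a free anomeric position).
    """
    linked_from = {}   # sugar (donor of C1) -> sugar whose O4 it bonds
    for s in sugars:
        c1 = s.atom("C1")
        if c1 is None:
            continue
        for t in sugars:
            if t is s:
                continue
            o4 = t.atom("O4")
            if o4 is not None and \
                    np.linalg.norm(c1.xyz - o4.xyz) <= GLYCOSIDIC_BOND_MAX:
                linked_from[id(s)] = t
    bonded_c1 = set(linked_from.keys())
    start = [s for s in sugars if id(s) not in bonded_c1]
    if len(start) != 1:
        # fall back to residue-number order (single sugar or broken chain)
        return sorted(sugars, key=lambda r: (r.chain_id, r.seq))
    chain = [start[0]]
    rev = {id(t): s for s, t in ((s, linked_from[id(s)]) for s in sugars
                                 if id(s) in linked_from)}
    while id(chain[-1]) in rev:
        chain.append(rev[id(chain[-1])])
    return chain


def map_subsites(structure: Structure, ligand_resnames=None,
                 catalytic_residue: tuple | int = 157,
                 hbond_dmax: float = HBOND_DMAX,
                 contact_dmax: float = CONTACT_DMAX) -> SubsiteMap:
    """Label bound sugars with glycosidase subsites and list their contacts.

    Sugars are ordered from the reducing end.  The sugar closest to the
    catalytic (proton-donor) residue takes subsite -1; successive sugars
    toward the non-reducing end take -2, -3, ... and toward the reducing end
    +1, +2, ...  Contacts per sugar combine hydrogen bonds (default
    heavy-atom criterion) and protein heavy atoms within ``contact_dmax``.
    """
    resnames = set(ligand_resnames) if ligand_resnames else SUGAR_RESNAMES
    sugars = _sugar_residues(structure, resnames)
    if not sugars:
        raise ValueError(f"no sugar residues ({sorted(resnames)}) in structure")
    ordered = _order_sugars(sugars)
    if isinstance(catalytic_residue, int):
        cat = next((r for r in structure.residues()
                    if r.record_kind == "polymer" and r.seq == catalytic_residue),
                   None)
    else:
        chain_id, seq = catalytic_residue
        cat = next((r for r in structure.residues()
                    if r.chain_id == chain_id and r.seq == seq), None)
    if cat is None:
        raise ValueError(f"catalytic residue {catalytic_residue} not found")
    cat_xyz = np.array([a.xyz for a in primary_conformer(cat.atoms)])

    def dist_to_cat(res):
        xyz = np.array([a.xyz for a in primary_conformer(res.atoms)])
        return float(np.min(np.linalg.norm(
            xyz[:, None, :] - cat_xyz[None, :, :], axis=2)))

    anchor = min(range(len(ordered)), key=lambda i: dist_to_cat(ordered[i]))
    subsites = {}
    for i, res in enumerate(ordered):
        # positions past the anchor toward the non-reducing end are -2, -3...;
        # toward the reducing end +1, +2...
        offset = i - anchor
        label = -1 - offset if offset >= 0 else -offset
        key = (res.chain_id, res.seq, res.name)
        subsites[key] = int(label)

    protein_atoms = primary_conformer(
        [a for r in structure.residues() if r.record_kind == "polymer"
         for a in r.atoms])
    all_bonds = detect_hbonds(
        protein_atoms + [a for r in ordered for a in primary_conformer(r.atoms)],
        d_max=hbond_dmax)
    tree = cKDTree(np.array([a.xyz for a in protein_atoms]))
    contacts = {}
    for res in ordered:
        key = (res.chain_id, res.seq, res.name)
        bonds = [h for h in all_bonds
                 if h.hb_class == "to-ligand" and h.involves(res.chain_id, res.seq)]
        near = set()
        for a in primary_conformer(res.atoms):
            for j in tree.query_ball_point(a.xyz, contact_dmax):
                near.add(protein_atoms[j].residue_key)
        contacts[key] = {
            "hbonds": bonds,
            "near": sorted(near, key=lambda k: (k[0], k[1], k[2])),
        }
    order_keys = [(r.chain_id, r.seq, r.name) for r in ordered]
    return SubsiteMap(order_keys, subsites, contacts)


# ---------------------------------------------------------------------------
# Henderson-Hasselbalch per-residue charge
# ---------------------------------------------------------------------------

#: Intrinsic pKa values; acids carry 0/-1 charge states, bases +1/0.
PKA_TABLE = {
    "ASP": ("acid", 3.9), "GLU": ("acid", 4.1), "CYS": ("acid", 8.4),
    "TYR": ("acid", 10.5), "HIS": ("base", 6.0), "LYS": ("base", 10.5),
    "ARG": ("base", 12.5),
}
PKA_NTERM = 8.0
PKA_CTERM = 3.1


@dataclass
class ChargeProfile:
    pH: float
    per_residue: dict     # (chain, seq, name) -> mean charge
    total: float


def mean_charge(kind: str, pka: float, pH: float) -> float:
    """Mean protonation-state charge of one titratable group."""
    if kind == "acid":
        return -1.0 / (1.0 + 10.0 ** (pka - pH))
    return 1.0 / (1.0 + 10.0 ** (pH - pka))


def charge_profile(residues, pH: float, pka_table: dict | None = None,
                   include_termini: bool = False) -> ChargeProfile:
    """Henderson-Hasselbalch mean charge per titratable residue at ``pH``.

    ``residues`` may be a Structure, a Selection, a list of residue objects,
    or a one-letter sequence string.  This is a qualitative surrogate for a
    Poisson-Boltzmann calculation: intrinsic pKa values, no coupling between
    sites.
    """
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH {pH} outside [0, 14]")
    table = dict(PKA_TABLE)
    if pka_table:
        table.update(pka_table)
    one_to_three = {"D": "ASP", "E": "GLU", "C": "CYS", "Y": "TYR",
                    "H": "HIS", "K": "LYS", "R": "ARG"}
    items = []
    if isinstance(residues, str):
        for i, aa in enumerate(residues.upper()):
            items.append(("", i + 1, one_to_three.get(aa, aa)))
    elif isinstance(residues, Structure):
        items = [(r.chain_id, r.seq, r.name) for r in residues.residues()
                 if r.record_kind == "polymer"]
    elif isinstance(residues, Selection):
        items = [(k[0], k[1], k[3]) for k in residues.residue_keys()]
    else:
        items = [(r.chain_id, r.seq, r.name) for r in residues]
    per = {}
    for key in items:
        name = key[2]
        if name in table:
            kind, pka = table[name]
            per[key] = mean_charge(kind, pka, pH)
    total = sum(per.values())
    if include_termini and items:
        total += mean_charge("base", PKA_NTERM, pH)
        total += mean_charge("acid", PKA_CTERM, pH)
    return ChargeProfile(pH, per, total)
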