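"""Synthetic inputs with analytically known properties.

Every input class the pipeline consumes can be generated here without
downloads: annotated viral contigs that exercise each genomic-context rule
branch, alignments with controlled residue frequencies and gap rates at the
key active-site columns, and idealized coordinate sets (helices, antiparallel
strand pairs, two-sphere dimers, random coils) whose geometric properties are
known in closed form.  Each generated structure ships with its ground truth
for assertion.

Generation is reproducible: one explicit integer seed per artifact, no global
random state.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field

import numpy as np

from .amg_classifier import (
    AMG_CANDIDATE,
    GENE_LABELS,
    AnnotatedContig,
    GeneRecord,
)
from .conservation_profiler import Alignment
from .structure_io import (
    Atom,
    Chain,
    Residue,
    Structure,
    apply_rigid_transform,
    rotation_from_euler,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# ---------------------------------------------------------------------------
# Annotated contigs
# ---------------------------------------------------------------------------

DEFAULT_GENE_LENGTH = 900
DEFAULT_GENE_GAP = 100


@dataclass(frozen=True)
class ContigSpec:
    """Recipe for a contig with one AMG candidate in a controlled context.

    ``amg_index`` is the 0-based position of the candidate, or ``"edge"`` to
    put it on the first gene.  ``labels_upstream``/``labels_downstream`` give
    the annotation class of each flanking gene (nearest last for upstream,
    nearest first for downstream in contig order).
    """

    n_genes: int
    amg_index: int | str
    labels_upstream: tuple = ()
    labels_downstream: tuple = ()
    circular: bool = False
    contig_id: str = "synthetic_contig"

    def resolved_amg_index(self) -> int:
        return 0 if self.amg_index == "edge" else int(self.amg_index)

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        idx = self.resolved_amg_index()
        if not 0 <= idx < self.n_genes:
            raise ValueError(f"amg_index {idx} out of range")
        if self.amg_index == "edge" and self.labels_upstream:
            raise ValueError("edge AMG cannot have upstream genes")
        if len(self.labels_upstream) != idx:
            raise ValueError("labels_upstream length must equal amg_index")
        if len(self.labels_downstream) != self.n_genes - idx - 1:
            raise ValueError("labels_downstream length inconsistent with n_genes")
        bad = (set(self.labels_upstream) | set(self.labels_downstream)) - GENE_LABELS
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}")


def make_contig(spec: ContigSpec, gene_length: int = DEFAULT_GENE_LENGTH,
                gap: int = DEFAULT_GENE_GAP) -> AnnotatedContig:
    """Realize a spec as an AnnotatedContig.

    Genes are consecutive non-overlapping forward-strand intervals; gene i
    occupies ``[1 + i*(gene_length+gap), ... + gene_length - 1]``.
    """
    spec.validate()
    idx = spec.resolved_amg_index()
    labels = list(spec.labels_upstream) + [AMG_CANDIDATE] + \
        list(spec.labels_downstream)
    genes = []
    for i, label in enumerate(labels):
        start = 1 + i * (gene_length + gap)
        genes.append(GeneRecord(spec.contig_id, i, start,
                                start + gene_length - 1, "+",
                                frozenset({label})))
    length = genes[-1].end + gap
    contig = AnnotatedContig(spec.contig_id, length, genes, spec.circular)
    assert contig.amg_indices() == [idx]
    return contig


def write_contig_table(contigs, path) -> None:
    """Write contigs as the tab-delimited per-gene annotation table."""
    import pandas as pd
    rows = []
    for c in contigs:
        for g in c.genes:
            rows.append({"contig_id": c.contig_id, "gene_index": g.index,
                         "start": g.start, "end": g.end, "strand": g.strand,
                         "label": ",".join(sorted(g.labels)),
                         "contig_length": c.length, "circular": c.circular})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Alignments with controlled column statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MsaSpec:
    """Recipe for an alignment with planted key-column frequencies.

    ``residue_distribution`` maps column index -> {residue: probability};
    columns without an entry are filled with ``background``.  ``gap_rate``
    maps column index -> probability of a gap in that column.
    """

    n_sequences: int
    n_columns: int
    key_columns: tuple
    residue_distribution: dict = field(default_factory=dict)
    gap_rate: dict = field(default_factory=dict)
    background: str = "A"
    seed: int = 0

    def validate(self) -> None:
        if self.n_sequences < 1 or self.n_columns < 1:
            raise ValueError("n_sequences and n_columns must be positive")
        cols = list(self.key_columns)
        if sorted(set(cols)) != cols:
            raise ValueError("key columns must be distinct and increasing")
        if cols and (cols[0] < 0 or cols[-1] >= self.n_columns):
            raise ValueError("key columns outside alignment")
        for col, dist in self.residue_distribution.items():
            if not 0 <= col < self.n_columns:
                raise ValueError(f"distribution column {col} out of range")
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"column {col} probabilities sum to {total}")
        for col, rate in self.gap_rate.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"gap rate {rate} outside [0, 1]")


def make_msa(spec: MsaSpec) -> Alignment:
    """Sample an alignment whose empirical column frequencies converge to the
    planted distribution as ``n_sequences`` grows; deterministic under seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    columns = []
    for col in range(spec.n_columns):
        dist = spec.residue_distribution.get(col)
        if dist:
            residues = sorted(dist)
            probs = np.array([dist[r] for r in residues])
            drawn = rng.choice(residues, size=spec.n_sequences,
                               p=probs / probs.sum())
        else:
            drawn = np.full(spec.n_sequences, spec.background)
        rate = spec.gap_rate.get(col, 0.0)
        if rate > 0:
            gaps = rng.random(spec.n_sequences) < rate
            drawn = np.where(gaps, "-", drawn)
        columns.append(drawn)
    matrix = np.stack(columns, axis=1)
    ids = [f"seq{i + 1:04d}" for i in range(spec.n_sequences)]
    return Alignment(ids, ["".join(row) for row in matrix])


# ---------------------------------------------------------------------------
# Idealized coordinate sets
# ---------------------------------------------------------------------------

# Standard backbone geometry (lengths in Angstrom, angles in degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA_TRANS = 180.0

HELIX_PHI_PSI = (-57.0, -47.0)
EXTENDED_PHI_PSI = (180.0, 180.0)

#: Chothia-style radius used for the two-sphere dimer pseudo-atoms.
TWO_SPHERE_ELEMENT = "C"
TWO_SPHERE_RADIUS = 1.87


@dataclass(frozen=True)
class GeometrySpec:
    """Recipe for an idealized coordinate set.

    ``kind``: ``ideal_helix`` (phi/psi -57/-47), ``ideal_sheet_pair`` (two
    antiparallel extended strands with engineered inter-strand H-bonds),
    ``two_sphere_dimer`` (two one-atom chains at controlled separation, for
    SASA closed forms) or ``random_coil``.  ``rigid_transform`` is
    (rx, ry, rz, tx, ty, tz) with rotations in degrees; ``noise_sigma`` adds
    iid Gaussian noise per coordinate.
    """

    kind: str
    n_residues: int = 12
    separation: float = 8.0         # two_sphere_dimer centre distance
    rigid_transform: tuple = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    noise_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        kinds = {"ideal_helix", "ideal_sheet_pair", "two_sphere_dimer",
                 "random_coil"}
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {sorted(kinds)}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.kind != "two_sphere_dimer" and self.n_residues < 2:
            raise ValueError("need at least 2 residues")


@dataclass
class GeneratedStructure:
    """A synthetic structure together with its analytically known properties."""

    structure: Structure
    ground_truth: dict


def _place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Internal-to-Cartesian (NeRF): position d given atoms a-b-c, the c-d
    bond length, the b-c-d angle and the a-b-c-d torsion (degrees)."""
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * math.cos(ang),
                   bond * math.cos(tor) * math.sin(ang),
                   bond * math.sin(tor) * math.sin(ang)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_backbone(phi_psi, chain_id: str = "A", start_seq: int = 1,
                   res_name: str = "ALA") -> Chain:
    """Build an N/CA/C/O backbone chain from a list of (phi, psi) pairs.

    The first residue's phi and the geometry of the chain start are fixed by
    convention (phi of residue 1 has no effect); the last psi only orients
    the final carbonyl.
    """
    coords = []  # per residue: dict name -> xyz
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(180.0 - ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, len(phi_psi)):
        prev = coords[-1]
        psi_prev = phi_psi[i - 1][1]
        n = _place_atom(prev["N"], prev["CA"], prev["C"],
                        BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca = _place_atom(prev["CA"], prev["C"], n,
                         BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
        c = _place_atom(prev["C"], n, ca,
                        BOND_CA_C, ANGLE_N_CA_C, phi_psi[i][0])
        coords.append({"N": n, "CA": ca, "C": c})
    # carbonyl oxygens: in the peptide plane, trans to the next N
    for i, res in enumerate(coords):
        psi = phi_psi[i][1]
        res["O"] = _place_atom(res["N"], res["CA"], res["C"],
                               BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
    chain = Chain(chain_id)
    serial = 0
    for i, res in enumerate(coords):
        r = Residue(res_name, start_seq + i, "", chain_id)
        for name in ("N", "CA", "C", "O"):
            serial += 1
            element = name[0]
            r.atoms.append(Atom(serial, name, element, "", res_name, chain_id,
                                start_seq + i, "", res[name]))
        chain.residues.append(r)
    return chain


BETA_PHI_PSI = (-139.0, 135.0)


def _sheet_pair_chains(n_residues: int):
    import copy
    return copy.deepcopy(_sheet_pair_chains_cached(n_residues))


@functools.lru_cache(maxsize=8)
def _sheet_pair_chains_cached(n_residues: int):
    """Two antiparallel beta strands with canonical inter-strand H-bonds.

    Strand B is a rigid copy of strand A whose placement is found by a
    deterministic least-squares fit: the narrow-pair residues (i, n-1-i for
    even i, the antiparallel register) are pulled to N...O = 2.9 A in both
    directions with the reconstructed amide hydrogens 1.9 A from the
    acceptor, under a C-alpha clash penalty.  Each engineered bond therefore
    clears the 3.5 A heavy-atom criterion by a wide margin and satisfies the
    Kabsch-Sander energy criterion.
    """
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    n = n_residues
    strand_a = build_backbone([BETA_PHI_PSI] * n, "A")
    res = strand_a.residues
    N = np.array([r.atom("N").xyz for r in res])
    CA = np.array([r.atom("CA").xyz for r in res])
    C = np.array([r.atom("C").xyz for r in res])
    O = np.array([r.atom("O").xyz for r in res])
    H = np.full_like(N, np.nan)
    for j in range(1, n):
        co = C[j - 1] - O[j - 1]
        H[j] = N[j] + co / np.linalg.norm(co)
    narrow = [(i, n - 1 - i) for i in range(0, n, 2) if i != n - 1 - i]

    def loss(p):
        R = Rotation.from_rotvec(p[:3]).as_matrix()
        t = p[3:]
        bN, bO, bC = N @ R.T + t, O @ R.T + t, C @ R.T + t
        bH = np.full_like(bN, np.nan)
        for j in range(1, n):
            co = bC[j - 1] - bO[j - 1]
            bH[j] = bN[j] + co / np.linalg.norm(co)
        val = 0.0
        for i, j in narrow:
            val += (np.linalg.norm(N[i] - bO[j]) - 2.9) ** 2
            val += (np.linalg.norm(bN[j] - O[i]) - 2.9) ** 2
            if not np.isnan(H[i]).any():
                val += (np.linalg.norm(H[i] - bO[j]) - 1.9) ** 2
            if not np.isnan(bH[j]).any():
                val += (np.linalg.norm(bH[j] - O[i]) - 1.9) ** 2
        bCA = CA @ R.T + t
        d = np.linalg.norm(CA[:, None, :] - bCA[None, :, :], axis=2)
        val += float(np.sum(np.clip(4.0 - d, 0.0, None) ** 2))
        return val

    rot0 = Rotation.from_euler("z", 180, degrees=True).as_rotvec()
    best = None
    for dy in (4.5, 5.0):
        for dx in (-2.0, 0.0, 2.0):
            p0 = np.concatenate([rot0, [dx, dy, 0.0]])
            fit = minimize(loss, p0, method="Nelder-Mead",
                           options=dict(maxiter=4000, fatol=1e-12, xatol=1e-9))
            if best is None or fit.fun < best.fun:
                best = fit
    R = Rotation.from_rotvec(best.x[:3]).as_matrix()
    t = best.x[3:]
    strand_b = build_backbone([BETA_PHI_PSI] * n, "B", start_seq=n + 10)
    for r in strand_b.residues:
        for a in r.atoms:
            a.xyz = R @ a.xyz + t
    # ground truth: the engineered narrow-pair N...O bonds, both directions
    engineered = []
    b_res = strand_b.residues
    for i, j in narrow:
        d1 = float(np.linalg.norm(res[i].atom("N").xyz - b_res[j].atom("O").xyz))
        d2 = float(np.linalg.norm(b_res[j].atom("N").xyz - res[i].atom("O").xyz))
        engineered.append((("A", res[i].seq), ("B", b_res[j].seq), d1))
        engineered.append((("B", b_res[j].seq), ("A", res[i].seq), d2))
    return strand_a, strand_b, engineered


def make_structure(spec: GeometrySpec) -> GeneratedStructure:
    """Generate an idealized structure plus its known property values."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    truth: dict = {"kind": spec.kind}
    if spec.kind == "ideal_helix":
        chain = build_backbone([HELIX_PHI_PSI] * spec.n_residues)
        structure = Structure("ideal_helix", [chain])
        truth["phi_psi"] = HELIX_PHI_PSI
        truth["n_residues"] = spec.n_residues
    elif spec.kind == "random_coil":
        phi_psi = [(float(rng.uniform(-180, 180)), float(rng.uniform(-180, 180)))
                   for _ in range(spec.n_residues)]
        chain = build_backbone(phi_psi)
        structure = Structure("random_coil", [chain])
        truth["phi_psi_list"] = phi_psi
    elif spec.kind == "ideal_sheet_pair":
        a, b, engineered = _sheet_pair_chains(spec.n_residues)
        structure = Structure("ideal_sheet_pair", [a, b])
        truth["hbond_pairs"] = engineered
        truth["n_residues_per_strand"] = spec.n_residues
    else:  # two_sphere_dimer
        d = float(spec.separation)
        atoms = []
        chains = []
        for cid, x in (("A", 0.0), ("B", d)):
            atom = Atom(len(atoms) + 1, "C1", TWO_SPHERE_ELEMENT, "", "SPH",
                        cid, 1, "", np.array([x, 0.0, 0.0]))
            atom.record_kind = "ligand"
            res = Residue("SPH", 1, "", cid, [atom])
            chains.append(Chain(cid, [res]))
            atoms.append(atom)
        structure = Structure("two_sphere_dimer", chains)
        truth.update(two_sphere_ground_truth(d))
    R = rotation_from_euler(*spec.rigid_transform[:3])
    t = np.array(spec.rigid_transform[3:6], dtype=float)
    structure = apply_rigid_transform(structure, R, t)
    if spec.noise_sigma > 0:
        for a in structure.atoms():
            a.xyz = a.xyz + rng.normal(0.0, spec.noise_sigma, size=3)
    truth["rigid_transform"] = spec.rigid_transform
    truth["noise_sigma"] = spec.noise_sigma
    return GeneratedStructure(structure, truth)


# ---------------------------------------------------------------------------
# Synthetic double-psi barrel (strand layer only)
# ---------------------------------------------------------------------------

CA_SPACING = 3.3   # C-alpha step along an idealized strand axis
SHEET_SPACING = 4.8


def _ca_strand(start, direction, n) -> np.ndarray:
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    return np.array([np.asarray(start, dtype=float) + i * CA_SPACING * d
                     for i in range(n)])


def make_psi_barrel_motif(twofold: bool = True):
    """Strand-level C-alpha model of one or two psi-motifs.

    One psi-motif here is a 12-residue strand bent 90 degrees (N-terminal
    half running +z into the sheet plane, C-terminal half along +x), an
    8-residue partner strand antiparallel above it, and a 4-residue short
    strand parallel below it.  With ``twofold=True`` a second motif related
    by an exact 180-degree rotation about z is added so that the two short
    strands form an adjacent antiparallel pair -- a minimal double-psi
    barrel whose pseudo-twofold RMSD is exactly zero.

    Returns ``(motif_assignment, ground_truth)`` where the assignment holds
    the strands (named in sequence order) ready for
    :func:`amgkit.structure_analysis.detect_psi_dpbb`.
    """
    from .structure_analysis import MotifAssignment, StrandElement

    bent = np.concatenate([
        _ca_strand((0.0, 0.0, -5 * CA_SPACING), (0, 0, 1), 6),
        _ca_strand((CA_SPACING, 0.0, 0.0), (1, 0, 0), 6),
    ])
    partner = _ca_strand((6 * CA_SPACING, 0.0, SHEET_SPACING), (-1, 0, 0), 8)
    short = _ca_strand((CA_SPACING, 0.0, -SHEET_SPACING), (1, 0, 0), 4)
    motif1 = [("bent", bent), ("partner", partner), ("short", short)]
    layers = [motif1]
    if twofold:
        Rz = np.diag([-1.0, -1.0, 1.0])
        t = np.array([5 * CA_SPACING, SHEET_SPACING, 0.0])
        layers.append([(role, coords @ Rz.T + t) for role, coords in motif1])
    ca_rows, residues, ss, strands = [], [], [], []
    roles = {}
    idx = 0
    for m, layer in enumerate(layers):
        for role, coords in layer:
            start = idx
            for c in coords:
                ca_rows.append(c)
                residues.append(("A", idx + 1, "ALA"))
                ss.append("E")
                idx += 1
            name = f"beta{len(strands) + 1}"
            strands.append(StrandElement(name, start, idx - 1))
            roles[name] = (m + 1, role)
            # coil spacer well away from the barrel
            ca_rows.append(coords[-1] + np.array([0.0, 40.0 + 10.0 * idx, 0.0]))
            residues.append(("A", idx + 1, "ALA"))
            ss.append("-")
            idx += 1
    motif = MotifAssignment(residues, "".join(ss), np.array(ca_rows),
                            strands=strands)
    truth = {
        "roles": roles,
        "n_motifs": len(layers),
        "dpbb_strands": sorted(roles) if twofold else [],
        "pseudo_twofold_rmsd": 0.0 if twofold else None,
    }
    return motif, truth


# ---------------------------------------------------------------------------
# Closed-form SASA ground truth
# ---------------------------------------------------------------------------


def sphere_sasa(radius: float, probe: float = 1.4) -> float:
    """Accessible area of an isolated sphere: 4 pi (r + probe)^2."""
    return 4.0 * math.pi * (radius + probe) ** 2


def two_sphere_ground_truth(separation: float,
                            radius: float = TWO_SPHERE_RADIUS,
                            probe: float = 1.4) -> dict:
    """Closed-form burial for two equal spheres at centre distance ``d``.

    Each solvent sphere of radius ``R = radius + probe`` loses a spherical
    cap of area ``2 pi R h`` with ``h = R - d/2`` when the spheres overlap
    (d < 2R); separated spheres lose nothing.
    """
    R = radius + probe
    isolated = 4.0 * math.pi * R ** 2
    if separation >= 2.0 * R:
        buried = 0.0
    elif separation <= 0.0:
        buried = isolated
    else:
        h = R - separation / 2.0
        buried = 2.0 * math.pi * R * h
    return {
        "separation": separation,
        "radius": radius,
        "probe": probe,
        "sasa_isolated_per_sphere": isolated,
        "buried_per_sphere": buried,
        "sasa_complex_per_sphere": isolated - buried,
        "buried_fraction": buried / isolated,
    }
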