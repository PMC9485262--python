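"""Superposition, SASA, H-bonds, dihedrals, secondary structure, motifs,
active-site cluster, subsites and charge profiles."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from amgkit.structure_analysis import (
    assign_secondary_structure,
    charge_profile,
    classify_rama_region,
    compute_phi_psi,
    detect_hbonds,
    detect_psi_dpbb,
    dihedral,
    find_acidic_cluster,
    interface_burial,
    kabsch,
    kabsch_superpose,
    map_subsites,
    mean_charge,
    rama_percentages,
    RamaRecord,
    shrake_rupley_sasa,
    sphere_points,
)
from amgkit.structure_io import select, to_pdb_string
from amgkit.synthetic_data import (
    GeometrySpec,
    make_psi_barrel_motif,
    make_structure,
    two_sphere_ground_truth,
)
from conftest import build_residue, single_chain_structure


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------


def test_rigid_copy_superposes_to_zero_rmsd(ideal_helix):
    moved = make_structure(GeometrySpec("ideal_helix", n_residues=12,
                                        rigid_transform=(25, -40, 110, 5, 6, 7)))
    res = kabsch_superpose(moved.structure, ideal_helix.structure)
    assert res.rmsd <= 1e-8
    assert res.n_pairs == 12
    assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)


def test_kabsch_agrees_with_scipy_oracle():
    rng = np.random.default_rng(17)
    P = rng.normal(size=(40, 3)) * 8
    Q = rng.normal(size=(40, 3)) * 8
    mine = kabsch(P, Q)
    # independent route: quaternion-based estimator on centred sets
    rot, rssd = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
    assert np.allclose(mine.rotation, rot.as_matrix(), atol=1e-8)
    assert mine.rmsd == pytest.approx(rssd / math.sqrt(len(P)), rel=1e-9)


def test_noise_recovery_rmsd_matches_chi_expectation():
    """RMSD of a noisy copy approaches sigma * sqrt(3) for iid noise."""
    rng = np.random.default_rng(23)
    sigma = 0.4
    P = rng.normal(size=(500, 3)) * 15
    r = kabsch(P + rng.normal(0, sigma, P.shape), P)
    assert r.rmsd == pytest.approx(sigma * math.sqrt(3), rel=0.08)


def test_rmsd_invariant_under_rigid_motion_of_either_input():
    rng = np.random.default_rng(2)
    P = rng.normal(size=(20, 3))
    Q = P + rng.normal(0, 0.3, P.shape)
    base = kabsch(P, Q).rmsd
    R = Rotation.from_euler("zyx", [11, 22, 33], degrees=True).as_matrix()
    assert kabsch(P @ R.T + 4.0, Q).rmsd == pytest.approx(base, abs=1e-9)
    assert kabsch(P, Q @ R.T - 2.0).rmsd == pytest.approx(base, abs=1e-9)


def test_kabsch_rejects_degenerate_input():
    line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
    with pytest.raises(ValueError, match="collinear"):
        kabsch(line, line)
    with pytest.raises(ValueError, match="at least 3"):
        kabsch(line[:2], line[:2])


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------


def lone_atom_structure():
    res = build_residue("SPH", 1, "A", {"C1": ("C", (0, 0, 0))}, kind="ligand")
    return single_chain_structure([res])


def test_lone_atom_area_is_closed_form():
    result = shrake_rupley_sasa(lone_atom_structure())
    exact = 4 * math.pi * (1.87 + 1.4) ** 2
    assert result.total == pytest.approx(exact, rel=5e-3)


def test_two_sphere_burial_matches_cap_formula(two_sphere_touching):
    truth = two_sphere_touching.ground_truth
    result = shrake_rupley_sasa(two_sphere_touching.structure)
    per_residue = result.per_residue()
    for area in per_residue.values():
        assert area == pytest.approx(truth["sasa_complex_per_sphere"], rel=5e-3)


def test_sasa_matches_monte_carlo_oracle():
    """Lattice SASA within 1% of a random-point Monte-Carlo estimate."""
    gen = make_structure(GeometrySpec("random_coil", n_residues=13, seed=31))
    atoms = list(gen.structure.atoms())
    assert len(atoms) >= 50
    result = shrake_rupley_sasa(gen.structure)

    rng = np.random.default_rng(123)
    radii = {"N": 1.65, "C": 1.87, "O": 1.40}
    xyz = np.array([a.xyz for a in result.atoms])
    R = np.array([radii[a.element] for a in result.atoms]) + 1.4
    mc_total = 0.0
    n_pts = 40_000
    for i in range(len(xyz)):
        pts = rng.normal(size=(n_pts, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts = xyz[i] + R[i] * pts
        occluded = np.zeros(n_pts, dtype=bool)
        for j in range(len(xyz)):
            if j != i:
                occluded |= np.sum((pts - xyz[j]) ** 2, axis=1) < R[j] ** 2
        mc_total += 4 * math.pi * R[i] ** 2 * (1 - occluded.mean())
    assert result.total == pytest.approx(mc_total, rel=0.01)


def test_sasa_total_invariant_under_rigid_motion(ideal_helix):
    base = shrake_rupley_sasa(ideal_helix.structure).total
    moved = make_structure(GeometrySpec("ideal_helix", n_residues=12,
                                        rigid_transform=(30, 60, 90, 1, 2, 3)))
    assert shrake_rupley_sasa(moved.structure).total == pytest.approx(
        base, rel=0.01)


def test_unknown_element_requires_override():
    res = build_residue("UNK", 1, "A", {"X1": ("XX", (0, 0, 0))}, kind="ligand")
    s = single_chain_structure([res])
    with pytest.raises(KeyError, match="radius"):
        shrake_rupley_sasa(s)
    result = shrake_rupley_sasa(s, radii_override={"XX": 2.0})
    assert result.total == pytest.approx(4 * math.pi * 3.4 ** 2, rel=5e-3)


def test_sphere_lattice_is_uniform_unit_set():
    pts = sphere_points(960)
    assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
    assert np.linalg.norm(pts.mean(axis=0)) < 0.01


# ---------------------------------------------------------------------------
# Interface burial
# ---------------------------------------------------------------------------


def test_separated_monomers_bury_nothing(two_sphere_far):
    rep = interface_burial(two_sphere_far.structure, "A", "B")
    assert rep.buried_area == {"A": 0.0, "B": 0.0}
    assert rep.buried_fraction == {"A": 0.0, "B": 0.0}
    assert rep.contact_residues == {"A": [], "B": []}


def test_dimer_burial_matches_analytic_cap(two_sphere_touching):
    truth = two_sphere_touching.ground_truth
    rep = interface_burial(two_sphere_touching.structure, "A", "B")
    for cid in "AB":
        assert rep.buried_area[cid] == pytest.approx(
            truth["buried_per_sphere"], rel=0.01)
        assert rep.buried_fraction[cid] == pytest.approx(
            truth["buried_fraction"], rel=0.01)
        assert rep.contact_residues[cid] == [(cid, 1, "", "SPH")]


def test_interface_requires_distinct_chains(two_sphere_touching):
    with pytest.raises(ValueError):
        interface_burial(two_sphere_touching.structure, "A", "A")


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------


def test_sheet_fixture_yields_exactly_the_engineered_bonds(sheet_pair):
    bonds = detect_hbonds(sheet_pair.structure)
    inter = {((h.donor.chain_id, h.donor.res_seq),
              (h.acceptor.chain_id, h.acceptor.res_seq))
             for h in bonds if h.hb_class == "mainchain-mainchain"
             and h.donor.chain_id != h.acceptor.chain_id}
    engineered = {(d, a) for d, a, _ in sheet_pair.ground_truth["hbond_pairs"]}
    assert inter == engineered


def test_distant_atoms_make_no_bond():
    w1 = build_residue("HOH", 1, "A", {"O": ("O", (0, 0, 0))}, kind="water")
    w2 = build_residue("HOH", 2, "A", {"O": ("O", (5, 0, 0))}, kind="water")
    assert detect_hbonds(single_chain_structure([w1, w2])) == []
    w3 = build_residue("HOH", 3, "A", {"O": ("O", (2.9, 0, 0))}, kind="water")
    bonds = detect_hbonds(single_chain_structure([w1, w3]))
    assert len(bonds) == 2  # both waters can donate
    assert all(b.hb_class == "to-water" for b in bonds)


def test_angle_criterion_rejects_backtracking_geometry():
    # acceptor placed on the same side as the antecedent: angle < 90
    donor_res = build_residue("SER", 1, "A", {
        "OG": ("O", (0.0, 0.0, 0.0)), "CB": ("C", (1.5, 0.0, 0.0))})
    acceptor = build_residue("HOH", 2, "A", {"O": ("O", (2.0, 1.5, 0.0))},
                             kind="water")
    bonds = detect_hbonds(single_chain_structure([donor_res, acceptor]))
    assert not any(h.donor.name == "OG" for h in bonds)


# ---------------------------------------------------------------------------
# Dihedrals and Ramachandran
# ---------------------------------------------------------------------------


def reference_dihedral(p0, p1, p2, p3):
    """Independent normal-vector formulation with triple-product sign."""
    p0, p1, p2, p3 = map(np.asarray, (p0, p1, p2, p3))
    n1 = np.cross(p1 - p0, p2 - p1)
    n2 = np.cross(p2 - p1, p3 - p2)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = math.degrees(math.acos(np.clip(cosang, -1, 1)))
    if np.dot(np.cross(n1, n2), p2 - p1) < 0:
        ang = -ang
    return ang


@pytest.mark.parametrize("angle", [-150.0, -60.0, -1.0, 0.0, 45.0, 179.0])
def test_dihedral_matches_analytic_formula(angle):
    rad = math.radians(angle)
    p0 = np.array([0.0, 1.0, 0.0])
    p1 = np.array([0.0, 0.0, 0.0])
    p2 = np.array([1.5, 0.0, 0.0])
    p3 = p2 + np.array([0.3, math.cos(rad), math.sin(rad)])
    got = dihedral(p0, p1, p2, p3)
    assert got == pytest.approx(reference_dihedral(p0, p1, p2, p3), abs=1e-6)


def test_helix_dihedrals_and_rama(ideal_helix):
    recs = compute_phi_psi(ideal_helix.structure.chains[0])
    inner = [r for r in recs if r.phi is not None and r.psi is not None]
    for r in inner:
        assert r.phi == pytest.approx(-57.0, abs=1.0)
        assert r.psi == pytest.approx(-47.0, abs=1.0)
    pct = rama_percentages(recs)
    assert pct["favored"] == 100.0
    assert pct["n"] == len(inner)


def test_chain_break_suppresses_angles():
    gen1 = make_structure(GeometrySpec("ideal_helix", n_residues=4))
    gen2 = make_structure(GeometrySpec("ideal_helix", n_residues=4,
                                       rigid_transform=(0, 0, 0, 50, 0, 0)))
    chain = gen1.structure.chains[0]
    far = gen2.structure.chains[0]
    for r in far.residues:
        r.seq += 4
        for a in r.atoms:
            a.res_seq += 4
    chain.residues.extend(far.residues)
    recs = compute_phi_psi(chain)
    assert recs[3].psi is None and recs[4].phi is None  # across the break


def test_one_outlier_in_ten_gives_90_10():
    recs = [RamaRecord("A", i, "ALA", -57.0, -47.0, "general")
            for i in range(9)]
    recs.append(RamaRecord("A", 9, "ALA", 60.0, -170.0, "general"))
    pct = rama_percentages(recs)
    assert pct["favored"] == pytest.approx(90.0)
    assert pct["outlier"] == pytest.approx(10.0)


def test_region_classes_use_residue_identity():
    # alpha-L is acceptable for glycine but an outlier for proline
    gly = RamaRecord("A", 1, "GLY", 60.0, 30.0, "glycine")
    pro = RamaRecord("A", 2, "PRO", 60.0, 30.0, "proline")
    assert classify_rama_region(gly) in {"favored", "allowed"}
    assert classify_rama_region(pro) == "outlier"


# ---------------------------------------------------------------------------
# Secondary structure
# ---------------------------------------------------------------------------


def mdtraj_ss(structure):
    import tempfile, os
    import mdtraj
    path = tempfile.mktemp(suffix=".pdb")
    try:
        with open(path, "w") as fh:
            fh.write(to_pdb_string(structure))
        codes = mdtraj.compute_dssp(mdtraj.load(path), simplified=False)[0]
    finally:
        if os.path.exists(path):
            os.remove(path)
    return "".join(c if c in "HGEB" else "-" for c in codes)


def test_helix_assignment_matches_dssp_oracle(ideal_helix):
    motif = assign_secondary_structure(ideal_helix.structure.chains[0])
    helical = motif.ss.count("H") + motif.ss.count("G")
    assert helical >= 8  # central residues all helical
    assert motif.ss == mdtraj_ss(ideal_helix.structure)


def test_sheet_assignment_two_strands_antiparallel(sheet_pair):
    motif = assign_secondary_structure(sheet_pair.structure)
    assert len(motif.strands) == 2
    assert all(k == "antiparallel" for _, _, k in motif.bridge_pairs)
    assert motif.beta_bridges == []
    assert motif.ss == mdtraj_ss(sheet_pair.structure)


def test_assignment_invariant_under_rigid_motion(sheet_pair):
    from amgkit.structure_io import apply_rigid_transform, rotation_from_euler
    moved = apply_rigid_transform(sheet_pair.structure,
                                  rotation_from_euler(15, 75, -30),
                                  [3.0, -8.0, 2.0])
    assert assign_secondary_structure(moved).ss == \
        assign_secondary_structure(sheet_pair.structure).ss


# ---------------------------------------------------------------------------
# psi / DPBB motifs
# ---------------------------------------------------------------------------


def test_twofold_barrel_detected_with_zero_rmsd():
    motif, truth = make_psi_barrel_motif()
    out = detect_psi_dpbb(motif)
    assert out.dpbb == truth["dpbb_strands"]
    assert len(out.psi_motifs) == 2
    assert out.psi_motifs[0].strands().isdisjoint(out.psi_motifs[1].strands())
    assert out.pseudo_twofold_rmsd == pytest.approx(0.0, abs=1e-9)


def test_helix_has_no_psi_motif(ideal_helix):
    motif = assign_secondary_structure(ideal_helix.structure.chains[0])
    out = detect_psi_dpbb(motif)
    assert out.psi_motifs == [] and out.dpbb == []


# ---------------------------------------------------------------------------
# Acidic cluster
# ---------------------------------------------------------------------------


def asp(seq, centre):
    cx, cy, cz = centre
    return build_residue("ASP", seq, "A", {
        "CG": ("C", (cx, cy, cz + 1.2)),
        "OD1": ("O", (cx - 0.5, cy - 0.5, cz)),
        "OD2": ("O", (cx + 0.5, cy + 0.5, cz)),
    })


def test_planted_adjacent_pair_forms_top_cluster():
    residues = [asp(10, (0, 0, 0)), asp(20, (4, 0, 0)), asp(99, (50, 50, 50))]
    s = single_chain_structure(residues)
    clusters = find_acidic_cluster(s, d_max=6.0)
    assert clusters[0] == [("A", 10, "ASP"), ("A", 20, "ASP")]
    assert clusters[1] == [("A", 99, "ASP")]
    # oracle: pairwise centroid distance really is below the linkage cutoff
    c1 = residues[0].centroid({"OD1", "OD2"})
    c2 = residues[1].centroid({"OD1", "OD2"})
    assert np.linalg.norm(c1 - c2) <= 6.0


def test_no_acidic_residues_gives_empty(ideal_helix):
    assert find_acidic_cluster(ideal_helix.structure) == []


# ---------------------------------------------------------------------------
# Substrate subsites
# ---------------------------------------------------------------------------


def sugar(seq, x0):
    return build_residue("GCS", seq, "S", {
        "C1": ("C", (x0, 0.0, 0.0)),
        "C2": ("C", (x0 + 0.8, 1.2, 0.0)),
        "N2": ("N", (x0 + 0.8, 2.65, 0.0)),
        "O4": ("O", (x0 + 2.0, 0.0, 0.0)),
        "O6": ("O", (x0, -1.4, 0.0)),
    }, kind="ligand")


def glcn_complex():
    """Three beta-1,4-linked glucosamines plus planted protein contacts."""
    sugars = [sugar(201, 0.0), sugar(202, 3.4), sugar(203, 6.8)]
    glu157 = build_residue("GLU", 157, "A", {
        "CD": ("C", (0.0, -5.5, 0.0)),
        "OE1": ("O", (0.0, -4.3, 0.0)),   # 2.9 A from GlcN-1 O6
        "OE2": ("O", (1.2, -5.9, 0.0)),
    })
    asp36 = build_residue("ASP", 36, "A", {
        "CG": ("C", (4.2, 6.6, 0.0)),
        "OD1": ("O", (4.2, 5.55, 0.0)),   # 2.9 A from GlcN-2 N2
        "OD2": ("O", (5.3, 7.0, 0.0)),
    })
    asp148 = build_residue("ASP", 148, "A", {
        "CG": ("C", (2.0, 5.6, 2.2)),
        "OD1": ("O", (2.0, 4.6, 1.5)),    # 3.3 A from GlcN-2 N2
        "OD2": ("O", (0.9, 6.0, 1.5)),
    })
    ala90 = build_residue("ALA", 90, "A", {
        "C": ("C", (5.0, 2.65, 4.2)),
        "O": ("O", (5.0, 2.65, 3.0)),     # carbonyl 3.0 A from GlcN-2 N2
    })
    from amgkit.structure_io import Chain, Structure
    return Structure("complex", [
        Chain("A", [asp36, ala90, asp148, glu157]),
        Chain("S", sugars),
    ])


def test_three_sugar_chain_is_labelled_from_the_catalytic_anchor():
    smap = map_subsites(glcn_complex(), {"GCS"}, catalytic_residue=157)
    assert [k[1] for k in smap.order] == [201, 202, 203]  # reducing end first
    assert [smap.subsites[k] for k in smap.order] == [-1, -2, -3]


def test_central_sugar_contacts_include_planted_partners():
    smap = map_subsites(glcn_complex(), {"GCS"}, catalytic_residue=157)
    key2 = smap.order[1]
    hb_partners = set()
    for h in smap.contacts[key2]["hbonds"]:
        for a in (h.donor, h.acceptor):
            if a.record_kind == "polymer":
                hb_partners.add((a.res_name, a.res_seq, a.name))
    assert ("ASP", 36, "OD1") in hb_partners
    assert ("ASP", 148, "OD1") in hb_partners
    assert ("ALA", 90, "O") in hb_partners   # main-chain carbonyl
    near = {(k[1]) for k in smap.contacts[key2]["near"]}
    assert {36, 90, 148} <= near


def test_single_sugar_near_catalytic_residue_is_minus_one():
    from amgkit.structure_io import Chain, Structure
    s = Structure("single", [
        Chain("A", [build_residue("GLU", 157, "A",
                                  {"OE1": ("O", (0, -4.3, 0)),
                                   "CD": ("C", (0, -5.5, 0))})]),
        Chain("S", [sugar(201, 0.0)]),
    ])
    smap = map_subsites(s, {"GCS"}, catalytic_residue=157)
    assert list(smap.subsites.values()) == [-1]


def test_no_sugars_is_an_error(ideal_helix):
    with pytest.raises(ValueError, match="no sugar"):
        map_subsites(ideal_helix.structure, {"GCS"}, 5)


# ---------------------------------------------------------------------------
# Charge vs pH
# ---------------------------------------------------------------------------


def test_acid_at_its_pka_carries_half_charge():
    assert mean_charge("acid", 3.9, 3.9) == pytest.approx(-0.5)
    assert mean_charge("base", 10.5, 10.5) == pytest.approx(0.5)


def test_toy_peptide_total_matches_hand_sum():
    profile = charge_profile("DEKH", 7.0)
    expected = (-1 / (1 + 10 ** (3.9 - 7.0))
                - 1 / (1 + 10 ** (4.1 - 7.0))
                + 1 / (1 + 10 ** (7.0 - 10.5))
                + 1 / (1 + 10 ** (7.0 - 6.0)))
    assert profile.total == pytest.approx(expected)


def test_cleft_more_negative_at_optimum_than_at_crystallization_ph():
    """The D-D-D-E cluster carries more negative charge at pH 5.5 than 4.6."""
    cleft = "DDDE"
    assert charge_profile(cleft, 5.5).total < charge_profile(cleft, 4.6).total


def test_charge_is_monotone_in_ph_and_bounded():
    values = [charge_profile("D", ph).total for ph in (2, 4, 6, 8, 10)]
    assert all(a > b for a, b in zip(values, values[1:]))
    assert all(-1 < v < 0 for v in values)
    with pytest.raises(ValueError):
        charge_profile("D", 15.0)


def test_selection_charge_uses_residue_identity(ideal_helix):
    sel = select(ideal_helix.structure, "polymer")
    profile = charge_profile(sel, 7.0)
    assert profile.per_residue == {}  # all-alanine helix has no titratable site
    assert profile.total == 0.0
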