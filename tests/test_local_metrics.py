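"""lDDT, stereochemistry, chi-angle and burial metrics."""
import numpy as np
import pytest
from scipy import special

from templateprobe._geom import random_rotation
from templateprobe.align import ResidueMapping
from templateprobe.errors import MetricUndefinedError
from templateprobe.local_metrics import (
    LDDTParams,
    burial,
    chi_angles,
    chi_mae,
    lddt,
    stereochemistry_check,
)
from templateprobe.perturb import gaussian_noise
from templateprobe.structio import Atom, Chain, Residue, Structure
from templateprobe.synthetic import (
    BackboneSpec,
    RotamerSpec,
    attach_sidechains,
    make_backbone,
)


def _two_residue_structure(d_ref):
    """Two single-atom residues at the given separation."""
    chain = Chain("A", [
        Residue("ALA", 1, atoms=[Atom("CA", "C", [0.0, 0.0, 0.0])]),
        Residue("ALA", 2, atoms=[Atom("CA", "C", [d_ref, 0.0, 0.0])]),
    ])
    return Structure([chain])


# -------------------------------------------------------------------- lDDT

def test_lddt_identity(globule_small):
    mapping = ResidueMapping.identity_map(globule_small.n_residues)
    res = lddt(globule_small, globule_small, mapping)
    assert res.global_score == 1.0
    assert all(v == 1.0 for v in res.per_residue.values())


def test_lddt_exact_threshold_construction():
    # one cross-residue pair whose distance changes by exactly 3 A: only the
    # 4 A tolerance is met -> per-pair (= global) score 1/4
    ref = _two_residue_structure(5.0)
    model = _two_residue_structure(8.0)
    res = lddt(ref, model, ResidueMapping.identity_map(2))
    assert res.global_score == pytest.approx(0.25)
    assert res.n_pairs == 1


def test_lddt_missing_model_atoms_score_zero():
    ref = _two_residue_structure(5.0)
    model = _two_residue_structure(5.0)
    model.chains[0].residues[1].atoms = []  # atom absent in the model
    res = lddt(ref, model, ResidueMapping.identity_map(2))
    assert res.global_score == 0.0


def test_lddt_gaussian_noise_matches_analytic_limit(globule_150):
    mapping = ResidueMapping.identity_map(globule_150.n_residues)
    sigma = 1.0
    values = [lddt(globule_150, gaussian_noise(globule_150, sigma, seed=k),
                   mapping).global_score for k in range(3)]
    # distant-pair limit: delta-d ~ Normal(0, 2 sigma^2)
    analytic = np.mean([special.erf(t / (2.0 * sigma)) for t in (0.5, 1, 2, 4)])
    assert np.mean(values) == pytest.approx(analytic, abs=0.02)


def test_lddt_monotone_in_noise(mixed_full):
    mapping = ResidueMapping.identity_map(mixed_full.n_residues)
    means = []
    for sigma in (0.0, 0.5, 1.0, 2.0, 4.0):
        scores = [lddt(mixed_full, gaussian_noise(mixed_full, sigma, seed=k),
                       mapping).global_score for k in range(10)]
        means.append(np.mean(scores))
    assert all(a >= b - 1e-12 for a, b in zip(means, means[1:]))


def test_lddt_rigid_motion_invariant(globule_small, rng):
    mapping = ResidueMapping.identity_map(globule_small.n_residues)
    model = gaussian_noise(globule_small, 1.0, seed=6)
    base = lddt(globule_small, model, mapping)
    moved = model.copy()
    rot = random_rotation(rng)
    moved.set_coords(moved.coords() @ rot.T + rng.normal(size=3) * 30)
    after = lddt(globule_small, moved, mapping)
    assert after.global_score == pytest.approx(base.global_score, abs=1e-9)
    for k in base.per_residue:
        assert after.per_residue[k] == pytest.approx(base.per_residue[k], abs=1e-9)


def test_lddt_symmetry_resolution_forgives_ring_flip(helix_full):
    model = helix_full.copy()
    flipped = 0
    for res in model.residues:
        if res.resname in ("PHE", "TYR"):
            for a, b in (("CD1", "CD2"), ("CE1", "CE2")):
                ca, cb = res.get(a), res.get(b)
                ca.coord, cb.coord = cb.coord.copy(), ca.coord.copy()
            flipped += 1
    assert flipped > 0
    mapping = ResidueMapping.identity_map(helix_full.n_residues)
    with_sym = lddt(helix_full, model, mapping, LDDTParams(symmetry_resolution=True))
    without = lddt(helix_full, model, mapping, LDDTParams(symmetry_resolution=False))
    assert with_sym.global_score == pytest.approx(1.0, abs=1e-12)
    assert without.global_score < 1.0


def test_lddt_stereo_checks_exclude_broken_sidechains(helix_full):
    model = helix_full.copy()
    # wreck one side chain: stretch its CB far from CA
    res = next(r for r in model.residues if r.resname == "LEU")
    res.get("CB").coord = res.coord("CA") + np.array([8.0, 0.0, 0.0])
    mapping = ResidueMapping.identity_map(helix_full.n_residues)
    loose = lddt(helix_full, model, mapping, LDDTParams(stereo_checks=False))
    strict = lddt(helix_full, model, mapping, LDDTParams(stereo_checks=True))
    # with checks on, the flagged side chain counts as missing -> also
    # non-conserved, but never higher than without checks
    assert strict.global_score <= loose.global_score + 1e-12


def test_lddt_empty_mapping_is_undefined(globule_small):
    with pytest.raises(MetricUndefinedError):
        lddt(globule_small, globule_small, ResidueMapping(pairs=[]))


# --------------------------------------------------- stereochemistry check

def test_stereo_clean_fixture_passes(helix_full):
    assert stereochemistry_check(helix_full) == []


def test_stereo_flags_stretched_bond(helix_full):
    broken = helix_full.copy()
    res = broken.residues[7]
    direction = res.coord("C") - res.coord("CA")
    direction /= np.linalg.norm(direction)
    res.get("C").coord = res.coord("CA") + 2.5 * direction
    flagged = stereochemistry_check(broken)
    assert 7 in flagged
    # the carbonyl moves with C, so only residue 7 and its peptide partner
    # may be implicated
    assert set(flagged) <= {7, 8}


def test_stereo_flags_majority_under_gaussian_noise(mixed_full):
    noisy = gaussian_noise(mixed_full, 1.0, seed=5)
    flagged = stereochemistry_check(noisy)
    assert len(flagged) > 0.5 * mixed_full.n_residues


# -------------------------------------------------------------- chi angles

def test_chi_angles_ala_gly_empty(helix_full):
    for res in helix_full.residues:
        if res.resname in ("ALA", "GLY"):
            assert chi_angles(res) == []


def test_chi_angles_roundtrip_leu():
    s = make_backbone(BackboneSpec(5, "helix", sequence="ALLLA"))
    full = attach_sidechains(s, chi_overrides={("A", 3): (-60.0, 170.0)})
    got = chi_angles(full.residues[2])
    assert got[0] == pytest.approx(-60.0, abs=0.5)
    assert got[1] == pytest.approx(170.0, abs=0.5)


def test_chi_angles_degenerate_geometry_truncates():
    res = Residue("LEU", 1, atoms=[
        Atom("N", "N", [0.0, 0.0, 0.0]),
        Atom("CA", "C", [1.5, 0.0, 0.0]),
        Atom("CB", "C", [3.0, 0.0, 0.0]),   # collinear with N, CA
        Atom("CG", "C", [4.5, 0.0, 0.0]),
    ])
    assert chi_angles(res) == []


# ----------------------------------------------------------------- chi MAE

def test_chi_mae_identity(helix_full):
    mapping = ResidueMapping.identity_map(helix_full.n_residues)
    result = chi_mae(helix_full, helix_full, mapping)
    assert result.overall == 0.0


def test_chi_mae_detects_uniform_chi1_shift():
    backbone = make_backbone(BackboneSpec(20, "strand"))
    ref = attach_sidechains(backbone, repair_clashes=False)
    shifted = {}
    for res in ref.residues:
        chis = chi_angles(res)
        if chis:
            chis = list(chis)
            chis[0] += 10.0
            shifted[("A", res.seqnum)] = chis
    model = attach_sidechains(backbone, chi_overrides=shifted, repair_clashes=False)
    result = chi_mae(ref, model, ResidueMapping.identity_map(20))
    assert result.per_index[1] == pytest.approx(10.0, abs=0.1)
    assert result.per_index[2] == pytest.approx(0.0, abs=0.1)


def test_chi_mae_ring_flip_scores_zero():
    backbone = make_backbone(BackboneSpec(5, "strand", sequence="AFAFA"))
    ref = attach_sidechains(backbone, repair_clashes=False)
    flipped = {}
    for res in ref.residues:
        if res.resname == "PHE":
            chis = list(chi_angles(res))
            chis[1] += 180.0
            flipped[("A", res.seqnum)] = chis
    model = attach_sidechains(backbone, chi_overrides=flipped, repair_clashes=False)
    result = chi_mae(ref, model, ResidueMapping.identity_map(5))
    assert result.per_index[2] == pytest.approx(0.0, abs=0.1)


def test_chi_mae_wraps_full_turns():
    backbone = make_backbone(BackboneSpec(5, "strand", sequence="ALALA"))
    ref = attach_sidechains(backbone, repair_clashes=False)
    wrapped = {}
    for res in ref.residues:
        chis = chi_angles(res)
        if chis:
            wrapped[("A", res.seqnum)] = [c + 360.0 for c in chis]
    model = attach_sidechains(backbone, chi_overrides=wrapped, repair_clashes=False)
    result = chi_mae(ref, model, ResidueMapping.identity_map(5))
    assert result.overall == pytest.approx(0.0, abs=1e-6)


def test_chi_mae_no_comparable_angles_is_undefined():
    s = make_backbone(BackboneSpec(4, "helix", sequence="AGAG"))
    full = attach_sidechains(s)
    with pytest.raises(MetricUndefinedError):
        chi_mae(full, full, ResidueMapping.identity_map(4))


# ------------------------------------------------------------------ burial

def test_burial_extended_chain_ends_least_buried():
    s = attach_sidechains(make_backbone(BackboneSpec(30, "strand")),
                          repair_clashes=False)
    result = burial(s)
    interior_min = result.counts[5:-5].min()
    assert result.counts[0] <= interior_min
    assert result.counts[-1] <= interior_min


def test_burial_globule_interior_exceeds_surface(globule_150):
    result = burial(globule_150)
    pts = []
    for res in globule_150.residues:
        p = res.coord("CB")
        pts.append(p if p is not None else res.coord("CA"))
    pts = np.asarray(pts)
    centroid_dist = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
    # the innermost tenth of residues should count at least as many
    # neighbours as the median of the outermost tenth
    order = np.argsort(centroid_dist)
    k = max(len(order) // 10, 1)
    assert result.counts[order[:k]].min() >= np.median(result.counts[order[-k:]])


def test_burial_single_residue_zero():
    chain = Chain("A", [Residue("ALA", 1, atoms=[Atom("CA", "C", [0.0, 0.0, 0.0])])])
    result = burial(Structure([chain]))
    assert result.counts.tolist() == [0.0]
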