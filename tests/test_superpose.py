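"""Superposition metrics against brute-force and closed-form oracles."""
import numpy as np
import pytest
from scipy.optimize import minimize

from templateprobe._geom import random_rotation, rotation_about_axis
from templateprobe.align import ResidueMapping
from templateprobe.errors import MetricUndefinedError, PairingError
from templateprobe.perturb import gaussian_noise
from templateprobe.superpose import (
    TMParams,
    all_atom_rmsd,
    alpha_rmsd,
    kabsch,
    tm_score,
)
from templateprobe.synthetic import BackboneSpec, make_backbone


def _rigid_copy(s, rng):
    out = s.copy()
    rot = random_rotation(rng)
    t = rng.normal(size=3) * 20
    out.set_coords(out.coords() @ rot.T + t)
    return out


# ------------------------------------------------------------------ kabsch

def test_kabsch_recovers_exact_rigid_copy(rng):
    ref = rng.normal(size=(12, 3)) * 5
    rot = rotation_about_axis([0.0, 0.0, 1.0], 37.0)
    mov = (ref - ref.mean(axis=0)) @ rot.T + ref.mean(axis=0) + [5.0, -2.0, 1.0]
    sup = kabsch(ref, mov)
    assert sup.rmsd < 1e-9
    assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)
    np.testing.assert_allclose(sup.rotation @ sup.rotation.T, np.eye(3), atol=1e-9)


def _best_proper_rmsd(ref, mov, n_starts=80, seed=0):
    """Independent oracle: minimize RMSD over proper rotations by multi-start
    local search on an angle-axis parameterization."""
    rng = np.random.default_rng(seed)
    ref_c = ref - ref.mean(axis=0)
    mov_c = mov - mov.mean(axis=0)

    def cost(v):
        theta = np.linalg.norm(v)
        if theta < 1e-12:
            rot = np.eye(3)
        else:
            rot = rotation_about_axis(v / theta, np.degrees(theta))
        return np.sqrt(((ref_c - mov_c @ rot.T) ** 2).sum(axis=1).mean())

    best = np.inf
    for _ in range(n_starts):
        x0 = rng.normal(size=3) * np.pi
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000})
        best = min(best, res.fun)
    return best


def test_kabsch_mirror_image_keeps_positive_residual(rng):
    ref = rng.normal(size=(4, 3)) * 3  # generic chiral 4-point set
    mov = ref * np.array([1.0, 1.0, -1.0])  # reflection
    sup = kabsch(ref, mov)
    oracle = _best_proper_rmsd(ref, mov)
    assert sup.rmsd > 0.0
    assert sup.rmsd == pytest.approx(oracle, abs=1e-6)


def test_kabsch_matches_numeric_minimizer_on_toy():
    ref = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    mov = np.array([[0.0, 0.0, 0.0], [1.1, 0.0, 0.0], [0.0, 1.0, 0.0]])
    sup = kabsch(ref, mov)
    assert sup.rmsd == pytest.approx(_best_proper_rmsd(ref, mov), abs=1e-6)


def test_kabsch_input_validation(rng):
    with pytest.raises(PairingError):
        kabsch(rng.normal(size=(5, 3)), rng.normal(size=(4, 3)))
    with pytest.raises(PairingError):
        kabsch(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))


# -------------------------------------------------------------- alpha-RMSD

def test_alpha_rmsd_identity_and_cap_behaviour(globule_small, rng):
    n = globule_small.n_residues
    mapping = ResidueMapping.identity_map(n)
    assert alpha_rmsd(globule_small, globule_small, mapping) == pytest.approx(0.0, abs=1e-9)

    # displace one residue far away: the rectified value equals rms of the
    # clipped deviations at the optimal superposition (computed independently)
    model = globule_small.copy()
    for atom in model.residues[n // 2].atoms:
        atom.coord = atom.coord + np.array([100.0, 0.0, 0.0])
    ref_ca0 = np.array([r.coord("CA") for r in globule_small.residues])
    mov_ca0 = np.array([r.coord("CA") for r in model.residues])
    sup = kabsch(ref_ca0, mov_ca0)
    dev = np.linalg.norm(ref_ca0 - sup.apply(mov_ca0), axis=1)
    expected = np.sqrt((np.minimum(dev, 5.0) ** 2).mean())
    assert alpha_rmsd(globule_small, model, mapping, cap=5.0) == pytest.approx(
        expected, abs=1e-9)
    # the outlier's contribution is bounded by cap/sqrt(n)
    assert expected <= np.sqrt((np.minimum(dev, 5.0)[dev < 50] ** 2).sum() / n) \
        + np.sqrt(5.0 ** 2 / n)
    # monotone in the cap; cap=inf equals the plain Kabsch CA RMSD
    caps = [1.0, 2.0, 5.0, 20.0, np.inf]
    values = [alpha_rmsd(globule_small, model, mapping, cap=c) for c in caps]
    assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))
    ref_ca = np.array([r.coord("CA") for r in globule_small.residues])
    mov_ca = np.array([r.coord("CA") for r in model.residues])
    assert values[-1] == pytest.approx(kabsch(ref_ca, mov_ca).rmsd, abs=1e-9)


# ---------------------------------------------------------------- TM-score

def test_tm_identity_is_one(globule_small):
    mapping = ResidueMapping.identity_map(globule_small.n_residues)
    assert tm_score(globule_small, globule_small, mapping) == pytest.approx(1.0, abs=1e-9)


def test_tm_d0_convention():
    assert TMParams.for_length(150).d0 == pytest.approx(
        1.24 * (150 - 15) ** (1 / 3) - 1.8)
    assert TMParams.for_length(16).d0 == 0.5  # floored


def test_tm_term_is_half_at_d0():
    # all pairs at distance exactly d0 in a fixed frame: per-pair term 1/2
    from templateprobe.superpose import _tm_value

    params = TMParams.for_length(30)
    ref = np.random.default_rng(0).normal(size=(30, 3)) * 8
    moved = ref + np.array([params.d0, 0.0, 0.0])
    assert _tm_value(ref, moved, params) == pytest.approx(0.5, abs=1e-12)


def _tm_bruteforce(ref_ca, model_ca, params, n_starts=120, seed=0):
    """Dense multi-start optimization of the TM objective over rigid motions."""
    rng = np.random.default_rng(seed)

    def value(rot, trans):
        moved = model_ca @ rot.T + trans
        d_sq = ((ref_ca - moved) ** 2).sum(axis=1)
        return (1.0 / (1.0 + d_sq / params.d0 ** 2)).sum() / params.l_ref

    def cost(x):
        theta = np.linalg.norm(x[:3])
        rot = np.eye(3) if theta < 1e-12 else rotation_about_axis(
            x[:3] / theta, np.degrees(theta))
        return -value(rot, x[3:])

    center_shift = ref_ca.mean(axis=0) - model_ca.mean(axis=0)
    best = -np.inf
    for k in range(n_starts):
        x0 = np.concatenate([rng.normal(size=3) * np.pi,
                             center_shift + rng.normal(size=3) * (2.0 if k else 0.0)])
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"maxiter": 3000, "xatol": 1e-8, "fatol": 1e-12})
        best = max(best, -res.fun)
    return best


def test_tm_matches_bruteforce_oracle_on_toys(rng):
    s = make_backbone(BackboneSpec(8, "helix"))
    mapping = ResidueMapping.identity_map(8)
    for trial in range(3):
        model = gaussian_noise(s, 0.8, seed=trial)
        # make one residue an outlier so a global fit is suboptimal
        for atom in model.residues[7].atoms:
            atom.coord = atom.coord + np.array([0.0, 12.0, 0.0])
        got = tm_score(s, model, mapping)
        ref_ca = np.array([r.coord("CA") for r in s.residues])
        mov_ca = np.array([r.coord("CA") for r in model.residues])
        oracle = _tm_bruteforce(ref_ca, mov_ca, TMParams.for_length(8), seed=trial)
        assert got == pytest.approx(oracle, abs=1e-3)


def test_tm_beats_single_global_kabsch(globule_small):
    mapping = ResidueMapping.identity_map(globule_small.n_residues)
    model = gaussian_noise(globule_small, 1.0, seed=4)
    # push a block of residues away: the global fit is dragged by outliers
    for res in model.residues[:10]:
        for atom in res.atoms:
            atom.coord = atom.coord + np.array([25.0, 0.0, 0.0])
    ref_ca = np.array([r.coord("CA") for r in globule_small.residues])
    mov_ca = np.array([r.coord("CA") for r in model.residues])
    sup = kabsch(ref_ca, mov_ca)
    params = TMParams.for_length(globule_small.n_residues)
    from templateprobe.superpose import _tm_value

    single = _tm_value(ref_ca, sup.apply(mov_ca), params)
    searched = tm_score(globule_small, model, mapping)
    assert searched >= single - 1e-12


def test_tm_and_alpha_rmsd_rigid_motion_invariant(globule_small, rng):
    mapping = ResidueMapping.identity_map(globule_small.n_residues)
    model = gaussian_noise(globule_small, 1.0, seed=2)
    tm0 = tm_score(globule_small, model, mapping)
    ar0 = alpha_rmsd(globule_small, model, mapping)
    moved = _rigid_copy(model, rng)
    assert tm_score(globule_small, moved, mapping) == pytest.approx(tm0, abs=1e-6)
    assert alpha_rmsd(globule_small, moved, mapping) == pytest.approx(ar0, abs=1e-6)


def test_tm_requires_five_pairs(globule_small):
    with pytest.raises(MetricUndefinedError):
        tm_score(globule_small, globule_small, ResidueMapping(pairs=[(0, 0), (1, 1)]))


# ----------------------------------------------------------- all-atom RMSD

def test_all_atom_rmsd_identity(globule_small):
    mapping = ResidueMapping.identity_map(globule_small.n_residues)
    rep = all_atom_rmsd(globule_small, globule_small, mapping)
    assert rep.rmsd == pytest.approx(0.0, abs=1e-9)
    assert rep.n_skipped == 0


def test_sidechain_rmsd_of_uniform_shift(helix_full):
    mapping = ResidueMapping.identity_map(helix_full.n_residues)
    model = helix_full.copy()
    for res in model.residues:
        for atom in res.atoms:
            if atom.name not in ("N", "CA", "C", "O"):
                atom.coord = atom.coord + np.array([1.0, 0.0, 0.0])
    # backbone is untouched, so the fitted superposition is the identity and
    # every side-chain atom contributes exactly 1 A
    rep = all_atom_rmsd(helix_full, model, mapping, atom_set="sidechain")
    assert rep.rmsd == pytest.approx(1.0, abs=1e-9)


def test_skipped_atom_accounting(helix_full):
    from templateprobe.perturb import strip_sidechains

    mapping = ResidueMapping.identity_map(helix_full.n_residues)
    stripped = strip_sidechains(helix_full, "absent")
    rep = all_atom_rmsd(helix_full, stripped, mapping)
    n_sidechain = sum(1 for _, _, a in helix_full.iter_atoms()
                      if a.name not in ("N", "CA", "C", "O"))
    assert rep.n_skipped == n_sidechain
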