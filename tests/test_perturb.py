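"""Perturbation protocols: noise statistics, projections, CB policies, hit filtering."""
import numpy as np
import pytest

from templateprobe._geom import random_rotation
from templateprobe.errors import DegenerateGeometryError, ParameterError
from templateprobe.perturb import (
    ORIGIN_CB,
    HitRecord,
    filter_template_hits,
    gaussian_noise,
    glycine_cb_template,
    heuristic_cbeta,
    pca_project,
    read_m8,
    strip_sidechains,
)
from templateprobe.structio import extract_sequence
from templateprobe.synthetic import (
    BackboneSpec,
    RotamerSpec,
    attach_sidechains,
    make_backbone,
)


@pytest.fixture(scope="module")
def big_structure():
    """~10^4 atoms so noise statistics converge."""
    s = make_backbone(BackboneSpec(1300, "helix"))
    return attach_sidechains(s, RotamerSpec("ideal_single", 0), repair_clashes=False)


# --------------------------------------------------------------- gaussian

def test_gaussian_sigma_zero_is_identity(helix_full):
    out = gaussian_noise(helix_full, 0.0, seed=1)
    np.testing.assert_array_equal(out.coords(), helix_full.coords())


def test_gaussian_displacement_statistics(big_structure):
    assert big_structure.n_atoms >= 10_000
    out = gaussian_noise(big_structure, 1.0, seed=3)
    delta = out.coords() - big_structure.coords()
    # all-atom displacement RMS converges to sqrt(3) sigma
    rms = np.sqrt((delta ** 2).sum(axis=1).mean())
    assert rms == pytest.approx(np.sqrt(3.0), rel=0.02)
    # per-component variance converges to sigma^2
    assert delta.var() == pytest.approx(1.0, rel=0.05)


def test_gaussian_deterministic_and_preserves_topology(helix_full):
    a = gaussian_noise(helix_full, 1.0, seed=9)
    b = gaussian_noise(helix_full, 1.0, seed=9)
    np.testing.assert_array_equal(a.coords(), b.coords())
    assert [r.resname for r in a.residues] == [r.resname for r in helix_full.residues]
    assert a.n_atoms == helix_full.n_atoms


def test_gaussian_rejects_negative_sigma(helix_full):
    with pytest.raises(ParameterError):
        gaussian_noise(helix_full, -0.5)


# -------------------------------------------------------------------- PCA

def test_pca_two_components_gives_planar_output(globule_small):
    out = pca_project(globule_small, 2)
    xyz = out.coords()
    centered = xyz - xyz.mean(axis=0)
    sv = np.linalg.svd(centered, full_matrices=False)[1]
    assert sv[2] < 1e-8 * sv[0]
    assert out.n_atoms == globule_small.n_atoms


def test_pca_idempotent_on_planar_input(globule_small):
    flat = pca_project(globule_small, 2)
    again = pca_project(flat, 2)
    np.testing.assert_allclose(again.coords(), flat.coords(), atol=1e-6)


def test_pca_one_component_matches_eigendecomposition(helix_full):
    out = pca_project(helix_full, 1)
    xyz = out.coords()
    centered = xyz - xyz.mean(axis=0)
    sv = np.linalg.svd(centered, full_matrices=False)[1]
    assert sv[1] < 1e-8 * sv[0]  # collinear
    # captured variance equals lambda1 / trace of the input covariance
    orig = helix_full.coords()
    cov = np.cov((orig - orig.mean(axis=0)).T, bias=True)
    evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    out_var = (centered ** 2).sum() / len(centered)
    assert out_var == pytest.approx(evals[0], rel=1e-9)


# ------------------------------------------------------------- CB policies

def test_strip_absent_keeps_backbone_only(helix_full):
    out = strip_sidechains(helix_full, "absent")
    ala = out.residues[0]
    assert ala.resname == "ALA"
    assert [a.name for a in ala.atoms] == ["N", "CA", "C", "O"]
    assert out.n_residues == helix_full.n_residues


def test_strip_origin_places_every_cb_at_constant(helix_full):
    out = strip_sidechains(helix_full, "origin")
    for res in out.residues:
        cb = res.coord("CB")
        assert cb is not None  # glycine too, in origin mode
        np.testing.assert_array_equal(cb, ORIGIN_CB)


def test_strip_template_keeps_original_cb(helix_full):
    out = strip_sidechains(helix_full, "template")
    for res_in, res_out in zip(helix_full.residues, out.residues):
        if res_in.resname == "GLY":
            assert res_out.coord("CB") is None
        else:
            np.testing.assert_array_equal(res_out.coord("CB"), res_in.coord("CB"))


def test_heuristic_cb_close_to_ideal_cb(helix_full):
    stripped = strip_sidechains(helix_full, "heuristic")
    for res_in, res_out in zip(helix_full.residues, stripped.residues):
        # GLY has no reference CB; PRO's ring closure needs a tighter
        # N-CA-CB angle than the generic heuristic assumes
        if res_in.resname in ("GLY", "PRO"):
            continue
        dist = np.linalg.norm(res_out.coord("CB") - res_in.coord("CB"))
        assert dist < 0.1


def test_heuristic_cbeta_geometry_and_equivariance(rng):
    n = np.array([-0.525, 1.363, 0.0])
    ca = np.zeros(3)
    c = np.array([1.526, 0.0, 0.0])
    cb = heuristic_cbeta(n, ca, c)
    assert np.linalg.norm(cb - ca) == pytest.approx(1.53, abs=0.02)
    cos = np.dot(n - ca, cb - ca) / (np.linalg.norm(n - ca) * np.linalg.norm(cb - ca))
    assert np.degrees(np.arccos(cos)) == pytest.approx(110.0, abs=2.0)
    rot = random_rotation(rng)
    t = rng.normal(size=3) * 10
    moved = heuristic_cbeta(rot @ n + t, rot @ ca + t, rot @ c + t)
    np.testing.assert_allclose(moved, rot @ cb + t, atol=1e-9)


def test_heuristic_cbeta_collinear_raises():
    with pytest.raises(DegenerateGeometryError):
        heuristic_cbeta([0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [2.0, 0.0, 0.0])


# ------------------------------------------------------- glycine reduction

def test_glycine_cb_template_reduces_everything():
    s = attach_sidechains(make_backbone(BackboneSpec(3, "helix", sequence="ASW")),
                          repair_clashes=False)
    out = glycine_cb_template(s)
    assert [r.resname for r in out.residues] == ["GLY", "GLY", "GLY"]
    for res in out.residues:
        assert [a.name for a in res.atoms] == ["N", "CA", "C", "O", "CB"]
    assert extract_sequence(out)[0].sequence == "GGG"
    # backbone coordinates bitwise unchanged
    for res_in, res_out in zip(s.residues, out.residues):
        for name in ("N", "CA", "C", "O"):
            np.testing.assert_array_equal(res_in.coord(name), res_out.coord(name))


def test_glycine_cb_template_idempotent(helix_full):
    once = glycine_cb_template(helix_full)
    twice = glycine_cb_template(once)
    np.testing.assert_array_equal(once.coords(), twice.coords())
    assert [a.name for _, _, a in once.iter_atoms()] == \
        [a.name for _, _, a in twice.iter_atoms()]


# ------------------------------------------------------------- hit filter

def _hit(query="q1", target="t1", pident=50.0, qstart=1, qend=90, qlen=100,
         evalue=1e-30):
    return HitRecord(query_id=query, target_id=target, pident=pident,
                     alnlen=qend - qstart + 1, qstart=qstart, qend=qend,
                     evalue=evalue, qlen=qlen)


@pytest.mark.parametrize("pident,qend,kept", [
    (50.0, 90, True),    # identity and coverage inside the window
    (75.0, 90, False),   # identity above 70
    (50.0, 79, False),   # coverage 0.79 below 0.8
    (30.0, 80, True),    # boundaries inclusive
    (70.0, 80, True),
    (29.9, 90, False),
])
def test_filter_window(pident, qend, kept):
    hits = [_hit(pident=pident, qend=qend)]
    out = filter_template_hits(hits)
    assert (len(out) == 1) is kept


def test_filter_keeps_best_hit_per_query():
    hits = [
        _hit(target="worse", evalue=1e-10),
        _hit(target="best", evalue=1e-40),
        _hit(target="tie_lowid", evalue=1e-40, pident=40.0),
        _hit(query="q2", target="only", evalue=1e-5),
    ]
    out = filter_template_hits(hits)
    assert [(h.query_id, h.target_id) for h in out] == [("q1", "best"), ("q2", "only")]
    # pure subset, deterministic
    assert all(h in hits for h in out)
    assert filter_template_hits(hits) == out


def test_filter_skips_unknown_query_length():
    hits = [_hit(qlen=None)]
    assert filter_template_hits(hits) == []


def test_read_m8_with_and_without_qlen(tmp_path):
    base = "q1\tt1\t55.5\t90\t40\t1\t1\t90\t11\t100\t1e-30\t250"
    p12 = tmp_path / "hits12.m8"
    p12.write_text(base + "\n")
    p13 = tmp_path / "hits13.m8"
    p13.write_text(base + "\t100\n")
    hits12 = read_m8(p12, qlen={"q1": 100})
    hits13 = read_m8(p13)
    for hits in (hits12, hits13):
        assert hits[0].pident == 55.5
        assert hits[0].qlen == 100
        assert hits[0].query_coverage == pytest.approx(0.9)
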