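"""Superposition-free local metrics.

* lDDT — fraction of reference interatomic distances (within an inclusion
  radius, across residues) preserved in the model within a set of
  tolerance thresholds; global and per-residue variants.
* stereochemistry check — bond/angle deviations from the ideal-geometry
  tables plus hard-sphere clashes; optionally feeds back into lDDT by
  excluding flagged side chains.
* chi angles and chi-MAE — side-chain dihedral recovery with 2-fold
  terminal symmetry handled (ASP chi2, GLU chi3, PHE/TYR chi2).
* burial — neighbor-count proxy for depth inside the fold, with quantile
  bins for stratified reporting.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ._geom import bond_angle, dihedral
from .align import ResidueMapping
from .errors import MetricUndefinedError
from .idealgeom import (
    AMBIGUOUS_ATOM_SWAPS,
    ANGLE_CA_C_N,
    ANGLE_CA_C_O,
    ANGLE_C_N_CA,
    ANGLE_N_CA_C,
    ANGLE_N_CA_CB,
    ANGLE_N_CA_CB_BY_RES,
    BOND_C_N,
    BOND_C_O,
    BOND_CA_C,
    BOND_CA_CB,
    BOND_N_CA,
    CHI_ATOMS,
    CHI_SYMMETRIC,
    CLASH_FLOOR,
    SIDECHAIN_ZMATRIX,
    STEREO_ANGLE_SIGMA,
    STEREO_BOND_SIGMA,
)
from .structio import Residue, Structure

logger = logging.getLogger("templateprobe.local_metrics")

BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass
class LDDTParams:
    """lDDT configuration: 15 A inclusion radius and 0.5/1/2/4 A thresholds
    by default; stereochemical checks disabled by default."""

    inclusion_radius: float = 15.0
    thresholds: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    include_sidechains: bool = True
    stereo_checks: bool = False
    symmetry_resolution: bool = True

    def __post_init__(self) -> None:
        t = tuple(self.thresholds)
        if not t or any(x <= 0 for x in t) or list(t) != sorted(t):
            raise ValueError("thresholds must be positive and sorted")
        self.thresholds = t


@dataclass
class LDDTResult:
    global_score: float
    per_residue: dict[int, float]   # ref residue index -> score
    n_pairs: int


@dataclass
class ChiMAEResult:
    per_index: dict[int, float | None]  # chi index (1-4) -> MAE in degrees
    overall: float
    n_angles: int


@dataclass
class BurialResult:
    counts: np.ndarray   # neighbor count per residue
    bins: np.ndarray     # quantile bin per residue (0 = most exposed)


# -------------------------------------------------------------------- lDDT

def _atom_table(s: Structure, include_sidechains: bool,
                excluded: set[tuple[int, str]] | None = None):
    """Flatten a structure to (coords, residue_index, atom_name)."""
    coords, res_idx, names = [], [], []
    for ri, (_, res) in enumerate(s.iter_residues()):
        for atom in res.atoms:
            if not include_sidechains and atom.name not in BACKBONE_NAMES:
                continue
            if excluded and (ri, atom.name) in excluded:
                continue
            coords.append(atom.coord)
            res_idx.append(ri)
            names.append(atom.name)
    return np.asarray(coords), np.asarray(res_idx), names


def lddt(ref: Structure, model: Structure, mapping: ResidueMapping,
         params: LDDTParams | None = None) -> LDDTResult:
    """Local Distance Difference Test, superposition-free.

    Candidate pairs are heavy-atom pairs of the REFERENCE closer than the
    inclusion radius and belonging to different residues.  A pair is
    conserved at tolerance t iff both atoms exist in the model (same mapped
    residue, same atom name) and |d_model - d_ref| < t; per-pair score is
    the fraction of thresholds conserved, with missing model atoms scoring
    zero.  The global score averages pairs; per-residue scores average the
    pairs touching each reference residue.

    With ``stereo_checks`` on, side-chain atoms of model residues flagged
    by :func:`stereochemistry_check` are treated as absent.  With
    ``symmetry_resolution`` on, residues with 2-fold ambiguous atom naming
    (ASP, GLU, PHE, TYR, ARG) may have the equivalent atoms swapped in the
    model, per residue, whichever naming conserves more.
    """
    params = params or LDDTParams()
    if len(mapping) == 0:
        raise MetricUndefinedError("empty residue mapping")
    ref_coords, ref_res_idx, ref_names = _atom_table(ref, params.include_sidechains)
    if len(ref_coords) == 0:
        raise MetricUndefinedError("reference has no atoms")

    excluded: set[tuple[int, str]] = set()
    if params.stereo_checks:
        flagged = stereochemistry_check(model)
        model_res = model.residues
        for mi in flagged:
            for atom in model_res[mi].atoms:
                if atom.name not in BACKBONE_NAMES:
                    excluded.add((mi, atom.name))

    # model atom lookup: (model residue index, atom name) -> coordinate
    model_atoms: dict[tuple[int, str], np.ndarray] = {}
    for mi, (_, res) in enumerate(model.iter_residues()):
        for atom in res.atoms:
            if (mi, atom.name) in excluded:
                continue
            model_atoms[(mi, atom.name)] = atom.coord
    ref_to_model = {r: m for r, m in mapping}

    tree = cKDTree(ref_coords)
    pairs = tree.query_pairs(params.inclusion_radius, output_type="ndarray")
    if len(pairs) == 0:
        raise MetricUndefinedError("no reference atom pairs within the inclusion radius")
    same_res = ref_res_idx[pairs[:, 0]] == ref_res_idx[pairs[:, 1]]
    pairs = pairs[~same_res]
    if len(pairs) == 0:
        raise MetricUndefinedError("no cross-residue pairs within the inclusion radius")

    d_ref = np.linalg.norm(ref_coords[pairs[:, 0]] - ref_coords[pairs[:, 1]], axis=1)

    def model_coords_for(swaps: dict[int, dict[str, str]]) -> tuple[np.ndarray, np.ndarray]:
        """Model coordinate per reference atom (NaN when absent), honoring
        per-residue ambiguous-name swaps."""
        out = np.full((len(ref_coords), 3), np.nan)
        for k in range(len(ref_coords)):
            ri = int(ref_res_idx[k])
            mi = ref_to_model.get(ri)
            if mi is None:
                continue
            name = ref_names[k]
            name = swaps.get(mi, {}).get(name, name)
            coord = model_atoms.get((mi, name))
            if coord is not None:
                out[k] = coord
        present = ~np.isnan(out[:, 0])
        return out, present

    swaps: dict[int, dict[str, str]] = {}
    model_xyz, present = model_coords_for(swaps)

    thresholds = np.asarray(params.thresholds)

    def pair_scores(model_xyz: np.ndarray, present: np.ndarray) -> np.ndarray:
        ok = present[pairs[:, 0]] & present[pairs[:, 1]]
        d_model = np.linalg.norm(
            model_xyz[pairs[:, 0]] - model_xyz[pairs[:, 1]], axis=1)
        delta = np.abs(d_model - d_ref)
        conserved = (delta[:, None] < thresholds[None, :]).mean(axis=1)
        return np.where(ok, conserved, 0.0)

    scores = pair_scores(model_xyz, present)

    if params.symmetry_resolution:
        model_res = model.residues
        # per-residue pair index lists (by reference residue)
        touching: dict[int, list[int]] = {}
        for p, (a, b) in enumerate(pairs):
            touching.setdefault(int(ref_res_idx[a]), []).append(p)
            touching.setdefault(int(ref_res_idx[b]), []).append(p)
        model_to_ref = {m: r for r, m in mapping}
        # reference atom rows per (residue, name) for targeted updates
        rows_by_res: dict[int, list[int]] = {}
        for k, ri in enumerate(ref_res_idx):
            rows_by_res.setdefault(int(ri), []).append(k)
        for mi, res in enumerate(model_res):
            swap_pairs = AMBIGUOUS_ATOM_SWAPS.get(res.resname)
            if not swap_pairs or mi not in model_to_ref:
                continue
            ri = model_to_ref[mi]
            idx = touching.get(ri)
            if not idx:
                continue
            swap_map: dict[str, str] = {}
            for a, b in swap_pairs:
                swap_map[a] = b
                swap_map[b] = a
            trial_xyz = model_xyz.copy()
            trial_present = present.copy()
            for k in rows_by_res.get(ri, []):
                name = ref_names[k]
                if name in swap_map:
                    coord = model_atoms.get((mi, swap_map[name]))
                    if coord is None:
                        trial_xyz[k] = np.nan
                        trial_present[k] = False
                    else:
                        trial_xyz[k] = coord
                        trial_present[k] = True
            idx_arr = np.asarray(idx)
            sub = pairs[idx_arr]
            ok = trial_present[sub[:, 0]] & trial_present[sub[:, 1]]
            d_m = np.linalg.norm(trial_xyz[sub[:, 0]] - trial_xyz[sub[:, 1]], axis=1)
            delta = np.abs(d_m - d_ref[idx_arr])
            trial_sub = np.where(
                ok, (delta[:, None] < thresholds[None, :]).mean(axis=1), 0.0)
            if trial_sub.sum() > scores[idx_arr].sum():
                model_xyz, present = trial_xyz, trial_present
                scores[idx_arr] = trial_sub

    per_residue: dict[int, float] = {}
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for p, (a, b) in enumerate(pairs):
        for ri in (int(ref_res_idx[a]), int(ref_res_idx[b])):
            sums[ri] = sums.get(ri, 0.0) + scores[p]
            counts[ri] = counts.get(ri, 0) + 1
    for ri in sums:
        per_residue[ri] = sums[ri] / counts[ri]

    return LDDTResult(global_score=float(scores.mean()),
                      per_residue=per_residue, n_pairs=len(pairs))


# --------------------------------------------------- stereochemistry check

def _bonded_topology(res: Residue) -> list[tuple[str, str, float]]:
    """Bonded atom pairs with ideal lengths, from the Z-matrix tables."""
    bonds = [("N", "CA", BOND_N_CA), ("CA", "C", BOND_CA_C), ("C", "O", BOND_C_O)]
    if res.resname != "GLY":
        bonds.append(("CA", "CB", BOND_CA_CB))
    for name, (_, _, parent), bond, _, _ in SIDECHAIN_ZMATRIX.get(res.resname, []):
        bonds.append((parent, name, bond))
    return bonds


def _angle_topology(res: Residue) -> list[tuple[str, str, str, float]]:
    angles = [("N", "CA", "C", ANGLE_N_CA_C), ("CA", "C", "O", ANGLE_CA_C_O)]
    if res.resname != "GLY":
        cb_angle = ANGLE_N_CA_CB_BY_RES.get(res.resname, ANGLE_N_CA_CB)
        angles.append(("N", "CA", "CB", cb_angle))
    for name, (_, b, c), _, angle, _ in SIDECHAIN_ZMATRIX.get(res.resname, []):
        angles.append((b, c, name, angle))
    return angles


def stereochemistry_check(s: Structure, tolerance_sigmas: float = 5.0) -> list[int]:
    """Residue indices violating ideal stereochemistry.

    A residue is flagged when any of its bonds deviates from the ideal
    length by more than ``tolerance_sigmas`` x 0.02 A, any covalent angle
    by more than ``tolerance_sigmas`` x 2.5 deg, or one of its heavy atoms
    sits closer than 1.5 A to a heavy atom of another residue (bonded
    peptide and proline-ring neighbours excepted).  The ideal values come
    from the same tables the synthetic generator builds from, so
    unperturbed synthetic structures are violation-free by construction.
    """
    bond_tol = tolerance_sigmas * STEREO_BOND_SIGMA
    angle_tol = tolerance_sigmas * STEREO_ANGLE_SIGMA
    flagged: set[int] = set()
    residues = list(s.iter_residues())
    # peptide bond C(i)-N(i+1) per chain
    for ri in range(len(residues) - 1):
        (ca_id, res), (cb_id, nxt) = residues[ri], residues[ri + 1]
        if ca_id != cb_id:
            continue
        c = res.coord("C")
        n = nxt.coord("N")
        if c is not None and n is not None:
            if abs(np.linalg.norm(c - n) - BOND_C_N) > bond_tol:
                flagged.update((ri, ri + 1))
        # inter-residue angles across the peptide bond
        ca_i, ca_j = res.coord("CA"), nxt.coord("CA")
        if c is not None and n is not None and ca_i is not None:
            if abs(bond_angle(ca_i, c, n) - ANGLE_CA_C_N) > angle_tol:
                flagged.update((ri, ri + 1))
        if c is not None and n is not None and ca_j is not None:
            if abs(bond_angle(c, n, ca_j) - ANGLE_C_N_CA) > angle_tol:
                flagged.update((ri, ri + 1))

    for ri, (_, res) in enumerate(residues):
        for a, b, ideal in _bonded_topology(res):
            pa, pb = res.coord(a), res.coord(b)
            if pa is None or pb is None:
                continue
            if abs(np.linalg.norm(pa - pb) - ideal) > bond_tol:
                flagged.add(ri)
                break
        if ri in flagged:
            continue
        for a, b, c, ideal in _angle_topology(res):
            pa, pb, pc = res.coord(a), res.coord(b), res.coord(c)
            if pa is None or pb is None or pc is None:
                continue
            if abs(bond_angle(pa, pb, pc) - ideal) > angle_tol:
                flagged.add(ri)
                break

    # hard-sphere clashes between residues
    coords, res_idx, names, resnames = [], [], [], []
    for ri, (_, res) in enumerate(residues):
        for atom in res.atoms:
            coords.append(atom.coord)
            res_idx.append(ri)
            names.append(atom.name)
            resnames.append(res.resname)
    if coords:
        coords = np.asarray(coords)
        tree = cKDTree(coords)
        for i, j in tree.query_pairs(CLASH_FLOOR, output_type="ndarray"):
            ri, rj = int(res_idx[i]), int(res_idx[j])
            if ri == rj:
                continue
            if abs(ri - rj) == 1:
                lo, hi = (i, j) if ri < rj else (j, i)
                if names[lo] == "C" and names[hi] == "N":
                    continue
                if (resnames[hi] == "PRO" and names[hi] in ("CD", "CG")
                        and names[lo] in ("C", "O", "CA")):
                    continue
            flagged.update((ri, rj))
    return sorted(flagged)


# -------------------------------------------------------------- chi angles

def chi_angles(residue: Residue) -> list[float]:
    """Side-chain chi angles (degrees, signed, up to 4).

    The list truncates at the first chi whose atom quadruple is incomplete
    or geometrically degenerate.
    """
    quads = CHI_ATOMS.get(residue.resname, [])
    out: list[float] = []
    for quad in quads:
        coords = [residue.coord(name) for name in quad]
        if any(c is None for c in coords):
            break
        b1 = coords[2] - coords[1]
        n1 = np.cross(coords[1] - coords[0], b1)
        n2 = np.cross(b1, coords[3] - coords[2])
        if np.linalg.norm(n1) < 1e-8 or np.linalg.norm(n2) < 1e-8:
            logger.warning("degenerate chi dihedral in %s%s",
                           residue.resname, residue.seqnum)
            break
        out.append(dihedral(*coords))
    return out


def _wrapped_abs(delta: float) -> float:
    delta = abs(delta) % 360.0
    return min(delta, 360.0 - delta)


def chi_mae(ref: Structure, model: Structure, mapping: ResidueMapping) -> ChiMAEResult:
    """Mean absolute error of the first four side-chain dihedrals.

    Residues pair via the mapping; each chi index is compared only when
    both sides define it.  Differences wrap on the circle, and the 2-fold
    symmetric terminal groups (ASP chi2, GLU chi3, PHE/TYR chi2) score the
    minimum over the 180-degree flip, so a flipped ring contributes zero.
    """
    if len(mapping) == 0:
        raise MetricUndefinedError("empty residue mapping")
    ref_res = ref.residues
    model_res = model.residues
    errors: dict[int, list[float]] = {1: [], 2: [], 3: [], 4: []}
    for r, m in mapping:
        rr, mr = ref_res[r], model_res[m]
        if rr.resname != mr.resname:
            continue
        ref_chis = chi_angles(rr)
        model_chis = chi_angles(mr)
        for k in range(min(len(ref_chis), len(model_chis))):
            err = _wrapped_abs(model_chis[k] - ref_chis[k])
            if (rr.resname, k + 1) in CHI_SYMMETRIC:
                err = min(err, _wrapped_abs(model_chis[k] - ref_chis[k] + 180.0))
            errors[k + 1].append(err)
    all_errors = [e for errs in errors.values() for e in errs]
    if not all_errors:
        raise MetricUndefinedError("no comparable chi angles")
    per_index = {k: (float(np.mean(v)) if v else None) for k, v in errors.items()}
    return ChiMAEResult(per_index=per_index, overall=float(np.mean(all_errors)),
                        n_angles=len(all_errors))


# ------------------------------------------------------------------ burial

def burial(ref: Structure, radius: float = 10.0, n_bins: int = 4) -> BurialResult:
    """Neighbor-count burial proxy with quantile bins.

    Per residue: the number of other residues whose CB (CA for glycine or
    when CB is absent) lies within ``radius`` of this residue's CB/CA.
    Higher counts mean deeper burial.  Bin 0 collects the most exposed
    quantile.
    """
    points = []
    for _, res in ref.iter_residues():
        p = res.coord("CB")
        if p is None:
            p = res.coord("CA")
        points.append(p)
    valid = [i for i, p in enumerate(points) if p is not None]
    counts = np.zeros(len(points))
    if len(valid) > 1:
        arr = np.asarray([points[i] for i in valid])
        tree = cKDTree(arr)
        neighbor_counts = tree.query_ball_point(arr, r=radius, return_length=True)
        for k, i in enumerate(valid):
            counts[i] = neighbor_counts[k] - 1  # exclude self
    if len(points) == 0:
        return BurialResult(counts=counts, bins=np.zeros(0, dtype=int))
    edges = np.quantile(counts, np.linspace(0, 1, n_bins + 1)[1:-1]) if len(counts) > 1 else []
    bins = np.digitize(counts, edges) if len(counts) > 1 else np.zeros(1, dtype=int)
    return BurialResult(counts=counts, bins=bins.astype(int))
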