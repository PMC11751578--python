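"""Idealized synthetic protein structures.

Stands in for downloadable benchmark targets: every perturbation and metric
in the toolkit is testable on structures built here from ideal internal
coordinates.  Three generators:

* :func:`make_backbone` — N/CA/C/O chain from per-residue (phi, psi, omega),
  with named presets (helix, strand, coil, mixed);
* :func:`attach_sidechains` — full heavy-atom side chains at prescribed or
  library chi angles;
* :func:`make_globule` — compact self-avoiding fold whose CA trace follows
  a box-filling serpentine curve, fitted in torsion space so bond lengths
  and angles stay exactly ideal.

Not physically realistic folding: no Ramachandran weighting, no hydrogen
atoms, no packing energetics beyond hard-sphere clash avoidance.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from ._geom import place_atom, random_rotation
from .errors import GenerationError, ParameterError
from .idealgeom import (
    ANGLE_C_N_CA,
    ANGLE_CA_C_N,
    ANGLE_CA_C_O,
    ANGLE_N_CA_C,
    ANGLE_N_CA_CB,
    ANGLE_N_CA_CB_BY_RES,
    BOND_C_N,
    BOND_C_O,
    BOND_CA_C,
    BOND_CA_CB,
    BOND_N_CA,
    IDEAL_SINGLE_CHI,
    IMPROPER_C_N_CA_CB,
    ONE_TO_THREE,
    PRESET_TORSIONS,
    RING_CHI2_RESIDUES,
    ROTAMER_LIBRARY_CHI,
    ROTAMER_LIBRARY_CHI1,
    ROTAMER_LIBRARY_RING_CHI2,
    SIDECHAIN_ZMATRIX,
    element_of,
    n_chi,
)
from .structio import Atom, Chain, Residue, Structure

logger = logging.getLogger("templateprobe.synthetic")

DEFAULT_SEQUENCE_CYCLE = "ARNDCQEGHILKMFPSTWYV"
BACKBONE_SET = frozenset(("N", "CA", "C", "O"))

# coil torsion bins: (phi, psi) centers sampled uniformly with +-15 deg jitter
_COIL_BINS = np.array([
    (-60.0, -45.0),   # alpha
    (-120.0, 130.0),  # beta
    (-75.0, 150.0),   # PPII-ish
    (-90.0, 0.0),     # bridge
    (55.0, 45.0),     # left-handed alpha
])


@dataclass
class BackboneSpec:
    """Recipe for an idealized backbone.

    ``torsion_profile`` is either a preset name ({helix, strand, coil,
    mixed}) or an explicit per-residue sequence of (phi, psi, omega)
    triples in degrees.
    """

    length: int
    torsion_profile: str | Sequence[tuple[float, float, float]] = "helix"
    seed: int = 0
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 3:
            raise ParameterError("backbone length must be >= 3")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ParameterError("sequence length must match backbone length")


@dataclass
class RotamerSpec:
    """Side-chain chi-angle policy: one fixed ideal set per residue type
    (``ideal_single``) or seeded draws from a small discrete library
    (``random_library``)."""

    mode: str = "ideal_single"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("ideal_single", "random_library"):
            raise ParameterError(f"unknown rotamer mode {self.mode!r}")


# ----------------------------------------------------------- torsion tables

def _resolve_torsions(spec: BackboneSpec) -> np.ndarray:
    """Per-residue (phi, psi, omega), shape (L, 3)."""
    if not isinstance(spec.torsion_profile, str):
        arr = np.asarray(spec.torsion_profile, dtype=float)
        if arr.shape != (spec.length, 3):
            raise ParameterError(f"torsion profile must have shape ({spec.length}, 3)")
        return arr
    rng = np.random.default_rng(spec.seed)
    name = spec.torsion_profile
    if name in PRESET_TORSIONS:
        phi, psi = PRESET_TORSIONS[name]
        return np.tile([phi, psi, 180.0], (spec.length, 1))
    if name == "coil":
        return _coil_torsions(spec.length, rng)
    if name == "mixed":
        # alternating helix / strand / coil segments of random length 4-12
        out = np.empty((spec.length, 3))
        i = 0
        kinds = ["helix", "strand", "coil"]
        k = 0
        while i < spec.length:
            seg = int(rng.integers(4, 13))
            kind = kinds[k % 3]
            if kind == "coil":
                out[i:i + seg] = _coil_torsions(min(seg, spec.length - i), rng)
            else:
                phi, psi = PRESET_TORSIONS[kind]
                out[i:i + seg] = [phi, psi, 180.0]
            i += seg
            k += 1
        return out
    raise ParameterError(f"unknown torsion preset {name!r}")


def _coil_torsions(n: int, rng: np.random.Generator) -> np.ndarray:
    bins = _COIL_BINS[rng.integers(0, len(_COIL_BINS), size=n)]
    jitter = rng.uniform(-15.0, 15.0, size=(n, 2))
    phipsi = bins + jitter
    return np.column_stack([phipsi, np.full(n, 180.0)])


def _default_sequence(length: int) -> str:
    reps = length // len(DEFAULT_SEQUENCE_CYCLE) + 1
    return (DEFAULT_SEQUENCE_CYCLE * reps)[:length]


# ----------------------------------------------------------- backbone build

def _build_backbone_coords(torsions: np.ndarray) -> np.ndarray:
    """Chain extension: returns (L, 4, 3) coordinates for N, CA, C, O."""
    L = len(torsions)
    xyz = np.zeros((L, 4, 3))
    n = np.zeros(3)
    ca = np.array([BOND_N_CA, 0.0, 0.0])
    # first C in the xy-plane
    theta = np.radians(180.0 - ANGLE_N_CA_C)
    c = ca + BOND_CA_C * np.array([np.cos(theta), np.sin(theta), 0.0])
    xyz[0, 0], xyz[0, 1], xyz[0, 2] = n, ca, c
    for i in range(L):
        phi_next, psi_i = (torsions[i + 1, 0], torsions[i, 1]) if i + 1 < L else (0.0, torsions[i, 1])
        omega_i = torsions[i, 2]
        n_i, ca_i, c_i = xyz[i, 0], xyz[i, 1], xyz[i, 2]
        # carbonyl O: dihedral N-CA-C-O = psi + 180
        xyz[i, 3] = place_atom(n_i, ca_i, c_i, BOND_C_O, ANGLE_CA_C_O, psi_i + 180.0)
        if i + 1 == L:
            break
        n_next = place_atom(n_i, ca_i, c_i, BOND_C_N, ANGLE_CA_C_N, psi_i)
        ca_next = place_atom(ca_i, c_i, n_next, BOND_N_CA, ANGLE_C_N_CA, omega_i)
        c_next = place_atom(c_i, n_next, ca_next, BOND_CA_C, ANGLE_N_CA_C, phi_next)
        xyz[i + 1, 0], xyz[i + 1, 1], xyz[i + 1, 2] = n_next, ca_next, c_next
    return xyz


def _backbone_to_structure(xyz: np.ndarray, sequence: str, source: str) -> Structure:
    chain = Chain("A")
    for i, letter in enumerate(sequence):
        resname = ONE_TO_THREE.get(letter, "ALA")
        res = Residue(resname, i + 1)
        for j, name in enumerate(("N", "CA", "C", "O")):
            res.atoms.append(Atom(name, element_of(name), xyz[i, j].copy()))
        chain.residues.append(res)
    return Structure([chain], source=source)


def make_backbone(spec: BackboneSpec) -> Structure:
    """Build an N/CA/C/O backbone from ideal internal coordinates.

    Deterministic in (spec, seed).  Consecutive CA-CA distances come out at
    3.80 A (trans peptide); helix preset gives the textbook ~1.5 A rise per
    residue.
    """
    torsions = _resolve_torsions(spec)
    xyz = _build_backbone_coords(torsions)
    seq = spec.sequence or _default_sequence(spec.length)
    return _backbone_to_structure(
        xyz, seq, source=f"synthetic:backbone:{spec.torsion_profile}:{spec.seed}")


# ------------------------------------------------------------- side chains

def _place_cb(res: Residue) -> np.ndarray:
    n, ca, c = res.coord("N"), res.coord("CA"), res.coord("C")
    angle = ANGLE_N_CA_CB_BY_RES.get(res.resname, ANGLE_N_CA_CB)
    return place_atom(c, n, ca, BOND_CA_CB, angle, IMPROPER_C_N_CA_CB)


def _chi_values(resname: str, spec: RotamerSpec, rng: np.random.Generator) -> tuple[float, ...]:
    k = n_chi(resname)
    if spec.mode == "ideal_single":
        return IDEAL_SINGLE_CHI.get(resname, ())[:k]
    chis = []
    for idx in range(1, k + 1):
        if idx == 1:
            chis.append(float(rng.choice(ROTAMER_LIBRARY_CHI1)))
        elif idx == 2 and resname in RING_CHI2_RESIDUES:
            chis.append(float(rng.choice(ROTAMER_LIBRARY_RING_CHI2)))
        elif resname == "PRO":
            chis.append(IDEAL_SINGLE_CHI["PRO"][idx - 1])
        else:
            chis.append(float(rng.choice(ROTAMER_LIBRARY_CHI)))
    if resname == "PRO":
        chis[0] = IDEAL_SINGLE_CHI["PRO"][0]
    return tuple(chis)


def _build_sidechain_atoms(res: Residue, chis: Sequence[float]) -> list[Atom]:
    """Heavy side-chain atoms (incl. CB) for one backbone-complete residue."""
    if res.resname == "GLY":
        return []
    coords: dict[str, np.ndarray] = {
        "N": res.coord("N"), "CA": res.coord("CA"), "C": res.coord("C")}
    o = res.coord("O")
    if o is not None:
        coords["O"] = o
    coords["CB"] = _place_cb(res)
    atoms = [Atom("CB", "C", coords["CB"])]
    for name, (a, b, c), bond, angle, torsion in SIDECHAIN_ZMATRIX.get(res.resname, []):
        if isinstance(torsion, tuple):
            _, k, offset = torsion
            if k - 1 >= len(chis):
                break
            tor = chis[k - 1] + offset
        else:
            tor = torsion
        pos = place_atom(coords[a], coords[b], coords[c], bond, angle, tor)
        coords[name] = pos
        atoms.append(Atom(name, element_of(name), pos))
    return atoms


def attach_sidechains(
    s: Structure,
    spec: RotamerSpec | None = None,
    chi_overrides: dict[tuple[str, int], Sequence[float]] | None = None,
    repair_clashes: bool = True,
) -> Structure:
    """Attach full heavy-atom side chains to a backbone-complete structure.

    Existing backbone atoms are never moved; existing side-chain atoms are
    replaced.  ``chi_overrides`` maps (chain_id, seqnum) to explicit chi
    angles in degrees, overriding the rotamer spec for those residues;
    overridden residues are exempt from clash repair.  With
    ``repair_clashes`` (default), residues whose side chains collide with
    other residues are re-rotamerized over a chi grid, so generated
    fixtures satisfy the hard-sphere stereochemistry floor.  Residues with
    an incomplete backbone are left backbone-only and logged.  Deterministic
    in (structure, spec, overrides).
    """
    spec = spec or RotamerSpec()
    rng = np.random.default_rng(spec.seed)
    out = s.copy()
    for chain in out.chains:
        for res in chain.residues:
            res.atoms = [a for a in res.atoms if a.name in ("N", "CA", "C", "O")]
            if not res.backbone_complete:
                logger.warning("residue %s %s%s: incomplete backbone, left bare",
                               res.resname, chain.chain_id, res.seqnum)
                continue
            key = (chain.chain_id, res.seqnum)
            if chi_overrides and key in chi_overrides:
                chis: Sequence[float] = tuple(chi_overrides[key])
            else:
                chis = _chi_values(res.resname, spec, rng)
            res.atoms.extend(_build_sidechain_atoms(res, chis))
    if repair_clashes:
        frozen = set()
        if chi_overrides:
            seqnums = {k[1] for k in chi_overrides}
            frozen = {ri for ri, (_, res) in enumerate(out.iter_residues())
                      if res.seqnum in seqnums}
        if not _repair_sidechain_clashes(out, frozen=frozen):
            if not _mutate_for_steric_relief(out):
                logger.warning("backbone-level clash persists after side-chain "
                               "repair; structure fails the hard-sphere floor")
    out.source = s.source + "+sidechains"
    return out


# ---------------------------------------------------------------- globules

_CA_FLOOR_MC = 4.2          # CA-CA floor (A) enforced during collapse, |i-j| > 2
_CA_FLOOR_SPEC = 3.5        # contract floor for the finished globule
_HEAVY_FLOOR = 1.6          # heavy-atom inter-residue floor after side chains
_BB_BAND_FLOOR_SQ = 2.4 ** 2  # backbone-atom floor at sequence separation 2-4


def target_radius_of_gyration(length: int) -> float:
    """Compact-globule radius of gyration scaling, ~2.2 L^(1/3) Angstrom."""
    return 2.2 * length ** (1.0 / 3.0)


def _ca_floor_for_sep(sep: np.ndarray) -> np.ndarray:
    """Minimum allowed CA-CA distance (A) by sequence separation."""
    floor = np.where(sep == 2, 3.8, _CA_FLOOR_MC).astype(float)
    floor[sep <= 1] = 0.0
    return floor


def _band_ok(xyz: np.ndarray) -> bool:
    """Backbone atoms of residues 2-4 apart must not interpenetrate; the
    protruding carbonyl O is the usual offender at tight turns."""
    for off in (2, 3, 4):
        if len(xyz) <= off:
            continue
        diff = xyz[:-off, :, None, :] - xyz[off:, None, :, :]
        if (np.einsum("ijkl,ijkl->ijk", diff, diff) < _BB_BAND_FLOOR_SQ).any():
            return False
    return True


def _place_batch(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                 bond: float, angle_deg: float, tors_deg: np.ndarray) -> np.ndarray:
    """Broadcasting variant of :func:`place_atom`: a, b, c are (..., 3)
    arrays and ``tors_deg`` broadcasts against their leading axes."""
    theta = np.radians(angle_deg)
    chi = np.radians(np.asarray(tors_deg, dtype=float))
    bc = c - b
    bc = bc / np.linalg.norm(bc, axis=-1, keepdims=True)
    n = np.cross(np.broadcast_to(b - a, bc.shape), bc)
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)
    d0 = -bond * np.cos(theta)
    d1 = (bond * np.sin(theta) * np.cos(chi))[..., None]
    d2 = (-bond * np.sin(theta) * np.sin(chi))[..., None]
    return c + d0 * bc + d1 * m + d2 * n


def _serpentine_targets(length: int, rng: np.random.Generator,
                        lane: float = 6.0, step: float = 3.8) -> np.ndarray:
    """Ideal CA positions along a box-filling serpentine polyline.

    Rows run along z, spaced ``lane`` Angstrom in x; layers are stacked in y
    at the same spacing.  The box edge is sized so the path holds ``length``
    residues at the CA step, giving Rg close to the 2.2 L^(1/3) compactness
    scaling by construction.  A seeded random rotation and per-point jitter
    decorrelate fixtures generated with different seeds.
    """
    edge = (length * step * lane * lane) ** (1.0 / 3.0)
    n_rows = max(2, int(np.ceil(edge / lane)))
    n_layers = max(1, int(np.ceil(edge / lane)))
    verts = []
    dirz = 1
    for iy in range(n_layers):
        order = range(n_rows) if iy % 2 == 0 else range(n_rows - 1, -1, -1)
        for ix in order:
            z0, z1 = (0.0, edge) if dirz > 0 else (edge, 0.0)
            verts.append((ix * lane, iy * lane, z0))
            verts.append((ix * lane, iy * lane, z1))
            dirz = -dirz
    verts = np.asarray(verts)
    seg = np.linalg.norm(np.diff(verts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    si = np.arange(length) * step
    while si[-1] > s[-1]:  # path too short (rounding): extend with one more layer
        extra = verts[-2 * n_rows:].copy()
        extra[:, 1] += n_layers * lane
        verts = np.vstack([verts, extra[::-1]])
        seg = np.linalg.norm(np.diff(verts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
    tgt = np.column_stack([np.interp(si, s, verts[:, k]) for k in range(3)])
    tgt = (tgt - tgt.mean(axis=0)) @ random_rotation(rng).T
    tgt += rng.normal(0.0, 0.3, size=tgt.shape)
    return tgt


_PHI_GRID = np.arange(-180.0, 180.0, 9.0)
_PSI_GRID = np.arange(-180.0, 180.0, 6.0)


def _fit_serpentine(length: int, rng: np.random.Generator) -> np.ndarray | None:
    """Fit backbone torsions so the CA trace follows the serpentine targets.

    At each residue i the pair (phi_i, psi_i) is chosen on a joint grid to
    bring CA_{i+1} closest to its target point, subject to every CA-CA floor
    (with a small margin) against the already-placed trace.  Two torsional
    degrees of freedom per step give enough reach to take the U-turns of the
    serpentine.  Bond lengths and angles stay exactly ideal.  Returns
    (L, 4, 3) backbone coordinates or None when the fit runs into a wall.
    """
    tgt = _serpentine_targets(length, rng)
    xyz = np.zeros((length, 4, 3))
    d0 = tgt[1] - tgt[0]
    d0 /= np.linalg.norm(d0)
    perp = np.cross(d0, rng.normal(size=3))
    perp /= np.linalg.norm(perp)
    ca0 = tgt[0]
    n0 = ca0 - BOND_N_CA * d0
    # dummy "previous carbonyl" fixing the phi reference frame of residue 0
    c_prev = n0 + BOND_C_N * perp
    xyz[0, 0], xyz[0, 1] = n0, ca0
    margin = 0.15
    reach = 3.8 + _CA_FLOOR_MC + margin  # only CAs this close can violate a floor
    bb_floor = np.sqrt(_BB_BAND_FLOOR_SQ) + margin
    n_psi = len(_PSI_GRID)
    c_prev0 = c_prev
    i = 0
    rescues = 0
    steps = 0
    while i < length - 1:
        steps += 1
        if steps > 8 * length:
            return None
        n_i, ca_i = xyz[i, 0], xyz[i, 1]
        c_prev = xyz[i - 1, 2] if i > 0 else c_prev0
        c_cand = _place_batch(c_prev, n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, _PHI_GRID)
        n_cand = _place_batch(n_i[None, None, :], ca_i[None, None, :],
                              c_cand[:, None, :], BOND_C_N, ANGLE_CA_C_N,
                              _PSI_GRID[None, :])
        ca_cand = _place_batch(ca_i[None, None, :], c_cand[:, None, :], n_cand,
                               BOND_N_CA, ANGLE_C_N_CA, 180.0)
        o_cand = _place_batch(n_i[None, None, :], ca_i[None, None, :],
                              c_cand[:, None, :], BOND_C_O, ANGLE_CA_C_O,
                              _PSI_GRID[None, :] + 180.0)
        flat_ca = ca_cand.reshape(-1, 3)
        err = np.linalg.norm(flat_ca - tgt[i + 1], axis=1)
        # CA-CA floors against nearby placed CAs (others cannot be violated)
        prev_ca = xyz[:i + 1, 1, :]
        near = np.where(np.linalg.norm(prev_ca - ca_i, axis=1) <= reach)[0]
        sep = (i + 1) - near
        floor = _ca_floor_for_sep(sep) + margin
        floor[sep <= 1] = 0.0
        feasible = (cdist(flat_ca, prev_ca[near]) >= floor[None, :]).all(axis=1)
        if i >= 1:
            # consecutive carbonyl oxygens collide at unusual psi pairs
            o_prev_dist = np.linalg.norm(o_cand.reshape(-1, 3) - xyz[i - 1, 3], axis=1)
            feasible &= o_prev_dist >= 2.2
        # backbone-band floors: candidate N/CA (vs residues <= i-1) and this
        # residue's O (vs residues <= i-2) must clear nearby placed atoms
        if i >= 2:
            placed = xyz[:i, :, :].reshape(-1, 3)
            near_bb = placed[np.linalg.norm(placed - ca_i, axis=1) <= reach]
            if len(near_bb):
                for cand in (flat_ca, n_cand.reshape(-1, 3)):
                    feasible &= (cdist(cand, near_bb) >= bb_floor).all(axis=1)
            placed_o = xyz[:max(i - 1, 0), :, :].reshape(-1, 3)
            near_o = placed_o[np.linalg.norm(placed_o - ca_i, axis=1) <= reach]
            if len(near_o):
                feasible &= (cdist(o_cand.reshape(-1, 3), near_o) >= bb_floor).all(axis=1)
                c_ok = (cdist(c_cand, near_o) >= bb_floor).all(axis=1)
                feasible &= np.repeat(c_ok, n_psi)
        if not feasible.any():
            # walled in: back up a few residues, re-jitter the local targets
            # and retrace a different path
            rescues += 1
            if rescues > 80:
                return None
            j = max(0, i - 8)
            hi = min(length, i + 8)
            tgt[j + 1:hi] += rng.normal(0.0, 0.5, size=(hi - j - 1, 3))
            i = j
            continue
        err = np.where(feasible, err, np.inf)
        k = int(np.argmin(err))
        kphi, kpsi = divmod(k, n_psi)
        c_i = c_cand[kphi]
        xyz[i, 2] = c_i
        xyz[i, 3] = o_cand[kphi, kpsi]
        xyz[i + 1, 0] = n_cand[kphi, kpsi]
        xyz[i + 1, 1] = ca_cand[kphi, kpsi]
        i += 1
    # last residue: placeholder phi/psi (helix values), no successor to fit
    n_l, ca_l = xyz[length - 1, 0], xyz[length - 1, 1]
    c_l = place_atom(xyz[length - 2, 2], n_l, ca_l, BOND_CA_C, ANGLE_N_CA_C,
                     PRESET_TORSIONS["helix"][0])
    xyz[length - 1, 2] = c_l
    xyz[length - 1, 3] = place_atom(n_l, ca_l, c_l, BOND_C_O, ANGLE_CA_C_O,
                                    PRESET_TORSIONS["helix"][1] + 180.0)
    if not _band_ok(xyz):
        return None
    return xyz


def _heavy_clashes(s: Structure) -> list[tuple[int, int]]:
    """Residue-index pairs with heavy atoms closer than the clash floor.

    Bonded topology across the peptide link is excluded: the C(i)-N(i+1)
    bond, and for X-PRO links the proline CD/CG vs the preceding C/O/CA
    (1-3 and 1-4 neighbours through the N-CD ring bond)."""
    coords = []
    res_idx = []
    names = []
    resnames = []
    for ri, (_, res) in enumerate(s.iter_residues()):
        for a in res.atoms:
            coords.append(a.coord)
            res_idx.append(ri)
            names.append(a.name)
            resnames.append(res.resname)
    coords = np.asarray(coords)
    res_idx = np.asarray(res_idx)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(_HEAVY_FLOOR, output_type="ndarray")
    out = set()
    for i, j in pairs:
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
        out.add((min(ri, rj), max(ri, rj)))
    return sorted(out)


_REPAIR_CHI_GRID = (-150.0, -120.0, -90.0, -65.0, -30.0, 30.0, 65.0, 90.0, 120.0, 150.0, 180.0)


def _repair_sidechain_clashes(s: Structure, passes: int = 12,
                              frozen: set[int] | None = None) -> bool:
    """Re-rotamerize clashing residues over a chi1/chi2 grid, deterministic
    in the input structure.  Returns True when no inter-residue heavy-atom
    clash remains."""
    residues = s.residues
    for _ in range(passes):
        clashes = _heavy_clashes(s)
        if not clashes:
            return True
        involved = sorted({ri for pair in clashes for ri in pair})
        changed = False
        coords = np.asarray([a.coord for _, _, a in s.iter_atoms()])
        offsets = np.cumsum([0] + [len(r.atoms) for r in residues])
        for ri in involved:
            if frozen and ri in frozen:
                continue
            res = residues[ri]
            if res.resname == "GLY" or n_chi(res.resname) == 0:
                continue
            base = list(IDEAL_SINGLE_CHI.get(res.resname, ()))
            if not base:
                continue
            candidates = [tuple(base)]
            chi1_grid = _REPAIR_CHI_GRID if res.resname != "PRO" else (base[0],)
            chi2_grid = _REPAIR_CHI_GRID if (len(base) > 1 and res.resname != "PRO") else (None,)
            for c1 in chi1_grid:
                for c2 in chi2_grid:
                    trial = list(base)
                    trial[0] = c1
                    if c2 is not None:
                        trial[1] = c2
                    candidates.append(tuple(trial))
            others_mask = np.ones(len(coords), dtype=bool)
            others_mask[offsets[ri]:offsets[ri + 1]] = False
            # tolerate the bonded peptide neighbours' N/C, which sit close
            # to this residue's backbone legitimately: compare side-chain
            # atoms only (backbone never moves here)
            other_tree = cKDTree(coords[others_mask])
            best_chis, best_min = None, -np.inf
            for chis in candidates:
                sc = _build_sidechain_atoms(res, chis)
                pts = np.asarray([a.coord for a in sc])
                dmin = float(other_tree.query(pts, k=1)[0].min()) if len(pts) else np.inf
                if dmin > best_min:
                    best_min, best_chis = dmin, chis
                if dmin > _HEAVY_FLOOR + 0.2:
                    break
            if best_chis is not None:
                old = [a.coord for a in res.atoms if a.name not in BACKBONE_SET]
                res.atoms = [a for a in res.atoms if a.name in BACKBONE_SET]
                new_atoms = _build_sidechain_atoms(res, best_chis)
                res.atoms.extend(new_atoms)
                coords[offsets[ri]:offsets[ri + 1]] = [a.coord for a in res.atoms]
                if len(old) != len(new_atoms) or any(
                        np.linalg.norm(o - n.coord) > 1e-9 for o, n in zip(old, new_atoms)):
                    changed = True
        if not changed:
            break
    return not _heavy_clashes(s)


def _mutate_for_steric_relief(s: Structure) -> bool:
    """Last-resort clash relief: shrink irreparably clashing residues to ALA
    (or GLY when even the CB clashes).  Returns False when backbone atoms of
    different residues clash, which rotamer choices cannot fix."""
    residues = s.residues
    chain_ids = [cid for cid, _ in s.iter_residues()]
    for _ in range(20):
        clashes = _heavy_clashes(s)
        if not clashes:
            return True
        ri, rj = clashes[0]
        ra, rb = residues[ri], residues[rj]
        pa = np.asarray([a.coord for a in ra.atoms])
        pb = np.asarray([a.coord for a in rb.atoms])
        dm = cdist(pa, pb)
        ia, ib = np.unravel_index(int(dm.argmin()), dm.shape)
        offender = None
        for res, atom in ((ra, ra.atoms[ia]), (rb, rb.atoms[ib])):
            if atom.name not in BACKBONE_SET and atom.name != "CB":
                offender = res
                break
        if offender is None:
            for res, atom in ((ra, ra.atoms[ia]), (rb, rb.atoms[ib])):
                if atom.name == "CB":
                    offender = res
                    break
            if offender is None:
                return False  # backbone-backbone clash
            offender.resname = "GLY"
            offender.atoms = [a for a in offender.atoms if a.name in BACKBONE_SET]
            logger.info("steric relief: residue %d -> GLY", offender.seqnum)
            continue
        offender.resname = "ALA"
        offender.atoms = [a for a in offender.atoms if a.name in BACKBONE_SET]
        offender.atoms.extend(_build_sidechain_atoms(offender, ()))
        logger.info("steric relief: residue %d -> ALA", offender.seqnum)
    return not _heavy_clashes(s)


def make_globule(length: int, seed: int = 0, max_attempts: int = 8) -> Structure:
    """Compact, self-avoiding all-atom structure of the given length.

    The backbone CA trace follows a box-filling serpentine curve sized to
    the ~2.2 L^(1/3) A compactness scaling, fitted in torsion space so bond
    lengths and angles stay exactly ideal; side chains are attached at the
    fixed ideal rotamer, re-rotamerized where they clash, and (rarely)
    shrunk to ALA/GLY for steric relief.  Bitwise deterministic in
    (length, seed).
    """
    if length < 20:
        raise ParameterError("globule length must be >= 20")
    for attempt in range(max_attempts):
        rng = np.random.default_rng([seed, attempt, length])
        xyz = _fit_serpentine(length, rng)
        if xyz is None:
            continue
        seq = _default_sequence(length)
        backbone = _backbone_to_structure(xyz, seq, source=f"synthetic:globule:{seed}")
        full = attach_sidechains(backbone, RotamerSpec("ideal_single", seed),
                                 repair_clashes=False)
        full.source = f"synthetic:globule:{seed}"
        if _repair_sidechain_clashes(full) or _mutate_for_steric_relief(full):
            return full
    raise GenerationError(
        f"globule generation failed after {max_attempts} attempts (length={length})")
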