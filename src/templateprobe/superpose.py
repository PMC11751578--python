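"""Superposition-based global metrics.

Kabsch optimal rigid superposition (reflections forbidden), plain and
rectified RMSD, and TM-score with the fragment-seeded iterative search of
the original TM-score scheme:

    TM = max over superpositions of (1/L_ref) sum_i 1 / (1 + (d_i/d0)^2)
    d0 = max(1.24 (L_ref - 15)^(1/3) - 1.8,  0.5)  [Angstrom]

The search seeds superpositions from gapless mapped fragments of lengths
L, L/2, L/4, ... (>= 4), refines each by iterating "superpose on the
close pairs, re-select pairs closer than a d0-based cutoff" to a fixed
point, and finally polishes the best transform by direct maximization of
the TM objective over the 6 rigid degrees of freedom.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .align import ResidueMapping
from .errors import MetricUndefinedError, PairingError
from .structio import Structure

BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass
class Superposition:
    """Optimal rigid transform mapping mobile onto reference points."""

    rotation: np.ndarray     # (3, 3), proper (det = +1)
    translation: np.ndarray  # (3,)
    rmsd: float              # over the fitted point set, Angstrom

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


@dataclass
class TMParams:
    """Reference length and the d0 normalization derived from it."""

    l_ref: int
    d0: float

    @classmethod
    def for_length(cls, l_ref: int) -> "TMParams":
        d0 = max(1.24 * np.cbrt(l_ref - 15.0) - 1.8, 0.5)
        return cls(l_ref=l_ref, d0=float(d0))


@dataclass
class RMSDReport:
    """All-atom RMSD plus the pairing bookkeeping."""

    rmsd: float
    n_paired: int
    n_skipped: int


# ------------------------------------------------------------------ kabsch

def kabsch(ref_points: np.ndarray, mov_points: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of mov onto ref.

    Solves min over proper rotations R and translations t of
    ||ref - (R mov + t)||; the SVD determinant correction forbids
    reflections, so mirror images retain a positive residual.
    """
    ref = np.asarray(ref_points, dtype=float)
    mov = np.asarray(mov_points, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise PairingError(f"point sets must both be (n, 3); got {ref.shape} vs {mov.shape}")
    if len(ref) < 3:
        raise PairingError("need at least 3 points for a determined superposition")
    ref_c = ref.mean(axis=0)
    mov_c = mov.mean(axis=0)
    h = (mov - mov_c).T @ (ref - ref_c)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ref_c - rot @ mov_c
    moved = mov @ rot.T + trans
    rmsd = float(np.sqrt(((ref - moved) ** 2).sum(axis=1).mean()))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd)


# --------------------------------------------------------------- CA access

def _mapped_ca(ref: Structure, model: Structure,
               mapping: ResidueMapping) -> tuple[np.ndarray, np.ndarray]:
    ref_res = ref.residues
    model_res = model.residues
    ref_ca, model_ca = [], []
    for r, m in mapping:
        a = ref_res[r].coord("CA")
        b = model_res[m].coord("CA")
        if a is not None and b is not None:
            ref_ca.append(a)
            model_ca.append(b)
    if not ref_ca:
        raise MetricUndefinedError("no mapped residue pair has CA in both structures")
    return np.asarray(ref_ca), np.asarray(model_ca)


# -------------------------------------------------------------- alpha-RMSD

def alpha_rmsd(ref: Structure, model: Structure, mapping: ResidueMapping,
               cap: float = 5.0) -> float:
    """Rectified CA RMSD after optimal superposition.

    Mapped CA sets are Kabsch-superposed; each per-residue deviation is
    clipped at ``cap`` Angstrom before squaring, bounding the influence of
    outlier residues.  ``cap=inf`` reduces to the plain CA RMSD.
    """
    if len(mapping) == 0:
        raise MetricUndefinedError("empty residue mapping")
    ref_ca, model_ca = _mapped_ca(ref, model, mapping)
    sup = kabsch(ref_ca, model_ca)
    dev = np.linalg.norm(ref_ca - sup.apply(model_ca), axis=1)
    dev = np.minimum(dev, cap)
    return float(np.sqrt((dev ** 2).mean()))


# ---------------------------------------------------------------- TM-score

def _tm_value(ref_ca: np.ndarray, moved_ca: np.ndarray, params: TMParams) -> float:
    d_sq = ((ref_ca - moved_ca) ** 2).sum(axis=1)
    return float((1.0 / (1.0 + d_sq / params.d0 ** 2)).sum() / params.l_ref)


def _rotvec_to_matrix(v: np.ndarray) -> np.ndarray:
    theta = np.linalg.norm(v)
    if theta < 1e-12:
        return np.eye(3)
    axis = v / theta
    k = np.array([[0.0, -axis[2], axis[1]],
                  [axis[2], 0.0, -axis[0]],
                  [-axis[1], axis[0], 0.0]])
    return np.eye(3) + np.sin(theta) * k + (1.0 - np.cos(theta)) * (k @ k)


def tm_score(ref: Structure, model: Structure, mapping: ResidueMapping,
             l_ref: int | None = None, polish: bool = True) -> float:
    """TM-score of the model against the reference under a fixed mapping.

    Normalized by the reference residue count (not the mapped count).  The
    superposition is searched, never taken from a single global Kabsch fit:
    fragment seeds of decreasing length, iterative close-pair refinement
    with a d0-based cutoff, and a final direct polish of the TM objective.
    The result can therefore only exceed (or match) the score of any single
    full-mapping Kabsch superposition.
    """
    if len(mapping) < 5:
        raise MetricUndefinedError("TM-score needs at least 5 mapped residue pairs")
    ref_ca, model_ca = _mapped_ca(ref, model, mapping)
    n = len(ref_ca)
    params = TMParams.for_length(l_ref if l_ref is not None else ref.n_residues)
    d_cut = max(params.d0, 4.5)

    best_tm = -1.0
    candidates: list[tuple[float, np.ndarray, np.ndarray]] = []

    def consider(sup: Superposition) -> None:
        nonlocal best_tm
        moved = sup.apply(model_ca)
        tm = _tm_value(ref_ca, moved, params)
        candidates.append((tm, sup.rotation, sup.translation))
        best_tm = max(best_tm, tm)

    if n <= 32:
        # small problems: exhaustive fragment seeds are cheap
        frag_lens = list(range(n, 3, -1))
    else:
        frag_len = n
        frag_lens = []
        while frag_len >= 4:
            frag_lens.append(frag_len)
            frag_len //= 2
    for fl in frag_lens:
        step = max(fl // 2, 1)
        for start in range(0, n - fl + 1, step):
            idx = np.arange(start, start + fl)
            try:
                sup = kabsch(ref_ca[idx], model_ca[idx])
            except PairingError:
                continue
            consider(sup)
            # iterative inclusion: superpose on close pairs until stable
            selected = idx
            for _ in range(20):
                moved = sup.apply(model_ca)
                d = np.linalg.norm(ref_ca - moved, axis=1)
                cut = d_cut
                new_sel = np.where(d < cut)[0]
                while len(new_sel) < 3:
                    cut += 0.5
                    new_sel = np.where(d < cut)[0]
                if np.array_equal(new_sel, selected):
                    break
                selected = new_sel
                sup = kabsch(ref_ca[selected], model_ca[selected])
                consider(sup)

    if polish and candidates:
        candidates.sort(key=lambda c: -c[0])
        for _, rot0, trans0 in candidates[:5]:
            # delta rotation/translation around each incumbent transform
            base = model_ca @ rot0.T + trans0
            base_center = base.mean(axis=0)

            def objective(x: np.ndarray) -> float:
                rot = _rotvec_to_matrix(x[:3])
                moved = (base - base_center) @ rot.T + base_center + x[3:]
                return -_tm_value(ref_ca, moved, params)

            res = minimize(objective, np.zeros(6), method="Nelder-Mead",
                           options={"maxiter": 600, "xatol": 1e-5, "fatol": 1e-9})
            res = minimize(objective, res.x, method="Nelder-Mead",
                           options={"maxiter": 300, "xatol": 1e-6, "fatol": 1e-10})
            best_tm = max(best_tm, float(-res.fun))
    return best_tm


# ----------------------------------------------------------- all-atom RMSD

def all_atom_rmsd(ref: Structure, model: Structure, mapping: ResidueMapping,
                  atom_set: str = "all") -> RMSDReport:
    """RMSD over atoms paired by (mapped residue, atom name).

    The superposition is fitted on the backbone atoms of the mapped
    residues; the RMSD is then evaluated over ``atom_set``: ``all`` heavy
    atoms or ``sidechain`` (non-backbone) only.  Atoms present in only one
    partner are skipped and counted.
    """
    if atom_set not in ("all", "sidechain"):
        raise ValueError(f"unknown atom_set {atom_set!r}")
    if len(mapping) == 0:
        raise MetricUndefinedError("empty residue mapping")
    ref_res = ref.residues
    model_res = model.residues
    fit_ref, fit_mov = [], []
    eval_ref, eval_mov = [], []
    n_skipped = 0
    for r, m in mapping:
        rr, mr = ref_res[r], model_res[m]
        ref_names = {a.name for a in rr.atoms}
        model_names = {a.name for a in mr.atoms}
        common = ref_names & model_names
        n_skipped += len(ref_names ^ model_names)
        for name in common:
            a = rr.coord(name)
            b = mr.coord(name)
            if name in BACKBONE_NAMES:
                fit_ref.append(a)
                fit_mov.append(b)
                if atom_set == "all":
                    eval_ref.append(a)
                    eval_mov.append(b)
            else:
                eval_ref.append(a)
                eval_mov.append(b)
    if len(fit_ref) < 3:
        raise MetricUndefinedError("fewer than 3 shared backbone atoms to fit")
    if not eval_ref:
        raise MetricUndefinedError(f"no shared atoms in set {atom_set!r}")
    sup = kabsch(np.asarray(fit_ref), np.asarray(fit_mov))
    moved = sup.apply(np.asarray(eval_mov))
    rmsd = float(np.sqrt(((np.asarray(eval_ref) - moved) ** 2).sum(axis=1).mean()))
    return RMSDReport(rmsd=rmsd, n_paired=len(eval_ref), n_skipped=n_skipped)
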