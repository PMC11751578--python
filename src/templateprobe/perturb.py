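"""Template perturbation protocols.

Controlled ways of degrading a structure before handing it to a predictor
as a template:

* :func:`gaussian_noise` — independent per-coordinate Gaussian displacement;
* :func:`pca_project` — projection onto the structure's own top principal
  components (1 or 2), collapsing it to a line or plane;
* :func:`strip_sidechains` — backbone-only template with four Cβ policies
  (absent / fixed near-origin / heuristic from backbone / original);
* :func:`glycine_cb_template` — every residue renamed to glycine and reduced
  to backbone + Cβ, erasing amino-acid identity while keeping geometry;
* :func:`filter_template_hits` — the identity/coverage window used to pick
  homology templates from a tabular search result.

All structure perturbations preserve residue count, ordering and chain
structure; they return modified copies and never touch the input.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, ParameterError
from .structio import Atom, Structure

logger = logging.getLogger("templateprobe.perturb")

# "Next to the origin": the non-informative CB position used for every
# residue.  Slightly off (0, 0, 0) so no atom pair ever coincides exactly.
ORIGIN_CB = np.array([0.1, 0.1, 0.1])

# fixed linear combination reconstructing CB from backbone N, CA, C
CB_WEIGHT_A = -0.58273431   # x (CA-N) x (C-CA)
CB_WEIGHT_B = 0.56802827    # x (CA-N)
CB_WEIGHT_C = -0.54067466   # x (C-CA)

BACKBONE_NAMES = ("N", "CA", "C", "O")

M8_COLUMNS = [
    "qseqid", "sseqid", "pident", "alnlen", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bits",
]


@dataclass
class PerturbationSpec:
    """One perturbation protocol and its parameters.

    kind: {identity, gaussian, pca_project, strip_sidechains, glycine_cb}.
    ``sigma`` applies to gaussian (Angstrom); ``n_components`` to
    pca_project; ``cbeta_mode`` to strip_sidechains
    ({absent, origin, heuristic, template}); ``cbeta_source`` to glycine_cb
    ({template, heuristic}).
    """

    kind: str
    sigma: float = 1.0
    n_components: int = 2
    cbeta_mode: str = "heuristic"
    cbeta_source: str = "template"
    seed: int = 0

    _KINDS = ("identity", "gaussian", "pca_project", "strip_sidechains", "glycine_cb")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ParameterError(f"unknown perturbation kind {self.kind!r}")
        if self.kind == "gaussian" and self.sigma < 0:
            raise ParameterError("sigma must be >= 0")
        if self.kind == "pca_project" and self.n_components not in (1, 2):
            raise ParameterError("n_components must be 1 or 2")
        if self.kind == "strip_sidechains" and self.cbeta_mode not in (
                "absent", "origin", "heuristic", "template"):
            raise ParameterError(f"unknown cbeta_mode {self.cbeta_mode!r}")
        if self.kind == "glycine_cb" and self.cbeta_source not in ("template", "heuristic"):
            raise ParameterError(f"unknown cbeta_source {self.cbeta_source!r}")

    @property
    def label(self) -> str:
        if self.kind == "gaussian":
            return f"gaussian(sigma={self.sigma:g})"
        if self.kind == "pca_project":
            return f"pca_project(n={self.n_components})"
        if self.kind == "strip_sidechains":
            return f"strip_sidechains(cbeta={self.cbeta_mode})"
        if self.kind == "glycine_cb":
            return f"glycine_cb(source={self.cbeta_source})"
        return self.kind

    def apply(self, s: Structure) -> Structure:
        if self.kind == "identity":
            return s.copy()
        if self.kind == "gaussian":
            return gaussian_noise(s, self.sigma, self.seed)
        if self.kind == "pca_project":
            return pca_project(s, self.n_components)
        if self.kind == "strip_sidechains":
            return strip_sidechains(s, self.cbeta_mode)
        return glycine_cb_template(s, self.cbeta_source)


# ------------------------------------------------------------ perturbations

def gaussian_noise(s: Structure, sigma: float = 1.0, seed: int = 0) -> Structure:
    """Displace every atomic coordinate component by an independent draw
    from Normal(0, sigma^2).

    One seeded generator; atoms are visited in file order, components in
    x, y, z order, so the output is reproducible.  ``sigma=0`` returns an
    exact copy.
    """
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    out = s.copy()
    if sigma == 0 or out.n_atoms == 0:
        return out
    rng = np.random.default_rng(seed)
    xyz = out.coords()
    xyz = xyz + rng.normal(0.0, sigma, size=xyz.shape)
    out.set_coords(xyz)
    out.source = s.source + f"+gaussian({sigma:g})"
    return out


def pca_project(s: Structure, n_components: int = 2,
                fit_atoms: str = "all") -> Structure:
    """Project the structure onto its own top principal components.

    Coordinates are mean-centered; the principal axes of the atom cloud are
    computed (from all heavy atoms by default, or CA only with
    ``fit_atoms="ca"``); components beyond ``n_components`` are zeroed; the
    mean is restored.  The output is a valid 3D structure whose points lie
    in an n-dimensional affine subspace.

    Eigenvectors are oriented so their largest-magnitude entry is positive,
    and eigenvalue ties resolve to the original axis order, so the
    projection is deterministic.  A degenerate (collinear) cloud with
    ``n_components=2`` proceeds with an arbitrary in-null-space second axis
    and a log notice.
    """
    if n_components not in (1, 2):
        raise ParameterError("n_components must be 1 or 2")
    if s.n_atoms < 4:
        raise ParameterError("need at least 4 atoms for a meaningful projection")
    out = s.copy()
    xyz = out.coords()
    if fit_atoms == "ca":
        fit = np.array([res.coord("CA") for _, res in s.iter_residues()
                        if res.coord("CA") is not None])
    else:
        fit = xyz
    center = fit.mean(axis=0)
    centered = fit - center
    if np.allclose(centered, 0.0):
        raise ParameterError("all coordinates identical; projection undefined")
    cov = centered.T @ centered / len(centered)
    evals, evecs = np.linalg.eigh(cov)          # ascending
    order = np.argsort(evals, kind="stable")[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if n_components == 2 and evals[1] < 1e-12 * max(evals[0], 1.0):
        logger.warning("degenerate covariance: second principal axis is "
                       "arbitrary within the null space")
    # deterministic sign: largest-|entry| component positive
    for k in range(3):
        j = int(np.argmax(np.abs(evecs[:, k])))
        if evecs[j, k] < 0:
            evecs[:, k] = -evecs[:, k]
    basis = evecs[:, :n_components]
    proj = (xyz - center) @ basis @ basis.T + center
    out.set_coords(proj)
    out.source = s.source + f"+pca({n_components})"
    return out


def heuristic_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal CB position from backbone N, CA, C.

    CB = CA + w_a (b x c') + w_b b + w_c c' with b = CA - N, c' = C - CA and
    fixed weights; exactly rigid-motion equivariant because it is a linear
    combination in a local frame.  Raises on collinear backbone.
    """
    n, ca, c = (np.asarray(x, dtype=float) for x in (n, ca, c))
    b = ca - n
    cp = c - ca
    a = np.cross(b, cp)
    if np.linalg.norm(a) < 1e-8:
        raise DegenerateGeometryError("backbone N, CA, C are collinear")
    return ca + CB_WEIGHT_A * a + CB_WEIGHT_B * b + CB_WEIGHT_C * cp


def strip_sidechains(s: Structure, cbeta_mode: str = "absent",
                     gly_cb: bool = True) -> Structure:
    """Reduce every residue to backbone N, CA, C, O plus an optional CB.

    ``cbeta_mode``:
      * ``absent`` — no CB at all;
      * ``origin`` — every CB at the fixed near-origin point (a
        deliberately non-informative placement);
      * ``heuristic`` — CB rebuilt from the backbone via
        :func:`heuristic_cbeta`;
      * ``template`` — the original CB kept where present.

    Glycine has no CB to keep in ``template``/``absent`` modes; in
    ``heuristic`` and ``origin`` modes it receives one when ``gly_cb`` is
    true (mirroring glycine-extension template construction).
    """
    if cbeta_mode not in ("absent", "origin", "heuristic", "template"):
        raise ParameterError(f"unknown cbeta_mode {cbeta_mode!r}")
    out = s.copy()
    for chain in out.chains:
        for res in chain.residues:
            backbone = [a for a in res.atoms if a.name in BACKBONE_NAMES]
            cb = None
            if cbeta_mode == "template":
                orig = res.get("CB")
                if orig is not None:
                    cb = orig.copy()
            elif cbeta_mode == "origin":
                if res.resname != "GLY" or gly_cb:
                    cb = Atom("CB", "C", ORIGIN_CB.copy())
            elif cbeta_mode == "heuristic":
                if res.resname != "GLY" or gly_cb:
                    if res.backbone_complete:
                        cb = Atom("CB", "C", heuristic_cbeta(
                            res.coord("N"), res.coord("CA"), res.coord("C")))
                    else:
                        logger.warning(
                            "residue %s%s: incomplete backbone, no heuristic CB",
                            res.resname, res.seqnum)
            res.atoms = backbone + ([cb] if cb is not None else [])
    out.source = s.source + f"+strip({cbeta_mode})"
    return out


def glycine_cb_template(s: Structure, cbeta_source: str = "template") -> Structure:
    """Erase amino-acid identity: every residue becomes GLY with backbone
    plus a CB.

    ``cbeta_source="template"`` keeps the original CB where present and
    falls back to the backbone heuristic; ``"heuristic"`` always rebuilds
    CB from the backbone.  Backbone coordinates are untouched; applying the
    operation twice equals applying it once.
    """
    if cbeta_source not in ("template", "heuristic"):
        raise ParameterError(f"unknown cbeta_source {cbeta_source!r}")
    out = s.copy()
    for chain in out.chains:
        for res in chain.residues:
            backbone = [a for a in res.atoms if a.name in BACKBONE_NAMES]
            cb = None
            if cbeta_source == "template":
                orig = res.get("CB")
                if orig is not None:
                    cb = orig.copy()
            if cb is None and res.backbone_complete:
                cb = Atom("CB", "C", heuristic_cbeta(
                    res.coord("N"), res.coord("CA"), res.coord("C")))
            if cb is None:
                logger.warning("residue %s%s: no CB source available",
                               res.resname, res.seqnum)
            res.resname = "GLY"
            res.atoms = backbone + ([cb] if cb is not None else [])
    out.source = s.source + "+glycine_cb"
    return out


# ------------------------------------------------------------ template hits

@dataclass
class HitRecord:
    """One row of a tabular homology search result (m8-style)."""

    query_id: str
    target_id: str
    pident: float          # percent identity, 0-100
    alnlen: int
    qstart: int
    qend: int
    evalue: float
    qlen: int | None = None
    bits: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pident <= 100.0:
            raise ParameterError(f"pident {self.pident} outside [0, 100]")
        if self.qstart > self.qend:
            raise ParameterError("qstart must be <= qend")

    @property
    def query_coverage(self) -> float | None:
        if self.qlen is None or self.qlen <= 0:
            return None
        return (self.qend - self.qstart + 1) / self.qlen


def read_m8(path: str | Path, qlen: dict[str, int] | None = None) -> list[HitRecord]:
    """Parse a 12-column tab-separated hit table (optional 13th qlen column).

    ``qlen`` supplies query lengths when the file has no 13th column, e.g.
    from a companion FASTA.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 12:
        raise ParameterError(
            f"{path}: expected >= 12 tab-separated columns, got {df.shape[1]}")
    names = M8_COLUMNS + (["qlen"] if df.shape[1] >= 13 else [])
    df = df.iloc[:, :len(names)]
    df.columns = names
    hits = []
    for row in df.itertuples(index=False):
        length = int(row.qlen) if hasattr(row, "qlen") else (
            qlen.get(str(row.qseqid)) if qlen else None)
        hits.append(HitRecord(
            query_id=str(row.qseqid), target_id=str(row.sseqid),
            pident=float(row.pident), alnlen=int(row.alnlen),
            qstart=int(row.qstart), qend=int(row.qend),
            evalue=float(row.evalue), qlen=length, bits=float(row.bits)))
    return hits


def filter_template_hits(hits: list[HitRecord], id_min: float = 30.0,
                         id_max: float = 70.0, cov_min: float = 0.8) -> list[HitRecord]:
    """Select one template per query from a hit table.

    Keeps hits with ``id_min <= pident <= id_max`` and query coverage
    ``(qend - qstart + 1)/qlen >= cov_min``, then returns the single best
    survivor per query (smallest e-value; ties broken by higher identity,
    then lexicographic target id).  Queries with unknown length are skipped
    with a warning.  Output order follows first appearance of each query.
    """
    surviving: dict[str, HitRecord] = {}
    order: list[str] = []
    for hit in hits:
        cov = hit.query_coverage
        if cov is None:
            logger.warning("query %s: unknown length, hit skipped", hit.query_id)
            continue
        if not (id_min <= hit.pident <= id_max and cov >= cov_min):
            continue
        if hit.query_id not in surviving:
            surviving[hit.query_id] = hit
            order.append(hit.query_id)
            continue
        best = surviving[hit.query_id]
        if (hit.evalue, -hit.pident, hit.target_id) < (
                best.evalue, -best.pident, best.target_id):
            surviving[hit.query_id] = hit
    return [surviving[q] for q in order]
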