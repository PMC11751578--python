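"""Global sequence alignment and residue mappings.

When a model and its reference share a sequence, residues pair up by
position.  When they differ (homology templates), the pairing comes from a
global Needleman-Wunsch alignment under BLOSUM62 with affine gap costs.
The alignment engine is Biopython's ``PairwiseAligner``; this module owns
the parameterization ('X' neutral, gap defaults) and the conversion of an
alignment into a :class:`ResidueMapping`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import AlignmentError
from .structio import Structure, extract_sequence

DEFAULT_GAP_OPEN = -10.0
DEFAULT_GAP_EXTEND = -0.5

_VALID = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class ResidueMapping:
    """Aligned residue pairs between a reference and a model.

    ``pairs`` holds (ref_index, model_index) tuples, strictly increasing in
    both coordinates (a global alignment cannot cross).  ``identity`` is the
    fraction of matched columns with equal letters; ``coverage`` is matched
    columns over reference length.
    """

    pairs: list[tuple[int, int]] = field(default_factory=list)
    identity: float = 1.0
    coverage: float = 1.0

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @classmethod
    def identity_map(cls, n: int) -> "ResidueMapping":
        return cls(pairs=[(i, i) for i in range(n)], identity=1.0, coverage=1.0)

    def validate(self, n_ref: int, n_model: int) -> None:
        prev = (-1, -1)
        for r, m in self.pairs:
            if not (0 <= r < n_ref and 0 <= m < n_model):
                raise AlignmentError(f"pair ({r}, {m}) out of bounds")
            if r <= prev[0] or m <= prev[1]:
                raise AlignmentError("mapping indices must strictly increase")
            prev = (r, m)


def _blosum62_with_neutral_x():
    m = substitution_matrices.load("BLOSUM62")
    if "X" in m.alphabet:
        for letter in m.alphabet:
            m["X", letter] = 0.0
            m[letter, "X"] = 0.0
    return m


_MATRIX = _blosum62_with_neutral_x()


def nw_align(ref_seq: str, model_seq: str, gap_open: float = DEFAULT_GAP_OPEN,
             gap_extend: float = DEFAULT_GAP_EXTEND) -> ResidueMapping:
    """Optimal global alignment of two sequences under BLOSUM62.

    Affine gap costs (``gap_open`` charged at gap opening, ``gap_extend``
    per extension); 'X' scores zero against everything.  The first optimal
    alignment in the engine's deterministic enumeration is used, so repeated
    calls give identical mappings.
    """
    ref_seq, model_seq = ref_seq.upper(), model_seq.upper()
    if not ref_seq or not model_seq:
        raise AlignmentError("cannot align an empty sequence")
    for seq, name in ((ref_seq, "reference"), (model_seq, "model")):
        bad = set(seq) - _VALID
        if bad:
            raise AlignmentError(f"{name} sequence has invalid letters {sorted(bad)}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _MATRIX
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    alignment = aligner.align(ref_seq, model_seq)[0]
    pairs: list[tuple[int, int]] = []
    matches = 0
    for (r0, r1), (m0, m1) in zip(*alignment.aligned):
        for off in range(r1 - r0):
            ri, mi = r0 + off, m0 + off
            pairs.append((ri, mi))
            if ref_seq[ri] == model_seq[mi]:
                matches += 1
    identity = matches / len(pairs) if pairs else 0.0
    coverage = len(pairs) / len(ref_seq)
    return ResidueMapping(pairs=pairs, identity=identity, coverage=coverage)


def alignment_score(ref_seq: str, model_seq: str, gap_open: float = DEFAULT_GAP_OPEN,
                    gap_extend: float = DEFAULT_GAP_EXTEND) -> float:
    """Optimal global alignment score under the same parameterization."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _MATRIX
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return float(aligner.score(ref_seq.upper(), model_seq.upper()))


def map_structures(ref: Structure, model: Structure, gap_open: float = DEFAULT_GAP_OPEN,
                   gap_extend: float = DEFAULT_GAP_EXTEND) -> ResidueMapping:
    """Residue mapping between two structures (residues flattened in chain
    order).

    Identical sequences map by position; differing sequences go through
    :func:`nw_align` on the concatenated per-chain sequences.
    """
    ref_seq = "".join(rec.sequence for rec in extract_sequence(ref))
    model_seq = "".join(rec.sequence for rec in extract_sequence(model))
    if ref_seq == model_seq:
        return ResidueMapping.identity_map(len(ref_seq))
    return nw_align(ref_seq, model_seq, gap_open, gap_extend)
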