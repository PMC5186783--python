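"""Pairwise protein alignment and local-alignment statistics.

Local search uses exact Smith-Waterman with affine gaps (BLOSUM62, gap
open 11 / extend 1 by default, i.e. a gap of length k costs 11 + k);
reference-anchored motif mapping uses true global Needleman-Wunsch with
end gaps penalized. Both are computed by Bio.Align.PairwiseAligner, which
guarantees the optimal score. E-values follow the Karlin-Altschul form
E = K * m * n * exp(-lambda * S) with the published ungapped BLOSUM62
constants as defaults; they are comparable only within a run.

``X`` scores 0 against every residue (neutral handling of ambiguity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"

LOG10E = math.log10(math.e)


def blosum62_with_neutral_x() -> substitution_matrices.Array:
    """BLOSUM62 restricted to the 20 canonical residues + X, with X scoring 0."""
    full = substitution_matrices.load("BLOSUM62")
    mat = substitution_matrices.Array(alphabet=ALPHABET, dims=2)
    for a in ALPHABET:
        for b in ALPHABET:
            mat[a, b] = 0.0 if "X" in (a, b) else full[a, b]
    return mat


@dataclass
class AlignmentParams:
    """Scoring scheme + Karlin-Altschul statistics parameters.

    ``gap_open``/``gap_extend`` use the BLAST convention: a gap of length
    k costs gap_open + k * gap_extend.
    """

    substitution_matrix: substitution_matrices.Array = field(
        default_factory=blosum62_with_neutral_x)
    gap_open: int = 11
    gap_extend: int = 1
    karlin_k: float = 0.041
    karlin_lambda: float = 0.267

    def __post_init__(self) -> None:
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must be <= gap_open")
        if self.karlin_k <= 0 or self.karlin_lambda <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")
        arr = np.asarray(self.substitution_matrix)
        if not np.array_equal(arr, arr.T):
            raise ValueError("substitution matrix must be symmetric")


_DEFAULT: Optional[AlignmentParams] = None


def default_params() -> AlignmentParams:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = AlignmentParams()
    return _DEFAULT


def _aligner(params: AlignmentParams, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = params.substitution_matrix
    # biopython charges open_gap_score on the first gapped position only
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    aligner.mode = mode
    return aligner


class _AlignerCache:
    """Reuse PairwiseAligner objects keyed by the params object identity."""

    def __init__(self) -> None:
        self._cache: dict[tuple[int, str], Align.PairwiseAligner] = {}

    def get(self, params: AlignmentParams, mode: str) -> Align.PairwiseAligner:
        key = (id(params), mode)
        if key not in self._cache:
            self._cache[key] = _aligner(params, mode)
        return self._cache[key]


_aligners = _AlignerCache()


def _check_seqs(a: str, b: str) -> None:
    if not a or not b:
        raise ValueError("alignment requires non-empty sequences")


def local_score(a: str, b: str, params: Optional[AlignmentParams] = None) -> float:
    """Optimal Smith-Waterman affine-gap local alignment score (>= 0)."""
    _check_seqs(a, b)
    params = params or default_params()
    return float(_aligners.get(params, "local").score(a, b))


def local_align(a: str, b: str,
                params: Optional[AlignmentParams] = None) -> tuple[float, tuple[str, str]]:
    """Optimal local alignment: (score, (gapped_a, gapped_b)).

    Tie-breaking is deterministic: the first optimal alignment in the
    aligner's canonical traceback order is returned.
    """
    _check_seqs(a, b)
    params = params or default_params()
    alignments = _aligners.get(params, "local").align(a, b)
    best = alignments[0]
    return float(best.score), (str(best[0]), str(best[1]))


def global_score(a: str, b: str, params: Optional[AlignmentParams] = None) -> float:
    """Optimal Needleman-Wunsch global score with end gaps penalized."""
    _check_seqs(a, b)
    params = params or default_params()
    return float(_aligners.get(params, "global").score(a, b))


def global_align_map(reference: str, target: str,
                     params: Optional[AlignmentParams] = None) -> list[Optional[int]]:
    """Map reference residue positions onto a target via global alignment.

    Returns a list of length ``len(reference)`` whose i-th entry (0-based)
    is the 0-based target index aligned to reference position i, or None
    when that reference residue aligns to a gap. The non-None entries are
    strictly increasing; the map is deterministic (first optimal alignment
    in canonical traceback order).
    """
    _check_seqs(reference, target)
    params = params or default_params()
    alignments = _aligners.get(params, "global").align(reference, target)
    best = alignments[0]
    mapping: list[Optional[int]] = [None] * len(reference)
    ref_blocks, tgt_blocks = best.aligned
    for (rs, re_), (ts, _te) in zip(ref_blocks, tgt_blocks):
        for k in range(re_ - rs):
            mapping[rs + k] = ts + k
    return mapping


def evalue(score: float, query_len: int, db_residues: int,
           params: Optional[AlignmentParams] = None) -> float:
    """Karlin-Altschul expected number of chance hits: K * m * n * exp(-lambda*S).

    Strictly decreasing in score, linear in both lengths. Underflows to 0.0
    for very high scores; use :func:`log10_evalue` for robust comparisons.
    """
    if query_len <= 0 or db_residues <= 0:
        raise ValueError("sequence lengths must be positive")
    if score < 0:
        raise ValueError("score must be non-negative")
    params = params or default_params()
    return params.karlin_k * query_len * db_residues * math.exp(
        -params.karlin_lambda * score)


def log10_evalue(score: float, query_len: int, db_residues: int,
                 params: Optional[AlignmentParams] = None) -> float:
    """log10 of :func:`evalue`; immune to floating-point underflow."""
    if query_len <= 0 or db_residues <= 0:
        raise ValueError("sequence lengths must be positive")
    if score < 0:
        raise ValueError("score must be non-negative")
    params = params or default_params()
    return (math.log10(params.karlin_k) + math.log10(query_len)
            + math.log10(db_residues) - params.karlin_lambda * score * LOG10E)
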