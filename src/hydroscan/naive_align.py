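"""Reference alignment scorers by exhaustive enumeration and plain DP.

These exist to validate the production aligner on tiny inputs and are
deliberately written along completely different lines: an explicit
recursive enumeration of every gapped alignment, and an independent
textbook Gotoh dynamic program in pure Python. Costs are exponential /
unoptimized; use only on short peptides.
"""

from __future__ import annotations

from typing import Optional

from .align import AlignmentParams, default_params


def _score_pair(a: str, b: str, params: AlignmentParams) -> float:
    return float(params.substitution_matrix[a, b])


def enumerate_global(a: str, b: str, params: Optional[AlignmentParams] = None) -> float:
    """Best global alignment score by recursion over all alignments.

    End gaps are penalized. Affine gap state is carried explicitly:
    extending an open gap costs gap_extend, opening costs
    gap_open + gap_extend (BLAST convention).
    """
    params = params or default_params()
    open_cost = params.gap_open + params.gap_extend
    extend_cost = params.gap_extend

    def rec(i: int, j: int, state: int) -> float:
        # state: 0 = no open gap, 1 = gap in b (a consumed), 2 = gap in a
        if i == len(a) and j == len(b):
            return 0.0
        best = -float("inf")
        if i < len(a) and j < len(b):
            s = _score_pair(a[i], b[j], params) + rec(i + 1, j + 1, 0)
            best = max(best, s)
        if i < len(a):
            cost = extend_cost if state == 1 else open_cost
            best = max(best, -cost + rec(i + 1, j, 1))
        if j < len(b):
            cost = extend_cost if state == 2 else open_cost
            best = max(best, -cost + rec(i, j + 1, 2))
        return best

    return rec(0, 0, 0)


def enumerate_local(a: str, b: str, params: Optional[AlignmentParams] = None) -> float:
    """Best local alignment score as the max over all substring pairs.

    Every local alignment is a global alignment of the substrings it
    covers, so maximizing :func:`enumerate_global` over all substring
    pairs (plus the empty alignment at score 0) is exhaustive.
    """
    params = params or default_params()
    best = 0.0
    for i in range(len(a)):
        for j in range(i + 1, len(a) + 1):
            sub_a = a[i:j]
            for k in range(len(b)):
                for l in range(k + 1, len(b) + 1):
                    best = max(best, enumerate_global(sub_a, b[k:l], params))
    return best


def gotoh_local(a: str, b: str, params: Optional[AlignmentParams] = None) -> float:
    """Smith-Waterman-Gotoh affine local score, plain-Python three-matrix DP."""
    params = params or default_params()
    open_cost = params.gap_open + params.gap_extend
    extend_cost = params.gap_extend
    n, m = len(a), len(b)
    NEG = -float("inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - open_cost, E[i][j - 1] - extend_cost)
            F[i][j] = max(H[i - 1][j] - open_cost, F[i - 1][j] - extend_cost)
            diag = H[i - 1][j - 1] + _score_pair(a[i - 1], b[j - 1], params)
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def gotoh_global(a: str, b: str, params: Optional[AlignmentParams] = None) -> float:
    """Needleman-Wunsch-Gotoh affine global score with end gaps penalized."""
    params = params or default_params()
    open_cost = params.gap_open + params.gap_extend
    extend_cost = params.gap_extend
    n, m = len(a), len(b)
    NEG = -float("inf")
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    H[0][0] = 0.0
    for j in range(1, m + 1):
        E[0][j] = -open_cost - (j - 1) * extend_cost
        H[0][j] = E[0][j]
    for i in range(1, n + 1):
        F[i][0] = -open_cost - (i - 1) * extend_cost
        H[i][0] = F[i][0]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - open_cost, E[i][j - 1] - extend_cost)
            F[i][j] = max(H[i - 1][j] - open_cost, F[i - 1][j] - extend_cost)
            diag = H[i - 1][j - 1] + _score_pair(a[i - 1], b[j - 1], params)
            H[i][j] = max(diag, E[i][j], F[i][j])
    return H[n][m]
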