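"""Independent exhaustive Smith-Waterman oracle for tiny sequences.

Plain-Python Gotoh dynamic programming with affine gaps (a gap of length g
costs open + g * extend, i.e. the first gap residue costs open + extend).
Used only in tests, as the ground truth the production aligner is checked
against on sequences short enough for exhaustive traceback enumeration.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

NEG = float("-inf")


def _score_fn(matrix_name: str = "BLOSUM62"):
    m = substitution_matrices.load(matrix_name)
    return lambda a, b: float(m[a][b])


def sw_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Best local alignment score (Gotoh affine DP)."""
    s = _score_fn()
    first = gap_open + gap_extend
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            H[i][j] = max(
                0.0,
                H[i - 1][j - 1] + s(a[i - 1], b[j - 1]),
                E[i][j],
                F[i][j],
            )
            best = max(best, H[i][j])
    return best


def sw_optimal_stats(
    a: str, b: str, gap_open: int = 11, gap_extend: int = 1, cap: int = 20000
) -> tuple[float, set[tuple[int, int]]]:
    """Best score plus the set of (identities, columns) over ALL optimal
    local alignments, by exhaustive traceback enumeration."""
    s = _score_fn()
    first = gap_open + gap_extend
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            H[i][j] = max(
                0.0, H[i - 1][j - 1] + s(a[i - 1], b[j - 1]), E[i][j], F[i][j]
            )
    best = max(max(row) for row in H)
    stats: set[tuple[int, int]] = set()
    if best == 0.0:
        return best, stats

    paths = 0

    def walk(i: int, j: int, state: str, ident: int, cols: int) -> None:
        nonlocal paths
        if paths > cap:
            return
        if state == "H":
            if H[i][j] == 0.0:
                paths += 1
                stats.add((ident, cols))
                return
            diag = H[i - 1][j - 1] + s(a[i - 1], b[j - 1])
            if H[i][j] == diag:
                walk(
                    i - 1, j - 1, "H",
                    ident + (a[i - 1] == b[j - 1]), cols + 1,
                )
            if H[i][j] == E[i][j]:
                walk(i, j, "E", ident, cols)
            if H[i][j] == F[i][j]:
                walk(i, j, "F", ident, cols)
        elif state == "E":
            if E[i][j] == H[i][j - 1] - first:
                walk(i, j - 1, "H", ident, cols + 1)
            if E[i][j] == E[i][j - 1] - gap_extend:
                walk(i, j - 1, "E", ident, cols + 1)
        else:
            if F[i][j] == H[i - 1][j] - first:
                walk(i - 1, j, "H", ident, cols + 1)
            if F[i][j] == F[i - 1][j] - gap_extend:
                walk(i - 1, j, "F", ident, cols + 1)

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if H[i][j] == best:
                walk(i, j, "H", 0, 0)
    return best, stats
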