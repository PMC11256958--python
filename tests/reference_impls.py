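"""Independent reference implementations used only as test oracles.

Deliberately simple and slow: a dictionary-driven Gotoh local-alignment DP
(score only) and a plain row-scan conserved-protein counter. They share no
code with the package paths they check.
"""

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def reference_local_score(query: str, subject: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Affine-gap Smith-Waterman score; gap of length g costs open + g*ext."""
    m, n = len(query), len(subject)
    neg = float("-inf")
    open_cost = gap_open + gap_extend
    best = 0
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[neg] * (n + 1) for _ in range(m + 1)]
    F = [[neg] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - open_cost, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - open_cost, F[i - 1][j] - gap_extend)
            sub = _B62[query[i - 1], subject[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)


def reference_count_conserved(rows, max_evalue=1e-5, min_identity=40.0, min_coverage=50.0):
    """Row scan over plain tuples (qid, pident, qstart, qend, evalue, qlen)."""
    passing = set()
    for qid, pident, qstart, qend, evalue, qlen in rows:
        coverage = 100.0 * (qend - qstart + 1) / qlen
        if evalue < max_evalue and pident > min_identity and coverage > min_coverage:
            passing.add(qid)
    return len(passing)
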