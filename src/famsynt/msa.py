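"""Progressive protein multiple alignment.

A self-contained ClustalW-style aligner: pairwise k-mer distances give a
UPGMA guide tree, and groups are merged by affine-gap Needleman–Wunsch on
frequency profiles scored with BLOSUM62 (gap open 10, gap extend 0.5).
The alignment is a means to distances and codon threading, not an end.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = ["align_pair", "progressive_align"]

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}
N_STATES = len(AA) + 1  # +1 silent state for gaps/unknowns (scores 0)

GAP_OPEN = 10.0
GAP_EXTEND = 0.5
NEG = -1e30


def _blosum() -> np.ndarray:
    b62 = substitution_matrices.load("BLOSUM62")
    M = np.zeros((N_STATES, N_STATES))
    for i, a in enumerate(AA):
        for j, b in enumerate(AA):
            M[i, j] = b62[a, b]
    return M


_B = _blosum()


def _profile(rows: list[str]) -> np.ndarray:
    """Column frequency profile (L x N_STATES) of equal-length sequences."""
    L = len(rows[0])
    P = np.zeros((L, N_STATES))
    for r in rows:
        idx = np.fromiter((AA_INDEX.get(c, N_STATES - 1) for c in r), dtype=np.int64, count=L)
        P[np.arange(L), idx] += 1.0
    P /= len(rows)
    return P


def _nw_profiles(pa: np.ndarray, pb: np.ndarray) -> list[str]:
    """Affine-gap global alignment of two profiles; returns column ops.

    Ops: 'M' consumes a column of both profiles, 'A' only of the first,
    'B' only of the second. Gap-to-gap transitions are not modelled.
    """
    n, m = len(pa), len(pb)
    S = pa @ _B @ pb.T  # (n, m) expected column match scores
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (consumes a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (consumes b)
    M[0, 0] = 0.0
    if n:
        X[1:, 0] = -GAP_OPEN - np.arange(n) * GAP_EXTEND
    if m:
        Y[0, 1:] = -GAP_OPEN - np.arange(m) * GAP_EXTEND
    js = np.arange(m + 1)
    for i in range(1, n + 1):
        best_prev = np.maximum(np.maximum(M[i - 1, :-1], X[i - 1, :-1]), Y[i - 1, :-1])
        M[i, 1:] = S[i - 1] + best_prev
        X[i, 1:] = np.maximum(M[i - 1, 1:] - GAP_OPEN, X[i - 1, 1:] - GAP_EXTEND)
        # Y[i, j] = max_{k<j} M[i, k] - open - (j-1-k)*extend, via running max
        T = np.maximum.accumulate(M[i] + js * GAP_EXTEND)
        Y[i, 1:] = T[:-1] - GAP_OPEN - js[1:] * GAP_EXTEND
        Y[i, 0] = NEG
    # traceback
    ops: list[str] = []
    i, j = n, m
    state = max((("M", M[n, m]), ("A", X[n, m]), ("B", Y[n, m])), key=lambda t: t[1])[0]
    eps = 1e-9
    while i > 0 or j > 0:
        if i == 0:
            ops.append("B")
            j -= 1
            continue
        if j == 0:
            ops.append("A")
            i -= 1
            continue
        if state == "M":
            ops.append("M")
            prev = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            if abs(prev - M[i, j]) < eps:
                state = "M"
            elif abs(prev - X[i, j]) < eps:
                state = "A"
            else:
                state = "B"
        elif state == "A":
            ops.append("A")
            if abs(X[i, j] - (M[i - 1, j] - GAP_OPEN)) < eps:
                state = "M"
            i -= 1
        else:
            ops.append("B")
            # re-derive the gap origin k for the running-max formulation
            if abs(Y[i, j] - (M[i, j - 1] - GAP_OPEN)) < eps:
                state = "M"
            j -= 1
    ops.reverse()
    return ops


def _merge(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    ops = _nw_profiles(_profile(rows_a), _profile(rows_b))
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in ("M", "A"):
            for k, r in enumerate(rows_a):
                out_a[k] += r[ia]
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += "-"
        if op in ("M", "B"):
            for k, r in enumerate(rows_b):
                out_b[k] += r[ib]
            ib += 1
        else:
            for k in range(len(rows_b)):
                out_b[k] += "-"
    return out_a, out_b


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    if len(a) < k or len(b) < k:
        return 1.0
    ca = Counter(a[i : i + k] for i in range(len(a) - k + 1))
    cb = Counter(b[i : i + k] for i in range(len(b) - k + 1))
    common = sum(min(ca[w], cb[w]) for w in ca)
    return 1.0 - common / (min(len(a), len(b)) - k + 1)


def align_pair(a: str, b: str) -> tuple[str, str]:
    """Global alignment of two protein sequences."""
    (ra,), (rb,) = _merge([a], [b])
    return ra, rb


def progressive_align(seqs: dict[str, str]) -> dict[str, str]:
    """Multiple alignment of named sequences; input order does not matter
    (the guide tree is built on sorted ids for determinism)."""
    ids = sorted(seqs)
    if not ids:
        return {}
    if len(ids) == 1:
        return {ids[0]: seqs[ids[0]]}
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _kmer_distance(seqs[ids[i]], seqs[ids[j]])
    Z = linkage(squareform(D, checks=False), method="average")
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [seqs[ids[i]]]) for i in range(n)
    }
    for step, (a, b, _, _) in enumerate(Z):
        ids_a, rows_a = clusters.pop(int(a))
        ids_b, rows_b = clusters.pop(int(b))
        new_a, new_b = _merge(rows_a, rows_b)
        clusters[n + step] = (ids_a + ids_b, new_a + new_b)
    (names, rows), = clusters.values()
    return dict(zip(names, rows))
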