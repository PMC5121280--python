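"""Shared codon-level machinery: genetic code tables, NG86 site/difference
counts, and the Goldman–Yang-style codon rate matrix used by the simulator.

All counting follows the standard genetic code (table 1). Site counts use the
classic convention in which every one of the nine single-nucleotide neighbours
of a codon contributes 1/3 of a site; neighbours that are stop codons count as
nonsynonymous, so S + N = 3 for every sense codon. Difference counts average
over all minimal mutational pathways, dropping pathways that pass through a
stop codon and renormalising the weights of those that remain.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations, product

import numpy as np
from Bio.Data import CodonTable

NUCS = ("T", "C", "A", "G")
_TABLE = CodonTable.unambiguous_dna_by_id[1]

ALL_CODONS = tuple("".join(p) for p in product(NUCS, repeat=3))
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)
SENSE_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_SENSE = len(SENSE_CODONS)  # 61

#: codon -> single-letter amino acid, stops mapped to '*'
CODON_TO_AA = {c: ("*" if c in STOP_CODONS else _TABLE.forward_table[c]) for c in ALL_CODONS}

_PURINES = frozenset("AG")


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a->b is a transition."""
    return a != b and ((a in _PURINES) == (b in _PURINES))


def translate_cds(cds: str) -> str:
    """Translate an in-frame CDS (no ambiguity codes); stops become '*'."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    return "".join(CODON_TO_AA[cds[i : i + 3]] for i in range(0, len(cds), 3))


@lru_cache(maxsize=1)
def site_counts() -> dict[str, tuple[float, float]]:
    """Per-codon (S, N) synonymous/nonsynonymous site counts, S + N = 3."""
    out = {}
    for codon in SENSE_CODONS:
        syn = 0
        for pos in range(3):
            for nuc in NUCS:
                if nuc == codon[pos]:
                    continue
                alt = codon[:pos] + nuc + codon[pos + 1 :]
                if alt not in STOP_CODONS and CODON_TO_AA[alt] == CODON_TO_AA[codon]:
                    syn += 1
        s = syn / 3.0
        out[codon] = (s, 3.0 - s)
    return out


def _pathway_steps(c1: str, c2: str, order: tuple[int, ...]):
    """Yield (from_codon, to_codon) steps mutating positions of c1 in `order`."""
    cur = c1
    for pos in order:
        nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
        yield cur, nxt
        cur = nxt


def pathway_diff(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (Sd, Nd) between two sense codons.

    All orderings of the differing positions are enumerated; orderings whose
    intermediate codons include a stop are excluded and the remaining weights
    renormalised. If every ordering is blocked, all orderings are used with
    steps into/out of stop codons counted as nonsynonymous.
    """
    diff = tuple(i for i in range(3) if c1[i] != c2[i])
    if not diff:
        return (0.0, 0.0)
    valid, blocked = [], []
    for order in permutations(diff):
        sd = nd = 0
        ok = True
        for a, b in _pathway_steps(c1, c2, order):
            if b in STOP_CODONS or a in STOP_CODONS:
                ok = False
            if CODON_TO_AA[a] == CODON_TO_AA[b]:
                sd += 1
            else:
                nd += 1
        (valid if ok else blocked).append((sd, nd))
    paths = valid if valid else blocked
    w = 1.0 / len(paths)
    return (w * sum(p[0] for p in paths), w * sum(p[1] for p in paths))


@lru_cache(maxsize=1)
def diff_table() -> dict[tuple[str, str], tuple[float, float]]:
    """Lookup of pathway-averaged (Sd, Nd) for every ordered sense-codon pair."""
    out = {}
    for c1 in SENSE_CODONS:
        for c2 in SENSE_CODONS:
            out[(c1, c2)] = pathway_diff(c1, c2)
    return out


def gy_rate_matrix(omega: float, kappa: float) -> np.ndarray:
    """61x61 continuous-time rate matrix, uniform codon frequencies.

    Off-diagonal rate between single-nucleotide neighbours is kappa for
    transitions (1 for transversions), multiplied by omega when the change is
    nonsynonymous. Scaled so the stationary mean substitution rate is one
    substitution per codon per unit branch length.
    """
    if omega < 0 or kappa <= 0:
        raise ValueError("omega must be >= 0 and kappa > 0")
    Q = np.zeros((N_SENSE, N_SENSE))
    for i, c1 in enumerate(SENSE_CODONS):
        for pos in range(3):
            for nuc in NUCS:
                if nuc == c1[pos]:
                    continue
                c2 = c1[:pos] + nuc + c1[pos + 1 :]
                j = SENSE_INDEX.get(c2)
                if j is None:  # stop codon: substitution rejected
                    continue
                rate = kappa if is_transition(c1[pos], nuc) else 1.0
                if CODON_TO_AA[c1] != CODON_TO_AA[c2]:
                    rate *= omega
                Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -np.mean(np.diag(Q))  # uniform frequencies
    if mean_rate > 0:
        Q /= mean_rate
    return Q
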