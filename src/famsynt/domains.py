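"""Domain-based family identification.

Family membership is defined structurally: a protein belongs to the family
iff it carries at least one QLQ (Gln-Leu-Gln protein-interaction) domain and
at least one WRC (Trp-Arg-Cys zinc-finger DNA-binding) domain. Domains are
found with position-specific scoring matrices built from packaged seed
alignments (synthetic seeds shipped under ``famsynt/data``): log-odds in
bits against a uniform background, additive pseudocounts, and a default
reporting threshold of 60% of the maximum attainable score. Hit E-values
come from a Gumbel tail fitted to shuffled-window scores at build time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.stats import gumbel_r

from .genome_io import Genome, read_fasta

__all__ = [
    "PSSM",
    "DomainHit",
    "FamilyMember",
    "build_pssm",
    "scan_protein",
    "call_family",
    "load_seed_alignment",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA20)}
_CALIBRATION_WINDOWS = 10_000
_CALIBRATION_SEED = 77  # fixed so a PSSM built twice is identical


@dataclass
class PSSM:
    domain_name: str
    matrix: np.ndarray  # (width, 20) log-odds in bits
    probs: np.ndarray  # (width, 20) column probabilities (sum to 1)
    threshold: float  # bits
    gumbel_loc: float = 0.0
    gumbel_scale: float = 1.0

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(AA20[i] for i in self.probs.argmax(axis=1))

    def tail_p(self, score: float) -> float:
        """P(window score >= score) for a random background window."""
        return float(gumbel_r.sf(score, loc=self.gumbel_loc, scale=self.gumbel_scale))


@dataclass
class DomainHit:
    gene_id: str
    domain_name: str
    start: int  # 1-based protein coordinates, inclusive
    end: int
    score: float  # bits
    evalue: float


@dataclass
class FamilyMember:
    member_id: str
    gene_id: str
    species: str
    chrom: str
    start: int
    end: int
    n_qlq: int
    n_wrc: int
    hits: list[DomainHit] = field(default_factory=list)


def load_seed_alignment(domain_name: str) -> list[str]:
    """Packaged synthetic seed alignment for 'QLQ' or 'WRC'."""
    fname = f"{domain_name.lower()}_seed.fasta"
    with resources.as_file(resources.files("famsynt.data") / fname) as path:
        return list(read_fasta(path).values())


def build_pssm(
    seed_alignment: list[str],
    domain_name: str = "domain",
    pseudocount: float = 0.5,
    threshold_frac: float = 0.6,
) -> PSSM:
    """Log-odds PSSM (bits, uniform 1/20 background) from a seed alignment.

    Only fully ungapped columns are used; all-gap or partially gapped
    columns are dropped with a warning. The reporting threshold defaults to
    ``threshold_frac`` of the maximum attainable score, and a Gumbel null is
    fitted on shuffled windows drawn from the seed residue composition.
    """
    if len(seed_alignment) < 3:
        raise ValueError("need at least 3 seed sequences")
    L = len(seed_alignment[0])
    if any(len(s) != L for s in seed_alignment):
        raise ValueError("seed sequences must be aligned (equal length)")
    cols = []
    n_dropped = 0
    for j in range(L):
        column = [s[j] for s in seed_alignment]
        if any(c in "-." for c in column):
            n_dropped += 1
            continue
        cols.append(column)
    if n_dropped:
        warnings.warn(f"{domain_name}: dropped {n_dropped} gapped column(s)")
    if len(cols) < 5:
        raise ValueError("fewer than 5 ungapped columns in seed alignment")
    counts = np.zeros((len(cols), 20))
    for j, column in enumerate(cols):
        for c in column:
            counts[j, AA_INDEX[c]] += 1.0
    probs = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + 20.0 * pseudocount)
    with np.errstate(divide="ignore"):
        matrix = np.log2(probs * 20.0)
    matrix = np.maximum(matrix, -100.0)  # finite floor for residues unseen at pseudocount 0
    pssm = PSSM(domain_name=domain_name, matrix=matrix, probs=probs, threshold=0.0)
    pssm.threshold = threshold_frac * pssm.max_score
    # Gumbel null from windows of the (shuffled) seed composition
    rng = np.random.default_rng(_CALIBRATION_SEED)
    pool = np.array([AA_INDEX[c] for col in cols for c in col])
    draws = pool[rng.integers(0, len(pool), size=(_CALIBRATION_WINDOWS, len(cols)))]
    scores = matrix[np.arange(len(cols)), draws].sum(axis=1)
    pssm.gumbel_loc, pssm.gumbel_scale = gumbel_r.fit(scores)
    return pssm


def _window_scores(protein: str, pssm: PSSM) -> np.ndarray:
    w = pssm.width
    n = len(protein) - w + 1
    if n <= 0:
        return np.zeros(0)
    idx = np.fromiter((AA_INDEX.get(c, -1) for c in protein), dtype=np.int64, count=len(protein))
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    valid = windows >= 0
    safe = np.where(valid, windows, 0)
    per_pos = pssm.matrix[np.arange(w)[None, :], safe]
    per_pos = np.where(valid, per_pos, np.log2(1.0 / 20.0))  # unknown residue
    return per_pos.sum(axis=1)


def scan_protein(protein: str, pssm: PSSM, gene_id: str = "") -> list[DomainHit]:
    """All windows scoring at or above threshold, greedily made non-overlapping.

    Overlap resolution keeps the best-scoring windows first (ties to the
    leftmost). Sequences shorter than the PSSM width yield no hits.
    """
    scores = _window_scores(protein, pssm)
    order = sorted(
        (i for i in range(len(scores)) if scores[i] >= pssm.threshold),
        key=lambda i: (-scores[i], i),
    )
    n_windows = max(len(scores), 1)
    taken: list[tuple[int, int]] = []
    hits: list[DomainHit] = []
    for i in order:
        s, e = i, i + pssm.width - 1
        if any(s <= te and e >= ts for ts, te in taken):
            continue
        taken.append((s, e))
        hits.append(
            DomainHit(
                gene_id=gene_id,
                domain_name=pssm.domain_name,
                start=s + 1,
                end=e + 1,
                score=float(scores[i]),
                evalue=n_windows * pssm.tail_p(float(scores[i])),
            )
        )
    hits.sort(key=lambda h: h.start)
    return hits


def call_family(
    genomes: list[Genome],
    pssms: dict[str, PSSM],
    prefix: dict[str, str] | None = None,
) -> list[FamilyMember]:
    """Identify family members: >=1 QLQ hit and >=1 WRC hit required.

    Members are named <prefix><NN> per species, numbered along chromosomes
    (chromosome name, then start). The default prefix is the species name
    followed by 'GRF'. The result is independent of input gene order.
    """
    if "QLQ" not in pssms or "WRC" not in pssms:
        raise ValueError("both QLQ and WRC PSSMs are required")
    members: list[FamilyMember] = []
    for genome in genomes:
        pre = (prefix or {}).get(genome.species, f"{genome.species}GRF")
        found = []
        for gene in genome.genes():  # sorted by chrom then start
            if not gene.protein_seq:
                continue
            qlq = scan_protein(gene.protein_seq, pssms["QLQ"], gene.gene_id)
            if not qlq:
                continue
            wrc = scan_protein(gene.protein_seq, pssms["WRC"], gene.gene_id)
            if not wrc:
                continue
            found.append((gene, qlq, wrc))
        for i, (gene, qlq, wrc) in enumerate(found, start=1):
            members.append(
                FamilyMember(
                    member_id=f"{pre}{i:02d}",
                    gene_id=gene.gene_id,
                    species=genome.species,
                    chrom=gene.chrom,
                    start=gene.start,
                    end=gene.end,
                    n_qlq=len(qlq),
                    n_wrc=len(wrc),
                    hits=qlq + wrc,
                )
            )
    return members
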