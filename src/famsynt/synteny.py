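"""Anchor-centred microsynteny detection and duplication-mode classification.

Each family member is an anchor; the protein-coding genes within a flank
radius (default 100 kb) on either side form its flank set. Conserved
flanking pairs are reciprocal best Smith–Waterman matches (BLOSUM62, gap
open 11 / extend 1) between the two flank sets passing an E-value cutoff
(default 1e-10, Karlin–Altschul statistics). A pair of anchors is called:

* ``tandem`` — same chromosome with at most ``max_intervening`` (default 1)
  genes between the anchors; takes precedence over the other calls;
* ``large_scale`` — at least ``min_pairs`` (default 4) conserved flanking
  pairs, the signature of a segmental/whole-genome duplication block;
* ``relaxed`` — 2 or 3 conserved pairs (weaker, older blocks);
* ``none`` — otherwise.

The same rules serve intra- and inter-species comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import GeneModel, Genome

__all__ = [
    "FlankSet",
    "MatchPair",
    "SyntenyBlock",
    "ProteinScorer",
    "extract_flanks",
    "best_nonself_matches",
    "classify_duplication",
    "interspecies_synteny",
    "non_syntenic_members",
]

# gapped BLASTP-like Karlin-Altschul constants; exposed so they can be
# overridden in a pipeline config
KA_LAMBDA = 0.267
KA_K = 0.041


@dataclass
class FlankSet:
    anchor_id: str
    species: str
    chrom: str
    window: tuple[int, int]
    genes: list[GeneModel]

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def total_residues(self) -> int:
        return sum(len(g.protein_seq) for g in self.genes)


@dataclass
class MatchPair:
    gene_a: str
    gene_b: str
    score: float
    evalue: float


@dataclass
class SyntenyBlock:
    anchor_a: str
    anchor_b: str
    scope: str  # intra | inter
    pairs: list[MatchPair] = field(default_factory=list)
    classification: str = "none"

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


class ProteinScorer:
    """Cached local protein alignment scores with Karlin–Altschul E-values."""

    def __init__(
        self,
        gap_open: float = 11.0,
        gap_extend: float = 1.0,
        ka_lambda: float = KA_LAMBDA,
        ka_k: float = KA_K,
    ):
        self.aligner = Align.PairwiseAligner()
        self.aligner.mode = "local"
        self.aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        self.aligner.open_gap_score = -gap_open
        self.aligner.extend_gap_score = -gap_extend
        self.ka_lambda = ka_lambda
        self.ka_k = ka_k
        self._cache: dict[tuple[str, str], float] = {}

    def score(self, id_a: str, seq_a: str, id_b: str, seq_b: str) -> float:
        key = (id_a, id_b) if id_a <= id_b else (id_b, id_a)
        s = self._cache.get(key)
        if s is None:
            if not seq_a or not seq_b:
                s = 0.0
            else:
                s = float(self.aligner.score(seq_a, seq_b))
            self._cache[key] = s
        return s

    def evalue(self, score: float, m: int, n: int) -> float:
        """E = K*m*n*exp(-lambda*S) for search space m (query) x n (database)."""
        return self.ka_k * m * max(n, 1) * math.exp(-self.ka_lambda * score)


def extract_flanks(genome: Genome, anchor_id: str, radius_bp: int = 100_000) -> FlankSet:
    """Genes whose span intersects [anchor.start - r, anchor.end + r].

    The anchor itself is excluded; the window is clipped implicitly at
    chromosome ends (an anchor at the start simply has no upstream genes).
    """
    anchor = genome.get(anchor_id)
    lo = anchor.start - radius_bp
    hi = anchor.end + radius_bp
    genes = [
        g
        for g in genome.chromosomes[anchor.chrom]
        if g.gene_id != anchor_id and g.span_overlaps(lo, hi)
    ]
    return FlankSet(
        anchor_id=anchor_id, species=genome.species, chrom=anchor.chrom,
        window=(lo, hi), genes=genes,
    )


def best_nonself_matches(
    flanks_a: FlankSet,
    flanks_b: FlankSet,
    evalue_max: float = 1e-10,
    scorer: ProteinScorer | None = None,
    exclude: set[str] | None = None,
    reciprocal: bool = True,
) -> list[MatchPair]:
    """Conserved flanking-gene pairs between two flank sets.

    For every gene in one set the highest-scoring non-self partner in the
    other set is found; a pair is conserved iff it is the best hit in both
    directions (set ``reciprocal=False`` for one-directional best hits) and
    its E-value passes the cutoff. Pairing is one-to-one, greedy by score
    with ties to the smaller gene-id pair. The E-value uses the larger of
    the two query lengths against the larger flank-set database, keeping
    the result symmetric in the argument order.
    """
    scorer = scorer or ProteinScorer()
    exclude = exclude or set()
    genes_a = [g for g in flanks_a.genes if g.gene_id not in exclude]
    genes_b = [g for g in flanks_b.genes if g.gene_id not in exclude]
    if not genes_a or not genes_b:
        return []

    def best_partner(g: GeneModel, others: list[GeneModel]) -> tuple[str, float] | None:
        cands = [
            (o, scorer.score(g.gene_id, g.protein_seq, o.gene_id, o.protein_seq))
            for o in others
            if o.gene_id != g.gene_id
        ]
        if not cands:
            return None
        # deterministic: highest score, ties to the smallest gene id
        best = sorted(cands, key=lambda t: (-t[1], t[0].gene_id))[0]
        return best[0].gene_id, best[1]

    best_ab = {g.gene_id: best_partner(g, genes_b) for g in genes_a}
    best_ba = {g.gene_id: best_partner(g, genes_a) for g in genes_b}
    n_db = max(flanks_a.total_residues, flanks_b.total_residues)
    by_id_a = {g.gene_id: g for g in genes_a}
    by_id_b = {g.gene_id: g for g in genes_b}

    candidates: list[MatchPair] = []
    for ga, hit in best_ab.items():
        if hit is None:
            continue
        gb, score = hit
        if reciprocal:
            back = best_ba.get(gb)
            if back is None or back[0] != ga:
                continue
        m = max(len(by_id_a[ga].protein_seq), len(by_id_b[gb].protein_seq))
        ev = scorer.evalue(score, m, n_db)
        if ev <= evalue_max:
            candidates.append(MatchPair(gene_a=ga, gene_b=gb, score=score, evalue=ev))
    # one-to-one greedy (already one-to-one under reciprocal best hits)
    candidates.sort(key=lambda p: (-p.score, p.gene_a, p.gene_b))
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairs = []
    for p in candidates:
        if p.gene_a in used_a or p.gene_b in used_b:
            continue
        used_a.add(p.gene_a)
        used_b.add(p.gene_b)
        pairs.append(p)
    return pairs


def _intervening_genes(genome: Genome, a: GeneModel, b: GeneModel) -> int:
    order = genome.chromosomes[a.chrom]
    ia, ib = order.index(a), order.index(b)
    return abs(ia - ib) - 1


def classify_duplication(
    genome_a: Genome,
    genome_b: Genome,
    anchor_a: str,
    anchor_b: str,
    radius_bp: int = 100_000,
    evalue_max: float = 1e-10,
    min_pairs: int = 4,
    max_intervening: int = 1,
    scorer: ProteinScorer | None = None,
    reciprocal: bool = True,
) -> SyntenyBlock:
    """Classify one anchor pair; symmetric in the anchor order.

    Tandem (same chromosome, adjacent up to ``max_intervening`` intervening
    genes) takes precedence; otherwise the conserved-flanking-pair count
    decides large_scale (>= min_pairs) vs relaxed (2-3) vs none.
    """
    scope = "intra" if genome_a.species == genome_b.species else "inter"
    ga, gb = genome_a.get(anchor_a), genome_b.get(anchor_b)
    block = SyntenyBlock(anchor_a=anchor_a, anchor_b=anchor_b, scope=scope)
    if scope == "intra" and ga.chrom == gb.chrom:
        if _intervening_genes(genome_a, ga, gb) <= max_intervening:
            block.classification = "tandem"
            return block
    flanks_a = extract_flanks(genome_a, anchor_a, radius_bp)
    flanks_b = extract_flanks(genome_b, anchor_b, radius_bp)
    block.pairs = best_nonself_matches(
        flanks_a, flanks_b, evalue_max=evalue_max, scorer=scorer,
        exclude={anchor_a, anchor_b}, reciprocal=reciprocal,
    )
    n = block.n_pairs
    if n >= min_pairs:
        block.classification = "large_scale"
    elif n >= 2:
        block.classification = "relaxed"
    return block


def interspecies_synteny(
    genome_a: Genome,
    genome_b: Genome,
    members_a: list[str],
    members_b: list[str],
    radius_bp: int = 100_000,
    evalue_max: float = 1e-10,
    min_pairs: int = 4,
    scorer: ProteinScorer | None = None,
) -> list[SyntenyBlock]:
    """All member x member anchor pairs between two species.

    Blocks with at least 2 conserved flanking pairs are reported, classified
    with the same thresholds as intra-species blocks.
    """
    if genome_a.species == genome_b.species:
        raise ValueError("interspecies_synteny needs two distinct species")
    scorer = scorer or ProteinScorer()
    blocks = []
    for a in members_a:
        for b in members_b:
            block = classify_duplication(
                genome_a, genome_b, a, b, radius_bp=radius_bp,
                evalue_max=evalue_max, min_pairs=min_pairs, scorer=scorer,
            )
            if block.n_pairs >= 2:
                blocks.append(block)
    return blocks


def non_syntenic_members(members: list[str], blocks: list[SyntenyBlock]) -> list[str]:
    """Members that anchor no reported block."""
    anchored = {b.anchor_a for b in blocks} | {b.anchor_b for b in blocks}
    return [m for m in members if m not in anchored]
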