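import numpy as np
import pytest

from famsynt.genome_io import GeneModel, Genome
from famsynt.simulate import SimulationConfig, simulate, shuffle_genome_order
from famsynt.synteny import (
    ProteinScorer,
    best_nonself_matches,
    classify_duplication,
    extract_flanks,
    interspecies_synteny,
    non_syntenic_members,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _linear_genome(n=30, spacing=10_000, species="sp", prefix="g", seed=0):
    rng = np.random.default_rng(seed)
    genome = Genome(species)
    for i in range(n):
        start = 1 + i * spacing
        prot = "".join(AA[j] for j in rng.integers(0, 20, 120))
        genome.add_gene(
            GeneModel(f"{prefix}{i:03d}", "chr1", start, start + 360, "+",
                      [(start, start + 360)], protein_seq=prot)
        )
    return genome


@pytest.fixture(scope="module")
def scorer():
    return ProteinScorer()


def test_flanks_at_chromosome_start_have_no_upstream_side():
    genome = _linear_genome()
    flanks = extract_flanks(genome, "g000", radius_bp=50_000)
    assert all(g.start > genome.get("g000").end for g in flanks.genes)
    assert len(flanks) == 5


def test_flank_radius_zero_keeps_only_overlapping_genes():
    genome = _linear_genome()
    assert len(extract_flanks(genome, "g010", radius_bp=0)) == 0


def test_flank_count_matches_fixture_geometry():
    # genes every 10 kb: a 100 kb radius catches 10 genes per side
    genome = _linear_genome(n=50)
    flanks = extract_flanks(genome, "g025", radius_bp=100_000)
    assert len(flanks) == 20


def test_unknown_anchor_is_error():
    with pytest.raises(KeyError):
        extract_flanks(_linear_genome(), "nope")


def test_identical_flank_sets_pair_every_gene(scorer):
    genome = _linear_genome(n=12)
    copy = Genome("sp2")
    for g in genome.genes():
        copy.add_gene(GeneModel("c_" + g.gene_id, g.chrom, g.start, g.end, g.strand,
                                list(g.exons), protein_seq=g.protein_seq))
    fa = extract_flanks(genome, "g005", radius_bp=10**9)
    fb = extract_flanks(copy, "c_g005", radius_bp=10**9)
    pairs = best_nonself_matches(fa, fb, scorer=scorer)
    assert len(pairs) == len(fa)
    assert all(p.gene_b == "c_" + p.gene_a for p in pairs)


def test_unrelated_random_proteins_yield_no_pairs(scorer):
    a = _linear_genome(n=15, seed=1)
    b = _linear_genome(n=15, species="sp2", prefix="h", seed=2)
    fa = extract_flanks(a, "g007", radius_bp=10**9)
    fb = extract_flanks(b, "h007", radius_bp=10**9)
    assert best_nonself_matches(fa, fb, scorer=scorer) == []


def test_one_to_one_pairing_no_gene_reused(scorer, one_species_sim):
    genomes, truth = one_species_sim
    genome = genomes[0]
    for a, b, etype, _ in truth.duplications:
        if etype != "segmental":
            continue
        fa = extract_flanks(genome, a)
        fb = extract_flanks(genome, b)
        pairs = best_nonself_matches(fa, fb, scorer=scorer, exclude={a, b})
        assert len({p.gene_a for p in pairs}) == len(pairs)
        assert len({p.gene_b for p in pairs}) == len(pairs)
        assert len(pairs) >= 4


def test_adjacent_family_genes_called_tandem(scorer, one_species_sim):
    genomes, truth = one_species_sim
    genome = genomes[0]
    for a, b, etype, _ in truth.duplications:
        blk = classify_duplication(genome, genome, a, b, scorer=scorer)
        want = "tandem" if etype == "tandem" else "large_scale"
        assert blk.classification == want


def test_classification_symmetric_in_anchor_order(scorer, one_species_sim):
    genomes, truth = one_species_sim
    genome = genomes[0]
    for a, b, _, _ in truth.duplications:
        f = classify_duplication(genome, genome, a, b, scorer=scorer)
        r = classify_duplication(genome, genome, b, a, scorer=scorer)
        assert f.classification == r.classification
        assert f.n_pairs == r.n_pairs


def test_distant_anchors_with_no_conserved_flankers_are_none(scorer):
    genome = _linear_genome(n=60, seed=3)
    blk = classify_duplication(genome, genome, "g005", "g055", scorer=scorer)
    assert blk.classification == "none"
    assert blk.n_pairs == 0


def test_n_pairs_monotone_in_evalue_and_radius(scorer, one_species_sim):
    genomes, truth = one_species_sim
    genome = genomes[0]
    seg = [d for d in truth.duplications if d[2] == "segmental"][0]
    a, b = seg[0], seg[1]

    def n_pairs(radius, emax):
        fa = extract_flanks(genome, a, radius)
        fb = extract_flanks(genome, b, radius)
        return len(best_nonself_matches(fa, fb, evalue_max=emax, scorer=scorer,
                                        exclude={a, b}))

    by_e = [n_pairs(100_000, e) for e in (1e-30, 1e-20, 1e-10, 1e-5)]
    assert by_e == sorted(by_e)
    by_r = [n_pairs(r, 1e-10) for r in (20_000, 50_000, 100_000, 200_000)]
    assert by_r == sorted(by_r)


def test_interspecies_recovers_ortholog_anchors(scorer, small_sim):
    genomes, truth = small_sim
    ga, gb = genomes[0], genomes[1]
    members_a = sorted(truth.family_genes[ga.species])
    members_b = sorted(truth.family_genes[gb.species])
    blocks = interspecies_synteny(ga, gb, members_a, members_b, scorer=scorer)
    found = {(b.anchor_a, b.anchor_b) for b in blocks}
    orth = [
        (x, y) for x, y in truth.orthologs
        if x in set(members_a) and y in set(members_b)
    ]
    recall = sum((x, y) in found for x, y in orth) / len(orth)
    assert recall >= 0.9
    assert all(b.scope == "inter" for b in blocks)


def test_shuffled_relative_shows_no_synteny(scorer, one_species_sim):
    genomes, truth = one_species_sim
    genome = genomes[0]
    other = shuffle_genome_order(genome, seed=5)
    other.species = "shuffled"
    members = sorted(truth.family_genes[genome.species])[:4]
    blocks = interspecies_synteny(genome, other, members, members, scorer=scorer)
    # only the anchor's own (identical) locus could ever match, and its
    # flanks are scrambled, so essentially nothing is reported
    assert len(blocks) <= 1
    assert non_syntenic_members(members, []) == members
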