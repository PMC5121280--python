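# Methods

This note documents the models and procedures implemented in `famsynt`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical decisions that affect
results. Nothing here reports an empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and gene models

All coordinates are GFF3-native: 1-based, inclusive, forward-strand.
Half-open intervals are never exposed; the GFF3 reader/writer are the
only places offsets change. One transcript is kept per gene — the one
with the longest summed CDS — because every downstream stage works with
one protein per gene. A trailing stop codon is trimmed from the CDS
before the translation check; genes whose CDS length is not a multiple
of three are flagged and excluded from codon-level analyses rather than
silently dropped.

## Domain identification (PSSM scan)

Family membership is a structural rule: at least one QLQ hit **and** one
WRC hit. The scanner is a position-specific scoring matrix over fully
ungapped seed-alignment columns: column probabilities with an additive
pseudocount (default 0.5), log-odds in bits against a uniform 1/20
background. With pseudocount 0, unseen residues are floored at −100 bits
to stay finite. The packaged seed alignments under `famsynt/data/` are
**synthetic**: ten noisy copies of hand-written consensus sequences that
echo the residue character of the QLQ and WRC domains (Q/L-rich;
W-R-C with CCCH-like cysteine spacing). They are fixtures for a
self-contained pipeline, not database profiles.

* Reporting threshold: 60% of the maximum attainable bit score,
  configurable. The threshold and the generator's domain conservation
  level (below) are jointly calibrated: the domain core is treated as
  nearly invariant, which is what makes a fixed fractional threshold
  meaningful.
* E-values: a Gumbel right tail fitted once at build time on 10,000
  random windows drawn from the seed residue composition (fixed internal
  seed 77 so that building a PSSM twice gives identical objects),
  multiplied by the number of windows scanned.
* Overlapping hits are resolved greedily by score, ties to the leftmost,
  so two WRC copies in one protein are counted (membership requires only
  one).

## Phylogeny

The MSA is a self-contained progressive aligner: 3-mer-count distances,
average-linkage guide tree, profile–profile Needleman–Wunsch with
BLOSUM62, affine gaps (open 10, extend 0.5), no gap-to-gap state. The
alignment is a means to distances and codon threading; on deeply
diverged toy sequences it shows ordinary progressive-alignment
greediness, which does not matter at the within-family identities it is
used for.

Distances are protein p-distances under pairwise deletion (sites gapped
in either member of a pair are skipped for that pair) with Poisson
correction d = −ln(1−p). A pair with p ≥ 1 or no comparable sites is
flagged undefined — an error in strict mode; inside the bootstrap it is
replaced by twice the largest finite distance of that replicate so a
replicate can never abort a run.

Neighbor joining follows Saitou–Nei with the Studier–Keppler Q
criterion; negative branch lengths are clamped to zero; Q ties are
broken by the lexicographically smallest taxon-label pair, making the
topology deterministic. On additive matrices NJ is exact; the test suite
verifies this against an exhaustive least-squares topology search for up
to six taxa.

Bootstrap support is the count of column-resampled replicates (default
1000) whose NJ tree contains each original internal bipartition.
Subfamilies are obtained by deleting the k−1 longest internal branches
with support ≥ `min_support` (default 500 of 1000) and labelling the
resulting leaf groups I, II, … by decreasing size (ties by smallest
member label). k defaults to 5; both k and the support floor are
parameters because clade structure at this granularity is a judgement
call on real data.

## Microsynteny and duplication classification

Each family member anchors a flank window of ±100 kb around its span
(genes partially overlapping the boundary are included; windows clip at
chromosome ends). Conserved flanking pairs between two windows are
reciprocal best hits under local alignment — Smith–Waterman, BLOSUM62,
gap open 11 / extend 1 (Biopython's PairwiseAligner) — passing a
Karlin–Altschul E-value cutoff, E = K·m·n·e^(−λS) with gapped-default
constants λ = 0.267, K = 0.041, query length m and database size n taken
as the larger of the two flank sets so the result is symmetric in the
anchor order. One-directional best hits are available
(`reciprocal=False`), but reciprocity is the default because it enforces
one-to-one pairing. Both anchors are excluded from their own flank sets
so the anchor pair never counts as its own evidence.

Classification rules, in precedence order: **tandem** if both anchors sit
on one chromosome with at most `max_intervening` (default 1) genes
between them — tandem wins even in synteny-rich regions; **large_scale**
if ≥ `min_pairs` (default 4) conserved flanking pairs; **relaxed** for
2–3 pairs; otherwise **none**. Inter-species comparisons use the same
flank/match rules over all member×member anchor pairs and report blocks
with ≥ 2 conserved pairs.

The conserved-pair count is monotone in the E-value cutoff by
construction. Under reciprocal best hits it is not formally monotone in
the window radius (removing a competitor can create a new best hit), but
on data of this kind alternative near-best partners at E ≤ 10⁻¹⁰ do not
occur, and the tests check monotonicity empirically on planted blocks.

## Ka/Ks (NG86)

Codon alignments are threaded from protein alignments (each protein gap
becomes a codon gap; trailing stops dropped; the ungapped output must
recover the CDS exactly — a mismatch is an error naming the first
discordant residue).

Site counting: every one of the nine single-nucleotide neighbours of a
codon contributes 1/3 of a site; neighbours that are stop codons count
as nonsynonymous, so S + N = 3 per sense codon exactly. Difference
counting averages over all minimal mutational pathways between two
codons; pathways through a stop codon are excluded and the remaining
weights renormalised (if every ordering is blocked, all are used).
Gap-containing codon columns are excluded from both site and difference
counts. Proportions pS = Sd/S and pN = Nd/N are corrected with
Jukes–Cantor, d = −(3/4)·ln(1 − (4/3)p); p ≥ 3/4 flags the rate
undefined, and a ratio is only reported when Ks is defined and positive.
Ka/Ks below/equal/above 1 is labelled purifying/neutral/positive with no
significance test attached.

The sliding window (default 150 bp window, 9 bp step, both multiples of
three) evaluates NG86 on the codons fully contained in each window;
windows never extend past the alignment end, giving
floor((L−window)/step)+1 windows. Undefined windows carry a flag, never
a fabricated ratio. Window starts are reported in 1-based alignment bp.

## Functional divergence

**Type I.** Per-column minimum substitution counts are computed for each
cluster by Fitch parsimony (sequential set-fold, gaps treated as
missing) on the cluster's own NJ subtree; columns that are
majority-gap across the cluster pair are excluded. The counts (x₁, x₂)
feed a two-state mixture: with probability θ the site's rate is
independent between clusters (F1), otherwise shared (F0); rates are
Gamma(α, mean 1) and counts Poisson with cluster tree-length scalars T₁,
T₂. Marginalising the rate gives closed-form negative-binomial
likelihoods, so the log-likelihood is exact. θ, α, T₁, T₂ are estimated
by L-BFGS-B on transformed parameters with five θ starts
(0.05…0.85, ftol 1e-10); the null (θ=0) refit gives the LRT, referred to
χ²(1) — conservative at the θ=0 boundary, which is intentional for the
calibration check. SE(θ) comes from the observed information
(central-difference Hessian); Q_k is the per-site posterior of F1.
Clusters need ≥ 4 sequences and ≥ 50 usable sites.

**Type II.** A moments estimator over a four-class amino-acid property
partition (nonpolar AVLIMFWPG, polar STNQYC, acidic DE, basic KRH;
crossing classes = radical). A site shows a fixed difference when each
cluster's consensus reaches 75% within the cluster and the consensuses
differ. With R the radical-fixed rate, D the fixed rate and π the
radical fraction among within-cluster changes (lightly smoothed toward
the random-pair rate), θ_II = (R − Dπ)/(1 − π) — negative values are
reported as-is (they mean fewer radical fixed differences than neutral
turnover predicts). SE is by the delta method over the binomial variances
of R, D and π, with the R⊆D covariance included. Q_k is the posterior of
the type-II state given a radical fixed difference; because the model
gives all radical-fixed sites identical likelihoods this posterior is
shared across them, so the Q_k > 0.9 rule is all-or-nothing per dataset —
a known limitation of moments-style type-II estimators, and why the
planted-site recall test averages over seeds.

Site numbering in all divergence reports is 1-based alignment-column
numbering; the `columns` field of each result maps kept sites back to
alignment columns.

## The synthetic-genome generator

`simulate()` builds an ancestral genome (default 4 chromosomes × 60
genes, mean intergenic spacing 10 kb, 1–6 exons per gene, background
CDS 80–200 codons), plants `n_family_genes` (default 10) family loci on
a jittered grid that keeps them ≥ 12 gene slots apart (so no 100 kb
window contains two independent family loci), and evolves everything
down a species tree (default: a three-species caterpillar with ~0.06
substitutions/codon branches) under a Goldman–Yang-style codon model —
uniform codon frequencies, transition/transversion ratio κ (default 2),
dN/dS ω = 0.2 outside the domains and 0.02 inside the QLQ/WRC cores.
The near-invariant domain core reflects real zinc-finger conservation
and is what makes domain recall at the 60% PSSM threshold a property of
the method rather than of luck. Branch lengths are expected
substitutions per codon site; substitutions into stop codons are
rejected (the state space is the 61 sense codons).

Family structure: one family root protein (domains planted from the
packaged consensus with 10% per-column noise) radiates into five
subfamily ancestors (0.5 subs/codon each — a star radiation, so each
subfamily is a well-supported clade and the four longest supported
internal branches separate exactly the planted groups), then into member
loci (0.12) and species (species-tree branches). A fraction `theta_sim`
(default 0.25) of non-domain sites get cluster-independent rate
multipliers on the subfamily branches (drawn from {0.25, 4}) — the
type-I divergence truth; domain sites are excluded so the family stays
identifiable.

Duplications are planted after speciation, assigned to species
round-robin: a tandem event inserts a copy adjacent to its source; a
segmental event copies a block of `segment_size_genes` (default 8)
consecutive genes around an anchor to another chromosome, each
non-anchor gene retained with probability 0.9, order and strand
preserved. Copies diverge by 0.05 subs/codon. Anchors are drawn from the
original family loci only, so planted events never nest. Insertion sites
keep ≥ 12 slots of clearance from existing family loci, relaxed stepwise
(floor 4, with a warning) when a dense genome leaves no fully clear
position. With Binomial(7, 0.9) flanker retention, about 2–3% of
segmental blocks keep ≤ 4 flankers and can legitimately fall to the
relaxed class — the classification benchmark is therefore a ≥ 95%
per-class accuracy over 20 seeds, not exactness.

What the generator does **not** emulate: indels within coding sequence
(pairs are alignment-free apart from planted structure), UTRs and
alternative splicing, codon-usage bias, rearrangements other than the
planted block copies, gene loss outside duplicated blocks, and
recombination. Passing tests therefore demonstrate method correctness
under the stated model, not robustness to annotation noise or assembly
artefacts in real genomes.

All randomness in one `simulate()` call flows from a single
`numpy` PCG64 generator seeded from the config, so equal seeds give
byte-identical FASTA/GFF3/TSV outputs.

## Pipeline and problem sizes

`famsynt run` executes the stages in dependency order and writes every
table plus a manifest (parameters, input hashes, output list — no
timestamps) under `<outdir>/report`; wall-clock logging goes to
`<outdir>/run.log` beside the report so that two runs with one seed
produce byte-identical report trees. Stage seeds are derived
deterministically from the config seed.

The shipped benchmarks run at deliberately moderate sizes chosen to give
stable statistics: 20 single-species simulations for family-calling and
duplication-classification recovery, 10 two-species simulations
(≈ 20 taxa, 1000 bootstrap replicates) for subfamily recovery, 200
replicate 300-codon pairs for ω recovery, 500 sites × 20 replicates for
θ_I calibration and recovery, and 50 random additive matrices (n ≤ 6)
against the exhaustive least-squares oracle. The ω-recovery check runs
the generator at κ = 1, the estimator-matched condition: NG86 counts
sites without transition bias, so "mean estimate = ω" is only the
correct expectation there; at the genome default κ = 2, NG86 is known to
be biased and the pipeline reports what it reports.

## Known limitations

* The progressive aligner has no iterative refinement; badly chosen
  guide-tree merges are never revisited.
* NG86 is the classic counting estimator: no transition/transversion or
  codon-frequency correction, no variance on Ka/Ks.
* The type-I LRT uses χ²(1) despite the boundary null, so it is
  conservative (rejection rate below nominal at θ = 0).
* The type-II Q_k is shared across radical-fixed sites (see above).
* Subfamily assignment assumes the true groups are separated by the
  longest well-supported branches; rate heterogeneity that stretches
  within-clade branches could defeat the cut rule.
* Karlin–Altschul constants are fixed gapped defaults, not fitted to the
  scoring system; E-values are comparative devices here, not calibrated
  significance statements.
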