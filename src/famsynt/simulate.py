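"""Synthetic genomes with a planted gene-family history.

The simulator emulates the data regime of a multi-species gene-family
survey: several chromosomes of protein-coding genes, a domain-defined
family (each member carrying one QLQ and one WRC domain instance) split
into subfamilies with deep divergence, planted tandem and segmental
duplications with conserved flanking genes, coding sequences evolved under
a Goldman–Yang-style codon model with region-specific dN/dS, and per-site
rate classes (F0 shared / F1 cluster-independent) planted on the family
alignment as type-I functional-divergence ground truth.

Every quantity that downstream stages estimate — family membership,
subfamily partition, duplication mode, pairwise omega, theta — is recorded
in a :class:`SimulationTruth` so recovery can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import yaml
from scipy.linalg import expm

from ._codon import CODON_TO_AA, SENSE_CODONS, SENSE_INDEX, gy_rate_matrix, translate_cds
from .genome_io import GeneModel, Genome, write_fasta, write_gff3, write_tsv

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate",
    "evolve_cds",
    "plant_rate_shift",
    "simulate_divergence_counts",
    "write_simulation",
    "shuffle_genome_order",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# synthetic consensus sequences for the two defining domains; these echo the
# residue character of the real QLQ (Gln-Leu-Gln protein-interaction) and WRC
# (Trp-Arg-Cys zinc-finger, CCCH spacing) domains without copying any
# database profile.
QLQ_CONSENSUS = "QQQLQLQELYPQQAVRFSPEQLQALRAQILAFQLLQRGQP"
WRC_CONSENSUS = "GRCRRTDGKKWRCSRDVVPGQKYCERHMHRGRNRSRKPVE"


@dataclass
class SimulationConfig:
    """Knobs of the planted-history generator.

    Branch lengths are expected substitutions per codon site. ``theta_sim``
    is the fraction of non-domain family-alignment sites given
    cluster-independent rates (type-I divergence truth).
    """

    n_species: int = 3
    species_tree: str = ""  # newick over species names; default caterpillar
    n_chroms: int = 4
    genes_per_chrom: int = 60
    n_family_genes: int = 10
    n_subfamilies: int = 5
    n_tandem_events: int = 2
    n_segmental_events: int = 2
    segment_size_genes: int = 8
    omega: float = 0.2          # dN/dS outside the domains
    omega_domain: float = 0.02  # dN/dS inside QLQ/WRC (near-invariant zinc-finger core)
    kappa: float = 2.0
    theta_sim: float = 0.25
    intergenic_bp: int = 10000
    retention_prob: float = 0.9
    min_family_gap_genes: int = 12
    family_len_codons: int = 300
    background_len_codons: tuple[int, int] = (80, 200)
    species_branch: float = 0.06
    subfamily_branch: float = 0.5
    within_branch: float = 0.12
    dup_branch: float = 0.05
    domain_noise: float = 0.1   # per-column substitution prob when planting
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_species, self.n_chroms, self.genes_per_chrom) < 1:
            raise ValueError("counts must be positive")
        if min(self.n_family_genes, self.n_tandem_events, self.n_segmental_events) < 0:
            raise ValueError("counts must be >= 0")
        if not 0.0 <= self.theta_sim <= 1.0:
            raise ValueError("theta_sim must be in [0, 1]")
        if self.omega < 0 or self.omega_domain < 0:
            raise ValueError("omega must be >= 0")
        if self.segment_size_genes < 5:
            raise ValueError("segment_size_genes must be >= 5")
        if self.segment_size_genes > self.genes_per_chrom:
            raise ValueError("segment_size_genes exceeds genes_per_chrom")

    @property
    def species_names(self) -> list[str]:
        return [f"sp{chr(65 + i)}" for i in range(self.n_species)]

    def resolved_tree(self) -> str:
        if self.species_tree:
            return self.species_tree
        names = self.species_names
        t = self.species_branch
        if len(names) == 1:
            return f"({names[0]}:{t});"
        nwk = f"{names[0]}:{t},{names[1]}:{t}"
        for name in names[2:]:
            nwk = f"({nwk}):{t / 2},{name}:{1.5 * t}"
        return f"({nwk});"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "background_len_codons" in data:
            data["background_len_codons"] = tuple(data["background_len_codons"])
        return cls(**data)


@dataclass
class SimulationTruth:
    """Ground truth for every planted feature of a simulated dataset."""

    duplications: list[tuple[str, str, str, str]] = field(default_factory=list)
    # (gene_a, gene_b, type in {tandem, segmental}, species)
    orthologs: list[tuple[str, str]] = field(default_factory=list)
    subfamily: dict[str, str] = field(default_factory=dict)  # gene -> SF label
    family_genes: dict[str, set[str]] = field(default_factory=dict)  # species -> ids
    site_classes: list[str] = field(default_factory=list)  # per root protein site
    exon_counts: dict[str, int] = field(default_factory=dict)
    true_omega: float = 0.2

    def all_gene_ids(self) -> set[str]:
        ids = set(self.exon_counts)
        return ids


# ---------------------------------------------------------------------------
# codon evolution

_P_CACHE: dict[tuple[float, float, float], np.ndarray] = {}


def _pmatrix(t: float, omega: float, kappa: float) -> np.ndarray:
    key = (round(float(t), 12), round(float(omega), 12), round(float(kappa), 12))
    P = _P_CACHE.get(key)
    if P is None:
        P = expm(gy_rate_matrix(omega, kappa) * t) if t > 0 else np.eye(len(SENSE_CODONS))
        np.maximum(P, 0.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        _P_CACHE[key] = P
    return P


def _encode(cds: str) -> np.ndarray:
    try:
        return np.fromiter(
            (SENSE_INDEX[cds[i : i + 3]] for i in range(0, len(cds), 3)),
            dtype=np.int64,
            count=len(cds) // 3,
        )
    except KeyError as exc:
        raise ValueError(f"internal stop or invalid codon in CDS: {exc}") from None


def _decode(idx: np.ndarray) -> str:
    return "".join(SENSE_CODONS[i] for i in idx)


def _evolve_indices(
    idx: np.ndarray, t: np.ndarray | float, omega: np.ndarray | float, kappa: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve codon indices; t and omega may be scalars or per-codon arrays."""
    n = len(idx)
    t = np.broadcast_to(np.asarray(t, dtype=float), (n,))
    omega = np.broadcast_to(np.asarray(omega, dtype=float), (n,))
    out = idx.copy()
    for key in sorted(set(zip(t.tolist(), omega.tolist()))):
        tv, ov = key
        mask = (t == tv) & (omega == ov)
        if tv <= 0:
            continue
        P = _pmatrix(tv, ov, kappa)
        cum = np.cumsum(P[out[mask]], axis=1)
        u = rng.random(int(mask.sum()))
        out[mask] = (cum < u[:, None]).sum(axis=1)
    return out


def evolve_cds(
    cds: str,
    t: float,
    omega: float | np.ndarray = 0.2,
    kappa: float = 2.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """Evolve a coding sequence along a branch of length ``t``.

    A continuous-time Markov codon process (rate proportional to kappa for
    transitions, times omega for nonsynonymous changes, uniform codon
    frequencies) restricted to sense codons, so substitutions into stop
    codons never occur. ``t`` is in expected substitutions per codon;
    ``omega`` may be per-codon. ``t=0`` returns the input unchanged.
    """
    if t < 0:
        raise ValueError("branch length must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = _encode(cds)
    return _decode(_evolve_indices(idx, t, omega, kappa, rng))


def _random_cds(n_codons: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, len(SENSE_CODONS), size=n_codons)


_AA_TO_CODONS: dict[str, list[int]] = {}
for _c, _aa in CODON_TO_AA.items():
    if _c in SENSE_INDEX:
        _AA_TO_CODONS.setdefault(_aa, []).append(SENSE_INDEX[_c])


def _backtranslate_protein(protein: str, rng: np.random.Generator) -> np.ndarray:
    return np.array([rng.choice(_AA_TO_CODONS[aa]) for aa in protein], dtype=np.int64)


# ---------------------------------------------------------------------------
# rate-shift planting (type-I divergence truth)


def plant_rate_shift(
    alignment: dict[str, str],
    cluster_a: list[str],
    cluster_b: list[str],
    theta_sim: float,
    seed: int = 0,
    t_scale: float = 1.0,
) -> tuple[dict[str, str], list[str]]:
    """Overlay cluster-specific site rates on a protein alignment.

    A fraction ``theta_sim`` of columns is drawn as F1 (independent
    exponential rates per cluster); the rest are F0 (one shared rate). Each
    sequence's residue at a column mutates to a random amino acid with
    probability 1 - exp(-rate * t_scale). Returns the perturbed alignment
    and per-column labels.
    """
    if not 0.0 <= theta_sim <= 1.0:
        raise ValueError("theta_sim must be in [0, 1]")
    overlap = set(cluster_a) & set(cluster_b)
    if overlap:
        raise ValueError(f"clusters overlap: {sorted(overlap)}")
    rng = np.random.default_rng(seed)
    ids = list(alignment)
    L = len(next(iter(alignment.values())))
    labels = ["F1" if rng.random() < theta_sim else "F0" for _ in range(L)]
    rows = {i: list(alignment[i]) for i in ids}
    for col, lab in enumerate(labels):
        if lab == "F0":
            r_a = r_b = rng.exponential(1.0)
        else:
            r_a, r_b = rng.exponential(1.0), rng.exponential(1.0)
        for cluster, rate in ((cluster_a, r_a), (cluster_b, r_b)):
            p = 1.0 - np.exp(-rate * t_scale)
            for name in cluster:
                if rows[name][col] != "-" and rng.random() < p:
                    rows[name][col] = AA20[rng.integers(len(AA20))]
    return {i: "".join(rows[i]) for i in ids}, labels


def simulate_divergence_counts(
    theta: float,
    n_sites: int,
    alpha: float = 1.0,
    t1: float = 2.0,
    t2: float = 2.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site substitution counts under the two-state rate model.

    Site rates are Gamma(alpha, mean 1); F0 sites (probability 1 - theta)
    share one rate across the two clusters, F1 sites draw independent
    rates. Counts are Poisson with mean rate*t. Returns (x1, x2, is_f1).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    is_f1 = rng.random(n_sites) < theta
    lam1 = rng.gamma(alpha, 1.0 / alpha, size=n_sites)
    lam_indep = rng.gamma(alpha, 1.0 / alpha, size=n_sites)
    lam2 = np.where(is_f1, lam_indep, lam1)
    x1 = rng.poisson(lam1 * t1)
    x2 = rng.poisson(lam2 * t2)
    return x1, x2, is_f1


def simulate_cluster_alignment(
    n_a: int = 6,
    n_b: int = 6,
    n_sites: int = 400,
    radical_frac: float = 0.10,
    neutral_fixed_frac: float = 0.005,
    noise: float = 0.03,
    seed: int = 0,
) -> tuple[dict[str, str], list[int]]:
    """Two-cluster protein alignment with planted radical fixed differences.

    ``radical_frac`` of sites get a between-cluster fixed difference that
    crosses amino-acid property classes (type-II divergence truth);
    ``neutral_fixed_frac`` get a fixed difference to a random other residue
    (neutral turnover); every residue is independently perturbed with
    probability ``noise``. Returns the alignment and the 1-based planted
    site list.
    """
    from .divergence import PROPERTY_CLASS

    rng = np.random.default_rng(seed)
    by_class: dict[str, list[str]] = {}
    for aa, cl in PROPERTY_CLASS.items():
        by_class.setdefault(cl, []).append(aa)
    classes = sorted(by_class)
    anc = [AA20[i] for i in rng.integers(0, len(AA20), size=n_sites)]
    alt = list(anc)
    n_rad = int(round(radical_frac * n_sites))
    n_cons = int(round(neutral_fixed_frac * n_sites))
    sites = rng.choice(n_sites, size=n_rad + n_cons, replace=False)
    radical_sites = sorted(int(s) + 1 for s in sites[:n_rad])
    for s in sites[:n_rad]:
        cl = PROPERTY_CLASS[anc[s]]
        other = classes[(classes.index(cl) + 1 + rng.integers(len(classes) - 1)) % len(classes)]
        if other == cl:
            other = classes[(classes.index(cl) + 1) % len(classes)]
        alt[s] = by_class[other][rng.integers(len(by_class[other]))]
    for s in sites[n_rad:]:
        pool = [a for a in AA20 if a != anc[s]]
        alt[s] = pool[rng.integers(len(pool))]
    aln = {}
    for name, base, n in (("a", anc, n_a), ("b", alt, n_b)):
        for i in range(n):
            row = [
                AA20[rng.integers(len(AA20))] if rng.random() < noise else c
                for c in base
            ]
            aln[f"{name}{i}"] = "".join(row)
    return aln, radical_sites


# ---------------------------------------------------------------------------
# the generator proper


@dataclass
class _GeneTemplate:
    anc_id: str
    strand: str
    exon_cds_lens: list[int]  # bp of CDS per exon, genomic order
    intron_lens: list[int]
    is_family: bool = False
    subfamily: str = ""


def _make_structure(cds_bp: int, n_exons: int, rng: np.random.Generator) -> tuple[list[int], list[int]]:
    if n_exons == 1:
        return [cds_bp], []
    cuts = np.sort(rng.choice(np.arange(1, cds_bp // 3), size=n_exons - 1, replace=False)) * 3
    bounds = [0, *cuts.tolist(), cds_bp]
    exon_lens = [bounds[i + 1] - bounds[i] for i in range(n_exons)]
    introns = rng.integers(100, 500, size=n_exons - 1).tolist()
    return exon_lens, introns


def _choose_family_slots(cfg: SimulationConfig, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Family gene positions: jittered grid spaced >= min_family_gap_genes.

    The grid construction guarantees a feasible placement whenever the
    chromosome capacity allows one; which grid slots are used is random.
    """
    margin = max(cfg.segment_size_genes + 2, 8)
    gap = cfg.min_family_gap_genes
    lo, hi = margin, cfg.genes_per_chrom - margin
    if hi <= lo:
        raise ValueError("genes_per_chrom too small for family placement margins")
    candidates: list[tuple[int, int]] = []
    for c in range(cfg.n_chroms):
        pos = lo + int(rng.integers(0, max(gap // 4, 1)))
        while pos < hi:
            candidates.append((c, pos))
            pos += gap + int(rng.integers(0, max(gap // 4, 1)))
    if len(candidates) < cfg.n_family_genes:
        raise ValueError(
            "could not place family genes with the required separation; "
            "increase genes_per_chrom/n_chroms or lower n_family_genes"
        )
    idx = rng.permutation(len(candidates))[: cfg.n_family_genes]
    return sorted(candidates[i] for i in idx)


def _plant_domains(cfg: SimulationConfig, protein: list[str], rng: np.random.Generator) -> tuple[list[str], list[tuple[int, int]]]:
    """Insert noisy QLQ and WRC consensus copies; returns protein and spans."""
    spans = []
    qlq_start, wrc_start = 10, 10 + len(QLQ_CONSENSUS) + 15
    for start, consensus in ((qlq_start, QLQ_CONSENSUS), (wrc_start, WRC_CONSENSUS)):
        for i, aa in enumerate(consensus):
            if rng.random() < cfg.domain_noise:
                aa = AA20[rng.integers(len(AA20))]
            protein[start + i] = aa
        spans.append((start, start + len(consensus)))
    return protein, spans


def simulate(cfg: SimulationConfig) -> tuple[list[Genome], SimulationTruth]:
    """Generate per-species genomes plus ground truth (deterministic in seed)."""
    rng = np.random.default_rng(cfg.seed)
    truth = SimulationTruth(true_omega=cfg.omega)

    # --- ancestral gene content -------------------------------------------
    family_slots = _choose_family_slots(cfg, rng) if cfg.n_family_genes else []
    family_slotset = set(family_slots)
    subfam_labels = [f"SF{1 + i % cfg.n_subfamilies}" for i in range(cfg.n_family_genes)]
    rng.shuffle(subfam_labels)

    # family root CDS with planted domains
    n_fam = cfg.family_len_codons
    root_protein = [AA20[i] for i in rng.integers(0, len(AA20), size=n_fam)]
    root_protein, domain_spans = _plant_domains(cfg, root_protein, rng)
    root_idx = _backtranslate_protein("".join(root_protein), rng)
    omega_per_codon = np.full(n_fam, cfg.omega)
    domain_mask = np.zeros(n_fam, dtype=bool)
    for s, e in domain_spans:
        omega_per_codon[s:e] = cfg.omega_domain
        domain_mask[s:e] = True

    # per-site rate classes (type-I divergence truth), outside domains only
    is_f1 = (rng.random(n_fam) < cfg.theta_sim) & ~domain_mask
    truth.site_classes = ["F1" if f else "F0" for f in is_f1]

    # subfamily ancestors: deep radiation with per-site rate multipliers
    subfam_cds: dict[str, np.ndarray] = {}
    for s in range(cfg.n_subfamilies):
        rates = np.ones(n_fam)
        rates[is_f1] = rng.choice([0.25, 4.0], size=int(is_f1.sum()))
        t_site = cfg.subfamily_branch * rates
        subfam_cds[f"SF{s + 1}"] = _evolve_indices(
            root_idx, t_site, omega_per_codon, cfg.kappa, rng
        )

    # ancestral genome templates and CDS
    templates: dict[int, list[_GeneTemplate]] = {c: [] for c in range(cfg.n_chroms)}
    anc_cds: dict[str, np.ndarray] = {}
    counter = 0
    fam_i = 0
    lo, hi = cfg.background_len_codons
    for c in range(cfg.n_chroms):
        for s in range(cfg.genes_per_chrom):
            counter += 1
            anc_id = f"g{counter:04d}"
            is_family = (c, s) in family_slotset
            if is_family:
                sf = subfam_labels[fam_i]
                fam_i += 1
                idx = _evolve_indices(
                    subfam_cds[sf], cfg.within_branch, omega_per_codon, cfg.kappa, rng
                )
                n_codons = n_fam
            else:
                sf = ""
                n_codons = int(rng.integers(lo, hi + 1))
                idx = _random_cds(n_codons, rng)
            n_exons = int(rng.integers(1, 7))
            exon_lens, introns = _make_structure(n_codons * 3, n_exons, rng)
            templates[c].append(
                _GeneTemplate(anc_id, "+-"[rng.integers(2)], exon_lens, introns,
                              is_family, sf)
            )
            anc_cds[anc_id] = idx

    # --- evolve along the species tree ------------------------------------
    tree = dendropy.Tree.get(data=cfg.resolved_tree(), schema="newick")
    leaf_cds: dict[str, dict[str, np.ndarray]] = {}

    def walk(node, cds_state: dict[str, np.ndarray]):
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            new_state = {}
            for anc_id, idx in cds_state.items():
                om = omega_per_codon if len(idx) == n_fam and _is_family_anc[anc_id] else cfg.omega
                new_state[anc_id] = _evolve_indices(idx, t, om, cfg.kappa, rng)
            if child.is_leaf():
                leaf_cds[child.taxon.label.replace(" ", "")] = new_state
            else:
                walk(child, new_state)

    _is_family_anc = {
        tpl.anc_id: tpl.is_family for chrom in templates.values() for tpl in chrom
    }
    walk(tree.seed_node, anc_cds)
    species_order = cfg.species_names
    missing = [s for s in species_order if s not in leaf_cds]
    if missing:
        raise ValueError(f"species tree lacks leaves for {missing}")

    # --- per-species gene lists, planted duplications ----------------------
    genomes: list[Genome] = []
    events: list[tuple[str, str]] = [
        *(("tandem", "") for _ in range(cfg.n_tandem_events)),
        *(("segmental", "") for _ in range(cfg.n_segmental_events)),
    ]
    per_species_events: dict[str, list[str]] = {s: [] for s in species_order}
    for i, (etype, _) in enumerate(events):
        per_species_events[species_order[i % len(species_order)]].append(etype)

    for sp in species_order:
        cds_state = leaf_cds[sp]
        # chromosome slot lists: (gene_id, template, cds_indices)
        chrom_slots: dict[int, list[tuple[str, _GeneTemplate, np.ndarray]]] = {}
        fam_positions: list[tuple[int, int]] = []
        for c in range(cfg.n_chroms):
            row = []
            for tpl in templates[c]:
                gid = f"{sp}_{tpl.anc_id}"
                row.append((gid, tpl, cds_state[tpl.anc_id]))
                if tpl.is_family:
                    fam_positions.append((c, len(row) - 1))
                    truth.subfamily[gid] = tpl.subfamily
            chrom_slots[c] = row

        original_family = {chrom_slots[c][i][0] for c, i in fam_positions}
        used_anchors: set[str] = set()
        dup_counter = 0
        for etype in per_species_events[sp]:
            # anchors are drawn from the original family loci only, so planted
            # events never nest (no copies of copies)
            candidates = [
                (c, i) for c, i in fam_positions
                if chrom_slots[c][i][0] in original_family
                and chrom_slots[c][i][0] not in used_anchors
            ]
            if not candidates:
                raise ValueError("not enough family genes for the requested events")
            c, i = candidates[int(rng.integers(len(candidates)))]
            src_id, src_tpl, src_idx = chrom_slots[c][i]
            used_anchors.add(src_id)
            dup_counter += 1
            if etype == "tandem":
                new_id = f"{src_id}d{dup_counter}"
                new_idx = _evolve_indices(
                    src_idx, cfg.dup_branch, omega_per_codon, cfg.kappa, rng
                )
                chrom_slots[c].insert(i + 1, (new_id, src_tpl, new_idx))
                truth.subfamily[new_id] = src_tpl.subfamily
                truth.duplications.append((src_id, new_id, "tandem", sp))
                fam_positions = [
                    (cc, ii if cc != c or ii <= i else ii + 1) for cc, ii in fam_positions
                ]
                fam_positions.append((c, i + 1))
            else:  # segmental block copy
                half = cfg.segment_size_genes // 2
                lo_i = max(0, i - half)
                hi_i = min(len(chrom_slots[c]), lo_i + cfg.segment_size_genes)
                block = chrom_slots[c][lo_i:hi_i]
                copied = []
                for gid, tpl, idx in block:
                    if gid != src_id and rng.random() > cfg.retention_prob:
                        continue  # flanking gene lost after duplication
                    om = omega_per_codon if tpl.is_family else cfg.omega
                    new_idx = _evolve_indices(idx, cfg.dup_branch, om, cfg.kappa, rng)
                    copied.append((f"{gid}d{dup_counter}", tpl, new_idx))
                # insertion site on another chromosome, clear of family loci;
                # clearance is relaxed stepwise (never below 4 intervening
                # slots) when the genome is too dense for the full gap
                feasible: list[tuple[int, int]] = []
                for gap_try in range(cfg.min_family_gap_genes, 3, -1):
                    feasible = [
                        (tc, pos)
                        for tc in range(cfg.n_chroms)
                        if not (tc == c and cfg.n_chroms > 1)
                        for pos in range(2, len(chrom_slots[tc]) - 2)
                        if all(
                            cc != tc or abs(ii - pos) >= gap_try
                            for cc, ii in fam_positions
                        )
                    ]
                    if feasible:
                        if gap_try < cfg.min_family_gap_genes:
                            warnings.warn(
                                f"segmental insertion clearance relaxed to {gap_try} slots"
                            )
                        break
                if not feasible:
                    raise ValueError("could not place segmental copy away from family loci")
                tc, pos = feasible[int(rng.integers(len(feasible)))]
                chrom_slots[tc][pos:pos] = copied
                fam_positions = [
                    (cc, ii if cc != tc or ii < pos else ii + len(copied))
                    for cc, ii in fam_positions
                ]
                copy_anchor = f"{src_id}d{dup_counter}"
                truth.subfamily[copy_anchor] = src_tpl.subfamily
                truth.duplications.append((src_id, copy_anchor, "segmental", sp))
                fam_positions.append((tc, pos + [g for g, _, _ in copied].index(copy_anchor)))

        # --- lay out coordinates and build the Genome ----------------------
        genome = Genome(sp)
        fam_out: set[str] = set()
        for c in range(cfg.n_chroms):
            chrom_name = f"{sp}_chr{c + 1}"
            pos = 1 + int(rng.integers(cfg.intergenic_bp // 2, cfg.intergenic_bp))
            for gid, tpl, idx in chrom_slots[c]:
                cds = _decode(idx)
                exons = []
                cur = pos
                for k, ex_len in enumerate(tpl.exon_cds_lens):
                    exons.append((cur, cur + ex_len - 1))
                    cur += ex_len
                    if k < len(tpl.intron_lens):
                        cur += tpl.intron_lens[k]
                end = exons[-1][1]
                genome.add_gene(
                    GeneModel(
                        gene_id=gid, chrom=chrom_name, start=pos, end=end,
                        strand=tpl.strand, exons=exons, cds_seq=cds,
                        protein_seq=translate_cds(cds),
                    )
                )
                truth.exon_counts[gid] = len(exons)
                if tpl.is_family:
                    fam_out.add(gid)
                gap = int(rng.integers(cfg.intergenic_bp // 2, (3 * cfg.intergenic_bp) // 2))
                pos = end + 1 + gap
        truth.family_genes[sp] = fam_out
        genomes.append(genome)

    # ortholog pairs (family genes sharing an ancestral slot)
    for tpl_row in templates.values():
        for tpl in tpl_row:
            if not tpl.is_family:
                continue
            for i, a in enumerate(species_order):
                for b in species_order[i + 1 :]:
                    truth.orthologs.append((f"{a}_{tpl.anc_id}", f"{b}_{tpl.anc_id}"))
    return genomes, truth


def shuffle_genome_order(genome: Genome, seed: int = 0) -> Genome:
    """Return a genome with gene content randomly reassigned to positions.

    Coordinates and chromosome layout are kept; which gene sits where is
    permuted. Used to emulate a rearranged (synteny-free) relative.
    """
    rng = np.random.default_rng(seed)
    genes = genome.genes()
    coords = [(g.chrom, g.start, g.end, g.strand, tuple(g.exons)) for g in genes]
    perm = rng.permutation(len(genes))
    out = Genome(genome.species + "_shuf")
    for slot, gi in enumerate(perm):
        g = genes[gi]
        chrom, start, _end, strand, _exons = coords[slot]
        # keep the original gene's structure but re-anchor it at the slot
        offset = start - g.start
        out.add_gene(
            GeneModel(
                gene_id=g.gene_id, chrom=chrom, start=g.start + offset,
                end=g.end + offset, strand=strand,
                exons=[(s + offset, e + offset) for s, e in g.exons],
                cds_seq=g.cds_seq, protein_seq=g.protein_seq,
            )
        )
    return out


# ---------------------------------------------------------------------------
# emission


def _genome_sequence(genome: Genome, rng: np.random.Generator) -> dict[str, str]:
    """Chromosome sequences with CDS embedded at exon coordinates."""
    from Bio.Seq import Seq

    chrom_seqs = {}
    for chrom, genes in genome.chromosomes.items():
        length = max(g.end for g in genes) + 1000
        arr = np.frombuffer(
            rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length).tobytes(),
            dtype=np.uint8,
        ).copy()
        for g in genes:
            placed = g.cds_seq if g.strand == "+" else str(Seq(g.cds_seq).reverse_complement())
            off = 0
            for s, e in g.exons:
                piece = placed[off : off + (e - s + 1)]
                arr[s - 1 : e] = np.frombuffer(piece.encode(), dtype=np.uint8)
                off += e - s + 1
        chrom_seqs[chrom] = arr.tobytes().decode()
    return chrom_seqs


def write_simulation(
    genomes: list[Genome],
    truth: SimulationTruth,
    outdir: str | Path,
    write_genome_fasta: bool = True,
    seed: int = 0,
) -> None:
    """Write genome.fa / genes.gff3 / cds.fa / proteins.fa per species + truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    for genome in genomes:
        d = outdir / genome.species
        d.mkdir(exist_ok=True)
        write_gff3(genome, d / "genes.gff3")
        write_fasta({g.gene_id: g.cds_seq for g in genome.genes()}, d / "cds.fa")
        write_fasta({g.gene_id: g.protein_seq for g in genome.genes()}, d / "proteins.fa")
        if write_genome_fasta:
            write_fasta(_genome_sequence(genome, rng), d / "genome.fa")
    rows = []
    for a, b, etype, sp in truth.duplications:
        rows.append({"record": "duplication", "species": sp, "a": a, "b": b, "label": etype})
    for a, b in truth.orthologs:
        rows.append({"record": "ortholog", "species": "", "a": a, "b": b, "label": ""})
    for gid, sf in sorted(truth.subfamily.items()):
        rows.append({"record": "subfamily", "species": "", "a": gid, "b": "", "label": sf})
    for i, lab in enumerate(truth.site_classes, start=1):
        rows.append({"record": "site_class", "species": "", "a": str(i), "b": "", "label": lab})
    for gid, n in sorted(truth.exon_counts.items()):
        rows.append({"record": "exons", "species": "", "a": gid, "b": "", "label": str(n)})
    write_tsv(rows, outdir / "truth.tsv")
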