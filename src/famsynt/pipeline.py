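"""End-to-end orchestration: simulate/load -> identify -> phylogeny ->
structure -> synteny -> Ka/Ks -> divergence -> summary.

A run writes every stage table under ``<outdir>/report`` together with a
``manifest.json`` recording parameters, input hashes and per-stage seeds.
The report directory is byte-reproducible for a fixed config and seed;
wall-clock logging goes to ``<outdir>/run.log`` outside the report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import divergence as div
from . import kaks as kk
from . import phylogeny as phy
from . import structure as struct
from . import synteny as syn
from .domains import build_pssm, call_family, load_seed_alignment
from .genome_io import Genome, read_fasta, read_gff3, write_newick, write_tsv
from .msa import progressive_align
from .simulate import SimulationConfig, simulate, write_simulation

__all__ = ["PipelineConfig", "run_pipeline", "summarize"]


@dataclass
class PipelineConfig:
    """All stage parameters in one place.

    The defaults are the standard settings of this kind of family survey:
    100 kb flank radius, E <= 1e-10, >= 4 conserved pairs for a
    large-scale call, 150 bp / 9 bp sliding windows, Q_k > 0.9,
    1000 bootstrap replicates, 5 subfamilies.
    """

    species_inputs: list[dict] = field(default_factory=list)
    # each: {species, gff3, cds, proteins}; ignored when simulate_enabled
    simulate_enabled: bool = True
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    radius_bp: int = 100_000
    evalue_max: float = 1e-10
    min_pairs: int = 4
    max_intervening: int = 1
    window_bp: int = 150
    step_bp: int = 9
    qk_threshold: float = 0.9
    n_bootstrap: int = 1000
    k_subfamilies: int = 5
    min_support: int = 500
    min_cluster: int = 4
    seed: int = 0
    stages: dict[str, bool] = field(default_factory=dict)  # per-stage enable

    _STAGE_NAMES = ("identify", "phylo", "structure", "synteny", "kaks", "diverge")

    def stage_enabled(self, name: str) -> bool:
        return self.stages.get(name, True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _load_genomes(cfg: PipelineConfig) -> tuple[list[Genome], object | None]:
    if cfg.simulate_enabled:
        sim_cfg = SimulationConfig(**{"seed": cfg.seed, **cfg.simulation})
        genomes, truth = simulate(sim_cfg)
        return genomes, truth
    genomes = []
    for spec in cfg.species_inputs:
        genomes.append(
            read_gff3(
                spec["gff3"], species=spec["species"],
                cds_fasta=spec.get("cds"), protein_fasta=spec.get("proteins"),
            )
        )
    return genomes, None


def _validate(cfg: PipelineConfig) -> None:
    if cfg.simulate_enabled:
        return
    if not cfg.species_inputs:
        raise ValueError("no species inputs and simulation disabled")
    missing = []
    for spec in cfg.species_inputs:
        for key in ("gff3", "cds", "proteins"):
            p = spec.get(key)
            if p and not Path(p).exists():
                missing.append(str(p))
    if missing:
        raise FileNotFoundError(f"missing inputs: {missing}")


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> Path:
    """Run all enabled stages; returns the report directory."""
    _validate(cfg)
    outdir = Path(outdir)
    report = outdir / "report"
    report.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    t_start = time.time()

    def log(msg: str) -> None:
        log_lines.append(f"[{time.time() - t_start:8.2f}s] {msg}")

    manifest: dict = {
        "parameters": {
            k: v for k, v in dataclasses.asdict(cfg).items() if k != "species_inputs"
        },
        "inputs": {},
        "outputs": [],
    }
    for spec in cfg.species_inputs:
        for key in ("gff3", "cds", "proteins"):
            p = spec.get(key)
            if p and Path(p).exists():
                manifest["inputs"][str(p)] = _file_hash(Path(p))

    genomes, truth = _load_genomes(cfg)
    log(f"loaded {len(genomes)} genomes: " + ", ".join(g.species for g in genomes))
    if cfg.simulate_enabled:
        sim_dir = report / "simulation"
        sim_cfg = SimulationConfig(**{"seed": cfg.seed, **cfg.simulation})
        write_simulation(genomes, truth, sim_dir, write_genome_fasta=False, seed=cfg.seed)
        log("simulation written")

    members = []
    members_tsv = report / "members.tsv"
    if cfg.stage_enabled("identify"):
        pssms = {name: build_pssm(load_seed_alignment(name), name) for name in ("QLQ", "WRC")}
        members = call_family(genomes, pssms)
        write_tsv(
            [
                {
                    "member_id": m.member_id, "gene_id": m.gene_id, "species": m.species,
                    "chrom": m.chrom, "start": m.start, "end": m.end,
                    "n_QLQ": m.n_qlq, "n_WRC": m.n_wrc,
                    "best_score": round(max(h.score for h in m.hits), 2),
                }
                for m in members
            ],
            members_tsv,
        )
        log(f"identify: {len(members)} members")
    by_gene = {m.gene_id: m for m in members}

    aln: dict[str, str] = {}
    subfam: dict[str, str] = {}
    if cfg.stage_enabled("phylo") and len(members) >= 3:
        genome_by_sp = {g.species: g for g in genomes}
        prots = {
            m.gene_id: genome_by_sp[m.species].get(m.gene_id).protein_seq for m in members
        }
        aln = progressive_align(prots)
        tree = phy.bootstrap(aln, n_reps=cfg.n_bootstrap, seed=cfg.seed + 1)
        write_newick(tree, report / "tree.nwk")
        subfam = phy.assign_subfamilies(tree, k=cfg.k_subfamilies, min_support=cfg.min_support)
        write_tsv(
            [
                {"gene_id": g, "member_id": by_gene[g].member_id if g in by_gene else g,
                 "subfamily": sf}
                for g, sf in sorted(subfam.items())
            ],
            report / "subfamilies.tsv",
        )
        log(f"phylo: {len(aln)} taxa, {cfg.n_bootstrap} bootstrap replicates")

    table: dict[str, struct.StructureRecord] = {}
    if cfg.stage_enabled("structure"):
        table = struct.structure_table(genomes, [m.gene_id for m in members] or None)
        write_tsv(
            [
                {
                    "gene_id": r.gene_id, "n_exons": r.n_exons, "n_introns": r.n_introns,
                    "exon_lengths": ",".join(map(str, r.exon_lengths)),
                }
                for r in table.values()
            ],
            report / "structure.tsv",
        )
        dist = struct.exon_distribution(table)
        write_tsv(
            [{"n_exons": k, "n_genes": v} for k, v in dist.items()],
            report / "exon_distribution.tsv",
        )
        log(f"structure: {len(table)} records")

    blocks: list[syn.SyntenyBlock] = []
    if cfg.stage_enabled("synteny") and members:
        scorer = syn.ProteinScorer()
        genome_by_sp = {g.species: g for g in genomes}
        members_by_sp: dict[str, list[str]] = {}
        for m in members:
            members_by_sp.setdefault(m.species, []).append(m.gene_id)
        for sp, ids in sorted(members_by_sp.items()):
            g = genome_by_sp[sp]
            for a, b in itertools.combinations(sorted(ids), 2):
                blocks.append(
                    syn.classify_duplication(
                        g, g, a, b, radius_bp=cfg.radius_bp, evalue_max=cfg.evalue_max,
                        min_pairs=cfg.min_pairs, max_intervening=cfg.max_intervening,
                        scorer=scorer,
                    )
                )
        for sp_a, sp_b in itertools.combinations(sorted(members_by_sp), 2):
            blocks.extend(
                syn.interspecies_synteny(
                    genome_by_sp[sp_a], genome_by_sp[sp_b],
                    members_by_sp[sp_a], members_by_sp[sp_b],
                    radius_bp=cfg.radius_bp, evalue_max=cfg.evalue_max,
                    min_pairs=cfg.min_pairs, scorer=scorer,
                )
            )
        write_tsv(
            [
                {
                    "anchor_a": b.anchor_a, "anchor_b": b.anchor_b, "scope": b.scope,
                    "n_pairs": b.n_pairs, "classification": b.classification,
                    "pairs": ";".join(f"{p.gene_a}|{p.gene_b}" for p in b.pairs),
                }
                for b in blocks
            ],
            report / "blocks.tsv",
        )
        log(f"synteny: {len(blocks)} anchor pairs evaluated")

    if cfg.stage_enabled("kaks") and members:
        genome_by_sp = {g.species: g for g in genomes}
        dup_pairs = [
            (b.anchor_a, b.anchor_b)
            for b in blocks
            if b.scope == "intra" and b.classification != "none"
        ]
        cds_all, prot_all = {}, {}
        for g in genomes:
            for gene in g.genes():
                if gene.codon_ok:
                    cds_all[gene.gene_id] = gene.cds_seq
                    prot_all[gene.gene_id] = gene.protein_seq
        rows, windows = kk.pairwise_report(
            dup_pairs, cds_all, prot_all, window_bp=cfg.window_bp, step_bp=cfg.step_bp
        )
        write_tsv(rows or [{"gene_a": "", "gene_b": "", "status": "no_pairs"}],
                  report / "kaks.tsv")
        wrows = []
        for (a, b), series in sorted(windows.items()):
            for s, res in zip(series.starts, series.results):
                wrows.append({
                    "gene_a": a, "gene_b": b, "window_start_bp": s,
                    "ka_ks": "NA" if res.ratio is None else round(res.ratio, 6),
                    "Ks": "NA" if res.Ks is None else round(res.Ks, 6),
                })
        write_tsv(wrows or [{"gene_a": "", "gene_b": "", "window_start_bp": "",
                             "ka_ks": "", "Ks": ""}], report / "windows.tsv")
        log(f"kaks: {len(rows)} pairs, {len(wrows)} windows")

    if cfg.stage_enabled("diverge") and aln and subfam:
        rows, results = div.divergence_report(
            aln, subfam, min_cluster=cfg.min_cluster, qk_threshold=cfg.qk_threshold
        )
        write_tsv(rows or [{"pair": "", "type": "none"}], report / "diverge.tsv")
        srows = []
        for (sa, sb, tname), r in sorted(results.items()):
            for col, q in zip(r.columns, r.qk):
                if q > 0.5:
                    srows.append({
                        "pair": f"{sa} vs {sb}", "type": tname, "column": col,
                        "qk": round(float(q), 4),
                    })
        write_tsv(srows or [{"pair": "", "type": "", "column": "", "qk": ""}],
                  report / "sites.tsv")
        log(f"diverge: {len(rows)} subfamily-pair rows")

    summary_rows = _summary_rows(genomes, members, subfam, blocks)
    write_tsv(summary_rows, report / "summary.tsv")

    manifest["outputs"] = sorted(p.name for p in report.iterdir() if p.is_file())
    (report / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log("done")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return report


def _summary_rows(genomes, members, subfam, blocks) -> list[dict]:
    rows = []
    members_by_sp: dict[str, list] = {}
    for m in members:
        members_by_sp.setdefault(m.species, []).append(m)
    for g in genomes:
        rows.append({
            "metric": "members", "key": g.species,
            "value": len(members_by_sp.get(g.species, [])),
        })
    counts: dict[str, int] = {}
    anchored: set[str] = set()
    for b in blocks:
        if b.scope != "intra":
            continue
        if b.classification != "none":
            counts[b.classification] = counts.get(b.classification, 0) + 1
            anchored.update((b.anchor_a, b.anchor_b))
    for cls in ("tandem", "large_scale", "relaxed"):
        rows.append({"metric": "duplication_pairs", "key": cls, "value": counts.get(cls, 0)})
    inter = [b for b in blocks if b.scope == "inter"]
    rows.append({"metric": "interspecies_blocks", "key": "all", "value": len(inter)})
    n_members = len(members)
    frac = len(anchored) / n_members if n_members else 0.0
    rows.append({
        "metric": "members_in_duplicated_regions", "key": "fraction",
        "value": round(frac, 4),
    })
    sf_counts: dict[str, int] = {}
    for sf in subfam.values():
        sf_counts[sf] = sf_counts.get(sf, 0) + 1
    for sf in sorted(sf_counts):
        rows.append({"metric": "subfamily_size", "key": sf, "value": sf_counts[sf]})
    return rows


def summarize(report_dir: str | Path):
    """Summary table of a completed run (reads report TSVs)."""
    import pandas as pd

    report_dir = Path(report_dir)
    path = report_dir / "summary.tsv"
    if not path.exists():
        missing = [
            name for name in ("summary.tsv", "manifest.json")
            if not (report_dir / name).exists()
        ]
        raise FileNotFoundError(f"incomplete run; missing {missing}")
    return pd.read_csv(path, sep="\t")
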