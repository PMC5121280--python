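"""Exon–intron structure statistics and gain/loss calls for gene pairs."""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

from .genome_io import Genome

__all__ = ["StructureRecord", "structure_table", "exon_distribution", "gain_loss"]


@dataclass
class StructureRecord:
    gene_id: str
    n_exons: int
    n_introns: int
    exon_lengths: list[int]  # bp, genomic order


def structure_table(
    genomes: list[Genome], member_gene_ids: list[str] | None = None
) -> dict[str, StructureRecord]:
    """One structure record per (member) gene; genes without exons are skipped.

    Exon counts use exon features (which for UTR-bearing annotations differ
    from CDS segment counts); n_introns = n_exons - 1.
    """
    wanted = set(member_gene_ids) if member_gene_ids is not None else None
    table: dict[str, StructureRecord] = {}
    for genome in genomes:
        for gene in genome.genes():
            if wanted is not None and gene.gene_id not in wanted:
                continue
            if not gene.exons:
                warnings.warn(f"{gene.gene_id}: no exon annotation; excluded")
                continue
            table[gene.gene_id] = StructureRecord(
                gene_id=gene.gene_id,
                n_exons=gene.n_exons,
                n_introns=gene.n_exons - 1,
                exon_lengths=[e - s + 1 for s, e in gene.exons],
            )
    return table


def exon_distribution(table: dict[str, StructureRecord]) -> dict[int, int]:
    """Count of genes per exon number (classes partition the gene set)."""
    return dict(sorted(Counter(rec.n_exons for rec in table.values()).items()))


def gain_loss(
    pairs: list[tuple[str, str]], table: dict[str, StructureRecord]
) -> list[dict]:
    """Exon gain/loss call per gene pair, relative to the first gene.

    delta = n_exons(b) - n_exons(a); positive is a gain in b, negative a
    loss. Missing genes are an error naming the gene.
    """
    rows = []
    for a, b in pairs:
        for gid in (a, b):
            if gid not in table:
                raise KeyError(f"gene {gid!r} missing from structure table")
        delta = table[b].n_exons - table[a].n_exons
        call = "equal" if delta == 0 else ("gain" if delta > 0 else "loss")
        rows.append({"gene_a": a, "gene_b": b, "delta_exons": delta, "call": call})
    return rows
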