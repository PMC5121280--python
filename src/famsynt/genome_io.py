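"""Genome, gene-model and file-format plumbing.

Every coordinate in this package is GFF3-native: 1-based, inclusive, on the
forward strand of the chromosome. Exons are stored in genomic order; use
:attr:`GeneModel.transcript_exons` for transcription order on the minus
strand. One transcript is kept per gene (the one with the longest CDS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._codon import translate_cds

__all__ = [
    "GeneModel",
    "Genome",
    "Gff3ParseError",
    "read_gff3",
    "write_gff3",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "read_tsv",
    "write_tsv",
]


class Gff3ParseError(ValueError):
    """Raised for a malformed GFF3 line; carries the 1-based line number."""


@dataclass
class GeneModel:
    """An annotated protein-coding gene (single representative transcript)."""

    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_seq: str = ""
    protein_seq: str = ""
    codon_ok: bool = True  # False when CDS length is not a multiple of 3

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping exons {(s1, e1)} {(s2, e2)}")

    @property
    def transcript_exons(self) -> list[tuple[int, int]]:
        """Exons in transcription order (reversed on the minus strand)."""
        return self.exons[::-1] if self.strand == "-" else self.exons

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def span_overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and self.end >= start

    def validate_translation(self) -> bool:
        """Check that the (stop-trimmed) CDS translates to protein_seq."""
        if not self.cds_seq or not self.codon_ok:
            return False
        return translate_cds(self.cds_seq) == self.protein_seq


class Genome:
    """A species' gene models, indexed by id and ordered along chromosomes."""

    def __init__(self, species: str, genes: list[GeneModel] | None = None):
        self.species = species
        self.chromosomes: dict[str, list[GeneModel]] = {}
        self._index: dict[str, GeneModel] = {}
        for g in genes or []:
            self.add_gene(g)

    def add_gene(self, gene: GeneModel) -> None:
        if gene.gene_id in self._index:
            raise ValueError(f"duplicate gene id {gene.gene_id!r}")
        self._index[gene.gene_id] = gene
        self.chromosomes.setdefault(gene.chrom, []).append(gene)
        self.chromosomes[gene.chrom].sort(key=lambda g: (g.start, g.gene_id))

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def __len__(self) -> int:
        return len(self._index)

    def get(self, gene_id: str) -> GeneModel:
        try:
            return self._index[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene {gene_id!r} in {self.species}") from None

    def genes(self) -> list[GeneModel]:
        return [g for chrom in sorted(self.chromosomes) for g in self.chromosomes[chrom]]

    def position_on_chrom(self, gene_id: str) -> int:
        """Ordinal index of a gene within its chromosome's gene order."""
        g = self.get(gene_id)
        return self.chromosomes[g.chrom].index(g)


# ---------------------------------------------------------------------------
# GFF3


def _validate_gff3_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise Gff3ParseError(f"{path}:{lineno}: expected 9 tab-separated fields")


def read_gff3(
    path: str | Path,
    species: str | None = None,
    cds_fasta: str | Path | None = None,
    protein_fasta: str | Path | None = None,
    genome_fasta: str | Path | None = None,
) -> Genome:
    """Parse a GFF3 file into a :class:`Genome`.

    One :class:`GeneModel` is built per gene, keeping the transcript with the
    longest summed CDS. Coding and protein sequences are taken from
    ``cds_fasta``/``protein_fasta`` (keyed by gene or transcript id) or, if a
    ``genome_fasta`` is supplied instead, extracted from the CDS features.
    Genes whose CDS length is not a multiple of 3 are flagged
    (``codon_ok=False``) and excluded from codon-level analyses downstream.
    """
    path = Path(path)
    _validate_gff3_lines(path)
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    cds_map = read_fasta(cds_fasta) if cds_fasta else {}
    prot_map = read_fasta(protein_fasta) if protein_fasta else {}
    chrom_seqs = read_fasta(genome_fasta) if genome_fasta else {}

    genome = Genome(species or path.stem)
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        best, best_len = None, -1
        for mrna in mrnas or [gene]:
            cds_len = sum(c.end - c.start + 1 for c in db.children(mrna, featuretype="CDS"))
            if cds_len > best_len:
                best, best_len = mrna, cds_len
        exons = sorted(
            (e.start, e.end) for e in db.children(best, featuretype="exon")
        )
        if not exons:
            exons = sorted((c.start, c.end) for c in db.children(best, featuretype="CDS"))
        if not exons:
            exons = [(gene.start, gene.end)]

        cds_seq = cds_map.get(gene.id, "") or cds_map.get(best.id, "")
        if not cds_seq and chrom_seqs:
            parts = sorted((c.start, c.end) for c in db.children(best, featuretype="CDS"))
            raw = "".join(chrom_seqs[gene.seqid][s - 1 : e] for s, e in parts)
            cds_seq = str(Seq(raw).reverse_complement()) if gene.strand == "-" else raw
        cds_seq = _trim_stop(cds_seq)

        codon_ok = len(cds_seq) % 3 == 0
        if not codon_ok:
            warnings.warn(
                f"{gene.id}: CDS length {len(cds_seq)} not divisible by 3; "
                "gene excluded from codon analyses"
            )
        protein = prot_map.get(gene.id, "") or prot_map.get(best.id, "")
        if not protein and cds_seq and codon_ok:
            protein = translate_cds(cds_seq)
        genome.add_gene(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand if gene.strand in "+-" else "+",
                exons=exons,
                cds_seq=cds_seq,
                protein_seq=protein,
                codon_ok=codon_ok,
            )
        )
    return genome


def _trim_stop(cds: str) -> str:
    if len(cds) >= 3 and len(cds) % 3 == 0 and cds[-3:].upper() in ("TAA", "TAG", "TGA"):
        return cds[:-3]
    return cds


def write_gff3(genome: Genome, path: str | Path) -> None:
    """Write gene/mRNA/exon/CDS features (UTR-less models, one mRNA/gene)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genome.genes():
            base = f"{g.chrom}\tfamsynt\t"
            tail = f"\t.\t{g.strand}\t"
            fh.write(f"{base}gene\t{g.start}\t{g.end}{tail}.\tID={g.gene_id}\n")
            tid = f"{g.gene_id}.t1"
            fh.write(f"{base}mRNA\t{g.start}\t{g.end}{tail}.\tID={tid};Parent={g.gene_id}\n")
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(f"{base}exon\t{s}\t{e}{tail}.\tID={tid}.exon{i};Parent={tid}\n")
                fh.write(f"{base}CDS\t{s}\t{e}{tail}0\tID={tid}.cds{i};Parent={tid}\n")


# ---------------------------------------------------------------------------
# FASTA / Newick / TSV


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id->sequence map; duplicate ids are an error."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq)
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")  # wraps at 60 columns


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(
        path=str(path), schema="newick",
        suppress_rooting=True, unquoted_underscores=True,
    )


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(records, path: str | Path) -> None:
    """Write a DataFrame or list of dicts as TSV with a header row."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    df.to_csv(path, sep="\t", index=False)
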