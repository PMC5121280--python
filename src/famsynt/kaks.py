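"""Nonsynonymous/synonymous substitution rates for duplicate gene pairs.

The estimator is Nei–Gojobori (1986) counting: synonymous and nonsynonymous
sites are counted per codon (S + N = 3, averaged over the two sequences),
differences are averaged over all minimal mutational pathways (pathways
through stop codons are excluded and the weights renormalised), and the
proportions are corrected for multiple hits with the Jukes–Cantor formula
d = -(3/4)ln(1 - (4/3)p). Ka/Ks < 1, = 1 and > 1 are read as purifying,
neutral and positive selection respectively.

A sliding-window scan (default 150 bp window, 9 bp step, matching common
DnaSP practice) localises selection signal along the alignment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from ._codon import SENSE_CODONS, diff_table, site_counts, translate_cds

__all__ = [
    "CodonAlignment",
    "KaKsResult",
    "WindowSeries",
    "backtranslate",
    "ng86",
    "sliding_window",
    "pairwise_report",
]

GAP_CODON = "---"


@dataclass
class CodonAlignment:
    """A pair of gap-aligned CDS strings whose columns are whole codons."""

    id_a: str
    id_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned CDS lengths differ")
        if len(self.seq_a) % 3:
            raise ValueError("aligned length not divisible by 3")

    def __len__(self) -> int:
        return len(self.seq_a)

    def codon_pairs(self) -> list[tuple[str, str]]:
        return [
            (self.seq_a[i : i + 3], self.seq_b[i : i + 3])
            for i in range(0, len(self.seq_a), 3)
        ]

    def window(self, start_bp: int, width_bp: int) -> "CodonAlignment":
        """Sub-alignment of the codons fully inside [start_bp, start_bp+width-1] (1-based)."""
        lo = start_bp - 1
        hi = lo + width_bp
        first = math.ceil(lo / 3)
        last = hi // 3  # exclusive codon index
        return CodonAlignment(
            self.id_a, self.id_b, self.seq_a[first * 3 : last * 3], self.seq_b[first * 3 : last * 3]
        )


@dataclass
class KaKsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float | None
    Ka: float | None
    ratio: float | None  # None when Ks is 0 or a correction is undefined

    @property
    def classification(self) -> str:
        if self.ratio is None:
            return "undefined"
        if self.ratio < 1.0:
            return "purifying"
        if self.ratio > 1.0:
            return "positive"
        return "neutral"


@dataclass
class WindowSeries:
    window_bp: int
    step_bp: int
    starts: list[int] = field(default_factory=list)  # 1-based alignment bp
    results: list[KaKsResult] = field(default_factory=list)


def backtranslate(
    protein_aln_a: str,
    protein_aln_b: str,
    cds_a: str,
    cds_b: str,
    id_a: str = "a",
    id_b: str = "b",
) -> CodonAlignment:
    """Thread two CDSs onto their aligned proteins (PAL2NAL-style).

    Each protein gap column becomes a codon gap; a trailing stop codon on
    either CDS is dropped. The ungapped output recovers each CDS exactly.
    """
    out = []
    for seq_p, cds, name in ((protein_aln_a, cds_a, id_a), (protein_aln_b, cds_b, id_b)):
        if len(cds) % 3 == 0 and cds and translate_cds(cds).endswith("*"):
            cds = cds[:-3]
        expected = seq_p.replace("-", "")
        got = translate_cds(cds)
        if got != expected:
            for i, (x, y) in enumerate(zip(got, expected)):
                if x != y:
                    raise ValueError(
                        f"{name}: CDS translation disagrees with protein at residue "
                        f"{i + 1} ({x!r} vs {y!r})"
                    )
            raise ValueError(f"{name}: CDS/protein length mismatch ({len(got)} vs {len(expected)})")
        pos = 0
        chunks = []
        for aa in seq_p:
            if aa == "-":
                chunks.append(GAP_CODON)
            else:
                chunks.append(cds[pos : pos + 3])
                pos += 3
        out.append("".join(chunks))
    return CodonAlignment(id_a, id_b, out[0], out[1])


def _jc_correct(p: float) -> float | None:
    """Jukes–Cantor multiple-hit correction; None when p >= 3/4."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def ng86(aln: CodonAlignment) -> KaKsResult:
    """Nei–Gojobori (1986) Ka/Ks for one codon alignment.

    Codon columns containing a gap (or a stop codon, which should not occur
    in a trimmed CDS) are excluded from both site and difference counts.
    """
    sites = site_counts()
    diffs = diff_table()
    S_a = N_a = S_b = N_b = 0.0
    Sd = Nd = 0.0
    n_cols = 0
    for ca, cb in aln.codon_pairs():
        if ca not in sites or cb not in sites:  # gap or stop codon column
            continue
        n_cols += 1
        sa, na = sites[ca]
        sb, nb = sites[cb]
        S_a += sa
        N_a += na
        S_b += sb
        N_b += nb
        sd, nd = diffs[(ca, cb)]
        Sd += sd
        Nd += nd
    if n_cols == 0:
        raise ValueError("no gap-free codon columns in alignment")
    S = (S_a + S_b) / 2.0
    N = (N_a + N_b) / 2.0
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks = _jc_correct(pS)
    Ka = _jc_correct(pN)
    ratio = None
    if Ka is not None and Ks is not None and Ks > 0:
        ratio = Ka / Ks
    return KaKsResult(S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, Ks=Ks, Ka=Ka, ratio=ratio)


def sliding_window(aln: CodonAlignment, window_bp: int = 150, step_bp: int = 9) -> WindowSeries:
    """NG86 in sliding windows along the alignment.

    Windows are fully contained: floor((L - window)/step) + 1 of them, the
    i-th starting at alignment bp 1 + i*step. Windows whose Ks is zero or
    whose correction is undefined carry ratio None, never a fabricated value.
    """
    if window_bp % 3:
        raise ValueError("window size must be divisible by 3")
    if step_bp < 1:
        raise ValueError("step must be >= 1")
    series = WindowSeries(window_bp=window_bp, step_bp=step_bp)
    L = len(aln)
    if L < window_bp:
        warnings.warn(f"alignment length {L} shorter than window {window_bp}; empty series")
        return series
    n_windows = (L - window_bp) // step_bp + 1
    for i in range(n_windows):
        start = 1 + i * step_bp
        sub = aln.window(start, window_bp)
        series.starts.append(start)
        series.results.append(ng86(sub))
    return series


def pairwise_report(
    pairs: list[tuple[str, str]],
    cds: dict[str, str],
    proteins: dict[str, str],
    aligner=None,
    window_bp: int = 150,
    step_bp: int = 9,
) -> tuple[list[dict], dict[tuple[str, str], WindowSeries]]:
    """Ka/Ks rows plus per-pair window series for a list of gene-id pairs.

    Protein pairs are globally aligned (via phylogeny.align_pair unless an
    aligner callable is supplied), back-translated and run through ng86.
    Pairs with missing sequences are emitted as flagged rows and skipped.
    """
    if aligner is None:
        from .msa import align_pair

        aligner = align_pair
    rows: list[dict] = []
    windows: dict[tuple[str, str], WindowSeries] = {}
    for a, b in pairs:
        row = {"gene_a": a, "gene_b": b}
        if a not in cds or b not in cds or a not in proteins or b not in proteins:
            row.update(status="missing_sequence", Ks="NA", Ka="NA", ka_ks="NA",
                       classification="NA")
            rows.append(row)
            continue
        pa, pb = aligner(proteins[a], proteins[b])
        caln = backtranslate(pa, pb, cds[a], cds[b], id_a=a, id_b=b)
        res = ng86(caln)
        row.update(
            status="ok",
            S=round(res.S, 4), N=round(res.N, 4),
            Sd=round(res.Sd, 4), Nd=round(res.Nd, 4),
            Ks="NA" if res.Ks is None else round(res.Ks, 6),
            Ka="NA" if res.Ka is None else round(res.Ka, 6),
            ka_ks="NA" if res.ratio is None else round(res.ratio, 6),
            classification=res.classification,
        )
        rows.append(row)
        if len(caln) >= window_bp:
            windows[(a, b)] = sliding_window(caln, window_bp, step_bp)
    return rows, windows
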