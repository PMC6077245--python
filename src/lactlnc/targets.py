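"""lncRNA target prediction: cis windows, trans correlation, miRNA precursors.

Cis targets are protein-coding genes within 10 kb / 100 kb of a lncRNA
(span-to-span gap, strand-agnostic membership, signed distance oriented by
the lncRNA's strand). Trans targets are genes whose expression correlates
with the lncRNA's across samples (Pearson on log2(FPKM+1), two-sided t
test, p < α, no multiplicity correction). Precursor detection reports
exact full-length occurrences of miRNA hairpin sequences inside spliced
lncRNA sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from lactlnc.genome_io import GenomicInterval, IntervalIndex, TranscriptModel

DEFAULT_WINDOWS = (10_000, 100_000)


@dataclass(frozen=True)
class TargetEdge:
    """A lncRNA–gene relation with its distance or correlation evidence."""

    lnc_id: str
    gene_id: str
    mode: str  # cis10k | cis100k | trans
    distance_bp: int | None = None  # signed; negative = gene upstream of lnc 5'
    r: float | None = None
    p: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("cis10k", "cis100k", "trans"):
            raise ValueError(f"unknown edge mode {self.mode!r}")


@dataclass(frozen=True)
class PrecursorHit:
    """An exact full-length hairpin occurrence inside a spliced lncRNA."""

    lnc_id: str
    mirna_id: str
    offset: int
    strand_of_match: str = "+"


def gene_spans(
    reference: Iterable[TranscriptModel],
) -> dict[str, GenomicInterval]:
    """Union span per gene_id over its transcripts (single-chrom genes)."""
    spans: dict[str, GenomicInterval] = {}
    for t in reference:
        cur = spans.get(t.gene_id)
        if cur is None:
            spans[t.gene_id] = t.span
        else:
            if cur.chrom != t.chrom:
                raise ValueError(f"gene {t.gene_id} spans multiple chromosomes")
            spans[t.gene_id] = GenomicInterval(
                cur.chrom,
                min(cur.start, t.start),
                max(cur.end, t.end),
                cur.strand,
            )
    return spans


def _signed_distance(lnc: GenomicInterval, gene: GenomicInterval) -> int:
    """Span-to-span gap, signed: negative when the gene lies upstream of the
    lncRNA's 5' end (strand-aware)."""
    gap = lnc.distance_to(gene)
    assert gap is not None
    if gap == 0:
        return 0
    gene_is_left = gene.end <= lnc.start
    if lnc.strand == "-":
        upstream = not gene_is_left
    else:
        upstream = gene_is_left
    return -gap if upstream else gap


def cis_neighbors(
    lncs: Sequence[TranscriptModel],
    reference: Sequence[TranscriptModel],
    windows: Sequence[int] = DEFAULT_WINDOWS,
) -> list[TargetEdge]:
    """Cis target edges: a gene is a cis target at window w iff the gap
    between the lncRNA span and the gene span is <= w (overlap → 0).

    Both windows are reported (the smaller-window edge set is a subset of
    the larger's). Strand-agnostic; the sign of ``distance_bp`` encodes
    upstream (negative) vs downstream relative to the lncRNA's 5' end.
    """
    windows = sorted(windows)
    spans = gene_spans(reference)
    index = IntervalIndex(
        (iv, gid, None) for gid, iv in sorted(spans.items())
    )
    wmax = windows[-1]
    edges = []
    for lnc in lncs:
        for iv, gid, _ in index.query_window(lnc.span, wmax):
            gap = lnc.span.distance_to(iv)
            if gap is None or gap > wmax:
                continue
            signed = _signed_distance(lnc.span, iv)
            for w in windows:
                if gap <= w:
                    mode = f"cis{w // 1000}k"
                    edges.append(
                        TargetEdge(lnc.transcript_id, gid, mode, distance_bp=signed)
                    )
    edges.sort(key=lambda e: (e.lnc_id, e.gene_id, e.mode))
    return edges


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p from the t transform with n−2 df."""
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    if math.isnan(r):
        return float("nan"), float("nan")
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return r, p


def trans_edges(
    lnc_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    alpha: float = 0.05,
    log_transform: bool = True,
) -> list[TargetEdge]:
    """Trans target edges from expression correlation across samples.

    For each (lncRNA, gene) pair, Pearson r is computed on log2(FPKM+1)
    (or raw values with ``log_transform=False``); an edge is emitted iff
    the two-sided p < alpha. Constant series yield no edge.
    """
    if list(lnc_expr.columns) != list(gene_expr.columns):
        raise ValueError("lncRNA and gene matrices must share sample columns")
    n = lnc_expr.shape[1]
    if n < 3:
        raise ValueError("need >= 3 samples for correlation")
    lx = np.log2(lnc_expr.to_numpy(dtype=float) + 1) if log_transform else (
        lnc_expr.to_numpy(dtype=float)
    )
    gx = np.log2(gene_expr.to_numpy(dtype=float) + 1) if log_transform else (
        gene_expr.to_numpy(dtype=float)
    )
    edges = []
    for i, lnc_id in enumerate(lnc_expr.index):
        if lx[i].std() == 0:
            continue
        for j, gene_id in enumerate(gene_expr.index):
            if gx[j].std() == 0:
                continue
            r, p = pearson_with_p(lx[i], gx[j])
            if not math.isnan(p) and p < alpha:
                edges.append(TargetEdge(str(lnc_id), str(gene_id), "trans", r=r, p=p))
    edges.sort(key=lambda e: (e.lnc_id, e.gene_id))
    return edges


def precursor_match(
    lnc_seqs: Mapping[str, str],
    hairpins: Mapping[str, str],
    search_revcomp: bool = False,
) -> list[PrecursorHit]:
    """Exact full-length hairpin occurrences inside spliced lncRNAs.

    Hairpin sequences are U→T normalized. All occurrences are reported; a
    single substitution is enough to miss (100% identity over the full
    hairpin length). Reverse-complement search is off by default because
    the library is stranded.
    """
    hits = []
    for mirna_id in sorted(hairpins):
        hp = hairpins[mirna_id].upper().replace("U", "T")
        if not hp:
            continue
        queries = [(hp, "+")]
        if search_revcomp:
            queries.append((str(Seq(hp).reverse_complement()), "-"))
        for lnc_id in sorted(lnc_seqs):
            seq = lnc_seqs[lnc_id].upper()
            for q, strand in queries:
                start = seq.find(q)
                while start != -1:
                    hits.append(PrecursorHit(lnc_id, mirna_id, start, strand))
                    start = seq.find(q, start + 1)
    hits.sort(key=lambda h: (h.lnc_id, h.mirna_id, h.offset))
    return hits


def write_edges(edges: Sequence[TargetEdge], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("lnc_id\tgene_id\tmode\tdistance_bp\tr\tp\n")
        for e in edges:
            d = "" if e.distance_bp is None else str(e.distance_bp)
            r = "" if e.r is None else f"{e.r:.6g}"
            p = "" if e.p is None else f"{e.p:.6g}"
            fh.write(f"{e.lnc_id}\t{e.gene_id}\t{e.mode}\t{d}\t{r}\t{p}\n")


def read_edges(path: str) -> list[TargetEdge]:
    edges = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            lnc, gene, mode, d, r, p = line.rstrip("\n").split("\t")
            edges.append(
                TargetEdge(
                    lnc,
                    gene,
                    mode,
                    distance_bp=int(d) if d else None,
                    r=float(r) if r else None,
                    p=float(p) if p else None,
                )
            )
    return edges


def write_precursor_hits(hits: Sequence[PrecursorHit], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("lnc_id\tmirna_id\toffset\tstrand\n")
        for h in hits:
            fh.write(f"{h.lnc_id}\t{h.mirna_id}\t{h.offset}\t{h.strand_of_match}\n")
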