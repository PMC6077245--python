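"""Genomic data types and plain-text format I/O.

Internal coordinates are 0-based half-open throughout the package; the
external formats handled here (GTF exon rows, SNP/QTL tables, per-base
conservation rows) are 1-based inclusive and are converted exactly once, at
this boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


class GtfParseError(ValueError):
    """Raised for malformed GTF input, naming the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open.

    Parameters
    ----------
    chrom : str
        Chromosome / sequence name (matched by exact string equality).
    start, end : int
        0-based half-open coordinates, ``0 <= start < end``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Half-open intersection test; strand is ignored."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def distance_to(self, other: "GenomicInterval") -> int | None:
        """Span-to-span gap in bp; 0 when overlapping, None across chroms."""
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        if other.end <= self.start:
            return self.start - other.end
        return other.start - self.end


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded multi-exon transcript with assembler/sample provenance."""

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    source_label: str = ""
    sample_id: str = ""
    attributes: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(
                f"{self.transcript_id}: exons must share one chrom and strand"
            )
        prev_end = -1
        for e in self.exons:
            if e.start < prev_end:
                raise ValueError(
                    f"{self.transcript_id}: exons must be sorted and non-overlapping"
                )
            prev_end = e.end

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def length(self) -> int:
        """Exonic (spliced) length in nt."""
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return tuple(out)

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        """Ordered (donor, acceptor) splice coordinates; empty if single-exon."""
        return tuple(
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        )

    def attr(self, key: str, default: str | None = None) -> str | None:
        for k, v in self.attributes:
            if k == key:
                return v
        return default


@dataclass
class FeatureTrack:
    """A set of identified genomic features with per-record payloads.

    Used for QTL intervals, SNP positions (width-1 intervals) and per-base
    conservation values. ``records`` is a list of
    ``(GenomicInterval, id, payload-dict)``.
    """

    records: list[tuple[GenomicInterval, str, dict]] = field(default_factory=list)
    kind: str = "generic"

    def __post_init__(self) -> None:
        ids = [r[1] for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate ids in {self.kind} track")
        if self.kind == "snp":
            for iv, rid, _ in self.records:
                if len(iv) != 1:
                    raise ValueError(f"SNP {rid} is not a width-1 interval")

    def __len__(self) -> int:
        return len(self.records)

    def base_score(self, chrom: str, pos: int) -> float | None:
        """Per-base lookup for conservation tracks (0-based position)."""
        index = getattr(self, "_base_index", None)
        if index is None:
            index = {}
            for iv, _, payload in self.records:
                if "score" in payload:
                    for p in range(iv.start, iv.end):
                        index[(iv.chrom, p)] = float(payload["score"])
            self._base_index = index
        return index.get((chrom, pos))


class IntervalIndex:
    """Overlap index over intervals, half-open semantics.

    Wraps one :class:`intervaltree.IntervalTree` per chromosome; queries may
    restrict matches by strand relative to the query (`ignore`, `same`,
    `opposite`).
    """

    def __init__(
        self, records: Iterable[tuple[GenomicInterval, str, object]] = ()
    ) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._records: list[tuple[GenomicInterval, str, object]] = []
        for iv, rid, payload in records:
            self.add(iv, rid, payload)

    def add(self, iv: GenomicInterval, rid: str, payload: object = None) -> None:
        idx = len(self._records)
        self._records.append((iv, rid, payload))
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, idx)

    @classmethod
    def from_transcripts(cls, transcripts: Iterable[TranscriptModel]) -> "IntervalIndex":
        """Index transcript spans, keyed by transcript_id, payload = model."""
        return cls((t.span, t.transcript_id, t) for t in transcripts)

    @classmethod
    def from_track(cls, track: FeatureTrack) -> "IntervalIndex":
        return cls(track.records)

    def query(
        self, iv: GenomicInterval, strand_mode: str = "ignore"
    ) -> list[tuple[GenomicInterval, str, object]]:
        """All records whose intervals intersect ``iv`` (half-open)."""
        if strand_mode not in ("ignore", "same", "opposite"):
            raise ValueError(f"unknown strand_mode {strand_mode!r}")
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        hits = [self._records[h.data] for h in tree.overlap(iv.start, iv.end)]
        if strand_mode == "same":
            hits = [h for h in hits if h[0].strand == iv.strand]
        elif strand_mode == "opposite":
            hits = [
                h
                for h in hits
                if {h[0].strand, iv.strand} == {"+", "-"}
            ]
        hits.sort(key=lambda h: (h[0].start, h[0].end, h[1]))
        return hits

    def query_window(
        self, iv: GenomicInterval, window: int, strand_mode: str = "ignore"
    ) -> list[tuple[GenomicInterval, str, object]]:
        """Records within ``window`` bp of ``iv`` (gap <= window)."""
        padded = GenomicInterval(
            iv.chrom, max(0, iv.start - window), iv.end + window, iv.strand
        )
        return self.query(padded, strand_mode)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def read_gtf(
    path: str, source_label: str = "", sample_id: str = ""
) -> list[TranscriptModel]:
    """Read exon features from a GTF file into transcript models.

    GTF coordinates are 1-based inclusive and converted to the internal
    0-based half-open convention. One :class:`TranscriptModel` is returned
    per distinct ``transcript_id``, exons sorted by start. Non-exon feature
    rows and comment lines are skipped.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    genes: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-delimited fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = (
                fields
            )
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if end1 < start1:
                raise GtfParseError(
                    f"{path}:{lineno}: exon end {end1} < start {start1}"
                )
            attributes = _parse_attributes(attrs)
            tid = attributes.get("transcript_id")
            gid = attributes.get("gene_id")
            if not tid or not gid:
                raise GtfParseError(
                    f"{path}:{lineno}: exon lacks transcript_id/gene_id"
                )
            if strand not in STRANDS:
                raise GtfParseError(f"{path}:{lineno}: bad strand {strand!r}")
            exons.setdefault(tid, []).append(
                GenomicInterval(chrom, start1 - 1, end1, strand)
            )
            genes[tid] = gid
    out = []
    for tid, ivs in exons.items():
        ivs.sort(key=lambda e: (e.start, e.end))
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=genes[tid],
                exons=tuple(ivs),
                source_label=source_label,
                sample_id=sample_id,
            )
        )
    out.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
    return out


def write_gtf(transcripts: Sequence[TranscriptModel], path: str) -> None:
    """Write transcripts as exon rows in Ensembl-dialect GTF.

    Coordinates are emitted 1-based inclusive; rows are grouped per
    transcript and ordered by (chrom, start, transcript_id).
    """
    ordered = sorted(transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id))
    with open(path, "w") as fh:
        for t in ordered:
            extra = "".join(
                f' {k} "{v}";' for k, v in t.attributes if k not in
                ("gene_id", "transcript_id")
            )
            for e in t.exons:
                fh.write(
                    f"{t.chrom}\t{t.source_label or 'lactlnc'}\texon\t"
                    f"{e.start + 1}\t{e.end}\t.\t{t.strand}\t.\t"
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                    f"{extra}\n"
                )


# ---------------------------------------------------------------------------
# FASTA / sequences
# ---------------------------------------------------------------------------


def read_sequences(path: str) -> dict[str, str]:
    """Read a FASTA file into a name → uppercase sequence map."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")
    }


def write_sequences(seqs: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def extract_spliced_sequence(t: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Spliced transcript sequence: exons concatenated in genomic order,
    reverse-complemented for '-' strand transcripts."""
    if t.chrom not in genome:
        raise KeyError(f"chromosome {t.chrom!r} not in genome")
    chrom_seq = genome[t.chrom]
    if t.end > len(chrom_seq):
        raise ValueError(
            f"{t.transcript_id}: exon out of bounds on {t.chrom} "
            f"({t.end} > {len(chrom_seq)})"
        )
    seq = "".join(chrom_seq[e.start : e.end] for e in t.exons)
    if t.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


# ---------------------------------------------------------------------------
# Tab-delimited tables: scores, domain hits, feature tracks
# ---------------------------------------------------------------------------


def read_score_table(path: str) -> dict[str, dict[str, float]]:
    """Read a headered TSV of coding-potential scores.

    First column is the transcript id; remaining columns are scorer names
    (conventionally CPC/PLEK/CNCI, sign convention: > 0 = coding-like).
    Unknown scorer columns are kept with a warning; a duplicated transcript
    row is an error.
    """
    known = {"CPC", "PLEK", "CNCI", "baseline"}
    out: dict[str, dict[str, float]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        scorers = header[1:]
        for name in scorers:
            if name not in known:
                logger.warning("unknown scorer column %r (kept)", name)
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            tid = fields[0]
            if tid in out:
                raise ValueError(f"duplicate transcript row {tid!r} in {path}")
            out[tid] = {s: float(v) for s, v in zip(scorers, fields[1:])}
    return out


def write_score_table(
    scores: Mapping[str, Mapping[str, float]], path: str
) -> None:
    scorers = sorted({s for row in scores.values() for s in row})
    with open(path, "w") as fh:
        fh.write("transcript_id\t" + "\t".join(scorers) + "\n")
        for tid in scores:
            fh.write(
                tid
                + "\t"
                + "\t".join(f"{scores[tid].get(s, 0.0):g}" for s in scorers)
                + "\n"
            )


def read_domain_hits(path: str) -> dict[str, list[tuple[str, float]]]:
    """Read a headered TSV of protein-domain hits:
    columns transcript_id, domain_id, evalue."""
    out: dict[str, list[tuple[str, float]]] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            tid, dom, ev = line.rstrip("\n").split("\t")[:3]
            evalue = float(ev)
            if evalue < 0:
                raise ValueError(f"negative e-value for {tid}/{dom}")
            out.setdefault(tid, []).append((dom, evalue))
    return out


def write_domain_hits(
    hits: Mapping[str, Sequence[tuple[str, float]]], path: str
) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tdomain_id\tevalue\n")
        for tid in hits:
            for dom, ev in hits[tid]:
                fh.write(f"{tid}\t{dom}\t{ev:g}\n")


def read_feature_track(path: str, kind: str) -> FeatureTrack:
    """Read a QTL/SNP/conservation table into a :class:`FeatureTrack`.

    All on-disk positions are 1-based: QTL rows are (chrom, start, end, id,
    trait) with inclusive ends; SNP rows are (chrom, pos, id, trait); a
    conservation row is (chrom, pos, score) and contributes a width-1
    interval carrying a ``score`` payload.
    """
    if kind not in ("qtl", "snp", "conservation"):
        raise ValueError(f"unknown track kind {kind!r}")
    records: list[tuple[GenomicInterval, str, dict]] = []
    with open(path) as fh:
        fh.readline()  # header
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if kind == "qtl":
                chrom, start, end, rid = fields[0], int(fields[1]), int(fields[2]), fields[3]
                payload = {"trait": fields[4]} if len(fields) > 4 else {}
                records.append(
                    (GenomicInterval(chrom, start - 1, end), rid, payload)
                )
            elif kind == "snp":
                chrom, pos, rid = fields[0], int(fields[1]), fields[2]
                payload = {"trait": fields[3]} if len(fields) > 3 else {}
                records.append(
                    (GenomicInterval(chrom, pos - 1, pos), rid, payload)
                )
            else:
                chrom, pos, score = fields[0], int(fields[1]), float(fields[2])
                records.append(
                    (
                        GenomicInterval(chrom, pos - 1, pos),
                        f"c{i}",
                        {"score": score},
                    )
                )
    return FeatureTrack(records=records, kind=kind)


def write_feature_track(track: FeatureTrack, path: str) -> None:
    with open(path, "w") as fh:
        if track.kind == "qtl":
            fh.write("chrom\tstart\tend\tid\ttrait\n")
            for iv, rid, payload in track.records:
                fh.write(
                    f"{iv.chrom}\t{iv.start + 1}\t{iv.end}\t{rid}\t"
                    f"{payload.get('trait', '')}\n"
                )
        elif track.kind == "snp":
            fh.write("chrom\tpos\tid\ttrait\n")
            for iv, rid, payload in track.records:
                fh.write(
                    f"{iv.chrom}\t{iv.start + 1}\t{rid}\t"
                    f"{payload.get('trait', '')}\n"
                )
        elif track.kind == "conservation":
            fh.write("chrom\tpos\tscore\n")
            for iv, _rid, payload in track.records:
                fh.write(f"{iv.chrom}\t{iv.start + 1}\t{payload['score']:g}\n")
        else:
            raise ValueError(f"cannot write track kind {track.kind!r}")


def iter_exonic_positions(t: TranscriptModel) -> Iterator[int]:
    """0-based genomic positions of every exonic base, in genomic order."""
    for e in t.exons:
        yield from range(e.start, e.end)
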