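"""Consensus ("stringent") merging of multi-assembler transcript sets.

Per-assembler, per-sample transcript models are collapsed on exact exon-chain
identity; a structure is kept when it is supported by at least two assembly
programs (across any samples) or occurs in at least two samples (under any
single assembler). Transcript ids are never compared across runs — different
assemblers do not share an id namespace — so identity is purely structural.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from lactlnc.genome_io import TranscriptModel


@dataclass(frozen=True)
class ExonChainKey:
    """Structural identity of a transcript: chrom, strand and exon chain.

    With ``end_tolerance`` 0 the chain is the literal exon coordinate list.
    With a positive tolerance the two *terminal* boundaries (first exon
    start, last exon end) are bucketed to a tolerance-sized grid before
    keying; internal splice boundaries are always exact.
    """

    chrom: str
    strand: str
    chain: tuple[tuple[int, int], ...]

    @property
    def start(self) -> int:
        return self.chain[0][0]

    @property
    def end(self) -> int:
        return self.chain[-1][1]


@dataclass
class SupportRecord:
    """A merged transcript structure with its supporting runs."""

    key: ExonChainKey
    supports: frozenset[tuple[str, str]]  # (source_label, sample_id)
    representative: TranscriptModel

    @property
    def n_assemblers(self) -> int:
        return len({a for a, _ in self.supports})

    @property
    def n_samples(self) -> int:
        return len({s for _, s in self.supports})


def exon_chain_key(t: TranscriptModel, end_tolerance: int = 0) -> ExonChainKey:
    """Structural key of a transcript for consensus merging."""
    if end_tolerance < 0:
        raise ValueError("end_tolerance must be non-negative")
    chain = [[e.start, e.end] for e in t.exons]
    if end_tolerance > 0:
        chain[0][0] = chain[0][0] // end_tolerance
        chain[-1][1] = chain[-1][1] // end_tolerance
    return ExonChainKey(
        chrom=t.chrom,
        strand=t.strand,
        chain=tuple((a, b) for a, b in chain),
    )


def select_representative(
    candidates: Sequence[TranscriptModel],
) -> TranscriptModel:
    """Deterministic representative of transcripts sharing a key:
    lexicographically smallest (source_label, sample_id, transcript_id),
    annotated with the full support list."""
    if not candidates:
        raise ValueError("no candidates")
    best = min(
        candidates, key=lambda t: (t.source_label, t.sample_id, t.transcript_id)
    )
    supports = sorted({(t.source_label, t.sample_id) for t in candidates})
    support_str = ",".join(f"{a}:{s}" for a, s in supports)
    attrs = tuple(
        (k, v) for k, v in best.attributes if k != "supports"
    ) + (("supports", support_str),)
    return TranscriptModel(
        transcript_id=best.transcript_id,
        gene_id=best.gene_id,
        exons=best.exons,
        source_label=best.source_label,
        sample_id=best.sample_id,
        attributes=attrs,
    )


def stringent_merge(
    runs: Iterable[tuple[str, str, Sequence[TranscriptModel]]],
    min_assemblers: int = 2,
    min_samples: int = 2,
    end_tolerance: int = 0,
) -> list[SupportRecord]:
    """Collapse assembler runs into the stringent transcript set.

    Parameters
    ----------
    runs : iterable of (source_label, sample_id, transcripts)
        One entry per assembler × sample run; (source_label, sample_id)
        pairs must be unique.
    min_assemblers, min_samples : int
        A structure is retained iff it is supported by at least
        ``min_assemblers`` distinct assemblers OR occurs in at least
        ``min_samples`` distinct samples (disjunction).
    end_tolerance : int
        Terminal-boundary bucketing passed to :func:`exon_chain_key`.

    Returns
    -------
    list of SupportRecord, sorted by (chrom, start).
    """
    runs = list(runs)
    if not runs:
        raise ValueError("at least one run required")
    labels = [(a, s) for a, s, _ in runs]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate (assembler, sample) run labels")

    by_key: dict[ExonChainKey, list[TranscriptModel]] = {}
    for source_label, sample_id, transcripts in runs:
        seen_in_run: set[ExonChainKey] = set()
        for t in transcripts:
            if t.source_label != source_label or t.sample_id != sample_id:
                t = TranscriptModel(
                    transcript_id=t.transcript_id,
                    gene_id=t.gene_id,
                    exons=t.exons,
                    source_label=source_label,
                    sample_id=sample_id,
                    attributes=t.attributes,
                )
            key = exon_chain_key(t, end_tolerance)
            # a structure reported twice by one run still counts once
            by_key.setdefault(key, []).append(t)
            seen_in_run.add(key)

    out = []
    for key, candidates in by_key.items():
        supports = frozenset(
            (t.source_label, t.sample_id) for t in candidates
        )
        n_assemblers = len({a for a, _ in supports})
        n_samples = len({s for _, s in supports})
        if n_assemblers >= min_assemblers or n_samples >= min_samples:
            out.append(
                SupportRecord(
                    key=key,
                    supports=supports,
                    representative=select_representative(candidates),
                )
            )
    out.sort(key=lambda r: (r.key.chrom, r.key.start, r.key.strand, r.key.chain))
    return out


def write_supports_table(records: Sequence[SupportRecord], path: str) -> None:
    """TSV of merged structures: representative id, assemblers, samples."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tchrom\tstart\tend\tstrand\tassemblers\tsamples\n")
        for r in records:
            assemblers = ",".join(sorted({a for a, _ in r.supports}))
            samples = ",".join(sorted({s for _, s in r.supports}))
            fh.write(
                f"{r.representative.transcript_id}\t{r.key.chrom}\t"
                f"{r.key.start}\t{r.key.end}\t{r.key.strand}\t"
                f"{assemblers}\t{samples}\n"
            )
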