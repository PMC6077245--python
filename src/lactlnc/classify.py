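"""lncRNA identification: class codes, ORF scanning, coding potential and
the six-step filter cascade.

The cascade partitions candidate transcripts against a reference annotation
into lncRNAs (with category lincRNA / ilncRNA / lncNAT), novel protein-coding
genes, known genes and rejects, recording for every transcript the first
step at which it failed:

1. class code   — keep only intergenic (u), intronic (i), antisense (x);
                  '=' is a known gene, other overlaps are discarded,
2. structure    — spliced length >= 200 nt and >= 2 exons,
3. expression   — max FPKM across samples >= 0.3,
4. ORF          — longest ORF < 120 amino acids, else novel mRNA,
5. coding potential — excluded if any (configurable: all) scorer calls the
                  transcript coding (score > 0), else novel mRNA,
6. protein domains — excluded on any significant domain hit.
"""

from __future__ import annotations

import logging
import math
import re
import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from lactlnc.genome_io import (
    FeatureTrack,
    GenomicInterval,
    IntervalIndex,
    TranscriptModel,
    iter_exonic_positions,
)

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}

#: class code → lncRNA category
CATEGORY_BY_CODE = {"u": "lincRNA", "i": "ilncRNA", "x": "lncNAT"}

CASCADE_STEPS = (
    "class_code",
    "structure",
    "expression",
    "orf",
    "coding_potential",
    "domain_hit",
)


@dataclass(frozen=True)
class ClassCode:
    """Relationship of a transcript to the reference annotation.

    ``code`` is one of ``=`` (complete intron-chain match), ``i`` (entirely
    within a single reference intron, any strand), ``u`` (no overlap with
    any reference transcript), ``x`` (exonic overlap on the opposite
    strand), or ``o`` (any other overlap, removed downstream).
    """

    code: str
    matched_ref_id: str | None = None

    def __post_init__(self) -> None:
        if self.code not in ("=", "i", "u", "x", "o"):
            raise ValueError(f"unknown class code {self.code!r}")
        if (self.matched_ref_id is None) != (self.code == "u"):
            raise ValueError("matched_ref_id present iff code != 'u'")


@dataclass(frozen=True)
class OrfResult:
    """Longest open reading frame of a spliced sequence.

    ``aa_length`` counts Met through the last residue before the stop codon
    (0 when no ATG-initiated ORF exists); ``start_offset`` is the 0-based
    position of the ATG in the spliced sequence, or None.
    """

    aa_length: int
    frame: int = 0
    start_offset: int | None = None
    has_stop: bool = False


@dataclass(frozen=True)
class KozakMatch:
    offset: int  # position of the GCC[AG]CCATGG match
    has_upstream_gcc: bool


@dataclass(frozen=True)
class FilterDecision:
    """Per-transcript outcome of the filter cascade (the audit trail)."""

    transcript_id: str
    verdict: str  # lncRNA | novel_mRNA | known_gene | rejected
    first_failed_step: str  # one of CASCADE_STEPS or "none"
    category: str  # lincRNA | ilncRNA | lncNAT | not_applicable

    def __post_init__(self) -> None:
        if self.verdict not in ("lncRNA", "novel_mRNA", "known_gene", "rejected"):
            raise ValueError(f"unknown verdict {self.verdict!r}")
        if self.first_failed_step not in CASCADE_STEPS + ("none",):
            raise ValueError(f"unknown step {self.first_failed_step!r}")
        if self.verdict == "lncRNA":
            if self.first_failed_step != "none" or self.category == "not_applicable":
                raise ValueError("lncRNA must pass all steps with a category")
        if self.verdict == "rejected" and self.first_failed_step == "none":
            raise ValueError("rejected decision needs a failing step")


# ---------------------------------------------------------------------------
# class codes
# ---------------------------------------------------------------------------


class ReferenceAnnotation:
    """Reference transcripts prepared for class-code assignment.

    Pre-indexes transcript spans, exons and introns, and the set of intron
    chains for '=' matching.
    """

    def __init__(self, transcripts: Iterable[TranscriptModel]) -> None:
        self.transcripts = list(transcripts)
        self.span_index = IntervalIndex.from_transcripts(self.transcripts)
        self.exon_index = IntervalIndex(
            (e, f"{t.transcript_id}.e{i}", t)
            for t in self.transcripts
            for i, e in enumerate(t.exons)
        )
        self.chains: dict[tuple, list[TranscriptModel]] = {}
        for t in self.transcripts:
            if t.n_exons >= 2:
                key = (t.chrom, t.strand, t.intron_chain)
                self.chains.setdefault(key, []).append(t)


def assign_class_code(t: TranscriptModel, ref: ReferenceAnnotation) -> ClassCode:
    """Assign a class code relative to the reference annotation.

    Precedence is ``=`` > ``i`` > ``x`` > ``o``; ``u`` only when the
    transcript overlaps no reference transcript span at all. A match
    requires complete intron-chain identity on the same strand (single-exon
    transcripts never match). An unstranded transcript cannot be tested for
    antisense overlap and is flagged and returned as ``o`` when it overlaps
    the annotation.
    """
    span_hits = ref.span_index.query(t.span, strand_mode="ignore")
    if not span_hits:
        return ClassCode("u")

    if t.strand == ".":
        logger.warning(
            "transcript %s is unstranded; antisense test impossible",
            t.transcript_id,
        )
        first = min(span_hits, key=lambda h: h[1])
        return ClassCode("o", matched_ref_id=first[1])

    # '=': complete intron-chain identity with a reference transcript
    if t.n_exons >= 2:
        matches = ref.chains.get((t.chrom, t.strand, t.intron_chain), [])
        if matches:
            best = min(matches, key=lambda r: r.transcript_id)
            return ClassCode("=", matched_ref_id=best.transcript_id)

    # 'i': entirely within a single intron of a reference transcript (any strand)
    for _iv, rid, ref_t in sorted(span_hits, key=lambda h: h[1]):
        for intron in ref_t.introns:
            if intron.contains(t.span):
                return ClassCode("i", matched_ref_id=ref_t.transcript_id)

    # 'x': >= 1 bp exonic overlap on the opposite strand
    opposite_hits = []
    for e in t.exons:
        opposite_hits.extend(ref.exon_index.query(e, strand_mode="opposite"))
    if opposite_hits:
        ref_t = min((h[2] for h in opposite_hits), key=lambda r: r.transcript_id)
        return ClassCode("x", matched_ref_id=ref_t.transcript_id)

    first = min(span_hits, key=lambda h: h[1])
    return ClassCode("o", matched_ref_id=first[1])


# ---------------------------------------------------------------------------
# ORF scan
# ---------------------------------------------------------------------------


def longest_orf(spliced_seq: str, require_stop: bool = True) -> OrfResult:
    """Longest ATG-initiated ORF over the three forward frames.

    The scan is sense-strand only (the library protocol is stranded). The
    ORF must terminate at an in-frame stop codon (TAA/TAG/TGA); with
    ``require_stop=False`` an ORF running off the 3' end is also admitted.
    ``aa_length`` includes the Met and excludes the stop. Ties are broken by
    smallest start offset, then smallest frame.
    """
    seq = spliced_seq.upper()
    n = len(seq)
    best = OrfResult(aa_length=0)
    for frame in range(3):
        open_starts: list[int] = []
        pos = frame
        while pos + 3 <= n:
            codon = seq[pos : pos + 3]
            if codon == "ATG":
                open_starts.append(pos)
            elif codon in STOP_CODONS:
                if open_starts:
                    start = open_starts[0]  # earliest start = longest ORF
                    aa = (pos - start) // 3
                    cand = OrfResult(aa, frame, start, True)
                    best = _better_orf(best, cand)
                open_starts = []
            pos += 3
        if not require_stop and open_starts:
            start = open_starts[0]
            aa = (n - start) // 3
            cand = OrfResult(aa, frame, start, False)
            best = _better_orf(best, cand)
    return best


def _better_orf(a: OrfResult, b: OrfResult) -> OrfResult:
    if b.aa_length != a.aa_length:
        return b if b.aa_length > a.aa_length else a
    if a.start_offset is None:
        return b
    if b.start_offset is None:
        return a
    if b.start_offset != a.start_offset:
        return b if b.start_offset < a.start_offset else a
    return b if b.frame < a.frame else a


# ---------------------------------------------------------------------------
# baseline coding-potential scorer
# ---------------------------------------------------------------------------


def train_hexamer_table(
    coding_seqs: Sequence[str],
    noncoding_seqs: Sequence[str],
    pseudocount: float = 1.0,
) -> dict[str, float]:
    """Hexamer log-likelihood-ratio table from training sequences.

    Counts all overlapping hexamers (step 1) in each class and returns, for
    every one of the 4096 ACGT hexamers, log(freq_coding / freq_noncoding)
    with pseudocount smoothing. With identical training sets every entry
    is exactly 0.
    """
    import itertools

    hexamers = ["".join(p) for p in itertools.product("ACGT", repeat=6)]

    def counts(seqs: Sequence[str]) -> dict[str, float]:
        c = dict.fromkeys(hexamers, 0.0)
        for s in seqs:
            s = s.upper()
            for i in range(len(s) - 5):
                h = s[i : i + 6]
                if h in c:
                    c[h] += 1.0
        return c

    cc, nc = counts(coding_seqs), counts(noncoding_seqs)
    tot_c = sum(cc.values()) + pseudocount * 4096
    tot_n = sum(nc.values()) + pseudocount * 4096
    return {
        h: math.log((cc[h] + pseudocount) / tot_c)
        - math.log((nc[h] + pseudocount) / tot_n)
        for h in hexamers
    }


def baseline_coding_score(
    spliced_seq: str, hexamer_table: Mapping[str, float]
) -> float:
    """Mean per-hexamer log-likelihood ratio over the longest-ORF region.

    Positive = coding-like, matching the CPC/PLEK/CNCI sign convention. If
    the sequence has no ORF the whole sequence is scored; sequences shorter
    than one hexamer score 0 with a warning.
    """
    seq = spliced_seq.upper()
    if len(seq) < 6:
        logger.warning("sequence shorter than 6 nt; coding score set to 0")
        return 0.0
    orf = longest_orf(seq, require_stop=False)
    if orf.aa_length > 0 and orf.start_offset is not None:
        region = seq[orf.start_offset : orf.start_offset + 3 * orf.aa_length]
        if len(region) < 6:
            region = seq
    else:
        region = seq
    vals = [
        hexamer_table.get(region[i : i + 6], 0.0)
        for i in range(len(region) - 5)
    ]
    return sum(vals) / len(vals) if vals else 0.0


# ---------------------------------------------------------------------------
# Kozak context
# ---------------------------------------------------------------------------

_KOZAK_RE = re.compile(r"(?=(GCC[AG]CCATGG))")


def kozak_scan(spliced_seq: str) -> list[KozakMatch]:
    """Find Kozak translation-initiation contexts GCC[AG]CCATGG.

    Each match also reports whether the optional additional upstream GCC is
    present immediately 5' of the core pattern.
    """
    seq = spliced_seq.upper().replace("U", "T")
    out = []
    for m in _KOZAK_RE.finditer(seq):
        off = m.start()
        out.append(
            KozakMatch(offset=off, has_upstream_gcc=seq[max(0, off - 3) : off] == "GCC")
        )
    return out


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------


def conservation_score(t: TranscriptModel, track: FeatureTrack) -> float | None:
    """Median per-base conservation over the transcript's exonic bases.

    Bases without a score are excluded; returns None when no exonic base is
    scored.
    """
    vals = []
    for pos in iter_exonic_positions(t):
        v = track.base_score(t.chrom, pos)
        if v is not None:
            vals.append(v)
    if not vals:
        return None
    return float(statistics.median(vals))


# ---------------------------------------------------------------------------
# the cascade
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CascadeParams:
    """Tunable thresholds of the identification cascade."""

    min_length: int = 200
    min_exons: int = 2
    min_fpkm: float = 0.3
    max_orf_aa: int = 120  # ORFs of >= this many AAs fail (strict "< 120")
    coding_combine: str = "any"  # "any": excluded if any scorer > 0; or "all"
    domain_evalue: float = 1e-5
    expression_stat: str = "max"  # or "mean" across samples

    def __post_init__(self) -> None:
        if self.coding_combine not in ("any", "all"):
            raise ValueError("coding_combine must be 'any' or 'all'")
        if self.expression_stat not in ("max", "mean"):
            raise ValueError("expression_stat must be 'max' or 'mean'")


def apply_filter_cascade(
    transcripts: Sequence[TranscriptModel],
    class_codes: Mapping[str, ClassCode],
    fpkm: Mapping[str, Sequence[float]],
    orf_lengths: Mapping[str, int],
    coding_scores: Mapping[str, Mapping[str, float]],
    domain_hits: Mapping[str, Sequence[tuple[str, float]]] | None = None,
    params: CascadeParams = CascadeParams(),
) -> list[FilterDecision]:
    """Run the six-step cascade and return one decision per transcript.

    ``fpkm`` maps transcript id → per-sample FPKM values; ``orf_lengths``
    maps transcript id → longest-ORF amino-acid length (from
    :func:`longest_orf` on the spliced sequence). Missing FPKM for a
    transcript that reaches the expression step is an error naming the
    transcript.
    """
    domain_hits = domain_hits or {}
    decisions = []
    for t in transcripts:
        tid = t.transcript_id
        code = class_codes[tid]

        if code.code == "=":
            decisions.append(FilterDecision(tid, "known_gene", "none", "not_applicable"))
            continue
        if code.code == "o":
            decisions.append(
                FilterDecision(tid, "rejected", "class_code", "not_applicable")
            )
            continue
        category = CATEGORY_BY_CODE[code.code]

        if t.length < params.min_length or t.n_exons < params.min_exons:
            decisions.append(
                FilterDecision(tid, "rejected", "structure", "not_applicable")
            )
            continue

        try:
            values = fpkm[tid]
        except KeyError as exc:
            raise KeyError(f"transcript {tid!r} missing from FPKM matrix") from exc
        stat = max(values) if params.expression_stat == "max" else (
            sum(values) / len(values)
        )
        if stat < params.min_fpkm:
            decisions.append(
                FilterDecision(tid, "rejected", "expression", "not_applicable")
            )
            continue

        if orf_lengths[tid] >= params.max_orf_aa:
            decisions.append(
                FilterDecision(tid, "novel_mRNA", "orf", "not_applicable")
            )
            continue

        score_vals = list(coding_scores.get(tid, {}).values())
        if score_vals:
            calls = [v > 0 for v in score_vals]
            coding = any(calls) if params.coding_combine == "any" else all(calls)
        else:
            coding = False
        if coding:
            decisions.append(
                FilterDecision(tid, "novel_mRNA", "coding_potential", "not_applicable")
            )
            continue

        hits = domain_hits.get(tid, [])
        if any(ev <= params.domain_evalue for _dom, ev in hits):
            decisions.append(
                FilterDecision(tid, "rejected", "domain_hit", "not_applicable")
            )
            continue

        decisions.append(FilterDecision(tid, "lncRNA", "none", category))
    return decisions


def write_decisions(decisions: Sequence[FilterDecision], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tverdict\tfirst_failed_step\tcategory\n")
        for d in decisions:
            fh.write(
                f"{d.transcript_id}\t{d.verdict}\t{d.first_failed_step}\t"
                f"{d.category}\n"
            )
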