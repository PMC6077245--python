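"""Seeded synthetic miniature datasets with planted truth.

Generates, from a single integer seed, everything the pipeline consumes:
a random genome with multi-exon protein-coding genes, planted noncoding
transcripts of each category (intergenic, intronic, antisense), noisy
per-assembler per-sample transcript sets, a 3-vs-3 negative-binomial count
matrix with planted fold changes and group-exclusive features, QTL/SNP
conservation tracks, coding-potential score tables, and miRNA hairpins
planted verbatim inside lncRNAs. Every planted label and effect is recorded
in a :class:`SyntheticTruth` so recovery can be scored exactly.

The default miniature scale (2 chromosomes x 500 kb, 40 coding genes,
~30 planted noncoding features, 4 assemblers x 6 samples) runs the full
pipeline in seconds on one CPU while exercising every code path.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from lactlnc.classify import longest_orf
from lactlnc.expression import ExpressionMatrix
from lactlnc.genome_io import FeatureTrack, GenomicInterval, TranscriptModel

ASSEMBLERS = ("cufflinks", "scripture", "stringtie", "transcomb")
SAMPLES = ("S1", "S2", "S3", "S4", "S5", "S6")
#: 3 high vs 3 low milk-protein-percentage samples
GROUPS = {"S1": "HP", "S2": "HP", "S3": "HP", "S4": "LP", "S5": "LP", "S6": "LP"}

STOPS = ("TAA", "TAG", "TGA")


def _load_table(name: str) -> list[tuple[str, float]]:
    path = importlib.resources.files("lactlnc.data") / name
    rows = []
    with path.open() as fh:
        fh.readline()
        for line in fh:
            k, v = line.split("\t")
            rows.append((k, float(v)))
    return rows


def codon_usage() -> tuple[list[str], np.ndarray]:
    """Sense-codon usage weights for synthetic coding sequence (GC-biased
    third positions, shipped as a fixture table)."""
    rows = _load_table("codon_usage.tsv")
    codons = [c for c, _ in rows]
    w = np.array([v for _, v in rows])
    return codons, w / w.sum()


def noncoding_background() -> tuple[list[str], np.ndarray]:
    """AT-rich background nucleotide composition for noncoding sequence."""
    rows = _load_table("noncoding_background.tsv")
    bases = [b for b, _ in rows]
    f = np.array([v for _, v in rows])
    return bases, f / f.sum()


def sample_coding_sequence(rng: np.random.Generator, n_codons: int) -> str:
    """An ATG-initiated, stop-terminated coding sequence of ``n_codons``
    amino acids drawn from the codon-usage fixture."""
    codons, p = codon_usage()
    body = rng.choice(codons, size=n_codons - 1, p=p)
    stop = STOPS[rng.integers(len(STOPS))]
    return "ATG" + "".join(body) + stop


def sample_noncoding_sequence(rng: np.random.Generator, length: int) -> str:
    bases, p = noncoding_background()
    return "".join(rng.choice(bases, size=length, p=p))


def default_hexamer_table(seed: int = 0, n: int = 50) -> dict[str, float]:
    """Hexamer log-ratio table trained on fixture-distribution sequences."""
    from lactlnc.classify import train_hexamer_table

    rng = np.random.default_rng(seed)
    coding = [sample_coding_sequence(rng, 200) for _ in range(n)]
    noncoding = [sample_noncoding_sequence(rng, 600) for _ in range(n)]
    return train_hexamer_table(coding, noncoding)


# ---------------------------------------------------------------------------
# truth bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTruth:
    """Planted labels and effects, recorded before any noise is applied."""

    labels: dict[str, str] = field(default_factory=dict)
    #: feature id -> planted log2(LP/HP) effect (0 for nulls)
    de_effects: dict[str, float] = field(default_factory=dict)
    #: feature id -> "hp_only" | "lp_only"
    exclusive: dict[str, str] = field(default_factory=dict)
    #: ids of run-specific artifact transcripts
    artifact_ids: set[str] = field(default_factory=set)
    #: (lnc_id, mirna_id, spliced offset)
    precursors: list[tuple[str, str, int]] = field(default_factory=list)
    hairpins: dict[str, str] = field(default_factory=dict)
    qtl_features: set[str] = field(default_factory=set)
    snp_features: set[str] = field(default_factory=set)
    function_genes: set[str] = field(default_factory=set)
    #: intended DE lncRNA -> partner gene assignments
    partner_pairs: list[tuple[str, str]] = field(default_factory=list)

    def ids_with_label(self, *labels: str) -> set[str]:
        return {tid for tid, lab in self.labels.items() if lab in labels}


# ---------------------------------------------------------------------------
# reference genome + annotation
# ---------------------------------------------------------------------------


def _write_seq(genome: dict[str, list[str]], t: TranscriptModel, spliced: str) -> None:
    """Write a spliced sequence into genome exon positions (strand-aware)."""
    from Bio.Seq import Seq

    plus = spliced if t.strand != "-" else str(Seq(spliced).reverse_complement())
    i = 0
    chrom = genome[t.chrom]
    for e in t.exons:
        chrom[e.start : e.end] = plus[i : i + len(e)]
        i += len(e)


def generate_reference(
    seed: int,
    n_genes: int = 40,
    n_chroms: int = 2,
    chrom_length: int = 500_000,
) -> tuple[dict[str, str], list[TranscriptModel]]:
    """Random genome plus multi-exon protein-coding gene annotation.

    Genes are non-overlapping, separated by 8-12 kb intergenic gaps, with
    3-5 exons (180-400 bp) and 1.5-2.5 kb introns; every gene's spliced
    sequence embeds an ORF of at least 120 amino acids. Deterministic per
    seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes >= 1 required")
    rng = np.random.default_rng(seed)
    bases, bg = noncoding_background()
    genome: dict[str, list[str]] = {
        f"chr{c + 1}": list(rng.choice(bases, size=chrom_length, p=bg))
        for c in range(n_chroms)
    }
    chroms = list(genome)
    per_chrom = [n_genes // n_chroms] * n_chroms
    for i in range(n_genes % n_chroms):
        per_chrom[i] += 1

    transcripts = []
    g = 0
    for chrom, n_here in zip(chroms, per_chrom):
        cursor = 3_000
        for _ in range(n_here):
            cursor += int(rng.integers(8_000, 12_000))
            n_exons = int(rng.integers(3, 6))
            exon_lens = rng.integers(180, 401, size=n_exons)
            intron_lens = rng.integers(1_500, 2_501, size=n_exons - 1)
            strand = "+" if rng.random() < 0.5 else "-"
            exons, pos = [], cursor
            for k in range(n_exons):
                exons.append(
                    GenomicInterval(chrom, pos, pos + int(exon_lens[k]), strand)
                )
                pos += int(exon_lens[k])
                if k < n_exons - 1:
                    pos += int(intron_lens[k])
            if pos + 3_000 > chrom_length:
                raise ValueError(
                    f"chromosome too short for {n_here} genes of this size"
                )
            cursor = pos
            gid = f"GENE{g:04d}"
            t = TranscriptModel(
                transcript_id=f"{gid}.t1",
                gene_id=gid,
                exons=tuple(exons),
                source_label="reference",
            )
            total = t.length
            utr5 = 12
            n_codons = (total - utr5 - 3) // 3 - 2  # leave a short 3' UTR
            cds = sample_coding_sequence(rng, n_codons)
            tail = sample_noncoding_sequence(rng, total - utr5 - len(cds))
            spliced = sample_noncoding_sequence(rng, utr5) + cds + tail
            _write_seq(genome, t, spliced)
            transcripts.append(t)
            g += 1
    return {c: "".join(s) for c, s in genome.items()}, transcripts


# ---------------------------------------------------------------------------
# planted noncoding (and novel coding) transcripts
# ---------------------------------------------------------------------------


def _intergenic_gaps(
    reference: Sequence[TranscriptModel], genome: Mapping[str, str], margin: int
) -> list[tuple[str, int, int]]:
    gaps = []
    for chrom in sorted({t.chrom for t in reference} | set(genome)):
        spans = sorted(
            (t.start, t.end) for t in reference if t.chrom == chrom
        )
        prev = 0
        for s, e in spans:
            if s - prev >= 2 * margin:
                gaps.append((chrom, prev + margin, s - margin))
            prev = max(prev, e)
        end = len(genome[chrom])
        if end - prev >= 2 * margin:
            gaps.append((chrom, prev + margin, end - margin))
    return gaps


def _noncoding_fill(
    rng: np.random.Generator, t: TranscriptModel, genome: dict[str, list[str]],
    max_orf_aa: int = 100, tries: int = 30,
) -> None:
    """Write noncoding-composition sequence into a planted transcript's
    exons, resampling until no ORF reaches ``max_orf_aa`` amino acids."""
    for _ in range(tries):
        spliced = sample_noncoding_sequence(rng, t.length)
        if longest_orf(spliced).aa_length < max_orf_aa:
            _write_seq(genome, t, spliced)
            return
    raise RuntimeError("could not draw an ORF-free noncoding sequence")


def plant_noncoding(
    seed: int,
    genome: Mapping[str, str],
    reference: Sequence[TranscriptModel],
    n_linc: int = 12,
    n_ilnc: int = 6,
    n_nat: int = 6,
    n_novel_mrna: int = 4,
    n_hairpins: int = 3,
    min_gap: int = 2_000,
) -> tuple[dict[str, str], list[TranscriptModel], SyntheticTruth]:
    """Plant lncRNAs of each category plus novel coding transcripts.

    lincRNAs sit at least ``min_gap`` from any gene; ilncRNAs lie strictly
    inside single reference introns; lncNATs overlap reference exons
    antisense; novel mRNAs are intergenic with a >= 125 AA ORF. Hairpin
    sequences are inserted verbatim into the first ``n_hairpins`` planted
    plus-strand lincRNAs and recorded with their spliced offsets.
    """
    rng = np.random.default_rng(seed)
    mutable = {c: list(s) for c, s in genome.items()}
    truth = SyntheticTruth()
    for t in reference:
        truth.labels[t.transcript_id] = "known_mRNA"
    planted: list[TranscriptModel] = []

    # --- intergenic placements (lincRNA + novel mRNA share the gap pool)
    gaps = _intergenic_gaps(reference, genome, min_gap)
    rng.shuffle(gaps)
    need = n_linc + n_novel_mrna
    slots = []
    for chrom, lo, hi in gaps:
        width = hi - lo
        n_fit = width // 6_000  # one slot per 6 kb of clear space
        for k in range(n_fit):
            slots.append((chrom, lo + k * 6_000, lo + (k + 1) * 6_000))
    if len(slots) < need:
        raise ValueError("insufficient intergenic space for requested features")
    rng.shuffle(slots)

    def build_multi_exon(chrom, lo, hi, n_exons, exon_rng, intron_rng, strand):
        exon_lens = rng.integers(*exon_rng, size=n_exons)
        intron_lens = rng.integers(*intron_rng, size=n_exons - 1)
        span = int(exon_lens.sum() + intron_lens.sum())
        start = int(lo + rng.integers(0, max(1, hi - lo - span)))
        exons, pos = [], start
        for k in range(n_exons):
            exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[k]), strand))
            pos += int(exon_lens[k])
            if k < n_exons - 1:
                pos += int(intron_lens[k])
        return exons

    linc_ids = []
    for i in range(n_linc):
        chrom, lo, hi = slots[i]
        # first few lincRNAs are forced to '+' so hairpins can be planted
        strand = "+" if i < n_hairpins else ("+" if rng.random() < 0.5 else "-")
        exons = build_multi_exon(
            chrom, lo, hi, int(rng.integers(2, 4)), (150, 301), (300, 801), strand
        )
        tid = f"LINC{i:04d}"
        t = TranscriptModel(tid, tid, tuple(exons), source_label="planted")
        _noncoding_fill(rng, t, mutable)
        truth.labels[tid] = "lincRNA"
        planted.append(t)
        linc_ids.append(tid)

    for i in range(n_novel_mrna):
        chrom, lo, hi = slots[n_linc + i]
        strand = "+" if rng.random() < 0.5 else "-"
        exons = build_multi_exon(
            chrom, lo, hi, int(rng.integers(2, 4)), (250, 401), (300, 801), strand
        )
        tid = f"NOVM{i:04d}"
        t = TranscriptModel(tid, tid, tuple(exons), source_label="planted")
        n_codons = max(125, (t.length - 9) // 3 - 4)
        if (t.length - 9) // 3 - 4 < 125:  # widen exons if too short
            exons = build_multi_exon(chrom, lo, hi, 2, (350, 401), (300, 501), strand)
            t = TranscriptModel(tid, tid, tuple(exons), source_label="planted")
            n_codons = (t.length - 9) // 3 - 4
        cds = sample_coding_sequence(rng, n_codons)
        spliced = sample_noncoding_sequence(rng, 6) + cds
        spliced += sample_noncoding_sequence(rng, t.length - len(spliced))
        _write_seq(mutable, t, spliced)
        truth.labels[tid] = "novel_mRNA"
        planted.append(t)

    # --- intronic lncRNAs
    hosts = [
        (t, i) for t in reference for i, intron in enumerate(t.introns)
        if len(intron) >= 600
    ]
    rng.shuffle(hosts)
    used_introns: set[tuple[str, int]] = set()
    made = 0
    for host, intron_idx in hosts:
        if made >= n_ilnc:
            break
        key = (host.transcript_id, intron_idx)
        if key in used_introns:
            continue
        intron = host.introns[intron_idx]
        e1, gap_len, e2 = 130, 120, 130
        span = e1 + gap_len + e2
        if len(intron) < span + 40:
            continue
        start = intron.start + 20 + int(
            rng.integers(0, len(intron) - span - 40 + 1)
        )
        strand = "+" if rng.random() < 0.5 else "-"
        exons = (
            GenomicInterval(intron.chrom, start, start + e1, strand),
            GenomicInterval(
                intron.chrom, start + e1 + gap_len, start + span, strand
            ),
        )
        tid = f"ILNC{made:04d}"
        t = TranscriptModel(tid, tid, exons, source_label="planted")
        _noncoding_fill(rng, t, mutable)
        truth.labels[tid] = "ilncRNA"
        planted.append(t)
        used_introns.add(key)
        made += 1
    if made < n_ilnc:
        raise ValueError("not enough host introns for requested ilncRNAs")

    # --- antisense lncRNAs (genome left untouched: their exons overlap
    #     reference exons, whose sequence must stay intact)
    genes = list(reference)
    rng.shuffle(genes)
    made = 0
    final_genome = {c: "".join(s) for c, s in mutable.items()}
    occupied = [t.span for t in planted]
    for host in genes:
        if made >= n_nat:
            break
        anti = "-" if host.strand == "+" else "+"
        target_exon = host.exons[0] if host.strand == "+" else host.exons[-1]
        overlap = min(120, len(target_exon) - 10)
        if host.strand == "+":
            e1 = GenomicInterval(
                host.chrom, target_exon.start - 160, target_exon.start + overlap, anti
            )
            e2 = GenomicInterval(host.chrom, e1.start - 400, e1.start - 400 + 140, anti)
            exons = (e2, e1)
        else:
            e1 = GenomicInterval(
                host.chrom, target_exon.end - overlap, target_exon.end + 160, anti
            )
            e2 = GenomicInterval(host.chrom, e1.end + 260, e1.end + 260 + 140, anti)
            exons = (e1, e2)
        if exons[0].start < 0:
            continue
        if any(exons[0].overlaps(s) or exons[1].overlaps(s) for s in occupied):
            continue
        tid = f"LNAT{made:04d}"
        t = TranscriptModel(tid, tid, exons, source_label="planted")
        from lactlnc.genome_io import extract_spliced_sequence

        if longest_orf(extract_spliced_sequence(t, final_genome)).aa_length >= 100:
            continue
        truth.labels[tid] = "lncNAT"
        planted.append(t)
        occupied.append(t.span)
        made += 1
    if made < n_nat:
        raise ValueError("could not place requested lncNATs")

    # --- plant hairpins inside plus-strand lincRNAs
    for h in range(n_hairpins):
        tid = linc_ids[h]
        t = next(p for p in planted if p.transcript_id == tid)
        hp = sample_noncoding_sequence(rng, 70)
        mirna_id = f"syn-mir-{h + 1:03d}"
        exon1 = t.exons[0]
        off = int(rng.integers(5, len(exon1) - 75))
        mutable[t.chrom][exon1.start + off : exon1.start + off + 70] = hp
        truth.hairpins[mirna_id] = hp
        truth.precursors.append((tid, mirna_id, off))

    out_genome = {c: "".join(s) for c, s in mutable.items()}
    planted.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
    return out_genome, planted, truth


# ---------------------------------------------------------------------------
# assembler-run simulation
# ---------------------------------------------------------------------------


def simulate_assembler_runs(
    seed: int,
    transcripts: Sequence[TranscriptModel],
    truth: SyntheticTruth | None = None,
    n_assemblers: int = 4,
    n_samples: int = 6,
    detect_prob: float = 1.0,
    jitter_sd: float = 0.0,
    artifact_rate: float = 0.0,
) -> dict[tuple[str, str], list[TranscriptModel]]:
    """Per-(assembler, sample) transcript sets with detection noise.

    Each run detects each true transcript independently with probability
    ``detect_prob``; detected copies jitter their terminal boundaries
    (never internal splice sites) by a rounded normal(0, jitter_sd); each
    run adds single-exon artifact fragments at ``artifact_rate`` per true
    transcript, labelled ``artifact`` in the truth.
    """
    if not (0 <= detect_prob <= 1):
        raise ValueError("detect_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    runs: dict[tuple[str, str], list[TranscriptModel]] = {}
    chrom_lens: dict[str, int] = {}
    for t in transcripts:
        chrom_lens[t.chrom] = max(chrom_lens.get(t.chrom, 0), t.end + 10_000)
    for a in ASSEMBLERS[:n_assemblers]:
        for s in SAMPLES[:n_samples]:
            out = []
            for i, t in enumerate(transcripts):
                if rng.random() >= detect_prob:
                    continue
                exons = [list((e.start, e.end)) for e in t.exons]
                if jitter_sd > 0:
                    exons[0][0] = max(
                        0, exons[0][0] + int(round(rng.normal(0, jitter_sd)))
                    )
                    exons[-1][1] += int(round(rng.normal(0, jitter_sd)))
                    if exons[0][0] >= exons[0][1]:
                        exons[0][0] = exons[0][1] - 1
                    if exons[-1][1] <= exons[-1][0]:
                        exons[-1][1] = exons[-1][0] + 1
                out.append(
                    TranscriptModel(
                        transcript_id=f"{a}_{s}_{i:05d}",
                        gene_id=f"{a}_{s}_g{i:05d}",
                        exons=tuple(
                            GenomicInterval(t.chrom, st, en, t.strand)
                            for st, en in exons
                        ),
                        source_label=a,
                        sample_id=s,
                    )
                )
            n_art = rng.poisson(artifact_rate * len(transcripts))
            for k in range(n_art):
                chrom = sorted(chrom_lens)[int(rng.integers(len(chrom_lens)))]
                length = int(rng.integers(80, 301))
                start = int(rng.integers(0, chrom_lens[chrom] - length))
                tid = f"{a}_{s}_art{k:04d}"
                out.append(
                    TranscriptModel(
                        transcript_id=tid,
                        gene_id=tid,
                        exons=(
                            GenomicInterval(
                                chrom, start, start + length,
                                "+" if rng.random() < 0.5 else "-",
                            ),
                        ),
                        source_label=a,
                        sample_id=s,
                    )
                )
                if truth is not None:
                    truth.artifact_ids.add(tid)
            runs[(a, s)] = out
    return runs


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def simulate_counts(
    seed: int,
    lengths: Mapping[str, int],
    baseline_mean: float = 100.0,
    dispersion: float = 0.1,
    log2fc: Mapping[str, float] | None = None,
    exclusive: Mapping[str, str] | None = None,
    noise: str = "nb",
    library_size: float = 1_000_000,
    truth: SyntheticTruth | None = None,
) -> ExpressionMatrix:
    """3-vs-3 count matrix with planted effects.

    Group means differ by the planted log2(LP/HP) effects, split
    symmetrically around a per-feature baseline; exclusive features have
    structural zeros in the named group. ``noise="nb"`` draws negative
    binomial counts (``dispersion=0`` gives the Poisson limit);
    ``noise="none"`` emits the expected counts exactly (the pipeline's
    noise-free mode, where recovery is deterministic).
    """
    if noise not in ("nb", "none"):
        raise ValueError("noise must be 'nb' or 'none'")
    rng = np.random.default_rng(seed)
    log2fc = dict(log2fc or {})
    exclusive = dict(exclusive or {})
    features = list(lengths)
    if noise == "none":
        libs = np.full(6, float(library_size))
        base = np.full(len(features), baseline_mean)
    else:
        libs = library_size * rng.uniform(0.9, 1.1, size=6)
        base = np.exp(rng.normal(math.log(baseline_mean), 0.4, size=len(features)))

    data = np.zeros((len(features), 6))
    for i, f in enumerate(features):
        lfc = log2fc.get(f, 0.0)
        mu_hp = base[i] * 2 ** (-lfc / 2)
        mu_lp = base[i] * 2 ** (lfc / 2)
        if exclusive.get(f) == "hp_only":
            mu_lp = 0.0
        elif exclusive.get(f) == "lp_only":
            mu_hp = 0.0
        for j in range(6):
            mu = (mu_hp if j < 3 else mu_lp) * libs[j] / library_size
            if mu == 0:
                continue
            if noise == "none":
                data[i, j] = round(mu)
            elif dispersion == 0:
                data[i, j] = rng.poisson(mu)
            else:
                r = 1.0 / dispersion
                data[i, j] = rng.negative_binomial(r, r / (r + mu))
        if truth is not None:
            truth.de_effects[f] = lfc
            if f in exclusive:
                truth.exclusive[f] = exclusive[f]

    counts = pd.DataFrame(data, index=features, columns=list(SAMPLES))
    return ExpressionMatrix(
        counts,
        pd.Series(libs, index=list(SAMPLES)),
        pd.Series(GROUPS),
    )


# ---------------------------------------------------------------------------
# tracks, scores, function list
# ---------------------------------------------------------------------------


def simulate_tracks(
    seed: int,
    reference: Sequence[TranscriptModel],
    planted: Sequence[TranscriptModel],
    truth: SyntheticTruth,
    coverage_fraction: float = 1.0,
    conservation_bases_per_feature: int = 60,
) -> dict[str, FeatureTrack]:
    """QTL/SNP/conservation tracks tied to the planted partner pairs.

    A ``coverage_fraction`` of the features appearing in
    ``truth.partner_pairs`` receives a covering QTL interval and a nearby
    SNP (recorded in the truth); the conservation track scores a sample of
    exonic bases, higher over coding exons than over planted lncRNAs.
    """
    rng = np.random.default_rng(seed)
    by_id = {t.transcript_id: t for t in list(reference) + list(planted)}
    gene_of = {t.gene_id: t for t in reference}

    pair_features: list[str] = []
    for lnc, gene in truth.partner_pairs:
        pair_features.extend([lnc, gene])
    seen = set()
    pair_features = [f for f in pair_features if not (f in seen or seen.add(f))]
    n_cov = int(round(coverage_fraction * len(pair_features)))
    covered = pair_features[:n_cov]

    qtl_records, snp_records = [], []
    for k, fid in enumerate(covered):
        t = by_id.get(fid) or gene_of[fid]
        span = t.span
        qtl_records.append(
            (
                GenomicInterval(span.chrom, max(0, span.start - 1_000), span.end + 1_000),
                f"QTL{k:03d}",
                {"trait": "milk_protein_pct"},
            )
        )
        mid = (span.start + span.end) // 2
        snp_records.append(
            (
                GenomicInterval(span.chrom, mid, mid + 1),
                f"SNP{k:03d}",
                {"trait": "milk_protein_pct"},
            )
        )
        truth.qtl_features.add(fid)
        truth.snp_features.add(fid)

    cons_records = []
    i = 0
    for t in list(reference) + list(planted):
        coding = truth.labels.get(t.transcript_id) in ("known_mRNA", "novel_mRNA")
        lo, hi = (0.55, 0.95) if coding else (0.05, 0.35)
        e = t.exons[0]
        n_b = min(conservation_bases_per_feature, len(e))
        for pos in range(e.start, e.start + n_b):
            cons_records.append(
                (
                    GenomicInterval(t.chrom, pos, pos + 1),
                    f"c{i}",
                    {"score": float(rng.uniform(lo, hi))},
                )
            )
            i += 1

    return {
        "qtl": FeatureTrack(qtl_records, kind="qtl"),
        "snp": FeatureTrack(snp_records, kind="snp"),
        "conservation": FeatureTrack(cons_records, kind="conservation"),
    }


def simulate_score_tables(
    seed: int,
    truth: SyntheticTruth,
    scorers: Sequence[str] = ("CPC", "PLEK", "CNCI"),
) -> dict[str, dict[str, float]]:
    """External-scorer stand-in tables consistent with the planted labels:
    coding-labelled transcripts score positive, noncoding negative."""
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, float]] = {}
    for tid, label in sorted(truth.labels.items()):
        coding = label in ("known_mRNA", "novel_mRNA")
        out[tid] = {
            s: float(rng.uniform(0.2, 2.0) if coding else rng.uniform(-2.0, -0.2))
            for s in scorers
        }
    return out


def simulate_domain_hits(
    truth: SyntheticTruth,
) -> dict[str, list[tuple[str, float]]]:
    """Domain-hit table: every coding-labelled transcript hits one domain."""
    return {
        tid: [("PF00001", 1e-10)]
        for tid, label in sorted(truth.labels.items())
        if label in ("known_mRNA", "novel_mRNA")
    }


# ---------------------------------------------------------------------------
# whole-study orchestration
# ---------------------------------------------------------------------------


@dataclass
class SyntheticStudy:
    """A complete miniature dataset bundle."""

    genome: dict[str, str]
    reference: list[TranscriptModel]
    planted: list[TranscriptModel]
    truth: SyntheticTruth
    runs: dict[tuple[str, str], list[TranscriptModel]]
    counts: ExpressionMatrix
    lengths: dict[str, int]
    tracks: dict[str, FeatureTrack]
    score_tables: dict[str, dict[str, float]]
    domain_hits: dict[str, list[tuple[str, float]]]

    @property
    def all_transcripts(self) -> list[TranscriptModel]:
        return self.reference + self.planted


def simulate_study(
    seed: int,
    n_genes: int = 40,
    n_chroms: int = 2,
    chrom_length: int = 500_000,
    n_linc: int = 12,
    n_ilnc: int = 6,
    n_nat: int = 6,
    n_novel_mrna: int = 4,
    n_de_pairs: int = 6,
    de_log2fc: float = 3.0,
    n_exclusive: int = 2,
    detect_prob: float = 1.0,
    jitter_sd: float = 0.0,
    artifact_rate: float = 0.0,
    noise: str = "none",
    dispersion: float = 0.05,
    coverage_fraction: float = 1.0,
) -> SyntheticStudy:
    """Generate the full study: reference, planted features, assembler
    runs, counts with planted DE pairs, and integration tracks.

    ``n_de_pairs`` planted lncRNAs are made differentially expressed with
    effect ±``de_log2fc`` together with their nearest reference gene (the
    partner); ``n_exclusive`` of the DE lncRNAs are made group-exclusive
    instead. The partner genes form the milk-protein function list.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=5)
    genome, reference = generate_reference(
        int(sub[0]), n_genes=n_genes, n_chroms=n_chroms, chrom_length=chrom_length
    )
    genome, planted, truth = plant_noncoding(
        int(sub[1]), genome, reference,
        n_linc=n_linc, n_ilnc=n_ilnc, n_nat=n_nat, n_novel_mrna=n_novel_mrna,
    )

    # choose DE lncRNAs (lincRNAs, which always have a nearby gene within
    # 100 kb at this scale) and their nearest reference gene as partner
    lincs = [t for t in planted if truth.labels[t.transcript_id] == "lincRNA"]
    lincs = [t for t in lincs if t.transcript_id not in
             {p[0] for p in truth.precursors}]
    de_lncs = lincs[:n_de_pairs]
    log2fc: dict[str, float] = {}
    exclusive: dict[str, str] = {}
    used_genes: set[str] = set()
    for k, lnc in enumerate(de_lncs):
        candidates = sorted(
            (t for t in reference
             if t.chrom == lnc.chrom and t.gene_id not in used_genes),
            key=lambda t: (abs((t.start + t.end) // 2 - (lnc.start + lnc.end) // 2)),
        )
        partner = candidates[0]
        used_genes.add(partner.gene_id)
        sign = 1.0 if k % 2 == 0 else -1.0
        if k < n_exclusive:
            exclusive[lnc.transcript_id] = "lp_only" if sign > 0 else "hp_only"
            log2fc[lnc.transcript_id] = 0.0
        else:
            log2fc[lnc.transcript_id] = sign * de_log2fc
        log2fc[partner.transcript_id] = sign * de_log2fc
        truth.partner_pairs.append((lnc.transcript_id, partner.gene_id))
        truth.function_genes.add(partner.gene_id)

    lengths = {t.transcript_id: t.length for t in reference + planted}
    counts = simulate_counts(
        int(sub[2]), lengths,
        dispersion=dispersion, log2fc=log2fc, exclusive=exclusive,
        noise=noise, truth=truth,
    )
    runs = simulate_assembler_runs(
        int(sub[3]), reference + planted, truth,
        detect_prob=detect_prob, jitter_sd=jitter_sd, artifact_rate=artifact_rate,
    )
    tracks = simulate_tracks(
        int(sub[4]), reference, planted, truth,
        coverage_fraction=coverage_fraction,
    )
    score_tables = simulate_score_tables(int(sub[4]) + 1, truth)
    domain_hits = simulate_domain_hits(truth)
    return SyntheticStudy(
        genome=genome,
        reference=reference,
        planted=planted,
        truth=truth,
        runs=runs,
        counts=counts,
        lengths=lengths,
        tracks=tracks,
        score_tables=score_tables,
        domain_hits=domain_hits,
    )


def write_study(study: SyntheticStudy, outdir: str) -> None:
    """Write every pipeline input of a study as plain-text files, plus a
    truth table, under ``outdir``."""
    import os

    from lactlnc.genome_io import (
        write_domain_hits,
        write_feature_track,
        write_gtf,
        write_score_table,
        write_sequences,
    )

    os.makedirs(outdir, exist_ok=True)
    write_sequences(study.genome, f"{outdir}/genome.fa")
    write_gtf(study.reference, f"{outdir}/reference.gtf")
    # all quantified transcript models (ids match the count matrix rows)
    write_gtf(study.all_transcripts, f"{outdir}/models.gtf")
    run_dir = f"{outdir}/runs"
    os.makedirs(run_dir, exist_ok=True)
    with open(f"{outdir}/runs_manifest.tsv", "w") as fh:
        fh.write("assembler\tsample\tpath\n")
        for (a, s), txs in sorted(study.runs.items()):
            path = f"{run_dir}/{a}_{s}.gtf"
            write_gtf(txs, path)
            fh.write(f"{a}\t{s}\t{path}\n")
    study.counts.values.round(0).astype(int).to_csv(
        f"{outdir}/counts.tsv", sep="\t", index_label="feature_id"
    )
    with open(f"{outdir}/samples.tsv", "w") as fh:
        fh.write("sample\tgroup\tlibrary_size\n")
        for s in study.counts.samples:
            fh.write(
                f"{s}\t{study.counts.groups[s]}\t"
                f"{study.counts.library_sizes[s]:.0f}\n"
            )
    write_feature_track(study.tracks["qtl"], f"{outdir}/qtl.tsv")
    write_feature_track(study.tracks["snp"], f"{outdir}/snps.tsv")
    write_feature_track(study.tracks["conservation"], f"{outdir}/conservation.tsv")
    write_score_table(study.score_tables, f"{outdir}/scores.tsv")
    write_domain_hits(study.domain_hits, f"{outdir}/domains.tsv")
    write_sequences(study.truth.hairpins, f"{outdir}/hairpins.fa")
    with open(f"{outdir}/functions.txt", "w") as fh:
        for g in sorted(study.truth.function_genes):
            fh.write(g + "\n")
    with open(f"{outdir}/truth.tsv", "w") as fh:
        fh.write("feature_id\tlabel\tlog2fc\texclusive\n")
        for tid in sorted(study.truth.labels):
            fh.write(
                f"{tid}\t{study.truth.labels[tid]}\t"
                f"{study.truth.de_effects.get(tid, 0)}\t"
                f"{study.truth.exclusive.get(tid, '')}\n"
            )


def expected_candidate_pairs(study: SyntheticStudy) -> set[tuple[str, str]]:
    """Brute-force enumeration of the candidate pairs the planted truth
    implies, computed directly from geometry, planted DE labels and plain
    Pearson correlation — independent of the pipeline modules.
    """
    from scipy import stats as _st

    truth = study.truth
    de_lnc = {
        f for f in truth.de_effects
        if truth.labels.get(f) in ("lincRNA", "ilncRNA", "lncNAT")
        and (truth.de_effects[f] != 0 or f in truth.exclusive)
    }
    gene_span: dict[str, tuple[str, int, int]] = {}
    gene_tx: dict[str, str] = {}
    for t in study.reference:
        gene_span[t.gene_id] = (t.chrom, t.start, t.end)
        gene_tx[t.gene_id] = t.transcript_id
    de_gene = {
        g for g, tx in gene_tx.items()
        if truth.de_effects.get(tx, 0) != 0 or tx in truth.exclusive
    }
    spans = {t.transcript_id: t for t in study.planted}

    # FPKM by direct formula, log2(x+1)
    counts = study.counts
    fpkm = {}
    for f in counts.features:
        row = counts.values.loc[f].to_numpy()
        fpkm[f] = np.log2(
            row * 1e9 / (study.lengths[f] * counts.library_sizes.to_numpy()) + 1
        )

    flagged = truth.qtl_features | truth.snp_features
    pairs = set()
    for lnc_id in sorted(de_lnc):
        lnc = spans[lnc_id]
        for gid in sorted(de_gene & truth.function_genes):
            chrom, gs, ge = gene_span[gid]
            cis = False
            if chrom == lnc.chrom:
                gap = 0 if (gs < lnc.end and lnc.start < ge) else (
                    lnc.start - ge if ge <= lnc.start else gs - lnc.end
                )
                cis = gap <= 100_000
            x, y = fpkm[lnc_id], fpkm[gene_tx[gid]]
            trans = False
            if x.std() > 0 and y.std() > 0:
                r, p = _st.pearsonr(x, y)
                trans = p < 0.05
            if not (cis or trans):
                continue
            if not ({lnc_id, gid} & flagged):
                continue
            pairs.add((lnc_id, gid))
    return pairs
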