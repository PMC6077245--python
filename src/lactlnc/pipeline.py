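"""End-to-end orchestration: merge → classify → DE → targets → integrate.

Runs the whole discovery pipeline over an in-memory
:class:`~lactlnc.synthetic.SyntheticStudy` (or equivalently assembled real
inputs). Merged structures are re-identified against the known transcript
models by their intron chain — internal splice boundaries are never
jittered by the run simulator, so the chain is the stable identity that
links a merged structure back to the feature quantified in the count
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

from lactlnc.classify import (
    CascadeParams,
    ClassCode,
    FilterDecision,
    ReferenceAnnotation,
    apply_filter_cascade,
    assign_class_code,
    longest_orf,
)
from lactlnc.consensus import SupportRecord, stringent_merge
from lactlnc.expression import DEResult, ExpressionMatrix, call_de, compute_fpkm
from lactlnc.genome_io import TranscriptModel, extract_spliced_sequence
from lactlnc.integrate import (
    CandidatePair,
    build_candidate_pairs,
    export_network,
    positional_flags,
)
from lactlnc.targets import (
    PrecursorHit,
    TargetEdge,
    cis_neighbors,
    gene_spans,
    precursor_match,
    trans_edges,
)
from lactlnc.synthetic import SyntheticStudy


@dataclass
class PipelineResult:
    """Everything the pipeline produces, stage by stage."""

    support_records: list[SupportRecord]
    merged: list[TranscriptModel]
    class_codes: dict[str, ClassCode]
    decisions: list[FilterDecision]
    lnc_transcripts: list[TranscriptModel]
    de_results: list[DEResult]
    edges: list[TargetEdge]
    precursor_hits: list[PrecursorHit]
    candidate_pairs: list[CandidatePair]

    @property
    def lnc_ids(self) -> set[str]:
        return {t.transcript_id for t in self.lnc_transcripts}

    def verdict_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for d in self.decisions:
            out[d.verdict] = out.get(d.verdict, 0) + 1
        return out


def identify_merged(
    transcripts: Sequence[TranscriptModel],
    known: Sequence[TranscriptModel],
) -> list[TranscriptModel]:
    """Map merged structures back to known transcript models.

    A merged structure whose (chrom, strand, intron chain) matches a known
    multi-exon model adopts that model's identity and geometry (the
    annotation-guided step); unmatched structures are kept as-is.
    """
    chain_map = {
        (t.chrom, t.strand, t.intron_chain): t
        for t in known
        if t.n_exons >= 2
    }
    out = []
    for rep in transcripts:
        match = chain_map.get((rep.chrom, rep.strand, rep.intron_chain))
        if match is not None:
            out.append(replace(match, attributes=rep.attributes))
        else:
            out.append(rep)
    return out


def run_pipeline(
    study: SyntheticStudy,
    cascade_params: CascadeParams | None = None,
    min_assemblers: int = 2,
    min_samples: int = 2,
    alpha: float = 0.05,
    trans_alpha: float = 0.05,
    snp_window: int = 5_000,
    cis_windows: Sequence[int] = (10_000, 100_000),
) -> PipelineResult:
    """Full pipeline over a synthetic study.

    ``snp_window`` defaults to 5 kb, scaled to the miniature genome (the
    integrate module's own default of 1 Mb is sized for a full mammalian
    chromosome).
    """
    cascade_params = cascade_params or CascadeParams()

    # 1. consensus merge of all assembler x sample runs
    runs = [(a, s, txs) for (a, s), txs in sorted(study.runs.items())]
    records = stringent_merge(
        runs, min_assemblers=min_assemblers, min_samples=min_samples
    )
    merged = identify_merged(
        [r.representative for r in records], study.all_transcripts
    )
    # boundary-jittered duplicates of one model collapse to a single feature
    seen: set[str] = set()
    merged = [
        t for t in merged
        if not (t.transcript_id in seen or seen.add(t.transcript_id))
    ]

    # 2. class codes + filter cascade
    ref_ann = ReferenceAnnotation(study.reference)
    class_codes = {
        t.transcript_id: assign_class_code(t, ref_ann) for t in merged
    }
    fpkm_matrix = compute_fpkm(study.counts, study.lengths)
    fpkm_rows = {
        f: fpkm_matrix.values.loc[f].tolist()
        for f in fpkm_matrix.features
    }
    orf_lengths = {
        t.transcript_id: longest_orf(
            extract_spliced_sequence(t, study.genome)
        ).aa_length
        for t in merged
    }
    decisions = apply_filter_cascade(
        merged,
        class_codes,
        fpkm_rows,
        orf_lengths,
        study.score_tables,
        study.domain_hits,
        cascade_params,
    )
    by_id = {t.transcript_id: t for t in merged}
    lnc_transcripts = [
        by_id[d.transcript_id] for d in decisions if d.verdict == "lncRNA"
    ]

    # 3. differential expression: genes at gene level, lncRNAs per transcript
    gene_rows, gene_lengths = {}, {}
    for t in study.reference:
        gene_rows.setdefault(t.gene_id, 0)
        gene_rows[t.gene_id] = (
            gene_rows[t.gene_id] + study.counts.values.loc[t.transcript_id]
        )
        gene_lengths[t.gene_id] = gene_lengths.get(t.gene_id, 0) + t.length
    lnc_ids = [t.transcript_id for t in lnc_transcripts]
    de_index = list(gene_rows) + lnc_ids
    de_values = pd.DataFrame(
        [gene_rows[g] for g in gene_rows]
        + [study.counts.values.loc[f] for f in lnc_ids],
        index=de_index,
    )
    de_counts = ExpressionMatrix(
        de_values, study.counts.library_sizes, study.counts.groups
    )
    de_lengths = dict(gene_lengths)
    de_lengths.update({f: study.lengths[f] for f in lnc_ids})
    de_results = call_de(de_counts, de_lengths, alpha=alpha)

    # 4. targets
    edges = cis_neighbors(lnc_transcripts, study.reference, cis_windows)
    de_fpkm = compute_fpkm(de_counts, de_lengths).values
    if lnc_ids:
        edges += trans_edges(
            de_fpkm.loc[lnc_ids], de_fpkm.loc[list(gene_rows)], alpha=trans_alpha
        )
    lnc_seqs = {
        t.transcript_id: extract_spliced_sequence(t, study.genome)
        for t in lnc_transcripts
    }
    precursor_hits = precursor_match(lnc_seqs, study.truth.hairpins)

    # 5. integration
    feature_spans = {t.transcript_id: t.span for t in lnc_transcripts}
    feature_spans.update(gene_spans(study.reference))
    flags = positional_flags(
        feature_spans, study.tracks["qtl"], study.tracks["snp"], snp_window
    )
    pairs = build_candidate_pairs(
        de_results, edges, flags, study.truth.function_genes
    )

    return PipelineResult(
        support_records=records,
        merged=merged,
        class_codes=class_codes,
        decisions=decisions,
        lnc_transcripts=lnc_transcripts,
        de_results=de_results,
        edges=edges,
        precursor_hits=precursor_hits,
        candidate_pairs=pairs,
    )


def write_results(result: PipelineResult, outdir: str) -> None:
    """Write the pipeline's tabular outputs under ``outdir``."""
    import os

    from lactlnc.classify import write_decisions
    from lactlnc.consensus import write_supports_table
    from lactlnc.expression import write_de_table
    from lactlnc.genome_io import write_gtf
    from lactlnc.integrate import write_candidates, write_network
    from lactlnc.targets import write_edges, write_precursor_hits

    os.makedirs(outdir, exist_ok=True)
    write_supports_table(result.support_records, f"{outdir}/supports.tsv")
    write_gtf(result.lnc_transcripts, f"{outdir}/lncrna.gtf")
    write_decisions(result.decisions, f"{outdir}/decisions.tsv")
    write_de_table(result.de_results, f"{outdir}/de.tsv")
    write_edges(result.edges, f"{outdir}/edges.tsv")
    write_precursor_hits(result.precursor_hits, f"{outdir}/precursors.tsv")
    write_candidates(result.candidate_pairs, f"{outdir}/candidates.tsv")
    nodes, net_edges = export_network(result.candidate_pairs)
    write_network(nodes, net_edges, f"{outdir}/nodes.tsv", f"{outdir}/network.sif")
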