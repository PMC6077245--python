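"""Positional integration of DE lncRNAs with QTL/GWAS tracks into candidate
lncRNA–mRNA pairs and an exportable network.

A pair (lncRNA, gene) is a candidate iff: both are differentially
expressed, they are linked by a cis or trans target edge, the gene is on
the supplied milk-protein function list, and at least one of the four
positional flags holds (lncRNA or gene overlapping a QTL interval, or
within the SNP window of a trait-associated SNP).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from lactlnc.expression import DEResult
from lactlnc.genome_io import FeatureTrack, GenomicInterval, IntervalIndex
from lactlnc.targets import TargetEdge

EVIDENCE_FLAGS = (
    "lnc_de",
    "gene_de",
    "cis",
    "trans",
    "lnc_qtl",
    "gene_qtl",
    "lnc_snp",
    "gene_snp",
    "function_hit",
)


@dataclass(frozen=True)
class PositionalFlags:
    qtl: bool = False
    snp: bool = False


@dataclass(frozen=True)
class CandidatePair:
    """A candidate regulatory lncRNA–gene pair with its evidence flags."""

    lnc_id: str
    gene_id: str
    evidence: tuple[str, ...]
    same_direction: bool | None  # None when a direction is undefined

    def __post_init__(self) -> None:
        unknown = set(self.evidence) - set(EVIDENCE_FLAGS)
        if unknown:
            raise ValueError(f"unknown evidence flags {unknown}")
        required = {"lnc_de", "gene_de", "function_hit"}
        if not required.issubset(self.evidence):
            raise ValueError("candidate lacks required DE/function evidence")
        if not ({"cis", "trans"} & set(self.evidence)):
            raise ValueError("candidate needs a cis or trans edge")
        if not (
            {"lnc_qtl", "gene_qtl", "lnc_snp", "gene_snp"} & set(self.evidence)
        ):
            raise ValueError("candidate needs a positional flag")


def positional_flags(
    features: Mapping[str, GenomicInterval],
    qtl: FeatureTrack,
    snps: FeatureTrack,
    snp_window: int = 1_000_000,
) -> dict[str, PositionalFlags]:
    """QTL/SNP flags per feature span.

    The QTL flag is set when the span intersects any QTL interval; the SNP
    flag when any SNP lies within ``snp_window`` bp of the span.
    """
    qtl_index = IntervalIndex.from_track(qtl)
    snp_index = IntervalIndex.from_track(snps)
    out = {}
    for fid, span in features.items():
        has_qtl = bool(qtl_index.query(span))
        has_snp = bool(snp_index.query_window(span, snp_window))
        out[fid] = PositionalFlags(qtl=has_qtl, snp=has_snp)
    return out


def build_candidate_pairs(
    de_results: Iterable[DEResult],
    target_edges: Iterable[TargetEdge],
    flags: Mapping[str, PositionalFlags],
    function_genes: set[str],
) -> list[CandidatePair]:
    """Assemble candidate pairs from DE calls, target edges, positional
    flags and the function gene list.

    Concordance (``same_direction``) compares DE directions; a feature
    whose direction is undefined yields ``same_direction=None``. Feature
    ids in ``de_results`` must cover both lncRNAs and genes referenced by
    the edges; edges to features without DE results are skipped.
    """
    de = {r.feature_id: r for r in de_results}
    modes: dict[tuple[str, str], set[str]] = {}
    for e in target_edges:
        key = (e.lnc_id, e.gene_id)
        modes.setdefault(key, set()).add(
            "cis" if e.mode.startswith("cis") else "trans"
        )

    pairs = []
    for (lnc_id, gene_id), edge_modes in sorted(modes.items()):
        lnc = de.get(lnc_id)
        gene = de.get(gene_id)
        if lnc is None or gene is None:
            continue
        if not (lnc.significant and gene.significant):
            continue
        if gene_id not in function_genes:
            continue
        lnc_flags = flags.get(lnc_id, PositionalFlags())
        gene_flags = flags.get(gene_id, PositionalFlags())
        positional = []
        if lnc_flags.qtl:
            positional.append("lnc_qtl")
        if gene_flags.qtl:
            positional.append("gene_qtl")
        if lnc_flags.snp:
            positional.append("lnc_snp")
        if gene_flags.snp:
            positional.append("gene_snp")
        if not positional:
            continue
        evidence = (
            ["lnc_de", "gene_de"]
            + sorted(edge_modes)
            + positional
            + ["function_hit"]
        )
        if lnc.direction == "na" or gene.direction == "na":
            same = None
        else:
            same = lnc.direction == gene.direction
        pairs.append(
            CandidatePair(lnc_id, gene_id, tuple(evidence), same)
        )
    return pairs


def count_direction_pairs(
    pairs: Iterable[CandidatePair],
) -> tuple[int, int]:
    """(same-direction count, inverse count) over pairs with defined
    concordance."""
    same = inverse = 0
    for p in pairs:
        if p.same_direction is True:
            same += 1
        elif p.same_direction is False:
            inverse += 1
    return same, inverse


def export_network(
    pairs: Sequence[CandidatePair],
    pathway_annotations: Mapping[str, Sequence[str]] | None = None,
) -> tuple[list[tuple[str, str]], list[tuple[str, str, str]]]:
    """Node and edge tables for the candidate lncRNA–mRNA–pathway network.

    Returns (nodes, edges): nodes are (id, type) with type in
    {lncRNA, mRNA, pathway}; edges are (source, target, relation) with
    relation "targets" (lncRNA → mRNA) or "member_of" (mRNA → pathway).
    Pathway annotations for genes not present in any pair are ignored with
    a warning. Ordering is deterministic.
    """
    import logging

    logger = logging.getLogger(__name__)
    pathway_annotations = pathway_annotations or {}
    genes = sorted({p.gene_id for p in pairs})
    lncs = sorted({p.lnc_id for p in pairs})
    for gid in pathway_annotations:
        if gid not in genes:
            logger.warning("pathway annotation for %s dangles (ignored)", gid)
    pathways = sorted(
        {pw for gid in genes for pw in pathway_annotations.get(gid, [])}
    )
    nodes = (
        [(x, "lncRNA") for x in lncs]
        + [(x, "mRNA") for x in genes]
        + [(x, "pathway") for x in pathways]
    )
    edges = [
        (p.lnc_id, p.gene_id, "targets")
        for p in sorted(pairs, key=lambda p: (p.lnc_id, p.gene_id))
    ]
    for gid in genes:
        for pw in sorted(pathway_annotations.get(gid, [])):
            edges.append((gid, pw, "member_of"))
    return nodes, edges


def write_network(
    nodes: Sequence[tuple[str, str]],
    edges: Sequence[tuple[str, str, str]],
    node_path: str,
    sif_path: str,
) -> None:
    """SIF-style edge list plus node-attribute TSV."""
    with open(node_path, "w") as fh:
        fh.write("id\ttype\n")
        for nid, ntype in nodes:
            fh.write(f"{nid}\t{ntype}\n")
    with open(sif_path, "w") as fh:
        for src, dst, rel in edges:
            fh.write(f"{src}\t{rel}\t{dst}\n")


def write_candidates(pairs: Sequence[CandidatePair], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("lnc_id\tgene_id\tevidence\tsame_direction\n")
        for p in pairs:
            same = "" if p.same_direction is None else str(int(p.same_direction))
            fh.write(
                f"{p.lnc_id}\t{p.gene_id}\t{','.join(p.evidence)}\t{same}\n"
            )
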