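"""Bundled reference datasets.

The package ships the differential-expression result tables for lncRNAs in
Holstein mammary tissue (3 high- vs 3 low-milk-protein-percentage cows):
one table of group-exclusive lncRNAs (expressed in only one group, so no
fold change is printed) and one of lncRNAs expressed in both groups with
their log2(LP/HP) fold changes. They serve as worked-example input and as
a fixed ground truth for the fold-change and bookkeeping arithmetic.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from lactlnc.genome_io import GenomicInterval


def _read(name: str) -> pd.DataFrame:
    path = importlib.resources.files("lactlnc.data") / name
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_exclusive_de_lncrnas() -> pd.DataFrame:
    """DE lncRNAs expressed in only one phenotype group.

    Columns: lncRNA_gene, lncRNA_transcript, position, hp_fpkm, lp_fpkm,
    p_value, q_value. A zero in one FPKM column marks the group the
    feature is absent from.
    """
    return _read("holstein_de_lncrna_exclusive.tsv")


def load_shared_de_lncrnas() -> pd.DataFrame:
    """DE lncRNAs expressed in both groups, with log2(LP/HP) fold change."""
    return _read("holstein_de_lncrna_shared.tsv")


def parse_position(position: str) -> GenomicInterval:
    """Parse a "chrom:start-end" locus (1-based inclusive) into the internal
    0-based half-open convention."""
    chrom, rest = position.rsplit(":", 1)
    start, end = rest.split("-")
    return GenomicInterval(chrom, int(start) - 1, int(end))


def de_lncrna_summary() -> dict[str, int]:
    """Bookkeeping over the bundled DE tables: exclusive counts per group
    and the total number of distinct DE lncRNA genes."""
    excl = load_exclusive_de_lncrnas()
    shared = load_shared_de_lncrnas()
    hp_only = int(((excl.hp_fpkm > 0) & (excl.lp_fpkm == 0)).sum())
    lp_only = int(((excl.hp_fpkm == 0) & (excl.lp_fpkm > 0)).sum())
    genes = set(excl.lncRNA_gene) | set(shared.lncRNA_gene)
    return {
        "hp_exclusive": hp_only,
        "lp_exclusive": lp_only,
        "shared": int(shared.shape[0]),
        "distinct_de_genes": len(genes),
    }
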