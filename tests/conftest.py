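"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results from first principles with
plain loops so they stay independent of the implementation paths they
check (interval index, class-code precedence, ORF scanner, BH step-up).
"""

from __future__ import annotations

import numpy as np
import pytest

from lactlnc.genome_io import GenomicInterval, TranscriptModel
from lactlnc.synthetic import simulate_study

STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# random-instance generators
# ---------------------------------------------------------------------------


def random_transcript(
    rng: np.random.Generator,
    tid: str,
    chrom: str = "chr1",
    region: int = 20_000,
    max_exons: int = 4,
    strand: str | None = None,
) -> TranscriptModel:
    n_exons = int(rng.integers(1, max_exons + 1))
    pos = int(rng.integers(0, region))
    exons = []
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    for _ in range(n_exons):
        length = int(rng.integers(50, 400))
        exons.append(GenomicInterval(chrom, pos, pos + length, strand))
        pos += length + int(rng.integers(50, 800))
    return TranscriptModel(tid, f"g_{tid}", tuple(exons))


def random_annotation(
    rng: np.random.Generator, n: int, region: int = 20_000
) -> list[TranscriptModel]:
    return [
        random_transcript(rng, f"ref{i:04d}", region=region, max_exons=5)
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def brute_force_class_code(
    t: TranscriptModel, refs: list[TranscriptModel]
) -> str:
    """Class code straight from the definitions, by exhaustive loops."""
    overlapping = [
        r
        for r in refs
        if r.chrom == t.chrom and r.start < t.end and t.start < r.end
    ]
    if not overlapping:
        return "u"
    if t.strand == ".":
        return "o"
    if t.n_exons >= 2:
        for r in refs:
            if (
                r.chrom == t.chrom
                and r.strand == t.strand
                and r.n_exons >= 2
                and r.intron_chain == t.intron_chain
            ):
                return "="
    for r in overlapping:
        for intron in r.introns:
            if intron.start <= t.start and t.end <= intron.end:
                return "i"
    for r in overlapping:
        if {r.strand, t.strand} == {"+", "-"}:
            for e in t.exons:
                for re_ in r.exons:
                    if e.start < re_.end and re_.start < e.end:
                        return "x"
    return "o"


def brute_force_orf(seq: str, require_stop: bool = True):
    """Exhaustive all-start, all-frame ORF scan.

    Returns (aa_length, frame, start_offset) with the same tie-breaks as
    the scanner: longest, then smallest start, then smallest frame.
    """
    seq = seq.upper()
    n = len(seq)
    best = (0, 0, None)
    candidates = []
    for frame in range(3):
        for s in range(frame, n - 2, 3):
            if seq[s : s + 3] != "ATG":
                continue
            found = False
            for e in range(s + 3, n - 2, 3):
                if seq[e : e + 3] in STOPS:
                    candidates.append(((e - s) // 3, s, frame))
                    found = True
                    break
            if not found and not require_stop:
                candidates.append(((n - s) // 3, s, frame))
    if not candidates:
        return best
    aa, s, f = max(candidates, key=lambda c: (c[0], -c[1], -c[2]))
    return (aa, f, s)


def brute_force_overlaps(records, query: GenomicInterval, strand_mode: str):
    """Linear scan over (interval, id, payload) records."""
    out = []
    for iv, rid, payload in records:
        if iv.chrom != query.chrom:
            continue
        if not (iv.start < query.end and query.start < iv.end):
            continue
        if strand_mode == "same" and iv.strand != query.strand:
            continue
        if strand_mode == "opposite" and {iv.strand, query.strand} != {"+", "-"}:
            continue
        out.append((iv, rid, payload))
    return sorted(out, key=lambda h: (h[0].start, h[0].end, h[1]))


def bh_step_up(p):
    """Reference BH step-up, computed rank by rank from the back."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def study():
    """One noise-free miniature study shared across tests."""
    return simulate_study(7)


@pytest.fixture(scope="session")
def noisy_study():
    """A study with detection noise, terminal jitter and artifacts."""
    return simulate_study(
        11, noise="nb", dispersion=0.05, detect_prob=0.9, jitter_sd=3.0,
        artifact_rate=0.2,
    )
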