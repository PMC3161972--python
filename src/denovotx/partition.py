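"""Tiered read assignment: map, remove mapped, continue to the next tier.

Reproduces the iterative mapping strategy used to trace where reads come
from: reads are mapped against an ordered cascade of references (own
contigs, the sister species' contigs, organelle genomes, a model-legume
genome, ...); after each tier the mapped reads are removed and the rest
carry on, so each read is attributed to the first tier it maps to.

Mapping is an exhaustive ungapped scan on both strands with a mismatch
budget (mirroring ``bowtie -v 3`` semantics, but exact rather than
seed-heuristic — correct at desk scale). N in the reference never matches,
and N in a read counts as a mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import Contig, reverse_complement


@dataclass(frozen=True)
class ReferenceTier:
    name: str
    sequences: tuple[Contig, ...]
    order_index: int


@dataclass
class PartitionReport:
    tiers: list[tuple[str, int, float]]  # (name, n_mapped, percent of input)
    n_unmapped: int
    n_input: int


def make_tiers(named: Sequence[tuple[str, Sequence[Contig]]]) -> list[ReferenceTier]:
    if not named:
        raise ValueError("at least one tier required")
    return [ReferenceTier(name, tuple(seqs), i) for i, (name, seqs) in enumerate(named)]


def _encode(seq: str, sentinel: int) -> np.ndarray:
    # N (and any non-ACGT) encodes to a sentinel that never equals a base;
    # reads and references use different sentinels so N never matches N
    table = np.full(256, sentinel, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        table[ord(b)] = i
    return table[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


def naive_map(read: str, refs: Iterable[Contig], max_mm: int = 3) -> bool:
    """True iff some ungapped placement of the read (either strand) on any
    reference has at most ``max_mm`` mismatches."""
    if not read:
        raise ValueError("empty read")
    queries = [_encode(read, 254), _encode(reverse_complement(read), 254)]
    m = len(read)
    for ref in refs:
        if len(ref) < m:
            continue
        enc_ref = _encode(ref.seq, 255)
        windows = np.lib.stride_tricks.sliding_window_view(enc_ref, m)
        for q in queries:
            # read N (255) never equals a reference base; ref N never equals a read base
            mm = (windows != q).sum(axis=1)
            if mm.min() <= max_mm:
                return True
    return False


def partition(
    reads: Sequence[str],
    tiers: Sequence[ReferenceTier],
    max_mm: int = 3,
) -> tuple[PartitionReport, list[str]]:
    """Assign each read to the first tier it maps to; returns the report and
    the reads left unmapped after the last tier."""
    if not tiers:
        raise ValueError("at least one tier required")
    n_input = len(reads)
    remaining = list(reads)
    rows: list[tuple[str, int, float]] = []
    for tier in tiers:
        still_unmapped = []
        mapped = 0
        for read in remaining:
            if naive_map(read, tier.sequences, max_mm):
                mapped += 1
            else:
                still_unmapped.append(read)
        pct = 100.0 * mapped / n_input if n_input else 0.0
        rows.append((tier.name, mapped, pct))
        remaining = still_unmapped
    return PartitionReport(rows, n_unmapped=len(remaining), n_input=n_input), remaining


def rrna_prefilter(
    reads: Sequence[str], rrna_refs: Sequence[Contig], max_mm: int = 3
) -> tuple[list[str], int]:
    """Remove reads mapping to ribosomal RNA references; returns (kept
    reads, removed count)."""
    if not reads:
        return [], 0
    report, kept = partition(reads, make_tiers([("rRNA", rrna_refs)]), max_mm)
    return kept, report.tiers[0][1]
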