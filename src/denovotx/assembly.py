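"""Assembly summary statistics and gap-run analysis.

Computes the usual short-read de novo transcriptome QC panel — contig
counts, total size, longest contig, N50, mean length, pooled GC%, and an
estimated sequencing coverage — together with per-contig N-gap runs, the
footprint scaffolding leaves in low-coverage regions.

Coverage is estimated as total read length divided by total assembly size.
Published tables are ambiguous about whether a read pair contributes one or
two read lengths to the numerator, so both counting dialects are exposed
(``coverage_counting={'pairs','reads'}``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .core import Contig, round_half_up


@dataclass
class AssemblySummary:
    n_contigs: int
    total_bp: int
    longest_bp: int
    n50_bp: int
    mean_bp: float
    gc_percent: float
    est_coverage_fold: float | None
    gap_runs: int
    # per-contig total gapped bp, over contigs that have any gap
    gap_total_range: tuple[int, int] | None
    rows: list[tuple[str, str]] = field(default_factory=list)


def n50(lengths: Sequence[int]) -> int:
    """N50: smallest length L such that contigs >= L hold half the assembly.

    Computed as the length at which the cumulative sum over lengths sorted
    descending first reaches >= total/2 (exact halves, no flooring).
    """
    if not lengths:
        raise ValueError("n50 of an empty length list is undefined")
    if any(x <= 0 for x in lengths):
        raise ValueError("contig lengths must be positive")
    half = sum(lengths) / 2
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")


def gc_percent(contigs: Iterable[Contig | str]) -> float:
    """Pooled GC% over all contigs; N is excluded from both numerator and
    denominator."""
    gc = acgt = 0
    for c in contigs:
        seq = c.seq if isinstance(c, Contig) else c.upper()
        gc += seq.count("G") + seq.count("C")
        acgt += sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("no non-N bases present; GC% undefined")
    return 100.0 * gc / acgt


def estimated_coverage(
    n_read_pairs: int,
    read_len: int,
    total_assembly_bp: int,
    counting: str = "pairs",
) -> float:
    """Estimated fold coverage: total read length / total assembly size.

    ``counting='pairs'`` charges each pair one read length (the dialect that
    reproduces typical published values); ``'reads'`` charges both mates.
    Reported to one decimal, half-up.
    """
    if n_read_pairs <= 0 or read_len <= 0:
        raise ValueError("read counts and read length must be positive")
    if total_assembly_bp <= 0:
        raise ValueError("assembly size must be positive")
    if counting not in ("pairs", "reads"):
        raise ValueError(f"unknown counting dialect {counting!r}")
    factor = 1 if counting == "pairs" else 2
    return round_half_up(factor * n_read_pairs * read_len / total_assembly_bp, 1)


def gap_runs(contig: Contig | str) -> list[tuple[int, int, int]]:
    """Maximal runs of N as (start 1-based, end inclusive, length)."""
    seq = contig.seq if isinstance(contig, Contig) else contig.upper()
    runs: list[tuple[int, int, int]] = []
    start = None
    for i, base in enumerate(seq):
        if base == "N":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start + 1, i, i - start))
            start = None
    if start is not None:
        runs.append((start + 1, len(seq), len(seq) - start))
    return runs


def filter_min_length(
    contigs: Sequence[Contig], min_len: int = 200
) -> tuple[list[Contig], int]:
    """Keep contigs of length >= min_len (order preserved); also return the
    kept total bp. The default mirrors the common >= 200 bp reference rule."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = [c for c in contigs if len(c) >= min_len]
    return kept, sum(len(c) for c in kept)


def summarize(
    contigs: Sequence[Contig],
    n_read_pairs: int | None = None,
    read_len: int = 51,
    coverage_counting: str = "pairs",
) -> AssemblySummary:
    """Full assembly QC panel over a contig set."""
    if not contigs:
        raise ValueError("cannot summarize an empty assembly")
    lengths = [len(c) for c in contigs]
    total = sum(lengths)
    cov = (
        estimated_coverage(n_read_pairs, read_len, total, coverage_counting)
        if n_read_pairs
        else None
    )
    all_runs = [gap_runs(c) for c in contigs]
    per_contig_gap_bp = [sum(r[2] for r in runs) for runs in all_runs if runs]
    summary = AssemblySummary(
        n_contigs=len(contigs),
        total_bp=total,
        longest_bp=max(lengths),
        n50_bp=n50(lengths),
        mean_bp=round_half_up(total / len(lengths)),
        gc_percent=round_half_up(gc_percent(contigs)),
        est_coverage_fold=cov,
        gap_runs=sum(len(r) for r in all_runs),
        gap_total_range=(min(per_contig_gap_bp), max(per_contig_gap_bp))
        if per_contig_gap_bp
        else None,
    )
    summary.rows = _table_rows(summary, n_read_pairs)
    return summary


def _table_rows(s: AssemblySummary, n_read_pairs: int | None) -> list[tuple[str, str]]:
    rows = []
    if n_read_pairs:
        rows.append(("Filtered reads (paired-ends)", f"{n_read_pairs:,}"))
        rows.append(("Filtered reads (single-ends)", f"{2 * n_read_pairs:,}"))
    rows += [
        ("Total assembled size (bp)", f"{s.total_bp:,}"),
        ("Number of contigs and scaffolds", f"{s.n_contigs:,}"),
        ("Longest contig (bp)", f"{s.longest_bp:,}"),
        ("N50 (bp)", f"{s.n50_bp:,}"),
        ("Average length (bp)", f"{s.mean_bp:,.0f}"),
        ("GC content (%)", f"{s.gc_percent:.0f}"),
    ]
    if s.est_coverage_fold is not None:
        rows.append(("Estimated coverage", f"{s.est_coverage_fold} x"))
    return rows
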