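"""SNP discovery from consensus pileup text: score cut, six-rule filter
cascade, substitution classes, and density summaries.

Input is the classic samtools consensus-pileup dialect: ten tab-separated
columns per reference position (name, 1-based position, reference base,
consensus base, consensus quality, SNP quality, RMS mapping quality, read
depth, encoded read bases, base qualities).

Putative variant columns (at least one non-reference read, SNP quality
>= 20) pass through six filters applied in a fixed order:

1. mapping and SNP quality both > 100,
2. depth >= 10 reads,
3. >= 3 reads carrying a non-reference allele,
4. bi-allelic (at most two well-supported alleles),
5. minor allele frequency >= 5%,
6. major + minor allele together >= 95% of reads.

Every failed rule id is recorded, so a call is auditable; pass/fail is
order-independent. Passing biallelic calls are classed as transitions
(purine-purine or pyrimidine-pyrimidine) or transversions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, TextIO

from .core import as_lines, round_half_up

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


@dataclass
class PileupColumn:
    ref_name: str
    pos: int  # 1-based
    ref_base: str
    consensus_base: str
    consensus_qual: int
    snp_qual: int
    rms_map_qual: int
    depth: int
    read_bases: str
    base_quals: str
    allele_counts: Counter = field(default_factory=Counter)

    @property
    def alt_reads(self) -> int:
        """Reads carrying any non-reference allele."""
        return sum(n for b, n in self.allele_counts.items() if b != self.ref_base)


@dataclass
class SnpFilterConfig:
    min_snp_score_initial: int = 20
    min_scores: int = 100
    min_depth: int = 10
    min_alt_reads: int = 3
    require_biallelic: bool = True
    min_maf: float = 0.05
    min_major_minor: float = 0.95
    score_mode: str = "both"  # 'both': map AND snp quality; 'sum': their sum
    strict_biallelic: bool = False  # count every observed allele in rule 4

    def __post_init__(self) -> None:
        if self.min_maf > 0.5 or self.min_maf < 0:
            raise ValueError("min_maf must be in [0, 0.5]")
        if self.score_mode not in ("both", "sum"):
            raise ValueError("score_mode must be 'both' or 'sum'")


@dataclass
class SnpCall:
    ref_name: str
    pos: int
    ref_allele: str
    alt_allele: str | None
    depth: int
    allele_counts: dict
    maf: float
    snp_qual: int
    rms_map_qual: int
    passed: bool
    failed_criteria: list[int]
    subst_class: str | None  # 'transition' | 'transversion'; pass calls only


@dataclass
class SnpSummary:
    n_putative: int
    n_filtered: int
    n_ts: int
    n_tv: int
    total_ref_bp: int | None
    freq_bp_per_snp: int | None  # None when no SNPs ('n/a' in reports)


# ---------------------------------------------------------------------------
# parsing


def decode_read_bases(read_bases: str, ref_base: str) -> Counter:
    """Decode a pileup base string into per-allele read counts.

    '.'/',' are reference-matching reads; ACGT (either case) are explicit
    alleles; '^' (+ mapping quality char) and '$' are read start/end
    markers; '+N<seq>'/'-N<seq>' indel records are skipped with their
    bases; '*' deletion placeholders consume a read without an allele.
    """
    counts: Counter = Counter()
    ref = ref_base.upper()
    i, n = 0, len(read_bases)
    while i < n:
        ch = read_bases[i]
        if ch == "^":
            i += 2
            continue
        if ch == "$":
            i += 1
            continue
        if ch in "+-":
            i += 1
            num = ""
            while i < n and read_bases[i].isdigit():
                num += read_bases[i]
                i += 1
            if not num:
                raise ValueError("malformed indel record in read bases")
            i += int(num)
            continue
        if ch in ".,":
            counts[ref] += 1
        elif ch.upper() in "ACGTN":
            counts[ch.upper()] += 1
        elif ch == "*":
            counts["*"] += 1
        else:
            raise ValueError(f"unexpected pileup character {ch!r}")
        i += 1
    return counts


def parse_pileup(source: str | TextIO | Iterable[str]) -> Iterator[PileupColumn]:
    """Parse 10-column consensus pileup text into :class:`PileupColumn`s.

    Raises ``ValueError`` with the line number on malformed lines, including
    a decoded read count that disagrees with the depth field.
    """
    for lineno, line in enumerate(as_lines(source), start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 10:
            raise ValueError(f"line {lineno}: expected 10 columns, got {len(fields)}")
        try:
            col = PileupColumn(
                ref_name=fields[0],
                pos=int(fields[1]),
                ref_base=fields[2].upper(),
                consensus_base=fields[3].upper(),
                consensus_qual=int(fields[4]),
                snp_qual=int(fields[5]),
                rms_map_qual=int(fields[6]),
                depth=int(fields[7]),
                read_bases=fields[8],
                base_quals=fields[9],
            )
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from None
        counts = decode_read_bases(col.read_bases, col.ref_base)
        if sum(counts.values()) != col.depth:
            raise ValueError(
                f"line {lineno}: decoded {sum(counts.values())} reads but depth "
                f"field says {col.depth}"
            )
        counts.pop("*", None)
        col.allele_counts = counts
        yield col


# ---------------------------------------------------------------------------
# filtering


def initial_score_cut(
    columns: Iterable[PileupColumn], min_snp_score_initial: int = 20
) -> Iterator[PileupColumn]:
    """Putative-SNP cut: at least one non-reference read and SNP quality not
    below the initial threshold."""
    for col in columns:
        if col.alt_reads >= 1 and col.snp_qual >= min_snp_score_initial:
            yield col


def _ranked_alleles(counts: Counter) -> list[tuple[str, int]]:
    # most reads first; alphabetical tie-break for determinism
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def apply_cascade(col: PileupColumn, cfg: SnpFilterConfig | None = None) -> SnpCall:
    """Evaluate all six filter rules on a candidate column.

    All rules are always evaluated and every failing rule id is recorded;
    the call passes iff none fail.
    """
    cfg = cfg or SnpFilterConfig()
    if col.depth == 0 or not col.allele_counts:
        raise ValueError(f"{col.ref_name}:{col.pos}: zero depth")
    counts = col.allele_counts
    total = sum(counts.values())
    ranked = _ranked_alleles(counts)
    major = ranked[0]
    minor = ranked[1] if len(ranked) > 1 else None
    maf = (minor[1] / total) if minor else 0.0
    alt_allele = next((b for b, _ in ranked if b != col.ref_base), None)

    failed: list[int] = []
    if cfg.score_mode == "both":
        score_ok = col.rms_map_qual > cfg.min_scores and col.snp_qual > cfg.min_scores
    else:
        score_ok = col.rms_map_qual + col.snp_qual > cfg.min_scores
    if not score_ok:
        failed.append(1)
    if col.depth < cfg.min_depth:
        failed.append(2)
    if col.alt_reads < cfg.min_alt_reads:
        failed.append(3)
    if cfg.require_biallelic:
        if cfg.strict_biallelic:
            n_alleles = len(counts)
        else:
            n_alleles = sum(1 for _, n in counts.items() if n >= cfg.min_alt_reads)
        if n_alleles > 2:
            failed.append(4)
    if maf < cfg.min_maf:
        failed.append(5)
    major_minor = (major[1] + (minor[1] if minor else 0)) / total
    if major_minor < cfg.min_major_minor:
        failed.append(6)

    passed = not failed
    subst = None
    if passed and alt_allele is not None:
        subst = classify_substitution(col.ref_base, alt_allele)
    return SnpCall(
        ref_name=col.ref_name,
        pos=col.pos,
        ref_allele=col.ref_base,
        alt_allele=alt_allele,
        depth=col.depth,
        allele_counts=dict(counts),
        maf=maf,
        snp_qual=col.snp_qual,
        rms_map_qual=col.rms_map_qual,
        passed=passed,
        failed_criteria=failed,
        subst_class=subst,
    )


def classify_substitution(ref_allele: str, alt_allele: str) -> str:
    """Transition (A<->G, C<->T) vs transversion."""
    ref, alt = ref_allele.upper(), alt_allele.upper()
    if ref == alt:
        raise ValueError("ref and alt alleles are identical")
    for b in (ref, alt):
        if b not in "ACGT":
            raise ValueError(f"invalid allele {b!r}")
    pair = {ref, alt}
    if pair <= PURINES or pair <= PYRIMIDINES:
        return "transition"
    return "transversion"


def snp_frequency(total_ref_bp: int, n_filtered: int) -> int | None:
    """One SNP every N bp, rounded half-up; None when no SNPs."""
    if n_filtered == 0:
        return None
    if n_filtered < 0 or total_ref_bp <= 0:
        raise ValueError("counts must be positive")
    return int(round_half_up(total_ref_bp / n_filtered))


def summarize(
    calls: Sequence[SnpCall],
    kept_contig_total_bp: int | None = None,
    n_putative: int | None = None,
) -> SnpSummary:
    """Tally a filtered run: pass count, ts/tv split, and SNP density over
    the reference actually used (contigs kept by the length filter)."""
    passed = [c for c in calls if c.passed]
    n_ts = sum(1 for c in passed if c.subst_class == "transition")
    n_tv = sum(1 for c in passed if c.subst_class == "transversion")
    assert n_ts + n_tv == len(passed)
    freq = (
        snp_frequency(kept_contig_total_bp, len(passed))
        if kept_contig_total_bp
        else None
    )
    return SnpSummary(
        n_putative=n_putative if n_putative is not None else len(calls),
        n_filtered=len(passed),
        n_ts=n_ts,
        n_tv=n_tv,
        total_ref_bp=kept_contig_total_bp,
        freq_bp_per_snp=freq,
    )


def filter_pileup(
    source: str | TextIO | Iterable[str],
    cfg: SnpFilterConfig | None = None,
    kept_contig_total_bp: int | None = None,
) -> tuple[list[SnpCall], SnpSummary]:
    """End-to-end: parse -> initial score cut -> cascade -> summary."""
    cfg = cfg or SnpFilterConfig()
    candidates = list(initial_score_cut(parse_pileup(source), cfg.min_snp_score_initial))
    calls = [apply_cascade(col, cfg) for col in candidates]
    return calls, summarize(calls, kept_contig_total_bp, n_putative=len(candidates))


def calls_table(calls: Iterable[SnpCall]) -> str:
    """VCF-like TSV of calls."""
    lines = ["CHROM\tPOS\tREF\tALT\tDEPTH\tMAF\tSNPQ\tMAPQ\tCLASS\tSTATUS\tFAILED"]
    for c in calls:
        lines.append(
            f"{c.ref_name}\t{c.pos}\t{c.ref_allele}\t{c.alt_allele or '.'}\t{c.depth}"
            f"\t{c.maf:.4f}\t{c.snp_qual}\t{c.rms_map_qual}\t{c.subst_class or '.'}"
            f"\t{'PASS' if c.passed else 'FAIL'}"
            f"\t{','.join(map(str, c.failed_criteria)) or '.'}"
        )
    return "\n".join(lines) + "\n"


def summary_table(s: SnpSummary) -> str:
    freq = f"1 every {s.freq_bp_per_snp:,} bp" if s.freq_bp_per_snp else "n/a"
    rows = [
        ("Putative SNPs", f"{s.n_putative:,}"),
        ("Filtered SNPs", f"{s.n_filtered:,}"),
        ("Transition SNPs", f"{s.n_ts:,}"),
        ("Transversion SNPs", f"{s.n_tv:,}"),
        ("SNP frequency", freq),
    ]
    if s.total_ref_bp is not None:
        rows.insert(0, ("Total size of contigs at least 200 bp (bp)", f"{s.total_ref_bp:,}"))
    return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"
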