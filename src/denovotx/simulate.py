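"""Synthetic inputs with planted truth for every pipeline stage.

Everything the toolkit consumes can be generated here with known ground
truth: hairpin-bearing contigs with a mature miRNA planted on one arm,
isoform families at controlled identity, consensus-pileup text with
planted bi-/tri-allelic variants at controlled depth and minor-allele
frequency, and paired-end reads (51 bp, 180-250 bp inserts, emulating a
short-read paired-end run). A :class:`TruthTable` records what was
planted so recall and precision are measurable.

The generators emulate the statistical structure the pipeline assumes —
not platform error profiles, indels, or paralog evolution. All randomness
flows from one seeded generator per invocation; identical configuration
gives byte-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import Contig, reverse_complement

_BASES = np.array(list("ACGT"))

# codons whose third position is four-fold degenerate; substitutions there
# are always synonymous and can never create a stop codon
_FOURFOLD_PREFIXES = ("GC", "GG", "CC", "AC", "GT", "CT", "TC", "CG")
_STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class SimConfig:
    seed: int
    read_len: int = 51
    insert_min: int = 180
    insert_max: int = 250
    error_rate: float = 0.01
    n_contigs: int = 50
    contig_len_range: tuple[int, int] = (300, 2000)

    def __post_init__(self) -> None:
        if self.insert_min > self.insert_max:
            raise ValueError("insert_min must be <= insert_max")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.read_len <= 0:
            raise ValueError("read_len must be positive")


@dataclass(frozen=True)
class PlantedSnp:
    contig_id: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    true_maf: float
    true_depth: int


@dataclass(frozen=True)
class PlantedHairpin:
    contig_id: str
    window: tuple[int, int]  # 0-based half-open: the hairpin core
    mature_seq: str  # RNA
    arm: str
    mature_start: int = 0  # 0-based on the contig


@dataclass(frozen=True)
class IsoformMember:
    contig_id: str
    member_label: str
    pairwise_identity: float  # realized identity vs the family base


@dataclass
class TruthTable:
    planted_snps: list[PlantedSnp] = field(default_factory=list)
    planted_hairpins: list[PlantedHairpin] = field(default_factory=list)
    isoform_families: dict[str, list[IsoformMember]] = field(default_factory=dict)

    def to_tsv(self) -> str:
        lines = []
        for s in self.planted_snps:
            lines.append("snp\t%s\t%d\t%s\t%s\t%r\t%d" % (
                s.contig_id, s.pos, s.ref_allele, s.alt_allele, s.true_maf, s.true_depth))
        for h in self.planted_hairpins:
            lines.append("hairpin\t%s\t%d\t%d\t%s\t%s\t%d" % (
                h.contig_id, h.window[0], h.window[1], h.mature_seq, h.arm, h.mature_start))
        for fam in sorted(self.isoform_families):
            for m in self.isoform_families[fam]:
                lines.append("isoform\t%s\t%s\t%s\t%r" % (
                    fam, m.contig_id, m.member_label, m.pairwise_identity))
        return "\n".join(lines) + ("\n" if lines else "")

    @classmethod
    def from_tsv(cls, text: str) -> "TruthTable":
        tt = cls()
        for line in text.splitlines():
            if not line:
                continue
            kind, *f = line.split("\t")
            if kind == "snp":
                tt.planted_snps.append(PlantedSnp(
                    f[0], int(f[1]), f[2], f[3], float(f[4]), int(f[5])))
            elif kind == "hairpin":
                tt.planted_hairpins.append(PlantedHairpin(
                    f[0], (int(f[1]), int(f[2])), f[3], f[4], int(f[5])))
            elif kind == "isoform":
                tt.isoform_families.setdefault(f[0], []).append(
                    IsoformMember(f[1], f[2], float(f[3])))
            else:
                raise ValueError(f"unknown truth record kind {kind!r}")
        return tt


def random_dna(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


# ---------------------------------------------------------------------------
# hairpin contigs


def make_hairpin_contig(
    stem: str,
    loop_len: int = 5,
    mature_offset: int = 0,
    mature_len: int | None = None,
    flank_len: int = 30,
    seed: int = 0,
    contig_id: str = "hairpin",
) -> tuple[Contig, PlantedHairpin]:
    """Build flank + stem + loop + revcomp(stem) + flank with the mature
    sequence taken from the 5' arm.

    Flanks are drawn from a weakly pairing alphabet ({A,C}) and the loop is
    poly-A so the planted stem stays the dominant structure under the
    folding model. ``mature_len`` defaults to min(21, arm space); a mature
    span that would cross into the loop is rejected.
    """
    stem = stem.upper().replace("U", "T")
    if not 20 <= len(stem) <= 40:
        raise ValueError("stem must be 20-40 nt")
    if loop_len < 3:
        raise ValueError("loop must be at least 3 nt")
    if mature_len is None:
        mature_len = min(21, len(stem) - mature_offset)
    if mature_offset < 0 or mature_offset + mature_len > len(stem):
        raise ValueError("mature span crosses the loop boundary")
    rng = np.random.default_rng(seed)
    flank5 = random_dna(rng, flank_len, "AC")
    flank3 = random_dna(rng, flank_len, "AC")
    loop = "A" * loop_len
    core = stem + loop + reverse_complement(stem)
    contig = Contig(contig_id, flank5 + core + flank3)
    mature_dna = stem[mature_offset : mature_offset + mature_len]
    truth = PlantedHairpin(
        contig_id=contig_id,
        window=(flank_len, flank_len + len(core)),
        mature_seq=mature_dna.replace("T", "U").upper(),
        arm="5p",
        mature_start=flank_len + mature_offset,
    )
    return contig, truth


def make_hairpin_set(
    n_contigs: int,
    seed: int = 0,
    stem_len: int = 30,
    loop_len: int = 5,
    flank_len: int = 40,
    mature_len: int = 21,
    mature_mismatches: int = 0,
    g_fraction: float = 0.5,
) -> tuple[list[Contig], list[PlantedHairpin], list[str]]:
    """A batch of hairpin contigs whose planted stem is provably the optimal
    fold.

    Stems are drawn from {A,G} (purine 5' arm): neither arm can then pair
    internally, the poly-A loop and {A,C} flanks are inert, and the only
    full nested pairing of the two arms is the planted register — so
    stem-loop validation is deterministic. Returns (contigs, truth, mature
    reference sequences), where each reference mature carries
    ``mature_mismatches`` substitutions relative to the planted arm
    (emulating a cross-species mature from a database).
    """
    rng = np.random.default_rng(seed)
    contigs, truths, matures = [], [], []
    for i in range(n_contigs):
        stem = "".join(
            "G" if rng.random() < g_fraction else "A" for _ in range(stem_len))
        offset = int(rng.integers(0, stem_len - mature_len + 1))
        contig, truth = make_hairpin_contig(
            stem, loop_len=loop_len, mature_offset=offset, mature_len=mature_len,
            flank_len=flank_len, seed=int(rng.integers(2**31)),
            contig_id=f"hp{i}")
        mature = list(truth.mature_seq)
        for p in rng.choice(mature_len, size=mature_mismatches, replace=False):
            choices = [b for b in "ACGU" if b != mature[p]]
            mature[p] = choices[rng.integers(0, 3)]
        contigs.append(contig)
        truths.append(truth)
        matures.append("".join(mature))
    return contigs, truths, matures


# ---------------------------------------------------------------------------
# isoform families


def make_isoform_family(
    base_seq: str,
    n_members: int,
    target_identity: float,
    seed: int = 0,
    prefix: str = "iso",
) -> tuple[list[Contig], list[IsoformMember]]:
    """Members derived from ``base_seq`` by point substitutions so each
    realized identity is within 1% of ``target_identity``.

    Substitutions are placed uniformly without replacement and never inside
    the first/last 25 nt, so window extraction near contig ends is
    unaffected.
    """
    if not 0 < target_identity <= 100:
        raise ValueError("target identity must be in (0, 100]")
    base_seq = base_seq.upper()
    rng = np.random.default_rng(seed)
    n = len(base_seq)
    n_subs = round(n * (1 - target_identity / 100.0))
    margin = 25 if n > 60 else 0
    eligible = np.arange(margin, n - margin)
    if n_subs > len(eligible):
        raise ValueError("sequence too short for requested divergence")
    contigs, members = [], []
    for i in range(n_members):
        seq = list(base_seq)
        for p in rng.choice(eligible, size=n_subs, replace=False):
            choices = [b for b in "ACGT" if b != seq[p]]
            seq[p] = choices[rng.integers(0, 3)]
        cid = f"{prefix}_m{i}"
        contigs.append(Contig(cid, "".join(seq)))
        members.append(IsoformMember(cid, f"m{i}", 100.0 * (1 - n_subs / n)))
    return contigs, members


# ---------------------------------------------------------------------------
# pileup


def _pileup_line(
    ref_name: str,
    pos: int,
    ref: str,
    counts: dict[str, int],
    snp_qual: int,
    rms_map_qual: int,
    consensus_qual: int = 30,
) -> str:
    depth = sum(counts.values())
    pieces = []
    n_ref = counts.get(ref, 0)
    pieces.append("".join("." if k % 2 == 0 else "," for k in range(n_ref)))
    for base in sorted(b for b in counts if b != ref):
        pieces.append("".join(
            base if k % 2 == 0 else base.lower() for k in range(counts[base])
        ))
    read_bases = "".join(pieces)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    consensus = ranked[0][0]
    return "\t".join(map(str, (
        ref_name, pos, ref, consensus, consensus_qual, snp_qual, rms_map_qual,
        depth, read_bases, "I" * depth,
    )))


def make_pileup(
    contig: Contig,
    planted: Sequence[PlantedSnp],
    depth_mean: float = 20,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[str, list[PlantedSnp]]:
    """Consensus-pileup text over a contig with planted variants.

    At planted sites the alternative-allele count is Binomial(depth, maf),
    clamped to at least one read whenever maf*depth >= 1 so planted truth is
    never silently absent. Elsewhere reads mismatch the reference at
    ``error_rate``. SNP quality is written as min(255, 10*alt reads) at
    planted sites — a monotone surrogate for a real caller's score — and is
    kept below the putative-SNP cut at error-only sites; RMS mapping quality
    is 150 at planted sites and 50 elsewhere.
    """
    if depth_mean < 1:
        raise ValueError("depth_mean must be >= 1")
    by_pos: dict[int, PlantedSnp] = {}
    for s in planted:
        if not 0 < s.true_maf <= 0.5:
            raise ValueError(f"planted MAF must be in (0, 0.5], got {s.true_maf}")
        if not 1 <= s.pos <= len(contig):
            raise ValueError(f"planted position {s.pos} outside contig")
        if contig.seq[s.pos - 1] != s.ref_allele:
            raise ValueError(
                f"planted ref allele {s.ref_allele} != contig base at {s.pos}")
        by_pos[s.pos] = s
    rng = np.random.default_rng(seed)
    lines = []
    for pos in range(1, len(contig) + 1):
        ref = contig.seq[pos - 1]
        if ref == "N":
            continue
        site = by_pos.get(pos)
        depth = site.true_depth if site else int(rng.poisson(depth_mean))
        if depth == 0:
            continue
        counts: dict[str, int] = {}
        if site:
            alt = int(rng.binomial(depth, site.true_maf))
            if alt == 0 and site.true_maf * depth >= 1:
                alt = 1
            alt = min(alt, depth)
            counts[site.alt_allele] = alt
            counts[ref] = depth - alt
            if counts[ref] == 0:
                del counts[ref]
        else:
            n_err = int(rng.binomial(depth, error_rate)) if error_rate else 0
            counts[ref] = depth - n_err
            for _ in range(n_err):
                b = "ACGT"[rng.integers(0, 4)]
                while b == ref:
                    b = "ACGT"[rng.integers(0, 4)]
                counts[b] = counts.get(b, 0) + 1
        alt_total = sum(n for b, n in counts.items() if b != ref)
        if site:
            snp_qual, rms = min(255, 10 * alt_total), 150
        else:
            snp_qual, rms = (5 * alt_total if alt_total else 0), 50
        lines.append(_pileup_line(contig.id, pos, ref, counts, snp_qual, rms))
    return "\n".join(lines) + "\n", list(planted)


# ---------------------------------------------------------------------------
# SNP filter benchmark (deterministic planted columns)


def _passing_column(rng: np.random.Generator, ref: str) -> tuple[dict[str, int], int, int]:
    depth = int(rng.integers(12, 61))
    frac = rng.uniform(0.2, 0.45)
    alt_n = max(3, round(frac * depth))
    alt = "ACGT"[rng.integers(0, 4)]
    while alt == ref:
        alt = "ACGT"[rng.integers(0, 4)]
    return {ref: depth - alt_n, alt: alt_n}, 150, 150


def _violating_column(
    rng: np.random.Generator, ref: str, rule: int
) -> tuple[dict[str, int], int, int]:
    others = [b for b in "ACGT" if b != ref]
    idx = rng.permutation(3)
    a1, a2, a3 = (others[i] for i in idx)
    if rule == 1:  # scores not above 100; everything else passes
        counts, _, _ = _passing_column(rng, ref)
        return counts, 90, 150
    if rule == 2:  # depth below 10
        return {ref: 6, a1: 3}, 150, 150
    if rule == 3:  # fewer than 3 non-reference reads
        return {ref: 18, a1: 2}, 150, 150
    if rule == 4:  # three well-supported alleles (major+minor still 95%)
        return {ref: 60, a1: 35, a2: 5}, 150, 150
    if rule == 5:  # minor allele frequency below 5%
        return {ref: 96, a1: 4}, 150, 150
    if rule == 6:  # major+minor below 95% (extra alleles weakly supported)
        return {ref: 28, a1: 8, a2: 2, a3: 2}, 150, 150
    raise ValueError(f"unknown rule {rule}")


def make_snp_benchmark(
    seed: int,
    n_columns: int = 10_000,
    n_pass: int = 100,
    n_violations: int = 100,
    contig_id: str = "bench",
) -> tuple[str, list[tuple[int, str, int | None]]]:
    """A pileup of ``n_columns`` columns with planted passing SNPs and
    planted single-rule violations (cycling through the six filter rules).

    Planted columns are constructed with exact allele counts and qualities
    so each violator breaks precisely its intended rule and each passing
    column satisfies all six. Returns (pileup text, truth) where truth rows
    are (pos, 'pass'|'violate', rule id or None).
    """
    rng = np.random.default_rng(seed)
    contig = Contig(contig_id, random_dna(rng, n_columns))
    n_planted = n_pass + n_violations
    positions = sorted(rng.choice(np.arange(1, n_columns + 1), size=n_planted,
                                  replace=False).tolist())
    order = rng.permutation(n_planted)
    kinds: list[tuple[str, int | None]] = [("pass", None)] * n_pass + [
        ("violate", 1 + i % 6) for i in range(n_violations)
    ]
    truth: list[tuple[int, str, int | None]] = []
    planted_rows: dict[int, str] = {}
    for pos, k in zip(positions, (kinds[i] for i in order)):
        ref = contig.seq[pos - 1]
        if k[0] == "pass":
            counts, sq, mq = _passing_column(rng, ref)
        else:
            counts, sq, mq = _violating_column(rng, ref, k[1])
        planted_rows[pos] = _pileup_line(contig_id, pos, ref, counts, sq, mq)
        truth.append((pos, k[0], k[1]))
    lines = []
    for pos in range(1, n_columns + 1):
        if pos in planted_rows:
            lines.append(planted_rows[pos])
        else:
            ref = contig.seq[pos - 1]
            depth = int(rng.poisson(15))
            if depth == 0:
                continue
            lines.append(_pileup_line(contig_id, pos, ref, {ref: depth}, 0, 50))
    return "\n".join(lines) + "\n", truth


# ---------------------------------------------------------------------------
# paired-end reads


def make_reads(
    transcripts: Sequence[Contig],
    n_pairs: int,
    cfg: SimConfig,
) -> tuple[str, str]:
    """Paired FASTQ text (mate 1, mate 2).

    Fragments are uniform on [insert_min, insert_max]; mates are read_len nt
    from opposite strands of the fragment. Transcripts shorter than
    insert_max are skipped with a warning.
    """
    rng = np.random.default_rng(cfg.seed)
    eligible = [t for t in transcripts if len(t) >= cfg.insert_max]
    skipped = len(transcripts) - len(eligible)
    if skipped:
        warnings.warn(f"skipped {skipped} transcript(s) shorter than insert_max")
    if n_pairs and not eligible:
        raise ValueError("no transcript long enough for the insert size")
    fq1, fq2 = [], []
    qual = "I" * cfg.read_len
    for i in range(n_pairs):
        t = eligible[rng.integers(0, len(eligible))]
        insert = int(rng.integers(cfg.insert_min, cfg.insert_max + 1))
        start = int(rng.integers(0, len(t) - insert + 1))
        frag = t.seq[start : start + insert]
        r1 = _with_errors(rng, frag[: cfg.read_len], cfg.error_rate)
        r2 = _with_errors(rng, reverse_complement(frag)[: cfg.read_len], cfg.error_rate)
        fq1.append(f"@pair{i}/1\n{r1}\n+\n{qual}")
        fq2.append(f"@pair{i}/2\n{r2}\n+\n{qual}")
    j1 = "\n".join(fq1) + ("\n" if fq1 else "")
    j2 = "\n".join(fq2) + ("\n" if fq2 else "")
    return j1, j2


def _with_errors(rng: np.random.Generator, read: str, error_rate: float) -> str:
    if not error_rate:
        return read
    seq = list(read)
    for p in np.nonzero(rng.random(len(seq)) < error_rate)[0]:
        choices = [b for b in "ACGT" if b != seq[p]]
        seq[p] = choices[rng.integers(0, 3)]
    return "".join(seq)


# ---------------------------------------------------------------------------
# coding contigs and family sets for the isoform rules


def make_coding_contig(
    rng: np.random.Generator,
    orf_codons: int = 160,
    utr_len: int = 40,
    contig_id: str = "cds",
) -> tuple[Contig, str]:
    """A contig with a planted forward-strand ORF (ATG + random non-stop
    codons + stop) between short UTRs; returns (contig, protein)."""
    from Bio.Seq import Seq

    codons = ["ATG"]
    while len(codons) < orf_codons:
        c = random_dna(rng, 3)
        if c not in _STOPS and c != "ATG":
            codons.append(c)
    cds = "".join(codons)
    seq = random_dna(rng, utr_len) + cds + "TAA" + random_dna(rng, utr_len)
    protein = str(Seq(cds).translate())
    return Contig(contig_id, seq), protein


def _synonymous_copy(
    rng: np.random.Generator, contig: Contig, utr_len: int, n_subs: int, new_id: str
) -> Contig:
    """Copy with ``n_subs`` synonymous third-position substitutions inside
    the planted ORF (four-fold degenerate codons only), so the protein is
    untouched and no stop can appear."""
    seq = list(contig.seq)
    cds_start = utr_len
    cds_end = len(seq) - utr_len  # includes the stop codon
    fourfold_thirds = [
        i + 2
        for i in range(cds_start, cds_end - 3, 3)
        if "".join(seq[i : i + 2]) in _FOURFOLD_PREFIXES
    ]
    if n_subs > len(fourfold_thirds):
        raise ValueError("not enough degenerate sites for requested divergence")
    for p in rng.choice(fourfold_thirds, size=n_subs, replace=False):
        choices = [b for b in "ACGT" if b != seq[p]]
        seq[p] = choices[rng.integers(0, 3)]
    return Contig(new_id, "".join(seq))


def make_family_set(
    seed: int,
    n_families: int = 10,
    ortholog_identity: float = 99.5,
    max_shared_nt: int = 16,
    species: tuple[str, str] = ("A", "B"),
) -> tuple[dict[str, dict[str, list[Contig]]], dict[str, tuple[int, int, int]]]:
    """A gene-family benchmark with planted ortholog pairs and distinct
    isoforms.

    Each family holds 1-2 shared isoforms (each present in both species as
    an ortholog pair at ``ortholog_identity``, produced by synonymous
    substitutions so the protein is conserved) plus occasionally one
    species-specific isoform. Distinct isoforms are independent random
    coding sequences rejection-sampled so that no within-family pair shares
    an exact run longer than ``max_shared_nt``.

    Returns (families mapping for :func:`denovotx.isoforms.assign_isoforms`,
    truth mapping family -> (n members species 1, n members species 2,
    n ortholog pairs)).
    """
    from .isoforms import MONOLIGNOL_FAMILIES, longest_orf, longest_shared_exact_match

    rng = np.random.default_rng(seed)
    utr = 40
    sp_a, sp_b = species
    families: dict[str, dict[str, list[Contig]]] = {}
    truth: dict[str, tuple[int, int, int]] = {}
    names = list(MONOLIGNOL_FAMILIES)[:n_families]
    while len(names) < n_families:
        names.append(f"FAM{len(names)}")
    for fam in names:
        n_shared = int(rng.integers(1, 3))
        extra_a = int(rng.integers(0, 2)) if n_shared == 1 else 0
        bases: list[Contig] = []

        def fresh_contig(cid: str) -> Contig:
            # rejection-sample until the new isoform shares no long exact
            # run with existing family members and keeps its planted ORF
            for _ in range(200):
                cand, protein = make_coding_contig(rng, orf_codons=160,
                                                   utr_len=utr, contig_id=cid)
                if longest_orf(cand).protein != protein:
                    continue
                if all(longest_shared_exact_match(cand.seq, b.seq) <= max_shared_nt
                       for b in bases):
                    return cand
            raise RuntimeError("could not sample a sufficiently novel isoform")

        members_a: list[Contig] = []
        members_b: list[Contig] = []
        contig_len = 2 * utr + 160 * 3 + 3  # UTRs + ORF + stop
        n_subs = round(contig_len * (1 - ortholog_identity / 100.0))
        for k in range(n_shared):
            base = fresh_contig(f"{fam}_{sp_a}_iso{k}")
            bases.append(base)
            members_a.append(base)
            members_b.append(
                _synonymous_copy(rng, base, utr, n_subs, f"{fam}_{sp_b}_iso{k}"))
        for k in range(extra_a):
            extra = fresh_contig(f"{fam}_{sp_a}_only{k}")
            bases.append(extra)
            members_a.append(extra)
        families[fam] = {sp_a: members_a, sp_b: members_b}
        truth[fam] = (len(members_a), len(members_b), n_shared)
    return families, truth
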