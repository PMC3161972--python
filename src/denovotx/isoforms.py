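"""Monolignol gene-family assignment and isoform/ortholog disambiguation.

Contigs are assigned to the ten monolignol-pathway families (PAL, C4H,
C3H, COMT, F5H, 4CL, HCT, CCoAOMT, CAD, CCR) from tabular homology hits,
screened for conserved amino-acid motifs and open reading frames, and then
disambiguated with two empirically grounded rules:

* a cross-species pair sharing >= 99% identity at both the nucleotide and
  the translated protein level is an ortholog pair;
* two within-species members sharing no exact run longer than 16 nt are
  distinct isoforms;
* anything in between (identity < 99% yet a long shared exact run) is
  reported as ambiguous rather than silently merged.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence, TextIO

import numpy as np
from Bio import Align
from Bio.Seq import Seq

from .core import Contig, as_lines, reverse_complement, round_half_up

MONOLIGNOL_FAMILIES = (
    "PAL", "C4H", "C3H", "COMT", "F5H", "4CL", "HCT", "CCoAOMT", "CAD", "CCR",
)


@dataclass(frozen=True)
class BlastHit:
    query_id: str
    subject_id: str
    identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float


@dataclass
class OrfRecord:
    frame: int = 0  # +1..+3 forward, -1..-3 reverse; 0 = none found
    start: int = 0  # 1-based on the contig forward strand
    end: int = 0
    protein: str = ""
    complete: bool = False


@dataclass
class IsoformAssignment:
    contig_a: str
    contig_b: str
    family: str
    relation: str  # 'ortholog' | 'distinct_isoform' | 'ambiguous'
    nt_identity: float
    protein_identity: float | None
    lcs_nt: int
    cross_species: bool


# ---------------------------------------------------------------------------
# homology hits


def parse_blast_tab(source: str | TextIO | Iterable[str]) -> list[BlastHit]:
    """Parse 12-column tabular hits (BLAST outfmt-6 dialect)."""
    hits = []
    for lineno, line in enumerate(as_lines(source), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 12:
            raise ValueError(f"line {lineno}: expected 12 columns, got {len(f)}")
        hits.append(BlastHit(
            f[0], f[1], float(f[2]), int(f[3]), int(f[4]), int(f[5]),
            int(f[6]), int(f[7]), int(f[8]), int(f[9]), float(f[10]), float(f[11]),
        ))
    return hits


def family_of_subject(subject_id: str) -> str:
    """Family label from a subject id: the token before the first '_' when it
    is one of the ten monolignol genes, else a generic 'other' label."""
    token = subject_id.split("_")[0].split("|")[0]
    return token if token in MONOLIGNOL_FAMILIES else "other"


def retain_family_hits(
    hits: Iterable[BlastHit],
    max_evalue: float = 1e-10,
    min_identity: float = 55.0,
    family_fn=family_of_subject,
) -> dict[str, dict[str, BlastHit]]:
    """Best hit per (family, contig), keeping only hits with E-value <=
    ``max_evalue`` and identity >= ``min_identity`` (low-homology contigs are
    excluded). Ties resolve to the higher bitscore."""
    best: dict[str, dict[str, BlastHit]] = {}
    for h in hits:
        if h.evalue > max_evalue or h.identity < min_identity:
            continue
        fam = family_fn(h.subject_id)
        cur = best.setdefault(fam, {}).get(h.query_id)
        if cur is None or h.bitscore > cur.bitscore:
            best[fam][h.query_id] = h
    return best


# ---------------------------------------------------------------------------
# motifs and ORFs


def load_motif_config(path: str | None = None) -> dict[str, list[str]]:
    """Per-family motif patterns (regular expressions over amino acids).

    The shipped default file is a synthetic, editable starting point; real
    analyses should substitute curated motifs. Invalid patterns raise at
    load time.
    """
    if path is None:
        text = resources.files("denovotx.data").joinpath("monolignol_motifs.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    config = {k: v for k, v in json.loads(text).items() if not k.startswith("_")}
    for fam, patterns in config.items():
        for p in patterns:
            try:
                re.compile(p)
            except re.error as exc:
                raise ValueError(f"family {fam}: invalid motif pattern {p!r}: {exc}")
    return config


def check_motifs(protein: str, motif_patterns: Sequence[str]) -> list[str]:
    """Subset of patterns found in the protein (regex search)."""
    return [p for p in motif_patterns if re.search(p, protein)]


def _orfs_in_frame(seq: str, offset: int) -> Iterable[tuple[int, int, str, bool]]:
    """ATG-initiated ORFs in one forward frame of ``seq``; yields
    (start, end, protein, complete) with 0-based half-open nt coords on
    ``seq``; ``end`` excludes the stop codon."""
    frame_seq = seq[offset:]
    n = len(frame_seq) - len(frame_seq) % 3
    codons = [frame_seq[i : i + 3] for i in range(0, n, 3)]
    i = 0
    while i < len(codons):
        if codons[i] == "ATG":
            j = i
            while j < len(codons) and codons[j] not in ("TAA", "TAG", "TGA"):
                j += 1
            prot = str(Seq("".join(codons[i:j])).translate())
            complete = j < len(codons)
            yield offset + 3 * i, offset + 3 * j, prot, complete
            i = j + 1
        else:
            i += 1


def longest_orf(contig: Contig) -> OrfRecord:
    """Longest ATG-initiated ORF over all six frames.

    Coordinates are 1-based on the contig's forward strand. ``complete``
    requires an in-frame stop after the ORF. Returns an empty record when
    no ATG-initiated ORF exists.
    """
    if len(contig) < 3:
        return OrfRecord()
    best = OrfRecord()
    n = len(contig)
    for strand, seq in ((1, contig.seq), (-1, reverse_complement(contig.seq))):
        for offset in range(3):
            for s, e, prot, complete in _orfs_in_frame(seq, offset):
                if len(prot) > len(best.protein) or (
                    len(prot) == len(best.protein) and complete and not best.complete
                ):
                    if strand == 1:
                        start, end = s + 1, e
                    else:  # map back to forward coordinates
                        start, end = n - e + 1, n - s
                    best = OrfRecord(strand * (offset + 1), start, end, prot, complete)
    return best


# ---------------------------------------------------------------------------
# pairwise comparison


def _aligner(mode: str) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = mode
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -2
    return a


def global_identity(a: str, b: str, mode: str = "global") -> float:
    """Percent identity as 100 * matches / alignment columns.

    ``mode='global'`` (default) aligns end to end with end gaps penalized;
    ``mode='local'`` scores the best local alignment only (identity over
    the aligned overlap), for callers who prefer an overlap-only reading.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if mode not in ("global", "local"):
        raise ValueError("mode must be 'global' or 'local'")
    aln = _aligner(mode).align(a.upper(), b.upper())[0]
    identities = aln.counts().identities
    columns = aln.length
    return 100.0 * identities / columns


def longest_shared_exact_match(a: str, b: str) -> int:
    """Length of the longest common substring (contiguous, same strand)."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    sa = np.frombuffer(a.upper().encode(), dtype=np.uint8)
    sb = np.frombuffer(b.upper().encode(), dtype=np.uint8)
    prev = np.zeros(len(sb) + 1, dtype=np.int32)
    best = 0
    for x in sa:
        cur = np.zeros_like(prev)
        cur[1:] = np.where(sb == x, prev[:-1] + 1, 0)
        m = int(cur.max())
        if m > best:
            best = m
        prev = cur
    return best


def _translated(contig: Contig) -> str:
    return longest_orf(contig).protein


def classify_pair(
    a: Contig,
    b: Contig,
    cross_species: bool,
    family: str = "other",
    min_identity: float = 99.0,
    max_shared_nt: int = 16,
    identity_mode: str = "global",
) -> IsoformAssignment:
    """Classify one contig pair with the identity / exact-match rules."""
    nt_id = global_identity(a.seq, b.seq, identity_mode)
    lcs = longest_shared_exact_match(a.seq, b.seq)
    prot_id = None
    relation = "ambiguous"
    if cross_species and nt_id >= min_identity:
        pa, pb = _translated(a), _translated(b)
        if pa and pb:
            prot_id = global_identity(pa, pb, identity_mode)
        if prot_id is not None and prot_id >= min_identity:
            relation = "ortholog"
    elif lcs <= max_shared_nt:
        relation = "distinct_isoform"
    return IsoformAssignment(
        contig_a=a.id,
        contig_b=b.id,
        family=family,
        relation=relation,
        nt_identity=round_half_up(nt_id, 2),
        protein_identity=round_half_up(prot_id, 2) if prot_id is not None else None,
        lcs_nt=lcs,
        cross_species=cross_species,
    )


@dataclass
class FamilyCounts:
    family: str
    n_species_a: int
    n_species_b: int
    n_ortholog_pairs: int
    n_ambiguous: int


def assign_isoforms(
    families: dict[str, dict[str, list[Contig]]],
    min_identity: float = 99.0,
    max_shared_nt: int = 16,
    identity_mode: str = "global",
) -> tuple[list[IsoformAssignment], list[FamilyCounts]]:
    """Disambiguate isoforms and orthologs family by family.

    ``families`` maps family -> species label -> family-assigned contigs
    (two species expected). All within-species pairs and all cross-species
    pairs are classified; per-family counts report members per species and
    recovered ortholog pairs, mirroring a species/shared membership diagram.
    """
    assignments: list[IsoformAssignment] = []
    counts: list[FamilyCounts] = []
    for family in sorted(families):
        by_species = families[family]
        species = sorted(by_species)
        if len(species) != 2:
            raise ValueError(f"family {family}: expected two species, got {species}")
        sa, sb = species
        pairs: list[IsoformAssignment] = []
        for sp in species:
            members = by_species[sp]
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    pairs.append(classify_pair(
                        members[i], members[j], cross_species=False, family=family,
                        min_identity=min_identity, max_shared_nt=max_shared_nt,
                        identity_mode=identity_mode,
                    ))
        for ca in by_species[sa]:
            for cb in by_species[sb]:
                pairs.append(classify_pair(
                    ca, cb, cross_species=True, family=family,
                    min_identity=min_identity, max_shared_nt=max_shared_nt,
                    identity_mode=identity_mode,
                ))
        assignments.extend(pairs)
        counts.append(FamilyCounts(
            family=family,
            n_species_a=len(by_species[sa]),
            n_species_b=len(by_species[sb]),
            n_ortholog_pairs=sum(1 for p in pairs if p.relation == "ortholog"),
            n_ambiguous=sum(1 for p in pairs if p.relation == "ambiguous"),
        ))
    return assignments, counts


def orf_gff3(contigs: Iterable[Contig]) -> str:
    """GFF3 of each contig's longest ORF (contigs without one are skipped)."""
    lines = ["##gff-version 3"]
    for c in contigs:
        orf = longest_orf(c)
        if not orf.protein:
            continue
        strand = "+" if orf.frame > 0 else "-"
        attrs = f"ID=orf_{c.id};frame={orf.frame:+d};complete={str(orf.complete).lower()}"
        lines.append(f"{c.id}\tdenovotx\tORF\t{orf.start}\t{orf.end}\t.\t{strand}\t0\t{attrs}")
    return "\n".join(lines) + "\n"


def assignment_table(assignments: Iterable[IsoformAssignment]) -> str:
    lines = ["contig_a\tcontig_b\tfamily\trelation\tnt_identity\tprotein_identity\tlcs_nt\tcross_species"]
    for a in assignments:
        prot = f"{a.protein_identity:.2f}" if a.protein_identity is not None else "."
        lines.append(
            f"{a.contig_a}\t{a.contig_b}\t{a.family}\t{a.relation}"
            f"\t{a.nt_identity:.2f}\t{prot}\t{a.lcs_nt}\t{int(a.cross_species)}"
        )
    return "\n".join(lines) + "\n"
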