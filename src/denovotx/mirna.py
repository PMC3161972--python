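"""miRNA precursor identification, MFEI scoring, and target prediction.

Conserved plant miRNAs can be found in a de novo transcriptome by locating
near-exact copies of known mature sequences, excising the surrounding
precursor window, folding it, and asking whether the fold is the single
predominant stem-loop characteristic of a miRNA precursor with an
energetically compact structure. The discriminating statistic is the
minimal folding energy index

    MFEI = AMFE / GC%,    AMFE = 100 * |MFE| / L

where MFE (kcal/mol, <= 0) is the folding energy of the L-nt precursor.
Genuine precursors have high MFEI relative to other non-coding or coding
RNA; candidates below a configurable cutoff are rejected.

Folding uses a deliberately simple maximum-weight nested-pairing model
(pair energies GC = -3, AU = -2, GU = -1 kcal/mol, minimum loop 3,
no pseudoknots). It is exactly solvable, which makes it testable against
exhaustive enumeration, and externally computed MFE values (e.g. from a
thermodynamic folder) can be supplied per precursor to override it.

Target prediction scans transcripts for sites complementary to the mature
sequence with a bounded weighted mismatch count; G:U wobble pairs may be
charged a reduced weight as plant target-prediction servers do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import Contig, reverse_complement, round_half_up

MIN_LOOP = 3  # minimum unpaired bases closed by any pair

# pair "energies" as positive weights; MFE = -(total weight)
_PAIR_WEIGHT = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}

_ENC = {"A": 0, "C": 1, "G": 2, "U": 3}
_W4 = np.zeros((4, 4), dtype=np.int64)
for (x, y), w in _PAIR_WEIGHT.items():
    _W4[_ENC[x], _ENC[y]] = w


@dataclass
class MirnaConfig:
    """Thresholds for hairpin scanning and target prediction."""

    window_len: int = 1000
    max_mature_mm: int = 3
    min_loop: int = MIN_LOOP
    mfei_cutoff: float = 0.5
    max_target_mm: float = 3
    wobble_weight: float = 1.0  # 0.5 charges G:U half a mismatch
    min_stem_fraction: float = 0.6

    def __post_init__(self) -> None:
        for name in ("window_len", "max_mature_mm", "min_loop", "mfei_cutoff",
                     "max_target_mm", "wobble_weight", "min_stem_fraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class HairpinCandidate:
    contig_id: str
    window: tuple[int, int]  # 0-based half-open on the contig
    precursor_seq: str  # RNA
    length_nt: int
    gc_percent: float
    structure: str
    mfe_kcal_mol: float
    amfe: float
    mfei: float
    mature_seq: str  # RNA
    mature_mismatches: int
    mature_span: tuple[int, int] | None  # 0-based half-open on the precursor
    arm: str | None = None  # '5p' | '3p'
    accepted: bool = False
    reasons: list[str] = field(default_factory=list)

    @property
    def status(self) -> str:
        return "accepted" if self.accepted else "rejected(%s)" % ",".join(self.reasons)


@dataclass(frozen=True)
class TargetHit:
    transcript_id: str
    site: tuple[int, int]  # 0-based half-open on the transcript
    mismatches: float
    site_seq: str
    mature_seq: str


def to_rna(seq: str) -> str:
    """Normalize a DNA/RNA string to upper-case RNA (T -> U)."""
    return seq.upper().replace("T", "U")


def _encode(seq: str) -> np.ndarray:
    rna = to_rna(seq)
    bad = set(rna) - set("ACGU")
    if bad:
        raise ValueError(f"non-ACGU characters after normalization: {sorted(bad)}")
    return np.array([_ENC[b] for b in rna], dtype=np.int64)


# ---------------------------------------------------------------------------
# folding


def _fill_python(enc: np.ndarray, W: np.ndarray, minloop: int) -> np.ndarray:
    n = len(enc)
    S = np.zeros((n + 1, n + 1), dtype=np.int64)
    for span in range(minloop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = S[i + 1, j]
            for k in range(i + minloop + 1, j + 1):
                w = W[enc[i], enc[k]]
                if w > 0:
                    v = w + S[i + 1, k - 1] + S[k + 1, j]
                    if v > best:
                        best = v
            S[i, j] = best
    return S


try:  # compiled fill is optional; results are identical
    from numba import njit

    _fill_fast = njit(cache=True)(_fill_python)
except Exception:  # pragma: no cover - numba present in normal installs
    _fill_fast = None


def fold(seq: str, min_loop: int = MIN_LOOP) -> tuple[str, float]:
    """Fold an RNA (or DNA; T is read as U) into its optimal nested structure.

    Returns (dot-bracket, MFE in kcal/mol). The model scores each pair
    GC -3, AU -2, GU -1 and forbids loops shorter than ``min_loop``;
    the optimum is exact (dynamic programming over intervals).
    """
    if len(seq) > 2000:
        raise ValueError("sequence longer than 2,000 nt; fold windows instead")
    enc = _encode(seq)
    n = len(enc)
    if n == 0:
        return "", 0.0
    fill = _fill_fast if _fill_fast is not None else _fill_python
    S = fill(enc, _W4, min_loop)

    # deterministic traceback: prefer leaving i unpaired, then smallest partner
    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or S[i, j] == 0:
            continue
        if S[i, j] == S[i + 1, j]:
            stack.append((i + 1, j))
            continue
        for k in range(i + min_loop + 1, j + 1):
            w = _W4[enc[i], enc[k]]
            if w > 0 and S[i, j] == w + S[i + 1, k - 1] + S[k + 1, j]:
                structure[i], structure[k] = "(", ")"
                stack.append((i + 1, k - 1))
                if k + 1 <= j:
                    stack.append((k + 1, j))
                break
        else:  # pragma: no cover - DP table guarantees a branch
            raise AssertionError("traceback failed")
    return "".join(structure), float(-S[0, n - 1])


def fold_exhaustive(seq: str, min_loop: int = MIN_LOOP) -> float:
    """Reference MFE by exhaustive enumeration of all nested structures.

    Exponential; intended for validating :func:`fold` on short sequences
    (<= ~16 nt). Shares no logic with the dynamic program.
    """
    enc = _encode(seq)
    n = len(enc)

    def structures(i: int, j: int):
        if j - i < min_loop + 1:
            yield 0
            return
        for rest in structures(i + 1, j):
            yield rest
        for k in range(i + min_loop + 1, j + 1):
            w = _W4[enc[i], enc[k]]
            if w > 0:
                for left in structures(i + 1, k - 1):
                    if k + 1 > j:
                        yield w + left
                    else:
                        for right in structures(k + 1, j):
                            yield w + left + right

    if n == 0:
        return 0.0
    return float(-max(structures(0, n - 1)))


def pairs_from_dotbracket(structure: str) -> list[tuple[int, int]]:
    pairs: list[tuple[int, int]] = []
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            pairs.append((stack.pop(), i))
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r}")
    if stack:
        raise ValueError("unbalanced '(' in structure")
    return sorted(pairs)


# ---------------------------------------------------------------------------
# scoring


def compute_amfe(mfe: float, length_nt: int) -> float:
    """Adjusted MFE: 100 * |MFE| / length, two decimals."""
    if length_nt <= 0:
        raise ValueError("length must be positive")
    if mfe > 0:
        raise ValueError("MFE must be <= 0 kcal/mol")
    return round_half_up(100.0 * abs(mfe) / length_nt, 2)


def compute_mfei(mfe: float, length_nt: int, gc_percent: float) -> float:
    """Minimal folding energy index: AMFE / GC%, two decimals half-up."""
    if gc_percent <= 0:
        raise ValueError("GC% must be positive")
    if length_nt <= 0:
        raise ValueError("length must be positive")
    amfe_raw = 100.0 * abs(mfe) / length_nt
    return round_half_up(amfe_raw / gc_percent, 2)


# ---------------------------------------------------------------------------
# mature-site scanning and windows


def _hamming_scan(contig_seq: str, query_dna: str, max_mm: int) -> list[tuple[int, int]]:
    n, m = len(contig_seq), len(query_dna)
    if n < m:
        return []
    arr = np.frombuffer(contig_seq.encode(), dtype=np.uint8)
    q = np.frombuffer(query_dna.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(arr, m)
    mm = (windows != q).sum(axis=1)
    return [(int(p), int(mm[p])) for p in np.nonzero(mm <= max_mm)[0]]


def find_mature_site(
    contig: Contig, mature: str, max_mm: int = 3
) -> list[tuple[int, str, int]]:
    """All ungapped placements of a mature miRNA on either strand of a contig
    with at most ``max_mm`` Hamming mismatches (U and T equivalent).

    Returns (0-based position on the contig forward strand, strand, mismatches).
    """
    mature_dna = mature.upper().replace("U", "T")
    if not 15 <= len(mature_dna) <= 30:
        raise ValueError("mature sequence must be 15-30 nt")
    if set(mature_dna) - set("ACGT"):
        raise ValueError("degenerate bases in mature sequence")
    hits = [(p, "+", d) for p, d in _hamming_scan(contig.seq, mature_dna, max_mm)]
    rc = reverse_complement(mature_dna)
    hits += [(p, "-", d) for p, d in _hamming_scan(contig.seq, rc, max_mm)]
    return sorted(hits)


def extract_window(
    contig: Contig, hit_pos: int, window_len: int = 1000
) -> tuple[int, int, str]:
    """A window of at most ``window_len`` nt centered on ``hit_pos``, clipped
    and shifted at contig ends. Returns (start, end, subsequence), 0-based
    half-open."""
    n = len(contig)
    if not 0 <= hit_pos < n:
        raise ValueError(f"hit position {hit_pos} outside contig of length {n}")
    if n <= window_len:
        return 0, n, contig.seq
    start = hit_pos - window_len // 2
    start = max(0, min(start, n - window_len))
    return start, start + window_len, contig.seq[start : start + window_len]


# ---------------------------------------------------------------------------
# hairpin validation


def _terminal_loops(pairs: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Pairs that close a terminal loop (no pair nested inside them)."""
    loops = []
    for (i, j) in pairs:
        if not any(i < a and b < j for (a, b) in pairs):
            loops.append((i, j))
    return loops


def validate_hairpin(candidate: HairpinCandidate, cfg: MirnaConfig) -> HairpinCandidate:
    """Apply the programmatic stem-loop acceptance rules.

    Accepted iff (a) one terminal loop's enclosing stem holds at least
    ``min_stem_fraction`` of all pairs (a single predominant stem-loop),
    (b) the mature span lies entirely on one arm, (c) the mature matched
    with at most ``max_mature_mm`` mismatches, and (d) MFEI >= cutoff.
    Every failing rule is recorded in ``reasons``.
    """
    if len(candidate.structure) != len(candidate.precursor_seq):
        raise ValueError("structure/sequence length mismatch")
    reasons: list[str] = []
    pairs = pairs_from_dotbracket(candidate.structure)
    arm = None
    if not pairs:
        reasons.append("no_structure")
    else:
        loops = _terminal_loops(pairs)
        # stem of a terminal loop (i, j): pairs enclosing it, itself included
        best_loop, best_count = None, -1
        for (i, j) in loops:
            count = sum(1 for (a, b) in pairs if a <= i and b >= j)
            if count > best_count:
                best_loop, best_count = (i, j), count
        assert best_loop is not None
        if best_count / len(pairs) < cfg.min_stem_fraction:
            reasons.append("no_dominant_stem")
        li, lj = best_loop
        if candidate.mature_span is None:
            reasons.append("mature_not_found")
        else:
            ms, me = candidate.mature_span
            if ms < 0 or me > len(candidate.precursor_seq):
                raise ValueError("mature span outside precursor")
            if me > li + 1 and ms < lj:  # overlaps the terminal-loop interior
                reasons.append("mature_in_loop")
            elif me <= li + 1:
                arm = "5p"
            else:
                arm = "3p"
    if candidate.mature_span is not None and candidate.mature_mismatches > cfg.max_mature_mm:
        reasons.append("too_many_mature_mismatches")
    if candidate.mfei < cfg.mfei_cutoff:
        reasons.append("low_mfei")
    candidate.arm = arm
    candidate.reasons = reasons
    candidate.accepted = not reasons
    return candidate


def _window_gc(seq: str) -> float:
    counted = sum(seq.count(b) for b in "ACGT") + sum(seq.count(b) for b in "U")
    gc = seq.count("G") + seq.count("C")
    if counted == 0:
        raise ValueError("empty or all-N window")
    return 100.0 * gc / counted


def make_candidate(
    contig: Contig,
    window: tuple[int, int],
    mature: str,
    mature_pos: int | None,
    mature_mismatches: int,
    cfg: MirnaConfig,
    external_mfe: float | None = None,
) -> HairpinCandidate:
    """Fold a precursor window and assemble a scored, validated candidate.

    ``mature_pos`` is the mature hit position on the contig (forward
    coordinates); ``external_mfe`` overrides the folding model's energy
    (the structure is still taken from the fold).
    """
    start, end = window
    precursor = to_rna(contig.seq[start:end])
    structure, mfe = fold(precursor, cfg.min_loop)
    if external_mfe is not None:
        mfe = float(external_mfe)
    gc = _window_gc(precursor)
    span = None
    if mature_pos is not None:
        span = (mature_pos - start, mature_pos - start + len(mature))
    cand = HairpinCandidate(
        contig_id=contig.id,
        window=(start, end),
        precursor_seq=precursor,
        length_nt=len(precursor),
        gc_percent=round_half_up(gc, 1),
        structure=structure,
        mfe_kcal_mol=mfe,
        amfe=compute_amfe(mfe, len(precursor)),
        mfei=compute_mfei(mfe, len(precursor), gc),
        mature_seq=to_rna(mature),
        mature_mismatches=mature_mismatches,
        mature_span=span,
    )
    return validate_hairpin(cand, cfg)


def scan_hairpins(
    contigs: Iterable[Contig],
    matures: dict[str, str],
    cfg: MirnaConfig | None = None,
    external_mfe: dict[str, float] | None = None,
    report_missing: bool = False,
) -> list[tuple[str, HairpinCandidate]]:
    """Scan contigs for precursor candidates of each named mature miRNA.

    Returns (mature name, candidate) tuples. With ``report_missing`` a
    contig without any mature hit yields a rejected placeholder candidate
    (reason ``mature_not_found``) so negatives stay visible.
    """
    cfg = cfg or MirnaConfig()
    out: list[tuple[str, HairpinCandidate]] = []
    for contig in contigs:
        for name, mature in matures.items():
            hits = find_mature_site(contig, mature, cfg.max_mature_mm)
            if not hits:
                if report_missing:
                    cand = make_candidate(contig, (0, min(len(contig), cfg.window_len)),
                                          mature, None, 0, cfg,
                                          (external_mfe or {}).get(contig.id))
                    out.append((name, cand))
                continue
            pos, _strand, mm = min(hits, key=lambda h: h[2])
            window = extract_window(contig, pos + len(mature) // 2, cfg.window_len)[:2]
            cand = make_candidate(contig, window, mature, pos, mm, cfg,
                                  (external_mfe or {}).get(contig.id))
            out.append((name, cand))
    return out


# ---------------------------------------------------------------------------
# target prediction

_WOBBLE = {("G", "A"), ("T", "C")}  # (transcript base, revcomp-mature base)


def predict_targets(
    transcripts: Iterable[Contig],
    mature: str,
    cfg: MirnaConfig | None = None,
) -> list[TargetHit]:
    """Sites on transcripts complementary to the mature miRNA with weighted
    mismatches <= ``max_target_mm``; G:U wobble pairs weigh ``wobble_weight``."""
    cfg = cfg or MirnaConfig()
    rc = reverse_complement(mature.upper().replace("U", "T"))
    m = len(rc)
    hits: list[TargetHit] = []
    for tx in transcripts:
        seq = tx.seq
        for p in range(len(seq) - m + 1):
            site = seq[p : p + m]
            score = 0.0
            for t, r in zip(site, rc):
                if t == r:
                    continue
                score += cfg.wobble_weight if (t, r) in _WOBBLE else 1.0
                if score > cfg.max_target_mm:
                    break
            if score <= cfg.max_target_mm:
                hits.append(TargetHit(tx.id, (p, p + m), score, site, to_rna(mature)))
    return hits


def vienna_text(results: Iterable[tuple[str, HairpinCandidate]]) -> str:
    """Candidates in Vienna format: header, sequence, dot-bracket + MFE."""
    blocks = []
    for name, c in results:
        blocks.append(
            f">{name}|{c.contig_id}:{c.window[0]}-{c.window[1]}\n"
            f"{c.precursor_seq}\n{c.structure} ({c.mfe_kcal_mol:.1f})"
        )
    return "\n".join(blocks) + ("\n" if blocks else "")


def candidate_table(results: Iterable[tuple[str, HairpinCandidate]]) -> str:
    """TSV of candidates in the conventional report column order."""
    lines = ["family\tmature_seq\tmismatches\tlength_nt\tMFE\tGC%\tMFEI\tstatus"]
    for name, c in results:
        lines.append(
            f"{name}\t{c.mature_seq.lower()}\t{c.mature_mismatches}\t{c.length_nt}"
            f"\t{c.mfe_kcal_mol:.1f}\t{c.gc_percent:.1f}\t{c.mfei:.2f}\t{c.status}"
        )
    return "\n".join(lines) + "\n"
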