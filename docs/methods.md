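# Methods

This note documents the models, rules, and numerical choices behind each
module, what the synthetic-data generators do and do not emulate, and the
design decisions taken where more than one reasonable convention exists.

## Assembly metrics

N50 is the length at which the cumulative sum over contig lengths sorted
descending first reaches at least half the total assembly size; exact
halves qualify (no flooring). This is the standard convention; a
property test checks it against a brute-force restatement (largest L such
that contigs ≥ L hold at least half the assembly).

Pooled GC% excludes N from both numerator and denominator, so gap runs do
not dilute the estimate.

Estimated coverage is total read length divided by total assembly size.
Published summaries are often ambiguous about whether a read *pair*
contributes one or two read lengths; both dialects are exposed
(`counting={'pairs','reads'}`), with `pairs` the default because it is the
reading consistent with the coverage values this toolkit mirrors to within
one unit of the final one-decimal rounding. Reported decimals round half-up
at the printed precision; a residual one-ulp discrepancy against a
published value is documented rather than silently matched.

Gap runs are maximal runs of N reported with 1-based inclusive
coordinates; their lengths always sum to the contig's N count.

## RNA folding model

Precursor windows are folded with a maximum-weight nested-pairing dynamic
program: pair energies GC −3, AU −2, GU −1 kcal/mol, a minimum of 3
unpaired bases in any closed loop, and no pseudoknots. The recurrence over
intervals [i, j] considers i unpaired or i paired with any admissible k;
the optimum is exact and the traceback is deterministic (leave-unpaired
preferred, then the smallest partner index), so identical input gives an
identical dot-bracket.

This model trades thermodynamic fidelity (no stacking, no loop-size
penalties, no dangles) for exact solvability: the package ships an
independent exhaustive enumerator of all nested structures
(`mirna.fold_exhaustive`) and the test suite requires DP/enumeration
agreement on random short sequences. For fidelity, externally computed
energies (e.g. from a thermodynamic folder) can be supplied per precursor
and override the model's MFE while keeping its structure for geometry
checks. The DP fill is compiled with numba when available; a pure-Python
fill produces identical tables.

MFEI is computed from the unrounded AMFE and rounded half-up to two
decimals for reporting, matching the convention of the worked examples the
test suite pins (all ten published precursor rows reproduce exactly).

## Hairpin validation

Visual inspection of secondary structures is replaced by three
programmatic rules, applied after folding and mature-site matching:

* **single predominant stem-loop** — among the structure's terminal loops
  (pairs with nothing nested inside), the best loop's enclosing stem must
  hold at least 60% of all pairs (`min_stem_fraction`, configurable);
* **mature on one arm** — no base of the mature span may fall inside the
  predominant terminal loop; the arm (5p/3p) is recorded;
* **thresholds** — mature mismatches ≤ 3 and MFEI ≥ cutoff.

The MFEI cutoff defaults to 0.5: accepted published precursors include an
MFEI of 0.59, so 0.5 is a safe lower bound for the screening the toolkit
emulates; it is exposed as `--mfei-cutoff`. Precursor windows default to
1,000 nt centered on the mature hit (anchoring at the hit start is the
plausible alternative; centering was chosen and windows are clipped and
shifted at contig ends). DNA input is normalized to RNA on ingestion;
precursor outputs are RNA, contig outputs DNA.

Target prediction scans the transcript's sense strand for sites matching
the reverse complement of the mature sequence with weighted mismatches
≤ 3. G:U wobble pairs weigh `wobble_weight` (default 1.0, plain counting;
0.5 reproduces the convention of plant target-prediction servers —
whether the original screening weighted wobble is not recoverable, so
both are exposed).

## SNP filter cascade

The pileup parser implements the ten-column consensus dialect, decoding
read-start (`^` + quality), read-end (`$`), indel (`+n…`/`-n…`) and
deletion (`*`) markers, and fails loudly (with the line number) when the
decoded read count disagrees with the depth field. Both the consensus
quality and RMS mapping quality columns are parsed; rule 1 uses RMS by
default.

Conventions where the rule list admits more than one reading:

* **"mapping and SNP score more than 100"** — conjunctive by default
  (both > 100); `score_mode='sum'` flips to their sum.
* **"at least three non-reference alleles"** — read as ≥ 3 *reads*
  carrying a non-reference base; three distinct alleles would contradict
  the bi-allelic rule.
* **bi-allelic** — at most two alleles among those with ≥ 3 supporting
  reads, so sequencing-error singletons do not disqualify a true
  bi-allelic site (otherwise the 95% major+minor rule would be vacuous)
  and a weakly covered site failing the alt-read rule is not additionally
  charged with an allele-count failure. `strict_biallelic` counts every
  observed allele.
* **MAF** — second-most-frequent allele count over all reads; reported
  alt allele is the most frequent non-reference allele, ties broken
  alphabetically. Coordinates are 1-based throughout, matching pileup.
* **density rounding** — bp-per-SNP rounds half-up, the only convention
  consistent with the published pair of values the tests pin (1,123.34 →
  1,123 and 1,703.59 → 1,704). Zero passing SNPs reports "n/a", not an
  error.

All six rules are always evaluated and every failing rule id recorded, so
pass/fail is order-independent and violations are auditable.

## Isoform and ortholog rules

Family assignment consumes 12-column tabular homology hits (best bitscore
per contig and family, E-value ≤ 1e-10, identity ≥ 55%). Motif checks use
per-family regular expressions from an editable JSON config; the shipped
file is a synthetic default (clearly marked), since curated motifs are a
per-project input. Translation uses the standard code; partial codons at
contig ends are dropped; the ORF finder scans all six frames, prefers
ATG-initiated ORFs, and flags completeness only when an in-frame stop
follows.

Pair classification: a cross-species pair with global identity ≥ 99% at
both nucleotide and protein level is an ortholog pair; a pair sharing no
exact run longer than 16 nt is two distinct isoforms; anything in between
is reported as ambiguous rather than silently merged. Identity is
matches / alignment columns from a global alignment (match +1, mismatch
−1, gap −2, end gaps penalized) — chosen because the original "similarity"
figure came from a local-alignment tool whose exact parameters are not
recoverable; whether the 99% rule applied to full-length sequences or
aligned overlap only is likewise unstated, and full-length is implemented.
The longest-shared-exact-match uses a rolling dynamic program checked
against a brute-force substring oracle.

## Read partitioning

An exhaustive ungapped scan on both strands with a mismatch budget
(default 3) replaces a seed-heuristic short-read mapper: exact at desk
scale, and a k-mer index could accelerate it without changing results.
N in the reference never matches; N in a read always counts as a
mismatch (conservative). Reads are treated as single-end throughout.
Each read is attributed to the first tier of the reference cascade it
maps to; per-tier counts always sum to the input count, and reordering
tiers moves only reads mappable to multiple tiers.

## Synthetic data

The generators encode the study conditions the toolkit assumes: 51-bp
paired-end reads with 180–250 bp inserts, per-base substitution error
1% by default (typical of the short-read platform generation emulated;
no indels, no position-dependent error profile), contigs of a few hundred
to a few thousand nt.

* **Hairpin contigs** are flank + stem + loop + revcomp(stem) + flank.
  `make_hairpin_set` draws stems from {A,G} (a purine 5' arm): neither arm
  can then pair internally, the poly-A loop and {A,C} flanks are inert
  under the folding model, and the only full nested pairing of the two
  arms is the planted register — so the planted hairpin is provably the
  optimal fold and validation is deterministic. Reference matures carry a
  controlled number of substitutions relative to the planted arm,
  emulating a cross-species database mature. Real precursors have bulges,
  mixed-composition arms and competing structure; passing these tests
  shows the rules fire correctly, not that the simple energy model folds
  arbitrary real precursors as a thermodynamic folder would.
* **Pileups** draw depth Poisson around the mean; planted sites draw the
  alternative-allele count Binomial(depth, MAF), clamped to ≥ 1 read
  whenever MAF·depth ≥ 1 so planted truth is never silently absent. SNP
  quality is the monotone surrogate min(255, 10·alt reads) at planted
  sites and is kept below the putative cut at error-only sites; RMS
  mapping quality is 150 at planted sites, 50 elsewhere. These are
  controllable handles for exercising the ≥ 20 and > 100 cuts, not a
  model of a genotype-likelihood caller.
* **The filter benchmark** (`make_snp_benchmark`) embeds deterministic
  columns — passing columns satisfying all six rules by construction, and
  violators cycling through the rules, each breaking exactly one (e.g. the
  rule-4 violator has a third allele at ≥ 3 reads while keeping
  major+minor at 95%) — in a clean background, so recall and per-rule
  attribution are exact.
* **Isoform families** plant ortholog pairs as synonymous-substitution
  copies (third positions of four-fold degenerate codons only), which
  pins nucleotide identity at the target while conserving the protein
  exactly and never creating a stop. Distinct isoforms are independent
  random coding sequences rejection-sampled to share no exact run longer
  than 16 nt, mirroring the empirical observation the rule is based on —
  near-identical mutated copies could not satisfy it.
* **Substitutions in `make_isoform_family`** avoid the first/last 25 nt so
  window extraction near contig ends is unaffected.

All generators take a single seed and use one `numpy` generator per
invocation; identical configuration yields byte-identical output.

## Problem sizes

The shipped tests and benchmarks use desk-scale sizes chosen to exercise
every code path with planted truth: 10,000-column pileups with 100
planted passing SNPs and 100 single-rule violators, 50 positive and 50
negative hairpin contigs (~145 nt precursors), a 10-family isoform set
(~560 nt coding contigs), 100 random short sequences for the folding
oracle, 500 random pairs for the substring oracle, and 1,000 random
length lists for the N50 oracle. Counts tied to a real sequencing run
(contig totals, genome-wide SNP counts, mapping percentages) depend on
the underlying reads and are not reproduction targets; the mechanisms
are.

## Known limitations

* The folding model ignores stacking and loop entropies; MFEI values from
  it are comparable within the model, not against thermodynamic folders
  (use the external-MFE input for that).
* The stem-dominance threshold (60% of pairs behind one terminal loop)
  is a programmatic stand-in for visual inspection; borderline multi-loop
  precursors will be rejected.
* The pileup parser targets the consensus (ten-column) dialect only.
* Global-identity on very different-length sequences penalizes end gaps;
  use the overlap/local mode flag where that is not wanted.
* The naive mapper is exhaustive and therefore quadratic; it is meant for
  synthetic fixtures and small reference sets, not full sequencing runs.
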