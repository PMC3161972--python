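"""Folding model, MFEI scoring, hairpin validation, target prediction."""

import numpy as np
import pytest

from denovotx import mirna, simulate as sim
from denovotx.core import Contig, reverse_complement
from denovotx.mirna import MirnaConfig

# printed worked examples: (MFE kcal/mol, length nt, GC%, MFEI)
MFEI_ROWS = [
    (-68.9, 197, 41.1, 0.85),
    (-63.0, 146, 44.5, 0.97),
    (-23.4, 87, 39.1, 0.69),
    (-29.4, 88, 56.8, 0.59),
    (-40.0, 103, 48.5, 0.80),
    (-57.8, 127, 59.1, 0.77),
    (-59.6, 165, 40.6, 0.89),
    (-82.0, 182, 41.2, 1.09),
    (-63.8, 145, 44.1, 1.00),
    (-23.4, 87, 39.1, 0.69),
]


@pytest.mark.parametrize("mfe, length, gc, expected", MFEI_ROWS)
def test_mfei_worked_examples(mfe, length, gc, expected):
    assert mirna.compute_mfei(mfe, length, gc) == expected


@pytest.mark.parametrize(
    "mfe, length, expected",
    [(-68.9, 197, 34.97), (0, 100, 0.0), (-82.0, 182, 45.05)],
)
def test_amfe(mfe, length, expected):
    assert mirna.compute_amfe(mfe, length) == expected


def test_score_input_validation():
    with pytest.raises(ValueError):
        mirna.compute_amfe(-10, 0)
    with pytest.raises(ValueError):
        mirna.compute_mfei(-10, 100, 0)
    assert mirna.compute_mfei(0, 100, 50.0) == 0.0


class TestFold:
    def test_perfect_gc_stem(self):
        structure, mfe = mirna.fold("GGGAAAACCC")
        assert structure == "(((....)))" and mfe == -9.0

    def test_unpairable(self):
        assert mirna.fold("AAAAAAAA") == ("........", 0.0)

    def test_dna_input_normalized(self):
        # T is read as U, so a DNA hairpin folds identically
        assert mirna.fold("GGGAAAACCC") == mirna.fold("GGGAAAACCC".replace("U", "T"))

    def test_min_loop_respected(self):
        structure, _ = mirna.fold("GAAAC")  # loop of 3 is the minimum
        assert structure == "(...)"
        structure, mfe = mirna.fold("GAAC")
        assert mfe == 0.0

    def test_rejects_bad_alphabet_and_length(self):
        with pytest.raises(ValueError):
            mirna.fold("ACGX")
        with pytest.raises(ValueError):
            mirna.fold("A" * 2001)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            seq = sim.random_dna(rng, int(rng.integers(5, 15)))
            assert mirna.fold(seq)[1] == mirna.fold_exhaustive(seq), seq

    def test_structure_energy_consistent(self):
        # the reported MFE equals the sum of pair energies in the structure
        weights = {frozenset(p): -w for p, w in
                   {("G", "C"): 3, ("A", "U"): 2, ("G", "U"): 1}.items()}
        rng = np.random.default_rng(3)
        for _ in range(20):
            seq = mirna.to_rna(sim.random_dna(rng, 60))
            structure, mfe = mirna.fold(seq)
            total = sum(weights[frozenset((seq[i], seq[j]))]
                        for i, j in mirna.pairs_from_dotbracket(structure))
            assert total == mfe


class TestMatureSite:
    def test_exact_and_threshold(self):
        rng = np.random.default_rng(0)
        mature = sim.random_dna(rng, 21)
        bg = sim.random_dna(rng, 200)
        contig = Contig("c", bg[:90] + mature + bg[90:])
        hits = mirna.find_mature_site(contig, mature.replace("T", "U"), 0)
        assert (90, "+", 0) in hits
        # plant 3 substitutions: found at max_mm=3, not at 2
        mutated = list(mature)
        for p in (2, 9, 17):
            mutated[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[p]]
        query = "".join(mutated)
        assert (90, "+", 3) in mirna.find_mature_site(contig, query, 3)
        assert all(h[0] != 90 or h[1] != "+"
                   for h in mirna.find_mature_site(contig, query, 2))

    def test_reverse_strand(self):
        rng = np.random.default_rng(1)
        mature = sim.random_dna(rng, 21)
        contig = Contig("c", sim.random_dna(rng, 50) + reverse_complement(mature)
                        + sim.random_dna(rng, 50))
        assert (50, "-", 0) in mirna.find_mature_site(contig, mature, 0)

    def test_degenerate_mature_rejected(self):
        with pytest.raises(ValueError):
            mirna.find_mature_site(Contig("c", "ACGT" * 20), "ACGTNACGTACGTACGTACGT", 3)


@pytest.mark.parametrize(
    "contig_len, hit, expected",
    [(10_000, 5_000, (4_500, 5_500)), (300, 100, (0, 300)), (10_000, 10, (0, 1_000)),
     (10_000, 9_995, (9_000, 10_000))],
)
def test_extract_window(contig_len, hit, expected):
    contig = Contig("c", "A" * contig_len)
    start, end, seq = mirna.extract_window(contig, hit, 1000)
    assert (start, end) == expected and len(seq) == end - start


class TestValidateHairpin:
    def test_generated_hairpin_accepted(self):
        contigs, truths, matures = sim.make_hairpin_set(5, seed=17)
        for contig, truth, mature in zip(contigs, truths, matures):
            (_, cand), = mirna.scan_hairpins([contig], {"m": mature})
            assert cand.accepted, cand.reasons
            assert cand.arm == "5p"
            assert cand.mfei >= MirnaConfig().mfei_cutoff

    def test_mature_in_loop_rejected(self):
        contigs, truths, _ = sim.make_hairpin_set(1, seed=23, stem_len=30, loop_len=5)
        contig, truth = contigs[0], truths[0]
        # a "mature" straddling the terminal loop
        mstart = truth.window[0] + 30 - 10
        mature = contig.seq[mstart : mstart + 21]
        (_, cand), = mirna.scan_hairpins([contig], {"m": mature})
        assert not cand.accepted and "mature_in_loop" in cand.reasons

    def test_low_mfei_rejected(self):
        contigs, _, matures = sim.make_hairpin_set(1, seed=29)
        cfg = MirnaConfig(mfei_cutoff=99.0)
        (_, cand), = mirna.scan_hairpins(contigs, {"m": matures[0]}, cfg)
        assert not cand.accepted and "low_mfei" in cand.reasons

    def test_missing_mature_reported(self):
        contigs, _, matures = sim.make_hairpin_set(1, seed=31)
        shuffled = Contig("shuf", "".join(
            np.random.default_rng(0).permutation(list(contigs[0].seq))))
        results = mirna.scan_hairpins([shuffled], {"m": matures[0]},
                                      report_missing=True)
        assert len(results) == 1
        assert not results[0][1].accepted
        assert "mature_not_found" in results[0][1].reasons

    def test_structure_length_mismatch_errors(self):
        cand = mirna.HairpinCandidate(
            contig_id="c", window=(0, 4), precursor_seq="ACGU", length_nt=4,
            gc_percent=50, structure="...", mfe_kcal_mol=0, amfe=0, mfei=1,
            mature_seq="ACGU", mature_mismatches=0, mature_span=(0, 2))
        with pytest.raises(ValueError):
            mirna.validate_hairpin(cand, MirnaConfig())

    def test_raising_cutoff_never_accepts_more(self):
        contigs, _, matures = sim.make_hairpin_set(10, seed=37)
        matdict = {f"m{i}": m for i, m in enumerate(matures)}
        previous = None
        for cutoff in (0.2, 0.5, 0.9, 1.2, 2.0):
            cfg = MirnaConfig(mfei_cutoff=cutoff)
            n = sum(c.accepted for _, c in mirna.scan_hairpins(contigs, matdict, cfg))
            if previous is not None:
                assert n <= previous
            previous = n


class TestTargets:
    def test_exact_reverse_complement(self):
        rng = np.random.default_rng(5)
        mature = sim.random_dna(rng, 21).replace("T", "U")
        site = reverse_complement(mature.replace("U", "T"))
        tx = Contig("t", sim.random_dna(rng, 30) + site + sim.random_dna(rng, 30))
        hits = mirna.predict_targets([tx], mature)
        assert any(h.site == (30, 51) and h.mismatches == 0 for h in hits)

    def test_matches_string_search_at_zero_mm(self):
        rng = np.random.default_rng(6)
        mature = sim.random_dna(rng, 21)
        rc = reverse_complement(mature)
        tx = Contig("t", rc + sim.random_dna(rng, 100) + rc)
        cfg = MirnaConfig(max_target_mm=0)
        hits = mirna.predict_targets([tx], mature, cfg)
        expected = {i for i in range(len(tx.seq) - 20) if tx.seq[i : i + 21] == rc}
        assert {h.site[0] for h in hits} == expected

    def test_four_substitutions_rejected(self):
        rng = np.random.default_rng(7)
        mature = sim.random_dna(rng, 21)
        site = list(reverse_complement(mature))
        for p in (1, 6, 11, 16):  # avoid wobble-compatible substitutions
            site[p] = next(b for b in "ACGT"
                           if b != site[p] and (b, site[p]) not in mirna._WOBBLE)
        tx = Contig("t", "".join(site))
        assert mirna.predict_targets([tx], mature) == []

    def test_wobble_weighting(self):
        rng = np.random.default_rng(8)
        mature = sim.random_dna(rng, 21)
        rc = reverse_complement(mature)
        site = list(rc)
        # two true mismatches plus two G:U wobbles
        wob = [i for i, ch in enumerate(rc) if ch == "A"][0]
        wob2 = [i for i, ch in enumerate(rc) if ch == "C"][0]
        site[wob], site[wob2] = "G", "T"
        mms = [i for i in range(21) if i not in (wob, wob2)][:2]
        for p in mms:
            site[p] = next(b for b in "ACGT"
                           if b != rc[p] and (b, rc[p]) not in mirna._WOBBLE)
        tx = Contig("t", "".join(site))
        half = mirna.predict_targets([tx], mature, MirnaConfig(wobble_weight=0.5))
        assert [h.mismatches for h in half] == [3.0]  # 2 + 2*0.5, at threshold
        plain = mirna.predict_targets([tx], mature, MirnaConfig(wobble_weight=1.0))
        assert plain == []  # 4 plain mismatches


def test_vienna_output_consistent_with_candidates():
    contigs, _, matures = sim.make_hairpin_set(2, seed=43)
    results = mirna.scan_hairpins(contigs, {"fam": matures[0]})
    text = mirna.vienna_text(results)
    for _, cand in results:
        assert cand.precursor_seq in text and cand.structure in text


def test_candidate_table_format():
    contigs, _, matures = sim.make_hairpin_set(2, seed=41)
    results = mirna.scan_hairpins(contigs, {"fam": matures[0]})
    table = mirna.candidate_table(results)
    header = table.splitlines()[0].split("\t")
    assert header == ["family", "mature_seq", "mismatches", "length_nt",
                      "MFE", "GC%", "MFEI", "status"]
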