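import random

import pytest

from ltrkit.core_io import ElementRecord, GenomicSequence, TRNAEntry, TRNALibrary, revcomp
from ltrkit.ltr_struct import LTRPair
from ltrkit.pbs_typing import (
    _edit_costs,
    call_pbs,
    find_exact_pbs,
    find_fuzzy_pbs,
    find_half_trna_pbs,
    find_self_primer,
    prepare_trnas,
)
from ltrkit.synth_fixtures import random_dna

from oracles import fuzzy_edit_oracle


def _element(downstream, ltr=None, rng_seed=0):
    """Element whose 5' LTR ends right before `downstream`."""
    rng = random.Random(rng_seed)
    ltr = ltr or ("TG" + random_dna(rng, 296) + "CA")
    residues = ltr + downstream + random_dna(rng, 60)
    n = len(residues)
    rec = ElementRecord(GenomicSequence("e", residues))
    rec.ltr = LTRPair((0, len(ltr)), (n - len(ltr), n), 100.0, True)
    return rec


@pytest.fixture()
def met(trnas):
    return next(t for t in trnas if t.isoacceptor == "tRNA-Met")


@pytest.fixture()
def ile(trnas):
    return next(t for t in trnas if t.isoacceptor == "tRNA-Ile")


class TestPrepareTrnas:
    def test_cca_appended(self):
        lib = TRNALibrary([TRNAEntry("t1", "tRNA-Met", "ACGTACGGT", 3)])
        out = prepare_trnas(lib)
        assert out.entries[0].residues == "ACGTACGGTCCA"

    def test_existing_cca_untouched(self):
        lib = TRNALibrary([TRNAEntry("t1", "tRNA-Met", "ACGTACCCA", 3)])
        assert prepare_trnas(lib).entries[0].residues == "ACGTACCCA"

    def test_idempotent(self, trnas):
        once = prepare_trnas(trnas)
        twice = prepare_trnas(once)
        assert [t.residues for t in once] == [t.residues for t in twice]
        assert all(t.residues.endswith("CCA") for t in once)


class TestExactPbs:
    def test_fourteen_bp_match_called(self, trnas, met):
        el = _element(revcomp(met.residues[-14:]) + random_dna(random.Random(1), 30))
        call = find_exact_pbs(el, trnas)
        assert call is not None
        assert call.mode == "full_tRNA"
        assert call.isoacceptor == "tRNA-Met"
        assert call.match_len >= 14
        assert call.diffs == call.indels == 0

    def test_eleven_bp_best_match_is_absent(self, met):
        eleven = revcomp(met.residues[-11:])
        # block extension on both sides of the planted 11-mer
        before = next(b for b in "ACGT" if b != revcomp(met.residues[-1]))
        after = next(b for b in "ACGT" if b != revcomp(met.residues[-12:])[-1])
        el = _element(before + eleven + after + random_dna(random.Random(2), 30))
        assert find_exact_pbs(el, TRNALibrary([met])) is None

    def test_tie_broken_by_offset_then_id(self):
        rng = random.Random(3)
        t_end = random_dna(rng, 60) + "GGT"
        a = TRNAEntry("a_trna", "tRNA-Ala", t_end, 30)
        b = TRNAEntry("b_trna", "tRNA-Arg", t_end, 30)  # identical 3' end
        lib = prepare_trnas(TRNALibrary([a, b]))
        el = _element(revcomp(lib.entries[0].residues[-13:]) + random_dna(rng, 30))
        call = find_exact_pbs(el, lib)
        assert call.trna_id == "a_trna"  # lexicographic tie-break

    def test_missing_ltr_is_error(self, trnas):
        rec = ElementRecord(GenomicSequence("e", "ACGT" * 100))
        with pytest.raises(ValueError, match="5. LTR"):
            find_exact_pbs(rec, trnas)


class TestFuzzyPbs:
    def _single(self, trna):
        return TRNALibrary([trna])

    def test_two_substitutions_accepted(self, met):
        pbs = list(revcomp(met.residues[-18:]))
        for p in (5, 11):
            pbs[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[pbs[p]]
        el = _element("".join(pbs) + random_dna(random.Random(4), 30))
        call = find_fuzzy_pbs(el, self._single(met))
        assert call is not None and call.mode == "fuzzy_tRNA"
        assert (call.diffs, call.indels) == (2, 0)

    def test_substitution_plus_indel_accepted(self, met):
        pbs = list(revcomp(met.residues[-18:]))
        pbs[6] = {"A": "C", "C": "A", "G": "T", "T": "G"}[pbs[6]]
        pbs.insert(10, "A" if pbs[10] != "A" else "C")  # 1 bp insertion
        el = _element("".join(pbs[:18]) + random_dna(random.Random(5), 30))
        call = find_fuzzy_pbs(el, self._single(met))
        assert call is not None
        assert call.diffs + call.indels <= 2 and call.indels == 1

    def test_three_substitutions_rejected(self, met):
        pbs = list(revcomp(met.residues[-18:]))
        for p in (5, 9, 13):
            pbs[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[pbs[p]]
        el = _element("".join(pbs) + random_dna(random.Random(6), 30))
        assert find_fuzzy_pbs(el, self._single(met)) is None

    def test_requires_tgg_near_ltr(self, met):
        pbs = revcomp(met.residues[-18:])  # starts TGG
        el = _element(random_dna(random.Random(7), 8).replace("T", "A") + pbs)
        # TGG now starts at offset 8 > 5: no seed
        assert find_fuzzy_pbs(el, self._single(met)) is None

    def test_edit_costs_match_exhaustive_oracle(self):
        rng = random.Random(8)
        for _ in range(200):
            q = random_dna(rng, 18)
            r = list(q)
            for i in rng.sample(range(18), rng.randrange(0, 4)):
                r[i] = rng.choice([b for b in "ACGT" if b != r[i]])
            if rng.random() < 0.5:
                pos = rng.randrange(18)
                r.insert(pos, rng.choice("ACGT"))
                r = r[:18]
            r = "".join(r)
            subs, indels = _edit_costs(q, r, 2)
            o_subs, o_indels = fuzzy_edit_oracle(q, r)
            total, o_total = subs + indels, o_subs + o_indels
            if o_total <= 2:  # decision region: counts must agree exactly
                assert (total, indels) == (o_total, o_indels), (q, r)
            else:
                assert total > 2 or indels > o_indels


class TestHalfTrnaPbs:
    def test_match_ending_in_cleavage_window(self, trnas, met):
        c = met.anticodon_start + 1
        el = _element(revcomp(met.residues[c - 13 : c]) + random_dna(random.Random(9), 30))
        call = find_half_trna_pbs(el, trnas)
        assert call is not None
        assert call.mode == "half_tRNA"
        assert call.isoacceptor == "tRNA-Met"
        assert call.match_len >= 13

    def test_match_ending_before_window_rejected(self, met):
        c = met.anticodon_start - 10  # well before the cleavage window
        el = _element(revcomp(met.residues[c - 13 : c]) + random_dna(random.Random(10), 30))
        assert find_half_trna_pbs(el, TRNALibrary([met])) is None

    def test_edited_position_pairs_like_inosine(self, ile):
        c = ile.anticodon_start + 1
        pbs = list(revcomp(ile.residues[c - 13 : c]))
        pbs[0] = "C"  # inosine at the wobble base pairs with C
        el = _element("".join(pbs) + random_dna(random.Random(11), 30))
        call = find_half_trna_pbs(el, TRNALibrary([ile]))
        assert call is not None and call.isoacceptor == "tRNA-Ile"


class TestSelfPrimer:
    def _with_plant(self, plant_len, rng_seed=12):
        rng = random.Random(rng_seed)
        down = random_dna(rng, plant_len)
        cont = random_dna(rng, 30)  # sequence following the planted region
        # guard base left of the plant blocks chance extension of the
        # complementary run beyond the planted length
        guard = next(b for b in "ACGT" if b != revcomp(cont[0]))
        ltr = "TG" + random_dna(rng, 140) + guard + revcomp(down) + random_dna(rng, 139) + "CA"
        return _element(down + cont, ltr=ltr), down

    def test_twelve_bp_complement_in_ltr(self):
        el, _ = self._with_plant(12)
        call = find_self_primer(el)
        assert call is not None and call.mode == "self"
        assert call.match_len >= 12

    def test_nine_bp_complement_rejected(self):
        el, _ = self._with_plant(9)
        call = find_self_primer(el)
        assert call is None or call.match_len >= 10  # a 9 bp run never qualifies

    def test_complement_outside_ltr_rejected(self):
        rng = random.Random(13)
        down = random_dna(rng, 12)
        # complement sits downstream of the LTR, not inside it
        el = _element(down + random_dna(rng, 10) + revcomp(down), rng_seed=13)
        assert find_self_primer(el) is None


class TestCallPrecedence:
    def test_full_beats_self(self, trnas, met):
        rng = random.Random(14)
        down = revcomp(met.residues[-14:])
        ltr = "TG" + random_dna(rng, 140) + revcomp(down[:12]) + random_dna(rng, 142) + "CA"
        el = _element(down + random_dna(rng, 30), ltr=ltr)
        assert find_self_primer(el) is not None  # both detectors fire
        assert call_pbs(el, trnas).mode == "full_tRNA"

    def test_self_only(self, trnas):
        rng = random.Random(15)
        down = random_dna(rng, 12)
        ltr = "TG" + random_dna(rng, 140) + revcomp(down) + random_dna(rng, 142) + "CA"
        el = _element(down + random_dna(rng, 30), ltr=ltr)
        assert call_pbs(el, trnas).mode == "self"

    def test_nothing_detected_is_none(self, trnas):
        el = _element(random_dna(random.Random(16), 50))
        call = call_pbs(el, trnas)
        assert call.mode in ("none", "self", "fuzzy_tRNA")  # random DNA: usually none
        # with this seed nothing fires
        assert call.mode == "none"

    def test_translation_equivariance(self, trnas, met):
        """Shifting the LTR end annotation by +k shifts the PBS interval by +k."""
        rng = random.Random(17)
        ltr = "TG" + random_dna(rng, 296) + "CA"
        down = revcomp(met.residues[-14:]) + random_dna(rng, 40)
        for k in (0, 7):
            residues = random_dna(random.Random(99), k) + ltr + down
            rec = ElementRecord(GenomicSequence("e", residues))
            rec.ltr = LTRPair((k, k + 300), (len(residues) - 10, len(residues)), 100.0, True)
            call = find_exact_pbs(rec, trnas)
            assert call.pbs_interval == (k + 300, k + 300 + call.match_len)

    def test_calls_respect_config_bounds(self, annotated_small):
        records, _ = annotated_small
        for rec in records:
            if rec.pbs is None:
                continue
            assert rec.pbs.diffs + rec.pbs.indels <= 2
            assert rec.pbs.indels <= 1
            if rec.pbs.mode in ("full_tRNA", "half_tRNA"):
                assert rec.pbs.match_len >= 12
            if rec.pbs.mode == "self":
                assert rec.pbs.match_len >= 10
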