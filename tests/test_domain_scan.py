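import random

import pytest
from hypothesis import given, strategies as st

from ltrkit.core_io import GenomicSequence, revcomp
from ltrkit.domain_scan import (
    DomainCall,
    ProteinHit,
    chain_hits,
    local_align,
    scan_domains,
    six_frame_translate,
    translate,
    validate_architecture,
)
from ltrkit.synth_fixtures import random_dna, random_protein, reverse_translate

from oracles import blosum, sw_affine_score

dna_strings = st.text(alphabet="ACGT", min_size=3, max_size=60)


class TestSixFrameTranslate:
    def test_simple_codons(self):
        assert translate("ATGGCC") == "MA"
        assert translate("TAA") == "*"
        assert translate("ATN") == "X"  # ambiguous codon

    @given(dna_strings)
    def test_reverse_complement_swaps_frames(self, dna):
        fwd = six_frame_translate(dna)
        rev = six_frame_translate(revcomp(dna))
        for f in (1, 2, 3):
            assert rev[f] == fwd[-f]
            assert rev[-f] == fwd[f]

    def test_frame_offsets(self):
        frames = six_frame_translate("AATGGCC")
        assert frames[2] == "MA"  # frame +2 skips the leading base


class TestLocalAlign:
    def test_identical_sequences_score_is_blosum_diagonal_sum(self):
        p = random_protein(random.Random(1), 50)
        score, identity, q_iv, r_iv = local_align(p, p)
        assert identity == 100.0
        assert score == pytest.approx(sum(blosum(a, a) for a in p))
        assert q_iv == r_iv == (0, 50)

    def test_all_negative_pairs_floor_at_zero(self):
        score, identity, q_iv, r_iv = local_align("WWWWW", "PPPPP")
        assert score == 0.0
        assert q_iv == r_iv == (0, 0)

    @pytest.mark.parametrize("seed", [2, 3, 4, 5, 6])
    def test_scores_match_dp_oracle(self, seed):
        rng = random.Random(seed)
        a = random_protein(rng, rng.randrange(30, 120))
        if seed % 2:  # related pair
            b = list(a)
            for i in rng.sample(range(len(a)), len(a) // 4):
                b[i] = rng.choice("ACDEFGHIKLMNPQRSTVWY")
            b = "".join(b)
        else:
            b = random_protein(rng, rng.randrange(30, 120))
        score, *_ = local_align(a, b)
        assert score == pytest.approx(sw_affine_score(a, b))


class TestScanDomains:
    def test_exact_cassettes_recovered_at_identity_100(self, annotated_small):
        records, manifests = annotated_small
        for rec, m in zip(records, manifests):
            by_type = {c.domain_type: c for c in rec.architecture.calls}
            for dtype, start, end in m.domains:
                assert dtype in by_type, (rec.seq.id, dtype)
                call = by_type[dtype]
                assert call.identity == 100.0
                assert call.dna_interval == (start, end)
                assert call.lineage == m.lineage_path

    def test_frameshift_splits_hit_and_chaining_restores_it(self, refdb):
        rng = random.Random(33)
        entry = next(e for e in refdb.entries if e.domain_type == "RT")
        cassette = reverse_translate(rng, entry.protein)
        mid = len(cassette) // 2
        broken = cassette[:mid] + cassette[mid + 1 :]  # 1 bp deletion
        seq = GenomicSequence("fs", random_dna(rng, 120) + broken + random_dna(rng, 120))
        hits = scan_domains(seq, refdb)
        rt_same_ref = [h for h in hits if h.ref_entry == entry.name]
        assert len(rt_same_ref) == 2
        assert len({h.frame for h in rt_same_ref}) == 2  # adjacent frames
        calls = chain_hits(hits)
        rt_calls = [c for c in calls if c.domain_type == "RT"]
        assert len(rt_calls) == 1
        assert rt_calls[0].support == 2
        # chained call covers the union of its constituents and outscores them
        lo = min(h.dna_interval[0] for h in rt_same_ref)
        hi = max(h.dna_interval[1] for h in rt_same_ref)
        assert rt_calls[0].dna_interval[0] <= lo and rt_calls[0].dna_interval[1] >= hi
        assert rt_calls[0].score >= max(h.score for h in rt_same_ref)

    def test_random_dna_yields_no_hits(self, refdb):
        seq = GenomicSequence("noise", random_dna(random.Random(44), 4000))
        assert scan_domains(seq, refdb) == []

    def test_reverse_strand_domain_mapped_back(self, refdb):
        rng = random.Random(55)
        entry = next(e for e in refdb.entries if e.domain_type == "INT")
        cassette = reverse_translate(rng, entry.protein)
        seq = GenomicSequence(
            "rc", random_dna(rng, 90) + revcomp(cassette) + random_dna(rng, 90)
        )
        hits = [h for h in scan_domains(seq, refdb) if h.ref_entry == entry.name]
        assert hits and hits[0].frame < 0
        s, e = hits[0].dna_interval
        assert (s, e) == (90, 90 + len(cassette))
        assert translate(revcomp(seq.residues[s:e])) == entry.protein


def _hit(dtype, dna, ref, frame=1, score=500.0, name=None):
    return ProteinHit(
        ref_entry=name or f"Ty3-{dtype}__X_v1",
        domain_type=dtype,
        lineage="Ty3/gypsy|chromovirus|CRM",
        dna_interval=dna,
        frame=frame,
        score=score,
        identity=90.0,
        ref_interval=ref,
        protein="A" * ((ref[1] - ref[0])),
    )


class TestChainHits:
    def test_overlapping_weaker_type_dropped(self):
        rt = _hit("RT", (1000, 1800), (0, 260), score=900)
        rh = _hit("RH", (1050, 1750), (0, 230), score=300)
        calls = chain_hits([rt, rh])
        assert [c.domain_type for c in calls] == ["RT"]

    def test_distant_same_type_hits_stay_separate(self):
        a = _hit("RT", (1000, 1700), (0, 230))
        b = _hit("RT", (4000, 4700), (0, 230))
        calls = chain_hits([a, b])
        assert len(calls) == 2
        arch = validate_architecture(calls)
        assert "duplicate_domain" in arch.flags


class TestValidateArchitecture:
    def _calls(self, order, prefix="Ty3"):
        pos = 0
        calls = []
        for d in order:
            calls.append(
                DomainCall(d, (pos, pos + 300), "+", f"{prefix}-{d}__X_v1",
                           "Ty3/gypsy|chromovirus|CRM", 500.0, 99.0, 1)
            )
            pos += 300
        return calls

    def test_copia_order_without_gag(self):
        arch = validate_architecture(self._calls(["PROT", "INT", "RT", "RH"], "Ty1"))
        assert arch.superfamily == "Ty1/copia"
        assert "missing_GAG" in arch.flags
        assert "bad_order" not in arch.flags

    def test_gypsy_order_with_arh_between_rh_and_int(self):
        arch = validate_architecture(self._calls(["GAG", "PROT", "RT", "RH", "aRH", "INT"]))
        assert arch.superfamily == "Ty3/gypsy"
        assert arch.arh_position == "RH_INT"

    def test_arh_between_prot_and_rt(self):
        arch = validate_architecture(self._calls(["GAG", "PROT", "aRH", "RT", "RH", "INT"]))
        assert arch.arh_position == "PROT_RT"

    def test_arh_after_int(self):
        arch = validate_architecture(self._calls(["GAG", "PROT", "RT", "RH", "INT", "aRH"]))
        assert arch.arh_position == "after_INT"

    def test_unexpected_order_flagged(self):
        arch = validate_architecture(self._calls(["GAG", "PROT", "RT", "INT", "RH"]))
        assert arch.superfamily == "undetermined"
        assert "bad_order" in arch.flags

    def test_mixed_superfamily_best_hits_flag_chimera(self):
        calls = self._calls(["GAG", "PROT", "RT", "RH", "INT"])
        calls[2] = DomainCall("RT", calls[2].dna_interval, "+", "Ty1-RT__Y_v1",
                              "Ty1/copia|Ale", 500.0, 99.0, 1)
        arch = validate_architecture(calls)
        assert "chimera" in arch.flags

    def test_empty_calls_undetermined(self):
        arch = validate_architecture([])
        assert arch.superfamily == "undetermined"
        assert "no_polyprotein" in arch.flags

    def test_corpus_superfamilies_match_generation(self, annotated_small):
        records, manifests = annotated_small
        for rec, m in zip(records, manifests):
            assert rec.architecture.superfamily == m.superfamily
            assert rec.architecture.arh_position == m.arh_position
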