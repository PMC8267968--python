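"""Edit reconciliation, translation and truncation prediction.

Brute-force oracles live in this file: an exhaustive contiguous-edit
decomposer and a from-scratch codon table, both independent of the
implementation paths they check.
"""

import random

import pytest
from hypothesis import given, strategies as st

from retphen import edits as ed
from retphen import fixtures as fx
from retphen.edits import (EditDescription, IdenticalSequencesError, MultipleEditsError,
                           NucSequence, PrimerSiteError)

# -- independent oracles ----------------------------------------------------

_BASES = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {a + b + c: _AAS[16 * i + 4 * j + k]
               for i, a in enumerate(_BASES)
               for j, b in enumerate(_BASES)
               for k, c in enumerate(_BASES)}


def oracle_translate(seq: str) -> str:
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aa = CODON_TABLE[seq[i:i + 3]]
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)


def oracle_minimal_edits(wt: str, edited: str):
    """All contiguous-edit decompositions of minimal total size."""
    best, out = None, []
    for p in range(len(wt) + 1):
        for dlen in range(len(wt) - p + 1):
            ilen = len(edited) - (len(wt) - dlen)
            if ilen < 0 or p + ilen > len(edited):
                continue
            ins = edited[p:p + ilen]
            if wt[:p] + ins + wt[p + dlen:] == edited:
                size = dlen + ilen
                if best is None or size < best:
                    best, out = size, []
                if size == best:
                    out.append((p + 1, wt[p:p + dlen], ins))
    return out


# -- reconciliation ---------------------------------------------------------

class TestReconcile:
    def test_printed_knockin_oligos(self):
        """The published guide/donor pair decomposes to del TCAA / ins AGT at c.10."""
        e = ed.reconcile_edit(fx.wildtype_orf_region(), fx.edited_orf_region())
        assert (e.position, e.deleted, e.inserted) == (10, "TCAA", "AGT")
        assert e.net_change == -1

    def test_identical_sequences_signal(self):
        s = NucSequence("a", "ATGCGT")
        with pytest.raises(IdenticalSequencesError):
            ed.reconcile_edit(s, NucSequence("b", "ATGCGT"))

    def test_disjoint_differences_rejected(self):
        # two substitutions separated by a long identical run
        wt = NucSequence("wt", "A" * 5 + "C" + "GATTACA" * 3 + "C" + "A" * 5)
        mut = NucSequence("mut", "A" * 5 + "T" + "GATTACA" * 3 + "T" + "A" * 5)
        with pytest.raises(MultipleEditsError):
            ed.reconcile_edit(wt, mut)

    @pytest.mark.parametrize("seed", range(8))
    def test_planted_edit_matches_bruteforce_oracle(self, seed):
        r = random.Random(seed)
        wt = "".join(r.choice("ACGT") for _ in range(60))
        p = r.randrange(10, 48)
        dlen = r.choice([1, 2, 3, 4])
        ins = "".join(r.choice("ACGT") for _ in range(r.choice([0, 1, 2, 3])))
        edited = wt[:p] + ins + wt[p + dlen:]
        if edited == wt:
            return
        got = ed.reconcile_edit(NucSequence("wt", wt), NucSequence("ed", edited))
        oracle = oracle_minimal_edits(wt, edited)
        assert (got.position, got.deleted, got.inserted) in oracle
        assert len(got.deleted) + len(got.inserted) == len(oracle[0][1]) + len(oracle[0][2])

    @given(st.text("ACGT", min_size=20, max_size=60), st.data())
    def test_apply_reconcile_round_trip(self, wt, data):
        p = data.draw(st.integers(1, len(wt) - 5))
        dlen = data.draw(st.integers(0, min(4, len(wt) - p)))
        ins = data.draw(st.text("ACGT", max_size=4))
        try:
            e = EditDescription(position=p, deleted=wt[p - 1:p - 1 + dlen], inserted=ins)
        except ValueError:
            return  # empty edit drawn
        seq = NucSequence("wt", wt)
        out = ed.apply_edit(seq, e)
        assert len(out.bases) == len(wt) + e.net_change
        try:
            back = ed.reconcile_edit(seq, out)
        except (IdenticalSequencesError, MultipleEditsError):
            return  # no-op or ambiguous edit; round trip undefined
        assert back.net_change == e.net_change
        assert ed.apply_edit(seq, back).bases == out.bases

    def test_apply_edit_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            ed.apply_edit(NucSequence("s", "ATGCCC"), EditDescription(2, deleted="AA"))


# -- translation and synonymy ----------------------------------------------

class TestTranslate:
    def test_lrat_first_codons(self):
        assert ed.translate(NucSequence("s", "ATGAAGAACTCA", "coding")) == "MKNS"

    def test_immediate_stop(self):
        assert ed.translate(NucSequence("s", "ATGTAA", "coding")) == "M"

    def test_requires_atg_in_coding_frame(self):
        with pytest.raises(ValueError, match="ATG"):
            ed.translate(NucSequence("s", "TTGAAA", "coding"))

    @given(st.text("ACGT", min_size=3, max_size=300))
    def test_matches_codon_table_oracle(self, s):
        got = ed.translate(NucSequence("s", s, "raw"))
        assert got == oracle_translate(s)


class TestSynonymy:
    def test_printed_silent_ser4(self):
        """Codon 4 of the knock-in: TCA→AGT, both serine."""
        out = ed.check_synonymy(fx.wildtype_orf_region(), fx.edited_orf_region(), 4)
        assert out == "synonymous"

    def test_identical_codons(self):
        wt = NucSequence("a", "ATGAAGAACTCA", "coding")
        assert ed.check_synonymy(wt, NucSequence("b", "ATGAAGAACTCG", "coding"), 2) == "synonymous"

    def test_missense(self):
        wt = NucSequence("a", "ATGTCAGGG", "coding")
        mut = NucSequence("b", "ATGGCAGGG", "coding")
        assert ed.check_synonymy(wt, mut, 2) == "missense"

    def test_codon_past_frameshift_is_frame_disrupted(self):
        wt = fx.wildtype_orf_region()
        edited = fx.edited_orf_region()
        assert ed.check_synonymy(wt, edited, 6) == "frame-disrupted"


# -- truncation prediction --------------------------------------------------

class TestTruncation:
    def test_toy_deletion_matches_translate_oracle(self):
        wt = "ATGGCTACTGGATTTAAGCTACCCGGGAAA"  # 10 codons, no stop
        for pos in (5, 8, 13):
            e = EditDescription(position=pos, deleted=wt[pos - 1])
            mutated = wt[:pos - 1] + wt[pos:]
            expect_prot = oracle_translate(mutated)
            wt_prot = oracle_translate(wt)
            fs = next(i for i, (a, b) in enumerate(zip(wt_prot, expect_prot + "*")) if a != b) + 1
            r = ed.predict_truncation(NucSequence("toy", wt, "coding"), e)
            assert r.protein_length == len(expect_prot)
            assert r.fs_codon == fs
            assert r.protein_length == r.fs_codon - 1 + r.stop_offset - 1

    def test_rat_c12dela_truncates_to_72_aa(self):
        """Frameshift after Ser4 on the rat CDS stand-in: 72-aa product."""
        cds = fx.load_fixture("synthetic_rat_lrat_cds")
        r = ed.predict_truncation(cds, fx.RAT_C12DELA)
        assert r.protein_length == 72
        assert (r.fs_codon, r.wt_residue, r.new_residue) == (5, "M", "C")

    def test_human_c12delc_truncates_to_57_aa(self):
        """Human stand-in: 57-aa product, fsX53 under the downstream-count label."""
        cds = fx.load_fixture("synthetic_human_lrat_cds")
        r = ed.predict_truncation(cds, fx.HUMAN_C12DELC)
        assert r.protein_length == 57
        assert r.hgvs_p_downstream == "p.M5CfsX53"
        assert r.hgvs_p == "p.M5CfsTer54"

    def test_compound_knockin_equals_pure_deletion(self):
        cds = fx.load_fixture("synthetic_rat_lrat_cds")
        a = ed.predict_truncation(cds, fx.KNOCKIN_EDIT)
        b = ed.predict_truncation(cds, fx.RAT_C12DELA)
        assert (a.protein_length, a.fs_codon, a.new_residue) == \
            (b.protein_length, b.fs_codon, b.new_residue)

    @pytest.mark.parametrize("deleted", ["GCT", "GCTACT"])
    def test_in_frame_edit_rejected(self, deleted):
        cds = NucSequence("toy", "ATGGCTACTGGATTTAAGCTACCCGGGAAA", "coding")
        with pytest.raises(ValueError, match="in-frame"):
            ed.predict_truncation(cds, EditDescription(position=4, deleted=deleted))


# -- variant normalization --------------------------------------------------

class TestNormalizeVariant:
    def test_knockin_reduces_to_c12dela(self):
        cds = fx.load_fixture("synthetic_rat_lrat_cds")
        nv = ed.normalize_variant(fx.KNOCKIN_EDIT, cds)
        assert nv.form_5prime == "c.12delA"
        assert nv.form_3prime == "c.13delA"
        assert nv.silent_codons == (4,)

    def test_already_minimal_edit_passthrough_form(self):
        cds = NucSequence("toy", "ATGGCTACTGGATTTAAGCTACCCGGGAAA", "coding")
        nv = ed.normalize_variant(EditDescription(position=5, deleted="C"), cds)
        assert nv.form_5prime == "c.5delC" == nv.form_3prime
        assert nv.silent_codons == ()

    def test_homopolymer_deletion_shifts_3prime(self):
        wt = "ATGGCTAAAAAACCCGGGTTTACT"  # A run at c.7-12
        cds = NucSequence("toy", wt, "coding")
        nv = ed.normalize_variant(EditDescription(position=8, deleted="A"), cds)
        assert nv.form_3prime == "c.12delA"
        # brute-force: deleting any A of the run yields the same product
        products = {wt[:p - 1] + wt[p:] for p in range(7, 13)}
        assert len(products) == 1

    def test_non_unit_edit_passes_through(self):
        cds = NucSequence("toy", "ATGGCTACTGGATTTAAGCTACCCGGGAAA", "coding")
        e = EditDescription(position=4, deleted="GCT")
        assert ed.normalize_variant(e, cds) is e


# -- amplicon arithmetic ----------------------------------------------------

class TestAmplicon:
    @staticmethod
    def _template(seed=7):
        r = random.Random(seed)
        t = "".join(r.choice("ACGT") for _ in range(100))
        fwd = t[10:30]
        rev = ed._revcomp(t[70:90])
        return NucSequence("t", t), fwd, rev

    def test_planted_primers_80_bp(self):
        t, fwd, rev = self._template()
        assert ed.amplicon_size(t, fwd, rev) == 80

    def test_absent_primer_errors(self):
        t, _, rev = self._template()
        with pytest.raises(PrimerSiteError, match="0 binding sites"):
            ed.amplicon_size(t, "A" * 25, rev)

    def test_multiple_sites_error_lists_them(self):
        t = NucSequence("t", "GATTACAGGG" * 3 + "CCCCCCCC")
        with pytest.raises(PrimerSiteError):
            ed.amplicon_size(t, "GATTACA", "GGGGGGGG")


# -- packaged fixtures ------------------------------------------------------

class TestFixtures:
    def test_printed_oligo_lengths(self):
        assert len(fx.SGRNA_PROTOSPACER) == 20
        assert len(fx.SSODN_DONOR) == 94
        assert fx.load_fixture("sgrna_protospacer").bases == "AAGGATGAAGAACTCAATGC"

    def test_regeneration_is_byte_identical_to_packaged_files(self):
        regen = fx.make_fixture_sequences()
        for name, seq in regen.items():
            assert fx.load_fixture(name).bases == seq.bases

    def test_cds_standins_are_full_orfs(self):
        for name in ("synthetic_rat_lrat_cds", "synthetic_human_lrat_cds"):
            cds = fx.load_fixture(name)
            assert len(cds.bases) == 693
            assert len(ed.translate(cds)) == 230
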