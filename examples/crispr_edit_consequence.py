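"""Characterize the Lrat knock-in from the published oligo sequences.

Reconciles the wildtype ORF region against the ssODN donor product,
reduces the compound edit to its minimal single-base form, and predicts
the frameshift consequence on both species' coding sequences.
"""

from retphen import edits as ed
from retphen import fixtures as fx

wt = fx.wildtype_orf_region()
donor = fx.edited_orf_region()

e = ed.reconcile_edit(wt, donor)
print(f"reconciled edit : {e.hgvs_c()}  (deleted {e.deleted}, inserted {e.inserted}, "
      f"net {e.net_change:+d} nt)")
print(f"codon 4 effect  : {ed.check_synonymy(wt, donor, 4)} (Ser -> Ser)")

rat = fx.load_fixture("synthetic_rat_lrat_cds")
nv = ed.normalize_variant(e, rat)
print(f"minimal form    : {nv.form_5prime} (strict 3'-shifted: {nv.form_3prime}), "
      f"silent codon(s) {nv.silent_codons}")

for name, edit in (("rat  ", fx.RAT_C12DELA), ("human", fx.HUMAN_C12DELC)):
    cds = fx.load_fixture(f"synthetic_{name.strip()}_lrat_cds")
    r = ed.predict_truncation(cds, edit)
    print(f"{name} {edit.hgvs_c()}: {r.hgvs_p} / {r.hgvs_p_downstream} -> "
          f"{r.protein_length}-aa truncated protein (full enzyme: "
          f"{len(ed.translate(cds))} aa)")

print("\nThe 4-nt deletion + 3-nt insertion is equivalent to a silent Ser4 codon")
print("swap plus one deleted base: the frameshift starts at Met5 and truncates")
print("the 230-aa enzyme to 72 aa (rat) and 57 aa (human).")
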