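# retphen

Quantification pipelines for phenotyping a rat model of retinitis
pigmentosa — an *Lrat* knockout carrying the rat equivalent (c.12delA)
of a human *LRAT* frameshift mutation (c.12delC) that disables the
retinoid cycle.  The package implements, as tested library code, every
numerical procedure such a phenotyping study needs downstream of data
acquisition:

* **ERG** (`retphen.erg`) — scotopic electroretinogram feature
  extraction: baseline zero-centering, dual zero-phase low-pass paths
  (4th-order Butterworth, forward+backward, 235 Hz for the a-wave and
  30 Hz for the b-wave so the oscillatory potentials are stripped),
  prominence-based peak picking with amplitudes read from the
  *unfiltered* trace, absolute b-wave = b − a, flicker P1/P2, and
  normalization to the wildtype 30 cd·s/m² response.
* **OCT** (`retphen.oct_thickness`) — retinal thickness sampled every
  1 mm with a 0.5 mm exclusion around the optic nerve over five
  B-scans per eye, pooled hierarchically (points → eye → animal →
  group ± SE), normalized to the 2-week wildtype baseline, and
  summarized by an exponential-decay fit T(t) = A + (T0 − A)·e^(−t/τ).
* **Behavior** (`retphen.behavior`) — light/dark-box metrics from
  tracked head coordinates in a 100 × 50 × 40 cm arena: zone assignment
  with a circular transition zone (radius 1.25 × doorway width) taking
  precedence, occupancy times that exactly partition the tracked
  duration, compartment-switch counts, doorway hesitation latencies
  per crossing direction, and normalization to pooled wildtype means.
* **CRISPR edits** (`retphen.edits`) — reconciliation of wildtype vs
  edited sequences into a minimal contiguous edit, reduction of
  compound indels to silent-codon-swap + single-base form (both the
  5′-most and strict 3′-shifted descriptions), translation, frameshift
  truncation prediction with both fs-label conventions, and PCR
  amplicon arithmetic.
* **Synthetic data** (`retphen.simulate`) — seeded generators for all
  three modalities, so every pipeline is verifiable against known
  ground truth without recordings.
* **Statistics** (`retphen.stats`) — ANOVA / Kruskal–Wallis designs
  with Bonferroni-adjusted pairwise post-hocs and the conventional
  star thresholds.

The intended users are vision scientists running rodent phenotyping
studies who want the analysis layer to be reproducible and testable.

## Worked example

The knock-in that creates the model is characterized entirely from the
published oligonucleotides (packaged under `retphen.fixtures`):

```bash
python examples/crispr_edit_consequence.py
```

```
reconciled edit : c.10_13delinsAGT  (deleted TCAA, inserted AGT, net -1 nt)
codon 4 effect  : synonymous (Ser -> Ser)
minimal form    : c.12delA (strict 3'-shifted: c.13delA), silent codon(s) (4,)
rat   c.12delA: p.M5CfsTer69 / p.M5CfsX68 -> 72-aa truncated protein (full enzyme: 230 aa)
human c.12delC: p.M5CfsTer54 / p.M5CfsX53 -> 57-aa truncated protein (full enzyme: 230 aa)
```

Reading this: the homology-directed repair donor replaces the four
bases TCAA at coding positions 10–13 with AGT — a silent serine-codon
swap at residue 4 plus a net single-base deletion (the minimal
description is c.12delA).  The frame shifts from Met5 onward and a
premature stop truncates the 230-residue enzyme to 72 amino acids in
the rat (57 for the homologous human deletion).  Both fs-label
conventions are printed because clinical reports differ in whether the
stop is counted.  The coding sequences used here are packaged
*synthetic stand-ins* (real printed edit-region sequence, modeled
downstream filler; see `retphen/fixtures.py`); with network access the
real reference CDS can be pulled via `retphen.fetch.fetch_cds`.

The other examples exercise one pipeline each and print the recovered
vs ground-truth numbers:

```bash
python examples/erg_feature_extraction.py    # b-wave ~0.08 of wildtype in knockouts
python examples/oct_thinning_trajectory.py   # thinning to ~78% by 16 weeks, tau ~4 wk
python examples/lightdark_box_metrics.py     # no-preference agent ~ area fraction
python examples/group_statistics.py          # Bonferroni-adjusted stars
```

A thin CLI mirrors the library for batch use:

```bash
retphen simulate erg --seed 1 --out sim/
retphen erg --traces sim/traces.csv --meta sim/meta.csv --out features.csv
retphen oct --profiles oct.csv --out summary.csv
retphen behavior --tracks tracks/ --sessions sessions.csv --geometry box.yaml --out metrics.csv
retphen edit reconcile --wt wt.fa --edited donor.fa
retphen report --features features.csv --value b_absolute --out stats.csv
```

## Layout

```
src/retphen/        library modules (+ packaged FASTA fixtures in data/)
examples/           one narrative script per capability
tests/              pytest suite incl. end-to-end acceptance checks
scripts/            acceptance.py
docs/methods.md     models, parameter choices, limitations
```
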