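# Methods

This note records the models behind each pipeline, the defaults and
why, what the synthetic generators do and do not emulate, and the
numerical choices a maintainer would want written down.

## ERG feature extraction

**Signal model.** A scotopic full-field ERG trace is treated as a
uniformly sampled voltage series (default 512 samples over 350 ms,
fs ≈ 1463 Hz) with the flash at 20 ms.  The pre-stimulus segment
(t < 20 ms by default, configurable) defines the baseline; its mean is
subtracted from the whole trace before anything else.

**Filtering.** Two zero-phase low-pass paths are built from 4th-order
Butterworth designs run forward and backward (`scipy.signal.filtfilt`
with even/reflective extension of at least three filter lengths to
suppress startup transients on short traces).  "4th order" is the
per-pass design order; the bidirectional application squares the
magnitude response, so the effective two-pass gain at frequency f with
cutoff fc is 1 / (1 + (f/fc)^8).  The 30 Hz path strips both noise and
the oscillatory potentials (OPs occupy roughly 30–235 Hz in rats); the
235 Hz path keeps the fast leading edge of the a-wave while removing
instrument noise.  Butterworth was chosen for its maximally flat
passband — amplitudes inside the band are not distorted — and because
it is the conventional choice for ERG conditioning.  The closed-form
two-pass magnitude doubles as the test oracle: measured attenuation of
pure tones at 2×, 4× and 8× the cutoff must agree within a factor of
3 (measured on long sinusoids, since deep in the stopband the residual
of a 512-sample trace is dominated by edge transients rather than the
steady-state response).

**Feature definitions.** The a-wave latency is the most prominent
negative excursion of the 235 Hz path inside a configurable window
(default 5–60 ms post-stimulus); the b-wave latency is the most
prominent positive peak of the 30 Hz path inside 20–150 ms.  Ties in
prominence resolve to the earliest latency.  Both amplitudes are the
values of the *unfiltered* (but zero-centered) trace at those
latencies, so filtering never attenuates a reported amplitude.  The
absolute b-wave is b − a (a is negative, so this is the trough-to-peak
excursion).  Components whose best peak falls below the prominence
floor (default 10 µV) are flagged undetected rather than raising —
the knockout phenotype routinely produces flat traces.  Note that a
prominence floor at ~2× the noise SD will occasionally pass noise
peaks on the wide 235 Hz path; analysts should set the floor at 3–4×
the noise level of their rig.

**Flicker.** Flicker traces (9 Hz trains here) are analyzed on the raw
trace only: P1 is the time from stimulus onset to the first positive
peak, P2 the amplitude of the second peak.  Fewer than two peaks flag
the response unrecordable — the expected knockout outcome.

**Normalization.** Group means of each feature are divided by the
wildtype mean at the reference intensity (30 cd·s/m²); the reference
cell is exactly 1.0 by construction.

## OCT thickness quantification

Thickness profiles (µm vs position in mm relative to the optic nerve)
arrive pre-segmented — segmentation is the device software's job, not
this package's.  Five scans per eye are labeled by offset from the
optic-nerve crossing (−20, −10, 0, +10, +20); the labels are treated
as identifiers, not physical angles.  Each profile is sampled at
±(0.5 + k·1.0) mm by linear interpolation — the grid is anchored at
the exclusion boundary so every admissible point closest to the nerve
is used, and linear interpolation is the simplest defensible
estimator at 1-mm spacing.  Sampled points pool hierarchically:
unweighted point mean per eye (missing scans tolerated down to one,
with a warning), eye mean per animal, then group mean ± SE per
genotype × age.  Whether eyes are averaged before animals is not
canonical; the per-eye → per-animal → group order is the default and
the code paths make other orders easy.

Group means are normalized to the wildtype mean at 2 weeks.  The
knockout trajectory is summarized by T(t) = A + (T0 − A)·e^(−t/τ)
fitted with `scipy.optimize.curve_fit` (τ bounded positive, starting
values from the series endpoints).  A flat series leaves τ
meaningless: the fit flags `tau_identifiable=False` (zero fitted
amplitude or exploded τ variance) instead of failing.

## Light/dark-box metrics

The arena is 100 × 50 cm split along its length; the doorway sits on
the divider and its width is deliberately **required configuration**
(no published default exists; the examples use 10 cm centered).  The
transition zone is the circle of radius 1.25 × doorway width at the
doorway base.  Zones partition the box exactly, with transition taking
precedence over dark/light — precedence had to be chosen and this
choice makes the three occupancy times sum to the tracked duration
identically.

Each inter-sample interval is attributed to the zone of its starting
sample.  Compartment switches are crossings of the dividing line
between consecutive samples, regardless of transition-zone membership
— "changed compartments" is about sides, not the staging area.
Detector dropouts (gaps > 5× the median frame interval) are excluded
from occupancy but reported as excluded time.

"Hesitation" is operationalized two ways, both reported, because the
notion is named but not defined in common usage: (a) the dwell from
transition-zone entry to the divider crossing, per crossing direction;
(b) the count of aborted approaches — transition-zone visits that
retreat to the starting side.  Either reading of doorway "doubt" is
therefore available.

Behavioral parameters are normalized per parameter to the wildtype
mean pooled over all timepoints (wildtype behavior is assumed
age-stable, which the generator honors).

## Statistics

`compare_groups` is thin glue: one-way ANOVA (`scipy.stats.f_oneway`),
two-way ANOVA (statsmodels OLS, type-II table, main effect reported),
or Kruskal–Wallis, followed by pairwise post-hocs — Welch t for the
ANOVA designs, Mann–Whitney U for the nonparametric one (the
nonparametric post-hoc had to be chosen; a rank test keeps the design
coherent) — Bonferroni-adjusted as min(1, m·p) over the m pairs.
Stars: * p ≤ 0.05, ** ≤ 0.01, *** ≤ 0.001, **** ≤ 0.0001.  An ANOVA
on log-transformed values is a flag.  Rank tests saturate at small n
(a Mann–Whitney with 6 per group cannot reach p < 0.002), so the
designs can legitimately disagree on stars.

## Synthetic generators

The generators exist to make every pipeline verifiable against known
truth; they are statistical emulations, not biophysics.

* **ERG**: Gaussian bumps for the a-trough (150 µV, 30 ms, σ 8 ms) and
  b-peak (300 µV, 70 ms, σ 12 ms), a windowed 120 Hz sinusoid for the
  OPs (40 µV), Gaussian noise (σ 5 µV), and a Naka–Rushton
  intensity–response V(I) = Vmax·Iⁿ/(Iⁿ + Kⁿ) with K = 1 cd·s/m² and
  n = 0.7 (typical rodent scotopic values), so the default wildtype
  b-excursion at 30 cd·s/m² is ~410 µV and 0.3 cd·s/m² sits at ~30%
  saturation.  Genotype scale factors default to 1.0 / 1.0 / 0.08 for
  +/+, +/−, −/− (heterozygotes are indistinguishable from wildtype;
  knockouts retain a sliver of response only at the brightest flash).
  The OP envelope is centered midway between the a-trough and b-peak
  with σ = a quarter of that interval: OPs ride the b-wave's rising
  limb, and centering them on the b-peak would contaminate the
  unfiltered amplitude read-out with an artifact of the generator
  rather than a property of the method.  What the generator does not
  emulate: photoreceptor/bipolar kinetics, intensity-dependent
  latencies, electrode drift, blink artifacts — so passing tests
  demonstrate correct signal processing, not physiological realism.
* **OCT**: knockout total thickness follows the same exponential-decay
  law the fitter assumes (baseline 230 µm = IPL 50 + INL 25 + ONL 60 +
  remainder 95, asymptote fraction 0.78, τ = 4 weeks, per-point noise
  σ 5 µm), with the loss taken from the ONL and other layers flat;
  wildtype and heterozygous retinas are flat.  Defaults put the
  16-week knockout at ~78% of baseline.  Because generator and fitter
  share the model class, the parameter-recovery tests check estimator
  correctness, not model adequacy for real retinas (real thinning need
  not be exponential, and τ here is a descriptive constant).
* **Tracks**: a reflected 2-D Gaussian random walk (step σ 2 cm at
  15 Hz for 1200 s) that can cross the divider only where its path
  intersects the physical doorway opening, after an exponential
  hesitation dwell timed from transition-zone entry (mean 1 s for the
  base agent), with crossing direction accepted with probability
  min(1, w) into dark and min(1, 1/w) into light for dark-preference
  w.  With w = 1 the dynamics are symmetric and the stationary
  occupancy of each zone is its area fraction; the 20-minute session
  retains a small start-in-light transient, which is why the
  ergodicity checks average over 50 seeds.  A long dwell models the
  sighted agent's doorway "doubt"; the indifferent (blind-like) base
  agent hesitates only briefly.  Not emulated: thigmotaxis, rearing,
  speed profiles, tracking jitter.

## Sequence fixtures

The packaged guide (20 nt) and donor (94 nt) oligos are verbatim; the
wildtype ORF region is the donor with the knock-in reversed
(AGT → TCAA at coding positions 10–12), which the guide sequence
confirms base-for-base.  The two coding sequences
(`synthetic_rat_lrat_cds.fa`, `synthetic_human_lrat_cds.fa`) are
**synthetic stand-ins**, not reference mRNAs: they preserve the real
edit-region sequence at the 5′ end, a 230-codon open reading frame,
and the −1-frame stop position that yields the documented truncated
products (72 aa rat, 57 aa human); downstream filler is deterministic
pseudo-random sense codons (fixed internal seed, byte-identical across
runs, rejection-sampled so neither frame contains an unintended stop).
Conclusions that depend on the *actual* downstream sequence — e.g.
independently re-deriving the truncation length from a public record —
require fetching the real CDS via `retphen.fetch.fetch_cds` (network).

Truncation labels are emitted in both conventions because published
reports mix them: `fsTer(n)` counts the new residue as 1 and includes
the stop (p.M5CfsTer54 ↔ 57-aa human product), while `fsX(n)` as used
in some clinical papers counts residues downstream excluding the stop
(p.M5CfsX53 for the same product).  The unambiguous quantity — the
truncated protein length — is always reported alongside.

## Numerical details and edge cases

* Edit reconciliation is the longest-common-prefix / longest-common-
  suffix decomposition; it is minimal among contiguous edits.  Two
  sequences differing in disjoint places have no single contiguous
  edit; this is detected heuristically (the deleted and inserted
  middles sharing a run of ≥ 6 identical bases) and rejected.
* Variant normalization for net ±1 edits searches the edit region
  (padded to codon boundaries) for single-base indel positions whose
  residual substitutions are whole-codon synonymous, preferring
  decompositions with the fewest substituted codons; the 5′-most and
  3′-most equivalent positions (extended through any homopolymer run)
  are both reported.
* Translation uses Biopython's standard table and stops at the first
  stop codon; coding-frame sequences must start with ATG.
* `filtfilt` padding: even (mirror) extension, padlen = 9 × (filter
  taps − 1), capped at trace length − 1.
* Peak ties: `numpy.argmax` on prominences returns the first (i.e.
  earliest-latency) maximum by construction.
* Grid sampling uses `numpy.interp` (no extrapolation: grid points are
  clipped to the profile extent).
* The degeneration fit treats a flat input as an exactly-degenerate
  case before optimization (amplitude 0, τ = NaN, flagged).

## Problem sizes

Tests and the acceptance script use the cohort sizes the generators
default to: 6 animals per genotype, 512-sample traces, 7-age OCT
series, 20-minute sessions; Monte-Carlo statements use 20 seeds (ERG
recovery, OCT fit recovery) or 50 seeds (occupancy ergodicity).

## Known limitations

* The OCT fitter and generator share a model class; no goodness-of-fit
  test against alternative thinning laws is provided.
* Hesitation latencies are conditional on completed crossings, so long
  dwells are censored by aborted approaches; the aborted-approach
  counts carry the complementary information.
* Amplicon sizing requires exact primer matches; degenerate or
  mismatched priming is out of scope.
* The two-way ANOVA reports the genotype main effect from a type-II
  table; interaction terms are fitted but not surfaced.
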