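"""Packaged sequence fixtures for the Lrat knock-in worked example.

Two kinds of sequence live here:

* The published oligonucleotides, verbatim: the 20-nt sgRNA protospacer
  and the 94-nt ssODN homology-directed-repair donor.  The wildtype
  counterpart of the donor region is reconstructed by reversing the
  knock-in edit (AGT back to TCAA at ORF positions 10–12), which the
  printed protospacer confirms base-for-base.

* SYNTHETIC stand-in coding sequences for rat Lrat and human LRAT
  (``synthetic_rat_lrat_cds`` / ``synthetic_human_lrat_cds``).  The
  reference mRNAs are not bundled; these stand-ins preserve everything
  the worked example depends on — the real edit-region sequence at the
  5' end (rat: reconstructed from the printed oligos; human: the
  c.12delC context with Ser4/Met5), a 230-codon open reading frame, and
  a −1-frame stop placed so the frameshifted products are 72 aa (rat)
  and 57 aa (human).  Downstream filler is deterministic pseudo-random
  sense codons; the stand-ins are NOT the biological sequences and are
  labelled synthetic wherever they appear.

All fixtures are byte-identical across runs (fixed internal seed,
independent of any user-facing seed).
"""

from __future__ import annotations

import random
from pathlib import Path

from .edits import EditDescription, NucSequence

__all__ = [
    "SGRNA_PROTOSPACER",
    "SSODN_DONOR",
    "KNOCKIN_EDIT",
    "RAT_C12DELA",
    "HUMAN_C12DELC",
    "wildtype_orf_region",
    "edited_orf_region",
    "make_fixture_sequences",
    "write_fixture_fastas",
    "load_fixture",
]

# Published oligos (5'→3').
SGRNA_PROTOSPACER = "AAGGATGAAGAACTCAATGC"
SSODN_DONOR = (
    "CAGTTGCGGCCAGCGAGAAACTCTGGTCTTTAAAGGATGAAGAACAGTTGC"
    "TGGAGGCTGCGTCCCTCCTTCTGGAGAAGCTGCTCCTTATTTC"
)

# The knock-in, in coding coordinates: c.10-13 TCAA replaced by AGT.
KNOCKIN_EDIT = EditDescription(position=10, deleted="TCAA", inserted="AGT")
# Its minimal protein-level equivalents: a single-base deletion after a
# silent Ser4 codon swap.
RAT_C12DELA = EditDescription(position=12, deleted="A")
HUMAN_C12DELC = EditDescription(position=12, deleted="C")

_ORF_START_IN_SSODN = SSODN_DONOR.find("ATGAAGAAC")
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
)
_FIXTURE_SEED = 20210705  # fixed: fixtures must be byte-identical across runs
_N_CODONS = 230  # LRAT ORF length in both species

# Human edit-region context: Ser4 codon TCC puts a C at c.12, Met5 follows;
# deleting c.12 reads ...TCA-TGC... (Ser4 silent, Met5→Cys frameshift),
# mirroring the rat c.12delA consequence.
_HUMAN_PREFIX = "ATGAAGAACTCCATGC"


def edited_orf_region() -> NucSequence:
    """ORF-trimmed edited sequence carried by the ssODN donor."""
    return NucSequence("ssODN_orf_region", SSODN_DONOR[_ORF_START_IN_SSODN:], "coding")


def wildtype_orf_region() -> NucSequence:
    """Wildtype ORF region, i.e. the donor region with the edit reversed."""
    ed = edited_orf_region().bases
    return NucSequence("wildtype_orf_region", ed[:9] + "TCAA" + ed[12:], "coding")


def _edited_frame(wt: str, del_index0: int) -> str:
    return wt[:del_index0] + wt[del_index0 + 1:]


def _build_synthetic_cds(prefix: str, stop_codon0: int, seed: int) -> str:
    """Deterministically build a 230-codon CDS around a fixed prefix.

    The single-base deletion at 0-based index 11 (c.12) must hit its
    first downstream stop exactly at shifted-frame codon ``stop_codon0``
    (0-based), and the unshifted frame must be stop-free for all 230
    codons.  Constructed by seeded rejection sampling.
    """
    rng = random.Random(seed)
    body_len = 3 * _N_CODONS
    for _ in range(10_000):
        seq = prefix
        # pad the partial codon, then whole sense codons
        while len(seq) % 3:
            seq += rng.choice("ACGT")
        while len(seq) < body_len:
            seq += rng.choice(_SENSE_CODONS)
        seq = seq[:body_len]
        # force the shifted-frame stop: shifted codon j reads wt bases
        # 3j+1 .. 3j+3 (0-based) once the deletion at index 11 is upstream
        w0 = 3 * stop_codon0 + 1
        seq = seq[:w0] + "TAA" + seq[w0 + 3:]
        wt_ok = all(seq[i:i + 3] not in _STOPS for i in range(0, body_len, 3))
        shifted = _edited_frame(seq, 11)
        sh_ok = (
            all(shifted[3 * j:3 * j + 3] not in _STOPS for j in range(stop_codon0))
            and shifted[3 * stop_codon0:3 * stop_codon0 + 3] in _STOPS
        )
        if wt_ok and sh_ok and seq.startswith(prefix):
            return seq + "TAA"
    raise RuntimeError("synthetic CDS construction failed to converge")  # pragma: no cover


def make_fixture_sequences() -> dict[str, NucSequence]:
    """Return every packaged fixture, rebuilt from scratch.

    Deterministic: repeated calls (and calls in different processes)
    yield byte-identical sequences.
    """
    rat_prefix = wildtype_orf_region().bases
    rat_cds = _build_synthetic_cds(rat_prefix, stop_codon0=72, seed=_FIXTURE_SEED)
    human_cds = _build_synthetic_cds(_HUMAN_PREFIX, stop_codon0=57, seed=_FIXTURE_SEED + 1)
    return {
        "sgrna_protospacer": NucSequence("sgrna_protospacer", SGRNA_PROTOSPACER),
        "ssodn_donor": NucSequence("ssodn_donor", SSODN_DONOR),
        "wildtype_orf_region": wildtype_orf_region(),
        "edited_orf_region": edited_orf_region(),
        "synthetic_rat_lrat_cds": NucSequence("synthetic_rat_lrat_cds", rat_cds, "coding"),
        "synthetic_human_lrat_cds": NucSequence("synthetic_human_lrat_cds", human_cds, "coding"),
    }


def write_fixture_fastas(out_dir: str | Path) -> list[Path]:
    """Write each fixture as a single-record FASTA; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, seq in make_fixture_sequences().items():
        p = out / f"{name}.fa"
        with open(p, "w") as fh:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.bases), 70):
                fh.write(seq.bases[i:i + 70] + "\n")
        paths.append(p)
    return paths


def load_fixture(name: str) -> NucSequence:
    """Load a packaged FASTA fixture by name (without the .fa suffix)."""
    from importlib import resources

    ref = resources.files("retphen").joinpath("data", f"{name}.fa")
    lines = ref.read_text().splitlines()
    if not lines or not lines[0].startswith(">"):
        raise ValueError(f"malformed fixture {name!r}")
    frame = "coding" if name.endswith("_cds") or name.endswith("_region") else "raw"
    return NucSequence(lines[0][1:].strip(), "".join(lines[1:]), frame)
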