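"""Sequence-level characterization of CRISPR knock-in edits.

This module reconciles a wildtype coding sequence against an edited one
(e.g. an HDR donor product), normalizes compound indels to their minimal
protein-level description, translates, and predicts the consequence of
frameshifting deletions — premature stop position and truncated-protein
length — in both the standard HGVS ``fsTer`` convention and the
"residues downstream" convention sometimes used in clinical reports.

Coding coordinates are 1-based with the ATG at c.1–3, so "c.12delA"
deletes the 12th base of the open reading frame.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field

from Bio.Seq import Seq

__all__ = [
    "NucSequence",
    "EditDescription",
    "TruncationResult",
    "NormalizedVariant",
    "reconcile_edit",
    "apply_edit",
    "translate",
    "check_synonymy",
    "predict_truncation",
    "normalize_variant",
    "amplicon_size",
    "IdenticalSequencesError",
    "MultipleEditsError",
    "PrimerSiteError",
]

_VALID_BASES = frozenset("ACGT")


class IdenticalSequencesError(ValueError):
    """Raised when reconciliation is asked for two identical sequences."""


class MultipleEditsError(ValueError):
    """Raised when two sequences differ by more than one contiguous edit."""


class PrimerSiteError(ValueError):
    """Raised when a primer has zero or multiple binding sites."""


def _clean(bases: str, *, what: str = "sequence") -> str:
    s = bases.strip().upper()
    if not s:
        raise ValueError(f"empty {what}")
    bad = set(s) - _VALID_BASES
    if bad:
        if "U" in bad:
            raise ValueError(f"{what} contains U; provide DNA, not RNA")
        raise ValueError(f"{what} contains invalid characters: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class NucSequence:
    """A nucleotide sequence with an explicit coordinate frame.

    coordinate_frame is ``"coding"`` (1-based, ATG = c.1) or ``"raw"``.
    Bases are upper-cased on construction; only A/C/G/T are accepted.
    """

    id: str
    bases: str
    coordinate_frame: str = "raw"

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", _clean(self.bases, what=f"sequence {self.id!r}"))
        if self.coordinate_frame not in ("coding", "raw"):
            raise ValueError(f"coordinate_frame must be 'coding' or 'raw', got {self.coordinate_frame!r}")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class EditDescription:
    """One contiguous replacement: ``deleted`` → ``inserted`` at ``position``.

    ``position`` is the 1-based coordinate of the first affected base.
    ``net_change`` is the length change of the edited sequence relative
    to wildtype (negative for net deletions), so the del-TCAA/ins-AGT
    knock-in edit has net_change = −1.
    """

    position: int
    deleted: str = ""
    inserted: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")
        if not self.deleted and not self.inserted:
            raise ValueError("an edit must delete and/or insert at least one base")
        for name in ("deleted", "inserted"):
            v = getattr(self, name)
            if v:
                object.__setattr__(self, name, _clean(v, what=name))

    @property
    def net_change(self) -> int:
        return len(self.inserted) - len(self.deleted)

    def hgvs_c(self) -> str:
        """Best-effort c.-style description of this edit."""
        p, d, i = self.position, self.deleted, self.inserted
        if d and not i:
            if len(d) == 1:
                return f"c.{p}del{d}"
            return f"c.{p}_{p + len(d) - 1}del{d}"
        if i and not d:
            return f"c.{p - 1}_{p}ins{i}"
        return f"c.{p}_{p + len(d) - 1}delins{i}"


@dataclass(frozen=True)
class TruncationResult:
    """Predicted protein consequence of a frameshifting edit.

    ``stop_offset`` counts residues from the first altered one (which
    counts as 1) to the new stop codon inclusive — the standard fsTer
    number.  ``downstream_count`` excludes the stop (stop_offset − 1);
    some reports use this "residues downstream" count instead, in which
    case protein_length = (fs_codon − 1) + downstream_count.
    """

    fs_codon: int
    wt_residue: str
    new_residue: str
    stop_offset: int
    protein_length: int

    def __post_init__(self) -> None:
        if self.fs_codon < 1:
            raise ValueError("fs_codon must be >= 1")
        if self.protein_length != self.fs_codon - 1 + self.stop_offset - 1:
            raise ValueError("inconsistent truncation arithmetic: "
                             "protein_length must equal fs_codon - 1 + stop_offset - 1")

    @property
    def downstream_count(self) -> int:
        return self.stop_offset - 1

    @property
    def hgvs_p(self) -> str:
        return f"p.{self.wt_residue}{self.fs_codon}{self.new_residue}fsTer{self.stop_offset}"

    @property
    def hgvs_p_downstream(self) -> str:
        """fs label under the 'residues downstream' convention."""
        return f"p.{self.wt_residue}{self.fs_codon}{self.new_residue}fsX{self.downstream_count}"


def reconcile_edit(wt: NucSequence, edited: NucSequence, *, min_disjoint_gap: int = 6) -> EditDescription:
    """Recover the minimal contiguous edit turning ``wt`` into ``edited``.

    Decomposes the pair as longest-common-prefix + middle + longest-
    common-suffix; the middle segments are the deleted and inserted
    bases.  A single contiguous edit is assumed: if the two middle
    segments share a run of ``min_disjoint_gap`` or more identical
    bases, the difference looks like two or more disjoint edits and a
    MultipleEditsError is raised.
    """
    a, b = wt.bases, edited.bases
    if a == b:
        raise IdenticalSequencesError("sequences are identical; no edit to reconcile")
    # longest common prefix
    p = 0
    lim = min(len(a), len(b))
    while p < lim and a[p] == b[p]:
        p += 1
    # longest common suffix not overlapping the prefix
    s = 0
    while s < lim - p and a[len(a) - 1 - s] == b[len(b) - 1 - s]:
        s += 1
    deleted = a[p:len(a) - s]
    inserted = b[p:len(b) - s]
    if deleted and inserted:
        m = difflib.SequenceMatcher(None, deleted, inserted, autojunk=False).find_longest_match(
            0, len(deleted), 0, len(inserted))
        if m.size >= min_disjoint_gap:
            raise MultipleEditsError(
                f"middle segments share a {m.size}-base run ({deleted[m.a:m.a + m.size]!r}); "
                "the sequences appear to differ by multiple disjoint edits")
    return EditDescription(position=p + 1, deleted=deleted, inserted=inserted)


def apply_edit(seq: NucSequence, e: EditDescription) -> NucSequence:
    """Apply an EditDescription, verifying the deleted bases match."""
    i = e.position - 1
    if i > len(seq.bases):
        raise ValueError(f"edit position {e.position} beyond sequence of length {len(seq)}")
    found = seq.bases[i:i + len(e.deleted)]
    if found != e.deleted:
        raise ValueError(
            f"deleted bases mismatch at position {e.position}: edit says {e.deleted!r}, "
            f"sequence has {found!r}")
    bases = seq.bases[:i] + e.inserted + seq.bases[i + len(e.deleted):]
    return NucSequence(id=f"{seq.id}|{e.hgvs_c()}", bases=bases,
                       coordinate_frame=seq.coordinate_frame)


def translate(cds: NucSequence, *, require_atg: bool | None = None) -> str:
    """Translate a CDS with the standard code, stopping at the first stop.

    For coding-frame sequences an ATG at c.1 is required (override with
    ``require_atg=False``).  Returns the residues before the stop; a
    trailing partial codon is ignored.
    """
    if len(cds.bases) < 3:
        raise ValueError("sequence shorter than one codon")
    if require_atg is None:
        require_atg = cds.coordinate_frame == "coding"
    if require_atg and not cds.bases.startswith("ATG"):
        raise ValueError(f"coding sequence {cds.id!r} does not start with ATG at c.1")
    usable = len(cds.bases) - len(cds.bases) % 3
    return str(Seq(cds.bases[:usable]).translate(to_stop=True))


def _codon(seq: NucSequence, codon_index: int) -> str:
    start = 3 * (codon_index - 1)
    c = seq.bases[start:start + 3]
    if len(c) < 3:
        raise ValueError(f"sequence {seq.id!r} does not cover codon {codon_index}")
    return c


def check_synonymy(wt_cds: NucSequence, edited_cds: NucSequence, codon_index: int) -> str:
    """Classify the edited codon: 'synonymous', 'missense' or 'frame-disrupted'.

    The codon is read at the same in-frame position in both sequences,
    which is meaningful only upstream of any net frameshift; a codon
    whose wildtype span reaches past the replaced region of a
    frame-changing edit is reported as 'frame-disrupted'.
    """
    if codon_index < 1:
        raise ValueError("codon_index is 1-based")
    try:
        e = reconcile_edit(wt_cds, edited_cds)
    except IdenticalSequencesError:
        return "synonymous"
    if e.net_change != 0:
        codon_end = 3 * codon_index  # 1-based coordinate of codon's last base
        replaced_end = e.position + len(e.deleted) - 1
        if codon_end > replaced_end:
            return "frame-disrupted"
    wt_aa = str(Seq(_codon(wt_cds, codon_index)).translate())
    ed_aa = str(Seq(_codon(edited_cds, codon_index)).translate())
    return "synonymous" if wt_aa == ed_aa else "missense"


def predict_truncation(cds: NucSequence, e: EditDescription) -> TruncationResult:
    """Predict the truncated protein produced by a frameshifting edit.

    Applies the edit, translates both sequences, and locates the first
    altered residue and the distance to the new stop.  In-frame edits
    (net change divisible by 3) are rejected — classify those with
    :func:`check_synonymy` instead.
    """
    if e.net_change % 3 == 0:
        raise ValueError("edit is in-frame (net change divisible by 3); "
                         "use check_synonymy for in-frame consequences")
    edited = apply_edit(cds, e)
    wt_protein = translate(cds)
    ed_protein = translate(edited)
    fs = next((i for i, (w, m) in enumerate(zip(wt_protein, ed_protein)) if w != m),
              min(len(wt_protein), len(ed_protein)))
    fs_codon = fs + 1
    if fs_codon > len(ed_protein):
        # the shifted frame stops immediately where a residue differed only by absence
        wt_res = wt_protein[fs] if fs < len(wt_protein) else "?"
        return TruncationResult(fs_codon=fs_codon, wt_residue=wt_res, new_residue="*",
                                stop_offset=1, protein_length=len(ed_protein))
    return TruncationResult(
        fs_codon=fs_codon,
        wt_residue=wt_protein[fs] if fs < len(wt_protein) else "?",
        new_residue=ed_protein[fs],
        stop_offset=len(ed_protein) - fs_codon + 2,
        protein_length=len(ed_protein),
    )


@dataclass(frozen=True)
class NormalizedVariant:
    """A compound ±1-nt edit reduced to silent codon changes + one indel.

    ``position_5prime``/``position_3prime`` bound the equivalent indel
    positions (identical products); clinical reports sometimes quote the
    5′-most form while strict HGVS normalization shifts 3′-most.
    """

    base: str
    position_5prime: int
    position_3prime: int
    kind: str  # "del" | "ins"
    silent_codons: tuple[int, ...] = field(default_factory=tuple)

    @property
    def form_5prime(self) -> str:
        return f"c.{self.position_5prime}{self.kind}{self.base}"

    @property
    def form_3prime(self) -> str:
        return f"c.{self.position_3prime}{self.kind}{self.base}"


def _single_indel_candidates(wt: str, edited: str, kind: str, lo: int, hi: int):
    """Yield 1-based positions p where a single-base del/ins at p, plus
    codon-synonymous substitutions, turns wt into edited."""
    for p in range(max(1, lo), hi + 1):
        if kind == "del":
            if p > len(wt):
                continue
            cand, base = wt[:p - 1] + wt[p:], wt[p - 1]
        else:
            if p > len(edited):
                continue
            cand, base = wt[:p - 1] + edited[p - 1] + wt[p - 1:], edited[p - 1]
        if len(cand) != len(edited):
            continue
        diffs = [i for i, (x, y) in enumerate(zip(cand, edited)) if x != y]
        if not diffs:
            yield p, base, ()
            continue
        codons = sorted({i // 3 for i in diffs})
        if any(3 * c + 3 > len(edited) for c in codons):
            continue
        ok = all(
            str(Seq(cand[3 * c:3 * c + 3]).translate()) == str(Seq(edited[3 * c:3 * c + 3]).translate())
            for c in codons)
        if ok:
            yield p, base, tuple(c + 1 for c in codons)


def normalize_variant(e: EditDescription, cds: NucSequence) -> NormalizedVariant | EditDescription:
    """Reduce a net-±1 compound edit to its minimal single-base form.

    For the knock-in edit (del TCAA / ins AGT at c.10) this recovers a
    silent Ser codon change plus deletion of one A from the c.12–13 AA
    dinucleotide, reported both as the 5′-most form "c.12delA" and the
    strictly 3′-shifted "c.13delA".  Edits whose net change is not ±1
    are passed through unchanged.
    """
    if e.net_change not in (-1, 1):
        return e
    wt = cds.bases
    edited = apply_edit(cds, e).bases
    kind = "del" if e.net_change == -1 else "ins"
    # search the edit region padded to codon boundaries, plus any homopolymer run
    lo = 3 * ((e.position - 1) // 3) + 1
    hi = e.position + max(len(e.deleted), len(e.inserted)) + 3
    found = list(_single_indel_candidates(wt, edited, kind, lo, min(hi, max(len(wt), len(edited)))))
    if not found:
        return e
    # prefer decompositions with the fewest substituted codons
    min_subs = min(len(sil) for _, _, sil in found)
    found = [f for f in found if len(f[2]) == min_subs]
    base = found[0][1]
    positions = [p for p, b, _ in found if b == base]
    p5, p3 = min(positions), max(positions)
    # extend 3' shifting through any homopolymer run of the indel base
    ref = wt if kind == "del" else edited
    while p3 < len(ref) and ref[p3] == base:
        p3 += 1
    return NormalizedVariant(base=base, position_5prime=p5, position_3prime=p3,
                             kind=kind, silent_codons=found[0][2])


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def amplicon_size(template: NucSequence, fwd: str, rev: str) -> int:
    """PCR product length for one exact forward and one reverse site.

    The reverse primer is matched as its reverse complement on the plus
    strand, downstream of the forward site.  The product length counts
    both primer footprints inclusively.
    """
    fwd = _clean(fwd, what="forward primer")
    rev_rc = _revcomp(_clean(rev, what="reverse primer"))
    f_sites = _find_all(template.bases, fwd)
    r_sites = _find_all(template.bases, rev_rc)
    if len(f_sites) != 1:
        raise PrimerSiteError(f"forward primer has {len(f_sites)} binding sites at {f_sites}")
    r_down = [r for r in r_sites if r >= f_sites[0]]
    if len(r_down) != 1:
        raise PrimerSiteError(
            f"reverse primer has {len(r_down)} downstream binding sites at {r_down} "
            f"(all plus-strand RC sites: {r_sites})")
    return r_down[0] + len(rev_rc) - f_sites[0]
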