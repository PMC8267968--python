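"""Optional online retrieval of reference coding sequences.

This module needs network access and is deliberately separated from the
offline analysis code: nothing in the package's pipelines, tests or
packaged fixtures depends on it.  Use it to pull the real LRAT/Lrat
reference CDS by RefSeq accession when a connection is available, e.g.
human ``NM_004744.4``.  Note that published rat accessions are
sometimes malformed in print, so the accession is always caller-
supplied and overridable.
"""

from __future__ import annotations

from .edits import NucSequence

__all__ = ["fetch_cds"]


def fetch_cds(accession: str, email: str, *, timeout: float = 60.0) -> NucSequence:
    """Fetch a GenBank record and extract its annotated CDS (network required)."""
    from Bio import Entrez, SeqIO

    Entrez.email = email
    with Entrez.efetch(db="nuccore", id=accession, rettype="gb", retmode="text") as handle:
        rec = SeqIO.read(handle, "genbank")
    for feat in rec.features:
        if feat.type == "CDS":
            cds = str(feat.extract(rec.seq))
            return NucSequence(accession, cds, "coding")
    raise ValueError(f"no CDS feature annotated on {accession}")
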