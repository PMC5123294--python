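"""Core domain types and coding-sequence utilities.

All coordinates are 0-based, half-open and expressed on the gene-forward
strand.  Genes annotated on the minus strand are reverse-complemented at
load time (see :mod:`spliceortho.io`), so every downstream computation is
strand-free; the provenance of that normalisation is recorded in
:attr:`GeneSequence.strand_note`.

A :class:`Transcript` is the ordered list of CDS exons of one isoform.
Following CCDS conventions the coding region runs from the start codon
through the stop codon inclusive; the terminal stop codon is required by
:func:`translate` and stripped from the returned protein.

Exon junctions are mapped to protein residues by :func:`junction_marks`.
A junction falling between two codons (phase 0) is assigned the residue
whose codon *ends* at the junction; a junction inside a codon (phase 1
or 2) is assigned the residue whose codon spans it.  The convention is
arbitrary but is applied identically to both species, which is all the
junction-preservation test requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq

VALID_NT = frozenset("ACGTN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class InputError(ValueError):
    """Malformed or out-of-range input (coordinates, alphabets, files)."""


class ValidationError(ValueError):
    """Input parses but violates a biological validity rule (frame, stops)."""


@dataclass(frozen=True)
class GeneSequence:
    """A genomic gene sequence in gene-forward orientation."""

    gene_id: str
    species: str
    seq: str
    strand_note: str = "forward"

    def __post_init__(self) -> None:
        if not self.seq:
            raise InputError(f"gene {self.gene_id}: empty sequence")
        bad = set(self.seq) - VALID_NT
        if bad:
            raise InputError(
                f"gene {self.gene_id}: invalid nucleotides {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class Exon:
    """A CDS exon span, 0-based half-open, gene-forward."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InputError(f"invalid exon span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Transcript:
    """Ordered CDS exons of one isoform of one gene.

    ``release`` is an optional integer timestamp (e.g. the CCDS release in
    which the accession first appeared) used for cohort partitioning.
    """

    accession: str
    gene_id: str
    exons: tuple[Exon, ...]
    release: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise InputError(f"{self.accession}: transcript without exons")
        object.__setattr__(self, "exons", tuple(self.exons))
        prev_end = -1
        for e in self.exons:
            if e.start < prev_end:
                raise InputError(
                    f"{self.accession}: exons overlap or are out of order"
                )
            prev_end = e.end

    @property
    def cds_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class JunctionMark:
    """An internal exon junction projected onto the protein.

    ``cds_offset`` counts CDS nucleotides before the junction; ``phase`` is
    ``cds_offset mod 3``; ``aa_index`` is the 1-based residue carrying the
    junction under the phase convention documented in the module docstring.
    """

    cds_offset: int
    aa_index: int
    phase: int


@dataclass(frozen=True)
class ProteinIsoform:
    """Translated isoform with its junction marks."""

    transcript_accession: str
    residues: str
    junctions: tuple[JunctionMark, ...]

    @property
    def n_exons(self) -> int:
        return len(self.junctions) + 1


@dataclass
class GenePair:
    """An orthologous gene pair with both species' transcript sets."""

    gene_a: GeneSequence
    gene_b: GeneSequence
    transcripts_a: list[Transcript]
    transcripts_b: list[Transcript]

    def gene(self, which: str) -> GeneSequence:
        return self.gene_a if which == "a" else self.gene_b

    def transcripts(self, which: str) -> list[Transcript]:
        return self.transcripts_a if which == "a" else self.transcripts_b


def splice_cds(t: Transcript, g: GeneSequence) -> str:
    """Concatenate the exon substrings of ``g`` in transcript order."""
    if t.gene_id != g.gene_id:
        raise InputError(
            f"{t.accession}: transcript gene {t.gene_id!r} != {g.gene_id!r}"
        )
    for e in t.exons:
        if e.end > len(g):
            raise InputError(
                f"{t.accession}: exon [{e.start},{e.end}) outside gene of "
                f"length {len(g)}"
            )
    cds = "".join(g.seq[e.start:e.end] for e in t.exons)
    if len(cds) % 3 != 0:
        raise ValidationError(
            f"{t.accession}: CDS length {len(cds)} not divisible by 3"
        )
    return cds


def translate(cds: str) -> str:
    """Translate a CDS with the standard genetic code.

    The CDS must end with a stop codon, which is stripped from the result.
    An internal stop raises :class:`ValidationError`: across species it is
    the signature of a candidate frame-shift and such isoforms are excluded
    from protein-level pairing.
    """
    if len(cds) % 3 != 0:
        raise ValidationError(f"CDS length {len(cds)} not divisible by 3")
    if len(cds) < 6:
        raise ValidationError("CDS shorter than two codons")
    if cds[-3:] not in STOP_CODONS:
        raise ValidationError(f"CDS does not end with a stop codon ({cds[-3:]})")
    protein = str(Seq(cds).translate(table=1))
    body = protein[:-1]
    if "*" in body:
        raise ValidationError(
            f"internal stop codon at residue {body.index('*') + 1}"
        )
    return body


def junction_marks(t: Transcript) -> list[JunctionMark]:
    """Junction marks of ``t``, one per internal junction (empty if 1 exon)."""
    marks: list[JunctionMark] = []
    offset = 0
    for e in t.exons[:-1]:
        offset += len(e)
        phase = offset % 3
        aa = offset // 3 if phase == 0 else offset // 3 + 1
        marks.append(JunctionMark(cds_offset=offset, aa_index=aa, phase=phase))
    return marks


def protein_isoform(t: Transcript, g: GeneSequence) -> ProteinIsoform:
    """Splice, translate and annotate junctions in one step."""
    residues = translate(splice_cds(t, g))
    return ProteinIsoform(
        transcript_accession=t.accession,
        residues=residues,
        junctions=tuple(junction_marks(t)),
    )


def is_valid_coding(t: Transcript, g: GeneSequence) -> tuple[bool, str]:
    """Check frame and translation validity; returns (ok, reason)."""
    try:
        translate(splice_cds(t, g))
    except (InputError, ValidationError) as exc:
        return False, str(exc)
    return True, ""
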