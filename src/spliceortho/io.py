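"""Readers and writers for the standard formats, plus run configuration.

FASTA is handled through Biopython, GFF3 through gffutils (in-memory
database); GTF input is accepted via a small conversion shim.  GFF3's
1-based inclusive coordinates are converted to the internal 0-based
half-open convention at this boundary, and minus-strand genes are
reverse-complemented on load so that all downstream logic is
strand-free (``GeneSequence.strand_note`` records the flip).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gffutils
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    Exon,
    GenePair,
    GeneSequence,
    InputError,
    Transcript,
    is_valid_coding,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline parameters with their published defaults."""

    flank_len: int = 20
    identity_threshold: float = 0.7
    vicinity: int = 2
    terminal_window: int = 10
    gap_open: int = 11
    gap_extend: int = 1
    cohort_boundaries: tuple[int, ...] = (2, 7, 19)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise InputError(f"unknown configuration key {key!r}")
            if key == "cohort_boundaries":
                value = tuple(value)
            setattr(cfg, key, value)
        return cfg

    def to_dict(self) -> dict:
        return {
            "flank_len": self.flank_len,
            "identity_threshold": self.identity_threshold,
            "vicinity": self.vicinity,
            "terminal_window": self.terminal_window,
            "gap_open": self.gap_open,
            "gap_extend": self.gap_extend,
            "cohort_boundaries": list(self.cohort_boundaries),
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(gene: GeneSequence, path: str | Path) -> None:
    record = SeqRecord(
        Seq(gene.seq), id=gene.gene_id, description=gene.species
    )
    SeqIO.write([record], str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
    }


# ---------------------------------------------------------------------------
# GFF3 / GTF

def write_gff3(
    transcripts: Iterable[Transcript],
    gene: GeneSequence,
    path: str | Path,
) -> None:
    """Write CDS features grouped by transcript (plus-strand, 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in transcripts:
            fh.write(
                f"{gene.gene_id}\tspliceortho\tmRNA\t"
                f"{t.exons[0].start + 1}\t{t.exons[-1].end}\t.\t+\t.\t"
                f"ID=transcript:{t.accession}\n"
            )
            cum = 0
            for i, e in enumerate(t.exons):
                phase = (3 - cum % 3) % 3
                fh.write(
                    f"{gene.gene_id}\tspliceortho\tCDS\t{e.start + 1}\t{e.end}"
                    f"\t.\t+\t{phase}\t"
                    f"ID=cds:{t.accession}.{i};Parent=transcript:{t.accession}\n"
                )
                cum += len(e)


def _gtf_to_gff3(text: str) -> str:
    """Minimal GTF → GFF3 attribute conversion for CDS grouping."""
    out = ["##gff-version 3"]
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise InputError(f"malformed GTF line: {line[:80]}")
        attrs = cols[8]
        tid = None
        for part in attrs.split(";"):
            part = part.strip()
            if part.startswith("transcript_id"):
                tid = part.split(None, 1)[1].strip().strip('"')
        if tid is None:
            continue
        cols[8] = f"Parent=transcript:{tid}"
        out.append("\t".join(cols))
    return "\n".join(out) + "\n"


def read_transcripts_gff(
    path: str | Path,
    releases: Optional[dict[str, int]] = None,
) -> tuple[list[Transcript], str]:
    """Parse CDS features grouped by Parent; returns (transcripts, strand).

    GTF files (``.gtf`` suffix) are converted on the fly.  Coordinates are
    returned 0-based half-open in file orientation; strand normalisation
    is applied by :func:`load_gene_pair` once the gene length is known.
    """
    path = Path(path)
    if path.suffix.lower() == ".gtf":
        db = gffutils.create_db(
            _gtf_to_gff3(path.read_text()),
            dbfn=":memory:",
            from_string=True,
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    else:
        try:
            db = gffutils.create_db(
                str(path),
                dbfn=":memory:",
                force=True,
                keep_order=True,
                merge_strategy="create_unique",
            )
        except Exception as exc:  # gffutils raises assorted parse errors
            raise InputError(f"malformed GFF3 {path}: {exc}") from exc
    groups: dict[str, list[tuple[int, int, str, str]]] = {}
    for feat in db.features_of_type("CDS"):
        parents = feat.attributes.get("Parent") or feat.attributes.get("ID")
        if not parents:
            raise InputError(
                f"{path}: CDS feature without Parent at line for "
                f"{feat.seqid}:{feat.start}-{feat.end}"
            )
        acc = parents[0].split(":")[-1]
        groups.setdefault(acc, []).append(
            (feat.start - 1, feat.end, feat.strand, feat.seqid)
        )
    strands = {s for exons in groups.values() for (_a, _b, s, _g) in exons}
    strands.discard(".")
    if len(strands) > 1:
        raise InputError(f"{path}: mixed strands in one gene")
    strand = strands.pop() if strands else "+"
    transcripts = []
    releases = releases or {}
    for acc, exons in sorted(groups.items()):
        exons.sort()
        gene_id = exons[0][3]
        transcripts.append(
            Transcript(
                accession=acc,
                gene_id=gene_id,
                exons=tuple(Exon(s, e) for (s, e, _st, _g) in exons),
                release=releases.get(acc),
            )
        )
    return transcripts, strand


def read_releases_tsv(path: str | Path) -> dict[str, int]:
    releases: dict[str, int] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            rel = row.get("release", "")
            if rel:
                releases[row["accession"]] = int(rel)
    return releases


def read_ortholog_table(path: str | Path) -> list[tuple[str, str]]:
    pairs = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            pairs.append((row["gene_a"], row["gene_b"]))
    counts: dict[str, int] = {}
    for a, b in pairs:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    if any(c > 1 for c in counts.values()):
        raise InputError("ortholog table is not one-to-one")
    return pairs


def _reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _normalize_strand(
    gene_id: str,
    species: str,
    seq: str,
    transcripts: list[Transcript],
    strand: str,
) -> tuple[GeneSequence, list[Transcript]]:
    if strand != "-":
        return GeneSequence(gene_id, species, seq), transcripts
    L = len(seq)
    flipped = [
        Transcript(
            t.accession,
            t.gene_id,
            tuple(
                Exon(L - e.end, L - e.start) for e in reversed(t.exons)
            ),
            t.release,
        )
        for t in transcripts
    ]
    gene = GeneSequence(
        gene_id, species, _reverse_complement(seq),
        strand_note="reverse_complemented",
    )
    return gene, flipped


def load_gene_pair(
    fasta_a: str | Path,
    gff_a: str | Path,
    fasta_b: str | Path,
    gff_b: str | Path,
    releases_tsv: Optional[str | Path] = None,
    species_a: str = "speciesA",
    species_b: str = "speciesB",
) -> tuple[GenePair, list[tuple[str, str]]]:
    """Load and validate one orthologous gene pair.

    Transcripts failing frame or translation validation are skipped with a
    warning and reported in the second return value as (accession, reason).
    """
    releases = read_releases_tsv(releases_tsv) if releases_tsv else {}
    skipped: list[tuple[str, str]] = []

    def _load_side(fasta, gff, species):
        seqs = read_fasta(fasta)
        transcripts, strand = read_transcripts_gff(gff, releases)
        if not transcripts:
            raise InputError(f"{gff}: no CDS features found")
        gene_id = transcripts[0].gene_id
        if gene_id not in seqs:
            if len(seqs) == 1:
                gene_id_only, = seqs
                transcripts = [
                    Transcript(t.accession, gene_id_only, t.exons, t.release)
                    for t in transcripts
                ]
                gene_id = gene_id_only
            else:
                raise InputError(f"gene {gene_id} not in {fasta}")
        gene, transcripts = _normalize_strand(
            gene_id, species, seqs[gene_id], transcripts, strand
        )
        valid = []
        for t in transcripts:
            ok, reason = is_valid_coding(t, gene)
            if ok:
                valid.append(t)
            else:
                logger.warning("skipping %s: %s", t.accession, reason)
                skipped.append((t.accession, reason))
        return gene, valid

    gene_a, ts_a = _load_side(fasta_a, gff_a, species_a)
    gene_b, ts_b = _load_side(fasta_b, gff_b, species_b)
    return GenePair(gene_a, gene_b, ts_a, ts_b), skipped


# ---------------------------------------------------------------------------
# report writing

def write_strings_csv(analysis, path: str | Path) -> None:
    """Gene models and transcript strings in block/signal notation."""
    rows = [
        {
            "kind": "gene_model",
            "species": analysis.reference.model_a.species,
            "accession": "",
            "symbols": analysis.reference.model_a.symbols,
        },
        {
            "kind": "gene_model",
            "species": analysis.reference.model_b.species,
            "accession": "",
            "symbols": analysis.reference.model_b.symbols,
        },
    ]
    for which in ("a", "b"):
        species = analysis.reference.gene(which).species
        for acc, ts in sorted(analysis.reference.strings(which).items()):
            rows.append(
                {
                    "kind": "transcript",
                    "species": species,
                    "accession": acc,
                    "symbols": ts.symbols,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_labels_csv(report, path: str | Path) -> None:
    rows = []
    for k, t in report.splicing_orthologs:
        rows.append({"accession": k, "label": "splicing_ortholog", "partner": t})
    for k in report.confirmed_yet_to_be_found:
        rows.append({"accession": k, "label": "confirmed_yet_to_be_found", "partner": ""})
    for k in report.confirmed_species_specific:
        rows.append({"accession": k, "label": "confirmed_species_specific", "partner": ""})
    for k, sub in report.unresolved:
        rows.append({"accession": k, "label": f"unresolved:{sub}", "partner": ""})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_table_csv(report, n_known_target: int, path: str | Path) -> None:
    """Summary table: counts, proportions, precision and recall."""
    from .covalidation import precision, recall, rounded

    a = len(report.splicing_orthologs)
    b = len(report.confirmed_yet_to_be_found)
    c = len(report.confirmed_species_specific)
    u = len(report.unresolved)
    d = report.total
    prec = precision(a, b)
    rec = recall(a, n_known_target)
    rows = [
        {"row": "splicing_orthologs", "value": a},
        {"row": "confirmed_yet_to_be_found", "value": b},
        {"row": "confirmed_species_specific", "value": c},
        {"row": "unresolved", "value": u},
        {"row": "total", "value": d},
        {"row": "proportion_yet_to_be_found",
         "value": rounded(b / d) if d else None},
        {"row": "proportion_species_specific",
         "value": rounded(c / d) if d else None},
        {"row": "precision", "value": rounded(prec)},
        {"row": "precision_exact", "value": prec},
        {"row": "recall", "value": rounded(rec)},
        {"row": "recall_exact", "value": rec},
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
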