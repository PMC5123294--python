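"""Synthetic orthologous gene pairs with known splicing-orthology truth.

The generator emulates CCDS-like input for one orthologous gene pair: an
ancestral multi-exon coding gene is built (canonical GT/AG introns, ATG
start, stop codon included in the CDS), two descendant genes diverge from
it by point substitutions (and optional intronic indels), and each
species receives a transcript repertoire assembled from a declared set of
alternative-splicing events:

``exon_skip``
    an isoform skipping one internal exon;
``alt_donor``
    a donor shift of 3 or 6 nt truncating an internal exon (an exon
    isoform, in frame);
``alt_acceptor``
    an acceptor shift of 6 nt truncating an exon start;
``nagnag``
    a tandem-acceptor (NAGNAG) shift of 3 nt, removing one residue next
    to the junction;
``species_specific_exon``
    a cassette exon present in only one gene (the other gene lacks the
    sequence entirely), used by a dedicated isoform of the carrier
    species;
``start_shift``
    an isoform starting at an internal ATG of a downstream exon;
``stop_shift``
    an isoform reading through a donor site into the intron up to an
    early stop codon.

All exon lengths are multiples of 3, so every junction has phase 0 and
all event shifts preserve frame across isoforms.  Splice dinucleotides,
start/stop codons and the motifs of the planned alternative sites are
protected from substitution (strong purifying selection), and coding
substitutions that would create a stop codon are resampled, so generated
transcripts always validate.  Ground-truth labels follow directly from
each isoform's presence pattern: present in both species → ortholog;
present in one species with all of its splice sites present in the other
gene → yet-to-be-found; using the species-specific exon → species
specific.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .core import Exon, GenePair, GeneSequence, Transcript

EVENT_NAMES = (
    "exon_skip",
    "alt_donor",
    "alt_acceptor",
    "nagnag",
    "species_specific_exon",
    "start_shift",
    "stop_shift",
)

STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
_CODONS = [
    "".join(c) for c in itertools.product(_BASES, repeat=3)
    if "".join(c) not in STOPS
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic benchmark.

    ``divergence`` is the expected pairwise nucleotide divergence between
    the two genes; each lineage receives half of it.  ``indel_rate`` is a
    per-site insertion/deletion probability applied to intron interiors
    only (CCDS coding regions are curated to be frame-consistent).
    """

    n_exons: tuple[int, int] = (6, 8)
    exon_len: tuple[int, int] = (30, 90)
    intron_len: tuple[int, int] = (40, 80)
    events: tuple[str, ...] = (
        "exon_skip",
        "alt_donor",
        "nagnag",
        "species_specific_exon",
    )
    divergence: float = 0.05
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must be in [0, 1]")
        if not 0.0 <= self.indel_rate <= 1.0:
            raise ValueError("indel_rate must be in [0, 1]")
        for ev in self.events:
            if ev not in EVENT_NAMES:
                raise ValueError(f"unknown event {ev!r}")


@dataclass
class TruthTable:
    """Expected labels per generated transcript accession."""

    labels: dict[str, tuple[str, Optional[str]]]  # acc -> (label, partner)
    expected_blocks: int

    def label(self, accession: str) -> str:
        return self.labels[accession][0]

    def partner(self, accession: str) -> Optional[str]:
        return self.labels[accession][1]


@dataclass
class _IsoformPlan:
    name: str
    exon_indices: list[int]
    presence: str  # 'both' | 'a' | 'b'
    donor_shift: dict[int, int] = field(default_factory=dict)
    acceptor_shift: dict[int, int] = field(default_factory=dict)
    start_offset: Optional[tuple[int, int]] = None  # (exon, offset)
    stop_extension: Optional[tuple[int, int]] = None  # (exon, length)
    uses_specific_exon: bool = False


def _random_codons(rng: np.random.Generator, n: int) -> list[str]:
    return [_CODONS[i] for i in rng.integers(0, len(_CODONS), n)]


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, n))


def generate_pair(cfg: SimConfig) -> tuple[GenePair, TruthTable]:
    """Generate one gene pair and its ground truth, reproducibly by seed."""
    rng = np.random.default_rng(cfg.seed)
    n = int(rng.integers(cfg.n_exons[0], cfg.n_exons[1] + 1))
    lo = max(6, cfg.exon_len[0] // 3)
    hi = max(lo, cfg.exon_len[1] // 3)
    exon_codons = [int(x) for x in rng.integers(lo, hi + 1, n)]
    exon_lens = [3 * c for c in exon_codons]
    intron_lens = [
        max(20, int(x))
        for x in rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1, n - 1)
    ]
    pad = 30

    internal = [int(1 + k) for k in rng.permutation(n - 2)]
    events = list(cfg.events)[: len(internal)]
    target_exon = {i: internal[i] for i in range(len(events))}

    # --- per-exon codon sequences with event motifs ----------------------
    exon_seq = [_random_codons(rng, c) for c in exon_codons]
    exon_seq[0][0] = "ATG"
    exon_seq[-1][-1] = STOPS[int(rng.integers(0, 3))]

    protected: set[tuple[int, int]] = set()  # (exon or intron id, offset)

    ss_exon: Optional[int] = None
    ss_carrier = "a"
    plans: list[_IsoformPlan] = []

    def _presence() -> str:
        return ("both", "a", "b")[int(rng.integers(0, 3))]

    # plan events first so sequence motifs can be installed
    for ei, ev in enumerate(events):
        x = target_exon[ei]
        if ev == "species_specific_exon":
            ss_exon = x
            ss_carrier = "a" if rng.integers(0, 2) == 0 else "b"

    base_exons = [i for i in range(n) if i != ss_exon]
    plans.append(_IsoformPlan("base", base_exons, "both"))

    intron_prefix: dict[int, str] = {}
    for ei, ev in enumerate(events):
        x = target_exon[ei]
        if ev == "species_specific_exon":
            plans.append(
                _IsoformPlan(
                    "cassette",
                    sorted(base_exons + [x]),
                    ss_carrier,
                    uses_specific_exon=True,
                )
            )
        elif ev == "exon_skip":
            plans.append(
                _IsoformPlan(
                    "skip", [i for i in base_exons if i != x], _presence()
                )
            )
        elif ev == "alt_donor":
            k = 3 if exon_lens[x] < 30 else int(rng.choice([3, 6]))
            # the truncated donor needs GT at its new border
            c = (exon_lens[x] - k) // 3
            exon_seq[x][c] = "GTG"
            protected.add(("e", x, exon_lens[x] - k))
            protected.add(("e", x, exon_lens[x] - k + 1))
            plans.append(
                _IsoformPlan(
                    "altdonor", list(base_exons), _presence(),
                    donor_shift={x: k},
                )
            )
        elif ev == "nagnag":
            exon_seq[x][0] = "CAG"  # NAGNAG: intron ...AG | CAG | exon
            protected.add(("e", x, 1))
            protected.add(("e", x, 2))
            plans.append(
                _IsoformPlan(
                    "nagnag", list(base_exons), _presence(),
                    acceptor_shift={x: 3},
                )
            )
        elif ev == "alt_acceptor":
            exon_seq[x][0] = "CTG"
            exon_seq[x][1] = "AAG"  # AG at offsets 4-5: alternative acceptor
            protected.add(("e", x, 4))
            protected.add(("e", x, 5))
            plans.append(
                _IsoformPlan(
                    "altacceptor", list(base_exons), _presence(),
                    acceptor_shift={x: 6},
                )
            )
        elif ev == "start_shift":
            exon_seq[x][3] = "ATG"  # internal start 9 nt into the exon
            for off in (9, 10, 11):
                protected.add(("e", x, off))
            plans.append(
                _IsoformPlan(
                    "startshift",
                    [i for i in base_exons if i >= x],
                    _presence(),
                    start_offset=(x, 9),
                )
            )
        elif ev == "stop_shift":
            intron_prefix[x] = "GTGAAATAA"  # read-through with early stop
            for off in range(9):
                protected.add(("i", x, off))
            plans.append(
                _IsoformPlan(
                    "stopshift",
                    [i for i in base_exons if i <= x],
                    _presence(),
                    stop_extension=(x, 9),
                )
            )

    # --- ancestral regions -----------------------------------------------
    regions: list[tuple[str, int, str]] = []  # (kind, index, seq)
    regions.append(("pad", -1, _random_nt(rng, pad)))
    for i in range(n):
        regions.append(("e", i, "".join(exon_seq[i])))
        if i < n - 1:
            L = intron_lens[i]
            prefix = intron_prefix.get(i, "GT")
            body = _random_nt(rng, L - len(prefix) - 2)
            regions.append(("i", i, prefix + body + "AG"))
    regions.append(("pad", n, _random_nt(rng, pad)))

    # protect start/stop codons and all splice dinucleotides
    for off in range(3):
        protected.add(("e", 0, off))
        protected.add(("e", n - 1, exon_lens[n - 1] - 3 + off))
    for i in range(n - 1):
        protected.add(("i", i, 0))
        protected.add(("i", i, 1))
        protected.add(("i", i, intron_lens[i] - 2))
        protected.add(("i", i, intron_lens[i] - 1))

    # --- mutate descendants ------------------------------------------------
    lineage_rate = cfg.divergence / 2.0

    def _mutate(kind: str, idx: int, seq: str) -> str:
        chars = list(seq)
        coding_ext = (
            intron_prefix.get(idx) is not None and kind == "i"
        )
        for p in range(len(chars)):
            if (kind, idx, p) in protected:
                continue
            if rng.random() >= lineage_rate:
                continue
            alternatives = [b for b in _BASES if b != chars[p]]
            order = rng.permutation(len(alternatives))
            for nb in (alternatives[int(i)] for i in order):
                if kind == "e" or (coding_ext and p < 9):
                    c0 = p - p % 3
                    codon = "".join(chars[c0:c0 + 3])
                    codon = codon[: p - c0] + nb + codon[p - c0 + 1:]
                    if codon in STOPS:
                        continue
                chars[p] = nb
                break
        out = "".join(chars)
        if kind == "i" and cfg.indel_rate > 0:
            out = _intron_indels(out, idx, rng, cfg.indel_rate, intron_prefix)
        return out

    def _descend(drop_exon: Optional[int]) -> tuple[str, dict[int, tuple[int, int]]]:
        seq_parts: list[str] = []
        exon_spans: dict[int, tuple[int, int]] = {}
        pos = 0
        skip_next_intron = False
        for kind, idx, seq in regions:
            if kind == "e" and idx == drop_exon:
                skip_next_intron = True
                continue
            if kind == "i" and skip_next_intron:
                skip_next_intron = False
                continue
            mutated = _mutate(kind, idx, seq)
            if kind == "e":
                exon_spans[idx] = (pos, pos + len(mutated))
            seq_parts.append(mutated)
            pos += len(mutated)
        return "".join(seq_parts), exon_spans

    drop_a = ss_exon if (ss_exon is not None and ss_carrier == "b") else None
    drop_b = ss_exon if (ss_exon is not None and ss_carrier == "a") else None
    seq_a, spans_a = _descend(drop_a)
    seq_b, spans_b = _descend(drop_b)

    gene_id_a = f"GENE{cfg.seed}A"
    gene_id_b = f"GENE{cfg.seed}B"
    gene_a = GeneSequence(gene_id_a, "speciesA", seq_a)
    gene_b = GeneSequence(gene_id_b, "speciesB", seq_b)

    # --- transcripts and truth --------------------------------------------
    def _exons_for(plan: _IsoformPlan, spans: dict[int, tuple[int, int]]) -> tuple[Exon, ...]:
        exons = []
        for i in plan.exon_indices:
            s, e = spans[i]
            if i in plan.donor_shift:
                e -= plan.donor_shift[i]
            if i in plan.acceptor_shift:
                s += plan.acceptor_shift[i]
            if plan.start_offset and plan.start_offset[0] == i:
                s += plan.start_offset[1]
            if plan.stop_extension and plan.stop_extension[0] == i:
                e += plan.stop_extension[1]
            exons.append(Exon(s, e))
        return tuple(exons)

    transcripts_a: list[Transcript] = []
    transcripts_b: list[Transcript] = []
    labels: dict[str, tuple[str, Optional[str]]] = {}
    num_a, num_b = 101, 201
    for plan in plans:
        release_a = 2 if plan.name == "base" else int(rng.integers(2, 20))
        release_b = 2 if plan.name == "base" else int(rng.integers(2, 20))
        acc_a = acc_b = None
        if plan.presence in ("both", "a"):
            acc_a = f"CCDS{num_a}.1"
            num_a += 1
            transcripts_a.append(
                Transcript(acc_a, gene_id_a, _exons_for(plan, spans_a), release_a)
            )
        if plan.presence in ("both", "b"):
            acc_b = f"CCDS{num_b}.1"
            num_b += 1
            transcripts_b.append(
                Transcript(acc_b, gene_id_b, _exons_for(plan, spans_b), release_b)
            )
        for acc, partner in ((acc_a, acc_b), (acc_b, acc_a)):
            if acc is None:
                continue
            if partner is not None:
                labels[acc] = ("ortholog", partner)
            elif plan.uses_specific_exon:
                labels[acc] = ("species_specific", None)
            else:
                labels[acc] = ("yet_to_be_found", None)

    splitting = {"alt_donor", "alt_acceptor", "nagnag", "start_shift", "stop_shift"}
    expected_blocks = n + sum(1 for ev in events if ev in splitting)
    truth = TruthTable(labels=labels, expected_blocks=expected_blocks)
    return GenePair(gene_a, gene_b, transcripts_a, transcripts_b), truth


def _intron_indels(
    seq: str,
    idx: int,
    rng: np.random.Generator,
    rate: float,
    intron_prefix: dict[int, str],
) -> str:
    """Apply short indels to an intron interior, sparing splice borders
    and any read-through extension prefix."""
    lo = 2 + (9 if idx in intron_prefix else 0)
    hi = len(seq) - 2
    out: list[str] = [seq[:lo]]
    p = lo
    while p < hi:
        if rng.random() < rate:
            length = min(5, int(rng.geometric(0.5)))
            if rng.integers(0, 2) == 0 and hi - p > length + 4:
                p += length  # deletion
                continue
            out.append(_random_nt(rng, length))  # insertion
        out.append(seq[p])
        p += 1
    out.append(seq[hi:])
    return "".join(out)


def write_fixture(
    pair: GenePair, truth: TruthTable, outdir: str | Path
) -> dict[str, Path]:
    """Serialize a generated pair as FASTA + GFF3 + TSV + truth CSV."""
    from . import io as io_mod

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta_a": outdir / "gene_a.fasta",
        "fasta_b": outdir / "gene_b.fasta",
        "gff_a": outdir / "gene_a.gff3",
        "gff_b": outdir / "gene_b.gff3",
        "transcripts": outdir / "transcripts.tsv",
        "orthologs": outdir / "orthologs.tsv",
        "truth": outdir / "truth.csv",
    }
    io_mod.write_fasta(pair.gene_a, paths["fasta_a"])
    io_mod.write_fasta(pair.gene_b, paths["fasta_b"])
    io_mod.write_gff3(pair.transcripts_a, pair.gene_a, paths["gff_a"])
    io_mod.write_gff3(pair.transcripts_b, pair.gene_b, paths["gff_b"])
    with open(paths["transcripts"], "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["accession", "gene_id", "release"])
        for t in pair.transcripts_a + pair.transcripts_b:
            w.writerow([t.accession, t.gene_id, t.release if t.release else ""])
    with open(paths["orthologs"], "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["gene_a", "gene_b"])
        w.writerow([pair.gene_a.gene_id, pair.gene_b.gene_id])
    with open(paths["truth"], "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["accession", "label", "partner"])
        for acc, (label, partner) in sorted(truth.labels.items()):
            w.writerow([acc, label, partner or ""])
    return paths
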