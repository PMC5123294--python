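"""Protein-level controller: junction-constrained ortholog pairing.

For one orthologous gene pair, the controller aligns protein isoforms of
the two species (semi-global, Blosum62, free end gaps) within groups of
equal exon count, keeps *unique* best reciprocal hits (strict score
maxima on both sides; ties yield no candidate), and accepts a candidate
pair only when

* every exon junction of one protein sits in the same alignment column
  as the corresponding junction of the other (``junction_ok``),
* no gap occurs within ``v`` columns (default 2) of any junction column
  (``vicinity_ok``) — insertions and deletions inside an exon are allowed,
* the alignment of the first exon's right segment and of the last exon's
  left segment, over at most ``w`` (default 10) amino acids, scores
  non-negatively with Blosum62 (``terminal_ok``) — terminal exon
  positions may differ, so their conserved side is tested explicitly.

Isoforms whose translation contains an internal stop codon (candidate
frame-shifts) are excluded before pairing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

from .align import GAP, Alignment, blosum62, semiglobal_align
from .core import JunctionMark, ProteinIsoform

logger = logging.getLogger(__name__)


@dataclass
class ControllerPair:
    """A candidate protein ortholog pair and its per-rule flags."""

    acc_a: str
    acc_b: str
    alignment: Alignment
    junction_ok: bool = False
    vicinity_ok: bool = False
    terminal_ok: bool = False
    brh_ok: bool = False

    @property
    def accepted(self) -> bool:
        return (
            self.junction_ok
            and self.vicinity_ok
            and self.terminal_ok
            and self.brh_ok
        )


def unique_brh(
    scores: dict[tuple[str, str], float],
    accs_a: list[str],
    accs_b: list[str],
) -> list[tuple[str, str]]:
    """Unique best reciprocal hits under strict score maxima.

    ``(p, q)`` is returned iff ``q`` is ``p``'s strictly best-scoring
    partner and vice versa; any tie for the maximum disqualifies the
    member, so each accession occurs in at most one pair.
    """
    if not accs_a or not accs_b:
        return []

    def strict_best(acc: str, others: list[str], first: bool) -> Optional[str]:
        vals = [
            (scores[(acc, o)] if first else scores[(o, acc)], o) for o in others
        ]
        top = max(v for v, _ in vals)
        winners = [o for v, o in vals if v == top]
        return winners[0] if len(winners) == 1 else None

    pairs = []
    for p in accs_a:
        q = strict_best(p, accs_b, True)
        if q is None:
            continue
        if strict_best(q, accs_a, False) == p:
            pairs.append((p, q))
    return pairs


def candidate_pairs(
    proteins_a: Iterable[ProteinIsoform],
    proteins_b: Iterable[ProteinIsoform],
    gap_open: int = 11,
    gap_extend: int = 1,
) -> list[ControllerPair]:
    """Unique BRH candidates among isoforms with equal exon counts."""
    by_count_a: dict[int, list[ProteinIsoform]] = {}
    by_count_b: dict[int, list[ProteinIsoform]] = {}
    for p in proteins_a:
        by_count_a.setdefault(p.n_exons, []).append(p)
    for p in proteins_b:
        by_count_b.setdefault(p.n_exons, []).append(p)

    out: list[ControllerPair] = []
    for count in sorted(set(by_count_a) & set(by_count_b)):
        ga = sorted(by_count_a[count], key=lambda p: p.transcript_accession)
        gb = sorted(by_count_b[count], key=lambda p: p.transcript_accession)
        alignments: dict[tuple[str, str], Alignment] = {}
        scores: dict[tuple[str, str], float] = {}
        for pa in ga:
            for pb in gb:
                al = semiglobal_align(
                    pa.residues, pb.residues, gap_open, gap_extend
                )
                key = (pa.transcript_accession, pb.transcript_accession)
                alignments[key] = al
                scores[key] = al.score
        for key in unique_brh(
            scores,
            [p.transcript_accession for p in ga],
            [p.transcript_accession for p in gb],
        ):
            out.append(
                ControllerPair(
                    acc_a=key[0],
                    acc_b=key[1],
                    alignment=alignments[key],
                    brh_ok=True,
                )
            )
    return out


def _junction_columns(
    al: Alignment, ja: Iterable[JunctionMark], jb: Iterable[JunctionMark]
) -> tuple[list[int], list[int]]:
    cols_a = al.columns_of("a")
    cols_b = al.columns_of("b")
    try:
        ca = [cols_a[m.aa_index] for m in ja]
        cb = [cols_b[m.aa_index] for m in jb]
    except KeyError as exc:
        raise ValueError(f"junction residue index {exc} beyond protein length")
    return ca, cb


def check_junctions(
    al: Alignment,
    ja: list[JunctionMark],
    jb: list[JunctionMark],
    v: int = 2,
) -> tuple[bool, bool]:
    """Junction-preservation and near-junction gap-freedom of an alignment.

    ``junction_ok``: every corresponding junction pair shares an alignment
    column.  ``vicinity_ok``: no gap character within ``v`` columns of any
    junction column (windows truncate at the alignment ends).
    """
    assert len(ja) == len(jb), "equal exon counts required"
    ca, cb = _junction_columns(al, ja, jb)
    junction_ok = all(x == y for x, y in zip(ca, cb))
    vicinity_ok = True
    ncol = al.n_columns
    for c in set(ca) | set(cb):
        lo, hi = max(0, c - v), min(ncol - 1, c + v)
        window_a = al.aligned_a[lo:hi + 1]
        window_b = al.aligned_b[lo:hi + 1]
        if GAP in window_a or GAP in window_b:
            vicinity_ok = False
            break
    return junction_ok, vicinity_ok


def _window_score(
    al: Alignment, lo: int, hi: int, gap_open: int, gap_extend: int
) -> int:
    """Blosum62 score of alignment columns [lo, hi]; gap columns score the
    gap penalty (open for the first column of a run, extend afterwards)."""
    score = 0
    for c in range(lo, hi + 1):
        x, y = al.aligned_a[c], al.aligned_b[c]
        if x != GAP and y != GAP:
            score += blosum62(x, y)
        else:
            seq = al.aligned_a if x == GAP else al.aligned_b
            opened = c == 0 or seq[c - 1] != GAP
            score -= gap_open if opened else gap_extend
    return score


def check_terminal_exons(
    al: Alignment,
    ja: list[JunctionMark],
    jb: list[JunctionMark],
    w: int = 10,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> bool:
    """Conservation test of the terminal exon segments adjacent to the
    first and last junctions.

    The right segment of the first exon (the up-to-``w`` columns ending at
    the first junction column) and the left segment of the last exon (the
    up-to-``w`` columns following the last junction) must each score
    non-negatively.  Windows truncate where either sequence enters its
    free end gap, so very small terminal exons are handled by truncation.
    """
    ca, cb = _junction_columns(al, ja, jb)
    first_col = ca[0]
    last_col = ca[-1]
    lo_bound = al.first_common_column()
    hi_bound = al.last_common_column()

    lo = max(first_col - w + 1, lo_bound)
    if lo <= first_col:
        if _window_score(al, lo, first_col, gap_open, gap_extend) < 0:
            return False

    start = last_col if ja[-1].phase != 0 else last_col + 1
    hi = min(start + w - 1, hi_bound)
    if start <= hi:
        if _window_score(al, start, hi, gap_open, gap_extend) < 0:
            return False
    return True


def controller_list(
    proteins_a: Iterable[ProteinIsoform],
    proteins_b: Iterable[ProteinIsoform],
    v: int = 2,
    terminal_window: int = 10,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> list[ControllerPair]:
    """All controller candidates with their validation flags.

    Accepted pairs (``.accepted``) are the putative protein ortholog pairs
    whose underlying transcripts have the same splicing pattern.
    """
    prots_a = list(proteins_a)
    prots_b = list(proteins_b)
    for p in prots_a + prots_b:
        if len(p.residues) < terminal_window:
            logger.warning(
                "isoform %s shorter than the terminal window (%d aa)",
                p.transcript_accession,
                len(p.residues),
            )
    by_acc_a = {p.transcript_accession: p for p in prots_a}
    by_acc_b = {p.transcript_accession: p for p in prots_b}
    pairs = candidate_pairs(prots_a, prots_b, gap_open, gap_extend)
    for pair in pairs:
        ja = list(by_acc_a[pair.acc_a].junctions)
        jb = list(by_acc_b[pair.acc_b].junctions)
        if not ja:  # single-exon group: no junction constraints apply
            pair.junction_ok = True
            pair.vicinity_ok = True
            pair.terminal_ok = True
            continue
        pair.junction_ok, pair.vicinity_ok = check_junctions(
            pair.alignment, ja, jb, v=v
        )
        if pair.junction_ok:
            pair.terminal_ok = check_terminal_exons(
                pair.alignment, ja, jb, terminal_window, gap_open, gap_extend
            )
    return pairs


def accepted_pairs(pairs: Iterable[ControllerPair]) -> list[tuple[str, str]]:
    return [(p.acc_a, p.acc_b) for p in pairs if p.accepted]
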