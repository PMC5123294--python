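"""Sequence alignment primitives.

Two alignment flavours are used by the pipeline:

* A semi-global protein alignment (free leading/trailing gaps, Blosum62,
  affine internal gap penalties) with fully deterministic tie-breaking and
  explicit column bookkeeping.  This is the controller's core primitive and
  is implemented here as a Gotoh dynamic program; a gap of length ``L``
  costs ``gap_open + gap_extend * (L - 1)``.
* Local nucleotide alignment used to locate exon segments (with flanking
  genomic context) inside the orthologous gene.  This stands in for the
  similarity searches of the original protocol and is delegated to
  Biopython's :class:`PairwiseAligner` (match +1, mismatch -1, gap -2).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

from Bio import Align
from Bio.Align import substitution_matrices

GAP = "-"
_NEG = -(10 ** 9)

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def blosum62(a: str, b: str) -> int:
    """Blosum62 substitution score for a residue pair."""
    return int(BLOSUM62[a, b])


def self_score(p: str) -> int:
    """Blosum62 score of aligning a protein with itself."""
    return sum(blosum62(x, x) for x in p)


@dataclass(frozen=True)
class Alignment:
    """A pairwise protein alignment with gap characters.

    ``score`` is the semi-global score: Blosum62 over substitution columns,
    affine penalties for internal gaps, leading/trailing gaps free.
    """

    aligned_a: str
    aligned_b: str
    score: int

    def __post_init__(self) -> None:
        assert len(self.aligned_a) == len(self.aligned_b)

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)

    def columns_of(self, which: str) -> dict[int, int]:
        """Map 1-based residue index of sequence 'a' or 'b' to its column."""
        aligned = self.aligned_a if which == "a" else self.aligned_b
        cols: dict[int, int] = {}
        r = 0
        for c, ch in enumerate(aligned):
            if ch != GAP:
                r += 1
                cols[r] = c
        return cols

    def first_common_column(self) -> int:
        """First column where neither sequence is in a leading end gap."""
        fa = next(c for c, ch in enumerate(self.aligned_a) if ch != GAP)
        fb = next(c for c, ch in enumerate(self.aligned_b) if ch != GAP)
        return max(fa, fb)

    def last_common_column(self) -> int:
        """Last column where neither sequence is in a trailing end gap."""
        la = max(c for c, ch in enumerate(self.aligned_a) if ch != GAP)
        lb = max(c for c, ch in enumerate(self.aligned_b) if ch != GAP)
        return min(la, lb)


# traceback states
_M, _GA, _GB = 0, 1, 2  # substitution / gap in aligned_a / gap in aligned_b


def semiglobal_align(
    a: str,
    b: str,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> Alignment:
    """Optimal semi-global alignment of proteins ``a`` and ``b``.

    Leading and trailing gaps are free; an internal gap of length ``L``
    costs ``gap_open + gap_extend*(L-1)``.  Ties are broken
    deterministically: substitution is preferred over a gap, and a gap in
    the first sequence over a gap in the second; among equal-scoring end
    points the one consuming most of both sequences is preferred.
    """
    if not a or not b:
        raise ValueError("semiglobal_align requires non-empty sequences")
    n, m = len(a), len(b)
    # score[state][i][j]; ptr holds the predecessor state
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    Ga = [[_NEG] * (m + 1) for _ in range(n + 1)]
    Gb = [[_NEG] * (m + 1) for _ in range(n + 1)]
    pM = [[-1] * (m + 1) for _ in range(n + 1)]
    pGa = [[-1] * (m + 1) for _ in range(n + 1)]
    pGb = [[-1] * (m + 1) for _ in range(n + 1)]

    M[0][0] = 0
    for j in range(1, m + 1):  # free leading gap in a (consumes b)
        Ga[0][j] = 0
    for i in range(1, n + 1):  # free leading gap in b (consumes a)
        Gb[i][0] = 0

    for i in range(1, n + 1):
        row_m, row_ga, row_gb = M[i], Ga[i], Gb[i]
        prev_m, prev_ga, prev_gb = M[i - 1], Ga[i - 1], Gb[i - 1]
        ai = a[i - 1]
        for j in range(1, m + 1):
            # substitution: predecessor preference M > Ga > Gb on ties
            best, state = prev_m[j - 1], _M
            if prev_ga[j - 1] > best:
                best, state = prev_ga[j - 1], _GA
            if prev_gb[j - 1] > best:
                best, state = prev_gb[j - 1], _GB
            row_m[j] = best + blosum62(ai, b[j - 1])
            pM[i][j] = state
            # gap in aligned_a, consuming b[j-1]
            best, state = row_m[j - 1] - gap_open, _M
            if row_ga[j - 1] - gap_extend > best:
                best, state = row_ga[j - 1] - gap_extend, _GA
            if row_gb[j - 1] - gap_open > best:
                best, state = row_gb[j - 1] - gap_open, _GB
            row_ga[j] = best
            pGa[i][j] = state
            # gap in aligned_b, consuming a[i-1]
            best, state = prev_m[j] - gap_open, _M
            if prev_ga[j] - gap_open > best:
                best, state = prev_ga[j] - gap_open, _GA
            if prev_gb[j] - gap_extend > best:
                best, state = prev_gb[j] - gap_extend, _GB
            row_gb[j] = best
            pGb[i][j] = state

    def cell_best(i: int, j: int) -> tuple[int, int]:
        best, state = M[i][j], _M
        if Ga[i][j] > best:
            best, state = Ga[i][j], _GA
        if Gb[i][j] > best:
            best, state = Gb[i][j], _GB
        return best, state

    # end point: trailing remainder is free; prefer the corner, then last
    # row right-to-left, then last column bottom-up
    end_candidates = [(n, j) for j in range(m, -1, -1)]
    end_candidates += [(i, m) for i in range(n - 1, -1, -1)]
    best_score, best_end, best_state = _NEG, (n, m), _M
    for (i, j) in end_candidates:
        sc, st = cell_best(i, j)
        if sc > best_score:
            best_score, best_end, best_state = sc, (i, j), st

    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = best_end
    # free trailing gaps
    for k in range(n - 1, i - 1, -1):
        out_a.append(a[k])
        out_b.append(GAP)
    for k in range(m - 1, j - 1, -1):
        out_a.append(GAP)
        out_b.append(b[k])
    state = best_state
    while i > 0 or j > 0:
        if state == _M:
            if i == 0 or j == 0:
                break  # origin reached via free leading handling below
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            state = pM[i][j]
            i, j = i - 1, j - 1
        elif state == _GA:
            if i == 0:  # free leading gap in a
                for k in range(j - 1, -1, -1):
                    out_a.append(GAP)
                    out_b.append(b[k])
                j = 0
                break
            out_a.append(GAP)
            out_b.append(b[j - 1])
            state = pGa[i][j]
            j -= 1
        else:  # _GB
            if j == 0:  # free leading gap in b
                for k in range(i - 1, -1, -1):
                    out_a.append(a[k])
                    out_b.append(GAP)
                i = 0
                break
            out_a.append(a[i - 1])
            out_b.append(GAP)
            state = pGb[i][j]
            i -= 1
    return Alignment("".join(reversed(out_a)), "".join(reversed(out_b)), best_score)


@dataclass
class LocalHit:
    """Best local alignment of a query inside a target sequence.

    ``blocks`` are the gap-free aligned runs as ``((t0, t1), (q0, q1))``
    pairs in increasing coordinate order.  ``ambiguous`` is set when a
    co-optimal alignment exists at a disjoint target location, which the
    pipeline treats as "no confident hit".
    """

    score: float
    identity: float
    t_start: int
    t_end: int
    q_start: int
    q_end: int
    blocks: tuple[tuple[tuple[int, int], tuple[int, int]], ...]
    ambiguous: bool = False

    def query_to_target(self, p: int) -> Optional[int]:
        """Project a query cut point (between-nucleotide coordinate).

        Positions inside a query gap collapse onto the following aligned
        run; positions outside the aligned query range return ``None``.
        """
        if not self.blocks:
            return None
        if p < self.blocks[0][1][0] or p > self.blocks[-1][1][1]:
            return None
        for (ts, _te), (qs, qe) in self.blocks:
            if qs <= p <= qe:
                return ts + (p - qs)
            if p < qs:
                return ts
        return None

    def query_position_aligned(self, p: int) -> bool:
        """True when query nucleotide ``p`` sits in a gap-free aligned run."""
        return any(qs <= p < qe for (_t, (qs, qe)) in self.blocks)

    def query_coverage(self, start: int, end: int) -> float:
        """Fraction of query interval [start, end) inside aligned runs."""
        if end <= start:
            return 1.0
        covered = sum(
            max(0, min(qe, end) - max(qs, start))
            for (_t, (qs, qe)) in self.blocks
        )
        return covered / (end - start)


def _nt_aligner(match: int, mismatch: int, gap: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def best_local_hit(
    query: str,
    target: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
    max_alternatives: int = 8,
) -> Optional[LocalHit]:
    """Best-scoring local alignment of ``query`` in ``target``.

    Identity is computed over all columns of the aligned region, gap
    columns included.  The hit is flagged ambiguous when another optimal
    alignment occupies a disjoint target span (e.g. a duplicated exon),
    mirroring the protocol's conservative treatment of tied best hits.
    """
    if not query or not target:
        return None
    aligner = _nt_aligner(match, mismatch, gap)
    alignments = aligner.align(target, query)
    try:
        first = alignments[0]
    except IndexError:
        return None
    t_blocks, q_blocks = first.aligned
    blocks = tuple(
        ((int(ts), int(te)), (int(qs), int(qe)))
        for (ts, te), (qs, qe) in zip(t_blocks, q_blocks)
    )
    if not blocks:
        return None
    matches = 0
    aligned_cols = 0
    for (ts, te), (qs, qe) in blocks:
        aligned_cols += te - ts
        matches += sum(
            1 for x, y in zip(target[ts:te], query[qs:qe]) if x == y
        )
    gap_cols = 0
    for k in range(1, len(blocks)):
        gap_cols += blocks[k][0][0] - blocks[k - 1][0][1]
        gap_cols += blocks[k][1][0] - blocks[k - 1][1][1]
    identity = matches / max(1, aligned_cols + gap_cols)
    t_start, t_end = blocks[0][0][0], blocks[-1][0][1]
    q_start, q_end = blocks[0][1][0], blocks[-1][1][1]
    ambiguous = False
    for alt in itertools.islice(alignments, 1, max_alternatives):
        if alt.score < first.score:
            break
        ats = int(alt.aligned[0][0][0])
        ate = int(alt.aligned[0][-1][1])
        if ate <= t_start or ats >= t_end:
            ambiguous = True
            break
    return LocalHit(
        score=float(first.score),
        identity=identity,
        t_start=t_start,
        t_end=t_end,
        q_start=q_start,
        q_end=q_end,
        blocks=blocks,
        ambiguous=ambiguous,
    )
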