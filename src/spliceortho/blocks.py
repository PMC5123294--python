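"""Common-reference construction for an orthologous gene pair.

The two genes' transcript sets induce a partition of each gene into
*blocks*: maximal exon segments that are either wholly contained in, or
disjoint from, every transcript of either species.  Orthologous segments
are identified by local alignment of each segment (with 20 nt of flanking
genomic context on each side) inside the other gene, requiring a best
reciprocal hit; segment boundaries are then projected across the pair so
both partitions refine each other.

Blocks are labelled alphabetically in gene order of the first species
(A, B, ... Z, AA, AB, ...), with blocks present only in the second
species interleaved at their mapped position.  The *gene model* of a
species is the ordered string of the blocks used by its transcripts,
decorated with four signals: '[' start codon, ']' stop codon, '<' donor
splice site at a block's 3' end, '>' acceptor splice site at a block's
5' end.  Each transcript is then a subsequence string of its gene model,
e.g. ``[A<>B<>C]`` for a three-exon transcript.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .align import LocalHit, best_local_hit
from .core import GeneSequence, Transcript

SIGNAL_KINDS = ("[", "]", "<", ">")

# fixed symbol order around a block; guarantees every transcript string is
# a subsequence of its gene model
_BLOCK_SYMBOL_ORDER = ("[", ">", "label", "<", "]")


class GenePairRejected(Exception):
    """Raised when a gene pair fails homology screening."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class ExonMatch:
    """Best local hit of one species' segment inside the other gene."""

    query_species: str
    query_span: tuple[int, int]
    hit_species: str
    hit_span: Optional[tuple[int, int]]  # projected core span in the target
    identity: float
    reciprocal: bool
    ambiguous: bool = False
    hit: Optional[LocalHit] = field(default=None, repr=False, compare=False)
    q_offset: int = field(default=0, repr=False, compare=False)

    @property
    def matched(self) -> bool:
        return self.hit_span is not None

    def gene_to_target(self, pos: int) -> Optional[int]:
        """Project a gene coordinate of the query species into the target."""
        if self.hit is None:
            return None
        return self.hit.query_to_target(pos - self.q_offset)


@dataclass
class Block:
    """An aligned exon segment of the common reference."""

    label: str
    span_a: Optional[tuple[int, int]] = None
    span_b: Optional[tuple[int, int]] = None

    def span(self, which: str) -> Optional[tuple[int, int]]:
        return self.span_a if which == "a" else self.span_b


@dataclass(frozen=True)
class Signal:
    """A start/stop/donor/acceptor signal anchored on a block."""

    kind: str  # one of '[', ']', '<', '>'
    anchor_block: str

    def __post_init__(self) -> None:
        assert self.kind in SIGNAL_KINDS


@dataclass
class GeneModel:
    """Ordered string of one species' blocks and signals."""

    species: str
    tokens: tuple[str, ...]
    signals: frozenset[Signal]
    block_labels: tuple[str, ...]

    @property
    def symbols(self) -> str:
        return "".join(self.tokens)


@dataclass
class TranscriptString:
    """Block/signal string of one transcript (subsequence of the model)."""

    accession: str
    tokens: tuple[str, ...]

    @property
    def symbols(self) -> str:
        return "".join(self.tokens)

    @property
    def block_labels(self) -> tuple[str, ...]:
        return tuple(t for t in self.tokens if t not in SIGNAL_KINDS)

    @property
    def donor_blocks(self) -> tuple[str, ...]:
        """Blocks carrying a donor signal at their 3' end in this transcript."""
        return tuple(
            self.tokens[i - 1]
            for i, t in enumerate(self.tokens)
            if t == "<"
        )

    @property
    def acceptor_blocks(self) -> tuple[str, ...]:
        return tuple(
            self.tokens[i + 1]
            for i, t in enumerate(self.tokens)
            if t == ">"
        )

    @property
    def pattern(self) -> Optional[tuple[str, ...]]:
        """Flexible-mode splicing pattern: symbols from the donor block of
        the first intron through the acceptor block of the last intron.

        Two transcripts (of the same or different species) have the same
        splicing pattern exactly when these symbol runs are identical; the
        extremities of the first and last exon are left free.  ``None``
        for single-exon transcripts.
        """
        if "<" not in self.tokens:
            return None
        first = self.tokens.index("<")
        last = len(self.tokens) - 1 - tuple(reversed(self.tokens)).index(">")
        return tuple(self.tokens[first - 1:last + 2])

    @property
    def first_exon_blocks(self) -> tuple[str, ...]:
        if "<" not in self.tokens:
            return self.block_labels
        return tuple(
            t for t in self.tokens[: self.tokens.index("<")]
            if t not in SIGNAL_KINDS
        )

    @property
    def last_exon_blocks(self) -> tuple[str, ...]:
        if ">" not in self.tokens:
            return self.block_labels
        last = len(self.tokens) - 1 - tuple(reversed(self.tokens)).index(">")
        return tuple(
            t for t in self.tokens[last:] if t not in SIGNAL_KINDS
        )


@dataclass
class ScreenResult:
    accepted: bool
    reason: Optional[str] = None


# ---------------------------------------------------------------------------
# boundary collection and segmentation

def collect_boundaries(transcripts: Iterable[Transcript]) -> list[int]:
    """Sorted union of exon starts/ends (incl. start/stop codon positions)."""
    bounds: set[int] = set()
    for t in transcripts:
        for e in t.exons:
            bounds.add(e.start)
            bounds.add(e.end)
    return sorted(bounds)


def exonic_intervals(transcripts: Iterable[Transcript]) -> list[tuple[int, int]]:
    """Merged union of all exon intervals."""
    spans = sorted((e.start, e.end) for t in transcripts for e in t.exons)
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def atomic_segments(
    boundaries: Iterable[int],
    exonic: Iterable[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Intervals between consecutive boundaries inside exonic regions."""
    bounds = sorted(set(boundaries))
    segments: list[tuple[int, int]] = []
    for s, e in exonic:
        inner = [b for b in bounds if s <= b <= e]
        for x, y in zip(inner, inner[1:]):
            if y > x:
                segments.append((x, y))
    return segments


# ---------------------------------------------------------------------------
# segment matching (stands in for the protocol's similarity searches)

def match_segments(
    gene_q: GeneSequence,
    gene_t: GeneSequence,
    segments: Iterable[tuple[int, int]],
    which_q: str,
    which_t: str,
    flank: int = 20,
    min_identity: float = 0.7,
    min_coverage: float = 0.9,
) -> list[ExonMatch]:
    """Locate each query segment (with flanks) in the target gene.

    A segment is *matched* when its best local hit is unambiguous, reaches
    ``min_identity`` over the aligned segment-plus-flanks and covers at
    least ``min_coverage`` of the segment core.
    """
    out: list[ExonMatch] = []
    for (s, e) in segments:
        q0 = max(0, s - flank)
        qseq = gene_q.seq[q0:min(len(gene_q), e + flank)]
        hit = best_local_hit(qseq, gene_t.seq)
        cs, ce = s - q0, e - q0
        hit_span = None
        identity = 0.0
        ambiguous = False
        if hit is not None:
            identity = hit.identity
            ambiguous = hit.ambiguous
            if (
                not hit.ambiguous
                and hit.identity >= min_identity
                and hit.query_coverage(cs, ce) >= min_coverage
            ):
                hs = hit.query_to_target(max(cs, hit.q_start))
                he = hit.query_to_target(min(ce, hit.q_end))
                if hs is not None and he is not None and he > hs:
                    hit_span = (hs, he)
        out.append(
            ExonMatch(
                query_species=which_q,
                query_span=(s, e),
                hit_species=which_t,
                hit_span=hit_span,
                identity=identity,
                reciprocal=False,
                ambiguous=ambiguous,
                hit=hit,
                q_offset=q0,
            )
        )
    return out


def _spans_overlap(x: tuple[int, int], y: tuple[int, int]) -> int:
    return max(0, min(x[1], y[1]) - max(x[0], y[0]))


def annotate_reciprocal(
    matches: list[ExonMatch],
    gene_q: GeneSequence,
    gene_t: GeneSequence,
    flank: int = 20,
    min_identity: float = 0.7,
) -> None:
    """Set the best-reciprocal-hit flag on matched segments in place.

    The hit span (with flanks) is realigned in the query gene; the match is
    reciprocal when the returned span recovers the original segment
    (overlap of at least half the shorter span).
    """
    for m in matches:
        if not m.matched:
            continue
        hs, he = m.hit_span  # type: ignore[misc]
        b0 = max(0, hs - flank)
        back_q = gene_t.seq[b0:min(len(gene_t), he + flank)]
        back = best_local_hit(back_q, gene_q.seq)
        if back is None or back.ambiguous or back.identity < min_identity:
            continue
        cs, ce = hs - b0, he - b0
        rs = back.query_to_target(max(cs, back.q_start))
        re_ = back.query_to_target(min(ce, back.q_end))
        if rs is None or re_ is None or re_ <= rs:
            continue
        need = max(1, min(re_ - rs, m.query_span[1] - m.query_span[0]) // 2)
        if _spans_overlap((rs, re_), m.query_span) >= need:
            m.reciprocal = True


# ---------------------------------------------------------------------------
# homology screening

def screen_gene_pair(
    matches_ab: list[ExonMatch],
    matches_ba: list[ExonMatch],
) -> ScreenResult:
    """Reject gene pairs with duplicated or rearranged exon homology.

    Duplication: two distinct segments of one species hit overlapping
    spans in the other.  Rearrangement: confidently matched segments are
    not collinear (a crossing pair exists).
    """
    for matches in (matches_ab, matches_ba):
        confident = [m for m in matches if m.matched]
        for m1, m2 in itertools.combinations(confident, 2):
            s1 = m1.hit_span
            s2 = m2.hit_span
            l1 = s1[1] - s1[0]
            l2 = s2[1] - s2[0]
            if _spans_overlap(s1, s2) > max(3, min(l1, l2) // 2):
                return ScreenResult(False, "duplicated")
        ordered = sorted(confident, key=lambda m: m.query_span[0])
        for m1, m2 in itertools.combinations(ordered, 2):
            mid1 = sum(m1.hit_span) / 2
            mid2 = sum(m2.hit_span) / 2
            if mid2 < mid1:
                return ScreenResult(False, "rearranged")
    return ScreenResult(True)


# ---------------------------------------------------------------------------
# block construction

def _block_labels(n: int) -> list[str]:
    """A..Z, AA, AB, ... label sequence of length n."""
    labels = []
    for i in range(n):
        s = ""
        k = i
        while True:
            s = chr(ord("A") + k % 26) + s
            k = k // 26 - 1
            if k < 0:
                break
        labels.append(s)
    return labels


def _merge_boundaries(
    own: Iterable[int],
    projected: Iterable[int],
    snap: int = 2,
) -> list[int]:
    merged = sorted(set(own))
    for p in sorted(set(projected)):
        if all(abs(p - b) > snap for b in merged):
            merged.append(p)
    return sorted(merged)


def _containing_match(
    matches: list[ExonMatch], span: tuple[int, int]
) -> Optional[ExonMatch]:
    for m in matches:
        if m.query_span[0] <= span[0] and span[1] <= m.query_span[1]:
            return m
    return None


def build_blocks(
    gene_a: GeneSequence,
    transcripts_a: list[Transcript],
    gene_b: GeneSequence,
    transcripts_b: list[Transcript],
    matches_ab: list[ExonMatch],
    matches_ba: list[ExonMatch],
) -> list[Block]:
    """Partition both genes into labelled blocks of the common reference.

    Boundaries of each species are projected through the segment matches
    into the other, every projected boundary within 2 nt of an existing
    one being snapped onto it; the refined partitions are then paired via
    the match coordinate maps.  Raises :class:`GenePairRejected` with
    reason ``inconsistent_borders`` when the projection does not yield a
    one-to-one pairing or the containment invariant breaks.
    """
    bounds_a = collect_boundaries(transcripts_a)
    bounds_b = collect_boundaries(transcripts_b)
    exonic_a = exonic_intervals(transcripts_a)
    exonic_b = exonic_intervals(transcripts_b)

    proj_into_a = [c for m in matches_ba if m.matched for c in m.hit_span]
    proj_into_b = [c for m in matches_ab if m.matched for c in m.hit_span]
    merged_a = _merge_boundaries(bounds_a, proj_into_a)
    merged_b = _merge_boundaries(bounds_b, proj_into_b)

    spans_a = atomic_segments(merged_a, exonic_a)
    spans_b = atomic_segments(merged_b, exonic_b)

    # pair A spans with B spans through the A->B maps
    paired_b: dict[tuple[int, int], tuple[int, int]] = {}
    blocks: list[Block] = []
    order_keys: list[tuple[float, int, int]] = []
    for span in spans_a:
        m = _containing_match(matches_ab, span)
        span_b = None
        if m is not None and m.matched:
            ps = m.gene_to_target(span[0])
            pe = m.gene_to_target(span[1])
            if ps is not None and pe is not None and pe > ps:
                best = None
                best_ov = 0
                for sb in spans_b:
                    ov = _spans_overlap((ps, pe), sb)
                    if ov > best_ov:
                        best, best_ov = sb, ov
                if best is not None and best_ov >= max(
                    1, min(pe - ps, best[1] - best[0]) // 2
                ):
                    span_b = best
        if span_b is not None:
            if span_b in paired_b:
                raise GenePairRejected("inconsistent_borders")
            paired_b[span_b] = span
        blocks.append(Block(label="", span_a=span, span_b=span_b))
        order_keys.append((float(span[0]), 1, span[0]))

    # interleave B-only blocks at their mapped position
    prev_anchor = -1.0
    bonly: list[tuple[tuple[float, int, int], Block]] = []
    for sb in spans_b:
        if sb in paired_b:
            a_span = paired_b[sb]
            prev_anchor = float(a_span[1])
            continue
        m = _containing_match(matches_ba, sb)
        anchor = None
        if m is not None and m.matched:
            anchor = m.gene_to_target(sb[0])
        key_anchor = float(anchor) if anchor is not None else prev_anchor
        bonly.append(((key_anchor, 0, sb[0]), Block(label="", span_b=sb)))

    keyed = list(zip(order_keys, blocks)) + bonly
    keyed.sort(key=lambda kb: kb[0])
    ordered = [b for _k, b in keyed]
    for label, b in zip(_block_labels(len(ordered)), ordered):
        b.label = label

    _check_containment(ordered, transcripts_a, "a")
    _check_containment(ordered, transcripts_b, "b")
    return ordered


def _check_containment(
    blocks: list[Block], transcripts: list[Transcript], which: str
) -> None:
    """Every block span must be inside or disjoint from every exon set."""
    for b in blocks:
        span = b.span(which)
        if span is None:
            continue
        for t in transcripts:
            ov = sum(_spans_overlap(span, (e.start, e.end)) for e in t.exons)
            if ov not in (0, span[1] - span[0]):
                raise GenePairRejected("inconsistent_borders")


# ---------------------------------------------------------------------------
# signals, gene models and transcript strings

def _species_blocks(blocks: list[Block], which: str) -> list[Block]:
    present = [b for b in blocks if b.span(which) is not None]
    present.sort(key=lambda b: b.span(which)[0])  # type: ignore[index]
    return present


def attach_signals(
    blocks: list[Block],
    transcripts: list[Transcript],
    which: str,
    species: str,
) -> GeneModel:
    """Build the gene model string of one species.

    A signal is attached when at least one transcript realises it: '['
    before a block at whose 5' boundary a start codon lies, ']' after a
    stop, '<' after a block whose 3' boundary is an exon/intron border,
    '>' before a block whose 5' boundary is an intron/exon border.
    """
    starts = {t.exons[0].start for t in transcripts}
    stops = {t.exons[-1].end for t in transcripts}
    donors = {e.end for t in transcripts for e in t.exons[:-1]}
    acceptors = {e.start for t in transcripts for e in t.exons[1:]}

    tokens: list[str] = []
    signals: set[Signal] = set()
    labels: list[str] = []
    for b in _species_blocks(blocks, which):
        s, e = b.span(which)  # type: ignore[misc]
        labels.append(b.label)
        if s in starts:
            tokens.append("[")
            signals.add(Signal("[", b.label))
        if s in acceptors:
            tokens.append(">")
            signals.add(Signal(">", b.label))
        tokens.append(b.label)
        if e in donors:
            tokens.append("<")
            signals.add(Signal("<", b.label))
        if e in stops:
            tokens.append("]")
            signals.add(Signal("]", b.label))
    return GeneModel(
        species=species,
        tokens=tuple(tokens),
        signals=frozenset(signals),
        block_labels=tuple(labels),
    )


def encode_transcript(
    t: Transcript, blocks: list[Block], which: str
) -> TranscriptString:
    """Represent a transcript as its block/signal string, e.g. ``[A<>C]``."""
    by_start = {
        b.span(which)[0]: b  # type: ignore[index]
        for b in blocks
        if b.span(which) is not None
    }
    tokens: list[str] = []
    last_exon = len(t.exons) - 1
    for i, exon in enumerate(t.exons):
        tokens.append("[" if i == 0 else ">")
        cur = exon.start
        while cur < exon.end:
            b = by_start.get(cur)
            if b is None:
                raise GenePairRejected("inconsistent_borders")
            tokens.append(b.label)
            cur = b.span(which)[1]  # type: ignore[index]
        if cur != exon.end:
            raise GenePairRejected("inconsistent_borders")
        tokens.append("]" if i == last_exon else "<")
    return TranscriptString(accession=t.accession, tokens=tuple(tokens))


def is_subsequence(sub: tuple[str, ...], full: tuple[str, ...]) -> bool:
    it = iter(full)
    return all(tok in it for tok in sub)


# ---------------------------------------------------------------------------
# full reference

@dataclass
class BlockReference:
    """Common block reference of one orthologous gene pair."""

    gene_a: GeneSequence
    gene_b: GeneSequence
    transcripts_a: list[Transcript]
    transcripts_b: list[Transcript]
    blocks: list[Block]
    matches_ab: list[ExonMatch]
    matches_ba: list[ExonMatch]
    model_a: GeneModel
    model_b: GeneModel
    strings_a: dict[str, TranscriptString]
    strings_b: dict[str, TranscriptString]

    def gene(self, which: str) -> GeneSequence:
        return self.gene_a if which == "a" else self.gene_b

    def transcripts(self, which: str) -> list[Transcript]:
        return self.transcripts_a if which == "a" else self.transcripts_b

    def model(self, which: str) -> GeneModel:
        return self.model_a if which == "a" else self.model_b

    def strings(self, which: str) -> dict[str, TranscriptString]:
        return self.strings_a if which == "a" else self.strings_b

    def block_by_label(self, label: str) -> Block:
        for b in self.blocks:
            if b.label == label:
                return b
        raise KeyError(label)


def build_reference(
    gene_a: GeneSequence,
    transcripts_a: list[Transcript],
    gene_b: GeneSequence,
    transcripts_b: list[Transcript],
    flank: int = 20,
    min_identity: float = 0.7,
) -> BlockReference:
    """Run boundary collection, matching, screening and block building.

    Raises :class:`GenePairRejected` when the pair fails screening.
    """
    if not transcripts_a or not transcripts_b:
        raise GenePairRejected("empty_transcript_set")
    segs_a = atomic_segments(
        collect_boundaries(transcripts_a), exonic_intervals(transcripts_a)
    )
    segs_b = atomic_segments(
        collect_boundaries(transcripts_b), exonic_intervals(transcripts_b)
    )
    matches_ab = match_segments(
        gene_a, gene_b, segs_a, "a", "b", flank=flank, min_identity=min_identity
    )
    matches_ba = match_segments(
        gene_b, gene_a, segs_b, "b", "a", flank=flank, min_identity=min_identity
    )
    annotate_reciprocal(matches_ab, gene_a, gene_b, flank, min_identity)
    annotate_reciprocal(matches_ba, gene_b, gene_a, flank, min_identity)
    screen = screen_gene_pair(matches_ab, matches_ba)
    if not screen.accepted:
        raise GenePairRejected(screen.reason or "screen")
    blocks = build_blocks(
        gene_a, transcripts_a, gene_b, transcripts_b, matches_ab, matches_ba
    )
    model_a = attach_signals(blocks, transcripts_a, "a", gene_a.species)
    model_b = attach_signals(blocks, transcripts_b, "b", gene_b.species)
    strings_a = {
        t.accession: encode_transcript(t, blocks, "a") for t in transcripts_a
    }
    strings_b = {
        t.accession: encode_transcript(t, blocks, "b") for t in transcripts_b
    }
    return BlockReference(
        gene_a=gene_a,
        gene_b=gene_b,
        transcripts_a=list(transcripts_a),
        transcripts_b=list(transcripts_b),
        blocks=blocks,
        matches_ab=matches_ab,
        matches_ba=matches_ba,
        model_a=model_a,
        model_b=model_b,
        strings_a=strings_a,
        strings_b=strings_b,
    )
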