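"""Pure prediction mode: scan the target gene and classify transcripts.

Given the gene model of the *known* species, the predictor searches the
raw nucleotide sequence of the *target* gene for every model block (with
20 nt flanks) and for the conservation of the splice-site dinucleotides
anchored on found blocks; its successes form a substring ``S`` of the
gene model.  A known transcript is *executable* by the target gene when
all of its donor and acceptor blocks — the blocks carrying '<' or '>'
within the transcript string — are found together with their signals; in
flexible mode the extremities of the first and last exon are exempt.

In simulation mode executable transcripts are further classified as
*found* (paired with a target transcript sharing the same flexible-mode
splicing pattern) or *yet-to-be-found*; non-executable transcripts are
candidates for species-specific isoforms.  Single-exon transcripts have
no donor or acceptor block and are reported as indeterminate, outside
all counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .align import best_local_hit
from .blocks import BlockReference, GeneModel, Signal, TranscriptString
from .core import GeneSequence


@dataclass
class FoundSet:
    """Blocks and signals of the known model found in the target gene."""

    tokens: tuple[str, ...]
    found_blocks: frozenset[str]
    found_signals: frozenset[Signal]

    @property
    def symbols(self) -> str:
        return "".join(self.tokens)


@dataclass
class PredictorOutput:
    """Partition of the known transcript set produced by the predictor."""

    pairs: list[tuple[str, str]]
    yet_to_be_found: list[str]
    non_executable: list[str]
    indeterminate: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        """Number of analyzed (multi-exon) known transcripts."""
        return (
            len(self.pairs)
            + len(self.yet_to_be_found)
            + len(self.non_executable)
        )


def _longest_increasing(found: list[tuple[str, int]]) -> set[str]:
    """Labels forming the longest chain of increasing target positions.

    Enforces collinearity of the scan: a found block must map between its
    neighbours' maps, so spurious repeats cannot populate ``S``.
    """
    if not found:
        return set()
    n = len(found)
    best_len = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if found[j][1] < found[i][1] and best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    i = max(range(n), key=lambda k: (best_len[k], -k))
    keep: set[str] = set()
    while i >= 0:
        keep.add(found[i][0])
        i = prev[i]
    return keep


def _project_border(hit, qpos: int):
    """Project a query border into the target, extrapolating gap-free past
    ends trimmed by the local alignment."""
    t = hit.query_to_target(qpos)
    if t is not None:
        return t
    if qpos > hit.q_end:
        return hit.t_end + (qpos - hit.q_end)
    if qpos < hit.q_start:
        return hit.t_start - (hit.q_start - qpos)
    return None


def scan_target(
    model: GeneModel,
    reference: BlockReference,
    known: str,
    target_gene: GeneSequence,
    flank: int = 20,
    min_identity: float = 0.7,
    min_coverage: float = 0.9,
) -> FoundSet:
    """Report blocks and signals of ``model`` found in the target gene.

    Only the known species' gene sequence and model are consulted besides
    the raw target sequence; target annotations play no role.  A block is
    found when its sequence with flanking context has an unambiguous,
    collinear local match above the identity threshold; a donor/acceptor
    signal is found when, in that match, the two intronic nucleotides at
    the border are aligned without gaps and conserved.
    """
    known_gene = reference.gene(known)
    hits: dict[str, object] = {}
    positions: list[tuple[str, int]] = []
    offsets: dict[str, int] = {}
    for label in model.block_labels:
        block = reference.block_by_label(label)
        span = block.span(known)
        if span is None:
            continue
        s, e = span
        q0 = max(0, s - flank)
        qseq = known_gene.seq[q0:min(len(known_gene), e + flank)]
        hit = best_local_hit(qseq, target_gene.seq)
        cs, ce = s - q0, e - q0
        if (
            hit is None
            or hit.ambiguous
            or hit.identity < min_identity
            or hit.query_coverage(cs, ce) < min_coverage
        ):
            continue
        hits[label] = hit
        offsets[label] = q0
        mid = hit.query_to_target(max(cs, hit.q_start))
        positions.append((label, mid if mid is not None else hit.t_start))
    found_blocks = _longest_increasing(positions)

    found_signals: set[Signal] = set()
    for sig in model.signals:
        if sig.anchor_block not in found_blocks:
            continue
        if sig.kind in ("[", "]"):
            found_signals.add(sig)
            continue
        block = reference.block_by_label(sig.anchor_block)
        s, e = block.span(known)  # type: ignore[misc]
        hit = hits[sig.anchor_block]
        q0 = offsets[sig.anchor_block]
        if sig.kind == "<":
            # donor: the two intronic nt right after the block's mapped end
            if e + 2 > len(known_gene):
                continue
            t = _project_border(hit, e - q0)
            if (
                t is not None
                and t + 2 <= len(target_gene)
                and target_gene.seq[t:t + 2] == known_gene.seq[e:e + 2]
            ):
                found_signals.add(sig)
        else:
            # acceptor: the two intronic nt right before the mapped start
            if s - 2 < 0:
                continue
            t = _project_border(hit, s - q0)
            if (
                t is not None
                and t >= 2
                and target_gene.seq[t - 2:t] == known_gene.seq[s - 2:s]
            ):
                found_signals.add(sig)

    tokens = _filter_model_tokens(model, found_blocks, found_signals)
    return FoundSet(
        tokens=tuple(tokens),
        found_blocks=frozenset(found_blocks),
        found_signals=frozenset(found_signals),
    )


def _filter_model_tokens(
    model: GeneModel,
    found_blocks: set[str],
    found_signals: set[Signal],
) -> list[str]:
    """Restrict the model string to found blocks and signals (the S string)."""
    out: list[str] = []
    i = 0
    toks = model.tokens
    n = len(toks)
    while i < n:
        tok = toks[i]
        if tok in ("[", ">"):
            # anchored on the following block label
            j = i
            while toks[j] in ("[", ">"):
                j += 1
            anchor = toks[j]
            if anchor in found_blocks and Signal(tok, anchor) in found_signals:
                out.append(tok)
        elif tok in ("<", "]"):
            j = i
            while toks[j] in ("<", "]"):
                j -= 1
            anchor = toks[j]
            if anchor in found_blocks and Signal(tok, anchor) in found_signals:
                out.append(tok)
        else:
            if tok in found_blocks:
                out.append(tok)
        i += 1
    return out


def classify_executable(
    ts: TranscriptString, found: FoundSet
) -> Optional[bool]:
    """Executability of a known transcript given the scan result ``S``.

    True/False for multi-exon transcripts; ``None`` (indeterminate) for
    single-exon transcripts, which carry no donor or acceptor block and
    are excluded from the analysis.
    """
    donors = ts.donor_blocks
    acceptors = ts.acceptor_blocks
    if not donors and not acceptors:
        return None
    for d in donors:
        if d not in found.found_blocks or Signal("<", d) not in found.found_signals:
            return False
    for a in acceptors:
        if a not in found.found_blocks or Signal(">", a) not in found.found_signals:
            return False
    return True


def match_transcripts(
    known: list[TranscriptString],
    target: list[TranscriptString],
    executable: dict[str, Optional[bool]],
) -> PredictorOutput:
    """Pair executable known transcripts with same-pattern target ones.

    Both string sets must be encoded against the common block alphabet and
    deduplicated per species (identical patterns keep the smallest
    accession), so a pattern identifies at most one transcript per side.
    """
    by_pattern: dict[tuple[str, ...], str] = {}
    for ts in target:
        if ts.pattern is None:
            continue
        assert ts.pattern not in by_pattern, (
            "duplicate splicing pattern in deduplicated target set"
        )
        by_pattern[ts.pattern] = ts.accession
    out = PredictorOutput(pairs=[], yet_to_be_found=[], non_executable=[])
    for ts in known:
        flag = executable.get(ts.accession)
        if flag is None:
            out.indeterminate.append(ts.accession)
        elif not flag:
            out.non_executable.append(ts.accession)
        else:
            partner = by_pattern.get(ts.pattern)  # type: ignore[arg-type]
            if partner is None:
                out.yet_to_be_found.append(ts.accession)
            else:
                out.pairs.append((ts.accession, partner))
    return out


def predict(
    reference: BlockReference,
    known: str = "a",
    known_strings: Optional[list[TranscriptString]] = None,
    target_strings: Optional[list[TranscriptString]] = None,
    flank: int = 20,
    min_identity: float = 0.7,
) -> tuple[FoundSet, PredictorOutput]:
    """Run scan + executability + pairing for one prediction direction.

    ``known_strings``/``target_strings`` default to all encoded transcripts
    of the reference; callers normally pass the deduplicated sets.
    """
    target = "b" if known == "a" else "a"
    model = reference.model(known)
    found = scan_target(
        model,
        reference,
        known,
        reference.gene(target),
        flank=flank,
        min_identity=min_identity,
    )
    if known_strings is None:
        known_strings = list(reference.strings(known).values())
    if target_strings is None:
        target_strings = list(reference.strings(target).values())
    executable = {
        ts.accession: classify_executable(ts, found) for ts in known_strings
    }
    output = match_transcripts(known_strings, target_strings, executable)
    return found, output
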