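"""End-to-end analysis of one orthologous gene pair.

Wires the stages together: coding validation → common block reference →
same-species deduplication → predictor (scan, executability, pairing) →
controller (junction-constrained protein BRH) → co-validation and
metrics.  ``known`` selects the prediction direction: transcripts of the
known species predict those of the target species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .blocks import BlockReference, GenePairRejected, TranscriptString, build_reference
from .controller import ControllerPair, accepted_pairs, controller_list
from .core import GenePair, Transcript, is_valid_coding, protein_isoform
from .covalidation import (
    ValidationReport,
    covalidate,
    dedupe_same_species,
    precision,
    recall,
)
from .io import RunConfig
from .predictor import FoundSet, PredictorOutput, predict


@dataclass
class DirectionMetrics:
    """Counts and metrics of one prediction direction."""

    splicing_orthologs: int
    confirmed_yet_to_be_found: int
    confirmed_species_specific: int
    unresolved: int
    total: int
    n_known_target: int
    precision: Optional[float]
    recall: Optional[float]
    agreement: Optional[float]


@dataclass
class PairAnalysis:
    """Everything computed for one gene pair and one direction."""

    reference: BlockReference
    known: str
    target: str
    found: FoundSet
    predictor_output: PredictorOutput
    controller: list[ControllerPair]
    controller_oriented: list[tuple[str, str]]
    report: ValidationReport
    known_strings: list[TranscriptString]
    target_strings: list[TranscriptString]
    skipped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def metrics(self) -> DirectionMetrics:
        a = len(self.report.splicing_orthologs)
        b = len(self.report.confirmed_yet_to_be_found)
        c = len(self.report.confirmed_species_specific)
        u = len(self.report.unresolved)
        d = self.report.total
        n_target = sum(
            1 for ts in self.target_strings if ts.pattern is not None
        )
        agreed = d - u
        return DirectionMetrics(
            splicing_orthologs=a,
            confirmed_yet_to_be_found=b,
            confirmed_species_specific=c,
            unresolved=u,
            total=d,
            n_known_target=n_target,
            precision=precision(a, b),
            recall=recall(a, n_target),
            agreement=(agreed / d) if d else None,
        )


def validate_transcripts(
    pair: GenePair,
) -> tuple[list[Transcript], list[Transcript], list[tuple[str, str]]]:
    """Drop transcripts failing frame/translation validation."""
    skipped: list[tuple[str, str]] = []

    def _filter(transcripts, gene):
        kept = []
        for t in transcripts:
            ok, reason = is_valid_coding(t, gene)
            if ok:
                kept.append(t)
            else:
                skipped.append((t.accession, reason))
        return kept

    return (
        _filter(pair.transcripts_a, pair.gene_a),
        _filter(pair.transcripts_b, pair.gene_b),
        skipped,
    )


def analyze_gene_pair(
    pair: GenePair,
    config: Optional[RunConfig] = None,
    known: str = "a",
) -> PairAnalysis:
    """Run the full predictor/controller/co-validation pipeline.

    Raises :class:`GenePairRejected` when the pair fails homology
    screening (duplicated or rearranged exons, inconsistent borders).
    """
    cfg = config or RunConfig()
    target = "b" if known == "a" else "a"
    ts_a, ts_b, skipped = validate_transcripts(pair)
    reference = build_reference(
        pair.gene_a,
        ts_a,
        pair.gene_b,
        ts_b,
        flank=cfg.flank_len,
        min_identity=cfg.identity_threshold,
    )
    deduped = {
        which: dedupe_same_species(reference.strings(which).values())
        for which in ("a", "b")
    }
    known_strings = deduped[known]
    target_strings = deduped[target]
    found, output = predict(
        reference,
        known=known,
        known_strings=known_strings,
        target_strings=target_strings,
        flank=cfg.flank_len,
        min_identity=cfg.identity_threshold,
    )
    kept_accs = {
        which: {ts.accession for ts in deduped[which]} for which in ("a", "b")
    }
    proteins = {
        which: [
            protein_isoform(t, reference.gene(which))
            for t in reference.transcripts(which)
            if t.accession in kept_accs[which]
        ]
        for which in ("a", "b")
    }
    ctrl = controller_list(
        proteins["a"],
        proteins["b"],
        v=cfg.vicinity,
        terminal_window=cfg.terminal_window,
        gap_open=cfg.gap_open,
        gap_extend=cfg.gap_extend,
    )
    oriented = accepted_pairs(ctrl)
    if known == "b":
        oriented = [(b, a) for a, b in oriented]
    report = covalidate(output, oriented)
    return PairAnalysis(
        reference=reference,
        known=known,
        target=target,
        found=found,
        predictor_output=output,
        controller=ctrl,
        controller_oriented=oriented,
        report=report,
        known_strings=known_strings,
        target_strings=target_strings,
        skipped=skipped,
    )
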