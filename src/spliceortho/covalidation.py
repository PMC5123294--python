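"""Co-validation of predictor and controller outputs, labels and metrics.

The two procedures are run independently and must agree; disagreements
are *unresolved*:

* a predictor pair also on the controller list → **splicing orthologs**;
* yet-to-be-found with no controller entry for the transcript →
  **confirmed yet-to-be-found**;
* non-executable with no controller entry → **confirmed species-specific**;
* anything else → unresolved, with one of three subtypes
  (``found_not_controlled``, ``ytbf_but_controlled``,
  ``specific_but_controlled``).

Precision is the proportion of splicing orthologs among positive
predictions (splicing orthologs + confirmed yet-to-be-found); recall is
the number of splicing orthologs over the number of known target-species
transcripts.  Unresolved cases enter neither numerator nor denominator
of precision.  Cohort partitioning by release timestamp reproduces the
time-stamped analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .blocks import TranscriptString
from .core import Transcript
from .predictor import PredictorOutput

UNRESOLVED_SUBTYPES = (
    "found_not_controlled",
    "ytbf_but_controlled",
    "specific_but_controlled",
)


@dataclass
class ValidationReport:
    """Final per-transcript labels for one prediction direction."""

    splicing_orthologs: list[tuple[str, str]] = field(default_factory=list)
    confirmed_yet_to_be_found: list[str] = field(default_factory=list)
    confirmed_species_specific: list[str] = field(default_factory=list)
    unresolved: list[tuple[str, str]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return (
            len(self.splicing_orthologs)
            + len(self.confirmed_yet_to_be_found)
            + len(self.confirmed_species_specific)
            + len(self.unresolved)
        )

    @property
    def counts(self) -> dict[str, int]:
        return {
            "splicing_orthologs": len(self.splicing_orthologs),
            "confirmed_yet_to_be_found": len(self.confirmed_yet_to_be_found),
            "confirmed_species_specific": len(self.confirmed_species_specific),
            "unresolved": len(self.unresolved),
            "total": self.total,
        }

    def label_of(self, accession: str) -> Optional[str]:
        for k, _t in self.splicing_orthologs:
            if k == accession:
                return "ortholog"
        if accession in self.confirmed_yet_to_be_found:
            return "yet_to_be_found"
        if accession in self.confirmed_species_specific:
            return "species_specific"
        for k, _sub in self.unresolved:
            if k == accession:
                return "unresolved"
        return None


@dataclass
class CohortPartition:
    boundaries: tuple[int, ...]
    assignment: dict[str, int]  # accession -> cohort index (1-based; 0 unknown)


def ccds_sort_key(accession: str) -> tuple[int, int, str]:
    """Numeric-first ordering of CCDS-like accessions (CCDS5.1 < CCDS12.1)."""
    m = re.match(r"^[A-Za-z]*?(\d+)", accession)
    if m:
        return (0, int(m.group(1)), accession)
    return (1, 0, accession)


def dedupe_same_species(
    strings: Iterable[TranscriptString],
) -> list[TranscriptString]:
    """Keep one transcript per same-species splicing pattern.

    Among transcripts with an identical flexible-mode pattern the one with
    the smallest accession is retained.  Single-exon transcripts are
    grouped by their full symbol string.
    """
    groups: dict[tuple[str, ...], list[TranscriptString]] = {}
    for ts in strings:
        key = ts.pattern if ts.pattern is not None else ts.tokens
        groups.setdefault(key, []).append(ts)
    kept = [
        min(group, key=lambda ts: ccds_sort_key(ts.accession))
        for group in groups.values()
    ]
    kept.sort(key=lambda ts: ccds_sort_key(ts.accession))
    return kept


def covalidate(
    pred: PredictorOutput,
    controller_pairs: Iterable[tuple[str, str]],
) -> ValidationReport:
    """Confront predictor classes with the controller list.

    ``controller_pairs`` must be oriented (known_accession,
    target_accession), i.e. mirrored beforehand when the known species is
    the second member of the gene pair.
    """
    ctrl = set(controller_pairs)
    controlled = {k for k, _t in ctrl}
    report = ValidationReport()
    for k, t in pred.pairs:
        if (k, t) in ctrl:
            report.splicing_orthologs.append((k, t))
        else:
            report.unresolved.append((k, "found_not_controlled"))
    for k in pred.yet_to_be_found:
        if k in controlled:
            report.unresolved.append((k, "ytbf_but_controlled"))
        else:
            report.confirmed_yet_to_be_found.append(k)
    for k in pred.non_executable:
        if k in controlled:
            report.unresolved.append((k, "specific_but_controlled"))
        else:
            report.confirmed_species_specific.append(k)
    return report


def precision(a: int, b: int) -> Optional[float]:
    """Splicing orthologs over positive predictions: a / (a + b)."""
    if a < 0 or b < 0:
        raise ValueError("counts must be non-negative")
    if a + b == 0:
        return None
    return a / (a + b)


def recall(e: int, f: int) -> Optional[float]:
    """Splicing orthologs over known target-species transcripts: e / f."""
    if f == 0:
        return None
    return e / f


def agreement_percent(agreed: int, total: int) -> Optional[float]:
    """Percentage of transcripts on which the two procedures agree."""
    if total == 0:
        return None
    return round(100 * agreed / total, 1)


def identification_rate_percent(found: int, known_target: int) -> Optional[float]:
    """Percent of the target species' known transcripts identified."""
    if known_target == 0:
        return None
    return float(round(100 * found / known_target))


def rounded(x: Optional[float], ndigits: int = 2) -> Optional[float]:
    """Metric rounding used in reports (exact values are kept alongside)."""
    return None if x is None else round(x, ndigits)


def partition_cohorts(
    transcripts: Iterable[Transcript],
    boundaries: tuple[int, ...] = (2, 7, 19),
) -> CohortPartition:
    """Assign each transcript to the smallest release interval containing
    its timestamp; transcripts without a release go to cohort 0 (unknown),
    excluded from per-cohort statistics."""
    bounds = tuple(sorted(boundaries))
    assignment: dict[str, int] = {}
    for t in transcripts:
        if t.release is None:
            assignment[t.accession] = 0
            continue
        idx = len(bounds) + 1
        for i, b in enumerate(bounds, start=1):
            if t.release <= b:
                idx = i
                break
        assignment[t.accession] = idx
    return CohortPartition(boundaries=bounds, assignment=assignment)


def cumulative_orthologs(
    pair_releases: Iterable[int],
    releases: Iterable[int],
) -> list[int]:
    """Cumulative counts of ortholog pairs confirmed by each release.

    ``pair_releases`` carries, per pair, the later of its two members'
    releases; the result is non-decreasing along ``releases``.
    """
    stamps = sorted(pair_releases)
    out = []
    for r in releases:
        n = 0
        for s in stamps:
            if s <= r:
                n += 1
            else:
                break
        out.append(n)
    return out
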