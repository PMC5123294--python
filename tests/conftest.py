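"""Shared fixtures: hand-built gene pairs and seeded synthetic ones."""

from __future__ import annotations

import numpy as np
import pytest

from spliceortho.core import Exon, GenePair, GeneSequence, Transcript
from spliceortho.synth import SimConfig, _random_codons, _random_nt, generate_pair


def make_simple_gene(
    seed: int = 123,
    gene_id: str = "G1",
    species: str = "speciesA",
    exon_codons: tuple[int, ...] = (10, 10, 10),
    intron_len: int = 40,
):
    """Deterministic 3-exon coding gene with full-length and skip isoforms.

    Returns (gene, [full_transcript, skip_transcript]).
    """
    rng = np.random.default_rng(seed)
    exons = [_random_codons(rng, c) for c in exon_codons]
    exons[0][0] = "ATG"
    exons[-1][-1] = "TAA"
    introns = [
        "GT" + _random_nt(rng, intron_len - 4) + "AG"
        for _ in range(len(exons) - 1)
    ]
    pad = _random_nt(rng, 25)
    parts = [pad]
    spans = []
    pos = len(pad)
    for i, ex in enumerate(exons):
        seq = "".join(ex)
        spans.append((pos, pos + len(seq)))
        parts.append(seq)
        pos += len(seq)
        if i < len(introns):
            parts.append(introns[i])
            pos += len(introns[i])
    parts.append(_random_nt(rng, 25))
    gene = GeneSequence(gene_id, species, "".join(parts))
    full = Transcript(
        "CCDS1.1", gene_id, tuple(Exon(s, e) for s, e in spans), release=2
    )
    if len(spans) < 3:
        return gene, [full]
    skip = Transcript(
        "CCDS2.1", gene_id, (Exon(*spans[0]), Exon(*spans[2])), release=5
    )
    return gene, [full, skip]


@pytest.fixture(scope="session")
def simple_gene():
    return make_simple_gene()


@pytest.fixture(scope="session")
def simple_identical_pair():
    """Two identical copies of the simple 3-exon gene."""
    gene_a, ts_a = make_simple_gene(gene_id="GA", species="speciesA")
    gene_b0, _ = make_simple_gene(gene_id="GB", species="speciesB")
    ts_b = [
        Transcript(
            t.accession.replace("CCDS", "CCDS10"), "GB", t.exons, t.release
        )
        for t in ts_a
    ]
    gene_b = GeneSequence("GB", "speciesB", gene_a.seq)
    return GenePair(gene_a, gene_b, ts_a, ts_b)


@pytest.fixture(scope="session")
def identical_synth():
    return generate_pair(SimConfig(seed=7, divergence=0.0))


@pytest.fixture(scope="session")
def diverged_synth():
    return generate_pair(SimConfig(seed=11, divergence=0.05))


@pytest.fixture(scope="session")
def specific_exon_synth():
    """Pair whose event set guarantees a species-specific cassette exon."""
    return generate_pair(
        SimConfig(
            seed=5,
            divergence=0.0,
            events=("species_specific_exon", "exon_skip"),
        )
    )
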