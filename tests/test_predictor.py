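"""Target-gene scanning, executability, and transcript pairing."""

import edlib
import numpy as np
import pytest

from spliceortho.blocks import Signal, build_reference
from spliceortho.predictor import (
    FoundSet,
    classify_executable,
    match_transcripts,
    predict,
    scan_target,
)
from spliceortho.synth import SimConfig, generate_pair


@pytest.fixture(scope="module")
def identical_ref(simple_identical_pair):
    p = simple_identical_pair
    return build_reference(
        p.gene_a, p.transcripts_a, p.gene_b, p.transcripts_b
    )


@pytest.fixture(scope="module")
def specific_ref(specific_exon_synth):
    pair, _truth = specific_exon_synth
    return build_reference(
        pair.gene_a, pair.transcripts_a, pair.gene_b, pair.transcripts_b
    )


class TestScanTarget:
    def test_self_scan_recovers_entire_model(self, identical_ref):
        found = scan_target(
            identical_ref.model_a, identical_ref, "a", identical_ref.gene_a
        )
        assert found.symbols == identical_ref.model_a.symbols
        assert found.found_blocks == set(identical_ref.model_a.block_labels)

    def test_species_specific_block_missing_from_scan(self, specific_ref):
        # the cassette exon exists in exactly one gene; scanning the model
        # of the carrier against the other gene must not find its block
        for known in ("a", "b"):
            target = "b" if known == "a" else "a"
            model = identical = specific_ref.model(known)
            one_sided = [
                b.label
                for b in specific_ref.blocks
                if b.span(known) is not None and b.span(target) is None
            ]
            found = scan_target(
                model, specific_ref, known, specific_ref.gene(target)
            )
            for label in one_sided:
                assert label not in found.found_blocks
            for label in set(model.block_labels) - set(one_sided):
                assert label in found.found_blocks

    def test_scan_agrees_with_edit_distance_oracle(self, specific_ref):
        # independent presence oracle on the divergence-free fixture:
        # a block is present iff its sequence occurs in the target gene
        # within a small edit distance
        found = scan_target(
            specific_ref.model_a, specific_ref, "a", specific_ref.gene_b
        )
        for b in specific_ref.blocks:
            if b.span_a is None or b.label not in specific_ref.model_a.block_labels:
                continue
            seq = specific_ref.gene_a.seq[b.span_a[0]:b.span_a[1]]
            res = edlib.align(seq, specific_ref.gene_b.seq, mode="HW")
            present = res["editDistance"] <= max(1, len(seq) // 10)
            assert (b.label in found.found_blocks) == present, b.label


class TestClassifyExecutable:
    def test_full_found_set_makes_everything_executable(self, identical_ref):
        found = scan_target(
            identical_ref.model_a, identical_ref, "a", identical_ref.gene_b
        )
        for ts in identical_ref.strings_a.values():
            assert classify_executable(ts, found) is True

    def test_single_exon_transcript_indeterminate(self, identical_ref):
        from spliceortho.blocks import TranscriptString

        ts = TranscriptString("X", ("[", "A", "]"))
        found = scan_target(
            identical_ref.model_a, identical_ref, "a", identical_ref.gene_b
        )
        assert classify_executable(ts, found) is None

    def test_transcripts_using_missing_block_not_executable(self, specific_ref):
        for known in ("a", "b"):
            target = "b" if known == "a" else "a"
            missing = {
                b.label
                for b in specific_ref.blocks
                if b.span(known) is not None and b.span(target) is None
            }
            if not missing:
                continue
            found = scan_target(
                specific_ref.model(known),
                specific_ref,
                known,
                specific_ref.gene(target),
            )
            for ts in specific_ref.strings(known).values():
                uses_missing = bool(
                    set(ts.donor_blocks + ts.acceptor_blocks) & missing
                )
                assert classify_executable(ts, found) is (not uses_missing)

    def test_matches_brute_force_subset_oracle(self, identical_ref):
        # random found-subsets; oracle re-derives donor/acceptor blocks from
        # transcript exon coordinates rather than from symbol strings
        rng = np.random.default_rng(4)
        model = identical_ref.model_a
        labels = list(model.block_labels)
        signals = list(model.signals)
        by_label = {b.label: b for b in identical_ref.blocks}
        for _ in range(500):
            fb = {lab for lab in labels if rng.random() < 0.7}
            fs = {
                s for s in signals
                if s.anchor_block in fb and rng.random() < 0.8
            }
            found = FoundSet(tokens=(), found_blocks=frozenset(fb),
                             found_signals=frozenset(fs))
            for t in identical_ref.transcripts_a:
                ts = identical_ref.strings_a[t.accession]
                got = classify_executable(ts, found)
                # oracle from coordinates
                want = True
                for e in t.exons[:-1]:  # donor at each internal exon end
                    lab = next(
                        b.label for b in identical_ref.blocks
                        if b.span_a is not None and b.span_a[1] == e.end
                        and b.label in ts.block_labels
                    )
                    if lab not in fb or Signal("<", lab) not in fs:
                        want = False
                for e in t.exons[1:]:
                    lab = next(
                        b.label for b in identical_ref.blocks
                        if b.span_a is not None and b.span_a[0] == e.start
                        and b.label in ts.block_labels
                    )
                    if lab not in fb or Signal(">", lab) not in fs:
                        want = False
                assert got == want

    def test_monotone_in_found_set(self, identical_ref):
        rng = np.random.default_rng(14)
        model = identical_ref.model_a
        labels = list(model.block_labels)
        signals = list(model.signals)
        for _ in range(100):
            fb = {lab for lab in labels if rng.random() < 0.5}
            fs = {s for s in signals if s.anchor_block in fb}
            small = FoundSet((), frozenset(fb), frozenset(fs))
            big = FoundSet(
                (), frozenset(labels),
                frozenset(s for s in signals),
            )
            for ts in identical_ref.strings_a.values():
                if classify_executable(ts, small) is True:
                    assert classify_executable(ts, big) is True


class TestMatchTranscripts:
    def test_self_prediction_pairs_every_transcript(self, identical_ref):
        found, out = predict(identical_ref, known="a")
        accs = {t.accession for t in identical_ref.transcripts_a}
        assert {k for k, _t in out.pairs} == accs
        assert not out.yet_to_be_found and not out.non_executable

    def test_partition_of_known_set(self, diverged_synth):
        pair, _ = diverged_synth
        ref = build_reference(
            pair.gene_a, pair.transcripts_a, pair.gene_b, pair.transcripts_b
        )
        found, out = predict(ref, known="a")
        listed = (
            [k for k, _t in out.pairs]
            + out.yet_to_be_found
            + out.non_executable
            + out.indeterminate
        )
        assert sorted(listed) == sorted(ref.strings_a)
        paired = {k for k, _ in out.pairs}
        for k in paired:
            assert k not in out.non_executable

    def test_matches_all_pairs_oracle_on_random_cases(self):
        # exhaustive string-comparison oracle over several synthetic pairs
        for seed in (31, 32, 33, 34, 35):
            pair, _ = generate_pair(SimConfig(seed=seed, divergence=0.02))
            ref = build_reference(
                pair.gene_a, pair.transcripts_a,
                pair.gene_b, pair.transcripts_b,
            )
            found, out = predict(ref, known="a")
            executable = {
                ts.accession: classify_executable(ts, found)
                for ts in ref.strings_a.values()
            }
            expected_pairs = set()
            for ka, ts in ref.strings_a.items():
                if executable[ka] is not True or ts.pattern is None:
                    continue
                for kb, tsb in ref.strings_b.items():
                    if tsb.pattern == ts.pattern:
                        expected_pairs.add((ka, kb))
            assert set(out.pairs) == expected_pairs
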