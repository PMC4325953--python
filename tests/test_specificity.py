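"""Flank windows, similarity search, and the chromosome-specificity screen."""

import math

import numpy as np
import pytest

from conftest import best_ungapped_score, make_window, oracle_hit_pairs, random_sequence
from ssrkit.genome_io import Chromosome, Genome
from ssrkit.specificity import (
    CHROMOSOME_SPECIFIC,
    REPETITIVE_WITHIN,
    SHARED_ACROSS,
    AlignParams,
    all_pairs_hits,
    assign_markers,
    cross_chromosome_screen,
    extract_flanks,
    similarity_search,
    within_chromosome_repetition,
)
from ssrkit.ssr_engine import SSRRecord, canonical_motif


def _rec(chrom, start, end, motif="AT"):
    return SSRRecord(
        chromosome=chrom, start=start, end=end, period=len(motif),
        observed_motif=motif, canonical_motif=canonical_motif(motif).canonical,
        mismatches=0, score=end - start,
    )


class TestExtractFlanks:
    def test_default_width_both_sides(self, rng):
        chrom = Chromosome("c", random_sequence(rng, 10_000))
        w = extract_flanks(_rec("c", 5000, 5016), chrom)
        assert (w.flank5_len, w.flank3_len) == (200, 200)
        assert len(w) == 400 + 16
        assert not w.truncated5 and not w.truncated3
        assert w.sequence == chrom.sequence[4800:5216]

    def test_truncation_at_chromosome_start(self, rng):
        chrom = Chromosome("c", random_sequence(rng, 1000))
        w = extract_flanks(_rec("c", 50, 66), chrom)
        assert w.flank5_len == 50 and w.truncated5
        assert w.flank3_len == 200 and not w.truncated3

    def test_out_of_bounds_rejected(self, rng):
        chrom = Chromosome("c", random_sequence(rng, 100))
        with pytest.raises(ValueError):
            extract_flanks(_rec("c", 90, 120), chrom)
        with pytest.raises(ValueError):
            extract_flanks(_rec("other", 0, 16), chrom)


class TestSimilaritySearch:
    def test_identical_windows_hit_far_below_threshold(self, rng):
        flank5, flank3 = random_sequence(rng, 200), random_sequence(rng, 200)
        q = make_window("q", "c1", flank5, "AT" * 15, flank3)
        t = make_window("t", "c2", flank5, "AT" * 15, flank3)
        (hit,) = similarity_search(q, [t])
        assert hit.score == len(q)  # 430 = full-length identity
        assert hit.log10_evalue < -100
        assert hit.e_value < 1e-100

    def test_empty_target_set(self, rng):
        q = make_window("q", "c1", random_sequence(rng, 200), "AT" * 8, "")
        assert similarity_search(q, []) == []

    def test_independent_random_windows_no_hit(self, rng):
        ws = [
            make_window(f"w{i}", "c", random_sequence(rng, 200), "AT" * 8,
                        random_sequence(rng, 200))
            for i in range(2)
        ]
        assert similarity_search(ws[0], [ws[1]]) == []
        # exhaustive check: even the best ungapped score is nowhere near
        s = best_ungapped_score(ws[0].sequence, ws[1].sequence)
        assert s < 60

    def test_same_motif_different_flanks_do_not_seed(self, rng):
        # the repeat tract alone must never make two SSRs similar
        q = make_window("q", "c1", random_sequence(rng, 200), "AT" * 40,
                        random_sequence(rng, 200))
        t = make_window("t", "c2", random_sequence(rng, 200), "AT" * 40,
                        random_sequence(rng, 200))
        assert similarity_search(q, [t]) == []

    def test_symmetry_on_equal_length_windows(self, rng):
        shared = random_sequence(rng, 430)
        ws = [
            make_window("a", "c1", shared[:200], shared[200:230], shared[230:]),
            make_window("b", "c2", shared[:200], shared[200:230], shared[230:]),
            make_window("r", "c3", random_sequence(rng, 200), shared[200:230],
                        random_sequence(rng, 200)),
        ]
        params = AlignParams(mask_tract_seeds=False)
        pairs = {(h.query_id, h.target_id) for h in all_pairs_hits(ws, params)}
        assert {(b, a) for a, b in pairs} == pairs


class TestOracleEquivalence:
    def test_hit_set_matches_exhaustive_alignment_oracle(self, rng):
        """Seed-and-extend must agree with an exhaustive all-pairs local
        alignment oracle on a mixed fixture of verbatim duplicates,
        high-identity copies and unrelated windows."""
        params = AlignParams()
        windows = []
        for i in range(8):
            windows.append(
                make_window(f"u{i}", f"c{i % 3}", random_sequence(rng, 200),
                            "AAT" * 6, random_sequence(rng, 200))
            )
        # verbatim and 97%-identity copies of u0/u1 on other chromosomes
        for j, src in enumerate(windows[:2]):
            seq = list(src.sequence)
            if j == 1:
                n_mut = round(0.03 * len(seq))
                for idx in rng.choice(len(seq), size=n_mut, replace=False):
                    seq[idx] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[idx]]
            windows.append(
                make_window(f"d{j}", "c9", "".join(seq[:200]), "".join(seq[200:218]),
                            "".join(seq[218:]))
            )
        got = {(h.query_id, h.target_id) for h in all_pairs_hits(windows, params)}
        expected = oracle_hit_pairs(windows, params)
        assert got == expected
        assert ("u0", "d0") in got and ("u1", "d1") in got


class TestWithinChromosome:
    def _windows(self, rng, n):
        return [
            make_window(f"w{i}", "c1", random_sequence(rng, 200), "AT" * 8,
                        random_sequence(rng, 200))
            for i in range(n)
        ]

    def test_all_dissimilar_all_uni(self, rng):
        stats = within_chromosome_repetition(self._windows(rng, 10))
        assert stats.uni_percent == 100.0
        assert stats.max_repetitions == 1

    def test_one_duplicated_window(self, rng):
        ws = self._windows(rng, 9)
        dup = make_window("w9", "c1", ws[0].sequence[:200], ws[0].sequence[200:216],
                          ws[0].sequence[216:])
        stats = within_chromosome_repetition(ws + [dup])
        assert stats.uni_count == 8
        assert stats.uni_percent == pytest.approx(80.0)
        assert stats.max_repetitions == 2

    def test_three_verbatim_copies_cluster(self, rng):
        ws = self._windows(rng, 7)
        copies = [
            make_window(f"c{i}", "c1", ws[0].sequence[:200], ws[0].sequence[200:216],
                        ws[0].sequence[216:])
            for i in range(2)
        ]
        stats = within_chromosome_repetition(ws + copies)
        assert stats.mean_repetitions == pytest.approx(3.0)
        assert stats.max_repetitions == 3

    def test_mixed_chromosomes_rejected(self, rng):
        ws = self._windows(rng, 2)
        bad = make_window("x", "c2", random_sequence(rng, 200), "AT" * 8, "")
        with pytest.raises(ValueError):
            within_chromosome_repetition(ws + [bad])


class TestCrossChromosomeScreen:
    def test_single_chromosome_unique_means_specific(self, rng):
        ws = [
            make_window(f"w{i}", "c1", random_sequence(rng, 200), "AAT" * 6,
                        random_sequence(rng, 200))
            for i in range(5)
        ]
        report = cross_chromosome_screen(ws)
        assert all(v == CHROMOSOME_SPECIFIC for v in report.labels.values())

    def test_verbatim_cross_copy_shared_both_sides(self, rng):
        a = make_window("a", "c1", random_sequence(rng, 200), "AT" * 8,
                        random_sequence(rng, 200))
        b = make_window("b", "c2", a.sequence[:200], a.sequence[200:216],
                        a.sequence[216:])
        c = make_window("c", "c2", random_sequence(rng, 200), "AT" * 8,
                        random_sequence(rng, 200))
        report = cross_chromosome_screen([a, b, c])
        assert report.labels["a"] == SHARED_ACROSS
        assert report.labels["b"] == SHARED_ACROSS
        assert report.labels["c"] == CHROMOSOME_SPECIFIC

    def test_within_repetition_trumps_cross(self, rng):
        a = make_window("a", "c1", random_sequence(rng, 200), "AT" * 8,
                        random_sequence(rng, 200))
        twin = make_window("t", "c1", a.sequence[:200], a.sequence[200:216],
                           a.sequence[216:])
        cross = make_window("x", "c2", a.sequence[:200], a.sequence[200:216],
                            a.sequence[216:])
        report = cross_chromosome_screen([a, twin, cross])
        assert report.labels["a"] == REPETITIVE_WITHIN
        assert report.labels["t"] == REPETITIVE_WITHIN
        assert report.labels["x"] == SHARED_ACROSS  # unique on c2, seen on c1

    def test_labels_conserve_totals(self, rng):
        ws = []
        for i in range(12):
            ws.append(
                make_window(f"w{i}", f"c{i % 3}", random_sequence(rng, 200),
                            "AAAT" * 4, random_sequence(rng, 200))
            )
        report = cross_chromosome_screen(ws)
        assert sum(
            report.count(l)
            for l in (CHROMOSOME_SPECIFIC, REPETITIVE_WITHIN, SHARED_ACROSS)
        ) == len(ws)
        for c in report.per_chromosome:
            assert c.specific_count <= c.uni_count  # specific is a subset of uni


def graded_identity_windows(rng):
    """Window set whose cross-chromosome copies range from verbatim to 60%
    identity, so the specific count depends on the E-value threshold."""
    ws = []
    for i in range(6):
        ws.append(
            make_window(f"u{i}", "c1", random_sequence(rng, 200), "AAT" * 6,
                        random_sequence(rng, 200))
        )
    for j, ident in enumerate([1.0, 0.98, 0.95, 0.9, 0.8, 0.6]):
        src = ws[j].sequence
        seq = list(src)
        n_mut = round((1 - ident) * len(seq))
        for idx in rng.choice(len(seq), size=n_mut, replace=False):
            seq[idx] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[idx]]
        ws.append(
            make_window(f"d{j}", "c2", "".join(seq[:200]), "".join(seq[200:218]),
                        "".join(seq[218:]))
        )
    return ws


def test_specific_count_monotone_in_threshold(rng):
    """Tightening the E-value cut-off from 1e-10 to 1e-150 can only keep or
    grow the chromosome-specific set; the permissive end loses almost all."""
    ws = graded_identity_windows(rng)
    counts = []
    for thr in [1e-10, 1e-50, 1e-100, 1e-150]:
        report = cross_chromosome_screen(ws, AlignParams(e_threshold=thr))
        counts.append(report.count(CHROMOSOME_SPECIFIC))
    assert counts == sorted(counts)
    assert counts[0] < counts[-1]


def test_assign_markers(rng):
    c1 = random_sequence(rng, 3000)
    c2 = random_sequence(rng, 3000)
    genome = Genome([Chromosome("chr1", c1), Chromosome("chr2", c2)])
    markers = {
        "m_clear": c1[1000:1400],
        "m_absent": random_sequence(rng, 400),
    }
    out = assign_markers(markers, genome, AlignParams(e_threshold=1e-50))
    assert out["m_clear"] == "chr1"
    assert out["m_absent"] == "unmapped"
    # a marker present on both chromosomes is ambiguous
    both = c1[500:900]
    genome2 = Genome([Chromosome("chr1", c1), Chromosome("chr2", c2[:1000] + both + c2[1400:])])
    out2 = assign_markers({"m_both": both}, genome2, AlignParams(e_threshold=1e-50))
    assert out2["m_both"] == "ambiguous"
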