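"""Heme-motif scanner tests, anchored by an independent brute-force oracle.

The oracle enumerates every motif match of every class with regex
lookahead, then applies the same leftmost-start / shortest-span greedy
selection by sorting and sweeping — a separate code path from the
scanner's resumable walk.
"""

import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ferroscan.hemes import (
    cohort_heme_ratio,
    profile_genome,
    profile_protein,
    scan_protein,
)
from ferroscan.records import GenomeAnnotation, ProteinRecord

_ORACLE_PATTERNS = [
    (5, re.compile(r"(?=C[A-Z]{2}CH)")),
    (6, re.compile(r"(?=C[A-Z]{3}CH)")),
    (7, re.compile(r"(?=C[A-Z]{4}CH)")),
]


def oracle_scan(sequence: str) -> list[tuple[int, int]]:
    """Enumerate-then-greedy reference: all (start, span) matches sorted,
    accepted left to right when non-overlapping."""
    matches = []
    for span, pat in _ORACLE_PATTERNS:
        for m in pat.finditer(sequence):
            matches.append((m.start(), span))
    matches.sort()
    chosen = []
    cursor = 0
    for start, span in matches:
        if start >= cursor:
            chosen.append((start, span))
            cursor = start + span
    return chosen


@pytest.mark.parametrize(
    "sequence,expected",
    [
        ("MCAACHK", [(1, 5)]),
        ("CCACCH", [(0, 6)]),  # leftmost start beats the nested CXXCH at 1
        ("CAACHCAAACH", [(0, 5), (5, 6)]),
        ("", []),
        ("CAHCH", [(0, 5)]),  # wildcards may be any residue, even H
        ("CACH", []),  # too short for any class
        ("CA*CH", []),  # motifs never span a stop codon
        ("CXXCH", [(0, 5)]),  # ambiguity codes are legal wildcards
        ("CAAAACH", [(0, 7)]),
    ],
)
def test_scan_examples(sequence, expected):
    hits = scan_protein(sequence)
    assert [(h.start, h.span) for h in hits] == expected
    assert oracle_scan(sequence) == expected


ALPHABET = "ACDEFGHIKLMNPQRSTVWY*"


@given(st.text(alphabet=ALPHABET, max_size=120))
@settings(max_examples=500, deadline=None)
def test_scanner_matches_oracle(seq):
    assert [(h.start, h.span) for h in scan_protein(seq)] == oracle_scan(seq)


@given(st.text(alphabet=ALPHABET, max_size=120))
@settings(max_examples=200, deadline=None)
def test_hits_non_overlapping_and_ordered(seq):
    hits = scan_protein(seq)
    for a, b in zip(hits, hits[1:]):
        assert a.start + a.span <= b.start


@given(
    st.text(alphabet=ALPHABET, max_size=80),
    st.text(alphabet=ALPHABET, min_size=1, max_size=20),
)
@settings(max_examples=200, deadline=None)
def test_appending_never_decreases_count(seq, extra):
    assert len(scan_protein(seq + extra)) >= len(scan_protein(seq))


def test_overlap_allow_reports_nested_matches():
    hits = scan_protein("CCACCH", overlap="allow")
    assert {(h.start, h.span) for h in hits} == {(0, 6), (1, 5)}


def _genome_with(seqs):
    return GenomeAnnotation(
        genome_id="g", group_label="x", completeness=99, contamination=0,
        proteins=[
            ProteinRecord(f"p{i}", "g", f"p{i}", "c1", i, "+", s)
            for i, s in enumerate(seqs)
        ],
    )


class TestProfiles:
    def test_decaheme_categorized_ten_plus(self):
        seq = "M" + "CAACHAA" * 10
        prof = profile_protein("p", seq)
        assert prof.total_hemes == 10
        assert prof.category == "10+"

    def test_monoheme_categorized_one(self):
        assert profile_protein("p", "MCAACHKK").category == "1"

    def test_motif_free_protein_has_no_profile(self):
        assert profile_protein("p", "MKLAAA") is None

    def test_genome_without_motifs(self):
        profiles, summary = profile_genome(_genome_with(["MKLA", "MRTV"]))
        assert profiles == []
        assert summary.n_motif_proteins == 0
        assert all(v == 0 for v in summary.histogram.values())

    def test_summary_consistent_with_profiles(self):
        seqs = ["MCAACHK", "M" + "CAACHAA" * 4, "M" + "CAACHAA" * 10, "MKLAAA"]
        profiles, summary = profile_genome(_genome_with(seqs))
        assert summary.n_motif_proteins == 3
        assert summary.n_mhc == 2  # >= 3 hemes
        assert summary.histogram == {"1": 1, "2": 0, "3": 0, "4-9": 1, "10+": 1}

    def test_unsorted_bin_edges_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            profile_genome(_genome_with(["MCAACHK"]), bin_edges=(1, 3, 2))


class TestHemeRatio:
    def test_arithmetic(self):
        a = [_genome_with(["MCAACHK"] * 3), _genome_with(["MCAACHK"] * 3)]
        b = [_genome_with(["MCAACHK"] * 2), _genome_with(["MCAACHK"] * 2)]
        # distinct genome ids
        for i, g in enumerate(a + b):
            g.genome_id = f"g{i}"
        res = cohort_heme_ratio(a, b)
        assert res["ratio"] == pytest.approx(1.5)
        assert res["mean_a"] == 3 and res["mean_b"] == 2

    def test_identity(self):
        g = _genome_with(["MCAACHK", "MKLA"])
        assert cohort_heme_ratio([g], [g])["ratio"] == pytest.approx(1.0)

    def test_degenerate_denominator(self):
        a = _genome_with(["MCAACHK"])
        b = _genome_with(["MKLA"])
        b.genome_id = "h"
        with pytest.raises(ValueError, match="denominator"):
            cohort_heme_ratio([a], [b])
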