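"""Local alignment: worked scores, independent DP oracle, and invariants.

The primary check is equivalence against a brute-force affine-gap dynamic
program written here from scratch (score only, dict-based, no traceback),
which is itself validated against exhaustive enumeration of every possible
local alignment for tiny sequences.
"""

import numpy as np
import pytest

from ampliquant import ScoringScheme, alignment_ref_coverage, smith_waterman
from ampliquant.align import DELETION, INSERTION, MATCH, MISMATCH, cigar_string
from ampliquant.locus import revcomp

from conftest import random_dna

SCHEME = ScoringScheme(match=5, mismatch=-4, gap_open=10, gap_extend=0.5)


# ---------------------------------------------------------------------------
# independent oracles (written before consulting the implementation)


def enumerate_best_local_score(a: str, b: str, scheme: ScoringScheme) -> float:
    """Exhaustively enumerate every local alignment (all starts, all op
    sequences); exponential, tiny inputs only."""
    best = 0.0

    def go(i, j, score, last):
        nonlocal best
        best = max(best, score)
        if i < len(a) and j < len(b):
            s = scheme.match if a[i] == b[j] else scheme.mismatch
            go(i + 1, j + 1, score + s, "M")
        if j < len(b):
            cost = scheme.gap_extend if last == "D" else scheme.gap_open + scheme.gap_extend
            go(i, j + 1, score - cost, "D")
        if i < len(a):
            cost = scheme.gap_extend if last == "I" else scheme.gap_open + scheme.gap_extend
            go(i + 1, j, score - cost, "I")

    for i in range(len(a) + 1):
        for j in range(len(b) + 1):
            go(i, j, 0.0, None)
    return best


def brute_force_affine_score(a: str, b: str, scheme: ScoringScheme) -> float:
    """Score-only affine-gap local DP, dict-based, independent of the
    package's kernel."""
    gap1 = scheme.gap_open + scheme.gap_extend
    H: dict = {}

    def get(state, i, j):
        return H.get((state, i, j), 0.0 if state == "M" else -np.inf)

    best = 0.0
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            s = scheme.match if a[i - 1] == b[j - 1] else scheme.mismatch
            m = max(0.0, s + max(get("M", i - 1, j - 1), get("D", i - 1, j - 1),
                                 get("I", i - 1, j - 1)))
            d = max(get("M", i, j - 1) - gap1, get("D", i, j - 1) - scheme.gap_extend,
                    get("I", i, j - 1) - gap1)
            x = max(get("M", i - 1, j) - gap1, get("D", i - 1, j) - gap1,
                    get("I", i - 1, j) - scheme.gap_extend)
            H[("M", i, j)], H[("D", i, j)], H[("I", i, j)] = m, d, x
            best = max(best, m)
    return best


def test_dp_oracle_matches_exhaustive_enumeration():
    """The test oracle itself agrees with exhaustive alignment enumeration."""
    rng = np.random.default_rng(7)
    for _ in range(40):
        a = random_dna(rng, int(rng.integers(1, 6)))
        b = random_dna(rng, int(rng.integers(1, 6)))
        assert brute_force_affine_score(a, b, SCHEME) == pytest.approx(
            enumerate_best_local_score(a, b, SCHEME)
        )


def test_scores_match_brute_force_oracle_on_random_pairs():
    """>= 500 random pairs up to length 30 score identically to the oracle."""
    rng = np.random.default_rng(42)
    for _ in range(500):
        a = random_dna(rng, int(rng.integers(1, 31)))
        b = random_dna(rng, int(rng.integers(1, 31)))
        aln = smith_waterman(a, b, SCHEME)
        expect = max(
            brute_force_affine_score(a, b, SCHEME),
            brute_force_affine_score(revcomp(a), b, SCHEME),
        )
        assert aln.score == pytest.approx(expect), (a, b)


# ---------------------------------------------------------------------------
# worked examples


def test_perfect_window_match_scores_53_matches(example_window):
    aln = smith_waterman(example_window.sequence, example_window, SCHEME)
    assert aln.score == pytest.approx(53 * 5)
    assert aln.operations == (type(aln.operations[0])(MATCH, 53),)
    assert aln.read_start == 0 and aln.read_end == 53
    assert aln.ref_start == 0 and aln.ref_end == 53
    assert cigar_string(aln) == "53="


def test_disjoint_alphabets_give_empty_alignment():
    aln = smith_waterman("AAAA", "CCCC", SCHEME)
    assert aln.score == 0
    assert aln.operations == ()
    assert alignment_ref_coverage(aln, "CCCC") == 0


def test_deletion_read_keeps_full_reference_coverage(example_window):
    """A read missing 4 window bases aligns with one 4-nt deletion run."""
    w = example_window.sequence
    read = w[:30] + w[34:]
    aln = smith_waterman(read, example_window, SCHEME)
    assert aln.ref_end - aln.ref_start == 53
    ops = {(op.op, op.length) for op in aln.operations if op.op == DELETION}
    assert ops == {(DELETION, 4)}
    assert aln.score == pytest.approx(49 * 5 - (10 + 0.5 * 4))


def test_insertion_read_reports_inserted_bases(example_window):
    w = example_window.sequence
    read = w[:30] + "TTAAGG" + w[30:]
    aln = smith_waterman(read, example_window, SCHEME)
    ins = [op for op in aln.operations if op.op == INSERTION]
    assert len(ins) == 1 and ins[0].bases == "TTAAGG"
    assert aln.score == pytest.approx(53 * 5 - (10 + 0.5 * 6))


def test_truncated_read_covers_partial_reference(example_window):
    read = example_window.sequence[:40]
    aln = smith_waterman(read, example_window, SCHEME)
    assert alignment_ref_coverage(aln, example_window) == 40


# ---------------------------------------------------------------------------
# invariants


def test_score_symmetry_under_sequence_swap(rng):
    for _ in range(50):
        a = random_dna(rng, int(rng.integers(1, 25)))
        b = random_dna(rng, int(rng.integers(1, 25)))
        assert smith_waterman(a, b, SCHEME).score == pytest.approx(
            smith_waterman(b, a, SCHEME).score
        )


def test_appending_bases_never_decreases_score(rng):
    for _ in range(30):
        b = random_dna(rng, 20)
        a = random_dna(rng, 10)
        prev = smith_waterman(a, b, SCHEME).score
        for _ in range(5):
            a += random_dna(rng, 1)
            cur = smith_waterman(a, b, SCHEME).score
            assert cur >= prev
            prev = cur


def test_reverse_complement_read_flips_strand_preserves_score(example_window):
    read = example_window.sequence[5:45]
    fwd = smith_waterman(read, example_window, SCHEME)
    rev = smith_waterman(revcomp(read), example_window, SCHEME)
    assert fwd.strand_used == "fwd"
    assert rev.strand_used == "rev"
    assert rev.score == pytest.approx(fwd.score)
    assert rev.operations == fwd.operations


def test_score_recomputes_from_operations(rng, example_window):
    for _ in range(50):
        read = random_dna(rng, int(rng.integers(10, 80)))
        aln = smith_waterman(read, example_window, SCHEME)
        assert aln.score == pytest.approx(aln.score_from_operations(SCHEME), abs=1e-9)
        consumed_read = sum(op.length for op in aln.operations
                            if op.op in (MATCH, MISMATCH, INSERTION))
        consumed_ref = sum(op.length for op in aln.operations
                           if op.op in (MATCH, MISMATCH, DELETION))
        assert consumed_read == aln.read_end - aln.read_start
        assert consumed_ref == aln.ref_end - aln.ref_start


def test_scheme_validation_rejects_bad_parameters():
    with pytest.raises(ValueError):
        ScoringScheme(match=-1, mismatch=-4)
    with pytest.raises(ValueError):
        ScoringScheme(gap_open=1, gap_extend=2)
    with pytest.raises(ValueError):
        smith_waterman("", "ACGT")
    with pytest.raises(ValueError):
        smith_waterman("ACGT", "")
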