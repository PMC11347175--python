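"""IUPAC consensus matching, amenability scoring, PFM and template expansion."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rasodesign import (
    RY_TEMPLATE,
    ScoreWeights,
    TranscriptSeq,
    VariantRecord,
    build_pfm,
    enumerate_template,
    expand_template_random,
    extract_context,
    match_consensus,
    parse_iupac,
    plus8_filter,
    score_context,
)
from rasodesign.susceptibility import (
    CardinalityError,
    PatternError,
    match_window,
)
from rasodesign.variant_context import Consequence

# independent oracle table, deliberately restated rather than imported
ORACLE_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _ctx(stop="TGA", nt4="C", w827="G" * 20, w57="AAA"):
    seq = TranscriptSeq("t", stop + nt4 + w57 + w827)
    rec = VariantRecord(gene="g", transcript_id="t", stop_start=1,
                        consequence=Consequence.NONSENSE)
    return extract_context(seq, rec)


class TestParseIupac:
    def test_r_and_y_sets(self):
        pat = parse_iupac("RY")
        assert pat.allowed_sets == (frozenset("AG"), frozenset("CT"))

    def test_n_matches_any(self):
        pat = parse_iupac("GNNT")
        assert pat.allowed_sets[1] == frozenset("ACGT")

    def test_invalid_character_offset(self):
        with pytest.raises(PatternError, match="offset 2"):
            parse_iupac("RX")


class TestMatchConsensus:
    def test_exact_identity(self):
        ctx = _ctx(w827="G" * 20)
        ok, mism = match_consensus(ctx, parse_iupac("G" * 20))
        assert ok and mism == []

    def test_single_mismatch_reported_in_plus_coordinates(self):
        # context deviating only at +14 (G where the pattern wants a pyrimidine),
        # tolerated at max_mismatch=1 — the JAG1-style near-consensus case
        w827 = "GAAAAA" + "G" + "A" * 13
        pat = parse_iupac("NNNNNN" + "Y" + "N" * 13, max_mismatch=1)
        ok, mism = match_consensus(_ctx(w827=w827), pat)
        assert ok and mism == [14]
        strict = parse_iupac("NNNNNN" + "Y" + "N" * 13, max_mismatch=0)
        assert not match_consensus(_ctx(w827=w827), strict)[0]

    def test_agrees_with_bruteforce_oracle_on_random_probes(self, rng):
        """Per-position set-membership oracle vs the matcher, 10,000 20-mers."""
        pat_str = RY_TEMPLATE[:20]
        pat = parse_iupac(pat_str)
        probes = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(10_000)]
        for probe in probes:
            expected = all(b in ORACLE_SETS[c] for b, c in zip(probe, pat_str))
            assert match_window(probe, pat)[0] == expected


class TestPlus8Filter:
    @pytest.mark.parametrize("first,expected", [("G", True), ("A", False),
                                                ("C", False), ("T", False)])
    def test_plus8_base(self, first, expected):
        assert plus8_filter(_ctx(w827=first + "A" * 19)) is expected


class TestScoreContext:
    def test_documented_formula_hand_evaluated(self):
        # UGA(2) + plus4 C(2) + plus8 G(3) + 0.5*4 G-run + 2*0.5 GC = 10.0
        w827 = "GGGG" + "CCCCCC" + "ATATATATAT"  # GC fraction exactly 0.5
        rep = score_context(_ctx(stop="TGA", nt4="C", w827=w827))
        assert rep.score == pytest.approx(10.0)
        assert rep.components["g_run_count"] == 4
        assert rep.components["gc_fraction"] == pytest.approx(0.5)

    def test_plus8_a_context_is_unlikely(self):
        # MECP2 R168X-like: strong stop, +8 A — not R-ASO amenable
        rep = score_context(_ctx(stop="TGA", nt4="G", w827="A" + "G" * 19))
        assert rep.tier == "unlikely"

    def test_zero_weights_zero_score(self, rng):
        w = ScoreWeights(w_stop={"TGA": 0, "TAG": 0, "TAA": 0},
                         w4=dict.fromkeys("ACGT", 0.0),
                         w8=dict.fromkeys("ACGT", 0.0), w_grun=0.0, w_gc=0.0)
        for _ in range(20):
            w827 = "".join(rng.choice(list("ACGT"), 20))
            assert score_context(_ctx(w827=w827), weights=w).score == 0.0

    def test_monotone_in_g_run_and_gc(self):
        base = "A" * 20
        prev = score_context(_ctx(w827=base)).score
        for i in range(4):  # grow the +8..+11 G-run
            w = "G" * (i + 1) + "A" * (19 - i)
            s = score_context(_ctx(w827=w)).score
            assert s >= prev
            prev = s
        # GC fraction falls as C's are removed (G-run untouched) -> score falls
        scores = [score_context(_ctx(w827="A" * i + "C" * (20 - i))).score
                  for i in range(5, 21)]
        assert all(a >= b or math.isclose(a, b)
                   for a, b in zip(scores, scores[1:]))

    def test_amenable_tier_requires_plus8_g(self, rng, default_pattern):
        for _ in range(200):
            w827 = "".join(rng.choice(list("ACGT"), 20))
            rep = score_context(_ctx(w827=w827), pattern=default_pattern)
            if rep.tier == "amenable":
                assert w827[0] == "G" and rep.consensus_match


class TestPfm:
    def test_conserved_column_two_bits(self):
        pfm = build_pfm(["G" + "A" * 19] * 4)
        assert list(pfm.counts[:, 0]) == [0, 0, 4, 0]
        assert pfm.information_bits[0] == pytest.approx(2.0)

    def test_uniform_column_zero_bits(self):
        pfm = build_pfm(["A" + "C" * 19, "C" + "C" * 19,
                         "G" + "C" * 19, "T" + "C" * 19])
        assert pfm.information_bits[0] == pytest.approx(0.0)
        assert pfm.counts[:, 0].sum() == 4

    def test_column_sums_and_bounds(self, rng):
        windows = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(500)]
        pfm = build_pfm(windows)
        assert (pfm.counts.sum(axis=0) == 500).all()
        assert ((pfm.information_bits >= 0) & (pfm.information_bits <= 2)).all()

    def test_random_contexts_carry_no_information(self, rng):
        windows = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(10_000)]
        pfm = build_pfm(windows)
        assert pfm.information_bits.mean() < 0.01

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_pfm([])


class TestExpandTemplate:
    def test_ry_draw_in_allowed_set(self):
        (s,) = expand_template_random("RY", 1, seed=3)
        assert s in {"AT", "AC", "GT", "GC"}

    def test_degenerate_template_constant(self):
        assert set(expand_template_random("G", 50, seed=0)) == {"G"}

    def test_reproducible_under_seed(self):
        a = expand_template_random(RY_TEMPLATE, 100, seed=11)
        b = expand_template_random(RY_TEMPLATE, 100, seed=11)
        assert a == b

    def test_all_draws_match_template_and_are_balanced(self):
        draws = expand_template_random(RY_TEMPLATE, 10_000, seed=5)
        pat = parse_iupac(RY_TEMPLATE)
        assert all(match_window(s, pat)[0] for s in draws)
        frac_a = sum(s[0] == "A" for s in draws) / len(draws)
        assert abs(frac_a - 0.5) < 0.015  # binomial CI at n = 10,000


class TestEnumerateTemplate:
    @pytest.mark.parametrize("template,cardinality", [("RY", 4), ("NN", 16),
                                                      ("RYR", 8)])
    def test_cardinality_and_distinctness(self, template, cardinality):
        enum = enumerate_template(template)
        seqs = list(enum)
        assert enum.cardinality == cardinality
        assert len(seqs) == len(set(seqs)) == cardinality
        pat = parse_iupac(template)
        assert all(match_window(s, pat)[0] for s in seqs)

    def test_cap_exceeded_reports_cardinality(self):
        with pytest.raises(CardinalityError, match=str(4**12)):
            enumerate_template("N" * 12, cap=4**11)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.text(alphabet=sorted(ORACLE_SETS), min_size=1, max_size=6),
       st.integers(0, 4**6 - 1))
def test_match_equals_enumeration_membership(template, probe_idx):
    """Exact-match decisions equal brute-force template expansion membership."""
    pat = parse_iupac(template)
    members = set(enumerate_template(pat, cap=4**6))
    L = len(template)
    probe = "".join("ACGT"[(probe_idx >> (2 * i)) & 3] for i in range(L))
    assert match_window(probe, pat)[0] == (probe in members)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.text(alphabet=sorted(ORACLE_SETS), min_size=1, max_size=8),
       st.integers(0, 2**31 - 1))
def test_expanded_draws_always_match_their_template(template, seed):
    pat = parse_iupac(template)
    for s in expand_template_random(pat, 5, seed=seed):
        assert match_window(s, pat)[0]
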