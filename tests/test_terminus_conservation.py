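"""Terminus stacking, information content and similarity curves."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from vlatt.element_discovery import LTRElement
from vlatt.lineage_classifier import LineageAssignment
from vlatt.terminus_conservation import (
    FIVE_PRIME,
    THREE_PRIME,
    TerminusStack,
    conservation_profile,
    extract_termini,
    info_profile,
    similarity_curves,
    similarity_profile,
    stack_group,
)


def make_element(genome, s, ltr_len, internal_len):
    e = s + 2 * ltr_len + internal_len
    return LTRElement(
        "e1", "g", s, e, s, s + ltr_len, e - ltr_len, e, 1.0, "ACGT"
    )


def stack_of(seqs, side=FIVE_PRIME):
    return TerminusStack(side, "Ale", "g", list(seqs))


class TestExtractTermini:
    def test_prefix_and_suffix(self):
        genome = "X" * 0 + "TGAAC" + "C" * 100 + "GTTCA"
        el = LTRElement("e", "g", 0, 110, 0, 5, 105, 110, 1.0)
        five, three = extract_termini(el, genome, window=5)
        assert five == "TGAAC"
        assert three == "GTTCA"

    def test_zero_rate_matches_template(self, models, small_genome):
        genome, truth = small_genome
        # use truth coordinates directly; template prefix diverges at 2%
        t = truth[0]
        el = LTRElement(
            t.element_id, "g", t.start, t.end, t.ltr5_start, t.ltr5_end,
            t.ltr3_start, t.ltr3_end, 1.0, t.tsd,
        )
        five, three = extract_termini(el, genome, window=40)
        assert five == genome[t.ltr5_start: t.ltr5_start + 40]
        assert three == genome[t.ltr3_end - 40: t.ltr3_end]

    def test_short_ltr_raises(self):
        genome = "TG" + "A" * 30 + "CA"
        el = LTRElement("e", "g", 0, 34, 0, 10, 24, 34, 1.0)
        with pytest.raises(ValueError):
            extract_termini(el, genome, window=40)

    def test_minus_orientation_swaps_and_complements(self):
        genome = "TGAAC" + "C" * 100 + "GTTCA"
        el = LTRElement("e", "g", 0, 110, 0, 5, 105, 110, 1.0)
        five, three = extract_termini(el, genome, window=5, orientation="-")
        assert five == "TGAAC"  # revcomp of "GTTCA"
        assert three == "GTTCA"


class TestStackGroup:
    def _mk(self, counts):
        """counts: {(lineage, genome): n} -> assignments/termini dicts."""
        assignments, termini, genome_of = [], {}, {}
        i = 0
        for (lineage, genome), n in counts.items():
            for _ in range(n):
                eid = f"e{i}"
                i += 1
                assignments.append(
                    LineageAssignment(eid, lineage, "x", 10.0, 1e-20, 1)
                )
                termini[eid] = ("A" * 40, "C" * 40)
                genome_of[eid] = genome
        return assignments, termini, genome_of

    def test_eight_copies_excluded_nine_included(self):
        asg, term, gof = self._mk({("Ale", "g1"): 8, ("Del", "g1"): 9})
        stacks, excluded = stack_group(asg, term, gof)
        per_genome = {(s.lineage, s.genome) for s in stacks if s.genome}
        assert ("Del", "g1") in per_genome
        assert ("Ale", "g1") not in per_genome
        assert excluded == [("Ale", "g1", 8)]

    def test_pooled_includes_excluded_groups(self):
        asg, term, gof = self._mk(
            {("Ale", "g1"): 8, ("Ale", "g2"): 5, ("Ale", "g3"): 9}
        )
        stacks, _ = stack_group(asg, term, gof)
        pooled = [
            s for s in stacks
            if s.lineage == "Ale" and s.genome is None and s.side == FIVE_PRIME
        ]
        assert len(pooled) == 1 and pooled[0].copy_count == 22

    def test_unclassified_ignored(self):
        asg, term, gof = self._mk({("unclassified", "g1"): 20})
        stacks, excluded = stack_group(asg, term, gof)
        assert stacks == [] and excluded == []


class TestInfoProfile:
    def test_analytic_columns(self):
        stack = stack_of(["AAT", "AAC", "ATG", "ACA"])
        # col0: all A -> 2.0; col1: A,A,T,C -> 2-H(1/2,1/4,1/4)=0.5
        ic = info_profile(stack)
        assert ic[0] == pytest.approx(2.0)
        assert ic[1] == pytest.approx(0.5)

    def test_uniform_column_zero_bits(self):
        ic = info_profile(stack_of(["A", "C", "G", "T"]))
        assert ic[0] == pytest.approx(0.0)

    def test_half_half_one_bit(self):
        ic = info_profile(stack_of(["A", "A", "T", "T"]))
        assert ic[0] == pytest.approx(1.0)

    def test_ambiguous_excluded(self):
        ic = info_profile(stack_of(["AN", "AN", "AN", "TN"]))
        assert np.isnan(ic[1])

    def test_bounds(self, small_genome):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(12)]
        ic = info_profile(stack_of(seqs))
        assert np.all(ic >= -1e-12) and np.all(ic <= 2 + 1e-12)


class TestSimilarityProfile:
    def test_identical_uniform_closed_form(self):
        """Identical sequences with equal base usage: centered score is
        match - E0 = 5 - (-1.75) = 6.75 at every position."""
        stack = stack_of(["ACGT" * 10] * 6)
        sim = similarity_profile(stack)
        assert np.allclose(sim, 6.75)

    def test_random_columns_mean_near_zero(self):
        rng = np.random.default_rng(42)
        seqs = ["".join(rng.choice(list("ACGT"), 10_000)) for _ in range(10)]
        sim = similarity_profile(stack_of(seqs))
        assert abs(np.nanmean(sim)) < 0.1

    def test_motif_then_random_tail(self, models):
        rng = np.random.default_rng(3)
        motif = "TGCATGCAT"
        seqs = [
            motif + "".join(rng.choice(list("ACGT"), 31)) for _ in range(20)
        ]
        _, plotcon, _ = similarity_curves(stack_of(seqs))
        assert np.all(plotcon[:7] > 0)
        assert np.mean(plotcon[15:] > 0) < 0.2

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACGT"), 15)) for _ in range(8)]
        a = similarity_profile(stack_of(seqs))
        b = similarity_profile(stack_of(seqs[::-1]))
        assert np.allclose(a, b, equal_nan=True)
        assert np.allclose(
            info_profile(stack_of(seqs)), info_profile(stack_of(seqs[::-1])),
            equal_nan=True,
        )

    def test_translation_equivariance(self):
        """Prepending identical conserved columns shifts the curve."""
        rng = np.random.default_rng(6)
        seqs = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(10)]
        k = 5
        shifted = ["ACGTA"[:k][::-1] * 0 + "GATTC"[:k] + s for s in seqs]
        base = similarity_profile(stack_of(seqs))
        moved = similarity_curves(stack_of(shifted))[0]
        # away from edges and the new columns, the curve is shifted by k
        # (centering baseline changes slightly with composition; loose tol)
        assert np.allclose(moved[k + 2: -2], base[2: -2], atol=0.35)


def brute_force_profiles(seqs, window=4, match=5.0, mismatch=-4.0):
    """Independent exhaustive computation of both curves."""
    n, L = len(seqs), len(seqs[0])
    raw = np.full(L, np.nan)
    for j in range(L):
        col = [s[j] for s in seqs if s[j] in "ACGT"]
        if len(col) < 2:
            continue
        scores = [
            match if a == b else mismatch
            for a, b in itertools.combinations(col, 2)
        ]
        raw[j] = np.mean(scores)
    flat = [c for s in seqs for c in s if c in "ACGT"]
    pi = np.array([flat.count(b) for b in "ACGT"], dtype=float)
    pi /= pi.sum()
    e0 = match * np.sum(pi**2) + mismatch * (1 - np.sum(pi**2))
    centered = raw - e0
    out = np.full(L, np.nan)
    for p in range(L):
        lo, hi = max(0, p - (window - 1) // 2), min(L, p + window // 2 + 1)
        vals = centered[lo:hi]
        vals = vals[~np.isnan(vals)]
        if vals.size:
            out[p] = vals.mean()
    ics = np.full(L, np.nan)
    for j in range(L):
        col = [s[j] for s in seqs if s[j] in "ACGT"]
        if not col:
            continue
        h = 0.0
        for b in "ACGT":
            f = col.count(b) / len(col)
            if f > 0:
                h -= f * np.log2(f)
        ics[j] = 2 - h
    return out, ics


@given(
    st.lists(
        st.text(alphabet="ACGT", min_size=10, max_size=10),
        min_size=2,
        max_size=5,
    )
)
def test_profiles_match_exhaustive_pairwise_computation(seqs):
    """Oracle equivalence on small stacks (<= 5 x 10)."""
    stack = stack_of(seqs)
    sim = similarity_profile(stack)
    ic = info_profile(stack)
    bf_sim, bf_ic = brute_force_profiles(seqs)
    assert np.allclose(sim, bf_sim, equal_nan=True, atol=1e-9)
    assert np.allclose(ic, bf_ic, equal_nan=True, atol=1e-9)


def test_frequencies_sum_to_one(small_genome):
    rng = np.random.default_rng(1)
    seqs = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(9)]
    prof = conservation_profile(stack_of(seqs))
    assert np.allclose(prof.base_freqs.sum(axis=1), 1.0)
    assert prof.delimit_curve == pytest.approx(
        prof.similarity + prof.e0, nan_ok=True
    )
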