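"""Structural detector: seeds, refinement, recovery against ground truth."""

import pytest

from vlatt.element_discovery import (
    DiscoveryParams,
    LTRElement,
    Rejection,
    discover,
    find_candidates,
    refine_pair,
)
from vlatt.io import GenomeRecord
from vlatt.synthetic_genome import make_background, plant_elements


def match_truth(elements, truth, tol=5):
    """Truth records recovered with both boundaries within tol nt."""
    hits = []
    for t in truth:
        for e in elements:
            if abs(e.start - t.start) <= tol and abs(e.end - t.end) <= tol:
                hits.append((t, e))
                break
    return hits


class TestFindCandidates:
    def test_empty_genome(self):
        assert find_candidates(GenomeRecord("g", "")) == []

    def test_no_repeats(self):
        seq = make_background(1000, 0.5, 1)
        assert find_candidates(GenomeRecord("g", seq)) == []

    def test_n_runs_never_seed(self):
        seq = "N" * 5000 + make_background(2000, 0.5, 2) + "N" * 5000
        assert find_candidates(GenomeRecord("g", seq)) == []

    def test_exact_copies_seed_pair(self, models):
        bg = make_background(30_000, 0.4, 3)
        genome, truth = plant_elements(bg, [models[0]], 1, 0.0, seed=4)
        pairs = find_candidates(GenomeRecord("g", genome))
        (t,) = truth
        off = t.ltr3_start - t.ltr5_start
        assert any(p.offset == off for p in pairs)

    def test_pairs_sorted(self, small_genome):
        genome, _ = small_genome
        pairs = find_candidates(GenomeRecord("g", genome))
        starts = [(p.start1, p.offset) for p in pairs]
        assert starts == sorted(starts)

    def test_seed_coverage_at_two_percent_divergence(self, small_genome):
        genome, truth = small_genome
        pairs = find_candidates(GenomeRecord("g", genome))
        covered = 0
        for t in truth:
            off = t.ltr3_start - t.ltr5_start
            if any(
                p.offset == off
                and t.ltr5_start - 10 <= p.start1 <= t.ltr5_end
                for p in pairs
            ):
                covered += 1
        assert covered >= len(truth) - 1


class TestRefinePair:
    def test_zero_rate_exact_recovery(self, models):
        bg = make_background(30_000, 0.4, 3)
        genome, truth = plant_elements(bg, [models[0]], 1, 0.0, seed=4)
        rec = GenomeRecord("g", genome)
        (t,) = truth
        pairs = find_candidates(rec)
        off = t.ltr3_start - t.ltr5_start
        pair = next(p for p in pairs if p.offset == off)
        el = refine_pair(rec, pair)
        assert isinstance(el, LTRElement)
        assert el.ltr_identity == 1.0
        assert el.tsd == t.tsd
        assert (el.start, el.end) == (t.start, t.end)
        assert (el.ltr5_start, el.ltr5_end) == (t.ltr5_start, t.ltr5_end)
        assert (el.ltr3_start, el.ltr3_end) == (t.ltr3_start, t.ltr3_end)

    def test_missing_tsd_rejected(self, models):
        """An element planted without a TSD fails the TSD criterion."""
        bg = make_background(30_000, 0.4, 3)
        genome, truth = plant_elements(
            bg, [models[0]], 1, 0.0, seed=4, tsd_len_range=(0, 0)
        )
        assert truth[0].tsd == ""
        rec = GenomeRecord("g", genome)
        pairs = find_candidates(rec)
        off = truth[0].ltr3_start - truth[0].ltr5_start
        pair = next(p for p in pairs if p.offset == off)
        result = refine_pair(rec, pair)
        assert isinstance(result, Rejection)
        assert result.reason == "tsd"

    def test_reported_elements_satisfy_thresholds(self, small_elements):
        p = DiscoveryParams()
        for el in small_elements:
            l5 = el.ltr5_end - el.ltr5_start
            l3 = el.ltr3_end - el.ltr3_start
            assert p.min_ltr_len <= l5 <= p.max_ltr_len
            assert p.min_ltr_len <= l3 <= p.max_ltr_len
            assert abs(l5 - l3) <= 20
            assert el.ltr_identity >= p.min_ltr_identity
            assert p.min_element_len <= el.span <= p.max_element_len
            assert el.ltr5_end <= el.ltr3_start
            assert (el.start, el.end) == (el.ltr5_start, el.ltr3_end)
            assert el.tsd and 4 <= len(el.tsd) <= 6


class TestDiscover:
    def test_empty(self):
        assert discover(GenomeRecord("g", "")) == []

    def test_recovery_at_two_percent(self, small_genome, small_elements):
        genome, truth = small_genome
        hits = match_truth(small_elements, truth)
        assert len(hits) >= 0.95 * len(truth)
        for t, e in hits:
            assert abs(e.ltr5_end - t.ltr5_end) <= 5
            assert abs(e.ltr3_start - t.ltr3_start) <= 5

    def test_tandem_copies_found_separately(self, models):
        m = models[0]
        bg = make_background(40_000, 0.4, 6)
        g1, t1 = plant_elements(bg[:15_000], [m], 1, 0.0, seed=7)
        g2, t2 = plant_elements(bg[15_000:30_000], [m], 1, 0.0, seed=8)
        e1 = g1[t1[0].start - len(t1[0].tsd): t1[0].end + len(t1[0].tsd)]
        e2 = g2[t2[0].start - len(t2[0].tsd): t2[0].end + len(t2[0].tsd)]
        tandem = bg[30_000:35_000] + e1 + e2 + bg[35_000:]
        els = discover(GenomeRecord("g", tandem))
        assert len(els) == 2

    def test_background_false_positive_rate(self):
        seq = make_background(2_000_000, 0.40, 99)
        els = discover(GenomeRecord("bg", seq))
        assert len(els) / 2.0 < 1.0  # < 1 per Mb

    def test_identity_monotonicity(self, small_genome):
        genome, _ = small_genome
        rec = GenomeRecord("g", genome)
        counts = [
            len(discover(rec, DiscoveryParams(min_ltr_identity=x)))
            for x in (0.85, 0.90, 0.95, 0.999)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_sorted_and_stable(self, small_genome, small_elements):
        genome, _ = small_genome
        starts = [e.start for e in small_elements]
        assert starts == sorted(starts)
        again = discover(GenomeRecord("g", genome))
        assert [(e.start, e.end) for e in again] == [
            (e.start, e.end) for e in small_elements
        ]


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        DiscoveryParams(min_ltr_len=500, max_ltr_len=100)
    with pytest.raises(ValueError):
        DiscoveryParams(min_ltr_identity=0.0)
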