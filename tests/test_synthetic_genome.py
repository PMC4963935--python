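"""Generator correctness: composition, mutation model, element anatomy."""

import pytest

from vlatt.synthetic_genome import (
    DEFAULT_ATT_LENGTHS,
    LINEAGES,
    LineageModel,
    make_background,
    mutate,
    plant_elements,
    truth_from_gff3,
    truth_to_gff3,
)


def hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


class TestBackground:
    def test_empty(self):
        assert make_background(0, 0.5, 1) == ""

    def test_zero_gc_contains_no_gc(self):
        seq = make_background(10_000, 0.0, 7)
        assert set(seq) <= {"A", "T"}

    def test_gc_fraction_concentrates(self):
        seq = make_background(100_000, 0.44, 42)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.44) < 0.01

    def test_deterministic(self):
        assert make_background(5000, 0.4, 3) == make_background(5000, 0.4, 3)

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            make_background(-1, 0.5, 1)


class TestMutate:
    def test_zero_rate_is_identity(self):
        assert mutate("ACGT", 0.0, 1) == "ACGT"

    def test_rate_one_changes_every_site(self):
        seq = "A" * 10_000
        out = mutate(seq, 1.0, 3)
        assert hamming(seq, out) == len(seq)

    def test_rate_concentrates(self):
        seq = "A" * 100_000
        out = mutate(seq, 0.05, 9)
        assert abs(hamming(seq, out) / len(seq) - 0.05) < 0.005

    def test_length_and_determinism(self):
        seq = make_background(1000, 0.5, 0)
        assert len(mutate(seq, 0.3, 4)) == len(seq)
        assert mutate(seq, 0.3, 4) == mutate(seq, 0.3, 4)

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            mutate("ACGT", 1.5, 1)


class TestLineageModels:
    def test_eleven_lineages_with_fixed_superfamilies(self, models):
        assert [m.name for m in models] == LINEAGES
        copia = [m.name for m in models if m.superfamily == "Copia"]
        gypsy = [m.name for m in models if m.superfamily == "Gypsy"]
        assert copia == ["Ale", "Angela", "Bianca", "Ivana", "Maximus", "Tar"]
        assert gypsy == ["Athila", "CRM", "Del", "Galadriel", "Reina"]

    def test_templates_have_canonical_termini_and_att_anchoring(self, models):
        for m in models:
            assert m.ltr_template.startswith("TG")
            assert m.ltr_template.endswith("CA")
            assert m.ltr_template.startswith(m.att5_motif)
            assert m.ltr_template.endswith(m.att3_motif)
            a5, a3 = DEFAULT_ATT_LENGTHS[m.name]
            assert (len(m.att5_motif), len(m.att3_motif)) == (a5, a3)

    def test_rt_peptides_dissimilar(self, models):
        for i, a in enumerate(models):
            for b in models[i + 1:]:
                ident = hamming(a.rt_peptide, b.rt_peptide)
                assert 1 - ident / len(a.rt_peptide) < 0.40

    def test_superfamily_mismatch_rejected(self, models):
        m = models[0]
        with pytest.raises(ValueError):
            LineageModel(
                name="Ale", superfamily="Gypsy",
                ltr_template=m.ltr_template, att5_motif=m.att5_motif,
                att3_motif=m.att3_motif, rt_peptide=m.rt_peptide,
            )


class TestPlantElements:
    def test_zero_copies_returns_background(self, models):
        bg = make_background(50_000, 0.4, 1)
        genome, truth = plant_elements(bg, models, 0, 0.02, seed=2)
        assert genome == bg and truth == []

    def test_zero_rate_anatomy(self, models):
        """At rate 0 (and no interior divergence) both LTRs equal the
        template and the flanking TSDs are identical."""
        m = models[0]
        bg = make_background(20_000, 0.4, 3)
        genome, truth = plant_elements(
            bg, [m], 1, 0.0, seed=4, interior_divergence=0.0
        )
        (t,) = truth
        l5 = genome[t.ltr5_start: t.ltr5_end]
        l3 = genome[t.ltr3_start: t.ltr3_end]
        assert l5 == l3 == m.ltr_template
        d = len(t.tsd)
        assert 4 <= d <= 6
        assert genome[t.start - d: t.start] == t.tsd
        assert genome[t.end: t.end + d] == t.tsd

    def test_full_set_truth_and_att_recoverability(self, models):
        bg = make_background(5_000_000, 0.40, 11)
        genome, truth = plant_elements(bg, models, 20, 0.02, seed=5)
        assert len(truth) == 220
        by_name = {m.name: m for m in models}
        mismatches = sites = 0
        for t in truth:
            m = by_name[t.lineage]
            found5 = genome[t.ltr5_start: t.ltr5_start + len(m.att5_motif)]
            found3 = genome[t.ltr3_end - len(m.att3_motif): t.ltr3_end]
            m5 = hamming(found5, m.att5_motif)
            m3 = hamming(found3, m.att3_motif)
            assert m5 <= 3 and m3 <= 3  # short motifs stay recognizable
            mismatches += m5 + m3
            sites += len(m.att5_motif) + len(m.att3_motif)
        # per-site mismatch rate concentrates at the 2% mutation rate
        assert mismatches / sites < 0.04

    def test_no_overlap_and_in_bounds(self, small_genome):
        genome, truth = small_genome
        intervals = sorted((t.start, t.end) for t in truth)
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            assert e1 <= s2
        assert all(0 <= t.start < t.end <= len(genome) for t in truth)

    def test_reproducible(self, models):
        bg = make_background(60_000, 0.4, 8)
        g1, t1 = plant_elements(bg, models[:2], 2, 0.05, seed=9)
        g2, t2 = plant_elements(bg, models[:2], 2, 0.05, seed=9)
        assert g1 == g2
        assert [vars(a) for a in t1] == [vars(b) for b in t2]

    def test_capacity_error(self, models):
        with pytest.raises(ValueError, match="insufficient background"):
            plant_elements("ACGT" * 100, models, 1, 0.0, seed=1)

    def test_ltr_intervals_flank_internal(self, small_genome):
        _, truth = small_genome
        for t in truth:
            assert t.start == t.ltr5_start
            assert t.end == t.ltr3_end
            assert t.ltr5_end <= t.ltr3_start


def test_truth_gff3_round_trip(tmp_path, small_genome):
    _, truth = small_genome
    path = tmp_path / "truth.gff3"
    truth_to_gff3(truth, path)
    back = truth_from_gff3(path)
    orig = sorted(truth, key=lambda t: t.start)
    assert len(back) == len(orig)
    for a, b in zip(back, orig):
        assert (a.element_id, a.lineage, a.start, a.end, a.tsd) == (
            b.element_id, b.lineage, b.start, b.end, b.tsd
        )
        assert (a.ltr5_start, a.ltr5_end, a.ltr3_start, a.ltr3_end) == (
            b.ltr5_start, b.ltr5_end, b.ltr3_start, b.ltr3_end
        )
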