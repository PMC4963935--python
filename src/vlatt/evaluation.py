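"""Benchmark runs of the pipeline on synthetic genomes with known truth.

These functions regenerate the study conditions used to validate each
stage - element discovery and boundary accuracy, false-positive rate on
pure background, lineage classification, and att-site recovery - and
return the measured rates.  They are used by the test suite and by
``scripts/acceptance.py``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from . import element_discovery as ed
from . import lineage_classifier as lc
from .io import GenomeRecord, PipelineConfig
from .pipeline import att_analysis
from .synthetic_genome import (
    LINEAGES,
    default_models,
    make_background,
    plant_elements,
)


@dataclass
class DiscoveryEval:
    n_planted: int
    n_recovered: int
    recall_pct: float
    max_boundary_error_nt: int
    genome: str
    truth: list
    elements: list
    matched: list  # (truth, element) pairs


def discovery_eval(
    seed: int,
    background_len: int = 5_000_000,
    copies: int = 20,
    rate: float = 0.02,
    gc: float = 0.40,
    boundary_tol: int = 5,
    models=None,
) -> DiscoveryEval:
    """Plant 11 lineages x ``copies`` elements and measure recovery.

    An element counts as recovered when both element boundaries are
    within ``boundary_tol`` nt of the planted truth.
    """
    models = models or default_models()
    bg = make_background(background_len, gc, seed)
    genome, truth = plant_elements(
        bg, models, copies, rate, seed=seed + 1, genome_id="synth"
    )
    elements = ed.discover(GenomeRecord("synth", genome))
    matched = []
    max_err = 0
    for t in truth:
        for e in elements:
            if (
                abs(e.start - t.start) <= boundary_tol
                and abs(e.end - t.end) <= boundary_tol
            ):
                matched.append((t, e))
                max_err = max(
                    max_err, abs(e.start - t.start), abs(e.end - t.end)
                )
                break
    return DiscoveryEval(
        n_planted=len(truth),
        n_recovered=len(matched),
        recall_pct=100.0 * len(matched) / len(truth) if truth else 0.0,
        max_boundary_error_nt=max_err,
        genome=genome,
        truth=truth,
        elements=elements,
        matched=matched,
    )


def false_positive_eval(
    seed: int, background_len: int = 10_000_000, gc: float = 0.40
) -> float:
    """Discovery calls per Mb on element-free background."""
    bg = make_background(background_len, gc, seed)
    calls = ed.discover(GenomeRecord("bg", bg))
    return len(calls) / (background_len / 1e6)


def classification_eval(
    disc: DiscoveryEval, profiles, evalue_threshold: float = 1e-10
) -> float:
    """Percent of recovered elements assigned their planted lineage."""
    if not disc.matched:
        return 0.0
    correct = 0
    for t, e in disc.matched:
        a = lc.classify(e, disc.genome, profiles, evalue_threshold)
        correct += a.lineage == t.lineage
    return 100.0 * correct / len(disc.matched)


def decoy_eval(
    seed: int, profiles, n_decoys: int = 25, length: int = 5000,
    evalue_threshold: float = 1e-10,
) -> float:
    """Percent of random sequences left unclassified at the threshold."""
    unclassified = 0
    for i in range(n_decoys):
        seq = make_background(length, 0.40, seed + i)
        a = lc.classify_sequence(seq, f"decoy{i}", profiles)
        unclassified += a.lineage == "unclassified"
    return 100.0 * unclassified / n_decoys


ATT_TEST_LENGTHS = (5, 7, 10, 13)


def att_length_cycle() -> dict[str, tuple[int, int]]:
    """Planted att lengths cycling through the benchmark set 5/7/10/13
    on both sides of every lineage."""
    cyc = itertools.cycle(ATT_TEST_LENGTHS)
    return {name: (next(cyc), next(cyc)) for name in LINEAGES}


@dataclass
class AttEval:
    n_groups: int
    n_recovered: int
    recovery_pct: float
    any_extension_triggered: bool
    details: list  # (lineage, side, planted, delimited or None)


def att_recovery_eval(
    seed: int,
    copies: int = 20,
    rate: float = 0.02,
    background_len: int = 2_500_000,
    tol: int = 2,
    use_truth_elements: bool = False,
) -> AttEval:
    """Recovery of planted att motif lengths through the full pipeline.

    Plants motifs of lengths 5/7/10/13, runs discovery + classification +
    terminus profiling + delimitation, and scores each per-genome
    (lineage, side) group as recovered when the delimited length is
    within ``tol`` nt of the planted one.
    """
    att_lengths = att_length_cycle()
    models = default_models(att_lengths=att_lengths)
    bg = make_background(background_len, 0.40, seed)
    genome, truth = plant_elements(
        bg, models, copies, rate, seed=seed + 1, genome_id="synth"
    )
    rec = GenomeRecord("synth", genome)
    if use_truth_elements:
        elements = [
            ed.LTRElement(
                t.element_id, "synth", t.start, t.end, t.ltr5_start,
                t.ltr5_end, t.ltr3_start, t.ltr3_end, 1.0, t.tsd,
            )
            for t in truth
        ]
        assignments = [
            lc.LineageAssignment(t.element_id, t.lineage, "x", 99.0, 1e-30, 1)
            for t in truth
        ]
    else:
        elements = ed.discover(rec)
        profiles = lc.profiles_from_models(models)
        assignments = [
            lc.classify(e, genome, profiles) for e in elements
        ]
    _, _, results, _ = att_analysis(
        {"synth": elements}, {"synth": genome}, assignments, PipelineConfig()
    )
    details = []
    extension = False
    for r in results:
        if r.genome is None:
            continue
        a5, a3 = att_lengths[r.lineage]
        for side_name, site, planted in (
            ("five_prime", r.five, a5),
            ("three_prime", r.three, a3),
        ):
            details.append(
                (r.lineage, side_name, planted,
                 site.length if site else None)
            )
            if site is not None and site.window_used != 40:
                extension = True
    n_groups = len(details)
    n_rec = sum(
        1 for _, _, planted, got in details
        if got is not None and abs(got - planted) <= tol
    )
    return AttEval(
        n_groups=n_groups,
        n_recovered=n_rec,
        recovery_pct=100.0 * n_rec / n_groups if n_groups else 0.0,
        any_extension_triggered=extension,
        details=details,
    )


@dataclass
class ExtensionEval:
    long_side_window: int | None
    long_side_length: int | None
    short_side_window: int | None
    short_side_length: int | None


def extension_eval(
    seed: int, long_motif: int = 60, copies: int = 20, rate: float = 0.02
) -> ExtensionEval:
    """A lineage with a ``long_motif``-nt 5' att must trigger the
    40 -> 150 window extension; its short 3' side must not."""
    att_lengths = {name: (7, 6) for name in LINEAGES}
    att_lengths["Del"] = (long_motif, 11)
    models = default_models(att_lengths=att_lengths)
    copies_vec = [copies if m.name == "Del" else 0 for m in models]
    bg = make_background(1_200_000, 0.40, seed)
    genome, truth = plant_elements(
        bg, models, copies_vec, rate, seed=seed + 1, genome_id="synth"
    )
    elements = [
        ed.LTRElement(
            t.element_id, "synth", t.start, t.end, t.ltr5_start,
            t.ltr5_end, t.ltr3_start, t.ltr3_end, 1.0, t.tsd,
        )
        for t in truth
    ]
    assignments = [
        lc.LineageAssignment(t.element_id, t.lineage, "x", 99.0, 1e-30, 1)
        for t in truth
    ]
    _, _, results, _ = att_analysis(
        {"synth": elements}, {"synth": genome}, assignments, PipelineConfig()
    )
    res = next(r for r in results if r.genome is not None)
    return ExtensionEval(
        long_side_window=res.five.window_used if res.five else None,
        long_side_length=res.five.length if res.five else None,
        short_side_window=res.three.window_used if res.three else None,
        short_side_length=res.three.length if res.three else None,
    )
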