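"""End-to-end pipeline: discover -> classify -> profile -> delimit -> barcode.

Every stage writes its outputs to the run directory, can be re-entered
from saved intermediates, and is deterministic under fixed seeds; counts
per stage are logged.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

from . import abundance_barcode as ab
from . import att_delimiter as att
from . import element_discovery as ed
from . import lineage_classifier as lc
from . import terminus_conservation as tc
from .io import GenomeRecord, PipelineConfig, elements_to_gff3, read_fasta

logger = logging.getLogger("vlatt")


def setup_logging(log_file=None, level=logging.INFO) -> None:
    handlers = [logging.StreamHandler(sys.stderr)]
    if log_file:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


@dataclass
class AttGroupResult:
    lineage: str
    genome: str | None
    five: att.AttSite | None
    three: att.AttSite | None

    @property
    def descriptor(self) -> str:
        return att.report_pair(self.five, self.three)


@dataclass
class PipelineResult:
    genomes: list[GenomeRecord]
    elements: dict[str, list[ed.LTRElement]]  # per genome id
    assignments: list[lc.LineageAssignment]
    stacks: list[tc.TerminusStack]
    excluded_groups: list[tuple[str, str, int]]
    att_results: list[AttGroupResult]
    matrix: ab.AbundanceMatrix | None
    normalized: ab.NormalizedMatrix | None
    signatures: dict[str, str] = field(default_factory=dict)
    skipped_short_ltr: int = 0


def att_analysis(
    elements_by_genome: dict[str, list[ed.LTRElement]],
    genome_seqs: dict[str, str],
    assignments: list[lc.LineageAssignment],
    config: PipelineConfig = PipelineConfig(),
) -> tuple[list[tc.TerminusStack], list, list[AttGroupResult], int]:
    """Terminus stacking, profiling and att delimitation for all groups.

    Returns (stacks, excluded groups, per-group att results, number of
    elements skipped because an LTR was shorter than the window).
    """
    by_id: dict[str, ed.LTRElement] = {}
    genome_of: dict[str, str] = {}
    for gid, els in elements_by_genome.items():
        for el in els:
            by_id[el.element_id] = el
            genome_of[el.element_id] = gid
    orientation_of = {
        a.element_id: ("-" if a.frame >= 4 else "+") for a in assignments
    }

    def extract_all(window: int) -> tuple[dict, int]:
        termini = {}
        skipped = 0
        for a in assignments:
            el = by_id.get(a.element_id)
            if el is None:
                continue
            try:
                termini[a.element_id] = tc.extract_termini(
                    el,
                    genome_seqs[genome_of[a.element_id]],
                    window=window,
                    orientation=orientation_of.get(a.element_id, "+"),
                )
            except ValueError:
                skipped += 1
        return termini, skipped

    termini40, skipped = extract_all(config.terminus_window)
    if skipped:
        logger.info("skipped %d elements with LTR < %d nt",
                    skipped, config.terminus_window)
    stacks, excluded = tc.stack_group(
        assignments, termini40, genome_of, min_copies=config.min_copies
    )
    for lineage, genome, n in excluded:
        logger.info("excluded low-copy group %s/%s (%d copies)",
                    lineage, genome, n)

    termini150_cache: dict | None = None

    def get_termini150():
        nonlocal termini150_cache
        if termini150_cache is None:
            termini150_cache = extract_all(config.extended_window)[0]
        return termini150_cache

    # index element ids per stack group for re-extraction
    ids_by_group: dict[tuple[str, str | None], list[str]] = {}
    for a in assignments:
        if a.lineage == "unclassified" or a.element_id not in termini40:
            continue
        g = genome_of[a.element_id]
        ids_by_group.setdefault((a.lineage, g), []).append(a.element_id)
        ids_by_group.setdefault((a.lineage, None), []).append(a.element_id)

    results: list[AttGroupResult] = []
    grouped: dict[tuple[str, str | None], dict[str, att.AttSite | None]] = {}
    for stack in stacks:
        profile = tc.conservation_profile(
            stack,
            window=config.similarity_window,
            match=config.match_score,
            mismatch=config.mismatch_score,
        )

        def reextract(stack=stack):
            t150 = get_termini150()
            ids = [
                i for i in ids_by_group.get((stack.lineage, stack.genome), [])
                if i in t150
            ]
            if len(ids) < config.min_copies:
                return None
            seqs = [
                t150[i][0] if stack.side == tc.FIVE_PRIME else t150[i][1]
                for i in ids
            ]
            s150 = tc.TerminusStack(
                stack.side, stack.lineage, stack.genome, seqs
            )
            p150 = tc.conservation_profile(
                s150,
                window=config.similarity_window,
                match=config.match_score,
                mismatch=config.mismatch_score,
            )
            return p150, s150

        site = att.delimit_with_extension(
            profile,
            reextract,
            max_gaps=config.max_gaps,
            max_gap_len=config.max_gap_len,
            stack40=stack,
            extended_window=config.extended_window,
        )
        grouped.setdefault((stack.lineage, stack.genome), {})[stack.side] = site
    for (lineage, genome), sides in sorted(
        grouped.items(), key=lambda kv: (kv[0][0], kv[0][1] or "")
    ):
        results.append(
            AttGroupResult(
                lineage=lineage,
                genome=genome,
                five=sides.get(tc.FIVE_PRIME),
                three=sides.get(tc.THREE_PRIME),
            )
        )
    return stacks, excluded, results, skipped


def run_pipeline(
    genomes: list[GenomeRecord],
    profiles: list[lc.RTProfile],
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage on a set of genome records."""
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        config.to_file(out / "config.txt")
    params = ed.DiscoveryParams(
        min_ltr_len=config.min_ltr_len,
        max_ltr_len=config.max_ltr_len,
        min_ltr_identity=config.min_ltr_identity,
        min_element_len=config.min_element_len,
        max_element_len=config.max_element_len,
        seed_kmer=config.seed_kmer,
        require_tg_ca=config.require_tg_ca,
        require_tsd=config.require_tsd,
    )

    elements_by_genome: dict[str, list[ed.LTRElement]] = {}
    genome_seqs: dict[str, str] = {}
    assignments: list[lc.LineageAssignment] = []
    genome_of: dict[str, str] = {}
    for rec in genomes:
        genome_seqs[rec.id] = rec.seq
        els = ed.discover(rec, params)
        elements_by_genome[rec.id] = els
        logger.info("genome %s: %d putative complete elements", rec.id, len(els))
        for el in els:
            a = lc.classify(el, rec.seq, profiles, config.evalue_threshold)
            assignments.append(a)
            genome_of[el.element_id] = rec.id
        if out:
            elements_to_gff3(els, out / f"{rec.id}.elements.gff3")
    n_class = sum(a.lineage != "unclassified" for a in assignments)
    logger.info("classified %d/%d elements", n_class, len(assignments))
    if out:
        lc.assignments_to_tsv(assignments, out / "assignments.tsv")

    stacks, excluded, att_results, skipped = att_analysis(
        elements_by_genome, genome_seqs, assignments, config
    )
    if out:
        sites = [
            s for r in att_results for s in (r.five, r.three) if s is not None
        ]
        att.sites_to_tsv(sites, out / "att_sites.tsv")
        with open(out / "att_descriptors.tsv", "w") as fh:
            fh.write("lineage\tgenome\tdescriptor\n")
            for r in att_results:
                fh.write(
                    f"{r.lineage}\t{r.genome or 'pooled'}\t{r.descriptor}\n"
                )

    matrix = normalized = None
    signatures: dict[str, str] = {}
    if assignments:
        matrix = ab.tabulate(
            assignments, genome_of, genomes=[g.id for g in genomes]
        )
        normalized = ab.normalize(matrix)
        for rec in genomes:
            if matrix.genome_totals[rec.id] > 0:
                sig = ab.signature_string(rec.id, normalized)
                signatures[rec.id] = sig
                if out:
                    ab.encode_qr(sig, png_path=out / f"{rec.id}.qr.png")
                    (out / f"{rec.id}.signature.txt").write_text(sig + "\n")
        if out:
            ab.counts_to_tsv(matrix, out / "counts.tsv")
            ab.percentages_to_tsv(normalized, out / "percentages.tsv")
            ab.superfamily_summary_to_tsv(matrix, out / "superfamilies.tsv")

    return PipelineResult(
        genomes=genomes,
        elements=elements_by_genome,
        assignments=assignments,
        stacks=stacks,
        excluded_groups=excluded,
        att_results=att_results,
        matrix=matrix,
        normalized=normalized,
        signatures=signatures,
        skipped_short_ltr=skipped,
    )


def run_pipeline_fasta(
    fasta: str | Path,
    profiles: list[lc.RTProfile],
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
) -> PipelineResult:
    return run_pipeline(read_fasta(fasta), profiles, config, out_dir)
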