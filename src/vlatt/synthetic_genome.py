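"""Synthetic plant genomes with planted LTR retrotransposons.

Every downstream stage of the pipeline (structural discovery, lineage
classification, terminus conservation profiling, att-site delimitation,
abundance barcoding) is validated against genomes produced here, where the
exact coordinates, lineage, target-site duplication and att motifs of each
planted element are known.

Element anatomy follows the canonical full-length LTR-RT structure: a 4-6 nt
target-site duplication (TSD) flanking the element, two near-identical long
terminal repeats (LTRs) beginning ``TG`` and ending ``CA``, and an internal
region carrying a lineage-specific reverse-transcriptase (RT) coding
sequence.  The two LTR copies of one element derive from a single per-copy
LTR, so after per-site mutation at rate *r* their expected identity is
(1-r)^2 per site - the property structural detectors exploit.

Across copies of a lineage, only the att motifs at the LTR termini (and the
RT domain) are conserved: the LTR interior is re-randomized per copy
(``interior_divergence``), emulating the fact that real insertions of a
lineage are separated by millions of years of drift everywhere except at
the constrained terminal attachment sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Fixed lineage order used throughout the package: the six Copia lineages
#: followed by the five Gypsy lineages.
LINEAGES = [
    "Ale", "Angela", "Bianca", "Ivana", "Maximus", "Tar",
    "Athila", "CRM", "Del", "Galadriel", "Reina",
]

SUPERFAMILY = {
    "Ale": "Copia", "Angela": "Copia", "Bianca": "Copia",
    "Ivana": "Copia", "Maximus": "Copia", "Tar": "Copia",
    "Athila": "Gypsy", "CRM": "Gypsy", "Del": "Gypsy",
    "Galadriel": "Gypsy", "Reina": "Gypsy",
}

#: Default (5' att, 3' att) motif lengths per lineage.  These mirror the
#: att-site lengths observed in plant genomes for each lineage (short sites
#: for Ale/Ivana/Reina, long ones for Angela/Maximus/CRM).
DEFAULT_ATT_LENGTHS = {
    "Ale": (7, 6), "Angela": (18, 10), "Bianca": (13, 13),
    "Ivana": (5, 6), "Maximus": (16, 5), "Tar": (6, 5),
    "Athila": (6, 6), "CRM": (12, 10), "Del": (10, 11),
    "Galadriel": (8, 8), "Reina": (5, 7),
}

DEFAULT_MODEL_SEED = 101

_CODON = {}


def _build_codon_table() -> dict[str, str]:
    # one representative codon per amino acid (standard code)
    table = {
        "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
        "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
        "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
        "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
    }
    return table


_CODON = _build_codon_table()


@dataclass(frozen=True)
class LineageModel:
    """Generative model of one LTR-RT lineage.

    ``att5_motif`` is a prefix of ``ltr_template`` and ``att3_motif`` a
    suffix, so the canonical TG...CA LTR termini are part of the motifs.
    """

    name: str
    superfamily: str
    ltr_template: str
    att5_motif: str
    att3_motif: str
    rt_peptide: str
    internal_length: int = 4000

    def __post_init__(self):
        if not (100 <= len(self.ltr_template) <= 600):
            raise ValueError("ltr_template length must be in [100, 600]")
        if not self.ltr_template.startswith("TG"):
            raise ValueError("ltr_template must start with TG")
        if not self.ltr_template.endswith("CA"):
            raise ValueError("ltr_template must end with CA")
        if not self.ltr_template.startswith(self.att5_motif):
            raise ValueError("att5_motif must be a prefix of ltr_template")
        if not self.ltr_template.endswith(self.att3_motif):
            raise ValueError("att3_motif must be a suffix of ltr_template")
        if not (5 <= len(self.att5_motif) <= 60):
            raise ValueError("att5_motif length out of range")
        if not (5 <= len(self.att3_motif) <= 60):
            raise ValueError("att3_motif length out of range")
        if len(self.rt_peptide) < 60:
            raise ValueError("rt_peptide must be >= 60 aa")
        if self.superfamily != SUPERFAMILY[self.name]:
            raise ValueError(
                f"{self.name} belongs to superfamily {SUPERFAMILY[self.name]}"
            )


@dataclass
class PlantedTruth:
    """Ground-truth record for one planted element (0-based half-open)."""

    element_id: str
    genome_id: str
    lineage: str
    start: int
    end: int
    ltr5_start: int
    ltr5_end: int
    ltr3_start: int
    ltr3_end: int
    tsd: str
    mutations: int = 0


def _seq_to_arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def _arr_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def make_background(length: int, gc: float, seed: int) -> str:
    """Random DNA of the requested length and expected GC fraction."""
    if length < 0:
        raise ValueError("length must be non-negative")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    if length == 0:
        return ""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(BASES, size=length, p=p)
    return _arr_to_seq(arr)


def mutate(seq: str, rate: float, seed: int) -> str:
    """Substitute each site independently with probability ``rate``.

    A substituted site always changes to one of the three other bases.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if not seq or rate == 0.0:
        return seq
    rng = np.random.default_rng(seed)
    arr = _seq_to_arr(seq)
    hit = rng.random(len(arr)) < rate
    idx = np.flatnonzero(hit)
    if idx.size:
        # map ACGT -> 0..3, add 1..3 mod 4, map back
        lut = np.full(256, 255, dtype=np.uint8)
        lut[BASES] = np.arange(4, dtype=np.uint8)
        codes = lut[arr[idx]]
        shift = rng.integers(1, 4, size=idx.size).astype(np.uint8)
        arr[idx] = BASES[(codes + shift) % 4]
    return _arr_to_seq(arr)


def encode_peptide(peptide: str) -> str:
    """Deterministic DNA encoding of a peptide (standard genetic code)."""
    return "".join(_CODON[aa] for aa in peptide)


def default_models(
    seed: int = DEFAULT_MODEL_SEED,
    att_lengths: dict[str, tuple[int, int]] | None = None,
    ltr_length: int = 400,
    internal_length: int = 4000,
    rt_length: int = 80,
) -> list[LineageModel]:
    """Build the 11 default lineage models.

    Each lineage gets an independent random LTR template (TG...CA), att
    motifs of lineage-specific lengths, and a random RT consensus peptide;
    random peptides of this length are ~5% pairwise identical, far below
    the 40% ceiling that keeps classification unambiguous.
    """
    att_lengths = att_lengths or DEFAULT_ATT_LENGTHS
    rng = np.random.default_rng(seed)
    models = []
    for name in LINEAGES:
        tmpl = _arr_to_seq(rng.choice(BASES, size=ltr_length))
        tmpl = "TG" + tmpl[2:-2] + "CA"
        a5, a3 = att_lengths[name]
        pep = "".join(
            AA20[i] for i in rng.integers(0, 20, size=rt_length)
        )
        models.append(
            LineageModel(
                name=name,
                superfamily=SUPERFAMILY[name],
                ltr_template=tmpl,
                att5_motif=tmpl[:a5],
                att3_motif=tmpl[-a3:],
                rt_peptide=pep,
                internal_length=internal_length,
            )
        )
    return models


def _internal_template(model: LineageModel, rng: np.random.Generator) -> str:
    """Internal-region template with the RT CDS embedded near the start."""
    cds = encode_peptide(model.rt_peptide)
    pad = model.internal_length - len(cds) - 90
    if pad < 0:
        raise ValueError("internal_length too short for RT coding sequence")
    left = _arr_to_seq(rng.choice(BASES, size=90))
    right = _arr_to_seq(rng.choice(BASES, size=pad))
    return left + cds + right


def _hamming(a: str, b: str) -> int:
    return int(np.count_nonzero(_seq_to_arr(a) != _seq_to_arr(b)))


def plant_elements(
    background: str,
    models: list[LineageModel],
    copies_per_model: list[int] | int,
    rate: float,
    seed: int,
    genome_id: str = "synth",
    interior_divergence: float = 0.75,
    tsd_len_range: tuple[int, int] = (4, 6),
) -> tuple[str, list[PlantedTruth]]:
    """Insert LTR-RT copies into a background sequence.

    Each element is ``TSD + LTR + internal + LTR' + TSD`` where LTR and
    LTR' are independent rate-``rate`` mutants of one per-copy LTR, itself
    the lineage template with its interior (between the att motifs)
    additionally diverged at ``interior_divergence`` per copy.  Insertion
    points are uniform over the background; because insertion expands the
    sequence, elements can never overlap.  Returns the final genome and
    exact ground-truth coordinates.
    """
    if isinstance(copies_per_model, int):
        copies_per_model = [copies_per_model] * len(models)
    if len(copies_per_model) != len(models):
        raise ValueError("copies_per_model length must match models")
    rng = np.random.default_rng(seed)

    jobs = []
    for model, n in zip(models, copies_per_model):
        for _ in range(n):
            jobs.append(model)
    total_len = sum(
        2 * len(m.ltr_template) + m.internal_length + 12 for m in jobs
    )
    if total_len > len(background):
        raise ValueError(
            f"insufficient background length: elements need {total_len} nt "
            f"but background has {len(background)} nt"
        )

    # one insertion point per element in background coordinates
    points = np.sort(
        rng.choice(len(background) + 1, size=len(jobs), replace=False)
    ) if jobs else np.array([], dtype=int)
    # shuffle lineage order over sorted points so placement is uniform
    order = rng.permutation(len(jobs))
    internal_templates = {
        m.name: _internal_template(m, np.random.default_rng(int(rng.integers(2**31))))
        for m in models
    }

    pieces = []
    truth: list[PlantedTruth] = []
    cursor = 0  # position in background
    offset = 0  # cumulative inserted length
    counter = 0
    for pt_idx, pt in enumerate(points):
        model = jobs[order[pt_idx]]
        pieces.append(background[cursor:pt])
        cursor = pt

        sub = lambda: int(rng.integers(2**31))  # noqa: E731
        tsd_len = int(rng.integers(tsd_len_range[0], tsd_len_range[1] + 1))
        tsd = _arr_to_seq(rng.choice(BASES, size=tsd_len))

        tmpl = model.ltr_template
        a5, a3 = len(model.att5_motif), len(model.att3_motif)
        interior = tmpl[a5: len(tmpl) - a3]
        copy_ltr = (
            model.att5_motif
            + mutate(interior, interior_divergence, sub())
            + model.att3_motif
        )
        ltr5 = mutate(copy_ltr, rate, sub())
        ltr3 = mutate(copy_ltr, rate, sub())
        internal = mutate(internal_templates[model.name], rate, sub())

        n_mut = (
            _hamming(ltr5, copy_ltr)
            + _hamming(ltr3, copy_ltr)
            + _hamming(internal, internal_templates[model.name])
        )

        element = tsd + ltr5 + internal + ltr3 + tsd
        start = int(pt) + offset + tsd_len  # element excludes the TSDs
        ltr5_start = start
        ltr5_end = start + len(ltr5)
        ltr3_start = ltr5_end + len(internal)
        ltr3_end = ltr3_start + len(ltr3)
        counter += 1
        truth.append(
            PlantedTruth(
                element_id=f"{genome_id}_e{counter:04d}",
                genome_id=genome_id,
                lineage=model.name,
                start=start,
                end=ltr3_end,
                ltr5_start=ltr5_start,
                ltr5_end=ltr5_end,
                ltr3_start=ltr3_start,
                ltr3_end=ltr3_end,
                tsd=tsd,
                mutations=n_mut,
            )
        )
        pieces.append(element)
        offset += len(element)
    pieces.append(background[cursor:])
    return "".join(pieces), truth


# ---------------------------------------------------------------------------
# Truth serialization
# ---------------------------------------------------------------------------


def truth_to_gff3(truth: list[PlantedTruth], path) -> None:
    from .io import GFFFeature, write_gff3_features

    feats = []
    for t in truth:
        feats.append(
            GFFFeature(
                t.genome_id, "vlatt_sim", "LTR_retrotransposon",
                t.start + 1, t.end, ".", "+", ".",
                {"ID": t.element_id, "lineage": t.lineage, "tsd": t.tsd},
            )
        )
        for name, (s, e) in (
            ("ltr5", (t.ltr5_start, t.ltr5_end)),
            ("ltr3", (t.ltr3_start, t.ltr3_end)),
        ):
            feats.append(
                GFFFeature(
                    t.genome_id, "vlatt_sim", "long_terminal_repeat",
                    s + 1, e, ".", "+", ".",
                    {"ID": f"{t.element_id}_{name}", "Parent": t.element_id},
                )
            )
    write_gff3_features(feats, path)


def truth_from_gff3(path) -> list[PlantedTruth]:
    from .io import read_gff3_features

    feats = read_gff3_features(path)
    parents = {}
    ltrs: dict[str, dict[str, tuple[int, int]]] = {}
    for f in feats:
        if f.ftype == "LTR_retrotransposon":
            parents[f.attrs["ID"]] = f
        elif f.ftype == "long_terminal_repeat":
            pid = f.attrs["Parent"]
            name = "ltr5" if f.attrs["ID"].endswith("ltr5") else "ltr3"
            ltrs.setdefault(pid, {})[name] = (f.start - 1, f.end)
    out = []
    for eid, f in parents.items():
        l5, l3 = ltrs[eid]["ltr5"], ltrs[eid]["ltr3"]
        out.append(
            PlantedTruth(
                element_id=eid,
                genome_id=f.seqid,
                lineage=f.attrs["lineage"],
                start=f.start - 1,
                end=f.end,
                ltr5_start=l5[0],
                ltr5_end=l5[1],
                ltr3_start=l3[0],
                ltr3_end=l3[1],
                tsd=f.attrs["tsd"],
            )
        )
    out.sort(key=lambda t: t.start)
    return out


def truth_to_tsv(truth: list[PlantedTruth], path) -> None:
    cols = [
        "element_id", "genome_id", "lineage", "start", "end",
        "ltr5_start", "ltr5_end", "ltr3_start", "ltr3_end", "tsd",
        "mutations",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for t in truth:
            fh.write("\t".join(str(getattr(t, c)) for c in cols) + "\n")
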