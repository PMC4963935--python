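"""FASTA / GFF3 / TSV input-output and pipeline configuration.

Internally every interval is 0-based half-open on the assembly forward
strand; GFF3 files use the format's 1-based inclusive convention and are
converted on the way in and out.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_DNA = set("ACGTRYSWKMBDHVN")

GFF3_HEADER = "##gff-version 3"


@dataclass(frozen=True)
class GenomeRecord:
    """A named DNA sequence with provenance."""

    id: str
    seq: str
    source: str = ""

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a FASTA file into GenomeRecords.

    Sequences are uppercased; characters outside the IUPAC DNA alphabet are
    rejected with an error naming the record and 1-based offset.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        for i, ch in enumerate(seq):
            if ch not in IUPAC_DNA:
                raise ValueError(
                    f"invalid character {ch!r} in record {rec.id!r} "
                    f"at position {i + 1} of {path}"
                )
        records.append(GenomeRecord(id=rec.id, seq=seq, source=str(path)))
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 for LTR retrotransposon features
# ---------------------------------------------------------------------------

_GFF_COLS = 9


def _fmt_attrs(attrs: dict[str, str]) -> str:
    if not attrs:
        return "."
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def _parse_attrs(text: str) -> dict[str, str]:
    if text in (".", ""):
        return {}
    out = {}
    for part in text.split(";"):
        if not part:
            continue
        k, _, v = part.partition("=")
        out[k] = v
    return out


@dataclass
class GFFFeature:
    seqid: str
    source: str
    ftype: str
    start: int  # 1-based inclusive, as in the file
    end: int
    score: str
    strand: str
    phase: str
    attrs: dict[str, str] = field(default_factory=dict)


def write_gff3_features(features: Iterable[GFFFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(GFF3_HEADER + "\n")
        for f in features:
            fh.write(
                "\t".join(
                    [
                        f.seqid,
                        f.source,
                        f.ftype,
                        str(f.start),
                        str(f.end),
                        f.score,
                        f.strand,
                        f.phase,
                        _fmt_attrs(f.attrs),
                    ]
                )
                + "\n"
            )


def read_gff3_features(path: str | Path) -> list[GFFFeature]:
    feats = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _GFF_COLS:
                raise ValueError(f"malformed GFF3 line in {path}: {line!r}")
            feats.append(
                GFFFeature(
                    seqid=cols[0],
                    source=cols[1],
                    ftype=cols[2],
                    start=int(cols[3]),
                    end=int(cols[4]),
                    score=cols[5],
                    strand=cols[6],
                    phase=cols[7],
                    attrs=_parse_attrs(cols[8]),
                )
            )
    return feats


def elements_to_gff3(elements, path: str | Path, source: str = "vlatt") -> None:
    """Write discovered elements (LTRElement) as GFF3.

    Each element is a LTR_retrotransposon feature with two
    long_terminal_repeat children and, when a TSD was found, two
    target_site_duplication children flanking the element.
    """
    feats = []
    for el in elements:
        attrs = {
            "ID": el.element_id,
            "ltr_identity": f"{el.ltr_identity:.4f}",
        }
        if el.tsd:
            attrs["tsd"] = el.tsd
        attrs["tg_ca"] = f"{int(el.tg_ca[0])},{int(el.tg_ca[1])}"
        feats.append(
            GFFFeature(
                el.genome_id, source, "LTR_retrotransposon",
                el.start + 1, el.end, ".", "+", ".", attrs,
            )
        )
        for name, (s, e) in (
            ("ltr5", (el.ltr5_start, el.ltr5_end)),
            ("ltr3", (el.ltr3_start, el.ltr3_end)),
        ):
            feats.append(
                GFFFeature(
                    el.genome_id, source, "long_terminal_repeat",
                    s + 1, e, ".", "+", ".",
                    {"ID": f"{el.element_id}_{name}", "Parent": el.element_id},
                )
            )
        if el.tsd:
            d = len(el.tsd)
            feats.append(
                GFFFeature(
                    el.genome_id, source, "target_site_duplication",
                    el.start - d + 1, el.start, ".", "+", ".",
                    {"ID": f"{el.element_id}_tsd5", "Parent": el.element_id},
                )
            )
            feats.append(
                GFFFeature(
                    el.genome_id, source, "target_site_duplication",
                    el.end + 1, el.end + d, ".", "+", ".",
                    {"ID": f"{el.element_id}_tsd3", "Parent": el.element_id},
                )
            )
    write_gff3_features(feats, path)


def elements_from_gff3(path: str | Path):
    """Inverse of :func:`elements_to_gff3` (lossless for package output)."""
    from .element_discovery import LTRElement

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
    elements = []
    for eid, f in parents.items():
        l5 = ltrs[eid]["ltr5"]
        l3 = ltrs[eid]["ltr3"]
        tg = f.attrs.get("tg_ca", "1,1").split(",")
        elements.append(
            LTRElement(
                element_id=eid,
                genome_id=f.seqid,
                start=f.start - 1,
                end=f.end,
                ltr5_start=l5[0],
                ltr5_end=l5[1],
                ltr3_start=l3[0],
                ltr3_end=l3[1],
                ltr_identity=float(f.attrs.get("ltr_identity", "0")),
                tsd=f.attrs.get("tsd"),
                tg_ca=(bool(int(tg[0])), bool(int(tg[1]))),
            )
        )
    elements.sort(key=lambda e: (e.genome_id, e.start))
    return elements


# ---------------------------------------------------------------------------
# Flat key/value configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Resolved parameters for every pipeline stage.

    Serialized as a flat ``key = value`` text file; unknown keys are
    rejected so typos cannot silently fall back to defaults.
    """

    # synthetic genome
    sim_length: int = 500_000
    sim_gc: float = 0.40
    sim_copies: int = 5
    sim_rate: float = 0.02
    sim_interior_divergence: float = 0.75
    seed: int = 1
    # discovery
    min_ltr_len: int = 100
    max_ltr_len: int = 2000
    min_ltr_identity: float = 0.85
    min_element_len: int = 1000
    max_element_len: int = 18000
    seed_kmer: int = 20
    require_tg_ca: bool = True
    require_tsd: bool = True
    # classification
    evalue_threshold: float = 1e-10
    # terminus profiling
    terminus_window: int = 40
    extended_window: int = 150
    similarity_window: int = 4
    match_score: float = 5.0
    mismatch_score: float = -4.0
    min_copies: int = 9
    # att delimitation
    max_gaps: int = 2
    max_gap_len: int = 2

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in known:
                    raise ValueError(
                        f"unknown config key {key!r} at line {lineno}"
                    )
                ftype = known[key].type
                if ftype in ("int", int):
                    kwargs[key] = int(value)
                elif ftype in ("float", float):
                    kwargs[key] = float(value)
                elif ftype in ("bool", bool):
                    kwargs[key] = value.lower() in ("1", "true", "yes")
                else:
                    kwargs[key] = value
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")
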