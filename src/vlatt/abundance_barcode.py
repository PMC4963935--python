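"""Genome x lineage abundance matrices, normalization and QR barcodes.

The copy-number matrix counts putative complete elements per lineage and
genome.  Normalization expresses each lineage as a percentage of the
genome's total putative complete LTR-RT content
(100 * count / genome total), which is what makes amplification patterns
comparable across genomes of very different sizes; the normalized row is
serialized into a canonical signature string and encoded as a QR symbol -
the genome's barcode.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable

import numpy as np
import pandas as pd

from .lineage_classifier import LineageAssignment
from .synthetic_genome import LINEAGES, SUPERFAMILY
from . import qr as qrcodec

COPIA = [l for l in LINEAGES if SUPERFAMILY[l] == "Copia"]
GYPSY = [l for l in LINEAGES if SUPERFAMILY[l] == "Gypsy"]


@dataclass
class AbundanceMatrix:
    counts: pd.DataFrame  # genomes x lineages, ints
    unclassified: pd.Series  # per-genome count of unclassified elements

    @property
    def genome_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def lineage_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.values.sum())


@dataclass
class NormalizedMatrix:
    percentages: pd.DataFrame  # one-decimal values, rows sum to ~100
    raw: pd.DataFrame  # unrounded fractions * 100


def tabulate(
    assignments: Iterable[LineageAssignment],
    genome_of: dict[str, str],
    genomes: list[str] | None = None,
) -> AbundanceMatrix:
    """Count classified elements per (genome, lineage).

    Unclassified elements are excluded from the matrix and counted
    separately.
    """
    assignments = list(assignments)
    if genomes is None:
        genomes = sorted({genome_of[a.element_id] for a in assignments})
    counts = pd.DataFrame(0, index=list(genomes), columns=LINEAGES, dtype=int)
    unclassified = pd.Series(0, index=list(genomes), dtype=int)
    for a in assignments:
        g = genome_of[a.element_id]
        if a.lineage == "unclassified":
            unclassified[g] += 1
        else:
            counts.loc[g, a.lineage] += 1
    return AbundanceMatrix(counts=counts, unclassified=unclassified)


def matrix_from_counts(counts: pd.DataFrame) -> AbundanceMatrix:
    """Wrap an existing genome x lineage count table (e.g. the published
    reference table) in an AbundanceMatrix."""
    counts = counts.reindex(columns=LINEAGES)
    return AbundanceMatrix(
        counts=counts.astype(int),
        unclassified=pd.Series(0, index=counts.index, dtype=int),
    )


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), ROUND_HALF_UP))


def normalize(matrix: AbundanceMatrix) -> NormalizedMatrix:
    """Per-genome percentages: 100 * lineage count / genome total.

    Rounded half-up to one decimal; genomes with zero total get NaN rows
    rather than a division failure.
    """
    totals = matrix.genome_totals
    raw = matrix.counts.astype(float)
    pct = pd.DataFrame(
        np.nan, index=raw.index, columns=raw.columns, dtype=float
    )
    for g in raw.index:
        t = totals[g]
        if t == 0:
            continue
        raw.loc[g] = 100.0 * matrix.counts.loc[g] / t
        pct.loc[g] = [_round1(v) for v in raw.loc[g]]
    raw[totals == 0] = np.nan
    return NormalizedMatrix(percentages=pct, raw=raw)


def superfamily_totals(
    matrix: AbundanceMatrix,
) -> tuple[int, int, float | None, float | None]:
    """(copia_total, gypsy_total, ratio rounded to 1 decimal, raw ratio).

    The ratio is gypsy/copia; None when there are no Copia elements.
    """
    copia = int(matrix.counts[COPIA].values.sum())
    gypsy = int(matrix.counts[GYPSY].values.sum())
    if copia == 0:
        return copia, gypsy, None, None
    ratio = gypsy / copia
    return copia, gypsy, _round1(ratio), ratio


def signature_string(genome: str, norm: NormalizedMatrix) -> str:
    """Canonical per-genome barcode payload.

    ``<genome>|Ale:<v>;Angela:<v>;...;Reina:<v>`` with the fixed lineage
    order and one-decimal values - byte-stable for identical rows.
    """
    row = norm.percentages.loc[genome]
    fields = ";".join(f"{l}:{row[l]:.1f}" for l in LINEAGES)
    return f"{genome}|{fields}"


def encode_qr(signature: str, png_path=None, scale: int = 8):
    """Encode a signature as a QR symbol (model 2, byte mode, EC level M).

    Returns the module matrix (bool ndarray); optionally writes a PNG.
    Decoding the symbol with :func:`vlatt.qr.decode` returns the exact
    signature string.
    """
    matrix = qrcodec.encode(signature)
    if png_path is not None:
        qrcodec.save_png(matrix, png_path, scale=scale)
    return matrix


def decode_qr(matrix) -> str:
    return qrcodec.decode(matrix)


def counts_to_tsv(matrix: AbundanceMatrix, path) -> None:
    df = matrix.counts.copy()
    df["Total"] = matrix.genome_totals
    df.to_csv(path, sep="\t")


def percentages_to_tsv(norm: NormalizedMatrix, path) -> None:
    norm.percentages.to_csv(path, sep="\t", float_format="%.1f")


def superfamily_summary_to_tsv(matrix: AbundanceMatrix, path) -> None:
    copia, gypsy, ratio, raw = superfamily_totals(matrix)
    with open(path, "w") as fh:
        fh.write("superfamily\ttotal\n")
        fh.write(f"Copia\t{copia}\n")
        fh.write(f"Gypsy\t{gypsy}\n")
        fh.write(f"gypsy_to_copia_ratio\t{'NA' if ratio is None else ratio}\n")
        fh.write(
            f"gypsy_to_copia_ratio_raw\t{'NA' if raw is None else f'{raw:.4f}'}\n"
        )
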