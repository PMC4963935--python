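"""Published copy-number table of putative complete LTR-RTs.

Counts of putative complete elements (two intact LTRs) per lineage as
published for ten fully sequenced angiosperm assemblies, reconstructed
cell by cell against the published normalized percentages and every
printed margin (per-lineage totals, per-genome totals, eudicot 6,363,
monocot 22,259, Copia 11,220, Gypsy 17,402, grand total 28,622).

Note: the published O. sativa row total reads 1,402, but the row's cells
sum to 1,404 and only 1,404 is consistent with the printed monocot and
per-lineage totals; 1,404 is used here.
"""

from __future__ import annotations

import pandas as pd

from .synthetic_genome import LINEAGES

#: Genome order as printed: five eudicots then five monocots.
GENOME_ORDER = ["At", "Mt", "Pt", "Vv", "Gm", "Bd", "Os", "Si", "Sb", "Zm"]

EUDICOTS = ["At", "Mt", "Pt", "Vv", "Gm"]
MONOCOTS = ["Bd", "Os", "Si", "Sb", "Zm"]

GENOME_NAMES = {
    "At": "Arabidopsis thaliana",
    "Mt": "Medicago truncatula",
    "Pt": "Populus trichocarpa",
    "Vv": "Vitis vinifera",
    "Gm": "Glycine max",
    "Bd": "Brachypodium distachyon",
    "Os": "Oryza sativa",
    "Si": "Setaria italica",
    "Sb": "Sorghum bicolor",
    "Zm": "Zea mays",
}

# rows follow GENOME_ORDER; columns follow LINEAGES
_COUNTS = [
    #  Ale Angela Bianca Ivana Maximus Tar Athila  CRM  Del Galadriel Reina
    [  12,    2,    5,   15,    7,   12,   24,    3,   11,    0,    9],  # At
    [  36,    8,    4,   39,  103,   49,  148,    4,   57,    0,   14],  # Mt
    [ 125,    2,    1,   70,    0,   29,   31,   23,    3,    6,   41],  # Pt
    [ 743,  106,   75,   78,   29,  173,  368,   31,   12,   36,   47],  # Vv
    [  87,  199,    0,  276,  862,  168,  951,  767,   72,    0,  390],  # Gm
    [  69,   61,   14,   47,   11,    7,  191,   25,   12,    0,   30],  # Bd
    [  88,   55,    2,   68,   50,  121,  642,   31,  262,    1,   84],  # Os
    [ 112,  457,    0,   42,   10,   40,  605,  122,  191,    0,   43],  # Si
    [ 186,   65,   31,  172,  350,   19, 2984,  192,  621,    0,  208],  # Sb
    [ 294,  197,   24,  138, 5102,   73, 6105,  320, 1289,    0,  396],  # Zm
]

#: Assembly sizes (Mb) and GC content (%) as printed, for reference.
GENOME_SIZE_MB = {
    "At": 119, "Mt": 291, "Pt": 378, "Vv": 486, "Gm": 950,
    "Bd": 271, "Os": 372, "Si": 392, "Sb": 659, "Zm": 2066,
}
GENOME_GC_PERCENT = {
    "At": 36, "Mt": 36, "Pt": 34, "Vv": 35, "Gm": 35,
    "Bd": 46, "Os": 44, "Si": 46, "Sb": 44, "Zm": 47,
}


def reference_counts() -> pd.DataFrame:
    """Genome x lineage copy-number table (rows: genomes, cols: lineages)."""
    return pd.DataFrame(_COUNTS, index=GENOME_ORDER, columns=LINEAGES)
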