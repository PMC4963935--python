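"""Positional conservation at LTR termini.

For each (lineage, genome) group the first 40 bases of the 5' LTR and the
last 40 bases of the 3' LTR are stacked (anchored at the LTR boundary, so
the stacks are ungapped and columnar) and two per-position curves are
computed:

* information content - the sequence-logo stack height, 2 - H(p) bits;
* windowed similarity - the mean pairwise substitution score per column
  (match +5 / mismatch -4, EDNAFULL-style), centered on the expectation
  under the stack's overall base composition and smoothed over a short
  window (default 4 columns).  Positive values mean "more similar than
  random", the property used downstream to delimit att sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .element_discovery import LTRElement
from .lineage_classifier import LineageAssignment

_COMP = str.maketrans("ACGTN", "TGCAN")

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"

_B_LUT = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _B_LUT[b] = i


@dataclass
class TerminusStack:
    """Fixed-length terminus sequences anchored at the LTR boundary."""

    side: str  # five_prime | three_prime
    lineage: str
    genome: str | None  # None = pooled over all genomes
    sequences: list[str]

    @property
    def copy_count(self) -> int:
        return len(self.sequences)

    @property
    def window(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0


@dataclass
class ConservationProfile:
    side: str
    lineage: str
    genome: str | None
    copy_count: int
    window: int  # smoothing window (columns)
    base_freqs: np.ndarray  # (L, 4), rows sum to 1 (NaN where no data)
    info_content: np.ndarray  # (L,) bits in [0, 2]; NaN where undefined
    similarity: np.ndarray  # (L,) centered windowed pairwise score
    plotcon: np.ndarray | None = None  # (L,) uncentered windowed score
    e0: float = 0.0  # random-expectation baseline under stack composition
    matrix_id: str = "match5/mismatch-4"

    @property
    def length(self) -> int:
        return self.info_content.size

    @property
    def delimit_curve(self) -> np.ndarray:
        """Curve used for att delimitation: the uncentered PlotCon-scale
        score, for which 0 separates conservation from background (random
        columns average the decisively negative e0)."""
        if self.plotcon is not None:
            return self.plotcon
        return self.similarity + self.e0


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def extract_termini(
    element: LTRElement,
    genome_seq: str,
    window: int = 40,
    orientation: str = "+",
) -> tuple[str, str]:
    """First ``window`` bases of the 5' LTR and last of the 3' LTR.

    Reported on the element's coding orientation: for a minus-orientation
    element the roles of the two LTRs swap and sequences are
    reverse-complemented.  Raises ValueError when an LTR is shorter than
    the window (callers skip and count these).
    """
    l5 = genome_seq[element.ltr5_start: element.ltr5_end]
    l3 = genome_seq[element.ltr3_start: element.ltr3_end]
    if len(l5) < window or len(l3) < window:
        raise ValueError(
            f"LTR shorter than window {window} for {element.element_id}"
        )
    if orientation == "-":
        l5, l3 = revcomp(l3), revcomp(l5)
    return l5[:window], l3[-window:]


def stack_group(
    assignments: Iterable[LineageAssignment],
    termini: dict[str, tuple[str, str]],
    genome_of: dict[str, str],
    min_copies: int = 9,
) -> tuple[list[TerminusStack], list[tuple[str, str, int]]]:
    """Group termini by (lineage, genome) and (lineage, pooled).

    Per-genome groups with copy count below ``min_copies`` (i.e. the
    low-copy <=8 rule at the default) are excluded from the per-genome
    output but still contribute to the pooled all-genome stacks.  Returns
    the stacks and a log of excluded (lineage, genome, count) groups.
    """
    per: dict[tuple[str, str], list[tuple[str, str]]] = {}
    pooled: dict[str, list[tuple[str, str]]] = {}
    for a in assignments:
        if a.lineage == "unclassified" or a.element_id not in termini:
            continue
        pair = termini[a.element_id]
        per.setdefault((a.lineage, genome_of[a.element_id]), []).append(pair)
        pooled.setdefault(a.lineage, []).append(pair)

    stacks: list[TerminusStack] = []
    excluded: list[tuple[str, str, int]] = []
    for (lineage, genome), pairs in sorted(per.items()):
        if len(pairs) < min_copies:
            excluded.append((lineage, genome, len(pairs)))
            continue
        stacks.append(
            TerminusStack(FIVE_PRIME, lineage, genome, [p[0] for p in pairs])
        )
        stacks.append(
            TerminusStack(THREE_PRIME, lineage, genome, [p[1] for p in pairs])
        )
    for lineage, pairs in sorted(pooled.items()):
        stacks.append(
            TerminusStack(FIVE_PRIME, lineage, None, [p[0] for p in pairs])
        )
        stacks.append(
            TerminusStack(THREE_PRIME, lineage, None, [p[1] for p in pairs])
        )
    return stacks, excluded


def _stack_codes(stack: TerminusStack) -> np.ndarray:
    arr = np.frombuffer(
        "".join(stack.sequences).encode("ascii"), dtype=np.uint8
    ).reshape(stack.copy_count, -1)
    return _B_LUT[arr]  # 255 for non-ACGT


def base_frequencies(stack: TerminusStack) -> np.ndarray:
    """(L, 4) observed base frequencies; ambiguous bases excluded per
    column; rows with no countable base are NaN."""
    codes = _stack_codes(stack)
    L = codes.shape[1]
    freqs = np.full((L, 4), np.nan)
    for j in range(L):
        col = codes[:, j]
        col = col[col < 4]
        if col.size:
            counts = np.bincount(col, minlength=4).astype(float)
            freqs[j] = counts / counts.sum()
    return freqs


def info_profile(stack: TerminusStack) -> np.ndarray:
    """Per-position information content IC(p) = 2 - H(p) bits.

    No small-sample correction is applied (groups are >= 9 copies by the
    exclusion rule).  Columns with no countable base are NaN.
    """
    if stack.copy_count < 2:
        raise ValueError("information profile needs >= 2 sequences")
    freqs = base_frequencies(stack)
    with np.errstate(divide="ignore", invalid="ignore"):
        logf = np.where(freqs > 0, np.log2(np.where(freqs > 0, freqs, 1)), 0.0)
    H = -np.nansum(freqs * logf, axis=1)
    ic = 2.0 - H
    ic[np.isnan(freqs).all(axis=1)] = np.nan
    return ic


def similarity_curves(
    stack: TerminusStack,
    window: int = 4,
    match: float = 5.0,
    mismatch: float = -4.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """(centered windowed, uncentered windowed, e0) similarity curves.

    The uncentered curve is the PlotCon-style quantity whose zero mark
    separates conserved columns from background (random columns average
    e0 = match*sum(pi^2) + mismatch*(1-sum(pi^2)) < 0 for mismatch-heavy
    matrices); the centered curve subtracts e0 so that 0 is the random
    expectation.
    """
    centered = similarity_profile(stack, window, match, mismatch)
    # recompute e0 from stack composition (same path as in the profile)
    codes = _stack_codes(stack)
    flat = codes[codes < 4]
    if flat.size == 0:
        return centered, centered.copy(), 0.0
    counts = np.bincount(flat, minlength=4).astype(float)
    pi = counts / counts.sum()
    e0 = float(match * np.sum(pi**2) + mismatch * (1 - np.sum(pi**2)))
    return centered, centered + e0, e0


def similarity_profile(
    stack: TerminusStack,
    window: int = 4,
    match: float = 5.0,
    mismatch: float = -4.0,
) -> np.ndarray:
    """Centered, windowed mean pairwise substitution score per position.

    raw(c) is the mean score over all sequence pairs at column c (computed
    from base counts); the centering baseline E0 = match*sum(pi^2) +
    mismatch*(1-sum(pi^2)) uses the stack's overall composition pi, so 0
    is the random expectation.  The curve is the mean of the centered
    values over a ``window``-column window centered at each position,
    truncated at the edges.
    """
    if stack.copy_count < 2:
        raise ValueError("similarity profile needs >= 2 sequences")
    codes = _stack_codes(stack)
    L = codes.shape[1]
    raw = np.full(L, np.nan)
    all_counts = np.zeros(4)
    for j in range(L):
        col = codes[:, j]
        col = col[col < 4]
        n = col.size
        if n < 2:
            continue
        counts = np.bincount(col, minlength=4).astype(float)
        all_counts += counts
        pairs = n * (n - 1) / 2.0
        match_pairs = float(np.sum(counts * (counts - 1) / 2.0))
        raw[j] = (match * match_pairs + mismatch * (pairs - match_pairs)) / pairs
    total = all_counts.sum()
    if total == 0:
        return np.zeros(L)
    pi = all_counts / total
    e0 = match * np.sum(pi**2) + mismatch * (1 - np.sum(pi**2))
    centered = raw - e0

    half_l = (window - 1) // 2
    half_r = window // 2
    out = np.full(L, np.nan)
    for p in range(L):
        lo, hi = max(0, p - half_l), min(L, p + half_r + 1)
        vals = centered[lo:hi]
        vals = vals[~np.isnan(vals)]
        if vals.size:
            out[p] = vals.mean()
    return out


def conservation_profile(
    stack: TerminusStack,
    window: int = 4,
    match: float = 5.0,
    mismatch: float = -4.0,
) -> ConservationProfile:
    centered, plotcon, e0 = similarity_curves(stack, window, match, mismatch)
    return ConservationProfile(
        side=stack.side,
        lineage=stack.lineage,
        genome=stack.genome,
        copy_count=stack.copy_count,
        window=window,
        base_freqs=base_frequencies(stack),
        info_content=info_profile(stack),
        similarity=centered,
        plotcon=plotcon,
        e0=e0,
    )


def consensus(stack: TerminusStack, start: int = 0, end: int | None = None) -> str:
    """Majority base per position over [start, end) of the stack."""
    freqs = base_frequencies(stack)
    end = freqs.shape[0] if end is None else end
    out = []
    for j in range(start, end):
        if np.isnan(freqs[j]).all():
            out.append("N")
        else:
            out.append("ACGT"[int(np.argmax(freqs[j]))])
    return "".join(out)


def profile_to_tsv(profile: ConservationProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "# lineage=%s genome=%s side=%s copies=%d matrix=%s\n"
            % (
                profile.lineage,
                profile.genome or "pooled",
                profile.side,
                profile.copy_count,
                profile.matrix_id,
            )
        )
        fh.write("position\tA\tC\tG\tT\tIC_bits\tsimilarity\n")
        for p in range(profile.length):
            f = profile.base_freqs[p]
            fh.write(
                f"{p + 1}\t{f[0]:.4f}\t{f[1]:.4f}\t{f[2]:.4f}\t{f[3]:.4f}\t"
                f"{profile.info_content[p]:.4f}\t{profile.similarity[p]:.4f}\n"
            )
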