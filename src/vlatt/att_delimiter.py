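"""Delimitation of virus-like attachment (att) sites.

An att site is the maximal segment of above-random similarity anchored at
the LTR boundary (position 1 of the 5' terminus window, or the last
position of the 3' window), tolerating at most two internal "quality
gaps" - runs of at-or-below-zero similarity - each at most two positions
long.  When the conserved segment reaches the far end of the default
40-base window, the analysis is repeated on a 150-base window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .terminus_conservation import (
    ConservationProfile,
    FIVE_PRIME,
    TerminusStack,
    consensus,
)


@dataclass
class AttSite:
    lineage: str
    genome: str | None
    side: str
    start: int  # 1-based inclusive within the terminus window
    end: int
    length: int
    consensus: str
    n_gaps: int
    window_used: int
    truncated: bool = False  # extension wanted but not possible


def _delimit_oriented(
    sim: np.ndarray, max_gaps: int, max_gap_len: int
) -> tuple[int, int] | None:
    """Longest legal prefix segment on an anchored similarity array.

    Returns (last_index_inclusive, n_gaps_crossed) in 0-based anchored
    coordinates, or None when the anchor itself is not above zero.
    NaN positions (no data) terminate the scan like a long gap.
    """
    vals = np.where(np.isnan(sim), -np.inf, sim)
    n = vals.size
    if n == 0:
        raise ValueError("empty similarity profile")
    if vals[0] <= 0:
        return None
    last_good = 0
    gaps = 0
    i = 1
    while i < n:
        if vals[i] > 0:
            last_good = i
            i += 1
            continue
        run = 0
        j = i
        while j < n and vals[j] <= 0:
            run += 1
            j += 1
        if j >= n or run > max_gap_len or gaps + 1 > max_gaps:
            break
        gaps += 1
        i = j
    # gaps counted only if actually crossed (inside the final segment)
    crossed = 0
    run = 0
    for k in range(1, last_good + 1):
        if vals[k] <= 0:
            run += 1
        else:
            if run:
                crossed += 1
            run = 0
    return last_good, crossed


def delimit(
    profile: ConservationProfile,
    side: str | None = None,
    max_gaps: int = 2,
    max_gap_len: int = 2,
    stack: TerminusStack | None = None,
) -> AttSite | None:
    """Delimit the anchored att site on a conservation profile.

    5' sites start at position 1; 3' sites end at the window's last
    position.  Delimitation runs on the PlotCon-scale (uncentered) curve,
    whose 0 mark cleanly separates conserved columns from background.
    Returns None when the anchored boundary position itself is not above
    zero.
    """
    side = side or profile.side
    sim = profile.delimit_curve
    L = sim.size
    if L < 1:
        raise ValueError("profile must have at least one position")
    oriented = sim if side == FIVE_PRIME else sim[::-1]
    res = _delimit_oriented(oriented, max_gaps, max_gap_len)
    if res is None:
        return None
    last, n_gaps = res
    if side == FIVE_PRIME:
        start, end = 1, last + 1
    else:
        start, end = L - last, L
    cons = (
        consensus(stack, start - 1, end) if stack is not None
        else ""
    )
    return AttSite(
        lineage=profile.lineage,
        genome=profile.genome,
        side=side,
        start=start,
        end=end,
        length=end - start + 1,
        consensus=cons,
        n_gaps=n_gaps,
        window_used=L,
    )


def delimit_with_extension(
    profile40: ConservationProfile,
    reextract: Callable[[], tuple[ConservationProfile, TerminusStack] | None],
    max_gaps: int = 2,
    max_gap_len: int = 2,
    stack40: TerminusStack | None = None,
    extended_window: int = 150,
) -> AttSite | None:
    """Apply the 40 -> 150 base extension rule.

    When the site delimited on the 40-base window reaches its far end
    (conservation not terminated inside the window), ``reextract`` is
    called to rebuild the profile at the extended window from the same
    elements; it returns None when too few LTRs are long enough, in which
    case the 40-base site is reported with a truncation flag.
    """
    site = delimit(profile40, max_gaps=max_gaps, max_gap_len=max_gap_len,
                   stack=stack40)
    if site is None:
        return None
    window = profile40.length
    reaches_end = (
        site.end == window if site.side == FIVE_PRIME else site.start == 1
    )
    if not reaches_end:
        return site
    ext = reextract()
    if ext is None:
        site.truncated = True
        return site
    profile150, stack150 = ext
    site150 = delimit(profile150, max_gaps=max_gaps, max_gap_len=max_gap_len,
                      stack=stack150)
    if site150 is None:
        site.truncated = True
        return site
    return site150


def brute_force_delimit(
    sim: np.ndarray, side: str, max_gaps: int = 2, max_gap_len: int = 2
) -> tuple[int, int] | None:
    """Exhaustive reference: the longest legal anchored segment
    (tie: fewest gaps), as (start, end) 1-based, or None.

    Independent of :func:`delimit`; used as the oracle in tests and
    intended only for short profiles.
    """
    vals = np.where(np.isnan(sim), -np.inf, sim)
    L = vals.size
    oriented = vals if side == FIVE_PRIME else vals[::-1]
    best = None  # (length, -gaps, end_index)
    for e in range(L):
        seg = oriented[: e + 1]
        if seg[0] <= 0 or seg[e] <= 0:
            continue
        runs = []
        run = 0
        for v in seg:
            if v <= 0:
                run += 1
            else:
                if run:
                    runs.append(run)
                run = 0
        if any(r > max_gap_len for r in runs) or len(runs) > max_gaps:
            continue
        cand = (e + 1, -len(runs), e)
        if best is None or cand > best:
            best = cand
    if best is None:
        return None
    e = best[2]
    if side == FIVE_PRIME:
        return 1, e + 1
    return L - e, L


def report_pair(five: AttSite | None, three: AttSite | None) -> str:
    """Site-pair descriptor in the "N bp-M bp" convention."""
    a = f"{five.length} bp" if five is not None else "–"
    b = f"{three.length} bp" if three is not None else "–"
    return f"{a}-{b}"


def sites_to_tsv(sites, path) -> None:
    cols = (
        "lineage\tgenome\tside\tstart\tend\tlength\tn_gaps\t"
        "window_used\ttruncated\tconsensus\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for s in sites:
            fh.write(
                f"{s.lineage}\t{s.genome or 'pooled'}\t{s.side}\t{s.start}\t"
                f"{s.end}\t{s.length}\t{s.n_gaps}\t{s.window_used}\t"
                f"{int(s.truncated)}\t{s.consensus}\n"
            )
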