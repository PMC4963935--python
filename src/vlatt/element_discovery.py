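"""Structural discovery of putative complete LTR retrotransposons.

A putative complete element carries two intact, near-identical LTRs.  The
detector works at desk scale in three stages:

1. ``find_candidates`` - exact k-mer seed pairs (default k=20) whose
   separation is compatible with a full-length element, merged into
   diagonal runs;
2. ``refine_pair`` - ungapped X-drop extension of each run to delimit the
   two LTR copies, boundary polish against the canonical TG...CA termini
   and the flanking target-site duplication (TSD), followed by identity
   and length filters;
3. ``discover`` - deduplication of overlapping calls (higher identity,
   then longer, then leftmost wins) and a final coordinate sort.

Only the forward strand is scanned: LTRs are direct repeats, so the pair
structure is strand-symmetric, and element orientation is recovered later
from the reading frame of the reverse-transcriptase hit.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from .io import GenomeRecord

_LUT = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _LUT[b] = i


@dataclass(frozen=True)
class DiscoveryParams:
    min_ltr_len: int = 100
    max_ltr_len: int = 2000
    min_ltr_identity: float = 0.85
    min_element_len: int = 1000
    max_element_len: int = 18000
    seed_kmer: int = 20
    require_tg_ca: bool = True
    require_tsd: bool = True
    tsd_len_range: tuple[int, int] = (4, 6)
    max_kmer_occurrences: int = 100  # skip ultra-repetitive seeds

    def __post_init__(self):
        if self.min_ltr_len > self.max_ltr_len:
            raise ValueError("min_ltr_len > max_ltr_len")
        if self.min_element_len > self.max_element_len:
            raise ValueError("min_element_len > max_element_len")
        if not 0 < self.min_ltr_identity <= 1:
            raise ValueError("min_ltr_identity must be in (0, 1]")


@dataclass
class LTRElement:
    """One putative complete LTR-RT (0-based half-open coordinates)."""

    element_id: str
    genome_id: str
    start: int
    end: int
    ltr5_start: int
    ltr5_end: int
    ltr3_start: int
    ltr3_end: int
    ltr_identity: float
    tsd: str | None = None
    tg_ca: tuple[bool, bool] = (True, True)

    @property
    def ltr5(self) -> tuple[int, int]:
        return (self.ltr5_start, self.ltr5_end)

    @property
    def ltr3(self) -> tuple[int, int]:
        return (self.ltr3_start, self.ltr3_end)

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class Rejection:
    reason: str
    detail: str = ""


@dataclass
class SeedPair:
    """A merged diagonal run of exact k-mer matches.

    ``start1``/``end1`` cover the run on the left copy; the right copy is
    the same interval shifted by ``offset``.
    """

    start1: int
    end1: int
    offset: int


def _encode(seq: str) -> np.ndarray:
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed 2-bit k-mer codes and the positions of valid (N-free) windows."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    valid = codes < 4
    # windows containing any non-ACGT base are dropped
    ok = np.ones(n, dtype=bool)
    bad = np.flatnonzero(~valid)
    for b in bad:
        lo = max(0, b - k + 1)
        ok[lo: b + 1] = False
    packed = np.zeros(n, dtype=np.uint64)
    c = codes.astype(np.uint64)
    for j in range(k):
        packed = (packed << np.uint64(2)) | c[j: j + n]
    pos = np.flatnonzero(ok)
    return packed[pos], pos


def find_candidates(
    genome: GenomeRecord, params: DiscoveryParams = DiscoveryParams()
) -> list[SeedPair]:
    """Exact k-mer seed pairs at element-compatible separations, merged
    into diagonal runs and reported in ascending coordinate order."""
    k = params.seed_kmer
    seq = genome.seq
    if len(seq) < k:
        return []
    codes = _encode(seq)
    kmers, pos = _kmer_codes(codes, k)
    if kmers.size == 0:
        return []
    order = np.argsort(kmers, kind="stable")
    kmers_s, pos_s = kmers[order], pos[order]
    boundaries = np.flatnonzero(np.diff(kmers_s)) + 1
    groups = np.split(pos_s, boundaries)

    min_sep = max(params.min_element_len - params.max_ltr_len, 1)
    max_sep = params.max_element_len
    pairs: list[tuple[int, int]] = []  # (p1, offset)
    for g in groups:
        m = g.size
        if m < 2 or m > params.max_kmer_occurrences:
            continue
        g = np.sort(g)
        for i in range(m - 1):
            for j in range(i + 1, m):
                sep = int(g[j] - g[i])
                if sep > max_sep:
                    break
                if sep >= min_sep:
                    pairs.append((int(g[i]), sep))
    if not pairs:
        return []
    pairs.sort(key=lambda t: (t[1], t[0]))  # by diagonal, then position
    merged: list[SeedPair] = []
    cur_off, cur_s, cur_e = pairs[0][1], pairs[0][0], pairs[0][0] + k
    for p1, off in pairs[1:]:
        if off == cur_off and p1 <= cur_e:
            cur_e = max(cur_e, p1 + k)
        else:
            merged.append(SeedPair(cur_s, cur_e, cur_off))
            cur_off, cur_s, cur_e = off, p1, p1 + k
    merged.append(SeedPair(cur_s, cur_e, cur_off))
    merged.sort(key=lambda s: (s.start1, s.offset))
    return merged


def _xdrop_extend(
    eq: np.ndarray, start: int, end: int, xdrop: float = 15.0,
    match: float = 1.0, mismatch: float = -2.0, cap: int = 2200,
) -> tuple[int, int]:
    """Extend [start, end) along a precomputed agreement vector.

    Returns the maximal-scoring ungapped extension bounds, each side capped
    at ``cap`` positions.
    """
    # right
    best, score, right = 0.0, 0.0, end
    i = end
    stop = min(len(eq), end + cap)
    while i < stop:
        score += match if eq[i] else mismatch
        if score > best:
            best, right = score, i + 1
        elif best - score > xdrop:
            break
        i += 1
    # left
    best, score, left = 0.0, 0.0, start
    i = start - 1
    stop = max(0, start - cap)
    while i >= stop:
        score += match if eq[i] else mismatch
        if score > best:
            best, left = score, i
        elif best - score > xdrop:
            break
        i -= 1
    return left, right


def _dinuc_hits(codes: np.ndarray, pos: int, dinuc: tuple[int, int]) -> int:
    if pos < 0 or pos + 1 >= len(codes):
        return 0
    return int(codes[pos] == dinuc[0]) + int(codes[pos + 1] == dinuc[1])


_TG = (_LUT[ord("T")], _LUT[ord("G")])
_CA = (_LUT[ord("C")], _LUT[ord("A")])


def _find_tsd(
    codes: np.ndarray, s: int, e: int, lens: tuple[int, int]
) -> str | None:
    """Longest identical 4-6-mer immediately flanking [s, e)."""
    for d in range(lens[1], lens[0] - 1, -1):
        if s - d < 0 or e + d > len(codes):
            continue
        a = codes[s - d: s]
        b = codes[e: e + d]
        if np.all(a == b) and np.all(a < 4):
            return "".join("ACGT"[c] for c in a)
    return None


def refine_pair(
    genome: GenomeRecord,
    seed_pair: SeedPair,
    params: DiscoveryParams = DiscoveryParams(),
    _codes: np.ndarray | None = None,
) -> LTRElement | Rejection:
    """Extend a seed run into a full element call or a tagged rejection."""
    codes = _codes if _codes is not None else _encode(genome.seq)
    off = seed_pair.offset
    n = len(codes)
    if seed_pair.end1 + off > n:
        return Rejection("bounds")
    lim = n - off
    cap = params.max_ltr_len + 200
    # agreement vector only around the seed: extension cannot leave it
    wlo = max(0, seed_pair.start1 - cap)
    whi = min(lim, seed_pair.end1 + cap)
    eq_local = codes[wlo:whi] == codes[wlo + off: whi + off]
    eq_local &= codes[wlo:whi] < 4
    left, right = _xdrop_extend(
        eq_local, seed_pair.start1 - wlo, seed_pair.end1 - wlo, cap=cap,
    )
    left += wlo
    right += wlo
    if right - left < 2:
        return Rejection("extension")
    # overlap of the two repeat copies -> not a clean LTR pair
    if right > left + off:
        return Rejection("overlap")

    # Boundary polish: joint choice of (start, end) near the X-drop limits.
    # The TSD pins both boundaries at once (identical flanking 4-6-mer), so
    # it outweighs the four TG/CA dinucleotide checks; ties fall back to
    # the X-drop bounds.
    win = 8
    s_lo, s_hi = max(0, left - win), min(left + win, right - 2)
    e_lo, e_hi = max(s_lo + 2, right - win), min(lim, right + win)
    best = None
    for s in range(s_lo, s_hi + 1):
        tg = _dinuc_hits(codes, s, _TG) + _dinuc_hits(codes, s + off, _TG)
        for e in range(e_lo, e_hi + 1):
            ca = _dinuc_hits(codes, e - 2, _CA) + _dinuc_hits(
                codes, e - 2 + off, _CA
            )
            tsd_here = _find_tsd(codes, s, e + off, params.tsd_len_range)
            score = (
                (6 if tsd_here else 0)
                + tg
                + ca
                - 0.01 * (abs(s - left) + abs(e - right))
            )
            if best is None or score > best[0]:
                best = (score, s, e, tsd_here)
    _, s, e, tsd = best
    ltr_len = e - s
    if ltr_len < params.min_ltr_len:
        return Rejection("ltr_len", f"{ltr_len} < {params.min_ltr_len}")
    if ltr_len > params.max_ltr_len:
        return Rejection("ltr_len", f"{ltr_len} > {params.max_ltr_len}")
    el_start, el_end = s, e + off
    el_len = el_end - el_start
    if not params.min_element_len <= el_len <= params.max_element_len:
        return Rejection("element_len", str(el_len))

    ltr5_seq = genome.seq[s:e]
    ltr3_seq = genome.seq[s + off: e + off]
    res = edlib.align(ltr5_seq, ltr3_seq, task="distance")
    dist = res["editDistance"]
    identity = 1.0 - dist / max(len(ltr5_seq), len(ltr3_seq))
    if identity < params.min_ltr_identity:
        return Rejection("identity", f"{identity:.3f}")

    tg5 = _dinuc_hits(codes, s, _TG)
    tg3 = _dinuc_hits(codes, s + off, _TG)
    ca5 = _dinuc_hits(codes, e - 2, _CA)
    ca3 = _dinuc_hits(codes, e - 2 + off, _CA)
    mismatches = 8 - (tg5 + tg3 + ca5 + ca3)
    if params.require_tg_ca and mismatches > 1:
        return Rejection("tg_ca", f"{mismatches} mismatches")

    if params.require_tsd and tsd is None:
        return Rejection("tsd")

    return LTRElement(
        element_id="",
        genome_id=genome.id,
        start=el_start,
        end=el_end,
        ltr5_start=s,
        ltr5_end=e,
        ltr3_start=s + off,
        ltr3_end=e + off,
        ltr_identity=identity,
        tsd=tsd,
        tg_ca=(tg5 + ca5 == 4, tg3 + ca3 == 4),
    )


def discover(
    genome: GenomeRecord,
    params: DiscoveryParams = DiscoveryParams(),
) -> list[LTRElement]:
    """Full per-genome discovery: seeds, refinement, deduplication."""
    codes = _encode(genome.seq) if genome.seq else np.empty(0, dtype=np.uint8)
    candidates = find_candidates(genome, params)
    calls: list[LTRElement] = []
    for sp in candidates:
        result = refine_pair(genome, sp, params, _codes=codes)
        if isinstance(result, LTRElement):
            calls.append(result)
    calls.sort(key=lambda e: (-e.ltr_identity, -e.span, e.start))
    kept: list[LTRElement] = []
    for el in calls:
        dup = False
        for other in kept:
            ov = min(el.end, other.end) - max(el.start, other.start)
            if ov > 0 and ov > 0.5 * min(el.span, other.span):
                dup = True
                break
        if not dup:
            kept.append(el)
    kept.sort(key=lambda e: e.start)
    for i, el in enumerate(kept, 1):
        el.element_id = f"{genome.id}_ltr{i:04d}"
    return kept
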