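# Methods

This note documents the models and procedures implemented in `vlatt`, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Element model and synthetic genomes

A putative complete LTR retrotransposon is modelled as

```
TSD — LTR(5′) — internal region — LTR(3′) — TSD
```

with a 4–6 nt target-site duplication (TSD) flanking the element, both
LTRs beginning `TG` and ending `CA`, and the internal region carrying a
lineage-specific reverse-transcriptase (RT) coding sequence.  The two LTRs
of one element are near-identical because they derive from a single
template at insertion time; after per-site substitution at rate *r* their
expected pairwise identity is (1−r)² + r²/3 per site (≈ 0.96 at r = 0.02).

The generator (`synthetic_genome`) emulates exactly this anatomy.  Per
lineage it holds a `LineageModel`: an LTR template (default 400 nt), att
motifs that are a prefix/suffix of that template (default lengths follow
the att-site lengths observed per lineage in plant genomes, e.g. Ale 7–6,
Bianca 13–13, Del 10–11, Angela 18–10), and an RT consensus peptide
(default 80 aa, random per lineage; pairwise identity between lineages
≈ 5%, far below the 40% ceiling needed for unambiguous classification).

Two divergence knobs control realism:

* `rate` — per-site substitution applied independently to each LTR copy,
  to the internal region, and (relative to the lineage consensus) to the
  att motifs.  Default 0.02, the study condition for all recovery
  benchmarks.
* `interior_divergence` — per-copy randomization of the LTR *interior*
  between the att motifs, default 0.75 (uniform substitution, which makes
  interiors statistically indistinguishable from random across copies:
  pairwise agreement 0.25).  Real insertions of a lineage are separated by
  millions of years, so outside the constrained terminal motifs their LTR
  sequences are effectively unrelated; without this knob every copy would
  descend visibly from one template and the whole 40-base terminus would
  look conserved, making att delimitation degenerate.  Within one element
  the two LTRs still match (they share the per-copy interior), so
  structural discovery is unaffected.  Setting it to 0 reproduces the
  textbook case where every LTR equals the template at rate 0.

Insertion points are uniform over the background; because insertion
expands the sequence, planted elements can never overlap.  Capacity is
bounded by requiring the background to be at least as long as the summed
element lengths.  Nested insertions, solo LTRs, recombination and decay
are deliberately out of scope.  Ground truth (exact coordinates, lineage,
TSD) is emitted as GFF3 (1-based inclusive) and TSV.

What passing tests on these genomes does *not* show: robustness to
indels (the mutation model is substitution-only), to nested or decayed
copies, or to the repeat landscape of real assemblies; boundary accuracy
on real data will be worse than the ≤ 5 nt measured here.

## Element discovery

Three stages (`element_discovery`):

1. **Seeding** — exact 20-mer matches (2-bit packed, vectorized) whose
   separation lies in [min_element − max_ltr, max_element] =
   [−1000 → 1, 18000] nt; k-mers touching non-ACGT bases never seed;
   k-mer values occurring > 100 times are skipped (repeat shielding).
   Matches on one diagonal merge into a single seed run.
2. **Refinement** — ungapped X-drop extension (match +1, mismatch −2,
   drop 15) of the agreement vector along the seed diagonal, computed
   only in a window around the seed.  Boundaries are then polished
   *jointly*: over a ±8 nt neighbourhood of the X-drop limits, the
   (start, end) pair maximizes a score of TSD presence (+6; the identical
   flanking 4–6-mer pins both boundaries at once) plus the eight TG/CA
   dinucleotide matches, with a small tie-break toward the X-drop bounds.
   Filters: LTR length in [100, 2000]; element length in [1000, 18000];
   LTR identity (edlib edit distance over the longer LTR) ≥ 0.85; at most
   one mismatch among the eight TG/CA bases; TSD required.  A failed
   criterion produces a tagged rejection.
3. **Deduplication** — calls sharing > 50% of the shorter span keep only
   the higher-identity (then longer, then leftmost) one; output sorted.

The TG/CA rule tolerates one mismatch because at 2% divergence the
probability that all eight terminal bases are intact is only 0.98⁸ ≈ 0.85;
one tolerated mismatch raises the ceiling to ≈ 0.99 while random sequence
still fails the joint TSD+terminus+length requirements (measured false
positives: 0 calls in 10 Mb of background).

Only the forward strand is scanned: LTR pairs are direct repeats, so the
pairing is strand-symmetric; element orientation is recovered from the
reading frame of the RT hit.

## Lineage classification

The internal region is conceptually translated in all six frames
(frames 1–3 forward, 4–6 reverse-complement; partial codons dropped,
stops kept as `*`, ambiguous codons as `X`).  Each lineage has a
position-specific scoring matrix built from an RT alignment: columns with
> 50% gaps dropped, add-one pseudocounts, log₂-odds against the
background.  A hit is the best ungapped full-width placement of the
profile on a frame (non-standard symbols score 0).

Scores convert to e-values through a Gumbel (extreme-value) tail fitted,
at build time with a fixed seed, to the best-window scores of 10,000
i.i.d. background decoy peptides of length 500; the e-value scales with
the number of residues actually scanned.  This reproduces profile-search
semantics (best hit under a 1e−10 cut-off) with a transparent scorer; it
is an approximation to a full profile HMM (no gaps in the profile
alignment), which is sufficient at the RT domain's conservation level —
true hits score hundreds of bits above the decoy distribution.  Best hit
wins; ties break by higher score, then lexicographic lineage name.
Classification is orientation-invariant up to the reported frame.

## Terminus conservation

For every classified element the first 40 bases of the 5′ LTR and the
last 40 of the 3′ LTR are extracted on the element's coding orientation.
Stacks are grouped by (lineage, genome) and (lineage, pooled); per-genome
groups with ≤ 8 copies are excluded (logged) but still pool.  Because the
sequences share a biological anchor point (the LTR boundary), stacks are
ungapped and columnar — no alignment step is needed.

Two per-position curves:

* **Information content** IC(p) = 2 − H(p) bits from the observed base
  frequencies; `N` excluded per column; no small-sample correction
  (copy counts are ≥ 9 by the exclusion rule).
* **Similarity** — the mean pairwise substitution score per column
  (match +5, mismatch −4, an EDNAFULL-style DNA matrix), smoothed over a
  4-column window (truncated at the edges).  Two scales are kept:
  * the *uncentered* (PlotCon-scale) curve, whose zero mark separates
    conservation from background — random columns average
    E0 = 5·Σπᵢ² − 4·(1−Σπᵢ²) ≈ −1.75 at uniform composition;
  * the *centered* curve (minus E0), for which 0 is the random
    expectation and identical uniform-composition stacks score exactly
    6.75.

Window size and matrix are configurable; the defaults (window 4,
+5/−4) follow common DNA plotting practice and are surfaced in the
pipeline config.

## Att-site delimitation

An att site is the maximal segment anchored at the LTR boundary
(position 1 for 5′ sites, the last window position for 3′ sites) along
which the similarity stays above zero, tolerating at most **two**
internal quality-gaps (runs of at-or-below-zero positions) of at most
**two** positions each; the site ends at the last above-zero position
before a disqualifying run.  Delimitation runs on the *uncentered*
PlotCon-scale curve: with the centered curve the threshold would sit at
the random expectation, where the windowed curve coin-flips and sites
systematically overrun the motif (measured: recovery of planted lengths
drops from 100% to 41%).  A greedy scan implements the rule; an
independent exhaustive enumerator over all legal anchored segments
(longest, tie: fewest gaps) is kept as the test oracle, and the two agree
on all sign patterns up to length 12 and on random profiles up to
length 20.

When the delimited site reaches the far end of the 40-base window, the
termini are re-extracted at 150 bases from the same elements and
delimitation reruns there (`window_used` records which window produced
the site).  Elements whose LTRs are shorter than 150 nt drop out of the
extended stack; if fewer than 9 remain the extension is abandoned and the
40-base site carries a truncation flag.  Unanchored interior segments are
never reported as att sites.  Site pairs print in the
"N bp-M bp" convention (5′ length first; "–" for an absent side).

## Abundance matrices and barcodes

Counts of classified elements per (genome, lineage) form the abundance
matrix (fixed lineage order: the six Copia then the five Gypsy lineages);
unclassified elements are counted separately and excluded from totals.
Normalization is 100 × count / genome total, rounded half-up to one
decimal (raw fractions kept alongside); a zero-total genome yields a row
of missing values rather than a division error.  Superfamily totals and
the Gypsy/Copia ratio are reported rounded and raw.

The per-genome signature is the canonical string
`<genome>|Ale:<v>;…;Reina:<v>` (fixed order, one decimal), chosen to be
human-readable and scanner-decodable; it is byte-stable, so identical
normalized rows give identical symbols.  The QR codec (model 2, byte
mode, error-correction level M, versions 1–20, mask chosen by the
standard penalty rules, Reed–Solomon over GF(256)) is implemented
in-package with both an encoder and a decoder, so the round-trip
`decode(encode(s)) == s` is verified for every emitted signature, and
moderate module damage within one RS block is corrected.

## Reference dataset

`vlatt.reference_data` bundles the published genome × lineage copy-number
table for ten angiosperm assemblies (five eudicots, five monocots;
28,622 putative complete elements).  The table was reconstructed cell by
cell against the published normalized percentages and every printed
margin; all constraints are satisfied simultaneously.  One printed row
total (O. sativa, "1402") is inconsistent with its own cells and the
printed monocot and per-lineage totals, which require 1,404; 1,404 is
used.

## Benchmark sizes and numerical choices

* Discovery/classification benchmark: 5 Mb background + 220 elements
  (11 lineages × 20 copies) at 2% divergence; false positives measured
  on 10 Mb of pure background.  Att benchmark: 2.5 Mb background,
  20 copies per lineage, planted att lengths cycling 5/7/10/13 nt on
  both sides; extension benchmark: one lineage with a 60 nt 5′ motif.
  These sizes exercise every code path at full elements counts while
  keeping a complete run in minutes on one core.
* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; identical inputs give byte-identical genomes, truth, outputs.
* Rounding of percentages is half-up via `decimal`; floating-point
  comparisons in delimitation use strict `> 0` with NaN (no-data)
  positions treated as terminating gaps.
* Tie-breaks: overlapping discovery calls — identity, then span, then
  leftmost; classification — e-value, then score, then lineage name.

## Known limitations

* Substitution-only divergence model; no indels, nesting, or solo LTRs.
* Ungapped profile scoring; a gapped RT alignment with indel-rich real
  elements would need a full profile HMM.
* The discovery stage assumes LTR pairs lie on one diagonal (no indels
  between the two copies); real diverged elements violate this.
* Per-sequence reading of the quality-gap rule (as opposed to the
  profile-level reading implemented here) is noted but not implemented.
* QR decoding expects an upright, unskewed module matrix (it is a codec,
  not an image scanner).
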