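# Methods

## Model

`lmnast` treats a genomic neighborhood as a string of gene-level
symbols. The query is an ordered list of *n* elements ("characters")
with strands expressed relative to the first element. A character is
present at a locus of a subject replicon whenever a BLAST hit for that
element scores below the E-value threshold there; the search itself
never looks at sequence, only at the coordinates, strands and
annotation of those character occurrences. A hit's score is the base
*n* minus the frank mutations needed to derive the observed arrangement
from the query:

- **deletions** — one unit per absent query character (realized as
  `n − m` for `m` matched characters);
- **insertions** — per maximal run of `g ≥ 1` intervening annotated
  genes between consecutive matched characters, an affine penalty
  `gap_open + gap_extend · (g − 1)`. Gap length is counted in *genes*,
  not base pairs: the disruption an insertion causes to an operon is
  better proxied by how many transcription units interpose than by raw
  distance. Genes carrying a nonscoring synonym of a query character do
  not count as insertions;
- **rearrangements** — query indices of the matched characters are
  compressed to ranks `1..m` (so deletions and insertions do not
  inflate order penalties); reading the candidate in whichever genomic
  direction gives fewer breakpoints, every genomically adjacent matched
  pair whose rank difference is not `+1` costs the rearrangement
  penalty. Choosing the reading direction per candidate means a wholly
  inverted system scores as co-linear, which is the biologically
  sensible reading of an inversion spanning the entire system;
- **redirections** — evaluated only over characters that participate in
  at least one rank-adjacent (order-maintained) pair. The count is the
  minimal number of strand flips needed to reconcile those characters
  with the query's relative-strand pattern, i.e. the mismatch count
  minimized over the two global orientations. This makes one physically
  flipped gene cost exactly one unit wherever it sits, and leaves a
  fully order-scrambled candidate with no direction penalty at all
  (direction is undefined where order is not maintained). Where order
  is partially maintained, only the ordered characters are judged.

Assumptions: annotation-bearing records (the gap unit needs gene
calls); no intra-hit duplication of a character (where a window offers
two copies, the alternatives are enumerated and at most one survives);
hits never span record boundaries.

## Parameters

| parameter | default | unit | notes |
|---|---|---|---|
| `evalue_threshold` | 0.1 | — | character membership filter; strict `<` |
| `gap_open` / `gap_extend` | 2 / 1 (stringent), 1 / 0.3 (weak) | score units per gene | weak values concede longer-range interactions |
| `rearrangement_penalty` | 1 | per breakpoint | the "standard deduction" |
| `direction_penalty` | 1 | per flipped character | idem |
| `max_join_distance` d | 5000 | bp | seed/join proximity bound; spans typical intergenic distances plus small insertions without bridging unrelated loci |
| `min_seed_characters` | 2 | characters | two homologs are the natural minimum arrangement |
| `min_retained_score` | 0 | score units | exclusive: hits must score > 0 |
| GC window / step | 200 / 50 | bp | resolves sub-gene-scale dips while keeping per-window binomial noise ≈ 0.035 |

Deletion cost is fixed at 1 per absent character. With queries of 4–8
elements this keeps `score > 0` attainable for the two-character
minimal hits that the retention rule is meant to admit.

## Criteria modes

*Stringent* assumes accurate annotation: a character occurrence must
have ≥ 80% of its interval inside a non-pseudo gene/CDS feature (the
80% tolerates translated-search hits slightly overhanging gene
boundaries), and each feature carries at most one character — conflicts
resolve by bit score, then E-value, then input order. *Weak* admits
intergenic occurrences, pseudogenes, and several characters per
feature, and uses the reduced gap penalties. Weak output is a superset
of stringent output on identical input by construction. In both modes,
overlapping same-character occurrences (> 50% of the smaller interval)
are merged keeping the best bit score, so alternative HSPs of one
element cannot masquerade as tandem copies.

## Trimming and tie-breaks

Candidates with ≤ 12 occurrences are maximized exactly over all
label-distinct subsets of size ≥ 2 (at most 2^12 evaluations, instant);
larger candidates fall back to greedy single-element drops that stop
when no drop strictly improves the score, after duplicates are resolved
to the best-bit copy. Ties prefer (1) more characters, (2) higher mean
element homology — or mean raw bit score when per-file statistics are
unavailable, a monotone proxy — and (3) the leftmost start.
Reconciliation across searches keeps, among interval-overlapping hits
on one record, the highest score, then higher meH, then more
characters.

Degenerate cases: a character whose BLAST file shows a single bit score
(max = min) contributes 1.0 to meH, reading self-identity as exact
likeness; a GC window of only ambiguous bases yields NaN and is ignored
by the dip statistic; origin-wrapping ("join") features on circular
records are parsed but excluded from search windows, since their
coordinates are not a single interval.

## Synthetic fixtures

The generator plants a realized copy of the query cassette (default
gene length 900 bp, spacers 120–240 bp — inside the join distance) into
a background replicon of i.i.d.-base genes at a target GC, then applies
declared edits in order, emitting GenBank records, per-character BLAST
tabular files (planted rows below threshold at the file maximum bit;
decoy rows above threshold anchoring the minimum), and a truth ledger
whose expected scores come from an exhaustive symbolic maximizer over
the post-edit cassette.

Two edit classes are constrained so that a single planted edit has an
unambiguous signature in the recovered penalty breakdown:

- a **transposition** relocates a gene to an interior position chosen
  so that no single end-character drop restores query order — a gene
  moved to the arrangement boundary is correctly, and irrecoverably,
  re-read by the trimmer as a deletion (the clean `m − 1` reading
  outscores the breakpoint reading);
- an **insertion** for recovery studies is planted between the two
  middle characters, because a gap abutting the arrangement end is
  likewise re-read as loss of the end character once the gap penalty
  exceeds 1.

These are properties of the scoring heuristic itself, not of the
generator: maximal-score trimming genuinely cannot distinguish those
boundary cases, so the recovery experiment measures the classifiable
interior events.

What the generator does *not* emulate: substitution-level sequence
evolution (bit scores follow a simple monotone divergence model),
alignment length/identity structure of real tabular rows, multi-contig
assemblies, and annotation errors other than the pseudo flag. Passing
tests therefore demonstrate the correctness of the arrangement
machinery on faithfully annotated records, not robustness to real-world
annotation noise.

## Problem sizes

The shipped studies use 30-gene background replicons (~30 kb), 4-to-6
character queries, 200 random candidates for the trim-vs-brute-force
comparison, 100 single-edit fixtures for recovery, and 6.2 kb sequences
for GC-dip detection; these sizes give stable statistics while keeping
the whole suite interactive.

## Known limitations

- Scores have no probabilistic calibration (no E-value analogue for
  arrangements); they are edit counts, comparable only within a query.
- Gap counting trusts gene calls; records annotating only CDS fall back
  to CDS features, and unannotated insertions are invisible.
- Greedy trimming above 12 occurrences can in principle lodge in a
  local maximum; the exact path is compared against brute force in the
  test suite, the greedy path only on its drop-by-drop contract.
- Hits are confined to single records; split-contig systems are not
  stitched.
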