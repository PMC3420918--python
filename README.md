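# lmnast

A local similarity search over **gene order and arrangement**. Given an
ordered query of gene elements (for example the four genes of a small
regulated operon), per-element homology hit lists (BLAST tabular), and
annotated replicons (GenBank flat files), `lmnast` finds, scores, and
analyzes homologous genomic arrangements — orthologous operons,
truncated or rearranged variants, divergently split systems, and
candidate horizontal-transfer events.

It is aimed at comparative genomicists studying the conservation of
small modular gene systems (operons, signaling cassettes, transporter
clusters) across prokaryotic genomes.

## The method

Each query element is a **character**. Any BLAST hit for that element
with E-value below a threshold (default 0.1) makes the character present
at that genomic locus. The search then works like a seed-and-extend
heuristic over gene order:

1. **Assign** characters to loci under *weak* or *stringent* annotation
   criteria (stringent requires each character to lie within a
   non-pseudo annotated gene, one character per gene; weak admits
   intergenic hits, pseudogenes, and shared annotations).
2. **Seed** on runs of distinct characters closer than a join distance
   *d* (default 5000 bp).
3. **Join** proximal characters and seeds into candidate windows by
   transitive closure of the <*d* relation.
4. **Score** each candidate arrangement against the query. For a query
   of *n* elements with *m* matched:

   ```
   score = n − (n − m)                        # deletions
             − Σ_runs [open + ext·(g − 1)]    # affine insertion gaps,
                                              #   g intervening genes
             − R · order_breakpoints          # rearrangements
             − D · direction_flips            # redirections
   ```

   Gap penalties (open, ext) are 1, 0.3 under weak criteria and 2, 1
   under stringent; R = D = 1. Order is evaluated on compressed query
   ranks (disregarding insertions and deletions), reading the candidate
   in whichever direction scores better; direction is evaluated only
   where order is maintained, as the minimal number of strand flips
   against the query's relative-strand pattern. Intra-hit gene
   duplications are disallowed.
5. **Trim** non-contiguous elements until the score is maximal (exact
   subset maximization up to 12 occurrences, greedy beyond); ties favor
   more characters, then higher mean element homology. Hits scoring
   above zero with ≥ 2 characters are retained, and overlapping hits
   within a record are reconciled to the highest-scoring one.

Around the search sit the ancillary analytics: **meH** (mean element
homology — per-character bit scores min-max normalized over each
character's whole BLAST result, averaged over the hit), **organizational
homology** (score / n), coincidence matrices with theoretical baselines
and difference maps, 2D similarity coordinates, per-hit trackback
series, extended-window queries, nonscoring annotation synonyms, and
sliding-window GC profiles with a dip statistic.

A first-class synthetic fixture generator (`lmnast.synth`) plants a
query arrangement into simulated replicons under a controlled edit
model (deletion, insertion, inversion, transposition, divergent split,
GC shift, pseudogenization, synonym decoys) with a ground-truth ledger,
so the whole pipeline is testable without any sequence database.

## Worked example

```sh
# synthesize a two-record fixture: one intact system, one with a
# pseudogenized third element
cat > edits.yaml <<EOF
query:
  labels: [geneA, geneB, geneC, geneD]
records:
  - edits: []
  - edits: [{kind: pseudogenize_char, target: geneC}]
EOF
lmnast synth --seed 3 --n-records 2 --edits edits.yaml --out fix/
lmnast search --query fix/query.json --records fix/records \
              --blast fix/blast --criteria stringent --out run/
```

The search logs one line per record and writes `hits.tsv`, `hits.json`,
`hits.bed` and `run_config.yaml`:

```
INFO record=SYN0003_000 candidates=1 hits=1
INFO record=SYN0003_001 candidates=1 hits=1
INFO records=2 hits=2
```

`run/hits.tsv` (columns abridged):

```
accession    score  base  deletions  gap_penalty_total  meH  characters
SYN0003_000  4.0    4     0          0.0                1    geneA,geneB,geneC,geneD
SYN0003_001  2.0    4     2          0.0                1    geneA,geneB
```

The intact record returns a perfect hit: score 4 of base 4, so
organizational homology 1.0, and meH 1.0 because every element sits at
its file's maximum bit score. On the edited record the stringent search
cannot use the pseudogenized `geneC`; keeping `geneD` would cost a
deletion plus an affine gap of 2 through the now-intervening pseudogene
(score 1), so trimming instead keeps the clean `geneA,geneB` pair with
two deletions (score 2). The same search under `--criteria weak`
accepts the pseudogene and scores 4 on both records.

From the hits, `lmnast report similarity|coincidence|trackback` exports
the 2D similarity coordinates, coincidence matrices, and per-hit
trackback series as TSV (and rendered PNG).

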