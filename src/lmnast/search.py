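"""The arrangement-search heuristic: seeds, joining, scoring, trimming.

The similarity of a putative arrangement to the query is the number of
frank mutations — deletions, insertions, rearrangements, redirections —
needed to produce it from the query:

* base score = query length ``n``;
* each absent query character deducts 1 (deletion);
* each maximal run of ``g`` intervening annotated genes between
  consecutive matched characters deducts ``gap_open +
  gap_extend * (g - 1)`` (affine insertion penalty, measured in genes);
* each order breakpoint — a genomically adjacent pair of matched
  characters whose compressed query ranks are not consecutive, reading
  the hit in whichever direction scores better — deducts
  ``rearrangement_penalty``;
* each redirected character deducts ``direction_penalty``; redirection
  is evaluated only where relative order is maintained (rank-adjacent
  pairs), and counted as the minimal number of strand flips relative to
  the query's relative-strand pattern under the better of the two global
  orientations.

Candidates are trimmed by dropping non-contiguous elements until the
score is maximal; ties favor the version with the most characters, then
higher mean element homology, then the leftmost hit. Hits scoring above
zero (configurable) with at least two characters are retained.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .assign import (
    AssignParams,
    CharacterOccurrence,
    assign_characters,
    filter_hits,
    tag_synonyms,
)
from .iolib import ElementHit, QuerySpec, QueryElement, Replicon
from .metrics import BlastStats, mean_element_homology

#: candidates at or below this many occurrences are trimmed by exact
#: exhaustive subset maximization; larger ones fall back to greedy
#: iterative dropping
EXACT_TRIM_LIMIT = 12


@dataclass
class ScoringParams:
    """Penalty and window parameters for arrangement scoring.

    Defaults are the stringent-criteria penalties (gap open 2, extension
    1); :meth:`weak` gives the relaxed set (1 and 0.3) used when longer
    range interactions are entertained.
    """

    gap_open: float = 2.0
    gap_extend: float = 1.0
    rearrangement_penalty: float = 1.0
    direction_penalty: float = 1.0
    max_join_distance: int = 5000
    min_seed_characters: int = 2
    min_retained_score: float = 0.0  # exclusive

    def __post_init__(self) -> None:
        for name in ("gap_open", "gap_extend", "rearrangement_penalty",
                     "direction_penalty"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.max_join_distance <= 0:
            raise ValueError("max_join_distance must be > 0")

    @classmethod
    def stringent(cls, **kw) -> "ScoringParams":
        return cls(gap_open=2.0, gap_extend=1.0, **kw)

    @classmethod
    def weak(cls, **kw) -> "ScoringParams":
        return cls(gap_open=1.0, gap_extend=0.3, **kw)


@dataclass(frozen=True)
class ScoreBreakdown:
    """Penalty decomposition of one scored arrangement."""

    base: int
    deletions: int
    gap_penalty_total: float
    order_breakpoints: int
    direction_flips: int
    score: float
    orientation: str = "forward"  # reading direction that scored better
    gap_runs: tuple[int, ...] = ()  # intervening-gene count per adjacent pair
    flipped_characters: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "base": self.base,
            "deletions": self.deletions,
            "gap_penalty_total": self.gap_penalty_total,
            "order_breakpoints": self.order_breakpoints,
            "direction_flips": self.direction_flips,
            "score": self.score,
            "orientation": self.orientation,
            "gap_runs": list(self.gap_runs),
            "flipped_characters": list(self.flipped_characters),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreBreakdown":
        return cls(
            base=d["base"],
            deletions=d["deletions"],
            gap_penalty_total=d["gap_penalty_total"],
            order_breakpoints=d["order_breakpoints"],
            direction_flips=d["direction_flips"],
            score=d["score"],
            orientation=d.get("orientation", "forward"),
            gap_runs=tuple(d.get("gap_runs", ())),
            flipped_characters=tuple(d.get("flipped_characters", ())),
        )


@dataclass(frozen=True)
class Seed:
    """A proximal run of character occurrences dense enough to extend."""

    occurrences: tuple[CharacterOccurrence, ...]

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(o.character for o in self.occurrences)

    @property
    def start(self) -> int:
        return self.occurrences[0].start

    @property
    def end(self) -> int:
        return self.occurrences[-1].end


def _occ_to_dict(o: CharacterOccurrence) -> dict:
    return {
        "character": o.character,
        "start": o.start,
        "end": o.end,
        "strand": o.strand,
        "bit_score": o.bit_score,
        "evalue": o.evalue,
        "anchored_feature": o.anchored_feature,
        "nonscoring": o.nonscoring,
        "annotation_text": o.annotation_text,
    }


@dataclass(frozen=True)
class LmnastHit:
    """A trimmed, scored arrangement homolog on one nucleotide record."""

    accession: str
    occurrences: tuple[CharacterOccurrence, ...]  # genomic order, scoring
    breakdown: ScoreBreakdown
    organizational_homology: float
    meH: Optional[float] = None
    nonscoring: tuple[CharacterOccurrence, ...] = ()

    def __post_init__(self) -> None:
        labels = [o.character for o in self.occurrences]
        if len(labels) < 2:
            raise ValueError("a hit needs at least two scoring characters")
        if len(set(labels)) != len(labels):
            raise ValueError("intra-hit gene duplications are disallowed")

    @property
    def orientation(self) -> str:
        return self.breakdown.orientation

    @property
    def score(self) -> float:
        return self.breakdown.score

    @property
    def characters(self) -> list[str]:
        return [o.character for o in self.occurrences]

    @property
    def start(self) -> int:
        return min(o.start for o in self.occurrences)

    @property
    def end(self) -> int:
        return max(o.end for o in self.occurrences)

    def to_dict(self) -> dict:
        return {
            "accession": self.accession,
            "start": self.start,
            "end": self.end,
            "orientation": self.orientation,
            "breakdown": self.breakdown.to_dict(),
            "organizational_homology": self.organizational_homology,
            "meH": self.meH,
            "occurrences": [_occ_to_dict(o) for o in self.occurrences],
            "nonscoring": [_occ_to_dict(o) for o in self.nonscoring],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LmnastHit":
        def occ(x: dict) -> CharacterOccurrence:
            return CharacterOccurrence(**x)

        return cls(
            accession=d["accession"],
            occurrences=tuple(occ(x) for x in d["occurrences"]),
            breakdown=ScoreBreakdown.from_dict(d["breakdown"]),
            organizational_homology=d["organizational_homology"],
            meH=d.get("meH"),
            nonscoring=tuple(occ(x) for x in d.get("nonscoring", ())),
        )


# ---------------------------------------------------------------------------
# seeds and joining


def find_seeds(
    occurrences: Sequence[CharacterOccurrence], params: ScoringParams
) -> list[Seed]:
    """Maximal proximity runs with enough distinct characters.

    Consecutive occurrences (sorted by start) belong to the same run
    when the base-pair distance between them is below the join distance
    ``d``. Runs carrying fewer distinct labels than
    ``min_seed_characters`` are discarded.
    """
    scoring = sorted(
        (o for o in occurrences if not o.nonscoring), key=lambda o: (o.start, o.end)
    )
    seeds: list[Seed] = []
    run: list[CharacterOccurrence] = []
    for occ in scoring:
        if run and occ.start - run[-1].end >= params.max_join_distance:
            if len({o.character for o in run}) >= params.min_seed_characters:
                seeds.append(Seed(tuple(run)))
            run = []
        run.append(occ)
    if run and len({o.character for o in run}) >= params.min_seed_characters:
        seeds.append(Seed(tuple(run)))
    return seeds


def join_neighbors(
    seeds: Sequence[Seed],
    occurrences: Sequence[CharacterOccurrence],
    params: ScoringParams,
) -> list[list[CharacterOccurrence]]:
    """Transitive closure of the <d proximity relation around seeds.

    Stray occurrences and seeds closer than ``d`` base pairs coalesce
    into candidate windows; windows containing no seed are discarded.
    When a character occurs twice inside one window both copies are kept
    in the candidate — trimming enumerates the label-distinct
    alternatives, and no final hit ever contains both copies.
    """
    scoring = sorted(
        (o for o in occurrences if not o.nonscoring), key=lambda o: (o.start, o.end)
    )
    # same proximity relation as seeding: the closure's connected
    # components are the maximal runs
    components: list[list[CharacterOccurrence]] = []
    run: list[CharacterOccurrence] = []
    for occ in scoring:
        if run and occ.start - run[-1].end >= params.max_join_distance:
            components.append(run)
            run = []
        run.append(occ)
    if run:
        components.append(run)

    def anchored(comp: list[CharacterOccurrence]) -> bool:
        lo, hi = comp[0].start, comp[-1].end
        return any(s.start >= lo and s.end <= hi for s in seeds)

    return [c for c in components if anchored(c)]


# ---------------------------------------------------------------------------
# scoring


def _intervening_genes(
    replicon: Replicon,
    left_end: int,
    right_start: int,
    excluded: Sequence[tuple[int, int]],
) -> int:
    """Count annotated gene units lying in the gap between two matches.

    A unit counts when at least half of it falls inside the open gap
    and it does not overlap any excluded interval (matched characters,
    nonscoring synonyms).
    """
    if right_start <= left_end:
        return 0
    g = 0
    for u in replicon.gene_units():
        if u.end <= left_end or u.start >= right_start:
            continue
        inside = min(u.end, right_start) - max(u.start, left_end)
        if inside < 0.5 * u.length:
            continue
        if any(min(u.end, e) - max(u.start, s) > 0 for s, e in excluded):
            continue
        g += 1
    return g


def score_candidate(
    query: QuerySpec,
    candidate: Sequence[CharacterOccurrence],
    replicon: Replicon,
    params: ScoringParams,
    nonscoring: Sequence[CharacterOccurrence] = (),
) -> ScoreBreakdown:
    """Score an ordered, label-distinct selection of occurrences.

    The candidate is read in whichever genomic direction (forward or
    reverse) yields the better score; relative order is evaluated on
    compressed query ranks, disregarding insertions and deletions.
    """
    labels = [o.character for o in candidate]
    if len(set(labels)) != len(labels):
        raise ValueError("candidate contains duplicate character labels")
    unknown = set(labels) - set(query.labels)
    if unknown:
        raise ValueError(f"candidate characters not in query: {sorted(unknown)}")

    cand = sorted(candidate, key=lambda o: (o.start, o.end))
    n = len(query)
    m = len(cand)
    deletions = n - m

    # affine insertion penalty per maximal run of intervening genes
    excluded = [(o.start, o.end) for o in cand] + [
        (o.start, o.end) for o in nonscoring
    ]
    gap_runs = []
    gap_total = 0.0
    for left, right in zip(cand, cand[1:]):
        g = _intervening_genes(replicon, left.end, right.start, excluded)
        gap_runs.append(g)
        if g >= 1:
            gap_total += params.gap_open + params.gap_extend * (g - 1)

    # compress query indices of present labels to ranks 1..m
    qindex = {e.label: i for i, e in enumerate(query.elements)}
    order = sorted(labels, key=lambda l: qindex[l])
    rank = {l: r + 1 for r, l in enumerate(order)}
    seq = [rank[o.character] for o in cand]

    def breakpoints(s: list[int]) -> int:
        return sum(1 for a, b in zip(s, s[1:]) if b - a != 1)

    bp_fwd = breakpoints(seq)
    bp_rev = breakpoints(list(reversed(seq)))
    if bp_rev < bp_fwd:
        orientation, bp, reading = "reverse", bp_rev, list(reversed(seq))
    else:
        orientation, bp, reading = "forward", bp_fwd, seq

    # redirection: only where order is maintained (rank-adjacent pairs)
    reading_occs = cand if orientation == "forward" else list(reversed(cand))
    evaluated: list[CharacterOccurrence] = []
    seen: set[int] = set()
    for i, (a, b) in enumerate(zip(reading, reading[1:])):
        if b - a == 1:
            for j in (i, i + 1):
                if j not in seen:
                    seen.add(j)
                    evaluated.append(reading_occs[j])
    qrel = {e.label: e.strand for e in query.elements}
    mismatched = [o for o in evaluated if o.strand != qrel[o.character]]
    if len(mismatched) * 2 <= len(evaluated):
        flips, flipped = len(mismatched), mismatched
    else:
        flipped = [o for o in evaluated if o.strand == qrel[o.character]]
        flips = len(flipped)

    score = (
        n
        - deletions
        - gap_total
        - params.rearrangement_penalty * bp
        - params.direction_penalty * flips
    )
    return ScoreBreakdown(
        base=n,
        deletions=deletions,
        gap_penalty_total=gap_total,
        order_breakpoints=bp,
        direction_flips=flips,
        score=score,
        orientation=orientation,
        gap_runs=tuple(gap_runs),
        flipped_characters=tuple(o.character for o in flipped),
    )


# ---------------------------------------------------------------------------
# trimming


def _selection_key(
    breakdown: ScoreBreakdown,
    selection: Sequence[CharacterOccurrence],
    blast_stats: Optional[BlastStats],
) -> tuple:
    if blast_stats is not None:
        homology = mean_element_homology(selection, blast_stats)
    else:
        # monotone proxy when per-character file statistics are unknown
        homology = sum(o.bit_score for o in selection) / len(selection)
    return (
        breakdown.score,
        len(selection),
        homology,
        -min(o.start for o in selection),
    )


def _label_distinct_selections(candidate: Sequence[CharacterOccurrence]):
    """All ways of keeping at most one copy of each duplicated label."""
    groups: dict[str, list[CharacterOccurrence]] = {}
    order: list[str] = []
    for o in candidate:
        if o.character not in groups:
            order.append(o.character)
        groups.setdefault(o.character, []).append(o)
    choices = [[None, *groups[l]] for l in order]
    for combo in itertools.product(*choices):
        sel = [o for o in combo if o is not None]
        if len(sel) >= 2:
            yield sorted(sel, key=lambda o: (o.start, o.end))


def trim_candidate(
    query: QuerySpec,
    candidate: Sequence[CharacterOccurrence],
    replicon: Replicon,
    params: ScoringParams,
    nonscoring: Sequence[CharacterOccurrence] = (),
    blast_stats: Optional[BlastStats] = None,
) -> Optional[LmnastHit]:
    """Drop elements until the arrangement score is maximal.

    Candidates with at most :data:`EXACT_TRIM_LIMIT` occurrences are
    maximized exactly over all label-distinct subsets of size >= 2;
    larger candidates are trimmed by greedy single-element drops until
    no drop improves the score. Ties prefer more characters, then
    higher mean element homology, then the leftmost start. Returns
    ``None`` when the best score does not exceed ``min_retained_score``.
    """
    cand = sorted(
        (o for o in candidate if not o.nonscoring and o.character in set(query.labels)),
        key=lambda o: (o.start, o.end),
    )
    if len({o.character for o in cand}) < 2:
        return None

    best_sel: Optional[list[CharacterOccurrence]] = None
    best_bd: Optional[ScoreBreakdown] = None
    best_key: Optional[tuple] = None

    if len(cand) <= EXACT_TRIM_LIMIT:
        for sel in _label_distinct_selections(cand):
            bd = score_candidate(query, sel, replicon, params, nonscoring)
            key = _selection_key(bd, sel, blast_stats)
            if best_key is None or key > best_key:
                best_sel, best_bd, best_key = sel, bd, key
    else:
        # deduplicate labels first (best bit, then E-value, then position)
        by_label: dict[str, CharacterOccurrence] = {}
        for o in cand:
            prev = by_label.get(o.character)
            if prev is None or (-o.bit_score, o.evalue, o.start) < (
                -prev.bit_score, prev.evalue, prev.start
            ):
                by_label[o.character] = o
        current = sorted(by_label.values(), key=lambda o: (o.start, o.end))
        cur_bd = score_candidate(query, current, replicon, params, nonscoring)
        while len(current) > 2:
            best_drop = None
            best_drop_key = None
            for i in range(len(current)):
                trial = current[:i] + current[i + 1:]
                bd = score_candidate(query, trial, replicon, params, nonscoring)
                key = _selection_key(bd, trial, blast_stats)
                if bd.score > cur_bd.score and (
                    best_drop_key is None or key > best_drop_key
                ):
                    best_drop, best_drop_key = (trial, bd), key
            if best_drop is None:
                break
            current, cur_bd = best_drop
        best_sel, best_bd = current, cur_bd
        best_key = _selection_key(cur_bd, current, blast_stats)

    if best_bd is None or best_bd.score <= params.min_retained_score:
        return None

    span_lo = min(o.start for o in best_sel)
    span_hi = max(o.end for o in best_sel)
    attached = tuple(
        o for o in nonscoring if o.start < span_hi and o.end > span_lo
    )
    meh = (
        mean_element_homology(best_sel, blast_stats)
        if blast_stats is not None
        else None
    )
    return LmnastHit(
        accession=replicon.accession,
        occurrences=tuple(best_sel),
        breakdown=best_bd,
        organizational_homology=best_bd.score / len(query),
        meH=meh,
        nonscoring=attached,
    )


# ---------------------------------------------------------------------------
# record-level pipeline


def search_record(
    replicon: Replicon,
    query: QuerySpec,
    hits: Sequence[ElementHit],
    assign_params: AssignParams,
    scoring_params: ScoringParams,
    blast_stats: Optional[BlastStats] = None,
) -> list[LmnastHit]:
    """Full per-record pipeline: assign -> seeds -> join -> trim -> reconcile.

    ``hits`` are the raw (unfiltered) per-character BLAST rows for this
    record; per-character bit-score extrema for mean element homology
    are taken from them unless ``blast_stats`` is supplied (stats should
    normally cover each character's *entire* result file, not just one
    record).
    """
    record_hits = [h for h in hits if h.subject_accession == replicon.accession]
    if blast_stats is None:
        blast_stats = BlastStats.from_hits(record_hits)
    kept = filter_hits(record_hits, assign_params)
    occs = assign_characters(replicon, kept, assign_params)
    with_syn = tag_synonyms(replicon, occs, assign_params)
    scoring = [o for o in with_syn if not o.nonscoring]
    nonscoring = [o for o in with_syn if o.nonscoring]
    if not scoring:
        return []
    seeds = find_seeds(scoring, scoring_params)
    candidates = join_neighbors(seeds, scoring, scoring_params)
    out: list[LmnastHit] = []
    for cand in candidates:
        hit = trim_candidate(
            query, cand, replicon, scoring_params, nonscoring, blast_stats
        )
        if hit is not None:
            out.append(hit)
    return reconcile([out])


def extend_query(
    query: QuerySpec,
    reference_replicon: Replicon,
    k_pre: int,
    k_post: int,
) -> QuerySpec:
    """Widen the query with flanking genes from its reference record.

    The new query gains up to ``k_pre`` annotated genes upstream and
    ``k_post`` downstream of the original span, labelled from the
    reference annotation. Truncates with a warning when fewer flanking
    genes exist.
    """
    import warnings

    if k_pre == 0 and k_post == 0:
        return QuerySpec(
            list(query.elements), query.source_accession, query.span
        )
    if query.span is None:
        raise ValueError("extended-window search needs the query span")
    lo, hi = query.span
    units = reference_replicon.gene_units()
    pre = [u for u in units if u.end <= lo]
    post = [u for u in units if u.start >= hi]
    if len(pre) < k_pre or len(post) < k_post:
        warnings.warn(
            f"only {len(pre)} upstream / {len(post)} downstream genes "
            f"available; truncating extension", stacklevel=2,
        )
    pre = pre[-k_pre:] if k_pre else []
    post = post[:k_post] if k_post else []

    # absolute strand of the original first element, from its feature
    first = query.elements[0]
    anchor = next(
        (u for u in units if u.feature_id == first.feature_id),
        next((u for u in units if lo <= u.start < hi), None),
    )
    first_abs = anchor.strand if anchor is not None else "+"

    def flip(s: str) -> str:
        return "-" if s == "+" else "+"

    def compose(rel: str, absolute_first: str) -> str:
        return absolute_first if rel == "+" else flip(absolute_first)

    used = set(query.labels)

    def unit_label(u) -> str:
        base = u.gene_name or u.feature_id
        label = base
        k = 2
        while label in used:
            label = f"{base}_{k}"
            k += 1
        used.add(label)
        return label

    ordered: list[tuple[str, str, Optional[str]]] = []
    for u in pre:
        ordered.append((unit_label(u), u.strand, u.feature_id))
    for e in query.elements:
        ordered.append((e.label, compose(e.strand, first_abs), e.feature_id))
    for u in post:
        ordered.append((unit_label(u), u.strand, u.feature_id))

    ref = ordered[0][1]
    elements = [
        QueryElement(label, "+" if strand == ref else "-", fid)
        for label, strand, fid in ordered
    ]
    new_span = (
        pre[0].start if pre else lo,
        post[-1].end if post else hi,
    )
    return QuerySpec(elements, reference_replicon.accession, new_span)


def reconcile(hit_sets: Sequence[Sequence[LmnastHit]]) -> list[LmnastHit]:
    """Resolve overlapping hits within each record.

    Among interval-overlapping hits on one accession only the
    highest-scoring survives; ties go to higher mean element homology,
    then more characters.
    """
    flat = [h for hs in hit_sets for h in hs]
    by_acc: dict[str, list[LmnastHit]] = {}
    for h in flat:
        by_acc.setdefault(h.accession, []).append(h)
    out: list[LmnastHit] = []
    for acc, hs in sorted(by_acc.items()):
        ranked = sorted(
            hs,
            key=lambda h: (
                -h.score,
                -(h.meH if h.meH is not None else 0.0),
                -len(h.occurrences),
                h.start,
            ),
        )
        kept: list[LmnastHit] = []
        for h in ranked:
            if not any(h.start < k.end and k.start < h.end for k in kept):
                kept.append(h)
        out.extend(sorted(kept, key=lambda h: h.start))
    return out
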