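"""Independent brute-force reference for arrangement scoring and trimming.

Written directly from the scoring definition with plain loops, kept
deliberately separate from the package's implementation so the two can
be compared on random candidates.
"""

from __future__ import annotations

import itertools


def oracle_score(query, selection, replicon, params, nonscoring=()):
    """Score one label-distinct selection, from first principles."""
    sel = sorted(selection, key=lambda o: (o.start, o.end))
    n = len(query.elements)
    m = len(sel)
    deletions = n - m

    # intervening annotated genes per gap (>=50% inside, no overlap with
    # any matched or nonscoring interval)
    excl = [(o.start, o.end) for o in sel] + [(o.start, o.end) for o in nonscoring]
    gap_total = 0.0
    for left, right in zip(sel, sel[1:]):
        lo, hi = left.end, right.start
        g = 0
        for u in replicon.gene_units():
            inside = min(u.end, hi) - max(u.start, lo)
            if inside < 0.5 * (u.end - u.start):
                continue
            if any(min(u.end, e) > max(u.start, s) for s, e in excl):
                continue
            g += 1
        if g:
            gap_total += params.gap_open + params.gap_extend * (g - 1)

    qorder = [e.label for e in query.elements]
    present = [l for l in qorder if l in {o.character for o in sel}]
    rank = {l: i + 1 for i, l in enumerate(present)}

    def count_bp(occs):
        adjacent_in_order = sum(
            1
            for a, b in zip(occs, occs[1:])
            if rank[b.character] - rank[a.character] == 1
        )
        return (len(occs) - 1) - adjacent_in_order

    bp = min(count_bp(sel), count_bp(sel[::-1]))
    reading = sel if count_bp(sel) <= count_bp(sel[::-1]) else sel[::-1]

    # characters in at least one rank-adjacent pair, minimal flips over
    # the two global orientations
    in_pair = set()
    for a, b in zip(reading, reading[1:]):
        if rank[b.character] - rank[a.character] == 1:
            in_pair.add(a.character)
            in_pair.add(b.character)
    qrel = {e.label: e.strand for e in query.elements}
    flip = {"+": "-", "-": "+"}
    flips = min(
        sum(
            1
            for o in sel
            if o.character in in_pair and o.strand != expect[qrel[o.character]]
        )
        for expect in ({"+": "+", "-": "-"}, {"+": "-", "-": "+"})
    )

    return (
        n
        - deletions
        - gap_total
        - params.rearrangement_penalty * bp
        - params.direction_penalty * flips
    )


def oracle_trim(query, candidate, replicon, params, nonscoring=(), stats=None):
    """Exhaustive subset maximization with the stated tie-breaks.

    Returns (score, n_characters, homology_proxy, start) of the winning
    selection, or None when nothing scores above the retention floor.
    """
    occs = sorted(candidate, key=lambda o: (o.start, o.end))
    best = None
    for r in range(2, len(occs) + 1):
        for combo in itertools.combinations(occs, r):
            labels = [o.character for o in combo]
            if len(set(labels)) != len(labels):
                continue
            score = oracle_score(query, combo, replicon, params, nonscoring)
            if stats is not None:
                homology = sum(
                    stats.normalized(o.character, o.bit_score) for o in combo
                ) / len(combo)
            else:
                homology = sum(o.bit_score for o in combo) / len(combo)
            key = (score, len(combo), homology, -min(o.start for o in combo))
            if best is None or key > best:
                best = key
    if best is None or best[0] <= params.min_retained_score:
        return None
    return (best[0], best[1], best[2], -best[3])
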