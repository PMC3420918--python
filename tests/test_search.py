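import numpy as np
import pytest

from lmnast import (
    AssignParams,
    QueryElement,
    QuerySpec,
    ScoringParams,
    extend_query,
    find_seeds,
    join_neighbors,
    reconcile,
    score_candidate,
    search_record,
    trim_candidate,
)
from lmnast.search import LmnastHit, ScoreBreakdown
from lmnast import synth

from conftest import (
    mk_occ,
    mk_replicon,
    planted_fixture,
    random_candidate,
    run_search,
)
from oracle import oracle_score, oracle_trim


STRINGENT = ScoringParams.stringent()
WEAK = ScoringParams.weak()


class TestFindSeeds:
    def test_two_proximal_characters_form_a_seed(self):
        occs = [mk_occ("A", 100, 1000), mk_occ("B", 1200, 2000)]
        (seed,) = find_seeds(occs, STRINGENT)
        assert seed.labels == {"A", "B"}

    def test_isolated_single_character_is_no_seed(self):
        assert find_seeds([mk_occ("A", 100, 1000)], STRINGENT) == []

    def test_distance_at_or_beyond_d_splits_runs(self):
        occs = [mk_occ("A", 100, 1000), mk_occ("B", 11_000, 12_000)]
        assert find_seeds(occs, STRINGENT) == []

    def test_duplicate_label_run_needs_a_second_character(self):
        occs = [mk_occ("A", 100, 1000), mk_occ("A", 1200, 2000)]
        assert find_seeds(occs, STRINGENT) == []


class TestJoinNeighbors:
    def test_proximal_seeds_coalesce_into_one_candidate(self):
        occs = [
            mk_occ("A", 100, 1000),
            mk_occ("B", 1200, 2000),
            mk_occ("C", 4000, 4800),
            mk_occ("D", 5000, 5800),
        ]
        seeds = find_seeds(occs, STRINGENT)
        (cand,) = join_neighbors(seeds, occs, STRINGENT)
        assert [o.character for o in cand] == ["A", "B", "C", "D"]

    def test_stray_occurrence_absorbed_into_candidate(self):
        occs = [
            mk_occ("A", 100, 1000),
            mk_occ("B", 1200, 2000),
            mk_occ("E", 3000, 3800),
        ]
        seeds = find_seeds(occs, STRINGENT)
        (cand,) = join_neighbors(seeds, occs, STRINGENT)
        assert [o.character for o in cand] == ["A", "B", "E"]

    def test_duplicate_copies_stay_in_window_never_in_one_hit(self, abcd_query):
        rep = mk_replicon(
            [
                ("g1", 100, 1000, "+"),
                ("g2", 1200, 2000, "+"),
                ("g3", 2200, 3000, "+"),
            ]
        )
        occs = [
            mk_occ("A", 100, 1000, bit=100.0, anchored="g1"),
            mk_occ("B", 1200, 2000, bit=90.0, anchored="g2"),
            mk_occ("A", 2200, 3000, bit=80.0, anchored="g3"),
        ]
        seeds = find_seeds(occs, STRINGENT)
        (cand,) = join_neighbors(seeds, occs, STRINGENT)
        assert len(cand) == 3
        hit = trim_candidate(abcd_query, cand, rep, STRINGENT)
        labels = hit.characters
        assert labels.count("A") == 1


@pytest.fixture
def abcd_query():
    return QuerySpec([QueryElement(l, "+") for l in "ABCD"])


def occs_for(rep, chars, strands=None):
    """Occurrences anchored one-to-one on a replicon's gene features."""
    units = rep.gene_units()
    strands = strands or [u.strand for u in units]
    out = []
    for u, c in zip(units, chars):
        if c is None:
            continue
        out.append(
            mk_occ(c, u.start, u.end, u.strand, anchored=u.feature_id)
        )
    return out


class TestScoreCandidate:
    def layout(self, n, strands=None):
        strands = strands or ["+"] * n
        genes = [
            (f"g{i}", 100 + i * 1100, 1000 + i * 1100, strands[i])
            for i in range(n)
        ]
        return mk_replicon(genes)

    def test_perfect_codirectional_arrangement_scores_n(self, abcd_query):
        rep = self.layout(4)
        cand = occs_for(rep, list("ABCD"))
        bd = score_candidate(abcd_query, cand, rep, STRINGENT)
        assert bd.score == 4
        assert (bd.deletions, bd.gap_penalty_total, bd.order_breakpoints,
                bd.direction_flips) == (0, 0.0, 0, 0)

    def test_one_absent_character_costs_one_deletion(self, abcd_query):
        rep = self.layout(3)
        cand = occs_for(rep, ["A", "B", "D"])
        bd = score_candidate(abcd_query, cand, rep, STRINGENT)
        assert bd.deletions == 1 and bd.score == 3
        assert bd.order_breakpoints == 0

    def test_divergently_flipped_first_element_costs_one_flip(self):
        # co-directional four-gene query; first gene divergently flipped
        # in the hit while order is maintained
        query = QuerySpec([QueryElement(l, "+") for l in ["lacI", "lacZ", "lacY", "lacA"]])
        rep = self.layout(4, strands=["-", "+", "+", "+"])
        cand = occs_for(rep, ["lacI", "lacZ", "lacY", "lacA"])
        bd = score_candidate(query, cand, rep, STRINGENT)
        assert bd.direction_flips == 1
        assert bd.order_breakpoints == 0
        assert bd.score == 3

    def test_affine_gap_for_two_intervening_genes_stringent(self, abcd_query):
        rep = mk_replicon(
            [
                ("g0", 100, 1000, "+"),
                ("g1", 1200, 2000, "+"),
                ("x1", 2200, 3000, "+"),
                ("x2", 3200, 4000, "+"),
                ("g2", 4200, 5000, "+"),
                ("g3", 5200, 6000, "+"),
            ]
        )
        cand = occs_for(rep, ["A", "B", None, None, "C", "D"])
        bd = score_candidate(abcd_query, cand, rep, STRINGENT)
        assert bd.gap_penalty_total == pytest.approx(2 + 1 * 1)
        assert bd.score == pytest.approx(4 - 3)
        bd_weak = score_candidate(abcd_query, cand, rep, WEAK)
        assert bd_weak.gap_penalty_total == pytest.approx(1 + 0.3)

    def test_nonscoring_synonym_does_not_count_as_insertion(self, abcd_query):
        rep = mk_replicon(
            [
                ("g0", 100, 1000, "+"),
                ("syn", 1200, 2000, "+"),
                ("g1", 2200, 3000, "+"),
                ("g2", 3200, 4000, "+"),
                ("g3", 4200, 5000, "+"),
            ]
        )
        cand = occs_for(rep, ["A", None, "B", "C", "D"])
        nonscoring = [mk_occ("B", 1200, 2000, nonscoring=True)]
        bd = score_candidate(abcd_query, cand, rep, STRINGENT, nonscoring)
        assert bd.gap_penalty_total == 0.0
        assert bd.score == 4

    def test_wholly_inverted_system_reads_reverse_and_scores_clean(self, abcd_query):
        rep = self.layout(4, strands=["-"] * 4)
        cand = occs_for(rep, ["D", "C", "B", "A"])
        bd = score_candidate(abcd_query, cand, rep, STRINGENT)
        assert bd.orientation == "reverse"
        assert bd.order_breakpoints == 0 and bd.direction_flips == 0
        assert bd.score == 4

    def test_duplicate_labels_are_a_contract_violation(self, abcd_query):
        rep = self.layout(2)
        cand = [mk_occ("A", 100, 1000), mk_occ("A", 1200, 2000)]
        with pytest.raises(ValueError, match="duplicate"):
            score_candidate(abcd_query, cand, rep, STRINGENT)


class TestTrimCandidate:
    def test_far_outlier_with_costly_gap_is_dropped(self, abcd_query):
        genes = [
            ("g0", 100, 1000, "+"),
            ("g1", 1200, 2000, "+"),
            ("g2", 2200, 3000, "+"),
            ("x1", 3200, 4000, "+"),
            ("x2", 4200, 5000, "+"),
            ("x3", 5200, 6000, "+"),
            ("g3", 6200, 7000, "+"),
        ]
        rep = mk_replicon(genes)
        cand = occs_for(rep, ["A", "B", "C", None, None, None, "D"])
        hit = trim_candidate(abcd_query, cand, rep, STRINGENT)
        assert hit.characters == ["A", "B", "C"]
        assert hit.score == 3  # 4 - 1 deletion beats 4 - (2+1+1) gap

    def test_score_tie_prefers_more_characters(self, abcd_query):
        # one intervening gene under weak parameters: keeping all four
        # (4 - 1.0 gap) ties dropping... construct exact tie instead:
        # stringent, gap of one gene costs 2; subset {A,B,C} scores 3,
        # keeping D too scores 4 - 2 = 2; so trim keeps {A,B,C} (no tie).
        # A genuine tie: weak params, gap 1 gene -> 4 - 1 = 3 vs drop D
        # -> 3. Most characters wins.
        genes = [
            ("g0", 100, 1000, "+"),
            ("g1", 1200, 2000, "+"),
            ("g2", 2200, 3000, "+"),
            ("x1", 3200, 4000, "+"),
            ("g3", 4200, 5000, "+"),
        ]
        rep = mk_replicon(genes)
        cand = occs_for(rep, ["A", "B", "C", None, "D"])
        hit = trim_candidate(abcd_query, cand, rep, WEAK)
        assert hit.score == pytest.approx(3.0)
        assert hit.characters == ["A", "B", "C", "D"]

    def test_nothing_above_zero_returns_none(self, abcd_query):
        # two characters, maximally rearranged and redirected relative
        # to each other plus a long insertion run: best subset scores <= 0
        genes = [
            ("g0", 100, 1000, "+"),
            ("x1", 1200, 2000, "+"),
            ("x2", 2200, 3000, "+"),
            ("x3", 3200, 4000, "+"),
            ("g1", 4200, 5000, "+"),
        ]
        rep = mk_replicon(genes)
        cand = occs_for(rep, ["D", None, None, None, "A"])
        # n=4, deletions=2, gap=2+1*2=4 -> score=-2 (stringent)
        assert trim_candidate(abcd_query, cand, rep, STRINGENT) is None

    def test_greedy_path_engages_above_exact_limit(self):
        labels = [f"c{i}" for i in range(14)]
        query = QuerySpec([QueryElement(l, "+") for l in labels])
        genes = [
            (f"g{i}", 100 + i * 1100, 1000 + i * 1100, "+") for i in range(14)
        ]
        rep = mk_replicon(genes)
        cand = occs_for(rep, labels)
        hit = trim_candidate(query, cand, rep, STRINGENT)
        assert hit is not None
        assert hit.score == 14


class TestOracleEquivalence:
    @pytest.mark.parametrize("params", [STRINGENT, WEAK], ids=["stringent", "weak"])
    def test_exact_trim_matches_brute_force_on_random_candidates(self, params):
        """200 random candidates, both parameter sets: identical outcome."""
        query = QuerySpec(
            [QueryElement(l, s) for l, s in zip("ABCDEF", "++-++-")]
        )
        rng = np.random.default_rng(42)
        agree = 0
        total = 100  # per parameter set; 200 over the two
        for _ in range(total):
            n_occ = int(rng.integers(3, 9))
            rep, occs = random_candidate(rng, query, n_occ)
            got = trim_candidate(query, occs, rep, params)
            want = oracle_trim(query, occs, rep, params)
            if got is None and want is None:
                agree += 1
                continue
            assert (got is None) == (want is None)
            key = (
                got.score,
                len(got.occurrences),
                round(sum(o.bit_score for o in got.occurrences)
                      / len(got.occurrences), 9),
                got.start,
            )
            want_key = (want[0], want[1], round(want[2], 9), want[3])
            assert key == want_key
            agree += 1
        assert agree == total

    def test_single_selection_scores_match_oracle(self):
        query = QuerySpec(
            [QueryElement(l, s) for l, s in zip("ABCDE", "+-+++")]
        )
        rng = np.random.default_rng(7)
        for _ in range(100):
            n_occ = int(rng.integers(2, 7))
            rep, occs = random_candidate(rng, query, n_occ)
            # reduce to a label-distinct selection
            seen, sel = set(), []
            for o in occs:
                if o.character not in seen:
                    seen.add(o.character)
                    sel.append(o)
            if len(sel) < 2:
                continue
            bd = score_candidate(query, sel, rep, WEAK)
            assert bd.score == pytest.approx(
                oracle_score(query, sel, rep, WEAK)
            )


class TestSearchRecord:
    def test_planted_perfect_system_recovered_exactly(self, abcd_query):
        found, truth, _ = run_search(abcd_query, seed=5)
        assert len(found) == 1
        hit = found[0]
        assert hit.score == 4
        assert hit.organizational_homology == 1.0
        assert hit.meH == pytest.approx(1.0)
        assert hit.characters == truth.present_characters()

    def test_planted_deletion_recovered(self, abcd_query):
        found, truth, _ = run_search(
            abcd_query, edits=[synth.EditEvent("delete_char", "C")], seed=6
        )
        (hit,) = found
        assert "C" not in hit.characters
        assert hit.breakdown.deletions == 1

    def test_no_assigned_characters_means_no_hits(self, abcd_query):
        rep = synth.make_replicon(10, rng_seed=9)
        hits = search_record(
            rep, abcd_query, [], AssignParams(), STRINGENT
        )
        assert hits == []

    def test_strand_symmetry_of_scores(self, abcd_query):
        """Mirroring the whole fixture leaves every hit score unchanged."""
        for edits in ([], [synth.EditEvent("invert_char", "B")],
                      [synth.EditEvent("transpose_char", "A", {"to": 2})]):
            planted, truth, hits = planted_fixture(abcd_query, edits, seed=13)
            fwd = search_record(
                planted, abcd_query, hits, AssignParams(), STRINGENT
            )
            mirrored, mhits = mirror_fixture(planted, hits)
            rev = search_record(
                mirrored, abcd_query, mhits, AssignParams(), STRINGENT
            )
            assert [h.score for h in fwd] == [h.score for h in rev]

    def test_extra_edit_never_raises_score(self, abcd_query):
        base_edits = [synth.EditEvent("delete_char", "D")]
        extra = base_edits + [synth.EditEvent("invert_char", "B")]
        s_base, _, _ = run_search(abcd_query, edits=base_edits, seed=21)
        s_extra, _, _ = run_search(abcd_query, edits=extra, seed=21)
        assert s_extra[0].score <= s_base[0].score

    def test_weak_params_never_score_below_stringent(self, abcd_query):
        for seed in range(5):
            edits = [synth.EditEvent("insert_genes", "B", {"g": 1})]
            w, _, _ = run_search(abcd_query, edits=edits, seed=seed, mode="weak")
            s, _, _ = run_search(abcd_query, edits=edits, seed=seed, mode="stringent")
            if w and s:
                assert w[0].score >= s[0].score

    def test_no_emitted_hit_repeats_a_character(self, abcd_query):
        for seed in range(8):
            found, _, _ = run_search(
                abcd_query,
                edits=[synth.EditEvent("insert_genes", "A", {"g": 1})],
                seed=seed,
            )
            for h in found:
                assert len(set(h.characters)) == len(h.characters)


def mirror_fixture(replicon, hits):
    """Reverse-complement a fixture: features and hits mirrored."""
    from dataclasses import replace as dc_replace

    L = replicon.length
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    flip = {"+": "-", "-": "+"}
    feats = [
        dc_replace(f, start=L - f.end, end=L - f.start, strand=flip[f.strand])
        for f in replicon.features
    ]
    seq = (
        "".join(comp.get(b, "N") for b in reversed(replicon.sequence))
        if replicon.sequence
        else None
    )
    from lmnast.iolib import Replicon

    mirrored = Replicon(
        accession=replicon.accession,
        length=L,
        features=feats,
        sequence=seq,
        circular=replicon.circular,
    )
    mhits = [
        dc_replace(h, start=L - h.end, end=L - h.start, strand=flip[h.strand])
        for h in hits
    ]
    return mirrored, mhits


class TestExtendQuery:
    def reference(self):
        genes = [
            (f"u{i}", 100 + i * 1100, 1000 + i * 1100, "+") for i in range(16)
        ]
        return mk_replicon(genes, accession="REF1")

    def query_on(self, rep, first, labels):
        units = rep.gene_units()
        span = (units[first].start, units[first + len(labels) - 1].end)
        elements = [
            QueryElement(l, "+", units[first + i].feature_id)
            for i, l in enumerate(labels)
        ]
        return QuerySpec(elements, rep.accession, span)

    def test_five_flanking_genes_each_side(self):
        rep = self.reference()
        q = self.query_on(rep, 6, ["A", "B", "C", "D"])
        ext = extend_query(q, rep, 5, 5)
        assert len(ext) == 14
        assert ext.labels[5:9] == ["A", "B", "C", "D"]

    def test_asymmetric_extension_matches_gene_counts(self):
        rep = self.reference()
        q = self.query_on(rep, 5, [f"c{i}" for i in range(8)])
        ext = extend_query(q, rep, 5, 3)
        assert len(ext) == 16

    def test_zero_extension_is_identity(self):
        rep = self.reference()
        q = self.query_on(rep, 6, ["A", "B", "C", "D"])
        ext = extend_query(q, rep, 0, 0)
        assert ext.labels == q.labels and ext.span == q.span

    def test_truncation_warns_when_flanks_run_out(self):
        rep = self.reference()
        q = self.query_on(rep, 1, ["A", "B", "C", "D"])
        with pytest.warns(UserWarning, match="truncating"):
            ext = extend_query(q, rep, 5, 0)
        assert len(ext) == 5  # only one upstream gene exists


class TestReconcile:
    def make_hit(self, acc, start, end, score, meh=0.5, n=2):
        occs = tuple(
            mk_occ(c, start + i * 100, start + i * 100 + 90)
            for i, c in enumerate("ABCDEF"[:n])
        )
        # stretch last occurrence to cover the span end
        occs = occs[:-1] + (mk_occ("Z", end - 90, end),)
        bd = ScoreBreakdown(
            base=4, deletions=0, gap_penalty_total=0.0,
            order_breakpoints=0, direction_flips=0, score=score,
        )
        return LmnastHit(
            accession=acc, occurrences=occs, breakdown=bd,
            organizational_homology=score / 4, meH=meh,
        )

    def test_highest_score_survives_overlap(self):
        h5 = self.make_hit("R1", 100, 900, 5)
        h3 = self.make_hit("R1", 500, 1200, 3)
        assert reconcile([[h5], [h3]]) == [h5]

    def test_non_overlapping_hits_both_survive(self):
        a = self.make_hit("R1", 100, 900, 5)
        b = self.make_hit("R1", 2000, 2900, 3)
        assert reconcile([[a, b]]) == [a, b]

    def test_equal_scores_break_by_meh(self):
        lo = self.make_hit("R1", 100, 900, 3, meh=0.4)
        hi = self.make_hit("R1", 500, 1200, 3, meh=0.9)
        assert reconcile([[lo, hi]]) == [hi]
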