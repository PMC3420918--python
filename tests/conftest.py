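from __future__ import annotations

import numpy as np
import pytest

from lmnast import (
    AssignParams,
    QueryElement,
    QuerySpec,
    Replicon,
    ScoringParams,
    search_record,
)
from lmnast.assign import CharacterOccurrence
from lmnast.iolib import GeneFeature, parse_blast_tabular
from lmnast import synth


@pytest.fixture
def abcd_query() -> QuerySpec:
    """A four-element co-directional query, the canonical small system."""
    return QuerySpec([QueryElement(l, "+") for l in "ABCD"])


def mk_replicon(genes, accession="REC1", length=None) -> Replicon:
    """Build a replicon from (name, start, end, strand[, pseudo]) tuples."""
    feats = []
    for g in genes:
        name, start, end, strand = g[:4]
        pseudo = g[4] if len(g) > 4 else False
        feats.append(
            GeneFeature(
                feature_id=name,
                kind="gene",
                start=start,
                end=end,
                strand=strand,
                gene_name=name,
                product=f"{name} protein",
                pseudo=pseudo,
            )
        )
    length = length or (max(f.end for f in feats) + 500 if feats else 1000)
    return Replicon(accession=accession, length=length, features=feats)


def mk_occ(character, start, end, strand="+", bit=100.0, evalue=1e-30,
           nonscoring=False, anchored=None) -> CharacterOccurrence:
    return CharacterOccurrence(
        character=character,
        start=start,
        end=end,
        strand=strand,
        bit_score=bit,
        evalue=evalue,
        anchored_feature=anchored,
        nonscoring=nonscoring,
    )


def planted_fixture(query, edits=(), seed=0, n_genes=30, background_gc=0.5):
    """Background replicon + planted system + per-character BLAST rows."""
    rep = synth.make_replicon(
        n_genes, background_gc=background_gc, rng_seed=seed
    )
    planted, truth = synth.plant_system(rep, query, list(edits), rng_seed=seed)
    blast = synth.emit_blast_for(planted, query, rng_seed=seed)
    hits = []
    for char, text in blast.items():
        hits.extend(parse_blast_tabular(text, char))
    return planted, truth, hits


def run_search(query, edits=(), seed=0, mode="stringent", **fixture_kw):
    planted, truth, hits = planted_fixture(query, edits, seed, **fixture_kw)
    scoring = (
        ScoringParams.weak() if mode == "weak" else ScoringParams.stringent()
    )
    found = search_record(
        planted, query, hits, AssignParams(mode=mode), scoring
    )
    return found, truth, planted


def random_candidate(rng: np.random.Generator, query, n_occ):
    """A random candidate window on a throwaway replicon.

    Genes are laid out sequentially; each slot is either a character
    occurrence (possibly a duplicate label, random strand) or an
    uncharacterized intervening gene.
    """
    labels = query.labels
    genes = []
    occs = []
    pos = 200
    placed = 0
    slot = 0
    while placed < n_occ:
        length = int(rng.integers(600, 1200))
        strand = "+" if rng.random() < 0.5 else "-"
        if rng.random() < 0.65:
            label = labels[int(rng.integers(0, len(labels)))]
            name = f"occ{slot}"
            genes.append((name, pos, pos + length, strand))
            occs.append(
                mk_occ(
                    label, pos, pos + length, strand,
                    bit=float(rng.integers(40, 250)),
                    evalue=10.0 ** -float(rng.integers(5, 60)),
                    anchored=name,
                )
            )
            placed += 1
        else:
            genes.append((f"bg{slot}", pos, pos + length, strand))
        pos += length + int(rng.integers(100, 400))
        slot += 1
    return mk_replicon(genes, accession="RAND"), occs
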