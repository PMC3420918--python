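"""Character assignment: raw homology hits -> occurrences on a replicon.

A query element ("character") is considered present wherever a BLAST hit
for it scores below the E-value threshold (default 0.1). Two
annotation-criteria modes control how hits relate to the record's gene
annotation:

* ``stringent`` assumes accurate annotation: an occurrence must lie
  within a non-pseudo gene/CDS feature, and each feature may carry at
  most one character (best bit score wins).
* ``weak`` does not require hits to lie within annotated coding
  sequence: intergenic hits, hits on pseudo genes, and several
  characters sharing one annotation are all admitted.

Nonscoring synonyms — loci whose annotation matches a character but
whose sequence homology failed the E-value filter — are tagged
separately and never contribute to scores or mean element homology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import inf
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .iolib import ElementHit, GeneFeature, Replicon

#: fraction of a hit interval that must fall inside a feature for the
#: hit to count as lying "within" that annotation (tblastn hits may
#: slightly overhang gene boundaries)
WITHIN_FEATURE_FRACTION = 0.8

#: same-character occurrences overlapping more than this fraction of
#: either interval are merged, keeping the better bit score
MERGE_OVERLAP_FRACTION = 0.5


@dataclass
class AssignParams:
    evalue_threshold: float = 0.1
    mode: str = "stringent"  # 'weak' | 'stringent'
    synonym_table: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be > 0")
        if self.mode not in ("weak", "stringent"):
            raise ValueError(f"unknown criteria mode {self.mode!r}")
        self.synonym_table = {
            k: frozenset(v) for k, v in dict(self.synonym_table).items()
        }


@dataclass(frozen=True)
class CharacterOccurrence:
    """A filtered homology hit assigned to a character at a genomic locus."""

    character: str
    start: int
    end: int
    strand: str
    bit_score: float
    evalue: float
    anchored_feature: Optional[str] = None
    nonscoring: bool = False
    annotation_text: Optional[str] = None

    @property
    def length(self) -> int:
        return self.end - self.start


def filter_hits(hits: Sequence[ElementHit], params: AssignParams) -> list[ElementHit]:
    """Keep exactly the hits with E-value strictly below the threshold."""
    return [h for h in hits if h.evalue < params.evalue_threshold]


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def _anchor_feature(
    hit: ElementHit, features: Sequence[GeneFeature]
) -> Optional[GeneFeature]:
    """Best feature containing >= WITHIN_FEATURE_FRACTION of the hit."""
    best, best_ov = None, 0
    for f in features:
        if f.wraps_origin or f.kind not in ("gene", "CDS"):
            continue
        ov = _overlap(hit.start, hit.end, f.start, f.end)
        if ov > best_ov:
            best, best_ov = f, ov
    if best is not None and best_ov >= WITHIN_FEATURE_FRACTION * (hit.end - hit.start):
        return best
    return None


def _merge_same_character(
    occs: list[CharacterOccurrence],
) -> list[CharacterOccurrence]:
    """Merge same-character occurrences overlapping > half of either."""
    kept: list[CharacterOccurrence] = []
    for occ in sorted(
        occs, key=lambda o: (-o.bit_score, o.evalue, o.start)
    ):
        clash = False
        for k in kept:
            if k.character != occ.character:
                continue
            ov = _overlap(occ.start, occ.end, k.start, k.end)
            if ov > MERGE_OVERLAP_FRACTION * min(occ.length, k.length):
                clash = True
                break
        if not clash:
            kept.append(occ)
    kept.sort(key=lambda o: (o.start, o.end))
    return kept


def assign_characters(
    replicon: Replicon,
    hits: Sequence[ElementHit],
    params: AssignParams,
) -> list[CharacterOccurrence]:
    """Turn E-value-filtered hits into character occurrences.

    Raises ``ValueError`` if a hit references a different record. The
    weak-mode output is always a superset of the stringent-mode output
    on identical input.
    """
    for h in hits:
        if h.subject_accession != replicon.accession:
            raise ValueError(
                f"hit for {h.character} references {h.subject_accession}, "
                f"not {replicon.accession}"
            )

    candidates: list[tuple[ElementHit, Optional[GeneFeature]]] = [
        (h, _anchor_feature(h, replicon.features)) for h in hits
    ]

    occs: list[CharacterOccurrence] = []
    if params.mode == "stringent":
        # one character per feature; hit must lie within a non-pseudo feature
        by_feature: dict[str, list[ElementHit]] = {}
        for h, feat in candidates:
            if feat is None or feat.pseudo:
                continue
            by_feature.setdefault(feat.feature_id, []).append(h)
        feat_by_id = {f.feature_id: f for f in replicon.features}
        for fid, fhits in by_feature.items():
            # conflict resolution: bit score, then E-value, then input order
            best = min(
                range(len(fhits)),
                key=lambda i: (-fhits[i].bit_score, fhits[i].evalue, i),
            )
            h = fhits[best]
            occs.append(
                CharacterOccurrence(
                    character=h.character,
                    start=h.start,
                    end=h.end,
                    strand=h.strand,
                    bit_score=h.bit_score,
                    evalue=h.evalue,
                    anchored_feature=fid,
                    annotation_text=feat_by_id[fid].product,
                )
            )
    else:
        for h, feat in candidates:
            occs.append(
                CharacterOccurrence(
                    character=h.character,
                    start=h.start,
                    end=h.end,
                    strand=h.strand,
                    bit_score=h.bit_score,
                    evalue=h.evalue,
                    anchored_feature=feat.feature_id if feat else None,
                    annotation_text=feat.product if feat else None,
                )
            )

    return _merge_same_character(occs)


def tag_synonyms(
    replicon: Replicon,
    occurrences: Sequence[CharacterOccurrence],
    params: AssignParams,
) -> list[CharacterOccurrence]:
    """Add nonscoring occurrences for annotation-matched loci.

    A feature whose gene name or product matches a synonym string
    (case-insensitive substring) for a character gains a nonscoring
    occurrence, unless a scoring occurrence of that character already
    overlaps the feature. Nonscoring occurrences never alter arrangement
    scores or mean element homology.
    """
    if not params.synonym_table:
        return list(occurrences)
    result = list(occurrences)
    for feat in replicon.features:
        if feat.kind not in ("gene", "CDS") or feat.wraps_origin:
            continue
        texts = [t.lower() for t in (feat.gene_name, feat.product) if t]
        if not texts:
            continue
        for character, synonyms in params.synonym_table.items():
            if not any(s.lower() in t for s in synonyms for t in texts):
                continue
            covered = any(
                o.character == character
                and not o.nonscoring
                and _overlap(o.start, o.end, feat.start, feat.end) > 0
                for o in occurrences
            )
            already = any(
                o.character == character
                and o.nonscoring
                and o.anchored_feature == feat.feature_id
                for o in result
            )
            if covered or already:
                continue
            result.append(
                CharacterOccurrence(
                    character=character,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand,
                    bit_score=0.0,
                    evalue=inf,
                    anchored_feature=feat.feature_id,
                    nonscoring=True,
                    annotation_text=feat.product or feat.gene_name,
                )
            )
    result.sort(key=lambda o: (o.start, o.end))
    return result


def load_synonym_table(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a two-column TSV (character, annotation string)."""
    table: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        character, text = line.split("\t", 1)
        table.setdefault(character, set()).add(text.strip())
    return {k: frozenset(v) for k, v in table.items()}
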