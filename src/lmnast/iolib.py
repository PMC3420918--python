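"""Readers and writers for the external formats the tool touches.

GenBank flat files are read through Biopython; BLAST tabular results
(outfmt 6/7) and query specifications are small line formats handled
directly so that row-level errors can name the offending line. All
coordinates are 0-based half-open internally; GenBank's 1-based
inclusive convention is converted at the boundary.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO


class FormatError(ValueError):
    """A file did not conform to its expected format."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene-level feature on a replicon.

    ``start``/``end`` form a 0-based half-open interval. ``wraps_origin``
    marks compound ("join") locations that span the origin of a circular
    record; such features are parsed but excluded from search windows.
    """

    feature_id: str
    kind: str  # 'gene' | 'CDS' | 'other'
    start: int
    end: int
    strand: str  # '+' | '-'
    gene_name: Optional[str] = None
    product: Optional[str] = None
    pseudo: bool = False
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if not self.wraps_origin and self.start >= self.end:
            raise ValueError(
                f"feature {self.feature_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.feature_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Replicon:
    """An annotated nucleotide record."""

    accession: str
    length: int
    features: list[GeneFeature] = field(default_factory=list)
    sequence: Optional[str] = None
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("replicon accession must be non-empty")
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        for f in self.features:
            if not f.wraps_origin and not (0 <= f.start < f.end <= self.length):
                raise ValueError(
                    f"feature {f.feature_id} interval [{f.start},{f.end}) "
                    f"outside record of length {self.length}"
                )

    def gene_units(self) -> list[GeneFeature]:
        """Distinct gene loci, for gap counting and window extension.

        Prefers ``gene`` features; falls back to CDS when a record
        annotates only coding sequences. Origin-wrapping features are
        excluded.
        """
        genes = [f for f in self.features if f.kind == "gene" and not f.wraps_origin]
        if genes:
            return genes
        return [f for f in self.features if f.kind == "CDS" and not f.wraps_origin]


@dataclass(frozen=True)
class ElementHit:
    """A raw homology hit for one query character on a subject record."""

    character: str
    subject_accession: str
    start: int
    end: int
    strand: str
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"hit {self.character}: start >= end")
        if self.evalue < 0:
            raise ValueError(f"hit {self.character}: negative E-value")


@dataclass(frozen=True)
class QueryElement:
    label: str
    strand: str  # relative to the first element: '+' | '-'
    feature_id: Optional[str] = None


@dataclass
class QuerySpec:
    """The ordered gene arrangement being searched for.

    At least two elements are required (two homologs are the natural
    minimum an arrangement hit may contain) and labels must be unique:
    intra-hit gene duplications are disallowed, so a duplicated query
    label would be unsatisfiable.
    """

    elements: list[QueryElement]
    source_accession: str = ""
    span: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if len(self.elements) < 2:
            raise ValueError("a query needs at least two elements")
        labels = [e.label for e in self.elements]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate query labels not allowed: {dupes}")

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.elements]

    def __len__(self) -> int:
        return len(self.elements)


# ---------------------------------------------------------------------------
# GenBank


def parse_genbank(text: str) -> Replicon:
    """Parse a GenBank flat file into a :class:`Replicon`.

    Coordinates are converted from 1-based inclusive to 0-based
    half-open. Compound locations that wrap the origin of a circular
    record are flagged ``wraps_origin``.
    """
    if "LOCUS" not in text.split("\n", 1)[0] and not text.lstrip().startswith("LOCUS"):
        raise FormatError("not a GenBank record: missing LOCUS line")
    try:
        record = SeqIO.read(io.StringIO(text), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError
        raise FormatError(f"malformed GenBank record: {exc}") from exc

    circular = "circular" in (record.annotations.get("topology", "") or "")
    features: list[GeneFeature] = []
    counter = 0
    for feat in record.features:
        if feat.type == "source":
            continue
        kind = feat.type if feat.type in ("gene", "CDS") else "other"
        quals = feat.qualifiers
        locus = (quals.get("locus_tag") or quals.get("gene") or [None])[0]
        counter += 1
        fid = locus or f"{record.id}_f{counter}"
        start = int(feat.location.start)
        end = int(feat.location.end)
        # a join over the origin shows up as parts out of ascending order
        wraps = False
        parts = getattr(feat.location, "parts", [feat.location])
        if len(parts) > 1:
            starts = [int(p.start) for p in parts]
            if starts != sorted(starts):
                wraps = True
        strand = "-" if feat.location.strand == -1 else "+"
        features.append(
            GeneFeature(
                feature_id=fid,
                kind=kind,
                start=start,
                end=end,
                strand=strand,
                gene_name=(quals.get("gene") or [None])[0],
                product=(quals.get("product") or [None])[0],
                pseudo="pseudo" in quals or "pseudogene" in quals,
                wraps_origin=wraps,
            )
        )
    if not features:
        warnings.warn(f"record {record.id}: no gene features", stacklevel=2)
    try:  # records without an ORIGIN block have an undefined sequence
        seq = str(record.seq) if len(record.seq) else None
    except Exception:
        seq = None
    return Replicon(
        accession=record.id,
        length=len(record.seq) or max((f.end for f in features), default=0),
        features=features,
        sequence=seq,
        circular=circular,
    )


# ---------------------------------------------------------------------------
# BLAST tabular

# standard outfmt 6 column order
_SSEQID, _SSTART, _SEND, _EVALUE, _BIT = 1, 8, 9, 10, 11


def parse_blast_tabular(text: str, character: str) -> list[ElementHit]:
    """Parse BLAST tabular (outfmt 6/7) rows into hits for one character.

    The subject strand is inferred from the coordinate order: rows with
    sstart > send are minus-strand and the interval is normalized to
    start < end. '#' comment lines (outfmt 7) are skipped.
    """
    hits: list[ElementHit] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t") if "\t" in line else line.split()
        if len(cols) < 12:
            raise FormatError(
                f"row {lineno}: expected >= 12 tabular columns, got {len(cols)}"
            )
        try:
            sstart = int(cols[_SSTART])
            send = int(cols[_SEND])
            evalue = float(cols[_EVALUE])
            bit = float(cols[_BIT])
        except ValueError as exc:
            raise FormatError(f"row {lineno}: non-numeric field ({exc})") from exc
        if sstart <= send:
            start, end, strand = sstart - 1, send, "+"
        else:
            start, end, strand = send - 1, sstart, "-"
        hits.append(
            ElementHit(
                character=character,
                subject_accession=cols[_SSEQID],
                start=start,
                end=end,
                strand=strand,
                evalue=evalue,
                bit_score=bit,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# query specs


def load_query(path: str | Path) -> QuerySpec:
    """Load a query spec from TSV or JSON (chosen by extension).

    TSV: header ``label  strand  feature_id``, optional directive lines
    ``# source_accession=...`` and ``# span=START-END`` (0-based
    half-open).
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
        elements = [
            QueryElement(e["label"], e.get("strand", "+"), e.get("feature_id"))
            for e in data["elements"]
        ]
        span = tuple(data["span"]) if data.get("span") else None
        return QuerySpec(elements, data.get("source_accession", ""), span)

    source = ""
    span = None
    rows: list[QueryElement] = []
    header_seen = False
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            directive = line.lstrip("#").strip()
            if directive.startswith("source_accession="):
                source = directive.split("=", 1)[1]
            elif directive.startswith("span="):
                lo, hi = directive.split("=", 1)[1].split("-")
                span = (int(lo), int(hi))
            continue
        cols = line.split("\t")
        if not header_seen:
            header_seen = True
            if cols[0].lower() == "label":
                continue
        rows.append(
            QueryElement(
                cols[0],
                cols[1] if len(cols) > 1 and cols[1] else "+",
                cols[2] if len(cols) > 2 and cols[2] else None,
            )
        )
    return QuerySpec(rows, source, span)


def write_query(query: QuerySpec, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = {
            "source_accession": query.source_accession,
            "span": list(query.span) if query.span else None,
            "elements": [
                {"label": e.label, "strand": e.strand, "feature_id": e.feature_id}
                for e in query.elements
            ],
        }
        path.write_text(json.dumps(data, indent=2) + "\n")
        return
    lines = ["label\tstrand\tfeature_id"]
    if query.source_accession:
        lines.insert(0, f"# source_accession={query.source_accession}")
    if query.span:
        lines.insert(
            1 if query.source_accession else 0,
            f"# span={query.span[0]}-{query.span[1]}",
        )
    for e in query.elements:
        lines.append(f"{e.label}\t{e.strand}\t{e.feature_id or ''}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# hit export

_HIT_TSV_COLUMNS = [
    "accession", "start", "end", "orientation", "score", "base",
    "deletions", "gap_penalty_total", "order_breakpoints",
    "direction_flips", "organizational_homology", "meH",
    "characters", "strands", "nonscoring",
]


def write_hits(hits: Sequence, out_dir: str | Path, stem: str = "hits") -> dict[str, Path]:
    """Export scored arrangement hits as TSV, JSON and BED.

    The JSON export is loss-less (round-trips through
    :func:`read_hits_json`); BED uses 0-based half-open intervals with
    the score column clamped to integer [0, 1000].
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tsv": out_dir / f"{stem}.tsv",
        "json": out_dir / f"{stem}.json",
        "bed": out_dir / f"{stem}.bed",
    }

    rows = []
    for h in hits:
        d = h.to_dict()
        rows.append(d)
    paths["json"].write_text(json.dumps(rows, indent=2) + "\n")

    tsv_lines = ["\t".join(_HIT_TSV_COLUMNS)]
    bed_lines = []
    for h, d in zip(hits, rows):
        b = d["breakdown"]
        tsv_lines.append(
            "\t".join(
                str(x)
                for x in [
                    d["accession"], d["start"], d["end"], d["orientation"],
                    b["score"], b["base"], b["deletions"],
                    b["gap_penalty_total"], b["order_breakpoints"],
                    b["direction_flips"],
                    f"{d['organizational_homology']:.6g}",
                    f"{d['meH']:.6g}" if d["meH"] is not None else "",
                    ",".join(o["character"] for o in d["occurrences"]),
                    ",".join(o["strand"] for o in d["occurrences"]),
                    ",".join(o["character"] for o in d["nonscoring"]),
                ]
            )
        )
        bed_score = max(0, min(1000, int(round(b["score"] * 100))))
        name = "|".join(o["character"] for o in d["occurrences"])
        strand = "+" if d["orientation"] == "forward" else "-"
        bed_lines.append(
            f"{d['accession']}\t{d['start']}\t{d['end']}\t{name}\t{bed_score}\t{strand}"
        )
    paths["tsv"].write_text("\n".join(tsv_lines) + "\n")
    paths["bed"].write_text("\n".join(bed_lines) + ("\n" if bed_lines else ""))
    return paths


def read_hits_json(path: str | Path) -> list:
    """Re-read a JSON hits export into LmnastHit objects."""
    from .search import LmnastHit  # local import avoids a module cycle

    data = json.loads(Path(path).read_text())
    return [LmnastHit.from_dict(d) for d in data]
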