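"""Synthetic fixtures: replicons with planted arrangement homologs.

The generator emulates the tool's three inputs — annotated nucleotide
records (GenBank), per-character BLAST tabular results, and query specs
— without any downloads. A query's gene arrangement is planted into a
simulated background replicon and then subjected to a controlled edit
model (character deletion, uncharactered-gene insertion, inversion,
transposition, divergent-operon split, GC shift, pseudogenization,
synonym decoys), with a ground-truth ledger recording what a correct
search should recover.

The sequence model is deliberately simple — independent bases at a
target GC, no substitution process — because the search operates on
annotation and hit coordinates, not on the sequence itself; only the GC
profile analytics read bases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .iolib import GeneFeature, QuerySpec, Replicon

EDIT_KINDS = (
    "delete_char",
    "insert_genes",
    "invert_char",
    "transpose_char",
    "split_divergent",
    "gc_shift",
    "pseudogenize_char",
    "synonym_decoy",
)

# fixed vocabulary so decoy names and synonym fixtures are reproducible
_WORDS = [
    "dnaQ", "recJ", "mutL", "pheS", "glnA", "aroK", "trpB", "hisC",
    "purM", "pyrF", "thiE", "ribA", "folC", "panB", "bioD", "nadE",
    "cysK", "metH", "serB", "lysA", "argG", "leuD", "ilvC", "valS",
    "gltX", "proC", "tyrA", "tatC", "secY", "ffh", "ftsZ", "minD",
    "mreB", "rodA", "murG", "ddlB", "uppS", "ispB", "hemL", "cobA",
]


@dataclass(frozen=True)
class EditEvent:
    """One planted mutation of the inserted system."""

    kind: str
    target: Optional[str] = None  # character label, where applicable
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EDIT_KINDS:
            raise ValueError(f"unknown edit kind {self.kind!r}")


@dataclass
class _Gene:
    """Symbolic gene prior to sequence realization."""

    name: str
    length: int
    strand: str
    gc: float
    pseudo: bool = False
    product: Optional[str] = None
    character: Optional[str] = None  # query label when planted
    divergence: float = 0.0


@dataclass
class FixtureTruth:
    """Ground truth for one planted fixture."""

    accession: str
    system_span: tuple[int, int]
    edits: list[EditEvent]
    #: post-edit cassette: (character-or-None, strand, pseudo) in order
    cassette: list[tuple[Optional[str], str, bool]]
    #: per planted character: (start, end, strand), post-edit coordinates
    character_intervals: dict
    query_labels: list[str]
    query_strands: list[str]

    def present_characters(self, mode: str = "stringent") -> list[str]:
        out = []
        for char, _strand, pseudo in self.cassette:
            if char is None:
                continue
            if pseudo and mode == "stringent":
                continue
            out.append(char)
        return out

    def expected_breakdown(self, params, mode: str = "stringent") -> dict:
        """Best achievable score, by exhaustive subset maximization.

        Works on the symbolic cassette: intervening genes are cassette
        members not in the kept subset; order and direction are read
        against the query pattern exactly as the scorer defines them.
        """
        return _symbolic_best(
            self.query_labels, self.query_strands, self.cassette, params, mode
        )


def _symbolic_best(
    qlabels: Sequence[str],
    qstrands: Sequence[str],
    cassette: Sequence[tuple[Optional[str], str, bool]],
    params,
    mode: str,
) -> dict:
    import itertools

    n = len(qlabels)
    qindex = {l: i for i, l in enumerate(qlabels)}
    qrel = dict(zip(qlabels, qstrands))
    usable = [
        i
        for i, (char, _s, pseudo) in enumerate(cassette)
        if char is not None and not (pseudo and mode == "stringent")
    ]
    best = None
    for r in range(2, len(usable) + 1):
        for sel in itertools.combinations(usable, r):
            labels = [cassette[i][0] for i in sel]
            if len(set(labels)) != len(labels):
                continue
            deletions = n - r
            gap_total = 0.0
            gap_runs = []
            for a, b in zip(sel, sel[1:]):
                g = sum(
                    1 for j in range(a + 1, b)
                )  # every skipped cassette member is an annotated gene
                gap_runs.append(g)
                if g >= 1:
                    gap_total += params.gap_open + params.gap_extend * (g - 1)
            order = sorted(labels, key=lambda l: qindex[l])
            rank = {l: k + 1 for k, l in enumerate(order)}
            seq = [rank[l] for l in labels]

            def bps(s):
                return sum(1 for x, y in zip(s, s[1:]) if y - x != 1)

            bp_f, bp_r = bps(seq), bps(seq[::-1])
            bp = min(bp_f, bp_r)
            reading = seq if bp_f <= bp_r else seq[::-1]
            reading_idx = list(sel) if bp_f <= bp_r else list(sel)[::-1]
            evaluated = []
            seen = set()
            for i, (x, y) in enumerate(zip(reading, reading[1:])):
                if y - x == 1:
                    for j in (i, i + 1):
                        if j not in seen:
                            seen.add(j)
                            evaluated.append(reading_idx[j])
            k = sum(
                1
                for j in evaluated
                if cassette[j][1] != qrel[cassette[j][0]]
            )
            flips = min(k, len(evaluated) - k)
            score = (
                n
                - deletions
                - gap_total
                - params.rearrangement_penalty * bp
                - params.direction_penalty * flips
            )
            key = (score, r)
            if best is None or key > best["_key"]:
                best = {
                    "_key": key,
                    "score": score,
                    "deletions": deletions,
                    "gap_penalty_total": gap_total,
                    "order_breakpoints": bp,
                    "direction_flips": flips,
                    "characters": labels,
                }
    if best is None:
        return {
            "score": float("-inf"),
            "deletions": n,
            "gap_penalty_total": 0.0,
            "order_breakpoints": 0,
            "direction_flips": 0,
            "characters": [],
        }
    best.pop("_key")
    return best


# ---------------------------------------------------------------------------
# sequence and replicon realization


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("AGCT"), size=length, p=p))


def _realize(
    accession: str,
    genes: Sequence[_Gene],
    rng: np.random.Generator,
    background_gc: float,
    intergenic_mean: int = 150,
) -> Replicon:
    seq_parts: list[str] = []
    features: list[GeneFeature] = []
    pos = 0
    for gi, g in enumerate(genes):
        spacer = int(rng.integers(intergenic_mean // 2, intergenic_mean * 2))
        seq_parts.append(random_sequence(spacer, background_gc, rng))
        pos += spacer
        seq_parts.append(random_sequence(g.length, g.gc, rng))
        fid = f"{accession}_{gi + 1:04d}"
        for kind in ("gene", "CDS"):
            features.append(
                GeneFeature(
                    feature_id=fid,
                    kind=kind,
                    start=pos,
                    end=pos + g.length,
                    strand=g.strand,
                    gene_name=g.name,
                    product=g.product,
                    pseudo=g.pseudo,
                )
            )
        pos += g.length
    tail = int(rng.integers(intergenic_mean // 2, intergenic_mean * 2))
    seq_parts.append(random_sequence(tail, background_gc, rng))
    pos += tail
    return Replicon(
        accession=accession,
        length=pos,
        features=features,
        sequence="".join(seq_parts),
        circular=False,
    )


def make_replicon(
    n_genes: int,
    mean_gene_len: int = 900,
    background_gc: float = 0.5,
    rng_seed: int = 0,
    accession: Optional[str] = None,
) -> Replicon:
    """A background replicon of non-overlapping random genes."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(rng_seed)
    accession = accession or f"SYN{rng_seed:06d}"
    genes = []
    for i in range(n_genes):
        length = max(150, int(rng.normal(mean_gene_len, mean_gene_len / 5)))
        name = f"{_WORDS[i % len(_WORDS)]}{'' if i < len(_WORDS) else i}"
        genes.append(
            _Gene(
                name=name,
                length=length,
                strand="+" if rng.random() < 0.5 else "-",
                gc=background_gc,
                product=f"{name} protein",
            )
        )
    return _realize(accession, genes, rng, background_gc)


# ---------------------------------------------------------------------------
# planting


def _system_genes(
    query: QuerySpec, gene_len: int, gc: float
) -> list[_Gene]:
    return [
        _Gene(
            name=e.label,
            length=gene_len,
            strand=e.strand,  # query strands are relative to element 1
            gc=gc,
            product=f"{e.label} homolog",
            character=e.label,
        )
        for e in query.elements
    ]


def _apply_edits(
    cassette: list[_Gene],
    edits: Sequence[EditEvent],
    rng: np.random.Generator,
    gc: float,
    query_labels: Sequence[str] = (),
) -> tuple[list[_Gene], list[_Gene]]:
    """Apply edits in declared order; returns (cassette, decoys)."""

    decoys: list[_Gene] = []
    deleted: set[str] = set()
    qpos = {l: k for k, l in enumerate(query_labels)}

    def is_sorted(genes: Sequence[_Gene]) -> bool:
        chars = [g.character for g in genes if g.character in qpos]
        ranks = [qpos[c] for c in chars]
        return ranks == sorted(ranks) or ranks == sorted(ranks, reverse=True)

    def unambiguous(genes: Sequence[_Gene]) -> bool:
        # a transposition whose signature survives trimming: no single
        # end-element drop restores query order (which would let the
        # trimmer read the hit as a plain deletion instead)
        if is_sorted(genes):
            return False
        return not (is_sorted(genes[1:]) or is_sorted(genes[:-1]))

    def locate(char: Optional[str]) -> int:
        if char in deleted:
            raise ValueError(f"edit references deleted character {char!r}")
        for i, g in enumerate(cassette):
            if g.character == char:
                return i
        raise ValueError(f"edit references unknown character {char!r}")

    for ev in edits:
        if ev.kind == "delete_char":
            i = locate(ev.target)
            deleted.add(ev.target)
            cassette.pop(i)
        elif ev.kind == "insert_genes":
            i = locate(ev.target)
            g = int(ev.params.get("g", 1))
            inserted = [
                _Gene(
                    name=f"ins{_WORDS[(i + k) % len(_WORDS)]}",
                    length=700,
                    strand="+" if rng.random() < 0.5 else "-",
                    gc=gc,
                    product="inserted uncharactered protein",
                )
                for k in range(g)
            ]
            cassette[i + 1 : i + 1] = inserted
        elif ev.kind == "invert_char":
            i = locate(ev.target)
            cassette[i] = replace(
                cassette[i],
                strand="-" if cassette[i].strand == "+" else "+",
            )
        elif ev.kind == "transpose_char":
            i = locate(ev.target)
            g = cassette.pop(i)
            j = ev.params.get("to")
            if j is None:
                choices = [k for k in range(len(cassette) + 1) if k != i]
                safe = [
                    k
                    for k in choices
                    if unambiguous(cassette[:k] + [g] + cassette[k:])
                ]
                j = int(rng.choice(safe or choices))
            cassette.insert(j, g)
        elif ev.kind == "split_divergent":
            i = locate(ev.target)
            # flip the operon upstream of the split so it reads away
            for k in range(i):
                cassette[k] = replace(
                    cassette[k],
                    strand="-" if cassette[k].strand == "+" else "+",
                )
        elif ev.kind == "gc_shift":
            delta = float(ev.params.get("delta", -0.2))
            for k, g in enumerate(cassette):
                if g.character is not None or ev.params.get("all", True):
                    cassette[k] = replace(
                        g, gc=float(np.clip(g.gc + delta, 0.05, 0.95))
                    )
        elif ev.kind == "pseudogenize_char":
            i = locate(ev.target)
            cassette[i] = replace(cassette[i], pseudo=True)
        elif ev.kind == "synonym_decoy":
            annotation = ev.params.get(
                "annotation", f"{ev.target} family protein"
            )
            decoys.append(
                _Gene(
                    name=f"dec{ev.target}",
                    length=800,
                    strand="+",
                    gc=gc,
                    product=annotation,
                )
            )
    return cassette, decoys


def plant_system(
    replicon: Replicon,
    query: QuerySpec,
    edits: Sequence[EditEvent] = (),
    rng_seed: int = 0,
    gene_len: int = 900,
    spacer: int = 120,
    system_gc: Optional[float] = None,
) -> tuple[Replicon, FixtureTruth]:
    """Insert the query's arrangement into a replicon, then edit it.

    The system cassette goes into a random intergenic locus of the
    (sequence-bearing) background replicon; edits apply in declared
    order, and the truth ledger records post-edit coordinates and the
    symbolic cassette from which expected scores derive.
    """
    if replicon.sequence is None:
        raise ValueError("background replicon must carry a sequence")
    rng = np.random.default_rng(rng_seed)
    gc = (
        system_gc
        if system_gc is not None
        else _sequence_gc(replicon.sequence)
    )
    cassette = _system_genes(query, gene_len, gc)
    cassette, decoys = _apply_edits(
        cassette, edits, rng, gc, query_labels=query.labels
    )

    units = replicon.gene_units()
    # a gap between consecutive background genes, away from the ends
    if len(units) < 2:
        raise ValueError("background replicon needs >= 2 genes")
    gap_idx = int(rng.integers(1, len(units) - 1))
    insert_at = units[gap_idx].start - 10

    block_parts: list[str] = []
    block_feats: list[GeneFeature] = []
    offset = 0
    char_intervals: dict = {}
    for gi, g in enumerate(cassette):
        sp = spacer + int(rng.integers(0, spacer))
        block_parts.append(random_sequence(sp, gc, rng))
        offset += sp
        block_parts.append(random_sequence(g.length, g.gc, rng))
        fid = f"{replicon.accession}_sys{gi + 1:02d}"
        for kind in ("gene", "CDS"):
            block_feats.append(
                GeneFeature(
                    feature_id=fid,
                    kind=kind,
                    start=offset,
                    end=offset + g.length,
                    strand=g.strand,
                    gene_name=g.name,
                    product=g.product,
                    pseudo=g.pseudo,
                )
            )
        if g.character is not None:
            char_intervals[g.character] = (
                insert_at + offset,
                insert_at + offset + g.length,
                g.strand,
            )
        offset += g.length
    block_parts.append(random_sequence(spacer, gc, rng))
    offset += spacer
    block = "".join(block_parts)

    new_seq = (
        replicon.sequence[:insert_at] + block + replicon.sequence[insert_at:]
    )
    shifted: list[GeneFeature] = []
    for f in replicon.features:
        if f.start >= insert_at:
            shifted.append(
                replace(f, start=f.start + offset, end=f.end + offset)
            )
        else:
            shifted.append(f)
    planted = [
        replace(f, start=f.start + insert_at, end=f.end + insert_at)
        for f in block_feats
    ]
    out = Replicon(
        accession=replicon.accession,
        length=len(new_seq),
        features=shifted + planted,
        sequence=new_seq,
        circular=replicon.circular,
    )

    # decoy loci go well away from the system
    for d in decoys:
        out = _splice_gene(out, d, rng)

    truth = FixtureTruth(
        accession=out.accession,
        system_span=(insert_at, insert_at + offset),
        edits=list(edits),
        cassette=[(g.character, g.strand, g.pseudo) for g in cassette],
        character_intervals=char_intervals,
        query_labels=list(query.labels),
        query_strands=[e.strand for e in query.elements],
    )
    return out, truth


def _splice_gene(
    replicon: Replicon, gene: _Gene, rng: np.random.Generator
) -> Replicon:
    # appended at the record end, far from any planted system, so that
    # previously recorded truth coordinates stay valid
    at = replicon.length
    block = (
        random_sequence(6000, gene.gc, rng)
        + random_sequence(gene.length, gene.gc, rng)
        + random_sequence(100, gene.gc, rng)
    )
    feats = []
    fid = f"{replicon.accession}_{gene.name}"
    for kind in ("gene", "CDS"):
        feats.append(
            GeneFeature(
                feature_id=fid,
                kind=kind,
                start=at + 6000,
                end=at + 6000 + gene.length,
                strand=gene.strand,
                gene_name=gene.name,
                product=gene.product,
                pseudo=gene.pseudo,
            )
        )
    return Replicon(
        accession=replicon.accession,
        length=replicon.length + len(block),
        features=list(replicon.features) + feats,
        sequence=(replicon.sequence or "") + block,
        circular=replicon.circular,
    )


def _sequence_gc(seq: str) -> float:
    s = seq.upper()
    ok = sum(s.count(b) for b in "ACGT")
    return (s.count("G") + s.count("C")) / ok if ok else 0.5


# ---------------------------------------------------------------------------
# BLAST emission


@dataclass
class BlastNoiseModel:
    """Monotone bit-score model: bit = min + (max-min) * (1 - divergence)."""

    max_bit: float = 250.0
    min_bit: float = 30.0
    bit_sd: float = 0.0
    evalue_planted: float = 1e-50
    n_decoys: int = 3
    decoy_evalue: float = 0.5


def emit_blast_for(
    replicon: Replicon,
    query: QuerySpec,
    noise: Optional[BlastNoiseModel] = None,
    rng_seed: int = 0,
) -> dict[str, str]:
    """Per-character BLAST tabular text for a planted replicon.

    Planted characters (features named after the query label, pseudo or
    not) are emitted below the E-value threshold with bits from the
    noise model; decoy rows above the threshold exercise the filter and
    anchor each file's minimum bit score.
    """
    noise = noise or BlastNoiseModel()
    rng = np.random.default_rng(rng_seed)
    out: dict[str, str] = {}
    genes = [f for f in replicon.features if f.kind == "gene"]
    for e in query.elements:
        rows = []
        for f in genes:
            if f.gene_name != e.label:
                continue
            div = 0.0
            bit = noise.min_bit + (noise.max_bit - noise.min_bit) * (1 - div)
            if noise.bit_sd:
                bit = float(
                    np.clip(
                        bit + rng.normal(0, noise.bit_sd),
                        noise.min_bit,
                        noise.max_bit,
                    )
                )
            sstart, send = f.start + 1, f.end
            if f.strand == "-":
                sstart, send = send, sstart
            rows.append(_row(e.label, replicon.accession, sstart, send,
                             noise.evalue_planted, bit))
        for _ in range(noise.n_decoys):
            pos = int(rng.integers(0, max(1, replicon.length - 500)))
            bit = noise.min_bit + float(rng.random() * 10)
            rows.append(_row(e.label, replicon.accession, pos + 1, pos + 400,
                             noise.decoy_evalue, bit))
        out[e.label] = "\n".join(rows) + ("\n" if rows else "")
    return out


def _row(q: str, s: str, sstart: int, send: int, evalue: float, bit: float) -> str:
    return "\t".join(
        str(x)
        for x in [q, s, "85.0", abs(send - sstart) + 1, 10, 1, 1,
                  abs(send - sstart) + 1, sstart, send,
                  f"{evalue:.2g}", f"{bit:.1f}"]
    )


# ---------------------------------------------------------------------------
# fixture emission (GenBank + tabular + truth)


def write_genbank(replicon: Replicon, path: str | Path) -> None:
    """Serialize a replicon as a GenBank flat file."""
    record = SeqRecord(
        Seq(replicon.sequence or "N" * replicon.length),
        id=replicon.accession,
        name=replicon.accession[:16],
        description="synthetic replicon",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if replicon.circular else "linear",
        },
    )
    for f in replicon.features:
        quals = {"locus_tag": [f.feature_id]}
        if f.gene_name:
            quals["gene"] = [f.gene_name]
        if f.product and f.kind == "CDS":
            quals["product"] = [f.product]
        if f.pseudo:
            quals["pseudo"] = [""]
        record.features.append(
            SeqFeature(
                FeatureLocation(f.start, f.end, 1 if f.strand == "+" else -1),
                type=f.kind if f.kind != "other" else "misc_feature",
                qualifiers=quals,
            )
        )
    with open(path, "w") as fh:
        SeqIO.write(record, fh, "genbank")


def write_fixture(
    out_dir: str | Path,
    replicon: Replicon,
    blast_texts: dict[str, str],
    truth: FixtureTruth,
) -> None:
    out_dir = Path(out_dir)
    (out_dir / "records").mkdir(parents=True, exist_ok=True)
    (out_dir / "blast").mkdir(parents=True, exist_ok=True)
    write_genbank(replicon, out_dir / "records" / f"{replicon.accession}.gbk")
    for char, text in blast_texts.items():
        # one tabular file per character spans every record searched
        with open(out_dir / "blast" / f"{char}.tsv", "a") as fh:
            fh.write(text)
    truth_path = out_dir / "truth.json"
    existing = (
        json.loads(truth_path.read_text()) if truth_path.exists() else []
    )
    existing.append(
        {
            "accession": truth.accession,
            "system_span": list(truth.system_span),
            "edits": [
                {"kind": e.kind, "target": e.target, "params": e.params}
                for e in truth.edits
            ],
            "cassette": [list(c) for c in truth.cassette],
            "character_intervals": {
                k: list(v) for k, v in truth.character_intervals.items()
            },
            "query_labels": truth.query_labels,
            "query_strands": truth.query_strands,
        }
    )
    truth_path.write_text(json.dumps(existing, indent=2) + "\n")
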