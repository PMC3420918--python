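"""Quantitative measures around arrangement hits.

* **mean element homology (meH)** — per-character bit scores min-max
  normalized against each character's entire BLAST result file and
  averaged over a hit's scoring elements; 1 means exact likeness, 0 the
  least observed similarity.
* **organizational homology** — arrangement-level similarity: the hit
  score divided by the query's self-score ``n``.
* **coincidence matrices** — for each character pair, how often hits
  containing the row character also contain the column character,
  normalized by the row character's hit total.
* **GC profiles** — sliding-window fractional GC with ambiguous bases
  excluded, plus a dip statistic for localized GC anomalies such as
  conserved intergenic regulatory regions or recently transferred DNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# mean element homology


@dataclass(frozen=True)
class BlastStats:
    """Per-character bit-score extrema over an entire BLAST result."""

    min_bit: dict
    max_bit: dict

    def __post_init__(self) -> None:
        for c in self.min_bit:
            if self.max_bit[c] < self.min_bit[c]:
                raise ValueError(f"{c}: max_bit < min_bit")

    @classmethod
    def from_hits(cls, hits: Sequence) -> "BlastStats":
        """Extrema from raw (unfiltered) hits grouped by character."""
        lo: dict = {}
        hi: dict = {}
        for h in hits:
            b = h.bit_score
            c = h.character
            lo[c] = b if c not in lo else min(lo[c], b)
            hi[c] = b if c not in hi else max(hi[c], b)
        return cls(lo, hi)

    def normalized(self, character: str, bit: float) -> float:
        if character not in self.min_bit:
            raise KeyError(f"no BLAST statistics for character {character!r}")
        lo, hi = self.min_bit[character], self.max_bit[character]
        if hi == lo:
            # a single observed bit score: self-identity reads as exact
            return 1.0
        return float(np.clip((bit - lo) / (hi - lo), 0.0, 1.0))


def mean_element_homology(occurrences: Sequence, stats: BlastStats) -> float:
    """Average normalized bit score over scoring occurrences."""
    scoring = [o for o in occurrences if not getattr(o, "nonscoring", False)]
    if not scoring:
        raise ValueError("no scoring occurrences to average")
    return float(
        np.mean([stats.normalized(o.character, o.bit_score) for o in scoring])
    )


def compute_meH(hit, stats: BlastStats) -> float:
    """Mean element homology of a hit; nonscoring synonyms are excluded."""
    return mean_element_homology(hit.occurrences, stats)


def organizational_homology(hit, query) -> float:
    """Hit score over the query's self-score (the query length)."""
    return hit.breakdown.score / len(query)


# ---------------------------------------------------------------------------
# coincidence matrices


@dataclass
class CoincidenceMatrix:
    """Character co-occurrence counts and row-normalized frequencies.

    ``counts[i, j]`` is the number of hits containing both the row and
    the column character; ``row_totals[i]`` (the "(#)" column of the
    heat maps) the number containing the row character at all;
    ``normalized`` divides each row by its total, so the diagonal is 1
    wherever the row total is positive. Counts are symmetric; the
    normalized matrix generally is not.
    """

    labels: list[str]
    counts: np.ndarray
    row_totals: np.ndarray
    normalized: np.ndarray

    def to_frame(self, which: str = "normalized") -> pd.DataFrame:
        mat = getattr(self, which)
        df = pd.DataFrame(mat, index=self.labels, columns=self.labels)
        df.insert(0, "(#)", self.row_totals)
        return df

    def write_tsv(self, path: str | Path, which: str = "normalized") -> None:
        self.to_frame(which).to_csv(path, sep="\t", float_format="%.6g")


def _label_sets(hits: Iterable) -> list[frozenset]:
    sets = []
    for h in hits:
        if hasattr(h, "occurrences"):
            sets.append(frozenset(o.character for o in h.occurrences))
        else:
            sets.append(frozenset(h))
    return sets


def coincidence_counts(hits: Sequence, labels: Sequence[str]) -> CoincidenceMatrix:
    """Co-occurrence of characters across hits (or plain label sets)."""
    labels = list(labels)
    idx = {l: i for i, l in enumerate(labels)}
    k = len(labels)
    counts = np.zeros((k, k), dtype=int)
    for s in _label_sets(hits):
        present = [idx[l] for l in s if l in idx]
        for i in present:
            for j in present:
                counts[i, j] += 1
    totals = np.diag(counts).copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = np.where(
            totals[:, None] > 0, counts / np.maximum(totals[:, None], 1), 0.0
        )
    return CoincidenceMatrix(labels, counts, totals, normalized)


def theoretical_coincidence(
    fragments: Sequence[Iterable[str]], labels: Optional[Sequence[str]] = None
) -> CoincidenceMatrix:
    """Coincidence of an idealized, evenly distributed fragment set."""
    frag_sets = [frozenset(f) for f in fragments]
    if labels is None:
        labels = sorted(set().union(*frag_sets)) if frag_sets else []
    return coincidence_counts(frag_sets, labels)


def difference_matrix(
    observed: CoincidenceMatrix, theoretical: CoincidenceMatrix
) -> np.ndarray:
    """Observed minus theoretical normalized frequencies, in [-1, 1]."""
    if observed.labels != theoretical.labels:
        raise ValueError(
            f"label mismatch: {observed.labels} vs {theoretical.labels}"
        )
    return observed.normalized - theoretical.normalized


# ---------------------------------------------------------------------------
# GC profiles


@dataclass
class GcProfile:
    """Sliding-window fractional GC along a sequence."""

    window: int
    step: int
    positions: np.ndarray  # window start coordinates, strictly increasing
    fractions: np.ndarray  # GC fraction per window, in [0, 1] (NaN if all-N)

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"position": self.positions, "gc_fraction": self.fractions}
        ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def gc_profile(sequence: str, window: int = 200, step: int = 50) -> GcProfile:
    """Windowed GC content; ambiguous bases are excluded entirely.

    Each window's fraction is GC / (unambiguous bases); a window of
    only ambiguous bases yields NaN.
    """
    if window > len(sequence):
        raise ValueError(
            f"window {window} exceeds sequence length {len(sequence)}"
        )
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    is_gc = np.isin(arr, np.frombuffer(b"GC", dtype=np.uint8)).astype(np.int64)
    is_acgt = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8)).astype(np.int64)
    cum_gc = np.concatenate([[0], np.cumsum(is_gc)])
    cum_ok = np.concatenate([[0], np.cumsum(is_acgt)])
    starts = np.arange(0, len(sequence) - window + 1, step)
    gc = cum_gc[starts + window] - cum_gc[starts]
    ok = cum_ok[starts + window] - cum_ok[starts]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(ok > 0, gc / np.maximum(ok, 1), np.nan)
    return GcProfile(window, step, starts, frac)


@dataclass(frozen=True)
class GcDipStats:
    dip: float  # flank mean minus region minimum
    region_min: float
    region_min_position: int
    flank_mean: float


def detect_gc_dip(
    profile: GcProfile, region: tuple[int, int], flank: int
) -> GcDipStats:
    """Depth of a localized GC dip inside ``region`` against its flanks.

    The statistic is the mean GC of windows within ``flank`` bp on
    either side of the region minus the minimum window GC inside it.
    """
    lo, hi = region
    pos = profile.positions
    ends = pos + profile.window
    inside = (pos < hi) & (ends > lo)
    left = (ends > lo - flank) & (ends <= lo)
    right = (pos >= hi) & (pos < hi + flank)
    if not inside.any():
        raise ValueError("no profile windows overlap the region")
    if not (left.any() or right.any()):
        raise ValueError("no profile windows fall in the flanks")
    region_frac = profile.fractions[inside]
    imin = int(np.nanargmin(region_frac))
    region_min = float(region_frac[imin])
    flank_mean = float(np.nanmean(profile.fractions[left | right]))
    return GcDipStats(
        dip=flank_mean - region_min,
        region_min=region_min,
        region_min_position=int(pos[inside][imin]),
        flank_mean=flank_mean,
    )
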