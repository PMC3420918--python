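"""Visual analytics as data exports plus optional rendered figures.

Three report kinds mirror the standard ways of looking at arrangement
hits: 2D similarity plots (mean element homology vs organizational
homology, dot size = hit multiplicity), coincidence heat maps, and
per-hit trackback series (query index vs hit ordinal, where deletions,
insertions, rearrangements and redirections appear as gaps,
discontinuities and flipped diagonals).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import CoincidenceMatrix


@dataclass(frozen=True)
class TrackbackPoint:
    query_index: int  # 1-based position in the query
    hit_ordinal: int  # 1-based position in the hit, reading orientation
    orientation: str  # '+' codirectional with expectation, '-' redirected
    gap_before: str  # 'deletion' | 'insertion' | 'none'


@dataclass
class TrackbackSeries:
    accession: str
    points: list[TrackbackPoint]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "query_index": p.query_index,
                    "hit_ordinal": p.hit_ordinal,
                    "orientation": p.orientation,
                    "gap_before": p.gap_before,
                }
                for p in self.points
            ]
        )


@dataclass(frozen=True)
class SimilarityPoint:
    organizational_homology: float
    meH: float
    multiplicity: int
    annotation_label: Optional[str] = None


def trackback(hit, query) -> TrackbackSeries:
    """Query-index vs hit-ordinal series for one hit.

    A perfect hit is the identity diagonal; an absent query character
    shows as a horizontal (deletion) gap, a run of intervening genes as
    a vertical (insertion) gap, and a redirected character flips its
    point's orientation.
    """
    qindex = {e.label: i + 1 for i, e in enumerate(query.elements)}
    occs = list(hit.occurrences)
    if hit.orientation == "reverse":
        occs = occs[::-1]
    gap_runs = list(hit.breakdown.gap_runs)
    if hit.orientation == "reverse":
        gap_runs = gap_runs[::-1]
    flipped = set(hit.breakdown.flipped_characters)

    points: list[TrackbackPoint] = []
    prev_qi: Optional[int] = None
    for ordinal, occ in enumerate(occs, start=1):
        qi = qindex[occ.character]
        gap = "none"
        if prev_qi is not None and abs(qi - prev_qi) > 1:
            gap = "deletion"
        elif ordinal > 1 and gap_runs[ordinal - 2] > 0:
            gap = "insertion"
        points.append(
            TrackbackPoint(
                query_index=qi,
                hit_ordinal=ordinal,
                orientation="-" if occ.character in flipped else "+",
                gap_before=gap,
            )
        )
        prev_qi = qi
    return TrackbackSeries(hit.accession, points)


def similarity_points(hits: Sequence) -> list[SimilarityPoint]:
    """Bin hits by identical (organizational homology, meH) coordinates."""
    bins: dict[tuple[float, float, Optional[str]], int] = {}
    for h in hits:
        meh = h.meH if h.meH is not None else float("nan")
        key = (
            round(h.organizational_homology, 6),
            round(meh, 6),
            getattr(h, "annotation_label", None),
        )
        bins[key] = bins.get(key, 0) + 1
    return [
        SimilarityPoint(org, meh, mult, label)
        for (org, meh, label), mult in sorted(
            bins.items(), key=lambda kv: (kv[0][0], kv[0][1], str(kv[0][2]))
        )
    ]


def write_similarity_tsv(points: Sequence[SimilarityPoint], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "organizational_homology": p.organizational_homology,
                "meH": p.meH,
                "multiplicity": p.multiplicity,
                "annotation_label": p.annotation_label or "",
            }
            for p in points
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def render(report_kind: str, data, path: str | Path) -> Path:
    """Render a report to an image file (PNG/SVG by extension).

    ``data`` is a list of :class:`SimilarityPoint` for ``similarity``, a
    :class:`CoincidenceMatrix` for ``coincidence``, or a
    :class:`TrackbackSeries` for ``trackback``. Rendering is
    deterministic given the data. Heat maps use a linear 0 -> 1 color
    scale.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 4.2))
    if report_kind == "similarity":
        xs = [p.organizational_homology for p in data]
        ys = [p.meH for p in data]
        sizes = [20 * p.multiplicity for p in data]
        ax.plot([0, 1], [0, 1], "--", color="0.6", lw=0.8)  # 1:1 line
        ax.scatter(xs, ys, s=sizes, color="0.4", alpha=0.7, edgecolors="none")
        ax.set_xlabel("organizational homology")
        ax.set_ylabel("mean element homology")
        ax.set_xlim(-0.02, 1.05)
        ax.set_ylim(-0.02, 1.05)
    elif report_kind == "coincidence":
        mat: CoincidenceMatrix = data
        im = ax.imshow(mat.normalized, vmin=0.0, vmax=1.0, cmap="viridis")
        ax.set_xticks(range(len(mat.labels)), mat.labels, rotation=90)
        ax.set_yticks(
            range(len(mat.labels)),
            [f"{l} ({t})" for l, t in zip(mat.labels, mat.row_totals)],
        )
        fig.colorbar(im, ax=ax, label="row-normalized coincidence (0-1 linear)")
    elif report_kind == "trackback":
        series: TrackbackSeries = data
        df = series.to_frame()
        ax.plot(
            df["hit_ordinal"], df["query_index"], "-", color="0.7", lw=0.8
        )
        for _, row in df.iterrows():
            marker = "v" if row["orientation"] == "-" else "^"
            color = {"deletion": "tab:red", "insertion": "tab:blue"}.get(
                row["gap_before"], "0.2"
            )
            ax.plot(
                row["hit_ordinal"], row["query_index"], marker, color=color
            )
        ax.set_xlabel("hit ordinal")
        ax.set_ylabel("query index")
        ax.set_title(series.accession)
    else:
        plt.close(fig)
        raise ValueError(f"unknown report kind {report_kind!r}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
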