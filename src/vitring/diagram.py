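"""Circular composition diagrams as deterministic JSON and static SVG.

Each reference cluster with at least one assigned read becomes a dot on
the ring at the cluster's layout angle.  Dot *area* is proportional to
the cluster's relative read abundance (clamped to a visible range), and
the radial position encodes the mean top-hit identity of the cluster's
reads in discrete bands (100, >=97, >=94, >=90, >=80 %).  Taxon labels
sit outside the ring at their circular-mean angles.  Rendering is a pure
function of the spec: the same spec always produces identical bytes.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .phylo_layout import TaxonPosition
from .profiler import GenusProfile

#: lower identity bounds of the radial bands, innermost first
IDENTITY_BANDS = (100.0, 97.0, 94.0, 90.0, 80.0)

MIN_DOT_AREA = 20.0  # px^2
MAX_DOT_AREA = 2000.0  # px^2

_CANVAS = 800.0
_RING_RADIUS = 320.0
_BAND_STEP = 28.0


def identity_band(identity: float) -> int:
    """Index of the radial band for a top-hit identity (0 = innermost =
    exact match)."""
    for i, bound in enumerate(IDENTITY_BANDS):
        if identity >= bound:
            return i
    return len(IDENTITY_BANDS) - 1


@dataclass(frozen=True)
class DiagramPoint:
    label: str
    angle: Optional[float]  # None -> unplaced sector
    band: int
    area: float
    read_count: int
    taxon: str


@dataclass
class DiagramSpec:
    level: str  # "phylum" | "genus"
    points: list[DiagramPoint] = field(default_factory=list)
    ring_labels: list[tuple[str, float]] = field(default_factory=list)

    @property
    def total_reads(self) -> int:
        return sum(p.read_count for p in self.points)


def build_diagram(
    profile: GenusProfile,
    layout_angles: dict[str, float],
    level: str,
    taxa: Sequence[TaxonPosition] = (),
) -> DiagramSpec:
    """Turn a profile plus layout angles into a renderable spec.

    ``layout_angles`` maps reference (cluster) ids to angles from the
    tree-topology-scan layout.  Clusters missing from the layout are
    placed in an "unplaced" sector with a warning rather than dropped.
    """
    counts = profile.cluster_counts
    total = sum(counts.values())
    if total == 0:
        return DiagramSpec(level, [], [(t.taxon, t.angle) for t in taxa])
    # mean top-hit identity per cluster decides the radial band
    ident_sum: dict[str, float] = {}
    genus_of: dict[str, str] = {}
    for a in profile.assignments:
        ident_sum[a.ref_id] = ident_sum.get(a.ref_id, 0.0) + a.identity
        genus_of[a.ref_id] = a.genus
    points: list[DiagramPoint] = []
    for ref_id in sorted(counts):
        n = counts[ref_id]
        rel = n / total
        area = min(MAX_DOT_AREA, max(MIN_DOT_AREA, rel * MAX_DOT_AREA))
        angle = layout_angles.get(ref_id)
        if angle is None:
            warnings.warn(f"cluster {ref_id!r} missing from layout; "
                          f"placed in the unplaced sector")
        points.append(
            DiagramPoint(
                ref_id,
                angle,
                identity_band(ident_sum[ref_id] / n),
                area,
                n,
                genus_of[ref_id],
            )
        )
    return DiagramSpec(level, points, [(t.taxon, t.angle) for t in taxa])


def render_json(spec: DiagramSpec, path: str | Path) -> None:
    payload = {
        "level": spec.level,
        "identity_bands": list(IDENTITY_BANDS),
        "points": [asdict(p) for p in spec.points],
        "ring_labels": [
            {"taxon": t, "angle": a} for t, a in spec.ring_labels
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def load_diagram_json(path: str | Path) -> DiagramSpec:
    with open(path) as fh:
        payload = json.load(fh)
    points = [DiagramPoint(**p) for p in payload["points"]]
    ring = [(r["taxon"], r["angle"]) for r in payload["ring_labels"]]
    return DiagramSpec(payload["level"], points, ring)


def _polar(angle: float, radius: float) -> tuple[float, float]:
    cx = cy = _CANVAS / 2.0
    # angle 0 at 12 o'clock, clockwise
    return (
        cx + radius * math.sin(angle),
        cy - radius * math.cos(angle),
    )


def render_svg(spec: DiagramSpec, path: str | Path) -> None:
    """Write a static SVG 1.1 rendering of the spec (byte-stable)."""
    parts: list[str] = []
    parts.append(
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_CANVAS:.0f}" height="{_CANVAS:.0f}" '
        f'viewBox="0 0 {_CANVAS:.0f} {_CANVAS:.0f}">'
    )
    parts.append(
        f'<rect width="{_CANVAS:.0f}" height="{_CANVAS:.0f}" fill="white"/>'
    )
    cx = cy = _CANVAS / 2.0
    for i in range(len(IDENTITY_BANDS)):
        r = _RING_RADIUS - i * _BAND_STEP
        parts.append(
            f'<circle cx="{cx:.1f}" cy="{cy:.1f}" r="{r:.1f}" fill="none" '
            f'stroke="#dddddd" stroke-width="1"/>'
        )
    unplaced_angle = -0.3  # reserved sector left of 12 o'clock
    for p in sorted(spec.points, key=lambda q: q.label):
        angle = p.angle if p.angle is not None else unplaced_angle
        radius = _RING_RADIUS - p.band * _BAND_STEP
        x, y = _polar(angle, radius)
        dot_r = math.sqrt(p.area / math.pi)
        fill = "#888888" if p.angle is None else "#1f77b4"
        parts.append(
            f'<circle cx="{x:.2f}" cy="{y:.2f}" r="{dot_r:.2f}" '
            f'fill="{fill}" fill-opacity="0.7">'
            f"<title>{p.label} ({p.taxon}): {p.read_count} reads</title>"
            f"</circle>"
        )
    for taxon, angle in sorted(spec.ring_labels):
        x, y = _polar(angle, _RING_RADIUS + 30.0)
        parts.append(
            f'<text x="{x:.2f}" y="{y:.2f}" font-size="12" '
            f'text-anchor="middle">{taxon}</text>'
        )
    parts.append("</svg>\n")
    with open(path, "w") as fh:
        fh.write("\n".join(parts))
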