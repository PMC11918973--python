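"""Fixed-layout Sankey diagrams of daily state transitions.

Unlike auto-optimized Sankey layouts, nodes here sit on a fixed grid:
the horizontal axis is the hospitalization day at equal intervals
(x = (day - 1) / 17 exactly) and, within a day, nodes are stacked in the
fixed display order (score 12 at the top down to score 0, then OTHER,
then DISCHARGED).  Link thickness encodes the transition count M(d)[i, j];
nodes with zero occupancy are omitted.  The JSON form is the lossless
interchange format; the HTML form embeds a static SVG rendering of the
same geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .states import HORIZON, STATES, State, state_from_label
from .stats import TransitionCounts, band_summary_from_counts, _categorize


@dataclass(frozen=True)
class SankeyNode:
    day: int
    state: State
    x: float
    y: float
    occupancy: int


@dataclass(frozen=True)
class SankeyLink:
    source_day: int
    source_state: State
    target_state: State
    volume: int
    highlighted: bool = False


@dataclass(frozen=True)
class SankeySpec:
    nodes: tuple[SankeyNode, ...]
    links: tuple[SankeyLink, ...]


def _x_of(day: int) -> float:
    return (day - 1) / (HORIZON - 1)


def build_sankey_spec(
    counts_by_day: Sequence[TransitionCounts],
    highlight: Optional[str] = None,
    n_eligible: Optional[int] = None,
) -> SankeySpec:
    """Assemble the fixed-layout diagram from consecutive count matrices.

    ``counts_by_day`` must cover consecutive day pairs starting at day 1
    and come from a single cohort (totals equal across days).  With
    ``highlight="top2:<d>"`` the links of the two most frequent named
    band paths at day pair d are flagged; ``highlight="bands:<d>"``
    flags every link belonging to any named band path at day pair d.
    """
    if not counts_by_day:
        return SankeySpec(nodes=(), links=())
    days = [tc.day for tc in counts_by_day]
    if days != list(range(1, len(days) + 1)):
        raise ValueError("counts_by_day must cover consecutive day pairs starting at day 1")
    totals = {tc.total for tc in counts_by_day}
    if len(totals) > 1:
        raise ValueError("count matrices disagree on cohort size; mixed cohorts?")

    highlight_cells: set[tuple[int, int, int]] = set()
    if highlight is not None:
        mode, _, day_str = highlight.partition(":")
        h_day = int(day_str) if day_str else 3
        tc = counts_by_day[h_day - 1]
        if mode == "top2":
            band = band_summary_from_counts(tc, n_eligible if n_eligible is not None else tc.total)
            wanted = set(band.top2_categories)
        elif mode == "bands":
            wanted = None  # any named category
        else:
            raise ValueError(f"unknown highlight rule {highlight!r}")
        for i, src in enumerate(STATES):
            for j, tgt in enumerate(STATES):
                if tc.counts[i, j] == 0:
                    continue
                cat = _categorize(src, tgt)
                if cat is not None and (wanted is None or cat in wanted):
                    highlight_cells.add((h_day, i, j))

    # occupancy per (day, state): outflow for day 1, inflow for days 2..18
    occupancy: dict[tuple[int, int], int] = {}
    for tc in counts_by_day:
        out_tot = tc.counts.sum(axis=1)
        in_tot = tc.counts.sum(axis=0)
        for i in range(len(STATES)):
            if tc.day == 1 and out_tot[i] > 0:
                occupancy[(1, i)] = int(out_tot[i])
            if in_tot[i] > 0:
                occupancy[(tc.day + 1, i)] = int(in_tot[i])

    nodes = []
    for day in range(1, max(days) + 2):
        occupied = sorted(i for (d, i) in occupancy if d == day)
        k = len(occupied)
        for pos, i in enumerate(occupied):
            y = pos / (k - 1) if k > 1 else 0.5
            nodes.append(
                SankeyNode(day=day, state=STATES[i], x=_x_of(day), y=y, occupancy=occupancy[(day, i)])
            )

    links = []
    for tc in counts_by_day:
        for i in range(len(STATES)):
            for j in range(len(STATES)):
                v = int(tc.counts[i, j])
                if v == 0:
                    continue
                links.append(
                    SankeyLink(
                        source_day=tc.day,
                        source_state=STATES[i],
                        target_state=STATES[j],
                        volume=v,
                        highlighted=(tc.day, i, j) in highlight_cells,
                    )
                )
    return SankeySpec(nodes=tuple(nodes), links=tuple(links))


def spec_to_dict(spec: SankeySpec) -> dict:
    return {
        "nodes": [
            {"day": n.day, "state": n.state.label, "x": n.x, "y": n.y, "occupancy": n.occupancy}
            for n in spec.nodes
        ],
        "links": [
            {
                "source_day": l.source_day,
                "source_state": l.source_state.label,
                "target_state": l.target_state.label,
                "volume": l.volume,
                "highlighted": l.highlighted,
            }
            for l in spec.links
        ],
    }


def spec_from_dict(payload: dict) -> SankeySpec:
    nodes = tuple(
        SankeyNode(
            day=n["day"], state=state_from_label(n["state"]), x=n["x"], y=n["y"], occupancy=n["occupancy"]
        )
        for n in payload["nodes"]
    )
    links = tuple(
        SankeyLink(
            source_day=l["source_day"],
            source_state=state_from_label(l["source_state"]),
            target_state=state_from_label(l["target_state"]),
            volume=l["volume"],
            highlighted=l.get("highlighted", False),
        )
        for l in payload["links"]
    )
    return SankeySpec(nodes=nodes, links=links)


def write_sankey(spec: SankeySpec, path: str | Path, format: str = "json") -> None:
    """Write the diagram as lossless JSON or a self-contained HTML/SVG page."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(spec_to_dict(spec), indent=1))
    elif format == "html":
        path.write_text(_render_html(spec))
    else:
        raise ValueError(f"unknown format {format!r}; expected 'json' or 'html'")


def read_sankey(path: str | Path) -> SankeySpec:
    return spec_from_dict(json.loads(Path(path).read_text()))


_SVG_W, _SVG_H, _MARGIN = 1200, 640, 48


def _render_html(spec: SankeySpec) -> str:
    """Static SVG honoring the fixed x/y layout; link width scales with volume."""
    def px(x: float) -> float:
        return _MARGIN + x * (_SVG_W - 2 * _MARGIN)

    def py(y: float) -> float:
        return _MARGIN + y * (_SVG_H - 2 * _MARGIN)

    pos = {(n.day, n.state.label): (px(n.x), py(n.y)) for n in spec.nodes}
    max_vol = max((l.volume for l in spec.links), default=1)
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        "<title>Nursing-demand trajectories</title></head><body>",
        f"<svg width='{_SVG_W}' height='{_SVG_H}' xmlns='http://www.w3.org/2000/svg'>",
    ]
    for l in spec.links:
        x1, y1 = pos[(l.source_day, l.source_state.label)]
        x2, y2 = pos[(l.source_day + 1, l.target_state.label)]
        w = max(0.5, 14.0 * l.volume / max_vol)
        color = "#d62728" if l.highlighted else "#9ecae1"
        mx = (x1 + x2) / 2
        parts.append(
            f"<path d='M {x1:.1f} {y1:.1f} C {mx:.1f} {y1:.1f}, {mx:.1f} {y2:.1f}, {x2:.1f} {y2:.1f}' "
            f"stroke='{color}' stroke-width='{w:.2f}' fill='none' opacity='0.65'>"
            f"<title>{l.source_state.label} day {l.source_day} → {l.target_state.label}: {l.volume}</title></path>"
        )
    for n in spec.nodes:
        x, y = pos[(n.day, n.state.label)]
        label = {"other": "The others", "discharged": "discharged"}.get(n.state.label, n.state.label)
        parts.append(
            f"<rect x='{x - 4:.1f}' y='{y - 7:.1f}' width='8' height='14' fill='#444'>"
            f"<title>day {n.day}, {label}: {n.occupancy}</title></rect>"
        )
        parts.append(
            f"<text x='{x - 8:.1f}' y='{y + 4:.1f}' font-size='9' text-anchor='end' fill='#333'>{label}</text>"
        )
    parts.append("</svg></body></html>")
    return "".join(parts)
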