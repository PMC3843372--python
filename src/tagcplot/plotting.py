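"""TAGC scatter plots: GC on x, log10 coverage on y, colored by taxon.

One pane per library plus a combined pane. Points whose taxon falls
under the legend threshold (or is a sentinel) are drawn gray. A sidecar
JSON legend manifest (taxon -> count, color) is always written next to
the image, because the manifest — not rendered pixels — is the test
surface.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional
from xml.sax.saxutils import escape

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from tagcplot.errors import TagcError  # noqa: E402
from tagcplot.formats_io import TagcTable  # noqa: E402
from tagcplot.tagc_builder import legend_counts, legend_taxa  # noqa: E402

GRAY = "#b0b0b0"

# deterministic palette, indexed by descending taxon count
PALETTE = [
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
    "#aec7e8", "#ffbb78", "#98df8a", "#ff9896", "#c5b0d5",
]


@dataclass
class PlotSpec:
    rank: str = "order"
    threshold: float = 0.01
    panes: Optional[List[str]] = None  # default: each library then "total"
    y_floor: float = 0.01
    fmt: str = "png"
    point_size: float = 6.0
    alpha: float = 0.6

    def __post_init__(self) -> None:
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must be in [0, 1]")
        if self.y_floor <= 0:
            raise ValueError("y_floor must be > 0")
        if self.fmt not in ("png", "svg"):
            raise ValueError(f"format must be png or svg, got {self.fmt!r}")


def build_legend_manifest(table: TagcTable, spec: PlotSpec) -> Dict[str, Dict]:
    """taxon -> {count, color} for legend taxa, in legend order."""
    taxa = legend_taxa(table, spec.rank, spec.threshold)
    counts = legend_counts(table, spec.rank)
    return {
        taxon: {"count": counts[taxon], "color": PALETTE[i % len(PALETTE)]}
        for i, taxon in enumerate(taxa)
    }


def _resolve_panes(table: TagcTable, spec: PlotSpec) -> List[str]:
    panes = spec.panes if spec.panes is not None else list(table.library_labels)
    for pane in panes:
        if pane not in table.library_labels:
            raise TagcError(f"unknown pane {pane!r}; table has {table.library_labels}")
    return panes


def _point_color(taxon: str, manifest: Dict[str, Dict]) -> str:
    entry = manifest.get(taxon)
    return entry["color"] if entry else GRAY


def render_tagc(table: TagcTable, spec: PlotSpec, path) -> Dict[str, Dict]:
    """Render the plot and write ``<path>.legend.json``; returns the
    legend manifest."""
    if not table.rows:
        raise TagcError("cannot plot an empty table")
    if spec.rank not in table.rank_labels:
        raise TagcError(f"rank {spec.rank!r} not in table")
    panes = _resolve_panes(table, spec)
    manifest = build_legend_manifest(table, spec)
    path = Path(path)

    if spec.fmt == "svg":
        _write_svg(table, spec, panes, manifest, path)
    else:
        _write_matplotlib(table, spec, panes, manifest, path)

    with open(str(path) + ".legend.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=False)
    return manifest


def export_svg(table: TagcTable, spec: PlotSpec, path) -> Dict[str, Dict]:
    """Render as hand-written SVG: one <circle> per plotted point, so
    point counts are assertable by element tally."""
    svg_spec = PlotSpec(
        rank=spec.rank, threshold=spec.threshold, panes=spec.panes,
        y_floor=spec.y_floor, fmt="svg",
        point_size=spec.point_size, alpha=spec.alpha,
    )
    return render_tagc(table, svg_spec, path)


def _y_value(cov: float, floor: float) -> float:
    return math.log10(max(cov, floor))


def _write_matplotlib(table, spec, panes, manifest, path) -> None:
    n = len(panes)
    fig, axes = plt.subplots(1, n, figsize=(5.0 * n, 4.5), squeeze=False)
    for ax, pane in zip(axes[0], panes):
        xs = [row.gc for row in table.rows]
        ys = [_y_value(row.coverages[pane], spec.y_floor) for row in table.rows]
        colors = [_point_color(row.taxa[spec.rank], manifest) for row in table.rows]
        ax.scatter(xs, ys, s=spec.point_size, c=colors, alpha=spec.alpha,
                   linewidths=0)
        ax.set_xlim(0.0, 1.0)
        ax.set_xlabel("GC")
        ax.set_ylabel("log10 coverage")
        ax.set_title(pane)
    if manifest:
        handles = [
            plt.Line2D([], [], marker="o", linestyle="", color=entry["color"],
                       label=f"{taxon} ({entry['count']})")
            for taxon, entry in manifest.items()
        ]
        axes[0][-1].legend(handles=handles, fontsize="small", loc="best")
    fig.tight_layout()
    fig.savefig(path, format=spec.fmt)
    plt.close(fig)


# hand-written SVG layout constants
_PANE_W, _PANE_H, _MARGIN = 500, 450, 50


def _write_svg(table, spec, panes, manifest, path) -> None:
    ys_all = [
        _y_value(row.coverages[pane], spec.y_floor)
        for pane in panes for row in table.rows
    ]
    y_min, y_max = min(ys_all), max(ys_all)
    if y_max == y_min:
        y_max = y_min + 1.0
    total_w = len(panes) * (_PANE_W + _MARGIN) + _MARGIN
    total_h = _PANE_H + 2 * _MARGIN
    r = max(1.0, spec.point_size ** 0.5)

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{total_w}" '
        f'height="{total_h}" viewBox="0 0 {total_w} {total_h}">'
    ]
    for i, pane in enumerate(panes):
        x0 = _MARGIN + i * (_PANE_W + _MARGIN)
        parts.append(f'<g class="pane" data-pane="{escape(pane)}">')
        parts.append(
            f'<rect x="{x0}" y="{_MARGIN}" width="{_PANE_W}" height="{_PANE_H}" '
            'fill="none" stroke="black"/>'
        )
        parts.append(
            f'<text x="{x0 + _PANE_W / 2}" y="{_MARGIN - 10}" '
            f'text-anchor="middle">{escape(pane)}</text>'
        )
        for row in table.rows:
            px = x0 + row.gc * _PANE_W
            y = _y_value(row.coverages[pane], spec.y_floor)
            py = _MARGIN + _PANE_H - (y - y_min) / (y_max - y_min) * _PANE_H
            color = _point_color(row.taxa[spec.rank], manifest)
            parts.append(
                f'<circle class="point" cx="{px:.2f}" cy="{py:.2f}" r="{r:.2f}" '
                f'fill="{color}" fill-opacity="{spec.alpha}"/>'
            )
        parts.append("</g>")
    if manifest:
        parts.append('<g class="legend">')
        for j, (taxon, entry) in enumerate(manifest.items()):
            ly = _MARGIN + 15 * (j + 1)
            parts.append(
                f'<rect x="{total_w - _MARGIN + 5}" y="{ly - 8}" width="8" '
                f'height="8" fill="{entry["color"]}"/>'
            )
            parts.append(
                f'<text x="{total_w - _MARGIN + 16}" y="{ly}" font-size="10">'
                f'{escape(taxon)} ({entry["count"]})</text>'
            )
        parts.append("</g>")
    parts.append("</svg>")
    Path(path).write_text("\n".join(parts))
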