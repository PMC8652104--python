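"""Deterministic geometry and static SVG output for the linear track view.

The view stacks, top to bottom: an optional miniature overview of the
whole panchromosome, a beeswarm of gene-annotation marks, a coordinate
axis, a core/variable classification track, a repeat-count track, and one
row per genome with one rectangle per visible block.  Block x-extent is
proportional to bp width (width is information-bearing), cells carry
``data-genome``/``data-block`` attributes so output can be checked
programmatically, and hover cards become ``<title>`` metadata on the
swarm marks.

Rendering is a pure function of its inputs: geometry is built as a list
of primitives, then serialized; identical inputs give byte-identical SVG.
The same primitives can optionally be rasterized to PNG via matplotlib.

Default palette (colorblind-safe): core orange ``#E69F00``, variable blue
``#56B4E9``, absent light gray ``#E8E8E8``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
from xml.sax.saxutils import escape, quoteattr

import numpy as np

from .io import AnnotationCard
from .model import (
    DEFAULT_CORE_THRESHOLD,
    PavMatrix,
    PavModelError,
    Status,
    classify_block,
)

__all__ = [
    "CORE_COLOR",
    "VARIABLE_COLOR",
    "ABSENT_COLOR",
    "SwarmPlacement",
    "ViewConfig",
    "layout_beeswarm",
    "overview_bins",
    "render_overview",
    "render_view",
    "render_png",
]

CORE_COLOR = "#E69F00"
VARIABLE_COLOR = "#56B4E9"
ABSENT_COLOR = "#E8E8E8"

MARGIN_LEFT = 100.0
MARGIN = 4.0
ROW_H = 14.0
TRACK_H = 12.0
AXIS_H = 18.0
OVERVIEW_H = 20.0
LANE_H = 10.0


@dataclass(frozen=True)
class SwarmPlacement:
    """A mark's horizontal extent and its vertical lane in the beeswarm."""

    feature_id: str
    x_center: float
    width: float
    lane: int

    @property
    def x_min(self) -> float:
        return self.x_center - self.width / 2

    @property
    def x_max(self) -> float:
        return self.x_center + self.width / 2


@dataclass
class ViewConfig:
    """Everything that parametrizes one rendering of the linear view."""

    panchromosome: str
    region: tuple[int, int] | None = None  # bp, half-open; None = whole axis
    px_per_bp: float = 0.1
    threshold: float = DEFAULT_CORE_THRESHOLD
    genome_order: Sequence[str] | None = None  # None = matrix order
    show_overview: bool = True
    show_annotations: bool = True
    show_coordinates: bool = True
    show_repeats: bool = True
    core_color: str = CORE_COLOR
    variable_color: str = VARIABLE_COLOR
    absent_color: str = ABSENT_COLOR

    def __post_init__(self) -> None:
        if self.px_per_bp <= 0:
            raise PavModelError(f"px_per_bp must be > 0, got {self.px_per_bp}")


def layout_beeswarm(
    features: Sequence[tuple[str, float, float]]
) -> list[SwarmPlacement]:
    """Greedy lane assignment preventing horizontal overlaps.

    Features (id, x_center, width) are processed in ascending x_center
    order (ties by id); each takes the lowest lane where its
    [x_center - w/2, x_center + w/2] extent touches nothing already
    placed.  Output order matches processing order.
    """
    for _, _, w in features:
        if w <= 0:
            raise PavModelError("swarm mark widths must be positive")
    ordered = sorted(features, key=lambda f: (f[1], f[0]))
    lane_right: list[float] = []  # rightmost occupied x per lane
    placements: list[SwarmPlacement] = []
    for fid, xc, w in ordered:
        x_min, x_max = xc - w / 2, xc + w / 2
        lane = next(
            (k for k, right in enumerate(lane_right) if x_min >= right), len(lane_right)
        )
        if lane == len(lane_right):
            lane_right.append(x_max)
        else:
            lane_right[lane] = x_max
        placements.append(SwarmPlacement(fid, xc, w, lane))
    return placements


def overview_bins(matrix: PavMatrix, panchromosome: str, width_px: int) -> np.ndarray:
    """Per-bin mean presence fraction over ``width_px`` horizontal bins.

    The panchromosome extent [0-based min start, max stop) is cut into
    ``width_px`` equal bins; each bin's value is the mean, over the blocks
    overlapping it, of the fraction of genomes carrying the block.  Bins
    overlapping no block get 0.
    """
    if width_px < 1:
        raise PavModelError(f"width_px must be >= 1, got {width_px}")
    blist = matrix.blocks.get(panchromosome)
    if not blist:
        raise PavModelError(f"unknown panchromosome {panchromosome!r}")
    lo, hi = matrix.extent(panchromosome)
    ids = [b.block_id for b in blist]
    frac = (matrix.counts.loc[ids].to_numpy() >= 1).mean(axis=1)
    edges = np.linspace(lo, hi, width_px + 1)
    values = np.zeros(width_px)
    for k in range(width_px):
        b_lo, b_hi = edges[k], edges[k + 1]
        hits = [
            frac[i] for i, b in enumerate(blist) if b.start < b_hi and b_lo < b.stop
        ]
        values[k] = float(np.mean(hits)) if hits else 0.0
    return values


def _fmt(v: float) -> str:
    s = f"{v:.2f}"
    return s.rstrip("0").rstrip(".") if "." in s else s


@dataclass
class _Rect:
    x: float
    y: float
    w: float
    h: float
    fill: str
    attrs: tuple[tuple[str, str], ...] = ()
    title: str = ""

    def to_svg(self) -> str:
        extra = "".join(f" {k}={quoteattr(v)}" for k, v in self.attrs)
        open_tag = (
            f'<rect x="{_fmt(self.x)}" y="{_fmt(self.y)}" width="{_fmt(self.w)}" '
            f'height="{_fmt(self.h)}" fill="{self.fill}"{extra}'
        )
        if self.title:
            return f"{open_tag}><title>{escape(self.title)}</title></rect>"
        return f"{open_tag}/>"


@dataclass
class _Text:
    x: float
    y: float
    text: str
    size: float = 9.0
    anchor: str = "start"

    def to_svg(self) -> str:
        return (
            f'<text x="{_fmt(self.x)}" y="{_fmt(self.y)}" font-size="{_fmt(self.size)}" '
            f'font-family="monospace" text-anchor="{self.anchor}">{escape(self.text)}</text>'
        )


@dataclass
class _Line:
    x1: float
    y1: float
    x2: float
    y2: float
    stroke: str = "#555555"

    def to_svg(self) -> str:
        return (
            f'<line x1="{_fmt(self.x1)}" y1="{_fmt(self.y1)}" x2="{_fmt(self.x2)}" '
            f'y2="{_fmt(self.y2)}" stroke="{self.stroke}" stroke-width="1"/>'
        )


@dataclass
class Scene:
    width: float
    height: float
    elements: list = field(default_factory=list)

    def to_svg(self) -> str:
        body = "\n".join(e.to_svg() for e in self.elements)
        return (
            '<?xml version="1.0" encoding="UTF-8"?>\n'
            f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
            f'width="{_fmt(self.width)}" height="{_fmt(self.height)}">\n'
            f"{body}\n</svg>\n"
        )


def _shade(frac: float) -> str:
    """Presence fraction -> grayscale hex (1.0 = darkest)."""
    level = int(round(235 * (1 - frac)))
    return f"#{level:02X}{level:02X}{level:02X}"


def _nice_tick_step(span_bp: float) -> int:
    target = span_bp / 8
    step = 1
    while True:
        for mult in (1, 2, 5):
            if step * mult >= target:
                return step * mult
        step *= 10


def build_scene(
    matrix: PavMatrix,
    cards: Sequence[AnnotationCard] | None,
    config: ViewConfig,
) -> Scene:
    """Compute the full multi-track geometry (pure, deterministic)."""
    chrom = config.panchromosome
    blist = matrix.blocks.get(chrom)
    if not blist:
        raise PavModelError(f"unknown panchromosome {chrom!r}")
    lo, hi = matrix.extent(chrom)
    if config.region is None:
        r_lo, r_hi = lo, hi
    else:
        r_lo, r_hi = config.region
        if r_lo >= r_hi:
            raise PavModelError(f"empty region {config.region}")
        if r_lo < 0 or r_hi > hi:
            raise PavModelError(
                f"region {config.region} outside panchromosome extent (0, {hi})"
            )
    visible = [b for b in blist if b.start < r_hi and r_lo < b.stop]
    genome_order = list(config.genome_order) if config.genome_order else matrix.genomes
    if sorted(genome_order) != sorted(matrix.genomes):
        raise PavModelError("genome_order must be a permutation of the matrix genomes")

    def x_of(bp: float) -> float:
        return MARGIN_LEFT + (bp - r_lo) * config.px_per_bp

    width = x_of(r_hi) + MARGIN
    elements: list = []
    y = MARGIN

    status = {
        b.block_id: classify_block(
            int((matrix.counts.loc[b.block_id] >= 1).sum()),
            matrix.n_genomes,
            config.threshold,
            block_id=b.block_id,
        ).status
        for b in visible
    }

    # -- overview strip (whole panchromosome, independent of the region)
    if config.show_overview:
        # capped so very wide views do not emit one rect per pixel
        n_bins = min(512, max(1, int(round(width - MARGIN_LEFT - MARGIN))))
        bins = overview_bins(matrix, chrom, n_bins)
        bin_w = (width - MARGIN_LEFT - MARGIN) / n_bins
        for k, v in enumerate(bins):
            elements.append(
                _Rect(
                    MARGIN_LEFT + k * bin_w, y, bin_w, OVERVIEW_H, _shade(float(v)),
                    attrs=(("class", "overview-bin"),),
                )
            )
        elements.append(_Text(MARGIN, y + OVERVIEW_H - 6, "overview"))
        y += OVERVIEW_H + MARGIN

    # -- annotation beeswarm
    if config.show_annotations:
        marks = []
        for c in cards or []:
            if c.panchromosome != chrom or c.stop <= r_lo or c.start >= r_hi:
                continue
            xc = x_of((c.start + c.stop) / 2)
            w = max((c.stop - c.start) * config.px_per_bp, 3.0)
            marks.append((c.gene_id, xc, w))
        placements = layout_beeswarm(marks)
        n_lanes = 1 + max((p.lane for p in placements), default=0)
        fn = {c.gene_id: c.function_text for c in cards or []}
        for p in placements:
            elements.append(
                _Rect(
                    p.x_min, y + p.lane * LANE_H + 1, p.width, LANE_H - 2, "#777777",
                    attrs=(("class", "swarm"), ("data-feature", p.feature_id),
                           ("data-lane", str(p.lane))),
                    title=f"{p.feature_id}: {fn.get(p.feature_id, '')}".rstrip(": "),
                )
            )
        elements.append(_Text(MARGIN, y + LANE_H - 2, "genes"))
        y += n_lanes * LANE_H + MARGIN

    # -- coordinate axis
    if config.show_coordinates:
        axis_y = y + AXIS_H - 6
        elements.append(_Line(x_of(r_lo), axis_y, x_of(r_hi), axis_y))
        step = _nice_tick_step(r_hi - r_lo)
        tick = ((r_lo + step - 1) // step) * step
        while tick <= r_hi:
            elements.append(_Line(x_of(tick), axis_y - 3, x_of(tick), axis_y + 3))
            elements.append(_Text(x_of(tick), axis_y - 5, str(tick), size=8, anchor="middle"))
            tick += step
        elements.append(_Text(MARGIN, axis_y, "bp"))
        y += AXIS_H + MARGIN

    # -- core/variable track
    for b in visible:
        color = (
            config.core_color if status[b.block_id] is Status.CORE else config.variable_color
        )
        elements.append(
            _Rect(
                x_of(b.start), y, b.width * config.px_per_bp, TRACK_H, color,
                attrs=(("class", "status"), ("data-block", b.block_id),
                       ("data-status", status[b.block_id].value)),
            )
        )
    elements.append(_Text(MARGIN, y + TRACK_H - 2, "core/var"))
    y += TRACK_H + MARGIN

    # -- repeat track (bar height proportional to repeat count)
    if config.show_repeats:
        max_rep = max((len(b.similar_positions) for b in visible), default=0)
        for b in visible:
            rep = len(b.similar_positions)
            h = TRACK_H * (rep / max_rep) if max_rep else 0.0
            if rep:
                elements.append(
                    _Rect(
                        x_of(b.start), y + TRACK_H - h, b.width * config.px_per_bp, h,
                        "#999999",
                        attrs=(("class", "repeat"), ("data-block", b.block_id),
                               ("data-repeats", str(rep))),
                    )
                )
        elements.append(_Text(MARGIN, y + TRACK_H - 2, "repeats"))
        y += TRACK_H + MARGIN

    # -- PAV matrix: one row per genome, one cell per visible block
    for gname in genome_order:
        for b in visible:
            count = int(matrix.counts.at[b.block_id, gname])
            if count < 1:
                fill = config.absent_color
            elif status[b.block_id] is Status.CORE:
                fill = config.core_color
            else:
                fill = config.variable_color
            elements.append(
                _Rect(
                    x_of(b.start), y, b.width * config.px_per_bp, ROW_H - 1, fill,
                    attrs=(("class", "cell"), ("data-genome", gname),
                           ("data-block", b.block_id), ("data-count", str(count))),
                )
            )
        elements.append(_Text(MARGIN, y + ROW_H - 4, gname))
        y += ROW_H
    y += MARGIN

    return Scene(width=width, height=y, elements=elements)


def render_view(
    matrix: PavMatrix,
    cards: Sequence[AnnotationCard] | None,
    config: ViewConfig,
) -> str:
    """Render the linear multi-track view as an SVG 1.1 document."""
    return build_scene(matrix, cards, config).to_svg()


def render_overview(matrix: PavMatrix, panchromosome: str, width_px: int) -> str:
    """Standalone miniature overview strip as an SVG fragment.

    One 1-px-wide bin per horizontal pixel, shaded by mean presence
    fraction of the blocks overlapping it.
    """
    bins = overview_bins(matrix, panchromosome, width_px)
    rects = [
        _Rect(float(k), 0.0, 1.0, OVERVIEW_H, _shade(float(v)),
              attrs=(("class", "overview-bin"), ("data-value", _fmt(float(v)))))
        for k, v in enumerate(bins)
    ]
    body = "\n".join(r.to_svg() for r in rects)
    return f'<g class="overview">\n{body}\n</g>\n'


def render_png(
    matrix: PavMatrix,
    cards: Sequence[AnnotationCard] | None,
    config: ViewConfig,
    path: str,
    dpi: int = 100,
) -> None:
    """Rasterize the same scene to PNG via matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    scene = build_scene(matrix, cards, config)
    fig, ax = plt.subplots(figsize=(scene.width / dpi, scene.height / dpi), dpi=dpi)
    ax.set_xlim(0, scene.width)
    ax.set_ylim(scene.height, 0)  # SVG y grows downward
    ax.axis("off")
    for e in scene.elements:
        if isinstance(e, _Rect):
            ax.add_patch(Rectangle((e.x, e.y), e.w, e.h, facecolor=e.fill, linewidth=0))
        elif isinstance(e, _Line):
            ax.plot([e.x1, e.x2], [e.y1, e.y2], color=e.stroke, linewidth=1)
        elif isinstance(e, _Text):
            ha = {"start": "left", "middle": "center", "end": "right"}[e.anchor]
            ax.text(e.x, e.y, e.text, fontsize=e.size * 72 / dpi, ha=ha, family="monospace")
    fig.subplots_adjust(left=0, right=1, top=1, bottom=0)
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
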