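"""Track-less SVG rendering of a region's beta values.

All groups are superimposed in a single coordinate frame (no per-group axis
rescaling) in one of three modes:

* ``points`` — one circle per (probe, sample) value, colored by group, with a
  static tooltip naming the sample and its metadata;
* ``distribution`` — per-probe summary glyphs per group (mean + min-max range
  by default, or median/IQR box), fanned horizontally around the probe;
* ``trace`` — per-group polyline through per-probe group means, optionally
  smoothed with a centered moving average. Probes without data for a group
  are skipped, never interpolated to zero: the line is a visual guide, not an
  imputed gradient.

Beneath the data sit CpG-island background rectangles (maximal runs of
consecutive island probes merged into one rectangle), and below the x-axis
three marker rows (SNP-in-probe squares, SNP-at-CpG squares, unreliable-probe
ticks) plus an optional gene-structure track.

Output is deterministic SVG 1.1 built on the standard library's ElementTree;
glyphs carry class attributes so coordinates can be recovered by any XML
parser.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from xml.etree import ElementTree as ET

from .errors import RenderError
from .grouping import GroupAssignment
from .types import GenomicRegion, RegionDataset

SVG_NS = "http://www.w3.org/2000/svg"

MODES = ("points", "distribution", "trace")

#: Colorblind-safe qualitative palette (cycled over groups in label order).
DEFAULT_PALETTE = (
    "#E69F00",
    "#56B4E9",
    "#009E73",
    "#F0E442",
    "#0072B2",
    "#D55E00",
    "#CC79A7",
    "#999999",
    "#882255",
    "#44AA99",
    "#332288",
    "#DDCC77",
)


@dataclass(frozen=True)
class Margins:
    top: int = 40
    right: int = 20
    bottom: int = 120  # room for marker rows + gene track
    left: int = 56


@dataclass(frozen=True)
class PlotConfig:
    width_px: int = 900
    height_px: int = 460
    margins: Margins = field(default_factory=Margins)
    mode: str = "points"
    palette: tuple = DEFAULT_PALETTE
    island_colors: dict = field(
        default_factory=lambda: {
            # deeper blue for high-density islands, lighter for intermediate
            "high_density": "#1f5fa8",
            "intermediate_density": "#a8c8e8",
        }
    )
    marker_colors: dict = field(
        default_factory=lambda: {
            "snp_in_probe": "#0000cc",  # blue squares below the x-axis
            "snp_at_cpg": "#cc0000",  # red squares below the x-axis
            "unreliable": "#00008b",
        }
    )
    trace_window: int = 1  # odd; 1 = raw per-probe means
    distribution_glyph: str = "mean_range"  # or "box"
    point_radius: float = 3.0
    glyph_width: float = 6.0
    glyph_spacing: float = 8.0
    island_pad_px: float = 4.0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise RenderError("plot width and height must be positive")
        if self.mode not in MODES:
            raise RenderError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.trace_window < 1 or self.trace_window % 2 == 0:
            raise RenderError(f"trace_window must be an odd integer >= 1, got {self.trace_window}")
        if self.distribution_glyph not in ("box", "mean_range"):
            raise RenderError(
                f"distribution_glyph must be 'box' or 'mean_range', got {self.distribution_glyph!r}"
            )

    def group_color(self, index: int) -> str:
        return self.palette[index % len(self.palette)]


class CoordinateTransform:
    """Affine map between (genomic position, beta) and pixel space.

    position=start maps to the plot box's left edge, position=end to the
    right edge; beta=0 maps to the bottom edge, beta=1 to the top (SVG y
    grows downward).
    """

    def __init__(self, region: GenomicRegion, cfg: PlotConfig):
        self.region = region
        m = cfg.margins
        self.left = float(m.left)
        self.right = float(cfg.width_px - m.right)
        self.top = float(m.top)
        self.bottom = float(cfg.height_px - m.bottom)
        if self.right <= self.left or self.bottom <= self.top:
            raise RenderError("margins leave no plot area")

    def genomic_to_x(self, position: int) -> float:
        r = self.region
        if not r.start <= position <= r.end:
            raise RenderError(f"position {position} outside region {r}")
        if r.start == r.end:
            return (self.left + self.right) / 2.0
        frac = (position - r.start) / (r.end - r.start)
        return self.left + frac * (self.right - self.left)

    def beta_to_y(self, beta: float) -> float:
        if not 0.0 <= beta <= 1.0:
            raise RenderError(f"beta {beta} outside [0, 1]")
        return self.bottom - beta * (self.bottom - self.top)


def _fmt(value: float) -> str:
    """Deterministic fixed-precision coordinate formatting."""
    text = f"{value:.3f}"
    return text.rstrip("0").rstrip(".") if "." in text else text


def _sub(parent, tag, **attrs):
    el = ET.SubElement(parent, tag)
    for k, v in attrs.items():
        el.set(k.replace("_", "-"), v if isinstance(v, str) else _fmt(float(v)))
    return el


def moving_average(series: list[float], window: int) -> list[float]:
    """Centered moving average; edges average over the available window."""
    if window == 1:
        return list(series)
    half = window // 2
    out = []
    for i in range(len(series)):
        lo, hi = max(0, i - half), min(len(series), i + half + 1)
        out.append(sum(series[lo:hi]) / (hi - lo))
    return out


def group_series(
    data: RegionDataset, groups: GroupAssignment, label: tuple
) -> tuple[list[int], list[float]]:
    """Per-probe mean beta over the group's members; probes with no values
    for the group are skipped."""
    members = set(groups.groups[label])
    positions, means = [], []
    for ann, betas in data.probes:
        values = [b for sid, b in betas.items() if sid in members]
        if values:
            positions.append(ann.position)
            means.append(sum(values) / len(values))
    return positions, means


# ------------------------------------------------------------------ document


def _base_document(data: RegionDataset, groups: GroupAssignment, cfg: PlotConfig, genes=None):
    t = CoordinateTransform(data.region, cfg)
    root = ET.Element(
        "svg",
        {
            "xmlns": SVG_NS,
            "version": "1.1",
            "width": str(cfg.width_px),
            "height": str(cfg.height_px),
            "viewBox": f"0 0 {cfg.width_px} {cfg.height_px}",
        },
    )
    _sub(root, "rect", x=0, y=0, width=cfg.width_px, height=cfg.height_px, fill="white")
    root.append(render_annotation_layers(data, cfg, transform=t, genes=genes))
    _draw_axes(root, data, cfg, t)
    _draw_legend(root, groups, cfg)
    data_layer = ET.SubElement(root, "g")
    data_layer.set("class", "data-layer")
    return root, data_layer, t


def _draw_axes(root, data: RegionDataset, cfg: PlotConfig, t: CoordinateTransform):
    axes = ET.SubElement(root, "g")
    axes.set("class", "axes")
    style = {"stroke": "black", "stroke-width": "1"}
    _sub(axes, "line", x1=t.left, y1=t.bottom, x2=t.right, y2=t.bottom, **style)
    _sub(axes, "line", x1=t.left, y1=t.top, x2=t.left, y2=t.bottom, **style)
    for tick in (0.0, 0.25, 0.5, 0.75, 1.0):
        y = t.beta_to_y(tick)
        _sub(axes, "line", x1=t.left - 4, y1=y, x2=t.left, y2=y, **style)
        label = _sub(axes, "text", x=t.left - 8, y=y + 4, font_size="11", text_anchor="end")
        label.text = f"{tick:g}"
    title = _sub(
        axes, "text", x=(t.left + t.right) / 2, y=t.top - 12, font_size="13", text_anchor="middle"
    )
    title.text = str(data.region)
    if not data.probes:
        empty = _sub(
            axes,
            "text",
            x=(t.left + t.right) / 2,
            y=(t.top + t.bottom) / 2,
            font_size="13",
            text_anchor="middle",
        )
        empty.set("class", "empty-message")
        empty.text = "no probes in region"


def _draw_legend(root, groups: GroupAssignment, cfg: PlotConfig):
    legend = ET.SubElement(root, "g")
    legend.set("class", "legend")
    x = float(cfg.margins.left)
    y = 16.0
    for i, label in enumerate(groups.labels):
        swatch = _sub(legend, "rect", x=x, y=y - 9, width=10, height=10, fill=cfg.group_color(i))
        swatch.set("class", "legend-swatch")
        text = _sub(legend, "text", x=x + 14, y=y, font_size="11")
        text.text = groups.label_text(label)
        x += 14 + 7 * len(groups.label_text(label)) + 16


# ---------------------------------------------------------------- modes


def render_points(
    data: RegionDataset, groups: GroupAssignment, cfg: PlotConfig, genes=None
) -> ET.Element:
    """One circle per (probe, sample) value, colored by the sample's group;
    excluded samples are omitted. Each circle carries a <title> tooltip."""
    if cfg.mode != "points":
        raise RenderError(f"config mode is {cfg.mode!r}, expected 'points'")
    root, layer, t = _base_document(data, groups, cfg, genes)
    color_of = {
        label: cfg.group_color(i) for i, label in enumerate(groups.labels)
    }
    label_of = groups.group_of()
    meta = {s.sample_id: s for s in data.samples}
    for ann, betas in data.probes:
        x = t.genomic_to_x(ann.position)
        for sid in sorted(betas):
            label = label_of.get(sid)
            if label is None:
                continue  # excluded from display
            circle = _sub(
                layer,
                "circle",
                cx=x,
                cy=t.beta_to_y(betas[sid]),
                r=cfg.point_radius,
                fill=color_of[label],
                fill_opacity="0.8",
            )
            circle.set("class", "data-point")
            circle.set("data-sample", sid)
            circle.set("data-probe", ann.probe_id)
            tooltip = ET.SubElement(circle, "title")
            record = meta.get(sid)
            parts = [sid]
            if record is not None:
                parts += [f"{k}={record.metadata[k]}" for k in sorted(record.metadata)]
            parts.append(f"{ann.probe_id} beta={betas[sid]:.3f}")
            tooltip.text = "; ".join(parts)
    return root


def _fan_offsets(n: int, spacing: float) -> list[float]:
    return [(i - (n - 1) / 2.0) * spacing for i in range(n)]


def render_distribution(
    data: RegionDataset, groups: GroupAssignment, cfg: PlotConfig, genes=None
) -> ET.Element:
    """Per-probe, per-group summary glyphs fanned around the probe's x."""
    if cfg.mode != "distribution":
        raise RenderError(f"config mode is {cfg.mode!r}, expected 'distribution'")
    root, layer, t = _base_document(data, groups, cfg, genes)
    labels = groups.labels
    offsets = _fan_offsets(len(labels), cfg.glyph_spacing)
    half = cfg.glyph_width / 2.0
    for ann, betas in data.probes:
        px = t.genomic_to_x(ann.position)
        for i, label in enumerate(labels):
            values = sorted(betas[sid] for sid in groups.groups[label] if sid in betas)
            if not values:
                continue
            x = px + offsets[i]
            color = cfg.group_color(i)
            y_lo, y_hi = t.beta_to_y(values[0]), t.beta_to_y(values[-1])
            glyph = ET.SubElement(layer, "g")
            glyph.set("class", f"dist-glyph dist-glyph-{cfg.distribution_glyph}")
            glyph.set("data-probe", ann.probe_id)
            glyph.set("data-group", groups.label_text(label))
            whisker = _sub(
                glyph, "line", x1=x, y1=y_hi, x2=x, y2=y_lo, stroke=color, stroke_width="1.5"
            )
            whisker.set("class", "dist-whisker")
            if cfg.distribution_glyph == "mean_range":
                mean = sum(values) / len(values)
                marker = _sub(
                    glyph,
                    "line",
                    x1=x - half,
                    y1=t.beta_to_y(mean),
                    x2=x + half,
                    y2=t.beta_to_y(mean),
                    stroke=color,
                    stroke_width="2.5",
                )
                marker.set("class", "dist-mean")
            else:
                q1, q3 = _quartiles(values)
                y_q1, y_q3 = t.beta_to_y(q1), t.beta_to_y(q3)
                box = _sub(
                    glyph,
                    "rect",
                    x=x - half,
                    y=y_q3,
                    width=cfg.glyph_width,
                    height=max(0.0, y_q1 - y_q3),
                    fill=color,
                    fill_opacity="0.5",
                    stroke=color,
                )
                box.set("class", "dist-box")
                med = _sub(
                    glyph,
                    "line",
                    x1=x - half,
                    y1=t.beta_to_y(statistics.median(values)),
                    x2=x + half,
                    y2=t.beta_to_y(statistics.median(values)),
                    stroke=color,
                    stroke_width="2",
                )
                med.set("class", "dist-median")
    return root


def _quartiles(sorted_values: list[float]) -> tuple[float, float]:
    """Lower/upper quartile with linear interpolation (numpy's default)."""

    def q(p: float) -> float:
        idx = p * (len(sorted_values) - 1)
        lo = math.floor(idx)
        hi = math.ceil(idx)
        return sorted_values[lo] + (sorted_values[hi] - sorted_values[lo]) * (idx - lo)

    return q(0.25), q(0.75)


def render_trace(
    data: RegionDataset, groups: GroupAssignment, cfg: PlotConfig, genes=None
) -> ET.Element:
    """One polyline per group through (possibly smoothed) per-probe means."""
    if cfg.mode != "trace":
        raise RenderError(f"config mode is {cfg.mode!r}, expected 'trace'")
    root, layer, t = _base_document(data, groups, cfg, genes)
    for i, label in enumerate(groups.labels):
        positions, means = group_series(data, groups, label)
        if not positions:
            continue
        smoothed = moving_average(means, cfg.trace_window)
        color = cfg.group_color(i)
        if len(positions) < 2:
            point = _sub(
                layer,
                "circle",
                cx=t.genomic_to_x(positions[0]),
                cy=t.beta_to_y(smoothed[0]),
                r=cfg.point_radius,
                fill=color,
            )
            point.set("class", "trace-point")
            point.set("data-group", groups.label_text(label))
            continue
        pts = " ".join(
            f"{_fmt(t.genomic_to_x(p))},{_fmt(t.beta_to_y(b))}"
            for p, b in zip(positions, smoothed)
        )
        line = ET.SubElement(layer, "polyline")
        line.set("points", pts)
        line.set("fill", "none")
        line.set("stroke", color)
        line.set("stroke-width", "2")
        line.set("class", "trace")
        line.set("data-group", groups.label_text(label))
    return root


# --------------------------------------------------------- annotation layers


def render_annotation_layers(
    data: RegionDataset,
    cfg: PlotConfig,
    transform: CoordinateTransform | None = None,
    genes=None,
) -> ET.Element:
    """Island background + below-axis marker rows + gene track, as one <g>.

    Maximal runs of consecutive probes sharing a non-"none" island class
    merge into a single background rectangle spanning the run.
    """
    t = transform if transform is not None else CoordinateTransform(data.region, cfg)
    layer = ET.Element("g")
    layer.set("class", "annotation-layer")

    islands = ET.SubElement(layer, "g")
    islands.set("class", "island-layer")
    for island_class, first_x, last_x in _island_runs(data, t):
        rect = _sub(
            islands,
            "rect",
            x=max(t.left, first_x - cfg.island_pad_px),
            y=t.top,
            width=min(t.right, last_x + cfg.island_pad_px)
            - max(t.left, first_x - cfg.island_pad_px),
            height=t.bottom - t.top,
            fill=cfg.island_colors[island_class],
            fill_opacity="0.35",
        )
        rect.set("class", f"island island-{island_class}")

    markers = ET.SubElement(layer, "g")
    markers.set("class", "marker-layer")
    size = 6.0
    rows = (
        ("snp_in_probe", t.bottom + 6),
        ("snp_at_cpg", t.bottom + 16),
    )
    for ann, _ in data.probes:
        x = t.genomic_to_x(ann.position)
        for flag, row_y in rows:
            if getattr(ann, flag):
                square = _sub(
                    markers,
                    "rect",
                    x=x - size / 2,
                    y=row_y,
                    width=size,
                    height=size,
                    fill=cfg.marker_colors[flag],
                )
                square.set("class", f"marker-{flag.replace('_', '-')}")
                square.set("data-probe", ann.probe_id)
        if not ann.reliable:
            tick = _sub(
                markers,
                "line",
                x1=x,
                y1=t.bottom + 26,
                x2=x,
                y2=t.bottom + 32,
                stroke=cfg.marker_colors["unreliable"],
                stroke_width="2",
            )
            tick.set("class", "marker-unreliable")
            tick.set("data-probe", ann.probe_id)

    track = ET.SubElement(layer, "g")
    track.set("class", "gene-track")
    if genes:
        _draw_gene_track(track, data.region, cfg, t, genes)
    return layer


def _island_runs(data: RegionDataset, t: CoordinateTransform):
    runs = []
    current = None  # (class, first_x, last_x)
    for ann, _ in data.probes:
        cls = ann.island_class
        x = t.genomic_to_x(ann.position)
        if cls == "none":
            if current:
                runs.append(current)
                current = None
        elif current and current[0] == cls:
            current = (cls, current[1], x)
        else:
            if current:
                runs.append(current)
            current = (cls, x, x)
    if current:
        runs.append(current)
    return runs


def _draw_gene_track(track, region: GenomicRegion, cfg: PlotConfig, t: CoordinateTransform, genes):
    y_mid = t.bottom + 48.0
    exon_h = 10.0

    def clamp_x(position: int) -> float:
        return t.genomic_to_x(min(max(position, region.start), region.end))

    for gene in genes:
        if not gene.overlaps(region):
            continue
        g = ET.SubElement(track, "g")
        g.set("class", "gene")
        g.set("data-gene", gene.name)
        for intron_start, intron_end in gene.introns:
            if intron_end < region.start or intron_start > region.end:
                continue
            line = _sub(
                g,
                "line",
                x1=clamp_x(intron_start),
                y1=y_mid,
                x2=clamp_x(intron_end),
                y2=y_mid,
                stroke="#555555",
                stroke_width="1",
            )
            line.set("class", "gene-intron")
        for exon_start, exon_end in gene.exons:
            if exon_end < region.start or exon_start > region.end:
                continue
            x1, x2 = clamp_x(exon_start), clamp_x(exon_end)
            rect = _sub(
                g,
                "rect",
                x=x1,
                y=y_mid - exon_h / 2,
                width=max(1.0, x2 - x1),
                height=exon_h,
                fill="#555555",
            )
            rect.set("class", "gene-exon")
        label = _sub(
            g, "text", x=clamp_x(gene.start), y=y_mid + exon_h + 4, font_size="10"
        )
        label.set("class", "gene-label")
        label.text = gene.name


# ------------------------------------------------------------------- output

_RENDERERS = {
    "points": render_points,
    "distribution": render_distribution,
    "trace": render_trace,
}


def render(
    data: RegionDataset, groups: GroupAssignment, cfg: PlotConfig, genes=None
) -> ET.Element:
    """Render in the mode named by ``cfg.mode``."""
    return _RENDERERS[cfg.mode](data, groups, cfg, genes=genes)


def write_svg(document: ET.Element, stream) -> None:
    """Serialize to standards-conformant, deterministic SVG 1.1 text."""
    text = ET.tostring(document, encoding="unicode")
    payload = '<?xml version="1.0" encoding="UTF-8"?>\n' + text + "\n"
    if hasattr(stream, "write"):
        stream.write(payload)
    else:
        with open(stream, "w", encoding="utf-8") as fh:
            fh.write(payload)
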