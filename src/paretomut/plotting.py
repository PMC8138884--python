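"""Publication-style vector graphics for alteration data.

Three figure types:

* alteration (oncoprint/waterfall) plots — genes as rows, samples as
  columns; within each sample column the first altered gene in display
  order is drawn in the first-alteration color (blue) and every further
  altered gene in the overlap color (green), so green cell count equals
  the selection's overlap omega(G);
* Pareto-front scatter plots of (coverage, second objective);
* solution membership matrices comparing which genes occur in which
  Pareto solutions.

SVG output is produced by a small deterministic builder (fixed number
formatting, no timestamps): identical inputs give byte-identical files.
PDF and PNG render the same geometry through matplotlib.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from .errors import ConfigurationError
from .metrics import AlterationMatrix, GeneSelection, coverage
from .moea import COVERAGE_OVERLAP, ParetoSet
from .ordering import PlotOrder, make_plot_order

_HEX = re.compile(r"^#[0-9a-fA-F]{6}$")


@dataclass(frozen=True)
class PlotStyle:
    """Colors and geometry for the alteration-plot family."""

    first_alteration_color: str = "#1f77b4"   # blue: first alteration in sample
    overlap_color: str = "#2ca02c"            # green: overlapping alterations
    empty_color: str = "#ececec"
    highlight_color: str = "#cc00cc"          # magenta: highlighted solutions
    cell_width: float = 12.0
    cell_height: float = 16.0
    cell_gap: float = 1.0
    label_width: float = 110.0
    percent_width: float = 58.0
    group_band_height: float = 22.0
    font_size: float = 11.0
    dpi: int = 150

    def __post_init__(self):
        for name in ("first_alteration_color", "overlap_color",
                     "empty_color", "highlight_color"):
            if not _HEX.match(getattr(self, name)):
                raise ConfigurationError(f"{name} must be a #rrggbb hex color")
        if self.cell_width <= 0 or self.cell_height <= 0:
            raise ConfigurationError("cell dimensions must be positive")


def _fmt(v: float) -> str:
    return f"{v:.2f}".rstrip("0").rstrip(".")


class _Svg:
    """Minimal deterministic SVG 1.1 document builder."""

    def __init__(self, width: float, height: float):
        self.width = width
        self.height = height
        self.parts: list[str] = []

    def rect(self, x, y, w, h, fill, cls=None, extra=""):
        cls_attr = f' class="{cls}"' if cls else ""
        self.parts.append(
            f'<rect{cls_attr} x="{_fmt(x)}" y="{_fmt(y)}" width="{_fmt(w)}"'
            f' height="{_fmt(h)}" fill="{fill}"{extra}/>'
        )

    def circle(self, cx, cy, r, fill, cls=None):
        cls_attr = f' class="{cls}"' if cls else ""
        self.parts.append(
            f'<circle{cls_attr} cx="{_fmt(cx)}" cy="{_fmt(cy)}" r="{_fmt(r)}"'
            f' fill="{fill}"/>'
        )

    def line(self, x1, y1, x2, y2, stroke="#000000", width=1.0):
        self.parts.append(
            f'<line x1="{_fmt(x1)}" y1="{_fmt(y1)}" x2="{_fmt(x2)}"'
            f' y2="{_fmt(y2)}" stroke="{stroke}" stroke-width="{_fmt(width)}"/>'
        )

    def text(self, x, y, content, size, anchor="start", fill="#000000",
             rotate=None):
        content = (str(content).replace("&", "&amp;").replace("<", "&lt;")
                   .replace(">", "&gt;"))
        transform = ""
        if rotate is not None:
            transform = f' transform="rotate({_fmt(rotate)} {_fmt(x)} {_fmt(y)})"'
        self.parts.append(
            f'<text x="{_fmt(x)}" y="{_fmt(y)}" font-size="{_fmt(size)}"'
            f' font-family="Helvetica, Arial, sans-serif"'
            f' text-anchor="{anchor}" fill="{fill}"{transform}>{content}</text>'
        )

    def tostring(self) -> str:
        header = (
            '<?xml version="1.0" encoding="UTF-8"?>\n'
            f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
            f'width="{_fmt(self.width)}" height="{_fmt(self.height)}" '
            f'viewBox="0 0 {_fmt(self.width)} {_fmt(self.height)}">\n'
        )
        return header + "\n".join(self.parts) + "\n</svg>\n"


def _write(svg_text: str, path) -> None:
    Path(path).write_text(svg_text, encoding="utf-8")


# ---------------------------------------------------------------------------
# Alteration plot
# ---------------------------------------------------------------------------


def _alteration_cells(matrix, gene_order, sample_list):
    """Yield (gene_row, sample_col, is_first) for every filled cell."""
    pos = {s: i for i, s in enumerate(matrix.sample_ids)}
    values = matrix.values
    gidx = matrix.column_indices(gene_order)
    for j, sample in enumerate(sample_list):
        seen_first = False
        for i, gi in enumerate(gidx):
            if values[pos[sample], gi]:
                yield i, j, not seen_first
                seen_first = True


def render_alteration_plot(
    matrix: AlterationMatrix,
    selection,
    order: PlotOrder | None = None,
    groups=None,
    style: PlotStyle | None = None,
    path=None,
) -> str:
    """Render an oncoprint-style alteration plot; returns the SVG text.

    One row per gene (display order), one column per sample; the first
    altered gene per sample column gets the first-alteration color,
    subsequent altered genes the overlap color.  Per-gene coverage
    percentages are annotated on the right; group bands, when groups are
    given, above the columns.  ``path`` with a .pdf/.png suffix renders
    through matplotlib instead of the native SVG writer.
    """
    style = style or PlotStyle()
    sel = selection if isinstance(selection, GeneSelection) else GeneSelection(selection)
    if not sel.members:
        raise ConfigurationError("selection must be nonempty")
    if order is None:
        order = make_plot_order(matrix, sel, groups=groups)
    if set(order.gene_order) != set(sel.members):
        raise ConfigurationError("order.gene_order is not a permutation of the selection")
    known = set(matrix.sample_ids)
    unknown = [s for s in order.sample_order if s not in known]
    if unknown:
        raise ConfigurationError(f"unknown sample in order: {unknown[0]!r}")

    genes = list(order.gene_order)
    samples = list(order.sample_order)
    cw, ch, gap = style.cell_width, style.cell_height, style.cell_gap
    top = style.group_band_height if order.group_boundaries else 8.0
    left = style.label_width
    width = left + len(samples) * (cw + gap) + style.percent_width
    height = top + len(genes) * (ch + gap) + 8.0
    svg = _Svg(width, height)
    svg.rect(0, 0, width, height, "#ffffff")

    if order.group_boundaries:
        for label, start, stop in order.group_boundaries:
            x0 = left + start * (cw + gap)
            x1 = left + stop * (cw + gap) - gap
            svg.rect(x0, 2, max(x1 - x0, 0), style.group_band_height - 8,
                     "#d8d8d8", cls="group-band")
            svg.text((x0 + x1) / 2, style.group_band_height - 10, label,
                     style.font_size, anchor="middle")

    n = matrix.n_samples
    for i, gene in enumerate(genes):
        y = top + i * (ch + gap)
        svg.text(left - 6, y + ch * 0.72, gene, style.font_size, anchor="end")
        for j in range(len(samples)):
            svg.rect(left + j * (cw + gap), y, cw, ch, style.empty_color,
                     cls="cell empty")
        pct = 100.0 * coverage(GeneSelection([gene]), matrix) / n if n else 0.0
        svg.text(left + len(samples) * (cw + gap) + 4, y + ch * 0.72,
                 f"{pct:.1f}%", style.font_size)

    for i, j, is_first in _alteration_cells(matrix, genes, samples):
        y = top + i * (ch + gap)
        x = left + j * (cw + gap)
        color = style.first_alteration_color if is_first else style.overlap_color
        cls = "cell first" if is_first else "cell overlap"
        svg.rect(
            x, y, cw, ch, color, cls=cls,
            extra=f' data-gene="{genes[i]}" data-sample="{samples[j]}"',
        )

    text = svg.tostring()
    if path is not None:
        path = Path(path)
        if path.suffix.lower() in (".pdf", ".png"):
            _alteration_plot_mpl(matrix, genes, samples, order, style, path)
        else:
            _write(text, path)
    return text


def _alteration_plot_mpl(matrix, genes, samples, order, style, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    fig, ax = plt.subplots(
        figsize=(max(2.0, len(samples) * 0.12 + 1.5),
                 max(1.5, len(genes) * 0.3 + 0.5))
    )
    for i in range(len(genes)):
        for j in range(len(samples)):
            ax.add_patch(Rectangle((j, len(genes) - 1 - i), 0.92, 0.92,
                                   color=style.empty_color))
    for i, j, is_first in _alteration_cells(matrix, genes, samples):
        color = style.first_alteration_color if is_first else style.overlap_color
        ax.add_patch(Rectangle((j, len(genes) - 1 - i), 0.92, 0.92, color=color))
    ax.set_xlim(0, len(samples))
    ax.set_ylim(0, len(genes))
    ax.set_yticks([len(genes) - 1 - i + 0.5 for i in range(len(genes))])
    ax.set_yticklabels(genes, fontsize=8)
    ax.set_xticks([])
    fig.savefig(path, dpi=style.dpi, bbox_inches="tight")
    plt.close(fig)


# ---------------------------------------------------------------------------
# Pareto front scatter
# ---------------------------------------------------------------------------


def render_pareto_front(
    pareto: ParetoSet,
    highlight=None,
    path=None,
    style: PlotStyle | None = None,
) -> str:
    """Scatter of (coverage, second objective), one point per entry.

    ``highlight`` is an iterable of (coverage, second) tuples to mark in
    the highlight color (magenta).  Returns the SVG text.
    """
    style = style or PlotStyle()
    if not pareto.entries:
        raise ConfigurationError("pareto set must be nonempty")
    highlight = {tuple(h) for h in (highlight or ())}
    xs = [vec.coverage for _, vec in pareto.entries]
    ys = [vec.second for _, vec in pareto.entries]
    width, height = 420.0, 320.0
    ml, mr, mt, mb = 60.0, 16.0, 16.0, 48.0
    x0, x1 = 0, max(max(xs), 1)
    y0, y1 = 0, max(max(ys), 1)

    def sx(v):
        return ml + (v - x0) / (x1 - x0) * (width - ml - mr)

    def sy(v):
        return height - mb - (v - y0) / (y1 - y0) * (height - mt - mb)

    svg = _Svg(width, height)
    svg.rect(0, 0, width, height, "#ffffff")
    svg.line(ml, height - mb, width - mr, height - mb)
    svg.line(ml, mt, ml, height - mb)
    for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
        xv = round(x0 + frac * (x1 - x0))
        yv = round(y0 + frac * (y1 - y0))
        svg.line(sx(xv), height - mb, sx(xv), height - mb + 4)
        svg.text(sx(xv), height - mb + 16, xv, style.font_size, anchor="middle")
        svg.line(ml - 4, sy(yv), ml, sy(yv))
        svg.text(ml - 8, sy(yv) + 4, yv, style.font_size, anchor="end")
    second_label = "overlap" if pareto.mode == COVERAGE_OVERLAP else "genes"
    svg.text((ml + width - mr) / 2, height - 10, "coverage (samples)",
             style.font_size, anchor="middle")
    svg.text(14, (mt + height - mb) / 2, second_label, style.font_size,
             anchor="middle", rotate=-90)
    for x, y in zip(xs, ys):
        if (x, y) in highlight:
            svg.circle(sx(x), sy(y), 5.0, style.highlight_color,
                       cls="point highlight")
        else:
            svg.circle(sx(x), sy(y), 4.0, style.first_alteration_color,
                       cls="point")
    text = svg.tostring()
    if path is not None:
        path = Path(path)
        if path.suffix.lower() in (".pdf", ".png"):
            _pareto_front_mpl(xs, ys, highlight, second_label, style, path)
        else:
            _write(text, path)
    return text


def _pareto_front_mpl(xs, ys, highlight, second_label, style, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    plain = [(x, y) for x, y in zip(xs, ys) if (x, y) not in highlight]
    hi = [(x, y) for x, y in zip(xs, ys) if (x, y) in highlight]
    if plain:
        ax.scatter(*zip(*plain), color=style.first_alteration_color)
    if hi:
        ax.scatter(*zip(*hi), color=style.highlight_color, zorder=3)
    ax.set_xlabel("coverage (samples)")
    ax.set_ylabel(second_label)
    fig.savefig(path, dpi=style.dpi, bbox_inches="tight")
    plt.close(fig)


# ---------------------------------------------------------------------------
# Solution membership matrix
# ---------------------------------------------------------------------------


def render_solution_matrix(
    solutions,
    color_classes: dict | None = None,
    path=None,
    style: PlotStyle | None = None,
) -> str:
    """Membership matrix: rows = union of genes, columns = solutions.

    ``solutions`` is a list of (label, GeneSelection) pairs; a rectangle
    marks gene membership.  ``color_classes`` maps gene -> hex color (e.g.
    shared vs. newly identified genes); unlisted genes use the default
    first-alteration color.  Returns the SVG text.
    """
    style = style or PlotStyle()
    solutions = [(label, sel if isinstance(sel, GeneSelection) else GeneSelection(sel))
                 for label, sel in solutions]
    if not solutions:
        raise ConfigurationError("at least one solution is required")
    occurrence: dict[str, int] = {}
    for _, sel in solutions:
        for g in sel.members:
            occurrence[g] = occurrence.get(g, 0) + 1
    genes = sorted(occurrence, key=lambda g: (-occurrence[g], g))
    if color_classes:
        unknown = [g for g in color_classes if g not in occurrence]
        if unknown:
            raise ConfigurationError(
                f"color class references unknown gene {unknown[0]!r}"
            )
        for g, c in color_classes.items():
            if not _HEX.match(c):
                raise ConfigurationError(f"invalid color {c!r} for gene {g!r}")

    cw, ch, gap = style.cell_width + 6, style.cell_height, style.cell_gap
    left, top = style.label_width, 54.0
    width = left + len(solutions) * (cw + gap) + 10
    height = top + len(genes) * (ch + gap) + 8
    svg = _Svg(width, height)
    svg.rect(0, 0, width, height, "#ffffff")
    for j, (label, _) in enumerate(solutions):
        svg.text(left + j * (cw + gap) + cw / 2, top - 8, label,
                 style.font_size, anchor="end", rotate=-45)
    for i, gene in enumerate(genes):
        y = top + i * (ch + gap)
        svg.text(left - 6, y + ch * 0.72, gene, style.font_size, anchor="end")
        for j, (_, sel) in enumerate(solutions):
            x = left + j * (cw + gap)
            if gene in sel:
                color = (color_classes or {}).get(
                    gene, style.first_alteration_color
                )
                svg.rect(x, y, cw, ch, color, cls="member",
                         extra=f' data-gene="{gene}" data-solution="{j}"')
            else:
                svg.rect(x, y, cw, ch, style.empty_color, cls="absent")
    text = svg.tostring()
    if path is not None:
        path = Path(path)
        if path.suffix.lower() in (".pdf", ".png"):
            _solution_matrix_mpl(solutions, genes, color_classes, style, path)
        else:
            _write(text, path)
    return text


def _solution_matrix_mpl(solutions, genes, color_classes, style, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    fig, ax = plt.subplots(
        figsize=(max(2.0, len(solutions) * 0.4 + 1.5),
                 max(1.5, len(genes) * 0.3 + 0.8))
    )
    for i, gene in enumerate(genes):
        for j, (_, sel) in enumerate(solutions):
            if gene in sel:
                color = (color_classes or {}).get(
                    gene, style.first_alteration_color
                )
            else:
                color = style.empty_color
            ax.add_patch(Rectangle((j, len(genes) - 1 - i), 0.92, 0.92,
                                   color=color))
    ax.set_xlim(0, len(solutions))
    ax.set_ylim(0, len(genes))
    ax.set_yticks([len(genes) - 1 - i + 0.5 for i in range(len(genes))])
    ax.set_yticklabels(genes, fontsize=8)
    ax.set_xticks([j + 0.5 for j in range(len(solutions))])
    ax.set_xticklabels([label for label, _ in solutions], rotation=45,
                       ha="right", fontsize=8)
    fig.savefig(path, dpi=style.dpi, bbox_inches="tight")
    plt.close(fig)
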