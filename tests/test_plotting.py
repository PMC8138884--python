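"""SVG rendering of alteration plots, Pareto fronts and solution matrices."""

import xml.etree.ElementTree as ET

import pytest

from paretomut import (
    COVERAGE_SIZE,
    ConfigurationError,
    GeneSelection,
    coverage,
    make_plot_order,
    overlap,
    pareto_front_exact,
)
from paretomut.plotting import (
    PlotStyle,
    render_alteration_plot,
    render_pareto_front,
    render_solution_matrix,
)

STYLE = PlotStyle()


def _cells(svg_text, cls):
    root = ET.fromstring(svg_text)
    ns = "{http://www.w3.org/2000/svg}"
    return [el for el in root.iter() if el.get("class") == cls]


class TestAlterationPlot:
    def test_first_vs_overlap_color_assignment(self, toy_matrix):
        sel = GeneSelection(["g1", "g2", "g3"])
        order = make_plot_order(toy_matrix, sel)
        svg = render_alteration_plot(toy_matrix, sel, order=order)
        first = _cells(svg, "cell first")
        over = _cells(svg, "cell overlap")
        # filled cells = sum of singleton coverages; overlap cells = omega
        assert len(first) + len(over) == sum(
            coverage(GeneSelection([g]), toy_matrix) for g in sel.members)
        assert len(over) == overlap(sel, toy_matrix) == 1
        the_overlap = over[0]
        assert the_overlap.get("data-sample") == "s2"
        assert the_overlap.get("data-gene") == "g2"
        assert the_overlap.get("fill") == STYLE.overlap_color
        s2_first = [c for c in first if c.get("data-sample") == "s2"]
        assert s2_first[0].get("data-gene") == "g1"
        assert s2_first[0].get("fill") == STYLE.first_alteration_color

    def test_exclusive_matrix_has_no_overlap_cells(self, toy_matrix):
        sel = GeneSelection(["g1", "g3"])
        svg = render_alteration_plot(toy_matrix, sel)
        assert _cells(svg, "cell overlap") == []
        assert len(_cells(svg, "cell first")) == 3

    def test_single_cell_plot(self, toy_matrix):
        svg = render_alteration_plot(toy_matrix.subset(samples=["s4"]),
                                     GeneSelection(["g3"]))
        assert len(_cells(svg, "cell first")) == 1

    def test_rendering_is_byte_identical(self, toy_matrix, tmp_path):
        sel = GeneSelection(["g1", "g2", "g3"])
        a = render_alteration_plot(toy_matrix, sel, path=tmp_path / "a.svg")
        b = render_alteration_plot(toy_matrix, sel, path=tmp_path / "b.svg")
        assert a == b
        assert (tmp_path / "a.svg").read_bytes() == \
            (tmp_path / "b.svg").read_bytes()

    def test_group_bands_rendered(self, toy_matrix):
        groups = {"A": ["s1", "s2"], "B": ["s3", "s4"]}
        order = make_plot_order(toy_matrix, ["g1", "g2", "g3"], groups=groups)
        svg = render_alteration_plot(toy_matrix, ["g1", "g2", "g3"],
                                     order=order, groups=groups)
        assert len(_cells(svg, "group-band")) == 2

    def test_empty_selection_rejected(self, toy_matrix):
        with pytest.raises(ConfigurationError):
            render_alteration_plot(toy_matrix, GeneSelection())

    def test_svg_parses_and_pdf_png_written(self, toy_matrix, tmp_path):
        sel = GeneSelection(["g1", "g2"])
        svg = render_alteration_plot(toy_matrix, sel, path=tmp_path / "p.svg")
        ET.fromstring(svg)  # valid XML
        render_alteration_plot(toy_matrix, sel, path=tmp_path / "p.png")
        render_alteration_plot(toy_matrix, sel, path=tmp_path / "p.pdf")
        assert (tmp_path / "p.png").stat().st_size > 0
        assert (tmp_path / "p.pdf").stat().st_size > 0


class TestParetoFrontPlot:
    def test_point_counts_and_highlight(self, toy_matrix):
        ps = pareto_front_exact(toy_matrix, mode=COVERAGE_SIZE)
        svg = render_pareto_front(ps, highlight=[(3, 2)])
        assert len(_cells(svg, "point")) == len(ps) - 1
        assert len(_cells(svg, "point highlight")) == 1

    def test_single_entry_set(self, toy_matrix):
        ps = pareto_front_exact(toy_matrix, candidate_genes=[],
                                mode=COVERAGE_SIZE)
        svg = render_pareto_front(ps)
        assert len(_cells(svg, "point")) == 1

    def test_front_is_a_monotone_staircase(self, toy_matrix):
        ps = pareto_front_exact(toy_matrix, mode=COVERAGE_SIZE)
        vecs = ps.vectors()
        assert vecs == sorted(vecs)
        xs = [v[0] for v in vecs]
        ys = [v[1] for v in vecs]
        assert xs == sorted(xs) and ys == sorted(ys)

    def test_determinism(self, toy_matrix):
        ps = pareto_front_exact(toy_matrix, mode=COVERAGE_SIZE)
        assert render_pareto_front(ps) == render_pareto_front(ps)


class TestSolutionMatrix:
    def test_membership_rectangle_count(self):
        sols = [
            ("A", GeneSelection(["g1", "g2"])),
            ("B", GeneSelection(["g2", "g3", "g4"])),
            ("C", GeneSelection(["g1"])),
        ]
        svg = render_solution_matrix(sols)
        assert len(_cells(svg, "member")) == sum(len(s) for _, s in sols)

    def test_identical_solutions_have_identical_columns(self):
        sols = [("A", GeneSelection(["x", "y"])), ("B", GeneSelection(["x", "y"]))]
        svg = render_solution_matrix(sols)
        members = _cells(svg, "member")
        by_col = {}
        for m in members:
            by_col.setdefault(m.get("data-solution"), set()).add(m.get("data-gene"))
        assert by_col["0"] == by_col["1"] == {"x", "y"}

    def test_disjoint_solutions_never_share_a_row(self):
        sols = [("A", GeneSelection(["a", "b"])), ("B", GeneSelection(["c"]))]
        svg = render_solution_matrix(sols)
        genes = [m.get("data-gene") for m in _cells(svg, "member")]
        assert len(genes) == len(set(genes))

    def test_color_classes_applied_and_validated(self):
        sols = [("A", GeneSelection(["a", "b"]))]
        svg = render_solution_matrix(sols, color_classes={"a": "#ff8800"})
        fills = {m.get("data-gene"): m.get("fill") for m in _cells(svg, "member")}
        assert fills["a"] == "#ff8800"
        assert fills["b"] == STYLE.first_alteration_color
        with pytest.raises(ConfigurationError, match="unknown gene"):
            render_solution_matrix(sols, color_classes={"zz": "#000000"})


def test_style_validation():
    with pytest.raises(ConfigurationError):
        PlotStyle(first_alteration_color="blue")
    with pytest.raises(ConfigurationError):
        PlotStyle(cell_width=0)
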