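import math
import statistics

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betascope import (
    GenomicRegion,
    GroupSpec,
    PlotConfig,
    ProbeAnnotation,
    RegionDataset,
    SampleRecord,
    group_samples,
    parse_gene_models,
    render,
    render_distribution,
    render_points,
    render_trace,
)
from betascope.errors import RenderError
from betascope.viz import CoordinateTransform, moving_average
from _svg import by_class, circle_centers, parse, polyline_points, to_text


def build_dataset(probe_betas, sex_by_sample, region=None, island=None, **ann_overrides):
    """probe_betas: {position: {sample_id: beta}}; island: {position: class}."""
    positions = sorted(probe_betas)
    probes = []
    for i, pos in enumerate(positions, 1):
        ann = ProbeAnnotation(
            probe_id=f"p{i:04d}",
            chromosome="chr1",
            position=pos,
            island_class=(island or {}).get(pos, "none"),
            **{k: v.get(pos, False) if isinstance(v, dict) else v
               for k, v in ann_overrides.items()},
        )
        probes.append((ann, dict(probe_betas[pos])))
    samples = [
        SampleRecord(sid, "p1", {"sex": sex} if sex is not None else {})
        for sid, sex in sex_by_sample.items()
    ]
    if region is None:
        region = GenomicRegion("chr1", positions[0], positions[-1])
    return RegionDataset(region=region, probes=probes, samples=samples)


def sex_groups(data):
    return group_samples(data.samples, GroupSpec(mode="within_project", keys=("sex",)))


@pytest.fixture
def simple_data():
    return build_dataset(
        {100: {"s1": 0.2, "s2": 0.4, "s3": 0.9}, 200: {"s1": 0.6, "s2": 0.8, "s3": 0.1}},
        {"s1": "F", "s2": "F", "s3": "M"},
    )


class TestCoordinateTransform:
    @pytest.fixture
    def transform(self):
        return CoordinateTransform(GenomicRegion("chr1", 100, 300), PlotConfig())

    def test_beta_bounds_map_to_plot_box_edges(self, transform):
        assert transform.beta_to_y(0.0) == transform.bottom
        assert transform.beta_to_y(1.0) == transform.top

    def test_beta_midpoint(self, transform):
        assert transform.beta_to_y(0.5) == pytest.approx(
            (transform.top + transform.bottom) / 2
        )

    def test_position_bounds_and_midpoint(self, transform):
        assert transform.genomic_to_x(100) == transform.left
        assert transform.genomic_to_x(300) == transform.right
        assert transform.genomic_to_x(200) == pytest.approx(
            (transform.left + transform.right) / 2
        )

    def test_out_of_range_rejected(self, transform):
        with pytest.raises(RenderError):
            transform.genomic_to_x(99)
        with pytest.raises(RenderError):
            transform.beta_to_y(1.5)

    @settings(max_examples=50, deadline=None)
    @given(
        p1=st.integers(100, 300),
        p2=st.integers(100, 300),
        b1=st.floats(0, 1, allow_nan=False),
        b2=st.floats(0, 1, allow_nan=False),
    )
    def test_monotone(self, p1, p2, b1, b2):
        transform = CoordinateTransform(GenomicRegion("chr1", 100, 300), PlotConfig())
        if p1 < p2:
            assert transform.genomic_to_x(p1) < transform.genomic_to_x(p2)
        if b1 < b2:
            # SVG y grows downward; differences below pixel/float resolution
            # may collapse to equal coordinates
            y1, y2 = transform.beta_to_y(b1), transform.beta_to_y(b2)
            assert y1 >= y2
            if b2 - b1 > 1e-12:
                assert y1 > y2

    def test_single_position_region_centers(self):
        t = CoordinateTransform(GenomicRegion("chr1", 100, 100), PlotConfig())
        assert t.genomic_to_x(100) == pytest.approx((t.left + t.right) / 2)


class TestPlotConfig:
    def test_even_trace_window_rejected(self):
        with pytest.raises(RenderError, match="odd"):
            PlotConfig(trace_window=2)

    def test_bad_mode_rejected(self):
        with pytest.raises(RenderError, match="points"):
            PlotConfig(mode="heatmap")

    def test_mode_mismatch_rejected(self, simple_data):
        with pytest.raises(RenderError, match="points"):
            render_points(simple_data, sex_groups(simple_data), PlotConfig(mode="trace"))


class TestRenderPoints:
    def test_circle_count(self, simple_data):
        root = parse(render_points(simple_data, sex_groups(simple_data), PlotConfig()))
        assert len(circle_centers(root)) == 6

    def test_excluded_sample_has_no_circles(self):
        data = build_dataset(
            {100: {"s1": 0.2, "s2": 0.4}, 200: {"s1": 0.6, "s2": 0.8}},
            {"s1": "F", "s2": None},
        )
        groups = sex_groups(data)
        assert groups.excluded == ["s2"]
        root = parse(render_points(data, groups, PlotConfig()))
        points = by_class(root, "data-point")
        assert len(points) == 2
        assert {el.get("data-sample") for el in points} == {"s1"}

    def test_circle_centers_match_transform_oracle(self, simple_data):
        cfg = PlotConfig()
        t = CoordinateTransform(simple_data.region, cfg)
        root = parse(render_points(simple_data, sex_groups(simple_data), cfg))
        expected = {
            (t.genomic_to_x(ann.position), t.beta_to_y(beta))
            for ann, betas in simple_data.probes
            for beta in betas.values()
        }
        recovered = circle_centers(root)
        assert len(recovered) == len(expected)
        for cx, cy in recovered:
            assert any(
                abs(cx - ex) <= 0.5 and abs(cy - ey) <= 0.5 for ex, ey in expected
            )

    def test_tooltips_name_sample_and_metadata(self, simple_data):
        root = parse(render_points(simple_data, sex_groups(simple_data), PlotConfig()))
        titles = [el.text for el in root.iter() if el.tag.endswith("title")]
        assert any("s1" in t and "sex=F" in t for t in titles)

    def test_group_colors_follow_label_order(self, simple_data):
        cfg = PlotConfig()
        groups = sex_groups(simple_data)
        root = parse(render_points(simple_data, groups, cfg))
        colors = {
            el.get("data-sample"): el.get("fill") for el in by_class(root, "data-point")
        }
        # labels sorted: F before M
        assert colors["s1"] == colors["s2"] == cfg.palette[0]
        assert colors["s3"] == cfg.palette[1]

    def test_empty_dataset_renders_with_message(self):
        data = RegionDataset(GenomicRegion("chr1", 1, 100), [], [])
        groups = group_samples([], GroupSpec(mode="within_project", keys=("sex",)))
        root = parse(render_points(data, groups, PlotConfig()))
        messages = by_class(root, "empty-message")
        assert messages and messages[0].text == "no probes in region"


class TestRenderDistribution:
    def test_mean_range_glyph_arithmetic(self):
        data = build_dataset({100: {"s1": 0.2, "s2": 0.4}}, {"s1": "F", "s2": "F"})
        cfg = PlotConfig(mode="distribution")
        t = CoordinateTransform(data.region, cfg)
        root = parse(render_distribution(data, sex_groups(data), cfg))
        whisker = by_class(root, "dist-whisker")[0]
        assert float(whisker.get("y1")) == pytest.approx(t.beta_to_y(0.4), abs=0.5)
        assert float(whisker.get("y2")) == pytest.approx(t.beta_to_y(0.2), abs=0.5)
        mean = by_class(root, "dist-mean")[0]
        assert float(mean.get("y1")) == pytest.approx(t.beta_to_y(0.3), abs=0.5)

    def test_single_member_group_degenerate_whisker(self):
        data = build_dataset({100: {"s1": 0.5}}, {"s1": "F"})
        cfg = PlotConfig(mode="distribution")
        root = parse(render_distribution(data, sex_groups(data), cfg))
        whisker = by_class(root, "dist-whisker")[0]
        assert float(whisker.get("y1")) == float(whisker.get("y2"))

    def test_glyph_extents_match_brute_force(self):
        data = build_dataset(
            {
                100: {"s1": 0.1, "s2": 0.9, "s3": 0.5, "s4": 0.4},
                200: {"s1": 0.3, "s3": 0.2, "s4": 0.8},
            },
            {"s1": "F", "s2": "F", "s3": "M", "s4": "M"},
        )
        cfg = PlotConfig(mode="distribution")
        t = CoordinateTransform(data.region, cfg)
        groups = sex_groups(data)
        root = parse(render_distribution(data, groups, cfg))
        member_of = {"s1": "F", "s2": "F", "s3": "M", "s4": "M"}
        for glyph in by_class(root, "dist-glyph"):
            probe = glyph.get("data-probe")
            label = glyph.get("data-group")
            betas = dict(data.probes[0 if probe == "p0001" else 1][1])
            values = [b for sid, b in betas.items() if member_of[sid] == label]
            whisker = by_class(glyph, "dist-whisker")[0]
            assert float(whisker.get("y1")) == pytest.approx(
                t.beta_to_y(max(values)), abs=0.5
            )
            assert float(whisker.get("y2")) == pytest.approx(
                t.beta_to_y(min(values)), abs=0.5
            )
            mean_el = by_class(glyph, "dist-mean")[0]
            assert float(mean_el.get("y1")) == pytest.approx(
                t.beta_to_y(statistics.fmean(values)), abs=0.5
            )

    def test_box_glyph_median_and_quartiles(self):
        values = [0.1, 0.2, 0.4, 0.8]
        data = build_dataset(
            {100: {f"s{i}": v for i, v in enumerate(values)}},
            {f"s{i}": "F" for i in range(len(values))},
        )
        cfg = PlotConfig(mode="distribution", distribution_glyph="box")
        t = CoordinateTransform(data.region, cfg)
        root = parse(render_distribution(data, sex_groups(data), cfg))
        median = by_class(root, "dist-median")[0]
        assert float(median.get("y1")) == pytest.approx(
            t.beta_to_y(statistics.median(values)), abs=0.5
        )
        box = by_class(root, "dist-box")[0]
        # linear-interpolation quartiles, computed by hand:
        # q1 at index 0.75 -> 0.175 ; q3 at index 2.25 -> 0.5
        y_q3 = t.beta_to_y(0.5)
        y_q1 = t.beta_to_y(0.175)
        assert float(box.get("y")) == pytest.approx(y_q3, abs=0.5)
        assert float(box.get("y")) + float(box.get("height")) == pytest.approx(
            y_q1, abs=0.5
        )

    def test_fan_offsets_centered_in_label_order(self):
        data = build_dataset(
            {100: {"s1": 0.5, "s2": 0.5}}, {"s1": "F", "s2": "M"},
            region=GenomicRegion("chr1", 50, 150),
        )
        cfg = PlotConfig(mode="distribution", glyph_spacing=8.0)
        t = CoordinateTransform(data.region, cfg)
        root = parse(render_distribution(data, sex_groups(data), cfg))
        xs = {
            g.get("data-group"): float(by_class(g, "dist-whisker")[0].get("x1"))
            for g in by_class(root, "dist-glyph")
        }
        center = t.genomic_to_x(100)
        assert xs["F"] == pytest.approx(center - 4.0, abs=0.5)
        assert xs["M"] == pytest.approx(center + 4.0, abs=0.5)


class TestRenderTrace:
    def test_polyline_through_group_means(self):
        data = build_dataset(
            {100: {"s1": 0.2, "s2": 0.4}, 200: {"s1": 0.6, "s2": 0.8}},
            {"s1": "F", "s2": "F"},
        )
        cfg = PlotConfig(mode="trace")
        t = CoordinateTransform(data.region, cfg)
        root = parse(render_trace(data, sex_groups(data), cfg))
        lines = by_class(root, "trace")
        assert len(lines) == 1
        pts = polyline_points(lines[0])
        assert pts[0][1] == pytest.approx(t.beta_to_y(0.3), abs=0.5)
        assert pts[1][1] == pytest.approx(t.beta_to_y(0.7), abs=0.5)

    def test_window_three_centered_average(self):
        data = build_dataset(
            {100: {"s1": 0.1}, 200: {"s1": 0.5}, 300: {"s1": 0.9}},
            {"s1": "F"},
        )
        cfg = PlotConfig(mode="trace", trace_window=3)
        t = CoordinateTransform(data.region, cfg)
        root = parse(render_trace(data, sex_groups(data), cfg))
        pts = polyline_points(by_class(root, "trace")[0])
        # middle vertex: full window; edges: truncated window
        assert pts[1][1] == pytest.approx(t.beta_to_y(0.5), abs=0.5)
        assert pts[0][1] == pytest.approx(t.beta_to_y(0.3), abs=0.5)
        assert pts[2][1] == pytest.approx(t.beta_to_y(0.7), abs=0.5)

    def test_probe_without_group_data_skipped_not_zero(self):
        data = build_dataset(
            {100: {"s1": 0.4}, 200: {"s2": 0.9}, 300: {"s1": 0.6}},
            {"s1": "F", "s2": "M"},
        )
        cfg = PlotConfig(mode="trace")
        root = parse(render_trace(data, sex_groups(data), cfg))
        f_line = [l for l in by_class(root, "trace") if l.get("data-group") == "F"][0]
        assert len(polyline_points(f_line)) == 2  # probe at 200 skipped

    def test_single_probe_group_renders_point_marker(self):
        data = build_dataset(
            {100: {"s1": 0.4, "s2": 0.5}, 200: {"s1": 0.6}},
            {"s1": "F", "s2": "M"},
        )
        cfg = PlotConfig(mode="trace")
        root = parse(render_trace(data, sex_groups(data), cfg))
        assert len(by_class(root, "trace")) == 1  # F has 2 probes
        markers = by_class(root, "trace-point")
        assert len(markers) == 1 and markers[0].get("data-group") == "M"

    def test_vertices_match_oracle_after_smoothing(self):
        probe_betas = {
            pos: {f"s{i}": ((pos + 37 * i) % 97) / 96 for i in range(6)}
            for pos in (100, 150, 260, 300, 410)
        }
        data = build_dataset(probe_betas, {f"s{i}": "FM"[i % 2] for i in range(6)})
        cfg = PlotConfig(mode="trace", trace_window=3)
        t = CoordinateTransform(data.region, cfg)
        root = parse(render_trace(data, sex_groups(data), cfg))
        for label in ("F", "M"):
            members = [f"s{i}" for i in range(6) if "FM"[i % 2] == label]
            means = []
            for pos in sorted(probe_betas):
                values = [probe_betas[pos][m] for m in members if m in probe_betas[pos]]
                means.append(sum(values) / len(values))
            smoothed = moving_average(means, 3)
            line = [l for l in by_class(root, "trace") if l.get("data-group") == label][0]
            pts = polyline_points(line)
            for (x, y), pos, mean in zip(pts, sorted(probe_betas), smoothed):
                assert x == pytest.approx(t.genomic_to_x(pos), abs=0.5)
                assert y == pytest.approx(t.beta_to_y(mean), abs=0.5)


class TestAnnotationLayers:
    def test_consecutive_island_probes_merge_to_one_rectangle(self):
        data = build_dataset(
            {p: {"s1": 0.5} for p in (100, 200, 300, 400)},
            {"s1": "F"},
            island={200: "high_density", 300: "high_density", 400: "high_density"},
        )
        root = parse(render_points(data, sex_groups(data), PlotConfig()))
        rects = by_class(root, "island-high_density")
        assert len(rects) == 1

    def test_island_rectangle_spans_probes(self):
        cfg = PlotConfig()
        data = build_dataset(
            {p: {"s1": 0.5} for p in (100, 200, 300, 400)},
            {"s1": "F"},
            island={200: "high_density", 300: "high_density"},
        )
        t = CoordinateTransform(data.region, cfg)
        root = parse(render_points(data, sex_groups(data), cfg))
        rect = by_class(root, "island-high_density")[0]
        x0, width = float(rect.get("x")), float(rect.get("width"))
        assert x0 <= t.genomic_to_x(200) and x0 + width >= t.genomic_to_x(300)
        assert float(rect.get("height")) == pytest.approx(t.bottom - t.top)

    def test_mixed_classes_split_runs(self):
        data = build_dataset(
            {p: {"s1": 0.5} for p in (100, 200, 300)},
            {"s1": "F"},
            island={
                100: "high_density",
                200: "intermediate_density",
                300: "high_density",
            },
        )
        root = parse(render_points(data, sex_groups(data), PlotConfig()))
        assert len(by_class(root, "island-high_density")) == 2
        assert len(by_class(root, "island-intermediate_density")) == 1

    def test_probe_with_both_snp_flags_gets_two_squares(self):
        data = build_dataset(
            {100: {"s1": 0.5}, 200: {"s1": 0.5}},
            {"s1": "F"},
            snp_in_probe={100: True},
            snp_at_cpg={100: True},
        )
        root = parse(render_points(data, sex_groups(data), PlotConfig()))
        in_probe = by_class(root, "marker-snp-in-probe")
        at_cpg = by_class(root, "marker-snp-at-cpg")
        assert len(in_probe) == 1 and len(at_cpg) == 1
        # two marker rows: different y
        assert float(in_probe[0].get("y")) != float(at_cpg[0].get("y"))

    def test_snp_at_cpg_marker_is_red_below_axis(self):
        cfg = PlotConfig()
        data = build_dataset({100: {"s1": 0.5}}, {"s1": "F"}, snp_at_cpg={100: True})
        t = CoordinateTransform(data.region, cfg)
        root = parse(render_points(data, sex_groups(data), cfg))
        marker = by_class(root, "marker-snp-at-cpg")[0]
        assert marker.get("fill") == cfg.marker_colors["snp_at_cpg"]
        assert float(marker.get("y")) > t.bottom  # below the x-axis

    def test_unreliable_probe_tick_in_third_row(self):
        data = build_dataset({100: {"s1": 0.5}}, {"s1": "F"}, reliable={100: False})
        root = parse(render_points(data, sex_groups(data), PlotConfig()))
        assert len(by_class(root, "marker-unreliable")) == 1

    def test_gene_track_exons_and_introns(self):
        bed = "chr1\t99\t400\tGENE1\t0\t+\t99\t400\t0\t3\t50,50,50,\t0,120,251,\n"
        genes = parse_gene_models(bed)
        data = build_dataset({150: {"s1": 0.5}, 350: {"s1": 0.6}}, {"s1": "F"},
                             region=GenomicRegion("chr1", 90, 410))
        root = parse(render_points(data, sex_groups(data), PlotConfig(), genes=genes))
        assert len(by_class(root, "gene-exon")) == 3
        assert len(by_class(root, "gene-intron")) == 2
        assert by_class(root, "gene-label")[0].text == "GENE1"


class TestSvgOutput:
    def test_output_is_well_formed_xml_with_size(self, simple_data):
        text = to_text(render_points(simple_data, sex_groups(simple_data), PlotConfig()))
        root = parse(text)
        assert root.tag.endswith("svg")
        assert root.get("width") == "900"
        assert root.get("height") == "460"
        assert text.startswith('<?xml version="1.0"')

    def test_empty_plot_parses(self):
        data = RegionDataset(GenomicRegion("chr1", 1, 10), [], [])
        groups = group_samples([], GroupSpec(mode="within_project", keys=("x",)))
        for mode, fn in (
            ("points", render_points),
            ("distribution", render_distribution),
            ("trace", render_trace),
        ):
            parse(fn(data, groups, PlotConfig(mode=mode)))

    def test_byte_identical_for_identical_inputs(self, simple_data):
        texts = {
            to_text(render_points(simple_data, sex_groups(simple_data), PlotConfig()))
            for _ in range(3)
        }
        assert len(texts) == 1

    def test_all_modes_validate_for_xci_fixture(self, xci_store):
        region = xci_store.resolve_locus("XISTL", flank=100)
        data = xci_store.query_region(region, ["xci_demo"])
        groups = sex_groups(data)
        for mode in ("points", "distribution", "trace"):
            parse(render(data, groups, PlotConfig(mode=mode)))


class TestInvariants:
    @settings(max_examples=30, deadline=None)
    @given(data=st.data())
    def test_data_glyphs_inside_plot_box(self, data):
        n_probes = data.draw(st.integers(1, 6))
        positions = sorted(
            data.draw(
                st.lists(st.integers(1, 1000), min_size=n_probes, max_size=n_probes,
                         unique=True)
            )
        )
        n_samples = data.draw(st.integers(1, 5))
        probe_betas = {}
        for pos in positions:
            betas = {}
            for i in range(n_samples):
                if data.draw(st.booleans()):
                    betas[f"s{i}"] = data.draw(st.floats(0, 1, allow_nan=False))
            probe_betas[pos] = betas
        ds = build_dataset(
            probe_betas,
            {f"s{i}": ["F", "M"][i % 2] for i in range(n_samples)},
            region=GenomicRegion("chr1", 1, 1000),
        )
        cfg = PlotConfig()
        t = CoordinateTransform(ds.region, cfg)
        root = parse(render_points(ds, sex_groups(ds), cfg))
        for cx, cy in circle_centers(root):
            assert t.left <= cx <= t.right
            assert t.top <= cy <= t.bottom

    def test_superimposition_no_per_group_rescaling(self, simple_data):
        """Rendering each group alone (same region/config) yields the same
        circle centers as the combined render."""
        cfg = PlotConfig()
        groups = sex_groups(simple_data)
        combined = sorted(circle_centers(parse(render_points(simple_data, groups, cfg))))
        solo_centers = []
        for label in groups.labels:
            members = set(groups.groups[label])
            subset = RegionDataset(
                region=simple_data.region,
                probes=[
                    (ann, {sid: b for sid, b in betas.items() if sid in members})
                    for ann, betas in simple_data.probes
                ],
                samples=[s for s in simple_data.samples if s.sample_id in members],
            )
            solo = group_samples(
                subset.samples, GroupSpec(mode="within_project", keys=("sex",))
            )
            solo_centers.extend(circle_centers(parse(render_points(subset, solo, cfg))))
        assert sorted(solo_centers) == combined

    def test_moving_average_window_one_is_identity(self):
        series = [0.1, 0.9, 0.4]
        assert moving_average(series, 1) == series
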