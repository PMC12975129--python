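"""Windowing, class annotation, log2 enrichment and per-class summaries."""

import numpy as np
import pytest

from talerep import (
    AnnotationSet,
    CoverageTrack,
    Genome,
    Interval,
    annotate_windows,
    class_summary,
    enrichment,
    normalize_to_control,
    profile,
    read_bedgraph,
    window_genome,
    write_bedgraph,
)
from talerep.repeat_profiler import BACKGROUND_LABEL


def genome_of_length(n, name="chr1"):
    return Genome({name: "A" * n})


class TestWindowing:
    def test_tiled_windows_keep_terminal_partial(self):
        grid = window_genome(genome_of_length(120), width=50)
        assert [(w.start, w.end) for w in grid.intervals] == [(0, 50), (50, 100), (100, 120)]
        assert list(grid.partial) == [False, False, True]

    def test_exact_fit_single_window(self):
        grid = window_genome(genome_of_length(50), width=50)
        assert [(w.start, w.end) for w in grid.intervals] == [(0, 50)]

    def test_sliding_windows(self):
        grid = window_genome(genome_of_length(60), width=50, step=5)
        assert [w.start for w in grid.intervals] == [0, 5, 10]

    def test_width_exceeding_sequence_warns_single_partial(self):
        with pytest.warns(UserWarning, match="partial"):
            grid = window_genome(genome_of_length(30), width=50)
        assert [(w.start, w.end) for w in grid.intervals] == [(0, 30)]

    def test_invalid_parameters(self):
        g = genome_of_length(100)
        with pytest.raises(ValueError):
            window_genome(g, width=0)
        with pytest.raises(ValueError):
            window_genome(g, width=50, step=60)


class TestAnnotateWindows:
    @pytest.fixture
    def grid(self):
        return window_genome(genome_of_length(200), width=50)

    def test_single_bp_overlap_assigns_class(self, grid):
        ann = AnnotationSet({"TEL": [Interval("chr1", 40, 200)]})
        classes = annotate_windows(grid, ann)
        assert classes[0] == frozenset({"TEL"})

    def test_multi_class_window_carries_all_labels(self, grid):
        ann = AnnotationSet(
            {"TEL": [Interval("chr1", 40, 60)], "R70": [Interval("chr1", 55, 80)]}
        )
        classes = annotate_windows(grid, ann)
        assert classes[1] == frozenset({"TEL", "R70"})

    def test_no_overlap_is_background(self, grid):
        ann = AnnotationSet({"TEL": [Interval("chr1", 100, 150)]})
        classes = annotate_windows(grid, ann)
        assert classes[0] == frozenset()


class TestEnrichment:
    def test_identical_tracks_give_zero_everywhere(self):
        t = CoverageTrack("a", np.array([3.0, 5.0, 7.0]), 50)
        assert np.allclose(enrichment(t, CoverageTrack("b", np.array([3.0, 5.0, 7.0]), 50)), 0)

    def test_closed_form_with_pseudocount(self):
        # cpm values 7 and 1 with c = 1 -> log2(8/2) = 2
        ip = CoverageTrack("ip", np.array([7.0]), 50, total_reads=1e6)
        inp = CoverageTrack("in", np.array([1.0]), 50, total_reads=1e6)
        assert enrichment(ip, inp, pseudocount_cpm=1.0)[0] == pytest.approx(2.0)

    def test_zero_counts_both_tracks_give_zero(self):
        ip = CoverageTrack("ip", np.array([0.0, 10.0]), 50)
        inp = CoverageTrack("in", np.array([0.0, 10.0]), 50)
        assert enrichment(ip, inp)[0] == 0.0

    def test_grid_mismatch_is_error(self):
        with pytest.raises(ValueError):
            enrichment(
                CoverageTrack("a", np.ones(3), 50), CoverageTrack("b", np.ones(4), 50)
            )

    def test_scaling_invariance_up_to_pseudocount(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(500, size=1000).astype(float)
        ip = CoverageTrack("ip", counts, 50)
        inp = CoverageTrack("in", rng.poisson(500, size=1000).astype(float), 50)
        base = enrichment(ip, inp)
        scaled = enrichment(
            CoverageTrack("ip", counts * 17, 50),
            CoverageTrack("in", inp.values * 17, 50),
        )
        assert np.max(np.abs(base - scaled)) <= 0.01

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            CoverageTrack("a", np.array([1.0, -2.0]), 50)


class TestNormalization:
    def test_self_subtraction_is_zero(self):
        x = np.array([0.3, -1.2, 2.0])
        assert np.allclose(normalize_to_control(x, x), 0)

    def test_windowwise_subtraction(self):
        assert normalize_to_control(np.array([2.0]), np.array([0.5]))[0] == 1.5

    def test_shape_mismatch_is_error(self):
        with pytest.raises(ValueError):
            normalize_to_control(np.ones(3), np.ones(4))

    def test_profile_without_notag_keeps_raw_ratio_only(self):
        g = genome_of_length(500)
        ann = AnnotationSet({"X": [Interval("chr1", 0, 100)]})
        tracks = [CoverageTrack(s, np.full(10, 50.0), 50) for s in ("ip", "in")]
        _, per_window, _ = profile(g, ann, tracks[0], tracks[1])
        assert "normalized" not in per_window.columns
        assert "log2_ratio" in per_window.columns


class TestClassSummary:
    def test_constant_field_gives_equal_means_and_zero_delta(self):
        grid = window_genome(genome_of_length(500), width=50)
        ann = AnnotationSet({"X": [Interval("chr1", 0, 100)]})
        classes = annotate_windows(grid, ann)
        df = class_summary(grid, classes, np.full(10, 1.5))
        assert set(df["class_label"]) == {BACKGROUND_LABEL, "X"}
        assert np.allclose(df["mean"], 1.5)
        assert np.allclose(df["delta"][df["class_label"] == "X"], 0.0)

    def test_window_accounting_partition(self):
        grid = window_genome(genome_of_length(1000), width=50)
        ann = AnnotationSet(
            {
                "A": [Interval("chr1", 0, 120)],
                "B": [Interval("chr1", 100, 220)],
            }
        )
        classes = annotate_windows(grid, ann)
        df = class_summary(grid, classes, np.zeros(20))
        n = df.attrs
        assert n["n_background"] + n["n_multi_class"] + n["n_single_class"] == n["n_windows_total"]
        # window [100,150) overlaps both A and B
        assert n["n_multi_class"] == 1

    def test_class_without_single_class_windows_warns_and_omitted(self):
        grid = window_genome(genome_of_length(100), width=50)
        ann = AnnotationSet(
            {"A": [Interval("chr1", 0, 100)], "B": [Interval("chr1", 0, 100)]}
        )
        classes = annotate_windows(grid, ann)
        with pytest.warns(UserWarning, match="no single-class"):
            df = class_summary(grid, classes, np.zeros(2))
        assert set(df["class_label"]) == set()  # only multi-class windows exist

    def test_planted_fold_recovered_as_delta(self):
        from talerep import CoverageSpec, make_genome, simulate_coverage, study_like_spec

        spec = study_like_spec(seed=5, scale=0.1)
        genome, ann, _ = make_genome(spec)
        cov = CoverageSpec(depth=100, fold={"REP177": 4.0}, seed=17)
        grid = window_genome(genome, width=50)
        ip = simulate_coverage(genome, ann, cov, "ip", grid=grid)
        inp = simulate_coverage(genome, ann, cov, "input", grid=grid)
        ntg = simulate_coverage(genome, ann, cov, "notag", grid=grid)
        _, _, summary = profile(genome, ann, ip, inp, notag_ip=ntg)
        delta = summary.set_index("class_label").loc["REP177", "delta"]
        assert delta == pytest.approx(2.0, abs=0.2)


class TestBedgraphIO:
    def test_window_aligned_roundtrip_exact(self, tmp_path):
        g = genome_of_length(250)
        grid = window_genome(g, width=50)
        values = np.array([1.0, 4.0, 0.0, 2.5, 7.0])
        p = tmp_path / "t.bedgraph"
        write_bedgraph(grid, values, p)
        track = read_bedgraph(p, grid)
        assert np.allclose(track.values, values)

    def test_region_spanning_windows_distributes_by_overlap(self, tmp_path):
        g = genome_of_length(150)
        grid = window_genome(g, width=50)
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t25\t125\t10\n")  # 100 bp region, value 10
        track = read_bedgraph(p, grid)
        assert np.allclose(track.values, [2.5, 5.0, 2.5])

    def test_fixed_step_wiggle(self, tmp_path):
        g = genome_of_length(100)
        grid = window_genome(g, width=50)
        p = tmp_path / "t.wig"
        p.write_text("fixedStep chrom=chr1 start=1 step=50 span=50\n3\n9\n")
        track = read_bedgraph(p, grid)
        assert np.allclose(track.values, [3.0, 9.0])

    def test_malformed_line_reports_number(self, tmp_path):
        g = genome_of_length(100)
        grid = window_genome(g, width=50)
        p = tmp_path / "bad.bedgraph"
        p.write_text("chr1\t0\t50\t1\nchr1\t50\n")
        with pytest.raises(ValueError, match="line 2"):
            read_bedgraph(p, grid)
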