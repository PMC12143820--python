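"""Super-enhancer calling: TSS filter, stitching, ranking, tangent cutoff."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sepipe.core_model import GenomeAnnotation, gap
from sepipe.se_caller import (
    SECallParams,
    call_superenhancers,
    filter_tss_proximal,
    rank_and_scale,
    stitch_peaks,
    tangent_cutoff,
)

from .conftest import peak


class TestFilterTssProximal:
    def test_fully_contained_peak_removed(self, toy_annotation):
        # gA TSS at 10000; window [8000, 12001)
        kept = filter_tss_proximal([peak("chr1", 9500, 10500)], toy_annotation, 2000)
        assert kept == []

    def test_partially_outside_peak_retained(self, toy_annotation):
        peaks = [peak("chr1", 7000, 9000)]  # left edge 7000 < 8000
        assert filter_tss_proximal(peaks, toy_annotation, 2000) == peaks

    def test_peak_exactly_filling_window_is_filtered(self, toy_annotation):
        # [tss - 2000, tss + 2001) around gA's TSS at 10000
        kept = filter_tss_proximal([peak("chr1", 8000, 12001)], toy_annotation, 2000)
        assert kept == []
        # one base wider on either side and it survives
        assert filter_tss_proximal([peak("chr1", 7999, 12001)], toy_annotation, 2000)
        assert filter_tss_proximal([peak("chr1", 8000, 12002)], toy_annotation, 2000)

    def test_chromosome_without_genes_retained(self, toy_annotation):
        peaks = [peak("chrX", 0, 100)]
        assert filter_tss_proximal(peaks, toy_annotation, 2000) == peaks

    def test_empty_annotation_warns_and_keeps_all(self):
        peaks = [peak("chr1", 0, 100)]
        with pytest.warns(UserWarning):
            assert filter_tss_proximal(peaks, GenomeAnnotation([]), 2000) == peaks

    def test_order_preserved(self, toy_annotation):
        peaks = [peak("chr1", 100_000 + 10_000 * i, 100_500 + 10_000 * i, name=f"p{i}")
                 for i in range(5)]
        assert filter_tss_proximal(peaks, toy_annotation, 2000) == peaks


class TestStitchPeaks:
    def test_gap_within_threshold_merges(self):
        peaks = [
            peak("chr1", 0, 1000, "p1", 1.0),
            peak("chr1", 5000, 6000, "p2", 2.0),
            peak("chr1", 30000, 31000, "p3", 4.0),
        ]
        result = stitch_peaks(peaks, 12500)
        members = [{m.name for m in e.members} for e in result]
        assert members == [{"p1", "p2"}, {"p3"}]
        assert result[0].total_signal == pytest.approx(3.0)
        assert result[0].span.start == 0 and result[0].span.end == 6000

    def test_gap_exactly_at_threshold_is_inclusive(self):
        peaks = [peak("chr1", 0, 1000, "p1"), peak("chr1", 13500, 14000, "p2")]
        assert len(stitch_peaks(peaks, 12500)) == 1
        # one base farther and they separate
        peaks = [peak("chr1", 0, 1000, "p1"), peak("chr1", 13501, 14000, "p2")]
        assert len(stitch_peaks(peaks, 12500)) == 2

    def test_single_peak_identity(self):
        (enhancer,) = stitch_peaks([peak("chr1", 10, 20, "only", 3.5)], 12500)
        assert enhancer.span.start == 10 and enhancer.span.end == 20
        assert enhancer.total_signal == 3.5

    def test_chromosomes_never_mix(self):
        peaks = [peak("chr1", 0, 1000), peak("chr2", 500, 1500)]
        assert len(stitch_peaks(peaks, 12500)) == 2

    @given(st.data())
    def test_matches_connected_components(self, data):
        """Sweep output equals components of the gap-threshold graph."""
        import networkx as nx

        n = data.draw(st.integers(1, 25))
        starts = data.draw(
            st.lists(st.integers(0, 200_000), min_size=n, max_size=n)
        )
        peaks = [
            peak("chr1", s, s + data.draw(st.integers(1, 3000)), name=f"p{i}")
            for i, s in enumerate(starts)
        ]
        graph = nx.Graph()
        graph.add_nodes_from(p.name for p in peaks)
        for i, a in enumerate(peaks):
            for b in peaks[i + 1:]:
                if gap(a.interval, b.interval) <= 12_500:
                    graph.add_edge(a.name, b.name)
        expected = {frozenset(c) for c in nx.connected_components(graph)}
        observed = {
            frozenset(m.name for m in e.members)
            for e in stitch_peaks(peaks, 12_500)
        }
        assert observed == expected


class TestRankAndScale:
    def test_minmax_arithmetic(self):
        enhancers = stitch_peaks(
            [
                peak("chr1", 0, 10, "a", 5.0),
                peak("chr1", 100_000, 100_010, "b", 1.0),
                peak("chr1", 200_000, 200_010, "c", 3.0),
            ],
            100,
        )
        ordered, sx, sy, degenerate = rank_and_scale(enhancers)
        assert [e.total_signal for e in ordered] == [1.0, 3.0, 5.0]
        assert sx.tolist() == [0.0, 0.5, 1.0]
        assert sy.tolist() == [0.0, 0.5, 1.0]
        assert not degenerate

    def test_flat_curve_degenerate(self):
        enhancers = stitch_peaks(
            [peak("chr1", i * 100_000, i * 100_000 + 10, f"p{i}", 2.0) for i in range(3)],
            100,
        )
        _, _, sy, degenerate = rank_and_scale(enhancers)
        assert degenerate and sy.tolist() == [0.0, 0.0, 0.0]

    def test_single_point_degenerate(self):
        enhancers = stitch_peaks([peak("chr1", 0, 10, "a", 5.0)], 100)
        _, sx, _, degenerate = rank_and_scale(enhancers)
        assert degenerate and sx.tolist() == [0.0]

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            rank_and_scale([])


class TestTangentCutoff:
    def test_quadratic_closed_form(self):
        """y = x^2 grid: the slope-1 tangency of x^2 is at x = 1/2."""
        x = np.linspace(0, 1, 101)
        signals = x**2  # already min-max scaled
        cutoff, rank = tangent_cutoff(x, signals, signals)
        assert x[rank - 1] == pytest.approx(0.5)
        assert cutoff == pytest.approx(0.25)
        assert int((signals > cutoff).sum()) == 50

    def test_diagonal_ties_resolve_to_top(self):
        x = np.linspace(0, 1, 11)
        cutoff, rank = tangent_cutoff(x, x, x)
        assert rank == 11  # greatest scaled_y among the all-way tie
        assert cutoff == pytest.approx(1.0)
        assert int((x > cutoff).sum()) == 0  # zero super-enhancers


class TestCallSuperenhancers:
    def _toy_peaks(self):
        rng = np.random.default_rng(0)
        peaks = [
            peak("chr1", 1_000_000 + 50_000 * i, 1_000_000 + 50_000 * i + 500,
                 f"bg{i}", float(s))
            for i, s in enumerate(rng.lognormal(3.0, 0.1, size=60))
        ]
        # one strong three-peak cluster
        for j in range(3):
            peaks.append(
                peak("chr1", 8_000_000 + j * 5_000, 8_000_000 + j * 5_000 + 800,
                     f"se{j}", 120.0)
            )
        return peaks

    def test_scale_invariance(self, toy_annotation):
        peaks = self._toy_peaks()
        base = call_superenhancers(peaks, toy_annotation)
        scaled = call_superenhancers(
            [peak(p.chrom, p.interval.start, p.interval.end, p.name, p.signal * 10)
             for p in peaks],
            toy_annotation,
        )
        assert {e.id for e in base.super_enhancers} == {
            e.id for e in scaled.super_enhancers
        }

    def test_permutation_invariance(self, toy_annotation):
        peaks = self._toy_peaks()
        base = call_superenhancers(peaks, toy_annotation)
        shuffled = call_superenhancers(peaks[::-1], toy_annotation)
        assert [e.id for e in base.enhancers] == [e.id for e in shuffled.enhancers]
        assert base.is_super.tolist() == shuffled.is_super.tolist()

    def test_partition_is_exhaustive(self, toy_annotation):
        peaks = self._toy_peaks()
        result = call_superenhancers(peaks, toy_annotation)
        assert len(result.super_enhancers) + len(result.typical_enhancers) == len(
            result.enhancers
        )
        member_names = sorted(
            m.name for e in result.enhancers for m in e.members
        )
        kept = filter_tss_proximal(peaks, toy_annotation, 2000)
        assert member_names == sorted(p.name for p in kept)

    def test_raising_a_signal_never_demotes(self, toy_annotation):
        peaks = self._toy_peaks()
        base = call_superenhancers(peaks, toy_annotation)

        def enhancer_with(result, member_name):
            (enhancer,) = [
                (e, s)
                for e, s in zip(result.enhancers, result.is_super)
                if any(m.name == member_name for m in e.members)
            ]
            return enhancer

        _, was_super = enhancer_with(base, "se1")
        assert was_super
        boosted = [
            peak(p.chrom, p.interval.start, p.interval.end, p.name,
                 p.signal * 4 if p.name == "se1" else p.signal)
            for p in peaks
        ]
        _, still_super = enhancer_with(
            call_superenhancers(boosted, toy_annotation), "se1"
        )
        assert still_super

    def test_all_peaks_tss_proximal_warns_empty(self, toy_annotation):
        peaks = [peak("chr1", 9500, 10500), peak("chr1", 46500, 48500)]
        with pytest.warns(UserWarning):
            result = call_superenhancers(peaks, toy_annotation)
        assert len(result.enhancers) == 0 and result.degenerate

    def test_too_few_enhancers_calls_nothing(self, toy_annotation):
        peaks = [peak("chr1", 1_000_000, 1_000_500, "a", 5.0),
                 peak("chr1", 2_000_000, 2_000_500, "b", 9.0)]
        with pytest.warns(UserWarning):
            result = call_superenhancers(peaks, toy_annotation)
        assert result.degenerate and result.n_super == 0

    def test_bedgraph_scoring_mode(self, toy_annotation, tmp_path):
        from sepipe.io_formats import read_bedgraph

        peaks = [peak("chr1", 1_000_000 + 100_000 * i, 1_000_000 + 100_000 * i + 100,
                      f"p{i}", 1.0) for i in range(4)]
        track_path = tmp_path / "t.bedgraph"
        lines = [
            f"chr1\t{p.interval.start}\t{p.interval.end}\t{v}\n"
            for p, v in zip(peaks, [1.0, 2.0, 3.0, 50.0])
        ]
        track_path.write_text("".join(lines))
        result = call_superenhancers(
            peaks, toy_annotation, signal_track=read_bedgraph(track_path)
        )
        totals = [e.total_signal for e in result.enhancers]
        assert totals == sorted(totals)
        assert totals[-1] == pytest.approx(50.0 * 100)
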