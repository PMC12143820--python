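"""Generator contracts: determinism, ground-truth consistency, fixtures."""

import numpy as np
import pytest

from sepipe.core_model import gap, overlaps
from sepipe.differential import expression_differential
from sepipe.synthetic_data import (
    SimulationConfig,
    simulate_expression,
    simulate_landscape,
    verify_fixture,
    write_fixture,
)


def small_config(**overrides) -> SimulationConfig:
    defaults = dict(
        seed=42,
        n_chrom=2,
        chrom_length=8_000_000,
        n_genes=400,
        n_background_peaks=200,
        n_typical_enhancers=10,
        n_super_clusters=6,
        n_differential_ses=2,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestSimulateLandscape:
    def test_seeded_determinism(self):
        cfg = small_config()
        first = simulate_landscape(cfg)
        second = simulate_landscape(cfg)
        assert [ (p.interval, p.name, p.signal) for p in first[1] ] == \
               [ (p.interval, p.name, p.signal) for p in second[1] ]
        assert [c.cluster_id for c in first[3].clusters] == \
               [c.cluster_id for c in second[3].clusters]

    def test_cluster_bookkeeping(self):
        cfg = small_config(n_super_clusters=5, n_differential_ses=2)
        _, _, _, truth = simulate_landscape(cfg)
        assert len(truth.super_clusters) == 5
        assert len(truth.differential_clusters) == 2
        directions = [c.direction for c in truth.differential_clusters]
        assert directions.count("up") == 1 and directions.count("down") == 1

    def test_truth_consistent_with_peaks(self):
        cfg = small_config()
        _, peaks_a, _, truth = simulate_landscape(cfg)
        for cluster in truth.clusters:
            members = [
                p for p in peaks_a
                if p.chrom == cluster.span.chrom and overlaps(p.interval, cluster.span)
            ]
            assert members, f"no peaks under planted cluster {cluster.cluster_id}"
            # planted clusters satisfy the stitching precondition
            members.sort(key=lambda p: p.interval.start)
            for left, right in zip(members, members[1:]):
                assert gap(left.interval, right.interval) <= 12_500

    def test_every_differential_cluster_has_a_nearest_gene(self):
        _, _, _, truth = simulate_landscape(small_config())
        for cluster in truth.differential_clusters:
            assert cluster.nearest_gene is not None
            assert cluster.nearest_gene in truth.gene_effects

    def test_condition_b_applies_effect_to_members_only(self):
        cfg = small_config()
        _, peaks_a, peaks_b, truth = simulate_landscape(cfg)
        by_name_a = {p.name: p for p in peaks_a}
        changed = {p.name for p in peaks_b if p.signal != by_name_a[p.name].signal}
        diff_spans = [c.span for c in truth.differential_clusters]
        for name in changed:
            p = by_name_a[name]
            assert any(
                p.chrom == s.chrom and overlaps(p.interval, s) for s in diff_spans
            )
        for cluster in truth.differential_clusters:
            factor = (
                cfg.differential_effect
                if cluster.direction == "up"
                else 1 / cfg.differential_effect
            )
            members = [
                p for p in peaks_a
                if p.chrom == cluster.span.chrom and overlaps(p.interval, cluster.span)
            ]
            for p in members:
                pb = next(q for q in peaks_b if q.name == p.name)
                assert pb.signal == pytest.approx(p.signal * factor)

    def test_tss_proximal_fraction_planted(self):
        cfg = small_config(tss_proximal_fraction=0.2)
        annotation, peaks_a, _, _ = simulate_landscape(cfg)
        proximal = [p for p in peaks_a if p.name.startswith("prox_")]
        assert len(proximal) == round(0.2 * cfg.n_background_peaks)
        for p in proximal:
            contained = any(
                g.tss - 2000 <= p.interval.start and p.interval.end <= g.tss + 2001
                for g in annotation.genes_on(p.chrom)
            )
            assert contained

    def test_infeasible_placement_errors(self):
        with pytest.raises(ValueError, match="infeasible"):
            simulate_landscape(small_config(chrom_length=100_000))


class TestSimulateExpression:
    def test_planted_fold_recovered(self):
        cfg = small_config()
        annotation, _, _, truth = simulate_landscape(cfg)
        counts, fpkm_table = simulate_expression(annotation, truth, cfg)
        assert len(counts) == len(annotation)
        cols_a = ["a_1", "a_2", "a_3"]
        cols_b = ["b_1", "b_2", "b_3"]
        hits = 0
        for gene_id, (direction, fold) in truth.gene_effects.items():
            row = fpkm_table.loc[fpkm_table.gene_id == gene_id].iloc[0]
            _, _, fc, _, _ = expression_differential(
                [row[c] for c in cols_a], [row[c] for c in cols_b]
            )
            if direction == "up" and fc > 2:
                hits += 1
            if direction == "down" and fc < 0.5:
                hits += 1
        assert hits == len(truth.gene_effects)

    def test_unplanted_gene_fold_near_one(self):
        cfg = small_config()
        annotation, _, _, truth = simulate_landscape(cfg)
        _, fpkm_table = simulate_expression(annotation, truth, cfg)
        neutral = fpkm_table[~fpkm_table.gene_id.isin(truth.gene_effects)]
        a = neutral[["a_1", "a_2", "a_3"]].mean(axis=1).to_numpy()
        b = neutral[["b_1", "b_2", "b_3"]].mean(axis=1).to_numpy()
        ratio = (b + 1) / (a + 1)
        assert np.median(ratio) == pytest.approx(1.0, abs=0.15)
        assert ((ratio > 0.5) & (ratio < 2.0)).mean() > 0.9

    def test_zero_replicates_error(self):
        cfg = small_config(n_replicates=0)
        annotation, _, _, truth = simulate_landscape(cfg)
        with pytest.raises(ValueError):
            simulate_expression(annotation, truth, cfg)


class TestWriteFixture:
    def test_manifest_lists_every_file_and_verifies(self, tmp_path):
        manifest = write_fixture(tmp_path, small_config())
        for name in manifest["files"]:
            assert (tmp_path / name).exists()
        assert len(manifest["files"]) == 9
        assert verify_fixture(tmp_path)

    def test_rerun_same_seed_identical_checksums(self, tmp_path):
        cfg = small_config()
        first = write_fixture(tmp_path / "x", cfg)
        second = write_fixture(tmp_path / "y", cfg)
        assert first["files"] == second["files"]

    def test_overwrite_protection(self, tmp_path):
        cfg = small_config()
        write_fixture(tmp_path, cfg)
        with pytest.raises(FileExistsError):
            write_fixture(tmp_path, cfg)
        write_fixture(tmp_path, cfg, overwrite=True)  # explicit overwrite ok

    def test_tampering_detected(self, tmp_path):
        write_fixture(tmp_path, small_config())
        target = tmp_path / "counts.tsv"
        target.write_text(target.read_text() + "tampered\t0\t0\t0\t0\t0\t0\n")
        assert not verify_fixture(tmp_path)

    def test_fixture_files_parse_back(self, tmp_path):
        from sepipe.io_formats import read_bedgraph, read_gtf_genes, read_narrowpeak

        cfg = small_config()
        write_fixture(tmp_path, cfg)
        peaks = read_narrowpeak(tmp_path / "peaks_a.narrowPeak")
        annotation = read_gtf_genes(tmp_path / "genes.gtf")
        track = read_bedgraph(tmp_path / "signal_a.bedgraph")
        assert len(peaks) == len(
            read_narrowpeak(tmp_path / "peaks_b.narrowPeak")
        )
        assert len(annotation) == cfg.n_genes
        assert track.chroms() == ("chr1", "chr2")
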