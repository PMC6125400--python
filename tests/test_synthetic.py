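"""Generator guarantees: planted truth exactness, noise calibration, determinism."""

import math

import pytest
from scipy import stats

from markconcord.synthetic import (
    SimConfig,
    SizingError,
    simulate_annotation,
    simulate_count_matrix,
    simulate_expression,
    simulate_peak_experiment,
)

from .oracles import bitmap_overlaps

SMALL = SimConfig(
    n_chroms=2, chrom_length=2_000_000, n_genes=40, n_shared_peaks=150,
    n_exclusive_a=12, n_exclusive_b=6, partial_support_spec=((10, 3), (8, 1)),
    seed=7,
)


class TestAnnotationSim:
    def test_seeded_determinism(self):
        assert simulate_annotation(SMALL) == simulate_annotation(SMALL)

    def test_zero_genes_is_fine(self):
        assert simulate_annotation(SimConfig(n_genes=0)) == []

    def test_genes_never_overlap_by_all_pairs_scan(self):
        genes = simulate_annotation(SMALL)
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for gs in by_chrom.values():
            for i, a in enumerate(gs):
                for b in gs[i + 1:]:
                    assert min(a.end, b.end) <= max(a.start, b.start)

    def test_too_small_genome_reports_required_size(self):
        with pytest.raises(SizingError, match="chrom_length"):
            simulate_annotation(SimConfig(n_chroms=1, chrom_length=100_000, n_genes=50))


class TestPeakExperiment:
    def test_noise_free_replicates_are_byte_identical(self):
        cfg = SimConfig(
            n_shared_peaks=100, n_exclusive_a=5, n_exclusive_b=5,
            partial_support_spec=(), jitter_sd=0.0, drop_prob=0.0, seed=3,
        )
        genes = simulate_annotation(cfg)
        land, _ = simulate_peak_experiment(cfg, genes)
        for reps in land.values():
            intervals = [[p.interval for p in peaks] for peaks in reps.values()]
            assert all(iv == intervals[0] for iv in intervals)

    def test_exclusive_truth_has_zero_other_support_by_all_pairs_scan(self):
        genes = simulate_annotation(SMALL)
        land, truth = simulate_peak_experiment(SMALL, genes)
        assert len(truth.exclusive_a) == 12 and len(truth.exclusive_b) == 6
        b_peaks = [p for peaks in land["ethanol"].values() for p in peaks]
        for row in truth.exclusive_a.itertuples(index=False):
            region = (row.chrom, row.start, row.end)
            assert not any(bitmap_overlaps(region, p.interval) for p in b_peaks)

    def test_exclusive_regions_in_every_own_replicate(self):
        genes = simulate_annotation(SMALL)
        land, truth = simulate_peak_experiment(SMALL, genes)
        for cond, frame in (("control", truth.exclusive_a), ("ethanol", truth.exclusive_b)):
            for row in frame.itertuples(index=False):
                region = (row.chrom, row.start, row.end)
                for peaks in land[cond].values():
                    assert any(bitmap_overlaps(region, p.interval) for p in peaks)

    def test_partial_regions_hit_exactly_k_other_replicates(self):
        genes = simulate_annotation(SMALL)
        land, truth = simulate_peak_experiment(SMALL, genes)
        partial = truth.regions[truth.regions["klass"].str.startswith("partial")]
        assert len(partial) == 18
        for row in partial.itertuples(index=False):
            region = (row.chrom, row.start, row.end)
            other = "ethanol" if row.owner == "control" else "control"
            hit = sum(
                1
                for peaks in land[other].values()
                if any(bitmap_overlaps(region, p.interval) for p in peaks)
            )
            assert hit == row.k_other

    def test_shared_peak_full_presence_rate_matches_binomial(self):
        cfg = SimConfig(
            n_chroms=8, chrom_length=5_000_000, n_genes=0, n_shared_peaks=1000,
            n_exclusive_a=0, n_exclusive_b=0, partial_support_spec=(),
            drop_prob=0.1, jitter_sd=0.0, seed=11,
        )
        land, truth = simulate_peak_experiment(cfg, [])
        # presence per region in all 4 control replicates
        present = {}
        for peaks in land["control"].values():
            for p in peaks:
                present[p.name] = present.get(p.name, 0) + 1
        frac = sum(1 for v in present.values() if v == 4) / 1000
        expected = 0.9**4
        se = math.sqrt(expected * (1 - expected) / 1000)
        assert abs(frac - expected) <= 3 * se

    def test_seeded_determinism_of_landscape(self):
        genes = simulate_annotation(SMALL)
        l1, t1 = simulate_peak_experiment(SMALL, genes)
        l2, t2 = simulate_peak_experiment(SMALL, genes)
        assert l1 == l2
        assert t1.regions.equals(t2.regions)

    def test_impossible_density_raises_sizing_error(self):
        cfg = SimConfig(n_chroms=1, chrom_length=200_000, n_genes=0,
                        n_shared_peaks=5000, partial_support_spec=())
        with pytest.raises(SizingError):
            simulate_peak_experiment(cfg, [])


class TestExpressionSim:
    def _sim(self, cfg, effect, null_sd=0.2):
        genes = simulate_annotation(cfg)
        _, truth = simulate_peak_experiment(cfg, genes)
        return genes, truth, simulate_expression(cfg, truth, genes, effect, null_sd)

    def test_seeded_determinism(self):
        _, _, a = self._sim(SMALL, 1.0)
        _, _, b = self._sim(SMALL, 1.0)
        assert a == b

    def test_null_p_values_are_uniform(self):
        cfg = SimConfig(n_chroms=8, chrom_length=40_000_000, n_genes=10_000,
                        n_exclusive_a=0, n_exclusive_b=0, n_shared_peaks=0,
                        partial_support_spec=(), seed=5)
        genes = simulate_annotation(cfg)
        _, truth = simulate_peak_experiment(cfg, genes)
        records = simulate_expression(cfg, truth, genes, effect_size=1.0)
        frac = sum(1 for r in records if r.p_value < 0.01) / len(records)
        assert abs(frac - 0.01) <= 3 * math.sqrt(0.01 * 0.99 / len(records))
        # and across the whole unit interval
        ks = stats.kstest([r.p_value for r in records], "uniform")
        assert ks.pvalue > 0.001

    def test_zero_effect_makes_planted_and_null_indistinguishable(self):
        cfg = SimConfig(n_chroms=4, chrom_length=10_000_000, n_genes=600,
                        n_exclusive_a=150, n_exclusive_b=150, n_shared_peaks=0,
                        partial_support_spec=(), seed=13)
        genes, truth, records = self._sim(cfg, effect=0.0)
        linked = set(truth.linked["gene_id"])
        fc_linked = [r.log_fc for r in records if r.gene_id in linked]
        fc_null = [r.log_fc for r in records if r.gene_id not in linked]
        assert stats.ks_2samp(fc_linked, fc_null).pvalue > 0.01

    def test_planted_directions_follow_the_mark_semantics(self):
        # repressive mark: treatment-only domain pushes expression down
        genes, truth, records = self._sim(SMALL, effect=2.0, null_sd=0.1)
        by_gene = {r.gene_id: r for r in records}
        for row in truth.linked.itertuples(index=False):
            fc = by_gene[row.gene_id].log_fc
            assert (fc > 0) == (row.expr_direction == "up")

    def test_unknown_linked_gene_rejected(self):
        genes = simulate_annotation(SMALL)
        _, truth = simulate_peak_experiment(SMALL, genes)
        with pytest.raises(ValueError, match="unknown gene_id"):
            simulate_expression(SMALL, truth, genes[:5])


class TestCountMatrix:
    def test_planted_and_design_shapes(self):
        counts, design, planted = simulate_count_matrix(50, 5, 4.0, seed=2)
        assert counts.shape == (50, 8) and len(planted) == 5
        assert sorted(set(design.values())) == ["control", "ethanol"]

    def test_determinism(self):
        a, _, _ = simulate_count_matrix(30, 3, 2.0, seed=9)
        b, _, _ = simulate_count_matrix(30, 3, 2.0, seed=9)
        assert a.equals(b)
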