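import numpy as np
import pandas as pd
import pytest

from tssmeth.profiles import (
    CoverageTrack,
    assign_quartiles,
    chip_meta_profile,
    gene_binned_coverage,
    methylation_meta_profile,
    randomized_background,
)
from tssmeth.scoring import window_scores
from tssmeth.simulate import CohortConfig, generate_chip_coverage, generate_cohort

from conftest import make_annotation, make_gene


def constant_track(chrom="chr1", value=3.0, end=10**6):
    return CoverageTrack(
        pd.DataFrame({"chrom": [chrom], "start": [0], "end": [end], "value": [value]})
    )


class TestAssignQuartiles:
    def make_expr(self, means, samples=("s1", "s2")):
        return pd.DataFrame(
            {s: means for s in samples}, index=[f"g{i}" for i in range(len(means))]
        )

    def test_even_split(self):
        qa = assign_quartiles(self.make_expr(range(8)), ["s1", "s2"])
        assert qa.sizes() == {"Q1": 2, "Q2": 2, "Q3": 2, "Q4": 2}
        assert qa.assignment["g0"] == "Q1" and qa.assignment["g7"] == "Q4"

    def test_remainders_go_to_low_quartiles_first(self):
        qa = assign_quartiles(self.make_expr(range(10)), ["s1", "s2"])
        assert [qa.sizes()[q] for q in ("Q1", "Q2", "Q3", "Q4")] == [3, 3, 2, 2]

    def test_all_ties_still_deterministic(self):
        qa1 = assign_quartiles(self.make_expr([1.0] * 8), ["s1", "s2"])
        qa2 = assign_quartiles(self.make_expr([1.0] * 8), ["s1", "s2"])
        assert qa1.assignment == qa2.assignment  # lexicographic tie rule

    def test_quartiles_partition_universe(self):
        rng = np.random.default_rng(0)
        qa = assign_quartiles(self.make_expr(rng.normal(size=101)), ["s1", "s2"])
        assert sum(qa.sizes().values()) == 101
        assert max(qa.sizes().values()) - min(qa.sizes().values()) <= 1


@pytest.fixture(scope="module")
def quartile_setup(planted_cohort):
    samples = planted_cohort.segments.samples_in_group("tumor")
    qa = assign_quartiles(planted_cohort.expression, samples, arm="tumor")
    return planted_cohort, qa


class TestMethylationMetaProfile:
    def test_planted_tss_anticorrelation_q1_above_q4(self, quartile_setup):
        """Low-expression genes carry more TSS methylation than high-expression genes."""
        cohort, qa = quartile_setup
        for partition in ("within_cgi", "outside_cgi"):
            prof = methylation_meta_profile(
                cohort.segments, cohort.annotation, qa,
                partition=partition, group="tumor",
            )
            bin0 = np.where(prof["Q1"].positions == 0)[0][0]
            assert prof["Q1"].mean_signal[bin0] > prof["Q4"].mean_signal[bin0]

    def test_all_zero_methylation_gives_zero_profile(self):
        from tssmeth.scoring import SegmentMethylationMatrix, segment_grid_for_annotation

        ann = make_annotation(
            [make_gene(f"g{i}", tss=100_000 + 20_000 * i) for i in range(4)],
            sizes={"chr1": 10**6},
        )
        chroms, starts = segment_grid_for_annotation(ann)
        segs = SegmentMethylationMatrix(
            chroms, starts, ["s1"], {"s1": "tumor"},
            np.zeros((len(starts), 1), dtype=np.uint8),
        )
        expr = pd.DataFrame({"s1": [1.0, 2.0, 3.0, 4.0]}, index=[f"g{i}" for i in range(4)])
        qa = assign_quartiles(expr, ["s1"])
        prof = methylation_meta_profile(segs, ann, qa, partition="all", group="tumor")
        for q in prof.values():
            assert np.nansum(q.mean_signal) == 0

    def test_union_is_gene_weighted_mean_of_quartiles(self, quartile_setup):
        """Conservation: pooling the quartiles equals their gene-count-weighted mean."""
        cohort, qa = quartile_setup
        prof = methylation_meta_profile(
            cohort.segments, cohort.annotation, qa, partition="all", group="tumor"
        )
        from tssmeth.profiles import QuartileAssignment

        pooled = methylation_meta_profile(
            cohort.segments, cohort.annotation,
            QuartileAssignment({g: "Q1" for g in qa.assignment}, arm="tumor"),
            partition="all", group="tumor",
        )["Q1"]
        weights = np.array([prof[q].n_genes for q in ("Q1", "Q2", "Q3", "Q4")])
        stacked = np.vstack([prof[q].mean_signal for q in ("Q1", "Q2", "Q3", "Q4")])
        weighted = (weights[:, None] * stacked).sum(0) / weights.sum()
        assert np.allclose(weighted, pooled.mean_signal, equal_nan=True)


class TestChipMetaProfile:
    def test_constant_coverage_gives_flat_profile(self, small_cohort):
        track = CoverageTrack(
            pd.DataFrame({"chrom": ["chrS"], "start": [0], "end": [10**7], "value": [3.0]})
        )
        samples = small_cohort.segments.samples_in_group("tumor")
        qa = assign_quartiles(small_cohort.expression, samples)
        prof = chip_meta_profile(track, small_cohort.annotation, qa)
        for q in prof.values():
            assert np.allclose(q.mean_signal, 3.0)

    def test_triangular_peak_at_tss_recovered(self):
        genes = [make_gene(f"g{i}", tss=100_000 + 50_000 * i) for i in range(4)]
        ann = make_annotation(genes, sizes={"chr1": 10**6})
        rows = []
        for g in genes:  # 500-bp triangular peak centred on each TSS
            for off in range(-500, 500, 10):
                rows.append(("chr1", g.tss + off, g.tss + off + 10, 500 - abs(off)))
        track = CoverageTrack(pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]))
        expr = pd.DataFrame({"s": [1, 2, 3, 4.0]}, index=[g.gene_id for g in genes])
        qa = assign_quartiles(expr, ["s"])
        prof = chip_meta_profile(track, ann, qa)
        for q in prof.values():
            if q.n_genes:
                assert abs(q.positions[np.argmax(q.mean_signal)]) <= 10

    def test_minus_strand_mirrored_fixture_identical(self):
        fwd = make_gene("f", tss=100_000, strand="+")
        rev = make_gene("r", chrom="chr2", tss=100_000, strand="-")
        ann = make_annotation([fwd, rev], sizes={"chr1": 10**6, "chr2": 10**6})
        rows = []
        rng = np.random.default_rng(8)
        vals = rng.poisson(5, size=1000).astype(float)
        for k, v in enumerate(vals):  # fwd bin k covers rel [-5000+10k, ...)
            rel = -5000 + 10 * k
            rows.append(("chr1", 100_000 + rel, 100_000 + rel + 10, v))
            # base-level reflection about the TSS: [a, b) -> [2t-b+1, 2t-a+1)
            rows.append(("chr2", 100_000 - rel - 9, 100_000 - rel + 1, v))
        track = CoverageTrack(pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]))
        a = gene_binned_coverage(track, fwd)
        b = gene_binned_coverage(track, rev)
        assert np.array_equal(a, b)

    def test_linearity_under_global_rescaling(self, small_cohort):
        expr = small_cohort.expression
        cov = generate_chip_coverage(
            small_cohort.annotation, expr.mean(axis=1), mark="active", seed=1, noise=False
        )
        samples = small_cohort.segments.samples_in_group("tumor")
        qa = assign_quartiles(expr, samples)
        p1 = chip_meta_profile(CoverageTrack(cov), small_cohort.annotation, qa)
        cov2 = cov.assign(value=cov["value"] * 3.5)
        p2 = chip_meta_profile(CoverageTrack(cov2), small_cohort.annotation, qa)
        for q in p1:
            assert np.allclose(3.5 * p1[q].mean_signal, p2[q].mean_signal)

    def test_negative_coverage_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            CoverageTrack(
                pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10], "value": [-1.0]})
            )


class TestGeneratedChipGeometry:
    def test_active_mark_peaks_downstream_for_high_expression(self, small_cohort):
        expr = small_cohort.expression.mean(axis=1)
        cov = generate_chip_coverage(
            small_cohort.annotation, expr, mark="active", seed=4, noise=False
        )
        track = CoverageTrack(cov)
        samples = small_cohort.segments.samples_in_group("tumor")
        qa = assign_quartiles(small_cohort.expression, samples)
        prof = chip_meta_profile(track, small_cohort.annotation, qa)
        peak_pos = prof["Q4"].positions[np.argmax(prof["Q4"].mean_signal)]
        assert 500 <= peak_pos <= 1500

    def test_repressive_mark_higher_for_low_expression(self, small_cohort):
        expr = small_cohort.expression.mean(axis=1)
        cov = generate_chip_coverage(
            small_cohort.annotation, expr, mark="repressive", seed=4, noise=False
        )
        track = CoverageTrack(cov)
        samples = small_cohort.segments.samples_in_group("tumor")
        qa = assign_quartiles(small_cohort.expression, samples)
        prof = chip_meta_profile(track, small_cohort.annotation, qa)
        flank = np.abs(prof["Q1"].positions) > 2000
        assert prof["Q1"].mean_signal[flank].mean() > prof["Q4"].mean_signal[flank].mean()

    def test_tumor_mode_removes_tss_dip(self, small_cohort):
        expr = small_cohort.expression.mean(axis=1)
        kw = dict(mark="repressive", seed=4, noise=False)
        normal = generate_chip_coverage(small_cohort.annotation, expr, **kw)
        tumor = generate_chip_coverage(small_cohort.annotation, expr, tumor_mode=True, **kw)
        gene = small_cohort.annotation.genes[0]
        n = gene_binned_coverage(CoverageTrack(normal), gene)
        t = gene_binned_coverage(CoverageTrack(tumor), gene)
        mid = len(n) // 2
        assert t[mid] >= n[mid]  # dip removed in tumor mode


class TestRandomizedBackground:
    def test_single_list_band_collapses(self, small_cohort):
        expr = small_cohort.expression.mean(axis=1)
        cov = generate_chip_coverage(small_cohort.annotation, expr, seed=2, noise=False)
        track = CoverageTrack(cov)
        universe = [g.gene_id for g in small_cohort.annotation.genes]
        band = randomized_background(
            track, small_cohort.annotation, universe, list_size=10, n_lists=1, seed=0
        )
        assert np.array_equal(band.lower, band.upper)

    def test_same_seed_identical_band(self, small_cohort):
        expr = small_cohort.expression.mean(axis=1)
        cov = generate_chip_coverage(small_cohort.annotation, expr, seed=2)
        track = CoverageTrack(cov)
        universe = [g.gene_id for g in small_cohort.annotation.genes]
        kw = dict(list_size=10, n_lists=20, seed=42)
        b1 = randomized_background(track, small_cohort.annotation, universe, **kw)
        b2 = randomized_background(track, small_cohort.annotation, universe, **kw)
        assert np.array_equal(b1.lower, b2.lower) and np.array_equal(b1.upper, b2.upper)

    def test_fresh_list_falls_inside_central95_band(self, small_cohort):
        """Coverage: a random same-size list lies in the central-95% band at >= 90% of bins."""
        expr = small_cohort.expression.mean(axis=1)
        cov = generate_chip_coverage(small_cohort.annotation, expr, seed=2)
        track = CoverageTrack(cov)
        universe = [g.gene_id for g in small_cohort.annotation.genes]
        band = randomized_background(
            track, small_cohort.annotation, universe,
            list_size=15, n_lists=200, seed=1, band="central95",
        )
        from tssmeth.profiles import _coverage_matrix

        mat, kept = _coverage_matrix(track, small_cohort.annotation, universe, 10, 5000)
        rng = np.random.default_rng(77)
        fracs = []
        for _ in range(50):
            idx = rng.choice(len(kept), size=15, replace=False)
            prof = mat[idx].mean(axis=0)
            fracs.append(band.contains(prof).mean())
        assert np.mean(fracs) >= 0.90

    def test_universe_smaller_than_list_errors(self, small_cohort):
        track = constant_track("chrS", end=10**7)
        with pytest.raises(ValueError, match="smaller"):
            randomized_background(
                track, small_cohort.annotation, ["g0000"], list_size=5, n_lists=2
            )
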