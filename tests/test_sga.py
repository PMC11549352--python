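import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agequant import sga, synth
from agequant.errors import (
    EmptyScreenError,
    InvalidInputError,
    InvalidParameterError,
)


def plate(grid, repeat="r1", role="control", gene_map=None):
    grid = np.asarray(grid, dtype=float)
    if gene_map is None:
        gene_map = np.array(
            [[f"g{i}_{j}" for j in range(grid.shape[1])] for i in range(grid.shape[0])],
            dtype=object,
        )
    return sga.ColonyPlate(
        plate_id=f"{role}_{repeat}", repeat_id=repeat, query_id=role,
        grid=grid, gene_map=gene_map,
    )


class TestFilterColonies:
    def test_boundary_at_100px(self):
        p = plate(np.full((8, 8), 500.0))
        p.grid[0, 0] = 99.0
        p.grid[0, 1] = 100.0
        mask, _ = sga.filter_colonies([p])
        assert mask[0, 0]
        assert not mask[0, 1]

    def test_absent_colony_excluded(self):
        p = plate(np.full((8, 8), 500.0))
        p.grid[3, 3] = np.nan
        mask, filtered = sga.filter_colonies([p])
        assert mask[3, 3]
        assert np.isnan(filtered[0].grid[3, 3])

    def test_clean_plate_identity(self):
        p = plate(np.full((8, 8), 500.0))
        mask, filtered = sga.filter_colonies([p])
        assert not mask.any()
        np.testing.assert_array_equal(filtered[0].grid, p.grid)

    def test_all_excluded_raises(self):
        p = plate(np.full((4, 4), 50.0))
        with pytest.raises(EmptyScreenError):
            sga.filter_colonies([p])

    def test_simulated_artifact_rate(self):
        rate = 0.05
        total_flagged, total_positions = 0, 0
        for seed in range(20):
            sim = synth.simulate_colony_screen(
                small_colony_rate=rate, seed=seed
            )
            mask, _ = sga.filter_colonies(sim.control_plates)
            total_flagged += mask.sum()
            total_positions += mask.size
        # binomial 99% bounds on the pooled exclusion fraction
        n = total_positions
        se = np.sqrt(rate * (1 - rate) / n)
        assert abs(total_flagged / n - rate) < 2.58 * se + 1e-9


class TestSpatialNormalize:
    def test_flat_plate_identity(self):
        p = plate(np.full((16, 24), 777.0))
        out = sga.spatial_normalize(p)
        np.testing.assert_allclose(out.grid, 777.0)

    def test_window_too_large_raises(self):
        p = plate(np.full((8, 8), 500.0))
        with pytest.raises(InvalidParameterError):
            sga.spatial_normalize(p, window=9)

    def test_even_window_raises(self):
        p = plate(np.full((8, 8), 500.0))
        with pytest.raises(InvalidParameterError):
            sga.spatial_normalize(p, window=4)

    def test_gradient_removed(self):
        rng = np.random.default_rng(0)
        rows, cols = 16, 24
        jj, ii = np.meshgrid(np.arange(cols), np.arange(rows))
        ci, cj = (rows - 1) / 2, (cols - 1) / 2
        dist = np.sqrt((ii - ci) ** 2 + (jj - cj) ** 2)
        surface = 1.0 + 0.3 * (1 - dist / dist.max() - 0.5)
        grid = 500.0 * surface
        p = plate(grid)
        out = sga.spatial_normalize(p)
        cv_in = np.nanstd(grid) / np.nanmean(grid)
        cv_out = np.nanstd(out.grid) / np.nanmean(out.grid)
        assert cv_out < cv_in / 5

    def test_isolated_outlier_preserved(self):
        grid = np.full((16, 24), 500.0)
        grid[8, 12] = 5000.0
        out = sga.spatial_normalize(plate(grid))
        # median smoothing must not absorb an isolated strong colony
        assert out.grid[8, 12] == pytest.approx(10 * out.grid[8, 11], rel=0.05)

    def test_plate_median_invariant(self):
        rng = np.random.default_rng(2)
        grid = 500.0 * np.exp(rng.normal(0, 0.2, (16, 24)))
        out = sga.spatial_normalize(plate(grid))
        assert np.nanmedian(out.grid) == pytest.approx(np.nanmedian(grid), rel=0.01)

    def test_excluded_positions_stay_excluded(self):
        grid = np.full((16, 24), 500.0)
        grid[2, 2] = np.nan
        out = sga.spatial_normalize(plate(grid))
        assert np.isnan(out.grid[2, 2])
        assert np.isfinite(out.grid[2, 3])


class TestExcludeLinked:
    def ann(self, gene, chrom, pos):
        return sga.GeneAnnotation(gene_id=gene, chromosome=chrom, position_bp=pos)

    def test_inclusive_boundary(self):
        anns = {
            "query": self.ann("query", "II", 1_000_000),
            "at_edge": self.ann("at_edge", "II", 1_250_000),
            "beyond": self.ann("beyond", "II", 1_250_001),
        }
        excluded = sga.exclude_linked(anns, ["query"])
        assert "at_edge" in excluded
        assert "beyond" not in excluded

    def test_other_chromosome_retained(self):
        anns = {
            "query": self.ann("query", "II", 1_000_000),
            "near_other": self.ann("near_other", "I", 1_000_000),
        }
        assert "near_other" not in sga.exclude_linked(anns, ["query"])

    def test_missing_annotation_warns_and_retains(self):
        anns = {"query": self.ann("query", "II", 1_000_000)}
        with pytest.warns(UserWarning):
            excluded = sga.exclude_linked(
                anns, ["query"], scored_genes=["query", "mystery"]
            )
        assert "mystery" not in excluded

    def test_random_against_brute_force(self):
        rng = np.random.default_rng(4)
        chroms = ["I", "II", "III"]
        anns = {
            f"g{k}": self.ann(f"g{k}", rng.choice(chroms), int(rng.integers(0, 5_000_000)))
            for k in range(300)
        }
        anns["locusA"] = self.ann("locusA", "II", 2_000_000)
        anns["locusB"] = self.ann("locusB", "I", 500_000)
        excluded = sga.exclude_linked(anns, ["locusA", "locusB"])
        brute = set()
        for g, a in anns.items():
            for la in (anns["locusA"], anns["locusB"]):
                if a.chromosome == la.chromosome and abs(a.position_bp - la.position_bp) <= 250_000:
                    brute.add(g)
        assert excluded == brute


class TestComputeGis:
    def run(self, q, c):
        return sga.compute_gis({"r1": {"g": q}}, {"r1": {"g": c}})["g"].gis_per_repeat["r1"]

    def test_equal_medians_zero(self):
        assert self.run([100, 110, 90], [100, 95, 115]) == 0.0

    def test_ratio_ten(self):
        assert self.run([1000], [100]) == pytest.approx(1.0)

    def test_clipping(self):
        assert self.run([1_000_000], [100]) == 2.0
        assert self.run([100], [1_000_000]) == -2.0

    def test_ratio_half(self):
        assert self.run([50], [100]) == pytest.approx(np.log10(0.5))
        assert self.run([50], [100]) == pytest.approx(-0.30103, abs=1e-5)

    def test_zero_control_positive_query(self):
        assert self.run([100], [0]) == 2.0

    def test_zero_control_zero_query_absent(self):
        assert self.run([0], [0]) is None

    def test_gene_absent_in_one_arm(self):
        res = sga.compute_gis({"r1": {"g1": [100]}}, {"r1": {"g2": [100]}})
        assert res == {}

    def test_no_shared_repeat_raises(self):
        with pytest.raises(InvalidInputError):
            sga.compute_gis({"r1": {"g": [1]}}, {"r2": {"g": [1]}})

    @given(
        st.lists(st.floats(1.0, 1e6), min_size=1, max_size=5),
        st.lists(st.floats(1.0, 1e6), min_size=1, max_size=5),
    )
    @settings(max_examples=200, deadline=None)
    def test_fuzzed_scores_within_clip_range(self, q, c):
        gis = self.run(q, c)
        assert -2.0 <= gis <= 2.0

    def test_swap_negates_unclipped(self):
        rng = np.random.default_rng(6)
        q = {"r1": {f"g{k}": rng.uniform(100, 1000, 3).tolist() for k in range(30)}}
        c = {"r1": {f"g{k}": rng.uniform(100, 1000, 3).tolist() for k in range(30)}}
        fwd = sga.compute_gis(q, c)
        rev = sga.compute_gis(c, q)
        for g in fwd:
            assert fwd[g].gis_per_repeat["r1"] == pytest.approx(
                -rev[g].gis_per_repeat["r1"]
            )


class TestCallHits:
    def make(self, scores):
        res = sga.GISResult(gene_id="g")
        res.gis_per_repeat = {f"r{i}": s for i, s in enumerate(scores)}
        return {"g": res}

    def test_two_of_three_negative(self):
        out = sga.call_hits(self.make([-0.3, -0.2, 0.05]))["g"]
        assert out.consensus_call == "negative"
        assert out.n_supporting_repeats == 2

    def test_below_cutoff_none(self):
        out = sga.call_hits(self.make([0.09, 0.09, 0.09]))["g"]
        assert out.consensus_call == "none"

    def test_boundary_inclusive(self):
        out = sga.call_hits(self.make([0.1, 0.1, 0.0]))["g"]
        assert out.consensus_call == "positive"

    def test_conflicting_signs_ambiguous(self):
        out = sga.call_hits(self.make([0.3, 0.3, -0.3, -0.4]))["g"]
        assert out.consensus_call == "none"
        assert out.ambiguous

    def test_random_against_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            scores = rng.uniform(-0.4, 0.4, size=3).tolist()
            out = sga.call_hits(self.make(scores))["g"]
            n_neg = sum(s <= -0.1 for s in scores)
            n_pos = sum(s >= 0.1 for s in scores)
            if n_neg >= 2 and n_pos >= 2:
                expected = "none"
            elif n_neg >= 2:
                expected = "negative"
            elif n_pos >= 2:
                expected = "positive"
            else:
                expected = "none"
            assert out.consensus_call == expected


class TestEndToEnd:
    def test_planted_interactions_recovered(self):
        effects = np.array([0.5] * 10 + [-0.5] * 10)
        sim = synth.simulate_colony_screen(
            grid_rows=20, grid_cols=30, n_genes=500, n_interactors=20,
            effect_log10=effects, gradient_amplitude=0.3,
            small_colony_rate=0.02, seed=42,
        )
        res = sga.score_screen(sim.query_plates, sim.control_plates)
        truth = dict(zip(sim.truth["gene_id"], sim.truth["true_gis"]))
        planted = {g for g, v in truth.items() if v != 0}
        called = set(
            res.loc[res["consensus_call"].isin(["negative", "positive"]), "gene_id"]
        )
        sens = len(called & planted) / len(planted)
        fdp = len(called - planted) / max(len(called), 1)
        assert sens >= 0.9
        assert fdp <= 0.1

    def test_signs_match_planted_effects(self):
        sim = synth.simulate_colony_screen(
            n_interactors=10, effect_log10=-0.6, gradient_amplitude=0.2, seed=5
        )
        res = sga.score_screen(sim.query_plates, sim.control_plates)
        planted = set(sim.truth.loc[sim.truth["true_gis"] != 0, "gene_id"])
        calls = res.loc[res["gene_id"].isin(planted), "consensus_call"]
        assert (calls == "negative").mean() >= 0.9

    def test_linked_genes_reported_separately(self):
        sim = synth.simulate_colony_screen(seed=9)
        genes = list(sim.truth["gene_id"])
        anns = {
            g: sga.GeneAnnotation(g, "I", 10_000 * k) for k, g in enumerate(genes)
        }
        res = sga.score_screen(
            sim.query_plates, sim.control_plates,
            annotations=anns, loci=[genes[0]],
        )
        linked = res[res["consensus_call"] == "excluded_linked"]
        assert len(linked) == 26  # genes 0..25 lie within 250 kb of gene 0
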